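"""Procrustes superimposition and tangent-space coordinates.

Conventions (standard geometric morphometrics):

* *Partial* Procrustes fits: every configuration is translated to a zero
  centroid and scaled to unit centroid size; only a rotation is then fitted
  (no reflection during fitting — reflection enters the analysis explicitly
  through the matching-symmetry step).
* Generalized Procrustes analysis (GPA) iterates rotation onto the running
  consensus until the consensus stabilizes; the global rotational
  indeterminacy is resolved by aligning the consensus to the first input
  configuration.
* Tangent coordinates are the orthogonal projection of the aligned
  coordinates, relative to the consensus, off the four similarity directions
  (two translations, rotation, scaling) at the consensus.  For ``k`` 2-D
  landmarks the shape space therefore has ``2k - 4`` dimensions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Dataset

logger = logging.getLogger(__name__)

__all__ = [
    "centroid_size",
    "standardize",
    "ordinary_procrustes",
    "procrustes_distance",
    "gpa",
    "GPAResult",
    "matching_symmetry",
    "SymmetryDecomposition",
    "similarity_basis",
    "tangent_project",
    "pca_reduce",
    "PCModel",
]


def centroid_size(coords: np.ndarray) -> float:
    """Square root of the summed squared distances of landmarks to their
    centroid.  Scale-equivariant: ``centroid_size(c * X) == c * centroid_size(X)``.
    """
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt((centered**2).sum()))
    if cs == 0.0:
        raise ValueError("degenerate configuration: all landmarks coincide (zero centroid size)")
    return cs


def standardize(coords: np.ndarray) -> np.ndarray:
    """Translate to centroid origin and scale to unit centroid size."""
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    return centered / centroid_size(coords)


def _optimal_rotation(target: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """2x2 rotation matrix minimizing ||target @ R - reference||_F (closed form).

    Both inputs centered.  Pure rotation (det +1), never a reflection.
    """
    a = float(np.sum(target * reference))
    b = float(
        np.sum(target[:, 0] * reference[:, 1] - target[:, 1] * reference[:, 0])
    )
    theta = np.arctan2(b, a)
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, s], [-s, c]])


def ordinary_procrustes(
    reference: np.ndarray, target: np.ndarray, allow_reflection: bool = False
) -> tuple[np.ndarray, float]:
    """Superimpose ``target`` onto ``reference`` (both standardized internally).

    Returns the aligned target and the partial Procrustes distance — the root
    summed squared difference between the two unit-size, optimally rotated
    configurations.  With ``allow_reflection`` the better of the rotated and
    the reflected-then-rotated fit is returned.
    """
    reference, target = np.asarray(reference, float), np.asarray(target, float)
    if reference.shape != target.shape:
        raise ValueError(
            f"landmark count mismatch: reference {reference.shape} vs target {target.shape}"
        )
    ref = standardize(reference)
    tgt = standardize(target)
    aligned = tgt @ _optimal_rotation(tgt, ref)
    dist = float(np.sqrt(((aligned - ref) ** 2).sum()))
    if allow_reflection:
        mirrored = tgt * np.array([-1.0, 1.0])
        aligned_m = mirrored @ _optimal_rotation(mirrored, ref)
        dist_m = float(np.sqrt(((aligned_m - ref) ** 2).sum()))
        if dist_m < dist:
            return aligned_m, dist_m
    return aligned, dist


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two configurations."""
    return ordinary_procrustes(a, b)[1]


@dataclass
class GPAResult:
    """Outcome of a generalized Procrustes analysis.

    ``consensus`` has zero centroid and unit centroid size; ``aligned`` holds
    the superimposed unit-size configurations, ``(n, k, 2)``.
    """

    consensus: np.ndarray
    aligned: np.ndarray
    centroid_sizes: np.ndarray
    iterations: int
    converged: bool

    @property
    def k(self) -> int:
        return self.consensus.shape[0]

    @property
    def n(self) -> int:
        return self.aligned.shape[0]


def _rotate_all(stack: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """Rotate each configuration of ``stack`` (n, k, 2) onto ``consensus``."""
    a = np.einsum("nki,ki->n", stack, consensus)
    b = np.einsum("nk,k->n", stack[:, :, 0], consensus[:, 1]) - np.einsum(
        "nk,k->n", stack[:, :, 1], consensus[:, 0]
    )
    theta = np.arctan2(b, a)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.empty((len(stack), 2, 2))
    rot[:, 0, 0] = c
    rot[:, 0, 1] = s
    rot[:, 1, 0] = -s
    rot[:, 1, 1] = c
    return np.einsum("nkj,nji->nki", stack, rot)


def gpa(configs, tol: float = 1e-10, max_iter: int = 200) -> GPAResult:
    """Generalized Procrustes analysis of ``n >= 2`` configurations.

    Iterates {rotate each onto the consensus; recompute, recenter and
    renormalize the consensus} until the consensus moves by less than ``tol``
    (Frobenius norm).  Non-convergence is flagged, not raised.
    """
    stack = np.stack([np.asarray(c, float) for c in configs])
    if stack.shape[0] < 2:
        raise ValueError("GPA needs at least 2 configurations")
    sizes = np.array([centroid_size(c) for c in stack])
    stack = (stack - stack.mean(axis=1, keepdims=True)) / sizes[:, None, None]

    # Anchoring the consensus orientation to the first (standardized) input
    # every iteration removes the neutral global-rotation mode, which would
    # otherwise let the consensus drift and stall convergence; it also fixes
    # the rotational indeterminacy of the result deterministically.
    anchor = stack[0].copy()
    consensus = stack[0].copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        stack = _rotate_all(stack, consensus)
        new = standardize(stack.mean(axis=0))
        new = new @ _optimal_rotation(new, anchor)
        change = float(np.sqrt(((new - consensus) ** 2).sum()))
        consensus = new
        if change < tol:
            converged = True
            break
    if not converged:
        logger.warning("GPA did not converge in %d iterations", max_iter)
    stack = _rotate_all(stack, consensus)
    return GPAResult(
        consensus=consensus,
        aligned=stack,
        centroid_sizes=sizes,
        iterations=iterations,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Matching symmetry
# ---------------------------------------------------------------------------

@dataclass
class SymmetryDecomposition:
    """Per-individual symmetric and asymmetric shape components.

    After reflecting one side and a single joint GPA, the symmetric component
    is the mean of an individual's two side means and the asymmetric component
    the half-difference, so ``side mean = symmetric ± asymmetric`` exactly.
    The asymmetric component is retained for completeness but not used by the
    downstream genetic analyses.
    """

    specimens: list[str]
    strains: list[str]
    symmetric: np.ndarray  # (n_individuals, k, 2)
    asymmetric: np.ndarray  # (n_individuals, k, 2)

    def symmetric_table(self) -> pd.DataFrame:
        flat = self.symmetric.reshape(len(self.specimens), -1)
        df = pd.DataFrame(flat)
        df.insert(0, "strain", self.strains)
        df.insert(0, "specimen", self.specimens)
        return df


def matching_symmetry(
    dataset: Dataset, reflect_side: str = "R"
) -> tuple[SymmetryDecomposition, GPAResult, pd.DataFrame]:
    """Matching-symmetry superimposition of a paired-structure dataset.

    All configurations of ``reflect_side`` are reflected to their mirror
    images (x negated) and a single joint GPA is run over every configuration
    and replicate.  Specimens lacking one side are excluded with a logged
    warning.

    Returns the symmetry decomposition, the joint GPA result, and the
    metadata table aligned row-for-row with ``gpa.aligned`` (columns
    specimen, strain, side, replicate).
    """
    meta = dataset.meta()
    complete = meta.groupby("specimen")["side"].nunique()
    keep_specimens = set(complete[complete == 2].index)
    dropped = sorted(set(complete.index) - keep_specimens)
    if dropped:
        logger.warning(
            "matching_symmetry: excluding %d specimen(s) without both sides: %s",
            len(dropped),
            dropped,
        )
    keep = meta["specimen"].isin(keep_specimens).to_numpy()
    if keep.sum() < 2:
        raise ValueError("fewer than 2 usable configurations after completeness filter")
    coords = dataset.coords_array()[keep]
    meta = meta.loc[keep].reset_index(drop=True)

    reflected = coords.copy()
    is_reflect = (meta["side"] == reflect_side).to_numpy()
    reflected[is_reflect, :, 0] *= -1.0

    result = gpa(reflected)

    order = []
    symmetric, asymmetric, strains = [], [], []
    aligned = result.aligned
    for spec, grp in meta.groupby("specimen", sort=True):
        side_means = {
            side: aligned[grp.index[grp["side"] == side]].mean(axis=0)
            for side in ("L", "R")
        }
        order.append(str(spec))
        strains.append(str(grp["strain"].iloc[0]))
        symmetric.append((side_means["L"] + side_means["R"]) / 2.0)
        asymmetric.append((side_means["L"] - side_means["R"]) / 2.0)

    decomp = SymmetryDecomposition(
        specimens=order,
        strains=strains,
        symmetric=np.stack(symmetric),
        asymmetric=np.stack(asymmetric),
    )
    return decomp, result, meta


# ---------------------------------------------------------------------------
# Tangent space
# ---------------------------------------------------------------------------

def similarity_basis(consensus: np.ndarray) -> np.ndarray:
    """Orthonormal basis ``(2k, 4)`` of the similarity-transform directions at
    a centered, unit-size consensus: x-translation, y-translation, rotation,
    scaling.  These four vectors are mutually orthogonal by construction.
    """
    consensus = np.asarray(consensus, float)
    k = consensus.shape[0]
    tx = np.zeros((k, 2))
    tx[:, 0] = 1.0 / np.sqrt(k)
    ty = np.zeros((k, 2))
    ty[:, 1] = 1.0 / np.sqrt(k)
    scale = consensus.copy()  # unit Frobenius norm already
    rot = np.column_stack([-consensus[:, 1], consensus[:, 0]])
    basis = np.column_stack(
        [tx.ravel(), ty.ravel(), rot.ravel() / np.linalg.norm(rot), scale.ravel()]
    )
    # Guard against a slightly off-spec consensus (non-zero centroid etc.).
    q, _ = np.linalg.qr(basis)
    return q


def tangent_project(result: GPAResult) -> np.ndarray:
    """Project aligned coordinates into the tangent space at the consensus.

    Returns an ``(n, 2k)`` matrix of tangent coordinates: the deviation of
    each aligned configuration from the consensus, with the four similarity
    directions removed by orthogonal projection.  The covariance of these
    coordinates has rank at most ``2k - 4``.
    """
    if not result.converged:
        logger.warning("tangent_project called on a non-converged GPA result")
    flat = result.aligned.reshape(result.n, -1) - result.consensus.ravel()
    basis = similarity_basis(result.consensus)
    return flat - (flat @ basis) @ basis.T


def project_vector(vector: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """Project a single ``(k, 2)`` displacement off the similarity directions
    at ``consensus``; returns a ``(k, 2)`` shape-space displacement."""
    basis = similarity_basis(consensus)
    flat = np.asarray(vector, float).ravel()
    out = flat - basis @ (basis.T @ flat)
    return out.reshape(-1, 2)


# ---------------------------------------------------------------------------
# PCA reduction
# ---------------------------------------------------------------------------

@dataclass
class PCModel:
    """Principal components of the tangent coordinates.

    ``loadings`` are orthonormal directions (columns, in tangent space),
    ``scores`` the centered data expressed on them.  ``variance_fractions``
    covers *all* components (sums to 1); ``n_retained`` marks the reduced set
    used by downstream tests.
    """

    eigenvalues: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    variance_fractions: np.ndarray
    n_retained: int
    mean: np.ndarray

    @property
    def retained_scores(self) -> np.ndarray:
        return self.scores[:, : self.n_retained]


def pca_reduce(
    tangent: np.ndarray,
    n_components: int | None = 14,
    variance_threshold: float | None = None,
) -> PCModel:
    """Eigendecomposition of the tangent covariance matrix.

    Retention policy: a fixed count (default 14, the usual choice for this
    design, capped at the matrix rank with a warning) or the smallest number
    of components reaching ``variance_threshold`` of total variance.
    """
    X = np.asarray(tangent, float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 observations")
    mean = X.mean(axis=0)
    Xc = X - mean
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = s**2 / (X.shape[0] - 1)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size and s[0] > 0 else 0
    eigenvalues = eigenvalues[:rank]
    loadings = vt[:rank].T
    scores = Xc @ loadings
    fractions = eigenvalues / eigenvalues.sum()
    if variance_threshold is not None:
        n_retained = int(np.searchsorted(np.cumsum(fractions), variance_threshold) + 1)
        n_retained = min(n_retained, rank)
    else:
        n_retained = int(n_components if n_components is not None else rank)
        if n_retained > rank:
            logger.warning(
                "requested %d components but rank is %d; capping", n_retained, rank
            )
            n_retained = rank
    return PCModel(
        eigenvalues=eigenvalues,
        loadings=loadings,
        scores=scores,
        variance_fractions=fractions,
        n_retained=n_retained,
        mean=mean,
    )
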