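"""Modularity and integration of landmark blocks.

The RV coefficient (Escoufier) measures multivariate association between two
blocks of variables; here the blocks are the x/y coordinate columns of two
landmark sets extracted from a single joint superimposition.  The modularity
test compares the RV of an a-priori bipartition against its distribution over
all same-size bipartitions (and over the anatomically contiguous subset, i.e.
bipartitions whose blocks both induce connected subgraphs of an adjacency
graph): a left-tail observed value supports the modularity hypothesis.

Integration between the two a-priori blocks is quantified with two-block
partial least squares — a singular value decomposition of the cross-block
covariance — assessed by row permutation of one block.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from .io import AdjacencyGraph

__all__ = [
    "PartitionHypothesis",
    "RvTestResult",
    "PlsResult",
    "rv_coefficient",
    "enumerate_bipartitions",
    "count_bipartitions",
    "contiguous_subset",
    "rv_partition_test",
    "left_tail_p",
    "two_block_pls",
    "pls_permutation_test",
]


@dataclass(frozen=True)
class PartitionHypothesis:
    """An a-priori bipartition of landmarks 1..k plus the adjacency graph
    used to decide contiguity."""

    block_a: frozenset[int]
    block_b: frozenset[int]
    graph: AdjacencyGraph

    def __post_init__(self):
        a, b = frozenset(self.block_a), frozenset(self.block_b)
        k = self.graph.k
        if a & b or (a | b) != frozenset(range(1, k + 1)):
            raise ValueError("blocks must cover landmarks 1..k disjointly")
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each block needs at least 2 landmarks")
        object.__setattr__(self, "block_a", a)
        object.__setattr__(self, "block_b", b)

    @property
    def sizes(self) -> tuple[int, int]:
        return len(self.block_a), len(self.block_b)


@dataclass
class RvTestResult:
    """Observed RV with its distribution over enumerated bipartitions.

    ``p_full`` (and ``p_contiguous``) is the exact left-tail proportion:
    the count of enumerated partitions with RV at or below the observed one
    (the observed partition included) over the number enumerated.
    """

    observed_rv: float
    n_total_partitions: int
    n_contiguous: int
    count_leq_full: int
    count_leq_contiguous: int
    p_full: float
    p_contiguous: float
    rv_distribution: np.ndarray
    contiguous_mask: np.ndarray
    partitions: list[frozenset[int]]


@dataclass
class PlsResult:
    """Two-block PLS decomposition of the cross-block covariance."""

    singular_values: np.ndarray
    covariance_fractions: np.ndarray
    x_scores: np.ndarray
    y_scores: np.ndarray
    score_correlations: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    degenerate: bool = False
    permutation_p_covariance: float | None = None
    permutation_p_correlation: float | None = None
    n_permutations: int | None = None
    seed: int | None = None


def _center(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, float)
    return M - M.mean(axis=0)


def rv_coefficient(X: np.ndarray, Y: np.ndarray) -> float:
    """Escoufier's RV between two blocks of variables on the same
    observations:

        RV = trace(Sxy Syx) / sqrt(trace(Sxx^2) * trace(Syy^2))

    with S the sample covariance blocks (columns centered internally).
    Lies in [0, 1]; equals 1 for identical blocks.
    """
    X, Y = _center(X), _center(Y)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("blocks must share observations")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    n = X.shape[0]
    sxx = X.T @ X / (n - 1)
    syy = Y.T @ Y / (n - 1)
    sxy = X.T @ Y / (n - 1)
    denom = np.sqrt((sxx**2).sum() * (syy**2).sum())
    if denom == 0:
        raise ValueError("zero within-block variation")
    return float((sxy**2).sum() / denom)


def count_bipartitions(k: int, sizes: tuple[int, int]) -> int:
    """Closed-form count of unordered bipartitions of 1..k into the given
    block sizes: C(k, a), halved when the blocks have equal size."""
    a, b = sizes
    if a + b != k:
        raise ValueError(f"sizes {sizes} do not sum to k={k}")
    if a < 2 or b < 2:
        raise ValueError("each block needs at least 2 landmarks")
    return comb(k, a) // 2 if a == b else comb(k, a)


def enumerate_bipartitions(k: int, sizes: tuple[int, int]):
    """Yield every unordered bipartition of 1..k with the given block sizes,
    each exactly once, as the frozenset of the first block.

    For equal sizes, landmark 1 is pinned to the first block so each
    unordered pair appears once.
    """
    a, b = sizes
    count_bipartitions(k, sizes)  # validates
    universe = range(1, k + 1)
    if a == b:
        rest = range(2, k + 1)
        for extra in combinations(rest, a - 1):
            yield frozenset((1,) + extra)
    else:
        for block in combinations(universe, a):
            yield frozenset(block)


def contiguous_subset(partitions, graph: AdjacencyGraph):
    """Filter bipartitions to those where BOTH blocks induce connected
    subgraphs of the adjacency graph."""
    full = frozenset(range(1, graph.k + 1))
    out = []
    for block_a in partitions:
        block_b = full - block_a
        if graph.is_connected_block(block_a) and graph.is_connected_block(block_b):
            out.append(block_a)
    return out


def left_tail_p(values: np.ndarray, observed: float) -> tuple[int, float]:
    """Exact left-tail empirical p: count of values <= observed (with a tiny
    numerical cushion so the observed partition always counts itself) over
    the total."""
    values = np.asarray(values, float)
    count = int(np.sum(values <= observed + 1e-12))
    return count, count / len(values)


#: memoized contiguity masks keyed by (k, sizes, graph edge set)
_CONTIG_CACHE: dict = {}


def _block_columns(block: frozenset[int]) -> np.ndarray:
    idx = np.array(sorted(block)) - 1
    return np.ravel(np.column_stack([2 * idx, 2 * idx + 1]))


def rv_partition_test(data: np.ndarray, hypothesis: PartitionHypothesis) -> RvTestResult:
    """Test an a-priori landmark bipartition against all same-size
    alternatives.

    ``data`` is an (n, 2k) matrix of tangent (or symmetric-shape) coordinates
    — strain means for the genetic-variation reading, or individual
    specimens.  The RV of every enumerated bipartition is computed from the
    single full covariance matrix (the squared Frobenius norms of its blocks),
    so the full 6435-partition scan for k=16 is immediate.
    """
    data = _center(np.asarray(data, float))
    n, q = data.shape
    k = hypothesis.graph.k
    if q != 2 * k:
        raise ValueError(f"data has {q} columns, expected {2 * k}")
    if n < 3:
        raise ValueError("need at least 3 observations")
    sizes = hypothesis.sizes
    a = min(sizes)
    # enumerate with the smaller block size first for a canonical ordering
    size_pair = (a, k - a)

    S = data.T @ data / (n - 1)
    S2 = S**2

    partitions = list(enumerate_bipartitions(k, size_pair))
    # Column-mask matrix (one row per partition) turns the scan into matrix
    # products: RV needs only the squared Frobenius norms of the covariance
    # blocks, and ||S_ab||^2, ||S_bb||^2 follow from row totals.
    masks = np.zeros((len(partitions), 2 * k))
    for i, block in enumerate(partitions):
        masks[i, _block_columns(block)] = 1.0
    ms2 = masks @ S2
    within_a = (ms2 * masks).sum(axis=1)
    total_a_rows = ms2.sum(axis=1)
    cross2 = total_a_rows - within_a  # = ||S_ab||_F^2
    within_b = S2.sum() - total_a_rows - cross2  # = ||S_bb||_F^2
    rvs = cross2 / np.sqrt(within_a * within_b)

    obs_block = (
        hypothesis.block_a if len(hypothesis.block_a) == a else hypothesis.block_b
    )
    # canonicalize: when sizes are equal the enumeration pins landmark 1
    if size_pair[0] == size_pair[1] and 1 not in obs_block:
        obs_block = frozenset(range(1, k + 1)) - obs_block
    try:
        obs_idx = partitions.index(obs_block)
    except ValueError as exc:
        raise ValueError("hypothesis blocks do not match the enumeration sizes") from exc
    observed = float(rvs[obs_idx])

    cache_key = (k, size_pair, frozenset(map(frozenset, hypothesis.graph.edges)))
    mask = _CONTIG_CACHE.get(cache_key)
    if mask is None:
        contig = set(contiguous_subset(partitions, hypothesis.graph))
        mask = np.array([p in contig for p in partitions])
        _CONTIG_CACHE[cache_key] = mask
    count_full, p_full = left_tail_p(rvs, observed)
    if mask.any():
        count_contig, p_contig = left_tail_p(rvs[mask], observed)
    else:
        count_contig, p_contig = 0, float("nan")
    return RvTestResult(
        observed_rv=observed,
        n_total_partitions=len(partitions),
        n_contiguous=int(mask.sum()),
        count_leq_full=count_full,
        count_leq_contiguous=count_contig,
        p_full=p_full,
        p_contiguous=p_contig,
        rv_distribution=rvs,
        contiguous_mask=mask,
        partitions=partitions,
    )


def two_block_pls(X: np.ndarray, Y: np.ndarray) -> PlsResult:
    """Two-block partial least squares: SVD of the cross-block covariance.

    Per axis: paired linear-combination scores, their correlation, and the
    covariance fraction ``sigma_i^2 / sum sigma^2``; axes are ordered by
    decreasing singular value.  A rank-0 cross-covariance yields a flagged
    degenerate result rather than an error.
    """
    Xc, Yc = _center(X), _center(Y)
    if Xc.shape[0] != Yc.shape[0]:
        raise ValueError("blocks must share observations")
    if Xc.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    n = Xc.shape[0]
    sxy = Xc.T @ Yc / (n - 1)
    u, s, vt = np.linalg.svd(sxy, full_matrices=False)
    if s.sum() == 0:
        return PlsResult(
            singular_values=s,
            covariance_fractions=np.zeros_like(s),
            x_scores=np.zeros((n, 0)),
            y_scores=np.zeros((n, 0)),
            score_correlations=np.zeros(0),
            x_loadings=u,
            y_loadings=vt.T,
            degenerate=True,
        )
    fractions = s**2 / (s**2).sum()
    xs = Xc @ u
    ys = Yc @ vt.T
    corrs = np.array(
        [
            np.corrcoef(xs[:, i], ys[:, i])[0, 1] if s[i] > 0 else np.nan
            for i in range(len(s))
        ]
    )
    return PlsResult(
        singular_values=s,
        covariance_fractions=fractions,
        x_scores=xs,
        y_scores=ys,
        score_correlations=corrs,
        x_loadings=u,
        y_loadings=vt.T,
    )


def pls_permutation_test(
    X: np.ndarray, Y: np.ndarray, n_perm: int = 10000, seed: int | None = None
) -> PlsResult:
    """Permutation assessment of the two-block PLS.

    Rows of ``Y`` are permuted ``n_perm`` times; for the total squared
    cross-covariance and the axis-1 score correlation,
    ``p = (1 + #{permuted >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    result = two_block_pls(X, Y)
    Xc, Yc = _center(X), _center(Y)
    n = Xc.shape[0]
    obs_cov = float((result.singular_values**2).sum())
    obs_corr = float(result.score_correlations[0]) if result.score_correlations.size else 0.0
    rng = np.random.default_rng(seed)
    ge_cov = 0
    ge_corr = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Yp = Yc[perm]
        sxy = Xc.T @ Yp / (n - 1)
        u, s, vt = np.linalg.svd(sxy, full_matrices=False)
        if float((s**2).sum()) >= obs_cov:
            ge_cov += 1
        if s[0] > 0:
            xs = Xc @ u[:, 0]
            ys = Yp @ vt[0]
            if np.corrcoef(xs, ys)[0, 1] >= obs_corr:
                ge_corr += 1
    result.permutation_p_covariance = (1 + ge_cov) / (n_perm + 1)
    result.permutation_p_correlation = (1 + ge_corr) / (n_perm + 1)
    result.n_permutations = n_perm
    result.seed = seed
    return result
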