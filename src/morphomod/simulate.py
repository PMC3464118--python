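"""Synthetic paired-structure landmark datasets with a congenic-panel design.

The generator emulates the statistical structure the downstream analyses
assume: a panel of inbred strains (one reference plus congenic strains each
carrying a few donor-genome segments), several individuals per strain, two
sides per individual (the right side observed as a mirror image), and two
digitization replicates per side.

Per (strain g, individual i, side s, replicate r) the underlying left-form
configuration is

    template + a_g + b_i ± delta + e_is + eps_isr

where every term lives in the ``2k - 4``-dimensional shape space at the
template:

* ``a_g`` — strain effect: the sum of one effect vector per donor segment,
  each of magnitude ``additivity_coefficient * (segment Mb share)`` so that
  strain effect size grows with donor-genome content, with directions mixing
  a within-module component and an isotropic component according to the
  modularity fraction ``rho``;
* ``b_i`` — isotropic individual deviation;
* ``±delta`` — a fixed side displacement (directional asymmetry), ``+`` on
  the left and ``-`` on the right form;
* ``e_is`` — individual-by-side deviation (fluctuating asymmetry);
* ``eps_isr`` — digitization error.

Each random term's variance is ``variance_proportions[effect] *
total_variance`` (expected squared Procrustes norm); the side displacement is
a fixed vector of squared norm ``p_side * total_variance``.  Every emitted
configuration finally receives an arbitrary similarity transform (rotation,
translation, mild scale jitter) so that superimposition is actually
exercised; the right side is emitted mirrored (x negated).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import null_space

from .io import Dataset, LandmarkConfiguration, StrainRecord, load_strain_table, load_template_shape
from .procrustes import similarity_basis, standardize

__all__ = ["SimulationParams", "default_params", "simulate_dataset"]

EFFECTS = ("strain", "individual", "side", "individual_x_side", "error")

#: Overall variance shares of the five design effects used by
#: :func:`default_params` (strain, individual, side, individual-by-side
#: i.e. fluctuating asymmetry, digitization error), as percentages.
DEFAULT_PCT = {
    "strain": 77.52,
    "individual": 6.49,
    "side": 6.71,
    "individual_x_side": 5.07,
    "error": 4.18,
}


@dataclass
class SimulationParams:
    """Parameters of the synthetic-data generator.

    ``variance_proportions`` maps the five effects to nonnegative weights
    summing to 1.  ``total_variance`` is the expected per-observation squared
    Procrustes deviation from the grand mean (squared Procrustes distance
    units, so typically ~1e-4 for within-species craniofacial variation).
    ``additivity_coefficient`` is the shape-effect magnitude per donor Mb;
    when ``None`` the strain-effect magnitudes are rescaled so their realized
    fixed-effect variance equals the strain share of ``total_variance``.
    ``modularity_mixing`` (rho) is the fraction of strain-effect variance
    confined to within-module directions of ``module_partition``.
    """

    template_shape: np.ndarray
    module_partition: tuple[frozenset[int], frozenset[int]]
    variance_proportions: dict[str, float]
    total_variance: float = 3.0e-4
    additivity_coefficient: float | None = None
    modularity_mixing: float = 0.75
    replicates: int = 2
    scale_jitter: float = 0.03
    seed: int = 20121001

    def __post_init__(self):
        self.template_shape = standardize(np.asarray(self.template_shape, float))
        k = self.template_shape.shape[0]
        a, b = (frozenset(self.module_partition[0]), frozenset(self.module_partition[1]))
        if a & b or (a | b) != frozenset(range(1, k + 1)):
            raise ValueError("module_partition must cover landmarks 1..k disjointly")
        self.module_partition = (a, b)
        missing = set(EFFECTS) - set(self.variance_proportions)
        if missing:
            raise ValueError(f"variance_proportions missing effects {sorted(missing)}")
        props = np.array([self.variance_proportions[e] for e in EFFECTS], float)
        if np.any(props < 0):
            raise ValueError("variance proportions must be nonnegative")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(f"variance proportions must sum to 1, got {props.sum()}")
        if not 0.0 <= self.modularity_mixing <= 1.0:
            raise ValueError("modularity_mixing must lie in [0, 1]")
        if self.total_variance < 0:
            raise ValueError("total_variance must be nonnegative")

    @property
    def k(self) -> int:
        return self.template_shape.shape[0]


def default_params(seed: int = 20121001) -> SimulationParams:
    """Study-design defaults: the packaged 16-landmark template, the anterior
    alveolar {1-4, 13-16} vs ascending-ramus {5-12} partition, and variance
    shares 77.52 / 6.49 / 6.71 / 5.07 / 4.18 % (strain / individual / side /
    side-by-individual / error), normalized to sum to one."""
    total_pct = sum(DEFAULT_PCT.values())
    proportions = {k: v / total_pct for k, v in DEFAULT_PCT.items()}
    alveolar = frozenset([1, 2, 3, 4, 13, 14, 15, 16])
    ramus = frozenset(range(5, 13))
    return SimulationParams(
        template_shape=load_template_shape(),
        module_partition=(alveolar, ramus),
        variance_proportions=proportions,
        seed=seed,
    )


def _module_basis(template: np.ndarray, landmarks: frozenset[int]) -> np.ndarray:
    """Orthonormal basis (2k, m) of shape-space directions supported only on
    the given (1-based) landmarks.

    A vector supported on a landmark subset lies in shape space iff it is
    orthogonal to the four similarity directions; that intersection has
    dimension ``2*|subset| - 4`` for a generic template.  Using such bases
    keeps within-module effects *exactly* block-diagonal: they displace no
    landmark of the other module.
    """
    k = template.shape[0]
    idx = sorted(landmarks)
    cols = np.array([[2 * (j - 1), 2 * (j - 1) + 1] for j in idx]).ravel()
    sim = similarity_basis(template)  # (2k, 4)
    constraints = sim[cols, :].T  # (4, 2m): similarity rows restricted to support
    local = null_space(constraints)  # (2m, 2m-4)
    basis = np.zeros((2 * k, local.shape[1]))
    basis[cols, :] = local
    return basis


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length direction")
    return v / n


def simulate_dataset(params: SimulationParams, strains: list[StrainRecord] | None = None) -> Dataset:
    """Generate a full paired-structure dataset for a strain panel.

    ``strains`` defaults to the packaged study design table.  Exactly one
    record must be flagged as the reference; it receives a zero strain
    effect.  The output contains, per individual, 2 sides x ``replicates``
    digitizations; the right side is emitted as the mirrored copy of its
    underlying left-form.  Bit-identical for identical seed and parameters.
    """
    if strains is None:
        strains = load_strain_table()
    if not strains:
        raise ValueError("strain list is empty")
    refs = [s for s in strains if s.is_reference]
    if len(refs) != 1:
        raise ValueError(f"need exactly one reference strain, found {len(refs)}")

    rng = np.random.default_rng(params.seed)
    template = params.template_shape
    k = params.k
    dim = 2 * k - 4

    sim = similarity_basis(template)
    shape_basis = null_space(sim.T)  # (2k, 2k-4) orthonormal shape-space basis
    module_bases = [_module_basis(template, m) for m in params.module_partition]

    def draw_shape_vec(scale: float, size: int = 1) -> np.ndarray:
        """(size, 2k) isotropic shape-space draws, per-dim sd ``scale``."""
        z = rng.normal(0.0, scale, size=(size, shape_basis.shape[1]))
        return z @ shape_basis.T

    v_total = params.total_variance
    p = params.variance_proportions
    per_dim = {e: np.sqrt(p[e] * v_total / dim) for e in EFFECTS}

    # --- strain effects -----------------------------------------------------
    rho = params.modularity_mixing
    effects: dict[str, np.ndarray] = {}
    for rec in strains:
        if rec.is_reference or rec.n_segments == 0:
            effects[rec.strain_id] = np.zeros(2 * k)
            continue
        a = np.zeros(2 * k)
        share = rec.seg_mb / rec.n_segments
        for _ in range(rec.n_segments):
            mod = module_bases[rng.integers(0, 2)]
            w = _unit(mod @ rng.normal(size=mod.shape[1]))
            z = _unit(shape_basis @ rng.normal(size=shape_basis.shape[1]))
            direction = _unit(np.sqrt(rho) * w + np.sqrt(1.0 - rho) * z)
            coeff = params.additivity_coefficient if params.additivity_coefficient is not None else 1.0
            a += coeff * share * direction
        effects[rec.strain_id] = a

    if params.additivity_coefficient is None:
        # Calibrate magnitudes so the weighted fixed-effect variance matches
        # the strain share of total_variance under the expected-mean-squares
        # convention: sum_g n_g |a_g - a_bar|^2 / ((G-1) * n_bar) = p_s * V.
        n_g = np.array([s.n_mice for s in strains], float)
        A = np.stack([effects[s.strain_id] for s in strains])
        a_bar = (n_g[:, None] * A).sum(axis=0) / n_g.sum()
        ss = float((n_g * ((A - a_bar) ** 2).sum(axis=1)).sum())
        g = len(strains)
        target = p["strain"] * v_total * (g - 1) * n_g.mean()
        c = np.sqrt(target / ss) if ss > 0 else 0.0
        effects = {sid: c * a for sid, a in effects.items()}

    # --- fixed directional asymmetry ---------------------------------------
    if p["side"] > 0:
        delta = _unit(shape_basis @ rng.normal(size=dim)) * np.sqrt(p["side"] * v_total)
    else:
        delta = np.zeros(2 * k)

    # --- individuals --------------------------------------------------------
    configs: list[LandmarkConfiguration] = []
    flat_template = template.ravel()
    mirror = np.ones(2 * k)
    mirror[0::2] = -1.0
    for rec in strains:
        a_g = effects[rec.strain_id]
        for i in range(rec.n_mice):
            spec_id = f"{rec.strain_id.replace('/', '')}-m{i + 1:02d}"
            b = draw_shape_vec(per_dim["individual"])[0]
            fa = {s: draw_shape_vec(per_dim["individual_x_side"])[0] for s in ("L", "R")}
            for side, sign in (("L", 1.0), ("R", -1.0)):
                form = flat_template + a_g + b + sign * delta + fa[side]
                for r in range(1, params.replicates + 1):
                    obs = form + draw_shape_vec(per_dim["error"])[0]
                    if side == "R":
                        obs = obs * mirror
                    coords = obs.reshape(k, 2)
                    theta = rng.uniform(0.0, 2.0 * np.pi)
                    c, s_ = np.cos(theta), np.sin(theta)
                    rot = np.array([[c, s_], [-s_, c]])
                    scale = float(np.exp(rng.normal(0.0, params.scale_jitter)))
                    shift = rng.uniform(-0.5, 0.5, size=2)
                    coords = scale * (coords @ rot) + shift
                    configs.append(
                        LandmarkConfiguration(spec_id, rec.strain_id, side, r, coords)
                    )
    return Dataset(configurations=configs, strain_table=list(strains))


def with_overrides(params: SimulationParams, **kwargs) -> SimulationParams:
    """Return a copy of ``params`` with fields replaced (convenience)."""
    return replace(params, **kwargs)
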