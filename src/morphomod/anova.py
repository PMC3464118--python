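"""Procrustes ANOVA: variance decomposition of superimposed shape data.

The design is strain / individual(strain) / side / individual-by-side /
digitization error.  Sums of squares are squared deviations summed over all
``2k`` coordinates of the jointly superimposed (side-reflected) tangent data;
Procrustes degrees of freedom are the univariate design dfs multiplied by the
shape-space dimension ``2k - 4`` (or by 2 for per-landmark tables).

Variance components are solved from the expected mean squares of the mixed
model (side fixed, individual random, strain estimated "as if random" for
quantification), with ``r`` replicates, ``s = 2`` sides, ``N`` individuals,
``G`` strains and ``n_bar`` the mean number of individuals per strain:

    MS_error          = sigma2_error
    MS_ind_x_side     = sigma2_error + r * sigma2_fa
    MS_individual     = sigma2_error + r * sigma2_fa + r*s * sigma2_ind
    MS_strain         = MS_individual ladder + r*s*n_bar * sigma2_strain
    MS_side           = sigma2_error + r * sigma2_fa
                        + r*N*s/(s-1) * sigma2_side

The side coefficient makes the reported side component equal the
per-observation variance contributed by the fixed side displacement, keeping
all five components on the same per-observation scale.  Negative solutions
are truncated at zero.  Goodall-style F ratios follow the same ladder
(strain over individual, individual / side over the interaction, interaction
over error).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaTable",
    "LandmarkVarianceTable",
    "procrustes_anova",
    "landmark_variance_components",
    "pct_by_landmark_group",
]

EFFECT_ORDER = ["individual", "strain", "side", "individual_x_side", "error"]
_LABELS = {
    "individual": "Individuals (I)",
    "strain": "Strain",
    "side": "Side (S)",
    "individual_x_side": "I x S",
    "error": "Error",
}


@dataclass
class AnovaTable:
    """Overall Procrustes ANOVA table.

    ``table`` has one row per effect with columns ``sum_of_squares, df,
    mean_square, variance_component, pct_variance, goodall_f, p``; dfs are
    Procrustes dfs (univariate df x shape dimension).
    """

    table: pd.DataFrame
    shape_dimension: int
    design: dict

    def df(self, effect: str) -> int:
        return int(self.table.loc[effect, "df"])

    def pct(self, effect: str) -> float:
        return float(self.table.loc[effect, "pct_variance"])

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out.index = [_LABELS[e] for e in out.index]
        return out


@dataclass
class LandmarkVarianceTable:
    """Variance components per effect and landmark (squared Procrustes units).

    ``components`` is an effects x landmarks DataFrame (columns 1..k,
    1-based landmark labels)."""

    components: pd.DataFrame

    @property
    def k(self) -> int:
        return self.components.shape[1]


def _design_arrays(meta: pd.DataFrame):
    spec = meta["specimen"].to_numpy()
    strain = meta["strain"].to_numpy()
    side = meta["side"].to_numpy()
    specimens, spec_idx = np.unique(spec, return_inverse=True)
    strains, strain_idx = np.unique(strain, return_inverse=True)
    sides, side_idx = np.unique(side, return_inverse=True)
    if len(sides) != 2:
        raise ValueError("Procrustes ANOVA needs exactly two sides")
    cell_key = spec_idx * 2 + side_idx
    cells, cell_idx = np.unique(cell_key, return_inverse=True)
    return specimens, spec_idx, strains, strain_idx, side_idx, cells, cell_idx


def _sums_of_squares(Y: np.ndarray, meta: pd.DataFrame) -> tuple[dict, dict, dict]:
    """Decompose ``Y`` (n_obs x q) by the nested/crossed design.

    Returns (per-column SS arrays by effect, univariate dfs, design info).
    Side and replicate must be balanced within individuals; strain sizes may
    be unbalanced.
    """
    specimens, spec_idx, strains, strain_idx, side_idx, cells, cell_idx = _design_arrays(meta)
    n_obs = Y.shape[0]
    n_spec, n_strain, n_cells = len(specimens), len(strains), len(cells)
    if n_cells != 2 * n_spec:
        raise ValueError("each specimen must be digitized on both sides")
    counts_cell = np.bincount(cell_idx)
    if counts_cell.min() < 2:
        raise ValueError("error stratum undefined: every specimen x side needs >= 2 replicates")
    if counts_cell.min() != counts_cell.max():
        raise ValueError("replicate counts must be balanced across specimen x side cells")
    r = int(counts_cell[0])
    s = 2

    grand = Y.mean(axis=0)

    def group_means(idx, n_groups):
        sums = np.zeros((n_groups, Y.shape[1]))
        np.add.at(sums, idx, Y)
        counts = np.bincount(idx, minlength=n_groups).astype(float)
        return sums / counts[:, None], counts

    m_strain, c_strain = group_means(strain_idx, n_strain)
    m_spec, c_spec = group_means(spec_idx, n_spec)
    m_side, c_side = group_means(side_idx, 2)
    m_cell, c_cell = group_means(cell_idx, n_cells)

    ss = {}
    ss["strain"] = (c_strain[:, None] * (m_strain - grand) ** 2).sum(axis=0)
    # individuals nested in strain
    spec_strain = np.zeros(n_spec, dtype=int)
    spec_strain[spec_idx] = strain_idx
    ss["individual"] = (c_spec[:, None] * (m_spec - m_strain[spec_strain]) ** 2).sum(axis=0)
    ss["side"] = (c_side[:, None] * (m_side - grand) ** 2).sum(axis=0)
    # interaction: cell mean - individual mean - side mean + grand
    cell_spec = np.zeros(n_cells, dtype=int)
    cell_spec[cell_idx] = spec_idx
    cell_side = np.zeros(n_cells, dtype=int)
    cell_side[cell_idx] = side_idx
    inter = m_cell - m_spec[cell_spec] - m_side[cell_side] + grand
    ss["individual_x_side"] = (c_cell[:, None] * inter**2).sum(axis=0)
    ss["error"] = ((Y - m_cell[cell_idx]) ** 2).sum(axis=0)

    n_per_strain = np.bincount(spec_strain, minlength=n_strain)

    dfs = {
        "strain": n_strain - 1,
        "individual": n_spec - n_strain,
        "side": s - 1,
        "individual_x_side": n_spec - 1,
        "error": n_obs - n_cells,
    }
    design = {
        "n_obs": n_obs,
        "n_individuals": n_spec,
        "n_strains": n_strain,
        "replicates": r,
        "sides": s,
        "individuals_per_strain": n_per_strain,
    }
    return ss, dfs, design


def _solve_components(ms: dict[str, float], design: dict, n_bar: str = "arithmetic"):
    """Solve the expected-mean-squares ladder; truncate negatives at zero."""
    r, s, n_ind = design["replicates"], design["sides"], design["n_individuals"]
    per = design["individuals_per_strain"]
    nbar = float(np.mean(per)) if n_bar == "arithmetic" else float(stats.hmean(per))
    comp = {
        "error": ms["error"],
        "individual_x_side": (ms["individual_x_side"] - ms["error"]) / r,
        "individual": (ms["individual"] - ms["individual_x_side"]) / (r * s),
        "strain": (ms["strain"] - ms["individual"]) / (r * s * nbar),
        "side": (ms["side"] - ms["individual_x_side"]) / (r * n_ind * s / (s - 1)),
    }
    return {e: max(0.0, v) for e, v in comp.items()}


_F_DENOM = {
    "strain": "individual",
    "individual": "individual_x_side",
    "side": "individual_x_side",
    "individual_x_side": "error",
}


def procrustes_anova(
    tangent: np.ndarray, meta: pd.DataFrame, k: int, n_bar: str = "arithmetic"
) -> AnovaTable:
    """Overall Procrustes ANOVA of jointly superimposed tangent coordinates.

    ``tangent`` is the (n_obs, 2k) tangent matrix from the matching-symmetry
    superimposition (rows aligned with ``meta``: specimen, strain, side,
    replicate).  ``n_bar`` selects the arithmetic (default) or harmonic mean
    of individuals per strain in the strain EMS coefficient.
    """
    Y = np.asarray(tangent, float)
    if Y.shape[1] != 2 * k:
        raise ValueError(f"tangent matrix has {Y.shape[1]} columns, expected {2 * k}")
    ss_cols, dfs_uni, design = _sums_of_squares(Y, meta)
    dim = 2 * k - 4
    rows = {}
    ms = {}
    for e in EFFECT_ORDER:
        ss = float(ss_cols[e].sum())
        df = dfs_uni[e] * dim
        ms[e] = ss / df
        rows[e] = {"sum_of_squares": ss, "df": df, "mean_square": ms[e]}
    comps = _solve_components(ms, design, n_bar=n_bar)
    total = sum(comps.values())
    for e in EFFECT_ORDER:
        rows[e]["variance_component"] = comps[e]
        rows[e]["pct_variance"] = 100.0 * comps[e] / total if total > 0 else np.nan
        denom = _F_DENOM.get(e)
        if denom is not None:
            f = ms[e] / ms[denom]
            rows[e]["goodall_f"] = f
            rows[e]["p"] = float(
                stats.f.sf(f, dfs_uni[e] * dim, dfs_uni[denom] * dim)
            )
        else:
            rows[e]["goodall_f"] = np.nan
            rows[e]["p"] = np.nan
    table = pd.DataFrame.from_dict(rows, orient="index").loc[EFFECT_ORDER]
    table["df"] = table["df"].astype(int)
    return AnovaTable(table=table, shape_dimension=dim, design=design)


def landmark_variance_components(
    tangent: np.ndarray, meta: pd.DataFrame, k: int, n_bar: str = "arithmetic"
) -> LandmarkVarianceTable:
    """Per-landmark variance components.

    For each landmark the x and y sums of squares are pooled, the univariate
    design dfs are multiplied by 2 (two coordinates), and the same
    expected-mean-squares solve is applied.  Summing a landmark table row
    over landmarks reproduces the overall SS per effect exactly.
    """
    Y = np.asarray(tangent, float)
    ss_cols, dfs_uni, design = _sums_of_squares(Y, meta)
    out = {}
    for j in range(k):
        cols = [2 * j, 2 * j + 1]
        ms = {e: float(ss_cols[e][cols].sum()) / (dfs_uni[e] * 2) for e in EFFECT_ORDER}
        out[j + 1] = _solve_components(ms, design, n_bar=n_bar)
    frame = pd.DataFrame(out).loc[EFFECT_ORDER]
    frame.columns.name = "landmark"
    return LandmarkVarianceTable(components=frame)


def pct_by_landmark_group(
    table: LandmarkVarianceTable, effect: str, group
) -> float:
    """Percentage of an effect's summed variance components carried by a
    group of landmarks (1-based indices)."""
    group = sorted(set(int(g) for g in group))
    if not group:
        raise ValueError("empty landmark group")
    bad = [g for g in group if g < 1 or g > table.k]
    if bad:
        raise ValueError(f"landmarks out of range 1..{table.k}: {bad}")
    row = table.components.loc[effect]
    total = float(row.sum())
    if total == 0:
        raise ValueError(f"effect {effect!r} has zero total variance")
    return 100.0 * float(row[group].sum()) / total
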