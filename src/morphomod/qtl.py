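"""Shape-QTL screening in a congenic panel.

Each congenic strain is tested against the reference strain with a two-group
MANOVA on principal components of the tangent coordinates (Wilks' lambda,
exact two-group F).  Effect sizes are Procrustes distances between strain
mean shapes and the reference mean, which can then be correlated with genomic
covariates (donor segment Mb, gene count) to probe additivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import StrainRecord
from .procrustes import pca_reduce, procrustes_distance

__all__ = [
    "ManovaResult",
    "EffectSizeRecord",
    "strain_manova",
    "pairwise_manova",
    "bonferroni_adjust",
    "qtl_screen",
    "shared_segment_test",
    "strain_distances",
    "effect_covariate_correlation",
]

#: The conventional Bonferroni-corrected significance level.
ALPHA_DEFAULT = 0.05
#: The historical raw-scale screening cutoff used with this panel design.
ALPHA_HISTORICAL = 0.002


@dataclass
class ManovaResult:
    """Two-group MANOVA summary (Wilks' lambda with exact two-group F)."""

    strain_a: str
    strain_b: str
    wilks_lambda: float
    f_stat: float
    df_num: int
    df_den: int
    p_raw: float
    p_adjusted: float | None = None

    @property
    def significant(self) -> bool:
        p = self.p_adjusted if self.p_adjusted is not None else self.p_raw
        return p < ALPHA_DEFAULT


@dataclass
class EffectSizeRecord:
    """Per-strain effect size and genomic covariates."""

    strain_id: str
    procrustes_distance_from_reference: float
    seg_mb: float
    n_genes: int


def strain_manova(scores: np.ndarray, groups, strain_a: str, strain_b: str) -> ManovaResult:
    """One-way two-group MANOVA on response columns of ``scores``.

    ``groups`` labels each row; only rows labelled ``strain_a`` or
    ``strain_b`` are used.  Wilks' lambda = det(E) / det(E + H) with E the
    pooled within-group and H the between-group cross-product matrix; the
    two-group case admits the exact F transform
    ``F = ((1 - L) / L) * (df_den / df_num)`` with ``df_num = p`` responses
    and ``df_den = n - p - 1``.
    """
    scores = np.asarray(scores, float)
    groups = np.asarray(groups)
    mask_a, mask_b = groups == strain_a, groups == strain_b
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("both groups need at least 2 specimens")
    X = scores[mask_a | mask_b]
    y = groups[mask_a | mask_b]
    n, p = X.shape
    if p > n - 2:
        raise ValueError(
            f"{p} responses with only {n} specimens; reduce the number of PCs"
        )
    grand = X.mean(axis=0)
    E = np.zeros((p, p))
    H = np.zeros((p, p))
    for g in (strain_a, strain_b):
        sub = X[y == g]
        m = sub.mean(axis=0)
        c = sub - m
        E += c.T @ c
        d = (m - grand)[:, None]
        H += len(sub) * (d @ d.T)
    sign_e, logdet_e = np.linalg.slogdet(E)
    sign_t, logdet_t = np.linalg.slogdet(E + H)
    if sign_e <= 0 or sign_t <= 0:
        raise ValueError(
            "singular within-group covariance; use fewer PCs than specimens"
        )
    wilks = float(np.exp(logdet_e - logdet_t))
    df_num = p
    df_den = n - p - 1
    f = (1.0 - wilks) / wilks * (df_den / df_num)
    p_raw = float(stats.f.sf(f, df_num, df_den))
    return ManovaResult(strain_a, strain_b, wilks, f, df_num, df_den, p_raw)


def pairwise_manova(
    tangent: np.ndarray,
    groups,
    strain_a: str,
    strain_b: str,
    n_pcs: int = 14,
    scores: np.ndarray | None = None,
) -> ManovaResult:
    """MANOVA between two strains on PCs of the tangent coordinates.

    By default the PCA is recomputed on the pooled pair of strains being
    compared (each test sees its own reduced space); pass precomputed global
    ``scores`` to test on a shared ordination instead.  The retained
    dimension is capped so the within-group covariance stays nonsingular.
    """
    groups = np.asarray(groups)
    if scores is not None:
        return strain_manova(np.asarray(scores)[:, :n_pcs], groups, strain_a, strain_b)
    mask = (groups == strain_a) | (groups == strain_b)
    sub = np.asarray(tangent, float)[mask]
    n = sub.shape[0]
    model = pca_reduce(sub, n_components=min(n_pcs, n - 3))
    return strain_manova(model.retained_scores, groups[mask], strain_a, strain_b)


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment ``min(1, m * p)``; ``m`` defaults to the number
    of tests."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m is None else int(m)
    if m < len(p):
        raise ValueError("m must be at least the number of p-values")
    return np.minimum(1.0, m * p)


def qtl_screen(
    tangent: np.ndarray,
    groups,
    reference: str,
    n_pcs: int = 14,
    alpha_mode: str = "bonferroni",
) -> pd.DataFrame:
    """Screen every non-reference strain against the reference.

    Returns a table (one row per strain) with Wilks' lambda, the exact F and
    its dfs, raw and Bonferroni-adjusted p-values, and a significance flag:
    adjusted p < 0.05 for ``alpha_mode='bonferroni'`` or raw p < 0.002 for
    the ``'historical'`` preset.
    """
    if alpha_mode not in ("bonferroni", "historical"):
        raise ValueError("alpha_mode must be 'bonferroni' or 'historical'")
    groups = np.asarray(groups)
    strains = [g for g in pd.unique(groups) if g != reference]
    if reference not in groups:
        raise ValueError(f"reference strain {reference!r} absent from data")
    results = [pairwise_manova(tangent, groups, s, reference, n_pcs=n_pcs) for s in strains]
    p_adj = bonferroni_adjust([r.p_raw for r in results], m=len(results))
    rows = []
    for r, pa in zip(results, p_adj):
        r.p_adjusted = float(pa)
        sig = (r.p_raw < ALPHA_HISTORICAL) if alpha_mode == "historical" else (pa < ALPHA_DEFAULT)
        rows.append(
            {
                "strain": r.strain_a,
                "df_num": r.df_num,
                "df_den": r.df_den,
                "wilks": r.wilks_lambda,
                "F": r.f_stat,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "significant": bool(sig),
            }
        )
    return pd.DataFrame(rows).set_index("strain")


def shared_segment_test(
    tangent: np.ndarray, groups, strain_a: str, strain_b: str, n_pcs: int = 14
) -> tuple[ManovaResult, str]:
    """MANOVA between two congenic strains suspected to carry the same donor
    segment.  A non-significant difference is labelled consistent with a
    single shared QTL; a significant one implicates additional loci."""
    res = pairwise_manova(tangent, groups, strain_a, strain_b, n_pcs=n_pcs)
    label = (
        "consistent with shared QTL"
        if res.p_raw >= ALPHA_DEFAULT
        else "additional loci implicated"
    )
    return res, label


def strain_distances(
    shapes: np.ndarray, strains, strain_table: list[StrainRecord], reference: str
) -> list[EffectSizeRecord]:
    """Procrustes distance of each strain's mean shape from the reference mean.

    ``shapes`` is (n_individuals, k, 2) — typically the symmetric components —
    with ``strains`` labelling rows.
    """
    strains = np.asarray(strains)
    if reference not in strains:
        raise ValueError(f"reference strain {reference!r} absent from data")
    covars = {r.strain_id: r for r in strain_table}
    means = {g: shapes[strains == g].mean(axis=0) for g in pd.unique(strains)}
    ref_mean = means[reference]
    records = []
    for g, m in means.items():
        if g == reference:
            continue
        rec = covars.get(g)
        records.append(
            EffectSizeRecord(
                strain_id=str(g),
                procrustes_distance_from_reference=procrustes_distance(ref_mean, m),
                seg_mb=rec.seg_mb if rec else np.nan,
                n_genes=rec.n_genes if rec else 0,
            )
        )
    return records


def effect_covariate_correlation(
    records: list[EffectSizeRecord], covariate: str = "seg_mb"
) -> tuple[float, float]:
    """Pearson correlation (with two-sided t-test on n-2 df) between strain
    effect sizes and a genomic covariate (``seg_mb`` or ``n_genes``)."""
    if covariate not in ("seg_mb", "n_genes"):
        raise ValueError("covariate must be 'seg_mb' or 'n_genes'")
    if len(records) < 3:
        raise ValueError("need at least 3 strains")
    x = np.array([getattr(r, covariate) for r in records], float)
    y = np.array([r.procrustes_distance_from_reference for r in records], float)
    if np.std(x) == 0:
        raise ValueError(f"covariate {covariate!r} has zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
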