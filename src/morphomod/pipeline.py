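"""End-to-end orchestration: simulate/load -> superimpose -> ANOVA ->
QTL screen -> CVA -> modularity/PLS, with CSV outputs and a run manifest.

All randomness flows from one root seed, split deterministically per stage
with :class:`numpy.random.SeedSequence`, so reruns with the same config are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .anova import landmark_variance_components, procrustes_anova
from .modularity import PartitionHypothesis, pls_permutation_test, rv_partition_test
from .ordination import cva, shape_regression
from .procrustes import matching_symmetry, pca_reduce, tangent_project
from .qtl import effect_covariate_correlation, qtl_screen, strain_distances
from .simulate import default_params, simulate_dataset, with_overrides

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineStageError", "ConfigError", "run_pipeline"]

STAGES = ["superimpose", "anova", "qtl", "effect_sizes", "cva", "modularity", "pls"]


class ConfigError(ValueError):
    """Invalid pipeline configuration (distinct from stage failures)."""


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Either ``data_path`` (TPS or long CSV) or ``simulate=True`` must be set.
    The partition hypothesis is given as 1-based landmark lists.
    """

    out_dir: str
    simulate: bool = True
    data_path: str | None = None
    strain_table_path: str | None = None
    adjacency_path: str | None = None
    reference_strain: str = "C57BL/6"
    n_pcs: int = 14
    alpha_mode: str = "bonferroni"
    block_a: list[int] = field(default_factory=lambda: [1, 2, 3, 4, 13, 14, 15, 16])
    block_b: list[int] = field(default_factory=lambda: list(range(5, 13)))
    modularity_level: str = "strain-means"
    n_permutations: int = 10000
    seed: int = 20121001

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def digest(self) -> str:
        """Hash of the analysis-relevant configuration (the output location
        does not influence results and is excluded)."""
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _load_dataset(config: PipelineConfig, seeds) -> mio.Dataset:
    strain_table = (
        mio.read_strain_table(config.strain_table_path)
        if config.strain_table_path
        else mio.load_strain_table()
    )
    if config.simulate:
        params = with_overrides(default_params(), seed=int(seeds["simulate"]))
        return simulate_dataset(params, strain_table)
    if not config.data_path:
        raise ConfigError("either simulate=true or data_path is required")
    path = Path(config.data_path)
    if path.suffix.lower() == ".tps":
        configs = mio.read_tps(path)
    else:
        configs = mio.read_landmark_csv(path)
    return mio.Dataset(configurations=configs, strain_table=strain_table)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every analysis stage in order, writing CSV artifacts and a JSON
    manifest (config hash, seed, per-stage row counts) to ``out_dir``.

    Stage failures raise :class:`PipelineStageError` naming the stage;
    artifacts from completed stages are left in place.  Configuration errors
    (e.g. a reference strain absent from the data) raise
    :class:`ConfigError` before any stage runs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: seq.generate_state(1)[0] % (2**31)
        for name, seq in zip(["simulate", "pls"], root.spawn(2))
    }

    dataset = _load_dataset(config, stage_seeds)
    if config.reference_strain not in {r.strain_id for r in dataset.strain_table}:
        raise ConfigError(f"reference strain {config.reference_strain!r} not in strain table")
    k = dataset.landmark_count
    for b, name in ((config.block_a, "block_a"), (config.block_b, "block_b")):
        if any(j < 1 or j > k for j in b):
            raise ConfigError(f"{name} indices outside 1..{k}")

    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
        "stages": {},
    }
    results: dict = {"dataset": dataset}

    def stage(name):
        def wrap(fn):
            try:
                logger.info("pipeline stage %s: start", name)
                n = fn()
                manifest["stages"][name] = {"rows": n}
                logger.info("pipeline stage %s: done (%s rows)", name, n)
            except (ConfigError,):
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                _write_manifest(out, manifest)
                raise PipelineStageError(name, exc) from exc

        return wrap

    header = f"# config={config.digest()} seed={config.seed}\n"

    def write_csv(name, df, index=True):
        path = out / name
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=index)

    @stage("superimpose")
    def _superimpose():
        decomp, gpa_res, meta = matching_symmetry(dataset)
        tangent = tangent_project(gpa_res)
        results.update(decomp=decomp, gpa=gpa_res, meta=meta, tangent=tangent)
        tang_df = pd.DataFrame(tangent)
        tang_df.insert(0, "replicate", meta["replicate"].to_numpy())
        tang_df.insert(0, "side", meta["side"].to_numpy())
        tang_df.insert(0, "strain", meta["strain"].to_numpy())
        tang_df.insert(0, "specimen", meta["specimen"].to_numpy())
        write_csv("tangent.csv", tang_df, index=False)
        write_csv("symmetric_shapes.csv", decomp.symmetric_table(), index=False)
        return len(tang_df)

    @stage("anova")
    def _anova():
        table = procrustes_anova(results["tangent"], results["meta"], k)
        by_lm = landmark_variance_components(results["tangent"], results["meta"], k)
        results.update(anova=table, anova_by_landmark=by_lm)
        out_tab = table.to_frame()
        out_tab["variance_component_x1e6"] = out_tab["variance_component"] * 1e6
        write_csv("anova.csv", out_tab)
        write_csv("anova_by_landmark.csv", (by_lm.components * 1e7).round(3))
        return len(out_tab)

    @stage("qtl")
    def _qtl():
        decomp = results["decomp"]
        sym_flat = decomp.symmetric.reshape(len(decomp.specimens), -1)
        screen = qtl_screen(
            sym_flat,
            decomp.strains,
            config.reference_strain,
            n_pcs=config.n_pcs,
            alpha_mode=config.alpha_mode,
        )
        results["manova"] = screen
        write_csv("manova.csv", screen)
        return len(screen)

    @stage("effect_sizes")
    def _effects():
        decomp = results["decomp"]
        records = strain_distances(
            decomp.symmetric, decomp.strains, dataset.strain_table, config.reference_strain
        )
        rows = []
        for cov in ("seg_mb", "n_genes"):
            r, p = effect_covariate_correlation(records, cov)
            rows.append({"covariate": cov, "r": r, "p": p})
        results["effect_records"] = records
        results["effect_correlations"] = pd.DataFrame(rows)
        eff = pd.DataFrame(
            {
                "strain": [r.strain_id for r in records],
                "procrustes_distance": [
                    r.procrustes_distance_from_reference for r in records
                ],
                "seg_mb": [r.seg_mb for r in records],
                "n_genes": [r.n_genes for r in records],
            }
        )
        write_csv("effect_sizes.csv", eff, index=False)
        write_csv("effect_correlations.csv", results["effect_correlations"], index=False)
        return len(eff)

    @stage("cva")
    def _cva():
        decomp = results["decomp"]
        sym_flat = decomp.symmetric.reshape(len(decomp.specimens), -1)
        model = pca_reduce(sym_flat, n_components=config.n_pcs)
        cva_res = cva(model.retained_scores, decomp.strains)
        results["cva"] = cva_res
        # shape change along axis 1 in the original coordinate space
        vec = shape_regression(cva_res.scores[:, 0], sym_flat - sym_flat.mean(axis=0))
        scores_df = pd.DataFrame(
            cva_res.scores, columns=[f"CV{i + 1}" for i in range(cva_res.scores.shape[1])]
        )
        scores_df.insert(0, "strain", decomp.strains)
        scores_df.insert(0, "specimen", decomp.specimens)
        write_csv("cva_scores.csv", scores_df, index=False)
        write_csv("cva_confusion.csv", cva_res.confusion_matrix)
        write_csv(
            "cva_axis1_shape_vectors.csv",
            pd.DataFrame(vec, columns=["dx", "dy"], index=pd.RangeIndex(1, k + 1, name="landmark")),
        )
        return len(scores_df)

    @stage("modularity")
    def _modularity():
        graph = (
            mio.read_adjacency(config.adjacency_path, k)
            if config.adjacency_path
            else mio.load_adjacency(k)
        )
        hyp = PartitionHypothesis(
            frozenset(config.block_a), frozenset(config.block_b), graph
        )
        decomp = results["decomp"]
        sym_flat = decomp.symmetric.reshape(len(decomp.specimens), -1)
        if config.modularity_level == "strain-means":
            df = pd.DataFrame(sym_flat)
            df["strain"] = decomp.strains
            data = df.groupby("strain").mean().to_numpy()
        elif config.modularity_level == "specimens":
            data = sym_flat
        else:
            raise ConfigError("modularity_level must be 'strain-means' or 'specimens'")
        rv = rv_partition_test(data, hyp)
        results["rv_test"] = rv
        results["modularity_data"] = data
        dist = pd.DataFrame(
            {
                "partition": ["|".join(map(str, sorted(p))) for p in rv.partitions],
                "rv": rv.rv_distribution,
                "contiguous": rv.contiguous_mask,
            }
        )
        write_csv("rv_distribution.csv", dist, index=False)
        summary = pd.DataFrame(
            [
                {
                    "observed_rv": rv.observed_rv,
                    "n_total_partitions": rv.n_total_partitions,
                    "n_contiguous": rv.n_contiguous,
                    "count_leq_full": rv.count_leq_full,
                    "count_leq_contiguous": rv.count_leq_contiguous,
                    "p_full": rv.p_full,
                    "p_contiguous": rv.p_contiguous,
                }
            ]
        )
        write_csv("rv_test.csv", summary, index=False)
        return len(dist)

    @stage("pls")
    def _pls():
        data = results["modularity_data"]
        cols_a = np.ravel(
            [[2 * (j - 1), 2 * (j - 1) + 1] for j in sorted(config.block_a)]
        )
        cols_b = np.ravel(
            [[2 * (j - 1), 2 * (j - 1) + 1] for j in sorted(config.block_b)]
        )
        pls = pls_permutation_test(
            data[:, cols_a],
            data[:, cols_b],
            n_perm=config.n_permutations,
            seed=int(stage_seeds["pls"]),
        )
        results["pls"] = pls
        n_axes = len(pls.singular_values)
        summary = pd.DataFrame(
            {
                "axis": np.arange(1, n_axes + 1),
                "singular_value": pls.singular_values,
                "covariance_fraction": pls.covariance_fractions,
                "score_correlation": pls.score_correlations,
            }
        )
        summary["p_covariance"] = pls.permutation_p_covariance
        summary["p_correlation_axis1"] = pls.permutation_p_correlation
        write_csv("pls.csv", summary, index=False)
        return n_axes

    _write_manifest(out, manifest)
    return results


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
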