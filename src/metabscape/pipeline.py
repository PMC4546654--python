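"""End-to-end orchestration: ingest -> filter -> per-metabolite models ->
cross-tissue landscape -> classifiers -> lipid statistics.

A single root seed deterministically spawns per-stage seeds (via
``numpy.random.SeedSequence``), so adding a stage never perturbs the random
streams of earlier stages, and two runs with the same config and seed produce
byte-identical numeric output.  Every run writes TSV result tables plus a
JSON manifest recording the config, stage seeds, timings and output hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._errors import ConfigurationError, MetabscapeError
from . import classifiers, feature_models, lipids, tissue_landscape
from .ingest import PeakTable, read_peak_table, write_results

logger = logging.getLogger(__name__)

_STAGES = ("models", "landscape", "lda", "forest", "lipids")


@dataclass
class RunConfig:
    """Configuration of one full analysis run.

    Defaults are the study's stated constants: nominal alpha 0.05, FDR 10%,
    30% fold-change gate, 500 forest trees, 1000 ratio permutations.
    """

    tissue_table: str | None = None
    cell_table: str | None = None
    metadata_columns: dict | None = None
    alpha: float = 0.05
    fdr_level: float = 0.10
    fc_threshold: float = 0.30
    min_nonzero_per_arm: int = 3
    ss_type: str = "sequential"
    log_transform: bool = False
    n_trees: int = 500
    n_perm_lda: int = 100
    n_perm_ratio: int = 1000
    sort_tissue: str = "striatum"
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self):
        for name in ("alpha", "fdr_level"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ConfigurationError(f"{name} must be in (0, 1), got {v}")
        if not self.fc_threshold > 0:
            raise ConfigurationError("fc_threshold must be > 0")
        for name in ("n_trees", "n_perm_lda", "n_perm_ratio", "min_nonzero_per_arm"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.ss_type not in ("sequential", "marginal"):
            raise ConfigurationError(f"unknown ss_type {self.ss_type!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys {sorted(unknown)!r}")
        return cls(**raw)


def stage_seeds(root_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds spawned from the root seed."""
    children = np.random.SeedSequence(root_seed).spawn(len(_STAGES))
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(_STAGES, children)
    }


def run_pipeline(
    config: RunConfig,
    tissue_table: PeakTable | None = None,
    cell_table: PeakTable | None = None,
) -> dict:
    """Execute every analysis stage; return the run manifest.

    Tables may be passed in memory or read from the paths in ``config``.
    Any stage failure aborts the run with the failing stage named.
    """
    if tissue_table is None:
        if config.tissue_table is None:
            raise ConfigurationError("no tissue table given (path or in-memory)")
        tissue_table = read_peak_table(config.tissue_table, config.metadata_columns)
    if cell_table is None and config.cell_table is not None:
        cell_table = read_peak_table(config.cell_table, config.metadata_columns)

    seeds = stage_seeds(config.seed)
    tables: dict[str, pd.DataFrame] = {}
    timings: dict[str, float] = {}

    def _run(stage, fn):
        t0 = time.perf_counter()
        try:
            fn()
        except MetabscapeError:
            raise
        except Exception as exc:  # noqa: BLE001 - name the failing stage
            raise MetabscapeError(f"stage {stage!r} failed: {exc}") from exc
        timings[stage] = round(time.perf_counter() - t0, 3)

    # ---- per-metabolite models ---------------------------------------
    results_by_tissue: dict[str, pd.DataFrame] = {}

    def _models():
        frames = []
        for tissue in tissue_table.tissues():
            res = feature_models.fit_tissue_models(
                tissue_table.subset_tissue(tissue),
                min_nonzero_per_arm=config.min_nonzero_per_arm,
                ss_type=config.ss_type,
                log_transform=config.log_transform,
            )
            results_by_tissue[tissue] = res
            frames.append(res)
        tables["factor_models"] = pd.concat(frames, ignore_index=True)

    _run("models", _models)
    all_results = tables["factor_models"]

    # ---- cross-tissue landscape --------------------------------------
    def _landscape():
        summary = tissue_landscape.count_significant(all_results, config.alpha)
        tables["table1"] = summary.pivot_table(
            index="tissue", columns="factor", values=["n_sig", "n_tested"],
            aggfunc="first",
        ).pipe(_flatten_columns)
        het_rows = []
        for factor in tissue_landscape.FACTORS:
            sub = summary[summary["factor"] == factor]
            if len(sub) >= 2 and (sub["n_tested"] > 0).all():
                chi, df, p = tissue_landscape.heterogeneity_test(sub)
                het_rows.append(
                    {"factor": factor, "chi_square": chi, "df": df, "p": p}
                )
        tables["heterogeneity"] = pd.DataFrame(het_rows)
        overlaps = [
            tissue_landscape.pairwise_overlap(all_results, factor, config.alpha)
            for factor in tissue_landscape.FACTORS
        ]
        tables["table2"] = pd.concat(overlaps, ignore_index=True)

    _run("landscape", _landscape)

    # ---- LDA tissue separation ---------------------------------------
    def _lda():
        if len(tissue_table.tissues()) < 2:
            logger.info("single tissue: skipping LDA stage")
            return
        est = classifiers.fit_lda(tissue_table)
        est.permutation_null(
            tissue_table.values,
            tissue_table.samples["tissue"].to_numpy(),
            n_perm=config.n_perm_lda,
            random_state=seeds["lda"],
        )
        proj = pd.DataFrame(
            est.projections_,
            columns=[f"LD{i+1}" for i in range(est.projections_.shape[1])],
        )
        proj.insert(0, "sample_id", tissue_table.samples["sample_id"].to_numpy())
        proj.insert(1, "tissue", tissue_table.samples["tissue"].to_numpy())
        tables["lda_projections"] = proj
        tables["lda_separation"] = pd.DataFrame(
            {
                "separation_score": [est.separation_score_],
                "permutation_p": [est.permutation_pvalue_],
                "n_perm": [config.n_perm_lda],
                "max_permuted_score": [np.nanmax(est.permuted_scores_)],
            }
        )

    _run("lda", _lda)

    # ---- per-tissue genotype forests ---------------------------------
    def _forest():
        rows = []
        imp_frames = []
        for i, tissue in enumerate(tissue_table.tissues()):
            sub = tissue_table.subset_tissue(tissue)
            est = classifiers.fit_genotype_forest(
                sub, n_trees=config.n_trees, seed=seeds["forest"] + i
            )
            imp = est.permutation_importance(
                feature_names=sub.metabolites, random_state=seeds["forest"] + i
            )
            imp.insert(0, "tissue", tissue)
            imp_frames.append(imp.head(25))
            rows.append(
                {
                    "tissue": tissue,
                    "final_oob_error": est.final_oob_error_,
                    "n_trees": config.n_trees,
                    "top_metabolite": imp["metabolite"].iloc[0],
                }
            )
        tables["forest_summary"] = pd.DataFrame(rows)
        tables["forest_importance"] = pd.concat(imp_frames, ignore_index=True)

    _run("forest", _forest)

    # ---- lipid statistics --------------------------------------------
    def _lipids():
        lipid_names = sorted(lipids.lipid_subset(tissue_table.metabolites))
        if not lipid_names:
            logger.info("no lipid species in table: skipping lipid stage")
            return
        lipid_results = all_results[all_results["metabolite"].isin(lipid_names)]
        if config.sort_tissue in set(lipid_results["tissue"]):
            tables["lipid_heatmap"] = lipids.order_by_tissue_pvalue(
                lipid_results, config.sort_tissue
            )
        ratio_rows = []
        for tissue in tissue_table.tissues():
            sub = tissue_table.subset_tissue(tissue)
            present = [m for m in lipid_names if (sub.values[m] > 0).any()]
            if not present:
                continue
            rs = lipids.ratio_distribution(
                sub.subset_metabolites(present),
                n_perm=config.n_perm_ratio,
                seed=seeds["lipids"],
            )
            ratio_rows.append(
                {
                    "tissue": tissue,
                    "observed_center": rs.observed_center_,
                    "permuted_center_mean": float(
                        np.nanmean(rs.permuted_centers_)
                    ),
                    "permutation_p": rs.pvalue_,
                    "n_species": len(rs.species_),
                    "n_perm": rs.n_perm_,
                }
            )
        tables["ratio_null"] = pd.DataFrame(ratio_rows)

        if cell_table is not None:
            pellet = cell_table.subset_tissue("cell_pellet")
            gate_in = feature_models.fit_tissue_models(
                pellet,
                min_nonzero_per_arm=config.min_nonzero_per_arm,
                ss_type=config.ss_type,
                log_transform=config.log_transform,
            )
            tables["cell_gate"] = feature_models.apply_gate(
                gate_in, config.fdr_level, config.fc_threshold
            )
            sort_res = results_by_tissue.get(config.sort_tissue)
            if sort_res is not None:
                t_ratio = _ratio_series(sort_res, lipid_names)
                c_ratio = _ratio_series(gate_in, lipid_names)
                if len(set(t_ratio.index) & set(c_ratio.index)):
                    q = lipids.quadrant_concordance(t_ratio, c_ratio)
                    tables["quadrants"] = pd.DataFrame(
                        {
                            "quadrant": ["up_up", "up_down", "down_up", "down_down"],
                            "count": list(q.counts),
                        }
                    ).assign(
                        n_species=q.n_species,
                        chi_square=q.chi_square,
                        df=q.df,
                        p=q.p,
                    )

    _run("lipids", _lipids)

    manifest = write_results(
        tables,
        config.out_dir,
        params=dataclasses.asdict(config),
        seed=config.seed,
    )
    manifest["stage_seeds"] = seeds
    manifest["stage_timings"] = timings
    manifest["output_hashes"] = {
        name: _sha256(Path(config.out_dir) / f"{name}.tsv") for name in tables
    }
    with open(Path(config.out_dir) / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _ratio_series(results: pd.DataFrame, lipid_names: list[str]) -> pd.Series:
    sub = results[results["metabolite"].isin(lipid_names)]
    ratios = 1.0 + sub["percent_change_genotype"].to_numpy(dtype=float) / 100.0
    s = pd.Series(ratios, index=sub["metabolite"].to_numpy())
    return s[np.isfinite(s.to_numpy(dtype=float))]


def _flatten_columns(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.copy()
    frame.columns = ["_".join(map(str, c)).strip("_") for c in frame.columns]
    return frame.reset_index()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()
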