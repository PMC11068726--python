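"""End-to-end orchestration: simulate -> decompose -> enrich -> survival ->
forest -> project, with deterministic seeding, a file manifest, and the
sensitivity (split-dataset robustness) analysis.

The manifest (`manifest.json`) lists every artifact with its SHA-256 and the
full parameter echo; it contains nothing time-dependent, so two runs with
the same config and master seed produce byte-identical manifests.  Wall
clock per stage lives in the separate `report.json`.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cica, enrichment, forest, io, projection, survival, synthetic
from .containers import ExpressionMatrix, MixingMatrix, SurvivalTable, TCSet

__all__ = ["PipelineConfig", "run_full", "run_sensitivity"]

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "decompose", "enrich", "survival", "forest", "project")


def _default_simulate() -> dict:
    return {
        "n_genes": 1000,
        "n_components": 5,
        "active_fraction": 0.1,
        "n_samples": 300,
        "activity_sd": 1.0,
        "noise_sd": 0.5,
        "hazard_betas": [0.8, -0.5, 0.0, 0.0, 0.0],
        "baseline_rate": 0.02,
        "censor_rate": 0.015,
        "n_null_sets": 50,
        "set_size_min": 10,
        "set_size_max": 100,
        "planted_per_component": 1,
        "spatial_grid": [10, 10],
        "spatial_boost": 5.0,
    }


def _default_decompose() -> dict:
    return {
        "n_runs": 25,
        "variance_threshold": 0.85,
        "r_threshold": 0.9,
        "credibility_threshold": 0.5,
    }


def _default_enrich() -> dict:
    return {"alpha": 0.05, "min_size": 10, "max_size": 500}


def _default_survival() -> dict:
    return {
        "covariates": ["sex", "msi", "braf", "kras", "location", "stage", "adjuvant"],
        "n_perm": 10000,
        "fdr": 0.05,
        "confidence": 0.8,
    }


def _default_forest() -> dict:
    return {
        "n_trees": 1000,
        "tcs_per_tree": 5,
        "min_node_size": 15,
        "min_node_events": 5,
        "split_alpha": 0.05,
        "k_max": 10,
        "alpha": 0.05,
    }


def _default_project() -> dict:
    return {"n_perm_spatial": 5000, "n_perm_sc": 3000, "subsample_fraction": 0.1,
            "min_overlap": 0.5, "r_threshold": 0.5}


@dataclass
class PipelineConfig:
    master_seed: int = 0
    outdir: str = "consica_run"
    stages: dict = field(
        default_factory=lambda: {s: True for s in _STAGES}
    )
    simulate: dict = field(default_factory=_default_simulate)
    decompose: dict = field(default_factory=_default_decompose)
    enrich: dict = field(default_factory=_default_enrich)
    survival: dict = field(default_factory=_default_survival)
    forest: dict = field(default_factory=_default_forest)
    project: dict = field(default_factory=_default_project)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        d = self.decompose
        for key in ("variance_threshold", "r_threshold", "credibility_threshold"):
            if not 0 < d[key] <= 1:
                raise ValueError(f"decompose.{key} must lie in (0, 1]")
        if self.survival["n_perm"] < 1:
            raise ValueError("survival.n_perm must be >= 1")
        if self.forest["tcs_per_tree"] < 1:
            raise ValueError("forest.tcs_per_tree must be >= 1")
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seeds(master_seed: int) -> dict:
    rng = np.random.default_rng(master_seed)
    return {s: int(rng.integers(0, 2**31 - 1)) for s in _STAGES}


def run_full(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the run report dict.

    Artifacts are written under ``config.outdir``; the manifest holds file
    hashes, the parameter echo and the per-stage counts.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.master_seed)
    manifest: dict = {"parameters": asdict(config), "files": {}, "counts": {}}
    timings: dict = {}
    files = manifest["files"]

    def record(path: Path):
        files[path.name] = _sha256(path)

    def stage_enabled(name: str) -> bool:
        return bool(config.stages.get(name, True))

    state: dict = {}

    try:
        if stage_enabled("simulate"):
            t0 = _time.perf_counter()
            sim = config.simulate
            sources = synthetic.generate_sources(
                sim["n_genes"], sim["n_components"], sim["active_fraction"],
                seed=seeds["simulate"],
            )
            X, A_true = synthetic.generate_expression(
                sources, sim["n_samples"], sim["activity_sd"], sim["noise_sd"],
                seed=seeds["simulate"] + 1,
            )
            surv = synthetic.generate_survival(
                A_true, sim["hazard_betas"], sim["baseline_rate"],
                sim["censor_rate"], seed=seeds["simulate"] + 2,
            )
            sets = synthetic.generate_gene_sets(
                sources, sim["n_null_sets"],
                (sim["set_size_min"], sim["set_size_max"]),
                sim["planted_per_component"], seed=seeds["simulate"] + 3,
            )
            rows, cols = sim["spatial_grid"]
            mask = np.zeros((rows, cols), dtype=bool)
            mask[: rows // 2, : cols // 2] = True
            spatial = synthetic.generate_spatial_profile(
                sources, (rows, cols), mask, sources.component_ids[0],
                sim["spatial_boost"], sim["noise_sd"], seed=seeds["simulate"] + 4,
            )
            io.write_expression_tsv(X, out / "expression.tsv")
            io.write_survival_csv(surv, out / "survival.csv")
            io.write_gmt(sets, out / "gene_sets.gmt")
            io.write_tcset(sources, out / "true_sources.tsv")
            io.write_mixing_tsv(A_true, out / "true_mixing.tsv")
            io.write_spatial(spatial, out / "spatial")
            for name in (
                "expression.tsv", "survival.csv", "gene_sets.gmt",
                "true_sources.tsv", "true_sources.tsv.json", "true_mixing.tsv",
                "spatial.mtx", "spatial_genes.tsv", "spatial_coords.csv",
            ):
                record(out / name)
            state.update(X=X, surv=surv, sets=sets, spatial=spatial, sources=sources)
            manifest["counts"]["n_genes"] = X.n_genes
            manifest["counts"]["n_samples"] = X.n_samples
            timings["simulate"] = _time.perf_counter() - t0

        if stage_enabled("decompose"):
            t0 = _time.perf_counter()
            X = state.get("X") or io.read_expression_tsv(out / "expression.tsv")
            dec = config.decompose
            tcs, mixing = cica.decompose(
                X,
                n_runs=dec["n_runs"],
                variance_threshold=dec["variance_threshold"],
                r_threshold=dec["r_threshold"],
                credibility_threshold=dec["credibility_threshold"],
                master_seed=seeds["decompose"],
            )
            io.write_tcset(
                tcs, out / "tcs.tsv",
                sidecar={"parameters": dec, "master_seed": seeds["decompose"]},
            )
            io.write_mixing_tsv(mixing, out / "mixing.tsv")
            for name in ("tcs.tsv", "tcs.tsv.json", "mixing.tsv"):
                record(out / name)
            state.update(tcs=tcs, mixing=mixing)
            manifest["counts"]["n_tcs"] = tcs.n_components
            timings["decompose"] = _time.perf_counter() - t0

        if stage_enabled("enrich"):
            t0 = _time.perf_counter()
            tcs = state.get("tcs") or io.read_tcset(out / "tcs.tsv")
            sets = state.get("sets") or io.read_gmt(out / "gene_sets.gmt")
            en = config.enrich
            filtered = enrichment.filter_gene_sets(
                sets, tcs.gene_ids, en["min_size"], en["max_size"]
            )
            table = enrichment.enrichment_table(tcs, filtered, alpha=en["alpha"])
            table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            record(out / "enrichment.tsv")
            manifest["counts"]["n_enriched_pairs"] = int(
                table["bonferroni_significant"].sum()
            )
            timings["enrich"] = _time.perf_counter() - t0

        if stage_enabled("survival"):
            t0 = _time.perf_counter()
            mixing = state.get("mixing") or io.read_mixing_tsv(out / "mixing.tsv")
            surv = state.get("surv") or io.read_survival_csv(out / "survival.csv")
            sv = config.survival
            uni = survival.permutation_fdr_select(
                mixing, surv, covariates=None, n_perm=sv["n_perm"],
                fdr=sv["fdr"], confidence=sv["confidence"],
                seed=seeds["survival"],
            )
            multi = survival.permutation_fdr_select(
                mixing, surv, covariates=sv["covariates"], n_perm=sv["n_perm"],
                fdr=sv["fdr"], confidence=sv["confidence"],
                seed=seeds["survival"] + 1,
            )
            combined = survival.combine_selections(uni, multi)
            combined.to_csv(out / "selected_tcs.csv", index=False)
            cox_rows = []
            for model, sel in (("univariate", uni), ("multivariate", multi)):
                for tc in sel.observed_p.index:
                    cox_rows.append(
                        {
                            "tc_id": tc,
                            "model": model,
                            "p_value": float(sel.observed_p[tc]),
                            "permutation_p": float(sel.permutation_p[tc]),
                            "selected": tc in sel.selected,
                        }
                    )
            pd.DataFrame(cox_rows).to_csv(out / "cox_results.tsv", sep="\t", index=False)
            record(out / "selected_tcs.csv")
            record(out / "cox_results.tsv")
            state.update(selection=combined)
            manifest["counts"]["n_selected_tcs"] = len(combined)
            timings["survival"] = _time.perf_counter() - t0

        if stage_enabled("forest"):
            t0 = _time.perf_counter()
            mixing = state.get("mixing") or io.read_mixing_tsv(out / "mixing.tsv")
            surv = state.get("surv") or io.read_survival_csv(out / "survival.csv")
            fo = config.forest
            selection = state.get("selection")
            tc_input = (
                list(selection["tc_id"]) if selection is not None and len(selection) >= fo["tcs_per_tree"]
                else list(mixing.component_ids)
            )
            sub = mixing.to_frame().loc[tc_input]
            mix_in = MixingMatrix(tc_input, mixing.sample_ids, sub.to_numpy())
            fst = forest.build_forest(
                mix_in, surv, n_trees=fo["n_trees"], tcs_per_tree=fo["tcs_per_tree"],
                min_node_size=fo["min_node_size"], min_node_events=fo["min_node_events"],
                split_alpha=fo["split_alpha"], seed=seeds["forest"],
            )
            P = forest.final_proximity(fst)
            imp = forest.importance_scores(fst)
            k_star, labels, table = forest.select_max_subgroups(
                P, surv, k_max=fo["k_max"], alpha=fo["alpha"]
            )
            pd.DataFrame(
                P.counts, index=P.sample_ids, columns=P.sample_ids
            ).to_csv(out / "proximity.tsv", sep="\t")
            imp.rename_axis("tc_id").to_csv(out / "importance.tsv", sep="\t")
            pd.DataFrame(
                {"sample_id": P.sample_ids, "subgroup": labels}
            ).to_csv(out / "subgroups.csv", index=False)
            table.to_csv(out / "subgroup_logrank.tsv", sep="\t", index=False)
            for name in ("proximity.tsv", "importance.tsv", "subgroups.csv", "subgroup_logrank.tsv"):
                record(out / name)
            manifest["counts"]["n_subgroups"] = int(k_star)
            timings["forest"] = _time.perf_counter() - t0

        if stage_enabled("project"):
            t0 = _time.perf_counter()
            tcs = state.get("tcs") or io.read_tcset(out / "tcs.tsv")
            spatial = state.get("spatial") or io.read_spatial(out / "spatial")
            pr = config.project
            spatial_map = projection.permutation_activity_significance(
                tcs, spatial, n_perm=pr["n_perm_spatial"], seed=seeds["project"],
                min_overlap=pr["min_overlap"],
            )
            spatial_map.to_csv(out / "spatial_map.tsv", sep="\t", index=False)
            record(out / "spatial_map.tsv")
            manifest["counts"]["n_spatial_units"] = int(
                spatial_map["unit_id"].nunique()
            )
            timings["project"] = _time.perf_counter() - t0
    except Exception as exc:
        (out / "manifest.partial.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    report = dict(manifest)
    report["wall_clock_s"] = {k: round(v, 3) for k, v in timings.items()}
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", out / "manifest.json")
    return report


def run_sensitivity(
    primary_X: ExpressionMatrix,
    secondary_X: ExpressionMatrix,
    dfs_X: ExpressionMatrix,
    surv: SurvivalTable,
    config: PipelineConfig,
) -> dict:
    """Split-dataset robustness analysis.

    Decomposes the primary and secondary datasets, matches TCs (|r| > 0.5
    robust), projects the robust secondary TCs onto the (sample-disjoint)
    DFS dataset, reruns the survival selection on both TC sets, builds both
    forests, and reports the Pearson correlation of the final proximity
    matrices.
    """
    overlap = set(secondary_X.sample_ids) & set(dfs_X.sample_ids)
    if overlap:
        raise ValueError(
            f"secondary and DFS datasets share {len(overlap)} samples; "
            "the robustness analysis requires disjoint sample sets"
        )
    seeds = _stage_seeds(config.master_seed)
    dec = config.decompose
    kwargs = dict(
        n_runs=dec["n_runs"],
        variance_threshold=dec["variance_threshold"],
        r_threshold=dec["r_threshold"],
        credibility_threshold=dec["credibility_threshold"],
    )
    tcs_p, _ = cica.decompose(primary_X, master_seed=seeds["decompose"], **kwargs)
    tcs_s, _ = cica.decompose(secondary_X, master_seed=seeds["decompose"] + 1, **kwargs)
    matches = projection.match_components(
        tcs_p, tcs_s, r_threshold=config.project["r_threshold"]
    )
    robust = [m for m in matches if m.robust]
    if not robust:
        raise RuntimeError(
            "no robust TC matches between primary and secondary decompositions"
        )
    robust_ids = [m.secondary_id for m in robust]
    idx = [tcs_s.component_ids.index(c) for c in robust_ids]
    tcs_robust = TCSet(
        robust_ids, tcs_s.gene_ids, tcs_s.weights[idx], tcs_s.credibility[idx]
    )

    act_primary = projection.project(tcs_p, dfs_X, config.project["min_overlap"])
    act_robust = projection.project(tcs_robust, dfs_X, config.project["min_overlap"])
    sv = config.survival
    sel_primary = survival.permutation_fdr_select(
        act_primary, surv, covariates=None, n_perm=sv["n_perm"], fdr=sv["fdr"],
        confidence=sv["confidence"], seed=seeds["survival"],
    )
    sel_robust = survival.permutation_fdr_select(
        act_robust, surv, covariates=None, n_perm=sv["n_perm"], fdr=sv["fdr"],
        confidence=sv["confidence"], seed=seeds["survival"] + 1,
    )
    fo = config.forest
    fkw = dict(
        n_trees=fo["n_trees"], tcs_per_tree=fo["tcs_per_tree"],
        min_node_size=fo["min_node_size"], min_node_events=fo["min_node_events"],
        split_alpha=fo["split_alpha"],
    )
    f1 = forest.build_forest(act_primary, surv, seed=seeds["forest"], **fkw)
    f2 = forest.build_forest(act_robust, surv, seed=seeds["forest"] + 1, **fkw)
    r_prox = forest.compare_proximity(
        forest.final_proximity(f1), forest.final_proximity(f2)
    )
    secondary_to_primary = {m.secondary_id: m.primary_id for m in robust}
    return {
        "n_primary_tcs": tcs_p.n_components,
        "n_secondary_tcs": tcs_s.n_components,
        "n_robust": len(robust),
        "robust_fraction": len(robust) / max(tcs_p.n_components, 1),
        "match_abs_r": [abs(m.r) for m in matches],
        "selected_primary": sel_primary.selected,
        "selected_robust_as_primary": [
            secondary_to_primary[c] for c in sel_robust.selected
        ],
        "proximity_pearson_r": r_prox,
    }
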