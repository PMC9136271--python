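"""End-to-end orchestration of the analysis chain.

Stages run in dependency order on either a simulated bundle or
user-supplied files: ingest/align → normalize → DE screen → variance
filter report → switched-gene detection → dose-profile clustering →
ssGSEA scoring → correlation screens → CCA.  Every stage logs its
parameters and record counts into a machine-readable run summary; any
stage failure aborts the run with the stage name, leaving earlier
outputs in place alongside a FAILED marker.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from selenoscope import association, ordination, profiles, ssgsea
from selenoscope.datamodel import (
    align_samples,
    read_design,
    read_expression_matrix,
    read_gene_sets,
    read_otu_table,
    read_phenotypes,
)
from selenoscope.preprocess import de_screen, median_of_ratios_normalize
from selenoscope.simulate import SY_GRADIENT, SimConfig, make_fixture_bundle
from selenoscope.switch import detect_switches, quartile_deviation_filter

__all__ = ["RunConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything a pipeline run needs; YAML-loadable."""

    outdir: str
    seed: int = 0
    simulate: bool = True
    sim_overrides: dict = field(default_factory=dict)
    counts: str | None = None
    otus: str | None = None
    design: str | None = None
    phenotypes: str | None = None
    gene_sets: str | None = None
    baseline_group: str = "SD"
    dose_order: list[str] = field(default_factory=lambda: list(SY_GRADIENT))
    # stage parameters
    lfc_threshold: float = 1.0
    fdr_threshold: float = 0.05
    switch_alpha: float = 0.05
    variance_filter_factor: float = 1.5
    apply_variance_filter_to_switches: bool = False
    sd_bound: float = 1.0
    max_profiles: int = 100
    min_r: float = 0.88
    n_perm: int = 1000
    profile_step: int = 1
    tau: float = 0.25
    score_sd_max: float = 0.1
    r_min: float = 0.6
    p_max: float = 0.05
    vif_threshold: float = 10.0
    skip_stages: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run summary dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": {}, "timings_s": {}}
    t_start = time.time()

    def stage(name):
        def deco(fn):
            if name in config.skip_stages:
                summary["stages"][name] = {"status": "skipped"}
                return None
            t0 = time.time()
            try:
                record = fn()
            except Exception as err:  # noqa: BLE001 — wrap with stage context
                (outdir / "FAILED").write_text(f"{name}: {err}\n")
                raise StageError(name, err) from err
            summary["timings_s"][name] = round(time.time() - t0, 3)
            record = record or {}
            record["status"] = "ok"
            summary["stages"][name] = record
            return record

        return deco

    state: dict = {}

    @stage("ingest")
    def _ingest():
        if config.simulate:
            sim = SimConfig(seed=config.seed, **config.sim_overrides)
            paths = make_fixture_bundle(outdir / "fixtures", sim)
            state["sim_config"] = sim
        else:
            missing = [
                k
                for k in ("counts", "otus", "design", "phenotypes", "gene_sets")
                if getattr(config, k) is None
            ]
            if missing:
                raise ValueError(f"missing input paths: {missing}")
            paths = {
                "counts": Path(config.counts),
                "otus": Path(config.otus),
                "design": Path(config.design),
                "phenotypes": Path(config.phenotypes),
                "gene_sets": Path(config.gene_sets),
            }
        matrix = read_expression_matrix(paths["counts"])
        otus = read_otu_table(paths["otus"])
        design = read_design(paths["design"], baseline_group=config.baseline_group)
        phenos = read_phenotypes(paths["phenotypes"])
        sets = read_gene_sets(paths["gene_sets"])
        aligned, report = align_samples(
            matrix=matrix, design=design, phenotypes=phenos, otu_table=otus
        )
        state.update(aligned)
        state["gene_sets"] = sets
        return {
            "n_genes": len(matrix.gene_ids),
            "n_otus": len(otus.otu_ids),
            "n_samples": len(report.shared_samples),
            "dropped": {k: len(v) for k, v in report.dropped.items()},
        }

    @stage("normalize")
    def _normalize():
        norm = median_of_ratios_normalize(state["matrix"])
        state["norm"] = norm
        norm.data.to_csv(outdir / "normalized.tsv", sep="\t", index_label="gene_id")
        return {
            "method": norm.method,
            "size_factor_range": [
                float(norm.size_factors.min()),
                float(norm.size_factors.max()),
            ],
        }

    @stage("de_screen")
    def _de():
        design = state["design"]
        norm = state["norm"]
        deg: set[str] = set()
        per_contrast = {}
        for group in config.dose_order[1:]:
            res = de_screen(
                norm,
                design,
                baseline=config.baseline_group,
                treatment=group,
                lfc_threshold=config.lfc_threshold,
                fdr_threshold=config.fdr_threshold,
            )
            res.to_csv(outdir / f"de_{group}.tsv", sep="\t", index_label="gene")
            hits = set(res.index[res["pass"]])
            per_contrast[group] = len(hits)
            deg |= hits
        state["deg"] = sorted(deg)
        return {"deg_per_contrast": per_contrast, "deg_union": len(deg)}

    @stage("variance_filter")
    def _vfilter():
        retained, filtered = quartile_deviation_filter(
            state["matrix"], factor=config.variance_filter_factor
        )
        state["variance_retained"] = retained
        return {"retained": len(retained), "filtered": len(filtered)}

    @stage("switches")
    def _switches():
        factor = (
            config.variance_filter_factor
            if config.apply_variance_filter_to_switches
            else None
        )
        switches, states = detect_switches(
            state["norm"].matrix,
            state["design"],
            alpha=config.switch_alpha,
            factor=factor,
            sd_bound=config.sd_bound,
        )
        switches.to_csv(outdir / "switches.tsv", sep="\t", index=False)
        states.to_csv(outdir / "states.tsv", sep="\t", index=False)
        state["switches"] = switches
        return {
            "switched_on": int((switches["direction"] == "switched_on").sum()),
            "switched_off": int((switches["direction"] == "switched_off").sum()),
        }

    @stage("profiles")
    def _profiles():
        deg = state["deg"]
        if not deg:
            state["profile_significance"] = pd.DataFrame()
            return {"assigned": 0, "significant_profiles": 0, "note": "no DEG"}
        candidates = profiles.generate_candidate_profiles(
            d=len(config.dose_order), c=config.profile_step
        )
        library = profiles.select_model_profiles(candidates, m=config.max_profiles)
        series = profiles.build_dose_series(
            state["norm"], state["design"], deg, config.dose_order
        )
        assignments = profiles.assign_genes(series, library, min_r=config.min_r)
        signif = profiles.profile_significance(
            assignments,
            series,
            library,
            n_perm=config.n_perm,
            seed=config.seed,
            min_r=config.min_r,
        )
        assignments.to_csv(outdir / "assignments.tsv", sep="\t", index_label="gene")
        signif.to_csv(outdir / "profile_significance.tsv", sep="\t", index=False)
        state["assignments"] = assignments
        state["profile_significance"] = signif
        return {
            "library_size": len(library),
            "assigned": int(assignments["retained"].sum()),
            "significant_profiles": int(signif["significant"].sum()),
        }

    @stage("ssgsea")
    def _ssgsea():
        scores = ssgsea.ssgsea_score(
            state["norm"], state["gene_sets"], tau=config.tau
        )
        filtered = ssgsea.score_sd_filter(scores, sd_max=config.score_sd_max)
        scores.to_csv(outdir / "ssgsea_scores.tsv", sep="\t", index_label="gene_set")
        state["scores"] = scores
        state["scores_filtered"] = filtered
        return {"sets_scored": len(scores), "sets_after_sd_filter": len(filtered)}

    @stage("associations")
    def _assoc():
        otus = state["otu_table"]
        phenos = state["phenotypes"]
        rel = otus.relative_abundance()
        edges_op = association.otu_phenotype_screen(otus, phenos)
        edges_op.to_csv(outdir / "edges_otu_phenotype.tsv", sep="\t", index=False)

        results = {"otu_phenotype_edges": len(edges_op)}
        switch_genes = (
            sorted(set(state["switches"]["gene"])) if "switches" in state else []
        )
        if switch_genes:
            gene_expr = state["norm"].data.loc[switch_genes]
            edges_go = association.screen(
                gene_expr,
                rel,
                r_min=config.r_min,
                p_max=config.p_max,
                layer_a="gene",
                layer_b="otu",
            )
            edges_go.to_csv(outdir / "edges_gene_otu.tsv", sep="\t", index=False)
            results["gene_otu_edges_pass"] = int(edges_go["pass"].sum())
            state["edges_gene_otu"] = edges_go
        if "scores" in state and len(state["scores"]):
            edges_po = association.screen(
                state["scores"],
                rel,
                r_min=config.r_min,
                p_max=config.p_max,
                correction="bh",
                layer_a="pathway",
                layer_b="otu",
            )
            edges_po.to_csv(outdir / "edges_pathway_otu.tsv", sep="\t", index=False)
            results["pathway_otu_edges_pass"] = int(edges_po["pass"].sum())
        return results

    @stage("cca")
    def _cca():
        otus = state["otu_table"]
        phenos = state["phenotypes"]
        constraints = phenos.data[["se_content", "laying_rate"]].copy()
        if "scores_filtered" in state and len(state["scores_filtered"]):
            # pathway-score explanatory variables (SD-filtered sets)
            scores_t = state["scores_filtered"].T
            scores_t.columns = [f"score_{c}" for c in scores_t.columns]
            constraints = constraints.join(scores_t)
        pruned, dropped_vars = ordination.vif_prune(
            constraints.dropna(), threshold=config.vif_threshold
        )
        community = otus.data.T.loc[pruned.index]
        result = ordination.cca_fit(community, pruned)
        for name, df in (
            ("site_scores", result.site_scores),
            ("feature_scores", result.feature_scores),
            ("biplot_scores", result.biplot_scores),
        ):
            df.to_csv(outdir / f"cca_{name}.tsv", sep="\t")
        pd.DataFrame(
            {
                "axis": [f"CCA{i+1}" for i in range(len(result.constrained_eigenvalues))],
                "eigenvalue": result.constrained_eigenvalues,
            }
        ).to_csv(outdir / "cca_eigenvalues.tsv", sep="\t", index=False)
        return {
            "constrained_eigenvalues": [
                round(float(v), 10) for v in result.constrained_eigenvalues
            ],
            "total_inertia": round(result.total_inertia, 10),
            "constrained_inertia": round(result.constrained_inertia, 10),
            "dropped_variables": dropped_vars,
        }

    summary["timings_s"]["total"] = round(time.time() - t_start, 3)
    summary["parameters"] = {
        k: v
        for k, v in vars(config).items()
        if k not in ("sim_overrides",) and not isinstance(v, (dict,))
    }
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=str) + "\n"
    )
    return summary
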