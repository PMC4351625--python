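"""Pipeline orchestration: simulate/load -> DMPs -> annotation -> DMRs ->
multivariate discrimination, with one structured config, logging and a
manifest.  Every stage's outputs are plain TSV files; rerunning with the
same seed reproduces them byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from .annotate import assign_features, boundary_profile, chromosome_density
from .discriminant import discriminant_report, region_feature_matrix
from .dmp import FdrPolicy, call_dmps
from .dmr import DmrParams, call_group_dmrs
from .formats_io import (GenomeAnnotation, read_annotation, read_centromeres,
                         read_chrom_sizes, read_table, write_table)
from .matrix import MethylomeMatrix
from .synthetic import SimulationConfig, simulate_study, write_study

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    input: dict = field(default_factory=dict)       # or pre-existing files
    reference_group: str = "wildtype"
    comparisons: list = field(default_factory=list)  # [[test, reference], ...]
    cg_fdr: float = 0.05
    non_cg_prefilter: float = 0.05
    non_cg_fdr: float = 0.035
    dmr_contexts: tuple = ("CG", "CHG")
    dmr: dict = field(default_factory=dict)          # DmrParams overrides
    profile_bin: int = 100
    profile_span: int = 2000
    density_window: int = 100_000
    n_components: int = 4
    n_functions: int = 2
    cv_folds: int = 10
    cv_repeats: int = 100

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def policies(self) -> dict[str, FdrPolicy]:
        return {
            "CG": FdrPolicy("CG", self.cg_fdr),
            "CHG": FdrPolicy("CHG", self.non_cg_fdr, self.non_cg_prefilter),
            "CHH": FdrPolicy("CHH", self.non_cg_fdr, self.non_cg_prefilter),
        }


def _load_inputs(cfg: PipelineConfig
                 ) -> tuple[GenomeAnnotation, MethylomeMatrix, dict[str, str]]:
    inp = cfg.input
    matrix = MethylomeMatrix.from_reports(inp["reports"])
    features = read_annotation(inp["annotation"], inp.get("dialect", "BED"))
    sizes = read_chrom_sizes(inp["chrom_sizes"])
    cents = read_centromeres(inp["centromeres"]) if "centromeres" in inp else {}
    groups_df = read_table(inp["groups"])
    groups = dict(zip(groups_df["sample"], groups_df["group"]))
    return GenomeAnnotation(sizes, cents, features), matrix, groups


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to disk)."""
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stages": []}

    def record(stage: str, rows: int, **params) -> None:
        logger.info("stage %-12s rows=%-6d %s", stage, rows, params)
        manifest["stages"].append(
            {"name": stage, "rows": int(rows), "params": params})

    # --- stage: data ------------------------------------------------------
    if config.input:
        try:
            annotation, matrix, groups = _load_inputs(config)
        except (KeyError, OSError, ValueError) as exc:
            raise PipelineError("load", str(exc)) from exc
        record("load", matrix.n_sites, samples=len(matrix.samples))
    else:
        sim_kwargs = dict(config.simulation)
        sim_kwargs.setdefault("seed", config.seed)
        sim = SimulationConfig(**sim_kwargs)
        annotation, matrix, truth = simulate_study(sim)
        groups = truth.profile_labels
        write_study(os.path.join(config.out_dir, "study"), annotation,
                    matrix, truth)
        record("simulate", matrix.n_sites, samples=len(matrix.samples),
               planted_dmps=len(truth.planted_dmps),
               planted_dmrs=len(truth.planted_dmrs))

    group_names = sorted(set(groups.values()))
    if config.reference_group not in group_names:
        raise PipelineError(
            "validate", f"reference group {config.reference_group!r} not in "
            f"{group_names}")
    by_group: dict[str, list[str]] = {}
    for s, g in groups.items():
        by_group.setdefault(g, []).append(s)
    comparisons = [tuple(c) for c in config.comparisons] or [
        (by_group[g][0], by_group[config.reference_group][0])
        for g in group_names if g != config.reference_group]
    for a, b in comparisons:
        if a not in groups or b not in groups:
            raise PipelineError("validate", f"comparison ({a},{b}) names an "
                                "unknown sample")

    # --- stage: pairwise DMPs + annotation --------------------------------
    policies = config.policies()
    all_dmp_tables = {}
    for a, b in comparisons:
        dmps = call_dmps(matrix, a, b, policies)
        annotated = assign_features(dmps, annotation)
        tag = f"{a}_vs_{b}"
        write_table(annotated, os.path.join(config.out_dir,
                                            f"dmps_{tag}.tsv"))
        all_dmp_tables[tag] = annotated
        record(f"dmps:{tag}", len(annotated),
               dmp=int((annotated["status"] == "DMP").sum()),
               ndmp=int((annotated["status"] == "NDMP").sum()))
        called = annotated[annotated["status"] == "DMP"]
        if len(called):
            prof = boundary_profile(called, annotation,
                                    bin_width=config.profile_bin,
                                    span=config.profile_span)
            write_table(prof, os.path.join(config.out_dir,
                                           f"profile_{tag}.tsv"))
            record(f"profile:{tag}", len(prof))
        dens = chromosome_density(
            called, annotated[annotated["status"] == "NDMP"],
            annotation.chrom_sizes, config.density_window)
        write_table(dens, os.path.join(config.out_dir, f"density_{tag}.tsv"))
        record(f"density:{tag}", len(dens), window=config.density_window)

    # --- stage: group-wise DMRs -------------------------------------------
    params = DmrParams(**config.dmr)
    dmr_tables = []
    for g in group_names:
        if g == config.reference_group:
            continue
        contrast = {s: grp for s, grp in groups.items()
                    if grp in (g, config.reference_group)}
        for ctx in config.dmr_contexts:
            dmrs = call_group_dmrs(matrix, contrast, ctx, params)
            dmrs["contrast"] = f"{g}_vs_{config.reference_group}"
            dmr_tables.append(dmrs)
            record(f"dmrs:{g}:{ctx}", len(dmrs),
                   significant=int((dmrs["status"] == "significant").sum())
                   if len(dmrs) else 0)
    all_dmrs = pd.concat(dmr_tables, ignore_index=True) if dmr_tables else \
        pd.DataFrame()
    write_table(all_dmrs, os.path.join(config.out_dir, "dmrs.tsv"))

    # --- stage: multivariate discrimination -------------------------------
    sig = all_dmrs[all_dmrs["status"] == "significant"] if len(all_dmrs) \
        else all_dmrs
    if len(sig) >= 2:
        regions = sig.drop_duplicates(["chrom", "start", "end", "context"])
        X = region_feature_matrix(regions, matrix)
        report = discriminant_report(
            X, groups, n_components=config.n_components,
            n_functions=config.n_functions, cv_folds=config.cv_folds,
            cv_repeats=config.cv_repeats, seed=config.seed)
        _write_report(report, X, config.out_dir)
        record("discriminate", len(X.columns),
               pillai=round(report["pillai"], 6),
               cv_lda=round(report["cv_lda"].mean_accuracy, 4),
               cv_svm=round(report["cv_svm"].mean_accuracy, 4))
    else:
        logger.warning("fewer than 2 significant DMRs; discriminant stage "
                       "skipped")
        record("discriminate", 0, skipped=True)

    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _write_report(report: dict, X: pd.DataFrame, out_dir: str) -> None:
    samples = report["samples"]
    pca, lda = report["pca"], report["lda"]
    write_table(pd.DataFrame(
        pca.scores, index=samples,
        columns=[f"PC{i+1}" for i in range(pca.scores.shape[1])]
    ).rename_axis("sample").reset_index(),
        os.path.join(out_dir, "pc_scores.tsv"))
    write_table(pd.DataFrame(
        {"component": [f"PC{i+1}" for i in
                       range(len(pca.variance_fractions))],
         "variance_fraction": pca.variance_fractions}),
        os.path.join(out_dir, "pc_variance.tsv"))
    ld_cols = [f"LD{i+1}" for i in range(lda.coordinates.shape[1])]
    coords = pd.DataFrame(lda.coordinates, index=samples, columns=ld_cols)
    coords["group"] = report["labels"]
    coords["ward_cluster"] = report["cluster_labels"]
    write_table(coords.rename_axis("sample").reset_index(),
                os.path.join(out_dir, "ld_coordinates.tsv"))
    if lda.region_loadings is not None:
        write_table(pd.DataFrame(lda.region_loadings, index=X.columns,
                                 columns=ld_cols
                                 ).rename_axis("region").reset_index(),
                    os.path.join(out_dir, "ld_loadings.tsv"))
    summary = pd.DataFrame([
        {"metric": "pillai_trace", "value": report["pillai"]},
        {"metric": "pillai_p", "value": report["pillai_p"]},
        {"metric": "cv_accuracy_lda", "value":
            report["cv_lda"].mean_accuracy},
        {"metric": "cv_accuracy_lda_sd", "value":
            report["cv_lda"].sd_accuracy},
        {"metric": "cv_accuracy_svm", "value":
            report["cv_svm"].mean_accuracy},
        {"metric": "cv_accuracy_svm_sd", "value":
            report["cv_svm"].sd_accuracy},
        {"metric": "cv_folds", "value": report["cv_lda"].folds},
    ])
    write_table(summary, os.path.join(out_dir, "discriminant_summary.tsv"))
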