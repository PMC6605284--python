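"""End-to-end orchestration of the pathway polygenic score analysis.

One call runs the full chain on file inputs: read and filter summary
statistics, mask long-range LD regions, harmonize cohorts, clump against
the reference panel, sweep score thresholds for the whole-genome, pathway
and pathway-complement SNP sets, meta-analyse cohorts per threshold, run
the competitive permutation null where the pathway score is significant,
and finish with the LD-aware gene and gene-set stage on the SNP-level
meta-analysed target.  Every stage logs its counts; outputs are
tab-delimited tables plus a JSON manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genes as genes_mod
from . import genestats, permutation, score, sumstats
from .errors import ConfigError, ThresholdEmptyError
from .ldpanel import ClumpParams, clump, load_panel, write_clump_result

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

ALL_LABEL = "all"
SET_LABEL = "pathway"
COMP_LABEL = "pathway_complement"


@dataclass
class RunConfig:
    """Everything one analysis run needs; maps 1:1 onto the config file."""

    discovery: str
    targets: list
    panel: str
    genes: str
    gene_set: str
    out_dir: str = "pathprs_out"
    min_maf: float = 0.01
    apply_masks: bool = True
    clump_p1: float = 0.5
    clump_p2: float = 0.5
    clump_kb: int = 300
    clump_r2: float = 0.05
    thresholds: list = field(default_factory=lambda: list(score.DEFAULT_THRESHOLDS))
    score_upstream_kb: float = 0.0
    score_downstream_kb: float = 0.0
    gene_upstream_kb: float = 35.0
    gene_downstream_kb: float = 10.0
    n_perm: int = 1000
    match_bins: int = 10
    permute_all: bool = False
    meta_method: str = "fixed"
    standardize_snp_meta: bool = True
    diag_threshold: float = 0.01
    seed: int = 0

    def clump_params(self) -> ClumpParams:
        return ClumpParams(self.clump_p1, self.clump_p2, self.clump_kb, self.clump_r2)


def load_config(path) -> RunConfig:
    """Read a flat key-value YAML run configuration.

    The file must declare ``schema_version``; unknown keys are a hard
    error (silent typos in analysis configs are a reproducibility hazard).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a flat key-value mapping")
    version = raw.pop("schema_version", None)
    if version != SCHEMA_VERSION:
        raise ConfigError(
            f"{path}: schema_version must be {SCHEMA_VERSION}, got {version!r}"
        )
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {unknown}")
    missing = [k for k in ("discovery", "targets", "panel", "genes", "gene_set")
               if k not in raw]
    if missing:
        raise ConfigError(f"{path}: missing mandatory keys {missing}")
    return RunConfig(**raw)


@dataclass
class AnalysisReport:
    """In-memory results of one full run."""

    per_threshold: pd.DataFrame
    meta_table: pd.DataFrame
    permutations: list
    gene_stats: list
    gene_set_result: object | None
    diagnostics: dict
    contributions: pd.DataFrame | None
    manifest: dict


def run_full_analysis(cfg: RunConfig, write: bool = True) -> AnalysisReport:
    """Execute every stage of the analysis described by ``cfg``."""
    out = Path(cfg.out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}}

    # --- inputs -----------------------------------------------------------
    discovery = sumstats.read_summary_stats(cfg.discovery, trait_label="discovery")
    targets = [
        sumstats.read_summary_stats(p, trait_label=f"target{k + 1}")
        for k, p in enumerate(cfg.targets)
    ]
    discovery = sumstats.filter_maf(discovery, cfg.min_maf)
    targets = [sumstats.filter_maf(t, cfg.min_maf) for t in targets]
    if cfg.apply_masks:
        discovery = sumstats.exclude_regions(discovery, sumstats.DEFAULT_MASKS)
    panel = load_panel(cfg.panel)
    annotation = genes_mod.read_gene_annotation(cfg.genes)
    gene_list = genes_mod.read_gene_set(cfg.gene_set)
    manifest["stages"]["inputs"] = {
        "n_disc_snps": discovery.n_snps,
        "n_target_snps": [t.n_snps for t in targets],
        "panel_snps": panel.n_snps,
        "panel_samples": panel.sample_count,
        "n_genes": len(annotation),
        "n_set_genes": len(gene_list),
        "masks_applied": cfg.apply_masks,
    }

    score_window = genes_mod.GeneWindowPolicy(cfg.score_upstream_kb, cfg.score_downstream_kb)
    gene_window = genes_mod.GeneWindowPolicy(cfg.gene_upstream_kb, cfg.gene_downstream_kb)

    # --- per-cohort: harmonize, clump, sweep ------------------------------
    sweep_frames = []
    cohort_results: dict[str, dict] = {}
    for k, target in enumerate(targets):
        cohort = target.trait_label
        aligned = sumstats.harmonize(discovery, target)
        result = clump(aligned, panel, cfg.clump_params())
        index = result.index_snps
        pathway = genes_mod.build_pathway_set(
            aligned, annotation, gene_list, score_window, label=SET_LABEL
        )
        complement = genes_mod.complement_set(aligned, pathway)
        index_set = set(index)
        sets = {
            ALL_LABEL: index_set,
            SET_LABEL: pathway.snp_ids & index_set,
            COMP_LABEL: complement.snp_ids & index_set,
        }
        sweeps = {
            label: score.threshold_sweep(
                aligned, ids, cfg.thresholds, target.cohort_n, set_label=label
            )
            for label, ids in sets.items()
        }
        for label, sw in sweeps.items():
            sweep_frames.append(score.sweep_frame(sw, cohort=cohort))
        cohort_results[cohort] = {
            "aligned": aligned,
            "clump": result,
            "pathway": pathway,
            "sets": sets,
            "sweeps": sweeps,
            "target_n": target.cohort_n,
        }
        manifest["stages"][f"cohort_{cohort}"] = {
            "aligned_snps": aligned.n_snps,
            "index_snps": result.n_index,
            "clump_assigned": len(result.assignments),
            "missing_from_panel": result.n_missing_panel,
            "pathway_snps": pathway.size,
        }
        if write:
            write_clump_result(result, aligned, out / f"clump_{cohort}.tsv")
    per_threshold = pd.concat(sweep_frames, ignore_index=True)

    # --- cross-cohort meta per (threshold, set) ---------------------------
    meta_rows = []
    for label in (ALL_LABEL, SET_LABEL, COMP_LABEL):
        for t in cfg.thresholds:
            ests = []
            for cohort, res in cohort_results.items():
                a = next(x for x in res["sweeps"][label] if x.threshold == t)
                if a.status == "ok":
                    ests.append((a.ahat, a.se))
            if not ests:
                continue
            mr = sumstats.meta_estimates(ests, method=cfg.meta_method)
            meta_rows.append(
                {
                    "COHORT": "meta",
                    "PT": t,
                    "N_SNPS": int(
                        sum(
                            next(x for x in r["sweeps"][label] if x.threshold == t).n_snps
                            for r in cohort_results.values()
                        )
                        / max(len(cohort_results), 1)
                    ),
                    "ESTIMATE": mr.estimate,
                    "SE": mr.se,
                    "Z": mr.z,
                    "P": mr.pvalue,
                    "K_STUDIES": mr.k_studies,
                    "SET_LABEL": label,
                }
            )
    meta_table = pd.DataFrame(meta_rows)

    # --- competitive permutation ------------------------------------------
    sig = meta_table.loc[
        (meta_table["SET_LABEL"] == SET_LABEL) & (meta_table["P"] < 0.05), "PT"
    ].tolist()
    perm_thresholds = cfg.thresholds if cfg.permute_all else sig
    permutations = []
    for cohort, res in cohort_results.items():
        for j, t in enumerate(perm_thresholds):
            spec = permutation.PermutationSpec(
                n_perm=cfg.n_perm,
                match_bins=cfg.match_bins,
                seed=cfg.seed + 1000 * (j + 1),
                threshold=t,
            )
            try:
                pr = permutation.permutation_test(
                    res["aligned"], res["clump"].index_snps, res["pathway"],
                    spec, res["target_n"],
                )
            except Exception as exc:  # keep partial outputs on stage failure
                logger.warning("permutation %s@%g failed: %s", cohort, t, exc)
                continue
            permutations.append((cohort, pr))
    manifest["stages"]["permutation"] = {
        "thresholds": list(map(float, perm_thresholds)),
        "results": [
            {"cohort": c, **pr.summary()} for c, pr in permutations
        ],
    }

    # --- gene / gene-set stage on the SNP-level meta-analysed target ------
    gene_stats_list: list = []
    gs_result = None
    if len(targets) >= 2:
        meta_ds = sumstats.meta_snp(targets, standardize=cfg.standardize_snp_meta)
    else:
        meta_ds = targets[0]
    coding = annotation.loc[annotation["coding"]].reset_index(drop=True)
    gene_map = genes_mod.map_snps_to_genes(meta_ds, coding, gene_window)
    gene_stats_list, excluded = genestats.gene_analysis(meta_ds, gene_map, panel)
    try:
        gs_result = genestats.gene_set_regression(
            gene_stats_list, gene_list, coding, excluded
        )
        manifest["stages"]["gene_set"] = gs_result.summary()
    except Exception as exc:
        logger.warning("gene-set regression failed: %s", exc)
        manifest["stages"]["gene_set"] = {"error": str(exc)}
    manifest["stages"]["genes"] = {
        "n_analysed": len(gene_stats_list),
        "n_excluded": len(excluded),
        "excluded": sorted(excluded),
    }

    # --- per-SNP diagnostics / gene contributions --------------------------
    diagnostics = {}
    nearest = genes_mod.nearest_gene_map(
        cohort_results[targets[0].trait_label]["aligned"].df, annotation
    )
    for cohort, res in cohort_results.items():
        try:
            table, line = score.snp_diagnostics(
                res["aligned"], res["sets"][SET_LABEL], cfg.diag_threshold,
                res["target_n"], nearest, set_label=SET_LABEL,
            )
            diagnostics[cohort] = (table, line)
        except ThresholdEmptyError:
            logger.info("diagnostics empty for %s at PT=%g", cohort, cfg.diag_threshold)
    contributions = None
    if diagnostics:
        first = next(iter(cohort_results.values()))
        contributions = genes_mod.gene_contributions(
            {c: t for c, (t, _) in diagnostics.items()}, first["pathway"]
        )

    # --- outputs -----------------------------------------------------------
    if write:
        run_meta = {
            "seed": cfg.seed,
            "thresholds": list(map(float, cfg.thresholds)),
            "clump": dataclasses.asdict(cfg.clump_params()),
            "n_rows": len(per_threshold),
        }
        sumstats.write_table(per_threshold, out / "associations.tsv",
                             metadata=run_meta)
        sumstats.write_table(meta_table, out / "meta_associations.tsv",
                             metadata={**run_meta, "method": cfg.meta_method,
                                       "n_rows": len(meta_table)})
        for c, pr in permutations:
            base = out / f"permutation_{c}_pt{pr.spec.threshold:g}"
            pd.DataFrame({"NULL_R2": pr.null_r2}).to_csv(
                f"{base}.tsv", sep="\t", index=False
            )
            with open(f"{base}.json", "w") as fh:
                json.dump(pr.summary(), fh, indent=2, sort_keys=True)
        if gene_stats_list:
            sumstats.write_table(
                genestats.gene_stats_frame(gene_stats_list), out / "gene_stats.tsv"
            )
        if gs_result is not None:
            with open(out / "gene_set_result.json", "w") as fh:
                json.dump(gs_result.summary(), fh, indent=2, sort_keys=True)
        for c, (table, line) in diagnostics.items():
            sumstats.write_table(table, out / f"diagnostics_{c}.tsv", metadata=line)
        if contributions is not None:
            sumstats.write_table(contributions, out / "gene_contributions.tsv")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=float)

    return AnalysisReport(
        per_threshold=per_threshold,
        meta_table=meta_table,
        permutations=permutations,
        gene_stats=gene_stats_list,
        gene_set_result=gs_result,
        diagnostics=diagnostics,
        contributions=contributions,
        manifest=manifest,
    )
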