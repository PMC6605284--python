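"""SNP-to-gene mapping and pathway SNP sets.

Genes are 1-based closed intervals with strand; SNPs are assigned to a
gene if they fall inside the gene body extended by a strand-aware window
(upstream is 5' of the transcription start, so it lies to the left of a
'+' gene and to the right of a '-' gene).  The pathway SNP set is the
union of the member genes' SNPs intersected with the aligned score table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import FormatError, GeneSetError
from .sumstats import AlignedScoreTable, SummaryDataset, _normalize_chrom

logger = logging.getLogger(__name__)

GENE_COLUMNS = ["gene_id", "chrom", "start_bp", "end_bp", "strand", "coding"]


@dataclass(frozen=True)
class GeneWindowPolicy:
    """Strand-aware flanking window in kb around the gene body."""

    upstream_kb: float = 35.0
    downstream_kb: float = 10.0

    def __post_init__(self) -> None:
        if self.upstream_kb < 0 or self.downstream_kb < 0:
            raise ValueError("window sizes must be non-negative")


#: regulatory-region window used for the gene-level (MAGMA-style) analysis
GENE_ANALYSIS_WINDOW = GeneWindowPolicy(35.0, 10.0)
#: gene-body-only window used when restricting the polygenic score itself
SCORE_WINDOW = GeneWindowPolicy(0.0, 0.0)


@dataclass
class SnpSet:
    """A labelled SNP set with per-SNP gene provenance."""

    label: str
    snp_ids: set
    provenance: dict

    @property
    def size(self) -> int:
        return len(self.snp_ids)


def read_gene_annotation(path) -> pd.DataFrame:
    """Read a gene annotation table (6-column TSV or BED).

    The TSV layout is ``GENE CHR START END STRAND CODING`` with 1-based
    closed coordinates.  Files whose name ends in ``.bed`` are parsed as
    BED (0-based half-open, columns chrom/start/end/name[/score/strand])
    and converted to 1-based closed; BED genes are flagged coding.
    Genes lacking strand default to '+' with a log message.
    """
    path = str(path)
    if path.endswith(".bed"):
        bed = pd.read_csv(path, sep="\t", header=None, comment="#")
        if bed.shape[1] < 4:
            raise FormatError(f"{path}: BED needs at least 4 columns")
        df = pd.DataFrame(
            {
                "gene_id": bed[3].astype(str),
                "chrom": _normalize_chrom(bed[0]),
                "start_bp": bed[1].astype(int) + 1,  # 0-based half-open -> 1-based closed
                "end_bp": bed[2].astype(int),
                "strand": bed[5].astype(str) if bed.shape[1] > 5 else ".",
                "coding": True,
            }
        )
    else:
        raw = pd.read_csv(path, sep="\t")
        need = ["GENE", "CHR", "START", "END", "STRAND", "CODING"]
        missing = [c for c in need if c not in raw.columns]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
        df = pd.DataFrame(
            {
                "gene_id": raw["GENE"].astype(str),
                "chrom": _normalize_chrom(raw["CHR"]),
                "start_bp": raw["START"].astype(int),
                "end_bp": raw["END"].astype(int),
                "strand": raw["STRAND"].astype(str),
                "coding": raw["CODING"].astype(bool),
            }
        )
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        logger.info("%d genes lack strand; defaulting to '+'", int(bad_strand.sum()))
        df.loc[bad_strand, "strand"] = "+"
    if (df["start_bp"] > df["end_bp"]).any():
        raise FormatError(f"{path}: gene with start > end")
    return df.reset_index(drop=True)


def read_gene_set(path) -> list[str]:
    """Read a gene-set file: one gene id per line, '#' comments allowed."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.append(line)
    return genes


def _windows(genes: pd.DataFrame, policy: GeneWindowPolicy) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene (lo, hi) bp bounds after applying the strand-aware window."""
    up = int(round(policy.upstream_kb * 1000))
    down = int(round(policy.downstream_kb * 1000))
    plus = (genes["strand"] == "+").to_numpy()
    lo = genes["start_bp"].to_numpy() - np.where(plus, up, down)
    hi = genes["end_bp"].to_numpy() + np.where(plus, down, up)
    return lo, hi


def map_snps_to_genes(
    ds: SummaryDataset | AlignedScoreTable | pd.DataFrame,
    genes: pd.DataFrame,
    policy: GeneWindowPolicy = GENE_ANALYSIS_WINDOW,
    coding_only: bool = False,
) -> dict[str, list[str]]:
    """Assign SNPs to genes; returns ``gene_id -> sorted SNP id list``.

    A SNP may map to several overlapping genes (multi-assignment is
    expected near gene clusters).  ``coding_only`` restricts the gene
    universe to protein-coding annotations.
    """
    if len(genes) == 0:
        raise GeneSetError("empty gene annotation")
    df = ds.df if hasattr(ds, "df") else ds
    if coding_only:
        genes = genes.loc[genes["coding"]]
    genes = genes.reset_index(drop=True)
    lo, hi = _windows(genes, policy)
    out: dict[str, list[str]] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        srt = np.argsort(pos, kind="mergesort")
        pos_sorted = pos[srt]
        ids_sorted = sub["snp_id"].to_numpy()[srt]
        g_rows = np.flatnonzero((genes["chrom"] == chrom).to_numpy())
        for g in g_rows:
            a = np.searchsorted(pos_sorted, lo[g], side="left")
            b = np.searchsorted(pos_sorted, hi[g], side="right")
            if b > a:
                out[genes.at[g, "gene_id"]] = sorted(ids_sorted[a:b])
    return out


def build_pathway_set(
    aligned: AlignedScoreTable,
    genes: pd.DataFrame,
    gene_list: list[str],
    policy: GeneWindowPolicy = SCORE_WINDOW,
    label: str = "pathway",
) -> SnpSet:
    """SNP set spanned by ``gene_list``, restricted to the aligned table.

    Raises if any listed gene is absent from the annotation (a silent
    no-op on a mistyped gene id would corrupt the analysis).
    """
    if not gene_list:
        raise GeneSetError("empty gene list")
    known = set(genes["gene_id"])
    missing = [g for g in gene_list if g not in known]
    if missing:
        raise GeneSetError(f"genes absent from annotation: {missing}")
    sub = genes.loc[genes["gene_id"].isin(gene_list)].reset_index(drop=True)
    mapping = map_snps_to_genes(aligned, sub, policy)
    provenance: dict[str, list[str]] = {}
    for gene, snps in mapping.items():
        for s in snps:
            provenance.setdefault(s, []).append(gene)
    provenance = {s: sorted(gs) for s, gs in provenance.items()}
    return SnpSet(label, set(provenance), provenance)


def complement_set(aligned: AlignedScoreTable, snp_set: SnpSet) -> SnpSet:
    """All aligned SNPs not in ``snp_set`` (the set-excluded score)."""
    universe = set(aligned.df["snp_id"])
    comp = universe - snp_set.snp_ids
    if not comp:
        logger.warning("complement of %s is empty", snp_set.label)
    return SnpSet(f"{snp_set.label}_complement", comp, {})


def nearest_gene_map(
    df: pd.DataFrame, genes: pd.DataFrame
) -> dict[str, str]:
    """Nearest gene per SNP by midpoint distance to the gene body.

    Ties go to the lexicographically smaller gene id, for determinism.
    """
    out: dict[str, str] = {}
    mid = ((genes["start_bp"] + genes["end_bp"]) / 2.0).to_numpy()
    for chrom, sub in df.groupby("chrom", sort=False):
        g = np.flatnonzero((genes["chrom"] == chrom).to_numpy())
        if g.size == 0:
            continue
        gids = genes["gene_id"].to_numpy()[g]
        gmid = mid[g]
        order = np.lexsort((gids, gmid))
        gids, gmid = gids[order], gmid[order]
        for snp, pos in zip(sub["snp_id"], sub["pos"]):
            d = np.abs(gmid - pos)
            best = d.min()
            cand = gids[d == best]
            out[snp] = min(cand)
    return out


def gene_contributions(
    diag_tables: dict[str, pd.DataFrame],
    snp_set: SnpSet,
) -> pd.DataFrame:
    """Per-gene contribution report across cohort diagnostic tables.

    For each gene of the set: number of contributing SNPs per cohort, the
    size of the cross-cohort intersection, and the mean target effect
    ``b`` (averaged over cohorts and SNPs).  Genes are ranked by most
    negative mean effect, the ordering used to pick out risk alleles with
    the largest volume-lowering effects.  SNPs in the provenance of more
    than one gene count for each and are flagged ambiguous.
    """
    if not diag_tables:
        raise ValueError("need at least one cohort diagnostics table")
    gene_snps: dict[str, set] = {}
    for snp, gs in snp_set.provenance.items():
        for g in gs:
            gene_snps.setdefault(g, set()).add(snp)
    ambiguous = {s for s, gs in snp_set.provenance.items() if len(gs) > 1}

    rows = []
    for gene, snps in gene_snps.items():
        per_cohort = {}
        present_sets = []
        bvals = []
        for cohort, table in diag_tables.items():
            hit = table.loc[table["snp_id"].isin(snps)]
            per_cohort[f"n_snps_{cohort}"] = len(hit)
            present_sets.append(set(hit["snp_id"]))
            bvals.extend(hit["b"].tolist())
        inter = set.intersection(*present_sets) if present_sets else set()
        rows.append(
            {
                "gene_id": gene,
                **per_cohort,
                "n_intersection": len(inter),
                "mean_b": float(np.mean(bvals)) if bvals else np.nan,
                "n_ambiguous_snps": len(snps & ambiguous),
            }
        )
    rep = pd.DataFrame(rows).sort_values("mean_b", kind="mergesort").reset_index(drop=True)
    rep["rank"] = np.arange(1, len(rep) + 1)
    return rep


def write_snp_set(snp_set: SnpSet, path) -> None:
    """Export a SNP set as two-column TSV (SNP, GENES semicolon-joined)."""
    rows = [
        {"SNP": s, "GENES": ";".join(snp_set.provenance.get(s, []))}
        for s in sorted(snp_set.snp_ids)
    ]
    pd.DataFrame(rows, columns=["SNP", "GENES"]).to_csv(path, sep="\t", index=False)
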