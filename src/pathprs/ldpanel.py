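"""Genotype reference panel, pairwise LD and P-value-ordered clumping.

The panel plays the role 1000 Genomes phase 3 plays in published polygenic
score pipelines: it supplies the linkage-disequilibrium structure used to
prune correlated risk alleles.  LD is the squared Pearson correlation of
additive genotype dosages (0/1/2); no phasing or haplotype estimation is
attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, PanelLookupError
from .sumstats import AlignedScoreTable

logger = logging.getLogger(__name__)


@dataclass
class ReferencePanel:
    """Additive-coded genotypes for LD computation.

    ``dosages`` is an individuals × SNPs matrix with values in [0, 2];
    ``snp_meta`` has one row per column: ``snp_id, chrom, pos, ref_allele,
    alt_allele``.  Monomorphic and multi-allelic sites are never retained.
    """

    dosages: np.ndarray
    snp_meta: pd.DataFrame
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.dosages.shape[1] != len(self.snp_meta):
            raise ValueError("dosage columns and snp_meta rows disagree")
        if not self._index:
            self._index = {s: i for i, s in enumerate(self.snp_meta["snp_id"])}
        if len(self._index) != len(self.snp_meta):
            raise ValueError("duplicate snp_id in panel")

    @property
    def sample_count(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def column(self, snp_id: str) -> np.ndarray:
        try:
            return self.dosages[:, self._index[snp_id]]
        except KeyError:
            raise PanelLookupError(f"SNP {snp_id!r} not in reference panel") from None

    def standardized(self) -> np.ndarray:
        """Column-standardized dosage matrix (mean 0, unit variance)."""
        x = self.dosages - self.dosages.mean(axis=0)
        sd = x.std(axis=0)
        return x / sd


@dataclass(frozen=True)
class ClumpParams:
    """Greedy clumping parameters (index p, clumped p, window, r² cutoff)."""

    p1: float = 0.5
    p2: float = 0.5
    window_kb: int = 300
    r2_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.p1 <= 1 and 0 < self.p2 <= 1):
            raise ValueError("p1 and p2 must lie in (0, 1]")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")
        if not 0 < self.r2_threshold < 1:
            raise ValueError("r2_threshold must lie in (0, 1)")


@dataclass
class ClumpResult:
    """Index SNPs surviving LD pruning, plus removed → index assignments."""

    index_snps: list
    assignments: dict
    params: ClumpParams
    n_missing_panel: int = 0

    @property
    def n_index(self) -> int:
        return len(self.index_snps)


def load_panel(vcf_path, maf_floor: float = 0.0) -> ReferencePanel:
    """Load a VCF into an additive dosage matrix.

    Only biallelic SNPs are retained; multi-allelic, monomorphic and
    MAF <= ``maf_floor`` sites are dropped and counted.  Missing genotypes
    are mean-imputed per site.
    """
    try:
        from cyvcf2 import VCF
        vcf = VCF(str(vcf_path), gts012=True)
    except Exception as exc:  # unreadable / not a VCF
        raise FormatError(f"cannot read VCF {vcf_path}: {exc}") from exc

    cols, meta = [], []
    n_multi = n_mono = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        g = var.gt_types.astype(float)  # 0/1/2, 3 = missing
        missing = g == 3
        if missing.all():
            n_mono += 1
            continue
        if missing.any():
            g[missing] = g[~missing].mean()
        if g.std() == 0:
            n_mono += 1
            continue
        f = g.mean() / 2.0
        if min(f, 1 - f) <= maf_floor:
            n_mono += 1
            continue
        cols.append(g)
        meta.append(
            (var.ID or f"{var.CHROM}:{var.POS}", str(var.CHROM).removeprefix("chr"),
             var.POS, var.REF, var.ALT[0])
        )
    if not cols:
        raise FormatError(f"{vcf_path}: no usable biallelic polymorphic sites")
    logger.info(
        "load_panel: kept %d sites (dropped %d multi-allelic, %d monomorphic/low-MAF)",
        len(cols), n_multi, n_mono,
    )
    dosages = np.column_stack(cols)
    snp_meta = pd.DataFrame(
        meta, columns=["snp_id", "chrom", "pos", "ref_allele", "alt_allele"]
    )
    return ReferencePanel(dosages, snp_meta)


def ld_r2(panel: ReferencePanel, snp_a: str, snp_b: str) -> float:
    """Squared Pearson correlation of two SNPs' dosage vectors."""
    a = panel.column(snp_a)
    b = panel.column(snp_b)
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def clump(
    aligned: AlignedScoreTable,
    panel: ReferencePanel,
    params: ClumpParams = ClumpParams(),
) -> ClumpResult:
    """Greedy P-value-ordered LD clumping.

    Candidates with discovery p <= ``p1`` are visited in ascending
    ``p_disc`` (ties broken by chrom, pos, snp_id).  Each still-unassigned
    candidate becomes an index SNP; every unassigned SNP with p <= ``p2``
    on the same chromosome within ``window_kb`` and r² >= ``r2_threshold``
    with the index is assigned (clumped) to it.  SNPs absent from the
    reference panel are excluded entirely, since their independence cannot
    be certified.
    """
    df = aligned.df
    in_panel = df["snp_id"].map(lambda s: s in panel)
    n_missing = int((~in_panel).sum())
    if n_missing:
        logger.warning("clump: %d aligned SNPs missing from panel (excluded)", n_missing)
    df = df.loc[in_panel].reset_index(drop=True)
    if df.empty or not (df["p_disc"] <= params.p1).any():
        logger.warning("clump: empty candidate set")
        return ClumpResult([], {}, params, n_missing)

    # standardized dosages for vectorized correlation: r = z_a . z_b / n
    cols = np.fromiter((panel._index[s] for s in df["snp_id"]), dtype=int, count=len(df))
    z = panel.dosages[:, cols]
    z = z - z.mean(axis=0)
    z /= z.std(axis=0)
    nsamp = z.shape[0]

    order = df.sort_values(
        ["p_disc", "chrom", "pos", "snp_id"], kind="mergesort"
    ).index.to_numpy()
    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy().astype(np.int64)
    pdisc = df["p_disc"].to_numpy()
    snp_ids = df["snp_id"].to_numpy()
    window_bp = params.window_kb * 1000

    # per-chromosome position-sorted views for fast window lookup
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in pd.unique(chrom):
        rows = np.flatnonzero(chrom == c)
        srt = rows[np.argsort(pos[rows], kind="mergesort")]
        by_chrom[c] = (pos[srt], srt)

    assigned = np.zeros(len(df), dtype=bool)
    index_rows: list[int] = []
    assignments: dict[str, str] = {}
    for row in order:
        if assigned[row] or pdisc[row] > params.p1:
            continue
        assigned[row] = True
        index_rows.append(row)
        cpos, crows = by_chrom[chrom[row]]
        lo = np.searchsorted(cpos, pos[row] - window_bp, side="left")
        hi = np.searchsorted(cpos, pos[row] + window_bp, side="right")
        cand = crows[lo:hi]
        cand = cand[~assigned[cand] & (pdisc[cand] <= params.p2)]
        if cand.size:
            r = z[:, cand].T @ z[:, row] / nsamp
            hit = cand[r * r >= params.r2_threshold]
            assigned[hit] = True
            for h in hit:
                assignments[snp_ids[h]] = snp_ids[row]
    index_snps = [snp_ids[i] for i in index_rows]
    logger.info(
        "clump: %d index SNPs, %d assigned, params %s",
        len(index_snps), len(assignments), params,
    )
    return ClumpResult(index_snps, assignments, params, n_missing)


def write_clump_result(result: ClumpResult, aligned: AlignedScoreTable, path) -> None:
    """Write the clump as TSV: INDEX_SNP, CHR, BP, P, N_ASSIGNED, ASSIGNED_IDS."""
    meta = aligned.df.set_index("snp_id")
    groups: dict[str, list[str]] = {s: [] for s in result.index_snps}
    for removed, idx in result.assignments.items():
        groups[idx].append(removed)
    rows = []
    for s in result.index_snps:
        rows.append(
            {
                "INDEX_SNP": s,
                "CHR": meta.at[s, "chrom"],
                "BP": meta.at[s, "pos"],
                "P": meta.at[s, "p_disc"],
                "N_ASSIGNED": len(groups[s]),
                "ASSIGNED_IDS": ";".join(sorted(groups[s])),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
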