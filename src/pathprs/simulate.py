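"""Synthetic reference panels and paired GWAS summary statistics.

Generates everything the pipeline consumes without external downloads: a
genotype panel with block-wise LD, a gene annotation tiling the SNP
coordinate space, a designated gene set, and discovery/target summary
statistics with a shared polygenic signal whose cross-trait covariance
can be concentrated inside the set.

Generative model
----------------
*Genotypes.*  SNPs sit in ``n_blocks`` equal blocks.  Each haplotype draws
a block-wise equicorrelated latent Gaussian (correlation
``within_block_rho`` within a block, independence across blocks) and
carries the alternate allele where the latent value falls below the
allele-frequency quantile; dosage is the sum of two haplotype draws.

*Effects.*  A fraction ``prop_causal`` of SNPs is causal.  Causal effects
for the discovery and target traits are bivariate normal with per-SNP
variances ``h2 / (m_causal · 2 f (1 − f))`` and correlation
``rg_background`` outside the designated gene set and
``min(1, rg_background · enrichment_factor)`` inside it — the enrichment
the competitive tests are built to detect.

*Summary statistics.*  Marginal (LD-smeared) effects are ``R β`` with R
the realized block dosage correlation; the estimated beta adds sampling
noise with SE ``1 / sqrt(n · 2 f (1 − f))``, scaled by the cohort's trait
units.  Case/control discovery GWAS are approximated by a continuous
trait at an effective sample size.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genes import SCORE_WINDOW, GeneWindowPolicy, map_snps_to_genes
from .ldpanel import ReferencePanel
from .sumstats import SummaryDataset

logger = logging.getLogger(__name__)

# ordered, non-palindromic allele pairs (ref, alt); avoids strand-ambiguous
# A/T and C/G sites so harmonization never drops simulated SNPs silently
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults emulate the statistical shape of the real analysis: a large
    discovery GWAS (effective n = 50,000) scoring two hippocampal-volume
    sized target cohorts (13,163 and 9,707), a 56-gene set among 1,000
    genes, and moderate polygenicity (5% causal SNPs, h² = 0.3 per trait,
    background cross-trait effect correlation 0.1 concentrated five-fold
    inside the set).
    """

    n_snps: int = 20_000
    n_blocks: int = 200
    within_block_rho: float = 0.8
    maf_range: tuple = (0.05, 0.5)
    panel_n: int = 500
    n_genes: int = 1_000
    gene_length_kb: tuple = (10.0, 100.0)
    set_size: int = 56
    prop_causal: float = 0.05
    h2_disc: float = 0.3
    h2_targ: float = 0.3
    rg_background: float = 0.1
    enrichment_factor: float = 5.0
    n_disc: int = 50_000
    n_targ: tuple = (13_163, 9_707)
    trait_scales: tuple | None = None
    snp_spacing_bp: int = 3_000
    block_gap_bp: int = 200_000
    n_chroms: int = 22
    allele_swap_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prop_causal <= 1:
            raise ValueError("prop_causal must lie in (0, 1]")
        if not (0 <= self.h2_disc < 1 and 0 <= self.h2_targ < 1):
            raise ValueError("heritabilities must lie in [0, 1)")
        if not 0 <= self.within_block_rho < 1:
            raise ValueError("within_block_rho must lie in [0, 1)")
        if not -1 <= self.rg_background <= 1:
            raise ValueError("rg_background must lie in [-1, 1]")
        if self.enrichment_factor < 0:
            raise ValueError("enrichment_factor must be >= 0")
        if self.set_size > self.n_genes:
            raise ValueError("set_size cannot exceed the number of genes")
        if self.n_snps % self.n_blocks:
            raise ValueError("n_snps must be a multiple of n_blocks")

    @property
    def targets(self) -> tuple:
        return self.n_targ if isinstance(self.n_targ, (tuple, list)) else (self.n_targ,)


@dataclass
class StudyBundle:
    """Everything one synthetic study produces, in memory."""

    config: SimulationConfig
    panel: ReferencePanel
    block_ids: np.ndarray
    genes: pd.DataFrame
    gene_set: list
    set_snp_mask: np.ndarray
    beta_disc: np.ndarray
    beta_targ: np.ndarray
    discovery: SummaryDataset
    targets: list

    def manifest(self) -> dict:
        cfg = self.config
        return {
            "seed": cfg.seed,
            "n_snps": cfg.n_snps,
            "n_blocks": cfg.n_blocks,
            "within_block_rho": cfg.within_block_rho,
            "panel_n": cfg.panel_n,
            "n_genes": cfg.n_genes,
            "set_size": cfg.set_size,
            "prop_causal": cfg.prop_causal,
            "h2_disc": cfg.h2_disc,
            "h2_targ": cfg.h2_targ,
            "rg_background": cfg.rg_background,
            "enrichment_factor": cfg.enrichment_factor,
            "n_disc": cfg.n_disc,
            "n_targ": list(cfg.targets),
            "n_causal": int(np.sum(self.beta_disc != 0)),
            "n_set_snps": int(self.set_snp_mask.sum()),
            "gene_set": list(self.gene_set),
        }


# ---------------------------------------------------------------------------
# panel / annotation


def _block_layout(cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Chromosome and position per SNP; blocks round-robin over chromosomes."""
    m = cfg.n_snps // cfg.n_blocks
    block_span = m * cfg.snp_spacing_bp
    chroms = np.empty(cfg.n_snps, dtype=object)
    pos = np.empty(cfg.n_snps, dtype=np.int64)
    block_ids = np.repeat(np.arange(cfg.n_blocks), m)
    per_chrom_count = np.zeros(cfg.n_chroms, dtype=int)
    for b in range(cfg.n_blocks):
        c = b % cfg.n_chroms
        slot = per_chrom_count[c]
        per_chrom_count[c] += 1
        start = 20_000_001 + slot * (block_span + cfg.block_gap_bp)
        rows = slice(b * m, (b + 1) * m)
        chroms[rows] = str(c + 1)
        pos[rows] = start + np.arange(m) * cfg.snp_spacing_bp
    return chroms, pos, block_ids


def simulate_panel(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ReferencePanel, np.ndarray, pd.DataFrame, list]:
    """Draw the reference panel, gene annotation and gene set.

    Returns ``(panel, block_ids, genes, gene_set)``.  Genes tile the SNP
    coordinate space (placed uniformly within LD blocks, so nearly all
    genes contain SNPs); set genes are sampled uniformly among genes.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    chroms, pos, block_ids = _block_layout(cfg)
    m = cfg.n_snps // cfg.n_blocks
    f = rng.uniform(*cfg.maf_range, size=cfg.n_snps)
    thr = stats.norm.ppf(f)
    rho = cfg.within_block_rho

    dosages = np.empty((cfg.panel_n, cfg.n_snps))
    for b in range(cfg.n_blocks):
        cols = slice(b * m, (b + 1) * m)
        hap_sum = np.zeros((cfg.panel_n, m))
        for _ in range(2):
            shared = rng.standard_normal((cfg.panel_n, 1))
            latent = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal(
                (cfg.panel_n, m)
            )
            hap_sum += latent < thr[cols]
        dosages[:, cols] = hap_sum
    # guard against realized monomorphism (vanishingly rare at these MAFs)
    sd = dosages.std(axis=0)
    for j in np.flatnonzero(sd == 0):
        dosages[0, j] = 1.0 if dosages[0, j] != 1.0 else 2.0
        logger.warning("nudged monomorphic simulated column %d", j)

    pair_idx = rng.integers(len(_ALLELE_PAIRS), size=cfg.n_snps)
    snp_meta = pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1}" for i in range(cfg.n_snps)],
            "chrom": chroms,
            "pos": pos,
            "ref_allele": [_ALLELE_PAIRS[i][0] for i in pair_idx],
            "alt_allele": [_ALLELE_PAIRS[i][1] for i in pair_idx],
        }
    )
    panel = ReferencePanel(dosages, snp_meta)

    genes = _simulate_genes(cfg, chroms, pos, block_ids, rng)
    set_rows = rng.choice(cfg.n_genes, size=cfg.set_size, replace=False)
    gene_set = sorted(genes.loc[set_rows, "gene_id"])
    return panel, block_ids, genes, gene_set


def _simulate_genes(
    cfg: SimulationConfig,
    chroms: np.ndarray,
    pos: np.ndarray,
    block_ids: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Place genes uniformly within LD blocks; lengths ~ U(gene_length_kb)."""
    per_block = np.full(cfg.n_blocks, cfg.n_genes // cfg.n_blocks)
    per_block[: cfg.n_genes % cfg.n_blocks] += 1
    rows = []
    gid = 0
    for b in range(cfg.n_blocks):
        in_block = block_ids == b
        b_lo, b_hi = pos[in_block].min(), pos[in_block].max()
        chrom = chroms[in_block][0]
        for _ in range(per_block[b]):
            length = int(rng.uniform(*cfg.gene_length_kb) * 1000)
            length = min(length, b_hi - b_lo)
            start = int(rng.integers(b_lo, max(b_lo + 1, b_hi - length)))
            gid += 1
            rows.append(
                {
                    "gene_id": f"G{gid:05d}",
                    "chrom": chrom,
                    "start_bp": start,
                    "end_bp": start + length,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "coding": True,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# effects / summary statistics


def simulate_effect_pairs(
    cfg: SimulationConfig,
    set_snp_mask: np.ndarray,
    freqs: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw true per-SNP effects (β_disc, β_targ) under the enrichment model."""
    n = len(set_snp_mask)
    causal = rng.random(n) < cfg.prop_causal
    m_causal = max(int(causal.sum()), 1)
    het = 2.0 * freqs * (1.0 - freqs)
    sd_d = np.sqrt(cfg.h2_disc / (m_causal * het))
    sd_t = np.sqrt(cfg.h2_targ / (m_causal * het))
    r_in = cfg.rg_background * cfg.enrichment_factor
    if abs(r_in) > 1:
        logger.warning("set correlation %.3g clamped to [-1, 1]", r_in)
        r_in = float(np.clip(r_in, -1.0, 1.0))
    r = np.where(set_snp_mask, r_in, cfg.rg_background)

    x = rng.standard_normal(n)
    y = r * x + np.sqrt(1.0 - r**2) * rng.standard_normal(n)
    beta_d = np.where(causal, sd_d * x, 0.0)
    beta_t = np.where(causal, sd_t * y, 0.0)
    return beta_d, beta_t


def _block_marginals(
    panel: ReferencePanel, block_ids: np.ndarray, beta: np.ndarray
) -> np.ndarray:
    """LD-smeared marginal effects R β, block by block on realized LD."""
    out = np.empty_like(beta)
    for b in np.unique(block_ids):
        cols = np.flatnonzero(block_ids == b)
        r = np.corrcoef(panel.dosages[:, cols], rowvar=False)
        out[cols] = r @ beta[cols]
    return out


def simulate_sumstats(
    panel: ReferencePanel,
    block_ids: np.ndarray,
    beta: np.ndarray,
    n: int,
    rng: np.random.Generator,
    trait_label: str = "trait",
    trait_scale: float = 1.0,
    allele_swap_prob: float = 0.0,
) -> SummaryDataset:
    """Summary statistics for one GWAS of ``n`` samples on true effects ``beta``.

    Per SNP the estimated beta is the LD-smeared marginal effect plus
    independent sampling noise, ``se = trait_scale / sqrt(n · 2 f (1 − f))``
    with f the realized alternate-allele frequency.  A fraction of rows
    (``allele_swap_prob``) is reported on the opposite allele — effect sign
    negated, frequency complemented — to exercise downstream allele
    harmonization without changing the statistics.
    """
    f = panel.dosages.mean(axis=0) / 2.0
    marginal = _block_marginals(panel, block_ids, beta)
    se = trait_scale / np.sqrt(n * 2.0 * f * (1.0 - f))
    bhat = trait_scale * marginal + rng.standard_normal(len(beta)) * se
    z = bhat / se
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)

    meta = panel.snp_meta
    ea = meta["alt_allele"].to_numpy().copy()
    oa = meta["ref_allele"].to_numpy().copy()
    eaf = f.copy()
    if allele_swap_prob > 0:
        swap = rng.random(len(beta)) < allele_swap_prob
        ea[swap], oa[swap] = oa[swap].copy(), ea[swap].copy()
        bhat = np.where(swap, -bhat, bhat)
        eaf = np.where(swap, 1.0 - eaf, eaf)

    df = pd.DataFrame(
        {
            "snp_id": meta["snp_id"],
            "chrom": meta["chrom"],
            "pos": meta["pos"],
            "effect_allele": ea,
            "other_allele": oa,
            "beta": bhat,
            "se": se,
            "pvalue": p,
            "eaf": eaf,
            "n": n,
        }
    ).sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return SummaryDataset(df, trait_label=trait_label, cohort_n=n)


def simulate_study(cfg: SimulationConfig) -> StudyBundle:
    """Run the whole generator: panel, genes, set, effects, all cohorts."""
    rng = np.random.default_rng(cfg.seed)
    panel, block_ids, genes, gene_set = simulate_panel(cfg, rng)

    sub = genes.loc[genes["gene_id"].isin(gene_set)].reset_index(drop=True)
    mapping = map_snps_to_genes(panel.snp_meta, sub, SCORE_WINDOW)
    set_ids = {s for snps in mapping.values() for s in snps}
    set_mask = panel.snp_meta["snp_id"].isin(set_ids).to_numpy()

    f = panel.dosages.mean(axis=0) / 2.0
    beta_d, beta_t = simulate_effect_pairs(cfg, set_mask, f, rng)

    discovery = simulate_sumstats(
        panel, block_ids, beta_d, cfg.n_disc, rng,
        trait_label="discovery", allele_swap_prob=cfg.allele_swap_prob,
    )
    scales = cfg.trait_scales or tuple(1.0 for _ in cfg.targets)
    targets = [
        simulate_sumstats(
            panel, block_ids, beta_t, n, rng,
            trait_label=f"target{k + 1}", trait_scale=scale,
            allele_swap_prob=cfg.allele_swap_prob,
        )
        for k, (n, scale) in enumerate(zip(cfg.targets, scales))
    ]
    return StudyBundle(
        config=cfg, panel=panel, block_ids=block_ids, genes=genes,
        gene_set=gene_set, set_snp_mask=set_mask,
        beta_disc=beta_d, beta_targ=beta_t,
        discovery=discovery, targets=targets,
    )


# ---------------------------------------------------------------------------
# writers


def write_vcf(panel: ReferencePanel, path) -> None:
    """Write the panel as a minimal GT-only VCF (v4.2, unphased)."""
    gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    n = panel.sample_count
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sorted(panel.snp_meta["chrom"].unique(), key=str):
            fh.write(f"##contig=<ID={chrom}>\n")
        samples = "\t".join(f"S{i + 1}" for i in range(n))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        meta = panel.snp_meta
        order = meta.sort_values(["chrom", "pos"], kind="mergesort").index
        for i in order:
            row = meta.loc[i]
            calls = "\t".join(gt[int(round(d))] for d in panel.dosages[:, i])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.ref_allele}"
                f"\t{row.alt_allele}\t.\tPASS\t.\tGT\t{calls}\n"
            )


def write_genes(genes: pd.DataFrame, path) -> None:
    out = genes.rename(
        columns={
            "gene_id": "GENE", "chrom": "CHR", "start_bp": "START",
            "end_bp": "END", "strand": "STRAND", "coding": "CODING",
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_gene_set(gene_set: list, path) -> None:
    with open(path, "w") as fh:
        fh.write("# designated gene set\n")
        for g in gene_set:
            fh.write(f"{g}\n")


def write_bundle(bundle: StudyBundle, outdir) -> dict:
    """Write all bundle artifacts; returns the path map."""
    from .sumstats import write_summary_stats

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "panel": outdir / "panel.vcf",
        "genes": outdir / "genes.tsv",
        "gene_set": outdir / "gene_set.txt",
        "discovery": outdir / "discovery.tsv",
        "manifest": outdir / "manifest.json",
    }
    write_vcf(bundle.panel, paths["panel"])
    write_genes(bundle.genes, paths["genes"])
    write_gene_set(bundle.gene_set, paths["gene_set"])
    write_summary_stats(bundle.discovery, paths["discovery"])
    paths["targets"] = []
    for k, t in enumerate(bundle.targets):
        p = outdir / f"target{k + 1}.tsv"
        write_summary_stats(t, p)
        paths["targets"].append(p)
    with open(paths["manifest"], "w") as fh:
        json.dump(bundle.manifest(), fh, indent=2, sort_keys=True)
    return paths
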