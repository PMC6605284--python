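"""GWAS summary-statistic containers, harmonization and meta-analysis.

The central objects are :class:`SummaryDataset` (one cohort's per-SNP
marginal effects, standard errors, p-values, allele frequencies and sample
sizes) and :class:`AlignedScoreTable` (discovery weights paired with target
effects after allele harmonization, oriented to the risk allele).

Summary statistics are exchanged as tab-delimited text with a header; the
canonical columns are ``SNP CHR BP A1 A2 BETA SE P EAF N`` where ``A1`` is
the effect allele.  ``column_map`` lets callers read dialects of that
format without rewriting files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    BuildMismatchError,
    EmptyInputError,
    EmptyOverlapError,
    FormatError,
)

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset({"A", "C", "G", "T"})
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column name -> internal field name
CANONICAL_COLUMNS = {
    "SNP": "snp_id",
    "CHR": "chrom",
    "BP": "pos",
    "A1": "effect_allele",
    "A2": "other_allele",
    "BETA": "beta",
    "SE": "se",
    "P": "pvalue",
    "EAF": "eaf",
    "N": "n",
}

_INTERNAL_FIELDS = list(CANONICAL_COLUMNS.values())


def _normalize_chrom(series: pd.Series) -> pd.Series:
    return series.astype(str).str.replace("^chr", "", regex=True)


@dataclass
class SummaryDataset:
    """One cohort's GWAS summary statistics.

    Parameters
    ----------
    df
        One row per SNP with columns ``snp_id, chrom, pos, effect_allele,
        other_allele, beta, se, pvalue, eaf, n``; unique ``snp_id``, sorted
        by ``(chrom, pos)``.
    trait_label
        Human-readable trait / cohort name.
    cohort_n
        Overall GWAS sample size (used where per-SNP ``n`` is absent and in
        the pseudo-R² of the score association).
    build_tag
        Genome build label; operations combining two datasets require the
        tags to agree (no liftover is attempted).
    """

    df: pd.DataFrame
    trait_label: str = ""
    cohort_n: int = 0
    build_tag: str = "GRCh37"

    @property
    def n_snps(self) -> int:
        return len(self.df)

    def copy(self) -> "SummaryDataset":
        return replace(self, df=self.df.copy())


@dataclass(frozen=True)
class RegionMask:
    """A closed 1-based genomic interval to exclude from scoring."""

    name: str
    chrom: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if not self.start_bp < self.end_bp:
            raise ValueError(f"mask {self.name}: start_bp must be < end_bp")


#: Long-range LD regions conventionally masked in AD polygenic analyses.
MHC_MASK = RegionMask("MHC", "6", 26_000_000, 34_000_000)
APOE_MASK = RegionMask("APOE", "19", 44_400_000, 46_500_000)
DEFAULT_MASKS = (MHC_MASK, APOE_MASK)


def read_region_masks(path) -> list[RegionMask]:
    """Read masks from BED (0-based half-open -> 1-based closed)."""
    masks = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: BED line needs >= 3 columns: {line!r}")
            chrom = parts[0].removeprefix("chr")
            name = parts[3] if len(parts) > 3 else f"{chrom}:{parts[1]}-{parts[2]}"
            masks.append(RegionMask(name, chrom, int(parts[1]) + 1, int(parts[2])))
    return masks


@dataclass
class AlignedScoreTable:
    """Discovery weights joined to target effects, risk-allele oriented.

    ``df`` columns: ``snp_id, chrom, pos, w, b, s, p_disc, p_targ, eaf``.
    ``w`` is the discovery effect oriented so that w >= 0 (the risk-allele
    weight entering the score); ``b``/``s`` are the target effect and SE on
    the same allele; ``eaf`` is the discovery frequency of that allele.
    """

    df: pd.DataFrame
    target_n: int
    discovery_label: str = ""
    target_label: str = ""

    @property
    def n_snps(self) -> int:
        return len(self.df)

    def copy(self) -> "AlignedScoreTable":
        return replace(self, df=self.df.copy())


@dataclass(frozen=True)
class MetaResult:
    """Combined estimate from a study-level meta-analysis."""

    estimate: float
    se: float
    z: float
    pvalue: float
    method: str
    k_studies: int
    tau2: float = 0.0


# ---------------------------------------------------------------------------
# reading / validation


def _validate_records(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop rows violating record invariants; return (valid, drop counts)."""
    counts: dict[str, int] = {}
    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    df = df.assign(effect_allele=ea, other_allele=oa)

    checks = {
        "bad_allele": ~(ea.isin(VALID_ALLELES) & oa.isin(VALID_ALLELES)),
        "same_alleles": ea == oa,
        "nonpositive_se": ~(df["se"] > 0),
        "bad_pvalue": ~((df["pvalue"] > 0) & (df["pvalue"] <= 1)),
        "bad_eaf": ~((df["eaf"] > 0) & (df["eaf"] < 1)),
        "bad_pos": ~(df["pos"] >= 1),
        "missing": df[["beta", "se", "pvalue", "eaf"]].isna().any(axis=1),
    }
    bad = pd.Series(False, index=df.index)
    for reason, mask in checks.items():
        fresh = mask & ~bad
        if fresh.any():
            counts[reason] = int(fresh.sum())
        bad |= mask
    valid = df.loc[~bad]
    dup = valid["snp_id"].duplicated(keep="first")
    if dup.any():
        counts["duplicate_snp_id"] = int(dup.sum())
        valid = valid.loc[~dup]
    return valid, counts


def read_summary_stats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_label: str = "",
    cohort_n: int | None = None,
    build_tag: str = "GRCh37",
    or_scale: bool = False,
) -> SummaryDataset:
    """Read and validate a tab-delimited summary-statistics file.

    Parameters
    ----------
    column_map
        Maps canonical names (``SNP``, ``CHR``, ...) to the file's actual
        column names, for dialects of the canonical layout.
    or_scale
        If true, the effect column holds odds ratios and is log-transformed
        to the beta scale on input.
    cohort_n
        Overall GWAS sample size; defaults to the median per-SNP ``N``.

    Rows violating the per-record invariants (SE <= 0, p outside (0, 1],
    frequency outside (0, 1), invalid or identical alleles) are dropped and
    counted in the log rather than raising.
    """
    raw = pd.read_csv(path, sep="\t", dtype={"SNP": str})
    rename: dict[str, str] = {}
    for canon, internal in CANONICAL_COLUMNS.items():
        source = (column_map or {}).get(canon, canon)
        if source not in raw.columns:
            raise FormatError(f"{path}: missing mandatory column {source!r}")
        rename[source] = internal
    df = raw.rename(columns=rename)[_INTERNAL_FIELDS].copy()
    df["snp_id"] = df["snp_id"].astype(str)
    df["chrom"] = _normalize_chrom(df["chrom"])
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce").astype("Int64")
    for col in ("beta", "se", "pvalue", "eaf"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["n"] = pd.to_numeric(df["n"], errors="coerce")
    if or_scale:
        df["beta"] = np.log(df["beta"])

    df = df.dropna(subset=["pos"])
    df["pos"] = df["pos"].astype(int)
    valid, counts = _validate_records(df)
    if counts:
        logger.warning("%s: dropped rows by reason: %s", path, counts)
    if valid.empty:
        raise EmptyInputError(f"{path}: no valid summary-statistic rows")
    valid = valid.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    if cohort_n is None:
        cohort_n = int(np.median(valid["n"]))
    valid["n"] = valid["n"].fillna(cohort_n).astype(int)
    return SummaryDataset(valid, trait_label=trait_label, cohort_n=cohort_n, build_tag=build_tag)


def write_summary_stats(ds: SummaryDataset, path, metadata: dict | None = None) -> None:
    """Write a dataset in the canonical tab-delimited layout (+ JSON sidecar)."""
    out = ds.df.rename(columns={v: k for k, v in CANONICAL_COLUMNS.items()})
    out[list(CANONICAL_COLUMNS)].to_csv(path, sep="\t", index=False)
    side = {
        "trait_label": ds.trait_label,
        "cohort_n": ds.cohort_n,
        "build_tag": ds.build_tag,
        "n_snps": ds.n_snps,
    }
    side.update(metadata or {})
    with open(f"{path}.json", "w") as fh:
        json.dump(side, fh, indent=2, sort_keys=True)


def write_table(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write any tabular output as TSV with a JSON run-metadata sidecar."""
    df.to_csv(path, sep="\t", index=False)
    if metadata is not None:
        with open(f"{path}.json", "w") as fh:
            json.dump(metadata, fh, indent=2, sort_keys=True, default=float)


# ---------------------------------------------------------------------------
# filtering / masking


def filter_maf(ds: SummaryDataset, min_maf: float = 0.01) -> SummaryDataset:
    """Retain SNPs with minor-allele frequency strictly above ``min_maf``.

    The frequency column stores the effect allele; the MAF is
    ``min(eaf, 1 - eaf)``, so near-fixed alleles on either side are removed
    symmetrically.
    """
    if not 0 <= min_maf < 0.5:
        raise ValueError("min_maf must be in [0, 0.5)")
    maf = np.minimum(ds.df["eaf"], 1.0 - ds.df["eaf"])
    kept = ds.df.loc[maf > min_maf].reset_index(drop=True)
    logger.info("filter_maf(%.4g): %d -> %d SNPs", min_maf, ds.n_snps, len(kept))
    return replace(ds, df=kept)


def exclude_regions(ds: SummaryDataset, masks: Iterable[RegionMask]) -> SummaryDataset:
    """Remove SNPs falling inside any mask (closed 1-based intervals)."""
    drop = pd.Series(False, index=ds.df.index)
    for m in masks:
        hit = (
            (ds.df["chrom"] == _normalize_chrom(pd.Series([m.chrom]))[0])
            & (ds.df["pos"] >= m.start_bp)
            & (ds.df["pos"] <= m.end_bp)
        )
        logger.info("mask %s removes %d SNPs", m.name, int(hit.sum()))
        drop |= hit
    return replace(ds, df=ds.df.loc[~drop].reset_index(drop=True))


# ---------------------------------------------------------------------------
# allele matching


def _match_orientation(
    ea_ref: pd.Series,
    oa_ref: pd.Series,
    ea_other: pd.Series,
    oa_other: pd.Series,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Classify allele pairs of ``other`` relative to ``ref``.

    Returns boolean arrays ``(matched, flip, palindromic)``: ``matched``
    rows are resolvable (possibly via strand complement), ``flip`` marks
    rows whose effect sign must be inverted, and ``palindromic`` marks
    strand-ambiguous A/T and C/G SNPs (judged on the reference alleles).
    """
    comp_ea = ea_other.map(COMPLEMENT)
    comp_oa = oa_other.map(COMPLEMENT)
    same = (ea_other == ea_ref) & (oa_other == oa_ref)
    swap = (ea_other == oa_ref) & (oa_other == ea_ref)
    strand = (comp_ea == ea_ref) & (comp_oa == oa_ref)
    strand_swap = (comp_ea == oa_ref) & (comp_oa == ea_ref)
    palindromic = ea_ref == oa_ref.map(COMPLEMENT)
    matched = (same | swap | strand | strand_swap).to_numpy()
    flip = ((swap | strand_swap) & ~(same | strand)).to_numpy()
    return matched, flip, palindromic.to_numpy()


def harmonize(
    discovery: SummaryDataset,
    target: SummaryDataset,
    rescue_palindromic: bool = False,
    eaf_margin: float = 0.08,
) -> AlignedScoreTable:
    """Join discovery and target statistics per SNP and orient to the risk allele.

    The join is an inner join on ``snp_id``.  Target rows whose alleles are
    swapped (or on the opposite strand) relative to discovery have their
    effect sign flipped; strand-ambiguous palindromic SNPs (A/T, C/G) are
    dropped unless ``rescue_palindromic`` resolves them by frequency
    (both cohorts' ``|eaf - 0.5| > eaf_margin``).  Finally every row is
    oriented so the discovery weight ``w`` is non-negative: where the
    discovery beta is negative, the signs of both effects are flipped and
    the allele frequency is complemented.
    """
    if discovery.build_tag != target.build_tag:
        raise BuildMismatchError(
            f"build mismatch: {discovery.build_tag} vs {target.build_tag}"
        )
    m = discovery.df.merge(
        target.df, on="snp_id", suffixes=("_d", "_t"), how="inner"
    )
    if m.empty:
        raise EmptyOverlapError("no shared SNPs between discovery and target")

    matched, flip, palindromic = _match_orientation(
        m["effect_allele_d"], m["other_allele_d"],
        m["effect_allele_t"], m["other_allele_t"],
    )
    keep = matched.copy()
    if rescue_palindromic:
        resolvable = (
            palindromic
            & (np.abs(m["eaf_d"] - 0.5) > eaf_margin).to_numpy()
            & (np.abs(m["eaf_t"] - 0.5) > eaf_margin).to_numpy()
        )
        # frequency concordance decides orientation for rescued rows
        freq_flip = (
            ((m["eaf_d"] - 0.5) * (m["eaf_t"] - 0.5)) < 0
        ).to_numpy()
        flip = np.where(resolvable, freq_flip, flip)
        keep &= ~palindromic | resolvable
    else:
        keep &= ~palindromic
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("harmonize: dropped %d unresolvable/palindromic SNPs", n_drop)
    m = m.loc[keep].reset_index(drop=True)
    flip = flip[keep]
    if m.empty:
        raise EmptyOverlapError("no resolvable shared SNPs after allele matching")

    b = m["beta_t"].to_numpy() * np.where(flip, -1.0, 1.0)
    w = m["beta_d"].to_numpy().copy()
    eaf = m["eaf_d"].to_numpy().copy()
    neg = w < 0
    w = np.abs(w)
    b = np.where(neg, -b, b)
    eaf = np.where(neg, 1.0 - eaf, eaf)

    out = pd.DataFrame(
        {
            "snp_id": m["snp_id"],
            "chrom": m["chrom_d"],
            "pos": m["pos_d"],
            "w": w,
            "b": b,
            "s": m["se_t"].to_numpy(),
            "p_disc": m["pvalue_d"].to_numpy(),
            "p_targ": m["pvalue_t"].to_numpy(),
            "eaf": eaf,
        }
    ).sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return AlignedScoreTable(
        out,
        target_n=target.cohort_n,
        discovery_label=discovery.trait_label,
        target_label=target.trait_label,
    )


def _align_to_anchor(anchor: pd.DataFrame, other: pd.DataFrame) -> pd.DataFrame:
    """Inner-join ``other`` onto ``anchor`` SNPs with allele-resolved signs.

    Returns the merged frame with ``beta_t``/``eaf_t`` re-expressed on the
    anchor's effect allele; unresolvable rows are dropped with a warning.
    """
    m = anchor.merge(other, on="snp_id", suffixes=("_a", "_t"), how="inner")
    matched, flip, palindromic = _match_orientation(
        m["effect_allele_a"], m["other_allele_a"],
        m["effect_allele_t"], m["other_allele_t"],
    )
    keep = matched & ~palindromic | (matched & palindromic & ~flip)
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("allele alignment dropped %d unresolvable records", dropped)
    m = m.loc[keep].reset_index(drop=True)
    flip = flip[keep]
    m["beta_t"] = m["beta_t"] * np.where(flip, -1.0, 1.0)
    m["eaf_t"] = np.where(flip, 1.0 - m["eaf_t"], m["eaf_t"])
    return m


def average_bilateral(
    left: SummaryDataset,
    right: SummaryDataset,
    rho: float | None = None,
    trait_label: str | None = None,
) -> SummaryDataset:
    """Average left/right-hemisphere GWAS of the same subjects per SNP.

    Because both GWAS are computed on the same individuals the sampling
    errors of the two betas are correlated; the averaged SE is
    ``sqrt(sL² + sR² + 2·rho·sL·sR) / 2``.  When ``rho`` is None it is
    estimated as the correlation of left/right Z-scores among null-ish SNPs
    (both p > 0.1), which approximates the phenotypic correlation of the
    hemispheres.  P-values are recomputed from the averaged Z.
    """
    if left.build_tag != right.build_tag:
        raise BuildMismatchError("bilateral averaging across genome builds")
    m = _align_to_anchor(left.df, right.df)
    if m.empty:
        raise EmptyOverlapError("no shared SNPs between hemispheres")
    bl = m["beta_a"].to_numpy()
    br = m["beta_t"].to_numpy()
    sl = m["se_a"].to_numpy()
    sr = m["se_t"].to_numpy()
    if rho is None:
        nullish = (m["pvalue_a"] > 0.1) & (m["pvalue_t"] > 0.1)
        if nullish.sum() >= 50:
            rho = float(np.clip(np.corrcoef(bl[nullish] / sl[nullish],
                                            br[nullish] / sr[nullish])[0, 1], 0.0, 1.0))
        else:
            rho = 1.0
            logger.warning("too few null SNPs to estimate rho; using 1.0")
        logger.info("bilateral rho estimated at %.3f", rho)
    if not 0 <= rho <= 1:
        raise ValueError("rho must be in [0, 1]")

    beta = (bl + br) / 2.0
    se = np.sqrt(sl**2 + sr**2 + 2.0 * rho * sl * sr) / 2.0
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame(
        {
            "snp_id": m["snp_id"],
            "chrom": m["chrom_a"],
            "pos": m["pos_a"],
            "effect_allele": m["effect_allele_a"],
            "other_allele": m["other_allele_a"],
            "beta": beta,
            "se": se,
            "pvalue": np.clip(p, np.finfo(float).tiny, 1.0),
            "eaf": (m["eaf_a"].to_numpy() + m["eaf_t"].to_numpy()) / 2.0,
            "n": m["n_a"],
        }
    ).sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    label = trait_label or f"{left.trait_label}_bilateral"
    return SummaryDataset(out, trait_label=label, cohort_n=left.cohort_n,
                          build_tag=left.build_tag)


# ---------------------------------------------------------------------------
# meta-analysis


def _standardized_effects(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Rescale (beta, se) to standardized-trait units from Z, EAF and N.

    b* = z / sqrt(2 f (1-f) (n + z²)), s* = 1 / sqrt(2 f (1-f) (n + z²)):
    the per-allele effect of a standardized phenotype implied by the
    observed Z-score, frequency and sample size.  Removes arbitrary trait
    units (e.g. mm³ vs standardized volumes) before SNP-level pooling.
    """
    z = df["beta"].to_numpy() / df["se"].to_numpy()
    f = df["eaf"].to_numpy()
    n = df["n"].to_numpy().astype(float)
    denom = np.sqrt(2.0 * f * (1.0 - f) * (n + z**2))
    return z / denom, 1.0 / denom


def meta_snp(
    datasets: Sequence[SummaryDataset],
    standardize: bool = False,
    trait_label: str = "meta",
) -> SummaryDataset:
    """Per-SNP fixed-effects (inverse-variance) combination across cohorts.

    SNPs carried by a single cohort are passed through unchanged and
    flagged in the ``n_studies`` column.  With ``standardize`` each
    cohort's effects are first rescaled to standardized-trait units so
    that cohorts reported in different phenotype units pool meaningfully.
    """
    if len(datasets) < 2:
        raise ValueError("meta_snp needs at least two datasets")
    tags = {d.build_tag for d in datasets}
    if len(tags) > 1:
        raise BuildMismatchError(f"mixed genome builds in meta: {tags}")

    anchor = datasets[0].df
    frames = []
    for k, ds in enumerate(datasets):
        if k == 0:
            df = ds.df.copy()
        else:
            m = _align_to_anchor(anchor, ds.df)
            df = pd.DataFrame(
                {
                    "snp_id": m["snp_id"],
                    "chrom": m["chrom_a"],
                    "pos": m["pos_a"],
                    "effect_allele": m["effect_allele_a"],
                    "other_allele": m["other_allele_a"],
                    "beta": m["beta_t"],
                    "se": m["se_t"],
                    "pvalue": m["pvalue_t"],
                    "eaf": m["eaf_t"],
                    "n": m["n_t"],
                }
            )
        if standardize:
            b, s = _standardized_effects(df)
            df = df.assign(beta=b, se=s)
        frames.append(df.assign(_study=k))
    long = pd.concat(frames, ignore_index=True)

    w = 1.0 / long["se"] ** 2
    long = long.assign(_w=w, _wb=w * long["beta"], _wf=w * long["eaf"])
    g = long.groupby("snp_id", sort=False)
    agg = g.agg(
        chrom=("chrom", "first"),
        pos=("pos", "first"),
        effect_allele=("effect_allele", "first"),
        other_allele=("other_allele", "first"),
        sw=("_w", "sum"),
        swb=("_wb", "sum"),
        swf=("_wf", "sum"),
        n=("n", "sum"),
        n_studies=("_study", "nunique"),
    )
    beta = agg["swb"] / agg["sw"]
    se = 1.0 / np.sqrt(agg["sw"])
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame(
        {
            "snp_id": agg.index,
            "chrom": agg["chrom"].to_numpy(),
            "pos": agg["pos"].to_numpy(),
            "effect_allele": agg["effect_allele"].to_numpy(),
            "other_allele": agg["other_allele"].to_numpy(),
            "beta": beta.to_numpy(),
            "se": se.to_numpy(),
            "pvalue": np.clip(p, np.finfo(float).tiny, 1.0),
            "eaf": (agg["swf"] / agg["sw"]).to_numpy(),
            "n": agg["n"].to_numpy().astype(int),
            "n_studies": agg["n_studies"].to_numpy(),
        }
    ).sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    singles = int((out["n_studies"] == 1).sum())
    if singles:
        logger.info("meta_snp: %d SNPs carried by a single cohort (passed through)", singles)
    total_n = int(sum(d.cohort_n for d in datasets))
    return SummaryDataset(out, trait_label=trait_label, cohort_n=total_n,
                          build_tag=datasets[0].build_tag)


def meta_estimates(
    results: Sequence[tuple[float, float]],
    method: str = "fixed",
) -> MetaResult:
    """Meta-analyse study-level (estimate, SE) pairs.

    ``fixed`` uses inverse-variance weights; ``random_dl`` first estimates
    the between-study variance with the DerSimonian–Laird moment estimator
    and weights by 1/(se² + τ²).  With a single study the input is returned
    unchanged.
    """
    if method not in {"fixed", "random_dl"}:
        raise ValueError(f"unknown meta-analysis method {method!r}")
    est = np.asarray([r[0] for r in results], dtype=float)
    se = np.asarray([r[1] for r in results], dtype=float)
    if len(est) == 0:
        raise ValueError("meta_estimates needs at least one study")
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")

    k = len(est)
    tau2 = 0.0
    if k == 1:
        combined, comb_se = float(est[0]), float(se[0])
    else:
        w = 1.0 / se**2
        fixed_est = float(np.sum(w * est) / np.sum(w))
        if method == "random_dl":
            q = float(np.sum(w * (est - fixed_est) ** 2))
            c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
            tau2 = max(0.0, (q - (k - 1)) / c)
            w = 1.0 / (se**2 + tau2)
        combined = float(np.sum(w * est) / np.sum(w))
        comb_se = float(1.0 / np.sqrt(np.sum(w)))
    z = combined / comb_se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MetaResult(combined, comb_se, z, p, method=method, k_studies=k, tau2=tau2)
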