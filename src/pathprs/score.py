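"""Summary-statistic polygenic score association.

When the target phenotype is itself only available as GWAS summary
statistics, the association between a weighted risk score and the trait
can be computed without individual-level data: it is the slope of a
weighted least-squares regression of the target effects ``b_i`` on the
score weights ``w_i`` through the origin, with weights ``1/s_i²``:

    ahat = Σ w_i b_i / s_i²  /  Σ w_i² / s_i²,      se(ahat) = (Σ w_i² / s_i²)^(-1/2)

(the estimator popularized by the gtx package and applied by PRSice when
scoring one GWAS against another).  Validity rests on the scored SNPs
being approximately independent, which is why scoring follows LD clumping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateWeightsError, ThresholdEmptyError
from .sumstats import AlignedScoreTable

logger = logging.getLogger(__name__)

#: discovery P-value thresholds swept by default
DEFAULT_THRESHOLDS = (0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass(frozen=True)
class PrsAssociation:
    """One (threshold, SNP set) score–trait association."""

    threshold: float
    n_snps: int
    ahat: float
    se: float
    z: float
    pvalue: float
    r2: float
    set_label: str = "all"
    status: str = "ok"

    @classmethod
    def empty(cls, threshold: float, set_label: str) -> "PrsAssociation":
        """Placeholder row for a threshold with no qualifying SNPs."""
        return cls(threshold, 0, np.nan, np.nan, np.nan, np.nan, np.nan,
                   set_label, status="empty")


def _select(aligned: AlignedScoreTable, snp_ids, threshold: float) -> pd.DataFrame:
    df = aligned.df
    mask = df["p_disc"] <= threshold
    if snp_ids is not None:
        keep = set(snp_ids)
        mask &= df["snp_id"].isin(keep)
    return df.loc[mask]


def prs_association(
    aligned: AlignedScoreTable,
    snp_ids,
    threshold: float,
    target_n: int | None = None,
    set_label: str = "all",
) -> PrsAssociation:
    """Score–trait association over SNPs in ``snp_ids`` with p_disc <= threshold.

    ``snp_ids`` is normally the clumped index-SNP list (possibly restricted
    to a pathway set); pass None to use every aligned SNP.  ``target_n``
    (defaulting to the aligned table's target GWAS size) enters only the
    pseudo-R², defined through the regression identity
    ``r2 = z² / (n - 2 + z²)``.
    """
    sub = _select(aligned, snp_ids, threshold)
    if sub.empty:
        raise ThresholdEmptyError(
            f"no SNPs with p_disc <= {threshold} in set {set_label!r}"
        )
    if target_n is None:
        target_n = aligned.target_n
    w = sub["w"].to_numpy()
    b = sub["b"].to_numpy()
    s = sub["s"].to_numpy()
    denom = float(np.sum(w**2 / s**2))
    if denom == 0.0:
        raise DegenerateWeightsError("all score weights are zero")
    ahat = float(np.sum(w * b / s**2)) / denom
    se = denom**-0.5
    z = ahat / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    r2 = z**2 / (target_n - 2 + z**2)
    return PrsAssociation(threshold, len(sub), ahat, se, z, p, r2, set_label)


def threshold_sweep(
    aligned: AlignedScoreTable,
    snp_ids,
    thresholds=DEFAULT_THRESHOLDS,
    target_n: int | None = None,
    set_label: str = "all",
) -> list[PrsAssociation]:
    """One association per ascending discovery P-threshold.

    Thresholds with no qualifying SNP yield a flagged placeholder row
    rather than an error, so sweeps over sparse sets stay aligned.
    """
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    out = []
    for t in thresholds:
        if not 0 < t <= 1:
            raise ValueError(f"threshold {t} outside (0, 1]")
        try:
            out.append(prs_association(aligned, snp_ids, t, target_n, set_label))
        except ThresholdEmptyError:
            logger.info("threshold %g empty for set %s", t, set_label)
            out.append(PrsAssociation.empty(t, set_label))
    return out


def sweep_frame(sweeps: list[PrsAssociation], cohort: str = "") -> pd.DataFrame:
    """Tabulate sweep results (columns mirror the per-threshold report)."""
    rows = [
        {
            "COHORT": cohort,
            "PT": a.threshold,
            "N_SNPS": a.n_snps,
            "ESTIMATE": a.ahat,
            "SE": a.se,
            "Z": a.z,
            "P": a.pvalue,
            "R2": a.r2,
            "SET_LABEL": a.set_label,
            "STATUS": a.status,
        }
        for a in sweeps
    ]
    return pd.DataFrame(rows)


def snp_diagnostics(
    aligned: AlignedScoreTable,
    snp_ids,
    threshold: float,
    target_n: int | None = None,
    nearest_gene: dict | None = None,
    set_label: str = "all",
) -> tuple[pd.DataFrame, dict]:
    """Per-SNP scatter data plus the fitted score–trait line.

    Returns (table, line): the table holds one row per scored SNP with its
    weight ``w`` (x), target effect ``b`` (y) and SE ``s``; ``line`` holds
    the common slope (= the association estimate) with its 95% CI, for
    reconstructing the weight-versus-effect diagnostic plot.
    """
    assoc = prs_association(aligned, snp_ids, threshold, target_n, set_label)
    sub = _select(aligned, snp_ids, threshold).copy()
    sub = sub[["snp_id", "chrom", "pos", "w", "b", "s", "p_disc", "p_targ"]]
    if nearest_gene:
        sub["nearest_gene"] = sub["snp_id"].map(nearest_gene)
    line = {
        "slope": assoc.ahat,
        "ci_low": assoc.ahat - 1.959963984540054 * assoc.se,
        "ci_high": assoc.ahat + 1.959963984540054 * assoc.se,
        "threshold": threshold,
        "n_snps": assoc.n_snps,
        "set_label": set_label,
    }
    return sub.reset_index(drop=True), line
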