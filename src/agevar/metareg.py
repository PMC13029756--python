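"""Fixed-effects meta-regression of stratum-level SNP effects on mean age.

For each SNP the per-stratum effect estimates are regressed on the
stratum's sample mean age by weighted least squares with inverse-variance
weights (weights 1/se^2, fixed-effect).  The slope delta is the estimated
change in the per-allele effect per year of age; its p-value uses a normal
(z) reference, the usual fixed-effects meta-regression convention.  An
intercept is included by default (a no-intercept fit forces the regression
line through age 0, far outside any adult cohort's range); pass
``intercept=False`` to reproduce the origin-constrained display form.

Also here: the inclusion-set classification (discovery SNPs with nominal
interaction evidence; additional genome-wide interaction signals after
clumping), the stratum-beta sign-change diagnostic, and the
individual-level G + A + GxA sensitivity scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable
from .gwas import clump

__all__ = [
    "InteractionRecord",
    "InclusionSets",
    "meta_regress_snp",
    "metareg_scan",
    "classify_inclusion",
    "sign_change_fraction",
    "interaction_scan_individual",
]


@dataclass
class InteractionRecord:
    variant_id: str
    intercept: float
    delta: float
    se_delta: float
    z: float
    p_int: float
    n_strata: int
    qe: float
    flag: str = ""


@dataclass
class InclusionSets:
    """Variant sets selected at the study's interaction thresholds.

    inclusion1: discovery SNPs with nominal (p < p1) interaction evidence.
    inclusion2: independent SNPs genome-wide with p_int < p2 after clumping.
    bonferroni: discovery SNPs surviving 0.05 / n_discovery.
    genomewide_interaction: inclusion2 SNPs with p_int < 5e-8.
    """

    discovery: list[str] = field(default_factory=list)
    inclusion1: list[str] = field(default_factory=list)
    inclusion2: list[str] = field(default_factory=list)
    bonferroni: list[str] = field(default_factory=list)
    genomewide_interaction: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "discovery": self.discovery,
            "inclusion1": self.inclusion1,
            "inclusion2": self.inclusion2,
            "bonferroni": self.bonferroni,
            "genomewide_interaction": self.genomewide_interaction,
        }


def _wls_line(y, a, w, intercept: bool):
    """Closed-form weighted fit of y on (1, a); returns coef/var/QE."""
    sw = w.sum()
    swa = (w * a).sum()
    swaa = (w * a * a).sum()
    swy = (w * y).sum()
    sway = (w * a * y).sum()
    if intercept:
        det = sw * swaa - swa**2
        if det <= 0:
            raise ValueError("degenerate moderator values (no age spread)")
        slope = (sw * sway - swa * swy) / det
        inter = (swaa * swy - swa * sway) / det
        var_slope = sw / det
        var_inter = swaa / det
    else:
        slope = sway / swaa
        inter = 0.0
        var_slope = 1.0 / swaa
        var_inter = np.nan
    resid = y - inter - slope * a
    qe = float((w * resid**2).sum())
    return inter, slope, var_inter, var_slope, qe


def meta_regress_snp(
    betas,
    ses,
    mean_ages,
    variant_id: str = "",
    intercept: bool = True,
) -> InteractionRecord:
    """Fixed-effects meta-regression of one SNP's stratum betas on mean age.

    SEs come straight from the weighted normal equations (no multiplicative
    rescaling), so a perfectly linear set of points has the same SE as a
    noisy one — the residual heterogeneity is reported separately as QE,
    the weighted residual sum of squares.
    """
    y = np.asarray(betas, float)
    se = np.asarray(ses, float)
    a = np.asarray(mean_ages, float)
    if not (len(y) == len(se) == len(a)):
        raise ValueError("betas, ses and mean_ages must have equal length")
    if len(y) < 3:
        raise ValueError("meta-regression needs at least 3 strata")
    if np.any(se <= 0):
        raise ValueError("all stratum SEs must be > 0")
    w = 1.0 / se**2
    inter, slope, _, var_slope, qe = _wls_line(y, a, w, intercept)
    se_slope = float(np.sqrt(var_slope))
    z = slope / se_slope if se_slope > 0 else np.inf * np.sign(slope)
    p = float(2 * stats.norm.sf(abs(z)))
    return InteractionRecord(
        variant_id=variant_id,
        intercept=float(inter),
        delta=float(slope),
        se_delta=se_slope,
        z=float(z),
        p_int=max(p, np.nextafter(0, 1)),
        n_strata=len(y),
        qe=qe,
    )


def metareg_scan(
    stratified: pd.DataFrame,
    intercept: bool = True,
    expected_strata: int | None = None,
) -> pd.DataFrame:
    """Meta-regress every SNP in a stratified association table.

    ``stratified`` needs columns variant_id, beta, se, mean_age (one row
    per SNP per stratum).  SNPs with missing or degenerate strata are
    fitted on what is available and flagged; SNPs with < 3 usable strata
    yield a flagged null record.
    """
    if expected_strata is None:
        expected_strata = stratified["stratum"].nunique()
    records = []
    for vid, grp in stratified.groupby("variant_id", sort=False):
        usable = grp[np.isfinite(grp["beta"]) & (grp["se"] > 0)]
        if len(usable) < 3:
            records.append(
                InteractionRecord(vid, np.nan, np.nan, np.nan, np.nan, np.nan,
                                  len(usable), np.nan, flag="too_few_strata")
            )
            continue
        rec = meta_regress_snp(
            usable["beta"], usable["se"], usable["mean_age"], vid, intercept
        )
        if len(usable) < expected_strata:
            rec.flag = "incomplete_strata"
        records.append(rec)
    return pd.DataFrame([r.__dict__ for r in records])


def classify_inclusion(
    discovery_ids,
    interactions: pd.DataFrame,
    r2_matrix: np.ndarray,
    p1: float = 0.05,
    p2: float = 5e-5,
    r2_thresh: float = 0.01,
    gw: float = 5e-8,
    n_discovery: int | None = None,
) -> InclusionSets:
    """Apply the two inclusion criteria to a table of interaction records.

    All thresholds are strict inequalities.  inclusion2 is clumped on the
    interaction p-value across *all* SNPs; the Bonferroni set divides 0.05
    by the number of discovery SNPs.
    """
    discovery_ids = [str(i) for i in discovery_ids]
    if len(discovery_ids) == 0:
        raise ValueError("discovery set is empty")
    if n_discovery is None:
        n_discovery = len(discovery_ids)
    disc = set(discovery_ids)
    tab = interactions.set_index("variant_id")

    def _pint(vid):
        return float(tab.loc[vid, "p_int"])

    inclusion1 = [v for v in discovery_ids if np.isfinite(_pint(v)) and _pint(v) < p1]
    bonf_thresh = 0.05 / n_discovery
    bonferroni = [v for v in inclusion1 if _pint(v) < bonf_thresh]
    inclusion2 = clump(
        interactions.rename(columns={"p_int": "pval"}),
        r2_matrix,
        p_thresh=p2,
        r2_thresh=r2_thresh,
    )
    gw_set = [v for v in inclusion2 if _pint(v) < gw]
    return InclusionSets(
        discovery=discovery_ids,
        inclusion1=inclusion1,
        inclusion2=inclusion2,
        bonferroni=bonferroni,
        genomewide_interaction=gw_set,
    )


def sign_change_fraction(stratified: pd.DataFrame, snp_ids=None) -> float:
    """Fraction of SNPs whose stratum betas change sign across strata.

    A SNP counts if it has at least one strictly positive and one strictly
    negative stratum beta; zero betas are ignored.
    """
    if snp_ids is not None:
        snp_ids = set(str(i) for i in snp_ids)
        stratified = stratified[stratified["variant_id"].astype(str).isin(snp_ids)]
    hits = 0
    total = 0
    for _, grp in stratified.groupby("variant_id", sort=False):
        b = grp["beta"].to_numpy(float)
        b = b[np.isfinite(b)]
        if len(b) == 0:
            continue
        total += 1
        if (b > 0).any() and (b < 0).any():
            hits += 1
    if total == 0:
        raise ValueError("no SNPs with usable stratum betas")
    return hits / total


def interaction_scan_individual(
    cohort: CohortTable,
    trait: str,
    covariates=("sex", "chip"),
    age_ref: float | None = None,
    maf_min: float = 1e-4,
) -> pd.DataFrame:
    """Individual-level G + A + GxA scan (sensitivity comparator).

    Per SNP, OLS of the trait on dosage, age, dosage x (age - age_ref) and
    covariates; returns the genetic main effect (at age_ref) and the
    interaction coefficient with classical SEs and t-based p-values.  SNPs
    with empirical MAF below ``maf_min`` are skipped with a flag.
    """
    d = cohort.data
    n = len(d)
    if age_ref is None:
        age_ref = cohort.config.age_ref if cohort.config else 40.0
    y = d[trait].to_numpy(float)
    age = d["age"].to_numpy(float)
    covs = [d[c].to_numpy(float) for c in covariates]
    eaf = cohort.eaf()
    maf = np.minimum(eaf, 1 - eaf)

    rows = []
    for j, vid in enumerate(cohort.snp_ids):
        if maf[j] < maf_min:
            rows.append(
                dict(variant_id=vid, beta_main=np.nan, se_main=np.nan, p_main=np.nan,
                     beta_inter=np.nan, se_inter=np.nan, p_inter=np.nan,
                     flag="maf_below_threshold")
            )
            continue
        g = cohort.dosages[:, j].astype(float)
        x_mat = np.column_stack([np.ones(n), g, age, g * (age - age_ref), *covs])
        coef, _, rank, _ = np.linalg.lstsq(x_mat, y, rcond=None)
        if rank < x_mat.shape[1]:
            rows.append(
                dict(variant_id=vid, beta_main=np.nan, se_main=np.nan, p_main=np.nan,
                     beta_inter=np.nan, se_inter=np.nan, p_inter=np.nan,
                     flag="degenerate_design")
            )
            continue
        resid = y - x_mat @ coef
        df = n - x_mat.shape[1]
        sigma2 = float(resid @ resid) / df
        cov = sigma2 * np.linalg.inv(x_mat.T @ x_mat)
        se = np.sqrt(np.diag(cov))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = coef / se
        pvals = 2 * stats.t.sf(np.abs(tvals), df)
        pvals = np.where(se == 0, 0.0, pvals)
        rows.append(
            dict(variant_id=vid,
                 beta_main=coef[1], se_main=se[1], p_main=max(pvals[1], np.nextafter(0, 1)),
                 beta_inter=coef[3], se_inter=se[3], p_inter=max(pvals[3], np.nextafter(0, 1)),
                 flag="")
        )
    return pd.DataFrame(rows)
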