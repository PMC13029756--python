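"""Trait derivation, age stratification, per-SNP association scans,
LD clumping and stratum-level power projection.

The cohort is split into two-year age strata (15 strata covering 40-69 by
default).  Because recruitment age is rarely uniform in real cohorts, the
stratification applies a maximum sample-size cap taken from a reference
stratum; larger strata are downsampled at random.  Associations are then
estimated by ordinary least squares of the trait on each SNP's dosage plus
covariates, per stratum and on the full age range ("discovery").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable

__all__ = [
    "derive_pp",
    "adjust_medication",
    "assign_strata",
    "stratum_table",
    "cap_strata",
    "assoc_scan",
    "dosage_r2",
    "clump",
    "power_projection",
]

EXCLUDED = -1  # stratum code for ages outside the covered range


def derive_pp(sbp, dbp):
    """Pulse pressure: systolic minus diastolic (mmHg)."""
    return np.asarray(sbp) - np.asarray(dbp) if np.ndim(sbp) else sbp - dbp


def adjust_medication(sbp, dbp, med_flag):
    """Counter the effect of anti-hypertensive medication on measured BP.

    Individuals on medication get +15 mmHg added to SBP and +10 mmHg to
    DBP; others are unchanged.  Applying the adjustment twice adds twice —
    it is a one-shot correction, not idempotent.
    """
    med = np.asarray(med_flag)
    return np.asarray(sbp) + 15 * med, np.asarray(dbp) + 10 * med


def assign_strata(ages, age_min: int = 40, n_strata: int = 15, width: int = 2):
    """Map ages to 1-based stratum indices; out-of-range ages get EXCLUDED.

    Stratum k covers the ``width`` consecutive integer years starting at
    age_min + (k-1)*width; the n_strata bins are mutually exclusive and
    jointly cover [age_min, age_min + n_strata*width - 1].
    """
    ages = np.asarray(ages)
    idx = np.floor_divide(ages - age_min, width) + 1
    idx = np.where((ages < age_min) | (idx > n_strata), EXCLUDED, idx)
    return idx.astype(np.int64)


@dataclass
class StratumSpec:
    index: int
    age_lo: int
    age_hi: int
    n: int
    mean_age: float


def stratum_table(
    cohort: CohortTable, age_min: int = 40, n_strata: int = 15, width: int = 2
) -> pd.DataFrame:
    """Per-stratum sizes and sample mean ages for a (possibly capped) cohort."""
    ages = cohort.data["age"].to_numpy()
    idx = assign_strata(ages, age_min, n_strata, width)
    rows = []
    for k in range(1, n_strata + 1):
        mask = idx == k
        rows.append(
            StratumSpec(
                index=k,
                age_lo=age_min + (k - 1) * width,
                age_hi=age_min + k * width - 1,
                n=int(mask.sum()),
                mean_age=float(ages[mask].mean()) if mask.any() else np.nan,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def cap_strata(
    cohort: CohortTable,
    reference_stratum: int = 7,
    seed: int = 0,
    age_min: int = 40,
    n_strata: int = 15,
    width: int = 2,
) -> CohortTable:
    """Cap every stratum at the reference stratum's size.

    Strata larger than the cap are downsampled uniformly at random without
    replacement; smaller strata are untouched.  Out-of-range individuals
    are dropped.  The returned cohort gains a ``stratum`` column.
    """
    rng = np.random.default_rng(seed)
    idx = assign_strata(cohort.data["age"].to_numpy(), age_min, n_strata, width)
    cap = int((idx == reference_stratum).sum())
    if cap == 0:
        raise ValueError(f"reference stratum {reference_stratum} is empty")
    keep = np.zeros(cohort.n, dtype=bool)
    for k in range(1, n_strata + 1):
        members = np.flatnonzero(idx == k)
        if len(members) > cap:
            members = rng.choice(members, size=cap, replace=False)
        keep[members] = True
    out = cohort.subset(keep)
    out.data["stratum"] = assign_strata(
        out.data["age"].to_numpy(), age_min, n_strata, width
    )
    return out


def _covariate_matrix(data: pd.DataFrame, covariates) -> np.ndarray:
    cols = [np.ones(len(data))]
    for c in covariates:
        cols.append(data[c].to_numpy(float))
    return np.column_stack(cols)


def assoc_scan(
    cohort: CohortTable,
    trait: str,
    covariates=("age", "sex", "chip"),
    stratum_label: str | int = "discovery",
    mean_age: float | None = None,
) -> pd.DataFrame:
    """Per-SNP OLS association scan of ``trait`` on dosage + covariates.

    Uses the Frisch-Waugh-Lovell decomposition: trait and dosages are
    residualised on the covariate matrix (with intercept) and the per-SNP
    slope is the simple regression on residuals, which equals the full-OLS
    coefficient; classical SEs use df = n - n_covariates - 2.  Monomorphic
    SNPs (or SNPs made degenerate by residualisation) come back flagged
    with null estimates instead of raising.
    """
    d = cohort.data
    n = len(d)
    c_mat = _covariate_matrix(d, covariates)
    k = c_mat.shape[1]
    if n < k + 2:
        raise ValueError("too few individuals for the design")
    y = d[trait].to_numpy(float)
    g = cohort.dosages.astype(float)

    # residualise on covariates (single QR shared by all SNPs)
    q, _ = np.linalg.qr(c_mat)
    y_r = y - q @ (q.T @ y)
    g_r = g - q @ (q.T @ g)

    gg = np.einsum("ij,ij->j", g_r, g_r)
    gy = g_r.T @ y_r
    yy = float(y_r @ y_r)
    df = n - k - 1

    ok = gg > 1e-12
    beta = np.full(cohort.n_snps, np.nan)
    se = np.full(cohort.n_snps, np.nan)
    pval = np.full(cohort.n_snps, np.nan)
    beta[ok] = gy[ok] / gg[ok]
    rss = np.maximum(yy - beta[ok] ** 2 * gg[ok], 0.0)
    sigma2 = rss / df
    se[ok] = np.sqrt(sigma2 / gg[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta[ok] / se[ok]
    pval[ok] = 2 * stats.t.sf(np.abs(tstat), df)
    pval[ok] = np.where(se[ok] == 0, 0.0, pval[ok])

    eaf = cohort.eaf()
    if mean_age is None:
        mean_age = float(d["age"].mean())
    return pd.DataFrame(
        {
            "variant_id": cohort.snp_ids,
            "effect_allele": cohort.effect_allele,
            "other_allele": cohort.other_allele,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pval": np.clip(pval, np.nextafter(0, 1), 1.0),
            "n": n,
            "stratum": stratum_label,
            "mean_age": mean_age,
            "flag": np.where(ok, "", "monomorphic"),
        }
    )


def scan_all_strata(
    cohort: CohortTable,
    trait: str,
    covariates=("age", "sex", "chip"),
    n_strata: int = 15,
) -> pd.DataFrame:
    """Run assoc_scan within every non-empty stratum of a capped cohort."""
    if "stratum" not in cohort.data.columns:
        raise ValueError("cohort must be stratified (run cap_strata first)")
    frames = []
    for k in range(1, n_strata + 1):
        mask = (cohort.data["stratum"] == k).to_numpy()
        if not mask.any():
            continue
        sub = cohort.subset(mask)
        frames.append(
            assoc_scan(
                sub,
                trait,
                covariates,
                stratum_label=k,
                mean_age=float(sub.data["age"].mean()),
            )
        )
    return pd.concat(frames, ignore_index=True)


def dosage_r2(dosages: np.ndarray) -> np.ndarray:
    """Pairwise squared Pearson correlation of dosage columns."""
    g = np.asarray(dosages, float)
    g = g - g.mean(axis=0)
    sd = g.std(axis=0)
    sd = np.where(sd == 0, np.nan, sd)
    corr = (g.T @ g) / len(g) / np.outer(sd, sd)
    r2 = np.nan_to_num(corr**2)
    np.fill_diagonal(r2, 1.0)
    return r2


def clump(
    assoc: pd.DataFrame,
    r2_matrix: np.ndarray,
    p_thresh: float = 5e-8,
    r2_thresh: float = 0.01,
    p_col: str = "pval",
) -> list[str]:
    """Greedy LD clumping: keep index variants ranked by significance.

    Repeatedly takes the smallest-p remaining variant below ``p_thresh``
    (ties broken by variant id), retains it, and removes everything with
    r^2 >= r2_thresh to it.  Retained variants are pairwise below the r^2
    threshold.
    """
    r2 = np.asarray(r2_matrix, float)
    m = len(assoc)
    if r2.shape != (m, m):
        raise ValueError("r2_matrix shape does not match the association table")
    if not np.allclose(r2, r2.T, atol=1e-8) or r2.min() < -1e-8 or r2.max() > 1 + 1e-8:
        raise ValueError("r2_matrix must be symmetric with entries in [0, 1]")

    ids = assoc["variant_id"].to_numpy()
    pvals = assoc[p_col].to_numpy(float)
    order = np.lexsort((ids, pvals))
    alive = np.ones(m, dtype=bool)
    retained: list[str] = []
    for i in order:
        if not alive[i] or not (pvals[i] < p_thresh):
            continue
        retained.append(str(ids[i]))
        alive &= r2[i] < r2_thresh
    return retained


def power_projection(discovery_betas, stratum_ses, alpha: float = 5e-8):
    """Expected stratum-level detection power for discovery-sized effects.

    For each SNP the expected Z in the stratum is the discovery effect
    divided by the stratum SE; power is the probability that
    N(E[Z], 1) exceeds the two-sided significance bound:
    power = Phi(-z_a + |E[Z]|) + Phi(-z_a - |E[Z]|).  The expected number
    of detectable loci is the sum of power over SNPs.
    """
    beta = np.asarray(discovery_betas, float)
    se = np.asarray(stratum_ses, float)
    if np.any(se <= 0):
        raise ValueError("stratum SEs must be > 0")
    ez = np.abs(beta / se)
    z_a = stats.norm.isf(alpha / 2)
    power = stats.norm.cdf(-z_a + ez) + stats.norm.cdf(-z_a - ez)
    return power, float(power.sum())
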