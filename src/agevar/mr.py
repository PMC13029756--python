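"""Two-sample summary-data Mendelian randomization estimators.

Implements the inverse-variance weighted (IVW) estimator, MR-Egger
regression, the weighted median, per-stratum ("age-stratified") IVW, and a
modified IVW in which each variant's age-interaction slope replaces its
exposure association.  The modified estimator targets the effect of the
*rate of change* of the genetically predicted exposure per year of age on
the outcome:

    Gamma_j = beta * delta_j + u_j

where Gamma_j is the SNP-outcome log-odds and delta_j the SNP's estimated
change in exposure effect per year.

All point estimators weight by the outcome variance only (NOME
convention); exposure SEs are carried through for reporting.  Default SEs
apply multiplicative random-effects inflation max(1, sqrt(Q/df)); pass
``fixed_se=True`` for plain fixed-effect SEs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MRResult",
    "harmonize",
    "ivw",
    "modified_ivw",
    "mr_egger",
    "weighted_median",
    "age_stratified_mr",
    "to_odds_ratio",
]

_PALINDROMIC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


@dataclass
class MRResult:
    method: str
    estimate: float
    se: float
    ci_lo: float
    ci_hi: float
    p: float
    n_snp: int
    q: float = np.nan
    overdispersion: float = 1.0
    label: str = ""

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _finish(method, est, se, n_snp, q=np.nan, phi=1.0, label="") -> MRResult:
    z = est / se if se > 0 else np.inf * np.sign(est)
    p = float(2 * stats.norm.sf(abs(z)))
    half = 1.959963984540054 * se
    return MRResult(
        method=method,
        estimate=float(est),
        se=float(se),
        ci_lo=float(est - half),
        ci_hi=float(est + half),
        p=max(p, np.nextafter(0, 1)),
        n_snp=int(n_snp),
        q=float(q),
        overdispersion=float(phi),
        label=label,
    )


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    eaf_window: tuple[float, float] = (0.42, 0.58),
    beta_x_col: str = "beta",
    se_x_col: str = "se",
) -> tuple[pd.DataFrame, list[dict]]:
    """Align exposure and outcome summary statistics on variant and allele.

    Inner-joins on variant id; when the outcome's effect/other alleles are
    swapped relative to the exposure, the outcome beta is negated (and its
    eaf flipped).  Palindromic variants whose eaf is inside the ambiguity
    window, and variants whose alleles cannot be reconciled, are dropped;
    every drop is recorded in the returned log.
    """
    exp = exposure.rename(
        columns={beta_x_col: "beta_x", se_x_col: "se_x",
                 "effect_allele": "ea_x", "other_allele": "oa_x", "eaf": "eaf_x"}
    )
    out = outcome.rename(
        columns={"beta": "beta_y", "se": "se_y",
                 "effect_allele": "ea_y", "other_allele": "oa_y", "eaf": "eaf_y"}
    )
    keep_x = ["variant_id", "ea_x", "oa_x", "beta_x", "se_x"] + (
        ["eaf_x"] if "eaf_x" in exp else []
    )
    keep_y = ["variant_id", "ea_y", "oa_y", "beta_y", "se_y"] + (
        ["eaf_y"] if "eaf_y" in out else []
    )
    merged = exp[keep_x].merge(out[keep_y], on="variant_id", how="inner")
    if merged.empty:
        raise ValueError("no variants shared between exposure and outcome")

    log: list[dict] = []
    rows = []
    for rec in merged.itertuples(index=False):
        ea_x, oa_x, ea_y, oa_y = rec.ea_x, rec.oa_x, rec.ea_y, rec.oa_y
        status = "aligned"
        beta_y = rec.beta_y
        eaf_y = getattr(rec, "eaf_y", np.nan)
        if (ea_x, oa_x) in _PALINDROMIC:
            eaf = getattr(rec, "eaf_x", np.nan)
            if np.isnan(eaf):
                eaf = eaf_y
            if np.isnan(eaf) or eaf_window[0] <= eaf <= eaf_window[1]:
                log.append(
                    {"variant_id": rec.variant_id, "action": "dropped",
                     "reason": "palindromic_ambiguous"}
                )
                continue
        if (ea_x, oa_x) == (ea_y, oa_y):
            pass
        elif (ea_x, oa_x) == (oa_y, ea_y):
            beta_y = -beta_y
            eaf_y = 1 - eaf_y if np.isfinite(eaf_y) else eaf_y
            status = "flipped"
        else:
            log.append(
                {"variant_id": rec.variant_id, "action": "dropped",
                 "reason": "allele_mismatch"}
            )
            continue
        rows.append(
            dict(variant_id=rec.variant_id, effect_allele=ea_x, other_allele=oa_x,
                 beta_x=rec.beta_x, se_x=rec.se_x, beta_y=beta_y, se_y=rec.se_y,
                 harmonization=status)
        )
    if not rows:
        raise ValueError("harmonization dropped every shared variant")
    return pd.DataFrame(rows), log


def _check_inputs(inputs: pd.DataFrame, min_snp: int = 1):
    bx = inputs["beta_x"].to_numpy(float)
    by = inputs["beta_y"].to_numpy(float)
    sy = inputs["se_y"].to_numpy(float)
    if len(bx) < min_snp:
        raise ValueError(f"need at least {min_snp} variants")
    if np.any(sy <= 0):
        raise ValueError("all outcome SEs must be > 0")
    return bx, by, sy


def ivw(inputs: pd.DataFrame, fixed_se: bool = False, label: str = "") -> MRResult:
    """Inverse-variance weighted estimate: weighted regression of the
    outcome betas on the exposure betas through the origin, weights
    1/se_y^2.  A single variant reduces to the Wald ratio with first-order
    delta-method SE.  Cochran's Q and the multiplicative overdispersion
    factor max(1, sqrt(Q/(n-1))) are reported; the factor inflates the SE
    unless ``fixed_se``.
    """
    bx, by, sy = _check_inputs(inputs, 1)
    if np.all(bx == 0):
        raise ValueError("all exposure betas are zero; estimand undefined")
    w = 1.0 / sy**2
    denom = float((w * bx**2).sum())
    est = float((w * bx * by).sum()) / denom
    se = np.sqrt(1.0 / denom)
    n = len(bx)
    if n == 1:
        return _finish("ivw", est, se, 1, label=label)
    q = float((w * (by - est * bx) ** 2).sum())
    phi = max(1.0, np.sqrt(q / (n - 1)))
    if not fixed_se:
        se *= phi
    return _finish("ivw", est, se, n, q=q, phi=phi, label=label)


def modified_ivw(
    interactions: pd.DataFrame,
    outcome: pd.DataFrame,
    fixed_se: bool = False,
    label: str = "",
) -> MRResult:
    """IVW with per-SNP age-interaction slopes as the exposure.

    ``interactions`` must carry variant_id, delta, se_delta (a metareg
    scan table); the estimator is exactly :func:`ivw` with
    beta_x <- delta, so the estimate is in log-odds per
    (exposure unit per year of age).
    """
    exp = interactions.rename(columns={"delta": "beta", "se_delta": "se"})[
        ["variant_id", "beta", "se"]
    ].copy()
    if "effect_allele" in interactions:
        exp["effect_allele"] = interactions["effect_allele"]
        exp["other_allele"] = interactions["other_allele"]
    else:
        # slopes share the coding of the outcome records they join to
        al = outcome.set_index("variant_id")[["effect_allele", "other_allele"]]
        exp = exp.join(al, on="variant_id")
    harmonized, _ = harmonize(exp, outcome)
    res = ivw(harmonized, fixed_se=fixed_se, label=label)
    res.method = "ivw_modified"
    return res


def mr_egger(
    inputs: pd.DataFrame, fixed_se: bool = False, label: str = ""
) -> tuple[MRResult, MRResult]:
    """MR-Egger: weighted regression of outcome on exposure betas with an
    intercept (directional-pleiotropy term).  Variants are first oriented
    so every exposure beta is non-negative — without that the fit is not
    invariant to allele recoding.  Returns (slope, intercept) results.
    """
    bx, by, sy = _check_inputs(inputs, 3)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2

    sw = w.sum()
    swx = (w * bx).sum()
    swxx = (w * bx * bx).sum()
    swy = (w * by).sum()
    swxy = (w * bx * by).sum()
    det = sw * swxx - swx**2
    if det <= 0:
        raise ValueError("degenerate exposure betas for Egger regression")
    slope = (sw * swxy - swx * swy) / det
    inter = (swxx * swy - swx * swxy) / det
    se_slope = np.sqrt(sw / det)
    se_inter = np.sqrt(swxx / det)
    n = len(bx)
    resid = by - inter - slope * bx
    q = float((w * resid**2).sum())
    phi = max(1.0, np.sqrt(q / (n - 2))) if n > 2 else 1.0
    if not fixed_se:
        se_slope *= phi
        se_inter *= phi
    return (
        _finish("egger_slope", slope, se_slope, n, q=q, phi=phi, label=label),
        _finish("egger_intercept", inter, se_inter, n, q=q, phi=phi, label=label),
    )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    cdf = np.cumsum(w) - 0.5 * w  # midpoint weighted empirical CDF
    if 0.5 <= cdf[0]:
        return float(r[0])
    if cdf[-1] <= 0.5:
        return float(r[-1])
    return float(np.interp(0.5, cdf, r))


def weighted_median(
    inputs: pd.DataFrame, n_boot: int = 2000, seed: int = 0, label: str = ""
) -> MRResult:
    """Weighted-median MR estimate with parametric-bootstrap SE.

    Per-SNP Wald ratios are weighted by their inverse variance
    (beta_x/se_y)^2 and the estimate is the weighted empirical CDF of the
    sorted ratios interpolated at 0.5 — consistent when at least half the
    weight comes from valid instruments.  The SE resamples (beta_x, beta_y)
    from normal distributions at their reported SEs.
    """
    bx, by, sy = _check_inputs(inputs, 3)
    if np.any(bx == 0):
        raise ValueError("weighted median is undefined for beta_x == 0")
    sx = inputs["se_x"].to_numpy(float) if "se_x" in inputs else np.zeros_like(bx)
    w = (bx / sy) ** 2
    est = _weighted_median(by / bx, w)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxs = bx + rng.standard_normal(len(bx)) * sx
        bys = by + rng.standard_normal(len(by)) * sy
        bxs[bxs == 0] = np.finfo(float).tiny
        boots[b] = _weighted_median(bys / bxs, (bxs / sy) ** 2)
    se = float(boots.std(ddof=1))
    return _finish("weighted_median", est, se, len(bx), label=label)


def age_stratified_mr(
    stratified: pd.DataFrame,
    outcome: pd.DataFrame,
    discovery_ids,
    strata=(1, 15),
    fixed_se: bool = False,
) -> dict[int, MRResult]:
    """IVW per age stratum, instrumenting with that stratum's betas.

    Typically run on the youngest and oldest strata to contrast the
    exposure-outcome estimate at the two ends of the age range.
    """
    discovery_ids = set(str(i) for i in discovery_ids)
    results: dict[int, MRResult] = {}
    for k in strata:
        sub = stratified[
            (stratified["stratum"] == k)
            & stratified["variant_id"].astype(str).isin(discovery_ids)
        ]
        harmonized, _ = harmonize(sub, outcome)
        results[k] = ivw(harmonized, fixed_se=fixed_se, label=f"stratum_{k}")
    return results


def to_odds_ratio(result: MRResult) -> tuple[float, tuple[float, float]]:
    """Exponentiate a log-odds MR estimate and its CI to the OR scale."""
    return float(np.exp(result.estimate)), (
        float(np.exp(result.ci_lo)),
        float(np.exp(result.ci_hi)),
    )
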