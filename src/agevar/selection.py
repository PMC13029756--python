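"""Selection-bias simulation study and attendance analyses.

The simulation quantifies when rank-based selection on a score
S = d1*A + d2*A*X + d3*X + d4*U + v can *induce* an apparently age-varying
genetic effect in age-group-stratified association estimates even though
the true SNP effect is constant in age.  The headline facts the study
establishes: with no age-by-trait interaction in selection (d2 = 0) the
same genetic association is estimated in every age group; with d2 != 0 and
a real genetic effect the per-group estimates diverge monotonically in
age; and with no genetic effect (beta_g = 0) selection cannot manufacture
an age-varying genetic signal.

The attendance analyses mirror the empirical repeat-clinic-visit study
design: a linear-probability model of attendance on the trait with
age-group dummies and trait-by-group interactions, and logistic
trait-by-age interaction fits overall and within age bins.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import CohortConfig, CohortTable, SelectionParams, apply_selection, generate_cohort

__all__ = [
    "SelectionSimSpec",
    "run_selection_sim",
    "attendance_curves",
    "attendance_interaction",
    "attendance_rate",
    "percent",
]


@dataclass
class SelectionSimSpec:
    """Grid specification for the selection-bias simulation.

    Each combination of (delta_age, delta_inter, delta_trait, beta_g) is a
    grid point; per point, ``n_reps`` cohorts of ``n`` individuals are
    generated, 50% removed by rank of S, and the per-age-group genetic
    effect estimated by OLS of X on (1, G, A).
    """

    delta_age: Sequence[float] = (0.0, 0.005)
    delta_inter: Sequence[float] = (0.0, 0.01)
    delta_trait: Sequence[float] = (0.0, 0.5)
    delta_u: float = 0.5
    beta_g: Sequence[float] = (0.0, 0.3)
    beta_age: float = 0.005
    beta_u: float = 0.5
    noise_sd: float = 1.0
    n: int = 50_000
    maf: float = 0.4
    missing_fraction: float = 0.5
    n_age_groups: int = 4
    n_reps: int = 200
    age_min: int = 40
    age_max: int = 69
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_age_groups < 2:
            raise ValueError("n_age_groups must be >= 2")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


def _age_group_edges(age_min: int, age_max: int, k: int) -> np.ndarray:
    """Equal-width group edges over the integer age range."""
    return np.linspace(age_min, age_max + 1, k + 1)


def _ols_gamma1(x, g, a):
    """OLS of x on (1, g, a); returns the coefficient on g."""
    design = np.column_stack([np.ones(len(x)), g, a])
    coef, _, rank, _ = np.linalg.lstsq(design, x, rcond=None)
    if rank < 3:
        return np.nan
    return coef[1]


def run_selection_sim(spec: SelectionSimSpec) -> pd.DataFrame:
    """Run the full simulation grid.

    Returns one row per (grid point, age group) with the mean estimated
    genetic effect, its bias relative to the generating beta_g, the
    Monte-Carlo SE of the mean, and — per grid point — the marginal R^2 of
    the missingness indicator on G alone and on age alone (computed on the
    full pre-selection sample and averaged over replicates).
    """
    edges = _age_group_edges(spec.age_min, spec.age_max, spec.n_age_groups)
    root = np.random.default_rng(spec.seed)
    rows = []
    grid = list(
        itertools.product(spec.delta_age, spec.delta_inter, spec.delta_trait, spec.beta_g)
    )
    for d1, d2, d3, bg in grid:
        gam = np.full((spec.n_reps, spec.n_age_groups), np.nan)
        r2_g = np.empty(spec.n_reps)
        r2_a = np.empty(spec.n_reps)
        for rep in range(spec.n_reps):
            seed_cohort = int(root.integers(2**31))
            seed_sel = int(root.integers(2**31))
            cfg = CohortConfig(
                n_individuals=spec.n,
                n_snps=1,
                maf=spec.maf,
                age_min=spec.age_min,
                age_max=spec.age_max,
                beta_age=spec.beta_age,
                beta_g=bg,
                theta=0.0,
                beta_u=spec.beta_u,
                noise_sd=spec.noise_sd,
                seed=seed_cohort,
            )
            cohort = generate_cohort(cfg)
            params = SelectionParams(
                delta_age=d1, delta_inter=d2, delta_trait=d3, delta_u=spec.delta_u,
                missing_fraction=spec.missing_fraction,
            )
            sel = apply_selection(cohort, params, seed=seed_sel)
            missing = 1 - sel.data["selected"].to_numpy()
            g_all = sel.dosages[:, 0].astype(float)
            a_all = sel.data["age"].to_numpy(float)
            r2_g[rep] = _marginal_r2(missing, g_all)
            r2_a[rep] = _marginal_r2(missing, a_all)

            obs = sel.subset(sel.data["selected"].to_numpy() == 1)
            a = obs.data["age"].to_numpy(float)
            x = obs.data["trait"].to_numpy(float)
            g = obs.dosages[:, 0].astype(float)
            group = np.clip(np.digitize(a, edges[1:-1]), 0, spec.n_age_groups - 1)
            for k in range(spec.n_age_groups):
                mask = group == k
                if mask.sum() < 10 or np.ptp(g[mask]) == 0:
                    continue  # flagged empty/degenerate group
                gam[rep, k] = _ols_gamma1(x[mask], g[mask], a[mask])
        for k in range(spec.n_age_groups):
            vals = gam[:, k][np.isfinite(gam[:, k])]
            rows.append(
                dict(
                    delta_age=d1, delta_inter=d2, delta_trait=d3, beta_g=bg,
                    age_group=k + 1,
                    age_lo=float(edges[k]), age_hi=float(edges[k + 1]),
                    n_reps_used=len(vals),
                    mean_gamma1=float(vals.mean()) if len(vals) else np.nan,
                    bias=float(vals.mean() - bg) if len(vals) else np.nan,
                    mc_se=float(vals.std(ddof=1) / np.sqrt(len(vals)))
                    if len(vals) > 1 else np.nan,
                    r2_missing_g=float(r2_g.mean()),
                    r2_missing_age=float(r2_a.mean()),
                )
            )
    return pd.DataFrame(rows)


def _marginal_r2(y, x) -> float:
    """R^2 of a simple regression of y on x."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    vx = x.var()
    vy = y.var()
    if vx == 0 or vy == 0:
        return 0.0
    c = np.cov(x, y, bias=True)[0, 1]
    return float(c * c / (vx * vy))


def attendance_curves(
    cohort: CohortTable,
    trait: str,
    n_age_groups: int = 5,
    trait_grid: np.ndarray | None = None,
) -> dict:
    """Linear-probability model of attendance with age-group interactions.

    Fits attended ~ trait + group dummies + trait x group dummies, so each
    age group has its own intercept and trait slope; returns per-group
    coefficients with SEs and fitted attendance probabilities over a trait
    grid.  Groups with fewer than 10 attendees or non-attendees are
    flagged.
    """
    d = cohort.data
    if "attended" not in d.columns:
        raise ValueError("cohort has no attendance indicator")
    age = d["age"].to_numpy(float)
    x = d[trait].to_numpy(float)
    y = d["attended"].to_numpy(float)
    cfg = cohort.config
    edges = _age_group_edges(cfg.age_min if cfg else 40, cfg.age_max if cfg else 69,
                             n_age_groups)
    group = np.clip(np.digitize(age, edges[1:-1]), 0, n_age_groups - 1)

    cols = [np.ones(len(d)), x]
    for k in range(1, n_age_groups):
        dummy = (group == k).astype(float)
        cols += [dummy, dummy * x]
    design = np.column_stack(cols)
    fit = sm.OLS(y, design).fit()
    coef, se = fit.params, fit.bse

    if trait_grid is None:
        trait_grid = np.linspace(np.percentile(x, 1), np.percentile(x, 99), 50)
    groups = []
    fitted = np.empty((n_age_groups, len(trait_grid)))
    for k in range(n_age_groups):
        inter = coef[0] + (coef[2 * k] if k > 0 else 0.0)
        slope = coef[1] + (coef[2 * k + 1] if k > 0 else 0.0)
        mask = group == k
        n_att = int(y[mask].sum())
        flagged = n_att < 10 or int((1 - y[mask]).sum()) < 10
        if k > 0:
            var_slope = se[1] ** 2 + se[2 * k + 1] ** 2 + 2 * fit.cov_params()[1, 2 * k + 1]
            slope_se = float(np.sqrt(max(var_slope, 0.0)))
        else:
            slope_se = float(se[1])
        groups.append(
            dict(age_group=k + 1, age_lo=float(edges[k]), age_hi=float(edges[k + 1]),
                 intercept=float(inter), slope=float(slope), slope_se=slope_se,
                 n=int(mask.sum()), flagged=bool(flagged))
        )
        fitted[k] = inter + slope * trait_grid
    return {
        "groups": pd.DataFrame(groups),
        "trait_grid": trait_grid,
        "fitted": fitted,
        "coefficients": np.asarray(coef),
        "design_columns": design.shape[1],
        "model": fit,
    }


def attendance_interaction(
    cohort: CohortTable,
    trait: str,
    age_bins: int = 5,
    tol: float = 1e-8,
    maxiter: int = 50,
) -> pd.DataFrame:
    """Logistic trait-by-age interaction on attendance, overall and per bin.

    Fits attended ~ trait + age + trait*age by iteratively reweighted
    least squares (deviance tolerance ``tol``); returns the interaction
    coefficient, SE and Wald p per bin plus the full-range fit.
    Non-convergent (separated) fits are flagged rather than raised.
    """
    d = cohort.data
    if "attended" not in d.columns:
        raise ValueError("cohort has no attendance indicator")
    age = d["age"].to_numpy(float)
    x = d[trait].to_numpy(float)
    y = d["attended"].to_numpy(float)
    cfg = cohort.config
    edges = _age_group_edges(cfg.age_min if cfg else 40, cfg.age_max if cfg else 69,
                             age_bins)
    group = np.clip(np.digitize(age, edges[1:-1]), 0, age_bins - 1)

    def _fit(mask, label):
        design = np.column_stack(
            [np.ones(mask.sum()), x[mask], age[mask], x[mask] * age[mask]]
        )
        try:
            res = sm.GLM(y[mask], design, family=sm.families.Binomial()).fit(
                tol=tol, maxiter=maxiter
            )
            converged = bool(res.converged)
        except Exception:
            return dict(bin=label, beta_inter=np.nan, se_inter=np.nan,
                        p_inter=np.nan, n=int(mask.sum()), flag="no_convergence")
        return dict(
            bin=label,
            beta_inter=float(res.params[3]),
            se_inter=float(res.bse[3]),
            p_inter=float(res.pvalues[3]),
            n=int(mask.sum()),
            flag="" if converged else "no_convergence",
        )

    rows = [_fit(np.ones(len(d), bool), "overall")]
    for k in range(age_bins):
        rows.append(_fit(group == k, f"bin_{k + 1}"))
    return pd.DataFrame(rows)


def percent(numerator: int, denominator: int, ndigits: int = 2) -> float:
    """Count ratio as a percentage, rounded to ``ndigits``."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator > denominator or numerator < 0:
        raise ValueError("numerator must lie in [0, denominator]")
    return round(100.0 * numerator / denominator, ndigits)


def attendance_rate(n_invited: int, n_attended: int) -> float:
    """Percentage of invitees who attended, to 2 decimal places."""
    return percent(n_attended, n_invited, ndigits=2)
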