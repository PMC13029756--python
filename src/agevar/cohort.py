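"""Synthetic individual-level cohorts with age-varying genetic effects.

This module generates the individual-level data every downstream stage
consumes: genotype dosages, a quantitative trait whose per-allele effects
change linearly with age at measurement, an unobserved confounder, a
rank-based selection mechanism (collider structure: selection may depend on
age, the trait, their product, and the confounder), a repeat-assessment
attendance indicator, and synthetic outcome-GWAS summary statistics.

The trait model is

    X_i = intercept + beta_age * A_i
          + sum_j (beta_g_j + theta_j * (A_i - age_ref)) * G_ij
          + beta_u * U_i + u_i,     u_i ~ N(0, noise_sd^2)

with A_i uniform on the integers [age_min, age_max], G_ij ~ Binomial(2, maf_j)
and U_i ~ N(0, 1).  ``theta_j`` is the generative age-interaction slope the
meta-regression stage is designed to recover.

The selection score is

    S_i = delta_age * A_i + delta_inter * A_i * X_i
          + delta_trait * X_i + delta_u * U_i + v_i,   v ~ N(0, noise_sd^2)

and a fixed fraction of individuals (ranked on S) is flagged unselected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "CohortConfig",
    "SelectionParams",
    "CohortTable",
    "generate_cohort",
    "apply_selection",
    "generate_outcome_summary",
    "generate_attendance",
]

#: fraction of individuals genotyped on the smaller of the two arrays
_CHIP_FRACTION = 0.1


@dataclass
class CohortConfig:
    """Parameters of the generative trait model.

    ``beta_g`` is the per-allele effect at ``age_ref``; ``theta`` is the
    change in that effect per year of age.  All three per-SNP vectors
    (``maf``, ``beta_g``, ``theta``) must have length ``n_snps``.
    """

    n_individuals: int
    n_snps: int = 1
    maf: Sequence[float] | float = 0.4
    age_min: int = 40
    age_max: int = 69
    beta_age: float = 0.0
    beta_g: Sequence[float] | float = 0.0
    theta: Sequence[float] | float = 0.0
    age_ref: float = 40.0
    beta_u: float = 0.0
    intercept: float = 0.0
    noise_sd: float = 1.0
    trait_name: str = "trait"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if self.n_snps <= 0:
            raise ValueError("n_snps must be positive")
        self.maf = np.broadcast_to(np.asarray(self.maf, float), (self.n_snps,)).copy()
        self.beta_g = np.broadcast_to(
            np.asarray(self.beta_g, float), (self.n_snps,)
        ).copy()
        self.theta = np.broadcast_to(np.asarray(self.theta, float), (self.n_snps,)).copy()
        if np.any((self.maf <= 0) | (self.maf > 0.5)):
            raise ValueError("all maf must lie in (0, 0.5]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.age_min >= self.age_max:
            raise ValueError("age_min must be < age_max")


@dataclass
class SelectionParams:
    """Coefficients of the selection score S.

    ``noise_sd`` scales the selection noise v (v ~ N(0, noise_sd^2));
    set it to 0 for a fully deterministic rank cut.
    ``direction='missing'`` removes the highest-S individuals (the
    operational convention); ``direction='selected'`` keeps them.
    """

    delta_age: float = 0.0
    delta_inter: float = 0.0
    delta_trait: float = 0.0
    delta_u: float = 0.0
    missing_fraction: float = 0.5
    direction: str = "missing"
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.direction not in ("missing", "selected"):
            raise ValueError("direction must be 'missing' or 'selected'")


@dataclass
class CohortTable:
    """Individual-level records plus the dosage matrix.

    ``data`` holds one row per individual (id, age, sex, chip, confounder,
    trait columns, med_flag, selection_score, selected, attended);
    ``dosages`` is an (n_individuals, n_snps) array of hard calls {0,1,2}
    for the effect allele.
    """

    data: pd.DataFrame
    dosages: np.ndarray
    snp_ids: list[str]
    effect_allele: list[str]
    other_allele: list[str]
    maf: np.ndarray
    config: CohortConfig | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset(self, mask: np.ndarray) -> "CohortTable":
        """Row-subset individuals; genotype/trait values are untouched."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return dataclasses.replace(
            self,
            data=self.data.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[idx],
        )

    def eaf(self) -> np.ndarray:
        """Empirical effect-allele frequencies."""
        return self.dosages.mean(axis=0) / 2.0

    def to_tsv(self, path, genotype_path=None) -> None:
        """Write individuals (and optionally a variant-major dosage matrix)."""
        self.data.to_csv(path, sep="\t", index=False)
        if genotype_path is not None:
            gt = pd.DataFrame(
                self.dosages.T,
                index=pd.Index(self.snp_ids, name="variant_id"),
                columns=[str(i) for i in self.data["id"]],
            )
            gt.to_csv(genotype_path, sep="\t")

    @classmethod
    def from_tsv(cls, path, genotype_path) -> "CohortTable":
        """Rebuild a cohort from the individual and variant-major TSVs."""
        data = pd.read_csv(path, sep="\t")
        gt = pd.read_csv(genotype_path, sep="\t", index_col="variant_id")
        dosages = gt.to_numpy().T.astype(np.int8)
        m = dosages.shape[1]
        return cls(
            data=data,
            dosages=dosages,
            snp_ids=[str(v) for v in gt.index],
            effect_allele=["A"] * m,
            other_allele=["G"] * m,
            maf=dosages.mean(axis=0) / 2.0,
        )


def _snp_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"rs{str(j + 1).zfill(width)}" for j in range(n)]


def generate_cohort(config: CohortConfig) -> CohortTable:
    """Simulate a cohort under the linear SNP-by-age trait model.

    Ages are integer years uniform on [age_min, age_max] so two-year
    stratum means are exact; genotypes are hard calls; the same
    (config, seed) always yields a byte-identical table.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_snps

    age = rng.integers(config.age_min, config.age_max + 1, size=n)
    sex = rng.integers(0, 2, size=n)
    chip = (rng.random(n) < _CHIP_FRACTION).astype(np.int64)
    u_conf = rng.standard_normal(n)
    dosages = rng.binomial(2, np.asarray(config.maf)[None, :], size=(n, m)).astype(
        np.int8
    )
    noise = rng.standard_normal(n) * config.noise_sd

    # per-individual genetic contribution with age-varying per-allele effect
    age_dev = age - config.age_ref
    genetic = dosages @ np.asarray(config.beta_g) + (dosages @ np.asarray(config.theta)) * age_dev
    trait = (
        config.intercept
        + config.beta_age * age
        + genetic
        + config.beta_u * u_conf
        + noise
    )

    data = pd.DataFrame(
        {
            "id": np.arange(n, dtype=np.int64),
            "age": age,
            "sex": sex,
            "chip": chip,
            "confounder": u_conf,
            config.trait_name: trait,
        }
    )
    return CohortTable(
        data=data,
        dosages=dosages,
        snp_ids=_snp_ids(m),
        effect_allele=["A"] * m,
        other_allele=["G"] * m,
        maf=np.asarray(config.maf, float),
        config=config,
        meta={"seed": config.seed, "info": 1.0},
    )


def apply_selection(
    cohort: CohortTable,
    params: SelectionParams,
    seed: int,
    trait: str | None = None,
) -> CohortTable:
    """Score and flag individuals under the collider selection model.

    Adds ``selection_score`` and a binary ``selected`` column; exactly
    round(missing_fraction * N) individuals are flagged unselected, ranked
    on S in the configured direction with ties broken by ascending id.
    Trait and genotype values are never altered.
    """
    trait = trait or (cohort.config.trait_name if cohort.config else "trait")
    if trait not in cohort.data.columns:
        raise ValueError(f"cohort has no trait column {trait!r}")
    rng = np.random.default_rng(seed)
    d = cohort.data
    x = d[trait].to_numpy(float)
    age = d["age"].to_numpy(float)
    v = rng.standard_normal(len(d)) * params.noise_sd
    s = (
        params.delta_age * age
        + params.delta_inter * age * x
        + params.delta_trait * x
        + params.delta_u * d["confounder"].to_numpy(float)
        + v
    )

    n_missing = int(round(params.missing_fraction * len(d)))
    ids = d["id"].to_numpy()
    selected = np.ones(len(d), dtype=np.int64)
    if params.direction == "missing":
        # highest-S individuals removed; ties by ascending id
        order = np.lexsort((ids, -s))
    else:
        # highest-S individuals kept, so the lowest-S end is removed
        order = np.lexsort((ids, s))
    selected[order[:n_missing]] = 0

    out = cohort.subset(np.arange(len(d)))
    out.data["selection_score"] = s
    out.data["selected"] = selected
    return out


def generate_outcome_summary(
    snp_ids: Sequence[str],
    delta_true: Sequence[float],
    pi_ref: Sequence[float],
    b_level: float,
    b_rate: float,
    se_outcome: Sequence[float] | float,
    seed: int,
    n_cases: int = 20_000,
    n_controls: int = 200_000,
    effect_allele: Sequence[str] | None = None,
    other_allele: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Draw per-SNP outcome (log-odds) summary statistics.

    Each SNP's outcome association is
    Gamma_j ~ N(b_level * pi_ref_j + b_rate * delta_true_j, se_j^2):
    ``b_level`` couples the outcome to the SNP's trait effect at the
    reference age, ``b_rate`` to its rate of change with age.  The
    generating parameters are recorded in ``DataFrame.attrs``.
    """
    snp_ids = list(snp_ids)
    m = len(snp_ids)
    delta_true = np.broadcast_to(np.asarray(delta_true, float), (m,))
    pi_ref = np.broadcast_to(np.asarray(pi_ref, float), (m,))
    se = np.broadcast_to(np.asarray(se_outcome, float), (m,))
    if np.any(se < 0):
        raise ValueError("se_outcome must be >= 0")

    rng = np.random.default_rng(seed)
    mean = b_level * pi_ref + b_rate * delta_true
    beta = mean + rng.standard_normal(m) * se
    se_rep = np.where(se > 0, se, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, beta / se_rep, np.inf * np.sign(beta))
    from scipy.stats import norm

    pval = np.where(np.isfinite(z), 2 * norm.sf(np.abs(z)), 0.0)
    pval = np.where(beta == 0, 1.0, pval)

    out = pd.DataFrame(
        {
            "variant_id": snp_ids,
            "effect_allele": list(effect_allele) if effect_allele is not None else ["A"] * m,
            "other_allele": list(other_allele) if other_allele is not None else ["G"] * m,
            "eaf": np.full(m, np.nan),
            "beta": beta,
            "se": np.where(se > 0, se, 0.0),
            "pval": pval,
            "n_cases": n_cases,
            "n_controls": n_controls,
        }
    )
    out.attrs["provenance"] = {
        "b_level": b_level,
        "b_rate": b_rate,
        "seed": seed,
        "generator": "generate_outcome_summary",
    }
    return out


def generate_attendance(
    cohort: CohortTable,
    alpha: float,
    b_trait: float = 0.0,
    b_trait_age: float = 0.0,
    seed: int = 0,
    trait: str | None = None,
    age_ref: float | None = None,
) -> CohortTable:
    """Simulate attendance at a repeat assessment.

    attended ~ Bernoulli(expit(alpha + (b_trait + b_trait_age*(A - age_ref)) * X)),
    i.e. the trait's effect on turning up itself changes with age.
    """
    trait = trait or (cohort.config.trait_name if cohort.config else "trait")
    if trait not in cohort.data.columns:
        raise ValueError(f"cohort has no trait column {trait!r}")
    if age_ref is None:
        age_ref = cohort.config.age_ref if cohort.config else 40.0
    rng = np.random.default_rng(seed)
    x = cohort.data[trait].to_numpy(float)
    age = cohort.data["age"].to_numpy(float)
    p = expit(alpha + (b_trait + b_trait_age * (age - age_ref)) * x)
    out = cohort.subset(np.arange(cohort.n))
    out.data["attended"] = (rng.random(cohort.n) < p).astype(np.int64)
    return out
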