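"""End-to-end orchestration: simulate -> discovery scan -> stratified scans
-> meta-regression -> inclusion sets -> MR (standard + modified + age-
stratified) -> manifest.

Each stage gets its own RNG seed derived from the master seed by a counter
scheme (SeedSequence(master, stage_counter)), so any stage can be re-run
in isolation and the whole run is bit-reproducible from the master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortConfig, SelectionParams, generate_cohort, generate_outcome_summary
from .gwas import assoc_scan, cap_strata, dosage_r2, scan_all_strata, stratum_table
from .metareg import classify_inclusion, metareg_scan, sign_change_fraction
from .mr import age_stratified_mr, harmonize, ivw, modified_ivw, mr_egger, weighted_median
from .sumstats import write_sumstats

logger = logging.getLogger("agevar")

STAGES = [
    "simulate",
    "discovery",
    "stratify",
    "stratum_gwas",
    "metareg",
    "inclusion",
    "outcome",
    "mr",
]


@dataclass
class RunConfig:
    """Master configuration of a pipeline run."""

    cohort: CohortConfig = field(
        default_factory=lambda: CohortConfig(n_individuals=5000, n_snps=50)
    )
    selection: SelectionParams | None = None
    n_strata: int = 15
    stratum_width: int = 2
    reference_stratum: int = 7
    p_discovery: float = 5e-8
    p1: float = 0.05
    p2: float = 5e-5
    r2_thresh: float = 0.01
    gw: float = 5e-8
    mr_methods: tuple = ("ivw", "egger", "wmedian")
    n_boot: int = 2000
    fixed_se: bool = False
    # outcome generator settings
    b_level: float = 0.3
    b_rate: float = 0.5
    se_outcome: float = 0.05
    master_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_discovery", "p1", "p2", "r2_thresh", "gw"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1), got {v}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortConfig(**raw.pop("cohort", {"n_individuals": 5000, "n_snps": 50}))
        sel = raw.pop("selection", None)
        selection = SelectionParams(**sel) if sel else None
        return cls(cohort=cohort, selection=selection, **raw)


def stage_seed(master_seed: int, stage: str) -> int:
    """Derived per-stage seed: SeedSequence(master, stage counter)."""
    counter = STAGES.index(stage)
    return int(np.random.SeedSequence([master_seed, counter]).generate_state(1)[0] % 2**31)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages in order; returns (and writes) the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "master_seed": config.master_seed,
        "stages": [],
        "files": {},
        "parameters": {
            "n_strata": config.n_strata,
            "reference_stratum": config.reference_stratum,
            "thresholds": {
                "p_discovery": config.p_discovery, "p1": config.p1,
                "p2": config.p2, "r2": config.r2_thresh, "gw": config.gw,
            },
        },
    }

    def _record(stage: str, t0: float, files: dict[str, Path]):
        manifest["stages"].append(
            {"stage": stage, "wall_time_s": round(time.perf_counter() - t0, 4)}
        )
        for key, path in files.items():
            manifest["files"][key] = {"path": path.name, "sha256": _digest(path)}
        logger.info("stage=%s done files=%s", stage, list(files))

    # --- simulate -----------------------------------------------------
    t0 = time.perf_counter()
    cfg = config.cohort
    cfg.seed = stage_seed(config.master_seed, "simulate")
    cohort = generate_cohort(cfg)
    if config.selection is not None:
        from .cohort import apply_selection

        cohort = apply_selection(
            cohort, config.selection, seed=stage_seed(config.master_seed, "simulate") + 1
        )
        cohort = cohort.subset(cohort.data["selected"].to_numpy() == 1)
    cohort_path = out / "cohort.tsv"
    cohort.to_tsv(cohort_path)
    _record("simulate", t0, {"cohort": cohort_path})

    # --- discovery scan ----------------------------------------------
    t0 = time.perf_counter()
    trait = cfg.trait_name
    discovery = assoc_scan(cohort, trait)
    r2 = dosage_r2(cohort.dosages)
    from .gwas import clump

    discovery_ids = clump(discovery, r2, p_thresh=config.p_discovery,
                          r2_thresh=config.r2_thresh)
    disc_path = out / "discovery.tsv"
    write_sumstats(discovery.drop(columns=["flag"]), disc_path)
    ids_path = out / "discovery_ids.txt"
    ids_path.write_text("\n".join(discovery_ids) + ("\n" if discovery_ids else ""))
    _record("discovery", t0, {"discovery": disc_path, "discovery_ids": ids_path})

    # --- stratify + per-stratum GWAS ---------------------------------
    t0 = time.perf_counter()
    capped = cap_strata(
        cohort, config.reference_stratum, seed=stage_seed(config.master_seed, "stratify"),
        age_min=cfg.age_min, n_strata=config.n_strata, width=config.stratum_width,
    )
    strata_path = out / "strata.tsv"
    stratum_table(capped, cfg.age_min, config.n_strata, config.stratum_width).to_csv(
        strata_path, sep="\t", index=False
    )
    _record("stratify", t0, {"strata": strata_path})

    t0 = time.perf_counter()
    stratified = scan_all_strata(capped, trait, n_strata=config.n_strata)
    strat_path = out / "stratified.tsv"
    write_sumstats(stratified.drop(columns=["flag"]), strat_path)
    _record("stratum_gwas", t0, {"stratified": strat_path})

    # --- meta-regression ---------------------------------------------
    t0 = time.perf_counter()
    interactions = metareg_scan(stratified, expected_strata=config.n_strata)
    inter_path = out / "interactions.tsv"
    interactions.to_csv(inter_path, sep="\t", index=False, na_rep=".")
    _record("metareg", t0, {"interactions": inter_path})

    # --- inclusion sets ----------------------------------------------
    t0 = time.perf_counter()
    sets = classify_inclusion(
        discovery_ids, interactions, r2,
        p1=config.p1, p2=config.p2, r2_thresh=config.r2_thresh, gw=config.gw,
    ) if discovery_ids else None
    sets_path = out / "inclusion_sets.json"
    payload = {
        "thresholds": manifest["parameters"]["thresholds"],
        "sets": sets.as_dict() if sets else {},
        "sign_change_fraction_inclusion2": (
            sign_change_fraction(stratified, sets.inclusion2)
            if sets and sets.inclusion2 else None
        ),
    }
    sets_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    _record("inclusion", t0, {"inclusion_sets": sets_path})

    # --- synthetic outcome + MR --------------------------------------
    t0 = time.perf_counter()
    outcome = generate_outcome_summary(
        cohort.snp_ids,
        delta_true=np.asarray(cfg.theta),
        pi_ref=np.asarray(cfg.beta_g),
        b_level=config.b_level,
        b_rate=config.b_rate,
        se_outcome=config.se_outcome,
        seed=stage_seed(config.master_seed, "outcome"),
        effect_allele=cohort.effect_allele,
        other_allele=cohort.other_allele,
    )
    outcome_path = out / "outcome.tsv"
    write_sumstats(outcome, outcome_path)

    mr_rows = []
    if sets and sets.discovery:
        exp = discovery[discovery["variant_id"].isin(sets.discovery)]
        harmonized, _ = harmonize(exp, outcome)
        for method in config.mr_methods:
            if method == "ivw":
                res = [ivw(harmonized, fixed_se=config.fixed_se, label="discovery")]
            elif method == "egger" and len(harmonized) >= 3:
                res = list(mr_egger(harmonized, fixed_se=config.fixed_se,
                                    label="discovery"))
            elif method == "wmedian" and len(harmonized) >= 3:
                res = [weighted_median(
                    harmonized, n_boot=config.n_boot,
                    seed=stage_seed(config.master_seed, "mr"), label="discovery")]
            else:
                continue
            mr_rows += [r.as_dict() for r in res]
        usable = interactions[
            interactions["variant_id"].isin(sets.discovery)
            & np.isfinite(interactions["delta"])
        ]
        if len(usable):
            mod = modified_ivw(usable, outcome, fixed_se=config.fixed_se,
                               label="discovery")
            mr_rows.append(mod.as_dict())
        strat_mr = age_stratified_mr(
            stratified, outcome, sets.discovery, strata=(1, config.n_strata),
            fixed_se=config.fixed_se,
        )
        mr_rows += [r.as_dict() for r in strat_mr.values()]
    mr_df = pd.DataFrame(mr_rows)
    if len(mr_df):
        mr_df["or"] = np.exp(mr_df["estimate"])
        mr_df["or_lo"] = np.exp(mr_df["ci_lo"])
        mr_df["or_hi"] = np.exp(mr_df["ci_hi"])
    mr_path = out / "mr_results.tsv"
    mr_df.to_csv(mr_path, sep="\t", index=False, na_rep=".")
    _record("mr", t0, {"outcome": outcome_path, "mr_results": mr_path})

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
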