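"""Tab-separated GWAS summary-statistics dialect used throughout.

One row per variant (per stratum for stratified files); required columns
``variant_id, effect_allele, other_allele, eaf, beta, se, pval, n``;
stratified files additionally require ``stratum`` and ``mean_age``.
Missing values are written as '.'; a header line is mandatory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["REQUIRED_COLUMNS", "STRATIFIED_COLUMNS", "read_sumstats",
           "write_sumstats", "validate_sumstats", "ValidationReport"]

REQUIRED_COLUMNS = [
    "variant_id", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n",
]
STRATIFIED_COLUMNS = REQUIRED_COLUMNS + ["stratum", "mean_age"]

_NUMERIC = {"eaf", "beta", "se", "pval", "n", "mean_age"}
_ALLELE_CHARS = set("ACGT")


def write_sumstats(df: pd.DataFrame, path) -> None:
    """Write a summary-statistics table; NaN becomes '.'."""
    df.to_csv(path, sep="\t", index=False, na_rep=".")


def read_sumstats(path) -> pd.DataFrame:
    """Read a summary-statistics table ('.' treated as missing)."""
    df = pd.read_csv(path, sep="\t", na_values=["."], dtype={"variant_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    return df


@dataclass
class ValidationReport:
    path: str
    errors: list[dict] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.errors

    def add(self, row: int | None, message: str) -> None:
        self.errors.append({"row": row, "message": message})


def validate_sumstats(path, stratified: bool = False) -> ValidationReport:
    """Row-level format validation of a summary-statistics file.

    Checks the header, numeric column parses, se > 0, p in (0, 1], allele
    characters in {A,C,G,T}; when ``stratified``, additionally requires the
    stratum/mean_age columns.  Row numbers are 1-based data rows.
    """
    report = ValidationReport(path=str(path))
    p = Path(path)
    if not p.exists():
        report.add(None, "file does not exist")
        return report
    try:
        df = pd.read_csv(p, sep="\t", na_values=["."], dtype=str)
    except Exception as exc:  # unreadable / not TSV
        report.add(None, f"unreadable: {exc}")
        return report

    required = STRATIFIED_COLUMNS if stratified else REQUIRED_COLUMNS
    for col in required:
        if col not in df.columns:
            kind = "dialect error: missing column" if col in ("stratum", "mean_age") \
                else "missing column"
            report.add(None, f"{kind} {col!r}")
    if report.errors:
        return report

    for i, rec in enumerate(df.itertuples(index=False), start=1):
        row = rec._asdict()
        for col in ("eaf", "beta", "se", "pval", "n", "mean_age"):
            if col not in row or pd.isna(row[col]):
                continue
            try:
                row[col] = float(row[col])
            except ValueError:
                report.add(i, f"non-numeric {col}: {row[col]!r}")
                row[col] = None
        se = row.get("se")
        if isinstance(se, float) and not se > 0:
            report.add(i, f"se must be > 0 (got {se})")
        pv = row.get("pval")
        if isinstance(pv, float) and not (0 < pv <= 1):
            report.add(i, f"pval must be in (0, 1] (got {pv})")
        eaf = row.get("eaf")
        if isinstance(eaf, float) and not (0 < eaf < 1):
            report.add(i, f"eaf must be in (0, 1) (got {eaf})")
        for col in ("effect_allele", "other_allele"):
            allele = row.get(col)
            if allele is not None and not pd.isna(allele):
                if not set(str(allele)) <= _ALLELE_CHARS:
                    report.add(i, f"invalid {col}: {allele!r}")
    return report
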