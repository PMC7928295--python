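"""Cohort tables: one row per biopsied blastocyst, with patient covariates.

The on-disk format is UTF-8 TSV with a mandatory header and fixed column
order ``embryo_id, patient_id, arm, gender, age, translocation, karyotype``.
``arm`` is ``carrier`` (Robertsonian translocation carrier couple) or
``control`` (couple at risk of a monogenic disorder, karyotypically
normal); ``translocation`` is empty for controls.  TSV rather than CSV so
karyotype strings like ``46,XY`` need no quoting.

Simulated cohorts may carry ground-truth columns (``true_mode``,
``true_ice``); these are written to a ``*.truth.tsv`` sidecar, never to the
main cohort file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .karyotype import (
    KaryotypeError,
    MolecularKaryotype,
    RobTranslocation,
    parse_karyotype,
    parse_translocation,
)

__all__ = ["CohortTable", "read_cohort", "write_cohort", "summarize_cohort", "AGE_BOUNDARY"]

COLUMNS = ["embryo_id", "patient_id", "arm", "gender", "age", "translocation", "karyotype"]
TRUTH_COLUMNS = ["embryo_id", "true_mode", "true_ice"]
ARMS = ("carrier", "control")
GENDERS = ("male", "female")

#: Age-band boundary in completed years: "<35" vs ">=35".
AGE_BOUNDARY = 35


def age_band(age: int) -> str:
    return "<35" if age < AGE_BOUNDARY else ">=35"


class CohortValidationError(ValueError):
    """A cohort table violates the dialect contract."""


@dataclass
class CohortTable:
    """Validated embryo cohort backed by a :class:`pandas.DataFrame`.

    The frame always holds the seven dialect columns plus a derived
    ``age_band`` column; simulated cohorts may add truth columns.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise CohortValidationError(f"missing column(s): {', '.join(missing)}")
        df["translocation"] = df["translocation"].fillna("").astype(str)
        df.loc[df["translocation"].str.lower().isin(("", "nan", "none")), "translocation"] = ""
        if df["embryo_id"].duplicated().any():
            dup = df.loc[df["embryo_id"].duplicated(), "embryo_id"].iloc[0]
            raise CohortValidationError(f"duplicate embryo_id {dup!r}")
        for row_num, row in enumerate(df.itertuples(index=False), start=2):
            if row.arm not in ARMS:
                raise CohortValidationError(
                    f"row {row_num}: unknown arm {row.arm!r} (expected carrier/control)"
                )
            if row.gender not in GENDERS:
                raise CohortValidationError(f"row {row_num}: unknown gender {row.gender!r}")
            try:
                parse_karyotype(row.karyotype)
            except KaryotypeError as e:
                raise CohortValidationError(f"row {row_num}: bad karyotype: {e}") from e
            if row.arm == "carrier":
                try:
                    parse_translocation(row.translocation)
                except KaryotypeError as e:
                    raise CohortValidationError(
                        f"row {row_num}: carrier row needs a valid translocation: {e}"
                    ) from e
            elif row.translocation:
                raise CohortValidationError(
                    f"row {row_num}: control row must not carry a translocation"
                )
        df["age"] = df["age"].astype(int)
        df["age_band"] = df["age"].map(age_band)
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def carriers(self) -> "CohortTable":
        return CohortTable(self.df[self.df["arm"] == "carrier"].drop(columns="age_band"))

    def controls(self) -> "CohortTable":
        return CohortTable(self.df[self.df["arm"] == "control"].drop(columns="age_band"))

    def karyotypes(self) -> list[MolecularKaryotype]:
        return [parse_karyotype(s) for s in self.df["karyotype"]]

    def translocations(self) -> list[Optional[RobTranslocation]]:
        return [parse_translocation(s) if s else None for s in self.df["translocation"]]

    @property
    def has_truth(self) -> bool:
        return "true_mode" in self.df.columns


def read_cohort(path, truth: bool = False) -> CohortTable:
    """Read and validate a cohort TSV; errors carry 1-based row numbers.

    With ``truth=True`` a ``<path>.truth.tsv`` sidecar (written by the
    simulator) is merged in if present.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{path}: missing column(s): {', '.join(missing)}")
    table = CohortTable(df)
    if truth:
        sidecar = path.with_suffix(path.suffix + ".truth.tsv")
        if sidecar.exists():
            tdf = pd.read_csv(sidecar, sep="\t", dtype=str, keep_default_na=False)
            table.df = table.df.merge(tdf, on="embryo_id", how="left")
    return table


def write_cohort(table: CohortTable, path) -> Path:
    """Write the cohort TSV (and a truth sidecar when truth labels exist)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.df[COLUMNS].to_csv(path, sep="\t", index=False)
    if table.has_truth:
        sidecar = path.with_suffix(path.suffix + ".truth.tsv")
        table.df[TRUTH_COLUMNS].to_csv(sidecar, sep="\t", index=False)
    return path


def summarize_cohort(table: CohortTable, attempted_biopsies: Optional[int] = None) -> pd.DataFrame:
    """Cohort composition summary: counts per arm, gender, age band and
    translocation type, plus the diagnosis rate when the number of
    attempted biopsies is supplied (diagnosed / attempted, as a percent to
    2 decimals).
    """
    if len(table) == 0:
        raise CohortValidationError("cannot summarize an empty cohort")
    df = table.df
    rows: list[dict] = []
    for arm in ARMS:
        rows.append({"section": "arm", "level": arm, "count": int((df["arm"] == arm).sum())})
    for g in GENDERS:
        rows.append({"section": "gender", "level": g, "count": int((df["gender"] == g).sum())})
    for band in ("<35", ">=35"):
        rows.append(
            {"section": "age_band", "level": band, "count": int((df["age_band"] == band).sum())}
        )
    carriers = df[df["arm"] == "carrier"]
    for ttype, n in carriers["translocation"].value_counts().items():
        frac = n / len(carriers) if len(carriers) else float("nan")
        rows.append(
            {
                "section": "translocation",
                "level": ttype,
                "count": int(n),
                "percent": round(100 * frac, 2),
            }
        )
    if attempted_biopsies is not None:
        rate = round(100 * len(df) / attempted_biopsies, 2)
        rows.append(
            {
                "section": "diagnosis_rate",
                "level": f"{len(df)}/{attempted_biopsies}",
                "count": len(df),
                "percent": rate,
            }
        )
    return pd.DataFrame(rows)
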