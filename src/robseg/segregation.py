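"""Trivalent meiotic-segregation classification and stratified tabulation.

During meiosis I the Robertsonian derivative and its two normal homologues
pair as a trivalent, which can resolve three ways: *alternate* (both normal
homologues to one pole, derivative to the other — balanced gametes),
*adjacent* (derivative plus one homologue together — gametes disomic or
nullisomic for one translocation chromosome), and *3:0* (all three elements
to one pole).  After fertilisation by a euploid gamete, an embryo's
constitutional dosage of the two translocation chromosomes identifies the
segregation product:

====================  ===========================
(dA, dB)              category
====================  ===========================
(0, 0)                alternate
one of ±1, other 0    adjacent
(+1, +1) / (−1, −1)   3:0
anything else         3:0/others (complex bucket)
====================  ===========================

Embryos whose only translocation-chromosome signal is mosaic or segmental
get no segregation call (a mitotic origin cannot be excluded); they are
flagged unclassifiable and excluded from segregation denominators.
Abnormalities of non-translocation chromosomes never affect the call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .cohort import CohortTable
from .karyotype import (
    GameteProduct,
    MolecularKaryotype,
    RobTranslocation,
    enumerate_gamete_products,
    parse_karyotype,
    parse_translocation,
)
from .stats import ComparisonResult, compare_2x2

__all__ = [
    "CATEGORIES",
    "SegregationCall",
    "SegregationTable",
    "classify_segregation",
    "tabulate_segregation",
    "compare_segregation",
    "SegregationAnalysis",
    "SegregationResults",
]

ALTERNATE = "alternate"
ADJACENT = "adjacent"
THREE_TO_ZERO_OTHER = "three_to_zero_other"
UNCLASSIFIABLE = "unclassifiable"

#: The three reportable categories, exhaustive over classifiable embryos.
CATEGORIES = (ALTERNATE, ADJACENT, THREE_TO_ZERO_OTHER)


@dataclass(frozen=True)
class SegregationCall:
    """Inferred segregation product for one embryo.

    ``product`` is the matching enumerated gamete when the dosage pattern is
    one of the eight theoretical products *and* the product is identifiable
    from copy number; the two alternate products (normal vs balanced
    carrier) share the (0,0) signature, so alternate calls carry no product.
    Complex patterns land in the 3:0/others bucket with ``product=None``.
    """

    category: str
    product: Optional[GameteProduct] = None
    reason: Optional[str] = None


def classify_segregation(k: MolecularKaryotype, t: RobTranslocation) -> SegregationCall:
    """Map an embryo karyotype to its trivalent segregation product.

    Deterministic in the constitutional whole-chromosome deviations of the
    carrier's two translocation chromosomes; see the module docs for the
    mapping table.
    """
    if not isinstance(t, RobTranslocation):
        raise TypeError("t must be a RobTranslocation")
    chrom_a, chrom_b = t.chromosomes
    da = k.constitutional_deviation(chrom_a)
    db = k.constitutional_deviation(chrom_b)

    if (da, db) == (0, 0):
        flagged = [
            c
            for chrom in (chrom_a, chrom_b)
            for c in k.calls_on(chrom)
            if c.is_mosaic or c.segmental
        ]
        if flagged:
            kinds = ", ".join(
                f"{'mosaic' if c.is_mosaic else 'segmental'} on chr{c.chromosome}"
                for c in flagged
            )
            return SegregationCall(
                UNCLASSIFIABLE,
                reason=f"translocation-chromosome signal is non-constitutional ({kinds})",
            )
        return SegregationCall(ALTERNATE)

    by_dev = {
        p.deviation: p for p in enumerate_gamete_products(t) if p.mode != "alternate"
    }
    product = by_dev.get((da, db))
    if product is not None and product.mode == "adjacent":
        return SegregationCall(ADJACENT, product=product)
    if product is not None:  # true 3:0 pattern
        return SegregationCall(THREE_TO_ZERO_OTHER, product=product)
    return SegregationCall(
        THREE_TO_ZERO_OTHER,
        reason=f"complex pattern (d{chrom_a}={da:+d}, d{chrom_b}={db:+d}) "
        f"outside the eight enumerated products",
    )


def classify_cohort(cohort: CohortTable) -> pd.DataFrame:
    """Per-embryo segregation calls for every carrier row of ``cohort``.

    Returns the cohort columns plus ``category``/``reason``; control rows
    are excluded (they have no trivalent).
    """
    df = cohort.df[cohort.df["arm"] == "carrier"].copy()
    cats, reasons = [], []
    for kary, trans in zip(df["karyotype"], df["translocation"]):
        call = classify_segregation(parse_karyotype(kary), parse_translocation(trans))
        cats.append(call.category)
        reasons.append(call.reason or "")
    df["category"] = cats
    df["reason"] = reasons
    return df


@dataclass
class SegregationTable:
    """Stratified segregation counts.

    ``data`` has one row per stratum with columns ``<category>`` (counts),
    ``<category>_pct`` (percent of classifiable embryos, 2 dp, NaN for an
    empty stratum), ``classifiable`` and ``unclassifiable``.
    """

    data: pd.DataFrame
    stratify_by: tuple[str, ...]

    def counts(self, stratum, category: str) -> int:
        return int(self.data.loc[stratum, category])

    def classifiable(self, stratum) -> int:
        return int(self.data.loc[stratum, "classifiable"])

    def to_long(self) -> pd.DataFrame:
        """Long format (stratum, category, count, percent) for plotting."""
        rows = []
        for stratum, row in self.data.iterrows():
            for cat in CATEGORIES:
                rows.append(
                    {
                        "stratum": stratum,
                        "category": cat,
                        "count": int(row[cat]),
                        "percent": row[f"{cat}_pct"],
                    }
                )
        return pd.DataFrame(rows)


def tabulate_segregation(
    cohort: CohortTable, stratify_by: Sequence[str] = ()
) -> SegregationTable:
    """Count segregation categories per stratum of carrier embryos.

    Percentages use classifiable embryos as the denominator; unclassifiable
    embryos are reported alongside but excluded from it.  An empty stratum
    is emitted with zero counts and absent percentages.
    """
    calls = classify_cohort(cohort)
    stratify_by = tuple(stratify_by)
    if stratify_by:
        bad = [c for c in stratify_by if c not in calls.columns]
        if bad:
            raise KeyError(f"unknown stratification covariate(s): {bad}")
        grouped = [
            (key[0] if isinstance(key, tuple) and len(stratify_by) == 1 else key, sub)
            for key, sub in calls.groupby(list(stratify_by), observed=False, sort=True)
        ]
    else:
        grouped = [("overall", calls)]

    rows = {}
    for key, sub in grouped:
        n_unc = int((sub["category"] == UNCLASSIFIABLE).sum())
        n_cls = len(sub) - n_unc
        row: dict = {"classifiable": n_cls, "unclassifiable": n_unc}
        for cat in CATEGORIES:
            c = int((sub["category"] == cat).sum())
            row[cat] = c
            row[f"{cat}_pct"] = round(100 * c / n_cls, 2) if n_cls else float("nan")
        rows[key] = row
    data = pd.DataFrame.from_dict(rows, orient="index")
    data.index.name = ",".join(stratify_by) if stratify_by else "stratum"
    return SegregationTable(data=data, stratify_by=stratify_by)


def compare_segregation(
    table: SegregationTable,
    category: str,
    levels: Optional[tuple] = None,
    yates: bool = False,
) -> ComparisonResult:
    """2×2 comparison of one category's rate between two strata.

    The table is (category vs other classifiable) × (level 1 vs level 2).
    ``levels`` may be omitted when the table has exactly two strata.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    idx = list(table.data.index)
    if levels is None:
        if len(idx) != 2:
            raise ValueError(
                f"table has {len(idx)} strata; pass levels=(a, b) to choose two"
            )
        levels = (idx[0], idx[1])
    a_tot, b_tot = (table.classifiable(lv) for lv in levels)
    if a_tot == 0 or b_tot == 0:
        raise ValueError("zero classifiable embryos in one comparison level")
    a_cat, b_cat = (table.counts(lv, category) for lv in levels)
    return compare_2x2(
        [[a_cat, a_tot - a_cat], [b_cat, b_tot - b_cat]], yates=yates
    )


class SegregationAnalysis:
    """Segregation-pattern analysis of a carrier cohort.

    Model object in the fit/results idiom: construct from a cohort (or a
    raw cohort dataframe), call :meth:`fit` to classify every embryo and
    build the stratified tables, and read estimates off the returned
    :class:`SegregationResults`.
    """

    def __init__(self, cohort: CohortTable):
        if int((cohort.df["arm"] == "carrier").sum()) == 0:
            raise ValueError("segregation analysis needs at least one carrier embryo")
        self.cohort = cohort

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SegregationAnalysis":
        return cls(CohortTable(df))

    def fit(
        self, strata: Sequence[Sequence[str]] = (("gender",), ("age_band",), ("translocation",))
    ) -> "SegregationResults":
        calls = classify_cohort(self.cohort)
        tables = {(): tabulate_segregation(self.cohort, ())}
        for s in strata:
            tables[tuple(s)] = tabulate_segregation(self.cohort, s)
        return SegregationResults(calls=calls, tables=tables)


@dataclass
class SegregationResults:
    """Fitted segregation analysis: per-embryo calls plus stratified tables."""

    calls: pd.DataFrame
    tables: dict

    @property
    def overall(self) -> SegregationTable:
        return self.tables[()]

    def table(self, *stratify_by: str) -> SegregationTable:
        key = tuple(stratify_by)
        if key not in self.tables:
            raise KeyError(f"no table stratified by {key}; refit with it in `strata`")
        return self.tables[key]

    def compare(
        self, factor: str, category: str, levels: Optional[tuple] = None, yates: bool = False
    ) -> ComparisonResult:
        return compare_segregation(self.table(factor), category, levels=levels, yates=yates)

    def summary(self) -> str:
        lines = ["Trivalent segregation analysis", "=" * 31]
        for key, table in self.tables.items():
            lines.append(f"\nStratified by: {', '.join(key) if key else '(overall)'}")
            lines.append(table.data.to_string())
        n_unc = int(self.overall.data["unclassifiable"].sum())
        if n_unc:
            lines.append(
                f"\n{n_unc} embryo(s) unclassifiable (mosaic/segmental-only signal "
                f"on a translocation chromosome); excluded from denominators."
            )
        return "\n".join(lines)
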