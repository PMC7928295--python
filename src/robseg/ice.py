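"""Interchromosomal effect (ICE): non-translocation chromosome abnormalities.

The ICE hypothesis holds that the trivalent disturbs the disjunction of
chromosome pairs *not* involved in the translocation, inflating their
aneuploidy rate.  This module categorises each embryo's non-translocation
chromosomes as normal / aneuploid / mosaic and compares carrier and
control cohorts stratum by stratum.

Category rule, with precedence aneuploid > mosaic > normal so the three
rows partition every cohort exactly:

* any constitutional whole-chromosome gain/loss or segmental imbalance on
  a non-excluded chromosome → **aneuploid**;
* otherwise any mosaic call with aneuploid-cell fraction strictly above
  the threshold (default 20%) → **mosaic**;
* otherwise **normal** (sub-threshold mosaic calls are treated as noise).

For carrier embryos the two translocation chromosomes are excluded — their
imbalances are segregation products, not ICE; controls exclude nothing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .karyotype import (
    CHROMOSOMES,
    MolecularKaryotype,
    RobTranslocation,
    parse_karyotype,
    parse_translocation,
)
from .stats import ComparisonResult, compare_2x2

__all__ = [
    "ICE_CATEGORIES",
    "IceConfig",
    "IceStatus",
    "classify_ice_status",
    "ice_contingency",
    "chromosome_spectrum",
    "IceAnalysis",
    "IceResults",
]

NORMAL = "normal"
ANEUPLOID = "aneuploid"
MOSAIC = "mosaic"
ICE_CATEGORIES = (NORMAL, ANEUPLOID, MOSAIC)

#: Covariates controls actually possess; carrier-only covariates (gender,
#: translocation) reuse the full control arm, as a shared comparison column.
CONTROL_COVARIATES = ("age_band",)


@dataclass(frozen=True)
class IceConfig:
    """Parameters of the ICE categorisation.

    ``mosaic_threshold`` is the aneuploid-cell fraction above which a
    mosaic call counts (strictly greater than; default 0.20).
    ``exclude_chromosomes`` holds the carrier's translocation pair, empty
    for controls.
    """

    mosaic_threshold: float = 0.20
    exclude_chromosomes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (0.0 < self.mosaic_threshold < 1.0):
            raise ValueError("mosaic_threshold must lie strictly between 0 and 1")
        object.__setattr__(self, "exclude_chromosomes", frozenset(self.exclude_chromosomes))

    @classmethod
    def for_carrier(cls, t: RobTranslocation, mosaic_threshold: float = 0.20) -> "IceConfig":
        return cls(mosaic_threshold=mosaic_threshold, exclude_chromosomes=frozenset(t.chromosomes))


@dataclass(frozen=True)
class IceStatus:
    """Per-embryo ICE category with the chromosomes that drove it.

    ``contributors`` lists (chromosome, dosage sign, is_mosaic) for every
    qualifying abnormality; excluded chromosomes never appear.
    """

    category: str
    contributors: tuple[tuple[str, int, bool], ...] = ()


def classify_ice_status(k: MolecularKaryotype, cfg: IceConfig = IceConfig()) -> IceStatus:
    """Categorise an embryo's non-excluded chromosomes (see module docs)."""
    aneuploid: list[tuple[str, int, bool]] = []
    mosaic: list[tuple[str, int, bool]] = []
    for call in k.calls:
        if call.chromosome in cfg.exclude_chromosomes:
            continue
        sign = int(np.sign(call.deviation(k.sex_constitution)))
        if call.is_mosaic:
            if call.mosaic_fraction > cfg.mosaic_threshold:
                mosaic.append((call.chromosome, sign, True))
        else:
            aneuploid.append((call.chromosome, sign, False))
    if aneuploid:
        return IceStatus(ANEUPLOID, tuple(aneuploid))
    if mosaic:
        return IceStatus(MOSAIC, tuple(mosaic))
    return IceStatus(NORMAL)


def classify_ice_cohort(cohort: CohortTable, mosaic_threshold: float = 0.20) -> pd.DataFrame:
    """Per-embryo ICE categories for a cohort (carrier rows exclude their
    own translocation pair)."""
    df = cohort.df.copy()
    cats = []
    for kary, trans in zip(df["karyotype"], df["translocation"]):
        if trans:
            cfg = IceConfig.for_carrier(parse_translocation(trans), mosaic_threshold)
        else:
            cfg = IceConfig(mosaic_threshold=mosaic_threshold)
        cats.append(classify_ice_status(parse_karyotype(kary), cfg).category)
    df["ice_category"] = cats
    return df


def _stratum_mask(df: pd.DataFrame, stratum: dict, restrict_to: Optional[Sequence[str]] = None):
    mask = pd.Series(True, index=df.index)
    for cov, val in stratum.items():
        if restrict_to is not None and cov not in restrict_to:
            continue
        mask &= df[cov] == val
    return mask


def ice_contingency(
    carriers: CohortTable,
    controls: CohortTable,
    strata: Sequence[Sequence[str]] = ((), ("age_band",), ("gender",), ("gender", "age_band")),
    mosaic_threshold: float = 0.20,
    yates: bool = False,
) -> pd.DataFrame:
    """Carrier-vs-control comparison of ICE categories, per stratum.

    For each stratum and each category a 2×2 (category vs rest × carrier
    vs control) is tested; the control arm is filtered only on covariates
    controls possess (age band), so the same control column is reused
    across carrier gender strata.  Returns a long dataframe with counts,
    percentages, OR, p and the chosen test.
    """
    if len(carriers) == 0 or len(controls) == 0:
        raise ValueError("both a carrier arm and a control arm are required")
    cdf = classify_ice_cohort(carriers, mosaic_threshold)
    kdf = classify_ice_cohort(controls, mosaic_threshold)
    cdf = cdf[cdf["arm"] == "carrier"]
    kdf = kdf[kdf["arm"] == "control"]
    if len(cdf) == 0 or len(kdf) == 0:
        raise ValueError("both a carrier arm and a control arm are required")

    rows = []
    for covs in strata:
        covs = tuple(covs)
        if covs:
            level_sets = [sorted(cdf[c].unique()) for c in covs]
            combos = [dict(zip(covs, vals)) for vals in itertools.product(*level_sets)]
        else:
            combos = [{}]
        for stratum in combos:
            car = cdf[_stratum_mask(cdf, stratum)]
            ctl = kdf[_stratum_mask(kdf, stratum, restrict_to=CONTROL_COVARIATES)]
            label = ",".join(f"{k}={v}" for k, v in stratum.items()) or "overall"
            for cat in ICE_CATEGORIES:
                a = int((car["ice_category"] == cat).sum())
                c = int((ctl["ice_category"] == cat).sum())
                row = {
                    "stratum": label,
                    "category": cat,
                    "carrier_count": a,
                    "carrier_total": len(car),
                    "carrier_pct": round(100 * a / len(car), 2) if len(car) else float("nan"),
                    "control_count": c,
                    "control_total": len(ctl),
                    "control_pct": round(100 * c / len(ctl), 2) if len(ctl) else float("nan"),
                }
                if len(car) and len(ctl) and 0 < a + c and (a < len(car) or c < len(ctl)):
                    res = compare_2x2(
                        [[a, len(car) - a], [c, len(ctl) - c]], yates=yates
                    )
                    row.update(
                        odds_ratio=res.odds_ratio,
                        or_ci_low=res.or_ci95[0],
                        or_ci_high=res.or_ci95[1],
                        p_value=res.p_value,
                        test_used=res.test_used,
                    )
                else:
                    row.update(
                        odds_ratio=float("nan"),
                        or_ci_low=float("nan"),
                        or_ci_high=float("nan"),
                        p_value=float("nan"),
                        test_used="none",
                    )
                rows.append(row)
    return pd.DataFrame(rows)


def chromosome_spectrum(cohort: CohortTable, mosaic_threshold: float = 0.20) -> pd.DataFrame:
    """Per-chromosome abnormality spectrum over chromosomes 1–22, X, Y.

    Counts every contributing chromosome (aneuploid and supra-threshold
    mosaic separately); proportions use the number of embryos in the cohort
    as denominator.  Carrier rows exclude their own translocation pair by
    construction.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    aneu = {c: 0 for c in CHROMOSOMES}
    mos = {c: 0 for c in CHROMOSOMES}
    for kary, trans in zip(cohort.df["karyotype"], cohort.df["translocation"]):
        if trans:
            cfg = IceConfig.for_carrier(parse_translocation(trans), mosaic_threshold)
        else:
            cfg = IceConfig(mosaic_threshold=mosaic_threshold)
        k = parse_karyotype(kary)
        for call in k.calls:
            if call.chromosome in cfg.exclude_chromosomes:
                continue
            if call.is_mosaic:
                if call.mosaic_fraction > cfg.mosaic_threshold:
                    mos[call.chromosome] += 1
            else:
                aneu[call.chromosome] += 1
    n = len(cohort)
    return pd.DataFrame(
        {
            "chromosome": list(CHROMOSOMES),
            "aneuploid_count": [aneu[c] for c in CHROMOSOMES],
            "aneuploid_prop": [aneu[c] / n for c in CHROMOSOMES],
            "mosaic_count": [mos[c] for c in CHROMOSOMES],
            "mosaic_prop": [mos[c] / n for c in CHROMOSOMES],
        }
    )


class IceAnalysis:
    """Carrier-vs-control ICE analysis in the fit/results idiom."""

    def __init__(
        self,
        carriers: CohortTable,
        controls: CohortTable,
        mosaic_threshold: float = 0.20,
        yates: bool = False,
    ):
        self.carriers = carriers
        self.controls = controls
        self.mosaic_threshold = mosaic_threshold
        self.yates = yates

    def fit(
        self,
        strata: Sequence[Sequence[str]] = ((), ("age_band",), ("gender",), ("gender", "age_band")),
    ) -> "IceResults":
        table = ice_contingency(
            self.carriers,
            self.controls,
            strata=strata,
            mosaic_threshold=self.mosaic_threshold,
            yates=self.yates,
        )
        return IceResults(
            table=table,
            carrier_spectrum=chromosome_spectrum(self.carriers, self.mosaic_threshold),
            control_spectrum=chromosome_spectrum(self.controls, self.mosaic_threshold),
            mosaic_threshold=self.mosaic_threshold,
        )


@dataclass
class IceResults:
    """Fitted ICE comparison: stratified contingency table plus the
    per-chromosome abnormality spectra of both arms."""

    table: pd.DataFrame
    carrier_spectrum: pd.DataFrame
    control_spectrum: pd.DataFrame
    mosaic_threshold: float

    def result_for(self, stratum: str, category: str) -> pd.Series:
        sub = self.table[(self.table["stratum"] == stratum) & (self.table["category"] == category)]
        if len(sub) != 1:
            raise KeyError(f"no unique row for stratum={stratum!r}, category={category!r}")
        return sub.iloc[0]

    def summary(self) -> str:
        lines = [
            "Interchromosomal-effect analysis",
            "=" * 32,
            f"mosaic threshold: fraction > {self.mosaic_threshold:.2f}",
            "(95% CIs are Woolf logit intervals, an extension over the source tables)",
            "",
            self.table.to_string(index=False),
        ]
        return "\n".join(lines)

    def plot_spectrum(self, ax=None):
        """Figure-style bar chart of per-chromosome abnormality proportions
        in both arms (aneuploid stacked with mosaic)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        x = np.arange(len(CHROMOSOMES))
        w = 0.4
        for off, spec, label in (
            (-w / 2, self.carrier_spectrum, "carriers"),
            (+w / 2, self.control_spectrum, "controls"),
        ):
            ax.bar(x + off, spec["aneuploid_prop"], width=w, label=f"{label}: aneuploid")
            ax.bar(
                x + off,
                spec["mosaic_prop"],
                width=w,
                bottom=spec["aneuploid_prop"],
                label=f"{label}: mosaic",
            )
        ax.set_xticks(x, CHROMOSOMES)
        ax.set_xlabel("chromosome")
        ax.set_ylabel("proportion of embryos")
        ax.legend(fontsize=8)
        return ax
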