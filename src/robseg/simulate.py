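"""Synthetic PGT cohort generator.

Simulates the data-generating process the analysis assumes: a carrier arm
whose embryos inherit one of the eight trivalent gamete products (mode
probabilities per carrier gender, optionally per translocation type, with a
uniform choice among the products of the drawn mode), plus a control arm;
both arms receive independent per-chromosome background whole-chromosome
errors (meiotic, constitutional) and single-chromosome mosaic events
(mitotic, with an aneuploid-cell fraction drawn uniformly).  Background
errors are never placed on a carrier embryo's translocation chromosomes,
so segregation ground truth stays well defined.

Every record carries ground-truth labels (true segregation mode, true ICE
category), checked against the classifiers at generation time.  All
randomness flows from a single seeded generator; draw order is: carrier
patients, carrier embryos (in order), control patients, control embryos.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import AGE_BOUNDARY, CohortTable
from .ice import IceConfig, classify_ice_status
from .karyotype import (
    CopyCall,
    GameteProduct,
    MolecularKaryotype,
    RobTranslocation,
    all_rob_translocations,
    enumerate_gamete_products,
    expected_copies,
    format_karyotype,
    parse_translocation,
)
from .segregation import UNCLASSIFIABLE, classify_segregation

__all__ = [
    "SimulationConfig",
    "EmbryoRecord",
    "default_parameters",
    "simulate_gamete",
    "simulate_embryo",
    "simulate_cohort",
]

_AUTOSOMES = tuple(str(i) for i in range(1, 23))


@dataclass
class SimulationConfig:
    """All probabilities and rates the generator uses.

    Defaults (see :func:`default_parameters`) reproduce the composition and
    stratum-specific rates of a two-arm PGT cohort: 977 carrier and 785
    control blastocysts; male-carrier embryo share 473/977; carrier
    alternate/adjacent/3:0 mode probabilities 0.8245/0.1712/0.0042 (male)
    and 0.6310/0.3611/0.0079 (female); background rates calibrated so the
    expected ICE aneuploidy proportion is 24.77% in carriers (20 eligible
    autosomes) and 20.25% in controls (22 autosomes), and mosaic
    proportions 6.55% / 5.35%.
    """

    n_carrier_embryos: int = 977
    n_control_embryos: int = 785
    seed: int = 0

    # cohort composition (embryo-level proportions)
    male_fraction: float = 473 / 977
    carrier_age_lt35_fraction: float = 836 / 977
    control_age_lt35_fraction: float = 621 / 785
    translocation_weights: dict = field(default_factory=dict)

    # segregation-mode probabilities (p_alt, p_adj, p_30) per gender,
    # with optional per-(gender, translocation) overrides keyed "male|rob(13;14)(q10;q10)"
    mode_probs: dict = field(default_factory=dict)
    mode_probs_by_type: dict = field(default_factory=dict)

    # background meiotic aneuploidy: per-chromosome per-embryo probability
    background_aneuploidy_rate_carrier: float = 0.0
    background_aneuploidy_rate_control: float = 0.0
    # per-embryo probability of one mosaic (mitotic) event
    mosaic_rate_carrier: float = 0.0
    mosaic_rate_control: float = 0.0
    mosaic_fraction_range: tuple = (0.2, 0.8)
    # probability a carrier embryo's translocation-chromosome signal is
    # mosaic-only (hence unclassifiable for segregation)
    unclassifiable_rate: float = 0.0
    include_sex_chromosomes_control: bool = False
    embryos_per_patient: float = 4.5

    def __post_init__(self) -> None:
        for name in (
            "male_fraction",
            "carrier_age_lt35_fraction",
            "control_age_lt35_fraction",
            "background_aneuploidy_rate_carrier",
            "background_aneuploidy_rate_control",
            "mosaic_rate_carrier",
            "mosaic_rate_control",
            "unclassifiable_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        lo, hi = self.mosaic_fraction_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("mosaic_fraction_range must satisfy 0 <= lo < hi <= 1")
        for key, probs in {**self.mode_probs, **self.mode_probs_by_type}.items():
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"mode probabilities for {key!r} do not sum to 1")
        if self.translocation_weights:
            tot = sum(self.translocation_weights.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError("translocation weights must sum to 1")

    def mode_probs_for(self, gender: str, translocation: str) -> tuple[float, float, float]:
        probs = self.mode_probs_by_type.get(f"{gender}|{translocation}")
        if probs is None:
            probs = self.mode_probs[gender]
        return tuple(probs)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = json.load(fh)
        base = dataclasses.asdict(default_parameters())
        base.update(raw)
        base["mosaic_fraction_range"] = tuple(base["mosaic_fraction_range"])
        base["mode_probs"] = {k: tuple(v) for k, v in base["mode_probs"].items()}
        base["mode_probs_by_type"] = {k: tuple(v) for k, v in base["mode_probs_by_type"].items()}
        return cls(**base)


def _normalized(p: Sequence[float]) -> tuple[float, float, float]:
    s = sum(p)
    return tuple(x / s for x in p)


def default_parameters(seed: int = 0) -> SimulationConfig:
    """Study-condition defaults.

    Mode probabilities come from the observed per-gender category
    proportions (male 390/81/2 of 473; female 318/182/4 of 504, lightly
    normalised).  The translocation mix gives rob(13;14) 55.3% and
    rob(14;21) 10.6% of carriers, the two most frequent fusions, with the
    remaining eight D;G types sharing the rest equally.  Background rates
    solve 1−(1−λ)^k = target aneuploidy proportion for k eligible autosomes
    (20 for carriers, 22 for controls); mosaic-event rates divide the
    target mosaic proportion by the probability of not also being
    aneuploid, since aneuploid takes precedence.
    """
    weights = {"rob(13;14)(q10;q10)": 0.553, "rob(14;21)(q10;q10)": 0.106}
    others = [t for t in all_rob_translocations() if str(t) not in weights]
    rest = (1.0 - sum(weights.values())) / len(others)
    for t in others:
        weights[str(t)] = rest

    p_aneu_car, p_aneu_ctl = 0.2477, 0.2025
    p_mos_car, p_mos_ctl = 0.0655, 0.0535
    return SimulationConfig(
        seed=seed,
        translocation_weights=weights,
        mode_probs={
            "male": _normalized((0.8245, 0.1712, 0.0042)),
            "female": _normalized((0.6310, 0.3611, 0.0079)),
        },
        background_aneuploidy_rate_carrier=1 - (1 - p_aneu_car) ** (1 / 20),
        background_aneuploidy_rate_control=1 - (1 - p_aneu_ctl) ** (1 / 22),
        mosaic_rate_carrier=p_mos_car / (1 - p_aneu_car),
        mosaic_rate_control=p_mos_ctl / (1 - p_aneu_ctl),
    )


@dataclass(frozen=True)
class EmbryoRecord:
    """One simulated blastocyst with its ground-truth labels."""

    embryo_id: str
    patient_id: str
    arm: str
    gender: str
    age: int
    translocation: str
    karyotype: MolecularKaryotype
    true_mode: str
    true_ice: str


_MODES = ("alternate", "adjacent", "three_to_zero")


def simulate_gamete(
    t: RobTranslocation, probs: Sequence[float], rng: np.random.Generator
) -> GameteProduct:
    """Draw a gamete product: mode with probabilities (p_alt, p_adj, p_30),
    then a uniform choice among that mode's 2 / 4 / 2 enumerated products."""
    probs = _normalized(probs)
    mode = _MODES[rng.choice(3, p=probs)]
    candidates = [p for p in enumerate_gamete_products(t) if p.mode == mode]
    return candidates[rng.integers(len(candidates))]


def _eligible_background(arm: str, translocation: str, cfg: SimulationConfig) -> tuple[str, ...]:
    if arm == "carrier":
        excl = set(parse_translocation(translocation).chromosomes)
        return tuple(c for c in _AUTOSOMES if c not in excl)
    chroms = _AUTOSOMES
    if cfg.include_sex_chromosomes_control:
        chroms = chroms + ("X", "Y")
    return chroms


def simulate_embryo(
    gamete: Optional[GameteProduct],
    cfg: SimulationConfig,
    covariates: dict,
    rng: np.random.Generator,
) -> EmbryoRecord:
    """Assemble one embryo: disomic baseline + gamete dosage deviations
    (carrier arm) + background constitutional errors + optional mosaic.

    ``covariates`` must hold embryo_id, patient_id, arm, gender, age and
    translocation ('' for controls).  Ground-truth labels come from the
    generating events and are asserted against the classifiers.
    """
    arm = covariates["arm"]
    if (gamete is None) == (arm == "carrier"):
        raise ValueError("a gamete is required for, and only for, carrier embryos")
    sex = "XX" if rng.random() < 0.5 else "XY"
    calls: list[CopyCall] = []
    true_mode = ""

    if arm == "carrier":
        t = parse_translocation(covariates["translocation"])
        if cfg.unclassifiable_rate > 0 and rng.random() < cfg.unclassifiable_rate:
            # translocation-chromosome signal is mosaic-only: no meiotic call
            chrom = t.chromosomes[rng.integers(2)]
            frac = round(rng.uniform(*cfg.mosaic_fraction_range), 2)
            sign = 1 if rng.random() < 0.5 else -1
            calls.append(
                CopyCall(chrom, expected_copies(chrom, sex) + sign, mosaic_fraction=frac)
            )
            true_mode = UNCLASSIFIABLE
        else:
            for chrom, dev in zip(t.chromosomes, gamete.deviation):
                if dev:
                    calls.append(CopyCall(chrom, 2 + dev))
            true_mode = (
                "three_to_zero_other" if gamete.mode == "three_to_zero" else gamete.mode
            )

    rate = (
        cfg.background_aneuploidy_rate_carrier
        if arm == "carrier"
        else cfg.background_aneuploidy_rate_control
    )
    eligible = _eligible_background(arm, covariates["translocation"], cfg)
    hit = rng.random(len(eligible)) < rate
    background_hits = []
    for chrom, h in zip(eligible, hit):
        if not h:
            continue
        sign = 1 if rng.random() < 0.5 else -1
        if expected_copies(chrom, sex) + sign < 0:  # e.g. loss of Y in an XX embryo
            sign = 1
        calls.append(CopyCall(chrom, expected_copies(chrom, sex) + sign))
        background_hits.append(chrom)

    mos_rate = cfg.mosaic_rate_carrier if arm == "carrier" else cfg.mosaic_rate_control
    mosaic_supra = False
    if rng.random() < mos_rate:
        taken = {c.chromosome for c in calls}
        free = [c for c in eligible if c not in taken]
        if free:
            chrom = free[rng.integers(len(free))]
            frac = round(rng.uniform(*cfg.mosaic_fraction_range), 2)
            sign = 1 if rng.random() < 0.5 else -1
            if expected_copies(chrom, sex) + sign < 0:
                sign = 1
            calls.append(
                CopyCall(chrom, expected_copies(chrom, sex) + sign, mosaic_fraction=frac)
            )
            mosaic_supra = frac > 0.20

    true_ice = "aneuploid" if background_hits else ("mosaic" if mosaic_supra else "normal")
    k = MolecularKaryotype(sex_constitution=sex, calls=tuple(calls))

    # generation-time consistency checks against the classifiers
    if arm == "carrier":
        got = classify_segregation(k, parse_translocation(covariates["translocation"]))
        assert got.category == true_mode, (got.category, true_mode)
        cfg_ice = IceConfig.for_carrier(parse_translocation(covariates["translocation"]))
    else:
        cfg_ice = IceConfig()
    assert classify_ice_status(k, cfg_ice).category == true_ice

    return EmbryoRecord(
        embryo_id=covariates["embryo_id"],
        patient_id=covariates["patient_id"],
        arm=arm,
        gender=covariates["gender"],
        age=covariates["age"],
        translocation=covariates["translocation"],
        karyotype=k,
        true_mode=true_mode,
        true_ice=true_ice,
    )


def _draw_patients(
    n_embryos: int, arm: str, cfg: SimulationConfig, rng: np.random.Generator
) -> list[dict]:
    n_pat = max(1, round(n_embryos / cfg.embryos_per_patient))
    lt35 = (
        cfg.carrier_age_lt35_fraction if arm == "carrier" else cfg.control_age_lt35_fraction
    )
    patients = []
    ttypes = sorted(cfg.translocation_weights)
    weights = np.array([cfg.translocation_weights[t] for t in ttypes])
    for i in range(n_pat):
        young = rng.random() < lt35
        age = int(rng.integers(25, AGE_BOUNDARY) if young else rng.integers(AGE_BOUNDARY, 43))
        patients.append(
            {
                "patient_id": f"{arm[:3]}P{i + 1:04d}",
                "gender": "male" if rng.random() < cfg.male_fraction else "female",
                "age": age,
                "translocation": ttypes[rng.choice(len(ttypes), p=weights)]
                if arm == "carrier"
                else "",
            }
        )
    return patients


def simulate_cohort(cfg: Optional[SimulationConfig] = None) -> CohortTable:
    """Generate the full two-arm cohort; reproducible from ``cfg.seed``."""
    if cfg is None:
        cfg = default_parameters()
    rng = np.random.default_rng(cfg.seed)
    records: list[EmbryoRecord] = []
    for arm, n in (("carrier", cfg.n_carrier_embryos), ("control", cfg.n_control_embryos)):
        if n == 0:
            continue
        patients = _draw_patients(n, arm, cfg, rng)
        assignments = rng.integers(len(patients), size=n)
        for i, pi in enumerate(assignments):
            pat = patients[pi]
            cov = {
                "embryo_id": f"{arm[:3]}E{i + 1:04d}",
                "arm": arm,
                **pat,
            }
            gamete = None
            if arm == "carrier":
                probs = cfg.mode_probs_for(pat["gender"], pat["translocation"])
                gamete = simulate_gamete(parse_translocation(pat["translocation"]), probs, rng)
            records.append(simulate_embryo(gamete, cfg, cov, rng))

    df = pd.DataFrame(
        {
            "embryo_id": [r.embryo_id for r in records],
            "patient_id": [r.patient_id for r in records],
            "arm": [r.arm for r in records],
            "gender": [r.gender for r in records],
            "age": [r.age for r in records],
            "translocation": [r.translocation for r in records],
            "karyotype": [format_karyotype(r.karyotype) for r in records],
            "true_mode": [r.true_mode for r in records],
            "true_ice": [r.true_ice for r in records],
        }
    )
    return CohortTable(df)
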