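"""Chromosome-level data model for Robertsonian translocations and embryo
molecular karyotypes.

A *molecular karyotype* is the chromosome-level copy-number profile of an
embryo inferred from a genome-wide array: one optional constitutional call
per chromosome (a whole-chromosome gain/loss shared by all biopsied cells,
or a segmental imbalance), plus any number of mosaic calls (an aneuploid
lineage present in only a fraction of cells).  Chromosomes without a call
are disomic, or at the sex-constitution baseline for X and Y.

Karyotypes are serialised in a compact dialect::

    <modal count>,<sex>[,<abn>...]

where ``<abn>`` is one of

* ``+N`` / ``-N``      — constitutional whole-chromosome gain / loss,
* ``mos+N(f)`` / ``mos-N(f)`` — mosaic gain / loss, ``f`` the aneuploid-cell
  fraction printed with two decimals,
* ``seg+N`` / ``seg-N`` — segmental (partial-chromosome) imbalance.

Examples: ``46,XY``; ``47,XX,+13``; ``45,XY,-21``; ``46,XX,mos+16(0.35)``;
``46,XY,seg-5``.  The modal count carries only constitutional whole-chromosome
deviations (46 − 1 + 1 for ``46,XY,-14,+21``); mosaic and segmental calls do
not move it.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "CHROMOSOMES",
    "ACROCENTRICS",
    "KaryotypeError",
    "RobTranslocation",
    "CopyCall",
    "MolecularKaryotype",
    "GameteProduct",
    "parse_karyotype",
    "format_karyotype",
    "parse_translocation",
    "enumerate_gamete_products",
]

#: The 24 human chromosomes in tabulation order.
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")

#: Acrocentric chromosomes able to participate in a Robertsonian fusion
#: (group D: 13, 14, 15; group G: 21, 22).
ACROCENTRICS: tuple[int, ...] = (13, 14, 15, 21, 22)

_CHROM_INDEX = {c: i for i, c in enumerate(CHROMOSOMES)}


def chromosome_index(label: str) -> int:
    """Position of ``label`` in the canonical 1..22, X, Y ordering."""
    try:
        return _CHROM_INDEX[label]
    except KeyError:
        raise KaryotypeError(f"unknown chromosome label {label!r}") from None


class KaryotypeError(ValueError):
    """Malformed karyotype or translocation string, or invalid model state."""


@dataclass(frozen=True, order=True)
class RobTranslocation:
    """A Robertsonian translocation: centric fusion of two acrocentrics.

    Stored with ``chr_a < chr_b`` numerically; both must be distinct members
    of {13, 14, 15, 21, 22}.
    """

    chr_a: int
    chr_b: int

    def __post_init__(self) -> None:
        if self.chr_a not in ACROCENTRICS or self.chr_b not in ACROCENTRICS:
            raise KaryotypeError(
                f"rob({self.chr_a};{self.chr_b}): both chromosomes must be "
                f"acrocentric (13, 14, 15, 21 or 22)"
            )
        if self.chr_a >= self.chr_b:
            raise KaryotypeError(
                f"rob({self.chr_a};{self.chr_b}): chromosomes must be distinct "
                f"and stored in increasing order"
            )

    @property
    def chromosomes(self) -> tuple[str, str]:
        return (str(self.chr_a), str(self.chr_b))

    def __str__(self) -> str:
        return f"rob({self.chr_a};{self.chr_b})(q10;q10)"


_ROB_RE = re.compile(r"^rob\((\d{1,2});(\d{1,2})\)(?:\(q10;q10\))?$")


def parse_translocation(text: str) -> RobTranslocation:
    """Parse ``rob(13;14)(q10;q10)`` (breakpoint suffix optional)."""
    m = _ROB_RE.match(text.strip())
    if not m:
        raise KaryotypeError(f"unrecognised translocation string {text!r}")
    a, b = sorted((int(m.group(1)), int(m.group(2))))
    return RobTranslocation(a, b)


def all_rob_translocations() -> list[RobTranslocation]:
    """The 10 possible D;G Robertsonian translocations."""
    return [RobTranslocation(a, b) for a, b in itertools.combinations(ACROCENTRICS, 2)]


@dataclass(frozen=True)
class CopyCall:
    """One copy-number abnormality call.

    ``copies`` is the affected lineage's whole-chromosome copy number.  A
    call with ``mosaic_fraction`` absent is constitutional (all biopsied
    cells share it); a mosaic call records the aneuploid lineage's copy
    number and the fraction of cells carrying it.  ``segmental`` flags an
    imbalance affecting only part of the chromosome; breakpoints are out of
    the model.
    """

    chromosome: str
    copies: int
    mosaic_fraction: Optional[float] = None
    segmental: bool = False

    def __post_init__(self) -> None:
        if self.chromosome not in _CHROM_INDEX:
            raise KaryotypeError(f"unknown chromosome label {self.chromosome!r}")
        if self.copies < 0:
            raise KaryotypeError(f"negative copy number on chromosome {self.chromosome}")
        if self.mosaic_fraction is not None and not (0.0 <= self.mosaic_fraction <= 1.0):
            raise KaryotypeError(
                f"mosaic fraction {self.mosaic_fraction} outside [0, 1] "
                f"on chromosome {self.chromosome}"
            )
        if self.mosaic_fraction is not None and self.segmental:
            raise KaryotypeError(
                f"chromosome {self.chromosome}: a call cannot be both mosaic and segmental"
            )

    @property
    def is_mosaic(self) -> bool:
        return self.mosaic_fraction is not None

    def deviation(self, sex: str) -> int:
        """Signed dosage deviation from the expected copy number."""
        return self.copies - expected_copies(self.chromosome, sex)


def expected_copies(chromosome: str, sex: str) -> int:
    """Baseline copy number given the sex constitution (XX or XY)."""
    if chromosome == "X":
        return 2 if sex == "XX" else 1
    if chromosome == "Y":
        return 1 if sex == "XY" else 0
    return 2


def _call_sort_key(call: CopyCall) -> tuple[int, int, float]:
    # chromosome order, then constitutional-whole < segmental < mosaic
    cls = 2 if call.is_mosaic else (1 if call.segmental else 0)
    return (chromosome_index(call.chromosome), cls, call.mosaic_fraction or 0.0)


@dataclass(frozen=True)
class MolecularKaryotype:
    """Copy-number profile of one embryo.

    ``sex_constitution`` is the disomic baseline ("XX" or "XY"); ``calls``
    hold every abnormality.  At most one constitutional call (whole or
    segmental) per chromosome; chromosomes without a call sit at baseline.
    Calls are kept in canonical order so equality matches the writer's
    round-trip guarantee.
    """

    sex_constitution: str
    calls: tuple[CopyCall, ...] = ()

    def __post_init__(self) -> None:
        if self.sex_constitution not in ("XX", "XY"):
            raise KaryotypeError(
                f"sex constitution must be 'XX' or 'XY', got {self.sex_constitution!r}"
            )
        ordered = tuple(sorted(self.calls, key=_call_sort_key))
        object.__setattr__(self, "calls", ordered)
        seen: set[str] = set()
        for call in ordered:
            if not call.is_mosaic:
                if call.chromosome in seen:
                    raise KaryotypeError(
                        f"duplicate constitutional call for chromosome {call.chromosome}"
                    )
                seen.add(call.chromosome)
            if call.is_mosaic and call.deviation(self.sex_constitution) == 0:
                raise KaryotypeError(
                    f"mosaic call on chromosome {call.chromosome} has the "
                    f"disomic copy number {call.copies}"
                )

    @property
    def modal_count(self) -> int:
        """Total chromosome count of the constitutional (majority) lineage."""
        dev = sum(
            c.deviation(self.sex_constitution)
            for c in self.calls
            if not c.is_mosaic and not c.segmental
        )
        return 46 + dev

    def constitutional_deviation(self, chromosome: str) -> int:
        """Whole-chromosome constitutional dosage deviation (0 if no call)."""
        for c in self.calls:
            if c.chromosome == chromosome and not c.is_mosaic and not c.segmental:
                return c.deviation(self.sex_constitution)
        return 0

    def calls_on(self, chromosome: str) -> tuple[CopyCall, ...]:
        return tuple(c for c in self.calls if c.chromosome == chromosome)

    def is_euploid(self) -> bool:
        return not self.calls

    def __str__(self) -> str:
        return format_karyotype(self)


_ABN_RE = re.compile(
    r"^(?:(?P<mos>mos)|(?P<seg>seg))?(?P<sign>[+-])(?P<chrom>\d{1,2}|X|Y)"
    r"(?:\((?P<frac>\d(?:\.\d+)?)\))?$"
)


def parse_karyotype(text: str) -> MolecularKaryotype:
    """Parse a karyotype string in the dialect described in the module docs.

    Unknown or malformed tokens are rejected with the offending token and
    its comma-separated position named; duplicate constitutional calls and
    modal-count mismatches raise :class:`KaryotypeError`.
    """
    parts = [p.strip() for p in text.strip().split(",")]
    if len(parts) < 2:
        raise KaryotypeError(f"karyotype {text!r}: expected '<count>,<sex>[,...]'")
    try:
        modal = int(parts[0])
    except ValueError:
        raise KaryotypeError(
            f"malformed modal count {parts[0]!r} at position 1 in {text!r}"
        ) from None
    sex = parts[1]
    if sex not in ("XX", "XY"):
        raise KaryotypeError(f"malformed sex token {sex!r} at position 2 in {text!r}")

    calls: list[CopyCall] = []
    for pos, token in enumerate(parts[2:], start=3):
        m = _ABN_RE.match(token)
        if not m:
            raise KaryotypeError(f"malformed token {token!r} at position {pos} in {text!r}")
        chrom = m.group("chrom")
        if chrom not in _CHROM_INDEX:
            raise KaryotypeError(
                f"unknown chromosome in token {token!r} at position {pos} in {text!r}"
            )
        sign = 1 if m.group("sign") == "+" else -1
        frac = m.group("frac")
        if (m.group("mos") is None) != (frac is None):
            raise KaryotypeError(
                f"malformed token {token!r} at position {pos} in {text!r}: "
                f"a fraction is required for, and only for, mosaic calls"
            )
        copies = expected_copies(chrom, sex) + sign
        if copies < 0:
            raise KaryotypeError(
                f"token {token!r} at position {pos} in {text!r} implies a "
                f"negative copy number"
            )
        calls.append(
            CopyCall(
                chromosome=chrom,
                copies=copies,
                mosaic_fraction=float(frac) if frac is not None else None,
                segmental=m.group("seg") is not None,
            )
        )

    k = MolecularKaryotype(sex_constitution=sex, calls=tuple(calls))
    if k.modal_count != modal:
        raise KaryotypeError(
            f"modal count {modal} in {text!r} does not match the constitutional "
            f"calls (expected {k.modal_count})"
        )
    return k


def format_karyotype(k: MolecularKaryotype) -> str:
    """Canonical string form; ``parse_karyotype(format_karyotype(k)) == k``.

    Abnormalities appear sorted by chromosome, constitutional before mosaic;
    mosaic fractions print with two decimals.
    """
    tokens = [str(k.modal_count), k.sex_constitution]
    for call in k.calls:  # already canonically ordered
        sign = "+" if call.deviation(k.sex_constitution) > 0 else "-"
        if call.is_mosaic:
            tokens.append(f"mos{sign}{call.chromosome}({call.mosaic_fraction:.2f})")
        elif call.segmental:
            tokens.append(f"seg{sign}{call.chromosome}")
        else:
            tokens.append(f"{sign}{call.chromosome}")
    return ",".join(tokens)


@dataclass(frozen=True)
class GameteProduct:
    """One of the eight gametes a trivalent can theoretically produce.

    ``deviation`` is the signed whole-chromosome dosage deviation from a
    balanced gamete for (chr_a, chr_b); ``carries_derivative`` records which
    pole received the fused derivative chromosome.  Alternate segregation
    sends both normal homologues to one pole and the derivative to the
    other, giving the two balanced products; adjacent sends the derivative
    plus one homologue together (four unbalanced products); 3:0 sends all
    three elements to one pole (two doubly unbalanced products).
    """

    translocation: RobTranslocation
    mode: str  # "alternate" | "adjacent" | "three_to_zero"
    deviation: tuple[int, int]
    carries_derivative: bool

    _MODES = ("alternate", "adjacent", "three_to_zero")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise KaryotypeError(f"unknown segregation mode {self.mode!r}")
        da, db = self.deviation
        ok = {
            "alternate": da == 0 and db == 0,
            "adjacent": (abs(da), abs(db)) in ((1, 0), (0, 1)),
            "three_to_zero": da == db and abs(da) == 1,
        }[self.mode]
        if not ok:
            raise KaryotypeError(
                f"deviation {self.deviation} inconsistent with mode {self.mode!r}"
            )


def enumerate_gamete_products(t: RobTranslocation) -> list[GameteProduct]:
    """All eight gamete products of the trivalent, 2/4/2 across
    alternate/adjacent/3:0.

    The two alternate products (normal and balanced-carrier gametes) share
    the (0, 0) dosage signature and differ only in whether the derivative is
    present — indistinguishable by copy number alone.
    """
    P = GameteProduct
    return [
        P(t, "alternate", (0, 0), carries_derivative=False),  # both normal homologues
        P(t, "alternate", (0, 0), carries_derivative=True),  # derivative only
        P(t, "adjacent", (+1, 0), carries_derivative=True),  # der + chrA
        P(t, "adjacent", (-1, 0), carries_derivative=False),  # chrB only
        P(t, "adjacent", (0, +1), carries_derivative=True),  # der + chrB
        P(t, "adjacent", (0, -1), carries_derivative=False),  # chrA only
        P(t, "three_to_zero", (+1, +1), carries_derivative=True),  # der + both
        P(t, "three_to_zero", (-1, -1), carries_derivative=False),  # empty pole
    ]
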