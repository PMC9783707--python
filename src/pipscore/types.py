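"""Core value types shared across the package.

Severity grades, evidence sources, categorical AUC-change bins, and the
metabolizer phenotype ladder used by drug-metabolizing enzyme genes.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass


class Severity(enum.IntEnum):
    """Ordered interaction severity: none < monitor < moderate < major < contraindicated.

    An interaction is *actionable* (i.e., expected to change clinical
    management — dose adjustment, alternative drug, or avoidance) when its
    severity is moderate or worse.
    """

    NONE = 0
    MONITOR = 1
    MODERATE = 2
    MAJOR = 3
    CONTRAINDICATED = 4

    @property
    def actionable(self) -> bool:
        return self >= Severity.MODERATE

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "Severity":
        try:
            return cls[str(label).strip().upper()]
        except KeyError:
            raise ValueError(f"unknown severity label: {label!r}") from None


class EvidenceSource(str, enum.Enum):
    """Evidence backing an interaction rule.

    Only FDA drug labelling and CPIC guideline levels A/B qualify a rule as
    evidence-based for the purposes of actionable-interaction counting.
    """

    FDA_LABEL = "FDA_label"
    CPIC_A = "CPIC_A"
    CPIC_B = "CPIC_B"
    OTHER = "other"

    @property
    def evidence_based(self) -> bool:
        return self is not EvidenceSource.OTHER

    @classmethod
    def from_label(cls, label: str) -> "EvidenceSource":
        for member in cls:
            if member.value.lower() == str(label).strip().lower():
                return member
        raise ValueError(f"unknown evidence source: {label!r}")


#: Ordinal bin labels for AUC decreases (reduced drug exposure), mildest first.
DECREASE_BINS = ("-0-30%", "-31-50%", "-51-80%", "-81-100%")
#: Ordinal bin labels for AUC increases (elevated drug exposure), mildest first.
INCREASE_BINS = ("0-25%", "26-75%", "76-200%", ">200%")

_DIRECTIONS = ("none", "decrease", "increase")


@dataclass(frozen=True)
class AUCCategory:
    """A categorical change in drug exposure (area under the plasma
    concentration-time curve).

    ``direction`` is ``"decrease"``, ``"increase"`` or ``"none"``; ``bin`` is
    the ordinal magnitude index within the direction (0 = mildest, 3 = most
    extreme).  Direction ``none`` has a single bin (0).
    """

    direction: str
    bin: int = 0

    def __post_init__(self) -> None:
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"unknown AUC direction: {self.direction!r}")
        if self.direction == "none":
            if self.bin != 0:
                raise ValueError("direction 'none' has exactly one bin (0)")
        elif not 0 <= self.bin <= 3:
            raise ValueError(f"AUC bin out of range: {self.bin}")

    @property
    def label(self) -> str:
        if self.direction == "none":
            return "none"
        bins = DECREASE_BINS if self.direction == "decrease" else INCREASE_BINS
        return bins[self.bin]

    @classmethod
    def from_label(cls, label: str) -> "AUCCategory":
        norm = _normalize_auc_label(label)
        if norm == "none":
            return cls("none", 0)
        for i, b in enumerate(DECREASE_BINS):
            if norm == b:
                return cls("decrease", i)
        for i, b in enumerate(INCREASE_BINS):
            if norm == b or norm == "+" + b:
                return cls("increase", i)
        raise ValueError(f"unrecognized AUC change label: {label!r}")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def _normalize_auc_label(label: str) -> str:
    # Published tables use unicode minus / en-dash interchangeably.
    s = str(label).strip()
    s = s.replace("−", "-").replace("–", "-").replace("—", "-")
    if s.startswith("+"):
        s = s[1:]
    return s


AUC_NONE = AUCCategory("none", 0)

#: Every representable AUC category (9 in total), useful for exhaustive checks.
ALL_AUC_CATEGORIES = tuple(
    [AUC_NONE]
    + [AUCCategory("decrease", i) for i in range(4)]
    + [AUCCategory("increase", i) for i in range(4)]
)

#: Ordered metabolizer phenotypes for drug-metabolizing enzymes, from
#: slowest to fastest clearance.
METABOLIZER_LADDER = ("poor", "intermediate", "normal", "rapid", "ultrarapid")

#: Two-state vocabulary for genes reported as carrier status rather than
#: metabolizer activity (e.g., HLA risk alleles).
CARRIER_VOCAB = ("non-carrier", "carrier")
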