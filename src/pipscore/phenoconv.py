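"""Phenoconversion model: combining categorical AUC changes and shifting
metabolizer phenotypes under co-medication.

Phenoconversion is the drug-induced mismatch between a patient's
genotype-predicted metabolizer phenotype and the phenotype they actually
express: an enzyme inhibitor can make a normal metabolizer behave like a
poor metabolizer, and an inducer can do the opposite.  This package models
exposure changes as ordinal categories (see :class:`~pipscore.types.AUCCategory`)
and combines them by ordinal escalation / de-escalation:

* two changes in the *same* direction push exposure one bin beyond the
  stronger of the two (saturating at the scale's extreme bin);
* changes in *opposite* directions pull the stronger change back one bin
  (saturating at the mildest bin of its direction);
* a "none" change is the identity.

When the two inputs sit in the same ordinal bin of opposite directions, the
decrease is treated as the stronger one: at equal bin index a decrease
corresponds to the larger fold-change in exposure (e.g., a 31-50% loss is a
1.4-2x fold-change, a 26-75% gain only 1.3-1.8x).  Interval arithmetic on
retention fractions was considered as an alternative combination rule, but
it cannot produce the escalations observed in curated interaction data
(e.g., a 51-80% decrease plus a 31-50% decrease landing in the 81-100%
bin), whereas ordinal escalation reproduces them; the interval rule is kept
as a reference oracle in the test-suite.
"""
from __future__ import annotations

from dataclasses import dataclass

from .types import AUCCategory, METABOLIZER_LADDER, Severity
from .kb import InteractionRule

MAX_BIN = 3


class UnsupportedPhenotypeError(ValueError):
    """Raised when a phenotype outside the metabolizer ladder is shifted."""


@dataclass(frozen=True)
class ModifierEffect:
    """Effect of a co-medication on substrates of ``gene``.

    ``auc_effect`` follows the parent-drug convention: enzyme inhibition is
    an exposure *increase*, induction a *decrease*.  For rules affecting a
    prodrug's active metabolite the knowledge base orients the sign before
    constructing the effect (see
    :meth:`pipscore.kb.KnowledgeBase.oriented_modifier_effect`).
    """

    gene: str
    auc_effect: AUCCategory

    def __post_init__(self) -> None:
        if self.auc_effect.direction == "none":
            raise ValueError("a stored modifier effect never has direction 'none'")

    @property
    def mechanism(self) -> str:
        """``"inhibitor"`` (exposure up) or ``"inducer"`` (exposure down)."""
        return "inhibitor" if self.auc_effect.direction == "increase" else "inducer"


def _strength_key(cat: AUCCategory) -> tuple[int, int]:
    # Higher bin wins; at equal bin the decrease direction is the larger
    # fold-change, hence stronger.
    return (cat.bin, 1 if cat.direction == "decrease" else 0)


def combine_auc(a: AUCCategory, b: AUCCategory) -> AUCCategory:
    """Combine two categorical AUC changes acting on the same drug.

    Commutative, with direction ``none`` as the identity element.
    """
    if a.direction == "none":
        return b
    if b.direction == "none":
        return a
    strong, weak = (a, b) if _strength_key(a) >= _strength_key(b) else (b, a)
    if a.direction == b.direction:
        return AUCCategory(strong.direction, min(strong.bin + 1, MAX_BIN))
    return AUCCategory(strong.direction, max(strong.bin - 1, 0))


def effective_phenotype(genetic: str, modifiers: list[ModifierEffect] | tuple) -> str:
    """Phenotype a patient is expected to *express* once co-medication is
    taken into account.

    Each inhibitor shifts the metabolizer phenotype one step toward poor,
    each inducer one step toward ultrarapid; shifts saturate at the ladder
    ends.  Modifier strength is deliberately a single step regardless of the
    magnitude bin: no published strength ladder exists, and one-step
    shifting is the minimal model consistent with the curated combination
    data.
    """
    if genetic not in METABOLIZER_LADDER:
        raise UnsupportedPhenotypeError(
            f"phenotype {genetic!r} is not on the metabolizer ladder; "
            "phenoconversion applies to drug-metabolizing enzymes only"
        )
    genes = {m.gene for m in modifiers}
    if len(genes) > 1:
        raise ValueError(f"modifiers target multiple genes: {sorted(genes)}")
    idx = METABOLIZER_LADDER.index(genetic)
    for mod in modifiers:
        if mod.mechanism == "inhibitor":
            idx = max(idx - 1, 0)
        else:
            idx = min(idx + 1, len(METABOLIZER_LADDER) - 1)
    return METABOLIZER_LADDER[idx]


def interaction_severity(rule: InteractionRule, combined_auc: AUCCategory) -> Severity:
    """Severity of a rule once phenoconversion is accounted for.

    The base severity escalates one level when the combined AUC change is
    one bin more extreme than the rule's own AUC change, and two levels
    (capped at contraindicated) when two or more bins more extreme; it is
    never reduced below the rule's stated severity.  Extremeness is only
    comparable within a direction: a combined change in the opposite
    direction (or ``none``) leaves the severity unchanged.
    """
    if (
        combined_auc.direction == "none"
        or combined_auc.direction != rule.auc_change.direction
    ):
        delta = 0
    else:
        delta = combined_auc.bin - rule.auc_change.bin
    escalation = min(max(delta, 0), 2)
    return Severity(min(int(rule.severity) + escalation, int(Severity.CONTRAINDICATED)))
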