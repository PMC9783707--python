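"""Interaction detection for genotyped patients, and the cohort-level
tabulations built on it.

Where the engine computes the *probability* of finding an actionable
interaction before testing, the detector answers the post-test question:
given a patient's interpreted phenotypes, which interactions are actually
present, of what kind (DGI, DDGI, DGGI, plus gene-free DDI/DDDI), and how
severe once phenoconversion is applied.  Detection is restricted to the
genes the patient was actually tested for, mirroring the adjusted-PIP
restriction.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from ._util import round_half_up
from .kb import CLINICAL_AREAS, KnowledgeBase, PhenotypePrevalence
from .phenoconv import combine_auc, interaction_severity
from .types import AUCCategory, AUC_NONE, Severity

#: Tie-break precedence among interaction kinds at equal severity:
#: gene-involving kinds first, more entities first.
KIND_PRECEDENCE = {"DGGI": 4, "DDGI": 3, "DGI": 2, "DDDI": 1, "DDI": 0}


@dataclass
class PatientRecord:
    """One patient: medications, tested-gene panel, interpreted phenotypes
    for the tested genes, and optional demographic annotations (never used
    in scoring)."""

    patient_id: str
    meds: list[str]
    tested_genes: frozenset[str] = frozenset()
    phenotypes: dict[str, str] = field(default_factory=dict)
    age: Optional[float] = None
    sex: Optional[str] = None
    race: Optional[str] = None

    def __post_init__(self) -> None:
        self.meds = [m.strip().lower() for m in self.meds if m.strip()]
        if not self.meds:
            raise ValueError("a patient record requires at least one medication")
        self.tested_genes = frozenset(self.tested_genes)
        extra = set(self.phenotypes) - self.tested_genes
        if extra:
            raise ValueError(
                f"phenotypes reported for untested genes: {sorted(extra)}"
            )


@dataclass(frozen=True)
class DetectedInteraction:
    """A concrete interaction found for a patient."""

    kind: str  # DGI | DDGI | DGGI | DDI | DDDI
    drugs: tuple[str, ...]
    genes: tuple[tuple[str, str], ...]  # (gene, phenotype) pairs
    severity: Severity
    combined_auc: AUCCategory
    clinical_area: str

    def __post_init__(self) -> None:
        expected = {"DGI": (1, 1), "DDGI": (2, 1), "DGGI": (1, 2),
                    "DDI": (2, 0), "DDDI": (3, 0)}
        n_drugs, n_genes = expected[self.kind]
        if len(self.drugs) != n_drugs or len(self.genes) != n_genes:
            raise ValueError(
                f"{self.kind} requires {n_drugs} drug(s) and {n_genes} gene(s)"
            )


def detect_interactions(
    patient: PatientRecord, kb: KnowledgeBase, strict: bool = False
) -> list[DetectedInteraction]:
    """Every interaction matched for the patient, with post-phenoconversion
    severity and combined AUC change, in deterministic order (severity
    descending, then drug names).

    A phenoconversion (DDGI) entry is emitted only when its severity
    exceeds that of the corresponding gene-free drug-drug interaction; the
    DDI itself is reported separately, so nothing already known without
    genetics is lost.
    """
    from .engine import _normalize_meds  # shared drug-name handling

    names = _normalize_meds(patient.meds, kb, strict)
    phenos = {
        g: ph for g, ph in patient.phenotypes.items() if g in patient.tested_genes
    }
    found: list[DetectedInteraction] = []
    for drug in names:
        area = kb.drugs[drug].clinical_area
        for rule in kb.rules_for_drug(drug):
            if phenos.get(rule.gene) != rule.phenotype:
                continue
            if rule.second_gene is not None:
                if phenos.get(rule.second_gene) != rule.second_phenotype:
                    continue
                found.append(
                    DetectedInteraction(
                        kind="DGGI",
                        drugs=(drug,),
                        genes=(
                            (rule.gene, rule.phenotype),
                            (rule.second_gene, rule.second_phenotype),
                        ),
                        severity=rule.severity,
                        combined_auc=rule.auc_change,
                        clinical_area=area,
                    )
                )
                continue
            found.append(
                DetectedInteraction(
                    kind="DGI",
                    drugs=(drug,),
                    genes=((rule.gene, rule.phenotype),),
                    severity=rule.severity,
                    combined_auc=rule.auc_change,
                    clinical_area=area,
                )
            )
            for other in names:
                if other == drug:
                    continue
                eff = kb.oriented_modifier_effect(other, rule.gene, rule.moiety)
                if eff is None:
                    continue
                combined = combine_auc(rule.auc_change, eff)
                sev = interaction_severity(rule, combined)
                ddi = kb.ddi_severity((drug, other))
                if ddi is not None and sev <= ddi:
                    continue
                found.append(
                    DetectedInteraction(
                        kind="DDGI",
                        drugs=(drug, other),
                        genes=((rule.gene, rule.phenotype),),
                        severity=sev,
                        combined_auc=combined,
                        clinical_area=area,
                    )
                )
    med_set = set(names)
    for ddi in kb.ddi_rules:
        if set(ddi.drugs) <= med_set:
            found.append(
                DetectedInteraction(
                    kind=ddi.kind,
                    drugs=ddi.drugs,
                    genes=(),
                    severity=ddi.severity,
                    combined_auc=AUC_NONE,
                    clinical_area=kb.drugs[ddi.drugs[0]].clinical_area,
                )
            )
    found.sort(
        key=lambda it: (
            -int(it.severity),
            it.drugs,
            -KIND_PRECEDENCE[it.kind],
            it.genes,
        )
    )
    return found


def has_eadgi(patient: PatientRecord, kb: KnowledgeBase, strict: bool = False) -> bool:
    """True iff the patient has at least one evidence-based actionable
    drug-gene interaction: a detected interaction involving one or more
    genes with severity moderate or worse."""
    return any(
        it.genes and it.severity.actionable
        for it in detect_interactions(patient, kb, strict=strict)
    )


def highest_severity_class(
    interactions: Sequence[DetectedInteraction],
) -> tuple[str, Severity]:
    """The class of the single most severe interaction, used when a patient
    with several interactions contributes once to a frequency analysis.

    Ties at equal severity are broken by kind precedence (DGGI > DDGI > DGI
    > DDDI > DDI), then by lexical drug order.  An empty list maps to
    ``("none", Severity.NONE)``.
    """
    if not interactions:
        return ("none", Severity.NONE)
    best = min(
        interactions,
        key=lambda it: (-int(it.severity), -KIND_PRECEDENCE[it.kind], it.drugs),
    )
    return (best.kind, best.severity)


def tabulate_by_area(
    interactions: Iterable[DetectedInteraction],
) -> pd.DataFrame:
    """Counts and percentages of actionable gene interactions by the
    affected drug's clinical area.

    Columns: moderate, major-or-contraindicated, and all actionable;
    percentages are relative to column totals, rounded half-up to one
    decimal.  Gene-free interactions (DDI/DDDI) and sub-actionable entries
    are ignored.
    """
    counts = {
        area: {"moderate": 0, "major_or_contraindicated": 0}
        for area in CLINICAL_AREAS
    }
    for it in interactions:
        if not it.genes or not it.severity.actionable:
            continue
        col = (
            "moderate"
            if it.severity == Severity.MODERATE
            else "major_or_contraindicated"
        )
        counts[it.clinical_area][col] += 1
    df = pd.DataFrame.from_dict(counts, orient="index")
    df.index.name = "clinical_area"
    df["all"] = df["moderate"] + df["major_or_contraindicated"]
    for col in ("moderate", "major_or_contraindicated", "all"):
        total = df[col].sum()
        df[f"{col}_pct"] = [
            round_half_up(100.0 * c / total, 1) if total else 0.0 for c in df[col]
        ]
    return df


def top_medications(
    interactions: Iterable[DetectedInteraction],
    kb: KnowledgeBase,
    prev: PhenotypePrevalence,
    ranking: Optional[Mapping[str, object]] = None,
    top: Optional[int] = 5,
) -> pd.DataFrame:
    """Rank affected medications by actionable gene-interaction count.

    For each drug: the count, its proportion of all counted interactions,
    the medication-level PIP (single-drug score from the engine), the
    number needed to test (1 / PIP), and an optional prescribing-frequency
    rank supplied by the caller as a plain mapping (no download performed).
    """
    from .engine import compute_pip

    tallies: dict[str, int] = {}
    for it in interactions:
        if not it.genes or not it.severity.actionable:
            continue
        tallies[it.drugs[0]] = tallies.get(it.drugs[0], 0) + 1
    total = sum(tallies.values())
    rows = []
    for drug, count in sorted(tallies.items(), key=lambda kv: (-kv[1], kv[0])):
        pip = compute_pip([drug], kb, prev).pip
        rows.append(
            {
                "drug": drug,
                "clinical_area": kb.drugs[drug].clinical_area,
                "count": count,
                "proportion_pct": round_half_up(100.0 * count / total, 1),
                "medication_pip_pct": round_half_up(100.0 * pip, 1),
                "nnt": round_half_up(1.0 / pip, 1) if pip > 0 else None,
                "rank": None if ranking is None else ranking.get(drug),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "drug", "clinical_area", "count", "proportion_pct",
            "medication_pip_pct", "nnt", "rank",
        ],
    )
    return df.head(top) if top is not None else df
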