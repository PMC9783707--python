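"""Drug-gene interaction knowledge base: data model, file format, and the
bundled demonstration knowledge base.

The production knowledge bases behind commercial pharmacogenomic decision
support are proprietary.  This module therefore defines an open, versioned
JSON schema (``pip-kb/1``) holding four sections:

``genes``
    gene symbol -> ordered phenotype vocabulary.  Drug-metabolizing CYP
    enzymes use the metabolizer ladder (poor .. ultrarapid); other genes use
    free-form vocabularies such as carrier / non-carrier.
``drugs``
    drug name -> clinical area plus any modifier effects the drug exerts on
    substrates of a gene (enzyme inhibition is stored as an AUC *increase*
    on parent-drug substrates; induction as a *decrease*; the sign is
    flipped when applied to a rule whose affected moiety is an active
    metabolite of a prodrug).
``rules``
    drug-gene-phenotype interaction rules with severity, categorical AUC
    change, and evidence source; rules may name a second gene (intrinsic
    two-gene interactions).
``ddi_rules``
    gene-free drug-drug and drug-drug-drug interactions (severity only).
``prevalence``
    optional embedded per-gene phenotype frequency table.

Frequencies may alternatively live in a sibling TSV (columns: gene,
phenotype, frequency); see :func:`load_prevalence_tsv`.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .types import (
    AUCCategory,
    CARRIER_VOCAB,
    EvidenceSource,
    METABOLIZER_LADDER,
    Severity,
)

SCHEMA_VERSION = "pip-kb/1"

#: The thirteen clinical areas used to classify the primary indication of
#: each drug.
CLINICAL_AREAS = (
    "behavioral health",
    "cardiology",
    "pain management",
    "hematology and oncology",
    "infectious disease",
    "gastroenterology",
    "urology",
    "transplant",
    "reproductive and sexual health",
    "neurology",
    "rheumatology",
    "endocrinology",
    "miscellaneous",
)

MOIETIES = ("parent", "metabolite")


class KBError(Exception):
    """Base class for knowledge-base errors."""


class KBParseError(KBError):
    """Raised when a knowledge-base file is structurally malformed."""


class KBValidationError(KBError):
    """Raised when a knowledge base violates referential invariants.

    Carries the complete list of diagnostics in ``diagnostics``.
    """

    def __init__(self, diagnostics: Sequence[str]):
        self.diagnostics = list(diagnostics)
        super().__init__("; ".join(self.diagnostics))


class PhenotypePrevalence:
    """Per-gene probability distribution over interpreted phenotypes.

    Frequencies for each gene must be non-negative and sum to 1 (within
    1e-9).  Population prevalences of this kind are what turn a medication
    list into a probability of finding an actionable interaction.
    """

    def __init__(self, table: Mapping[str, Mapping[str, float]]):
        self._table: dict[str, dict[str, float]] = {
            gene: {ph: float(f) for ph, f in dist.items()}
            for gene, dist in table.items()
        }
        for gene, dist in self._table.items():
            if any(f < 0 for f in dist.values()):
                raise ValueError(f"negative phenotype frequency for gene {gene}")
            total = sum(dist.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(
                    f"phenotype frequencies for gene {gene} sum to {total!r}, not 1"
                )

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self._table)

    def distribution(self, gene: str) -> dict[str, float]:
        try:
            return dict(self._table[gene])
        except KeyError:
            raise KeyError(f"no phenotype prevalence for gene {gene!r}") from None

    def frequency(self, gene: str, phenotype: str) -> float:
        return self.distribution(gene).get(phenotype, 0.0)

    def items(self):
        return self._table.items()

    def to_dict(self) -> dict[str, dict[str, float]]:
        return {g: dict(d) for g, d in sorted(self._table.items())}

    def __eq__(self, other) -> bool:
        return isinstance(other, PhenotypePrevalence) and self._table == other._table

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhenotypePrevalence({len(self._table)} genes)"


@dataclass(frozen=True)
class Drug:
    """A medication entry: name, primary clinical area, and the modifier
    (inhibitor/inducer) effects it exerts on substrates of other genes."""

    name: str
    clinical_area: str
    modifier_effects: Mapping[str, AUCCategory] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", self.name.strip().lower())
        object.__setattr__(
            self, "modifier_effects", dict(self.modifier_effects)
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Drug)
            and self.name == other.name
            and self.clinical_area == other.clinical_area
            and dict(self.modifier_effects) == dict(other.modifier_effects)
        )

    def __hash__(self) -> int:
        return hash((self.name, self.clinical_area))


@dataclass(frozen=True)
class InteractionRule:
    """A drug-gene(-gene) interaction rule.

    ``moiety`` states which species the ``auc_change`` refers to: the parent
    drug or, for prodrugs, the active metabolite.  For metabolite rules an
    enzyme inhibitor lowers active-metabolite exposure, so modifier signs
    are flipped when applied (see :meth:`KnowledgeBase.oriented_modifier_effect`).
    """

    drug: str
    gene: str
    phenotype: str
    severity: Severity
    auc_change: AUCCategory
    evidence: EvidenceSource
    moiety: str = "parent"
    second_gene: Optional[str] = None
    second_phenotype: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "drug", self.drug.strip().lower())
        if self.moiety not in MOIETIES:
            raise ValueError(f"unknown moiety: {self.moiety!r}")
        if (self.second_gene is None) != (self.second_phenotype is None):
            raise ValueError(
                "second_gene and second_phenotype must be given together"
            )

    @property
    def is_two_gene(self) -> bool:
        return self.second_gene is not None

    @property
    def key(self):
        return (
            self.drug,
            self.gene,
            self.phenotype,
            self.second_gene or "",
            self.second_phenotype or "",
        )


@dataclass(frozen=True)
class DDIRule:
    """A gene-free drug-drug (2 drugs) or drug-drug-drug (3 drugs)
    interaction, kept so that gene information can be required to *exceed*
    the severity already known without genetics."""

    drugs: tuple[str, ...]
    severity: Severity

    def __post_init__(self) -> None:
        drugs = tuple(sorted(d.strip().lower() for d in self.drugs))
        object.__setattr__(self, "drugs", drugs)
        if len(drugs) not in (2, 3):
            raise ValueError("a DDI rule involves 2 or 3 drugs")
        if len(set(drugs)) != len(drugs):
            raise ValueError("DDI rule drugs must be distinct")

    @property
    def kind(self) -> str:
        return "DDI" if len(self.drugs) == 2 else "DDDI"


@dataclass
class KnowledgeBase:
    """Validated collection of genes, drugs, and interaction rules, with an
    optionally embedded phenotype-prevalence table."""

    genes: dict[str, tuple[str, ...]]
    drugs: dict[str, Drug]
    rules: tuple[InteractionRule, ...]
    ddi_rules: tuple[DDIRule, ...] = ()
    prevalence: Optional[PhenotypePrevalence] = None

    def __post_init__(self) -> None:
        self.drugs = {d.name: d for d in self.drugs.values()}
        self.rules = tuple(sorted(self.rules, key=lambda r: r.key))
        self.ddi_rules = tuple(sorted(self.ddi_rules, key=lambda r: r.drugs))
        self._rules_by_drug: dict[str, tuple[InteractionRule, ...]] = {}
        for rule in self.rules:
            self._rules_by_drug.setdefault(rule.drug, ())
        for rule in self.rules:
            self._rules_by_drug[rule.drug] = self._rules_by_drug[rule.drug] + (rule,)
        self._ddi_severity: dict[tuple[str, ...], Severity] = {
            r.drugs: r.severity for r in self.ddi_rules
        }

    # -- lookups -----------------------------------------------------------
    def has_drug(self, name: str) -> bool:
        return name.strip().lower() in self.drugs

    def rules_for_drug(self, name: str) -> tuple[InteractionRule, ...]:
        return self._rules_by_drug.get(name.strip().lower(), ())

    def substrate_genes(self, name: str) -> frozenset[str]:
        genes: set[str] = set()
        for rule in self.rules_for_drug(name):
            genes.add(rule.gene)
            if rule.second_gene:
                genes.add(rule.second_gene)
        return frozenset(genes)

    def modifier_effect(self, drug: str, gene: str) -> Optional[AUCCategory]:
        d = self.drugs.get(drug.strip().lower())
        if d is None:
            return None
        return d.modifier_effects.get(gene)

    def oriented_modifier_effect(
        self, drug: str, gene: str, moiety: str = "parent"
    ) -> Optional[AUCCategory]:
        """Modifier effect of ``drug`` on ``gene`` substrates, oriented for
        the affected moiety.

        Stored effects use the parent-drug convention (inhibition raises
        exposure).  For a rule whose affected moiety is the active
        metabolite of a prodrug, inhibiting the activating enzyme *lowers*
        active-metabolite exposure, so the direction is flipped here, in the
        data layer, keeping the combination algebra sign-free.
        """
        eff = self.modifier_effect(drug, gene)
        if eff is None or eff.direction == "none":
            return eff
        if moiety == "metabolite":
            flipped = "decrease" if eff.direction == "increase" else "increase"
            return AUCCategory(flipped, eff.bin)
        return eff

    def ddi_severity(self, drugs: Iterable[str]) -> Optional[Severity]:
        key = tuple(sorted(d.strip().lower() for d in drugs))
        return self._ddi_severity.get(key)

    # -- validation --------------------------------------------------------
    def validate(self) -> list[str]:
        """Return a list of diagnostics; empty means the KB is valid."""
        diags: list[str] = []
        for gene, vocab in self.genes.items():
            if len(set(vocab)) != len(vocab):
                diags.append(f"gene {gene}: duplicate phenotype labels")
            if gene.upper().startswith("CYP"):
                missing = [p for p in METABOLIZER_LADDER if p not in vocab]
                if missing:
                    diags.append(
                        f"gene {gene}: CYP gene vocabulary missing metabolizer "
                        f"phenotypes {missing}"
                    )
        for name, drug in self.drugs.items():
            if drug.clinical_area not in CLINICAL_AREAS:
                diags.append(
                    f"drug {name}: unknown clinical area {drug.clinical_area!r}"
                )
            for gene, eff in drug.modifier_effects.items():
                if gene not in self.genes:
                    diags.append(
                        f"drug {name}: modifier effect references unknown gene {gene}"
                    )
                elif eff.direction == "none":
                    diags.append(
                        f"drug {name}: modifier effect on {gene} has direction 'none'"
                    )
        seen: set[tuple] = set()
        for rule in self.rules:
            ident = f"rule {rule.drug}/{rule.gene}/{rule.phenotype}"
            if rule.drug not in self.drugs:
                diags.append(f"{ident}: unknown drug {rule.drug}")
            for gene, phen in (
                (rule.gene, rule.phenotype),
                (rule.second_gene, rule.second_phenotype),
            ):
                if gene is None:
                    continue
                if gene not in self.genes:
                    diags.append(f"{ident}: unknown gene {gene}")
                elif phen not in self.genes[gene]:
                    diags.append(
                        f"{ident}: phenotype {phen!r} not in vocabulary of {gene}"
                    )
            if rule.key in seen:
                diags.append(f"{ident}: duplicate rule key")
            seen.add(rule.key)
        for ddi in self.ddi_rules:
            for d in ddi.drugs:
                if d not in self.drugs:
                    diags.append(f"ddi rule {ddi.drugs}: unknown drug {d}")
        if self.prevalence is not None:
            for gene in self.prevalence.genes:
                if gene not in self.genes:
                    diags.append(f"prevalence: unknown gene {gene}")
                else:
                    extra = set(self.prevalence.distribution(gene)) - set(
                        self.genes[gene]
                    )
                    if extra:
                        diags.append(
                            f"prevalence for {gene}: phenotypes {sorted(extra)} "
                            "not in gene vocabulary"
                        )
        return diags

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, KnowledgeBase)
            and self.genes == other.genes
            and self.drugs == other.drugs
            and self.rules == other.rules
            and self.ddi_rules == other.ddi_rules
            and self.prevalence == other.prevalence
        )


# ---------------------------------------------------------------------------
# serialization


def _rule_to_json(rule: InteractionRule) -> dict:
    out = {
        "drug": rule.drug,
        "gene": rule.gene,
        "phenotype": rule.phenotype,
        "severity": rule.severity.label,
        "auc_change": rule.auc_change.label,
        "evidence": rule.evidence.value,
        "moiety": rule.moiety,
    }
    if rule.second_gene is not None:
        out["second_gene"] = rule.second_gene
        out["second_phenotype"] = rule.second_phenotype
    return out


def _rule_from_json(obj: dict, where: str) -> InteractionRule:
    try:
        return InteractionRule(
            drug=obj["drug"],
            gene=obj["gene"],
            phenotype=obj["phenotype"],
            severity=Severity.from_label(obj["severity"]),
            auc_change=AUCCategory.from_label(obj["auc_change"]),
            evidence=EvidenceSource.from_label(obj["evidence"]),
            moiety=obj.get("moiety", "parent"),
            second_gene=obj.get("second_gene"),
            second_phenotype=obj.get("second_phenotype"),
        )
    except (KeyError, ValueError) as exc:
        raise KBParseError(f"{where}: {exc}") from exc


def kb_to_json(kb: KnowledgeBase) -> dict:
    doc: dict = {
        "schema": SCHEMA_VERSION,
        "genes": {g: list(v) for g, v in sorted(kb.genes.items())},
        "drugs": {
            name: {
                "clinical_area": d.clinical_area,
                "modifier_effects": {
                    g: eff.label for g, eff in sorted(d.modifier_effects.items())
                },
            }
            for name, d in sorted(kb.drugs.items())
        },
        "rules": [_rule_to_json(r) for r in kb.rules],
        "ddi_rules": [
            {"drugs": list(r.drugs), "severity": r.severity.label}
            for r in kb.ddi_rules
        ],
    }
    if kb.prevalence is not None:
        doc["prevalence"] = kb.prevalence.to_dict()
    return doc


def kb_from_json(doc: dict, where: str = "<json>") -> KnowledgeBase:
    if not isinstance(doc, dict):
        raise KBParseError(f"{where}: top level must be an object")
    schema = doc.get("schema")
    if schema != SCHEMA_VERSION:
        raise KBParseError(
            f"{where}: unsupported schema {schema!r} (expected {SCHEMA_VERSION!r})"
        )
    try:
        genes = {g: tuple(v) for g, v in doc.get("genes", {}).items()}
        drugs = {}
        for name, spec in doc.get("drugs", {}).items():
            effects = {
                g: AUCCategory.from_label(lbl)
                for g, lbl in spec.get("modifier_effects", {}).items()
            }
            drugs[name.lower()] = Drug(
                name=name,
                clinical_area=spec["clinical_area"],
                modifier_effects=effects,
            )
    except (KeyError, TypeError, AttributeError, ValueError) as exc:
        raise KBParseError(f"{where}: malformed genes/drugs section: {exc}") from exc
    rules = tuple(
        _rule_from_json(obj, f"{where}: rules[{i}]")
        for i, obj in enumerate(doc.get("rules", []))
    )
    try:
        ddi_rules = tuple(
            DDIRule(tuple(obj["drugs"]), Severity.from_label(obj["severity"]))
            for obj in doc.get("ddi_rules", [])
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise KBParseError(f"{where}: malformed ddi_rules section: {exc}") from exc
    prevalence = None
    if "prevalence" in doc:
        try:
            prevalence = PhenotypePrevalence(doc["prevalence"])
        except (TypeError, AttributeError, ValueError) as exc:
            raise KBParseError(f"{where}: malformed prevalence section: {exc}") from exc
    kb = KnowledgeBase(
        genes=genes, drugs=drugs, rules=rules, ddi_rules=ddi_rules,
        prevalence=prevalence,
    )
    diags = kb.validate()
    if diags:
        raise KBValidationError(diags)
    return kb


def load_kb(path) -> KnowledgeBase:
    """Load and validate a ``pip-kb/1`` JSON knowledge base."""
    path = Path(path)
    try:
        with path.open("r", encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise KBParseError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}")
    return kb_from_json(doc, where=str(path))


def save_kb(kb: KnowledgeBase, path) -> None:
    """Write a knowledge base in canonical form (sorted sections and rules);
    two saves of the same KB are byte-identical."""
    path = Path(path)
    text = json.dumps(kb_to_json(kb), indent=2, sort_keys=True, ensure_ascii=False)
    path.write_text(text + "\n", encoding="utf-8")


def kb_checksum(kb: KnowledgeBase) -> str:
    """SHA-256 of the canonical serialization."""
    import hashlib

    text = json.dumps(kb_to_json(kb), indent=2, sort_keys=True, ensure_ascii=False)
    return hashlib.sha256(text.encode("utf-8")).hexdigest()


def load_prevalence_tsv(path) -> PhenotypePrevalence:
    """Read a prevalence table from TSV (columns: gene, phenotype, frequency)."""
    import csv

    table: dict[str, dict[str, float]] = {}
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"gene", "phenotype", "frequency"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise KBParseError(
                f"{path}: prevalence TSV must have columns gene, phenotype, frequency"
            )
        for i, row in enumerate(reader, start=2):
            try:
                table.setdefault(row["gene"], {})[row["phenotype"]] = float(
                    row["frequency"]
                )
            except (TypeError, ValueError) as exc:
                raise KBParseError(f"{path}: line {i}: {exc}") from exc
    return PhenotypePrevalence(table)


def save_prevalence_tsv(prev: PhenotypePrevalence, path) -> None:
    lines = ["gene\tphenotype\tfrequency"]
    for gene, dist in sorted(prev.items()):
        for ph, f in sorted(dist.items()):
            lines.append(f"{gene}\t{ph}\t{f!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# demonstration knowledge base

#: Gene panels offered historically: a 3-gene base, plus nested 5/14/25-gene
#: extensions.
PANEL_GENES: dict[int, tuple[str, ...]] = {
    3: ("CYP2C19", "CYP2C9", "CYP2D6"),
    5: ("CYP2C19", "CYP2C9", "CYP2D6", "CYP3A4", "CYP3A5"),
    14: (
        "CYP2C19", "CYP2C9", "CYP2D6", "CYP3A4", "CYP3A5",
        "CYP2B6", "CYP4F2", "SLCO1B1", "TPMT", "DPYD",
        "HLA-B*57:01", "IFNL3", "UGT1A1", "VKORC1",
    ),
    25: (
        "CYP2C19", "CYP2C9", "CYP2D6", "CYP3A4", "CYP3A5",
        "CYP2B6", "CYP4F2", "SLCO1B1", "TPMT", "DPYD",
        "HLA-B*57:01", "IFNL3", "UGT1A1", "VKORC1",
        "ADRA2A", "COMT", "CYP1A2", "F2", "F5", "GRIK4",
        "HTR2A", "HTR2C", "MTHFR", "NAT2", "OPRM1",
    ),
}


def _cyp(poor, intermediate, normal, rapid=0.0, ultrarapid=0.0):
    return {
        "poor": poor,
        "intermediate": intermediate,
        "normal": normal,
        "rapid": rapid,
        "ultrarapid": ultrarapid,
    }


def _carrier(freq):
    return {"carrier": freq, "non-carrier": round(1.0 - freq, 12)}


def demo_kb() -> tuple[KnowledgeBase, PhenotypePrevalence]:
    """Build the bundled demonstration knowledge base and its prevalence
    table.

    The demo KB is calibrated so that the single-medication interaction
    probabilities of eight common drugs (metoprolol 48%, amitriptyline 50%,
    codeine and tramadol 9%, omeprazole / pantoprazole / clopidogrel 29%,
    es(citalopram) 32%) equal their published medication-level scores, and
    so that the ten most common published drug-drug-gene phenoconversion
    combinations are reproduced by the AUC algebra.  Because no per-phenotype
    breakdown of those scores is public, the assignment of actionable
    phenotype mass to specific phenotypes, and the nesting of co-substrate
    actionable sets (smaller set contained in the larger), are documented
    conventions of this package, not published fact.
    """
    inc = lambda b: AUCCategory("increase", b)  # noqa: E731
    dec = lambda b: AUCCategory("decrease", b)  # noqa: E731

    genes: dict[str, tuple[str, ...]] = {}
    for g in PANEL_GENES[25]:
        if g.upper().startswith("CYP"):
            genes[g] = METABOLIZER_LADDER
        elif g == "SLCO1B1":
            genes[g] = ("normal-function", "decreased-function", "poor-function")
        else:
            genes[g] = CARRIER_VOCAB

    prevalence = PhenotypePrevalence(
        {
            # Calibrated: actionable sets below pick out the printed masses.
            "CYP2D6": _cyp(0.06, 0.39, 0.50, 0.02, 0.03),
            "CYP2C19": _cyp(0.02, 0.27, 0.41, 0.27, 0.03),
            # Plausible North-American-like distributions; no demo rules.
            "CYP2C9": _cyp(0.03, 0.32, 0.65),
            "CYP3A4": _cyp(0.01, 0.25, 0.74),
            "CYP3A5": _cyp(0.80, 0.10, 0.10),
            "CYP2B6": _cyp(0.06, 0.24, 0.70),
            "CYP1A2": _cyp(0.01, 0.09, 0.55, 0.30, 0.05),
            "CYP4F2": _cyp(0.02, 0.28, 0.70),
            "SLCO1B1": {
                "normal-function": 0.73,
                "decreased-function": 0.25,
                "poor-function": 0.02,
            },
            "HLA-B*57:01": _carrier(0.06),
            "TPMT": _carrier(0.10),
            "DPYD": _carrier(0.05),
            "UGT1A1": _carrier(0.30),
            "VKORC1": _carrier(0.35),
            "IFNL3": _carrier(0.45),
            "ADRA2A": _carrier(0.40),
            "COMT": _carrier(0.45),
            "F2": _carrier(0.02),
            "F5": _carrier(0.05),
            "GRIK4": _carrier(0.30),
            "HTR2A": _carrier(0.40),
            "HTR2C": _carrier(0.20),
            "MTHFR": _carrier(0.40),
            "NAT2": _carrier(0.50),
            "OPRM1": _carrier(0.25),
        }
    )

    def drug(name, area, **effects):
        return Drug(
            name=name,
            clinical_area=area,
            modifier_effects={g: e for g, e in effects.items()},
        )

    drug_list = [
        # Substrates with calibrated interaction rules.
        drug("metoprolol", "cardiology"),
        drug("clopidogrel", "cardiology"),
        drug("simvastatin", "cardiology"),
        drug("amitriptyline", "behavioral health"),
        drug("citalopram", "behavioral health"),
        drug("escitalopram", "behavioral health"),
        drug("omeprazole", "gastroenterology"),
        drug("pantoprazole", "gastroenterology"),
        # Esomeprazole is both a substrate and a CYP2C19 inhibitor.
        drug("esomeprazole", "gastroenterology", CYP2C19=inc(1)),
        # Tramadol/codeine are CYP2D6 prodrugs; tramadol additionally
        # competes at CYP2C19, lowering clopidogrel activation.
        drug("tramadol", "pain management", CYP2C19=inc(1)),
        drug("codeine", "pain management"),
        drug("abacavir", "infectious disease"),
        # Modifier-only entries (enzyme inhibitors; stored parent convention).
        drug("bupropion", "behavioral health", CYP2D6=inc(1)),
        drug("fluvoxamine", "behavioral health", CYP2C19=inc(1)),
        drug("dronedarone", "cardiology", CYP2D6=inc(1)),
        drug("oxycodone", "pain management", CYP2C19=inc(1)),
        drug("morphine", "pain management", CYP2C19=inc(1)),
        drug("hydrocodone", "pain management", CYP2C19=inc(1)),
        # Enzyme inducer, for phenoconversion in the inducing direction.
        drug("rifampin", "infectious disease", CYP2C19=dec(1)),
    ]
    # Medications without high-evidence pharmacogenomic impact (including
    # vitamins/supplements), so that simulated regimens resemble real
    # polypharmacy.
    inert = {
        "cardiology": [
            "lisinopril", "amlodipine", "losartan", "furosemide", "aspirin",
            "atorvastatin", "hydrochlorothiazide", "carvedilol", "diltiazem",
            "spironolactone",
        ],
        "behavioral health": [
            "sertraline", "trazodone", "mirtazapine", "buspirone", "lorazepam",
            "quetiapine",
        ],
        "pain management": [
            "acetaminophen", "ibuprofen", "naproxen", "gabapentin", "lidocaine",
        ],
        "gastroenterology": ["famotidine", "ondansetron", "docusate"],
        "endocrinology": ["levothyroxine", "metformin", "insulin-glargine",
                          "glipizide"],
        "neurology": ["levetiracetam", "topiramate", "sumatriptan"],
        "urology": ["tamsulosin", "oxybutynin"],
        "rheumatology": ["celecoxib", "methotrexate"],
        "infectious disease": ["amoxicillin", "azithromycin", "doxycycline"],
        "hematology and oncology": ["anastrozole", "hydroxyurea"],
        "transplant": ["mycophenolate"],
        "reproductive and sexual health": ["sildenafil", "estradiol"],
        "miscellaneous": [
            "multivitamin", "vitamin-d", "fish-oil", "calcium", "melatonin",
            "loratadine", "montelukast",
        ],
    }
    for area, names in inert.items():
        for name in names:
            drug_list.append(drug(name, area))

    R = InteractionRule
    S = Severity
    E = EvidenceSource
    rules: list[InteractionRule] = [
        # -- CYP2D6 substrates ------------------------------------------------
        # metoprolol: actionable {poor, intermediate, ultrarapid} = 0.48
        R("metoprolol", "CYP2D6", "poor", S.MODERATE, inc(3), E.CPIC_A),
        R("metoprolol", "CYP2D6", "intermediate", S.MODERATE, inc(2), E.CPIC_A),
        R("metoprolol", "CYP2D6", "ultrarapid", S.MODERATE, dec(1), E.CPIC_A),
        # amitriptyline: actionable {poor, intermediate, rapid, ultrarapid} = 0.50
        R("amitriptyline", "CYP2D6", "poor", S.MAJOR, inc(2), E.CPIC_A),
        R("amitriptyline", "CYP2D6", "intermediate", S.MODERATE, inc(1), E.CPIC_A),
        R("amitriptyline", "CYP2D6", "rapid", S.MODERATE, dec(1), E.CPIC_A),
        R("amitriptyline", "CYP2D6", "ultrarapid", S.MODERATE, dec(2), E.CPIC_A),
        # amitriptyline is a dual CYP2D6/CYP2C19 substrate: intrinsic
        # two-gene rule (couples the two genes into one cluster).
        R(
            "amitriptyline", "CYP2D6", "intermediate", S.MAJOR, inc(2), E.CPIC_A,
            second_gene="CYP2C19", second_phenotype="poor",
        ),
        # codeine / tramadol prodrugs: actionable {poor, ultrarapid} = 0.09
        R("codeine", "CYP2D6", "poor", S.MAJOR, dec(2), E.CPIC_A,
          moiety="metabolite"),
        R("codeine", "CYP2D6", "ultrarapid", S.CONTRAINDICATED, inc(2),
          E.FDA_LABEL, moiety="metabolite"),
        R("tramadol", "CYP2D6", "poor", S.MAJOR, dec(2), E.CPIC_A,
          moiety="metabolite"),
        R("tramadol", "CYP2D6", "ultrarapid", S.CONTRAINDICATED, inc(2),
          E.FDA_LABEL, moiety="metabolite"),
        # -- CYP2C19 substrates -----------------------------------------------
        # clopidogrel prodrug: actionable {poor, intermediate} = 0.29
        R("clopidogrel", "CYP2C19", "poor", S.MAJOR, dec(2), E.FDA_LABEL,
          moiety="metabolite"),
        R("clopidogrel", "CYP2C19", "intermediate", S.MODERATE, dec(1),
          E.CPIC_A, moiety="metabolite"),
        # proton-pump inhibitors: actionable {poor, intermediate} = 0.29
        R("omeprazole", "CYP2C19", "poor", S.MODERATE, inc(2), E.CPIC_A),
        R("omeprazole", "CYP2C19", "intermediate", S.MODERATE, inc(1), E.CPIC_A),
        R("pantoprazole", "CYP2C19", "poor", S.MODERATE, inc(2), E.CPIC_A),
        R("pantoprazole", "CYP2C19", "intermediate", S.MODERATE, inc(1), E.CPIC_A),
        R("esomeprazole", "CYP2C19", "poor", S.MODERATE, inc(2), E.CPIC_A),
        R("esomeprazole", "CYP2C19", "intermediate", S.MODERATE, inc(1), E.CPIC_A),
        # -- SLCO1B1 / HLA substrates (larger panels only) ---------------------
        R("simvastatin", "SLCO1B1", "decreased-function", S.MODERATE, inc(1),
          E.CPIC_A),
        R("simvastatin", "SLCO1B1", "poor-function", S.MAJOR, inc(2), E.CPIC_A),
        R("abacavir", "HLA-B*57:01", "carrier", S.CONTRAINDICATED, AUCCategory("none"),
          E.FDA_LABEL),
    ]
    # citalopram / escitalopram share rules (the published ranking treats
    # them as one aggregated entry): actionable {poor, intermediate,
    # ultrarapid} = 0.32; the rapid-metabolizer rule is monitor-level and so
    # contributes nothing to the probability, but participates in
    # phenoconversion combinations.
    for name in ("citalopram", "escitalopram"):
        rules += [
            R(name, "CYP2C19", "poor", S.MAJOR, inc(2), E.FDA_LABEL),
            R(name, "CYP2C19", "intermediate", S.MODERATE, inc(1), E.CPIC_A),
            R(name, "CYP2C19", "ultrarapid", S.MAJOR, dec(2), E.CPIC_A),
            R(name, "CYP2C19", "rapid", S.MONITOR, dec(1), E.CPIC_B),
        ]

    ddi_rules = (
        DDIRule(("tramadol", "bupropion"), S.MODERATE),
        DDIRule(("metoprolol", "dronedarone"), S.MODERATE),
        DDIRule(("amitriptyline", "tramadol", "bupropion"), S.MAJOR),
    )

    kb = KnowledgeBase(
        genes=genes,
        drugs={d.name: d for d in drug_list},
        rules=tuple(rules),
        ddi_rules=ddi_rules,
        prevalence=prevalence,
    )
    diags = kb.validate()
    if diags:  # pragma: no cover - construction bug guard
        raise KBValidationError(diags)
    return kb, prevalence
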