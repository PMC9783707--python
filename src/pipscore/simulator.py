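"""Synthetic cohort generation.

The patient cohorts on which interaction-probability scores are validated
in practice are proprietary, so this module generates cohorts with the
statistical structure the analysis assumes: a long-tailed medication-count
distribution (mean 9.4, range 1-62, including vitamins and supplements with
no pharmacogenomic impact), a mix of 3/5/14/25-gene test panels in the
proportions observed in a large commercial testing population, phenotypes
drawn independently per gene from population prevalences, and demographics
carried as annotations only.

Medication sampling is two-stage: clinical areas are weighted, and drugs
are drawn (without replacement) with weight proportional to their area's
weight split evenly within the area, so that multi-area polypharmacy
emerges naturally.  Real joint co-prescription structure beyond this model
is out of scope.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np

from .detector import PatientRecord
from .kb import (
    CLINICAL_AREAS,
    DDIRule,
    Drug,
    InteractionRule,
    KnowledgeBase,
    PANEL_GENES,
    PhenotypePrevalence,
)
from .types import AUCCategory, EvidenceSource, METABOLIZER_LADDER, Severity

#: Panel ordering mix (exclusive shares) matching a 36,511-patient testing
#: population in which 28,613 orders covered at least the 5-gene panel,
#: 3192 at least the 14-gene panel, and 2068 the full 25-gene panel.
DEFAULT_PANEL_MIX: dict[int, float] = {
    3: (36511 - 28613) / 36511,
    5: (28613 - 3192) / 36511,
    14: (3192 - 2068) / 36511,
    25: 2068 / 36511,
}

#: Default clinical-area prescription weights (normalized at use).  Chosen
#: to put most prescribing mass in cardiology, behavioral health, pain
#: management, and gastroenterology, the areas that dominate actionable
#: interaction counts in practice.
DEFAULT_AREA_WEIGHTS: dict[str, float] = {
    "cardiology": 0.21,
    "behavioral health": 0.17,
    "pain management": 0.14,
    "gastroenterology": 0.11,
    "miscellaneous": 0.09,
    "endocrinology": 0.08,
    "neurology": 0.05,
    "infectious disease": 0.04,
    "urology": 0.03,
    "rheumatology": 0.03,
    "hematology and oncology": 0.02,
    "reproductive and sexual health": 0.02,
    "transplant": 0.01,
}

#: Demographic marginals used for annotation sampling (never scoring).
SEX_MARGINALS = {"female": 0.563, "male": 0.393, "unknown": 0.044}
RACE_MARGINALS = {
    "white": 0.472,
    "unknown": 0.339,
    "hispanic": 0.093,
    "black": 0.081,
    "asian": 0.011,
    "ashkenazi": 0.004,
}


@dataclass(frozen=True)
class MedCountModel:
    """Shifted negative-binomial medication-count model, truncated to
    [minimum, maximum].

    Defaults give mean 9.4 on support 1-62; only the mean and range of the
    real distribution are public, and a shifted negative binomial is the
    standard overdispersed count model matching a long polypharmacy tail.
    """

    mean: float = 9.4
    dispersion: float = 2.0
    minimum: int = 1
    maximum: int = 62

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        mu = self.mean - self.minimum
        if mu <= 0:
            return np.full(size, self.minimum)
        p = self.dispersion / (self.dispersion + mu)
        x = self.minimum + rng.negative_binomial(self.dispersion, p, size=size)
        return np.clip(x, self.minimum, self.maximum)


@dataclass
class CohortConfig:
    n_patients: int
    panel_mix: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_PANEL_MIX)
    )
    med_count: MedCountModel = field(default_factory=MedCountModel)
    area_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AREA_WEIGHTS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        unknown = set(self.panel_mix) - set(PANEL_GENES)
        if unknown:
            raise ValueError(f"unknown panel sizes: {sorted(unknown)}")
        total = sum(self.panel_mix.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"panel_mix must sum to 1, got {total}")
        if any(w < 0 for w in self.panel_mix.values()):
            raise ValueError("panel_mix weights must be non-negative")
        bad = set(self.area_weights) - set(CLINICAL_AREAS)
        if bad:
            raise ValueError(f"unknown clinical areas: {sorted(bad)}")
        if not self.med_count.minimum >= 1:
            raise ValueError("medication counts start at 1")


@dataclass
class SyntheticCohort:
    patients: list[PatientRecord]
    config: CohortConfig

    def __len__(self) -> int:
        return len(self.patients)


def sample_phenotypes(
    genes, prev: PhenotypePrevalence, rng: np.random.Generator
) -> dict[str, str]:
    """Independent categorical phenotype draw per gene; deterministic for a
    given generator state."""
    out: dict[str, str] = {}
    for gene in sorted(genes):
        dist = sorted(prev.distribution(gene).items())
        labels = [ph for ph, _ in dist]
        cum = np.cumsum([f for _, f in dist])
        out[gene] = labels[int(np.searchsorted(cum, rng.random(), side="right"))]
    return out


def simulate_cohort(
    config: CohortConfig,
    kb: KnowledgeBase,
    prev: Optional[PhenotypePrevalence] = None,
) -> SyntheticCohort:
    """Generate a cohort of patient records; fixing the seed fixes the
    entire cohort."""
    if prev is None:
        prev = kb.prevalence
    if prev is None:
        raise ValueError("a phenotype prevalence table is required")
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    if n == 0:
        return SyntheticCohort([], config)

    drug_names = sorted(kb.drugs)
    area_of = {d: kb.drugs[d].clinical_area for d in drug_names}
    area_w = {a: w for a, w in config.area_weights.items() if w > 0}
    per_area_counts: dict[str, int] = {}
    for d in drug_names:
        per_area_counts[area_of[d]] = per_area_counts.get(area_of[d], 0) + 1
    weights = np.array(
        [
            area_w.get(area_of[d], 0.0) / per_area_counts[area_of[d]]
            for d in drug_names
        ]
    )
    if weights.sum() <= 0:
        raise ValueError("no drug receives positive sampling weight")
    weights = weights / weights.sum()

    counts = config.med_count.sample(rng, n)
    counts = np.minimum(counts, int((weights > 0).sum()))

    panel_sizes = sorted(config.panel_mix)
    panel_probs = np.array([config.panel_mix[k] for k in panel_sizes])
    panels = rng.choice(panel_sizes, size=n, p=panel_probs / panel_probs.sum())

    # Weighted sampling without replacement via the exponential race: the
    # med list of patient i is the counts[i] drugs with the smallest
    # exponential arrival times E_j / w_j.
    with np.errstate(divide="ignore"):
        race = rng.exponential(size=(n, len(drug_names))) / weights
    order = np.argsort(race, axis=1)

    # Per-gene phenotype draws for the whole cohort at once.
    all_panel_genes = sorted(set(PANEL_GENES[25]))
    draws: dict[str, np.ndarray] = {}
    for gene in all_panel_genes:
        dist = sorted(prev.distribution(gene).items())
        labels = np.array([ph for ph, _ in dist], dtype=object)
        cum = np.cumsum([f for _, f in dist])
        draws[gene] = labels[
            np.searchsorted(cum, rng.random(n), side="right").clip(0, len(labels) - 1)
        ]

    ages = np.clip(np.rint(rng.normal(61.0, 18.0, size=n)), 0, 110).astype(int)
    sexes = rng.choice(
        list(SEX_MARGINALS), size=n, p=np.array(list(SEX_MARGINALS.values()))
    )
    races = rng.choice(
        list(RACE_MARGINALS), size=n, p=np.array(list(RACE_MARGINALS.values()))
    )

    patients: list[PatientRecord] = []
    for i in range(n):
        meds = [drug_names[j] for j in order[i, : counts[i]]]
        panel = frozenset(PANEL_GENES[int(panels[i])])
        phenotypes = {g: str(draws[g][i]) for g in sorted(panel)}
        patients.append(
            PatientRecord(
                patient_id=f"P{i:06d}",
                meds=meds,
                tested_genes=panel,
                phenotypes=phenotypes,
                age=int(ages[i]),
                sex=str(sexes[i]),
                race=str(races[i]),
            )
        )
    return SyntheticCohort(patients, config)


# ---------------------------------------------------------------------------
# cohort file format (delimited text)


def write_cohort_tsv(cohort: SyntheticCohort, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["patient_id", "meds", "tested_genes", "phenotypes", "age", "sex", "race"]
        )
        for p in cohort.patients:
            writer.writerow(
                [
                    p.patient_id,
                    ";".join(p.meds),
                    ";".join(sorted(p.tested_genes)),
                    ";".join(
                        f"{g}={ph}" for g, ph in sorted(p.phenotypes.items())
                    ),
                    "" if p.age is None else p.age,
                    p.sex or "",
                    p.race or "",
                ]
            )


def read_cohort_tsv(path) -> list[PatientRecord]:
    path = Path(path)
    patients: list[PatientRecord] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            phenotypes = {}
            for item in (row.get("phenotypes") or "").split(";"):
                if item:
                    g, _, ph = item.partition("=")
                    phenotypes[g] = ph
            patients.append(
                PatientRecord(
                    patient_id=row["patient_id"],
                    meds=[m for m in row["meds"].split(";") if m],
                    tested_genes=frozenset(
                        g for g in (row.get("tested_genes") or "").split(";") if g
                    ),
                    phenotypes=phenotypes,
                    age=int(row["age"]) if row.get("age") else None,
                    sex=row.get("sex") or None,
                    race=row.get("race") or None,
                )
            )
    return patients


# ---------------------------------------------------------------------------
# randomized small knowledge bases (oracle cross-checks)


def random_kb(
    rng: np.random.Generator,
    max_genes: int = 3,
    max_drugs: int = 5,
) -> tuple[KnowledgeBase, PhenotypePrevalence]:
    """A small random-but-valid knowledge base with strictly positive
    phenotype prevalences, used to cross-check the factorized probability
    computation against full joint enumeration."""
    n_genes = int(rng.integers(1, max_genes + 1))
    genes = {f"CYPG{i}": METABOLIZER_LADDER for i in range(n_genes)}
    gene_names = sorted(genes)
    prev = PhenotypePrevalence(
        {
            g: dict(
                zip(
                    METABOLIZER_LADDER,
                    (rng.dirichlet(np.ones(5)) * 0.98 + 0.004).tolist(),
                )
            )
            for g in gene_names
        }
    )
    n_drugs = int(rng.integers(2, max_drugs + 1))
    drug_names = [f"drug{i}" for i in range(n_drugs)]
    severities = [Severity.MONITOR, Severity.MODERATE, Severity.MAJOR,
                  Severity.CONTRAINDICATED]
    evidences = list(EvidenceSource)

    def random_auc() -> AUCCategory:
        if rng.random() < 0.1:
            return AUCCategory("none", 0)
        direction = "decrease" if rng.random() < 0.5 else "increase"
        return AUCCategory(direction, int(rng.integers(0, 4)))

    drugs = {}
    rules: list[InteractionRule] = []
    seen_keys: set[tuple] = set()
    for name in drug_names:
        effects = {}
        for g in gene_names:
            if rng.random() < 0.35:
                direction = "increase" if rng.random() < 0.7 else "decrease"
                effects[g] = AUCCategory(direction, int(rng.integers(0, 3)))
        drugs[name] = Drug(
            name=name,
            clinical_area=str(rng.choice(CLINICAL_AREAS)),
            modifier_effects=effects,
        )
        n_rules = int(rng.integers(0, 4))
        for _ in range(n_rules):
            gene = str(rng.choice(gene_names))
            phenotype = str(rng.choice(METABOLIZER_LADDER[:2] + ("rapid", "ultrarapid")))
            second_gene = second_ph = None
            if n_genes >= 2 and rng.random() < 0.25:
                others = [g for g in gene_names if g != gene]
                second_gene = str(rng.choice(others))
                second_ph = str(rng.choice(METABOLIZER_LADDER))
            rule = InteractionRule(
                drug=name,
                gene=gene,
                phenotype=phenotype,
                severity=severities[int(rng.integers(0, len(severities)))],
                auc_change=random_auc(),
                evidence=evidences[int(rng.integers(0, len(evidences)))],
                moiety="metabolite" if rng.random() < 0.3 else "parent",
                second_gene=second_gene,
                second_phenotype=second_ph,
            )
            if rule.key not in seen_keys:
                seen_keys.add(rule.key)
                rules.append(rule)
    ddi_rules = []
    if n_drugs >= 2 and rng.random() < 0.4:
        pair = rng.choice(drug_names, size=2, replace=False)
        ddi_rules.append(
            DDIRule(tuple(pair), severities[int(rng.integers(1, len(severities)))])
        )
    kb = KnowledgeBase(
        genes=genes, drugs=drugs, rules=tuple(rules),
        ddi_rules=tuple(ddi_rules), prevalence=prev,
    )
    return kb, prev
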