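"""PIP engine: the probability that a medication list will yield at least
one evidence-based, actionable drug-gene interaction.

Given a medication list, an interaction knowledge base, and population
phenotype prevalences, the engine enumerates *interaction opportunities* —
rules that could fire depending on the patient's (unknown) phenotypes —
and computes

    PIP = P(at least one opportunity is actionable)
        = 1 - prod over gene clusters of (1 - P(cluster actionable)),

where phenotypes are drawn independently per gene, genes coupled by a
two-gene rule are enumerated jointly as one cluster, and disjoint clusters
are treated as independent (pharmacogenes are unlinked).  The *adjusted*
PIP is the same quantity restricted to the genes actually present on the
ordered test panel.

Exclusion filters applied before any probability is computed:

* opportunities whose best post-phenoconversion severity is monitor or none
  are dropped — monitoring alone would not change clinical management;
* a phenoconversion (drug-drug-gene) escalation is dropped when its
  severity does not exceed that of the corresponding gene-free drug-drug
  interaction, because genetic testing would add nothing to what is already
  known about the pair.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .kb import KnowledgeBase, PhenotypePrevalence, InteractionRule
from .phenoconv import combine_auc, interaction_severity
from .types import AUCCategory, Severity


class UnknownDrugError(KeyError):
    def __init__(self, names: Sequence[str]):
        self.names = sorted(names)
        super().__init__(f"unknown drug name(s): {', '.join(self.names)}")


class OracleTooLargeError(ValueError):
    """Raised when full joint enumeration would exceed the combination cap."""


@dataclass(frozen=True)
class ModifierContext:
    """A co-medication acting on the gene of a rule: the drug name and its
    AUC effect oriented for the rule's affected moiety."""

    drug: str
    effect: AUCCategory


@dataclass(frozen=True)
class Opportunity:
    """A rule that may fire for this medication list, with the co-medication
    modifier context on its gene and the best achievable (post-
    phenoconversion, DDI-filtered) severity."""

    rule: InteractionRule
    modifiers: tuple[ModifierContext, ...]
    severity: Severity

    @property
    def genes(self) -> tuple[str, ...]:
        if rule_second := self.rule.second_gene:
            return (self.rule.gene, rule_second)
        return (self.rule.gene,)

    def matches(self, assignment: dict) -> bool:
        """True if the phenotype assignment activates this rule."""
        if assignment.get(self.rule.gene) != self.rule.phenotype:
            return False
        if self.rule.second_gene is not None:
            return assignment.get(self.rule.second_gene) == self.rule.second_phenotype
        return True


@dataclass
class PIPResult:
    """Full and panel-adjusted interaction probabilities, with per-cluster
    contributions and the number of contributing opportunities."""

    pip: float
    adjusted_pip: float
    per_cluster: dict[frozenset, float] = field(default_factory=dict)
    opportunity_count: int = 0


def _normalize_meds(
    meds: Iterable[str], kb: KnowledgeBase, strict: bool
) -> list[str]:
    seen: list[str] = []
    unknown: list[str] = []
    for m in meds:
        name = m.strip().lower()
        if not name:
            continue
        if name not in kb.drugs:
            unknown.append(name)
            continue
        if name not in seen:
            seen.append(name)
    if strict and unknown:
        raise UnknownDrugError(unknown)
    return seen


def interaction_opportunities(
    meds: Sequence[str],
    kb: KnowledgeBase,
    gene_set: Iterable[str],
    strict: bool = False,
) -> list[Opportunity]:
    """Enumerate filtered interaction opportunities for a medication list.

    Unknown medications (vitamins, supplements, drugs without knowledge-base
    entries) are silently ignored unless ``strict`` is set, in which case an
    :class:`UnknownDrugError` lists every offender.
    """
    if not meds:
        raise ValueError("medication list must be non-empty")
    names = _normalize_meds(meds, kb, strict)
    genes = set(gene_set)
    unknown_genes = genes - set(kb.genes)
    if unknown_genes:
        raise KeyError(f"genes not in knowledge base: {sorted(unknown_genes)}")
    out: list[Opportunity] = []
    for drug in names:
        for rule in kb.rules_for_drug(drug):
            if rule.gene not in genes:
                continue
            if rule.second_gene is not None and rule.second_gene not in genes:
                continue
            mods: list[ModifierContext] = []
            if rule.second_gene is None:
                # Two-gene rules carry their stated severity directly; the
                # combination algebra applies to co-medication on the single
                # gene of an ordinary rule.
                for other in names:
                    if other == drug:
                        continue
                    eff = kb.oriented_modifier_effect(other, rule.gene, rule.moiety)
                    if eff is not None:
                        mods.append(ModifierContext(other, eff))
            best = rule.severity
            for mod in mods:
                combined = combine_auc(rule.auc_change, mod.effect)
                sev = interaction_severity(rule, combined)
                ddi = kb.ddi_severity((drug, mod.drug))
                if ddi is not None and sev <= ddi:
                    # Gene information does not exceed what the plain
                    # drug-drug interaction already tells the clinician.
                    continue
                if sev > best:
                    best = sev
            if not best.actionable:
                continue  # monitor / none: would not change management
            out.append(Opportunity(rule, tuple(mods), best))
    return out


def gene_clusters(opportunities: Sequence[Opportunity]) -> list[frozenset[str]]:
    """Partition the genes of the opportunities into connected clusters;
    genes sharing a two-gene rule are coupled, everything else is a
    singleton."""
    parent: dict[str, str] = {}

    def find(g: str) -> str:
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for opp in opportunities:
        for g in opp.genes:
            parent.setdefault(g, g)
        for a, b in itertools.pairwise(opp.genes):
            union(a, b)
    clusters: dict[str, set[str]] = {}
    for g in parent:
        clusters.setdefault(find(g), set()).add(g)
    return sorted((frozenset(c) for c in clusters.values()), key=sorted)


def cluster_actionable_probability(
    cluster: frozenset[str] | Iterable[str],
    opportunities: Sequence[Opportunity],
    prev: PhenotypePrevalence,
) -> float:
    """Probability that at least one opportunity within the cluster is
    actionable, by exact enumeration over the Cartesian product of the
    cluster genes' phenotypes."""
    genes = sorted(cluster)
    opps = [o for o in opportunities if set(o.genes) <= set(genes)]
    if not opps:
        return 0.0
    dists = [sorted(prev.distribution(g).items()) for g in genes]
    prob = 0.0
    for combo in itertools.product(*dists):
        assignment = {g: ph for g, (ph, _) in zip(genes, combo)}
        if any(o.matches(assignment) for o in opps):
            p = 1.0
            for _, f in combo:
                p *= f
            prob += p
    return prob


def _pip_over(
    opportunities: Sequence[Opportunity], prev: PhenotypePrevalence
) -> tuple[float, dict[frozenset, float]]:
    per_cluster: dict[frozenset, float] = {}
    survival = 1.0
    for cluster in gene_clusters(opportunities):
        p = cluster_actionable_probability(cluster, opportunities, prev)
        per_cluster[cluster] = p
        survival *= 1.0 - p
    return 1.0 - survival, per_cluster


def compute_pip(
    meds: Sequence[str],
    kb: KnowledgeBase,
    prev: PhenotypePrevalence,
    tested_genes: Optional[Iterable[str]] = None,
    strict: bool = False,
) -> PIPResult:
    """Compute the full and adjusted interaction probabilities.

    The full score considers every gene the knowledge base (and prevalence
    table) knows about; the adjusted score restricts to ``tested_genes``
    (defaults to the full set).  Probabilities are kept in double precision
    with no rounding; presentation rounding belongs to the report layer.
    """
    all_genes = set(kb.genes) & prev.genes
    full_opps = interaction_opportunities(meds, kb, all_genes, strict=strict)
    pip, per_cluster = _pip_over(full_opps, prev)

    if tested_genes is None:
        tested = all_genes
    else:
        tested = set(tested_genes) & all_genes
    if tested == all_genes:
        adjusted = pip
    else:
        adj_opps = interaction_opportunities(meds, kb, tested, strict=False)
        adjusted, _ = _pip_over(adj_opps, prev)

    # An opportunity counts only if it can actually occur under the
    # prevalence model (every referenced phenotype has positive mass).
    def possible(o: Opportunity) -> bool:
        pairs = [(o.rule.gene, o.rule.phenotype)]
        if o.rule.second_gene is not None:
            pairs.append((o.rule.second_gene, o.rule.second_phenotype))
        return all(prev.frequency(g, ph) > 0 for g, ph in pairs)

    count = sum(1 for o in full_opps if possible(o))
    return PIPResult(
        pip=pip, adjusted_pip=adjusted, per_cluster=per_cluster,
        opportunity_count=count,
    )


def pip_bruteforce(
    meds: Sequence[str],
    kb: KnowledgeBase,
    prev: PhenotypePrevalence,
    tested_genes: Optional[Iterable[str]] = None,
    cap: int = 10 ** 6,
) -> float:
    """Exact interaction probability by full joint enumeration.

    Enumerates every joint phenotype assignment over the genes relevant to
    the medication list, runs the *detector* on each concrete assignment,
    and accumulates the probability mass of assignments with at least one
    actionable gene interaction.  This is an independent oracle for
    :func:`compute_pip`: the two share only the knowledge base, not the
    factorized probability computation.
    """
    from . import detector  # local import; detector also consumes this module

    all_genes = set(kb.genes) & prev.genes
    tested = all_genes if tested_genes is None else set(tested_genes) & all_genes
    names = _normalize_meds(meds, kb, strict=False)
    relevant: set[str] = set()
    for drug in names:
        relevant |= kb.substrate_genes(drug)
    relevant &= tested
    genes = sorted(relevant)
    total = math.prod(len(prev.distribution(g)) for g in genes) if genes else 0
    if total > cap:
        raise OracleTooLargeError(
            f"joint enumeration over {total} phenotype combinations exceeds cap {cap}"
        )
    if not names or not genes:
        return 0.0
    dists = [sorted(prev.distribution(g).items()) for g in genes]
    prob = 0.0
    for combo in itertools.product(*dists):
        assignment = {g: ph for g, (ph, _) in zip(genes, combo)}
        patient = detector.PatientRecord(
            patient_id="oracle",
            meds=list(names),
            tested_genes=frozenset(genes),
            phenotypes=assignment,
        )
        if detector.has_eadgi(patient, kb):
            p = 1.0
            for _, f in combo:
                p *= f
            prob += p
    return prob
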