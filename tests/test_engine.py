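"""PIP engine: opportunity enumeration, exclusion filters, factorized
probability computation, and agreement with the full-enumeration oracle."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pipscore import (
    OracleTooLargeError,
    Severity,
    UnknownDrugError,
    cluster_actionable_probability,
    compute_pip,
    gene_clusters,
    interaction_opportunities,
    pip_bruteforce,
    random_kb,
)

SUBSTRATES = [
    "metoprolol", "amitriptyline", "codeine", "tramadol", "omeprazole",
    "pantoprazole", "clopidogrel", "citalopram", "escitalopram",
    "simvastatin", "abacavir", "esomeprazole",
]
MODIFIERS = ["bupropion", "fluvoxamine", "dronedarone", "oxycodone", "rifampin"]


def test_no_substrate_means_no_opportunities(kb):
    assert interaction_opportunities(["multivitamin"], kb, set(kb.genes)) == []


def test_empty_medication_list_is_rejected(kb):
    with pytest.raises(ValueError):
        interaction_opportunities([], kb, set(kb.genes))


def test_unknown_drug_error_lists_names(kb, prev):
    with pytest.raises(UnknownDrugError, match="notadrug"):
        compute_pip(["metoprolol", "notadrug"], kb, prev, strict=True)
    # lenient mode silently ignores the unknown entry
    r = compute_pip(["metoprolol", "notadrug"], kb, prev)
    assert r.pip == pytest.approx(0.48)


def test_monitor_severity_rules_are_excluded(kb):
    # citalopram's rapid-metabolizer rule is monitor-level: no opportunity.
    opps = interaction_opportunities(["citalopram"], kb, {"CYP2C19"})
    assert all(o.rule.phenotype != "rapid" for o in opps)
    assert all(o.severity.actionable for o in opps)


def test_comedication_adds_ddgi_escalation(kb):
    opps = interaction_opportunities(["clopidogrel", "tramadol"], kb, {"CYP2C19"})
    im = [o for o in opps if o.rule.drug == "clopidogrel"
          and o.rule.phenotype == "intermediate"]
    assert len(im) == 1
    # base moderate escalates to major through the tramadol inhibition
    assert im[0].severity == Severity.MAJOR
    assert any(m.drug == "tramadol" for m in im[0].modifiers)


def test_ddi_suppresses_non_exceeding_escalation(kb):
    # metoprolol UM + dronedarone: opposed directions de-escalate, severity
    # stays moderate, which does not exceed the known moderate DDI — the
    # opportunity survives only at its base severity.
    opps = interaction_opportunities(["metoprolol", "dronedarone"], kb, {"CYP2D6"})
    um = [o for o in opps if o.rule.phenotype == "ultrarapid"]
    assert um[0].severity == Severity.MODERATE


def test_cluster_probability_is_actionable_phenotype_mass(kb, prev):
    opps = interaction_opportunities(["metoprolol"], kb, {"CYP2D6"})
    p = cluster_actionable_probability(frozenset({"CYP2D6"}), opps, prev)
    assert p == pytest.approx(0.48, abs=1e-12)


def test_nested_actionable_sets_union_to_the_larger_mass(kb, prev):
    # citalopram (0.32) and clopidogrel (0.29) share CYP2C19 with the
    # smaller actionable set nested in the larger.
    r = compute_pip(["citalopram", "clopidogrel"], kb, prev)
    assert r.pip == pytest.approx(0.32)


def test_empty_opportunities_give_zero(prev, kb):
    assert cluster_actionable_probability(frozenset({"CYP2D6"}), [], prev) == 0.0
    r = compute_pip(["multivitamin", "lisinopril"], kb, prev)
    assert r.pip == 0.0
    assert r.adjusted_pip == 0.0
    assert r.opportunity_count == 0


def test_disjoint_genes_combine_independently(kb, prev):
    r = compute_pip(["citalopram", "codeine"], kb, prev)
    assert r.pip == pytest.approx(1 - 0.68 * 0.91, abs=1e-12)


def test_per_cluster_contributions_multiply_to_pip(kb, prev):
    r = compute_pip(["citalopram", "codeine", "simvastatin"], kb, prev)
    survival = 1.0
    for p in r.per_cluster.values():
        survival *= 1 - p
    assert r.pip == pytest.approx(1 - survival, abs=1e-12)


def test_two_gene_rule_couples_genes_into_one_cluster(kb, prev):
    r = compute_pip(["amitriptyline"], kb, prev)
    assert frozenset({"CYP2D6", "CYP2C19"}) in r.per_cluster
    # joint enumeration still gives the calibrated single-drug score
    assert r.pip == pytest.approx(0.50)


def test_gene_clusters_partition_and_merge():
    class FakeOpp:
        def __init__(self, genes):
            self.genes = genes

    clusters = gene_clusters(
        [FakeOpp(("A",)), FakeOpp(("B", "C")), FakeOpp(("C",)), FakeOpp(("D",))]
    )
    assert clusters == [frozenset({"A"}), frozenset({"B", "C"}), frozenset({"D"})]


def test_adjusted_pip_restricted_to_tested_genes(kb, prev):
    r = compute_pip(["citalopram", "codeine"], kb, prev, tested_genes={"CYP2C19"})
    assert r.adjusted_pip == pytest.approx(0.32)
    assert r.pip == pytest.approx(1 - 0.68 * 0.91)
    assert r.adjusted_pip <= r.pip


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    meds=st.sets(st.sampled_from(SUBSTRATES + MODIFIERS), min_size=1, max_size=5),
    extra=st.sampled_from(SUBSTRATES + MODIFIERS),
    genes=st.sets(
        st.sampled_from(["CYP2D6", "CYP2C19", "SLCO1B1", "HLA-B*57:01"])
    ),
)
def test_pip_monotone_in_meds_and_genes(kb, prev, meds, extra, genes):
    """Appending a medication never lowers the score; enlarging the tested
    panel never lowers the adjusted score; adjusted <= full always."""
    meds = sorted(meds)
    r = compute_pip(meds, kb, prev, tested_genes=genes)
    assert 0.0 <= r.adjusted_pip <= r.pip <= 1.0
    r_more = compute_pip(meds + [extra], kb, prev, tested_genes=genes)
    assert r_more.pip >= r.pip - 1e-12
    bigger = set(genes) | {"CYP2D6"}
    r_genes = compute_pip(meds, kb, prev, tested_genes=bigger)
    assert r_genes.adjusted_pip >= r.adjusted_pip - 1e-12


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    meds=st.sets(st.sampled_from(SUBSTRATES + MODIFIERS), min_size=1, max_size=4)
)
def test_factorized_pip_equals_bruteforce_on_demo_kb(kb, prev, meds):
    r = compute_pip(sorted(meds), kb, prev)
    b = pip_bruteforce(sorted(meds), kb, prev)
    assert r.pip == pytest.approx(b, abs=1e-9)


def test_bruteforce_refuses_oversized_enumerations(kb, prev):
    with pytest.raises(OracleTooLargeError):
        pip_bruteforce(["amitriptyline"], kb, prev, cap=3)


def test_bruteforce_collapses_to_cluster_probability_for_one_gene(kb, prev):
    opps = interaction_opportunities(["metoprolol"], kb, {"CYP2D6"})
    p_cluster = cluster_actionable_probability(frozenset({"CYP2D6"}), opps, prev)
    assert pip_bruteforce(["metoprolol"], kb, prev) == pytest.approx(
        p_cluster, abs=1e-12
    )


def test_monte_carlo_eadgi_rate_matches_pip(kb, prev):
    """Calibration identity: with phenotypes drawn from the prevalence
    model, the detected-interaction indicator has expectation equal to the
    computed probability (checked at n=10,000 within 3 binomial SE)."""
    from pipscore import PatientRecord, has_eadgi, sample_phenotypes

    meds = ["clopidogrel", "tramadol", "citalopram"]
    genes = {"CYP2C19", "CYP2D6"}
    pip = compute_pip(meds, kb, prev, tested_genes=genes).adjusted_pip
    rng = np.random.default_rng(2024)
    n = 10_000
    hits = 0
    for _ in range(n):
        phenos = sample_phenotypes(genes, prev, rng)
        patient = PatientRecord("mc", list(meds), frozenset(genes), phenos)
        hits += has_eadgi(patient, kb)
    se = np.sqrt(pip * (1 - pip) / n)
    assert abs(hits / n - pip) <= 3 * se
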