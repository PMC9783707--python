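"""Validation statistics: NNT, one-proportion z-test, panel summaries,
threshold bins, and the report writer."""
import json

import numpy as np
import pytest

from pipscore import (
    CohortConfig,
    CohortScorer,
    PatientRecord,
    UndefinedNNTError,
    nnt,
    one_prop_ztest,
    panel_summary,
    pip_band,
    report,
    score_cohort,
    simulate_cohort,
    threshold_bins,
)
from pipscore._util import round_half_up
from pipscore.kb import PANEL_GENES


@pytest.mark.parametrize(
    "n,count,expected",
    [
        (36511, 8174, 4.5),
        (28613, 6707, 4.3),
        (3192, 937, 3.4),
        (2068, 545, 3.8),
        (100, 100, 1.0),
    ],
)
def test_nnt_reproduces_printed_values(n, count, expected):
    assert round_half_up(nnt(n, count), 1) == expected


def test_nnt_is_exact_before_rounding():
    for n, c in [(10, 3), (1000, 7), (36511, 8174)]:
        assert nnt(n, c) * c == pytest.approx(n, abs=1e-9)


def test_nnt_undefined_without_positives():
    with pytest.raises(UndefinedNNTError):
        nnt(100, 0)


def test_ztest_examples():
    z, p = one_prop_ztest(50, 100, 0.5)
    assert z == 0.0 and p == 1.0
    z, p = one_prop_ztest(60, 100, 0.5)
    assert z == pytest.approx(2.0)
    assert p == pytest.approx(0.0455, abs=2e-4)
    z, p = one_prop_ztest(0, 10, 0.5)
    assert z == pytest.approx(-3.162, abs=1e-3)
    assert p == pytest.approx(0.00157, abs=2e-5)


def test_ztest_symmetry_and_domain():
    for count, n, p0 in [(3, 10, 0.4), (17, 40, 0.2), (0, 5, 0.9)]:
        _, p1 = one_prop_ztest(count, n, p0)
        _, p2 = one_prop_ztest(n - count, n, 1 - p0)
        assert p1 == pytest.approx(p2, rel=1e-12)
    with pytest.raises(ValueError):
        one_prop_ztest(1, 10, 0.0)
    with pytest.raises(ValueError):
        one_prop_ztest(1, 10, 1.0)


@pytest.fixture(scope="module")
def scored_cohort(kb, prev):
    cohort = simulate_cohort(CohortConfig(n_patients=4000, seed=17), kb, prev)
    return score_cohort(cohort.patients, kb, prev), cohort


def test_panel_summary_is_calibrated(scored_cohort):
    scored, _ = scored_cohort
    s = panel_summary(scored, 3)
    assert s.n == len(scored)
    assert s.eadgi_rate == s.eadgi_count / s.n
    assert s.nnt == pytest.approx(s.n / s.eadgi_count)
    se = np.sqrt(s.mean_adjusted_pip * (1 - s.mean_adjusted_pip) / s.n)
    assert abs(s.eadgi_rate - s.mean_adjusted_pip) <= 3 * se
    assert s.p_value > 0.05
    assert s.mean_adjusted_pip <= s.mean_pip


def test_panel_subgroups_shrink_with_min_genes(scored_cohort):
    scored, _ = scored_cohort
    sizes = [panel_summary(scored, k).n for k in (3, 5, 14, 25)]
    assert sizes == sorted(sizes, reverse=True)


def test_removing_zero_score_patients_rescales_mean_and_rate(scored_cohort):
    """Dropping patients with an adjusted score of 0 (no medications with
    high-evidence impact) raises the mean score and the observed rate
    together, preserving calibration."""
    scored, _ = scored_cohort
    nonzero = scored[scored["adjusted_pip"] > 0]
    assert len(nonzero) < len(scored)
    assert not nonzero.empty
    mean_nz = nonzero["adjusted_pip"].mean()
    rate_nz = nonzero["eadgi"].mean()
    assert mean_nz > scored["adjusted_pip"].mean()
    # zero-score patients never have an actionable interaction
    zeros = scored[scored["adjusted_pip"] == 0]
    assert not zeros["eadgi"].any()
    se = np.sqrt(mean_nz * (1 - mean_nz) / len(nonzero))
    assert abs(rate_nz - mean_nz) <= 3 * se


def test_zero_score_subgroup_has_undefined_nnt(kb, prev):
    patients = [
        PatientRecord(f"z{i}", ["multivitamin", "lisinopril"],
                      frozenset(PANEL_GENES[3]),
                      {g: "normal" for g in PANEL_GENES[3]})
        for i in range(10)
    ]
    scored = score_cohort(patients, kb, prev)
    s = panel_summary(scored, 3)
    assert s.eadgi_rate == 0.0
    assert s.nnt is None and s.p_value is None


def test_band_boundary_convention():
    assert pip_band(0.0) == "<25%"
    assert pip_band(0.2499) == "<25%"
    assert pip_band(0.25) == "25-50%"
    assert pip_band(0.50) == "25-50%"
    assert pip_band(0.5001) == ">50%"


def test_threshold_bins_monotone_interaction_fraction(scored_cohort):
    scored, _ = scored_cohort
    bins = threshold_bins(scored)
    assert list(bins["band"]) == ["<25%", "25-50%", ">50%"]
    fracs = [r for r, n in zip(bins["any_interaction_frac"], bins["n"]) if n > 0]
    assert fracs == sorted(fracs)
    assert bins["n"].sum() == len(scored)


def test_threshold_bins_zero_score_cohort(kb, prev):
    patients = [
        PatientRecord(f"z{i}", ["multivitamin"], frozenset(PANEL_GENES[3]),
                      {g: "normal" for g in PANEL_GENES[3]})
        for i in range(5)
    ]
    bins = threshold_bins(score_cohort(patients, kb, prev))
    assert bins.loc[bins["band"] == "<25%", "n"].iloc[0] == 5
    assert bins.loc[bins["band"] == "<25%", "none_pct"].iloc[0] == 100.0


def test_report_is_deterministic_and_manifest_tracks_kb(kb, prev, tmp_path):
    cohort = simulate_cohort(CohortConfig(n_patients=150, seed=2), kb, prev)
    out1, out2 = tmp_path / "r1", tmp_path / "r2"
    paths1 = report(cohort.patients, kb, prev, out1, seed=2)
    paths2 = report(cohort.patients, kb, prev, out2, seed=2)
    for name in paths1:
        assert paths1[name].read_bytes() == paths2[name].read_bytes()
    manifest = json.loads((out1 / "manifest.json").read_text())
    assert manifest["n_patients"] == 150
    # the checksum responds to knowledge-base content
    import dataclasses
    from pipscore.kb import kb_checksum
    smaller = dataclasses.replace(kb, rules=kb.rules[:-1])
    assert kb_checksum(smaller) != manifest["kb_sha256"]


def test_scorer_matches_uncached_engine_and_detector(kb, prev):
    """The caching cohort scorer must agree with direct engine/detector
    calls patient by patient."""
    from pipscore import compute_pip, detect_interactions, has_eadgi

    cohort = simulate_cohort(CohortConfig(n_patients=60, seed=21), kb, prev)
    scorer = CohortScorer(kb, prev)
    for p in cohort.patients:
        row = scorer.score(p)
        direct = compute_pip(p.meds, kb, prev, tested_genes=p.tested_genes)
        assert row["pip"] == pytest.approx(direct.pip, abs=1e-12)
        assert row["adjusted_pip"] == pytest.approx(direct.adjusted_pip, abs=1e-12)
        assert row["eadgi"] == has_eadgi(p, kb)
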