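"""Interaction detection for genotyped patients and cohort tabulations."""
import pytest

from pipscore import (
    AUCCategory,
    DetectedInteraction,
    PatientRecord,
    Severity,
    detect_interactions,
    has_eadgi,
    highest_severity_class,
    tabulate_by_area,
    top_medications,
)


def _patient(meds, phenotypes, **kw):
    return PatientRecord(
        patient_id=kw.pop("patient_id", "p1"),
        meds=meds,
        tested_genes=frozenset(phenotypes),
        phenotypes=phenotypes,
        **kw,
    )


def test_phenoconversion_ddgi_clopidogrel_tramadol(kb):
    p = _patient(["clopidogrel", "tramadol"], {"CYP2C19": "intermediate",
                                               "CYP2D6": "normal"})
    ddgis = [i for i in detect_interactions(p, kb) if i.kind == "DDGI"]
    assert len(ddgis) == 1
    it = ddgis[0]
    assert set(it.drugs) == {"clopidogrel", "tramadol"}
    assert it.combined_auc == AUCCategory.from_label("−51–80%")
    assert it.severity == Severity.MAJOR  # escalated from the moderate DGI


def test_phenoconversion_ddgi_amitriptyline_bupropion(kb):
    p = _patient(["amitriptyline", "bupropion"], {"CYP2D6": "poor"})
    ddgis = [i for i in detect_interactions(p, kb) if i.kind == "DDGI"]
    assert ddgis[0].combined_auc == AUCCategory.from_label(">200%")


def test_all_normal_phenotypes_yield_nothing(kb):
    p = _patient(
        ["metoprolol", "citalopram"],
        {"CYP2D6": "normal", "CYP2C19": "normal"},
    )
    assert detect_interactions(p, kb) == []
    assert not has_eadgi(p, kb)


def test_monitor_only_interaction_is_not_actionable(kb):
    # citalopram + CYP2C19 rapid metabolizer is monitor-level; adding
    # esomeprazole attenuates the exposure change (−0–30%) and the severity
    # stays monitor, so no actionable interaction is found.
    p = _patient(["citalopram", "esomeprazole"], {"CYP2C19": "rapid"})
    inters = detect_interactions(p, kb)
    ddgi = [i for i in inters if i.kind == "DDGI"]
    assert ddgi[0].combined_auc == AUCCategory.from_label("−0–30%")
    assert ddgi[0].severity == Severity.MONITOR
    assert not has_eadgi(p, kb)


def test_gene_free_interactions_do_not_count_as_eadgi(kb):
    p = _patient(["tramadol", "bupropion"], {"CYP2D6": "normal"})
    inters = detect_interactions(p, kb)
    assert any(i.kind == "DDI" for i in inters)
    assert not has_eadgi(p, kb)


def test_ddd_interaction_detected_for_triple(kb):
    p = _patient(["amitriptyline", "tramadol", "bupropion"],
                 {"CYP2D6": "normal"})
    assert any(i.kind == "DDDI" for i in detect_interactions(p, kb))


def test_detection_restricted_to_tested_genes(kb):
    p = _patient(["clopidogrel"], {"CYP2D6": "poor"})
    assert detect_interactions(p, kb) == []


def test_detection_is_deterministic_and_severity_sorted(kb):
    p = _patient(
        ["clopidogrel", "tramadol", "citalopram", "metoprolol"],
        {"CYP2C19": "intermediate", "CYP2D6": "poor"},
    )
    first = detect_interactions(p, kb)
    second = detect_interactions(p, kb)
    assert first == second
    sevs = [int(i.severity) for i in first]
    assert sevs == sorted(sevs, reverse=True)


def _fake(kind, severity, drugs=("a",), genes=(("G", "poor"),),
          area="cardiology"):
    shapes = {"DGI": (1, 1), "DDGI": (2, 1), "DGGI": (1, 2),
              "DDI": (2, 0), "DDDI": (3, 0)}
    nd, ng = shapes[kind]
    drugs = tuple(drugs)[:nd] + tuple(f"x{i}" for i in range(nd - len(drugs)))
    genes = (tuple(genes) * 2)[:ng]
    return DetectedInteraction(kind, drugs, genes, severity,
                               AUCCategory("none"), area)


def test_highest_severity_class_picks_max_then_kind():
    inters = [_fake("DGI", Severity.MODERATE), _fake("DDGI", Severity.MAJOR)]
    assert highest_severity_class(inters) == ("DDGI", Severity.MAJOR)
    assert highest_severity_class([]) == ("none", Severity.NONE)


@pytest.mark.parametrize(
    "kinds,expected",
    [
        (("DGI", "DDGI"), "DDGI"),
        (("DDI", "DGI"), "DGI"),
        (("DDI", "DDDI"), "DDDI"),
        (("DGGI", "DDGI", "DGI"), "DGGI"),
    ],
)
def test_equal_severity_ties_break_by_kind_precedence(kinds, expected):
    inters = [_fake(k, Severity.MODERATE) for k in kinds]
    assert highest_severity_class(inters) == (expected, Severity.MODERATE)


def test_area_tabulation_percentages_and_conservation():
    inters = (
        [_fake("DGI", Severity.MAJOR, area="behavioral health")] * 1106
        + [_fake("DGI", Severity.MODERATE, area="behavioral health")] * 765
        + [_fake("DGI", Severity.MAJOR, area="cardiology")] * 877
        + [_fake("DGI", Severity.CONTRAINDICATED, area="pain management")] * 456
        + [_fake("DGI", Severity.MODERATE, area="cardiology")] * 3230
        + [_fake("DDI", Severity.MAJOR, area="cardiology")] * 50  # ignored
    )
    table = tabulate_by_area(inters)
    assert table.loc["behavioral health", "major_or_contraindicated"] == 1106
    assert table["major_or_contraindicated"].sum() == 2444 - 5
    # published proportion: 1106 of 2444 major/contraindicated = 45.3%
    table2 = tabulate_by_area(
        inters + [_fake("DGI", Severity.MAJOR, area="neurology")] * 5
    )
    assert table2.loc["behavioral health", "major_or_contraindicated_pct"] == 45.3
    assert table2["moderate"].sum() + table2["major_or_contraindicated"].sum() \
        == table2["all"].sum()


def test_area_tabulation_handles_empty_and_single():
    empty = tabulate_by_area([])
    assert (empty["all"] == 0).all()
    single = tabulate_by_area([_fake("DGI", Severity.MODERATE, area="urology")])
    assert single.loc["urology", "all_pct"] == 100.0


def test_top_medications_counts_pip_and_nnt(kb, prev):
    inters = (
        [_fake("DGI", Severity.MODERATE, drugs=("metoprolol",),
               genes=(("CYP2D6", "poor"),), area="cardiology")] * 2852
        + [_fake("DGI", Severity.MODERATE, drugs=("omeprazole",),
                 genes=(("CYP2C19", "poor"),), area="gastroenterology")] * 6952
    )
    table = top_medications(inters, kb, prev, ranking={"metoprolol": 5})
    row = table[table["drug"] == "metoprolol"].iloc[0]
    assert row["count"] == 2852
    assert row["proportion_pct"] == 29.1  # 2852 / 9804
    assert row["medication_pip_pct"] == 48.0
    assert row["nnt"] == 2.1
    assert row["rank"] == 5


def test_top_medications_single_drug_is_everything(kb, prev):
    inters = [_fake("DGI", Severity.MAJOR, drugs=("codeine",),
                    genes=(("CYP2D6", "poor"),), area="pain management")] * 3
    table = top_medications(inters, kb, prev)
    assert table.iloc[0]["proportion_pct"] == 100.0
    assert table.iloc[0]["nnt"] == 11.1  # 1 / 0.09


def test_patient_record_invariants():
    with pytest.raises(ValueError, match="medication"):
        PatientRecord("p", [])
    with pytest.raises(ValueError, match="untested"):
        PatientRecord("p", ["aspirin"], frozenset(),
                      phenotypes={"CYP2D6": "poor"})
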