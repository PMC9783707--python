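"""Validation statistics and report layouts.

The headline check for an interaction-probability score is calibration:
across a tested cohort, the mean panel-adjusted score should equal the
fraction of patients in whom testing actually finds at least one
actionable drug-gene interaction (the EADGI rate).  This module provides
the supporting statistics — number needed to test, the one-proportion
z-test used to compare a rate against a fixed expected proportion, panel
subgroup summaries, score-threshold bins — and a report writer producing
deterministic delimited-text tables plus a run manifest.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_up
from .detector import (
    DetectedInteraction,
    PatientRecord,
    detect_interactions,
    highest_severity_class,
    tabulate_by_area,
    top_medications,
)
from .engine import compute_pip
from .kb import KnowledgeBase, PANEL_GENES, PhenotypePrevalence, kb_checksum
from .types import Severity


class UndefinedNNTError(ZeroDivisionError):
    """Raised when no patient has an actionable interaction: the number
    needed to test is undefined (reported as an em dash, not infinity)."""


def nnt(n: int, eadgi_count: int) -> float:
    """Number needed to test: patients tested per patient with at least one
    actionable interaction found.  Exact (``nnt * count == n``); rounding to
    one decimal happens only at the report layer."""
    if eadgi_count <= 0:
        raise UndefinedNNTError(
            "number needed to test is undefined when no interaction was found"
        )
    if not 0 <= eadgi_count <= n:
        raise ValueError("eadgi_count must be between 0 and n")
    return n / eadgi_count


def one_prop_ztest(count: int, n: int, p0: float) -> tuple[float, float]:
    """One-proportion z-test of an observed rate against a fixed expected
    proportion ``p0``, two-sided normal tails, no continuity correction.

    Returns ``(z, p_value)`` with ``z = (count/n - p0) / sqrt(p0 (1-p0)/n)``.
    """
    if not 0 < p0 < 1:
        raise ValueError("p0 must be strictly between 0 and 1")
    if not 0 <= count <= n:
        raise ValueError("count must be between 0 and n")
    phat = count / n
    z = (phat - p0) / np.sqrt(p0 * (1.0 - p0) / n)
    p_value = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p_value, 1.0))


@dataclass
class PanelSummary:
    """Summary of the patients whose ordered panel covers a minimum gene
    set: score means, observed actionable-interaction rate, NNT, and the
    z-test of rate against mean adjusted score."""

    min_genes: int
    n: int
    mean_pip: float
    mean_adjusted_pip: float
    eadgi_rate: float
    eadgi_count: int
    nnt: Optional[float]
    z: Optional[float]
    p_value: Optional[float]


# ---------------------------------------------------------------------------
# cohort scoring


class CohortScorer:
    """Scores patients against one knowledge base + prevalence table.

    Caches per distinct (relevant medications, relevant tested genes)
    profile, and per phenotype assignment within a profile, so large
    simulated cohorts score in seconds: the score depends only on the
    medications carrying rules, modifier effects, or drug-drug rules, and
    detection additionally only on the phenotypes of genes those
    medications touch.
    """

    def __init__(self, kb: KnowledgeBase, prev: PhenotypePrevalence):
        self.kb = kb
        self.prev = prev
        relevant: set[str] = set()
        for name in kb.drugs:
            if kb.rules_for_drug(name) or kb.drugs[name].modifier_effects:
                relevant.add(name)
        for ddi in kb.ddi_rules:
            relevant.update(ddi.drugs)
        self._relevant_drugs = frozenset(relevant)
        self._genes_by_meds: dict[frozenset, frozenset] = {}
        self._pip_cache: dict[frozenset, float] = {}
        self._adj_cache: dict[tuple, float] = {}
        self._det_cache: dict[tuple, tuple] = {}

    def _relevant_genes(self, meds_key: frozenset) -> frozenset:
        cached = self._genes_by_meds.get(meds_key)
        if cached is None:
            genes: set[str] = set()
            for d in meds_key:
                genes |= self.kb.substrate_genes(d)
            cached = frozenset(genes & self.prev.genes)
            self._genes_by_meds[meds_key] = cached
        return cached

    def score(self, patient: PatientRecord) -> dict:
        """Score one patient: full and adjusted PIP, whether an actionable
        gene interaction is present, and the highest-severity interaction
        class."""
        meds_key = frozenset(m for m in patient.meds if m in self._relevant_drugs)
        tested = frozenset(patient.tested_genes)
        if not meds_key:
            return {
                "patient_id": patient.patient_id,
                "n_meds": len(set(patient.meds)),
                "tested_genes": tested,
                "pip": 0.0,
                "adjusted_pip": 0.0,
                "eadgi": False,
                "top_kind": "none",
                "top_severity": Severity.NONE.label,
            }
        pip = self._pip_cache.get(meds_key)
        if pip is None:
            pip = compute_pip(sorted(meds_key), self.kb, self.prev).pip
            self._pip_cache[meds_key] = pip
        genes_key = self._relevant_genes(meds_key) & tested
        adj_key = (meds_key, genes_key)
        adjusted = self._adj_cache.get(adj_key)
        if adjusted is None:
            adjusted = compute_pip(
                sorted(meds_key), self.kb, self.prev, tested_genes=genes_key
            ).adjusted_pip
            self._adj_cache[adj_key] = adjusted
        assignment = tuple(
            (g, patient.phenotypes[g]) for g in sorted(genes_key)
            if g in patient.phenotypes
        )
        det_key = (meds_key, assignment)
        det = self._det_cache.get(det_key)
        if det is None:
            reduced = PatientRecord(
                patient_id="profile",
                meds=sorted(meds_key),
                tested_genes=frozenset(g for g, _ in assignment),
                phenotypes=dict(assignment),
            )
            interactions = detect_interactions(reduced, self.kb)
            eadgi = any(
                it.genes and it.severity.actionable for it in interactions
            )
            kind, sev = highest_severity_class(interactions)
            eadgis = tuple(
                it for it in interactions if it.genes and it.severity.actionable
            )
            det = (eadgi, kind, sev.label, eadgis)
            self._det_cache[det_key] = det
        eadgi, kind, sev_label, _ = det
        return {
            "patient_id": patient.patient_id,
            "n_meds": len(set(patient.meds)),
            "tested_genes": tested,
            "pip": pip,
            "adjusted_pip": adjusted,
            "eadgi": eadgi,
            "top_kind": kind,
            "top_severity": sev_label,
        }

    def eadgis(self, patient: PatientRecord) -> tuple[DetectedInteraction, ...]:
        """The patient's actionable gene interactions (post-detection)."""
        self.score(patient)
        meds_key = frozenset(m for m in patient.meds if m in self._relevant_drugs)
        if not meds_key:
            return ()
        genes_key = self._relevant_genes(meds_key) & frozenset(patient.tested_genes)
        assignment = tuple(
            (g, patient.phenotypes[g]) for g in sorted(genes_key)
            if g in patient.phenotypes
        )
        return self._det_cache[(meds_key, assignment)][3]


def score_cohort(
    patients: Sequence[PatientRecord],
    kb: KnowledgeBase,
    prev: PhenotypePrevalence,
    scorer: Optional[CohortScorer] = None,
) -> pd.DataFrame:
    """Score and detect for every patient; one row per patient."""
    scorer = scorer or CohortScorer(kb, prev)
    rows = [scorer.score(p) for p in patients]
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "n_meds", "tested_genes", "pip", "adjusted_pip",
            "eadgi", "top_kind", "top_severity",
        ],
    )


# ---------------------------------------------------------------------------
# summaries


def panel_summary(scored: pd.DataFrame, min_genes: int) -> PanelSummary:
    """Summarize the subgroup whose ordered panel covers the ``min_genes``
    gene set; the z-test compares the observed rate with the mean adjusted
    score as the fixed expected proportion."""
    panel = set(PANEL_GENES[min_genes])
    mask = scored["tested_genes"].map(lambda gs: panel <= set(gs))
    sub = scored[mask]
    n = int(len(sub))
    if n == 0:
        raise ValueError(f"no patients cover the {min_genes}-gene panel")
    count = int(sub["eadgi"].sum())
    mean_pip = float(sub["pip"].mean())
    mean_adj = float(sub["adjusted_pip"].mean())
    nnt_value = nnt(n, count) if count > 0 else None
    if 0 < mean_adj < 1:
        z, p = one_prop_ztest(count, n, mean_adj)
    else:
        z = p = None
    return PanelSummary(
        min_genes=min_genes,
        n=n,
        mean_pip=mean_pip,
        mean_adjusted_pip=mean_adj,
        eadgi_rate=count / n,
        eadgi_count=count,
        nnt=nnt_value,
        z=z,
        p_value=p,
    )


#: Adjusted-score bands: below 25% is low, 25-50% (inclusive at both edges)
#: moderate, above 50% high.
PIP_BANDS = ("<25%", "25-50%", ">50%")


def pip_band(adjusted_pip: float) -> str:
    if adjusted_pip < 0.25:
        return PIP_BANDS[0]
    if adjusted_pip <= 0.50:
        return PIP_BANDS[1]
    return PIP_BANDS[2]


def threshold_bins(scored: pd.DataFrame) -> pd.DataFrame:
    """Per adjusted-score band: patient count and the frequency of each
    highest-severity interaction class (including gene-free interactions
    and "none")."""
    bands = scored["adjusted_pip"].map(pip_band)
    kinds = ["DGGI", "DDGI", "DGI", "DDDI", "DDI", "none"]
    rows = []
    for band in PIP_BANDS:
        sub = scored[bands == band]
        n = int(len(sub))
        row: dict = {"band": band, "n": n}
        for kind in kinds:
            c = int((sub["top_kind"] == kind).sum())
            row[f"{kind}_count"] = c
            row[f"{kind}_pct"] = round_half_up(100.0 * c / n, 1) if n else 0.0
        row["any_interaction_frac"] = (
            float((sub["top_kind"] != "none").mean()) if n else 0.0
        )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# report


def report(
    patients: Sequence[PatientRecord],
    kb: KnowledgeBase,
    prev: PhenotypePrevalence,
    out_dir,
    ranking: Optional[Mapping[str, object]] = None,
    seed: Optional[int] = None,
    config: Optional[Mapping] = None,
) -> dict[str, Path]:
    """Score, detect, and write the study-style tables.

    Writes panel summaries, interaction counts by clinical area, top
    medications (all-actionable and major-or-contraindicated), threshold
    bins, and a JSON manifest (seed, config, knowledge-base checksum).
    Deterministic given identical inputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scorer = CohortScorer(kb, prev)
    scored = score_cohort(patients, kb, prev, scorer=scorer)
    interactions: list[DetectedInteraction] = []
    for p in patients:
        interactions.extend(scorer.eadgis(p))

    paths: dict[str, Path] = {}

    panel_rows = []
    for k in sorted(PANEL_GENES):
        try:
            s = panel_summary(scored, k)
        except ValueError:
            continue
        panel_rows.append(
            {
                "min_genes": s.min_genes,
                "n": s.n,
                "mean_pip_pct": round_half_up(100 * s.mean_pip, 1),
                "mean_adjusted_pip_pct": round_half_up(100 * s.mean_adjusted_pip, 1),
                "eadgi_rate_pct": round_half_up(100 * s.eadgi_rate, 1),
                "eadgi_count": s.eadgi_count,
                "nnt": "—" if s.nnt is None else round_half_up(s.nnt, 1),
                "p_value": "" if s.p_value is None else round(s.p_value, 4),
            }
        )
    paths["panels"] = out_dir / "panel_summary.tsv"
    pd.DataFrame(panel_rows).to_csv(paths["panels"], sep="\t", index=False)

    paths["areas"] = out_dir / "eadgis_by_area.tsv"
    tabulate_by_area(interactions).to_csv(paths["areas"], sep="\t")

    paths["top_all"] = out_dir / "top_medications.tsv"
    top_medications(interactions, kb, prev, ranking=ranking).to_csv(
        paths["top_all"], sep="\t", index=False
    )
    major = [
        it for it in interactions if it.severity >= Severity.MAJOR
    ]
    paths["top_major"] = out_dir / "top_medications_major.tsv"
    top_medications(major, kb, prev, ranking=ranking).to_csv(
        paths["top_major"], sep="\t", index=False
    )

    paths["bins"] = out_dir / "threshold_bins.tsv"
    threshold_bins(scored).to_csv(paths["bins"], sep="\t", index=False)

    manifest = {
        "n_patients": len(patients),
        "seed": seed,
        "config": dict(config) if config else None,
        "kb_sha256": kb_checksum(kb),
        "tables": {k: p.name for k, p in sorted(paths.items())},
    }
    paths["manifest"] = out_dir / "manifest.json"
    paths["manifest"].write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return paths
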