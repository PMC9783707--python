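# Methods

## Model

A pharmacogenomic interaction probability (PIP) score answers a pre-test
question: if this patient's pharmacogenes were tested today, how likely is
the panel to surface at least one evidence-based, actionable drug–gene
interaction (EADGI) given the medications they already take?

The model has three ingredients.

1. **Interaction rules.** A knowledge base maps (drug, gene, interpreted
   phenotype) to a severity grade (none < monitor < moderate < major <
   contraindicated), a categorical AUC change, and an evidence source.
   Severities of moderate and above are *actionable*: they come with
   concrete prescribing guidance (dose change, alternative drug,
   avoidance). Monitor-level rules are retained in the knowledge base but
   never counted: monitoring alone does not change management. Rules may
   name a second gene (intrinsic drug–gene–gene interactions) and may
   state that their AUC change refers to a prodrug's active metabolite.

2. **Phenoconversion.** Co-medications that inhibit or induce an enzyme
   change the exposure a genetic phenotype alone would predict. Exposure
   changes are ordinal categories — decreases binned 0–30 / 31–50 / 51–80 /
   81–100 %, increases binned 0–25 / 26–75 / 76–200 / >200 % — and two
   changes combine by *ordinal escalation*: same-direction inputs move one
   bin beyond the stronger input (saturating at the extreme bin);
   opposite-direction inputs pull the stronger input back one bin; "none"
   is the identity. When opposite-direction inputs occupy the same bin
   index, the decrease counts as stronger, because at equal index a
   decrease is the larger fold-change in exposure (a 31–50 % loss is a
   1.4–2.0× fold-change, a 26–75 % gain only 1.3–1.8×). Rule severity then
   escalates one level per bin by which the combined change exceeds the
   rule's own AUC change (capped at contraindicated, never reduced).
   The alternative combination rule — interval arithmetic on retention
   fractions — cannot produce the escalations observed in curated
   interaction data (a 51–80 % decrease plus a 31–50 % decrease lands in
   the 81–100 % bin, which midpoint interval multiplication never reaches);
   it is kept as a reference oracle in the test-suite. The package also
   exposes the equivalent phenotype-ladder view (`effective_phenotype`):
   each inhibitor shifts a metabolizer phenotype one step toward poor, each
   inducer one step toward ultrarapid, saturating at the ladder ends.
   A single step per modifier, regardless of bin magnitude, is the minimal
   model consistent with the curated combinations; no public source grades
   inhibitor strength on this categorical scale.

3. **Population prevalences.** Each gene carries a probability
   distribution over its interpreted phenotypes. Phenotypes are drawn
   independently across genes (pharmacogenes are unlinked; nothing else is
   computable from gene-level prevalences), while within a gene all drugs
   see the *same* draw, which the engine handles exactly.

The score is `PIP = 1 − ∏ (1 − P(cluster actionable))` over gene clusters:
genes coupled by a two-gene rule are merged and enumerated jointly over
the Cartesian product of their phenotype vocabularies (exact, and cheap
for ≤ 25 genes); all other genes are singletons. The adjusted score
restricts to the genes actually ordered. Probabilities stay in double
precision end to end; half-up rounding to one decimal happens only in the
report layer.

Two exclusion filters mirror clinical reporting practice: opportunities
whose best post-phenoconversion severity is below moderate are dropped,
and a phenoconversion escalation is dropped when it does not *exceed* the
severity of the corresponding gene-free drug–drug interaction (testing
would add nothing). The filter applies per co-medication context; the base
drug–gene opportunity always survives, which keeps the score monotone in
the medication list.

### Design choices on genuinely open points

* **Two-gene rules carry their stated severity.** Co-medication modifiers
  do not escalate drug–gene–gene rules: the interaction taxonomy (DGI /
  DDGI / DGGI / DDI / DDDI) has no 2-drug + 2-gene class, and the engine
  and detector must agree exactly. Phenoconversion evidence enters a
  two-gene rule through its stated severity and AUC change.
* **Severity escalation is capped stepwise** (one level per bin, at most
  two, capped at contraindicated); whether extreme combined exposure may
  skip levels is not publicly specified.
* **Kind tie-breaks** at equal severity prefer gene-involving classes
  (DGGI > DDGI > DGI > DDDI > DDI), then lexical drug order.
* **Score bands** are [0, 0.25) low, [0.25, 0.50] moderate, (0.50, 1]
  high; published phrasing is ambiguous at the boundaries, so both edge
  values fall in the moderate band, documented and tested.
* **Detection is restricted to tested genes**, mirroring the adjusted
  score: a rule whose gene (or second gene) was not tested cannot fire.
* Unknown medications are ignored by default (real lists contain vitamins
  and supplements without PGx impact); `strict` mode raises instead.

## Demonstration knowledge base

The production knowledge bases behind commercial PGx decision support are
proprietary, so the package ships an open demo KB (schema `pip-kb/1`)
calibrated to published medication-level scores. Calibration convention:
each drug's actionable phenotypes are chosen so their prevalence mass
equals the published single-medication score, and co-substrates of a gene
nest their actionable sets (smaller inside larger). Concretely:

| gene | poor | intermediate | normal | rapid | ultrarapid |
|---|---|---|---|---|---|
| CYP2D6 | .06 | .39 | .50 | .02 | .03 |
| CYP2C19 | .02 | .27 | .41 | .27 | .03 |

giving metoprolol {PM, IM, UM} = 0.48, amitriptyline {PM, IM, RM, UM} =
0.50, codeine/tramadol {PM, UM} = 0.09, clopidogrel and the proton-pump
inhibitors {PM, IM} = 0.29, and es(citalopram) {PM, IM, UM} = 0.32 (its
rapid-metabolizer rule is monitor-level and contributes no mass but
participates in phenoconversion). No per-phenotype breakdown of the
published scores is public: this mass assignment is a package convention,
not published fact. The same applies to the overlap structure; a published
worked value of 62 % for es(citalopram) + clopidogrel + codeine/tramadol is
not reproducible without the proprietary overlap structure (the demo KB
gives 38.1 %).

Modifier magnitudes and gene-component AUC bins are set so the ten most
common published drug-drug-gene combinations reproduce exactly; prodrug
rules (clopidogrel, codeine, tramadol) are marked `metabolite`, and the
data layer flips an inhibitor's sign for them (inhibiting the activating
enzyme lowers active-metabolite exposure). Prevalences for the remaining
panel genes are plausible North-American-like values carrying no demo
rules except simvastatin–SLCO1B1 and abacavir–HLA-B\*57:01, which exercise
the larger panels.

## Synthetic cohorts

`simulator` generates cohorts with the structure the validation assumes,
not any real cohort's joint co-prescription distribution:

* **Medication count**: shifted negative binomial (dispersion 2) truncated
  to [1, 62] with mean 9.4 — only the mean and range of real regimens are
  public, and an overdispersed count model with a long tail is the
  standard choice.
* **Medications**: two-stage — clinical areas weighted (cardiology .21,
  behavioral health .17, pain management .14, gastroenterology .11, nine
  further areas sharing the rest), drugs uniform within area, sampled
  without replacement via the exponential-race trick. The drug pool mixes
  substrates, inhibitors/inducers, and ~45 inert entries so that regimens
  dilute realistically.
* **Panels**: 3/5/14/25-gene panels with exclusive shares derived from a
  36,511-order population (≈ 21.6 / 69.6 / 3.1 / 5.7 %); phenotypes are
  sampled per tested gene from the prevalence table.
* **Demographics** (age ~ N(61, 18²) clipped to [0, 110], sex, race
  marginals) are annotations only and never enter scoring.

Passing calibration on these cohorts shows that the engine, detector, and
prevalence model are mutually consistent — the score equals the detection
rate *by construction* when phenotypes truly follow the prevalence table.
It does not show that any particular prevalence table matches a real
population, nor that real co-prescription patterns are captured.

## Validation statistics

* `nnt(n, count) = n / count`, exact before rounding; undefined (reported
  as "—") when no patient has a finding.
* `one_prop_ztest(count, n, p0)`: z = (count/n − p0) / √(p0(1−p0)/n),
  two-sided normal tails, no continuity correction; the mean adjusted
  score is the fixed null proportion. Because patient-level scores are
  heterogeneous, the true variance of the count is Poisson-binomial and
  smaller than the binomial term used, so the test is mildly conservative
  — appropriate for a calibration check.
* `panel_summary` filters patients whose ordered genes cover a panel's
  minimum set, then reports means, rate, NNT, and the z-test.
* `threshold_bins` tabulates highest-severity interaction classes per
  score band; the fraction of patients with any interaction is reported
  per band and checked to be non-decreasing by the test-suite (it is not a
  runtime assertion: tiny cohorts can violate it by chance).

## Problem sizes and numerics

The test-suite's calibration check uses 100 replicates of 10,000 simulated
patients (≈ 1.5 minutes with the caching cohort scorer, which memoizes by
relevant-medication profile and phenotype assignment); oracle equivalence
uses 200 randomized small knowledge bases (≤ 3 genes, ≤ 5 drugs) compared
to full joint enumeration at 1e-9. Cluster enumeration is exact; no
sampling enters the score itself. All randomness flows through explicit
seeds; fixing a seed fixes a cohort exactly.

## Known limitations

* Gene-level independence ignores any real correlation between
  pharmacogene phenotypes and prescribing (confounding by indication).
* Ordinal AUC algebra does not model dose, timing, or inhibitor potency.
* The demo knowledge base covers a small drug set; its calibration
  conventions are documented above and isolated in one constructor.
* Race/ethnicity-stratified prevalences, age weighting, and
  diplotype-to-phenotype translation are out of scope.
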