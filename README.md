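# pipscore

Pharmacogenomic interaction probability (PIP) scoring: given a patient's
medication list and the population prevalence of interpreted pharmacogene
phenotypes, predict the probability that panel-based pharmacogenomic (PGx)
testing would reveal **at least one evidence-based, actionable drug–gene
interaction** — a DGI (drug–gene), DDGI (drug–drug–gene, i.e.
phenoconversion by a co-medication), or DGGI (drug–gene–gene) of moderate,
major, or contraindicated severity backed by FDA labelling or CPIC level
A/B guidance (an *EADGI*).

The package is for biostatisticians and PGx informaticists who want an
open, testable implementation of this class of pre-test risk score: a
documented knowledge-base schema, the phenoconversion AUC algebra, the
probability engine with its exact enumeration oracle, a post-test
interaction detector, a synthetic cohort simulator, and the validation
statistics (EADGI rate, number needed to test, one-proportion z-test,
stratified tabulations).

## The score

For a medication list *M* and tested gene set *G*, every knowledge-base
rule (drug *d* ∈ *M*, gene *g* ∈ *G*, phenotype *φ*) defines an
*opportunity* that fires when the patient's phenotype at *g* equals *φ*.
Co-medications that inhibit or induce the enzyme shift exposure further;
their categorical AUC effects combine with the gene effect by ordinal
escalation, and severity escalates one level per bin the combined change
exceeds the rule's own. Opportunities whose best severity stays below
moderate, or whose phenoconversion does not exceed the matching gene-free
drug–drug interaction, are excluded. With phenotypes drawn independently
per gene from population prevalences *p<sub>g</sub>(φ)*,

    PIP(M, G) = 1 − ∏_c (1 − P(cluster c actionable)),

where clusters are genes coupled by two-gene rules (singletons otherwise)
and each cluster probability is computed by exact enumeration over the
Cartesian product of its genes' phenotypes. The *adjusted* PIP restricts
*G* to the genes actually ordered on the patient's panel; number needed to
test is NNT = 1/PIP.

The score is calibrated by construction: over patients whose phenotypes
follow the prevalence model, the expected fraction with a detected
actionable interaction equals the mean score — the property the validation
statistics test on simulated cohorts.

## Worked example

The bundled demonstration knowledge base is calibrated so that
single-medication scores match published medication-level values
(metoprolol 48%, omeprazole/pantoprazole/clopidogrel 29%, es(citalopram)
32%, tramadol/codeine 9%, amitriptyline 50%):

```sh
$ pipscore score --meds "clopidogrel,tramadol,omeprazole" --genes CYP2C19,CYP2D6
{
  "pip": 0.3539,
  "pip_pct": 35.4,
  "adjusted_pip": 0.3539,
  "adjusted_pip_pct": 35.4,
  "opportunity_count": 6,
  "per_cluster": {
    "CYP2C19": 0.29000000000000004,
    "CYP2D6": 0.09
  }
}
```

Reading: clopidogrel and omeprazole share CYP2C19 (actionable phenotype
mass 0.29, the smaller actionable set nested in the larger, so the union
stays 0.29); tramadol contributes 0.09 on CYP2D6; the two clusters are
independent, so PIP = 1 − 0.71 × 0.91 = 35.4%. Tramadol also inhibits
CYP2C19, which escalates clopidogrel's intermediate-metabolizer rule from
moderate to major (a DDGI) but adds no new probability mass because those
phenotypes were already actionable. One patient in 1/0.354 ≈ 2.8 with this
regimen is expected to have an actionable finding.

Other entry points:

```sh
pipscore kb demo --out kb.json          # write the demo KB (schema pip-kb/1)
pipscore kb validate kb.json
pipscore simulate --n 10000 --seed 1 --out cohort.tsv
pipscore validate --cohort cohort.tsv --out report/
pipscore run-study --n 10000 --seed 1 --out study/
```

`run-study` simulates a cohort, scores and genotypes it, detects
interactions, and writes panel summaries (mean PIP, mean adjusted PIP,
EADGI rate, NNT, z-test p-value), interaction counts by clinical area, top
medications, score-threshold bins, and a manifest with the knowledge-base
checksum.

## Limitations

The production knowledge base and the tested patient cohorts behind
published validations are proprietary; the demo knowledge base documents
its calibration conventions and the simulator its distributional
assumptions (see `docs/methods.md`). Race/ethnicity-stratified prevalences,
age/Beers-criteria weighting, diplotype-to-phenotype translation, and EHR
integration are out of scope.
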