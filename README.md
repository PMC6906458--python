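# cnascape

Copy-number association landscapes and elastic-net phenotype prediction for
tumor cohorts.

Many solid epithelial cancers are substantially copy-number driven: recurrent
DNA gains and losses shape expression programs (proliferation, estrogen
signaling, immune infiltration) that are usually read out with mRNA-based
gene-expression signatures. `cnascape` implements the two complementary ways
of linking segment-level somatic copy-number alterations (CNAs) to such
phenotypes, for researchers who want to ask whether a phenotype is DNA-dosage
explained — and predictable from DNA alone, e.g. from a clinical gene panel:

1. **Genome-wide association landscape.** For one signature with per-sample
   score *s* and gene-level CNA scores *c<sub>g</sub>* (derived from CBS
   segmentation by the GISTIC-style *extreme* method), every gene is tested
   twice: a Spearman rank correlation ρ(s, c<sub>g</sub>), and one-sided
   Fisher exact tests comparing the frequency of gain (c<sub>g</sub> > 0.3)
   or loss (c<sub>g</sub> < −0.3) between the top score quartile and the
   rest. Each p-value family is Benjamini–Hochberg adjusted across genes; a
   gene is called a candidate **driver** when q<sub>corr</sub> < 0.01,
   q<sub>gain</sub> < 0.01 and ρ > 0, and a candidate **repressor** when
   q<sub>corr</sub> < 0.01, q<sub>loss</sub> < 0.01 and ρ < 0. A linear-model
   variant (score ~ CNA + subtype indicators) removes associations explained
   by molecular-subtype composition.

2. **Elastic-net prediction.** Segment-mean CNA features *X* predict a binary
   phenotype *y* (e.g. top-third vs bottom-two-thirds signature score) by
   penalized logistic regression minimizing

   ```
   (1/n)·NLL(β) + λ·[ α·‖β‖₁ + (1−α)/2·‖β‖₂² ]
   ```

   Tuning follows a fixed protocol: a stratified 70/30 train/test split; a
   grid of α ∈ {0.1, …, 1.0} × 100 log-spaced λ per α (λ_max from the
   null-model gradient); 200 rounds of Monte-Carlo cross-validation at 0.75
   training fraction scored by classification accuracy; ROC AUC on held-out
   sets, with AUC > 0.75 on every test set defining "highly predictable";
   and a label-permutation null to calibrate that threshold. A gaussian
   variant handles continuous outcomes, and segment coefficients re-map to
   member genes for interpretation. Kaplan–Meier/log-rank utilities check
   whether tertile risk groups — from observed scores or model
   probabilities — stratify 10-year cause-specific survival.

A synthetic-cohort generator plants driver segments with known weights in a
segment-structured genome and emits every input format the pipeline reads
(SEG, BED-like gene table, expression TSV, GMT, clinical TSV, MAF, segment
membership TSV), so the whole method is testable end to end without any
external download.

## Worked example

Generate the reference cohort (600 samples, 2000 genes, 40 segments, one
planted driver segment with weight 1), build the landscape, train a
classifier on a reduced tuning grid, and check survival stratification:

```python
import cnascape as cs
from cnascape.simulate import SimulationConfig, simulate_cohort

cohort = simulate_cohort(SimulationConfig(seed=20191211))
X = cs.segment_scores(cohort.gene_cna, cohort.segment_defs).T   # samples x segments
scores = cs.score_median(cohort.expression, cohort.signatures[0])

land = cs.landscape(scores, cohort.gene_cna)
driver = cohort.truth.driver_segments[0]
driver_genes = cohort.segment_defs.members[driver]
print("driver genes called positive_gain:",
      f"{(land.loc[driver_genes, 'call'] == 'positive_gain').mean():.0%}")

labels = cs.dichotomize(scores, "top_third")
split = cs.stratified_split(cohort.clinical,
                            ["gender", "er_status", "os_months", "os_event"],
                            seed=20191211)
clf = cs.ElasticNetPhenotypeClassifier(alphas=(0.1, 0.5, 1.0), n_lambda=20,
                                       n_rounds=50, random_state=20191211)
clf.fit(X.loc[split.train], labels.labels.loc[split.train])
ev = cs.evaluate(clf.model_, X.loc[split.test], labels.labels.loc[split.test])
print(f"tuned (alpha, lambda) = ({clf.alpha_}, {clf.lambda_:.4f})")
print(f"test AUC = {ev.auc:.3f};  driver coefficient = {clf.coef_[driver]:.2f};"
      f"  segments selected = {int((clf.coef_ != 0).sum())}")

records = cs.censor_10yr_cause_specific(cohort.survival)
rg = cs.risk_groups(scores, records)
chi2, p = cs.logrank(records, rg.groups)
print(f"log-rank p = {p:.2e};  events high {rg.events['high'][0]}/{rg.events['high'][1]},"
      f" low {rg.events['low'][0]}/{rg.events['low'][1]}")
```

Output:

```
driver genes called positive_gain: 100%
tuned (alpha, lambda) = (0.5, 0.0360)
test AUC = 0.923;  driver coefficient = 3.17;  segments selected = 12
log-rank p = 2.88e-02;  events high 116/200, low 209/400
```

All 50 genes of the planted driver segment are jointly significant (and no
gene outside it), the model recovers the driver with a positive coefficient
and classifies the held-out samples at AUC 0.92, and the top-third risk group
has elevated 10-year disease-specific mortality (58% vs 52% events; log-rank
power across replicate cohorts is exercised in the test suite).

The same protocol is available from the shell:

```bash
cnascape simulate --seed 20191211 --out data/
cnascape score data/expression.tsv data/signatures.gmt --out scores.tsv
cnascape cna data/copy_number.seg data/genes.bed --segments data/segments.tsv --out gene_cna.tsv
cnascape associate scores.tsv gene_cna.tsv --out landscape.tsv
cnascape run config.yaml        # full pipeline from a YAML config
```

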