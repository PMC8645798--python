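# dfnckit

Dynamic functional network connectivity (dFNC) states and how they change
with age — as a reusable, tested Python pipeline.

Resting-state fMRI connectivity is usually summarized as one correlation
matrix per scan ("static" connectivity). Dynamic approaches instead let
connectivity vary over the session: a tapered window slides across the
ICA component time courses, each window's correlation matrix is estimated
with a graphical lasso (L1-penalized sparse inverse covariance, penalty
chosen per session by cross-validated held-out likelihood), the
Fisher-Z-transformed window patterns from every session are pooled and
clustered with correlation-distance k-means into a small set of recurring
**dynamic states**, and each session is summarized by its **mean dwell
time (MDT)** per state, its **number of transitions (NT)** between
states, and the temporal SD of every connection. In a two-visit
longitudinal design those summaries become outcomes of random-intercept
linear mixed models

```
y_ij = β0 + β_age · age_c,ij + β_sex · I(girl_i) + u_i + ε_ij ,   u_i ~ N(0, σ_u²)
```

with age centered at the visit-1 mean, Box-Cox-transformed dwell times,
step-wise likelihood-ratio screening of age² and age×sex terms,
sex-stratified fits where the interaction holds, Benjamini–Hochberg FDR
across outcomes, and clustered-bootstrap prediction bands.

The package is for researchers who work with ICA component time courses
(the pipeline starts *after* spatial preprocessing and group ICA) and for
methodologists who need a fully synthetic, ground-truth-bearing testbed:
cohort data of this kind are generally not public, so `dfnckit` ships a
generator that emits longitudinal cohorts of state-switching multivariate
Gaussian time courses with motion traces, artifacts, and *planted* age
and sex effects on state dwell dynamics — every stage of the pipeline is
validated by parameter recovery against that ground truth.

## Worked example

```python
import dfnckit as dk

# a 6-subject, two-visit synthetic cohort with the default planted effects
design = dk.default_design(n_subjects=6, retention=1.0, seed=21)
model = dk.DynamicFNCAnalysis.from_synthetic(design)
model.config.clustering["n_init"] = 20     # restarts; default 500
res = model.fit()
print(res.summary())
```

prints (abridged):

```
Dynamic functional network connectivity analysis
================================================
Sessions: 12 scanned, 12 passed motion QC
States: k=5, global occupancy state 1: 35.1%, state 2: 28.2%, state 3: 18.6%, state 4: 9.7%, state 5: 8.4%
Windows per session: 171

Age- and sex-associations with state summary metrics
(random-intercept linear mixed models; dwell times Box-Cox transformed)

      outcome term  estimate  ci_low  ci_high  p_value      AIC      BIC   p_fdr
   mdt_state1  age   -0.6435 -1.2990   0.0119   0.0543  62.7745  65.1990  0.1926
   mdt_state1  sex   -0.8470 -4.1263   2.4322   0.6127  62.7745  65.1990  0.7352
   ...
n_transitions  sex   -1.5294 -2.7698  -0.2891   0.0157  40.9572  43.3817  0.0940
```

Each scan session contributes 171 windows of 44 s (25 TR at TR = 1.76 s,
step 1 TR); the five states are numbered by descending global occupancy.
The `estimate` column for `age` is the change in (Box-Cox-transformed)
dwell time per year of age. At this toy cohort size (6 subjects) none of
the planted effects reach FDR significance, as the wide confidence
intervals show — sign and significance recovery of the planted effects
is demonstrated at realistic cohort sizes by the validation script
below. `res` also carries the QC table,
per-session Fisher-Z window matrices with their selected penalties, state
centroids, occurrence-over-scan profiles with bootstrap bands, and
per-pair temporal SDs; `res.save(outdir)` writes everything as
tab-separated text plus a run log that fully reconstructs the
configuration.

The same pipeline is scriptable from the shell:

```bash
dfnckit simulate --out cohort/ --subjects 20 --seed 1
dfnckit run-all --manifest cohort/manifest.tsv --out results/ --seed 1
# or stage by stage: qc, fnc, cluster, metrics, stats
```

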