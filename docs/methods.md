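# Methods

## Scope

`chickstress` re-implements, as one tested pipeline, the statistical
analysis of a sex-stratified early-stress experiment in chickens: two
treatment arms (early stress, ES, vs control, C) crossed with sex, scored
by an open-field (OF) test, a tonic-immobility (TI) test, same-sex
dominance pair contests, gonadal hormone titres at sexual maturation, and
hypothalamic expression profiling at two ages (28 d, with a
baseline/restraint split, and 213 d, baseline only) on pooled RNA samples.
The package consumes already-normalised log2 expression; array
normalisation (RMA) and all wet-lab steps are out of scope.

## Behavioural and endocrine statistics

- **Normality gate.** Anderson–Darling test of composite normality per OF
  endpoint.  The statistic comes from `scipy.stats.anderson`; since scipy
  reports no P for the estimated-parameters case, the P value is the
  standard approximation applied to the small-sample corrected statistic
  `A*² = A²(1 + 0.75/n + 2.25/n²)` (piecewise exponential in `A*²`).  The
  gate only warns: the GLM is still reported, flagged, when it fails.
- **Two-factor GLM.** OLS of the endpoint on treatment, sex and their
  interaction, partial (Type III) sums of squares with sum-to-zero factor
  coding — the convention whose F values match commercial-package defaults
  on unbalanced 2×2 designs; sequential (Type I) SS is available and
  coincides with Type III on balanced data.  When the interaction P falls
  below α, treatment is re-tested within each sex by a one-way F
  (equivalently squared pooled t) using the stratum's own residual
  variance, df (1, n_stratum − 2).
- **Tonic immobility.** Latencies are capped at 600 s; times at the cap
  are right-censored, never events.  Kaplan–Meier curves and the log-rank
  test (df = 1, hypergeometric variance under ties) are delegated to
  `lifelines` and cross-checked in the tests against a hand-rolled
  observed-minus-expected accumulator.  Birds that never entered TI carry
  a recorded rightening time of 0; a zero-time event is degenerate for the
  product-limit estimator, so these birds are excluded from the rightening
  analysis by default, with inclusion-as-immediate-event available as an
  option (which policy the original analysis used is not stated anywhere,
  so neither is asserted as "the" analysis).
- **Dominance.** Exact binomial test of the ES win count against p = ½,
  two-sided by doubling the smaller tail (capped at 1).  Under this
  convention 1 ES win in 9 pairs gives P = 2(1+9)/2⁹ = 0.0391; the
  minimum-likelihood convention is available as an option.  Pairs are
  analysed within sex only; mixed-sex tables are rejected.
- **Hormones.** Independent two-sample t on log concentrations with the
  pooled-variance df n₁+n₂−2 (df 14 at 8 birds per arm); the t statistic
  is invariant to the log base.  Non-positive concentrations are an input
  error when the transform is on.

## The transcriptomic persistence procedure

Per age × sex × condition stratum the per-gene fold change is
`FC_g = mean(log2 ES pools) − mean(log2 C pools)`.  For each sex the K
genes with the largest fold changes at each of the two ages are
intersected ("overlapping genes"; K defaults to 1000) and the Pearson
correlation of their (FC_young, FC_adult) pairs is the persistence
statistic, tested with `t = r√(m−2)/√(1−r²)`, two-sided.  Conventions:

- "Largest fold change" means largest |FC| (down-regulation is as
  informative as up-regulation); signed-descending ranking is an option.
- Ties in |FC| are broken by lexicographic gene id, making the top-K list
  deterministic across platforms.
- The gene universe is every gene on the matrix; no expression filter and
  no P-value filter are applied before ranking.
- An overlap of fewer than 3 genes returns a defined result with the
  correlation marked absent (`None`) instead of raising.
- Alongside r, the result reports the null expectation K²/G of the
  overlap size and its hypergeometric upper-tail P: under independent
  profiles the overlap is Hypergeom(G, K, K), which the test suite
  verifies by goodness of fit over 500 simulated replicates.

**Permutation null.**  Because the analytic t assumes the overlap set is
fixed, a treatment-label permutation null re-runs the entire
fold-change → top-K → overlap → r procedure with labels permuted
independently at the two ages; the empirical P is
`(1 + #{|r_perm| ≥ |r_obs|})/(1 + n_perm)`.  At the study's pooled design
only C(4,2)² = 36 pool-level relabelings exist, so pool-level input is
refused with the attainable minimum P; passing individual-level matrices
with `pool_sizes=(3, 4)` permutes individuals and re-pools each time,
which is the exchangeability the design actually supports.  The
permutation loop runs through a vectorised numpy path that repeats the
pipeline arithmetic exactly (verified against the pandas path to 1e-9 on
every call); seeds make it fully reproducible.

**Enrichment.**  Overlapping genes from significantly correlated pairs
are tested per gene set by the one-sided hypergeometric (Fisher) upper
tail within the matrix's gene universe, Benjamini–Hochberg adjusted across
terms.  This is a plain hypergeometric test over user-supplied GMT sets;
no claim is made that it replicates EASE-modified web-service scores.

## Synthetic data generator

The generator emulates the study design so every stage has ground truth:

| parameter | default | meaning |
|---|---|---|
| `n_birds_per_cell` | 20 | birds per sex × treatment for behaviour tables |
| `of_effect` | 0.65 | standardized downward shift of ES-male OF distance |
| `ti_hazard_ratio` | 2.0 | ES/C hazard ratio, male time to first head movement |
| `p_es_dominant_f` / `_m` | 0.11 / 0.5 | probability the ES bird wins its pair |
| `p_no_ti` | 0.1 | probability a bird never enters TI (rightening scored 0) |
| hormone params | T: ln 2.5 ± 0.5, effect −1.0 sd; E2: ln 180 ± 0.4, effect −0.6 sd | log-normal titres (ng/ml, pg/ml) |
| `n_genes` / `n_persistent` | 5000 / 300 | genome size; genes with a persistent male signature |
| `fc_sd` / `noise_sd` | 0.5 / 0.2 | per-gene treatment-effect and residual sd (log2) |
| young/adult per cell | 6 / 8 | individuals per expression stratum, pooled 3 / 4 |

Distributional families are modelling choices, not claims about the
original data (which reports none): OF endpoints are zero-truncated
normals; TI times are Weibull (shape 1.1, scales 250 s / 450 s for head
movement / rightening) with a proportional-hazards treatment effect and
the 600 s cap, chosen for censoring realism; hormones are log-normal.
Effect-size defaults were set to the magnitudes the study reports (e.g.
the female dominance win probability ≈ 1/9, hormone shifts giving |t| ≈ 2
and ≈ 1.2 at n = 8) before any calibration against the test suite.

Expression follows
`log2 x = baseline_g + male_g + restraint_g + delta_g·[ES] + ε`,
ε ~ N(0, noise_sd).  The `n_persistent` signature genes draw
`delta_g ~ N(0, fc_sd)` per stratum — but in males the young-restraint
and adult strata *share* one latent draw, which is what induces a positive
cross-age fold-change correlation, while young-baseline (males) and all
female strata draw independently.  This reproduces the study's qualitative
outcome: all four sex × stratum pairs show overlap enrichment, but only
the male restraint-vs-adult pair is correlated.  Pooling mimics physical
RNA mixing: members are averaged on the linear intensity scale and
re-expressed in log2 (log-scale averaging is a switchable option).  One
master seed drives every sub-stream by fixed offsets; a fixed seed gives
bit-identical tables.

What the generator does **not** emulate: probe-level structure, array
batch effects, heteroskedastic intensity-dependent noise, correlated gene
modules, unequal cell sizes, or drop-out/mortality.  Passing tests
therefore demonstrate correctness and calibration of the statistics under
a clean version of the design, not robustness to real microarray artefacts.

## Problem sizes and runtime choices

Monte-Carlo checks run at desk scale: type-I calibration uses 500
replicates at 20 birds per cell; the null-overlap law uses 500 replicates
at G = 10 000, K = 1000; the power check uses 100 replicates of the
G = 5000 / 300-persistent-gene scenario with 199 permutations each.  The
acceptance script analyses one full simulated study at the default design
plus a 200-replicate null-overlap measurement.

## Known limitations

- The analytic t for r conditions on the selected overlap; under strong
  selection it is anti-conservative, which is why the permutation P is
  reported alongside it.
- Head-movement and rightening times are drawn independently, so a bird
  may right before it first moves; irrelevant for the per-endpoint
  survival analyses, but not physiological.
- Hormone inference at n = 8 per arm is underpowered, as in the study;
  single simulated replicates routinely miss the −1 sd testosterone shift.
- Reproduction of the published numbers requires the deposited per-bird
  workbook / expression matrices supplied by the user; the repository
  ships no third-party data.
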