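# Methods

## Data model

The pipeline's numeric substrate is a features × samples matrix of
extracted-ion-chromatogram (XIC) intensities, non-negative with zero
encoding non-detection. Each feature carries an m/z (sanity-checked
against a 150–1500 Da acquisition window), a retention time (seconds
internally; a reader flag converts minutes) and exactly one molecular
subnetwork; features left unclustered by molecular networking become
singleton subnetworks `S:<feature_id>`. Samples carry one of three
roles: extraction `blank`, seawater `control`, or `treatment`. Zeros and
missing cells are unified to 0 at read time because presence/absence is
the semantically meaningful state for the filtering rules.

## Filter cascade

Three stages, in order, with an auditable count report:

1. **Background.** Feature `f` is flagged when its mean log₁₀ intensity
   over non-blank samples (non-detections entering as
   `nondetect_log_value`, default 0 = log₁₀ of one count; excluding them
   would make sparsely detected contaminants unfilterable) is ≤
   `blank_multiplier` (default 2) × the maximum *log₁₀* blank intensity.
   Applying the multiplier on the log scale on both sides is the only
   scale-consistent reading — comparing a log quantity to twice a raw
   count mixes units; the raw-blank variant remains available
   (`blank_max_on_log_scale: false`) for sensitivity analysis. A feature
   never seen in blanks has blank max 0 and is effectively never
   flagged while detected. Subnetworks with strictly more than
   `background_subnetwork_fraction` (default 0.5) flagged members are
   removed wholesale, non-flagged members included. Blank columns leave
   the analysis set after this stage.
2. **Transient.** Present (XIC strictly > 0) in at most
   `transient_max_samples` (default 2) non-blank samples with the
   per-feature maximum strictly below `transient_intensity_threshold`
   (default 5·10⁴ counts). Presence is counted over non-blank samples
   only, consistent with blanks having already left the analysis.
3. **Rare.** Subnetworks whose maximum feature intensity is strictly
   below a reference "average ion intensity", by default the grand mean
   of the *nonzero* entries of the post-transient matrix
   (`rare_reference: grand_mean_nonzero`; `grand_mean_all` and
   `mean_of_feature_max` are selectable since "average" admits several
   readings). Because intensities are heavy-tailed, this mean sits well
   above the typical entry; with only ~10 samples a subnetwork's
   maximum is often below it, so the rule bites much harder at
   simulation scale than it would on a several-hundred-sample study —
   low-abundance planted-enriched subnetworks can legitimately be
   removed here, which is why recovery statistics downstream are
   reported conditional on filter survival.

Tie semantics follow the rule wording exactly: "not greater than" → ≤,
"below" → <, "greater than 50%" → strict >. Stages 1–2 are idempotent;
stage 3 is not (removing features moves the reference mean), which is a
property of the rule, not a defect.

## Subnetwork enrichment

Feature intensities are summed per subnetwork and sample; statistics run
on log₁₀ sums (same non-detection convention). Inference is a two-stage
screen-then-test:

* **Screen.** A random forest (default 29,188 trees; simulation-study
  profile 300) classifies control vs treatment samples from the
  subnetwork profiles. Importance is classical out-of-bag
  mean-decrease-accuracy: for each tree, accuracy on its out-of-bag
  samples before vs after permuting one predictor, averaged over trees
  and over `n_importance_reps / n_predictors` (min 1) independent
  permutations per predictor (default 10,000 total; study profile
  1,000). The forest-level alternative (permute, then score the whole
  forest's majority vote) is degenerate at n ≈ 10 samples — trees
  memorize the training set, every importance is ~0, and the threshold
  below selects everything — so the per-tree OOB formulation is used.
  Subnetworks with MDA ≥ mean + `mda_sd_multiplier` × SD (sample SD,
  n−1; inclusive ≥, so an all-equal MDA vector selects everything) are
  carried forward. With `rng_seed` fixed the screen is bit-reproducible.
* **Test.** Selected subnetworks get a two-tailed two-sample *t*-test on
  log₁₀ sums. Pooled variance is the default (the model-formula idiom
  this mirrors defaults to pooled; Welch via `welch: true`). Zero
  variance in both groups yields p = 1 at equal means, p = 0 with a
  warning otherwise. BH-FDR correction runs across the *selected* family
  only, matching a screen-then-test design. Direction requires
  q < `alpha` (default 0.05) and the corresponding group mean higher.
  Screening and testing on the same data is anti-conservative by
  construction; the null-calibration study below quantifies the
  realized behaviour of the full two-stage procedure.

Treatment-enriched subnetworks in which at least
`treatment_only_fraction` (default 1.0, i.e. all) member features are
zero in every control sample are flagged treatment-only. Ontology
composition partitions the enriched pool's raw summed intensity per
treatment sample by consensus superclass (missing → "unclassified"),
reporting mean ± sample SD of percentages across treatment samples;
per-sample percentages sum to 100 exactly.

## Settlement statistics

Per-well settled/added proportions are variance-stabilized with the
angular transform arcsin√p (radians, [0, π/2]); the analysis endpoint is
the final (day-3) cumulative count, with per-day analysis available. A
Type-II two-way factorial ANOVA (statsmodels OLS) covers the two design
factors; single-level factors are dropped with a warning, and a
zero-variance response reports F = 0, p = 1 for every term rather than
0/0.

Dunnett many-to-one comparisons use the max-t statistic of the
multivariate-t null with correlation
ρᵢⱼ = √(nᵢnⱼ/((nᵢ+n₀)(nⱼ+n₀))) and pooled residual degrees of freedom,
evaluated by seeded Monte-Carlo integration (`dunnett_draws`, default
10⁵; deterministic given the seed). The alternative is one-sided
"greater than control" by default — the scientific question is whether a
treatment *induces* settlement — with two-sided via config. A
single-treatment family is computed analytically and equals the
one-sided pooled t-test exactly. For fractionation designs each
treatment is tested against the unfractionated seawater control (one
family across all treatments) and against its own resin control
(per-resin Dunnett, BH pooled across all resin-side comparisons);
significance requires *both* FDR-corrected p-values below `alpha`, and a
treatment with no resin control is reported not evaluable. FDR family
boundaries are stated in each result's metadata since several scopings
are defensible.

## Synthetic data

The generator emulates the structure the pipeline assumes rather than
raw spectra. Per-feature baseline log₁₀ intensity is N(μ=5.0, σ=0.8)
across subnetwork centers with a within-subnetwork spread of 0.8;
replicate noise across samples is N(0, 0.2) on the log₁₀ scale (~60%
CV, a realistic biological-replicate variability for untargeted
seawater-exudate runs). Detection dropout is logistic in log₁₀
intensity (midpoint 3.0, scale 0.4), so faint features plausibly trip
the transient rule. Background features carry blank intensities at a
configurable carry-over ratio (default 1.0) of their sample level, so
the blank rule flags them by construction; transient features are
forced to ≤ 2 detections below the intensity threshold; enriched
subnetworks shift all member features by `effect_log10` (default 0.602,
i.e. 4-fold) in treatment samples; treatment-only subnetworks
additionally have control entries zeroed. Settlement counts are
Binomial(larvae per well, p) per well with uniform settlement-day
assignment, making daily cumulative counts monotone. Defaults: 200
subnetworks with geometric member counts (mean 5), 3 blanks, 5 controls,
5 treatments, 5 wells × 10 larvae × 3 days.

What the generator does *not* model: chemically realistic m/z or
retention-time structure, correlated noise between co-eluting features,
batch or drift effects, non-binomial overdispersion in settlement.
Passing recovery tests therefore demonstrates correctness of the
statistical machinery under the stated model, not performance on any
particular real dataset.

## Operating characteristics

`exocue.evaluation` (driven by `scripts/acceptance.py` and the test
suite) measures, per run seed:

* exact agreement of all three filter flag sets with naive
  definition-level recomputations on 100 random matrices (≤ 50 × 12);
* sensitivity/specificity of background and transient flagging against
  planted labels (background fraction 0.2, transient 0.1, 10 seeds);
* recovery and empirical FDR for 10% planted 4-fold enrichment among
  200 subnetworks at n = 5 per group (50 seeds), and the null call
  fraction with no effect (200 datasets) — both with the 300-tree /
  1,000-permutation study profile, chosen so the full battery runs in
  minutes on one CPU; results are insensitive to raising either knob;
* Dunnett degenerate-case exactness and k = 3 agreement with a 10⁶-draw
  raw-simulation oracle;
* the dual-control conjunction's any-flag rate under a global
  settlement null (500 datasets) and its detection rate for a 0.8 vs
  0.2 planted elevation (100 seeds).

## Known limitations

* The rare-subnetwork rule depends on sample count through the grand
  mean (see above); cross-study comparisons of retained-feature counts
  should hold the `rare_reference` choice and sample size fixed.
* MDA importance splits between correlated informative subnetworks,
  which can push individually informative subnetworks below the
  mean + 1 SD threshold when many carry the same signal; the threshold
  is honored as specified rather than replaced with a permutation null.
* The screen-then-test procedure's FDR control is empirical, not
  guaranteed: BH runs within the data-selected family.
* Dunnett p-values are Monte-Carlo estimates; precision scales as
  1/√`dunnett_draws` (≈ 0.003 at the default 10⁵).
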