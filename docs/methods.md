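# Methods

`radmetab` reimplements, as a tested pipeline, the analysis chain used to
screen liver and plasma metabolomes of mice for early biomarkers of
radiation-induced liver disease (RILD): paired liver/plasma feature tables
from whole-liver-irradiated (WLI) cohorts (untreated n=6, sham 0 Gy n=8,
10 Gy n=8, 50 Gy n=8) and a whole-body-irradiated (WBI) companion
(0 Gy / 10 Gy, n=12 each) pass through sham-normalization, univariate
screening with an FDR gate, a decision-tree validation cascade, cross-tissue
and cross-modality concordance, correlation/ontology maps, and
class-separation classifiers. Because no raw data are deposited for the
original study, a synthetic cohort generator with planted ground truth
stands in for the data and makes every stage testable.

## Preprocessing

Raw feature tables (instrument-area units, missing cells empty) are:

1. **Imputed** per metabolite with the minimum observed value — the standard
   left-censoring reading of MS missingness. Metabolites observed nowhere
   are dropped.
2. **Sham-normalized**: each metabolite is rescaled so its mean over the
   0 Gy (sham laparotomy) group is exactly 1, per tissue × modality. Fold
   changes are then directly readable; the operation is idempotent and
   cancels in any within-metabolite ratio.
3. **Log-transformed** (natural log) for all hypothesis tests, stabilizing
   the variance growth with signal that multiplicative MS data show.

Fold changes are reported as ratios of *arithmetic* group means on the
sham-normalized scale (not geometric means); the two differ whenever
within-group spread differs, and a numeric check of that divergence is part
of the test suite.

## Univariate screening

Per metabolite and contrast: Welch's unequal-variance t, the Wilcoxon rank
sum (exact null when the combined n ≤ 12 and there are no ties, otherwise
the tie-corrected normal approximation), and a one-way fixed-effects ANOVA
across all dose groups. Significance is the joint gate **p < 0.05 AND
q < 0.10**, with the Welch p as the primary p-value for two-group contrasts
and Benjamini–Hochberg step-up q-values computed within one family per
tissue × contrast (not pooled across tissues). Degenerate inputs follow a
documented rule: both groups constant and equal → p = 1; constant and
unequal → p = 0; fewer than two observations in a group → untestable,
excluded from the FDR family.

BH was chosen over Storey's q-value because it has no tuning parameters;
the adjustment lives behind one function (`adjust_fdr`) and is swappable.
All tests are two-sided.

## Validation cascade

The decision tree asks for replicated evidence before calling a biomarker:

- **validated_primary_confirmed** — significant in 50 Gy vs 0 Gy AND in
  50 Gy vs untreated with the same direction;
- **validated_primary** — significant in 50 Gy vs 0 Gy, unconfirmed at
  50 Gy but significant in a low-dose contrast (10 Gy vs 0 Gy or vs
  untreated) with a consistent direction;
- **validated_low_dose** — not significant at 50 Gy vs 0 Gy but significant
  in *both* low-dose contrasts with the same direction;
- **single_level_unconfirmed** — significant somewhere but matching none of
  the rules above (the "YY" case: one dose level, no confirming contrast);
- **not_significant** otherwise.

Two interpretive choices were open and are fixed here: confirmation
requires the *same direction* (an opposite-direction "confirmation" is
biologically incoherent), and a standalone low-dose validation requires
both low-dose contrasts (otherwise a single-contrast hit could never be
"found only at one Gy"). Both gates (p and q) apply at every node.

**Cross-tissue**: a metabolite carried by the cascade in both liver and
plasma enters the biomarker panel, sorted by the minimum confirming q.
**Cross-modality**: WLI metabolites stuck at single_level_unconfirmed but
significant in the WBI 10 Gy vs 0 Gy contrast are upgraded to
validated_low_dose; for metabolites significant in both modalities the
10 Gy fold-change ratios are compared by which side of 1 they fall on and
labeled shared_same_direction / shared_opposite_direction — the latter is
the signature of responses that reverse under whole-body versus liver-only
exposure. Untreated and sham are never pooled (they separate in PCA).

## Correlation and ontology aggregation

Spearman's rank correlation (average ranks for ties, pairwise deletion,
minimum three complete pairs) is computed over **all dose groups pooled**.
This deliberately conflates dose response with within-group association:
a plasma metabolite that tracks a liver metabolite across doses is exactly
what a surrogate marker should be. A within-group mode exists but is off by
default. Liver–plasma concordance aligns samples by animal id and ranks
shared metabolites by rho, descending.

Metabolite-level matrices are clustered by average linkage on the distance
1 − rho; dendrograms are exported as Newick text. Pathway-level ("CoolMap"
style) matrices collapse the leaf matrix with an aggregator (mean, median,
min, max — "average" is accepted as an alias of mean) over all leaf pairs
spanning two pathways. On the diagonal, self-pairs rho(a, a) = 1 are
excluded so the entry measures within-pathway coherence; a singleton
pathway's diagonal falls back to the leaf value 1, which keeps aggregation
an exact identity when every pathway is a singleton. Unmapped features
("known unknowns" — reproducible spectral features with no database
identity) are excluded from pathway aggregation and instead profiled
against every pathway; the pathway with the largest absolute aggregated
rho is reported as the unknown's top association.

## Class separation

All projection methods run on autoscaled (centered, unit-variance) log
tables, the convention of the commercial packages used in this field.

- **PCA** is the quality-control view (scores, orthonormal loadings,
  explained-variance fractions).
- **PLS-DA** fits a NIPALS partial least squares regression on the one-hot
  class matrix; predicted class is the argmax of predicted indicators.
  Plain PLS-DA is implemented rather than its orthogonalized variant: the
  two give identically defined VIP scores and the plain form has fewer
  moving parts. VIP (variable importance in projection) is
  `VIP_j = sqrt(p * Σ_a SSY_a (w_ja/||w_a||)² / Σ_a SSY_a)`; the mean
  squared VIP is identically 1, which the suite verifies on random fits,
  and VIP > 1 flags class-separating metabolites. Reports are emitted in
  both resubstitution and leave-one-out modes — resubstitution flatters
  (perfect liver classification is consistent with it), leave-one-out
  estimates generalization. Default 2 components, overridable.
- **Random forest** uses bagged randomized trees (default 500), mean
  impurity decrease as importance, and the out-of-bag confusion matrix —
  the canonical near-unbiased error estimate for bagging.
- **SOM**: a batch-trained rectangular self-organizing map (default 10×10,
  100 epochs) with a Gaussian neighborhood whose radius decays linearly
  from half the larger grid dimension to 0.1. The small final radius makes
  the last updates effectively hard assignments; combined with an
  *uninformed* Gaussian initialization around the data centroid (one
  per-feature standard deviation wide) this guarantees in practice that the
  final quantization error does not exceed the initial one — a "smart"
  init (PCA plane, sampled data points) can start below the trained error
  and void that contract. Component planes (per-metabolite codebook
  slices) and per-node class hit counts are exported; the pipeline writes
  plane files for the top-N metabolites by VIP (default 12) rather than
  all ~400, the full set being available from the API.

Report percentages (per-class error rates, overall accuracy) are rounded
half-up to integers; that rounding reproduces every printed cell of the
reference confusion tables (1/6 → 17%, 2/7 → 29%, 1/8 → 13%, 3/8 → 38%).

## Synthetic cohorts

The generator is a log-normal hierarchy — the simplest model that
reproduces what downstream stages consume:

    log abundance = baseline_m + loading_m · F[pathway(m), animal]
                    + dose effect + sham-surgery effect + animal offset + ε

- `baseline_m ~ N(2, 1)` per metabolite and tissue (log units).
- `F` is a per-animal standard-normal factor per pathway, shared between
  the two tissues of an animal; the loading is chosen so the within-pathway
  correlation approaches `pathway_block_rho` (default 0.6). All known
  features load; a configurable fraction of unknowns (default 0.3) is
  coupled too — these are the unknowns that later sort into pathways by
  correlation alone.
- Dose effects are planted log-folds at 10 and 50 Gy on designated
  metabolites; residual noise sd defaults to 0.3, the animal offset
  (shared across tissues) to 0.1, and an optional sham-surgery effect
  (default off) perturbs a random 30% subset in all laparotomy groups.
- Dropout is missing-not-at-random: the probability rises logistically as
  log abundance falls (`2·rate·sigmoid(−strength·z)`), default rate 0.05,
  strength 1 — the low-abundance censoring typical of MS platforms.

Defaults mirror the emulated study design: 407 liver / 347 plasma features
with 159 shared ids and ~35% known identities; WLI group sizes 6/8/8/8;
WBI 12 + 12. The default planted panel (`default_panel_config`) carries 17
cross-tissue biomarkers (3–7-fold at 50 Gy), a ~20-fold high-dose plasma
spike, a 2–9-fold liver pathway block, six amino-acid-style depletions
(0.4–0.7-fold), and a flip subset whose WBI effect reverses sign. Metabolite
ids are systematic (S###/L###/P### for shared/liver/plasma knowns,
X-prefixed for unknowns).

What the generator does **not** emulate: retention times, m/z values,
batch and injection-order effects, heteroscedastic technical noise,
non-log-normal marginals, and correlated (structured) missingness. Passing
tests therefore demonstrate correctness of the analysis chain and its
operating characteristics under a plausible generative model, not
performance on real instrument data.

## Benchmark configurations and problem sizes

The acceptance-level checks run at these sizes, chosen to keep a full run
in minutes on one core while leaving Monte-Carlo error small:

- **FDR calibration**: two groups of 8, 500 independent null features
  (block correlation, animal offsets and dropout off, so the nominal
  per-observation sd is the whole variability), 300 simulations in the test
  suite / 200 in the acceptance script. Under the global null the realized
  false-discovery proportion is 1 whenever any q < 0.10 call occurs, so its
  mean estimates the family-wise error BH controls at 0.10.
- **Cascade recovery**: 20 planted both-tissue biomarkers, |fold| ≥ 3 at
  50 Gy, noise sd 0.3, study group sizes, dropout 0.05 (so imputation is
  exercised); 50 seeds (suite) / 25 (script).
- **Flip sensitivity**: 2-fold 10 Gy effects, n = 12 per group, noise sd
  0.3, isolated-effect configuration *including* dropout off: with MNAR
  dropout plus minimum imputation, an unlucky dropout draw in a treated
  group injects the global minimum into that group and inflates the Welch
  variance — a real, documented limitation of minimum imputation (the
  rank-sum test is robust to it; the Welch-gated pipeline is not).
- **SOM contract**: 50 seeds of two 12-sample Gaussian clusters 8 sd apart
  on a 2×1 grid.
- **Oracle agreement**: 1000 random tied vectors against a brute-force
  rank-then-Pearson implementation (tolerance 1e-12); pathway aggregation
  against direct enumeration on random ontologies of up to 10 pathways.

## Known limitations

- Minimum imputation can corrupt group variances under MNAR dropout (see
  above); pairwise-deletion testing or left-censored likelihood models
  would be the upgrades.
- Tests treat samples as independent groups; the paired liver/plasma and
  repeated-animal structure is used only for correlation alignment, not in
  mixed models.
- Pooled-group Spearman values are dominated by dose response whenever
  effects are large; they should not be read as within-condition
  coexpression.
- The SOM is a reference implementation for component-plane inspection,
  not a tuned topology-preserving embedding; quantization error is the
  only training diagnostic exported.
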