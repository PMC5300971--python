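# Methods

## The analysis in brief

The package stratifies a cytometry cohort by NK-cell maturation profile in
five stages: (1) pre-gate viable, dump-negative NK events; (2) cluster each
sample's events in the 5-marker space (CD56, CD16, NKG2A, NKG2C, CD57) with a
finite mixture model; (3) pool the per-sample cluster centroids, rescale,
hierarchically merge them into metaclusters and annotate these as named NK
populations; (4) convert per-population event counts into a patients ×
populations frequency matrix and cluster patients into maturation groups;
(5) compare frequencies and clinical covariates between groups with rank
tests. Every stage is deterministic given its seed.

## Gating

An event is an NK candidate when every dump channel (CD3, CD14, CD19) and the
viability stain are at or below their cutoffs and the event is not
CD56⁻CD16⁻: the union of the CD56⁺CD16⁺, CD56⁺CD16⁻ and CD56⁻CD16⁺ quadrants.
Manual gates are not reproducible programmatically, so cutoffs either come
from the caller (tests use the synthetic generator's known level grid) or from
`auto_thresholds`: a kernel-density valley between the two lowest-intensity
modes of a channel, falling back to a fixed quantile (default 0.99) on
channels without two modes. Gating is idempotent and every threshold is
recorded in the gate result for audit.

## Mixture clustering

Events are modelled per sample as a K-component Gaussian mixture with full
covariance (a Student-t family with fixed degrees of freedom, default ν = 4,
is available behind an option; its scale weights follow the standard
EM-for-t update). Box-Cox transformation is deliberately not part of the
model — variance stabilisation belongs upstream in `transform_events`
(identity/arcsinh/log), and the downstream analysis depends on centroids, not
the exact likelihood family.

Numerical choices:

* initialisation by k-means++ centers with hard nearest-center
  responsibilities; `n_init` restarts (default 3), best final log-likelihood
  wins; restart seeds derive deterministically from the option seed;
* covariance ridge of `reg`·trace(global covariance)/d (default `reg` = 1e-6)
  added at every M step, which keeps components from collapsing on duplicated
  events while perturbing the likelihood below the monotonicity tolerance;
* convergence when the total log-likelihood changes by less than `tol` per
  event (default 1e-6), capped at `max_iter` (default 150);
* a fit *fails* when the sample has fewer events than components or when
  every restart ends degenerate: non-finite likelihood, a component weight
  below 1/(10n), or a covariance condition number above 1e12. Cohort runs
  collect failures instead of aborting — samples that cannot be computed are
  reported and the remaining samples analysed.

Model-count selection reports BIC = 2·logL − p·log n (larger is better;
p = (K−1) + Kd + Kd(d+1)/2) and ICL = BIC − 2·H, with H the total entropy of
the posterior responsibilities; failed fits are excluded from the argmax. The
cohort default is a fixed K = 27 for every sample.

MAP assignment breaks posterior ties toward the lowest cluster id (numpy
argmax takes the first maximum), making event labels reproducible.

## Metaclustering and annotation

Pooled centroids are rescaled per marker by the linear map
x ↦ −3 + 6·(x − p5)/(p95 − p5), where p5/p95 are the pooled 5th/95th
percentiles (linear-interpolation percentiles); values outside [−3, 3] are
kept. No additional row normalisation is applied: any further per-cluster
operation would distort the marker semantics the annotation rules rely on.
A `unit-row-norm` style option was considered and rejected for that reason.

The rescaled centroids are merged by average-linkage hierarchical clustering
on Euclidean distances (scipy implementation behind the `hcl` surface; merge
ties follow scipy's deterministic order, and the resulting partitions are
invariant to input row order on tie-free data). Interactive tree cutting is
replaced by an explicit `n_groups` parameter, default 19 — the only honest
deterministic surrogate for a human cut. Metaclusters with fewer than
`min_members` member clusters (default 3) are flagged rare and not named;
their events stay in the total-NK denominator, because populations are
reported as percentages of *total* NK cells.

Annotation applies priority-ordered marker-level rules to each metacluster's
mean signature, with level cutoffs on the rescaled scale at neg < −1,
low ∈ [−1, 0), dim ∈ [0, 1.5), bright/high ≥ 1.5 (thirds of the anchored
range; all overridable). The 13 default rules name: two CD56^bright^ variants
(CD16⁻ and CD16^low^), seven CD56^dim^ variants spanning the
NKG2A/NKG2C/CD57 combinations, and four CD56^neg^/CD16^low^ dysfunctional
variants. Signatures matching no rule are `unclassified`; several
metaclusters may share a name and are pooled downstream. In practice the
percentile anchors can blur the neg/low distinction on CD16, so the two
CD56^bright^ variants are occasionally pooled under one name — their mass
still lands in the right maturation category.

## Cohort analysis

Population frequencies are 100 × (events in the population's metaclusters) /
(total gated NK events of the sample). Populations whose *cohort-wide mean*
frequency is strictly below 0.5% are excluded (the mean across patients — not
a per-patient maximum — because rare populations typically appear in several
patients at once); row mass of excluded, rare, or unclassified metaclusters
remains in the denominator.

Patients are stratified at inclusion (T0) only, by average-linkage
clustering of their raw frequency vectors (no re-standardisation; the
display scale of the frequency heatmap is the natural metric here) cut into
3 groups. Groups are named post hoc: X = highest median CD56^dim^NKG2A⁺,
Y = highest median CD56^dim^CD57⁺, Z = highest median CD56^dim^ triple-
negative; ambiguous matches keep generic G1..Gn labels with a warning. M3
samples are scored against the T0-derived groups through their patient ids.

The maturation summary reports, per sample, the summed frequency of all
CD57⁺ populations and five category aggregates. The category map is an
explicit reconstruction (the original category memberships were never
published) and fully overridable: Progenitors = CD56^bright^ variants;
Effectors = CD56^dim^NKG2A⁺ (± NKG2C); Intermediate = CD56^dim^
triple-negative and NKG2C⁺CD57⁻; Mature = all CD56^dim^CD57⁺ variants;
Dysfunctional = CD56^neg^/CD16^low^ variants.

`suppression_table` counts patients below 50 HIV-RNA copies/mL at M3 per
group (optionally pooled groups) and reports exact arithmetic percentages.

## Statistics

All rank statistics use mid-ranks. Kruskal–Wallis:
H = [12/(N(N+1)) Σ R²_g/n_g − 3(N+1)] / (1 − Σ(t³−t)/(N³−N)), p from χ² on
k−1 df; all-identical data return H = 0, p = 1. Dunn's posttest:
z_ij = (R̄_i − R̄_j)/√[(N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/n_i + 1/n_j)],
two-sided normal p, Bonferroni-adjusted over all k(k−1)/2 pairs by default
(the Prism convention) and within each variable only; stars at
0.05/0.01/0.001. Spearman is the Pearson correlation of mid-ranks with a
t-approximation p; regression is ordinary least squares with a t-test on the
slope. Only large-sample approximations are implemented; p-values for very
small groups (the 4-patient group in particular) are approximate, which the
report's group sizes make visible.

## Synthetic cohort: what it emulates, and what it does not

The generator plants a known truth for every quantity the pipeline
estimates. Its defaults are the study conditions:

* **Phenotypes** — 13 named phenotypes on the level grid neg = 0, low = 1,
  dim = 2.5, bright/high = 4 (a transformed-intensity scale), diagonal
  Gaussian per phenotype with sd 0.30 per marker, so any two phenotypes are
  ≥ 3 sd apart on at least one marker and a nearest-centroid classifier on
  noiseless means is exact. The published record gives only signature levels,
  not event-level variances; the grid and sd are the simplest choice with
  controllable separability.
* **Groups** — 14 X + 10 Y + 4 Z patients; per-group frequency centers anchor
  the four published signature medians (CD56^dim^NKG2A⁺ 34/13.8/14.3%,
  CD56^dim^CD57⁺ 2.9/21/7.2%, CD56^dim^NKG2C⁺CD57⁺ 2.9/17.8/0.9%,
  triple-negative 17.5/16/42.6%) and the published category totals where the
  two are compatible; populations with no published value absorb the
  remaining mass. One population (CD56^neg^CD16⁺CD57⁺) is planted at 0.3% to
  exercise the 0.5% exclusion. Patient-level noise is logistic-normal:
  multiplicative log-normal jitter (sd 0.15) on the positive centers,
  renormalised to the simplex.
* **Structure** — two further patients carry degenerate T0 acquisitions
  (20 events, fewer than K = 27) so the clustering stage fails on exactly two
  of the 61 files, reproducing the study's accounting: 30 patients,
  60 patient samples + 1 healthy donor, 59 × 27 = 1593 cluster records,
  28 × 27 = 756 at T0.
* **Kinetics** — at M3 an additive shift of summed CD57⁺ mass (X +6.6,
  Y +1.4, Z +7.7 percentage points) moves from the triple-negative and
  NKG2A⁺ pools into the CD57⁺ pools, proportionally to their centers.
* **Metadata** — group-specific clipped-normal draws within the published
  median (range) values; viral suppression at M3 planted at exactly 6/14,
  7/10 and 1/4 patients per group; HIV-RNA floored at log₁₀(20 copies/mL);
  IL-6 below the 0.92 pg/mL detection limit imputed at 0.46 pg/mL.
* **Contaminants** — 5% dump-positive (CD14-high, CD16⁺,
  non-classical-monocyte-like) events per sample, removed by the gate.

Not emulated: spectral spillover/compensation, doublets, acquisition drift,
heavy-tailed or skewed event distributions, inter-sample batch effects, and
any event-level DC panel. Passing tests therefore demonstrate that the
pipeline recovers structure *of this idealised kind*; they cannot certify
performance on instrument data, where transform choice, compensation quality
and manual-gate placement dominate.

## Problem sizes

Simulation sizes are chosen so every check runs on a single CPU in minutes:
the acceptance script simulates ten cohorts at 800 events per sample
(EM with 2 restarts, 80 iterations) and reports medians across cohorts
(~10 minutes); the test suite's shared cohort and its recovery test use
400 events per sample over 3 seeds. Recovered group medians are compared to
planted centers within ±4 percentage points for the majority of seeds —
at these event counts the binomial error on a 34% population is ~1.7
percentage points per sample, well inside that band. All other generator
parameters are identical everywhere.

## Known limitations

* The mixture engine is not a numerical clone of any particular reference
  implementation; only the behavioural contract (centroids, counts, failure
  semantics) is reproduced.
* Tree cuts (19 metaclusters) and the rare-cluster threshold (3 members)
  stand in for interactive judgement; both are parameters, and the defaults
  mimic the published counts only.
* The category map and the healthy-donor profile are documented
  reconstructions, not published values.
* Dunn/KW p-values use asymptotic approximations; with 4 patients in a group
  they are indicative, not exact.
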