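# Methods

## The testing model

Each omics layer is a features × samples matrix from a two-group design
(case vs control), typically with four to five biological replicates per
group. Per feature we compute two complementary statistics:

* **t** — Welch's two-sample t on log2-transformed values (unpooled
  variances; configurable to Student's pooled form via
  `RunConfig.t_flavor`). Log2 transformation is on by default for every
  layer (`RunConfig.log_transform`); non-positive raw values are treated
  as missing on the log scale.
* **f** — log2(median(case)/median(control)) on the raw scale, the
  midpoint convention for even group sizes. The median ratio is robust to
  a single aberrant replicate, which the mean-based t is not; requiring
  both statistics to be extreme suppresses calls driven by one outlier.

**Permutation null.** With n = 5 vs 5 a per-feature permutation null has
at most 252 points — far too coarse. We therefore pool: every distinct
case/control relabeling (all of them when their number is ≤ `n_perm`,
otherwise `n_perm` drawn uniformly without replacement from a seeded
generator; the observed labeling always excluded) is applied to every
testable feature, and the resulting statistics form one pooled null per
statistic. Pooling assumes features are exchangeable under the null after
the log transform — reasonable when per-feature spreads are comparable,
optimistic when variance varies strongly across features (see
Limitations). Two-tailed p-values use the pseudocount estimator
p = (1 + #{|null| ≥ |obs|}) / (1 + N), which is never 0 and attains its
minimum 1/(N+1) for an observation beyond the null range. An optional
smoothed estimator (`null_mode: pooled_kde`, Gaussian KDE with Silverman
bandwidth on |null|) is available; the ECDF form is the default and the
one whose calibration is tested.

**Testability.** A feature needs ≥ 2 observed values per group for t and
≥ 1 observed value per group with both medians positive for f. Untestable
features carry missing p-values, are excluded from the pooled null, and —
for the metabolite layers — fall through to the unique-to-group rule. A
fully degenerate layer (constant matrix) yields p = 1 everywhere by the
estimator itself and is flagged in the result's `attrs`.

**Combined significance (Pcom).** Targeted metabolite and lipid panels
have few features and noisy per-feature inference, so Pt and Pf are
combined with Stouffer's z-score method, z_k = Φ⁻¹(1 − p_k). Because both
statistics are computed from the same ten numbers, z_t and z_f correlate
at ρ ≈ 0.5 under the null, and the independence form
1 − Φ((z₁+z₂)/√2) is anti-conservative (empirically ~0.10 of null
features at the 0.05 threshold). The default therefore refers the
observed z₁+z₂ to its own permutation null: the aligned (relabeling,
feature) statistic pairs are converted to z-scores through the same
pooled-null ECDFs, and Pcom is the pseudocount tail probability of the
observed sum among the null sums. This keeps Pcom calibrated by the same
mechanism that calibrates Pt and Pf, at no extra permutation cost. The
closed independence form remains available both as the
`stouffer_combine` primitive (p-values are clamped into
[`clamp_eps`, 1 − `clamp_eps`], ε = 1e−12, before inversion) and as the
pipeline behavior when `dependence_correction` is off.

No additional multiple-testing correction is applied by default — the
layer thresholds are applied to Pt/Pf/Pcom directly; optional BH-adjusted
columns can be added per layer (`bh_correct`).

## Layer calling

* **Threshold rule** (peptides, bulk genes): significant iff Pt ≤ 0.05
  and Pf ≤ 0.10, boundaries inclusive; direction is the sign of f.
* **Roll-up** (proteins): a protein is differential iff it has
  ≥ `min_depeptides` differential peptides, all sharing one direction;
  proteins with both up- and down-regulated differential peptides are
  excluded regardless of count. The default `min_depeptides = 2` reads
  the conventional "at least two supporting peptides" requirement; the
  stricter ≥ 3 reading is one flag away. Roll-up is purely call-based —
  no quantitative protein ratio is formed.
* **Metabolites/lipids**: significant iff Pcom ≤ 0.05 or the feature is
  detected (≥ `min_detect`, default 1) in one group and in zero samples
  of the other. The unique-to-group branch exists because targeted panels
  censor below-LOD values to missing: a metabolite present only in cases
  is biologically a strong "up" signal yet untestable by either
  statistic. Rule provenance is recorded per call; when both branches
  apply, `threshold` is recorded.
* **Single-cell**: within each cell-type cluster (labels are inputs, not
  inferred), cells are the replicate units and the same dual test runs
  with condition labels permuted across cells, capped at `n_perm`
  relabelings; calls at Pt ≤ 0.10 and Pf ≤ 0.20. Treating cells as
  replicates pseudo-replicates donors — a per-unit pseudobulk mode
  (`aggregate_by`) is provided but off by default to mirror the
  cell-level convention. Clusters with fewer than two cells per condition
  are skipped with a warning.

## Cross-layer concordance

Identifier harmonization defaults to case-normalized symbol equality
(mouse "Vamp2" ↔ human "VAMP2"); an explicit two-column ortholog map
takes precedence where provided and must be 1:1. Lipid names are
canonicalized by stripping whitespace and uppercasing the class token
while preserving chain descriptors ("pc (38:0)" → "PC(38:0)";
"SM(d18:1/24:0)" unchanged). Matched features are cross-tabulated into a
3×3 pivot over {up, down, unchanged} (non-significant = unchanged); the
concordant ("same trend") set is the union of the (up, up) and
(down, down) cells. The pivot conserves mass: its grand total is the
matched-feature count and its marginals are the per-layer direction
tallies on the matched universe.

## Enrichment

One-sided hypergeometric upper-tail over-representation against an
explicit universe (the background is a user decision, not a default),
sets intersected with the universe before testing, BH correction across
tested sets, stable p-then-name ordering. Category summaries at a chosen
hierarchy level attribute a feature annotated to k categories 1/k to each
so proportions sum to one; a full-count mode exists for overlap-tolerant
summaries.

## Synthetic data

The generators produce study-shaped inputs with planted, persisted truth:

* **Proteome**: protein log2 baselines ~ N(20, 2); 2–6 peptides per
  protein, each inheriting the protein's effect plus a per-peptide
  baseline offset (N(0, 1), mimicking ionization-efficiency spread);
  i.i.d. N(0, σ) noise per cell, σ = 0.25 by default; a fraction
  `frac_de` = 0.10 of proteins get a ±`effect_log2fc` (default 1.0, i.e.
  two-fold) shift in cases. Raw intensities are 2^log2.
* **Metabolome**: log2 baselines ~ N(3, 1.5); per-feature LOD at the
  `lod_quantile` of the feature's generating distribution, values below
  it censored to missing; additional features forced all-censored in one
  group (marked `mechanism = "unique"` in the truth, on top of the
  round(frac_de · n) fold-planted rows) to exercise the unique-to-group
  rule.
* **Paired human layer**: each mouse-differential protein replicates in
  the human gene layer with the same direction with probability
  `concordance_rho` (default 0.8), the opposite direction or no effect
  each with (1 − ρ)/2; identifiers are emitted uppercase to exercise
  harmonization.
* **Single cell**: negative-binomial counts (dispersion `nb_dispersion`),
  cluster-specific mean profiles (a random tenth of genes scaled 4× per
  cluster), log-normal library sizes (σ = 0.3 on log2), condition effects
  planted only in designated clusters (default the excitatory-neuron-like
  "Ex" cluster). Expected means are stored in `var`/`uns` so moments are
  externally checkable.
* **Gene sets**: random sets plus one deliberately loaded with
  differential features, with a level map, so enrichment recovery is
  testable.

What the generators do **not** emulate: correlated feature blocks,
feature-specific variances, intensity-dependent missingness beyond LOD
censoring, batch effects, ambient RNA or doublets. Passing recovery tests
therefore demonstrates the machinery is correct under the stated model,
not that real data meet that model.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run at desk scale, chosen as
the smallest sizes at which the measured properties are statistically
meaningful: 2000 features for null calibration (binomial 3σ bands around
α ∈ {0.01, 0.05, 0.10}), 250 proteins × 2–6 peptides (~1000 peptides) for
recovery over five replicate simulations, 252-relabeling exhaustive nulls
throughout the 5 vs 5 designs. Floats are written at 6 significant
digits; all tables have fixed column order, so identical configurations
produce byte-identical outputs. Relabeling sampling enumerates the space
when it has ≤ 200,000 elements and rejection-samples distinct subsets
beyond that.

## Known limitations

* The pooled null trades per-feature resolution for global resolution; a
  feature with unusually large within-group variance is tested against a
  null that is too tight for it (and vice versa). The permuted statistics
  of truly differential features also inflate the pooled null's tails,
  making the remaining features' p-values conservative in proportion to
  the planted effect mass.
* Direction ties to the median-ratio sign; a feature with f = 0 exactly
  is never called by the threshold or Pcom branches.
* Cell-level single-cell testing ignores donor structure; use the
  pseudobulk mode when donors are known.
* Symbol-based cross-species matching misses non-orthologous symbol
  collisions and renamed genes; supply an ortholog map where it matters.
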