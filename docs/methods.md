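# Methods

`devalign` implements an expression analysis for cohorts that combine
tumour molecular subgroups with an ordered series of developmental control
samples, asking where each subgroup sits on the developmental continuum.
The motivating setting is medulloblastoma: four consensus subgroups (WNT,
SHH, Group 3, Group 4) compared against neural stem cells (NSC), neural
progenitor cells (NPC), fetal germinal matrix (NFGM) and a single pooled
fetal brain profile (NFB), i.e. four developmental stages ordered
NSC → NPC → NFGM → NFB. All group sizes default to the study-realistic
values: WNT 8, SHH 21, Group 3 22, Group 4 14 tumours; NSC 3, NPC 3, NFGM
2, NFB 1 controls.

The method has four legs, each exposed as a library module and exercised by
a numbered driver under `analysis/`:

1. **Subgroup classification** (`classify`). PCA is fitted on a labelled
   reference cohort restricted to a classifier gene panel (the package
   ships the 20-gene subgroup panel available on the U133A array; any
   one-gene-per-line panel file is accepted, and absent panel genes are
   counted and warned about rather than fatal). Query samples are projected
   into the fixed reference geometry — never refitted — and each takes the
   label of the nearest reference-label centroid (Euclidean, first
   `n_components` components, default 4). Nearest-centroid is a declared
   operationalisation of "alignment to the reference subgroups"; no
   probabilistic calls are attempted.

2. **Ordination and centroid distances** (`ordination`). The combined
   cohort (genes centred) is decomposed by SVD; group centroids are mean
   score vectors on an explicit component list, and pairwise geometric
   distances between centroids give, per tumour subgroup, an ascending
   ranking of the controls. The component list is configuration, not
   inference: on real data an analyst may exclude a component that
   separates neoplastic from non-neoplastic tissue; the synthetic cohort
   has no such technical axis, so the default list is the first four
   components. Metric axioms of the distance table are asserted on every
   run, and sample dendrograms (average linkage on 1 − Pearson) are
   exported as Newick.

3. **Intersect differential expression** (`intersect`). Every (subgroup,
   control) pair is tested per gene: a two-sided pooled-variance Student t
   test (Welch by flag) for controls with n > 1, with fold change reported
   as the linear ratio 2^(Δ mean log2); for the single pooled profile the
   sigma-fold deviation (x_ref − mean_S)/sd_S with a k-standard-deviation
   membership cutoff (k = 2 by default; the reference more than k·sd
   *below* the subgroup mean means the subgroup over-expresses the gene).
   The step-wise intersect then classifies genes per subgroup: *exclusive*
   ("$") when significantly differential in the requested direction against
   every multi-sample control and in no other subgroup, *shared* ("∧") when
   the same evidence exists in more than one subgroup. Single-profile
   controls corroborate (membership outside, same direction) but can never
   veto a call. Raw p < 0.05 is the significance rule; a Benjamini–Hochberg
   option exists but is off by default to match the raw-p convention of the
   original analysis style. Top tables are sorted by |fold change| with
   down-regulation rendered as signed folds (−1/ratio).

4. **Co-expression network and alignment orders** (`network`). After
   removing `_x_at` (cross-hybridizing) probe sets and the low-variance
   bulk, an unsigned weighted network a_ij = |cor(i,j)|^β is built; β is
   the smallest candidate whose connectivity histogram fits a scale-free
   log-log line with signed R² above 0.8, falling back to the best-fitting
   power (planted-block simulations rarely reach the target — a dense block
   network is not scale-free, and the fallback is the expected path there).
   Modules are branches of the average-linkage tree on 1 − TOM cut at a
   static height (default 0.97), discarding clusters below 20 genes;
   static cutting was chosen over the dynamic hybrid cut for determinism
   and transparency. Each module is summarised by its eigengene — the
   unit-norm first right singular vector of the standardized member genes,
   sign-fixed so mean correlation with members is non-negative — and
   eigengenes are grouped into cluster families (average linkage on
   1 − cor, default cut 0.8). Binary subgroup-membership traits are
   correlated with eigengenes (Pearson r with two-sided t-approximation
   p, df = n − 2). Finally, every injective map of the four subgroups onto
   the four control stages (4! = 24 orders) induces a per-sample stage
   trait — controls keep their own stage, tumours take their mapped
   stage — and each order is scored by its most descriptive module:
   max r over eigengenes. Requiring positive r (expression increasing
   with stage) resolves the reversal ambiguity, because control samples
   anchor the orientation of the stage axis; max |r| is available by flag.
   The stage trait uses stage ranks 1..K by default; an alternative
   encoding by control-group mean intensity is provided because either
   reading of "correlated to mean intensity of developmental controls in
   alignment order" is defensible.

**Enrichment** (`enrichment`) is a transparent surrogate for knowledge-base
pathway analysis: one-sided hypergeometric over-representation of a query
set against GMT collections, with BH adjustment reported alongside raw p.
The universe is the detection-filtered gene space, so probe sets the
platform could not see never count as misses.

## Preprocessing rules

* **Quantile normalization** maps every sample onto the common distribution
  of row means of order statistics (the cross-array component of RMA,
  applied at probe-set-matrix level). Ties are broken by stable row order,
  which makes the transform idempotent. It assumes most genes are
  non-differential; the synthetic cohorts violate that assumption (a
  quarter of their genes carry planted signal) and are generated on a
  common scale anyway, so the pipeline's `quantile_normalize: auto` applies
  it to file input only.
* **Detection filter**: a probe set whose *maximum* linear intensity across
  all samples stays below 200 units is below the detection limit and
  removed. The max rule keeps genes detected in any single group, which the
  per-subgroup over-expression queries need. Thresholds are linear-scale;
  data are log2 internally (the limit is log2(200) ≈ 7.64).
* **Network prefilter**: `_x_at` suffixed ids are dropped outright; then
  the lowest-variance fraction `q` (default 0.75) of the survivors is
  dropped, ties broken deterministically by gene id. Each removed gene is
  counted once, in the first filter that removed it.

## The synthetic cohort generator

Everything is simulated in log2 space; the 200-unit detection rule applies
to 2^x. For gene g and sample s:

    x_gs = b_g + slope · stage(s) · [g in a gradient module]
         + effect · [g is a marker of s's subgroup]
         + λ · f_{m(g), s} + ε_gs

* `b_g` — per-gene baseline, Normal(9, 0.8) truncated above the detection
  floor, except a planted fraction (default 0.1) of background genes set
  uniformly in [4, 6] so their expected linear intensity stays below 200.
* `stage(s)` — a control's own stage index, or the tumour subgroup's latent
  stage (defaults mirror the WNT < SHH < Group 3 < Group 4 continuum).
  Gradient modules are linear and monotone in stage; nonlinearity is out of
  scope. The default slope is 0.5 log2/stage — a continuum drifts modestly
  between adjacent stages — while the alignment and centroid recovery
  experiments run at 1.5 log2/stage, a clearly ordered gradient.
* markers — each subgroup owns a disjoint set (default 25) of genes
  over-expressed by `effect` (default 2 log2 units, i.e. four-fold, a
  strong oncogenic signature) in that subgroup only.
* `f_{m,s}` — a per-module, per-sample standard-normal latent factor with
  loading λ (default 1.0): co-expression *within* sample groups, which is
  what makes modules detectable as modules rather than as group contrasts.
* `ε` — Normal(0, noise_sd²), default 0.5 log2 units, a typical residual
  array noise level. `noise_sd = 0` is the exact noise-free limit used by
  the corresponding tests.
* 5% of background genes get `_x_at` ids to exercise the suffix filter.
* The single-profile control (NFB analogue) is one draw from the same
  model — no pooling simulation.
* A second cohort can be drawn against an existing truth (same gene roles,
  baselines and stage map, fresh factors and noise), providing the
  independent labelled reference cohort for classification.

What the generator does **not** emulate: batch effects, probe-level (CEL)
structure, copy-number-driven expression, correlated marker/gradient
overlap, or heavy-tailed noise. Passing recovery tests therefore
demonstrates the pipeline's correctness and its behaviour under the
planted statistical structure — not performance on any real cohort.

## What the recovery experiments measure

All experiments (in `devalign.experiments`, shared by the test suite and
`scripts/acceptance.py`) simulate at the study group sizes, 1200 genes:

* **Marker recovery** — pooled precision/recall of exclusivity calls vs
  planted markers, median over 50 seeds, at defaults. At the default
  gentle slope, gradient genes almost never pass the intersect for the
  top-stage subgroup, so precision stays high; at steep slopes
  (1.5 log2/stage) genes monotone in stage genuinely satisfy the
  exclusivity rule for the top-stage subgroup — visible as extra Group 4
  calls in `analysis/04` — which is a property of the rule, not an error.
* **Module recovery** — ARI between detected modules and the planted
  partition, restricted to planted-module genes (marker genes legitimately
  form their own co-expression clusters and have no planted module id).
* **Alignment-order recovery** — whether the planted map ranks first among
  all 24, scored on planted-module eigengenes (module detection quality is
  measured separately); noise-free runs must score exactly r = 1.
* **Centroid recovery** — whether the nearest-control ranking on PC1–4
  recovers every subgroup's planted stage simultaneously.
* **Calibration** — the empirical size of the trait-association test at
  α = 0.05 under 10⁴ trait permutations.

## Numerical choices and degenerate inputs

* Student t with both-group zero variance: p = 1 (equal means) or p = 0
  with the sign of the difference; sigma-fold with zero subgroup sd:
  membership by exact equality. Correlation p-values use the two-sided t
  approximation; |r| = 1 maps to p = 0.
* PCA errors on constant matrices; trailing numerically-null components
  (singular values < 1e-12 of the largest) are dropped. Oracle agreement
  is asserted at 1e-8 in the tests.
* Module labels are relabelled by decreasing size with ties broken by the
  smallest member gene id, so they are invariant to gene order. Eigengene
  sign is fixed by the mean member correlation.
* All randomness flows from explicit integer seeds; replicate seeds are
  spawned from one base seed via `numpy.random.SeedSequence` and kept
  below 2³¹. Pipeline bundles are byte-identical for a fixed config and
  seed (no timestamps; every table carries the config hash).

## Known limitations

* Small subgroups may not form detectable marker modules at high soft
  powers (the WNT group, n = 8, often leaves its markers unassigned in the
  `analysis/05` run) — the module-trait matrix then under-reports that
  subgroup's association, while the intersect analysis still finds its
  markers.
* The static tree cut trades the adaptivity of dynamic cutting for
  determinism; very unequal module densities may need a different
  `tree_cut_height`.
* The variance prefilter quantile is a free parameter; the analysis keeps
  the top quarter by variance, and the retained count is cohort-dependent.
* Simulations use 1200 genes (≥ 20 k on real arrays) with proportionally
  scaled planted structure; absolute filter counts are not comparable to
  real-cohort values.
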