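# Methods

## Model

`smartdeconv` treats a spatial-transcriptomics (ST) slide as a corpus: each
capture spot *d* is a bag of `N_d` mRNA molecules, each molecule carries a
gene label `w_di ∈ {1..V}`, and each of `K` cell types is a topic. The
generative process is a keyword-guided mixture of Dirichlet-multinomials:

- `θ_d ~ Dirichlet(α)` — per-spot cell-type proportions; `α_k` has a
  Gamma(η̃₁, η̃₂) prior for the first `K̃` marker-bearing types and a
  Gamma(η₁, η₂) prior for the no-marker types.
- `z_di ~ Categorical(θ_d)` — the molecule's cell type.
- For a marker-bearing type `k ≤ K̃`, a switch `s_di ~ Bernoulli(π_k)` with
  `π_k ~ Beta(γ₁, γ₂)` chooses between the marker-restricted gene
  distribution `φ̃_k ~ Dirichlet(β̃)` (support = the type's marker genes)
  and the standard distribution `φ_k ~ Dirichlet(β)` over all genes. For a
  no-marker type only `φ_k` exists.
- `w_di` is drawn from the selected distribution.

Because `β̃ > β`, a marker gene has a higher prior mean inside its own type
than any non-marker gene, which is what anchors topic *k* to the cell type
whose markers were supplied — the output rows arrive already labeled, no
post-hoc annotation step. The reported cell-type expression is the mixture

```
φ*_kv = (1 − π_k) · φ_kv + π_k · φ̃_kv            (φ*_k = φ_k for k > K̃)
```

Spots are modeled as independent; no spatial smoothing is applied.

## Inference

`(θ, φ, φ̃, π)` are integrated out analytically and the discrete `(z, s)`
are sampled by collapsed Gibbs sampling. With all counts excluding the
current molecule (gene `v`, spot `d`), the full conditional is

```
P(k, s=0) ∝ (n_dk + α_k) · (n_k + γ₂)/(n_k + ñ_k + γ₁ + γ₂) · (n_kv + β)/(n_k + βV)
P(k, s=1) ∝ (n_dk + α_k) · (ñ_k + γ₁)/(n_k + ñ_k + γ₁ + γ₂) · (ñ_kv + β̃)/(ñ_k + β̃L_k)
```

where the `s=1` branch exists only for `k ≤ K̃` and `v ∈ markers(k)`, and
the Beta fraction is dropped for no-marker types. This conditional is not
taken on faith: the test suite enumerates the collapsed joint over all
`(z, s)` configurations of a 5-molecule instance with an independently
written oracle and requires the chain's marginals to agree within 3
Monte-Carlo standard errors.

`α` is resampled once per sweep, coordinate-wise, by slice sampling its
collapsed conditional (Gamma prior × Dirichlet-multinomial likelihood over
the weighted spot-type counts) on the log scale. The slice sampler uses
stepping-out with shrinkage — the variant that needs no extra acceptance
test for correctness — and is validated against quadrature and prior-moment
oracles. `π_k` is never sampled explicitly; its Beta-Bernoulli posterior
mean `(ñ_k + γ₁)/(n_k + ñ_k + γ₁ + γ₂)` is used wherever `π` appears.

**Inverse-frequency gene weighting.** To stop ubiquitously expressed genes
from dominating every topic, each gene's count increments are weighted by
`m_v = −log₂(f_v)`, normalized so the average weight per molecule is 1
(`Σ_v f_v m_v = 1`), where `f_v` is the gene's corpus-wide relative
frequency. Weights enter the count tables and the weighted library size
used in the `θ` estimator; uniform frequencies reduce the scheme to
unweighted counting. It can be disabled (`use_weighting=False`), which the
exactness oracles rely on.

**Estimates.** After burn-in, every `thin`-th sweep is snapshotted; the
posterior-mean formulas (`θ_dk = (n_dk + α_k)/(N_d^w + Σ_j α_j)`, smoothed
`φ`, `φ̃`, `π`, and the `φ*` mixture) are evaluated per snapshot, averaged,
and row-renormalized. `fit` can average `n_repeats` independent chains with
derived seeds; marked types are label-aligned by construction, and
no-marker types are matched across repeats by greedy maximum correlation of
their `φ` rows (ties by index).

**Defaults.** `β = 0.01`, `β̃ = 0.1`, `γ₁ = γ₂ = 1`, `(η̃₁, η̃₂) = (1, 2)`
for marked types, `(η₁, η₂) = (2, 1)` for no-marker types, 1500 sweeps with
750 burn-in and thinning 5, weighting on. These are engineering defaults:
the marked-type concentration prior is deliberately the smaller one so that
marked types behave sparsely and the data, not the prior, decides their
share. All are configurable.

## Two-stage subtype deconvolution

Stage one fits the major cell types (plus one no-marker type). For a target
major type *k*, the per-spot library size attributable to it is
`N_dk = N_d · θ_dk`. A companion type *m* — user-chosen or the argmax-PCC /
argmin-Euclidean neighbor of `φ*_k` among marked types — is included to
recapture counts misallocated between *k* and *m* in stage one. The counts
attributed to {*k*, *m*} are extracted per spot, rounded half-up to
integers, and re-deconvolved into subtypes (plus the companion with its
stage-one markers, plus a no-marker type). Spots whose extracted counts
round to zero are dropped from stage two and reported. Stage-two
proportions can be re-expressed on the original-spot scale by multiplying
with `(θ_dk + θ_dm)`.

**Extraction rule.** Two attributions are implemented. The *expected* rule
reconstructs `c_dv = Σ_t N_dt φ*_tv`; because `φ*_t` is a single global
profile, the target-type part of every spot then has the same composition,
which erases the very signal (which subtype occupies which spot) stage two
must recover. The default *responsibility* rule therefore splits the
observed counts by posterior responsibility,
`c_dv = x_dv · Σ_t θ_dt φ*_tv / Σ_j θ_dj φ*_jv`; its expectation under the
model equals the expected rule, but it preserves each spot's observed
composition. The package default is `responsibility`.

**Marker re-use.** Subtype marker lists in stage two should include the
shared lineage markers of the parent type in *every* subtype's list (marker
overlap between types is supported). Without them the shared lineage mass
belongs to no anchored topic and the stage-two no-marker type absorbs it;
with them, measured subtype recovery on the synthetic benchmark improves
from ≈0.74 to ≈0.87 PCC even under oracle extraction. This is the re-use of
stage-one-discarded, non-specific markers that motivates the two-stage
design in the first place.

## Covariate model

Spot-level covariates `x_d` (first entry 1) replace the shared `α` with
`θ_d ~ Dirichlet(exp(λᵀ x_d))`, `λ_mk ~ N(μ, σ²)` i.i.d. (defaults `μ = 0`,
`σ² = 1`). The Gibbs sweep is unchanged except that `α_dk` is spot-specific;
instead of sampling `α`, every `λ_mk` is slice-sampled each sweep against
its Normal-prior × Dirichlet-multinomial conditional (validated against a
1-D grid-quadrature oracle). An intercept-only design reduces to the base
model with a shared, log-normally-prioried `α`; the reduction is checked
empirically (θ agreement PCC ≈ 1).

Condition-specific expression `φ*^{(c)}` is computed by restricting the
assignment count tables to molecules in spots of condition *c* at each
snapshot and applying the same smoothing formulas — the only construction
available from the model's latent variables, since conditions do not enter
the emission model. Per-condition counts partition the global counts by
construction. Fold changes between conditions are reported as
`log₂((φ_a + ε)/(φ_b + ε))` with `ε = 1e-6`; downstream gene-set analysis
is out of scope (the ranked vector is exported for external tools).

## Synthetic data

`grid_bin` emulates pseudo-spot construction from single-cell-resolution ST
(MERFISH/CosMx-style): the image is cut into `side × side` squares anchored
at the minimum x/y coordinate (half-open boxes), squares whose far corner
exceeds the maximum coordinate are removed (edge rule), squares with fewer
than two cells are removed, and member-cell counts are summed. Ground-truth
proportions are member-cell type fractions; ground-truth profiles are
per-type mean count vectors over the whole dataset. `derive_markers`
reproduces the standard marker pipeline: per-cell count normalization,
one-vs-rest two-sided Wilcoxon rank-sum per gene, Benjamini–Hochberg within
type, adjusted p < 0.05, fold change > 2 (pseudocount 1e-9, up-regulation
required), cross-type specificity pruning, and truncation to the top 10 by
fold change.

`generate_from_model` executes the generative process forward and returns
the realized truth — the input for parameter-recovery experiments. Two
scenario generators define the benchmark conditions:

- `generate_subtype_scenario`: five true types — subtypes A1 and A2 sharing
  a strong lineage block and differing in moderate subtype blocks, majors B
  and C, and an *unlisted* type E absent from all marker lists. A2 is rare
  and both subtype blocks are over-expressed in B, so the subtype markers
  are non-specific tissue-wide. The unlisted type matters: in early designs
  without residual structure, the stage-one no-marker topic's best use was
  to absorb one subtype outright, which no second stage can undo; real
  tissues contain unlisted populations that occupy that topic instead.
- `generate_covariate_scenario`: two equal spot groups; the prior odds of
  type 1 are doubled in group 1 through the log-linear concentration model.

What these generators do *not* emulate: platform noise (segmentation
errors, ambient RNA, probe efficiency), spatial autocorrelation of cell
types, and real marker-list imperfection beyond the constructed sharing.
Passing tests therefore demonstrate correctness of the inference machinery
and the claimed qualitative behaviors under the model's own assumptions,
not performance on any real platform.

## Numerical and degenerate-input choices

- Spots with zero total counts are rejected at load time; `N_d = 1` is
  allowed. All-zero matrices are errors. Non-integer input expression is
  rounded half-up with a logged count of affected entries.
- Marker symbols match gene identifiers case-insensitively; unmatched
  symbols are dropped with a warning, and a marker-bearing type losing all
  its markers is an error. Marker-bearing types precede no-marker types in
  the fitted order (reordered with a warning if declared otherwise).
- Ties: top-gene rankings break ties by input gene order (stable sort);
  companion selection and repeat matching break ties by type order.
- A zero-variance proportion vector yields an undefined (NaN) per-type
  correlation, reported with a warning rather than silently dropped.
- The loss-comparison statistic (Diebold–Mariano form) uses the lag-0
  variance: spots carry no ordering, so no autocorrelation correction is
  applied; with paired losses it coincides with a one-sample t statistic on
  the loss differences, with a standard-normal reference.
- All randomness flows from the configured seed; repeat chains use derived
  seeds (kept below 2³¹), and the sweep kernel's generator is seeded per
  chain, so identical inputs give identical outputs.

## Problem sizes used in the checks

The parameter-recovery reference setting is `D = 200` spots, `V = 100`
genes, `K = K̃ = 5` types with 5 disjoint markers each, `N_d = 500`, 1000
sweeps (500 burn-in). The marker-count comparison fits the same setting
with 10-marker truth and lists truncated to 3 vs 10, over 5 seeds. The
two-stage benchmark uses `D = 150`, depth 400, 600 sweeps, 5 seeds; the
covariate benchmark uses `D = 120`, `V = 45`, depth 300, 400 sweeps, 10
seeds. These sizes were chosen once as realistic desk-scale experiments;
the sampler processes roughly 10⁷ molecule updates per second, so each full
fit takes seconds.

## Known limitations

- Gene weighting applies the standard plug-in conditional to weighted
  counts; with weighting enabled the chain is not an exact sampler for any
  single joint (the usual trade-off for this class of weighting), which is
  why the exactness oracles run with weighting disabled.
- The no-marker topic is a modeling resource, not a guarantee: if the data
  contain strong structure unclaimed by any marker list (including subtype
  substructure of a listed type), the no-marker topic may absorb it.
  Inspect its fitted profile and share.
- Responsibility-based extraction inherits stage-one errors; subtype
  recovery is bounded by the quality of the stage-one proportions.
- Condition-specific profiles assume conditions partition spots; per-sample
  hierarchies (multiple slides per condition) are not modeled.
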