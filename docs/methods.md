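# Methods

This note documents the statistical procedures implemented in
`resilnet`, the assumptions behind them, the defaults and why they were
chosen, and what the synthetic-data validation does and does not show.

## Model

Each group's item responses are modelled as arising from a latent
multivariate Gaussian whose inverse covariance (precision) matrix `K`
encodes the network: nodes are items, and the edge between items *i*
and *j* carries the partial correlation
`w_ij = -κ_ij / √(κ_ii κ_jj)` — the association between the two items
conditional on all other items. `w_ij = 0` (equivalently `κ_ij = 0`)
means conditional independence. Items belong to one of two communities
(intrapersonal vs social-ecological protective factors); edges crossing
between the communities are *bridges*.

Responses are observed on a 5-point ordinal scale. By default networks
are estimated from Pearson correlations of the raw 1–5 scores, treating
the ordinal codes as continuous; Spearman and pairwise two-step
polychoric correlations are available behind the `method` flag. The
correlation type is recorded in every estimate so reports are
unambiguous. Ordinal discretization attenuates Pearson correlations
relative to the latent values (roughly 10–15% at the default
thresholds), which shrinks edge weights uniformly but leaves the
support and sign pattern intact.

## Estimation: recursive significance pruning

1. Compute the saturated network: all partial correlations from the
   standardized negative inverse of the correlation matrix.
2. Test every edge two-sidedly with the Fisher-z statistic
   `z = atanh(w_ij)·√(n − k − 3)`, where `k = p − 2` is the size of the
   conditioning set, i.e. an effective factor `√(n − p − 1)`.
3. Remove *all* edges with `p ≥ α` (default α = .05) simultaneously.
4. Refit the model under the accumulated zero constraints (below),
   recompute the implied partials, and retest the surviving edges.
5. Repeat until a round removes nothing. Pruned edges are never
   re-added.

Simultaneous removal per round (rather than backward one-at-a-time)
matches the re-evaluate-after-initial-pruning semantics of recursive
pruning and keeps the procedure order-independent: the result is
invariant to item permutation up to relabelling (tested). Significance
is assessed by the closed-form Fisher z on implied partials rather than
ML standard errors; this is reproducible and fast, but edge counts from
tools that use Wald statistics on the constrained fit may differ
slightly near the threshold.

### Constrained fit (covariance selection)

The refit under zero constraints is the Gaussian MLE with an exact zero
pattern in the precision matrix, computed by the coordinate-wise
regression algorithm for covariance selection: cycling over nodes, each
node's covariances with the rest are replaced by the best linear
prediction from its graph neighbours. At convergence the implied
covariance Σ equals the sample matrix S on the diagonal and on every
retained pair, while Σ⁻¹ is exactly zero on pruned pairs. Convergence
is declared when the largest absolute change in Σ over a sweep falls
below 1e-8 (cap 1000 sweeps; non-convergence raises with the attained
tolerance). Within pruning, successive refits warm-start from the
previous Σ. The fit is verified in the test suite against a brute-force
numerical optimizer of the constrained likelihood (agreement to 1e-5
entrywise on 3–5 node problems, Σ = S on retained pairs to 1e-7).

### Fit indices

With discrepancy `F = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p` and
`T = (n−1)·F`: RMSEA = `√(max(T−df,0)/(df(n−1)))` (0 at df = 0), CFI and
TLI use the diagonal (independence) model as baseline with
`df_b = p(p−1)/2`, and `BIC = −2·logL + q·ln n` with `q = p +`
(number of retained edges) free parameters (data standardized, means
excluded). `df` equals the number of pruned edges. At df = 0 TLI is
reported as 1 with a note; when `T < df`, TLI can exceed 1 and the
report notes it. The `(n−1)` multiplier for T and `n` inside the BIC
penalty are fixed conventions of this package; the log-likelihood uses
all `n` observations.

## Centrality

- Expected influence: `EI_i = Σ_j w_ij` (one-step, signed). Only direct
  neighbours contribute; no two-step variant is provided.
- Bridge expected influence: the signed sum of node *i*'s edges into
  the other community, divided (when normalized, the default) by the
  number of nodes in that other community. The divisor-by-other-size
  convention equalizes the two unequally sized domains; because bridge
  software conventions differ, absolute bridge-EI values may differ
  from other tools by a constant factor, while rankings and tests are
  unaffected.
- Global indices: `EI_G = Σ_i EI_i` (each edge counted at both
  endpoints, so `EI_G = 2·Σ w_ij`) and `EI_BG = Σ_i EIB_i` over
  normalized bridge EIs. Per-community sums and per-node means are
  reported alongside, given the unequal community sizes.

## Between-group tests

**Structure (predictive KL check).** The observed statistic is the
symmetric KL divergence between the two groups' pruned-model-implied
covariances, `0.5·[tr(Σb⁻¹Σa) + tr(Σa⁻¹Σb)] − p`. The null
distribution pools the rows, fits the pooled pruned model, and for each
of `n_draws` replicates simulates two Gaussian datasets of the original
group sizes from the pooled fit and re-estimates each with the same
pipeline; `p = (1 + #{null ≥ obs})/(1 + n_draws)`. This is a *plug-in*
predictive scheme: it conditions on the pooled point estimate rather
than sampling a posterior over precision matrices, removing any
prior-specification ambiguity at the cost of ignoring pooled-fit
uncertainty. Calibration simulations (both groups drawn from one
network, n = 400 per group, 200 draws) put the type-I rate at α = .05
around 0.02–0.03 — mildly conservative, a known property of plug-in
predictive checks; power against ten 0.2-sized edge differences at
n = 500 per group exceeds 95%.

**Global and local permutation tests.** Group labels are reshuffled
over the pooled rows (original sizes kept) and the *entire* estimation
pipeline is re-run per permuted split, so the null reflects the full
procedure including pruning. One shared permutation stream per pair
feeds all statistics: |ΔEI_G|, |ΔEI_BG|, per-edge |Δw| over the union
of edges retained in either observed network (pairs pruned in both are
not tested), and per-node |ΔEI| and |ΔEIB|. P-values use the add-one
estimator and honour the floor `1/(n_permutations+1)`; counts of
significant elements use uncorrected p < .05 (Holm-adjusted values
available behind a flag). Pairs are canonicalized by sorted group label
so (a, b) and (b, a) give identical results under the same seed.
Permutation-replicate estimation failures are skipped and counted; more
than 1% aborts.

## Stability and variability

**Case-drop bootstrap.** Each replicate drops `⌊0.25·n⌋` distinct
respondents uniformly without replacement and re-runs the pipeline.
Reported: per-edge inclusion proportion, per-edge 2.5/50/97.5 weight
percentiles (pruned replicates contribute weight 0), and the mean
inclusion over the full-sample network's edges — both per group and as
the pooled mean across groups, since a single summary can be read
either way. Replicate failures are skipped; more than 5% aborts.

**Variability networks.** Across-group sample SD (n_groups − 1
denominator, conventional for a handful of groups) of each edge weight
— pruned edges counted as 0 so presence/absence variation contributes —
and of each node's EI. `top_varying_edges` returns the top
`⌈fraction·m⌉` of the m nonzero-SD edges, ties broken by lexicographic
node pair.

## Synthetic-data generator

The generator is the validation instrument: it emulates the structure
of a two-domain resilience survey with known truth.

- **Precision construction.** Identity diagonal with `-w_ij` on a
  sampled support: within-community pairs at density `within_density`
  (default 0.15), `bridge_count` (default 8) between-community pairs of
  which `negative_bridge_count` (default 1) are negative; magnitudes
  uniform on `weight_range` (default [0.1, 0.35]). Within-community
  edges are always positive (matching the near-positive manifold of
  protective-factor data); only bridges may be negative. If the matrix
  is not positive definite, a ridge is added in doublings from 0.05 (at
  most 20 attempts) and the matrix re-standardized to a unit-diagonal
  implied covariance; the ridge shrinks all partials by a common factor
  and preserves support and signs. At the default density no ridge is
  needed and true partials equal the requested weights exactly.
- **Responses.** Latent draws from the implied covariance are cut at
  thresholds Φ⁻¹(0.15, 0.40, 0.70, 0.90) by default — a mildly
  right-shifted Likert profile — into categories 1–5 (category count
  configurable).
- **Straight-liners.** A fraction `⌊rate·n⌋` of respondents (exactly,
  per group) have their rows overwritten with one uniformly drawn
  constant category, independent of the latent process: disengagement
  artifact, not a trait.
- **Demographics.** Ages uniform integers on a configurable closed
  range; sex labels at a fixed 52/47.3/0.7 split.

What the generator does *not* emulate: differential item functioning
across groups, local dependence beyond the Gaussian copula,
missingness (the emulated surveys force complete responses), response
styles other than straight-lining, and realistic scale reliabilities
(the sparse default networks give weaker inter-item correlations than
real resilience scales, so synthetic Cronbach's α is lower than
typical published values). Passing tests therefore demonstrate that the
*procedures* are correct and calibrated under the latent-Gaussian
ordinal model, not that any substantive result generalizes to real
survey data.

## Cleaning and screening defaults

Cleaning order: age window first (closed interval, integer years,
default 20–29), then straight-liner exclusion (identical response
across the union of all 27 items; per-scale constancy is not
exclusion-worthy). Scale sums can be rescaled to 0–100 via
`(x − min)/(max − min)·100`. Cronbach's α uses sample variances (n−1)
throughout. Redundancy screening flags item pairs with |r| ≥ .7 whose
correlation profiles with third items are statistically
indistinguishable: for each third item the pair's two dependent
correlations are compared with the Hittner back-transformed-z test
(two-sided, α = .05); a pair is flagged when fewer than 20% of
comparisons differ. Raw Pearson correlations are the default input
(recorded in the report); the degenerate case of exactly duplicated
items is treated as "no detectable difference".

## Problem sizes used in validation

The statistical acceptance tests run at desk scale, chosen to keep the
full suite under ten minutes on one CPU while leaving Monte-Carlo error
well inside the asserted bands: edge recovery on the full 27-node
network (n = 2000, 20 replicates); type-I calibration on an 8-node
two-community network (n = 400 per group, 200 replicates × 200
permutations for the permutation test, 100 replicates × 200 draws for
the predictive check); power on a 14-node pair differing in 10 edges of
0.2 (n = 500 per group, 50 replicates, 99 permutations/draws);
bootstrap stability on the 27-node network with weights ≥ 0.25
(n = 2000, 200 replicates). The acceptance script runs the pipeline at
the scale of the emulated study: 7 groups × 900 respondents, 21
pairwise comparisons with 200 permutations and 100 predictive draws
each, and 200 case-drop bootstraps per group.

## Known limitations

- Pearson-on-ordinal attenuates edge weights; polychoric input is
  available but slow (pairwise two-step ML) and not the default.
- The predictive structure test is mildly conservative (see above).
- Fisher-z edge tests are asymptotic; at n close to p they lose
  accuracy, hence the pipeline's default guard of n ≥ 10·p per group.
- No regularized (glasso/EBIC) estimation: thresholding was chosen
  deliberately for its lower false-positive rate, and mixing the two
  selection paradigms is out of scope.
- Measurement invariance across groups is assumed, not tested.
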