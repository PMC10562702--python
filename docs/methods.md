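# Methods

## Study model and assumptions

The pipeline assumes a balanced two-genotype design: log2-scale normalized
expression (RMA-like, typical range 4–14) for WT and a mutant genotype at six
ages (0.6, 1, 2.5, 4, 6, 12 months), with ≥ 2 (normally 3) replicates per
(genotype, time point) cell. Features are opaque identifiers (probe sets or
gene symbols); no probe-to-gene collapsing is performed. Missing values are
rejected at load time (optionally features with missing values can be
dropped); upstream normalization is out of scope.

## Dynamic-gene calling

Per feature and genotype, the statistic `χ² = Σᵢ (X̄ᵢ − X̄)²/X̄` over the six
time-point replicate means is referred to the upper tail of χ² with 5 df.
The statistic treats expression like a count, so its scale matters:

* **Default (`scale="linear"`)** — replicate values are linearized (`2^x`)
  before averaging, so `X̄ᵢ` are intensity-scale means. On this scale a
  2-fold excursion from a baseline of a few hundred units gives χ² in the
  tens to hundreds and the test has real power.
* **`scale="log2"`** — the formula applied to the stored log2 means. With
  means near 8 and excursions ≤ 2 log2 units the statistic is ≈ 0.2–2
  against a cutoff of 15.09 (p < 0.01, 5 df), i.e. the test essentially
  never fires. The option exists for completeness; it is not the default
  because a variance-stabilized scale removes the mean–variance coupling
  the statistic relies on.

A consequence of the intensity scale is that power is baseline-dependent:
at exactly 2-fold, a low-baseline feature can sit just above p = 0.01 while
a high-baseline one is far below. The fold-change gate is scale-fixed:
`FC = 2^(max X̄ᵢ − min X̄ᵢ)` on the log2 means, compared as `FC ≥ threshold`
after rounding FC to 9 decimals — averaging three identical float64
replicates is inexact at the last ulp about 19% of the time, and the
rounding makes an exact planted 2-fold boundary decide deterministically.
Features whose grand mean is non-positive on the chosen scale (possible
after aggressive background correction on the log2 scale) get an undefined
statistic and are flagged non-dynamic with a warning rather than failing
the run. The p-gate uses raw p < 0.01 (no multiple-testing correction);
Benjamini–Hochberg correction is applied only in the between-genotype
contrast.

The between-genotype contrast at each time point is an empirical-Bayes
moderated t: per-feature pooled variances are shrunk toward a prior
variance with prior df estimated by moment matching in log space (digamma/
trigamma inversion); `prior_df=0` reproduces the ordinary pooled t exactly,
which is the tested parity anchor. BH adjustment is applied across features
within each contrast.

## Expression waves

Dynamic features' time-point means are row-standardized (population sd) and
clustered by fuzzy c-means in Euclidean space: memberships
`u = 1/Σ_k (d_j/d_k)^(2/(m−1))`, centroids as `u^m`-weighted means,
fuzzifier m = 1.25, convergence when the largest centroid shift
drops below 1e−9 (300 iteration cap, warning on non-convergence).
Memberships are initialized uniformly at random from a seeded generator;
10 restarts are run and the lowest-objective solution kept, making results
reproducible bit-for-bit given the seed. Exact centroid hits get their
membership split evenly across the coinciding centroids. A feature is
assigned to its argmax wave only when that membership is ≥ 0.5, else it is
left unassigned.

The cluster count is the largest c in the searched range for which no
centroid pair correlates at ≥ 0.85 (a flat centroid counts as overlapping);
if no c qualifies the smallest is returned with a warning. This rule is
honest but knife-edged on data with genuine within-wave substructure:
correlated member wobble can create admissible sub-centroids and over-split.
Recovery benchmarks therefore fit at the planted count (the standard
protocol for scoring clustering recovery) while count selection is verified
separately on planted distinct profiles.

Waves are named from the standardized centroid: sign `+`/`-` by the
direction of the strongest excursion (ties toward `+`), peak time points =
local extrema with |z| ≥ 0.5, at most 3 labels, ordered by decreasing peak
magnitude measured as fold change on the members' mean log2 profile. The
down sign is rendered as ASCII `-`.

## Flow network

Edges run WT → mutant. For each ordered wave pair the weight is the shared
dynamic-transcript count; the edge is kept when
`weight ≥ ceil(sensitivity × WT-wave size)` with sensitivity 0.10, so a
10-member wave needs exactly one shared transcript. Node specificity =
fraction of members not dynamic in the other genotype. Dynamic features
left unassigned by the membership threshold contribute to specificity
denominators but to no edges.

## Signature synchronization

ssGSEA per sample: features ranked by expression descending; the score
accumulates the difference between the weighted in-set ECDF (weights
`|value|^α`, α = 0.25) and the unweighted out-of-set ECDF over the whole
ranking. Scores are normalized by the overall score range and averaged
within (genotype, time point) to a six-point enrichment profile. A gene set
with zero overlap with the profile, or covering it entirely, is an error.

Intra-signature typing: pairwise Pearson r over member six-point mean
profiles; the significance bound `r_crit` inverts
`t = r√((n−2)/(1−r²))` at two-sided α = 0.05, n = 6 (r_crit = 0.811).
With `f₊`/`f₋` the fractions of pairs at `r ≥ r_crit` / `r ≤ −r_crit` and a
fraction threshold of 0.2: type 2 if only `f₊` qualifies, 3 if only `f₋`,
4 if both, 1 otherwise. These numeric boundaries are this package's
concretization of a qualitative four-type taxonomy and are configurable.
Members with no temporal variance are dropped (tolerance 1e−10 relative,
absorbing ulp-level jitter from averaging identical replicates); fewer than
3 usable members is an error. Note a geometric constraint: a positive-
semidefinite correlation matrix cannot hold a large fraction of pairs at
r ≤ −0.81 without compensating positive pairs, so pure type-3 signatures
with more than two anti-correlated groups cannot exist at this stringency —
type 3 is reachable only for small or marginal sets.

Inter-signature clusters: Pearson over enrichment profiles, significance
edges at p ≤ 0.05 (exact t transform, not permutation), clusters = maximal
cliques of the significance graph, reported largest first; overlapping
cliques are reported as-is. Two-sample KS (asymptotic p) compares a
signature's r distribution between genotypes.

## Hub networks

Per wave, unsigned adjacency `|Pearson r|^β` over member time-point mean
profiles (mean-level, matching the clustering substrate; replicate-level
input was evaluated and gives systematically noisier hub ranking at this
design size). β is the smallest power whose connectivity distribution fits
scale-free topology (signed R² of log10 p(k) vs log10 k over 10 bins,
threshold 0.80). Inside a tight co-expression cluster the degree
distribution is typically *not* scale-free, so the fit rarely qualifies;
the fallback is the conventional unsigned-network default power 6 — not the
argmax of the fit index, which drifts to the extreme of the power grid
where single extreme 6-point correlation estimates dominate connectivity.
A degenerate all-|r| = 1 matrix returns the smallest power with a warning.

Connectivity `kᵢ` is the adjacency row sum (diagonal excluded); hubs are
the `ceil(0.10 × size)` most connected members, ties broken by feature
identifier order so the hub set is deterministic. TOM smoothing is not
applied; hub calling uses raw whole-network connectivity. The conserved-hub
fraction defaults to the share of mutant hubs also found among WT hubs
(denominator configurable to the union), overall and per age phase, where
a wave's phase is read from its leading (strongest) peak label.

## Synthetic data

The generator mirrors the target design exactly: 2 genotypes × 6 time
points × 3 replicates, 2000 features, baselines uniform in [6, 10] log2
units, Gaussian replicate noise (default sd 0.25 log2), planted amplitude
1.5 log2 peak-to-trough. Six waves per genotype (single-peak up, bimodal,
down shapes; templates rescaled to span exactly [0, 1]); per WT wave of
150 members, 60% keep their wave index in the mutant, 20% move to the next
wave, 20% lose their dynamics, and each mutant wave gains 100 mutant-only
members — giving a planted 12-edge flow map that is exactly recoverable
under the 10% rule.

Member heterogeneity is structured so that hub identity is a property of
the data, not of sampling luck: ordinary wave members carry a private
temporal wobble of **fixed magnitude** `√6 × 1.4 × noise_sd`, drawn in the
subspace orthogonal to the constant vector and the wave shape (the two
directions correlation is blind to); hub-block members (the top decile)
carry no wobble and follow the wave program exactly, optionally plus a
small shared latent factor (default off — any hub-only latent decorrelates
hubs from the bulk terms that dominate connectivity). All structured
perturbations scale with `noise_sd`, so the zero-noise study is exactly
clean: replicates identical, dynamic calls, wave assignment and flow edges
all perfectly recoverable. In that limit hub identity is *unidentifiable* —
every member profile is identical up to an affine transform, all
correlations are exactly 1 and the deterministic tie-break decides — so hub
recall is meaningful only at positive noise, where it is ≈ 0.95 at the
default settings.

Planted signatures: type 2 = one wave's shared hub core; type 4 = the two
halves of an anti-correlated wave pair (the wave plan contains an exact
anti-pair in each genotype, mapped onto each other by the flow map so the
signature stays bimodal in both genotypes); type 1 = stable features given
independent wobble. Type-1 members are exactly flat at zero noise and are
then dropped by the degenerate-input rule, so type accuracy is always
reported over scorable signatures. Type 3 is supported by the classifier
but not planted (see the geometric constraint above).

What the generator does not emulate: batch effects, probe-level noise,
missing values, unbalanced designs, intensity-dependent noise variance,
and gradual (non-wave) temporal drift. Passing recovery tests therefore
demonstrates correctness of the pipeline's logic under the declared noise
model, not robustness to real-array artifacts.

## Problem sizes and determinism

Default benchmarks use 2000 features; the test suite's end-to-end fixtures
use 700 for speed, and recovery at realistic noise is averaged over 5 seeds.
Every random choice (generator, fuzzy c-means restarts) flows from a single
integer seed through `numpy.random.default_rng`; pipeline runs write a
manifest with SHA-256 hashes of all outputs, and identical configs
reproduce identical files.

## Known limitations

* The χ² statistic's power depends on absolute intensity; two features with
  identical fold changes but different baselines can be called differently
  near the gate.
* Cluster-count selection by the non-overlap rule over-splits when waves
  contain correlated substructure; on real data the chosen count should be
  inspected, and the fitted-at-known-c protocol is used for benchmarking.
* With only six time points, pairwise correlation estimates are coarse
  (significance bound 0.811); signature typing and hub ranking inherit that
  granularity.
* Maximal cliques can overlap; the reported functional clusters are not a
  partition.
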