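# Methods

This note records the statistical conventions, numerical choices and design
decisions behind `podsoc`, and what its simulation-based tests do and do not
establish.

## Data model and inclusion rules

The unit of observation is a *group sighting*: a dated group of animals,
each row one photo-identified member, with per-group covariates (observed
size, number identified, trammel-net-within-100-m flag) and per-individual
attributes (sex F/M/UN, age class A/J/C). Associations follow the gambit of
the group: all members of a group are taken to be associating.

Inclusion filtering is a **single fixed-order pass**: (1) large groups
(>8 observed animals) with under 80% of members identified are dropped —
partial identification biases the half-weight index downward and the bias
grows with group size; (2) calves are dropped (their association reflects
the mother–calf bond, not independent social choice); (3) individuals with
fewer than 6 remaining sightings are dropped, because an index built on
fewer co-occurrence opportunities is dominated by sampling noise. The pass
is deliberately not iterated to a fixed point: re-filtering after counts
drop would make each animal's reported sighting total depend on the whole
filter cascade, sacrificing reproducibility of per-individual totals for
marginal extra strictness. Daily de-duplication (keep the first sighting of
each animal per day, ordered by an explicit time column when present, else
by group id) precedes filtering and is enforced by a flag on the table;
it removes within-day serial autocorrelation.

Attribute edits that belong to an analysis rather than to the raw data —
e.g. reclassifying animals whose sex was only "estimated" to unknown — go
through the reader's `attribute_overrides` config block, never into code.

The mean group size used as the small/large cut-off in residence profiles is
always computed from the pooled data at hand, never hard-coded.

## Half-weight index and dyad classes

`HWI_ij = 2x_ij / (d_i + d_j)` with `x_ij` joint sightings and `d_i` total
sightings; 0 = never together, 1 = always together. Dyads whose combined
sighting count is zero are masked (NaN) and excluded from all means. The
preferred-association threshold is **twice the mean index over unordered
off-diagonal dyads, zeros included**; avoided = exactly zero. Because
published totals in this literature are inconsistent about the dyad
universe (n² vs n(n−1) vs n(n−1)/2), reports carry all three counts so any
external total can be compared. HWI class bins are low < 0.3,
moderate 0.3–0.5 (both boundaries closed), high > 0.5.

## Permutation null

The null model permutes group memberships **within daily sampling periods**
by checkerboard flips: two groups from one day, one animal in each in the
checkerboard pattern, swapped. Every flip preserves all group sizes and
each animal's daily sighting count, so the null conditions on
gregariousness and on daily presence (hence on births, deaths and
migration). Sampling is a single sequential chain (the standard
implementation of this null): 10,000 burn-in flips, then one sample every
`flips_per_permutation` *successful* flips — "flips" counts successful
swaps, with infeasible draws redrawn and only logged. The chain is driven
by an xorshift64\* generator compiled with numba, so null distributions are
bit-for-bit reproducible for a given seed.

A high observed SD of HWIs relative to the null indicates preferred/avoided
companions; the CV is the sharper statistic for *long-term* preferences
because short-term preferences depress the mean. p-values use the add-one
convention `(r+1)/(n+1)` and both tails are always reported, since the
field literature quotes either direction (`p > 0.9999` in the
observed-exceeds-random sense equals `p_greater ≈ 0.0001` here). The
two-sided significance level defaults to 0.05 and is a configuration value.
`stabilized_pvalue` doubles the permutation count until successive
estimates differ by less than a tolerance (default 0.001, cap 10⁶).

The Mantel test (matrix correlation with simultaneous row/column label
permutation) is implemented in-package for seed control and the same p
convention; its statistic is cross-checked against scikit-bio in the test
suite.

## Network metrics and social differentiation

Strength is the row sum of the HWI matrix. The weighted clustering
coefficient is `C_i = Σ_{j,k} w_ij w_jk w_ki / (max(w) · Σ_{j≠k} w_ij w_ik)`,
normalised by the matrix maximum so a binary clique scores exactly 1 —
this normalisation is logged in output, as other conventions exist.
Affinity is `Σ_j w_ij s_j / s_i`, the association-weighted mean strength of
an animal's associates. Bootstrap standard errors resample **groups** (the
sampling unit for association), not days, with replacement.

Social differentiation S is the coefficient of variation of the *true*
association indices. Each dyad's joint-sighting count is modelled as
binomial with `n_ij = ⌈(d_i + d_j)/2⌉` effective trials (the half-weight
denominator) and a success probability drawn from Beta(a, b); (a, b) are
fitted by maximum likelihood (Nelder–Mead on log-parameters, three
moment-informed starts, tolerance 1e-8) and
`S = CV(Beta) = sqrt(b / (a(a+b+1)))`. The SE is a delete-one-individual
jackknife; a method-of-moments estimate (observed index variance minus its
expected binomial sampling component) is always reported alongside, and is
the fallback if the optimizer fails. When every observed index is
identical, S is exactly 0. The likelihood choice is validated by parameter
recovery (see below), not by matching any published value, since the
likelihood used by legacy tooling is not documented.

## Community division

Clustering operates on similarity = HWI directly (the internal 1 − HWI
distance is never exposed, avoiding the `1−w` vs `max−w` ambiguity).
Average linkage is used because single extreme similarities perturb it
least. Adequacy of the tree is the Pearson correlation between HWIs and
cophenetic join similarities; ≥ 0.80 counts as a good match.

Modularity of a partition is weighted Newman
`Q = Σ_c [W_c/W − (S_c/2W)²]`. Candidate partitions are **dendrogram cuts
only** (every merge height plus the all-singleton cut); a free exhaustive
search exists in the tests as an oracle. Ties break toward fewer
communities; the single-community partition scores exactly 0. Q > 0.3 is
reported as the usefulness convention; divisions below it are still
returned, flagged. The `gregariousness` variant evaluates the same Q on the
gregariousness-corrected matrix (each index divided by the product of the
dyad's strengths, rescaled to preserve total weight), which removes
community signal that is purely due to some animals being seen in more
groups; the two variants coincide on strength-homogeneous data.

## Lagged association rate

`g(τ)` is estimated by ratio-of-sums over all ordered period pairs:
numerator — ordered pairs associated at both periods; denominator — ordered
pairs associated at the earlier period whose **first member** was
identified at the later one (the standard denominator convention; it makes
the estimator robust to animals missing from later periods). Sampling
periods are days. Lags are pooled into log-spaced bins merged upward until
each holds ≥ 20 denominator counts; the bin's τ is its denominator-weighted
mean lag. The null association rate under random mixing is
`(k̄ − 1)/(N − 1)` (mean identified group size k̄, N identified animals):
a random associate is any of the other N−1 animals with equal probability.

The eight-model family combines constant companions (CC), one or two
exponential casual-acquaintance terms (CA) and rapid disassociation (RD —
present whenever g(0⁺) < 1): `{CC: g=1}`, `{CA: e^{−a₁τ}}`,
`{CC+CA: a₂+(1−a₂)e^{−a₁τ}}`, `{RD+CC: a₂}`, `{RD+CA: a₃e^{−a₁τ}}`,
`{RD+CC+CA: a₂+a₃e^{−a₁τ}}`, two-level CA, and RD + two-level CA (the most
general). Fitting maximises the binomial quasi-likelihood of the binned
counts (L-BFGS-B, bounds: rates in [1e−6, 20], proportions in [0, 1], five
seeded starts, tolerance 1e-12 relative). Because the same dyads are
counted across many period pairs the counts are heavily overdispersed, so
models are ranked by QAIC: ĉ = deviance/df of the most general model,
`QAIC = deviance/ĉ + 2K` with K = parameters + 1 for ĉ; ΔQAIC > 2 is
reported as "essentially no support". Acquaintance duration is the
reciprocal of a decay rate, in days. Standard errors of the curve and of
parameters come from a delete-one-block jackknife over contiguous 30-day
date blocks (≥3 blocks required).

A fitted decay whose characteristic duration exceeds the study span is
structurally indistinguishable from constant companionship;
`LARModelFit.effective_components()` makes that classification explicit
(with a 1% proportion floor), so a four-parameter fit whose second "decay"
has rate ~1/3000 days is read as CC, not as a second acquaintance level.

## Synthetic societies

The generator plants known structure so every stage has a recovery test.
Mechanism per day: present animals (per-residency daily sighting
probability) assemble into *teams* (constant-companion pairs, within
units); persistent *alliances* between teams implement casual
acquaintances, dissolving with daily survival `exp(−a₁)`; one-day *mergers*
implement rapid disassociation; partner choice is weighted by the planted
unit propensities (within vs between). The steady-state alliance and merger
counts are derived from `cc_fraction`/`ca_fraction` so the dyad-weight
shares match the planted CC/CA/RD mixture. With group packing off, the true
all-dyad lagged association rate is `a₂* + a₃*·e^{−a₁τ}` where `a₂*`,
`a₃*` are the planted shares corrected for the baseline probability that a
dissolved pair re-associates at random (`q = (alliances+mergers)/C(T,2)`
for T teams) — `Society.true_lar_params()` returns these corrected values,
which are the generator's honest ground truth. An optional packing step
aggregates teams into larger groups (propensity-weighted, seeded) for
realistic group sizes; packing adds co-grouping noise, so the temporal
recovery experiments run with it off.

Defaults emulate a small coastal photo-ID study: 34 individuals (sex ratio
9F/12M/13UN, ages 20A/11J/3C with calves riding their mother's team),
residency classes from very-frequent (daily sighting probability 0.90) to
occasional (0.05), two units with trammel-net probabilities 0.30/0.45,
eight 45-day summer seasons, a 20% daily survey probability and at most two
focal groups recorded per survey day — yielding on the order of 100–140
usable group sightings. These probabilities are the package's own choices
for a realistic sampling regime; the published record they emulate states
totals, not daily rates.

What the simulator does **not** emulate: photographic quality variation and
misidentification, spatially explicit movement, demographic turnover
(births/deaths), and observation effort that depends on group size or
behaviour. Passing recovery tests therefore demonstrate estimator
correctness under the stated sampling model, not robustness to those
field realities.

## Experiment sizes used by the test suite

Chosen as the smallest designs at which each recovery signal is clearly
resolvable: type-I calibration uses 500 preference-free replicates of a
20-animal, 60-day society at 1000 permutations; community recovery plants
two units (propensity contrast 1.0 vs 0.05) over 300 survey days, 20 seeds;
temporal recovery plants a₂=0.4, a₃=0.3, a₁=0.3/day over 200 days with
three observed groups per day, 25 seeds, comparing pooled estimates against
`true_lar_params()` within two jackknife SEs; social differentiation draws
Beta(2,5) true indices (closed-form CV = √(5/16) ≈ 0.559) with 30
observations per dyad, 100 replicates, requiring the mean estimate within
10%.

## Known limitations

- The LAR estimator's jackknife assumes approximate independence between
  30-day blocks; with very long-lived acquaintances the SEs are optimistic.
- ĉ from the most general model conflates residual lack-of-fit with
  overdispersion; with very large denominators this flattens QAIC contrasts
  between nested models (the effective-components classification exists
  precisely because the most general model can win on noise).
- The beta-binomial model for S treats the half-weight denominator
  `(d_i+d_j)/2` as a binomial trial count, which is exact only when both
  animals are seen together or not at all in each period; for loosely
  associated dyads it is an approximation.
- The within-day permutation null requires days with ≥2 recorded groups;
  single-group surveys contribute data to estimation but not to the null.
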