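# Methods

## The question the package addresses

Genome scans for recent positive selection fall into two families: those
that contrast a candidate region's site-frequency spectrum (SFS) against the
genome-wide "background" spectrum (SweepFinder-style composite likelihood
ratios), and those that look for the spatial linkage-disequilibrium (LD)
signature a completed sweep leaves (the omega statistic).  Both are widely
applied to populations that recently colonized new habitats — populations
that are typically also severely bottlenecked.  A severe bottleneck mimics a
sweep: it forces the same burst of coalescence, the same excess of rare
alleles, and much of the same LD structure, but genome-wide rather than
locally.  This package provides a controlled simulation laboratory for
measuring how much true power and how many false positives these scans have
under exactly this confounding, using demographic parameterizations modeled
on two wild mouse populations (a Florida Gulf-Coast beach-mouse colonization
and a Nebraska Sand Hills deer-mouse colonization) plus generalized grids.

## Demographic and selection model

`DemographicModel` is a piecewise-constant diploid history, looking backward
from sampling:

| epoch | size (diploids) |
|---|---|
| `[0, t_r)` | `c_recovery * N_anc` (contemporary, post-recovery) |
| `[t_r, d)` | `f * N_anc` (bottleneck phase) |
| `[d, inf)` | `N_anc` (ancestral) |

All times are in units of `2 * N_anc` generations; a helper converts to raw
generations and to the `4N` units used by Hudson's `ms`.  The hard sweep
(`SweepModel`) is a single de novo mutation arising in the bottleneck-phase
population (size `N_b = f * N_anc`) and fixing exactly at `tau`, with
`t_r <= tau < d`.  The selected site sits at `x_sel` (region center by
default).

Preset parameterizations follow the published demographic inference for the
two mouse populations.  The `florida`/`nebraska` presets carry the inferred
values (N = 2482 / 53080, f = 0.001 / 0.004, recovery 0.413 / 0.662,
divergence 1.225 / 0.067).  The `*-table2` variants use the rounded sizes
(2500 / 50000) of the power-table experiments and place the recovery at
`t_r = 0.1`, the value the rejection-rate experiments quote.  The published
sources give two recovery times (0.01 in the methods text, 0.1 in the
figure captions) and a Nebraska divergence (0.067) that cannot precede
fixation times of 0.1–0.3; we resolve these by exposing `t_r` as a model
field, defaulting the table-style presets to 0.1 (the only reading under
which a sweep fixing at `tau = 0.1` is ancestral to any sampled lineage),
and setting the `nebraska-table2` divergence to `d = 0.5` so that every
studied `(s, tau)` combination fits inside the post-divergence epoch.
Shared region settings: L = 180 kb, n = 40 chromosomes, mu = 3.7e-8 and
r = 5.6e-7 per site per generation (rodent-derived estimates; `r` is the
value that makes the `0.01 * s / r` sweep-width heuristic consistent with a
10 kb target window, and both are `RegionConfig` fields).

## The simulator

### Allele-frequency trajectory

The beneficial-allele path is sampled by forward Wright–Fisher binomial
steps with selection (`p' = x(1+s) / (1+sx)`) in the `2 N_b`-chromosome
bottleneck population, starting from a single copy and rejection-sampled
until fixation; rejection of the unconditioned walk yields exactly the
fixation-conditioned path law.  This is the default whenever drift matters
(Florida's bottleneck holds ~2.5 diploids, where a deterministic sweep is
meaningless).  When `2 N_b s > 100` a deterministic logistic path sampled at
integer generations is used instead; its sojourn time `(2/s) ln(2N_b - 1)`
is verified against the closed form in the tests.  The path is time-indexed
so fixation lands exactly at `tau`; if the implied origin predates the
divergence the configuration is rejected with an instructive error.

### Ancestral recombination graph

Sampled chromosomes are traced backward through the full ARG.  Lineages
carry sorted intervals of ancestral material tagged with the subset of
sampled chromosomes below them (a 128-bit mask); recombination splits a
lineage at a point uniform on its material span, coalescence merges two
lineages and stops tracking intervals whose subtree is complete.  Epoch
changes rescale the pair-coalescence rate.  During the sweep phase the
simulation switches to discrete generations: lineages are labelled by
background (linked to the beneficial copy or not), each lineage draws a
parent uniformly among the `round(2 N_b x(t))` beneficial (or remaining
wild-type) chromosomes — so multiple mergers in the tiny beneficial class
are handled naturally and the final generation, where the class has one
chromosome, coalesces all remaining swept lineages into the founding mutant
— and recombination between a lineage's material and the selected site
re-samples its background from the current frequency.  Mutations are
infinite-sites: Poisson on branch duration times material length, placed
uniformly, with known ancestral states.  Output is the polymorphic 0/1
haplotype matrix (all derived counts in `[1, n-1]` by construction).

The event loops are numba-compiled over flat arrays (segment pools as
linked lists, a Fenwick tree for span-weighted lineage sampling), which
keeps a Nebraska-scale replicate (~300k ARG events) near one second.
Capacities are generous and a replicate retries once with larger pools if
exhausted.  Correctness is established in the test suite against closed
forms (E[pi] = 4 N mu, Watterson's E[S]) and against msprime as an
independent distributional oracle (two-sample Kolmogorov–Smirnov on S and
pi under the bottleneck demography; hitchhiking trough under a strong
sweep).  msprime is never used by the implementation itself.

No sequential-Markov approximation is provided: the full ARG is exact and
fast enough through `N_anc = 1e5`; constant-memory approximations for
`N_anc = 1e6` regions are out of scope, and runs at that size are
impractical with this implementation.

### Seeding

Every public entry point takes a seed (integer, `SeedSequence`, or
`Generator`).  Replicate streams derive from a master seed by the counter
scheme `SeedSequence(master, spawn_key=(i,))`, recorded in each matrix's
metadata; given a seed, all results are bit-for-bit reproducible.

## The scan statistics

### Composite likelihood ratio (SweepFinder-style)

The null probability of a site with derived count `k` is the normalized
background SFS `b_k` (by default the scanned replicate's own spectrum,
optionally pooled with extra simulated neutral regions).  The sweep model
at test position `X` and intensity `alpha` lets each of the `n` lineages
escape the sweep independently with probability `p_e = 1 - exp(-alpha d)`
(`d` = distance from the site to `X`); the `e` escapees plus the swept
ancestor form an ancestral sample of `e + 1` drawn from the background
spectrum projected by hypergeometric downsampling (monomorphic projection
classes retained), the swept ancestor's allele is copied to the `n - e`
collapsed lineages, and the mixture over `e ~ Binomial(n, p_e)` is
conditioned on polymorphism.  The statistic is
`Lambda(X) = 2 [max_alpha sum_i log P(k_i | alpha, d_i) - sum_i log b_{k_i}]`.

Numerical choices: `alpha` is maximized over a 40-point logarithmic grid
spanning escape probabilities ~1e-6 to ~1 at the region half-width, plus an
explicit `alpha = inf` member equal to the null — so `Lambda >= 0` exactly.
Site probabilities are precomputed on a 512-point logarithmic `alpha * d`
lattice spanning `[1e-8, 60]` and interpolated linearly in `log(alpha d)`
(interpolation error < 5e-3 in log-likelihood, checked in tests; beyond the
lattice the distribution has converged to its limits).  At `alpha d = 0`
the polymorphism conditioning is degenerate and the single-escapee limit is
used.  The test grid is 1 kb spacing by default (`grid_spacing_bp`).

### Omega

For a split of a window into left/right blocks,
`omega = [mean r^2 within blocks] / [mean r^2 across blocks]` (counting
unordered pairs), which a completed sweep elevates at the swept site's
flanks.  The scan places the split at each grid position, takes the nearest
`ell <= 50` sites per side within a 25 kb half-window, searches both block
extents exhaustively (at least 2 sites per side), and reports the maximum;
2-D prefix sums over the `r^2` matrix make each window O(1).  A window with
an exactly zero across-block sum yields `inf`, which exceeds any finite
threshold.  Window caps are configuration, not science: the original
omega-scan tools do not publish their settings.

A property worth knowing: in strongly bottlenecked samples most sites are
singletons, and `r^2` between two singletons is either 1 (same haplotype)
or `1/(n-1)^2` (different haplotypes).  Small windows built from such sites
produce large, quantized omega values in neutral and swept data alike, so
the null 95th percentile is high and the statistic's discrimination at
bottleneck-dominated parameterizations is poor.  This is a real property of
the statistic on such data, not an artifact of this implementation; the
package deliberately applies no minor-allele-count filter (inputs are
polymorphic simulated sites, filtered only of monomorphic columns).

## Calibration and power evaluation

Significance cutoffs are calibrated per case from neutral simulations under
the same demography.  "Theta matched" means: a 20-replicate pilot measures
the expected segregating-site count at the base mutation rate, and `mu` is
rescaled so the null's E[S] equals the sweep replicates' mean S.  The
cutoff is the `ceil((1-alpha) n)`-th order statistic of the per-replicate
maximum statistic (the "95th percentile" convention; `alpha_level = 0.05`,
`n_null_replicates = 1000` by default, reduced in the shipped scaled-down
runs with correspondingly wider Monte-Carlo error).  A sweep replicate is a
true positive if any grid point above the cutoff lies within the 10 kb
window centered on the selected site, a false positive if any such point
lies outside; one replicate can be both, and false positives are measured
on the sweep replicates themselves (a neutral-replicate rejection-rate mode
exists and is labelled separately).  The window width follows the
`0.01 s / r` sweep-extent heuristic: at most ~1.8 kb for the strongest
selection studied, comfortably inside 10 kb.

## What the generator emulates, and what it does not

The synthetic data reproduce the *sampling structure* of the empirical
capture-sequencing studies — 40 phased chromosomes over a 180 kb region
with known ancestral states and no missing data or genotyping error — under
exactly specified demography and selection.  They do not emulate
sequencing/mapping error, unphased genotypes, polarization error, gene
conversion, migration after divergence, soft sweeps from standing
variation, or recurrent selection; passing tests therefore demonstrate the
statistical behaviour of the scans under the stated model, not robustness
to those data artifacts.

Two reported empirical anchors are *not* reproduced by this model, and the
corresponding acceptance checks are expected to fail honestly rather than
being tuned to pass: the published Florida-model median diversity range
(6.5–6.9e-5; the stated piecewise demography yields E[pi] = 2 mu E[T2] of
about 3.3e-5, and no reading of the published recovery times reaches the
printed range) and the published Nebraska omega true-positive rates (the
stated demography coalesces every lineage long before a fixation at
tau = 0.3, and the singleton quantization above saturates the omega null at
tau = 0.1).  The scaled-down problem sizes used by the shipped tests and
the acceptance script (20–100 replicates per cell, 30–100 nulls) are the
package's choice of desk-scale reproduction; rates carry binomial error of
roughly ±5–10 percentage points at these sizes.

## Known limitations

- `n <= 128` chromosomes (mask width); `N_anc` up to ~1e5 is practical,
  1e6 is not.
- The discrete-generation sweep phase treats `round(2 N_b x)` as the
  beneficial-class size; for `2 N_b < ~4` this is a coarse (but
  drift-dominated anyway) discretization.
- Infinite-sites positions are continuous; duplicate positions arising from
  5-decimal `ms` serialization are nudged by one ulp on read.
- The CLR's `alpha * d` lattice interpolation trades ~5e-3 log-likelihood
  accuracy for a ~100x scan speedup; the exact path is available through
  `sweep_site_probability`.
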