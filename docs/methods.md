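# Methods

## The model

`skewd` studies how lineage-specific substitution-rate variation corrupts
site-pattern tests for introgression in shallow four-taxon phylogenies.  The
species tree is the asymmetric (((P1,P2),P3),O) with divergence times
tau1 < tau2 < tau3 measured in expected mutations per site (tau = T*mu for T
in generations) and a single haploid sequence per taxon.  All populations
share the scaled size theta = 4*N*mu.  Gene trees follow the multispecies
coalescent; an optional episodic introgression pulse from P1 into P3 is
parameterised by a proportion gamma and a time tau_g < tau1: backward in
time, the P3 lineage jumps into the P1 population at tau_g with probability
gamma.  Sequences evolve by JC69, so multiple hits (homoplasy) are possible.

Rate variation enters as multipliers lambda_P1, lambda_P3, lambda_O attached
to the terminal populations (P2 and all ancestral populations keep rate 1).
A gene-tree segment resident in a population accrues mutation length
lambda_pop x duration x mu.  While the migrant lineage resides in P1, the P1
population size is scaled to lambda_P1 * theta alongside its branch length;
this makes the coalescent exposure of the pulse window invariant to
lambda_P1 and is the one place where the lambda-theta scaling matters (a
single resident lineage cannot coalesce, so the scaling is moot for P3 or O).

Under a strict clock, incomplete lineage sorting produces the discordant
patterns ABBA and BABA at equal frequencies, so E[D] = 0 for
D = (N_ABBA - N_BABA)/(N_ABBA + N_BABA).  With lambda_P1 != 1 homoplasies
accumulate asymmetrically -- the slower sister shares more derived alleles
with P3 because the outgroup, which defines the ancestral state, mutates
faster than P3 -- and E[D] moves away from zero even without gene flow.

## Exact pattern frequencies (`skewd.theory`)

`pattern_freqs` computes P(ABBA), P(BABA), P(BBAA) exactly:

1. Coalescent history classes are enumerated: the introgression indicator,
   then which lineages coalesce in each epoch ([tau_g,tau1] inside P1,
   [tau1,tau2], [tau2,tau3], and the root epoch) and in what order.  Four
   lineages give exactly three coalescences per history and a few dozen
   classes.
2. For a history class, branch lengths in mutation units are affine
   functions of the epoch-wise exponential waiting times, with coefficients
   set by the per-population rate multipliers.
3. The JC69 probability of a site pattern given the gene tree is expanded
   over the 4^3 internal-state assignments and the per-edge transition
   probabilities 1/4 +- c*exp(-4d/3), yielding a sum of exponentials of
   branch lengths.  Pattern probabilities aggregate the 12 ordered
   nucleotide pairs (x, y), x != y, realising the pattern; JC69 symmetry
   makes them equal, so a single representative is computed and scaled.
4. The expectation over waiting times is taken term by term in closed form
   (integrals of exponentials over truncated/untruncated exponential
   densities), eliminating variables in reverse temporal order.  No
   quadrature is involved; the only numerical guard rejects exponents below
   1e-12 where the truncated-exponential primitive would lose precision
   (unreachable for the parameter ranges used here).

Correctness is pinned three ways in the test suite: the total density of the
enumerated histories integrates to 1; the ABBA-BABA difference matches the
closed form (3/16)(1 - e^{-(4/3)(lambda-1)tau1})/(1 + 4 theta/3)
(e^{-8tau2/3} - e^{-8tau3/3}) to 1e-8 over random parameter sweeps; and
simulated pattern counts agree with the expectations within binomial error.

`expected_D` forms D from the expected frequencies; `tau_for_target_D`
solves expected_D(tau) = target by Brent root-finding on the depth
parameterisation tau1 = tau, tau2 = 2 tau, tau3 = 3 tau (the curve is
monotone over the default bracket [1e-4, 1e-2]); `limit_D` traces the
degenerate regime in which D approaches 1.

## The simulator (`skewd.simulate`)

The generator reproduces the study conditions: 100-bp non-recombining loci,
free recombination between loci (independent gene trees), one haploid
sample per taxon, mu = 2e-8 per site per generation, and the scenario-grid
semantics for branch lengths (T_S, T_I, T_O), "2N", rate multipliers,
genome size, and the introgression pulse (gamma = 0.05 at T_G = 0.95 T_S in
the introgression scenario).  "2N" is read as the number of haploid gene
copies: a pair coalesces at rate 1/(2N) per generation and
theta = 2*(2N)*mu.  This reading reproduces the reference mean-D value for
the benchmark cell (analytic D = 0.0598 against the reference 20-replicate
mean 0.063, see the acceptance tests), whereas the diploid reading
(D = 0.050) does not.

Gene trees are drawn by a vectorised backward-in-time sampler (the four
lineages pass through at most four epochs, so per-epoch masked numpy
operations handle the whole locus batch at once).  The same demography can
be run through msprime (`backend="msprime"`; haploid samples, population
splits, a mass-migration pulse), which serves as an independent cross-check
of the tree distribution in the tests, not as the default engine.

Sequences evolve by JC69 along each tree with branch lengths in expected
substitutions per site (per-population multipliers applied as above).  Two
counting paths exist:

- `per_site` (default): site states are simulated explicitly; the optional
  FASTA is written from those same states, so file-based recounting is
  site-for-site identical to the internal counts.
- `multinomial`: for each locus the exact JC69 pattern probabilities given
  its gene tree are computed by pruning (vectorised over loci) and the
  locus's counts are drawn multinomially.  Conditional on the tree, sites
  are iid, so this is the same sampling distribution at a fraction of the
  cost; it is used for large replicate grids and verified against both the
  per-site path and a brute-force pruning oracle.

The sampling-time-shift construction (`time_shift_transform`) re-expresses
a scenario with one rate-shifted tip as a uniform-rate scenario: for an
accelerated tip all divergence times move into the past by
(lambda - 1) x (tip branch duration), the shifted tip is sampled at the
present and the others at the shift; for a decelerated tip the slow tip is
instead sampled in the past with divergence times unchanged.  With gamma = 0
the construction is exactly equivalent to direct rate scaling (the tests
verify this on pooled counts).  With gamma > 0 the two differ slightly: the
shift recipe moves T_G along with the divergence times, which leaves the
migrant's residence in P1 unscaled, whereas the direct model dilates it by
lambda_P1; the direct model follows the theory and is the default.

## Tests on counts (`skewd.dstat`)

- D-statistic with delete-one block-jackknife SE over contiguous equal-length
  blocks (default 100 per genome; there is no canonical block count for this
  procedure, so it is exposed as a parameter rather than fixed).
  Significance is a two-sided normal test of
  z = D/SE at alpha = 0.01 (the tail convention is switchable).  D > 0 is
  read as P2<->P3 introgression, D < 0 as P1<->P3.
- HyDe_jk: the hybrid-detection question reduced to whether the two least
  frequent of the three patterns occur at comparable frequencies.  The
  statistic is the normalised difference of the two smallest genome totals,
  jackknifed the same way; ties are broken in the fixed order BABA, ABBA,
  BBAA and flagged.  A significant result names the ingroup pair sharing
  alleles in the smallest pattern as parents and the remaining ingroup
  taxon as hybrid.  This is deliberately not a re-implementation of the
  HyDe program's invariant-based statistic, so rejection rates reported by
  that program with a jackknife wrapper may differ slightly from this
  module's.
- Relative rate test: tip branch lengths a, b from the JC69-corrected
  distance triplet, rate difference |a-b|/max(a,b), and a clock z-statistic
  for d1O - d2O with a delta-method variance using the empirical per-site
  covariance of the two mismatch indicators (they share the outgroup path).
  This large-sample variance is one of several in use for relative-rate
  clock tests, so the p-values are approximate; the rate difference itself
  does not depend on the variance choice.

## Experiments (`skewd.experiments`)

`expand_scenario_grid` expands the eight scenario rows into cells;
`run_scenario`/`summarize` produce per-replicate records and per-cell
FP/power rates.  A false positive is a significant call of an event that was
not simulated; power is a significant call of the simulated P1->P3 event
(for the hybrid test, power requires naming the recipient P3 -- by this
definition the hybrid test has no power in the introgression scenario, where
it systematically blames P1, and those calls are counted as false
positives).  The desk profile runs 10 Mb genomes with 20 replicates and 100
blocks; mean-D anchors are genome-size-free in expectation, while
false-positive rates are tied to the full 100-500 Mb genome sizes, which
the desk profile replaces by the calibration, monotonicity and
sign-convention properties in the acceptance tests.  TSV tables are the
canonical output; no plotting is shipped.

## Problem sizes and numerical choices

- The acceptance script averages D over 500/240/60 independent 10 Mb
  replicates for the three simulation targets, keeping the Monte-Carlo SE of
  each reported mean near 0.003-0.009 (about 3 SE inside each reference
  value's rounding band).  Informative sites are sparse at these depths
  (about 2e-5 per site), which is why replicate counts, not genome sizes,
  are scaled up.
- Jackknife SEs are validated against the replicate SD of D (ratio within
  [0.7, 1.3] at 100 blocks).
- The root-finding anchor at theta = 2e-4 evaluates to tau = 5.75e-4, on
  the rounding boundary of the 2-significant-figure value 5.8e-4; the test
  asserts agreement within 2%.
- Degenerate inputs: zero-length epochs (tau_g = 0, tau2 = tau3) integrate
  exactly to zero-measure contributions; saturated JC69 distances
  (mismatch >= 3/4) raise; negative relative-rate branch estimates are
  clamped to zero.

## What the generator does and does not emulate

Simulated data are clean by construction: no missing bases, no alignment
error, no intra-locus recombination, no rate variation along the genome, a
known outgroup, and exactly one haplotype per species.  Passing tests
therefore demonstrate the statistical behaviour of the tests under the
model -- rate variation alone inflating D and the hybrid statistic -- not
robustness to the many additional artefacts of real genome alignments.
Ghost lineages, more taxa, population samples and non-JC69 substitution
models are out of scope.
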