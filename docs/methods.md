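# Methods

This note documents the models and procedures implemented in
`paleoscan`, the parameters that matter, the numerical choices, what
the synthetic data do and do not emulate, and known limitations.

## Demographic model

The default model (`demography.prh_model`) is a four-population history
with time in generations before present (generation time 25 years at
the year interface):

| quantity | default | meaning |
|---|---|---|
| N_PRH | 13,975 diploids | Native American lineage size, split → bottleneck |
| N_TSIM | 6,006 diploids | modern size after the post-contact bottleneck |
| T_NA | 605 gen (15,125 y) | split of the Native lineage from CHB |
| T_B_Col | 7 gen (175 y) | post-contact bottleneck time |
| ancient sampling | 60 gen | age of the ancient exome panel |
| admixture | 0.33 at 4 gen (100 y) | European (GBR) pulse into the modern population |
| CHB / GBR | 550 / 1,032 diploids at the 920-gen split, exponential growth | outgroup and European reference |
| OOA bottleneck | N = 1,861 at 2,040 gen | fixed |
| African root | 14,474 (7,310 before 5,920 gen) | fixed |
| μ = r | 2.5 × 10⁻⁸ /bp/gen | mutation and recombination |
| sequence length | 7.4 Mb | monomorphic + polymorphic sites |

The first four rows are the free parameters of the fit; the rest are
fixed.  The CHB and GBR growth rates since their split are not
identifiable from this design and are accepted as inputs (defaults
0.48%/0.38% per generation).  Where a constant-size stand-in for a
growing population is needed, `equivalent_constant_ne` returns the
harmonic-mean size — the constant N with the same elapsed coalescent
time, ∫ dt/2N(t) = L/2N_c.  The trajectory analyses pin the CHB
constant-equivalent at 8,250 diploids; this value is taken as given
rather than derived from a growth rate, and is exposed in
`ShiftSimConfig`.

Ancient samples are drawn from the lineage at 60 generations by
modelling the modern population as a daughter "continuation" split;
sampled populations that are the ancestral side of a split are marked
initially active so present-day outgroup samples remain valid.

`rescale_model(model, λ)` divides sizes and times by λ and multiplies
the per-base rates by λ, preserving θ, ρ and drift per scaled
generation.  Results computed under a rescaled model are flagged
(`FitResult.rescaled`).

## SFS simulation and composite-likelihood fitting

`simulate_joint_sfs` simulates the joint derived SFS with msprime
(infinite-sites mutations, derived polarization from the simulated
ancestral state) and fills the all-ancestral cell so the spectrum sums
to the sequence length in sites.  With `num_chunks > 1` the genome is
simulated as independent replicates of equal length — the likelihood
below treats cells as independent anyway.

The fit maximizes the multinomial composite log-likelihood
Σ_cells obs·log p̂_cell, where p̂ comes from a simulated expected
spectrum.  Numerical choices:

- empty expected cells are floored at 1/(2 × expected total sites)
  before the log;
- the expected spectrum is simulated once per likelihood evaluation
  with a **fixed** seed (common random numbers), so the noisy surface
  is at least a fixed deterministic surface and the whole fit is
  reproducible from one seed;
- the expected genome is `expected_factor` (default 10×) longer than
  the data genome, keeping expected-proportion noise below the data's
  sampling noise;
- optimization is bounded Nelder–Mead in log-parameter space with
  uniform random restarts (`n_optimizations`); excursions beyond the
  bounds are clamped with a warning;
- 95% intervals come from a percentile parametric bootstrap (refits to
  spectra simulated at the fitted values); the point estimate is
  included in the percentile sample so reported intervals always
  bracket it, which matters at desk-scale replicate counts; individual
  refit failures are logged and skipped.

Composite likelihood over linked sites is overconfident and the
(N_PRH, T_NA) pair sits on a drift ridge (t/N nearly constant), so
point estimates scatter along the ridge while bootstrap intervals —
which resimulate the data — remain honestly wide.  Desk-scale runs in
the test suite use a λ = 20 rescaled model, a 0.74 Mb genome, 10–20
haploids per population, 60 expected-spectrum chunks, 3 restarts and 6
bootstrap replicates (≈3 minutes); coarser 10-haploid spectra give the
best-conditioned surfaces because per-cell counts stay well away
from the floor.

## Frequencies from genotype likelihoods

Per site, the derived-allele frequency maximizes
Π_i Σ_g GL_i(g)·Binom(g; 2, f) via EM (f ← mean posterior genotype/2),
initialized at 0.25, tolerance 10⁻⁸ on f, with the log-likelihood
asserted non-decreasing at every step.  Flat-likelihood ties therefore
resolve along the trajectory from the 0.25 start.  Sites with every
individual missing are undefined (NaN at table level, an error for the
single-site call).  SNP calling for spectra uses a likelihood-ratio
test against the best monomorphic model (f ∈ {0,1}), referred to the
½·χ²₁ boundary mixture, at p < 10⁻⁶.  Scans keep only sites with ≥ 5
non-missing individuals in every scanned population; a C/T–G/A mask is
available for damage-sensitive structure analyses.

## PBS scan

F_ST estimators (haploid sample sizes): Reynolds coancestry (default,
matching the statistic's original use) and Hudson with sample-size
corrected numerator.  Negative single-site estimates truncate to 0
(logged); monomorphic-in-both sites contribute (0, 0) components, so
they count toward `n_sites` but not the F_ST sums.  Branch lengths use
T = −log(1 − F_ST) with F_ST capped at 1 − 10⁻⁹ (T ≈ 20.72 at a fixed
difference).  Per-gene values aggregate numerator/denominator sums
across the transcript ± 10 kb window before the ratio
(ratio of averages); a per-site-PBS mean is available as an option.

Admixture correction: per locus, α on the grid {0, 0.01, …, 0.99}
minimizing the **untruncated** F_ST estimator between the corrected
modern frequency and the outgroup.  The untruncated objective is
monotone in the squared frequency difference, so the minimum is unique
at the best match; minimizing the truncated estimator would create a
zero plateau whose smallest-α tie rule biases α downward.  Exact ties
(e.g. f_EUR = f_modern) still resolve to the smallest α.  Corrected
frequencies are clamped to [0, 1] (clamps logged).  Because α minimizes
F_ST(modern, outgroup), the correction can only shrink the
outgroup-facing branch on average; the ancient branch is kept honest by
applying the identical correction inside the neutral null.

The null draws a region length per replicate from the supplied
transcript-length distribution + 20 kb (a file of lengths or the
generator's log-normal), simulates all four populations (50 haplotypes
each), and runs the same per-gene path, correction included when
flagged.  Replicates with no segregating sites score PBS = 0 and are
retained.  Empirical p is the upper-tail proportion of null values at
or above the observed score ("more extreme" is one-sided: selection
inflates PBS); p = 0 is reported as "< 1/n_reps".  The comparison pools
all replicates rather than length-matching per gene.

## Selection-shift trajectories

All Wright–Fisher steps apply the deterministic update on genotype
fitnesses (1, 1+hs, 1+s) followed by Binomial(2N) resampling;
backward-neutral sampling applies the binomial kernel in reverse
(count_prev ~ Binom(2N, f)), the standard approximate time reversal.
Paths absorbed at 0 are kept and removed by the downstream
ancient-frequency acceptance (selection cannot rescue a lost allele).

The regime study: sample the split frequency by 605 backward-neutral
generations in CHB (f_present = 0.475, N = 8,250); draw
s_original ~ U(0, 0.1); run forward at N = 13,975; accept if
f > 0.8 at generation 60; continue to contact (generation 12); then
branch per regime — s = 0, s ~ U(−0.3, 0), or s = s_original — through
the bottleneck (N = 6,006 from generation 7); finally draw a
Binomial(50, f_present) modern sample.  A replicate "reaches" the
observed decline when its sampled frequency is at or below 0.37
(count ≤ 18 of 50).  Dominance is additive (h = 0.5) by default and
configurable — the regime fractions are sensitive to it.  Under these
default conditions the neutral and positive regimes produce 0 of 10⁴
compatible replicates, while the negative regime produces well under
1%: roughly 80% of accepted trajectories are already fixed at contact
(a fixed allele cannot respond to selection), and the 12-generation
window with s ≥ −0.3 only rescues trajectories below ≈0.87.  The
compatible fraction is thus governed almost entirely by the
segregating-at-contact fraction (≈20% here) times the decline
probability, and any implementation detail that changes either —
dominance, the acceptance rule, where the shift starts — moves it by
orders of magnitude.

The (t, s) posterior proposes t ~ U(0, 30), s ~ U(−0.5, 0) (and
s_original as above), accepts on the ancient condition (f₆₀ ≥ 0.8) plus
an exact match of the modern derived count (19 of 50; tolerance
configurable), and returns the accepted pairs with full proposal
bookkeeping; hitting the proposal cap returns a partial sample with a
warning.  The drift-only null reuses the backward/forward machinery
with s = 0 and reports P(f₆₀ ≥ 0.8), about 10⁻³ under the defaults.

All samplers are vectorized across replicates; 10⁴ accepted regime
replicates take a few seconds.

## Balancing-selection null

Overdominance with s = 0.1, h = 100 gives fitnesses (1, 11, 1.1) — an
extreme parameterization, implemented as specified — whose interior
equilibrium h/(2h−1) ≈ 0.5025 pins the allele in every population.
The selected site is simulated forward through the entire tree from a
single copy 200,000 generations ago (growth populations replaced by
their constant equivalents), losses redrawn.  Linked neutral variation
in the transcript + 20 kb region is generated **conditionally** with a
structured-coalescent-style approximation: every population is split
into two allelic-class demes sized by the equilibrium frequencies,
lineages swap classes at rate r·(L/4)·(other-class frequency) — a
single representative recombination distance of a quarter region — and
the classes merge at the introduction time.  Samples are allocated to
classes binomially from each replicate's simulated frequencies, the
selected site is appended to the genotype matrix, and the
ancient-branch per-gene PBS is computed through the standard path with
the admixture correction.  λ-rescaling (default tests use λ = 10)
shortens the forward pass; the equilibrium is invariant under it.

What the approximation captures: ancient trans-population polymorphism
around the balanced site, equalized frequencies across populations, and
the resulting downward shift of regional PBS relative to neutrality.
What it does not: distance-resolved recombination within the region,
selection on the linked sites themselves, and fluctuations of the
class sizes — adequate for a null distribution of an aggregate
regional statistic, not for haplotype-resolved questions.

## Synthetic exomes

`generate_exome_dataset` simulates each gene region (log-normal
transcript lengths, default median ≈2.5 kb, + 10 kb flanks)
independently under the demographic model, lays the genes on one
synthetic chromosome, and emits: haplotypes, true sample frequencies,
gene annotations, and genotype likelihoods from a depth/error model —
depth ~ Poisson(7.97) ancient / Poisson(9.66) modern per individual per
site, derived-read counts binomial with base error 0.002 (defaults),
missing when depth is 0 or with an extra masking rate.  The truth
record (true frequencies, generative admixture fraction, selected gene
and trajectory) stays attached.  `inject_selected_gene` overwrites one
gene: the focal SNP's panel frequencies are redrawn binomially from a
supplied trajectory at generations 60 and 0, and linked sites are
pulled toward the focal frequency by an exponential distance-decay
kernel (default scale 5 kb) — a deliberately simple hitchhiking
stand-in sufficient to exercise per-gene aggregation, not a forward
simulation.  Not emulated: read-level artefacts (mapping bias,
post-mortem deamination — a C/T–G/A site mask stands in downstream),
contamination, and LD between genes.  Passing tests on these data
therefore validate the estimators and the pipeline plumbing, not
robustness to read-level noise.

## Determinism and units

Every stochastic entry point takes a seed; child seeds are derived via
`numpy` seed sequences, and msprime seeds stay below 2³¹.  Same seed ⇒
bit-identical spectra, trajectories, datasets and fits.  Time is
integer-ish generations internally; years appear only at interfaces.
BED input is 0-based half-open, converted to the 1-based inclusive
coordinates used everywhere else; strand is ignored.  Output files
carry a header with the package version, seed and a parameter digest,
and CLI stages write manifests with output checksums.

## Known limitations

- The composite likelihood ignores linkage, so its curvature overstates
  information; rely on the bootstrap intervals, not the surface.
- N_TSIM and T_B_Col act over ≤7 generations and are nearly
  unidentifiable from spectra of this size; their intervals are wide by
  nature.
- The regime-fraction statistic is brittle (see above): it should be
  read together with the segregating-at-contact fraction, which the
  result object exposes via the final-frequency samples.
- The balancing null's single representative recombination distance
  flattens the within-region gradient of linkage to the selected site.
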