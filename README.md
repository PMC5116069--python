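# paleoscan

Population-genetic analysis of an exome **time transect**: the same
population sampled before and after an environmental upheaval, here an
ancient panel (~60 generations before present) and its modern
descendants from the Northwest Coast of North America, with East Asian
(CHB) and European (GBR) reference panels.  The package asks, end to
end: did immune genes carry signatures of positive selection in the
ancient group, did the population collapse after European contact, and
did selection pressures on the same alleles reverse afterwards?

It provides, as a library plus a thin CLI:

- **Demographic inference** (`paleoscan.demography`): a four-population
  model with an out-of-Africa bottleneck, CHB/GBR split with growth, a
  Native American lineage sampled at two time points, a post-contact
  bottleneck and a European admixture pulse (fraction 0.33); joint
  derived site-frequency-spectrum (SFS) simulation via msprime with
  ancient sampling, multinomial composite-likelihood fitting with
  random restarts, parametric-bootstrap confidence intervals, and
  growth-equivalent constant sizes (harmonic-mean N over an epoch).
- **Allele frequencies from genotype likelihoods**
  (`paleoscan.freqs`): the EM maximum-likelihood estimator
  f ← mean posterior genotype / 2 for low-coverage data, a
  likelihood-ratio SNP-calling filter (p < 10⁻⁶), and the
  ≥5-non-missing-individuals site filter.
- **PBS selection scan** (`paleoscan.pbs`): for populations (X, Y, Z)
  with pairwise F_ST transformed to branch lengths T = −log(1 − F_ST),

      PBS_X = (T_XY + T_XZ − T_YZ) / 2,

  per SNP and per gene (transcript ± 10 kb, ratio-of-averages F_ST
  aggregation; Reynolds estimator by default, Hudson optional); the
  per-locus admixture correction f_pre = (f_post − α·f_EUR)/(1 − α)
  with α chosen to minimize F_ST against the outgroup; neutral
  gene-scale simulations for empirical p-values; the ancient-vs-modern
  frequency-change outlier scan; haplotype pairwise-difference
  profiles.
- **Selection-shift trajectories** (`paleoscan.trajectory`):
  Wright–Fisher machinery (deterministic selection update on fitnesses
  (1, 1+hs, 1+s) followed by binomial resampling) for backward neutral
  conditioning on the modern outgroup frequency, forward simulation
  through the bottleneck, the three post-contact regimes (neutral /
  negative / positive), a rejection-sampling posterior for the shift
  time t and coefficient s, and the drift-only null.
- **Balancing-selection null** (`paleoscan.balancing`): long-term
  heterozygote advantage (s = 0.1, h = 100, mutation introduced 5 Myr
  ago) simulated through the whole demography, with linked neutral
  variation generated by a two-allelic-class structured-coalescent
  approximation, giving the PBS null against which sweep-like scores
  are judged.
- **Synthetic exomes** (`paleoscan.synthetic`): fully testable stand-in
  data — genes, haplotypes, true frequencies, genotype likelihoods
  under a depth/error model (7.97× ancient, 9.66× modern), optional
  injected sweep gene — with the generating truth retained.

## Worked example

The selection-shift study (`python examples/shift_regimes_demo.py`):

```
  neutral:   0.00% of 10000 replicates reach the observed modern frequency
 negative:   0.07% of 10000 replicates reach the observed modern frequency
 positive:   0.00% of 10000 replicates reach the observed modern frequency

drift-only null: P(f >= 0.8 at generation 60) = 0.0014
```

Accepted trajectories are near-fixed at the ancient sampling time, as
observed; continuing them unchanged (positive) or neutrally never
produces the modern decline to frequency 0.37, and pure drift almost
never produces the ancient near-fixation in the first place
(P ≈ 0.001).  Only a shift to negative selection at contact can reach
the observed modern frequency, and then only through the small minority
of trajectories still segregating at contact — the fraction is
correspondingly small.

The scan on a synthetic exome with one injected sweep gene
(`python examples/pbs_scan_demo.py`):

```
gene_id    pbs_x  n_sites p_label
    G12 0.327937      121 < 0.002
     G0 0.189766      111   0.002
     G4 0.086878       93   0.044

injected gene recovered as top hit: True
```

`pbs_x` is the ancient-branch PBS per gene; the injected gene (fixed
derived in the ancient panel, 0.37 in the modern) tops the scan and
lies beyond all 500 neutral simulations.  Other examples cover
frequency estimation from genotype likelihoods, the demographic fit,
and the balancing-selection comparison.

## Command line

`paleoscan` exposes the pipeline stages as subcommands
(`make-synthetic`, `est-freqs`, `pbs-scan`, `pbs-null`, `pbs-pvalues`,
`fit-demography`, `shift-sim`, `posterior-ts`, `drift-null`,
`balancing-null`, `hap-profile`); each writes its outputs plus a
manifest with input paths, parameters, seed and output checksums.

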