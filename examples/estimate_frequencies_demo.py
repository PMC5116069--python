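"""Allele-frequency estimation from noisy genotype likelihoods.

Generates a small exome with realistic depth (7.97x ancient, 9.66x
modern), missingness and base error, estimates per-population derived-
allele frequencies by EM from the genotype likelihoods, applies the
five-individual site filter, and measures the error against the truth.
"""

import numpy as np

from paleoscan import freqs, synthetic

cfg = synthetic.SyntheticExomeConfig(n_genes=10, seed=21, missingness=0.1)
ds = synthetic.generate_exome_dataset(cfg)

table = freqs.frequency_table(ds.genotype_likelihoods)
n_before = table.df.groupby(["chrom", "pos"]).ngroups
table = freqs.apply_site_filters(table, min_nonmissing=5)
n_after = table.df.groupby(["chrom", "pos"]).ngroups
print(f"sites: {n_before} called, {n_after} pass the >=5-individual filter")

truth = ds.truth["true_frequencies"]
merged = table.df.merge(truth, on=["chrom", "pos", "pop"], suffixes=("_em", "_true"))
err = np.abs(merged["freq_em"] - merged["freq_true"])
for pop, sub in merged.assign(err=err).groupby("pop"):
    print(f"{pop:>5}: mean |EM - truth| = {sub['err'].mean():.4f} "
          f"over {len(sub)} site calls")
# EM error reflects binomial read sampling at ~8-10x depth; the ancient
# panel (PRH) is noisiest, matching its lower coverage.
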