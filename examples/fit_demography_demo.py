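"""Composite-likelihood demographic fit on a rescaled synthetic SFS.

Simulates a joint derived SFS (CHB / ancient panel / modern panel) at
the point-estimate parameters of a lambda-20 rescaled model, then
re-estimates the ancestral Native American size by bounded random-
restart search over the simulated-likelihood surface.  A quick one-
parameter demo on 10-haploid panels (coarse spectra keep the per-cell
Monte-Carlo noise of the simulated likelihood low); the full four-
parameter fit with parametric-bootstrap intervals runs in the
acceptance suite.
"""

from paleoscan import demography as dm

LAM = 20.0


def builder(n_prh=13_975 / LAM):
    return dm.rescale_model(
        dm.prh_model(n_prh=n_prh * LAM, sequence_length=7.4e5, sample_size=10),
        LAM)


observed = dm.simulate_joint_sfs(builder(), seed=42, pops=("CHB", "PRH", "TSIM"),
                                 num_chunks=8)
seg = observed.total_sites - observed.counts[(0, 0, 0)]
print(f"observed SFS: {observed.total_sites:.0f} sites, {seg:.0f} segregating")

fit = dm.fit_demography(
    observed, builder, {"n_prh": (150.0, 3000.0)},
    n_optimizations=2, seed=11, sim_chunks=60, expected_factor=10.0,
    maxiter=40, rescaled=True)
print(f"fitted n_prh = {fit.params['n_prh']:.0f} (truth {13_975 / LAM:.0f})")
print(f"composite log-likelihood = {fit.loglik:.1f}  [rescaled model, lambda=20]")
# parameters are in rescaled units (diploids / 20, generations / 20);
# multiply by 20 to read them on the natural scale.
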