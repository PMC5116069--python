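"""Post-contact selection regimes for a declining immune allele.

The focal allele is near fixation in the ancient panel (60 generations
ago) but observed at 19/50 chromosomes today.  Accepted positive-
selection trajectories are continued from European contact (12
generations ago) under three regimes, and the fraction of replicates
whose sampled modern frequency reaches the observed 0.37 is reported,
together with the drift-only null at the ancient sampling time.
"""

from paleoscan import trajectory

cfg = trajectory.ShiftSimConfig(n_reps=10_000)
result = trajectory.simulate_shift_models(cfg, seed=1)
for regime, frac in result.fractions.items():
    print(f"{regime:>9}: {100 * frac:6.2f}% of {result.n_accepted} replicates "
          f"reach the observed modern frequency")

drift = trajectory.drift_only_null(cfg, n_reps=10_000, seed=2)
print(f"\ndrift-only null: P(f >= {drift.threshold} at generation 60) "
      f"= {drift.tail_probability:.4f}")
# Neutral and still-positive regimes never reach the observed decline;
# only a shift to negative selection can, and even then only through
# trajectories still segregating at contact.  The drift tail shows the
# near-fixed ancient frequency itself is no drift artefact.
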