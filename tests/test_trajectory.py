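"""Wright-Fisher forward/backward machinery and the shift analysis."""

import numpy as np
import pytest
from scipy import stats

from paleoscan import trajectory as tj


def _binomial_transition_matrix(two_n):
    """Exact WF transition matrix on counts 0..2N (neutral)."""
    i = np.arange(two_n + 1)
    M = np.zeros((two_n + 1, two_n + 1))
    for a in i:
        M[a] = stats.binom.pmf(i, two_n, a / two_n)
    return M


class TestForward:
    def test_neutral_mean_preserved(self):
        # martingale: E[f_final] = f0
        f = tj.wf_forward_batch(np.full(4000, 0.3), sizes=100.0, s=0.0,
                                n_gens=25, seed=1)
        se = f.std() / np.sqrt(f.size)
        assert abs(f.mean() - 0.3) < 3 * se + 1e-12

    def test_absorption_at_zero_and_one(self):
        t0 = tj.wf_forward(0.0, sizes=50.0, s=0.1, n_gens=20, seed=2)
        assert np.all(t0.freqs == 0.0) and t0.absorbed
        t1 = tj.wf_forward(1.0, sizes=50.0, s=-0.2, n_gens=20, seed=3)
        assert np.all(t1.freqs == 1.0)

    def test_quasi_deterministic_matches_recursion(self):
        # N = 1e7 suppresses drift; compare to the deterministic
        # selection recursion coded independently here
        s, h, n_gens = 0.05, 0.5, 100
        traj = tj.wf_forward(0.1, sizes=1e7, s=s, h=h, n_gens=n_gens, seed=4)
        p = 0.1
        for _ in range(n_gens):
            w11, w01 = 1 + s, 1 + h * s
            p = (p * p * w11 + p * (1 - p) * w01) / (
                p * p * w11 + 2 * p * (1 - p) * w01 + (1 - p) ** 2
            )
        assert traj.freqs[-1] == pytest.approx(p, abs=1e-3)

    def test_lethal_fitness_rejected(self):
        with pytest.raises(ValueError):
            tj.wf_forward(0.5, sizes=100.0, s=-1.5, n_gens=5, seed=5)

    def test_selection_beats_neutral_fixation(self):
        # stochastic ordering: fixation is more likely with s > 0
        f_sel = tj.wf_forward_batch(np.full(3000, 0.1), 50.0, 0.1, n_gens=400, seed=6)
        f_neu = tj.wf_forward_batch(np.full(3000, 0.1), 50.0, 0.0, n_gens=400, seed=7)
        assert (f_sel == 1.0).mean() > (f_neu == 1.0).mean()

    def test_neutral_new_allele_fixes_at_rate_1_over_2n(self):
        two_n = 20
        f = tj.wf_forward_batch(np.full(100_000, 1 / two_n), two_n / 2, 0.0,
                                n_gens=8 * two_n, seed=8)
        fixed = (f == 1.0).mean()
        # binomial SE on 1e5 reps at p = 0.05
        assert abs(fixed - 1 / two_n) < 4 * np.sqrt(0.05 * 0.95 / 100_000) + 0.002

    def test_trajectory_frequencies_stay_in_unit_interval(self):
        traj = tj.wf_forward(0.5, sizes=30.0, s=0.3, h=0.5, n_gens=200, seed=9)
        assert np.all((traj.freqs >= 0) & (traj.freqs <= 1))


class TestBackward:
    def test_absorbed_zero_stays_zero(self):
        assert tj.wf_backward_neutral(0.0, 100.0, 50, seed=1) == 0.0

    def test_neutral_reversibility_mean(self):
        f = tj.wf_backward_neutral(np.full(5000, 0.4), 100.0, 20, seed=2)
        se = f.std() / np.sqrt(f.size)
        assert abs(f.mean() - 0.4) < 3 * se + 1e-12

    def test_toy_2n8_matches_transition_matrix(self):
        # exact oracle: three applications of the binomial kernel
        two_n, steps, reps = 8, 3, 100_000
        M = _binomial_transition_matrix(two_n)
        v = np.zeros(two_n + 1)
        v[4] = 1.0  # start at frequency 1/2
        expected = v @ np.linalg.matrix_power(M, steps)
        f = tj.wf_backward_neutral(np.full(reps, 0.5), two_n / 2, steps, seed=3)
        counts = np.bincount(np.round(f * two_n).astype(int), minlength=two_n + 1)
        chi2 = ((counts - reps * expected) ** 2 / (reps * expected)).sum()
        assert stats.chi2.sf(chi2, df=two_n) > 1e-3


class TestShiftConfig:
    def test_defaults_describe_the_study_conditions(self):
        cfg = tj.ShiftSimConfig()
        assert cfg.chb_present_freq == 0.475
        assert cfg.split_gen == 605 and cfg.bottleneck_gen == 7
        assert cfg.observed_derived == 19 and cfg.modern_chromosomes == 50
        assert cfg.observed_count_max == 18  # floor(50 * 0.37)

    def test_invalid_orderings_rejected(self):
        with pytest.raises(ValueError):
            tj.ShiftSimConfig(contact_gen=70)
        with pytest.raises(ValueError):
            tj.ShiftSimConfig(ancient_accept_threshold=0.0)
        with pytest.raises(ValueError):
            tj.ShiftSimConfig(negative_prior=(0.1, 0.2))


class TestShiftModels:
    def test_deterministic_and_complete(self):
        cfg = tj.ShiftSimConfig(n_reps=300)
        r1 = tj.simulate_shift_models(cfg, seed=11)
        r2 = tj.simulate_shift_models(cfg, seed=11)
        assert r1.fractions == r2.fractions
        assert set(r1.fractions) == {"neutral", "negative", "positive"}
        assert r1.n_accepted == 300
        for regime in r1.final_freqs:
            assert np.all((r1.final_freqs[regime] >= 0) & (r1.final_freqs[regime] <= 1))

    def test_neutral_and_positive_regimes_never_reach_observed(self):
        # the observed decline (1.0 -> 0.37) requires a shift to
        # negative selection; without it no replicate reaches it
        res = tj.simulate_shift_models(tj.ShiftSimConfig(n_reps=2000), seed=12)
        assert res.fractions["neutral"] == 0.0
        assert res.fractions["positive"] == 0.0
        assert res.fractions["negative"] >= 0.0

    def test_impossible_acceptance_raises_with_diagnostics(self):
        cfg = tj.ShiftSimConfig(n_reps=10, ancient_accept_threshold=1.0,
                                chb_present_freq=0.0, max_proposal_factor=2)
        with pytest.raises(RuntimeError, match="no trajectory accepted"):
            tj.simulate_shift_models(cfg, seed=13)


class TestPosterior:
    def test_samples_respect_prior_support(self):
        cfg = tj.ShiftSimConfig()
        post = tj.sample_posterior_ts(cfg, n_accept=40, seed=21, tolerance=2)
        assert post.n_accepted == post.t.size == post.s.size
        assert np.all((post.t >= 0) & (post.t <= 30))
        assert np.all((post.s >= -0.5) & (post.s <= 0))

    def test_full_tolerance_reduces_to_ancient_condition(self):
        # with the modern match always satisfied, the acceptance rate
        # equals the ancient-condition rate alone
        cfg = tj.ShiftSimConfig()
        post = tj.sample_posterior_ts(cfg, n_accept=200, seed=22, tolerance=50)
        assert post.n_modern_ok == post.n_ancient_ok
        strict = tj.sample_posterior_ts(cfg, n_accept=200, seed=22, tolerance=0)
        assert strict.n_modern_ok < strict.n_ancient_ok

    def test_posterior_concentrates_on_strong_negative_selection(self):
        # matching the observed decline requires strongly negative s;
        # near-neutral s should be rare among accepted pairs
        post = tj.sample_posterior_ts(tj.ShiftSimConfig(), n_accept=60, seed=23,
                                      tolerance=2)
        frac_strong = np.mean(post.s < -0.25)
        frac_weak = np.mean(post.s > -0.05)
        assert frac_strong > frac_weak

    def test_same_seed_identical(self):
        cfg = tj.ShiftSimConfig()
        p1 = tj.sample_posterior_ts(cfg, n_accept=25, seed=24, tolerance=3)
        p2 = tj.sample_posterior_ts(cfg, n_accept=25, seed=24, tolerance=3)
        assert np.array_equal(p1.t, p2.t) and np.array_equal(p1.s, p2.s)


class TestDriftNull:
    def test_mean_matches_modern_frequency(self):
        null = tj.drift_only_null(tj.ShiftSimConfig(), n_reps=4000, seed=31)
        f = null.freqs_at_ancient
        se = f.std() / np.sqrt(f.size)
        assert abs(f.mean() - 0.475) < 4 * se

    def test_toy_chain_matches_transition_matrix_oracle(self):
        # 2N = 8, backward 6 + forward 3 neutral steps: the full chain is
        # the 9th power of the binomial kernel
        two_n = 8
        cfg = tj.ShiftSimConfig(
            chb_present_freq=0.5, chb_const_ne=two_n / 2, split_gen=6,
            ancestral_ne=two_n / 2, ancient_sample_gen=3, contact_gen=2,
            bottleneck_gen=1,
        )
        null = tj.drift_only_null(cfg, n_reps=100_000, seed=32)
        M = _binomial_transition_matrix(two_n)
        v = np.zeros(two_n + 1)
        v[4] = 1.0
        expected = v @ np.linalg.matrix_power(M, 9)
        counts = np.bincount(
            np.round(null.freqs_at_ancient * two_n).astype(int), minlength=two_n + 1
        )
        chi2 = ((counts - null.n_reps * expected) ** 2 / (null.n_reps * expected)).sum()
        assert stats.chi2.sf(chi2, df=two_n) > 1e-3
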