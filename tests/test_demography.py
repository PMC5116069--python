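"""Demographic model, joint-SFS simulation and composite-likelihood fitting."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import integrate

from paleoscan import demography as dm


class TestEquivalentConstantNe:
    def test_constant_history_returns_plain_n(self):
        assert dm.equivalent_constant_ne(100.0, lambda t: 1000.0) == pytest.approx(1000.0)

    def test_exponential_growth_matches_numerical_integration(self):
        # doubling from 500 to 1000 over the epoch; oracle = direct
        # quadrature of the coalescent-time identity, done here
        T = 80.0
        r = math.log(2) / T
        hist = lambda t: 500.0 * math.exp(r * t)
        val, _ = integrate.quad(lambda t: 1.0 / hist(t), 0, T)
        oracle = T / val
        got = dm.equivalent_constant_ne(T, hist)
        assert got == pytest.approx(oracle, rel=1e-8)
        assert got == pytest.approx(1000.0 * math.log(2), rel=1e-6)

    def test_zero_rate_limit_equals_present_size(self):
        got = dm.equivalent_constant_ne(50.0, lambda t: 750.0 * math.exp(1e-12 * t))
        assert got == pytest.approx(750.0, rel=1e-9)

    def test_between_min_and_max_of_history(self):
        hist = lambda t: 100.0 + 50.0 * math.sin(t / 10.0) ** 2
        got = dm.equivalent_constant_ne(100.0, hist)
        assert 100.0 <= got <= 150.0

    def test_nonpositive_history_rejected(self):
        with pytest.raises(ValueError):
            dm.equivalent_constant_ne(10.0, lambda t: 100.0 - 30.0 * t)


@pytest.mark.parametrize(
    "years,expected", [(15_125, 605), (175, 7), (0, 0), (30, 1)]
)
def test_years_to_generations(years, expected):
    assert dm.years_to_generations(years) == expected


def test_years_to_generations_rejects_negative():
    with pytest.raises(ValueError):
        dm.years_to_generations(-5)


def test_bottleneck_size_reduction_is_57_percent():
    assert round(100 * dm.size_reduction(13_975, 6_006)) == 57


class TestModelValidation:
    def test_epochs_must_be_contiguous(self):
        with pytest.raises(dm.ModelValidationError):
            dm.PopulationSpec("A", (dm.Epoch(0, 5, 10.0), dm.Epoch(7, 9, 10.0)))

    def test_epoch_sizes_positive(self):
        with pytest.raises(dm.ModelValidationError):
            dm.Epoch(0, 5, -3.0)

    def test_split_times_ordered_along_lineage(self):
        pops = [
            dm.PopulationSpec("A", (dm.Epoch(0, math.inf, 100.0),), sample_size=4),
            dm.PopulationSpec("B", (dm.Epoch(0, math.inf, 100.0),), sample_size=4),
            dm.PopulationSpec("C", (dm.Epoch(0, math.inf, 100.0),)),
        ]
        splits = [dm.Split(50.0, ("A",), "B"), dm.Split(20.0, ("B",), "C")]
        with pytest.raises(dm.ModelValidationError):
            dm.DemographicModel(populations=pops, splits=splits)

    def test_ancient_sample_must_precede_split(self):
        with pytest.raises(dm.ModelValidationError):
            dm.prh_model(ancient_sample_gen=700.0)  # older than the 605-gen split

    def test_admixture_fraction_bounds(self):
        with pytest.raises(dm.ModelValidationError):
            dm.Admixture(4.0, "GBR", "TSIM", 1.5)


class TestJointSFS:
    def test_total_sites_conserved_and_deterministic(self, small_model):
        sfs1 = dm.simulate_joint_sfs(small_model, seed=11, pops=("CHB", "PRH", "TSIM"))
        sfs2 = dm.simulate_joint_sfs(small_model, seed=11, pops=("CHB", "PRH", "TSIM"))
        assert sfs1.total_sites == small_model.sequence_length
        assert np.array_equal(sfs1.counts, sfs2.counts)
        assert sfs1.counts.shape == (11, 11, 11)

    def test_neutral_single_population_sfs_follows_1_over_i(self, one_pop_model):
        # classical neutral expectation: E[count at derived frequency i]
        # is proportional to 1/i; recombination set well above the
        # mutation rate so sites are near-independent and the
        # chi-square sampling model applies
        model = one_pop_model(n=500.0, sample_size=10, L=5e5, mu=5e-7)
        model = dataclasses.replace(model, recombination_rate=5e-5)
        sfs = dm.simulate_joint_sfs(model, seed=3, num_chunks=20)
        seg = sfs.counts[1:-1]
        expected = 1.0 / np.arange(1, 10)
        expected = expected / expected.sum() * seg.sum()
        # chi-square against the 1/i shape
        chi2 = float(((seg - expected) ** 2 / expected).sum())
        from scipy import stats

        assert stats.chi2.sf(chi2, df=8) > 1e-3

    def test_zero_admixture_fraction_is_a_null_event(self):
        base = dm.prh_model(admixture_fraction=0.0, sequence_length=2e4)
        with_null = dataclasses.replace(
            base, admixture=dm.Admixture(4.0, "GBR", "TSIM", 0.0)
        )
        s1 = dm.simulate_joint_sfs(base, seed=5, pops=("CHB", "PRH", "TSIM"))
        s2 = dm.simulate_joint_sfs(with_null, seed=5, pops=("CHB", "PRH", "TSIM"))
        assert np.array_equal(s1.counts, s2.counts)

    def test_frame_round_trip(self, small_model):
        sfs = dm.simulate_joint_sfs(small_model, seed=2, pops=("CHB", "TSIM"))
        back = dm.JointSFS.from_frame(sfs.to_frame(), sfs.pops, sfs.counts.shape)
        assert np.array_equal(back.counts, sfs.counts)


class TestCompositeLoglik:
    def test_matches_hand_computed_multinomial(self):
        obs = dm.JointSFS(("P",), np.array([3.0, 7.0]))
        exp = dm.JointSFS(("P",), np.array([30.0, 70.0]))
        assert dm.composite_loglik(obs, exp) == pytest.approx(
            3 * math.log(0.3) + 7 * math.log(0.7)
        )

    def test_self_proportions_are_maximal(self):
        rng = np.random.default_rng(0)
        obs = dm.JointSFS(("P",), rng.integers(1, 50, size=6).astype(float))
        best = dm.composite_loglik(obs, obs)
        for _ in range(20):
            perturbed = dm.JointSFS(("P",), obs.counts + rng.uniform(0, 10, 6))
            assert dm.composite_loglik(obs, perturbed) <= best + 1e-9

    def test_permuting_expected_cells_lowers_value(self):
        obs = dm.JointSFS(("P",), np.array([50.0, 30.0, 15.0, 5.0]))
        exp = dm.JointSFS(("P",), np.array([50.0, 30.0, 15.0, 5.0]))
        permuted = dm.JointSFS(("P",), np.array([5.0, 15.0, 30.0, 50.0]))
        assert dm.composite_loglik(obs, permuted) < dm.composite_loglik(obs, exp)

    def test_axis_mismatch_rejected(self):
        a = dm.JointSFS(("P",), np.ones(3))
        b = dm.JointSFS(("Q",), np.ones(4))
        with pytest.raises(ValueError):
            dm.composite_loglik(a, b)

    def test_empty_expected_cell_floored_not_infinite(self):
        obs = dm.JointSFS(("P",), np.array([5.0, 5.0]))
        exp = dm.JointSFS(("P",), np.array([10.0, 0.0]))
        assert math.isfinite(dm.composite_loglik(obs, exp))


class TestFitDemography:
    def test_zero_free_params_returns_template_likelihood(self, one_pop_model):
        template = one_pop_model()  # builder defaults == template
        obs = dm.simulate_joint_sfs(template, seed=1, num_chunks=4)
        fit = dm.fit_demography(obs, one_pop_model, {}, seed=2, sim_chunks=4)
        ref = dm.composite_loglik(
            obs, dm.simulate_joint_sfs(template, seed=2, num_chunks=4)
        )
        assert fit.loglik == pytest.approx(ref)
        assert fit.params == {}

    def test_single_free_param_matches_grid_search_oracle(self, one_pop_model):
        # 1-D oracle: brute-force the population size on a log grid with
        # its own fixed-seed expected spectra; the optimizer should land
        # in the same likelihood basin
        obs = dm.simulate_joint_sfs(one_pop_model(n=500.0, L=3e5), seed=21,
                                    num_chunks=6)

        def expected_at(n):
            model = one_pop_model(n=n, L=3e6)
            return dm.simulate_joint_sfs(model, seed=77, num_chunks=30)

        grid = np.exp(np.linspace(np.log(150), np.log(1600), 25))
        lls = [dm.composite_loglik(obs, expected_at(n)) for n in grid]
        oracle_n = grid[int(np.argmax(lls))]

        fit = dm.fit_demography(
            obs, one_pop_model, {"n": (150.0, 1600.0)}, n_optimizations=2,
            seed=5, sim_chunks=30, expected_factor=10.0, maxiter=40,
        )
        assert abs(math.log(fit.params["n"] / oracle_n)) < 0.35
        assert abs(math.log(fit.params["n"] / 500.0)) < 0.5

    def test_fit_deterministic_given_seed(self, one_pop_model):
        obs = dm.simulate_joint_sfs(one_pop_model(L=5e4), seed=3, num_chunks=4)
        kw = dict(n_optimizations=1, seed=9, sim_chunks=6, expected_factor=4.0,
                  maxiter=10)
        f1 = dm.fit_demography(obs, one_pop_model, {"n": (100.0, 2000.0)}, **kw)
        f2 = dm.fit_demography(obs, one_pop_model, {"n": (100.0, 2000.0)}, **kw)
        assert f1.params == f2.params
        assert f1.loglik == f2.loglik


class TestParametricBootstrap:
    def test_two_reps_gives_ordered_degenerate_interval(self, one_pop_model):
        ci = dm.parametric_bootstrap(
            one_pop_model, {"n": 400.0}, {"n": (100.0, 2000.0)},
            observed_pops=["POP"], n_reps=2, seed=4, sim_chunks=4,
            expected_factor=2.0, maxiter=8,
        )
        lo, hi = ci["n"]
        assert lo <= 400.0 <= hi

    def test_fewer_than_two_reps_rejected(self, one_pop_model):
        with pytest.raises(ValueError):
            dm.parametric_bootstrap(
                one_pop_model, {"n": 400.0}, {"n": (100.0, 2000.0)},
                observed_pops=["POP"], n_reps=1, seed=4,
            )


def test_rescaled_model_preserves_compound_parameters():
    base = dm.prh_model()
    scaled = dm.rescale_model(base, 10.0)
    assert scaled.mutation_rate == pytest.approx(base.mutation_rate * 10)
    tsim_b = base.population("TSIM").epochs[0]
    tsim_s = scaled.population("TSIM").epochs[0]
    assert tsim_s.size == pytest.approx(tsim_b.size / 10)
    assert tsim_s.end_gen == pytest.approx(tsim_b.end_gen / 10)
    assert scaled.population("PRH").sampling_time == pytest.approx(6.0)
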