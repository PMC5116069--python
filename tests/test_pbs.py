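"""F_ST, PBS, admixture correction, neutral null and companion scans."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleoscan import demography as dm
from paleoscan import pbs
from paleoscan.freqs import FrequencyTable


def _reynolds_oracle(p1, n1, p2, n2):
    """Independently coded two-population coancestry estimator."""
    h1, h2 = 2 * p1 * (1 - p1), 2 * p2 * (1 - p2)
    shared = (n1 * h1 + n2 * h2) / (n1 + n2 - 2)
    a = (p1 - p2) ** 2 - (n1 + n2) * shared / (4 * n1 * n2)
    ab = (p1 - p2) ** 2 + (4 * n1 * n2 - n1 - n2) * shared / (4 * n1 * n2)
    return a, ab


def _hudson_oracle(p1, n1, p2, n2):
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


class TestFst:
    def test_identical_populations_truncate_to_zero(self):
        assert pbs.fst(0.4, 50, 0.4, 50) == 0.0
        assert pbs.fst(0.4, 50, 0.4, 50, "hudson") == 0.0

    @pytest.mark.parametrize("n1,n2", [(10, 8), (50, 50), (4, 30)])
    def test_fixed_difference_is_one_hudson(self, n1, n2):
        assert pbs.fst(1.0, n1, 0.0, n2, "hudson") == pytest.approx(1.0)

    def test_matches_formula_oracles_to_1e12(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            n1, n2 = rng.integers(4, 80, size=2)
            p1 = rng.integers(0, n1 + 1) / n1
            p2 = rng.integers(0, n2 + 1) / n2
            for est, oracle in (("reynolds", _reynolds_oracle), ("hudson", _hudson_oracle)):
                num, den = oracle(p1, n1, p2, n2)
                expect = 0.0 if den <= 0 else min(1.0, max(0.0, num / den))
                assert pbs.fst(p1, n1, p2, n2, est) == pytest.approx(expect, abs=1e-12)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            pbs.fst(0.5, 1, 0.5, 10)

    def test_unknown_estimator_rejected(self):
        with pytest.raises(ValueError):
            pbs.fst(0.5, 10, 0.5, 10, "nei")


class TestBranchLength:
    def test_zero(self):
        assert pbs.branch_length(0.0) == 0.0

    def test_half_is_ln_two(self):
        assert pbs.branch_length(0.5) == pytest.approx(math.log(2))

    def test_cap_at_one(self):
        assert pbs.branch_length(1.0) == pytest.approx(-math.log(1e-9), rel=1e-6)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pbs.branch_length(1.2)


class TestPBSPerSNP:
    def test_symmetric_tree_closed_form(self):
        # all pairwise F_ST equal -> PBS_X = -log(1-f)/2 for every branch
        rec = pbs.PBSRecord("u", 0.2, 0.2, 0.2)
        assert rec.pbs_x == pytest.approx(-math.log(0.8) / 2)
        assert rec.pbs_y == rec.pbs_x and rec.pbs_z == rec.pbs_x

    def test_focal_branch_closed_form(self):
        rec = pbs.PBSRecord("u", 0.2, 0.2, 0.0)
        assert rec.pbs_x == pytest.approx(-math.log(0.8), rel=1e-12)
        assert rec.pbs_y == pytest.approx(0.0, abs=1e-12)

    def test_focal_snp_with_reported_frequencies(self):
        # ancient panel fixed derived (1.0), modern 0.37, outgroup 0.46,
        # 50 chromosomes each: the ancient branch carries nearly all the
        # differentiation; oracle recomputes through the raw formulas
        rec = pbs.pbs_per_snp(1.0, 0.37, 0.46, 50, 50, 50, unit_id="rs9272426")
        f = lambda a, b: min(1.0, max(0.0, np.divide(*_reynolds_oracle(a, 50, b, 50))))
        t = lambda x: -math.log1p(-min(x, 1 - 1e-9))
        expect = (t(f(1.0, 0.37)) + t(f(1.0, 0.46)) - t(f(0.37, 0.46))) / 2
        assert rec.pbs_x == pytest.approx(expect, rel=1e-12)
        assert rec.pbs_x > rec.pbs_y and rec.pbs_x > rec.pbs_z

    def test_missing_frequency_rejected(self):
        with pytest.raises(ValueError):
            pbs.pbs_per_snp(0.5, float("nan"), 0.5, 50, 50, 50)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.floats(0, 1), st.floats(0, 1), st.floats(0, 1),
        st.integers(2, 100), st.integers(2, 100), st.integers(2, 100),
    )
    def test_branch_identity(self, px, py, pz, nx, ny, nz):
        # (PBS_X + PBS_Y) recovers T_XY exactly for every record
        rec = pbs.pbs_per_snp(px, py, pz, nx, ny, nz)
        assert rec.pbs_x + rec.pbs_y == pytest.approx(rec.t_xy, abs=1e-12)
        total = rec.pbs_x + rec.pbs_y + rec.pbs_z
        assert total == pytest.approx((rec.t_xy + rec.t_xz + rec.t_yz) / 2, abs=1e-12)


class TestPBSPerGene:
    def test_single_site_reduces_to_per_snp(self):
        gene = pbs.pbs_per_gene([0.9], [0.4], [0.5], [50], [50], [50])
        snp = pbs.pbs_per_snp(0.9, 0.4, 0.5, 50, 50, 50)
        assert gene.pbs_x == pytest.approx(snp.pbs_x, rel=1e-12)

    def test_identical_sites_equal_single_site(self):
        k = 6
        gene = pbs.pbs_per_gene([0.9] * k, [0.4] * k, [0.5] * k, [50] * k, [50] * k, [50] * k)
        single = pbs.pbs_per_gene([0.9], [0.4], [0.5], [50], [50], [50])
        assert gene.pbs_x == pytest.approx(single.pbs_x, rel=1e-12)
        assert gene.n_sites == k

    def test_outlier_site_pulls_value_between_extremes(self):
        px = [0.5, 0.5, 0.5, 1.0]
        py = [0.5, 0.5, 0.5, 0.1]
        pz = [0.5, 0.5, 0.5, 0.2]
        gene = pbs.pbs_per_gene(px, py, pz, 50, 50, 50)
        low = pbs.pbs_per_snp(0.5, 0.5, 0.5, 50, 50, 50).pbs_x
        high = pbs.pbs_per_snp(1.0, 0.1, 0.2, 50, 50, 50).pbs_x
        assert low < gene.pbs_x < high

    def test_monomorphic_sites_counted_but_not_summed(self):
        with_mono = pbs.pbs_per_gene([0.9, 0.0], [0.4, 0.0], [0.5, 0.0],
                                     [50, 50], [50, 50], [50, 50])
        without = pbs.pbs_per_gene([0.9], [0.4], [0.5], [50], [50], [50])
        assert with_mono.pbs_x == pytest.approx(without.pbs_x, rel=1e-12)
        assert with_mono.n_sites == 2

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            pbs.pbs_per_gene([], [], [], [], [], [])


class TestAdmixtureCorrection:
    def test_zero_alpha_is_identity(self):
        assert pbs.correct_frequency(0.37, 0.9, 0.0) == 0.37

    def test_symmetric_point_invariant(self):
        for a in (0.1, 0.4, 0.8):
            assert pbs.correct_frequency(0.5, 0.5, a) == pytest.approx(0.5)

    def test_worked_arithmetic(self):
        assert pbs.correct_frequency(0.37, 0.9, 0.2) == pytest.approx(0.2375)

    def test_alpha_one_rejected(self):
        with pytest.raises(ValueError):
            pbs.correct_frequency(0.5, 0.5, 1.0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 0.95))
    def test_mix_correct_round_trip(self, f_pre, f_eur, alpha):
        mixed = (1 - alpha) * f_pre + alpha * f_eur
        back = pbs.correct_frequency(mixed, f_eur, alpha)
        assert back == pytest.approx(f_pre, abs=1e-12)


class TestEstimateAlpha:
    def test_already_matching_gives_zero(self):
        assert pbs.estimate_alpha(0.3, 50, 0.9, 0.3, 50) == 0.0

    def test_recovers_forward_mixing_fraction(self):
        for a_true in (0.1, 0.3, 0.5):
            f_post = (1 - a_true) * 0.3 + a_true * 0.9
            a = pbs.estimate_alpha(f_post, 50, 0.9, 0.3, 50)
            assert a == pytest.approx(a_true, abs=0.011)

    def test_flat_objective_ties_resolve_to_zero(self):
        # f_eur == f_tsim: corrected frequency constant in alpha
        assert pbs.estimate_alpha(0.5, 50, 0.5, 0.8, 50) == 0.0


class TestPvalues:
    def test_reported_table_value_arithmetic(self):
        rng = np.random.default_rng(0)
        null = rng.permutation(np.linspace(0, 1, 100_000, endpoint=False))
        observed = 1.0 - 1_675 / 100_000  # exceeded by exactly 1,675 values
        assert pbs.pbs_pvalue(observed, null) == pytest.approx(0.01675)

    def test_observed_below_all_gives_one(self):
        assert pbs.pbs_pvalue(-1.0, np.arange(10.0)) == 1.0

    def test_observed_above_all_reports_resolution_bound(self):
        p = pbs.pbs_pvalue(99.0, np.linspace(0.0, 1.0, 1000))
        assert p == 0.0
        assert pbs.format_pvalue(p, 1000) == "< 0.001"

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            pbs.pbs_pvalue(1.0, np.array([]))


def _freq_table(rows):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "pop", "freq"])
    df["ancestral"], df["derived"] = "A", "G"
    df["n_haploid"], df["n_nonmissing"] = 50, 25
    return FrequencyTable(df)


class TestFreqChangeScan:
    def test_reported_snp_change(self):
        anc = _freq_table([("chr6", 100, "PRH", 1.0), ("chr6", 200, "PRH", 0.5)])
        mod = _freq_table([("chr6", 100, "TSIM", 0.37), ("chr6", 200, "TSIM", 0.5)])
        out = pbs.freq_change_scan(anc, mod)
        row = out[out["pos"] == 100].iloc[0]
        assert row["delta"] == pytest.approx(0.63)
        assert row["quantile"] == 1.0  # largest decline in this toy exome

    def test_identical_tables_give_zero_changes(self):
        t = _freq_table([("c", i, "P", 0.3) for i in range(1, 6)])
        out = pbs.freq_change_scan(t, t)
        assert np.allclose(out["delta"], 0.0)

    def test_disjoint_tables_rejected(self):
        a = _freq_table([("c", 1, "P", 0.3)])
        b = _freq_table([("c", 2, "P", 0.3)])
        with pytest.raises(ValueError):
            pbs.freq_change_scan(a, b)


class TestHaplotypeProfile:
    def test_reference_to_itself_is_zero(self):
        ref = np.array([0, 1, 1, 0])
        out = pbs.haplotype_diff_profile({"P": ref[None, :]}, ref)
        assert out["differences"].tolist() == [0]

    def test_complement_is_full_length(self):
        ref = np.array([0, 1, 1, 0, 1])
        out = pbs.haplotype_diff_profile({"P": (1 - ref)[None, :]}, ref)
        assert out["differences"].tolist() == [5]

    def test_toy_haplotypes_hand_counted_and_sorted(self):
        ref = np.array([0, 0, 0, 0])
        haps = np.array([[1, 1, 0, 0], [0, 0, 0, 1], [1, 1, 1, 1], [0, 0, 0, 0]])
        out = pbs.haplotype_diff_profile({"P": haps}, ref)
        assert out["differences"].tolist() == [0, 1, 2, 4]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pbs.haplotype_diff_profile({"P": np.zeros((2, 3))}, np.zeros(4))


class TestNeutralNull:
    def test_same_seed_identical_and_lengths_resampled(self, small_model):
        lengths = np.array([2000.0, 3000.0, 4000.0])
        n1 = pbs.neutral_pbs_null(small_model, lengths, 6, seed=5)
        n2 = pbs.neutral_pbs_null(small_model, lengths, 6, seed=5)
        assert np.array_equal(n1.values, n2.values)
        assert np.array_equal(n1.lengths, n2.lengths)
        assert set(n1.lengths) <= set(lengths)

    def test_zero_site_replicates_contribute_zero(self, small_model):
        silent = dataclasses.replace(small_model, mutation_rate=1e-15)
        null = pbs.neutral_pbs_null(silent, np.array([500.0]), 3, seed=1)
        assert np.allclose(null.values, 0.0)

    def test_correction_never_inflates_outgroup_branch(self, small_model):
        # per-locus alpha minimizes F_ST between corrected modern and
        # outgroup, so the branch toward the outgroup can only shrink
        # on average on neutral admixed data
        raw_z, corr_z = [], []
        for seed in range(30):
            region = dm.simulate_region(small_model, sequence_length=4000.0,
                                        seed=100 + seed)
            if region.genotypes.shape[0] == 0:
                continue
            fx, fy, fz = (region.frequencies(p) for p in ("PRH", "TSIM", "CHB"))
            feur = region.frequencies("GBR")
            nx = ny = nz = 10
            raw_z.append(pbs.pbs_per_gene(fx, fy, fz, nx, ny, nz).pbs_z)
            alpha = pbs.estimate_alpha(fy, ny, feur, fz, nz)
            fy_c = pbs.correct_frequency(fy, feur, alpha)
            corr_z.append(pbs.pbs_per_gene(fx, fy_c, fz, nx, ny, nz).pbs_z)
        assert np.mean(corr_z) <= np.mean(raw_z) + 1e-9

    def test_pvalues_uniform_when_observed_drawn_from_null(self, small_model):
        from scipy import stats

        lengths = np.array([3000.0])
        obs = pbs.neutral_pbs_null(small_model, lengths, 120, seed=21)
        null = pbs.neutral_pbs_null(small_model, lengths, 500, seed=22)
        pvals = np.array([pbs.pbs_pvalue(v, null) for v in obs.values])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_gene_scan_windows_and_metadata(small_model):
    rng = np.random.default_rng(2)
    pos = np.arange(1, 61) * 500
    rows = []
    for pop in ("PRH", "TSIM", "CHB", "GBR"):
        for p in pos:
            rows.append(("chr1", p, pop, rng.integers(0, 51) / 50))
    table = _freq_table(rows)
    genes = [
        pbs.GeneAnnotation("inside", "chr1", 10_000, 12_000, flank=1_000),
        pbs.GeneAnnotation("desert", "chr2", 1, 100, flank=0),
    ]
    scan = pbs.pbs_scan_genes(table, genes, correct=True)
    assert scan["gene_id"].tolist() == ["inside"]  # empty window skipped
    assert scan.attrs["admixture_corrected"] is True
    n_expected = ((pos >= 9_000) & (pos <= 13_000)).sum()
    assert scan.iloc[0]["n_sites"] == n_expected
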