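"""Difference graphs, joint spectra, distances and the cohort ANOVA."""

import numpy as np
import pytest
from scipy.stats import f_oneway

from kmerdelta import (
    ABSENT,
    BinScheme,
    BinnedSpectrum,
    KmerDump,
    anova_partition,
    binned_genome_size,
    count_reference_kmers,
    diff_graph,
    distance_matrix,
    joint_marginals,
    joint_spectrum,
    make_pair,
    permutation_check,
    scale_and_bin,
    spectrum_of,
    total_gs_difference,
    GenomeSpec,
)

from conftest import random_dna


def _random_dump(rng, k=7, n_entries=200, max_count=60):
    dump = count_reference_kmers(random_dna(rng, 4 * n_entries), k)
    counts = rng.integers(1, max_count, size=len(dump)).astype(np.int64)
    return KmerDump(k, dump.codes, counts)


class TestDiffGraph:
    def test_identical_samples_give_zero(self):
        b = scale_and_bin_from({7: 100, 14: 300})
        d = diff_graph(b, b)
        assert d.total_bp == 0.0
        assert np.all(d.count_diff == 0)
        assert np.all(d.cumulative_bp == 0)

    def test_planted_extra_peak_at_copy_four(self):
        scheme = BinScheme()
        bin4 = scheme.index(4.0)
        a = BinnedSpectrum(scheme, {7: 500}, 10)
        b = BinnedSpectrum(scheme, {7: 500, bin4: 1000}, 10)
        d = diff_graph(a, b)
        assert d.total_bp == pytest.approx(-1000 * scheme.representative(bin4))
        # cumulative flat except the single step at bin(4)
        steps = np.flatnonzero(np.diff(np.concatenate(([0.0], d.cumulative_bp))))
        assert list(d.bins[steps]) == [bin4]

    def test_antisymmetry_under_swap(self):
        rng = np.random.default_rng(9)
        scheme = BinScheme()
        for _ in range(10):
            a = BinnedSpectrum(
                scheme,
                {int(i): int(n) for i, n in zip(rng.integers(0, 80, 15), rng.integers(1, 500, 15))},
                10,
            )
            b = BinnedSpectrum(
                scheme,
                {int(i): int(n) for i, n in zip(rng.integers(0, 80, 15), rng.integers(1, 500, 15))},
                10,
            )
            d_ab, d_ba = diff_graph(a, b), diff_graph(b, a)
            assert np.array_equal(d_ab.bins, d_ba.bins)
            assert np.array_equal(d_ab.count_diff, -d_ba.count_diff)
            assert np.allclose(d_ab.bp_diff, -d_ba.bp_diff)
            assert np.allclose(d_ab.cumulative_bp, -d_ba.cumulative_bp)

    def test_total_equals_binned_size_difference(self):
        rng = np.random.default_rng(13)
        scheme = BinScheme()
        a = BinnedSpectrum(scheme, {i: int(rng.integers(1, 100)) for i in range(30)}, 10)
        b = BinnedSpectrum(scheme, {i: int(rng.integers(1, 100)) for i in range(5, 40)}, 10)
        d = diff_graph(a, b)
        assert d.total_bp == pytest.approx(
            binned_genome_size(a) - binned_genome_size(b)
        )

    def test_scheme_mismatch_rejected(self):
        a = BinnedSpectrum(BinScheme(), {1: 1}, 10)
        b = BinnedSpectrum(BinScheme(0.5, 1.2), {1: 1}, 10)
        with pytest.raises(ValueError):
            diff_graph(a, b)

    def test_planted_repeat_difference_steps_near_its_copy_number(self):
        # one genome carries 500 extra satellite copies per haplotype: the
        # cumulative difference graph must step at the satellite's copy number
        spec = GenomeSpec(
            unique_len=120_000,
            heterozygosity=0.002,
            satellite=(145, 1_500),
            te=(2_000, 5, 0.02),
            rdna=(3_000, 5),
            organelle=(50_000, 1.0),
            seed=77,
        )
        g_ref, g_small = make_pair(spec, {"satellite": -500})
        dumps = [
            count_reference_kmers([g.haplotype_a, g.haplotype_b], 21)
            for g in (g_ref, g_small)
        ]
        # counting both haplotypes of an assembly: monoploid copy number = 1
        binned = [scale_and_bin(spectrum_of(d), 1.0) for d in dumps]
        d = diff_graph(binned[0], binned[1])
        peak_bin = int(d.bins[np.argmax(d.bp_diff)])
        rep = d.scheme.representative(peak_bin)
        assert 1_500 * 2 * 0.8 <= rep <= 1_500 * 2 * 1.2
        # step magnitude: all 145 satellite k-mers at the reference copy number
        assert d.bp_diff.max() == pytest.approx(145 * 3_000, rel=0.10)
        assert d.total_bp > 0


def scale_and_bin_from(counts, c=10.0):
    return BinnedSpectrum(BinScheme(), counts, c)


class TestTotalGsDifference:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (1227.92, 999.98, 227.94),
            (989.23, 999.98, -10.75),
            (1055.93, 999.98, 55.95),
            (1104.84, 1104.84, 0.0),
        ],
    )
    def test_pairwise_differences(self, a, b, expected):
        assert total_gs_difference(a, b) == pytest.approx(expected)


class TestJointSpectrum:
    def test_two_kmer_hand_join(self):
        a = KmerDump.from_dict(3, {"ACG": 10, "GTA": 20})
        b = KmerDump.from_dict(3, {"ACG": 10})
        j = joint_spectrum(a, b, 10, 10)
        scheme = j.scheme
        assert j.cells == {
            (scheme.index(1.0), scheme.index(1.0)): 1,
            (scheme.index(2.0), ABSENT): 1,
        }

    def test_identical_dumps_all_diagonal(self):
        rng = np.random.default_rng(21)
        a = _random_dump(rng)
        j = joint_spectrum(a, a, 10, 10)
        assert all(i == jj for (i, jj) in j.cells)

    def test_empty_inputs_give_empty_matrix(self):
        j = joint_spectrum(KmerDump.empty(3), KmerDump.empty(3), 10, 10)
        assert j.cells == {}
        ma, mb = joint_marginals(j)
        assert ma.counts == {} and mb.counts == {}

    def test_k_mismatch_rejected(self):
        with pytest.raises(ValueError):
            joint_spectrum(KmerDump.empty(3), KmerDump.empty(5), 10, 10)

    def test_inner_join_drops_absent(self):
        a = KmerDump.from_dict(3, {"ACG": 10, "GTA": 20})
        b = KmerDump.from_dict(3, {"ACG": 10})
        j = joint_spectrum(a, b, 10, 10, join="inner")
        assert all(i != ABSENT and jj != ABSENT for (i, jj) in j.cells)
        assert j.total_kmers == 1

    def test_marginals_match_binned_spectra_on_random_dumps(self):
        rng = np.random.default_rng(31)
        for _ in range(8):
            a = _random_dump(rng, n_entries=int(rng.integers(50, 400)))
            b = _random_dump(rng, n_entries=int(rng.integers(50, 400)))
            c_a, c_b = float(rng.uniform(5, 30)), float(rng.uniform(5, 30))
            j = joint_spectrum(a, b, c_a, c_b)
            ma, mb = joint_marginals(j)
            assert ma.counts == scale_and_bin(spectrum_of(a), c_a).counts
            assert mb.counts == scale_and_bin(spectrum_of(b), c_b).counts

    def test_hand_join_marginal(self):
        a = KmerDump.from_dict(3, {"ACG": 10, "GTA": 20})
        b = KmerDump.from_dict(3, {"ACG": 10})
        ma, _ = joint_marginals(joint_spectrum(a, b, 10, 10))
        scheme = BinScheme()
        assert ma.counts == {scheme.index(1.0): 1, scheme.index(2.0): 1}

    def test_table_roundtrip_shape(self):
        rng = np.random.default_rng(41)
        j = joint_spectrum(_random_dump(rng), _random_dump(rng), 10, 12)
        table = j.to_table()
        assert set(table.columns) == {"count", "bin_a", "bin_b"}
        assert table["count"].sum() == j.total_kmers


class TestDistances:
    def test_duplicate_samples_zero(self):
        b = scale_and_bin_from({3: 10, 9: 40})
        d = distance_matrix([b, b], "manhattan", labels=["x", "y"])
        assert d.get("x", "y") == 0.0

    def test_manhattan_single_bin_difference(self):
        a = scale_and_bin_from({3: 10})
        b = scale_and_bin_from({3: 15})
        assert distance_matrix([a, b], "manhattan").values[0, 1] == 5.0

    def test_gower_bounded(self):
        rng = np.random.default_rng(17)
        samples = [
            scale_and_bin_from(
                {int(i): int(n) for i, n in zip(rng.integers(0, 40, 10), rng.integers(1, 900, 10))}
            )
            for _ in range(5)
        ]
        d = distance_matrix(samples, "gower")
        assert d.values.min() >= 0 and d.values.max() <= 1
        assert np.allclose(d.values, d.values.T)
        assert np.all(np.diag(d.values) == 0)

    def test_manhattan_triangle_inequality(self):
        rng = np.random.default_rng(19)
        samples = [
            scale_and_bin_from(
                {int(i): int(n) for i, n in zip(rng.integers(0, 40, 12), rng.integers(1, 900, 12))}
            )
            for _ in range(6)
        ]
        d = distance_matrix(samples, "manhattan").values
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            distance_matrix([scale_and_bin_from({1: 1})])


# 2C genome sizes (Mbp) of the seven samples, grouped by species
COHORT_GS = [999.98, 989.23, 1055.93, 1227.92, 1126.64, 1096.44, 1104.84]
COHORT_SPECIES = ["anglica", "anglica", "vigursii", "rostkoviana",
                  "rivularis", "rivularis", "rivularis"]


class TestAnova:
    def test_species_explains_cohort_genome_sizes(self):
        res = anova_partition(COHORT_GS, COHORT_SPECIES)
        assert round(res.F, 2) == 72.43
        assert res.df_between == 3 and res.df_within == 3
        assert round(100 * res.variance_explained, 1) == 98.6
        assert res.p == pytest.approx(0.0027, abs=0.0001)

    def test_matches_scipy_f_oneway(self):
        res = anova_partition(COHORT_GS, COHORT_SPECIES)
        ref = f_oneway(
            COHORT_GS[0:2], COHORT_GS[2:3], COHORT_GS[3:4], COHORT_GS[4:7]
        )
        assert res.F == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_all_equal_values(self):
        res = anova_partition([5.0, 5.0, 5.0, 5.0], ["a", "a", "b", "b"])
        assert res.F == 0.0 and res.variance_explained == 0.0

    def test_hand_computed_sums_of_squares(self):
        # groups {1,3} and {5,7}: SSB = 16, SSW = 4, F = (16/1)/(4/2) = 8
        res = anova_partition([1, 3, 5, 7], ["a", "a", "b", "b"])
        assert res.F == pytest.approx(8.0)
        assert res.variance_explained == pytest.approx(16 / 20)

    def test_degenerate_df_rejected(self):
        with pytest.raises(ValueError):
            anova_partition([1.0, 2.0], ["a", "b"])
        with pytest.raises(ValueError):
            anova_partition([1.0, 2.0], ["a", "a"])


class TestPermutationCheck:
    def test_deterministic_under_seed(self):
        r1 = permutation_check(COHORT_GS, COHORT_SPECIES, 99, seed=5)
        r2 = permutation_check(COHORT_GS, COHORT_SPECIES, 99, seed=5)
        assert np.array_equal(r1.f_perm, r2.f_perm)
        assert r1.f_exceedance == r2.f_exceedance

    def test_rank_bound_of_exceedance(self):
        # add-one rule: exceedance = (1 + #{perm >= obs}) / (1 + n_perm),
        # so it is minimal exactly when the observed F beats every permutation
        res = permutation_check(COHORT_GS, COHORT_SPECIES, 199, seed=1)
        ties = int((res.f_perm >= res.observed.F).sum())
        assert res.f_exceedance == (1 + ties) / (1 + 199)
        assert res.f_exceedance >= 1 / (1 + 199)
        if ties == 0:
            assert res.f_exceedance == 1 / (1 + 199)
        assert 0 < res.f_exceedance <= 1

    def test_cohort_statistics_unlikely_by_chance(self):
        res = permutation_check(COHORT_GS, COHORT_SPECIES, 499, seed=2)
        assert res.observed.F > res.f_q95
        assert res.observed.variance_explained > res.ve_q95

    def test_uninformative_labels_are_calibrated(self):
        rng = np.random.default_rng(8)
        hits = 0
        runs = 40
        for _ in range(runs):
            vals = rng.normal(size=9)
            groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
            res = permutation_check(vals, groups, 99, seed=int(rng.integers(2**31)))
            if res.observed.F <= res.f_q95:
                hits += 1
        # about 95% of null runs should fall inside the one-sided 95% interval
        assert hits >= int(0.8 * runs)

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            permutation_check(COHORT_GS, COHORT_SPECIES, 50, seed=0)
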