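"""Diversity, phi-ST AMOVA, permutation and Mantel tests."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stockshift import (
    DataError,
    DistanceMatrix,
    HaplotypeCounts,
    HaplotypePanel,
    LabeledMatrix,
    UndefinedStatisticError,
    haplotype_diversity,
    mantel_test,
    nucleotide_diversity,
    pairwise_differences,
    pairwise_phi_matrix,
    phi_st,
    phi_st_permutation_test,
    year_distance_matrix,
)


class TestPairwiseDifferences:
    def test_zero_diagonal_and_single_mismatch(self):
        panel = HaplotypePanel({"A": "ACGT", "B": "ACGA"})
        d = pairwise_differences(panel)
        assert d[("A", "A")] == 0 and d[("A", "B")] == 1

    def test_ambiguous_positions_skipped(self):
        panel = HaplotypePanel({"A": "ACGT", "B": "NCGA"})
        assert pairwise_differences(panel)[("A", "B")] == 1  # position 0 skipped

    def test_matches_position_loop_oracle(self, small_panel, distances6):
        names = small_panel.names
        for i, j in itertools.combinations(range(len(names)), 2):
            si, sj = small_panel.entries[names[i]], small_panel.entries[names[j]]
            oracle = sum(
                a != b and a in "ACGT" and b in "ACGT" for a, b in zip(si, sj)
            )
            assert distances6.values[i, j] == oracle


class TestDiversity:
    def test_monomorphic_h_zero(self):
        assert haplotype_diversity(HaplotypeCounts("x", {"A": 17})) == 0.0

    def test_two_singletons_h_one(self):
        assert haplotype_diversity(HaplotypeCounts("x", {"A": 1, "B": 1})) == 1.0

    def test_hand_evaluated_value(self):
        # h = (4/3)(1 - (9+1)/16) = 0.5
        assert haplotype_diversity(HaplotypeCounts("x", {"A": 3, "B": 1})) == pytest.approx(0.5)

    def test_h_needs_two_individuals(self):
        with pytest.raises(DataError):
            haplotype_diversity(HaplotypeCounts("x", {"A": 1}))

    @given(st.integers(2, 40), st.integers(0, 40), st.integers(0, 40))
    @settings(max_examples=30, deadline=None)
    def test_h_invariant_under_relabeling(self, a, b, c):
        counts = {"A": a, "B": b, "C": c}
        relabeled = {"X": a, "Y": b, "Z": c}
        assert haplotype_diversity(HaplotypeCounts("l", counts)) == pytest.approx(
            haplotype_diversity(HaplotypeCounts("l", relabeled))
        )

    def test_pi_monomorphic_zero(self, distances6, small_panel):
        counts = HaplotypeCounts("x", {small_panel.names[0]: 9})
        assert nucleotide_diversity(counts, distances6, small_panel.length) == 0.0

    def test_pi_closed_form_two_haplotypes(self):
        d = DistanceMatrix(("A", "B"), np.array([[0.0, 1.0], [1.0, 0.0]]))
        counts = HaplotypeCounts("x", {"A": 5, "B": 5})
        assert nucleotide_diversity(counts, d, 474) == pytest.approx(2 * 0.5 * 0.5 / 474)

    def test_pi_matches_double_loop_oracle(self, small_panel, distances6):
        counts = HaplotypeCounts("x", {n: c for n, c in zip(small_panel.names, (5, 3, 2, 1))})
        n = counts.n
        oracle = 0.0
        for hi, ci in counts.counts.items():
            for hj, cj in counts.counts.items():
                oracle += (ci / n) * (cj / n) * distances6[(hi, hj)]
        oracle /= small_panel.length
        assert nucleotide_diversity(counts, distances6, small_panel.length) == pytest.approx(oracle)

    def test_pi_scales_inversely_with_length(self, small_panel, distances6):
        counts = HaplotypeCounts("x", {small_panel.names[0]: 4, small_panel.names[1]: 4})
        assert nucleotide_diversity(counts, distances6, 100) == pytest.approx(
            nucleotide_diversity(counts, distances6, 200) * 2
        )


@pytest.fixture()
def two_hap_distance():
    return DistanceMatrix(("A", "B"), np.array([[0.0, 3.0], [3.0, 0.0]]))


class TestPhiSt:
    def test_no_variation_undefined(self, two_hap_distance):
        with pytest.raises(UndefinedStatisticError):
            phi_st(
                HaplotypeCounts("a", {"A": 5}), HaplotypeCounts("b", {"A": 5}), two_hap_distance
            )

    def test_fixed_difference_gives_one(self, two_hap_distance):
        phi = phi_st(
            HaplotypeCounts("a", {"A": 10}), HaplotypeCounts("b", {"B": 10}), two_hap_distance
        )
        assert phi == pytest.approx(1.0)

    def test_identical_mixtures_non_positive(self, two_hap_distance):
        phi = phi_st(
            HaplotypeCounts("a", {"A": 5, "B": 5}),
            HaplotypeCounts("b", {"A": 5, "B": 5}),
            two_hap_distance,
        )
        assert phi <= 0

    def test_matches_individual_level_oracle(self, distances6, small_panel, phi_oracle):
        names = small_panel.names
        ga = {names[0]: 4, names[1]: 2, names[2]: 1}
        gb = {names[0]: 1, names[3]: 3, names[4]: 2}
        phi = phi_st(HaplotypeCounts("a", ga), HaplotypeCounts("b", gb), distances6)
        assert phi == pytest.approx(phi_oracle([ga, gb], distances6))

    @pytest.mark.parametrize("scale", [0.5, 2.0, 17.0])
    def test_invariant_under_distance_scaling(self, distances6, small_panel, scale):
        names = small_panel.names
        ga, gb = HaplotypeCounts("a", {names[0]: 6, names[1]: 2}), HaplotypeCounts(
            "b", {names[0]: 2, names[2]: 5}
        )
        scaled = DistanceMatrix(distances6.labels, distances6.values * scale)
        assert phi_st(ga, gb, distances6) == pytest.approx(phi_st(ga, gb, scaled))


class TestPhiPermutation:
    def test_reproducible_given_seed(self, distances6, small_panel):
        names = small_panel.names
        ga = HaplotypeCounts("a", {names[0]: 5, names[1]: 5})
        gb = HaplotypeCounts("b", {names[0]: 2, names[2]: 8})
        r1 = phi_st_permutation_test(ga, gb, distances6, n_perm=300, seed=42)
        r2 = phi_st_permutation_test(ga, gb, distances6, n_perm=300, seed=42)
        assert (r1.phi_st, r1.p_value) == (r2.phi_st, r2.p_value)

    def test_null_composition_large_p(self, two_hap_distance):
        # identical group compositions: true null, p should average ~0.5+
        ps = [
            phi_st_permutation_test(
                HaplotypeCounts("a", {"A": 6, "B": 4}),
                HaplotypeCounts("b", {"A": 6, "B": 4}),
                two_hap_distance,
                n_perm=99,
                seed=s,
            ).p_value
            for s in range(20)
        ]
        assert np.mean(ps) > 0.35

    def test_maximal_statistic_small_p(self, two_hap_distance):
        res = phi_st_permutation_test(
            HaplotypeCounts("a", {"A": 10}),
            HaplotypeCounts("b", {"B": 10}),
            two_hap_distance,
            n_perm=999,
            seed=1,
        )
        assert res.phi_st == pytest.approx(1.0)
        assert res.p_value <= 0.01

    def test_matches_exhaustive_enumeration(self, two_hap_distance, phi_oracle):
        """Monte-Carlo p within 3 binomial SE of the exact enumeration p on 6 individuals."""
        ga, gb = {"A": 2, "B": 1}, {"A": 1, "B": 2}
        observed = phi_oracle([ga, gb], two_hap_distance)
        pooled = ["A", "A", "A", "B", "B", "B"]
        n_ge = 0
        total = 0
        for combo in itertools.combinations(range(6), 3):  # exact: all splits equally likely
            grp_a = [pooled[i] for i in combo]
            grp_b = [pooled[i] for i in range(6) if i not in combo]
            ca = {h: grp_a.count(h) for h in set(grp_a)}
            cb = {h: grp_b.count(h) for h in set(grp_b)}
            total += 1
            if phi_oracle([ca, cb], two_hap_distance) >= observed - 1e-12:
                n_ge += 1
        exact_p = n_ge / total
        n_perm = 2000
        res = phi_st_permutation_test(
            HaplotypeCounts("a", ga), HaplotypeCounts("b", gb), two_hap_distance,
            n_perm=n_perm, seed=7,
        )
        se = math.sqrt(exact_p * (1 - exact_p) / n_perm)
        assert abs(res.p_value - exact_p) <= 3 * se + 1 / (n_perm + 1)


class TestPairwisePhiMatrix:
    def test_requires_three_partitions(self, distances6, small_panel):
        parts = [HaplotypeCounts(f"p{i}", {small_panel.names[i]: 5}) for i in range(2)]
        with pytest.raises(DataError):
            pairwise_phi_matrix(parts, distances6)

    def test_identical_partitions_non_positive(self, distances6, small_panel):
        names = small_panel.names
        parts = [HaplotypeCounts(f"p{i}", {names[0]: 5, names[1]: 5}) for i in range(3)]
        mat = pairwise_phi_matrix(parts, distances6)
        off = mat.values[np.triu_indices(3, 1)]
        assert np.all(off <= 1e-12)

    def test_matches_per_pair_calls(self, distances6, small_panel):
        rng = np.random.default_rng(8)
        names = small_panel.names
        parts = []
        for i in range(4):
            counts = {n: int(c) for n, c in zip(names, rng.multinomial(30, rng.dirichlet(np.ones(6)))) if c}
            parts.append(HaplotypeCounts(f"y{i}", counts))
        mat = pairwise_phi_matrix(parts, distances6)
        for i, j in itertools.combinations(range(4), 2):
            assert mat.values[i, j] == pytest.approx(phi_st(parts[i], parts[j], distances6))

    def test_undefined_cells_flagged_nan(self, distances6, small_panel):
        names = small_panel.names
        parts = [
            HaplotypeCounts("p0", {names[0]: 5}),
            HaplotypeCounts("p1", {names[0]: 5}),
            HaplotypeCounts("p2", {names[1]: 5}),
        ]
        mat = pairwise_phi_matrix(parts, distances6)
        assert np.isnan(mat.values[0, 1]) and np.isfinite(mat.values[0, 2])


def random_matrix(labels, seed):
    rng = np.random.default_rng(seed)
    a = np.triu(rng.uniform(0.5, 5.0, (len(labels), len(labels))), 1)
    return LabeledMatrix(tuple(labels), a + a.T)


class TestMantel:
    def test_self_correlation(self):
        mat = random_matrix("abcdef", 1)
        res = mantel_test(mat, mat, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0) and res.r_squared == pytest.approx(1.0)

    def test_constant_matrix_undefined(self):
        mat = random_matrix("abcdef", 2)
        const = np.ones((6, 6)) - np.eye(6)
        flat = LabeledMatrix(mat.labels, const)
        with pytest.raises(UndefinedStatisticError):
            mantel_test(mat, flat, n_perm=99, seed=0)

    def test_matches_exhaustive_enumeration(self):
        """MC p within 3 binomial SE of the exact p over all 120 permutations of 5 labels."""
        rng = np.random.default_rng(12)
        labels = tuple("abcde")
        a = rng.uniform(0, 1, (5, 5))
        a = np.triu(a, 1)
        a = a + a.T
        b = year_distance_matrix({l: y for l, y in zip(labels, [2006, 2008, 2011, 2015, 2016])})
        mat_a = LabeledMatrix(labels, a)
        iu = np.triu_indices(5, 1)
        r_obs = np.corrcoef(a[iu], b.values[iu])[0, 1]
        n_ge = 0
        for perm in itertools.permutations(range(5)):
            ap = a[np.ix_(perm, perm)]
            if np.corrcoef(ap[iu], b.values[iu])[0, 1] >= r_obs - 1e-12:
                n_ge += 1
        exact_p = n_ge / 120
        n_perm = 3000
        res = mantel_test(mat_a, b, n_perm=n_perm, seed=5)
        assert res.r == pytest.approx(r_obs)
        se = math.sqrt(exact_p * (1 - exact_p) / n_perm)
        assert abs(res.p_value - exact_p) <= 3 * se + 1 / (n_perm + 1)

    def test_nan_cells_excluded_pairwise(self):
        mat = random_matrix("abcdef", 3)
        vals = mat.values.copy()
        vals[0, 1] = vals[1, 0] = np.nan
        holey = LabeledMatrix(mat.labels, vals)
        res = mantel_test(holey, random_matrix("abcdef", 4), n_perm=99, seed=3)
        assert np.isfinite(res.r)
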