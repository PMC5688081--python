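"""Haploid Weir θ against a straight-line oracle, and permutation behaviour."""
from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sweepscan import permutation_pvalues, weir_haploid_fst
from sweepscan.fst import _theta_components, fst_contrast_vector, multilocus_theta

from conftest import make_matrix


def oracle_theta(n1, c1, n2, c2):
    """Independent scalar evaluation of MSP/MSG/n_c/θ, straight off the formulas."""
    if n1 < 2 or n2 < 2:
        return float("nan")
    p1, p2 = c1 / n1, c2 / n2
    n_t = n1 + n2
    p_bar = (c1 + c2) / n_t
    msp = n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n_t - 2)
    n_c = n_t - (n1 * n1 + n2 * n2) / n_t
    denom = msp + (n_c - 1) * msg
    if (msp == 0 and msg == 0) or denom == 0:
        return float("nan")
    return (msp - msg) / denom


def matrix_from_counts(n1, c1, n2, c2):
    col = [1] * c1 + [0] * (n1 - c1) + [1] * c2 + [0] * (n2 - c2)
    calls = np.array(col, dtype=np.int8)[:, None]
    return make_matrix(calls, populations=["A"] * n1 + ["B"] * n2)


class TestTheta:
    def test_fixed_difference_gives_one(self):
        for n in (2, 5, 30):
            m = matrix_from_counts(n, n, n, 0)
            assert weir_haploid_fst(m, "A", "B").theta[0] == 1.0

    def test_monomorphic_site_undefined(self):
        m = matrix_from_counts(5, 0, 5, 0)
        assert np.isnan(weir_haploid_fst(m, "A", "B").theta[0])

    def test_example_counts_match_oracle(self):
        # n1 = n2 = 10, alt counts 8 and 2
        m = matrix_from_counts(10, 8, 10, 2)
        got = weir_haploid_fst(m, "A", "B").theta[0]
        assert got == pytest.approx(oracle_theta(10, 8, 10, 2), abs=1e-12)

    def test_random_counts_match_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            n1, n2 = rng.integers(2, 15, 2)
            c1 = rng.integers(0, n1 + 1)
            c2 = rng.integers(0, n2 + 1)
            got = _theta_components(n1, c1, n2, c2)[0]
            want = oracle_theta(n1, c1, n2, c2)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)
                assert got <= 1.0

    def test_symmetry_in_population_order(self, two_pop_matrix):
        ab = weir_haploid_fst(two_pop_matrix, "A", "B").theta
        ba = weir_haploid_fst(two_pop_matrix, "B", "A").theta
        np.testing.assert_allclose(ab, ba, rtol=0, atol=1e-12)

    @given(
        n1=st.integers(2, 12), n2=st.integers(2, 12),
        f1=st.floats(0, 1), f2=st.floats(0, 1),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_allele_coding_swap_invariance(self, n1, n2, f1, f2):
        c1, c2 = round(f1 * n1), round(f2 * n2)
        direct = oracle_theta(n1, c1, n2, c2)
        swapped = _theta_components(n1, n1 - c1, n2, n2 - c2)[0]
        if np.isnan(direct):
            assert np.isnan(swapped)
        else:
            assert swapped == pytest.approx(direct, abs=1e-12)

    def test_unknown_population_errors(self, two_pop_matrix):
        with pytest.raises(ValueError, match="unknown population"):
            weir_haploid_fst(two_pop_matrix, "A", "Z")

    def test_missing_calls_reduce_sample_size(self):
        m = matrix_from_counts(6, 4, 6, 1)
        m.calls[0, 0] = -1  # one A sample missing
        res = weir_haploid_fst(m, "A", "B")
        assert res.n1[0] == 5
        assert res.theta[0] == pytest.approx(oracle_theta(5, 3, 6, 1), abs=1e-12)


class TestPermutations:
    def exhaustive_oracle(self, calls, n_a):
        """Brute-force p over all label assignments, independent of the library."""
        n = len(calls)
        obs = oracle_theta(n_a, int(sum(calls[:n_a])), n - n_a, int(sum(calls[n_a:])))
        hits = total = 0
        for combo in itertools.combinations(range(n), n_a):
            in_a = [calls[i] for i in combo]
            out = [calls[i] for i in range(n) if i not in combo]
            t = oracle_theta(n_a, int(sum(in_a)), n - n_a, int(sum(out)))
            total += 1
            if not np.isnan(t) and t >= obs:
                hits += 1
        return hits / total

    def test_fixed_difference_three_vs_three(self):
        # θ_obs = 1; only the original split and its mirror reach it: p = 2/20
        m = matrix_from_counts(3, 3, 3, 0)
        res = permutation_pvalues(m, "A", "B", exhaustive=True)
        assert res.pvalues[0] == pytest.approx(2 / 20)

    def test_exhaustive_matches_independent_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n_a = int(rng.integers(2, 5))
            n_b = int(rng.integers(2, 5))
            calls = rng.integers(0, 2, n_a + n_b)
            m = make_matrix(calls.astype(np.int8)[:, None],
                            populations=["A"] * n_a + ["B"] * n_b)
            res = permutation_pvalues(m, "A", "B", exhaustive=True)
            want = self.exhaustive_oracle(list(calls), n_a)
            if np.isnan(res.pvalues[0]):
                continue
            assert res.pvalues[0] == pytest.approx(want)

    def test_sampled_close_to_exhaustive(self):
        m = matrix_from_counts(4, 3, 4, 1)
        exact = permutation_pvalues(m, "A", "B", exhaustive=True).pvalues[0]
        sampled = permutation_pvalues(m, "A", "B", n_perm=4000, seed=9).pvalues[0]
        sd = np.sqrt(exact * (1 - exact) / 4000)
        assert abs(sampled - exact) <= 3 * sd + 1e-9

    def test_null_site_has_large_p(self):
        # identical allele columns in both populations: θ_obs is typical
        calls = np.array([1, 0, 1, 0, 1, 0, 1, 0], dtype=np.int8)[:, None]
        m = make_matrix(calls, populations=["A"] * 4 + ["B"] * 4)
        res = permutation_pvalues(m, "A", "B", n_perm=500, seed=1)
        assert res.pvalues[0] > 0.5

    def test_zero_permutations_error(self, two_pop_matrix):
        with pytest.raises(ValueError):
            permutation_pvalues(two_pop_matrix, "A", "B", n_perm=0)


class TestContrastVector:
    def test_negation_applied_to_third_pair(self, two_pop_matrix):
        r = weir_haploid_fst(two_pop_matrix, "A", "B")
        triple = fst_contrast_vector(r, r, r)
        np.testing.assert_allclose(triple[:, 0], r.theta)
        np.testing.assert_allclose(triple[:, 2], -r.theta)

    def test_site_list_mismatch_errors(self, two_pop_matrix):
        r = weir_haploid_fst(two_pop_matrix, "A", "B")
        other = weir_haploid_fst(two_pop_matrix, "A", "B")
        other.positions_bp = other.positions_bp + 1
        with pytest.raises(ValueError, match="site lists"):
            fst_contrast_vector(r, other, r)


def test_multilocus_theta_matches_driftexpectation():
    """Two isolated demes drifting t generations: θ ≈ 1 − (1 − 1/N)^t."""
    from dataclasses import replace
    from sweepscan.simulate import SimulationConfig, simulate_three_populations

    N, t = 50, 10
    cfg = SimulationConfig(
        n_sites=400, chrom_length_bp=100_000, recomb_rate=1e-7, mut_rate=0.0,
        pop_size_ancestral=N, pop_size_A=N, pop_size_E=N,
        t_split=0, t_admix=0, t_invasion=0, admix_prop_E=0.0,
        founder_size=N, n_selected_loci=0, sel_coeff=0.0,
        generations_post_invasion=t, sample_sizes=(N, N, N), seed=77,
    )
    thetas = []
    for seed in range(77, 82):
        m, _ = simulate_three_populations(replace(cfg, seed=seed))
        thetas.append(multilocus_theta(weir_haploid_fst(m, "gAHB", "AHB")))
    expected = 1 - (1 - 1 / N) ** t
    assert np.mean(thetas) == pytest.approx(expected, abs=0.05)
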