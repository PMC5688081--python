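"""EHH profiles against a string-grouping oracle; iES quadrature; Rsb algebra."""
from __future__ import annotations

import numpy as np
import pytest

from sweepscan import GeneticMap, ehh_s_profile, integrate_ies, rsb_scan
from sweepscan.ehh import EhhProfile, standardize_ln_ratio

from conftest import make_matrix


def oracle_ehh(calls: np.ndarray, core: int, x: int) -> float:
    """Homozygosity of full strings over [min(core,x)..max(core,x)], by counting."""
    lo, hi = min(core, x), max(core, x)
    strings = ["".join(map(str, row[lo:hi + 1])) for row in calls]
    n = len(strings)
    total = 0
    for s in set(strings):
        k = strings.count(s)
        total += k * (k - 1) // 2
    return total / (n * (n - 1) / 2)


class TestEhhProfile:
    def test_identical_haplotypes_stay_at_one(self):
        calls = np.tile(np.array([0, 1, 0, 1, 1], dtype=np.int8), (6, 1))
        m = make_matrix(calls)
        p = ehh_s_profile(m, 2)
        assert np.all(p.left_ehh == 1.0) and np.all(p.right_ehh == 1.0)
        assert p.truncation_left == "scaffold_end"
        assert p.truncation_right == "scaffold_end"

    def test_two_pairs_at_first_marker(self):
        # four haplotypes split into two pairs over {core, marker}
        calls = np.array(
            [[0, 0], [0, 0], [0, 1], [0, 1]], dtype=np.int8
        )
        p = ehh_s_profile(make_matrix(calls), 0)
        # EHH_S = 2·C(2,2)/C(4,2) = 1/3
        assert p.right_ehh[0] == pytest.approx(1 / 3)

    def test_all_distinct_stops_extension(self):
        calls = np.array(
            [[0, 0, 0], [0, 0, 1], [0, 1, 0], [0, 1, 1]], dtype=np.int8
        )
        p = ehh_s_profile(make_matrix(calls), 0, decay_threshold=0.05)
        assert p.right_ehh[-1] == 0.0
        assert p.truncation_right == "threshold"

    def test_matches_string_grouping_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(25):
            n = int(rng.integers(2, 11))
            L = int(rng.integers(2, 51))
            calls = rng.integers(0, 2, (n, L)).astype(np.int8)
            m = make_matrix(calls)
            core = int(rng.integers(0, L))
            p = ehh_s_profile(m, core, decay_threshold=0.0)  # full extension
            for j, v in zip(p.left_index, p.left_ehh):
                assert v == pytest.approx(oracle_ehh(calls, core, j), abs=1e-12)
            for j, v in zip(p.right_index, p.right_ehh):
                assert v == pytest.approx(oracle_ehh(calls, core, j), abs=1e-12)

    def test_profiles_monotone_non_increasing(self):
        rng = np.random.default_rng(31)
        calls = rng.integers(0, 2, (8, 30)).astype(np.int8)
        m = make_matrix(calls)
        for core in range(0, 30, 5):
            p = ehh_s_profile(m, core, decay_threshold=0.0)
            assert np.all(np.diff(np.concatenate([[1.0], p.left_ehh])) <= 1e-12)
            assert np.all(np.diff(np.concatenate([[1.0], p.right_ehh])) <= 1e-12)

    def test_missing_calls_rejected(self):
        calls = np.array([[0, -1], [1, 0], [0, 0]], dtype=np.int8)
        with pytest.raises(ValueError, match="rescue_missing"):
            ehh_s_profile(make_matrix(calls), 0)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            ehh_s_profile(make_matrix(np.array([[0, 1]], dtype=np.int8)), 0)


def profile_from(core_m, left, right):
    """Hand-built profile in Morgan coordinates: lists of (morgans, ehh)."""
    return EhhProfile(
        core_index=0, core_bp=0, core_morgans=core_m,
        left_index=np.arange(len(left)),
        left_bp=np.zeros(len(left), dtype=np.int64),
        left_morgans=np.array([x for x, _ in left]),
        left_ehh=np.array([y for _, y in left]),
        right_index=np.arange(len(right)),
        right_bp=np.zeros(len(right), dtype=np.int64),
        right_morgans=np.array([x for x, _ in right]),
        right_ehh=np.array([y for _, y in right]),
    )


class TestIntegrateIes:
    def test_rectangle(self):
        # EHH ≡ 1 over ±0.01 M → iES = 0.02
        p = profile_from(0.05, [(0.045, 1.0), (0.04, 1.0)], [(0.055, 1.0), (0.06, 1.0)])
        assert integrate_ies(p) == pytest.approx(0.02, abs=1e-12)

    def test_triangle(self):
        # linear decay 1 → 0 over 0.01 M each side → two triangles of area 0.005
        p = profile_from(0.05, [(0.045, 0.5), (0.04, 0.0)], [(0.055, 0.5), (0.06, 0.0)])
        assert integrate_ies(p) == pytest.approx(0.01, abs=1e-12)

    def test_matches_numpy_quadrature(self):
        rng = np.random.default_rng(4)
        xs = np.sort(rng.uniform(0, 0.02, 12))
        ys = np.sort(rng.uniform(0, 1, 12))[::-1]
        p = profile_from(0.03, [], [(0.03 + x, y) for x, y in zip(xs, ys)])
        want = np.trapezoid(np.concatenate([[1.0], ys]), np.concatenate([[0.03], 0.03 + xs]))
        assert integrate_ies(p) == pytest.approx(want, abs=1e-12)

    def test_no_flanking_markers_is_zero(self):
        assert integrate_ies(profile_from(0.01, [], [])) == 0.0

    def test_map_scaling_scales_ies(self):
        calls = np.random.default_rng(2).integers(0, 2, (6, 20)).astype(np.int8)
        pos = np.arange(1, 21) * 50
        m1 = make_matrix(calls, positions=pos,
                         genetic_pos=(pos - 1) * 1e-6)
        m2 = make_matrix(calls, positions=pos,
                         genetic_pos=(pos - 1) * 2e-6)
        p1 = ehh_s_profile(m1, 10)
        p2 = ehh_s_profile(m2, 10)
        assert integrate_ies(p2) == pytest.approx(2 * integrate_ies(p1), rel=1e-12)


class TestRsb:
    def test_swapping_populations_negates_ln_ratio(self, random_complete_matrix):
        m = random_complete_matrix
        a = rsb_scan(m, "P", "Q")
        b = rsb_scan(m, "Q", "P")
        ok = np.isfinite(a.ln_ratio)
        np.testing.assert_allclose(a.ln_ratio[ok], -b.ln_ratio[ok], atol=0, rtol=0)

    def test_identical_populations_give_rsb_one(self):
        rng = np.random.default_rng(9)
        calls_one = rng.integers(0, 2, (5, 25)).astype(np.int8)
        calls = np.vstack([calls_one, calls_one])
        m = make_matrix(calls, populations=["P"] * 5 + ["Q"] * 5)
        with pytest.warns(UserWarning, match="degenerate"):
            res = rsb_scan(m, "P", "Q")
        np.testing.assert_allclose(res.ln_ratio[np.isfinite(res.ln_ratio)], 0.0)
        np.testing.assert_allclose(res.rsb[np.isfinite(res.rsb)], 1.0)

    def test_standardized_median_is_zero(self, random_complete_matrix):
        res = rsb_scan(random_complete_matrix, "P", "Q")
        med = np.median(res.standardized[np.isfinite(res.standardized)])
        assert abs(med) < 1e-9

    def test_median_ln_ratio_maps_to_rsb_one(self, random_complete_matrix):
        res = rsb_scan(random_complete_matrix, "P", "Q")
        ok = np.isfinite(res.ln_ratio)
        j = np.argsort(np.abs(res.ln_ratio[ok] - np.median(res.ln_ratio[ok])))[0]
        assert res.rsb[ok][j] == pytest.approx(
            np.exp(res.standardized[ok][j])
        )

    def test_standardization_invariant_to_map_rescaling(self):
        rng = np.random.default_rng(13)
        calls = rng.integers(0, 2, (10, 30)).astype(np.int8)
        pops = ["P"] * 5 + ["Q"] * 5
        pos = np.arange(1, 31) * 40
        m1 = make_matrix(calls, populations=pops, positions=pos,
                         genetic_pos=(pos - 1) * 1e-6)
        m2 = make_matrix(calls, populations=pops, positions=pos,
                         genetic_pos=(pos - 1) * 3e-6)
        r1 = rsb_scan(m1, "P", "Q")
        r2 = rsb_scan(m2, "P", "Q")
        ok = np.isfinite(r1.standardized)
        np.testing.assert_allclose(r1.standardized[ok], r2.standardized[ok], atol=1e-9)

    def test_mad_scale_option(self, random_complete_matrix):
        res = rsb_scan(random_complete_matrix, "P", "Q", scale="mad")
        med = np.median(res.standardized[np.isfinite(res.standardized)])
        assert abs(med) < 1e-9
        assert res.scale == "mad"


def test_planted_sweep_elevates_mean_rsb_over_replicates():
    """Across seeded replicates, mean Rsb at selected sites exceeds the mean
    at neutral sites (selection slows haplotype decay in the focal deme)."""
    from dataclasses import replace

    from sweepscan.simulate import SimulationConfig, simulate_three_populations

    cfg = SimulationConfig(
        n_sites=300, chrom_length_bp=300_000, pop_size_ancestral=600,
        pop_size_A=600, pop_size_E=300, t_split=40, t_admix=50, t_invasion=70,
        founder_size=150, n_selected_loci=5, sel_coeff=0.1,
        generations_post_invasion=12, seed=0,
    )
    sel_means, neut_means = [], []
    for seed in range(20):
        m, truth = simulate_three_populations(replace(cfg, seed=300 + seed))
        res = rsb_scan(m, "gAHB", "AHB")
        sel = np.zeros(m.n_sites, dtype=bool)
        sel[truth.selected_site_indices] = True
        ok = np.isfinite(res.rsb)
        sel_means.append(np.mean(res.rsb[sel & ok]))
        neut_means.append(np.mean(res.rsb[~sel & ok]))
    assert np.mean(sel_means) > np.mean(neut_means)
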