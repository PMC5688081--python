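"""csd allele extraction and the diploid-male likelihood P(d)."""
from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd
import pytest

from sweepscan import compare_populations, diploid_male_likelihood, extract_csd_alleles
from sweepscan.csd import CsdAlleleTable

from conftest import make_matrix


def table_from_counts(focal_counts, other_counts, focal="gAHB", other="AHB"):
    """Build a two-population allele table directly from count vectors."""
    k = max(len(focal_counts), len(other_counts))
    fc = list(focal_counts) + [0] * (k - len(focal_counts))
    oc = list(other_counts) + [0] * (k - len(other_counts))
    counts = pd.DataFrame({focal: fc, other: oc},
                          index=[f"allele_{i+1}" for i in range(k)])
    return CsdAlleleTable(alleles=[(i,) for i in range(k)], counts=counts,
                          site_indices=[0])


class TestExtraction:
    def test_single_allele_everywhere(self):
        calls = np.zeros((9, 4), dtype=np.int8)
        m = make_matrix(calls, populations=["A"] * 3 + ["B"] * 3 + ["C"] * 3)
        t = extract_csd_alleles(m, [0, 1, 2, 3])
        assert t.K == 1
        assert all(t.k(p) == 1 for p in ("A", "B", "C"))
        assert t.counts.loc["allele_1"].tolist() == [3, 3, 3]

    def test_two_sites_split_alleles(self):
        calls = np.array([[0, 0], [1, 1], [0, 0], [1, 1]], dtype=np.int8)
        m = make_matrix(calls, populations=["A", "A", "B", "B"])
        t = extract_csd_alleles(m, [0, 1])
        assert t.K == 2
        assert sorted(t.alleles) == [(0, 0), (1, 1)]

    def test_hand_tally_on_six_samples(self):
        calls = np.array(
            [[0, 0], [0, 1], [0, 0], [1, 1], [0, 1], [1, 1]], dtype=np.int8
        )
        m = make_matrix(calls, populations=["A"] * 3 + ["B"] * 3)
        t = extract_csd_alleles(m, [0, 1])
        # A: {00: 2, 01: 1}; B: {11: 2, 01: 1}
        assert t.counts["A"].sum() == 3 and t.counts["B"].sum() == 3
        idx = {a: lab for a, lab in zip(t.alleles, t.counts.index)}
        assert t.counts["A"][idx[(0, 0)]] == 2
        assert t.counts["B"][idx[(1, 1)]] == 2
        assert t.counts["A"][idx[(0, 1)]] == 1

    def test_empty_site_list_and_missing_rejected(self):
        m = make_matrix(np.zeros((2, 2), dtype=np.int8))
        with pytest.raises(ValueError):
            extract_csd_alleles(m, [])
        m.calls[0, 1] = -1
        with pytest.raises(ValueError, match="rescue_missing"):
            extract_csd_alleles(m, [0, 1])


class TestLikelihood:
    def test_focal_3_2_1_vs_pooled_3_2_1_4(self):
        t = table_from_counts([3, 2, 1, 0], [0, 0, 0, 4])
        # numerator C(3,2)+C(2,2)+C(1,2) = 4; denominator adds C(4,2) = 6
        assert diploid_male_likelihood(t, "gAHB") == pytest.approx(0.4)

    def test_all_singletons_give_zero(self):
        t = table_from_counts([1, 1, 1], [5, 5, 0])
        assert diploid_male_likelihood(t, "gAHB") == 0.0

    def test_single_shared_allele_30_per_population(self):
        counts = pd.DataFrame({"gAHB": [30], "AHB": [30], "EHB": [30]},
                              index=["allele_1"])
        t = CsdAlleleTable(alleles=[(0,)], counts=counts, site_indices=[0])
        # C(30,2)/C(90,2) = 435/4005 under the pooled denominator
        assert diploid_male_likelihood(t, "gAHB") == pytest.approx(435 / 4005)

    def test_within_denominator_consistency(self):
        # restricting the denominator to the focal population's own counts
        # collapses every pair into both sums: the consistency check P(d) = 1
        t = table_from_counts([3, 2], [4, 1])
        assert diploid_male_likelihood(t, "gAHB", denominator="within") == 1.0

    def test_merging_alleles_never_decreases_numerator(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            counts = rng.integers(1, 6, 4)
            t1 = table_from_counts(list(counts), [2, 2, 2, 2])
            merged = [counts[0] + counts[1], counts[2], counts[3]]
            t2 = table_from_counts(merged, [2, 2, 2, 0])
            num1 = sum(comb(int(h), 2) for h in counts)
            num2 = sum(comb(int(h), 2) for h in merged)
            assert num2 >= num1
            assert diploid_male_likelihood(t2, "gAHB") >= 0

    def test_all_singletons_everywhere_undefined(self):
        t = table_from_counts([1, 0], [0, 1])
        assert np.isnan(diploid_male_likelihood(t, "gAHB"))

    def test_unknown_population_rejected(self):
        t = table_from_counts([2], [2])
        with pytest.raises(ValueError):
            diploid_male_likelihood(t, "nope")


class TestComparison:
    def test_identical_spectra_ratio_one(self):
        counts = pd.DataFrame({"A": [3, 2], "B": [3, 2]},
                              index=["allele_1", "allele_2"])
        t = CsdAlleleTable(alleles=[(0,), (1,)], counts=counts, site_indices=[0])
        comp = compare_populations(t)
        assert comp.ratio("A", "B") == pytest.approx(1.0)

    def test_spectra_are_frequencies(self):
        t = table_from_counts([6, 2], [4, 4])
        comp = compare_populations(t)
        assert comp.spectra["gAHB"].tolist() == pytest.approx([0.75, 0.25])

    def test_bottleneck_raises_diploid_male_likelihood(self):
        """Founder effect: stronger bottleneck → fewer, more uneven csd
        alleles → higher P(d), averaged over replicate simulations."""
        from dataclasses import replace
        from sweepscan.simulate import SimulationConfig, simulate_three_populations

        base = SimulationConfig(
            n_sites=80, chrom_length_bp=40_000, recomb_rate=2e-6, mut_rate=0.0,
            pop_size_ancestral=300, pop_size_A=300, pop_size_E=100,
            t_split=8, t_admix=12, t_invasion=20, n_selected_loci=0,
            sel_coeff=0.0, generations_post_invasion=12,
            sample_sizes=(30, 30, 30), seed=0,
        )
        sites = list(range(36, 44))  # contiguous csd-like locus
        means = {}
        for founder in (10, 300):
            vals = []
            for seed in range(10):
                m, _ = simulate_three_populations(
                    replace(base, founder_size=founder, seed=200 + seed)
                )
                t = extract_csd_alleles(m, sites)
                vals.append(diploid_male_likelihood(t, "gAHB"))
            means[founder] = np.nanmean(vals)
        assert means[10] > means[300]


def test_balancing_selection_evens_csd_allele_spectrum():
    """With negative frequency-dependent selection on csd alleles, the
    allele-frequency spectrum is more even (lower variance) than neutral."""
    from dataclasses import replace

    from sweepscan.simulate import SimulationConfig, simulate_three_populations

    base = SimulationConfig(
        n_sites=60, chrom_length_bp=30_000, recomb_rate=0.0, mut_rate=0.0,
        pop_size_ancestral=200, pop_size_A=200, pop_size_E=100,
        t_split=4, t_admix=6, t_invasion=8, founder_size=100,
        n_selected_loci=0, sel_coeff=0.0, generations_post_invasion=25,
        sample_sizes=(40, 20, 20), ancestral_haplotypes=12,
        csd_sites=tuple(range(24, 32)),
    )
    spectra_var = {}
    for b in (0.0, 30.0):
        vs = []
        for seed in range(10):
            m, _ = simulate_three_populations(
                replace(base, csd_balancing=b, seed=50 + seed)
            )
            t = extract_csd_alleles(m, list(range(24, 32)))
            f = t.counts["gAHB"].to_numpy()
            f = f[f > 0] / f.sum()
            vs.append(np.var(f))
        spectra_var[b] = float(np.mean(vs))
    assert spectra_var[30.0] < spectra_var[0.0]
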