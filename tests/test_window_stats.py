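"""Window engine and selection statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sweepscan.io_core import MISSING, PopulationMap
from sweepscan.window_stats import (compute_pair_scan, make_windows, site_pi,
                                    site_fst_hudson, tajima_constants,
                                    tajimas_d_from_summaries)
from conftest import make_matrix
from oracles import (hudson_window_fst_oracle, pi_bruteforce_pairs,
                     tajima_d_oracle, window_pi_bruteforce)


class TestMakeWindows:
    def test_exact_fit_single_window(self):
        grid = make_windows({"c": 100_000})
        np.testing.assert_array_equal(grid.windows["c"], [[1, 100_000]])

    def test_no_full_window_fits(self):
        assert len(make_windows({"c": 99_999}).windows["c"]) == 0

    def test_enumerated_starts_for_250kb(self):
        grid = make_windows({"c": 250_000})
        w = grid.windows["c"]
        assert len(w) == 16
        np.testing.assert_array_equal(w[:, 0], 1 + 10_000 * np.arange(16))
        assert w[-1].tolist() == [150_001, 250_000]

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            make_windows({"c": 1000}, window_size=0)
        with pytest.raises(ValueError):
            make_windows({"c": 1000}, step=-1)

    @given(length=st.integers(1, 2_000_000))
    @settings(max_examples=50, deadline=None)
    def test_recurrence_and_bounds(self, length):
        grid = make_windows({"c": length})
        w = grid.windows["c"]
        if len(w):
            assert np.all(np.diff(w[:, 0]) == 10_000)
            assert w[-1, 1] <= length
            assert length - w[-1, 1] < 10_000 or len(w) == 0


class TestSitePi:
    def test_monomorphic_zero(self):
        assert site_pi(0, 10) == 0 and site_pi(10, 10) == 0

    def test_single_differing_pair(self):
        assert site_pi(1, 2) == pytest.approx(1.0)

    def test_undefined_below_two_alleles(self):
        assert np.isnan(site_pi(0, 1))

    @given(n=st.integers(2, 40), j=st.data())
    @settings(max_examples=60, deadline=None)
    def test_matches_pair_enumeration(self, n, j):
        j = j.draw(st.integers(0, n))
        assert site_pi(j, n) == pytest.approx(pi_bruteforce_pairs(j, n),
                                              abs=1e-12)


class TestTajima:
    def test_constants_n2(self):
        k = tajima_constants(2)
        assert k["a1"] == 1.0 and k["a2"] == 1.0

    def test_constants_n10_direct_sum(self):
        k = tajima_constants(10)
        assert k["a1"] == pytest.approx(sum(1 / i for i in range(1, 10)), abs=1e-12)
        assert k["a2"] == pytest.approx(sum(1 / i**2 for i in range(1, 10)), abs=1e-12)

    def test_e_constants_positive_over_grid(self):
        for n in list(range(4, 100)) + [250, 500, 1000]:
            k = tajima_constants(n)
            assert k["e1"] > 0 and k["e2"] > 0

    def test_undefined_when_no_segregating_sites(self):
        assert np.isnan(tajimas_d_from_summaries(0.0, 0, 20))

    def test_all_singletons_give_negative_d(self):
        # 20 singleton sites among n=20 haplotypes: rare-variant excess
        n = 20
        s = 20
        pi_sum = s * 2 * 1 * (n - 1) / (n * (n - 1))
        assert tajimas_d_from_summaries(pi_sum, s, n) < 0


class TestHudsonSite:
    def test_fixed_difference(self):
        num, den = site_fst_hudson(0.0, 20, 1.0, 20)
        assert num == pytest.approx(1.0) and den == pytest.approx(1.0)

    def test_hand_evaluated_case(self):
        num, den = site_fst_hudson(0.2, 20, 0.8, 20)
        assert num == pytest.approx(0.343158, abs=1e-6)
        assert den == pytest.approx(0.68, abs=1e-12)
        assert num / den == pytest.approx(0.50464, abs=1e-5)

    def test_equal_frequencies_nonpositive_numerator(self):
        num, _ = site_fst_hudson(0.5, 1000, 0.5, 1000)
        assert num <= 0


def _two_pop_matrix(rng, n_sites=60, n_per_pop=8, missing_rate=0.0,
                    length=100_000):
    dosage = rng.integers(0, 3, size=(n_sites, 2 * n_per_pop)).astype(np.int8)
    if missing_rate:
        dosage[rng.random(dosage.shape) < missing_rate] = MISSING
    positions = np.sort(rng.choice(length, size=n_sites, replace=False) + 1)
    samples = [f"a{i}" for i in range(n_per_pop)] + [f"b{i}" for i in range(n_per_pop)]
    gm = make_matrix(dosage, positions=positions, samples=samples)
    pmap = PopulationMap(
        assignments={s: ("A" if s.startswith("a") else "B") for s in samples},
        roles={"A": "indigenous", "B": "commercial"})
    return gm, pmap


class TestPairScan:
    def test_window_pi_matches_bruteforce_on_complete_data(self):
        rng = np.random.default_rng(11)
        gm, pmap = _two_pop_matrix(rng)
        grid = make_windows({"chr1": 100_000})
        scan = compute_pair_scan(gm, pmap, "A", "B", grid)
        idx_a = gm.sample_indices(pmap.samples_of("A"))
        expected = window_pi_bruteforce(gm.dosage[:, idx_a])
        assert scan["pi_ind"].iloc[0] == pytest.approx(expected, abs=1e-10)

    def test_window_fst_matches_bruteforce(self):
        rng = np.random.default_rng(12)
        gm, pmap = _two_pop_matrix(rng, missing_rate=0.1)
        grid = make_windows({"chr1": 100_000})
        scan = compute_pair_scan(gm, pmap, "A", "B", grid)
        idx_a = gm.sample_indices(pmap.samples_of("A"))
        idx_b = gm.sample_indices(pmap.samples_of("B"))
        expected = hudson_window_fst_oracle(gm.dosage[:, idx_a],
                                            gm.dosage[:, idx_b])
        assert scan["fst"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_tajimas_d_matches_oracle_with_missing_data(self):
        rng = np.random.default_rng(13)
        gm, pmap = _two_pop_matrix(rng, missing_rate=0.15)
        grid = make_windows({"chr1": 100_000})
        scan = compute_pair_scan(gm, pmap, "A", "B", grid)
        idx_a = gm.sample_indices(pmap.samples_of("A"))
        expected = tajima_d_oracle(gm.dosage[:, idx_a])
        assert scan["d_ind"].iloc[0] == pytest.approx(expected, abs=1e-10)

    def test_identical_populations_fst_nonpositive(self):
        rng = np.random.default_rng(14)
        half = rng.integers(0, 3, size=(80, 10)).astype(np.int8)
        dosage = np.hstack([half, half])  # same columns duplicated
        samples = [f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)]
        gm = make_matrix(dosage, positions=np.arange(1, 81) * 1000,
                         samples=samples)
        pmap = PopulationMap(
            assignments={s: ("A" if s.startswith("a") else "B") for s in samples},
            roles={"A": "indigenous", "B": "commercial"})
        scan = compute_pair_scan(gm, pmap, "A", "B",
                                 make_windows({"chr1": 100_000}))
        assert scan["fst"].iloc[0] <= 1e-9

    def test_allele_label_swap_invariance(self):
        rng = np.random.default_rng(15)
        gm, pmap = _two_pop_matrix(rng)
        grid = make_windows({"chr1": 100_000})
        fst1 = compute_pair_scan(gm, pmap, "A", "B", grid)["fst"].iloc[0]
        swapped = make_matrix(2 - gm.dosage, positions=gm.sites["pos"].to_numpy(),
                              samples=gm.samples)
        fst2 = compute_pair_scan(swapped, pmap, "A", "B", grid)["fst"].iloc[0]
        assert fst1 == pytest.approx(fst2, abs=1e-12)

    def test_monomorphic_window_undefined_not_zero(self):
        dosage = np.zeros((10, 8), dtype=np.int8)
        samples = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        gm = make_matrix(dosage, positions=np.arange(1, 11) * 1000,
                         samples=samples)
        pmap = PopulationMap(
            assignments={s: ("A" if s.startswith("a") else "B") for s in samples},
            roles={"A": "indigenous", "B": "commercial"})
        scan = compute_pair_scan(gm, pmap, "A", "B",
                                 make_windows({"chr1": 100_000}))
        row = scan.iloc[0]
        assert row["pi_ind"] == 0 and row["pi_com"] == 0
        assert np.isnan(row["fst"]) and np.isnan(row["log2_pi_ratio"])
        assert np.isnan(row["d_diff"])

    def test_scan_deterministic(self):
        rng = np.random.default_rng(16)
        gm, pmap = _two_pop_matrix(rng, n_sites=200, length=400_000)
        grid = make_windows({"chr1": 400_000})
        s1 = compute_pair_scan(gm, pmap, "A", "B", grid)
        s2 = compute_pair_scan(gm, pmap, "A", "B", grid)
        pd.testing.assert_frame_equal(s1, s2)

    def test_unknown_population_lookup_error(self):
        rng = np.random.default_rng(17)
        gm, pmap = _two_pop_matrix(rng)
        with pytest.raises(KeyError):
            compute_pair_scan(gm, pmap, "Z", "B",
                              make_windows({"chr1": 100_000}))

    def test_weir_cockerham_close_to_hudson_on_balanced_data(self):
        rng = np.random.default_rng(18)
        gm, pmap = _two_pop_matrix(rng, n_sites=200, n_per_pop=20,
                                   length=100_000)
        grid = make_windows({"chr1": 100_000})
        h = compute_pair_scan(gm, pmap, "A", "B", grid)["fst"].iloc[0]
        wc = compute_pair_scan(gm, pmap, "A", "B", grid,
                               fst_estimator="weir_cockerham")["fst"].iloc[0]
        assert h == pytest.approx(wc, abs=0.05)


def test_panmictic_split_mean_fst_near_zero():
    """A random split of one panmictic population is undifferentiated."""
    rng = np.random.default_rng(19)
    freqs = rng.uniform(0.05, 0.95, size=2000)
    dosage = rng.binomial(2, freqs[:, None], size=(2000, 50)).astype(np.int8)
    samples = [f"a{i}" for i in range(25)] + [f"b{i}" for i in range(25)]
    gm = make_matrix(dosage, positions=np.arange(1, 2001) * 100,
                     samples=samples)
    pmap = PopulationMap(
        assignments={s: ("A" if s.startswith("a") else "B") for s in samples},
        roles={"A": "indigenous", "B": "commercial"})
    grid = make_windows({"chr1": 200_100})
    scan = compute_pair_scan(gm, pmap, "A", "B", grid)
    assert abs(np.nanmean(scan["fst"])) < 0.01


def test_balding_nichols_realized_fst_calibration():
    """Two populations drawn at F = 0.1 around a shared ancestral frequency
    give mean Hudson window FST within +-0.02 of 0.1 (50 diploids/pop,
    5000 sites)."""
    rng = np.random.default_rng(20)
    f = 0.1
    p = rng.uniform(0.05, 0.95, size=5000)
    ratio = (1 - f) / f
    dosage = np.hstack([
        rng.binomial(2, rng.beta(p * ratio, (1 - p) * ratio)[:, None],
                     size=(5000, 50)),
        rng.binomial(2, rng.beta(p * ratio, (1 - p) * ratio)[:, None],
                     size=(5000, 50))]).astype(np.int8)
    samples = [f"a{i}" for i in range(50)] + [f"b{i}" for i in range(50)]
    gm = make_matrix(dosage, positions=np.arange(1, 5001) * 100,
                     samples=samples)
    pmap = PopulationMap(
        assignments={s: ("A" if s.startswith("a") else "B") for s in samples},
        roles={"A": "indigenous", "B": "commercial"})
    grid = make_windows({"chr1": 500_100})
    scan = compute_pair_scan(gm, pmap, "A", "B", grid)
    assert np.nanmean(scan["fst"]) == pytest.approx(0.1, abs=0.02)
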