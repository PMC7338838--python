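"""Band-pair metrics, exhaustive enumeration, front extraction, matching."""

import numpy as np
import pytest

from bandopt import errors
from bandopt.bands import (
    Band,
    BandPair,
    band_power,
    band_ratio,
    collection_efficiency,
    enumerate_band_pairs,
    evaluate_custom_setup,
    evaluate_pairs_arrays,
    match_at_efficiency,
    optimize,
    pareto_front,
    separation,
)
from bandopt.spectra import PMFSpectrum

from conftest import (
    brute_force_band_power,
    brute_force_front_mask,
    brute_force_pair_count,
)


class TestBandTypes:
    def test_band_rejects_inverted(self):
        with pytest.raises(errors.InputError):
            Band(510, 500)

    def test_pair_rejects_overlap(self):
        with pytest.raises(errors.InputError):
            BandPair(Band(500, 520), Band(520, 540))  # touching is overlap


class TestBandPower:
    def test_full_grid_is_one(self, hand_spectra):
        s1, _ = hand_spectra
        assert band_power(s1, Band(500, 540)) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "band, expected", [(Band(500, 510), 0.7), (Band(530, 540), 0.1)]
    )
    def test_hand_sums(self, hand_spectra, band, expected):
        s1, _ = hand_spectra
        assert band_power(s1, band) == pytest.approx(expected, abs=1e-12)

    def test_outside_grid_raises(self, hand_spectra):
        s1, _ = hand_spectra
        with pytest.raises(errors.BandError):
            band_power(s1, Band(600, 650))

    def test_matches_brute_force_on_random(self, random_pmf_factory):
        rng = np.random.default_rng(3)
        s = random_pmf_factory(rng, n_points=26)
        for _ in range(20):
            lo, hi = sorted(rng.choice(s.wavelengths_nm, size=2, replace=True))
            assert band_power(s, Band(lo, hi)) == pytest.approx(
                brute_force_band_power(s, lo, hi), abs=1e-12
            )


class TestRatioSeparationEfficiency:
    PAIR = BandPair(Band(500, 510), Band(530, 540))
    WIDE = BandPair(Band(500, 520), Band(530, 540))

    def test_band_ratio(self, hand_spectra):
        s1, s2 = hand_spectra
        assert band_ratio(s1, self.PAIR) == pytest.approx(7.0, abs=1e-9)
        assert band_ratio(s2, self.PAIR) == pytest.approx(1 / 7, abs=1e-9)

    def test_uniform_symmetric_ratio_is_one(self):
        u = PMFSpectrum(np.arange(500.0, 540.1, 10.0), np.full(5, 0.2))
        assert band_ratio(u, self.PAIR) == pytest.approx(1.0, abs=1e-12)

    def test_separation_hand_values(self, hand_spectra):
        s1, s2 = hand_spectra
        assert separation(s1, s2, self.PAIR).separation == pytest.approx(49.0, abs=1e-9)
        assert separation(s1, s2, self.WIDE).separation == pytest.approx(21.0, abs=1e-9)

    def test_separation_identical_spectra_is_one(self, hand_spectra):
        s1, _ = hand_spectra
        m = separation(s1, s1, self.PAIR)
        assert m.separation == pytest.approx(1.0, abs=1e-12)
        assert not m.swapped

    def test_swapped_branch(self, hand_spectra):
        s1, s2 = hand_spectra
        m = separation(s2, s1, self.PAIR)  # exchanged inputs take 1/r branch
        assert m.separation == pytest.approx(49.0, abs=1e-9)
        assert m.swapped

    def test_efficiency_hand_values(self, hand_spectra):
        s1, s2 = hand_spectra
        assert collection_efficiency(s1, s2, self.PAIR) == pytest.approx(
            (0.7 * 0.1 * 0.1 * 0.7) ** 0.25, abs=1e-9
        )
        assert collection_efficiency(s1, s2, self.WIDE) == pytest.approx(
            (0.9 * 0.1 * 0.3 * 0.7) ** 0.25, abs=1e-9
        )

    def test_efficiency_bound_attained_for_flat_split(self):
        grid = np.arange(500.0, 540.1, 10.0)
        u = PMFSpectrum(grid, np.full(5, 0.2))
        # bands of 2 + 2 nodes carry 0.4 each; use a 10-node grid for halves
        grid10 = np.arange(500.0, 591.0, 10.0)
        u10 = PMFSpectrum(grid10, np.full(10, 0.1))
        pair = BandPair(Band(500, 540), Band(550, 590))
        assert collection_efficiency(u10, u10, pair) == pytest.approx(0.5, abs=1e-12)

    def test_degenerate_band_raises(self, hand_spectra):
        s1, s2 = hand_spectra
        pair = BandPair(Band(500, 510), Band(540, 540))  # zero power in s1
        with pytest.raises(errors.DegenerateBandError):
            separation(s1, s2, pair)

    def test_metrics_invariant_under_spectrum_and_band_exchange(
        self, random_pmf_factory
    ):
        rng = np.random.default_rng(11)
        for _ in range(20):
            s1 = random_pmf_factory(rng, n_points=24)
            s2 = random_pmf_factory(rng, n_points=24)
            wl = s1.wavelengths_nm
            pair = BandPair(Band(wl[0], wl[6]), Band(wl[10], wl[20]))
            m = separation(s1, s2, pair)
            m_swap = separation(s2, s1, pair)
            assert m_swap.separation == pytest.approx(m.separation, rel=1e-12)
            assert m_swap.efficiency == pytest.approx(m.efficiency, rel=1e-12)
            if m.separation > 1.0:
                assert m_swap.swapped != m.swapped

    def test_intensity_scale_invariance(self, random_pmf_factory):
        from bandopt.spectra import Spectrum, normalize_pmf

        rng = np.random.default_rng(13)
        grid = np.linspace(425.0, 650.0, 24)
        vals = rng.uniform(0.1, 1.0, size=24)
        s_ref = normalize_pmf(Spectrum(grid, vals))
        s_scaled = normalize_pmf(Spectrum(grid, 123.4 * vals))
        other = random_pmf_factory(rng, n_points=24)
        pair = BandPair(Band(grid[0], grid[8]), Band(grid[12], grid[-1]))
        m1 = separation(s_ref, other, pair)
        m2 = separation(s_scaled, other, pair)
        assert m1.separation == pytest.approx(m2.separation, rel=1e-12)
        assert m1.efficiency == pytest.approx(m2.efficiency, rel=1e-12)


class TestEnumeration:
    def test_five_node_count(self):
        grid = np.arange(500.0, 541.0, 10.0)
        pairs = enumerate_band_pairs(grid, 10.0)
        assert len(pairs) == 35
        assert len(pairs) == brute_force_pair_count(5)

    def test_two_node_lattice(self):
        pairs = enumerate_band_pairs(np.array([500.0, 510.0]), 10.0)
        assert pairs == [BandPair(Band(500, 500), Band(510, 510))]

    @pytest.mark.parametrize("n_nodes", [2, 3, 7, 12])
    @pytest.mark.parametrize("min_width_steps", [0, 1, 2])
    def test_count_matches_brute_force(self, n_nodes, min_width_steps):
        grid = 400.0 + 10.0 * np.arange(n_nodes)
        pairs = enumerate_band_pairs(grid, 10.0, min_width_nm=10.0 * min_width_steps)
        assert len(pairs) == brute_force_pair_count(n_nodes, min_width_steps)

    def test_constraints_hold_and_order_deterministic(self):
        grid = np.arange(500.0, 571.0, 10.0)
        pairs = enumerate_band_pairs(grid, 10.0, min_width_nm=10.0)
        edges = [p.edges for p in pairs]
        assert edges == sorted(edges)
        for p in pairs:
            assert p.band1.end_nm < p.band2.start_nm
            assert p.band1.width_nm >= 10.0 and p.band2.width_nm >= 10.0

    def test_one_node_lattice_raises(self):
        with pytest.raises(errors.InputError):
            enumerate_band_pairs(np.array([500.0, 501.0]), 0.5)


class TestOptimize:
    def test_fast_path_matches_direct_summation(self, random_pmf_factory):
        rng = np.random.default_rng(21)
        grid = np.linspace(425.0, 650.0, 20)
        step = grid[1] - grid[0]
        max_err = 0.0
        for _ in range(50):
            s1 = random_pmf_factory(rng, n_points=20)
            s2 = random_pmf_factory(rng, n_points=20)
            res = optimize(s1, s2, step_nm=step)
            for row in res.pairs.itertuples():
                pair = BandPair(
                    Band(row.band1_start_nm, row.band1_end_nm),
                    Band(row.band2_start_nm, row.band2_end_nm),
                )
                m = separation(s1, s2, pair)  # direct per-pair summation path
                max_err = max(
                    max_err,
                    abs(m.separation - row.separation),
                    abs(m.efficiency - row.efficiency),
                )
        assert max_err < 1e-9

    def test_identical_spectra_all_separations_one(self, random_pmf_factory):
        rng = np.random.default_rng(22)
        s = random_pmf_factory(rng)
        res = optimize(s, s, step_nm=5.0)
        np.testing.assert_allclose(res.pairs["separation"], 1.0, atol=1e-9)

    def test_bounds_on_random_inputs(self, random_pmf_factory):
        rng = np.random.default_rng(23)
        for _ in range(5):
            res = optimize(
                random_pmf_factory(rng), random_pmf_factory(rng), step_nm=5.0
            )
            assert (res.pairs["separation"] >= 1.0).all()
            assert (res.pairs["efficiency"] <= 0.5).all()
            assert (res.pairs["efficiency"] > 0.0).all()

    def test_zero_power_pairs_excluded_and_counted(self):
        # s1 has zero mass at 540 nm, s2 at 500 nm: any pair whose band
        # collects only those nodes is degenerate and must be dropped
        grid = np.arange(500.0, 541.0, 10.0)
        s1 = PMFSpectrum(grid, [0.4, 0.3, 0.2, 0.1, 0.0])
        s2 = PMFSpectrum(grid, [0.0, 0.1, 0.2, 0.3, 0.4])
        res = optimize(s1, s2, step_nm=10.0)
        assert res.excluded_count == 35 - len(res)
        assert res.excluded_count > 0
        assert (res.pairs["separation"] >= 1.0).all()

    def test_all_pairs_degenerate_raises(self):
        grid = np.arange(500.0, 541.0, 10.0)
        s1 = PMFSpectrum(grid, [1.0, 0.0, 0.0, 0.0, 0.0])
        s2 = PMFSpectrum(grid, [1.0, 0.0, 0.0, 0.0, 0.0])
        with pytest.raises(errors.EmptyResultError):
            optimize(s1, s2, step_nm=10.0)

    def test_grid_mismatch_raises(self, random_pmf_factory):
        rng = np.random.default_rng(24)
        s1 = random_pmf_factory(rng, n_points=20)
        s2 = random_pmf_factory(rng, n_points=21)
        with pytest.raises(errors.GridError):
            optimize(s1, s2, step_nm=s1.step_nm)

    def test_deterministic_output(self, random_pmf_factory):
        rng1 = np.random.default_rng(25)
        rng2 = np.random.default_rng(25)
        r1 = optimize(random_pmf_factory(rng1), random_pmf_factory(rng1), 5.0)
        r2 = optimize(random_pmf_factory(rng2), random_pmf_factory(rng2), 5.0)
        assert r1.pairs.equals(r2.pairs)


class TestParetoFront:
    def test_singleton(self):
        grid = np.arange(500.0, 541.0, 10.0)
        u = PMFSpectrum(grid, [0.1, 0.2, 0.4, 0.2, 0.1])
        res = optimize(u, u, step_nm=40.0)  # 2-node lattice -> 1 pair
        front = pareto_front(res)
        assert len(front) == 1 == len(res)

    @pytest.mark.parametrize("seed", [31, 32, 33])
    def test_matches_dominance_oracle(self, random_pmf_factory, seed):
        rng = np.random.default_rng(seed)
        s1 = random_pmf_factory(rng, n_points=18)
        s2 = random_pmf_factory(rng, n_points=18)
        res = optimize(s1, s2, step_nm=s1.step_nm)
        assert len(res) <= 5000
        front = pareto_front(res)
        eff = res.pairs["efficiency"].to_numpy()
        sep = res.pairs["separation"].to_numpy()
        oracle = brute_force_front_mask(eff, sep)
        got = set(map(tuple, front[["efficiency", "separation"]].to_numpy()))
        expected = set(zip(eff[oracle], sep[oracle]))
        assert got == expected

    def test_front_monotone_non_increasing_in_efficiency(self, random_pmf_factory):
        rng = np.random.default_rng(34)
        res = optimize(random_pmf_factory(rng), random_pmf_factory(rng), 5.0)
        front = pareto_front(res)
        eff = front["efficiency"].to_numpy()
        sep = front["separation"].to_numpy()
        assert (np.diff(eff) <= 1e-15).all()  # sorted by efficiency descending
        assert (np.diff(sep) >= -1e-12).all()  # separation rises as eff drops


class TestMatchAtEfficiency:
    def test_reference_is_always_candidate(self, random_pmf_factory):
        rng = np.random.default_rng(41)
        s1 = random_pmf_factory(rng)
        s2 = random_pmf_factory(rng)
        res = optimize(s1, s2, step_nm=5.0)
        ref = BandPair(Band(450, 490), Band(510, 650))
        _, metrics, gain = match_at_efficiency(res, ref)
        assert gain >= 1.0

    def test_winner_beats_all_in_tolerance_pairs(self, random_pmf_factory):
        rng = np.random.default_rng(42)
        s1 = random_pmf_factory(rng)
        s2 = random_pmf_factory(rng)
        res = optimize(s1, s2, step_nm=5.0)
        ref = BandPair(Band(440, 495), Band(520, 640))
        ref_metrics = evaluate_custom_setup(s1, s2, ref)
        _, winner_metrics, _ = match_at_efficiency(res, ref, rel_tolerance=0.001)
        eff = res.pairs["efficiency"].to_numpy()
        sep = res.pairs["separation"].to_numpy()
        in_tol = np.abs(eff - ref_metrics.efficiency) <= 0.001 * ref_metrics.efficiency
        assert in_tol.any()
        assert winner_metrics.separation >= sep[in_tol].max() - 1e-12

    def test_gaussian_pair_matched_beats_reference(self):
        from bandopt.spectra import normalize_pmf
        from bandopt.synthetic import two_class_pair

        a, b = two_class_pair(shift_nm=15.0, noise_sd=0.0, seed=0)
        s1, s2 = normalize_pmf(a), normalize_pmf(b)
        res = optimize(s1, s2, step_nm=5.0)
        ref = BandPair(Band(450, 490), Band(510, 650))
        ref_metrics = evaluate_custom_setup(s1, s2, ref)
        _, winner_metrics, gain = match_at_efficiency(res, ref)
        assert winner_metrics.separation >= ref_metrics.separation - 1e-12
        assert gain >= 1.0

    def test_no_candidate_names_nearest(self, hand_spectra):
        s1, s2 = hand_spectra
        res = optimize(s1, s2, step_nm=10.0)
        # restrict to a tolerance so tight nothing matches an off-lattice eff
        df = res.pairs
        import pandas as pd

        sparse = type(res)(
            pairs=df.iloc[:1].assign(efficiency=0.001),
            excluded_count=res.excluded_count,
            grid_step_nm=res.grid_step_nm,
            s1=s1,
            s2=s2,
        )
        ref = BandPair(Band(500, 510), Band(530, 540))
        with pytest.raises(errors.ToleranceError, match="nearest"):
            match_at_efficiency(sparse, ref, rel_tolerance=1e-6)


class TestEvaluateCustomSetup:
    def test_cross_check_against_optimize(self, random_pmf_factory):
        rng = np.random.default_rng(51)
        s1 = random_pmf_factory(rng)
        s2 = random_pmf_factory(rng)
        res = optimize(s1, s2, step_nm=5.0)
        row = res.pairs.iloc[1234]
        pair = BandPair(
            Band(row.band1_start_nm, row.band1_end_nm),
            Band(row.band2_start_nm, row.band2_end_nm),
        )
        m = evaluate_custom_setup(s1, s2, pair)
        assert m.separation == pytest.approx(row.separation, abs=1e-9)
        assert m.efficiency == pytest.approx(row.efficiency, abs=1e-9)

    def test_literature_reference_accepted(self, random_pmf_factory):
        rng = np.random.default_rng(52)
        s1 = random_pmf_factory(rng)
        s2 = random_pmf_factory(rng)
        m = evaluate_custom_setup(s1, s2, BandPair(Band(425, 490), Band(510, 650)))
        assert m.separation >= 1.0 and 0.0 < m.efficiency <= 0.5
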