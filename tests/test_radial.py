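"""Radial profiles, normalization, band summaries, aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mpq.radial import (
    RadialProfile,
    aggregate_profiles,
    band_summary,
    normalize_profile,
    radial_profile,
)
from mpq.synthetic import ACTIVIN_PRESETS, nucleus_records_from_truth


def _records(distances, intensities):
    return pd.DataFrame(
        {
            "colony_id": "c",
            "distance_um": distances,
            "median_intensity": intensities,
        }
    )


class TestProfile:
    def test_constant_intensity_constant_bins(self):
        rec = _records([5, 15, 33, 120, 240], [5.0] * 5)
        p = radial_profile(rec, 10, 250)
        nonempty = np.isfinite(p.bin_means)
        assert np.all(p.bin_means[nonempty] == 5.0)
        assert p.bin_counts.sum() == 5

    def test_half_open_bin_assignment(self):
        p = radial_profile(_records([12.0], [3.0]), 10, 250)
        assert p.bin_counts[1] == 1 and p.bin_counts.sum() == 1
        # exactly on an edge goes to the upper bin
        p2 = radial_profile(_records([10.0], [3.0]), 10, 250)
        assert p2.bin_counts[1] == 1 and p2.bin_counts[0] == 0

    def test_overflow_excluded(self):
        p = radial_profile(_records([10.0, 400.0], [1.0, 9.0]), 10, 250)
        assert p.overflow_count == 1
        assert p.bin_counts.sum() == 1

    def test_empty_records_raise(self):
        with pytest.raises(ValueError):
            radial_profile(_records([], []), 10, 250)

    def test_wt_colony_edge_high_center_low(self):
        from mpq.synthetic import assign_activation, generate_colony_layout

        lay = generate_colony_layout(250, 1500, 8.0, seed=41)
        pheno = ACTIVIN_PRESETS["WT"]
        act = assign_activation(lay, pheno, seed=42)
        rec = nucleus_records_from_truth(lay, act, pheno, seed=43)
        p = radial_profile(rec, 10, 250)
        inner = np.nanmean(p.bin_means[:15])  # < 150 µm: inactive zone
        outer = np.nanmean(p.bin_means[-4:])  # outermost 40 µm
        assert inner == pytest.approx(
            pheno.intensity_off + pheno.noise.background, rel=0.05
        )
        assert outer == pytest.approx(
            pheno.intensity_on + pheno.noise.background, rel=0.05
        )


class TestNormalize:
    def test_divide_by_max(self):
        p = RadialProfile(
            np.array([0.0, 10, 20, 30]),
            np.array([2.0, 4.0, 8.0]),
            np.array([1, 1, 1]),
        )
        n = normalize_profile(p)
        assert np.allclose(n.bin_means, [0.25, 0.5, 1.0])
        assert np.nanmax(n.bin_means) == 1.0
        assert n.normalized

    def test_idempotent(self):
        p = RadialProfile(
            np.array([0.0, 10, 20]), np.array([3.0, 6.0]), np.array([1, 1])
        )
        once = normalize_profile(p)
        twice = normalize_profile(once)
        assert np.array_equal(once.bin_means, twice.bin_means)

    def test_single_bin(self):
        p = RadialProfile(np.array([0.0, 10]), np.array([7.0]), np.array([1]))
        assert normalize_profile(p).bin_means[0] == 1.0

    def test_degenerate_raises(self):
        p = RadialProfile(np.array([0.0, 10]), np.array([0.0]), np.array([1]))
        with pytest.raises(ValueError):
            normalize_profile(p)

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(
            st.floats(0.01, 1e6, allow_nan=False), min_size=1, max_size=30
        )
    )
    def test_max_exactly_one_and_order_preserved(self, means):
        k = len(means)
        p = RadialProfile(
            np.arange(k + 1, dtype=float), np.array(means), np.ones(k, int)
        )
        n = normalize_profile(p)
        assert np.nanmax(n.bin_means) == 1.0
        assert np.array_equal(np.argsort(p.bin_means), np.argsort(n.bin_means))


class TestBands:
    def test_uniform_colony_center_equals_edge(self):
        rec = _records([15, 20, 180, 200], [4.0, 4.0, 4.0, 4.0])
        b = band_summary(rec)
        assert b.center_mean == b.edge_mean == 4.0

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            band_summary(_records([1], [1]), (10, 100), (50, 200))

    def test_empty_band_is_missing(self):
        b = band_summary(_records([200.0], [4.0]))
        assert np.isnan(b.center_mean) and b.center_n == 0
        assert b.edge_mean == 4.0

    def test_wt_truth_bands(self):
        from dataclasses import replace

        from mpq.synthetic import (
            NoiseParams,
            assign_activation,
            generate_colony_layout,
        )

        lay = generate_colony_layout(250, 1500, 8.0, seed=51)
        pheno = replace(ACTIVIN_PRESETS["WT"], noise=NoiseParams.off())
        act = assign_activation(lay, pheno, seed=52)
        rec = nucleus_records_from_truth(lay, act, pheno, seed=53)
        b = band_summary(rec)
        assert b.center_mean == pheno.intensity_off
        assert b.edge_mean == pheno.intensity_on

    def test_ko_center_equals_edge_within_5pct(self):
        from mpq.synthetic import assign_activation, generate_colony_layout

        lay = generate_colony_layout(250, 1500, 8.0, seed=54)
        pheno = ACTIVIN_PRESETS["KO"]
        act = assign_activation(lay, pheno, seed=55)
        rec = nucleus_records_from_truth(lay, act, pheno, seed=56)
        b = band_summary(rec)
        assert b.center_mean == pytest.approx(b.edge_mean, rel=0.05)


class TestAggregate:
    def _profile(self, means):
        k = len(means)
        return RadialProfile(
            np.arange(0.0, 10 * (k + 1), 10), np.array(means, float), np.ones(k, int)
        )

    def test_single_profile_identity_sd_zero(self):
        p = self._profile([1.0, 2.0, 3.0])
        agg = aggregate_profiles([p])
        assert np.array_equal(agg.mean, p.bin_means)
        assert np.all(agg.sd == 0.0)

    def test_two_profiles_mean(self):
        agg = aggregate_profiles([self._profile([0, 1]), self._profile([1, 0])])
        assert np.allclose(agg.mean, [0.5, 0.5])

    def test_mismatched_grids_raise(self):
        with pytest.raises(ValueError, match="mismatched"):
            aggregate_profiles([self._profile([1, 2]), self._profile([1, 2, 3])])

    def test_wt_mean_profile_rises_outward(self):
        from mpq.synthetic import assign_activation, generate_colony_layout

        profiles = []
        for i in range(15):
            lay = generate_colony_layout(250, 1200, 8.0, seed=100 + i)
            pheno = ACTIVIN_PRESETS["WT"]
            act = assign_activation(lay, pheno, seed=200 + i)
            rec = nucleus_records_from_truth(lay, act, pheno, seed=300 + i)
            profiles.append(normalize_profile(radial_profile(rec, 10, 250)))
        agg = aggregate_profiles(profiles)
        outer = agg.mean[-5:]
        finite = outer[np.isfinite(outer)]
        assert np.all(np.diff(finite) >= -0.02)  # monotone over the rim
        assert np.nanmean(agg.mean[-3:]) > 3 * np.nanmean(agg.mean[1:3])
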