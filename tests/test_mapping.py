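"""Binning, the positive-detection rule, categories, and map assembly."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import filomap as fm
from filomap.errors import IntegrityError, ShortProfileError
from filomap.mapping import _bin_assignment


def brute_force_bins(values, n_bins=40):
    """Independent floor-partition / median oracle."""
    n = len(values)
    out = []
    for b in range(n_bins):
        members = [values[i] for i in range(n) if (i * n_bins) // n == b]
        out.append(np.median(members) if members else np.nan)
    return np.array(out)


def _profile(values):
    return fm.LineProfile("p", {"poi": np.asarray(values, dtype=float)}, 0.04)


def _binned(bins):
    return fm.BinnedProfile("b", np.asarray(bins, dtype=float))


def _cohort(profiles, name="poi"):
    return fm.POICohort(name, list(profiles))


class TestBinProfile:
    def test_constant_profile_fills_all_bins(self):
        b = fm.bin_profile(_profile(np.full(123, 777.0)))
        assert b.n_bins == 40
        assert np.allclose(b.bins, 777.0)

    def test_forty_samples_is_the_identity_partition(self):
        values = np.arange(40, dtype=float) * 100
        b = fm.bin_profile(_profile(values))
        assert np.array_equal(b.bins, values)

    def test_173_sample_profile_matches_brute_force_oracle(self, rng):
        values = rng.integers(0, 65536, size=173).astype(float)
        b = fm.bin_profile(_profile(values))
        assert np.array_equal(b.bins, brute_force_bins(values))

    @given(n=st.integers(min_value=40, max_value=400),
           seed=st.integers(min_value=0, max_value=10_000))
    def test_binning_equals_oracle_for_any_length(self, n, seed):
        values = np.random.default_rng(seed).integers(0, 65536, size=n).astype(float)
        b = fm.bin_profile(_profile(values))
        assert b.n_bins == 40
        assert np.array_equal(b.bins, brute_force_bins(values))

    def test_short_profile_rejected_unless_allowed(self):
        prof = _profile(np.linspace(0, 39000, 25))
        with pytest.raises(ShortProfileError):
            fm.bin_profile(prof)
        b = fm.bin_profile(prof, allow_short=True)
        assert b.interpolated and b.n_bins == 40
        assert not np.isnan(b.bins).any()

    def test_order_preserving_for_monotone_profiles(self):
        values = np.linspace(60000, 100, 217)
        b = fm.bin_profile(_profile(values))
        assert np.all(np.diff(b.bins) <= 0)

    def test_even_bin_median_is_mean_of_middle_pair(self):
        # 80 samples -> every bin holds exactly 2 samples
        values = np.arange(80, dtype=float)
        b = fm.bin_profile(_profile(values))
        assert np.array_equal(b.bins, np.arange(80).reshape(40, 2).mean(axis=1))

    def test_assignment_is_contiguous_and_covers_all_bins(self):
        for n in (40, 41, 173, 399):
            a = _bin_assignment(n, 40)
            assert a[0] == 0 and a[-1] == 39
            assert np.all(np.diff(a) >= 0)
            assert len(np.unique(a)) == 40


class TestIsPositive:
    def test_all_zero_bins_negative(self):
        assert not fm.is_positive(_binned(np.zeros(40)))

    @pytest.mark.parametrize("n_hits,value,expected", [
        (3, 10000, True),   # exactly the printed rule
        (2, 65535, False),  # brightness cannot substitute for bin count
        (3, 9999, False),   # strict floor
        (4, 10001, True),
    ])
    def test_detection_rule_boundaries(self, n_hits, value, expected):
        bins = np.zeros(40)
        bins[:n_hits] = value
        assert fm.is_positive(_binned(bins)) is expected

    @given(st.integers(min_value=0, max_value=39),
           st.floats(min_value=0, max_value=65535))
    def test_raising_a_bin_never_flips_positive_to_negative(self, idx, bump):
        rng = np.random.default_rng(42)
        bins = rng.uniform(0, 20000, size=40)
        before = fm.is_positive(_binned(bins))
        raised = bins.copy()
        raised[idx] = min(65535.0, raised[idx] + bump)
        after = fm.is_positive(_binned(raised))
        assert after or not before


class TestPercentPositiveAndCategories:
    def _mixed_cohort(self, k, n=100):
        pos = np.zeros(40); pos[:5] = 30000
        neg = np.zeros(40)
        return _cohort([_binned(pos)] * k + [_binned(neg)] * (n - k))

    def test_percent_positive_exact_counting(self):
        assert fm.percent_positive(self._mixed_cohort(0)) == 0.0
        assert fm.percent_positive(self._mixed_cohort(65)) == 65.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(IntegrityError):
            fm.percent_positive(_cohort([]))

    @pytest.mark.parametrize("pct,expected", [
        (65, "core"), (60, "core"), (59.99, "intermediate"), (50, "intermediate"),
        (40, "accessory"), (25, "accessory"), (10, "accessory"),
        (9.99, "absent"), (5, "absent"), (0, "absent"), (100, "core"),
    ])
    def test_category_boundaries(self, pct, expected):
        assert fm.classify_poi(pct) == expected

    def test_category_monotone_in_detection_frequency(self):
        order = {"absent": 0, "accessory": 1, "intermediate": 2, "core": 3}
        ranks = [order[fm.classify_poi(p)] for p in np.linspace(0, 100, 401)]
        assert np.all(np.diff(ranks) >= 0)


class TestMapAssembly:
    def test_single_profile_row_is_that_profile(self):
        bins = np.linspace(100, 30000, 40)
        row = fm.average_map_row(_cohort([_binned(bins)]))
        assert np.allclose(row, bins)

    def test_two_flat_profiles_average_midway(self):
        row = fm.average_map_row(_cohort([_binned(np.full(40, 10000.0)),
                                          _binned(np.full(40, 30000.0))]))
        assert np.allclose(row, 20000.0)

    def test_cohort_average_recovers_tip_fold(self):
        cohort = fm.generate_binned_cohort(
            500, fm.localization_class("tip_enriched", tip_fold=2.0,
                                       detection_prob=1.0),
            noise_sd=1500.0, seed=3)
        row = fm.average_map_row(cohort)
        assert row[:6].mean() / row[6:].mean() == pytest.approx(2.0, rel=0.05)

    def _summaries(self):
        cohorts = [
            fm.generate_binned_cohort(
                30, fm.localization_class(cls, detection_prob=1.0),
                seed=i, poi_name=name)
            for i, (name, cls) in enumerate([
                ("tipper", "tip_enriched"), ("flat", "uniform"),
                ("shafty", "shaft_enriched")])
        ]
        return [fm.summarize_cohort(c) for c in cohorts]

    def test_single_poi_map_shape(self):
        fmap = fm.assemble_map(self._summaries()[:1])
        assert fmap.matrix.shape == (1, 40)

    def test_median_enrichment_ordering_sorts_descending(self):
        fmap = fm.assemble_map(self._summaries(), ordering="median_enrichment")
        assert fmap.row_order == ["tipper", "flat", "shafty"]

    def test_row_max_scaling_normalizes_each_row(self):
        fmap = fm.assemble_map(self._summaries(), row_scaling="rowmax")
        assert np.allclose(fmap.scaled().max(axis=1), 1.0)
        # raw means retained unscaled
        assert fmap.matrix.max(axis=1).max() > 1.0

    def test_duplicate_poi_names_rejected(self):
        s = self._summaries()[0]
        with pytest.raises(IntegrityError):
            fm.assemble_map([s, s])

    def test_heatmap_renders_to_file(self, tmp_path):
        path = tmp_path / "map.png"
        fm.plot_map(fm.assemble_map(self._summaries()), path=path)
        assert path.stat().st_size > 0
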