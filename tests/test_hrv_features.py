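import collections
import dataclasses

import numpy as np
import pytest
from scipy.stats import spearmanr

from apneahrv.hrv_features import (
    SpectralConfig,
    extract_features,
    hrv_triangular_index,
    resample_tachogram,
    stft_band_powers,
    time_domain_features,
)
from apneahrv.synthetic_cohort import SyntheticConfig, generate_cohort
from conftest import make_series


class TestTimeDomain:
    def test_constant_series_all_zero(self):
        td = time_domain_features(make_series([800.0] * 30))
        assert all(v == 0.0 for v in td.values())

    def test_worked_example(self):
        td = time_domain_features(make_series([800.0, 860.0, 820.0]))
        # diffs {+60, -40}: one of two exceeds 50 ms
        assert td["pnn50"] == pytest.approx(50.0)
        assert td["rmssd"] == pytest.approx(np.sqrt((3600 + 1600) / 2), abs=1e-9)
        assert td["madrr"] == pytest.approx(50.0)

    def test_irrr_linear_interpolation_quantiles(self):
        td = time_domain_features(make_series([700.0, 800, 900, 1000, 1100]))
        assert td["irrr"] == pytest.approx(200.0)

    def test_sdnn_is_population_sd(self):
        rr = np.array([700.0, 900.0])
        td = time_domain_features(make_series(rr))
        assert td["sdnn"] == pytest.approx(100.0)  # ddof=0

    def test_matches_naive_definitions(self):
        rng = np.random.default_rng(5)
        rr = rng.uniform(600.0, 1200.0, 500)
        td = time_domain_features(make_series(rr))
        d = np.diff(rr)
        assert td["sdnn"] == pytest.approx(float(np.sqrt(np.mean((rr - rr.mean()) ** 2))))
        assert td["pnn50"] == pytest.approx(100 * sum(abs(x) > 50 for x in d) / len(d))
        assert td["rmssd"] == pytest.approx(float(np.sqrt(sum(x * x for x in d) / len(d))))
        assert td["madrr"] == pytest.approx(float(np.median(sorted(abs(x) for x in d))))

    def test_verbatim_madrr_switch(self):
        rr = [700.0, 800, 900, 1000, 1100]
        td = time_domain_features(make_series(rr), madrr_verbatim=True)
        assert td["madrr"] == pytest.approx(900.0)

    def test_single_beat_errors(self):
        with pytest.raises(ValueError, match="2 beats"):
            time_domain_features(make_series([800.0]))


class TestTriangularIndex:
    def test_identical_intervals_give_one(self):
        assert hrv_triangular_index(make_series([800.0] * 128)) == 1.0

    def test_two_equal_bins_give_two(self):
        rr = [800.0] * 64 + [900.0] * 64
        assert hrv_triangular_index(make_series(rr)) == 2.0

    def test_matches_naive_histogram(self):
        rng = np.random.default_rng(8)
        rr = rng.normal(900.0, 60.0, 2000).clip(400, 1400)
        got = hrv_triangular_index(make_series(rr))
        counts = collections.Counter(int(v // 7.8125) for v in rr)
        assert got == pytest.approx(len(rr) / max(counts.values()))


class TestResampling:
    def test_constant_series_constant_signal(self):
        s = make_series([500.0] * 1200)  # 600 s span
        _, sig = resample_tachogram(s)
        np.testing.assert_allclose(sig, 500.0)

    def test_sample_count(self):
        s = make_series([500.0] * 1200)
        t, sig = resample_tachogram(s)
        span = s.onsets_s[-1] - s.onsets_s[0]
        assert sig.size == int(np.floor(span * 4.0)) + 1
        assert t[0] == s.onsets_s[0]

    def test_grid_points_at_beat_times_reproduce_rr(self):
        # beats every 250 ms land exactly on the 4 Hz grid
        rng = np.random.default_rng(2)
        n = 2400
        rr = np.full(n, 250.0)
        onsets = np.cumsum(rr) / 1000.0
        values = 250.0 + rng.uniform(-5, 5, n)
        s = make_series(values, onsets_s=onsets, filtered=True)
        t, sig = resample_tachogram(s)
        at_beats = np.interp(s.onsets_s, t, sig)
        np.testing.assert_allclose(at_beats, values, atol=1e-9)

    def test_short_span_errors(self):
        with pytest.raises(ValueError, match="window"):
            resample_tachogram(make_series([800.0] * 10))


@pytest.fixture(scope="module")
def grid():
    fs = 4.0
    return np.arange(0, 3600.0, 1.0 / fs)


class TestBandPowers:
    def test_constant_signal_zero_power(self, grid):
        bp = stft_band_powers(np.full(grid.size, 1000.0))
        assert (bp.to_numpy() < 1e-6).all()

    @pytest.mark.parametrize("window_s", [300.0, 100.0])
    @pytest.mark.parametrize("amp,freq,band", [(50.0, 0.10, "lf"), (30.0, 0.25, "hf")])
    def test_sinusoid_recovered_at_half_amplitude_squared(self, grid, window_s,
                                                          amp, freq, band):
        cfg = SpectralConfig(window_s=window_s)
        sig = 1000.0 + amp * np.sin(2 * np.pi * freq * grid)
        bp = stft_band_powers(sig, cfg).mean()
        expected = amp**2 / 2
        assert bp[band] == pytest.approx(expected, rel=0.10)
        others = [b for b in ("ulf", "vlf", "lf", "hf") if b != band]
        assert all(bp[band] >= 20 * bp[b] for b in others)

    def test_off_bin_sinusoid_still_within_tolerance(self, grid):
        # 0.117 Hz is not a bin centre of a 300 s window; leakage stays local
        sig = 1000.0 + 40.0 * np.sin(2 * np.pi * 0.117 * grid)
        bp = stft_band_powers(sig).mean()
        assert bp["lf"] == pytest.approx(800.0, rel=0.10)
        assert bp["ulf"] < 0.05 * bp["lf"]


class TestExtractFeatures:
    def test_metadata_invariance(self):
        rng = np.random.default_rng(0)
        rr = rng.uniform(700, 1100, 800)
        a = extract_features(make_series(rr, subject_id="x", sensor="belt"))
        b = extract_features(make_series(rr, subject_id="y", sensor="patch"))
        assert a.to_dict() == b.to_dict()

    def test_features_finite_nonnegative_on_cohort(self, small_cohort):
        _, records, _ = small_cohort
        for rec in records[:5]:
            fv = extract_features(rec.recordings["belt"])
            vals = fv.to_dict()
            assert all(np.isfinite(v) for v in vals.values())
            assert all(v >= 0 for v in vals.values())

    def test_lfhf_is_ratio_of_aggregated_means(self, small_cohort):
        _, records, _ = small_cohort
        fv = extract_features(records[0].recordings["patch"])
        assert fv.lfhf == pytest.approx(fv.lf / fv.hf)

    def test_window_100_vs_300_rank_agreement(self):
        cfg = dataclasses.replace(SyntheticConfig(), n_subjects=50,
                                  night_duration_s=10800.0, seed=21)
        records, _ = generate_cohort(cfg, sensors=("patch",))
        lf300, lf100 = [], []
        for rec in records:
            s = rec.recordings["patch"]
            lf300.append(extract_features(s).lf)
            lf100.append(extract_features(s, SpectralConfig(window_s=100.0)).lf)
        rho = spearmanr(lf300, lf100).statistic
        assert rho >= 0.9
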