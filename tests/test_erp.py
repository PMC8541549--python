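import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
import hypothesis.extra.numpy as hnp

from eegcompare import erp
from eegcompare.recording import EventList

from conftest import make_recording

SR = 1024.0


def _recording_with_events(n_events=10, spacing=0.45, n_ch=3, noise=0.0,
                           seed=0):
    rng = np.random.default_rng(seed)
    onsets = (np.arange(n_events) * spacing * SR + SR).astype(int)
    n = int(onsets[-1] + SR)
    data = noise * rng.standard_normal((n_ch, n))
    return make_recording(data, SR, events=EventList(onsets,
                                                     ["reversal"] * n_events))


class TestExtractEpochs:
    def test_vep_settings_give_512_samples(self):
        rec = _recording_with_events()
        ep = erp.extract_epochs(rec, tmin=-0.1, tmax=0.4)
        assert ep.data.shape[2] == 512
        assert ep.times[0] == pytest.approx(-0.1, abs=1e-3)

    def test_all_300_events_become_trials(self):
        rec = _recording_with_events(n_events=300)
        ep = erp.extract_epochs(rec, tmin=-0.1, tmax=0.4)
        assert ep.n_trials == 300

    def test_constant_channel_zero_after_baseline_correction(self):
        rec = _recording_with_events()
        rec.data[:] = 5.0
        ep = erp.extract_epochs(rec, tmin=-0.1, tmax=0.4)
        assert np.max(np.abs(ep.data)) == 0.0

    def test_edge_events_dropped_with_warning(self, caplog):
        import logging
        rec = _recording_with_events(n_events=5)
        ev = EventList(np.array([10, *rec.events.onsets]),
                       ["reversal"] * 6)
        with caplog.at_level(logging.WARNING):
            ep = erp.extract_epochs(rec, events=ev, tmin=-0.1, tmax=0.4)
        assert ep.n_trials == 5
        assert any("edge" in r.message for r in caplog.records)


class TestAverageErp:
    def test_identical_trials_average_to_one_trial(self):
        data = np.tile(np.random.default_rng(0).standard_normal((1, 2, 50)),
                       (7, 1, 1))
        ep = erp.EpochSet(data, np.arange(50) / SR, ["a", "b"])
        avg = erp.average_erp(ep)
        assert np.allclose(avg.to_numpy(), data[0])

    def test_noise_shrinks_as_sqrt_n(self):
        rng = np.random.default_rng(1)
        template = np.sin(np.linspace(0, 4 * np.pi, 256))
        trials = template + rng.standard_normal((300, 1, 256))
        ep = erp.EpochSet(trials, np.arange(256) / SR, ["a"])
        err_avg = np.abs(erp.average_erp(ep).to_numpy()[0] - template).max()
        err_one = np.abs(trials[0, 0] - template).max()
        ratio = err_one / err_avg
        assert 0.3 * np.sqrt(300) < ratio < 3 * np.sqrt(300)

    def test_masked_channel_missing_in_output(self):
        data = np.random.default_rng(2).standard_normal((5, 2, 30))
        valid = np.ones((5, 2), dtype=bool)
        valid[:, 1] = False
        ep = erp.EpochSet(data, np.arange(30) / SR, ["a", "b"], valid=valid)
        avg = erp.average_erp(ep)
        assert np.isnan(avg.loc["b"]).all()
        assert not np.isnan(avg.loc["a"]).any()

    def test_baseline_then_average_equals_average_then_baseline(self):
        rng = np.random.default_rng(3)
        rec = _recording_with_events(n_events=8, noise=5.0, seed=3)
        ep = erp.extract_epochs(rec, tmin=-0.1, tmax=0.4,
                                baseline=(-0.1, 0.0))
        avg_of_corrected = erp.average_erp(ep).to_numpy()
        ep_raw = erp.extract_epochs(rec, tmin=-0.1, tmax=0.4, baseline=None)
        avg_raw = erp.average_erp(ep_raw).to_numpy()
        bmask = (ep_raw.times >= -0.1) & (ep_raw.times < 0.0)
        corrected_avg = avg_raw - avg_raw[:, bmask].mean(axis=1,
                                                         keepdims=True)
        assert np.max(np.abs(avg_of_corrected - corrected_avg)) < 1e-10


def brute_force_gfp(u: np.ndarray) -> float:
    """Pairwise double-sum oracle with 1/(2 n^2) normalization."""
    n = u.size
    total = 0.0
    for i in range(n):
        for j in range(n):
            total += (u[i] - u[j]) ** 2
    return np.sqrt(total / (2 * n * n))


class TestGfp:
    def test_worked_three_channel_example(self):
        u = np.array([2.0, 0.0, -2.0])
        g = erp.gfp_timecourse(u[:, None])
        assert g.gfp[0] == pytest.approx(np.sqrt(8 / 3), abs=1e-12)
        assert g.gfp[0] == pytest.approx(brute_force_gfp(u), abs=1e-12)

    def test_equal_channels_give_zero(self):
        g = erp.gfp_timecourse(np.full((5, 3), 7.0))
        assert np.allclose(g.gfp, 0.0)

    @given(hnp.arrays(np.float64, (29,),
                      elements=st.floats(-100, 100)),
           st.floats(-5, 5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_pairwise_oracle_and_scales_homogeneously(self, u, c):
        g = erp.gfp_timecourse(u[:, None]).gfp[0]
        oracle = brute_force_gfp(u)
        assert g == pytest.approx(oracle, abs=1e-10 * max(1.0, oracle))
        gc = erp.gfp_timecourse((c * u)[:, None]).gfp[0]
        assert gc == pytest.approx(abs(c) * g, abs=1e-8)

    def test_fewer_than_two_channels_rejected(self):
        with pytest.raises(ValueError, match="2 non-missing"):
            erp.gfp_timecourse(np.ones((1, 4)))


class TestCompareGfp:
    def _series(self, values):
        values = np.asarray(values, dtype=float)
        return erp.GFPSeries(np.arange(values.size) / SR, values, 29)

    def test_identical_series(self):
        a = self._series(np.random.default_rng(0).random(100))
        c = erp.compare_gfp(a, a)
        assert c.rho == pytest.approx(1.0)
        assert c.rmsd == 0.0

    def test_monotone_transform_keeps_rho_one(self):
        vals = np.random.default_rng(1).random(50)
        a = self._series(vals)
        b = self._series(vals ** 3)
        c = erp.compare_gfp(a, b)
        assert c.rho == pytest.approx(1.0)
        assert c.rmsd > 0

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(2)
        a, b = self._series(rng.random(64)), self._series(rng.random(64))
        ab, ba = erp.compare_gfp(a, b), erp.compare_gfp(b, a)
        assert ab.rho == pytest.approx(ba.rho)
        assert ab.rmsd == pytest.approx(ba.rmsd)

    def test_constant_series_has_undefined_rho(self):
        a = self._series(np.ones(20))
        b = self._series(np.random.default_rng(3).random(20))
        assert np.isnan(erp.compare_gfp(a, b).rho)


class TestFindPeaks:
    def test_gaussian_bump_found_at_center(self):
        t = np.arange(0, 0.4, 1 / SR)
        g = erp.GFPSeries(t, np.exp(-0.5 * ((t - 0.15) / 0.02) ** 2), 29)
        peaks = erp.find_gfp_peaks(g, {"P": (0.1, 0.2)})
        assert peaks.loc["P", "latency_s"] == pytest.approx(0.15,
                                                            abs=1.5 / SR)

    def test_two_bumps_separated_by_windows(self):
        t = np.arange(0, 0.5, 1 / SR)
        y = (np.exp(-0.5 * ((t - 0.12) / 0.01) ** 2)
             + 2 * np.exp(-0.5 * ((t - 0.3) / 0.02) ** 2))
        g = erp.GFPSeries(t, y, 29)
        peaks = erp.find_gfp_peaks(g, {"early": (0.05, 0.2),
                                       "late": (0.25, 0.4)})
        assert peaks.loc["early", "latency_s"] == pytest.approx(0.12,
                                                                abs=2 / SR)
        assert peaks.loc["late", "latency_s"] == pytest.approx(0.30,
                                                               abs=2 / SR)
        assert peaks.loc["late", "amplitude_uv"] > \
            peaks.loc["early", "amplitude_uv"]

    def test_empty_window_rejected(self):
        g = erp.GFPSeries(np.arange(204) / SR, np.ones(204), 29)
        with pytest.raises(ValueError, match="empty"):
            erp.find_gfp_peaks(g, {"x": (0.5, 0.6)})
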