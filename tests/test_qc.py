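import numpy as np
import pandas as pd
import pytest

from eegcompare import qc

from conftest import make_recording

SR = 256.0


def _sin(freq, amp, duration=10.0):
    t = np.arange(int(duration * SR)) / SR
    return amp * np.sin(2 * np.pi * freq * t)


class TestGlobalChannelFlags:
    def test_flat_and_loud_channels_rejected_quiet_kept(self):
        # mean|A sin| = 2A/pi: 100 uV -> 63.7 (reject), 10 uV -> 6.37 (keep)
        rec = make_recording(np.vstack([np.zeros(int(10 * SR)),
                                        _sin(10, 100.0), _sin(10, 10.0)]),
                             SR, labels=["Fz", "Cz", "Pz"])
        rep = qc.flag_bad_channels_global(rec)
        assert rep.channel_flags["Fz"].startswith("amplitude<1uV")
        assert rep.channel_flags["Cz"].startswith("amplitude>50uV")
        assert "Pz" not in rep.channel_flags

    def test_empty_recording_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            qc.flag_bad_channels_global(make_recording(np.empty((1, 0))))


class TestTaskChannelFlags:
    def test_identical_channels_all_kept(self):
        # SD across channels is 0 and the threshold is strict
        row = _sin(10, 10.0)
        rec = make_recording(np.tile(row, (29, 1)), SR,
                             labels=[f"E{i}" for i in range(29)])
        rep = qc.flag_bad_channels_task(rec, window_len=0.5)
        assert rep.channel_flags == {}

    def test_single_loud_channel_caught_by_mean_2sd(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((29, int(10 * SR))) * 3.0
        data[7] *= 10.0  # still below 50 uV mean amplitude
        rec = make_recording(data, SR, labels=[f"E{i}" for i in range(29)])
        rep = qc.flag_bad_channels_task(rec, window_len=0.5)
        assert list(rep.channel_flags) == ["E7"]
        assert "mean+2SD" in rep.channel_flags["E7"]

    def test_excess_power_in_one_band_is_not_enough(self):
        rng = np.random.default_rng(6)
        data = rng.standard_normal((10, int(20 * SR))) * 3.0
        # concentrate E2's power in delta while keeping its total variance
        # (and hence its mean amplitude) at the cohort level
        data[2] = data[2] * np.sqrt(0.5) + _sin(2.5, 3.0, 20.0)
        rec = make_recording(data, SR, labels=[f"E{i}" for i in range(10)])
        rep = qc.flag_bad_channels_task(rec, window_len=3.0)
        assert "E2" not in rep.channel_flags


class TestUnitFlags:
    def test_identical_units_none_rejected(self):
        unit = np.tile(_sin(10, 5.0, 1.0), (4, 1))
        data = np.tile(unit, (6, 1, 1))
        rep = qc.flag_bad_units(data, SR, ["a", "b", "c", "d"])
        assert rep.unit_flags == {}

    def test_burst_trial_flagged_on_its_channel_only(self):
        rng = np.random.default_rng(7)
        data = rng.standard_normal((20, 3, int(SR))) * 2.0
        data[4, 1] *= 10.0
        rep = qc.flag_bad_units(data, SR, ["x", "y", "z"])
        assert (4, "y") in rep.unit_flags
        # the burst is the only flagged unit on its channel (thresholds are
        # per channel, so other channels may carry chance flags)
        assert [u for (u, lab) in rep.unit_flags if lab == "y"] == [4]

    def test_gamma_spike_window_flagged_under_gamma_criterion(self):
        rng = np.random.default_rng(8)
        data = rng.standard_normal((15, 2, int(SR))) * 2.0
        data[3, 0] += _sin(40.0, 20.0, 1.0)
        rep = qc.flag_bad_units(data, SR, ["u", "v"], bands=qc.GAMMA_ONLY,
                                min_bands=1, unit="window")
        assert (3, "u") in rep.unit_flags

    def test_too_few_units_rejected(self):
        with pytest.raises(ValueError, match="3 units"):
            qc.flag_bad_units(np.zeros((2, 2, 256)), SR, ["a", "b"])


class TestReliability:
    def test_silent_channel_fully_reliable(self):
        rec = make_recording(np.zeros((1, int(10 * SR))), SR)
        assert qc.channel_reliability(rec).iloc[0] == 100.0

    def test_one_bad_window_out_of_ten(self):
        data = np.zeros((1, int(10 * SR)))
        data[0, int(3.5 * SR)] = 500.0  # one 500 uV spike in window 3
        rec = make_recording(data, SR)
        assert qc.channel_reliability(rec).iloc[0] == pytest.approx(90.0)

    def test_zero_threshold_with_noise_gives_zero(self):
        rng = np.random.default_rng(0)
        rec = make_recording(rng.standard_normal((1, int(5 * SR))), SR)
        assert qc.channel_reliability(rec, p2p_threshold=0.0).iloc[0] == 0.0

    def test_recording_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            qc.channel_reliability(make_recording(np.zeros((1, 10)), SR))


class TestRejectionSummary:
    def test_nothing_rejected_is_zero_percent(self):
        rep = qc.QCReport(labels=["a", "b"], duration_s=10.0)
        per_channel, subject = qc.rejection_summary([rep])
        assert subject == 0.0
        assert (per_channel == 0).all()

    def test_one_fully_rejected_channel_of_29(self):
        labels = [f"E{i}" for i in range(29)]
        rep = qc.QCReport(labels=labels, duration_s=60.0,
                          channel_flags={"E0": "amplitude<1uV"})
        per_channel, subject = qc.rejection_summary([rep])
        assert per_channel["E0"] == 100.0
        assert subject == pytest.approx(100.0 / 29, abs=1e-9)

    def test_unit_flags_add_channel_seconds(self):
        rep = qc.QCReport(labels=["a", "b"], duration_s=10.0,
                          unit_flags={(0, "a"): "amp", (3, "a"): "amp"},
                          n_units=10, unit_duration_s=1.0)
        per_channel, subject = qc.rejection_summary([rep])
        assert per_channel["a"] == pytest.approx(20.0)
        assert subject == pytest.approx(10.0)

    def test_dry_cohort_rejects_more_than_gel(self, reduced_config):
        """Directional check: with the dry system's higher corruption rate
        the dry percent-rejected exceeds gel's on average."""
        import dataclasses
        from eegcompare.synthetic import simulate_subject
        from eegcompare.preprocessing import (filter_zero_phase,
                                              BANDPASS_BROAD)
        cfg = dataclasses.replace(reduced_config, seed=21,
                                  p_bad_channel_dry=0.25,
                                  p_bad_channel_gel=0.02, n_subjects=6)
        means = {}
        for system in ("dry", "gel"):
            pcts = []
            for s in range(cfg.n_subjects):
                recs, _ = simulate_subject(cfg, s, system, tasks=("CHECK",))
                rec = filter_zero_phase(recs["CHECK"], BANDPASS_BROAD)
                rep = qc.flag_bad_channels_global(rec)
                pcts.append(qc.rejection_summary([rep])[1])
            means[system] = np.mean(pcts)
        assert means["dry"] > means["gel"]


class TestInvariants:
    def test_cascade_is_deterministic(self):
        rng = np.random.default_rng(11)
        data = rng.standard_normal((8, int(10 * SR))) * 5
        rec = make_recording(data, SR)
        r1 = qc.flag_bad_channels_task(rec, 1.0)
        r2 = qc.flag_bad_channels_task(rec, 1.0)
        assert r1.channel_flags == r2.channel_flags

    def test_adding_corruption_never_unrejects(self):
        """Monotonicity over 100 random fixtures: adding a flat channel
        never rescues a rejected one, and absolute-amplitude (criterion 1)
        rejections survive any added channel.

        The relative mean+2SD criteria are *not* monotone under additions
        that inflate the cross-channel statistics (a single-pass threshold
        recomputation cannot be); only the guarantees above hold.
        """
        rng = np.random.default_rng(12)
        for _ in range(100):
            n_ch = int(rng.integers(5, 12))
            data = rng.standard_normal((n_ch, 2048)) * rng.uniform(1, 5)
            data[rng.integers(n_ch)] *= 8
            labels = [f"E{i}" for i in range(n_ch)]
            rec = make_recording(data, SR, labels=labels)
            rep = qc.flag_bad_channels_task(rec, 1.0)
            before = set(rep.channel_flags)
            crit1_before = {l for l, c in rep.channel_flags.items()
                            if "amplitude<1uV" in c or "amplitude>50uV" in c}

            flat = make_recording(np.vstack([data, np.zeros((1, 2048))]),
                                  SR, labels=labels + ["X"])
            after_flat = set(qc.flag_bad_channels_task(flat, 1.0).channel_flags)
            assert before <= after_flat

            loud = make_recording(
                np.vstack([data, 90 * rng.standard_normal((1, 2048))]),
                SR, labels=labels + ["X"])
            after_loud = set(qc.flag_bad_channels_task(loud, 1.0).channel_flags)
            assert crit1_before <= after_loud
            assert "X" in after_loud

    def test_decisions_match_naive_reference(self):
        """mean+2SD decisions equal a direct formula transcription on 50
        random small instances."""
        rng = np.random.default_rng(13)
        for _ in range(50):
            n_u, n_c = int(rng.integers(4, 9)), int(rng.integers(2, 5))
            amp = rng.gamma(2.0, 2.0, size=(n_u, n_c))
            ours = qc._exceeds_2sd(amp, axis=0)
            naive = np.zeros_like(ours)
            for c in range(n_c):
                col = amp[:, c]
                thr = col.mean() + 2 * col.std(ddof=1)
                for u in range(n_u):
                    naive[u, c] = col[u] > thr
            assert np.array_equal(ours, naive)
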