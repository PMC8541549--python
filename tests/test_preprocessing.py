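import numpy as np
import pytest

from eegcompare import preprocessing as pre
from eegcompare.montage import SHARED_CHANNELS
from eegcompare.recording import Recording

from conftest import make_recording

SR = 1024.0


def _sinusoid(freq, duration=10.0, amp=1.0):
    t = np.arange(int(duration * SR)) / SR
    return amp * np.sin(2 * np.pi * freq * t), t


class TestZeroPhaseFilter:
    def test_no_phase_shift_at_10hz_through_broadband(self):
        x, t = _sinusoid(10.0)
        rec = make_recording(x, SR)
        out = pre.filter_zero_phase(rec, pre.BANDPASS_BROAD)
        mid = slice(int(2 * SR), int(8 * SR))
        y = out.data[0, mid]
        # project onto the quadrature pair to estimate the residual phase
        s = np.sin(2 * np.pi * 10 * t[mid])
        c = np.cos(2 * np.pi * 10 * t[mid])
        phase = np.degrees(np.arctan2(y @ c, y @ s))
        assert abs(phase) < 0.1

    def test_line_noise_attenuated_at_least_20db(self):
        x, _ = _sinusoid(50.0)
        out = pre.filter_zero_phase(make_recording(x, SR), pre.BANDSTOP_LINE)
        steady = out.data[0, int(2 * SR):int(8 * SR)]
        measured_db = 20 * np.log10(np.max(np.abs(steady)) + 1e-300)
        analytic_db = 20 * np.log10(
            pre.BANDSTOP_LINE.magnitude_at(50.0, SR) + 1e-300)
        assert measured_db <= -20
        assert analytic_db <= -20

    def test_dc_offset_removed_by_highpass(self):
        rec = make_recording(np.full(int(10 * SR), 100.0), SR)
        out = pre.filter_zero_phase(rec, pre.BANDPASS_BROAD)
        steady = out.data[0, int(3 * SR):int(7 * SR)]
        assert np.mean(np.abs(steady)) < 1.0
        assert pre.BANDPASS_BROAD.magnitude_at(1e-9, SR) < 1e-6

    def test_filtering_is_linear_and_shape_preserving(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((3, 2048))
        b = rng.standard_normal((3, 2048))
        fa = pre.filter_zero_phase(make_recording(a), pre.BANDPASS_BROAD).data
        fb = pre.filter_zero_phase(make_recording(b), pre.BANDPASS_BROAD).data
        fab = pre.filter_zero_phase(make_recording(a + 2 * b),
                                    pre.BANDPASS_BROAD).data
        assert fab.shape == a.shape
        assert np.allclose(fab, fa + 2 * fb, atol=1e-8)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            pre.filter_zero_phase(make_recording(np.zeros(256), 64.0),
                                  pre.BANDPASS_BROAD)


class TestHarmonize:
    def _paired(self, seed=0, zero_m2=False):
        rng = np.random.default_rng(seed)
        from eegcompare.montage import make_montage
        dry_m, gel_m = make_montage("dry"), make_montage("gel")
        dry = Recording(rng.standard_normal((32, 512)), 256.0,
                        list(dry_m.labels), system="dry", montage=dry_m)
        gel_data = rng.standard_normal((32, 512))
        if zero_m2:
            gel_data[gel_m.index("M2")] = 0.0
        gel = Recording(gel_data, 256.0, list(gel_m.labels), system="gel",
                        montage=gel_m)
        return dry, gel

    def test_zero_m2_makes_rereferencing_identity(self):
        dry, gel = self._paired(zero_m2=True)
        _, gel29 = pre.harmonize_and_rereference(dry, gel)
        for lab in gel29.channel_labels:
            assert np.array_equal(gel29.get_channel(lab),
                                  gel.get_channel(lab))

    def test_outputs_have_identical_channel_order(self):
        dry, gel = self._paired()
        d29, g29 = pre.harmonize_and_rereference(dry, gel)
        assert d29.channel_labels == g29.channel_labels
        assert len(d29.channel_labels) == 29
        assert set(d29.channel_labels) == set(SHARED_CHANNELS)

    def test_rereferencing_is_idempotent(self):
        dry, gel = self._paired()
        d1, g1 = pre.harmonize_and_rereference(dry, gel)
        d2, g2 = pre.harmonize_and_rereference(d1, g1)
        assert np.array_equal(g1.data, g2.data)
        assert np.array_equal(d1.data, d2.data)

    def test_gel_subtracts_m2(self):
        dry, gel = self._paired()
        m2 = gel.get_channel("M2").copy()
        _, g29 = pre.harmonize_and_rereference(dry, gel)
        assert np.allclose(g29.get_channel("Fz"),
                           gel.get_channel("Fz") - m2)

    def test_missing_m2_and_unreferenced_gel_rejected(self):
        dry, gel = self._paired()
        gel = gel.drop(["M2"])
        object.__setattr__(gel, "reference_label", "CPz")
        with pytest.raises(ValueError, match="M2"):
            pre.harmonize_and_rereference(dry, gel)


class TestComponentRemoval:
    def _decomp(self, n_ch=6, n=4096, seed=1):
        rng = np.random.default_rng(seed)
        rec = make_recording(rng.standard_normal((n_ch, n)), 256.0)
        return rec, pre.decompose(rec, seed=0)

    def test_reconstruction_and_empty_removal_identity(self):
        rec, d = self._decomp()
        assert np.max(np.abs(d.reconstruct() - rec.data)) < 1e-6
        out = pre.remove_components(rec, d, [])
        assert np.max(np.abs(out.data - rec.data)) < 1e-6

    def test_removing_all_components_zeroes_the_recording(self):
        rec, d = self._decomp()
        out = pre.remove_components(rec, d, range(d.n_components))
        assert np.max(np.abs(out.data)) < 1e-6

    def test_out_of_range_index_rejected(self):
        rec, d = self._decomp()
        with pytest.raises(IndexError):
            pre.remove_components(rec, d, [99])


@pytest.fixture(scope="module")
def blink_session(reduced_config):
    import dataclasses
    from eegcompare.synthetic import simulate_subject
    cfg = dataclasses.replace(reduced_config, blink_rate=12.0,
                              p_bad_channel_dry=0.0, drift_sd_dry=5.0)
    recs, gt = simulate_subject(cfg, 0, "dry", tasks=("EOEC",))
    rec = pre.filter_zero_phase(recs["EOEC"], pre.BANDPASS_BROAD)
    return rec, gt


class TestBlinkSelection:
    def test_seeded_blink_component_is_found_and_removal_helps(self, blink_session):
        rec, gt = blink_session
        decomp = pre.decompose(rec, seed=0)
        idx = pre.identify_blink_component(decomp, rec.sample_rate)
        assert idx is not None
        # the selected source should spike at the injected blink times
        onsets = np.array(gt.blink_onsets["EOEC"])
        src = np.abs(decomp.sources[idx])
        at_blinks = np.array([src[o:o + int(0.4 * rec.sample_rate)].max()
                              for o in onsets])
        assert np.median(at_blinks) > 3 * np.median(src)
        cleaned = pre.remove_components(rec, decomp, [idx])
        fp1 = rec.channel_index("Fp1")
        assert cleaned.data[fp1].var() < rec.data[fp1].var()

    def test_no_blinks_means_no_component(self, reduced_config):
        import dataclasses
        from eegcompare.synthetic import simulate_subject
        cfg = dataclasses.replace(reduced_config, blink_rate=0.0,
                                  p_bad_channel_dry=0.0)
        recs, _ = simulate_subject(cfg, 0, "dry", tasks=("CHECK",))
        rec = pre.filter_zero_phase(recs["CHECK"], pre.BANDPASS_BROAD)
        decomp = pre.decompose(rec, seed=0)
        assert pre.identify_blink_component(decomp, rec.sample_rate) is None

    def test_zero_frontality_component_never_selected(self):
        # hand-built decomposition: component 0 is occipital-only yet blinky
        sr = 256.0
        n = int(60 * sr)
        src = np.zeros(n)
        from eegcompare.synthetic import blink_template
        tmpl = blink_template(sr, 50.0)
        for onset in range(int(2 * sr), n - tmpl.size, int(5 * sr)):
            src[onset:onset + tmpl.size] += tmpl
        rng = np.random.default_rng(0)
        sources = np.vstack([src, rng.standard_normal(n)])
        labels = ["Oz", "Pz", "Fp1", "Fp2"]
        mixing = np.array([[1.0, 0.1], [0.8, 0.1], [0.0, 0.5], [0.0, 0.5]])
        d = pre.ComponentDecomposition(mixing=mixing, sources=sources,
                                       channel_labels=labels)
        assert pre.identify_blink_component(d, sr) != 0
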