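"""Filtering, channel rejection, ICA artifact removal, and windowing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from eegfiction import preprocess as pp
from eegfiction.io import ContractError, EventAnnotation, Montage, Recording
from eegfiction.simulate import NoiseSpec, generate_design, synthesize_recording

from conftest import make_tone_recording, small_design

FS = 500.0


def _steady(x, fs=FS, skip_s=2.0):
    n = int(skip_s * fs)
    return x[n:-n]


class TestBandlimit:
    def test_45hz_tone_attenuated_40db(self):
        rec = make_tone_recording(45.0)
        out = pp.apply_bandlimit(rec).samples[0]
        ratio = np.sqrt(np.mean(_steady(out) ** 2)) / np.sqrt(0.5)
        assert 20 * np.log10(ratio) < -40

    def test_dc_offset_removed(self):
        m = Montage(("A",))
        rec = Recording("p", m, FS, np.full((1, int(20 * FS)), 7.0))
        out = pp.apply_bandlimit(rec).samples[0]
        assert np.sqrt(np.mean(_steady(out) ** 2)) < 7.0 * 1e-2

    def test_10hz_tone_within_5_percent(self):
        rec = make_tone_recording(10.0)
        out = pp.apply_bandlimit(rec).samples[0]
        rms_in = np.sqrt(np.mean(_steady(rec.samples[0]) ** 2))
        rms_out = np.sqrt(np.mean(_steady(out) ** 2))
        assert rms_out == pytest.approx(rms_in, rel=0.05)

    def test_linearity(self, rng):
        m = Montage(("A",))
        x = rng.standard_normal(int(10 * FS))
        y = rng.standard_normal(int(10 * FS))
        f = lambda v: pp.apply_bandlimit(
            Recording("p", m, FS, v[None, :])
        ).samples[0]
        lhs = f(x + y)
        rhs = f(x) + f(y)
        assert np.abs(lhs - rhs).max() <= 1e-6 * np.abs(rhs).max()

    def test_zero_phase_at_10hz(self):
        rec = make_tone_recording(10.0)
        out = pp.apply_bandlimit(rec).samples[0]
        a, b = _steady(rec.samples[0]), _steady(out)
        xc = np.correlate(b, a, mode="full")
        assert xc.argmax() == len(a) - 1  # zero lag

    def test_nan_rejected(self):
        m = Montage(("A",))
        data = np.zeros((1, int(1 * FS)))
        data[0, 10] = np.nan
        with pytest.raises(ContractError):
            pp.apply_bandlimit(Recording("p", m, FS, data))

    def test_events_preserved(self):
        rec = make_tone_recording(10.0)
        rec.events = [EventAnnotation(1.0, 2.0, "s", "original")]
        out = pp.apply_bandlimit(rec)
        assert out.events == rec.events


class TestRejectChannels:
    def test_loud_channel_is_rejected(self, rng):
        data = rng.standard_normal((8, 5000))
        data[3] *= 100.0
        rec = Recording(
            "p", Montage(tuple(f"C{i}" for i in range(8))), FS, data
        )
        out, rejected = pp.reject_channels(rec, z_threshold=5.0)
        assert rejected == ["C3"]
        assert out.n_channels == 7
        assert "C3" not in out.montage.channel_names

    def test_homogeneous_channels_kept(self, rng):
        data = rng.standard_normal((8, 5000))
        rec = Recording(
            "p", Montage(tuple(f"C{i}" for i in range(8))), FS, data
        )
        _, rejected = pp.reject_channels(rec, 5.0)
        assert rejected == []

    def test_infinite_threshold_keeps_everything(self, rng):
        data = rng.standard_normal((4, 1000))
        data[0] *= 1e6
        rec = Recording(
            "p", Montage(tuple(f"C{i}" for i in range(4))), FS, data
        )
        _, rejected = pp.reject_channels(rec, np.inf)
        assert rejected == []

    def test_too_few_channels_rejected(self, rng):
        rec = Recording(
            "p", Montage(("A", "B")), FS, rng.standard_normal((2, 1000))
        )
        with pytest.raises(ContractError):
            pp.reject_channels(rec, 5.0)


class TestIca:
    def _mixture(self, rng, n=20000):
        # two independent super-Gaussian (Laplace) sources
        s = rng.laplace(size=(2, n))
        mix = rng.normal(size=(2, 2)) + 2 * np.eye(2)
        return s, mix, mix @ s

    def test_separates_supergaussian_sources(self, rng):
        s, mix, x = self._mixture(rng)
        rec = Recording("p", Montage(("A", "B")), FS, x)
        dec = pp.decompose_ica(rec, seed=0)
        # match recovered to true sources up to permutation/sign/scale
        corr = np.abs(np.corrcoef(np.vstack([s, dec.sources]))[:2, 2:])
        best = corr.max(axis=1)
        assert (best >= 0.95).all()
        assert {corr[0].argmax(), corr[1].argmax()} == {0, 1}

    def test_unmixing_inverts_mixing(self, rng):
        _, _, x = self._mixture(rng)
        rec = Recording("p", Montage(("A", "B")), FS, x)
        dec = pp.decompose_ica(rec, seed=0)
        np.testing.assert_allclose(
            dec.unmixing @ dec.mixing, np.eye(2), atol=1e-8
        )

    def test_deterministic_under_seed(self, rng):
        _, _, x = self._mixture(rng, n=5000)
        rec = Recording("p", Montage(("A", "B")), FS, x)
        d1 = pp.decompose_ica(rec, seed=3)
        d2 = pp.decompose_ica(rec, seed=3)
        np.testing.assert_array_equal(d1.mixing, d2.mixing)
        np.testing.assert_array_equal(d1.sources, d2.sources)

    def test_too_short_recording_rejected(self, rng):
        rec = Recording(
            "p", Montage(("A", "B")), FS, rng.standard_normal((2, 50))
        )
        with pytest.raises(ContractError):
            pp.decompose_ica(rec)

    def test_rank_deficient_reduces_with_warning(self, rng):
        base = rng.laplace(size=(1, 20000))
        x = np.vstack([base, 2 * base, base + 2 * base])
        rec = Recording("p", Montage(("A", "B", "C")), FS, x)
        with pytest.warns(RuntimeWarning, match="rank"):
            dec = pp.decompose_ica(rec, seed=0)
        assert dec.mixing.shape[1] < 3


def _decomposition_with(topography, source, channel_names, fs=FS):
    k = 1
    mixing = np.asarray(topography, dtype=float)[:, None]
    return pp.Decomposition(
        mixing=mixing,
        unmixing=np.linalg.pinv(mixing),
        sources=np.asarray(source, dtype=float)[None, :],
        mean=np.zeros(len(channel_names)),
        channel_names=tuple(channel_names),
        sampling_rate_hz=fs,
    )


class TestScoreComponents:
    CHANNELS = (
        "Fp1", "Fp2", "F7", "F8", "Fz", "Cz", "Pz", "Oz",
        "T7", "T8", "FT9", "FT10",
    )

    def _probs(self, dec):
        out = {}
        for s in pp.score_components(dec):
            out.setdefault(s.component_index, {})[s.artifact_class] = s.probability
        return out

    def test_blink_component_scores_eye(self, rng):
        topo = [1.0, 1.0, 0.6, 0.6, 0.3, 0.1, 0.05, 0.05, 0.05, 0.05, 0.05, 0.05]
        t = np.arange(int(30 * FS)) / FS
        source = np.zeros_like(t)
        for onset in np.arange(1.0, 29.0, 2.5):  # blink train, ~1 Hz content
            source += np.exp(-0.5 * ((t - onset) / 0.08) ** 2)
        probs = self._probs(
            _decomposition_with(topo, source, self.CHANNELS)
        )[0]
        assert probs["eye"] >= 0.85

    def test_muscle_component_scores_muscle(self, rng):
        topo = [0.05] * 8 + [1.0, 1.0, 0.8, 0.8]
        n = int(30 * FS)
        white = rng.standard_normal(n)
        sos = sps.butter(4, [25 / 250, 45 / 250], btype="band", output="sos")
        source = sps.sosfilt(sos, white)
        probs = self._probs(
            _decomposition_with(topo, source, self.CHANNELS)
        )[0]
        assert probs["muscle"] >= 0.85

    def test_flat_uniform_component_scores_brain_or_other(self, rng):
        topo = [1.0] * len(self.CHANNELS)
        source = rng.standard_normal(int(30 * FS))
        probs = self._probs(
            _decomposition_with(topo, source, self.CHANNELS)
        )[0]
        top = max(probs, key=probs.get)
        assert top in ("brain", "other")

    def test_probabilities_sum_to_one_per_component(self, rng):
        topo = [1.0] * len(self.CHANNELS)
        dec = _decomposition_with(
            topo, rng.standard_normal(int(10 * FS)), self.CHANNELS
        )
        probs = self._probs(dec)[0]
        assert sum(probs.values()) == pytest.approx(1.0)


@pytest.fixture(scope="module")
def blink_setup():
    spec = small_design(
        n_participants=1, n_trials=2, duration=(5.0, 6.0),
        noise=NoiseSpec(
            pink_scale_uv=2.0, sensor_white_uv=1.0,
            blink_rate_hz=0.3, muscle_burst_rate_hz=0.0,
        ),
        seed=3,
    )
    meta, sched = generate_design(spec)[0]
    rec = pp.apply_bandlimit(synthesize_recording(meta, sched, spec))
    dec = pp.decompose_ica(rec, seed=0)
    scores = pp.score_components(dec)
    return rec, dec, scores


class TestRemoveArtifacts:
    @staticmethod
    def _band(rec, ch, lo, hi):
        f, p = sps.welch(rec.channel(ch), fs=rec.sampling_rate_hz, nperseg=1000)
        return p[(f >= lo) & (f < hi)].sum()

    def test_blink_power_removed_alpha_untouched(self, blink_setup):
        rec, dec, scores = blink_setup
        clean = pp.remove_artifacts(rec, dec, scores, 0.85)
        fp1_reduction = 1 - self._band(clean, "Fp1", 0.5, 4) / self._band(
            rec, "Fp1", 0.5, 4
        )
        pz_change = abs(
            self._band(clean, "Pz", 8, 13) / self._band(rec, "Pz", 8, 13) - 1
        )
        assert fp1_reduction >= 0.80
        assert pz_change <= 0.10

    def test_idempotent_at_fixed_decomposition(self, blink_setup):
        rec, dec, scores = blink_setup
        once = pp.remove_artifacts(rec, dec, scores, 0.85)
        twice = pp.remove_artifacts(once, dec, scores, 0.85)
        np.testing.assert_allclose(once.samples, twice.samples, atol=1e-9)

    def test_nothing_flagged_is_identity(self, blink_setup):
        rec, dec, scores = blink_setup
        out = pp.remove_artifacts(rec, dec, scores, threshold=1.0)
        high = [
            s for s in scores
            if s.artifact_class in ("eye", "muscle") and s.probability >= 1.0
        ]
        if not high:
            np.testing.assert_array_equal(out.samples, rec.samples)

    def test_zero_threshold_rejected(self, blink_setup):
        rec, dec, scores = blink_setup
        with pytest.raises(ContractError):
            pp.remove_artifacts(rec, dec, scores, threshold=0.0)


class TestWindows:
    def test_10s_stimulus_gives_19_windows(self):
        assert pp.window_count(10.0, 1.0, 0.5) == 19

    def test_exact_length_gives_one_window(self):
        assert pp.window_count(1.0, 1.0, 0.5) == 1

    def test_short_stimulus_gives_none(self):
        assert pp.window_count(0.8, 1.0, 0.5) == 0

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        duration=st.integers(1, 600),  # tenths of a second
        length=st.integers(1, 40),
        step=st.integers(1, 40),
    )
    def test_window_count_matches_brute_force(self, duration, length, step):
        d, l, s = duration / 10, length / 10, step / 10
        brute = 0
        start = 0
        while start * s + l <= d + 1e-9:
            brute += 1
            start += 1
        assert pp.window_count(d, l, s) == brute

    def test_segments_carry_labels_and_window_grid(self):
        spec = small_design(n_participants=1, n_trials=1, montage_size=4)
        meta, sched = generate_design(spec)[0]
        rec = synthesize_recording(meta, sched, spec)
        segments = pp.segment_windows(rec)
        assert len(segments) == len(rec.events)
        for seg, ev in zip(segments, rec.events):
            assert seg.text_type == ev.text_type
            expected = pp.window_count(ev.duration_s, 1.0, 0.5)
            assert abs(seg.n_windows - expected) <= 1  # sample rounding
            w = seg.windows(seg.channel_names[0])
            assert w.shape == (seg.n_windows, 500)

    def test_event_outside_recording_rejected(self):
        rec = make_tone_recording(10.0, duration_s=2.0)
        ev = EventAnnotation(1.5, 1.0, "s", "original")
        with pytest.raises(ContractError):
            pp.segment_windows(rec, events=[ev])

    def test_invalid_window_spec_rejected(self):
        with pytest.raises(ContractError):
            pp.WindowSpec(length_s=1.0, step_s=0.0)
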