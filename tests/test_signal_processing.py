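"""Filtering and threshold detection against constructed oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from slicephys.recording import RawRecording
from slicephys.signal_processing import (
    FilterSpec,
    bessel_gain,
    bessel_highpass,
    dc_remove,
    detect_spikes,
    extract_spikes,
    extract_waveform,
    filter_channel,
    filter_recording,
)
from slicephys.synthetic_data import biphasic_template

FS = 20_000.0


def _recording(samples: np.ndarray, filtered: bool = False,
               n_traces: int | None = None) -> RawRecording:
    samples = np.atleast_2d(np.asarray(samples, dtype=np.float32))
    n_traces = n_traces or int(np.ceil(samples.shape[1] / FS))
    return RawRecording(
        samples=samples,
        sampling_rate=FS,
        regions=["DG"] * samples.shape[0],
        n_traces=n_traces,
        filtered=filtered,
    )


class TestBesselHighpass:
    def test_dc_is_rejected(self):
        x = np.full(int(FS), 0.5)
        y = bessel_highpass(x, FS)
        assert np.max(np.abs(y[int(FS / 2):])) < 1e-6

    @pytest.mark.parametrize("freq", [100.0, 1000.0, 5000.0])
    def test_steady_state_gain_matches_analytic_prototype(self, freq):
        """Sine steady-state gain vs. the analog 2-pole magnitude (within 2%;
        -3 dB at the 1000 Hz cutoff)."""
        t = np.arange(int(FS * 2)) / FS
        y = bessel_highpass(np.sin(2 * np.pi * freq * t), FS, 1000.0)
        tail = y[int(FS):]
        gain = np.sqrt(2.0) * np.sqrt(np.mean(tail**2))
        assert gain == pytest.approx(bessel_gain(freq, 1000.0), rel=0.02)
        if freq == 1000.0:
            assert gain == pytest.approx(1 / np.sqrt(2), abs=0.02)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bessel_highpass(np.zeros(100), 4000.0, cutoff=2500.0)

    @settings(derandomize=True, deadline=None, max_examples=20)
    @given(scale=st.floats(min_value=-50, max_value=50,
                           allow_nan=False, allow_infinity=False))
    def test_linearity(self, scale):
        rng = np.random.default_rng(3)
        x = rng.normal(size=2000)
        assert np.allclose(
            bessel_highpass(scale * x, FS), scale * bessel_highpass(x, FS),
            atol=1e-10,
        )


class TestDCRemove:
    def test_constant_offset_removed_exactly(self):
        y = dc_remove(np.full(4000, 0.1, dtype=np.float32), FS)
        assert np.max(np.abs(y)) < 1e-7

    def test_one_ms_pulse_retains_95_percent_of_peak(self):
        x = np.zeros(4000, dtype=np.float32)
        x[2000 : 2000 + 20] = 0.1  # 1 ms at 20 kHz
        y = dc_remove(x, FS)
        assert y.max() >= 0.095

    def test_slow_ramp_suppressed(self):
        n = int(10 * FS)
        x = np.linspace(0, 0.1, n).astype(np.float32)
        y = dc_remove(x, FS)
        assert np.max(np.abs(y)) < 0.005

    def test_window_at_or_below_2ms_rejected(self):
        with pytest.raises(ValueError, match="dc_window"):
            dc_remove(np.zeros(100), FS, dc_window_ms=2.0)


class TestDetect:
    def test_all_zero_recording_gives_no_events(self):
        rec = _recording(np.zeros((2, int(FS))), filtered=True)
        assert detect_spikes(rec) == []

    def test_unfiltered_recording_refused(self):
        rec = _recording(np.zeros((1, int(FS))))
        with pytest.raises(ValueError, match="filtered"):
            detect_spikes(rec)

    def test_injected_template_detected_against_direct_scan_oracle(self):
        """One biphasic template in zero noise: exactly one event whose
        amplitudes equal the signed extrema of the filtered trace (direct
        scan) and whose time is within 0.5 ms of the injection (the causal
        filter delays the first crossing by ~0.3 ms)."""
        x = np.zeros((1, int(FS)), dtype=np.float32)
        tpl = biphasic_template(FS, 0.05, -0.04)
        i0 = int(0.5 * FS)
        x[0, i0 : i0 + tpl.size] += tpl.astype(np.float32)
        events = extract_spikes(_recording(x))
        assert len(events) == 1
        ev = events[0]
        assert abs(ev.time - 0.5) <= 0.5e-3
        y = filter_channel(x[0], FS)
        j0 = int(round(ev.time * FS))
        j1 = int(round(ev.end_time * FS)) + 1
        assert ev.amp_pos == pytest.approx(float(y[j0:j1].max()), abs=1e-9)
        assert ev.amp_neg == pytest.approx(float(y[j0:j1].min()), abs=1e-9)
        assert ev.amp_pos >= 0.021 and ev.amp_neg <= -0.021

    @pytest.mark.parametrize("freq", [200.0, 1000.0, 2000.0])
    def test_subthreshold_sine_yields_no_events(self, freq):
        """A steady 0.020 mV sine stays below the +/-0.021 mV thresholds
        (ramped on over 50 ms so the filter's switch-on transient does not
        masquerade as signal)."""
        t = np.arange(int(FS)) / FS
        ramp = np.clip(t / 0.05, 0.0, 1.0)
        x = (0.020 * ramp * np.sin(2 * np.pi * freq * t)).astype(np.float32)
        assert extract_spikes(_recording(x[None, :])) == []

    def test_merge_rule_dead_time(self):
        """Two templates closer than the dead time merge into one event;
        separated by more than 2 ms they stay distinct."""
        tpl = biphasic_template(FS, 0.05, -0.04).astype(np.float32)

        def build(gap_ms):
            x = np.zeros((1, int(FS)), dtype=np.float32)
            i0 = int(0.5 * FS)
            i1 = i0 + int(gap_ms * 1e-3 * FS)
            x[0, i0 : i0 + tpl.size] += tpl
            x[0, i1 : i1 + tpl.size] += tpl
            return x

        close = extract_spikes(_recording(build(0.8)))
        far = extract_spikes(_recording(build(3.0)))
        assert len(close) == 1
        assert len(far) == 2

    def test_detect_matches_streaming_extract(self, small_config):
        from slicephys.synthetic_data import simulate_recording

        rec, _ = simulate_recording(small_config, "wt", 0, 0, "normal")
        ev_stream = extract_spikes(rec)
        ev_batch = detect_spikes(filter_recording(rec))
        assert [(e.channel, e.time) for e in ev_stream] == [
            (e.channel, e.time) for e in ev_batch
        ]
        # sorted by (channel, time)
        keys = [(e.channel, e.time) for e in ev_stream]
        assert keys == sorted(keys)


class TestWaveformExtraction:
    def _rec_with_event(self):
        x = np.zeros((1, int(FS)), dtype=np.float32)
        tpl = biphasic_template(FS, 0.05, -0.04)
        i0 = int(0.5 * FS)
        x[0, i0 : i0 + tpl.size] += tpl.astype(np.float32)
        rec = _recording(x, filtered=True)
        return rec, detect_spikes(rec)[0]

    def test_snippet_length_matches_window_arithmetic(self):
        """An event spanning exactly 1 ms at 20 kHz with 1 ms context each
        side: 60 +/- 1 samples (20 + 20 + 20)."""
        x = np.zeros((1, int(FS)), dtype=np.float32)
        i0 = int(0.5 * FS)
        x[0, i0 : i0 + 20] = 0.05  # 20 supra-threshold samples = 1 ms
        rec = _recording(x, filtered=True)
        ev = detect_spikes(rec)[0]
        snippet, truncated = extract_waveform(rec, ev)
        assert not truncated
        assert abs(snippet.size - 60) <= 1

    def test_event_at_recording_start_is_left_truncated(self):
        x = np.zeros((1, int(FS)), dtype=np.float32)
        x[0, :5] = 0.05
        rec = _recording(x, filtered=True)
        ev = detect_spikes(rec)[0]
        _, truncated = extract_waveform(rec, ev)
        assert truncated

    def test_native_sampling_no_downsampling(self):
        rec, ev = self._rec_with_event()
        snippet, _ = extract_waveform(rec, ev)
        i0 = int(round(ev.time * FS)) - int(1e-3 * FS)
        assert np.array_equal(snippet, rec.samples[0, i0 : i0 + snippet.size])

    def test_event_outside_recording_rejected(self):
        rec, ev = self._rec_with_event()
        ev.time = ev.end_time = rec.duration + 1.0
        with pytest.raises(ValueError):
            extract_waveform(rec, ev)


class TestFilterSpec:
    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="order"):
            FilterSpec(order=4).validate(FS)
        with pytest.raises(ValueError, match="Nyquist"):
            FilterSpec(cutoff=3000.0).validate(4100.0)
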