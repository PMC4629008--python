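import numpy as np
import pytest

from prososcreen import (
    AudioSignal,
    Envelope,
    PitchTrack,
    SyllableNucleus,
    VoicedRegion,
    annotate_f0,
    compute_envelope,
    detect_peaks,
    detect_syllables,
    estimate_boundaries,
    write_textgrid,
)


def test_zero_signal_zero_envelope():
    sig = AudioSignal(np.zeros(44100), 44100)
    env = compute_envelope(sig)
    assert np.all(env.values == 0)


def test_envelope_hop_is_220_samples_at_44k1():
    sig = AudioSignal(np.random.default_rng(0).normal(0, 0.1, 44100), 44100)
    env = compute_envelope(sig, window_s=0.010, hop_s=0.005)
    np.testing.assert_allclose(np.diff(env.frame_times), 220 / 44100)


def test_tone_burst_envelope_peak_position():
    """A 150 ms burst centered at 0.5 s peaks there; cross-checked against a
    plain-loop RMS of the band-passed signal."""
    fs = 44100
    t = np.arange(fs) / fs
    burst = np.zeros(fs)
    a, b = int(0.425 * fs), int(0.575 * fs)
    burst[a:b] = np.sin(2 * np.pi * 500 * t[a:b]) * np.hanning(b - a)
    sig = AudioSignal(0.8 * burst, fs)
    env = compute_envelope(sig)
    t_peak = env.frame_times[np.argmax(env.values)]
    assert abs(t_peak - 0.5) <= 0.010

    # independent brute-force frame RMS (no weighting, no smoothing)
    from scipy.signal import butter, sosfiltfilt

    y = sosfiltfilt(butter(4, [300, 2500], btype="bandpass", fs=fs, output="sos"),
                    sig.samples)
    L, H = 441, 220
    rms = [np.sqrt(np.mean(y[i:i + L] ** 2)) for i in range(0, fs - L + 1, H)]
    t_oracle = (np.argmax(rms) * H + L / 2) / fs
    assert abs(t_peak - t_oracle) <= 0.010


def _bump_envelope(positions, width=8, n=400, height=1.0, hop=0.005):
    v = np.zeros(n)
    for p in positions:
        i = int(p / hop)
        w = np.hanning(2 * width + 1) * height
        lo = max(0, i - width)
        v[lo:i + width + 1] += w[width - (i - lo):]
    return Envelope(np.arange(n) * hop, v, 0.010, hop)


def test_flat_envelope_no_peaks():
    env = Envelope(np.arange(100) * 0.005, np.ones(100), 0.010, 0.005)
    assert detect_peaks(env).size == 0


def test_two_separated_bumps_two_peaks():
    env = _bump_envelope([0.5, 0.8])
    peaks = detect_peaks(env, rel_threshold=0.3, min_gap_s=0.06)
    assert peaks.size == 2
    np.testing.assert_allclose(peaks, [0.5, 0.8], atol=0.005)


def test_close_bumps_merge_keeping_larger():
    env = _bump_envelope([0.500], height=1.0)
    env2 = _bump_envelope([0.530], height=0.6)
    merged = Envelope(env.frame_times, env.values + env2.values, 0.010, 0.005)
    peaks = detect_peaks(merged, min_gap_s=0.06)
    assert peaks.size == 1
    assert abs(peaks[0] - 0.5) < 0.02


def test_threshold_monotonicity_random_envelopes():
    """Raising the relative threshold never yields more peaks."""
    rng = np.random.default_rng(5)
    for _ in range(30):
        raw = rng.normal(0, 1, 300)
        v = np.abs(np.convolve(raw, np.hanning(9), mode="same"))
        env = Envelope(np.arange(300) * 0.005, v, 0.010, 0.005)
        counts = [detect_peaks(env, rel_threshold=r).size for r in (0.15, 0.3, 0.5, 0.7)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_peak_times_amplitude_invariant(small_utterance):
    sig, _ = small_utterance
    e1 = compute_envelope(sig)
    e2 = compute_envelope(sig.scaled(2.0))
    np.testing.assert_array_equal(detect_peaks(e1), detect_peaks(e2))


def test_synthetic_utterance_exact_peak_count(small_utterance):
    sig, truth = small_utterance
    peaks = detect_peaks(compute_envelope(sig))
    assert peaks.size == truth.nsy


def _manual_envelope():
    # plateau 0.5, dips to 0.1 at t=0.95 and t=1.06, peak 1.0 at t=1.00
    hop = 0.01
    t = np.arange(0, 201) * hop  # 0..2.0 s
    v = np.full(t.size, 0.5)
    v[95] = 0.1
    v[96:100] = np.linspace(0.4, 0.9, 4)
    v[100] = 1.0
    v[101:106] = np.linspace(0.9, 0.3, 5)
    v[106] = 0.1
    return Envelope(t, v, 0.01, hop)


def test_boundaries_from_envelope_minima():
    env = _manual_envelope()
    nuclei = estimate_boundaries([1.00], env, [VoicedRegion(0.90, 1.10)])
    assert len(nuclei) == 1
    assert nuclei[0].onset == pytest.approx(0.95)
    assert nuclei[0].offset == pytest.approx(1.06)


def test_boundaries_clipped_by_voicing_limit():
    env = _manual_envelope()
    nuclei = estimate_boundaries([1.00], env, [VoicedRegion(0.90, 1.03)])
    assert nuclei[0].offset == pytest.approx(1.03)
    assert nuclei[0].onset == pytest.approx(0.95)


def test_boundary_clipped_to_signal_start():
    hop = 0.005
    t = np.arange(100) * hop
    v = np.linspace(1.0, 0.0, 100)  # peak at the very first frame
    env = Envelope(t, v, 0.01, hop)
    nuclei = estimate_boundaries([0.01], env, [])
    assert len(nuclei) == 1
    assert nuclei[0].onset == 0.0


def test_peak_outside_envelope_errors():
    env = _manual_envelope()
    with pytest.raises(ValueError):
        estimate_boundaries([5.0], env, [])


def test_annotate_f0_mean_and_unvoiced_flag():
    hop = 0.005
    times = np.arange(20) * hop
    voiced = np.zeros(20, bool)
    f0 = np.full(20, np.nan)
    voiced[4:7] = True
    f0[4:7] = [100.0, 110.0, 120.0]
    track = PitchTrack(times, f0, voiced, hop)
    nuclei = [
        SyllableNucleus(peak_time=0.03, onset=0.0, offset=0.06, peak_value=1.0),
        SyllableNucleus(peak_time=0.085, onset=0.075, offset=0.095, peak_value=1.0),
    ]
    out = annotate_f0(nuclei, track)
    assert out[0].voiced and out[0].mean_f0_hz == pytest.approx(110.0)
    assert not out[1].voiced and np.isnan(out[1].mean_f0_hz)


def test_constant_f0_syllable_recovered_within_one_semitone():
    from prososcreen import UtteranceSpec, synth_utterance

    spec = UtteranceSpec(n_syllables=3, f0_base=140.0, f0_jitter_st=0.0,
                         f0_glide_st=0.0, seed=9)
    sig, truth = synth_utterance(spec)
    nuclei, track, env = detect_syllables(sig)
    assert len(nuclei) == 3
    for nuc in nuclei:
        assert abs(12 * np.log2(nuc.mean_f0_hz / 140.0)) < 1.0


def test_nuclei_disjoint_and_contain_peaks(small_utterance):
    sig, _ = small_utterance
    nuclei, track, env = detect_syllables(sig)
    for nuc in nuclei:
        assert nuc.onset <= nuc.peak_time <= nuc.offset
        assert nuc.duration > 0
    for a, b in zip(nuclei[:-1], nuclei[1:]):
        assert a.offset <= b.onset
        assert a.peak_time < b.peak_time


def test_textgrid_export(tmp_path, small_utterance):
    sig, _ = small_utterance
    nuclei, *_ = detect_syllables(sig)
    out = tmp_path / "nuc.TextGrid"
    write_textgrid(nuclei, sig.duration, out)
    text = out.read_text()
    assert 'Object class = "TextGrid"' in text
    assert '"nucleus"' in text
    assert text.count('text = "nuc"') == len(nuclei)
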