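"""EDF I/O, montage derivation, resampling and normalization."""

import numpy as np
import pytest

from rtseiz.eeg_io import (DOUBLE_BANANA_PAIRS, MONTAGE_ELECTRODES,
                           MontageRecording, NormalizationStats, RawRecording,
                           SeizureAnnotation, apply_normalizer,
                           build_double_banana, canonical_label,
                           fit_normalizer, load_recording, read_edf,
                           resample_to_common_rate, save_recording)
from rtseiz.synthetic_data import ELECTRODES_19, generate_background, write_edf


def _random_raw(rng, n=2000, fs=256.0):
    return RawRecording(
        patient_id="r", channel_names=list(ELECTRODES_19),
        sampling_rate_hz=fs, samples=rng.normal(size=(19, n)) * 30,
    )


def _montage(samples, fs=200.0, normalized=False):
    return MontageRecording(patient_id="m",
                            pair_names=list(DOUBLE_BANANA_PAIRS),
                            sampling_rate_hz=fs, samples=samples,
                            normalized=normalized)


# ---------------------------------------------------------------------------
# EDF round trips and label handling
# ---------------------------------------------------------------------------

def test_edf_round_trip_within_quantization(tmp_path, rng):
    rec = generate_background(10, 256, seed=3)
    rec.patient_id = "p0"
    write_edf(rec, tmp_path / "p0.edf")
    back = read_edf(tmp_path / "p0.edf")
    assert back.sampling_rate_hz == 256
    assert back.channel_names == rec.channel_names
    step = 2 * 8192.0 / 65535
    assert np.max(np.abs(back.samples - rec.samples)) <= step


def test_edf_missing_electrode_named(tmp_path):
    rec = generate_background(2, 256, seed=0)
    idx = rec.channel_names.index("cz")
    rec.channel_names.pop(idx)
    rec.samples = np.delete(rec.samples, idx, axis=0)
    write_edf(rec, tmp_path / "x.edf")
    with pytest.raises(ValueError, match="cz"):
        read_edf(tmp_path / "x.edf")


def test_edf_label_canonicalization(tmp_path):
    """Vendor-style labels like 'EEG Fp1-Ref' map to bare electrode names."""
    rec = generate_background(2, 256, seed=1)
    rec.channel_names = [f"EEG {n.capitalize()}-Ref" for n in rec.channel_names]
    write_edf(rec, tmp_path / "v.edf")
    back = read_edf(tmp_path / "v.edf")
    assert back.channel_names[:2] == ["fp1", "f7"]
    assert set(MONTAGE_ELECTRODES) <= set(back.channel_names)


@pytest.mark.parametrize("raw,expected", [
    ("EEG Fp1-Ref", "fp1"), ("Cz", "cz"), ("EEG T3-LE", "t3"), (" O2 ", "o2"),
])
def test_canonical_label(raw, expected):
    assert canonical_label(raw) == expected


def test_edf_amplitude_range_error(tmp_path):
    rec = generate_background(2, 256, seed=2)
    rec.samples[3] += 9000.0
    with pytest.raises(ValueError, match=rec.channel_names[3]):
        write_edf(rec, tmp_path / "big.edf")


def test_edf_empty_recording_error(tmp_path):
    rec = generate_background(2, 256, seed=2)
    rec.samples = rec.samples[:, :0]
    with pytest.raises(ValueError):
        write_edf(rec, tmp_path / "empty.edf")


# ---------------------------------------------------------------------------
# Montage
# ---------------------------------------------------------------------------

def test_montage_constant_difference(rng):
    raw = _random_raw(rng)
    raw.samples[:] = 0.0
    raw.samples[raw.channel_names.index("fp1")] = 5.0
    raw.samples[raw.channel_names.index("f7")] = 2.0
    mont = build_double_banana(raw)
    assert np.allclose(mont.samples[mont.pair_names.index("fp1-f7")], 3.0)


def test_montage_identical_channels_zero(rng):
    raw = _random_raw(rng)
    raw.samples[:] = raw.samples[0]
    mont = build_double_banana(raw)
    assert np.all(mont.samples == 0.0)


def test_montage_matches_loop_oracle_exactly(rng):
    """Differencing equals an independent per-pair subtraction loop, with
    zero error, over 100 random recordings (integer-safe included)."""
    for trial in range(100):
        samples = rng.integers(-500, 500, size=(19, 200)).astype(float) \
            if trial % 2 else rng.normal(size=(19, 200)) * 40
        raw = RawRecording("t", list(ELECTRODES_19), 256.0, samples)
        mont = build_double_banana(raw)
        for i, pair in enumerate(DOUBLE_BANANA_PAIRS):
            a, b = pair.split("-")
            expected = raw.channel(a) - raw.channel(b)
            assert np.max(np.abs(mont.samples[i] - expected)) == 0.0


def test_montage_order_ends_with_midline():
    assert DOUBLE_BANANA_PAIRS[-2:] == ("fz-cz", "cz-pz")
    assert len(DOUBLE_BANANA_PAIRS) == 22


def test_montage_missing_electrode_error(rng):
    raw = _random_raw(rng)
    raw.channel_names[raw.channel_names.index("pz")] = "xx"
    with pytest.raises(ValueError, match="cz-pz"):
        build_double_banana(raw)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def test_resample_length_and_identity(rng):
    m = _montage(rng.normal(size=(22, 24000)), fs=400.0)
    out = resample_to_common_rate(m)
    assert out.sampling_rate_hz == 200.0
    assert out.samples.shape == (22, 12000)
    same = resample_to_common_rate(_montage(rng.normal(size=(22, 400)), fs=200.0))
    assert same.sampling_rate_hz == 200.0


def test_resample_upsampling_rejected(rng):
    m = _montage(rng.normal(size=(22, 1000)), fs=128.0)
    with pytest.raises(ValueError):
        resample_to_common_rate(m)


def test_resample_preserves_sine_amplitude(rng):
    """A 10 Hz sinusoid survives 400->200 Hz with <1% amplitude error at the
    dominant DFT peak."""
    fs, dur = 400.0, 60.0
    t = np.arange(int(fs * dur)) / fs
    sine = np.sin(2 * np.pi * 10.0 * t)
    m = _montage(np.tile(sine, (22, 1)), fs=fs)
    out = resample_to_common_rate(m)
    spec = np.abs(np.fft.rfft(out.samples[0])) / out.samples.shape[1] * 2
    freqs = np.fft.rfftfreq(out.samples.shape[1], 1 / 200.0)
    peak = freqs[np.argmax(spec)]
    assert abs(peak - 10.0) < 0.1
    assert abs(spec.max() - 1.0) < 0.01


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def test_fit_normalizer_single_and_concat(rng):
    m1 = _montage(rng.normal(size=(22, 100)))
    m1.samples[0, :3] = [-3.0, 0.0, 7.0]
    m1.samples[0, 3:] = 0.0
    stats = fit_normalizer([m1])
    assert stats.per_channel_min[0] == -3.0 and stats.per_channel_max[0] == 7.0

    m2 = _montage(rng.normal(size=(22, 150)))
    joint = fit_normalizer([m1, m2])
    concat = _montage(np.concatenate([m1.samples, m2.samples], axis=1))
    direct = fit_normalizer([concat])
    assert np.array_equal(joint.per_channel_min, direct.per_channel_min)
    assert np.array_equal(joint.per_channel_max, direct.per_channel_max)


def test_fit_normalizer_matches_brute_force_and_order_invariant(rng):
    recs = [_montage(rng.normal(size=(22, rng.integers(50, 200))) * 50)
            for _ in range(10)]
    stats = fit_normalizer(recs)
    allcat = np.concatenate([r.samples for r in recs], axis=1)
    assert np.array_equal(stats.per_channel_min, allcat.min(axis=1))
    assert np.array_equal(stats.per_channel_max, allcat.max(axis=1))
    rev = fit_normalizer(recs[::-1])
    assert np.array_equal(stats.per_channel_min, rev.per_channel_min)


def test_apply_normalizer_midpoint_and_degenerate(rng):
    m = _montage(np.zeros((22, 4)))
    m.samples[0] = [0, 10, 5, 10]
    stats = NormalizationStats(np.zeros(22), np.r_[10.0, np.zeros(21)])
    out = apply_normalizer(m, stats)
    assert out.normalized
    assert out.samples[0, 2] == 0.5
    assert np.all(out.samples[1:] == 0.0)  # max == min -> zeros


def test_apply_normalizer_round_trip_and_double_norm_error(rng):
    m = _montage(rng.normal(size=(22, 300)) * 40)
    stats = fit_normalizer([m])
    out = apply_normalizer(m, stats)
    span = stats.per_channel_max - stats.per_channel_min
    back = out.samples * span[:, None] + stats.per_channel_min[:, None]
    assert np.max(np.abs(back - m.samples)) < 1e-9
    with pytest.raises(ValueError):
        apply_normalizer(out, stats)


def test_no_clipping_outside_training_range(rng):
    m = _montage(rng.normal(size=(22, 100)))
    stats = NormalizationStats(np.full(22, -1.0), np.full(22, 1.0))
    m.samples[0, 0] = 5.0
    out = apply_normalizer(m, stats)
    assert out.samples[0, 0] == 3.0  # (5 - (-1)) / 2, not clipped to 1


# ---------------------------------------------------------------------------
# Cache container
# ---------------------------------------------------------------------------

def test_cache_round_trip(tmp_path, rng):
    m = _montage(rng.normal(size=(22, 500)).astype(np.float32).astype(float),
                 normalized=True)
    save_recording(m, tmp_path / "m.rec")
    back = load_recording(tmp_path / "m.rec")
    assert back.normalized and back.sampling_rate_hz == 200.0
    assert np.array_equal(back.samples, m.samples)


def test_annotation_validation():
    with pytest.raises(ValueError):
        SeizureAnnotation(5.0, 4.0, "CAE")
    with pytest.raises(ValueError):
        SeizureAnnotation(0.0, 1.0, "XYZ")
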