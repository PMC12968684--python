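"""Synthetic pediatric EEG cohorts with annotated, type-specific seizures.

The clinical recordings this package targets are not public, so every other
module is exercised against cohorts built here: spatially correlated 1/f
background with a posterior-dominant ~9 Hz rhythm, plus additive parametric
ictal waveforms for the four seizure categories —

* **CAE** — generalized ~3 Hz spike-and-slow-wave complexes, all electrodes;
* **IESS** — a single brief (~1 s) high-amplitude slow wave with a diamond
  amplitude envelope, followed by ~1 s of diffuse amplitude attenuation
  (electrodecrement);
* **GN** — generalized polyspike-and-wave bursts at ~4.5 Hz;
* **FC** — a focal oscillation confined to a contiguous electrode
  neighbourhood whose frequency evolves linearly (4 → 8 Hz).

Morphologies are transparent caricatures for pipeline testing, not clinical
simulations.  Default cohort composition and event-duration targets mirror
the study cohort's per-group proportions and mean event lengths at roughly
one tenth of its size; recordings are generated at 256 Hz so the 200 Hz
resampler is exercised on every cohort.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .eeg_io import (
    MONTAGE_ELECTRODES,
    SEIZURE_TYPES,
    RawRecording,
    SeizureAnnotation,
    write_annotation_csv,
)

__all__ = [
    "ELECTRODES_19",
    "SyntheticSpec",
    "SeizureMorphology",
    "default_morphology",
    "generate_background",
    "inject_seizure",
    "PatientRecord",
    "Cohort",
    "generate_cohort",
    "write_edf",
]

#: 19 scalp electrodes in a front-to-back chain ordering, so that a
#: contiguous slice is a spatially plausible focal neighbourhood.
ELECTRODES_19: tuple[str, ...] = (
    "fp1", "f7", "t3", "t5", "o1", "p3", "c3", "f3", "fz", "cz",
    "pz", "f4", "c4", "p4", "fp2", "f8", "t4", "t6", "o2",
)
assert set(ELECTRODES_19) == set(MONTAGE_ELECTRODES)

_POSTERIOR = {"o1": 1.0, "o2": 1.0, "t5": 0.5, "t6": 0.5, "p3": 0.5, "p4": 0.5}


# ---------------------------------------------------------------------------
# Background EEG
# ---------------------------------------------------------------------------

def _pink_noise(n: int, fs: float, rng: np.random.Generator,
                alpha: float = 1.0) -> np.ndarray:
    """Zero-mean noise whose power spectrum falls off as 1/f^alpha."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-alpha / 2.0)
    x = np.fft.irfft(spec * shaping, n=n)
    return x / x.std()


def generate_background(duration_s: float, fs: float,
                        n_electrodes: int = 19,
                        seed: int | np.random.Generator = 0,
                        background_std_uv: float = 20.0,
                        alpha: float = 1.0) -> RawRecording:
    """Seizure-free multichannel background EEG.

    Each electrode mixes its own 1/f^alpha process with a shared one (spatial
    correlation ~0.3 between any two electrodes); posterior electrodes get an
    amplitude-modulated ~9 Hz dominant rhythm on top.  Scale is tens of
    microvolts, reproducible under the seed.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration and sampling rate must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = list(ELECTRODES_19[:n_electrodes])
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    shared = _pink_noise(n, fs, rng, alpha)
    rho = 0.3
    rows = np.empty((len(names), n))
    for i in range(len(names)):
        own = _pink_noise(n, fs, rng, alpha)
        rows[i] = np.sqrt(1 - rho) * own + np.sqrt(rho) * shared
    rows *= background_std_uv

    # posterior-dominant rhythm: 9 Hz with a slowly wandering envelope
    env = 1.0 + 0.5 * np.sin(2 * np.pi * 0.1 * t + rng.uniform(0, 2 * np.pi))
    pdr = np.sin(2 * np.pi * 9.0 * t + rng.uniform(0, 2 * np.pi)) * env
    for i, name in enumerate(names):
        gain = _POSTERIOR.get(name, 0.0)
        rows[i] += 9.0 * background_std_uv / 20.0 * gain * pdr

    return RawRecording(patient_id="synthetic", channel_names=names,
                        sampling_rate_hz=float(fs), samples=rows)


# ---------------------------------------------------------------------------
# Seizure morphologies
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SeizureMorphology:
    """Parametric description of one ictal waveform family.

    ``electrodes`` lists the affected electrodes (all 19 for generalized
    types, a contiguous subset for focal); ``gains`` gives the per-electrode
    multiplier applied to the common waveform — distinct values so bipolar
    differencing never cancels the event; ``amplitude_uv`` is the peak scale
    of the additive waveform.
    """

    type_label: str
    electrodes: list[str]
    gains: np.ndarray
    oscillation_hz: float
    amplitude_uv: float

    def __post_init__(self):
        if self.type_label not in SEIZURE_TYPES:
            raise ValueError(f"unknown seizure type {self.type_label!r}")
        if self.type_label == "FC" and len(self.electrodes) >= len(ELECTRODES_19):
            raise ValueError("focal morphology must mask a strict electrode subset")


def default_morphology(type_label: str, rng: np.random.Generator,
                       amplitude_uv: float = 80.0,
                       focal_size: int = 6) -> SeizureMorphology:
    """Textbook-shaped default morphology for each seizure category."""
    if type_label == "FC":
        start = int(rng.integers(0, len(ELECTRODES_19) - focal_size + 1))
        electrodes = list(ELECTRODES_19[start: start + focal_size])
        osc = 4.0  # evolves to 8 Hz over the event
    else:
        electrodes = list(ELECTRODES_19)
        osc = {"CAE": 3.0, "IESS": 1.5, "GN": 4.5}[type_label]
    # Non-uniform scalp topography: random per-electrode magnitude and
    # polarity.  A spatially smooth taper would nearly cancel in the bipolar
    # montage (adjacent electrodes get subtracted); sign flips keep every
    # derivation's share of the discharge large.
    gains = (rng.uniform(0.55, 1.0, size=len(electrodes))
             * rng.choice([-1.0, 1.0], size=len(electrodes)))
    return SeizureMorphology(type_label=type_label, electrodes=electrodes,
                             gains=gains, oscillation_hz=osc,
                             amplitude_uv=amplitude_uv)


def _spike_train(t: np.ndarray, rate_hz: float, width_s: float,
                 offsets_s: Sequence[float] = (0.0,)) -> np.ndarray:
    """Sum of Gaussian spikes repeating at rate_hz, one per offset per cycle."""
    phase = np.mod(t, 1.0 / rate_hz)
    out = np.zeros_like(t)
    for off in offsets_s:
        out += np.exp(-0.5 * ((phase - off) / width_s) ** 2)
    return out


def _ictal_waveform(m: SeizureMorphology, duration_s: float,
                    fs: float) -> np.ndarray:
    """The common (pre-gain) additive waveform of one event."""
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    if m.type_label == "CAE":
        # ~3 Hz spike-and-slow-wave complexes
        wave = 0.55 * np.sin(2 * np.pi * m.oscillation_hz * t)
        wave += 1.1 * _spike_train(t, m.oscillation_hz, 0.012, offsets_s=(0.04,))
        env = _tukey(n, 0.15)
    elif m.type_label == "IESS":
        # single high-amplitude slow wave, diamond (triangular) envelope
        wave = np.sin(np.pi * np.clip(t / duration_s, 0, 1))
        env = 1.0 - np.abs(2 * t / duration_s - 1.0)
        wave = 1.6 * wave
    elif m.type_label == "GN":
        # polyspike-and-wave bursts: three 25 Hz spikes per ~4.5 Hz cycle
        period = 1.0 / m.oscillation_hz
        offs = (0.02, 0.06, 0.10)
        wave = 0.45 * np.sin(2 * np.pi * m.oscillation_hz * t)
        wave += 1.0 * _spike_train(t, m.oscillation_hz, 0.008, offsets_s=offs)
        del period
        env = _tukey(n, 0.15)
    elif m.type_label == "FC":
        # linear chirp 4 -> 8 Hz on the masked electrodes
        f0, f1 = m.oscillation_hz, 2.0 * m.oscillation_hz
        phase = 2 * np.pi * (f0 * t + (f1 - f0) / (2 * duration_s) * t ** 2)
        wave = np.sin(phase)
        env = _tukey(n, 0.25)
    else:  # pragma: no cover - guarded by SeizureMorphology
        raise ValueError(m.type_label)
    return m.amplitude_uv * wave * env


def _tukey(n: int, frac: float) -> np.ndarray:
    from scipy.signal.windows import tukey

    return tukey(n, alpha=2 * frac)


def inject_seizure(rec: RawRecording, morphology: SeizureMorphology,
                   onset_s: float, duration_s: float,
                   existing: Sequence[SeizureAnnotation] = (),
                   ) -> tuple[RawRecording, SeizureAnnotation]:
    """Add one ictal event to a recording; returns (new recording, annotation).

    Additive on the masked electrodes only; for IESS the event is followed by
    1 s of 50% diffuse amplitude attenuation (electrodecrement).  Overlap
    with an existing annotation is an error; unmasked channels are untouched.
    """
    fs = rec.sampling_rate_hz
    offset_s = onset_s + duration_s
    if onset_s < 0 or offset_s > rec.duration_s:
        raise ValueError("event does not fit inside the recording")
    for a in existing:
        if onset_s < a.offset_s and a.onset_s < offset_s:
            raise ValueError(
                f"event [{onset_s}, {offset_s}) overlaps annotation "
                f"[{a.onset_s}, {a.offset_s})"
            )
    i0 = int(round(onset_s * fs))
    i1 = i0 + int(round(duration_s * fs))
    wave = _ictal_waveform(morphology, duration_s, fs)

    samples = rec.samples.copy()
    index = {n: i for i, n in enumerate(rec.channel_names)}
    for e, g in zip(morphology.electrodes, morphology.gains):
        samples[index[e], i0:i1] += g * wave[: i1 - i0]
    if morphology.type_label == "IESS":
        j1 = min(i1 + int(round(1.0 * fs)), samples.shape[1])
        samples[:, i1:j1] *= 0.5
    out = RawRecording(patient_id=rec.patient_id,
                       channel_names=list(rec.channel_names),
                       sampling_rate_hz=fs, samples=samples)
    ann = SeizureAnnotation(onset_s=onset_s, offset_s=offset_s,
                            type_label=morphology.type_label)
    return out, ann


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

_DEFAULT_PATIENTS = {"normal": 10, "CAE": 5, "IESS": 2, "GN": 1, "FC": 2}
_DEFAULT_EVENTS = {"CAE": 6, "IESS": 12, "GN": 5, "FC": 2}
#: training-split mean event lengths of the study cohort (seconds)
_DEFAULT_DURATION_MEAN = {"CAE": 9.2, "IESS": 0.95, "GN": 7.95, "FC": 83.96}


@dataclasses.dataclass
class SyntheticSpec:
    """Cohort recipe.  Defaults mirror the study cohort at ~1/10 size:
    per-group patient counts proportional to 101/49/16/14/19 and the
    training-split mean event lengths per type; events per patient follow
    the per-patient event rates of the same table."""

    n_patients: dict = dataclasses.field(default_factory=lambda: dict(_DEFAULT_PATIENTS))
    recording_minutes: float = 10.0
    events_per_patient: dict = dataclasses.field(default_factory=lambda: dict(_DEFAULT_EVENTS))
    event_duration_mean_s: dict = dataclasses.field(
        default_factory=lambda: dict(_DEFAULT_DURATION_MEAN))
    event_duration_sigma: float = 0.25  # sigma of log-duration
    snr: float = 4.0                    # ictal peak amplitude / background std
    background_std_uv: float = 20.0
    sampling_rate_hz: float = 256.0
    seed: int = 0

    def __post_init__(self):
        if any(v <= 0 for v in self.n_patients.values()):
            raise ValueError("patient counts must be positive")
        if self.recording_minutes <= 0:
            raise ValueError("recording_minutes must be positive")
        if self.sampling_rate_hz < 200:
            raise ValueError("native rate must be >= the 200 Hz common rate")


@dataclasses.dataclass
class PatientRecord:
    patient_id: str
    group: str  # normal | CAE | IESS | GN | FC
    recording: RawRecording
    annotations: list[SeizureAnnotation]


@dataclasses.dataclass
class Cohort:
    spec: SyntheticSpec | None
    patients: list[PatientRecord]

    def manifest(self) -> dict:
        """Per-group bookkeeping in the negative/positive-seconds schema."""
        groups: dict[str, dict] = {}
        for g in ("normal",) + SEIZURE_TYPES:
            members = [p for p in self.patients if p.group == g]
            pos = sum(a.duration_s for p in members for a in p.annotations)
            total = sum(p.recording.duration_s for p in members)
            n_ev = sum(len(p.annotations) for p in members)
            groups[g] = {
                "n_patients": len(members),
                "negative_seconds": round(total - pos, 3),
                "positive_seconds": round(pos, 3),
                "n_events": n_ev,
                "mean_event_length_s": round(pos / n_ev, 3) if n_ev else None,
            }
        seed = self.spec.seed if self.spec is not None else None
        return {"seed": seed, "groups": groups}

    def annotations_by_patient(self) -> dict[str, list[SeizureAnnotation]]:
        return {p.patient_id: list(p.annotations) for p in self.patients}


def _sample_durations(group: str, n: int, spec: SyntheticSpec,
                      rng: np.random.Generator) -> np.ndarray:
    """Lognormal event durations with the configured mean; IESS capped at 2 s."""
    mean = spec.event_duration_mean_s[group]
    sigma = spec.event_duration_sigma
    mu = np.log(mean) - sigma ** 2 / 2.0
    d = rng.lognormal(mu, sigma, size=n)
    if group == "IESS":
        d = np.clip(d, 0.3, 2.0)
    return d


def _place_events(durations: np.ndarray, total_s: float, min_gap_s: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Random non-overlapping onsets with at least min_gap_s between events
    and to the recording edges, via random allocation of the slack."""
    n = len(durations)
    slack = total_s - durations.sum() - (n + 1) * min_gap_s
    if slack < 0:
        raise ValueError(
            f"{n} events totalling {durations.sum():.0f} s do not fit in "
            f"{total_s:.0f} s with {min_gap_s:.0f} s gaps"
        )
    cuts = np.sort(rng.uniform(0, slack, size=n))
    extra = np.concatenate([[cuts[0]], np.diff(cuts)])
    onsets = np.empty(n)
    t = min_gap_s
    for i in range(n):
        t += extra[i]
        onsets[i] = t
        t += durations[i] + min_gap_s
    return onsets


def generate_cohort(spec: SyntheticSpec,
                    out_dir: str | Path | None = None) -> Cohort:
    """Generate the full annotated cohort; optionally persist it as EDF files
    plus an annotation CSV and a manifest JSON.

    Patients are generated in a fixed group order, so the cohort is a pure
    function of the spec (seed included).
    """
    rng = np.random.default_rng(spec.seed)
    duration_s = spec.recording_minutes * 60.0
    amplitude = spec.snr * spec.background_std_uv
    patients: list[PatientRecord] = []

    for group in ("normal",) + SEIZURE_TYPES:
        for k in range(spec.n_patients.get(group, 0)):
            pid = f"{group.lower()}_{k:02d}"
            rec = generate_background(
                duration_s, spec.sampling_rate_hz, seed=rng,
                background_std_uv=spec.background_std_uv)
            rec.patient_id = pid
            anns: list[SeizureAnnotation] = []
            if group != "normal":
                n_ev = int(spec.events_per_patient[group])
                durations = _sample_durations(group, n_ev, spec, rng)
                onsets = _place_events(durations, duration_s,
                                       min_gap_s=10.0, rng=rng)
                for onset, dur in zip(onsets, durations):
                    morph = default_morphology(group, rng, amplitude_uv=amplitude)
                    rec, ann = inject_seizure(rec, morph, float(onset),
                                              float(dur), existing=anns)
                    anns.append(ann)
            patients.append(PatientRecord(pid, group, rec, anns))

    cohort = Cohort(spec=spec, patients=patients)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for p in cohort.patients:
            write_edf(p.recording, out_dir / f"{p.patient_id}.edf")
        write_annotation_csv(cohort.annotations_by_patient(),
                             out_dir / "annotations.csv")
        with open(out_dir / "manifest.json", "w") as f:
            json.dump(cohort.manifest(), f, indent=2)
    return cohort


# ---------------------------------------------------------------------------
# EDF writer
# ---------------------------------------------------------------------------

_PHYS_RANGE_UV = 8192.0  # symmetric physical range; step ~0.25 uV over 16 bits


def write_edf(rec: RawRecording, path: str | Path,
              phys_range_uv: float = _PHYS_RANGE_UV) -> None:
    """Write a standard 16-bit EDF file (1-second data records).

    The recording must have an integer number of seconds, an integer
    sampling rate, and amplitudes within ±phys_range_uv (error names the
    first offending channel).  Round-trip error through :func:`read_edf`
    is bounded by one quantization step, 2*phys_range/65535.
    """
    if rec.samples.size == 0:
        raise ValueError("cannot write an empty recording")
    fs = rec.sampling_rate_hz
    if fs != int(fs):
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(fs)
    n = rec.samples.shape[1]
    if n % fs != 0:
        raise ValueError("EDF writer requires an integer number of seconds")
    n_records = n // fs
    for name, row in zip(rec.channel_names, rec.samples):
        peak = np.max(np.abs(row))
        if peak > phys_range_uv:
            raise ValueError(
                f"channel {name!r} amplitude {peak:.1f} uV exceeds the "
                f"±{phys_range_uv:.0f} uV physical range"
            )

    ns = len(rec.channel_names)

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            raise ValueError(f"header field too long: {text!r}")
        return b.ljust(width)

    header = b"".join([
        pad("0", 8),
        pad(rec.patient_id[:80], 80),
        pad("rtseiz synthetic", 80),
        pad("01.01.20", 8),
        pad("00.00.00", 8),
        pad(str(256 * (ns + 1)), 8),
        pad("", 44),
        pad(str(n_records), 8),
        pad("1", 8),
        pad(str(ns), 4),
    ])
    fields = [
        ("".join, 16, [pad(c, 16) for c in rec.channel_names]),
        ("".join, 80, [pad("", 80)] * ns),
        ("".join, 8, [pad("uV", 8)] * ns),
        ("".join, 8, [pad(f"{-phys_range_uv:.0f}", 8)] * ns),
        ("".join, 8, [pad(f"{phys_range_uv:.0f}", 8)] * ns),
        ("".join, 8, [pad("-32768", 8)] * ns),
        ("".join, 8, [pad("32767", 8)] * ns),
        ("".join, 80, [pad("", 80)] * ns),
        ("".join, 8, [pad(str(fs), 8)] * ns),
        ("".join, 32, [pad("", 32)] * ns),
    ]
    sig_header = b"".join(b"".join(chunks) for _, _, chunks in fields)

    # physical -> digital: linear map over the full 16-bit range
    scale = (32767 - (-32768)) / (2 * phys_range_uv)
    digital = np.round((rec.samples + phys_range_uv) * scale - 32768.0)
    digital = np.clip(digital, -32768, 32767).astype("<i2")

    with open(path, "wb") as f:
        f.write(header)
        f.write(sig_header)
        for r in range(n_records):
            block = digital[:, r * fs: (r + 1) * fs]
            f.write(np.ascontiguousarray(block).tobytes())
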