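"""EEG input/output and signal conditioning.

Reads referential scalp EEG from EDF files, derives the 22-pair
longitudinal-bipolar ("double banana", with transverse pairs) montage,
resamples every recording to the common 200 Hz rate, and applies min–max
amplitude normalization whose statistics come from training data only.

Amplitudes are handled in microvolts throughout.  Annotations travel in a
CSV sidecar (columns ``patient_id, onset_s, offset_s, type_label``) rather
than embedded EDF+ events.
"""

from __future__ import annotations

import dataclasses
import json
import struct
from pathlib import Path
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

__all__ = [
    "DOUBLE_BANANA_PAIRS",
    "MONTAGE_ELECTRODES",
    "SEIZURE_TYPES",
    "CLASS_LABELS",
    "COMMON_RATE_HZ",
    "RawRecording",
    "MontageRecording",
    "SeizureAnnotation",
    "NormalizationStats",
    "canonical_label",
    "read_edf",
    "read_annotation_csv",
    "write_annotation_csv",
    "build_double_banana",
    "resample_to_common_rate",
    "fit_normalizer",
    "apply_normalizer",
    "save_recording",
    "load_recording",
]

#: Longitudinal bipolar pairs plus transverse pairs, in the fixed clinical
#: reading order; montage rows always follow this order, ending fz-cz, cz-pz.
DOUBLE_BANANA_PAIRS: tuple[str, ...] = (
    "fp1-f7", "fp2-f8", "f7-t3", "f8-t4", "t3-t5", "t4-t6", "t5-o1", "t6-o2",
    "t3-c3", "c4-t4", "c3-cz", "cz-c4", "fp1-f3", "fp2-f4", "f3-c3", "f4-c4",
    "c3-p3", "c4-p4", "p3-o1", "p4-o2", "fz-cz", "cz-pz",
)

MONTAGE_ELECTRODES: tuple[str, ...] = tuple(sorted(
    {e for pair in DOUBLE_BANANA_PAIRS for e in pair.split("-")}
))

#: The four ILAE-aligned seizure-type labels; "normal" is the fifth class of
#: the classification task, carried by recordings with no annotations.
SEIZURE_TYPES: tuple[str, ...] = ("CAE", "IESS", "GN", "FC")
CLASS_LABELS: tuple[str, ...] = ("normal",) + SEIZURE_TYPES

COMMON_RATE_HZ: float = 200.0

# Modern 10-20 names mapped onto the classical ones used by the montage.
_MODERN_ALIASES = {"t7": "t3", "t8": "t4", "p7": "t5", "p8": "t6"}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RawRecording:
    """Referential multichannel EEG: one row of microvolt samples per electrode."""

    patient_id: str
    channel_names: list[str]
    sampling_rate_hz: float
    samples: np.ndarray  # (n_channels, n_samples), microvolts

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if self.samples.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.samples.shape[0]} sample rows but "
                f"{len(self.channel_names)} channel names"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("duplicate channel names")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.sampling_rate_hz

    def channel(self, name: str) -> np.ndarray:
        return self.samples[self.channel_names.index(name)]


@dataclasses.dataclass
class MontageRecording:
    """22-pair bipolar derivation of a RawRecording."""

    patient_id: str
    pair_names: list[str]
    sampling_rate_hz: float
    samples: np.ndarray  # (22, n_samples)
    normalized: bool = False

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if tuple(self.pair_names) != DOUBLE_BANANA_PAIRS:
            raise ValueError("pair_names must be the canonical 22-pair montage order")
        if self.samples.shape[0] != len(DOUBLE_BANANA_PAIRS):
            raise ValueError("expected 22 montage rows")

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.sampling_rate_hz


@dataclasses.dataclass(frozen=True)
class SeizureAnnotation:
    """One ictal event in recording time (seconds, half-open [onset, offset))."""

    onset_s: float
    offset_s: float
    type_label: str

    def __post_init__(self):
        if self.type_label not in SEIZURE_TYPES:
            raise ValueError(f"unknown seizure type {self.type_label!r}")
        if not self.offset_s > self.onset_s:
            raise ValueError("offset must exceed onset")
        if self.onset_s < 0:
            raise ValueError("onset must be non-negative")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclasses.dataclass(frozen=True)
class NormalizationStats:
    """Per-montage-pair min/max learned from training recordings only."""

    per_channel_min: np.ndarray
    per_channel_max: np.ndarray
    source: str = ""

    def __post_init__(self):
        object.__setattr__(self, "per_channel_min",
                           np.asarray(self.per_channel_min, dtype=np.float64))
        object.__setattr__(self, "per_channel_max",
                           np.asarray(self.per_channel_max, dtype=np.float64))
        if np.any(self.per_channel_max < self.per_channel_min):
            raise ValueError("max < min in normalization stats")


# ---------------------------------------------------------------------------
# EDF reading
# ---------------------------------------------------------------------------

def canonical_label(label: str) -> str:
    """Canonicalize an EDF channel label to a bare lowercase electrode name.

    Strips an "EEG " prefix and "-Ref"/"-LE"/"-REF" reference suffixes and
    lowercases, e.g. "EEG Fp1-Ref" -> "fp1".  Modern temporal names (t7, t8,
    p7, p8) are mapped to the classical t3/t4/t5/t6 by the caller only when
    the classical name is absent.
    """
    s = label.strip().lower()
    if s.startswith("eeg "):
        s = s[4:]
    for suffix in ("-ref", "-le", "-avg"):
        if s.endswith(suffix):
            s = s[: -len(suffix)]
    return s.strip()


def read_edf(path: str | Path, patient_id: str | None = None) -> RawRecording:
    """Read an EDF file into a RawRecording (microvolts, original rate).

    Channel labels are canonicalized; every electrode the 22-pair montage
    references must be present (after alias resolution) or a ``ValueError``
    naming the missing electrode is raised.  Having both the classical and
    the modern alias of the same temporal electrode is ambiguous and is an
    error.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise IOError(f"EDF file not found: {path}")
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # mne returns volts
    names = [canonical_label(n) for n in raw.ch_names]

    # resolve modern temporal aliases, refusing ambiguity
    resolved = list(names)
    for i, n in enumerate(resolved):
        if n in _MODERN_ALIASES:
            classical = _MODERN_ALIASES[n]
            if classical in resolved:
                raise ValueError(
                    f"ambiguous channels: both {n!r} and {classical!r} present"
                )
            resolved[i] = classical

    missing = [e for e in MONTAGE_ELECTRODES if e not in resolved]
    if missing:
        raise ValueError(f"EDF {path.name} lacks required electrode(s): "
                         + ", ".join(missing))

    return RawRecording(
        patient_id=patient_id or path.stem,
        channel_names=resolved,
        sampling_rate_hz=float(raw.info["sfreq"]),
        samples=data_uv,
    )


def read_annotation_csv(path: str | Path) -> dict[str, list[SeizureAnnotation]]:
    """Read the annotation sidecar; returns patient_id -> sorted annotations."""
    df = pd.read_csv(path)
    required = {"patient_id", "onset_s", "offset_s", "type_label"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation CSV needs columns {sorted(required)}")
    out: dict[str, list[SeizureAnnotation]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.patient_id), []).append(
            SeizureAnnotation(float(row.onset_s), float(row.offset_s),
                              str(row.type_label))
        )
    for anns in out.values():
        anns.sort(key=lambda a: a.onset_s)
    return out


def write_annotation_csv(annotations: dict[str, list[SeizureAnnotation]],
                         path: str | Path) -> None:
    rows = [
        {"patient_id": pid, "onset_s": a.onset_s, "offset_s": a.offset_s,
         "type_label": a.type_label}
        for pid, anns in annotations.items() for a in anns
    ]
    pd.DataFrame(rows, columns=["patient_id", "onset_s", "offset_s",
                                "type_label"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Montage, resampling, normalization
# ---------------------------------------------------------------------------

def build_double_banana(raw: RawRecording) -> MontageRecording:
    """Derive the 22 bipolar pairs: row i = first electrode − second electrode."""
    index = {n: i for i, n in enumerate(raw.channel_names)}
    rows = np.empty((len(DOUBLE_BANANA_PAIRS), raw.samples.shape[1]))
    for i, pair in enumerate(DOUBLE_BANANA_PAIRS):
        a, b = pair.split("-")
        for e in (a, b):
            if e not in index:
                raise ValueError(f"pair {pair!r}: electrode {e!r} missing")
        rows[i] = raw.samples[index[a]] - raw.samples[index[b]]
    return MontageRecording(
        patient_id=raw.patient_id,
        pair_names=list(DOUBLE_BANANA_PAIRS),
        sampling_rate_hz=raw.sampling_rate_hz,
        samples=rows,
    )


def resample_to_common_rate(rec: MontageRecording,
                            target_hz: float = COMMON_RATE_HZ) -> MontageRecording:
    """Polyphase-resample to the common rate (default 200 Hz, the cohort's
    lowest recorded frequency).  Upsampling is out of scope and an error.
    The polyphase filter is zero-phase, so event times are not shifted.
    """
    if rec.sampling_rate_hz < target_hz:
        raise ValueError(
            f"cannot upsample {rec.sampling_rate_hz} Hz to {target_hz} Hz"
        )
    if rec.sampling_rate_hz == target_hz:
        return rec
    frac = Fraction(target_hz / rec.sampling_rate_hz).limit_denominator(1000)
    out = resample_poly(rec.samples, frac.numerator, frac.denominator, axis=1)
    return MontageRecording(
        patient_id=rec.patient_id,
        pair_names=list(rec.pair_names),
        sampling_rate_hz=target_hz,
        samples=out,
        normalized=rec.normalized,
    )


def fit_normalizer(training_recs: Iterable[MontageRecording],
                   per_channel: bool = True,
                   source: str = "") -> NormalizationStats:
    """Per-pair (or, with per_channel=False, global scalar) min/max over the
    concatenation of all training recordings."""
    recs = list(training_recs)
    if not recs:
        raise ValueError("empty training collection")
    for r in recs:
        if r.normalized:
            raise ValueError("normalizer must be fit on unnormalized recordings")
    mins = np.min([r.samples.min(axis=1) for r in recs], axis=0)
    maxs = np.max([r.samples.max(axis=1) for r in recs], axis=0)
    if not per_channel:
        mins = np.full_like(mins, mins.min())
        maxs = np.full_like(maxs, maxs.max())
    return NormalizationStats(mins, maxs, source=source)


def apply_normalizer(rec: MontageRecording,
                     stats: NormalizationStats) -> MontageRecording:
    """Map each pair by x -> (x - min) / (max - min).

    Constant (max == min) channels map to zeros.  Values outside the training
    range are NOT clipped: test-set excursions fall outside [0, 1] and keep
    their rank information.
    """
    if rec.normalized:
        raise ValueError("recording already normalized")
    span = stats.per_channel_max - stats.per_channel_min
    safe = np.where(span > 0, span, 1.0)
    out = (rec.samples - stats.per_channel_min[:, None]) / safe[:, None]
    out[span == 0, :] = 0.0
    return MontageRecording(
        patient_id=rec.patient_id,
        pair_names=list(rec.pair_names),
        sampling_rate_hz=rec.sampling_rate_hz,
        samples=out,
        normalized=True,
    )


# ---------------------------------------------------------------------------
# Cache container: channel-major float32 payload behind a JSON header
# ---------------------------------------------------------------------------

_MAGIC = b"RTSZREC1"


def save_recording(rec: MontageRecording, path: str | Path) -> None:
    header = {
        "patient_id": rec.patient_id,
        "pair_names": list(rec.pair_names),
        "sampling_rate_hz": rec.sampling_rate_hz,
        "normalized": rec.normalized,
        "shape": list(rec.samples.shape),
    }
    blob = json.dumps(header).encode()
    with open(path, "wb") as f:
        f.write(_MAGIC)
        f.write(struct.pack("<I", len(blob)))
        f.write(blob)
        f.write(np.ascontiguousarray(rec.samples, dtype=np.float32).tobytes())


def load_recording(path: str | Path) -> MontageRecording:
    with open(path, "rb") as f:
        if f.read(8) != _MAGIC:
            raise IOError(f"{path}: not a recording cache file")
        (hlen,) = struct.unpack("<I", f.read(4))
        header = json.loads(f.read(hlen).decode())
        data = np.frombuffer(f.read(), dtype=np.float32)
    samples = data.reshape(header["shape"]).astype(np.float64)
    return MontageRecording(
        patient_id=header["patient_id"],
        pair_names=header["pair_names"],
        sampling_rate_hz=header["sampling_rate_hz"],
        samples=samples,
        normalized=header["normalized"],
    )
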