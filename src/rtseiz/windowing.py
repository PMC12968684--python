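"""Windowing: from annotated recordings to model-ready segments.

Stage 1 (real-time detection) consumes non-overlapping 30 s chunks tiled
from "context" segments — each seizure bracketed by up to one hour of
surrounding non-seizure signal — with trailing remainders under 30 s
dropped, per-second binary labels, 10:1 negative subsampling on the
training stream, and sliding windows (4 s or 12 s, 1 s shift) within each
chunk.  Stage 2 (classification) consumes one clip per seizure: up to 30 s
pre-ictal, the first 120 s of the event, and up to 5 s post-ictal.

Time convention: seconds from recording start, half-open intervals
[onset, offset).  Chunk tiling is anchored at the segment start.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .eeg_io import MontageRecording, SeizureAnnotation

__all__ = [
    "CHUNK_LEN_S",
    "Segment",
    "DetectionChunk",
    "SlidingWindow",
    "ClassificationClip",
    "extract_context",
    "chunk_detection",
    "sample_negatives",
    "slide",
    "label_window",
    "build_classification_clip",
    "build_normal_clips",
    "chunk_manifest",
]

CHUNK_LEN_S = 30
MAX_PRE_ICTAL_S = 30.0
MAX_ICTAL_S = 120.0
MAX_POST_ICTAL_S = 5.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Segment:
    """A context-extracted span of a recording, with annotations re-based to
    segment-local time and the absolute start kept for audit."""

    recording: MontageRecording
    start_s: float
    annotations: list[SeizureAnnotation]


@dataclasses.dataclass
class DetectionChunk:
    """One non-overlapping 30 s detection interval with per-second labels."""

    patient_id: str
    start_s: float  # absolute recording time
    end_s: float
    samples: np.ndarray  # (22, 30 * fs)
    sampling_rate_hz: float
    per_second_labels: np.ndarray  # (30,) of {0,1}

    def __post_init__(self):
        self.per_second_labels = np.asarray(self.per_second_labels, dtype=np.int8)
        if self.per_second_labels.shape != (CHUNK_LEN_S,):
            raise ValueError("per_second_labels must have length 30")
        if abs((self.end_s - self.start_s) - CHUNK_LEN_S) > 1e-9:
            raise ValueError("chunk duration must be exactly 30 s")
        expected = int(round(CHUNK_LEN_S * self.sampling_rate_hz))
        if self.samples.shape[1] != expected:
            raise ValueError(
                f"chunk has {self.samples.shape[1]} samples, expected {expected}")

    @property
    def contains_seizure(self) -> bool:
        return bool(self.per_second_labels.any())


@dataclasses.dataclass
class SlidingWindow:
    """A window_len_s excerpt of a chunk, advanced by the shift."""

    patient_id: str
    chunk_start_s: float
    offset_s: int  # start offset within the chunk, seconds
    window_len_s: int
    samples: np.ndarray  # (22, window_len_s * fs)
    label: int  # {0,1}


@dataclasses.dataclass
class ClassificationClip:
    """Stage-2 input: [pre-ictal | ictal (<=120 s) | post-ictal] signal.

    Normal-class clips carry no ictal content: their whole duration is
    booked as pre_ictal_s and the pre-ictal bound does not apply to them.
    """

    patient_id: str
    samples: np.ndarray  # (22, T)
    sampling_rate_hz: float
    pre_ictal_s: float
    ictal_s: float
    post_ictal_s: float
    type_label: str  # normal | CAE | IESS | GN | FC
    start_s: float | None = None  # clip onset in recording time, for audit

    def __post_init__(self):
        if self.type_label != "normal":
            if not self.ictal_s > 0:
                raise ValueError("seizure clip must have positive ictal span")
            if self.pre_ictal_s > MAX_PRE_ICTAL_S + 1e-9:
                raise ValueError("pre-ictal span exceeds 30 s")
            if self.ictal_s > MAX_ICTAL_S + 1e-9:
                raise ValueError("ictal span exceeds 120 s")
            if self.post_ictal_s > MAX_POST_ICTAL_S + 1e-9:
                raise ValueError("post-ictal span exceeds 5 s")
        total = self.pre_ictal_s + self.ictal_s + self.post_ictal_s
        if abs(self.samples.shape[1] / self.sampling_rate_hz - total) > \
                1.5 / self.sampling_rate_hz:
            raise ValueError("clip sample count inconsistent with durations")

    @property
    def duration_s(self) -> float:
        return self.pre_ictal_s + self.ictal_s + self.post_ictal_s


# ---------------------------------------------------------------------------
# Context extraction and chunking
# ---------------------------------------------------------------------------

def extract_context(rec: MontageRecording,
                    annotations: Sequence[SeizureAnnotation],
                    flank_s: float = 3600.0) -> list[Segment]:
    """Bracket each seizure with up to ``flank_s`` of non-seizure signal on
    either side, merging overlapping brackets; returns one Segment per
    merged interval with annotations re-based to segment time."""
    dur = rec.duration_s
    anns = sorted(annotations, key=lambda a: a.onset_s)
    for a in anns:
        if a.onset_s < 0 or a.offset_s > dur + 1e-9:
            raise ValueError(
                f"annotation [{a.onset_s}, {a.offset_s}) outside recording "
                f"of {dur:.1f} s")
    if not anns:
        return []
    intervals = [(max(0.0, a.onset_s - flank_s), min(dur, a.offset_s + flank_s))
                 for a in anns]
    merged = [list(intervals[0])]
    for lo, hi in intervals[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])

    fs = rec.sampling_rate_hz
    segments = []
    for lo, hi in merged:
        i0, i1 = int(round(lo * fs)), int(round(hi * fs))
        local = [SeizureAnnotation(a.onset_s - lo, a.offset_s - lo, a.type_label)
                 for a in anns if lo <= a.onset_s and a.offset_s <= hi + 1e-9]
        seg_rec = MontageRecording(
            patient_id=rec.patient_id, pair_names=list(rec.pair_names),
            sampling_rate_hz=fs, samples=rec.samples[:, i0:i1],
            normalized=rec.normalized)
        segments.append(Segment(recording=seg_rec, start_s=lo, annotations=local))
    return segments


def _second_labels(start_s: float, annotations: Sequence[SeizureAnnotation]
                   ) -> np.ndarray:
    """Per-second labels for the 30 seconds beginning at start_s (segment
    time): second k is 1 iff [start+k, start+k+1) overlaps any annotation."""
    labels = np.zeros(CHUNK_LEN_S, dtype=np.int8)
    for a in annotations:
        lo = max(0, int(np.floor(a.onset_s - start_s)))
        hi = min(CHUNK_LEN_S, int(np.ceil(a.offset_s - start_s)))
        if hi > lo:
            labels[lo:hi] = 1
    return labels


def chunk_detection(segment: Segment) -> list[DetectionChunk]:
    """Tile consecutive 30 s chunks from the segment start; a trailing
    remainder shorter than 30 s is excluded."""
    rec = segment.recording
    fs = rec.sampling_rate_hz
    n_chunks = int(rec.samples.shape[1] // (CHUNK_LEN_S * fs))
    chunks = []
    step = int(round(CHUNK_LEN_S * fs))
    for k in range(n_chunks):
        local_start = k * CHUNK_LEN_S
        chunks.append(DetectionChunk(
            patient_id=rec.patient_id,
            start_s=segment.start_s + local_start,
            end_s=segment.start_s + local_start + CHUNK_LEN_S,
            samples=rec.samples[:, k * step: (k + 1) * step],
            sampling_rate_hz=fs,
            per_second_labels=_second_labels(local_start, segment.annotations),
        ))
    return chunks


def sample_negatives(chunks: Sequence[DetectionChunk], ratio: int = 10,
                     seed: int = 0) -> list[DetectionChunk]:
    """Keep every seizure chunk; subsample non-seizure chunks without
    replacement to at most ``ratio`` per positive.  Training streams only —
    evaluation uses the full stream so metrics see the true imbalance."""
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    positives = [c for c in chunks if c.contains_seizure]
    negatives = [c for c in chunks if not c.contains_seizure]
    cap = ratio * len(positives)
    if len(negatives) > cap:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(negatives), size=cap, replace=False))
        negatives = [negatives[i] for i in idx]
    kept = positives + negatives
    kept.sort(key=lambda c: (c.patient_id, c.start_s))
    return kept


# ---------------------------------------------------------------------------
# Sliding windows
# ---------------------------------------------------------------------------

def label_window(offset_s: int, window_len_s: int,
                 per_second_labels: np.ndarray,
                 min_fraction: float | None = None) -> int:
    """Window label from the chunk's per-second labels.

    Default (any-overlap): 1 iff any second of the window is ictal —
    favouring sensitivity.  With ``min_fraction``, 1 iff at least that
    fraction of the window's seconds is ictal.
    """
    if offset_s < 0 or offset_s + window_len_s > len(per_second_labels):
        raise ValueError("window extends outside its chunk")
    ictal = int(per_second_labels[offset_s: offset_s + window_len_s].sum())
    if min_fraction is None:
        return int(ictal > 0)
    return int(ictal / window_len_s >= min_fraction)


def slide(chunk: DetectionChunk, window_len_s: int, shift_s: int = 1,
          min_fraction: float | None = None) -> list[SlidingWindow]:
    """Ordered sliding windows of a chunk; count = (30 - len)/shift + 1."""
    if window_len_s > CHUNK_LEN_S:
        raise ValueError("window longer than the 30 s chunk")
    fs = chunk.sampling_rate_hz
    wlen = int(round(window_len_s * fs))
    windows = []
    for off in range(0, CHUNK_LEN_S - window_len_s + 1, shift_s):
        i0 = int(round(off * fs))
        windows.append(SlidingWindow(
            patient_id=chunk.patient_id,
            chunk_start_s=chunk.start_s,
            offset_s=off,
            window_len_s=window_len_s,
            samples=chunk.samples[:, i0: i0 + wlen],
            label=label_window(off, window_len_s, chunk.per_second_labels,
                               min_fraction),
        ))
    return windows


# ---------------------------------------------------------------------------
# Classification clips
# ---------------------------------------------------------------------------

def build_classification_clip(rec: MontageRecording, ann: SeizureAnnotation,
                              prev_boundary_s: float = 0.0) -> ClassificationClip:
    """One Stage-2 clip for a seizure: up to 30 s pre-ictal (truncated at the
    previous seizure's offset or recording start), the first 120 s of the
    event, and up to 5 s post-ictal (truncated at recording end)."""
    dur = rec.duration_s
    if ann.onset_s < 0 or ann.offset_s > dur + 1e-9:
        raise ValueError("annotation outside recording")
    pre = min(MAX_PRE_ICTAL_S, max(0.0, ann.onset_s - prev_boundary_s))
    ictal = min(ann.duration_s, MAX_ICTAL_S)
    ictal_end = ann.onset_s + ictal
    post = min(MAX_POST_ICTAL_S, max(0.0, dur - ictal_end))
    fs = rec.sampling_rate_hz
    i0 = int(round((ann.onset_s - pre) * fs))
    i1 = int(round((ictal_end + post) * fs))
    return ClassificationClip(
        patient_id=rec.patient_id,
        samples=rec.samples[:, i0:i1],
        sampling_rate_hz=fs,
        pre_ictal_s=pre, ictal_s=ictal, post_ictal_s=post,
        type_label=ann.type_label,
        start_s=ann.onset_s - pre,
    )


def build_normal_clips(rec: MontageRecording, n_per_patient: int,
                       clip_duration_s: float = 60.0,
                       seed: int = 0) -> list[ClassificationClip]:
    """Randomly placed clips from a seizure-free recording, labeled normal.

    Placements are uniform over the valid onset range and reproducible
    under the seed; clips may overlap one another.
    """
    dur = rec.duration_s
    if dur < clip_duration_s:
        raise ValueError(
            f"recording of {dur:.0f} s shorter than clip ({clip_duration_s:.0f} s)")
    rng = np.random.default_rng(seed)
    fs = rec.sampling_rate_hz
    wlen = int(round(clip_duration_s * fs))
    clips = []
    for start in rng.uniform(0.0, dur - clip_duration_s, size=n_per_patient):
        i0 = int(round(start * fs))
        clips.append(ClassificationClip(
            patient_id=rec.patient_id,
            samples=rec.samples[:, i0: i0 + wlen],
            sampling_rate_hz=fs,
            pre_ictal_s=wlen / fs, ictal_s=0.0, post_ictal_s=0.0,
            type_label="normal",
            start_s=float(start),
        ))
    return clips


# ---------------------------------------------------------------------------
# Audit manifest
# ---------------------------------------------------------------------------

def chunk_manifest(chunks: Sequence[DetectionChunk],
                   split: str = "") -> pd.DataFrame:
    """Flat CSV-ready manifest (patient, span, label, split) for audit."""
    return pd.DataFrame([
        {"patient_id": c.patient_id, "start_s": c.start_s, "end_s": c.end_s,
         "label": int(c.contains_seizure), "split": split}
        for c in chunks
    ], columns=["patient_id", "start_s", "end_s", "label", "split"])
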