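"""Chunking, sliding windows, negative sampling and clip construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rtseiz.eeg_io import DOUBLE_BANANA_PAIRS, MontageRecording, \
    SeizureAnnotation
from rtseiz.windowing import (ClassificationClip, Segment,
                              build_classification_clip, build_normal_clips,
                              chunk_detection, extract_context, label_window,
                              sample_negatives, slide)

FS = 200.0


def _montage(duration_s, seed=0, normalized=True):
    rng = np.random.default_rng(seed)
    return MontageRecording(
        patient_id="p", pair_names=list(DOUBLE_BANANA_PAIRS),
        sampling_rate_hz=FS,
        samples=rng.normal(size=(22, int(duration_s * FS))),
        normalized=normalized)


def _segment(duration_s, anns=(), seed=0, start=0.0):
    return Segment(_montage(duration_s, seed), start, list(anns))


def _chunks(duration_s, anns=(), seed=0):
    return chunk_detection(_segment(duration_s, anns, seed))


# ---------------------------------------------------------------------------
# Context extraction
# ---------------------------------------------------------------------------

def test_context_basic_interval():
    rec = _montage(3 * 3600.0)
    segs = extract_context(rec, [SeizureAnnotation(5400, 5410, "CAE")])
    assert len(segs) == 1
    assert segs[0].start_s == 1800.0
    assert segs[0].recording.duration_s == pytest.approx(9010 - 1800)
    assert segs[0].annotations[0].onset_s == pytest.approx(3600.0)


def test_context_merges_nearby_seizures():
    rec = _montage(3 * 3600.0)
    anns = [SeizureAnnotation(4000, 4010, "CAE"),
            SeizureAnnotation(4610, 4620, "CAE")]  # 10 min apart
    segs = extract_context(rec, anns)
    assert len(segs) == 1
    assert len(segs[0].annotations) == 2


def test_context_outside_recording_error():
    rec = _montage(100.0)
    with pytest.raises(ValueError):
        extract_context(rec, [SeizureAnnotation(90, 120, "FC")])


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.floats(0, 500), st.floats(0.5, 30)),
                min_size=1, max_size=6),
       st.floats(20, 120))
def test_context_equals_interval_union_oracle(events, flank):
    """Merged segments equal the brute-force union of flanked intervals."""
    dur = 600.0
    anns = sorted((SeizureAnnotation(o, min(o + d, dur), "GN")
                   for o, d in events if o + 0.5 <= dur),
                  key=lambda a: a.onset_s)
    if not anns:
        return
    rec = _montage(dur, seed=1)
    segs = extract_context(rec, anns, flank_s=flank)

    # oracle: mark covered seconds on a fine grid
    grid = np.zeros(int(dur * 10) + 1, bool)
    for a in anns:
        lo = max(0.0, a.onset_s - flank)
        hi = min(dur, a.offset_s + flank)
        grid[int(lo * 10): int(hi * 10) + 1] = True
    covered = grid.sum() / 10.0
    total = sum(s.recording.duration_s for s in segs)
    assert total == pytest.approx(covered, abs=0.5)
    starts = [s.start_s for s in segs]
    assert starts == sorted(starts)


# ---------------------------------------------------------------------------
# Chunking
# ---------------------------------------------------------------------------

def test_chunk_counts():
    assert len(_chunks(95.0)) == 3   # 5 s remainder dropped
    assert len(_chunks(29.0)) == 0   # shorter than 30 s excluded
    assert len(_chunks(30.0)) == 1


def test_chunk_per_second_labels_from_overlap():
    chunks = _chunks(90.0, [SeizureAnnotation(40, 48, "CAE")])
    labels = chunks[1].per_second_labels
    expected = np.zeros(30, int)
    expected[10:18] = 1
    assert np.array_equal(labels, expected)
    assert chunks[1].contains_seizure and not chunks[0].contains_seizure


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.floats(30, 400))
def test_chunking_is_partition(duration):
    """Chunks are disjoint, ordered, and union + remainder = segment."""
    seg = _segment(duration)
    chunks = chunk_detection(seg)
    assert len(chunks) == int(duration // 30)
    for i, c in enumerate(chunks):
        assert c.start_s == pytest.approx(i * 30.0)
        assert c.end_s == pytest.approx(i * 30.0 + 30.0)
    n_used = sum(c.samples.shape[1] for c in chunks)
    remainder = seg.recording.samples.shape[1] - n_used
    assert 0 <= remainder < 30 * FS
    if chunks:
        reassembled = np.concatenate([c.samples for c in chunks], axis=1)
        assert np.array_equal(reassembled,
                              seg.recording.samples[:, :n_used])


# ---------------------------------------------------------------------------
# Negative sampling
# ---------------------------------------------------------------------------

def _labeled_chunks(n_pos, n_neg, seed=0):
    chunks = _chunks(30.0 * (n_pos + n_neg), seed=seed)
    for i, c in enumerate(chunks):
        c.per_second_labels[:] = 1 if i < n_pos else 0
    return chunks


def test_negative_sampling_cap():
    kept = sample_negatives(_labeled_chunks(2, 50), ratio=10, seed=0)
    assert sum(c.contains_seizure for c in kept) == 2
    assert sum(not c.contains_seizure for c in kept) == 20


def test_negative_sampling_cap_not_binding():
    kept = sample_negatives(_labeled_chunks(1, 5), ratio=10, seed=0)
    assert len(kept) == 6


def test_negative_sampling_reproducible_and_seed_sensitive():
    chunks = _labeled_chunks(1, 40)
    a = sample_negatives(chunks, ratio=10, seed=3)
    b = sample_negatives(chunks, ratio=10, seed=3)
    assert [c.start_s for c in a] == [c.start_s for c in b]
    # probability two seeds pick identical 10-of-40 subsets is 1/C(40,10)
    # ~= 1.2e-9; across 20 seeds a collision is effectively impossible
    picks = {tuple(c.start_s for c in sample_negatives(chunks, 10, seed=s))
             for s in range(20)}
    assert len(picks) == 20


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(0, 5), st.integers(0, 60), st.integers(1, 12),
       st.integers(0, 2 ** 31 - 1))
def test_negative_sampling_invariants(n_pos, n_neg, ratio, seed):
    """Positives always survive; negatives never exceed ratio * positives."""
    chunks = _labeled_chunks(n_pos, n_neg, seed=1)
    kept = sample_negatives(chunks, ratio=ratio, seed=seed)
    pos_in = {c.start_s for c in chunks if c.contains_seizure}
    pos_out = {c.start_s for c in kept if c.contains_seizure}
    assert pos_in == pos_out
    assert sum(not c.contains_seizure for c in kept) == min(n_neg,
                                                            ratio * n_pos)


# ---------------------------------------------------------------------------
# Sliding windows
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("window,expected", [(4, 27), (12, 19)])
def test_window_counts(window, expected):
    chunk = _chunks(30.0)[0]
    wins = slide(chunk, window)
    assert len(wins) == expected
    assert [w.offset_s for w in wins] == list(range(expected))
    assert all(w.samples.shape == (22, window * 200) for w in wins)


def test_window_labeling_any_overlap_vs_min_fraction():
    labels = np.zeros(30, int)
    labels[10] = 1  # a single ictal second
    assert label_window(0, 12, labels) == 1          # any-overlap
    assert label_window(0, 12, labels, min_fraction=0.25) == 0
    labels[8:20] = 1
    assert label_window(8, 12, labels) == 1
    assert label_window(20, 4, labels) == 0


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 32 - 1), st.sampled_from([4, 12]))
def test_window_labels_match_enumeration_oracle(seed, window):
    rng = np.random.default_rng(seed)
    labels = (rng.random(30) < 0.3).astype(np.int8)
    chunk = _chunks(30.0)[0]
    chunk.per_second_labels = labels
    for frac in (None, 0.25, 0.5):
        wins = slide(chunk, window, min_fraction=frac)
        for w in wins:
            overlap = labels[w.offset_s: w.offset_s + window].sum()
            expected = (overlap > 0) if frac is None \
                else (overlap / window >= frac)
            assert w.label == int(expected)


# ---------------------------------------------------------------------------
# Classification clips
# ---------------------------------------------------------------------------

def test_clip_printed_rule():
    rec = _montage(300.0)
    clip = build_classification_clip(rec, SeizureAnnotation(100, 120, "GN"))
    assert (clip.pre_ictal_s, clip.ictal_s, clip.post_ictal_s) == (30, 20, 5)
    assert clip.samples.shape[1] == 55 * 200


def test_clip_truncations():
    rec = _montage(500.0)
    early = build_classification_clip(rec, SeizureAnnotation(10, 30, "FC"))
    assert early.pre_ictal_s == 10.0  # maximum possible pre-ictal collected
    long = build_classification_clip(rec, SeizureAnnotation(50, 350, "FC"))
    assert long.ictal_s == 120.0      # confined to initial 120 s
    prev = build_classification_clip(rec, SeizureAnnotation(100, 110, "CAE"),
                                     prev_boundary_s=95.0)
    assert prev.pre_ictal_s == 5.0
    at_boundary = build_classification_clip(
        rec, SeizureAnnotation(100, 110, "CAE"), prev_boundary_s=100.0)
    assert at_boundary.pre_ictal_s == 0.0


@settings(max_examples=250, deadline=None, derandomize=True)
@given(st.floats(0, 550), st.floats(0.5, 400), st.floats(0, 550))
def test_clip_duration_bounds_random_layouts(onset, dur, prev):
    rec = _montage(600.0, seed=2)
    offset = min(onset + dur, 600.0)
    if offset <= onset:
        return
    clip = build_classification_clip(
        rec, SeizureAnnotation(onset, offset, "FC"), prev_boundary_s=prev)
    assert 0 <= clip.pre_ictal_s <= 30.0
    assert 0 < clip.ictal_s <= 120.0
    assert 0 <= clip.post_ictal_s <= 5.0
    assert clip.samples.shape[1] == pytest.approx(
        clip.duration_s * FS, abs=1.5)


def test_normal_clips_basic_and_seeded():
    rec = _montage(600.0)
    clips = build_normal_clips(rec, 3, clip_duration_s=60.0, seed=9)
    assert len(clips) == 3
    assert all(c.type_label == "normal" for c in clips)
    assert all(c.samples.shape[1] == 60 * 200 for c in clips)
    again = build_normal_clips(rec, 3, clip_duration_s=60.0, seed=9)
    assert all(np.array_equal(a.samples, b.samples)
               for a, b in zip(clips, again))
    with pytest.raises(ValueError):
        build_normal_clips(_montage(30.0), 1, clip_duration_s=60.0)


def test_normal_clip_placement_uniform():
    """Placement start times pass a KS test against uniform at alpha=0.01."""
    from scipy.stats import kstest
    rec = _montage(600.0, seed=3)
    clips = build_normal_clips(rec, 10000, clip_duration_s=60.0, seed=11)
    starts = np.array([c.start_s for c in clips])
    assert (starts >= 0).all() and (starts <= 540.0).all()
    assert kstest(starts / 540.0, "uniform").pvalue > 0.01
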