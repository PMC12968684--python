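"""Feature extraction: raw signal passthrough or frequency-band averages.

The band extractor averages short-time spectral magnitude over seven fixed
ranges — 1–4, 4–8, 8–12, 12–30, 30–50, 50–70 and 70–100 Hz — per channel
and per frame (Hann window, 1 s frames, 0.5 s hop by default; magnitude
rather than power, with a power option).  Bin membership is half-open
[lo, hi) so every DFT bin belongs to exactly one band.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "DEFAULT_BAND_EDGES_HZ",
    "BandDefinition",
    "FeatureTensor",
    "raw_passthrough",
    "frequency_bands",
]

DEFAULT_BAND_EDGES_HZ: tuple[tuple[float, float], ...] = (
    (1, 4), (4, 8), (8, 12), (12, 30), (30, 50), (50, 70), (70, 100),
)


@dataclasses.dataclass(frozen=True)
class BandDefinition:
    edges_hz: tuple[tuple[float, float], ...] = DEFAULT_BAND_EDGES_HZ

    def __post_init__(self):
        for lo, hi in self.edges_hz:
            if not hi > lo >= 0:
                raise ValueError(f"bad band ({lo}, {hi})")

    @property
    def n_bands(self) -> int:
        return len(self.edges_hz)


@dataclasses.dataclass
class FeatureTensor:
    """Model input.  ``data`` is (channels, samples) for raw, or
    (channels, frames, n_bands) for the band extractor."""

    data: np.ndarray
    extractor_tag: str  # "raw" | "frequency_bands"

    def __post_init__(self):
        if self.extractor_tag == "raw" and self.data.ndim != 2:
            raise ValueError("raw features must be (channels, samples)")
        if self.extractor_tag == "frequency_bands" and self.data.ndim != 3:
            raise ValueError("band features must be (channels, frames, bands)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


def raw_passthrough(window_samples: np.ndarray, n_channels: int = 22
                    ) -> FeatureTensor:
    """Identity wrap of a (22, T) window."""
    x = np.asarray(window_samples, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] != n_channels:
        raise ValueError(f"expected ({n_channels}, T) window, got {x.shape}")
    return FeatureTensor(data=x, extractor_tag="raw")


def frequency_bands(window_samples: np.ndarray,
                    bands: BandDefinition = BandDefinition(),
                    frame_len_s: float = 1.0,
                    hop_s: float = 0.5,
                    sampling_rate_hz: float = 200.0,
                    power: bool = False) -> FeatureTensor:
    """Per-channel, per-frame mean spectral magnitude in each band.

    Frames are Hann-windowed; the DFT bin at frequency f contributes to the
    band whose [lo, hi) contains f.  Output is (channels, frames, n_bands).
    """
    x = np.asarray(window_samples, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("expected (channels, T) window")
    nyquist = sampling_rate_hz / 2.0
    for lo, hi in bands.edges_hz:
        if hi > nyquist:
            raise ValueError(f"band edge {hi} Hz above Nyquist {nyquist} Hz")
    frame = int(round(frame_len_s * sampling_rate_hz))
    hop = int(round(hop_s * sampling_rate_hz))
    if x.shape[1] < frame:
        raise ValueError("window shorter than one frame")
    n_frames = (x.shape[1] - frame) // hop + 1
    taper = np.hanning(frame)
    freqs = np.fft.rfftfreq(frame, d=1.0 / sampling_rate_hz)
    masks = [(freqs >= lo) & (freqs < hi) for lo, hi in bands.edges_hz]
    for (lo, hi), m in zip(bands.edges_hz, masks):
        if not m.any():
            raise ValueError(f"band ({lo}, {hi}) Hz contains no DFT bins "
                             f"at frame length {frame}")

    out = np.empty((x.shape[0], n_frames, bands.n_bands))
    for j in range(n_frames):
        seg = x[:, j * hop: j * hop + frame] * taper
        mag = np.abs(np.fft.rfft(seg, axis=1))
        if power:
            mag = mag ** 2
        for b, m in enumerate(masks):
            out[:, j, b] = mag[:, m].mean(axis=1)
    return FeatureTensor(data=out, extractor_tag="frequency_bands")
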