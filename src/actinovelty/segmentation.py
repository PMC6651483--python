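"""Fragmentation of synchronized recordings into 8-second windows.

Each recording is divided into non-overlapping 8 s windows (80 samples at
10 Hz); the first 6 s (60 samples) are the forecaster input, the last 2 s
(20 samples) the prediction target.  Each window carries its movement
intensity, measured as the sample standard deviation of the pooled data
from all four sensors over the whole window, and is assigned to a
half-open intensity bin in g units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import SynchronizedRecording


class SegmentationError(ValueError):
    pass


@dataclass
class IntensityBins:
    """Half-open intensity intervals ``[lo, hi)`` of combined SD in g."""

    edges: tuple = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0, np.inf)

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if e.ndim != 1 or e.size < 2 or not np.all(np.diff(e) > 0):
            raise SegmentationError("bin edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def labels(self) -> list:
        return [
            f"[{self.edges[i]:g}, {self.edges[i + 1]:g})" for i in range(self.n_bins)
        ]

    def indices_in_band(self, band: tuple) -> list:
        """Bins wholly contained in the closed-open interval ``band``."""
        lo, hi = band
        return [
            i
            for i in range(self.n_bins)
            if self.edges[i] >= lo and self.edges[i + 1] <= hi
        ]


@dataclass
class WindowPair:
    """One 8 s fragment: 6 s input ``x`` (60x4) and 2 s target ``y`` (20x4)."""

    participant_id: str
    window_index: int
    x: np.ndarray
    y: np.ndarray
    intensity_sd: float


def combined_sd(window: np.ndarray | WindowPair) -> float:
    """Sample SD (ddof=1) of all pooled values in an 8 s window.

    Pools the 80 samples x 4 channels into one flat sample of 320 values,
    the literal 'combined data from all 4 sensors in the fragment'.
    """
    if isinstance(window, WindowPair):
        window = np.vstack([window.x, window.y])
    return float(np.std(window, ddof=1))


def assign_bin(sd: float, bins: IntensityBins) -> int:
    """Index of the half-open bin ``[lo, hi)`` containing ``sd``."""
    if sd < bins.edges[0]:
        raise SegmentationError(f"intensity {sd} below the lowest bin edge")
    idx = int(np.searchsorted(bins.edges, sd, side="right")) - 1
    if idx >= bins.n_bins:
        raise SegmentationError(f"intensity {sd} above the highest bin edge")
    return idx


def segment_windows(
    recording: SynchronizedRecording,
    window_s: float = 8.0,
    input_s: float = 6.0,
) -> list:
    """Split a recording into non-overlapping input/target window pairs.

    Yields ``floor(L / 80)`` windows in temporal order; the trailing
    remainder shorter than one window is discarded.
    """
    rate = recording.rate_hz
    w = int(round(window_s * rate))
    n_in = int(round(input_s * rate))
    if not (0 < n_in < w):
        raise SegmentationError("input duration must be positive and below window")
    data = recording.data
    n_windows = data.shape[0] // w
    pairs = []
    for j in range(n_windows):
        block = data[j * w : (j + 1) * w]
        pairs.append(
            WindowPair(
                participant_id=recording.participant_id,
                window_index=j,
                x=block[:n_in],
                y=block[n_in:],
                intensity_sd=float(np.std(block, ddof=1)),
            )
        )
    return pairs
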