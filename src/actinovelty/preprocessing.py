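"""Orientation-invariant preprocessing of raw tri-axial accelerometer streams.

Wearable accelerometers record in a sensor-anchored frame that rotates with
the limb, so raw axes are not comparable across sensors or over time.  The
pipeline implemented here recovers an orientation-invariant scalar signal per
sensor:

1. estimate the gravity vector in the sensor frame with a centred
   moving-average low-pass filter (gravity is the dominant DC component,
   voluntary movement lives above ~0.5 Hz);
2. subtract it to obtain the movement acceleration ``am``;
3. project ``am`` onto the unit gravity direction, giving the geo-referenced
   vertical acceleration ``av`` in g units;
4. align the four sensors of one participant on the deliberate simultaneous
   shake burst recorded while the devices are held together.

All indexing is 0-based with half-open ranges; time is carried as sample
index plus a nominal rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SENSOR_IDS = ("lf", "lh", "rf", "rh")

#: Sensor measurement range in g; samples beyond this are rejected as corrupt.
SENSOR_RANGE_G = 16.0

_DEGENERATE_GRAVITY_NORM = 1e-6


class PreprocessingError(ValueError):
    """Raised for malformed traces or failed shake detection."""


@dataclass
class TriaxialTrace:
    """One sensor's raw acceleration sequence ``at(i)`` in the sensor frame.

    Parameters
    ----------
    sensor_id : str
        One of ``lf, lh, rf, rh`` (left/right foot/hand).
    rate_hz : float
        Nominal sampling rate (10 Hz in the study design).
    samples : ndarray, shape (n, 3)
        Acceleration in g units, sensor-frame axes.
    """

    sensor_id: str
    rate_hz: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise PreprocessingError(
                f"trace samples must have shape (n, 3), got {self.samples.shape}"
            )
        if self.sensor_id not in SENSOR_IDS:
            raise PreprocessingError(
                f"unknown sensor_id {self.sensor_id!r}, expected one of {SENSOR_IDS}"
            )
        if self.rate_hz <= 0:
            raise PreprocessingError("rate_hz must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise PreprocessingError("trace contains non-finite samples")
        norms = np.linalg.norm(self.samples, axis=1)
        if norms.size and norms.max() > SENSOR_RANGE_G:
            raise PreprocessingError(
                f"sample norm {norms.max():.2f} g exceeds sensor range "
                f"{SENSOR_RANGE_G} g"
            )

    def __len__(self) -> int:
        return self.samples.shape[0]


@dataclass
class GravityEstimate:
    """Slow-varying gravity vector ``g'(i)`` in the sensor frame (g units)."""

    vectors: np.ndarray  # (n, 3)
    window_N: int


@dataclass
class VerticalSignal:
    """Geo-referenced vertical movement acceleration ``av(i)`` (g units)."""

    sensor_id: str
    rate_hz: float
    values: np.ndarray  # (n,)

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class SyncParams:
    """Thresholds for shake-burst synchronization.

    ``th1`` separates the burst from ordinary movement (entry threshold),
    ``th2`` bounds the mean |av| of the quiet signal right after the burst,
    and ``n_sync`` is the forward averaging window length parameter N
    (the window spans ``n_sync + 1`` samples).
    """

    th1: float = 2.0
    th2: float = 0.5
    n_sync: int = 10

    def __post_init__(self) -> None:
        if not (self.th1 > self.th2 > 0):
            raise PreprocessingError("require th1 > th2 > 0")
        if self.n_sync < 1:
            raise PreprocessingError("n_sync must be >= 1")


@dataclass
class SynchronizedRecording:
    """Four aligned vertical-acceleration channels for one participant.

    ``data`` columns are ordered (lf, lh, rf, rh); all channels are trimmed
    to start at their own post-burst index and truncated to the common
    minimum length.  ``origins`` records the detected shake-end index of
    each channel in its original trace.
    """

    participant_id: str
    rate_hz: float
    data: np.ndarray  # (L, 4)
    origins: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return self.data.shape[0]


def estimate_gravity(trace: TriaxialTrace, window_N: int = 20) -> GravityEstimate:
    """Moving-average gravity estimate over a centred ``window_N + 1`` window.

    ``g'(i)`` is the mean of ``at(j)`` for ``j`` in ``[i - N/2, i + N/2]``,
    intersected with the valid index range: windows shrink at the trace
    boundaries rather than padding with invented data.
    """
    if window_N <= 0 or window_N % 2 != 0:
        raise PreprocessingError("window_N must be a positive even integer")
    n = len(trace)
    if n <= window_N:
        raise PreprocessingError(
            f"trace length {n} not longer than filter window {window_N}"
        )
    half = window_N // 2
    csum = np.vstack([np.zeros(3), np.cumsum(trace.samples, axis=0)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    vectors = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)[:, None]
    return GravityEstimate(vectors=vectors, window_N=window_N)


def decompose(
    trace: TriaxialTrace, gravity: GravityEstimate
) -> tuple[np.ndarray, np.ndarray]:
    """Split movement acceleration into vertical and horizontal parts.

    Returns ``(amv, amh)`` with ``am = at - g' = amv + amh``, ``amv`` parallel
    to ``g'`` and ``amh`` orthogonal to it at every sample.
    """
    norms = _gravity_norms(trace, gravity)
    am = trace.samples - gravity.vectors
    coef = np.einsum("ij,ij->i", am, gravity.vectors) / norms**2
    amv = coef[:, None] * gravity.vectors
    return amv, am - amv


def vertical_projection(
    trace: TriaxialTrace, gravity: GravityEstimate
) -> VerticalSignal:
    """Signed component of movement acceleration along the gravity direction.

    ``av(i) = am(i) . ghat'(i)`` in g units, where ``ghat'`` is the unit
    gravity estimate.  This is the gravity-frame projection up to the factor
    ``|g'|`` (within ~1 of unity), keeping thresholds and intensities in g.
    """
    norms = _gravity_norms(trace, gravity)
    am = trace.samples - gravity.vectors
    av = np.einsum("ij,ij->i", am, gravity.vectors) / norms
    return VerticalSignal(sensor_id=trace.sensor_id, rate_hz=trace.rate_hz, values=av)


def _gravity_norms(trace: TriaxialTrace, gravity: GravityEstimate) -> np.ndarray:
    if gravity.vectors.shape[0] != len(trace):
        raise PreprocessingError("gravity estimate length does not match trace")
    norms = np.linalg.norm(gravity.vectors, axis=1)
    bad = np.flatnonzero(norms < _DEGENERATE_GRAVITY_NORM)
    if bad.size:
        raise PreprocessingError(
            f"degenerate gravity estimate (|g'| < {_DEGENERATE_GRAVITY_NORM}) "
            f"at index {bad[0]}"
        )
    return norms


def detect_shake_end(signal: VerticalSignal, params: SyncParams) -> int:
    """Index of the first post-burst sample of the synchronization shake.

    Returns the smallest ``k`` such that some earlier sample reached
    ``|av| >= th1`` (the burst was seen) and the forward window
    ``av[k .. k + n_sync]`` is quiet: mean |av| at most ``th2`` and no sample
    at or above ``th1``.  The burst-free condition keeps the detector from
    stopping while the averaging window still straddles the burst tail.
    """
    absav = np.abs(signal.values)
    n = absav.shape[0]
    if n == 0:
        raise PreprocessingError("empty signal")
    hits = np.flatnonzero(absav >= params.th1)
    if hits.size == 0:
        raise PreprocessingError(
            f"no shake detected on sensor {signal.sensor_id!r}: "
            f"no sample reached th1={params.th1}"
        )
    m = params.n_sync + 1
    if n < m:
        raise PreprocessingError("signal shorter than the sync averaging window")
    windows = np.lib.stride_tricks.sliding_window_view(absav, m)
    quiet = (windows.mean(axis=1) <= params.th2) & (windows.max(axis=1) < params.th1)
    first_hit = hits[0]
    candidates = np.flatnonzero(quiet[first_hit + 1 :])
    if candidates.size == 0:
        raise PreprocessingError(
            f"burst never ends on sensor {signal.sensor_id!r}: forward mean "
            f"never fell to th2={params.th2}"
        )
    return int(first_hit + 1 + candidates[0])


def synchronize(
    signals: dict[str, VerticalSignal] | list[VerticalSignal],
    params: SyncParams,
    participant_id: str = "",
) -> SynchronizedRecording:
    """Align the four sensors of one participant on the shake burst.

    Each channel is trimmed to start at its own detected shake-end index and
    all channels are truncated to the common minimum length.  Channel order
    in the output is fixed: (lf, lh, rf, rh).
    """
    if isinstance(signals, list):
        signals = {s.sensor_id: s for s in signals}
    if set(signals) != set(SENSOR_IDS):
        raise PreprocessingError(
            f"expected exactly sensors {SENSOR_IDS}, got {sorted(signals)}"
        )
    rates = {signals[s].rate_hz for s in SENSOR_IDS}
    if len(rates) != 1:
        raise PreprocessingError(f"inconsistent sampling rates: {sorted(rates)}")
    origins: dict[str, int] = {}
    tails: list[np.ndarray] = []
    for sid in SENSOR_IDS:
        k = detect_shake_end(signals[sid], params)
        origins[sid] = k
        tails.append(signals[sid].values[k:])
    length = min(t.shape[0] for t in tails)
    data = np.column_stack([t[:length] for t in tails])
    return SynchronizedRecording(
        participant_id=participant_id,
        rate_hz=rates.pop(),
        data=data,
        origins=origins,
    )


def preprocess_participant(
    traces: dict[str, TriaxialTrace] | list[TriaxialTrace],
    window_N: int = 20,
    sync: SyncParams | None = None,
    participant_id: str = "",
) -> SynchronizedRecording:
    """Full per-participant preprocessing: gravity, projection, shake sync."""
    if isinstance(traces, list):
        traces = {t.sensor_id: t for t in traces}
    sync = sync or SyncParams()
    signals = {}
    for sid, trace in traces.items():
        gravity = estimate_gravity(trace, window_N)
        signals[sid] = vertical_projection(trace, gravity)
    return synchronize(signals, sync, participant_id=participant_id)


# ---------------------------------------------------------------------------
# CSV dialects


def read_trace_csv(path, sensor_id: str, rate_hz: float = 10.0) -> TriaxialTrace:
    """Read one sensor CSV with columns t_ms, ax_g, ay_g, az_g."""
    df = pd.read_csv(path)
    required = ["t_ms", "ax_g", "ay_g", "az_g"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PreprocessingError(f"{path}: missing columns {missing}")
    return TriaxialTrace(
        sensor_id=sensor_id,
        rate_hz=rate_hz,
        samples=df[["ax_g", "ay_g", "az_g"]].to_numpy(dtype=float),
    )


def write_synchronized_csv(recording: SynchronizedRecording, path) -> None:
    """Write a synchronized recording as (t_index, lf, lh, rf, rh) in g."""
    df = pd.DataFrame(recording.data, columns=list(SENSOR_IDS))
    df.insert(0, "t_index", np.arange(len(recording)))
    df.to_csv(path, index=False)


def read_synchronized_csv(
    path, participant_id: str = "", rate_hz: float = 10.0
) -> SynchronizedRecording:
    df = pd.read_csv(path)
    missing = [c for c in SENSOR_IDS if c not in df.columns]
    if missing:
        raise PreprocessingError(f"{path}: missing channels {missing}")
    return SynchronizedRecording(
        participant_id=participant_id,
        rate_hz=rate_hz,
        data=df[list(SENSOR_IDS)].to_numpy(dtype=float),
    )
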