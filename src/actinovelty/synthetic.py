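"""Seeded synthetic 4-sensor accelerometer cohorts with known ground truth.

The study design this package analyses — multi-sensor wrist/ankle actigraphy
scored by a forecaster trained on a control group — published no recordings,
so validation runs on simulated cohorts that reproduce the statistical
structure the analysis relies on:

* a deliberate simultaneous high-amplitude shake burst at the start of each
  recording (for cross-sensor synchronization), with per-sensor lead-in
  offsets emulating unsynchronized device clocks;
* gravity plus a slowly drifting, randomly oriented sensor frame (so raw
  axes are uninformative and the vertical projection is exercised);
* band-limited movement "motifs" (voluntary limb movement concentrates
  below ~2 Hz) scheduled at mixed intensities, separated by rest;
* an atypical group in which a controllable fraction ``delta`` of motifs
  inside a chosen intensity band is replaced by motifs from a disjoint
  dictionary — the planted group difference the pipeline must recover.

Motifs are zero-mean Fourier series on a 2.1 s fundamental (harmonics at
0.476–1.905 Hz), tiled periodically within an event and smoothly tapered at
the edges.  2.1 s equals the default gravity-filter window of the
preprocessing module, so in the drift-free, noise-free limit the gravity
estimate is exact away from event edges and the preprocessing round-trip
recovers the planted vertical acceleration to machine precision; the
``GroundTruth.steady_mask`` marks the filter-transient regions around event
boundaries where this does not hold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .preprocessing import SENSOR_IDS, TriaxialTrace

#: peak |value| / pooled SD cap for motif templates, so that the largest
#: scheduled motif stays clearly below the shake amplitude.
_PEAK_TO_SD_CAP = 2.2


class SyntheticError(ValueError):
    """Raised for invalid generator parameters."""


@dataclass
class MotifDictionary:
    """Bank of 4-channel vertical-acceleration templates (g units).

    Each motif is a zero-mean periodic waveform of ``period_samples``
    fundamental period, stored as two periods, normalised to unit pooled
    standard deviation across its four channels.
    """

    motifs: list  # of (2 * period_samples, 4) arrays
    period_samples: int
    rate_hz: float
    band_limit_hz: float = 2.0
    amplitude_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.amplitude_scale is None:
            self.amplitude_scale = np.ones(len(self.motifs))

    def __len__(self) -> int:
        return len(self.motifs)


@dataclass
class ShakeSpec:
    """Synchronization burst: alternating-sign vertical acceleration."""

    amplitude_g: float = 3.0
    duration_s: float = 3.0
    offsets: tuple = (0, 5, 10, 15)  # per-sensor lead-in, samples (lf, lh, rf, rh)
    gap_s: float = 2.0  # quiet gap between burst and movement content


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults are the scaled-down study conditions used throughout the test
    suite: 9 participants per group, 10 minutes of signal at 10 Hz, with the
    planted divergence confined to the 0.4–1.0 g intensity band at fraction
    ``divergence_fraction``.
    """

    n_per_group: int = 9
    duration_s: float = 600.0
    rate_hz: float = 10.0
    divergence_fraction: float = 0.8
    divergence_band: tuple = (0.4, 1.0)
    rest_fraction: float = 0.3
    noise_sd: float = 0.02
    orientation_drift_rate: float = 0.005  # rad/s, tangent-space random walk
    intensity_range: tuple = (0.05, 1.15)  # target fragment SD range, g
    shake: ShakeSpec = field(default_factory=ShakeSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise SyntheticError("rate_hz must be positive")
        n = self.duration_s * self.rate_hz
        if abs(n - round(n)) > 1e-9:
            raise SyntheticError("duration_s * rate_hz must be an integer")
        if not (0.0 <= self.divergence_fraction <= 1.0):
            raise SyntheticError("divergence_fraction must be in [0, 1]")
        if not (0.0 <= self.rest_fraction <= 1.0):
            raise SyntheticError("rest_fraction must be in [0, 1]")
        if self.intensity_range[1] * _PEAK_TO_SD_CAP >= self.shake.amplitude_g:
            raise SyntheticError(
                "shake amplitude must strictly exceed the largest motif peak"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.rate_hz))


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    participant_id: str
    group: str
    rate_hz: float
    av: dict  # sensor_id -> full-timeline true vertical acceleration (g)
    shake_end: dict  # sensor_id -> first post-burst sample index
    content_start: dict  # sensor_id -> first movement-content sample index
    events: list  # of dicts: kind, start, end, sd, motif_index, divergent, ramp
    seed: int

    def steady_mask(self, sensor_id: str, filter_halfwidth: int = 10) -> np.ndarray:
        """Boolean mask of samples unaffected by gravity-filter transients.

        Excludes the shake burst and lead-in entirely, plus ``filter_halfwidth``
        samples around every motif-event edge and its taper ramps, where the
        moving-average gravity estimate sees a discontinuity.
        """
        n = self.av[sensor_id].shape[0]
        mask = np.ones(n, dtype=bool)
        start = self.content_start[sensor_id]
        mask[: start + filter_halfwidth] = False
        mask[n - filter_halfwidth :] = False
        for ev in self.events:
            if ev["kind"] != "motif":
                continue
            a = start + ev["start"]
            b = start + ev["end"]
            ramp = ev["ramp"]
            mask[max(0, a - filter_halfwidth - 1) : min(n, a + ramp + filter_halfwidth + 1)] = False
            mask[max(0, b - ramp - filter_halfwidth - 1) : min(n, b + filter_halfwidth + 1)] = False
        return mask


@dataclass
class Participant:
    participant_id: str
    group: str
    traces: dict  # sensor_id -> TriaxialTrace
    ground_truth: GroundTruth


@dataclass
class Cohort:
    spec: CohortSpec
    participants: list

    def by_group(self, group: str) -> list:
        return [p for p in self.participants if p.group == group]


# ---------------------------------------------------------------------------
# Motif dictionaries


def generate_motif_dictionary(
    n_motifs: int,
    band_limit_hz: float = 2.0,
    seed: int = 0,
    rate_hz: float = 10.0,
    period_s: float = 2.1,
) -> MotifDictionary:
    """Draw ``n_motifs`` random band-limited 4-channel motif templates.

    Templates are random Fourier series over the harmonics of
    ``1 / period_s`` that fall at or below ``band_limit_hz``, so their
    spectral power above the band limit is exactly zero.  Deterministic
    given ``seed``.
    """
    if n_motifs < 1:
        raise SyntheticError("n_motifs must be >= 1")
    period = int(round(period_s * rate_hz))
    if abs(period_s * rate_hz - period) > 1e-9:
        raise SyntheticError("period_s * rate_hz must be an integer")
    n_harm = int(np.floor(band_limit_hz * period_s + 1e-9))
    if n_harm < 1:
        raise SyntheticError(
            f"band_limit_hz={band_limit_hz} is below the fundamental "
            f"{1 / period_s:.3f} Hz"
        )
    rng = np.random.default_rng(seed)
    t = np.arange(period)
    motifs = []
    for _ in range(n_motifs):
        for _attempt in range(64):
            a = rng.normal(size=(n_harm, 4))
            b = rng.normal(size=(n_harm, 4))
            x = np.zeros((period, 4))
            for k in range(1, n_harm + 1):
                phase = 2.0 * np.pi * k * t / period
                x += np.cos(phase)[:, None] * a[k - 1] + np.sin(phase)[:, None] * b[k - 1]
            x /= np.sqrt(np.mean(x**2))
            if np.abs(x).max() <= _PEAK_TO_SD_CAP:
                break
        motifs.append(np.tile(x, (2, 1)))
    return MotifDictionary(
        motifs=motifs,
        period_samples=period,
        rate_hz=rate_hz,
        band_limit_hz=band_limit_hz,
    )


def tile_motif(
    template: np.ndarray,
    period: int,
    n_samples: int,
    sd: float,
    ramp: int,
) -> np.ndarray:
    """Tile one motif period to ``n_samples``, scale to target pooled SD,
    and taper ``ramp`` samples at each edge with a raised cosine."""
    base = template[:period]
    reps = int(np.ceil(n_samples / period))
    sig = np.tile(base, (reps, 1))[:n_samples] * sd
    r = min(ramp, n_samples // 2)
    if r > 0:
        w = 0.5 * (1.0 - np.cos(np.pi * (np.arange(r) + 0.5) / r))
        sig[:r] *= w[:, None]
        sig[n_samples - r :] *= w[::-1, None]
    return sig


def _dictionaries_disjoint(a: MotifDictionary, b: MotifDictionary) -> bool:
    for ma in a.motifs:
        for mb in b.motifs:
            if ma.shape == mb.shape and np.allclose(ma, mb, atol=1e-9):
                return False
    return True


# ---------------------------------------------------------------------------
# Participant generation


def _schedule_events(spec: CohortSpec, n_motifs: int, group: str, rng) -> list:
    """Event schedule over the movement content of one participant.

    Consumes an identical random stream for control and atypical groups, so
    with ``divergence_fraction == 0`` the two are sample-for-sample equal.
    """
    period = int(round(2.1 * spec.rate_hz))
    lo, hi = spec.intensity_range
    band_lo, band_hi = spec.divergence_band
    events = []
    pos = 0
    n = spec.n_samples
    while pos < n:
        u_kind = rng.random()
        u_dur = rng.random()
        u_sd = rng.random()
        u_div = rng.random()
        u_motif = rng.random()
        if u_kind < spec.rest_fraction:
            length = int(round((8.0 + 8.0 * u_dur) * spec.rate_hz))
            events.append({"kind": "rest", "start": pos, "end": min(n, pos + length)})
        else:
            n_periods = 6 + int(u_dur * 7)  # 6..12 periods (12.6-25.2 s)
            length = n_periods * period
            sd = lo + (hi - lo) * u_sd
            divergent = (
                group == "atypical"
                and band_lo <= sd < band_hi
                and u_div < spec.divergence_fraction
            )
            events.append(
                {
                    "kind": "motif",
                    "start": pos,
                    "end": min(n, pos + length),
                    "sd": sd,
                    "divergent": bool(divergent),
                    "motif_index": int(u_motif * n_motifs),
                    "ramp": period,
                }
            )
        pos += length
    return events


def generate_participant(
    spec: CohortSpec,
    dictionary: MotifDictionary,
    divergent_dictionary: MotifDictionary,
    group: str,
    participant_seed: int,
    participant_id: str = "p",
) -> Participant:
    """Generate one participant's four raw sensor traces plus ground truth.

    The world-frame signal is gravity (+1 g up) plus the scheduled vertical
    motif acceleration and independent band-limited horizontal movement at
    30% of the vertical amplitude; each sensor observes it through its own
    randomly oriented, slowly drifting frame, with additive white noise.
    """
    if group not in ("control", "atypical"):
        raise SyntheticError(f"group must be 'control' or 'atypical', got {group!r}")
    if not _dictionaries_disjoint(dictionary, divergent_dictionary):
        raise SyntheticError("control and divergent dictionaries must be disjoint")
    if len(dictionary) != len(divergent_dictionary):
        raise SyntheticError("dictionaries must have equal size (schedule symmetry)")
    if dictionary.period_samples != divergent_dictionary.period_samples:
        raise SyntheticError("dictionaries must share the motif period")

    rng = np.random.default_rng(participant_seed)
    rate = spec.rate_hz
    dt = 1.0 / rate
    n = spec.n_samples
    period = dictionary.period_samples

    events = _schedule_events(spec, len(dictionary), group, rng)

    # world-frame movement over the content: vertical (shared by sensors)
    # and horizontal (independent per sensor, two world axes)
    v = np.zeros((n, 4))
    h = np.zeros((n, 4, 2))
    for ev in events:
        if ev["kind"] != "motif":
            continue
        a, b = ev["start"], ev["end"]
        length = b - a
        if length <= 0:
            raise SyntheticError("internal error: overlapping event schedule")
        d = divergent_dictionary if ev["divergent"] else dictionary
        template = d.motifs[ev["motif_index"]] * d.amplitude_scale[ev["motif_index"]]
        v[a:b] = tile_motif(template, period, length, ev["sd"], ev["ramp"])
        # horizontal: same harmonic family, fresh coefficients per sensor/axis
        n_harm = int(np.floor(d.band_limit_hz * period / rate + 1e-9))
        t = np.arange(period)
        ha = rng.normal(size=(n_harm, 4, 2))
        hb = rng.normal(size=(n_harm, 4, 2))
        hx = np.zeros((period, 4, 2))
        for k in range(1, n_harm + 1):
            phase = 2.0 * np.pi * k * t / period
            hx += np.cos(phase)[:, None, None] * ha[k - 1]
            hx += np.sin(phase)[:, None, None] * hb[k - 1]
        hx /= np.sqrt(np.mean(hx**2, axis=0))[None]
        htile = np.tile(hx, (int(np.ceil(length / period)), 1, 1))[:length]
        htile = htile * (0.3 * ev["sd"])
        r = min(ev["ramp"], length // 2)
        if r > 0:
            w = 0.5 * (1.0 - np.cos(np.pi * (np.arange(r) + 0.5) / r))
            htile[:r] *= w[:, None, None]
            htile[length - r :] *= w[::-1, None, None]
        h[a:b] = htile

    shake = spec.shake
    n_shake = int(round(shake.duration_s * rate))
    n_gap = int(round(shake.gap_s * rate))
    burst = shake.amplitude_g * np.where(np.arange(n_shake) % 2 == 0, 1.0, -1.0)

    traces: dict[str, TriaxialTrace] = {}
    av_true: dict[str, np.ndarray] = {}
    shake_end: dict[str, int] = {}
    content_start: dict[str, int] = {}
    for s_idx, sid in enumerate(SENSOR_IDS):
        offset = int(shake.offsets[s_idx])
        n_total = offset + n_shake + n_gap + n
        av = np.zeros(n_total)
        av[offset : offset + n_shake] = burst
        av[offset + n_shake + n_gap :] = v[:, s_idx]
        hx = np.zeros((n_total, 2))
        hx[offset + n_shake + n_gap :] = h[:, s_idx, :]

        world = np.column_stack([hx[:, 0], hx[:, 1], 1.0 + av])

        quat = rng.normal(size=4)
        r0 = Rotation.from_quat(quat / np.linalg.norm(quat))
        if spec.orientation_drift_rate > 0:
            steps = rng.normal(
                scale=spec.orientation_drift_rate * dt, size=(n_total, 3)
            )
            rot = r0 * Rotation.from_rotvec(np.cumsum(steps, axis=0))
            samples = rot.inv().apply(world)
        else:
            rng.normal(size=(n_total, 3))  # keep the stream aligned across specs
            samples = r0.inv().apply(world)
        if spec.noise_sd > 0:
            samples = samples + rng.normal(scale=spec.noise_sd, size=(n_total, 3))
        else:
            rng.normal(size=(n_total, 3))

        peak = np.abs(av[offset + n_shake :]).max() if n else 0.0
        if peak >= shake.amplitude_g:
            raise SyntheticError(
                "internal error: motif amplitude reached the shake amplitude"
            )

        traces[sid] = TriaxialTrace(sensor_id=sid, rate_hz=rate, samples=samples)
        av_true[sid] = av
        shake_end[sid] = offset + n_shake
        content_start[sid] = offset + n_shake + n_gap

    gt = GroundTruth(
        participant_id=participant_id,
        group=group,
        rate_hz=rate,
        av=av_true,
        shake_end=shake_end,
        content_start=content_start,
        events=events,
        seed=int(participant_seed),
    )
    return Participant(
        participant_id=participant_id, group=group, traces=traces, ground_truth=gt
    )


# ---------------------------------------------------------------------------
# Cohorts

#: default manifest groups and the generator behaviour backing each
DEFAULT_GROUPS = {
    "control_train": "control",
    "control_test": "control",
    "atypical": "atypical",
}


def participant_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-participant seeds derived from the cohort seed."""
    return np.random.SeedSequence(seed).generate_state(n)


def generate_cohort(
    spec: CohortSpec,
    dictionary: MotifDictionary | None = None,
    divergent_dictionary: MotifDictionary | None = None,
    groups: dict | None = None,
    out_dir=None,
) -> Cohort:
    """Generate a full cohort (default: control_train / control_test /
    atypical, ``n_per_group`` each), optionally writing it to ``out_dir``.

    Deterministic given ``spec.seed``: per-participant seeds are spawned
    from it, and the two motif dictionaries (when not supplied) are derived
    from it as well.
    """
    groups = dict(groups or DEFAULT_GROUPS)
    if dictionary is None:
        dictionary = generate_motif_dictionary(
            6, seed=int(np.random.SeedSequence(spec.seed).generate_state(1)[0]) + 1,
            rate_hz=spec.rate_hz,
        )
    if divergent_dictionary is None:
        divergent_dictionary = generate_motif_dictionary(
            6, seed=int(np.random.SeedSequence(spec.seed).generate_state(1)[0]) + 2,
            rate_hz=spec.rate_hz,
        )
    n_total = spec.n_per_group * len(groups)
    seeds = participant_seeds(spec.seed, n_total)
    participants = []
    i = 0
    for label, kind in groups.items():
        for j in range(spec.n_per_group):
            pid = f"{label}_{j:02d}"
            participants.append(
                generate_participant(
                    spec,
                    dictionary,
                    divergent_dictionary,
                    group=kind,
                    participant_seed=int(seeds[i]),
                    participant_id=pid,
                )
            )
            participants[-1] = Participant(
                participant_id=pid,
                group=label,
                traces=participants[-1].traces,
                ground_truth=participants[-1].ground_truth,
            )
            i += 1
    cohort = Cohort(spec=spec, participants=participants)
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write per-sensor trace CSVs, the manifest, and ground-truth sidecars."""
    out = Path(out_dir)
    traces_dir = out / "traces"
    traces_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in cohort.participants:
        paths = {}
        for sid, trace in p.traces.items():
            path = traces_dir / f"{p.participant_id}_{sid}.csv"
            t_ms = (np.arange(len(trace)) * 1000.0 / trace.rate_hz).astype(int)
            pd.DataFrame(
                {
                    "t_ms": t_ms,
                    "ax_g": trace.samples[:, 0],
                    "ay_g": trace.samples[:, 1],
                    "az_g": trace.samples[:, 2],
                }
            ).to_csv(path, index=False, float_format="%.6f")
            paths[sid] = str(path.relative_to(out))
        gt = p.ground_truth
        sidecar = out / "traces" / f"{p.participant_id}_truth.json"
        with open(sidecar, "w") as fh:
            json.dump(
                {
                    "participant_id": gt.participant_id,
                    "group": p.group,
                    "rate_hz": gt.rate_hz,
                    "seed": gt.seed,
                    "shake_end": gt.shake_end,
                    "content_start": gt.content_start,
                    "events": gt.events,
                    "av": {k: np.round(v, 5).tolist() for k, v in gt.av.items()},
                },
                fh,
            )
        rows.append(
            {
                "participant_id": p.participant_id,
                "group": p.group,
                "seed": gt.seed,
                **{f"path_{sid}": paths[sid] for sid in SENSOR_IDS},
            }
        )
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)


def read_cohort_traces(manifest_path, rate_hz: float = 10.0):
    """Load (participant_id, group, traces dict) triples from a manifest."""
    from .preprocessing import read_trace_csv

    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    df = pd.read_csv(manifest_path)
    out = []
    for _, row in df.iterrows():
        traces = {
            sid: read_trace_csv(root / row[f"path_{sid}"], sid, rate_hz)
            for sid in SENSOR_IDS
        }
        out.append((row["participant_id"], row["group"], traces))
    return out
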