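"""File dialects for the staged pipeline.

Every interchange format is plain text:

* sensor traces: ``t_ms, ax_g, ay_g, az_g`` CSV (written by ``synthetic``);
* synchronized recordings: ``t_index, lf, lh, rf, rh`` CSV;
* windows: one CSV per participant, one row per 8 s window —
  ``window_index, intensity_sd, bin`` followed by the 320 pooled values
  ``v000..v319`` laid out time-major (value ``t * 4 + ch``), input steps
  first (t = 0..59) then target steps (t = 60..79);
* fragment scores and participant summaries: CSV;
* the stats report: JSON.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .segmentation import IntensityBins, WindowPair, assign_bin

N_WINDOW = 80
N_CHANNELS = 4
N_INPUT = 60


def write_windows_csv(windows: list, path, bins: IntensityBins) -> None:
    cols = [f"v{k:03d}" for k in range(N_WINDOW * N_CHANNELS)]
    rows = []
    for w in windows:
        payload = np.vstack([w.x, w.y]).reshape(-1)
        rows.append(
            [w.window_index, w.intensity_sd, assign_bin(w.intensity_sd, bins)]
            + payload.tolist()
        )
    df = pd.DataFrame(rows, columns=["window_index", "intensity_sd", "bin"] + cols)
    df.to_csv(path, index=False, float_format="%.6g")


def read_windows_csv(path, participant_id: str) -> list:
    df = pd.read_csv(path)
    cols = [f"v{k:03d}" for k in range(N_WINDOW * N_CHANNELS)]
    windows = []
    for _, row in df.iterrows():
        block = row[cols].to_numpy(dtype=float).reshape(N_WINDOW, N_CHANNELS)
        windows.append(
            WindowPair(
                participant_id=participant_id,
                window_index=int(row["window_index"]),
                x=block[:N_INPUT],
                y=block[N_INPUT:],
                intensity_sd=float(row["intensity_sd"]),
            )
        )
    return windows


def config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


class RunLog:
    """Line-oriented run log with ISO timestamps."""

    def __init__(self, path):
        self.path = Path(path)
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self._fh = open(self.path, "a")

    def write(self, message: str) -> None:
        stamp = datetime.datetime.now().isoformat(timespec="seconds")
        self._fh.write(f"{stamp} {message}\n")
        self._fh.flush()

    def close(self) -> None:
        self._fh.close()
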