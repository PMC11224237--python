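"""Reading and writing sensor sessions, results, and population tables.

Session format: a long CSV with columns ``t_s, channel, value`` (channels
``ppg``, ``accel_z_g``, ``touch_x``) plus a JSON sidecar next to it
(``<name>.json``) holding ``arm_length_m``, the sampling rates, the seed,
flags, and optionally the simulator ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import SchemaError
from .signal_sim.sessions import GroundTruth, SensorSession

__all__ = ["write_session", "read_session", "sidecar_path",
           "write_pp_result", "write_population", "read_population"]

_CHANNELS = {"ppg": ("t_ppg", "ppg"),
             "accel_z_g": ("t_accel", "accel_z"),
             "touch_x": ("t_touch", "touch_x")}


def sidecar_path(csv_path) -> Path:
    return Path(csv_path).with_suffix(".json")


def write_session(session: SensorSession, csv_path,
                  ground_truth: Optional[GroundTruth] = None) -> Path:
    """Write a session as long CSV + JSON sidecar; returns the CSV path."""
    csv_path = Path(csv_path)
    frames = []
    for channel, (tname, vname) in _CHANNELS.items():
        frames.append(pd.DataFrame({
            "t_s": getattr(session, tname),
            "channel": channel,
            "value": getattr(session, vname),
        }))
    # %.17g preserves doubles exactly through the text round trip
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False,
                                                float_format="%.17g")

    meta = {"arm_length_m": session.arm_length_m, **session.metadata}
    if ground_truth is not None:
        meta["ground_truth"] = {
            "pp_mmHg": ground_truth.pp_mmHg,
            "sp_heart": ground_truth.sp_heart,
            "dp_heart": ground_truth.dp_heart,
            "hr_bpm": ground_truth.hr_bpm,
            "beat_times_s": np.asarray(ground_truth.beat_times_s).tolist(),
        }
    with open(sidecar_path(csv_path), "w") as fh:
        json.dump(meta, fh, indent=1)
    return csv_path


def read_session(csv_path) -> SensorSession:
    """Read a session CSV + sidecar and validate its invariants."""
    csv_path = Path(csv_path)
    if not csv_path.exists():
        raise SchemaError(f"session file not found: {csv_path}")
    side = sidecar_path(csv_path)
    if not side.exists():
        raise SchemaError(f"missing JSON sidecar: {side}")
    df = pd.read_csv(csv_path, float_precision="round_trip")
    for col in ("t_s", "channel", "value"):
        if col not in df.columns:
            raise SchemaError(f"session CSV missing column {col!r}")
    with open(side) as fh:
        meta = json.load(fh)
    if "arm_length_m" not in meta:
        raise SchemaError("sidecar missing field 'arm_length_m'")
    arm = float(meta["arm_length_m"])

    kwargs = {}
    for channel, (tname, vname) in _CHANNELS.items():
        sub = df[df["channel"] == channel]
        if len(sub) == 0:
            raise SchemaError(f"session CSV missing channel {channel!r}")
        kwargs[tname] = sub["t_s"].to_numpy(dtype=float)
        kwargs[vname] = sub["value"].to_numpy(dtype=float)

    metadata = {k: v for k, v in meta.items()
                if k not in ("arm_length_m", "ground_truth")}
    session = SensorSession(arm_length_m=arm, metadata=metadata, **kwargs)
    session.validate()
    return session


def read_ground_truth(csv_path) -> Optional[dict]:
    """Ground-truth block from a session sidecar, if present."""
    side = sidecar_path(csv_path)
    with open(side) as fh:
        return json.load(fh).get("ground_truth")


def write_pp_result(result, path=None) -> str:
    """Serialize a PPResult (and its validity report) as JSON."""
    d = {
        "pp_mmHg": result.pp_mmHg,
        "hr_bpm": result.hr_bpm,
        "fit": None,
        "validity": result.validity.to_dict() if result.validity else None,
        "diagnostics": result.diagnostics,
    }
    if result.fit is not None:
        d["fit"] = {
            "amp": result.fit.amp, "c1": result.fit.c1, "c2": result.fit.c2,
            "w1": result.fit.w1, "w2": result.fit.w2,
            "rms_residual": result.fit.rms_residual,
        }
    text = json.dumps(d, indent=1)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def write_population(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_population(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"population file not found: {path}")
    return pd.read_csv(path)
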