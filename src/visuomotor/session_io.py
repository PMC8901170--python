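"""HDF5 and CSV persistence for session containers.

Layout (schema version 1):

    /behavior/t, /behavior/speed, /behavior/flow
    /traces                       neurons x time
    /events/kind, /events/time, /events/attrs   (attrs as JSON strings)
    /ground_truth                 optional JSON string of neuron models
    root attrs: dt, condition, gain, is_dff, schema_version
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synthetic import BehaviorTraces, EventTable, NeuronModel, SessionData

SCHEMA_VERSION = 1


def write_session(path, session: SessionData) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["dt"] = session.dt
        f.attrs["condition"] = session.behavior.condition
        f.attrs["gain"] = session.behavior.gain
        f.attrs["is_dff"] = session.is_dff
        beh = f.create_group("behavior")
        beh.create_dataset("t", data=session.behavior.t)
        beh.create_dataset("speed", data=session.behavior.running_speed)
        beh.create_dataset("flow", data=session.behavior.visual_flow)
        f.create_dataset("traces", data=session.traces)
        ev = f.create_group("events")
        str_dtype = h5py.string_dtype()
        ev.create_dataset("kind", data=np.array(session.events.kind, dtype=object), dtype=str_dtype)
        ev.create_dataset("time", data=session.events.time)
        ev.create_dataset(
            "attrs",
            data=np.array([json.dumps(a) for a in session.events.attrs], dtype=object),
            dtype=str_dtype,
        )
        if session.ground_truth is not None:
            f.create_dataset(
                "ground_truth",
                data=json.dumps([dataclasses.asdict(m) for m in session.ground_truth]),
                dtype=str_dtype,
            )


def read_session(path) -> SessionData:
    with h5py.File(path, "r") as f:
        if int(f.attrs["schema_version"]) != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema version {f.attrs['schema_version']}")
        behavior = BehaviorTraces(
            t=f["behavior/t"][()],
            running_speed=f["behavior/speed"][()],
            visual_flow=f["behavior/flow"][()],
            condition=str(f.attrs["condition"]),
            dt=float(f.attrs["dt"]),
            gain=float(f.attrs["gain"]),
        )
        events = EventTable(
            kind=[k.decode() if isinstance(k, bytes) else str(k) for k in f["events/kind"][()]],
            time=f["events/time"][()],
            attrs=[
                json.loads(a.decode() if isinstance(a, bytes) else a)
                for a in f["events/attrs"][()]
            ],
        )
        ground_truth = None
        if "ground_truth" in f:
            raw = f["ground_truth"][()]
            raw = raw.decode() if isinstance(raw, bytes) else str(raw)
            ground_truth = [NeuronModel(**d) for d in json.loads(raw)]
        return SessionData(
            behavior=behavior,
            events=events,
            traces=f["traces"][()],
            dt=float(f.attrs["dt"]),
            is_dff=bool(f.attrs["is_dff"]),
            ground_truth=ground_truth,
        )


def behavior_to_csv(path, behavior: BehaviorTraces) -> None:
    pd.DataFrame(
        {
            "t": behavior.t,
            "running_speed": behavior.running_speed,
            "visual_flow": behavior.visual_flow,
        }
    ).to_csv(path, index=False)


def events_to_csv(path, events: EventTable) -> None:
    events.to_frame().to_csv(path, index=False)


def trials_to_csv(path, trials) -> None:
    """Flatten navigation trials to one long CSV (trial_id, t, x, y, heading, speed)."""
    frames = []
    for i, trial in enumerate(trials):
        n = trial.positions.shape[0]
        frames.append(
            pd.DataFrame(
                {
                    "trial_id": i,
                    "t": np.arange(n) * trial.dt,
                    "x": trial.positions[:, 0],
                    "y": trial.positions[:, 1],
                    "heading_deg": trial.headings,
                    "speed": trial.speeds,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(Path(path), index=False)
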