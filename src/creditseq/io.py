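"""Persistent artifacts: session CSVs, activity tensors (HDF5), YAML configs."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import h5py
import numpy as np
import pandas as pd
import yaml

from .task_engine import EVENT_ORDER, SessionRecord, TaskConfig, TrialRecord
from .synthetic_data import PopulationActivity

PathLike = Union[str, Path]


def save_session_csv(session: SessionRecord, path: PathLike) -> None:
    """Session CSV: trial, choice, outcome, block, stimulated, event-time columns."""
    session.to_dataframe().to_csv(path, index=False)


def load_session_csv(path: PathLike, config: Optional[TaskConfig] = None) -> SessionRecord:
    df = pd.read_csv(path)
    trials = []
    for _, row in df.iterrows():
        ev = {}
        for name in EVENT_ORDER:
            col = f"t_{name}"
            if col in row and pd.notna(row[col]):
                ev[name] = float(row[col])
        trials.append(
            TrialRecord(
                index=int(row["trial"]),
                choice=str(row["choice"]),
                outcome=int(row["outcome"]),
                block=str(row["block"]),
                stimulated=bool(row["stimulated"]),
                event_times=ev,
            )
        )
    return SessionRecord(trials=trials, config=config or TaskConfig())


def save_activity_h5(trials: Sequence[PopulationActivity], path: PathLike) -> None:
    """Activity tensor HDF5: rates (trial x neuron x time), peak_times, side_labels."""
    first = trials[0]
    with h5py.File(path, "w") as f:
        f.create_dataset("rates", data=np.stack([a.rates for a in trials]))
        f.create_dataset("peak_times", data=first.peak_times)
        f.create_dataset(
            "side_labels", data=np.array([s.encode() for s in first.side_labels])
        )
        f.attrs["dt"] = first.dt
        f.attrs["t0"] = first.t0


def load_activity_h5(path: PathLike) -> list:
    with h5py.File(path, "r") as f:
        rates = f["rates"][...]
        peaks = f["peak_times"][...]
        sides = np.array([s.decode() for s in f["side_labels"][...]])
        dt = float(f.attrs["dt"])
        t0 = float(f.attrs["t0"])
    return [
        PopulationActivity(rates=r, side_labels=sides, peak_times=peaks, dt=dt, t0=t0)
        for r in rates
    ]


def save_kernels_h5(kernels: dict, path: PathLike, attrs: Optional[dict] = None) -> None:
    """Event-labelled kernel arrays with fit metadata as attributes."""
    with h5py.File(path, "w") as f:
        for event, kernel in kernels.items():
            f.create_dataset(event, data=np.asarray(kernel))
        for k, v in (attrs or {}).items():
            if v is not None:
                f.attrs[k] = v


def load_task_config_yaml(path: PathLike) -> TaskConfig:
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    return TaskConfig(**data)


def save_task_config_yaml(config: TaskConfig, path: PathLike) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(dataclasses.asdict(config), f)


def save_agent_checkpoint(agent, path: PathLike, meta: Optional[dict] = None) -> None:
    """Dynamics-agent checkpoint as npz plus a JSON metadata sidecar."""
    path = Path(path)
    np.savez(
        path,
        cw=agent.critic.w,
        cu=agent.critic.u,
        cb=agent.critic.b,
        aw=agent.actor.w,
        au=agent.actor.u,
        ab=agent.actor.b,
        w_v=agent.w_v,
        b_v=np.array(agent.b_v),
        w_pi=agent.w_pi,
        b_pi=agent.b_pi,
    )
    sidecar = path.with_suffix(".json")
    config = dataclasses.asdict(agent.config)
    with open(sidecar, "w") as f:
        json.dump({"config": config, **(meta or {})}, f, indent=1, default=list)


def load_agent_checkpoint(path: PathLike):
    from .dynamics_model import DynamicsAgent, DynamicsConfig, LSTMWeights

    path = Path(path)
    with open(path.with_suffix(".json")) as f:
        meta = json.load(f)
    cfg_raw = dict(meta["config"])
    for key in ("reward_mu_range",):
        if key in cfg_raw and isinstance(cfg_raw[key], list):
            cfg_raw[key] = tuple(cfg_raw[key])
    cfg = DynamicsConfig(**cfg_raw)
    z = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    agent = DynamicsAgent(
        config=cfg,
        critic=LSTMWeights(z["cw"], z["cu"], z["cb"]),
        actor=LSTMWeights(z["aw"], z["au"], z["ab"]),
        w_v=z["w_v"],
        b_v=float(z["b_v"]),
        w_pi=z["w_pi"],
        b_pi=z["b_pi"],
    )
    return agent, meta
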