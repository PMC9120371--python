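"""Reading configs and writing simulation outputs.

Trajectories are written either as columnar CSV (time in ms plus one column
per population rate/state) or as a compressed ``.npz`` container that also
stores parameters, seed and integration settings as JSON metadata.
Experiment configuration lives in one YAML file with ``thalamus``,
``cortex``, ``loop`` and ``sim`` sections mapping directly onto the
parameter dataclasses.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd
import yaml

from .numerics import SimGrid
from .thalamus.model import ThalamicParams
from .cortex.model import CorticalParams
from .cortex.transfer import AdExNeuronParams
from .network import LoopConfig

__all__ = ["trajectory_to_csv", "trajectory_to_npz", "trajectory_from_npz",
           "load_config", "read_rate_csv"]


def trajectory_to_csv(out: dict, path) -> None:
    cols = {"t_ms": out["t"]}
    cols.update({k: v for k, v in out.items() if k != "t"})
    pd.DataFrame(cols).to_csv(path, index=False)


def trajectory_to_npz(out: dict, path, meta: dict | None = None) -> None:
    payload = {k: np.asarray(v) for k, v in out.items()}
    payload["_meta"] = np.frombuffer(
        json.dumps(meta or {}, default=_jsonify).encode(), dtype=np.uint8)
    np.savez_compressed(path, **payload)


def trajectory_from_npz(path) -> tuple[dict, dict]:
    with np.load(path) as z:
        out = {k: z[k].copy() for k in z.files if k != "_meta"}
        meta = json.loads(bytes(z["_meta"]).decode()) if "_meta" in z.files else {}
    return out, meta


def read_rate_csv(path, column: str | None = None) -> tuple[np.ndarray, float]:
    """Load one rate column (plus its sampling rate) from a trajectory CSV."""
    df = pd.read_csv(path)
    t = df["t_ms"].to_numpy()
    fs = 1000.0 / float(np.median(np.diff(t)))
    if column is None:
        column = [c for c in df.columns if c != "t_ms"][0]
    return df[column].to_numpy(dtype=float), fs


def _jsonify(obj):
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def _build(cls, section: dict):
    if not section:
        return cls()
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**section)


def default_config() -> dict:
    """All-default parameter set (same layout as :func:`load_config`)."""
    return {"thalamus": ThalamicParams(), "cortex": CorticalParams(),
            "loop": LoopConfig(), "sim": SimGrid(duration=30000.0)}


def load_config(path) -> dict:
    """Parse a YAML config into parameter objects.

    Returns dict with keys ``thalamus``, ``cortex``, ``loop``, ``sim``
    (missing sections fall back to defaults).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    ctx_sec = dict(raw.get("cortex", {}) or {})
    neuron = _build(AdExNeuronParams, ctx_sec.pop("neuron", {}) or {})
    cortex = _build(CorticalParams, {**ctx_sec, "neuron": neuron})
    return {
        "thalamus": _build(ThalamicParams, raw.get("thalamus", {}) or {}),
        "cortex": cortex,
        "loop": _build(LoopConfig, raw.get("loop", {}) or {}),
        "sim": _build(SimGrid, raw.get("sim", {"duration": 30000.0}) or
                      {"duration": 30000.0}),
    }
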