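"""Trace/parameter serialization and run manifests.

Traces travel as long-format CSV with columns ``time_ms, site, observable,
value`` (values at full ``repr`` precision, so a round trip is lossless at
printed precision).  Every run directory gets a ``manifest.json`` recording
the config hash, seed and package version — enough to reproduce the run
exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .solver import Trace

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_params",
    "read_params",
    "config_hash",
    "write_manifest",
]

VERSION = "0.1.0"


def _observable_of(label: str) -> str:
    tail = label.rsplit(".", 1)[-1]
    return {"v": "voltage", "s": "synapse_s", "ca": "calcium"}.get(
        tail, "gate"
    )


def write_trace_csv(trace: Trace, path) -> None:
    trace = trace.detached()
    frames = []
    for i, label in enumerate(trace.labels):
        frames.append(pd.DataFrame({
            "time_ms": trace.times,
            "site": label,
            "observable": _observable_of(label),
            "value": np.asarray(trace.values)[i],
        }))
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, index=False, float_format="%.17g")


def read_trace_csv(path) -> Trace:
    df = pd.read_csv(path, float_precision="round_trip")
    need = {"time_ms", "site", "observable", "value"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    labels = list(dict.fromkeys(df["site"]))
    times = np.asarray(sorted(df["time_ms"].unique()))
    values = np.empty((len(labels), len(times)))
    for i, label in enumerate(labels):
        sub = df[df["site"] == label].sort_values("time_ms")
        if len(sub) != len(times):
            raise ValueError(f"{path}: ragged trace for site {label!r}")
        values[i] = sub["value"].to_numpy()
    return Trace(times=times, values=values, labels=labels)


def write_params(pv, path) -> None:
    from .params import ParameterView

    assert isinstance(pv, ParameterView)
    Path(path).write_text(json.dumps(pv.to_dict(), indent=2) + "\n")


def read_params(path):
    from .params import ParameterView

    return ParameterView.from_dict(json.loads(Path(path).read_text()))


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(outdir, config: dict, seed: int, extra: dict | None = None
                   ) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": VERSION,
        "seed": int(seed),
        "config_hash": config_hash(config),
        "config": config,
    }
    if extra:
        manifest.update(extra)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
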