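"""Structured-text (JSON) model checkpoints: topology, scaler, theta, metadata."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .network import NetworkParameters, Topology
from .preprocess import Scaler


def save_model(path: str | Path, net: NetworkParameters, scaler: Scaler | None,
               metadata: dict | None = None) -> None:
    payload = {
        "topology": {"n_in": net.topology.n_in,
                     "n_hidden": net.topology.n_hidden,
                     "n_out": net.topology.n_out},
        "theta": net.theta.tolist(),
        "scaler": None if scaler is None else {
            "in_min": scaler.in_min, "in_max": scaler.in_max,
            "out_min": scaler.out_min, "out_max": scaler.out_max},
        "metadata": metadata or {},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> tuple[NetworkParameters, Scaler | None, dict]:
    payload = json.loads(Path(path).read_text())
    topo = Topology(**payload["topology"])
    net = NetworkParameters(topo, np.asarray(payload["theta"], dtype=float))
    sc = payload.get("scaler")
    scaler = None if sc is None else Scaler(**sc)
    return net, scaler, payload.get("metadata", {})
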