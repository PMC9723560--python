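"""File formats and run metadata.

All delimited outputs are tab-separated, UTF-8, with a header row and '.'
decimal point.  Times are decimal days internally (epoch = window start);
an ISO epoch date in the file header comment is used for conversion when
present.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ModelSpec, spec_to_dict
from .dynamics import Forcing
from .objective import ObservationSeries
from .simulate import StateTrajectory

__all__ = [
    "read_observations", "write_observations",
    "read_forcing", "write_forcing",
    "write_trajectory", "read_trajectory",
    "write_ledger", "read_ledger",
    "write_network", "RunMetadata",
]


def read_observations(path) -> list[ObservationSeries]:
    """TSV columns: series_id, time, value[, weight]."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out = []
    for sid, g in df.groupby("series_id", sort=False):
        w = float(g["weight"].iloc[0]) if "weight" in g else 1.0
        out.append(ObservationSeries(str(sid), g.time.to_numpy(float),
                                     g.value.to_numpy(float), weight=w))
    return out


def write_observations(observations: list[ObservationSeries], path) -> None:
    rows = []
    for o in observations:
        for t, v in zip(o.t, o.v):
            rows.append((o.series_id, t, v, o.weight))
    pd.DataFrame(rows, columns=["series_id", "time", "value", "weight"]) \
        .to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_forcing(path) -> Forcing:
    """TSV columns: time, variable, value (long form)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    t = np.unique(df.time.to_numpy(float))
    series = {}
    for var, g in df.groupby("variable"):
        series[str(var)] = np.interp(t, g.time.to_numpy(float), g.value.to_numpy(float))
    return Forcing(t=t, series=series)


def write_forcing(forcing: Forcing, path) -> None:
    rows = []
    for var, vals in forcing.series.items():
        for t, v in zip(forcing.t, vals):
            rows.append((t, var, v))
    pd.DataFrame(rows, columns=["time", "variable", "value"]) \
        .to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_trajectory(traj: StateTrajectory, path) -> None:
    traj.frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_trajectory(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_ledger(traj: StateTrajectory, path) -> None:
    if traj.ledger is None:
        raise ValueError("trajectory has no ledger")
    traj.ledger.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_ledger(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_network(snapshot, edges_path, nodes_path=None, graphml_path=None) -> None:
    snapshot.edges.to_csv(edges_path, sep="\t", index=False, float_format="%.17g")
    if nodes_path:
        snapshot.nodes.to_csv(nodes_path, sep="\t", index=False, float_format="%.17g")
    if graphml_path:
        import networkx as nx
        nx.write_graphml(snapshot.graph(), graphml_path)


@dataclass
class RunMetadata:
    """Everything needed to reproduce a run bit-for-bit at a code version."""

    config_hash: str = ""
    seeds: list[int] = field(default_factory=list)
    schedule_digest: str = ""
    software_version: str = ""
    eval_counts: dict[str, int] = field(default_factory=dict)
    converged: dict[str, bool] = field(default_factory=dict)

    @staticmethod
    def digest(obj) -> str:
        return hashlib.sha256(
            json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]

    @staticmethod
    def for_spec(spec: ModelSpec) -> str:
        return RunMetadata.digest(spec_to_dict(spec))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @staticmethod
    def load(path) -> "RunMetadata":
        return RunMetadata(**json.loads(Path(path).read_text()))
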