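"""Readers, writers, configuration and run manifests.

File conventions: agent ids are 1-based in files (matching how small
study networks are usually tabulated) and 0-based in memory; times are
0-based integers with t = 0 the baseline; missing values are empty CSV
cells, never sentinel numbers; every CSV carries a header.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import LikertScale, Network, OpinionTrajectory, likert_forward
from .ga import FitResult, GAConfig
from .pilot import MEASURE_SCALES, PilotMeasure, PilotNetwork, SyntheticPilotNetwork

__all__ = [
    "read_opinions",
    "write_opinions",
    "read_network",
    "write_network",
    "read_weights",
    "write_weights",
    "load_ga_config",
    "RunManifest",
    "write_results",
    "read_pilot_csvs",
    "write_pilot_csvs",
]


# ---------------------------------------------------------------------------
# opinions
# ---------------------------------------------------------------------------

_OPINION_COLS = ["network_id", "agent_id", "time", "value"]


def read_opinions(path, scale: LikertScale | None = None) -> dict:
    """Read a long-format opinion CSV into trajectories per network.

    Columns ``network_id, agent_id, time, value``; an empty value cell is
    a missing observation.  Times must be consecutive integers from 0.
    Values must lie in [0, 1] unless a ``scale`` is given, in which case
    they are integer composite scores and are forward-transformed.

    Returns ``{network_id: (OpinionTrajectory, agent_ids)}`` with agent
    ids sorted ascending and mapped to row order.
    """
    df = pd.read_csv(path)
    missing_cols = set(_OPINION_COLS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"opinion CSV lacks columns {sorted(missing_cols)}")
    out = {}
    for nid, g in df.groupby("network_id"):
        if g.duplicated(["agent_id", "time"]).any():
            raise ValueError(f"duplicate (agent, time) rows in network {nid}")
        agents = np.sort(g["agent_id"].unique())
        times = np.sort(g["time"].unique())
        if not np.array_equal(times, np.arange(len(times))):
            raise ValueError(
                f"times must be consecutive integers from 0 in network {nid}")
        values = np.zeros((len(agents), len(times)))
        mask = np.zeros_like(values, dtype=bool)
        aidx = {a: k for k, a in enumerate(agents)}
        for _, row in g.iterrows():
            if pd.isna(row["value"]):
                continue
            v = float(row["value"])
            if scale is not None:
                v = likert_forward(int(v), scale)
            elif not 0.0 <= v <= 1.0:
                raise ValueError(
                    f"opinion {v} outside [0, 1] in network {nid}")
            i, t = aidx[row["agent_id"]], int(row["time"])
            values[i, t] = v
            mask[i, t] = True
        out[nid] = (OpinionTrajectory(values, mask), agents)
    return out


def write_opinions(trajectories: dict, path) -> None:
    """Inverse of :func:`read_opinions` (continuous values); masked cells
    are written empty."""
    rows = []
    for nid, (traj, agents) in trajectories.items():
        for i, a in enumerate(agents):
            for t in range(traj.n_times):
                rows.append({
                    "network_id": nid, "agent_id": a, "time": t,
                    "value": traj.values[i, t] if traj.observed[i, t] else None,
                })
    pd.DataFrame(rows, columns=_OPINION_COLS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# networks and weight matrices
# ---------------------------------------------------------------------------


def read_network(path, mode: str = "matrix", n_agents: int | None = None) -> Network:
    """Read a network from a dense CSV (header row and index column of
    agent ids) or a two-column edge-list CSV.

    Edge lists are symmetrised and self-loops added; ``n_agents`` bounds
    the size when isolated agents exist beyond the largest id mentioned.
    """
    if mode == "matrix":
        df = pd.read_csv(path, index_col=0)
        a = df.to_numpy()
        if not np.array_equal(a, a.T):
            raise ValueError("dense network CSV must be symmetric")
        np.fill_diagonal(a, 1)
        return Network(a)
    if mode == "edges":
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError("edge list needs two columns")
        edges = df.iloc[:, :2].to_numpy()
        top = int(edges.max()) if edges.size else 0
        n = n_agents if n_agents is not None else top
        if edges.size and top > n:
            raise ValueError("edge references agent beyond n_agents")
        return Network.from_edges(n, [(int(a) - 1, int(b) - 1) for a, b in edges])
    raise ValueError("mode must be 'matrix' or 'edges'")


def _agent_labels(n: int):
    return [str(i + 1) for i in range(n)]


def write_network(network: Network, path) -> None:
    labels = _agent_labels(network.n_agents)
    pd.DataFrame(network.adjacency, index=labels, columns=labels).to_csv(path)


def write_weights(weights: np.ndarray, path) -> None:
    """Dense CSV with 1-based agent ids on both axes, full precision."""
    w = np.asarray(weights)
    labels = _agent_labels(w.shape[0])
    pd.DataFrame(w, index=labels, columns=labels).to_csv(
        path, float_format="%.17g")


def read_weights(path) -> np.ndarray:
    return pd.read_csv(path, index_col=0,
                       float_precision="round_trip").to_numpy()


# ---------------------------------------------------------------------------
# configuration and manifests
# ---------------------------------------------------------------------------


def load_ga_config(path) -> GAConfig:
    """GA hyperparameters from a YAML or JSON file using the canonical
    key names (probb, factorb, ...); omitted keys take their defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must hold a mapping")
    return GAConfig.from_dict(data)


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass(frozen=True)
class RunManifest:
    """Record of one command invocation, sufficient to reproduce it."""

    command: str
    config: dict
    seed: int | None
    input_digests: dict
    output_paths: list
    timestamp: str


def write_manifest(out_dir, command: str, config: dict, seed,
                   inputs: dict | None = None,
                   outputs: list | None = None) -> RunManifest:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        command=command,
        config=config,
        seed=seed,
        input_digests={k: _digest(v) for k, v in (inputs or {}).items()},
        output_paths=[str(p) for p in (outputs or [])],
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    (out_dir / "manifest.json").write_text(
        json.dumps(asdict(manifest), indent=2, sort_keys=True))
    return manifest


def write_results(result: FitResult, out_dir, command: str = "fit",
                  inputs: dict | None = None) -> RunManifest:
    """Write a fit's weight matrix (dense CSV), scalars and resolved
    configuration (JSON) and a run manifest with deterministic field
    ordering."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    wpath = out_dir / "weights.csv"
    write_weights(result.weights.weights, wpath)
    rpath = out_dir / "result.json"
    payload = {
        "objective": result.objective,
        "gene_objectives": [float(v) for v in result.gene_objectives],
        "iterations": result.iterations,
        "weights": [[float(v) for v in row] for row in result.weights.weights],
        "history": result.history,
        "config": result.config.to_dict(),
        "seed": result.seed,
    }
    rpath.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return write_manifest(out_dir, command, result.config.to_dict(),
                          result.seed, inputs, [str(wpath), str(rpath)])


# ---------------------------------------------------------------------------
# pilot-format CSVs
# ---------------------------------------------------------------------------


def write_pilot_csvs(studies: list, out_dir) -> dict:
    """Emit the three pilot CSVs (measures, edges, roles) for a list of
    :class:`SyntheticPilotNetwork` or ``(PilotNetwork, measures)`` items.
    Agent and network ids are 1-based in the files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    m_rows, e_rows, r_rows = [], [], []
    for k, item in enumerate(studies):
        if isinstance(item, SyntheticPilotNetwork):
            pn, measures = item.network, item.measures
        else:
            pn, measures = item
        nid = k + 1
        for name, meas in measures.items():
            for tlabel, arr in (("baseline", meas.baseline),
                                ("followup", meas.followup)):
                for i in range(pn.n_agents):
                    m_rows.append({
                        "network_id": nid, "agent_id": i + 1,
                        "measure": name, "time": tlabel,
                        "score": None if np.isnan(arr[i]) else int(arr[i]),
                    })
        for pair in sorted(tuple(sorted(e)) for e in pn.known_edges):
            e_rows.append({"network_id": nid, "a": pair[0] + 1,
                           "b": pair[1] + 1, "status": "present"})
        for pair in sorted(tuple(sorted(e)) for e in pn.known_non_edges):
            e_rows.append({"network_id": nid, "a": pair[0] + 1,
                           "b": pair[1] + 1, "status": "absent"})
        for i in range(pn.n_agents):
            # an agent can be both the seed and a leader: one row per role
            if i == pn.seed_agent:
                r_rows.append({"network_id": nid, "agent_id": i + 1,
                               "role": "seed"})
            if i in pn.leaders:
                r_rows.append({"network_id": nid, "agent_id": i + 1,
                               "role": "leader"})
            if i != pn.seed_agent and i not in pn.leaders:
                r_rows.append({"network_id": nid, "agent_id": i + 1,
                               "role": "member"})
    paths = {
        "measures": out_dir / "measures.csv",
        "edges": out_dir / "edges.csv",
        "roles": out_dir / "roles.csv",
    }
    pd.DataFrame(m_rows).to_csv(paths["measures"], index=False)
    pd.DataFrame(e_rows, columns=["network_id", "a", "b", "status"]).to_csv(
        paths["edges"], index=False)
    pd.DataFrame(r_rows).to_csv(paths["roles"], index=False)
    return paths


def read_pilot_csvs(measures_path, edges_path, roles_path) -> list:
    """Read the three pilot CSVs back into
    ``(PilotNetwork, {name: PilotMeasure})`` pairs, ordered by network id.

    A seed agent counts as a leader if flagged with role ``seed`` and also
    listed under ``leader`` -- roles files may carry one row per role, so
    both conventions are accepted.
    """
    measures = pd.read_csv(measures_path)
    edges = pd.read_csv(edges_path)
    roles = pd.read_csv(roles_path)
    out = []
    for nid in sorted(roles["network_id"].unique()):
        r = roles[roles["network_id"] == nid]
        n = r["agent_id"].max()
        seed_rows = r[r["role"] == "seed"]["agent_id"]
        if seed_rows.empty:
            raise ValueError(f"network {nid} lacks a seed agent")
        seed_agent = int(seed_rows.iloc[0]) - 1
        leaders = {int(a) - 1 for a in r[r["role"] == "leader"]["agent_id"]}
        if not leaders:
            leaders = {seed_agent}
        e = edges[edges["network_id"] == nid]
        known = {(int(a) - 1, int(b) - 1)
                 for a, b in e[e["status"] == "present"][["a", "b"]].to_numpy()}
        absent = {(int(a) - 1, int(b) - 1)
                  for a, b in e[e["status"] == "absent"][["a", "b"]].to_numpy()}
        pn = PilotNetwork(int(n), frozenset(known), frozenset(absent),
                          frozenset(leaders), seed_agent)
        m = measures[measures["network_id"] == nid]
        mdict = {}
        for name in m["measure"].unique():
            scale = MEASURE_SCALES.get(name)
            if scale is None:
                raise ValueError(f"unknown measure {name!r}")
            base = np.full(int(n), np.nan)
            fup = np.full(int(n), np.nan)
            for _, row in m[m["measure"] == name].iterrows():
                if pd.isna(row["score"]):
                    continue
                idx = int(row["agent_id"]) - 1
                if row["time"] == "baseline":
                    base[idx] = float(row["score"])
                elif row["time"] == "followup":
                    fup[idx] = float(row["score"])
                else:
                    raise ValueError(f"unknown time label {row['time']!r}")
            mdict[name] = PilotMeasure(name, scale, base, fup)
        out.append((pn, mdict))
    return out
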