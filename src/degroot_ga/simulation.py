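"""Simulation-study harness: data generation, error metrics, factorial runs.

The study design crosses network size, target degree, target self-weight,
number of observed time steps and proportion of missing data.  For each
feasible design point a connected Erdos-Renyi network is drawn, a
row-stochastic weight matrix generated around the target self-weight, a
21-step DeGroot trajectory simulated from uniform initial opinions, and the
observed data set formed by truncating to T time steps and masking entries.
The GA is then fitted repeatedly and judged by three root-mean-square
errors: fit (observed time steps, ignoring the mask), extrapolation
(withheld time steps) and recovery (non-fixed weights).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .core import Network, OpinionTrajectory, WeightMatrix, simulate_diffusion
from .ga import FixedMask, GAConfig, fit

__all__ = [
    "StudyDesign",
    "SimulatedDataset",
    "generate_connected_er",
    "sample_connected_er_degrees",
    "generate_weights",
    "simulate_dataset",
    "apply_missingness",
    "rmse_fit",
    "rmse_ext",
    "rmse_rec",
    "run_factorial",
    "summarize",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StudyDesign:
    """Factor levels of the factorial simulation study.

    ``total_steps`` counts simulated time points (initial plus 20 updates);
    ``replicates`` is the number of GA fits per generated data set and
    ``datasets`` the number of independently generated data sets per cell.
    """

    sizes: tuple = (4, 10, 20, 50)
    degrees: tuple = (2, 5, 9)
    self_weights: tuple = (0.1, 0.5, 0.8)
    time_steps: tuple = (2, 3, 6, 11)
    missingness: tuple = (0.0, 0.1, 0.25, 0.5)
    total_steps: int = 21
    replicates: int = 10
    datasets: int = 1
    concentration: float = 10.0

    def feasible_cells(self):
        """All factor combinations that are mathematically possible.

        A target degree must be below the network size, and a missingness
        level is only usable when the required number of masked entries
        leaves every agent at least one observed non-initial entry
        (minimum two observations per agent); with T = 2 any positive
        missingness is excluded.
        """
        for n, d, sw, T, miss in itertools.product(
            self.sizes, self.degrees, self.self_weights,
            self.time_steps, self.missingness,
        ):
            if d >= n:
                continue
            if not missingness_feasible(n, T, miss):
                continue
            yield n, d, sw, T, miss


def missingness_feasible(n: int, T: int, prop: float) -> bool:
    if prop == 0:
        return True
    if T <= 2:
        return False
    return int(np.floor(prop * n * (T - 1))) <= n * (T - 2)


@dataclass(frozen=True)
class SimulatedDataset:
    """One generated study instance: truth plus the masked observed data."""

    network: Network
    true_weights: WeightMatrix
    full_trajectory: OpinionTrajectory
    observed: OpinionTrajectory
    design_point: dict


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _er_batch_degrees(n: int, p: float, batch: int, rng: np.random.Generator):
    """Generate a batch of ER graphs, returning the upper-triangle edge
    draws plus the indices of graphs that are connected."""
    iu, ju = np.triu_indices(n, 1)
    edges = rng.random((batch, iu.size)) < p
    # node degrees via the edge-node incidence matrix (fast for big batches)
    incidence = np.zeros((iu.size, n))
    incidence[np.arange(iu.size), iu] = 1.0
    incidence[np.arange(iu.size), ju] = 1.0
    deg = (edges @ incidence).astype(np.int64)
    # quick pre-filter: a connected graph has no isolated vertex
    candidates = np.flatnonzero((deg > 0).all(axis=1))
    accepted = []
    for b in candidates:
        adj = np.zeros((n, n), dtype=np.int8)
        adj[iu, ju] = edges[b]
        adj |= adj.T
        if connected_components(adj, directed=False, return_labels=False) == 1:
            accepted.append(b)
    return edges, deg, accepted


def generate_connected_er(n: int, target_degree: int,
                          rng: np.random.Generator) -> Network:
    """Erdos-Renyi network with p = d/(n-1), conditioned on connectivity.

    Whole graphs are resampled until connected; the conditioning inflates
    the realised mean degree above the target, most visibly for sparse
    graphs.  The returned adjacency carries a unit diagonal.
    """
    if target_degree >= n:
        raise ValueError("target degree must be below the network size")
    p = target_degree / (n - 1)
    iu, ju = np.triu_indices(n, 1)
    batch = 64
    while True:
        edges, _, accepted = _er_batch_degrees(n, p, batch, rng)
        if accepted:
            b = accepted[0]
            adj = np.eye(n, dtype=np.int8)
            adj[iu, ju] = edges[b]
            adj[ju, iu] = edges[b]
            return Network(adj)
        batch = min(batch * 2, 8192)


def sample_connected_er_degrees(n: int, target_degree: int, n_graphs: int,
                                rng: np.random.Generator) -> np.ndarray:
    """Node degrees (self-loops excluded) pooled over ``n_graphs`` accepted
    connected ER graphs; vectorised for the sparse regimes where
    acceptance is rare."""
    if target_degree >= n:
        raise ValueError("target degree must be below the network size")
    p = target_degree / (n - 1)
    out = []
    got = 0
    batch = max(256, min(n_graphs * 4, 20000))
    while got < n_graphs:
        edges, deg, accepted = _er_batch_degrees(n, p, batch, rng)
        for b in accepted:
            out.append(deg[b])
            got += 1
            if got >= n_graphs:
                break
    return np.concatenate(out) if n > 1 else np.zeros(0)


def generate_weights(network: Network, target_self_weight: float,
                     concentration: float = 10.0,
                     rng: np.random.Generator | None = None) -> WeightMatrix:
    """Random weight matrix around a target self-weight.

    Each diagonal entry is drawn from Beta(kappa*target, kappa*(1-target))
    with kappa the concentration, so its mean equals the target; the
    remaining ``1 - w_ii`` is spread over the row's network neighbours via
    a flat Dirichlet.  Agents without neighbours get w_ii = 1.
    """
    if not 0 < target_self_weight < 1:
        raise ValueError("target self-weight must lie strictly in (0, 1)")
    rng = rng if rng is not None else np.random.default_rng()
    n = network.n_agents
    a = concentration * target_self_weight
    b = concentration * (1.0 - target_self_weight)
    w = np.zeros((n, n))
    for i in range(n):
        nb = np.flatnonzero(network.adjacency[i])
        nb = nb[nb != i]
        if nb.size == 0:
            w[i, i] = 1.0
            continue
        w[i, i] = rng.beta(a, b)
        w[i, nb] = rng.dirichlet(np.ones(nb.size)) * (1.0 - w[i, i])
    return WeightMatrix(w, network)


def simulate_dataset(w: WeightMatrix, total_steps: int = 20,
                     rng: np.random.Generator | None = None) -> OpinionTrajectory:
    """Full trajectory from Unif(0, 1) initial opinions: columns
    ``0..total_steps`` of the exact DeGroot recursion."""
    rng = rng if rng is not None else np.random.default_rng()
    x0 = rng.uniform(0.0, 1.0, size=w.n_agents)
    return simulate_diffusion(w, x0, total_steps)


def apply_missingness(traj: OpinionTrajectory, T: int, prop: float,
                      rng: np.random.Generator) -> OpinionTrajectory:
    """Observed data set: first T columns with ``floor(prop*N*(T-1))``
    uniformly chosen non-initial entries masked.

    The initial column stays fully observed and every agent keeps at least
    one observed non-initial entry (at least two observations in total).
    Masked sets are drawn by rejection; if the constraint makes uniform
    rejection hopeless, one observed slot per agent is reserved uniformly
    at random and the mask drawn over the remainder.
    """
    if not 0 <= prop < 1:
        raise ValueError("missingness proportion must lie in [0, 1)")
    if T < 2 or T > traj.n_times:
        raise ValueError("T must lie in [2, trajectory length]")
    if not missingness_feasible(traj.n_agents, T, prop):
        raise ValueError(f"missingness {prop} infeasible with T={T}")
    n = traj.n_agents
    values = traj.values[:, :T].copy()
    mask = traj.observed[:, :T].copy()
    m = int(np.floor(prop * n * (T - 1)))
    if m == 0:
        return OpinionTrajectory(values, mask)
    slots = [(i, t) for i in range(n) for t in range(1, T)]
    chosen = None
    for _ in range(200):
        pick = rng.choice(len(slots), size=m, replace=False)
        hit = np.zeros(n, dtype=np.int64)
        for s in pick:
            hit[slots[s][0]] += 1
        if (hit <= T - 2).all():
            chosen = pick
            break
    if chosen is None:
        # reserve one observed non-initial slot per agent, mask among the rest
        reserved = {(i, int(rng.integers(1, T))) for i in range(n)}
        free = [s for s in range(len(slots)) if slots[s] not in reserved]
        chosen = rng.choice(len(free), size=m, replace=False)
        chosen = [free[c] for c in chosen]
    for s in chosen:
        i, t = slots[s]
        mask[i, t] = False
    return OpinionTrajectory(values, mask)


# ---------------------------------------------------------------------------
# error metrics
# ---------------------------------------------------------------------------


def rmse_fit(pred: OpinionTrajectory, truth: OpinionTrajectory, T: int) -> float:
    """RMSE over the time steps provided to the algorithm, t = 0..T-1,
    against the complete truth (missing-data masks are ignored) with
    denominator N(T-1); predictions seeded at x(0) contribute nothing at
    t = 0, so the divisor counts the informative terms."""
    if T < 2:
        raise ValueError("rmse_fit needs T >= 2")
    n = truth.n_agents
    d = pred.values[:, :T] - truth.values[:, :T]
    return float(np.sqrt((d * d).sum() / (n * (T - 1))))


def rmse_ext(pred: OpinionTrajectory, truth: OpinionTrajectory, T: int) -> float:
    """RMSE over the extrapolated time steps t = T..20 with denominator
    N(21-T); the truth must carry all 21 columns."""
    total = truth.n_times
    if T >= total:
        raise ValueError("no extrapolated time steps beyond T")
    n = truth.n_agents
    d = pred.values[:, T:total] - truth.values[:, T:total]
    return float(np.sqrt((d * d).sum() / (n * (total - T))))


def rmse_rec(estimated: WeightMatrix, truth: WeightMatrix,
             network: Network) -> float:
    """Recovery RMSE over the P entries not structurally fixed at zero
    (P = sum of the adjacency, self-loops included)."""
    if estimated.n_agents != truth.n_agents or truth.n_agents != network.n_agents:
        raise ValueError("mismatched sizes")
    mask = network.adjacency == 1
    d = estimated.weights[mask] - truth.weights[mask]
    return float(np.sqrt((d * d).sum() / mask.sum()))


# ---------------------------------------------------------------------------
# factorial driver
# ---------------------------------------------------------------------------


def make_dataset(n: int, d: int, sw: float, T: int, miss: float,
                 rng: np.random.Generator, total_steps: int = 21,
                 concentration: float = 10.0) -> SimulatedDataset:
    """One study instance at a design point."""
    network = generate_connected_er(n, d, rng)
    w = generate_weights(network, sw, concentration, rng)
    full = simulate_dataset(w, total_steps - 1, rng)
    obs = apply_missingness(full, T, miss, rng)
    return SimulatedDataset(
        network=network, true_weights=w, full_trajectory=full, observed=obs,
        design_point={"size": n, "degree": d, "self_weight": sw,
                      "time_steps": T, "missingness": miss},
    )


def run_factorial(design: StudyDesign, ga_config: GAConfig | None = None,
                  seed: int = 0, out_dir=None) -> pd.DataFrame:
    """Run the factorial study: per feasible cell, ``datasets`` generated
    data sets and ``replicates`` GA fits on each; returns one row per fit.

    Cell-level randomness is derived from ``seed`` through a spawned
    SeedSequence so cells are independent and the whole run reproducible.
    Infeasible cells are skipped with a logged reason.
    """
    ga_config = ga_config or GAConfig()
    rows = []
    ss = np.random.SeedSequence(seed)
    cells = list(design.feasible_cells())
    child_seqs = ss.spawn(len(cells))
    for (cell, cseq) in zip(cells, child_seqs):
        n, d, sw, T, miss = cell
        dataset_seqs = cseq.spawn(design.datasets)
        for ds_i, dseq in enumerate(dataset_seqs):
            rng = np.random.default_rng(dseq)
            data = make_dataset(n, d, sw, T, miss, rng,
                                design.total_steps, design.concentration)
            run_seeds = dseq.generate_state(design.replicates + 1)[1:] % (2**31)
            for r, rseed in enumerate(run_seeds):
                res = fit(data.observed, data.network,
                          config=ga_config, objective="continuous",
                          seed=int(rseed))
                pred = simulate_diffusion(
                    res.weights, data.full_trajectory.values[:, 0],
                    design.total_steps - 1)
                rows.append({
                    "size": n, "degree": d, "self_weight": sw,
                    "time_steps": T, "missingness": miss,
                    "dataset": ds_i, "replicate": r,
                    "mean_degree": float(data.network.degrees().mean()),
                    "mean_self_weight": float(
                        data.true_weights.self_weights().mean()),
                    "rmse_fit": rmse_fit(pred, data.full_trajectory, T),
                    "rmse_ext": rmse_ext(pred, data.full_trajectory, T),
                    "rmse_rec": rmse_rec(res.weights, data.true_weights,
                                         data.network),
                    "objective": res.objective,
                    "iterations": res.iterations,
                    "seed": int(rseed),
                })
        logger.info("cell size=%d degree=%d sw=%.2f T=%d miss=%.2f done",
                    n, d, sw, T, miss)
    df = pd.DataFrame(rows)
    if out_dir is not None:
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / "runs.csv", index=False)
        summarize(df, ["time_steps", "missingness"]).to_csv(
            out_dir / "summary_by_time_missing.csv")
        summarize(df, ["size", "degree"]).to_csv(
            out_dir / "summary_by_size_degree.csv")
        summarize(df, ["self_weight"]).to_csv(
            out_dir / "summary_by_self_weight.csv")
    return df


def summarize(df: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
    """Median and IQR of the three RMSE measures keyed by design factors."""
    def iqr(x):
        q = np.percentile(x, [25, 75])
        return q[1] - q[0]

    return df.groupby(keys)[["rmse_fit", "rmse_ext", "rmse_rec"]].agg(
        ["median", iqr])
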