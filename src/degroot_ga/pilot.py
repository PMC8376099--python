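"""Application workflow for the network-intervention pilot design.

The pilot setting: small recruited social networks (4-12 members) in which
designated *network leaders* were trained to diffuse favourable opinions
about PrEP, with two composite Likert measures (willingness 3-15,
self-efficacy 8-32) assessed at baseline and three months later.  Because
friends likely interacted repeatedly between assessments, one DeGroot time
step is taken to be one month, so the observed data occupy t = 0 and t = 3
with t = 1, 2 treated as missing for everyone.

Network knowledge is partial: recruitment reveals some ties with certainty
and some absences with certainty.  Two bracketing adjacency matrices are
therefore analysed -- *build* (start from no ties, add the known ones) and
*remove* (start from all ties, delete the known absences).  The GA is run
repeatedly per network under the binned Likert objective; means and
standard deviations of estimated weights across runs quantify algorithmic
variability.

The raw pilot data are restricted, so :func:`generate_synthetic_pilot`
emulates their structure (ring-of-recruitment networks, seeds, leaders,
composite scores, sparse missingness) from a latent DeGroot process.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    SELF_EFFICACY_SCALE,
    WILLINGNESS_SCALE,
    LikertScale,
    Network,
    OpinionTrajectory,
    WeightMatrix,
    likert_back,
    likert_forward,
    bin_deviation,
    simulate_diffusion,
)
from .ga import FixedMask, GAConfig, fit

__all__ = [
    "PilotNetwork",
    "PilotMeasure",
    "MultiRunResult",
    "SyntheticPilotNetwork",
    "build_adjacency",
    "remove_adjacency",
    "impute_baseline",
    "expand_monthly",
    "fit_multi_run",
    "leader_summary",
    "generate_synthetic_pilot",
    "run_pilot",
]

logger = logging.getLogger(__name__)

#: weights above this are counted as practically non-zero in summaries
PRACTICAL_WEIGHT_THRESHOLD = 0.005

MEASURE_SCALES = {
    "willingness": WILLINGNESS_SCALE,
    "self_efficacy": SELF_EFFICACY_SCALE,
}


@dataclass(frozen=True)
class PilotNetwork:
    """Partial knowledge of one recruited network.

    ``known_edges`` are ties certain to exist (recruitment links),
    ``known_non_edges`` ties certain not to; agents are 0-based indices.
    """

    n_agents: int
    known_edges: frozenset
    known_non_edges: frozenset
    leaders: frozenset
    seed_agent: int

    def __post_init__(self) -> None:
        ke = frozenset(frozenset(e) for e in self.known_edges)
        kn = frozenset(frozenset(e) for e in self.known_non_edges)
        if ke & kn:
            raise ValueError("an edge cannot be both known present and absent")
        agents = set(range(self.n_agents))
        for pair in ke | kn:
            if not set(pair) <= agents or len(pair) != 2:
                raise ValueError("edge references an unknown agent")
        if self.seed_agent not in agents:
            raise ValueError("seed must be one of the agents")
        if not self.leaders:
            raise ValueError("at least one leader must be designated")
        if not set(self.leaders) <= agents:
            raise ValueError("leader references an unknown agent")
        object.__setattr__(self, "known_edges", ke)
        object.__setattr__(self, "known_non_edges", kn)
        object.__setattr__(self, "leaders", frozenset(self.leaders))


@dataclass(frozen=True)
class PilotMeasure:
    """Composite scores for one measure at baseline and follow-up.

    Scores are floats with NaN marking missing responses; present scores
    must be integers within the scale bounds.
    """

    name: str
    scale: LikertScale
    baseline: np.ndarray
    followup: np.ndarray

    def __post_init__(self) -> None:
        b = np.array(self.baseline, dtype=np.float64)
        f = np.array(self.followup, dtype=np.float64)
        if b.shape != f.shape or b.ndim != 1:
            raise ValueError("baseline and followup must be equal-length vectors")
        for arr in (b, f):
            present = arr[~np.isnan(arr)]
            if ((present < self.scale.min_score)
                    | (present > self.scale.max_score)).any():
                raise ValueError("scores outside the scale bounds")
            if (present != np.round(present)).any():
                raise ValueError("scores must be integers")
        object.__setattr__(self, "baseline", b)
        object.__setattr__(self, "followup", f)

    @property
    def n_agents(self) -> int:
        return self.baseline.shape[0]


@dataclass(frozen=True)
class MultiRunResult:
    """Aggregate of repeated GA runs on one network and measure."""

    mean_weights: np.ndarray
    sd_weights: np.ndarray
    rmse_alg: float
    rmse_fit_app: float
    run_objectives: np.ndarray
    run_weights: np.ndarray  # (n_runs, n, n)


# ---------------------------------------------------------------------------
# adjacency construction
# ---------------------------------------------------------------------------


def build_adjacency(pn: PilotNetwork) -> Network:
    """Lower-bound network: only the ties known to exist (plus self-loops)."""
    return Network.from_edges(pn.n_agents, [tuple(e) for e in pn.known_edges])


def remove_adjacency(pn: PilotNetwork) -> Network:
    """Upper-bound network: all ties except those known not to exist."""
    a = np.ones((pn.n_agents, pn.n_agents), dtype=np.int8)
    for e in pn.known_non_edges:
        i, j = tuple(e)
        a[i, j] = a[j, i] = 0
    return Network(a)


# ---------------------------------------------------------------------------
# measure preparation
# ---------------------------------------------------------------------------


def _lower_median(values: np.ndarray) -> float:
    """Median keeping the result on the integer scale: for an even count,
    the lower of the two middle values."""
    s = np.sort(values)
    return float(s[(s.size - 1) // 2])


def impute_baseline(measure: PilotMeasure) -> PilotMeasure:
    """Fill missing baselines from the agent's own follow-up where
    available, else the median baseline of the other agents.  Missing
    follow-ups stay missing."""
    b = measure.baseline.copy()
    missing = np.isnan(b)
    if missing.all():
        raise ValueError("cannot impute: all baselines missing")
    for i in np.flatnonzero(missing):
        if not np.isnan(measure.followup[i]):
            b[i] = measure.followup[i]
        else:
            others = measure.baseline[~np.isnan(measure.baseline)]
            b[i] = _lower_median(others)
    return PilotMeasure(measure.name, measure.scale, b, measure.followup)


def expand_monthly(measure: PilotMeasure) -> OpinionTrajectory:
    """Monthly time grid t = 0..3: transformed baselines at t = 0, the
    intermediate months fully missing, transformed follow-ups at t = 3
    (missing where the follow-up is missing).  Baselines must be complete
    (run :func:`impute_baseline` first)."""
    if np.isnan(measure.baseline).any():
        raise ValueError("baselines must be imputed before expansion")
    n = measure.n_agents
    values = np.zeros((n, 4))
    mask = np.zeros((n, 4), dtype=bool)
    values[:, 0] = likert_forward(measure.baseline.astype(np.int64),
                                  measure.scale)
    mask[:, 0] = True
    has_fu = ~np.isnan(measure.followup)
    fu = np.where(has_fu, measure.followup, measure.scale.min_score)
    values[:, 3] = likert_forward(fu.astype(np.int64), measure.scale)
    mask[:, 3] = has_fu
    return OpinionTrajectory(np.where(mask, values, 0.0), mask)


# ---------------------------------------------------------------------------
# multi-run fitting and summaries
# ---------------------------------------------------------------------------


def fit_multi_run(traj: OpinionTrajectory, network: Network,
                  config: GAConfig | None = None,
                  scale: LikertScale | None = None, n_runs: int = 10,
                  seed: int = 0, seeds=None) -> MultiRunResult:
    """Repeated GA fits under the binned Likert objective.

    Run r uses seed ``seed + r`` (or the explicit ``seeds`` sequence).
    Returns per-entry means and standard deviations (sample SD across
    runs; exactly 0 on fixed entries), the algorithmic-variability RMSE

        RMSE_alg = sqrt( sum_{i,j,r} (wbar_ij - what_ij,r)^2 / (R * sum a_ij) )

    and the application fit RMSE computed from the mean-weight predictions
    at the follow-up month,

        RMSE_fit = sqrt( sum_i B(xhat_i(3), x_i(3))^2 / (C N (T-1)) ),

    with C the bin count, T = 4 monthly columns and agents missing their
    follow-up contributing nothing.
    """
    if scale is None:
        raise ValueError("a Likert scale is required")
    if seeds is None:
        if n_runs < 2:
            raise ValueError("n_runs must be at least 2")
        seeds = [seed + r for r in range(n_runs)]
    seeds = list(seeds)
    n_runs = len(seeds)
    results = [
        fit(traj, network, config=config, objective="likert", scale=scale,
            seed=int(s))
        for s in seeds
    ]
    run_w = np.stack([r.weights.weights for r in results])
    mean_w = run_w.mean(axis=0)
    # where every run agrees the mean is that value exactly (avoids float
    # summation noise turning identical runs into spurious variability)
    same = (run_w == run_w[0]).all(axis=0)
    mean_w[same] = run_w[0][same]
    sd_w = run_w.std(axis=0, ddof=1) if n_runs > 1 else np.zeros_like(mean_w)
    sd_w[same] = 0.0  # fixed entries (identical across runs) included

    p = int(network.adjacency.sum())
    rmse_alg = float(np.sqrt(((run_w - mean_w) ** 2).sum() / (n_runs * p)))

    pred = simulate_diffusion(WeightMatrix(mean_w), traj.values[:, 0], 3)
    n = traj.n_agents
    dev2 = 0.0
    for i in range(n):
        if traj.observed[i, 3]:
            dev2 += bin_deviation(pred.values[i, 3], traj.values[i, 3],
                                  scale) ** 2
    rmse_fit_app = float(np.sqrt(dev2 / (scale.n_bins * n * 3)))

    return MultiRunResult(
        mean_weights=mean_w, sd_weights=sd_w, rmse_alg=rmse_alg,
        rmse_fit_app=rmse_fit_app,
        run_objectives=np.array([r.objective for r in results]),
        run_weights=run_w,
    )


def leader_summary(result: MultiRunResult, pn: PilotNetwork,
                   network: Network) -> pd.DataFrame:
    """Received-weight and self-weight summaries for leaders vs others.

    Received weights are the adjacency-allowed off-diagonal entries of the
    mean weight matrix, grouped by whether the *sender* (the agent whose
    opinion is weighted) is a leader; receiving agents not connected to
    any leader are excluded from both groups.  Counts and proportions use
    the strict threshold weight > 0.005.  Self-weight means and SDs cover
    all agents, split by leadership.
    """
    w = result.mean_weights
    n = pn.n_agents
    leaders = np.zeros(n, dtype=bool)
    leaders[list(pn.leaders)] = True
    a = network.adjacency
    connected_to_leader = np.array([
        any(a[i, j] and j != i for j in np.flatnonzero(leaders))
        for i in range(n)
    ])
    rows = []
    for is_leader in (True, False):
        senders = leaders if is_leader else ~leaders
        received = [
            w[i, j]
            for i in range(n)
            if connected_to_leader[i]
            for j in np.flatnonzero(senders)
            if j != i and a[i, j]
        ]
        received = np.array(received, dtype=float)
        selfw = np.diag(w)[leaders if is_leader else ~leaders]
        rows.append({
            "leader": is_leader,
            "self_weight_mean": float(selfw.mean()) if selfw.size else np.nan,
            "self_weight_sd": (float(selfw.std(ddof=1))
                               if selfw.size > 1 else np.nan),
            "mean_weight": float(received.mean()) if received.size else np.nan,
            "number": int((received > PRACTICAL_WEIGHT_THRESHOLD).sum()),
            "proportion": (
                float((received > PRACTICAL_WEIGHT_THRESHOLD).mean())
                if received.size else np.nan),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synthetic pilot generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticPilotNetwork:
    """A generated stand-in for one restricted pilot network: the partial
    network knowledge and measures the pipeline sees, plus the latent
    truth that produced them (for validation only)."""

    network: PilotNetwork
    measures: dict  # name -> PilotMeasure
    true_network: Network
    true_weights: WeightMatrix


def generate_synthetic_pilot(n_networks: int, rng: np.random.Generator,
                             leader_boost: float = 3.0,
                             self_weight: float = 0.5,
                             missing_prob: float = 0.05) -> list:
    """Generate synthetic pilot networks emulating the study's structure.

    Each network has 4-12 agents recruited in two rings from a seed: the
    seed names the first ring, whose members each name their second-ring
    recruits.  Recruitment ties are the known-present edges; a random
    subset of the truly absent ties is flagged known-absent.  The latent
    true network adds extra ties among members, and the latent weight
    matrix places ``leader_boost`` times more weight on leader neighbours
    than on others.  Leaders (including, usually, the seed) hold favourable
    baseline opinions; follow-ups arise from three DeGroot steps of the
    latent process, back-transformed to the composite scales, with a small
    fraction of responses missing.
    """
    if n_networks < 1:
        raise ValueError("need at least one network")
    out = []
    for _ in range(n_networks):
        n = int(rng.integers(4, 13))
        # two recruitment rings from the seed (agent 0)
        n_first = int(rng.integers(1, n - 1)) if n > 2 else 1
        first_ring = list(range(1, 1 + n_first))
        second_ring = list(range(1 + n_first, n))
        known_edges = {(0, j) for j in first_ring}
        for j in second_ring:
            known_edges.add((int(rng.choice(first_ring)), j))
        # leaders: one-eighth to one-third of the network, seed usually one
        n_leaders = max(1, int(np.ceil(n * rng.uniform(0.125, 1 / 3))))
        if rng.random() < 0.8:
            leaders = {0}
        else:
            leaders = set()
        while len(leaders) < n_leaders:
            leaders.add(int(rng.integers(0, n)))
        # latent truth: recruitment tree plus random extra ties
        adj = np.eye(n, dtype=np.int8)
        for i, j in known_edges:
            adj[i, j] = adj[j, i] = 1
        for i in range(n):
            for j in range(i + 1, n):
                if not adj[i, j] and rng.random() < 0.3:
                    adj[i, j] = adj[j, i] = 1
        true_net = Network(adj)
        # absences flagged known-absent with probability 1/2
        known_non_edges = {
            (i, j)
            for i in range(n) for j in range(i + 1, n)
            if not adj[i, j] and rng.random() < 0.5
        }
        pn = PilotNetwork(n, frozenset(known_edges),
                          frozenset(known_non_edges), frozenset(leaders), 0)
        # latent weights with boosted mass on leader neighbours
        w = np.zeros((n, n))
        for i in range(n):
            nb = np.flatnonzero(adj[i])
            nb = nb[nb != i]
            if nb.size == 0:
                w[i, i] = 1.0
                continue
            w[i, i] = rng.beta(10 * self_weight, 10 * (1 - self_weight))
            raw = rng.dirichlet(np.ones(nb.size))
            boost = np.array([leader_boost if j in leaders else 1.0
                              for j in nb])
            raw = raw * boost
            w[i, nb] = raw / raw.sum() * (1.0 - w[i, i])
        true_w = WeightMatrix(w, true_net)

        measures = {}
        for name, scale in MEASURE_SCALES.items():
            nb_bins = scale.n_bins
            base = scale.min_score + rng.binomial(nb_bins - 1, 0.45, size=n)
            for j in leaders:  # favourable opinions among trained leaders
                base[j] = scale.min_score + rng.binomial(nb_bins - 1, 0.85)
            x0 = likert_forward(base, scale)
            x3 = simulate_diffusion(true_w, x0, 3).values[:, 3]
            follow = likert_back(x3, scale).astype(np.float64)
            baseline = base.astype(np.float64)
            miss_b = rng.random(n) < missing_prob
            if miss_b.all():
                miss_b[int(rng.integers(0, n))] = False
            baseline[miss_b] = np.nan
            follow[rng.random(n) < missing_prob] = np.nan
            measures[name] = PilotMeasure(name, scale, baseline, follow)
        out.append(SyntheticPilotNetwork(pn, measures, true_net, true_w))
    return out


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


def run_pilot(networks_and_measures, adjacency: str = "build",
              config: GAConfig | None = None, n_runs: int = 10,
              seed: int = 0):
    """Run the full application workflow over a list of
    ``(PilotNetwork, {name: PilotMeasure})`` pairs (or
    :class:`SyntheticPilotNetwork` records).

    Returns ``(summary, details)``: a tidy RMSE table (one row per network
    and measure) and a dict of per-(network, measure) results holding the
    :class:`MultiRunResult` and leader summary.
    """
    if adjacency not in ("build", "remove"):
        raise ValueError("adjacency must be 'build' or 'remove'")
    rows = []
    details = {}
    for k, item in enumerate(networks_and_measures):
        if isinstance(item, SyntheticPilotNetwork):
            pn, measures = item.network, item.measures
        else:
            pn, measures = item
        net = build_adjacency(pn) if adjacency == "build" else remove_adjacency(pn)
        for name, measure in measures.items():
            traj = expand_monthly(impute_baseline(measure))
            result = fit_multi_run(
                traj, net, config=config, scale=measure.scale,
                n_runs=n_runs, seed=seed + 1000 * k)
            summary = leader_summary(result, pn, net)
            details[(k, name)] = {"result": result, "leader_summary": summary,
                                  "network": net}
            rows.append({
                "network": k, "n_agents": pn.n_agents, "measure": name,
                "adjacency": adjacency, "rmse_alg": result.rmse_alg,
                "rmse_fit": result.rmse_fit_app,
            })
            logger.info("network %d measure %s (%s): rmse_alg=%.3f "
                        "rmse_fit=%.3f", k, name, adjacency,
                        result.rmse_alg, result.rmse_fit_app)
    return pd.DataFrame(rows), details
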