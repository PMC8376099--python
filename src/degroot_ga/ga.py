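"""Genetic algorithm for estimating DeGroot weight matrices.

The estimation problem: given an observed opinion trajectory (possibly with
missing entries and typically with far fewer observations than parameters)
and a network fixing which influence weights are structurally zero, find
the row-stochastic weight matrix ``W`` minimising an objective measuring
the deviation between predicted and observed opinions.

A *chromosome* is a candidate weight matrix; a *gene* is one of its rows
(one agent's influence profile).  Because the objective decomposes by
agent, fitness can be assessed per gene, which the algorithm exploits with
a gene-swapping operator on top of the classical selection-with-elitism,
blending, within-gene crossover, mutation and survival operators adapted
from genetic algorithms for constrained mixture designs.  Crossover and
mutation probabilities and the mutation scale anneal multiplicatively
after stretches of stagnation, while the blending probability grows, and a
periodically reintroduced chromosome (an elite clone or the identity-like
diagonal matrix) replaces the worst solution.

The hot loop lives in :mod:`degroot_ga._kernels` (numba-compiled); the
functions here provide the object-level API and share those kernels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from . import _kernels
from .core import (
    LikertScale,
    Network,
    OpinionTrajectory,
    WeightMatrix,
    ROW_SUM_TOL,
)

__all__ = [
    "FixedMask",
    "Chromosome",
    "GAConfig",
    "GAState",
    "FitResult",
    "init_population",
    "evaluate",
    "gene_swap",
    "select_elite",
    "blend",
    "blend_genes",
    "crossover",
    "mutate",
    "mutate_gene_values",
    "survival",
    "adapt_hyperparameters",
    "reintroduce",
    "fit",
]

logger = logging.getLogger(__name__)

_OBJ_CODES = {"continuous": _kernels.OBJ_CONTINUOUS, "likert": _kernels.OBJ_LIKERT}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixedMask:
    """Entries of ``W`` constrained a priori.

    ``fixed[i, j]`` marks entry (i, j) as held at ``values[i, j]``; chiefly
    these are the zeros induced by absent network ties, but known weights
    can be pinned too.  Within each row the fixed values must leave
    positive mass for the free entries unless the entire row is fixed, in
    which case the fixed values must sum to one.
    """

    fixed: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        f = np.array(self.fixed, dtype=bool)
        v = np.array(self.values, dtype=np.float64)
        if f.shape != v.shape or f.ndim != 2 or f.shape[0] != f.shape[1]:
            raise ValueError("fixed mask and values must be square and matching")
        if v[~f].any():
            raise ValueError("fixed_values must be 0 on non-fixed entries")
        if ((v < 0) | (v > 1)).any():
            raise ValueError("fixed values must lie in [0, 1]")
        row_fixed = np.where(f, v, 0.0).sum(axis=1)
        whole = f.all(axis=1)
        if (np.abs(row_fixed[whole] - 1.0) > 1e-9).any():
            raise ValueError("a fully fixed row must have fixed values summing to 1")
        if (row_fixed[~whole] >= 1.0 - 1e-12).any():
            raise ValueError(
                "fixed values must leave positive mass for the free entries"
            )
        object.__setattr__(self, "fixed", f)
        object.__setattr__(self, "values", v)

    @property
    def n_agents(self) -> int:
        return self.fixed.shape[0]

    @classmethod
    def from_network(cls, network: Network, extra_fixed=None,
                     extra_values=None) -> "FixedMask":
        """Zeros wherever the adjacency is zero, plus optional extra pins."""
        f = network.adjacency == 0
        v = np.zeros_like(f, dtype=np.float64)
        if extra_fixed is not None:
            extra_fixed = np.asarray(extra_fixed, dtype=bool)
            f = f | extra_fixed
            if extra_values is not None:
                v = np.where(extra_fixed, np.asarray(extra_values, float), v)
        return cls(f, v)

    def row_fixed_sums(self) -> np.ndarray:
        """w_fixed,i: the per-row total of fixed weight."""
        return np.where(self.fixed, self.values, 0.0).sum(axis=1)

    def free_layout(self) -> tuple[np.ndarray, np.ndarray]:
        """Padded (indices, counts) arrays of free entries per row, as the
        kernels expect."""
        n = self.n_agents
        idx = np.zeros((n, n), dtype=np.int64)
        cnt = np.zeros(n, dtype=np.int64)
        for i in range(n):
            free = np.flatnonzero(~self.fixed[i])
            cnt[i] = free.size
            idx[i, : free.size] = free
        return idx, cnt

    def diagonal_chromosome(self) -> np.ndarray:
        """The self-reliant matrix: 1 - w_fixed,i on each free diagonal,
        zero on the other free entries.  If a diagonal entry is itself
        fixed, the remaining mass is spread evenly over the row's free
        entries instead."""
        n = self.n_agents
        w = np.where(self.fixed, self.values, 0.0)
        rfs = self.row_fixed_sums()
        for i in range(n):
            free = np.flatnonzero(~self.fixed[i])
            if free.size == 0:
                continue
            if not self.fixed[i, i]:
                w[i, i] = 1.0 - rfs[i]
            else:
                w[i, free] = (1.0 - rfs[i]) / free.size
        return w


@dataclass(frozen=True, eq=False)
class Chromosome:
    """A candidate weight matrix with cached objective values.

    ``gene_objectives[i]`` is the objective contribution of agent i under
    this chromosome's own predicted trajectory; ``total_objective`` is
    their sum.  Both are ``None`` until :func:`evaluate` fills them.
    """

    weights: np.ndarray
    fixed: FixedMask
    gene_objectives: np.ndarray | None = None
    total_objective: float | None = None

    def __post_init__(self) -> None:
        w = np.array(self.weights, dtype=np.float64)
        object.__setattr__(self, "weights", w)

    @property
    def evaluated(self) -> bool:
        return self.total_objective is not None

    def weight_matrix(self) -> WeightMatrix:
        return WeightMatrix(self.weights)


def _table1():
    # Hyperparameter defaults shared by the simulation study and the
    # application runs.
    return dict(
        chromosomes=21,
        probb=0.01, factorb=2.0, maxb=0.2, iterb=1000,
        probc=0.2, factorc=0.5, minc=0.0, iterc=1000,
        probm=0.2, factorm=0.5, minm=0.01, iterm=1000,
        sigma=1.0, factors=0.5, mins=0.001, iters=2000,
        max_iter=1_000_000, min_improve=0.0, min_dev=0.0,
        reintroduce="elite", iterr=2500,
    )


@dataclass(frozen=True)
class GAConfig:
    """GA hyperparameters.

    Field names match the configuration-file keys: ``probb/factorb/maxb/
    iterb`` control the blending probability (initial value, multiplicative
    step, cap, stagnation span), the ``c``/``m`` groups the crossover and
    mutation probabilities (with floors ``minc``/``minm``), and ``sigma/
    factors/mins/iters`` the mutation standard deviation.  ``min_improve``
    is the smallest decrease of the best objective that counts as
    improvement, ``min_dev`` the objective level at which the run stops
    early, and ``reintroduce``/``iterr`` select what replaces the worst
    chromosome after ``iterr`` stagnant iterations ("elite" clone or the
    "diagonal" self-reliant matrix).
    """

    chromosomes: int = 21
    probb: float = 0.01
    factorb: float = 2.0
    maxb: float = 0.2
    iterb: int = 1000
    probc: float = 0.2
    factorc: float = 0.5
    minc: float = 0.0
    iterc: int = 1000
    probm: float = 0.2
    factorm: float = 0.5
    minm: float = 0.01
    iterm: int = 1000
    sigma: float = 1.0
    factors: float = 0.5
    mins: float = 0.001
    iters: int = 2000
    max_iter: int = 1_000_000
    min_improve: float = 0.0
    min_dev: float = 0.0
    reintroduce: str = "elite"
    iterr: int = 2500

    def __post_init__(self) -> None:
        if self.chromosomes < 2:
            raise ValueError("need at least 2 chromosomes")
        for name in ("probb", "probc", "probm"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.reintroduce not in ("elite", "diagonal"):
            raise ValueError("reintroduce must be 'elite' or 'diagonal'")

    @classmethod
    def from_dict(cls, d: dict) -> "GAConfig":
        base = _table1()
        unknown = set(d) - set(base)
        if unknown:
            raise ValueError(f"unknown hyperparameter keys: {sorted(unknown)}")
        base.update(d)
        for k in ("chromosomes", "iterb", "iterc", "iterm", "iters",
                  "max_iter", "iterr"):
            base[k] = int(base[k])
        return cls(**base)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GAState:
    """Current adapted hyperparameter values and stagnation counters."""

    iteration: int = 0
    current_pb: float = 0.01
    current_pc: float = 0.2
    current_pm: float = 0.2
    current_sigma: float = 1.0
    counters: dict = field(
        default_factory=lambda: {"b": 0, "c": 0, "m": 0, "s": 0, "r": 0}
    )
    best_objective_history: list = field(default_factory=list)
    rng_seed: int | None = None

    @classmethod
    def from_config(cls, config: GAConfig, seed: int | None = None) -> "GAState":
        return cls(
            current_pb=config.probb,
            current_pc=config.probc,
            current_pm=config.probm,
            current_sigma=config.sigma,
            rng_seed=seed,
        )


@dataclass(frozen=True)
class FitResult:
    """Outcome of a GA run."""

    weights: WeightMatrix
    objective: float
    gene_objectives: np.ndarray
    iterations: int
    history: list  # [(iteration, best objective)] at each improvement
    adaptations: list  # [(iteration, quantity, new value)]
    state: GAState
    config: GAConfig
    seed: int | None


# ---------------------------------------------------------------------------
# population setup and evaluation
# ---------------------------------------------------------------------------


def _check_network_fixed(network: Network, fixed: FixedMask) -> None:
    if fixed.n_agents != network.n_agents:
        raise ValueError("network and fixed mask sizes differ")
    if not fixed.fixed[network.adjacency == 0].all():
        raise ValueError("entries absent from the network must be fixed at 0")
    if fixed.values[network.adjacency == 0].any():
        raise ValueError("entries absent from the network must be fixed at 0")


def init_population(network: Network, fixed: FixedMask, config: GAConfig,
                    rng: np.random.Generator) -> list[Chromosome]:
    """Initial population: the diagonal (self-reliant) chromosome plus
    ``chromosomes - 1`` random ones whose free row entries are drawn from a
    flat Dirichlet scaled to the free mass ``1 - w_fixed,i``."""
    _check_network_fixed(network, fixed)
    n = network.n_agents
    rfs = fixed.row_fixed_sums()
    base = np.where(fixed.fixed, fixed.values, 0.0)
    pop = [Chromosome(fixed.diagonal_chromosome(), fixed)]
    for _ in range(config.chromosomes - 1):
        w = base.copy()
        for i in range(n):
            free = np.flatnonzero(~fixed.fixed[i])
            if free.size == 0:
                continue
            w[i, free] = rng.dirichlet(np.ones(free.size)) * (1.0 - rfs[i])
        pop.append(Chromosome(w, fixed))
    return pop


def _obj_setup(objective: str, scale: LikertScale | None):
    if objective not in _OBJ_CODES:
        raise ValueError("objective must be 'continuous' or 'likert'")
    if objective == "likert":
        if scale is None:
            raise ValueError("the likert objective requires a scale")
        return _kernels.OBJ_LIKERT, scale.n_bins
    return _kernels.OBJ_CONTINUOUS, 1


def evaluate(chrom: Chromosome, obs: OpinionTrajectory, objective: str = "continuous",
             scale: LikertScale | None = None) -> Chromosome:
    """Fill a chromosome's per-gene and total objective values.

    Predictions are seeded at the observed initial opinions, so the t = 0
    terms vanish; masked entries contribute nothing.
    """
    obs.require_initial_observed()
    code, n_bins = _obj_setup(objective, scale)
    gene = np.empty(chrom.weights.shape[0])
    total = _kernels.evaluate(chrom.weights, obs.values, obs.observed,
                              code, n_bins, gene)
    return replace(chrom, gene_objectives=gene, total_objective=float(total))


def _stack(chroms: list[Chromosome]):
    pop = np.stack([c.weights for c in chroms]).astype(np.float64)
    gene = np.stack([c.gene_objectives for c in chroms]).astype(np.float64)
    totals = np.array([c.total_objective for c in chroms], dtype=np.float64)
    return pop, gene, totals


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------


def gene_swap(best: Chromosome, others: list[Chromosome], obs: OpinionTrajectory,
              objective: str = "continuous", scale: LikertScale | None = None):
    """Swap fitter genes from ``others`` into ``best``, en bloc.

    Per gene, the donor is the chromosome holding the strictly fittest
    corresponding gene (in its own context); donated genes are exchanged,
    not copied.  All swaps are kept iff the modified best chromosome
    improves strictly, otherwise everything is reverted.  Returns
    ``(best, others, accepted)``.
    """
    if not others:
        return best, [], False
    chroms = [best] + list(others)
    for c in chroms:
        if not c.evaluated:
            raise ValueError("gene_swap requires evaluated chromosomes")
    code, n_bins = _obj_setup(objective, scale)
    pop, gene, totals = _stack(chroms)
    accepted = bool(
        _kernels.elite_gene_swap(pop, gene, totals, 0, obs.values,
                                 obs.observed, code, n_bins)
    )
    if not accepted:
        return best, list(others), False
    out = [
        Chromosome(pop[k], chroms[k].fixed, gene[k], float(totals[k]))
        for k in range(len(chroms))
    ]
    return out[0], out[1:], True


def select_elite(population: list[Chromosome]):
    """Identify the elite (lowest total objective, ties to the lowest
    index); returns ``(elite, non_elite)``."""
    totals = [c.total_objective for c in population]
    if any(t is None for t in totals):
        raise ValueError("select_elite requires an evaluated population")
    e = int(np.argmin(totals))  # argmin takes the first minimum on ties
    return population[e], population[:e] + population[e + 1 :]


def blend_genes(b_row, c_row, beta: float, fixed: FixedMask, i: int):
    """Deterministic blending of gene i of two chromosomes: the free
    entries become beta*B + (1-beta)*C and (1-beta)*B + beta*C."""
    b = np.array(b_row, dtype=np.float64)
    c = np.array(c_row, dtype=np.float64)
    idx, cnt = fixed.free_layout()
    _kernels.blend_gene(b, c, float(beta), idx[i], cnt[i])
    return b, c


def blend(pair: tuple[Chromosome, Chromosome], p_b: float,
          rng: np.random.Generator) -> tuple[Chromosome, Chromosome]:
    """Blend a chromosome pair: independently per gene, with probability
    ``p_b``, replace the gene pair by beta-weighted averages with
    beta ~ Unif(0, 1).  Fixed entries are untouched."""
    a, b = pair
    wa = a.weights.copy()
    wb = b.weights.copy()
    idx, cnt = a.fixed.free_layout()
    for i in range(wa.shape[0]):
        if cnt[i] > 0 and rng.random() < p_b:
            beta = rng.random()
            _kernels.blend_gene(wa[i], wb[i], beta, idx[i], cnt[i])
    return (Chromosome(wa, a.fixed), Chromosome(wb, b.fixed))


def crossover(chrom: Chromosome, p_c: float,
              rng: np.random.Generator) -> Chromosome:
    """Within-gene crossover: independently per gene, with probability
    ``p_c``, uniformly permute the free weights among the free positions.
    Row sums and fixed entries are preserved exactly."""
    w = chrom.weights.copy()
    idx, cnt = chrom.fixed.free_layout()
    for i in range(w.shape[0]):
        if cnt[i] > 1 and rng.random() < p_c:
            _kernels.crossover_gene(w[i], idx[i], cnt[i], rng)
    return Chromosome(w, chrom.fixed)


def mutate_gene_values(row, fixed: FixedMask, i: int, selected: int,
                       eps: float) -> np.ndarray:
    """Deterministic mutation of gene i: perturb the ``selected``-th free
    weight by ``eps`` and renormalise per the boundary rules (see
    :func:`degroot_ga._kernels.mutate_gene`)."""
    out = np.array(row, dtype=np.float64)
    idx, cnt = fixed.free_layout()
    if not 0 <= selected < cnt[i]:
        raise ValueError("selected free-weight index out of range")
    _kernels.mutate_gene(out, idx[i], cnt[i], fixed.row_fixed_sums()[i],
                         selected, float(eps))
    return out


def mutate(chrom: Chromosome, p_m: float, sigma: float, fixed: FixedMask,
           rng: np.random.Generator) -> Chromosome:
    """Mutation: independently per gene, with probability ``p_m``, add a
    N(0, sigma^2) perturbation to one uniformly chosen free weight and
    renormalise the row.  Genes without free choice are skipped."""
    w = chrom.weights.copy()
    idx, cnt = fixed.free_layout()
    rfs = fixed.row_fixed_sums()
    for i in range(w.shape[0]):
        if cnt[i] > 1 and rng.random() < p_m:
            sel = int(rng.integers(0, cnt[i]))
            eps = float(rng.normal(0.0, sigma))
            _kernels.mutate_gene(w[i], idx[i], cnt[i], rfs[i], sel, eps)
    return Chromosome(w, chrom.fixed)


def survival(parents: list[Chromosome], offspring: list[Chromosome],
             obs: OpinionTrajectory, objective: str = "continuous",
             scale: LikertScale | None = None) -> list[Chromosome]:
    """Keep the fitter of each parent/offspring pair (ties keep the
    parent), then gene-swap each retained chromosome against its rejected
    counterpart under the same accept-or-revert-all rule."""
    if len(parents) != len(offspring):
        raise ValueError("parents and offspring must pair up")
    code, n_bins = _obj_setup(objective, scale)
    out = []
    for par, off in zip(parents, offspring):
        if not par.evaluated:
            par = evaluate(par, obs, objective, scale)
        if not off.evaluated:
            off = evaluate(off, obs, objective, scale)
        if off.total_objective < par.total_objective:
            ret, rej = off, par
        else:
            ret, rej = par, off
        w = ret.weights.copy()
        g = ret.gene_objectives.copy()
        total = _kernels.pairwise_gene_swap(
            w, g, ret.total_objective, rej.weights, rej.gene_objectives,
            obs.values, obs.observed, code, n_bins)
        out.append(Chromosome(w, ret.fixed, g, float(total)))
    return out


def adapt_hyperparameters(state: GAState, config: GAConfig,
                          improved: bool = False) -> GAState:
    """Advance the adaptation schedule by one iteration.

    On improvement every stagnation counter resets.  Otherwise all
    counters advance and any that reaches its span triggers its
    multiplicative adjustment (p_b up to ``maxb``; p_c, p_m and sigma down
    to their floors) and resets.
    """
    new = GAState(
        iteration=state.iteration + 1,
        current_pb=state.current_pb,
        current_pc=state.current_pc,
        current_pm=state.current_pm,
        current_sigma=state.current_sigma,
        counters=dict(state.counters),
        best_objective_history=list(state.best_objective_history),
        rng_seed=state.rng_seed,
    )
    if improved:
        for k in new.counters:
            new.counters[k] = 0
        return new
    for k in new.counters:
        new.counters[k] += 1
    if new.counters["b"] >= config.iterb:
        new.current_pb = min(new.current_pb * config.factorb, config.maxb)
        new.counters["b"] = 0
    if new.counters["c"] >= config.iterc:
        new.current_pc = max(new.current_pc * config.factorc, config.minc)
        new.counters["c"] = 0
    if new.counters["m"] >= config.iterm:
        new.current_pm = max(new.current_pm * config.factorm, config.minm)
        new.counters["m"] = 0
    if new.counters["s"] >= config.iters:
        new.current_sigma = max(new.current_sigma * config.factors, config.mins)
        new.counters["s"] = 0
    return new


def reintroduce(population: list[Chromosome], elite: Chromosome,
                fixed: FixedMask, config: GAConfig) -> list[Chromosome]:
    """Replace the worst chromosome (highest total objective) with a clone
    of the elite or with the diagonal chromosome, per
    ``config.reintroduce``.  Population size is unchanged."""
    totals = [c.total_objective for c in population]
    if any(t is None for t in totals):
        raise ValueError("reintroduce requires an evaluated population")
    worst = int(np.argmax(totals))
    out = list(population)
    if config.reintroduce == "elite":
        out[worst] = Chromosome(elite.weights.copy(), fixed,
                                None if elite.gene_objectives is None
                                else elite.gene_objectives.copy(),
                                elite.total_objective)
    else:
        out[worst] = Chromosome(fixed.diagonal_chromosome(), fixed)
    return out


# ---------------------------------------------------------------------------
# fitting driver
# ---------------------------------------------------------------------------

_ADAPT_NAMES = {
    _kernels.ADAPT_PB: "p_b",
    _kernels.ADAPT_PC: "p_c",
    _kernels.ADAPT_PM: "p_m",
    _kernels.ADAPT_SIGMA: "sigma",
    _kernels.ADAPT_REINTRODUCE: "reintroduce",
}


def fit(obs: OpinionTrajectory, network: Network,
        fixed: FixedMask | None = None, config: GAConfig | None = None,
        objective: str = "continuous", scale: LikertScale | None = None,
        seed: int | None = None) -> FitResult:
    """Estimate the weight matrix of a DeGroot process from observed data.

    Runs GA iterations -- elite identification, elite gene swap, blending
    over random pairs of non-elite chromosomes, crossover, mutation,
    survival with pairwise gene swap, hyperparameter adaptation and
    (last) the reintroduction check -- until the best objective reaches
    ``min_dev`` or ``max_iter`` iterations elapse.  The best objective is
    non-increasing across iterations and the whole run is reproducible
    from ``seed``.
    """
    config = config or GAConfig()
    if fixed is None:
        fixed = FixedMask.from_network(network)
    _check_network_fixed(network, fixed)
    if obs.n_agents != network.n_agents:
        raise ValueError("trajectory and network sizes differ")
    if obs.n_times < 2:
        raise ValueError("need at least 2 time steps to fit")
    obs.require_initial_observed()
    code, n_bins = _obj_setup(objective, scale)

    rng = np.random.default_rng(seed)
    pop = np.stack(
        [c.weights for c in init_population(network, fixed, config, rng)]
    )
    idx, cnt = fixed.free_layout()
    wfixed = fixed.row_fixed_sums()
    diag = fixed.diagonal_chromosome()

    (best_w, best_total, best_gene, iterations,
     imp_iters, imp_vals, ad_iters, ad_codes, ad_vals,
     pb, pc, pm, sig) = _kernels.ga_fit(
        pop, obs.values, obs.observed, idx, cnt, wfixed, diag,
        code, n_bins,
        config.probb, config.factorb, config.maxb, config.iterb,
        config.probc, config.factorc, config.minc, config.iterc,
        config.probm, config.factorm, config.minm, config.iterm,
        config.sigma, config.factors, config.mins, config.iters,
        config.max_iter, config.min_improve, config.min_dev,
        config.reintroduce == "elite", config.iterr,
        rng,
    )

    history = [(int(i), float(v)) for i, v in zip(imp_iters, imp_vals)]
    adaptations = [
        (int(i), _ADAPT_NAMES[int(c)], float(v))
        for i, c, v in zip(ad_iters, ad_codes, ad_vals)
    ]
    for i, v in history:
        logger.info("iter=%d best_objective=%.6g", i, v)
    for i, name, v in adaptations:
        logger.info("iter=%d adapted %s -> %.6g", i, name, v)

    state = GAState(
        iteration=int(iterations),
        current_pb=float(pb), current_pc=float(pc), current_pm=float(pm),
        current_sigma=float(sig),
        best_objective_history=[v for _, v in history],
        rng_seed=seed,
    )
    return FitResult(
        weights=WeightMatrix(best_w),
        objective=float(best_total),
        gene_objectives=np.asarray(best_gene),
        iterations=int(iterations),
        history=history,
        adaptations=adaptations,
        state=state,
        config=config,
        seed=seed,
    )
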