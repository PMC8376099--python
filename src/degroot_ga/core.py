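"""DeGroot forward model, objective functions, and Likert-scale transforms.

The DeGroot model describes opinion diffusion over a social network of
``N`` agents: at each time step every agent replaces its opinion with a
convex combination of the current opinions of itself and its network
neighbours,

    X(t+1) = W X(t),

where ``X(t)`` is the vector of opinions (each in ``[0, 1]``) and ``W`` is a
row-stochastic influence matrix.  ``w_ij`` is the weight agent ``i`` places
on the opinion of agent ``j``; it is structurally zero whenever ``i`` and
``j`` are not connected in the network, and the unit diagonal of the
adjacency matrix lets agents weight their own current opinion.

This module holds the domain containers (:class:`Network`,
:class:`WeightMatrix`, :class:`OpinionTrajectory`, :class:`LikertScale`),
the forward simulation, the two objective functions used for fitting
(a squared-deviation objective for continuous opinions and a binned
absolute-deviation objective for composite Likert measures), and the
forward/back transforms between an integer composite scale and the
continuous ``[0, 1]`` opinion scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Network",
    "WeightMatrix",
    "OpinionTrajectory",
    "LikertScale",
    "simulate_diffusion",
    "objective_continuous",
    "objective_continuous_agent",
    "objective_likert",
    "likert_forward",
    "likert_back",
    "bin_deviation",
]

#: absolute tolerance on row sums of a weight matrix
ROW_SUM_TOL = 1e-9
#: rows whose sum is within this of 1 are silently renormalised on input
ROW_SUM_RENORM = 1e-6
#: tie guard making the half-up rounding of bin midpoints exact in floating
#: point (the midpoint (k - 0.5)/n times n may land an ulp below k - 0.5)
_HALF_UP_EPS = 1e-12


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Network:
    """Undirected social network as a symmetric 0/1 adjacency matrix.

    The diagonal is all ones so that agents update on their own current
    opinions; ``adjacency[i, j] == 0`` forces the influence weight
    ``w_ij`` to zero.
    """

    adjacency: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if not (np.diag(a) == 1).all():
            raise ValueError("adjacency diagonal must be all ones")
        object.__setattr__(self, "adjacency", a.astype(np.int8))

    @property
    def n_agents(self) -> int:
        return self.adjacency.shape[0]

    def degrees(self) -> np.ndarray:
        """Node degrees, self-loops excluded."""
        return self.adjacency.sum(axis=1) - 1

    @classmethod
    def complete(cls, n: int) -> "Network":
        return cls(np.ones((n, n), dtype=np.int8))

    @classmethod
    def from_edges(cls, n: int, edges) -> "Network":
        """Build from an iterable of unordered agent-index pairs (0-based)."""
        a = np.eye(n, dtype=np.int8)
        for i, j in edges:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"edge ({i}, {j}) references unknown agent")
            a[i, j] = a[j, i] = 1
        return cls(a)


@dataclass(frozen=True)
class WeightMatrix:
    """Row-stochastic influence matrix of a DeGroot process.

    Entries lie in ``[0, 1]`` and every row sums to one within
    ``ROW_SUM_TOL``.  Rows whose sums deviate by at most ``ROW_SUM_RENORM``
    are renormalised on construction; larger deviations are rejected.  If a
    ``network`` is supplied, entries are additionally required to vanish
    wherever the adjacency does.
    """

    weights: np.ndarray
    network: Network | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        w = np.array(self.weights, dtype=np.float64)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if (w < -ROW_SUM_TOL).any() or (w > 1 + ROW_SUM_RENORM).any():
            raise ValueError("weights must lie in [0, 1]")
        sums = w.sum(axis=1)
        if (np.abs(sums - 1.0) > ROW_SUM_RENORM).any():
            raise ValueError("every row of a weight matrix must sum to 1")
        bad = np.abs(sums - 1.0) > ROW_SUM_TOL
        if bad.any():
            w[bad] = w[bad] / sums[bad, None]
        w = np.clip(w, 0.0, 1.0)
        if self.network is not None:
            if self.network.n_agents != w.shape[0]:
                raise ValueError("network size does not match weight matrix")
            if w[self.network.adjacency == 0].any():
                raise ValueError("weights must be zero where adjacency is zero")
        object.__setattr__(self, "weights", w)

    @property
    def n_agents(self) -> int:
        return self.weights.shape[0]

    def self_weights(self) -> np.ndarray:
        return np.diag(self.weights).copy()


@dataclass(frozen=True)
class OpinionTrajectory:
    """Agents x time grid of opinions in ``[0, 1]`` with a missingness mask.

    ``observed[i, t]`` is True where a value was actually recorded.  The
    initial column (t = 0) must be fully observed whenever the trajectory
    is used for fitting; masked cells carry no information and their stored
    value is arbitrary (kept at 0).
    """

    values: np.ndarray
    observed: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.array(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("values must be a 2-d (agents x times) array")
        obs = self.observed
        if obs is None:
            obs = np.ones(v.shape, dtype=bool)
        else:
            obs = np.array(obs, dtype=bool)
            if obs.shape != v.shape:
                raise ValueError("observed mask shape must match values")
        if ((v[obs] < 0) | (v[obs] > 1)).any():
            raise ValueError("observed opinions must lie in [0, 1]")
        v = np.where(obs, v, 0.0)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "observed", obs)

    @property
    def n_agents(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    def require_initial_observed(self) -> None:
        if not self.observed[:, 0].all():
            raise ValueError("initial opinions (t = 0) must all be observed")


@dataclass(frozen=True)
class LikertScale:
    """An integer composite scale ``min_score..max_score`` with one bin per
    attainable score.

    The pilot measures are composites of item-level Likert responses:
    willingness to use PrEP sums three 5-point items (scores 3..15, 13 bins)
    and PrEP self-efficacy sums eight 4-point items (scores 8..32, 25 bins).
    """

    min_score: int
    max_score: int

    def __post_init__(self) -> None:
        if self.max_score <= self.min_score:
            raise ValueError("max_score must exceed min_score")

    @property
    def n_bins(self) -> int:
        return self.max_score - self.min_score + 1


#: composite willingness-to-use-PrEP scale (three 5-point items)
WILLINGNESS_SCALE = LikertScale(3, 15)
#: composite PrEP self-efficacy scale (eight 4-point items)
SELF_EFFICACY_SCALE = LikertScale(8, 32)


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------


def simulate_diffusion(w: WeightMatrix, x0, n_steps: int) -> OpinionTrajectory:
    """Run the DeGroot update ``X(t+1) = W X(t)`` for ``n_steps`` steps.

    Returns a fully observed trajectory with columns ``0..n_steps``; column
    ``t`` equals ``W**t @ x0``.  Because each row of ``W`` is a convex
    combination, every column stays inside ``[min(x0), max(x0)]``.
    """
    x0 = np.asarray(x0, dtype=np.float64)
    if n_steps < 0:
        raise ValueError("n_steps must be non-negative")
    if x0.ndim != 1 or x0.shape[0] != w.n_agents:
        raise ValueError("x0 length must match the weight matrix")
    if ((x0 < 0) | (x0 > 1)).any():
        raise ValueError("initial opinions must lie in [0, 1]")
    out = np.empty((w.n_agents, n_steps + 1))
    out[:, 0] = x0
    for t in range(n_steps):
        out[:, t + 1] = w.weights @ out[:, t]
    return OpinionTrajectory(out)


# ---------------------------------------------------------------------------
# objective functions
# ---------------------------------------------------------------------------


def _check_shapes(pred: OpinionTrajectory, obs: OpinionTrajectory) -> None:
    if pred.values.shape != obs.values.shape:
        raise ValueError("predicted and observed trajectories differ in shape")


def objective_continuous(pred: OpinionTrajectory, obs: OpinionTrajectory) -> float:
    """Total squared-deviation objective f_C over observed entries.

    ``sum_i sum_t (xhat_i(t) - x_i(t))**2`` for ``t = 0..T-1``, restricted
    to entries observed in ``obs``.  When predictions are seeded at the
    observed initial opinions the ``t = 0`` terms vanish.
    """
    _check_shapes(pred, obs)
    d = np.where(obs.observed, pred.values - obs.values, 0.0)
    return float((d * d).sum())


def objective_continuous_agent(pred_row, obs_row, mask_row=None) -> float:
    """Per-agent (per-gene) squared-deviation objective over observed entries."""
    pred_row = np.asarray(pred_row, dtype=np.float64)
    obs_row = np.asarray(obs_row, dtype=np.float64)
    if pred_row.shape != obs_row.shape:
        raise ValueError("rows differ in length")
    if mask_row is None:
        mask_row = np.ones(pred_row.shape, dtype=bool)
    else:
        mask_row = np.asarray(mask_row, dtype=bool)
        if mask_row.shape != pred_row.shape:
            raise ValueError("mask length must match rows")
    d = np.where(mask_row, pred_row - obs_row, 0.0)
    return float((d * d).sum())


def objective_likert(
    pred: OpinionTrajectory, obs: OpinionTrajectory, scale: LikertScale
) -> float:
    """Binned absolute-deviation objective f_L for composite-scale data.

    ``sum_i sum_t B(xhat, x) * |xhat - x|`` over observed entries, where
    ``B`` counts the bins separating the back-transformed prediction and
    observation.  A prediction anywhere inside the correct bin incurs no
    penalty; the continuous deviation is not squared because ``B`` already
    penalises large deviations a second time.
    """
    _check_shapes(pred, obs)
    b = np.abs(
        likert_back(pred.values, scale).astype(np.int64)
        - likert_back(obs.values, scale).astype(np.int64)
    )
    term = b * np.abs(pred.values - obs.values)
    return float(np.where(obs.observed, term, 0.0).sum())


def objective_likert_agent(pred_row, obs_row, scale: LikertScale, mask_row=None) -> float:
    """Per-agent version of :func:`objective_likert`.

    Note the source material labels the agent-level objective f_C in both
    the continuous and composite-scale settings; this is the f_L analogue.
    """
    pred_row = np.asarray(pred_row, dtype=np.float64)
    obs_row = np.asarray(obs_row, dtype=np.float64)
    if pred_row.shape != obs_row.shape:
        raise ValueError("rows differ in length")
    if mask_row is None:
        mask_row = np.ones(pred_row.shape, dtype=bool)
    b = np.abs(
        likert_back(pred_row, scale).astype(np.int64)
        - likert_back(obs_row, scale).astype(np.int64)
    )
    term = b * np.abs(pred_row - obs_row)
    return float(np.where(np.asarray(mask_row, dtype=bool), term, 0.0).sum())


# ---------------------------------------------------------------------------
# Likert-scale transforms
# ---------------------------------------------------------------------------


def likert_forward(score, scale: LikertScale):
    """Map an integer composite score to the midpoint of its bin in (0, 1).

    With ``n`` bins and ``k = score - min_score + 1`` the value is
    ``(k - 0.5)/n`` -- the middle of the k-th of ``n`` equal sub-intervals
    of ``[0, 1]``.  Accepts scalars or arrays.
    """
    score = np.asarray(score)
    if ((score < scale.min_score) | (score > scale.max_score)).any():
        raise ValueError(
            f"score outside scale range [{scale.min_score}, {scale.max_score}]"
        )
    k = score - scale.min_score + 1
    out = (k - 0.5) / scale.n_bins
    return float(out) if out.ndim == 0 else out


def likert_back(y, scale: LikertScale):
    """Map a continuous opinion in ``[0, 1]`` back to an integer score.

    Multiplies by the bin count and rounds half-up, clamping the bin index
    to ``[1, n_bins]`` so the boundaries 0 and 1 map to the extreme scores.
    Half-up rounding guarantees bin midpoints round back to their own bin.
    Accepts scalars or arrays.
    """
    y = np.asarray(y, dtype=np.float64)
    if ((y < 0) | (y > 1)).any():
        raise ValueError("continuous opinions must lie in [0, 1]")
    k = np.floor(y * scale.n_bins + 0.5 + _HALF_UP_EPS)
    k = np.clip(k, 1, scale.n_bins)
    out = scale.min_score + k - 1
    return int(out) if out.ndim == 0 else out.astype(np.int64)


def bin_deviation(pred_y: float, obs_y: float, scale: LikertScale) -> int:
    """Absolute deviation, in bins, between two continuous opinions.

    Zero exactly when both back-transform to the same composite score
    (the prediction is "in the correct bin"); symmetric in its arguments.
    """
    return abs(likert_back(pred_y, scale) - likert_back(obs_y, scale))
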