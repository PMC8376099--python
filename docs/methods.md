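# Methods

## Model and estimation problem

The DeGroot process updates an opinion vector `X(t) ∈ [0,1]^N` by
`X(t+1) = W X(t)` with `W` row-stochastic and constrained to the network:
`w_ij = 0` whenever agents `i` and `j` share no tie, and the adjacency
diagonal is 1 so agents weight their own opinions.  Given observed
opinions at `T` time steps (possibly with missing entries), the estimate
minimises the squared-deviation objective

    f_C(Ŵ) = Σ_i Σ_{t=0}^{T-1} (x̂_i(t) − x_i(t))²

over observed entries, where the predicted trajectory is seeded at the
observed initial opinions (`x̂(0) = x(0)`, so the `t = 0` terms vanish)
and evolves by the candidate `Ŵ`.  Missing entries contribute nothing:
with predictions seeded at the observed baseline, this is the only
reading under which fitting with missing data is well defined.  For
composite Likert data the binned objective

    f_L(Ŵ) = Σ_i Σ_t B(x̂_i(t), x_i(t)) · |x̂_i(t) − x_i(t)|

is used instead, where `B` counts the bins separating the
back-transformed prediction and observation; predictions inside the
correct bin incur no penalty, and the continuous deviation enters
unsquared because `B` already penalises distant predictions a second
time.

The problem is typically underdetermined (up to `N²` parameters, as few
as `N` informative observations), so the estimator is a stochastic
search returning a solution consistent with the data, not a unique
maximum-likelihood point; multi-run variability (see the pilot workflow)
is the honest uncertainty summary.

## The genetic algorithm

A chromosome is a candidate `W`; a gene is one row.  Each iteration:

1. **Elite selection** — the chromosome with the lowest total objective
   (ties: lowest index) is exempt from all stochastic operators.
2. **Gene swapping (elite)** — for each gene, if any other chromosome's
   corresponding gene has a strictly lower per-gene objective *in its own
   context*, the fittest such gene (ties: lowest chromosome index) is
   swapped with the elite's.  Because genes interact through the
   predicted opinions, all swaps are accepted only if the modified elite
   strictly improves; otherwise every chromosome is restored.  Donors
   keep the received elite genes on acceptance — the operation is a swap,
   not a copy.
3. **Blending** — non-elite chromosomes are paired uniformly at random
   (an odd one sits out); per gene, with probability `p_b`, the gene pair
   is replaced by `βB_i + (1−β)C_i` and its mirror image, `β ~ U(0,1)`.
4. **Crossover** — per gene, with probability `p_c`, the free weights are
   uniformly permuted within the row (Fisher–Yates), preserving the row
   sum exactly.
5. **Mutation** — per gene, with probability `p_m`, one free weight gets
   a `N(0, σ²)` perturbation, with boundary rules: negative results clip
   to 0; results above the free mass `1 − w_fixed` take all of it and
   zero the other free weights; if the selected weight already held all
   free mass the excess is spread evenly.  Otherwise the other free
   weights are rescaled so the row sums to 1.
6. **Survival** — each parent/offspring pair keeps the fitter member
   (ties keep the parent), followed by the same accept-or-revert-all gene
   swap between the retained chromosome and its rejected counterpart.
7. **Adaptation / reintroduction** — after `iterb`/`iterc`/`iterm`/`iters`
   iterations without improvement, `p_b` doubles (cap 0.2) while `p_c`,
   `p_m` and `σ` halve (floors 0, 0.01, 0.001); each quantity keeps its
   own stagnation counter and all counters reset when the best objective
   strictly improves by more than `min_improve`.  After `iterr` stagnant
   iterations the worst chromosome is replaced by an elite clone (or the
   self-reliant diagonal matrix).  The reintroduction check runs last in
   the iteration.

The initial population holds the diagonal chromosome (`1 − w_fixed` on
each free diagonal) plus random chromosomes whose free row entries are
flat-Dirichlet draws scaled to the free mass — the flat simplex is the
natural uninformative choice for row-stochastic rows.  Defaults: 21
chromosomes, `p_b = 0.01`, `p_c = p_m = 0.2`, `σ = 1`, adaptation spans
1000 (2000 for `σ`), reintroduction span 2500, up to 1e6 iterations,
stopping early only when the objective reaches `min_dev` (default 0,
attainable by `f_L` when every prediction lands in the correct bin).

Two printed-rule clarifications are deliberate: the mutation rescale
uses `(1 − w_fixed − w*)/(1 − w_fixed − w)` — the factor that actually
restores the row sum and that the boundary cases imply — applied against
the floating-point sum of the other free weights for numerical exactness;
and "improvement" is judged on the total (not per-gene) objective.

All randomness flows from one seeded generator threaded through every
operator, so a fit is bit-reproducible from its seed.  The inner loop is
numba-compiled; the operator API wraps the same kernels.

## Simulation study

Factors: network size {4, 10, 20, 50}, target degree {2, 5, 9}, target
self-weight {0.1, 0.5, 0.8}, observed time steps {2, 3, 6, 11},
missingness {0, 10, 25, 50}%.  Networks are Erdős–Rényi with
`p = d/(N−1)`, rejection-sampled until connected — which inflates
realised degree above target, most strongly for small sparse graphs
(mean degree ≈ 2.15 at N = 4 up to ≈ 2.62 at N = 50 for target 2).
Self-weights are Beta(κ·target, κ·(1−target)) with κ = 10, so the mean
matches the target; the remaining row mass is flat-Dirichlet over
neighbours.  Trajectories run 21 steps from Unif(0, 1) initial opinions;
the observed set keeps the first `T` columns and masks
`⌊prop·N·(T−1)⌋` uniformly chosen non-initial entries subject to a fully
observed baseline and ≥ 1 observed non-initial entry per agent (uniform
rejection with a reserve-one-slot fallback where rejection is hopeless).
Cells where the constraint cannot hold (any missingness at T = 2, or too
many required masks) are excluded.

Performance metrics: `RMSE_fit` over `t = 0..T−1` against the complete
truth with denominator `N(T−1)` (the count of informative terms, since
the seeded `t = 0` terms vanish); `RMSE_ext` over the withheld
`t = T..20` with denominator `N(21−T)`; `RMSE_rec` over the `P` weight
entries not structurally zero.  Each design point draws one
network/weights/trajectory per data set and fits the GA `replicates`
times on it.

### Scaled-down reproduction

The full factorial (10 replicates per cell at 1e6 iterations) is far
beyond a test suite, so the acceptance checks run a reduced version:
sizes {4, 10}, degrees {2, 5}, all three self-weights, three data sets
per cell, one fit each at 1e5 iterations, restricted to the cells under
test (complete data at T = 2, 3, 6; all missingness levels at T = 3).
At this scale the median recovery RMSE reproduces the full study's
pattern — ≈ 0.15 at T = 2, ≈ 0.09 at T = 3, ≈ 0.06 at T = 6 on complete
data, strictly improving with time steps and strictly degrading with
missingness at fixed T.

## Likert transforms and the pilot workflow

An `n`-bin composite scale maps score `k` (1-based bin) to the bin
midpoint `(k − 0.5)/n`; the back-transform multiplies by `n` and rounds
half-up, clamped to `[1, n]`.  Half-up rounding makes the midpoint round
trip exact; a `1e-12` tie guard in the rounding keeps it exact under
floating point.  Note the two notions of "bin" differ slightly:
`likert_back` implements the multiply-and-round rule, which partitions
`[0, 1]` into intervals centred on `k/n`, not the equal `n`-subinterval
partition of the forward transform.  The deviation count `B` uses the
back-transform, consistently with how predictions are evaluated on the
original scale.

Pilot structure emulated by the synthetic generator: 5 networks of 4–12
agents recruited in two rings from a seed; recruitment ties are
known-present edges and a subset of absences known-absent, giving a
*build* (lower-bound) and *remove* (upper-bound) adjacency; willingness
(3–15) and self-efficacy (8–32) composites at baseline and month 3; a
latent weight matrix placing 3× weight on leader neighbours generates
follow-ups via three DeGroot steps; ~5% of responses go missing.  The
generator emulates structure, not the restricted data themselves: it
does not model item-level response error, informative missingness, or
correlation between the two measures, so pipeline tests demonstrate
mechanical and statistical soundness on DeGroot-faithful data, not
fidelity to the real pilot responses.

Workflow per network and measure: impute missing baselines (own
follow-up if present, else the lower-middle median of the other agents'
baselines, keeping the score integral); expand to a monthly grid
(t = 0 baseline, t = 1, 2 missing, t = 3 follow-up); fit the GA under
`f_L` ten times with seeds `base + run`; report per-entry means and
sample SDs (exact zeros wherever runs agree, hence on fixed entries),

    RMSE_alg = sqrt( Σ_{i,j,r} (w̄_ij − ŵ_ij,r)² / (R Σ a_ij) ),

and the application fit RMSE from the *mean-weight* predictions,

    RMSE_fit = sqrt( Σ_i B(x̂_i(3), x_i(3))² / (C N (T−1)) ),

with `C` the bin count and `T − 1 = 3` exactly as the denominator of the
monthly grid dictates, agents with missing follow-ups contributing
nothing.  Leader summaries compare the mean received weight (over
adjacency-allowed off-diagonal entries of the mean weight matrix,
grouped by sender leadership), the count and proportion strictly
exceeding 0.005, and self-weight means/SDs; receivers not connected to
any leader are excluded from the received-weight denominators but all
agents enter the self-weight summary.

## Numerical and design choices

* Row-stochasticity tolerance 1e-9; rows within 1e-6 renormalise on
  input, larger deviations are rejected.
* Elite/survival ties keep the incumbent; gene-swap donor ties take the
  lowest index.
* Multi-run means are set to the common value wherever all runs agree,
  so identical runs yield exactly zero variability.
* Study cell seeds derive from a spawned `SeedSequence`, making cells
  independent and the whole factorial reproducible from one seed.

## Known limitations

* The estimator returns one consistent solution, not a posterior; on
  two-wave data many weight matrices fit equally well and only
  multi-run spread hints at that non-identifiability.
* Fast-mixing weight matrices (low self-weight) make trajectories nearly
  collinear after a few steps, so recovery error can be large even at
  machine-zero objective — visible in the factorial results as the
  self-weight effect.
* The DeGroot model itself has no external information sources or
  time-varying weights; the estimates absorb such effects into `W`.
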