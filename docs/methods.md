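# Methods

## Model and conventions

The stage game has N players and M actions per player; a joint action
profile σ = (σ₁, …, σ_N) is flat-indexed lexicographically with player 1
most significant and action 1 before action 2 (`profile_flatten`). Payoffs
are flat vectors s_a over profiles, extended by the constant vector
s₀ ≡ 1. The repeated game is undiscounted; the `Game` object fixes the
discount factor at 1 and refuses anything else, because the entire
analysis rests on stationary distributions of the undiscounted chain.

A memory-n strategy stores, for each own action, a vector over the
M^(nN) histories (σ⁽⁻¹⁾, …, σ⁽⁻ⁿ⁾), flat-indexed with the most recent
profile most significant. For the two-player binary memory-two case this
makes the cooperation table the familiar 4×4 matrix with rows σ′ (last
round) and columns σ″ (second-to-last round), both in profile order
(1,1), (1,2), (2,1), (2,2). Binary-action tables store T(1|·); T(2|·) is
derived as 1 − T(1|·), which is what makes the two Press–Dyson slices
cancel per history.

The joint chain lives on n-tuples of profiles. A transition appends the
newly realized profile and drops the oldest, so each of the M^(nN) states
has at most M^N successors; the transition probability is the product of
the players' conditional action probabilities. State spaces above 65 536
states are refused outright; transition matrices are stored sparsely above
256 states and densely below (every stationary solve is dense anyway,
restricted to one recurrent class).

## Stationary analysis

Deterministic strategies (TFT, TFT-ATFT, all-D) make reducible chains
common, so the engine never assumes irreducibility: it finds the closed
communicating classes of the transition graph (strongly connected
components with no outgoing edge) and solves one stationary distribution
per class. The solve replaces one row of (Tᵀ − I) with the normalization
Σp = 1 and uses a direct dense solve; the fixed-point residual must come
out below 1e-10 or an error is raised — an unnormalized or non-stationary
vector is never returned silently. A 10⁵-step power iteration serves as an
independent oracle in the tests (agreement to 1e-8), never as the
implementation.

Akin's identity — the contraction of any Press–Dyson slice with any
stationary distribution of a chain its owner plays in — holds per class,
so all ZD relation checks are asserted per recurrent class. Which class a
trajectory realizes depends on the initial condition; the simulator
reports the empirical class (its final state), and `compare_exact` refuses
to compare a run against a distribution whose support the run did not end
in.

## ZD detection, relations and construction

For binary actions the per-history normalization collapses the per-action
combination weights to a single scale, so ZD membership reduces to whether
the cooperation Press–Dyson vector lies in the span of the (N+1)ⁿ payoff
product tensors. Detection solves the least-squares projection and uses
the *relative* residual ‖projection remainder‖/‖T̂‖ with tolerance 1e-10:
catalog tables are exact rationals of the payoffs, so genuine ZD
strategies sit at machine-epsilon residuals and the gap to the nearest
non-ZD strategy is many orders of magnitude. For M > 2 the joint
homogeneous system in (weights, α) is solved by SVD with the last weight
gauged to zero. The payoff-product basis has rank (N+1)ⁿ for generic
Prisoner's-Dilemma payoffs (rank 9 at n = N = 2, against 16 strategy
degrees of freedom — which is why almost no random strategy is ZD, as a
200-seed sweep in the tests confirms); rank deficiency is reported as a
non-uniqueness flag rather than an error. Alternative (non-payoff-product)
bases are out of scope.

Relation coefficients are determined only up to an overall scale, which is
fixed canonically: divide by the largest magnitude and orient so the first
nonzero entry in lexicographic index order is positive. A coefficient
tensor is flagged degenerate when only the all-constant index is nonzero
(the "relation" 0 = α₀…₀ is contradictory) or when it is identically zero;
the Repeat strategy, whose Press–Dyson matrix vanishes, is reported
degenerate rather than ZD.

Construction inverts detection: given α, form D = Σ α_b (basis tensor) and
the one-parameter family T(1|·) = Repeat + w·D. Each history contributes
an exact interval of admissible w (keeping the entry in [0,1]); the
intersection always contains w = 0 (Repeat itself), and the relation is
enforceable iff it contains a nonzero w. The returned table sits at the
endpoint of maximal magnitude — the convention under which each catalog
strategy is recovered *exactly* from its own relation coefficients — with
ties resolved to the endpoint farther from zero. Infeasibility (interval
pinned to {0}) is reported with the binding histories; the
payoff-role-swapped variant of the correlation-enforcing example is the
canonical infeasible case, and it is infeasible for every Prisoner's
Dilemma payoff ordering, not just the benchmark values. Construction is
implemented for binary actions; the degenerate-α case is rejected.

The catalog generates every payoff-dependent table from its symbolic entry
formulas at the supplied payoffs, so violated feasibility conditions
(T − P ≥ P − S for the correlation example; 2R > T + S for FTFT;
additionally 2P < T + S for ZSS/EZSS) surface as out-of-range
probabilities and are rejected with the violated inequality named. The
modified correlation-example table for T − P < P − S has no published
form, so that case is rejected rather than guessed. Memory-one members
(TFT, ZSS, probe, all-D, Repeat) are built as memory-one tables and lifted
to memory two by `embed_memory`, which repeats entries across the older
round; a property test confirms the lift changes no stationary marginal or
lag-1 correlation.

## Simulation

`run_match` draws the first n rounds uniformly (each player's action
independently uniform), then samples each player from its conditional
table; one RNG stream per match (numpy PCG64, explicit seed), player 1
drawing before player 2 each round, so runs are bitwise reproducible. The
horizon counts rounds after the initial round 0; estimators follow the
time-average convention Σ_{t′=1..t} s_b(σ(t′)) s_c(σ(t′−1))/t, whose first
term pairs round 1 with the uniformly drawn round 0. Standard errors use
batch means over 100 equal batches because the chain is autocorrelated and
i.i.d. formulas would understate the error; z-scores against exact
stationary values are the agreement metric, with |z| ≤ 4–5 the documented
(probabilistic, seed-fixed) acceptance band. Matches of 10⁵ rounds take
well under a second, so the full catalog × probe sweep stays cheap.

## Problem sizes and defaults

The benchmark payoffs are (R,S,T,P) = (3,0,5,1) and the probe opponent
cooperates with probability q after mutual cooperation and 2/3 otherwise —
the standard sweep configuration for tracing enforced lines; q defaults to
0.5 (the midpoint) where a single value is needed. Exact checks run on the
16-state pair chain; simulated checks use t = 10⁵ rounds, the scale at
which the time averages visibly settle onto the enforced lines. The payoff
grid for symbolic-table checks adds three further (R,S,T,P) sets
satisfying all catalog preconditions. The randomized sweeps use 200 fixed
seeds: interior (Dirichlet) tables make the chain irreducible, which the
sweep asserts alongside the Akin identity for both players and all
actions.

## What the generators do and do not emulate

Random interior strategies exercise the generic (irreducible,
full-support) regime; random sparse strategies the deterministic regime.
Neither models implementation noise (trembling hand), discounting δ < 1,
imperfect monitoring, evolutionary dynamics or structured populations —
all outside the package's scope — so passing tests say nothing about ZD
behaviour under those complications. The Monte-Carlo protocol matches the
well-mixed, error-free setting of the exact analysis; its agreement with
the exact stationary values is a consistency check of both engines, not
evidence about robustness.

## Known limitations

- Construction (and the collapsed detection path) assumes binary actions;
  multi-action detection is implemented but has no catalog examples.
- Whether TFT-ATFT is a memory-two ZD strategy has no published ground
  truth; the detector reports its verdict, and the test suite checks only
  the report's internal consistency, asserting nothing about the answer.
- For reducible chains the package reports every recurrent class; which
  class a real trajectory realizes depends on initial conditions, and only
  the simulator resolves the empirical one.
- Payoff asymmetric games are supported by the engines but the catalog and
  its feasibility conditions assume the symmetric (R,S,T,P) form.
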