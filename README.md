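# zdgames

Exact algebra and simulation for **zero-determinant (ZD) strategies** in
repeated games, with full support for memory-*n* strategies.

## The problem

In a repeated game, a memory-*n* strategy of player *a* is a conditional
probability T_a(σ_a | σ⁽⁻¹⁾, …, σ⁽⁻ⁿ⁾) of each own action given the joint
action profiles of the last *n* rounds. Subtracting the "Repeat" rule (the
indicator that the candidate action equals the player's own most recent
action) yields the **Press–Dyson matrix**

T̂_a(σ_a | σ⁽⁻¹⁾, …, σ⁽⁻ⁿ⁾) = T_a(σ_a | …) − δ(σ_a, σ_a⁽⁻¹⁾),

which by (the memory-*n* extension of) **Akin's lemma** has zero mean under
*every* stationary distribution of the induced Markov chain over state
tuples. When a combination of a player's Press–Dyson matrices lies in the
span of the payoff product tensors s_b⁽⁻¹⁾ ⊗ ⋯ ⊗ s_b⁽⁻ⁿ⁾ (with s₀ ≡ 1),

Σ_{σ_a} c_{σ_a} T̂_a(σ_a | ·) = Σ_b α_b s_{b⁽⁻¹⁾}(σ⁽⁻¹⁾) ⋯ s_{b⁽⁻ⁿ⁾}(σ⁽⁻ⁿ⁾),

the strategy is a memory-*n* ZD strategy: it *unilaterally* enforces the
linear relation Σ_b α_b ⟨s_{b⁽⁻¹⁾}(t+n−1) ⋯ s_{b⁽⁻ⁿ⁾}(t)⟩ = 0 among
stationary payoff correlation functions, whatever the opponents play. For
memory one these are the classic relations among average payoffs
(equalizers, extortioners, tit-for-tat); for memory two they constrain
lag-1 correlations ⟨s_b(t+1) s_c(t)⟩ as well.

The package is for game theorists and theoretical biologists who want to

- compute exact stationary distributions (per recurrent class) of strategy
  pairings in the repeated Prisoner's Dilemma and beyond,
- test any strategy table for ZD membership and recover its enforced
  relation coefficients,
- construct a strategy table from target relation coefficients, with an
  exact feasibility analysis (some relations admit no strategy at all),
- verify enforced relations in seeded Monte-Carlo matches with batch-means
  error bars.

A catalog provides the standard memory-two ZD strategies of the repeated
Prisoner's Dilemma — extended tit-for-tat (ETFT, ETFT-2), fickle
tit-for-tat (FTFT), the zero-sum strategy (ZSS) and its memory-two
extension (EZSS), a correlation-enforcing example, plus TFT, TFT-ATFT,
all-D, Repeat and the probe opponent used to sweep the enforced lines.

## Worked example

ETFT against the probe opponent (cooperate with probability q = 0.5 after
mutual cooperation, 2/3 otherwise) at payoffs (R,S,T,P) = (3,0,5,1):

```python
import zdgames as z

g = z.make_pd_game(3, 0, 5, 1)
tm = z.build_transition([z.etft(), z.probe(0.5)], g)
d = z.stationary(tm)                       # exact, 16-state pair chain
print([z.correlation(d, g, a, 0) for a in (1, 2)])  # average payoffs
print(z.correlation(d, g, 1, 2))           # <s1(t+1) s2(t)>

alpha = z.enforced_relation("etft", g)
print(z.evaluate_relation(alpha, d, g))    # the ZD relation, exactly 0

sim = z.run_match([z.etft(), z.probe(0.5)], g, horizon=100_000, seed=1)
v, se = z.relation_se(sim, alpha)
print(v, se)
```

prints

```
[2.4782608695652177, 2.478260869565218]
5.739130434782608
0.0
0.031 0.0407
```

Both players average 2.478; the lag-1 correlation ⟨s₁(t+1)s₂(t)⟩ is 5.739;
the combination ETFT enforces — ⟨s₁(t+1)s₂(t)⟩ + ⟨s₂(t+1)s₁(t)⟩ −
⟨s₁(t+1)s₁(t)⟩ − ⟨s₂(t+1)s₂(t)⟩ + (T−S)(⟨s₁⟩−⟨s₂⟩) — is exactly zero under
the exact stationary law, and the 100 000-round Monte-Carlo estimate
(0.031 ± 0.041) is consistent with zero within one standard error.

The same from the shell:

```bash
zdgames verify-zd --strategy etft --payoffs 3,0,5,1
```

reports `is_zd: true`, projection residual ~2e-15, and the relation
coefficients in rationalized form (α₁₀=1, α₁₁=−1/5, α₁₂=1/5, α₂₀=−1, …,
i.e. the ETFT relation scaled so its largest coefficient is 1). Other
subcommands: `stationary`, `simulate` (with `--q-grid` sweeps),
`construct`, `catalog`, `random`.

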