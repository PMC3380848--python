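# thermoflux

Thermodynamic feasibility analysis of metabolic flux directions: fast
perceptron-style solvers for chemical potentials, and identification and
removal of thermodynamically infeasible reaction loops.

## The problem

In a constraint-based model of metabolism, the second law requires every
reaction *r* running with net direction σ_r (+1 forward, −1 backward) to
dissipate Gibbs energy:

    σ_r · ΔG_r ≤ 0,     ΔG_r = Σ_i S_ir · μ_i,

where **S** is the M×N stoichiometric matrix (substrates negative, products
positive) and μ_i is the chemical potential of metabolite *i* (kJ/mol).
Given a direction vector σ — e.g. from a sampled steady-state flux
configuration — two questions arise:

1. **Landscape reconstruction.** If the system is solvable, which
   potential vectors μ (equivalently, which metabolite log-concentrations,
   via μ = ΔG_f° + RT·ln c) are consistent with the directions *and* close
   to prior biochemical knowledge?
2. **Feasibility and repair.** If it is not solvable, which reactions are
   responsible, and which direction flips fix it?  By the Farkas–Minkowski
   lemma the system is unsolvable iff it contains an *infeasible loop*: a
   reaction set L with weights γ_r > 0 such that Σ_{r∈L} γ_r σ_r S^(r) = 0
   — the analogue of a current loop violating Kirchhoff's voltage law.

`thermoflux` answers both with the MinOver relaxation: repeatedly pick the
least satisfied constraint r₀ = argmax_r σ_r ΔG_r and step
μ ← μ − λ σ_r₀ S^(r₀).  If a positive-margin solution exists the sweep
provably converges; if the directions contain a loop, r₀ cycles around it,
and the visited reactions betray the loop, which is then certified
algebraically and repaired by flipping one of its reversible members.
A penalty method (the explicit minimizer of the distance to the prior), a
classical Agmon–Motzkin relaxation, an exact LP/Farkas oracle, prior
construction from formation energies and concentration ranges, and a
ground-truth synthetic fixture generator complete the toolkit.

## Worked example

Generate a small fixture with one planted 3-loop, check it, repair it:

```
$ thermoflux simulate --M 8 --N 10 --loops 1 --seed 5 --out fixture
wrote fixture with M=11, N=13 to fixture

$ thermoflux check --network fixture/network.tsv --directions fixture/directions.tsv --lenient
{"status": "INFEASIBLE", "certificate": {"reactions": ["LR0_0", "LR0_1", "LR0_2"],
 "signs": [1, 1, 1], "gamma": [1.0, 1.0, 0.9999999999999999],
 "reversible_members": ["LR0_0"], "length": 3}}          # exit code 1

$ thermoflux fix-loops --network fixture/network.tsv --directions fixture/directions.tsv \
      --lenient --max-iter 4000 --seed 3 --out fixed
status FEASIBLE; 1 loops removed; flipped: LR0_0

$ thermoflux check --network fixture/network.tsv --directions fixed/directions_fixed.tsv --lenient
{"status": "FEASIBLE", "margin": 1.0}                    # exit code 0
```

The `check` certificate is a proof: the three reactions' signed columns,
weighted by γ ≈ (1, 1, 1), sum to zero, so no potential vector can orient
all three downhill.  `fix-loops` located the same loop from the solver's
cycling tail and flipped its one reversible member (`LR0_0`); the repaired
assignment is feasible with unit LP margin.  `fixed/potentials.tsv` holds
a consistent potential vector; every output embeds the seed and a config
hash as header comments.  Exit codes separate scientific verdicts
(1 = infeasible) from input errors (2).

`thermoflux solve --samples K` draws K prior vectors, relaxes each to
feasibility, and writes per-draw potentials and Gibbs changes plus a
per-metabolite summary with derived log-concentrations.

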