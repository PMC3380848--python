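# Methods

## Model

A metabolic network is an M×N stoichiometric matrix **S** (substrates
negative, products positive) with a reversibility annotation per reaction.
A direction assignment σ ∈ {+1, −1, 0}^N fixes the net direction of each
reaction (0 = unconstrained; its inequality is simply absent).  The
thermodynamic constraint set is

    σ_r · ΔG_r ≤ −ε,   ΔG_r = Σ_i S_ir μ_i,   for every r with σ_r ≠ 0,

over chemical potentials μ ∈ R^M (kJ/mol).  The margin ε (default 10⁻⁶
kJ/mol) replaces the physical strict inequality: floating point cannot
certify `< 0`, and the convergence guarantee for MinOver anyway assumes a
solution with positive margin.  The solution set is a convex cone (plus a
polyhedron once clamps or bounds are added); it is unbounded unless enough
potentials are clamped or boxed, which is both how the energy scale is set
and what `boundedness_check` verifies (LP probes of the recession cone,
coordinate by coordinate, capped at ‖x‖∞ ≤ 1 — a rank test would miss
inequality-only rays).

## Solvers

**MinOver** (default).  Iterate: find the least satisfied constraint
r₀ = argmax σ_r ΔG_r (ties to the lowest index, for deterministic
reruns); if its value ≤ −ε stop, else step μ ← μ − λ σ_r₀ S^(r₀) on
unclamped coordinates.  The implementation keeps the Gram matrix
G = Sᵀ_free S_free so each iteration is O(N), with a periodic exact
recomputation of ΔG to cancel incremental drift.  λ (default 0.1 kJ/mol)
is scale-sensitive: it should be small relative to the spread of the
prior.  Convergence for any λ > 0 is guaranteed when a positive-margin
solution exists, with an iteration bound that grows as the inverse squared
margin; the validation suite confirms termination for λ ∈ {0.01, 0.1, 1}
and a median iteration count that decreases with the planted margin.

**Relaxation** (Agmon–Motzkin).  Same sweep, but the step is
α·(violation + ε)/‖S^(r₀)_free‖² along the constraint normal, α ∈ (0, 2).
At ε = 0 this is the textbook rule — α = 1 projects exactly onto the
constraint boundary, α = 2 would reflect (excluded) — and the `+ ε` term
is the modification that makes the scheme terminate at a positive
feasibility margin, where the raw rule would approach the boundary without
ever clearing −ε.

**Penalty.**  Gradient descent on ½‖μ − μ⁰‖² + β·Σ_violated σ_r ΔG_r with
rate η (default 10⁻³); β starts at 1 and grows by 1 each time a minimum is
reached while violations remain.  Because the penalty is piecewise linear,
"minimum reached" is detected on the penalized cost over a 100-iteration
window rather than on the step norm alone — at the non-smooth kink the
iterate chatters with sizeable steps but no cost decrease.  The first
fully feasible iterate is returned; for a single active constraint this is
the Euclidean projection of the anchor onto the feasible half-space up to
an O(η) overshoot (measured: 9.9·10⁻⁵ at η = 10⁻³, 9.4·10⁻⁶ at η = 2·10⁻⁵
on the two-metabolite example).  The penalty solution is the package's
distance-minimizing benchmark: on 50 cell-scale fixtures MinOver's mean
distance to the prior draw exceeds it by ≈ 1%, consistent with MinOver
"roughly minimizing" the distance while being far cheaper per iteration.

**Box bounds** L_i ≤ μ_i ≤ U_i are folded into every solver identically:
each finite bound becomes a synthetic forward column touching the bounded
metabolite and one auxiliary metabolite clamped at potential 1, so its
"Gibbs change" is exactly μ_i − U_i (resp. L_i − μ_i) and the unmodified
update rules apply — one code path, no special cases.

**Clamps** are bit-preserved: solvers only ever write to unclamped
coordinates.

## Priors

μ = ΔG_f° + RT ln c (dilute solution; RT = 2.4790 kJ/mol at 298.15 K,
temperature configurable).  A metabolite with measured concentration
c ± sd gets a uniform box over the image of [c − 2sd, c + 2sd]; by default
the box is centered at μ(c) with halfwidth half the mapped width (the
mapped interval is asymmetric around μ(c); a policy flag instead centers
at the interval midpoint, which puts the endpoints exactly on the mapped
points).  A metabolite with only ΔG_f° gets a box spanning four decades of
concentration (halfwidth 2·RT·ln 10 ≈ 11.42 kJ/mol) around a default level
of 10⁻³ M.  Metabolites like water are clamped (zero-width box).  Draws
are per-coordinate uniform and reproducible from an injected generator;
the prior only initializes the solver — solutions may and do leave the
boxes, which is how inconsistent prior information gets corrected.

## Loops

If no solution exists, MinOver's least-satisfied index eventually cycles.
`correct_directions` runs the solver with a bounded iteration budget,
collects the distinct reactions in the tail window of least-satisfied
indices, and searches them for a loop: first the visit-count shortcut
(over an exact period the update counts themselves are valid γ weights),
then subsets of increasing size k = 2..k_max (default 8; the enumeration
is capped at 2·10⁶ subsets with an explicit budget error, since subset
search is exponential in the worst case).  Each subset is tested for a
strictly positive null combination of its signed columns — directly when
the nullspace is one-dimensional, by a small LP otherwise, with a cheap
necessary precheck (every touched metabolite row needs both signs).
Searching by increasing k guarantees the returned certificate is
member-minimal within the candidate set.  If the tail yields nothing, one
escalation retries with every reaction that was ever least-satisfied.

A certificate is repaired by flipping one reversible member chosen
uniformly (recorded, replayable); a loop with no reversible member is
surfaced as an unrepairable error with its certificate — those directions
are pinned by the network's topology.  The identify-and-remove cycle
repeats until feasible, and by construction only reversible reactions ever
differ from the input.  `catalogue_loops` maps this over an ensemble of
random direction draws (irreversible reactions forward, reversible ±1 with
probability ½ — the worst-case all-active scenario) and deduplicates
certificates by reaction set and sign pattern up to global inversion.

The exact cross-check, `lp_feasibility_oracle`, solves max s subject to
σ_r S^(r)·μ ≤ −s, s ≤ 1: s* > 0 gives a feasibility witness, otherwise
the dual weights on the constraints are a (possibly non-minimal) Farkas
certificate.  The oracle is used only for validation and the `check`
verdict, never inside the MinOver pipeline, so the two routes stay
independent.

## Synthetic ground truth

The generator produces random sparse integer stoichiometries (every column
has at least one substrate and one product — certificates verify exactly
and TSVs round-trip bit-exactly), directions feasible by construction
(σ = −sign(ΔG(μ*)) for a random witness μ*, resampled until every margin
clears a prescribed c), planted loops appended as directed k-cycles over
fresh metabolites (the ground-truth certificate γ = 1 is then unique and
minimal, making recovery tests exact), and prior tables in the real-data
layout.  Table formation energies are a least-squares fit to standard
reaction energies drawn N(0, 20 kJ/mol): in curated tables formation
energies largely cancel across balanced reactions, and with independent
per-metabolite draws the synthetic (non-mass-balanced) columns would give
|ΔG°| in the thousands of kJ/mol, rendering every prior draw trivially
feasible.  Desk-scale study sizes: 500 instances (M ≤ 20, N ≤ 25) for the
oracle cross-validation, 200 for loop recovery and repair, 50 fixtures at
M ≈ 35, N ≈ 40 (the cellular scale of the landscape study) for the
distance comparison with λ = 0.02, margins {0.1, 1} kJ/mol for the
convergence study.

What the fixtures do *not* emulate: mass-balanced (atom-conserving)
stoichiometry, realistic degree distributions, compartments, or loops
entangled with pre-existing metabolites.  Passing tests therefore
demonstrate correctness of the algorithms on networks with known answers,
not biological accuracy of predictions on real reconstructions.

## Numerical choices and edge cases

- Certificate residual tolerance 10⁻⁸ (∞-norm, weights normalized to max
  γ = 1); integer fixture coefficients keep residuals at rounding level.
- LP feasibility threshold s* > 10⁻⁹; boundedness ray threshold 10⁻⁷.
- A nullspace vector with a (relative 10⁻⁹) zero entry is rejected as a
  certificate: its support is a smaller subset, found earlier.
- A constraint column touching only clamped metabolites cannot improve:
  solvers raise a stall error rather than looping.
- Penalty divergence guard at ‖μ‖ > 10¹² with a hint to reduce η.
- Tie-breaks (argmax, subset order) are deterministic; all randomness
  flows from injected seeds/generators — same seed, same output, tested
  end-to-end through the CLI.

## Correlation diagnostic

`potential_correlations` is the empirical covariance of final potentials
across prior draws.  Its sign structure depends on the operating regime:
with step λ much smaller than the prior spread, repeated solutions of a
single reaction collapse substrate and product onto their midpoint and the
pair correlates *positively*; when λ is comparable to the spread, the
step-quantization noise (updates push substrate up and product down by
equal amounts) dominates and opposite-side metabolites anti-correlate —
the regime the tests probe (measured C_AB = −0.087 at λ = 1 with halfwidth
0.5, versus +0.032 at λ = 0.01).  Only this empirical diagnostic is
provided; no analytic decomposition is implemented.

## Known limitations

- The tool consumes directions; it does not generate steady-state flux
  vectors, and repaired assignments are not guaranteed consistent with any
  particular steady state.
- Uniform sampling of the (bounded) solution cone is out of scope; the
  solvers explore solutions near the prior, not uniformly.
- Loop search is complete only up to k_max within the candidate set;
  pathological long loops require raising k_max and the subset budget.
- SBML is not read; the TSV dialect is this package's own.
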