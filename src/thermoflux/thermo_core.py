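"""Chemical-potential solvers for direction-constrained metabolic networks.

The second law requires every reaction r running in direction
``sigma_r`` (+1 forward, -1 backward) to dissipate Gibbs energy:

    sigma_r * DeltaG_r <= 0,      DeltaG_r = sum_i S_ir * mu_i,

where ``mu_i`` is the chemical potential of metabolite i (kJ/mol) and S
the stoichiometric matrix.  Three iterative solvers for this system of
linear inequalities are provided:

* :func:`minover_solve` -- perceptron-style MinOver relaxation: at every
  iteration the *least satisfied* constraint takes a fixed-size step
  ``mu <- mu - lam * sigma_r0 * S[:, r0]`` along its normal.  Converges
  whenever a solution with positive margin exists; when the direction
  assignment contains an infeasible loop the least-satisfied index cycles
  around the loop forever, which downstream loop analysis exploits.
* :func:`relaxation_solve` -- the classical Agmon--Motzkin scheme: the
  same sweep but with step length proportional to the current violation.
* :func:`penalty_solve` -- gradient descent on the squared distance to a
  prior vector plus a linear penalty on violated constraints, with a
  penalty weight that grows each time the descent stalls.  This is the
  explicit minimizer of the Euclidean distance to the prior and serves as
  the benchmark MinOver is compared against.

Selected chemical potentials may be *clamped* (held fixed) to set the
energy scale and bound the solution cone; box bounds ``L_i <= mu_i <= U_i``
are folded into the same machinery as synthetic single-metabolite
constraint columns so all solvers treat them identically.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field

import numpy as np

from .errors import DivergenceError, StallError, ValidationError
from .network_io import DirectionAssignment, ReactionNetwork

__all__ = [
    "PotentialVector",
    "SolverConfig",
    "SolveResult",
    "gibbs_changes",
    "least_satisfied",
    "minover_step",
    "minover_solve",
    "relaxation_solve",
    "penalty_solve",
    "distance_to_prior",
    "potential_correlations",
]

FEASIBLE = "FEASIBLE"
MAX_ITERS = "MAX_ITERS"


@dataclass
class PotentialVector:
    """Chemical potentials (kJ/mol) with a per-metabolite clamp mask."""

    mu: np.ndarray
    clamped: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.clamped = np.asarray(self.clamped, dtype=bool)
        if self.mu.shape != self.clamped.shape or self.mu.ndim != 1:
            raise ValidationError("mu and clamped must be equal-length vectors")
        if not np.all(np.isfinite(self.mu)):
            raise ValidationError("chemical potentials must be finite")

    @classmethod
    def zeros(cls, m: int) -> "PotentialVector":
        return cls(np.zeros(m), np.zeros(m, dtype=bool))

    def copy(self) -> "PotentialVector":
        return PotentialVector(self.mu.copy(), self.clamped.copy())


@dataclass
class SolverConfig:
    """Tunable solver parameters.

    ``lam`` is the fixed MinOver step (kJ/mol); it is scale-sensitive and
    should be small relative to the spread of the prior.  ``eps`` is the
    feasibility margin: a constraint counts as satisfied when
    ``sigma*DeltaG <= -eps`` (floating point cannot certify a strict
    inequality).  ``window`` is the length of the stored tail of
    least-satisfied indices used by loop analysis.  ``alpha`` is the
    relaxation over/under-projection factor in (0, 2); ``eta``, ``beta0``
    and ``beta_step`` drive the penalty method.
    """

    lam: float = 0.1
    eps: float = 1e-6
    max_iters: int | None = None
    window: int | None = None
    seed: int = 0
    mode: str = "minover"
    alpha: float = 1.0
    eta: float = 1e-3
    beta0: float = 1.0
    beta_step: float = 1.0
    inner_tol: float = 1e-8

    def __post_init__(self):
        if self.lam <= 0:
            raise ValidationError("lam must be positive")
        if self.eps < 0:
            raise ValidationError("eps must be nonnegative")
        if not (0 < self.alpha < 2):
            raise ValidationError("alpha must lie in (0, 2)")
        if self.mode not in ("minover", "relaxation", "penalty"):
            raise ValidationError(f"unknown solver mode {self.mode!r}")
        if self.eta <= 0 or self.beta0 <= 0 or self.beta_step <= 0:
            raise ValidationError("penalty parameters must be positive")

    def resolved(self, n_reactions: int) -> tuple[int, int]:
        """Return (max_iters, window) with size-dependent defaults filled in."""
        max_iters = self.max_iters if self.max_iters is not None else 10 * n_reactions * 1000
        window = self.window if self.window is not None else min(10_000, max_iters)
        if max_iters < 1 or window < 1:
            raise ValidationError("max_iters and window must be positive")
        return max_iters, min(window, max_iters)


@dataclass
class SolveResult:
    """Outcome of an inequality solver run.

    ``r0_tail`` is the tail (most recent last) of least-satisfied reaction
    indices, restricted to real reactions; ``tail_counts`` are the visit
    counts within that tail -- in a pure cycling regime they are the trial
    loop weights.  ``visited`` maps every reaction that was ever least
    satisfied to its total update count.  ``violations`` holds the final
    ``sigma_r * DeltaG_r`` per reaction (NaN where unconstrained).
    """

    status: str
    mu: PotentialVector
    iterations: int
    r0_tail: list[int] = field(default_factory=list)
    tail_counts: dict[int, int] = field(default_factory=dict)
    visited: dict[int, int] = field(default_factory=dict)
    violations: np.ndarray = field(default_factory=lambda: np.empty(0))


def gibbs_changes(network: ReactionNetwork, mu: PotentialVector) -> np.ndarray:
    """DeltaG_r = sum_i S_ir mu_i for every reaction (kJ/mol)."""
    if mu.mu.shape[0] != network.M:
        raise ValidationError(
            f"potential vector has length {mu.mu.shape[0]}, network has {network.M} metabolites"
        )
    return network.S.T @ mu.mu


def least_satisfied(network: ReactionNetwork, sigma: DirectionAssignment,
                    mu: PotentialVector) -> tuple[int, float]:
    """Index and value of the worst constraint ``max_r sigma_r DeltaG_r``.

    Unconstrained reactions (sigma 0) are excluded; ties break to the
    lowest reaction index so reruns are deterministic.
    """
    if sigma.sigma.shape[0] != network.N:
        raise ValidationError("direction assignment length does not match network")
    if not np.any(sigma.constrained):
        raise ValidationError("no constrained reactions (all sigma are 0)")
    v = np.where(sigma.constrained, sigma.sigma * gibbs_changes(network, mu), -np.inf)
    r0 = int(np.argmax(v))
    return r0, float(v[r0])


def minover_step(network: ReactionNetwork, sigma: DirectionAssignment,
                 mu: PotentialVector, r0: int, lam: float) -> PotentialVector:
    """One MinOver update of constraint ``r0``: ``mu -= lam*sigma_r0*S[:, r0]``
    on unclamped metabolites.  The updated constraint value decreases by
    ``lam * ||S_unclamped[:, r0]||^2``."""
    if sigma.sigma[r0] == 0:
        raise ValidationError(f"reaction {r0} is unconstrained; cannot update it")
    col = network.S[:, r0]
    free = ~mu.clamped
    if not np.any(col[free] != 0.0):
        raise StallError(
            f"reaction column {r0} touches only clamped metabolites; "
            "its constraint cannot improve"
        )
    out = mu.copy()
    out.mu[free] -= lam * sigma.sigma[r0] * col[free]
    return out


def _augmented(network: ReactionNetwork, sigma: DirectionAssignment,
               mu0: PotentialVector, bounds):
    """Fold optional box bounds into extra single-metabolite columns.

    A bound ``mu_i <= U_i`` becomes a forward pseudo-reaction with column
    ``+e_i - U_i * e_aux`` where the auxiliary metabolite is clamped at
    potential 1, so its DeltaG is exactly ``mu_i - U_i``; lower bounds are
    analogous.  Every solver then handles bounds with its unmodified
    update rule.
    """
    S = network.S
    sig = sigma.sigma
    mu = mu0.mu
    clamped = mu0.clamped
    if bounds is None:
        return S, sig, mu.copy(), clamped.copy(), network.N
    lower, upper = bounds
    extra_cols = []
    for i in range(network.M):
        u = upper[i] if upper is not None else None
        l = lower[i] if lower is not None else None
        if u is not None and np.isfinite(u):
            col = np.zeros(network.M + 1)
            col[i] = 1.0
            col[-1] = -float(u)
            extra_cols.append(col)
        if l is not None and np.isfinite(l):
            col = np.zeros(network.M + 1)
            col[i] = -1.0
            col[-1] = float(l)
            extra_cols.append(col)
    S_aug = np.vstack([S, np.zeros((1, network.N))])
    if extra_cols:
        S_aug = np.hstack([S_aug, np.column_stack(extra_cols)])
        sig = np.concatenate([sig, np.ones(len(extra_cols), dtype=int)])
    mu_aug = np.concatenate([mu, [1.0]])
    clamped_aug = np.concatenate([clamped, [True]])
    return S_aug, sig, mu_aug, clamped_aug, network.N


def _sweep_solve(network, sigma, mu0, config, bounds, rule):
    """Shared least-satisfied sweep for the minover and relaxation rules."""
    if mu0.mu.shape[0] != network.M:
        raise ValidationError("mu0 length does not match network")
    S, sig, mu, clamped, n_real = _augmented(network, sigma, mu0, bounds)
    n_cols = S.shape[1]
    constrained = sig != 0
    if not constrained[:n_real].any():
        raise ValidationError("no constrained reactions (all sigma are 0)")
    max_iters, window = config.resolved(network.N)
    free = ~clamped
    S_free = S[free]
    G = S_free.T @ S_free  # Gram matrix: O(N) incremental DeltaG updates
    dG = S.T @ mu
    tail: deque[int] = deque(maxlen=window)
    visited: Counter[int] = Counter()
    t = 0
    while True:
        v = np.where(constrained, sig * dG, -np.inf)
        r0 = int(np.argmax(v))
        worst = float(v[r0])
        if worst <= -config.eps:
            status = FEASIBLE
            break
        if t >= max_iters:
            status = MAX_ITERS
            break
        gram = G[r0, r0]
        if gram == 0.0:
            raise StallError(
                f"reaction column {r0} touches only clamped metabolites; "
                "its constraint cannot improve"
            )
        step = rule(config, worst, gram) * sig[r0]
        mu[free] -= step * S_free[:, r0]
        dG -= step * G[:, r0]
        tail.append(r0)
        visited[r0] += 1
        t += 1
        if t % 50_000 == 0:  # guard against incremental drift
            dG = S.T @ mu
    dG = S.T @ mu
    viol = np.where(constrained[:n_real], sig[:n_real] * dG[:n_real], np.nan)
    result_mu = PotentialVector(mu[: network.M], clamped[: network.M])
    tail_real = [r for r in tail if r < n_real]
    return SolveResult(
        status=status,
        mu=result_mu,
        iterations=t,
        r0_tail=tail_real,
        tail_counts=dict(Counter(tail_real)),
        visited={r: c for r, c in visited.items() if r < n_real},
        violations=viol,
    )


def minover_solve(network: ReactionNetwork, sigma: DirectionAssignment,
                  mu0: PotentialVector, config: SolverConfig | None = None,
                  bounds=None) -> SolveResult:
    """Iterate least-satisfied + fixed-step update until feasibility.

    Terminates FEASIBLE as soon as every constrained reaction satisfies
    ``sigma_r DeltaG_r <= -eps`` (possibly after zero iterations), or
    MAX_ITERS with the cycling tail populated for loop analysis.
    """
    config = config or SolverConfig()
    return _sweep_solve(network, sigma, mu0, config, bounds,
                        rule=lambda cfg, worst, gram: cfg.lam)


def relaxation_solve(network: ReactionNetwork, sigma: DirectionAssignment,
                     mu0: PotentialVector, config: SolverConfig | None = None,
                     bounds=None) -> SolveResult:
    """Agmon--Motzkin relaxation: step proportional to the violation.

    With ``alpha = 1`` the targeted constraint lands exactly on the
    feasibility margin ``-eps``; ``alpha`` in (0, 2) under/over-projects.
    """
    config = config or SolverConfig()
    return _sweep_solve(
        network, sigma, mu0, config, bounds,
        rule=lambda cfg, worst, gram: cfg.alpha * (worst + cfg.eps) / gram,
    )


def penalty_solve(network: ReactionNetwork, sigma: DirectionAssignment,
                  mu0: PotentialVector, config: SolverConfig | None = None,
                  bounds=None) -> SolveResult:
    """Minimize ``0.5 ||mu - mu0||^2 + beta * sum_violated sigma_r DeltaG_r``.

    Plain gradient descent with rate ``eta``; whenever the iterate stops
    moving while violations remain, ``beta`` grows by ``beta_step`` and
    the descent resumes.  Terminates FEASIBLE at the first iterate with no
    violations, which for a single active constraint is the Euclidean
    projection of ``mu0`` onto the feasible half-space (up to a step-size
    overshoot of order ``eta``).
    """
    config = config or SolverConfig()
    if mu0.mu.shape[0] != network.M:
        raise ValidationError("mu0 length does not match network")
    S, sig, mu, clamped, n_real = _augmented(network, sigma, mu0, bounds)
    anchor = mu.copy()
    constrained = sig != 0
    if not constrained[:n_real].any():
        raise ValidationError("no constrained reactions (all sigma are 0)")
    max_iters, _ = config.resolved(network.N)
    free = ~clamped
    S_free = S[free]
    beta = config.beta0
    t = 0
    check_every = 100
    prev_cost = np.inf
    status = MAX_ITERS
    while t <= max_iters:
        dG = S.T @ mu
        vmask = constrained & (sig * dG > -config.eps)
        if not vmask.any():
            status = FEASIBLE
            break
        if t == max_iters:
            break
        grad = (mu - anchor)[free] + beta * (S_free[:, vmask] @ sig[vmask])
        step = config.eta * grad
        mu[free] -= step
        t += 1
        if float(np.linalg.norm(step)) < config.inner_tol:
            beta += config.beta_step
            prev_cost = np.inf
        elif t % check_every == 0:
            # a minimum of the penalized cost was reached (possibly a
            # chattering kink) while violations remain: raise the penalty
            cost = 0.5 * float(np.sum((mu - anchor)[free] ** 2))
            cost += beta * float(np.sum(sig[vmask] * dG[vmask] + config.eps))
            if prev_cost - cost < 1e-9 * max(1.0, abs(cost)):
                beta += config.beta_step
                prev_cost = np.inf
            else:
                prev_cost = cost
        if not np.all(np.isfinite(mu)) or float(np.linalg.norm(mu)) > 1e12:
            raise DivergenceError("penalty descent diverged; try a smaller eta")
    dG = S.T @ mu
    viol = np.where(constrained[:n_real], sig[:n_real] * dG[:n_real], np.nan)
    return SolveResult(
        status=status,
        mu=PotentialVector(mu[: network.M], clamped[: network.M]),
        iterations=t,
        violations=viol,
    )


def solve(network, sigma, mu0, config: SolverConfig | None = None, bounds=None) -> SolveResult:
    """Dispatch to the solver named by ``config.mode``."""
    config = config or SolverConfig()
    fn = {"minover": minover_solve, "relaxation": relaxation_solve,
          "penalty": penalty_solve}[config.mode]
    return fn(network, sigma, mu0, config, bounds)


def distance_to_prior(mu: PotentialVector, mu0: PotentialVector) -> float:
    """Euclidean distance ``||mu - mu0||`` over unclamped entries."""
    if mu.mu.shape != mu0.mu.shape:
        raise ValidationError("potential vectors have different lengths")
    free = ~(mu.clamped | mu0.clamped)
    return float(np.linalg.norm(mu.mu[free] - mu0.mu[free]))


def potential_correlations(solutions: list[PotentialVector]) -> np.ndarray:
    """Empirical connected-correlation (covariance) matrix across solutions.

    Row/column i is metabolite i; the diagonal is the per-metabolite
    sample variance.  Requires at least two solutions.
    """
    if len(solutions) < 2:
        raise ValidationError("need at least 2 solutions to estimate correlations")
    lengths = {s.mu.shape[0] for s in solutions}
    if len(lengths) != 1:
        raise ValidationError("solutions have unequal lengths")
    X = np.column_stack([s.mu for s in solutions])  # (M, n_samples)
    c = np.cov(X, ddof=1)
    return np.atleast_2d(c)
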