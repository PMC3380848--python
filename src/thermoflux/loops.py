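"""Infeasible-loop certificates: detection, exact LP oracle, and repair.

By the Farkas--Minkowski alternative, the direction-constrained system
``sigma_r * S[:, r] . mu <= 0`` (over constrained reactions r) admits only
trivial solutions iff there is an *infeasible loop*: a reaction subset L
with strictly positive weights gamma such that

    sum_{r in L} gamma_r * sigma_r * S[:, r] = 0.

Such a loop is the thermodynamic analogue of a current loop violating
Kirchhoff's voltage law: no potential assignment can make Gibbs energy
decrease around it.  When MinOver fails to converge, the least-satisfied
constraint index cycles around a loop; the distinct reactions in the tail
of that trajectory are a small candidate set in which the loop can be
found, either directly from the tail visit counts (which approximate the
gamma weights over a period) or by brute-force search over subsets of
increasing size.  Repair flips the direction of one reversible loop
member chosen uniformly at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.linalg import null_space
from scipy.optimize import linprog

from .errors import (BudgetExceededError, LoopSearchError, UnrepairableLoopError,
                     ValidationError)
from .network_io import DirectionAssignment, ReactionNetwork
from .thermo_core import (FEASIBLE, PotentialVector, SolverConfig, gibbs_changes,
                          minover_solve)

__all__ = [
    "LoopCertificate",
    "verify_loop_certificate",
    "find_loop",
    "lp_feasibility_oracle",
    "remove_loop",
    "correct_directions",
    "catalogue_loops",
    "CorrectionResult",
    "CatalogueResult",
]

RESIDUAL_TOL = 1e-8


@dataclass
class LoopCertificate:
    """Proof of infeasibility: reactions L, weights gamma > 0, signs sigma_L
    with vanishing signed weighted column sum.  Normalized to max gamma 1."""

    reactions: tuple[int, ...]
    gamma: tuple[float, ...]
    signs: tuple[int, ...]

    def __post_init__(self):
        self.reactions = tuple(int(r) for r in self.reactions)
        self.gamma = tuple(float(g) for g in self.gamma)
        self.signs = tuple(int(s) for s in self.signs)
        if len(self.reactions) < 2:
            raise ValidationError("a loop certificate needs at least 2 reactions")
        if not (len(self.reactions) == len(self.gamma) == len(self.signs)):
            raise ValidationError("certificate fields must have equal lengths")
        if any(g <= 0 for g in self.gamma):
            raise ValidationError("certificate weights must be strictly positive")
        if any(s not in (-1, 1) for s in self.signs):
            raise ValidationError("certificate signs must be +/-1")

    @property
    def length(self) -> int:
        return len(self.reactions)

    def canonical_key(self):
        """Dedup key: reaction/sign multiset, invariant to gamma scaling and
        to global sign inversion (a cycle and its reverse are one cycle)."""
        fwd = tuple(sorted(zip(self.reactions, self.signs)))
        rev = tuple(sorted(zip(self.reactions, (-s for s in self.signs))))
        return min(fwd, rev)


def _residual(network: ReactionNetwork, cert: LoopCertificate) -> float:
    cols = network.S[:, list(cert.reactions)]
    w = np.array(cert.gamma) * np.array(cert.signs)
    return float(np.max(np.abs(cols @ w)))


def verify_loop_certificate(network: ReactionNetwork, cert: LoopCertificate) -> bool:
    """True iff all gamma > 0 (guaranteed by construction) and the signed
    weighted column sum vanishes within ``RESIDUAL_TOL``."""
    if any(r < 0 or r >= network.N for r in cert.reactions):
        raise ValidationError("certificate names a reaction outside the network")
    return _residual(network, cert) <= RESIDUAL_TOL


def _positive_nullvector(A: np.ndarray) -> np.ndarray | None:
    """A strictly positive gamma with A @ gamma = 0, or None.

    One-dimensional nullspaces are decided directly; higher-dimensional
    ones through a small feasibility LP (min sum gamma, A gamma = 0,
    gamma >= 1).  A gamma with a (numerically) zero entry is rejected:
    its support would be a smaller subset, found earlier in the search.
    """
    ns = null_space(A)
    if ns.shape[1] == 0:
        return None
    if ns.shape[1] == 1:
        v = ns[:, 0]
        amax = np.max(np.abs(v))
        if np.min(np.abs(v)) < 1e-9 * amax:
            return None
        if np.all(v > 0) or np.all(v < 0):
            g = np.abs(v)
            return g / g.max()
        return None
    k = A.shape[1]
    res = linprog(np.ones(k), A_eq=A, b_eq=np.zeros(A.shape[0]),
                  bounds=[(1.0, None)] * k, method="highs")
    if res.status == 0:
        g = res.x
        return g / g.max()
    return None


def find_loop(network: ReactionNetwork, sigma: DirectionAssignment,
              candidates, k_max: int = 8, counts: dict[int, int] | None = None,
              budget: int = 2_000_000) -> LoopCertificate | None:
    """Search ``candidates`` for the smallest infeasible loop.

    First the visit-count shortcut is tried: the counts with which each
    candidate was updated over the cycling tail are used directly as trial
    gamma (over a period they satisfy the loop identity exactly).  If that
    fails, subsets are enumerated by increasing size k = 2..k_max in
    lexicographic order and each is tested for a strictly positive null
    combination.  Returns the first certificate found, None if no subset
    up to ``k_max`` qualifies, and raises :class:`BudgetExceededError`
    (distinct from None) if the enumeration cap is hit first.
    """
    cands = sorted({int(r) for r in candidates})
    if any(sigma.sigma[r] == 0 for r in cands):
        raise ValidationError("candidates must be constrained reactions")
    if k_max < 2:
        raise ValidationError("k_max must be at least 2")
    signed_cols = {r: sigma.sigma[r] * network.S[:, r] for r in cands}

    if counts:
        members = [r for r in cands if counts.get(r, 0) > 0]
        if len(members) >= 2:
            g = np.array([counts[r] for r in members], dtype=float)
            cols = np.column_stack([signed_cols[r] for r in members])
            if np.max(np.abs(cols @ g)) <= RESIDUAL_TOL * g.max():
                g = g / g.max()
                return LoopCertificate(members, g, [sigma.sigma[r] for r in members])

    # per-candidate sign masks for the fast necessary test
    pos = {r: signed_cols[r] > 0 for r in cands}
    neg = {r: signed_cols[r] < 0 for r in cands}
    examined = 0
    for k in range(2, min(k_max, len(cands)) + 1):
        for subset in combinations(cands, k):
            examined += 1
            if examined > budget:
                raise BudgetExceededError(
                    f"loop search examined {budget} subsets without a decision"
                )
            p = np.logical_or.reduce([pos[r] for r in subset])
            n = np.logical_or.reduce([neg[r] for r in subset])
            if np.any(p ^ n):  # some row cannot cancel
                continue
            A = np.column_stack([signed_cols[r] for r in subset])
            g = _positive_nullvector(A)
            if g is not None:
                return LoopCertificate(subset, g, [sigma.sigma[r] for r in subset])
    return None


@dataclass
class OracleResult:
    status: str  # "FEASIBLE" or "INFEASIBLE"
    mu: PotentialVector | None = None
    margin: float = 0.0
    certificate: LoopCertificate | None = None


def lp_feasibility_oracle(network: ReactionNetwork, sigma: DirectionAssignment,
                          eps: float = 0.0, clamped_mu: PotentialVector | None = None,
                          bounds=None) -> OracleResult:
    """Exact feasibility decision by linear programming.

    Solves ``max s`` subject to ``sigma_r S[:,r].mu <= -s`` for every
    constrained reaction and ``s <= 1``.  A strictly positive optimum
    certifies feasibility with witness ``mu`` (in the homogeneous case the
    witness is rescaled to margin ``eps`` when requested); otherwise the
    dual weights on the constraints, normalized to max 1, are supported on
    an infeasible loop and returned as a (possibly non-minimal)
    certificate.
    """
    cons = np.flatnonzero(sigma.sigma != 0)
    if cons.size == 0:
        raise ValidationError("no constrained reactions (all sigma are 0)")
    if clamped_mu is not None:
        clamped = clamped_mu.clamped
        mu_fix = clamped_mu.mu
    else:
        clamped = np.zeros(network.M, dtype=bool)
        mu_fix = np.zeros(network.M)
    free_idx = np.flatnonzero(~clamped)
    nfree = free_idx.size
    A = np.zeros((cons.size, nfree + 1))
    b = np.zeros(cons.size)
    for row, r in enumerate(cons):
        s_r = sigma.sigma[r]
        A[row, :nfree] = s_r * network.S[free_idx, r]
        A[row, -1] = 1.0
        b[row] = -s_r * float(network.S[clamped, r] @ mu_fix[clamped])
    var_bounds = []
    lower, upper = bounds if bounds is not None else (None, None)
    for i in free_idx:
        lo = lower[i] if lower is not None else None
        hi = upper[i] if upper is not None else None
        var_bounds.append((lo, hi))
    var_bounds.append((None, 1.0))  # s
    c = np.zeros(nfree + 1)
    c[-1] = -1.0
    res = linprog(c, A_ub=A, b_ub=b, bounds=var_bounds, method="highs")
    if res.status != 0:
        raise ValidationError(f"feasibility LP did not solve: {res.message}")
    s_opt = float(res.x[-1])
    if s_opt > 1e-9:
        mu = mu_fix.copy()
        mu[free_idx] = res.x[:nfree]
        homogeneous = clamped_mu is None and bounds is None
        if homogeneous and eps > 0:
            mu *= eps / s_opt
        return OracleResult("FEASIBLE", mu=PotentialVector(mu, clamped), margin=s_opt)
    duals = -np.asarray(res.ineqlin.marginals)
    support = duals > 1e-9 * max(duals.max(), 1.0)
    members = [int(cons[i]) for i in np.flatnonzero(support)]
    g = duals[support]
    g = g / g.max()
    cert = LoopCertificate(members, g, [int(sigma.sigma[r]) for r in members])
    return OracleResult("INFEASIBLE", certificate=cert)


def remove_loop(sigma: DirectionAssignment, cert: LoopCertificate,
                reversible: np.ndarray, rng) -> DirectionAssignment:
    """Flip the direction of one reversible loop member chosen uniformly.

    Raises :class:`UnrepairableLoopError` when every member is
    irreversible: the loop pins those directions and the assignment
    cannot be repaired by direction flips.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    flippable = [r for r in cert.reactions if reversible[r]]
    if not flippable:
        raise UnrepairableLoopError(
            "infeasible loop with no reversible member; directions "
            f"{cert.reactions} are pinned", certificate=cert,
        )
    choice = int(rng.choice(len(flippable)))
    out = sigma.copy()
    out.sigma[flippable[choice]] *= -1
    return out


@dataclass
class CorrectionResult:
    sigma: DirectionAssignment
    mu: PotentialVector
    certificates: list[LoopCertificate]
    status: str
    rounds: int
    escalations: int = 0


def correct_directions(network: ReactionNetwork, sigma0: DirectionAssignment,
                       priors=None, config: SolverConfig | None = None, *,
                       seed=0, k_max: int = 8, max_rounds: int = 100,
                       loop_budget: int = 2_000_000) -> CorrectionResult:
    """Identify-and-remove pipeline until a feasible assignment is reached.

    Each round runs MinOver from a fresh prior draw (or zeros); on
    MAX_ITERS the distinct reactions of the cycling tail are searched for
    a loop, with one escalation to every reaction that was ever least
    satisfied, and one reversible loop member is flipped.  On success the
    returned sigma differs from ``sigma0`` only on reversible reactions
    and the returned potentials certify feasibility.
    """
    from .priors import sample_prior  # local import avoids a cycle

    config = config or SolverConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = sigma0.copy()
    certs: list[LoopCertificate] = []
    escalations = 0
    for rnd in range(1, max_rounds + 1):
        if priors is not None:
            mu0 = sample_prior(priors, rng)
        else:
            mu0 = PotentialVector.zeros(network.M)
        res = minover_solve(network, sigma, mu0, config)
        if res.status == FEASIBLE:
            return CorrectionResult(sigma, res.mu, certs, "FEASIBLE", rnd, escalations)
        cert = find_loop(network, sigma, sorted(set(res.r0_tail)), k_max,
                         counts=res.tail_counts, budget=loop_budget)
        if cert is None:
            escalations += 1
            cert = find_loop(network, sigma, sorted(res.visited), k_max,
                             budget=loop_budget)
            if cert is None:
                raise LoopSearchError(
                    f"solver cycled but no loop of length <= {k_max} was found "
                    f"among {len(res.visited)} visited reactions"
                )
        sigma = remove_loop(sigma, cert, network.reversible, rng)
        certs.append(cert)
    raise BudgetExceededError(
        f"loop removal did not reach feasibility in {max_rounds} rounds",
        partial=certs,
    )


@dataclass
class CatalogueEntry:
    certificate: LoopCertificate
    occurrences: int


@dataclass
class CatalogueResult:
    entries: list[CatalogueEntry]
    feasible_fraction: float
    statuses: list[str]


def catalogue_loops(network: ReactionNetwork, sigmas, config: SolverConfig | None = None,
                    *, seed=0, k_max: int = 8, max_rounds: int = 100) -> CatalogueResult:
    """Run :func:`correct_directions` over an ensemble of direction draws.

    Loops are deduplicated by reaction set and sign pattern up to global
    inversion; per-draw failures are recorded in ``statuses`` instead of
    aborting the ensemble.  ``feasible_fraction`` is the share of draws
    that were feasible without any repair.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dedup: dict[tuple, CatalogueEntry] = {}
    statuses = []
    n_clean = 0
    sigmas = list(sigmas)
    if not sigmas:
        raise ValidationError("ensemble must be nonempty")

    def _log(cert: LoopCertificate):
        key = cert.canonical_key()
        if key in dedup:
            dedup[key].occurrences += 1
        else:
            dedup[key] = CatalogueEntry(cert, 1)

    for s0 in sigmas:
        try:
            r = correct_directions(network, s0, config=config, seed=rng,
                                   k_max=k_max, max_rounds=max_rounds)
        except UnrepairableLoopError as e:
            if e.certificate is not None:
                _log(e.certificate)
            statuses.append("UNREPAIRABLE")
            continue
        except (LoopSearchError, BudgetExceededError) as e:
            statuses.append(f"ERROR: {e}")
            continue
        if not r.certificates:
            n_clean += 1
            statuses.append("FEASIBLE")
        else:
            statuses.append("REPAIRED")
            for cert in r.certificates:
                _log(cert)
    return CatalogueResult(
        entries=list(dedup.values()),
        feasible_fraction=n_clean / len(sigmas),
        statuses=statuses,
    )


def certified_feasibility(network: ReactionNetwork, sigma: DirectionAssignment,
                          mu: PotentialVector, eps: float) -> bool:
    """Recompute Gibbs changes and confirm every constrained reaction
    satisfies ``sigma_r DeltaG_r <= -eps`` (with 1e-9 slack)."""
    dg = gibbs_changes(network, mu)
    cons = sigma.sigma != 0
    return bool(np.all(sigma.sigma[cons] * dg[cons] <= -eps + 1e-9))
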