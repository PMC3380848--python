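"""Desk-scale validation experiments on synthetic ground-truth fixtures.

Each function generates its own fixtures from a seed, runs the method
under study, and returns summary statistics.  They back both the test
suite and the reproduction script, so the numbers reported there are
always recomputed from scratch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UnrepairableLoopError
from .loops import (correct_directions, find_loop, lp_feasibility_oracle,
                    verify_loop_certificate)
from .network_io import DirectionAssignment
from .priors import build_prior, sample_prior
from .synthetic import (FixtureSpec, generate_network, generate_prior_table,
                        plant_feasible_directions, plant_loop)
from .thermo_core import (FEASIBLE, MAX_ITERS, PotentialVector, SolverConfig,
                          distance_to_prior, minover_solve, penalty_solve)

__all__ = [
    "classify",
    "random_instance",
    "oracle_agreement_experiment",
    "loop_recovery_experiment",
    "repair_experiment",
    "distance_comparison_experiment",
    "convergence_experiment",
]


def classify(network, sigma, config: SolverConfig | None = None, *,
             chunk: int = 4000, max_total: int = 60_000, k_max: int = 8):
    """MinOver-based feasibility classification.

    Runs MinOver in chunks; a FEASIBLE exit classifies immediately, while
    a MAX_ITERS exit triggers a loop search over the cycling tail -- only
    a verified certificate classifies the instance as infeasible,
    otherwise the sweep resumes from the current iterate.  Returns
    ("FEASIBLE" | "INFEASIBLE" | "UNDECIDED", certificate_or_None).
    """
    cfg = config or SolverConfig()
    mu = PotentialVector.zeros(network.M)
    spent = 0
    while spent < max_total:
        step_cfg = SolverConfig(lam=cfg.lam, eps=cfg.eps, max_iters=chunk,
                                window=min(chunk, 2000), seed=cfg.seed)
        res = minover_solve(network, sigma, mu, step_cfg)
        spent += res.iterations
        if res.status == FEASIBLE:
            return "FEASIBLE", None
        cert = find_loop(network, sigma, sorted(set(res.r0_tail)), k_max,
                         counts=res.tail_counts)
        if cert is not None and verify_loop_certificate(network, cert):
            return "INFEASIBLE", cert
        mu = res.mu
    return "UNDECIDED", None


def random_instance(seed: int, *, feasible: bool, margin: float = 0.5,
                    loop_length: int = 3, m_max: int = 20, n_max: int = 25,
                    reversible_loop: bool = True):
    """One desk-scale instance with known feasibility status.

    Feasible instances carry directions planted with the given margin;
    infeasible ones additionally carry a planted loop of the given length
    (over fresh metabolites, so it is the unique minimal certificate).
    Returns (network, sigma, planted_certificate_or_None).
    """
    rng = np.random.default_rng(seed)
    m = int(rng.integers(6, m_max - 6 if not feasible else m_max)) + 1
    n = int(rng.integers(8, n_max - loop_length if not feasible else n_max)) + 1
    spec = FixtureSpec(M=max(m, 4), N=max(n, 5), density=0.3,
                       reversible_fraction=0.5, seed=int(rng.integers(2**31)))
    net = generate_network(spec)
    sigma, _ = plant_feasible_directions(net, margin, rng)
    if feasible:
        return net, sigma, None
    pattern = ([True] * loop_length if reversible_loop
               else [False] * loop_length)
    if reversible_loop:
        # mix of reversible and irreversible members, at least one reversible
        pattern = [True] + [bool(rng.random() < 0.5) for _ in range(loop_length - 1)]
    net, sigma, cert = plant_loop(net, sigma, loop_length,
                                  reversible_pattern=pattern)
    return net, sigma, cert


def oracle_agreement_experiment(n_instances: int = 500, seed: int = 0,
                                margins=(0.1, 1.0), loop_lengths=(2, 3, 4, 5, 6),
                                config: SolverConfig | None = None) -> dict:
    """Cross-validate MinOver classification against the LP/Farkas oracle.

    Half the instances are planted feasible, half carry planted loops;
    returns the agreement fraction and the per-class tallies.
    """
    rng = np.random.default_rng(seed)
    agree = 0
    tallies = {"feasible": 0, "infeasible": 0, "undecided": 0}
    for i in range(n_instances):
        feas = i % 2 == 0
        margin = margins[i % len(margins)]
        length = loop_lengths[i % len(loop_lengths)]
        net, sigma, _ = random_instance(int(rng.integers(2**31)), feasible=feas,
                                        margin=margin, loop_length=length)
        verdict, _ = classify(net, sigma, config)
        oracle = lp_feasibility_oracle(net, sigma)
        if verdict == "UNDECIDED":
            tallies["undecided"] += 1
        elif verdict == oracle.status:
            agree += 1
            tallies[verdict.lower()] += 1
    return {"agreement": agree / n_instances, "n": n_instances, "tallies": tallies}


def loop_recovery_experiment(n_instances: int = 200, seed: int = 0,
                             loop_lengths=(2, 3, 4, 5, 6),
                             config: SolverConfig | None = None) -> dict:
    """Planted-loop recovery: the certificate found from the MinOver tail
    must verify and its reaction set must equal the planted set."""
    rng = np.random.default_rng(seed)
    exact = 0
    for i in range(n_instances):
        length = loop_lengths[i % len(loop_lengths)]
        net, sigma, planted = random_instance(int(rng.integers(2**31)),
                                              feasible=False, loop_length=length)
        verdict, cert = classify(net, sigma, config)
        if (verdict == "INFEASIBLE" and cert is not None
                and verify_loop_certificate(net, cert)
                and set(cert.reactions) == set(planted.reactions)):
            exact += 1
    return {"recovery": exact / n_instances, "n": n_instances}


def repair_experiment(n_instances: int = 200, seed: int = 0,
                      config: SolverConfig | None = None) -> dict:
    """Repair soundness on planted repairable loops.

    Every success must be oracle-feasible and differ from the input only
    on reversible reactions; all-irreversible loops must surface as
    unrepairable errors carrying a certificate.
    """
    rng = np.random.default_rng(seed)
    cfg = config or SolverConfig(max_iters=6000, window=2000)
    sound = 0
    n_unrepairable = 0
    unrepairable_certified = 0
    for i in range(n_instances):
        repairable = i % 5 != 0  # every 5th instance gets an all-irreversible loop
        length = 2 + i % 5
        net, sigma0, _ = random_instance(int(rng.integers(2**31)), feasible=False,
                                         loop_length=length,
                                         reversible_loop=repairable)
        try:
            res = correct_directions(net, sigma0, config=cfg,
                                     seed=int(rng.integers(2**31)))
        except UnrepairableLoopError as e:
            n_unrepairable += 1
            if e.certificate is not None and verify_loop_certificate(net, e.certificate):
                unrepairable_certified += 1
            continue
        changed = np.flatnonzero(res.sigma.sigma != sigma0.sigma)
        only_rev = bool(np.all(net.reversible[changed]))
        oracle_ok = lp_feasibility_oracle(net, res.sigma).status == "FEASIBLE"
        if only_rev and oracle_ok:
            sound += 1
    n_repairable = n_instances - n_unrepairable
    return {
        "soundness": sound / n_repairable if n_repairable else 0.0,
        "n_repairable": n_repairable,
        "n_unrepairable": n_unrepairable,
        "unrepairable_certified": unrepairable_certified,
    }


def plant_directions_from_prior(network, priors, margin, rng, budget: int = 10_000):
    """Directions feasible by construction *and* consistent with the prior.

    A witness is drawn from the prior boxes and metabolites of any
    reaction with ``|DeltaG| < margin`` are redrawn from their own boxes
    until every margin clears; ``sigma = -sign(DeltaG)``.  This emulates
    the cellular setting where steady-state flux directions are broadly
    compatible with the biochemical landscape.
    """
    centers = np.array([p.mu_center for p in priors])
    half = np.array([p.mu_halfwidth for p in priors])
    clamped = np.array([p.clamp for p in priors], dtype=bool)
    mu = sample_prior(priors, rng).mu
    for _ in range(budget):
        dg = network.S.T @ mu
        bad = np.abs(dg) < margin
        if not bad.any():
            return DirectionAssignment(-np.sign(dg).astype(int)), mu
        touched = np.unique(np.nonzero(network.S[:, bad])[0])
        touched = touched[~clamped[touched]]
        mu[touched] = centers[touched] + half[touched] * rng.uniform(
            -1.0, 1.0, size=touched.size)
    raise RuntimeError(f"could not plant margin {margin} within prior boxes")


def distance_comparison_experiment(n_instances: int = 50, seed: int = 0,
                                   M: int = 35, N: int = 40,
                                   lam: float = 0.02) -> dict:
    """MinOver vs penalty-method distance to the prior on cell-scale
    fixtures with priors built from synthetic thermodynamic tables.

    Directions are planted from a witness inside the prior boxes, both
    solvers start at / anchor to the same fresh prior draw, and
    feasibility of both solutions is confirmed by the LP oracle.  Returns
    the two mean distances and their ratio.
    """
    rng = np.random.default_rng(seed)
    d_min, d_pen = [], []
    feasible_checked = 0
    for _ in range(n_instances):
        spec = FixtureSpec(M=M, N=N, density=0.15, reversible_fraction=0.5,
                           seed=int(rng.integers(2**31)))
        net = generate_network(spec)
        table = generate_prior_table(net, rng)
        priors = build_prior(net, table)
        sigma, _ = plant_directions_from_prior(net, priors, 1.0, rng)
        mu0 = sample_prior(priors, rng)
        mo = minover_solve(net, sigma, mu0, SolverConfig(lam=lam, max_iters=400_000))
        pe = penalty_solve(net, sigma, mu0,
                           SolverConfig(eta=1e-3, beta0=1.0, beta_step=1.0,
                                        max_iters=400_000))
        if (mo.status == FEASIBLE and pe.status == FEASIBLE
                and lp_feasibility_oracle(net, sigma).status == "FEASIBLE"):
            feasible_checked += 1
            d_min.append(distance_to_prior(mo.mu, mu0))
            d_pen.append(distance_to_prior(pe.mu, mu0))
    mean_min = float(np.mean(d_min)) if d_min else float("nan")
    mean_pen = float(np.mean(d_pen)) if d_pen else float("nan")
    return {
        "mean_distance_minover": mean_min,
        "mean_distance_penalty": mean_pen,
        "ratio": mean_min / mean_pen if mean_pen else float("nan"),
        "n_feasible_pairs": feasible_checked,
        "n": n_instances,
    }


def convergence_experiment(n_instances: int = 100, seed: int = 0,
                           lams=(0.01, 0.1, 1.0), margins=(0.1, 1.0)) -> dict:
    """Termination across step sizes and iteration counts across margins.

    Every planted-feasible instance must terminate FEASIBLE for each step
    constant; the median iteration count at the larger margin must not
    exceed the median at the smaller one.
    """
    rng = np.random.default_rng(seed)
    converged = 0
    total = 0
    iters = {c: [] for c in margins}
    for i in range(n_instances):
        inst_seed = int(rng.integers(2**31))
        for c in margins:
            net, sigma, _ = random_instance(inst_seed, feasible=True, margin=c)
            for lam in lams:
                res = minover_solve(net, sigma, PotentialVector.zeros(net.M),
                                    SolverConfig(lam=lam, max_iters=2_000_000))
                total += 1
                if res.status == FEASIBLE:
                    converged += 1
                if lam == 0.1:
                    iters[c].append(res.iterations)
    medians = {c: float(np.median(v)) for c, v in iters.items()}
    return {
        "converged_fraction": converged / total,
        "n_runs": total,
        "median_iters_by_margin": medians,
    }
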