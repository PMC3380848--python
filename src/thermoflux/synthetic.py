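"""Synthetic networks, priors and direction assignments with ground truth.

Fixtures emulate the two study settings at desk scale: small random sparse
stoichiometries with integer coefficients (so certificates verify exactly
and TSV round trips are bit-exact), direction assignments that are feasible
by construction (planted from a known potential vector with a prescribed
margin), short planted loops over fresh metabolites (so the ground-truth
certificate is unique and minimal), and per-metabolite prior tables with
stated centers and widths.  All generators are pure functions of their
(spec, seed) arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .loops import LoopCertificate
from .network_io import DirectionAssignment, ReactionNetwork

__all__ = [
    "FixtureSpec",
    "generate_network",
    "plant_feasible_directions",
    "plant_loop",
    "random_direction_assignment",
    "generate_prior_table",
]


@dataclass
class FixtureSpec:
    """Parameters of a random network fixture."""

    M: int = 10
    N: int = 12
    density: float = 0.3
    coeff_values: tuple[int, ...] = (1, 2)
    n_planted_loops: int = 0
    loop_lengths: tuple[int, ...] = ()
    reversible_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.density <= 1):
            raise ValidationError("density must lie in (0, 1]")
        if self.M < 2 or self.N < 1:
            raise ValidationError("need M >= 2 (a substrate and a product) and N >= 1")
        if any(k < 2 for k in self.loop_lengths):
            raise ValidationError("loop lengths must be >= 2")
        if not (0 <= self.reversible_fraction <= 1):
            raise ValidationError("reversible_fraction must lie in [0, 1]")


def generate_network(spec: FixtureSpec) -> ReactionNetwork:
    """Random sparse stoichiometry; every reaction has at least one
    substrate and one product, coefficients drawn from +/-coeff_values."""
    rng = np.random.default_rng(spec.seed)
    S = np.zeros((spec.M, spec.N))
    vals = np.asarray(spec.coeff_values, dtype=float)
    for j in range(spec.N):
        k = max(2, int(rng.binomial(spec.M, spec.density)))
        k = min(k, spec.M)
        rows = rng.choice(spec.M, size=k, replace=False)
        coeffs = rng.choice(vals, size=k) * rng.choice([-1.0, 1.0], size=k)
        # force at least one substrate and one product
        coeffs[0] = -abs(coeffs[0])
        coeffs[1] = abs(coeffs[1])
        S[rows, j] = coeffs
    reversible = rng.random(spec.N) < spec.reversible_fraction
    mids = [f"M{i:03d}" for i in range(spec.M)]
    rids = [f"R{j:03d}" for j in range(spec.N)]
    return ReactionNetwork(mids, rids, S, reversible)


def plant_feasible_directions(network: ReactionNetwork, margin: float, seed,
                              mu_scale: float = 5.0, budget: int = 10_000
                              ) -> tuple[DirectionAssignment, np.ndarray]:
    """Directions feasible by construction with margin >= ``margin``.

    Draws a witness mu* uniformly on [-mu_scale, mu_scale], sets
    ``sigma_r = -sign(DeltaG_r(mu*))`` and resamples the metabolites of
    any reaction with ``|DeltaG_r| < margin`` until all margins clear, so
    the pair (sigma, mu*) satisfies ``sigma_r DeltaG_r <= -margin``.
    """
    if margin <= 0:
        raise ValidationError("margin must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu = rng.uniform(-mu_scale, mu_scale, size=network.M)
    for _ in range(budget):
        dg = network.S.T @ mu
        bad = np.abs(dg) < margin
        if not bad.any():
            sigma = -np.sign(dg).astype(int)
            return DirectionAssignment(sigma), mu
        touched = np.unique(np.nonzero(network.S[:, bad])[0])
        mu[touched] = rng.uniform(-mu_scale, mu_scale, size=touched.size)
    raise ValidationError(
        f"could not plant margin {margin} within {budget} resamples; "
        "try a smaller margin or larger mu_scale"
    )


def plant_loop(network: ReactionNetwork, sigma: DirectionAssignment, k: int,
               attach_points=None, reversible_pattern=None, signs=None,
               tag: int | None = None
               ) -> tuple[ReactionNetwork, DirectionAssignment, LoopCertificate]:
    """Append a directed k-cycle whose signed columns cancel exactly.

    The cycle runs over k metabolites (fresh by default; ``attach_points``
    may name existing metabolite indices to route it through).  Reaction j
    converts node j into node j+1 (mod k); when ``signs[j]`` is -1 the
    column is stored reversed so that ``sigma_j * S[:, j]`` still follows
    the cycle, making gamma = (1, ..., 1) an exact certificate.
    Reversibility of the new reactions follows ``reversible_pattern``
    (default: all reversible).
    """
    if k < 2:
        raise ValidationError("a loop needs at least 2 reactions")
    attach = list(attach_points or [])
    if len(attach) > k:
        raise ValidationError("more attach points than loop nodes")
    signs = list(signs) if signs is not None else [1] * k
    pattern = list(reversible_pattern) if reversible_pattern is not None else [True] * k
    if len(signs) != k or len(pattern) != k:
        raise ValidationError("signs and reversible_pattern must have length k")
    tag = tag if tag is not None else 0
    n_fresh = k - len(attach)
    fresh_ids = [f"LM{tag}_{i}" for i in range(n_fresh)]
    mids = network.metabolite_ids + fresh_ids
    node_rows = attach + [network.M + i for i in range(n_fresh)]
    m_new = len(mids)
    S_new = np.zeros((m_new, network.N + k))
    S_new[: network.M, : network.N] = network.S
    rids = network.reaction_ids + [f"LR{tag}_{j}" for j in range(k)]
    new_sigma = np.concatenate([sigma.sigma, np.asarray(signs, dtype=int)])
    for j in range(k):
        col = np.zeros(m_new)
        col[node_rows[j]] = -1.0
        col[node_rows[(j + 1) % k]] = 1.0
        S_new[:, network.N + j] = signs[j] * col  # sigma_j * column follows the cycle
    reversible = np.concatenate([network.reversible, np.asarray(pattern, dtype=bool)])
    net = ReactionNetwork(mids, rids, S_new, reversible)
    cert = LoopCertificate(
        tuple(range(network.N, network.N + k)),
        (1.0,) * k,
        tuple(int(s) for s in signs),
    )
    return net, DirectionAssignment(new_sigma), cert


def random_direction_assignment(network: ReactionNetwork, seed) -> DirectionAssignment:
    """Worst-case all-active draw: irreversible reactions keep their
    annotated forward direction; each reversible reaction independently
    gets +/-1 with probability one half; no reaction is left unassigned."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = np.ones(network.N, dtype=int)
    rev = network.reversible
    sigma[rev] = rng.choice([-1, 1], size=int(rev.sum()))
    return DirectionAssignment(sigma)


def generate_prior_table(network: ReactionNetwork, seed, *,
                         missing_conc_fraction: float = 0.15,
                         clamp_first: bool = False,
                         deltaG0_sd: float = 20.0,
                         log10_conc_range: tuple[float, float] = (-5.0, -2.0),
                         sd_fraction: float = 0.2) -> pd.DataFrame:
    """Synthetic thermodynamic prior table mirroring the real-data layout.

    Formation energies are generated so that *standard reaction* Gibbs
    energies are modest -- each reaction's target DeltaG0 is drawn
    N(0, deltaG0_sd kJ/mol) and per-metabolite formation energies are the
    least-squares fit to those targets -- matching curated tables, where
    formation energies largely cancel across balanced reactions (the
    absolute scale is irrelevant: only differences enter DeltaG).  Concentrations are log-uniform over
    ``log10_conc_range`` (molar) with standard deviation
    ``sd_fraction * c`` (so c - 2 sd stays positive), a
    ``missing_conc_fraction`` share of metabolites lacks concentration
    data, and optionally the first metabolite is clamped (playing the role
    water plays in the cellular system).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    target = rng.normal(0.0, deltaG0_sd, size=network.N)
    fit, *_ = np.linalg.lstsq(network.S.T, target, rcond=None)
    dgf0 = fit
    rows = []
    for i, mid in enumerate(network.metabolite_ids):
        dgf = float(dgf0[i])
        if rng.random() < missing_conc_fraction:
            c = sd = None
        else:
            c = float(10.0 ** rng.uniform(*log10_conc_range))
            sd = sd_fraction * c
        rows.append({
            "metabolite_id": mid,
            "dGf0_kJ_per_mol": dgf,
            "conc_center_M": c,
            "conc_sd_M": sd,
            "clamp": 1 if (clamp_first and i == 0) else 0,
        })
    return pd.DataFrame(rows)
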