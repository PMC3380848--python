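"""Biochemical priors: from formation energies and concentration ranges to
trial distributions for chemical potentials.

Under the dilute-solution hypothesis the chemical potential of metabolite
i at concentration ``c`` (molar) is

    mu_i = dGf0_i + R*T*ln(c / c0),        c0 = 1 M,

with ``dGf0_i`` the standard Gibbs energy of formation (kJ/mol).  A
metabolite with a measured concentration ``c +/- sd`` gets a uniform trial
interval spanning the image of ``[c - 2 sd, c + 2 sd]``; a metabolite with
a known formation energy but no concentration estimate gets an interval
spanning four orders of magnitude in concentration around a default level;
clamped metabolites (e.g. water, which sets the energy scale) get a
zero-width interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .errors import ValidationError
from .network_io import DirectionAssignment, ReactionNetwork
from .thermo_core import PotentialVector

__all__ = [
    "R_KJ",
    "DEFAULT_T",
    "MetabolitePrior",
    "PriorPolicy",
    "mu_from_concentration",
    "concentration_from_mu",
    "build_prior",
    "sample_prior",
    "boundedness_check",
    "read_priors",
    "write_priors",
]

#: Gas constant in kJ/(mol K); R*T = 2.4790 kJ/mol at 298.15 K.
R_KJ = 8.314462618e-3
DEFAULT_T = 298.15


def mu_from_concentration(dGf0: float, c: float, T: float = DEFAULT_T) -> float:
    """mu = dGf0 + RT ln(c/1M); strictly increasing in c."""
    if c <= 0:
        raise ValidationError(f"concentration must be positive, got {c}")
    if T <= 0:
        raise ValidationError(f"temperature must be positive, got {T}")
    return float(dGf0 + R_KJ * T * math.log(c))


def concentration_from_mu(dGf0: float, mu: float, T: float = DEFAULT_T) -> float:
    """Exact inverse of :func:`mu_from_concentration` (molar)."""
    if T <= 0:
        raise ValidationError(f"temperature must be positive, got {T}")
    x = (mu - dGf0) / (R_KJ * T)
    if abs(x) > 700:
        raise ValidationError("concentration overflow: |mu - dGf0|/RT > 700")
    return float(math.exp(x))


@dataclass
class MetabolitePrior:
    """Uniform trial distribution for one metabolite's chemical potential."""

    metabolite_id: str
    mu_center: float
    mu_halfwidth: float
    clamp: bool = False
    dGf0: float | None = None
    conc_center: float | None = None
    conc_sd: float | None = None

    def __post_init__(self):
        if self.mu_halfwidth < 0 or not np.isfinite(self.mu_halfwidth):
            raise ValidationError(
                f"{self.metabolite_id}: halfwidth must be finite and nonnegative"
            )
        if self.clamp and self.mu_halfwidth != 0.0:
            raise ValidationError(f"{self.metabolite_id}: clamped prior must have zero width")


@dataclass
class PriorPolicy:
    """How to treat metabolites with partial or missing thermodynamic data.

    ``default_conc`` is the concentration assumed when only the formation
    energy is known; ``decades`` the full uniform span (in orders of
    magnitude of concentration) assigned to such metabolites;
    ``symmetric_in`` chooses whether the two-standard-deviation span is
    symmetric in concentration ('c', center at mu(c)) or symmetrized in
    the potential scale ('mu', center at the interval midpoint);
    ``default_dGf0``, if set, covers metabolites missing from the table
    entirely.
    """

    default_conc: float = 1e-3
    decades: float = 4.0
    temperature: float = DEFAULT_T
    symmetric_in: str = "c"
    default_dGf0: float | None = None

    def __post_init__(self):
        if self.symmetric_in not in ("c", "mu"):
            raise ValidationError("symmetric_in must be 'c' or 'mu'")
        if self.default_conc <= 0 or self.decades <= 0 or self.temperature <= 0:
            raise ValidationError("policy parameters must be positive")


def _prior_from_record(mid, dGf0, c, sd, clamp, policy: PriorPolicy) -> MetabolitePrior:
    T = policy.temperature
    if dGf0 is None:
        if policy.default_dGf0 is None:
            raise ValidationError(
                f"metabolite {mid!r} has no thermodynamic data and the policy "
                "provides no default formation energy"
            )
        dGf0 = policy.default_dGf0
    if c is not None and sd is not None:
        lo_c, hi_c = c - 2 * sd, c + 2 * sd
        if lo_c <= 0:
            raise ValidationError(
                f"metabolite {mid!r}: c - 2sd = {lo_c} is not positive (degenerate range)"
            )
        lo = mu_from_concentration(dGf0, lo_c, T)
        hi = mu_from_concentration(dGf0, hi_c, T)
        if policy.symmetric_in == "c":
            center = mu_from_concentration(dGf0, c, T)
        else:
            center = 0.5 * (lo + hi)
        halfwidth = 0.5 * (hi - lo)
    else:
        center = mu_from_concentration(dGf0, c if c is not None else policy.default_conc, T)
        halfwidth = R_KJ * T * math.log(10.0) * policy.decades / 2.0
    if clamp:
        halfwidth = 0.0
    return MetabolitePrior(mid, center, halfwidth, clamp=bool(clamp),
                           dGf0=dGf0, conc_center=c, conc_sd=sd)


def build_prior(network: ReactionNetwork, prior_table, policy: PriorPolicy | None = None
                ) -> list[MetabolitePrior]:
    """Build one :class:`MetabolitePrior` per network metabolite, in order.

    ``prior_table`` is a DataFrame (or list of dicts) with columns
    ``metabolite_id, dGf0_kJ_per_mol, conc_center_M, conc_sd_M, clamp``;
    missing values are NaN/None.  Metabolites absent from the table fall
    back to the policy's ``default_dGf0`` or raise.
    """
    policy = policy or PriorPolicy()
    if not isinstance(prior_table, pd.DataFrame):
        prior_table = pd.DataFrame(list(prior_table))
    records = {}
    for _, row in prior_table.iterrows():
        mid = str(row["metabolite_id"])
        def _get(col):
            v = row.get(col)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return None
            return float(v)
        records[mid] = (
            _get("dGf0_kJ_per_mol"),
            _get("conc_center_M"),
            _get("conc_sd_M"),
            bool(int(row.get("clamp", 0) or 0)),
        )
    priors = []
    for mid in network.metabolite_ids:
        if mid in records:
            dGf0, c, sd, clamp = records[mid]
        else:
            dGf0, c, sd, clamp = None, None, None, False
        priors.append(_prior_from_record(mid, dGf0, c, sd, clamp, policy))
    return priors


def sample_prior(priors: list[MetabolitePrior], seed) -> PotentialVector:
    """Draw each unclamped potential uniformly from its prior interval.

    ``seed`` may be an integer or a ``numpy.random.Generator``; clamped
    entries are returned at their center exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    centers = np.array([p.mu_center for p in priors])
    half = np.array([p.mu_halfwidth for p in priors])
    clamped = np.array([p.clamp for p in priors], dtype=bool)
    draw = centers + half * rng.uniform(-1.0, 1.0, size=len(priors))
    draw[clamped] = centers[clamped]
    return PotentialVector(draw, clamped)


@dataclass
class BoundednessResult:
    status: str  # "BOUNDED" or "UNBOUNDED"
    ray: np.ndarray | None = None  # full-length witness direction (zeros at clamped)


def boundedness_check(network: ReactionNetwork, sigma: DirectionAssignment,
                      clamped: np.ndarray | None = None, bounds=None,
                      tol: float = 1e-7) -> BoundednessResult:
    """Decide whether the solution space's recession cone is {0}.

    The cone lives on unclamped coordinates x and consists of directions
    with ``sigma_r * S[:, r] . x <= 0`` for every constrained reaction,
    plus the homogeneous residue of any box bounds (a finite upper bound
    kills growth upward, a finite lower bound kills growth downward).
    Each coordinate's reach is probed by a pair of LPs capped at
    ``|x|_inf <= 1``; any strictly nonzero optimum yields a witness ray.
    """
    clamped = np.zeros(network.M, dtype=bool) if clamped is None else np.asarray(clamped, bool)
    free_idx = np.flatnonzero(~clamped)
    if free_idx.size == 0:
        return BoundednessResult("BOUNDED")
    cons = np.flatnonzero(sigma.sigma != 0)
    A_ub = (network.S[free_idx][:, cons] * sigma.sigma[cons]).T if cons.size else None
    b_ub = np.zeros(cons.size) if cons.size else None
    var_bounds = []
    lower, upper = bounds if bounds is not None else (None, None)
    for i in free_idx:
        lo, hi = -1.0, 1.0
        if upper is not None and upper[i] is not None and np.isfinite(upper[i]):
            hi = 0.0
        if lower is not None and lower[i] is not None and np.isfinite(lower[i]):
            lo = 0.0
        var_bounds.append((lo, hi))
    n = free_idx.size
    for j in range(n):
        for sign in (-1.0, 1.0):
            c = np.zeros(n)
            c[j] = sign  # minimize sign*x_j  ==  maximize -sign*x_j
            res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=var_bounds, method="highs")
            if res.status != 0:
                raise ValidationError(f"recession-cone LP failed: {res.message}")
            if -res.fun > tol:
                ray = np.zeros(network.M)
                ray[free_idx] = res.x
                return BoundednessResult("UNBOUNDED", ray=ray)
    return BoundednessResult("BOUNDED")


def read_priors(path) -> pd.DataFrame:
    """Read a priors TSV (metabolite_id, dGf0_kJ_per_mol, conc_center_M,
    conc_sd_M, clamp); empty cells become NaN."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"metabolite_id": str})
    expected = {"metabolite_id", "dGf0_kJ_per_mol", "conc_center_M", "conc_sd_M", "clamp"}
    missing = expected - set(df.columns)
    if missing:
        raise ValidationError(f"priors file missing columns: {sorted(missing)}")
    df["clamp"] = df["clamp"].fillna(0).astype(int)
    return df


def write_priors(table: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t", index=False)
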