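"""Plain-text I/O for networks, direction assignments, potentials and loops.

Formats are deliberately simple TSV dialects (UTF-8, ``.`` decimal point,
blank lines and ``#``-comments ignored):

* network file -- first data row lists the reaction identifiers (an
  optional leading label cell such as ``metabolite_id`` is tolerated); an
  optional ``#rev`` row carries one 0/1 reversibility flag per reaction;
  every following row is a metabolite identifier followed by the N signed
  stoichiometric coefficients of that metabolite (substrates negative,
  products positive).
* direction file -- two columns, ``reaction_id`` and a value in
  {-1, 0, +1}; 0 means the reaction carries no direction constraint.
* potentials / Gibbs tables -- small TSVs written by :func:`write_report`.
* loop catalogues -- JSON lists of certificate objects.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ReactionNetwork",
    "DirectionAssignment",
    "read_network",
    "write_network",
    "read_directions",
    "write_directions",
    "write_report",
]


@dataclass
class ReactionNetwork:
    """A stoichiometric matrix with metabolite/reaction labels.

    Attributes
    ----------
    metabolite_ids : list of str
        Unique row labels, length M.
    reaction_ids : list of str
        Unique column labels, length N.
    S : (M, N) ndarray of float
        Signed stoichiometric coefficients; substrates negative, products
        positive.
    reversible : (N,) ndarray of bool
        Reversibility annotation per reaction.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray
    reversible: np.ndarray

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.reversible = np.asarray(self.reversible, dtype=bool)
        if self.S.ndim != 2:
            raise ValidationError("stoichiometric matrix must be 2-D")
        m, n = self.S.shape
        if m < 1 or n < 1:
            raise ValidationError("network needs at least one metabolite and one reaction")
        if len(self.metabolite_ids) != m or len(self.reaction_ids) != n:
            raise ValidationError("identifier lists do not match matrix shape")
        for kind, ids in (("metabolite", self.metabolite_ids), ("reaction", self.reaction_ids)):
            seen = set()
            for i in ids:
                if i in seen:
                    raise FormatError(f"duplicate {kind} id: {i!r}")
                seen.add(i)
        if not np.all(np.isfinite(self.S)):
            raise ValidationError("stoichiometric coefficients must be finite")
        zero = ~np.any(self.S != 0.0, axis=0)
        if np.any(zero):
            bad = self.reaction_ids[int(np.argmax(zero))]
            raise ValidationError(f"reaction {bad!r} has an all-zero stoichiometric column")
        if self.reversible.shape != (n,):
            raise ValidationError("reversible flags must have one entry per reaction")

    @property
    def M(self) -> int:
        return self.S.shape[0]

    @property
    def N(self) -> int:
        return self.S.shape[1]

    def reaction_index(self, rid: str) -> int:
        try:
            return self.reaction_ids.index(rid)
        except ValueError:
            raise KeyError(f"unknown reaction id: {rid!r}") from None

    def metabolite_index(self, mid: str) -> int:
        try:
            return self.metabolite_ids.index(mid)
        except ValueError:
            raise KeyError(f"unknown metabolite id: {mid!r}") from None


@dataclass
class DirectionAssignment:
    """Per-reaction direction signs: +1 forward, -1 backward, 0 unassigned."""

    sigma: np.ndarray

    def __post_init__(self):
        self.sigma = np.asarray(self.sigma, dtype=int)
        if self.sigma.ndim != 1:
            raise ValidationError("sigma must be a vector")
        bad = ~np.isin(self.sigma, (-1, 0, 1))
        if np.any(bad):
            raise ValidationError(
                f"direction values must be in {{-1, 0, +1}}; got {self.sigma[bad][0]}"
            )

    def copy(self) -> "DirectionAssignment":
        return DirectionAssignment(self.sigma.copy())

    @property
    def constrained(self) -> np.ndarray:
        return self.sigma != 0


def _data_lines(path):
    """Yield (lineno, stripped line) skipping blanks and plain comments.

    ``#rev`` rows are data, not comments."""
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith("#") and not line.startswith("#rev"):
                continue
            yield lineno, line


def read_network(path) -> ReactionNetwork:
    """Read a network TSV file; see the module docstring for the layout."""
    reaction_ids = None
    rev_cells = None
    met_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in _data_lines(path):
        cells = line.split("\t")
        if cells[0].startswith("#rev"):
            rev_cells = (lineno, cells[1:])
            continue
        if reaction_ids is None:
            # tolerate a leading label cell on the header row
            if cells[0].strip() in ("", "metabolite_id", "id"):
                cells = cells[1:]
            reaction_ids = [c.strip() for c in cells]
            if not reaction_ids or any(not c for c in reaction_ids):
                raise FormatError(f"{path}: line {lineno}: empty reaction id in header")
            continue
        met_ids.append(cells[0].strip())
        if len(cells) - 1 != len(reaction_ids):
            raise FormatError(
                f"{path}: line {lineno}: expected {len(reaction_ids)} coefficients, "
                f"got {len(cells) - 1}"
            )
        row = []
        for j, cell in enumerate(cells[1:]):
            try:
                row.append(float(cell))
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}, column {j + 2}: non-numeric cell {cell!r}"
                ) from None
        rows.append(row)
    if reaction_ids is None or not rows:
        raise FormatError(f"{path}: file contains no network data")
    n = len(reaction_ids)
    if rev_cells is not None:
        lineno, cells = rev_cells
        if len(cells) != n:
            raise FormatError(f"{path}: line {lineno}: #rev row needs {n} flags")
        try:
            reversible = np.array([int(c) for c in cells], dtype=bool)
        except ValueError:
            raise FormatError(f"{path}: line {lineno}: #rev flags must be 0/1") from None
    else:
        reversible = np.zeros(n, dtype=bool)
    return ReactionNetwork(met_ids, reaction_ids, np.array(rows, dtype=float), reversible)


def write_network(network: ReactionNetwork, path, header_comment: str | None = None) -> None:
    """Write a network TSV; coefficients use shortest round-trip repr."""
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("metabolite_id\t" + "\t".join(network.reaction_ids) + "\n")
        fh.write("#rev\t" + "\t".join(str(int(r)) for r in network.reversible) + "\n")
        for i, mid in enumerate(network.metabolite_ids):
            coeffs = "\t".join(repr(float(x)) for x in network.S[i])
            fh.write(f"{mid}\t{coeffs}\n")


def read_directions(path, network: ReactionNetwork, strict: bool = True) -> DirectionAssignment:
    """Read a two-column direction TSV aligned to ``network``'s reactions.

    In strict mode (default) a nonzero sign against an irreversible
    annotation, or a 0 on an irreversible reaction, is rejected; in lenient
    mode it is accepted with a logged warning.
    """
    values: dict[str, int] = {}
    for lineno, line in _data_lines(path):
        cells = [c.strip() for c in line.split("\t")]
        if cells[0] == "reaction_id":
            continue
        if len(cells) != 2:
            raise FormatError(f"{path}: line {lineno}: expected 2 columns, got {len(cells)}")
        rid, val = cells
        if rid in values:
            raise FormatError(f"{path}: line {lineno}: reaction {rid!r} listed twice")
        try:
            v = int(val)
        except ValueError:
            raise FormatError(f"{path}: line {lineno}: non-integer direction {val!r}") from None
        if v not in (-1, 0, 1):
            raise FormatError(f"{path}: line {lineno}: direction {v} outside {{-1, 0, +1}}")
        values[rid] = v
    unknown = set(values) - set(network.reaction_ids)
    if unknown:
        raise FormatError(f"{path}: unknown reaction id: {sorted(unknown)[0]!r}")
    missing = [r for r in network.reaction_ids if r not in values]
    if missing:
        raise FormatError(f"{path}: missing direction for reaction {missing[0]!r}")
    sigma = np.array([values[r] for r in network.reaction_ids], dtype=int)
    conflict = (~network.reversible) & ((sigma == -1) | (sigma == 0))
    if np.any(conflict):
        rid = network.reaction_ids[int(np.argmax(conflict))]
        msg = (
            f"direction {sigma[int(np.argmax(conflict))]} conflicts with the "
            f"irreversible annotation of reaction {rid!r}"
        )
        if strict:
            raise ValidationError(msg)
        logger.warning("%s (accepted: lenient mode)", msg)
    return DirectionAssignment(sigma)


def write_directions(sigma: DirectionAssignment, network: ReactionNetwork, path,
                     header_comment: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("reaction_id\tsigma\n")
        for rid, s in zip(network.reaction_ids, sigma.sigma):
            fh.write(f"{rid}\t{int(s)}\n")


def _write_potentials(pv, network, path, header_comment=None):
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("metabolite_id\tmu\n")
        for mid, mu in zip(network.metabolite_ids, pv.mu):
            fh.write(f"{mid}\t{repr(float(mu))}\n")


def _write_gibbs(network, deltag, sigma, eps, path, header_comment=None):
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("reaction_id\tdeltaG\tsigma\tsatisfied\n")
        for rid, dg, s in zip(network.reaction_ids, deltag, sigma.sigma):
            ok = 1 if (s == 0 or s * dg <= -eps + 1e-12) else 0
            fh.write(f"{rid}\t{repr(float(dg))}\t{int(s)}\t{ok}\n")


def certificate_to_dict(cert, network: ReactionNetwork, occurrences: int | None = None) -> dict:
    """JSON-serializable view of a loop certificate (Table-style columns)."""
    rids = [network.reaction_ids[r] for r in cert.reactions]
    rev = [network.reaction_ids[r] for r in cert.reactions if network.reversible[r]]
    d = {
        "reactions": rids,
        "signs": [int(s) for s in cert.signs],
        "gamma": [float(g) for g in cert.gamma],
        "reversible_members": rev,
        "length": len(rids),
    }
    if occurrences is not None:
        d["occurrences"] = int(occurrences)
    return d


def write_report(result, path, network: ReactionNetwork | None = None, *,
                 sigma: DirectionAssignment | None = None, eps: float = 0.0,
                 header_comment: str | None = None) -> None:
    """Write a result object to ``path`` in its canonical plain-text form.

    Dispatches on type: a potential vector becomes a two-column TSV, a
    ``(deltaG array, sigma)`` report a four-column TSV, a loop catalogue a
    JSON list, and a solver result a JSON trace summary.
    """
    from .loops import LoopCertificate
    from .thermo_core import PotentialVector, SolveResult

    if isinstance(result, PotentialVector):
        if network is None:
            raise ValidationError("writing potentials requires the network for labels")
        _write_potentials(result, network, path, header_comment)
    elif isinstance(result, np.ndarray) and sigma is not None:
        if network is None:
            raise ValidationError("writing Gibbs changes requires the network for labels")
        _write_gibbs(network, result, sigma, eps, path, header_comment)
    elif isinstance(result, SolveResult):
        payload = {
            "status": result.status,
            "iterations": int(result.iterations),
            "violations": [None if not np.isfinite(v) else float(v) for v in result.violations],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")
    elif isinstance(result, (list, tuple)) and all(
        isinstance(c, LoopCertificate) for c in result
    ):
        if network is None:
            raise ValidationError("writing a loop catalogue requires the network for labels")
        payload = [certificate_to_dict(c, network) for c in result]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")
    else:
        raise ValidationError(f"write_report does not understand {type(result).__name__}")
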