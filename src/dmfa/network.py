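"""Metabolic network representation and steady-state null space.

A network is a list of species, each tagged ``internal`` or ``external``,
and a list of reactions with signed stoichiometric coefficients
(consumption negative, production positive).  From these the internal
stoichiometric matrix ``N`` (rows = internal species) and the external
matrix ``P`` (rows = external species) are assembled; columns follow the
reaction order.  Under the intracellular steady-state assumption,
admissible volumetric flux vectors satisfy ``N @ V = 0`` and are
parameterized as ``V = K @ U`` with ``K`` an orthonormal basis of the
null space of ``N``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Species",
    "Reaction",
    "MetabolicNetwork",
    "NullSpaceBasis",
    "null_space",
    "irreversibility_rows",
    "parse_reaction_equation",
    "read_network",
    "write_network",
]


class NetworkError(ValueError):
    """Raised for malformed network definitions."""


@dataclass(frozen=True)
class Species:
    id: str
    compartment_role: str  # "internal" or "external"
    name: str = ""

    def __post_init__(self) -> None:
        if self.compartment_role not in ("internal", "external"):
            raise NetworkError(
                f"species {self.id!r}: compartment_role must be "
                f"'internal' or 'external', got {self.compartment_role!r}"
            )


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: dict  # species id -> signed coefficient
    reversible: bool = False

    def __post_init__(self) -> None:
        coeffs = np.asarray(list(self.stoichiometry.values()), dtype=float)
        if coeffs.size == 0 or not np.any(coeffs != 0.0):
            raise NetworkError(f"reaction {self.id!r} has no nonzero coefficient")
        if not np.all(np.isfinite(coeffs)):
            raise NetworkError(f"reaction {self.id!r} has non-finite coefficients")


@dataclass
class MetabolicNetwork:
    """Validated network with stoichiometric matrices built on construction."""

    species: list
    reactions: list
    N: np.ndarray = field(init=False)
    P: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise NetworkError(f"duplicate species ids: {dup}")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            raise NetworkError("duplicate reaction ids")
        known = set(ids)
        for r in self.reactions:
            unknown = sorted(set(r.stoichiometry) - known)
            if unknown:
                raise NetworkError(
                    f"reaction {r.id!r} references unknown species {unknown}"
                )
        self.N, self.P = self._build_matrices()

    # -- bookkeeping ---------------------------------------------------
    @property
    def internal_species(self) -> list:
        return [s for s in self.species if s.compartment_role == "internal"]

    @property
    def external_species(self) -> list:
        return [s for s in self.species if s.compartment_role == "external"]

    @property
    def external_ids(self) -> list:
        return [s.id for s in self.external_species]

    @property
    def reaction_ids(self) -> list:
        return [r.id for r in self.reactions]

    @property
    def irreversible_ids(self) -> list:
        return [r.id for r in self.reactions if not r.reversible]

    def _build_matrices(self):
        internal = self.internal_species
        external = self.external_species
        n_rxn = len(self.reactions)
        N = np.zeros((len(internal), n_rxn))
        P = np.zeros((len(external), n_rxn))
        idx_int = {s.id: i for i, s in enumerate(internal)}
        idx_ext = {s.id: i for i, s in enumerate(external)}
        for j, r in enumerate(self.reactions):
            for sid, coeff in r.stoichiometry.items():
                if sid in idx_int:
                    N[idx_int[sid], j] = coeff
                else:
                    P[idx_ext[sid], j] = coeff
        return N, P

    def null_space_basis(self, rtol: float = 1e-10) -> "NullSpaceBasis":
        return null_space(self.N, self, rtol=rtol)


@dataclass
class NullSpaceBasis:
    """Orthonormal basis K of null(N) with the irreversible-row selection."""

    K: np.ndarray
    K_irr: np.ndarray
    irreversible_ids: list


def null_space(N: np.ndarray, network: MetabolicNetwork | None = None,
               rtol: float = 1e-10) -> NullSpaceBasis:
    """Orthonormal null-space basis of the internal stoichiometric matrix.

    The basis comes from the SVD (right singular vectors whose singular
    value falls below ``rtol * sigma_max``); each column's sign is fixed
    so its largest-magnitude entry is positive, making the basis
    deterministic.  Downstream fits are invariant to the basis choice.
    """
    N = np.atleast_2d(np.asarray(N, dtype=float))
    if N.shape[1] == 0:
        raise NetworkError("network has no reactions")
    n_rxn = N.shape[1]
    if N.shape[0] == 0 or not np.any(N != 0.0):
        K = np.eye(n_rxn)
    else:
        _, s, Vt = np.linalg.svd(N)
        tol = rtol * (s[0] if s.size else 1.0)
        rank = int(np.sum(s > tol))
        if rank >= n_rxn:
            raise NetworkError("no free fluxes; steady state over-determined")
        K = Vt[rank:].T
        # deterministic sign convention
        for j in range(K.shape[1]):
            i = int(np.argmax(np.abs(K[:, j])))
            if K[i, j] < 0:
                K[:, j] = -K[:, j]
    if network is not None:
        irr = network.irreversible_ids
        K_irr = irreversibility_rows(K, irr, network)
    else:
        irr, K_irr = [], np.zeros((0, K.shape[1]))
    return NullSpaceBasis(K=K, K_irr=K_irr, irreversible_ids=irr)


def irreversibility_rows(K: np.ndarray, irreversible_ids: list,
                         network: MetabolicNetwork) -> np.ndarray:
    """Rows of K corresponding to irreversible reactions, in request order."""
    order = {rid: i for i, rid in enumerate(network.reaction_ids)}
    rows = []
    for rid in irreversible_ids:
        if rid not in order:
            raise NetworkError(f"unknown reaction id {rid!r}")
        rows.append(K[order[rid]])
    if not rows:
        return np.zeros((0, K.shape[1]))
    return np.vstack(rows)


# ---------------------------------------------------------------------
# plain-text network format
# ---------------------------------------------------------------------

_TERM = re.compile(r"^\s*(?:(\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s+)?(\S+)\s*$")


def parse_reaction_equation(rid: str, equation: str):
    """Parse ``a A + b B -> c C`` (or ``<->`` for reversible).

    Either side may be empty (pure uptake/secretion, e.g. ``Xv ->``).
    Returns (stoichiometry dict, reversible flag).
    """
    if "<->" in equation:
        lhs, rhs = equation.split("<->")
        reversible = True
    elif "->" in equation:
        lhs, rhs = equation.split("->")
        reversible = False
    else:
        raise NetworkError(f"reaction {rid!r}: no '->' or '<->' in {equation!r}")
    stoich: dict = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            m = _TERM.match(term)
            if not m:
                raise NetworkError(f"reaction {rid!r}: cannot parse term {term!r}")
            coeff = float(m.group(1)) if m.group(1) else 1.0
            sid = m.group(2)
            stoich[sid] = stoich.get(sid, 0.0) + sign * coeff

    add_side(lhs, -1.0)
    add_side(rhs, +1.0)
    return stoich, reversible


def read_network(path) -> MetabolicNetwork:
    """Read the plain-text network format.

    ::

        [species]
        Glc external
        PYR internal
        [reactions]
        v1: Glc -> 2 PYR
        v2: PYR <-> Lac
    """
    species: list = []
    reactions: list = []
    section = None
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.lower() in ("[species]", "[reactions]"):
                section = line.lower()
                continue
            if section == "[species]":
                parts = line.split()
                if len(parts) < 2:
                    raise NetworkError(f"bad species line: {line!r}")
                species.append(Species(id=parts[0], compartment_role=parts[1],
                                       name=" ".join(parts[2:])))
            elif section == "[reactions]":
                if ":" not in line:
                    raise NetworkError(f"bad reaction line: {line!r}")
                rid, eq = line.split(":", 1)
                stoich, rev = parse_reaction_equation(rid.strip(), eq)
                reactions.append(Reaction(id=rid.strip(), stoichiometry=stoich,
                                          reversible=rev))
            else:
                raise NetworkError(f"line outside any section: {line!r}")
    return MetabolicNetwork(species=species, reactions=reactions)


def write_network(network: MetabolicNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("[species]\n")
        for s in network.species:
            fh.write(f"{s.id} {s.compartment_role}"
                     + (f" {s.name}" if s.name else "") + "\n")
        fh.write("[reactions]\n")
        for r in network.reactions:
            arrow = "<->" if r.reversible else "->"
            lhs = " + ".join(_fmt_term(-c, sid)
                             for sid, c in r.stoichiometry.items() if c < 0)
            rhs = " + ".join(_fmt_term(c, sid)
                             for sid, c in r.stoichiometry.items() if c > 0)
            fh.write(f"{r.id}: {lhs} {arrow} {rhs}".rstrip() + "\n")


def _fmt_term(coeff: float, sid: str) -> str:
    if coeff == 1.0:
        return sid
    return f"{coeff:.12g} {sid}"
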