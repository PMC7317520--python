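"""Elementary flux modes and their macro-reaction matrix.

An elementary mode (EM) is a support-minimal steady-state flux pattern
respecting reaction irreversibility; every admissible steady-state flux
is a non-negative combination of EMs.  Each EM induces a *macro-reaction*
on the external (medium) species, ``P @ v``; these columns, L2-normalized,
form the matrix ``E`` used by the DMFA-for-EM estimator.

Enumeration uses the double-description (tableau) construction on the
pointed cone obtained after splitting reversible reactions into
forward/backward non-negative pairs, followed by support-minimality
filtering and removal of the spurious forward+backward two-cycles.  It is
exact and intended for small networks; large EM sets computed by external
tools are read with :func:`read_em_matrix`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import MetabolicNetwork

__all__ = [
    "ElementaryModeMatrix",
    "enumerate_ems",
    "normalize_columns",
    "cosine_similarity",
    "geometric_reduction",
    "read_em_matrix",
    "write_em_matrix",
]


class EMError(ValueError):
    pass


@dataclass
class ElementaryModeMatrix:
    """External macro-reaction matrix with optional full flux patterns.

    ``E`` is (n_external x n_EM) with unit-norm columns (unless ``raw``);
    ``flux_patterns`` (n_reactions x n_EM) holds the underlying network
    flux vectors when the EMs were enumerated internally.
    """

    E: np.ndarray
    species_ids: list
    em_ids: list
    flux_patterns: np.ndarray | None = None
    raw: bool = False

    def __post_init__(self) -> None:
        self.E = np.atleast_2d(np.asarray(self.E, dtype=float))
        norms = np.linalg.norm(self.E, axis=0)
        if np.any(norms == 0.0):
            k = int(np.argmin(norms))
            raise EMError(f"EM {self.em_ids[k]!r} is the zero vector")
        if not self.raw and np.any(np.abs(norms - 1.0) > 1e-9):
            raise EMError("columns not unit-norm; pass raw=True or normalize")

    @property
    def n_modes(self) -> int:
        return self.E.shape[1]

    def subset(self, mask) -> "ElementaryModeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return ElementaryModeMatrix(
            E=self.E[:, idx],
            species_ids=list(self.species_ids),
            em_ids=[self.em_ids[i] for i in idx],
            flux_patterns=None if self.flux_patterns is None
            else self.flux_patterns[:, idx],
            raw=self.raw,
        )

    def normalized(self) -> "ElementaryModeMatrix":
        return ElementaryModeMatrix(
            E=normalize_columns(self.E),
            species_ids=list(self.species_ids),
            em_ids=list(self.em_ids),
            flux_patterns=self.flux_patterns,
            raw=False,
        )


def normalize_columns(E_raw: np.ndarray) -> np.ndarray:
    """Scale every column to unit Euclidean norm (signs preserved)."""
    E = np.atleast_2d(np.asarray(E_raw, dtype=float))
    norms = np.linalg.norm(E, axis=0)
    if np.any(norms == 0.0):
        raise EMError(f"zero column at index {int(np.argmin(norms))}")
    return E / norms


def cosine_similarity(e_a: np.ndarray, e_b: np.ndarray) -> float:
    a = np.asarray(e_a, dtype=float).ravel()
    b = np.asarray(e_b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise EMError("cosine similarity undefined for zero vector")
    return float(a @ b / (na * nb))


# ---------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------

def _double_description(N: np.ndarray, zero_tol: float = 1e-10) -> np.ndarray:
    """Extreme rays of {v >= 0 : N v = 0} via the iterative tableau.

    Returns rays as columns, each scaled to max-entry 1.  Uses the
    combinatorial adjacency (support-minimality) test, exact for the
    problem sizes targeted here.
    """
    n = N.shape[1]
    rays = [np.eye(n)[:, j] for j in range(n)]
    for row in np.atleast_2d(N):
        if not np.any(row != 0.0):
            continue
        vals = [float(row @ r) for r in rays]
        scale = max(1.0, max(abs(v) for v in vals))
        zeros = [r for r, v in zip(rays, vals) if abs(v) <= zero_tol * scale]
        pos = [(r, v) for r, v in zip(rays, vals) if v > zero_tol * scale]
        neg = [(r, v) for r, v in zip(rays, vals) if v < -zero_tol * scale]
        new = list(zeros)
        for rp, vp in pos:
            for rn, vn in neg:
                cand = vp * rn - vn * rp  # positive combination, row @ cand = 0
                cand = cand / np.max(np.abs(cand))
                cand[np.abs(cand) <= zero_tol] = 0.0
                new.append(cand)
        rays = _minimal_support(new, zero_tol)
    return np.array(rays).T if rays else np.zeros((n, 0))


def _minimal_support(rays: list, zero_tol: float) -> list:
    """Keep rays whose support is not a strict superset of another's."""
    supports = [frozenset(np.flatnonzero(np.abs(r) > zero_tol)) for r in rays]
    keep = []
    seen = set()
    for i, (r, s) in enumerate(zip(rays, supports)):
        if not s or s in seen:
            continue
        minimal = True
        for j, s2 in enumerate(supports):
            if j != i and s2 and s2 < s:
                minimal = False
                break
        if minimal:
            keep.append(r)
            seen.add(s)
    return keep


def enumerate_ems(network: MetabolicNetwork, max_modes: int = 5000,
                  normalize: bool = True) -> ElementaryModeMatrix:
    """Enumerate elementary modes of a small network.

    Reversible reactions are split into forward/backward non-negative
    columns; the two-cycle artifacts of the split are discarded and the
    pair is recombined into one signed flux pattern.  Macro-reactions are
    ``P @ v``, L2-normalized unless ``normalize=False``.
    """
    rev = [r.reversible for r in network.reactions]
    n_rxn = len(network.reactions)
    # split: columns [all reactions forward, then backward copies of reversibles]
    cols = [network.N[:, j] for j in range(n_rxn)]
    back_of = {}
    for j in range(n_rxn):
        if rev[j]:
            back_of[len(cols)] = j
            cols.append(-network.N[:, j])
    N_split = np.column_stack(cols) if cols else np.zeros((0, 0))
    rays = _double_description(N_split)
    # map back to signed flux patterns, dropping two-cycles
    patterns = []
    for k in range(rays.shape[1]):
        v_split = rays[:, k]
        v = v_split[:n_rxn].copy()
        for col, j in back_of.items():
            v[j] -= v_split[col]
        if np.all(np.abs(v) <= 1e-12):   # forward+backward two-cycle
            continue
        patterns.append(v)
    # dedupe collinear patterns (can arise after recombination)
    uniq = []
    for v in patterns:
        vn = v / np.linalg.norm(v)
        # signed test: a mode and its reverse are distinct EMs
        if not any(vn @ (u / np.linalg.norm(u)) > 1.0 - 1e-10 for u in uniq):
            uniq.append(v)
    if len(uniq) > max_modes:
        raise EMError(
            f"{len(uniq)} modes exceeds cap {max_modes}; enumerate externally "
            "and import with read_em_matrix")
    V = np.column_stack(uniq) if uniq else np.zeros((n_rxn, 0))
    E_raw = network.P @ V
    keep = np.linalg.norm(E_raw, axis=0) > 1e-12  # purely internal cycles
    V, E_raw = V[:, keep], E_raw[:, keep]
    em_ids = [f"EM{k + 1}" for k in range(E_raw.shape[1])]
    E = normalize_columns(E_raw) if normalize and E_raw.shape[1] else E_raw
    return ElementaryModeMatrix(E=E, species_ids=network.external_ids,
                                em_ids=em_ids, flux_patterns=V,
                                raw=not normalize)


# ---------------------------------------------------------------------
# geometric reduction
# ---------------------------------------------------------------------

@dataclass
class ReductionTrace:
    thresholds: list = field(default_factory=list)
    sizes: list = field(default_factory=list)
    ssr: list = field(default_factory=list)


def _medoid_groups(E: np.ndarray, threshold: float) -> list:
    """Connected components of the cosine-similarity graph at ``threshold``;
    each component is represented by its medoid (max mean similarity)."""
    n = E.shape[1]
    S = normalize_columns(E).T @ normalize_columns(E)
    adj = S >= threshold
    unvisited = set(range(n))
    reps = []
    while unvisited:
        seed = min(unvisited)
        comp = {seed}
        frontier = {seed}
        while frontier:
            nxt = set()
            for i in frontier:
                nxt |= set(np.flatnonzero(adj[i])) & unvisited - comp
            comp |= nxt
            frontier = nxt
        unvisited -= comp
        comp = sorted(comp)
        mean_sim = S[np.ix_(comp, comp)].mean(axis=1)
        reps.append(comp[int(np.argmax(mean_sim))])
    return sorted(reps)


def geometric_reduction(ems: ElementaryModeMatrix, datasets, grid,
                        tol_fraction: float = 0.01,
                        thresholds=None, solver=None,
                        xv_interp=None):
    """Discard geometrically similar EMs subject to an SSR budget.

    Starting from a high cosine-similarity threshold and lowering it on a
    schedule, similar EMs are grouped (connected components at the
    threshold) and each group is replaced by its medoid.  After each
    step, the DMFA-for-EM problem is re-solved on all ``datasets``; the
    reduction stops before the summed SSR exceeds
    ``(1 + tol_fraction) * SSR(full set)``.

    Returns ``(reduced ElementaryModeMatrix, ReductionTrace)``.
    """
    from .estimators import DMFA

    if tol_fraction < 0:
        raise EMError("tol_fraction must be >= 0")
    if thresholds is None:
        thresholds = [1 - 1e-10, 0.9999, 0.999, 0.995, 0.99, 0.98, 0.95,
                      0.9, 0.8, 0.7]
    if solver is None:
        def solver(em_subset):
            total = 0.0
            for data in datasets:
                est = DMFA(mode="em", grid=grid, alpha=0.0)
                est.fit(data, ems=em_subset, xv_interp=xv_interp)
                total += est.ssr_
            return total

    ems = ems.normalized()
    ssr0 = solver(ems)
    budget = ssr0 + tol_fraction * max(ssr0, np.finfo(float).tiny)
    trace = ReductionTrace(thresholds=[None], sizes=[ems.n_modes], ssr=[ssr0])
    current = ems
    for s in sorted(thresholds, reverse=True):
        reps = _medoid_groups(current.E, s)
        if len(reps) == current.n_modes:
            continue
        candidate = current.subset(np.asarray(reps))
        ssr = solver(candidate)
        if ssr > budget:
            break
        current = candidate
        trace.thresholds.append(s)
        trace.sizes.append(current.n_modes)
        trace.ssr.append(ssr)
    return current, trace


# ---------------------------------------------------------------------
# delimited i/o
# ---------------------------------------------------------------------

def write_em_matrix(ems: ElementaryModeMatrix, path) -> None:
    """TSV with external species as labeled rows and EM ids as columns."""
    df = pd.DataFrame(ems.E, index=ems.species_ids, columns=ems.em_ids)
    df.to_csv(path, sep="\t", float_format="%.15g")


def read_em_matrix(path, species_order, orientation: str = "species_rows",
                   normalize: bool = True) -> ElementaryModeMatrix:
    """Read a delimited EM matrix and align rows to ``species_order``.

    ``orientation`` is ``"species_rows"`` (default) or ``"modes_rows"``.
    Unnormalized input is normalized unless ``normalize=False``.
    """
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if orientation == "modes_rows":
        df = df.T
    elif orientation != "species_rows":
        raise EMError(f"unknown orientation {orientation!r}")
    missing = [s for s in species_order if s not in df.index]
    if missing:
        raise EMError(f"EM matrix missing species {missing}")
    df = df.loc[list(species_order)]
    E = df.to_numpy(dtype=float)
    norms = np.linalg.norm(E, axis=0)
    if np.any(np.abs(norms - 1.0) > 1e-9):
        if normalize:
            E = normalize_columns(E)
        else:
            return ElementaryModeMatrix(E=E, species_ids=list(species_order),
                                        em_ids=list(df.columns), raw=True)
    return ElementaryModeMatrix(E=E, species_ids=list(species_order),
                                em_ids=list(df.columns))
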