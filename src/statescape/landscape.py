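"""Energy-landscape structure over the state hypercube.

States are nodes of the N-dimensional hypercube (neighbours differ by one
ROI flip).  Dynamics are modelled as a ball rolling downhill: from any
state, steepest single-flip descent ends in a local minimum, whose
attraction region is its basin.  Basin depth — the barrier that must be
crossed to reach another minimum — quantifies the stability of the
attractor state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LandscapeSummary", "local_minima", "basin_assignment", "basin_depth"]


def _as_energy_vector(energies) -> tuple[np.ndarray, int]:
    e = np.asarray(getattr(energies, "energies_", energies), dtype=float)
    if e.ndim != 1 or e.size < 2 or e.size & (e.size - 1):
        raise ValueError("energies must be a length 2**N vector, N >= 1")
    n = int(e.size).bit_length() - 1
    return e, n


def _neighbour_matrix(n: int) -> np.ndarray:
    k = np.arange(1 << n)
    return k[:, None] ^ (1 << np.arange(n))  # (2**N, N) single-flip neighbours


def local_minima(energies) -> list[int]:
    """States strictly lower in energy than all N single-flip neighbours."""
    e, n = _as_energy_vector(energies)
    nb = _neighbour_matrix(n)
    is_min = (e[:, None] < e[nb]).all(axis=1)
    return [int(k) for k in np.flatnonzero(is_min)]


@dataclass
class LandscapeSummary:
    """Minima, basin membership and basin depths of one energy table."""

    minima: list[int]
    basin_of: np.ndarray
    depth: dict[int, float] = field(default_factory=dict)
    energies: np.ndarray | None = None

    def basin_sizes(self) -> dict[int, int]:
        return {m: int((self.basin_of == m).sum()) for m in self.minima}


def basin_assignment(energies) -> LandscapeSummary:
    """Steepest single-flip descent from every state to its local minimum.

    Ties in neighbour energy are broken toward the lower state index, so the
    assignment is deterministic.  A state with no strictly lower neighbour is
    its own terminus (a local minimum).
    """
    e, n = _as_energy_vector(energies)
    nb = _neighbour_matrix(n)
    # next-state pointer: lowest-energy neighbour if strictly lower, else self
    order = np.argsort(nb, axis=1)  # ensures ties pick the lower index
    nb_sorted = np.take_along_axis(nb, order, axis=1)
    e_nb = e[nb_sorted]
    best = np.argmin(e_nb, axis=1)  # argmin returns first (= lowest index) tie
    nxt = nb_sorted[np.arange(e.size), best]
    improves = e[nxt] < e
    nxt = np.where(improves, nxt, np.arange(e.size))
    # pointer jumping until fixpoint (path length <= 2**N, doubling is fast)
    while True:
        nxt2 = nxt[nxt]
        if np.array_equal(nxt2, nxt):
            break
        nxt = nxt2
    minima = local_minima(e)
    summary = LandscapeSummary(minima=minima, basin_of=nxt, energies=e)
    summary.depth = basin_depth(e, summary)
    return summary


def basin_depth(energies, summary: LandscapeSummary | None = None) -> dict[int, float]:
    """Barrier height to escape each basin, by threshold percolation.

    For minimum ``m``, the saddle level is the lowest energy ``L`` such that
    the subgraph of states with ``E <= L`` connects ``m`` to another
    minimum; ``depth(m) = L - E(m)``.  Computed by sweeping states in
    ascending energy through a union-find over the hypercube.  A landscape
    with a single minimum is assigned ``depth = max(E) - E(m)``.
    """
    e, n = _as_energy_vector(energies)
    minima = summary.minima if summary is not None else local_minima(e)
    if not minima:
        raise ValueError("landscape has no local minimum")
    if len(minima) == 1:
        m = minima[0]
        return {m: float(e.max() - e[m])}

    size = e.size
    parent = np.arange(size)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    min_set = set(minima)
    has_min = {}  # root -> bool
    unresolved = {}  # root -> list of minima awaiting a saddle
    saddle = {}
    added = np.zeros(size, dtype=bool)
    order = np.lexsort((np.arange(size), e))  # stable, index breaks ties
    nb = _neighbour_matrix(n)
    for k in order:
        k = int(k)
        added[k] = True
        has_min[k] = k in min_set
        unresolved[k] = [k] if k in min_set else []
        for kk in nb[k]:
            kk = int(kk)
            if not added[kk]:
                continue
            ra, rb = find(k), find(kk)
            if ra == rb:
                continue
            if has_min[ra] and has_min[rb]:
                level = e[k]  # current sweep level is the saddle energy
                for m in unresolved[ra] + unresolved[rb]:
                    saddle[m] = level
                merged_unresolved = []
            else:
                merged_unresolved = unresolved[ra] + unresolved[rb]
            parent[ra] = rb
            has_min[rb] = has_min[ra] or has_min[rb]
            unresolved[rb] = merged_unresolved
            has_min.pop(ra, None)
            unresolved.pop(ra, None)
    return {m: float(saddle[m] - e[m]) for m in minima}
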