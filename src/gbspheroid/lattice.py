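"""Discrete compartment: cells on a 2D square lattice.

Each lattice site holds at most one cell. Cells age toward their
phenotype's doubling time; on reaching it they search the surrounding
Moore rings (up to the phenotype's proliferation depth ``r``) for an
empty site, pushing intervening neighbours outward along a Chebyshev
geodesic when the empty site lies beyond the first ring. A cell that
finds no space becomes quiescent: its age freezes and it re-attempts
division every iteration. Cells die only when local oxygen falls below
a configurable threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

Site = Tuple[int, int]

__all__ = [
    "Phenotype",
    "CellGrid",
    "DivisionEvent",
    "moore_ring",
    "ring_offsets",
    "find_empty_site",
    "push_chain",
    "attempt_division",
    "apply_death",
]


@dataclass(frozen=True)
class Phenotype:
    """A clone's proliferative traits.

    Parameters
    ----------
    id : int
        Non-negative integer label, unique within a simulation.
    doubling_time_h : float
        Mean duration of one growth-and-division cycle, in hours.
    proliferation_depth_r : int
        Maximum Moore ring searched for empty space (and across which
        neighbours may be pushed); the model's proxy for mechanical
        contact inhibition.
    """

    id: int
    doubling_time_h: float
    proliferation_depth_r: int = 2

    def __post_init__(self) -> None:
        if self.id < 0:
            raise ValueError(f"phenotype id must be >= 0, got {self.id}")
        if not np.isfinite(self.doubling_time_h) or self.doubling_time_h <= 0:
            raise ValueError(
                f"doubling_time_h must be finite and > 0, got {self.doubling_time_h}"
            )
        if self.proliferation_depth_r < 1:
            raise ValueError(
                f"proliferation_depth_r must be >= 1, got {self.proliferation_depth_r}"
            )


@lru_cache(maxsize=64)
def ring_offsets(k: int) -> np.ndarray:
    """(dr, dc) offsets of the k-Moore ring in row-major order, shape (8k, 2)."""
    if k < 1:
        raise ValueError(f"ring index k must be >= 1, got {k}")
    offs = [
        (dr, dc)
        for dr in range(-k, k + 1)
        for dc in range(-k, k + 1)
        if max(abs(dr), abs(dc)) == k
    ]
    a = np.array(offs, dtype=np.int64)
    a.setflags(write=False)
    return a


def moore_ring(site: Site, k: int, n: int) -> List[Site]:
    """In-bounds sites at Chebyshev distance exactly ``k`` from ``site``.

    The ring (not the filled neighbourhood), in deterministic row-major
    order so random tie-breaking is seed-reproducible.
    """
    r, c = site
    if not (0 <= r < n and 0 <= c < n):
        raise ValueError(f"site {site} outside {n}x{n} grid")
    offs = ring_offsets(k)
    rows = r + offs[:, 0]
    cols = c + offs[:, 1]
    ok = (rows >= 0) & (rows < n) & (cols >= 0) & (cols < n)
    return list(zip(rows[ok].tolist(), cols[ok].tolist()))


class CellGrid:
    """Lattice occupancy plus per-cell state arrays.

    ``occ[i, j]`` is the index of the cell at site (i, j) or -1 if the
    site is empty. Per-cell state lives in flat arrays indexed by cell
    id; slots of dead cells are never reused (``alive`` masks them out).
    """

    def __init__(
        self,
        n: int,
        cell_size_um: float,
        phenotypes: Sequence[Phenotype],
        capacity: int = 1024,
    ) -> None:
        if n < 1:
            raise ValueError(f"grid side must be >= 1, got {n}")
        if cell_size_um <= 0:
            raise ValueError(f"cell size must be > 0, got {cell_size_um}")
        if not phenotypes:
            raise ValueError("at least one phenotype is required")
        self.n = int(n)
        self.cell_size_um = float(cell_size_um)
        self.phenotypes: dict[int, Phenotype] = {}
        for p in phenotypes:
            if p.id in self.phenotypes:
                raise ValueError(f"duplicate phenotype id {p.id}")
            self.phenotypes[p.id] = p
        max_id = max(self.phenotypes)
        self.dt_by_id = np.full(max_id + 1, np.nan)
        self.r_by_id = np.zeros(max_id + 1, dtype=np.int64)
        for p in self.phenotypes.values():
            self.dt_by_id[p.id] = p.doubling_time_h
            self.r_by_id[p.id] = p.proliferation_depth_r
        self.max_depth = int(self.r_by_id.max())

        self.occ = np.full((self.n, self.n), -1, dtype=np.int64)
        cap = max(capacity, 16)
        self.row = np.zeros(cap, dtype=np.int64)
        self.col = np.zeros(cap, dtype=np.int64)
        self.age_h = np.zeros(cap)
        self.phen = np.zeros(cap, dtype=np.int64)
        self.alive = np.zeros(cap, dtype=bool)
        self.size = 0        # used slots
        self.n_cells = 0     # live cells

    # -- storage ---------------------------------------------------------

    def _ensure_capacity(self, extra: int = 1) -> None:
        if self.size + extra <= self.row.shape[0]:
            return
        new_cap = max(2 * self.row.shape[0], self.size + extra)
        for name in ("row", "col", "age_h", "phen", "alive"):
            arr = getattr(self, name)
            grown = np.zeros(new_cap, dtype=arr.dtype)
            grown[: self.size] = arr[: self.size]
            setattr(self, name, grown)

    def add_cell(self, site: Site, phenotype_id: int, age_h: float = 0.0) -> int:
        r, c = site
        if self.occ[r, c] != -1:
            raise ValueError(f"site {site} already occupied")
        if phenotype_id not in self.phenotypes:
            raise ValueError(f"unknown phenotype id {phenotype_id}")
        if age_h < 0:
            raise ValueError(f"age must be >= 0, got {age_h}")
        self._ensure_capacity()
        idx = self.size
        self.row[idx] = r
        self.col[idx] = c
        self.age_h[idx] = age_h
        self.phen[idx] = phenotype_id
        self.alive[idx] = True
        self.occ[r, c] = idx
        self.size += 1
        self.n_cells += 1
        return idx

    def remove_cell(self, idx: int) -> None:
        if not self.alive[idx]:
            raise ValueError(f"cell {idx} is not alive")
        self.occ[self.row[idx], self.col[idx]] = -1
        self.alive[idx] = False
        self.n_cells -= 1

    def move_cell(self, idx: int, new_site: Site) -> None:
        r, c = new_site
        if self.occ[r, c] != -1:
            raise ValueError(f"cannot move cell {idx}: site {new_site} occupied")
        self.occ[self.row[idx], self.col[idx]] = -1
        self.row[idx], self.col[idx] = r, c
        self.occ[r, c] = idx

    # -- queries ---------------------------------------------------------

    def live_indices(self) -> np.ndarray:
        return np.nonzero(self.alive[: self.size])[0]

    def site_of(self, idx: int) -> Site:
        return int(self.row[idx]), int(self.col[idx])

    def occupied_mask(self) -> np.ndarray:
        return self.occ >= 0

    def cell_states(self) -> Iterable[tuple[Site, int, float]]:
        """Yield (site, phenotype_id, age_h) for each live cell."""
        for i in self.live_indices():
            yield self.site_of(i), int(self.phen[i]), float(self.age_h[i])


@dataclass(frozen=True)
class DivisionEvent:
    """Outcome of one division attempt."""

    divided: bool
    daughter_site: Optional[Site] = None
    searched_depth: int = 0


def find_empty_site(
    site: Site, grid: CellGrid, r: int, rng: np.random.Generator
) -> Optional[Site]:
    """First-ring-priority random empty site within depth ``r`` of ``site``.

    Rings k = 1..r are scanned outward; a uniformly random empty site is
    returned from the first ring that has one, or ``None`` when every
    ring is fully occupied (the quiescence outcome). Off-grid sites never
    count as empty.
    """
    sr, sc = site
    n = grid.n
    occ = grid.occ
    for k in range(1, r + 1):
        offs = ring_offsets(k)
        rows = sr + offs[:, 0]
        cols = sc + offs[:, 1]
        ok = (rows >= 0) & (rows < n) & (cols >= 0) & (cols < n)
        rows = rows[ok]
        cols = cols[ok]
        empty = np.nonzero(occ[rows, cols] == -1)[0]
        if empty.size:
            j = empty[rng.integers(empty.size)] if empty.size > 1 else empty[0]
            return int(rows[j]), int(cols[j])
    return None


def push_chain(origin: Site, target: Site) -> List[Site]:
    """Chebyshev-geodesic chain of sites from next-to-``origin`` to ``target``.

    Stepping by (sign(drow), sign(dcol)) from ``origin`` reduces the
    Chebyshev distance to ``target`` by exactly 1 per step. Shifting each
    chain occupant one position toward the target (processed from the
    target backwards) vacates the first chain site, which is 1-Moore
    adjacent to the origin.
    """
    dist = max(abs(target[0] - origin[0]), abs(target[1] - origin[1]))
    if dist < 2:
        raise ValueError(
            f"push chain requires Chebyshev distance >= 2, got {dist} "
            f"(origin {origin}, target {target})"
        )
    chain: List[Site] = []
    r, c = origin
    while (r, c) != target:
        r += int(np.sign(target[0] - r))
        c += int(np.sign(target[1] - c))
        chain.append((r, c))
    return chain


def attempt_division(
    cell_idx: int,
    grid: CellGrid,
    rng: np.random.Generator,
    age_policy: str = "carry",
) -> DivisionEvent:
    """Let an age-ripe cell attempt to divide; quiescence if no space.

    If the nearest empty site lies in ring k >= 2, the k-1 occupants on
    the geodesic chain are each shifted one site toward it, vacating a
    1-Moore site where the daughter (same phenotype, age 0) is placed.
    The parent's age is reduced by one doubling time (``carry``) or
    zeroed (``zero``). Total cell count rises by exactly one; all other
    cells keep their phenotype and age.
    """
    if age_policy not in ("carry", "zero"):
        raise ValueError(f"age_policy must be 'carry' or 'zero', got {age_policy!r}")
    pid = int(grid.phen[cell_idx])
    dt = grid.dt_by_id[pid]
    if grid.age_h[cell_idx] < dt:
        raise ValueError(
            f"cell {cell_idx} is not ripe: age {grid.age_h[cell_idx]} < {dt}"
        )
    site = grid.site_of(cell_idx)
    depth = int(grid.r_by_id[pid])
    target = find_empty_site(site, grid, depth, rng)
    if target is None:
        return DivisionEvent(divided=False, searched_depth=depth)

    dist = max(abs(target[0] - site[0]), abs(target[1] - site[1]))
    if dist >= 2:
        chain = push_chain(site, target)
        # Rings 1..k-1 were full, so every chain site before the target is
        # occupied; shift occupants outward starting at the target end.
        for j in range(len(chain) - 2, -1, -1):
            occupant = grid.occ[chain[j][0], chain[j][1]]
            grid.move_cell(int(occupant), chain[j + 1])
        daughter_site = chain[0]
    else:
        daughter_site = target

    if age_policy == "carry":
        grid.age_h[cell_idx] -= dt
    else:
        grid.age_h[cell_idx] = 0.0
    grid.add_cell(daughter_site, pid, age_h=0.0)
    return DivisionEvent(divided=True, daughter_site=daughter_site, searched_depth=dist)


def apply_death(
    grid: CellGrid, oxygen: np.ndarray, o_deadly: float
) -> List[Site]:
    """Remove every cell whose local oxygen is strictly below ``o_deadly``.

    Vacated sites become empty space immediately (within the same
    iteration). Returns the removed sites.
    """
    if oxygen.shape != (grid.n, grid.n):
        raise ValueError(
            f"oxygen field shape {oxygen.shape} != grid shape {(grid.n, grid.n)}"
        )
    if o_deadly <= 0:
        return []
    live = grid.live_indices()
    local = oxygen[grid.row[live], grid.col[live]]
    doomed = live[local < o_deadly]
    removed: List[Site] = []
    for idx in doomed:
        removed.append(grid.site_of(int(idx)))
        grid.remove_cell(int(idx))
    return removed
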