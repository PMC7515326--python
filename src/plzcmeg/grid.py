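"""Homogeneous 3-D source grids with contiguous atlas-style region partitions.

The analysis operates on a rectangular lattice of cortical source positions
(the scaled-down analogue of a 1-cm beamformer grid).  Two sources are
*neighbors* iff their Euclidean distance is at most ``ADJACENCY_FACTOR``
times the grid spacing, which on a homogeneous lattice is 6-connectivity.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

#: Neighborhood rule: distance <= factor * spacing (6-connectivity on a lattice).
ADJACENCY_FACTOR = 1.1


@dataclass(frozen=True)
class SourceGrid:
    """A homogeneous grid of source positions labeled by atlas region.

    Parameters
    ----------
    positions : (n_sources, 3) float array, positions in mm.
    spacing : grid spacing in mm (nearest-neighbor distance).
    region_id : (n_sources,) int array, region index of each source.
    region_names : names of the regions, indexed by region id.
    """

    positions: np.ndarray
    spacing: float
    region_id: np.ndarray
    region_names: tuple[str, ...]

    @property
    def n_sources(self) -> int:
        return self.positions.shape[0]

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    def adjacency(self) -> list[np.ndarray]:
        """Neighbor lists under the distance rule (cached per instance)."""
        cached = getattr(self, "_adjacency_cache", None)
        if cached is None:
            cached = adjacency_lists(self.positions, self.spacing)
            object.__setattr__(self, "_adjacency_cache", cached)
        return cached


def adjacency_lists(positions: np.ndarray, spacing: float) -> list[np.ndarray]:
    """Neighbor index lists: distance <= ADJACENCY_FACTOR * spacing, excluding self."""
    pos = np.asarray(positions, dtype=float)
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    thresh = (ADJACENCY_FACTOR * spacing) ** 2
    adj = (d2 <= thresh) & ~np.eye(len(pos), dtype=bool)
    return [np.flatnonzero(row) for row in adj]


def make_grid(
    n_per_axis: tuple[int, int, int],
    spacing: float,
    n_regions: int,
    seed: int,
) -> SourceGrid:
    """Build a homogeneous rectangular grid partitioned into contiguous regions.

    Regions are grown by seeded multi-source breadth-first search, so every
    region is a connected set under the adjacency rule.

    Raises
    ------
    ValueError
        For non-positive spacing or axis counts, or more regions than sources.
    """
    n_per_axis = tuple(int(n) for n in n_per_axis)
    if len(n_per_axis) != 3 or any(n < 1 for n in n_per_axis):
        raise ValueError(f"each axis count must be >= 1, got {n_per_axis}")
    if spacing <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    n_total = int(np.prod(n_per_axis))
    if not (1 <= n_regions <= n_total):
        raise ValueError(f"n_regions must be in [1, {n_total}], got {n_regions}")

    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in n_per_axis), indexing="ij")
    positions = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
    positions *= spacing

    rng = np.random.default_rng(seed)
    adj = adjacency_lists(positions, spacing)
    region_id = _grow_regions(adj, n_regions, rng)
    names = tuple(f"region_{r:02d}" for r in range(n_regions))
    return SourceGrid(positions=positions, spacing=float(spacing),
                      region_id=region_id, region_names=names)


def _grow_regions(adj: list[np.ndarray], n_regions: int, rng: np.random.Generator) -> np.ndarray:
    """Partition the graph into connected regions by multi-seed BFS growth."""
    n = len(adj)
    region_id = np.full(n, -1, dtype=np.int64)
    seeds = rng.choice(n, size=n_regions, replace=False)
    queue: deque[int] = deque()
    for r, s in enumerate(seeds):
        region_id[s] = r
        queue.append(int(s))
    while queue:
        node = queue.popleft()
        r = region_id[node]
        for nb in adj[node]:
            if region_id[nb] < 0:
                region_id[nb] = r
                queue.append(int(nb))
    # A lattice graph is connected, so BFS from the seeds reaches every node.
    assert (region_id >= 0).all()
    return region_id


def contiguous_patch(grid: SourceGrid, size: int, start: int | None = None) -> np.ndarray:
    """Return ``size`` source indices forming a connected patch grown from ``start``.

    By default the patch grows from the source with the largest coordinate sum
    (a "posterior corner" of the grid).
    """
    if not (1 <= size <= grid.n_sources):
        raise ValueError(f"patch size must be in [1, {grid.n_sources}], got {size}")
    if start is None:
        start = int(np.argmax(grid.positions.sum(axis=1)))
    adj = grid.adjacency()
    seen = {start}
    order = [start]
    queue = deque([start])
    while queue and len(order) < size:
        node = queue.popleft()
        for nb in sorted(int(x) for x in adj[node]):
            if nb not in seen:
                seen.add(nb)
                order.append(nb)
                queue.append(nb)
                if len(order) == size:
                    break
    return np.array(sorted(order[:size]), dtype=np.int64)


def is_contiguous(sources: np.ndarray, grid: SourceGrid) -> bool:
    """True iff the given source set is connected under the grid adjacency."""
    sources = np.asarray(sources, dtype=np.int64)
    if sources.size == 0:
        return False
    member = set(int(s) for s in sources)
    adj = grid.adjacency()
    seen = {int(sources[0])}
    queue = deque(seen)
    while queue:
        node = queue.popleft()
        for nb in adj[node]:
            nb = int(nb)
            if nb in member and nb not in seen:
                seen.add(nb)
                queue.append(nb)
    return len(seen) == len(member)
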