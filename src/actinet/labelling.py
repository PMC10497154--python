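"""Filament labelling: partition a 1-px skeleton into individual filaments.

Branch points (skeleton pixels with three or more 8-connected skeleton
neighbours) are temporarily removed, the remaining fragments are
flood-fill labelled, and at every junction the two incident fragments
whose local directions are closest to a straight continuation are merged
back into a single filament.  Remaining incident fragments keep their own
labels — they are the branches.  Each labelled filament finally gets an
ordered endpoint-to-endpoint pixel path (passing through the junction
pixels it was merged across).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .extraction import CONNECTIVITY, Skeleton

logger = logging.getLogger(__name__)

__all__ = ["BranchPoint", "LabelledNetwork", "find_branch_points", "label_filaments", "trace_path"]

_NEIGHBOUR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])

# window (in path steps) over which a fragment's direction at a junction is
# estimated; matches the curvature sampling scale of ~5 px.
DIRECTION_WINDOW = 5


@dataclass
class BranchPoint:
    """A junction of the skeleton.

    ``pixels`` is the full cluster of mutually adjacent >=3-neighbour
    pixels; ``coord`` the representative pixel (nearest the cluster
    centroid).  ``filaments`` holds the ids of incident filaments after
    labelling, ``main`` the id of the merged through-filament (if any).
    """

    coord: tuple[int, int]
    pixels: list[tuple[int, int]] = field(default_factory=list)
    filaments: set[int] = field(default_factory=set)
    main: Optional[int] = None


@dataclass
class LabelledNetwork:
    """Integer-labelled filaments plus branch points and traced paths.

    ``labels`` is 0 background, k >= 1 the k-th filament; branch-point
    pixels carry label 0 but are recorded in ``branch_points``.  ``paths``
    maps filament id -> ordered (row, col) array from one endpoint to the
    other, including any junction pixels traversed.
    """

    labels: np.ndarray
    branch_points: list[BranchPoint]
    paths: dict[int, np.ndarray]
    skeleton: Optional[Skeleton] = None

    @property
    def n_filaments(self) -> int:
        return len(self.paths)

    @property
    def n_branch_points(self) -> int:
        return len(self.branch_points)


def _neighbour_counts(grid: np.ndarray) -> np.ndarray:
    return ndi.convolve(grid.astype(np.uint8), _NEIGHBOUR_KERNEL, mode="constant")


def find_branch_points(skeleton: Skeleton | np.ndarray) -> list[BranchPoint]:
    """Locate junctions: skeleton pixels with >= 3 skeleton neighbours.

    Thinning often emits small clusters of adjacent junction pixels at a
    single crossing; mutually adjacent qualifying pixels are merged into
    one :class:`BranchPoint` whose representative is the member nearest
    the cluster centroid.
    """
    grid = skeleton.grid if isinstance(skeleton, Skeleton) else np.asarray(skeleton, bool)
    counts = _neighbour_counts(grid)
    candidates = grid & (counts >= 3)
    if not candidates.any():
        return []
    clusters, n = ndi.label(candidates, structure=np.ones((3, 3)))
    points = []
    for idx in range(1, n + 1):
        rows, cols = np.nonzero(clusters == idx)
        pixels = list(zip(rows.tolist(), cols.tolist()))
        centroid = (rows.mean(), cols.mean())
        d2 = (rows - centroid[0]) ** 2 + (cols - centroid[1]) ** 2
        rep = pixels[int(np.argmin(d2))]
        points.append(BranchPoint(coord=rep, pixels=pixels))
    return points


def _path_endpoints(grid: np.ndarray) -> list[tuple[int, int]]:
    counts = _neighbour_counts(grid)
    rows, cols = np.nonzero(grid & (counts <= 1))
    return list(zip(rows.tolist(), cols.tolist()))


def trace_path(label_grid: np.ndarray, filament_id: int) -> np.ndarray:
    """Order a filament's pixels from one endpoint to the other.

    The filament must be a simple 8-connected curve.  A cyclic filament
    (no endpoints) is broken at an arbitrary pixel with a warning.
    Returns an (n, 2) array of (row, col) coordinates.
    """
    grid = np.asarray(label_grid) == filament_id
    n_px = int(grid.sum())
    if n_px == 0:
        raise ValueError(f"filament {filament_id} not found")
    endpoints = _path_endpoints(grid)
    if len(endpoints) == 0:
        warnings.warn(
            f"filament {filament_id} is cyclic; breaking at an arbitrary pixel",
            stacklevel=2,
        )
        rows, cols = np.nonzero(grid)
        start = (int(rows[0]), int(cols[0]))
    else:
        start = endpoints[0]
    return _walk(grid, start, n_px, filament_id)


def _walk(grid: np.ndarray, start: tuple[int, int], n_px: int, fid) -> np.ndarray:
    h, w = grid.shape
    visited = np.zeros_like(grid, dtype=bool)
    path = [start]
    visited[start] = True
    cur = start
    for _ in range(n_px - 1):
        r, c = cur
        nxt = None
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and grid[rr, cc] and not visited[rr, cc]:
                    if nxt is None or (dr * dr + dc * dc) < nxt[2]:
                        # prefer 4-connected steps so diagonal shortcuts do
                        # not skip corner pixels
                        nxt = (rr, cc, dr * dr + dc * dc)
        if nxt is None:
            break
        cur = (nxt[0], nxt[1])
        visited[cur] = True
        path.append(cur)
    if len(path) != n_px:
        raise ValueError(
            f"filament {fid} is not a simple path ({len(path)} of {n_px} pixels traced)"
        )
    return np.asarray(path, dtype=int)


def _fragment_direction(path: np.ndarray, from_end: str) -> np.ndarray:
    """Unit direction pointing *away from* the given end of the path."""
    if from_end == "start":
        a = path[0].astype(float)
        b = path[min(DIRECTION_WINDOW, len(path) - 1)].astype(float)
    else:
        a = path[-1].astype(float)
        b = path[max(0, len(path) - 1 - DIRECTION_WINDOW)].astype(float)
    v = b - a
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.zeros(2)


def _adjacent(p: tuple[int, int], q: tuple[int, int]) -> bool:
    return max(abs(p[0] - q[0]), abs(p[1] - q[1])) == 1


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        self.parent[self.find(a)] = self.find(b)


def label_filaments(skeleton: Skeleton | np.ndarray) -> LabelledNetwork:
    """Label individual filaments of a 1-px skeleton.

    Junction pixels are removed, fragments are connected-component
    labelled, and at each junction incident fragments are greedily paired
    by straightness (incoming directions nearest to pi apart), so a plain
    crossing reconnects into two through-filaments.  Ties go to the pair
    with the larger combined length.  Leftover unpaired fragments are the
    branches; the straightest pair is the junction's main filament.
    """
    skel = skeleton if isinstance(skeleton, Skeleton) else Skeleton(np.asarray(skeleton, bool))
    grid = skel.grid
    branch_points = find_branch_points(grid)
    bp_mask = np.zeros_like(grid)
    for bp in branch_points:
        for px in bp.pixels:
            bp_mask[px] = True

    fragments = grid & ~bp_mask
    frag_labels = measure.label(fragments, connectivity=CONNECTIVITY)
    n_frag = int(frag_labels.max())

    # Trace every fragment once, up front.
    frag_paths: dict[int, np.ndarray] = {}
    for fid in range(1, n_frag + 1):
        frag_paths[fid] = trace_path(frag_labels, fid)

    uf = _UnionFind(n_frag + 1)
    # merges[(fid, end)] = (junction index, partner fid, partner end)
    joins: list[tuple[int, int, str, int, str]] = []

    for j, bp in enumerate(branch_points):
        # incident fragments: those whose path end is adjacent to a cluster px
        incident: list[tuple[int, str, np.ndarray]] = []
        for fid, path in frag_paths.items():
            for end, coord in (("start", tuple(path[0])), ("end", tuple(path[-1]))):
                if any(_adjacent(coord, px) for px in bp.pixels):
                    d = _fragment_direction(path, end)
                    incident.append((fid, end, d))
                    break  # one incidence per fragment per junction
        bp.filaments = {fid for fid, _, _ in incident}
        if len(incident) < 2:
            warnings.warn(
                f"junction at {bp.coord} has {len(incident)} incident fragments; no merge",
                stacklevel=2,
            )
            continue
        # Greedy pairing by straightness: repeatedly merge the pair whose
        # outgoing directions are most nearly opposite, until fewer than
        # two unpaired arms remain.  The first (straightest) pair is the
        # junction's main filament; unpaired leftovers are branches.
        unpaired = list(range(len(incident)))
        first = True
        while len(unpaired) >= 2:
            best = None
            for a in range(len(unpaired)):
                for b in range(a + 1, len(unpaired)):
                    fi, ei, di = incident[unpaired[a]]
                    fk, ek, dk = incident[unpaired[b]]
                    if fi == fk:
                        continue  # both ends of the same fragment
                    cosang = float(np.clip(np.dot(di, dk), -1.0, 1.0))
                    straightness = np.arccos(cosang)  # pi = perfectly straight
                    length = len(frag_paths[fi]) + len(frag_paths[fk])
                    key = (straightness, length)
                    if best is None or key > best[0]:
                        best = (key, (fi, ei, fk, ek), (unpaired[a], unpaired[b]))
            if best is None:
                break
            fi, ei, fk, ek = best[1]
            uf.union(fi, fk)
            joins.append((j, fi, ei, fk, ek))
            if first:
                bp.main = fi  # refined to the final label below
                first = False
            unpaired = [u for u in unpaired if u not in best[2]]

    # Assemble merged paths: fragments joined pairwise across junctions.
    # Each (fragment, end) participates in at most one join; duplicate
    # joins on the same end are dropped (degenerate thinning geometry).
    used_ends: set[tuple[int, str]] = set()
    links: dict[tuple[int, str], tuple[int, str, tuple[int, int]]] = {}
    for j, fi, ei, fk, ek in joins:
        if (fi, ei) in used_ends or (fk, ek) in used_ends:
            warnings.warn("conflicting merges at one fragment end; keeping first", stacklevel=2)
            continue
        used_ends.add((fi, ei))
        used_ends.add((fk, ek))
        rep = branch_points[j].coord
        links[(fi, ei)] = (fk, ek, rep)
        links[(fk, ek)] = (fi, ei, rep)

    merged_paths = _assemble_chains(frag_paths, links)

    # Relabel to consecutive ids, longest filament first (stable output).
    order = sorted(merged_paths, key=lambda p: (-len(merged_paths[p]), p))
    labels = np.zeros(grid.shape, dtype=np.int32)
    paths: dict[int, np.ndarray] = {}
    frag_to_final: dict[int, int] = {}
    for new_id, key in enumerate(order, start=1):
        path, members = merged_paths[key]
        paths[new_id] = path
        for fid in members:
            frag_to_final[fid] = new_id
        for r, c in path:
            if not bp_mask[r, c]:
                labels[r, c] = new_id

    for bp in branch_points:
        bp.filaments = {frag_to_final[f] for f in bp.filaments if f in frag_to_final}
        bp.main = frag_to_final.get(bp.main) if bp.main is not None else None

    net = LabelledNetwork(
        labels=labels, branch_points=branch_points, paths=paths, skeleton=skel
    )
    logger.debug(
        "labelled %d filaments, %d branch points", net.n_filaments, net.n_branch_points
    )
    return net


def _assemble_chains(
    frag_paths: dict[int, np.ndarray],
    links: dict[tuple[int, str], tuple[int, str, tuple[int, int]]],
) -> dict[int, tuple[np.ndarray, list[int]]]:
    """Chain fragments joined at junctions into full filament paths.

    Returns {chain key: (ordered path, member fragment ids)}.  Chains are
    walked from a free end; a fully cyclic chain is broken at an arbitrary
    fragment with a warning.
    """
    out: dict[int, tuple[np.ndarray, list[int]]] = {}
    seen: set[int] = set()

    def oriented(fid: int, first_end: str) -> np.ndarray:
        p = frag_paths[fid]
        return p if first_end == "start" else p[::-1]

    for fid in frag_paths:
        if fid in seen:
            continue
        # find a free end to start from
        start_fid, start_end = fid, "start"
        guard = 0
        while (start_fid, start_end) in links and guard <= len(frag_paths):
            nfid, nend, _ = links[(start_fid, start_end)]
            if nfid == fid and guard > 0:
                warnings.warn("cyclic filament chain; breaking arbitrarily", stacklevel=2)
                break
            start_fid, start_end = nfid, "start" if nend == "end" else "end"
            guard += 1

        members = [start_fid]
        seen.add(start_fid)
        # walk from start_end's opposite side through the chain
        path = oriented(start_fid, start_end)
        tail_end = "end" if start_end == "start" else "start"
        cur = (start_fid, tail_end)
        while cur in links:
            nfid, nend, rep = links[cur]
            if nfid in seen:
                break
            seg = oriented(nfid, nend)
            path = np.vstack([path, np.asarray([rep], dtype=int), seg])
            members.append(nfid)
            seen.add(nfid)
            cur = (nfid, "end" if nend == "start" else "start")
        out[start_fid] = (path, members)
    return out
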