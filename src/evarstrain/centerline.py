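"""Lumen skeletonization, branch pruning, bifurcation merging, resampling.

The skeleton of the segmented lumen is decomposed into a branch graph
(endpoint/junction delimited chains).  After EVAR the lumen has three main
branches — the aortic trunk and the two endograft limbs — so the three
longest branches are kept, the limbs are merged into a combined mid-path
below the bifurcation, and the resulting single centerline is resampled
equidistantly (1 mm by default) to drive the straightened CPR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
from skimage.morphology import skeletonize as _sk_skeletonize
from scipy import ndimage

from .core import BinaryMask

logger = logging.getLogger(__name__)

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class Centerline:
    """Ordered 3D point path (mm), proximal to distal."""

    points: np.ndarray
    branch_labels: np.ndarray | None = None
    sampling_distance: float | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise ValueError("centerline needs >= 2 points of dimension 3")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg < 1e-12):
            raise ValueError("centerline has duplicate consecutive points")
        if self.branch_labels is None:
            self.branch_labels = np.zeros(len(self.points), dtype=int)
        else:
            self.branch_labels = np.asarray(self.branch_labels, dtype=int)
            if len(self.branch_labels) != len(self.points):
                raise ValueError("branch_labels length mismatch")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


def skeletonize(lumen: BinaryMask) -> BinaryMask:
    """Topology-preserving thinning of the lumen to a 1-voxel-wide curve set."""
    vox = lumen.as_bool()
    if not vox.any():
        raise ValueError("cannot skeletonize an empty mask")
    if vox.sum() == 1:
        return BinaryMask(vox.astype(np.uint8), lumen.spacing, lumen.origin)
    sk = _sk_skeletonize(vox)
    # guard against pathological total erasure of a tiny component
    if not sk.any():
        sk = vox.copy()
    return BinaryMask(sk.astype(np.uint8), lumen.spacing, lumen.origin)


# ---------------------------------------------------------------------------
# Branch graph
# ---------------------------------------------------------------------------

_OFFSETS = np.array([(dx, dy, dz)
                     for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
                     if (dx, dy, dz) != (0, 0, 0)])


def _path_length_mm(path: np.ndarray, spacing: np.ndarray) -> float:
    if len(path) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(path * spacing, axis=0), axis=1).sum())


def _skeleton_chains(sk: np.ndarray):
    """Decompose a skeleton into chains between endpoints/junctions.

    Returns (chains, node_degree) where each chain is an ordered index array
    including both terminal voxels.
    """
    voxels = set(map(tuple, np.argwhere(sk)))
    nbrs = {}
    for v in voxels:
        ns = []
        for off in _OFFSETS:
            w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if w in voxels:
                ns.append(w)
        nbrs[v] = ns
    deg = {v: len(n) for v, n in nbrs.items()}
    nodes = {v for v, d in deg.items() if d != 2}
    chains = []
    seen_edges = set()
    for start in nodes:
        for nxt in nbrs[start]:
            edge = frozenset((start, nxt))
            if edge in seen_edges:
                continue
            chain = [start, nxt]
            seen_edges.add(edge)
            prev, cur = start, nxt
            while cur not in nodes:
                options = [w for w in nbrs[cur] if w != prev]
                if not options:
                    break
                nxt2 = options[0]
                seen_edges.add(frozenset((cur, nxt2)))
                chain.append(nxt2)
                prev, cur = cur, nxt2
            chains.append(np.asarray(chain))
    # pure cycles (all degree-2): pick an arbitrary start
    visited = {tuple(v) for ch in chains for v in ch}
    for v in voxels - visited:
        if deg[v] == 2:
            chain = [v]
            prev, cur = None, v
            while True:
                options = [w for w in nbrs[cur] if w != prev]
                if not options:
                    break
                nxt2 = options[0]
                if nxt2 == v:
                    chain.append(nxt2)
                    break
                chain.append(nxt2)
                prev, cur = cur, nxt2
                if tuple(cur) == v:
                    break
            chains.append(np.asarray(chain))
            visited.update(map(tuple, chain))
        elif deg[v] == 0:
            chains.append(np.asarray([v]))
            visited.add(v)
    return chains, deg


def _build_graph(chains, spacing: np.ndarray) -> nx.MultiGraph:
    g = nx.MultiGraph()
    for ch in chains:
        a, b = tuple(ch[0]), tuple(ch[-1])
        g.add_edge(a, b, path=ch, length=_path_length_mm(ch.astype(float), spacing))
    return g


def _remove_spurs(g: nx.MultiGraph, spur_mm: float) -> None:
    changed = True
    while changed:
        changed = False
        for a, b, key, data in list(g.edges(keys=True, data=True)):
            if g.degree(a) == 1 or g.degree(b) == 1:
                # a terminal chain; remove if short and not the only edge
                if data["length"] < spur_mm and g.number_of_edges() > 1:
                    g.remove_edge(a, b, key=key)
                    changed = True
        for n in [n for n in g.nodes if g.degree(n) == 0]:
            g.remove_node(n)


def _merge_degree2(g: nx.MultiGraph) -> None:
    changed = True
    while changed:
        changed = False
        for n in list(g.nodes):
            if g.degree(n) == 2 and n in g.nodes:
                edges = list(g.edges(n, keys=True, data=True))
                if len(edges) != 2:
                    continue  # self-loop counted twice
                (a1, b1, k1, d1), (a2, b2, k2, d2) = edges
                o1 = b1 if a1 == n else a1
                o2 = b2 if a2 == n else a2
                if o1 == n or o2 == n:
                    continue
                p1 = d1["path"] if tuple(d1["path"][-1]) == n else d1["path"][::-1]
                p2 = d2["path"] if tuple(d2["path"][0]) == n else d2["path"][::-1]
                newpath = np.concatenate([p1, p2[1:]])
                g.remove_edge(a1, b1, key=k1)
                g.remove_edge(a2, b2, key=k2)
                g.remove_node(n)
                g.add_edge(o1, o2, path=newpath,
                           length=d1["length"] + d2["length"])
                changed = True
                break


def _break_loops(g: nx.MultiGraph) -> None:
    """Reduce the graph to its maximum spanning forest by chain length.

    Deterministic Kruskal pass: edges are kept longest-first as long as they
    do not close a cycle, so every loop loses its shortest chain (self-loops
    always dropped).  Linear-ish in the number of chains, which matters for
    noisy skeletons with many small loops.
    """
    for a, b, key in list(nx.selfloop_edges(g, keys=True)):
        g.remove_edge(a, b, key=key)
    edges = sorted(g.edges(keys=True, data=True),
                   key=lambda e: (-e[3]["length"], e[0], e[1], e[2]))
    parent: dict = {}

    def find(x):
        root = x
        while parent.get(root, root) != root:
            root = parent[root]
        while parent.get(x, x) != x:
            parent[x], x = root, parent[x]
        return root

    for a, b, key, _ in edges:
        ra, rb = find(a), find(b)
        if ra == rb:
            g.remove_edge(a, b, key=key)
        else:
            parent[ra] = rb


def prune_to_main_branches(skeleton: BinaryMask, n: int = 3,
                           spur_length_mm: float = 5.0) -> list[np.ndarray]:
    """Decompose the skeleton into branches and keep the ``n`` longest.

    Spurs shorter than ``spur_length_mm`` and loops are removed first.
    Returns ordered point paths in world mm; if fewer than ``n`` branches
    exist all are returned with a logged warning.
    """
    spacing = np.asarray(skeleton.spacing)
    origin = np.asarray(skeleton.origin)
    chains, _ = _skeleton_chains(skeleton.as_bool())
    chains = [ch for ch in chains if len(ch) >= 2]
    if not chains:
        idx = np.argwhere(skeleton.as_bool()).astype(float)
        return [origin + spacing * idx]
    g = _build_graph(chains, spacing)
    _break_loops(g)
    _remove_spurs(g, spur_length_mm)
    _merge_degree2(g)
    _remove_spurs(g, spur_length_mm)
    edges = sorted(g.edges(data=True), key=lambda e: -e[2]["length"])
    if len(edges) < n:
        logger.warning("only %d branch(es) found, %d requested", len(edges), n)
    paths = []
    for a, b, data in edges[:n]:
        pts = origin + spacing * data["path"].astype(float)
        paths.append(pts)
    return paths


# ---------------------------------------------------------------------------
# Bifurcation merging & resampling
# ---------------------------------------------------------------------------

def _arc_resample(points: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    """Linear interpolation of a polyline at given arc-length fractions."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        return np.repeat(points[:1], len(fractions), axis=0)
    target = fractions * total
    out = np.empty((len(target), 3))
    for d in range(3):
        out[:, d] = np.interp(target, s, points[:, d])
    return out


def merge_bifurcation(branches: Sequence[np.ndarray],
                      landmark: Sequence[float] | None = None) -> Centerline:
    """Merge a trunk and two limbs into a single centerline.

    The two limbs are paired by arc-length fraction and replaced by their
    midpoints (the "combined lumen" path between the endograft submodules).
    The trunk is the branch whose free end lies nearest the renal landmark
    when one is given, otherwise the longest branch; the output runs
    proximal (trunk free end) to distal.
    """
    if len(branches) != 3:
        raise ValueError(f"merge_bifurcation needs exactly 3 branches, got {len(branches)}")
    branches = [np.asarray(b, dtype=float) for b in branches]

    # junction = the mutually closest endpoint triple
    ends = [(b[0], b[-1]) for b in branches]

    def _junction_cost(choice):
        pts = [ends[i][choice[i]] for i in range(3)]
        c = np.mean(pts, axis=0)
        return sum(np.linalg.norm(p - c) for p in pts)

    best = min(((i, j, k) for i in (0, 1) for j in (0, 1) for k in (0, 1)),
               key=_junction_cost)
    # orient every branch to start at its junction end
    oriented = []
    for b, c in zip(branches, best):
        oriented.append(b if c == 0 else b[::-1])

    lengths = [float(np.linalg.norm(np.diff(b, axis=0), axis=1).sum()) for b in oriented]
    if landmark is not None:
        lm = np.asarray(landmark, dtype=float)
        trunk_i = int(np.argmin([np.linalg.norm(b[-1] - lm) for b in oriented]))
    else:
        trunk_i = int(np.argmax(lengths))
    limbs = [oriented[i] for i in range(3) if i != trunk_i]
    trunk = oriented[trunk_i][::-1]  # proximal free end -> junction

    z0 = [min(l[:, 2].min(), l[:, 2].max()) for l in limbs]
    z1 = [max(l[:, 2].min(), l[:, 2].max()) for l in limbs]
    lo = max(limbs[0][:, 2].min(), limbs[1][:, 2].min())
    hi = min(limbs[0][:, 2].max(), limbs[1][:, 2].max())
    if hi <= lo:
        raise ValueError("limb branches have disjoint axial extents; cannot merge")

    k = max(len(limbs[0]), len(limbs[1]))
    fr = np.linspace(0.0, 1.0, k)
    mid = 0.5 * (_arc_resample(limbs[0], fr) + _arc_resample(limbs[1], fr))

    pts = [trunk]
    labels = [np.zeros(len(trunk), dtype=int)]
    # skip merged points overlapping the trunk junction point
    start = 1 if np.linalg.norm(mid[0] - trunk[-1]) < 1e-9 else 0
    pts.append(mid[start:])
    labels.append(np.ones(len(mid) - start, dtype=int))
    points = np.concatenate(pts)
    # drop any residual duplicate consecutive points
    keep = np.concatenate([[True], np.linalg.norm(np.diff(points, axis=0), axis=1) > 1e-9])
    return Centerline(points[keep], np.concatenate(labels)[keep])


def resample_centerline(cl: Centerline, delta: float = 1.0) -> Centerline:
    """Arc-length parameterized resampling at 0, delta, 2*delta, ...

    The start point is included and the original endpoint is appended as the
    final sample when the total length is not a multiple of ``delta``.
    """
    if delta <= 0:
        raise ValueError(f"sampling distance must be > 0, got {delta}")
    pts = cl.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total < delta:
        raise ValueError(f"centerline length {total:.3f} mm shorter than delta {delta}")
    n_full = int(np.floor(total / delta + 1e-9))
    targets = np.arange(n_full + 1) * delta
    if total - targets[-1] > 1e-9:
        targets = np.concatenate([targets, [total]])
    out = np.empty((len(targets), 3))
    for d in range(3):
        out[:, d] = np.interp(targets, s, pts[:, d])
    labels = None
    if cl.branch_labels is not None:
        idx = np.searchsorted(s, targets, side="right") - 1
        idx = np.clip(idx, 0, len(cl.branch_labels) - 1)
        labels = cl.branch_labels[idx]
    return Centerline(out, labels, sampling_distance=delta)
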