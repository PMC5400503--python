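"""Skeleton-level measurements.

Path lengths, spherical (Sholl-style) radial profiles, branch-node
detection with a minimum-daughter-length exclusion, linear densities of
point annotations, branch-node density vs soma distance, and the
light-microscopy post-processing steps (z smoothing, resampling).

Radial profiles use the Euclidean distance from the soma centroid by
default; geodesic (along-path) distance is available on request.  Edge
lengths are apportioned across distance bins by linear interpolation of
the radius along the edge, so profiles conserve total path length exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import networkx as nx
import numpy as np

from ._geometry import apportion_to_bins, resample_polyline
from .errors import ParameterError, SkeletonStructureError
from .skeleton import AnnotationPoint, Skeleton


def _compartment_predicate(compartment_filter) -> Callable[[str], bool]:
    if compartment_filter is None:
        return lambda c: True
    if callable(compartment_filter):
        return compartment_filter
    if isinstance(compartment_filter, str):
        allowed = {compartment_filter}
    else:
        allowed = set(compartment_filter)
    return lambda c: c in allowed


@dataclass
class RadialProfile:
    """Per-bin quantity (path length in µm, or node count) vs soma distance."""

    bin_edges: np.ndarray
    values: np.ndarray
    metric: str = "euclidean"
    quantity: str = "path_length"

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, float)
        self.values = np.asarray(self.values, float)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def normalized(self) -> np.ndarray:
        total = self.values.sum()
        return self.values / total if total > 0 else self.values

    def total(self) -> float:
        return float(self.values.sum())

    def fraction_within(self, r: float) -> float:
        """Fraction of the profiled quantity at distances <= r (bin-resolved)."""
        total = self.values.sum()
        if total == 0:
            return 0.0
        inside = 0.0
        for lo, hi, v in zip(self.bin_edges[:-1], self.bin_edges[1:], self.values):
            if hi <= r:
                inside += v
            elif lo < r < hi:
                inside += v * (r - lo) / (hi - lo)
        return float(inside / total)


# ---------------------------------------------------------------- lengths


def path_length(skeleton: Skeleton, compartment_filter=None) -> float:
    """Total Euclidean edge length (µm) over edges passing the filter.

    An edge contributes only when both endpoints pass; a soma-adjacent
    dendrite edge is therefore excluded from a pure-dendrite filter unless
    the filter admits the soma tag too.
    """
    pred = _compartment_predicate(compartment_filter)
    p0, p1 = skeleton.edge_arrays(pred)
    if len(p0) == 0:
        return 0.0
    return float(np.linalg.norm(p1 - p0, axis=1).sum())


def _geodesic_distances(skeleton: Skeleton, source: int) -> dict[int, float]:
    return nx.single_source_dijkstra_path_length(
        skeleton.graph, source, weight=lambda u, v, d: skeleton.edge_length(u, v)
    )


def radial_profile(
    skeleton: Skeleton,
    bin_width: float = 10.0,
    compartment_filter=None,
    metric: str = "euclidean",
    origin: np.ndarray | None = None,
    max_radius: float | None = None,
) -> RadialProfile:
    """Spherical Sholl-style profile: path length per soma-distance bin.

    Each edge is split across bins at bin-boundary crossings (linear
    interpolation of radius along the edge), so the profile sums exactly
    to the filtered path length.
    """
    if origin is None:
        origin = skeleton.origin()  # raises if missing
    origin = np.asarray(origin, float)
    pred = _compartment_predicate(compartment_filter)

    if metric == "euclidean":
        p0, p1 = skeleton.edge_arrays(pred)
        if len(p0) == 0:
            edges = np.arange(2) * bin_width
            return RadialProfile(edges, np.zeros(1), metric=metric)
        r0 = np.linalg.norm(p0 - origin, axis=1)
        r1 = np.linalg.norm(p1 - origin, axis=1)
        lengths = np.linalg.norm(p1 - p0, axis=1)
    elif metric == "geodesic":
        sn = skeleton.soma_node()
        if sn is None:
            raise SkeletonStructureError("geodesic profile requires a soma node")
        dist = _geodesic_distances(skeleton, sn)
        r0l, r1l, ll = [], [], []
        for u, v in skeleton.graph.edges:
            cu = skeleton.node_compartment(u)
            cv = skeleton.node_compartment(v)
            if not (pred(cu) and pred(cv)):
                continue
            if u not in dist or v not in dist:
                continue
            r0l.append(dist[u])
            r1l.append(dist[v])
            ll.append(skeleton.edge_length(u, v))
        r0, r1, lengths = map(np.asarray, (r0l, r1l, ll))
        if len(lengths) == 0:
            edges = np.arange(2) * bin_width
            return RadialProfile(edges, np.zeros(1), metric=metric)
    else:
        raise ParameterError(f"unknown metric {metric!r}")

    rmax = max_radius if max_radius is not None else float(max(r0.max(), r1.max()))
    n_bins = max(1, int(np.ceil(rmax / bin_width + 1e-12)))
    edges = np.arange(n_bins + 1) * bin_width
    values = apportion_to_bins(r0, r1, lengths, edges)
    return RadialProfile(edges, values, metric=metric)


# ---------------------------------------------------------------- branch nodes


def _max_extension(graph: nx.Graph, start: int, blocked: int, skeleton: Skeleton) -> float:
    """Longest path length from ``blocked`` into the subtree entered via ``start``."""
    best = 0.0
    stack = [(start, blocked, skeleton.edge_length(blocked, start))]
    while stack:
        node, prev, acc = stack.pop()
        best = max(best, acc)
        for nb in graph.neighbors(node):
            if nb != prev:
                stack.append((nb, node, acc + skeleton.edge_length(node, nb)))
    return best


def detect_branch_nodes(
    skeleton: Skeleton, min_daughter_length: float = 15.0
) -> list[AnnotationPoint]:
    """Branch nodes (degree >= 3), excluding those with a short daughter.

    A candidate is dropped when any daughter subtree extends less than
    ``min_daughter_length`` µm beyond the node (measured as maximum path
    extension, not straight-line distance).  Daughters are defined
    relative to the tree rooted at the soma node (or, lacking one, at each
    component's minimum node id): the neighbor on the root side is the
    parent, all other neighbors head daughter subtrees.
    """
    skeleton.validate_forest()
    g = skeleton.graph
    soma = skeleton.soma_node()
    out: list[AnnotationPoint] = []
    for comp in nx.connected_components(g):
        root = soma if (soma is not None and soma in comp) else min(comp)
        parent = dict(nx.bfs_predecessors(g.subgraph(comp), root))
        for node in comp:
            if g.degree(node) < 3:
                continue
            par = parent.get(node)
            daughters = [nb for nb in g.neighbors(node) if nb != par]
            if all(
                _max_extension(g, d, node, skeleton) >= min_daughter_length
                for d in daughters
            ):
                out.append(
                    AnnotationPoint(
                        kind="branch_node",
                        position=skeleton.node_position(node).copy(),
                        node_id=node,
                    )
                )
    return out


# ---------------------------------------------------------------- densities


def linear_density(markers: Sequence, path: float) -> float:
    """Count per unit path (e.g. spines/µm): len(markers) / path."""
    if path <= 0:
        raise ParameterError("path length must be > 0")
    n = markers if isinstance(markers, (int, np.integer)) else len(markers)
    return float(n) / float(path)


def branch_linear_densities(
    skeleton: Skeleton, markers: Sequence[AnnotationPoint]
) -> list[dict]:
    """Per-branch marker densities with branch midpoint soma distances.

    A branch is an unbranched run between nodes of degree != 2.  Markers
    are assigned to the branch containing their nearest skeleton node.
    """
    origin = skeleton.origin()
    runs = _unbranched_runs(skeleton)
    node_to_run: dict[int, int] = {}
    for i, run in enumerate(runs):
        for n in run:
            node_to_run.setdefault(n, i)
    counts = np.zeros(len(runs))
    all_ids = skeleton.node_ids()
    all_pos = skeleton.positions(all_ids)
    for m in markers:
        if m.node_id is not None and m.node_id in node_to_run:
            counts[node_to_run[m.node_id]] += 1
            continue
        nearest = all_ids[int(np.argmin(np.linalg.norm(all_pos - m.position, axis=1)))]
        if nearest in node_to_run:
            counts[node_to_run[nearest]] += 1
    out = []
    for i, run in enumerate(runs):
        pts = skeleton.positions(run)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        length = float(seg.sum())
        if length <= 0:
            continue
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        mid = np.array(
            [np.interp(length / 2, cum, pts[:, k]) for k in range(3)]
        )
        out.append(
            {
                "length_um": length,
                "midpoint_distance_um": float(np.linalg.norm(mid - origin)),
                "count": float(counts[i]),
                "density_per_um": float(counts[i] / length),
            }
        )
    return out


@dataclass
class BranchNodeDensityProfile:
    """Per-bin branch-node density (mm^-1) with its ingredient profiles."""

    length_profile: RadialProfile
    count_profile: RadialProfile
    density_per_mm: np.ndarray = field(init=False)
    reliable: np.ndarray = field(init=False)
    min_path_um: float = 50.0

    def __post_init__(self):
        length_um = self.length_profile.values
        counts = self.count_profile.values
        with np.errstate(divide="ignore", invalid="ignore"):
            dens = np.where(length_um > 0, counts / (length_um / 1000.0), np.nan)
        self.density_per_mm = dens
        self.reliable = length_um >= self.min_path_um


def branch_node_density_profile(
    skeletons: Sequence[Skeleton],
    bin_width: float = 25.0,
    compartment_filter="axon",
    min_daughter_length: float = 15.0,
    min_path_um: float = 50.0,
    max_radius: float | None = None,
) -> BranchNodeDensityProfile:
    """Branch-node density vs Euclidean soma distance, pooled over cells.

    Per bin: density = node count / path length, reported per mm.  Bins
    holding less than ``min_path_um`` of path are flagged unreliable.
    """
    pred = _compartment_predicate(compartment_filter)
    rmax = 0.0
    per_cell = []
    for skel in skeletons:
        origin = skel.origin()
        p0, p1 = skel.edge_arrays(pred)
        if len(p0) == 0:
            continue
        r0 = np.linalg.norm(p0 - origin, axis=1)
        r1 = np.linalg.norm(p1 - origin, axis=1)
        lengths = np.linalg.norm(p1 - p0, axis=1)
        nodes = detect_branch_nodes(skel, min_daughter_length=min_daughter_length)
        node_r = np.array(
            [np.linalg.norm(n.position - origin) for n in nodes]
        ) if nodes else np.zeros(0)
        rmax = max(rmax, float(max(r0.max(), r1.max())))
        if len(node_r):
            rmax = max(rmax, float(node_r.max()))
        per_cell.append((r0, r1, lengths, node_r))
    if not per_cell:
        raise SkeletonStructureError("no axon path in any input skeleton")
    if max_radius is not None:
        rmax = max_radius
    n_bins = max(1, int(np.ceil(rmax / bin_width + 1e-12)))
    edges = np.arange(n_bins + 1) * bin_width
    length_vals = np.zeros(n_bins)
    count_vals = np.zeros(n_bins)
    for r0, r1, lengths, node_r in per_cell:
        length_vals += apportion_to_bins(r0, r1, lengths, edges)
        if len(node_r):
            idx = np.clip(
                np.searchsorted(edges, node_r, side="right") - 1, 0, n_bins - 1
            )
            np.add.at(count_vals, idx, 1.0)
    prof = BranchNodeDensityProfile(
        length_profile=RadialProfile(edges, length_vals),
        count_profile=RadialProfile(edges, count_vals, quantity="node_count"),
        min_path_um=min_path_um,
    )
    return prof


# ---------------------------------------------------------------- LM post-processing


def _unbranched_runs(skeleton: Skeleton) -> list[list[int]]:
    """Maximal unbranched runs: node paths between nodes of degree != 2."""
    g = skeleton.graph
    runs = []
    visited_edges = set()
    anchors = [n for n in g.nodes if g.degree(n) != 2]
    for a in anchors:
        for nb in g.neighbors(a):
            if (a, nb) in visited_edges:
                continue
            run = [a, nb]
            visited_edges.add((a, nb))
            visited_edges.add((nb, a))
            prev, cur = a, nb
            while g.degree(cur) == 2:
                nxt = next(x for x in g.neighbors(cur) if x != prev)
                visited_edges.add((cur, nxt))
                visited_edges.add((nxt, cur))
                run.append(nxt)
                prev, cur = cur, nxt
            runs.append(run)
    # pure cycles would be missed, but skeletons are forests by invariant
    return runs


def smooth_and_resample(
    skeleton: Skeleton, window: int = 9, spacing: float = 1.0
) -> Skeleton:
    """LM post-processing: z smoothing then ~uniform resampling.

    The z-coordinate of each node is replaced by the mean over itself and
    up to (window-1)/2 neighbors each way along its unbranched run
    (shorter windows near branch points and tips use the available nodes).
    Each run is then resampled to ~``spacing`` µm point spacing.  Branch
    points and tips — the topology — are preserved exactly.
    """
    if spacing <= 0:
        raise ParameterError("spacing must be > 0")
    if window < 1 or window % 2 == 0:
        raise ParameterError("window must be a positive odd integer")
    skeleton.validate_forest()
    half = (window - 1) // 2
    g = skeleton.graph
    runs = _unbranched_runs(skeleton)

    smoothed: dict[int, float] = {}
    for run in runs:
        z = np.array([g.nodes[n]["pos"][2] for n in run])
        for i, n in enumerate(run):
            if g.degree(n) != 2:
                continue  # anchors keep their coordinates
            lo, hi = max(0, i - half), min(len(z), i + half + 1)
            smoothed.setdefault(n, float(z[lo:hi].mean()))

    out = Skeleton(
        soma_position=None
        if skeleton.soma_position is None
        else skeleton.soma_position.copy(),
        labeled=skeleton.labeled,
        skeleton_id=skeleton.skeleton_id,
        metadata=dict(skeleton.metadata),
    )
    next_id = 0
    anchor_new: dict[int, int] = {}

    def new_node(pos, radius, comp):
        nonlocal next_id
        out.add_node(next_id, pos, radius=radius, compartment=comp)
        next_id += 1
        return next_id - 1

    for run in runs:
        pts = []
        for n in run:
            p = g.nodes[n]["pos"].copy()
            if n in smoothed:
                p[2] = smoothed[n]
            pts.append(p)
        pts = np.asarray(pts)
        new_pts = resample_polyline(pts, spacing)
        comp = g.nodes[run[len(run) // 2]]["compartment"]
        ids = []
        for j, p in enumerate(new_pts):
            if j == 0 or j == len(new_pts) - 1:
                anchor = run[0] if j == 0 else run[-1]
                if anchor not in anchor_new:
                    a = g.nodes[anchor]
                    anchor_new[anchor] = new_node(p, a["radius"], a["compartment"])
                ids.append(anchor_new[anchor])
            else:
                ids.append(new_node(p, 0.0, comp))
        for u, v in zip(ids[:-1], ids[1:]):
            out.add_edge(u, v)
    # isolated nodes (degree 0) carry over untouched
    for n in g.nodes:
        if g.degree(n) == 0:
            d = g.nodes[n]
            new_node(d["pos"].copy(), d["radius"], d["compartment"])
    return out
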