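"""Postsynaptic cell typing from spine density, and same-cell merging.

HVC's three main cell classes separate cleanly by dendritic spine density
(spines per µm of dendritic path): inhibitory interneurons are nearly
aspinous, RA-projecting excitatory neurons moderately spiny, and
Area-X-projecting neurons densely spiny.  Short dendritic stretches traced
from individual synapses can therefore be typed, provided at least a
minimum path length was recovered.  Stretches traced from different
synapses but belonging to the same cell are detected by skeleton overlap
(point-to-segment distance) and merged before classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from ._geometry import min_point_to_polyline_distance
from .errors import ParameterError
from .morphometry import _max_extension
from .skeleton import Skeleton


@dataclass
class SpineDensityClassifier:
    """Threshold rule on spine density D (µm^-1).

    D < threshold_low -> interneuron (INT); threshold_low < D <
    threshold_high -> RA-projector (RA); D > threshold_high ->
    X-projector (X).  A density exactly at a threshold is assigned to the
    higher-density class.  Stretches shorter than ``min_dendrite_length``
    are returned as ``unknown``.
    """

    threshold_low: float = 0.11
    threshold_high: float = 0.46
    min_dendrite_length: float = 10.0

    def __post_init__(self):
        if not (0 < self.threshold_low < self.threshold_high):
            raise ParameterError("thresholds must satisfy 0 < low < high")


@dataclass
class OverlapMergeParams:
    """Parameters of the same-cell merge criterion."""

    node_to_edge_distance_um: float = 0.4  # 400 nm
    overlap_fraction: float = 0.25

    def __post_init__(self):
        if self.node_to_edge_distance_um <= 0:
            raise ParameterError("node-to-edge distance must be > 0")
        if not (0 < self.overlap_fraction <= 1):
            raise ParameterError("overlap fraction must lie in (0, 1]")


def count_spines(dendrite: Skeleton, min_length: float = 1.0, max_tip_synapses: int = 1) -> int:
    """Count dendritic spines on a skeletonized dendrite segment.

    The shaft is the longest path through each component; every side
    branch longer than ``min_length`` µm counts as a spine unless more
    than ``max_tip_synapses`` synapse annotations sit on it (polysynaptic
    protrusions, typical of interneurons, are excluded).
    """
    g = dendrite.graph
    if g.number_of_nodes() == 0:
        return 0
    dendrite.validate_forest()

    synapse_nodes: dict[int, int] = {}
    all_ids = dendrite.node_ids()
    all_pos = dendrite.positions(all_ids)
    for ann in dendrite.annotations:
        if ann.kind not in ("synapse_in", "synapse_out"):
            continue
        node = ann.node_id
        if node is None:
            node = all_ids[
                int(np.argmin(np.linalg.norm(all_pos - ann.position, axis=1)))
            ]
        synapse_nodes[node] = synapse_nodes.get(node, 0) + 1

    count = 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        shaft = _longest_path_nodes(dendrite, sub)
        shaft_set = set(shaft)
        for node in shaft:
            for nb in sub.neighbors(node):
                if nb in shaft_set:
                    continue
                # protrusion subtree rooted at nb, hanging off the shaft
                length = _max_extension(g, nb, node, dendrite)
                if length <= min_length:
                    continue
                n_syn = _subtree_synapses(g, nb, node, synapse_nodes)
                if n_syn <= max_tip_synapses:
                    count += 1
    return count


def _subtree_synapses(g, start, blocked, synapse_nodes) -> int:
    total = 0
    stack = [(start, blocked)]
    while stack:
        node, prev = stack.pop()
        total += synapse_nodes.get(node, 0)
        for nb in g.neighbors(node):
            if nb != prev:
                stack.append((nb, node))
    return total


def _longest_path_nodes(skel: Skeleton, sub) -> list[int]:
    """Nodes of the longest (path-length-weighted) path in a tree component."""
    nodes = list(sub.nodes)
    if len(nodes) == 1:
        return nodes

    def farthest(src):
        dist = {src: 0.0}
        pred = {src: None}
        stack = [src]
        while stack:
            u = stack.pop()
            for v in sub.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + skel.edge_length(u, v)
                    pred[v] = u
                    stack.append(v)
        far = max(dist, key=dist.get)
        return far, pred

    a, _ = farthest(nodes[0])
    b, pred = farthest(a)
    path = [b]
    while pred[path[-1]] is not None:
        path.append(pred[path[-1]])
    return path


def shaft_length(dendrite: Skeleton) -> float:
    """Summed length of the longest path through each component (the shaft),
    excluding the spine protrusions themselves."""
    g = dendrite.graph
    total = 0.0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        shaft = _longest_path_nodes(dendrite, sub)
        for u, v in zip(shaft[:-1], shaft[1:]):
            total += dendrite.edge_length(u, v)
    return total


def spine_density(dendrite: Skeleton) -> float:
    """Spines per µm of dendritic shaft path."""
    length = shaft_length(dendrite)
    if length <= 0:
        raise ParameterError("dendrite has zero shaft path length")
    return count_spines(dendrite) / length


def classify_dendrite(
    density: float,
    dendrite_length: float,
    clf: SpineDensityClassifier | None = None,
) -> str:
    """Type a dendritic stretch from its spine density: INT / RA / X / unknown."""
    clf = clf or SpineDensityClassifier()
    if density < 0:
        raise ParameterError("spine density must be >= 0")
    if dendrite_length < clf.min_dendrite_length:
        return "unknown"
    if density < clf.threshold_low:
        return "INT"
    if density < clf.threshold_high:
        return "RA"
    return "X"


def overlap_fraction(a: Skeleton, b: Skeleton, max_distance: float) -> float:
    """Share of a's nodes within ``max_distance`` of any edge of b."""
    pts = a.positions()
    if len(pts) == 0:
        return 0.0
    seg_a, seg_b = b.edge_arrays()
    if len(seg_a) == 0:
        # degenerate: b has nodes but no edges; use node-to-node distance
        bp = b.positions()
        if len(bp) == 0:
            return 0.0
        d = np.min(
            np.linalg.norm(pts[:, None, :] - bp[None, :, :], axis=2), axis=1
        )
    else:
        d = min_point_to_polyline_distance(pts, seg_a, seg_b)
    return float(np.mean(d <= max_distance))


def merge_same_cell(
    dendrites: Sequence[Skeleton],
    params: OverlapMergeParams | None = None,
) -> list[list[int]]:
    """Partition dendrite reconstructions into putative same-cell groups.

    Two reconstructions are linked when at least ``overlap_fraction`` of
    either one's nodes lie within the node-to-edge distance of the other
    (the criterion is evaluated in both directions and linked if either
    passes).  Groups are the connected components of the link graph;
    grouping is therefore transitive and permutation-invariant.  Returns
    groups as lists of indices into ``dendrites``.
    """
    params = params or OverlapMergeParams()
    n = len(dendrites)
    link = nx.Graph()
    link.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            fij = overlap_fraction(
                dendrites[i], dendrites[j], params.node_to_edge_distance_um
            )
            fji = overlap_fraction(
                dendrites[j], dendrites[i], params.node_to_edge_distance_um
            )
            if max(fij, fji) >= params.overlap_fraction:
                link.add_edge(i, j)
    groups = [sorted(c) for c in nx.connected_components(link)]
    return sorted(groups)


def group_spine_density(member_densities: Sequence[float]) -> float:
    """Per-group spine density: unweighted mean of member densities,
    averaged before classification."""
    if len(member_densities) == 0:
        raise ParameterError("empty group")
    return float(np.mean(member_densities))


def active_zone_area(diameter: float) -> float:
    """Active-zone area (µm²) from its diameter, assuming a circular contact."""
    if np.any(np.asarray(diameter) < 0):
        raise ParameterError("diameter must be >= 0")
    return np.pi * np.asarray(diameter) ** 2 / 4.0
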