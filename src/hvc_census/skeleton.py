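"""In-memory containers for neurite reconstructions and point annotations.

A :class:`Skeleton` is an undirected forest of 3D nodes (positions in µm)
with per-node compartment tags (soma / axon / dendrite / undetermined),
an optional soma position, a labeling flag (e.g. tracer-filled or not) and
a list of attached point annotations (spines, boutons, branch nodes,
synapses).  The graph lives in a :class:`networkx.Graph`; node attributes
are ``pos`` (length-3 float array), ``radius`` (µm) and ``compartment``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

import networkx as nx
import numpy as np

from .errors import SkeletonStructureError, ValidationError

COMPARTMENTS = ("soma", "axon", "dendrite", "undetermined")

#: SWC structure codes -> compartment tags
SWC_CODE_TO_COMPARTMENT = {1: "soma", 2: "axon", 3: "dendrite", 5: "undetermined"}
COMPARTMENT_TO_SWC_CODE = {"soma": 1, "axon": 2, "dendrite": 3, "undetermined": 5}

ANNOTATION_KINDS = ("spine", "bouton", "branch_node", "synapse_in", "synapse_out")

POLARITIES = ("symmetric", "asymmetric", "unknown")
POSTSYNAPTIC_TYPES = ("INT", "RA", "X", "unknown")


@dataclass
class AnnotationPoint:
    """A typed point marker attached to a skeleton location."""

    kind: str
    position: np.ndarray
    node_id: int | None = None
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ANNOTATION_KINDS:
            raise ValidationError(
                f"unknown annotation kind {self.kind!r}; expected one of {ANNOTATION_KINDS}"
            )
        self.position = np.asarray(self.position, float)


@dataclass
class SynapseRecord:
    """One synapse from an annotation table.

    ``polarity`` uses the ultrastructural vocabulary: ``asymmetric``
    (pronounced postsynaptic density, presumed excitatory) or ``symmetric``
    (presumed inhibitory).  ``postsynaptic_type`` is the target cell class:
    inhibitory interneuron (INT), RA-projecting (RA) or Area-X-projecting
    (X) excitatory neuron.
    """

    synapse_id: int
    skeleton_id: int
    position: np.ndarray
    polarity: str = "unknown"
    active_zone_diameter: float | None = None
    presynaptic_labeled: bool = False
    postsynaptic_skeleton_id: int | None = None
    postsynaptic_type: str = "unknown"

    def __post_init__(self):
        if self.polarity not in POLARITIES:
            raise ValidationError(
                f"unknown polarity {self.polarity!r}; expected one of {POLARITIES}"
            )
        if self.postsynaptic_type not in POSTSYNAPTIC_TYPES:
            raise ValidationError(
                f"unknown postsynaptic type {self.postsynaptic_type!r}; "
                f"expected one of {POSTSYNAPTIC_TYPES}"
            )
        if self.active_zone_diameter is not None and self.active_zone_diameter < 0:
            raise ValidationError("active_zone_diameter must be >= 0")
        self.position = np.asarray(self.position, float)


@dataclass
class Skeleton:
    """A tree-structured neurite reconstruction in physical (µm) space."""

    graph: nx.Graph = field(default_factory=nx.Graph)
    soma_position: np.ndarray | None = None
    labeled: bool = False
    annotations: list[AnnotationPoint] = field(default_factory=list)
    skeleton_id: int | None = None
    metadata: dict = field(default_factory=dict)

    # -- construction -------------------------------------------------

    def add_node(
        self,
        node_id: int,
        position,
        radius: float = 0.0,
        compartment: str = "undetermined",
    ) -> None:
        if compartment not in COMPARTMENTS:
            raise ValidationError(f"unknown compartment {compartment!r}")
        self.graph.add_node(
            node_id,
            pos=np.asarray(position, float),
            radius=float(radius),
            compartment=compartment,
        )

    def add_edge(self, u: int, v: int) -> None:
        if u not in self.graph or v not in self.graph:
            raise SkeletonStructureError(f"edge ({u}, {v}) references unknown node")
        self.graph.add_edge(u, v)

    # -- accessors ----------------------------------------------------

    def node_position(self, node_id: int) -> np.ndarray:
        return self.graph.nodes[node_id]["pos"]

    def node_compartment(self, node_id: int) -> str:
        return self.graph.nodes[node_id]["compartment"]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def node_ids(self) -> list[int]:
        return list(self.graph.nodes)

    def positions(self, nodes: Iterable[int] | None = None) -> np.ndarray:
        nodes = self.node_ids() if nodes is None else list(nodes)
        if not nodes:
            return np.zeros((0, 3))
        return np.array([self.graph.nodes[n]["pos"] for n in nodes])

    def edge_arrays(
        self, compartment_filter: Callable[[str], bool] | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """(p0, p1) position arrays over edges whose BOTH endpoints pass the filter."""
        p0, p1 = [], []
        for u, v in self.graph.edges:
            if compartment_filter is not None:
                cu = self.graph.nodes[u]["compartment"]
                cv = self.graph.nodes[v]["compartment"]
                if not (compartment_filter(cu) and compartment_filter(cv)):
                    continue
            p0.append(self.graph.nodes[u]["pos"])
            p1.append(self.graph.nodes[v]["pos"])
        if not p0:
            return np.zeros((0, 3)), np.zeros((0, 3))
        return np.array(p0), np.array(p1)

    def edge_length(self, u: int, v: int) -> float:
        return float(
            np.linalg.norm(self.graph.nodes[u]["pos"] - self.graph.nodes[v]["pos"])
        )

    def soma_node(self) -> int | None:
        """The node tagged soma nearest ``soma_position`` (or any soma node)."""
        soma_nodes = [
            n for n, d in self.graph.nodes(data=True) if d["compartment"] == "soma"
        ]
        if not soma_nodes:
            return None
        if self.soma_position is None:
            return soma_nodes[0]
        pos = self.positions(soma_nodes)
        return soma_nodes[int(np.argmin(np.linalg.norm(pos - self.soma_position, axis=1)))]

    def origin(self) -> np.ndarray:
        """The reference point for soma-distance measurements."""
        if self.soma_position is not None:
            return np.asarray(self.soma_position, float)
        sn = self.soma_node()
        if sn is not None:
            return self.node_position(sn)
        raise SkeletonStructureError("skeleton has no soma position or soma node")

    # -- validation ---------------------------------------------------

    def validate_forest(self) -> None:
        """Raise unless the graph is a forest (acyclic)."""
        if self.graph.number_of_edges() and not nx.is_forest(self.graph):
            raise SkeletonStructureError("skeleton graph contains a cycle")

    def components(self) -> list[set]:
        return [set(c) for c in nx.connected_components(self.graph)]
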