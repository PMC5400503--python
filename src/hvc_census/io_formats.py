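"""Readers and writers for the standard on-disk formats.

* SWC skeletons (7-column whitespace-delimited, ``#`` comments)
* KNOSSOS-style NML skeleton annotations (XML; voxel coordinates converted
  to µm at ingest using the file's ``<scale>`` element)
* CSV synapse annotation tables (explicit headers, UTF-8, ``.`` decimals)
* YAML / JSON structured configuration

All internal coordinates are µm in continuous physical space; voxel→µm
conversion happens only here.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from lxml import etree

from .errors import SkeletonParseError, SkeletonStructureError, ValidationError
from .skeleton import (
    COMPARTMENT_TO_SWC_CODE,
    SWC_CODE_TO_COMPARTMENT,
    Skeleton,
    SynapseRecord,
)

#: Default NML voxel size in nm (x, y, z) for EM stacks lacking a scale element
DEFAULT_EM_SCALE_NM = (11.0, 11.0, 29.0)

SYNAPSE_CSV_COLUMNS = [
    "synapse_id",
    "skeleton_id",
    "x",
    "y",
    "z",
    "polarity",
    "active_zone_diameter",
    "presynaptic_labeled",
    "postsynaptic_skeleton_id",
    "postsynaptic_type",
]


# ---------------------------------------------------------------- SWC


def read_swc(path) -> Skeleton:
    """Read a 7-column SWC file into a :class:`Skeleton`.

    Unknown structure codes map to compartment ``undetermined`` with a
    warning.  Multiple roots produce multiple connected components,
    flagged in ``metadata['n_components']``.
    """
    path = Path(path)
    skel = Skeleton()
    parents: dict[int, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SkeletonParseError(
                    f"{path}:{lineno}: expected 7 columns, got {len(parts)}"
                )
            try:
                nid = int(parts[0])
                code = int(parts[1])
                x, y, z, radius = (float(p) for p in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise SkeletonParseError(f"{path}:{lineno}: {exc}") from None
            if nid in skel.graph:
                raise SkeletonStructureError(f"{path}:{lineno}: duplicate node id {nid}")
            comp = SWC_CODE_TO_COMPARTMENT.get(code)
            if comp is None:
                warnings.warn(
                    f"{path}:{lineno}: unknown SWC structure code {code}; "
                    "mapping to 'undetermined'",
                    stacklevel=2,
                )
                comp = "undetermined"
            skel.add_node(nid, (x, y, z), radius=radius, compartment=comp)
            parents[nid] = parent
    n_roots = 0
    for nid, parent in parents.items():
        if parent == -1:
            n_roots += 1
            continue
        if parent not in skel.graph:
            raise SkeletonStructureError(
                f"{path}: node {nid} references missing parent {parent}"
            )
        skel.add_edge(nid, parent)
    skel.validate_forest()
    skel.metadata["n_components"] = max(n_roots, 1)
    skel.metadata["source"] = str(path)
    sn = skel.soma_node()
    if sn is not None:
        skel.soma_position = skel.node_position(sn).copy()
    return skel


def write_swc(skeleton: Skeleton, path) -> None:
    """Write a skeleton as standard 7-column SWC (one root per component)."""
    path = Path(path)
    lines = ["# id type x y z radius parent"]
    # choose a root per component: soma node if present, else min id
    parent_of: dict[int, int] = {}
    soma = skeleton.soma_node()
    import networkx as nx

    for comp in nx.connected_components(skeleton.graph):
        root = soma if soma in comp else min(comp)
        for child, parent in nx.bfs_predecessors(skeleton.graph.subgraph(comp), root):
            parent_of[child] = parent
        parent_of[root] = -1
    for nid in sorted(skeleton.graph.nodes):
        d = skeleton.graph.nodes[nid]
        code = COMPARTMENT_TO_SWC_CODE[d["compartment"]]
        x, y, z = (float(c) for c in d["pos"])
        # shortest round-trip float repr: read(write(s)) preserves coordinates
        lines.append(
            f"{nid} {code} {x!r} {y!r} {z!r} {float(d['radius'])!r} "
            f"{parent_of.get(nid, -1)}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------- NML


def read_nml(path, scale_nm: tuple[float, float, float] | None = None) -> list[Skeleton]:
    """Read a KNOSSOS-style NML file into a list of skeletons (one per <thing>).

    Node coordinates are voxels; they are converted to µm with the file's
    ``<scale>`` element (nm per voxel).  If the file has no scale element,
    ``scale_nm`` must be supplied (the conventional EM voxel size is
    ``DEFAULT_EM_SCALE_NM``).
    """
    path = Path(path)
    tree = etree.parse(str(path))
    root = tree.getroot()
    scale_el = root.find("parameters/scale")
    if scale_el is not None:
        scale = np.array(
            [float(scale_el.get(ax)) for ax in ("x", "y", "z")], float
        )
    elif scale_nm is not None:
        scale = np.asarray(scale_nm, float)
    else:
        raise SkeletonParseError(
            f"{path}: no <scale> element and no scale override supplied"
        )
    scale_um = scale / 1000.0
    skeletons = []
    for thing in root.findall("thing"):
        skel = Skeleton(skeleton_id=int(thing.get("id", 0)) or None)
        for node in thing.findall("nodes/node"):
            nid = int(node.get("id"))
            pos = np.array(
                [float(node.get(ax)) for ax in ("x", "y", "z")], float
            ) * scale_um
            radius_vox = float(node.get("radius", 0.0))
            skel.add_node(nid, pos, radius=radius_vox * scale_um[0])
        for edge in thing.findall("edges/edge"):
            u, v = int(edge.get("source")), int(edge.get("target"))
            if u not in skel.graph or v not in skel.graph:
                raise SkeletonStructureError(
                    f"{path}: edge ({u}, {v}) references unknown node"
                )
            skel.add_edge(u, v)
        skel.validate_forest()
        skel.metadata["source"] = str(path)
        skel.metadata["scale_nm"] = tuple(scale)
        skeletons.append(skel)
    return skeletons


# ---------------------------------------------------------------- synapse CSV


def read_synapse_table(path) -> list[SynapseRecord]:
    """Read a synapse annotation CSV into validated records.

    The header must contain at least ``synapse_id, skeleton_id, x, y, z,
    polarity``; remaining columns are optional.  Closed vocabularies are
    enforced (unknown polarity / target-type strings are rejected).
    """
    df = pd.read_csv(path)
    missing = {"synapse_id", "skeleton_id", "x", "y", "z", "polarity"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing required columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        diam = getattr(row, "active_zone_diameter", None)
        if diam is not None and pd.isna(diam):
            diam = None
        post_id = getattr(row, "postsynaptic_skeleton_id", None)
        if post_id is not None and pd.isna(post_id):
            post_id = None
        post_type = getattr(row, "postsynaptic_type", "unknown")
        if pd.isna(post_type):
            post_type = "unknown"
        records.append(
            SynapseRecord(
                synapse_id=int(row.synapse_id),
                skeleton_id=int(row.skeleton_id),
                position=np.array([row.x, row.y, row.z], float),
                polarity=str(row.polarity),
                active_zone_diameter=None if diam is None else float(diam),
                presynaptic_labeled=bool(getattr(row, "presynaptic_labeled", False)),
                postsynaptic_skeleton_id=None if post_id is None else int(post_id),
                postsynaptic_type=str(post_type),
            )
        )
    return records


def write_synapse_table(records: list[SynapseRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "synapse_id": r.synapse_id,
                "skeleton_id": r.skeleton_id,
                "x": r.position[0],
                "y": r.position[1],
                "z": r.position[2],
                "polarity": r.polarity,
                "active_zone_diameter": r.active_zone_diameter,
                "presynaptic_labeled": r.presynaptic_labeled,
                "postsynaptic_skeleton_id": r.postsynaptic_skeleton_id,
                "postsynaptic_type": r.postsynaptic_type,
            }
        )
    pd.DataFrame(rows, columns=SYNAPSE_CSV_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------- config


def read_config(path) -> dict:
    """Read a YAML or JSON configuration file into a dict."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def write_config(cfg: dict, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(cfg, indent=2), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=False), encoding="utf-8")
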