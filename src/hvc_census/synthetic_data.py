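"""Seeded synthetic HVC-like circuits with known ground truth.

The generator emulates the statistical structure the analysis assumes —
not the biophysics of real arbors:

* RA-projecting (RA) cell axons grow as persistent random walks with
  branching as an inhomogeneous Poisson process whose intensity per unit
  path is the exponential branch-node density Db(r) = A exp(-r/lambda) + c
  (defaults A = 35.448 mm^-1, lambda = 43.5 µm, c = 0.613 mm^-1).
* Synapses are placed along axons as a homogeneous Poisson process
  (default 75.4 per mm); each synapse's postsynaptic cell class is drawn
  from a distance-dependent logistic mixture pinned to the observed
  proximal (~95% interneuron) and distal (~35% interneuron, ~37% RA)
  target compositions.
* Dendrites are radial-shoot arbors tuned so ~95% of dendritic path lies
  within 100 µm of the soma (default 3.2 mm per RA cell); spine markers
  are placed at cell-class-specific densities (0.01/0.21/0.70 µm^-1 for
  INT/RA/X, Gaussian scatter truncated at 0).
* Tracer labeling is Bernoulli per cell (default 1/7 of somata) followed
  by per-branch label dropout, reaching a configurable overall axon
  labeling probability (default 0.076).

Every stochastic step flows from one integer seed, and the emitted
skeleton/synapse objects are valid inputs for the io and analysis modules
with no special-casing.  A :class:`GroundTruth` records what was actually
generated, so recovery tests compare estimates against known values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._geometry import segment_box_interval
from .errors import ConfigError
from .skeleton import AnnotationPoint, Skeleton, SynapseRecord
from .soma_distance import DensityModel


@dataclass
class MixtureCurve:
    """Distance-dependent postsynaptic-type mixture (logistic in r).

    Interneuron probability decays from ``p_int_near`` at r = 0 to
    ``p_int_far``; the RA share rises from ``p_ra_near`` to ``p_ra_far``;
    the X share is the remainder.  The logistic form is a stand-in: only
    the endpoints are constrained by observation.
    """

    p_int_near: float = 0.95
    p_int_far: float = 0.354
    p_ra_near: float = 0.033
    p_ra_far: float = 0.369
    r_mid_um: float = 100.0
    slope_um: float = 30.0

    def probabilities(self, r) -> np.ndarray:
        """(n, 3) array of (INT, RA, X) probabilities at distances r (µm)."""
        r = np.atleast_1d(np.asarray(r, float))
        sig = 1.0 / (1.0 + np.exp((r - self.r_mid_um) / self.slope_um))
        sig0 = 1.0 / (1.0 + np.exp(-self.r_mid_um / self.slope_um))
        s = sig / sig0  # exactly 1 at r = 0, -> 0 far from the soma
        p_int = self.p_int_far + (self.p_int_near - self.p_int_far) * s
        p_ra = self.p_ra_far + (self.p_ra_near - self.p_ra_far) * s
        p_x = np.clip(1.0 - p_int - p_ra, 0.0, None)
        p = np.stack([p_int, p_ra, p_x], axis=1)
        return p / p.sum(axis=1, keepdims=True)


@dataclass
class CircuitConfig:
    """Study conditions of the synthetic circuit.

    Defaults are the whole-nucleus values the analysis takes as inputs;
    tests and examples scale ``volume``, cell counts and per-cell path
    down while keeping the densities and probabilities fixed.
    """

    volume_um: tuple[float, float, float] = (2000.0, 500.0, 500.0)
    em_box_um: tuple[float, float, float] = (166.0, 166.0, 77.0)
    n_ra: int = 20
    n_int: int = 5
    n_x: int = 5
    dendrite_path_um: float = 3200.0
    dendrite_radial_scale_um: float = 30.0  # ~95-96% of path within 100 µm
    axon_path_um: float = 14700.0
    density_model: DensityModel = field(
        default_factory=lambda: DensityModel(35.448, 43.5, 0.613)
    )
    synapse_density_per_mm: float = 75.4
    mixture: MixtureCurve = field(default_factory=MixtureCurve)
    spine_density_classes: dict = field(
        default_factory=lambda: {"INT": (0.01, 0.01), "RA": (0.21, 0.07), "X": (0.70, 0.13)}
    )
    soma_label_prob: float = 1.0 / 7.0
    axon_label_prob: float = 0.076
    incoming_excitatory_per_cell: float = 786.0
    external_excitatory_per_cell: float = 595.0  # non-homotypic excitatory inputs
    step_um: float = 2.0
    direction_sigma: float = 0.25  # per-step angular persistence of the walk
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.axon_label_prob <= self.soma_label_prob <= 1):
            raise ConfigError(
                "need 0 <= axon_label_prob <= soma_label_prob <= 1 "
                "(per-branch dropout cannot raise the labeling probability)"
            )
        if min(self.volume_um) <= 0 or self.axon_path_um < 0 or self.dendrite_path_um < 0:
            raise ConfigError("volume and path lengths must be positive")
        vol = float(np.prod(self.volume_um))
        # sanity: a single cell's axon must fit loosely inside the volume
        if self.axon_path_um > 0 and vol / self.axon_path_um < self.step_um:
            raise ConfigError("axon path exceeds what the volume can plausibly hold")
        for k, (mu, sd) in self.spine_density_classes.items():
            if mu < 0 or sd < 0:
                raise ConfigError(f"negative spine density parameters for {k}")


@dataclass
class GroundTruth:
    """What the generator actually made, for recovery tests."""

    config: CircuitConfig
    cell_types: dict = field(default_factory=dict)  # skeleton_id -> type
    cell_labeled: dict = field(default_factory=dict)
    soma_positions: dict = field(default_factory=dict)
    spine_densities: dict = field(default_factory=dict)
    total_axon_path_um: float = 0.0
    labeled_axon_path_um: float = 0.0
    synapse_types: dict = field(default_factory=dict)  # synapse_id -> target type
    synapse_distances_um: dict = field(default_factory=dict)
    incoming_homotypic: dict = field(default_factory=dict)  # RA cell -> count
    external_excitatory: dict = field(default_factory=dict)  # RA cell -> count
    fragment_distances_um: dict = field(default_factory=dict)  # filled by cropping

    def homotypic_fraction_true(self) -> float:
        """Realized homotypic share of incoming excitatory synapses."""
        homo = sum(self.incoming_homotypic.values())
        ext = sum(self.external_excitatory.values())
        return homo / (homo + ext) if homo + ext else 0.0

    @property
    def labeled_axon_fraction(self) -> float:
        if self.total_axon_path_um == 0:
            return 0.0
        return self.labeled_axon_path_um / self.total_axon_path_um

    def homotypic_share_outgoing(self) -> float:
        """True RA share among outgoing synapse targets."""
        types = list(self.synapse_types.values())
        if not types:
            return 0.0
        return sum(t == "RA" for t in types) / len(types)

    def to_json(self) -> str:
        return json.dumps(
            {
                "cell_types": self.cell_types,
                "cell_labeled": self.cell_labeled,
                "soma_positions": {k: list(v) for k, v in self.soma_positions.items()},
                "spine_densities": self.spine_densities,
                "total_axon_path_um": self.total_axon_path_um,
                "labeled_axon_path_um": self.labeled_axon_path_um,
                "synapse_types": self.synapse_types,
                "synapse_distances_um": self.synapse_distances_um,
                "fragment_distances_um": self.fragment_distances_um,
            },
            indent=2,
            default=str,
        )


@dataclass
class Circuit:
    """A generated circuit: skeletons, a synapse table, and ground truth."""

    skeletons: list[Skeleton]
    synapses: list[SynapseRecord]
    ground_truth: GroundTruth

    def by_type(self, cell_type: str) -> list[Skeleton]:
        gt = self.ground_truth
        return [s for s in self.skeletons if gt.cell_types.get(s.skeleton_id) == cell_type]


# ---------------------------------------------------------------- growth


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _reflect(pos: np.ndarray, direction: np.ndarray, vol: np.ndarray) -> None:
    """Reflect position/direction at the volume walls, in place."""
    for ax in range(3):
        if pos[ax] < 0:
            pos[ax] = -pos[ax]
            direction[ax] = -direction[ax]
        elif pos[ax] > vol[ax]:
            pos[ax] = 2 * vol[ax] - pos[ax]
            direction[ax] = -direction[ax]


def _grow_axon(
    skel: Skeleton,
    soma_id: int,
    cfg: CircuitConfig,
    rng: np.random.Generator,
) -> list[int]:
    """Grow one axon tree; returns the node ids that are branch nodes.

    Active tips advance in ``step_um`` steps with persistent random
    directions (reflecting walls); at each step the tip bifurcates with
    probability Db(r) * step, which realizes an inhomogeneous Poisson
    branch-node process with intensity Db(r) per unit path.
    """
    vol = np.asarray(cfg.volume_um, float)
    soma_pos = skel.node_position(soma_id)
    next_id = max(skel.graph.nodes) + 1
    tips = [(soma_id, _random_unit(rng))]
    total = 0.0
    branch_nodes: list[int] = []
    budget = cfg.axon_path_um
    step = cfg.step_um
    while total < budget and tips:
        idx = rng.integers(len(tips))
        node, direction = tips.pop(idx)
        direction = direction + cfg.direction_sigma * rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = skel.node_position(node).copy()
        pos = pos + direction * step
        _reflect(pos, direction, vol)
        skel.add_node(next_id, pos, compartment="axon")
        skel.add_edge(node, next_id)
        total += step
        r = float(np.linalg.norm(pos - soma_pos))
        p_branch = cfg.density_model(r) * step / 1000.0  # mm^-1 -> per µm
        if rng.random() < p_branch:
            branch_nodes.append(next_id)
            tips.append((next_id, _random_unit(rng)))
            tips.append((next_id, _random_unit(rng)))
        else:
            tips.append((next_id, direction))
        next_id += 1
    return branch_nodes


def _grow_dendrite(
    skel: Skeleton, soma_id: int, cfg: CircuitConfig, rng: np.random.Generator
) -> None:
    """Radial-shoot dendrite: straight 1-µm-sampled branches from the soma
    with exponentially distributed lengths (scale = dendrite_radial_scale).

    This is a statistical stand-in tuned to reproduce the radial
    compactness of real dendrites, not their branching geometry.
    """
    soma_pos = skel.node_position(soma_id)
    vol = np.asarray(cfg.volume_um, float)
    next_id = max(skel.graph.nodes) + 1
    total = 0.0
    while total < cfg.dendrite_path_um:
        u = _random_unit(rng)
        length = rng.exponential(cfg.dendrite_radial_scale_um)
        length = float(np.clip(length, 2.0, cfg.dendrite_path_um - total + 2.0))
        n_steps = max(2, int(round(length)))
        prev = soma_id
        for k in range(1, n_steps + 1):
            pos = soma_pos + u * (k * length / n_steps)
            pos = np.clip(pos, 0.0, vol)  # dendrites stay inside the volume
            skel.add_node(next_id, pos, compartment="dendrite")
            skel.add_edge(prev, next_id)
            prev = next_id
            next_id += 1
        total += length


def _truncated_normal(mu: float, sd: float, rng) -> float:
    """One draw from N(mu, sd) truncated at 0 (resampling)."""
    if sd == 0:
        return max(mu, 0.0)
    for _ in range(1000):
        x = rng.normal(mu, sd)
        if x >= 0:
            return float(x)
    return max(mu, 0.0)


def _place_spines(skel: Skeleton, density_per_um: float, rng) -> int:
    """Poisson spine markers along the dendrite at the given linear density."""
    n_placed = 0
    g = skel.graph
    for u, v in g.edges:
        if (
            g.nodes[u]["compartment"] != "dendrite"
            and g.nodes[v]["compartment"] != "dendrite"
        ):
            continue
        length = skel.edge_length(u, v)
        k = rng.poisson(density_per_um * length)
        for _ in range(k):
            t = rng.random()
            pos = g.nodes[u]["pos"] + t * (g.nodes[v]["pos"] - g.nodes[u]["pos"])
            skel.annotations.append(
                AnnotationPoint(kind="spine", position=pos, node_id=u)
            )
            n_placed += 1
    return n_placed


def _apply_labeling(
    skel: Skeleton, cfg: CircuitConfig, rng
) -> tuple[float, float]:
    """Per-cell then per-branch tracer labeling; returns (total, labeled) axon path."""
    g = skel.graph
    cell_labeled = bool(rng.random() < cfg.soma_label_prob)
    skel.labeled = cell_labeled
    dropout_keep = (
        cfg.axon_label_prob / cfg.soma_label_prob if cfg.soma_label_prob > 0 else 0.0
    )
    # branch granularity: unbranched runs of the axon
    from .morphometry import _unbranched_runs

    total = 0.0
    labeled = 0.0
    for n in g.nodes:
        g.nodes[n]["labeled"] = False
    for run in _unbranched_runs(skel):
        comps = {g.nodes[n]["compartment"] for n in run}
        if "axon" not in comps:
            continue
        keep = cell_labeled and (rng.random() < dropout_keep)
        run_len = sum(
            skel.edge_length(u, v) for u, v in zip(run[:-1], run[1:])
        )
        total += run_len
        if keep:
            labeled += run_len
            for n in run:
                if g.nodes[n]["compartment"] == "axon":
                    g.nodes[n]["labeled"] = True
    return total, labeled


def _place_synapses(
    skel: Skeleton,
    cfg: CircuitConfig,
    rng,
    next_synapse_id: int,
    ra_ids: list[int],
    int_ids: list[int],
    x_ids: list[int],
) -> tuple[list[SynapseRecord], int]:
    """Poisson synapses along the axon; types from the distance mixture."""
    g = skel.graph
    soma_pos = skel.origin()
    records = []
    type_pools = {"INT": int_ids, "RA": ra_ids, "X": x_ids}
    for u, v in g.edges:
        if g.nodes[u]["compartment"] != "axon" or g.nodes[v]["compartment"] != "axon":
            continue
        length = skel.edge_length(u, v)
        k = rng.poisson(cfg.synapse_density_per_mm * length / 1000.0)
        for _ in range(k):
            t = rng.random()
            pos = g.nodes[u]["pos"] + t * (g.nodes[v]["pos"] - g.nodes[u]["pos"])
            r = float(np.linalg.norm(pos - soma_pos))
            p = cfg.mixture.probabilities(r)[0]
            target = ("INT", "RA", "X")[rng.choice(3, p=p)]
            pool = type_pools[target]
            post_id = int(pool[rng.integers(len(pool))]) if pool else None
            az_area = rng.lognormal(mean=np.log(0.17), sigma=1.2)
            diam = float(np.sqrt(4.0 * az_area / np.pi))
            labeled_here = bool(
                g.nodes[u].get("labeled", False) and g.nodes[v].get("labeled", False)
            )
            records.append(
                SynapseRecord(
                    synapse_id=next_synapse_id,
                    skeleton_id=skel.skeleton_id,
                    position=pos,
                    polarity="asymmetric",
                    active_zone_diameter=diam,
                    presynaptic_labeled=labeled_here,
                    postsynaptic_skeleton_id=post_id,
                    postsynaptic_type=target,
                )
            )
            skel.annotations.append(
                AnnotationPoint(
                    kind="synapse_out",
                    position=pos,
                    node_id=u,
                    attributes={"target_type": target, "distance_um": r},
                )
            )
            next_synapse_id += 1
    return records, next_synapse_id


# ---------------------------------------------------------------- top level


def generate_circuit(cfg: CircuitConfig | None = None, seed: int | None = None) -> Circuit:
    """Generate a full synthetic circuit under ``cfg`` (seeded, reproducible)."""
    cfg = cfg or CircuitConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    vol = np.asarray(cfg.volume_um, float)

    skeletons: list[Skeleton] = []
    gt = GroundTruth(config=cfg)
    sid = 0
    type_plan = ["RA"] * cfg.n_ra + ["INT"] * cfg.n_int + ["X"] * cfg.n_x
    ra_ids = list(range(cfg.n_ra))
    int_ids = list(range(cfg.n_ra, cfg.n_ra + cfg.n_int))
    x_ids = list(range(cfg.n_ra + cfg.n_int, len(type_plan)))

    for cell_type in type_plan:
        skel = Skeleton(skeleton_id=sid)
        soma_pos = rng.uniform(np.zeros(3), vol)
        skel.add_node(0, soma_pos, radius=5.0, compartment="soma")
        skel.soma_position = soma_pos.copy()
        _grow_dendrite(skel, 0, cfg, rng)
        if cell_type == "RA":
            _grow_axon(skel, 0, cfg, rng)
        mu, sd = cfg.spine_density_classes[cell_type]
        dens = _truncated_normal(mu, sd, rng)
        _place_spines(skel, dens, rng)
        gt.spine_densities[sid] = dens
        gt.cell_types[sid] = cell_type
        gt.soma_positions[sid] = soma_pos.copy()
        skeletons.append(skel)
        sid += 1

    synapses: list[SynapseRecord] = []
    next_syn = 0
    for skel in skeletons:
        if gt.cell_types[skel.skeleton_id] != "RA":
            gt.cell_labeled[skel.skeleton_id] = False
            continue
        total, labeled = _apply_labeling(skel, cfg, rng)
        gt.cell_labeled[skel.skeleton_id] = skel.labeled
        gt.total_axon_path_um += total
        gt.labeled_axon_path_um += labeled
        recs, next_syn = _place_synapses(
            skel, cfg, rng, next_syn, ra_ids, int_ids, x_ids
        )
        synapses.extend(recs)
    for rec in synapses:
        gt.synapse_types[rec.synapse_id] = rec.postsynaptic_type
        origin = gt.soma_positions[rec.skeleton_id]
        gt.synapse_distances_um[rec.synapse_id] = float(
            np.linalg.norm(rec.position - origin)
        )
    # incoming-synapse bookkeeping on RA cells: homotypic inputs are the
    # RA-targeted outgoing synapses; external excitatory inputs (afferents
    # from outside the modeled population) are count-level draws
    for cid in ra_ids:
        gt.incoming_homotypic[cid] = 0
        gt.external_excitatory[cid] = int(
            rng.poisson(cfg.external_excitatory_per_cell)
        )
    for rec in synapses:
        if rec.postsynaptic_type == "RA" and rec.postsynaptic_skeleton_id is not None:
            gt.incoming_homotypic[rec.postsynaptic_skeleton_id] += 1
    return Circuit(skeletons=skeletons, synapses=synapses, ground_truth=gt)


# ---------------------------------------------------------------- segment simulation


def simulate_branch_segments(
    model: DensityModel,
    n_segments: int = 500,
    r_range_um: tuple[float, float] = (0.0, 300.0),
    l_range_mm: tuple[float, float] = (0.2, 2.0),
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate axon segments with Poisson branch-node counts.

    Each segment sits at a soma distance r drawn uniformly from
    ``r_range_um``, has a length l uniform in ``l_range_mm``, and a
    branch-node count N ~ Poisson(Db(r) * l).  Returns (r, l_mm, N) —
    the raw material for validating the density-model fit.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r = rng.uniform(*r_range_um, size=n_segments)
    l_mm = rng.uniform(*l_range_mm, size=n_segments)
    n = rng.poisson(model(r) * l_mm)
    return r, l_mm, n


# ---------------------------------------------------------------- cropping


def crop_to_subvolume(
    circuit: Circuit, box_min, box_max
) -> tuple[list[Skeleton], list[Skeleton]]:
    """Clip the circuit's skeletons to a box; return (attached, orphans).

    Skeleton pieces are clipped at the box faces; a piece is *attached*
    when it contains its cell's soma node, otherwise it is an *orphaned*
    fragment.  Each orphan's true (path-length-weighted mean Euclidean)
    soma distance is recorded in the circuit's ground truth under the
    fragment's skeleton_id.
    """
    box_min = np.asarray(box_min, float)
    box_max = np.asarray(box_max, float)
    gt = circuit.ground_truth
    attached: list[Skeleton] = []
    orphans: list[Skeleton] = []
    next_id = 10000
    for skel in circuit.skeletons:
        g = skel.graph
        origin = skel.origin()
        clip = Skeleton(
            labeled=skel.labeled, metadata={"parent_skeleton": skel.skeleton_id}
        )
        next_node = 0
        inside_map: dict[int, int] = {}

        def keep_node(orig, pos, comp, labeled_flag):
            nonlocal next_node
            clip.add_node(next_node, pos, compartment=comp)
            clip.graph.nodes[next_node]["labeled"] = labeled_flag
            if orig is not None:
                inside_map[orig] = next_node
            next_node += 1
            return next_node - 1

        def inside(p):
            return bool(np.all(p >= box_min) and np.all(p <= box_max))

        for n in g.nodes:
            p = g.nodes[n]["pos"]
            if inside(p):
                keep_node(
                    n, p.copy(), g.nodes[n]["compartment"], g.nodes[n].get("labeled", False)
                )
        for u, v in g.edges:
            pu, pv = g.nodes[u]["pos"], g.nodes[v]["pos"]
            iu, iv = inside(pu), inside(pv)
            if iu and iv:
                clip.add_edge(inside_map[u], inside_map[v])
            else:  # one or both endpoints outside: keep the clipped piece

                interval = segment_box_interval(pu, pv, box_min, box_max)
                if interval is None:
                    continue
                t0, t1 = interval
                d = pv - pu
                comp = g.nodes[u]["compartment"]
                lab = g.nodes[u].get("labeled", False) and g.nodes[v].get(
                    "labeled", False
                )
                a = inside_map[u] if iu else keep_node(None, pu + t0 * d, comp, lab)
                b = inside_map[v] if iv else keep_node(None, pu + t1 * d, comp, lab)
                if a != b:
                    clip.add_edge(a, b)
        if clip.n_nodes == 0:
            continue
        # split into connected pieces
        import networkx as nx

        soma_new = None
        sn = skel.soma_node()
        if sn is not None and sn in inside_map:
            soma_new = inside_map[sn]
        for comp_nodes in nx.connected_components(clip.graph):
            piece = Skeleton(
                labeled=skel.labeled,
                skeleton_id=next_id,
                metadata={"parent_skeleton": skel.skeleton_id},
            )
            remap = {}
            for i, n in enumerate(sorted(comp_nodes)):
                d = clip.graph.nodes[n]
                piece.add_node(i, d["pos"].copy(), compartment=d["compartment"])
                piece.graph.nodes[i]["labeled"] = d.get("labeled", False)
                remap[n] = i
            for u, v in clip.graph.subgraph(comp_nodes).edges:
                piece.add_edge(remap[u], remap[v])
            if soma_new is not None and soma_new in comp_nodes:
                piece.soma_position = skel.soma_position.copy()
                piece.metadata["attached"] = True
                attached.append(piece)
            else:
                piece.metadata["attached"] = False
                # true soma distance: path-weighted mean over the piece
                p0, p1 = piece.edge_arrays()
                if len(p0):
                    lengths = np.linalg.norm(p1 - p0, axis=1)
                    rmid = 0.5 * (
                        np.linalg.norm(p0 - origin, axis=1)
                        + np.linalg.norm(p1 - origin, axis=1)
                    )
                    r_true = float((lengths * rmid).sum() / lengths.sum())
                else:
                    r_true = float(
                        np.linalg.norm(piece.positions().mean(axis=0) - origin)
                    )
                gt.fragment_distances_um[next_id] = r_true
                orphans.append(piece)
            next_id += 1
    return attached, orphans


# ---------------------------------------------------------------- export


def write_circuit(circuit: Circuit, outdir) -> dict:
    """Write SWC skeletons, a synapse CSV and a ground-truth JSON; returns paths."""
    from .io_formats import write_swc, write_synapse_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"skeletons": []}
    for skel in circuit.skeletons:
        p = outdir / f"cell_{skel.skeleton_id:04d}.swc"
        write_swc(skel, p)
        paths["skeletons"].append(str(p))
    syn_path = outdir / "synapses.csv"
    write_synapse_table(circuit.synapses, syn_path)
    paths["synapses"] = str(syn_path)
    gt_path = outdir / "ground_truth.json"
    gt_path.write_text(circuit.ground_truth.to_json(), encoding="utf-8")
    paths["ground_truth"] = str(gt_path)
    return paths
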