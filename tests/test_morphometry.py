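"""Path lengths, radial profiles, branch-node detection, densities, smoothing."""

import networkx as nx
import numpy as np
import pytest

from hvc_census import morphometry as mm
from hvc_census.errors import ParameterError
from hvc_census.skeleton import Skeleton
from hvc_census.synthetic_data import CircuitConfig, generate_circuit
from tests.conftest import make_path_skeleton


# ------------------------------------------------------------- path length


def test_two_edge_path_length():
    skel = make_path_skeleton([(0, 0, 0), (1, 0, 0), (1.5, np.sqrt(3) / 2, 0)])
    assert mm.path_length(skel) == pytest.approx(2.0)


def test_path_length_matches_brute_force_edge_sum(small_circuit):
    skel = small_circuit.skeletons[0]
    brute = sum(
        np.linalg.norm(skel.graph.nodes[u]["pos"] - skel.graph.nodes[v]["pos"])
        for u, v in skel.graph.edges
    )
    assert mm.path_length(skel) == pytest.approx(brute, rel=1e-12)


def test_compartment_filter_requires_both_endpoints():
    skel = make_path_skeleton([(0, 0, 0), (1, 0, 0), (2, 0, 0)])
    # soma->dendrite edge dropped by a pure-dendrite filter
    assert mm.path_length(skel, "dendrite") == pytest.approx(1.0)
    assert mm.path_length(skel, {"soma", "dendrite"}) == pytest.approx(2.0)


def test_dendrite_path_length_near_configured_total():
    cfg = CircuitConfig(
        volume_um=(400, 400, 400), n_ra=1, n_int=0, n_x=0,
        axon_path_um=0.0, dendrite_path_um=3200.0, seed=5,
    )
    skel = generate_circuit(cfg).skeletons[0]
    total = mm.path_length(skel, {"soma", "dendrite"})
    assert total == pytest.approx(3200.0, rel=0.05)


# ------------------------------------------------------------- radial profile


def test_radial_profile_all_mass_in_first_bin():
    pts = [(0, 0, 0)] + [(0.5 + 0.4 * k / 9, 0, 0) for k in range(10)]
    skel = make_path_skeleton(pts)
    prof = mm.radial_profile(skel, bin_width=10.0)
    assert prof.normalized()[0] == pytest.approx(1.0)


def test_radial_profile_conserves_path_length(small_circuit):
    for skel in small_circuit.skeletons[:3]:
        prof = mm.radial_profile(
            skel, bin_width=10.0, compartment_filter={"soma", "dendrite"}
        )
        total = mm.path_length(skel, {"soma", "dendrite"})
        assert prof.total() == pytest.approx(total, abs=1e-6)


def test_synthetic_dendrite_is_radially_compact():
    cfg = CircuitConfig(
        volume_um=(400, 400, 400), n_ra=2, n_int=0, n_x=0,
        axon_path_um=0.0, dendrite_path_um=3200.0, seed=9,
    )
    for skel in generate_circuit(cfg).skeletons:
        prof = mm.radial_profile(
            skel, bin_width=10.0, compartment_filter={"soma", "dendrite"}
        )
        assert prof.fraction_within(100.0) >= 0.93


def test_radial_profile_invariant_under_rotation(small_circuit):
    skel = small_circuit.skeletons[0]
    prof = mm.radial_profile(skel, bin_width=20.0)
    R = np.array([[0, 0, 1], [1, 0, 0], [0, 1, 0]], float)
    rot = Skeleton(soma_position=R @ skel.soma_position)
    for n in skel.node_ids():
        d = skel.graph.nodes[n]
        rot.add_node(n, R @ d["pos"], compartment=d["compartment"])
    for u, v in skel.graph.edges:
        rot.add_edge(u, v)
    prof_rot = mm.radial_profile(rot, bin_width=20.0)
    np.testing.assert_allclose(prof.values, prof_rot.values, atol=1e-8)


# ------------------------------------------------------------- branch nodes


def _y_skeleton(daughter_lengths, stem=20.0):
    """Stem along +x ending at a junction with two daughters."""
    skel = Skeleton()
    skel.add_node(0, (0, 0, 0), compartment="soma")
    skel.soma_position = np.zeros(3)
    skel.add_node(1, (stem, 0, 0), compartment="axon")
    skel.add_edge(0, 1)
    nid = 2
    for k, L in enumerate(daughter_lengths):
        direction = np.array([np.cos(0.5 + k), np.sin(0.5 + k), 0.0])
        prev = 1
        for step in range(1, int(L) + 1):
            skel.add_node(nid, np.array([stem, 0, 0]) + direction * step,
                          compartment="axon")
            skel.add_edge(prev, nid)
            prev = nid
            nid += 1
    return skel


def test_branch_node_detected_with_long_daughters():
    skel = _y_skeleton([20, 20])
    nodes = mm.detect_branch_nodes(skel, min_daughter_length=15.0)
    assert len(nodes) == 1
    assert nodes[0].node_id == 1


def test_branch_node_excluded_by_short_daughter():
    skel = _y_skeleton([20, 10])
    assert mm.detect_branch_nodes(skel, min_daughter_length=15.0) == []


def test_branch_nodes_match_brute_force_subtree_oracle(small_circuit):
    """Branch detection equals an independent recursive subtree-depth scan."""
    skel = small_circuit.by_type("RA")[0]
    g = skel.graph

    def subtree_depth(node, prev):
        # recursive longest-extension oracle, independent of the implementation
        best = 0.0
        for nb in g.neighbors(node):
            if nb == prev:
                continue
            d = skel.edge_length(node, nb) + subtree_depth(nb, node)
            best = max(best, d)
        return best

    import sys

    sys.setrecursionlimit(100000)
    soma = skel.soma_node()
    expected = set()
    bfs_parent = dict(nx.bfs_predecessors(g, soma))
    for node in g.nodes:
        if g.degree(node) < 3:
            continue
        par = bfs_parent.get(node)
        daughters = [nb for nb in g.neighbors(node) if nb != par]
        if all(
            skel.edge_length(node, d) + subtree_depth(d, node) >= 15.0
            for d in daughters
        ):
            expected.add(node)
    got = {a.node_id for a in mm.detect_branch_nodes(skel, min_daughter_length=15.0)}
    assert got == expected


# ------------------------------------------------------------- densities


def test_linear_density_examples():
    assert mm.linear_density(21, 100.0) == pytest.approx(0.21)
    assert mm.linear_density([], 50.0) == 0.0
    with pytest.raises(ParameterError):
        mm.linear_density(3, 0.0)


def test_branch_node_density_uniform_arbor():
    """A long straight axon with evenly spaced junctions has flat density."""
    skel = Skeleton()
    skel.add_node(0, (0, 0, 0), compartment="soma")
    skel.soma_position = np.zeros(3)
    prev = 0
    nid = 1
    for k in range(1, 2001):  # 2 mm shaft, 1 µm steps
        skel.add_node(nid, (k, 0, 0), compartment="axon")
        skel.add_edge(prev, nid)
        prev = nid
        nid += 1
        if k % 200 == 0 and k < 2000:  # a junction every 200 µm = 5 per mm
            side_prev = prev
            for s in range(1, 21):  # 20 µm daughters
                skel.add_node(nid, (k, s, 0), compartment="axon")
                skel.add_edge(side_prev, nid)
                side_prev = nid
                nid += 1
    prof = mm.branch_node_density_profile([skel], bin_width=500.0)
    dens = prof.density_per_mm[prof.reliable]
    assert np.all(np.abs(dens - 5.0) < 2.0)


def test_branch_density_profile_counts_conserved(small_circuit):
    ra = small_circuit.by_type("RA")
    prof = mm.branch_node_density_profile(ra, bin_width=25.0, min_daughter_length=0.0)
    total_nodes = sum(
        len(mm.detect_branch_nodes(s, min_daughter_length=0.0)) for s in ra
    )
    assert prof.count_profile.total() == pytest.approx(total_nodes)
    total_path = sum(mm.path_length(s, "axon") for s in ra)
    # length profile misses only the soma-adjacent stub edge per cell
    assert prof.length_profile.total() == pytest.approx(total_path, rel=0.01)


def test_generated_branch_density_tracks_the_programmed_model():
    """Measured branch-node density of a generated ensemble follows Db(r)."""
    cfg = CircuitConfig(
        volume_um=(600, 600, 600), n_ra=15, n_int=0, n_x=0,
        axon_path_um=8000.0, dendrite_path_um=0.0, seed=17,
    )
    circuit = generate_circuit(cfg)
    prof = mm.branch_node_density_profile(
        circuit.by_type("RA"), bin_width=25.0, min_daughter_length=0.0
    )
    model = cfg.density_model
    centers = prof.length_profile.bin_centers
    for c, d, L, ok in zip(
        centers, prof.density_per_mm, prof.length_profile.values, prof.reliable
    ):
        if not ok or L < 2000.0 or not np.isfinite(d):
            continue
        expected = model(c)
        n_expected = expected * L / 1000.0
        tol = 4.0 * np.sqrt(max(n_expected, 1.0)) / (L / 1000.0)  # 4 sigma Poisson
        assert abs(d - expected) < tol, (c, d, expected, tol)
    near = prof.density_per_mm[0]
    assert 20.0 < near < 50.0  # near-soma density in the tens per mm


# ------------------------------------------------------------- smoothing


def test_smoothing_straight_line_is_identity_up_to_resampling():
    pts = [(k, 0, 0) for k in range(11)]
    skel = make_path_skeleton(pts, soma_first=False)
    out = mm.smooth_and_resample(skel, window=9, spacing=1.0)
    assert out.n_nodes == pytest.approx(11, abs=1)
    assert mm.path_length(out) == pytest.approx(10.0, rel=0.01)
    assert np.allclose(out.positions()[:, 2], 0.0)


def test_smoothing_flattens_alternating_z_noise():
    pts = [(k, 0, (-1.0) ** k) for k in range(100)]
    skel = make_path_skeleton(pts, soma_first=False)
    out = mm.smooth_and_resample(skel, window=9, spacing=1.0)
    z = out.positions()[:, 2]
    interior = z[1:-1]
    assert np.all(np.abs(interior) <= 1.0 / 9 + 0.35)  # windowed mean of +-1
    assert np.mean(np.abs(interior)) < 0.2


def test_resampling_spacing_and_invalid_parameters():
    pts = [(k, 0, 0) for k in range(0, 11, 2)]  # 10 µm in 2 µm steps
    skel = make_path_skeleton(pts, soma_first=False)
    out = mm.smooth_and_resample(skel, spacing=1.0)
    assert abs(out.n_nodes - 11) <= 1
    with pytest.raises(ParameterError):
        mm.smooth_and_resample(skel, spacing=0.0)
    with pytest.raises(ParameterError):
        mm.smooth_and_resample(skel, window=4)


def test_smoothing_preserves_topology(small_circuit):
    skel = small_circuit.by_type("RA")[0]
    out = mm.smooth_and_resample(skel, spacing=2.0)
    deg_in = sorted(d for _, d in skel.graph.degree if d != 2)
    deg_out = sorted(d for _, d in out.graph.degree if d != 2)
    assert deg_in == deg_out  # tips and branch points preserved
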