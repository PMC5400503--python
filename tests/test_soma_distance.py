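"""Density-model fitting, Poisson likelihood, prior/posterior, NN sampler."""

import numpy as np
import pytest
from scipy import stats

from hvc_census import soma_distance as sd
from hvc_census.errors import ParameterError
from hvc_census.skeleton import Skeleton
from hvc_census.synthetic_data import (
    CircuitConfig,
    generate_circuit,
    simulate_branch_segments,
)

MODEL = sd.DensityModel(35.448, 43.5, 0.613)


# ------------------------------------------------------------- fitting


def test_fit_recovers_noiseless_model():
    r = np.arange(5.0, 400.0, 10.0)
    dens = MODEL(r)
    fit = sd.fit_density_model(r, dens, weights=np.ones_like(r))
    assert fit.amplitude == pytest.approx(MODEL.amplitude, rel=1e-6)
    assert fit.length_constant == pytest.approx(MODEL.length_constant, rel=1e-6)
    assert fit.offset == pytest.approx(MODEL.offset, rel=1e-6)


def test_fit_constant_density_flags_unidentifiable_lambda():
    r = np.arange(5.0, 400.0, 10.0)
    fit = sd.fit_density_model(r, np.full_like(r, 3.0))
    assert fit.amplitude == pytest.approx(0.0, abs=1e-3)
    assert fit.offset == pytest.approx(3.0, abs=1e-3)
    assert not fit.lambda_identifiable


def test_fit_on_poisson_sampled_segments_recovers_amplitude():
    amps = []
    for rep in range(10):
        r, l_mm, n = simulate_branch_segments(MODEL, 500, seed=100 + rep)
        amps.append(sd.fit_density_model_from_segments(r, l_mm, n).amplitude)
    assert abs(np.mean(amps) - MODEL.amplitude) / MODEL.amplitude < 0.20


def test_fit_needs_enough_bins():
    with pytest.raises(Exception):
        sd.fit_density_model(np.array([1.0, 2.0]), np.array([3.0, 2.0]))


# ------------------------------------------------------------- likelihood


def test_poisson_likelihood_closed_form():
    frag = sd.FragmentStats(3, 1.0)
    model = sd.DensityModel(1e-12, 1.0, 4.0)  # Db == 4 everywhere
    p = sd.branch_count_likelihood(frag, 100.0, model)
    assert p == pytest.approx(4**3 * np.exp(-4) / 6, rel=1e-9)


def test_zero_count_short_fragment_likelihood_tends_to_one():
    frag = sd.FragmentStats(0, 1e-9)
    assert sd.branch_count_likelihood(frag, 50.0, MODEL) == pytest.approx(1.0, abs=1e-6)


def test_high_density_fragment_likelihood_peaks_at_origin():
    """A fragment with N/l = Db(0) has its likelihood argmax at r ~ 0."""
    frag = sd.FragmentStats(36, 1.0)
    grid = np.arange(0.0, 700.0, 1.0)
    ll = sd.branch_count_log_likelihood(frag, grid, MODEL)
    assert grid[np.argmax(ll)] == pytest.approx(0.0, abs=2.0)


def test_likelihood_stable_for_large_counts():
    frag = sd.FragmentStats(10_000, 300.0)
    ll = sd.branch_count_log_likelihood(frag, np.array([0.0, 300.0]), MODEL)
    assert np.all(np.isfinite(ll))


def test_negative_fragment_length_rejected():
    with pytest.raises(ParameterError):
        sd.FragmentStats(3, -1.0)


# ------------------------------------------------------------- prior


def _arbor_at_radius(r0: float, n_nodes: int = 200) -> Skeleton:
    """An axon ring at constant soma distance r0 (µm)."""
    skel = Skeleton()
    skel.add_node(0, (0, 0, 0), compartment="soma")
    skel.soma_position = np.zeros(3)
    thetas = np.linspace(0, 2 * np.pi, n_nodes, endpoint=False)
    for i, t in enumerate(thetas, start=1):
        skel.add_node(i, (r0 * np.cos(t), r0 * np.sin(t), 0), compartment="axon")
        if i > 1:
            skel.add_edge(i - 1, i)
    return skel


def test_prior_peaks_at_the_only_radius():
    prior = sd.build_prior([_arbor_at_radius(100.0)])
    assert prior.grid[np.argmax(prior.density)] == pytest.approx(100.0, abs=5.0)
    assert prior.mass().sum() == pytest.approx(1.0, abs=1e-6)


def test_prior_mass_beyond_matches_path_distribution(small_circuit):
    """KDE prior mass beyond a radius tracks the per-unit-path share there."""
    ra = small_circuit.by_type("RA")
    samples = sd.axon_distance_samples(ra)
    raw_frac = float(np.mean(samples > 200.0))
    prior = sd.build_prior(ra)
    assert prior.mass_beyond(200.0) == pytest.approx(raw_frac, abs=0.05)


def test_prior_requires_axon_path():
    with pytest.raises(Exception):
        sd.build_prior([Skeleton()])


# ------------------------------------------------------------- posterior


def test_posterior_normalization_and_support():
    prior = sd.uniform_prior()
    for n, l in [(0, 0.3), (3, 0.5), (40, 1.2), (500, 10.0)]:
        post = sd.posterior_distance(sd.FragmentStats(n, l), MODEL, prior)
        assert post.pmf.sum() == pytest.approx(1.0, abs=1e-9)
        med = post.median()
        assert prior.grid[0] <= med <= prior.grid[-1]


def test_posterior_concentrates_near_soma_for_dense_fragments():
    prior = sd.uniform_prior()
    post = sd.posterior_distance(sd.FragmentStats(40, 1.0), MODEL, prior)
    assert post.quantile(0.9) < 60.0


def test_zero_count_long_fragment_pushes_posterior_outward(small_circuit):
    prior = sd.build_prior(small_circuit.by_type("RA"))
    prior_median = np.interp(0.5, np.cumsum(prior.mass()), prior.grid)
    post = sd.posterior_distance(sd.FragmentStats(0, 3.0), MODEL, prior)
    assert post.median() > prior_median


def test_posterior_median_monotone_in_branch_count():
    prior = sd.uniform_prior()
    medians = [
        sd.posterior_distance(sd.FragmentStats(n, 1.0), MODEL, prior).median()
        for n in range(0, 30, 2)
    ]
    assert all(a >= b - 1e-9 for a, b in zip(medians[:-1], medians[1:]))


def test_quantiles_of_discretized_gaussian():
    grid = np.arange(0.0, 200.0, 0.5)
    pmf = stats.norm.pdf(grid, 100.0, 20.0)
    post = sd.DistancePosterior(grid, pmf / pmf.sum())
    q16, q84 = sd.posterior_quantiles(post, [0.16, 0.84])
    assert q16 == pytest.approx(stats.norm.ppf(0.16, 100, 20), abs=0.5)
    assert q84 == pytest.approx(stats.norm.ppf(0.84, 100, 20), abs=0.5)
    with pytest.raises(ParameterError):
        sd.posterior_quantiles(post, [0.0])


# ------------------------------------------------------------- branch library


def test_grid_placement_count_for_em_shaped_box():
    assert len(sd.grid_placements((166.0, 166.0, 77.0), 10.0)) == 17 * 17 * 8


def test_library_piece_lengths_conserve_total_path():
    """Without the enter-and-leave filter, pieces of one placement tile the arbor."""
    cfg = CircuitConfig(
        volume_um=(200, 200, 200), n_ra=1, n_int=0, n_x=0,
        axon_path_um=1500.0, dendrite_path_um=0.0, seed=21,
    )
    skel = generate_circuit(cfg).skeletons[0]
    from hvc_census.morphometry import path_length

    lib = sd.build_branch_library(
        [skel], box=(1000.0, 1000.0, 1000.0), shift=1000.0,
        require_enter_and_leave=False,
    )
    # one placement, cells of 1 mm tile everything: piece lengths sum to total
    assert lib.length_mm.sum() * 1000.0 == pytest.approx(
        path_length(skel, "axon"), rel=1e-6
    )


def test_fully_contained_arbor_yields_no_entering_and_leaving_pieces():
    skel = _arbor_at_radius(20.0)
    lib_all = sd.build_branch_library(
        [skel], box=(500.0, 500.0, 500.0), shift=500.0,
        require_enter_and_leave=False,
    )
    assert len(lib_all) > 0
    with pytest.raises(Exception):
        sd.build_branch_library(
            [skel], box=(500.0, 500.0, 500.0), shift=500.0,
            require_enter_and_leave=True,
        )


def test_straight_axon_library_oracle():
    """A straight axon cut by a 100 µm grid: pieces and distances by hand."""
    skel = Skeleton()
    skel.add_node(0, (0.0, 50.0, 50.0), compartment="soma")
    skel.soma_position = np.array([0.0, 50.0, 50.0])
    # axon nodes at x = 0.7k so grid planes never pass exactly through a node
    for i in range(1, 431):
        skel.add_node(i, (0.7 * i, 50.0, 50.0), compartment="axon")
        skel.add_edge(i - 1, i)
    lib = sd.build_branch_library(
        [skel], box=(100.0, 100.0, 100.0), shift=100.0,
        require_enter_and_leave=True,
    )
    # the grid splits the line at x = 100.7, 200.7 and 300.7; the two
    # 100 µm interior pieces enter and leave their cells, the end stubs
    # touch one face only and are filtered out
    assert len(lib) == 2
    assert np.all(lib.n_nodes == 0)
    np.testing.assert_allclose(lib.length_mm, [0.1, 0.1], rtol=1e-6)
    np.testing.assert_allclose(sorted(lib.distance_um), [150.7, 250.7], atol=0.5)


def test_nn_sampler_matches_brute_force_scan(small_circuit):
    ra = small_circuit.by_type("RA")[:2]
    lib = sd.build_branch_library(ra, box=(80.0, 80.0, 40.0), shift=40.0)
    assert len(lib) > 10
    frag = sd.FragmentStats(int(np.median(lib.n_nodes)), float(np.median(lib.length_mm)))
    result = sd.nn_distance_sample(frag, lib, length_tol=0.10)
    brute = [
        r
        for n, l, r in zip(lib.n_nodes, lib.length_mm, lib.distance_um)
        if n == frag.n_branch_nodes
        and abs(l - frag.length_mm) <= 0.10 * frag.length_mm
    ]
    assert sorted(result.samples) == pytest.approx(sorted(brute))


def test_nn_sampler_edge_cases():
    lib = sd.BranchSampleLibrary(
        n_nodes=np.array([2]), length_mm=np.array([0.5]), distance_um=np.array([50.0])
    )
    match = sd.nn_distance_sample(sd.FragmentStats(2, 0.52), lib)
    assert match.median() == 50.0
    empty = sd.nn_distance_sample(sd.FragmentStats(99, 0.5), lib)
    assert empty.empty
    with pytest.raises(ParameterError):
        empty.quantile(0.5)
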