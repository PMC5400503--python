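"""Inferring an orphaned axon fragment's distance from its (unseen) soma.

The observable is the fragment's branch-node count N and path length l.
Branch-node density along HVC_RA axons falls off with soma distance r as a
three-parameter exponential, Db(r) = A*exp(-r/lambda) + c (A, c in mm^-1,
lambda and r in µm, l in mm).  Treating branch nodes as independently
placed, N | r is Poisson with mean Db(r)*l, which gives a likelihood over
r.  Combined with a prior Pa(r) — the per-unit-path distribution of axon
soma distances in reference (light-microscopy) arbors, estimated with a
Gaussian KDE — this yields a discrete posterior P(r | N, l) over a 1-µm
grid, with quantile queries for credible intervals.

A second, model-free estimator chops the reference arbors into EM-shaped
subvolumes over a dense grid of placements and records (N, l, r) for every
axon piece that both enters and leaves its subvolume; matching a fragment
by exact N and ±10% length yields an empirical distance distribution.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln

from .errors import FitError, ParameterError, SkeletonStructureError
from .morphometry import BranchNodeDensityProfile, _compartment_predicate
from .skeleton import Skeleton

#: Default evaluation grid (µm): covers HVC's long axis at 1 µm resolution
DEFAULT_GRID = np.arange(0.0, 701.0, 1.0)


# ---------------------------------------------------------------- density model


@dataclass
class DensityModel:
    """Branch-node density vs soma distance: Db(r) = A*exp(-r/lam) + c."""

    amplitude: float  # A, mm^-1
    length_constant: float  # lambda, µm
    offset: float  # c, mm^-1
    stderr: tuple[float, float, float] | None = None
    lambda_identifiable: bool = True

    def __post_init__(self):
        if self.amplitude < 0 or self.offset < 0:
            raise ParameterError("amplitude and offset must be >= 0")
        if self.length_constant <= 0:
            raise ParameterError("length constant must be > 0")

    def __call__(self, r) -> np.ndarray:
        """Density in mm^-1 at soma distance r (µm)."""
        r = np.asarray(r, float)
        return self.amplitude * np.exp(-r / self.length_constant) + self.offset


@dataclass
class FragmentStats:
    """Observables of an axon fragment: branch-node count and path length."""

    n_branch_nodes: int  # N
    length_mm: float  # l

    def __post_init__(self):
        if self.length_mm <= 0:
            raise ParameterError("fragment length must be > 0")
        if self.n_branch_nodes < 0:
            raise ParameterError("branch-node count must be >= 0")


def _exp_model(r, A, lam, c):
    return A * np.exp(-r / lam) + c


def fit_density_model(
    r: np.ndarray,
    density: np.ndarray,
    weights: np.ndarray | None = None,
    lambda_starts: Sequence[float] = (10.0, 50.0, 200.0),
) -> DensityModel:
    """Weighted nonlinear least squares of A*exp(-r/lam)+c to binned densities.

    ``weights`` are the per-bin path lengths (more path, more trust).
    A multi-start over the length constant guards against the fit falling
    into a local minimum; the best-SSE solution wins.  When the amplitude
    collapses to ~0 (constant data) the length constant is unidentifiable
    and flagged as such.
    """
    r = np.asarray(r, float)
    density = np.asarray(density, float)
    ok = np.isfinite(density)
    r, density = r[ok], density[ok]
    if weights is None:
        weights = np.ones_like(r)
    else:
        weights = np.asarray(weights, float)[ok]
    if len(r) < 4:
        raise FitError("need at least 4 informative bins to fit the density model")
    sigma = 1.0 / np.sqrt(np.clip(weights, 1e-12, None))
    amp0 = max(float(density.max() - density.min()), 1e-6)
    c0 = max(float(density.min()), 0.0)
    best = None
    errors = []
    for lam0 in lambda_starts:
        try:
            popt, pcov = optimize.curve_fit(
                _exp_model,
                r,
                density,
                p0=(amp0, lam0, c0),
                sigma=sigma,
                absolute_sigma=False,
                bounds=([0.0, 1e-6, 0.0], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError) as exc:
            errors.append(f"lam0={lam0}: {exc}")
            continue
        resid = (density - _exp_model(r, *popt)) / sigma
        sse = float(resid @ resid)
        if best is None or sse < best[0]:
            best = (sse, popt, pcov)
    if best is None:
        raise FitError(
            "exponential density fit failed from all starts: " + "; ".join(errors)
        )
    _, popt, pcov = best
    stderr = tuple(np.sqrt(np.clip(np.diag(pcov), 0, None)))
    A, lam, c = popt
    identifiable = A > 10 * max(stderr[0], 1e-12) or A > 0.05 * max(c, 1e-12)
    return DensityModel(
        amplitude=float(A),
        length_constant=float(lam),
        offset=float(c),
        stderr=stderr,
        lambda_identifiable=bool(identifiable),
    )


def fit_density_model_from_segments(
    r_um: np.ndarray,
    l_mm: np.ndarray,
    n_nodes: np.ndarray,
    bin_width: float = 10.0,
) -> DensityModel:
    """Bin (r, l, N) segment observations by distance and fit the model.

    Per-bin density = total branch-node count / total path in the bin;
    the fit is weighted by the per-bin path.
    """
    r_um = np.asarray(r_um, float)
    l_mm = np.asarray(l_mm, float)
    n_nodes = np.asarray(n_nodes, float)
    edges = np.arange(0.0, r_um.max() + bin_width, bin_width)
    idx = np.clip(np.searchsorted(edges, r_um, side="right") - 1, 0, len(edges) - 2)
    path = np.bincount(idx, weights=l_mm, minlength=len(edges) - 1)
    counts = np.bincount(idx, weights=n_nodes, minlength=len(edges) - 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mask = path > 0
    density = counts[mask] / path[mask]
    return fit_density_model(centers[mask], density, weights=path[mask])


def fit_density_model_from_profile(profile: BranchNodeDensityProfile) -> DensityModel:
    """Fit the exponential model to a pooled branch-node density profile."""
    mask = profile.reliable & np.isfinite(profile.density_per_mm)
    return fit_density_model(
        profile.length_profile.bin_centers[mask],
        profile.density_per_mm[mask],
        weights=profile.length_profile.values[mask],
    )


# ---------------------------------------------------------------- likelihood


def branch_count_log_likelihood(
    frag: FragmentStats, r, model: DensityModel
) -> np.ndarray:
    """log P(N | r, l): Poisson with mean Db(r)*l, stable for large N."""
    mu = model(r) * frag.length_mm
    mu = np.clip(mu, 1e-300, None)
    n = frag.n_branch_nodes
    return n * np.log(mu) - mu - gammaln(n + 1)


def branch_count_likelihood(frag: FragmentStats, r, model: DensityModel) -> np.ndarray:
    """P(N | r, l) on the natural scale (log-space internally)."""
    return np.exp(branch_count_log_likelihood(frag, r, model))


# ---------------------------------------------------------------- prior


@dataclass
class DistancePrior:
    """Per-unit-path distribution of axon soma distance on a discrete grid."""

    grid: np.ndarray
    density: np.ndarray  # µm^-1, integrates to 1 over the grid

    def __post_init__(self):
        self.grid = np.asarray(self.grid, float)
        self.density = np.asarray(self.density, float)
        if (self.density < 0).any():
            raise ParameterError("prior density must be non-negative")

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def mass(self) -> np.ndarray:
        return self.density * self.step

    def mass_beyond(self, r: float) -> float:
        return float(self.mass()[self.grid > r].sum())


def uniform_prior(grid: np.ndarray = DEFAULT_GRID) -> DistancePrior:
    dens = np.full(len(grid), 1.0 / (len(grid) * (grid[1] - grid[0])))
    return DistancePrior(grid, dens)


def axon_distance_samples(
    arbors: Sequence[Skeleton], spacing: float = 1.0, compartment_filter="axon"
) -> np.ndarray:
    """Soma distances sampled per unit axon path (~``spacing`` µm apart).

    Each edge contributes ceil(len/spacing) evenly spaced sample points, so
    sample weight is proportional to local path length.
    """
    pred = _compartment_predicate(compartment_filter)
    out = []
    for skel in arbors:
        origin = skel.origin()
        p0, p1 = skel.edge_arrays(pred)
        for a, b in zip(p0, p1):
            length = float(np.linalg.norm(b - a))
            k = max(1, int(np.ceil(length / spacing)))
            t = (np.arange(k) + 0.5) / k
            pts = a + t[:, None] * (b - a)
            out.append(np.linalg.norm(pts - origin, axis=1))
    if not out:
        raise SkeletonStructureError("no axon path in the reference arbors")
    return np.concatenate(out)


def build_prior(
    arbors: Sequence[Skeleton],
    grid: np.ndarray = DEFAULT_GRID,
    spacing: float = 1.0,
) -> DistancePrior:
    """Gaussian-KDE prior (Scott bandwidth) over soma distance.

    Mass leaking to r < 0 is reflected back to r >= 0, then the density is
    renormalized on the grid.
    """
    samples = axon_distance_samples(arbors, spacing=spacing)
    kde = stats.gaussian_kde(samples, bw_method="scott")
    grid = np.asarray(grid, float)
    dens = kde(grid) + kde(-grid)  # reflection at r = 0
    step = grid[1] - grid[0]
    total = dens.sum() * step
    if total <= 0:
        raise SkeletonStructureError("prior has zero mass on the grid")
    return DistancePrior(grid, dens / total)


# ---------------------------------------------------------------- posterior


@dataclass
class DistancePosterior:
    """Discrete posterior over soma distance with quantile queries."""

    grid: np.ndarray
    pmf: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid, float)
        self.pmf = np.asarray(self.pmf, float)

    def mean(self) -> float:
        return float(self.grid @ self.pmf)

    def variance(self) -> float:
        m = self.mean()
        return float(((self.grid - m) ** 2) @ self.pmf)

    def quantile(self, q) -> float | np.ndarray:
        return posterior_quantiles(self, np.atleast_1d(q)) if np.ndim(q) else float(
            posterior_quantiles(self, [q])[0]
        )

    def median(self) -> float:
        return float(self.quantile(0.5))


def posterior_distance(
    frag: FragmentStats,
    model: DensityModel,
    prior: DistancePrior,
) -> DistancePosterior:
    """P(r | N, l) ∝ P(N | r, l) * Pa(r), renormalized on the prior's grid."""
    logl = branch_count_log_likelihood(frag, prior.grid, model)
    logl = logl - logl.max()
    unnorm = np.exp(logl) * prior.mass()
    total = unnorm.sum()
    if total <= 0 or not np.isfinite(total):
        raise FloatingPointError(
            "posterior mass underflowed; evaluate in log space with a finer grid"
        )
    return DistancePosterior(prior.grid, unnorm / total)


def posterior_quantiles(post: DistancePosterior, q) -> np.ndarray:
    """Quantiles by linear interpolation of the discrete CDF."""
    q = np.asarray(q, float)
    if ((q <= 0) | (q >= 1)).any():
        raise ParameterError("quantile probabilities must lie in (0, 1)")
    cdf = np.cumsum(post.pmf)
    cdf = cdf / cdf[-1]
    return np.interp(q, cdf, post.grid)


# ---------------------------------------------------------------- NN sampler


@dataclass
class BranchSampleLibrary:
    """(N, l, r) records harvested from reference arbors in EM-shaped boxes."""

    n_nodes: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    length_mm: np.ndarray = field(default_factory=lambda: np.zeros(0))
    distance_um: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __len__(self) -> int:
        return len(self.n_nodes)


@dataclass
class EmpiricalDistanceDistribution:
    """Matched library distances; quantile interface mirrors the posterior."""

    samples: np.ndarray

    def __post_init__(self):
        self.samples = np.asarray(self.samples, float)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def empty(self) -> bool:
        return len(self.samples) == 0

    def mean(self) -> float:
        return float(self.samples.mean())

    def median(self) -> float:
        return float(np.median(self.samples))

    def quantile(self, q) -> np.ndarray:
        if self.empty:
            raise ParameterError("empty match set has no quantiles")
        return np.quantile(self.samples, q)


def grid_placements(
    box: tuple[float, float, float], shift: float = 10.0
) -> list[tuple[float, float, float]]:
    """Offsets of the division grid, shifted in ``shift``-µm increments.

    The grid repeats with period ``box`` along each axis, so the number of
    distinct placements per axis is ceil(box/shift) — e.g. a (166, 166, 77)
    box at 10 µm shifts gives 17 x 17 x 8 divisions.
    """
    counts = [int(np.ceil(b / shift)) for b in box]
    return [
        (i * shift, j * shift, k * shift)
        for i, j, k in itertools.product(*(range(c) for c in counts))
    ]


def _pieces_in_placement(
    skel: Skeleton,
    box: np.ndarray,
    offset: np.ndarray,
    pred,
    origin: np.ndarray,
    bbox_min: np.ndarray,
):
    """Chop one arbor under one grid placement into per-subvolume pieces.

    Returns (N, l_mm, r_um, n_cut_points) per piece.  Pieces are connected
    components of the axon graph clipped to each grid cell; edge crossings
    of cell boundaries become cut points.  N counts nodes that are branch
    points in the original skeleton (degree >= 3).
    """
    g = skel.graph
    grid_origin = bbox_min - box + offset

    def cell_of(p):
        return tuple(np.floor((p - grid_origin) / box).astype(int))

    # union-find over (cell, node-id) with virtual ids for cut points
    parent: dict = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        parent.setdefault(a, a)
        parent.setdefault(b, b)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    # piece accumulators keyed by representative after the pass
    seg_records = []  # (key_a, key_b, length, r_mid) per sub-segment
    cut_counts: dict = {}
    node_is_branch = {n: g.degree(n) >= 3 for n in g.nodes}
    next_virtual = [0]

    def virtual_key(cell):
        next_virtual[0] += 1
        return (cell, f"cut{next_virtual[0]}")

    for u, v in g.edges:
        cu = skel.node_compartment(u)
        cv = skel.node_compartment(v)
        if not (pred(cu) and pred(cv)):
            continue
        pu, pv = g.nodes[u]["pos"], g.nodes[v]["pos"]
        cell_u, cell_v = cell_of(pu), cell_of(pv)
        if cell_u == cell_v:
            key_u, key_v = (cell_u, u), (cell_u, v)
            union(key_u, key_v)
            length = float(np.linalg.norm(pv - pu))
            r_mid = 0.5 * (
                np.linalg.norm(pu - origin) + np.linalg.norm(pv - origin)
            )
            seg_records.append((key_u, length, r_mid))
        else:
            # split the edge at every grid-plane crossing
            d = pv - pu
            ts = [0.0, 1.0]
            for ax in range(3):
                if d[ax] == 0:
                    continue
                lo = min(pu[ax], pv[ax])
                hi = max(pu[ax], pv[ax])
                k0 = int(np.ceil((lo - grid_origin[ax]) / box[ax]))
                k1 = int(np.floor((hi - grid_origin[ax]) / box[ax]))
                for k in range(k0, k1 + 1):
                    plane = grid_origin[ax] + k * box[ax]
                    t = (plane - pu[ax]) / d[ax]
                    if 0.0 < t < 1.0:
                        ts.append(float(t))
            ts = sorted(set(ts))
            for t0, t1 in zip(ts[:-1], ts[1:]):
                mid = pu + 0.5 * (t0 + t1) * d
                cell = cell_of(mid)
                a = pu + t0 * d
                b = pu + t1 * d
                key_a = (cell, u) if t0 == 0.0 else virtual_key(cell)
                key_b = (cell, v) if t1 == 1.0 else virtual_key(cell)
                for key, is_cut in ((key_a, t0 != 0.0), (key_b, t1 != 1.0)):
                    parent.setdefault(key, key)
                    if is_cut:
                        cut_counts[key] = 1
                union(key_a, key_b)
                length = float(np.linalg.norm(b - a))
                r_mid = 0.5 * (
                    np.linalg.norm(a - origin) + np.linalg.norm(b - origin)
                )
                seg_records.append((key_a, length, r_mid))

    # aggregate per connected piece
    agg: dict = {}
    for key, length, r_mid in seg_records:
        rep = find(key)
        rec = agg.setdefault(rep, [0.0, 0.0, 0, 0])  # length, len*r, N, cuts
        rec[0] += length
        rec[1] += length * r_mid
    for key in list(parent):
        rep = find(key)
        if rep not in agg:
            continue
        cell, tag = key
        if isinstance(tag, str):
            agg[rep][3] += cut_counts.get(key, 0)
        elif node_is_branch.get(tag, False):
            agg[rep][2] += 1
    return [
        (rec[2], rec[0] / 1000.0, rec[1] / rec[0] if rec[0] > 0 else 0.0, rec[3])
        for rec in agg.values()
        if rec[0] > 0
    ]


def build_branch_library(
    arbors: Sequence[Skeleton],
    box: tuple[float, float, float] = (166.0, 166.0, 77.0),
    shift: float = 10.0,
    compartment_filter="axon",
    require_enter_and_leave: bool = True,
) -> BranchSampleLibrary:
    """Harvest (N, l, r) from reference arbors chopped into EM-shaped cells.

    For every placement of a ``box``-periodic division grid (shifted in
    ``shift``-µm increments along all three axes) every maximal axon piece
    inside a grid cell is recorded: N = branch-node count, l = path length
    (mm), r = path-length-weighted mean Euclidean soma distance (µm).
    Only pieces that both enter and leave their cell (>= 2 boundary cut
    points) are kept, matching how orphaned fragments present in an EM
    volume.
    """
    box = np.asarray(box, float)
    pred = _compartment_predicate(compartment_filter)
    Ns, ls, rs = [], [], []
    for skel in arbors:
        origin = skel.origin()
        p0, p1 = skel.edge_arrays(pred)
        if len(p0) == 0:
            continue
        bbox_min = np.minimum(p0.min(axis=0), p1.min(axis=0))
        for offset in grid_placements(tuple(box), shift):
            pieces = _pieces_in_placement(
                skel, box, np.asarray(offset, float), pred, origin, bbox_min
            )
            for n, l_mm, r_um, cuts in pieces:
                if require_enter_and_leave and cuts < 2:
                    continue
                if l_mm <= 0:
                    continue
                Ns.append(n)
                ls.append(l_mm)
                rs.append(r_um)
    if not Ns:
        raise SkeletonStructureError("branch library is empty")
    return BranchSampleLibrary(
        n_nodes=np.asarray(Ns, int),
        length_mm=np.asarray(ls, float),
        distance_um=np.asarray(rs, float),
    )


def nn_distance_sample(
    frag: FragmentStats,
    lib: BranchSampleLibrary,
    length_tol: float = 0.10,
) -> EmpiricalDistanceDistribution:
    """Library records with the same N and a length within ±``length_tol``.

    Zero matches yield an explicitly empty distribution; no widening of
    the match predicate is ever applied silently.
    """
    if len(lib) == 0:
        raise ParameterError("library is empty")
    mask = (lib.n_nodes == frag.n_branch_nodes) & (
        np.abs(lib.length_mm - frag.length_mm) <= length_tol * frag.length_mm
    )
    return EmpiricalDistanceDistribution(lib.distance_um[mask])
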