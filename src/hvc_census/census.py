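"""Synapse-census estimators with first-order error propagation.

The central correction is stereological: biotinylated-dextran tracer
labels only a fraction of RA-projecting axons, so raw double-labeled
synapse counts understate homotypic (RA->RA) connectivity.  The labeling
efficiency is estimated by comparing the labeled axonal path density —
measured in randomly placed unit cubes — with the density expected from
the published cell count and the mean per-cell axon path.  Homotypic
synapse fractions are then derived from two independent perspectives
(counting double-labeled synapses on dendrites, and typing the targets of
labeled axons), each with a delta-method standard error that assumes
independent input errors.

Conventions: path densities in µm of path per µm³; linear synapse
densities per mm of axon or per µm of dendrite; volumes in mm³ where the
inputs are whole-nucleus constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._geometry import clip_segments_to_box
from .errors import ParameterError
from .skeleton import Skeleton

#: Upper-bound SEM used for a Poisson count of zero (simple Feldman-style choice)
POISSON_ZERO_UPPER = 1.84


@dataclass
class ValueWithError:
    """A scalar with a standard error (SEM unless noted otherwise)."""

    value: float
    sem: float = 0.0
    kind: str = "sem"  # 'sem' or 'sd', recorded for audit

    def __post_init__(self):
        if self.sem < 0:
            raise ParameterError("standard error must be >= 0")

    @property
    def rel(self) -> float:
        return self.sem / self.value if self.value != 0 else 0.0


def _as_ve(x) -> ValueWithError:
    if isinstance(x, ValueWithError):
        return x
    if isinstance(x, (tuple, list)):
        return ValueWithError(*x)
    return ValueWithError(float(x), 0.0)


@dataclass
class CensusResult:
    """A point estimate with propagated SEM and an audit of its inputs."""

    estimate: float
    sem: float
    inputs: dict = field(default_factory=dict)
    formula: str = ""
    units: str = ""

    def __post_init__(self):
        if self.sem < 0:
            raise ParameterError("sem must be >= 0")

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "sem": self.sem,
            "formula": self.formula,
            "units": self.units,
            "inputs": {
                k: {"value": v.value, "sem": v.sem, "kind": v.kind}
                for k, v in self.inputs.items()
            },
        }


# ---------------------------------------------------------------- propagation


def propagate_error(values: Sequence, operation: str, coefficients=None) -> float:
    """First-order (delta-method) SEM of a combination of independent inputs.

    ``product`` / ``ratio``: relative variances add.  ``linear``: absolute
    variances add with squared coefficients (default all 1).
    """
    ves = [_as_ve(v) for v in values]
    if operation in ("product", "ratio"):
        if operation == "ratio" and any(v.value == 0 for v in ves[1:]):
            raise ParameterError("ratio with zero denominator")
        result = ves[0].value
        for v in ves[1:]:
            result = result * v.value if operation == "product" else result / v.value
        rel_var = sum(v.rel**2 for v in ves)
        return abs(result) * math.sqrt(rel_var)
    if operation == "linear":
        coef = [1.0] * len(ves) if coefficients is None else list(coefficients)
        return math.sqrt(sum((c * v.sem) ** 2 for c, v in zip(coef, ves)))
    raise ParameterError(f"unknown operation {operation!r}")


def poisson_sem(k: int) -> float:
    """SEM of a Poisson count: sqrt(k); an upper bound for k = 0."""
    return math.sqrt(k) if k > 0 else POISSON_ZERO_UPPER


def binomial_sem(p: float, n: int) -> float:
    """SEM of a binomial proportion: sqrt(p (1-p) / n)."""
    if n <= 0:
        raise ParameterError("n must be > 0")
    return math.sqrt(p * (1.0 - p) / n)


# ---------------------------------------------------------------- cube sampling


@dataclass
class CubeSampleSet:
    """Randomly placed sampling cubes and the labeled path each contains."""

    edge_um: float
    origins: np.ndarray
    lengths_um: np.ndarray  # labeled axonal path per cube

    @property
    def n_cubes(self) -> int:
        return len(self.origins)

    def total_length(self) -> float:
        return float(self.lengths_um.sum())

    def density(self) -> ValueWithError:
        """Mean path density (µm per µm³) with its Monte-Carlo SEM."""
        vol = self.edge_um**3
        per_cube = self.lengths_um / vol
        sem = float(per_cube.std(ddof=1) / np.sqrt(self.n_cubes)) if self.n_cubes > 1 else 0.0
        return ValueWithError(float(per_cube.mean()), sem)


def labeled_axon_segments(skeletons: Sequence[Skeleton]) -> tuple[np.ndarray, np.ndarray]:
    """Segment endpoint arrays of labeled axon path across skeletons.

    A segment counts as labeled when both endpoints carry a truthy
    ``labeled`` node attribute, or when the whole skeleton is flagged
    labeled and nodes carry no per-node flag.
    """
    p0s, p1s = [], []
    for skel in skeletons:
        g = skel.graph
        for u, v in g.edges:
            du, dv = g.nodes[u], g.nodes[v]
            if du["compartment"] != "axon" or dv["compartment"] != "axon":
                continue
            lu = du.get("labeled", skel.labeled)
            lv = dv.get("labeled", skel.labeled)
            if lu and lv:
                p0s.append(du["pos"])
                p1s.append(dv["pos"])
    if not p0s:
        return np.zeros((0, 3)), np.zeros((0, 3))
    return np.array(p0s), np.array(p1s)


def sample_cubes(
    skeletons: Sequence[Skeleton],
    volume_min,
    volume_max,
    n: int = 300,
    edge: float = 1.0,
    seed: int | np.random.Generator = 0,
    segments: tuple[np.ndarray, np.ndarray] | None = None,
) -> CubeSampleSet:
    """Place ``n`` cubes uniformly (fully inside the volume) and measure the
    labeled axonal path length inside each, by exact segment–box clipping."""
    volume_min = np.asarray(volume_min, float)
    volume_max = np.asarray(volume_max, float)
    if np.any(volume_max - volume_min <= edge):
        raise ParameterError("cube edge must be smaller than every volume side")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    origins = rng.uniform(volume_min, volume_max - edge, size=(n, 3))
    if segments is None:
        p0, p1 = labeled_axon_segments(skeletons)
    else:
        p0, p1 = segments
    lengths = np.zeros(n)
    if len(p0):
        lo = np.minimum(p0, p1)
        hi = np.maximum(p0, p1)
        for i, o in enumerate(origins):
            near = np.all((hi >= o) & (lo <= o + edge), axis=1)
            if near.any():
                lengths[i] = clip_segments_to_box(
                    p0[near], p1[near], o, o + edge
                ).sum()
    return CubeSampleSet(edge_um=edge, origins=origins, lengths_um=lengths)


# ---------------------------------------------------------------- estimators


def labeling_efficiency(
    observed_density,
    total_path_m,
    ref_volume_mm3,
) -> CensusResult:
    """Labeling efficiency = observed labeled density / expected density.

    ``observed_density`` is µm of labeled axon per µm³ (from cube
    sampling); the expected density is the combined axonal path of all
    cells (metres) divided by the reference volume (mm³).  Note
    1 m / 1 mm³ = 1e6 µm / 1e9 µm³ = 1e-3 µm/µm³.
    """
    obs = _as_ve(observed_density)
    total = _as_ve(total_path_m)
    vol = _as_ve(ref_volume_mm3)
    expected = total.value * 1e-3 / vol.value  # µm / µm³
    if expected <= 0:
        raise ParameterError("expected density must be > 0")
    eff = obs.value / expected
    # obs / (total/vol): relative variances of all three add (delta method)
    sem = abs(eff) * math.sqrt(obs.rel**2 + total.rel**2 + vol.rel**2)
    return CensusResult(
        estimate=eff,
        sem=sem,
        inputs={
            "observed_density_um_per_um3": obs,
            "total_path_m": total,
            "ref_volume_mm3": vol,
            "expected_density_um_per_um3": ValueWithError(expected),
        },
        formula="efficiency = observed_density / (total_path / ref_volume)",
        units="fraction",
    )


def density_deficit_ratio(observed_density, total_path_m, ref_volume_mm3) -> float:
    """How many times smaller the observed labeled density is than expected."""
    eff = labeling_efficiency(observed_density, total_path_m, ref_volume_mm3)
    return 1.0 / eff.estimate


def expected_count_in_volume(n_total, v_sub_um3: float, v_total_mm3) -> CensusResult:
    """Expected number of somata (or any census object) in a subvolume."""
    n = _as_ve(n_total)
    v = _as_ve(v_total_mm3)
    if v.value <= 0 or v_sub_um3 <= 0:
        raise ParameterError("volumes must be > 0")
    est = n.value * (v_sub_um3 * 1e-9) / v.value
    sem = abs(est) * math.sqrt(n.rel**2 + v.rel**2)
    return CensusResult(
        estimate=est,
        sem=sem,
        inputs={
            "n_total": n,
            "v_sub_um3": ValueWithError(v_sub_um3),
            "v_total_mm3": v,
        },
        formula="n_total * v_sub / v_total",
        units="count",
    )


def per_cell_synapse_count(linear_density, path) -> CensusResult:
    """Expected synapses per cell: linear density × path length.

    Units must agree (per-mm density with mm path, or per-µm with µm).
    The propagated error is an SEM if both inputs carry SEMs, an SD if
    they carry SDs — the kind is recorded from the inputs.
    """
    d = _as_ve(linear_density)
    p = _as_ve(path)
    est = d.value * p.value
    sem = abs(est) * math.sqrt(d.rel**2 + p.rel**2)
    kind = "sd" if "sd" in (d.kind, p.kind) else "sem"
    return CensusResult(
        estimate=est,
        sem=sem,
        inputs={"linear_density": d, "path": p},
        formula="density * path",
        units="count",
    )


def homotypic_fraction_dendritic(
    n_double: int,
    total_excitatory,
    efficiency,
) -> CensusResult:
    """Homotypic share of excitatory inputs, from the dendritic perspective.

    fraction = (n_double / total_excitatory) / efficiency, where
    ``n_double`` is the number of double-labeled (labeled axon onto
    labeled dendrite) synapses, ``total_excitatory`` the excitatory
    synapse count over the same dendrites, and ``efficiency`` the axonal
    labeling probability.  The SEM combines Poisson variance of the
    double count with the inputs' errors.
    """
    total = _as_ve(total_excitatory)
    eff = _as_ve(efficiency)
    if eff.value <= 0 or eff.value > 1:
        raise ParameterError("efficiency must lie in (0, 1]")
    if total.value <= 0:
        raise ParameterError("total excitatory count must be > 0")
    frac = (n_double / total.value) / eff.value
    rel_double = (poisson_sem(n_double) / n_double) if n_double > 0 else 0.0
    sem = abs(frac) * math.sqrt(rel_double**2 + total.rel**2 + eff.rel**2)
    if n_double == 0:
        # report the Poisson-derived upper SEM on the zero estimate
        sem = (POISSON_ZERO_UPPER / total.value) / eff.value
    return CensusResult(
        estimate=frac,
        sem=sem,
        inputs={
            "n_double": ValueWithError(n_double, poisson_sem(n_double)),
            "total_excitatory": total,
            "efficiency": eff,
        },
        formula="(n_double / total_excitatory) / efficiency",
        units="fraction",
    )


@dataclass
class TargetTally:
    """Postsynaptic-type counts for a set of typed synapses."""

    INT: int = 0
    RA: int = 0
    X: int = 0
    context: str = ""

    def __post_init__(self):
        if min(self.INT, self.RA, self.X) < 0:
            raise ParameterError("tally counts must be >= 0")

    @property
    def total(self) -> int:
        return self.INT + self.RA + self.X

    def share(self, cell_type: str) -> float:
        if self.total == 0:
            raise ParameterError("empty tally has no shares")
        return getattr(self, cell_type) / self.total

    def excitatory_share(self) -> float:
        return (self.RA + self.X) / self.total


def homotypic_fraction_axonal(
    outgoing_per_cell,
    tally: TargetTally,
    incoming_excitatory_per_cell,
) -> tuple[CensusResult, CensusResult]:
    """Homotypic synapses per cell, and their share of incoming excitatory
    synapses, from the axonal (presynaptic) perspective.

    Per-cell homotypic = outgoing_per_cell × (RA share of the target
    tally); by symmetry, incoming and outgoing homotypic synapses per cell
    are equal on average.  The tally share carries binomial variance.
    """
    out = _as_ve(outgoing_per_cell)
    inc = _as_ve(incoming_excitatory_per_cell)
    if tally.total <= 0:
        raise ParameterError("tally must contain at least one synapse")
    p_ra = tally.share("RA")
    share = ValueWithError(p_ra, binomial_sem(p_ra, tally.total))
    homo = out.value * p_ra
    homo_sem = (
        abs(homo) * math.sqrt(out.rel**2 + share.rel**2) if p_ra > 0 else 0.0
    )
    per_cell = CensusResult(
        estimate=homo,
        sem=homo_sem,
        inputs={"outgoing_per_cell": out, "ra_share": share},
        formula="outgoing_per_cell * tally.RA / tally.total",
        units="count",
    )
    if inc.value <= 0:
        raise ParameterError("incoming excitatory count must be > 0")
    frac = homo / inc.value
    frac_sem = (
        abs(frac) * math.sqrt(out.rel**2 + share.rel**2 + inc.rel**2)
        if p_ra > 0
        else 0.0
    )
    fraction = CensusResult(
        estimate=frac,
        sem=frac_sem,
        inputs={
            "homotypic_per_cell": ValueWithError(homo, homo_sem),
            "incoming_excitatory_per_cell": inc,
        },
        formula="homotypic_per_cell / incoming_excitatory_per_cell",
        units="fraction",
    )
    return per_cell, fraction


# ---------------------------------------------------------------- distance-resolved


@dataclass
class SegmentObservation:
    """One axon segment: a distance estimate, a target tally, a path length."""

    distance_um: float
    distance_q16: float
    distance_q84: float
    tally: TargetTally
    length_mm: float
    summed_az_area_um2: float | None = None


def distance_resolved_fractions(
    segments: Sequence[SegmentObservation],
) -> tuple[pd.DataFrame, dict]:
    """Per-segment inhibitory fraction and per-type synapse densities vs
    estimated soma distance, with their stated error models.

    Inhibitory fraction p carries a binomial SEM sqrt(p(1-p)/n); a count k
    over path l carries a Poisson SEM sqrt(k)/l.  Horizontal uncertainty
    is the 0.16–0.84 interval of the segment's distance estimate.
    Segments with zero synapses are excluded with a warning entry in the
    returned diagnostics.  Pearson correlations of the fraction and the
    excitatory densities against distance are reported alongside.
    """
    rows = []
    skipped = 0
    for seg in segments:
        n = seg.tally.total
        if n == 0:
            skipped += 1
            continue
        p_inh = seg.tally.INT / n
        row = {
            "distance_um": seg.distance_um,
            "distance_q16": seg.distance_q16,
            "distance_q84": seg.distance_q84,
            "n_synapses": n,
            "length_mm": seg.length_mm,
            "inhibitory_fraction": p_inh,
            "inhibitory_fraction_sem": binomial_sem(p_inh, n),
        }
        for t in ("INT", "RA", "X"):
            k = getattr(seg.tally, t)
            row[f"density_{t}_per_mm"] = k / seg.length_mm
            row[f"density_{t}_sem"] = poisson_sem(k) / seg.length_mm if k > 0 else (
                POISSON_ZERO_UPPER / seg.length_mm
            )
        if seg.summed_az_area_um2 is not None:
            row["az_area_per_mm"] = seg.summed_az_area_um2 / seg.length_mm
        rows.append(row)
    df = pd.DataFrame(rows).sort_values("distance_um").reset_index(drop=True)
    diag = {"n_segments": len(df), "n_skipped_zero_synapse": skipped}
    if len(df) >= 3:
        r, p = stats.pearsonr(df["distance_um"], df["inhibitory_fraction"])
        diag["pearson_inhibitory_fraction"] = {"r": float(r), "p": float(p)}
        exc = df["density_RA_per_mm"] + df["density_X_per_mm"]
        r2, p2 = stats.pearsonr(df["distance_um"], exc)
        diag["pearson_excitatory_density"] = {"r": float(r2), "p": float(p2)}
    return df, diag
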