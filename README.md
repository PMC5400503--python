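# hvc-census

Quantitative connectomic census tools for the songbird premotor nucleus
HVC: skeleton morphometry of light- and electron-microscopy neuron
reconstructions, inference of an orphaned axon fragment's distance from
its (unseen) soma, spine-density cell typing, stereological
labeling-efficiency correction, and error-propagated estimates of
homotypic (RA→RA) synapse fractions — together with a seeded synthetic
circuit generator so that every stage is testable against known ground
truth.

## Who this is for

Connectomics groups analyzing sparse tracer-labeled reconstructions: the
situation where an EM volume is far smaller than the neurons it samples,
tracer labeling is incomplete, and axon fragments cannot be traced back
to their somata. The package turns those partial observations into
corrected, error-bounded population estimates.

## The models at the core

**Soma-distance inference.** Branch-node density along HVC_RA axons falls
with Euclidean soma distance *r* as a three-parameter exponential

    Db(r) = A·exp(−r/λ) + c,     A = 35.448 mm⁻¹, λ = 43.5 µm, c = 0.613 mm⁻¹

Treating branch nodes as independently placed, a fragment of length *l*
(mm) with *N* branch nodes has a Poisson likelihood

    P(N | r, l) = (Db(r)·l)^N · exp(−Db(r)·l) / N!

which, multiplied by a Gaussian-KDE prior Pa(r) over the per-unit-path
distribution of axon soma distances in reference arbors, yields a
discrete posterior P(r | N, l) with quantile queries (0.16/0.84 credible
intervals). A model-free alternative chops reference arbors into
EM-shaped subvolumes over a 10 µm-shifted grid of placements and matches
fragments by exact *N* and ±10% length.

**Cell typing.** Dendritic spine density D (µm⁻¹) separates the three
HVC cell classes: interneuron (D < 0.11), RA-projecting (0.11–0.46),
X-projecting (> 0.46); reconstructions of the same cell are merged first
by skeleton overlap (≥25% of nodes within 400 nm of the other skeleton's
edges).

**Census.** Labeling efficiency = (labeled axon density from randomly
placed unit cubes) / (total axon path of all cells / nucleus volume).
Homotypic synapse fractions come from two independent perspectives —
double-labeled synapse counts corrected by the efficiency, and target-type
tallies of labeled axons — with first-order (delta-method) standard
errors throughout.

## Worked example

The headline census chain from its whole-nucleus inputs (38.6 µm of
labeled axon across 300 sampling cubes of 1 µm³; 40,000 cells × 14.7 mm
axon; 0.35 mm³ nucleus volume):

```sh
$ hvc-census efficiency --observed-total-um 38.6
{
  "estimate": 0.0766,          # labeling efficiency ~7.7%
  "sem": 0.0090,
  "deficit_ratio": 13.06,      # labeled density ~13x below expectation
  ...
}

$ hvc-census homotypic
{
  "dendritic_perspective":  { "estimate": 0.152, "sem": 0.039, ... },
  "axonal_perspective": {
    "homotypic_per_cell":   { "estimate": 190.0, ... },
    "fraction_of_incoming_excitatory": { "estimate": 0.242, ... }
  }
}
```

Reading: only ~1% of excitatory synapses onto the inspected dendrites
were visibly double-labeled, but after correcting for the ~7.6% axon
labeling probability the homotypic share is ~15% (dendritic view) to
~24% (axonal view, ~190 homotypic synapses per cell) of each cell's
incoming excitatory synapses.

Distance inference for a densely branched orphan fragment (11 branch
nodes on 1.0 mm of path) under the default density model and a uniform
prior:

```sh
$ hvc-census distance -n 11 -l 1.0
{
  "median_um": 54.6,
  "q16_um": 41.3,
  "q84_um": 69.6,
  "mean_um": 56.0
}
```

High local branch density places the fragment within tens of µm of its
soma. An end-to-end synthetic run (`hvc-census run-all --seed 0 --out
out/`) generates a circuit, refits the density model from its arbors,
and writes a summary plus a manifest that makes the run bit-for-bit
reproducible.

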