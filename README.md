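# neurofish

Compartment-aware quantification of single-molecule FISH (smFISH) mRNA
localization in neurons.

Neurons localize mRNAs across morphologically extreme compartments — a
dense soma and dendrites that run hundreds of µm — so generic cell-level
spatial statistics (distance to cell centroid, global clustering scores)
say little about them. `neurofish` works from the neuron's own geometry:

1. **Segmentation (Part 1).** Manual annotations of a 2D projection are
   normalized into disjoint binary *prints* (nucleus ⊆ soma; dendrites
   disjoint from the soma and each other), and each dendrite print is
   thinned to a 1-px *skeleton* carrying the exact shortest-path
   (geodesic) distance from the soma, in nm, at every pixel.
2. **Statistics (Part 2).** Spot tables from an upstream detector
   (FISH-Quant-style, nm coordinates) are assigned to compartments and
   scored with four statistics:
   * per-compartment counts and **densities** (mRNAs per pixel of print),
     with log2 fold changes between species or compartments;
   * the **dendritic distance profile**: spots histogrammed by geodesic
     distance from the soma in fixed 25-µm bins (0–25 … >150 µm);
   * **colocalization**: each molecule's nearest-neighbor distance
     (binned to 4500 nm in 500-nm steps) against a 25-simulation
     random-placement null, compared by a two-sample Kolmogorov–Smirnov
     test;
   * **synapse occupancy**: the percentage of PSD95-marked spines with
     ≥ k mRNAs (k = 1..5) within a 500-nm radius, against a
     50-simulation null, with z-scores.

Both Monte-Carlo statistics share one null model: the observed number of
dendritic molecules re-placed uniformly at random on the dendrite prints
(per-dendrite counts preserved), with sub-pixel resolution and full seed
provenance. A synthetic-data module generates complete fields — masks,
skeleton truth, synapses, and spots with known somatic fraction,
exponential dendritic decay, synapse enrichment and paired placement — so
every statistic is testable against ground truth without any imaging
data. See `docs/methods.md` for the model details and numerical choices.

## Worked example

```python
import neurofish as nf
from neurofish.synthetic import SyntheticTruth

# a synthetic field: soma + 5 dendrites, 400 spots (70% somatic,
# dendritic density decaying with L = 30 um), 25 synapses
fov = nf.generate_synthetic_fov(
    n_spots=400, n_synapses=25, truth=SyntheticTruth(seed=20220520)
)

prints = nf.build_prints(fov.raw_masks, closing_radius_px=1)
skeletons = nf.skeletons_for(prints, fov.geometry)
assignment = nf.assign_spots(fov.spots, prints, skeletons, fov.geometry)
print(nf.compartment_counts(assignment))

null = nf.simulate_matched_null(assignment, prints, fov.geometry, n_sims=50, seed=12)
dend = assignment[assignment.compartment == "dendrite"]
xy = fov.spots.set_index("spot_id").loc[dend.spot_id]
occ = nf.spine_occupancy(xy, fov.synapses, null)
print(occ.table[["k", "observed_pct", "null_mean_pct", "z_score"]].head(2))
```

prints:

```
{'nucleus': 75, 'soma': 205, 'dendrite': 120, 'unassigned': 0}
   k  observed_pct  null_mean_pct   z_score
0  1          52.0           38.0  1.506445
1  2           0.0           7.36 -1.246789
```

400 spots partition exactly over the compartments (none lost). 52% of the
25 synapses hold ≥ 1 mRNA versus 38% expected under random placement —
1.5 null SDs, i.e. no significant synaptic enrichment in this field,
which is correct: the generator placed no enrichment.

The same workflow runs from the shell:

```bash
neurofish simulate-fov --outdir fov --seed 20220520 --n-spots 400 --n-synapses 25
neurofish all --masks fov/masks.tif --spots fov/spots.csv \
    --synapses fov/synapses.csv --outdir out --seed 11
```

writing `density.csv`, `distance_profile_{pooled,per_dendrite}.csv`,
`coloc_bins.csv` + `coloc_summary.json`, `occupancy.csv`,
`skeleton_distances.csv`, `assignment.csv` and the resolved run
configuration. Re-running with the same seeds reproduces every file
bit-for-bit.

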