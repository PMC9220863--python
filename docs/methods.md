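# Methods

`neurofish` quantifies where single mRNA molecules sit inside cultured
neurons imaged by single-molecule FISH (smFISH). The inputs are (i) manual
annotations of a maximum-intensity projection — binary masks ("prints") of
the nucleus, the soma, and each dendrite — and (ii) tables of
diffraction-limited spot coordinates in nm from an upstream spot detector
(e.g. a FISH-Quant-style export), optionally with PSD95-derived synapse
centroids. All analysis is 2D: z coordinates are preserved on load but
never enter a distance computation, because the segmentation operates on
2D projections.

## Coordinate convention

One convention is used everywhere: the origin is the top-left corner of
pixel (0, 0); x grows with column index and y with row index;
`nm = index · pixel_size`; a physical point belongs to pixel
`floor(coord / pixel_size)`, so a point exactly on a boundary belongs to
the higher-index pixel. The default lateral pixel pitch is 107.5 nm and
the default z-step 200 nm, matching the widefield acquisition geometry
the defaults emulate.

## Print normalization

Hand-drawn masks carry pinholes, ragged borders and overlaps. Each mask is
hole-filled and morphologically closed (default radius 2 px — bridges
1–2 px annotation gaps). The nucleus is clipped to the soma; soma pixels
are removed from every dendrite, so dendritic distances start at the soma
edge; contested pixels between two dendrite annotations go to the lower
dendrite id; the largest connected component is kept per print. Every
repair is logged. A dendrite print that vanishes under normalization is
dropped with a log line, never a crash. Excluding the soma-overlap region
from dendrite prints is a choice (the alternative — keeping it — would
shift all dendritic distances by roughly the overlap length); it is
surfaced in the normalization log.

## Skeletons and geodesic distance

A dendrite's midline is the morphological thinning (scikit-image
`skeletonize`) of its print. Side twigs shorter than `prune_px` (default
5 px) that hang off a branch point are removed — they are thinning
artifacts of ragged annotation borders, not branches. The *anchor* is the
skeleton pixel with minimal Euclidean distance to the soma print (ties:
smallest (row, col)). Geodesic distance is the exact shortest path on the
8-connected skeleton graph with axial edges costing one pixel pitch and
diagonal edges √2 pitches, computed with Dijkstra's algorithm
(`scipy.sparse.csgraph`); an independent `networkx` Dijkstra serves as the
oracle in the tests.

Two numerical properties of this construction are worth knowing:

* **Endpoint orientation sensitivity.** Thinning may keep or drop one
  terminal pixel depending on the print's orientation, so a 90° rotation
  can change the skeleton by one end pixel; all shared pixels keep
  identical distances. Distances are exactly translation-invariant.
* **Octagonal metric stretch.** The 8-connected path length overestimates
  the true curve length of an arbitrarily oriented midline by up to ~8%
  (zero at multiples of 45°). On random-walk synthetic dendrites this
  appears as a ~4–6% upward stretch of recovered distances. It is a
  property of the chosen metric, shared by any pixel-graph distance
  without sub-pixel smoothing.

## Spot assignment

A spot belongs to the compartment owning its pixel with precedence
nucleus > soma > dendrite > unassigned. A dendritic spot inherits the
geodesic distance of the Euclidean-nearest skeleton pixel of its own
dendrite (ties: the smaller geodesic value); the spot→skeleton offset is
reported so thick prints and branch regions can be audited, and spots
farther than 20 px (configurable) from the skeleton warn but are still
assigned. Counts partition exactly: nucleus + soma + dendrite +
unassigned = total, on every input.

Mature and nascent molecules are separated: transcription-site records
(flagged in the input, with a nascent count quantified upstream) are
excluded from all mature-mRNA statistics and summed per nucleus
separately. "Per-soma" totals pool cytoplasmic somatic spots with nuclear
single molecules by default (`nuclear_singles_in_soma=False` turns this
off), over the full soma print area.

## The four statistics

**Density.** Counts and counts-per-pixel (and per nm²) per compartment
and species, dendrites individually and pooled. Fold changes between
species or compartments are reported as log2 ratios; a zero density
yields an explicit undefined marker rather than ±inf or a pseudocount —
any imputation would silently bias compartments with few molecules.

**Dendritic distance profile.** Dendritic spots are histogrammed by
geodesic distance in fixed 25-µm bins (0–25 … 125–150, >150 µm),
half-open and lower-closed (a spot at exactly 25 µm goes to 25–50).
Profiles are emitted both pooled over dendrites and per dendrite, since
either normalization is defensible. Bins beyond a dendrite's skeleton
length are reported with count 0 and flagged unreachable, so absent mRNA
is never confused with absent dendrite.

The helper `estimate_decay_length_um` fits `log(count)` against bin
centers (equal-width bins make this exactly linear for an exponential
profile with slope −1/L) and uses only bins whose upper edge lies within
the reach of the *shortest* dendrite: a bin covered by only some
dendrites has a depressed count that would bias the decay steep. On
synthetic fields this estimator carries the octagonal-metric stretch
(~+5%) described above.

**Random-placement null.** Both Monte-Carlo statistics compare against
the same null: the observed number of dendritic molecules re-placed
uniformly at random on the dendrite prints. A point is drawn by choosing
a domain pixel uniformly, then a uniform sub-pixel offset — the 500-nm
scales probed are under 5 px, so sub-pixel resolution matters. By default
each simulation preserves the observed per-dendrite counts, which removes
dendrite-size confounding (`per_dendrite=False` re-places the global
total over the pooled prints). Somatic spots are never randomized. The
ensemble is fully determined by its seed, which is recorded in every
downstream report.

**Synapse occupancy.** A molecule localizes to a spine when it lies
within 500 nm (closed disk; Euclidean, not geodesic — spine necks leave
the shaft where the skeleton metric is undefined) of a PSD95 centroid.
The statistic is the percentage of synapses with ≥ k molecules, k = 1..5,
against a 50-simulation null: per-simulation percentages give the null
mean and SD, and z = (observed − mean)/SD (NaN when the SD is 0).
Synapse centroids farther than 500 nm from every dendrite print are
flagged. With ~20 synapses per field the per-field percentage carries
binomial noise of ~10 points, so enrichment analyses should pool
occupancy over fields — single-field z-scores at a biologically plausible
3-fold enrichment sit near 3 and fluctuate by ±1 between fields, while
percentages pooled over ten such fields exceed the pooled null by ~8–9
null SDs.

**Colocalization.** For each dendritic molecule, the 2D distance to the
closest other molecule of the same species (or of the other species in
cross mode), histogrammed to 4500 nm in 500-nm bins with an overflow bin
(counted in the denominator, usually omitted from plots; a cumulative
variant is emitted alongside). The observed distribution is compared to
the pooled nearest-neighbor distances of a 25-simulation null with a
two-sample Kolmogorov–Smirnov test on the raw (unbinned) distances.

One correction is applied before the KS test: in self mode, every
*mutually*-nearest pair contributes its distance twice — two identical,
perfectly dependent sample values. The KS p-value assumes independent
observations, and with ~60% of molecules in mutual pairs the test
rejects structureless data far above its nominal rate (15–20% at
α = 0.05 in engine-vs-engine runs). The KS is therefore computed on
*unique-pair* samples (each mutual pair counted once, for observed and
simulated fields alike), which restores the nominal rate (measured
2.5–3% at α = 0.05) while leaving genuine clustering — e.g. molecules
laid down as 200-nm pairs — detected at overwhelming significance. The
plotted per-bin fractions keep the per-molecule convention.

## Synthetic data

The generator builds a complete field with known truth: a soma disk with
a concentric nucleus; dendrites as non-self-intersecting random-walk
ribbons (2-px steps, heading jitter σ = 0.06 rad per step, heading
clamped to ±75° of the radial direction) of configurable width (default
7 px ≈ 750 nm) leaving the soma in evenly spread directions; synapse
centroids on ribbon borders. Spots honor a somatic fraction (default
0.7 — somatic localization dominates in these neurons); dendritic spots
are placed along the midlines with density ∝ exp(−d/L) (default
L = 30 µm, matching the strongly proximal profiles seen in culture), or
uniformly over the prints when `L = None`, in which case the pattern is
statistically identical to the null engine by construction. Optional
structure: a synapse-enrichment multiple (the fraction of dendritic
molecules within 500 nm of a synapse is E times the uniform expectation)
and duplicated molecule pairs at a fixed separation (colocalization
truth). Every spot records its true compartment, dendrite, geodesic
distance, synapse association and pair id.

What the generator does *not* emulate: detection noise and false
positives of the spot detector, annotation error in the masks (prints are
exact), spine morphology, axons, 3D structure, and optical blur. Passing
tests therefore certify the statistics pipeline downstream of detection
and annotation, not those upstream steps.

Default fixture size is 512×512 px (≈55×55 µm); the decay-recovery
analysis uses 1792×1792 px with ≥78-µm dendrites so that three full
25-µm bins are reachable on every dendrite, at n = 5000 spots, where the
fitted L lands within ~8% of truth across seeds (15% is the acceptance
bound). Full-pipeline compartment recovery on the default fixture is
≥ 99.9%.

## Determinism

All randomness flows through `numpy.random.default_rng` seeds carried in
function arguments and recorded in reports; identical seeds give
bit-identical outputs, which the golden-report test enforces end to end
through the CLI.
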