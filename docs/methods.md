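# Methods

This document records the models, parameters, and numerical choices
behind each module, and the realism and limits of the synthetic-data
generator.

## Image geometry

Stacks are anisotropic 3D arrays `(z, y, x)` with 0.3 µm z-spacing and
0.108 µm in-plane pixels, the geometry of a typical confocal foci
acquisition; 5 or 7 z-slices are the expected depths (other depths
work but trigger a warning). All distance computations use the voxel
anisotropy factor `z_weight = 0.3 / 0.108 ≈ 2.78`.

## Foci quantification

The per-cell pipeline runs in fixed order:

1. **Background subtraction.** Either a constant or the mean over a
   cell-free mask is subtracted from each channel; values are floored
   at zero and the estimate recorded in the stack provenance.
2. **ROI restriction.** Analysis is confined to a per-cell ROI
   (manual outline in practice, exact cell mask for synthetic data).
3. **Nucleus segmentation.** Otsu threshold on the DAPI channel inside
   the ROI, hole filling, then the largest 26-connected component.
4. **Foci thresholding with frozen parameters.** The threshold is the
   mean + k·SD (k = 3) of the background-subtracted foci channel over
   the untreated (NT) fields of the *same experiment*. The resulting
   `FociParams` carry an `experiment_id`; applying them to another
   experiment raises `ExperimentMismatchError` unless reuse is
   explicitly allowed. Freezing per experiment prevents per-image
   threshold tuning from leaking treatment effects into the counts.
5. **Component labeling.** `scipy.ndimage.label` with a structuring
   element from `generate_binary_structure`; 6, 18 and 26-connectivity
   are supported, 26 is the default (a diagonal touch in 3D is a
   touch). Labeling is verified in the test suite against a
   brute-force flood-fill oracle with explicit neighbour offsets.
6. **Classification and size filters.** A component overlapping the
   nucleus mask by at least one voxel is nuclear, otherwise
   cytoplasmic. Nuclear foci must span 3–100 voxels; nuclear objects
   above 100 voxels are relabeled *nucleolar* (nucleoli bind the G4
   probe strongly but are not foci) and excluded from counts;
   cytoplasmic foci must span 20–100 voxels. In γH2AX mode only the
   nucleus is analysed and the minimum size drops to 2 voxels
   (configurable), reflecting the smaller puncta of that marker.
7. **Outlier flagging.** Cells are flagged (not silently dropped) when
   their DAPI volume or intensity deviates by more than 3 robust z
   units (median/MAD) from the condition, when DAPI is missing or
   strongly lowered, or — in TASQ mode — when no nucleolus is found
   (a staining failure indicator). Flagged cells are excluded from
   summaries; the flags remain in the per-cell table.
8. **Summaries.** Mean foci per cell are first averaged within each
   experiment, then across experiments (mean ± SD), so experiments are
   the unit of replication. Fold change and delta are taken versus the
   NT condition; a zero NT mean leaves the fold undefined with a
   warning rather than producing an infinity.

## Synthetic cell generator

The generator's contract is *exact* ground truth: every planted object
occupies a literal, recorded voxel set, so recovery can be asserted
voxel-for-voxel, not just statistically.

- **Cell and nucleus.** The cell ROI is a 2D ellipse broadcast over z;
  the nucleus is a 3D ellipsoid (semi-axes 0.52·nz, 0.30·ny, 0.30·nx).
  Placement cores are eroded once so objects sit strictly inside their
  compartment; the cytoplasmic core additionally excludes a twice-
  dilated nucleus so cytoplasmic objects cannot touch the nucleus.
- **Blob construction.** An n-voxel blob centred at c is the set of
  the n grid voxels nearest c under the anisotropic metric, with ties
  broken toward the central z-plane and then lexicographically. This
  is the discrete analogue of thresholding a point-spread blob at
  whatever level yields the target volume: it is connected under
  26-connectivity, roughly ellipsoidal, and has an exactly known voxel
  count — which a sampled-and-thresholded Gaussian spot would not.
- **Placement.** Objects are placed largest-first (large objects need
  the scarcest space) at candidate centres drawn without replacement
  from the admissible core; in separable mode (default) each placed
  object also blocks its 26-neighbourhood, so no two objects touch and
  planted counts equal component counts by construction. Placement
  fails only when every admissible centre has been exhausted — a
  genuine geometric infeasibility, reported as `PlacementError`.
  Nucleoli (110–220 voxels, 2–4 per cell) and nuclear foci compete for
  the same compartment and are therefore placed in a single joint
  pass.
- **Intensity model.** The foci channel is Gaussian camera noise
  (mean 40, SD 3) plus diffuse cytoplasmic (15) and nuclear (25)
  staining; each planted object adds an amplitude profile decreasing
  from its centre (foci: 200·(0.6 + 0.4·(1 − d/dmax)); nucleoli:
  150·(0.85 + 0.15·(1 − d/dmax))), keeping even edge voxels far above
  the detection threshold. The DAPI channel is a bright nuclear
  ellipsoid (1000) over dim cytoplasm (100) and background (10) with
  SD-20 noise.
- **Realism and limits.** The generator reproduces the features the
  pipeline must be robust to — anisotropy, nucleoli as bright
  non-focus objects, diffuse compartment staining, camera noise — but
  deliberately omits others: no point-spread blur across object
  borders, no intensity gradients with depth, no touching or
  overlapping cells, no mitotic figures. Consequently recovery on
  synthetic data is a necessary correctness check, not a claim about
  segmentation difficulty on real images. In separable mode the
  planted count is exactly recoverable; with `separable=False` objects
  may merge and only then does the counts-versus-truth comparison
  become statistical.
- **Capacity.** Separable placement needs room: the default 5-slice
  96×96 geometry holds the default size ranges comfortably, but many
  large (≥50-voxel) foci plus nucleoli can exhaust the nucleus; the
  7-slice 128×128 geometry roughly doubles the capacity and is used
  where the full 3–100 voxel nuclear window is exercised.

## Dose–response

The 4-parameter logistic `y = bottom + (top − bottom)/(1 + (d/mid)^h)`
is fitted on log10(dose) with `scipy.optimize.curve_fit`. The
midpoint is initialised at the dose whose response is nearest the
half-range, the Hill slope at 1; log-midpoint bounds extend one decade
beyond the dose range and the Hill slope is bounded to [0.1, 10]. The
reported midpoint is the *relative* IC50 (inflection of the fitted
curve, not the 50%-of-control crossing). Standard errors come from
the fit covariance with the midpoint SE delta-method-propagated from
log space. Fits require at least 5 distinct positive doses; constant
responses are rejected as "no dose dependence"; non-convergence is
reported with the best iterate and a flag rather than an exception.

Viability is normalised per plate to the NT mean (≥2 NT wells
required). Fluorescence-quenching titrations (classical: titrate
ligand against labeled oligonucleotide; reverse: fix ligand, titrate
oligonucleotide) use the response 100·F(T60)/F(T0) per well and report
the fitted midpoint as appKD.

## FRET melting

Curves are min–max normalised to 0–100% over the heating ramp (≥20
points required, monotonic temperature grid). T1/2 is the temperature
of the first upward crossing of 50%, linearly interpolated between the
bracketing points, after an optional 3-point running-median smoothing
(default on) that removes single-point spikes without shifting a
monotonic transition. ΔT1/2 subtracts two results measured on the
same temperature grid and protocol (checked); ΔΔT1/2 compares two
such shifts, e.g. with and without a competitor.

## Bliss synergy

For fractional effects fa, fb ∈ [0, 1] the Bliss expectation is
`fa + fb − fa·fb`; the score of a combination well is
`100·(f_observed − expected)` in percentage points, computed from a
long-format dose-matrix table with both zero-dose margins present.
Viability is clipped to [0, 100]% before scoring (with a warning and a
clip count). A pair is flagged synergistic when its score exceeds 10
points; the matrix mean is taken over combination cells only.

**Boundary-clipping bias.** When monotherapy viabilities sit at or
above 100% (weak doses of potent agents plus upward noise), clipping
truncates the noise distribution asymmetrically and biases scores
toward zero; the same happens when `expected + excess` exceeds 1 in
the generator's construction. Quantitative recovery claims are
therefore stated for matrices whose responses stay inside (0, 100)%;
demo matrices with realistic potencies show a slightly attenuated mean
score, which is a property of the clipped construction, not an
estimator error.

The foci-based comparison `foci_additive_comparison` divides the
NT-corrected combination delta by the sum of the single-agent deltas;
a fold above 1 indicates supra-additive DSB induction. A non-positive
additive expectation leaves the fold undefined with a warning.

## Pipeline and reproducibility

Run configurations (YAML/JSON) are schema-validated with pydantic:
known units, existing input paths, and no segmentation-parameter id
shared between experiments (the frozen-parameters rule) unless reuse
is explicitly allowed. Every result set is written atomically
(temp-file rename) with a manifest carrying input SHA-256 hashes,
parameters, package version, and timings; CSVs use a fixed float
format and JSONs sorted keys, so identical results produce identical
bytes (timings aside). All randomness flows from
`numpy.random.default_rng` seeds, with per-cell seeds derived through
`SeedSequence`, making every study deterministic for a fixed seed.
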