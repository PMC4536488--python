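# Methods

## The assay and what is quantified

A donor cell whose endocytic organelles and membranes carry a lipophilic
dye (DiD), optionally also expressing an EGFP-tagged protein, is co-cultured
at very low ratio inside a confluent lawn of unlabelled acceptor cells.
Transfer of labelled material into acceptors is read out per field as the
sum of grayscale values of voxels that (i) lie strictly above a global
intensity threshold, (ii) fall inside segmented acceptor-cell volumes, and
(iii) fall outside the dilated donor volume. The paired readout is the
number of such voxels (transfer volume); their ratio is the transfer
density. Signal above threshold outside any cell is reported as unspecific
transfer and never counted. Donor-free fields are quantified identically
through a *pseudo-donor* (the cell nearest the image centre is blanked), so
background is measured by the same code path as transfer.

All intensity thresholds are defined on the 8-bit scale. Higher-bit-depth
input must be passed through `normalize_to_8bit` (linear rescale with
round-half-up); thresholds are never silently re-interpreted on other
scales. "Above threshold" is strict (`> t`): signal at exactly the
threshold value is background.

## Parameters (`QuantConfig`)

| parameter | default | unit | role |
|---|---|---|---|
| `did_threshold` | 100 | 8-bit grayscale | transfer threshold, DiD channel |
| `egfp_threshold` | 100 (alt. 160) | grayscale | transfer threshold, EGFP channel |
| `donor_min_volume` | 1000 | µm³ | minimum volume of a donor object |
| `cell_min_volume` | 100 | µm³ | acceptor cells below this are excluded (dead-cell guard) |
| `closing_radius` | 2 | voxels | structuring element of donor closing |
| `dilation_radius` | 1 | voxels/axis | donor blanking rim |
| `exclusion_distance` | 200 | µm | donor isolation / control clearance |
| `nuclei_radius` | 200 | µm | radius of the confluency check |
| `min_nuclei` | 15 | count | minimum nuclei within that radius |
| `max_controls` | 15 | count | control positions per well |
| `donor_intensity_threshold` | 250 | grayscale | donor recognition level |
| `field_extent` | 228 | µm | high-resolution field footprint |

`donor_intensity_threshold` is this package's own choice: donors are
acquired with laser power set so that roughly half the donor volume is at
detector saturation, so near-saturation (250/255) is the intended
signature; it is configurable because weakly stained donors exist and are
flagged (`weak_donor`) rather than quantified. The EGFP threshold
alternative (160) is selected explicitly per experiment via configuration;
the software never switches automatically.

Donor closing is applied per z-slice with a radius-2 disk by default. A 3D
ball is available (`closing_3d`), but in-plane closing is the conservative
reading given the strong z-anisotropy of confocal stacks (1.01 µm z-steps
versus ~0.45 µm pixels).

Boundary exclusion applies to the lateral (x, y) image borders only. The
z-range of an acquisition is chosen to span the cells, so every cell
touches the axial extremes of its own extent; excluding on z would discard
every cell.

Stacks in which the thresholded donor approximation maps to more than one
segmented cell are rejected (`MultipleDonorsError`): doublets and groups of
donors make attribution impossible and are excluded, not quantified.

## Segmentation

Four stages on the membrane (WGA) channel: Perona–Malik anisotropic
diffusion (3 iterations, conductance 30, time step 1/7; 6-neighbour
exponential-conductance scheme, Neumann boundaries); nucleus markers from
the Hoechst channel (26-connected components above 120 with volume
≥ 20 µm³); marker-controlled watershed with the membrane intensity as
topographic surface; classification removing regions larger than
30,000 µm³ or whose one-voxel boundary shell carries a mean membrane
intensity below 40.

Two choices matter for correctness at image borders:

- The background marker is the low-membrane-intensity space connected to
  the **axial (z) faces** of the stack — the medium above and substrate
  below the lawn. The lateral faces are not used because they slice through
  cells and would expose cell interiors as "background".
- The background region acts as a flood **mask**, not a competing seed:
  cells climb and keep their own membrane shells instead of ceding ridge
  voxels to a background basin. On default synthetic lawns this yields
  per-cell Jaccard ≈ 0.995 against ground truth.

These internal parameters are not published constants of the original
segmentation tool; they are this package's frozen defaults, tuned once
against the synthetic generator and kept fixed so results are reproducible.
Watershed flooding order (scikit-image) is deterministic, which fixes ridge
tie-breaking.

## ROI selection on well mosaics

Low-resolution tiles (775 µm fields, ~1.51 µm/px) are assembled row-major
without blending; stage position of pixel (row, col) is
`origin + (col, row)·µm_per_px`. Donors are 8-connected components above
the donor intensity level with area ≥ 50 µm² (the minimum blob area is not
a published value; 50 µm² rejects debris while keeping any plausible cell).
Nuclei are local maxima above 80 with ≥ 10 µm separation. A donor position
qualifies iff its nearest other donor is at least 200 µm away **and** at
least 15 nuclei lie within 200 µm of its centroid; distances are inclusive
at the boundary ("at least" ⇒ ≥), and counts are taken from the ROI/donor
centre. Controls are rejection-sampled uniformly (seeded, deterministic)
under the same distance and density requirements plus pairwise disjointness
of the square field footprints (default side 228 µm, the high-resolution
field of view). Fewer than 15 controls are returned when the attempt budget
(2,000) is exhausted — e.g. when donor exclusion zones pave the well.

## Statistics

Per-donor-cell integrated intensities are normalized so the control
condition's median is exactly 100 %, then transformed with the natural
logarithm; all tests run on the transformed values. Multiple conditions:
one-way ANOVA, then Dunnett's many-to-one comparisons against the control
using the exact multivariate-*t* distribution (`scipy.stats.dunnett`).
Two conditions: two-sided Student's *t*-test (equal variances by default,
Welch available). Significance is α = 0.05. Dot-plot summaries report
medians of the untransformed normalized values.

Zeros (fully inhibited donors) would break the log transform; they are
replaced by a configurable pseudo-count (default 1 grayscale·voxel on the
raw scale) and the substitution count is reported. Normality is checked
with a chi-square goodness-of-fit test against a normal with the sample
mean and SD, using equal-probability bins (⌈n/5⌉ bins, capped at 20) and
bins − 3 degrees of freedom; the binning scheme is frozen because the
p-value depends on it. With parameters estimated from ungrouped data this
recipe is only asymptotically χ²; Monte-Carlo checks in the test suite show
it is calibrated at the sample sizes used (≤ 5 % false rejection at n ≈ 800,
family-wise error of the full normalize → ln → ANOVA/Dunnett pipeline
0.045–0.06 at nominal 0.05 over 1,000 null experiments).

## The synthetic generator

The generator emulates the screening acquisition geometry: 1.01 µm z-steps
and 512-px-capable fields; the xy pixel pitch defaults to 0.445 µm,
consistent with a ~228 µm field at 512 px (the xy pixel size of the
original acquisition is not published, which is why voxel size is mandatory
input metadata for real data, never guessed).

Acceptor cells are the 3D Voronoi cells of Poisson-disc-sampled nucleus
centres, clipped to a slab (cells sit on a virtual substrate with medium
above). Membrane shells (intensity 200) mark every inter-cell and
cell–background boundary; nuclei are bright ellipsoids; the DiD channel
carries uniform noise strictly below the transfer threshold. The donor is
painted with the fraction of its volume nearest the centroid at saturation
(default 0.5, mimicking the half-saturated acquisition) and the remainder
at a sub-saturation rim (180) so donor detection cannot rely on saturation
alone. Transfer puncta are spheres of constant supra-threshold intensity
placed ≥ 2 voxels inside their target cell and clear of the dilated donor,
so a ±1-voxel segmentation error cannot reassign ground truth — this
deliberately isolates quantification correctness from segmentation
accuracy. Ground truth records the exact painted per-cell sums.

Well mosaics render nuclei as Gaussian spots and donors as saturated disks
(8 µm core) with Gaussian halos; the default nucleus density (4·10⁻⁴/µm²)
corresponds to the plating density of the screening co-cultures
(~35,000 cells/cm²).

What the generator does **not** emulate: point-spread blur, spectral
bleed-through, photobleaching, intensity gradients, irregular cell shapes,
nanotubes, or partial volume effects. Passing tests therefore demonstrate
the correctness of the *algorithms* (thresholding, filtering, attribution,
selection, statistics) on well-calibrated input, not robustness to optical
artefacts of real microscopy data.

## Problem sizes used in tests and the acceptance script

Unit tests run on 18×128×128 lawns with 14 cells; acceptance checks use the
full 20×256×256 / 50-cell geometry (50 stacks for oracle equivalence, 20
wells for ROI equivalence, 1,000 null + 300 shifted replicates for the
statistics calibration). These sizes give exact integer checks and stable
Monte-Carlo estimates at interactive runtimes.

## Known limitations

- The segmentation stage reproduces the published four-stage *structure*
  (filtering, markers, watershed, classification), not the bit-exact
  behaviour of the original MATLAB tools, whose internal parameters are not
  published.
- Control-position sampling can return fewer than the requested maximum in
  crowded wells; callers should check the returned count.
- Statistics pool values across experiments; batch effects are not
  modelled (no mixed-effects layer). A per-experiment grouping column can
  be carried through the TSV for users who need it.
- The acquisition-side module ends at the coordinate CSV; microscope
  control loops are out of scope.
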