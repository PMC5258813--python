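# Methods

This note documents the models, defaults and design choices behind
`colonycyto`. The package analyses imaging-cytometry data of human
pluripotent stem-cell (hPSC) colonies and validates every stage on a
synthetic specimen with known ground truth; nothing here depends on
proprietary instrument software.

## The synthetic specimen

**What it emulates.** Fixed hPSC cultures in a *quasi-undifferentiated*
state: flat monolayer colonies of tightly packed cells with large nuclei
and scant cytoplasm, mostly undifferentiated (OCT-3/4⁺ and positive for
the surface markers SSEA3/SSEA4/TRA-1-60) with a differentiated minority
(SSEA1⁺) concentrated at, or delaminated from, colony peripheries. Each
simulated field is one double staining: a DNA stain (`nuclear`), a nuclear
transcription-factor marker (`marker_x`, OCT-3/4) and one cell-surface
marker (`marker_y`).

**Geometry.** Colony footprints are star-convex radial blobs
r(θ) = R·(1 + Σₖ aₖ cos(kθ + φₖ)), harmonics k = 2…5, total perturbation
≤ 0.3·R, placed fully inside the field without mutual overlap (dart
throwing with whole-configuration restarts; an impossible request raises
`PackingError`). Nuclei have radii ~N(6, 0.7²) px and are packed by
rejection sampling with minimum centre separation 0.95·(rᵢ + rⱼ); by
default each colony fills to saturation (stop after 400 consecutive
rejections), which reproduces the tightly packed morphology. A small
number of delaminated cells (default 20) lie outside all footprints.
Default field: 700×700 px, 4 colonies of base radius 75–105 px, ≈ 450–550
cells. Coordinates are 0-based (row, col) with pixel centres at integers.

**Phenotypes.** Each cell carries one quadrant class —
`double_pos`, `x_single_pos`, `y_single_pos`, `double_neg` — drawn with
the configured class fractions. `fractions_from_marginals(p_x, p_y, a)`
builds the four fractions from two marginal positive fractions and an
association a ∈ [−1, 1] that shifts the joint away from independence while
preserving both marginals exactly (a = +0.5 for undifferentiated-state
surface markers, −0.5 for SSEA1, whose positives anti-correlate with
OCT-3/4). The default mixture is the OCT-3/4 × SSEA1 pairing of the
201B7-like profile (85.2% / 30.2%). The line profiles shipped in
`LINE_PROFILES` give marginal percent-positive values for four lines;
201B7's five-marker profile (OCT-3/4 85.2, SSEA3 94.0, SSEA4 95.0,
TRA-1-60 87.0, SSEA1 30.2%) is a realistic measured-style anchor for a
quasi-undifferentiated culture of that line, while 253G1, Tic and H9
carry *synthetic*, biologically plausible profiles.

**Edge bias.** The differentiated class of the current pairing
(`y_single_pos` for SSEA1, `double_neg` for undifferentiated-state
markers) is allocated to cells with probability ∝ exp(−β·d), where
d ∈ [0, 1] is the normalized distance from the colony boundary and
β = `edge_bias` (default 3.0, a strong peripheral concentration chosen by
a design power analysis for the spatial test at its reference study size);
class *counts* are drawn first from the marginal fractions, so the
marginals are preserved exactly and β only redistributes positions.
Delaminated cells enter the allocation with d = 0. β = 0 makes the labels
exchangeable, the regime used to check the permutation test's calibration.

**Expression and instruments.** True expression is lognormal per
(phenotype, channel): positives LN(ln 420, 0.7²), negatives LN(ln 8,
0.6²), in arbitrary pre-instrument units; the negative distribution also
serves as the negative-control level (staining without primary antibody).
The camera renders each cell as an isotropic Gaussian-profile disc with
hard support: the DNA stain wide (σ = ⅔·r, support 2r — adjacent nuclei
genuinely merge, which is what exercises the splitting step), the
transcription factor confined to the nucleus (σ = 0.5·r, support r) and
the surface marker to the nucleus plus a small membrane annulus (σ =
0.4·r, support 1.1·r; the cells have scant cytoplasm, and wider membrane
kernels would let neighbour signal dominate the measured nucleus areas).
Pixels = Σ kernels + N(100, 5²) background, rounded and clipped to the
12-bit ceiling 2¹² − 1 (4096 levels). The flow simulator multiplies true
expression by mean-1 lognormal noise with CV 0.25, clips to 10⁴ (4 log
decades) and shuffles cell order (dissociation destroys position). One
`numpy` generator seeded from `SimConfig.seed` drives all imaging draws in
a fixed order (colony geometry → packing → delaminated cells → phenotype
counts → edge-weighted allocation → expression → per-channel noise), so
identical configs give bit-identical output; the flow stream is seeded
separately so the two instruments are independent measurements.

**What the simulator does not model** — and hence what passing tests do
not establish about real data: no point-spread function, chromatic shift,
vignetting or tile-edge artifacts; no 3-D structure, mitotic figures,
debris or apoptotic nuclei; no staining heterogeneity within a class
beyond the lognormal; no feeder cells; colonies never merge or clip the
field border. Real segmentation and gating error rates will be worse than
the synthetic ones.

## Segmentation

Pipeline: Gaussian smoothing (σ = 2 px) → subtract the image's 5th
percentile (robust to how much of the field the colonies cover) → global
Otsu threshold → fill holes → seeded watershed → per-region shrink → area
band → border policy → relabel to 1..K. All operations use 4-connectivity.

Two choices depart from the textbook recipe and deserve justification:

- *Seeds from intensity, not the distance transform.* Inside a confluent
  colony the thresholded foreground is one solid blob; the Euclidean
  distance transform of that mask has its maxima along the colony
  midline and carries no per-nucleus saddles, so distance-based h-maxima
  cannot split it. Each nucleus does contribute one peak to the smoothed
  intensity, so seeds are local maxima of the smoothed background-
  subtracted image with (i) an intensity floor of `split_h` × the
  object's maximum (default 0.3; 1.0 disables splitting and reduces the
  operator to plain connected components, a property the tests exploit as
  an oracle) and (ii) a minimum separation derived from
  `min_nucleus_area`. The watershed then flows on inverted smoothed
  intensity.
- *Region shrinking.* The watershed tiles each blob completely, so raw
  regions extend to the inter-nuclear boundary, where the abutting
  neighbours' membrane marker lives. Each region is eroded by
  `shrink_radius` = 2 px (largest connected piece kept), making the
  reported "Nuc area" the nucleus interior. Without this, surface-marker
  means of negative cells in positive-rich colonies are inflated by
  several counts and percent-positive estimates biased upward.

A guard rejects foreground entirely when the Otsu threshold does not
clear 8× the robust (MAD) background spread; otherwise pure camera noise
would be segmented. Area band default 25–400 px² around the ≈ 80–120 px²
eroded nuclei; `border_policy` defaults to `keep` (whole-well analyses
make border cells rare). Quality on default fields: centroid-matching
F1 ≈ 0.99 against ground truth at a one-nucleus-radius match distance.

## Quantification

One record per label: unweighted centroid, area, half-open bounding box,
and the mean of every channel over exactly the label's pixel set — surface
markers included, measured over the nucleus area like everything else.
The per-cell statistic is the mean (one dot per cell in the profile
plots); integrated intensity is area × mean. No per-cell background
correction is applied beyond the global subtraction inside segmentation.

## Gating

Thresholds come from a matched negative-control specimen: the gate is the
empirical q-quantile (linear interpolation; default q = 0.995) of control
cells' mean intensity per channel. The no-primary-antibody control is the
only threshold rule the assay description supports; the quantile value is
exposed in every interface. Positivity is *strict* (ties count negative —
documented, arbitrary). Quadrant classes partition every cell; their
percentages sum to 100 and their marginals equal the one-channel
percent-positive values by construction. Histograms use log-spaced bins
over [1, camera ceiling] with out-of-range values clipped into the end
bins so counts conserve n. With the default generator and q = 0.995, the
full chain recovers ground-truth marginals within ~±1.5 percentage points
at n ≥ 2000 cells (≈ +1–2 false-positive points at low fractions from the
residual neighbour crosstalk, minus ~1 point at high fractions).

## Concordance

Imaging and flow percentages differ cell-biologically and
instrumentally; the claim under test is profile agreement. Pearson's r is
computed per replicate across the marker vector (5 markers), then
summarized per line as mean ± SE over replicates (SE = sd/√n with the
n − 1 denominator; a single replicate reports SE = 0 with an explicit
flag). This per-replicate reading matches a "mean ± SE, n = replicates"
summary; pooling all (marker, replicate) points into one correlation per
line is available behind `pool_replicates=True` but is not the default.
In the simulated four-line design (three replicates, ~2000 cells per
replicate, default noise) every line's mean r lands around 0.99 —
comfortably above the 0.7 working bound for acceptable concordance.

## Spatial analysis

- *Colonies* are single-linkage connected components of cell centroids at
  `linkage_distance` (default 3× the median nucleus diameter, estimated
  from measured areas); components below `min_colony_size` (default 5)
  stay unassigned, like delaminated cells. Footprints are the union of
  member nucleus masks dilated by one median radius, holes filled.
  Centroid linkage (rather than footprint merging) is robust to
  segmentation dropouts and is checkable against a brute-force
  union–find oracle.
- *Edge scores*: boundary distance is the Euclidean distance transform of
  the footprint at the cell centroid; the normalized score divides by the
  colony's maximum depth (single-cell colonies score 0 by convention; a
  centroid outside its footprint is clamped to 0 with a warning). The
  edge flag uses an absolute band (default 1.5× median nucleus diameter)
  because peripheral localization is about physical adjacency to the
  boundary, not relative depth.
- *Edge enrichment*: E = (edge fraction among phenotype cells) − (edge
  fraction among all in-colony cells), with a two-sided permutation null
  obtained by shuffling phenotype labels over in-colony cells (default
  1999 permutations, seeded) and the add-one correction
  p = (b + 1)/(m + 1). A permutation null is used deliberately: edge
  flags are spatially autocorrelated within colonies, so an analytic
  binomial null would be anticonservative. This statistic is this
  package's formalization of otherwise anecdotal centre-vs-periphery
  reports; at β = 0 its type-I error is calibrated (checked over 200
  simulated fields), and at the default β it detects enrichment with
  power ≥ 0.9 at ≈ 1000 in-colony cells.
- *Backtracking* returns padded per-channel crops plus the nucleus mask
  and outline for any cell ids, reproducing the profile-point →
  marked-cell workflow; the quadrant class recomputed from a crop equals
  the stored class exactly.

## Pipeline and reproducibility

`run_pipeline` executes simulate → segment → measure → gate → flow →
(optional concordance experiment) → spatial, persists every intermediate
(TIFF/CSV/JSON), and writes a manifest with the config hash, seeds and
sha256 checksums of all data artifacts. The global seed propagates to
every stochastic stage; re-running an identical config reproduces
bit-identical images, tables and checksums. Figures (quadrant scatter,
gated histogram, concordance panel) are listed in the manifest but not
checksummed. Every number in `report.json` is recomputable from the
persisted CSVs.

## Problem sizes used in the validation suite

The test suite and the acceptance script choose deliberate, moderate
problem sizes: default 700×700 px fields (≈ 500 cells each; four stained
fields ≈ 2000–2300 cells per simulated replicate); the four-line
concordance replication analyses ≈ 22,000 cells; marginal-recovery checks
pool fields to ≥ 2000 cells per fraction; the permutation-test
calibration uses 200 ground-truth fields (≈ 150–250 in-colony cells each)
and the power check 50 full-chain fields of ≈ 1000 in-colony cells.

## Known limitations

- The real instrument's segmentation parameters are not public; this
  operator is a reconstruction tuned on the synthetic specimen, not a
  transcription.
- The gating rule (control quantile, strict inequality) is a reproducible
  surrogate for gates that practitioners usually draw manually.
- The concordance experiment's three non-201B7 line profiles are
  invented; only the design (4 lines × 5 markers × replicates) and the
  201B7 profile are anchored.
- Single global thresholds per field; no illumination-gradient handling,
  which real tiled acquisitions would need.
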