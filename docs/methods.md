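# Methods

## The measurement problem

Blastocyst-stage mouse embryos are ~60 µm balls in which an inner cell mass
(ICM: epiblast plus primitive endoderm) sits against one pole of a
trophectoderm (TE) shell. Confocal immunofluorescence stacks of such embryos
(8-bit, 2 µm optical sections) must be reduced to one record per nucleus —
position, volume, and per-channel mean and integrated density — before any
comparison of marker levels across embryonic stages (E3.5, E4.5, diapause)
is possible. Nuclei are too crowded for reliable one-shot 3D segmentation,
so the pipeline detects nucleus cross-sections per 2D section and links them
through z into 3D objects, the same architecture as a StarDist-detect /
TrackMate-link workflow.

## Segmentation by z-linking

Per section of the DNA channel:

1. **Unsharp mask**, ImageJ convention `(I − w·G_σ(I))/(1 − w)` with
   σ = 15 px, w = 0.6, clipped to the input range. A constant image is a
   fixed point; w ≥ 1 is rejected as degenerate.
2. **Percentile normalisation** mapping the 1.0 percentile to 0 and the
   99.9 percentile to 1, clipped; a constant section maps to zeros.
3. **Detection**: threshold at 0.2 on the normalised image, fill holes,
   split touching nuclei by watershed on the smoothed Euclidean distance
   transform (markers = local-maximum plateaus within a 9-px window),
   suppress overlapping candidates above 0.2 IoU keeping the higher mean
   intensity, and keep candidates whose calibrated area lies strictly
   inside (5, 30) µm². Components and fragments at or below the area floor
   are pruned early; splitting never grows a region, so this cannot change
   the result. The detector is a classical stand-in that preserves the
   roles of a learned detector's probability and non-maximum-suppression
   thresholds; mask-level equivalence with a trained network is not
   claimed.
4. **Linking**: greedy nearest-neighbour matching of detection centroids
   between consecutive sections, accepting links up to
   `max_link_dist_um = 1.5` µm (half the nominal nucleus radius).
   Consecutive-section centroid jitter of a correctly detected nucleus is a
   small fraction of its radius (p99 ≈ 0.6 µm in synthetic stacks), while
   distinct nuclei sit ≥ 2 radii apart, so this bound tolerates jitter,
   forbids cross-nucleus links, and starves chance alignments of noise
   debris that the area filter alone admits. Ties break by smaller
   distance, then smaller detection index, then older track — fully
   deterministic. Gap closing is off by default (`max_gap = 0`). Tracks
   with fewer than `min_track_len = 6` detections (duration strictly
   greater than 5 sections) are discarded.

The label volume assigns each track's pixel masks to its label; in the rare
event two tracks claim one voxel the nearer same-section centroid wins.
Labels are relabelled contiguously 1..K.

The area filter's published bounds carry no units; they are interpreted as
calibrated µm² (configurable), which is also what makes them consistent with
the volume QC window below at 2 µm sections.

## Quantification and QC

Measurements use the raw (unprocessed) stack under the label mask:
unweighted voxel centroid in µm, voxel count, volume = count × pixel
area × z step, per-channel mean, and integrated density. Integrated density
is stored as `mean × voxel_count`, making that identity bit-exact in the
table and after CSV round-trip (it equals the raw voxel sum to one ulp).

Two open-interval QC windows remove mis-segmented objects:

* **DNA mean in (2, 10)** on a 0–10 scale. The scale is the per-section
  1–99.9 percentile-normalised DNA image (values in [0, 1]) times 10 —
  a window of (2, 10) then means "the object's DNA signal is at least 20%
  of the section's dynamic range". Real nuclei in synthetic stacks score
  4–7; sub-nuclear debris scores near the lower bound. The raw 8-bit mean
  is also exported, and the filter can be pointed at any column.
* **Volume in (150, 700) µm³**, the plausible range for a nucleus rendered
  over ≥ 6 sections of in-window cross-sections.

Boundary-equal values are removed (the published "upper/lower limit"
wording is read as an open interval; both windows are configurable).
Region restriction sets a per-record `in_region` flag by centroid membership
in a boolean mask — cheap, deterministic, and matching the semantics of
manually cropping away the mural trophectoderm. The default order is crop,
then QC.

## Statistics

The unit of analysis is the nucleus, pooled across embryos within a stage,
exactly as the violin plots of such experiments are drawn; a per-embryo-mean
mode exists because pooling treats nuclei of one embryo as independent and
inflates n. All tests are two-sided.

* **Wilcoxon rank-sum**: midranks for ties. When the smaller sample has
  ≤ 8 observations and the pooled sample is tie-free, the p-value comes
  from exact enumeration of the rank-sum null distribution (dynamic
  programming over ranks); otherwise from a tie-corrected normal
  approximation *without* continuity correction, so that for two groups
  the Kruskal–Wallis H equals the squared standardised rank-sum statistic
  and the chi-square and normal p-values coincide. Identical samples give
  p = 1.
* **Kruskal–Wallis**: H with tie correction, p from χ²(k−1); all-tied data
  defines H = 0, p = 1.
* **Diagnostics**: Brown–Forsythe (median-centred Levene) by default —
  the robust standard for skewed data, mean-centred available — and
  Shapiro–Wilk (3 ≤ n ≤ 5000, non-constant input required).
* **Labels**: ns p>0.05; \* ≤0.05; \*\* ≤0.01; \*\*\* ≤0.001; \*\*\*\* ≤0.0001,
  most stringent wins.
* Pairwise p-values are unadjusted by default (matching how such pairwise
  tests are usually reported over violins); Holm step-down is available.

## Gating and in-silico embryos

Gates act on the per-nucleus table: a threshold gate keeps records with
integrated density strictly above its cutoff; a polygon gate keeps records
whose point in the 2D co-expression plane lies inside a validated,
non-self-intersecting polygon, with boundary points counting as inside
(an interactive hand-drawn selection has no such convention; this one is
deterministic and documented). Selections are lists of (embryo_id,
nucleus_id), stable under row reordering. Reconstructions are point clouds
of measured centroids coloured by a chosen channel. The region-enrichment
report (selected-fraction in region / overall fraction, with a one-sided
hypergeometric p) quantifies what is otherwise a visual claim; the
hypergeometric p is an extension and is labelled as such in the output.
The size–intensity check uses Spearman correlation, consistent with the
rank-based stance (Pearson by flag). Embryos with zero surviving records
do not appear in the per-embryo summary (their absence is visible in the
run log's per-embryo counts).

## The synthetic embryo generator

The generator emulates the statistical structure the analysis relies on,
not optics:

* **Geometry.** `n_te` nuclei on a sphere of radius 28 µm, `n_epi + n_pre`
  in a ball of radius 13 µm offset 14 µm along the embryonic axis, with a
  minimum ellipsoidal separation (2.05 × mean radii) enforced by bounded
  dart-throwing (`PackingError` if impossible). The embryonic-region ROI is
  the hemisphere on the ICM side of the plane through the embryo centre, so
  epiblast and primitive endoderm are in-region and mural TE is not.
* **Nuclei** are Gaussian blobs truncated at 2.5 σ, in-plane radius
  3.0 ± 0.15 µm and axial radius 4.2 × larger. The axial elongation stands
  in for the axial smear of confocal imaging and is what lets a nucleus
  present in-window (5, 30) µm² cross-sections over more than 5 consecutive
  2-µm sections — the regime the published area and duration filters
  jointly presuppose. Ground truth records the analytic ellipsoid volume,
  the rendered support, and the exact pre-noise rendered sum per channel.
* **Intensities** are lognormal per lineage × channel × stage (positive
  support and right skew, as IF intensities show). Defaults encode the
  biology the pipeline must resolve: in the epiblast, pY705 and TFCP2L1
  median amplitudes order diapause > E3.5 > E4.5; NANOG dips at E4.5; TE is
  dim in every marker at every stage (hence bimodal pooled distributions);
  DAPI is lineage- and stage-invariant. No absolute intensity scales exist
  for this kind of data, so the medians are free parameters of the
  simulation, chosen to sit well inside 8-bit range, and all are
  overridable. Draws are capped at 250 so noise-free peaks cannot saturate.
* **Noise**: Poisson shot noise at 0.8 photons per intensity unit on signal
  plus a background of 3, then Gaussian read noise (σ = 2), then clipping
  and rounding to uint8. Setting both noise terms to zero gives exact
  conservation: the voxel sum over a nucleus's true support equals its
  ground-truth total within quantisation error.
* **Determinism**: one `numpy` Generator seeded from the spec; identical
  specs render bit-identical stacks. Cohorts derive per-embryo sub-seeds
  from `SeedSequence([seed, stage_index, embryo_index])` (kept below 2³¹),
  so cohorts are reproducible without global state. Optional per-embryo
  count jitter (lognormal, CV ≈ 0.15) emulates the natural spread of cell
  numbers across embryos when per-embryo summaries are of interest.
* **Table-level sampling** (`sample_cohort_table`) draws per-nucleus
  feature records from the same amplitude and geometry distributions
  without rendering voxels, for statistics-scale studies (hundreds of
  cohorts) where rendering would dominate. `null_profiles()` gives a
  profile map with no lineage/channel/stage structure, the correct iid
  null for error-rate calibration — note that "identical profiles per
  stage" alone leaves fixed per-embryo lineage strata and makes pooled
  comparisons conservative, which is itself visible in the tests.

Not emulated: point-spread convolution, spectral bleed-through, depth- and
time-dependent fluorescence quenching, irregular (non-ellipsoidal) nuclear
shapes, mitotic figures, and cell debris. Passing tests therefore show that
the pipeline's logic is correct under its stated assumptions, not that the
detector matches a trained network on real microscope data.

## Problem sizes and tolerances

The test and acceptance workloads use 256 × 256 × 40 stacks (0.5 µm pixels,
2 µm sections) with ~30 nuclei per embryo and cohorts of 5–15 embryos —
large enough that every filter and statistic operates in its intended
regime, small enough that the full suite runs in a few minutes on one CPU.
Error-rate calibration uses 200 table-level cohorts (exact central binomial
95% interval around α = 0.05) and power checks 100 cohorts with ≥ 100
in-region nuclei per group. Recovery is scored by greedy one-to-one
centroid matching within one nucleus radius; quantification fidelity by
Pearson correlation between measured integrated density and ground-truth
rendered signal. Floating-point contracts (integrated-density identity,
CSV round-trips) are exact, not approximate; CSV reads use round-trip
float parsing.

## Known limitations

* The detector assumes nuclei are brighter than their surroundings on each
  section after percentile normalisation; on sections containing no nuclei
  the normalisation amplifies noise, and rejection of the resulting debris
  relies entirely on the area, linking and duration filters.
* The area and volume windows are calibrated-unit interpretations of
  published unitless thresholds; data acquired at very different pixel
  sizes requires re-deriving them.
* Greedy linking is only guaranteed optimal when optimal links are mutual
  nearest neighbours (verified exhaustively at small sizes); pathological
  geometries can in principle differ from a global assignment.
* Pooling nuclei across embryos inflates n; the per-embryo mode is the
  conservative alternative.
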