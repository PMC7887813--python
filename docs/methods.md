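# Methods

## Level-set segmentation

The segmentation core is a two-phase piecewise-constant region evolution
(Chan–Vese family). For an image *I* and a foreground region Ω the energy is

    E(Ω) = ∫_Ω (I − c1)² + ∫_Ω̄ (I − c2)² + ν·Perimeter(Ω) + µ·Area(Ω)

with c1, c2 the current foreground/background means. It is minimized by
threshold dynamics: every sweep recomputes c1/c2 and flips each pixel to the
phase of lower energy, where the area term contributes a constant penalty µ
per foreground pixel and the perimeter term enters through a Gaussian-smoothed
indicator (σ = 1 px), a standard mean-curvature proxy. Convergence is declared
when the relative symmetric difference between consecutive masks falls below
`tol` (default 1e-3), with a hard cap of `max_iter` = 200 sweeps; a run that
hits the cap returns the current mask and logs a warning.

The weights act on the image's native intensity scale, where the data term is
of order (c1 − c2)². For the bright, high-contrast structures this pipeline
targets, the defaults ν = 2 and µ = 3 (nucleus and soma passes) and ν = 2,
µ = 2 (cytoplasm pass) are deliberately weak regularizers: they trim
single-pixel noise and bias the contour toward compact regions without
competing with the data term. Larger values produce measurably smoother and
smaller masks — the property tests demonstrate both monotonicities on
low-contrast fixtures where the regularizers are comparable to the data term.
The exact discretization is an implementation choice; only the parameter
semantics (perimeter and area penalties) and fixture performance are claimed,
not agreement with any particular reference discretization.

### Staged pipeline

* **Nuclei**: DAPI channel, Otsu initialization, components < 30 px removed.
* **Somas**: pixelwise sum of the four membrane channels, Otsu initialization,
  components < 50 px removed. A soma must overlap at least one segmented
  nucleus pixel (a soma contains its nucleus); the filter can be disabled in
  the configuration since it is a biological expectation, not a definition.
* **Vessels**: Otsu on the autofluorescence channel; connected components
  strictly larger than 4000 px. The boundary is read as *strictly* greater:
  a 4000 px component is not a vessel. An absent autofluorescence channel
  yields an empty vessel mask.
* **Cytoplasm**: the soma pass repeated with µ = 2 to capture the dimmer cell
  area. When a vessel is present in the field, initialization switches from
  Otsu to Li's minimum-cross-entropy threshold, which is less sensitive to the
  vessel's very bright pixels; vessel pixels are excluded from the result.
* **Assignment**: a cytoplasm component overlapping exactly one soma joins
  that soma's cell; components overlapping two or more somas are split by a
  marker-controlled watershed flooding the distance-to-nearest-soma landscape
  from the overlapping somas, which partitions the component exactly (pixel
  conservation is asserted in tests). Components overlapping no soma are
  candidate detached processes.
* **Process attachment**: an orphan component whose minimum Euclidean
  pixel-centre distance to any soma region is ≤ 10 px is attached to the
  nearest soma. Distance is measured from the soma *boundary* (the region,
  not its centroid), and "within a 10 px radius" is read as ≤ 10.0. Exact
  ties — possible because squared distances between pixel centres are
  integers — go to the lower soma id and are logged. Farther orphans are
  discarded.
* **Plaques**: either Otsu threshold + binary closing + minimum-area filter
  (default 100 px) on the Aβ channel, or a semi-supervised pixel classifier:
  a random forest (50 trees, explicit seed) over a feature bank of Gaussian
  smoothings, gradient magnitudes and Laplacians at σ ∈ {1, 2, 4} px, trained
  from sparse foreground/background scribbles and thresholded at probability
  0.5. The classifier is this package's own replacement for interactive
  pixel-classification tools.

Per-cell marker means are computed over the union of soma, cytoplasm and
attached-process pixels. The whole segmentation is deterministic (RNG-free;
classifier training takes an explicit seed).

### Evaluation

Predicted cells are matched one-to-one to ground-truth instances greedily by
descending Dice (2|A∩B|/(|A|+|B|)); ties break on lower truth id, then lower
prediction index. Pairs with Dice ≥ `match_dice_min` (default 0.5 — the
matching criterion is a free choice and configurable) are correct; unmatched
predictions/truths are false positives/negatives. Dice of two empty masks is
an error, not 0.

## Phenotyping

The four per-cell marker means are z-scored **pooled across all subjects**
(sample sd, ddof = 1): clusters are compared across subjects and need a
common scale; a per-subject flag exists for sensitivity analyses. Cells are
embedded in a k-nearest-neighbour graph (Euclidean, k = 100) whose edges are
reweighted by the Jaccard overlap of the endpoints' neighbour sets; zero-
weight edges are dropped. Communities come from Louvain modularity
maximization (resolution 1.0, explicit seed) and are relabelled 1..K by
decreasing size. k = 100 is large relative to a four-marker space on purpose:
small k fragments genuine clusters (the tests show 3 planted components
splitting into 6 communities at k = 30 and recovered exactly at k = 100).
A warning threshold (default 12 clusters) guards against overclustering on
structureless data.

Cluster post-processing mirrors what is otherwise a manual curation step and
is therefore config-driven: clusters whose median z-scores for TMEM119,
P2RY12 *and* Iba1 all fall below a threshold (default −0.5) are flagged
non-microglial and removed; cluster pairs whose median z-profiles differ by
less than a configurable Euclidean distance (default 0 = off), or listed
explicitly, are merged. Labels are compacted after both steps.

Summaries are per-cluster marker medians (the heatmap input), per-cluster
cell counts, and per-subject/region prevalences (fractions of each subject's
cells, which sum to 1). The 2D overview embedding is t-SNE on the same
z-scored matrix (perplexity 30, PCA initialization, fixed seed).

## Spatial analysis and statistics

A cell *infiltrates* a plaque when its pixel set intersects the plaque mask
dilated by `plaque_dilation_px` (default 0 = direct overlap — the most
conservative reading; the dilation knob expresses "proximity"). A cell
touching several plaques is assigned once, to the plaque with the largest
overlap, ties to the lower plaque id. A plaque is *infiltrated* when at least
one cell infiltrates it. The all-mic vs Aβ-mic comparison contrasts, per
subject, the cluster composition of all cells with that of the infiltrating
subset; subjects with no infiltrating cells have an undefined Aβ-mic
composition and are excluded from paired tests (logged).

Two-group comparisons assess normality per group with Shapiro–Wilk at
α = 0.05 (constant samples are treated as non-normal), then use the two-tailed
unpaired Student's t-test (both groups normal) or the Mann–Whitney U test.
Paired data use the two-tailed paired t-test when the differences are normal
and the Wilcoxon signed-rank test otherwise — the non-normal paired branch is
this package's choice of the standard counterpart. A `force_test` override
pins the selection. Bonferroni correction multiplies p by the family size m
and caps at 1; the family definition (e.g. number of clusters tested) is a
configuration input. Correlation is Pearson's r with the two-sided p from the
t-distribution with n − 2 df.

## Synthetic data

The generator emulates the *structure* the pipeline assumes, not microscope
optics. Per cell: a flat soma disk (radius 4.5–6 px at the 0.5 µm/px working
resolution), 3–5 random-walk polyline processes 16–28 px long and 1–3 px wide
at 0.55× the soma amplitude, and a DAPI nucleus disk inside the soma (radius
max(4, 0.7·soma radius) ≈ 5 µm across, as real nuclei are). With probability
`detach_probability` (0.2 in the benchmark, matching the stated share of
detached processes) a process's root is erased over a 4 px gap — under the
10 px attachment radius, so the pipeline can reclaim it. Marker amplitudes
are drawn per cell from one of five nominal cluster profiles (homeostatic
P2RY12+TMEM119+, iron-associated FTL+Iba1+, intermediate, Iba1-only,
P2RY12-high); the profiles are qualitative shapes with free absolute scales,
and nothing downstream depends on those scales. Plaques are soft disks
(radius 9–15 px) on the Aβ channel; vessels are elongated dilated lines
> 4000 px on the autofluorescence channel. Channels are softened (Gaussian
σ = 0.7 px) and receive additive Gaussian noise (sd 5 against soma sums of
order 300–400 — "moderate": process-level SNR ≈ 6) clipped at 0. All
generators draw from a single explicitly-seeded RNG stream and are
bit-reproducible.

Cohort simulation plants the group contrasts the analysis is meant to
recover: AD subjects get more plaques and a higher proportion of the
FTL+Iba1+ cluster, and cells of the enriched cluster are placed adjacent to
plaques with their infiltration odds multiplied by the configured enrichment
(default 3×). A lighter, rendering-free cohort simulator
(`simulate_infiltration_cohort`) draws cluster labels and infiltration flags
directly at realistic cohort scale (12 subjects × 400 cells) and is used for
the power and calibration studies, where image rendering would add nothing to
the quantities under test.

### What passing on synthetic data does and does not show

The generator omits: uneven illumination and unmixing residuals, touching
nuclei from non-microglial cells, autofluorescent debris, intensity gradients
between grey and white matter, and truly continuous phenotype spectra (its
clusters are Gaussian and well separated at the default profiles). Passing
the benchmarks therefore shows the pipeline's logic is correct and its
planted effects recoverable — not that performance transfers to tissue, where
thresholds are recomputed per image and manual curation of clusters remains
necessary.

## Problem sizes and numerical choices

The test and acceptance workloads use 384×384 px fields with 22 cells each
(7 fields, 154 cells) for segmentation, n = 2000 / k = 100 for cluster
recovery, 20 + 200 simulated cohorts for power/calibration, and 500 random
images for the particle-counting oracle — sizes chosen so the full suite
completes in minutes on one core while keeping every estimate's Monte-Carlo
error well inside the asserted margins.

Other numerical decisions: component labelling uses 8-connectivity by default
(1 px diagonal processes stay connected; 4-connectivity is a config option);
intensity images are promoted to float64 internally, while thresholds are
computed on the native integer bins when the input is integer; the iron-stain
size window [4, 100] px is inclusive on both ends and applied after
labelling, so an over-large blob is excluded rather than split; dark-object
polarity (`gray <= threshold`) is the default for the DAB reaction product;
label masks round-trip through 16/32-bit unsigned TIFF; CSV exports are
comma-separated UTF-8 with '.' decimals and a mandatory header, and intensity
means are written at full precision (repr) so round trips are exact.

## Known limitations

* 2D only; no 3D stacks, no whole-slide pyramidal formats, no spectral
  unmixing (component images are taken as input).
* The level-set scheme assigns a pixel to the phase with the nearer mean;
  structures dimmer than the midpoint of foreground/background means (very
  faint processes) are unrecoverable by the cytoplasm pass and can only be
  reclaimed via the orphan-attachment stage.
* Louvain on kNN graphs is permutation-invariant only when the community
  structure is unambiguous; on plateau structure the partition may depend on
  row order.
* Cluster counts on real tissue depend on manual curation; only planted-truth
  recovery is claimed.
* The region (GM/WM) raster is an input; there is no automatic tissue
  classification. Without it every cell is reported as grey matter.
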