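# Methods

## Scope and model

`ctcscope` treats a cartridge scan as a set of co-registered 2-D intensity
grids, one per fluorescence channel, on a common pixel pitch (0.64 µm/pixel
for the 12-bit CellTracks scanner; 16-bit for the LED microscope).  The
analysis assumes (i) DNA staining marks every cell of interest, so
segmentation runs on DAPI alone; (ii) marker identity is decidable from
background-subtracted mean intensity plus geometry (stain area and overlap
with the nucleus); and (iii) touching cells need not be split pixel-wise —
they are counted as one event and typed by shape instead.

## Background subtraction

Each channel is filtered with a frequency-domain band-pass
`H(f) = (1 − G_low(f))·G_high(f)`, `G_σ(f) = exp(−|f|²/(2σ²))`.  The DC
component is removed exactly, so intensity gates are relative to a zero
background.  Defaults: `sigma_low = 1/50` cycles/px (removes illumination
structure coarser than ~50 px) and `sigma_high = 1/2` cycles/px (damps
pixel-scale noise); both are exposed in `FilterConfig`.  Because the filter
is a product of analytic Gaussians it equals a difference of two matched
spatial Gaussian blurs under periodic boundary conditions; the tests exploit
this with widths small enough (σ_f ≤ ~0.1 cycles/px) that the sampled spatial
kernels are alias-free, where the two routes agree to better than 1e-6
relative.

## Segmentation

Events are 8-connected components of DAPI pixels above
`max(k · σ̂, floor)` with `k = 3`; components under 4 px are dropped.  σ̂ is a
median-absolute-deviation estimate of the filtered image's spread
(1.4826·MAD), not the raw standard deviation: bright cells would otherwise
inflate their own detection threshold, which visibly fragments nuclei and
erodes marker rings in crowded fields.  The absolute floor (default 20 on the
12-bit filtered scale) guards the opposite corner: in a noise-free render the
MAD collapses to filter ringing, and nothing dimmer than the floor could pass
the mean-intensity ≥ 50 gate anyway.  Marker masks are thresholded the same
way inside a bounding box dilated by 5 px, keeping only stain components
(≥4 px) that touch the dilated nucleus, so a neighbour's stain does not leak
into an event's features.

## Shape scores and their calibration

Roundness is `1 − 4πA/P²` (clipped at 0) and P2A is `P²/(4πA)`; they satisfy
`p2a = 1/(1 − roundness)` wherever the clip is inactive.  `P` is the length
of the marching-squares contour of the mask after **one pass of closed-polygon
vertex smoothing** with kernel (0.18, 0.64, 0.18).  The smoothing weight is a
calibration constant, fixed by geometry before any pipeline tuning: the raw
marching-squares polygon of a digital disk overestimates 2πr by 7–9%
(p2a ≈ 1.15–1.19), which would push singles toward the doublet band, while
heavy smoothing (e.g. Gaussian pre-blur of the mask with σ ≥ 0.8 px) destroys
1-px-thin structures entirely.  One light pass leaves a digital disk at
p2a ≈ 1.05–1.08, a tangent disk pair at ≈ 2.07 (analytically 2), a 6-chain at
≈ 6.0 (analytically 6), and a 1×10 px bar within 10% of its crack length 22.
Scale invariance is meant physically: the same shape rasterized at k× finer
pitch reports ~k× the perimeter (within 2% for disks of r ≥ 10 px).
Replicating pixels k× (`np.kron`) is *not* that operation — it produces a
genuinely blockier polygon — and is not a supported equivalence.
Masks under 4 px have no meaningful contour: roundness reports 1, P2A
reports ∞, and the event is flagged degenerate (it cannot pass the gate).

## Gating, cluster bands, lineage rules

Gate thresholds follow the printed boundary semantics exactly: mean ≥ 50,
sd ≥ 20 pass at the boundary; size < 500 µm² and roundness < 0.95 fail at it.
P2A bands are left-closed: [1.5, 2.5) doublet, [2.5, 4) small cluster, ≥4
large cluster.  Marker presence is `mean > presence_threshold` (default 5 on
the filtered scale) — an idealized "0 vs >0" column never holds exactly in
noisy images.  Rules are evaluated CTC → leukocyte rows → non-specific →
bare/unstained; they are mutually exclusive by construction, so the order
only breaks ties at threshold boundaries.  Three deliberate choices where the
population table is ambiguous:

* The leukocyte rows carry their nucleus-overlay conditions (CD45 and/or
  CD16 overlay > 0) as the table lists them.
* The membrane-stain (">0" wga) column is enforced only for the
  bare-nucleus/unstained-cell split by default; a `strict_wga` flag applies
  it to every row.  Rationale: genuinely identified leukocytes frequently
  lack detectable membrane stain, so the literal reading would reclassify
  them as unidentified.
* CTC classification uses the table only (CK mean ≥ 50, overlay > 0.4, CK
  stain > 9 µm², CD45−/CD16−); no additional minimum-diameter morphology rule
  is stacked on top.

Channels absent from the panel count as "not present", which makes the CD16
rules inert on the base panel and removes the bare/unstained split when the
membrane stain was not acquired.

## Thumbnails and 8-bit casting

Event crops are padded to 80×80 with the median intensity of the crop's
boundary pixels (per channel); larger events are center-cropped for the
thumbnail while features always use the full mask.  12-bit scans cast to
8 bits as `round(v/4095·255)`.  16-bit LED scans are normalized per channel
by the 99.9th percentile of all thumbnail pixels of the sample (isolated
saturated pixels clip at 255); the percentile is computed per sample — a flag
for per-cohort pooling is not provided because the in-memory unit here is one
sample.

## Subsample-and-extrapolate

`n = clamp(round(0.10·N), min(1000, N), 5000)` events are drawn uniformly
without replacement with a recorded seed; per-class estimates are
`N·count/n`, rounded by largest remainder so they sum to N exactly (remainder
ties break toward the larger fractional part, then label order).  The
estimator is the standard unbiased expansion estimator; the test suite checks
its bias over repeated draws against binomial sampling error, which slightly
overstates the true (hypergeometric) spread and is therefore conservative.

## Cohort statistics

Totals are compared with a two-sided Mann–Whitney U test on
`log10(count + 1)`; the +1 offset accommodates zero counts.  When the smaller
group has ≤ 8 observations and there are ≤ 25 in total, the p-value is exact:
the U distribution is enumerated over all C(n1+n2, n1) group assignments with
midranks for ties, and p = P(|U − n1·n2/2| ≥ |u_obs − n1·n2/2|).  Larger
problems use the normal approximation with tie correction.  Replicate
variability is summarized as CV% = 100·sd/mean (sample sd).  No
multiple-testing adjustment is applied; p-values are reported raw.

## The simulator

The generator renders what the gates and rules consume, not microscope
physics.  Nuclei are Gaussian-smoothed disks (radius 5 ± 0.8 µm by default);
doublets and clusters are chains of 2 / 3–5 / 6–8 near-tangent disks
(spacing 1.95 r along a gently turning walk, tightened until connected),
which gives the analytic P2A signature by construction.  Cytokeratin is a
filled disk of 1.4 r (so nucleus overlay ≈ 1 and stain area ≫ 9 µm²);
membrane markers (CD45, CD16, wga) are annuli from 0.8 r to 1.3 r, straddling
the nucleus edge so their nucleus overlay is positive but partial.  Artifacts:
a smooth multiplicative illumination field with mean exactly 1 and bounded
relative amplitude (default 0.2 on a 100 px scale); Poisson shot noise plus
Gaussian read noise (sd 10) over a background of 100 counts; and fragmented
staining, implemented by masking a marker blob with a random ~50%-coverage
patch field (default probability 0.1).  Default composition is a
granulocyte-dominated mix typical of an enriched sample (CD16+ 45%, CD45+
15%, CD45+/CD16+ 10%, bare nuclei 15%, unstained 10%, CTC 5%), with 80%
singles.  Placement is uniform, optionally with a minimum distance enforced
between individual nuclei (not cluster centroids); footprints crossing the
border are re-placed or clipped per configuration, and if the spacing
constraint saturates, the cell is placed unconstrained with a warning.

What the simulator does **not** emulate: optical point-spread functions,
ferrofluid light absorption, chromatic registration errors, autofluorescence
texture, or realistic intensity distributions — the background and noise
levels are chosen for test coverage, since no quantitative description of
real levels is available.  Passing tests therefore demonstrate that the
*rules and estimators* are implemented correctly and recover known truth
under controlled degradation; they do not validate performance on real
cartridges.

## Learning harness

The thumbnail segmenter is a two-level U-net written directly in numpy
(im2col/GEMM convolutions with hand-derived backward passes, float32): two
3×3 conv+ReLU layers (8 filters), 2×2 max-pool, a 16-filter bottleneck,
nearest-neighbour upsampling concatenated with the skip tensor, a 3×3
decoder conv and a 1×1 logit head.  Loss is pixel-wise binary cross-entropy;
the optimizer is Adam (lr 1e-3); training uses batch 16 for ten epochs on a
seeded 80/20 train/validation split, which finishes in well under a minute on
one CPU for a few hundred 80×80 thumbnails.  Supervision comes from threshold
masks of events in clean, sparse samples, channels separated — one training
pair per channel per event — mirroring how trusted classic segmentations
supervise the network.  Determinism: identical seeds give identical weights;
analytic gradients are verified against central differences in the test
suite.  At inference the mask is `sigmoid(logit) > 0.5`, and downstream
features and lineage rules are computed by exactly the same code as the
threshold path, on the background-filtered intensities placed into the
thumbnail frame.

## Problem sizes in the test and acceptance runs

Unit and property tests use 256–1024 px images with 12–140 cells; the
end-to-end recovery check uses a 1536² cartridge with 300 cells spanning all
six populations; the extrapolation check uses a 20,000-event label population
with 200 seeded draws; the learning checks train on 200 easy thumbnails and
on ~300 sample-derived pairs.  These sizes were chosen so each property is
measured with comfortable statistical margin while the whole suite stays
desk-scale.

## Known limitations

* Crowded fields merge footprints by design; merged events inherit a single
  (majority) identity, so per-class counts blur as density approaches the
  packed regime.
* The perimeter estimator is calibrated for cell-scale blobs (r ≥ ~5 px);
  very small masks score high P2A and conservatively fall toward cluster
  bands.
* The intensity gates assume the 12-bit CellTracks scale; LED (16-bit) data
  pass through the same gates only after the percentile-based 8-bit
  normalization or with user-adjusted thresholds.
* The numpy U-net is a desk-scale harness: it demonstrates the training
  contract and the feed-back path, not state-of-the-art segmentation.
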