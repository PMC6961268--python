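# Methods

## The assay model

Each target transcript is captured by a padlock probe carrying a 4-nt
barcode; editing sites are interrogated by a probe pair differing only in
the 3′ base (A or G) and the barcode, so an editing site contributes two
codebook entries (`edited_variant` / `unedited_variant` sharing a
`site_id`). Markers (Sst, Pvalb, Vip, Cck, Nrn1 → interneuron; Pcp4, Ndnf →
pyramidal; Plp1, Enpp2 → oligodendrocyte; Gfap → astrocyte) and the ADAR
enzyme transcripts are additional single-barcode targets. Rolling-circle
amplification produces one fluorescent spot per captured molecule; the
barcode is read over L = 4 cycles in 4 channels. The channel order A, C, G,
T mapping to channels 0–3 is a package constant used consistently by the
decoder and the simulator (the assay itself does not fix an order).

## Decoding

**Registration.** Each cycle's merged signal (A+C+G+T) is aligned to the
first cycle's general stain by the integer translation at the FFT
cross-correlation peak (no phase normalization, i.e. plain cross-
correlation). Sub-pixel models are deliberately not fitted: spots are
re-extracted with a window maximum, which absorbs ≤ 1 px residual error.
Flat (zero-variance) images make registration undefined and raise.

**Spot detection.** The general stain is enhanced with a white top-hat
(disk radius 3 px by default), then smoothed with a small Gaussian
(σ = 1 px by default) before peak finding — the smoothing step is our
addition; it suppresses single-pixel noise maxima that would otherwise
seed spurious watershed basins on noisy images. Local maxima above
`min_intensity` seed a watershed on the inverted enhanced image so touching
amplicons split; each basin contributes one spot at its intensity maximum.

**Base calling and quality.** Per cycle the called base is the argmax
channel; ties are broken by the fixed channel order A<C<G<T (deterministic,
and of measure zero under noise). The per-base quality is
`max / sum` over the four channel intensities. This is the unique simple
statistic with exactly the documented range: it equals 0.25 when all four
channels are equal (pure ambiguity) and 1 when a single channel carries all
signal, and it is adopted here as the normative definition. The read
quality is the minimum base quality over cycles. A cycle with zero total
intensity makes the spot uncallable; it is flagged and excluded with that
reason rather than given a pseudo-quality.

**Matching and thresholding.** Barcodes are matched to the codebook
exactly — no 1-mismatch rescue, consistent with reporting an
unexpected-read fraction. `pass_qc ⇔ quality ≥ threshold ∧ matched` (the
matching requirement can be disabled). The default threshold 0.40 sits
mid-range of the working 0.35–0.5 interval; alternatively the threshold is
calibrated as the smallest value on the {0.25, 0.26, …, 1.00} grid (0.01
steps, matching two-decimal reporting) at which matched reads make up
≥ 95% (configurable; 96% is the other used value) of all passing reads.
If unattainable, 1.00 is returned with a warning flag. Count conservation
(`n_total = n_pass + n_fail`) holds for every filter call.

## Cells and regions

Nuclei: Otsu threshold → distance-transform watershed to split touching
nuclei → area bounds (and optional solidity ≥ 0.8) as a reproducible proxy
for shape-descriptor filtering. Cells: each nucleus is expanded by ≤ 20 px
*Euclidean* distance (the pixel unit is left uncalibrated on purpose;
physical pixel size is not modeled); contested pixels go to the nearest
nucleus, which draws the watershed-style frontier on the perpendicular
bisector and keeps cells pairwise disjoint. Reads take the cell label
covering their coordinate (0 = unassigned background) and the ROI polygon
containing them, boundary-inclusive for determinism at ROI edges;
overlapping ROI polygons are rejected at load since the anatomical regions
are disjoint.

## Editing quantification

`level = n_edited / (n_edited + n_unedited)` over pass-QC reads; a zero
denominator is NA, and NA propagates everywhere instead of being imputed
as zero. Coverage filters (all boundaries inclusive, ≥):

| filter | scope | rule |
|---|---|---|
| 500 reads | whole tissue | replicate-mean of min(n_edited, n_unedited) ≥ 500 at ≥ 1 stage |
| 100 reads | region × replicate | combined variant reads ≥ 100 |
| 100 cells | marker stratum | replicate-mean qualifying cells ≥ 100 |
| 20 cells | class × replicate | qualifying cells ≥ 20 |

A qualifying cell for the cell-count filters carries the marker **and** at
least one read of either site variant; whether the original analysis
required the site read for the 100-cell count is not stated, and this
definition is our recorded choice.

Replicate aggregation is the unweighted mean of per-replicate levels with
the ddof = 1 sample SD (NA for a single replicate) — not pooled counts —
matching mean ± SD reporting per stage; pooled counting remains available
by summing the tidy count tables. Editing ratios are computed per
replicate (`level_in / level_out` against the complement stratum:
whole-minus-region, or marker-negative cells) and then replicate-averaged;
either side failing its coverage filter propagates NA.

ADAR2 decomposition: editing at the intronic −1 site creates the
alternative splice site that yields the frameshifted **inactive** isoform,
so `inactive = round(level_auto × total)` with half rounding *up* on the
inactive side (a determinism choice; only proportions are scientifically
meaningful) and `active = total − inactive`.

Cell classification is non-strict multi-label: a cell is positive for a
class if it has ≥ 1 read of any of the class's markers (threshold
configurable), and a cell with markers of several classes belongs to all
of them. Marker-negative means zero reads of that marker, including cells
positive for other markers.

## Mixed-cell null model

For one site, the denominator is the cells with ≥ 2 reads of the site's
transcript (both variants combined); a mixed cell has ≥ 1 read of each
variant. (A figure-caption phrasing of the source analysis instead
suggests "≥ 1 read of each variant" as the denominator; the main-text
definition is the one implemented, and the discrepancy is documented here,
not resolved.) Under the null that each read is independently edited with
probability p — taken as the level pooled over *all* reads of the site in
the stratum — a cell with n reads is mixed with probability
`1 − p^n − (1−p)^n`, and the expectation conditions on the full observed
read-count histogram (not a mean n, since the expectation is strictly
concave in n). The expectation is symmetric in p ↔ 1−p and maximal at
p = 0.5. Observed and expected proportions across sites are compared by
Pearson correlation; sites with observed < expected are flagged
under-represented (heterogeneity/bimodality signal). No formal test of
under-representation is attached, matching the descriptive use.

## Rank statistics

Kruskal–Wallis with mid-ranks and the standard tie correction
(editing levels from small count tables tie frequently), p from
χ²(k−1); all-identical data returns H = 0, p = 1. Dunn's pairwise z uses
the tie-corrected rank variance `N(N+1)/12 − Σ(t³−t)/(12(N−1))`, two-sided
normal p, Šidák family-wise adjustment `1 − (1−p)^m` over the
m = k(k−1)/2 pairs (Bonferroni behind a flag). "Dunn–Šidák" is interpreted
as this standard pairing. With the replicate counts this field works at
(2–5), the χ²/normal p-values are asymptotic; an exact permutation p for H
(full enumeration) is provided for N ≤ 10 as an oracle. On small-N
fixtures the χ² p tracks the exact permutation p to within 0.15 absolute
(e.g. {1,2,3} vs {4,5,6}: H = 3.857, χ² p = 0.0495 vs exact 2/20 = 0.10);
that tolerance is what the cross-check asserts.

## Synthetic scenes

The generator emulates the data structure the analysis assumes: nuclei
rejection-sampled with pairwise center distance ≥ 2 r (default r = 6 px;
an optional larger spacing produces contest-free scenes), cell classes
drawn by configured proportions, cell region decided by nucleus center
point-in-polygon (unambiguous ground truth), per-cell read counts Poisson,
and per-read targets drawn as class markers / ADAR probes / site variants
with a per-(site, region, class) editing probability table (wildcards
resolve exact → region → class → default). Reads are placed uniformly in
the soma disk of radius r + 20 px, matching the downstream fixed-distance
cell model so noiseless assignment is essentially exact; a 1 px guard band
inside the nominal rim keeps rim reads inside the pixel-discretized
expanded cell, since segmented nucleus boundaries are only pixel-accurate.
Intensities per cycle: the true channel gets the signal level, others the
background level, then the 4×4 crosstalk matrix, additive i.i.d. Gaussian
noise, and clipping at zero (physical nonnegativity, which also keeps the
quality statistic in its analytic range). A configured fraction of reads
receives a barcode absent from the codebook (unexpected reads). Rendering
stamps an isotropic Gaussian (σ = 1.5 px) per spot and blurred nucleus
disks for DAPI; the general stain is the channel sum. Identical configs
(including the seed) give bit-identical tables and images.

What the generator does **not** emulate: tissue autofluorescence fields,
tile stitching artifacts and the tile-edge cell correction, z-stacks,
optical PSFs beyond Gaussian spots, segmentation-error-driven read
misassignment beyond soma overlap, and panel versioning (one codebook per
run). Passing tests therefore demonstrate correctness of the computations
and their filters on data with the assumed structure — not robustness to
every artifact of real tissue images.

## Problem sizes and defaults

Simulated validation scenes use a few hundred cells with tens of reads per
cell. Real sections average 1.9–6.2 reads/cell over 10⁴–10⁵ cells; the
package's scenes compress the cell count and raise per-cell depth so the
same absolute coverage filters (500/100/100/20) are exercised at desk
scale — the filters, not the per-cell depth, drive the analysis. The demo
run uses 3 replicates × 300 cells × Poisson(110) reads, a 22-site panel
with 7 deliberately scarce sites (15 retained), four rectangular ROIs, and
thalamic editing configured 0.10 above the other regions; its recovered
mean thalamus editing ratio is ≈ 1.19.

## Known limitations

- Registration is integer-translation only; rotation/scaling drift is out
  of scope.
- Exact barcode matching: a single miscalled base drops the read rather
  than rescuing it.
- Asymptotic p-values at replicate counts of 2–5 carry the usual caveat;
  the exact-permutation option is limited to N ≤ 10.
- The mixed-cell analysis is descriptive (no significance attached to
  under-representation).
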