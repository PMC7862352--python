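# Methods

`chrombarcode` implements a cell-cycle ChIP-seq analysis pipeline for
histone post-translational modifications (H3K9ac, H3K4me3, H3K27me3): reads
are quantified in rolling windows, normalized across samples, correlated
between cell-cycle phases and cell types, rendered as pseudo-karyotypes, and
compared at the level of biological features (TSS windows, gene bodies,
TADs) with an intensity-difference outlier statistic and bivalency quadrant
classification. A synthetic-data generator provides a fully specified truth
set so every stage can be verified without external data.

## Rolling-window quantification and normalization

Windows of size W are placed every `step` bp along each chromosome (a
partition when step = W; the terminal window is clipped at the chromosome
end). Two counting rules are offered:

* **midpoint** (default): a read is assigned to every window containing its
  midpoint — exactly one window when step = W, giving exact count
  conservation;
* **overlap**: a read contributes to every window it overlaps by at least
  1 bp (the behaviour of some interactive genome-quantification tools).

Midpoint is the default because its conservation property makes counts
testable against brute-force oracles; the choice matters little above a few
hundred bp.

Normalized values are

    value_i = log2( raw_i × reference_total / total_reads + pseudocount )

with `reference_total` the largest library size among the samples being
compared, so all tracks share one scale. The default pseudocount of one
read-equivalent keeps zero-count windows at exactly 0 and avoids log of
zero; it is added after library scaling.

## Correlation, the elbow, and depth titration

Pairs of tracks on identical grids are compared by the Pearson
product-moment coefficient over all windows finite in both tracks (windows
lost to zero-variance guards are dropped pairwise). The coefficient is
computed directly as Sxy/√(Sxx·Syy); this form returns exactly 1.0 for a
track against itself, which the test suite relies on.

Scanning W from 100 bp to 1 Mb (log-spaced, step = W except where a step is
explicitly requested) produces the R-vs-W curve: R is near 1 at large W and
falls as windows become small enough that per-window counts are dominated
by Poisson noise. The **knee estimate** is the W maximizing the
perpendicular distance from the chord joining the curve's endpoints in
(log10 W, R) space — a deterministic, documented proxy for the visual
"elbow". It returns nothing for flat curves or fewer than three points.

`depth_titration` downsamples both samples (each read kept independently
with probability f, seeded) and recomputes the curve per fraction; reducing
depth lowers R at small W and shifts the knee toward larger windows,
because the elbow is a counting-noise phenomenon, not a biological scale.

## Pseudo-karyotypes

Window values are averaged into genomic pixels (default 1.5 Mb, the
approximate resolution of a metaphase immunofluorescence image) and mapped
linearly from red (low) through yellow to green (high) between the 5th and
95th percentiles of the pixel-value distribution pooled over **all** tracks
rendered together, so phases share one scale bar. Zero-coverage regions
(centric heterochromatin) sit at the value floor and render red; pixels
with no underlying windows render grey. Chromosomes are drawn as vertical
ideograms, one column per track per chromosome, labelled with the built-in
bitmap font. Rendering is purely a function of the input values:
identical inputs give byte-identical PNGs.

## Feature-level quantification

All feature windows are strand-oriented and anchored at the TSS (start of
a '+' gene, the 5'-most base of a '-' gene):

* proximal TSS window: −500 to +750 bp (the −1 nucleosome through the
  first three downstream nucleosomes);
* gene-body window: +750 to +1750 bp.

Offsets are taken from the TSS regardless of gene length (short genes are
not truncated), keeping windows comparable across genes. One TSS per
gene_id. Windows extending past a chromosome end are clipped; windows
falling entirely outside are dropped with a warning.

TAD-level counts are corrected for interval length ("probe size"): the
library-scaled count is divided by the interval length in kb before the
log2, so a TAD twice as long with proportionally more reads scores the
same.

Metagene profiles map read midpoints to strand-signed offsets from each
TSS over ±5 kb in 100 bp bins; per-bin library-scaled counts are averaged
over genes (mean over genes, not reads, so large genes do not dominate).

Gene density of a region set is the number of TSS falling in the merged
union of the intervals divided by the union length in Mb.

## Intensity-difference outlier statistic

For paired per-feature values (x_i, y_i) with difference d_i = y_i − x_i
and mean intensity m_i = (x_i + y_i)/2, the statistic asks whether d_i is
extreme **relative to features of similar intensity** — count data are
noisier at low intensity, so a global null would flag only low-intensity
features. The local null for feature i is a normal distribution fitted to
the d values of the k = max(⌈frac·n⌉, min_k) features nearest in m
(default frac = 1%, min_k = 50), found as the tightest contiguous block in
m-sorted order excluding i itself. p_i is the two-tailed normal tail
probability; Benjamini–Hochberg q values are reported alongside, but
selection defaults to raw p (both permissive p < 0.5 and strict p < 0.05
thresholds are in routine use for this statistic). Features whose local
sigma is zero are flagged untestable (p missing). Swapping conditions
negates every d and leaves every p unchanged.

Calibration, verified by the test suite under an exchangeable null at
n = 10,000: the p < 0.05 fraction lies in [0.04, 0.06] and the KS distance
of p from uniform is below 0.02; 4σ planted shifts are recovered with
recall ≥ 0.9 at p < 0.05.

## Tail selection and quadrant classification

`select_tails` ranks windows by d and takes the outlying fraction (default
3%) on each side, ties broken by feature order (stable sort). Genes are
attached to selected windows by the TSS-membership rule.

Bivalency quadrants classify genes by TSS-level H3K4me3 and H3K27me3 into
neither / K4_only / K27_only / bivalent. Thresholds are either supplied or
estimated per mark as the density valley between the two most prominent
modes of a Gaussian-KDE of the marginal distribution (evaluated on a grid
padded beyond the data range so edge modes register); unimodal marginals
raise an error demanding explicit thresholds. Values exactly at a
threshold count as low. Cross-phase tracking applies one set of thresholds
to both phases and reports the 4×4 transition matrix and the stability
score (trace/total). Per-quadrant expression summaries report the
five-number summary with genes lacking expression dropped and counted.

## The synthetic-data generator

The generator emulates the structure these analyses assume, at desk scale
(default: one 20 Mb chromosome):

* **Bands** — gene-dense enriched regions covering 45–55% of each
  chromosome. Band sizes follow the 10–50 Mb scale of metaphase
  immunofluorescence bands where the chromosome permits; on a 20 Mb
  desk-scale chromosome the coverage budget yields a single ~10 Mb band.
* **Sub-bands** — 1–5 Mb tiles within bands, each with an enrichment
  multiplier drawn uniformly from 2–6 (the literature gives no quantitative
  magnitudes; these are calibration choices). Two cell types built from the
  same seed share all coordinates; ~25% of sub-band multipliers (at least
  one per chromosome) are redrawn from a cell-type-specific stream, making
  the banding cell-type-specific while the skeleton is shared.
* **Heterochromatin** — one centric block per chromosome at a multiplier
  of 0.02 (near-zero signal for every mark).
* **Genes** — placed at 24/Mb inside bands and 4.8/Mb outside (≥3× ratio,
  genome average ≈14/Mb), log-normal lengths (median 8 kb, clipped
  1.5–60 kb), random strand. Classes: silent (30%), mitotic (6% of active),
  housekeeping (20% of active), and small fixed ribosomal-protein sets
  (RP_large/RP_small).
* **TSS shape** (active marks, non-silent genes) — two Gaussian bumps
  (σ = 80 bp) at ±150 bp modelling the −1/+1 nucleosomes, a multiplicative
  nucleosome-free dip at the TSS (half-width 100 bp, depth 0.9), and an
  exponential gene-body tail with decay length 700 bp, which returns the
  signal to baseline by roughly 2 kb. Peak amplitude is 25× the local
  background.
* **H3K27me3** — broad domains over silent genes (gene body ±20 kb),
  clipped at the boundaries of the TAD containing the gene; amplitude 4×
  background. K27 does **not** inherit the acetylation sub-band
  multipliers — its domain structure is its banding; sharing the
  multipliers would correlate the K4 and K27 baselines and manufacture
  spurious bivalent promoters.
* **TADs** — tile each chromosome with lengths 0.5–2 Mb.
* **Phase effects** — (class, phase) → amplitude multipliers on the TSS
  and/or gene-body kernel components. Defaults: mitotic genes ×4 on the
  gene-body component in G2M; RP genes ×2.5 on the TSS component (×1.5
  body) in M, emulating mitotic-gene acetylation in G2M and the persistence
  of RP-gene TSS signal through metaphase.

Reads are drawn by sampling midpoints proportionally to the per-position
intensity (10 bp resolution), exactly `depth` reads per simulation, fixed
150 bp unstranded fragments (mononucleosome scale). Every random draw
comes from one seeded generator per call; no global state.

**What the generator does not emulate:** sequence composition,
mappability or GC bias, PCR duplicates, fragment-length variation, diffuse
enhancer signal, isoform structure, and replication-timing effects.
Passing tests therefore demonstrate the correctness and calibration of the
pipeline's computations on data with the assumed banded structure — not
that real libraries satisfy those assumptions.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open everywhere; GTF input is shifted at
  the boundary. Strand '.' is allowed for reads, required for genes.
* Zero-variance tracks yield a missing R with a warning rather than an
  error; titration at near-zero surviving depth propagates missing points.
* round(fraction·n) features per tail; fraction·n < 1 is an error.
* The knee estimator treats a maximum chord distance ≤ 1e-12 as "no knee".
* bedGraph output carries six decimals; NaN is written as the literal
  sentinel `nan` and read back as missing.
* Window/feature counting is vectorised (difference-array and binary
  search); brute-force O(n·m) scans in the test suite verify exact
  agreement on randomized instances.

## Problem sizes used in the verification suite

The test suite and `scripts/acceptance.py` run everything on a 20 Mb
single-chromosome model at 10⁶ reads per sample (per-window counts at 5 kb
comparable to a deeply sequenced human library), 20 seed pairs for the
depth-titration comparison and 10 for the rendering contrast test. The
bundled demo config uses 12 Mb / 1.5×10⁵ reads per sample.

## Known limitations

* At desk scale, the plain 3%-tail selection between cell types is
  dominated by shot noise in the near-empty heterochromatin block (log2
  differences between 0 and 2 reads exceed the planted band contrast), so
  tail gene densities can be zero — the same low-count pathology that
  produces the R-vs-W elbow. The intensity-difference statistic, whose
  local null absorbs this intensity dependence, selects gene-dense banded
  windows instead; the acceptance script reports both.
* The quadrant threshold estimator needs visibly bimodal marginals; at
  very low depth the discreteness of counts can hide the valley, in which
  case explicit thresholds must be supplied.
* The knee estimator depends on the endpoints of the scanned W range;
  curves truncated before the plateau bias the knee upward.
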