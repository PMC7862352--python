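# chrombarcode

Analysis of the "chromosomal bar code": the cell-type-specific, cell-cycle-
stable banding of histone modifications (H3K9ac, H3K4me3, H3K27me3) seen in
ChIP-seq of sorted G1, G2M and M populations. The package is aimed at
epigenomics researchers who want to quantify and compare histone-PTM tracks
across cell-cycle phases and cell types at scales from single nucleosomes
to whole-chromosome bands.

## What it computes

* **Rolling-window signal tracks** — reads counted in windows of size W
  every `step` bp and normalized as
  `value = log2(raw · N_ref / N + pseudocount)`, with `N_ref` the largest
  library in the comparison set.
* **R-vs-W elbow analysis** — Pearson R between two tracks as a function of
  window size (100 bp – 1 Mb). R ≈ 1 at large W and drops at small W as
  per-window counts become noise-dominated; the elbow W* is estimated as
  the point of maximum distance from the chord in (log₁₀W, R) space, and a
  depth-titration mode shows the elbow shifting right as reads are
  downsampled.
* **Pseudo-karyotypes** — tracks averaged into ~1.5 Mb pixels and rendered
  as red→green vertical ideograms on a shared percentile-anchored scale,
  emulating antibody-stained metaphase spreads.
* **Feature scores** — strand-aware proximal-TSS (−500..+750 bp) and
  gene-body (+750..+1750 bp) windows, length-corrected TAD quantification,
  metagene profiles over ±5 kb around all TSS, and gene densities of window
  sets.
* **Comparative statistics** — the intensity-difference outlier test
  (each feature's between-condition difference d tested against a normal
  fitted to the d of the ~1% of features nearest in mean intensity),
  3%-tail selection, bivalency quadrant classification
  (H3K4me3 × H3K27me3 with valley-estimated or explicit thresholds) with
  cross-phase transition tracking, and per-quadrant expression summaries.
* **Synthetic data** — a generator planting bands (45–55% coverage),
  1–5 Mb sub-bands with cell-type-specific multipliers, centric
  heterochromatin, TADs, classed genes, bimodal TSS peaks with a
  nucleosome-free region, TAD-confined H3K27me3 domains and phase effects
  (mitotic genes up in G2M, RP genes marked through M) — the truth set
  behind every test.

See `docs/methods.md` for the full model and parameter documentation.

## Worked example

```sh
chrombarcode run --demo --out demo_out --seed 7
```

simulates three marks in G1 and G2M on a 12 Mb genome and runs every stage.
`demo_out/summary.txt` from that exact command:

```
pearson_r	{'H3K9ac:G1_vs_G2M_W5000': 0.9825, 'H3K4me3:G1_vs_G2M_W5000': 0.982, 'H3K27me3:G1_vs_G2M_W5000': 0.9755}
knee_W_bp	2000.0
outlier_count	19
tail_gene_density_per_mb	{'lower': 0.0, 'upper': 19.44}
quadrant_counts	{'neither': 13, 'K4_only': 69, 'K27_only': 48, 'bivalent': 25}
quadrant_stability	0.9871
```

Reading it: the two phases correlate at R ≈ 0.98 in 5 kb windows for all
three marks (histone modification patterns barely change through the cell
cycle); the R-vs-W curve has its elbow near 2 kb at this depth; 19
gene-body windows are intensity-difference outliers at p < 0.05 (driven by
the planted mitotic-gene G2M effect); and 98.7% of genes keep their bivalency
quadrant from G1 to G2M. The run directory also contains `karyo.png` (the
red-green pseudo-karyogram), `curve.tsv` (R per window size and titration
fraction), per-sample bedGraph tracks, TSS/TAD quantifications and the
truth files of the simulated genome, plus `manifest.json` recording every
resolved parameter and seed — rerunning with the same config and seed
reproduces every output byte for byte.

The same stages are available as library functions
(`chrombarcode.quantify`, `elbow_curve`, `intensity_difference`,
`classify_quadrants`, …) and as individual subcommands (`simulate`,
`quantify`, `correlate`, `karyotype`, `features`, `outliers`,
`quadrants`).

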