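"""Synthetic ChIP-seq genomes with banded, phase-specific structure.

The generator emulates the statistical structure of cell-cycle-sorted
histone-PTM ChIP-seq on human-like chromosomes, at desk scale:

* gene-dense enriched **bands** covering 40-60% of each chromosome, composed
  of 1-5 Mb **sub-bands**, each carrying a cell-type-specific enrichment
  multiplier (two cell types share band coordinates but differ in ~25% of
  sub-band multipliers);
* a near-silent centric **heterochromatin** block per chromosome;
* genes placed preferentially inside bands (>=3x density ratio), with class
  labels (silent, housekeeping, mitotic, RP_large, RP_small);
* sharp bimodal **TSS peaks** with a nucleosome-free dip for H3K9ac and
  H3K4me3, decaying exponentially into the gene body (back to background by
  roughly 2 kb for the default decay length of 700 bp);
* broad **H3K27me3 domains** over silent genes, clipped at the boundaries of
  the TAD containing each gene;
* **phase effects**: mitotic genes gain gene-body acetylation in G2M, and
  ribosomal-protein genes retain strong TSS signal through M.

Reads are drawn from the resulting position-dependent intensity; exactly
``depth`` reads are emitted per simulation, all reproducible from a single
integer seed.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    GenomeLayout,
    GeneAnnotation,
    IntervalSet,
    ReadCollection,
    SampleMeta,
    write_gene_classes,
    write_genes_bed,
    write_intervals_bed,
)

MARKS = ("H3K9ac", "H3K4me3", "H3K27me3")
ACTIVE_MARKS = ("H3K9ac", "H3K4me3")

_BIN = 10  # bp resolution of the simulation intensity profile

# Calibration defaults (the paper-scale structure gives no magnitudes):
_SUBBAND_MULT_RANGE = (2.0, 6.0)
_CELL_SPECIFIC_FRACTION = 0.25
_HET_MULT = 0.02
_TSS_AMP = 25.0  # peak-to-background ratio of the +1 nucleosome bump
_K27_DOMAIN_AMP = 4.0
_K27_SPREAD = 20_000  # bp each side of a silent gene body
_GENE_DENSITY_IN = 24.0  # genes per Mb inside bands
_GENE_DENSITY_OUT = 4.8  # genes per Mb outside (5x ratio; genome mean ~14/Mb)


@dataclass(frozen=True)
class TssShape:
    """Geometry of the TSS signal: -1/+1 nucleosome bumps at ±plus1_center
    flanking a nucleosome-free dip of half-width nfr_halfwidth, with an
    exponential gene-body tail of the given decay length (signal reaches
    background by ~2000 bp at the default 700 bp)."""

    nfr_halfwidth: int = 100
    plus1_center: int = 150
    decay_length: int = 700

    def __post_init__(self) -> None:
        if self.plus1_center <= 0 or self.decay_length <= 0:
            raise ValueError("plus1_center and decay_length must be > 0")


@dataclass
class SyntheticModel:
    """Full generative layout: genome, bands, genes, TADs, phase effects."""

    layout: GenomeLayout
    cell_type: str
    bands: IntervalSet
    sub_bands: IntervalSet  # extra column: multiplier
    heterochromatin: IntervalSet
    tads: IntervalSet
    genes: GeneAnnotation
    tss_shape: TssShape = field(default_factory=TssShape)
    # (gene class, phase) -> {'tss': m, 'body': m} amplitude multipliers
    phase_effects: dict = field(default_factory=dict)
    background_rate: float = 0.01  # nominal reads/bp at multiplier 1

    def to_dict(self) -> dict:
        return {
            "cell_type": self.cell_type,
            "chromosomes": list(map(list, self.layout.chromosomes)),
            "tss_shape": vars(self.tss_shape).copy(),
            "phase_effects": {
                f"{cls}|{phase}": eff for (cls, phase), eff in self.phase_effects.items()
            },
            "background_rate": self.background_rate,
            "n_genes": len(self.genes),
            "n_bands": len(self.bands),
            "n_sub_bands": len(self.sub_bands),
        }


def default_phase_effects() -> dict:
    return {
        ("mitotic", "G2M"): {"body": 4.0},
        ("RP_large", "M"): {"tss": 2.5, "body": 1.5},
        ("RP_small", "M"): {"tss": 2.5, "body": 1.5},
    }


def _rng_for(seed: int, *tokens: str) -> np.random.Generator:
    """One seeded generator per logical stream; no global state."""
    entropy = [int(seed)] + [zlib.crc32(t.encode()) for t in tokens]
    return np.random.default_rng(entropy)


def _chunk_lengths(rng, total: int, lo: int, hi: int) -> list[int]:
    """Split `total` into chunks of length ~U(lo, hi); remainder < lo is
    absorbed into the final chunk."""
    out: list[int] = []
    left = total
    while left > 0:
        c = int(min(left, rng.uniform(lo, hi)))
        if left - c < lo:
            c = left
        out.append(c)
        left -= c
    return out


def build_default_model(
    n_chrom: int = 1,
    chrom_length: int = 20_000_000,
    cell_type: str = "LCL",
    seed: int = 0,
    tss_shape: TssShape | None = None,
    phase_effects: dict | None = None,
) -> SyntheticModel:
    """Build a banded genome model.

    Band coordinates, gene placement, TADs and class labels are drawn from a
    stream shared by all cell types, so two models built with the same seed
    but different ``cell_type`` have identical coordinates and differ only in
    the ~25% of sub-band multipliers redrawn from a cell-type-specific
    stream.  Band sizes follow the 10-50 Mb scale where the chromosome
    permits; shorter chromosomes receive a single band holding the 40-60%
    coverage budget.
    """
    min_band = 10_000_000
    if chrom_length < min_band:
        raise ValueError(
            f"chrom_length {chrom_length} too small to host one band (>= {min_band} bp)"
        )
    shared = _rng_for(seed, "shared-structure")
    cellrng = _rng_for(seed, "cell", cell_type)

    layout = GenomeLayout(tuple((f"chr{i + 1}", chrom_length) for i in range(n_chrom)))

    band_rows, sub_rows, het_rows, tad_rows = [], [], [], []
    gene_rows: list[tuple] = []
    gid = 0
    for ci, (chrom, L) in enumerate(layout.chromosomes):
        coverage = shared.uniform(0.45, 0.55)
        budget = int(coverage * L)
        band_lens = _chunk_lengths(shared, budget, min(min_band, budget), 50_000_000)
        n_gaps = len(band_lens) + 1
        gap_w = shared.random(n_gaps) + 0.2
        gap_lens = np.floor(gap_w / gap_w.sum() * (L - budget)).astype(int)
        gap_lens[-1] += (L - budget) - int(gap_lens.sum())

        pos = 0
        gaps: list[tuple[int, int]] = []
        for bi, blen in enumerate(band_lens):
            gaps.append((pos, pos + int(gap_lens[bi])))
            pos += int(gap_lens[bi])
            bs, be = pos, pos + blen
            band_rows.append((chrom, bs, be, f"band_{chrom}_{bi}"))
            pos = be
        gaps.append((pos, L))

        # sub-bands tile each band; multipliers drawn once from the shared
        # stream, a cell-specific fraction redrawn from the cell stream.
        # At least one sub-band per chromosome is always cell-specific so
        # any two cell types differ somewhere on every chromosome.
        chrom_subs = []
        for chrom_b, bs, be, bname in [r for r in band_rows if r[0] == chrom]:
            cursor = bs
            for si, slen in enumerate(_chunk_lengths(shared, be - bs, 1_000_000, 5_000_000)):
                mult = float(shared.uniform(*_SUBBAND_MULT_RANGE))
                flag = shared.random() < _CELL_SPECIFIC_FRACTION
                chrom_subs.append([chrom, cursor, cursor + slen, f"{bname}_s{si}", mult, flag])
                cursor += slen
        if chrom_subs and not any(r[5] for r in chrom_subs):
            chrom_subs[0][5] = True
        for r in chrom_subs:
            if r[5]:
                r[4] = float(cellrng.uniform(*_SUBBAND_MULT_RANGE))
            sub_rows.append(tuple(r[:5]))

        # one centric-heterochromatin block per chromosome, in the widest gap
        gs, ge = max(gaps, key=lambda g: g[1] - g[0])
        het_len = int(min(0.6 * (ge - gs), shared.uniform(1_000_000, 3_000_000)))
        if het_len >= 200_000:
            mid = (gs + ge) // 2
            het_rows.append((chrom, mid - het_len // 2, mid + het_len - het_len // 2, f"het_{chrom}"))

        # TADs tile the chromosome (0.5-2 Mb)
        cursor = 0
        for ti, tlen in enumerate(_chunk_lengths(shared, L, 500_000, 2_000_000)):
            tad_rows.append((chrom, cursor, cursor + tlen, f"tad_{chrom}_{ti}"))
            cursor += tlen

        # genes: dense inside bands, sparse outside (excluding heterochromatin)
        het_iv = [(s, e) for c, s, e, _ in het_rows if c == chrom]
        band_iv = [(s, e) for c, s, e, _ in band_rows if c == chrom]

        def _place(regions, density_per_mb):
            nonlocal gid
            for rs, re_ in regions:
                n = shared.poisson(density_per_mb * (re_ - rs) / 1e6)
                starts = np.sort(shared.integers(rs, max(rs + 1, re_ - 2000), n))
                for s in starts:
                    glen = int(np.clip(shared.lognormal(np.log(8000), 0.6), 1500, 60_000))
                    ge_ = min(int(s) + glen, L)
                    strand = "+" if shared.random() < 0.5 else "-"
                    gene_rows.append((f"g{gid:05d}", chrom, int(s), ge_, strand))
                    gid += 1

        _place(band_iv, _GENE_DENSITY_IN)
        outside = []
        cursor = 0
        blocked = sorted(band_iv + het_iv)
        for bs, be in blocked:
            if bs > cursor:
                outside.append((cursor, bs))
            cursor = max(cursor, be)
        if cursor < L:
            outside.append((cursor, L))
        _place(outside, _GENE_DENSITY_OUT)

    genes_df = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"]
    ).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    # class labels: silent 30%; of the rest, mitotic 6%, housekeeping 20%;
    # fixed small RP sets drawn from the active genes
    n = len(genes_df)
    u = shared.random(n)
    silent = u < 0.30
    u2 = shared.random(n)
    mitotic = (~silent) & (u2 < 0.06)
    u3 = shared.random(n)
    housekeeping = (~silent) & (~mitotic) & (u3 < 0.20)
    classes = [set() for _ in range(n)]
    for i in range(n):
        if silent[i]:
            classes[i].add("silent")
        if mitotic[i]:
            classes[i].add("mitotic")
        if housekeeping[i]:
            classes[i].add("housekeeping")
    plain = np.flatnonzero(~silent & ~mitotic)
    n_rp_l, n_rp_s = min(8, len(plain)), min(6, max(0, len(plain) - 8))
    rp = shared.choice(plain, size=n_rp_l + n_rp_s, replace=False) if len(plain) else []
    for j, i in enumerate(rp):
        classes[i].add("RP_large" if j < n_rp_l else "RP_small")
    genes_df["classes"] = [frozenset(c) for c in classes]

    return SyntheticModel(
        layout=layout,
        cell_type=cell_type,
        bands=IntervalSet(pd.DataFrame(band_rows, columns=["chrom", "start", "end", "name"])),
        sub_bands=IntervalSet(
            pd.DataFrame(sub_rows, columns=["chrom", "start", "end", "name", "multiplier"])
        ),
        heterochromatin=IntervalSet(
            pd.DataFrame(het_rows, columns=["chrom", "start", "end", "name"])
        ),
        tads=IntervalSet(pd.DataFrame(tad_rows, columns=["chrom", "start", "end", "name"])),
        genes=GeneAnnotation(genes_df),
        tss_shape=tss_shape or TssShape(),
        phase_effects=default_phase_effects() if phase_effects is None else phase_effects,
    )


# ---------------------------------------------------------------------------
# Intensity profiles
# ---------------------------------------------------------------------------


def _tss_kernels(shape: TssShape) -> tuple[np.ndarray, np.ndarray, int]:
    """Precompute (tss, body) kernel components on a _BIN-bp offset grid.

    tss: -1/+1 nucleosome Gaussian bumps multiplied by the NFR dip;
    body: exponential tail from the +1 nucleosome into the gene body.
    Returns (tss_kernel, body_kernel, index offset of position 0).
    """
    lo, hi = -1500, 4000
    o = np.arange(lo, hi, _BIN, dtype=np.float64)
    c, s = shape.plus1_center, 80.0
    bumps = np.exp(-0.5 * ((o - c) / s) ** 2) + np.exp(-0.5 * ((o + c) / s) ** 2)
    dip = 1.0 - 0.9 * np.exp(-0.5 * (o / shape.nfr_halfwidth) ** 2)
    tail = np.where(o > c, np.exp(-(o - c) / shape.decay_length), 0.0)
    return bumps * dip, tail * dip, -lo // _BIN


def _regional_multiplier(
    model: SyntheticModel, chrom: str, nbins: int, banded: bool = True
) -> np.ndarray:
    """Sub-band enrichment multipliers (for the banded active marks) and the
    near-zero centric heterochromatin floor (all marks)."""
    mult = np.ones(nbins, dtype=np.float64)
    if banded:
        sb = model.sub_bands.df
        for row in sb.loc[sb["chrom"] == chrom].itertuples(index=False):
            mult[row.start // _BIN : -(-row.end // _BIN)] = row.multiplier
    het = model.heterochromatin.df
    for row in het.loc[het["chrom"] == chrom].itertuples(index=False):
        mult[row.start // _BIN : -(-row.end // _BIN)] = _HET_MULT
    return mult


def _phase_mults(model: SyntheticModel, gene_classes: frozenset, phase: str) -> tuple[float, float]:
    t = b = 1.0
    for cls in gene_classes:
        eff = model.phase_effects.get((cls, phase))
        if eff:
            t *= eff.get("tss", 1.0)
            b *= eff.get("body", 1.0)
    return t, b


def _tad_bounds(model: SyntheticModel, chrom: str, pos: int) -> tuple[int, int]:
    td = model.tads.df
    sub = td.loc[(td["chrom"] == chrom) & (td["start"] <= pos) & (td["end"] > pos)]
    if len(sub):
        row = sub.iloc[0]
        return int(row["start"]), int(row["end"])
    return 0, model.layout.lengths[chrom]


def intensity_profile(model: SyntheticModel, mark: str, phase: str, chrom: str) -> np.ndarray:
    """Per-bin (10 bp) relative read intensity for one chromosome."""
    if mark not in MARKS:
        raise ValueError(f"unknown mark {mark!r}; expected one of {MARKS}")
    L = model.layout.lengths[chrom]
    nbins = -(-L // _BIN)
    # the acetylation/K4 banding multipliers do not apply to H3K27me3,
    # which forms its own domain structure over silent genes
    mult = _regional_multiplier(model, chrom, nbins, banded=mark in ACTIVE_MARKS)
    factor = np.ones(nbins, dtype=np.float64)

    gdf = model.genes.df
    genes = gdf.loc[gdf["chrom"] == chrom]
    if mark in ACTIVE_MARKS:
        k_tss, k_body, zero_i = _tss_kernels(model.tss_shape)
        klen = len(k_tss)
        for row in genes.itertuples(index=False):
            if "silent" in row.classes:
                continue
            tmult, bmult = _phase_mults(model, row.classes, phase)
            kern = _TSS_AMP * (tmult * k_tss + bmult * k_body)
            tss = row.start if row.strand == "+" else row.end - 1
            ti = tss // _BIN
            if row.strand == "+":
                lo = ti - zero_i
                seg = kern
            else:
                lo = ti - (klen - 1 - zero_i)
                seg = kern[::-1]
            a, b = max(lo, 0), min(lo + klen, nbins)
            if a < b:
                factor[a:b] += seg[a - lo : b - lo]
    else:  # H3K27me3: broad domains over silent genes, clipped at TAD edges
        for row in genes.itertuples(index=False):
            if "silent" not in row.classes:
                continue
            ts, te = _tad_bounds(model, chrom, row.start)
            ds = max(row.start - _K27_SPREAD, ts)
            de = min(row.end + _K27_SPREAD, te)
            factor[ds // _BIN : -(-de // _BIN)] += _K27_DOMAIN_AMP

    return model.background_rate * mult * factor


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def simulate_reads(
    model: SyntheticModel,
    mark: str,
    phase: str,
    depth: int,
    seed: int,
    read_length: int = 150,
) -> ReadCollection:
    """Draw exactly ``depth`` reads from the model's intensity landscape.

    Read midpoints are sampled proportionally to the per-position intensity;
    each read is an unstranded ``read_length`` bp interval clipped to its
    chromosome.  Fully deterministic for a given (model, mark, phase, depth,
    seed).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if phase not in ("G1", "S", "G2M", "M", "asynchronous"):
        raise ValueError(f"unknown phase {phase!r}")
    rng = _rng_for(seed, "simulate", mark, phase)
    # intensity depends only on (model, mark, phase): memoize on the model
    cache = model.__dict__.setdefault("_profile_cache", {})
    profiles = cache.get((mark, phase))
    if profiles is None:
        profiles = [intensity_profile(model, mark, phase, c) for c in model.layout.names]
        cache[(mark, phase)] = profiles
    weights = np.array([p.sum() for p in profiles])
    per_chrom = rng.multinomial(depth, weights / weights.sum())

    cidx, starts = [], []
    for ci, (chrom, L) in enumerate(model.layout.chromosomes):
        n = int(per_chrom[ci])
        if n == 0:
            continue
        cdf = np.cumsum(profiles[ci])
        u = rng.random(n) * cdf[-1]
        bins = np.searchsorted(cdf, u, side="right")
        mids = bins * _BIN + rng.integers(0, _BIN, n)
        s = np.clip(mids - read_length // 2, 0, max(L - read_length, 0))
        cidx.append(np.full(n, ci, dtype=np.int32))
        starts.append(s.astype(np.int64))
    cidx = np.concatenate(cidx) if cidx else np.empty(0, dtype=np.int32)
    starts = np.concatenate(starts) if starts else np.empty(0, dtype=np.int64)
    lengths = np.array([l for _, l in model.layout.chromosomes], dtype=np.int64)
    ends = np.minimum(starts + read_length, lengths[cidx] if len(cidx) else starts)
    return ReadCollection(
        model.layout,
        cidx,
        starts,
        ends,
        np.full(len(starts), ".", dtype="<U1"),
        SampleMeta(mark=mark, phase=phase, cell_type=model.cell_type, total_reads=len(starts)),
    )


def downsample(reads: ReadCollection, fraction: float, seed: int) -> ReadCollection:
    """Keep each read independently with probability ``fraction``."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    rng = _rng_for(seed, "downsample")
    keep = rng.random(len(reads)) < fraction
    from dataclasses import replace

    return ReadCollection(
        reads.layout,
        reads.chrom_idx[keep],
        reads.start[keep],
        reads.end[keep],
        reads.strand[keep],
        replace(reads.meta, total_reads=int(keep.sum())),
    )


def simulate_expression(model: SyntheticModel, seed: int) -> pd.Series:
    """Per-gene expression values consistent with the chromatin classes:
    active genes high (housekeeping highest), silent genes low, log-normal
    noise throughout.  Returned as a Series indexed by gene_id."""
    rng = _rng_for(seed, "expression")
    means = []
    for classes in model.genes.df["classes"]:
        if "silent" in classes:
            means.append(np.log(20.0))
        elif "housekeeping" in classes or "RP_large" in classes or "RP_small" in classes:
            means.append(np.log(800.0))
        else:
            means.append(np.log(200.0))
    vals = rng.lognormal(np.array(means), 0.8)
    return pd.Series(vals, index=model.genes.df["gene_id"].to_numpy(), name="value")


def write_expression(expression: pd.Series, path) -> None:
    with open(path, "w") as fh:
        for gid, v in expression.items():
            fh.write(f"{gid}\t{v:.4f}\n")


def write_truth(model: SyntheticModel, outdir) -> dict[str, Path]:
    """Write the model's truth files (bands, sub-bands, genes, TADs, sizes)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "chrom_sizes": outdir / "chrom.sizes",
        "bands": outdir / "bands.bed",
        "subbands": outdir / "subbands.bed",
        "heterochromatin": outdir / "heterochromatin.bed",
        "tads": outdir / "tads.bed",
        "genes": outdir / "genes.bed",
        "gene_classes": outdir / "gene_classes.tsv",
        "model": outdir / "model.json",
    }
    with open(paths["chrom_sizes"], "w") as fh:
        for name, length in model.layout.chromosomes:
            fh.write(f"{name}\t{length}\n")
    write_intervals_bed(model.bands, paths["bands"])
    write_intervals_bed(model.sub_bands, paths["subbands"], extra_cols=["multiplier"])
    write_intervals_bed(model.heterochromatin, paths["heterochromatin"])
    write_intervals_bed(model.tads, paths["tads"])
    write_genes_bed(model.genes, paths["genes"])
    write_gene_classes(model.genes, paths["gene_classes"])
    paths["model"].write_text(json.dumps(model.to_dict(), indent=2, sort_keys=True))
    return paths
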