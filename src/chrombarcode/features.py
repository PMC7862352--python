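"""Feature-level quantification: TSS windows, gene bodies, TADs, metagene
profiles and gene density.

All feature windows are strand-aware and anchored at the TSS (start of a
'+' gene, end of a '-' gene): the proximal TSS window spans -500 to +750 bp
(the -1 nucleosome through the first three downstream nucleosomes) and the
gene-body window +750 to +1750 bp, in transcription-direction coordinates.
Offsets are taken from the TSS regardless of gene length, so short genes
are not truncated and all genes contribute comparable fixed-width windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneAnnotation, GenomeLayout, IntervalSet, ReadCollection

TSS_SPAN = (-500, 750)
GENE_BODY_SPAN = (750, 1750)


@dataclass
class FeatureQuantification:
    """Per-feature counts and normalized values.

    ``df`` columns: feature_id, chrom, start, end, length, raw, value
    (value is log2 of the library-scaled count, per-kb if length-corrected).
    """

    df: pd.DataFrame
    length_corrected: bool
    reference_total: int

    def __len__(self) -> int:
        return len(self.df)

    def values_by_id(self) -> pd.Series:
        return self.df.set_index("feature_id")["value"]


@dataclass
class MetageneProfile:
    """Mean normalized read density around the TSS of a gene set.

    ``edges`` are bin edges in strand-signed bp relative to the TSS (length
    n_bins+1); ``values`` are mean library-scaled read counts per gene per
    bin.  The mean is over genes, not over reads.
    """

    edges: np.ndarray
    values: np.ndarray
    n_genes: int

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2

    def mean_over(self, lo: int, hi: int) -> float:
        """Mean bin value over relative positions [lo, hi)."""
        sel = (self.centers >= lo) & (self.centers < hi)
        return float(self.values[sel].mean())


def _strand_windows(
    genes: GeneAnnotation, layout: GenomeLayout, span: tuple[int, int]
) -> IntervalSet:
    lo, hi = span
    if hi <= lo:
        raise ValueError("span must satisfy lo < hi")
    lengths = genes.df["chrom"].map(layout.lengths).to_numpy()
    tss = genes.tss
    plus = genes.df["strand"].to_numpy() == "+"
    start = np.where(plus, tss + lo, tss - hi + 1)
    end = np.where(plus, tss + hi, tss - lo + 1)
    cstart = np.clip(start, 0, lengths)
    cend = np.clip(end, 0, lengths)
    keep = cend > cstart
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(f"dropped {dropped} genes with windows outside bounds", stacklevel=3)
    return IntervalSet(
        pd.DataFrame(
            {
                "chrom": genes.df["chrom"].to_numpy()[keep],
                "start": cstart[keep],
                "end": cend[keep],
                "name": genes.df["gene_id"].to_numpy()[keep],
            }
        )
    )


def tss_windows(
    genes: GeneAnnotation, layout: GenomeLayout, span: tuple[int, int] = TSS_SPAN
) -> IntervalSet:
    """Proximal TSS intervals (default -500 to +750 bp, strand-oriented)."""
    return _strand_windows(genes, layout, span)


def gene_body_windows(
    genes: GeneAnnotation, layout: GenomeLayout, span: tuple[int, int] = GENE_BODY_SPAN
) -> IntervalSet:
    """Early gene-body intervals (default +750 to +1750 bp, strand-oriented)."""
    return _strand_windows(genes, layout, span)


def quantify_features(
    reads: ReadCollection,
    intervals: IntervalSet,
    reference_total: int | None = None,
    length_correct: bool = False,
    pseudocount: float = 1.0,
) -> FeatureQuantification:
    """Count read midpoints per interval and normalize to a reference library.

    value = log2(raw x reference/total + pc), or with ``length_correct`` the
    scaled count per kb of interval ("probe size" correction for features of
    unequal length, e.g. TADs): log2(scaled/length_kb + pc).
    """
    df = intervals.df.reset_index(drop=True)
    if len(df) and (df["end"] - df["start"] <= 0).any():
        raise ValueError("zero-length interval")
    total = reads.meta.total_reads
    if total == 0:
        raise ValueError("cannot normalize with zero total reads")
    if reference_total is None:
        reference_total = total
    raw = np.zeros(len(df), dtype=np.int64)
    name_to_idx = {n: i for i, n in enumerate(reads.layout.names)}
    for chrom, sub in df.groupby("chrom", sort=False):
        ci = name_to_idx.get(chrom)
        if ci is None:
            raise ValueError(f"interval chromosome {chrom!r} not in read layout")
        mids = np.sort(reads.midpoints[reads.chrom_idx == ci])
        lo = np.searchsorted(mids, sub["start"].to_numpy(), side="left")
        hi = np.searchsorted(mids, sub["end"].to_numpy(), side="left")
        raw[sub.index.to_numpy()] = hi - lo
    scaled = raw * (reference_total / total)
    if length_correct:
        scaled = scaled / ((df["end"] - df["start"]).to_numpy() / 1000.0)
    value = np.log2(scaled + pseudocount)
    out = pd.DataFrame(
        {
            "feature_id": df["name"].to_numpy(),
            "chrom": df["chrom"].to_numpy(),
            "start": df["start"].to_numpy(),
            "end": df["end"].to_numpy(),
            "length": (df["end"] - df["start"]).to_numpy(),
            "raw": raw,
            "value": value,
        }
    )
    return FeatureQuantification(out, length_correct, int(reference_total))


def metagene_profile(
    reads: ReadCollection,
    genes: GeneAnnotation,
    half_span: int = 5000,
    bin_size: int = 100,
    reference_total: int | None = None,
) -> MetageneProfile:
    """Average strand-oriented read density in a window centred on all TSS.

    Read midpoints are mapped to signed offsets from each gene's TSS
    (downstream positive); per-bin counts are scaled to the reference
    library size and averaged over genes.
    """
    if len(genes) == 0:
        raise ValueError("empty gene set")
    if (2 * half_span) % bin_size != 0:
        raise ValueError("bin_size must divide 2*half_span")
    total = reads.meta.total_reads
    if total == 0:
        raise ValueError("cannot normalize with zero total reads")
    if reference_total is None:
        reference_total = total
    edges = np.arange(-half_span, half_span + bin_size, bin_size, dtype=np.int64)
    counts = np.zeros(len(edges) - 1, dtype=np.float64)
    name_to_idx = {n: i for i, n in enumerate(reads.layout.names)}
    mids_by_chrom = {
        c: np.sort(reads.midpoints[reads.chrom_idx == i]) for c, i in name_to_idx.items()
    }
    tss = genes.tss
    for g in range(len(genes)):
        chrom = genes.df["chrom"].iat[g]
        mids = mids_by_chrom.get(chrom)
        if mids is None:
            continue
        lo = np.searchsorted(mids, tss[g] - half_span, side="left")
        hi = np.searchsorted(mids, tss[g] + half_span, side="left")
        off = mids[lo:hi] - tss[g]
        if genes.df["strand"].iat[g] == "-":
            off = -off
        sel = (off >= -half_span) & (off < half_span)
        counts += np.bincount(
            ((off[sel] + half_span) // bin_size).astype(np.int64),
            minlength=len(counts),
        )
    values = counts * (reference_total / total) / len(genes)
    return MetageneProfile(edges, values, len(genes))


def geneset_profile(
    reads: ReadCollection,
    genes: GeneAnnotation,
    class_label: str,
    half_span: int = 5000,
    bin_size: int = 100,
    reference_total: int | None = None,
) -> MetageneProfile:
    """Metagene profile restricted to genes carrying ``class_label``
    (e.g. 'RP_large'/'RP_small' ribosomal-protein sets, or 'mitotic')."""
    subset = genes.with_class(class_label)
    return metagene_profile(reads, subset, half_span, bin_size, reference_total)


def merge_intervals(intervals: IntervalSet) -> IntervalSet:
    """Union of possibly-overlapping intervals, per chromosome."""
    rows = []
    for chrom, sub in intervals.df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["name"] = [f"u{i}" for i in range(len(df))]
    return IntervalSet(df)


def genes_with_tss_in(intervals: IntervalSet, genes: GeneAnnotation) -> list[str]:
    """gene_ids whose TSS falls inside the union of the intervals."""
    merged = merge_intervals(intervals)
    out = []
    tss = genes.tss
    for g in range(len(genes)):
        chrom = genes.df["chrom"].iat[g]
        sub = merged.df.loc[merged.df["chrom"] == chrom]
        if ((sub["start"] <= tss[g]) & (tss[g] < sub["end"])).any():
            out.append(genes.df["gene_id"].iat[g])
    return out


def gene_density(intervals: IntervalSet, genes: GeneAnnotation) -> float:
    """Genes per Mb: TSS count inside the interval union / union length."""
    if len(intervals) == 0:
        raise ValueError("empty interval set")
    merged = merge_intervals(intervals)
    union_bp = int((merged.df["end"] - merged.df["start"]).sum())
    if union_bp == 0:
        raise ValueError("zero union length")
    n = len(genes_with_tss_in(intervals, genes))
    return n / (union_bp / 1e6)
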