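"""Rolling-window quantification and library-size normalization.

Reads are counted in windows of size W placed every `step` bp along each
chromosome (a tiling partition when step == W).  Counts are normalized to a
reference library size — by convention the largest library in the comparison
set — and reported as log2 of the scaled count plus a pseudocount, so that
zero-read windows sit at exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GenomeLayout, ReadCollection, SampleMeta


@dataclass(frozen=True)
class WindowGrid:
    """Ordered genome-wide windows: starts at 0, step, 2·step, … per
    chromosome while start < length; the terminal window is clipped at the
    chromosome end."""

    layout: GenomeLayout
    W: int
    step: int
    chrom_idx: np.ndarray  # int32, one entry per window
    start: np.ndarray  # int64
    end: np.ndarray  # int64
    chrom_slices: tuple[tuple[int, int], ...]  # [lo, hi) window range per chromosome

    def __len__(self) -> int:
        return len(self.start)

    @property
    def midpoints(self) -> np.ndarray:
        return (self.start + self.end) // 2

    def windows_on(self, name: str) -> slice:
        lo, hi = self.chrom_slices[self.layout.index(name)]
        return slice(lo, hi)


@dataclass
class SignalTrack:
    """Per-window raw counts and normalized values on a WindowGrid."""

    grid: WindowGrid
    raw: np.ndarray
    value: np.ndarray | None = None
    meta: SampleMeta = field(default_factory=SampleMeta)

    def __post_init__(self) -> None:
        if len(self.raw) != len(self.grid):
            raise ValueError("raw length does not match grid")
        if self.value is not None and len(self.value) != len(self.grid):
            raise ValueError("value length does not match grid")


def make_grid(layout: GenomeLayout, W: int, step: int | None = None) -> WindowGrid:
    """Build the rolling-window grid for a genome layout.

    ``step`` defaults to W (non-overlapping tiling).
    """
    if step is None:
        step = W
    if step < 1:
        raise ValueError("step must be >= 1")
    if W < step:
        raise ValueError("window size W must be >= step")
    if W > max(l for _, l in layout.chromosomes):
        raise ValueError("W exceeds the longest chromosome")
    cidx, starts, ends, slices = [], [], [], []
    offset = 0
    for i, (_, length) in enumerate(layout.chromosomes):
        s = np.arange(0, length, step, dtype=np.int64)
        e = np.minimum(s + W, length)
        cidx.append(np.full(len(s), i, dtype=np.int32))
        starts.append(s)
        ends.append(e)
        slices.append((offset, offset + len(s)))
        offset += len(s)
    return WindowGrid(
        layout,
        W,
        step,
        np.concatenate(cidx),
        np.concatenate(starts),
        np.concatenate(ends),
        tuple(slices),
    )


def _range_counts(n_windows: int, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Count, per window index, how many [lo_i, hi_i) ranges cover it."""
    diff = np.zeros(n_windows + 1, dtype=np.int64)
    np.add.at(diff, lo, 1)
    np.add.at(diff, hi, -1)
    return np.cumsum(diff)[:-1]


def count_reads(
    reads: ReadCollection, grid: WindowGrid, mode: str = "midpoint"
) -> SignalTrack:
    """Count reads per window.

    ``midpoint`` assigns each read to every window containing its midpoint
    (exactly one when step == W, giving exact conservation); ``overlap``
    counts any overlap of at least 1 bp.
    """
    if mode not in ("midpoint", "overlap"):
        raise ValueError("mode must be 'midpoint' or 'overlap'")
    if reads.layout.chromosomes != grid.layout.chromosomes:
        raise ValueError("reads and grid use different genome layouts")
    W, step = grid.W, grid.step
    raw = np.zeros(len(grid), dtype=np.int64)
    for ci, (lo_w, hi_w) in enumerate(grid.chrom_slices):
        sel = reads.chrom_idx == ci
        if not sel.any():
            continue
        n_win = hi_w - lo_w
        if mode == "midpoint":
            m = (reads.start[sel] + reads.end[sel]) // 2
            # windows with start in (m - W, m]: start index range
            lo = np.maximum((m - W) // step + 1, 0)
            hi = np.minimum(m // step + 1, n_win)
        else:
            s, e = reads.start[sel], reads.end[sel]
            # windows with start in (s - W, e)
            lo = np.maximum((s - W) // step + 1, 0)
            hi = np.minimum((e - 1) // step + 1, n_win)
        lo = np.minimum(lo, hi)  # reads whose window range is empty after clipping
        raw[lo_w:hi_w] = _range_counts(n_win, lo, hi)
    return SignalTrack(grid, raw, None, reads.meta)


def normalize(
    track: SignalTrack,
    reference_total: int | None = None,
    pseudocount: float = 1.0,
) -> SignalTrack:
    """Fill normalized values: log2(raw × reference_total / total + pseudocount).

    ``reference_total`` defaults to the track's own library size; when
    comparing a sample set, pass the maximum library size over the set (the
    "largest data store" convention) so all tracks share a scale.
    """
    total = track.meta.total_reads
    if total == 0:
        raise ValueError("cannot normalize a track with zero total reads")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if reference_total is None:
        reference_total = total
    if reference_total < total:
        raise ValueError("reference_total must be >= the track's total reads")
    scaled = track.raw.astype(np.float64) * (reference_total / total)
    value = np.log2(scaled + pseudocount)
    return SignalTrack(track.grid, track.raw, value, track.meta)


def quantify(
    reads: ReadCollection,
    layout: GenomeLayout,
    W: int,
    step: int | None = None,
    mode: str = "midpoint",
    reference_total: int | None = None,
    pseudocount: float = 1.0,
) -> SignalTrack:
    """Convenience: grid → count → normalize in one call."""
    grid = make_grid(layout, W, step)
    return normalize(count_reads(reads, grid, mode), reference_total, pseudocount)
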