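"""Track correlation, the R-vs-window-size elbow scan, and depth titration.

Two tracks quantified on identical grids are compared by Pearson R over all
shared windows.  Scanning R across window sizes W produces the elbow curve:
R stays high at large W and falls once windows are small enough that
counting noise dominates; reducing read depth shifts the elbow to larger W.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenomeLayout, ReadCollection, SampleMeta
from .synthetic_data import downsample
from .window_quant import SignalTrack, count_reads, make_grid, normalize

#: Window sizes for the elbow scan, 100 bp to 1 Mb (log-spaced).
DEFAULT_W_LIST = (
    100, 200, 500,
    1_000, 2_000, 5_000,
    10_000, 20_000, 50_000,
    100_000, 200_000, 500_000,
    1_000_000,
)


@dataclass
class CorrelationCurve:
    """R as a function of window size W for one pair of samples."""

    points: pd.DataFrame  # columns: W, R, n_windows (R is NaN where undefined)
    sample_pair: tuple[SampleMeta, SampleMeta]
    fraction: float = 1.0

    def __post_init__(self) -> None:
        w = self.points["W"].to_numpy()
        if len(w) and not np.all(np.diff(w) > 0):
            raise ValueError("W values must be strictly increasing")

    def r_at(self, W: int) -> float:
        row = self.points.loc[self.points["W"] == W]
        if not len(row):
            raise KeyError(f"no point at W={W}")
        return float(row["R"].iloc[0])


def pearson_r(track_a: SignalTrack, track_b: SignalTrack) -> float:
    """Pearson product-moment correlation of two tracks' normalized values.

    Windows where either value is missing are dropped pairwise.  Returns NaN
    (with a warning) if fewer than two windows remain or either side has
    zero variance.
    """
    if track_a.grid.layout.chromosomes != track_b.grid.layout.chromosomes or (
        track_a.grid.W != track_b.grid.W or track_a.grid.step != track_b.grid.step
    ):
        raise ValueError("tracks are on different grids")
    a, b = track_a.value, track_b.value
    if a is None or b is None:
        raise ValueError("tracks must be normalized before correlation")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("correlation undefined (zero variance or <2 windows)", stacklevel=2)
        return float("nan")
    # direct product-moment form: sqrt(Sxx*Syy) keeps R(track, itself)
    # exactly 1.0 (sqrt(x*x) == |x| in IEEE round-to-nearest)
    am = a - a.mean()
    bm = b - b.mean()
    r = (am * bm).sum() / np.sqrt((am * am).sum() * (bm * bm).sum())
    return float(np.clip(r, -1.0, 1.0))


def elbow_curve(
    reads_a: ReadCollection,
    reads_b: ReadCollection,
    layout: GenomeLayout,
    w_list=DEFAULT_W_LIST,
    reference_total: int | None = None,
    mode: str = "midpoint",
    pseudocount: float = 1.0,
    fraction: float = 1.0,
) -> CorrelationCurve:
    """Quantify both samples at each window size (step = W) and correlate.

    ``reference_total`` defaults to the larger of the two library sizes (the
    "largest data store" convention).
    """
    w_list = sorted(set(int(w) for w in w_list))
    if reference_total is None:
        reference_total = max(reads_a.meta.total_reads, reads_b.meta.total_reads, 1)
    rows = []
    for W in w_list:
        grid = make_grid(layout, W, W)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                ta = normalize(count_reads(reads_a, grid, mode), reference_total, pseudocount)
                tb = normalize(count_reads(reads_b, grid, mode), reference_total, pseudocount)
                r = pearson_r(ta, tb)
            except ValueError:
                r = float("nan")
        rows.append((W, r, len(grid)))
    return CorrelationCurve(
        pd.DataFrame(rows, columns=["W", "R", "n_windows"]),
        (reads_a.meta, reads_b.meta),
        fraction,
    )


def depth_titration(
    reads_a: ReadCollection,
    reads_b: ReadCollection,
    layout: GenomeLayout,
    fractions=(1.0, 0.5, 0.1),
    w_list=DEFAULT_W_LIST,
    seed: int = 0,
    reference_total: int | None = None,
) -> list[CorrelationCurve]:
    """Recompute the elbow curve after downsampling both samples.

    Each fraction uses an independent seeded subsample of each side; curves
    are returned in the caller's fraction order.  Lower depth raises the
    counting noise at small W, moving the elbow to larger window sizes.
    """
    curves = []
    for fi, frac in enumerate(fractions):
        if frac == 1.0:
            da, db = reads_a, reads_b
        else:
            da = downsample(reads_a, frac, seed * 1000 + 2 * fi)
            db = downsample(reads_b, frac, seed * 1000 + 2 * fi + 1)
        curves.append(
            elbow_curve(da, db, layout, w_list, reference_total, fraction=frac)
        )
    return curves


def knee_estimate(curve: CorrelationCurve) -> float | None:
    """Estimate the elbow W as the point of maximum perpendicular distance
    from the chord joining the curve's endpoints in (log10 W, R) space.

    Returns None for fewer than three finite points or a flat curve (no
    point leaves the chord).
    """
    pts = curve.points.dropna(subset=["R"])
    if len(pts) < 3:
        return None
    x = np.log10(pts["W"].to_numpy(dtype=float))
    y = pts["R"].to_numpy(dtype=float)
    p0 = np.array([x[0], y[0]])
    p1 = np.array([x[-1], y[-1]])
    chord = p1 - p0
    norm = np.hypot(*chord)
    if norm == 0:
        return None
    rel = np.stack([x - p0[0], y - p0[1]], axis=1)
    dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0]) / norm
    if np.max(dist) <= 1e-12:
        return None
    return float(pts["W"].to_numpy()[int(np.argmax(dist))])


def curve_table(curves) -> pd.DataFrame:
    """Stack one or more curves into a tidy table (fraction, W, R, n_windows)."""
    if isinstance(curves, CorrelationCurve):
        curves = [curves]
    frames = []
    for c in curves:
        df = c.points.copy()
        df.insert(0, "fraction", c.fraction)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
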