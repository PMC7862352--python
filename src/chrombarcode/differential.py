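"""Comparative statistics between paired quantifications.

* **Intensity difference**: each feature's between-condition difference
  d = y - x is tested against a normal fitted to the d values of the
  features with the most similar mean intensity (x+y)/2 — an MA-plot-style
  local null that adapts to the intensity-dependent variance of count data.
  Raw two-tailed p values drive selection (permissive and strict thresholds
  are both in routine use); Benjamini-Hochberg q values are reported
  alongside.
* **Tail selection**: the outlying fraction (default 3%) on each side of
  the ranked d distribution, e.g. for cell-type comparisons.
* **Bivalency quadrants**: genes classified by H3K4me3/H3K27me3 TSS levels
  into neither / K4_only / K27_only / bivalent, with cross-phase transition
  tracking and per-quadrant expression summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal, stats
from statsmodels.stats.multitest import multipletests

from .features import gene_density, genes_with_tss_in
from .io import GeneAnnotation, IntervalSet

QUADRANTS = ("neither", "K4_only", "K27_only", "bivalent")


@dataclass
class IntensityDiffResult:
    """Per-feature local-null test results.

    ``df`` columns: feature_id, x, y, d, local_mu, local_sigma, p, q.
    Features with a degenerate (zero) local sigma are untestable: p and q
    are NaN.
    """

    df: pd.DataFrame
    frac: float
    min_k: int
    k: int

    def significant(self, alpha: float = 0.05, adjusted: bool = False) -> pd.DataFrame:
        col = "q" if adjusted else "p"
        return self.df.loc[self.df[col] < alpha]


@dataclass
class TailSelection:
    """Upper/lower outlying windows of the d = y - x distribution."""

    df: pd.DataFrame  # feature_id, x, y, d (+ chrom/start/end if provided)
    lower_idx: np.ndarray
    upper_idx: np.ndarray
    fraction: float

    @property
    def lower(self) -> pd.DataFrame:
        return self.df.iloc[self.lower_idx]

    @property
    def upper(self) -> pd.DataFrame:
        return self.df.iloc[self.upper_idx]


@dataclass
class QuadrantAssignment:
    """Per-gene bivalency quadrant labels for one phase."""

    df: pd.DataFrame  # gene_id, k4, k27, quadrant
    thresholds: tuple[float, float]

    def counts(self) -> pd.Series:
        return self.df["quadrant"].value_counts().reindex(QUADRANTS, fill_value=0)


def intensity_difference(
    xs,
    ys,
    ids=None,
    frac: float = 0.01,
    min_k: int = 50,
) -> IntensityDiffResult:
    """Local-neighbourhood outlier test for paired values.

    For each feature i with mean intensity m_i = (x_i + y_i)/2, the
    k = max(ceil(frac*n), min_k) features nearest in m (excluding i, found
    as the tightest contiguous block in m-sorted order) define a normal null
    for d; p_i is the two-tailed tail probability of d_i under it.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("xs and ys must be paired")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("values must be finite")
    k = max(int(np.ceil(frac * n)), min_k)
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} features, got {n}")
    if ids is None:
        ids = np.array([f"f{i}" for i in range(n)])
    ids = np.asarray(ids)

    m = (x + y) / 2.0
    d = y - x
    order = np.argsort(m, kind="stable")
    ms, dsrt = m[order], d[order]

    # tightest (k+1)-wide block containing each position: slide the span
    # ms[l+k] - ms[l] over candidate left edges l in [p-k, p]
    span = ms[k:] - ms[: n - k]  # length n-k
    pad = np.full(k, np.inf)
    spad = np.concatenate([pad[: min(k, n)], span, pad])
    rows = sliding_window_view(spad, k + 1)[:n]
    rel = np.argmin(rows, axis=1)  # first minimum → smallest l (deterministic)
    l = np.arange(n) - k + rel
    l = np.clip(l, 0, n - k - 1)

    csum = np.concatenate([[0.0], np.cumsum(dsrt)])
    csq = np.concatenate([[0.0], np.cumsum(dsrt**2)])
    wsum = csum[l + k + 1] - csum[l] - dsrt
    wsq = csq[l + k + 1] - csq[l] - dsrt**2
    mu = wsum / k
    var = (wsq - k * mu**2) / (k - 1)
    sigma = np.sqrt(np.maximum(var, 0.0))

    p = np.full(n, np.nan)
    testable = sigma > 0
    z = np.abs(dsrt[testable] - mu[testable]) / sigma[testable]
    p[testable] = np.clip(2.0 * stats.norm.sf(z), np.finfo(float).tiny, 1.0)
    if not testable.all():
        warnings.warn(
            f"{int((~testable).sum())} features untestable (zero local sigma)",
            stacklevel=2,
        )

    q = np.full(n, np.nan)
    if testable.any():
        q[testable] = multipletests(p[testable], method="fdr_bh")[1]

    inv = np.empty(n, dtype=np.int64)
    inv[order] = np.arange(n)
    df = pd.DataFrame(
        {
            "feature_id": ids,
            "x": x,
            "y": y,
            "d": d,
            "local_mu": mu[inv],
            "local_sigma": sigma[inv],
            "p": p[inv],
            "q": q[inv],
        }
    )
    return IntensityDiffResult(df, frac, min_k, k)


def select_tails(xs, ys, ids=None, fraction: float = 0.03, intervals=None) -> TailSelection:
    """Outlying ``fraction`` of features on each side of the d = y - x
    distribution; ties broken by feature order (stable sort)."""
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("xs and ys must be paired")
    if not (0 < fraction < 0.5):
        raise ValueError("fraction must be in (0, 0.5)")
    nsel = int(round(fraction * n))
    if nsel < 1:
        raise ValueError("fraction*n < 1: nothing to select")
    if ids is None:
        ids = np.array([f"f{i}" for i in range(n)])
    d = y - x
    order = np.argsort(d, kind="stable")  # stable: ties keep feature order
    cols = {"feature_id": np.asarray(ids), "x": x, "y": y, "d": d}
    if intervals is not None:
        idf = intervals.df.reset_index(drop=True)
        if len(idf) != n:
            raise ValueError("intervals must align with xs/ys")
        cols.update(
            chrom=idf["chrom"].to_numpy(),
            start=idf["start"].to_numpy(),
            end=idf["end"].to_numpy(),
        )
    return TailSelection(pd.DataFrame(cols), order[:nsel], order[-nsel:], fraction)


def genes_in_windows(selection: TailSelection, genes: GeneAnnotation) -> dict:
    """Genes whose TSS falls in each tail's selected windows, with the gene
    density (genes/Mb) of each tail's window union."""
    if "chrom" not in selection.df.columns:
        raise ValueError("selection carries no window coordinates")
    out = {}
    for tail, rows in (("lower", selection.lower), ("upper", selection.upper)):
        iv = IntervalSet(rows[["chrom", "start", "end"]].assign(name=rows["feature_id"]))
        gene_ids = genes_with_tss_in(iv, genes)
        out[tail] = {
            "genes": gene_ids,
            "density_per_mb": gene_density(iv, genes),
            "n_windows": len(rows),
        }
    return out


def _valley_threshold(values: np.ndarray, grid_points: int = 512) -> float:
    """Density valley between the two largest modes of a marginal distribution.

    A Gaussian KDE (Scott bandwidth) is evaluated on a grid padded beyond
    the data range so edge modes register as peaks; the threshold is the
    density minimum between the two most prominent modes.
    """
    values = np.asarray(values, dtype=float)
    if np.ptp(values) == 0:
        raise ValueError("marginal distribution is degenerate; supply explicit thresholds")
    lo, hi = values.min(), values.max()
    pad = 0.15 * (hi - lo)
    xs = np.linspace(lo - pad, hi + pad, grid_points)
    dens = stats.gaussian_kde(values)(xs)
    peaks, props = signal.find_peaks(dens, prominence=0.02 * dens.max())
    if len(peaks) < 2:
        raise ValueError("marginal distribution is unimodal; supply explicit thresholds")
    top2 = peaks[np.argsort(props["prominences"])[-2:]]
    a, b = np.sort(top2)
    valley = a + int(np.argmin(dens[a : b + 1]))
    return float(xs[valley])


def classify_quadrants(
    k4_values,
    k27_values,
    ids,
    thresholds: tuple[float, float] | None = None,
) -> QuadrantAssignment:
    """Assign genes to bivalency quadrants.

    Thresholds (t_k4, t_k27) are estimated as the valley between the two
    largest modes of each mark's marginal distribution unless given
    explicitly.  Values exactly at a threshold count as low (<= inclusive).
    """
    k4 = np.asarray(k4_values, dtype=float)
    k27 = np.asarray(k27_values, dtype=float)
    if len(k4) != len(k27) or len(k4) != len(ids):
        raise ValueError("k4, k27 and ids must align")
    if thresholds is None:
        thresholds = (_valley_threshold(k4), _valley_threshold(k27))
    t4, t27 = thresholds
    hi4, hi27 = k4 > t4, k27 > t27
    quadrant = np.where(
        hi4 & hi27, "bivalent", np.where(hi4, "K4_only", np.where(hi27, "K27_only", "neither"))
    )
    df = pd.DataFrame(
        {"gene_id": np.asarray(ids), "k4": k4, "k27": k27, "quadrant": quadrant}
    )
    return QuadrantAssignment(df, (float(t4), float(t27)))


def track_quadrants(assign_a: QuadrantAssignment, assign_b: QuadrantAssignment):
    """4x4 transition counts between two phases' assignments, plus the
    stability score trace/total."""
    a, b = assign_a.df, assign_b.df
    if list(a["gene_id"]) != list(b["gene_id"]):
        raise ValueError("assignments cover different gene sets")
    if assign_a.thresholds != assign_b.thresholds:
        raise ValueError("assignments used different thresholds")
    mat = (
        pd.crosstab(a["quadrant"], b["quadrant"])
        .reindex(index=QUADRANTS, columns=QUADRANTS, fill_value=0)
        .astype(int)
    )
    total = int(mat.to_numpy().sum())
    stability = float(np.trace(mat.to_numpy()) / total) if total else float("nan")
    return mat, stability


def quadrant_expression_summary(
    assignment: QuadrantAssignment, expression: pd.Series
) -> pd.DataFrame:
    """Five-number summary (median, quartiles, min, max) of expression per
    quadrant; genes without expression values are dropped and counted."""
    rows = []
    for quad in QUADRANTS:
        gene_ids = assignment.df.loc[assignment.df["quadrant"] == quad, "gene_id"]
        vals = expression.reindex(gene_ids)
        missing = int(vals.isna().sum())
        vals = vals.dropna()
        if len(vals):
            rows.append(
                (
                    quad,
                    len(vals),
                    missing,
                    float(vals.min()),
                    float(vals.quantile(0.25)),
                    float(vals.median()),
                    float(vals.quantile(0.75)),
                    float(vals.max()),
                )
            )
        else:
            rows.append((quad, 0, missing, *([float("nan")] * 5)))
    out = pd.DataFrame(
        rows,
        columns=["quadrant", "n", "n_missing_expression", "min", "q1", "median", "q3", "max"],
    )
    if out["n"].sum() == 0:
        warnings.warn("no quadrant has expression data", stacklevel=2)
    return out
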