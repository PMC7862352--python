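"""Pseudo-karyotype rendering: signal tracks as red-green banded ideograms.

Normalized window values are averaged into genomic pixels (default 1.5 Mb,
the resolution of a metaphase immunofluorescence image), anchored to the
5th/95th percentiles of the joint pixel distribution, and mapped linearly
from red (low) through yellow to green (high) — emulating the look of
antibody-stained metaphase chromosome spreads.  Pixels with no underlying
windows are grey.  Rendering is fully deterministic: identical inputs give
byte-identical PNG files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from PIL import Image, ImageDraw

from .window_quant import SignalTrack

DEFAULT_PIXEL_SIZE = 1_500_000
LOW_COLOUR = (255, 0, 0)
HIGH_COLOUR = (0, 255, 0)
MISSING_COLOUR = (128, 128, 128)
DEFAULT_ANCHORS = (5.0, 95.0)  # percentiles


@dataclass
class KaryotypeImage:
    """Pixel vectors per (track, chromosome) plus the rendered raster."""

    pixels: list[dict[str, np.ndarray]]  # one dict per track
    pixel_size: int
    anchors: tuple[float, float]  # resolved value anchors (not percentiles)
    image: np.ndarray  # HxWx3 uint8
    track_labels: list[str]

    def save(self, path) -> None:
        Image.fromarray(self.image, mode="RGB").save(path, format="PNG")


def bin_to_pixels(track: SignalTrack, pixel_size: int = DEFAULT_PIXEL_SIZE) -> dict[str, np.ndarray]:
    """Average window values into genomic pixels, per chromosome.

    A window contributes to the pixel containing its midpoint; pixels with
    no windows are NaN.  Pixel count per chromosome = ceil(length / pixel_size).
    """
    if track.value is None:
        raise ValueError("track must be normalized before rendering")
    if pixel_size < track.grid.W:
        raise ValueError("pixel_size must be >= the track's window size")
    out: dict[str, np.ndarray] = {}
    grid = track.grid
    mids = grid.midpoints
    for ci, (chrom, length) in enumerate(grid.layout.chromosomes):
        npix = -(-length // pixel_size)
        sl = slice(*grid.chrom_slices[ci])
        idx = mids[sl] // pixel_size
        vals = track.value[sl]
        ok = np.isfinite(vals)
        sums = np.bincount(idx[ok], weights=vals[ok], minlength=npix)
        counts = np.bincount(idx[ok], minlength=npix)
        with np.errstate(invalid="ignore"):
            out[chrom] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return out


def _resolve_anchors(pixel_sets, percentiles) -> tuple[float, float]:
    allvals = np.concatenate(
        [v for pixels in pixel_sets for v in pixels.values()]
    )
    allvals = allvals[np.isfinite(allvals)]
    if not len(allvals):
        raise ValueError("no finite pixel values to anchor the colour scale")
    p_lo, p_hi = percentiles
    if not (0 <= p_lo < p_hi <= 100):
        raise ValueError("anchor percentiles must satisfy 0 <= low < high <= 100")
    lo, hi = np.percentile(allvals, [p_lo, p_hi])
    if hi <= lo:
        hi = lo + 1e-9
    return float(lo), float(hi)


def colour_for(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Map values to RGB: red at/below lo, green at/above hi, linear between."""
    missing = ~np.isfinite(values)
    t = np.clip((np.where(missing, lo, values) - lo) / (hi - lo), 0.0, 1.0)
    rgb = np.empty(values.shape + (3,), dtype=np.uint8)
    for ch in range(3):
        span = HIGH_COLOUR[ch] - LOW_COLOUR[ch]
        rgb[..., ch] = np.rint(LOW_COLOUR[ch] + t * span).astype(np.uint8)
    rgb[missing] = MISSING_COLOUR
    return rgb


def render(
    tracks,
    pixel_size: int = DEFAULT_PIXEL_SIZE,
    anchors: tuple[float, float] = DEFAULT_ANCHORS,
    block: tuple[int, int] = (14, 4),
    gap: int = 6,
) -> KaryotypeImage:
    """Render one or more tracks as side-by-side vertical ideograms.

    Colour anchors are percentiles of the pixel-value distribution pooled
    over *all* tracks, so phases rendered together share one scale bar.
    ``block`` is the (width, height) in screen pixels of one genomic pixel.
    """
    if isinstance(tracks, SignalTrack):
        tracks = [tracks]
    layout = tracks[0].grid.layout
    for t in tracks:
        if t.grid.layout.chromosomes != layout.chromosomes:
            raise ValueError("tracks must share a genome layout")
    pixel_sets = [bin_to_pixels(t, pixel_size) for t in tracks]
    lo, hi = _resolve_anchors(pixel_sets, anchors)

    bw, bh = block
    max_pix = max(
        len(v) for pixels in pixel_sets for v in pixels.values()
    )
    n_cols = len(layout) * len(tracks)
    label_h = 12
    width = n_cols * bw + (n_cols + 1) * gap
    height = max_pix * bh + 2 * gap + label_h
    canvas = np.full((height, width, 3), 255, dtype=np.uint8)

    col = 0
    for chrom, _ in layout.chromosomes:
        for pixels in pixel_sets:
            vec = pixels[chrom]
            if np.all(~np.isfinite(vec)):
                warnings.warn(f"{chrom}: all pixels missing; rendered grey", stacklevel=2)
            rgb = colour_for(vec, lo, hi)
            x0 = gap + col * (bw + gap)
            body = np.repeat(rgb[:, None, :], bw, axis=1)
            body = np.repeat(body, bh, axis=0)
            canvas[gap : gap + body.shape[0], x0 : x0 + bw] = body
            col += 1

    labels = [
        f"{t.meta.mark or 'track'}:{t.meta.phase or '?'}" for t in tracks
    ]
    # chromosome names under each column group (built-in bitmap font:
    # deterministic bytes)
    img = Image.fromarray(canvas, mode="RGB")
    draw = ImageDraw.Draw(img)
    for i, (chrom, _) in enumerate(layout.chromosomes):
        x0 = gap + i * len(tracks) * (bw + gap)
        draw.text((x0, height - label_h), chrom, fill=(0, 0, 0))
    return KaryotypeImage(pixel_sets, pixel_size, (lo, hi), np.asarray(img), labels)


def compare_phases(
    tracks, pixel_size: int = DEFAULT_PIXEL_SIZE, anchors=DEFAULT_ANCHORS
) -> KaryotypeImage:
    """Side-by-side karyogram of several phases on one jointly anchored scale."""
    return render(tracks, pixel_size=pixel_size, anchors=anchors)
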