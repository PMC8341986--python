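"""Layer-wise quantification of grayscale ISH images.

Each slice is reduced to four numbers — one per lamina of the superior
colliculus (SuG, Op, InG/InWh, DpG) — by (1) min-max rescaling the image to
8-bit, (2) automatic IsoData thresholding to a binary signal mask, (3)
computing the area fraction (percent of signal pixels) inside each layer ROI
and inside a user-chosen background ROI, and (4) subtracting the background
area fraction, clipping at zero.  Multiple slices of the same gene are
averaged.

ROIs are boolean masks congruent with the image; choosing them (including the
weakest-signal background region) is the user's job, mirroring manual ROI
drawing in an image-analysis tool.  :func:`propose_background` is an optional
convenience extension that suggests the darkest sliding-window rectangle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "LAYERS",
    "ISHImage",
    "ROISet",
    "to_8bit",
    "isodata_threshold",
    "auto_threshold",
    "area_fraction",
    "signal_intensity",
    "quantify_gene",
    "quantify_slices",
    "propose_background",
]

#: Lamina names in fixed superficial-to-deep order.
LAYERS: tuple[str, ...] = ("SuG", "Op", "InG/InWh", "DpG")


@dataclass(frozen=True)
class ISHImage:
    """A single grayscale slice of one gene's ISH stain."""

    pixels: np.ndarray
    gene: str = ""
    slice_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError("image must be a 2-D grid of at least 2x2 pixels")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite pixels")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ROISet:
    """Boolean masks for the four laminae plus one background region.

    ``layer_masks`` maps each name in :data:`LAYERS` to a mask; masks must be
    congruent, non-empty, and pairwise disjoint (background included).
    """

    layer_masks: Mapping[str, np.ndarray]
    background: np.ndarray

    def __post_init__(self) -> None:
        bg = np.asarray(self.background, dtype=bool)
        masks = {k: np.asarray(v, dtype=bool) for k, v in self.layer_masks.items()}
        if set(masks) != set(LAYERS):
            raise ValueError(f"layer masks must be exactly {LAYERS}, got {sorted(masks)}")
        shape = bg.shape
        if not bg.any():
            raise ValueError("background mask is empty")
        occupied = bg.copy()
        for name in LAYERS:
            m = masks[name]
            if m.shape != shape:
                raise ValueError(f"mask {name!r} shape {m.shape} != {shape}")
            if not m.any():
                raise ValueError(f"layer mask {name!r} is empty")
            if (m & occupied).any():
                raise ValueError(f"mask {name!r} overlaps another ROI")
            occupied |= m
        object.__setattr__(self, "layer_masks", masks)
        object.__setattr__(self, "background", bg)

    @property
    def shape(self) -> tuple[int, int]:
        return self.background.shape


def to_8bit(image: ISHImage) -> ISHImage:
    """Linearly rescale pixel values to integers in [0, 255].

    The rescale is min-max with round-half-up; a constant image maps to all
    zeros.  Monotone: pixel ordering is preserved.
    """
    px = image.pixels.astype(float)
    lo, hi = px.min(), px.max()
    if hi == lo:
        out = np.zeros(px.shape, dtype=np.uint8)
    else:
        scaled = (px - lo) * (255.0 / (hi - lo))
        out = np.floor(scaled + 0.5).astype(np.uint8)
    return ISHImage(out, gene=image.gene, slice_id=image.slice_id)


def isodata_threshold(image_8bit: np.ndarray) -> float:
    """IsoData (iterative intermeans) threshold level on the 256-bin histogram.

    Starting from the global mean, the level is repeatedly replaced by the
    average of the mean below and the mean at-or-above it until it is stable.
    Returns the final (fractional) level; callers classify ``pixel >= level``
    as signal.  Raises on a constant image (no signal/background split).
    """
    px = np.asarray(image_8bit)
    hist = np.bincount(px.ravel().astype(np.intp), minlength=256).astype(float)
    bins = np.arange(256, dtype=float)
    if np.count_nonzero(hist) < 2:
        raise ValueError("constant image has no threshold")
    t = float((hist * bins).sum() / hist.sum())
    for _ in range(256):
        below = bins < t
        w0, w1 = hist[below].sum(), hist[~below].sum()
        if w0 == 0 or w1 == 0:
            # all mass on one side; nudge to the midpoint of occupied bins
            occ = bins[hist > 0]
            t_new = (occ.min() + occ.max()) / 2.0
        else:
            m0 = (hist[below] * bins[below]).sum() / w0
            m1 = (hist[~below] * bins[~below]).sum() / w1
            t_new = (m0 + m1) / 2.0
        if abs(t_new - t) < 0.5:
            return t_new
        t = t_new
    return t


def auto_threshold(image: ISHImage, manual: float | None = None) -> np.ndarray:
    """Binary signal mask of an 8-bit image.

    Pixels with value >= the IsoData level are signal; a ``manual`` level
    overrides the automatic one.  A constant image yields an empty mask with
    a warning (no signal can be distinguished).
    """
    px = image.pixels
    if manual is not None:
        return px >= manual
    try:
        level = isodata_threshold(px)
    except ValueError:
        warnings.warn(f"constant image {image.gene}/{image.slice_id}: empty signal mask")
        return np.zeros(px.shape, dtype=bool)
    return px >= level


def area_fraction(mask: np.ndarray, roi: np.ndarray) -> float:
    """Percentage of ROI pixels that are signal: 100 * |mask & roi| / |roi|."""
    mask = np.asarray(mask, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    if mask.shape != roi.shape:
        raise ValueError(f"mask shape {mask.shape} != roi shape {roi.shape}")
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("empty ROI has no area fraction")
    return 100.0 * int((mask & roi).sum()) / n_roi


def signal_intensity(
    image: ISHImage, rois: ROISet, manual_threshold: float | None = None
) -> np.ndarray:
    """Background-subtracted layer signal of one slice (4-vector, in [0, 100]).

    intensity(layer) = max(0, AF(layer) - AF(background)) after 8-bit
    conversion and thresholding.  Negative differences are noise and clip to
    zero.
    """
    if rois.shape != image.shape:
        raise ValueError(f"ROI shape {rois.shape} != image shape {image.shape}")
    mask = auto_threshold(to_8bit(image), manual=manual_threshold)
    af_bg = area_fraction(mask, rois.background)
    return np.array(
        [max(0.0, area_fraction(mask, rois.layer_masks[l]) - af_bg) for l in LAYERS]
    )


def quantify_slices(
    slices: Sequence[tuple[ISHImage, ROISet]],
    manual_threshold: float | None = None,
) -> tuple[np.ndarray, int]:
    """Per-layer mean of per-slice intensities for one gene.

    Returns (4-vector of mean intensities, number of slices).  Order of
    slices does not matter.
    """
    if len(slices) == 0:
        raise ValueError("at least one slice is required to quantify a gene")
    per_slice = np.stack(
        [signal_intensity(img, rois, manual_threshold) for img, rois in slices]
    )
    return per_slice.mean(axis=0), len(slices)


def quantify_gene(
    slices_by_gene: Mapping[str, Sequence[tuple[ISHImage, ROISet]]],
    manual_threshold: float | None = None,
):
    """Quantify several genes at once: gene -> (4-vector, slice count).

    Thin convenience over :func:`quantify_slices`; returns a pandas DataFrame
    of intensities (genes x layers) and a Series of slice counts.
    """
    import pandas as pd

    rows, counts = {}, {}
    for gene, slices in slices_by_gene.items():
        vec, n = quantify_slices(slices, manual_threshold)
        rows[gene] = vec
        counts[gene] = n
    intensity = pd.DataFrame.from_dict(rows, orient="index", columns=list(LAYERS))
    intensity.index.name = "gene"
    return intensity, pd.Series(counts, name="n_slices")


def propose_background(
    image: ISHImage, window: tuple[int, int] = (20, 20)
) -> np.ndarray:
    """Suggest a background ROI: the window-sized rectangle of minimal mean.

    Convenience extension only — the published procedure picks the
    weakest-signal region by eye; this helper automates that choice with a
    sliding-window mean and returns the winning rectangle as a boolean mask.
    """
    px = image.pixels.astype(float)
    wr, wc = window
    if wr > px.shape[0] or wc > px.shape[1]:
        raise ValueError("window larger than image")
    windows = np.lib.stride_tricks.sliding_window_view(px, window)
    means = windows.mean(axis=(-2, -1))
    i, j = np.unravel_index(np.argmin(means), means.shape)
    mask = np.zeros(px.shape, dtype=bool)
    mask[i : i + wr, j : j + wc] = True
    return mask
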