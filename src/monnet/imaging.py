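"""Spheroid segmentation, signal aggregation, morphometrics, and registration.

Movies are reduced to a maximum-intensity projection along time, spheroid
units are segmented with a watershed on the thresholded projection, the
frame-wise mean intensity outside the total segmentation mask is subtracted
as background, and per-spheroid traces are the mean intensity inside each
label.  Before/after-treatment stacks are aligned with a translation that
maximizes histogram-based mutual information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import feature, filters, measure, morphology, segmentation

from .traces import FluorescenceMatrix

__all__ = [
    "ImageStack",
    "SpheroidLabels",
    "Translation",
    "max_projection",
    "segment_spheroids",
    "background_subtract",
    "aggregate_signal",
    "morphometrics",
    "register_translation",
]


@dataclass
class ImageStack:
    """Time-lapse intensity stack, frames x height x width."""

    data: np.ndarray
    pixel_size: float = 1.0  # um / px
    frame_rate: float = 30.0  # Hz

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError("stack must be frames x height x width with >= 1 frame")
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise ValueError("intensities must be nonnegative and finite")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


@dataclass
class SpheroidLabels:
    """Integer label image (0 = background) with a per-label property table.

    The table has columns label, area_um2, centroid_x_um, centroid_y_um;
    centroids use x = column * pixel_size, y = row * pixel_size.
    """

    labels: np.ndarray
    pixel_size: float = 1.0
    table: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label image must be 2-D")
        present = np.unique(self.labels[self.labels > 0])
        if len(present) and not np.array_equal(present, np.arange(1, len(present) + 1)):
            raise ValueError("labels must be consecutive positive integers")
        if self.table is None:
            self.table = _label_table(self.labels, self.pixel_size)

    @property
    def n_labels(self) -> int:
        return int(self.labels.max(initial=0))

    def mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass(frozen=True)
class Translation:
    """Rigid in-plane shift in pixels (fractional allowed)."""

    dx: float
    dy: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.dx) and np.isfinite(self.dy)):
            raise ValueError("translation must be finite")

    def __neg__(self) -> "Translation":
        return Translation(-self.dx, -self.dy)


def _label_table(labels: np.ndarray, pixel_size: float) -> pd.DataFrame:
    props = measure.regionprops(labels)
    rows = [
        {
            "label": p.label,
            "area_um2": p.area * pixel_size**2,
            "centroid_x_um": p.centroid[1] * pixel_size,
            "centroid_y_um": p.centroid[0] * pixel_size,
        }
        for p in props
    ]
    return pd.DataFrame(rows, columns=["label", "area_um2", "centroid_x_um",
                                       "centroid_y_um"])


def max_projection(stack: ImageStack | np.ndarray) -> np.ndarray:
    """Per-pixel maximum intensity over frames."""
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack, float)
    if data.ndim == 2:
        return data.copy()
    if data.ndim != 3 or data.shape[0] < 1:
        raise ValueError("need a nonempty frames x height x width stack")
    return data.max(axis=0)


def segment_spheroids(
    projection: np.ndarray,
    lower_thr: float,
    upper_thr: float | None = None,
    min_size: int = 1,
    pixel_size: float = 1.0,
    smooth_sigma: float = 2.0,
    min_seed_distance: int = 5,
) -> SpheroidLabels:
    """Watershed segmentation of spheroid units on a (projection) image.

    The projection is Gaussian-smoothed (``smooth_sigma`` px), the foreground
    is the intensity band [lower_thr, upper_thr], watershed seeds are local
    maxima of the distance transform of the foreground, objects smaller than
    ``min_size`` px are removed and labels relabeled consecutively.  An image
    with no foreground yields an empty (all-zero) labeling.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    img = np.asarray(projection, float)
    sm = filters.gaussian(img, sigma=smooth_sigma, preserve_range=True) \
        if smooth_sigma > 0 else img
    fg = sm >= lower_thr
    if upper_thr is not None:
        fg &= sm <= upper_thr
    if not fg.any():
        return SpheroidLabels(np.zeros(img.shape, dtype=np.int32), pixel_size)
    dist = ndimage.distance_transform_edt(fg)
    peak_idx = feature.peak_local_max(
        dist, min_distance=min_seed_distance, labels=fg, exclude_border=False
    )
    seeds = np.zeros(img.shape, dtype=np.int32)
    seeds[tuple(peak_idx.T)] = np.arange(1, len(peak_idx) + 1)
    labels = segmentation.watershed(-dist, seeds, mask=fg)
    sizes = np.bincount(labels.ravel())
    too_small = np.flatnonzero(sizes < min_size)
    labels[np.isin(labels, too_small)] = 0
    labels, _, _ = segmentation.relabel_sequential(labels)
    return SpheroidLabels(labels.astype(np.int32), pixel_size)


def background_subtract(
    stack: ImageStack, labels: SpheroidLabels
) -> ImageStack:
    """Subtract the frame-wise mean intensity outside the segmentation mask.

    Negative results are clipped at 0 so negative fluorescence cannot
    propagate into the dF/F division.  With an empty labeling the whole-frame
    mean is subtracted.
    """
    if labels.labels.shape != stack.shape:
        raise ValueError("labels and stack spatial shapes differ")
    bg_mask = ~labels.mask()
    if not bg_mask.any():
        raise ValueError("segmentation mask covers the entire image; "
                         "background undefined")
    bg = stack.data[:, bg_mask].mean(axis=1)
    out = np.clip(stack.data - bg[:, None, None], 0.0, None)
    return ImageStack(out, stack.pixel_size, stack.frame_rate)


def aggregate_signal(
    stack: ImageStack, labels: SpheroidLabels
) -> FluorescenceMatrix:
    """Mean intensity inside each label per frame, rows in label order."""
    if labels.labels.shape != stack.shape:
        raise ValueError("labels and stack spatial shapes differ")
    n = labels.n_labels
    lab = labels.labels.ravel()
    counts = np.bincount(lab, minlength=n + 1)[1:]
    flat = stack.data.reshape(stack.n_frames, -1)
    sums = np.stack(
        [np.bincount(lab, weights=frame, minlength=n + 1)[1:] for frame in flat]
    ).T
    F = sums / counts[:, None]
    return FluorescenceMatrix(F, frame_rate=stack.frame_rate,
                              source_ids=list(range(1, n + 1)))


def morphometrics(
    labels: SpheroidLabels, pixel_size: float | None = None
) -> pd.DataFrame:
    """Per-spheroid sizes and nearest-neighbour centre-to-centre distances.

    Returns the label table with an extra ``nn_dist_um`` column (NaN when
    fewer than two labels exist).
    """
    ps = pixel_size if pixel_size is not None else labels.pixel_size
    table = _label_table(labels.labels, ps)
    if len(table) == 0:
        raise ValueError("no labels to measure")
    xy = table[["centroid_x_um", "centroid_y_um"]].to_numpy()
    if len(table) < 2:
        warnings.warn("fewer than 2 labels; nearest-neighbour distances undefined")
        table["nn_dist_um"] = np.nan
        return table
    d = np.hypot(*(xy[:, None, :] - xy[None, :, :]).transpose(2, 0, 1))
    np.fill_diagonal(d, np.inf)
    table["nn_dist_um"] = d.min(axis=1)
    return table


def _mutual_information(a: np.ndarray, b: np.ndarray, n_bins: int) -> float:
    hist, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=n_bins)
    p = hist / hist.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px[:, None] * py[None, :])[nz])))


def register_translation(
    reference: np.ndarray,
    moving: np.ndarray,
    n_bins: int = 32,
    max_shift: int = 20,
    subpixel: bool = False,
) -> Translation:
    """Translation of ``moving`` relative to ``reference`` maximizing MI.

    Exhaustive integer grid search over shifts within ``max_shift`` px on the
    histogram-based (Mattes-style) mutual information of the overlapping
    region, with optional parabolic sub-pixel refinement.  The returned
    ``Translation`` (dx, dy) is such that ``moving`` equals ``reference``
    shifted by (dx, dy); applying the inverse shift to ``moving`` aligns it.
    """
    ref = np.asarray(reference, float)
    mov = np.asarray(moving, float)
    if ref.shape != mov.shape:
        raise ValueError("images must share a shape")
    if np.ptp(ref) == 0 or np.ptp(mov) == 0:
        raise ValueError("mutual information undefined for a constant image")
    h, w = ref.shape
    if max_shift >= min(h, w) // 2:
        raise ValueError("max_shift too large for the image size")

    mi = np.full((2 * max_shift + 1, 2 * max_shift + 1), -np.inf)
    for iy, dy in enumerate(range(-max_shift, max_shift + 1)):
        for ix, dx in enumerate(range(-max_shift, max_shift + 1)):
            # overlap of reference with moving shifted back by (dx, dy)
            ry0, ry1 = max(0, dy), min(h, h + dy)
            rx0, rx1 = max(0, dx), min(w, w + dx)
            a = ref[ry0 - dy : ry1 - dy, rx0 - dx : rx1 - dx]
            b = mov[ry0:ry1, rx0:rx1]
            mi[iy, ix] = _mutual_information(a, b, n_bins)
    iy, ix = np.unravel_index(np.argmax(mi), mi.shape)
    dy = iy - max_shift
    dx = ix - max_shift
    fy, fx = float(dy), float(dx)
    if subpixel:
        fx += _parabolic_offset(mi[iy, max(ix - 1, 0) : ix + 2]) if 0 < ix < 2 * max_shift else 0.0
        fy += _parabolic_offset(mi[max(iy - 1, 0) : iy + 2, ix]) if 0 < iy < 2 * max_shift else 0.0
    return Translation(fx, fy)


def _parabolic_offset(triplet: np.ndarray) -> float:
    """Vertex offset of a parabola through three equally spaced samples."""
    if len(triplet) != 3:
        return 0.0
    a, b, c = triplet
    denom = a - 2 * b + c
    if denom == 0:
        return 0.0
    return float(np.clip(0.5 * (a - c) / denom, -0.5, 0.5))
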