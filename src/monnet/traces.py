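"""Fluorescence trace processing: dF/F, denoising, onset inference, activity stats.

The raw per-source signal is normalized to dF/F against a sliding low-percentile
baseline (8th percentile over a 500-frame centered window, truncated at the
recording edges so the baseline is defined at every frame), median-denoised,
and deconvolved against a second-order autoregressive calcium kernel to infer
activity onsets.  Onsets exceeding 5 robust standard deviations of the trace
residual are counted as significant events for the activity rate and for the
clustered-activity-duration (full width at 75% or 50% of the dF/F peak)
statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .simulate import ar2_impulse_response, _check_ar2_stable

logger = logging.getLogger(__name__)

__all__ = [
    "FluorescenceMatrix",
    "DffMatrix",
    "OnsetMatrix",
    "estimate_baseline",
    "compute_dff",
    "denoise_median",
    "estimate_ar2",
    "infer_onsets",
    "significant_onset_mask",
    "activity_rate",
    "clustered_activity_duration",
]

MAD_TO_SD = 1.4826  # consistency factor for Gaussian noise


@dataclass
class FluorescenceMatrix:
    """Raw per-source fluorescence, sources x frames."""

    F: np.ndarray
    frame_rate: float = 30.0
    source_ids: list | None = None

    def __post_init__(self) -> None:
        self.F = np.atleast_2d(np.asarray(self.F, float))
        if self.F.shape[1] < 2:
            raise ValueError("need at least 2 frames")
        if not np.all(np.isfinite(self.F)):
            raise ValueError("fluorescence must be finite")
        if self.source_ids is None:
            self.source_ids = list(range(self.F.shape[0]))

    @property
    def n_sources(self) -> int:
        return self.F.shape[0]

    @property
    def n_frames(self) -> int:
        return self.F.shape[1]


@dataclass
class DffMatrix:
    """Baseline-normalized fluorescence (dimensionless) with provenance."""

    dff: np.ndarray
    baseline: np.ndarray
    frame_rate: float = 30.0
    window: int = 500
    percentile: float = 8.0
    source_ids: list | None = None
    valid: np.ndarray | None = None  # per-source mask; False = degenerate baseline

    def __post_init__(self) -> None:
        self.dff = np.atleast_2d(np.asarray(self.dff, float))
        self.baseline = np.atleast_2d(np.asarray(self.baseline, float))
        if self.dff.shape != self.baseline.shape:
            raise ValueError("dff and baseline shapes differ")
        if self.source_ids is None:
            self.source_ids = list(range(self.dff.shape[0]))
        if self.valid is None:
            self.valid = np.ones(self.dff.shape[0], dtype=bool)

    @property
    def n_sources(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]


@dataclass
class OnsetMatrix:
    """Inferred nonnegative activity onsets and the kernel used."""

    s: np.ndarray  # sources x frames, >= 0
    g1: float
    g2: float
    noise_sd_est: np.ndarray = field(default_factory=lambda: np.array([]))
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        self.s = np.atleast_2d(np.asarray(self.s, float))
        if np.any(self.s < -1e-12):
            raise ValueError("onset amplitudes must be nonnegative")
        self.s = np.maximum(self.s, 0.0)

    def reconstruction(self) -> np.ndarray:
        """Forward AR(2) reconstruction of the calcium trace from onsets."""
        n_src, n_frames = self.s.shape
        c = np.zeros_like(self.s)
        c[:, 0] = self.s[:, 0]
        if n_frames > 1:
            c[:, 1] = self.g1 * c[:, 0] + self.s[:, 1]
        for t in range(2, n_frames):
            c[:, t] = self.g1 * c[:, t - 1] + self.g2 * c[:, t - 2] + self.s[:, t]
        return c


def estimate_baseline(
    F: np.ndarray, window: int = 500, percentile: float = 8.0
) -> np.ndarray:
    """Sliding-percentile baseline, centered window truncated at the edges.

    At frame ``t`` the baseline is the given percentile of the trace over a
    window of ``window`` frames centered at ``t``; near the recording edges
    the window is truncated so the baseline is defined everywhere.  For traces
    shorter than the window this reduces to the percentile of the whole trace.
    """
    F = np.atleast_2d(np.asarray(F, float))
    if window < 2:
        raise ValueError("window must be >= 2")
    if np.isnan(F).all():
        raise ValueError("all-NaN input")
    n_src, T = F.shape
    half_lo = (window - 1) // 2  # frames before t in a centered window
    half_hi = window - 1 - half_lo
    out = np.empty_like(F)
    if T >= window:
        # interior frames: full windows, vectorized in source chunks to keep
        # the percentile working set small
        sw = np.lib.stride_tricks.sliding_window_view(F, window, axis=1)
        chunk = max(1, int(2e7 // (sw.shape[1] * window)))
        for i in range(0, n_src, chunk):
            out[i : i + chunk, half_lo : T - half_hi] = np.percentile(
                sw[i : i + chunk], percentile, axis=2
            )
    lo_edge = min(half_lo, T)
    for t in range(lo_edge):
        out[:, t] = np.percentile(F[:, : min(t + half_hi + 1, T)], percentile, axis=1)
    start = max(T - half_hi, half_lo)
    for t in range(start, T):
        out[:, t] = np.percentile(F[:, max(t - half_lo, 0):], percentile, axis=1)
    return out


def compute_dff(
    F: np.ndarray | FluorescenceMatrix,
    baseline: np.ndarray | None = None,
    window: int = 500,
    percentile: float = 8.0,
    eps: float = 1e-9,
) -> DffMatrix:
    """dF/F = (F - baseline) / baseline.

    Sources whose baseline falls below ``eps`` anywhere are flagged invalid
    (their dff is set to NaN) and excluded from downstream sample averages.
    """
    frame_rate = 30.0
    source_ids = None
    if isinstance(F, FluorescenceMatrix):
        frame_rate = F.frame_rate
        source_ids = F.source_ids
        F = F.F
    F = np.atleast_2d(np.asarray(F, float))
    if baseline is None:
        baseline = estimate_baseline(F, window=window, percentile=percentile)
    baseline = np.atleast_2d(np.asarray(baseline, float))
    valid = ~(baseline <= eps).any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = (F - baseline) / baseline
    if not valid.all():
        dff[~valid] = np.nan
        logger.warning(
            "%d source(s) excluded: baseline <= %.1e", int((~valid).sum()), eps
        )
    return DffMatrix(dff, baseline, frame_rate=frame_rate, window=window,
                     percentile=percentile, source_ids=source_ids, valid=valid)


def denoise_median(dff: np.ndarray | DffMatrix, width: int = 3):
    """Per-source 1-D median filter; edges handled by reflection."""
    if width % 2 == 0 or width < 3:
        raise ValueError("width must be odd and >= 3")
    if isinstance(dff, DffMatrix):
        out = ndimage.median_filter(dff.dff, size=(1, width), mode="reflect")
        return DffMatrix(out, dff.baseline, dff.frame_rate, dff.window,
                         dff.percentile, dff.source_ids, dff.valid)
    arr = np.atleast_2d(np.asarray(dff, float))
    return ndimage.median_filter(arr, size=(1, width), mode="reflect")


def _stability_project(g1: float, g2: float) -> tuple[float, float]:
    """Pull AR(2) coefficients just inside the stability triangle."""
    m = 1e-4
    g2 = min(max(g2, -1 + m), 1 - m)
    g1 = min(g1, 1 - g2 - m)
    g1 = max(g1, g2 - 1 + m)
    return g1, g2


def estimate_ar2(trace: np.ndarray, max_lag: int = 5) -> tuple[float, float]:
    """Method-of-moments AR(2) coefficients from autocovariance lags 1..max_lag.

    Solves the Yule-Walker-style regression r_k = g1 r_{k-1} + g2 r_{k-2}
    over k = 2..max_lag in least squares, then projects into the stability
    region.
    """
    x = np.asarray(trace, float)
    x = x - x.mean()
    T = len(x)
    r = np.array([np.dot(x[: T - k], x[k:]) / T for k in range(max_lag + 1)])
    A = np.column_stack([r[1:max_lag], r[0 : max_lag - 1]])
    b = r[2 : max_lag + 1]
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return _stability_project(float(sol[0]), float(sol[1]))


def _deconvolve_one(
    y: np.ndarray, g1: float, g2: float, kappa: float = 3.0
) -> np.ndarray:
    """Sparse nonnegative deconvolution of a single trace.

    The AR(2) model is exactly invertible: d_t = y_t - g1 y_{t-1} - g2 y_{t-2}
    equals the onset train for a noiseless trace.  Candidate onset frames are
    taken where d exceeds ``kappa`` robust SDs of d (or a tiny absolute floor
    when the trace is noiseless), and the onset amplitudes are then refit by
    nonnegative least squares on the truncated impulse-response columns,
    which removes the spurious candidates that thresholding lets through.
    """
    T = len(y)
    d = y.copy()
    d[1:] -= g1 * y[:-1]
    if T > 2:
        d[2:] -= g2 * y[:-2]
    scale = np.max(np.abs(y)) or 1.0
    sigma_d = MAD_TO_SD * np.median(np.abs(d - np.median(d)))
    thr = max(kappa * sigma_d, 1e-9 * scale)
    support = np.flatnonzero(d > thr)
    s = np.zeros(T)
    if len(support) == 0:
        return s
    # truncated impulse response (long enough that the tail is negligible)
    h_full = ar2_impulse_response(g1, g2, T)
    keep = np.flatnonzero(np.abs(h_full) > 1e-12 * np.abs(h_full).max())
    h = h_full[: keep[-1] + 1] if len(keep) else h_full[:1]
    m = len(h)
    A = np.zeros((T, len(support)))
    for j, t0 in enumerate(support):
        n = min(m, T - t0)
        A[t0 : t0 + n, j] = h[:n]
    coef, _ = optimize.nnls(A, y)
    s[support] = coef
    return s


def infer_onsets(
    dff: np.ndarray | DffMatrix,
    g1: float | None = None,
    g2: float | None = None,
    kappa: float = 3.0,
) -> OnsetMatrix:
    """Infer nonnegative activity onsets under an AR(2) generative model.

    When ``g1``/``g2`` are not supplied they are estimated per-sample from the
    trace autocovariance (method of moments, projected into the stability
    region).  Invalid (flagged) sources get all-zero onsets.
    """
    frame_rate = 30.0
    valid = None
    if isinstance(dff, DffMatrix):
        frame_rate = dff.frame_rate
        valid = dff.valid
        arr = dff.dff
    else:
        arr = np.atleast_2d(np.asarray(dff, float))
    if g1 is None or g2 is None:
        # pool sources: average per-source estimates weighted by variance
        ests = [estimate_ar2(row) for row in arr if np.isfinite(row).all()
                and np.ptp(row) > 0]
        if not ests:
            g1, g2 = 0.0, 0.0
        else:
            g1 = float(np.median([e[0] for e in ests]))
            g2 = float(np.median([e[1] for e in ests]))
            g1, g2 = _stability_project(g1, g2)
        logger.info("estimated AR(2) coefficients g1=%.4f g2=%.4f", g1, g2)
    _check_ar2_stable(g1, g2)
    n_src, T = arr.shape
    s = np.zeros((n_src, T))
    for i in range(n_src):
        if valid is not None and not valid[i]:
            continue
        row = arr[i]
        if not np.isfinite(row).all():
            continue
        s[i] = _deconvolve_one(row, g1, g2, kappa=kappa)
    onsets = OnsetMatrix(s, g1, g2, frame_rate=frame_rate)
    resid = arr - onsets.reconstruction()
    resid = np.where(np.isfinite(resid), resid, 0.0)
    med = np.median(resid, axis=1, keepdims=True)
    onsets.noise_sd_est = MAD_TO_SD * np.median(np.abs(resid - med), axis=1)
    return onsets


def significant_onset_mask(
    onsets: OnsetMatrix, sd_thresh: float = 5.0
) -> np.ndarray:
    """Frames whose onset amplitude strictly exceeds ``sd_thresh`` noise SDs.

    The noise scale is the per-source robust SD of the dF/F residual after
    subtracting the AR(2) reconstruction (MAD * 1.4826).  The comparison is a
    strict ``>``: an amplitude exactly at threshold does not count.
    """
    sd = onsets.noise_sd_est
    if sd.size == 0:
        raise ValueError("onsets carry no noise estimate; run infer_onsets")
    return onsets.s > sd_thresh * sd[:, None]


def activity_rate(
    onsets: OnsetMatrix, frame_rate: float | None = None, sd_thresh: float = 5.0
) -> tuple[np.ndarray, float]:
    """Per-source significant-event rate (events/min) and the sample mean."""
    fr = frame_rate if frame_rate is not None else onsets.frame_rate
    if fr <= 0:
        raise ValueError("frame_rate must be positive")
    events = significant_onset_mask(onsets, sd_thresh).sum(axis=1)
    minutes = onsets.s.shape[1] / fr / 60.0
    rates = events / minutes
    return rates, float(rates.mean())


def _peak_width(dff: np.ndarray, onset_frame: int, level: float) -> tuple[int, int, int]:
    """Forward-traverse to the peak, then find the frames at >= level*peak.

    Returns (left, right, width_frames) for the contiguous run of frames with
    dff >= level * peak containing the peak.
    """
    T = len(dff)
    p = onset_frame
    while p + 1 < T and dff[p + 1] > dff[p]:
        p += 1
    thr = level * dff[p]
    left = p
    while left - 1 >= 0 and dff[left - 1] >= thr:
        left -= 1
    right = p
    while right + 1 < T and dff[right + 1] >= thr:
        right += 1
    return left, right, right - left + 1


def clustered_activity_duration(
    dff: np.ndarray | DffMatrix,
    onsets: OnsetMatrix,
    level: float = 0.75,
    frame_rate: float | None = None,
    sd_thresh: float = 5.0,
) -> tuple[np.ndarray, float]:
    """Full width of dF/F transients at ``level`` of the peak, in seconds.

    For each significant onset, an iterative forward traversal locates the
    local dF/F peak; the width is the count of contiguous frames at or above
    ``level * peak`` around it (relative to the dF/F baseline of 0), in
    seconds.  Onsets falling inside an already-analyzed peak are skipped.
    Returns per-source mean durations (NaN where a source has no significant
    onsets) and the mean over sources that have any.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    arr = dff.dff if isinstance(dff, DffMatrix) else np.atleast_2d(np.asarray(dff, float))
    fr = frame_rate if frame_rate is not None else onsets.frame_rate
    sig = significant_onset_mask(onsets, sd_thresh)
    n_src = arr.shape[0]
    per_source = np.full(n_src, np.nan)
    for i in range(n_src):
        frames = np.flatnonzero(sig[i])
        if len(frames) == 0:
            continue
        widths = []
        analyzed_until = -1
        for f in frames:
            if f <= analyzed_until:
                continue  # inside an already-analyzed peak
            left, right, w = _peak_width(arr[i], f, level)
            widths.append(w)
            analyzed_until = right
        per_source[i] = np.mean(widths) / fr
    has = ~np.isnan(per_source)
    if not has.any():
        warnings.warn("no source had a significant onset; sample mean undefined")
        return per_source, float("nan")
    return per_source, float(per_source[has].mean())
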