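"""Weighted single-cell trace extraction and per-recording metrics.

Converts a photon-count movie plus target centroids into fluorescence
traces: crop an ROI around each known spot centroid, segment the responsive
(membrane) pixels, weight every pixel by the non-negative slope of its
regression onto the mean trace of the segmented pixels, extract the
weighted trace, remove the slow photobleaching trend, and express the
result as -%dF/F0 (sign-flipped so that depolarisation of a negative-going
indicator is positive).  Also computes the recording-quality metrics:
SNR, photostability, photorecovery, correlation image/FWHM and
signal-to-background ratio.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from skimage.filters import threshold_otsu

from .synthetic import Movie

__all__ = [
    "RoiCrop",
    "PixelWeights",
    "FluorescenceTrace",
    "NoResponsiveCellError",
    "NoiseFreeInputError",
    "SBRResult",
    "crop_roi",
    "initial_segment",
    "pixel_weights",
    "extract_trace",
    "detrend",
    "dff",
    "snr",
    "photostability",
    "photorecovery",
    "correlation_image",
    "correlation_fwhm",
    "sbr",
]


class NoResponsiveCellError(ValueError):
    """Raised when an ROI contains no voltage-responsive pixels."""


class NoiseFreeInputError(ValueError):
    """Raised when a baseline has zero variance (no noise to normalise by)."""


@dataclass
class RoiCrop:
    """A cropped pixel stack plus the offset back into the source movie."""

    stack: np.ndarray                 # (T, h, w)
    origin: tuple[int, int]           # (row, col) of crop[0, 0] in the movie
    centroid_um: tuple[float, float]
    pixel_size_um: float
    frame_rate_hz: float

    def to_movie_indices(self, rows: np.ndarray,
                         cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map crop pixel indices back to movie indices."""
        return rows + self.origin[0], cols + self.origin[1]


@dataclass
class PixelWeights:
    weights: np.ndarray               # (h, w), >= 0, sums to 1
    support: np.ndarray               # bool (h, w)
    n_pixels_used: int


@dataclass
class FluorescenceTrace:
    times_ms: np.ndarray
    raw: np.ndarray
    frame_rate_hz: float
    detrended: np.ndarray | None = None
    F0: float | None = None
    dff_pct: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def crop_roi(movie: Movie, centroid_um: tuple[float, float],
             size_px: int) -> RoiCrop:
    """Crop a ``size_px`` square centred on the (known) spot centroid.

    Crops are clipped at the movie borders with a warning; the origin
    offset is recorded so crop coordinates round-trip to movie coordinates.
    """
    if size_px <= 0:
        raise ValueError("size must be positive")
    T, H, W = movie.data.shape
    col_c = centroid_um[0] / movie.pixel_size_um
    row_c = centroid_um[1] / movie.pixel_size_um
    if not (0 <= col_c < W and 0 <= row_c < H):
        raise ValueError(f"centroid {centroid_um} um outside movie")
    r0 = int(round(row_c - size_px / 2))
    c0 = int(round(col_c - size_px / 2))
    r1, c1 = r0 + size_px, c0 + size_px
    if r0 < 0 or c0 < 0 or r1 > H or c1 > W:
        warnings.warn("ROI clipped at movie border", stacklevel=2)
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1, H), min(c1, W)
    return RoiCrop(movie.data[:, r0:r1, c0:c1].astype(float), (r0, c0),
                   centroid_um, movie.pixel_size_um, movie.frame_rate_hz)


def _highpass(traces: np.ndarray, frame_rate_hz: float) -> np.ndarray:
    """Remove slow trends (~<2 Hz) along the first axis."""
    sigma = max(frame_rate_hz / 10.0, 2.0)
    slow = ndimage.gaussian_filter1d(traces, sigma, axis=0)
    return traces - slow


def initial_segment(roi: RoiCrop, corr_floor: float | None = None,
                    sub_region: np.ndarray | None = None) -> np.ndarray:
    """Segment the voltage-responsive pixels of an ROI.

    Each pixel's high-passed trace is correlated with the high-passed ROI
    mean; pixels above an adaptive threshold (halfway between a
    significance floor of 5 null standard deviations, i.e. 5/sqrt(T), and
    the Otsu split of the supra-floor correlations) form the mask.
    ``sub_region`` restricts the search to a manually identified area (for
    the rare case of overlapping cells).  Raises
    :class:`NoResponsiveCellError` when nothing exceeds the floor.
    """
    T = roi.stack.shape[0]
    if T < 100:
        raise ValueError("need at least 100 frames to segment")
    if corr_floor is None:
        corr_floor = max(0.05, 5.0 / math.sqrt(T))
    stack = roi.stack
    if sub_region is not None:
        stack = np.where(sub_region[None], stack, np.nan)
    flat = stack.reshape(T, -1)
    hp = _highpass(np.nan_to_num(flat), roi.frame_rate_hz)
    ref = np.nanmean(hp[:, ~np.isnan(flat[0])], axis=1)
    ref = ref - ref.mean()
    px = hp - hp.mean(axis=0)
    denom = np.sqrt((px ** 2).sum(axis=0) * (ref ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (px * ref[:, None]).sum(axis=0) / denom
    corr = np.nan_to_num(corr).reshape(roi.stack.shape[1:])
    if sub_region is not None:
        corr[~sub_region] = 0.0

    above = corr > corr_floor
    if not above.any():
        raise NoResponsiveCellError("no responsive cell in ROI")
    try:
        # halfway between the floor and Otsu keeps the thin membrane rim
        thr = max(corr_floor, 0.5 * (corr_floor + threshold_otsu(corr[above])))
    except ValueError:
        thr = corr_floor
    mask = corr >= thr
    if not mask.any():
        mask = above
    mask = _remove_small(mask, 4)
    if not mask.any():
        raise NoResponsiveCellError("no responsive cell in ROI")
    return mask


def _remove_small(mask: np.ndarray, min_size: int) -> np.ndarray:
    lbl, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(mask, lbl, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_size) + 1
    return np.isin(lbl, keep)


def pixel_weights(roi: RoiCrop, mask: np.ndarray,
                  t_threshold: float = 2.0) -> PixelWeights:
    """Regression-based pixel weighting.

    Every pixel's trace is regressed (ordinary least squares, intercept
    included) against the mean trace of the segmented pixels; the weights
    are the non-negative slopes, renormalised to sum to one.  Pixels whose
    slope is non-positive, or not significantly positive (slope t-statistic
    below ``t_threshold``), leave the support — this is what shrinks the
    analysed pixel set relative to the segmentation.
    """
    if not mask.any():
        raise ValueError("mask is empty")
    T = roi.stack.shape[0]
    flat = roi.stack.reshape(T, -1)
    ref = flat[:, mask.ravel()].mean(axis=1)
    ref_c = ref - ref.mean()
    var = (ref_c ** 2).sum()
    if var <= 0:
        raise ValueError("degenerate (constant) reference trace")
    centred = flat - flat.mean(axis=0)
    slopes = centred.T @ ref_c / var
    # slope standard error from the residual variance
    sse = (centred ** 2).sum(axis=0) - slopes ** 2 * var
    se = np.sqrt(np.maximum(sse, 0.0) / max(T - 2, 1) / var)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = np.where(se > 0, slopes / se, np.inf * np.sign(slopes))
    keep = (slopes > 0) & (tstat >= t_threshold) & mask.ravel()
    w = np.where(keep, slopes, 0.0).reshape(roi.stack.shape[1:])
    total = w.sum()
    if total <= 0:
        raise ValueError("all regression slopes non-positive")
    w /= total
    support = w > 0
    return PixelWeights(w, support, int(support.sum()))


def extract_trace(roi: RoiCrop, weights: PixelWeights | np.ndarray
                  ) -> FluorescenceTrace:
    """Weighted mean trace, trace_t = sum_px w_px * stack_t,px."""
    w = weights.weights if isinstance(weights, PixelWeights) else weights
    if not math.isclose(float(w.sum()), 1.0, rel_tol=1e-6):
        raise ValueError("weights must be normalised")
    T = roi.stack.shape[0]
    raw = roi.stack.reshape(T, -1) @ w.ravel()
    times = np.arange(T) * 1000.0 / roi.frame_rate_hz
    return FluorescenceTrace(times, raw, roi.frame_rate_hz)


def _bi_exp(t, a, tau1, tau2, frac, c):
    return a * (c + (1 - c) * (frac * np.exp(-t / tau1)
                               + (1 - frac) * np.exp(-t / tau2)))


def _running_percentile(x: np.ndarray, frame_rate_hz: float,
                        q: float, window_s: float = 1.0) -> np.ndarray:
    win = max(int(window_s * frame_rate_hz), 5)
    return ndimage.percentile_filter(x, q, size=win, mode="nearest")


def detrend(trace: FluorescenceTrace,
            illumination_epochs_ms: list[tuple[float, float]] | None = None,
            method: str = "biexp", polarity: str = "negative"
            ) -> FluorescenceTrace:
    """Remove the slow multiplicative (bleaching) trend.

    Default: fit a bi-exponential-with-offset to a running-percentile
    baseline (80th percentile for a negative-going indicator, so that
    transient dips do not drag the fit down) within the illumination
    epochs, then divide it out, preserving the initial level.  Falls back
    to the smoothed percentile baseline itself if the fit fails.
    Fast transients are preserved (steps attenuated by < 2%).
    """
    raw, times = trace.raw, trace.times_ms
    if illumination_epochs_ms:
        lit = np.zeros(len(raw), bool)
        for on, off in illumination_epochs_ms:
            lit |= (times >= on) & (times < off)
        if not lit.any():
            lit[:] = True
    else:
        lit = np.ones(len(raw), bool)

    q = 80.0 if polarity == "negative" else 20.0
    baseline = _running_percentile(raw, trace.frame_rate_hz, q)
    t_s = (times - times[lit][0]) / 1000.0
    trend = None
    if method == "biexp":
        try:
            scale = baseline[lit][:5].mean()
            p0 = (scale, 2.0, 20.0, 0.7, 0.7)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = optimize.curve_fit(
                    _bi_exp, t_s[lit], baseline[lit], p0=p0,
                    bounds=([0, 1e-3, 1e-3, 0, 0],
                            [np.inf, 1e3, 1e4, 1, 1]), maxfev=4000)
            trend = _bi_exp(np.where(t_s > 0, t_s, 0.0), *popt)
            if not np.all(np.isfinite(trend)) or trend.min() <= 0:
                trend = None
        except (RuntimeError, ValueError):
            trend = None
        if trend is None:
            warnings.warn("bi-exponential fit failed; falling back to "
                          "running-percentile baseline", stacklevel=2)
    if trend is None or method == "percentile":
        trend = ndimage.gaussian_filter1d(baseline,
                                          trace.frame_rate_hz / 4.0)
        trend = np.maximum(trend, 1e-12)

    ref_level = float(trend[lit][0])
    det = raw / (trend / ref_level)
    out = FluorescenceTrace(times, raw, trace.frame_rate_hz,
                            detrended=det, meta=dict(trace.meta))
    out.meta["detrend_method"] = method if trend is not None else "percentile"
    return out


def dff(trace: FluorescenceTrace,
        baseline_window_ms: tuple[float, float]) -> FluorescenceTrace:
    """-%dF/F0 = 100 * (F0 - F) / F0 on the detrended trace.

    F0 is the mean over the baseline window; positive values mean
    fluorescence dimming (depolarisation for a negative-going indicator).
    """
    f = trace.detrended if trace.detrended is not None else trace.raw
    sel = (trace.times_ms >= baseline_window_ms[0]) & \
          (trace.times_ms < baseline_window_ms[1])
    if not sel.any():
        raise ValueError("baseline window outside trace")
    F0 = float(f[sel].mean())
    if F0 <= 0:
        raise ValueError("non-positive F0")
    out = FluorescenceTrace(trace.times_ms, trace.raw, trace.frame_rate_hz,
                            detrended=trace.detrended, F0=F0,
                            dff_pct=100.0 * (F0 - f) / F0,
                            meta=dict(trace.meta))
    return out


def snr(dff_trace: np.ndarray, times_ms: np.ndarray,
        signal_window_ms: tuple[float, float],
        baseline_window_ms: tuple[float, float]) -> float:
    """Signal amplitude divided by the baseline standard deviation."""
    sig = (times_ms >= signal_window_ms[0]) & (times_ms < signal_window_ms[1])
    base = (times_ms >= baseline_window_ms[0]) & \
           (times_ms < baseline_window_ms[1])
    if not sig.any() or not base.any():
        raise ValueError("empty window")
    if sig[base].any() if len(sig) == len(base) else False:
        raise ValueError("windows must be disjoint")
    sd = float(dff_trace[base].std())
    if sd == 0:
        raise NoiseFreeInputError("baseline has zero variance")
    amp = float(dff_trace[sig].mean() - dff_trace[base].mean())
    return amp / sd


def photostability(trace: np.ndarray, times_ms: np.ndarray,
                   illumination_epoch_ms: tuple[float, float]) -> float:
    """Fraction of fluorescence retained at the end of an epoch:
    mean of the final 5% of illuminated samples over the first 5%."""
    on, off = illumination_epoch_ms
    idx = np.nonzero((times_ms >= on) & (times_ms < off))[0]
    if idx.size < 20:
        raise ValueError("epoch too short (< 20 samples)")
    k = max(int(0.05 * idx.size), 1)
    return float(trace[idx[-k:]].mean() / trace[idx[:k]].mean())


def photorecovery(trace: np.ndarray, times_ms: np.ndarray,
                  epochs_ms: list[tuple[float, float]],
                  n_samples: int = 5) -> float:
    """Fluorescence at the second epoch's start relative to the first's."""
    if len(epochs_ms) < 2:
        raise ValueError("need two illumination epochs")
    starts = []
    for on, off in epochs_ms[:2]:
        idx = np.nonzero((times_ms >= on) & (times_ms < off))[0]
        if idx.size < n_samples:
            raise ValueError("epoch too short")
        starts.append(trace[idx[:n_samples]].mean())
    return float(starts[1] / starts[0])


def correlation_image(roi: RoiCrop, reference_trace: np.ndarray
                      ) -> np.ndarray:
    """Per-pixel Pearson correlation with a reference trace."""
    T = roi.stack.shape[0]
    if T < 500:
        raise ValueError("need at least 500 frames")
    ref = np.asarray(reference_trace, float)
    ref = ref - ref.mean()
    if ref.std() == 0:
        raise ValueError("constant reference trace")
    flat = roi.stack.reshape(T, -1)
    px = flat - flat.mean(axis=0)
    denom = np.sqrt((px ** 2).sum(axis=0) * (ref ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (px * ref[:, None]).sum(axis=0) / denom
    return np.nan_to_num(c).reshape(roi.stack.shape[1:])


def correlation_fwhm(image: np.ndarray, pixel_size_um: float,
                     centre: tuple[float, float] | None = None) -> float:
    """FWHM (um) of the radially averaged correlation profile.

    The profile is averaged in 1-pixel annular bins about ``centre``
    (default: intensity-weighted centroid of the positive part) and the
    half-maximum crossing is located by linear interpolation.
    """
    img = np.maximum(np.asarray(image, float), 0.0)
    if centre is None:
        total = img.sum()
        if total <= 0:
            raise ValueError("image has no positive values")
        yy, xx = np.mgrid[: img.shape[0], : img.shape[1]]
        centre = ((img * yy).sum() / total, (img * xx).sum() / total)
    yy, xx = np.mgrid[: img.shape[0], : img.shape[1]]
    r = np.hypot(yy - centre[0], xx - centre[1])
    bins = np.arange(0, r.max() + 1)
    which = np.digitize(r.ravel(), bins)
    prof = np.array([img.ravel()[which == i].mean()
                     if (which == i).any() else 0.0
                     for i in range(1, len(bins))])
    if prof.size == 0 or prof.max() <= 0:
        raise ValueError("empty radial profile")
    half = prof.max() / 2.0
    above = prof >= half
    last = int(np.nonzero(above)[0].max())
    if last + 1 >= prof.size:
        radius = bins[last] + 0.5
    else:
        p0, p1 = prof[last], prof[last + 1]
        frac = (p0 - half) / (p0 - p1) if p0 != p1 else 0.0
        radius = bins[last] + 0.5 + frac
    return 2.0 * radius * pixel_size_um


@dataclass
class SBRResult:
    value: float
    definition: str
    capped: bool = False

    def __float__(self) -> float:
        return self.value


def sbr(roi: RoiCrop, weights: PixelWeights,
        dff_amplitude_fn=None,
        background_annulus: np.ndarray | None = None,
        signal_window: tuple[int, int] | None = None,
        baseline_window: tuple[int, int] | None = None,
        cap: float = 1e6) -> SBRResult:
    """Signal-to-background ratio.

    Mean signal amplitude over the weight support divided by the mean
    amplitude in a disjoint background region (default: everything outside
    a one-pixel dilation of the support).  Amplitude is the absolute
    baseline-to-signal-window change of the mean trace of each region.
    A zero-fluctuation background is guarded by capping and flagging.
    """
    support = weights.support
    if background_annulus is None:
        background_annulus = ~ndimage.binary_dilation(support, iterations=2)
    if not background_annulus.any():
        raise ValueError("empty background region")
    if (background_annulus & support).any():
        raise ValueError("background overlaps support")
    T = roi.stack.shape[0]
    if signal_window is None or baseline_window is None:
        raise ValueError("signal and baseline frame windows required")

    def amplitude(mask: np.ndarray) -> float:
        tr = roi.stack[:, mask].mean(axis=1)
        b = tr[baseline_window[0]:baseline_window[1]].mean()
        s = tr[signal_window[0]:signal_window[1]].mean()
        return abs(s - b)

    sig = amplitude(support)
    bg = amplitude(background_annulus)
    definition = ("mean in-support signal amplitude / mean background "
                  "amplitude (baseline-to-signal-window change)")
    if bg == 0:
        return SBRResult(cap, definition, capped=True)
    return SBRResult(sig / bg, definition)
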