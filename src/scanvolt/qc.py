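"""Motion quality control for camera voltage-imaging recordings.

The movie is smoothed with a 3-D Gaussian kernel (default sigmas 1 frame
temporally and 5 pixels in each spatial axis), the intensity centre of
mass of every smoothed frame is computed, and the recording is rejected
when fluorescence-intensity changes are correlated with centre-of-mass
displacement (a motion artefact masquerading as signal).  QC only
annotates; it never modifies the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .synthetic import Movie

__all__ = ["MotionReport", "motion_check"]


@dataclass
class MotionReport:
    com_px: np.ndarray            # (T, 2) centre of mass (row, col)
    displacement_px: np.ndarray   # (T,) distance from the median CoM
    mean_intensity: np.ndarray    # (T,)
    correlation: float            # |dCoM| vs |dIntensity| Pearson r
    max_displacement_px: float
    reject: bool
    sigmas: tuple[float, float, float] = (1.0, 5.0, 5.0)
    thresholds: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.com_px)


def motion_check(movie: Movie,
                 sigmas: tuple[float, float, float] = (1.0, 5.0, 5.0),
                 corr_threshold: float = 0.5,
                 displacement_floor_px: float = 0.5) -> MotionReport:
    """Detect intensity-correlated motion in a movie.

    Frames are smoothed with a 3-D Gaussian (sigmas in frames, pixels,
    pixels), background-subtracted (per-frame median, clipped at zero so
    the centre of mass weights only supra-background fluorescence), and the
    per-frame centre of mass is computed.  The recording is rejected when
    |Pearson correlation| between per-frame |CoM displacement| and
    |mean-intensity change| exceeds ``corr_threshold`` AND the maximum
    displacement exceeds ``displacement_floor_px``.
    """
    data = movie.data.astype(float)
    if data.shape[0] < 50:
        raise ValueError("need at least 50 frames for motion QC")
    if not np.any(data):
        raise ValueError("degenerate all-zero movie")
    sm = ndimage.gaussian_filter(data, sigma=sigmas)
    med = np.median(sm, axis=(1, 2), keepdims=True)
    fg = np.maximum(sm - med, 0.0)
    totals = fg.sum(axis=(1, 2))
    totals[totals == 0] = np.nan
    yy, xx = np.mgrid[: data.shape[1], : data.shape[2]]
    com = np.column_stack([
        np.nansum(fg * yy, axis=(1, 2)) / totals,
        np.nansum(fg * xx, axis=(1, 2)) / totals,
    ])
    com = np.nan_to_num(com, nan=np.nanmedian(com))
    centre = np.median(com, axis=0)
    disp = np.hypot(com[:, 0] - centre[0], com[:, 1] - centre[1])
    mean_i = sm.mean(axis=(1, 2))
    d_disp = np.abs(np.diff(disp))
    d_int = np.abs(np.diff(mean_i))
    if d_disp.std() == 0 or d_int.std() == 0:
        corr = 0.0
    else:
        corr = float(stats.pearsonr(d_disp, d_int).statistic)
    max_disp = float(disp.max())
    reject = bool(abs(corr) > corr_threshold and
                  max_disp > displacement_floor_px)
    return MotionReport(com, disp, mean_i, corr, max_disp, reject,
                        tuple(sigmas),
                        {"corr_threshold": corr_threshold,
                         "displacement_floor_px": displacement_floor_px})
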