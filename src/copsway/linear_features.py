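"""Magnitude-based sway metrics from a filtered CoP trial.

All metrics are computed on the filtered trial and its first-difference
velocity: mean planar velocity, 95% confidence-ellipse area, directional
mean velocities and velocity SDs, and the velocity-to-excursion mean
frequency ratio.
"""

from __future__ import annotations

import warnings
from typing import Dict, Tuple

import numpy as np
from scipy import stats

from copsway.core import CoPTrial, VelocitySeries
from copsway.preprocess import cop_velocity

__all__ = [
    "mean_planar_velocity",
    "ellipse_area_95",
    "directional_velocity_stats",
    "mfreq",
    "compute_linear_features",
]

# 0.95 quantile of chi-square with 2 df; the 95% confidence ellipse of a
# bivariate Gaussian has area pi * q95 * sqrt(det(cov)).
_CHI2_Q95_2DF = float(stats.chi2.ppf(0.95, df=2))


def mean_planar_velocity(vel: VelocitySeries) -> float:
    """Mean of the planar speed sqrt(v_ap**2 + v_ml**2), cm/s."""
    if vel.vel_ap.size == 0:
        raise ValueError("empty velocity series")
    return float(np.mean(np.hypot(vel.vel_ap, vel.vel_ml)))


def ellipse_area_95(trial: CoPTrial) -> float:
    """Area of the 95% confidence ellipse of the CoP point cloud, cm**2.

    ``pi * q95 * sqrt(lambda1 * lambda2)`` with the eigenvalues of the 2x2
    sample covariance of (AP, ML).  A rank-deficient covariance (degenerate
    trajectory) yields 0 with a warning.
    """
    if trial.n_samples < 3:
        raise ValueError("need at least 3 samples for a covariance estimate")
    cov = np.cov(trial.cop_ap, trial.cop_ml, ddof=1)
    det = float(np.linalg.det(cov))
    if det <= 0 or not np.isfinite(det):
        warnings.warn("degenerate CoP trajectory: confidence-ellipse area set to 0")
        return 0.0
    return float(np.pi * _CHI2_Q95_2DF * np.sqrt(det))


def directional_velocity_stats(vel: VelocitySeries) -> Tuple[float, float, float, float]:
    """(velo_ap, velo_ml, velo_sd_ap, velo_sd_ml).

    Means use the rectified velocity |v| (the signed mean is ~0 by
    construction); SDs use the signed velocity with the n-1 denominator.
    """
    if vel.vel_ap.size < 2:
        raise ValueError("need at least 2 velocity samples")
    return (
        float(np.mean(np.abs(vel.vel_ap))),
        float(np.mean(np.abs(vel.vel_ml))),
        float(np.std(vel.vel_ap, ddof=1)),
        float(np.std(vel.vel_ml, ddof=1)),
    )


def mfreq(trial: CoPTrial, vel: VelocitySeries) -> Tuple[float, float]:
    """Mean frequency per axis: mean |velocity| / mean |position - center|.

    The spatial center is the per-trial mean position per axis; units 1/s.
    Implemented as the plain ratio without the 1/(2*pi) or 1/4 constants
    used by some conventions (configurable downstream if cross-study
    comparability is needed).  A zero mean excursion makes the ratio
    undefined (NaN, with a warning).
    """
    out = []
    for pos, v in ((trial.cop_ap, vel.vel_ap), (trial.cop_ml, vel.vel_ml)):
        mean_dist = float(np.mean(np.abs(pos - pos.mean())))
        if mean_dist == 0.0:
            warnings.warn("zero mean excursion: mfreq undefined")
            out.append(float("nan"))
        else:
            out.append(float(np.mean(np.abs(v))) / mean_dist)
    return out[0], out[1]


def compute_linear_features(trial: CoPTrial) -> Dict[str, float]:
    """All linear metrics of one filtered trial, keyed by canonical name."""
    vel = cop_velocity(trial)
    velo_ap, velo_ml, velo_sd_ap, velo_sd_ml = directional_velocity_stats(vel)
    mfreq_ap, mfreq_ml = mfreq(trial, vel)
    return {
        "velo": mean_planar_velocity(vel),
        "area": ellipse_area_95(trial),
        "velo_ap": velo_ap,
        "velo_ml": velo_ml,
        "velo_sd_ap": velo_sd_ap,
        "velo_sd_ml": velo_sd_ml,
        "mfreq_ap": mfreq_ap,
        "mfreq_ml": mfreq_ml,
    }
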