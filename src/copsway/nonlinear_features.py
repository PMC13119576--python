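"""Temporal-structure (nonlinear) sway metrics.

Implements the dynamical descriptors of quiet-standing CoP series:

* sway density curve summary indices (MP3, MT3, MD3),
* Katz fractal dimension of the planar trajectory,
* detrended fluctuation analysis (DFA) scaling exponents,
* stabilogram diffusion analysis (SDA) short/long-term diffusion
  coefficients and the critical point between regimes,
* multiscale entropy (sample entropy over coarse-grained scales), and
* recurrence quantification analysis (DET, LAM) on a delay embedding whose
  delay and dimension are selected by auto mutual information and false
  nearest neighbors, with the recurrence threshold calibrated to a ~5%
  recurrence point density.

Pairwise-comparison hot loops (sample-entropy match counting, recurrence
line counting) are numba-compiled; recurrence distances use a BLAS-backed
Gram-matrix formulation in float32.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from numba import njit
from scipy import signal as sps
from scipy.spatial import cKDTree

from copsway.core import CoPTrial

__all__ = [
    "SDCResult",
    "SDAResult",
    "EmbeddingSpec",
    "RQAResult",
    "CalibrationError",
    "sway_density",
    "katz_fd",
    "dfa",
    "sda",
    "sample_entropy",
    "mse",
    "select_delay_ami",
    "select_dim_fnn",
    "delay_embedding",
    "rqa",
    "rqa_auto",
    "NonlinearConfig",
    "compute_nonlinear_features",
]


class CalibrationError(RuntimeError):
    """Recurrence-threshold calibration failed to reach the target density."""


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class SDCResult:
    """Sway-density summary: MP3 (s), MT3 (s), MD3 (cm).

    MT3/MD3 are NaN with ``defined=False`` when fewer than two peaks exist.
    """

    mp3: float
    mt3: float
    md3: float
    n_peaks: int
    defined: bool = True


@dataclass
class SDAResult:
    """Stabilogram-diffusion parameters (per-axis-equivalent units).

    ``ds``/``dl`` are the short- and long-term diffusion coefficients
    (cm**2/s, planar MSD slope divided by 4); ``crit_t`` (s) and ``crit_d``
    (cm**2) locate the intersection of the two fitted lines.  ``flagged``
    marks degenerate fits; ``diagnostics`` records why.
    """

    ds: float
    dl: float
    crit_t: float
    crit_d: float
    flagged: bool = False
    diagnostics: dict = field(default_factory=dict)


@dataclass
class EmbeddingSpec:
    """Delay-embedding parameters plus the calibrated recurrence threshold."""

    delay: int
    dim: int
    threshold: Optional[float] = None  # cm; None until calibrated
    achieved_rr: Optional[float] = None

    def __post_init__(self) -> None:
        if self.delay < 1 or self.dim < 1:
            raise ValueError("delay and dim must be >= 1")


@dataclass
class RQAResult:
    det: float
    lam: float
    achieved_rr: float
    spec: EmbeddingSpec


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sampen_counts(x, m, r):  # pragma: no cover - exercised via sample_entropy
    """Richman-Moorman match counts over the N-m templates of length m+1."""
    n = x.shape[0] - m
    a = 0
    b = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            d = 0.0
            ok = True
            for k in range(m):
                t = abs(x[i + k] - x[j + k])
                if t > d:
                    d = t
                if d > r:
                    ok = False
                    break
            if ok:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return a, b


@njit(cache=True)
def _diag_line_stats(rec, theiler, lmin):  # pragma: no cover
    """(points on diagonal lines >= lmin, all recurrent points), upper triangle."""
    n = rec.shape[0]
    pts = 0
    line_pts = 0
    for off in range(theiler + 1, n):
        run = 0
        for i in range(n - off):
            if rec[i, i + off]:
                pts += 1
                run += 1
            else:
                if run >= lmin:
                    line_pts += run
                run = 0
        if run >= lmin:
            line_pts += run
    return line_pts, pts


@njit(cache=True)
def _vert_line_stats(rec, lmin):  # pragma: no cover
    """(points on vertical lines >= lmin, all recurrent points), full matrix."""
    n = rec.shape[0]
    pts = 0
    line_pts = 0
    for j in range(n):
        run = 0
        for i in range(n):
            if rec[i, j]:
                pts += 1
                run += 1
            else:
                if run >= lmin:
                    line_pts += run
                run = 0
        if run >= lmin:
            line_pts += run
    return line_pts, pts


# ---------------------------------------------------------------------------
# Sway density
# ---------------------------------------------------------------------------

def sway_density(
    trial: CoPTrial,
    radius: float = 0.3,
    smooth_cutoff: float = 2.5,
    min_prominence_frac: float = 0.05,
) -> SDCResult:
    """Sway-density curve summary indices.

    ``SDC(t)`` is the time (s) the trajectory spends within ``radius`` cm of
    the position at sample ``t``.  The curve is low-pass smoothed (zero
    phase, second-order design applied forward-backward) before peak
    picking; peaks are local maxima with prominence of at least
    ``min_prominence_frac`` times the smoothed-curve range, which discards
    ripple introduced by the smoothing filter itself.  MP3 = mean peak
    value, MT3 = mean inter-peak interval, MD3 = mean planar distance
    between CoP positions at successive peaks.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    pts = trial.planar()
    tree = cKDTree(pts)
    counts = tree.query_ball_point(pts, r=radius, return_length=True)
    sdc = counts / trial.fs
    b, a = sps.butter(2, smooth_cutoff, btype="low", fs=trial.fs)
    smooth = sps.filtfilt(b, a, sdc)
    prominence = min_prominence_frac * float(np.ptp(smooth))
    peaks, _ = sps.find_peaks(smooth, prominence=prominence or None)
    if peaks.size < 1:
        return SDCResult(mp3=float("nan"), mt3=float("nan"), md3=float("nan"),
                         n_peaks=0, defined=False)
    mp3 = float(np.clip(np.mean(smooth[peaks]), 0.0, trial.duration))
    if peaks.size < 2:
        return SDCResult(mp3=mp3, mt3=float("nan"), md3=float("nan"),
                         n_peaks=int(peaks.size), defined=False)
    mt3 = float(np.mean(np.diff(peaks)) / trial.fs)
    steps = np.diff(pts[peaks], axis=0)
    md3 = float(np.mean(np.hypot(steps[:, 0], steps[:, 1])))
    return SDCResult(mp3=mp3, mt3=mt3, md3=md3, n_peaks=int(peaks.size))


# ---------------------------------------------------------------------------
# Katz fractal dimension
# ---------------------------------------------------------------------------

def katz_fd(trial: CoPTrial) -> float:
    """Katz fractal dimension of the planar trajectory.

    ``FD = log10(n) / (log10(n) + log10(d / L))`` with ``n`` the number of
    steps, ``L`` the total planar path length and ``d`` the maximal planar
    distance from the first point.  A straight line gives exactly 1; any
    trajectory gives >= 1.  Degenerate (zero-length) trajectories return 1
    with a warning.
    """
    if trial.n_samples < 3:
        raise ValueError("need at least 3 samples")
    pts = trial.planar()
    steps = np.diff(pts, axis=0)
    L = float(np.sum(np.hypot(steps[:, 0], steps[:, 1])))
    if L == 0.0:
        warnings.warn("degenerate (constant) trajectory: Katz FD set to 1")
        return 1.0
    rel = pts - pts[0]
    d = float(np.max(np.hypot(rel[:, 0], rel[:, 1])))
    n = trial.n_samples - 1
    return float(math.log10(n) / (math.log10(n) + math.log10(d / L)))


# ---------------------------------------------------------------------------
# Detrended fluctuation analysis
# ---------------------------------------------------------------------------

def dfa(
    series: np.ndarray,
    box_sizes: Optional[Sequence[int]] = None,
    order: int = 1,
) -> Tuple[float, np.ndarray, np.ndarray]:
    """DFA scaling exponent of a 1-D series.

    The demeaned series is integrated; for each box size the profile is
    split into non-overlapping boxes (taken from both ends so all data are
    used), each least-squares detrended with a polynomial of the given
    order; ``F(n)`` is the RMS residual and ``alpha`` the slope of
    ``log F(n)`` vs ``log n``.  Returns ``(alpha, sizes, F)``.

    Defaults: ~20 log-spaced box sizes from 10 to N/8, linear detrending.
    """
    x = np.asarray(series, dtype=float).ravel()
    n_tot = x.size
    if box_sizes is None:
        if n_tot < 80:
            raise ValueError("series too short for default DFA box sizes")
        box_sizes = np.unique(
            np.geomspace(10, max(11, n_tot // 8), 20).astype(int)
        )
    sizes = np.array(sorted({int(s) for s in box_sizes if order + 2 <= s <= n_tot // 4}))
    if sizes.size < 4:
        raise ValueError("fewer than 4 usable box sizes")
    profile = np.cumsum(x - x.mean())
    fluct = np.empty(sizes.size)
    for si, n in enumerate(sizes):
        k = n_tot // n
        segs = np.vstack(
            [profile[: k * n].reshape(k, n), profile[n_tot - k * n :].reshape(k, n)]
        )
        design = np.vander(np.arange(n, dtype=float), order + 1)
        coef, *_ = np.linalg.lstsq(design, segs.T, rcond=None)
        resid = segs.T - design @ coef
        fluct[si] = math.sqrt(float(np.mean(resid**2)))
    alpha = float(np.polyfit(np.log(sizes), np.log(fluct), 1)[0])
    return alpha, sizes, fluct


# ---------------------------------------------------------------------------
# Stabilogram diffusion analysis
# ---------------------------------------------------------------------------

def sda(
    trial: CoPTrial,
    max_lag: float = 10.0,
    short_window: Tuple[float, float] = (0.1, 0.8),
    long_window: Tuple[float, float] = (2.0, 10.0),
) -> SDAResult:
    """Stabilogram diffusion analysis of the planar trajectory.

    The planar mean-square displacement ``MSD(dt)`` is fitted with two
    least-squares lines (linear coordinates), one over the short-lag and one
    over the long-lag window; the slopes divided by 4 give the per-axis
    short- and long-term diffusion coefficients, and the intersection of the
    two lines gives the critical point (CriT, CriD).
    """
    fs = trial.fs
    max_k = int(round(max_lag * fs))
    if trial.n_samples <= max_k:
        raise ValueError("trial shorter than max_lag")
    x, y = trial.cop_ap, trial.cop_ml
    msd = np.empty(max_k)
    for k in range(1, max_k + 1):
        dx = x[k:] - x[:-k]
        dy = y[k:] - y[:-k]
        msd[k - 1] = np.mean(dx * dx + dy * dy)
    lags = np.arange(1, max_k + 1) / fs

    if not msd.any():
        return SDAResult(
            ds=float("nan"), dl=float("nan"), crit_t=float("nan"), crit_d=float("nan"),
            flagged=True, diagnostics={"reason": "constant trajectory, MSD identically 0"},
        )

    def _fit(window):
        lo, hi = window
        mask = (lags >= lo) & (lags <= hi)
        if mask.sum() < 2:
            raise ValueError(f"fit window {window} contains < 2 lags")
        return np.polyfit(lags[mask], msd[mask], 1)

    m_s, b_s = _fit(short_window)
    m_l, b_l = _fit(long_window)
    diag: dict = {}
    flagged = False
    if m_s <= 0:
        flagged = True
        diag["reason"] = "non-positive short-term slope"
    if m_s == m_l:
        crit_t = crit_d = float("nan")
        flagged = True
        diag["reason"] = "parallel short/long fits, no intersection"
    else:
        crit_t = float((b_l - b_s) / (m_s - m_l))
        crit_d = float(m_s * crit_t + b_s)
        if not 0.0 < crit_t <= max_lag:
            flagged = True
            diag.setdefault("reason", f"critical time {crit_t:.3g}s outside (0, {max_lag}]s")
    return SDAResult(
        ds=float(m_s / 4.0), dl=float(m_l / 4.0),
        crit_t=crit_t, crit_d=crit_d, flagged=flagged, diagnostics=diag,
    )


# ---------------------------------------------------------------------------
# Multiscale entropy
# ---------------------------------------------------------------------------

def sample_entropy(series: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """Sample entropy SampEn(m, r) with Chebyshev distance, nats.

    ``-ln(A/B)`` where B counts m-length template matches and A counts
    (m+1)-length matches over the ``N - m`` templates, self-matches
    excluded.  Returns NaN when no matches exist (small-sample saturation).
    """
    x = np.ascontiguousarray(series, dtype=np.float64).ravel()
    if x.size <= m + 1:
        raise ValueError("series too short for the requested template length")
    a, b = _sampen_counts(x, m, float(r))
    if a == 0 or b == 0:
        return float("nan")
    return float(-math.log(a / b))


def mse(
    series: np.ndarray,
    m: int = 2,
    r_factor: float = 0.2,
    scales: Sequence[int] = (1, 10, 40),
) -> Dict[int, float]:
    """Multiscale entropy: SampEn of non-overlapping coarse-grained means.

    The tolerance ``r = r_factor * SD(original series)`` is computed once
    from the scale-1 series and held fixed across scales.  Scales whose
    match counts vanish yield NaN (propagated as missing, never as 0).
    """
    x = np.asarray(series, dtype=float).ravel()
    max_scale = max(scales)
    if x.size // max_scale < 100:
        raise ValueError(
            f"series of length {x.size} too short for scale {max_scale} "
            "(need >= 100 coarse-grained points)"
        )
    r = r_factor * float(np.std(x))
    out: Dict[int, float] = {}
    for s in scales:
        if s < 1:
            raise ValueError("scales must be >= 1")
        k = x.size // s
        cg = x[: k * s].reshape(k, s).mean(axis=1) if s > 1 else x
        out[int(s)] = sample_entropy(cg, m=m, r=r)
    return out


# ---------------------------------------------------------------------------
# Embedding selection
# ---------------------------------------------------------------------------

def select_delay_ami(
    series: np.ndarray, max_lag: int = 200, n_bins: int = 32, smooth: int = 5
) -> int:
    """Embedding delay from the first local minimum of auto mutual information.

    Histogram (plugin) MI between ``x(t)`` and ``x(t + tau)`` for
    ``tau = 1..max_lag``; the raw MI curve is jittery at the plugin
    estimator's bin resolution, so the local-minimum search runs on a short
    centered moving average (width ``smooth``).  If the lag-1 MI is already
    at the independence bias floor the series is effectively memoryless and
    1 is returned; if no local minimum exists, the first lag where MI drops
    below ``I(1)/e`` is used, and failing that the global minimum.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size <= max_lag + 1:
        raise ValueError("series too short for the requested max_lag")
    if np.ptp(x) == 0:
        raise ValueError("constant series: mutual information undefined")
    edges = np.histogram_bin_edges(x, bins=n_bins)
    idx = np.clip(np.digitize(x, edges[1:-1]), 0, n_bins - 1)

    def _mi(lag: int) -> float:
        joint = np.bincount(idx[:-lag] * n_bins + idx[lag:], minlength=n_bins * n_bins)
        n = joint.sum()
        pj = joint / n
        px = pj.reshape(n_bins, n_bins).sum(axis=1)
        py = pj.reshape(n_bins, n_bins).sum(axis=0)
        outer = np.outer(px, py).ravel()
        nz = pj > 0
        return float(np.sum(pj[nz] * np.log(pj[nz] / outer[nz])))

    mi = np.array([_mi(lag) for lag in range(1, max_lag + 1)])
    # plugin-MI bias for independent data is ~ (n_bins - 1)^2 / (2N) nats
    bias = (n_bins - 1) ** 2 / (2.0 * (x.size - 1))
    if mi[0] <= 2.0 * bias:
        return 1
    if smooth > 1 and mi.size > smooth:
        kernel = np.ones(smooth) / smooth
        mi_s = np.convolve(mi, kernel, mode="same")
        half = smooth // 2  # moving average is unreliable at the edges
    else:
        mi_s = mi
        half = 0
    # first minimum over a +-order neighborhood: robust to plugin jitter
    order = max(2, smooth + 2)
    margin = max(half, order)
    mins = sps.argrelmin(mi_s, order=order)[0]
    mins = mins[(mins >= margin) & (mins < mi_s.size - margin)]
    if mins.size:
        return int(mins[0]) + 1
    below = np.flatnonzero(mi < mi[0] / math.e)
    if below.size:
        return int(below[0]) + 1
    return int(np.argmin(mi)) + 1


def delay_embedding(series: np.ndarray, delay: int, dim: int) -> np.ndarray:
    """Time-delay embedding matrix of shape ``(N - (dim-1)*delay, dim)``."""
    x = np.asarray(series, dtype=float).ravel()
    n = x.size - (dim - 1) * delay
    if n < 1:
        raise ValueError("series too short for this embedding")
    return np.column_stack([x[i * delay : i * delay + n] for i in range(dim)])


def select_dim_fnn(
    series: np.ndarray,
    delay: int,
    max_dim: int = 10,
    rtol: float = 10.0,
    atol: float = 2.0,
    threshold: float = 0.01,
    max_queries: int = 1500,
) -> int:
    """Embedding dimension by the false-nearest-neighbors criterion.

    For each dimension m the Euclidean nearest neighbor of embedded points
    is tested: it is *false* if the extra-coordinate distance exceeds
    ``rtol`` times the m-dimensional distance, or if the (m+1)-dimensional
    distance exceeds ``atol`` times the attractor size (series SD).  Returns
    the smallest m whose false fraction is below ``threshold``, else
    ``max_dim`` (noise never converges).  Neighbors are searched among all
    embedded points; the false fraction is evaluated on an evenly-strided
    subsample of at most ``max_queries`` query points.
    """
    if delay < 1:
        raise ValueError("delay must be >= 1")
    x = np.asarray(series, dtype=float).ravel()
    if x.size - max_dim * delay < 20:
        raise ValueError("series too short for the requested max_dim * delay span")
    attractor_size = float(np.std(x))
    if attractor_size == 0:
        raise ValueError("constant series")
    for m in range(1, max_dim + 1):
        n = x.size - m * delay  # extension coordinate must exist
        emb = np.column_stack([x[i * delay : i * delay + n] for i in range(m)])
        stride = max(1, n // max_queries)
        q = np.arange(0, n, stride)
        tree = cKDTree(emb)
        dist, nn = tree.query(emb[q], k=2)
        dist, nn = dist[:, 1], nn[:, 1]
        extra = np.abs(x[q + m * delay] - x[nn + m * delay])
        with np.errstate(divide="ignore", invalid="ignore"):
            # exact repeats (dist 0, extra 0) are true neighbors
            ratio = np.where(
                dist > 0, extra / np.where(dist > 0, dist, 1.0),
                np.where(extra > 0, np.inf, 0.0),
            )
        dist_next = np.hypot(dist, extra)
        false = (ratio > rtol) | (dist_next / attractor_size > atol)
        # pairs whose (m+1)-distance is at float rounding level are exact
        # repeats; the distance ratio there is numerical noise
        false &= dist_next > 1e-10 * attractor_size
        if np.mean(false) < threshold:
            return m
    return max_dim


# ---------------------------------------------------------------------------
# Recurrence quantification analysis
# ---------------------------------------------------------------------------

def _pairwise_sqdist(emb: np.ndarray) -> np.ndarray:
    """Squared Euclidean distance matrix in float32 via the Gram matrix."""
    x = np.ascontiguousarray(emb, dtype=np.float32)
    sq = np.einsum("ij,ij->i", x, x)
    d2 = x @ x.T
    d2 *= -2.0
    d2 += sq[:, None]
    d2 += sq[None, :]
    np.maximum(d2, 0.0, out=d2)
    return d2


def rqa(
    series: np.ndarray,
    spec: EmbeddingSpec,
    lmin: int = 2,
    theiler: Optional[int] = None,
    target_rr: float = 0.05,
    rr_band: Tuple[float, float] = (0.045, 0.055),
    max_iter: int = 100,
    min_points: int = 200,
) -> RQAResult:
    """Recurrence quantification of one channel.

    The series is delay-embedded per ``spec``; recurrences are Euclidean
    neighborhoods ``||X_i - X_j|| <= eps`` outside a Theiler window
    (default: the embedding delay).  Unless ``spec.threshold`` is preset,
    ``eps`` is calibrated by bisection until the recurrence point density
    lies in ``rr_band`` (target ~5%).  DET is the fraction of recurrent
    points on diagonal lines of length >= ``lmin``; LAM the same for
    vertical lines.
    """
    emb = delay_embedding(series, spec.delay, spec.dim)
    n = emb.shape[0]
    if n < min_points:
        raise ValueError(f"embedded series has {n} points; need >= {min_points}")
    if theiler is None:
        theiler = spec.delay
    d2 = _pairwise_sqdist(emb)
    # exclude the Theiler band (|i - j| <= theiler) including the main diagonal
    ii = np.arange(n)
    for off in range(0, theiler + 1):
        d2[ii[: n - off], ii[: n - off] + off] = np.inf
        if off:
            d2[ii[: n - off] + off, ii[: n - off]] = np.inf
    n_valid = n * n - (2 * theiler + 1) * n + theiler * (theiler + 1)

    if spec.threshold is not None:
        eps2 = float(spec.threshold) ** 2
        rr = float(np.count_nonzero(d2 <= eps2)) / n_valid
        eps = float(spec.threshold)
    else:
        # cheap quantile of a strided distance subsample seeds the bisection
        sample = d2.ravel()[:: max(1, d2.size // 2_000_000)]
        sample = sample[np.isfinite(sample)]
        guess = float(np.quantile(sample, target_rr))
        lo, hi = 0.0, float(sample.max())
        mid = guess if lo < guess < hi else 0.5 * (lo + hi)
        trace = []
        for _ in range(max_iter):
            rr = float(np.count_nonzero(d2 <= mid)) / n_valid
            trace.append((math.sqrt(mid), rr))
            if rr < rr_band[0]:
                lo = mid
            elif rr > rr_band[1]:
                hi = mid
            else:
                break
            mid = 0.5 * (lo + hi)
        else:
            raise CalibrationError(
                f"recurrence-rate calibration did not reach {rr_band} "
                f"(target {target_rr}); eps/RR trace: {trace}"
            )
        eps2 = mid
        eps = math.sqrt(mid)

    rec = d2 <= eps2
    diag_line_pts, diag_pts = _diag_line_stats(rec, theiler, lmin)
    vert_line_pts, vert_pts = _vert_line_stats(rec, lmin)
    det = diag_line_pts / diag_pts if diag_pts else float("nan")
    lam = vert_line_pts / vert_pts if vert_pts else float("nan")
    out_spec = EmbeddingSpec(
        delay=spec.delay, dim=spec.dim, threshold=eps, achieved_rr=rr
    )
    return RQAResult(det=float(det), lam=float(lam), achieved_rr=rr, spec=out_spec)


def rqa_auto(
    series: np.ndarray,
    lmin: int = 2,
    max_lag: int = 200,
    n_bins: int = 32,
    max_dim: int = 10,
    rtol: float = 10.0,
    atol: float = 2.0,
    target_rr: float = 0.05,
    rr_band: Tuple[float, float] = (0.045, 0.055),
) -> RQAResult:
    """AMI delay + FNN dimension selection followed by calibrated RQA."""
    tau = select_delay_ami(series, max_lag=max_lag, n_bins=n_bins)
    dim = select_dim_fnn(series, tau, max_dim=max_dim, rtol=rtol, atol=atol)
    # keep the embedded length comfortably above the minimum
    while dim > 1 and len(series) - (dim - 1) * tau < 200:
        dim -= 1
    return rqa(
        series,
        EmbeddingSpec(delay=tau, dim=dim),
        lmin=lmin,
        theiler=tau,
        target_rr=target_rr,
        rr_band=rr_band,
    )


# ---------------------------------------------------------------------------
# Aggregate per-trial extraction
# ---------------------------------------------------------------------------

@dataclass
class NonlinearConfig:
    """Tunable settings of the temporal-structure estimators."""

    sdc_radius: float = 0.3  # cm; 3 mm neighborhood of the sway-density curve
    sdc_smooth_hz: float = 2.5
    sdc_min_prominence_frac: float = 0.05
    dfa_order: int = 1
    sda_max_lag: float = 10.0
    sda_short_window: Tuple[float, float] = (0.1, 0.8)
    sda_long_window: Tuple[float, float] = (2.0, 10.0)
    mse_m: int = 2
    mse_r_factor: float = 0.2
    mse_scales: Tuple[int, ...] = (1, 10, 40)
    ami_max_lag: int = 200
    ami_bins: int = 32
    fnn_max_dim: int = 10
    fnn_rtol: float = 10.0
    fnn_atol: float = 2.0
    rqa_lmin: int = 2
    rqa_target_rr: float = 0.05
    rqa_rr_band: Tuple[float, float] = (0.045, 0.055)


def compute_nonlinear_features(
    trial: CoPTrial, config: Optional[NonlinearConfig] = None
) -> Dict[str, float]:
    """All temporal-structure metrics of one filtered trial.

    Undefined estimates (too few sway-density peaks, vanished entropy match
    counts, degenerate diffusion fits) are NaN, never 0.
    """
    cfg = config or NonlinearConfig()
    out: Dict[str, float] = {}

    sdc = sway_density(
        trial,
        radius=cfg.sdc_radius,
        smooth_cutoff=cfg.sdc_smooth_hz,
        min_prominence_frac=cfg.sdc_min_prominence_frac,
    )
    out["mp3"], out["mt3"], out["md3"] = sdc.mp3, sdc.mt3, sdc.md3
    out["fd"] = katz_fd(trial)

    sd = sda(
        trial,
        max_lag=cfg.sda_max_lag,
        short_window=cfg.sda_short_window,
        long_window=cfg.sda_long_window,
    )
    out["sda_ds"], out["sda_dl"] = sd.ds, sd.dl
    out["sda_crit"], out["sda_crid"] = sd.crit_t, sd.crit_d

    for suffix, x in (("ap", trial.cop_ap), ("ml", trial.cop_ml)):
        out[f"alpha_{suffix}"], _, _ = dfa(x, order=cfg.dfa_order)
        ent = mse(x, m=cfg.mse_m, r_factor=cfg.mse_r_factor, scales=cfg.mse_scales)
        for s, v in ent.items():
            out[f"mse{s}_{suffix}"] = v
        rq = rqa_auto(
            x,
            lmin=cfg.rqa_lmin,
            max_lag=cfg.ami_max_lag,
            n_bins=cfg.ami_bins,
            max_dim=cfg.fnn_max_dim,
            rtol=cfg.fnn_rtol,
            atol=cfg.fnn_atol,
            target_rr=cfg.rqa_target_rr,
            rr_band=cfg.rqa_rr_band,
        )
        out[f"det_{suffix}"] = rq.det
        out[f"lam_{suffix}"] = rq.lam
    return out
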