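"""Population statistics: speed mixtures and anomalous-diffusion MSD fits.

Segment speed magnitudes are summarized by fitting a sum of Gaussians to a
2 nm/s histogram, with the first component's mean pinned to zero (the
immobile population); the processive speed is the mean of the component
closest to the histogram's non-zero mode, with a case-resampling bootstrap
for its 95% CI.  Diffusive tracks are summarized by time-averaged MSD and a
weighted log-log regression against MSD = 4·D_eff·t^α.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize


@dataclass
class SpeedMixtureFit:
    n_components: int
    weights: np.ndarray
    means: np.ndarray            # nm/s; means[0] == 0 exactly
    sds: np.ndarray              # nm/s
    processive_mean: float       # nm/s
    ci95: Optional[tuple] = None
    converged: bool = True
    histogram_bin_width: float = 2.0
    message: str = ""


@dataclass
class MSDCurve:
    lags: np.ndarray             # s
    msd: np.ndarray              # µm²
    n_pairs: np.ndarray
    truncated: bool = False


@dataclass
class AnomalousFit:
    D_eff: float                 # µm²/s^alpha
    alpha: float
    fit_lags_used: tuple


# ---------------------------------------------------------------------------
# Gaussian-sum speed mixture
# ---------------------------------------------------------------------------

def _mixture_density(x, amps, means, sds):
    out = np.zeros_like(x, dtype=float)
    for a, m, s in zip(amps, means, sds):
        out += a / (s * math.sqrt(2 * math.pi)) * np.exp(
            -0.5 * ((x - m) / s) ** 2)
    return out


def fit_speed_mixture(speeds: Sequence[float], n_components: int = 3,
                      bin_width: float = 2.0,
                      p0: Optional[Sequence[float]] = None,
                      maxfev: int = 5000) -> SpeedMixtureFit:
    """Fit a sum of Gaussians to a histogram of speed magnitudes.

    The zero-mean component is fixed; remaining means, all SDs and all
    amplitudes are free, fitted by nonlinear least squares on the histogram
    counts with several initializations.  The processive mean is the mean of
    the component nearest the histogram's non-zero mode.
    """
    speeds = np.abs(np.asarray(speeds, dtype=float))
    if n_components not in (2, 3):
        raise ValueError("n_components must be 2 or 3")
    if len(speeds) < 50:
        raise ValueError("need at least 50 speeds for a mixture fit")
    hi = np.quantile(speeds, 0.999) + bin_width
    edges = np.arange(0, max(hi, 6 * bin_width), bin_width)
    counts, edges = np.histogram(speeds, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = counts.sum() * bin_width

    # candidate processive means: non-zero histogram mode and quantiles
    interior = counts.copy()
    interior[centers < 2 * bin_width] = 0
    cands = [centers[np.argmax(interior)] if interior.any() else 10.0,
             float(np.quantile(speeds, 0.6)),
             float(np.quantile(speeds, 0.8))]
    mode_nonzero = cands[0]

    best = None
    if p0 is not None:
        cands = cands[:1]
    for mu0 in cands:
        mu0 = max(mu0, bin_width)
        if n_components == 3:
            start0 = [0.4 * total, 2.5,
                  0.5 * total, mu0, max(0.3 * mu0, 2.0),
                  0.1 * total, max(5 * mu0, 50.0), max(3 * mu0, 40.0)]
            xmax = float(centers[-1]) + bin_width
            lb = [0, 0.3, 0, bin_width / 2, 0.3, 0, bin_width / 2, 0.3]
            ub = [10 * total, xmax, 10 * total, xmax, xmax,
                  10 * total, 10 * xmax, 10 * xmax]

            def model(x, a0, s0, a1, m1, s1, a2, m2, s2):
                return _mixture_density(x, [a0, a1, a2], [0, m1, m2],
                                        [s0, s1, s2])
        else:
            start0 = [0.6 * total, 2.5, 0.4 * total, mu0, max(0.3 * mu0, 2.0)]
            xmax = float(centers[-1]) + bin_width
            lb = [0, 0.3, 0, bin_width / 2, 0.3]
            ub = [10 * total, xmax, 10 * total, xmax, xmax]

            def model(x, a0, s0, a1, m1, s1):
                return _mixture_density(x, [a0, a1], [0, m1], [s0, s1])
        start = list(p0) if p0 is not None else start0
        try:
            start = [min(max(v, l), u) for v, l, u in zip(start, lb, ub)]
            popt, _ = optimize.curve_fit(
                model, centers, counts / bin_width, p0=start,
                bounds=(lb, ub), maxfev=maxfev,
                x_scale=[max(abs(v), 1.0) for v in start])
            rss = float(np.sum((model(centers, *popt)
                                - counts / bin_width) ** 2))
            if best is None or rss < best[0]:
                best = (rss, popt)
        except (RuntimeError, ValueError):
            continue
    if best is None:
        return SpeedMixtureFit(n_components, np.array([]), np.array([]),
                               np.array([]), float("nan"), converged=False,
                               histogram_bin_width=bin_width,
                               message="all initializations failed")
    popt = best[1]
    if n_components == 3:
        amps = np.array([popt[0], popt[2], popt[5]])
        means = np.array([0.0, popt[3], popt[6]])
        sds = np.array([popt[1], popt[4], popt[7]])
    else:
        amps = np.array([popt[0], popt[2]])
        means = np.array([0.0, popt[3]])
        sds = np.array([popt[1], popt[4]])
    weights = amps / amps.sum()
    nonzero = np.arange(1, n_components)
    proc_idx = nonzero[np.argmin(np.abs(means[1:] - mode_nonzero))]
    msg = ""
    if weights[proc_idx] < 0.05 or means[proc_idx] < 2 * bin_width:
        msg = ("degenerate: processive component absent or overlapping "
               "the zero-speed population")
    return SpeedMixtureFit(n_components, weights, means, sds,
                           processive_mean=float(means[proc_idx]),
                           converged=True, histogram_bin_width=bin_width,
                           message=msg)


def bootstrap_mixture_ci(speeds: Sequence[float], n_components: int = 3,
                         n_boot: int = 1000, seed: int = 0,
                         bin_width: float = 2.0) -> tuple:
    """Percentile 95% CI of the processive mean by case resampling.

    Failed refits are dropped; if more than 20% fail the returned tuple
    carries a warning flag as its third element.
    """
    speeds = np.abs(np.asarray(speeds, dtype=float))
    rng = np.random.default_rng(seed)
    if np.ptp(speeds) == 0:
        v = float(speeds[0])
        return (v, v, False)
    # warm-start replicate refits from the full-sample fit
    full = fit_speed_mixture(speeds, n_components, bin_width)
    p0 = None
    if full.converged and len(full.weights):
        amps = full.weights * len(speeds) * bin_width
        if n_components == 3:
            p0 = [amps[0], full.sds[0], amps[1], full.means[1], full.sds[1],
                  amps[2], full.means[2], full.sds[2]]
        else:
            p0 = [amps[0], full.sds[0], amps[1], full.means[1], full.sds[1]]
        p0 = [max(v, 0.31) for v in p0]
    est = []
    failed = 0
    for _ in range(n_boot):
        sample = rng.choice(speeds, size=len(speeds), replace=True)
        try:
            fit = fit_speed_mixture(sample, n_components, bin_width,
                                    p0=p0, maxfev=2000)
            if fit.converged and np.isfinite(fit.processive_mean):
                est.append(fit.processive_mean)
            else:
                failed += 1
        except ValueError:
            failed += 1
    if not est:
        return (float("nan"), float("nan"), True)
    lo, hi = np.percentile(est, [2.5, 97.5])
    return (float(lo), float(hi), failed > 0.2 * n_boot)


# ---------------------------------------------------------------------------
# MSD and anomalous-diffusion fits
# ---------------------------------------------------------------------------

def compute_msd(xy_nm: np.ndarray, frame_interval: float = 1.0,
                max_lag: int = 10) -> MSDCurve:
    """Time-averaged MSD of one trajectory over lags 1..max_lag.

    ``xy_nm`` is an (n, 2) Cartesian trajectory in nm; the MSD is returned
    in µm², averaged over all start times per lag.
    """
    xy = np.asarray(xy_nm, dtype=float)
    n = len(xy)
    if n < 2:
        raise ValueError("trajectory too short for an MSD")
    truncated = max_lag >= n
    lags = np.arange(1, min(max_lag, n - 1) + 1)
    msd = np.empty(len(lags))
    n_pairs = np.empty(len(lags), dtype=int)
    for k, lag in enumerate(lags):
        d = xy[lag:] - xy[:-lag]
        msd[k] = np.mean(np.sum(d ** 2, axis=1))
        n_pairs[k] = len(d)
    return MSDCurve(lags=lags * frame_interval, msd=msd * 1e-6,
                    n_pairs=n_pairs, truncated=truncated)


def polar_to_xy(theta_rad: np.ndarray, r_nm: np.ndarray) -> np.ndarray:
    """Convert ring coordinates to Cartesian nm, shape (n, 2)."""
    return np.column_stack([r_nm * np.cos(theta_rad),
                            r_nm * np.sin(theta_rad)])


def fit_anomalous_diffusion(msd: MSDCurve) -> AnomalousFit:
    """Fit MSD = 4·D_eff·t^α by n_pairs-weighted linear regression in log-log.

    Zero-MSD lags are dropped; at least 4 usable lags are required.
    ``alpha`` is the slope and ``D_eff = exp(intercept)/4`` (µm²/s^α).
    """
    keep = msd.msd > 0
    lags, vals, w = msd.lags[keep], msd.msd[keep], msd.n_pairs[keep]
    if len(lags) < 4:
        raise ValueError("need at least 4 non-zero MSD lags")
    X = np.vstack([np.log(lags), np.ones(len(lags))]).T
    y = np.log(vals)
    W = np.sqrt(w.astype(float))
    coef, *_ = np.linalg.lstsq(X * W[:, None], y * W, rcond=None)
    alpha, intercept = float(coef[0]), float(coef[1])
    return AnomalousFit(D_eff=math.exp(intercept) / 4.0, alpha=alpha,
                        fit_lags_used=(float(lags[0]), float(lags[-1])))
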