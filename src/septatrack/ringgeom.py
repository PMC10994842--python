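"""Ring geometry: background subtraction, circle fitting, radial kymographs.

A division-septum movie shows fluorophores confined to an annulus.  The
pipeline here projects the movie over time, removes the diffuse cytoplasmic
signal, fits a circle to the projected ring, and unwraps every frame into a
time × ring-angle kymograph sampled on that circle.

Conventions: image coordinates are continuous with pixel centers at integer
(row, col); angles are measured from the image +x axis, counter-clockwise
positive, and kymograph bin 0 starts at 0°.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, optimize
from skimage.morphology import disk, opening


@dataclass
class RingGeometry:
    """Fitted septal circle in pixel coordinates (center) and both units."""

    center_x: float       # px (column)
    center_y: float       # px (row)
    radius_px: float
    radius_nm: float
    fit_residual: float   # nm rms of the algebraic fit


@dataclass
class RadialKymograph:
    """time × angular-bin intensity map sampled along the fitted ring."""

    values: np.ndarray        # (T, n_bins)
    n_bins: int
    bin_arc_length: float     # nm
    origin_rotation: float    # degrees
    geometry: RingGeometry

    @property
    def bin_angles_deg(self) -> np.ndarray:
        return (np.arange(self.n_bins) * 360.0 / self.n_bins
                + self.origin_rotation) % 360.0


def max_intensity_projection(movie: np.ndarray) -> np.ndarray:
    """Per-pixel maximum over time of a (T, H, W) stack."""
    movie = np.asarray(movie)
    if movie.ndim != 3 or movie.shape[0] < 1:
        raise ValueError("movie must be a non-empty (T, H, W) stack")
    return movie.max(axis=0)


def subtract_cytoplasmic_background(image: np.ndarray,
                                    selem_radius: int = 8) -> np.ndarray:
    """Remove the smooth cytoplasmic signal by morphological opening.

    The structuring element must be larger than the PSF so single-molecule
    spots survive; the opened image estimates the background, which is
    subtracted and negatives are clipped to zero.
    """
    image = np.asarray(image, dtype=float)
    if 2 * selem_radius + 1 > min(image.shape):
        raise ValueError("structuring element larger than image")
    bg = opening(image, disk(selem_radius))
    return np.clip(image - bg, 0, None)


def _taubin_circle(x: np.ndarray, y: np.ndarray,
                   w: np.ndarray) -> tuple:
    """Intensity-weighted algebraic (Taubin/Kåsa) circle fit → (cx, cy, r)."""
    w = w / w.sum()
    xm, ym = (w * x).sum(), (w * y).sum()
    u, v = x - xm, y - ym
    Suu, Svv, Suv = (w * u * u).sum(), (w * v * v).sum(), (w * u * v).sum()
    Suuu, Svvv = (w * u ** 3).sum(), (w * v ** 3).sum()
    Suvv, Svuu = (w * u * v * v).sum(), (w * v * u * u).sum()
    A = np.array([[Suu, Suv], [Suv, Svv]])
    b = 0.5 * np.array([Suuu + Suvv, Svvv + Svuu])
    try:
        uc, vc = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as e:
        raise ValueError("degenerate point set for circle fit") from e
    r = math.sqrt(uc * uc + vc * vc + Suu + Svv)
    return xm + uc, ym + vc, r


def _ring_mean_intensity(image: np.ndarray, cx: float, cy: float,
                         r: float, n_samples: int = 180) -> float:
    ang = np.linspace(0, 2 * np.pi, n_samples, endpoint=False)
    xs = cx + r * np.cos(ang)
    ys = cy + r * np.sin(ang)
    vals = ndimage.map_coordinates(image, [ys, xs], order=1, mode="constant")
    return float(vals.mean())


def _circle_score(image: np.ndarray, cx: float, cy: float, r: float,
                  n_samples: int = 180) -> float:
    ang = np.linspace(0, 2 * np.pi, n_samples, endpoint=False)
    vals = ndimage.map_coordinates(
        image, [cy + r * np.sin(ang), cx + r * np.cos(ang)], order=1,
        mode="constant")
    return float(np.minimum(vals, 0.5).mean() + 0.1 * vals.mean())


def _grid_search_circle(image: np.ndarray, xf: np.ndarray, yf: np.ndarray,
                        w: np.ndarray, r_min: float = 3.5) -> tuple:
    """Coarse (center, radius) grid maximizing robust on-circle intensity."""
    cx_c = float(np.average(xf, weights=w))
    cy_c = float(np.average(yf, weights=w))
    cxs = cx_c + np.arange(-4, 4.01, 0.5)
    cys = cy_c + np.arange(-4, 4.01, 0.5)
    rmax = min(image.shape) / 2.0 - 1.0
    rs = np.arange(r_min, rmax + 1e-9, 0.25)
    ang = np.arange(0, 2 * np.pi, 2 * np.pi / 72)
    ca, sa = np.cos(ang), np.sin(ang)
    CX, CY, RR = np.meshgrid(cxs, cys, rs, indexing="ij")
    xs_all = CX[..., None] + RR[..., None] * ca
    ys_all = CY[..., None] + RR[..., None] * sa
    vals = ndimage.map_coordinates(
        image, [ys_all.ravel(), xs_all.ravel()], order=1, mode="constant")
    vals = vals.reshape(xs_all.shape)
    # clipped score ~ angular coverage: stops tiny circles through one
    # bright spot from outscoring the true, partially covered ring
    score = np.minimum(vals, 0.5).mean(axis=-1) + 0.1 * vals.mean(axis=-1)
    i, j, k = np.unravel_index(np.argmax(score), score.shape)
    return float(cxs[i]), float(cys[j]), float(rs[k])


def _local_maxima(image: np.ndarray, thr: float) -> tuple:
    """Spot-level local maxima (x, y, weight) above a relative threshold."""
    mx = ndimage.maximum_filter(image, size=3)
    ys, xs = np.nonzero((image == mx) & (image > thr))
    w = image[ys, xs]
    order = np.argsort(w)[::-1][:60]
    return xs[order].astype(float), ys[order].astype(float), w[order]


def _circle_through(p1, p2, p3):
    ax, ay = p1
    bx, by = p2
    cx, cy = p3
    d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-9:
        return None
    ux = ((ax ** 2 + ay ** 2) * (by - cy) + (bx ** 2 + by ** 2) * (cy - ay)
          + (cx ** 2 + cy ** 2) * (ay - by)) / d
    uy = ((ax ** 2 + ay ** 2) * (cx - bx) + (bx ** 2 + by ** 2) * (ax - cx)
          + (cx ** 2 + cy ** 2) * (bx - ax)) / d
    return ux, uy, math.hypot(ax - ux, ay - uy)


def _ransac_circle(px: np.ndarray, py: np.ndarray, pw: np.ndarray,
                   r_min: float, r_max: float,
                   tol: float = 1.5) -> list:
    """Best circles through spot-maxima triplets by weighted inlier mass.

    Spot maxima sit on the ridge of the true ring even when molecules
    cluster on one arc, so a point-level consensus resists the thick-band
    degeneracy that area-based scores suffer from.
    """
    n = len(px)
    if n < 3:
        return []
    best, best_score = None, -1.0
    idx = np.arange(n)
    import itertools
    triplets = list(itertools.combinations(idx[:min(n, 25)], 3))
    for i, j, k in triplets:
        c = _circle_through((px[i], py[i]), (px[j], py[j]), (px[k], py[k]))
        if c is None or not (r_min <= c[2] <= r_max):
            continue
        resid = np.abs(np.hypot(px - c[0], py - c[1]) - c[2])
        score = float(pw[resid < tol].sum())
        if score > best_score:
            best, best_score = c, score
    if best is None:
        return []
    resid = np.abs(np.hypot(px - best[0], py - best[1]) - best[2])
    keep = resid < tol
    out = [best]
    if keep.sum() >= 3:
        try:
            out.append(_taubin_circle(px[keep], py[keep], pw[keep]))
        except ValueError:
            pass
    return out


def fit_ring(image: np.ndarray, pixel_size: float,
             threshold_rel: float = 0.25,
             min_radius_nm: float = 250.0) -> RingGeometry:
    """Fit the septal circle on a background-subtracted projection.

    Candidate circles come from three routes — an intensity-weighted
    algebraic (Taubin) fit of bright pixels, a RANSAC consensus over
    spot-level local maxima, and a coarse grid search maximizing robust
    on-circle intensity — and the best-scoring candidate is polished by a
    trust-region Nelder-Mead on the on-circle intensity score.  Sparse
    single-molecule rings only partially cover the circle; the candidate
    competition plus trust region keep the fit from collapsing onto a
    bright arc.  Radii below ``min_radius_nm`` (smaller than any real
    septum) are excluded.
    """
    image = np.asarray(image, dtype=float)
    if image.max() <= 0:
        raise ValueError("image has no positive signal")
    image = image / image.max()   # exact invariance to intensity scaling
    thr = threshold_rel
    ys, xs = np.nonzero(image > thr)
    if len(xs) < 6:
        raise ValueError("too few bright pixels to fit a ring (need >= 6)")
    w = image[ys, xs]
    xf, yf = xs.astype(float), ys.astype(float)
    r_min = min_radius_nm / pixel_size
    r_max = min(image.shape) / 2.0 - 1.0
    candidates = [_taubin_circle(xf, yf, w)]
    px, py, pw = _local_maxima(image, thr)
    candidates.extend(_ransac_circle(px, py, pw, r_min, r_max))
    candidates.append(_grid_search_circle(image, xf, yf, w, r_min=r_min))
    # trimmed algebraic refit around each candidate (sub-pixel when the
    # inliers cover enough of the circle)
    for cx0, cy0, r0 in list(candidates):
        keep = np.abs(np.hypot(xf - cx0, yf - cy0) - r0) < 2.0
        if keep.sum() >= 6:
            try:
                candidates.append(_taubin_circle(xf[keep], yf[keep], w[keep]))
            except ValueError:
                pass
    candidates = [c for c in candidates if r_min <= c[2] <= r_max] or candidates

    def point_mass(c):
        resid = np.abs(np.hypot(px - c[0], py - c[1]) - c[2])
        return float(pw[resid < 1.5].sum())

    # primary criterion: weighted spot-maxima consensus (robust to thick
    # bright arcs); on-circle intensity only breaks near-ties
    cx0, cy0, r0 = max(candidates,
                       key=lambda c: (point_mass(c),
                                      _circle_score(image, *c)))

    trust = 0.75  # px

    def neg_ring(params):
        cx, cy, r = params
        if r <= max(1.0, 0.9 * r_min):
            return 1e9
        pen = sum(max(0.0, abs(d) - trust) ** 2 * 1e3
                  for d in (cx - cx0, cy - cy0, r - r0))
        return -_circle_score(image, cx, cy, r) + pen

    res = optimize.minimize(neg_ring, x0=[cx0, cy0, r0],
                            method="Nelder-Mead",
                            options={"xatol": 1e-3, "fatol": 1e-10,
                                     "maxiter": 2000})
    cx, cy, r = res.x
    if _circle_score(image, cx, cy, r) < _circle_score(image, cx0, cy0, r0):
        cx, cy, r = cx0, cy0, r0
    d = np.hypot(xf - cx, yf - cy)
    residual = float(np.sqrt(np.average((d - r) ** 2, weights=w))) * pixel_size
    h, wd = image.shape
    if not (0 <= cx < wd and 0 <= cy < h):
        raise ValueError("fitted ring center outside image")
    return RingGeometry(center_x=float(cx), center_y=float(cy),
                        radius_px=float(r), radius_nm=float(r * pixel_size),
                        fit_residual=residual)


def unwrap_to_kymograph(movie: np.ndarray, geometry: RingGeometry,
                        pixel_size: float, n_bins: int = 360,
                        band_halfwidth: float = 100.0) -> RadialKymograph:
    """Sample each frame along the fitted circle into angular bins.

    For every frame and bin the intensity is bilinearly interpolated at the
    bin's angle over radii ``[r - band, r + band]`` (nm) and averaged.
    """
    movie = np.asarray(movie, dtype=float)
    T, h, w = movie.shape
    r_px = geometry.radius_px
    band_px = band_halfwidth / pixel_size
    radii = np.linspace(r_px - band_px, r_px + band_px,
                        max(3, int(2 * band_px) + 1))
    if (geometry.center_x - radii[-1] < -0.5 or
            geometry.center_y - radii[-1] < -0.5 or
            geometry.center_x + radii[-1] > w - 0.5 or
            geometry.center_y + radii[-1] > h - 0.5):
        raise ValueError("sampling circle extends outside the image")
    ang = np.arange(n_bins) * 2 * np.pi / n_bins
    xs = geometry.center_x + np.outer(radii, np.cos(ang))
    ys = geometry.center_y + np.outer(radii, np.sin(ang))
    coords = np.array([ys.ravel(), xs.ravel()])
    values = np.empty((T, n_bins))
    for t in range(T):
        samp = ndimage.map_coordinates(movie[t], coords, order=1,
                                       mode="nearest")
        values[t] = samp.reshape(len(radii), n_bins).mean(axis=0)
    arc = 2 * np.pi * geometry.radius_nm / n_bins
    return RadialKymograph(values=values, n_bins=n_bins, bin_arc_length=arc,
                           origin_rotation=0.0, geometry=geometry)


def rotate_kymograph_origin(kymo: RadialKymograph,
                            shift_deg: float) -> RadialKymograph:
    """Cyclically shift the angular origin; values are only permuted."""
    shift_bins = int(round(shift_deg / 360.0 * kymo.n_bins)) % kymo.n_bins
    values = np.roll(kymo.values, -shift_bins, axis=1)
    return replace(kymo, values=values,
                   origin_rotation=(kymo.origin_rotation + shift_deg) % 360.0)
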