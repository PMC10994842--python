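"""Synthetic single-molecule septal-ring movies and trajectories.

Single fluorescently labelled peptidoglycan-synthase molecules on a division
ring are modelled as a three-state semi-Markov process:

* ``immobile`` — the molecule holds its ring angle (putatively wall-bound),
* ``processive`` — directed motion along the ring at a speed drawn once per
  episode, with occasional direction reversals,
* ``fast`` — slow subdiffusive wandering, modelled as 2-D fractional Brownian
  motion with time-averaged MSD ``4 * D_eff * t**alpha``.

Dwell times in each state are exponential; on leaving a state a competing
outcome is drawn (switch state, reverse direction, or a terminal event —
photobleaching, dissociation or end of acquisition).  Trajectories are
rendered into 16-bit TIFF-compatible movies with a Gaussian PSF, motion blur,
Poisson shot noise and Gaussian read noise, alongside a ground-truth record
sufficient to score every downstream estimator.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

STATES = ("immobile", "processive", "fast")

#: Outcome labels for the end of a state episode.
END_CAUSES = (
    "to_immobile",
    "to_processive",
    "to_fast",
    "direction_flip",
    "terminal",
    "censored",
)


@dataclass
class OpticsConfig:
    """Camera and illumination model for rendering.

    Defaults describe an sCMOS single-molecule setup: 65 nm effective pixels,
    1 s frame interval with a 0.5 s exposure, and a PSF sigma of 110 nm
    (about the diffraction limit for ~580 nm emission).
    """

    pixel_size: float = 65.0          # nm / pixel
    frame_interval: float = 1.0       # s
    exposure: float = 0.5             # s
    psf_sigma: float = 110.0          # nm
    photons_per_fluorophore_per_frame: float = 400.0
    background_level: float = 20.0    # counts / pixel inside the cell
    read_noise_sd: float = 2.0        # counts rms
    image_size: int = 48              # pixels (square)

    def __post_init__(self) -> None:
        if self.psf_sigma <= self.pixel_size / 2:
            raise ValueError("psf_sigma must exceed half a pixel for sampling")
        if self.exposure > self.frame_interval:
            raise ValueError("exposure cannot exceed the frame interval")


@dataclass
class SimPreset:
    """Operating point of the motion model for one experimental condition.

    Lifetimes are mean exponential dwell times in seconds; the
    ``from_*_fractions`` maps are the competing-outcome probabilities drawn
    when the corresponding state is left.  ``initial_state_probs`` is both the
    state distribution at molecule arrival and the restart distribution used
    when computing long-run occupancies.
    """

    name: str
    processive_speed_mean: float = 13.4       # nm/s
    processive_speed_sd: float = 4.0          # nm/s (assumed; not measured)
    immobile_lifetime_mean: float = 48.0      # s
    processive_lifetime_mean: float = 40.0    # s
    fast_lifetime_mean: float = 10.0          # s
    from_processive_fractions: dict = field(default_factory=lambda: {
        "direction_flip": 0.29, "to_immobile": 0.12,
        "to_fast": 0.05, "terminal": 0.54})
    from_immobile_fractions: dict = field(default_factory=lambda: {
        "to_processive": 0.2181, "to_fast": 0.2335, "terminal": 0.5484})
    from_fast_fractions: dict = field(default_factory=lambda: {
        "to_immobile": 0.30, "to_processive": 0.20, "terminal": 0.50})
    initial_state_probs: dict = field(default_factory=lambda: {
        "immobile": 0.38, "processive": 0.59, "fast": 0.03})
    D_eff: float = 6.5e-3                     # µm²/s^alpha
    alpha: float = 0.80                       # anomalous exponent
    ring_radius: float = 450.0                # nm
    lane_offsets: tuple = ()                  # nm, optional extra lanes
    bleach_rate: float = 0.005                # 1/s per fluorophore
    arrival_rate: float = 0.0                 # 1/s, new-molecule arrivals

    def __post_init__(self) -> None:
        for m in (self.from_processive_fractions, self.from_immobile_fractions,
                  self.from_fast_fractions, self.initial_state_probs):
            if abs(sum(m.values()) - 1.0) > 1e-9:
                raise ValueError(f"probabilities must sum to 1, got {m}")
        if not 0 < self.alpha < 2:
            raise ValueError("alpha must lie in (0, 2)")
        for tau in (self.immobile_lifetime_mean, self.processive_lifetime_mean,
                    self.fast_lifetime_mean):
            if tau <= 0:
                raise ValueError("state lifetimes must be positive")

    def lifetime(self, state: str) -> float:
        return {"immobile": self.immobile_lifetime_mean,
                "processive": self.processive_lifetime_mean,
                "fast": self.fast_lifetime_mean}[state]

    def exit_fractions(self, state: str) -> dict:
        return {"immobile": self.from_immobile_fractions,
                "processive": self.from_processive_fractions,
                "fast": self.from_fast_fractions}[state]


@dataclass
class TrueSegment:
    """One ground-truth state episode of a trajectory."""

    state: str
    start_time: float     # s
    end_time: float       # s
    speed: float          # nm/s, signed for processive episodes, 0 otherwise
    end_cause: str        # one of END_CAUSES
    censored: bool

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


@dataclass
class StatePath:
    """A trajectory sampled on the frame grid, with ground-truth episodes."""

    times: np.ndarray          # s
    theta: np.ndarray          # radians, wrapped to [0, 2π)
    r: np.ndarray              # nm
    state_labels: np.ndarray   # str per frame
    direction: np.ndarray      # ±1 per frame (processive), 0 otherwise
    n_fluorophores: np.ndarray
    censored_end: bool
    segments: list = field(default_factory=list)  # list[TrueSegment]

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class GroundTruth:
    """Sidecar record rendered alongside a movie; serializable to JSON."""

    preset_name: str
    seed: int
    paths: list                       # list[StatePath]
    center_px: tuple = (0.0, 0.0)
    radius_nm: float = 0.0
    clipped: bool = False

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))
        return json.dumps(dataclasses.asdict(self), default=enc, indent=1)


# ---------------------------------------------------------------------------
# Preset registry
# ---------------------------------------------------------------------------

def _registry() -> dict:
    untreated = SimPreset(name="untreated_rich_30C")
    pc = SimPreset(name="pc190723", processive_speed_mean=8.1,
                   processive_speed_sd=3.0)
    g106s = SimPreset(name="ftsZ_G106S", processive_speed_mean=8.1,
                      processive_speed_sd=3.0)
    # transpeptidation / lipid-II synthesis blocked: processive population
    # abolished, only immobile + fast remain
    blocked_exit = {"to_fast": 0.25, "terminal": 0.75}
    blocked = dict(
        processive_speed_mean=0.0, processive_speed_sd=1e-6,
        from_immobile_fractions=blocked_exit,
        from_fast_fractions={"to_immobile": 0.30, "terminal": 0.70},
        initial_state_probs={"immobile": 0.9, "processive": 0.0, "fast": 0.1},
        from_processive_fractions={"terminal": 1.0},
    )
    pen = SimPreset(name="penicillinG", **blocked)
    fos = SimPreset(name="fosfomycin", **blocked)
    diff = SimPreset(
        name="diffusive_only",
        initial_state_probs={"immobile": 0.0, "processive": 0.0, "fast": 1.0},
        from_fast_fractions={"terminal": 1.0},
        fast_lifetime_mean=1e6,   # effectively window-limited episodes
        bleach_rate=0.0,
    )
    return {p.name: p for p in (untreated, pc, g106s, pen, fos, diff)}


_PRESETS = _registry()


def make_preset(name: str, **overrides) -> SimPreset:
    """Return a registered condition preset, optionally with field overrides.

    Raises ``KeyError`` with the list of valid names for unknown presets.
    """
    if name not in _PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; valid presets: {sorted(_PRESETS)}")
    preset = dataclasses.replace(_PRESETS[name])
    if overrides:
        preset = dataclasses.replace(preset, **overrides)
    return preset


def preset_names() -> tuple:
    return tuple(sorted(_PRESETS))


# ---------------------------------------------------------------------------
# Fractional Brownian motion
# ---------------------------------------------------------------------------

def fgn(n: int, hurst: float, dt: float, rng: np.random.Generator) -> np.ndarray:
    """Sample ``n`` fractional-Gaussian-noise increments with unit scale.

    The increments are those of fractional Brownian motion B_H sampled at
    spacing ``dt``, i.e. Var[sum of k increments] = (k*dt)**(2H).  Uses the
    Davies–Harte circulant embedding; falls back to a Cholesky factorization
    of the fGn covariance when the embedding is not nonnegative definite.
    """
    if n == 0:
        return np.zeros(0)
    H = hurst
    k = np.arange(n + 1, dtype=float)
    # autocovariance of unit-spacing fGn, scaled to spacing dt afterwards
    gamma = 0.5 * ((k + 1) ** (2 * H) - 2 * k ** (2 * H)
                   + np.abs(k - 1) ** (2 * H))
    row = np.concatenate([gamma[:-1], gamma[-1:], gamma[-2:0:-1]])
    lam = np.fft.rfft(row).real
    scale = dt ** H
    if np.min(lam) >= -1e-10:
        lam = np.clip(lam, 0, None)
        m = len(row)
        z = rng.standard_normal(m // 2 + 1) + 1j * rng.standard_normal(m // 2 + 1)
        z[0] = z[0].real * math.sqrt(2)
        if m % 2 == 0:
            z[-1] = z[-1].real * math.sqrt(2)
        w = np.fft.irfft(z * np.sqrt(lam * m / 2), n=m)
        return scale * w[:n]
    cov = np.empty((n, n))
    idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    cov[:] = gamma[idx]
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(n))
    return scale * (L @ rng.standard_normal(n))


def fbm_track(n_steps: int, D_eff_um2: float, alpha: float, dt: float,
              rng: np.random.Generator) -> np.ndarray:
    """2-D fBm positions (nm), shape (n_steps+1, 2), starting at the origin.

    Scaled so the ensemble MSD is ``4 * D_eff * t**alpha`` (µm² with t in s),
    i.e. ``2 D t^alpha`` per Cartesian axis.
    """
    D_nm = D_eff_um2 * 1e6  # nm²/s^alpha
    amp = math.sqrt(2.0 * D_nm)
    H = alpha / 2.0
    steps = np.column_stack([fgn(n_steps, H, dt, rng),
                             fgn(n_steps, H, dt, rng)]) * amp
    pos = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
    return pos


# ---------------------------------------------------------------------------
# Semi-Markov trajectory sampling
# ---------------------------------------------------------------------------

def _draw_outcome(fractions: dict, rng: np.random.Generator) -> str:
    keys = sorted(fractions)
    probs = np.array([fractions[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def sample_state_path(preset: SimPreset, duration: float,
                      seed: Optional[int] = None,
                      rng: Optional[np.random.Generator] = None,
                      theta0: Optional[float] = None,
                      frame_interval: float = 1.0) -> StatePath:
    """Sample one molecule's trajectory over an observation window.

    Episodes are drawn event-by-event: exponential dwell in the current state,
    then a competing outcome from the preset's exit fractions.  A
    ``direction_flip`` outcome starts a fresh processive episode with the
    speed redrawn and the sign reversed; ``terminal`` ends the trajectory
    (dissociation/bleaching); reaching ``duration`` right-censors the final
    episode.  Positions are reported on the frame grid; processive episodes
    advance the ring angle at ``±v / ring_radius`` rad/s, immobile episodes
    hold it fixed, and fast episodes follow 2-D fractional Brownian motion in
    the (arc, radial) plane.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    dt = frame_interval
    r0 = preset.ring_radius

    # --- event-driven episode list -------------------------------------
    init_keys = sorted(preset.initial_state_probs)
    init_p = np.array([preset.initial_state_probs[k] for k in init_keys])
    state = init_keys[rng.choice(len(init_keys), p=init_p / init_p.sum())]
    direction = int(rng.choice([-1, 1]))
    segments: list[TrueSegment] = []
    t = 0.0
    censored_end = False
    while True:
        dwell = rng.exponential(preset.lifetime(state))
        v = 0.0
        if state == "processive":
            v = direction * _trunc_normal(preset.processive_speed_mean,
                                          preset.processive_speed_sd, rng)
        t_end = t + dwell
        if t_end >= duration:
            segments.append(TrueSegment(state, t, duration, v,
                                        "censored", True))
            censored_end = True
            break
        outcome = _draw_outcome(preset.exit_fractions(state), rng)
        segments.append(TrueSegment(state, t, t_end, v, outcome, False))
        t = t_end
        if outcome == "terminal":
            break
        if outcome == "direction_flip":
            direction = -direction
            state = "processive"
        else:
            state = outcome.removeprefix("to_")
            if state == "processive":
                direction = int(rng.choice([-1, 1]))

    # --- discretize onto the frame grid --------------------------------
    total = segments[-1].end_time
    n_frames = max(2, int(math.floor(total / dt)) + 1)
    times = np.arange(n_frames) * dt
    times = times[times <= total + 1e-9]
    theta = np.empty(len(times))
    r = np.empty(len(times))
    labels = np.empty(len(times), dtype=object)
    dirs = np.zeros(len(times), dtype=int)
    th = rng.uniform(0, 2 * np.pi) if theta0 is None else float(theta0)
    rad = r0
    seg_iter = iter(segments)
    seg = next(seg_iter)
    fast_pos = None
    fast_i = 0
    for i, ti in enumerate(times):
        while ti > seg.end_time + 1e-9:
            seg = next(seg_iter)
            fast_pos = None
        if i > 0:
            step = times[i] - times[i - 1]
            if seg.state == "processive":
                th += seg.speed / rad * step
            elif seg.state == "fast":
                if fast_pos is None:
                    n_in = int(math.ceil(seg.duration / dt)) + 2
                    fast_pos = fbm_track(n_in, preset.D_eff, preset.alpha,
                                         dt, rng)
                    fast_i = 0
                fast_i += 1
                d_arc = fast_pos[fast_i, 0] - fast_pos[fast_i - 1, 0]
                d_rad = fast_pos[fast_i, 1] - fast_pos[fast_i - 1, 1]
                th += d_arc / rad
                rad = rad + d_rad
                # diffusing molecules sit at or outside the septal leading
                # edge (the septum interior is occluded): reflect inward
                # excursions at a boundary just inside the ring
                r_in = preset.ring_radius - 100.0
                if rad < r_in:
                    rad = 2 * r_in - rad
        theta[i] = th % (2 * np.pi)
        r[i] = rad
        labels[i] = seg.state
        dirs[i] = int(np.sign(seg.speed)) if seg.state == "processive" else 0

    n_fl = np.ones(len(times), dtype=int)
    return StatePath(times=times, theta=theta, r=r, state_labels=labels,
                     direction=dirs, n_fluorophores=n_fl,
                     censored_end=censored_end, segments=segments)


def _trunc_normal(mean: float, sd: float, rng: np.random.Generator) -> float:
    """Normal draw truncated to positive values (speeds cannot be ≤ 0)."""
    for _ in range(100):
        v = rng.normal(mean, sd)
        if v > 0:
            return v
    return abs(rng.normal(mean, sd)) + 1e-6


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _add_gaussian(img: np.ndarray, x: float, y: float, sigma_px: float,
                  photons: float) -> bool:
    """Accumulate an integrated-Gaussian PSF; returns True if clipped."""
    n = img.shape[0]
    half = int(math.ceil(4 * sigma_px))
    x0, x1 = int(math.floor(x)) - half, int(math.floor(x)) + half + 1
    y0, y1 = int(math.floor(y)) - half, int(math.floor(y)) + half + 1
    clipped = x0 < 0 or y0 < 0 or x1 > n or y1 > n
    xs = np.arange(max(x0, 0), min(x1, n))
    ys = np.arange(max(y0, 0), min(y1, n))
    if len(xs) == 0 or len(ys) == 0:
        return True
    gx = np.exp(-0.5 * ((xs - x) / sigma_px) ** 2)
    gy = np.exp(-0.5 * ((ys - y) / sigma_px) ** 2)
    kern = np.outer(gy, gx)
    kern *= photons / (2 * math.pi * sigma_px ** 2)
    img[np.ix_(ys, xs)] += kern
    return clipped


def render_ring_movie(paths: Sequence[StatePath], optics: OpticsConfig,
                      preset: SimPreset, seed: int,
                      noise: bool = True) -> tuple:
    """Render trajectories into a (T, N, N) uint16 movie plus ground truth.

    Each frame accumulates a cytoplasmic background disk and one Gaussian PSF
    per molecule per sub-frame position (5 positions across the exposure
    window approximate motion blur), then applies Poisson shot noise and
    Gaussian read noise and quantizes to 16 bits.  Deterministic given
    (paths, optics, seed).
    """
    if not paths:
        raise ValueError("paths must be non-empty")
    rng = np.random.default_rng(seed)
    n = optics.image_size
    px = optics.pixel_size
    cx = cy = (n - 1) / 2.0
    margin = preset.ring_radius / px + 4 * optics.psf_sigma / px
    if margin > min(cx, cy):
        raise ValueError("image too small to contain the ring plus PSF margin")
    n_frames = max(len(p) for p in paths)
    frames = np.zeros((n_frames, n, n), dtype=float)

    # cytoplasmic background: smooth disk slightly larger than the ring
    yy, xx = np.mgrid[0:n, 0:n]
    rr = np.hypot((xx - cx) * px, (yy - cy) * px)
    disk_r = preset.ring_radius * 1.35
    bg = optics.background_level / (1 + np.exp((rr - disk_r) / (0.5 * px)))
    frames += bg[None, :, :]

    sigma_px = optics.psf_sigma / px
    n_sub = 5
    duty = optics.exposure / optics.frame_interval
    clipped = False
    for p in paths:
        th_u = unwrap_angle(p.theta)
        for i in range(len(p)):
            if p.n_fluorophores[i] <= 0:
                continue
            th_next = th_u[i + 1] if i + 1 < len(p) else th_u[i]
            r_next = p.r[i + 1] if i + 1 < len(p) else p.r[i]
            amp = (p.n_fluorophores[i]
                   * optics.photons_per_fluorophore_per_frame / n_sub)
            for j in range(n_sub):
                f = duty * (j + 0.5) / n_sub
                th = th_u[i] + f * (th_next - th_u[i])
                rad = p.r[i] + f * (r_next - p.r[i])
                x = cx + rad * math.cos(th) / px
                y = cy + rad * math.sin(th) / px
                clipped |= _add_gaussian(frames[i], x, y, sigma_px, amp)

    if noise:
        frames = rng.poisson(np.clip(frames, 0, None)).astype(float)
        frames += rng.normal(0, optics.read_noise_sd, frames.shape)
    movie = np.clip(np.round(frames), 0, 65535).astype(np.uint16)
    truth = GroundTruth(preset_name=preset.name, seed=seed, paths=list(paths),
                        center_px=(cx, cy), radius_nm=preset.ring_radius,
                        clipped=clipped)
    return movie, truth


def unwrap_angle(theta: np.ndarray) -> np.ndarray:
    """Unwrap ring angles by the ±2π branch minimizing each step."""
    return np.unwrap(np.asarray(theta, dtype=float))


# ---------------------------------------------------------------------------
# Fluorophore-count traces
# ---------------------------------------------------------------------------

def simulate_intensity_trace(initial_n: int, bleach_rate: float,
                             arrival_rate: float, duration: float,
                             seed: Optional[int] = None,
                             frame_interval: float = 1.0,
                             rng: Optional[np.random.Generator] = None
                             ) -> np.ndarray:
    """Per-frame fluorophore counts under memoryless bleaching and arrivals.

    Each fluorophore bleaches independently at ``bleach_rate``; new
    fluorophores arrive as a Poisson process at ``arrival_rate``.
    """
    if initial_n < 1:
        raise ValueError("initial_n must be >= 1")
    if bleach_rate < 0 or arrival_rate < 0:
        raise ValueError("rates must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_frames = int(math.floor(duration / frame_interval)) + 1
    t_frames = np.arange(n_frames) * frame_interval

    events = []  # (time, +1/-1)
    for _ in range(initial_n):
        if bleach_rate > 0:
            events.append((rng.exponential(1.0 / bleach_rate), -1))
    if arrival_rate > 0:
        t = 0.0
        while True:
            t += rng.exponential(1.0 / arrival_rate)
            if t > duration:
                break
            events.append((t, +1))
            if bleach_rate > 0:
                events.append((t + rng.exponential(1.0 / bleach_rate), -1))
    counts = np.full(n_frames, initial_n, dtype=int)
    for te, delta in sorted(events):
        counts[t_frames >= te] += delta
    return np.clip(counts, 0, None)
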