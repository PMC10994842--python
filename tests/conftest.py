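import numpy as np
import pytest

import septatrack as st


@pytest.fixture(scope="session")
def untreated():
    return st.make_preset("untreated_rich_30C")


@pytest.fixture(scope="session")
def optics():
    return st.OpticsConfig()


@pytest.fixture(scope="session")
def rendered_movie(untreated, optics):
    """One seeded untreated movie with ground truth (8 molecules, 120 s)."""
    rng = np.random.default_rng(42)
    paths = [st.sample_state_path(untreated, 120, rng=rng) for _ in range(8)]
    movie, truth = st.render_ring_movie(paths, optics, untreated, seed=42)
    return movie, truth


def synthetic_ring_image(n=40, cx=20.0, cy=20.0, r=6.9, sigma=1.7, amp=100.0):
    """Noiseless Gaussian annulus used as a circle-fit oracle fixture."""
    yy, xx = np.mgrid[0:n, 0:n]
    d = np.hypot(xx - cx, yy - cy)
    return amp * np.exp(-0.5 * ((d - r) / sigma) ** 2)


def noisy_track_from_path(path, preset, rng, loc_noise_nm=15.0, track_id=0):
    """Ring-mode Track built from a simulated path plus localization noise."""
    from septatrack.tracking import Spot, Track
    arc = (np.unwrap(path.theta) * preset.ring_radius
           + rng.normal(0, loc_noise_nm, len(path)))
    spots = [Spot(frame=int(f), x=0.0, y=0.0, amplitude=1.0,
                  theta=float(np.degrees(a / preset.ring_radius)))
             for f, a in zip(path.times, arc)]
    return Track(id=track_id, spots=spots, mode="ring")
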