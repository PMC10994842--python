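"""Generator tests: presets, semi-Markov paths, fBm, rendering, bleaching."""

import dataclasses

import numpy as np
import pytest

import septatrack as st
from septatrack.simulate import fgn


class TestPresets:
    @pytest.mark.parametrize("name,speed", [
        ("untreated_rich_30C", 13.4),
        ("pc190723", 8.1),
        ("ftsZ_G106S", 8.1),
    ])
    def test_processive_speed(self, name, speed):
        assert st.make_preset(name).processive_speed_mean == speed

    def test_untreated_operating_point(self, untreated):
        assert untreated.immobile_lifetime_mean == 48.0
        assert untreated.D_eff == pytest.approx(6.5e-3)
        assert untreated.alpha == pytest.approx(0.80)
        f = untreated.from_processive_fractions
        assert f["direction_flip"] == 0.29
        assert f["to_immobile"] == 0.12
        assert f["to_fast"] == 0.05
        assert f["terminal"] == 0.54
        assert sum(f.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(untreated.initial_state_probs.values()) == \
            pytest.approx(1.0, abs=1e-9)

    def test_synthesis_blocked_presets_have_no_processive_influx(self):
        for name in ("penicillinG", "fosfomycin"):
            p = st.make_preset(name)
            assert p.initial_state_probs["processive"] == 0.0
            assert "to_processive" not in p.from_immobile_fractions
            assert "to_processive" not in p.from_fast_fractions

    def test_unknown_preset_lists_valid_names(self):
        with pytest.raises(KeyError, match="untreated_rich_30C"):
            st.make_preset("nonexistent")

    def test_overrides_and_invariant_enforcement(self):
        p = st.make_preset("untreated_rich_30C", ring_radius=500.0)
        assert p.ring_radius == 500.0
        with pytest.raises(ValueError):
            st.make_preset("untreated_rich_30C", alpha=2.5)
        with pytest.raises(ValueError):
            st.make_preset("untreated_rich_30C",
                           initial_state_probs={"immobile": 0.7,
                                                "processive": 0.7,
                                                "fast": 0.0})


class TestStatePath:
    def test_immobile_only_path_is_static(self, untreated):
        p = dataclasses.replace(
            untreated,
            initial_state_probs={"immobile": 1.0, "processive": 0.0,
                                 "fast": 0.0},
            immobile_lifetime_mean=1e9)
        path = st.sample_state_path(p, 60, seed=0)
        assert len(path.segments) == 1
        assert path.segments[0].state == "immobile"
        assert np.ptp(path.theta) == 0.0

    def test_processive_step_matches_speed_over_radius(self, untreated):
        p = dataclasses.replace(
            untreated,
            initial_state_probs={"immobile": 0.0, "processive": 1.0,
                                 "fast": 0.0},
            processive_lifetime_mean=1e9, processive_speed_sd=1e-9,
            ring_radius=450.0)
        path = st.sample_state_path(p, 60, seed=1)
        dth = np.abs(np.diff(np.unwrap(path.theta)))
        assert np.allclose(dth, 13.4 / 450.0, rtol=1e-6)

    def test_long_run_occupancy_matches_event_driven_oracle(self, untreated):
        """Aggregate time fractions agree with a brute-force chain oracle."""
        # independent oracle: event-driven simulation of states only
        rng = np.random.default_rng(11)
        init = untreated.initial_state_probs
        occ_o = {s: 0.0 for s in init}
        state = "processive"
        t_total = 0.0
        while t_total < 2e5:
            dwell = rng.exponential(untreated.lifetime(state))
            occ_o[state] += dwell
            t_total += dwell
            fr = untreated.exit_fractions(state)
            keys = list(fr)
            outcome = keys[rng.choice(len(keys), p=[fr[k] for k in keys])]
            if outcome == "terminal":
                keys = list(init)
                state = keys[rng.choice(len(keys),
                                        p=[init[k] for k in keys])]
            elif outcome == "direction_flip":
                state = "processive"
            else:
                state = outcome.removeprefix("to_")
        occ_o = {k: v / t_total for k, v in occ_o.items()}

        # sampled trajectories
        rng = np.random.default_rng(12)
        tot = {s: 0.0 for s in init}
        T = 0.0
        while T < 1e5:
            path = st.sample_state_path(untreated, 120, rng=rng)
            for s in path.segments:
                tot[s.state] += s.duration
                T += s.duration
        occ_s = {k: v / T for k, v in tot.items()}
        for s in occ_o:
            assert occ_s[s] == pytest.approx(occ_o[s], abs=0.03)
        # and both agree with the analytic stationary solve
        occ_a = st.semi_markov_occupancy(
            {s: untreated.lifetime(s) for s in occ_o},
            {s: untreated.exit_fractions(s) for s in occ_o},
            untreated.initial_state_probs)
        assert occ_a["processive"] == pytest.approx(0.59, abs=0.005)

    def test_unwrapped_theta_has_no_wraparound_jumps(self, untreated):
        rng = np.random.default_rng(3)
        for _ in range(20):
            path = st.sample_state_path(untreated, 120, rng=rng)
            steps = np.abs(np.diff(np.unwrap(path.theta)))
            # fastest plausible per-frame motion is far below a half-turn
            assert steps.max() < np.pi / 2

    def test_invalid_duration_raises(self, untreated):
        with pytest.raises(ValueError):
            st.sample_state_path(untreated, 0.0, seed=0)


class TestFractionalBrownianMotion:
    def test_fgn_variance_scaling(self):
        rng = np.random.default_rng(0)
        for H in (0.4, 0.5, 0.75):
            inc = np.array([fgn(64, H, 1.0, rng) for _ in range(1500)])
            bm = np.cumsum(inc, axis=1)
            var = bm.var(axis=0)
            k = np.array([4, 16, 64])
            expect = k.astype(float) ** (2 * H)
            assert np.allclose(var[k - 1], expect, rtol=0.15)

    def test_ensemble_msd_matches_anomalous_form(self):
        rng = np.random.default_rng(1)
        msds = [st.compute_msd(st.fbm_track(50, 6.5e-3, 0.8, 1.0, rng)).msd
                for _ in range(400)]
        mean = np.mean(msds, axis=0)
        lags = np.arange(1, 11)
        expect = 4 * 6.5e-3 * lags ** 0.8
        assert np.allclose(mean, expect, rtol=0.05)


class TestRendering:
    def test_deterministic_given_seed(self, untreated, optics):
        rng = np.random.default_rng(5)
        paths = [st.sample_state_path(untreated, 30, rng=rng)]
        m1, t1 = st.render_ring_movie(paths, optics, untreated, seed=9)
        m2, t2 = st.render_ring_movie(paths, optics, untreated, seed=9)
        assert np.array_equal(m1, m2)

    def test_zero_photons_zero_background_is_dark(self, untreated):
        opt = st.OpticsConfig(photons_per_fluorophore_per_frame=0.0,
                              background_level=0.0, read_noise_sd=0.0)
        paths = [st.sample_state_path(untreated, 20, seed=0)]
        movie, _ = st.render_ring_movie(paths, opt, untreated, seed=0,
                                        noise=False)
        assert movie.max() == 0

    def test_static_spot_renders_symmetric_peak(self, untreated):
        # image_size 49 puts the center on a pixel; radius 455 nm = 7 px
        opt = st.OpticsConfig(background_level=0.0, read_noise_sd=0.0,
                              image_size=49)
        p = dataclasses.replace(
            untreated,
            initial_state_probs={"immobile": 1.0, "processive": 0.0,
                                 "fast": 0.0},
            immobile_lifetime_mean=1e9, ring_radius=455.0)
        path = st.sample_state_path(p, 10, seed=2, theta0=0.0)
        movie, truth = st.render_ring_movie([path], opt, p, seed=0,
                                            noise=False)
        frame = movie[0].astype(float)
        iy, ix = np.unravel_index(np.argmax(frame), frame.shape)
        cx, cy = truth.center_px
        assert (ix, iy) == (cx + 7, cy)
        assert frame[iy, ix - 2] == pytest.approx(frame[iy, ix + 2], rel=0.1)
        assert frame[iy - 2, ix] == pytest.approx(frame[iy + 2, ix], rel=0.1)

    def test_integrated_counts_match_photon_budget(self, untreated):
        opt = st.OpticsConfig(background_level=0.0, read_noise_sd=0.0,
                              photons_per_fluorophore_per_frame=400.0)
        p = dataclasses.replace(
            untreated,
            initial_state_probs={"immobile": 1.0, "processive": 0.0,
                                 "fast": 0.0},
            immobile_lifetime_mean=1e9)
        path = st.sample_state_path(p, 499, seed=3)
        movie, _ = st.render_ring_movie([path], opt, p, seed=3)
        integrated = movie.astype(float).sum(axis=(1, 2))
        assert integrated.mean() == pytest.approx(400.0, rel=0.05)

    def test_image_too_small_raises(self, untreated):
        opt = st.OpticsConfig(image_size=10)
        path = st.sample_state_path(untreated, 10, seed=0)
        with pytest.raises(ValueError):
            st.render_ring_movie([path], opt, untreated, seed=0)


class TestIntensityTrace:
    def test_no_rates_constant_count(self):
        c = st.simulate_intensity_trace(3, 0.0, 0.0, 50, seed=0)
        assert np.all(c == 3)

    def test_counts_only_decrease_without_arrivals(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            c = st.simulate_intensity_trace(2, 0.05, 0.0, 200, rng=rng)
            assert np.all(np.diff(c) <= 0)
            assert c[0] == 2

    def test_mean_survival_time_is_inverse_bleach_rate(self):
        rng = np.random.default_rng(5)
        surv = []
        for _ in range(10000):
            c = st.simulate_intensity_trace(1, 0.01, 0.0, 2000, rng=rng)
            gone = np.nonzero(c == 0)[0]
            surv.append(gone[0] if len(gone) else 2000)
        assert np.mean(surv) == pytest.approx(100.0, rel=0.05)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            st.simulate_intensity_trace(1, -0.1, 0.0, 10, seed=0)
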