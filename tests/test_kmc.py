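"""Kinetic Monte Carlo simulator: jump laws, near-field dynamics, events."""

import numpy as np
import pytest
from scipy.special import erfc
from scipy.stats import ks_2samp, kstest

from chemosense.geometry import ReceptorConfig
from chemosense.homogenized import capture_probability
from chemosense.kmc import (
    EventTable,
    SimulationConfig,
    far_field_step,
    near_field_step,
    simulate,
)


class TestFarFieldStep:
    def test_start_on_shell_hits_immediately(self, rng):
        pos = np.array([0.0, 1.2, 0.0])
        res = far_field_step(pos, rng, shell=1.2)
        assert not res.escaped and res.elapsed == 0.0
        assert np.allclose(res.point, pos)

    def test_inside_shell_rejected(self, rng):
        with pytest.raises(ValueError):
            far_field_step(np.array([0.0, 0.0, 1.0]), rng, shell=1.2)

    def test_escape_frequency_matches_splitting_probability(self, rng):
        """From r = 2s the walker returns with probability exactly 1/2."""
        pos = np.array([0.0, 0.0, 2.4])
        n = 20_000
        esc = sum(far_field_step(pos, rng, shell=1.2).escaped for _ in range(n))
        se = np.sqrt(0.25 / n)
        assert abs(esc / n - 0.5) < 3 * se

    def test_hit_time_law(self, rng):
        """Conditioned on hitting, the elapsed time follows the Levy
        first-passage density over the radial gap."""
        pos = np.array([0.0, 0.0, 2.4])
        shell, D = 1.2, 1.0
        times = []
        while len(times) < 4000:
            res = far_field_step(pos, rng, shell=shell, D=D)
            if not res.escaped:
                times.append(res.elapsed)
        gap = pos[2] - shell
        cdf = lambda t: erfc(gap / np.sqrt(4.0 * D * np.asarray(t)))
        assert kstest(times, cdf).pvalue > 0.01

    def test_hit_point_matches_fine_step_brownian_oracle(self, rng):
        """The inverse-CDF harmonic-measure sampler agrees with a direct
        small-step Brownian simulation of the same first-passage problem."""
        shell, r0 = 1.2, 2.4
        # oracle: plain Gaussian walk from (0,0,r0) until |x|<shell or far away
        n_or, dt = 1200, 5e-4
        sig = np.sqrt(2.0 * dt)
        pos = np.zeros((n_or, 3))
        pos[:, 2] = r0
        alive = np.ones(n_or, dtype=bool)
        mu_oracle = np.full(n_or, np.nan)
        for _ in range(60_000):
            idx = np.flatnonzero(alive)
            if idx.size == 0:
                break
            pos[idx] += rng.standard_normal((idx.size, 3)) * sig
            rr = np.linalg.norm(pos[idx], axis=1)
            hit = rr <= shell
            gone = rr > 60.0
            hit_ids = idx[hit]
            mu_oracle[hit_ids] = pos[hit_ids, 2] / np.linalg.norm(
                pos[hit_ids], axis=1)
            alive[idx[hit | gone]] = False
        mu_oracle = mu_oracle[~np.isnan(mu_oracle)]
        assert mu_oracle.size > 300  # enough resolved hits

        mu_kmc = []
        start = np.array([0.0, 0.0, r0])
        while len(mu_kmc) < mu_oracle.size:
            res = far_field_step(start, rng, shell=shell)
            if not res.escaped:
                mu_kmc.append(res.point[2] / shell)
        assert ks_2samp(mu_oracle, np.asarray(mu_kmc)).pvalue > 0.01


class TestNearFieldStep:
    def test_position_outside_near_region_rejected(self, receptors, rng):
        cfg = SimulationConfig(M=1, R=5.0, receptors=receptors)
        with pytest.raises(ValueError):
            near_field_step(np.array([0.0, 0.0, 3.0]), cfg, rng)

    def test_outcomes_and_reflection_stay_outside_sphere(self, receptors, rng):
        cfg = SimulationConfig(M=1, R=5.0, receptors=receptors)
        pos = np.array([0.0, 0.0, 1.00005])
        seen = set()
        for _ in range(3000):
            res = near_field_step(pos, cfg, rng)
            seen.add(res.outcome)
            if res.outcome in ("moved", "reflected"):
                assert np.linalg.norm(res.position) >= 1.0 - 1e-12
            if res.outcome == "absorbed":
                assert np.linalg.norm(res.position) == pytest.approx(1.0, abs=1e-9)
        assert {"moved", "reflected"} <= seen

    def test_absorption_above_receptor_center(self, receptors, rng):
        """A walker hovering just above a cap centre binds to that cap."""
        cfg = SimulationConfig(M=1, R=5.0, receptors=receptors)
        start = receptors.centers[0] * 1.00002
        hits = 0
        for _ in range(500):
            pos = start.copy()
            for _ in range(50):
                res = near_field_step(pos, cfg, rng)
                if res.outcome == "absorbed":
                    assert res.receptor == 0
                    hits += 1
                    break
                pos = res.position
                if np.linalg.norm(pos) > cfg.near_shell:
                    break
        assert hits > 50

    def test_resolution_condition_enforced_at_startup(self, receptors):
        with pytest.raises(ValueError, match="resolution"):
            SimulationConfig(M=10, R=5.0, receptors=receptors,
                             dt_near=receptors.a**2)


class TestSimulate:
    def test_seed_determinism(self, receptors):
        cfg = SimulationConfig(M=400, R=5.0, receptors=receptors, seed=99)
        a, b = simulate(cfg), simulate(cfg)
        assert a.Ma == b.Ma and a.escaped == b.escaped
        assert a.events.equals(b.events)

    def test_events_sorted_and_on_sphere_inside_caps(self, reference_events,
                                                     receptors):
        et = reference_events
        assert np.all(np.diff(et.arrival_times) > 0) or et.ties == 0
        xyz = et.events[["x", "y", "z_coord"]].to_numpy()
        assert np.allclose(np.linalg.norm(xyz, axis=1), 1.0, atol=1e-9)
        cos_cap = np.sqrt(1.0 - receptors.a**2)
        best = (xyz @ receptors.centers.T).max(axis=1)
        assert np.all(best >= cos_cap - 1e-12)
        rid = et.events["receptor_id"].to_numpy()
        assert np.all((rid >= 0) & (rid < receptors.N))

    def test_zero_receptors_never_bind(self):
        et = simulate(SimulationConfig(M=300, R=3.0, receptors=None, seed=5,
                                       t_max=5.0))
        assert et.Ma == 0
        assert et.escaped + et.censored == 300

    def test_fully_absorbing_sphere_capture(self):
        """Classical exterior hitting probability: capture = 1/R."""
        M, R = 6000, 5.0
        et = simulate(SimulationConfig(M=M, R=R, receptors=None, seed=7,
                                       absorb_on_contact=True, dt_near=2e-5))
        p = 1.0 / R
        se = np.sqrt(p * (1 - p) / M)
        assert abs(et.Ma / M - p) < 3.5 * se

    def test_azimuthal_symmetry(self, reference_events):
        """No azimuthal bias in aggregate: Rayleigh test on the binding
        azimuths (the cap layout is discrete, so a circular-mean test is
        the appropriate uniformity check)."""
        ev = reference_events.events
        phi = np.arctan2(ev["y"], ev["x"]).to_numpy()
        n = phi.size
        rbar2 = (np.cos(phi).sum() ** 2 + np.sin(phi).sum() ** 2) / n**2
        p_rayleigh = np.exp(-n * rbar2)
        assert p_rayleigh > 0.01

    def test_capture_error_shrinks_with_step_size(self, receptors, ref_params):
        """Refining dt moves the capture fraction toward the homogenized
        prediction (within sampling noise)."""
        M = 8000
        p = capture_probability(ref_params)
        se = np.sqrt(p * (1 - p) / M)
        errs = []
        for dt in (receptors.a**2 / 16.0, receptors.a**2 / 144.0):
            et = simulate(SimulationConfig(M=M, R=5.0, receptors=receptors,
                                           seed=314, dt_near=dt))
            errs.append(abs(et.Ma / M - p))
        assert errs[1] <= errs[0] + 2.0 * np.sqrt(2.0) * se

    def test_censoring_reported(self, receptors):
        et = simulate(SimulationConfig(M=500, R=5.0, receptors=receptors,
                                       seed=3, t_max=0.3))
        assert et.censored >= 0
        assert et.Ma + et.escaped + et.censored == 500
        assert np.all(et.arrival_times <= 0.3 + 1e-12)

    def test_event_table_roundtrip(self, tmp_path, receptors):
        et = simulate(SimulationConfig(M=300, R=5.0, receptors=receptors, seed=11))
        path = tmp_path / "events.csv"
        et.to_csv(path)
        back = EventTable.from_csv(path)
        assert back.Ma == et.Ma and back.seed == et.seed
        assert np.allclose(back.arrival_times, et.arrival_times)
        assert back.config.M == et.config.M
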