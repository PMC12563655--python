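"""Force oracles, integrator statistics, determinism, and run() contracts."""

import numpy as np
import pytest

from anionflux.model import FIELD_COUPLING, FieldSpec, SimConfig, build_fcc, build_species
from anionflux.simulate import (
    HAVE_NUMBA,
    ForceModel,
    PackingError,
    SimState,
    compute_forces,
    initialize_state,
    run,
    random_unit_quaternions,
    step,
)
from anionflux.trajectory import unwrap
from anionflux.transport import axial_velocities


def _state(centers, box=100.0, seed=0, n=None, quats=None):
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    n = len(centers)
    rng = np.random.default_rng(seed)
    q = quats if quats is not None else np.tile([1.0, 0.0, 0.0, 0.0], (n, 1))
    return SimState(
        anion_centers=centers,
        anion_orientations=np.asarray(q, dtype=float),
        wrap_counts=np.zeros((n, 3), dtype=int),
        box=np.full(3, float(box)),
        time=0.0,
        rng=rng,
    )


class TestForceOracles:
    def test_isolated_anion_feels_nothing(self, p3):
        model = ForceModel(field=FieldSpec(0.0))
        f, t = compute_forces(_state([[50.0, 50.0, 50.0]]), model, None, p3)
        assert np.allclose(f, 0.0) and np.allclose(t, 0.0)

    def test_field_force_is_q_times_E(self, p2):
        model = ForceModel(field=FieldSpec(0.3))
        f, _ = compute_forces(_state([[50.0, 50.0, 50.0]]), model, None, p2)
        assert f[0, 0] == pytest.approx(p2.total_charge * 0.3 * model.field_coupling)
        assert f[0, 1] == f[0, 2] == 0.0

    def test_wca_zero_at_cutoff_distance(self, p2):
        """No interaction beyond 2^(1/6) sigma_s from the NP surface."""
        lat = build_fcc(lattice_constant=50.0, np_radius=1.2)
        model = ForceModel(
            field=FieldSpec(0.0), bjerrum_scale=0.0, adsorption_depth=0.0
        )
        sigma_s = 0.5 * p2.bead_diameter
        h = 2.0 ** (1.0 / 6.0) * sigma_s
        # orient along y so both beads sit at equal distance from the NP at origin
        quats = [[np.cos(np.pi / 4), 0.0, 0.0, np.sin(np.pi / 4)]]
        d = np.sqrt((1.2 + h) ** 2 - 0.3**2)  # beads at +-0.3 along y
        st = _state([[d, 0.0, 0.0]], box=50.0, quats=quats)
        f, _ = compute_forces(st, model, lat, p2)
        assert np.allclose(f, 0.0, atol=1e-12)
        st2 = _state([[d - 0.05, 0.0, 0.0]], box=50.0, quats=quats)
        f2, _ = compute_forces(st2, model, lat, p2)
        assert f2[0, 0] > 0.1  # repulsive just inside

    @pytest.mark.parametrize("use_numba", [False] + ([True] if HAVE_NUMBA else []))
    def test_np_force_matches_finite_difference_of_potential(self, p2, use_numba):
        """Yukawa + adsorption force along x equals -dU/dx of an independently
        written potential, to 1e-6 relative."""
        lat = build_fcc(lattice_constant=60.0, np_radius=1.2)
        model = ForceModel(
            field=FieldSpec(0.0),
            bjerrum_scale=0.7,
            debye_length=0.6,
            adsorption_depth=1.0,
            adsorption_range=0.35,
        )
        quats = [[np.cos(np.pi / 4), 0.0, 0.0, np.sin(np.pi / 4)]]
        body = p2.bead_coords()

        k = 2.0 * np.pi * np.round(60.0 / model.corrugation_spacing) / 60.0

        def potential(cx):
            u = 0.0
            for b, q in zip(body, p2.bead_charges):
                # body x-axis rotated onto lab y by the quaternion above
                pos = np.array([cx, b[0], 0.0])
                r = np.linalg.norm(pos)
                if r < 4 * model.debye_length:
                    u += model.bjerrum_scale * q * lat.np_charge * np.exp(-r / model.debye_length) / r
                h = r - lat.np_radius
                g = 1.0 + model.corrugation * np.cos(k * pos[0]) * np.cos(k * pos[1]) * np.cos(k * pos[2])
                u += -model.adsorption_depth * g * np.exp(-0.5 * (h / model.adsorption_range) ** 2)
            return u

        x0 = 1.2 + 0.6  # within both Yukawa and adsorption range, outside WCA
        st = _state([[x0, 0.0, 0.0]], box=60.0, quats=quats)
        f, _ = compute_forces(st, model, lat, p2, use_numba=use_numba)
        eps = 1e-5
        expected = -(potential(x0 + eps) - potential(x0 - eps)) / (2 * eps)
        assert f[0, 0] == pytest.approx(expected, rel=1e-6)

    @pytest.mark.skipif(not HAVE_NUMBA, reason="numba not installed")
    def test_numpy_and_numba_paths_agree(self, p3, lattice):
        cfg = SimConfig(
            species=p3, lattice=lattice, field=FieldSpec(0.2), seed=11, n_steps=10
        )
        st = initialize_state(cfg, np.random.default_rng(11))
        model = ForceModel(field=FieldSpec(0.2), adsorption_depth=1.0)
        f1, t1 = compute_forces(st, model, lattice, p3, use_numba=False)
        f2, t2 = compute_forces(st, model, lattice, p3, use_numba=True)
        assert np.allclose(f1, f2, rtol=1e-10, atol=1e-12)
        assert np.allclose(t1, t2, rtol=1e-10, atol=1e-12)


class TestStep:
    def test_unbiased_diffusion_mean_zero(self, p2):
        """Zero force: ensemble mean displacement within 4 SE of zero."""
        n = 400
        rng = np.random.default_rng(5)
        centers = rng.random((n, 3)) * 400.0
        st = _state(centers, box=400.0, seed=5)
        st.anion_orientations = random_unit_quaternions(n, rng)
        model = ForceModel(field=FieldSpec(0.0))
        start = st.unwrapped_centers().copy()
        for _ in range(400):
            step(st, 0.01, model, None, p2, friction=2.0)
        disp = st.unwrapped_centers() - start
        d_t = 0.5 / p2.n_beads
        se = np.sqrt(2 * d_t * st.time / n)
        assert np.all(np.abs(disp.mean(axis=0)) < 4 * se)

    def test_msd_slope_matches_einstein_relation(self, p2):
        """MSD of free anions grows as 6 D_t t within 5% (500 walkers)."""
        n = 500
        rng = np.random.default_rng(42)
        st = _state(rng.random((n, 3)) * 500.0, box=500.0, seed=42)
        model = ForceModel(field=FieldSpec(0.0))
        start = st.unwrapped_centers().copy()
        times, msds = [], []
        for k in range(60):
            for _ in range(10):
                step(st, 0.01, model, None, p2, friction=2.0)
            d = st.unwrapped_centers() - start
            times.append(st.time)
            msds.append(np.mean(np.sum(d * d, axis=1)))
        slope = np.polyfit(times, msds, 1)[0]
        d_t = 0.5 / p2.n_beads
        assert slope == pytest.approx(6 * d_t, rel=0.05)

    def test_same_seed_bit_identical(self, p3, lattice):
        cfg = SimConfig(
            species=p3, lattice=lattice, field=FieldSpec(0.1), seed=3, n_steps=200, save_every=20
        )
        t1, t2 = run(cfg), run(cfg)
        assert np.array_equal(t1.centers, t2.centers)
        assert np.array_equal(t1.wrap_counts, t2.wrap_counts)

    def test_orientations_stay_unit_norm(self, p3, lattice):
        cfg = SimConfig(species=p3, lattice=lattice, field=FieldSpec(0.0), seed=9, n_steps=50)
        st = initialize_state(cfg, np.random.default_rng(9))
        model = ForceModel(field=FieldSpec(0.0))
        for _ in range(200):
            step(st, cfg.timestep, model, lattice, p3)
        norms = np.linalg.norm(st.anion_orientations, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-9)

    def test_bad_dt_rejected(self, p3):
        st = _state([[1.0, 1.0, 1.0]])
        with pytest.raises(ValueError):
            step(st, -0.1, ForceModel(field=FieldSpec(0.0)), None, p3)


class TestRun:
    def test_free_drift_matches_mobility_times_force(self, p2):
        """v_x = (D_t/kBT) q E within 2% for non-interacting anions."""
        n = 500
        rng = np.random.default_rng(7)
        # grid placement, 10 nm apart: interactions stay out of range
        g = np.arange(8) * 10.0 + 5.0
        pts = np.array(np.meshgrid(g, g, g)).reshape(3, -1).T[:n]
        st = _state(pts, box=80.0, seed=7)
        st.anion_orientations = random_unit_quaternions(n, rng)
        model = ForceModel(field=FieldSpec(0.4))
        start = st.unwrapped_centers().copy()
        for _ in range(2500):
            step(st, 0.01, model, None, p2, friction=2.0)
        v = (st.unwrapped_centers() - start)[:, 0] / st.time
        d_t = 0.5 / p2.n_beads
        expected = d_t * p2.total_charge * 0.4 * model.field_coupling
        assert v.mean() == pytest.approx(expected, rel=0.02)

    def test_full_lattice_zero_field_no_net_drift(self, p3, lattice):
        cfg = SimConfig(
            species=p3, lattice=lattice, field=FieldSpec(0.0), seed=21, n_steps=4000, save_every=100
        )
        traj = run(cfg)
        v = axial_velocities(unwrap(traj))
        se = v.std(ddof=1) / np.sqrt(len(v))
        assert abs(v.mean()) < 4 * se + 1e-12

    def test_different_seeds_different_paths_same_statistics(self, p3, lattice):
        cfgs = [
            SimConfig(
                species=p3, lattice=lattice, field=FieldSpec(0.0), seed=s, n_steps=2000, save_every=100
            )
            for s in (1, 2)
        ]
        t1, t2 = run(cfgs[0]), run(cfgs[1])
        assert not np.allclose(t1.centers, t2.centers)
        m1 = np.abs(unwrap(t1).values[-1]).mean()
        m2 = np.abs(unwrap(t2).values[-1]).mean()
        assert m1 == pytest.approx(m2, rel=0.5)  # same scale of wandering

    def test_frames_and_metadata(self, small_config):
        traj = run(small_config)
        assert traj.n_frames == small_config.n_steps // small_config.save_every + 1
        assert traj.n_anions == 32
        assert np.all(np.isfinite(traj.centers))
        assert traj.metadata["seed"] == 7
        assert traj.metadata["config_hash"] == small_config.config_hash()
        assert np.all(traj.centers >= 0) and np.all(traj.centers < 10.0)

    def test_packing_error_when_too_crowded(self, p3):
        # NP clearance shells cover the whole cell: no admissible position
        lat = build_fcc(lattice_constant=3.72, np_radius=1.3, np_charge=24.0)
        cfg = SimConfig(species=p3, lattice=lat, field=FieldSpec(0.0), seed=1, n_steps=10)
        with pytest.raises(PackingError):
            initialize_state(cfg, np.random.default_rng(1))
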