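"""MSM estimation and free-energy analysis."""

import numpy as np
import pytest

from pacsmd.dynamics import DoubleWell1D, MDParams, mb_velocities, propagate
from pacsmd.msm import (MSMError, acceleration_ratio, assign_to_centers,
                        count_matrix, dG_to_kd, estimate_msm,
                        free_energy_profile, implied_timescales, kd_to_dG,
                        kmeans_pp, order_of_magnitude, sample_markov_chain,
                        stationary_distribution, standard_binding_dG,
                        transition_matrix)
from pacsmd.units import KB, R_KCAL, STANDARD_VOLUME


class TestKmeansPP:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal(loc=0.0, scale=0.1, size=500)
        b = rng.normal(loc=5.0, scale=0.1, size=500)
        data = np.concatenate([a, b])
        centers, labels = kmeans_pp(data, 2, seed=1)
        blob = labels[:500]
        majority = np.bincount(blob).argmax()
        agreement = max((blob == majority).mean(),
                        (labels[500:] == 1 - majority).mean())
        assert agreement >= 0.99
        assert sorted(centers[:, 0].round(1)) == [0.0, 5.0]

    def test_k_equals_m_zero_inertia(self):
        data = np.arange(6.0)
        centers, labels = kmeans_pp(data, 6, seed=2)
        assigned = centers[labels][:, 0]
        assert np.abs(np.sort(assigned) - data).max() < 1e-12

    def test_deterministic_given_seed(self):
        data = np.random.default_rng(3).normal(size=(200, 2))
        c1, _ = kmeans_pp(data, 5, seed=7)
        c2, _ = kmeans_pp(data, 5, seed=7)
        assert np.array_equal(c1, c2)

    def test_k_larger_than_m_rejected(self):
        with pytest.raises(MSMError):
            kmeans_pp(np.arange(3.0), 4, seed=0)


class TestCountMatrix:
    def test_direct_count_lag_1(self):
        c = count_matrix([np.array([0, 0, 1, 1, 0])], lag=1)
        assert np.array_equal(c, [[1, 1], [1, 1]])

    def test_lag_4_single_pair(self):
        c = count_matrix([np.array([0, 0, 1, 1, 0])], lag=4)
        assert c.sum() == 1 and c[0, 0] == 1

    def test_counts_never_cross_segment_boundaries(self):
        segs = [np.array([0, 1]), np.array([1, 0])]
        c = count_matrix(segs, lag=1)
        assert np.array_equal(c, [[0, 1], [1, 0]])

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        dtrajs = [rng.integers(0, 4, size=rng.integers(2, 50))
                  for _ in range(20)]
        lag = 3
        c = count_matrix(dtrajs, lag, n_states=4)
        oracle = np.zeros((4, 4), dtype=int)
        for d in dtrajs:
            for t in range(len(d) - lag):
                oracle[d[t], d[t + lag]] += 1
        assert np.array_equal(c, oracle)

    def test_all_too_short_rejected(self):
        with pytest.raises(MSMError):
            count_matrix([np.array([0, 1])], lag=5)


class TestTransitionMatrix:
    def test_row_normalization(self):
        t, active = transition_matrix(np.array([[9, 1], [2, 8]]))
        assert np.allclose(t, [[0.9, 0.1], [0.2, 0.8]])
        assert list(active) == [0, 1]

    def test_symmetrized_satisfies_detailed_balance(self):
        rng = np.random.default_rng(5)
        c = rng.integers(1, 50, size=(4, 4))
        t, _ = transition_matrix(c, estimator="symmetrized")
        pi = stationary_distribution(t)
        flux = pi[:, None] * t
        assert np.abs(flux - flux.T).max() < 1e-10

    def test_disconnected_keeps_larger_block(self):
        c = np.zeros((5, 5), dtype=int)
        c[:3, :3] = 1  # 3-state block
        c[3:, 3:] = 1  # 2-state block
        t, active = transition_matrix(c)
        assert list(active) == [0, 1, 2]
        assert t.shape == (3, 3)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(6)
        c = rng.integers(0, 20, size=(6, 6)) + np.eye(6, dtype=int)
        t, _ = transition_matrix(c)
        assert np.abs(t.sum(axis=1) - 1.0).max() < 1e-12


class TestStationaryDistribution:
    def test_two_state_closed_form(self):
        # pi solves pi T = pi: for p12=0.1, p21=0.2 -> pi = (2/3, 1/3)
        t = np.array([[0.9, 0.1], [0.2, 0.8]])
        assert np.allclose(stationary_distribution(t), [2 / 3, 1 / 3])

    def test_doubly_stochastic_is_uniform(self):
        t = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])
        assert np.allclose(stationary_distribution(t), 1 / 3)

    def test_fixed_point_residual(self):
        rng = np.random.default_rng(7)
        c = rng.integers(1, 30, size=(5, 5))
        t, _ = transition_matrix(c, estimator="symmetrized")
        pi = stationary_distribution(t)
        assert np.abs(pi @ t - pi).max() < 1e-12
        assert pi.sum() == pytest.approx(1.0)


class TestImpliedTimescales:
    def test_two_state_closed_form(self):
        t = np.array([[0.9, 0.1], [0.2, 0.8]])
        ts = implied_timescales(t, lag=1, n=1)
        assert ts[0] == pytest.approx(-1 / np.log(0.7), rel=1e-12)

    def test_chapman_kolmogorov_lag_doubling(self):
        rng = np.random.default_rng(8)
        # diagonally dominant reversible counts: real, positive spectrum
        c = rng.integers(1, 40, size=(4, 4)) + 400 * np.eye(4, dtype=int)
        t, _ = transition_matrix(c, estimator="symmetrized")
        t1 = implied_timescales(t, lag=1, n=3)
        t2 = implied_timescales(t @ t, lag=2, n=3)
        assert np.abs(t1 - t2).max() < 1e-8

    def test_near_unity_eigenvalue_diverges(self):
        eps = 1e-300
        t = np.array([[1 - eps, eps], [eps, 1 - eps]])
        ts = implied_timescales(t, lag=1, n=1)
        assert ts[0] > 1e250

    def test_too_many_requested(self):
        with pytest.raises(MSMError):
            implied_timescales(np.eye(2), lag=1, n=2)


class TestFreeEnergyProfile:
    def test_two_state_ratio(self):
        prof = free_energy_profile(np.array([2 / 3, 1 / 3]),
                                   np.array([0.0, 1.0]), 300.0)
        assert prof.f[0] == 0.0
        assert prof.f[1] == pytest.approx(KB * 300 * np.log(2), rel=1e-12)

    def test_uniform_is_flat(self):
        prof = free_energy_profile(np.full(5, 0.2), np.arange(5.0), 300.0)
        assert np.abs(prof.f).max() == 0.0

    def test_zero_probability_bins_excluded(self):
        prof = free_energy_profile(np.array([0.5, 0.0, 0.5]),
                                   np.arange(3.0), 300.0)
        assert len(prof.f) == 2
        assert np.isfinite(prof.f).all()

    def test_bins_sorted_by_center(self):
        prof = free_energy_profile(np.array([0.25, 0.75]),
                                   np.array([2.0, 1.0]), 300.0)
        assert list(prof.centers) == [1.0, 2.0]


def synthetic_profile(centers, f, temperature=300.0):
    from pacsmd.msm import FreeEnergyProfile

    return FreeEnergyProfile(centers=np.asarray(centers, dtype=float),
                             f=np.asarray(f, dtype=float),
                             temperature=temperature)


def shell_points(n=200, r_lo=1.6, r_hi=2.0, seed=9):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    return v * rng.uniform(r_lo, r_hi, size=n)[:, None]


class TestStandardBindingDG:
    def make_profile(self, depth_kj=20.0):
        centers = np.linspace(0.3, 2.0, 30)
        f = np.zeros(30)
        f[0] = 0.0
        f[1:] = depth_kj  # deep single bound bin, flat plateau
        return synthetic_profile(centers, f)

    def test_identity_volume_means_no_correction(self):
        prof = self.make_profile()
        # points whose hull volume equals the standard-state volume
        pts = shell_points()
        hull_vol = __import__("pacsmd.geometry", fromlist=["convex_hull"]) \
            .convex_hull(pts).volume
        scale = (STANDARD_VOLUME / hull_vol) ** (1 / 3)
        res = standard_binding_dG(prof, pts * scale)
        assert res.v_sim == pytest.approx(STANDARD_VOLUME, rel=1e-6)
        assert res.correction_kcal == pytest.approx(0.0, abs=1e-9)
        assert res.dG_kcal == pytest.approx(-res.dW_kJ / 4.184, rel=1e-9)

    def test_doubling_volume_shifts_by_rt_ln2(self):
        prof = self.make_profile()
        pts = shell_points()
        res1 = standard_binding_dG(prof, pts)
        res2 = standard_binding_dG(prof, pts * 2 ** (1 / 3))
        shift = res2.dG_kcal - res1.dG_kcal
        assert shift == pytest.approx(-R_KCAL * 300 * np.log(2), rel=1e-6)

    def test_unconverged_plateau_rejected(self):
        centers = np.linspace(0.3, 2.0, 30)
        f = np.linspace(0.0, 10.0, 30)  # steadily rising, no plateau
        with pytest.raises(MSMError, match="converged"):
            standard_binding_dG(synthetic_profile(centers, f),
                                shell_points())

    def test_degenerate_unbound_points_rejected(self):
        prof = self.make_profile()
        with pytest.raises(Exception):
            standard_binding_dG(prof, np.zeros((10, 3)))


class TestConversions:
    def test_kd_one_molar_is_zero(self):
        assert kd_to_dG(1.0, 310.0) == 0.0

    def test_kd_19_nM_at_300K(self):
        # 19 nM at 300 K -> -10.6 kcal/mol to 3 significant figures
        dg = kd_to_dG(19e-9, 300.0)
        assert round(dg, 1) == -10.6

    def test_roundtrip_bijection(self):
        kd = 3.7e-8
        assert dG_to_kd(kd_to_dG(kd, 285.0), 285.0) == pytest.approx(
            kd, rel=1e-12)

    def test_nonpositive_kd_rejected(self):
        with pytest.raises(ValueError):
            kd_to_dG(0.0, 300.0)

    def test_acceleration_identity(self):
        res = acceleration_ratio(1.0, 1.0)
        assert res.ratio == 1.0
        assert res.ratio_order == 1.0

    def test_event_time_and_ratio_orders_for_slow_unbinding(self):
        # 0.16 per minute -> event time ~375 s (order 10^2); against a 3 ns
        # simulation the acceleration is of order 10^11
        k_off = 0.16 / 60.0
        res = acceleration_ratio(k_off, 3e-9)
        assert res.event_time == pytest.approx(375.0)
        assert res.event_time_order == 100.0
        assert res.ratio_order == 1e11

    def test_order_of_magnitude_floor_convention(self):
        assert order_of_magnitude(375.0) == 100.0
        assert order_of_magnitude(0.002) == pytest.approx(1e-3)
        with pytest.raises(ValueError):
            order_of_magnitude(0.0)


class TestParameterRecovery:
    def test_three_state_chain_recovered(self):
        t_true = np.array([[0.90, 0.08, 0.02],
                           [0.10, 0.80, 0.10],
                           [0.02, 0.18, 0.80]])
        dtraj = sample_markov_chain(t_true, 100_000, seed=10)
        c = count_matrix([dtraj], lag=1)
        t_est, active = transition_matrix(c)
        assert len(active) == 3
        assert np.abs(t_est - t_true).max() < 0.02
        pi_true = stationary_distribution(t_true)
        pi_est = stationary_distribution(t_est)
        assert np.abs(pi_est - pi_true).max() < 0.01
        its_true = implied_timescales(t_true, 1, 1)[0]
        its_est = implied_timescales(t_est, 1, 1)[0]
        assert abs(its_est - its_true) / its_true < 0.05


@pytest.fixture(scope="module")
def well_samples():
    """Long equilibrium Langevin sampling of a 2 kBT double well with
    64 independent walkers started half in each basin."""
    temperature = 300.0
    system = DoubleWell1D(barrier=2 * KB * temperature, mass=1.0,
                          n_atoms=64)
    x0 = system.initial_coords()
    x0[32:] = system.a
    params = MDParams(dt=0.01, n_steps=50_000, save_interval=10,
                      temperature=temperature, friction=1.0, seed=14)
    v0 = mb_velocities(system.masses, temperature, 15, dim=1)
    xs, _ = propagate(system, x0, v0, params)
    xs = xs[100:]  # discard equilibration
    trajs = [xs[:, i, 0] for i in range(64)]
    return system, temperature, trajs


class TestPipelineOnDoubleWell:
    def test_pmf_matches_analytic_boltzmann_profile(self, well_samples):
        system, temperature, trajs = well_samples
        model = estimate_msm(trajs, k=25, lag=10, temperature=temperature,
                             seed=16)
        prof = free_energy_profile(model.pi, model.active_centers,
                                   temperature)
        ref = analytic_bin_profile(system, temperature, model)
        # shift-invariant comparison on populated bins
        dev = (prof.f - prof.f.mean()) - (ref - ref.mean())
        assert np.abs(dev).max() < 0.3 * KB * temperature

    def test_chapman_kolmogorov_two_state_populations(self, well_samples):
        system, temperature, trajs = well_samples
        m1 = estimate_msm(trajs, k=20, lag=5, temperature=temperature,
                          seed=17)
        dtrajs = m1.dtrajs
        c2 = count_matrix(dtrajs, lag=10, n_states=20)
        t2, active2 = transition_matrix(c2)
        # coarse-grain into the two basins and compare the probability of
        # staying in the left basin: T(lag)^2 vs the directly estimated
        # T(2 lag)
        left1 = np.array([m1.centers[s, 0] < 0 for s in m1.active])
        pi1 = stationary_distribution(m1.transition)
        p_stay_t1sq = _stay_probability(np.linalg.matrix_power(
            m1.transition, 2), pi1, left1)
        left2 = np.array([m1.centers[s, 0] < 0 for s in active2])
        pi2 = stationary_distribution(t2)
        p_stay_t2 = _stay_probability(t2, pi2, left2)
        assert p_stay_t1sq == pytest.approx(p_stay_t2, abs=0.05)


def _stay_probability(t, pi, member):
    start = pi * member
    start = start / start.sum()
    return float((start @ t)[member].sum())


def analytic_bin_profile(system, temperature, model):
    """-kT ln of the Boltzmann weight integrated over each Voronoi bin of
    the model's active centers (independent quadrature oracle)."""
    centers = np.sort(model.active_centers[:, 0])
    edges = np.concatenate([[-np.inf], (centers[1:] + centers[:-1]) / 2,
                            [np.inf]])
    grid = np.linspace(-2.5 * system.a, 2.5 * system.a, 20001)
    dens = system.boltzmann_density(grid, temperature)
    f = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (grid >= lo) & (grid < hi)
        f.append(np.trapezoid(dens[m], grid[m]))
    f = -KB * temperature * np.log(np.asarray(f))
    return f - f.min()


class TestDimerBindingPipeline:
    def test_cascade_msm_dG_matches_integral_oracle(self, tmp_path):
        """Full dissociation-cascade -> MSM -> volume-corrected dG on the
        LJ dimer agrees within 1 kBT with the same formula applied to the
        exact pair Boltzmann populations (1-D quadrature oracle).

        A 3 kBT well keeps the unbinding samplable; ten cascade trials
        provide the statistics for the 1-D MSM along the pair distance.
        """
        from pacsmd.config_io import config_from_dict, read_trajectory
        from pacsmd.dynamics import LJDimer
        from pacsmd.engine import run_trial
        from pacsmd.posttools import genfeature, load_feature_arrays

        temperature, eps, wall = 300.0, 7.5, 1.5
        mdconf = tmp_path / "md.toml"
        mdconf.write_text(
            '[system]\nname = "lj_dimer"\n'
            f"epsilon = {eps}\nwall_radius = {wall}\n"
            "[md]\ndt = 0.002\nn_steps = 800\nsave_interval = 10\n"
            f"temperature = {temperature}\nfriction = 2.0\n")
        rel_vectors, rs, feats = [], [], []
        for t in range(10):
            cfg = config_from_dict(dict(
                simulator="toy", type="dissociation", n_replica=10,
                max_cycle=15, threshold=wall * 0.95,
                selection1="index 0", selection2="index 1",
                mdconf=str(mdconf), trial=t + 1, seed=100 + t))
            run_trial(cfg, root=tmp_path)
            tdir = tmp_path / f"trial{t + 1:03d}"
            genfeature(tdir, "com_distance", selection1="index 0",
                       selection2="index 1")
            feats += load_feature_arrays(tdir / "features")
            for p in tdir.glob("cycle???/replica???/traj.npz"):
                for s in read_trajectory(p):
                    d = s.coords[1] - s.coords[0]
                    rel_vectors.append(d)
                    rs.append(np.linalg.norm(d))
        rel_vectors, rs = np.array(rel_vectors), np.array(rs)
        model = estimate_msm(feats, k=15, lag=10, temperature=temperature,
                             seed=1)
        prof = free_energy_profile(model.pi, model.active_centers,
                                   temperature)
        r_hi = rs.max()
        shell = rel_vectors[rs >= r_hi - 0.1 * (r_hi - rs.min())]
        res = standard_binding_dG(prof, shell, plateau_tol=KB * temperature)

        # oracle: identical formula on exact Boltzmann bin populations
        system = LJDimer(epsilon=eps, wall_radius=wall)
        centers = np.sort(model.active_centers[:, 0])
        edges = np.concatenate([[max(0.05, centers[0] - 0.05)],
                                (centers[1:] + centers[:-1]) / 2, [r_hi]])
        grid = np.linspace(edges[0], edges[-1], 40001)
        w = grid ** 2 * np.exp(-system.pair_potential(grid)
                               / (KB * temperature))
        pops = np.array([
            np.trapezoid(w[(grid >= lo) & (grid < hi)],
                         grid[(grid >= lo) & (grid < hi)])
            for lo, hi in zip(edges[:-1], edges[1:])])
        prof_exact = free_energy_profile(pops / pops.sum(), centers,
                                         temperature)
        res_exact = standard_binding_dG(prof_exact, shell, plateau_tol=KB * temperature)

        kbt_kcal = KB * temperature / 4.184
        assert abs(res.dG_kcal - res_exact.dG_kcal) < kbt_kcal
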