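"""Restraint scoring, the two docking engines, ensemble statistics, validation."""

import numpy as np
import pytest

from peldock.docking import (DockingEnsemble, EmptyEnsembleError, Restraint,
                             RigidBodyDocking, clash_check_pose,
                             cross_method_rmsd, decoy_dock, ensemble_stats,
                             gradient_dock, residual_table,
                             restraints_from_json, restraints_to_json,
                             score_pose, _Problem)
from peldock.geometry import RigidTransform, random_rotation
from peldock.labelling import (LabelSite, RotamerCloud, modal_distance,
                               predict_distance_distribution)
from peldock.structures import ca_rmsd, clash_count


def _point_cloud(site, xyz):
    return RotamerCloud(site, np.asarray([xyz], float), np.array([1.0]))


def _two_site_setup(d_model):
    """One restraint between two single-point clouds a distance d_model apart."""
    sf, sm = LabelSite("A", 1), LabelSite("B", 1)
    cf = {("A", 1): _point_cloud(sf, [0.0, 0.0, 0.0])}
    cm = {("B", 1): _point_cloud(sm, [d_model, 0.0, 0.0])}
    return sf, sm, cf, cm


class TestRestraint:
    def test_sanity_window_enforced(self):
        with pytest.raises(ValueError, match="sanity"):
            Restraint(LabelSite("A", 1), LabelSite("B", 1), 150.0, 2.0)
        with pytest.raises(ValueError, match="sigma"):
            Restraint(LabelSite("A", 1), LabelSite("B", 1), 30.0, 0.0)

    def test_json_round_trip(self, tmp_path):
        rs = [Restraint(LabelSite("A", 5), LabelSite("B", 9), 33.5, 2.5, 0.8)]
        path = tmp_path / "r.json"
        restraints_to_json(rs, path)
        back = restraints_from_json(path)
        assert back == rs


class TestScorePose:
    def test_exact_restraints_score_zero(self):
        sf, sm, cf, cm = _two_site_setup(30.0)
        r = Restraint(sf, sm, 30.0, 1.0)
        s = score_pose(RigidTransform.identity(), [r], cf, cm,
                       clash_penalty_per_pair=0.0)
        assert s == pytest.approx(0.0, abs=1e-9)

    def test_two_angstrom_violation_analytic(self):
        sf, sm, cf, cm = _two_site_setup(32.0)
        r = Restraint(sf, sm, 30.0, 1.0, 1.0)
        s = score_pose(RigidTransform.identity(), [r], cf, cm,
                       clash_penalty_per_pair=0.0)
        assert s == pytest.approx(4.0, abs=1e-9)

    def test_matches_term_by_term_recomputation(self, benchmark):
        """Arbitrary pose: score equals the definition recomputed directly."""
        fixed, mobile = benchmark.fixed, benchmark.mobile
        rng = np.random.default_rng(3)
        pose = RigidTransform(random_rotation(rng),
                              benchmark.true_pose.translation + rng.normal(size=3))
        s = score_pose(pose, benchmark.restraints, benchmark.clouds_fixed,
                       benchmark.clouds_mobile, clash_penalty_per_pair=7.0,
                       fixed_ca=fixed.ca_coords(), mobile_ca=mobile.ca_coords(),
                       mode="coarse")
        expected = 0.0
        for r in benchmark.restraints:
            c_f = benchmark.clouds_fixed[(r.site_fixed.chain, r.site_fixed.resnum)]
            c_m = benchmark.clouds_mobile[(r.site_mobile.chain, r.site_mobile.resnum)]
            d = np.linalg.norm(c_f.centroid() - pose.apply(c_m.centroid()))
            expected += r.weight * ((d - r.d_exp) / r.sigma) ** 2
        expected += 7.0 * clash_count(fixed.ca_coords(),
                                      pose.apply(mobile.ca_coords()), 4.0)
        assert s == pytest.approx(expected, rel=1e-9)

    def test_missing_cloud_raises(self):
        sf, sm, cf, cm = _two_site_setup(30.0)
        r = Restraint(sf, LabelSite("B", 99), 30.0, 1.0)
        with pytest.raises(KeyError, match="B:99"):
            score_pose(RigidTransform.identity(), [r], cf, cm)

    def test_frame_independence(self, benchmark, rng):
        """Score is invariant when both bodies and clouds move together."""
        fixed, mobile = benchmark.fixed, benchmark.mobile
        pose = benchmark.true_pose
        base = score_pose(pose, benchmark.restraints, benchmark.clouds_fixed,
                          benchmark.clouds_mobile,
                          fixed_ca=fixed.ca_coords(),
                          mobile_ca=mobile.ca_coords(), mode="coarse")
        g = RigidTransform(random_rotation(rng), rng.normal(scale=30, size=3))
        cf2 = {k: c.transformed(g) for k, c in benchmark.clouds_fixed.items()}
        moved = score_pose(g.compose(pose), benchmark.restraints, cf2,
                           benchmark.clouds_mobile,
                           fixed_ca=g.apply(fixed.ca_coords()),
                           mobile_ca=mobile.ca_coords(), mode="coarse")
        assert moved == pytest.approx(base, rel=1e-9)


class TestMeanDistances:
    def test_covariance_expansion_matches_exact_mean(self, benchmark):
        """Linear-averaged distances agree with the exact weighted mean."""
        from scipy.spatial.distance import cdist
        prob = _Problem(benchmark.restraints, benchmark.clouds_fixed,
                        benchmark.clouds_mobile,
                        benchmark.fixed.ca_coords(), benchmark.mobile.ca_coords())
        pose = benchmark.true_pose
        approx = prob.mean_distances(pose.rotation, pose.translation)
        for i, r in enumerate(benchmark.restraints):
            cf = benchmark.clouds_fixed[(r.site_fixed.chain, r.site_fixed.resnum)]
            cm = benchmark.clouds_mobile[(r.site_mobile.chain, r.site_mobile.resnum)]
            d = cdist(cf.positions, pose.apply(cm.positions))
            exact = float(np.outer(cf.weights, cm.weights).ravel() @ d.ravel())
            assert approx[i] == pytest.approx(exact, abs=0.05)

    def test_batch_agrees_with_single(self, benchmark, rng):
        prob = _Problem(benchmark.restraints, benchmark.clouds_fixed,
                        benchmark.clouds_mobile,
                        benchmark.fixed.ca_coords(), benchmark.mobile.ca_coords())
        Rs = np.stack([random_rotation(rng) for _ in range(4)])
        ts = rng.normal(scale=30, size=(4, 3))
        batch = prob.mean_distances_batch(Rs, ts)
        for i in range(4):
            assert np.allclose(batch[i], prob.mean_distances(Rs[i], ts[i]))


class TestEnsembleStats:
    def test_identical_poses_zero_spread(self, benchmark):
        pose = benchmark.true_pose
        ens = ensemble_stats([pose, pose, pose], benchmark.mobile)
        assert ens.internal_rmsd_pairwise == pytest.approx(0.0, abs=1e-9)
        assert ens.internal_rmsd_to_mean == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(ens.mean_pose.rotation, pose.rotation, atol=1e-9)
        assert ens.n_clusters == 1

    def test_known_rotation_displacement_analytic(self, benchmark):
        """Pairwise RMSD of two poses differing by a 10 degree rotation about
        an axis through the mobile centroid matches the closed form
        sqrt(mean |(R - I) x|^2) over centred CA coordinates."""
        from scipy.spatial.transform import Rotation
        mobile = benchmark.mobile
        ca = mobile.ca_coords()
        centre = ca.mean(axis=0)
        axis = np.array([0.0, 0.0, 1.0])
        R = Rotation.from_rotvec(np.deg2rad(10.0) * axis).as_matrix()
        # pose B = rotate about the centre after pose A (identity)
        a = RigidTransform.identity()
        b = RigidTransform(R, centre - R @ centre)
        ens = ensemble_stats([a, b], mobile)
        x = ca - centre
        expected = np.sqrt(np.mean(np.sum((x @ R.T - x) ** 2, axis=1)))
        assert ens.internal_rmsd_pairwise == pytest.approx(expected, rel=1e-9)

    def test_mean_of_duplicate_transform_is_itself(self, benchmark):
        t = benchmark.true_pose
        ens = ensemble_stats([t, t], benchmark.mobile)
        assert np.allclose(ens.mean_pose.rotation, t.rotation, atol=1e-12)
        assert np.allclose(ens.mean_pose.translation, t.translation, atol=1e-12)

    def test_empty_ensemble_rejected(self, benchmark):
        with pytest.raises(EmptyEnsembleError):
            ensemble_stats([], benchmark.mobile)

    def test_distinct_families_flagged_degenerate(self, benchmark, rng):
        near = benchmark.true_pose
        far = RigidTransform(random_rotation(rng),
                             near.translation + np.array([40.0, 0, 0]))
        with pytest.warns(UserWarning, match="degenerate"):
            ens = ensemble_stats([near, near, far], benchmark.mobile)
        assert ens.degenerate and ens.n_clusters == 2


class TestDecoyDock:
    def test_recovers_truth_on_noise_free_benchmark(self, benchmark):
        ens = decoy_dock(benchmark.restraints, benchmark.clouds_fixed,
                         benchmark.clouds_mobile, benchmark.fixed,
                         benchmark.mobile, n_decoys=20000, top_k=40, seed=5)
        posed_t = benchmark.mobile.transformed(benchmark.true_pose)
        best = ens.poses[int(np.argmin(ens.scores))]
        assert ca_rmsd(posed_t, benchmark.mobile.transformed(best)) < 2.0
        assert ens.engine == "decoy"

    def test_best_score_nonincreasing_with_more_decoys(self, small_benchmark):
        """Decoy pools are nested in seed, so a larger pool can only improve
        the best coarse score."""
        from peldock.docking import _Problem, _sample_poses
        b = small_benchmark
        prob = _Problem(b.restraints, b.clouds_fixed, b.clouds_mobile,
                        b.fixed.ca_coords(), b.mobile.ca_coords())
        centre = b.mobile.centroid()
        best = []
        pools = {}
        for n in (2000, 8000):
            Rs, ts = _sample_poses(prob, n, 2, centre)
            pools[n] = (Rs, ts)
            d = prob.centroid_distances_batch(Rs, ts)
            s = np.sum(prob.weight * ((d - prob.d_exp) / prob.sigma) ** 2, axis=1)
            best.append(s.min())
        assert np.array_equal(pools[2000][0], pools[8000][0][:2000])
        assert best[1] <= best[0]

    def test_underdetermined_restraints_warn_and_flag(self, small_benchmark):
        """Three restraints leave the pose under-determined: multiple pose
        families must be reported rather than silently averaged."""
        b = small_benchmark
        subset = b.restraints[:3]
        with pytest.warns(UserWarning):
            ens = decoy_dock(subset, b.clouds_fixed, b.clouds_mobile,
                             b.fixed, b.mobile, n_decoys=4000, top_k=30,
                             seed=4, clash_penalty=0.0)
        assert ens.n_clusters > 1
        assert ens.degenerate

    def test_n_decoys_must_cover_top_k(self, small_benchmark):
        b = small_benchmark
        with pytest.raises(ValueError):
            decoy_dock(b.restraints, b.clouds_fixed, b.clouds_mobile,
                       b.fixed, b.mobile, n_decoys=10, top_k=20)


class TestGradientDock:
    def test_majority_of_starts_reach_truth_basin(self, benchmark):
        ens = gradient_dock(benchmark.restraints, benchmark.clouds_fixed,
                            benchmark.clouds_mobile, benchmark.fixed,
                            benchmark.mobile, n_starts=40, seed=6)
        assert len(ens) >= 0.8 * 40
        assert ens.internal_rmsd_pairwise < 2.0
        assert ens.engine == "minimization"

    def test_violating_solutions_filtered(self, benchmark):
        """Tightening the acceptance width must not admit more solutions."""
        b = benchmark
        loose = gradient_dock(b.restraints, b.clouds_fixed, b.clouds_mobile,
                              b.fixed, b.mobile, n_starts=15, seed=3,
                              accept_n_sigma=2.0)
        tight = gradient_dock(b.restraints, b.clouds_fixed, b.clouds_mobile,
                              b.fixed, b.mobile, n_starts=15, seed=3,
                              accept_n_sigma=0.5)
        assert len(tight) <= len(loose)

    def test_impossible_restraints_raise_with_violations(self, small_benchmark):
        b = small_benchmark
        bad = [Restraint(r.site_fixed, r.site_mobile,
                         float(np.clip(r.d_exp + (15.0 if i % 2 else -15.0),
                                       10, 100)), 0.5)
               for i, r in enumerate(b.restraints)]
        with pytest.raises(EmptyEnsembleError) as exc:
            gradient_dock(bad, b.clouds_fixed, b.clouds_mobile,
                          b.fixed, b.mobile, n_starts=10, seed=1)
        assert len(exc.value.worst_violations) == len(bad)


class TestValidation:
    def test_cross_method_rmsd_of_identical_ensembles_zero(self, benchmark):
        ens = ensemble_stats([benchmark.true_pose], benchmark.mobile)
        assert cross_method_rmsd(ens, ens, benchmark.mobile) == 0.0

    def test_cross_method_rmsd_equals_direct_ca_rmsd(self, benchmark, rng):
        a = ensemble_stats([benchmark.true_pose], benchmark.mobile)
        other = RigidTransform(benchmark.true_pose.rotation,
                               benchmark.true_pose.translation + rng.normal(size=3))
        b = ensemble_stats([other], benchmark.mobile)
        direct = ca_rmsd(benchmark.mobile.transformed(a.mean_pose),
                         benchmark.mobile.transformed(b.mean_pose))
        assert cross_method_rmsd(a, b, benchmark.mobile) == pytest.approx(direct)

    def test_residual_table_truth_pose_small_residuals(self, benchmark):
        df = residual_table(benchmark.true_pose, benchmark.restraints,
                            benchmark.clouds_fixed, benchmark.clouds_mobile)
        body = df.iloc[:-1]
        assert len(body) == len(benchmark.restraints)
        assert np.abs(body["delta_A"]).max() <= 0.5
        assert df.iloc[-1]["pair"] == "mean|delta|"

    def test_residual_arithmetic(self):
        sf, sm, cf, cm = _two_site_setup(33.0)
        r = Restraint(sf, sm, 30.0, 1.0)
        df = residual_table(RigidTransform.identity(), [r], cf, cm)
        assert df.iloc[0]["delta_A"] == pytest.approx(3.0, abs=0.5)

    def test_residual_model_distances_match_prediction_oracle(self, benchmark):
        df = residual_table(benchmark.true_pose, benchmark.restraints,
                            benchmark.clouds_fixed, benchmark.clouds_mobile)
        for row, r in zip(df.itertuples(), benchmark.restraints):
            cf = benchmark.clouds_fixed[(r.site_fixed.chain, r.site_fixed.resnum)]
            cm = benchmark.clouds_mobile[
                (r.site_mobile.chain, r.site_mobile.resnum)].transformed(
                    benchmark.true_pose)
            expected = modal_distance(predict_distance_distribution(cf, cm))
            assert row.d_model_A == pytest.approx(expected, abs=1e-9)

    def test_clash_check_pose_far_and_overlaid(self, benchmark):
        far = RigidTransform(np.eye(3), np.array([300.0, 0.0, 0.0]))
        count, verdict = clash_check_pose(far, benchmark.mobile, benchmark.fixed)
        assert (count, verdict) == (0, "clear")
        overlaid = RigidTransform.identity()
        count, verdict = clash_check_pose(overlaid, benchmark.mobile,
                                          benchmark.fixed)
        assert count >= len(benchmark.mobile.ca_coords()) / 2
        assert verdict == "clashing"

    def test_clash_check_matches_brute_force(self, benchmark):
        pose = benchmark.true_pose
        count, _ = clash_check_pose(pose, benchmark.mobile, benchmark.fixed,
                                    cutoff=8.0)
        a = benchmark.fixed.ca_coords()
        b = pose.apply(benchmark.mobile.ca_coords())
        brute = sum(1 for x in a for y in b if np.linalg.norm(x - y) < 8.0)
        assert count == brute


class TestModelSurface:
    def test_fit_returns_results_with_residuals_and_summary(self, benchmark):
        model = RigidBodyDocking(benchmark.fixed, benchmark.mobile,
                                 benchmark.restraints,
                                 benchmark.clouds_fixed, benchmark.clouds_mobile)
        res = model.fit("decoy", seed=2, n_decoys=5000, top_k=15)
        assert res.n_accepted >= 1
        assert len(res.residuals) == len(benchmark.restraints) + 1
        text = res.summary()
        assert "decoy" in text and "internal RMSD" in text

    def test_save_writes_ensemble_artifacts(self, benchmark, tmp_path):
        model = RigidBodyDocking(benchmark.fixed, benchmark.mobile,
                                 benchmark.restraints,
                                 benchmark.clouds_fixed, benchmark.clouds_mobile)
        res = model.fit("minimization", seed=2, n_starts=10)
        out = tmp_path / "out"
        res.save(out)
        assert (out / "averaged_mobile.pdb").exists()
        assert (out / "ensemble.pdb").exists()
        assert (out / "residuals.csv").exists()
        assert (out / "ensemble.json").exists()
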