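import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from kinasedyn.errors import (
    DegenerateGeometryError,
    EmptySelectionError,
    EmptySeriesError,
    UnderdeterminedFitError,
)
from kinasedyn.geometry_metrics import (
    AngleDefinition,
    MetricSeries,
    boxplot_summary,
    centre_of_geometry,
    cog_distance,
    cog_distance_series,
    exclude_equilibration,
    interval_shift_validation,
    kabsch,
    pool_replicas,
    rmsd_series,
    rmsf_per_residue,
    segment_angle,
    segment_angle_series,
    shift_interval,
    superpose,
)
from kinasedyn.structures_io import SegmentSelection, Trajectory
from kinasedyn.synthetic_data import (
    ToyKinaseSpec,
    build_helix,
    make_hinged_trajectory,
    make_jitter_replicas,
)

from .conftest import TOY_ANGLE_DEFN, toy_points_frame

TOY_DEFN = AngleDefinition(**TOY_ANGLE_DEFN)


class TestCentreOfGeometry:
    def test_identity(self):
        np.testing.assert_allclose(centre_of_geometry([(1.0, 2.0, 3.0)]), [1, 2, 3])

    def test_midpoint(self):
        np.testing.assert_allclose(
            centre_of_geometry([(0, 0, 0), (2, 0, 0)]), [1, 0, 0]
        )

    def test_brute_force_mean(self):
        rng = np.random.default_rng(0)
        points = rng.normal(size=(50, 3))
        # independent oracle: plain Python summation
        oracle = [sum(p[k] for p in points) / len(points) for k in range(3)]
        np.testing.assert_allclose(centre_of_geometry(points), oracle, atol=1e-12)

    def test_empty_raises(self):
        with pytest.raises(EmptySelectionError):
            centre_of_geometry(np.empty((0, 3)))


def law_of_cosines_angle(cog_a, cog_v, cog_b):
    """Independent oracle: apex angle from the three cog-cog distances."""
    a = np.linalg.norm(np.subtract(cog_a, cog_v))
    b = np.linalg.norm(np.subtract(cog_b, cog_v))
    c = np.linalg.norm(np.subtract(cog_a, cog_b))
    cos_angle = (a**2 + b**2 - c**2) / (2 * a * b)
    return np.degrees(np.arccos(np.clip(cos_angle, -1, 1)))


class TestSegmentAngle:
    def test_orthogonal_rays(self):
        frame = toy_points_frame((1, 0, 0), (0, 0, 0), (0, 1, 0))
        assert segment_angle(frame, TOY_DEFN) == pytest.approx(90.0, abs=1e-9)

    def test_parallel_rays(self):
        frame = toy_points_frame((1, 0, 0), (0, 0, 0), (3, 0, 0))
        assert segment_angle(frame, TOY_DEFN) == pytest.approx(0.0, abs=1e-9)

    def test_law_of_cosines_oracle(self):
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(1000):
            cogs = rng.normal(scale=10, size=(3, 3))
            frame = toy_points_frame(*cogs, jitter_rng=rng)
            got = segment_angle(frame, TOY_DEFN)
            want = law_of_cosines_angle(*cogs)
            worst = max(worst, abs(got - want))
        assert worst < 1e-8

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        frame = toy_points_frame((5, 1, 0), (0, 0, 0), (2, 7, 3), jitter_rng=rng)
        reference = segment_angle(frame, TOY_DEFN)
        rotation = Rotation.random(random_state=11).as_matrix()
        shifted = frame.coordinates @ rotation.T + np.array([12.0, -5.0, 30.0])
        moved = Trajectory(frame.topology, shifted[None], [0.0]).frame(0)
        assert segment_angle(moved, TOY_DEFN) == pytest.approx(reference, abs=1e-8)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        frame = toy_points_frame((5, 1, 0), (0, 0, 0), (2, 7, 3), jitter_rng=rng)
        reference = segment_angle(frame, TOY_DEFN)
        # permute atoms within each 4-atom residue block
        perm = np.concatenate([rng.permutation(4) + 4 * b for b in range(3)])
        permuted_topo = tuple(frame.topology[i] for i in perm)
        permuted = Trajectory(
            permuted_topo, frame.coordinates[perm][None], [0.0]
        ).frame(0)
        assert segment_angle(permuted, TOY_DEFN) == pytest.approx(reference, abs=1e-10)

    def test_degenerate_raises(self):
        frame = toy_points_frame((0, 0, 0), (0, 0, 0), (1, 0, 0))
        with pytest.raises(DegenerateGeometryError):
            segment_angle(frame, TOY_DEFN)

    def test_identical_selections_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            AngleDefinition(
                SegmentSelection("A", 1, 1),
                SegmentSelection("A", 1, 1),
                SegmentSelection("A", 3, 3),
            )


class TestIntervalShift:
    def test_zero_shift_identity(self, hinged):
        traj, _ = hinged
        deviation = interval_shift_validation(traj, AngleDefinition(), 0)
        np.testing.assert_allclose(deviation, 0.0, atol=1e-12)

    def test_shift_interval_arithmetic(self):
        sel = SegmentSelection("A", 250, 264)
        assert shift_interval(sel, -5) == SegmentSelection("A", 250, 259)
        assert shift_interval(sel, 5) == SegmentSelection("A", 255, 264)

    def test_deviation_matches_recompute_oracle(self, hinged):
        traj, _ = hinged
        defn = AngleDefinition()
        for shift in (-5, 5):
            deviation = interval_shift_validation(traj, defn, shift)
            shifted_defn = AngleDefinition(
                shift_interval(defn.ray_a, shift), defn.vertex, defn.ray_b
            )
            oracle = (
                segment_angle_series(traj, shifted_defn).values
                - segment_angle_series(traj, defn).values
            )
            np.testing.assert_allclose(deviation, oracle, atol=1e-12)


class TestCogDistance:
    def test_same_selection_zero(self, hinged):
        traj, _ = hinged
        sel = SegmentSelection("A", 250, 264)
        assert cog_distance(traj.frame(0), sel, sel) == 0.0

    def test_pure_translation(self):
        atoms, coords = build_helix(5)
        atoms2, coords2 = build_helix(5, start_residue=50,
                                      start_serial=len(atoms) + 1)
        coords2 = coords + np.array([20.0, 0.0, 0.0])  # exact translated copy
        traj = Trajectory(atoms + atoms2, np.vstack([coords, coords2])[None], [0.0])
        d = cog_distance(
            traj.frame(0), SegmentSelection("A", 1, 5), SegmentSelection("A", 50, 54)
        )
        assert d == pytest.approx(2.0, abs=1e-12)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            cogs = rng.normal(scale=8, size=(3, 3))
            frame = toy_points_frame(*cogs, jitter_rng=rng)
            got = cog_distance(frame, SegmentSelection("A", 1, 1),
                               SegmentSelection("A", 3, 3))
            want = np.sqrt(sum((cogs[0][k] - cogs[2][k]) ** 2 for k in range(3))) / 10
            assert got == pytest.approx(want, abs=1e-10)

    def test_symmetry_and_triangle_inequality(self, static_dimer):
        traj, _ = static_dimer
        frame = traj.frame(0)
        sels = [
            SegmentSelection("A", 102, 126),
            SegmentSelection("A", 250, 264),
            SegmentSelection("A", 286, 302),
        ]
        d01 = cog_distance(frame, sels[0], sels[1])
        d10 = cog_distance(frame, sels[1], sels[0])
        assert d01 == d10
        d12 = cog_distance(frame, sels[1], sels[2])
        d02 = cog_distance(frame, sels[0], sels[2])
        assert d02 <= d01 + d12 + 1e-12


class TestSuperpose:
    def test_identity(self, hinged):
        traj, _ = hinged
        frame = traj.frame(0)
        sel = SegmentSelection("A", 139, 154)
        fitted, rotation, translation = superpose(frame, frame, sel)
        np.testing.assert_allclose(rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(fitted.coordinates, frame.coordinates, atol=1e-9)

    def test_rotation_recovery(self, hinged):
        traj, _ = hinged
        frame = traj.frame(0)
        rot90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = Trajectory(
            frame.topology, (frame.coordinates @ rot90.T)[None], [0.0]
        ).frame(0)
        sel = SegmentSelection("A", 139, 302)
        fitted, _, _ = superpose(moved, frame, sel)
        rmsd = np.sqrt(np.mean(np.sum((fitted.coordinates - frame.coordinates) ** 2, axis=1)))
        assert rmsd < 1e-6

    def test_kabsch_vs_scipy_oracle(self):
        rng = np.random.default_rng(21)
        reference = rng.normal(scale=5, size=(40, 3))
        true_rot = Rotation.random(random_state=5).as_matrix()
        noisy = reference @ true_rot.T + np.array([3.0, -2.0, 8.0])
        noisy += rng.normal(scale=0.2, size=noisy.shape)
        rotation, translation = kabsch(noisy, reference)
        fitted = noisy @ rotation.T + translation
        # independent oracle: scipy's own Kabsch solver
        oracle_rot, _ = Rotation.align_vectors(
            reference - reference.mean(axis=0), noisy - noisy.mean(axis=0)
        )
        oracle_fit = (noisy - noisy.mean(axis=0)) @ oracle_rot.as_matrix().T \
            + reference.mean(axis=0)
        ours = np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1)))
        oracle = np.sqrt(np.mean(np.sum((oracle_fit - reference) ** 2, axis=1)))
        assert ours == pytest.approx(oracle, abs=1e-9)

    def test_underdetermined_raises(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        with pytest.raises(UnderdeterminedFitError):
            kabsch(line, line)
        with pytest.raises(UnderdeterminedFitError):
            kabsch(line[:2], line[:2])


class TestRmsd:
    def test_static_trajectory_zero(self, helix_trajectory):
        traj = Trajectory(
            helix_trajectory.topology,
            np.repeat(helix_trajectory.coordinates, 5, axis=0),
            np.arange(5.0),
        )
        series = rmsd_series(traj, traj.frame(0), SegmentSelection("A", 1, 20, "ca"))
        np.testing.assert_allclose(series.values, 0.0, atol=1e-12)

    def test_translation_without_fit(self, helix_trajectory):
        offsets = np.array([0.0, 5.0, 10.0])
        coords = np.stack([
            helix_trajectory.coordinates[0] + np.array([off, 0, 0])
            for off in offsets
        ])
        traj = Trajectory(helix_trajectory.topology, coords, np.arange(3.0))
        series = rmsd_series(
            traj, traj.frame(0), SegmentSelection("A", 1, 20, "ca"), fit=False
        )
        np.testing.assert_allclose(series.values, offsets / 10.0, atol=1e-12)

    def test_fit_never_increases_rmsd(self, helix_trajectory):
        rng = np.random.default_rng(2)
        base = helix_trajectory.coordinates[0]
        frames = []
        for k in range(5):
            rotation = Rotation.random(random_state=k).as_matrix()
            frames.append(base @ rotation.T + rng.normal(scale=0.3, size=base.shape))
        traj = Trajectory(helix_trajectory.topology, np.stack(frames), np.arange(5.0))
        sel = SegmentSelection("A", 1, 20, "ca")
        fitted = rmsd_series(traj, traj.frame(0), sel, fit=True)
        raw = rmsd_series(traj, traj.frame(0), sel, fit=False)
        assert np.all(fitted.values <= raw.values + 1e-12)

    def test_fit_matches_kabsch_oracle(self, helix_trajectory):
        rng = np.random.default_rng(8)
        base = helix_trajectory.coordinates[0]
        rotation = Rotation.random(random_state=3).as_matrix()
        noisy = base @ rotation.T + rng.normal(scale=0.5, size=base.shape) + 7.0
        traj = Trajectory(helix_trajectory.topology, noisy[None], [0.0])
        sel = SegmentSelection("A", 1, 20, "backbone")
        series = rmsd_series(traj, helix_trajectory.frame(0), sel, fit=True)
        idx = np.arange(base.shape[0])
        rot, trans = kabsch(noisy, base)
        oracle = np.sqrt(np.mean(np.sum(((noisy @ rot.T + trans) - base) ** 2, axis=1))) / 10
        assert series.values[0] == pytest.approx(oracle, abs=1e-12)


class TestRmsf:
    def test_static_zero(self, helix_trajectory):
        traj = Trajectory(
            helix_trajectory.topology,
            np.repeat(helix_trajectory.coordinates, 4, axis=0),
            np.arange(4.0),
        )
        table = rmsf_per_residue([traj], SegmentSelection("A", 1, 20, "backbone"))
        np.testing.assert_allclose(table["rmsf_mean_nm"], 0.0, atol=1e-12)

    def test_isotropic_jitter_closed_form(self):
        sigma = 0.5
        replicas = make_jitter_replicas(sigma=sigma, n_replicas=1, n_frames=800, seed=4)
        table = rmsf_per_residue(replicas, SegmentSelection("A", 1, 125, "backbone"))
        expected = sigma * np.sqrt(3) / 10.0  # nm
        assert np.allclose(table["rmsf_mean_nm"], expected, rtol=0.05)

    def test_replica_aggregation_matches_oracle(self):
        replicas = make_jitter_replicas(sigma=0.4, n_replicas=5, n_frames=60, seed=6)
        sel = SegmentSelection("A", 1, 125, "backbone")
        table = rmsf_per_residue(replicas, sel)
        per_rep = np.vstack([
            rmsf_per_residue([rep], sel)["rmsf_mean_nm"].to_numpy()
            for rep in replicas
        ])
        np.testing.assert_allclose(table["rmsf_mean_nm"], per_rep.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(table["rmsf_sd_nm"], per_rep.std(axis=0), atol=1e-12)
        assert (table["rmsf_mean_nm"] >= 0).all()


class TestExcludeEquilibration:
    def test_paper_count(self):
        series = MetricSeries(np.arange(1000.0), "nm", times_ns=np.arange(1000.0))
        kept = exclude_equilibration(series, 250.0)
        assert len(kept) == 750
        assert kept.equilibration_excluded

    def test_zero_cutoff_identity(self, hinged):
        traj, _ = hinged
        kept = exclude_equilibration(traj, 0.0)
        assert kept.n_frames == traj.n_frames

    def test_boundary_keeps_frame_at_cutoff(self):
        series = MetricSeries(np.arange(10.0), "nm", times_ns=np.arange(10.0) * 2.0)
        kept = exclude_equilibration(series, 5.0)
        assert kept.times_ns[0] == 6.0  # first time >= 5 is 6
        kept2 = exclude_equilibration(series, 6.0)
        assert kept2.times_ns[0] == 6.0  # frame exactly at cutoff retained

    def test_all_excluded_raises(self):
        series = MetricSeries(np.arange(5.0), "nm", times_ns=np.arange(5.0))
        with pytest.raises(EmptySeriesError):
            exclude_equilibration(series, 100.0)


def sort_based_boxplot_oracle(values):
    """Independent oracle using sorted data and manual interpolation."""
    data = sorted(float(v) for v in values)
    n = len(data)

    def quantile(q):
        pos = q * (n - 1)
        lo = int(np.floor(pos))
        hi = int(np.ceil(pos))
        return data[lo] + (pos - lo) * (data[hi] - data[lo])

    q1, med, q3 = quantile(0.25), quantile(0.5), quantile(0.75)
    iqr = q3 - q1
    inside = [v for v in data if q1 - 1.5 * iqr <= v <= q3 + 1.5 * iqr]
    outliers = [v for v in data if v < min(inside) or v > max(inside)]
    return med, q1, q3, min(inside), max(inside), outliers


class TestBoxplotSummary:
    def test_constant_series(self):
        summary = boxplot_summary([4.2] * 10)
        assert summary.median == summary.q1 == summary.q3 == 4.2
        assert summary.outliers == ()

    def test_known_outlier(self):
        summary = boxplot_summary([1, 2, 3, 4, 100])
        med, q1, q3, wl, wh, outliers = sort_based_boxplot_oracle([1, 2, 3, 4, 100])
        assert summary.outliers == (100,)
        assert summary.median == med
        assert (summary.q1, summary.q3) == (q1, q3)
        assert (summary.whisker_low, summary.whisker_high) == (wl, wh)

    def test_pooled_equals_concatenated(self):
        rng = np.random.default_rng(5)
        a = MetricSeries(rng.normal(size=50), "degrees" if False else "nm")
        b = MetricSeries(rng.normal(size=70), "nm")
        pooled = pool_replicas([a, b])
        direct = np.concatenate([a.values, b.values])
        assert boxplot_summary(pooled) == boxplot_summary(direct)

    def test_empty_raises(self):
        with pytest.raises(EmptySeriesError):
            boxplot_summary([])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=200))
    def test_matches_sort_oracle(self, values):
        summary = boxplot_summary(values)
        med, q1, q3, wl, wh, outliers = sort_based_boxplot_oracle(values)
        assert summary.median == pytest.approx(med, rel=1e-12, abs=1e-9)
        assert summary.q1 == pytest.approx(q1, rel=1e-12, abs=1e-9)
        assert summary.q3 == pytest.approx(q3, rel=1e-12, abs=1e-9)
        assert summary.whisker_low == pytest.approx(wl, abs=1e-9)
        assert summary.whisker_high == pytest.approx(wh, abs=1e-9)
        assert list(summary.outliers) == sorted(outliers)
        assert summary.q1 <= summary.median <= summary.q3
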