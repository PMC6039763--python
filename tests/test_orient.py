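import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from membmode.orient import (ModeLabel, OrientationSeries, ReferencePose,
                             classify_bound, classify_mode, density_map,
                             orientation_series, superpose)
from membmode.traj import Domain, Selection, select

from helpers import classify_run, make_trajectory, toy_topology


def random_points(rng, n=10):
    return rng.uniform(-3, 3, (n, 3))


class TestSuperpose:
    def test_identity(self):
        x = random_points(np.random.default_rng(0))
        T, rmsd = superpose(x, x)
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(T.translation, 0, atol=1e-12)
        assert rmsd == pytest.approx(0, abs=1e-12)

    def test_half_turn_about_x_gives_rzz_minus_one(self):
        x = random_points(np.random.default_rng(1))
        R180 = Rotation.from_euler("x", 180, degrees=True).as_matrix()
        T, rmsd = superpose(x @ R180.T, x)
        assert T.rotation[2, 2] == pytest.approx(-1.0)
        assert rmsd == pytest.approx(0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_applied_random_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = random_points(rng)
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.uniform(-5, 5, 3)
        T, rmsd = superpose(x, x @ R.T + t)
        np.testing.assert_allclose(T.rotation, R, atol=1e-10)
        np.testing.assert_allclose(T.translation, t, atol=1e-10)
        assert rmsd < 1e-10

    def test_agrees_with_scipy_align_vectors(self):
        # independent oracle: scipy's own Kabsch implementation
        rng = np.random.default_rng(5)
        x = random_points(rng, 20)
        y = random_points(rng, 20)
        T, rmsd = superpose(x, y)
        rot, _ = Rotation.align_vectors(y - y.mean(0), x - x.mean(0))
        np.testing.assert_allclose(T.rotation, rot.as_matrix(), atol=1e-8)

    @settings(derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10 ** 6))
    def test_rotation_always_proper_orthogonal(self, seed):
        rng = np.random.default_rng(seed)
        T, _ = superpose(random_points(rng, 8), random_points(rng, 8))
        R = T.rotation
        np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-8)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-8)

    def test_weighted_fit_prefers_heavy_points(self):
        x = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        y = x + np.array([2.0, 0, 0])
        y[3] += 5.0  # outlier, nearly zero weight
        T, _ = superpose(x, y, weights=[1, 1, 1, 1e-9])
        np.testing.assert_allclose(T.translation, [2, 0, 0], atol=1e-4)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0.0]])
        with pytest.raises(ValueError, match="collinear"):
            superpose(line, line)


def _rigid_body_traj(theta_per_frame, dz=4.5, n_frames=20):
    """Protein plus one lipid bead; protein rotated about x by theta(t)
    and held at height dz above the lipid plane."""
    rng = np.random.default_rng(11)
    body = rng.uniform(-1, 1, (6, 3))
    body -= body.mean(axis=0)
    top = toy_topology(n_protein=6, lipid_species=["PC"])
    coords = []
    for i in range(n_frames):
        R = Rotation.from_euler("x", theta_per_frame * i).as_matrix()
        prot = body @ R.T + np.array([5.0, 5.0, dz])
        lip = np.array([[5.0, 5.0, 0.0]])
        coords.append(np.vstack([prot, lip]))
    return make_trajectory(top, coords, box=(10, 10, 30))


class TestOrientationSeries:
    def test_constant_pose_gives_constant_series(self):
        traj = _rigid_body_traj(0.0, dz=4.5)
        protein = Selection(indices=np.arange(6))
        membrane = Selection(indices=np.array([6]))
        ref = ReferencePose(traj.frames[0].coordinates[:6], protein)
        s = orientation_series(traj, protein, membrane, ref)
        np.testing.assert_allclose(s.frame["rzz"], 1.0, atol=1e-12)
        np.testing.assert_allclose(s.frame["dz"], 4.5, atol=1e-9)
        np.testing.assert_allclose(s.frame["d"], 4.5, atol=1e-9)

    def test_scripted_rotation_matches_cosine(self):
        theta = 0.1
        traj = _rigid_body_traj(theta)
        protein = Selection(indices=np.arange(6))
        membrane = Selection(indices=np.array([6]))
        ref = ReferencePose(traj.frames[0].coordinates[:6], protein)
        s = orientation_series(traj, protein, membrane, ref)
        expected = np.cos(theta * np.arange(traj.n_frames))
        np.testing.assert_allclose(s.frame["rzz"], expected, atol=1e-8)

    def test_dz_uses_minimum_image_along_z(self):
        traj = _rigid_body_traj(0.0, dz=28.0)  # box z = 30 -> image at 2
        protein = Selection(indices=np.arange(6))
        membrane = Selection(indices=np.array([6]))
        ref = ReferencePose(traj.frames[0].coordinates[:6], protein)
        s = orientation_series(traj, protein, membrane, ref)
        np.testing.assert_allclose(s.frame["dz"], 2.0, atol=1e-9)


def _series(dz_values):
    n = len(dz_values)
    return OrientationSeries(frame=pd.DataFrame({
        "time": np.arange(n, dtype=float), "rzz": np.zeros(n),
        "dz": np.asarray(dz_values, dtype=float),
        "d": np.asarray(dz_values, dtype=float)}))


class TestDensityMap:
    def test_point_mass_occupies_single_bin(self):
        s = _series([4.25] * 50)
        d = density_map(s, np.linspace(-1, 1, 41), np.linspace(0, 10, 101))
        assert d.rho.sum() == pytest.approx(1.0)
        assert d.rho.max() == pytest.approx(1.0)
        assert (d.deltaD == 1.0).sum() == 1

    def test_probability_conserved_and_max_ratio_one(self):
        rng = np.random.default_rng(8)
        s = _series(rng.uniform(0, 9, 500))
        s.frame["rzz"] = rng.uniform(-1, 1, 500)
        d = density_map(s, np.linspace(-1, 1, 21), np.linspace(0, 10, 21))
        assert d.rho.sum() == pytest.approx(1.0, abs=1e-9)
        assert d.deltaD.max() == pytest.approx(1.0)
        assert d.rho0 == pytest.approx(d.rho.max())

    def test_uniform_law_gives_flat_ratio_map(self):
        rng = np.random.default_rng(13)
        n = 10 ** 5
        s = _series(rng.uniform(0, 10, n))
        s.frame["rzz"] = rng.uniform(-1, 1, n)
        rzz_edges = np.linspace(-1, 1, 11)
        d_edges = np.linspace(0, 10, 11)
        d = density_map(s, rzz_edges, d_edges)
        n_bins = 100
        p = 1.0 / n_bins
        sigma = np.sqrt(p * (1 - p) / n) / p  # relative sampling error
        ratio = d.rho / p
        assert np.all(np.abs(ratio - 1.0) < 5 * sigma)

    def test_out_of_grid_observations_rejected(self):
        s = _series([50.0] * 10)
        with pytest.raises(ValueError, match="binned domain"):
            density_map(s, np.linspace(-1, 1, 5), np.linspace(0, 10, 5))


class TestClassifyBound:
    def test_never_close_gives_empty(self):
        assert classify_bound(_series([10.0] * 30), 5.0, 1) == []

    def test_constant_in_stable_band_spans_whole_run(self):
        # 4.5 nm sits inside the 4-5 nm stable-interaction band
        assert classify_bound(_series([4.5] * 40), 5.0, 10) == [(0, 40)]

    def test_dwell_filter_hand_enumerated(self):
        dz = [10.0] * 20 + [4.0] * 30 + [10.0] * 20
        assert classify_bound(_series(dz), 5.0, 20) == [(20, 50)]
        assert classify_bound(_series(dz), 5.0, 40) == []

    def test_intervals_disjoint_and_ordered(self):
        rng = np.random.default_rng(4)
        dz = rng.choice([3.0, 10.0], size=200)
        iv = classify_bound(_series(dz), 5.0, 2)
        for (a1, b1), (a2, b2) in zip(iv, iv[1:]):
            assert b1 < a2


class TestClassifyMode:
    def _fixture(self, clobe_near):
        domains = ([Domain.NLOBE.value] * 3 + [Domain.CLOBE.value] * 3)
        top = toy_topology(n_protein=6, protein_domains=domains,
                           lipid_species=["PIP2"] * 4)
        nz = 0.5
        cz = 0.5 if clobe_near else 3.0
        prot = np.array([[4.0, 5, nz], [4.5, 5, nz], [5.0, 5, nz],
                         [6.0, 5, cz], [6.5, 5, cz], [7.0, 5, cz]])
        lip = np.array([[4.0, 5, 0], [5.0, 5, 0], [6.0, 5, 0],
                        [7.0, 5, 0.0]])
        coords = [np.vstack([prot, lip])] * 12
        traj = make_trajectory(top, coords, box=(10, 10, 30))
        nlobe = select(top, domain=Domain.NLOBE)
        clobe = select(top, domain=Domain.CLOBE)
        heads = select(top, headgroup=True)
        return traj, nlobe, clobe, heads

    def test_nlobe_only_contact_is_mode1(self):
        traj, nlobe, clobe, heads = self._fixture(clobe_near=False)
        m = classify_mode(traj, nlobe, clobe, heads, [(0, 12)])
        assert all(l is ModeLabel.MODE1 for l in m.labels)
        assert m.dominant is ModeLabel.MODE1

    def test_both_lobes_contact_is_mode2(self):
        traj, nlobe, clobe, heads = self._fixture(clobe_near=True)
        m = classify_mode(traj, nlobe, clobe, heads, [(0, 12)])
        assert m.dominant is ModeLabel.MODE2

    def test_far_protein_is_unbound(self):
        traj, nlobe, clobe, heads = self._fixture(clobe_near=False)
        m = classify_mode(traj, nlobe, clobe, heads, [])
        assert all(l is ModeLabel.UNBOUND for l in m.labels)
        assert m.dominant is ModeLabel.UNBOUND


class TestOnGeneratorOutput:
    def test_bound_fixture_sits_in_stable_band(self, small_bound_run):
        """A bound synthetic kinase sits at 4-5 nm COM separation."""
        traj, gt = small_bound_run
        series, bound, _ = classify_run(traj)
        assert bound, "fixture failed to bind"
        dz = np.concatenate([
            series.frame["dz"].to_numpy()[a:b] for a, b in bound])
        assert 4.0 <= np.median(dz) <= 5.0
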