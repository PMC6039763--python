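import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from membmode import synth
from membmode.clusters import (LipidTimecourse, _merge_gaps, _unwrap_xy,
                               count_distribution_fit,
                               interacting_lipid_count, lateral_diffusion,
                               lipid_timecourse, residence_times)
from membmode.synth import SyntheticParams
from membmode.traj import Selection

from helpers import make_trajectory, toy_topology


def _multibead_lipid_topology():
    """One protein bead and one PIP2 lipid with three headgroup beads."""
    import numpy as np
    from membmode.traj import Topology
    names = ["BB", "PO4", "P1", "P2"]
    return Topology(
        particle_names=np.array(names, dtype=object),
        residue_ids=np.array([600, 1000, 1000, 1000]),
        residue_names=np.array(["KIN", "POP2", "POP2", "POP2"],
                               dtype=object),
        molecule_ids=np.array([0, 1, 1, 1]),
        domain_labels=np.array(["NLOBE", "LIPID", "LIPID", "LIPID"],
                               dtype=object),
        species=np.array(["PROTEIN", "PIP2", "PIP2", "PIP2"],
                         dtype=object),
        is_headgroup=np.array([False, True, True, True]),
    )


class TestInteractingCount:
    def test_no_lipid_in_range_gives_zeros(self):
        top = toy_topology(n_protein=1, lipid_species=["PIP2"] * 3)
        coords = [np.array([[5, 5, 9.0], [1, 1, 0], [2, 2, 0],
                            [3, 3, 0.0]])] * 5
        traj = make_trajectory(top, coords, box=(20, 20, 20))
        counts = interacting_lipid_count(traj, Selection(indices=[0]),
                                         "PIP2")
        assert np.all(counts == 0)

    def test_planted_nine_lipids_counted(self):
        rng = np.random.default_rng(17)
        top = toy_topology(n_protein=1, lipid_species=["PIP2"] * 12)
        near = np.array([5.0, 5.0, 5.0]) + rng.uniform(-0.4, 0.4, (9, 3))
        far = rng.uniform(0, 1.0, (3, 3))
        coords = [np.vstack([[[5, 5, 5.0]], near, far])]
        traj = make_trajectory(top, coords, box=(20, 20, 20))
        counts = interacting_lipid_count(traj, Selection(indices=[0]),
                                         "PIP2")
        assert counts[0] == 9

    def test_molecule_counts_once_despite_multiple_beads(self):
        top = _multibead_lipid_topology()
        coords = [np.array([[5, 5, 5.0], [5.2, 5, 5], [5.4, 5, 5],
                            [5.6, 5, 5.0]])]
        traj = make_trajectory(top, coords, box=(20, 20, 20))
        counts = interacting_lipid_count(traj, Selection(indices=[0]),
                                         "PIP2")
        assert counts[0] == 1

    def test_absent_species_rejected(self):
        top = toy_topology(n_protein=1, lipid_species=["PC"])
        coords = [np.zeros((2, 3)) + 1.0]
        traj = make_trajectory(top, coords, box=(10, 10, 10))
        with pytest.raises(ValueError, match="PIP3"):
            interacting_lipid_count(traj, Selection(indices=[0]), "PIP3")

    def test_column_sums_match_count_series(self, small_bound_run):
        traj, _ = small_bound_run
        from membmode.traj import Species, select
        protein = select(traj.topology, species=Species.PROTEIN)
        tc = lipid_timecourse(traj, protein, "PIP2")
        counts = interacting_lipid_count(traj, protein, "PIP2")
        np.testing.assert_array_equal(tc.counts(), counts)

    def test_count_monotone_in_cutoff_and_bounded(self, small_bound_run):
        traj, _ = small_bound_run
        from membmode.traj import Species, select
        protein = select(traj.topology, species=Species.PROTEIN)
        n_pip2 = len(np.unique(traj.topology.molecule_ids[
            traj.topology.species == "PIP2"]))
        c1 = interacting_lipid_count(traj, protein, "PIP2", cutoff=0.8)
        c2 = interacting_lipid_count(traj, protein, "PIP2", cutoff=1.2)
        assert np.all(c2 >= c1)
        assert c2.max() <= n_pip2


class TestGaussianFit:
    def test_constant_series(self):
        fit = count_distribution_fit([7] * 50)
        assert fit.mean == 7.0 and fit.sd == 0.0 and fit.n == 50

    def test_mean_equals_sample_mean_exactly(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 15, 200)
        fit = count_distribution_fit(x)
        assert fit.mean == pytest.approx(x.mean(), abs=1e-12)

    def test_recovers_planted_mean_within_three_se(self):
        rng = np.random.default_rng(99)
        x = np.rint(rng.normal(9.0, 2.0, 3000))
        fit = count_distribution_fit(x)
        se = 2.0 / np.sqrt(3000)
        assert abs(fit.mean - 9.0) < 3 * se + 0.5 / 3000  # rounding bias
        assert fit.sd == pytest.approx(2.0, rel=0.1)

    def test_bound_restriction(self):
        series = np.array([0, 0, 5, 5, 5, 0, 0])
        fit = count_distribution_fit(series, [(2, 5)])
        assert fit.mean == 5.0 and fit.n == 3

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            count_distribution_fit([4])


class TestResidence:
    def _tc(self, rows):
        mat = np.array(rows, dtype=bool)
        return LipidTimecourse(species="PIP2",
                               lipid_ids=np.arange(len(mat)),
                               matrix=mat, cutoff=0.8)

    def test_all_true_row_is_one_persistent_dwell(self):
        df = residence_times(self._tc([[1] * 100]), gap_tolerance=0)
        assert df.loc[0, "dwells"] == [100]
        assert df.loc[0, "label"] == "persistent"

    def test_gap_tolerance_hand_enumerated(self):
        row = [1, 1, 1, 0, 0, 1, 1]
        assert residence_times(self._tc([row]),
                               gap_tolerance=0).loc[0, "dwells"] == [3, 2]
        assert residence_times(self._tc([row]),
                               gap_tolerance=2).loc[0, "dwells"] == [7]

    def test_all_false_row(self):
        df = residence_times(self._tc([[0] * 10]), gap_tolerance=1)
        assert df.loc[0, "dwells"] == []
        assert df.loc[0, "label"] == "transient"

    @settings(derandomize=True, max_examples=50)
    @given(row=st.lists(st.booleans(), min_size=1, max_size=60))
    def test_dwell_total_equals_true_count_without_gap_merge(self, row):
        df = residence_times(self._tc([row]), gap_tolerance=0)
        assert sum(df.loc[0, "dwells"]) == sum(row)

    @settings(derandomize=True, max_examples=50)
    @given(row=st.lists(st.booleans(), min_size=1, max_size=60),
           gap=st.integers(0, 5))
    def test_merged_runs_are_disjoint_and_cover_true_entries(self, row,
                                                             gap):
        merged = _merge_gaps(np.array(row, dtype=bool), gap)
        for (a1, b1), (a2, b2) in zip(merged, merged[1:]):
            assert a2 - b1 > gap
        covered = set()
        for a, b in merged:
            covered.update(range(a, b))
        assert {i for i, v in enumerate(row) if v} <= covered


class TestDiffusion:
    def test_immobile_lipids_have_zero_d(self):
        p = SyntheticParams(seed=1, n_lipids=40, n_steps=200,
                            save_every=2,
                            D_species={s: 0.0 for s in
                                       ("PC", "PS", "PIP2", "PIP3")})
        traj, _ = synth.simulate_membrane_only(p)
        res = lateral_diffusion(traj, "PC")
        assert res.D["PC"] == pytest.approx(0.0, abs=1e-12)
        assert res.msd_curves["PC"]["msd_nm2"].iloc[0] == 0.0

    def test_recovers_planted_d_within_ten_percent(self):
        ratios = {"PC": [], "PIP2": []}
        for seed in (1, 2, 3):
            p = SyntheticParams(
                seed=seed, n_lipids=500, n_steps=1000, save_every=1,
                composition={"PC": 0.5, "PS": 0.0, "PIP2": 0.5,
                             "PIP3": 0.0},
                D_species={"PC": 0.06, "PS": 0.05, "PIP2": 0.02,
                           "PIP3": 0.05})
            traj, gt = synth.simulate_membrane_only(p)
            res = lateral_diffusion(traj, ["PC", "PIP2"])
            ratios["PC"].append(res.D["PC"] / 0.06)
            ratios["PIP2"].append(res.D["PIP2"] / 0.02)
        for sp, r in ratios.items():
            assert abs(np.mean(r) - 1.0) < 0.10

    def test_unwrapping_matches_ground_truth(self):
        p = SyntheticParams(seed=4, n_lipids=50, n_steps=400, save_every=4)
        traj, gt = synth.simulate_membrane_only(p)
        heads = np.nonzero(traj.topology.is_headgroup)[0]
        pos = traj.coordinates(heads)[:, :, :2]
        unwrapped = _unwrap_xy(pos, traj.frames[0].box[:2])
        # displacement from the first frame must match the no-wrap truth
        truth = gt.unwrapped_xy - gt.unwrapped_xy[0]
        np.testing.assert_allclose(unwrapped - unwrapped[0], truth,
                                   atol=1e-9)

    def test_nonuniform_timestep_rejected(self):
        top = toy_topology(n_protein=0, lipid_species=["PC"])
        frames = []
        from membmode.traj import Frame, Trajectory
        for t in (0.0, 1.0, 3.0):
            frames.append(Frame(coordinates=np.ones((1, 3)),
                                box=[10] * 3, time=t))
        traj = Trajectory(topology=top, frames=frames)
        with pytest.raises(ValueError, match="constant time step"):
            lateral_diffusion(traj, "PC")

    def test_pip2_slower_than_pc_under_attraction(self, tether_pairs):
        """Planted equal free diffusivities; protein attraction slows
        the PIP2 pool relative to PC."""
        d_pc, d_pip2 = [], []
        for _, (traj, gt) in tether_pairs:
            res = lateral_diffusion(traj, ["PC", "PIP2"])
            d_pc.append(res.D["PC"])
            d_pip2.append(res.D["PIP2"])
        assert np.mean(d_pip2) < np.mean(d_pc)
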