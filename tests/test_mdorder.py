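"""Smol order parameters, hydrogen-bond counting and the synthetic ensembles."""

import math

import numpy as np
import pytest

from memepr.mdframes import TrajectoryFrames
from memepr.mdorder import (
    ChainTopology,
    HBondCriteria,
    MdOrderError,
    count_hbonds,
    phosphate_z_band,
    resident_mask,
    smol_profile,
    synth_trajectory,
)


def brute_force_smol(frames, names, axis=2):
    """Per-molecule, per-frame loop reference for Smol."""
    idx = frames.atom_index()
    mols = sorted(set(int(m) for m in frames.mol_ids))
    sums = np.zeros(len(names) - 2)
    count = 0
    for f in range(frames.n_frames):
        for mol in mols:
            for k in range(1, len(names) - 1):
                v = (
                    frames.coords[f, idx[(mol, names[k + 1])]]
                    - frames.coords[f, idx[(mol, names[k - 1])]]
                )
                sums[k - 1] += (v[axis] / np.linalg.norm(v)) ** 2
        count += 1
    mean = sums / (count * len(mols))
    return 0.5 * (3.0 * mean - 1.0)


def brute_force_hbonds(coords, box, donors, acceptors, criteria):
    """All-pairs O(N^2) reference for the geometric hydrogen-bond count."""
    cos_cut = math.cos(math.radians(criteria.angle_cutoff_deg))
    count = 0
    for d, h in donors:
        for a in acceptors:
            if a == d or a == h:
                continue
            da = coords[a] - coords[d]
            dh = coords[h] - coords[d]
            if box is not None:
                da = da - box * np.round(da / box)
                dh = dh - box * np.round(dh / box)
            r = np.linalg.norm(da)
            if r == 0 or r > criteria.distance_cutoff:
                continue
            if np.dot(dh, da) / (np.linalg.norm(dh) * r) >= cos_cut:
                count += 1
    return count


def chain_frames(vectors, n_carbons):
    """One molecule whose segmental vectors are all equal to ``vectors``."""
    pos = np.zeros((n_carbons, 3))
    pos[1] = [0.3, 0.3, 0.5]
    for n in range(1, n_carbons - 1):
        pos[n + 1] = pos[n - 1] + vectors
    return TrajectoryFrames(
        mol_ids=[1] * n_carbons,
        resnames=["CHN"] * n_carbons,
        atom_names=[f"C{k + 1}" for k in range(n_carbons)],
        coords=np.repeat(pos[None, :, :], 2, axis=0),  # 2 frames for block stats
    )


class TestSmol:
    def test_parallel_vectors_give_one(self):
        frames = chain_frames(np.array([0.0, 0.0, 2.5]), 6)
        topo = ChainTopology(chains={"c": [f"C{k + 1}" for k in range(6)]})
        profile = smol_profile(frames, topo, n_blocks=2)
        np.testing.assert_allclose(profile.chains["c"]["smol"], 1.0, atol=1e-12)

    def test_in_plane_vectors_give_minus_half(self):
        frames = chain_frames(np.array([2.5, 0.0, 0.0]), 6)
        topo = ChainTopology(chains={"c": [f"C{k + 1}" for k in range(6)]})
        profile = smol_profile(frames, topo, n_blocks=2)
        np.testing.assert_allclose(profile.chains["c"]["smol"], -0.5, atol=1e-12)

    def test_matches_brute_force_reference(self):
        frames = synth_trajectory([0.4, 0.6, 0.8], n_molecules=5, n_frames=10, seed=2)
        names = [f"C{k + 1}" for k in range(5)]
        topo = ChainTopology(chains={"sn1": names})
        profile = smol_profile(frames, topo, n_blocks=2)
        np.testing.assert_allclose(
            profile.chains["sn1"]["smol"], brute_force_smol(frames, names), atol=1e-12
        )

    def test_isotropic_ensemble_is_disordered(self):
        frames = synth_trajectory([1.0 / 3.0], n_molecules=500, n_frames=100, seed=5)
        topo = ChainTopology(chains={"sn1": ["C1", "C2", "C3"]})
        profile = smol_profile(frames, topo, n_blocks=5)
        assert abs(profile.chains["sn1"]["smol"][0]) < 0.01

    def test_bounds_never_violated(self):
        for seed in range(4):
            targets = np.random.default_rng(seed).uniform(0, 1, 3)
            frames = synth_trajectory(list(targets), n_molecules=20, n_frames=14, seed=seed)
            topo = ChainTopology(chains={"sn1": [f"C{k + 1}" for k in range(5)]})
            smol = smol_profile(frames, topo, n_blocks=2).chains["sn1"]["smol"]
            assert np.all(smol >= -0.5 - 1e-12) and np.all(smol <= 1.0 + 1e-12)

    def test_block_error_shrinks_with_samples(self):
        """On stationary data the block error scales roughly like 1/sqrt(frames)."""
        small = synth_trajectory([0.5], n_molecules=50, n_frames=70, seed=8)
        large = synth_trajectory([0.5], n_molecules=50, n_frames=700, seed=8)
        topo = ChainTopology(chains={"sn1": ["C1", "C2", "C3"]})
        err_small = smol_profile(small, topo).chains["sn1"]["block_error"][0]
        err_large = smol_profile(large, topo).chains["sn1"]["block_error"][0]
        assert err_large < err_small

    def test_double_bond_carbons_are_flagged_but_values_match_plain(self):
        """For adjacent sp² pairs the substituted vectors equal the plain ones."""
        frames = synth_trajectory([0.4, 0.6, 0.8], n_molecules=5, n_frames=6, seed=1)
        names = [f"C{k + 1}" for k in range(5)]
        plain = smol_profile(
            frames, ChainTopology(chains={"sn1": names}), n_blocks=2
        )
        marked = smol_profile(
            frames,
            ChainTopology(chains={"sn1": names}, double_bond_pairs={"sn1": [(2, 3)]}),
            n_blocks=2,
        )
        np.testing.assert_allclose(
            plain.chains["sn1"]["smol"], marked.chains["sn1"]["smol"], atol=1e-12
        )
        assert marked.chains["sn1"]["double_bond_carbons"] == {2, 3}
        assert plain.chains["sn1"]["double_bond_carbons"] == set()

    def test_short_chain_rejected_naming_chain(self):
        with pytest.raises(MdOrderError, match="sn9"):
            ChainTopology(chains={"sn9": ["C1", "C2"]})

    def test_non_adjacent_double_bond_pair_rejected(self):
        with pytest.raises(MdOrderError, match="adjacent"):
            ChainTopology(chains={"c": ["C1", "C2", "C3", "C4"]},
                          double_bond_pairs={"c": [(0, 2)]})

    def test_too_few_frames_for_blocks_rejected(self):
        frames = synth_trajectory([0.5], n_molecules=3, n_frames=3, seed=0)
        topo = ChainTopology(chains={"sn1": ["C1", "C2", "C3"]})
        with pytest.raises(MdOrderError, match="blocks"):
            smol_profile(frames, topo, n_blocks=7)


class TestHBonds:
    def pair_frame(self, angle_deg, dist=2.8):
        a = math.radians(angle_deg)
        coords = np.array([[[0, 0, 0], [math.cos(a), math.sin(a), 0.0], [dist, 0, 0]]])
        return TrajectoryFrames(
            mol_ids=[1, 1, 2],
            resnames=["W", "W", "W"],
            atom_names=["OD", "HD", "OA"],
            coords=coords,
        )

    def test_hand_geometry_cases(self):
        criteria = HBondCriteria(3.5, 30.0)
        near = count_hbonds(self.pair_frame(10.0), criteria, [(0, 1)], {"w": [2]})
        far = count_hbonds(self.pair_frame(60.0), criteria, [(0, 1)], {"w": [2]})
        assert near.per_frame[0, 0] == 1
        assert far.per_frame[0, 0] == 0

    def test_distance_criterion(self):
        criteria = HBondCriteria(3.5, 30.0)
        result = count_hbonds(
            self.pair_frame(10.0, dist=4.2), criteria, [(0, 1)], {"w": [2]}
        )
        assert result.per_frame[0, 0] == 0

    def test_matches_all_pairs_reference(self):
        criteria = HBondCriteria(3.5, 30.0)
        rng = np.random.default_rng(0)
        for trial in range(10):
            n = 200
            box = np.array([18.0, 18.0, 18.0])
            coords = rng.uniform(0, 18, (1, n, 3))
            donors = [(i, i + 1) for i in range(0, 60, 2)]
            acceptors = list(range(100, 200))
            frames = TrajectoryFrames(
                mol_ids=np.arange(n) // 2,
                resnames=np.array(["X"] * n, dtype=object),
                atom_names=np.array([f"A{i}" for i in range(n)], dtype=object),
                coords=coords,
                box=box[None, :],
            )
            fast = count_hbonds(frames, criteria, donors, {"c": acceptors})
            slow = brute_force_hbonds(coords[0], box, donors, acceptors, criteria)
            assert fast.per_frame[0, 0] == slow

    def test_empty_sets_rejected(self):
        frames = self.pair_frame(10.0)
        with pytest.raises(MdOrderError, match="donor"):
            count_hbonds(frames, HBondCriteria(), [], {"w": [2]})
        with pytest.raises(MdOrderError, match="acceptor"):
            count_hbonds(frames, HBondCriteria(), [(0, 1)], {})

    def test_invalid_criteria_rejected(self):
        with pytest.raises(MdOrderError):
            HBondCriteria(distance_cutoff=-1.0)
        with pytest.raises(MdOrderError):
            HBondCriteria(angle_cutoff_deg=120.0)

    def test_resident_filter_excludes_expelled_molecule(self):
        # two "retinoid" molecules: one inside the membrane slab, one in water
        coords = np.zeros((1, 8, 3))
        coords[0, 0:2] = [[0, 0, -15.0], [1, 0, -15.0]]  # lower phosphates
        coords[0, 2:4] = [[0, 1, 15.0], [1, 1, 15.0]]  # upper phosphates
        coords[0, 4:6] = [[3, 3, 0.0], [3.96, 3.28, 0.0]]  # resident donor+H
        coords[0, 6:8] = [[6, 6, 40.0], [6.96, 6.28, 40.0]]  # expelled donor+H
        frames = TrajectoryFrames(
            mol_ids=[1, 1, 2, 2, 3, 3, 4, 4],
            resnames=["POPC"] * 4 + ["RET"] * 4,
            atom_names=["P1", "P2", "P3", "P4", "O1", "H1", "O2", "H2"],
            coords=coords,
        )
        band = phosphate_z_band(frames, [0, 1, 2, 3], margin=5.0)
        np.testing.assert_allclose(band, [[-20.0, 20.0]])
        mask = resident_mask(frames, [3, 4], band)
        np.testing.assert_array_equal(mask, [[True, False]])
        # acceptor within reach of both donors' positions in z=0 plane
        acceptors = {"w": [2]}
        coords[0, 2] = [3.5, 3.0, 2.0]
        donors = [(4, 5), (6, 7)]
        donor_mask = mask[:, [0, 1]]
        res = count_hbonds(
            frames, HBondCriteria(5.0, 90.0), donors, acceptors,
            donor_frame_mask=donor_mask,
        )
        assert res.per_frame[0, 0] == 1


class TestSynthTrajectory:
    def test_target_one_is_exact(self):
        frames = synth_trajectory([1.0], n_molecules=10, n_frames=5, seed=0)
        topo = ChainTopology(chains={"sn1": ["C1", "C2", "C3"]})
        smol = smol_profile(frames, topo, n_blocks=2).chains["sn1"]["smol"]
        np.testing.assert_allclose(smol, 1.0, atol=1e-12)

    def test_prescribed_cos2_recovered(self):
        frames = synth_trajectory([0.6], n_molecules=500, n_frames=200, seed=12)
        topo = ChainTopology(chains={"sn1": ["C1", "C2", "C3"]})
        smol = smol_profile(frames, topo).chains["sn1"]["smol"][0]
        assert smol == pytest.approx(0.40, abs=0.02)

    def test_determinism_under_seed(self):
        a = synth_trajectory([0.5], n_molecules=6, n_frames=4, seed=9)
        b = synth_trajectory([0.5], n_molecules=6, n_frames=4, seed=9)
        c = synth_trajectory([0.5], n_molecules=6, n_frames=4, seed=10)
        np.testing.assert_array_equal(a.coords, b.coords)
        assert not np.array_equal(a.coords, c.coords)

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_infeasible_target_rejected(self, bad):
        with pytest.raises(MdOrderError, match="target"):
            synth_trajectory([bad], n_molecules=2, n_frames=2, seed=0)
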