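"""Commute times, threshold calibration, contacts/H-bonds and pathway growth."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import allocomm as ac
from allocomm.communication import CommuteTimeMatrix, ContactMap
from allocomm.exceptions import CalibrationError, DegenerateEnsembleError

from conftest import ensemble_from_ca, oracle_paths, random_instance


class TestCommuteTimes:
    def test_rigid_ensemble_all_zero(self):
        ca = np.tile(np.random.default_rng(0).uniform(-5, 5, (1, 6, 3)), (4, 1, 1))
        ct = ac.compute_commute_times(ensemble_from_ca(ca))
        np.testing.assert_allclose(ct.ct, 0.0, atol=1e-12)

    def test_alternating_distance_variance_one(self):
        # distance alternates 9 / 11 A -> population variance 1.0
        ca = np.zeros((10, 2, 3))
        ca[::2, 1, 0] = 9.0
        ca[1::2, 1, 0] = 11.0
        ct = ac.compute_commute_times(ensemble_from_ca(ca))
        assert ct.ct[0, 1] == pytest.approx(1.0)

    def test_matches_two_pass_oracle(self, rng):
        ca = rng.uniform(-10, 10, (50, 10, 3))
        ens = ensemble_from_ca(ca)
        ct = ac.compute_commute_times(ens).ct
        for i in range(10):
            for j in range(i + 1, 10):
                d = np.linalg.norm(ca[:, i] - ca[:, j], axis=1)
                mean = d.sum() / 50
                var = ((d - mean) ** 2).sum() / 50
                assert ct[i, j] == pytest.approx(var, rel=1e-10)

    def test_single_frame_degenerate(self, rng):
        with pytest.raises(DegenerateEnsembleError):
            ac.compute_commute_times(ensemble_from_ca(rng.normal(size=(1, 4, 3))))

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        ca = rng.uniform(-5, 5, (8, 6, 3))
        perm = rng.permutation(6)
        ct = ac.compute_commute_times(ensemble_from_ca(ca)).ct
        ct_p = ac.compute_commute_times(ensemble_from_ca(ca[:, perm, :])).ct
        np.testing.assert_allclose(ct_p, ct[np.ix_(perm, perm)], atol=1e-12)


class TestThresholdCalibration:
    def test_constructed_twenty_percent_row(self):
        n = 11
        ct = np.full((n, n), 2.0)
        np.fill_diagonal(ct, 0.0)
        # residue 0: exactly 2 of its 10 pairs (20%) at 0.05, the rest >= 1
        for j in (3, 7):
            ct[0, j] = ct[j, 0] = 0.05
        ctm = CommuteTimeMatrix(ct=ct, n_frames=10, seq_ids=np.arange(1, n + 1))
        eps = ac.calibrate_threshold(ctm, target_fraction=0.20)
        assert eps == pytest.approx(0.05)
        # exhaustive-scan oracle: smallest candidate value reaching the target
        vals = sorted(set(ct[np.triu_indices(n, 1)]))
        best = next(
            v for v in vals
            if max(((ct[i] <= v).sum() - 1) / (n - 1) for i in range(n)) >= 0.20
        )
        assert eps == pytest.approx(best)

    def test_target_one_covers_best_connected_row(self, rng):
        # at target 1.0 the best-connected residue must reach *all* others,
        # so epsilon is the smallest row maximum
        ca = rng.uniform(-5, 5, (20, 7, 3))
        ctm = ac.compute_commute_times(ensemble_from_ca(ca))
        eps = ac.calibrate_threshold(ctm, target_fraction=1.0)
        off = ctm.ct + np.where(np.eye(7, dtype=bool), -np.inf, 0.0)
        assert eps == pytest.approx(off.max(axis=1).min())
        assert ctm.fast_fractions().max() == 1.0

    def test_rigid_matrix_uncalibratable(self):
        ctm = CommuteTimeMatrix(
            ct=np.zeros((5, 5)), n_frames=10, seq_ids=np.arange(1, 6)
        )
        with pytest.raises(CalibrationError):
            ac.calibrate_threshold(ctm)


class TestHbonds:
    def _pair_ensemble(self, dist):
        ref = ac.make_toy_structure(6, "extended")
        coords = np.repeat(ref.coords, 3, axis=0)
        don = ref.residues[0]
        acc = ref.residues[4]
        d_idx = don.atoms[don.atom_names.index("ND")]
        a_idx = acc.atoms[acc.atom_names.index("OA")]
        coords[:, a_idx] = coords[:, d_idx] + np.array([dist, 0.0, 0.0])
        return ac.ConformationalEnsemble(coords=coords, residues=ref.residues)

    def test_pair_below_cutoff_full_occupancy(self):
        tab = ac.detect_hbonds(self._pair_ensemble(3.4))
        row = tab[(tab.donor_res == 1) & (tab.acceptor_res == 5)
                  & (tab.donor_atom == 'ND') & (tab.acceptor_atom == 'OA')]
        assert row.occupancy.item() == pytest.approx(1.0)

    def test_pair_above_cutoff_absent(self):
        tab = ac.detect_hbonds(self._pair_ensemble(3.6))
        assert tab[(tab.donor_res == 1) & (tab.acceptor_res == 5)
                   & (tab.donor_atom == 'ND') & (tab.acceptor_atom == 'OA')].empty

    def test_no_polar_atoms_gives_empty_table(self, rng):
        ens = ensemble_from_ca(rng.normal(size=(3, 5, 3)))
        assert ac.detect_hbonds(ens).empty


class TestContacts:
    def test_forty_percent_not_persistent(self):
        ref = ac.make_toy_structure(10, "extended")
        ens = ac.plant_contacts(ref, [(0, 5)], occupancy=0.4, n_frames=50, seed=0)
        cmap = ac.detect_contacts(ens)
        assert cmap.occupancy[0, 5] == pytest.approx(0.4)
        assert not cmap.persistent[0, 5]

    def test_permanent_close_contact(self):
        ref = ac.make_toy_structure(10, "extended")
        coords = np.repeat(ref.coords, 4, axis=0)
        # drop residue 7's Ca within 3.0 A of residue 2's Ca
        r2, r7 = ref.residues[2], ref.residues[7]
        shift = coords[0, r2.ca_atom] + np.array([3.0, 0, 0]) - coords[0, r7.ca_atom]
        coords[:, list(r7.atoms), :] += shift
        ens = ac.ConformationalEnsemble(coords=coords, residues=ref.residues)
        cmap = ac.detect_contacts(ens)
        assert cmap.occupancy[2, 7] == pytest.approx(1.0)
        assert cmap.persistent[2, 7]

    def test_occupancy_matches_bruteforce(self, rng):
        ref = ac.make_toy_structure(6, "extended")
        d = ac.PlantedDesign(n_residues=6, background_sigma2=1.5, seed=13)
        ens = ac.sample_ensemble(d, ref, 30)
        cmap = ac.detect_contacts(ens, heavy_atom_cutoff=4.0)
        n = ens.n_residues
        brute = np.zeros((n, n))
        for f in range(30):
            for a in range(n):
                for b in range(n):
                    if a == b:
                        continue
                    da = ens.coords[f, list(ens.residues[a].heavy_atoms)]
                    db = ens.coords[f, list(ens.residues[b].heavy_atoms)]
                    dmin = np.linalg.norm(da[:, None] - db[None, :], axis=2).min()
                    brute[a, b] += dmin <= 4.0
        np.testing.assert_allclose(cmap.occupancy, brute / 30, atol=1e-12)

    def test_ca_only_fallback(self, caplog):
        ca = np.tile(np.arange(6)[None, :, None] * np.array([5.0, 0, 0]), (4, 1, 1))
        cmap = ac.detect_contacts(ensemble_from_ca(ca))
        assert cmap.criteria["mode"] == "ca_fallback"
        assert cmap.persistent[0, 2] is not None
        # 5 A spacing: |i-j| == 1 within 7 A but sequence-adjacent, excluded
        assert not cmap.persistent[0, 1]


class TestNeighbors:
    def test_contact_free_residue_has_none(self, rng):
        ctm, cmap = random_instance(rng, 8)
        cmap.persistent[3, :] = False
        cmap.persistent[:, 3] = False
        assert ac.neighbors(3, ctm, cmap) == []

    def test_sequence_adjacent_always_excluded(self):
        n = 6
        ct = np.zeros((n, n)) + 0.01
        np.fill_diagonal(ct, 0.0)
        occ = np.ones((n, n))
        seq = np.arange(1, n + 1)
        cmap = ContactMap(occupancy=occ, persistent=occ >= 0.5, seq_ids=seq)
        ctm = CommuteTimeMatrix(ct=ct, n_frames=10, seq_ids=seq, epsilon=1.0)
        nbrs = ac.neighbors(2, ctm, cmap)
        assert 1 not in nbrs and 3 not in nbrs and 2 not in nbrs
        assert set(nbrs) == {0, 4, 5}

    def test_equals_three_criteria_intersection(self, rng):
        ctm, cmap = random_instance(rng, 6)
        for i in range(6):
            expected = {
                j for j in range(6)
                if j != i
                and abs(ctm.seq_ids[i] - ctm.seq_ids[j]) >= 2
                and cmap.persistent[i, j]
                and ctm.ct[i, j] <= ctm.epsilon
            }
            assert set(ac.neighbors(i, ctm, cmap)) == expected


class TestGrowPathways:
    def test_isolated_start_yields_nothing(self, rng):
        ctm, cmap = random_instance(rng, 8)
        cmap.persistent[0, :] = False
        cmap.persistent[:, 0] = False
        assert len(ac.grow_pathways(0, ctm, cmap)) == 0

    def test_five_residue_skip_chain(self):
        # only (i, i+2) pairs are persistent contacts; all CT below epsilon
        n = 5
        ct = np.full((n, n), 0.01)
        np.fill_diagonal(ct, 0.0)
        seq = np.arange(1, n + 1)
        pers = np.zeros((n, n), dtype=bool)
        for i in range(n - 2):
            pers[i, i + 2] = pers[i + 2, i] = True
        cmap = ContactMap(occupancy=pers.astype(float), persistent=pers, seq_ids=seq)
        ctm = CommuteTimeMatrix(ct=ct, n_frames=10, seq_ids=seq, epsilon=0.05)
        pset = ac.grow_pathways(0, ctm, cmap)
        assert [p.members for p in pset] == [(0, 2, 4)]

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        ctm, cmap = random_instance(rng, n)
        start = int(rng.integers(n))
        pset = ac.grow_pathways(start, ctm, cmap)
        got = {p.members for p in pset}
        want = oracle_paths(start, ctm.ct, ctm.epsilon, cmap.persistent, ctm.seq_ids)
        assert got == want
        self._assert_pathway_invariants(pset, ctm, cmap)

    @staticmethod
    def _assert_pathway_invariants(pset, ctm, cmap):
        for p in pset:
            members = p.members
            assert len(set(members)) == len(members)  # no repeats
            for u, v in zip(members, members[1:]):
                assert cmap.persistent[u, v]
                assert abs(ctm.seq_ids[u] - ctm.seq_ids[v]) >= 2
            sub = ctm.ct[np.ix_(members, members)]
            assert (sub <= ctm.epsilon + 1e-12).all()
            assert p.pairwise_ct == pytest.approx(sub.max())

    def test_lowering_epsilon_never_adds_paths(self, rng):
        ctm, cmap = random_instance(rng, 9)
        start = 0
        high = {p.members for p in ac.grow_pathways(start, ctm, cmap)}
        reachable_high = {m for mem in high for m in mem}
        ctm.epsilon *= 0.5
        low = {p.members for p in ac.grow_pathways(start, ctm, cmap)}
        reachable_low = {m for mem in low for m in mem}
        assert reachable_low <= reachable_high

    def test_raising_min_occupancy_never_adds_edges(self, rng):
        ref = ac.make_toy_structure(8, "extended")
        ens = ac.plant_contacts(ref, [(0, 4), (1, 6)], occupancy=[0.6, 0.8],
                                n_frames=20, seed=3)
        loose = ac.detect_contacts(ens, min_occupancy=0.5)
        strict = ac.detect_contacts(ens, min_occupancy=0.7)
        assert (strict.persistent <= loose.persistent).all()

    def test_truncation_flagged(self, rng):
        ctm, cmap = random_instance(rng, 12)
        cmap.persistent[:] = np.abs(
            ctm.seq_ids[:, None] - ctm.seq_ids[None, :]
        ) >= 2
        ctm.epsilon = 1.0  # everything fast: combinatorial blowup
        pset = ac.grow_pathways(0, ctm, cmap, max_paths=50)
        assert pset.truncated
        assert len(pset) == 50


class TestPathwayStats:
    def test_fast_fraction_is_percent_of_others(self, rng):
        n = 10
        ct = np.full((n, n), 1.0)
        np.fill_diagonal(ct, 0.0)
        for j in (2, 5, 8):
            ct[0, j] = ct[j, 0] = 0.01
        ctm = CommuteTimeMatrix(
            ct=ct, n_frames=10, seq_ids=np.arange(1, n + 1), epsilon=0.1,
            target_fraction=0.2,
        )
        stats = ac.pathway_stats(ctm, {})
        assert stats.table.fast_fraction[0] == pytest.approx(100 * 3 / 9)

    def test_pathless_residue_convention(self, rng):
        ctm, cmap = random_instance(rng, 8)
        cmap.persistent[:] = False
        stats = ac.pathway_stats(ctm, ac.grow_all_pathways(ctm, cmap))
        assert (stats.table.max_path_length == 1).all()
        assert (stats.table.n_paths == 0).all()

    def test_stats_match_oracle_recount(self, rng):
        ctm, cmap = random_instance(rng, 9)
        all_paths = ac.grow_all_pathways(ctm, cmap)
        stats = ac.pathway_stats(ctm, all_paths)
        for i in range(9):
            want = oracle_paths(i, ctm.ct, ctm.epsilon, cmap.persistent, ctm.seq_ids)
            row = stats.table.iloc[i]
            assert row.n_paths == len(want)
            assert row.max_path_length == max((len(w) for w in want), default=1)
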