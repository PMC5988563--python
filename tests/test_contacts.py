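"""Distances under PBC, smoothing, interaction rules, interval extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import CDL_BEADS, PL_BEADS, make_table, make_trajectory
from lipidsite import (ModeError, ParameterError, SelectionError,
                       atomistic_contact_frequency, contact_mask,
                       extract_intervals, min_distance_series,
                       residue_contact_table, smooth_series)
from lipidsite.contacts import running_mean
from oracles import contact_sets_oracle, min_image_distance_oracle

PROT1 = ("PROTEIN", [("BB", False)])


def _one_popc_traj(coords, box=(10.0, 10.0, 10.0)):
    return make_trajectory([PROT1, ("POPC", PL_BEADS)], coords, box=box)


class TestMinDistance:
    def test_direct_distance(self):
        c = np.zeros((1, 4, 3))
        c[0, 0] = [5.0, 5.0, 5.0]          # protein
        c[0, 1] = [6.0, 5.0, 5.0]          # phosphate 1 nm away
        c[0, 2] = [6.0, 5.0, 4.0]
        c[0, 3] = [6.0, 5.0, 3.0]
        s = min_distance_series(_one_popc_traj(c), lipid_id=1)
        assert s.values[0] == pytest.approx(1.0)

    def test_minimum_image_across_boundary(self):
        c = np.zeros((1, 4, 3))
        c[0, 0] = [0.5, 5.0, 5.0]
        c[0, 1] = [9.5, 5.0, 5.0]          # 1 nm via the periodic image
        c[0, 2] = [9.5, 5.0, 4.0]
        c[0, 3] = [9.5, 5.0, 3.0]
        s = min_distance_series(_one_popc_traj(c), lipid_id=1)
        assert s.values[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        layout = [PROT1] * 10 + [("CDL", CDL_BEADS)] * 2
        box = (7.0, 9.0, 11.0)
        coords = rng.uniform(0, 1, size=(3, 22, 3)) * np.array(box)
        traj = make_trajectory(layout, coords, box=box)
        for lipid in (10, 11):
            s = min_distance_series(traj, lipid, lipid_bead_filter="all")
            beads = traj.topology.beads_of_molecule(lipid)
            prot = traj.topology.protein_indices()
            for f in range(3):
                expect = min(
                    min_image_distance_oracle(coords[f, b], coords[f, p], box)
                    for b in beads for p in prot)
                assert s.values[f] == pytest.approx(expect, rel=1e-12)

    def test_translation_by_whole_boxes_is_invariant(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 10, size=(2, 4, 3))
        t1 = _one_popc_traj(coords)
        shifted = coords.copy()
        shifted[:, 1:, :] += np.array([10.0, -20.0, 30.0])  # lipid only
        t2 = _one_popc_traj(shifted)
        np.testing.assert_allclose(
            min_distance_series(t1, 1, "all").values,
            min_distance_series(t2, 1, "all").values, rtol=1e-9)

    def test_empty_protein_selection_rejected(self, simple_cdl_traj):
        with pytest.raises(SelectionError):
            min_distance_series(simple_cdl_traj, 1,
                                protein_selection=np.array([], dtype=int))


class TestSmoothing:
    def test_constant_series_unchanged(self):
        x = np.full(200, 3.3)
        assert np.allclose(running_mean(x, 50), x)

    def test_reported_span_is_window_times_spacing(self):
        c = np.zeros((60, 4, 3))
        c[:, 1:, 0] = 3.0
        s = min_distance_series(_one_popc_traj(c), 1)
        sm = smooth_series(s, window=50)
        assert sm.effective_span_ns == pytest.approx(60.0)  # 50 x 1.2 ns
        assert sm.values.size == s.values.size

    def test_spike_spread_by_window(self):
        x = np.zeros(51)
        x[25] = 5.0
        sm = running_mean(x, 5)
        assert sm.max() == pytest.approx(1.0)  # h / window
        assert np.count_nonzero(sm) == 5

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ParameterError):
            running_mean(np.zeros(10), 11)


class TestContactRules:
    def _cdl_frame(self, phos1, phos2, tails_far=True):
        c = np.zeros((1, 7, 3))
        c[0, 0] = [5.0, 5.0, 5.0]
        c[0, 1] = phos1
        c[0, 2] = phos2
        c[0, 3:] = [1.0, 1.0, 1.0] if tails_far else [5.2, 5.0, 5.0]
        return make_trajectory([PROT1, ("CDL", CDL_BEADS)], c)

    def test_headgroup_needs_only_one_phosphate(self):
        traj = self._cdl_frame([5.5, 5.0, 5.0], [9.0, 9.0, 9.0])
        m = contact_mask(traj, 1, mode="headgroup", smoothing_window=1)
        assert m.values[0]

    def test_headgroup_false_when_both_phosphates_outside(self):
        traj = self._cdl_frame([8.0, 5.0, 5.0], [9.0, 9.0, 9.0])
        m = contact_mask(traj, 1, mode="headgroup", smoothing_window=1)
        assert not m.values[0]

    @pytest.mark.parametrize("n_inside,expect", [(3, False), (4, True)])
    def test_whole_lipid_needs_four_beads(self, n_inside, expect):
        c = np.full((1, 7, 3), 9.0)
        c[0, 0] = [5.0, 5.0, 5.0]
        for k in range(n_inside):
            c[0, 1 + k] = [5.5, 5.0, 5.0]
        traj = make_trajectory([PROT1, ("CDL", CDL_BEADS)], c)
        m = contact_mask(traj, 1, mode="whole_lipid", smoothing_window=1)
        assert bool(m.values[0]) is expect

    def test_all_far_gives_empty_mask(self):
        c = np.full((5, 7, 3), 1.0)
        c[:, 0] = [8.0, 8.0, 8.0]
        traj = make_trajectory([PROT1, ("CDL", CDL_BEADS)], c)
        m = contact_mask(traj, 1, smoothing_window=3)
        assert not m.values.any()

    def test_unknown_mode_rejected(self, simple_cdl_traj):
        with pytest.raises(ParameterError):
            contact_mask(simple_cdl_traj, 1, mode="nonsense")

    def test_mask_monotone_in_cutoff(self):
        rng = np.random.default_rng(5)
        c = rng.uniform(0, 10, size=(40, 7, 3))
        traj = make_trajectory([PROT1, ("CDL", CDL_BEADS)], c)
        m1 = contact_mask(traj, 1, cutoff=2.0, smoothing_window=5).values
        m2 = contact_mask(traj, 1, cutoff=4.0, smoothing_window=5).values
        assert np.all(m2[m1])  # mask(c1) implies mask(c2) for c1 <= c2

    def test_smoothing_removes_flicker_intervals(self):
        # long contact with 1-frame dropouts every 3 frames: the raw mask
        # fragments into 2-frame slivers that smoothing must merge away
        d = np.full(300, 0.3)
        d[::3] = 2.0
        base = np.zeros((300, 4, 3))
        base[:, 0] = [5.0, 5.0, 5.0]
        base[:, 1, 0] = 5.0 + d
        base[:, 1, 1] = 5.0
        base[:, 1, 2] = 5.0
        base[:, 2:] = 1.0
        traj = _one_popc_traj(base)
        raw = extract_intervals(
            contact_mask(traj, 1, smoothing_window=1), 1.2)
        sm = extract_intervals(
            contact_mask(traj, 1, smoothing_window=5), 1.2)
        short = lambda ivs: sum(1 for iv in ivs.intervals  # noqa: E731
                                if iv.end_frame - iv.start_frame + 1 < 3)
        assert short(sm) < short(raw)
        assert len(sm.intervals) < len(raw.intervals)


class TestExtractIntervals:
    def test_run_length_encoding(self):
        s = extract_intervals(np.array([0, 1, 1, 1, 0, 1, 0], bool), 1.2)
        assert [(i.start_frame, i.end_frame) for i in s.intervals] == \
            [(1, 3), (5, 5)]
        assert s.durations == pytest.approx([3.6, 1.2])
        assert not any(i.censored_left or i.censored_right for i in s.intervals)

    def test_boundary_runs_are_censored(self):
        s = extract_intervals(np.array([1, 1, 0, 1, 1], bool), 1.0)
        assert s.intervals[0].censored_left
        assert s.intervals[-1].censored_right

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.booleans(), min_size=1, max_size=60))
    def test_total_duration_equals_true_frames(self, mask):
        mask = np.array(mask, bool)
        s = extract_intervals(mask, 1.2)
        assert sum(s.durations) == pytest.approx(1.2 * mask.sum())


class TestResidueContactTable:
    def _toy(self, d_phos):
        # 1 CDL whose first phosphate sits d_phos from a 1-bead residue
        c = np.zeros((1, 8, 3))
        c[0, 0] = [5.0, 5.0, 5.0]          # residue 0
        c[0, 1] = [1.0, 1.0, 1.0]          # residue 1, far away
        c[0, 2] = [5.0 + d_phos, 5.0, 5.0]
        c[0, 3] = [9.0, 9.0, 9.0]
        c[0, 4:] = [9.0, 1.0, 9.0]
        return make_trajectory([PROT1, PROT1, ("CDL", CDL_BEADS)], c)

    def test_cutoff_is_sharp(self):
        t_in = residue_contact_table(self._toy(0.65))
        assert list(zip(t_in.frame, t_in.lipid_id, t_in.residue)) == [(0, 2, 0)]
        t_out = residue_contact_table(self._toy(0.75))
        assert t_out.n_events == 0

    def test_no_cardiolipin_warns_and_returns_empty(self):
        c = np.zeros((2, 4, 3))
        traj = make_trajectory([PROT1, ("POPC", PL_BEADS)], c)
        with pytest.warns(UserWarning, match="no cardiolipin"):
            table = residue_contact_table(traj)
        assert table.n_events == 0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        layout = [PROT1] * 5 + [("CDL", CDL_BEADS)] * 2
        coords = rng.uniform(0, 6, size=(4, 17, 3))
        box = (6.0, 6.0, 6.0)
        traj = make_trajectory(layout, coords, box=box)
        table = residue_contact_table(traj, cutoff=1.0)
        top = traj.topology
        phos_by_cdl = {m: [b for b in top.beads_of_molecule(m)
                           if top.is_phosphate[b]] for m in (5, 6)}
        beads_by_res = {r: [r] for r in range(5)}
        expect = contact_sets_oracle(traj.coords, traj.box, phos_by_cdl,
                                     beads_by_res, 1.0)
        got = {}
        for f, l, r in zip(table.frame, table.lipid_id, table.residue):
            got.setdefault((int(f), int(l)), set()).add(int(r))
        assert got == expect


class TestAtomisticContacts:
    def _traj(self, dist_nm, atomistic=True):
        c = np.zeros((1, 8, 3))
        c[0, 0] = [5.0, 5.0, 5.0]
        c[0, 1] = [1.0, 1.0, 1.0]
        c[0, 2] = [5.0 + dist_nm, 5.0, 5.0]
        c[0, 3:] = [9.0, 9.0, 9.0]
        return make_trajectory([PROT1, PROT1, ("CDL", CDL_BEADS)], c,
                               is_atomistic=atomistic)

    def test_three_angstrom_threshold(self):
        counts = atomistic_contact_frequency(self._traj(0.29))
        assert counts[0] == 1 and counts[1] == 0
        counts = atomistic_contact_frequency(self._traj(0.31))
        assert counts[0] == 0

    def test_requires_atomistic_flag(self):
        with pytest.raises(ModeError):
            atomistic_contact_frequency(self._traj(0.29, atomistic=False))

    def test_empty_trajectory_all_zero(self):
        c = np.full((3, 8, 3), 0.0)
        c[:, 2:, :] = 9.0
        traj = make_trajectory([PROT1, PROT1, ("CDL", CDL_BEADS)], c,
                               is_atomistic=True)
        assert (atomistic_contact_frequency(traj) == 0).all()
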