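"""Binding-mode definitions, assignment, occupancy and transitions."""

import numpy as np
import pandas as pd
import pytest

import ligmodes as lm
from ligmodes.modes import DistanceTable, ModeTrace


def make_table(rows, anchors=("R427", "H248", "K426", "K365", "K296",
                              "R292", "R148", "R374"), boundaries=(0,)):
    """Distance table from a list of per-frame {anchor: distance} dicts."""
    data = {a: [row.get(a, 50.0) for row in rows] for a in anchors}
    return DistanceTable(distances=pd.DataFrame(data),
                         boundaries=np.array(boundaries))


class TestDefaultDefinitions:
    def test_six_modes_with_unique_precedence(self, mode_definitions):
        assert len(mode_definitions) == 6
        ranks = [d.precedence_rank for d in mode_definitions]
        assert len(set(ranks)) == 6

    def test_mode1_conditions_r427_h248(self, mode_definitions):
        mode1 = next(d for d in mode_definitions if d.mode_id == 1)
        conds = {(a.label, a.atom_name, c) for a, c in mode1.conditions}
        assert conds == {("R427", "CZ", 5.0), ("H248", "NE2", 11.0)}

    def test_all_cutoffs_5_except_h248(self, mode_definitions):
        for d in mode_definitions:
            for anchor, cutoff in d.conditions:
                expected = 11.0 if anchor.label == "H248" else 5.0
                assert cutoff == expected

    def test_mode6_is_empty_fallback(self, mode_definitions):
        mode6 = next(d for d in mode_definitions if d.mode_id == 6)
        assert mode6.is_fallback and mode6.conditions == []

    def test_anchor_atom_convention(self, mode_definitions):
        for d in mode_definitions:
            for anchor, _ in d.conditions:
                expected = {"R": "CZ", "K": "NZ", "H": "NE2"}[anchor.label[0]]
                assert anchor.atom_name == expected

    def test_his_nd1_variant_selectable(self):
        defs = lm.default_mode_definitions(his_atom="ND1")
        mode1 = next(d for d in defs if d.mode_id == 1)
        his = next(a for a, _ in mode1.conditions if a.label == "H248")
        assert his.atom_name == "ND1"

    def test_yaml_round_trip(self, mode_definitions, tmp_path):
        path = tmp_path / "profile.yaml"
        lm.save_mode_definitions(mode_definitions, path)
        back = lm.load_mode_definitions(path)
        assert [(d.mode_id, d.precedence_rank, d.is_fallback)
                for d in back] == \
            [(d.mode_id, d.precedence_rank, d.is_fallback)
             for d in mode_definitions]
        for a, b in zip(back, mode_definitions):
            assert [(x.label, x.atom_name, c) for x, c in a.conditions] == \
                [(x.label, x.atom_name, c) for x, c in b.conditions]


class TestComputeDistanceTable:
    def test_3_4_5_triangle(self, receptor, anchors):
        spec = lm.SyntheticSpec(jitter_sigma=0.0, n_frames=1, seed=0)
        traj, _ = lm.emit_trajectory(receptor, np.array([6]), spec)
        # move the ligand P so that R427's CZ (origin) sits at (3,4,0) away
        p_sel = lm.select(traj.topology, "resname G3P and name P")
        delta = np.array([3.0, 4.0, 0.0]) - traj.frames[0, p_sel.indices[0]]
        traj.frames[0, -10:, :] += delta
        table = lm.compute_distance_table(traj, p_sel, anchors)
        assert table.distances["R427"].iloc[0] == pytest.approx(5.0)

    def test_coincident_anchor_gives_zero(self, receptor, anchors):
        spec = lm.SyntheticSpec(jitter_sigma=0.0, n_frames=1, seed=0)
        traj, _ = lm.emit_trajectory(receptor, np.array([6]), spec)
        p_sel = lm.select(traj.topology, "resname G3P and name P")
        traj.frames[0, -10:, :] -= traj.frames[0, p_sel.indices[0]]
        table = lm.compute_distance_table(traj, p_sel, anchors)
        assert table.distances["R427"].iloc[0] == 0.0

    def test_matches_per_frame_brute_force(self, receptor, anchors):
        spec = lm.SyntheticSpec(jitter_sigma=0.5, n_frames=10, seed=2)
        labels = lm.simulate_mode_walk(spec.transition_matrix, 10, 2,
                                       mode_ids=spec.mode_ids)
        traj, _ = lm.emit_trajectory(receptor, labels, spec)
        table = lm.compute_distance_table(traj, "resname G3P and name P",
                                          anchors)
        p_idx = lm.select(traj.topology, "resname G3P and name P").indices[0]
        for a in anchors:
            a_idx = a.resolve(traj.topology)
            for t in range(10):
                expected = np.linalg.norm(
                    traj.frames[t, p_idx] - traj.frames[t, a_idx])
                assert table.distances[a.label].iloc[t] == pytest.approx(
                    expected, abs=1e-12)

    def test_ambiguous_p_selection_rejected(self, noiseless_walk, anchors):
        traj, _, _ = noiseless_walk
        with pytest.raises(ValueError):
            lm.compute_distance_table(traj, "resname G3P", anchors)


class TestAssignModes:
    def test_mode1_when_r427_and_h248_close(self, mode_definitions):
        table = make_table([{"R427": 4.0, "H248": 9.0}])
        trace = lm.assign_modes(table, mode_definitions)
        assert trace.labels[0] == 1

    def test_fallback_when_nothing_holds(self, mode_definitions):
        table = make_table([{"R427": 8.0, "H248": 20.0}])
        trace = lm.assign_modes(table, mode_definitions)
        assert trace.labels[0] == 6

    def test_precedence_mode2_beats_mode5(self, mode_definitions):
        # satisfies both mode 2 (K296, R292) and mode 5 (R427, K365) but
        # not mode 1 (H248 too far): precedence gives mode 2
        table = make_table([{"K296": 4.0, "R292": 4.0, "R427": 4.0,
                             "K365": 4.0, "H248": 20.0}])
        trace = lm.assign_modes(table, mode_definitions)
        assert trace.labels[0] == 2

    def test_mode3_only_after_1_and_5(self, mode_definitions):
        # R427+K426 close, H248 far, K365 far: mode 3
        table = make_table([{"R427": 3.0, "K426": 3.0, "H248": 20.0}])
        assert lm.assign_modes(table, mode_definitions).labels[0] == 3
        # same but H248 within 11: mode 1 wins
        table = make_table([{"R427": 3.0, "K426": 3.0, "H248": 10.0}])
        assert lm.assign_modes(table, mode_definitions).labels[0] == 1

    def test_boundary_inclusive(self, mode_definitions):
        table = make_table([{"R427": 5.0, "H248": 11.0}])
        assert lm.assign_modes(table, mode_definitions).labels[0] == 1

    def test_missing_anchor_column_rejected(self, mode_definitions):
        table = DistanceTable(distances=pd.DataFrame({"R427": [1.0]}),
                              boundaries=np.array([0]))
        with pytest.raises(ValueError):
            lm.assign_modes(table, mode_definitions)

    def test_deterministic_function_of_table(self, mode_definitions):
        rng = np.random.default_rng(0)
        rows = [{a: rng.uniform(2, 15) for a in
                 ("R427", "H248", "K426", "K365", "K296", "R292",
                  "R148", "R374")} for _ in range(50)]
        table = make_table(rows)
        a = lm.assign_modes(table, mode_definitions)
        b = lm.assign_modes(table, mode_definitions)
        assert np.array_equal(a.labels, b.labels)

    def test_raising_h248_cutoff_never_decreases_mode1(self, mode_definitions):
        rng = np.random.default_rng(1)
        rows = [{a: rng.uniform(2, 15) for a in
                 ("R427", "H248", "K426", "K365", "K296", "R292",
                  "R148", "R374")} for _ in range(200)]
        table = make_table(rows)
        occupancies = []
        for cutoff in (5.0, 8.0, 11.0, 14.0):
            defs = lm.default_mode_definitions()
            mode1 = next(d for d in defs if d.mode_id == 1)
            mode1.conditions = [
                (a, cutoff if a.label == "H248" else c)
                for a, c in mode1.conditions]
            occ = lm.mode_occupancy(lm.assign_modes(table, defs))
            occupancies.append(occ[1])
        assert all(b >= a - 1e-12 for a, b in zip(occupancies, occupancies[1:]))


class TestOccupancyAndTransitions:
    def _trace(self, labels, boundaries=(0,)):
        return ModeTrace(labels=np.array(labels),
                         boundaries=np.array(boundaries),
                         mode_ids=(1, 2, 3, 4, 5, 6))

    def test_all_one_mode(self):
        occ = lm.mode_occupancy(self._trace([1] * 5))
        assert occ[1] == 100.0 and occ[2] == 0.0

    def test_60_40_split(self):
        occ = lm.mode_occupancy(self._trace([1, 1, 3, 3, 1]))
        assert occ[1] == pytest.approx(60.0)
        assert occ[3] == pytest.approx(40.0)

    def test_occupancies_partition_to_100(self, noiseless_walk,
                                          mode_definitions, anchors):
        traj, _, _ = noiseless_walk
        table = lm.compute_distance_table(traj, "resname G3P and name P",
                                          anchors)
        occ = lm.mode_occupancy(lm.assign_modes(table, mode_definitions))
        assert occ.sum() == pytest.approx(100.0, abs=1e-9)

    def test_constant_trace_no_transitions(self):
        matrix, events = lm.transition_summary(self._trace([2] * 10))
        assert matrix.to_numpy().sum() == 0 and events == []

    def test_direct_count_of_changes(self):
        matrix, events = lm.transition_summary(self._trace([1, 3, 3, 5]))
        assert events == [(1, 1, 3), (3, 3, 5)]
        assert matrix.loc[1, 3] == 1 and matrix.loc[3, 5] == 1
        assert matrix.to_numpy().sum() == 2

    def test_boundary_pairs_excluded(self):
        matrix, events = lm.transition_summary(
            self._trace([1, 1, 2, 2], boundaries=(0, 2)))
        assert matrix.to_numpy().sum() == 0 and events == []


class TestRepresentFrames:
    def test_stride_two_keeps_first(self):
        trace = ModeTrace(labels=np.arange(2000) % 6 + 1,
                          boundaries=np.array([0]), mode_ids=(1, 2, 3, 4, 5, 6))
        rep = lm.represent_frames(trace, n=1000)
        assert rep.n_frames == 1000
        assert np.array_equal(rep.labels, trace.labels[::2])

    def test_n_equal_t_is_identity(self):
        trace = ModeTrace(labels=np.ones(100, dtype=int),
                          boundaries=np.array([0]), mode_ids=(1, 2, 3, 4, 5, 6))
        rep = lm.represent_frames(trace, n=100)
        assert np.array_equal(rep.labels, trace.labels)

    def test_eight_sources_concatenate_to_8000(self):
        labels = np.ones(8 * 2000, dtype=int)
        boundaries = np.arange(8) * 2000
        trace = ModeTrace(labels=labels, boundaries=boundaries,
                          mode_ids=(1, 2, 3, 4, 5, 6))
        rep = lm.represent_frames(trace, n=1000)
        assert rep.n_frames == 8000
        assert np.array_equal(rep.boundaries, np.arange(8) * 1000)

    def test_short_source_kept_whole_with_warning(self):
        trace = ModeTrace(labels=np.ones(50, dtype=int),
                          boundaries=np.array([0]), mode_ids=(1, 2, 3, 4, 5, 6))
        with pytest.warns(UserWarning):
            rep = lm.represent_frames(trace, n=1000)
        assert rep.n_frames == 50

    def test_nonpositive_n_rejected(self):
        trace = ModeTrace(labels=np.ones(5, dtype=int),
                          boundaries=np.array([0]), mode_ids=(1,))
        with pytest.raises(ValueError):
            lm.represent_frames(trace, n=0)


class TestRecovery:
    def test_sigma0_labels_recovered_exactly(self, noiseless_walk,
                                             mode_definitions, anchors):
        traj, labels, _ = noiseless_walk
        table = lm.compute_distance_table(traj, "resname G3P and name P",
                                          anchors)
        trace = lm.assign_modes(table, mode_definitions)
        assert np.array_equal(trace.labels, labels)

    def test_sigma0_transitions_match_ground_truth_exactly(
            self, noiseless_walk, mode_definitions, anchors):
        traj, labels, _ = noiseless_walk
        table = lm.compute_distance_table(traj, "resname G3P and name P",
                                          anchors)
        matrix, events = lm.transition_summary(
            lm.assign_modes(table, mode_definitions))
        true_changes = int(np.sum(labels[1:] != labels[:-1]))
        assert matrix.to_numpy().sum() == true_changes
        assert len(events) == true_changes

    def test_sigma05_agreement_at_least_99_pct(self, receptor,
                                               mode_definitions, anchors):
        spec = lm.SyntheticSpec(jitter_sigma=0.5, n_frames=10_000, seed=13)
        labels = lm.simulate_mode_walk(spec.transition_matrix, spec.n_frames,
                                       seed=13, mode_ids=spec.mode_ids)
        traj, _ = lm.emit_trajectory(receptor, labels, spec)
        table = lm.compute_distance_table(traj, "resname G3P and name P",
                                          anchors)
        trace = lm.assign_modes(table, mode_definitions)
        agreement = np.mean(trace.labels == labels)
        assert agreement >= 0.99

    def test_occupancies_within_3_binomial_se(self, receptor,
                                              mode_definitions, anchors):
        spec = lm.SyntheticSpec(jitter_sigma=0.5, n_frames=10_000, seed=29)
        labels = lm.simulate_mode_walk(spec.transition_matrix, spec.n_frames,
                                       seed=29, mode_ids=spec.mode_ids)
        traj, _ = lm.emit_trajectory(receptor, labels, spec)
        table = lm.compute_distance_table(traj, "resname G3P and name P",
                                          anchors)
        occ = lm.mode_occupancy(lm.assign_modes(table, mode_definitions))
        T = spec.n_frames
        for m in range(1, 7):
            p = np.mean(labels == m)
            se = max(np.sqrt(p * (1 - p) / T), 1e-9)
            assert abs(occ[m] / 100.0 - p) <= 3 * se
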