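"""Assignment engine: synchronized movement, freeze/thaw propagation,
tweak-and-freeze, manual peaks, deletion, export and replay."""

import numpy as np
import pytest

from peaknets import network as nw
from peaknets.network import (AmbiguousPeakError, AssignmentError,
                              FrozenAtomError, OpLog)


def _some_peak(net, exp="noesy"):
    return net.peaklists[exp][0]


class TestBuild:
    def test_index_inverts_assignments(self, demo22):
        for atom_key, refs in demo22.index.items():
            for exp, pid, d in refs:
                assert demo22.peaks[(exp, pid)].dims[d].atom_key == atom_key

    def test_shared_atom_has_multiple_entries(self, demo22):
        counts = [len(v) for v in demo22.index.values()]
        assert max(counts) > 1

    def test_positions_agree_globally(self, demo22):
        assert demo22.check_consistency() == []

    def test_nothing_frozen_initially(self, demo22):
        assert not demo22.shifts.frozen_records()

    def test_dangling_atom_rejected(self, fresh22):
        from peaknets.peakgen import PeakBox, Dim, ExperimentScheme, DimSpec
        bad = PeakBox(0, "extra", [Dim((99, "H1'"), 5.0), Dim((1, "H8"), 7.0)])
        scheme = ExperimentScheme("extra", [DimSpec("1H"), DimSpec("1H")],
                                  "noesy")
        with pytest.raises(AssignmentError, match="absent"):
            fresh22.add_experiment(scheme, [bad])


class TestMove:
    def test_synchronous_movement(self, fresh22):
        key = (7, "H1'")
        refs = fresh22.index[key]
        assert len(refs) >= 3
        old = fresh22.shifts[key].current_ppm
        nw.move_atom(fresh22, key, old + 0.10)
        for exp, pid, d in refs:
            assert fresh22.peaks[(exp, pid)].dims[d].ppm == \
                pytest.approx(old + 0.10)
        # nothing else moved
        assert fresh22.check_consistency() == []

    def test_move_to_same_value_noop(self, fresh22):
        key = (7, "H1'")
        before = fresh22.state_hash()
        nw.move_atom(fresh22, key, fresh22.shifts[key].current_ppm,
                     _log=False)
        assert fresh22.state_hash() == before

    def test_move_frozen_rejected(self, fresh22):
        peak = _some_peak(fresh22)
        nw.freeze_peak(fresh22, "noesy", peak.id)
        key = peak.dims[0].atom_key
        before = fresh22.state_hash()
        with pytest.raises(FrozenAtomError):
            nw.move_atom(fresh22, key, 9.99)
        assert fresh22.state_hash() == before


class TestFreezeThaw:
    def test_propagates_exactly_to_linked_dims(self, fresh22):
        peak = _some_peak(fresh22)
        atoms = set(peak.atom_keys)
        nw.freeze_peak(fresh22, "noesy", peak.id)
        for (exp, pid), box in fresh22.peaks.items():
            for d, dim in enumerate(box.dims):
                assert dim.frozen == (dim.atom_key in atoms)

    def test_partially_frozen_cross_peak(self, fresh22):
        """A peak sharing one atom with a frozen peak is locked in that
        dimension only and can still slide along the free one."""
        peak = _some_peak(fresh22)
        nw.freeze_peak(fresh22, "noesy", peak.id)
        a0 = peak.dims[0].atom_key
        exp, pid, d = next(iter(
            r for r in fresh22.index[a0] if (r[0], r[1]) != ("noesy", peak.id)))
        other = fresh22.peaks[(exp, pid)]
        assert other.dims[d].frozen
        free = other.dims[1 - d]
        if free.atom_key not in set(peak.atom_keys):
            assert not free.frozen
            nw.move_atom(fresh22, free.atom_key, free.ppm + 0.05)

    def test_freeze_updates_shift_table(self, fresh22):
        peak = _some_peak(fresh22)
        nw.freeze_peak(fresh22, "noesy", peak.id)
        for d in peak.dims:
            rec = fresh22.shifts[d.atom_key]
            assert rec.frozen and rec.current_ppm == d.ppm

    def test_freeze_idempotent(self, fresh22):
        peak = _some_peak(fresh22)
        nw.freeze_peak(fresh22, "noesy", peak.id)
        h = fresh22.state_hash()
        nw.freeze_peak(fresh22, "noesy", peak.id)
        assert fresh22.state_hash() == h

    def test_thaw_inverts_freeze(self, fresh22):
        before = fresh22.state_hash()
        peak = _some_peak(fresh22)
        nw.freeze_peak(fresh22, "noesy", peak.id)
        nw.thaw_peak(fresh22, "noesy", peak.id)
        assert fresh22.state_hash() == before

    def test_thaw_is_atom_level(self, fresh22):
        """Thawing any peak referencing a frozen atom thaws the atom."""
        peak = _some_peak(fresh22)
        a0 = peak.dims[0].atom_key
        nw.freeze_peak(fresh22, "noesy", peak.id)
        exp, pid, _ = next(iter(
            r for r in fresh22.index[a0] if (r[0], r[1]) != ("noesy", peak.id)))
        nw.thaw_peak(fresh22, exp, pid)
        assert not fresh22.shifts[a0].frozen

    def test_thaw_untouched_noop(self, fresh22):
        h = fresh22.state_hash()
        nw.thaw_peak(fresh22, "noesy", _some_peak(fresh22).id, _log=False)
        assert fresh22.state_hash() == h


class TestTweakAndFreeze:
    def test_unique_candidate_snap(self, fresh22):
        peak = _some_peak(fresh22)
        x, y = peak.dims[0].ppm, peak.dims[1].ppm
        nw.tweak_and_freeze(fresh22, "noesy", peak.id,
                            [(x + 0.02, y - 0.02)],
                            tolerances=[0.05, 0.05])
        assert peak.dims[0].ppm == pytest.approx(x + 0.02)
        assert peak.dims[1].ppm == pytest.approx(y - 0.02)
        assert all(d.frozen for d in peak.dims)
        assert fresh22.check_consistency() == []

    def test_no_candidate_errors_and_leaves_state(self, fresh22):
        peak = _some_peak(fresh22)
        h = fresh22.state_hash()
        with pytest.raises(AssignmentError, match="tolerance"):
            nw.tweak_and_freeze(fresh22, "noesy", peak.id,
                                [(peak.dims[0].ppm + 1.0,
                                  peak.dims[1].ppm)],
                                tolerances=[0.05, 0.05])
        assert fresh22.state_hash() == h

    def test_equidistant_candidates_ambiguous(self, fresh22):
        peak = _some_peak(fresh22)
        x, y = peak.dims[0].ppm, peak.dims[1].ppm
        with pytest.raises(AmbiguousPeakError):
            nw.tweak_and_freeze(fresh22, "noesy", peak.id,
                                [(x + 0.02, y), (x - 0.02, y)],
                                tolerances=[0.05, 0.05])

    def test_frozen_dim_constrains_candidates(self, fresh22):
        """With the x-dimension frozen, only observed peaks on that exact
        coordinate are candidates."""
        peak = _some_peak(fresh22)
        x, y = peak.dims[0].ppm, peak.dims[1].ppm
        nw.freeze_atom(fresh22, peak.dims[0].atom_key)
        chosen = nw.tweak_and_freeze(
            fresh22, "noesy", peak.id,
            [(x, y + 0.01), (x - 0.62, y + 0.01)],
            tolerances=[0.05, 0.05])
        assert chosen == (x, y + 0.01)


class TestManualPeaks:
    def test_candidates_within_tolerance_sorted(self, fresh22):
        g7 = (7, "H1'")
        nw.move_atom(fresh22, g7, 5.74)
        nw.freeze_atom(fresh22, g7)
        box, cands = nw.add_manual_peak(fresh22, "noesy", (5.75, 7.80),
                                        tolerances=[0.02, 0.02])
        assert box.status == "manual"
        assert g7 in [c[0] for c in cands[0]]

    def test_no_frozen_atoms_no_candidates(self, fresh22):
        _, cands = nw.add_manual_peak(fresh22, "noesy", (5.75, 7.80))
        assert cands == [[], []]

    def test_stable_sort_by_delta_then_residue(self, fresh22):
        a, b = (3, "H1'"), (9, "H1'")
        nw.move_atom(fresh22, a, 5.74)
        nw.move_atom(fresh22, b, 5.76)
        nw.freeze_atom(fresh22, a)
        nw.freeze_atom(fresh22, b)
        _, cands = nw.add_manual_peak(fresh22, "noesy", (5.75, 7.80),
                                      tolerances=[0.05, 0.05])
        h1p = [c for c in cands[0] if c[0] in (a, b)]
        assert [c[0] for c in h1p] == [a, b]   # tie broken by residue index

    def test_assign_dimension_links(self, fresh22):
        g7 = (7, "H1'")
        nw.freeze_atom(fresh22, g7)
        box, _ = nw.add_manual_peak(fresh22, "noesy", (5.75, 7.80))
        nw.assign_dimension(fresh22, "noesy", box.id, 0, g7)
        assert ("noesy", box.id, 0) in fresh22.index[g7]
        assert box.dims[0].ppm == fresh22.shifts[g7].current_ppm
        assert box.dims[0].frozen


class TestDelete:
    def test_deleted_absent_from_index_and_export(self, fresh22):
        peak = _some_peak(fresh22)
        nw.freeze_peak(fresh22, "noesy", peak.id)
        nw.delete_peak(fresh22, "noesy", peak.id)
        for d, dim in enumerate(peak.dims):
            assert ("noesy", peak.id, d) not in fresh22.index[dim.atom_key]
        # frozen atoms survive deletion (still referenced elsewhere)
        assert fresh22.shifts[peak.dims[0].atom_key].frozen

    def test_double_delete_noop(self, fresh22):
        peak = _some_peak(fresh22)
        nw.delete_peak(fresh22, "noesy", peak.id)
        h = fresh22.state_hash()
        nw.delete_peak(fresh22, "noesy", peak.id)
        assert fresh22.state_hash() == h

    def test_shift_record_kept_for_unreferenced_atom(self, fresh22):
        peak = _some_peak(fresh22)
        keys = list(peak.atom_keys)
        nw.delete_peak(fresh22, "noesy", peak.id)
        assert all(k in fresh22.shifts for k in keys)


class TestExport:
    def test_empty_without_freezes(self, fresh22):
        assert nw.export_assignments(fresh22) == []

    def test_one_box_two_entries(self, fresh22):
        peak = _some_peak(fresh22)
        nw.freeze_peak(fresh22, "noesy", peak.id)
        out = nw.export_assignments(fresh22)
        assert len(out) == 2
        assert {(r[0], r[2]) for r in out} == set(peak.atom_keys)

    def test_matches_frozen_records(self, fresh22):
        for pid in (0, 5, 10):
            nw.freeze_peak(fresh22, "noesy", pid)
        out = nw.export_assignments(fresh22)
        frozen = {r.atom_key: r.current_ppm
                  for r in fresh22.shifts.frozen_records()}
        assert {(r[0], r[2]): r[3] for r in out} == frozen
        assert out == sorted(out, key=lambda r: (r[0], r[2]))


def _random_session(net, rng, n_ops=200):
    atoms = sorted(net.networked_atoms())
    peaks = sorted(net.peaks)
    for _ in range(n_ops):
        op = rng.integers(0, 4)
        if op == 0:
            key = atoms[rng.integers(len(atoms))]
            if not net.is_frozen(key):
                delta = float(rng.normal(0, 0.05))
                nw.move_atom(net, key,
                             net.shifts[key].current_ppm + delta)
        elif op == 1:
            exp, pid = peaks[rng.integers(len(peaks))]
            if net.peaks[(exp, pid)].status != "deleted":
                nw.freeze_peak(net, exp, pid)
        elif op == 2:
            exp, pid = peaks[rng.integers(len(peaks))]
            if net.peaks[(exp, pid)].status != "deleted":
                nw.thaw_peak(net, exp, pid)
        else:
            exp, pid = peaks[rng.integers(len(peaks))]
            nw.delete_peak(net, exp, pid)


class TestReplay:
    def test_empty_log_is_fresh_network(self, fresh22):
        h = fresh22.state_hash()
        nw.replay(OpLog(), fresh22)
        assert fresh22.state_hash() == h

    def test_recorded_session_replays_to_equal_state(self, fresh22, rng):
        from peaknets.fixtures import demo_network_22
        _random_session(fresh22, rng, n_ops=200)
        text = fresh22.oplog.to_text()
        clone = demo_network_22()
        nw.replay(OpLog.from_text(text), clone)
        assert clone.state_hash() == fresh22.state_hash()

    def test_illegal_op_raises_at_same_step(self, fresh22):
        peak = _some_peak(fresh22)
        key = peak.dims[0].atom_key
        log = OpLog()
        log.append("freeze", "noesy", peak.id)
        log.append("move", key[0], key[1], 5.0)
        with pytest.raises(FrozenAtomError, match="step 1"):
            nw.replay(log, fresh22)


def test_random_ops_keep_global_invariants(fresh22, rng):
    """After any operation sequence, linked dimension positions equal the
    atom's current shift and frozen shifts never drift."""
    net = fresh22
    frozen_snapshot = {}
    atoms = sorted(net.networked_atoms())
    peaks = sorted(net.peaks)
    for step in range(2000):
        op = rng.integers(0, 4)
        exp, pid = peaks[rng.integers(len(peaks))]
        if op == 0:
            key = atoms[rng.integers(len(atoms))]
            try:
                nw.move_atom(net, key,
                             net.shifts[key].current_ppm
                             + float(rng.normal(0, 0.05)))
            except FrozenAtomError:
                assert key in frozen_snapshot
        elif op == 1 and net.peaks[(exp, pid)].status != "deleted":
            nw.freeze_peak(net, exp, pid)
            for d in net.peaks[(exp, pid)].dims:
                frozen_snapshot.setdefault(d.atom_key,
                                           net.shifts[d.atom_key].current_ppm)
        elif op == 2 and net.peaks[(exp, pid)].status != "deleted":
            for d in net.peaks[(exp, pid)].dims:
                frozen_snapshot.pop(d.atom_key, None)
            nw.thaw_peak(net, exp, pid)
        else:
            nw.delete_peak(net, exp, pid)
        if step % 200 == 0:
            assert net.check_consistency() == []
            for key, ppm in frozen_snapshot.items():
                assert net.shifts[key].current_ppm == ppm
    assert net.check_consistency() == []
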