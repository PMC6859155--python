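"""The assignment engine: linked peak-boxes, synchronized movement,
freeze/thaw propagation and assignment export.

State model
-----------
The shift table holds the one mutable coordinate per atom; peak-box
dimensions mirror it.  Frozen-ness is *atom-level*: freezing a peak-box
freezes its dimension atoms, which instantly freezes every dimension of
every peak-box (in any experiment) assigned to those atoms — the peak is
the gesture, the atom is the state.  Thawing any peak referencing a
frozen atom thaws the atom, which is also why two boxes can never be
frozen at conflicting positions for the same atom.

All mutating operations append to an operation log whose replay on a
freshly generated network reproduces the session exactly; this is the
scripted, GUI-free equivalent of the interactive workflow.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

from .peakgen import PeakBox, Dim, ExperimentScheme
from .shifts import ShiftTable
from .topology import Molecule


class AssignmentError(ValueError):
    pass


class FrozenAtomError(AssignmentError):
    """Attempt to move an atom whose shift has been frozen."""


class AmbiguousPeakError(AssignmentError):
    """Two observed candidates tie; the engine refuses to guess."""


@dataclass
class OpLogEntry:
    op: str
    args: tuple

    def to_line(self) -> str:
        return " ".join([self.op] + [str(a) for a in self.args])


@dataclass
class OpLog:
    entries: list = field(default_factory=list)

    def append(self, op: str, *args) -> None:
        self.entries.append(OpLogEntry(op, args))

    def to_text(self) -> str:
        return "\n".join(e.to_line() for e in self.entries) + (
            "\n" if self.entries else "")

    @classmethod
    def from_text(cls, text: str) -> "OpLog":
        log = cls()
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            log.append(parts[0], *parts[1:])
        return log

    def __len__(self) -> int:
        return len(self.entries)


class AssignmentNetwork:
    """Molecule + shift table + peak lists, indexed by shared atoms."""

    def __init__(self, molecule: Molecule, shifts: ShiftTable):
        self.molecule = molecule
        self.shifts = shifts
        self.schemes: dict[str, ExperimentScheme] = {}
        self.peaklists: dict[str, list] = {}
        self.peaks: dict[tuple, PeakBox] = {}      # (exp, id) -> box
        self.index: dict[tuple, set] = {}          # atom -> {(exp, id, dim)}
        self.oplog = OpLog()

    # -- construction --------------------------------------------------
    def add_experiment(self, scheme: ExperimentScheme, peaks: list) -> None:
        if scheme.name in self.peaklists:
            raise AssignmentError(f"duplicate experiment {scheme.name!r}")
        self.schemes[scheme.name] = scheme
        self.peaklists[scheme.name] = peaks
        for p in peaks:
            self.peaks[(scheme.name, p.id)] = p
            for d, dim in enumerate(p.dims):
                if dim.atom_key is None:
                    continue
                if dim.atom_key not in self.shifts:
                    raise AssignmentError(
                        f"peak {scheme.name}/{p.id} references atom "
                        f"{dim.atom_key} absent from the shift table")
                self.index.setdefault(dim.atom_key, set()).add(
                    (scheme.name, p.id, d))
                rec = self.shifts[dim.atom_key]
                dim.ppm = rec.current_ppm
                dim.frozen = rec.frozen

    # -- queries --------------------------------------------------------
    def peak(self, experiment: str, peak_id: int) -> PeakBox:
        try:
            return self.peaks[(experiment, peak_id)]
        except KeyError:
            raise AssignmentError(
                f"no peak {peak_id} in experiment {experiment!r}") from None

    def linked_dims(self, atom_key) -> set:
        return set(self.index.get(atom_key, ()))

    def networked_atoms(self) -> set:
        return {k for k, refs in self.index.items() if refs}

    def is_frozen(self, atom_key) -> bool:
        rec = self.shifts.get(atom_key)
        return bool(rec and rec.frozen)

    def state_hash(self) -> str:
        h = hashlib.sha256()
        for key in sorted(self.shifts.records):
            r = self.shifts.records[key]
            h.update(
                f"{key}|{r.current_ppm:.6f}|{r.frozen}|{r.source}\n".encode())
        for (exp, pid) in sorted(self.peaks):
            p = self.peaks[(exp, pid)]
            h.update(f"{exp}|{pid}|{p.status}".encode())
            for d in p.dims:
                h.update(f"|{d.atom_key}|{d.ppm:.6f}|{d.frozen}".encode())
            h.update(b"\n")
        return h.hexdigest()

    # -- primitives -----------------------------------------------------
    def _sync_atom(self, atom_key) -> None:
        rec = self.shifts[atom_key]
        for exp, pid, d in self.index.get(atom_key, ()):
            dim = self.peaks[(exp, pid)].dims[d]
            dim.ppm = rec.current_ppm
            dim.frozen = rec.frozen

    def check_consistency(self) -> list:
        """Return a list of invariant violations (empty when healthy)."""
        bad = []
        for atom_key, refs in self.index.items():
            rec = self.shifts.get(atom_key)
            if rec is None:
                bad.append(f"{atom_key}: no shift record")
                continue
            for exp, pid, d in refs:
                p = self.peaks[(exp, pid)]
                dim = p.dims[d]
                if dim.atom_key != atom_key:
                    bad.append(f"{exp}/{pid}.{d}: index inversion broken")
                if p.status != "deleted" and dim.ppm != rec.current_ppm:
                    bad.append(
                        f"{exp}/{pid}.{d}: position {dim.ppm} != "
                        f"current shift {rec.current_ppm} of {atom_key}")
                if dim.frozen != rec.frozen:
                    bad.append(f"{exp}/{pid}.{d}: frozen flag out of sync")
        return bad


def build_network(molecule: Molecule, shifts: ShiftTable,
                  experiments: list) -> AssignmentNetwork:
    """Assemble the network from ``[(scheme, peaklist), ...]``.

    All positions start at the predicted shifts and nothing is frozen.
    """
    net = AssignmentNetwork(molecule, shifts)
    for scheme, peaks in experiments:
        net.add_experiment(scheme, peaks)
    return net


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def move_atom(net: AssignmentNetwork, atom_key, new_ppm: float,
              _log: bool = True) -> None:
    """Move an atom's shift; every linked dimension follows synchronously."""
    atom_key = tuple(atom_key)
    rec = net.shifts.get(atom_key)
    if rec is None:
        raise AssignmentError(f"atom {atom_key} not in shift table")
    if rec.frozen:
        raise FrozenAtomError(f"atom {atom_key} is frozen")
    rec.current_ppm = float(new_ppm)
    net._sync_atom(atom_key)
    if _log:
        net.oplog.append("move", atom_key[0], atom_key[1],
                         f"{float(new_ppm):.6f}")


def _freeze_atoms(net: AssignmentNetwork, atom_keys) -> None:
    for key in atom_keys:
        rec = net.shifts[key]
        rec.frozen = True
        net._sync_atom(key)


def freeze_peak(net: AssignmentNetwork, experiment: str, peak_id: int,
                _log: bool = True) -> None:
    """Freeze both dimensions of a peak-box at their current positions.

    All dimensions linked through the same atoms, in this and every other
    experiment, become frozen too, and the shift table records the frozen
    values.  Idempotent.
    """
    p = net.peak(experiment, peak_id)
    if p.status == "deleted":
        raise AssignmentError("cannot freeze a deleted peak")
    _freeze_atoms(net, [d.atom_key for d in p.dims if d.atom_key])
    for d in p.dims:
        if d.atom_key is None:
            d.frozen = True
    if _log:
        net.oplog.append("freeze", experiment, peak_id)
        log.info("freeze %s/%s at (%s)", experiment, peak_id,
                 ", ".join(f"{d.ppm:.4f}" for d in p.dims))


def freeze_atom(net: AssignmentNetwork, atom_key, _log: bool = True) -> None:
    """Freeze a single atom at its current shift (engine primitive used
    by scripted assignment; the interactive gesture is freeze_peak)."""
    atom_key = tuple(atom_key)
    if atom_key not in net.shifts:
        raise AssignmentError(f"atom {atom_key} not in shift table")
    _freeze_atoms(net, [atom_key])
    if _log:
        net.oplog.append("freeze_atom", atom_key[0], atom_key[1])


def thaw_peak(net: AssignmentNetwork, experiment: str, peak_id: int,
              _log: bool = True) -> None:
    """Un-freeze the peak's dimension atoms (and thereby every linked
    dimension).  No-op when nothing is frozen."""
    p = net.peak(experiment, peak_id)
    for d in p.dims:
        if d.atom_key is None:
            d.frozen = False
            continue
        rec = net.shifts[d.atom_key]
        if rec.frozen:
            rec.frozen = False
            net._sync_atom(d.atom_key)
    if _log:
        net.oplog.append("thaw", experiment, peak_id)
        log.info("thaw %s/%s", experiment, peak_id)


def tweak_and_freeze(net: AssignmentNetwork, experiment: str, peak_id: int,
                     observed: list, tolerances=None,
                     frozen_eps: float = 1e-6, _log: bool = True) -> tuple:
    """Snap a peak-box onto the nearest observed peak, then freeze it.

    ``observed`` is a list of position tuples.  Frozen dimensions
    constrain candidates to their fixed value (within ``frozen_eps``);
    unfrozen dimensions search within the per-dimension tolerance.  The
    nearest candidate by tolerance-scaled Euclidean distance wins; an
    exact tie is an error — the scripted engine must not guess.
    Returns the chosen position tuple.
    """
    if not observed:
        raise AssignmentError("observed peak list is empty")
    p = net.peak(experiment, peak_id)
    scheme = net.schemes[experiment]
    if tolerances is None:
        tolerances = scheme.tolerances
    candidates = []
    for pos in observed:
        score = 0.0
        ok = True
        for d, dim in enumerate(p.dims):
            delta = abs(float(pos[d]) - dim.ppm)
            if dim.frozen:
                if delta > frozen_eps:
                    ok = False
                    break
            else:
                if delta > tolerances[d]:
                    ok = False
                    break
                score += (delta / tolerances[d]) ** 2
        if ok:
            candidates.append((math.sqrt(score), tuple(map(float, pos))))
    if not candidates:
        raise AssignmentError(
            f"no observed peak within tolerance of {experiment}/{peak_id}")
    candidates.sort(key=lambda c: c[0])
    if len(candidates) > 1 and candidates[1][0] - candidates[0][0] < 1e-9:
        raise AmbiguousPeakError(
            f"two observed peaks are equidistant from {experiment}/{peak_id}")
    best = candidates[0][1]
    for d, dim in enumerate(p.dims):
        if dim.frozen:
            continue
        if dim.atom_key is None:
            dim.ppm = best[d]
        else:
            move_atom(net, dim.atom_key, best[d], _log=_log)
    freeze_peak(net, experiment, peak_id, _log=_log)
    return best


def add_manual_peak(net: AssignmentNetwork, experiment: str, positions,
                    tolerances=None, _log: bool = True):
    """Add an unassigned peak-box at the given positions.

    Returns ``(box, candidates)`` where ``candidates[d]`` lists
    ``(atom_key, frozen_ppm)`` for frozen atoms of the dimension's
    nucleus whose shifts lie within tolerance, sorted by
    (|delta-ppm|, residue index, atom name)."""
    scheme = net.schemes[experiment]
    if tolerances is None:
        tolerances = scheme.tolerances
    pid = 1 + max((p.id for p in net.peaklists[experiment]), default=-1)
    box = PeakBox(pid, experiment,
                  [Dim(None, float(x)) for x in positions],
                  status="manual", origin="user")
    net.peaklists[experiment].append(box)
    net.peaks[(experiment, pid)] = box
    candidates = []
    from .peakgen import NUCLEUS_ELEMENT
    for d, spec in enumerate(scheme.dims):
        element = NUCLEUS_ELEMENT[spec.nucleus]
        hits = []
        for rec in net.shifts.frozen_records():
            if rec.element != element:
                continue
            delta = abs(rec.current_ppm - float(positions[d]))
            if delta <= tolerances[d]:
                hits.append((delta, rec.atom_key[0], rec.atom_key[1]))
        hits.sort()
        candidates.append([((r, a), net.shifts[(r, a)].current_ppm)
                           for _, r, a in hits])
    if _log:
        net.oplog.append("add_manual", experiment,
                         *[f"{float(x):.6f}" for x in positions])
    return box, candidates


def assign_dimension(net: AssignmentNetwork, experiment: str, peak_id: int,
                     dim_index: int, atom_key, _log: bool = True) -> None:
    """Link one dimension of a (manual) peak-box to an atom."""
    atom_key = tuple(atom_key)
    p = net.peak(experiment, peak_id)
    dim = p.dims[dim_index]
    if dim.atom_key is not None:
        net.index[dim.atom_key].discard((experiment, peak_id, dim_index))
    rec = net.shifts.get(atom_key)
    if rec is None:
        raise AssignmentError(f"atom {atom_key} not in shift table")
    dim.atom_key = atom_key
    net.index.setdefault(atom_key, set()).add(
        (experiment, peak_id, dim_index))
    dim.ppm = rec.current_ppm
    dim.frozen = rec.frozen
    if _log:
        net.oplog.append("assign", experiment, peak_id, dim_index,
                         atom_key[0], atom_key[1])


def delete_peak(net: AssignmentNetwork, experiment: str, peak_id: int,
                _log: bool = True) -> None:
    """Mark a peak deleted and unlink it; frozen atoms keep their state."""
    p = net.peak(experiment, peak_id)
    if p.status == "deleted":
        return
    p.status = "deleted"
    for d, dim in enumerate(p.dims):
        if dim.atom_key is not None:
            refs = net.index.get(dim.atom_key)
            if refs:
                refs.discard((experiment, peak_id, d))
    if _log:
        net.oplog.append("delete", experiment, peak_id)


def export_assignments(net: AssignmentNetwork) -> list:
    """Assignment list from frozen atoms only.

    Returns ``[(residue_index, residue_name, atom_name, ppm), ...]``
    sorted by residue then atom name.
    """
    out = []
    for rec in net.shifts.frozen_records():
        idx, name = rec.atom_key
        out.append((idx, net.molecule.residue_name(idx), name,
                    rec.current_ppm))
    out.sort(key=lambda r: (r[0], r[2]))
    return out


# ---------------------------------------------------------------------------
# Replay
# ---------------------------------------------------------------------------

def replay(oplog: OpLog, net: AssignmentNetwork) -> AssignmentNetwork:
    """Re-run a recorded session on a freshly built network.

    Raises the original error at the same step if the log contains an
    illegal operation (e.g. moving a frozen atom).
    """
    for step, e in enumerate(oplog.entries):
        try:
            if e.op == "move":
                move_atom(net, (int(e.args[0]), e.args[1]),
                          float(e.args[2]))
            elif e.op == "freeze":
                freeze_peak(net, e.args[0], int(e.args[1]))
            elif e.op == "freeze_atom":
                freeze_atom(net, (int(e.args[0]), e.args[1]))
            elif e.op == "thaw":
                thaw_peak(net, e.args[0], int(e.args[1]))
            elif e.op == "delete":
                delete_peak(net, e.args[0], int(e.args[1]))
            elif e.op == "add_manual":
                add_manual_peak(net, e.args[0],
                                [float(x) for x in e.args[1:]])
            elif e.op == "assign":
                assign_dimension(net, e.args[0], int(e.args[1]),
                                 int(e.args[2]),
                                 (int(e.args[3]), e.args[4]))
            else:
                raise AssignmentError(f"unknown operation {e.op!r}")
        except AssignmentError as exc:
            raise type(exc)(f"replay step {step}: {exc}") from exc
    return net
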