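"""Synthetic spectra and the scripted greedy assigner.

``simulate_truth`` perturbs predicted shifts with per-nucleus Gaussian
error (the prediction-error model); ``simulate_observed`` turns the
generated peak-boxes into unassigned observed peak lists at the true
positions, with optional missing peaks, spurious peaks and positional
jitter.  ``greedy_assign`` is the scripted, GUI-free surrogate for the
interactive workflow: it freezes peak-boxes whose observed candidate is
unambiguous, propagates frozen coordinates through the network, and
resolves remaining ambiguity clusters by exhaustive consistency over the
whole set of coupled peaks — an individual peak may be ambiguous, the
coupled set usually is not.  It never guesses: components admitting more
than one consistent placement are left unfrozen (notably prochiral
geminal pairs, which cannot be stereospecifically assigned from peak
positions alone).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .network import (AssignmentNetwork, freeze_atom, move_atom,
                      tweak_and_freeze)
from .shifts import ShiftRecord, ShiftTable

#: prediction-error model (ppm), per element
DEFAULT_SIGMA = {"H": 0.15, "C": 0.8, "N": 1.5}
#: observed-position noise (ppm), per element
DEFAULT_JITTER = {"H": 0.005, "C": 0.05, "N": 0.05}
#: candidate capture window for the assigner: 4 sigma of the error model
CAPTURE_TOLERANCE = {"H": 0.6, "C": 3.2, "N": 6.0}


@dataclass
class SimConfig:
    seed: int = 0
    sigma_ppm: dict = None
    p_missing: float = 0.05
    n_extra: int = 5
    jitter_ppm: dict = None

    def __post_init__(self):
        if self.sigma_ppm is None:
            self.sigma_ppm = dict(DEFAULT_SIGMA)
        if self.jitter_ppm is None:
            self.jitter_ppm = dict(DEFAULT_JITTER)
        if not 0.0 <= self.p_missing <= 1.0:
            raise ValueError("p_missing must be in [0, 1]")
        if self.n_extra < 0:
            raise ValueError("n_extra must be >= 0")
        if any(s < 0 for s in self.sigma_ppm.values()):
            raise ValueError("sigmas must be >= 0")
        if any(s < 0 for s in self.jitter_ppm.values()):
            raise ValueError("jitters must be >= 0")


def simulate_truth(shifts: ShiftTable, config: SimConfig) -> ShiftTable:
    """Ground-truth shift table: prediction + Gaussian(0, sigma_nucleus).

    Deterministic in ``config.seed``; atoms are perturbed in sorted key
    order so the draw for a given atom does not depend on dict order.
    """
    rng = np.random.default_rng([config.seed, 0])
    truth = ShiftTable()
    for key in sorted(shifts.records):
        rec = shifts.records[key]
        sigma = config.sigma_ppm.get(rec.element, 0.0)
        true_ppm = rec.predicted_ppm + (rng.normal(0.0, sigma) if sigma > 0
                                        else 0.0)
        truth.records[key] = ShiftRecord(
            key, rec.element, rec.predicted_ppm, true_ppm, source=rec.source)
    return truth


def simulate_observed(peaklists: dict, truth: ShiftTable,
                      config: SimConfig) -> dict:
    """Observed peak lists (positions only, shuffled, unassigned).

    For each generated peak-box a peak is emitted with probability
    ``1 - p_missing`` at the truth positions of its atoms plus jitter;
    ``n_extra`` spurious peaks are appended uniformly inside the observed
    bounding box of each experiment.
    """
    rng = np.random.default_rng([config.seed, 1])
    observed = {}
    for exp in sorted(peaklists):
        peaks = []
        for box in peaklists[exp]:
            if box.status != "predicted":
                continue
            if any(d.atom_key is None for d in box.dims):
                continue
            pos = []
            for d in box.dims:
                rec = truth.records[d.atom_key]
                jit = config.jitter_ppm.get(rec.element, 0.0)
                pos.append(rec.current_ppm
                           + (rng.normal(0.0, jit) if jit > 0 else 0.0))
            if rng.random() < 1.0 - config.p_missing:
                peaks.append(tuple(pos))
        if peaks and config.n_extra:
            arr = np.asarray(peaks)
            lo, hi = arr.min(axis=0), arr.max(axis=0)
            for _ in range(config.n_extra):
                peaks.append(tuple(rng.uniform(lo, hi)))
        order = rng.permutation(len(peaks))
        observed[exp] = [peaks[i] for i in order]
    return observed


# ---------------------------------------------------------------------------
# Scripted assignment
# ---------------------------------------------------------------------------

class _Abort(Exception):
    pass


class _PeakGrid:
    """Spatial hash over one experiment's observed peaks for fast
    exact-coincidence queries."""

    def __init__(self, obs, cell: float):
        self.obs = obs
        self.cell = max(cell, 1e-9)
        self.map = {}
        for j, (x, y) in enumerate(obs):
            key = (math.floor(x / self.cell), math.floor(y / self.cell))
            self.map.setdefault(key, []).append(j)

    def near(self, x: float, y: float, eps: float, claimed) -> list:
        cx, cy = math.floor(x / self.cell), math.floor(y / self.cell)
        hits = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for j in self.map.get((cx + dx, cy + dy), ()):
                    if j in claimed:
                        continue
                    px, py = self.obs[j]
                    if abs(px - x) <= eps and abs(py - y) <= eps:
                        hits.append(j)
        return hits


def _cluster(values, eps: float) -> list:
    out = []
    run = []
    for v in sorted(values):
        if run and v - run[-1] > eps:
            out.append(sum(run) / len(run))
            run = []
        run.append(v)
    if run:
        out.append(sum(run) / len(run))
    return out


@dataclass
class _Problem:
    """Working state shared by the assigner stages."""

    net: AssignmentNetwork
    observed: dict
    tol: dict                         # element -> capture window (ppm)
    eps: float                        # coincidence tolerance (ppm)
    claimed: dict = field(default_factory=dict)
    grids: dict = field(default_factory=dict)
    obs_arr: dict = field(default_factory=dict)

    def __post_init__(self):
        for exp, obs in self.observed.items():
            self.claimed[exp] = set()
            self.grids[exp] = _PeakGrid(obs, cell=max(2 * self.eps, 1e-4))
            self.obs_arr[exp] = (np.asarray(obs, dtype=float)
                                 if obs else np.empty((0, 2)))

    def element(self, key) -> str:
        return self.net.shifts[key].element

    def live_boxes(self):
        for (exp, pid), box in sorted(self.net.peaks.items()):
            if box.status != "predicted":
                continue
            if any(d.atom_key is None for d in box.dims):
                continue
            yield exp, box

    def edge(self, exp, x, y) -> bool:
        return bool(self.grids[exp].near(x, y, self.eps, self.claimed[exp]))

    def claim_frozen(self) -> None:
        """Associate fully frozen boxes with the observed peak at their
        exact position, removing it from further candidate searches."""
        for exp, box in self.live_boxes():
            if not all(d.frozen for d in box.dims):
                continue
            hits = self.grids[exp].near(box.dims[0].ppm, box.dims[1].ppm,
                                        self.eps, self.claimed[exp])
            if hits:
                self.claimed[exp].add(hits[0])


def _box_candidates(prob: _Problem, exp, box) -> list:
    """Observed candidates consistent with frozen dims and tolerances."""
    arr = prob.obs_arr[exp]
    if not len(arr):
        return []
    mask = np.ones(len(arr), dtype=bool)
    for d, dim in enumerate(box.dims):
        window = (prob.eps if dim.frozen
                  else prob.tol[prob.element(dim.atom_key)])
        mask &= np.abs(arr[:, d] - dim.ppm) <= window
    return [j for j in np.nonzero(mask)[0] if j not in prob.claimed[exp]]


def _stage_exact(prob: _Problem) -> bool:
    """Freeze boxes already sitting exactly on an observed peak.

    Only fires on coincidences within the (tiny) coincidence tolerance —
    in practice when predictions are error-free — and makes the
    degenerate observed == predicted case converge immediately."""
    changed = False
    for exp, box in list(prob.live_boxes()):
        if all(d.frozen for d in box.dims):
            continue
        hits = prob.grids[exp].near(box.dims[0].ppm, box.dims[1].ppm,
                                    prob.eps, prob.claimed[exp])
        if not hits:
            continue
        pos = prob.observed[exp][hits[0]]
        tolerances = [prob.tol[prob.element(d.atom_key)] for d in box.dims]
        tweak_and_freeze(prob.net, exp, box.id, [pos],
                         tolerances=tolerances, frozen_eps=prob.eps)
        prob.claimed[exp].add(hits[0])
        changed = True
    if changed:
        prob.claim_frozen()
    return changed


def _stage_unique(prob: _Problem) -> bool:
    """Freeze every box with exactly one observed candidate; repeat to a
    fixed point.  Frozen dimensions restrict candidates to an exact
    coordinate, so each freeze typically unlocks its neighbours."""
    any_change = False
    changed = True
    while changed:
        changed = False
        for exp, box in list(prob.live_boxes()):
            if all(d.frozen for d in box.dims):
                continue
            cand = _box_candidates(prob, exp, box)
            if len(cand) != 1:
                continue
            pos = prob.observed[exp][cand[0]]
            tolerances = [prob.tol[prob.element(d.atom_key)]
                          for d in box.dims]
            tweak_and_freeze(prob.net, exp, box.id, [pos],
                             tolerances=tolerances, frozen_eps=prob.eps)
            prob.claimed[exp].add(cand[0])
            prob.claim_frozen()
            changed = True
            any_change = True
    return any_change


# -- exhaustive consistency over ambiguity clusters -------------------------

def _twin_atoms(net: AssignmentNetwork) -> set:
    """Prochiral/equivalent proton groups (>=2 protons on one heavy atom):
    indistinguishable from peak positions, excluded from the solver."""
    mol = net.molecule
    twins = set()
    by_heavy = {}
    for atom in mol.protons():
        heavies = [b for b in mol.bonded(atom) if b.element != "H"]
        if heavies:
            by_heavy.setdefault(heavies[0].key, []).append(atom.key)
    for group in by_heavy.values():
        if len(group) >= 2:
            twins.update(group)
    return twins


def _solver_problem(prob: _Problem):
    """Variables, usable constraint boxes and per-variable domains."""
    net = prob.net
    twins = _twin_atoms(net)
    vars_ = {k for k in net.networked_atoms()
             if not net.is_frozen(k) and k not in twins}
    while True:
        usable = []
        counts = {v: 0 for v in vars_}
        for exp, box in prob.live_boxes():
            keys = [d.atom_key for d in box.dims]
            ok = all(net.is_frozen(k) or k in vars_ for k in keys)
            if not ok:
                continue
            if all(net.is_frozen(k) for k in keys):
                continue
            usable.append((exp, box))
            for k in keys:
                if k in vars_:
                    counts[k] += 1
        dead = {v for v, c in counts.items() if c == 0}
        if not dead:
            break
        vars_ -= dead

    domains = {}
    for v in vars_:
        pred = net.shifts[v].current_ppm
        window = prob.tol[prob.element(v)]
        vals = []
        for exp, box in usable:
            for d, dim in enumerate(box.dims):
                if dim.atom_key != v:
                    continue
                arr = prob.obs_arr[exp]
                col = arr[:, d]
                for j in np.nonzero(np.abs(col - pred) <= window)[0]:
                    if j not in prob.claimed[exp]:
                        vals.append(float(col[j]))
        domains[v] = _cluster(vals, 2 * prob.eps)
    return vars_, usable, domains


def _components(vars_, usable):
    parent = {v: v for v in vars_}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for exp, box in usable:
        keys = [d.atom_key for d in box.dims if d.atom_key in parent]
        for a, b in zip(keys, keys[1:]):
            parent[find(a)] = find(b)
    comps = {}
    for v in vars_:
        comps.setdefault(find(v), set()).add(v)
    return list(comps.values())


def _solve_component(prob: _Problem, comp, usable, domains,
                     node_cap: int, max_solutions: int):
    """Enumerate consistent placements of one ambiguity cluster.

    Strict mode: every predicted box must sit on an observed peak
    (exact-coincidence edge).  Returns (completed, solutions) where each
    solution maps atom -> value; zero solutions means peaks are missing
    and the cluster is handed to the support-based stage instead.
    """
    net = prob.net
    boxes = []
    for exp, box in usable:
        keys = [d.atom_key for d in box.dims]
        if any(k in comp for k in keys):
            boxes.append((exp, box, keys))

    nodes = [0]
    solutions = []
    used: dict = {}      # (exp, peak_index) -> consumed by a box

    def consume(exp, x, y):
        """Reserve one unconsumed observed peak at this exact position.
        Peak-level injectivity: two boxes may share a coordinate but not
        an observed peak, which rules out degenerate many-to-one
        collapses while allowing genuinely overlapped positions."""
        for j in prob.grids[exp].near(x, y, prob.eps, prob.claimed[exp]):
            if (exp, j) not in used:
                used[(exp, j)] = True
                return (exp, j)
        return None

    def dfs(domains_now, assigned):
        nodes[0] += 1
        if nodes[0] > node_cap:
            raise _Abort
        todo = [v for v in comp if v not in assigned]
        if not todo:
            solutions.append(dict(assigned))
            if len(solutions) >= max_solutions:
                raise _Abort
            return
        var = min(todo, key=lambda v: len(domains_now[v]))
        for val in domains_now[var]:
            assigned[var] = val
            tokens = []
            feasible = True
            # boxes with both endpoints now known must each consume a peak
            for exp, box, keys in boxes:
                if var not in keys:
                    continue
                coords = []
                for k in keys:
                    if net.is_frozen(k):
                        coords.append(net.shifts[k].current_ppm)
                    elif k in assigned:
                        coords.append(assigned[k])
                    else:
                        coords.append(None)
                if None in coords:
                    continue
                token = consume(exp, coords[0], coords[1])
                if token is None:
                    feasible = False
                    break
                tokens.append(token)
            if feasible:
                # forward restriction: values of unassigned partners must
                # keep an exact-coincidence edge with the new value
                new_domains = {}
                ok = True
                for v2 in todo:
                    if v2 == var:
                        continue
                    dom = domains_now[v2]
                    for exp, box, keys in boxes:
                        if var not in keys or v2 not in keys:
                            continue
                        d_var = keys.index(var)
                        dom = [w for w in dom
                               if prob.edge(exp,
                                            *((val, w) if d_var == 0
                                              else (w, val)))]
                    if not dom:
                        ok = False
                        break
                    new_domains[v2] = dom
                if ok:
                    for v2 in todo:
                        if v2 != var and v2 not in new_domains:
                            new_domains[v2] = domains_now[v2]
                    dfs(new_domains, assigned)
            for token in tokens:
                used.pop(token, None)
            del assigned[var]

    try:
        dfs({v: domains[v] for v in comp}, {})
        return True, solutions
    except _Abort:
        return False, solutions


def _stage_clusters(prob: _Problem, node_cap: int,
                    max_solutions: int) -> bool:
    vars_, usable, domains = _solver_problem(prob)
    if not vars_:
        return False
    changed = False
    for comp in sorted(_components(vars_, usable), key=sorted):
        if any(not domains[v] for v in comp):
            continue
        completed, sols = _solve_component(
            prob, comp, usable, domains, node_cap, max_solutions)
        if not completed or not sols:
            continue
        first = sols[0]
        agreed = {v: first[v] for v in comp
                  if all(abs(s[v] - first[v]) <= 2 * prob.eps
                         for s in sols[1:])}
        if not agreed:
            continue
        for v in sorted(agreed):
            move_atom(prob.net, v, agreed[v])
            freeze_atom(prob.net, v)
        prob.claim_frozen()
        changed = True
    return changed


def _stage_support(prob: _Problem) -> bool:
    """Best-supported-value propagation for spectra with missing peaks.

    When exhaustive consistency is impossible (some predicted boxes have
    no observed counterpart), each candidate value is scored by how many
    of the atom's boxes it can explain given the partners' remaining
    candidates; dominated values are pruned and atoms whose domain
    reduces to a single best-supported value are frozen there.  This is
    a maximum-support heuristic: unlike the exact stages it can misplace
    an atom, which the recovery report measures."""
    net = prob.net
    vars_, usable, domains = _solver_problem(prob)
    if not vars_:
        return False
    boxes_of = {v: [] for v in vars_}
    for exp, box in usable:
        keys = [d.atom_key for d in box.dims]
        for d, k in enumerate(keys):
            if k in boxes_of:
                boxes_of[k].append((exp, d, keys[1 - d]))
    changed_any = False
    changed = True
    while changed:
        changed = False
        edge_cache: dict = {}

        def edge(exp, x, y):
            key = (exp, round(x, 7), round(y, 7))
            if key not in edge_cache:
                edge_cache[key] = prob.edge(exp, x, y)
            return edge_cache[key]

        for v in sorted(vars_):
            if net.is_frozen(v) or not domains[v]:
                continue
            support = []
            for val in domains[v]:
                s = 0
                for exp, d, other in boxes_of[v]:
                    if other is None:
                        continue
                    if net.is_frozen(other):
                        partner_vals = [net.shifts[other].current_ppm]
                    else:
                        partner_vals = domains.get(other, [])
                    for w in partner_vals:
                        xy = (val, w) if d == 0 else (w, val)
                        if edge(exp, xy[0], xy[1]):
                            s += 1
                            break
                support.append(s)
            smax = max(support)
            best = [val for val, s in zip(domains[v], support) if s == smax]
            if len(best) < len(domains[v]):
                domains[v] = best
                changed = True
            if len(best) == 1 and smax >= 1:
                move_atom(net, v, best[0])
                freeze_atom(net, v)
                changed = True
                changed_any = True
        if changed_any:
            prob.claim_frozen()
    return changed_any


def greedy_assign(net: AssignmentNetwork, observed: dict,
                  tolerances: dict | None = None,
                  coincidence_eps: float = 1e-6,
                  truth: ShiftTable | None = None,
                  compare_tol: float = 1e-4,
                  node_cap: int = 50_000,
                  max_solutions: int = 6,
                  heuristic: bool = False) -> dict:
    """Scripted assignment to a fixed point; returns a recovery report.

    ``tolerances`` (per element, ppm) is the capture window for
    candidate observed peaks around predicted positions; the default is
    four sigma of the prediction-error model.  ``coincidence_eps`` is
    the coordinate agreement tolerance for peaks sharing an atom — for
    jittered observations pass a few times the jitter sigma.

    The report gives the fraction of networked atoms frozen and, when
    ``truth`` is supplied, the fraction of frozen atoms whose final
    shift matches the ground truth within ``compare_tol``.

    ``heuristic=True`` additionally enables the best-supported-value
    stage, which can bootstrap assignment when peaks are missing but may
    misassign; by default only the exact stages run, so ambiguity and
    incomplete peak sets leave atoms unfrozen rather than wrongly frozen.
    """
    tol = dict(CAPTURE_TOLERANCE)
    if tolerances:
        tol.update(tolerances)
    prob = _Problem(net, observed, tol, coincidence_eps)
    prob.claim_frozen()
    progress = True
    while progress:
        progress = _stage_exact(prob)
        progress = _stage_unique(prob) or progress
        if not progress:
            progress = _stage_clusters(prob, node_cap, max_solutions)
        if not progress and heuristic:
            progress = _stage_support(prob)
    networked = net.networked_atoms()
    frozen = [k for k in networked if net.is_frozen(k)]
    report = {
        "n_networked": len(networked),
        "n_frozen": len(frozen),
        "frozen_fraction": (len(frozen) / len(networked)
                            if networked else 0.0),
        "n_ops": len(net.oplog),
    }
    if truth is not None:
        good = sum(
            1 for k in frozen
            if abs(net.shifts[k].current_ppm
                   - truth.records[k].current_ppm) <= compare_tol)
        report["n_correct"] = good
        report["accuracy"] = good / len(frozen) if frozen else 1.0
    return report
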