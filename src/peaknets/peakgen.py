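"""Pre-assigned peak-box generation for TOCSY/COSY, HMQC and NOESY.

Every generated peak-box carries an atom assignment per dimension and is
positioned at the assigned atom's current predicted shift, so the output
of these generators is a fully assigned network before any spectrum has
been inspected.  Isotope edit-filters (13C/15N-filtered or -rejected
dimensions) and 2H labeling are applied to mirror what a labeled sample
would show.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .topology import Molecule, SecondaryStructure, Atom
from .shifts import ShiftTable

log = logging.getLogger(__name__)

NUCLEUS_ELEMENT = {"1H": "H", "13C": "C", "15N": "N"}

#: default per-dimension matching tolerances (ppm) by nucleus
DEFAULT_TOLERANCE = {"1H": 0.05, "13C": 0.5, "15N": 0.5}


@dataclass
class DimSpec:
    nucleus: str                  # "1H" | "13C" | "15N"
    filter: str = "none"          # none | require_13C_bonded |
                                  # require_15N_bonded | reject_13C_bonded


@dataclass
class ExperimentScheme:
    name: str
    dims: list                    # [DimSpec, DimSpec]
    transfer: str                 # "tocsy" | "onebond_hc" | "noesy"
    max_steps: int | None = None  # tocsy only; None = unlimited
    tolerances: list = None       # per-dim ppm

    def __post_init__(self):
        if len(self.dims) != 2:
            raise ValueError("only 2D experiments are supported")
        if self.tolerances is None:
            self.tolerances = [DEFAULT_TOLERANCE[d.nucleus]
                               for d in self.dims]


@dataclass
class Dim:
    atom_key: tuple | None        # None for unassigned (manual) dims
    ppm: float
    frozen: bool = False


@dataclass
class PeakBox:
    id: int
    experiment: str
    dims: list                    # [Dim, Dim]
    status: str = "predicted"     # predicted | manual | deleted
    origin: str = "jcoupling"

    @property
    def atom_keys(self) -> tuple:
        return tuple(d.atom_key for d in self.dims)


def _make_box(pid, scheme, atoms, shifts, origin) -> PeakBox | None:
    dims = []
    for atom in atoms:
        rec = shifts.get(atom.key)
        if rec is None:
            return None
        dims.append(Dim(atom.key, rec.current_ppm))
    return PeakBox(pid, scheme.name, dims, origin=origin)


def _dedupe(peaks: list) -> list:
    seen = set()
    out = []
    for p in peaks:
        key = (p.experiment, p.atom_keys)
        if key in seen:
            continue
        seen.add(key)
        out.append(p)
    return out


# ---------------------------------------------------------------------------
# Scalar-coupled experiments
# ---------------------------------------------------------------------------

def j_coupling_graph(mol: Molecule, include_exchangeable: bool = False):
    """Graph of protons with one edge per J-coupling step.

    A step links two protons separated by 2 (geminal) or 3 (vicinal)
    covalent bonds, i.e. protons on the same or on directly bonded heavy
    atoms — the standard spin-system connectivity.  Deuterated positions
    are absent from the graph.
    """
    g = nx.Graph()
    protons = [a for a in mol.protons()
               if include_exchangeable or not a.exchangeable]
    heavy_of = {}
    for h in protons:
        g.add_node(h.key)
        heavies = [b for b in mol.bonded(h) if b.element != "H"]
        if heavies:
            heavy_of[h.key] = heavies[0].key
    for i, a in enumerate(protons):
        ha = heavy_of.get(a.key)
        if ha is None:
            continue
        for b in protons[i + 1:]:
            hb = heavy_of.get(b.key)
            if hb is None:
                continue
            if ha == hb or mol.graph.has_edge(ha, hb):
                g.add_edge(a.key, b.key)
    return g


def gen_tocsy(mol: Molecule, shifts: ShiftTable, scheme: ExperimentScheme,
              include_exchangeable: bool = False) -> list:
    """Peak-boxes for proton pairs within ``max_steps`` J-coupling steps.

    Both (a, b) and (b, a) are emitted, matching the symmetry of the
    homonuclear 2D experiment.  ``max_steps=None`` relays through the
    whole spin system (the full ribose, for RNA).
    """
    if scheme.transfer != "tocsy":
        raise ValueError("scheme.transfer must be 'tocsy'")
    if scheme.max_steps is not None and scheme.max_steps < 1:
        return []
    g = j_coupling_graph(mol, include_exchangeable)
    peaks = []
    pid = 0
    for a_key in sorted(g.nodes):
        reach = nx.single_source_shortest_path_length(
            g, a_key, cutoff=scheme.max_steps)
        for b_key, steps in sorted(reach.items()):
            if steps == 0:
                continue
            box = _make_box(pid, scheme,
                            (mol.atom_by_key(a_key), mol.atom_by_key(b_key)),
                            shifts, "jcoupling")
            if box is not None:
                peaks.append(box)
                pid += 1
    return _dedupe(peaks)


def gen_cosy(mol: Molecule, shifts: ShiftTable, scheme: ExperimentScheme,
             include_exchangeable: bool = False) -> list:
    """COSY = TOCSY limited to a single transfer step."""
    import dataclasses
    one_step = dataclasses.replace(scheme, max_steps=1,
                                   tolerances=list(scheme.tolerances))
    one_step.transfer = "tocsy"
    return gen_tocsy(mol, shifts, one_step, include_exchangeable)


def gen_hmqc(mol: Molecule, shifts: ShiftTable,
             scheme: ExperimentScheme) -> list:
    """One peak-box per directly bonded H-C pair.

    Methylene/methyl protons give separate boxes sharing the carbon
    dimension.  Dimension order follows the scheme (1H dim, 13C dim).
    """
    if scheme.transfer != "onebond_hc":
        raise ValueError("scheme.transfer must be 'onebond_hc'")
    nuclei = [d.nucleus for d in scheme.dims]
    if sorted(nuclei) != ["13C", "1H"]:
        raise ValueError("HMQC scheme needs one 1H and one 13C dimension")
    h_first = nuclei[0] == "1H"
    peaks = []
    pid = 0
    for h in mol.protons():
        carbons = [b for b in mol.bonded(h) if b.element == "C"]
        for c in carbons:
            atoms = (h, c) if h_first else (c, h)
            box = _make_box(pid, scheme, atoms, shifts, "onebond")
            if box is not None:
                peaks.append(box)
                pid += 1
    return _dedupe(peaks)


# ---------------------------------------------------------------------------
# NOESY from 3D coordinates
# ---------------------------------------------------------------------------

def gen_noesy_structure(mol: Molecule, shifts: ShiftTable,
                        scheme: ExperimentScheme, coords: dict,
                        cutoff: float = 5.0,
                        include_exchangeable: bool = True,
                        max_missing_fraction: float = 0.5) -> list:
    """Peak-boxes for all proton pairs closer than ``cutoff`` (Å).

    ``coords`` maps atom keys to 3-vectors.  Protons without coordinates
    are skipped with a warning; if more than ``max_missing_fraction`` of
    protons lack coordinates the name matching is considered broken and
    an error is raised.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    protons = [a for a in mol.protons()
               if include_exchangeable or not a.exchangeable]
    have = [a for a in protons if a.key in coords]
    missing = [a for a in protons if a.key not in coords]
    if protons and len(missing) / len(protons) > max_missing_fraction:
        raise ValueError(
            f"{len(missing)}/{len(protons)} protons have no coordinates; "
            f"atom naming mismatch between topology and structure?")
    for a in missing:
        log.warning("no coordinates for %s; skipped in NOESY generation", a)
    if len(have) < 2:
        return []
    xyz = np.asarray([coords[a.key] for a in have], dtype=float)
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    peaks = []
    pid = 0
    for i, j in sorted(map(tuple, pairs)):
        if not np.linalg.norm(xyz[i] - xyz[j]) < cutoff:   # strict <
            continue
        for a, b in ((have[i], have[j]), (have[j], have[i])):
            box = _make_box(pid, scheme, (a, b), shifts, "noe_structure")
            if box is not None:
                peaks.append(box)
                pid += 1
    return _dedupe(peaks)


# ---------------------------------------------------------------------------
# NOESY from secondary-structure rules
# ---------------------------------------------------------------------------

@dataclass
class NoeRule:
    context: str                  # intra | helix_sequential |
                                  # helix_crossstrand | helix_pair_adjacent |
                                  # tetraloop
    pattern1: str
    pattern2: str
    offset: str                   # "0" | "+1" | "partner+1" | "+1pair"


def load_noe_rules(path=None) -> list:
    if path is None:
        text = resources.files("peaknets.data").joinpath(
            "noe_rules.tsv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    rules = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].rstrip()
        if not line:
            continue
        f = line.split("\t")
        if len(f) != 4:
            raise ValueError(f"malformed NOE rule line: {raw!r}")
        rules.append(NoeRule(*f))
    return rules


def _resolve_pattern(mol: Molecule, residue_index: int, pattern: str):
    """Resolve an atom-name pattern against one residue; None if absent."""
    resname = mol.residue_name(residue_index)
    if "@" in pattern:
        name, rtype = pattern.split("@", 1)
        if resname != rtype:
            return None
        pattern = name
    if pattern == "AROM":
        pattern = "H8" if resname in ("A", "G") else "H6"
    elif pattern == "IMINO":
        if resname == "G":
            pattern = "H1"
        elif resname == "U":
            pattern = "H3"
        else:
            return None
    if not mol.has_atom(residue_index, pattern):
        return None
    atom = mol.atom(residue_index, pattern)
    if atom.deuterated:
        return None
    return atom


def gen_noesy_rules(mol: Molecule, ss: SecondaryStructure,
                    shifts: ShiftTable, scheme: ExperimentScheme,
                    rules: list | None = None,
                    include_exchangeable: bool = True) -> list:
    """Expand the NOE rule set over the secondary-structure segments.

    Produces intra-residue boxes everywhere, sequential and cross-strand
    boxes inside helices, imino-imino boxes between stacked pairs, and
    the sequential walk through tetraloops (loop plus closing pair).
    Symmetric partners are emitted for every box.
    """
    if rules is None:
        rules = load_noe_rules()
    n = len(mol.residues)
    helix_strands = []
    for run in ss.helices:
        left = [i for i, _ in run]
        right = [j for _, j in reversed(run)]
        helix_strands.extend([left, right])

    pairs_list: list[tuple[Atom, Atom, str]] = []
    for rule in rules:
        hits = 0
        for r1, r2 in _rule_residue_pairs(rule, ss, helix_strands, n):
            a = _resolve_pattern(mol, r1, rule.pattern1)
            b = _resolve_pattern(mol, r2, rule.pattern2)
            if a is None or b is None or a.key == b.key:
                continue
            if not include_exchangeable and (a.exchangeable
                                             or b.exchangeable):
                continue
            origin = {"intra": "noe_intra"}.get(rule.context, "noe_rule")
            pairs_list.append((a, b, origin))
            hits += 1
        if hits == 0:
            log.warning("NOE rule %s %s/%s matched no atoms; skipped",
                        rule.context, rule.pattern1, rule.pattern2)

    peaks = []
    pid = 0
    for a, b, origin in pairs_list:
        for x, y in ((a, b), (b, a)):
            box = _make_box(pid, scheme, (x, y), shifts, origin)
            if box is not None:
                peaks.append(box)
                pid += 1
    return _dedupe(peaks)


def _rule_residue_pairs(rule, ss, helix_strands, n):
    """Yield (residue1, residue2) index pairs a rule applies to."""
    if rule.context == "intra":
        for i in range(1, n + 1):
            yield (i, i)
    elif rule.context == "helix_sequential":
        for strand in helix_strands:
            for i in strand:
                if i + 1 in strand:
                    yield (i, i + 1)
    elif rule.context == "helix_crossstrand":
        for run in ss.helices:
            for i, j in run:
                for a, b in ((i, j), (j, i)):
                    if b + 1 <= n:
                        yield (a, b + 1)
    elif rule.context == "helix_pair_adjacent":
        for run in ss.helices:
            for (i1, j1), (i2, j2) in zip(run, run[1:]):
                for a in (i1, j1):
                    for b in (i2, j2):
                        yield (a, b)
    elif rule.context == "tetraloop":
        for seg in ss.tetraloops():
            walk = list(range(seg.start - 1, seg.end + 2))  # closing pair
            for i, j in zip(walk, walk[1:]):
                yield (i, j)
    else:
        raise ValueError(f"unknown NOE rule context {rule.context!r}")


# ---------------------------------------------------------------------------
# Isotope edit-filters
# ---------------------------------------------------------------------------

def _dim_predicate(mol: Molecule, atom_key, isotope: str) -> bool:
    """True when the dimension's signal carries the heteronucleus label:
    the atom itself if it is of that element, otherwise via its directly
    bonded heteroatom (the one-bond filter acts through 1J coupling)."""
    atom = mol.atom_by_key(atom_key)
    element = {"13C": "C", "15N": "N"}[isotope]
    if atom.element == element:
        return atom.is_labeled(isotope)
    return any(b.element == element and b.is_labeled(isotope)
               for b in mol.bonded(atom))


def filter_peaks(peaks: list, scheme: ExperimentScheme,
                 mol: Molecule) -> list:
    """Apply per-dimension isotope edit-filters; deuterated protons are
    always dropped (the signal simply is not there)."""
    out = []
    for p in peaks:
        keep = True
        for dim, spec in zip(p.dims, scheme.dims):
            if dim.atom_key is None:
                continue
            atom = mol.atom_by_key(dim.atom_key)
            if atom.deuterated:
                keep = False
                break
            if spec.filter == "none":
                continue
            if spec.filter == "require_13C_bonded":
                ok = _dim_predicate(mol, dim.atom_key, "13C")
            elif spec.filter == "require_15N_bonded":
                ok = _dim_predicate(mol, dim.atom_key, "15N")
            elif spec.filter == "reject_13C_bonded":
                ok = not _dim_predicate(mol, dim.atom_key, "13C")
            else:
                raise ValueError(f"unknown edit-filter {spec.filter!r}")
            if not ok:
                keep = False
                break
        if keep:
            out.append(p)
    return out
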