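"""Covalent topology for RNA, peptides and generic small molecules.

Molecules are built from sequence using residue templates taken from the
Chemical Component Dictionary (via :mod:`biotite.structure.info`), trimmed
to their in-chain form and joined with the appropriate inter-residue
linkage (phosphodiester for RNA, amide for peptides).  Secondary structure
is parsed from Vienna dot-bracket strings into base pairs plus a
helix/loop segment classification that downstream NOE rules consume.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx
import biotite.structure.info as _ccd_info

RNA_RESIDUES = ("A", "G", "C", "U")
AA3 = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()
AA1_TO_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

#: isotopes tracked on atoms; 2H on a proton means the position is deuterated
ISOTOPES = ("13C", "15N", "2H")

UNREACHABLE = -1


class TopologyError(ValueError):
    """Raised for malformed sequences, structures or residue names."""


@dataclass
class Atom:
    """One named atom of a molecule.

    ``(residue_index, atom_name)`` is the unique key used everywhere else
    in the package (shift tables, peak-box dimensions, networks).
    """

    residue_index: int            # 1-based
    residue_name: str             # "G", "ALA", ...
    atom_name: str                # PDB v3 name, primes as U+0027 ("H5''")
    element: str                  # "H", "C", "N", "O", "P", "S"
    labeled: dict = field(default_factory=dict)       # isotope -> bool
    exchangeable: bool = False

    @property
    def key(self) -> tuple[int, str]:
        return (self.residue_index, self.atom_name)

    def is_labeled(self, isotope: str) -> bool:
        return bool(self.labeled.get(isotope, False))

    @property
    def deuterated(self) -> bool:
        return self.element == "H" and self.is_labeled("2H")

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"{self.residue_name}{self.residue_index}.{self.atom_name}"


class Molecule:
    """Covalent graph of named atoms grouped into numbered residues."""

    def __init__(self, kind: str):
        if kind not in ("rna", "peptide", "generic"):
            raise TopologyError(f"unknown molecule kind {kind!r}")
        self.kind = kind
        self.atoms: list[Atom] = []
        self.residues: list[tuple[int, str]] = []
        self._by_key: dict[tuple[int, str], Atom] = {}
        self.graph = nx.Graph()

    # -- construction -------------------------------------------------
    def add_atom(self, atom: Atom) -> Atom:
        if atom.key in self._by_key:
            raise TopologyError(f"duplicate atom {atom.key}")
        self.atoms.append(atom)
        self._by_key[atom.key] = atom
        self.graph.add_node(atom.key)
        return atom

    def add_bond(self, a: tuple[int, str], b: tuple[int, str]) -> None:
        if a not in self._by_key or b not in self._by_key:
            raise TopologyError(f"bond endpoint missing: {a}-{b}")
        self.graph.add_edge(a, b)

    # -- queries -------------------------------------------------------
    def atom(self, residue_index: int, atom_name: str) -> Atom:
        try:
            return self._by_key[(residue_index, atom_name)]
        except KeyError:
            raise TopologyError(
                f"no atom {atom_name!r} in residue {residue_index}"
            ) from None

    def has_atom(self, residue_index: int, atom_name: str) -> bool:
        return (residue_index, atom_name) in self._by_key

    def atom_by_key(self, key: tuple[int, str]) -> Atom:
        return self.atom(*key)

    @property
    def bonds(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    def bonded(self, atom: Atom) -> list[Atom]:
        return [self._by_key[k] for k in self.graph.neighbors(atom.key)]

    def protons(self, include_deuterated: bool = False) -> list[Atom]:
        return [
            a for a in self.atoms
            if a.element == "H" and (include_deuterated or not a.deuterated)
        ]

    def residue_atoms(self, residue_index: int) -> list[Atom]:
        return [a for a in self.atoms if a.residue_index == residue_index]

    def residue_name(self, residue_index: int) -> str:
        for idx, name in self.residues:
            if idx == residue_index:
                return name
        raise TopologyError(f"no residue {residue_index}")

    def __len__(self) -> int:
        return len(self.atoms)


# ---------------------------------------------------------------------------
# Residue templates (CCD-derived)
# ---------------------------------------------------------------------------

# atoms present only in the free monomer, removed in all polymer contexts
_RNA_MONOMER_ONLY = {"OP3", "HOP3", "HOP2"}
_AA_MONOMER_ONLY = {"OXT", "HXT", "H2"}


@lru_cache(maxsize=None)
def _template(name: str):
    try:
        arr = _ccd_info.residue(name)
    except Exception:
        raise TopologyError(f"unknown residue name {name!r}") from None
    if arr is None:
        raise TopologyError(f"unknown residue name {name!r}")
    names = tuple(str(n) for n in arr.atom_name)
    elements = tuple(str(e).capitalize() for e in arr.element)
    bonds = tuple((names[i], names[j]) for i, j, _ in arr.bonds.as_array())
    return names, elements, bonds


def _normalize_rna_seq(sequence) -> list[str]:
    if isinstance(sequence, str):
        sequence = list(sequence.upper().replace("T", "U"))
    seq = [str(s).upper() for s in sequence]
    for s in seq:
        if s not in RNA_RESIDUES:
            raise TopologyError(f"unknown RNA residue {s!r}")
    return seq


def _normalize_peptide_seq(sequence) -> list[str]:
    if isinstance(sequence, str):
        seq = [AA1_TO_AA3.get(c.upper()) for c in sequence]
        if None in seq:
            bad = sequence[seq.index(None)]
            raise TopologyError(f"unknown amino acid {bad!r}")
        return seq
    seq = [str(s).upper() for s in sequence]
    for s in seq:
        if s not in AA3:
            raise TopologyError(f"unknown amino acid {s!r}")
    return seq


def build_molecule(
    sequence,
    kind: str = "rna",
    *,
    five_prime_phosphate: bool = False,
    cyclic: bool = False,
    connection_table: str | None = None,
) -> Molecule:
    """Instantiate a molecule from sequence and the residue library.

    RNA chains get phosphodiester O3'(i)-P(i+1) linkages and, by default,
    a 5'-OH terminus (set ``five_prime_phosphate`` to keep the 5' phosphate,
    as in a triphosphate-initiated transcript after dephosphorylation the
    OH form is the common case).  Peptides get amide C(i)-N(i+1) linkages;
    ``cyclic`` adds the closing C(n)-N(1) bond and suppresses both termini.
    Generic molecules are read from a connection-table string instead
    (see :func:`parse_connection_table`).
    """
    if kind == "generic":
        if connection_table is None:
            raise TopologyError("generic molecules require a connection table")
        return parse_connection_table(connection_table)
    if not sequence:
        raise TopologyError("empty sequence")
    if kind == "rna":
        seq = _normalize_rna_seq(sequence)
        return _build_rna(seq, five_prime_phosphate)
    if kind == "peptide":
        seq = _normalize_peptide_seq(sequence)
        return _build_peptide(seq, cyclic)
    raise TopologyError(f"unknown molecule kind {kind!r}")


def _default_labels() -> dict:
    return {iso: False for iso in ISOTOPES}


def _add_residue(mol: Molecule, idx: int, resname: str, drop: set) -> None:
    names, elements, bonds = _template(resname)
    keep = [i for i, n in enumerate(names) if n not in drop]
    kept = set()
    for i in keep:
        mol.add_atom(Atom(idx, resname, names[i], elements[i],
                          labeled=_default_labels()))
        kept.add(names[i])
    for a, b in bonds:
        if a in kept and b in kept:
            mol.add_bond((idx, a), (idx, b))


def _build_rna(seq: list[str], five_prime_phosphate: bool) -> Molecule:
    mol = Molecule("rna")
    n = len(seq)
    for i, resname in enumerate(seq, start=1):
        drop = set(_RNA_MONOMER_ONLY)
        if i > 1 or not five_prime_phosphate:
            # no free phosphate protons anywhere; strip P entirely at a 5'-OH
            if i == 1:
                drop |= {"P", "OP1", "OP2"}
        if i < n:
            drop.add("HO3'")  # O3' is esterified to the next phosphate
        mol.residues.append((i, resname))
        _add_residue(mol, i, resname, drop)
        if i == 1 and not five_prime_phosphate:
            mol.add_atom(Atom(1, resname, "HO5'", "H",
                              labeled=_default_labels()))
            mol.add_bond((1, "O5'"), (1, "HO5'"))
        if i > 1:
            mol.add_bond((i - 1, "O3'"), (i, "P"))
    _mark_exchangeable(mol)
    return mol


def _build_peptide(seq: list[str], cyclic: bool) -> Molecule:
    mol = Molecule("peptide")
    n = len(seq)
    for i, resname in enumerate(seq, start=1):
        drop = set(_AA_MONOMER_ONLY)
        if not cyclic and i == 1:
            drop.discard("H2")       # free N-terminal amine keeps both H
        if not cyclic and i == n:
            drop -= {"OXT", "HXT"}   # free carboxy terminus
        mol.residues.append((i, resname))
        _add_residue(mol, i, resname, drop)
        if i > 1:
            mol.add_bond((i - 1, "C"), (i, "N"))
    if cyclic and n > 1:
        mol.add_bond((n, "C"), (1, "N"))
    _mark_exchangeable(mol)
    return mol


def _mark_exchangeable(mol: Molecule) -> None:
    # solvent-exchangeable = proton bonded to N or O (imino, amino, hydroxyl)
    for atom in mol.atoms:
        if atom.element != "H":
            continue
        heavies = mol.bonded(atom)
        atom.exchangeable = any(h.element in ("N", "O") for h in heavies)


# ---------------------------------------------------------------------------
# Generic molecules: connection-table text format
# ---------------------------------------------------------------------------

def parse_connection_table(text: str, residue_name: str = "LIG") -> Molecule:
    """Parse the minimal connection-table format for generic molecules.

    Two sections::

        atoms
        H1 H
        C1 C
        bonds
        H1 C1

    Atom lines are ``name element``; bond lines reference atom names.
    Comments start with '#'.  All atoms go into residue 1.
    """
    mol = Molecule("generic")
    mol.residues.append((1, residue_name))
    section = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower() in ("atoms", "bonds"):
            section = line.lower()
            continue
        fields = line.split()
        if section == "atoms":
            if len(fields) != 2:
                raise TopologyError(
                    f"line {lineno}: atom lines are 'name element'")
            name, element = fields
            mol.add_atom(Atom(1, residue_name, name, element.capitalize(),
                              labeled=_default_labels()))
        elif section == "bonds":
            if len(fields) != 2:
                raise TopologyError(
                    f"line {lineno}: bond lines are 'name name'")
            try:
                mol.add_bond((1, fields[0]), (1, fields[1]))
            except TopologyError as exc:
                raise TopologyError(f"line {lineno}: {exc}") from None
        else:
            raise TopologyError(
                f"line {lineno}: content before 'atoms'/'bonds' header")
    _mark_exchangeable(mol)
    return mol


# ---------------------------------------------------------------------------
# Covalent distance
# ---------------------------------------------------------------------------

def covalent_distance(mol: Molecule, a: Atom, b: Atom) -> int:
    """Number of covalent bonds on the shortest path between two atoms.

    Returns :data:`UNREACHABLE` (-1) for atoms in disconnected components.
    """
    if a.key == b.key:
        return 0
    try:
        return nx.shortest_path_length(mol.graph, a.key, b.key)
    except nx.NetworkXNoPath:
        return UNREACHABLE


# ---------------------------------------------------------------------------
# Secondary structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    kind: str                      # "helix" | "tetraloop" | "loop" | "single"
    start: int                     # 1-based, inclusive
    end: int                       # inclusive


@dataclass
class SecondaryStructure:
    """Base pairs plus derived helix/loop classification."""

    sequence: str
    pairs: set                      # {(i, j)} with i < j, 1-based
    helices: list = field(default_factory=list)   # [[(i,j), ...] stacked runs]
    segments: list = field(default_factory=list)  # [Segment]

    def partner(self, i: int) -> int | None:
        for a, b in self.pairs:
            if a == i:
                return b
            if b == i:
                return a
        return None

    def paired(self, i: int) -> bool:
        return self.partner(i) is not None

    def tetraloops(self) -> list[Segment]:
        return [s for s in self.segments if s.kind == "tetraloop"]

    def to_dotbracket(self) -> str:
        chars = ["."] * len(self.sequence)
        for i, j in self.pairs:
            chars[i - 1] = "("
            chars[j - 1] = ")"
        return "".join(chars)


def parse_dotbracket(sequence: str, dotbracket: str) -> SecondaryStructure:
    """Stack-match a Vienna dot-bracket string into base pairs and segments.

    Only ``.`` and round brackets are accepted; extended bracket levels
    (used elsewhere for pseudoknots) are rejected because the downstream
    helix classification assumes a nested structure.
    """
    if len(sequence) != len(dotbracket):
        raise TopologyError(
            f"sequence length {len(sequence)} != structure length "
            f"{len(dotbracket)}")
    if re.search(r"[\[\]{}<>]", dotbracket):
        raise TopologyError("pseudoknot brackets are not supported")
    bad = set(dotbracket) - set(".()")
    if bad:
        raise TopologyError(f"invalid dot-bracket characters {sorted(bad)}")
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(dotbracket, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise TopologyError(f"unbalanced ')' at position {pos}")
            pairs.add((stack.pop(), pos))
    if stack:
        raise TopologyError(f"unbalanced '(' at position {stack[-1]}")
    ss = SecondaryStructure(sequence=sequence, pairs=pairs)
    _classify(ss)
    return ss


def _classify(ss: SecondaryStructure) -> None:
    n = len(ss.sequence)
    by_i = dict(sorted(ss.pairs))
    # maximal stacks of consecutive pairs
    helices: list[list[tuple[int, int]]] = []
    used: set[tuple[int, int]] = set()
    for i, j in sorted(ss.pairs):
        if (i, j) in used:
            continue
        run = [(i, j)]
        used.add((i, j))
        while (run[-1][0] + 1, run[-1][1] - 1) in ss.pairs:
            nxt = (run[-1][0] + 1, run[-1][1] - 1)
            run.append(nxt)
            used.add(nxt)
        if len(run) >= 2:
            helices.append(run)
    ss.helices = helices

    paired_set = {i for p in ss.pairs for i in p}
    segments: list[Segment] = []
    for run in helices:
        segments.append(Segment("helix", run[0][0], run[-1][0]))
        segments.append(Segment("helix", run[-1][1], run[0][1]))
    # unpaired runs
    pos = 1
    while pos <= n:
        if pos in paired_set:
            pos += 1
            continue
        start = pos
        while pos <= n and pos not in paired_set:
            pos += 1
        end = pos - 1
        left_pair = start - 1 if start > 1 else None
        right_pair = end + 1 if end < n else None
        if (left_pair is not None and right_pair is not None
                and (left_pair, right_pair) in ss.pairs
                and end - start + 1 == 4):
            kind = "tetraloop"
        elif left_pair is None or right_pair is None:
            kind = "single"
        else:
            kind = "loop"
        segments.append(Segment(kind, start, end))
    ss.segments = sorted(segments, key=lambda s: (s.start, s.end))


# ---------------------------------------------------------------------------
# Isotope labeling
# ---------------------------------------------------------------------------

@dataclass
class LabelRule:
    """One labeling rule: which residues, which isotope, which atoms.

    ``selector`` is a residue-type name ("G", "ALA"), the wildcard "*",
    or an explicit set of residue indices.  ``atoms`` is an atom-name
    glob pattern ("H8", "C*", "all").  Later rules override earlier ones.
    """

    selector: object               # str or set[int]
    isotope: str                   # "13C" | "15N" | "2H"
    atoms: str = "all"
    value: bool = True


@dataclass
class LabelingScheme:
    rules: list = field(default_factory=list)

    def add(self, selector, isotope, atoms="all", value=True) -> None:
        self.rules.append(LabelRule(selector, isotope, atoms, value))


def _atom_pattern_match(pattern: str, atom_name: str) -> bool:
    if pattern in ("all", "*"):
        return True
    rx = "^" + re.escape(pattern).replace(r"\*", ".*") + "$"
    return re.match(rx, atom_name) is not None


def apply_labeling(mol: Molecule, scheme: LabelingScheme) -> Molecule:
    """Set isotope-label flags in place per the scheme (rules in order)."""
    known_types = {name for _, name in mol.residues}
    for rule in scheme.rules:
        if rule.isotope not in ISOTOPES:
            raise TopologyError(f"unknown isotope {rule.isotope!r}")
        if isinstance(rule.selector, str):
            if rule.selector != "*" and rule.selector not in known_types:
                raise TopologyError(
                    f"labeling selector {rule.selector!r} matches no "
                    f"residue type in molecule")
            selected = {
                idx for idx, name in mol.residues
                if rule.selector in ("*", name)
            }
        else:
            selected = set(rule.selector)
        element = {"13C": "C", "15N": "N", "2H": "H"}[rule.isotope]
        for atom in mol.atoms:
            if atom.residue_index not in selected:
                continue
            if atom.element != element:
                continue
            if _atom_pattern_match(rule.atoms, atom.atom_name):
                atom.labeled[rule.isotope] = rule.value
    return mol
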