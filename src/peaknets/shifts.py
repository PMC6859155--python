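"""Chemical-shift prediction and the atom assignment table.

The :class:`ShiftTable` is the single source of truth for peak positions:
every peak-box dimension always sits at the *current* shift of its atom.
Predictions come from bundled lookup tables — a context-keyed RNA table
with documented back-off and a residue-average amino-acid table — or from
an external text file produced by third-party prediction software.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .topology import Molecule, SecondaryStructure, Atom

PURINES = {"A", "G"}

#: override precedence for prediction sources (higher wins)
SOURCE_RANK = {"table": 1, "external": 2, "manual": 3}


@dataclass
class ShiftRecord:
    atom_key: tuple
    element: str
    predicted_ppm: float
    current_ppm: float
    frozen: bool = False
    source: str = "table"


@dataclass
class ShiftTable:
    """Atom -> shift record; ``uncovered`` lists assignable atoms without
    any table entry (relevant for non-canonical residues)."""

    records: dict = field(default_factory=dict)
    uncovered: set = field(default_factory=set)

    def __contains__(self, key) -> bool:
        return key in self.records

    def __getitem__(self, key) -> ShiftRecord:
        return self.records[key]

    def get(self, key):
        return self.records.get(key)

    def __len__(self) -> int:
        return len(self.records)

    def set_prediction(self, atom: Atom, ppm: float, source: str = "table"):
        """Install a predicted shift, respecting source precedence
        (manual > external > table) regardless of application order."""
        rec = self.records.get(atom.key)
        if rec is not None and SOURCE_RANK[rec.source] > SOURCE_RANK[source]:
            return rec
        rec = ShiftRecord(atom.key, atom.element, float(ppm), float(ppm),
                          frozen=False, source=source)
        self.records[atom.key] = rec
        return rec

    def frozen_records(self) -> list:
        return [r for r in self.records.values() if r.frozen]


# ---------------------------------------------------------------------------
# Bundled tables
# ---------------------------------------------------------------------------

def _data_text(name: str) -> str:
    return resources.files("peaknets.data").joinpath(name).read_text()


class RnaShiftTableFile:
    """Parsed bundled RNA table: context / pair / residue levels plus
    neighbour deltas and element fallbacks."""

    def __init__(self, text: str):
        self.context: dict = {}     # (window, atom) -> ppm
        self.pair: dict = {}        # (res, paired, atom) -> ppm
        self.residue: dict = {}     # (res, atom) -> ppm
        self.delta: dict = {}       # (direction, cls, atom) -> ppm
        self.element: dict = {}     # element -> ppm
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].rstrip()
            if not line:
                continue
            f = line.split("\t")
            kind = f[0]
            if kind == "context":
                self.context[(f[1], f[2])] = float(f[3])
            elif kind == "pair":
                self.pair[(f[1], f[2] == "paired", f[3])] = float(f[4])
            elif kind == "residue":
                self.residue[(f[1], f[2])] = float(f[3])
            elif kind == "delta":
                self.delta[(f[1], f[2], f[3])] = float(f[4])
            elif kind == "element":
                self.element[f[1]] = float(f[2])


_RNA_TABLE: RnaShiftTableFile | None = None


def _rna_table() -> RnaShiftTableFile:
    global _RNA_TABLE
    if _RNA_TABLE is None:
        _RNA_TABLE = RnaShiftTableFile(_data_text("rna_shifts.tsv"))
    return _RNA_TABLE


_PEPTIDE_TABLE: list | None = None


def _peptide_table() -> list:
    global _PEPTIDE_TABLE
    if _PEPTIDE_TABLE is None:
        rows = []
        for raw in _data_text("peptide_shifts.tsv").splitlines():
            line = raw.split("#", 1)[0].rstrip()
            if not line:
                continue
            res, atom, ppm = line.split("\t")
            rows.append((res, atom, float(ppm)))
        _PEPTIDE_TABLE = rows
    return _PEPTIDE_TABLE


# ---------------------------------------------------------------------------
# RNA prediction
# ---------------------------------------------------------------------------

def rna_context_window(ss: SecondaryStructure, i: int) -> str:
    """Five-character window string, paired residues uppercase, unpaired
    lowercase, '-' past the sequence ends; centre at residue ``i``."""
    n = len(ss.sequence)
    chars = []
    for k in range(i - 2, i + 3):
        if k < 1 or k > n:
            chars.append("-")
        else:
            c = ss.sequence[k - 1].upper()
            chars.append(c if ss.paired(k) else c.lower())
    return "".join(chars)


def _assignable(mol: Molecule) -> list:
    """H/C/N atoms worth predicting: protons that are not hydroxyl/thiol,
    and heavy C/N atoms carrying at least one proton."""
    out = []
    for atom in mol.atoms:
        if atom.element == "H":
            heavy = mol.bonded(atom)
            if any(h.element in ("O", "S") for h in heavy):
                continue
            out.append(atom)
        elif atom.element in ("C", "N"):
            if any(b.element == "H" for b in mol.bonded(atom)):
                out.append(atom)
    return out


def predict_rna(mol: Molecule, ss: SecondaryStructure,
                table: RnaShiftTableFile | None = None) -> ShiftTable:
    """Predict shifts for every assignable atom of an RNA.

    Lookup order per atom: exact five-residue context window; then the
    (residue type, paired) level plus additive neighbour corrections;
    then the residue-type average; finally an element-level fallback, so
    coverage is total by construction.
    """
    if mol.kind != "rna":
        raise ValueError("predict_rna requires an RNA molecule")
    if len(ss.sequence) != len(mol.residues):
        raise ValueError("secondary structure length != molecule length")
    tbl = table if table is not None else _rna_table()
    out = ShiftTable()
    for atom in _assignable(mol):
        i = atom.residue_index
        res = atom.residue_name
        window = rna_context_window(ss, i)
        name = atom.atom_name
        ppm = tbl.context.get((window, name))
        if ppm is None:
            base = tbl.pair.get((res, ss.paired(i), name))
            if base is not None:
                ppm = base + _neighbour_delta(tbl, ss, i, name)
            else:
                ppm = tbl.residue.get((res, name))
        if ppm is None:
            ppm = tbl.element[atom.element]
        out.set_prediction(atom, ppm, source="table")
    return out


def _neighbour_delta(tbl: RnaShiftTableFile, ss: SecondaryStructure,
                     i: int, atom_name: str) -> float:
    d = 0.0
    n = len(ss.sequence)
    if i > 1:
        cls = "purine" if ss.sequence[i - 2].upper() in PURINES else "pyrimidine"
        d += tbl.delta.get(("prev", cls, atom_name), 0.0)
    if i < n:
        cls = "purine" if ss.sequence[i].upper() in PURINES else "pyrimidine"
        d += tbl.delta.get(("next", cls, atom_name), 0.0)
    return d


# ---------------------------------------------------------------------------
# Peptide prediction
# ---------------------------------------------------------------------------

def predict_peptide(mol: Molecule) -> ShiftTable:
    """Residue-average shifts for peptides.

    Atoms of residues (or atom names) missing from the bundled table are
    collected in the returned table's ``uncovered`` set instead of raising,
    so that an external import can fill them in afterwards.
    """
    if mol.kind not in ("peptide", "generic"):
        raise ValueError("predict_peptide requires a peptide molecule")
    rows = _peptide_table()
    exact = {(r, a): p for r, a, p in rows if "*" not in a}
    patterns = [(r, a, p) for r, a, p in rows if "*" in a]
    out = ShiftTable()
    for atom in _assignable(mol):
        key = (atom.residue_name, atom.atom_name)
        ppm = exact.get(key)
        if ppm is None:
            for res, pat, val in patterns:
                if res == atom.residue_name and _glob_match(pat, atom.atom_name):
                    ppm = val
                    break
        if ppm is None:
            out.uncovered.add(atom.key)
            continue
        out.set_prediction(atom, ppm, source="table")
    return out


def _glob_match(pattern: str, name: str) -> bool:
    rx = "^" + re.escape(pattern).replace(r"\*", ".*") + "$"
    return re.match(rx, name) is not None


# ---------------------------------------------------------------------------
# External import
# ---------------------------------------------------------------------------

class ShiftImportError(ValueError):
    pass


def import_shifts(table: ShiftTable, path, mol: Molecule):
    """Overlay externally predicted shifts from a text file.

    Rows are ``residue_index atom_name ppm`` (whitespace-delimited,
    '#' comments).  Rows naming atoms absent from the molecule are
    skipped with a warning; an unparseable ppm aborts with the line
    number.  Returns ``(table, warnings)``.
    """
    warnings: list[str] = []
    text = Path(path).read_text()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 3:
            raise ShiftImportError(
                f"line {lineno}: expected 'residue atom ppm', got {raw!r}")
        idx_s, name, ppm_s = fields
        try:
            idx = int(idx_s)
            ppm = float(ppm_s)
        except ValueError:
            raise ShiftImportError(
                f"line {lineno}: unparseable number in {raw!r}") from None
        if not mol.has_atom(idx, name):
            warnings.append(
                f"line {lineno}: atom {name!r} in residue {idx} not in "
                f"molecule; row skipped")
            continue
        atom = mol.atom(idx, name)
        table.set_prediction(atom, ppm, source="external")
        table.uncovered.discard(atom.key)
    return table, warnings
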