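"""Readers and writers: native TSV peak lists, Sparky .list files,
shift files, NMR-STAR chemical-shift export, FASTA and YAML configs.

The TSV dialect is the lossless native format (id, per-dim assignment,
position, frozen flag).  Sparky .list is supported for interoperability;
it has no frozen column, so that information is dropped on write
(documented lossy).  ppm values print with 4 decimals for 1H and 3 for
heteronuclei, which exceeds every matching tolerance in the package.
"""

from __future__ import annotations

import re
from pathlib import Path

import yaml

from .peakgen import Dim, PeakBox
from .topology import LabelingScheme


class PeakFileError(ValueError):
    pass


def _fmt_ppm(ppm: float, element: str) -> str:
    return f"{ppm:.4f}" if element == "H" else f"{ppm:.3f}"


def _element_of_atom_name(name: str) -> str:
    m = re.match(r"[A-Z]", name)
    if not m:
        raise PeakFileError(f"cannot infer element from atom name {name!r}")
    return name[0]


# ---------------------------------------------------------------------------
# Native TSV peak lists
# ---------------------------------------------------------------------------

_TSV_HEADER = ("id\tstatus\torigin\tres1\tatom1\tppm1\tfrozen1"
               "\tres2\tatom2\tppm2\tfrozen2")


def write_peaks(peaks, path, dialect: str = "tsv",
                experiment: str = "exp", molecule=None) -> None:
    if dialect == "tsv":
        _write_tsv(peaks, path, experiment)
    elif dialect == "sparky_list":
        _write_sparky(peaks, path, molecule)
    else:
        raise PeakFileError(f"unknown dialect {dialect!r}")


def read_peaks(path, dialect: str = "tsv",
               experiment: str = "exp") -> list:
    if dialect == "tsv":
        return _read_tsv(path, experiment)
    if dialect == "sparky_list":
        return _read_sparky(path, experiment)
    raise PeakFileError(f"unknown dialect {dialect!r}")


def _write_tsv(peaks, path, experiment) -> None:
    lines = [f"# peaknets peaks v1\texperiment={experiment}", _TSV_HEADER]
    for p in sorted(peaks, key=lambda b: b.id):
        row = [str(p.id), p.status, p.origin]
        for d in p.dims:
            if d.atom_key is None:
                row += ["?", "?", f"{d.ppm:.4f}", str(int(d.frozen))]
            else:
                elem = _element_of_atom_name(d.atom_key[1])
                row += [str(d.atom_key[0]), d.atom_key[1],
                        _fmt_ppm(d.ppm, elem), str(int(d.frozen))]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def _read_tsv(path, experiment) -> list:
    peaks = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(),
                                 start=1):
        if not raw.strip() or raw.startswith("#") or raw.startswith("id\t"):
            continue
        f = raw.split("\t")
        if len(f) != 11:
            raise PeakFileError(f"line {lineno}: expected 11 columns, "
                                f"got {len(f)}")
        try:
            dims = []
            for res, atom, ppm, frz in (f[3:7], f[7:11]):
                key = None if res == "?" else (int(res), atom)
                dims.append(Dim(key, float(ppm), bool(int(frz))))
            peaks.append(PeakBox(int(f[0]), experiment, dims,
                                 status=f[1], origin=f[2]))
        except ValueError as exc:
            raise PeakFileError(f"line {lineno}: {exc}") from None
    return peaks


# ---------------------------------------------------------------------------
# Sparky .list
# ---------------------------------------------------------------------------

_SPARKY_ASSIGN = re.compile(r"^([A-Za-z]+?)(\d+)(\S+)$")


def _write_sparky(peaks, path, molecule=None) -> None:
    lines = [f"{'Assignment':>17} {'w1':>10} {'w2':>10}", ""]
    for p in sorted(peaks, key=lambda b: b.id):
        toks = []
        for d in p.dims:
            if d.atom_key is None:
                toks.append("?")
            else:
                res_idx, atom = d.atom_key
                letter = (molecule.residue_name(res_idx)
                          if molecule is not None else "X")
                toks.append(f"{letter}{res_idx}{atom}")
        label = "-".join(toks)
        w = [f"{d.ppm:10.4f}" for d in p.dims]
        lines.append(f"{label:>17} {w[0]} {w[1]}")
    Path(path).write_text("\n".join(lines) + "\n")


def _read_sparky(path, experiment, molecule=None) -> list:
    """Read a Sparky peak list.  Assignment tokens are
    ``<residue-letter(s)><number><atom>`` joined by '-', '?' when
    unassigned; residue letters are ignored on input (the number and
    atom name identify the atom)."""
    peaks = []
    pid = 0
    for lineno, raw in enumerate(Path(path).read_text().splitlines(),
                                 start=1):
        line = raw.strip()
        if not line or line.lower().startswith("assignment"):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise PeakFileError(f"line {lineno}: expected label w1 w2")
        label, w1, w2 = fields[0], fields[1], fields[2]
        toks = label.split("-")
        if len(toks) != 2:
            raise PeakFileError(f"line {lineno}: bad assignment {label!r}")
        dims = []
        for tok, w in zip(toks, (w1, w2)):
            try:
                ppm = float(w)
            except ValueError:
                raise PeakFileError(
                    f"line {lineno}: bad position {w!r}") from None
            if tok == "?":
                dims.append(Dim(None, ppm))
                continue
            m = _SPARKY_ASSIGN.match(tok)
            if not m:
                raise PeakFileError(
                    f"line {lineno}: bad assignment token {tok!r}")
            dims.append(Dim((int(m.group(2)), m.group(3)), ppm))
        status = ("manual" if any(d.atom_key is None for d in dims)
                  else "predicted")
        peaks.append(PeakBox(pid, experiment, dims, status=status,
                             origin="user"))
        pid += 1
    return peaks


# ---------------------------------------------------------------------------
# Observed (unassigned) peak lists
# ---------------------------------------------------------------------------

def write_observed(positions, path) -> None:
    """Positions-only TSV (one observed peak per line).

    Six decimals: observed lists feed the assigner, whose propagation
    relies on coordinate coincidences between peaks sharing an atom, so
    the write precision must sit below the coincidence tolerance."""
    lines = ["# peaknets observed v1", "ppm1\tppm2"]
    for pos in positions:
        lines.append("\t".join(f"{x:.6f}" for x in pos))
    Path(path).write_text("\n".join(lines) + "\n")


def read_observed(path) -> list:
    out = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(),
                                 start=1):
        if not raw.strip() or raw.startswith("#") or raw.startswith("ppm"):
            continue
        try:
            out.append(tuple(float(x) for x in raw.split()))
        except ValueError:
            raise PeakFileError(
                f"line {lineno}: unparseable position") from None
    return out


# ---------------------------------------------------------------------------
# Shift files
# ---------------------------------------------------------------------------

def write_shifts(table, path, predicted: bool = False) -> None:
    """Write ``residue atom ppm`` rows (readable by import_shifts)."""
    lines = ["# residue_index atom_name ppm"]
    for key in sorted(table.records):
        rec = table.records[key]
        ppm = rec.predicted_ppm if predicted else rec.current_ppm
        lines.append(f"{key[0]} {key[1]} {_fmt_ppm(ppm, rec.element)}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# NMR-STAR export
# ---------------------------------------------------------------------------

_ISOTOPE = {"H": 1, "C": 13, "N": 15}


def _star_quote(s: str) -> str:
    if re.search(r"[\s'\"]", s):
        return '"' + s + '"'
    return s


def write_star(assignments, path, entry_name: str = "peaknets") -> None:
    """Write an NMR-STAR v3 assigned-chemical-shift save frame.

    ``assignments`` is the ``export_assignments`` output:
    ``[(residue_index, residue_name, atom_name, ppm), ...]``.  Isotope
    numbers are inferred from the element (1H, 13C, 15N).
    """
    lines = [
        f"data_{entry_name}",
        "",
        "save_assigned_chemical_shifts",
        "   _Assigned_chem_shift_list.Sf_category    "
        "assigned_chemical_shifts",
        "   _Assigned_chem_shift_list.Sf_framecode   "
        "assigned_chemical_shifts",
        "",
    ]
    if assignments:
        lines += [
            "   loop_",
            "      _Atom_chem_shift.ID",
            "      _Atom_chem_shift.Comp_index_ID",
            "      _Atom_chem_shift.Comp_ID",
            "      _Atom_chem_shift.Atom_ID",
            "      _Atom_chem_shift.Atom_type",
            "      _Atom_chem_shift.Atom_isotope_number",
            "      _Atom_chem_shift.Val",
            "",
        ]
        for i, (res_idx, res_name, atom, ppm) in enumerate(assignments,
                                                           start=1):
            elem = _element_of_atom_name(atom)
            iso = _ISOTOPE.get(elem, ".")
            lines.append(
                f"      {i} {res_idx} {_star_quote(res_name)} "
                f"{_star_quote(atom)} {elem} {iso} {_fmt_ppm(ppm, elem)}")
        lines += ["   stop_"]
    lines += ["", "save_", ""]
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# FASTA / config
# ---------------------------------------------------------------------------

def read_fasta_single(path) -> tuple:
    """Read one FASTA record (or bare sequence text); a dot-bracket line
    following the sequence (Vienna convention) is returned alongside."""
    seq_lines, db_lines = [], []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith((">", ";")):
            continue
        if set(line) <= set(".()"):
            db_lines.append(line)
        else:
            seq_lines.append(line)
    seq = "".join(seq_lines)
    db = "".join(db_lines) or None
    if not seq:
        raise PeakFileError("no sequence found")
    return seq, db


def load_config(path) -> dict:
    """Load a YAML run configuration.

    Keys: sequence, dotbracket, kind (rna|peptide), cyclic,
    tocsy_max_steps, labeling (list of {selector, isotope, atoms, value}),
    noe_rules (path), tolerances.
    """
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if "labeling" in cfg and cfg["labeling"]:
        scheme = LabelingScheme()
        for rule in cfg["labeling"]:
            selector = rule["selector"]
            if isinstance(selector, list):
                selector = set(int(i) for i in selector)
            scheme.add(selector, str(rule["isotope"]),
                       rule.get("atoms", "all"), bool(rule.get("value", True)))
        cfg["labeling"] = scheme
    else:
        cfg["labeling"] = None
    return cfg
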