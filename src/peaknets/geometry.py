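"""Coordinate input for structure-based NOESY generation.

Real structures come from PDB files (read with gemmi-free, minimal ATOM
parsing is deliberately avoided — we use biotite's PDB reader).  For
tests and demonstrations without a deposited structure there is a
synthetic helical coordinate generator: it places every atom on a
deterministic helix (rise + twist per residue, per-atom radial/angular
offsets derived from a hash of the atom name).  It is *not* a physical
model — distances are plausible in scale only — but it exercises the
distance-cutoff machinery with a fully reproducible geometry.
"""

from __future__ import annotations

import hashlib

import numpy as np

from .topology import Molecule

#: common alternative proton spellings -> PDB v3 names
ATOM_NAME_ALIASES = {
    "H5'1": "H5'", "H5'2": "H5''", "1H5'": "H5'", "2H5'": "H5''",
    "H2'1": "H2'", "HO'2": "HO2'", "H5M1": "H71", "O1P": "OP1",
    "O2P": "OP2",
}


def normalize_atom_name(name: str) -> str:
    name = name.strip().replace("*", "'")
    return ATOM_NAME_ALIASES.get(name, name)


def read_pdb_coords(path, model: int = 1) -> dict:
    """Read per-atom coordinates from a PDB file (first model by default).

    Returns ``{(residue_index, atom_name): ndarray(3)}`` with atom names
    normalized to the package's PDB v3 convention.
    """
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile.read(str(path))
    arr = f.get_structure(model=model)
    coords = {}
    for i in range(arr.array_length()):
        key = (int(arr.res_id[i]), normalize_atom_name(str(arr.atom_name[i])))
        coords[key] = np.asarray(arr.coord[i], dtype=float)
    return coords


def synthetic_helix_coords(mol: Molecule, rise: float = 2.8,
                           twist_deg: float = 32.0,
                           radius: float = 9.0) -> dict:
    """Deterministic pseudo-helical coordinates for every atom.

    Each residue advances by ``rise`` Å along z and ``twist_deg`` degrees
    around it; atoms within a residue are spread by name-hash-derived
    radial, angular and axial offsets so that intra- and sequential-
    residue proton distances fall in the NOE-relevant few-Å range.
    Synthetic stand-in geometry — see module docstring.
    """
    coords = {}
    twist = np.deg2rad(twist_deg)
    for atom in mol.atoms:
        h = hashlib.sha256(atom.atom_name.encode()).digest()
        # offsets in [0, 1) derived from the atom name only, so the same
        # atom sits identically in every residue
        u1, u2, u3 = (h[0] / 256.0, h[1] / 256.0, h[2] / 256.0)
        r = radius - 4.0 * u1
        ang = twist * (atom.residue_index - 1) + 0.9 * u2
        z = rise * (atom.residue_index - 1) + 2.0 * u3
        coords[atom.key] = np.array(
            [r * np.cos(ang), r * np.sin(ang), z])
    return coords
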