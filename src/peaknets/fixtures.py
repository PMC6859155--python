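"""Bundled demonstration systems and the standard experiment set.

Two RNA hairpins (22 and 50 nucleotides, UUCG/GNRA tetraloops) at the
scales typical for network-assignment demonstrations, plus a six-residue
cyclic peptide.  ``standard_rna_network`` wires sequence + dot-bracket
through prediction and peak generation into a ready assignment network
with the usual three-experiment set (2D TOCSY, 1H-13C HMQC, 2D NOESY
from secondary-structure rules).
"""

from __future__ import annotations

from . import peakgen
from .network import AssignmentNetwork, build_network
from .peakgen import DimSpec, ExperimentScheme
from .shifts import predict_peptide, predict_rna
from .topology import (LabelingScheme, apply_labeling, build_molecule,
                       parse_dotbracket)

HAIRPIN22_SEQ = "GGCAGCGUCUUCGGACGCUGCC"
HAIRPIN22_DB = "(((((((((....)))))))))"

HAIRPIN50_SEQ = ("GGUCACGGCAUGCAAUCGGUACG" + "GAAA"
                 + "CGUACCGAUUGCAUGCCGUGACC")
HAIRPIN50_DB = "(" * 23 + "...." + ")" * 23

#: six-residue cyclic peptide (three-letter codes)
PEPTIDE6 = ("GLY", "ALA", "PHE", "LEU", "SER", "VAL")


def ribose_55_deuteration() -> LabelingScheme:
    """Labeling scheme emulating 5',5''-deuterated NTP sample preparation,
    a common selective-deuteration strategy that removes the prochiral
    C5' protons (which cannot be stereospecifically assigned from peak
    positions alone) from all spectra."""
    scheme = LabelingScheme()
    scheme.add("*", "2H", "H5'", True)
    scheme.add("*", "2H", "H5''", True)
    return scheme


def standard_rna_schemes(tocsy_max_steps=None) -> dict:
    return {
        "tocsy": ExperimentScheme(
            "tocsy", [DimSpec("1H"), DimSpec("1H")], "tocsy",
            max_steps=tocsy_max_steps),
        "cosy": ExperimentScheme(
            "cosy", [DimSpec("1H"), DimSpec("1H")], "tocsy", max_steps=1),
        "hmqc": ExperimentScheme(
            "hmqc", [DimSpec("1H"), DimSpec("13C")], "onebond_hc"),
        "noesy": ExperimentScheme(
            "noesy", [DimSpec("1H"), DimSpec("1H")], "noesy"),
    }


def standard_rna_network(sequence: str, dotbracket: str,
                         labeling: LabelingScheme | None = None,
                         tocsy_max_steps=None,
                         noe_rules=None) -> AssignmentNetwork:
    """Build the full pre-assigned network for an RNA hairpin."""
    mol = build_molecule(sequence, "rna")
    ss = parse_dotbracket(sequence, dotbracket)
    if labeling is not None:
        apply_labeling(mol, labeling)
    shifts = predict_rna(mol, ss)
    schemes = standard_rna_schemes(tocsy_max_steps)
    experiments = [
        (schemes["tocsy"],
         peakgen.gen_tocsy(mol, shifts, schemes["tocsy"])),
        (schemes["cosy"],
         peakgen.gen_cosy(mol, shifts, schemes["cosy"])),
        (schemes["hmqc"],
         peakgen.gen_hmqc(mol, shifts, schemes["hmqc"])),
        (schemes["noesy"],
         peakgen.gen_noesy_rules(mol, ss, shifts, schemes["noesy"],
                                 rules=noe_rules)),
    ]
    experiments = [(s, peakgen.filter_peaks(p, s, mol))
                   for s, p in experiments]
    return build_network(mol, shifts, experiments)


def demo_network_22(deuterated: bool = True) -> AssignmentNetwork:
    """The 22-nt hairpin demo network; by default with 5',5''-ribose
    deuteration (see :func:`ribose_55_deuteration`)."""
    labeling = ribose_55_deuteration() if deuterated else None
    return standard_rna_network(HAIRPIN22_SEQ, HAIRPIN22_DB,
                                labeling=labeling)


def peptide_network(sequence=PEPTIDE6, cyclic: bool = True,
                    tocsy_max_steps=None) -> AssignmentNetwork:
    """TOCSY + HMQC network for a (cyclic) peptide."""
    mol = build_molecule(list(sequence), "peptide", cyclic=cyclic)
    shifts = predict_peptide(mol)
    schemes = {
        "tocsy": ExperimentScheme(
            "tocsy", [DimSpec("1H"), DimSpec("1H")], "tocsy",
            max_steps=tocsy_max_steps),
        "hmqc": ExperimentScheme(
            "hmqc", [DimSpec("1H"), DimSpec("13C")], "onebond_hc"),
    }
    experiments = [
        (schemes["tocsy"],
         peakgen.gen_tocsy(mol, shifts, schemes["tocsy"])),
        (schemes["hmqc"], peakgen.gen_hmqc(mol, shifts, schemes["hmqc"])),
    ]
    return build_network(mol, shifts, experiments)
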