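"""Peak-box generators: scalar-coupled, one-bond, NOESY, edit-filters."""

import itertools

import numpy as np
import pytest

from peaknets import peakgen
from peaknets.peakgen import (DimSpec, ExperimentScheme, filter_peaks,
                              gen_cosy, gen_hmqc, gen_noesy_rules,
                              gen_noesy_structure, gen_tocsy, load_noe_rules)
from peaknets.geometry import synthetic_helix_coords
from peaknets.shifts import predict_peptide, predict_rna
from peaknets.topology import (LabelingScheme, apply_labeling,
                               build_molecule, covalent_distance,
                               parse_dotbracket)


def _tocsy_scheme(max_steps=None):
    return ExperimentScheme("tocsy", [DimSpec("1H"), DimSpec("1H")],
                            "tocsy", max_steps=max_steps)


def _hmqc_scheme(filt1="none", filt2="none"):
    return ExperimentScheme("hmqc", [DimSpec("1H", filt1),
                                     DimSpec("13C", filt2)], "onebond_hc")


def _noesy_scheme():
    return ExperimentScheme("noesy", [DimSpec("1H"), DimSpec("1H")],
                            "noesy")


def _rna(seq, db=None):
    mol = build_molecule(seq, "rna")
    ss = parse_dotbracket(seq, db or "." * len(seq))
    return mol, ss, predict_rna(mol, ss)


def _pairs(peaks):
    return {p.atom_keys for p in peaks}


class TestTocsyCosy:
    def test_cytidine_h5_h6(self):
        mol, _, shifts = _rna("C")
        pairs = _pairs(gen_tocsy(mol, shifts, _tocsy_scheme(1)))
        assert ((1, "H5"), (1, "H6")) in pairs
        assert ((1, "H6"), (1, "H5")) in pairs

    def test_single_step_matches_bond_distance_oracle(self):
        """One J-step = proton pair 2 or 3 covalent bonds apart."""
        mol, _, shifts = _rna("C")
        protons = [a for a in mol.protons() if not a.exchangeable]
        expected = set()
        for a, b in itertools.permutations(protons, 2):
            if covalent_distance(mol, a, b) in (2, 3):
                expected.add((a.key, b.key))
        assert _pairs(gen_tocsy(mol, shifts, _tocsy_scheme(1))) == expected

    def test_relay_matches_bfs_oracle(self):
        """k-step TOCSY = paths of <=k single steps (BFS in the step
        graph built independently here)."""
        mol, _, shifts = _rna("A")
        protons = [a for a in mol.protons() if not a.exchangeable]
        step = {(a.key, b.key)
                for a, b in itertools.permutations(protons, 2)
                if covalent_distance(mol, a, b) in (2, 3)}
        for k in (1, 2, 3):
            reach = set(step)
            for _ in range(k - 1):
                reach = reach | {(a, c) for (a, b) in reach
                                 for (b2, c) in step
                                 if b2 == b and c != a}
            got = _pairs(gen_tocsy(mol, shifts, _tocsy_scheme(k)))
            assert got == reach

    def test_max_steps_zero_empty(self):
        mol, _, shifts = _rna("C")
        assert gen_tocsy(mol, shifts, _tocsy_scheme(0)) == []

    def test_monotone_in_steps(self):
        mol, _, shifts = _rna("GA")
        prev = set()
        for k in range(5):
            cur = _pairs(gen_tocsy(mol, shifts, _tocsy_scheme(k)))
            assert prev <= cur
            prev = cur

    def test_symmetry(self):
        mol, _, shifts = _rna("CA")
        pairs = _pairs(gen_tocsy(mol, shifts, _tocsy_scheme()))
        assert pairs == {(b, a) for a, b in pairs}

    def test_cosy_is_one_step_tocsy(self):
        mol, _, shifts = _rna("GACU")
        scheme = _tocsy_scheme(4)
        assert _pairs(gen_cosy(mol, shifts, scheme)) == \
            _pairs(gen_tocsy(mol, shifts, _tocsy_scheme(1)))

    def test_glycine_geminal_pair(self):
        mol = build_molecule(["GLY"], "peptide")
        shifts = predict_peptide(mol)
        pairs = _pairs(gen_cosy(mol, shifts, _tocsy_scheme()))
        assert ((1, "HA2"), (1, "HA3")) in pairs

    def test_deuterated_positions_skipped(self):
        mol, ss, _ = _rna("GG")
        scheme = LabelingScheme()
        scheme.add({2}, "2H", "H8", True)
        apply_labeling(mol, scheme)
        shifts = predict_rna(mol, ss)
        pairs = _pairs(gen_tocsy(mol, shifts, _tocsy_scheme()))
        assert not any((2, "H8") in p for p in pairs)

    def test_exchangeable_excluded_by_default(self):
        mol, _, shifts = _rna("G")
        pairs = _pairs(gen_tocsy(mol, shifts, _tocsy_scheme()))
        assert not any(key[1].startswith("HO") or key[1] in ("H1",)
                       for p in pairs for key in p)


class TestHmqc:
    def test_adenosine_boxes(self):
        mol, _, shifts = _rna("A")
        pairs = _pairs(gen_hmqc(mol, shifts, _hmqc_scheme()))
        assert pairs == {
            ((1, "H2"), (1, "C2")), ((1, "H8"), (1, "C8")),
            ((1, "H1'"), (1, "C1'")), ((1, "H2'"), (1, "C2'")),
            ((1, "H3'"), (1, "C3'")), ((1, "H4'"), (1, "C4'")),
            ((1, "H5'"), (1, "C5'")), ((1, "H5''"), (1, "C5'")),
        }

    def test_fully_deuterated_empty(self):
        mol, ss, _ = _rna("A")
        scheme = LabelingScheme()
        scheme.add("*", "2H", "all", True)
        apply_labeling(mol, scheme)
        shifts = predict_rna(mol, ss)
        assert gen_hmqc(mol, shifts, _hmqc_scheme()) == []

    def test_13c_edit_filter_keeps_labeled_only(self):
        mol, ss, _ = _rna("GC")
        lab = LabelingScheme()
        lab.add("G", "13C", "all", True)
        apply_labeling(mol, lab)
        shifts = predict_rna(mol, ss)
        scheme = _hmqc_scheme("require_13C_bonded", "require_13C_bonded")
        peaks = filter_peaks(gen_hmqc(mol, shifts, scheme), scheme, mol)
        residues = {k[0] for p in peaks for k in p.atom_keys}
        assert residues == {1}


class TestFilters:
    def test_unlabeled_require_empty(self):
        mol, _, shifts = _rna("GC")
        scheme = _hmqc_scheme("require_13C_bonded", "none")
        assert filter_peaks(gen_hmqc(mol, shifts, _hmqc_scheme()),
                            scheme, mol) == []

    def test_none_identity(self):
        mol, _, shifts = _rna("GC")
        peaks = gen_hmqc(mol, shifts, _hmqc_scheme())
        assert filter_peaks(peaks, _hmqc_scheme(), mol) == peaks

    def test_require_reject_partition(self, rng):
        """require/reject on the same isotope partition the peak set."""
        mol, ss, _ = _rna("GGCAGCGUCUUCGGACGCUGCC",
                          "(((((((((....)))))))))")
        lab = LabelingScheme()
        labeled = set(int(i) for i in rng.choice(22, size=8, replace=False)
                      ) or {1}
        lab.add({i + 1 for i in labeled}, "13C", "all", True)
        apply_labeling(mol, lab)
        shifts = predict_rna(mol, ss)
        peaks = gen_hmqc(mol, shifts, _hmqc_scheme())
        req = ExperimentScheme("hmqc", [DimSpec("1H", "require_13C_bonded"),
                                        DimSpec("13C")], "onebond_hc")
        rej = ExperimentScheme("hmqc", [DimSpec("1H", "reject_13C_bonded"),
                                        DimSpec("13C")], "onebond_hc")
        kept = filter_peaks(peaks, req, mol)
        dropped = filter_peaks(peaks, rej, mol)
        ids = lambda ps: {p.id for p in ps}
        assert ids(kept) | ids(dropped) == ids(peaks)
        assert ids(kept) & ids(dropped) == set()
        # surviving protons really sit on labeled carbons
        for p in kept:
            h = mol.atom_by_key(p.dims[0].atom_key)
            assert any(b.element == "C" and b.is_labeled("13C")
                       for b in mol.bonded(h))


class TestNoesyStructure:
    def test_cutoff_strict(self):
        from peaknets.topology import parse_connection_table
        mol = parse_connection_table(
            "atoms\nC1 C\nH1 H\nC2 C\nH2 H\nbonds\nC1 H1\nC2 H2\nC1 C2\n")
        from peaknets.shifts import ShiftTable
        shifts = ShiftTable()
        for atom in mol.atoms:
            shifts.set_prediction(atom, 1.0)
        coords = {(1, "C1"): (0, 0, 0), (1, "H1"): (0, 0, 0),
                  (1, "C2"): (0, 0, 4.2), (1, "H2"): (0, 0, 4.2)}
        coords = {k: np.asarray(v, float) for k, v in coords.items()}
        near = gen_noesy_structure(mol, shifts, _noesy_scheme(), coords,
                                   cutoff=5.0)
        assert _pairs(near) == {((1, "H1"), (1, "H2")),
                                ((1, "H2"), (1, "H1"))}
        coords[(1, "H2")] = np.array([0, 0, 6.5])
        coords[(1, "C2")] = np.array([0, 0, 6.5])
        assert gen_noesy_structure(mol, shifts, _noesy_scheme(), coords,
                                   cutoff=5.0) == []

    def test_matches_all_pairs_oracle(self):
        mol, _, shifts = _rna("GGCAGC", "((..))")
        coords = synthetic_helix_coords(mol)
        for cutoff in (5.0, 6.0):
            got = _pairs(gen_noesy_structure(mol, shifts, _noesy_scheme(),
                                             coords, cutoff=cutoff))
            # hydroxyl protons carry no shift prediction, hence no box
            protons = [a for a in mol.protons() if a.key in shifts.records]
            expected = set()
            for a, b in itertools.permutations(protons, 2):
                d = np.linalg.norm(coords[a.key] - coords[b.key])
                if d < cutoff:
                    expected.add((a.key, b.key))
            assert got == expected

    def test_missing_coordinates(self):
        mol, _, shifts = _rna("G")
        coords = synthetic_helix_coords(mol)
        some = dict(list(coords.items())[:3])
        with pytest.raises(ValueError, match="no coordinates"):
            gen_noesy_structure(mol, shifts, _noesy_scheme(), some)


class TestNoesyRules:
    def test_single_stranded_intra_only(self):
        mol, ss, shifts = _rna("GACU")
        peaks = gen_noesy_rules(mol, ss, shifts, _noesy_scheme())
        assert peaks
        assert all(p.origin == "noe_intra" for p in peaks)
        assert all(len({k[0] for k in p.atom_keys}) == 1 for p in peaks)

    def test_helix_sequential_rule_fires(self):
        mol, ss, shifts = _rna("GGCC", "(())")
        pairs = _pairs(gen_noesy_rules(mol, ss, shifts, _noesy_scheme()))
        assert ((1, "H1'"), (2, "H8")) in pairs

    def test_tetraloop_confined(self):
        seq, db = "GGCAGCGUCUUCGGACGCUGCC", "(((((((((....)))))))))"
        mol, ss, shifts = _rna(seq, db)
        peaks = gen_noesy_rules(mol, ss, shifts, _noesy_scheme())
        loop_and_closing = set(range(9, 15))    # loop 10-13 + pair (9,14)
        for p in peaks:
            if p.origin != "noe_rule":
                continue
            res = {k[0] for k in p.atom_keys}
            if res <= set(range(10, 14)) or (res & set(range(10, 14))):
                assert res <= loop_and_closing or not (
                    res & set(range(10, 14)))

    def test_imino_walk_present(self):
        mol, ss, shifts = _rna("GGCC", "(())")
        pairs = _pairs(gen_noesy_rules(mol, ss, shifts, _noesy_scheme()))
        assert ((1, "H1"), (2, "H1")) in pairs   # stacked G iminos

    def test_exclude_exchangeable(self):
        mol, ss, shifts = _rna("GGCC", "(())")
        peaks = gen_noesy_rules(mol, ss, shifts, _noesy_scheme(),
                                include_exchangeable=False)
        assert not any(k[1] == "H1" for p in peaks for k in p.atom_keys)

    def test_positions_equal_predictions(self):
        mol, ss, shifts = _rna("GGCC", "(())")
        for p in gen_noesy_rules(mol, ss, shifts, _noesy_scheme()):
            for d in p.dims:
                assert d.ppm == shifts[d.atom_key].current_ppm
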