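# peaknets

Pre-assigned peak-box networks for NMR chemical shift assignment of RNA,
peptides and small organic molecules.

## The problem

Conventional NMR assignment picks peaks first and then tries to attach an
atom to each one — thousands of scalar- and dipolar-coupled peaks across
several spectra, with the bookkeeping done by hand. `peaknets` inverts
the workflow: starting from the covalent topology (sequence plus a
residue library) and predicted chemical shifts, it generates for every
experiment a network of *peak-boxes that are already assigned*, placed at
their predicted positions. Peak-boxes that share an atom are linked:
moving one atom's shift moves every linked dimension synchronously, and
committing ("freezing") a peak-box locks its atoms' shifts across all
experiments, leaving linked peak-boxes movable only along their free
dimension. Because a single peak near a signal may be ambiguous while a
whole coupled set is not, placement decisions propagate instead of being
made peak by peak. The final assignment list contains exactly the frozen
atoms.

It is written for spectroscopists assigning mid-sized RNAs (hairpins,
tens of nucleotides), cyclic peptides and small molecules from 2D
homonuclear TOCSY/COSY, ¹H-¹³C HMQC and 2D NOESY spectra, including
isotope-labeled samples (¹³C/¹⁵N edit-filters, ²H as signal absence).

## What it computes

- **Topology** — covalent graphs from sequence via CCD residue templates
  (RNA with 5'-OH or 5'-phosphate termini, linear or cyclic peptides,
  generic molecules from a connection table); Vienna dot-bracket parsing
  into base pairs, helices and tetraloops.
- **Shift prediction** — context-keyed RNA lookup (five-residue window,
  pairing state, neighbour ring-current corrections, documented back-off)
  and residue-average peptide tables; external predictions imported from
  plain text override the bundled tables.
- **Peak-box generation** — TOCSY from J-coupling step counts over the
  spin-system graph (COSY = one step), HMQC from H–C bonds, NOESY either
  from 3D coordinates (all H–H pairs under a distance cutoff) or from
  secondary-structure rules (intra-residue, sequential walk, cross-strand
  adenine H2, imino–imino, tetraloop), filtered by the sample's labeling
  scheme.
- **The assignment engine** — synchronized movement, atom-level
  freeze/thaw with cross-experiment propagation, tweak-and-freeze
  snapping onto observed peaks, manual peaks with candidate suggestions,
  an operation log whose replay reproduces a session exactly, and export
  to NMR-STAR.
- **Synthetic benchmark** — ground-truth shifts perturbed by a
  per-nucleus Gaussian error model, simulated observed peak lists
  (missing peaks, spurious peaks, positional jitter), and a scripted
  assigner (`greedy_assign`) that freezes a peak-box only when its
  placement is provably unambiguous.

## Worked example

A 22-nt hairpin with a UUCG tetraloop, 5',5''-ribose-deuterated (a common
labeling scheme that removes the prochiral C5' protons, which cannot be
stereospecifically assigned from peak positions):

```yaml
# run.yaml
sequence: GGCAGCGUCUUCGGACGCUGCC
dotbracket: '(((((((((....)))))))))'
kind: rna
labeling:
  - {selector: '*', isotope: 2H, atoms: "H5'", value: true}
  - {selector: '*', isotope: 2H, atoms: "H5''", value: true}
```

```text
$ peaknets predict --config run.yaml --out shifts.txt
wrote 392 predicted shifts to shifts.txt

$ peaknets genpeaks --config run.yaml --outdir peaks
cosy: 156 peak-boxes -> peaks/cosy.tsv
hmqc: 124 peak-boxes -> peaks/hmqc.tsv
noesy: 314 peak-boxes -> peaks/noesy.tsv
tocsy: 288 peak-boxes -> peaks/tocsy.tsv

$ peaknets simulate --config run.yaml --seed 7 --outdir sim \
      --p-missing 0 --n-extra 0 --jitter-h 0 --jitter-c 0
$ peaknets assign --config run.yaml --auto --observed-dir sim --outdir assigned
frozen 257/257 networked atoms (100.0%)
exported 257 frozen assignments
```

`simulate` drew ground-truth shifts around the predictions (σ = 0.15 ppm
for ¹H, 0.8 ppm for ¹³C by default) and emitted unassigned observed peak
lists at the true positions. `assign --auto` then recovered the
assignment: all 257 atoms appearing in the four peak networks were frozen
and `assigned/assignments.str` (NMR-STAR) lists each at its true shift.
The same run can be replayed later from `assigned/session.oplog` with
`assign --script`.

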