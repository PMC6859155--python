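# Methods

## Molecular topology

Molecules are assembled from sequence using Chemical Component Dictionary
residue templates (via biotite), trimmed to their in-chain form: RNA
residues lose the monomer-only phosphate atoms (OP3 and phosphate
protons), internal residues lose HO3', and a 5'-OH terminus (the default,
matching common in vitro transcripts; a flag restores the 5'-phosphate)
replaces the phosphate with an added HO5'. Peptides lose OXT/HXT/H2
internally; cyclic peptides close C(n)–N(1) and have no termini. A proton
bonded to N or O is marked solvent-exchangeable. Generic molecules load
from a two-section connection table (`atoms` lines `name element`,
`bonds` lines `name name`).

Dot-bracket strings are stack-matched into base pairs; only `.` and
round brackets are accepted, so inputs are nested by construction and
pseudoknot bracket levels are rejected outright rather than silently
dropped — a misclassified helix would corrupt the NOE rules downstream.
Helices are maximal stacks of ≥2 consecutive pairs; a tetraloop is a
hairpin loop of exactly four unpaired residues closed by a pair.

Isotope labeling is an ordered rule list (residue type or explicit index
set × isotope × atom-name pattern), later rules overriding earlier ones.
¹³C/¹⁵N labels are boolean satellite flags consumed only by edit-filters;
²H on a proton means the signal is absent, and every generator skips it.

## Chemical shift prediction

The RNA table (`data/rna_shifts.tsv`) is a versioned, editable lookup
with four levels, tried in order per atom:

1. exact five-residue context window (case encodes pairing state),
2. (residue type, paired flag) base value plus additive neighbour
   corrections (ring-current-style, ¹H only, a few hundredths to tenths
   of a ppm, signed by whether the neighbour is a purine),
3. residue-type average,
4. element fallback.

Coverage is therefore total by construction. The values are approximate
consensus numbers for A-form helical versus loop nucleotides; they are
starting positions for an interactively refined network, not a trained
predictor, and the file (plus the `RnaShiftTableFile` interface) is the
contract for swapping in a better one. Peptides use a residue-average
table in the style of the BMRB statistics; atoms of non-canonical
residues without entries are collected in an `uncovered` set rather than
raising, because the external-import path (`residue_index atom_name ppm`
rows, `#` comments) is expected to fill them. Source precedence is
manual > external > table regardless of application order.

Prediction targets are protons not bonded to O/S (hydroxyl and thiol
protons are excluded — broadened and rarely usable) and C/N atoms
carrying at least one proton.

## Peak-box generation

One J-coupling step links two protons 2 or 3 covalent bonds apart
(geminal/vicinal) — the standard spin-system interpretation; TOCSY
relays along paths of such steps up to `max_steps` (default unlimited,
which confines transfer to the residue's spin system in practice), and
COSY is the same generator at one step. Both symmetric orders (a, b) and
(b, a) are emitted for homonuclear experiments. HMQC emits one box per
H–C bond, methylene/methyl protons sharing the carbon dimension.

Structure-based NOESY emits all proton pairs closer than the cutoff
(default 5 Å, strict inequality) using a KD-tree; its oracle equivalence
against the naive all-pairs scan is part of the acceptance checks.
Rule-based NOESY expands a shipped, editable rule file over the
secondary-structure segments: intra-residue sugar-to-base and H5–H6
contacts everywhere; the sequential aromatic–anomeric walk, adenine H2
sequential and cross-strand contacts, and imino–imino contacts between
stacked pairs inside helices; the sequential walk continued through the
four loop residues and the closing pair in tetraloops (an approximation
to the stereotyped GNRA/UUCG patterns; the rule file is the contract).
Pyrimidine/purine aromatic selection (H6 vs H8) happens at expansion
time. Duplicate boxes (same experiment, same atom pair) are merged,
keeping the first origin tag.

Edit-filters act per dimension: `require_13C_bonded` keeps a proton
dimension only if its attached carbon is labeled (a carbon dimension,
only if the carbon itself is), `reject_13C_bonded` is the complement, so
require/reject partition any peak list exactly.

## The assignment engine

The shift table owns one mutable coordinate per atom; every peak-box
dimension mirrors it, which *is* the synchronized-movement rule. Frozen
state lives on the atom: freezing a peak-box freezes its dimension
atoms, and therefore every dimension of every box assigned to those
atoms, in all experiments; a box sharing one atom stays slidable along
its free dimension. Thawing any box referencing a frozen atom thaws the
atom — atom-level semantics also make "two boxes frozen at conflicting
positions for one atom" unrepresentable. Tweak-and-freeze snaps onto the
nearest observed peak by tolerance-scaled Euclidean distance over the
unfrozen dimensions (frozen dimensions restrict candidates to their
exact value); an exact tie raises an error — the scripted engine never
guesses where an interactive user would decide. Manual peaks enter
unassigned; candidate atoms per dimension are the frozen shifts within
tolerance, sorted by (|Δppm|, residue, atom name). Export lists frozen
atoms only, sorted by residue then atom name.

Every mutating operation appends to a line-oriented operation log;
replaying the log on a freshly generated network reproduces the state
hash exactly, which is the basis of the `assign --script` mode and of
the session artifacts the CLI writes.

## Synthetic data

`simulate_truth` draws ground truth = prediction + N(0, σ) per nucleus
(defaults σ(¹H) = 0.15, σ(¹³C) = 0.8, σ(¹⁵N) = 1.5 ppm — large enough
to create real ambiguity in crowded regions). `simulate_observed` emits
one unassigned peak per generated box with probability 1 − p_missing at
the truth positions plus per-nucleus jitter (defaults 0.005/0.05 ppm;
p_missing 0.05, 5 spurious peaks uniform in the observed bounding box),
then shuffles. What it does *not* emulate: lineshapes, intensity,
overlap-dependent peak merging, solvent exchange broadening — so passing
recovery tests demonstrate the constraint-propagation logic, not
robustness to real spectral artifacts.

The bundled fixtures are a 22-nt and a 50-nt hairpin (UUCG and GAAA
tetraloops) and a six-residue cyclic peptide. The 22-nt demo network
uses the standard four-experiment set (TOCSY, COSY, ¹H-¹³C HMQC,
rule-based NOESY) with a 5',5''-ribose deuteration scheme. Both of
these choices are load-bearing and deliberate: prochiral H5'/H5''
cannot be stereospecifically assigned from peak positions alone (the
two placements are exactly exchangeable), and C5'-deuterated NTPs are a
real sample-preparation practice that removes them; the COSY carries
the coupling-order information (H1'–H2' but not H1'–H3') that an
unlimited-mixing TOCSY destroys, without which the 3'-terminal ribose
protons are permutable. On the protonated fixture the assigner leaves
the prochiral pairs unfrozen by design.

## The scripted assigner

`greedy_assign` is the GUI-free surrogate of the interactive workflow.
Capture windows default to 4σ of the prediction-error model (0.6 ppm ¹H,
3.2 ppm ¹³C, 6.0 ppm ¹⁵N); the coincidence tolerance ε (default 1e-6
ppm; set to a few times the jitter, or the file write precision, when
those are nonzero) defines when two coordinates count as the same atom.
Stages, iterated to a global fixed point:

0. *Exact prior match*: a box already sitting on an observed peak
   (within ε) freezes there — this makes the degenerate
   observed-equals-predicted case converge immediately.
1. *Unique candidate*: a box with exactly one unclaimed observed peak
   consistent with its frozen dimensions (within ε) and capture windows
   is tweak-and-frozen onto it. Fully frozen boxes claim their observed
   peak, removing it from other searches; frozen dimensions turn the
   search into exact 1D slices, so each freeze typically unlocks
   neighbours.
2. *Ambiguity clusters*: remaining unfrozen atoms are grouped into
   components linked by shared boxes and solved by backtracking over
   atom→coordinate assignments, where every predicted box must consume a
   *distinct* observed peak at its implied position (peak-level
   injectivity permits genuinely overlapped coordinates but forbids
   degenerate many-to-one collapses). A component is frozen only when
   its consistent placement is unique; prochiral twin protons (≥2 on one
   heavy atom) are excluded as unknowable. Search is bounded (node cap
   50,000, solution cap 6); hitting a bound freezes nothing.

These stages never guess: with complete peak lists they either solve a
cluster exactly or leave it unfrozen, which is why the clean-conditions
recovery is simultaneously 100% and exact. With missing peaks strict
consistency is unsatisfiable and recovery collapses toward zero; an
opt-in heuristic stage (`heuristic=True`) then prunes candidate values
to the best-supported ones and freezes singletons. It recovers the bulk
of the network but, unlike the exact stages, can misassign — the
recovery report's accuracy field measures this, and the flag stays off
by default.

## Numerical choices

- Matching tolerances for interactive candidate suggestion: 0.05 ppm ¹H,
  0.5 ppm ¹³C/¹⁵N; capture windows for the assigner as above.
- ppm printing: 4 decimals (¹H) / 3 (¹³C, ¹⁵N) in peak-box, shift and
  NMR-STAR files — beyond every matching tolerance; observed peak lists
  use 6 decimals because the assigner's coincidence structure must
  survive the round-trip.
- Tie-breaks: equidistant tweak candidates error out; manual-peak
  candidate lists break |Δppm| ties by residue index then atom name.
- Degenerate inputs: empty sequences, unknown residues, unbalanced
  brackets, dangling atom references and malformed file rows raise with
  location information; double delete and thaw-of-unfrozen are no-ops.

## Known limitations

- The shift tables are static consensus values; prediction quality, not
  the engine, limits how far initial positions sit from truth.
- NOE rules cover helices, tetraloops and intra-residue contacts only;
  larger loops and tertiary contacts need 3D coordinates or manual
  peaks, as intended by the bootstrapping workflow.
- The exact assigner requires near-complete peak lists; real spectra
  with substantial overlap or missing peaks need the interactive
  workflow (or the heuristic stage, accepting its error rate).
- 2D experiments only; no quantitative NOE intensities, relaxation or
  coupling constants; pseudoknots and modified nucleotides beyond
  user-supplied connection tables are out of scope.
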