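# Methods

This note documents the models, parameter defaults and numerical choices
behind `mutmap3d`, and what the synthetic test fixtures do and do not
establish about behaviour on real data.

## Structure model and normalization

Structures are parsed with gemmi into a uniform hierarchy
(chains → residues → atoms).  Residues are categorized by component code:
protein (standard amino acids plus a table of common modified residues,
e.g. MSE → M), nucleic (`DA DC DG DT DU A C G U`, configurable; RNA is
deliberately included and treated under the DNA-interface rule), water,
metal (single-element ion codes), and ligand (any other non-polymer).
Simple buffer ions (Na⁺, K⁺, Mg²⁺, Ca²⁺, Cl⁻) are metals, never ligands;
zinc is a metal singled out by the zinc-site annotation because of its
structural role in domains such as the p53 DNA-binding domain.

Normalization rules, chosen for determinism and comparability:

* multi-model files (NMR ensembles) keep model 1 only, logged;
* alternate locations resolve to the highest-occupancy conformer, ties
  broken by altloc letter order — residue counts never change;
* hydrogens are parsed and flagged but excluded from all SASA and
  distance computations (most X-ray depositions lack them; including them
  where present would make cutoffs incomparable across entries);
* waters are retained but excluded from scoring and occlusion;
* occupancies outside [0,1] are clamped with a warning; blank element
  columns are inferred from atom names.

Only chains present in the file are used: no assembly generation from
symmetry operators.  Whether an asymmetric unit or a biological assembly
is the right input for interface detection is the user's call; the
pipeline operates on the file as given.

## Renumbering

Each protein chain's observed one-letter sequence is aligned to the
reference with an affine-gap semi-global aligner (Gotoh dynamic program):
BLOSUM62 scores, gap open −10, gap extend −0.5 (the first residue of a
gap costs −10, each further residue −0.5), and free end gaps on the
observed side, because crystallized constructs are almost always
fragments of the full-length protein.  Traceback ties break
deterministically: aligned pair over query-gap over reference-gap;
adjacent opposite-direction gaps are disallowed (with this matrix a
mismatch always outscores an open–close gap pair, so no optimum is lost).

Every observed residue aligned to a non-gap reference column maps to that
column's 1-based position.  Mismatched aligned pairs are mapped *and*
counted — engineered substitutions in crystal constructs sit at exactly
the positions mutation studies care about, so dropping them would lose
the signal.  A chain whose alignment identity falls below 0.30
(configurable) is rejected as belonging to a different protein.

Two caveats on exact recovery of a "true" numbering, verified by the test
suite's planted-corruption experiments: a deletion flanked by identical
residues admits several equally optimal alignments (the gap can slide),
and a deletion within a few residues of a chain end can be absorbed into
the free end gap more cheaply than an internal gap.  In both situations
no aligner can identify the intended placement from sequence alone; the
recovery guarantee holds for interior, unambiguous corruption, which is
what the tests plant.

## Solvent accessibility and burial

SASA uses the Shrake–Rupley quadrature: `n_points` test points on each
atom's expanded sphere (radius r_atom + probe), placed by a deterministic
golden-section spiral; the accessible fraction times 4π(r+probe)² is the
atom's area.  Defaults: probe 1.4 Å (water), 960 points (single-sphere
quadrature error bounded by one point's share, ≈0.1 %); 100 points is a
reasonable fast setting and the pipeline exposes the knob.  Van der Waals
radii come from a bundled element-keyed table (ProtOr-style protein
values, Bondi values for other elements) with optional per-atom
overrides; both tables are plain text and replaceable.

SASA is computed on the full assembly as given — dimer partners, ligands
and ions occlude each other — because one per-residue value feeds one
burial classification.

Relative accessibility divides a residue's area by its type's theoretical
maximum in an extended Gly-X-Gly tripeptide (bundled Tien et al. 2013
values).  Burial classes: RSA < 25 % core, 25–80 % inclusive
noninterface, > 80 % exposed; residues without a normalization entry are
reported *unscored*, never silently zero.  Two notes: the thresholds are
interpreted on the relative scale (absolute Å² thresholds of 25/80 would
systematically misclassify large residues), and the high-accessibility
class is sometimes called "interface" in the solvent-accessibility
literature — this package reserves "interface" for the distance-based
annotations and labels the class "exposed".

## Distance-based contexts

Four independent flags per protein residue, from minimal heavy-atom
distances: ligand site ≤ 6.0 Å to any ligand; dimer interface ≤ 5.0 Å to
a *different* protein chain; DNA interface ≤ 5.0 Å to any nucleic
residue; zinc site ≤ 5.0 Å to a Zn ion.  Flags are independent rather
than exclusive — a DNA-contact residue can simultaneously coordinate
zinc.  The search uses a k-d tree (scipy cKDTree) but is contractually
identical to exhaustive all-pairs search; property tests enforce the
equivalence on randomized clouds, and cutoff monotonicity and chain-pair
symmetry are asserted as invariants.

## Mutation tables and frequency

The reader accepts COSMIC-shaped delimited text (TSV/CSV autodetect,
configurable column names; defaults `Gene name`, `Mutation AA`,
`Sample name`).  Accepted notations: bare (`R248Q`), one-letter HGVS
(`p.R248Q`), three-letter HGVS (`p.Arg248Gln`), and nonsense
(`R306*`/`p.Arg306Ter`, alt `*`).  Synonymous, frameshift, in-frame
indel and splice notations are rejected with typed reasons and tallied,
never silently dropped.

*Frequency* of a unique substitution is its count divided by the total
number of accepted rows for the gene, so frequencies over unique records
sum to 1 — a within-gene prevalence measure.  ("Frequency" could equally
mean per-sample or per-tumour-type prevalence; the definition here is
stated rather than inherited.)  When a sample column exists, duplicate
(sample, mutation) pairs count once, since catalogue rows can repeat a
sample across studies.  Records whose reference residue disagrees with
the FASTA are flagged (`ref_mismatch`, `out_of_range`) and retained.

## Coverage, disorder, mapping

Coverage counts, per reference position, the number of distinct
*structures* with an aligned residue there (a homodimer contributes one),
and reports the covered fraction plus the uncovered segments.  Disorder
is defined on the predicted model: a position is disordered when its
residue's mean atomic pLDDT is below 50 (strict; 70 is a documented
stricter alternative via the `threshold` argument).  The
disorder-mutation statistic is the percentage of *unique* mutations at
disordered positions, rounded half-up to one decimal.

Each unique mutation is mapped onto every experimental structure chain
covering its position — one row per chain, because burial and contexts
genuinely differ between copies in a dimer — and onto the predicted model
only when no experimental structure covers it (or on request).  Accepted
= covered + fallback is asserted and printed, and per-stage counts
(parsed, renumbered, scored, mapped, skipped) make silent loss
impossible.  Reruns on identical inputs are byte-identical.

## Synthetic fixtures: what they show and what they do not

The fixtures module generates idealized geometry: α-helices (rise 1.5 Å,
twist 100°/residue, Cα radius 2.3 Å) with minimal side chains (Cβ plus
one placeholder atom for residues larger than alanine), B-DNA duplexes
(rise 3.4 Å, twist 36°, three atoms per nucleotide), zinc ions and small
ligands placed at exact planted distances from named anchor atoms, pLDDT
patterns painted onto predicted models, and mutation tables with known
multiplicities, shuffled deterministically by seed.  Every complex ships
with ground truth computed by an exhaustive all-pairs distance scan,
independent of the pipeline's k-d-tree path, and generation is a pure
function of the seed.

Passing the planted-truth tests therefore establishes the *logic*:
renumbering arithmetic, cutoff handling, flag independence, frequency
bookkeeping, determinism.  It does not establish robustness to the mess
of real depositions — full rotamers, alternate conformations beyond the
simple cases tested, chain breaks, non-standard residues beyond the
bundled table, or physically realistic packing densities (fixture SASA
values are far more exposed than globular-protein values).  The SASA
cross-check against an independent implementation and the PDB/mmCIF
dialect-equivalence tests cover part of that distance; real-structure
validation beyond desk scale is out of scope here.

## Problem sizes used in checks

The bundled verification script and test suite run at desk scale chosen
for thorough coverage per second: the end-to-end scenario uses a
300-residue reference with a 60-residue, two-chain complex (120 points
per sphere in tests, 960 for SASA accuracy checks); neighbour-search
equivalence uses 100 randomized clouds of up to ~700 atoms; renumbering
recovery uses 100 corrupted fixtures of 30–80 residues.
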