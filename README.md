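# mutmap3d

Map somatic protein mutations onto 3D structures and classify each mutated
residue's structural context.

Cancer mutation catalogues (COSMIC and similar) report protein changes as
positions in the UniProt canonical sequence, while deposited structures
carry arbitrary author numbering, cover only fragments of the protein, and
mix protein chains with DNA, ligands, metal ions and waters.  `mutmap3d`
bridges the two worlds for a single gene: given local structure files
(experimental PDB/mmCIF and an optional predicted model carrying pLDDT), a
reference FASTA and a mutation table, it

1. **renumbers** every protein chain onto the reference by semi-global
   affine-gap alignment (BLOSUM62, gap open −10 / extend −0.5, free end
   gaps on the observed fragment), so each structure residue gets its
   1-based UniProt position;
2. computes **solvent accessibility** with a Shrake–Rupley implementation
   (probe 1.4 Å, 960 quadrature points on a golden-section spiral) and
   classifies burial on the relative-accessibility scale: RSA < 25 %
   *core*, 25–80 % *noninterface*, > 80 % *exposed*;
3. annotates **structural contexts** by minimal heavy-atom distance:
   ligand sites within 6 Å of a ligand, and dimer interfaces, protein–DNA
   interfaces and zinc sites within 5 Å of a partner chain, nucleic chain
   or Zn²⁺ respectively — independent flags, so one residue can carry
   several;
4. aggregates the mutation table into **unique substitutions** with
   occurrence counts and frequencies (count / accepted rows, so
   frequencies sum to 1), parsing `R248Q`, `p.R248Q` and `p.Arg248Gln`
   notations and skipping synonymous/frameshift/indel rows with typed
   reasons;
5. reports **coverage** of the reference across structures, **disorder**
   from predicted-model confidence (mean residue pLDDT < 50), and the
   fraction of unique mutations falling in disordered regions; then maps
   every unique mutation onto every covering structure chain, falling back
   to the predicted model for positions no experimental structure covers.

Everything runs offline from local files.  A fixtures module generates
fully ground-truthed synthetic inputs (idealized helices, B-DNA duplexes,
planted zinc/ligand/interface geometry, COSMIC-shaped tables), so the
entire pipeline is testable without downloads.

## Worked example

Generate the synthetic demonstration scenario (a 300-residue reference, a
homodimer complex with DNA, zinc and a ligand covering positions 240–299,
a predicted model, and a mutation table with 20 unique substitutions
including the classic p53 DNA-contact hotspots):

```bash
mutmap3d fixtures --seed 5 --out fx
cat > fx/config.yaml <<EOF
reference_fasta: fx/reference.fasta
mutation_table: fx/mutations.tsv
structures:
  - path: fx/synth1.pdb
    id: SYNTH1
predicted_model: fx/af_synth.pdb
gene: GENE1
output_dir: fx/out
EOF
mutmap3d run --config fx/config.yaml
```

prints (abridged):

```json
{
 "covered_fraction": 0.2,
 "disorder_fraction": 0.41,
 "mutations_covered_experimental": 14,
 "mutations_in_disorder": 6,
 "mutations_in_disorder_pct": 30.0,
 "mutations_via_predicted": 6,
 "per_structure": {
  "SYNTH1": {
   "dimer_interface_mutations": 2,
   "dna_interface_mutations": 4,
   "ligand_site_mutations": 1,
   "zinc_site_mutations": 1,
   "rows_per_chain": {"A": 14, "B": 14},
   "unique_mutations": 14
  }
 },
 "unique_mutation_count": 20,
 "skipped_rows": 3
}
```

Reading: the experimental dimer covers 20 % of the reference
(positions 240–299); 41 % of positions are disordered in the predicted
model; of the 20 unique mutations, 14 land on the dimer (one row per
chain, hence 28 rows) and 6 fall back to the predicted model; 6 of the 20
(30.0 %) sit in the disordered region; per structure, 4 unique mutations
touch the DNA interface, 2 the dimer interface, 1 the ligand site and 1
the zinc site.  Three table rows (synonymous, frameshift, splice) were
skipped with reasons logged to `fx/out/skipped.tsv`.  The per-structure
table `fx/out/SYNTH1_mutations.tsv` holds one row per
mutation × chain with burial class, relative SASA and all context flags:

```
gene    position  ref_aa  alt_aa  count  frequency    structure_id  chain_id  ...  burial        dimer_interface  dna_interface  zinc_site
GENE1   240       L       C       5      0.028089888  SYNTH1        A         ...  noninterface  True             False          False
```

Per-stage subcommands (`mutmap3d renumber`, `mutmap3d sasa`,
`mutmap3d annotate`, `mutmap3d map`) expose each step separately; the same
functionality is available as a library (`mutmap3d.run_pipeline`,
`mutmap3d.shrake_rupley`, `mutmap3d.build_residue_map`, ...).

## Limitations

Mutant-structure modelling, stability prediction, web serving and any
network retrieval (wwPDB, AlphaFold DB, COSMIC API) are out of scope; all
inputs are local files.  See `docs/methods.md` for the model, parameter
defaults and numerical choices.
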