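# van der Waals radii (Angstrom) used for solvent-accessibility
# calculations, keyed by element symbol.  Values follow the ProtOr /
# Tsai et al. convention for protein heavy atoms, with standard Bondi
# radii for elements that appear in ligands, nucleic acids and cofactors.
# Lines: ELEM <symbol> <radius>.  Residue-specific overrides may be added
# as: ATOM <comp_id> <atom_name> <radius>.
ELEM H 1.20
ELEM D 1.20
ELEM C 1.70
ELEM N 1.55
ELEM O 1.52
ELEM S 1.80
ELEM P 1.80
ELEM SE 1.90
ELEM F 1.47
ELEM CL 1.75
ELEM BR 1.85
ELEM I 1.98
ELEM ZN 1.39
ELEM MG 1.18
ELEM CA 1.97
ELEM NA 2.27
ELEM K 2.75
ELEM MN 1.39
ELEM FE 1.40
ELEM CU 1.40
ELEM NI 1.63
ELEM CO 1.40
ELEM CD 1.58
ELEM HG 1.55
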