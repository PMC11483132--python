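"""Synthetic, fully ground-truthed inputs: structures and mutation tables.

Every stage of the pipeline is testable offline against fixtures built
here: idealized alpha-helical protein chains (rise 1.5 A, twist 100 deg
per residue) with minimal side-chain stubs, idealized B-DNA duplexes
(rise 3.4 A, twist 36 deg), zinc ions, small ligands, predicted models
with planted pLDDT patterns, and COSMIC-shaped mutation tables with known
multiplicities.

Geometry is intentionally minimal: residues carry N, CA, C, O and a CB
stub (plus one placeholder side-chain atom for residues larger than
alanine), because every distance-based rule in the pipeline is planted
against specific atoms, not against rotamer realism.  Each generated
complex ships with a machine-readable ground-truth context table computed
by an exhaustive all-pairs distance scan that is independent of the
package's k-d-tree annotation path.

Generation is a pure function of the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .context_annotation import INTERFACE_CUTOFF, LIGAND_CUTOFF, ContextFlags
from .model import (
    AA1,
    Atom,
    Chain,
    ONE_TO_THREE,
    ResidueCategory,
    ResidueKey,
    ResidueRecord,
    StructureModel,
    StructureSource,
)

__all__ = [
    "FixtureSpec",
    "make_helix",
    "make_bdna",
    "make_complex",
    "make_predicted_model",
    "make_mutation_table",
    "write_pdb",
    "random_sequence",
    "case_study_scenario",
]

HELIX_RISE = 1.5
HELIX_TWIST = math.radians(100.0)
HELIX_RADIUS = 2.3
BDNA_RISE = 3.4
BDNA_TWIST = math.radians(36.0)
BDNA_RADIUS = 9.0

#: residues that get only CB (or nothing) rather than CB + placeholder
_SMALL = {"G": 0, "A": 1}


def random_sequence(rng: np.random.Generator, n: int) -> str:
    """Uniform random amino-acid sequence of length n."""
    return "".join(rng.choice(list(AA1), size=n))


def _helix_point(t: float, radius: float, origin: np.ndarray, rise: float, twist: float) -> np.ndarray:
    return origin + np.array(
        [radius * math.cos(twist * t), radius * math.sin(twist * t), rise * t]
    )


def make_helix(
    sequence: str,
    offset: int = 1,
    chain_id: str = "A",
    origin: Sequence[float] = (0.0, 0.0, 0.0),
    temp_factors: Optional[Sequence[float]] = None,
) -> StructureModel:
    """Idealized alpha-helix for ``sequence`` with auth numbering starting
    at ``offset``.

    Each residue carries N, CA, C, O plus a CB stub (non-glycine) and one
    placeholder side-chain atom CG (residues larger than alanine), all on
    the helix surface; consecutive CA atoms are ~3.8 A apart.
    """
    seq = sequence.upper()
    bad = sorted(set(seq) - set(AA1))
    if not seq or bad:
        raise ValueError(f"invalid amino-acid letters: {bad}")
    origin = np.asarray(origin, dtype=float)
    chain = Chain(chain_id=chain_id)
    for i, letter in enumerate(seq):
        comp = ONE_TO_THREE[letter]
        b = float(temp_factors[i]) if temp_factors is not None else 0.0
        ca = _helix_point(i, HELIX_RADIUS, origin, HELIX_RISE, HELIX_TWIST)
        n = _helix_point(i - 0.35, 1.6, origin, HELIX_RISE, HELIX_TWIST)
        c = _helix_point(i + 0.35, 1.6, origin, HELIX_RISE, HELIX_TWIST)
        o = c + np.array([0.0, 0.0, 1.23])
        outward = (ca - np.array([origin[0], origin[1], ca[2]]))
        outward /= np.linalg.norm(outward)
        res = ResidueRecord(
            chain_id=chain_id,
            auth_seq_num=offset + i,
            insertion_code="",
            comp_id=comp,
            category=ResidueCategory.PROTEIN,
        )
        atoms = [
            Atom(name="N", element="N", coords=n, temp_factor=b),
            Atom(name="CA", element="C", coords=ca, temp_factor=b),
            Atom(name="C", element="C", coords=c, temp_factor=b),
            Atom(name="O", element="O", coords=o, temp_factor=b),
        ]
        n_side = _SMALL.get(letter, 2)
        if n_side >= 1:
            atoms.append(Atom(name="CB", element="C", coords=ca + 1.53 * outward, temp_factor=b))
        if n_side >= 2:
            atoms.append(Atom(name="CG", element="C", coords=ca + 2.9 * outward, temp_factor=b))
        res.atoms = atoms
        chain.residues.append(res)
    model = StructureModel(
        structure_id=f"helix_{chain_id}", source=StructureSource.EXPERIMENTAL, chains=[chain]
    )
    model.validate()
    return model


def make_bdna(
    n_bp: int,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
    chain_ids: tuple[str, str] = ("D", "E"),
    sequence: str = "",
    phase: float = 0.0,
) -> list[Chain]:
    """Idealized B-DNA duplex (rise 3.4 A, twist 36 deg) as two chains.

    Each nucleotide carries three heavy atoms (P, C1', N1) on the double
    helix; base pairing is positional only, with no sequence-specific
    geometry.
    """
    if n_bp < 1:
        raise ValueError("n_bp must be >= 1")
    seq = (sequence or "ATGC" * (n_bp // 4 + 1))[:n_bp].upper()
    comp_of = {"A": "DA", "T": "DT", "G": "DG", "C": "DC"}
    pair = {"A": "DT", "T": "DA", "G": "DC", "C": "DG"}
    origin = np.asarray(origin, dtype=float)
    chains = [Chain(chain_id=chain_ids[0]), Chain(chain_id=chain_ids[1])]
    for i in range(n_bp):
        for strand, (strand_phase, comp) in enumerate(
            [(0.0, comp_of[seq[i]]), (math.pi * 0.75, pair[seq[i]])]
        ):
            angle = phase + BDNA_TWIST * i + strand_phase
            z = BDNA_RISE * i
            p = origin + np.array(
                [BDNA_RADIUS * math.cos(angle), BDNA_RADIUS * math.sin(angle), z]
            )
            c1 = origin + np.array(
                [6.0 * math.cos(angle + 0.3), 6.0 * math.sin(angle + 0.3), z]
            )
            n1 = origin + np.array(
                [3.0 * math.cos(angle + 0.5), 3.0 * math.sin(angle + 0.5), z]
            )
            num = i + 1 if strand == 0 else n_bp - i
            res = ResidueRecord(
                chain_id=chain_ids[strand],
                auth_seq_num=num,
                insertion_code="",
                comp_id=comp,
                category=ResidueCategory.NUCLEIC,
                atoms=[
                    Atom(name="P", element="P", coords=p),
                    Atom(name="C1'", element="C", coords=c1),
                    Atom(name="N1", element="N", coords=n1),
                ],
            )
            chains[strand].residues.append(res)
    return chains


@dataclass
class FixtureSpec:
    """Declarative recipe for a ground-truthed synthetic complex.

    Positions are 1-based indices into ``sequence``; ``numbering_offset``
    shifts the author numbering of chain A (chain B, when present, uses
    ``numbering_offset_b``).  Planted contexts are realized geometrically
    and then re-verified by brute force before the fixture is returned.
    """

    seed: int = 0
    sequence: str = ""
    n_residues: int = 30
    numbering_offset: int = 1
    numbering_offset_b: int = 1
    deleted_segments: list[tuple[int, int]] = field(default_factory=list)
    with_dimer: bool = False
    dimer_approach: float = 4.5
    dna_near: Optional[int] = None  # position whose CG stub anchors the duplex
    dna_distance: float = 4.0
    dna_n_bp: int = 6
    zinc_near: Optional[int] = None
    zinc_distance: float = 3.0
    ligand_near: Optional[int] = None
    ligand_distance: float = 4.0
    plddt_pattern: Optional[list[float]] = None
    mutations: list[tuple[str, int]] = field(default_factory=list)  # (notation, count)
    rejects: list[str] = field(default_factory=list)
    gene: str = "GENE1"


def _apply_deletions(seq_positions: list[int], deleted: list[tuple[int, int]]) -> list[int]:
    out = []
    for p in seq_positions:
        if any(a <= p <= b for a, b in deleted):
            continue
        out.append(p)
    return out


def _subset_helix(full: StructureModel, keep_positions: list[int], offset: int,
                  chain_id: str) -> Chain:
    """Extract helix residues at 1-based sequence positions, renumbering
    authors to ``offset + (pos - 1)`` so gaps stay visible."""
    chain = full.chains[0]
    keep = set(keep_positions)
    out = Chain(chain_id=chain_id)
    for i, res in enumerate(chain.residues, start=1):
        if i not in keep:
            continue
        r = ResidueRecord(
            chain_id=chain_id,
            auth_seq_num=offset + i - 1,
            insertion_code="",
            comp_id=res.comp_id,
            category=res.category,
            atoms=[Atom(a.name, a.element, a.coords.copy(), a.occupancy, a.temp_factor)
                   for a in res.atoms],
        )
        out.residues.append(r)
    return out


def _brute_force_contexts(model: StructureModel,
                          ligand_cutoff: float = LIGAND_CUTOFF,
                          interface_cutoff: float = INTERFACE_CUTOFF,
                          ) -> dict[ResidueKey, ContextFlags]:
    """Exhaustive all-pairs context computation (generator-internal oracle)."""
    protein = model.residues_by_category(ResidueCategory.PROTEIN)
    ligands = model.residues_by_category(ResidueCategory.LIGAND)
    nucleic = model.residues_by_category(ResidueCategory.NUCLEIC)
    zincs = [r for r in model.residues_by_category(ResidueCategory.METAL)
             if r.comp_id.upper() == "ZN"]

    def min_dist(r1: ResidueRecord, r2: ResidueRecord) -> float:
        best = math.inf
        for a in r1.heavy_atoms():
            for b in r2.heavy_atoms():
                d = float(np.linalg.norm(a.coords - b.coords))
                best = min(best, d)
        return best

    flags: dict[ResidueKey, ContextFlags] = {}

    def get(key: ResidueKey) -> ContextFlags:
        return flags.setdefault(key, ContextFlags())

    for pres in protein:
        for lig in ligands:
            d = min_dist(pres, lig)
            if d <= ligand_cutoff:
                cf = get(pres.key)
                cf.ligand_site = True
                if lig.comp_id not in cf.ligand_ids:
                    cf.ligand_ids.append(lig.comp_id)
                cf.min_distances["ligand_site"] = min(
                    cf.min_distances.get("ligand_site", math.inf), d)
        for other in protein:
            if other.chain_id == pres.chain_id:
                continue
            d = min_dist(pres, other)
            if d <= interface_cutoff:
                cf = get(pres.key)
                cf.dimer_interface = True
                if other.chain_id not in cf.partner_chains:
                    cf.partner_chains.append(other.chain_id)
                cf.min_distances["dimer_interface"] = min(
                    cf.min_distances.get("dimer_interface", math.inf), d)
        for nuc in nucleic:
            d = min_dist(pres, nuc)
            if d <= interface_cutoff:
                cf = get(pres.key)
                cf.dna_interface = True
                cf.min_distances["dna_interface"] = min(
                    cf.min_distances.get("dna_interface", math.inf), d)
        for zn in zincs:
            d = min_dist(pres, zn)
            if d <= interface_cutoff:
                cf = get(pres.key)
                cf.zinc_site = True
                cf.min_distances["zinc_site"] = min(
                    cf.min_distances.get("zinc_site", math.inf), d)
    for cf in flags.values():
        cf.partner_chains.sort()
    return flags


def make_complex(spec: FixtureSpec) -> tuple[StructureModel, dict[ResidueKey, ContextFlags]]:
    """Assemble a synthetic complex and its brute-force ground truth.

    The returned ground truth maps residue keys (of the *author-numbered*
    model, exactly as written to PDB) to expected :class:`ContextFlags`;
    it is computed by exhaustive distance search, independent of the
    package's neighbour-search implementation.
    """
    rng = np.random.default_rng(spec.seed)
    seq = spec.sequence or random_sequence(rng, spec.n_residues)
    n = len(seq)

    full_a = make_helix(seq, offset=1, chain_id="A")
    keep = _apply_deletions(list(range(1, n + 1)), spec.deleted_segments)
    if not keep:
        raise ValueError("deleted_segments remove every residue")
    chains = [_subset_helix(full_a, keep, spec.numbering_offset, "A")]

    anchor = {i: full_a.chains[0].residues[i - 1] for i in keep}

    if spec.with_dimer:
        # parallel helix B shifted in +x, then mirrored about its own axis so
        # the CG stubs of phase-0 residues face chain A across exactly
        # dimer_approach Angstrom (stub tips at radius HELIX_RADIUS + 2.9)
        shift = 2 * (HELIX_RADIUS + 2.9) + spec.dimer_approach
        full_b = make_helix(seq, offset=1, chain_id="B", origin=(shift, 0.0, 0.0))
        for res in full_b.chains[0].residues:
            for atom in res.atoms:
                atom.coords[0] = 2 * shift - atom.coords[0]
        chains.append(_subset_helix(full_b, keep, spec.numbering_offset_b, "B"))

    model = StructureModel(
        structure_id=f"fixture_{spec.seed}",
        source=StructureSource.EXPERIMENTAL,
        chains=chains,
    )

    def _stub_atom(pos: int) -> Atom:
        res = anchor.get(pos)
        if res is None:
            raise ValueError(f"planted position {pos} was deleted")
        for a in res.atoms:
            if a.name == "CG":
                return a
        return res.atoms[-1]

    hetero = Chain(chain_id="X")
    if spec.zinc_near is not None:
        a = _stub_atom(spec.zinc_near)
        outward = a.coords - np.array([0.0, 0.0, a.coords[2]])
        outward /= np.linalg.norm(outward)
        hetero.residues.append(
            ResidueRecord("X", 900, "", "ZN", ResidueCategory.METAL,
                          [Atom("ZN", "ZN", a.coords + spec.zinc_distance * outward)])
        )
    if spec.ligand_near is not None:
        a = _stub_atom(spec.ligand_near)
        outward = a.coords - np.array([0.0, 0.0, a.coords[2]])
        outward /= np.linalg.norm(outward)
        base = a.coords + spec.ligand_distance * outward
        hetero.residues.append(
            ResidueRecord("X", 901, "", "LIG", ResidueCategory.LIGAND,
                          [Atom("C1", "C", base),
                           Atom("C2", "C", base + np.array([1.4, 0.0, 0.0])),
                           Atom("O1", "O", base + np.array([0.0, 1.3, 0.0]))])
        )
    if hetero.residues:
        model.chains.append(hetero)

    if spec.dna_near is not None:
        a = _stub_atom(spec.dna_near)
        outward = a.coords - np.array([0.0, 0.0, a.coords[2]])
        outward /= np.linalg.norm(outward)
        # duplex axis dna_distance + 3 A away from the anchor atom, with one
        # nucleotide placed at the anchor's z and its N1 (radius 3 A from the
        # axis) rotated to face the anchor: closest approach = dna_distance
        center = a.coords + (spec.dna_distance + 3.0) * outward
        mid = (spec.dna_n_bp - 1) // 2
        origin = center - np.array([0.0, 0.0, BDNA_RISE * mid])
        facing = math.atan2(-outward[1], -outward[0])
        phase = facing - BDNA_TWIST * mid - 0.5
        for ch in make_bdna(spec.dna_n_bp, origin=origin, phase=phase):
            model.chains.append(ch)

    model.validate()
    truth = _brute_force_contexts(model)

    # sanity: the planted anchors must actually be flagged
    def _planted_key(pos: int) -> ResidueKey:
        return ("A", spec.numbering_offset + pos - 1, "")

    if spec.zinc_near is not None and spec.zinc_distance <= INTERFACE_CUTOFF:
        if not truth.get(_planted_key(spec.zinc_near), ContextFlags()).zinc_site:
            raise RuntimeError("unrealizable spec: planted zinc site not realized")
    if spec.ligand_near is not None and spec.ligand_distance <= LIGAND_CUTOFF:
        if not truth.get(_planted_key(spec.ligand_near), ContextFlags()).ligand_site:
            raise RuntimeError("unrealizable spec: planted ligand site not realized")
    if spec.dna_near is not None and spec.dna_distance <= INTERFACE_CUTOFF:
        if not truth.get(_planted_key(spec.dna_near), ContextFlags()).dna_interface:
            raise RuntimeError("unrealizable spec: planted DNA interface not realized")
    if spec.with_dimer and spec.dimer_approach <= INTERFACE_CUTOFF:
        if not any(cf.dimer_interface for cf in truth.values()):
            raise RuntimeError("unrealizable spec: planted dimer interface not realized")
    return model, truth


def make_predicted_model(
    sequence: str,
    plddt: Sequence[float],
    structure_id: str = "af_model",
) -> StructureModel:
    """Single-chain predicted model carrying per-residue pLDDT in the
    B-factor column, numbered 1..len(sequence)."""
    if len(plddt) != len(sequence):
        raise ValueError("plddt pattern length must equal sequence length")
    model = make_helix(sequence, offset=1, chain_id="A", temp_factors=list(plddt))
    model.structure_id = structure_id
    model.source = StructureSource.PREDICTED
    return model


def make_mutation_table(
    spec: FixtureSpec,
    path: str | Path,
) -> list[tuple[str, int]]:
    """Write a COSMIC-shaped TSV with the spec's mutation multiplicities.

    Rows are shuffled deterministically by the seed; each observation gets
    a distinct sample id.  Rejectable notations from ``spec.rejects`` are
    interleaved.  Returns the expected (notation, count) list unchanged.
    """
    rng = np.random.default_rng(spec.seed + 1)
    rows: list[tuple[str, str, str]] = []
    sample_no = 1
    for notation, count in spec.mutations:
        if count < 1:
            raise ValueError("multiplicities must be >= 1")
        for _ in range(count):
            rows.append((spec.gene, notation, f"TUMOUR_{sample_no:04d}"))
            sample_no += 1
    for notation in spec.rejects:
        rows.append((spec.gene, notation, f"TUMOUR_{sample_no:04d}"))
        sample_no += 1
    order = rng.permutation(len(rows))
    with open(path, "w") as fh:
        fh.write("Gene name\tMutation AA\tSample name\n")
        for i in order:
            fh.write("\t".join(rows[i]) + "\n")
    return list(spec.mutations)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model as a minimal standards-conforming PDB file."""
    serial = 1
    lines: list[str] = []
    for chain in model.chains:
        is_polymer = chain.polymer_type is not None
        for res in chain.residues:
            record = "ATOM  " if res.category in (
                ResidueCategory.PROTEIN, ResidueCategory.NUCLEIC) else "HETATM"
            for atom in res.atoms:
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                x, y, z = atom.coords
                lines.append(
                    f"{record}{serial:5d} {name:<4s}{'':1s}{res.comp_id:>3s} "
                    f"{chain.chain_id:1s}{res.auth_seq_num:4d}{res.insertion_code or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.temp_factor:6.2f}"
                    f"          {atom.element:>2s}"
                )
                serial += 1
        if is_polymer:
            lines.append(f"TER   {serial:5d}")
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def case_study_scenario(seed: int, out_dir: str | Path) -> dict:
    """Generate the full end-to-end scenario: homodimer + DNA + zinc +
    ligand complex, a predicted model with a planted disorder pattern, a
    reference FASTA, and a mutation table including the classic DNA-contact
    hotspot notations (R248Q, R248W, R273H, R273C, R282W, G245S).

    Returns a manifest with all paths and ground truth.  The reference is
    300 residues; the experimental dimer covers positions 240-299 so the
    remaining positions exercise the predicted-model fallback, and the
    first 123 positions (41%) carry low pLDDT.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n_ref = 300
    seq = list(random_sequence(rng, n_ref))
    # hotspot reference residues must match their notations; 240 and 276
    # are the dimer-facing helix positions and need full-length stubs
    for pos, aa in [(240, "L"), (245, "G"), (248, "R"), (273, "R"), (276, "E"), (282, "R")]:
        seq[pos - 1] = aa
    reference = "".join(seq)

    window_start, window_end = 240, 299  # inclusive, 1-based
    sub_seq = reference[window_start - 1 : window_end]

    spec = FixtureSpec(
        seed=seed,
        sequence=sub_seq,
        numbering_offset=1040,       # arbitrary author numbering, recovered by alignment
        numbering_offset_b=40,
        with_dimer=True,
        dimer_approach=4.5,
        dna_near=248 - window_start + 1,
        dna_distance=4.0,
        zinc_near=282 - window_start + 1,
        zinc_distance=3.0,
        ligand_near=260 - window_start + 1,
        ligand_distance=4.0,
        gene="GENE1",
    )
    complex_model, truth = make_complex(spec)
    complex_model.structure_id = "SYNTH1"
    pdb_path = out_dir / "synth1.pdb"
    write_pdb(complex_model, pdb_path)

    plddt = [30.0 if i < 123 else 90.0 for i in range(n_ref)]
    predicted = make_predicted_model(reference, plddt, structure_id="AF_SYNTH")
    pred_path = out_dir / "af_synth.pdb"
    write_pdb(predicted, pred_path)

    fasta_path = out_dir / "reference.fasta"
    fasta_path.write_text(
        ">SYNTH_REF synthetic reference\n"
        + "\n".join(reference[i : i + 60] for i in range(0, n_ref, 60))
        + "\n"
    )

    # 20 unique planted mutations: 6 hotspots + 8 covered + 6 in the
    # disordered N-terminal region (predicted-model fallback)
    covered_positions = [240, 250, 255, 260, 270, 276, 281, 290]
    disorder_positions = [5, 20, 47, 60, 88, 110]
    mutations: list[tuple[str, int]] = []
    hotspots = ["R248Q", "R248W", "R273H", "R273C", "R282W", "G245S"]
    hotspot_counts = [30, 22, 25, 18, 15, 12]
    for notation, cnt in zip(hotspots, hotspot_counts):
        mutations.append((notation, cnt))
    for pos in covered_positions + disorder_positions:
        ref_aa = reference[pos - 1]
        alt = rng.choice([a for a in AA1 if a != ref_aa])
        mutations.append((f"{ref_aa}{pos}{alt}", int(rng.integers(1, 9))))
    table_spec = FixtureSpec(seed=seed, mutations=mutations, gene="GENE1",
                             rejects=["p.Thr125Thr", "p.Gly154fs", "p.?"])
    table_path = out_dir / "mutations.tsv"
    make_mutation_table(table_spec, table_path)

    return {
        "reference_fasta": str(fasta_path),
        "reference": reference,
        "structure_pdb": str(pdb_path),
        "predicted_pdb": str(pred_path),
        "mutation_table": str(table_path),
        "window": (window_start, window_end),
        "numbering_offset": spec.numbering_offset,
        "numbering_offset_b": spec.numbering_offset_b,
        "context_truth": truth,
        "planted_mutations": mutations,
        "n_rejects": 3,
        "disordered_positions": set(range(1, 124)),
        "plddt": plddt,
        "gene": "GENE1",
    }
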