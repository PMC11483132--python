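"""Distance-based structural context annotation.

Four independent, overlapping contexts are flagged per protein residue
from minimal heavy-atom distances:

* ligand site: any heavy atom within 6.0 A of a ligand heavy atom
  (waters and simple ions are never ligands),
* dimer interface: within 5.0 A of a heavy atom of a *different* protein
  chain,
* DNA interface: within 5.0 A of a nucleic-acid heavy atom (RNA chains
  are treated under the same rule),
* zinc site: within 5.0 A of a zinc ion.

Neighbour search uses a k-d tree but is contractually identical to an
exhaustive all-pairs scan; the test suite enforces this against a
brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy.spatial import cKDTree

from .model import ResidueCategory, ResidueKey, ResidueRecord, StructureModel

__all__ = [
    "ContextFlags",
    "find_neighbors",
    "annotate_ligand_sites",
    "annotate_dimer_interface",
    "annotate_dna_interface",
    "annotate_zinc_sites",
    "annotate_contexts",
    "LIGAND_CUTOFF",
    "INTERFACE_CUTOFF",
]

LIGAND_CUTOFF = 6.0
INTERFACE_CUTOFF = 5.0


@dataclass
class ContextFlags:
    """Independent structural-context flags for one protein residue.

    ``min_distances`` records, per context name, the minimal heavy-atom
    distance that triggered the flag; it holds entries only for contexts
    that are flagged true.
    """

    ligand_site: bool = False
    ligand_ids: list[str] = field(default_factory=list)
    dimer_interface: bool = False
    partner_chains: list[str] = field(default_factory=list)
    dna_interface: bool = False
    zinc_site: bool = False
    min_distances: dict[str, float] = field(default_factory=dict)

    def any(self) -> bool:
        return self.ligand_site or self.dimer_interface or self.dna_interface or self.zinc_site


def _residue_atoms(residues: Iterable[ResidueRecord]):
    """Flatten residues into (coords array, residue-index array, residue list)."""
    res_list = list(residues)
    coords = []
    owner = []
    for idx, res in enumerate(res_list):
        for atom in res.heavy_atoms():
            coords.append(atom.coords)
            owner.append(idx)
    if not coords:
        return np.empty((0, 3)), np.empty(0, dtype=int), res_list
    return np.asarray(coords), np.asarray(owner, dtype=int), res_list


def find_neighbors(
    source: Iterable[ResidueRecord],
    target: Iterable[ResidueRecord],
    cutoff: float,
) -> dict[tuple[ResidueKey, ResidueKey], float]:
    """Residue pairs with any heavy-atom pair within ``cutoff`` Angstrom.

    Returns ``{(source_key, target_key): min_distance}`` containing exactly
    the pairs whose minimal heavy-atom distance is <= cutoff.  Pairs of a
    residue with itself are excluded.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    s_xyz, s_owner, s_res = _residue_atoms(source)
    t_xyz, t_owner, t_res = _residue_atoms(target)
    out: dict[tuple[ResidueKey, ResidueKey], float] = {}
    if len(s_xyz) == 0 or len(t_xyz) == 0:
        return out
    tree = cKDTree(t_xyz)
    pairs = tree.query_ball_point(s_xyz, cutoff)
    for si, hits in enumerate(pairs):
        if not hits:
            continue
        skey = s_res[s_owner[si]].key
        d = np.sqrt(np.sum((t_xyz[hits] - s_xyz[si]) ** 2, axis=1))
        for ti, dist in zip(hits, d):
            tkey = t_res[t_owner[ti]].key
            if tkey == skey:
                continue
            pair = (skey, tkey)
            if pair not in out or dist < out[pair]:
                out[pair] = float(dist)
    return out


def _ensure(flags: dict[ResidueKey, ContextFlags], key: ResidueKey) -> ContextFlags:
    if key not in flags:
        flags[key] = ContextFlags()
    return flags[key]


def _record_distance(cf: ContextFlags, context: str, dist: float) -> None:
    if context not in cf.min_distances or dist < cf.min_distances[context]:
        cf.min_distances[context] = dist


def annotate_ligand_sites(
    model: StructureModel,
    cutoff: float = LIGAND_CUTOFF,
    flags: Optional[dict[ResidueKey, ContextFlags]] = None,
) -> dict[ResidueKey, ContextFlags]:
    """Flag protein residues within ``cutoff`` of any ligand heavy atom."""
    flags = flags if flags is not None else {}
    protein = model.residues_by_category(ResidueCategory.PROTEIN)
    ligands = model.residues_by_category(ResidueCategory.LIGAND)
    lig_comp = {r.key: r.comp_id for r in ligands}
    for (pkey, lkey), dist in find_neighbors(protein, ligands, cutoff).items():
        cf = _ensure(flags, pkey)
        cf.ligand_site = True
        comp = lig_comp[lkey]
        if comp not in cf.ligand_ids:
            cf.ligand_ids.append(comp)
        _record_distance(cf, "ligand_site", dist)
    return flags


def annotate_dimer_interface(
    model: StructureModel,
    cutoff: float = INTERFACE_CUTOFF,
    flags: Optional[dict[ResidueKey, ContextFlags]] = None,
) -> dict[ResidueKey, ContextFlags]:
    """Flag protein residues within ``cutoff`` of a different protein chain."""
    flags = flags if flags is not None else {}
    chains = model.protein_chains()
    for chain in chains:
        others = [
            r
            for other in chains
            if other.chain_id != chain.chain_id
            for r in other.protein_residues()
        ]
        if not others:
            continue
        hits = find_neighbors(chain.protein_residues(), others, cutoff)
        for (pkey, okey), dist in hits.items():
            cf = _ensure(flags, pkey)
            cf.dimer_interface = True
            partner = okey[0]
            if partner not in cf.partner_chains:
                cf.partner_chains.append(partner)
            _record_distance(cf, "dimer_interface", dist)
    for cf in flags.values():
        cf.partner_chains.sort()
    return flags


def annotate_dna_interface(
    model: StructureModel,
    cutoff: float = INTERFACE_CUTOFF,
    flags: Optional[dict[ResidueKey, ContextFlags]] = None,
) -> dict[ResidueKey, ContextFlags]:
    """Flag protein residues within ``cutoff`` of nucleic-acid atoms."""
    flags = flags if flags is not None else {}
    protein = model.residues_by_category(ResidueCategory.PROTEIN)
    nucleic = model.residues_by_category(ResidueCategory.NUCLEIC)
    for (pkey, _nkey), dist in find_neighbors(protein, nucleic, cutoff).items():
        cf = _ensure(flags, pkey)
        cf.dna_interface = True
        _record_distance(cf, "dna_interface", dist)
    return flags


def annotate_zinc_sites(
    model: StructureModel,
    cutoff: float = INTERFACE_CUTOFF,
    flags: Optional[dict[ResidueKey, ContextFlags]] = None,
) -> dict[ResidueKey, ContextFlags]:
    """Flag protein residues within ``cutoff`` of any zinc ion."""
    flags = flags if flags is not None else {}
    protein = model.residues_by_category(ResidueCategory.PROTEIN)
    zincs = [
        r for r in model.residues_by_category(ResidueCategory.METAL)
        if r.comp_id.upper() == "ZN"
    ]
    for (pkey, _zkey), dist in find_neighbors(protein, zincs, cutoff).items():
        cf = _ensure(flags, pkey)
        cf.zinc_site = True
        _record_distance(cf, "zinc_site", dist)
    return flags


def annotate_contexts(
    model: StructureModel,
    ligand_cutoff: float = LIGAND_CUTOFF,
    interface_cutoff: float = INTERFACE_CUTOFF,
) -> dict[ResidueKey, ContextFlags]:
    """Run all four context annotations; contexts are independent flags,
    so one residue may carry several simultaneously (e.g. a zinc-site
    residue at the DNA interface)."""
    flags: dict[ResidueKey, ContextFlags] = {}
    annotate_ligand_sites(model, ligand_cutoff, flags)
    annotate_dimer_interface(model, interface_cutoff, flags)
    annotate_dna_interface(model, interface_cutoff, flags)
    annotate_zinc_sites(model, interface_cutoff, flags)
    return flags
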