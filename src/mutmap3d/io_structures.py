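"""Read PDB / mmCIF files into the internal structure model; write result tables.

Parsing is delegated to gemmi; this module maps gemmi's hierarchy onto the
package's :class:`~mutmap3d.model.StructureModel` and applies the
normalization rules used throughout the pipeline:

* multi-model files keep model 1 only (logged),
* alternate locations are resolved to the highest-occupancy conformer
  (ties broken by altloc letter order),
* hydrogens are parsed and flagged but excluded from SASA and distance
  computations downstream,
* waters are retained but categorized separately.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Optional

import gemmi
import pandas as pd

from .model import (
    Atom,
    Chain,
    NUCLEIC_CODES,
    ResidueCategory,
    ResidueRecord,
    StructureModel,
    StructureSource,
    THREE_TO_ONE,
    categorize_residue,
)

logger = logging.getLogger(__name__)

__all__ = [
    "parse_structure",
    "observed_sequence",
    "write_annotation_table",
    "read_annotation_table",
    "ANNOTATION_COLUMNS",
]


class NoProteinContentError(ValueError):
    """Raised when a parsed file contains no protein residues."""


def _detect_format(path: Path, format: str) -> gemmi.CoorFormat:
    if format == "pdb":
        return gemmi.CoorFormat.Pdb
    if format == "mmcif":
        return gemmi.CoorFormat.Mmcif
    if format == "auto":
        suffix = path.suffix.lower()
        if suffix in (".pdb", ".ent"):
            return gemmi.CoorFormat.Pdb
        if suffix in (".cif", ".mmcif"):
            return gemmi.CoorFormat.Mmcif
        return gemmi.CoorFormat.Detect
    raise ValueError(f"unknown structure format {format!r}")


def _altloc_char(atom: gemmi.Atom) -> str:
    return atom.altloc if atom.altloc and atom.altloc != "\x00" else ""


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties broken by
    altloc letter order.  Never changes the residue count."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = by_name.get(atom.name)
        if prev is None or (atom.occ, -ord(_altloc_char(atom) or "~")) > (
            prev.occ,
            -ord(_altloc_char(prev) or "~"),
        ):
            by_name[atom.name] = atom
    return list(by_name.values())


def parse_structure(
    path: str | Path,
    format: str = "auto",
    structure_id: Optional[str] = None,
    source: StructureSource | str = StructureSource.EXPERIMENTAL,
    nucleic_codes: frozenset[str] = NUCLEIC_CODES,
) -> StructureModel:
    """Parse a PDB or mmCIF file into a :class:`StructureModel`.

    Parameters
    ----------
    path:
        Path to the coordinate file.
    format:
        ``"pdb"``, ``"mmcif"`` or ``"auto"`` (infer from extension, then
        content).
    structure_id:
        Identifier for the structure; defaults to the file stem.
    source:
        ``experimental`` or ``predicted``.  For predicted models the
        B-factor column is interpreted as pLDDT downstream.

    Raises
    ------
    NoProteinContentError
        If the file contains no protein residues.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    source = StructureSource(source)
    st = gemmi.read_structure(str(path), format=_detect_format(path, format))
    st.setup_entities()

    if len(st) == 0:
        raise NoProteinContentError(f"{path}: no coordinate models")
    if len(st) > 1:
        logger.info("%s: %d models present; keeping model 1 only", path.name, len(st))
    gmodel = st[0]

    model = StructureModel(
        structure_id=structure_id or path.stem,
        source=source,
        model_number=1,
    )
    unknown_codes: set[str] = set()
    for gchain in gmodel:
        chain = Chain(chain_id=gchain.name)
        for gres in gchain:
            comp = gres.name.strip().upper()
            category = categorize_residue(comp, nucleic_codes=nucleic_codes)
            if (
                category is ResidueCategory.LIGAND
                and comp not in unknown_codes
                and not gemmi.find_tabulated_residue(comp).found()
            ):
                unknown_codes.add(comp)
                logger.warning("unknown residue code %s categorized as ligand", comp)
            icode = gres.seqid.icode.strip()
            rec = ResidueRecord(
                chain_id=gchain.name,
                auth_seq_num=gres.seqid.num,
                insertion_code=icode,
                comp_id=comp,
                category=category,
            )
            for gatom in _resolve_altlocs(gres):
                el = gatom.element
                element = "" if el.name in ("X", "") else el.name
                rec.atoms.append(
                    Atom(
                        name=gatom.name,
                        element=element,
                        coords=[gatom.pos.x, gatom.pos.y, gatom.pos.z],
                        occupancy=gatom.occ,
                        temp_factor=gatom.b_iso,
                        alt_loc=_altloc_char(gatom),
                        is_hydrogen=bool(el.is_hydrogen),
                    )
                )
            if rec.atoms:
                chain.residues.append(rec)
        if chain.residues:
            model.chains.append(chain)

    model.validate()
    if not any(r.category is ResidueCategory.PROTEIN for r in model.iter_residues()):
        raise NoProteinContentError(f"{path}: no protein content")
    return model


def observed_sequence(
    model: StructureModel, chain_id: str
) -> tuple[str, list[tuple[int, str]]]:
    """One-letter sequence of a protein chain plus parallel residue numbers.

    Non-standard amino acids map through the modified-residue table
    (e.g. MSE -> M); residues with unknown codes become 'X'.

    Returns
    -------
    (sequence, numbering):
        ``sequence[i]`` is the one-letter code of the residue identified by
        ``numbering[i] == (auth_seq_num, insertion_code)``.
    """
    chain = model.get_chain(chain_id)
    if chain.polymer_type is not ResidueCategory.PROTEIN:
        raise ValueError(f"chain {chain_id!r} is not a protein chain")
    letters: list[str] = []
    numbering: list[tuple[int, str]] = []
    for res in chain.residues:
        if res.category is not ResidueCategory.PROTEIN:
            continue
        letters.append(res.one_letter())
        numbering.append((res.auth_seq_num, res.insertion_code))
    return "".join(letters), numbering


#: fixed column order of the annotated-mutation table (TSV header).
ANNOTATION_COLUMNS = [
    "gene",
    "position",
    "ref_aa",
    "alt_aa",
    "count",
    "frequency",
    "structure_id",
    "chain_id",
    "mapped_via",
    "observed_aa",
    "ref_mismatch",
    "relative_sasa",
    "burial",
    "ligand_site",
    "ligand_ids",
    "dimer_interface",
    "partner_chains",
    "dna_interface",
    "zinc_site",
    "in_disorder",
]


def write_annotation_table(
    rows: Iterable[dict],
    path: str | Path,
    format: str = "tsv",
) -> None:
    """Write annotated mutations to TSV (fixed header) or JSON (array of
    objects).  Both formats round-trip through
    :func:`read_annotation_table` losslessly."""
    path = Path(path)
    records = [dict(r) for r in rows]
    df = pd.DataFrame(records, columns=ANNOTATION_COLUMNS)
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1, sort_keys=False)
            fh.write("\n")
    else:
        raise ValueError(f"unknown table format {format!r}")


def read_annotation_table(path: str | Path, format: str = "tsv") -> list[dict]:
    """Read back a table written by :func:`write_annotation_table`."""
    path = Path(path)
    if format == "json":
        with open(path) as fh:
            return json.load(fh)
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    out = []
    for rec in df.to_dict(orient="records"):
        clean = {}
        for k, v in rec.items():
            if isinstance(v, float) and pd.isna(v):
                v = None
            clean[k] = v
        out.append(clean)
    return out
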