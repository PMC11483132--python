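"""Internal structure model: atoms, residues, chains, structures.

All coordinates are in Angstrom.  Residues are categorized into five
classes (protein, nucleic, ligand, metal, water) that drive every
downstream annotation rule: ligand-site and zinc-site detection select on
``category``, DNA-interface detection selects on ``nucleic``, and SASA /
burial scoring considers protein residues only.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Optional

import numpy as np

logger = logging.getLogger(__name__)

#: residue codes treated as nucleic acid (DNA + RNA); configurable via
#: :func:`categorize_residue`'s ``nucleic_codes`` argument.
NUCLEIC_CODES = frozenset({"DA", "DC", "DG", "DT", "DU", "A", "C", "G", "U"})

#: water residue codes
WATER_CODES = frozenset({"HOH", "WAT", "DOD", "H2O"})

#: single-element ion codes mapped to the metal category.  ZN is a metal
#: like the rest but is singled out by the zinc-site annotation.
METAL_CODES = frozenset(
    {"ZN", "NA", "K", "MG", "CA", "MN", "FE", "CU", "NI", "CO", "CD", "HG", "CL", "BR", "IOD", "F"}
)

#: three-letter -> one-letter amino-acid codes, including common
#: chemically modified residues seen in depositions.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # modified residues -> parent
    "MSE": "M", "SEC": "U", "PYL": "O", "SEP": "S", "TPO": "T",
    "PTR": "Y", "CSO": "C", "CSD": "C", "CME": "C", "OCS": "C",
    "HYP": "P", "MLY": "K", "M3L": "K", "KCX": "K", "LLP": "K",
    "FME": "M", "PCA": "E", "CGU": "E", "DAL": "A", "ABA": "A",
}

ONE_TO_THREE = {v: k for k, v in reversed(list(THREE_TO_ONE.items()))}

AA1 = "ACDEFGHIKLMNPQRSTVWY"


class ResidueCategory(str, Enum):
    PROTEIN = "protein"
    NUCLEIC = "nucleic"
    LIGAND = "ligand"
    METAL = "metal"
    WATER = "water"


class StructureSource(str, Enum):
    EXPERIMENTAL = "experimental"
    PREDICTED = "predicted"


def categorize_residue(
    comp_id: str,
    nucleic_codes: frozenset[str] = NUCLEIC_CODES,
) -> ResidueCategory:
    """Assign a residue category from its component code.

    Unknown codes fall through to ``ligand`` (with a warning emitted by the
    parser); waters are retained but categorized separately so geometric
    annotations can skip them.
    """
    comp = comp_id.strip().upper()
    if comp in THREE_TO_ONE:
        return ResidueCategory.PROTEIN
    if comp in nucleic_codes:
        return ResidueCategory.NUCLEIC
    if comp in WATER_CODES:
        return ResidueCategory.WATER
    if comp in METAL_CODES:
        return ResidueCategory.METAL
    return ResidueCategory.LIGAND


@dataclass
class Atom:
    """One atom with coordinates in Angstrom.

    ``temp_factor`` carries the crystallographic B-factor for experimental
    structures and the per-residue pLDDT confidence (0-100) for predicted
    models.
    """

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    temp_factor: float = 0.0
    alt_loc: str = ""
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coords must be 3 finite reals")
        if not 0.0 <= self.occupancy <= 1.0:
            logger.warning(
                "atom %s: occupancy %.3f outside [0,1]; clamped", self.name, self.occupancy
            )
            self.occupancy = min(max(self.occupancy, 0.0), 1.0)
        if not self.element:
            self.element = infer_element(self.name)
        self.element = self.element.strip().upper()
        if not self.is_hydrogen and self.element in ("H", "D"):
            self.is_hydrogen = True


def infer_element(atom_name: str) -> str:
    """Infer an element symbol from a PDB atom name when the element
    column is blank.  Digits and apostrophes are stripped; a leading H in
    names like ``1HB`` or ``HG21`` means hydrogen."""
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    if stripped[0] in ("H", "D") and (len(atom_name.strip()) > 2 or atom_name[:1].isdigit()):
        return stripped[0]
    # two-letter elements occur left-justified in 4-char names (FE, ZN, MG)
    two = stripped[:2].upper()
    if two in ("FE", "ZN", "MG", "MN", "CU", "NI", "CO", "CD", "SE", "BR", "CL", "NA"):
        return two
    return stripped[0].upper()


ResidueKey = tuple[str, int, str]  # (chain_id, auth_seq_num, insertion_code)


@dataclass
class ResidueRecord:
    chain_id: str
    auth_seq_num: int
    insertion_code: str
    comp_id: str
    category: ResidueCategory
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.auth_seq_num, self.insertion_code)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def one_letter(self) -> str:
        """One-letter code for protein residues; 'X' for unknown codes."""
        return THREE_TO_ONE.get(self.comp_id.upper(), "X")

    def mean_temp_factor(self) -> float:
        vals = [a.temp_factor for a in self.atoms]
        return float(np.mean(vals)) if vals else float("nan")


@dataclass
class Chain:
    chain_id: str
    residues: list[ResidueRecord] = field(default_factory=list)

    @property
    def polymer_type(self) -> Optional[ResidueCategory]:
        """Dominant polymer category of the chain, or None if non-polymer."""
        counts = {ResidueCategory.PROTEIN: 0, ResidueCategory.NUCLEIC: 0}
        for r in self.residues:
            if r.category in counts:
                counts[r.category] += 1
        if not any(counts.values()):
            return None
        return max(counts, key=lambda c: counts[c])

    def protein_residues(self) -> list[ResidueRecord]:
        return [r for r in self.residues if r.category is ResidueCategory.PROTEIN]


@dataclass
class StructureModel:
    structure_id: str
    source: StructureSource
    chains: list[Chain] = field(default_factory=list)
    model_number: int = 1

    def get_chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(f"chain {chain_id!r} not found in {self.structure_id}")

    def protein_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.polymer_type is ResidueCategory.PROTEIN]

    def iter_residues(self) -> Iterator[ResidueRecord]:
        for ch in self.chains:
            yield from ch.residues

    def residues_by_category(self, category: ResidueCategory) -> list[ResidueRecord]:
        return [r for r in self.iter_residues() if r.category is category]

    def residue_index(self) -> dict[ResidueKey, ResidueRecord]:
        return {r.key: r for r in self.iter_residues()}

    def copy(self) -> "StructureModel":
        return copy.deepcopy(self)

    def validate(self) -> None:
        """Check the uniqueness invariant on residue identifiers."""
        seen: set[ResidueKey] = set()
        for r in self.iter_residues():
            if r.key in seen:
                raise ValueError(f"duplicate residue identifier {r.key} in {self.structure_id}")
            seen.add(r.key)
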