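"""Shrake-Rupley solvent-accessible surface area and burial classification.

The Shrake-Rupley algorithm estimates each atom's solvent-accessible
surface area (SASA) by distributing ``n_points`` test points on a sphere
of radius ``r_atom + probe`` around the atom and counting the points not
occluded by any neighbouring atom's expanded sphere:

    area = (accessible points / n_points) * 4 * pi * (r_atom + probe)^2

Test points are placed by a deterministic golden-section spiral, so
results are exactly reproducible.  The probe radius defaults to 1.4 A
(water).  Hydrogens and waters are excluded both as scored atoms and as
occluders by default, keeping values comparable to standard practice for
X-ray depositions that lack hydrogens.

Residue burial is classified on the *relative* accessibility scale
(percent of the residue type's theoretical Gly-X-Gly maximum):
below 25% core, 25-80% noninterface, above 80% exposed.  The exposed
class is sometimes called "interface" in the solvent-accessibility
literature; this package reserves "interface" for the distance-based
chain-chain and protein-DNA annotations and labels the SASA class
"exposed".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .model import ResidueCategory, ResidueKey, StructureModel

__all__ = [
    "SasaResult",
    "BurialClass",
    "shrake_rupley",
    "relative_sasa",
    "classify_burial",
    "sphere_points",
    "load_radii_table",
    "load_max_area_table",
    "DEFAULT_PROBE_RADIUS",
    "DEFAULT_N_POINTS",
    "CORE_THRESHOLD",
    "EXPOSED_THRESHOLD",
]

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_N_POINTS = 960
CORE_THRESHOLD = 25.0
EXPOSED_THRESHOLD = 80.0

BurialClass = str  # one of "core", "noninterface", "exposed", "unscored"


def _data_text(name: str) -> str:
    return resources.files("mutmap3d.data").joinpath(name).read_text()


def load_radii_table(path: Optional[str | Path] = None) -> dict:
    """Load the van der Waals radii table.

    Returns a dict with keys ``"element"`` (symbol -> radius) and
    ``"override"`` ((comp_id, atom_name) -> radius).
    """
    text = Path(path).read_text() if path else _data_text("sasa_radii.txt")
    element: dict[str, float] = {}
    override: dict[tuple[str, str], float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if parts[0] == "ELEM" and len(parts) == 3:
            element[parts[1].upper()] = float(parts[2])
        elif parts[0] == "ATOM" and len(parts) == 4:
            override[(parts[1].upper(), parts[2].upper())] = float(parts[3])
        else:
            raise ValueError(f"bad radii table line: {line!r}")
    return {"element": element, "override": override}


def load_max_area_table(path: Optional[str | Path] = None) -> dict[str, float]:
    """Load the per-residue-type maximum-area normalization table (A^2)."""
    text = Path(path).read_text() if path else _data_text("max_sasa.txt")
    table: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        comp, area = line.split()
        table[comp.upper()] = float(area)
    return table


def sphere_points(n: int) -> np.ndarray:
    """``n`` points on the unit sphere along a golden-section spiral.

    Deterministic and nearly uniform; quadrature error of the resulting
    area estimate is bounded by one point's share of the sphere.
    """
    if n < 32:
        raise ValueError("n_points must be >= 32")
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = k * math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


@dataclass
class SasaResult:
    """Per-atom and per-residue solvent accessibility.

    ``per_atom_area`` is keyed by ``(residue_key, atom_name)``;
    ``per_residue_area`` sums each residue's heavy atoms exactly;
    ``per_residue_relative`` is in percent of the residue type's maximum
    (``None`` when the type has no normalization entry).
    """

    per_atom_area: dict[tuple[ResidueKey, str], float] = field(default_factory=dict)
    per_residue_area: dict[ResidueKey, float] = field(default_factory=dict)
    per_residue_relative: dict[ResidueKey, Optional[float]] = field(default_factory=dict)
    probe_radius: float = DEFAULT_PROBE_RADIUS
    n_sphere_points: int = DEFAULT_N_POINTS

    @property
    def total_area(self) -> float:
        return float(sum(self.per_residue_area.values()))


def _atom_radius(comp_id: str, atom_name: str, element: str, radii: dict,
                 default_radius: Optional[float]) -> float:
    r = radii["override"].get((comp_id.upper(), atom_name.upper()))
    if r is not None:
        return r
    r = radii["element"].get(element.upper())
    if r is not None:
        return r
    if default_radius is not None:
        return default_radius
    raise KeyError(
        f"no radius for element {element!r} (atom {atom_name} in {comp_id}); "
        "add it to the radii table or set default_radius"
    )


def shrake_rupley(
    model: StructureModel,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    radii: Optional[dict] = None,
    max_area_table: Optional[dict[str, float]] = None,
    include_waters: bool = False,
    default_radius: Optional[float] = None,
) -> SasaResult:
    """Compute SASA for every non-hydrogen atom of the model.

    The structure is scored as given in the file: in a complex, partner
    chains, ligands and ions occlude each other.  Waters are excluded from
    both scoring and occlusion unless ``include_waters``.

    Relative per-residue accessibility is filled for protein residues
    whose type appears in the max-area table; other residues get ``None``.
    """
    radii = radii if radii is not None else load_radii_table()
    max_area_table = max_area_table if max_area_table is not None else load_max_area_table()

    atoms: list[tuple[ResidueKey, str, float]] = []  # (residue key, atom name, radius)
    coords: list[np.ndarray] = []
    residues = []
    for res in model.iter_residues():
        if res.category is ResidueCategory.WATER and not include_waters:
            continue
        residues.append(res)
        for atom in res.heavy_atoms():
            atoms.append(
                (res.key, atom.name,
                 _atom_radius(res.comp_id, atom.name, atom.element, radii, default_radius))
            )
        coords.extend(a.coords for a in res.heavy_atoms())
    if not atoms:
        raise ValueError("model has no non-hydrogen atoms to score")

    xyz = np.asarray(coords, dtype=float)
    rad = np.array([a[2] for a in atoms], dtype=float)
    expanded = rad + probe_radius
    unit = sphere_points(n_points)

    tree = cKDTree(xyz)
    max_expanded = float(expanded.max())
    result = SasaResult(probe_radius=probe_radius, n_sphere_points=n_points)

    for i in range(len(atoms)):
        pts = xyz[i] + expanded[i] * unit
        # any neighbour within expanded_i + expanded_j can occlude
        neighbors = tree.query_ball_point(xyz[i], expanded[i] + max_expanded)
        neighbors = [j for j in neighbors if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
        frac = accessible.sum() / n_points
        area = frac * 4.0 * math.pi * expanded[i] ** 2
        result.per_atom_area[(atoms[i][0], atoms[i][1])] = float(area)

    for res in residues:
        key = res.key
        area = float(
            sum(result.per_atom_area[(key, a.name)] for a in res.heavy_atoms())
        )
        result.per_residue_area[key] = area
    result.per_residue_relative = relative_sasa(result, max_area_table,
                                                {r.key: r.comp_id for r in residues})
    return result


def relative_sasa(
    result: SasaResult,
    max_area_table: dict[str, float],
    comp_ids: dict[ResidueKey, str],
) -> dict[ResidueKey, Optional[float]]:
    """Convert absolute residue areas to percent of the type maximum.

    Residues whose type is absent from the table are marked ``None``
    (missing), never silently zero.
    """
    out: dict[ResidueKey, Optional[float]] = {}
    for key, area in result.per_residue_area.items():
        max_area = max_area_table.get(comp_ids.get(key, "").upper())
        out[key] = 100.0 * area / max_area if max_area else None
    return out


def classify_burial(relative_pct: Optional[float]) -> BurialClass:
    """Classify a residue's burial from its relative accessibility.

    Below 25% core; 25-80% (inclusive) noninterface; above 80% exposed.
    Missing values yield ``"unscored"``.
    """
    if relative_pct is None or (isinstance(relative_pct, float) and math.isnan(relative_pct)):
        return "unscored"
    if relative_pct < 0:
        raise ValueError(f"relative accessibility must be >= 0, got {relative_pct}")
    if relative_pct < CORE_THRESHOLD:
        return "core"
    if relative_pct <= EXPOSED_THRESHOLD:
        return "noninterface"
    return "exposed"
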