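"""Shrake-Rupley SASA: analytic single-sphere oracle, additivity,
occlusion monotonicity, burial boundaries, and cross-validation against
the independent Bio.PDB implementation."""

import math

import numpy as np
import pytest

from mutmap3d.fixtures import FixtureSpec, make_complex, make_helix, write_pdb
from mutmap3d.model import (
    Atom,
    Chain,
    ResidueCategory,
    ResidueRecord,
    StructureModel,
    StructureSource,
)
from mutmap3d.sasa import (
    CORE_THRESHOLD,
    EXPOSED_THRESHOLD,
    classify_burial,
    load_max_area_table,
    load_radii_table,
    relative_sasa,
    shrake_rupley,
    sphere_points,
)

RADII = load_radii_table()
PROBE = 1.4


def _single_atom_model(element: str, comp: str = "LIG") -> StructureModel:
    res = ResidueRecord("A", 1, "", comp, ResidueCategory.LIGAND,
                        [Atom(element, element, np.zeros(3))])
    return StructureModel("one", StructureSource.EXPERIMENTAL, [Chain("A", [res])])


def _cloud_model(xyz: np.ndarray) -> StructureModel:
    chain = Chain("A")
    for i, p in enumerate(xyz):
        chain.residues.append(
            ResidueRecord("A", i + 1, "", "LIG", ResidueCategory.LIGAND,
                          [Atom("C1", "C", p)])
        )
    return StructureModel("cloud", StructureSource.EXPERIMENTAL, [chain])


@pytest.mark.parametrize("element", sorted(set(RADII["element"]) - {"H", "D"}))
def test_single_atom_matches_closed_form(element):
    """An isolated sphere's SASA is exactly 4*pi*(r+probe)^2: with no
    occluders every quadrature point is accessible."""
    n_points = 960
    result = shrake_rupley(_single_atom_model(element), n_points=n_points)
    r = RADII["element"][element]
    expected = 4.0 * math.pi * (r + PROBE) ** 2
    quadrature_resolution = expected / n_points
    assert result.total_area == pytest.approx(expected, abs=quadrature_resolution)


def test_two_distant_atoms_additive():
    chain = Chain("A")
    for i, x in enumerate((0.0, 100.0)):
        chain.residues.append(
            ResidueRecord("A", i + 1, "", "LIG", ResidueCategory.LIGAND,
                          [Atom("C1", "C", [x, 0.0, 0.0])])
        )
    model = StructureModel("two", StructureSource.EXPERIMENTAL, [chain])
    result = shrake_rupley(model, n_points=960)
    single = 4.0 * math.pi * (RADII["element"]["C"] + PROBE) ** 2
    for area in result.per_residue_area.values():
        assert area == pytest.approx(single)


def test_fully_caged_atom_has_zero_area():
    chain = Chain("A")
    chain.residues.append(
        ResidueRecord("A", 1, "", "MG", ResidueCategory.METAL,
                      [Atom("MG", "MG", np.zeros(3))])
    )
    cage = ResidueRecord("A", 2, "", "LIG", ResidueCategory.LIGAND, [])
    for k, axis in enumerate(np.vstack([np.eye(3), -np.eye(3)])):
        cage.atoms.append(Atom(f"C{k + 1}", "C", 2.0 * axis))
    chain.residues.append(cage)
    model = StructureModel("cage", StructureSource.EXPERIMENTAL, [chain])
    result = shrake_rupley(model, n_points=960)
    assert result.per_residue_area[("A", 1, "")] == 0.0


def test_additivity_exact(scenario):
    from mutmap3d.io_structures import parse_structure

    model = parse_structure(scenario["structure_pdb"])
    result = shrake_rupley(model, n_points=120)
    per_atom_sum = sum(result.per_atom_area.values())
    per_res_sum = sum(result.per_residue_area.values())
    assert per_atom_sum == pytest.approx(per_res_sum, abs=1e-9)
    assert result.total_area == pytest.approx(per_atom_sum, abs=1e-9)


def test_occlusion_monotonicity():
    """Adding an occluding atom never increases any other atom's area."""
    rng = np.random.default_rng(2)
    xyz = rng.uniform(0, 12, size=(30, 3))
    base = shrake_rupley(_cloud_model(xyz), n_points=240)
    extra = np.vstack([xyz, xyz[0] + [1.0, 1.0, 1.0]])
    more = shrake_rupley(_cloud_model(extra), n_points=240)
    for key, area in base.per_atom_area.items():
        assert more.per_atom_area[key] <= area + 1e-9


def test_hydrogens_and_waters_excluded():
    model = make_helix("ACD")
    model.chains[0].residues[0].atoms.append(Atom("H", "H", [0.0, 0.0, -1.0]))
    model.chains[0].residues.append(
        ResidueRecord("A", 99, "", "HOH", ResidueCategory.WATER,
                      [Atom("O", "O", [0.0, 0.0, -5.0])])
    )
    result = shrake_rupley(model, n_points=120)
    scored = {name for (_, name) in result.per_atom_area}
    assert "H" not in scored
    assert ("A", 99, "") not in result.per_residue_area


def test_relative_sasa_unknown_type_flagged():
    result = shrake_rupley(_single_atom_model("C", comp="XYZ"), n_points=120)
    assert result.per_residue_relative[("A", 1, "")] is None
    assert classify_burial(result.per_residue_relative[("A", 1, "")]) == "unscored"


def test_relative_sasa_scaling():
    table = {"ALA": 129.0}
    from mutmap3d.sasa import SasaResult

    res = SasaResult(per_residue_area={("A", 1, ""): 129.0, ("A", 2, ""): 0.0})
    rel = relative_sasa(res, table, {("A", 1, ""): "ALA", ("A", 2, ""): "ALA"})
    assert rel[("A", 1, "")] == pytest.approx(100.0)
    assert rel[("A", 2, "")] == 0.0


@pytest.mark.parametrize(
    "value,expected",
    [
        (10.0, "core"),
        (24.999, "core"),
        (25.0, "noninterface"),
        (50.0, "noninterface"),
        (80.0, "noninterface"),
        (80.001, "exposed"),
        (90.0, "exposed"),
    ],
)
def test_burial_boundaries(value, expected):
    assert classify_burial(value) == expected


def test_negative_relative_rejected():
    with pytest.raises(ValueError):
        classify_burial(-1.0)


def test_sphere_points_unit_norm_and_spread():
    pts = sphere_points(480)
    assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
    assert np.linalg.norm(pts.mean(axis=0)) < 0.01  # nearly centro-symmetric
    with pytest.raises(ValueError):
        sphere_points(16)


def _biopython_per_residue(pdb_path, n_points):
    """Independent per-residue SASA via Bio.PDB's Shrake-Rupley, fed the
    same element radii."""
    from Bio.PDB import PDBParser
    from Bio.PDB.SASA import ShrakeRupley

    radii = {k.capitalize(): v for k, v in RADII["element"].items()}
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("x", str(pdb_path))
    sr = ShrakeRupley(probe_radius=PROBE, n_points=n_points, radii_dict=radii)
    sr.compute(structure[0], level="R")
    out = {}
    for chain in structure[0]:
        for res in chain:
            het, num, icode = res.id
            out[(chain.id, num, icode.strip())] = float(res.sasa)
    return out


def test_cross_validation_against_biopython(tmp_path):
    """Per-residue absolute areas agree with an independent established
    implementation within 5% at n_points >= 960."""
    model, _ = make_complex(
        FixtureSpec(seed=31, n_residues=18, zinc_near=5, zinc_distance=3.0,
                    ligand_near=12, ligand_distance=4.0)
    )
    path = tmp_path / "xval.pdb"
    write_pdb(model, path)
    theirs = _biopython_per_residue(path, n_points=960)
    from mutmap3d.io_structures import parse_structure

    ours = shrake_rupley(parse_structure(path), n_points=960)
    assert set(ours.per_residue_area) == set(theirs)
    for key, area in ours.per_residue_area.items():
        ref = theirs[key]
        assert area == pytest.approx(ref, rel=0.05, abs=1.0), key


def test_glycine_extended_tripeptide_vs_independent(tmp_path):
    """Centre glycine of an extended Gly-X-Gly-like stretch: our relative
    accessibility matches the independent implementation's within 25%."""
    chain = Chain("A")
    for i, letter_comp in enumerate([("GLY", 0), ("GLY", 0), ("GLY", 0)]):
        x = 3.8 * i
        res = ResidueRecord("A", i + 1, "", "GLY", ResidueCategory.PROTEIN,
                            [Atom("N", "N", [x - 1.2, 0.3, 0.0]),
                             Atom("CA", "C", [x, 0.0, 0.0]),
                             Atom("C", "C", [x + 1.2, 0.4, 0.0]),
                             Atom("O", "O", [x + 1.3, 1.6, 0.2])])
        chain.residues.append(res)
    model = StructureModel("gxg", StructureSource.EXPERIMENTAL, [chain])
    path = tmp_path / "gxg.pdb"
    write_pdb(model, path)
    ours = shrake_rupley(model, n_points=960)
    theirs = _biopython_per_residue(path, n_points=960)
    gmax = load_max_area_table()["GLY"]
    ours_rel = 100.0 * ours.per_residue_area[("A", 2, "")] / gmax
    theirs_rel = 100.0 * theirs[("A", 2, "")] / gmax
    assert ours_rel == pytest.approx(theirs_rel, rel=0.25)
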