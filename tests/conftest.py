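import numpy as np
import pytest

from mutmap3d.fixtures import FixtureSpec, case_study_scenario, make_complex, make_helix


@pytest.fixture(scope="session")
def scenario(tmp_path_factory):
    """The full ground-truthed end-to-end scenario (session-scoped: the
    generator is deterministic, so sharing it is safe)."""
    out = tmp_path_factory.mktemp("scenario")
    return case_study_scenario(seed=7, out_dir=out)


@pytest.fixture()
def poly_ala():
    return make_helix("A" * 10)


@pytest.fixture()
def small_complex():
    """Single-chain helix with a zinc, a ligand and a DNA duplex planted."""
    spec = FixtureSpec(
        seed=11,
        n_residues=24,
        zinc_near=4,
        zinc_distance=3.0,
        ligand_near=12,
        ligand_distance=4.0,
        dna_near=20,
        dna_distance=4.0,
    )
    return make_complex(spec)


def brute_force_pairs(src_xyz, src_owner, tgt_xyz, tgt_owner, cutoff):
    """O(N^2) residue-pair oracle used by neighbour-search tests."""
    from scipy.spatial.distance import cdist

    pairs = {}
    if len(src_xyz) == 0 or len(tgt_xyz) == 0:
        return pairs
    d = cdist(np.asarray(src_xyz), np.asarray(tgt_xyz))
    for i in range(d.shape[0]):
        for j in range(d.shape[1]):
            if d[i, j] <= cutoff:
                key = (src_owner[i], tgt_owner[j])
                if key[0] == key[1]:
                    continue
                if key not in pairs or d[i, j] < pairs[key]:
                    pairs[key] = d[i, j]
    return pairs
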