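"""Alignment engine and structure-to-reference residue mapping."""

import itertools

import numpy as np
import pytest
from Bio.Align import PairwiseAligner, substitution_matrices

from mutmap3d.fixtures import FixtureSpec, make_complex, make_helix
from mutmap3d.renumbering import (
    GAP_EXTEND,
    GAP_OPEN,
    ChainMappingError,
    build_residue_map,
    global_align,
    renumber_structure,
)

_B62 = substitution_matrices.load("BLOSUM62")


def oracle_score(query: str, reference: str) -> float:
    """Exhaustive-enumeration alignment oracle for tiny sequences.

    Enumerates every monotone alignment path with affine gap scoring
    (first gap residue GAP_OPEN, each further GAP_EXTEND) and free end
    gaps on the query side, implemented as a free choice of the reference
    window the query aligns into.
    """
    m, n = len(query), len(reference)
    best = -np.inf

    def rec(i, j, j_end, last, score):
        nonlocal best
        if i == m and j == j_end:
            best = max(best, score)
            return
        if i < m and j < j_end:
            rec(i + 1, j + 1, j_end, "M", score + _B62[query[i], reference[j]])
        if j < j_end:  # gap in query (internal: costs)
            cost = GAP_EXTEND if last == "X" else GAP_OPEN
            rec(i, j + 1, j_end, "X", score + cost)
        if i < m:  # gap in reference
            cost = GAP_EXTEND if last == "Y" else GAP_OPEN
            rec(i + 1, j, j_end, "Y", score + cost)

    for j_start in range(n + 1):
        for j_end in range(j_start, n + 1):
            rec(0, j_start, j_end, None, 0.0)
    return float(best)


def test_identity_alignment():
    res = global_align("ACDE", "ACDE")
    assert res.aligned_query == "ACDE"
    assert res.aligned_reference == "ACDE"
    assert res.identity_fraction == 1.0


def test_free_end_gaps_place_fragment():
    res = global_align("CDE", "ACDEF")
    assert res.aligned_query == "-CDE-"
    assert res.aligned_reference == "ACDEF"
    # fragment placed at reference positions 2..4; free end gaps cost nothing
    assert res.score == _B62["C", "C"] + _B62["D", "D"] + _B62["E", "E"]


def test_single_substitution_identity_fraction():
    rng = np.random.default_rng(5)
    letters = list("ACDEFGHIKLMNPQRSTVWY")
    seq = "".join(rng.choice(letters, size=30))
    mutated = list(seq)
    mutated[13] = "W" if seq[13] != "W" else "Y"
    res = global_align("".join(mutated), seq)
    assert res.identity_fraction == pytest.approx(29 / 30)


def test_alignment_recovers_inputs_property():
    rng = np.random.default_rng(17)
    letters = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(25):
        q = "".join(rng.choice(letters, size=rng.integers(1, 40)))
        r = "".join(rng.choice(letters, size=rng.integers(1, 40)))
        res = global_align(q, r)
        assert res.aligned_query.replace("-", "") == q
        assert res.aligned_reference.replace("-", "") == r
        assert len(res.aligned_query) == len(res.aligned_reference)


@pytest.mark.parametrize("seed", range(12))
def test_score_matches_exhaustive_oracle(seed):
    """DP score equals brute-force enumeration over all alignments for
    short sequences on a 4-letter alphabet."""
    rng = np.random.default_rng(seed)
    letters = list("ACGT")
    q = "".join(rng.choice(letters, size=rng.integers(1, 7)))
    r = "".join(rng.choice(letters, size=rng.integers(1, 9)))
    assert global_align(q, r).score == pytest.approx(oracle_score(q, r))


def test_all_pairs_length_le_3_match_oracle():
    letters = "ACGT"
    seqs = [
        "".join(p)
        for k in (1, 2, 3)
        for p in itertools.product(letters, repeat=k)
    ]
    rng = np.random.default_rng(0)
    idx = rng.choice(len(seqs), size=40)
    for i, j in zip(idx[::2], idx[1::2]):
        q, r = seqs[i], seqs[j]
        assert global_align(q, r).score == pytest.approx(oracle_score(q, r)), (q, r)


def test_score_cross_check_biopython():
    """Independent check of the optimum against Bio.Align.PairwiseAligner
    configured with the same scoring model."""
    aligner = PairwiseAligner()
    aligner.substitution_matrix = _B62
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    # free end gaps on the fragment: align reference as target, fragment
    # as query, with free end gaps on the query sequence
    aligner.open_left_deletion_score = 0.0
    aligner.extend_left_deletion_score = 0.0
    aligner.open_right_deletion_score = 0.0
    aligner.extend_right_deletion_score = 0.0
    rng = np.random.default_rng(23)
    letters = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(10):
        ref = "".join(rng.choice(letters, size=60))
        start, end = sorted(rng.integers(0, 60, size=2))
        if end - start < 5:
            end = min(60, start + 5)
        frag = ref[start:end]
        ours = global_align(frag, ref).score
        theirs = aligner.score(ref, frag)
        assert ours == pytest.approx(theirs)


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        global_align("", "ACDE")


def test_residue_map_offset_chain():
    rng = np.random.default_rng(3)
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=10))
    model = make_helix(seq, offset=101)
    rm = build_residue_map(model, "A", seq)
    assert rm.entries == {(101 + i, ""): i + 1 for i in range(10)}
    assert rm.identity_fraction == 1.0
    assert rm.n_mismatches == 0


def test_residue_map_with_deletion():
    """Residues 5..9 deleted: every observed residue still maps; reference
    positions 5..9 are absent from the image."""
    spec = FixtureSpec(seed=9, n_residues=20, deleted_segments=[(5, 9)])
    model, _ = make_complex(spec)
    seq = None
    from mutmap3d.fixtures import random_sequence

    seq = random_sequence(np.random.default_rng(9), 20)
    rm = build_residue_map(model, "A", seq)
    observed = [r.auth_seq_num for r in model.get_chain("A").residues]
    assert set(rm.entries) == {(n, "") for n in observed}
    image = rm.uniprot_positions()
    assert image.isdisjoint(set(range(5, 10)))
    assert len(image) == 15


def test_insertion_code_residue_gets_no_entry():
    """A residue inserted relative to the reference aligns to a query-gap
    column and receives no map entry."""
    seq = "ACDEFGHIKL"
    model = make_helix(seq + "W", offset=50)  # 11 observed vs 10 reference
    # turn the extra W into an insertion-coded residue between 54 and 55
    extra = model.chains[0].residues[-1]
    extra.auth_seq_num, extra.insertion_code = 54, "A"
    model.chains[0].residues.sort(key=lambda r: (r.auth_seq_num, r.insertion_code))
    rm = build_residue_map(model, "A", seq)
    assert (54, "A") not in rm.entries
    assert len(rm.entries) == 10
    assert sorted(rm.uniprot_positions()) == list(range(1, 11))


def test_mismatches_mapped_and_counted():
    seq = "ACDEFGHIKL"
    model = make_helix(seq)
    model.chains[0].residues[4].comp_id = "TRP"  # engineered F5W
    rm = build_residue_map(model, "A", seq)
    assert rm.n_mismatches == 1
    assert rm.entries[(5, "")] == 5  # mapped, not dropped


def test_low_identity_raises():
    model = make_helix("AAAAAAAAAA")
    with pytest.raises(ChainMappingError):
        build_residue_map(model, "A", "WWWWWWWWWW")


def test_renumber_structure_round_trip():
    rng = np.random.default_rng(41)
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=15))
    model = make_helix(seq, offset=201)
    rm = build_residue_map(model, "A", seq)
    out = renumber_structure(model, [rm])
    assert [r.auth_seq_num for r in out.get_chain("A").residues] == list(range(1, 16))
    # identity-numbered chain: renumbering is a no-op
    ident = make_helix(seq, offset=1)
    rm2 = build_residue_map(ident, "A", seq)
    out2 = renumber_structure(ident, [rm2])
    assert [r.auth_seq_num for r in out2.get_chain("A").residues] == [
        r.auth_seq_num for r in ident.get_chain("A").residues
    ]
    # original untouched
    assert model.get_chain("A").residues[0].auth_seq_num == 201


def test_renumber_homodimer_independent_offsets(scenario):
    from mutmap3d.io_structures import parse_structure

    model = parse_structure(scenario["structure_pdb"])
    ref = scenario["reference"]
    maps = [build_residue_map(model, c.chain_id, ref) for c in model.protein_chains()]
    out = renumber_structure(model, maps)
    w0, w1 = scenario["window"]
    for chain_id in ("A", "B"):
        nums = [r.auth_seq_num for r in out.get_chain(chain_id).residues]
        assert nums == list(range(w0, w1 + 1))


def test_injectivity_enforced():
    from mutmap3d.renumbering import ResidueMap

    with pytest.raises(ValueError):
        ResidueMap("s", "A", entries={(1, ""): 5, (2, ""): 5})
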