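"""Align structure chains to the UniProt reference and renumber residues.

Structure files number residues by author convention (arbitrary offsets,
insertion codes, engineered constructs); mutation catalogues number by the
UniProt canonical sequence.  This module bridges the two: each protein
chain's observed sequence is aligned to the reference with a semi-global
affine-gap alignment (end gaps on the structure-observed side are free,
since crystallized constructs are almost always fragments of the full
protein), and every aligned residue receives the 1-based UniProt position
of its reference column.

Scoring is BLOSUM62 with gap open -10 and gap extend -0.5 (the opening
residue of a gap costs -10, each further residue -0.5).  Traceback ties are
broken deterministically: diagonal (match/mismatch) is preferred over a
gap in the query, which is preferred over a gap in the reference.
Adjacent opposite-direction gaps are disallowed; with this matrix a
mismatch always outscores an open-close gap pair, so no optimum is lost.

Mismatched aligned pairs are *mapped* but counted in ``n_mismatches`` —
crystal constructs commonly carry engineered substitutions at exactly the
positions mutation studies target, so dropping them would be destructive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

from .io_structures import observed_sequence
from .model import ResidueCategory, StructureModel

__all__ = [
    "AlignmentResult",
    "ResidueMap",
    "ChainMappingError",
    "global_align",
    "build_residue_map",
    "renumber_structure",
    "read_reference_fasta",
]

GAP_OPEN = -10.0
GAP_EXTEND = -0.5
IDENTITY_FLOOR = 0.30

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_ALPHABET = _BLOSUM62.alphabet


def _encode(seq: str) -> np.ndarray:
    idx = np.array([_ALPHABET.find(c) for c in seq], dtype=int)
    if np.any(idx < 0):
        bad = sorted({c for c in seq if c not in _ALPHABET})
        raise ValueError(f"sequence contains letters outside the substitution alphabet: {bad}")
    return idx


class ChainMappingError(ValueError):
    """Raised when a chain cannot be reconciled with the reference."""


@dataclass
class AlignmentResult:
    """A pairwise alignment with gap characters ('-')."""

    aligned_query: str
    aligned_reference: str
    score: float
    identity_fraction: float

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_reference):
            raise ValueError("aligned strings must have equal length")


@dataclass
class ResidueMap:
    """Mapping from structure residue identifiers to UniProt positions.

    ``entries`` maps ``(auth_seq_num, insertion_code)`` to the 1-based
    position in the reference sequence.  The map is injective per chain.
    """

    structure_id: str
    chain_id: str
    entries: dict[tuple[int, str], int] = field(default_factory=dict)
    identity_fraction: float = 0.0
    n_mismatches: int = 0

    def __post_init__(self) -> None:
        positions = list(self.entries.values())
        if len(positions) != len(set(positions)):
            raise ValueError(f"residue map for chain {self.chain_id} is not injective")

    def uniprot_positions(self) -> set[int]:
        return set(self.entries.values())


def global_align(
    query: str,
    reference: str,
    matrix=_BLOSUM62,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
) -> AlignmentResult:
    """Optimal semi-global alignment of ``query`` against ``reference``.

    End gaps on the query side (reference overhangs before/after the
    aligned query) are free; internal gaps and query overhangs pay the
    affine penalty.  Deterministic traceback: diagonal > query-gap >
    reference-gap.
    """
    if not query or not reference:
        raise ValueError("sequences must be non-empty")
    q = _encode(query.upper())
    r = _encode(reference.upper())
    m, n = len(q), len(r)
    sub = np.asarray(matrix)[np.ix_(q, r)]  # (m, n) substitution scores

    NEG = -1e18
    # M: ends in aligned pair; X: ends in query-gap (ref consumed);
    # Y: ends in reference-gap (query consumed).
    M = np.full((m + 1, n + 1), NEG)
    X = np.full((m + 1, n + 1), NEG)
    Y = np.full((m + 1, n + 1), NEG)
    M[0, 0] = 0.0
    X[0, 1:] = 0.0  # free leading query-gap
    Y[1:, 0] = gap_open + gap_extend * np.arange(m)

    for i in range(1, m + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = prev_best[:-1] + sub[i - 1]
        Y[i] = np.maximum(M[i - 1] + gap_open, Y[i - 1] + gap_extend)
        Y[i, 0] = gap_open + gap_extend * (i - 1)
        # X[i, j] = max over k < j of M[i, k] + open + extend*(j-1-k)
        base = M[i] + gap_open - gap_extend * np.arange(n + 1)
        run = np.maximum.accumulate(base)
        X[i, 1:] = run[:-1] + gap_extend * np.arange(n)

    # trailing query-gaps are free: end at (m, j) in state M or Y, best j
    end_scores = np.maximum(M[m], Y[m])
    j_end = int(np.argmax(end_scores))  # smallest j on ties (deterministic)
    score = float(end_scores[j_end])

    # traceback from (m, j_end) to (0, 0); columns collected in reverse
    qs, rs = query.upper(), reference.upper()
    aq: list[str] = []
    ar: list[str] = []
    i, j = m, j_end
    state = "M" if M[m, j_end] >= Y[m, j_end] else "Y"
    while i > 0 or j > 0:
        if i == 0:
            # leading reference overhang: free query-gaps
            while j > 0:
                aq.append("-")
                ar.append(rs[j - 1])
                j -= 1
            break
        if j == 0:
            state = "Y"
        if state == "M":
            aq.append(qs[i - 1])
            ar.append(rs[j - 1])
            prev = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            i, j = i - 1, j - 1
            if i == 0 or j == 0:
                continue
            state = "MXY"[int(np.argmax(prev))]  # tie-break: M > X > Y
        elif state == "X":
            aq.append("-")
            ar.append(rs[j - 1])
            cont = X[i, j - 1] + gap_extend
            opened = M[i, j - 1] + gap_open
            j -= 1
            if j == 0:
                continue
            if opened >= cont:
                state = "M"
        else:  # Y
            aq.append(qs[i - 1])
            ar.append("-")
            cont = Y[i - 1, j] + gap_extend
            opened = M[i - 1, j] + gap_open
            i -= 1
            if i == 0:
                continue
            if opened >= cont:
                state = "M"
    aq_s = "".join(reversed(aq)) + "-" * (n - j_end)
    ar_s = "".join(reversed(ar)) + rs[j_end:]

    pairs = [
        (a, b) for a, b in zip(aq_s, ar_s) if a != "-" and b != "-"
    ]
    matches = sum(1 for a, b in pairs if a == b)
    identity = matches / len(pairs) if pairs else 0.0
    result = AlignmentResult(aq_s, ar_s, score, identity)
    assert result.aligned_query.replace("-", "") == qs
    assert result.aligned_reference.replace("-", "") == rs
    return result


def build_residue_map(
    model: StructureModel,
    chain_id: str,
    reference: str,
    identity_floor: float = IDENTITY_FLOOR,
) -> ResidueMap:
    """Map a protein chain's residues onto 1-based reference positions.

    Every observed residue aligned to a non-gap reference column is mapped;
    non-identical aligned pairs are counted in ``n_mismatches``.  An
    identity fraction below ``identity_floor`` raises
    :class:`ChainMappingError` (the chain likely belongs to a different
    protein).
    """
    if not reference:
        raise ValueError("reference sequence must be non-empty")
    chain = model.get_chain(chain_id)
    if chain.polymer_type is not ResidueCategory.PROTEIN:
        raise ValueError(f"chain {chain_id!r} is not a protein chain")
    seq, numbering = observed_sequence(model, chain_id)
    aln = global_align(seq, reference.upper())
    if aln.identity_fraction < identity_floor:
        raise ChainMappingError(
            f"chain {chain_id} does not match reference: identity "
            f"{aln.identity_fraction:.2f} < floor {identity_floor:.2f}"
        )
    entries: dict[tuple[int, str], int] = {}
    mismatches = 0
    qi = 0  # index into observed sequence
    rj = 0  # 0-based reference position
    for a, b in zip(aln.aligned_query, aln.aligned_reference):
        if a != "-" and b != "-":
            entries[numbering[qi]] = rj + 1
            if a != b:
                mismatches += 1
        if a != "-":
            qi += 1
        if b != "-":
            rj += 1
    return ResidueMap(
        structure_id=model.structure_id,
        chain_id=chain_id,
        entries=entries,
        identity_fraction=aln.identity_fraction,
        n_mismatches=mismatches,
    )


def renumber_structure(model: StructureModel, maps: list[ResidueMap]) -> StructureModel:
    """Return a copy whose mapped residues carry UniProt numbering.

    Mapped residues get ``auth_seq_num = uniprot_pos`` and an empty
    insertion code; unmapped residues and non-protein chains are unchanged.
    """
    by_chain = {rm.chain_id: rm for rm in maps}
    if not any(ch.chain_id in by_chain for ch in model.protein_chains()):
        raise ValueError("maps cover no protein chain of the model")
    out = model.copy()
    for chain in out.chains:
        rm = by_chain.get(chain.chain_id)
        if rm is None:
            continue
        for res in chain.residues:
            pos = rm.entries.get((res.auth_seq_num, res.insertion_code))
            if pos is not None:
                res.auth_seq_num = pos
                res.insertion_code = ""
    return out


def read_reference_fasta(path: str | Path, accession: Optional[str] = None) -> tuple[str, str]:
    """Read the reference amino-acid sequence from a FASTA file.

    Returns ``(record_id, sequence)``.  The first record is used unless
    ``accession`` selects one explicitly; multi-record files without an
    accession raise an error to prevent silent mis-selection.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    if accession is None:
        if len(records) > 1:
            raise ValueError(
                f"{path}: {len(records)} records; pass an accession to select one"
            )
        rec = records[0]
    else:
        matches = [r for r in records if accession in r.id or accession in r.description]
        if not matches:
            raise ValueError(f"{path}: accession {accession!r} not found")
        rec = matches[0]
    return rec.id, str(rec.seq).upper()
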