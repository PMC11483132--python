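"""Parse COSMIC-style mutation tables and aggregate unique substitutions.

The reader accepts delimited text (TSV/CSV autodetected) shaped like a
COSMIC targeted-screen export: one row per sample observation with a gene
symbol, a protein-change string, and optionally a sample identifier.
Protein changes are accepted in bare ("R248Q"), one-letter HGVS
("p.R248Q") and three-letter HGVS ("p.Arg248Gln") notation; nonsense
variants ("R306*", "p.Arg306Ter") are kept with alt '*'.  Synonymous,
frameshift, in-frame indel and splice notations are rejected with a typed
reason so callers can tally skips instead of losing rows silently.

Frequency of a unique substitution is defined as its observation count
divided by the total number of accepted rows for the gene; frequencies
over the unique records therefore sum to 1.  When a sample column is
present, duplicate (sample, mutation) pairs are counted once - COSMIC
rows can repeat the same sample across studies.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .model import AA1

__all__ = [
    "MutationRecord",
    "ParseOutcome",
    "parse_protein_change",
    "format_protein_change",
    "read_mutation_table",
    "aggregate_mutations",
    "validate_against_reference",
    "DEFAULT_COLUMNS",
]

#: default column names (COSMIC targeted-screen export shape)
DEFAULT_COLUMNS = {"gene": "Gene name", "aa": "Mutation AA", "sample": "Sample name"}

THREE_LETTER = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*", "Sec": "U",
}
ONE_TO_THREE_HGVS = {v: k for k, v in THREE_LETTER.items()}

_RE_ONE = re.compile(r"^([A-Z])(\d+)([A-Z*])$")
_RE_THREE = re.compile(r"^([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2}|\*)$")


@dataclass(frozen=True)
class ParseOutcome:
    """Result of parsing one protein-change string.

    ``ok`` is True for an accepted substitution, in which case ``ref_aa``,
    ``position`` and ``alt_aa`` are set; otherwise ``reason`` explains the
    rejection (synonymous, frameshift, indel, splice, unparseable).
    """

    ok: bool
    ref_aa: Optional[str] = None
    position: Optional[int] = None
    alt_aa: Optional[str] = None
    reason: Optional[str] = None


def _reject(reason: str) -> ParseOutcome:
    return ParseOutcome(ok=False, reason=reason)


def parse_protein_change(notation: str) -> ParseOutcome:
    """Parse a protein-change string into (ref, position, alt).

    Accepts "R248Q", "p.R248Q", "p.Arg248Gln", nonsense "R306*" /
    "p.Arg306Ter".  Synonymous ("p.Thr125Thr", "p.T125="), frameshift,
    indel and splice notations are rejected with a typed reason.
    """
    if not notation or not notation.strip():
        return _reject("unparseable")
    s = notation.strip()
    if s.lower().startswith("p."):
        s = s[2:]
    low = s.lower()
    if low in ("?", "(?)"):
        return _reject("splice")
    if "fs" in low:
        return _reject("frameshift")
    if any(tok in low for tok in ("delins", "del", "ins", "dup", "ext")):
        return _reject("indel")
    if s.endswith("="):
        return _reject("synonymous")

    m = _RE_ONE.match(s)
    if m:
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
    else:
        m = _RE_THREE.match(s)
        if not m:
            return _reject("unparseable")
        ref3, pos, alt3 = m.group(1), int(m.group(2)), m.group(3)
        if ref3 not in THREE_LETTER:
            return _reject("unparseable")
        ref = THREE_LETTER[ref3]
        if alt3 == "*":
            alt = "*"
        elif alt3 in THREE_LETTER:
            alt = THREE_LETTER[alt3]
        else:
            return _reject("unparseable")
    if ref not in AA1 or (alt not in AA1 and alt != "*"):
        return _reject("unparseable")
    if pos < 1:
        return _reject("unparseable")
    if ref == alt:
        return _reject("synonymous")
    return ParseOutcome(ok=True, ref_aa=ref, position=pos, alt_aa=alt)


def format_protein_change(ref_aa: str, position: int, alt_aa: str, style: str = "bare") -> str:
    """Format a substitution; inverse of :func:`parse_protein_change`."""
    if style == "bare":
        return f"{ref_aa}{position}{alt_aa}"
    if style == "hgvs1":
        return f"p.{ref_aa}{position}{alt_aa}"
    if style == "hgvs3":
        alt3 = "Ter" if alt_aa == "*" else ONE_TO_THREE_HGVS[alt_aa]
        return f"p.{ONE_TO_THREE_HGVS[ref_aa]}{position}{alt3}"
    raise ValueError(f"unknown style {style!r}")


@dataclass
class MutationRecord:
    """One unique amino-acid substitution with its observation count.

    ``frequency`` is count / total accepted rows for the gene, so the
    frequencies of all unique records sum to 1.
    """

    gene: str
    position: int
    ref_aa: str
    alt_aa: str
    count: int = 1
    frequency: float = 0.0
    raw_notation: str = ""
    consistent: Optional[bool] = None  # set by validate_against_reference
    validation_flag: str = ""

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.ref_aa, self.alt_aa)

    def notation(self) -> str:
        return format_protein_change(self.ref_aa, self.position, self.alt_aa)


def read_mutation_table(
    path: str | Path,
    columns: Optional[dict[str, str]] = None,
    sep: Optional[str] = None,
) -> pd.DataFrame:
    """Read a COSMIC-shaped delimited table (TSV/CSV autodetect).

    Returns a DataFrame with normalized columns ``gene``, ``aa`` and, when
    present in the input, ``sample``.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c", dtype=str)
    missing = [cols[k] for k in ("gene", "aa") if cols[k] not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}; found {list(df.columns)}")
    renames = {cols["gene"]: "gene", cols["aa"]: "aa"}
    if cols.get("sample") and cols["sample"] in df.columns:
        renames[cols["sample"]] = "sample"
    return df.rename(columns=renames)[list(renames.values())]


def aggregate_mutations(
    rows: pd.DataFrame | Sequence[dict],
    gene: Optional[str] = None,
) -> tuple[list[MutationRecord], list[dict]]:
    """Deduplicate parsed rows into unique substitutions with frequencies.

    Returns ``(records, skipped)``: records ordered by descending count,
    then position, then alt residue; skipped rows carry their rejection
    reason.  Raises if no row is accepted.
    """
    if isinstance(rows, pd.DataFrame):
        rows = rows.to_dict(orient="records")
    accepted: list[tuple[tuple[int, str, str], Optional[str], str, str]] = []
    skipped: list[dict] = []
    for row in rows:
        g = str(row.get("gene", "")).strip()
        if gene is not None and g and g != gene:
            skipped.append({**row, "reason": "other_gene"})
            continue
        notation = str(row.get("aa", "")).strip()
        outcome = parse_protein_change(notation)
        if not outcome.ok:
            skipped.append({**row, "reason": outcome.reason})
            continue
        sample = row.get("sample")
        sample = None if sample is None or pd.isna(sample) else str(sample)
        accepted.append(
            ((outcome.position, outcome.ref_aa, outcome.alt_aa), sample, notation, g)
        )
    if not accepted:
        raise ValueError("no rows with a parseable substitution were accepted")

    # count once per (sample, mutation) when samples are known
    counted: dict[tuple[int, str, str], int] = {}
    raw: dict[tuple[int, str, str], str] = {}
    genes: dict[tuple[int, str, str], str] = {}
    seen_pairs: set[tuple[Optional[str], tuple[int, str, str]]] = set()
    total = 0
    for key, sample, notation, g in accepted:
        if sample is not None:
            pair = (sample, key)
            if pair in seen_pairs:
                continue
            seen_pairs.add(pair)
        counted[key] = counted.get(key, 0) + 1
        raw.setdefault(key, notation)
        genes.setdefault(key, g)
        total += 1

    records = [
        MutationRecord(
            gene=genes[key],
            position=key[0],
            ref_aa=key[1],
            alt_aa=key[2],
            count=cnt,
            frequency=cnt / total,
            raw_notation=raw[key],
        )
        for key, cnt in counted.items()
    ]
    records.sort(key=lambda r: (-r.count, r.position, r.alt_aa))
    return records, skipped


def validate_against_reference(
    records: Sequence[MutationRecord], reference: str
) -> tuple[list[MutationRecord], list[MutationRecord]]:
    """Partition records into reference-consistent and mismatched.

    A record is consistent iff ``reference[position-1] == ref_aa``.
    Mismatched and out-of-range records are flagged and retained, never
    dropped.
    """
    if not reference:
        raise ValueError("reference sequence must be non-empty")
    consistent: list[MutationRecord] = []
    mismatched: list[MutationRecord] = []
    for rec in records:
        if rec.position > len(reference):
            rec.consistent = False
            rec.validation_flag = "out_of_range"
            mismatched.append(rec)
        elif reference[rec.position - 1] == rec.ref_aa:
            rec.consistent = True
            rec.validation_flag = ""
            consistent.append(rec)
        else:
            rec.consistent = False
            rec.validation_flag = "ref_mismatch"
            mismatched.append(rec)
    return consistent, mismatched
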