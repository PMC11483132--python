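"""Orchestrate the full mutation-mapping run.

Stages: parse every structure, align each protein chain to the reference
and renumber, compute SASA and burial, annotate distance-based contexts,
aggregate the mutation table, and map every unique mutation onto every
covering structure chain.  Positions not covered by any experimental
structure fall back to the predicted model when one is supplied.

The run is deterministic: identical inputs produce byte-identical output
tables.  Per-stage counts (parsed, renumbered, scored, mapped, skipped)
are logged and returned so silent data loss is impossible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import coverage_disorder as cd
from .context_annotation import (
    INTERFACE_CUTOFF,
    LIGAND_CUTOFF,
    ContextFlags,
    annotate_contexts,
)
from .io_structures import parse_structure, write_annotation_table
from .model import ResidueCategory, StructureModel, StructureSource
from .mutation_data import (
    MutationRecord,
    aggregate_mutations,
    read_mutation_table,
    validate_against_reference,
)
from .renumbering import (
    IDENTITY_FLOOR,
    ChainMappingError,
    ResidueMap,
    build_residue_map,
    read_reference_fasta,
)
from .sasa import DEFAULT_N_POINTS, SasaResult, classify_burial, shrake_rupley

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "AnnotatedMutation", "PipelineResult", "map_mutation", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    reference_fasta: str
    mutation_table: str
    structures: list[dict] = field(default_factory=list)  # {path, format?, id?}
    predicted_model: Optional[str] = None
    gene: Optional[str] = None
    accession: Optional[str] = None
    column_mapping: dict = field(default_factory=dict)
    ligand_cutoff: float = LIGAND_CUTOFF
    interface_cutoff: float = INTERFACE_CUTOFF
    sasa_n_points: int = DEFAULT_N_POINTS
    disorder_threshold: float = cd.DISORDER_PLDDT_THRESHOLD
    identity_floor: float = IDENTITY_FLOOR
    output_dir: str = "mutmap3d_out"

    def __post_init__(self) -> None:
        if self.ligand_cutoff <= 0 or self.interface_cutoff <= 0:
            raise ValueError("cutoffs must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def validate_paths(self) -> None:
        missing = [
            p
            for p in [self.reference_fasta, self.mutation_table, self.predicted_model]
            + [s["path"] for s in self.structures]
            if p is not None and not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")


@dataclass
class AnnotatedMutation:
    """One unique mutation joined to one structure chain."""

    mutation: MutationRecord
    structure_id: str
    chain_id: str
    mapped_via: str  # "experimental" | "predicted"
    observed_aa: str
    ref_mismatch: bool
    relative_sasa: Optional[float]
    burial: str
    contexts: ContextFlags
    in_disorder: bool

    def to_row(self) -> dict:
        cf = self.contexts
        return {
            "gene": self.mutation.gene,
            "position": self.mutation.position,
            "ref_aa": self.mutation.ref_aa,
            "alt_aa": self.mutation.alt_aa,
            "count": self.mutation.count,
            "frequency": round(self.mutation.frequency, 9),
            "structure_id": self.structure_id,
            "chain_id": self.chain_id,
            "mapped_via": self.mapped_via,
            "observed_aa": self.observed_aa,
            "ref_mismatch": self.ref_mismatch,
            "relative_sasa": None if self.relative_sasa is None else round(self.relative_sasa, 3),
            "burial": self.burial,
            "ligand_site": cf.ligand_site,
            "ligand_ids": ";".join(cf.ligand_ids),
            "dimer_interface": cf.dimer_interface,
            "partner_chains": ";".join(cf.partner_chains),
            "dna_interface": cf.dna_interface,
            "zinc_site": cf.zinc_site,
            "in_disorder": self.in_disorder,
        }


@dataclass
class _AnnotatedStructure:
    model: StructureModel
    maps: dict[str, ResidueMap]              # chain_id -> map
    sasa: SasaResult
    contexts: dict                           # residue key -> ContextFlags
    position_index: dict                     # (chain_id, uniprot_pos) -> ResidueRecord


@dataclass
class PipelineResult:
    config: RunConfig
    reference_id: str
    reference: str
    records: list[MutationRecord]
    skipped: list[dict]
    coverage: cd.CoverageProfile
    disorder: Optional[cd.DisorderProfile]
    annotations: list[AnnotatedMutation]
    summary: dict
    stage_counts: dict


def map_mutation(
    record: MutationRecord,
    annotated: _AnnotatedStructure,
    mapped_via: str,
    disorder: Optional[cd.DisorderProfile],
) -> list[AnnotatedMutation]:
    """Map one unique mutation onto every chain of one annotated structure
    that covers its position; empty list when not covered."""
    rows: list[AnnotatedMutation] = []
    for chain_id in sorted(annotated.maps):
        res = annotated.position_index.get((chain_id, record.position))
        if res is None:
            continue
        observed = res.one_letter()
        rel = annotated.sasa.per_residue_relative.get(res.key)
        cf = annotated.contexts.get(res.key, ContextFlags())
        rows.append(
            AnnotatedMutation(
                mutation=record,
                structure_id=annotated.model.structure_id,
                chain_id=chain_id,
                mapped_via=mapped_via,
                observed_aa=observed,
                ref_mismatch=observed != record.ref_aa,
                relative_sasa=rel,
                burial=classify_burial(rel),
                contexts=cf,
                in_disorder=(
                    disorder is not None and record.position in disorder.disordered_positions
                ),
            )
        )
    return rows


def _annotate_structure(
    model: StructureModel, reference: str, config: RunConfig
) -> Optional[_AnnotatedStructure]:
    maps: dict[str, ResidueMap] = {}
    for chain in model.protein_chains():
        try:
            maps[chain.chain_id] = build_residue_map(
                model, chain.chain_id, reference, identity_floor=config.identity_floor
            )
        except ChainMappingError as exc:
            logger.warning("%s: %s", model.structure_id, exc)
    if not maps:
        logger.warning("%s: no chain matches the reference; skipped", model.structure_id)
        return None
    sasa = shrake_rupley(model, n_points=config.sasa_n_points)
    contexts = annotate_contexts(
        model, ligand_cutoff=config.ligand_cutoff, interface_cutoff=config.interface_cutoff
    )
    index = {}
    for chain_id, rm in maps.items():
        chain = model.get_chain(chain_id)
        by_auth = {
            (r.auth_seq_num, r.insertion_code): r
            for r in chain.residues
            if r.category is ResidueCategory.PROTEIN
        }
        for auth, pos in rm.entries.items():
            res = by_auth.get(auth)
            if res is not None:
                index[(chain_id, pos)] = res
    return _AnnotatedStructure(model, maps, sasa, contexts, index)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full run and write the report bundle to
    ``config.output_dir`` (per-structure TSVs, ``summary.json``,
    ``skipped.tsv``)."""
    config.validate_paths()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ref_id, reference = read_reference_fasta(config.reference_fasta, config.accession)

    # mutations
    table = read_mutation_table(config.mutation_table, columns=config.column_mapping or None)
    records, skipped = aggregate_mutations(table, gene=config.gene)
    validate_against_reference(records, reference)

    stage_counts = {
        "rows_read": int(len(table)),
        "rows_skipped": len(skipped),
        "unique_mutations": len(records),
        "structures_parsed": 0,
        "structures_mapped": 0,
    }

    # structures
    annotated_structures: list[_AnnotatedStructure] = []
    for entry in config.structures:
        model = parse_structure(
            entry["path"],
            format=entry.get("format", "auto"),
            structure_id=entry.get("id"),
            source=StructureSource.EXPERIMENTAL,
        )
        stage_counts["structures_parsed"] += 1
        ann = _annotate_structure(model, reference, config)
        if ann is not None:
            annotated_structures.append(ann)
            stage_counts["structures_mapped"] += 1

    predicted_ann: Optional[_AnnotatedStructure] = None
    disorder: Optional[cd.DisorderProfile] = None
    if config.predicted_model:
        pred = parse_structure(
            config.predicted_model, source=StructureSource.PREDICTED
        )
        predicted_ann = _annotate_structure(pred, reference, config)
        if predicted_ann is not None:
            first_map = next(iter(predicted_ann.maps.values()))
            disorder = cd.compute_disorder(
                pred, first_map, threshold=config.disorder_threshold, length=len(reference)
            )

    all_maps = [rm for ann in annotated_structures for rm in ann.maps.values()]
    coverage = cd.compute_coverage(all_maps, len(reference))

    # map every unique mutation onto every covering experimental structure;
    # fall back to the predicted model when uncovered everywhere
    annotations: list[AnnotatedMutation] = []
    n_covered = 0
    n_fallback = 0
    for record in records:
        rows: list[AnnotatedMutation] = []
        for ann in annotated_structures:
            rows.extend(map_mutation(record, ann, "experimental", disorder))
        if rows:
            n_covered += 1
        elif predicted_ann is not None:
            rows = map_mutation(record, predicted_ann, "predicted", disorder)
            if rows:
                n_fallback += 1
        annotations.extend(rows)

    # summary statistics, per-structure context counts at both granularities
    per_structure: dict[str, dict] = {}
    for ann_row in annotations:
        st = per_structure.setdefault(
            ann_row.structure_id,
            {
                "n_rows": 0,
                "unique_mutations": set(),
                "dna_interface": set(),
                "dimer_interface": set(),
                "ligand_site": set(),
                "zinc_site": set(),
                "per_chain_rows": {},
            },
        )
        st["n_rows"] += 1
        key = ann_row.mutation.key
        st["unique_mutations"].add(key)
        st["per_chain_rows"][ann_row.chain_id] = st["per_chain_rows"].get(ann_row.chain_id, 0) + 1
        for ctx in ("dna_interface", "dimer_interface", "ligand_site", "zinc_site"):
            if getattr(ann_row.contexts, ctx):
                st[ctx].add(key)

    summary = {
        "reference_id": ref_id,
        "reference_length": len(reference),
        "n_structures": len(annotated_structures),
        "covered_fraction": round(coverage.covered_fraction, 6),
        "uncovered_segments": coverage.uncovered_segments,
        "disorder_fraction": None if disorder is None else round(disorder.disorder_fraction, 6),
        "unique_mutation_count": len(records),
        "mutations_covered_experimental": n_covered,
        "mutations_via_predicted": n_fallback,
        "skipped_rows": len(skipped),
    }
    if disorder is not None:
        n_dis, pct = cd.mutations_in_disorder(records, disorder)
        summary["mutations_in_disorder"] = n_dis
        summary["mutations_in_disorder_pct"] = pct
    summary["per_structure"] = {
        sid: {
            "n_rows": st["n_rows"],
            "unique_mutations": len(st["unique_mutations"]),
            "dna_interface_mutations": len(st["dna_interface"]),
            "dimer_interface_mutations": len(st["dimer_interface"]),
            "ligand_site_mutations": len(st["ligand_site"]),
            "zinc_site_mutations": len(st["zinc_site"]),
            "rows_per_chain": dict(sorted(st["per_chain_rows"].items())),
        }
        for sid, st in sorted(per_structure.items())
    }

    # write report bundle
    by_structure_rows: dict[str, list[dict]] = {}
    for ann_row in annotations:
        by_structure_rows.setdefault(ann_row.structure_id, []).append(ann_row.to_row())
    for sid, rows in sorted(by_structure_rows.items()):
        rows.sort(key=lambda r: (r["position"], r["alt_aa"], r["chain_id"]))
        write_annotation_table(rows, out_dir / f"{sid}_mutations.tsv", format="tsv")
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    with open(out_dir / "skipped.tsv", "w") as fh:
        fh.write("gene\taa\tsample\treason\n")
        for row in skipped:
            fh.write(
                f"{row.get('gene', '')}\t{row.get('aa', '')}\t"
                f"{row.get('sample', '')}\t{row.get('reason', '')}\n"
            )

    stage_counts["mutations_covered"] = n_covered
    stage_counts["mutations_via_predicted"] = n_fallback
    stage_counts["annotation_rows"] = len(annotations)
    logger.info("pipeline complete: %s", stage_counts)

    return PipelineResult(
        config=config,
        reference_id=ref_id,
        reference=reference,
        records=records,
        skipped=skipped,
        coverage=coverage,
        disorder=disorder,
        annotations=annotations,
        summary=summary,
        stage_counts=stage_counts,
    )
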