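"""Serialization, file naming, and corpus/database round trips.

The released database is a CSV with a fixed, documented column order and
UTF-8-SIG encoding (byte-order mark first), matching the conventions of
downstream R/Python macroecology workflows.  Row order is deterministic
(input order after deduplication), so repeated runs on identical inputs
produce byte-identical files.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import IOFailure, UnknownUnit
from .pages import (
    extract_document,
    merge_table_continuations,
    reconstruct_sequence,
    write_page_file,
)
from .sandbox import (
    Provenance,
    RejectionLog,
    StandardizedRecord,
    deduplicate_records,
    process_document,
)
from .units import normalize_mass, parse_unit

#: released table column order; one row per standardized record
DATABASE_COLUMNS = (
    "phylum", "class", "order", "family", "genus", "species_binomial",
    "body_mass_kg", "brain_volume_ml", "vo2_std",
    "mr_mass_specific_w_per_kg", "mr_total_w", "temperature_c",
    "sex", "sample_size", "original_value", "original_unit",
    "reference", "year",
    "document_id", "page_index", "block_index", "row_index",
)

_TAXON_RANKS = ("phylum", "class", "order", "family", "genus")


def records_to_frame(records: Sequence[StandardizedRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {rank: rec.taxonomy.get(rank, "") for rank in _TAXON_RANKS}
        row.update(
            species_binomial=rec.species_binomial,
            body_mass_kg=rec.body_mass_kg,
            brain_volume_ml=rec.brain_volume_ml,
            vo2_std=rec.vo2_std,
            mr_mass_specific_w_per_kg=rec.mr_mass_specific_w_per_kg,
            mr_total_w=rec.mr_total_w,
            temperature_c=rec.temperature_c,
            sex=rec.sex,
            sample_size=rec.sample_size,
            original_value=rec.original_value,
            original_unit=rec.original_unit,
            reference=rec.reference.get("citation", ""),
            year=rec.reference.get("year"),
            document_id=rec.document_id,
            page_index=rec.provenance.page_index,
            block_index=rec.provenance.block_index,
            row_index=rec.provenance.row_index,
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=list(DATABASE_COLUMNS))


def export_csv(records: Sequence[StandardizedRecord], path: str | Path) -> Path:
    """Write the database CSV: UTF-8-SIG (BOM-prefixed), comma-delimited,
    minimal quoting, deterministic row order."""
    path = Path(path)
    try:
        frame = records_to_frame(records)
        # fixed float formatting keeps repeated runs byte-identical
        frame.to_csv(path, index=False, encoding="utf-8-sig",
                     float_format="%.12g", lineterminator="\n")
    except OSError as exc:
        raise IOFailure(str(exc)) from exc
    return path


def read_database_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8-sig")


def export_rejection_log(log: RejectionLog, path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "document_id": e.document_id,
            "page_index": e.provenance.page_index,
            "block_index": e.provenance.block_index,
            "row_index": e.provenance.row_index,
            "rule_id": e.rule_id,
            "detail": e.detail,
        }
        for e in log.entries
    ]
    pd.DataFrame(
        rows,
        columns=["document_id", "page_index", "block_index", "row_index",
                 "rule_id", "detail"],
    ).to_csv(path, index=False, encoding="utf-8-sig", lineterminator="\n")
    return path


def frame_to_records(frame: pd.DataFrame) -> list[StandardizedRecord]:
    """Rebuild standardized records from a database CSV frame."""

    def _opt(v):
        return None if pd.isna(v) else float(v)

    records = []
    for row in frame.to_dict("records"):
        records.append(
            StandardizedRecord(
                species_binomial=str(row["species_binomial"]),
                taxonomy={
                    rank: ("" if pd.isna(row[rank]) else str(row[rank]))
                    for rank in _TAXON_RANKS
                },
                body_mass_kg=_opt(row["body_mass_kg"]),
                brain_volume_ml=_opt(row["brain_volume_ml"]),
                vo2_std=_opt(row["vo2_std"]),
                mr_mass_specific_w_per_kg=_opt(row["mr_mass_specific_w_per_kg"]),
                mr_total_w=_opt(row["mr_total_w"]),
                temperature_c=_opt(row["temperature_c"]),
                sex=None if pd.isna(row["sex"]) else str(row["sex"]),
                sample_size=None if pd.isna(row["sample_size"]) else int(row["sample_size"]),
                original_value="" if pd.isna(row["original_value"]) else str(row["original_value"]),
                original_unit="" if pd.isna(row["original_unit"]) else str(row["original_unit"]),
                reference={"citation": "" if pd.isna(row["reference"]) else str(row["reference"]),
                           "year": None if pd.isna(row["year"]) else int(row["year"])},
                document_id="" if pd.isna(row["document_id"]) else str(row["document_id"]),
                provenance=Provenance(int(row["page_index"]), int(row["block_index"]),
                                      int(row["row_index"]), True),
            )
        )
    return records


OBSERVATION_COLUMNS = (
    "document_id", "species_binomial", "field_kind", "raw_value", "raw_unit",
    "temperature_raw", "class", "page_index", "block_index", "row_index",
    "citation", "year",
)


def export_observations(observations, path: str | Path) -> Path:
    """Serialize raw trait observations (the extract stage output)."""
    rows = [
        {
            "document_id": o.document_id,
            "species_binomial": o.species_binomial,
            "field_kind": o.field_kind,
            "raw_value": o.raw_value,
            "raw_unit": o.raw_unit,
            "temperature_raw": o.temperature_raw or "",
            "class": o.taxonomy.get("class", ""),
            "page_index": o.provenance.page_index,
            "block_index": o.provenance.block_index,
            "row_index": o.provenance.row_index,
            "citation": o.reference.get("citation", ""),
            "year": o.reference.get("year", ""),
        }
        for o in observations
    ]
    path = Path(path)
    pd.DataFrame(rows, columns=list(OBSERVATION_COLUMNS)).to_csv(
        path, index=False, encoding="utf-8-sig", lineterminator="\n"
    )
    return path


def read_observations(path: str | Path) -> list:
    from .sandbox import RawTraitObservation

    frame = pd.read_csv(path, encoding="utf-8-sig", keep_default_na=False)
    observations = []
    for row in frame.to_dict("records"):
        observations.append(
            RawTraitObservation(
                species_binomial=str(row["species_binomial"]),
                field_kind=str(row["field_kind"]),
                raw_value=str(row["raw_value"]),
                raw_unit=str(row["raw_unit"]),
                taxonomy={"class": str(row["class"])} if str(row["class"]) else {},
                temperature_raw=str(row["temperature_raw"]) or None,
                reference={"citation": str(row["citation"]),
                           "year": int(row["year"]) if str(row["year"]) else None},
                provenance=Provenance(int(row["page_index"]), int(row["block_index"]),
                                      int(row["row_index"]), True),
                document_id=str(row["document_id"]),
            )
        )
    return observations


# --------------------------------------------------------------------------
# safe file naming
# --------------------------------------------------------------------------

_SLUG_RE = re.compile(r"[^A-Za-z0-9]+")


def safe_filename(
    metadata: dict,
    existing: Optional[set[str]] = None,
    suffix: str = ".csv",
) -> str:
    """Generate a conflict-free, filesystem-safe filename from extracted
    metadata (reference citation + year).  Whitelist [A-Za-z0-9_-]; name
    collisions within ``existing`` resolve by a numeric suffix."""
    citation = str(metadata.get("citation", "") or "")
    year = metadata.get("year")
    base = _SLUG_RE.sub("_", citation).strip("_").lower()
    parts = [p for p in (base, str(year) if year else "") if p]
    slug = "_".join(parts) or "untitled"
    existing = existing if existing is not None else set()
    name = slug + suffix
    counter = 2
    while name in existing:
        name = f"{slug}_{counter}{suffix}"
        counter += 1
    return name


# --------------------------------------------------------------------------
# reference-table reading and harmonization
# --------------------------------------------------------------------------

REFERENCE_COLUMNS = ("binomial", "body_mass", "body_mass_unit",
                     "metabolic_rate", "metabolic_rate_unit")


def harmonize_reference(frame: pd.DataFrame,
                        caloric_equivalent_j_per_ml: float = 20.1) -> pd.DataFrame:
    """Convert a raw reference table to canonical units through the unit
    engine: body mass -> kg; basal metabolic rate (whole-body oxygen
    consumption) -> W via the same oxygen caloric equivalent the pipeline
    uses.  Returns columns binomial / body_mass / metabolic_rate."""
    out = []
    for _, row in frame.iterrows():
        mass = row.get("body_mass")
        mr = row.get("metabolic_rate")
        mass_kg = None
        mr_w = None
        if pd.notna(mass):
            mass_kg = normalize_mass(float(mass), str(row["body_mass_unit"]))
        if pd.notna(mr):
            dim = parse_unit(str(row["metabolic_rate_unit"]))
            if dim.quantity_kind != "oxygen_rate" or dim.is_mass_specific:
                raise UnknownUnit(
                    "reference metabolic rate must be a whole-body oxygen rate"
                )
            vo2_ml_per_h = float(mr) * dim.scale_to_canonical
            mr_w = vo2_ml_per_h / 3600.0 * caloric_equivalent_j_per_ml
        out.append({"binomial": row["binomial"], "body_mass": mass_kg,
                    "metabolic_rate": mr_w})
    return pd.DataFrame(out, columns=["binomial", "body_mass", "metabolic_rate"])


def read_reference_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, encoding="utf-8-sig")
    missing = set(REFERENCE_COLUMNS) - set(frame.columns)
    if missing:
        raise IOFailure(f"reference table missing columns: {sorted(missing)}")
    return frame


# --------------------------------------------------------------------------
# corpus directories and the end-to-end runner
# --------------------------------------------------------------------------


def write_corpus(corpus, root: str | Path) -> Path:
    """Write a GoldCorpus to disk: one directory per document with
    page_NNNN.json blocks and a meta.json (reference, year), plus gold
    annotations and labels for evaluation."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    for doc_id, pages in corpus.documents.items():
        doc_dir = root / doc_id
        doc_dir.mkdir(exist_ok=True)
        for page in pages:
            write_page_file(doc_dir / f"page_{page.page_index:04d}.json", page)
        (doc_dir / "meta.json").write_text(
            json.dumps(corpus.references[doc_id]), encoding="utf-8"
        )
    gold = [
        {
            "document_id": a.document_id,
            "field_kind": a.field_kind,
            "species": a.species,
            "value": a.value,
            "unit": a.unit,
        }
        for a in corpus.gold_annotations
    ]
    pd.DataFrame(
        gold, columns=["document_id", "field_kind", "species", "value", "unit"]
    ).to_csv(root / "gold_annotations.csv", index=False, encoding="utf-8-sig",
             lineterminator="\n")
    return root


def read_gold_annotations(path: str | Path) -> list:
    from .evaluation import FieldValue

    frame = pd.read_csv(path, encoding="utf-8-sig", keep_default_na=False)
    return [
        FieldValue(str(r.document_id), str(r.field_kind), str(r.species),
                   str(r.value), str(r.unit))
        for r in frame.itertuples()
    ]


def run_pipeline(
    corpus_root: str | Path,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[list[StandardizedRecord], RejectionLog]:
    """End-to-end run over a corpus directory: scripted extraction, page
    reconstruction, table merging, sandbox standardization, and a final
    corpus-level deduplication pass.  Deterministic document order."""
    corpus_root = Path(corpus_root)
    all_records: list[StandardizedRecord] = []
    log = RejectionLog()
    for doc_dir in sorted(p for p in corpus_root.iterdir() if p.is_dir()):
        meta_path = doc_dir / "meta.json"
        reference = (
            json.loads(meta_path.read_text(encoding="utf-8"))
            if meta_path.exists()
            else {}
        )
        aggregate = extract_document(
            doc_dir, concurrency=config.concurrency, max_retries=config.max_retries
        )
        records, doc_log = process_document(
            aggregate, doc_dir.name, reference, config
        )
        all_records.extend(records)
        log.entries.extend(doc_log.entries)
        log.merges.extend(doc_log.merges)
    kept, _ = deduplicate_records(all_records, config.temperature_round_c, log)
    return kept, log


def run_corpus(
    corpus,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[list[StandardizedRecord], RejectionLog]:
    """Like :func:`run_pipeline`, but over an in-memory GoldCorpus."""
    all_records: list[StandardizedRecord] = []
    log = RejectionLog()
    for doc_id in sorted(corpus.documents):
        aggregate = merge_table_continuations(
            reconstruct_sequence(corpus.documents[doc_id])
        )
        records, doc_log = process_document(
            aggregate, doc_id, corpus.references.get(doc_id, {}), config
        )
        all_records.extend(records)
        log.entries.extend(doc_log.entries)
        log.merges.extend(doc_log.merges)
    kept, _ = deduplicate_records(all_records, config.temperature_round_c, log)
    return kept, log
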