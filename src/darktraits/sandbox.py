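"""Deterministic verification core.

The sandbox is the quality-control engine between raw extracted trait
observations and the released database.  It is a pure function of its inputs
and configuration: no randomness, no hidden state, byte-identical output on
repeated runs.  Its responsibilities, in pipeline order:

1. *Circuit breaking* — tables that report regression-derived quantities
   (slopes, intercepts of allometric models) are rejected wholesale so only
   empirical measurements enter the database.
2. *Standardization* — numeric cleaning and unit routing via
   :mod:`darktraits.units`, aligning oxygen consumption to mL O2 kg^-1 h^-1.
3. *Thermodynamic conversion* — oxygen consumption to power using the
   oxygen caloric equivalent (20.1 J per mL O2):
   ``MR_mass_specific = VO2 / 3600 * 20.1`` (W/kg) and
   ``MR_total = MR_mass_specific * M`` (W).
4. *Physical consistency checks* — positivity, temperature range, the
   MR_total identity, and a wide plausibility corridor for mass-specific
   metabolic rate.
5. *Deduplication* — records sharing the composite primary key
   (species, original temperature) AND identical standardized values
   collapse to the first occurrence; distinct measurements are retained.

Every input observation group is accounted for either in the output records
or in the append-only rejection log.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import (
    AmbiguousUnit,
    ImplausibleTemperature,
    MalformedBinomial,
    MissingBodyMass,
    NonPositiveMass,
    NonPositiveValue,
    UnknownUnit,
    UnparsableNumber,
)
from .pages import DocumentAggregate, TableBlock
from .units import (
    clean_numeric,
    normalize_brain,
    normalize_mass,
    normalize_temperature,
    parse_unit,
    standardize_vo2,
)

FIELD_KINDS = (
    "body_mass",
    "brain_size",
    "metabolic_rate",
    "temperature",
    "sex",
    "sample_size",
)

REJECTION_RULES = (
    "regression_table",
    "unparsable",
    "ambiguous_unit",
    "implausible_value",
    "missing_mass",
)


def canonicalize_binomial(name: str) -> str:
    """Canonicalize a two-token Latin binomial: trim, collapse internal
    whitespace, capitalize the genus, lowercase the epithet.

    Raises :class:`MalformedBinomial` for anything but two tokens.
    """
    tokens = name.strip().split()
    if len(tokens) != 2:
        raise MalformedBinomial(f"expected 'Genus epithet', got {name!r}")
    genus, epithet = tokens
    return f"{genus.capitalize()} {epithet.lower()}"


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Provenance:
    """Where an observation came from inside its source document."""

    page_index: int = 0
    block_index: int = 0
    row_index: int = 0
    table_flag: bool = False


@dataclass(frozen=True)
class RawTraitObservation:
    """One extracted (species, field, raw value, raw unit) tuple."""

    species_binomial: str
    field_kind: str
    raw_value: str
    raw_unit: str = ""
    taxonomy: dict = field(default_factory=dict)
    temperature_raw: Optional[str] = None
    reference: dict = field(default_factory=dict)
    provenance: Provenance = field(default_factory=Provenance)
    document_id: str = ""

    def group_key(self) -> tuple:
        p = self.provenance
        return (self.document_id, p.page_index, p.block_index, p.row_index,
                self.species_binomial)


@dataclass
class StandardizedRecord:
    """A normalized trait record, one row of the released database."""

    species_binomial: str
    taxonomy: dict = field(default_factory=dict)
    body_mass_kg: Optional[float] = None
    brain_volume_ml: Optional[float] = None
    vo2_std: Optional[float] = None  # mL O2 kg^-1 h^-1
    mr_mass_specific_w_per_kg: Optional[float] = None
    mr_total_w: Optional[float] = None
    temperature_c: Optional[float] = None
    sex: Optional[str] = None
    sample_size: Optional[int] = None
    original_value: str = ""
    original_unit: str = ""
    reference: dict = field(default_factory=dict)
    document_id: str = ""
    provenance: Provenance = field(default_factory=Provenance)

    def composite_key(self, grid: float = 0.1) -> tuple:
        """(species, original temperature) primary key; temperature snapped
        to the configured rounding grid, absent temperature its own stratum."""
        if self.temperature_c is None:
            return (self.species_binomial, None)
        return (self.species_binomial, round(self.temperature_c / grid) * grid)

    def trait_signature(self) -> tuple:
        return (
            self.body_mass_kg,
            self.brain_volume_ml,
            self.vo2_std,
            self.mr_mass_specific_w_per_kg,
            self.mr_total_w,
            self.sex,
            self.sample_size,
        )


@dataclass(frozen=True)
class RejectionEntry:
    document_id: str
    provenance: Provenance
    rule_id: str
    detail: str


@dataclass
class RejectionLog:
    """Append-only log of everything excluded (or merged) during processing."""

    entries: list[RejectionEntry] = field(default_factory=list)
    merges: list[RejectionEntry] = field(default_factory=list)

    def add(self, document_id: str, provenance: Provenance, rule_id: str,
            detail: str) -> None:
        if rule_id not in REJECTION_RULES:
            raise ValueError(f"unknown rejection rule {rule_id!r}")
        self.entries.append(RejectionEntry(document_id, provenance, rule_id, detail))

    def count(self, rule_id: str) -> int:
        return sum(1 for e in self.entries if e.rule_id == rule_id)


# --------------------------------------------------------------------------
# thermodynamic conversion
# --------------------------------------------------------------------------


def convert_metabolic_rate(
    vo2_std: float,
    body_mass_kg: Optional[float] = None,
    caloric_equivalent_j_per_ml: float = 20.1,
) -> tuple[float, Optional[float]]:
    """Convert standardized oxygen consumption into metabolic power.

    ``MR_mass_specific = VO2 / 3600 * q`` in W/kg, with VO2 in
    mL O2 kg^-1 h^-1, 3600 the hours-to-seconds coefficient and *q* the
    oxygen caloric equivalent in J/mL.  ``MR_total = MR_mass_specific * M``
    in W when body mass *M* (kg) is present, else absent.
    """
    if vo2_std < 0:
        raise NonPositiveValue(f"negative VO2: {vo2_std}")
    if body_mass_kg is not None and body_mass_kg <= 0:
        raise NonPositiveMass(f"body mass must be positive, got {body_mass_kg}")
    mr_mass_specific = vo2_std / 3600.0 * caloric_equivalent_j_per_ml
    mr_total = None if body_mass_kg is None else mr_mass_specific * body_mass_kg
    return mr_mass_specific, mr_total


# --------------------------------------------------------------------------
# circuit breaker
# --------------------------------------------------------------------------

#: allometric-equation shape "Y = a M ^ b"
_EQUATION_RE = re.compile(
    r"[A-Za-z]\w*\s*=\s*[-+]?\d+(?:\.\d+)?\s*[·*]?\s*[A-Za-z]\w*\s*\^\s*[-+]?\d+(?:\.\d+)?"
)


def apply_circuit_breaker(
    table: TableBlock,
    keywords: Sequence[str] = DEFAULT_CONFIG.circuit_breaker_keywords,
) -> tuple[str, str]:
    """Classify a table as empirical (``accept``) or regression-derived
    (``reject``).

    A table is rejected iff any header or cell contains a detection keyword
    (whole-token, case-insensitive) or matches the allometric equation
    pattern ``Y = a M ^ b``.  Pure classification; never raises.
    """
    texts = list(table.headers)
    for row in table.rows:
        texts.extend(str(c) for c in row)
    patterns = [
        re.compile(rf"(?<!\w){re.escape(kw.lower())}(?!\w)") for kw in keywords
    ]
    for text in texts:
        low = str(text).lower()
        for kw, pat in zip(keywords, patterns):
            if pat.search(low):
                return "reject", f"keyword:{kw}"
        if _EQUATION_RE.search(str(text)):
            return "reject", "equation_pattern"
    return "accept", ""


# --------------------------------------------------------------------------
# physical consistency
# --------------------------------------------------------------------------


def check_physical_consistency(
    record: StandardizedRecord, config: PipelineConfig = DEFAULT_CONFIG
) -> tuple[bool, list[str]]:
    """Collect (never short-circuit) physical violations of a record."""
    violations: list[str] = []
    if record.body_mass_kg is not None and record.body_mass_kg <= 0:
        violations.append("nonpositive_mass")
    if record.brain_volume_ml is not None and record.brain_volume_ml <= 0:
        violations.append("nonpositive_volume")
    mr = record.mr_mass_specific_w_per_kg
    if mr is not None and mr < 0:
        violations.append("negative_mr")
    if record.temperature_c is not None:
        lo, hi = config.temperature_bounds_c
        if not lo <= record.temperature_c <= hi:
            violations.append("temperature_range")
    if record.mr_total_w is not None:
        if record.body_mass_kg is None or mr is None:
            violations.append("mr_total_without_mass")
        else:
            expected = mr * record.body_mass_kg
            scale = max(abs(expected), abs(record.mr_total_w), 1e-300)
            if abs(record.mr_total_w - expected) / scale > 1e-9:
                violations.append("mr_identity")
    if mr is not None and mr > 0:
        lo, hi = config.mr_plausible_w_per_kg
        if not lo <= mr <= hi:
            violations.append("mr_corridor")
    return (not violations), violations


# --------------------------------------------------------------------------
# deduplication
# --------------------------------------------------------------------------


def _values_identical(a: tuple, b: tuple, rel_tol: float = 1e-9) -> bool:
    if len(a) != len(b):
        return False
    for x, y in zip(a, b):
        if x is None and y is None:
            continue
        if (x is None) != (y is None):
            return False
        if isinstance(x, float) or isinstance(y, float):
            if not math.isclose(x, y, rel_tol=rel_tol, abs_tol=0.0):
                return False
        elif x != y:
            return False
    return True


def deduplicate_records(
    records: Sequence[StandardizedRecord],
    grid: float = 0.1,
    log: Optional[RejectionLog] = None,
) -> tuple[list[StandardizedRecord], int]:
    """Merge exact duplicates sharing the composite key and identical
    standardized values (1e-9 relative); first occurrence wins, output order
    is the input order of survivors.  Distinct measurements under the same
    key are retained as separate records."""
    kept: list[StandardizedRecord] = []
    by_key: dict[tuple, list[StandardizedRecord]] = {}
    merged = 0
    for rec in records:
        key = rec.composite_key(grid)
        duplicate = False
        for prior in by_key.get(key, ()):
            if _values_identical(prior.trait_signature(), rec.trait_signature()):
                duplicate = True
                break
        if duplicate:
            merged += 1
            if log is not None:
                log.merges.append(
                    RejectionEntry(rec.document_id, rec.provenance, "merge",
                                   "merged exact duplicate")
                )
            continue
        kept.append(rec)
        by_key.setdefault(key, []).append(rec)
    return kept, merged


# --------------------------------------------------------------------------
# observation harvesting from reconstructed documents
# --------------------------------------------------------------------------

_HEADER_FIELD_PATTERNS: tuple[tuple[str, str], ...] = (
    (r"species|binomial", "species"),
    (r"phylum", "tax:phylum"),
    (r"\bclass\b", "tax:class"),
    (r"\border\b", "tax:order"),
    (r"family", "tax:family"),
    (r"genus", "tax:genus"),
    (r"body\s*mass|mass|weight", "body_mass"),
    (r"brain", "brain_size"),
    (r"vo2|metabolic|oxygen", "metabolic_rate"),
    (r"temp", "temperature"),
    (r"\bsex\b", "sex"),
    (r"\bn\b|sample\s*size", "sample_size"),
)

_UNIT_IN_HEADER_RE = re.compile(r"\(([^()]*)\)\s*$")


def classify_header(header: str) -> tuple[Optional[str], str]:
    """Map a table header to a trait field and extract its unit annotation.

    Returns (field, unit) where field is a trait kind, ``species``,
    ``tax:<rank>`` or None for unrecognized columns.
    """
    unit = ""
    m = _UNIT_IN_HEADER_RE.search(header.strip())
    label = header.strip()
    if m:
        unit = m.group(1).strip()
        label = label[: m.start()].strip()
    low = label.lower()
    for pattern, fieldname in _HEADER_FIELD_PATTERNS:
        if re.search(pattern, low):
            return fieldname, unit
    return None, unit


def harvest_observations(
    aggregate: DocumentAggregate,
    document_id: str = "",
    reference: Optional[dict] = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[list[RawTraitObservation], RejectionLog]:
    """Walk a reconstructed document, apply the circuit breaker to each
    table, and turn accepted table rows into grouped raw observations."""
    log = RejectionLog()
    observations: list[RawTraitObservation] = []
    reference = reference or {}
    for placed in aggregate.blocks:
        if placed.kind != "table":
            continue
        table = placed.payload
        prov = Provenance(placed.page_index, placed.block_index, 0, True)
        verdict, detail = apply_circuit_breaker(
            table, config.circuit_breaker_keywords
        )
        if verdict == "reject":
            log.add(document_id, prov, "regression_table", detail)
            continue
        fields = [classify_header(h) for h in table.headers]
        species_col = next(
            (i for i, (f, _) in enumerate(fields) if f == "species"), None
        )
        if species_col is None:
            continue
        for r_idx, row in enumerate(table.rows):
            species = str(row[species_col])
            taxonomy = {
                f.split(":", 1)[1]: str(row[i])
                for i, (f, _) in enumerate(fields)
                if f and f.startswith("tax:") and i < len(row)
            }
            row_prov = Provenance(
                placed.page_index, placed.block_index, r_idx, True
            )
            temperature_raw = None
            for i, (fieldname, unit) in enumerate(fields):
                if fieldname == "temperature" and i < len(row) and str(row[i]).strip():
                    temperature_raw = str(row[i])
            for i, (fieldname, unit) in enumerate(fields):
                if i >= len(row) or fieldname is None:
                    continue
                if fieldname == "species" or fieldname.startswith("tax:"):
                    continue
                cell = str(row[i]).strip()
                if not cell:
                    continue
                observations.append(
                    RawTraitObservation(
                        species_binomial=species,
                        field_kind=fieldname,
                        raw_value=cell,
                        raw_unit=unit,
                        taxonomy=taxonomy,
                        temperature_raw=(
                            temperature_raw if fieldname == "metabolic_rate" else None
                        ),
                        reference=reference,
                        provenance=row_prov,
                        document_id=document_id,
                    )
                )
    return observations, log


# --------------------------------------------------------------------------
# the sandbox proper
# --------------------------------------------------------------------------


def _standardize_group(
    obs: list[RawTraitObservation],
    config: PipelineConfig,
    log: RejectionLog,
) -> Optional[StandardizedRecord]:
    doc = obs[0].document_id
    prov = obs[0].provenance
    try:
        species = canonicalize_binomial(obs[0].species_binomial)
    except MalformedBinomial as exc:
        log.add(doc, prov, "unparsable", f"species: {exc}")
        return None

    rec = StandardizedRecord(
        species_binomial=species,
        taxonomy=dict(obs[0].taxonomy),
        reference=dict(obs[0].reference),
        document_id=doc,
        provenance=prov,
    )

    by_kind: dict[str, RawTraitObservation] = {}
    for o in obs:
        by_kind.setdefault(o.field_kind, o)

    def _log(rule: str, detail: str) -> None:
        log.add(doc, prov, rule, detail)

    if "body_mass" in by_kind:
        o = by_kind["body_mass"]
        try:
            value = clean_numeric(o.raw_value).value
            rec.body_mass_kg = normalize_mass(value, o.raw_unit)
        except (UnparsableNumber, NonPositiveValue) as exc:
            _log("unparsable", f"body_mass: {exc}")
        except UnknownUnit as exc:
            _log("ambiguous_unit", f"body_mass: {exc}")

    if "brain_size" in by_kind:
        o = by_kind["brain_size"]
        try:
            value = clean_numeric(o.raw_value).value
            rec.brain_volume_ml = normalize_brain(
                value, o.raw_unit, config.brain_density_g_per_ml
            )
        except (UnparsableNumber, NonPositiveValue) as exc:
            _log("unparsable", f"brain_size: {exc}")
        except UnknownUnit as exc:
            _log("ambiguous_unit", f"brain_size: {exc}")

    temp_obs = by_kind.get("temperature")
    temp_raw = temp_obs.raw_value if temp_obs else None
    if temp_raw is None and "metabolic_rate" in by_kind:
        temp_raw = by_kind["metabolic_rate"].temperature_raw
    if temp_raw is not None:
        try:
            rec.temperature_c = normalize_temperature(
                temp_raw, config.temperature_bounds_c
            )
        except UnparsableNumber as exc:
            _log("unparsable", f"temperature: {exc}")
        except ImplausibleTemperature as exc:
            _log("implausible_value", f"temperature: {exc}")

    if "metabolic_rate" in by_kind:
        o = by_kind["metabolic_rate"]
        rec.original_value = o.raw_value
        rec.original_unit = o.raw_unit
        try:
            value = clean_numeric(o.raw_value).value
            dim = parse_unit(o.raw_unit)
            vo2, _form = standardize_vo2(value, dim, rec.body_mass_kg)
            rec.vo2_std = vo2
            ms, total = convert_metabolic_rate(
                vo2, rec.body_mass_kg, config.oxygen_caloric_equivalent_j_per_ml
            )
            rec.mr_mass_specific_w_per_kg = ms
            rec.mr_total_w = total
        except MissingBodyMass as exc:
            _log("missing_mass", f"metabolic_rate: {exc}")
        except (UnparsableNumber, NonPositiveValue, NonPositiveMass) as exc:
            _log("unparsable", f"metabolic_rate: {exc}")
        except (UnknownUnit, AmbiguousUnit) as exc:
            _log("ambiguous_unit", f"metabolic_rate: {exc}")
    elif "body_mass" in by_kind:
        o = by_kind["body_mass"]
        rec.original_value = o.raw_value
        rec.original_unit = o.raw_unit

    if "sex" in by_kind:
        rec.sex = by_kind["sex"].raw_value.strip() or None
    if "sample_size" in by_kind:
        try:
            rec.sample_size = int(clean_numeric(by_kind["sample_size"].raw_value).value)
        except UnparsableNumber as exc:
            _log("unparsable", f"sample_size: {exc}")

    ok, violations = check_physical_consistency(rec, config)
    if not ok:
        _log("implausible_value", "record: " + ",".join(violations))
        return None
    return rec


def run_sandbox(
    observations: Iterable[RawTraitObservation],
    config: PipelineConfig = DEFAULT_CONFIG,
    log: Optional[RejectionLog] = None,
) -> tuple[list[StandardizedRecord], RejectionLog]:
    """Standardize grouped observations into database records.

    Composes clean -> parse_unit -> standardize -> convert -> consistency ->
    dedup.  Every observation group yields either a record or at least one
    rejection entry; per-record errors never abort the batch.  Referentially
    transparent: identical inputs and config give identical output.
    """
    log = log if log is not None else RejectionLog()
    groups: dict[tuple, list[RawTraitObservation]] = {}
    order: list[tuple] = []
    for o in observations:
        key = o.group_key()
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(o)

    records: list[StandardizedRecord] = []
    for key in order:
        rec = _standardize_group(groups[key], config, log)
        if rec is not None:
            records.append(rec)

    kept, _merged = deduplicate_records(records, config.temperature_round_c, log)
    return kept, log


def process_document(
    aggregate: DocumentAggregate,
    document_id: str = "",
    reference: Optional[dict] = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[list[StandardizedRecord], RejectionLog]:
    """Circuit-break, harvest and standardize one reconstructed document."""
    observations, log = harvest_observations(
        aggregate, document_id, reference, config
    )
    records, log = run_sandbox(observations, config, log)
    return records, log
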