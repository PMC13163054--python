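"""Ground-truth corpus generators.

Emulates the statistical structure of a century of physiological
literature so every pipeline stage is testable with known truth and no
external data: power-law trait structure with lognormal noise, mixed unit
dialects (``cc O2``, per-gram, per-minute forms), parenthetical and ±
annotations, exact duplicate records, injected regression-coefficient
tables, and cross-page table splits.

The generators are seeded and fully deterministic.  Gold records carry the
exact values a perfect pipeline must recover: raw cell strings are rounded
first, and gold standardized values are then derived from those rounded
strings with the same canonical conversion arithmetic the sandbox defines —
so in the noiseless, contamination-free limit the end-to-end pipeline output
matches gold bitwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import InvalidSpec
from .evaluation import FieldValue
from .pages import Block, PageExtraction, TableBlock
from .sandbox import Provenance, StandardizedRecord
from .validation import aggregate_to_species

# dialect factor tables used to derive gold values from rounded raw strings;
# values mirror the canonical definitions (mL, kg, hours)
_MASS_FACTORS = {"g": 1e-3, "kg": 1.0, "mg": 1e-6}
_BRAIN_FACTORS = {"mL": ("volume", 1.0), "cc": ("volume", 1.0),
                  "mm3": ("volume", 0.001), "g": ("mass", 1e-3)}
#: metabolic-rate dialects: unit string -> (scale to canonical, mass_specific?)
_MR_DIALECTS = {
    "mL O2 kg-1 h-1": (1.0, True),
    "mL O2 g-1 h-1": (1.0 / 1e-3, True),
    "cc O2 g-1 hr-1": (1.0 / 1e-3, True),
    "mL O2 h-1": (1.0, False),
    "mL O2 min-1": (1.0 / (1.0 / 60.0), False),
}

_REGRESSION_HEADER_SETS = (
    ("Class", "slope b", "intercept log a", "r2"),
    ("Group", "Regression", "Exponent", "r²"),
    ("Taxon", "Allometric equation", "n", "r2"),
)


@dataclass(frozen=True)
class ClassParams:
    """Per-class allometric parameters Y = a * M^b."""

    mr_a_w: float  # whole-body metabolic rate at 1 kg, W
    mr_b: float
    brain_a_ml: float  # brain volume at 1 kg, mL
    brain_b: float
    temp_loc_c: float
    temp_scale_c: float


DEFAULT_CLASS_PARAMS: dict[str, ClassParams] = {
    "Mammalia": ClassParams(3.4, 0.67, 9.0, 0.75, 37.5, 1.0),
    "Aves": ClassParams(3.9, 0.67, 6.0, 0.75, 40.0, 1.0),
    "Reptilia": ClassParams(0.15, 0.67, 0.6, 0.75, 27.0, 5.0),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions of a synthetic corpus run; the seed is mandatory."""

    seed: int
    n_species: int = 150
    n_documents: int = 110
    records_per_document: int = 3
    class_weights: tuple[tuple[str, float], ...] = (
        ("Mammalia", 0.5), ("Aves", 0.25), ("Reptilia", 0.25)
    )
    class_params: tuple[tuple[str, ClassParams], ...] = tuple(
        DEFAULT_CLASS_PARAMS.items()
    )
    noise_sd_log10: float = 0.2
    mass_range_kg: tuple[float, float] = (0.001, 500.0)
    mass_units: tuple[tuple[str, float], ...] = (
        ("g", 0.5), ("kg", 0.4), ("mg", 0.1)
    )
    brain_units: tuple[tuple[str, float], ...] = (
        ("mL", 0.4), ("cc", 0.3), ("g", 0.2), ("mm3", 0.1)
    )
    mr_dialects: tuple[tuple[str, float], ...] = (
        ("mL O2 kg-1 h-1", 0.3), ("mL O2 g-1 h-1", 0.25),
        ("cc O2 g-1 hr-1", 0.2), ("mL O2 h-1", 0.15), ("mL O2 min-1", 0.1)
    )
    duplicate_rate: float = 0.05
    regression_table_rate: float = 0.1
    annotation_noise_rate: float = 0.2
    multipage_split_rate: float = 0.3
    temperature_presence_rate: float = 0.7
    brain_density_g_per_ml: float = 1.036
    oxygen_caloric_equivalent_j_per_ml: float = 20.1

    def validate(self) -> None:
        for name, probs in (
            ("class_weights", self.class_weights),
            ("mass_units", self.mass_units),
            ("brain_units", self.brain_units),
            ("mr_dialects", self.mr_dialects),
        ):
            total = sum(p for _, p in probs)
            if not math.isclose(total, 1.0, rel_tol=1e-9):
                raise InvalidSpec(f"{name} probabilities sum to {total}, not 1")
        for name in ("duplicate_rate", "regression_table_rate",
                     "annotation_noise_rate", "multipage_split_rate",
                     "temperature_presence_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidSpec(f"{name}={v} outside [0, 1]")
        if self.noise_sd_log10 < 0:
            raise InvalidSpec("noise_sd_log10 must be >= 0")
        lo, hi = self.mass_range_kg
        if not 0 < lo < hi:
            raise InvalidSpec("mass_range_kg must be 0 < lo < hi")


@dataclass
class GoldCorpus:
    """Page-block corpus plus everything a grader needs: gold records,
    per-table labels, duplicate counts, and per-field gold annotations."""

    documents: dict[str, list[PageExtraction]]
    references: dict[str, dict]
    gold_records: list[StandardizedRecord]
    table_labels: list[tuple[str, int, int, str]]  # (doc, page, block, label)
    gold_annotations: list[FieldValue]
    n_duplicates_injected: int
    n_regression_tables: int
    true_params: dict[str, ClassParams]

    @property
    def document_ids(self) -> list[str]:
        return sorted(self.documents)


def _sig(x: float, digits: int = 6) -> float:
    return float(f"{x:.{digits}g}")


def _choice(rng: np.random.Generator, weighted: tuple[tuple[str, float], ...]) -> str:
    names = [n for n, _ in weighted]
    probs = np.asarray([p for _, p in weighted], dtype=float)
    return names[int(rng.choice(len(names), p=probs / probs.sum()))]


# --------------------------------------------------------------------------
# record-level generator
# --------------------------------------------------------------------------


def _species_pool(spec: SyntheticSpec, rng: np.random.Generator) -> list[tuple[str, str]]:
    pool = []
    for i in range(spec.n_species):
        cls = _choice(rng, spec.class_weights)
        pool.append((f"Synthgenus{i:03d} species{i:03d}", cls))
    return pool


def generate_allometric_records(
    spec: SyntheticSpec,
    trait: str = "metabolic_rate",
    n_records: Optional[int] = None,
) -> tuple[list[StandardizedRecord], dict[str, ClassParams]]:
    """Generate standardized records following per-class power laws.

    Masses are log-uniform over the spec's range; the trait is
    a·M^b · 10^eps with eps ~ Normal(0, noise_sd_log10) in log10 space.
    Returns the records and the true generating parameters.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    params = dict(spec.class_params)
    n = n_records if n_records is not None else spec.n_documents * spec.records_per_document
    pool = _species_pool(spec, rng)
    lo, hi = spec.mass_range_kg
    records = []
    for i in range(n):
        species, cls = pool[int(rng.integers(len(pool)))]
        p = params[cls]
        mass = float(10.0 ** rng.uniform(np.log10(lo), np.log10(hi)))
        eps = float(rng.normal(0.0, spec.noise_sd_log10))
        rec = StandardizedRecord(
            species_binomial=species,
            taxonomy={"class": cls},
        )
        rec.body_mass_kg = mass
        if trait in ("metabolic_rate", "both"):
            total = p.mr_a_w * mass**p.mr_b * 10.0**eps
            rec.mr_total_w = total
            rec.mr_mass_specific_w_per_kg = total / mass
            rec.vo2_std = (
                rec.mr_mass_specific_w_per_kg
                * 3600.0
                / spec.oxygen_caloric_equivalent_j_per_ml
            )
        if trait in ("brain_volume", "both"):
            eps_b = float(rng.normal(0.0, spec.noise_sd_log10))
            rec.brain_volume_ml = p.brain_a_ml * mass**p.brain_b * 10.0**eps_b
        records.append(rec)
    return records, params


# --------------------------------------------------------------------------
# page-corpus generator
# --------------------------------------------------------------------------

_HEADERS_TEMPLATE = (
    "Species", "Class", "Body mass ({m})", "Brain size ({b})",
    "VO2 ({v})", "Temperature (°C)", "Sex", "N",
)


def _annotate(rng: np.random.Generator, cell: str) -> str:
    v = float(cell)
    kind = int(rng.integers(3))
    if kind == 0:
        lo, hi = _sig(v * 0.9, 4), _sig(v * 1.1, 4)
        return f"{cell} ({lo}–{hi})"
    if kind == 1:
        return f"{cell} ± {_sig(abs(v) * 0.05 + 0.01, 3)}"
    return f"{cell} (n.s.)"


def generate_page_corpus(spec: SyntheticSpec) -> GoldCorpus:
    """Serialize synthetic trait records into a page-block corpus with
    dialect-mixed units, annotation noise, exact duplicates, regression
    tables and cross-page table splits — all labeled."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    params = dict(spec.class_params)
    pool = _species_pool(spec, rng)
    lo, hi = spec.mass_range_kg
    q = spec.oxygen_caloric_equivalent_j_per_ml

    documents: dict[str, list[PageExtraction]] = {}
    references: dict[str, dict] = {}
    gold_records: list[StandardizedRecord] = []
    table_labels: list[tuple[str, int, int, str]] = []
    annotations: list[FieldValue] = []
    n_duplicates = 0
    n_regression = 0

    for d in range(spec.n_documents):
        doc_id = f"doc{d:04d}"
        year = 1908 + int(rng.integers(118))
        reference = {"citation": f"Author{d:04d} et al.", "year": year}
        references[doc_id] = reference

        mass_unit = _choice(rng, spec.mass_units)
        brain_unit = _choice(rng, spec.brain_units)
        mr_dialect = _choice(rng, spec.mr_dialects)
        mr_scale, mr_mass_specific = _MR_DIALECTS[mr_dialect]
        headers = tuple(
            h.format(m=mass_unit, b=brain_unit, v=mr_dialect)
            for h in _HEADERS_TEMPLATE
        )

        rows: list[tuple[str, ...]] = []
        doc_gold: list[StandardizedRecord] = []
        for _ in range(spec.records_per_document):
            species, cls = pool[int(rng.integers(len(pool)))]
            p = params[cls]
            mass = float(10.0 ** rng.uniform(np.log10(lo), np.log10(hi)))

            # raw cells are rounded first; gold derives from the rounded raws
            raw_mass = _sig(mass / _MASS_FACTORS[mass_unit])
            gold_mass = raw_mass * _MASS_FACTORS[mass_unit]

            eps_b = float(rng.normal(0.0, spec.noise_sd_log10))
            brain_ml = p.brain_a_ml * gold_mass**p.brain_b * 10.0**eps_b
            bkind, bfac = _BRAIN_FACTORS[brain_unit]
            if bkind == "volume":
                raw_brain = _sig(brain_ml / bfac)
                gold_brain = raw_brain * bfac
            else:  # reported as a mass; density converts back to volume
                raw_brain = _sig(brain_ml * spec.brain_density_g_per_ml / (bfac * 1000.0))
                gold_brain = (raw_brain * bfac * 1000.0) / spec.brain_density_g_per_ml

            eps = float(rng.normal(0.0, spec.noise_sd_log10))
            total_w = p.mr_a_w * gold_mass**p.mr_b * 10.0**eps
            vo2_target = total_w / gold_mass / q * 3600.0
            if mr_mass_specific:
                raw_mr = _sig(vo2_target / mr_scale)
                gold_vo2 = raw_mr * mr_scale
            else:
                raw_mr = _sig(vo2_target * gold_mass / mr_scale)
                gold_vo2 = raw_mr * mr_scale / gold_mass
            gold_ms = gold_vo2 / 3600.0 * q
            gold_total = gold_ms * gold_mass

            has_temp = rng.random() < spec.temperature_presence_rate
            if has_temp:
                temp = round(float(rng.normal(p.temp_loc_c, p.temp_scale_c)), 1)
                temp = min(max(temp, -9.0), 59.0)
                raw_temp = f"{temp:.1f}"
            else:
                temp = None
                raw_temp = ""
            sex = str(rng.choice(["M", "F", ""], p=[0.3, 0.3, 0.4]))
            n_sample = int(rng.integers(1, 40))

            mass_cell = str(raw_mass)
            mr_cell = str(raw_mr)
            if rng.random() < spec.annotation_noise_rate:
                mass_cell = _annotate(rng, mass_cell)
            if rng.random() < spec.annotation_noise_rate:
                mr_cell = _annotate(rng, mr_cell)

            rows.append((species, cls, mass_cell, str(raw_brain), mr_cell,
                         raw_temp, sex, str(n_sample)))
            rec = StandardizedRecord(
                species_binomial=species,
                taxonomy={"class": cls},
                body_mass_kg=gold_mass,
                brain_volume_ml=gold_brain,
                vo2_std=gold_vo2,
                mr_mass_specific_w_per_kg=gold_ms,
                mr_total_w=gold_total,
                temperature_c=temp,
                sex=sex or None,
                sample_size=n_sample,
                original_value=mr_cell,
                original_unit=mr_dialect,
                reference=reference,
                document_id=doc_id,
            )
            doc_gold.append(rec)
            for kind, val, unit in (
                ("taxonomic", species, ""),
                ("body_mass", mass_cell, mass_unit),
                ("metabolic_rate", mr_cell, mr_dialect),
                ("temperature", raw_temp, "°C"),
            ):
                if val:
                    annotations.append(
                        FieldValue(doc_id, kind, species, val, unit)
                    )

        # exact duplicates appended after the originals (first occurrence wins)
        n_rows_unique = len(rows)
        for i in range(n_rows_unique):
            if rng.random() < spec.duplicate_rate:
                rows.append(rows[i])
                n_duplicates += 1

        split = spec.multipage_split_rate > 0 and (
            rng.random() < spec.multipage_split_rate and len(rows) >= 2
        )
        pages: list[PageExtraction] = []
        caption = Block(0, "caption", f"Table 1. Physiological traits ({year}).")
        if split:
            cut = len(rows) // 2
            part1 = TableBlock(headers, tuple(rows[:cut]))
            repeat_header = bool(rng.integers(2))
            if repeat_header:
                part2 = TableBlock(headers, tuple(rows[cut:]), has_header=True)
            else:
                part2 = TableBlock((), tuple(rows[cut:]), has_header=False)
            pages.append(PageExtraction(1, (caption, Block(1, "table", part1))))
            pages.append(PageExtraction(2, (Block(0, "table", part2),)))
            table_labels.append((doc_id, 1, 1, "empirical"))
        else:
            table = TableBlock(headers, tuple(rows))
            pages.append(PageExtraction(1, (caption, Block(1, "table", table))))
            table_labels.append((doc_id, 1, 1, "empirical"))

        # merged-table provenance: page 1, block 1, sequential row index
        for r_idx, rec in enumerate(doc_gold):
            rec.provenance = Provenance(1, 1, r_idx, True)

        if rng.random() < spec.regression_table_rate:
            n_regression += 1
            reg_page = len(pages) + 1
            hset = _REGRESSION_HEADER_SETS[int(rng.integers(len(_REGRESSION_HEADER_SETS)))]
            if "equation" in " ".join(hset).lower():
                reg_rows = tuple(
                    (cls, f"MR = {_sig(p.mr_a_w, 3)} M^{p.mr_b}", "12", "0.91")
                    for cls, p in list(params.items())[:2]
                )
            else:
                reg_rows = tuple(
                    (cls, f"{p.mr_b:.3f}", f"{np.log10(p.mr_a_w):.3f}", "0.91")
                    for cls, p in list(params.items())[:2]
                )
            reg_table = TableBlock(hset, reg_rows)
            pages.append(
                PageExtraction(
                    reg_page,
                    (Block(0, "caption", "Table 2. Fitted allometric models."),
                     Block(1, "table", reg_table)),
                )
            )
            table_labels.append((doc_id, reg_page, 1, "regression"))

        documents[doc_id] = pages
        gold_records.extend(doc_gold)

    return GoldCorpus(
        documents=documents,
        references=references,
        gold_records=gold_records,
        table_labels=table_labels,
        gold_annotations=annotations,
        n_duplicates_injected=n_duplicates,
        n_regression_tables=n_regression,
        true_params=params,
    )


# --------------------------------------------------------------------------
# reference-table generator
# --------------------------------------------------------------------------


def generate_reference_table(
    gold_records: list[StandardizedRecord],
    perturbation_sd_log10: float = 0.0,
    dropout_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Build a species-level reference table from gold records, emulating a
    curated comparator: per-species medians, multiplicative lognormal
    perturbation (10^Normal(0, sd)), and random species dropout.

    Columns follow the curated-database convention: body mass in grams and
    basal metabolic rate as whole-body oxygen consumption (mL O2 h^-1),
    with explicit unit columns — harmonization back to canonical units is
    the concordance reader's job.
    """
    rng = np.random.default_rng(seed)
    aggregates = aggregate_to_species(gold_records)
    rows = []
    for agg in aggregates:
        if dropout_rate and rng.random() < dropout_rate:
            continue
        mass = agg.traits.get("body_mass")
        mr_w = agg.traits.get("metabolic_rate")
        if perturbation_sd_log10:
            if mass is not None:
                mass = mass * 10.0 ** float(rng.normal(0, perturbation_sd_log10))
            if mr_w is not None:
                mr_w = mr_w * 10.0 ** float(rng.normal(0, perturbation_sd_log10))
        rows.append(
            {
                "binomial": agg.species_binomial,
                "body_mass": None if mass is None else mass / 1e-3,
                "body_mass_unit": "g",
                "metabolic_rate": (
                    None if mr_w is None else mr_w * 3600.0 / 20.1
                ),
                "metabolic_rate_unit": "mL O2 h-1",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["binomial", "body_mass", "body_mass_unit",
                 "metabolic_rate", "metabolic_rate_unit"],
    )
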