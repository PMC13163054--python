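"""Sandbox: thermodynamic conversion, circuit breaker, consistency, dedup."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from darktraits.config import PipelineConfig
from darktraits.errors import MalformedBinomial, NonPositiveMass
from darktraits.io import run_corpus
from darktraits.pages import TableBlock
from darktraits.sandbox import (
    Provenance,
    RawTraitObservation,
    StandardizedRecord,
    apply_circuit_breaker,
    canonicalize_binomial,
    check_physical_consistency,
    convert_metabolic_rate,
    deduplicate_records,
    run_sandbox,
)


def _record(species="Mus musculus", mass=1.0, ms=20.1, temp=25.0, **kwargs):
    total = kwargs.pop("total", None if mass is None or ms is None else ms * mass)
    return StandardizedRecord(
        species_binomial=species,
        body_mass_kg=mass,
        mr_mass_specific_w_per_kg=ms,
        mr_total_w=total,
        vo2_std=None if ms is None else ms * 3600 / 20.1,
        temperature_c=temp,
        **kwargs,
    )


class TestConvertMetabolicRate:
    def test_oxycaloric_substitution(self):
        assert convert_metabolic_rate(3600.0, 1.0) == (20.1, 20.1)

    def test_mass_specific_only_when_mass_absent(self):
        ms, total = convert_metabolic_rate(1.0)
        assert math.isclose(ms, 20.1 / 3600.0, rel_tol=1e-12)
        assert total is None

    def test_zero(self):
        assert convert_metabolic_rate(0.0, 2.0) == (0.0, 0.0)

    def test_nonpositive_mass(self):
        with pytest.raises(NonPositiveMass):
            convert_metabolic_rate(10.0, -1.0)

    def test_total_identity_at_unit_mass(self):
        ms, total = convert_metabolic_rate(123.4, 1.0)
        assert total == ms


class TestCircuitBreaker:
    @pytest.mark.parametrize(
        "headers, verdict",
        [
            (("Species", "slope b", "intercept log a"), "reject"),
            (("Species", "Body mass (g)", "VO2 (mL O2/g/h)"), "accept"),
            (("Taxon", "Regression model", "n"), "reject"),
            (("Species", "Exponent", "r2"), "reject"),
            (("Species", "Temperature (°C)", "Sex", "N"), "accept"),
        ],
    )
    def test_header_keywords(self, headers, verdict):
        table = TableBlock(headers, (tuple("x" * len(headers)),))
        got, _ = apply_circuit_breaker(table)
        assert got == verdict

    def test_equation_pattern_in_cell(self):
        table = TableBlock(("Group", "Model"), (("Aves", "MR = 3.2 M^0.75"),))
        verdict, detail = apply_circuit_breaker(table)
        assert verdict == "reject" and detail == "equation_pattern"

    def test_keyword_needs_word_boundary(self):
        # "Slopeland vole" must not trip the 'slope' keyword
        table = TableBlock(("Species", "Mass (g)"), (("Slopeland vole", "21"),))
        assert apply_circuit_breaker(table)[0] == "accept"


class TestPhysicalConsistency:
    def test_valid_record_passes(self):
        ok, violations = check_physical_consistency(_record())
        assert ok and violations == []

    def test_hummingbird_extreme_not_flagged(self):
        ok, _ = check_physical_consistency(_record(mass=0.0032, ms=142.5))
        assert ok

    def test_reptile_minimum_not_flagged(self):
        ok, _ = check_physical_consistency(_record(mass=80.0, ms=0.05))
        assert ok

    def test_violations_collected_not_short_circuited(self):
        rec = _record(mass=-3.0, ms=2e3, temp=99.0, total=5.0)
        ok, violations = check_physical_consistency(rec)
        assert not ok
        assert {"nonpositive_mass", "temperature_range", "mr_corridor",
                "mr_identity"} <= set(violations)

    def test_mr_total_identity_tolerance(self):
        rec = _record(mass=2.0, ms=10.0, total=20.0 * (1 + 1e-6))
        ok, violations = check_physical_consistency(rec)
        assert "mr_identity" in violations and not ok


class TestDeduplication:
    def test_exact_duplicates_merge_first_wins(self):
        a, b = _record(), _record()
        kept, merged = deduplicate_records([a, b])
        assert kept == [a] and merged == 1

    def test_distinct_values_same_key_retained(self):
        kept, merged = deduplicate_records([_record(mass=2.0), _record(mass=2.1)])
        assert len(kept) == 2 and merged == 0

    def test_different_temperature_different_key(self):
        kept, _ = deduplicate_records([_record(temp=20.0), _record(temp=30.0)])
        assert len(kept) == 2

    def test_absent_temperature_own_stratum(self):
        kept, merged = deduplicate_records([_record(temp=None), _record(temp=None)])
        assert len(kept) == 1 and merged == 1
        kept, merged = deduplicate_records([_record(temp=None), _record(temp=25.0)])
        assert len(kept) == 2

    def test_temperature_rounding_grid(self):
        kept, merged = deduplicate_records([_record(temp=25.02), _record(temp=25.04)])
        assert len(kept) == 1 and merged == 1

    @given(st.lists(st.sampled_from([20.0, 20.0, 30.0, None]), max_size=8))
    @settings(max_examples=40, derandomize=True)
    def test_idempotent_and_never_grows(self, temps):
        records = [_record(temp=t) for t in temps]
        kept, _ = deduplicate_records(records)
        assert len(kept) <= len(records)
        again, merged = deduplicate_records(kept)
        assert again == kept and merged == 0


class TestBinomial:
    def test_canonicalization(self):
        assert canonicalize_binomial(" Mus   musculus ") == "Mus musculus"
        assert canonicalize_binomial("MUS MUSCULUS") == "Mus musculus"

    @pytest.mark.parametrize("bad", ["Mus", "Mus musculus domesticus", ""])
    def test_malformed(self, bad):
        with pytest.raises(MalformedBinomial):
            canonicalize_binomial(bad)


def _obs(field_kind, raw_value, raw_unit="", species="Mus musculus", row=0, **kw):
    return RawTraitObservation(
        species_binomial=species,
        field_kind=field_kind,
        raw_value=raw_value,
        raw_unit=raw_unit,
        provenance=Provenance(1, 1, row, True),
        **kw,
    )


class TestRunSandbox:
    def test_empty_input(self):
        records, log = run_sandbox([])
        assert records == [] and log.entries == []

    def test_full_group_standardization(self):
        obs = [
            _obs("body_mass", "5,000", "g"),
            _obs("metabolic_rate", "1.0 (0.9–1.1)", "mL O2 g-1 h-1"),
            _obs("temperature", "25 ± 1 °C"),
            _obs("sample_size", "12"),
        ]
        records, log = run_sandbox(obs)
        assert len(records) == 1 and not log.entries
        rec = records[0]
        assert rec.body_mass_kg == 5.0
        assert rec.vo2_std == 1000.0
        assert math.isclose(rec.mr_mass_specific_w_per_kg, 1000 / 3600 * 20.1)
        assert math.isclose(rec.mr_total_w, rec.mr_mass_specific_w_per_kg * 5.0)
        assert rec.temperature_c == 25.0 and rec.sample_size == 12

    def test_whole_body_without_mass_retained_with_log(self):
        obs = [_obs("metabolic_rate", "40", "mL O2 h-1")]
        records, log = run_sandbox(obs)
        assert len(records) == 1
        assert records[0].mr_total_w is None and records[0].vo2_std is None
        assert log.count("missing_mass") == 1

    def test_malformed_species_logged_not_kept(self):
        records, log = run_sandbox([_obs("body_mass", "5", "kg", species="Mus")])
        assert records == [] and log.count("unparsable") == 1

    def test_every_group_accounted_for(self, default_corpus):
        records, log = run_corpus(default_corpus)
        # groups = gold records + injected duplicates; each is a kept record,
        # a merged duplicate, or traceable to a rejection entry
        n_groups = len(default_corpus.gold_records) + default_corpus.n_duplicates_injected
        assert len(records) + len(log.merges) == n_groups

    def test_determinism(self, lossless_corpus):
        first = run_corpus(lossless_corpus)
        second = run_corpus(lossless_corpus)
        assert [r.trait_signature() for r in first[0]] == [
            r.trait_signature() for r in second[0]
        ]
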