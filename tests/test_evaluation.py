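"""Evaluation metrics: semantic matching, P/R/F1 scoring, t-intervals,
and the repeated-sampling validation protocol."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from darktraits.errors import InsufficientDocuments, InsufficientSamples
from darktraits.evaluation import (
    FieldValue,
    run_validation_protocol,
    score_fields,
    semantic_match,
    t_interval,
)
from darktraits.synthetic import SyntheticSpec, generate_page_corpus


class TestSemanticMatch:
    def test_mass_across_units(self):
        assert semantic_match("5000", "g", "5", "kg", "body_mass")
        assert not semantic_match("5.1", "kg", "5", "kg", "body_mass")

    def test_binomial_canonicalization(self):
        assert semantic_match("mus musculus", "", "Mus musculus", "", "taxonomic")
        assert not semantic_match("Mus domesticus", "", "Mus musculus", "", "taxonomic")

    def test_metabolic_rate_across_dialects(self):
        assert semantic_match("1.0", "cc O2 g-1 hr-1", "1000", "mL O2 kg-1 h-1",
                              "metabolic_rate")

    def test_dimensional_form_mismatch_is_non_match(self):
        # a mass-specific rate never matches a whole-body rate numerically
        assert not semantic_match("60", "mL O2 kg-1 h-1", "60", "mL O2 h-1",
                                  "metabolic_rate")

    def test_temperature_kelvin(self):
        assert semantic_match("298.15", "K", "25", "°C", "temperature")

    def test_unparseable_counts_as_non_match(self):
        assert not semantic_match("n.d.", "g", "5", "kg", "body_mass")
        assert not semantic_match("5", "furlong", "5", "kg", "body_mass")


def _fv(doc, kind, species, value, unit=""):
    return FieldValue(doc, kind, species, value, unit)


class TestScoreFields:
    def test_perfect_predictions(self):
        gold = [
            _fv("d1", "taxonomic", "Mus musculus", "Mus musculus"),
            _fv("d1", "body_mass", "Mus musculus", "21", "g"),
            _fv("d2", "metabolic_rate", "Apus apus", "2.1", "mL O2 g-1 h-1"),
        ]
        report = score_fields(list(gold), gold)
        for score in report.per_field.values():
            assert score.precision == score.recall == score.f1 == 1.0
        assert report.macro_f1 == 1.0

    def test_counts_give_expected_metrics(self):
        gold = [_fv("d1", "body_mass", f"G{i:d} sp", "5", "kg") for i in range(5)]
        preds = [_fv("d1", "body_mass", f"G{i:d} sp", "5", "kg") for i in range(3)]
        preds.append(_fv("d1", "body_mass", "G9 sp", "7", "kg"))  # FP
        report = score_fields(preds, gold)
        s = report.per_field["body_mass"]
        assert (s.tp, s.fp, s.fn) == (3, 1, 2)
        assert s.precision == 0.75 and s.recall == 0.6
        assert s.f1 == pytest.approx(2 / 3)
        assert s.fp_rate_pct == 25.0 and s.fn_rate_pct == 40.0

    def test_empty_predictions_degenerate_case(self):
        gold = [_fv("d1", "body_mass", "Mus musculus", "5", "kg")]
        report = score_fields([], gold)
        s = report.per_field["body_mass"]
        assert s.precision == 0.0 and s.recall == 0.0 and s.f1 == 0.0

    def test_one_to_one_matching_each_gold_used_once(self):
        gold = [_fv("d1", "body_mass", "Mus musculus", "5", "kg")]
        preds = [_fv("d1", "body_mass", "Mus musculus", "5000", "g")] * 2
        s = score_fields(preds, gold).per_field["body_mass"]
        assert (s.tp, s.fp, s.fn) == (1, 1, 0)

    def test_macro_is_unweighted_mean(self):
        gold = (
            [_fv("d1", "taxonomic", f"G{i} sp", f"G{i} sp") for i in range(8)]
            + [_fv("d1", "body_mass", "G0 sp", "5", "kg")]
        )
        preds = [g for g in gold if g.field_kind == "taxonomic"]
        report = score_fields(preds, gold)
        f1s = [report.per_field["taxonomic"].f1, report.per_field["body_mass"].f1]
        assert report.macro_f1 == pytest.approx(sum(f1s) / 2)

    def test_stratum_aggregation(self):
        gold = [
            _fv("d1", "taxonomic", "A a", "A a"),
            _fv("d1", "body_mass", "A a", "5", "kg"),
            _fv("d1", "temperature", "A a", "25", "°C"),
            _fv("d1", "metabolic_rate", "A a", "3", "mL O2 kg-1 h-1"),
        ]
        report = score_fields(list(gold), gold)
        assert set(report.per_stratum) == {"low", "medium", "high"}

    @given(st.integers(0, 6), st.integers(0, 6), st.integers(0, 6))
    @settings(max_examples=40, derandomize=True)
    def test_oracle_equivalence_with_confusion_enumeration(self, n_tp, n_fp, n_fn):
        # brute-force oracle on unambiguous fixtures: shared values are TPs,
        # surplus predictions FPs, unmatched gold FNs
        gold = [_fv("d1", "body_mass", f"S{i:d} sp", str(i + 1), "kg")
                for i in range(n_tp + n_fn)]
        preds = [_fv("d1", "body_mass", f"S{i:d} sp", str(i + 1), "kg")
                 for i in range(n_tp)]
        preds += [_fv("d1", "body_mass", f"X{i:d} sp", "999", "kg")
                  for i in range(n_fp)]
        s = score_fields(preds, gold).per_field.get("body_mass")
        if s is None:
            assert n_tp + n_fp + n_fn == 0
            return
        assert (s.tp, s.fp, s.fn) == (n_tp, n_fp, n_fn)
        p = n_tp / (n_tp + n_fp) if n_tp + n_fp else 0.0
        r = n_tp / (n_tp + n_fn) if n_tp + n_fn else 0.0
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        assert s.precision == p and s.recall == r
        assert s.f1 == pytest.approx(f1)
        assert min(p, r) - 1e-12 <= s.f1 <= max(p, r) + 1e-12


class TestTInterval:
    def test_zero_variance(self):
        assert t_interval([0.9] * 5) == (0.9, 0.9, 0.9)

    def test_hand_computed_half_width(self):
        # sd of {0.9,...,0.98} = sqrt(0.001); t_{0.975,4} = 2.7764451052
        mean, lo, hi = t_interval([0.9, 0.92, 0.94, 0.96, 0.98])
        sd = math.sqrt(0.001)
        half = 2.7764451052 * sd / math.sqrt(5)
        assert mean == pytest.approx(0.94)
        assert hi - mean == pytest.approx(half, rel=1e-9)
        assert mean - lo == pytest.approx(half, rel=1e-9)

    def test_single_value_rejected(self):
        with pytest.raises(InsufficientSamples):
            t_interval([0.5])


@pytest.fixture(scope="module")
def corpus():
    return generate_page_corpus(SyntheticSpec(seed=303))


class TestValidationProtocol:

    def test_perfect_extractor_gives_unit_f1_zero_width_ci(self, corpus):
        report = run_validation_protocol(
            corpus.document_ids, corpus.gold_annotations, corpus.gold_annotations,
            seed=1,
        )
        assert report.macro_f1_ci == (1.0, 1.0, 1.0)

    def test_seed_reproducibility(self, corpus):
        a = run_validation_protocol(corpus.document_ids, corpus.gold_annotations,
                                    corpus.gold_annotations, seed=7)
        b = run_validation_protocol(corpus.document_ids, corpus.gold_annotations,
                                    corpus.gold_annotations, seed=7)
        assert a.macro_f1_ci == b.macro_f1_ci
        assert a.per_field_f1_ci == b.per_field_f1_ci

    def test_targeted_corruption_hits_only_that_field(self, corpus):
        corrupted = []
        n_corrupted = 0
        for p in corpus.gold_annotations:
            if p.field_kind == "body_mass" and n_corrupted < 40:
                corrupted.append(FieldValue(p.document_id, p.field_kind,
                                            p.species, "123456789", p.unit))
                n_corrupted += 1
            else:
                corrupted.append(p)
        report = run_validation_protocol(corpus.document_ids, corrupted,
                                         corpus.gold_annotations, seed=1)
        assert report.per_field_f1_ci["body_mass"][0] < 1.0
        for fieldname in ("taxonomic", "metabolic_rate", "temperature"):
            assert report.per_field_f1_ci[fieldname][0] == 1.0

    def test_insufficient_documents(self, corpus):
        with pytest.raises(InsufficientDocuments):
            run_validation_protocol(corpus.document_ids[:50],
                                    corpus.gold_annotations,
                                    corpus.gold_annotations, seed=1)
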