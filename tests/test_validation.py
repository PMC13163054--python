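"""Validation statistics: species aggregation, binomial matching,
allometric OLS, concordance reports."""

import math

import numpy as np
import pandas as pd
import pytest

from darktraits.errors import InsufficientData
from darktraits.sandbox import StandardizedRecord
from darktraits.synthetic import SyntheticSpec, generate_allometric_records
from darktraits.validation import (
    aggregate_to_species,
    aggregates_to_frame,
    compute_concordance,
    fit_allometry,
    match_binomials,
)

MAMMAL_ONLY = (("Mammalia", 1.0), ("Aves", 0.0), ("Reptilia", 0.0))


def _rec(species, mass=None, brain=None, total=None):
    return StandardizedRecord(
        species_binomial=species,
        body_mass_kg=mass,
        brain_volume_ml=brain,
        mr_total_w=total,
        mr_mass_specific_w_per_kg=None if total is None or mass is None else total / mass,
    )


class TestAggregateToSpecies:
    def test_median_conventions(self):
        records = [_rec("Mus musculus", mass=m) for m in (1.0, 2.0, 10.0)]
        agg = aggregate_to_species(records)
        assert agg[0].traits["body_mass"] == 2.0
        records.append(_rec("Mus musculus", mass=4.0))
        agg = aggregate_to_species(records)
        assert agg[0].traits["body_mass"] == 3.0  # midpoint of (2, 4)

    def test_single_record_is_itself(self):
        agg = aggregate_to_species([_rec("Mus musculus", mass=7.5, brain=0.4)])
        assert agg[0].traits == {"body_mass": 7.5, "brain_volume": 0.4}
        assert agg[0].record_counts == {"body_mass": 1, "brain_volume": 1}

    def test_nonpositive_excluded_before_aggregation(self):
        records = [_rec("Mus musculus", mass=2.0), _rec("Mus musculus", mass=-1.0)]
        agg = aggregate_to_species(records)
        assert agg[0].traits["body_mass"] == 2.0


class TestMatchBinomials:
    def test_whitespace_and_case_insensitive(self):
        shared, malformed = match_binomials(
            ["Mus  musculus ", "MUS MUSCULUS", "Rattus norvegicus"],
            ["Mus musculus"],
        )
        assert shared == ["Mus musculus"] and malformed == 0

    def test_no_synonym_expansion(self):
        shared, _ = match_binomials(["Canis familiaris"], ["Canis lupus"])
        assert shared == []

    def test_malformed_excluded_and_counted(self):
        shared, malformed = match_binomials(["Mus", "Mus musculus"], ["Mus musculus"])
        assert shared == ["Mus musculus"] and malformed == 1


class TestFitAllometry:
    def test_exact_power_law(self):
        records = [_rec("Mus musculus", mass=m, total=2.0 * m**0.75)
                   for m in (0.1, 1.0, 10.0, 100.0)]
        fit = fit_allometry(records, "metabolic_rate")
        assert fit.slope == pytest.approx(0.75, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept_log10 == pytest.approx(math.log10(2.0), abs=1e-12)
        assert fit.n == 4

    def test_insufficient_data(self):
        records = [_rec("A a", mass=1.0, total=2.0), _rec("B b", mass=2.0, total=3.0)]
        with pytest.raises(InsufficientData):
            fit_allometry(records, "metabolic_rate")

    def test_nonpositive_excluded_with_count(self):
        records = [_rec("A a", mass=m, total=2.0 * m**0.75)
                   for m in (0.1, 1.0, 10.0, 100.0)]
        records.append(_rec("Z z", mass=-1.0, total=1.0))
        fit = fit_allometry(records, "metabolic_rate")
        assert fit.n == 4 and fit.n_excluded == 1

    def test_recovers_generating_exponent_under_noise(self):
        spec = SyntheticSpec(seed=11, noise_sd_log10=0.2, class_weights=MAMMAL_ONLY)
        records, params = generate_allometric_records(spec, n_records=500)
        fit = fit_allometry(records, "metabolic_rate")
        assert abs(fit.slope - params["Mammalia"].mr_b) < 0.05

    def test_slope_ci_covers_truth_in_most_replicates(self):
        hits = 0
        n_reps = 100
        for seed in range(n_reps):
            spec = SyntheticSpec(seed=seed, noise_sd_log10=0.2,
                                 class_weights=MAMMAL_ONLY)
            records, params = generate_allometric_records(spec, n_records=120)
            fit = fit_allometry(records, "metabolic_rate")
            lo, hi = fit.slope_ci95()
            hits += lo <= params["Mammalia"].mr_b <= hi
        assert hits >= 90


def _frame(values, species=None):
    species = species or [f"Genus{i:02d} sp{i:02d}" for i in range(len(values))]
    return pd.DataFrame({"binomial": species, "body_mass": values})


class TestConcordance:
    def test_self_comparison_identity(self):
        left = _frame([0.02, 0.3, 1.7, 12.0, 85.0, 410.0])
        rep = compute_concordance(left, left.copy(), "body_mass")
        assert rep.pearson_log10 == pytest.approx(1.0, abs=1e-12)
        assert rep.spearman_log10 == pytest.approx(1.0, abs=1e-12)
        assert rep.median_abs_dlog10 == 0.0
        assert rep.median_fold_difference == 1.0
        assert rep.ols_slope_log10 == pytest.approx(1.0, abs=1e-9)
        assert rep.ols_intercept_log10 == pytest.approx(0.0, abs=1e-9)

    def test_uniform_tenfold_shift(self):
        left = _frame([0.02, 0.3, 1.7, 12.0, 85.0, 410.0])
        right = left.copy()
        right["body_mass"] *= 10.0
        rep = compute_concordance(left, right, "body_mass")
        assert rep.median_abs_dlog10 == pytest.approx(1.0, abs=1e-12)
        assert rep.median_fold_difference == pytest.approx(10.0, rel=1e-12)
        assert rep.ols_slope_log10 == pytest.approx(1.0, abs=1e-9)
        assert rep.ols_intercept_log10 == pytest.approx(-1.0, abs=1e-9)

    def test_fold_difference_identity_on_noisy_report(self):
        rng = np.random.default_rng(4)
        left = _frame(list(10.0 ** rng.uniform(-2, 2, size=12)))
        right = left.copy()
        right["body_mass"] = right["body_mass"] * 10.0 ** rng.normal(0, 0.1, 12)
        rep = compute_concordance(left, right, "body_mass")
        assert rep.median_fold_difference == pytest.approx(
            10.0 ** rep.median_abs_dlog10, rel=1e-9
        )

    def test_correlations_match_first_principles_on_six_species(self):
        # independent oracle: moment/rank formulas written out by hand
        left = _frame([0.5, 2.0, 3.5, 10.0, 40.0, 200.0])
        right = left.copy()
        right["body_mass"] = [0.6, 1.8, 4.0, 9.0, 55.0, 150.0]
        rep = compute_concordance(left, right, "body_mass")

        x = np.log10(left["body_mass"].to_numpy())
        y = np.log10(right["body_mass"].to_numpy())
        pearson = (((x - x.mean()) * (y - y.mean())).sum()
                   / math.sqrt(((x - x.mean()) ** 2).sum()
                               * ((y - y.mean()) ** 2).sum()))

        def ranks(v):
            order = np.argsort(v)
            r = np.empty(len(v))
            r[order] = np.arange(1, len(v) + 1)
            return r

        rx, ry = ranks(x), ranks(y)
        spearman = (((rx - rx.mean()) * (ry - ry.mean())).sum()
                    / math.sqrt(((rx - rx.mean()) ** 2).sum()
                                * ((ry - ry.mean()) ** 2).sum()))
        assert rep.pearson_log10 == pytest.approx(pearson, rel=1e-12)
        assert rep.spearman_log10 == pytest.approx(spearman, rel=1e-12)

    def test_correlation_symmetry(self):
        left = _frame([0.5, 2.0, 3.5, 10.0, 40.0, 200.0])
        right = left.copy()
        right["body_mass"] = [0.6, 1.8, 4.0, 9.0, 55.0, 150.0]
        ab = compute_concordance(left, right, "body_mass")
        ba = compute_concordance(right, left, "body_mass")
        assert ab.pearson_log10 == pytest.approx(ba.pearson_log10, rel=1e-12)
        assert ab.spearman_log10 == pytest.approx(ba.spearman_log10, rel=1e-12)
        assert ab.median_abs_dlog10 == pytest.approx(ba.median_abs_dlog10, rel=1e-12)

    def test_insufficient_shared_species(self):
        left = _frame([1.0, 2.0])
        with pytest.raises(InsufficientData):
            compute_concordance(left, left.copy(), "body_mass")

    def test_aggregates_to_frame_round_trip(self):
        records = [_rec("Mus musculus", mass=2.0), _rec("Rattus norvegicus", mass=0.3)]
        frame = aggregates_to_frame(aggregate_to_species(records), "body_mass")
        assert list(frame["binomial"]) == ["Mus musculus", "Rattus norvegicus"]
        assert list(frame["body_mass"]) == [2.0, 0.3]
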