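"""Biological plausibility and concordance statistics.

Two complementary checks of a standardized trait database:

* **Allometric plausibility** — traits are expected to follow power laws
  Y = a·M^b in body mass M, i.e. straight lines on log–log axes.  OLS of
  log10(Y) on log10(M) recovers the scaling exponent b, the normalization
  log10(a) and R².
* **Concordance against a curated reference** — records are aggregated to
  species level by the median, matched to a reference table by exact
  canonical binomial equality (no synonym expansion), and compared on the
  log10 scale: Pearson and Spearman correlations, the median absolute log10
  difference, its fold-difference equivalent 10^median|Δlog10|, and an OLS
  line of our values on the reference values.

All log-space statistics exclude non-positive values, with counts reported.
No phylogenetic correction is applied: these are descriptive cross-species
checks, not phylogenetically independent contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InsufficientData, MalformedBinomial
from .sandbox import StandardizedRecord, canonicalize_binomial

TRAIT_FIELDS = {
    "metabolic_rate": "mr_total_w",
    "brain_volume": "brain_volume_ml",
    "body_mass": "body_mass_kg",
}


# --------------------------------------------------------------------------
# species-level aggregation and matching
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciesAggregate:
    species_binomial: str
    traits: dict  # trait name -> median value
    record_counts: dict  # trait name -> contributing record count


def aggregate_to_species(
    records: Sequence[StandardizedRecord],
    traits: Sequence[str] = ("body_mass", "brain_volume", "metabolic_rate"),
) -> list[SpeciesAggregate]:
    """Summarize repeated measurements per species by the median
    (midpoint convention for even counts); non-positive values are excluded
    before aggregation."""
    values: dict[str, dict[str, list[float]]] = {}
    order: list[str] = []
    for rec in records:
        sp = rec.species_binomial
        if sp not in values:
            values[sp] = {t: [] for t in traits}
            order.append(sp)
        for trait in traits:
            v = getattr(rec, TRAIT_FIELDS[trait])
            if v is not None and v > 0:
                values[sp][trait].append(v)
    aggregates = []
    for sp in order:
        med = {
            t: float(np.median(vs)) for t, vs in values[sp].items() if vs
        }
        counts = {t: len(vs) for t, vs in values[sp].items() if vs}
        aggregates.append(SpeciesAggregate(sp, med, counts))
    return aggregates


def match_binomials(
    left: Iterable[str], right: Iterable[str]
) -> tuple[list[str], int]:
    """Exact binomial-name intersection under canonical equality.

    Returns the shared canonical names (order of first appearance in
    ``left``) and the count of malformed names excluded.  No synonym
    reconciliation is attempted.
    """
    malformed = 0

    def _canon(names: Iterable[str]) -> list[str]:
        nonlocal malformed
        out = []
        for n in names:
            try:
                out.append(canonicalize_binomial(n))
            except MalformedBinomial:
                malformed += 1
        return out

    left_c = _canon(left)
    right_set = set(_canon(right))
    seen: set[str] = set()
    shared = []
    for name in left_c:
        if name in right_set and name not in seen:
            shared.append(name)
            seen.add(name)
    return shared, malformed


# --------------------------------------------------------------------------
# allometric OLS
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AllometricFit:
    """OLS fit of log10(trait) on log10(body mass): Y = a * M^b."""

    trait: str
    n: int
    slope: float  # exponent b
    intercept_log10: float  # log10 a
    r_squared: float
    slope_stderr: float
    subset_label: str = "all"
    n_excluded: int = 0

    def slope_ci95(self) -> tuple[float, float]:
        half = stats.t.ppf(0.975, self.n - 2) * self.slope_stderr
        return self.slope - half, self.slope + half


def fit_allometry(
    records: Sequence[StandardizedRecord],
    trait: str = "metabolic_rate",
    subset_filter: Optional[Callable[[StandardizedRecord], bool]] = None,
    subset_label: str = "all",
) -> AllometricFit:
    """Estimate the allometric scaling of a trait against body mass by
    ordinary least squares on log–log axes.

    Records lacking a strictly positive mass or trait value are excluded
    (count reported on the fit); fewer than 3 usable records raises
    :class:`InsufficientData`.
    """
    field = TRAIT_FIELDS[trait]
    xs, ys = [], []
    excluded = 0
    for rec in records:
        if subset_filter is not None and not subset_filter(rec):
            continue
        m = rec.body_mass_kg
        y = getattr(rec, field)
        if m is None or y is None or m <= 0 or y <= 0:
            excluded += 1
            continue
        xs.append(np.log10(m))
        ys.append(np.log10(y))
    if len(xs) < 3:
        raise InsufficientData(
            f"{len(xs)} usable records for trait {trait!r}; need >= 3"
        )
    X = sm.add_constant(np.asarray(xs))
    fit = sm.OLS(np.asarray(ys), X).fit()
    return AllometricFit(
        trait=trait,
        n=len(xs),
        slope=float(fit.params[1]),
        intercept_log10=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        slope_stderr=float(fit.bse[1]),
        subset_label=subset_label,
        n_excluded=excluded,
    )


# --------------------------------------------------------------------------
# concordance against a reference table
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ConcordanceReport:
    trait: str
    shared_n: int
    pearson_log10: float
    spearman_log10: float
    median_abs_dlog10: float
    median_fold_difference: float
    ols_slope_log10: float
    ols_intercept_log10: float
    n_excluded_nonpositive: int = 0


def compute_concordance(
    left: pd.DataFrame,
    right: pd.DataFrame,
    trait: str,
) -> ConcordanceReport:
    """Quantify species-level agreement between our aggregates (``left``)
    and a reference table (``right``) for one trait.

    Both frames need columns ``binomial`` and ``trait``; values must already
    be in identical canonical units.  On shared species with both values
    positive: Pearson and Spearman on log10 values, the median |Δlog10|,
    fold difference 10^median|Δlog10|, and OLS of left on right in log10
    space.  Fewer than 3 shared species raises :class:`InsufficientData`.
    """
    lt = left[["binomial", trait]].dropna()
    rt = right[["binomial", trait]].dropna()
    merged = lt.merge(rt, on="binomial", suffixes=("_left", "_right"))
    positive = merged[
        (merged[f"{trait}_left"] > 0) & (merged[f"{trait}_right"] > 0)
    ]
    excluded = len(merged) - len(positive)
    if len(positive) < 3:
        raise InsufficientData(
            f"{len(positive)} shared species with positive {trait!r}; need >= 3"
        )
    lx = np.log10(positive[f"{trait}_left"].to_numpy(dtype=float))
    rx = np.log10(positive[f"{trait}_right"].to_numpy(dtype=float))

    if np.allclose(lx, lx[0]) or np.allclose(rx, rx[0]):
        pearson = spearman = float("nan")
    else:
        pearson = float(stats.pearsonr(lx, rx).statistic)
        spearman = float(stats.spearmanr(lx, rx).statistic)
    median_abs = float(np.median(np.abs(lx - rx)))
    X = sm.add_constant(rx)
    ols = sm.OLS(lx, X).fit()
    return ConcordanceReport(
        trait=trait,
        shared_n=int(len(positive)),
        pearson_log10=pearson,
        spearman_log10=spearman,
        median_abs_dlog10=median_abs,
        median_fold_difference=float(10.0 ** median_abs),
        ols_slope_log10=float(ols.params[1]),
        ols_intercept_log10=float(ols.params[0]),
        n_excluded_nonpositive=excluded,
    )


def aggregates_to_frame(
    aggregates: Sequence[SpeciesAggregate], trait: str
) -> pd.DataFrame:
    """Flatten species aggregates into the two-column frame
    :func:`compute_concordance` consumes."""
    rows = [
        {"binomial": a.species_binomial, trait: a.traits[trait]}
        for a in aggregates
        if trait in a.traits
    ]
    return pd.DataFrame(rows, columns=["binomial", trait])
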