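# Methods

## Scope and model

The package standardizes trait observations extracted from page-structured
documents into a record-level physiological database and validates it. The
core quantitative content is small and fully deterministic:

**Thermodynamic conversion.** Oxygen consumption standardized to the
intermediate metric VO2 (mL O2 kg⁻¹ h⁻¹) converts to metabolic power via
the oxygen caloric equivalent q:

    MR_mass-specific = VO2 / 3600 × q     [W/kg]
    MR_total         = MR_mass-specific × M   [W]

with M body mass in kg and 3600 the hours→seconds coefficient. The default
q = 20.1 J mL⁻¹ O2 is the standard oxycaloric equivalent for mixed-substrate
aerobic metabolism; it is a config key
(`oxygen_caloric_equivalent_j_per_ml`) because some protocols prefer
substrate-specific values (19.6–21.1 J/mL). No temperature correction (Q10
or otherwise) is applied anywhere: records carry their original experimental
temperature instead, as part of the composite primary key.

**Allometric validation.** Traits are modelled as power laws Y = a·M^b,
fitted by OLS of log₁₀(Y) on log₁₀(M). The slope is the scaling exponent b,
the intercept log₁₀(a). These are descriptive cross-species fits; species
are treated as independent points and no phylogenetic regression (PGLS) is
attempted — the fits certify that a database preserves expected large-scale
structure, not comparative-evolutionary estimates.

**Concordance.** Species-level agreement with a curated reference is
measured on log₁₀ values of shared species (exact canonical binomial match,
no synonym reconciliation): Pearson and Spearman correlations, the median
absolute log₁₀ difference and its fold equivalent 10^median|Δlog₁₀|, and an
OLS line of our values on the reference values (that orientation is fixed
and documented here; the reverse regression is obtainable by swapping
arguments).

## Deterministic sandbox rules

*Numeric cleaning* applies in fixed order: unicode minus/whitespace
normalization → parenthetical/bracket removal → "± tail" removal →
thousands-separator removal; the leading numeric token is the point
estimate. Bare ranges ("11.0–14.0") are rejected, not averaged — purity
over recall: an averaged range is not a measurement any author reported.

*Unit parsing* uses a closed token table (shipped as an editable TSV at
`darktraits/data/unit_tokens.tsv`): volume {mL, cc, cm³, mm³, L}, mass
{mg, g, kg}, time {s, min, h/hr/hour, d}, with `/x`, `per x`, `x-1`, `x⁻¹`
all read as negative exponents. An O2 marker routes to oxygen-rate; the
presence of a negative mass dimension decides mass-specific vs whole-body
form. Unknown tokens raise — the parser never guesses, because a silent
wrong factor is worse than a logged rejection. Whole-body rates without a
body mass are retained with metabolic-rate fields empty and a
`missing_mass` log entry (the record's other traits are still valid data).

*Brain size* in mass units converts to volume through a configurable tissue
density, default 1.036 g/mL (fresh vertebrate brain tissue, marginally
denser than water). Temperatures without an explicit K marker are read as
°C, the convention of the historical physiology literature.

*Circuit breaker.* A table is rejected when any header or cell contains one
of the keywords {slope, intercept, regression, exponent, "log a", r2, r²}
as a whole token, or matches the equation shape `Y = a M ^ b`. The keyword
list is config-extensible; whole-token matching prevents false trips on
e.g. species epithets containing a keyword as substring. Rejection is
all-or-nothing per table: regression coefficients indicate the entire table
reports model output, not measurements.

*Physical consistency* collects (never short-circuits) violations:
non-positive mass/volume, negative metabolic rate, temperature outside
[−10, 60] °C, MR_total ≠ MR_mass-specific × M beyond 1e−9 relative, and
mass-specific MR outside [10⁻³, 10³] W/kg. That corridor deliberately
brackets the biological extremes — hummingbird hovering metabolism near
140 W/kg and large-ectotherm minima near 0.05 W/kg — with an order of
magnitude of margin on each side, so genuine outliers are never filtered.
Records with violations are logged and dropped.

*Deduplication.* The composite primary key is (species binomial,
experimental temperature rounded to a 0.1 °C grid; records with no
temperature form their own stratum). Records merge only when they share the
key *and* every standardized value agrees to 1e−9 relative; the first
occurrence wins and the merge is logged. Same-key records with differing
values are distinct measurements and are all retained.

## Page pipeline

Pages are extracted concurrently (thread pool, configurable width k) but the
result is contractually a pure function of (pages, extractor, template):
outputs are keyed and ordered by page index, never by completion order.
Malformed page outputs are retried up to 2 times under the same
schema-constrained settings, then emitted flagged. Reconstruction
concatenates blocks in strict (page, block) order and rejects duplicate or
missing page indices.

Cross-page table merging is conservative: the last block of page *i* and
the first of page *i+1* merge iff both are tables with equal column counts
and the continuation either has no header row or repeats the previous
header verbatim (the repeat is dropped). Everything else stays separate
with the reason logged. The rule is associative over runs of three or more
pages, idempotent, and conserves non-header cell counts. Treating a
verbatim-repeated header as continuation is a design choice: repeated
headers are the dominant historical convention for "table continued",
while a *changed* header signals a new table.

## Evaluation metrics

Predicted field values match gold under semantic and dimensional equality:
numeric fields compare after conversion to canonical units at 1e−6 relative
tolerance (so 5000 g ≡ 5 kg, and `cc O2 g⁻¹ hr⁻¹` ≡ ×1000 in
mL O2 kg⁻¹ h⁻¹); a mass-specific rate never matches a whole-body rate;
species names compare after binomial canonicalization. Matching is
one-to-one and greedy in document order, each gold instance creditable
once. Precision = TP/(TP+FP) with the zero-denominator case reported as 0
so macro averages stay defined; F1 = 2PR/(P+R); macro metrics are
unweighted means over fields. Complexity strata follow a fixed field map —
taxonomic entities low; body mass and temperature medium; normalized
metabolic rate high — and FP/FN rates are reported per stratum as
percentages. Confidence intervals are t-based across repeated disjoint
document samples (default 5 samples of 20 documents, seeded):
mean ± t₀.₉₇₅,ₙ₋₁ · sd/√n with the n−1 sample standard deviation,
computed over per-sample metric values (not pooled counts). Inter-annotator
agreement statistics are out of scope: there is no second annotator in a
synthetic-gold design.

## Synthetic corpus generator

The generator emulates the features of the historical record that the
pipeline must survive, with defaults chosen once as realistic study
conditions:

- masses log-uniform over 0.001–500 kg (gram-scale amphibians to
  hundred-kilogram reptiles);
- per-class power laws: metabolic exponent b = 0.67 (surface-area
  expectation) with normalizations 3.4 / 3.9 / 0.15 W at 1 kg for
  Mammalia / Aves / Reptilia (endotherm–ectotherm contrast), and brain–body
  exponent b = 0.75 with class-specific normalizations — defaults, not
  claims about truth;
- lognormal trait noise, sd 0.2 in log₁₀ (typical residual spread of
  cross-species allometries);
- unit dialect mixtures over five metabolic-rate forms (including two
  whole-body forms), three mass units and four brain-size units;
- annotation noise (ranges, ± tails, "n.s.") at rate 0.2, exact duplicates
  at 0.05, regression-coefficient tables at 0.1, cross-page table splits at
  0.3, temperature present in 70% of records (exercising both composite-key
  strata);
- 110 documents × 3 records by default, sized to support the 5×20
  validation-sampling protocol.

Raw cell values are rounded to 6 significant digits *first* and gold
standardized values are derived from the rounded strings with the same
canonical conversion arithmetic the sandbox defines, so the lossless limit
(all rates and noise at zero) demands bitwise equality between pipeline
output and gold. The generator emulates unit/notation heterogeneity and
table topology; it does not emulate OCR character noise, layout detection
errors, or taxonomic synonymy drift — passing tests therefore certify the
deterministic standardization and validation machinery, not the perception
quality of any real extraction backend.

The synthetic reference table emulates a curated species-level comparator:
per-species medians, stored in curated-database conventions (mass in grams,
BMR as whole-body mL O2 h⁻¹) with explicit unit columns, optionally
perturbed by 10^Normal(0, sd) and thinned by seeded dropout; harmonization
back to kg and W goes through the same unit engine and oxycaloric
equivalent as the pipeline itself.

## Numerical choices and limitations

- All statistics use log₁₀ (the reporting convention of the field);
  non-positive values are excluded from log-space computations with counts
  carried on the result objects.
- Spearman ties use average ranks (scipy default).
- Float equality for dedup and the MR identity uses 1e−9 relative
  tolerance; semantic matching uses 1e−6 (annotated gold values are printed
  at finite precision).
- OLS fits need ≥3 points; concordance needs ≥3 shared species; t-intervals
  need ≥2 samples — all enforced with typed errors rather than NaN returns.
- CSV exports are UTF-8-SIG with fixed column order and %.12g float
  formatting, making repeated runs byte-identical.
- The scripted extractor replays serialized page blocks; integrating a real
  vision backend means implementing the one-callable `ExtractorContract`.
  Nothing in this package performs OCR, rasterization or model inference.
- Problem sizes in the test and acceptance runs (tens to ~110 documents,
  500-record fits, 100 replicate seeds) were chosen as the smallest sizes at
  which the statistical checks are stable; all generators scale to larger
  corpora by changing the spec.
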