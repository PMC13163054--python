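"""Pipeline configuration.

All deterministic constants of the verification sandbox live here so a run is
a pure function of (inputs, config, seed).  The defaults encode the standard
physiological conventions: the oxygen caloric equivalent of 20.1 J per mL O2
used to convert respirometry into power, a brain tissue density of
1.036 g/mL for mass-to-volume normalization, and a [-10, 60] degC corridor of
plausible experimental temperatures.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
#: keywords whose presence in a table header or cell marks the table as
#: reporting regression-derived quantities rather than empirical measurements
DEFAULT_CIRCUIT_BREAKER_KEYWORDS: tuple[str, ...] = (
    "slope",
    "intercept",
    "regression",
    "exponent",
    "log a",
    "r2",
    "r²",
)


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable constants of the deterministic sandbox.

    Parameters
    ----------
    oxygen_caloric_equivalent_j_per_ml : float
        Energy released per mL O2 consumed, J/mL. 20.1 is the standard
        oxycaloric equivalent for mixed substrate metabolism.
    brain_density_g_per_ml : float
        Tissue density used to convert brain masses into volumes.
    mr_plausible_w_per_kg : (float, float)
        Plausibility corridor for mass-specific metabolic rate, W/kg.  Wide
        enough to keep hummingbird maxima (~142.5 W/kg) and reptilian minima
        (~0.05 W/kg) with margin on both sides.
    temperature_bounds_c : (float, float)
        Acceptable experimental temperature range, degC.
    temperature_round_c : float
        Rounding grid applied to temperature when forming the composite
        record key (species, temperature).
    circuit_breaker_keywords : sequence of str
        Case-insensitive keywords triggering regression-table rejection;
        extensible via config files.
    concurrency : int
        Worker threads for page-parallel extraction.  The result is
        contractually independent of this value.
    max_retries : int
        Times a malformed page extraction is re-attempted before being
        emitted with ``malformed=True``.
    """

    oxygen_caloric_equivalent_j_per_ml: float = 20.1
    brain_density_g_per_ml: float = 1.036
    mr_plausible_w_per_kg: tuple[float, float] = (1e-3, 1e3)
    temperature_bounds_c: tuple[float, float] = (-10.0, 60.0)
    temperature_round_c: float = 0.1
    circuit_breaker_keywords: tuple[str, ...] = DEFAULT_CIRCUIT_BREAKER_KEYWORDS
    concurrency: int = 4
    max_retries: int = 2
    raster_dpi: int = 300

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load overrides from a JSON config file (unknown keys rejected)."""
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("mr_plausible_w_per_kg", "temperature_bounds_c",
                    "circuit_breaker_keywords"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(data, indent=2), encoding="utf-8")


DEFAULT_CONFIG = PipelineConfig()
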