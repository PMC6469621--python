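"""Temporal decline of tissue residues against historical baselines.

With only a handful of historical survey points per species, decline is
expressed as a simple average rate rather than a fitted curve.  The
default metric is the linear percent-of-baseline rate

    100 × (c₀ − c_t) / c₀ / years,

i.e. the total fractional loss spread evenly over the interval.  An
exponential (constant relative loss per year) rate is also provided for
comparison:

    100 × (1 − (c_t/c₀)^(1/years)).
"""

from __future__ import annotations

from dataclasses import dataclass

from .concentrations import DomainError


@dataclass(frozen=True)
class TrendPoint:
    """One historical concentration, mg/kg lipid weight."""

    year_label: str
    concentration: float

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise DomainError("concentration must be non-negative")


def annual_decline_percent(c0: float, ct: float, years: float) -> float:
    """Average linear decline, percent of baseline per year.

    Negative results indicate an increase.  Complete disappearance over
    ``years`` gives 100/years.
    """
    if c0 <= 0:
        raise DomainError("baseline concentration must be positive")
    if years <= 0:
        raise DomainError("interval must be positive")
    return 100.0 * (c0 - ct) / c0 / years


def exponential_decline_percent(c0: float, ct: float, years: float) -> float:
    """Constant relative (log-linear) decline, percent per year."""
    if c0 <= 0 or ct <= 0:
        raise DomainError("concentrations must be positive")
    if years <= 0:
        raise DomainError("interval must be positive")
    return 100.0 * (1.0 - (ct / c0) ** (1.0 / years))


def ng_per_g_to_mg_per_kg(conc_ng_per_g: float) -> float:
    """Unit bridge ng/g → mg/kg (÷1000), keeping unit provenance explicit."""
    if conc_ng_per_g < 0:
        raise DomainError("concentration must be non-negative")
    return conc_ng_per_g / 1000.0
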