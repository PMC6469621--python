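"""Scenario-based dietary exposure: estimated weekly intake (EWI) and
comparison with the tolerable weekly intake (TWI).

The estimated weekly intake of a contaminant from game-bird tissue is

    EWI = c_ww × portion × meals_per_year / 52 / body_weight,

per kg body weight per week, where ``c_ww`` is the wet-weight tissue
level.  The default consumer classes follow a game-consumption survey
convention: adults of 70 kg and children of 23 kg; meat portions of
200 g (adult) and 100 g (child); liver portions of 120 g and 60 g;
consumption frequencies of 24 (frequent), 6 (periodic) and 2
(occasional) meals per year.

dl-PCB intakes (pg-TEQ/kg bw/week) are additionally expressed as a
percentage of the TWI of 14 pg-TEQ/kg bw/week.  No TWI exists for the
indicator-PCB sum, so Σi-PCB intakes carry no such percentage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .concentrations import ConfigurationError, DomainError
from .teq import LimitRegistry

WEEKS_PER_YEAR = 52.0

#: Default consumption frequencies, meals per year.
FREQUENCIES = {"frequent": 24, "periodic": 6, "occasional": 2}


@dataclass(frozen=True)
class ExposureScenario:
    """One consumer class: frequency, portion sizes and body weight."""

    label: str
    meals_per_year: int
    portion_g: Mapping[str, float]
    body_weight_kg: float

    def __post_init__(self) -> None:
        if self.meals_per_year <= 0:
            raise DomainError("meals_per_year must be positive")
        if self.body_weight_kg <= 0:
            raise DomainError("body_weight_kg must be positive")
        for organ, grams in self.portion_g.items():
            if grams <= 0:
                raise DomainError(f"portion for {organ!r} must be positive")


#: Adult/child portion maps, grams per meal.
ADULT_PORTIONS = {"muscle": 200.0, "liver": 120.0}
CHILD_PORTIONS = {"muscle": 100.0, "liver": 60.0}


def default_scenarios() -> list[ExposureScenario]:
    """The six default consumer classes (3 frequencies × adult/child)."""
    out = []
    for freq_label, meals in FREQUENCIES.items():
        out.append(
            ExposureScenario(
                label=f"{freq_label}_adult",
                meals_per_year=meals,
                portion_g=dict(ADULT_PORTIONS),
                body_weight_kg=70.0,
            )
        )
        out.append(
            ExposureScenario(
                label=f"{freq_label}_child",
                meals_per_year=meals,
                portion_g=dict(CHILD_PORTIONS),
                body_weight_kg=23.0,
            )
        )
    return out


def weekly_intake(
    conc_ww: float, scenario: ExposureScenario, organ: str
) -> float:
    """Estimated weekly intake per kg body weight under one scenario.

    ``conc_ww`` is the wet-weight tissue level per gram (ng/g for Σi-PCB,
    pg-TEQ/g for dl-PCBs); the result carries the same mass unit per kg
    bw per week.
    """
    if conc_ww < 0:
        raise DomainError("concentration must be non-negative")
    try:
        portion = scenario.portion_g[organ]
    except KeyError:
        raise ConfigurationError(
            f"scenario {scenario.label!r} has no portion for organ {organ!r}"
        ) from None
    return (
        conc_ww * portion * scenario.meals_per_year
        / WEEKS_PER_YEAR / scenario.body_weight_kg
    )


def percent_of_twi(
    ewi_teq: float, limits: LimitRegistry | None = None
) -> float:
    """A dl-PCB TEQ weekly intake as a percentage of the TWI."""
    if ewi_teq < 0:
        raise DomainError("intake must be non-negative")
    limits = limits or LimitRegistry()
    return 100.0 * ewi_teq / limits.twi


@dataclass(frozen=True)
class IntakeResult:
    """One EWI cell; ``pct_of_twi`` is present only for TEQ intakes."""

    species: str
    organ: str
    percentile: str
    scenario: str
    analyte: str
    level_ww: float
    ewi: float
    pct_of_twi: float | None = None


def intake_table(
    levels: Mapping[tuple[str, str, str], float],
    scenarios: Sequence[ExposureScenario] | None = None,
    analyte: str = "sum_ipcb",
    limits: LimitRegistry | None = None,
) -> pd.DataFrame:
    """Full cross of tissue levels × consumption scenarios.

    ``levels`` maps ``(species, organ, percentile_label)`` to a wet-weight
    level (ng/g for ``analyte="sum_ipcb"``, pg-TEQ/g for
    ``analyte="dl_teq"``).  TEQ rows are annotated with their percentage
    of the TWI; Σi-PCB rows have no such column value (no TWI exists).
    """
    if scenarios is None:
        scenarios = default_scenarios()
    results = []
    for (species, organ, percentile), level in levels.items():
        for scenario in scenarios:
            ewi = weekly_intake(level, scenario, organ)
            pct = percent_of_twi(ewi, limits) if analyte == "dl_teq" else None
            results.append(
                IntakeResult(
                    species=species,
                    organ=organ,
                    percentile=percentile,
                    scenario=scenario.label,
                    analyte=analyte,
                    level_ww=level,
                    ewi=ewi,
                    pct_of_twi=pct,
                )
            )
    columns = [
        "species", "organ", "percentile", "scenario", "analyte",
        "level_ww", "ewi", "pct_of_twi",
    ]
    if not results:
        df = pd.DataFrame(columns=columns)
    else:
        df = pd.DataFrame([r.__dict__ for r in results], columns=columns)
    # absent %TWI (sum_ipcb rows) is NaN, keeping the column numeric
    df["pct_of_twi"] = pd.to_numeric(df["pct_of_twi"])
    return df
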