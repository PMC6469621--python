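"""Analytical quality control: recovery against certified reference material.

Recovery is the obtained concentration as a percentage of the certified
value, 100 × obtained / certified, conventionally reported to one
decimal.  Measured sample concentrations are analysed uncorrected — a
recovery below 100% means reported residues are underestimates — but a
correction helper (division by recovery/100) is provided for sensitivity
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .concentrations import DomainError
from .records import check_congener


def recovery_percent(
    obtained: float, certified: float, ndigits: int | None = 1
) -> float:
    """Recovery of an analyte from reference material, percent.

    Rounded to ``ndigits`` decimals (1 by convention); pass ``None`` for
    the unrounded value.
    """
    if certified <= 0:
        raise DomainError("certified concentration must be positive")
    if obtained < 0:
        raise DomainError("obtained concentration must be non-negative")
    pct = 100.0 * obtained / certified
    return pct if ndigits is None else round(pct, ndigits)


@dataclass(frozen=True)
class ReferenceComparison:
    """One congener's certified vs obtained concentration, ng/g ww."""

    congener: int
    certified: float
    obtained: float

    def __post_init__(self) -> None:
        check_congener(self.congener)
        if self.certified <= 0:
            raise DomainError("certified concentration must be positive")
        if self.obtained < 0:
            raise DomainError("obtained concentration must be non-negative")

    @property
    def recovery(self) -> float:
        """Recovery percent, one-decimal convention."""
        return recovery_percent(self.obtained, self.certified)


def recovery_range(
    comparisons: Sequence[ReferenceComparison],
) -> tuple[float, float]:
    """(minimum, maximum) recovery percent over a set of comparisons."""
    if not comparisons:
        raise DomainError("recovery_range requires at least one comparison")
    recs = [c.recovery for c in comparisons]
    return (min(recs), max(recs))


def correct_for_recovery(concentration: float, recovery_pct: float) -> float:
    """Scale a measured concentration up/down by its analytical recovery.

    Off by default in the pipeline: regulatory comparisons use uncorrected
    values.
    """
    if recovery_pct <= 0:
        raise DomainError("recovery percent must be positive")
    if concentration < 0:
        raise DomainError("concentration must be non-negative")
    return concentration / (recovery_pct / 100.0)


def reference_comparisons_from_fixture(
    fixture: dict[int, tuple[float, float, float]] | None = None,
) -> list[ReferenceComparison]:
    """Build comparisons from the packaged SRM 1946 validation rows."""
    from .refdata import SRM1946_RECOVERY

    fixture = fixture if fixture is not None else SRM1946_RECOVERY
    return [
        ReferenceComparison(congener=c, certified=cert, obtained=obt)
        for c, (cert, obt, _printed) in sorted(fixture.items())
    ]
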