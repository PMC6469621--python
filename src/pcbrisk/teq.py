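"""TEF-weighted toxic equivalents and regulatory maximum-level comparison.

The toxic equivalent (TEQ) of a dioxin-like PCB mixture is the
TEF-weighted sum of congener concentrations, TEQ = Σ cᵢ·TEFᵢ, expressed
in pg-TEQ/g.  TEFs default to the WHO-2005 consensus values.  Regulatory
ceilings default to the EU maxima for food of animal origin: 40 ng/g fat
for the indicator-PCB sum, a 1.25–4 pg-TEQ/g fat range for meat (the
level depends on the animal category), 10 pg/g for liver, and the
tolerable weekly intake of 14 pg-TEQ/kg body weight for dl-PCBs.

Concentrations enter TEQ computation in pg/g; :func:`ng_to_pg` bridges
from the ng/g used elsewhere in the package (1 ng = 1000 pg).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .concentrations import DomainError
from .records import ValidationError
from .refdata import WHO2005_TEF


@dataclass(frozen=True)
class TEFRegistry:
    """Versioned congener → toxic equivalency factor map."""

    version: str = "WHO-2005"
    tef: Mapping[int, float] = field(default_factory=lambda: dict(WHO2005_TEF))

    def __post_init__(self) -> None:
        for congener, value in self.tef.items():
            if not 0 < value <= 1:
                raise ValidationError(
                    f"TEF for PCB {congener} outside (0, 1]: {value}"
                )

    def __getitem__(self, congener: int) -> float:
        try:
            return self.tef[congener]
        except KeyError:
            raise ValidationError(
                f"no TEF for PCB {congener} in registry {self.version!r}"
            ) from None


@dataclass(frozen=True)
class LimitRegistry:
    """Regulatory maxima for PCBs in food of animal origin.

    ``mrl_sum_ipcb`` in ng/g fat; TEQ maximum levels in pg-TEQ/g; ``twi``
    in pg-TEQ/kg body weight per week.
    """

    mrl_sum_ipcb: float = 40.0
    ml_teq_meat: tuple[float, float] = (1.25, 4.0)
    ml_teq_liver: float = 10.0
    twi: float = 14.0

    def __post_init__(self) -> None:
        lo, hi = self.ml_teq_meat
        if not 0 < lo <= hi:
            raise ValidationError(f"invalid TEQ ML interval {self.ml_teq_meat}")
        for name in ("mrl_sum_ipcb", "ml_teq_liver", "twi"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


def ng_to_pg(value_ng: float) -> float:
    """Unit bridge ng/g → pg/g (×1000)."""
    return value_ng * 1000.0


def compute_teq(
    concs_pg: Mapping[int, float], registry: TEFRegistry | None = None
) -> float:
    """TEF-weighted sum Σ cᵢ·TEFᵢ of a congener mixture, pg-TEQ/g.

    ``concs_pg`` must be in pg/g; every congener present must have a TEF
    in the registry.  The result is on the same (ww or lw) basis as the
    input, which the caller tracks.
    """
    registry = registry or TEFRegistry()
    return float(sum(c * registry[congener] for congener, c in concs_pg.items()))


def percent_of_limit(value: float, limit):
    """Value as a percentage of a scalar limit or of a limit interval.

    For an interval ``(lo, hi)`` returns ``(100·value/hi, 100·value/lo)``
    — the smaller share against the looser ceiling first — so the output
    is always ordered low ≤ high.
    """
    if isinstance(limit, (tuple, list)):
        lo, hi = limit
        if lo <= 0 or hi <= 0:
            raise DomainError("limit bounds must be positive")
        return (100.0 * value / hi, 100.0 * value / lo)
    if limit <= 0:
        raise DomainError("limit must be positive")
    return 100.0 * value / limit


def format_percent_range(pct: tuple[float, float]) -> str:
    """Integer-rounded presentation of a percent interval, e.g. ``8–25%``."""
    lo, hi = pct
    return f"{_round_half_up(lo)}–{_round_half_up(hi)}%"


def _round_half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))


def exceeds_limit(value: float, limit: float) -> bool:
    """True iff ``value`` strictly exceeds a maximum level.

    A value equal to the ceiling is compliant (the limits are maximum
    levels, not action thresholds).
    """
    if limit <= 0:
        raise DomainError("limit must be positive")
    return value > limit


def percent_below_limit(values: Sequence[float], limit: float) -> float:
    """Share (percent) of per-sample values at or below a maximum level."""
    if limit <= 0:
        raise DomainError("limit must be positive")
    if len(values) == 0:
        raise DomainError("no values supplied")
    compliant = sum(1 for v in values if not exceeds_limit(v, limit))
    return 100.0 * compliant / len(values)
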