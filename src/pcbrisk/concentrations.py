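"""Basis conversion, indicator-PCB aggregation, homolog profiling and
censored summary statistics.

Residue concentrations are reported either per gram of wet tissue (ww) or
per gram of extractable lipid (lw); the two are linked by the tissue lipid
mass fraction.  When a sample-specific lipid fraction was not measured,
conversion falls back on typical lipid contents of wild-bird tissue —
1.5% for muscle, 5% for liver and 30% for adipose tissue — whose
integer-rounded reciprocals are the conventional ww→lw factors 67, 20
and 3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .records import INDICATOR_CONGENERS, MeasurementRecord, ValidationError, check_congener

#: Typical lipid mass fraction of wild-bird tissue, by tissue type.
DEFAULT_LIPID_FRACTIONS = {"muscle": 0.015, "liver": 0.05, "fat": 0.30}

# Ballschmiter–Zell numbering assigns congeners in blocks of increasing
# chlorine count; each entry is (first congener number, chlorine count).
_HOMOLOG_BLOCKS = (
    (1, 1),    # 1-3    mono
    (4, 2),    # 4-15   di
    (16, 3),   # 16-39  tri
    (40, 4),   # 40-81  tetra
    (82, 5),   # 82-127 penta
    (128, 6),  # 128-169 hexa
    (170, 7),  # 170-193 hepta
    (194, 8),  # 194-205 octa
    (206, 9),  # 206-208 nona
    (209, 10), # 209    deca
)


class DomainError(ValueError):
    """Input outside the mathematical domain of an operation."""


class ConfigurationError(ValueError):
    """Missing or inconsistent conversion configuration."""


@dataclass(frozen=True)
class BasisConversion:
    """Wet-weight ↔ lipid-weight conversion settings.

    ``integer_factors`` reproduces the conventional rounded factors
    (67, 20, 3) when a record has no measured lipid fraction; with the
    flag off the exact reciprocals of the default fractions are used.
    """

    default_lipid_fraction: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LIPID_FRACTIONS)
    )
    integer_factors: bool = True

    def __post_init__(self) -> None:
        for tissue, f in self.default_lipid_fraction.items():
            if not 0 < f <= 1:
                raise ConfigurationError(
                    f"default lipid fraction for {tissue!r} outside (0, 1]: {f}"
                )

    def factor(self, tissue: str) -> float:
        """ww→lw multiplication factor for a tissue's default lipid content."""
        try:
            frac = self.default_lipid_fraction[tissue]
        except KeyError:
            raise ConfigurationError(
                f"no default lipid fraction for tissue {tissue!r}"
            ) from None
        return round(1.0 / frac) if self.integer_factors else 1.0 / frac


def to_lipid_basis(
    record: MeasurementRecord, conv: BasisConversion | None = None
) -> MeasurementRecord:
    """Convert a wet-weight record to the lipid-weight basis.

    Divides by the record's own lipid fraction when measured, otherwise
    multiplies by the tissue default factor of ``conv``.
    """
    if record.basis != "wet_weight":
        raise ValidationError(f"record already on basis {record.basis!r}")
    if record.lipid_fraction is not None:
        if record.lipid_fraction == 0:
            raise DomainError("lipid_fraction must be positive")
        value = record.concentration / record.lipid_fraction
    else:
        conv = conv or BasisConversion()
        value = record.concentration * conv.factor(record.tissue)
    return replace(record, concentration=value, basis="lipid_weight")


def to_wet_basis(
    record: MeasurementRecord, conv: BasisConversion | None = None
) -> MeasurementRecord:
    """Inverse of :func:`to_lipid_basis`."""
    if record.basis != "lipid_weight":
        raise ValidationError(f"record already on basis {record.basis!r}")
    if record.lipid_fraction is not None:
        if record.lipid_fraction == 0:
            raise DomainError("lipid_fraction must be positive")
        value = record.concentration * record.lipid_fraction
    else:
        conv = conv or BasisConversion()
        value = record.concentration / conv.factor(record.tissue)
    return replace(record, concentration=value, basis="wet_weight")


def sum_indicator(
    concs: Mapping[int, float], allow_missing: bool = False
) -> float:
    """Sum of the six indicator congeners (28, 52, 101, 138, 153, 180).

    PCB 118 and any other congener present in ``concs`` are excluded.
    Unless ``allow_missing``, all six must be present.
    """
    missing = sorted(INDICATOR_CONGENERS - set(concs))
    if missing and not allow_missing:
        raise ValidationError(f"missing indicator congeners: {missing}")
    return float(sum(concs[c] for c in INDICATOR_CONGENERS if c in concs))


def homolog_of(congener: int) -> int:
    """Chlorine count (1–10) of a congener per Ballschmiter–Zell numbering."""
    n = check_congener(congener)
    count = 1
    for start, chlorines in _HOMOLOG_BLOCKS:
        if n >= start:
            count = chlorines
    return count


def homolog_profile(
    records: Iterable[MeasurementRecord],
) -> dict[int, float]:
    """Total concentration per homolog (chlorine-count) class.

    All records must share one basis; classes absent from the input map
    to 0, so the result always has keys 1–10 and its total equals the
    total of the input concentrations.
    """
    profile = {k: 0.0 for k in range(1, 11)}
    basis = None
    for r in records:
        if basis is None:
            basis = r.basis
        elif r.basis != basis:
            raise ValidationError("mixed bases in homolog profile input")
        profile[homolog_of(r.congener)] += r.concentration
    return profile


@dataclass(frozen=True)
class SummaryStats:
    """n, mean, sample sd (n−1), min, max and selected percentiles."""

    n: int
    mean: float
    sd: float
    min: float
    max: float
    percentiles: dict[float, float] = field(default_factory=dict)


def summarize(
    values: Sequence[float], percentile_ps: Sequence[float] = (50.0, 97.5)
) -> SummaryStats:
    """Summary statistics of a sample of concentrations.

    Percentiles use linear interpolation between closest order statistics
    (position p(n−1)/100 + 1).  The sample sd uses the n−1 denominator and
    is NaN for a single observation.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise DomainError("summarize requires at least one value")
    if np.isnan(arr).any():
        raise DomainError(
            "NaN concentration present; apply a censoring substitution first"
        )
    pct = {
        float(p): float(np.percentile(arr, p, method="linear"))
        for p in percentile_ps
    }
    return SummaryStats(
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else math.nan,
        min=float(arr.min()),
        max=float(arr.max()),
        percentiles=pct,
    )


def summary_table(
    records: Sequence[MeasurementRecord],
    percentile_ps: Sequence[float] = (50.0, 97.5),
):
    """Per-(species, tissue, congener) summary plus indicator sums.

    Returns a tidy :class:`pandas.DataFrame` with one row per congener and
    one ``sum_iPCB`` row per (species, tissue) built from per-bird sums of
    the six indicator congeners (missing congeners counted as zero).
    All records must share one basis.
    """
    import pandas as pd

    if not records:
        return pd.DataFrame(
            columns=["species", "tissue", "congener", "basis", "n", "mean",
                     "sd", "min", "max"]
            + [f"P{p:g}" for p in percentile_ps]
        )
    bases = {r.basis for r in records}
    if len(bases) > 1:
        raise ValidationError("mixed bases in summary input")
    basis = bases.pop()

    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "species": [r.species for r in records],
            "tissue": [r.tissue for r in records],
            "congener": [r.congener for r in records],
            "concentration": [r.concentration for r in records],
        }
    )
    rows = []
    for (species, tissue, congener), grp in df.groupby(
        ["species", "tissue", "congener"], sort=True
    ):
        rows.append(
            _summary_row(species, tissue, str(congener), basis,
                         grp["concentration"].tolist(), percentile_ps)
        )
    # per-bird indicator sums
    ind = df[df["congener"].isin(INDICATOR_CONGENERS)]
    for (species, tissue), grp in ind.groupby(["species", "tissue"], sort=True):
        per_bird = grp.groupby("sample_id")["concentration"].sum()
        rows.append(
            _summary_row(species, tissue, "sum_iPCB", basis,
                         per_bird.tolist(), percentile_ps)
        )
    return pd.DataFrame(rows)


def _summary_row(species, tissue, congener, basis, values, percentile_ps):
    s = summarize(values, percentile_ps)
    row = {
        "species": species,
        "tissue": tissue,
        "congener": congener,
        "basis": basis,
        "n": s.n,
        "mean": s.mean,
        "sd": s.sd,
        "min": s.min,
        "max": s.max,
    }
    for p in percentile_ps:
        row[f"P{p:g}"] = s.percentiles[float(p)]
    return row
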