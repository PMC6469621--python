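"""Data model and I/O for censored congener concentration measurements.

A measurement is one congener concentration in one tissue of one bird.
Concentrations are stored in ng/g throughout on either a wet-weight or a
lipid-weight basis.  Values below the limit of quantification (LOQ) are
left-censored: they carry ``censored=True`` and, until a substitution
policy is applied, a NaN concentration.

The canonical interchange format is a tidy CSV with one row per congener
measurement and columns ``sample_id, species, tissue, congener,
concentration, basis, lipid_fraction, censored`` (UTF-8, "." decimal
separator).  Censored concentrations round-trip through the sentinel token
``<LOQ`` when still unsubstituted.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

SPECIES = ("common_goldeneye", "tufted_duck", "common_pochard", "greater_scaup")
TISSUES = ("muscle", "liver", "fat")
BASES = ("wet_weight", "lipid_weight")

#: The six non-dioxin-like indicator congeners of EU food regulation.
INDICATOR_CONGENERS = frozenset({28, 52, 101, 138, 153, 180})
#: Dioxin-like congeners analysed in the sea-duck survey.
DIOXIN_LIKE_CONGENERS = frozenset({77, 114, 118, 126, 156, 157, 169})

#: Sentinel token for a below-LOQ cell in CSV input.
LOQ_SENTINEL = "<LOQ"

CSV_COLUMNS = (
    "sample_id",
    "species",
    "tissue",
    "congener",
    "concentration",
    "basis",
    "lipid_fraction",
    "censored",
)


class SchemaError(ValueError):
    """A required column is absent from the input file."""


class ValidationError(ValueError):
    """A row violates the measurement-record invariants."""


def check_congener(number: int) -> int:
    """Validate a Ballschmiter–Zell PCB congener number (1–209)."""
    n = int(number)
    if not 1 <= n <= 209:
        raise ValidationError(f"congener number {number!r} outside 1-209")
    return n


@dataclass(frozen=True)
class MeasurementRecord:
    """One congener concentration in one tissue of one bird.

    ``concentration`` is ng/g on the basis given by ``basis``.  For a
    censored record the stored concentration is NaN until a
    :class:`LOQPolicy` substitution has been applied.  ``lipid_fraction``
    is the measured lipid mass fraction of the tissue aliquot, in (0, 1],
    or ``None`` when not determined.
    """

    sample_id: str
    species: str
    tissue: str
    congener: int
    concentration: float
    basis: str = "wet_weight"
    lipid_fraction: float | None = None
    censored: bool = False

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValidationError(f"unknown species {self.species!r}")
        if self.tissue not in TISSUES:
            raise ValidationError(f"unknown tissue {self.tissue!r}")
        if self.basis not in BASES:
            raise ValidationError(f"unknown basis {self.basis!r}")
        check_congener(self.congener)
        if not math.isnan(self.concentration) and self.concentration < 0:
            raise ValidationError(
                f"negative concentration {self.concentration} "
                f"for sample {self.sample_id!r}"
            )
        if self.lipid_fraction is not None and not 0 < self.lipid_fraction <= 1:
            raise ValidationError(
                f"lipid_fraction {self.lipid_fraction} outside (0, 1]"
            )


@dataclass(frozen=True)
class LOQPolicy:
    """Limit of quantification and the substitution rule for censored values.

    The survey LOQ is 0.02 ng/g wet weight.  ``substitution`` is one of
    ``zero`` (default; consistent with published minima of 0.00),
    ``half_loq`` and ``loq`` — the three conventional single-value
    imputation rules for left-censored residue data.
    """

    loq: float = 0.02
    substitution: str = "zero"

    _VALID = ("zero", "half_loq", "loq")

    def __post_init__(self) -> None:
        if self.loq <= 0:
            raise ValidationError(f"loq must be positive, got {self.loq}")
        if self.substitution not in self._VALID:
            raise ValidationError(
                f"substitution must be one of {self._VALID}, "
                f"got {self.substitution!r}"
            )

    @property
    def substituted_value(self) -> float:
        """The concentration assigned to a censored measurement."""
        if self.substitution == "zero":
            return 0.0
        if self.substitution == "half_loq":
            return self.loq / 2.0
        return self.loq


def substitute_censored(
    records: Sequence[MeasurementRecord], policy: LOQPolicy
) -> list[MeasurementRecord]:
    """Replace every censored record's concentration by the policy value.

    Non-censored records pass through unchanged; input order is preserved.
    Idempotent for a fixed policy.
    """
    value = policy.substituted_value
    return [
        replace(r, concentration=value) if r.censored else r for r in records
    ]


# default column-name map; a "dialect" maps canonical names to foreign headers
_DEFAULT_DIALECT = {name: name for name in CSV_COLUMNS}

_REQUIRED = ("sample_id", "species", "tissue", "congener", "concentration")


def read_measurements(
    path,
    dialect: Mapping[str, str] | None = None,
    sentinel: str = LOQ_SENTINEL,
) -> list[MeasurementRecord]:
    """Read measurement records from a tidy CSV file.

    Parameters
    ----------
    path
        CSV file with a header row.
    dialect
        Optional map from canonical column names to the file's header
        names, for foreign headers.
    sentinel
        Token marking a below-LOQ concentration cell; such rows yield
        ``censored=True`` with a NaN concentration pending substitution.

    A ``censored`` column, when present, is also honoured (true/1/yes).
    """
    colmap = dict(_DEFAULT_DIALECT)
    if dialect:
        colmap.update(dialect)

    records: list[MeasurementRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for canonical in _REQUIRED:
            if colmap[canonical] not in header:
                raise SchemaError(
                    f"missing required column {colmap[canonical]!r}"
                )
        for lineno, row in enumerate(reader, start=2):
            records.append(_parse_row(row, colmap, sentinel, lineno))
    return records


def _parse_row(row, colmap, sentinel, lineno) -> MeasurementRecord:
    def get(name, default=""):
        key = colmap.get(name, name)
        value = row.get(key)
        return default if value is None else value.strip()

    raw_conc = get("concentration")
    censored = _parse_bool(get("censored"), lineno)
    if raw_conc == sentinel:
        concentration = math.nan
        censored = True
    else:
        try:
            concentration = float(raw_conc)
        except ValueError:
            raise ValidationError(
                f"row {lineno}: unreadable concentration {raw_conc!r}"
            ) from None
        if concentration < 0:
            raise ValidationError(
                f"row {lineno}: negative concentration {concentration}"
            )

    species = get("species")
    tissue = get("tissue")
    if species not in SPECIES:
        raise ValidationError(f"row {lineno}: unknown species {species!r}")
    if tissue not in TISSUES:
        raise ValidationError(f"row {lineno}: unknown tissue {tissue!r}")

    raw_lf = get("lipid_fraction")
    lipid_fraction = float(raw_lf) if raw_lf else None
    basis = get("basis") or "wet_weight"
    try:
        congener = int(get("congener"))
    except ValueError:
        raise ValidationError(
            f"row {lineno}: unreadable congener {get('congener')!r}"
        ) from None

    try:
        return MeasurementRecord(
            sample_id=get("sample_id"),
            species=species,
            tissue=tissue,
            congener=congener,
            concentration=concentration,
            basis=basis,
            lipid_fraction=lipid_fraction,
            censored=censored,
        )
    except ValidationError as exc:
        raise ValidationError(f"row {lineno}: {exc}") from None


def _parse_bool(token: str, lineno: int) -> bool:
    if token == "":
        return False
    if token.lower() in ("true", "1", "yes"):
        return True
    if token.lower() in ("false", "0", "no"):
        return False
    raise ValidationError(f"row {lineno}: unreadable censored flag {token!r}")


def write_measurements(
    records: Iterable[MeasurementRecord], path, sentinel: str = LOQ_SENTINEL
) -> None:
    """Write records to the canonical CSV layout.

    Numbers are written with ``repr`` (shortest round-trip form), so
    ``read_measurements`` recovers them exactly.  A censored record whose
    concentration is still NaN is written as the sentinel token.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in records:
            conc = sentinel if math.isnan(r.concentration) else repr(r.concentration)
            lf = "" if r.lipid_fraction is None else repr(r.lipid_fraction)
            writer.writerow(
                [
                    r.sample_id,
                    r.species,
                    r.tissue,
                    r.congener,
                    conc,
                    r.basis,
                    lf,
                    str(r.censored).lower(),
                ]
            )
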