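"""Synthetic per-bird congener measurements.

The survey publishes only per-(species, tissue, congener) summary
statistics, not per-bird values, so every pipeline stage is exercised on
synthetic cohorts drawn to match those summaries.  For each bird, each
configured (tissue, congener) cell draws one lipid-weight concentration
from a moment-matched right-skewed distribution (lognormal by default,
gamma as an alternative), draws a lipid mass fraction for the (bird,
tissue) pair from a rescaled beta distribution centred on the typical
tissue lipid contents (1.5 / 5 / 30%), derives the wet-weight value, and
left-censors it at the analytical LOQ of 0.02 ng/g ww.

Congener draws are independent within a bird by default; an optional
shared lognormal per-bird multiplier (``frailty_sigma`` > 0) induces the
positive inter-congener correlation typical of real residue data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .concentrations import DEFAULT_LIPID_FRACTIONS, DomainError
from .records import LOQPolicy, MeasurementRecord
from .refdata import RESIDUE_SUMMARY_LW, SPECIES_N


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched log-scale parameters (mu, sigma).

    sigma² = ln(1 + sd²/mean²) and mu = ln(mean) − sigma²/2, so a
    lognormal with these parameters has exactly the requested mean and
    sd; sd = 0 degenerates to a point mass at ``mean``.
    """
    if mean <= 0:
        raise DomainError("mean must be positive")
    if sd < 0:
        raise DomainError("sd must be non-negative")
    sigma_sq = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma_sq / 2.0
    return mu, math.sqrt(sigma_sq)


@dataclass(frozen=True)
class CellParams:
    """Target lipid-weight mean and sd (ng/g lw) for one cohort cell."""

    target_mean: float
    target_sd: float

    def __post_init__(self) -> None:
        if self.target_mean <= 0:
            raise DomainError("target_mean must be positive")
        if self.target_sd < 0:
            raise DomainError("target_sd must be non-negative")


#: Plausible lipid-fraction ranges per tissue, centred on the typical
#: contents used for basis conversion.
DEFAULT_LIPID_RANGES = {
    "muscle": (0.005, 0.030),
    "liver": (0.020, 0.100),
    "fat": (0.150, 0.500),
}


@dataclass(frozen=True)
class CohortConfig:
    """Specification of a synthetic cohort.

    ``cells`` maps (species, tissue, congener) to lipid-weight targets;
    ``n_birds`` gives cohort sizes per species.  Lipid fractions are
    drawn from a beta distribution rescaled to ``lipid_ranges[tissue]``
    with its mean at the tissue's typical lipid content and sharpness
    ``lipid_beta_concentration``.
    """

    cells: Mapping[tuple[str, str, int], CellParams]
    n_birds: Mapping[str, int] = field(default_factory=lambda: dict(SPECIES_N))
    lipid_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LIPID_RANGES)
    )
    lipid_beta_concentration: float = 10.0
    loq_policy: LOQPolicy = field(default_factory=LOQPolicy)
    family: str = "lognormal"
    frailty_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "gamma"):
            raise DomainError(f"unknown family {self.family!r}")
        if self.frailty_sigma < 0:
            raise DomainError("frailty_sigma must be non-negative")
        for species, n in self.n_birds.items():
            if n < 1:
                raise DomainError(f"n_birds for {species!r} must be >= 1")


def default_config(seed: int = 0, **overrides) -> CohortConfig:
    """Cohort calibrated to the published survey summaries.

    Cells cover the six indicator congeners and PCB 118 in the three
    tissues of all four species, with the published cohort sizes
    (8 / 9 / 9 / 16 birds).
    """
    cells = {
        key: CellParams(target_mean=mean, target_sd=sd)
        for key, (mean, sd) in RESIDUE_SUMMARY_LW.items()
    }
    return CohortConfig(cells=cells, seed=seed, **overrides)


def _draw_cell(rng, params: CellParams, family: str, size: int) -> np.ndarray:
    if params.target_sd == 0:
        return np.full(size, params.target_mean)
    if family == "lognormal":
        mu, sigma = lognormal_params(params.target_mean, params.target_sd)
        return rng.lognormal(mu, sigma, size)
    # gamma, moment-matched
    shape = (params.target_mean / params.target_sd) ** 2
    scale = params.target_sd**2 / params.target_mean
    return rng.gamma(shape, scale, size)


def _draw_lipid_fraction(rng, config: CohortConfig, tissue: str) -> float:
    lo, hi = config.lipid_ranges[tissue]
    target = DEFAULT_LIPID_FRACTIONS[tissue]
    m = (target - lo) / (hi - lo)
    k = config.lipid_beta_concentration
    return float(lo + (hi - lo) * rng.beta(m * k, (1.0 - m) * k))


def generate_cohort(config: CohortConfig) -> list[MeasurementRecord]:
    """Draw one synthetic cohort of wet-weight measurement records.

    Records are on the wet-weight basis and carry the bird's simulated
    tissue lipid fraction, so lipid-weight values are recoverable by
    exact division.  Wet-weight values below the LOQ are censored and
    already substituted per the configured policy.  Identical
    configuration (including seed) gives identical output.
    """
    rng = np.random.default_rng(config.seed)
    policy = config.loq_policy

    # stable iteration order: by species, bird, tissue, congener
    by_species: dict[str, list[tuple[str, int, CellParams]]] = {}
    for (species, tissue, congener), params in sorted(config.cells.items()):
        by_species.setdefault(species, []).append((tissue, congener, params))

    records: list[MeasurementRecord] = []
    for species in sorted(by_species):
        n = config.n_birds.get(species)
        if n is None:
            raise DomainError(f"no cohort size configured for {species!r}")
        cells = by_species[species]
        tissues = sorted({tissue for tissue, _, _ in cells})
        for bird in range(n):
            sample_id = f"{species}_{bird + 1:04d}"
            lipid = {
                t: _draw_lipid_fraction(rng, config, t) for t in tissues
            }
            frailty = (
                rng.lognormal(
                    -config.frailty_sigma**2 / 2.0, config.frailty_sigma
                )
                if config.frailty_sigma > 0
                else 1.0
            )
            for tissue, congener, params in cells:
                lw = float(_draw_cell(rng, params, config.family, 1)[0])
                lw *= frailty
                ww = lw * lipid[tissue]
                censored = ww < policy.loq
                records.append(
                    MeasurementRecord(
                        sample_id=sample_id,
                        species=species,
                        tissue=tissue,
                        congener=congener,
                        concentration=(
                            policy.substituted_value if censored else ww
                        ),
                        basis="wet_weight",
                        lipid_fraction=lipid[tissue],
                        censored=censored,
                    )
                )
    return records
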