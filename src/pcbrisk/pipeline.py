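"""End-to-end report pipeline.

Ties the stages together in the order the analysis runs: measurement
input (file or synthetic cohort) → censoring substitution → basis
conversion → residue summaries → homolog profile → normative comparison
→ dietary intake → organ/species contrasts → QC recovery — and writes
one CSV per report plus a machine-readable run log.

Presentation CSVs round concentrations to 2 decimals and TEQ values to
3; full-precision companions carry a ``_raw`` suffix.  Every CSV starts
with a ``# units:`` comment line.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import qc, ranktests
from .concentrations import (
    BasisConversion,
    homolog_profile,
    summary_table,
    to_lipid_basis,
)
from .exposure import ExposureScenario, default_scenarios, intake_table
from .records import (
    DIOXIN_LIKE_CONGENERS,
    LOQPolicy,
    MeasurementRecord,
    ValidationError,
    read_measurements,
    substitute_censored,
)
from .simulate import default_config, generate_cohort
from .teq import (
    LimitRegistry,
    TEFRegistry,
    compute_teq,
    exceeds_limit,
    ng_to_pg,
    percent_of_limit,
)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_path`` / ``synthetic`` selects the data
    source.
    """

    outdir: str | Path
    input_path: str | Path | None = None
    synthetic: bool = False
    seed: int = 0
    loq_policy: LOQPolicy = field(default_factory=LOQPolicy)
    conversion: BasisConversion = field(default_factory=BasisConversion)
    tef_registry: TEFRegistry = field(default_factory=TEFRegistry)
    limits: LimitRegistry = field(default_factory=LimitRegistry)
    scenarios: Sequence[ExposureScenario] | None = None
    percentiles: tuple[float, ...] = (50.0, 97.5)

    def __post_init__(self) -> None:
        if self.synthetic == (self.input_path is not None):
            raise ValidationError(
                "exactly one of input_path / synthetic must be selected"
            )


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def load_records(config: RunConfig) -> list[MeasurementRecord]:
    if config.synthetic:
        records = generate_cohort(
            default_config(seed=config.seed, loq_policy=config.loq_policy)
        )
    else:
        records = read_measurements(config.input_path)
    return substitute_censored(records, config.loq_policy)


def _units_header(path: Path, units: str, df: pd.DataFrame) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# units: {units}\n")
        df.to_csv(fh, index=False)


def _records_lw(records, conversion) -> list[MeasurementRecord]:
    return [
        to_lipid_basis(r, conversion) if r.basis == "wet_weight" else r
        for r in records
    ]


@_stage("summaries")
def write_summaries(records, config: RunConfig, outdir: Path) -> list[str]:
    ww = [r for r in records if r.basis == "wet_weight"]
    lw = _records_lw(records, config.conversion)
    written = []
    for label, recs, units in (
        ("ww", ww, "ng/g wet weight"),
        ("lw", lw, "ng/g lipid weight"),
    ):
        if not recs:
            continue
        df = summary_table(recs, config.percentiles)
        raw = outdir / f"summary_{label}_raw.csv"
        _units_header(raw, units, df)
        rounded = df.copy()
        for col in ("mean", "sd", "min", "max") + tuple(
            c for c in df.columns if c.startswith("P")
        ):
            rounded[col] = rounded[col].round(2)
        out = outdir / f"summary_{label}.csv"
        _units_header(out, units, rounded)
        written += [str(out), str(raw)]
    return written


@_stage("homolog_profile")
def write_homolog_profile(records, config: RunConfig, outdir: Path) -> list[str]:
    lw = _records_lw(records, config.conversion)
    rows = []
    keys = sorted({(r.species, r.tissue) for r in lw})
    for species, tissue in keys:
        subset = [r for r in lw if (r.species, r.tissue) == (species, tissue)]
        profile = homolog_profile(subset)
        n_birds = len({r.sample_id for r in subset})
        for chlorines, total in profile.items():
            rows.append(
                {
                    "species": species,
                    "tissue": tissue,
                    "homolog_chlorines": chlorines,
                    "mean_total_ng_g_lw": round(total / n_birds, 2)
                    if n_birds
                    else 0.0,
                }
            )
    df = pd.DataFrame(rows)
    out = outdir / "homolog_profile.csv"
    _units_header(out, "ng/g lipid weight, per-bird mean of homolog totals", df)
    return [str(out)]


def _per_bird_sums(lw_records) -> pd.DataFrame:
    from .records import INDICATOR_CONGENERS

    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in lw_records],
            "species": [r.species for r in lw_records],
            "tissue": [r.tissue for r in lw_records],
            "congener": [r.congener for r in lw_records],
            "concentration": [r.concentration for r in lw_records],
        }
    )
    ind = df[df["congener"].isin(INDICATOR_CONGENERS)]
    return (
        ind.groupby(["species", "tissue", "sample_id"])["concentration"]
        .sum()
        .reset_index(name="sum_ipcb")
    )


def _per_bird_teq(lw_records, registry: TEFRegistry) -> pd.DataFrame:
    """Per-bird dl-PCB TEQ (pg-TEQ/g lw) from whichever dl congeners exist."""
    rows: dict[tuple[str, str, str], dict[int, float]] = {}
    for r in lw_records:
        if r.congener in DIOXIN_LIKE_CONGENERS and r.congener in registry.tef:
            key = (r.species, r.tissue, r.sample_id)
            rows.setdefault(key, {})[r.congener] = ng_to_pg(r.concentration)
    out = [
        {
            "species": species,
            "tissue": tissue,
            "sample_id": sample_id,
            "teq": compute_teq(concs, registry),
        }
        for (species, tissue, sample_id), concs in rows.items()
    ]
    return pd.DataFrame(out, columns=["species", "tissue", "sample_id", "teq"])


@_stage("normative_comparison")
def write_normative(records, config: RunConfig, outdir: Path) -> list[str]:
    lw = _records_lw(records, config.conversion)
    sums = _per_bird_sums(lw)
    teqs = _per_bird_teq(lw, config.tef_registry)
    limits = config.limits
    rows = []
    for (species, tissue), grp in sums.groupby(["species", "tissue"]):
        mean_sum = float(grp["sum_ipcb"].mean())
        tgrp = teqs[(teqs["species"] == species) & (teqs["tissue"] == tissue)]
        mean_teq = float(tgrp["teq"].mean()) if len(tgrp) else float("nan")
        ml = (
            limits.ml_teq_liver
            if tissue == "liver"
            else limits.ml_teq_meat
        )
        if isinstance(ml, tuple):
            pct_lo, pct_hi = percent_of_limit(mean_teq, ml)
        else:
            pct_lo = pct_hi = percent_of_limit(mean_teq, ml)
        rows.append(
            {
                "species": species,
                "tissue": tissue,
                "teq_lw": mean_teq,
                "pct_of_ml_low": pct_lo,
                "pct_of_ml_high": pct_hi,
                "sum_ipcb_lw": mean_sum,
                "exceeds_mrl": exceeds_limit(mean_sum, limits.mrl_sum_ipcb),
            }
        )
    df = pd.DataFrame(rows)
    raw = outdir / "normative_comparison_raw.csv"
    units = "TEQ pg-TEQ/g lw; sums ng/g lw; limits: EU maxima for animal fat"
    _units_header(raw, units, df)
    rounded = df.copy()
    rounded["teq_lw"] = rounded["teq_lw"].round(3)
    for col in ("pct_of_ml_low", "pct_of_ml_high"):
        rounded[col] = rounded[col].round(1)
    rounded["sum_ipcb_lw"] = rounded["sum_ipcb_lw"].round(2)
    out = outdir / "normative_comparison.csv"
    _units_header(out, units, rounded)
    return [str(out), str(raw)]


@_stage("intake")
def write_intake(records, config: RunConfig, outdir: Path) -> list[str]:
    scenarios = (
        list(config.scenarios)
        if config.scenarios is not None
        else default_scenarios()
    )
    ww = [r for r in records if r.basis == "wet_weight"]
    frames = []
    if ww and scenarios:
        sums = _per_bird_sums(ww)
        teqs = _per_bird_teq(ww, config.tef_registry)
        game = ("tufted_duck", "common_pochard")
        organs = ("muscle", "liver")
        # per-bird TEQ is already pg-TEQ/g ww; indicator sums are ng/g ww
        for analyte, per_bird, col in (
            ("sum_ipcb", sums, "sum_ipcb"),
            ("dl_teq", teqs, "teq"),
        ):
            levels: dict[tuple[str, str, str], float] = {}
            for (species, organ), grp in per_bird.groupby(["species", "tissue"]):
                if species not in game or organ not in organs:
                    continue
                for p in config.percentiles:
                    label = f"P{p:g}"
                    levels[(species, organ, label)] = float(
                        grp[col].quantile(p / 100.0)
                    )
            frames.append(
                intake_table(levels, scenarios, analyte, config.limits)
            )
    frames = [f for f in frames if len(f)]
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = intake_table({}, scenarios or [], "sum_ipcb", config.limits)
    units = (
        "sum_ipcb: ng/kg bw/week (levels ng/g ww); "
        "dl_teq: pg-TEQ/kg bw/week (levels pg/g ww)"
    )
    raw = outdir / "intake_raw.csv"
    _units_header(raw, units, df)
    rounded = df.copy()
    if len(rounded):
        rounded["level_ww"] = rounded["level_ww"].round(3)
        rounded["ewi"] = rounded["ewi"].round(3)
        rounded["pct_of_twi"] = rounded["pct_of_twi"].round(3)
    out = outdir / "intake.csv"
    _units_header(out, units, rounded)
    return [str(out), str(raw)]


@_stage("stats")
def write_stats(records, config: RunConfig, outdir: Path) -> list[str]:
    lw = _records_lw(records, config.conversion)
    sums = _per_bird_sums(lw)
    rows = []

    def add(label, groups, result):
        rows.append(
            {
                "comparison": label,
                "groups": ";".join(groups),
                "statistic": round(result.statistic, 4),
                "p_value": round(result.p_value, 4),
                "method": result.method,
                "n": ";".join(str(k) for k in result.n),
                "significant_at_0.05": result.significant,
            }
        )

    # intraspecies organ contrasts on per-bird indicator sums
    for species, grp in sums.groupby("species"):
        tissues = sorted(grp["tissue"].unique())
        if len(tissues) >= 2:
            samples = [
                grp[grp["tissue"] == t]["sum_ipcb"].tolist() for t in tissues
            ]
            add(f"{species}: sum_iPCB across tissues", tissues,
                ranktests.kruskal_wallis(samples))
            for i in range(len(tissues)):
                for j in range(i + 1, len(tissues)):
                    add(
                        f"{species}: sum_iPCB {tissues[i]} vs {tissues[j]}",
                        [tissues[i], tissues[j]],
                        ranktests.mann_whitney_u(samples[i], samples[j]),
                    )
    # interspecies contrasts per tissue
    for tissue, grp in sums.groupby("tissue"):
        species = sorted(grp["species"].unique())
        if len(species) >= 2:
            samples = [
                grp[grp["species"] == s]["sum_ipcb"].tolist() for s in species
            ]
            add(f"{tissue}: sum_iPCB across species", species,
                ranktests.kruskal_wallis(samples))
    # concentration vs lipid fraction (wet-weight records with a measured
    # lipid fraction), muscle and liver
    ww = [r for r in records if r.basis == "wet_weight" and r.lipid_fraction]
    if ww:
        ww_sums = _per_bird_sums(ww)
        lf = {
            (r.species, r.tissue, r.sample_id): r.lipid_fraction for r in ww
        }
        for tissue in ("muscle", "liver"):
            grp = ww_sums[ww_sums["tissue"] == tissue]
            x = grp["sum_ipcb"].tolist()
            y = [
                lf[(row.species, row.tissue, row.sample_id)]
                for row in grp.itertuples()
            ]
            if len(x) >= 3:
                add(
                    f"{tissue}: sum_iPCB (ww) vs lipid fraction",
                    ["all species"],
                    ranktests.spearman_rs(x, y),
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "comparison", "groups", "statistic", "p_value", "method", "n",
            "significant_at_0.05",
        ],
    )
    out = outdir / "stats_tests.csv"
    _units_header(out, "two-sided p values; midrank tie handling", df)
    return [str(out)]


@_stage("qc_recovery")
def write_qc(config: RunConfig, outdir: Path) -> list[str]:
    comparisons = qc.reference_comparisons_from_fixture()
    df = pd.DataFrame(
        {
            "congener": [c.congener for c in comparisons],
            "certified_ng_g_ww": [c.certified for c in comparisons],
            "obtained_ng_g_ww": [c.obtained for c in comparisons],
            "recovery_percent": [c.recovery for c in comparisons],
        }
    )
    lo, hi = qc.recovery_range(comparisons)
    df["range_min"] = lo
    df["range_max"] = hi
    out = outdir / "qc_recovery.csv"
    _units_header(out, "ng/g ww; recovery percent of certified value", df)
    return [str(out)]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the run-log dictionary.

    Emits the residue summaries (per basis, rounded + raw), the homolog
    profile, the normative comparison, the intake table, the statistical
    contrasts, the QC recovery report and ``run_log.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = load_records(config)
    outputs: list[str] = []
    outputs += write_summaries(records, config, outdir)
    outputs += write_homolog_profile(records, config, outdir)
    outputs += write_normative(records, config, outdir)
    outputs += write_intake(records, config, outdir)
    outputs += write_stats(records, config, outdir)
    outputs += write_qc(config, outdir)
    log = {
        "seed": config.seed,
        "synthetic": config.synthetic,
        "input_path": str(config.input_path) if config.input_path else None,
        "loq": config.loq_policy.loq,
        "substitution": config.loq_policy.substitution,
        "tef_version": config.tef_registry.version,
        "percentiles": list(config.percentiles),
        "n_records": len(records),
        "outputs": sorted(outputs),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    log_path = outdir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2), encoding="utf-8")
    log["log_path"] = str(log_path)
    return log
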