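# pcbrisk

Residue-to-risk analysis of polychlorinated biphenyl (PCB) congeners in
wildlife tissue, built around a 2013 winter survey of four diving sea-duck
species (common goldeneye, tufted duck, common pochard, greater scaup)
wintering on the southern Baltic coast. The package is aimed at
ecotoxicologists and food-safety assessors who work with congener-level
residue tables: it takes tidy per-bird concentration records — including
left-censored values below the limit of quantification (LOQ) — and carries
them through to regulatory compliance and consumer-exposure measures.

## What it computes

* **Censored concentration handling.** Measurements below the LOQ
  (0.02 ng/g wet weight) are flagged and substituted by a configurable
  policy: zero (default), LOQ/2, or LOQ.
* **Basis conversion.** Wet-weight (ww) ↔ lipid-weight (lw) using the
  sample's measured lipid fraction, or the typical wild-bird tissue lipid
  contents (muscle 1.5%, liver 5%, fat 30%), whose integer-rounded
  reciprocals give the conventional ww→lw factors 67, 20 and 3.
* **Indicator-PCB aggregation.** Σi-PCB = Σ c_i over the six EU indicator
  congeners {28, 52, 101, 138, 153, 180}, and homolog (chlorine-count)
  profiles from Ballschmiter–Zell numbering.
* **Toxic equivalents.** TEQ = Σ c_i · TEF_i over dioxin-like congeners
  using the WHO-2005 toxic equivalency factors, in pg-TEQ/g, and
  comparison against the EU maximum levels (Σi-PCB 40 ng/g fat; TEQ
  1.25–4 pg/g fat for meat, 10 pg/g for liver).
* **Dietary exposure.** Estimated weekly intake
  EWI = c_ww · portion · meals/yr / 52 / bw for adult (70 kg) and child
  (23 kg) consumers eating game-duck meat or liver 24, 6 or 2 times a
  year, with dl-PCB intakes expressed against the tolerable weekly
  intake (TWI, 14 pg-TEQ/kg bw/week).
* **Temporal decline.** Average linear percent-of-baseline decline rates
  against early-1980s fat-tissue burdens.
* **Analytical QC.** Recovery percentages against the SRM 1946 certified
  reference material.
* **Non-parametric contrasts.** Tie-aware Mann–Whitney U, Kruskal–Wallis
  and Spearman rank tests, with exact small-sample null distributions
  computed by enumeration conditional on the observed (tied) data.
* **Synthetic cohorts.** A generator that draws per-bird measurements
  moment-matched to the published survey summaries, so the whole pipeline
  is testable without the (undeposited) raw data.

## Worked example

```python
from pcbrisk import (sum_indicator, percent_of_limit, format_percent_range,
                     weekly_intake, percent_of_twi, default_scenarios,
                     annual_decline_percent)

muscle = {28: 9.11, 52: 2.09, 101: 3.18, 138: 245.01, 153: 398.04, 180: 296.44}
print(f"goldeneye muscle sum of indicator PCBs: {sum_indicator(muscle):.2f} ng/g lw")

pct = percent_of_limit(0.71, (1.25, 4.0))
print(f"tufted duck muscle TEQ vs meat ML: {format_percent_range(pct)}")

periodic_adult = [s for s in default_scenarios() if s.label == "periodic_adult"][0]
print(f"EWI, adult eating duck 6x/year: "
      f"{weekly_intake(7.746, periodic_adult, 'muscle'):.3f} ng/kg bw/week")

frequent_child = [s for s in default_scenarios() if s.label == "frequent_child"][0]
ewi_teq = weekly_intake(0.011, frequent_child, "muscle")
print(f"dl-PCB TEQ intake, child 24x/year: {ewi_teq:.4f} pg-TEQ/kg bw/week "
      f"({percent_of_twi(ewi_teq):.2f}% of TWI)")

print(f"fat-tissue decline since 1981-82: "
      f"{annual_decline_percent(52.0, 0.1918, 30.0):.1f}%/year")
```

prints

```
goldeneye muscle sum of indicator PCBs: 953.87 ng/g lw
tufted duck muscle TEQ vs meat ML: 18–57%
EWI, adult eating duck 6x/year: 2.554 ng/kg bw/week
dl-PCB TEQ intake, child 24x/year: 0.0221 pg-TEQ/kg bw/week (0.16% of TWI)
fat-tissue decline since 1981-82: 3.3%/year
```

Reading the output: the goldeneye muscle Σi-PCB of ~954 ng/g lw is more
than 20× the EU 40 ng/g-fat maximum residue limit, so the tissue is not
compliant as food; yet the dioxin-like intake even for the
highest-exposure consumer class (a child eating duck 24 times a year)
stays below 0.2% of the tolerable weekly intake — contamination and
dietary dl-PCB risk point in opposite directions for these birds.

## Command line

```
pcbrisk all --synthetic --seed 1 --outdir out/
```

writes the full report bundle: residue summaries per basis, the homolog
profile, the normative (maximum-level) comparison, the intake table with
%TWI annotations, the statistical contrasts, the QC recovery report, and
a machine-readable run log. Individual stages are available as
`summarize`, `profile`, `limits`, `intake`, `stats`, `qc`, `trends` and
`simulate`; `--config` accepts a TOML file overriding TEFs, limits, the
LOQ policy and the scenario set.

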