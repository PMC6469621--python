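# Methods

This note documents the models, conventions and design choices behind
`pcbrisk`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Measurement model and censoring

A measurement is one congener concentration (ng/g) in one tissue of one
bird, on a wet-weight (ww) or lipid-weight (lw) basis, with an optional
measured lipid mass fraction and a left-censoring flag. The analytical
LOQ is 0.02 ng/g ww. Censored values are substituted by a single-value
policy: **zero** (default), **LOQ/2** or **LOQ**. Zero is the default
because the survey's published per-congener minima are printed as 0.00
alongside below-LOQ entries, which is only consistent with zero
substitution; the other two policies are standard sensitivity choices for
left-censored residue data. Substitution is idempotent and
order-preserving; no distributional (e.g. regression-on-order-statistics)
imputation is attempted — with n between 8 and 16 birds per species it
would not be defensible.

## Basis conversion

lw = ww / lipid-fraction when the fraction was measured. Otherwise the
typical wild-bird tissue lipid contents are assumed — muscle 1.5%,
liver 5%, adipose 30% — and, by default, their integer-rounded
reciprocals 67, 20 and 3 are used as multiplication factors, matching
the conventional reporting practice for this matrix. Exact reciprocals
are available by flag (`BasisConversion(integer_factors=False)`); only
the exact form makes ww→lw→ww a strict round trip.

## Aggregates

* **Σi-PCB** is the sum over the six EU indicator congeners
  {28, 52, 101, 138, 153, 180}; PCB 118 (dioxin-like, mono-ortho) is
  deliberately excluded. Missing congeners are an error unless an
  explicit allow-missing flag treats them as zero.
* Two Σi-PCB readings exist: the sum of per-cell mean concentrations and
  the mean of per-bird sums. Both are exposed; on complete data they
  coincide. Checks against the published summary table use the
  sum-of-means form, because only means are printed there.
* **Homologs** are derived from Ballschmiter–Zell numbering, which
  assigns congener numbers in blocks of increasing chlorine count
  (1–3 mono … 209 deca); the profile maps every chlorine count 1–10 and
  conserves total mass.
* **Summary statistics** use the arithmetic mean, the sample (n−1)
  standard deviation, and percentiles by linear interpolation between
  closest order statistics (position p(n−1)/100 + 1, numpy's default).
  The survey's own percentile rule is unstated; its printed intake
  values suggest unrounded internal percentiles, which is why
  printed-vs-recomputed intake comparisons carry a ±1% tolerance (below).

## Toxic equivalents and limits

TEQ = Σ cᵢ·TEFᵢ in pg-TEQ/g, over the dioxin-like congeners, with the
WHO-2005 consensus TEFs packaged as a versioned registry (PCB 126 carries
the maximum, 0.1). Inputs in ng/g are bridged by ×1000; TEQ is the only
place pg appears. Regulatory defaults are the EU maxima for food of
animal origin: Σi-PCB 40 ng/g fat; TEQ 1.25–4 pg/g fat for meat (a range
because the level varies by animal category) and 10 pg/g for liver; TWI
14 pg-TEQ/kg bw/week for dl-PCBs. A value against a limit **interval**
is reported as (100·v/hi, 100·v/lo) — the smaller share against the
looser ceiling first — and presented integer-rounded (half-up), e.g.
"8–25%". A value equal to a maximum level is compliant; exceedance is
strict.

## Dietary exposure

EWI = c_ww · portion · meals-per-year / 52 / body-weight, per kg bw per
week. The consumer classes are adults of 70 kg and children of 23 kg;
portions 200/100 g (meat) and 120/60 g (liver); frequencies 24, 6 and 2
meals per year. The divisor of 52 weeks per year is this package's
choice; it reproduces the published periodic- and occasional-consumer
cells to printed precision. Σi-PCB intakes carry no %TWI — no TWI has
been established for indicator PCBs — so that field is absent (NaN in
tables), not zero. Comparisons against the published intake table use a
±1–2% tolerance: recomputation shows its frequent-adult and
occasional-child cells deviate by up to ~1.7% from the direct formula
(an artefact of the source's rounding chain), while the periodic cells
agree to 0.1%. The assessment is deterministic per percentile level; no
Monte-Carlo exposure modelling is attempted.

## Temporal decline

With only two or three historical points per species, decline is an
average rate, not a regression. The default metric is linear
percent-of-baseline per year, 100·(c₀−c_t)/c₀/years; an exponential
(constant relative loss) rate is exposed for comparison and is always
the larger of the two for a declining series. The baseline convention is
the 1981–82 winter with a 30-year span to the 2013 survey, stored as a
named constant. Only the tufted-duck rate is reproducible from published
numbers; the published goldeneye and scaup rates cannot be recovered
from any (formula, baseline, interval) combination of the printed
points, so they are carried as reference values only.

## Analytical QC

Recovery = 100·obtained/certified, one-decimal convention, computed
against the packaged SRM 1946 rows. Two source rows are internally
problematic: the PCB 52 certified value is ambiguous (8.1 vs 8.13) and
is omitted; the PCB 169 printed recovery (83.2%) differs from its own
certified/obtained quotient (83.0%) and is flagged
(`SRM1946_INCONSISTENT_ROWS`) and excluded from the per-row
reproduction check, while remaining in the fixture (it does not affect
the recovery range). Measured concentrations are analysed uncorrected —
recoveries of 80–91% mean reported residues are underestimates — with a
correction helper available for sensitivity analysis only.

## Rank statistics

All contrasts are non-parametric: the residue data are small-sample,
right-skewed and, after zero substitution, tied at zero. Ties get
midranks everywhere and tie-corrected variances in the asymptotic
approximations; all p values are two-sided; significance is reported at
0.05 with no multiplicity adjustment by default (a Holm helper is
provided).

The exact small-sample tests are computed **conditionally on the
observed values**, which keeps them exact under ties (the classical
no-tie tables do not apply):

* Mann–Whitney U (U = #{xᵢ>yⱼ} + ½ ties): the null distribution of the
  doubled rank sum over all nₓ-subsets is built by a dynamic programme
  over items (integer doubled midranks), feasible to pooled n = 20; the
  two-sided p is the null mass at least as far from nₓn_y/2 as observed.
  Tests verify it against explicit assignment enumeration for every
  pooled size up to 10, and that its attained size at α = 0.05 for
  n = (5,5) does not exceed the nominal level.
* Kruskal–Wallis H with tie correction; χ² reference with k−1 df, or
  exact enumeration of all group assignments for total n ≤ 10. For two
  groups H equals the squared tie-corrected (uncorrected-for-continuity)
  Mann–Whitney deviate, which is tested to 1e−9. All pooled values
  identical gives H = 0, p = 1 by convention.
* Spearman's r_s as the product-moment correlation of midranks, p from
  the t approximation with n−2 df; |r_s| = 1 reports p = 0.

The continuity correction (0.5) is applied in the Mann–Whitney normal
approximation by default and can be disabled.

## Synthetic cohorts

The generator emulates the survey's structure: per-species cohort sizes
8/9/9/16, three tissues, the six indicator congeners plus PCB 118, with
per-cell lipid-weight targets transcribed from the published mean/sd
summaries. Each cell draws one value per bird from a moment-matched
**lognormal** (σ² = ln(1+CV²), μ = ln m − σ²/2; exact mean and sd by
construction) — chosen because residues are positive and right-skewed
(published maxima far exceed means) — with a moment-matched gamma as the
alternative family. Lipid fractions come from a beta distribution
rescaled to plausible per-tissue ranges (0.5–3%, 2–10%, 15–50%) with
mean at the typical content and concentration parameter 10. Wet-weight
values are derived by multiplication and censored at the LOQ; identical
configuration and seed give identical output.

Congener draws are independent within a bird by default; the strong
inter-congener correlation of real residue profiles is not calibratable
from published summaries, but an optional shared lognormal per-bird
frailty multiplier induces positive correlation for sensitivity work.
The generator does not simulate analytical error, recovery loss or
temporal trends.

**What passing tests do and do not show.** Moment fidelity of the
sampler is tested on the latent lipid-weight draws at n = 2000 per
species against calibrated 4-standard-error bands — for the
high-CV cells the relative standard error of the sample sd is 8–16%
(lognormal kurtosis 80–200), far wider than the naive 1/√(2n). Two
structural effects mean the *censored* cohort cannot reproduce all
published cell means tightly, at any n: cells with lw means around
2 ng/g in muscle correspond to ww values at or below the LOQ, so zero
substitution removes a substantial share of their mass (the published
survey carries the same internal tension, reporting muscle means whose
ww equivalents sit below its stated LOQ). Tests on synthetic data
therefore validate pipeline arithmetic and contracts, not the field
realism of any individual cell.

## Numerical conventions

* Exact-test p values use a 1e−9 slack when comparing statistics to the
  observed value, so ties in the null distribution are counted in.
* Percent presentation rounds half-up to integers (the survey's own
  convention for limit shares); CSV reports round concentrations to 2
  decimals and TEQ to 3, with full-precision `_raw` companions.
* Reruns of the pipeline with the same configuration and seed are
  byte-identical except for the timestamp in the run log.
* Degenerate inputs are errors, not silent defaults: empty summaries,
  empty test groups, non-positive limits/baselines, zero rank variance.

## Known limitations

* Single-value censoring substitution biases means of heavily censored
  cells; acceptable here because censoring is rare outside the
  low-concentration muscle cells (~5% of default synthetic records).
* The exact Mann–Whitney is limited to pooled n ≤ 20 and exact
  Kruskal–Wallis to n ≤ 10 by enumeration cost; beyond that the
  tie-corrected approximations are used.
* The trend module deliberately refuses to regress over the sparse
  historical points; rates are descriptive.
* PCDD/F contributions to total TEQ are out of scope; only dl-PCB TEQ is
  computed.
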