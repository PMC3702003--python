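# Methods

This note records the models, conventions and design choices behind
`aquarisk`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Screening model

The assessment is a deterministic screening chain, compound by compound:

1. **Toxicity basis.** Each compound carries one or more bases
   `(point of departure, route, composite uncertainty factor)` with
   `derived_dose = pod / UF` in µg/kg/day. Routes: toxicological
   (NOAEL/LOAEL ÷ UF), therapeutic (lowest daily dose ÷ UF),
   microbiological (MIC-derived intake ÷ UF), carcinogenic (MTD ÷ linear
   extrapolation divisor at a stated lifetime risk, e.g. 10⁻⁶). The
   *most restrictive* (minimum) derived dose is used; exact ties break by
   route priority carcinogenic > toxicological > microbiological >
   therapeutic (graver endpoint class wins; ties never occur in the bundled
   registry, the rule exists to make selection deterministic).
2. **DWEL.** `DWEL = dose × RSC × 10⁶ / rate` in ng/L, where `rate` is the
   95th-percentile consumers-only community-water ingestion in mL per kg
   body weight per day for one of 12 age intervals on [0, 70) years. Using
   per-kg rates makes body weight cancel, so no separate body-weight table
   exists. Intervals are half-open `[start, end)`; fractional ages are
   valid. DWELs are kept at full floating precision; 3-significant-figure
   rounding is applied only at report time.
3. **Risk quotient.** `RQ = campaign-maximum concentration / DWEL` per
   interval (the campaign-wide maximum is the screening numerator; per-city
   assessment can be done by feeding a per-city summary). `RQ ≥ 1` flags
   potential concern. RQ is linear in concentration and inversely linear in
   RSC.
4. **Grouping.** Group 1 iff max RQ ≥ 0.01; else Group 2 iff every RQ ≥
   10⁻⁴; else Group 3 iff strictly more than half the intervals are below
   10⁻⁴; remaining profiles default to Group 2. The "strict majority"
   reading of *most intervals below 10⁻⁴* is a documented operationalisation
   that keeps the three groups a partition; profiles that straddle the floor
   without a majority below it are conservatively kept in Group 2.
5. **RSC sensitivity.** A scenario RSC rescales a profile by
   `rsc_used / rsc_scenario` and re-derives its group. In the end-to-end
   `assess()` pipeline, scenario values *multiply each record's own
   allocation* (a 20% scenario turns caffeine's 0.1 default into 0.02), so
   every scenario is conservative for every compound. Scaling is exact in
   floating point: a 0.2 scenario of an RSC-1 profile multiplies every RQ
   by exactly 5.
6. **Indicators.** Origin × chlorination treatability maps bijectively to
   groups A/B/C/D. Selection requires origin specificity (compounds tagged
   `both` are excluded outright), detection frequency ≥ 0.05 (configurable),
   and keeps at most two indicators per group ranked by frequency then
   median detected level. The per-group cap of two is a package convention:
   it reflects that an indicator suite should stay small, and reproduces the
   classic six-indicator choice on the bundled registry. Scenario
   interpretation is monotone in the detected-group set: A∪B ⇒ verify
   treatment operation, C∪D ⇒ source-water impact (trace sources,
   short-term control, long-term regulation, consider upgrades), A∪C ⇒
   municipal origin, B∪D ⇒ veterinary origin.

## Occurrence statistics and censoring

Measurements below the LOQ are left-censored (`ND`). Medians and maxima are
computed over detected values only — the only coherent convention when many
compounds are detected in well under half the samples; an LOQ/2 substitution
mode exists behind a flag for sensitivity analysis. Even-count medians use
the midpoint. A *sample* is the triple (city, season, sample_id), so
replicates are distinct samples. Percent-positive counts samples with ≥ 1
detected compound; percent-below uses a strict `<` comparison at the stated
threshold (default 50 ng/L). The detection index is detections across all
compounds per sample within a city; an index ≥ 3 flags a hot spot. Absent
rows are simply absent — the package does not impute a censored row for
compound–sample pairs missing from a campaign file.

## Bundled fixtures (synthetic reconstructions)

The original survey's sample-level data and supplementary tables are not
redistributable, so the packaged inputs are *synthetic reconstructions*,
flagged as such in their filenames and header comments:

* `exposure_factors_synthetic.csv` — 12 intervals, birth to 70 y. The
  infant (238 mL/kg/day), early-adolescent minimum (36) and adult 21–<70 y
  (41) rates are anchored so that the published screening outputs are
  reproduced (infant DWEL 27.8 ng/L for dimetridazole; infant-to-adult RQ
  ratio 5.8); the remaining entries are representative handbook-style
  values. The per-kg maximum falls in the first month of life; rates are
  *not* monotone with age (they dip through adolescence and rise slightly
  in adulthood), and the table validator deliberately does not assume
  monotonicity.
* `compound_registry_synthetic.csv` — 17 compounds, one row per toxicity
  basis. Anchors: dimetridazole MTD 4 200 µg/kg/day (benign mammary tumours
  in rats) with an extrapolation divisor chosen so the derived RSD
  (≈ 0.00661 µg/kg/day) reproduces the published DWEL span 27.8–184 ng/L
  and RQ profile 0.08–0.53 at full precision; caffeine ADI 150 µg/kg/day
  (registry maximum) with RSC 0.1; thiamphenicol (haemotoxicity),
  sulfamethazine (thyroid follicular adenoma) and clarithromycin (gut-flora
  inhibition) dosed so they join dimetridazole in Group 1. Other points of
  departure and uncertainty factors are representative screening-level
  values. Salicylic acid and thiamphenicol are tagged origin `both`
  (natural/food salicylate sources; dual human and veterinary thiamphenicol
  use), which correctly excludes them from indicator selection.
* `occurrence_reference_synthetic.csv` — per-compound frequency, median and
  maximum. Published values are used where available; the
  salicylic/clofibric/carbamazepine frequencies are split 0.33/0.23/0.31
  within their published 23–33 % band, and minor veterinary compounds are
  filled with representative values.

Because the dimetridazole RSD is calibrated *within* the band implied by
the published display values, the full-precision pipeline reproduces the
printed numbers (27.8, 184, 0.53, 0.08, 2.65, 0.40) under ordinary rounding;
no "round-then-scale" display arithmetic is needed anywhere.

## Synthetic campaign generator

Per (city, season, replicate, compound): a Bernoulli draw at
`min(1, p × city_multiplier)` decides whether a source signal is present;
present signals draw a concentration from
`LogNormal(ln(median) + ln(city_mult × season_mult), log_sd)`; draws below
the LOQ are recorded as censored, not redrawn, so the configured `p` is the
probability of an above-zero source signal and realized detection
frequencies sit slightly below it under aggressive LOQs. Output is
byte-identical under a fixed seed (single `numpy` Generator, fixed
iteration order). Compounds are independent given the city multiplier —
the multiplier induces realistic spatial correlation (clean cities are
clean for everything), but there is no compound-to-compound co-occurrence
structure beyond it, and no hydrology or fate-transport realism.

The bundled preset emulates a 13-city survey: 67 dry-season samples (all
cities) and 46 wet-season samples (9 cities), 5–6 replicates each, n = 113.
City multipliers encode the observed geography (Yangtze-region cities and
Guangzhou ≈ 1.3, a nearly clean groundwater-fed capital at 0.05, coastal
cities ≈ 0.6); the dry:wet season multiplier ratio is 1.5:1, a qualitative
choice reflecting the observation that maximal levels occur in the dry
season. Per-compound `log_sd` values were set from the target
median-to-maximum spread at the expected number of detections, then the
preset was calibrated once, by a 200-seed Monte-Carlo run, to the two
campaign-level targets: ≈ 89 % of samples positive and ≈ 92 % of detections
below 50 ng/L.

**Known limitation.** Under per-compound independence, an overall caffeine
frequency of 0.88 and a sample-positivity rate of 0.89 cannot hold
simultaneously (if caffeine alone were detected in 88 % of samples,
independent co-detections would push positivity well above 0.93; the real
survey's near-coincidence of the two numbers implies strong within-sample
correlation of absences). The preset therefore treats caffeine's 0.88 as
the *typical-city* detection probability parameter — a multiplier-1 city
realizes ≈ 0.88 (LOQ censoring is negligible at caffeine's levels) — while
the campaign-wide caffeine frequency, averaged over clean and contaminated
cities, comes out near 0.73. Passing calibration checks therefore
demonstrate that the generator matches the campaign-level statistics it was
calibrated to, not that it reproduces the real survey's full joint
occurrence structure.

## Numerical conventions and degenerate inputs

* Age-interval lookup is by binary search on interval starts; contiguity is
  validated at load time with a 10⁻⁶-year tolerance.
* Detected values are rounded to 0.01 ng/L by the generator (instrument
  reporting style); a rounding that would cross the LOQ is clamped to it.
* Zero exposure concentration yields an all-zero RQ profile, Group 3.
* A registry compound without a toxicity basis is carried as
  "not assessable" and skipped (with notice) rather than failing a run.
* Report rounding: DWELs at 3 significant figures, RQs at 2 decimals;
  everything internal is full double precision.
* CLI exit codes: 2 usage, 3 validation/domain, 4 I/O.

## Problem sizes used in checks

The test suite and acceptance script use: the 12-interval exposure table
and 17-compound registry for all deterministic results; 10 000 randomized
profiles for the grouping-rule cross-check against a brute-force oracle;
single-city campaigns of n = 5 000 for binomial/lognormal convergence; and
200 independent 113-sample campaigns for generator calibration. These sizes
give sampling errors well inside the asserted tolerances while keeping the
full suite fast.

## Out of scope

Mixture/cumulative toxicity, prenatal and breastfeeding exposure,
inhalation/dermal routes, benchmark-dose modelling, probabilistic exposure
factors, analytical chemistry, and quantitative treatment-process modelling
(treatability is a boolean registry attribute; extending to ozonation or
activated carbon is a registry schema extension).
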