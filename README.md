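# aquarisk

Life-stage screening risk assessment of pharmaceuticals in drinking water.

Trace pharmaceuticals — antibiotics, analgesics, stimulants, veterinary
drugs — pass through sewage and drinking-water treatment and turn up in tap
water at ng/L levels. `aquarisk` is a toolkit for water-quality scientists
and regulators who need to turn a multi-city monitoring campaign into a
prioritised human-health screening assessment and a practical monitoring
plan. It implements:

* **toxicity bases** — acceptable daily intakes (ADI) or risk-specific doses
  (RSD) derived from toxicological (NOAEL/UF), therapeutic (lowest dose),
  microbiological (MIC-based) or carcinogenic (MTD linear extrapolation)
  routes, with most-restrictive selection per compound;
* **age-dependent DWELs** — drinking-water equivalent levels per life stage,

  ```
  DWEL (ng/L) = dose (µg/kg/day) × RSC × 10⁶ / IngR (mL/kg/day)
  ```

  over 12 age intervals from birth to 70 years using 95th-percentile
  per-body-weight water ingestion rates (so body weight cancels);
* **risk quotients** — RQ = highest observed concentration / DWEL, per life
  stage, with relative-source-contribution (RSC) sensitivity scenarios and a
  three-group prioritisation (Group 1: any RQ ≥ 0.01; Group 2: all RQs ≥
  10⁻⁴; Group 3: most RQs < 10⁻⁴);
* **occurrence statistics** for left-censored campaign data — detection
  frequencies, detected-only medians and maxima, percent of samples positive,
  percent of detections below a threshold, per-city detection indices with
  hot-spot flagging, and dry/wet seasonal comparison;
* **an indicator-based monitoring framework** — origin (municipal vs
  veterinary) × chlorination treatability → indicator groups A–D, with
  scenario interpretations (treatment verification vs source impact) and
  recommended actions;
* **a synthetic campaign generator** — a 13-city, two-season, 113-sample
  survey preset with per-compound detection probabilities, lognormal
  concentrations, city/season contamination multipliers and LOQ censoring,
  so the whole pipeline is testable without restricted survey data.

## Worked example

The bundled registry and occurrence summary describe 17 compounds detected
in a 13-city tap-water survey. The end-to-end assessment:

```
$ aquarisk assess --rsc 1.0 --rsc 0.2
=== risk ranking at RSC scenario 1 ===
groups: 1 -> 4 compounds, 2 -> 7, 3 -> 6
        compound  group  max_rq   max_rq_interval  exceeds_unity  rsc  exposure_concentration_ng_L
   dimetridazole      1  0.5293 birth to <1 month          False  1.0                         14.7
   thiamphenicol      1  0.0496 birth to <1 month          False  1.0                        104.3
  sulfamethazine      1  0.0355 birth to <1 month          False  1.0                         89.6
  clarithromycin      1  0.0202 birth to <1 month          False  1.0                         11.9
        caffeine      2  0.0089 birth to <1 month          False  0.1                        564.0
...
=== indicator scenario ===
groups detected: ['A', 'B', 'C', 'D']
interpretation: a chlorination-treatable indicator reached finished water: ...
```

Reading the numbers: dimetridazole, a potentially carcinogenic veterinary
nitroimidazole, has age-dependent DWELs of 27.8–184 ng/L; at its observed
maximum of 14.7 ng/L its life-stage RQs run 0.08–0.53 — below 1, but within
one order of magnitude of concern, and highest in the first month of life
because infants drink the most water per kg of body weight. Four compounds
(dimetridazole, thiamphenicol, sulfamethazine, clarithromycin) have at least
one life-stage RQ ≥ 0.01 and head the management priority list. Under the
conservative scenario that tap water supplies only 20% of the acceptable
dose (`--rsc 0.2`), every RQ rises five-fold and dimetridazole exceeds unity
(2.65) for young infants.

Other useful commands:

```
aquarisk simulate --seed 3 --out campaign.csv   # synthetic 113-sample survey
aquarisk summarize campaign.csv --seasonal      # occurrence statistics
aquarisk derive-dwel                            # DWEL table per compound
aquarisk indicators                             # indicator grid A-D
```

Each stage is equally usable as a library; see `aquarisk.assess`,
`aquarisk.dwel_profile`, `aquarisk.rq_profile`, `aquarisk.campaign_summary`,
`aquarisk.select_indicators`, `aquarisk.generate_campaign`.

## Scope notes

The package performs compound-by-compound screening only: mixture toxicity,
prenatal/breastfeeding exposure and analytical chemistry (sample extraction
and quantification) are out of scope. See `docs/methods.md` for the model
assumptions, fixture provenance and known limitations.
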