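# Methods

## Model

The package scores each commercial-vessel arrival with a unitless potential
propagule pressure (PPP) score built from two proxies:

* **Ballast-water component** — reported ballast water discharge volume
  (BWD, m³) for the arrival, normalized by the population median discharge
  `medBWD`.  The proxy assumes propagule supply increases with discharged
  volume and that management (exchange/treatment) is applied as required;
  the score ranks relative pressure, it does not predict establishment.
* **Biofouling component** — total wetted surface area (TWSA, m²)
  normalized by the population median `medTWSA`.  TWSA = WSA · (1 + N_p),
  where N_p is the fraction of wetted area in protected niche areas (sea
  chests, rudders, bow thrusters), which foul disproportionately.

`score = BWD/medBWD + TWSA/medTWSA`.  The components are dimensionless, and
the score is additive, scale-invariant (rescaling all discharges or areas in
both population and arrivals leaves it unchanged), and exactly 2 for an
arrival at both medians.

### Wetted surface area

For six vessel types, WSA comes from a published power-law regression on
gross tonnage, `WSA = m · GT^b` (packaged coefficients, shipped bit-exact
and overridable from a CSV):

| type      | m     | b      | N_p  |
|-----------|-------|--------|------|
| general   | 20.02 | 0.5728 | 0.09 |
| passenger | 5.46  | 0.6951 | 0.27 |
| roro      | 25.04 | 0.5309 | 0.09 |
| bulker    | 15    | 0.6294 | 0.07 |
| container | 10.66 | 0.6501 | 0.09 |
| tanker    | 17.57 | 0.6105 | 0.08 |

ATBs and unmanned barge+tug pairs get no regression; each component's WSA
is either supplied precomputed or evaluated directly from hull parameters
with the Holtrop-style formula
`S = L(2T+B)√C_m(0.453 + 0.4425C_b − 0.2862C_m − 0.003467B/T + 0.3696C_wp)
+ 2.38·A_BT/C_b`.  Missing composite data is an error carried per arrival —
never silently defaulted — because typical-coefficient guesses would be
invisible in downstream rankings.

**ATB niche handling.** The niche proportions for composite arrivals are
published per component (0.033 barge, 0.25 tug) without stating whether
they apply per component or summed on the combined area.  The default
applies them per component (`barge·1.033 + tug·1.25`), since each value is
labelled with its component; a `summed` mode
(`(barge+tug)·1.283`) is available behind the `atb_niche_mode` switch.

`refit_regression` performs ordinary least squares of log WSA on log GT
(numpy `polyfit`) for users fitting their own fleet; it reports m, b and
the log–log r².  It is a convenience for new jurisdictions, not a
re-derivation of the packaged table.

## Median policies

Two genuinely open choices in forming the baseline are exposed explicitly:

* **Zero discharges.**  Most arrivals discharge nothing, so the
  all-arrivals median discharge is frequently 0, which would break the
  normalization.  Default: median over discharging arrivals only
  (`discharge="discharging"`).  The `all` policy uses every arrival and
  raises a loud error when its median is 0.
* **Observation unit.**  "Median individual vessel value" can mean one
  observation per arrival (default, matching a population defined as
  historical arrivals) or one per unique vessel (median of each vessel's
  own median, `basis="vessel"`), which de-weights frequent callers.

The trial driver (`run_trial_all_policies`, `ppp reproduce-trial`) runs all
four combinations and reports infeasible ones, so a jurisdiction can see how
sensitive its rankings are to the choice.  Even-count medians are the
midpoint of the two central values (the standard convention; stated because
it affects bit-exact reproduction).  A missing discharge field on input is
read as 0 m³ with a logged warning — no report of discharge is treated as no
discharge.

## Prioritization

Arrivals are grouped by the calendar date recorded on the arrival (no
timestamp arithmetic) and ranked by score descending.  Ties break by
discharge volume descending, then arrival id ascending, making runs fully
reproducible.  The top `capacity` arrivals are selected; the default 6/day
corresponds to inspecting roughly a quarter of arrivals in a population of
~9,400/year and is fully configurable.  Suspected-noncompliant arrivals are
always selected, independent of score; by default they do not consume
capacity (strict-capacity mode counts them).  An optional repeat-vessel
policy keeps only each vessel's chronologically first arrival in the
selection pool; later arrivals remain scored and reported.

## Aggregation

Cumulative scores per port / vessel type / period are plain sums, so they
are conserved under partition refinement; each group also reports the mean
score and its standard error (sample standard deviation over √n — the
conventional reading of "± SE"; 0 for singleton groups).  An optional
port→complex map merges jointly-reported ports (e.g. Los Angeles + Long
Beach) before grouping rather than hard-coding any merge.

## Synthetic populations

`vesselppp.synthetic` generates arrival populations with the structure the
model assumes, so every stage is testable without external data:

* type mix proportional to a real one-year California arrival census
  (container 3608 : tanker 2194 : bulker 1135 : roro 951 : passenger 628 :
  barge+tug 382 : atb 303 : general 227);
* per-type log-normal GT (e.g. container median 55,000 GT, σ_log 0.55;
  passenger 90,000, σ_log 0.35) — tonnage within a type is right-skewed;
* zero-inflated discharge: a per-type discharge probability (bulker 0.7,
  tanker 0.5, container 0.25, barge+tug 0.1, …) gating a log-normal volume
  (bulker median 15,000 m³, container 2,000 m³, …).  The zero inflation is
  deliberate: it exercises the discharge-median policy branches;
* per-component log-normal WSA for composite types (barge ≈ 2,500–3,000 m²,
  tug ≈ 450–500 m²), since hull coefficients are rarely reported for them;
* a vessel pool of ~30% of the arrival count per type, so repeat visits
  occur and per-vessel medians differ from per-arrival medians;
* weighted California-style port list, uniform dates over the configured
  range, 1% noncompliance.

Distribution parameters were chosen once as typical of a mixed deep-sea
fleet at large west-coast ports and live in `FleetConfig` for calibration
to other jurisdictions.  The generator emulates structure only: it does not
reproduce seasonality, port–type association (e.g. bulker-dominated river
ports), voyage histories, or any real dataset's exact medians.  Passing
tests therefore demonstrate correctness of the computations and policies on
realistically shaped data, not agreement with any specific jurisdiction's
published score summaries.

`generate_known_answer_set` pairs each generated population with expected
TWSA/score values computed by a deliberately separate, standard-library
re-implementation of the two formulas, giving a dual-implementation oracle
(agreement required to 1e−12 relative).

## Numerical and design notes

* Scoring is pure floating-point arithmetic; identical inputs give
  bit-identical outputs, and pipeline artifacts embed a config hash plus
  the baseline provenance window.
* GT is used as-is (dimensionless); no tonnage conversions are attempted.
  Vessel-type strings are normalized through an explicit alias map;
  unmapped strings are errors, not guesses.
* Batch scoring collects per-arrival failures (unresolvable type, missing
  composite WSA) and continues; `strict=True` aborts on the first.
* The acceptance script runs the retrospective trial at four years ×
  ~9,428 arrivals/year — the scale the package targets — which completes in
  seconds; the test suite uses populations of 100–2,000 arrivals.

## Limitations

* The score ranks *potential* pressure; it does not model environmental
  matching, voyage history, management method efficacy, or establishment
  probability, and makes no inference about differences between groups.
* Regression coefficients are means over large fleets; individual hulls
  (unusual trim, retrofits) can deviate substantially.
* The multi-year retrospective workflow on a real jurisdiction's data
  requires that jurisdiction's arrival table; the packaged trial runs on
  synthetic populations.
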