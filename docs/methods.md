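# Methods

## The model

MoGSA (Modified Green Star Area) is a rule-based multi-criteria score.
It assumes the user can describe a reaction as a set of named substances
with roles (reagent, product, solvent, auxiliary, catalyst, feedstock,
waste), each carrying its GHS hazard statements and a
degradability/renewability profile, plus declared process metadata
(temperature and pressure regime, reagent excess, byproduct formation,
derivatization count, monitoring mode). No structures, quantities or
kinetics are used: substance identity is by name, and hazards are taken
as declared. The metric is therefore only as complete as the input — an
omitted H-code silently improves the score, which is why the package
resolves every ambiguity in the hazardous direction (see below).

### Severity scores

Each H-code collapses to S ∈ {1,2,3} within its hazard class via an
exact transcription of the published code table
(`src/mogsa/data/ghs_hazard_scores.csv`, 76 rows). Four codes (H228,
H242, H261, H272) split by GHS category/type and carry a qualifier.
Three deliberate policies:

* **Split code without qualifier** → the more hazardous row, with a
  warning. Missing metadata must not overstate greenness.
* **Well-formed code absent from the table** (the table is not the full
  GHS catalogue) → score 2 with a warning by default; a silent 1 would
  understate hazard, a silent 3 would punish incomplete transcription.
  `unknown_policy="strict"` raises instead.
* **EUH and P-statements are rejected**, not ignored, so the user learns
  their input was not scored rather than assuming it was.

The transcription keeps the table as printed, including H304 in the
health High row and H305 in Moderate, although other GHS-derived
groupings order these two differently; fidelity to the published rule
set takes precedence over second-guessing it.

### Per-principle points

Applicable principles earn 1–3 points. Where the rule reduces to a
worst-case severity S, points = 4 − S with S aggregated as a maximum
over the substances in scope and the hazard classes in scope:

| principle | substances in scope | hazard classes |
|---|---|---|
| P1 | waste role (fallback: all non-products, warned) | health + environmental |
| P3 | all | health + environmental |
| P4 | products | health + environmental |
| P5 | solvents + auxiliaries | all three |
| P9 | catalysts | all three |
| P10 | all | degradability severity |
| P12 | all | physical + health |

P1/P3/P4 count health and environmental hazards because the waste/
synthesis/product criteria are phrased as hazard "to human health and
the environment"; physical hazards of the same substances are counted
once, under P12 ("considering health and physical hazards"); P5 and P9
cite the hazard table without restriction and use all three classes.
Worst-case (max) aggregation is used throughout because the published
criteria assign a single S per decision; it also gives the useful
monotonicity property that removing a declared hazard can never lower
any principle's points.

The metadata-driven principles: P2 scores 3/2/1 by how many of
{reagent excess > 10 %, byproducts formed (water exempt)} hold; P6
scores 3 at ambient pressure and room temperature, 2 at ambient pressure
with 0–100 °C (heating/cooling needed), else 1; P7 scores by the
all/some/none renewable feedstock count; P8 by 0/1/≥2 derivatizations;
P11 by continuous/periodic/no monitoring.

Parameters with defaults worth knowing: room temperature is 20–25 °C
inclusive (`ROOM_TEMPERATURE_RANGE`) — the criterion never defines it
numerically and this is the conventional laboratory band; the pressure
criterion is a declared ambient/non-ambient boolean rather than a
numeric band, since the published wording gives no pressure numbers; the
excess threshold is 10 % exclusive (`EXCESS_THRESHOLD_PERCENT`); the
byproduct exemption list defaults to water alone.

Edge policies: a principle whose required role is absent (P4 with no
product, P7 with no feedstock) is automatically non-applicable with a
warning rather than guessed. P1 with no waste-role substance falls back
to all non-product substances (warned); if everything is a product it
scores 3 as "no waste produced". Substances may hold several roles at
once and are counted under each.

### Aggregation, band, star

The overall score over n ≥ 1 applicable principles is
100·Σpᵢ/(3n), rounded half-up to two decimals at the final step only,
giving the range [33.33, 100]. Non-applicable principles enter neither
numerator nor denominator, so excluding a principle is an exact
re-normalization, not a zero. Bands: < 50 unacceptable, 50–75
acceptable, ≥ 75 excellent (configurable thresholds). A geometric
star-area ratio (`star_area_fraction`, cyclic polygon over the
applicable spokes) is provided as a clearly non-canonical secondary
statistic: the normalized points sum is the score, because it is exact
under arbitrary principle exclusion, whereas a polygon area depends on
which sectors happen to be adjacent.

The star renders as twelve fixed 30° sectors, P1 at the top then
clockwise: green (3), half green/half red split at 50 % radius (2), red
(1), yellow (non-applicable). Colors are pinned (#1a9850/#d73027/#fee08b)
and the SVG is built from fixed-precision strings with no timestamps, so
rendering is a pure function of the result and byte-identical across
runs.

## Synthetic data

`generate_synthetic_assessment(seed, n_substances)` emulates the shape
of real inputs: hazard codes drawn from the shipped table (so every
statement resolves exactly), random role sets with a guaranteed product,
random degradability/renewability, conditions spanning all three P6
bands, and a random applicability mask with at least one principle kept.
It does **not** emulate chemical plausibility — co-occurrence of hazard
codes, realistic role/hazard correlations, or consistent
stoichiometry — so property tests built on it demonstrate the engine's
invariants (determinism, schema validity, monotonicity), not the realism
of any particular score.

The packaged case-study fixtures (four acetophenone-reduction routes,
three extraction techniques) are labelled `reconstruction`: the
published comparison reports only the overall scores and band words, not
the per-principle inputs behind them, so the fixtures were rebuilt from
the routes' published descriptions (catalyst type, solvents,
temperature, workup) such that the engine reproduces the reported
overall scores (46.67, 50, 80; the second chemical route lands at 70.00
in the acceptable band) with P4 and P11 excluded — the only exclusion
pair consistent with 46.67 = 100·14/30 and 80 = 100·24/30. Per-principle
values in these files are this package's reading of the routes, not
published data.

## Numerical choices

Rounding is half-up via `decimal` (not banker's rounding) at the final
score only; all intermediate arithmetic is exact integer/rational.
Comparison ranking is a stable sort on (−score, −n_applicable), so exact
ties keep input order. Degenerate inputs are errors, not defaults: zero
applicable principles, empty substance lists, out-of-range scores, and
schema violations (including an applicability map not covering all
twelve principles, or unknown top-level keys) all raise with the
offending field named.

## Problem sizes

All checks are desk-scale by construction: rule-table fidelity is
exhaustive over the 76-row hazard table and every criterion row; the
exclusion-renormalization property is verified against a brute-force
re-summation oracle over all 3ⁿ point vectors for n ≤ 5; generator
properties use 150 seeded draws. The whole suite runs in a few seconds.

## Known limitations

* No structure awareness: the same compound under two names is two
  substances; no SMILES/InChI support by design.
* Hazard data is user-supplied; there is no PubChem/ECHA lookup.
* Byproducts, excess and derivatizations are declared, not inferred from
  the reaction equation.
* The metric applies to synthetic chemistry; analytical methods have
  their own principle sets and metrics (GAPI/AGREE family) and are out
  of scope.
* Principle weighting is binary applicability only; no fractional
  weights.
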