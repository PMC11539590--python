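# Methods

## Accounting model

`basinfoot` implements a linear, demand- and supply-driven attribution of
species-threat mass over a multi-basin input-output economy. The unit of
account is the threatened-species *equivalent*: each species in the account
contributes total mass 1, distributed over the basin-sectors that directly
threaten it. Linearity is assumed throughout — threat intensity per unit
gross output is constant, so attribution scales with monetary flows and the
three perspectives (production `φ′x̂`, consumption `φ′LY`, income `V G φ`)
conserve the same national total. This is an accounting identity, not a
behavioural model: it assigns responsibility for observed threats; it does
not predict ecological response to marginal changes in output.

Index layout is basin-major, sector-minor everywhere: position `b·c + s`
holds basin `b`, sector `s`. International trade enters as one extra
final-demand column (exports, consumer "abroad") and one extra primary-input
row (imports, supplier "abroad"). No threat intensity is assigned to foreign
production: the account covers domestic threats only, so "abroad" can bear
responsibility as a consumer or supplier but never appears as a producer.

## Satellite account

The chain from threat records to intensities is:

1. `B1` (factors × sectors, binary) is expanded per basin into
   `B^(b)` (factors × basin-sectors), zero outside basin `b`'s block.
2. Each row is made stochastic: mapped sectors are weighted by gross output,
   except rows of climate-change factors, which use CO₂ emissions — a
   forcing-proportional allocation that an output weighting would misstate.
   Rows whose weights sum to zero stay zero and are logged.
3. Each (species, basin, cause) record takes its own basin's normalised row
   (records are basin-specific, and `N^(b)` is zero outside basin `b`, so
   the basin binding is the only consistent choice).
4. Record rows are summed over (species, basin) pairs (`C_ag`; row sums
   equal mapped-cause counts), weighted, and normalised.

The pair weight is the product `area(s,b) · HII(b)`, normalised across the
species' basins — the simplest monotone combination of a species'
within-basin exposure (distribution area) and the pressure it experiences
there (Human Influence Index). Within a pair, causes share equally. With
uniform areas and HII the construction provably reduces to plain equal
weighting (checked against an independently coded oracle).

Causes whose factor maps to no sector carry no mass. By default the species'
remaining mass is renormalised over its mapped causes, preserving unit mass
per species; a `drop` policy instead discards the unattributable fraction
(the species then sums to less than 1). Both behaviours are exposed because
the right choice depends on whether an unmapped cause means "not economic"
or "not yet classified"; the per-species unattributable fraction is reported
either way.

## Numerical choices

- Inverses are dense solves (`n = m·c ≲ 1,500` at full scale); truncated
  Neumann series appear only as test oracles.
- Spectral radii use dense eigenvalues up to `n = 600` and power iteration
  above (coefficient matrices are non-negative, so the Perron root is what
  power iteration finds). A radius ≥ 1 is a hard error, never clipped.
- Zero-output basin-sectors get zero coefficient columns/rows and zero
  intensity; attribution mass on a zero-output sector is an input error.
- Balance is validated (default relative tolerance 1e-8, against
  `max(X, 1)` so zero-output rows are held to an absolute standard) and
  never repaired; table repair belongs to compilation, which is out of
  scope. Normalisation checks use 1e-10.
- Tie-breaks in top-flux rankings are deterministic: descending value, then
  producer index, then partner index.

## Trade scenarios

A scenario is an allowed basin×basin relation (diagonal always allowed).
Disallowed import-coefficient blocks `A_qr` are added to the importer's
domestic block `A_rr` and zeroed; disallowed final-demand imports are
reassigned to the importer's own supply of the same commodity. This folding
preserves column sums of `A`, so the substituted economy remains productive
and column-balanced with baseline primary-input coefficients, and applying
the adjacent-only and distant-only substitutions in sequence is exactly the
no-trade substitution. Output is re-solved, the Ghosh system is rebuilt from
the counterfactual transactions, and threats are re-attributed with
*baseline* intensities — the counterfactual moves production, not threat
technology.

Whose technology produces the newly domestic goods is genuinely open. The
default (`importer`) keeps the importing basin's own input recipes — the
basin expands what it already does. The `exporter` variant instead blends
the former exporters' column recipes into the importing column,
demand-weighted and localized under the same allowed relation; it breaks
the column-sum preservation and is offered as a sensitivity check, not the
default. Sectors with zero baseline output that receive substituted demand
get the national-average input recipe for that sector, localized to the
basin and logged, so production there is not spuriously free. International
flows are kept unchanged in every scenario, and both intermediate and
final-demand imports are substituted.

Group summaries (net importers vs net exporters, classified at baseline)
report mean, min, max and the standard error `sd/√n` over basins in the
group; a single-basin group reports SE 0 and is flagged.

## Synthetic study systems

The generator emulates the structure the pipeline needs — not any real
economy. Defaults: 4 basins × 5 sectors, 30 species, 12 factors, 90
records; the `full-scale` preset scales to 16 basins × 82 sectors, 348
species, 166 factors and 1,846 records, matching the dimensions of a
national multi-basin study system.

- **Adjacency**: a random spanning tree plus a few extra edges — connected,
  with at least one distant pair from 4 basins up.
- **Economy**: every column of `A` allocates a fixed share
  `trade_openness` (default 0.3, a mid-range interregional sourcing share)
  to other basins, split by the gravity weight `d^(−distance_decay)`
  (default exponent 1.0) over graph distance `d`, and is normalised to a
  common column sum `spectral_target` (default 0.6, a typical
  intermediate-input share of output). Equal column sums make the Perron
  root exactly the target and guarantee positive primary inputs
  `V = (1 − colsum A)·x > 0`, so balance holds by construction with no
  repair or retry. Final demand has a 3× domestic bias with the same
  gravity decay, plus a 10% international-export share.
- **Threat account**: each species gets 1–4 basins and each pair 1–5
  distinct causes, grown until the requested record count is met exactly;
  every factor maps to 1–3 sectors; exactly one factor is flagged climate
  change. Areas are log-normal (km²-scaled), HII uniform on [5, 40] (its
  conventional 0–64 scale), CO₂ log-normal per basin-sector.
- **Determinism**: one RNG stream per component, derived from the master
  seed by fixed offsets; identical seeds give byte-identical CSV exports.

What the generator does *not* emulate: realistic sector taxonomies, spatial
autocorrelation of species ranges, correlation between threat intensity and
trade position, or heavy-tailed transaction size distributions. Passing
tests therefore demonstrate the correctness of the accounting algebra and
its invariants (conservation, marginals, composition, nulls) — not that any
particular empirical share or flux magnitude would be recovered on real
data.

## Problem sizes

The default test suite runs economies from 1×1 up to the full-scale preset
(1,312 basin-sectors); the acceptance script uses the full-scale preset
end to end. Conservation and marginal identities are asserted at 1e-8
relative, oracle agreement at 1e-6, normalisation at 1e-10, and the
two-basin closed-form scenario at 1e-10.

## Limitations

- The account weights all threatened (non-extinct) species equally; no
  extinction-risk grading.
- Attribution is first-order in supply-chain position (source → destination
  matrix); no full structural path analysis.
- Scenarios hold prices, technologies and intensities fixed; no
  general-equilibrium response or substitution elasticities.
- Negative final-demand entries (inventory drawdown) are accepted on load
  as long as column sums stay non-negative; they can make individual
  consumption shares exceed 1 locally while totals still conserve.
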