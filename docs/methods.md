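# Methods

This note documents the models, conventions and numerical choices behind
fermscope, and what the synthetic-data generators do and do not emulate.

## Batch fermentation model

State (X, S, Ac): cell dry mass, glucose and acetate, all g/L, in a stirred
batch of configurable working volume (default 4 L, inoculated at
X₀ = 0.4 g/L with S₀ = 40 g/L glucose).

- Growth: dX/dt = μ(S)·X with Monod μ(S) = μ_max·S/(K_s + S); μ = 0 for
  t < t_lag (the lag is a hard switch because only a lag *duration* is
  observable in batch data, not an adaptation trajectory).
- Glucose uptake: q_s = μ/Y_X/S (growth-associated only; no maintenance
  term — batch runs here end within hours, where maintenance is a
  second-order effect).
- Overflow acetate: q_ac,prod = k_ov·max(0, q_s − q_s,crit), the classical
  threshold picture of overflow metabolism.
- Acetate re-uptake at q_ac,up,max when glucose is depleted or — for
  B-type kinetics — once acetate exceeds a control threshold
  (default 1 g/L). The observed B-strain acetate peak-and-decline could
  equally be conversion or reduced formation; re-uptake above a threshold
  is implemented as one stated hypothesis, and the alternatives remain
  expressible through the kinetic parameters (set q_ac,up,max = 0 and
  lower k_ov).
- CO2 carbon by closure: at every instant, carbon in consumed glucose =
  carbon in new biomass + net acetate + configurable minor side fluxes
  (formate/pyruvate/lactate as constant fractions of consumed glucose,
  default 0) + CO2. Closure makes the downstream carbon balance exact on
  noiseless data, which is the property the balance machinery is tested
  against.

Numerics: fixed-step RK4 at dt = 0.01 h (deterministic and ample for these
smooth dynamics); when glucose would cross zero inside a step the step is
re-taken at the linearly interpolated crossing fraction, so biomass does
not overshoot the yield relation; integration stops at glucose exhaustion
or the configured duration. The trajectory is sampled every 0.1 h into the
output series. The emitted off-gas rate column is made trapezoid-consistent
with the closure cumulative (r_{i+1} = 2Δc/Δt − r_i), mirroring the
calibration of an integrating gas analyzer; trapezoidal re-integration
downstream therefore recovers the cumulative CO2 exactly rather than to
O(Δt²).

Measurement noise is multiplicative lognormal with a configurable CV
(default 0.02 in the pipeline) applied per channel; the mean is bias-
corrected so E[measured] equals the true value.

Strain presets (`K12_HMS_like`, `K12_RV_like`, `B_like`) are simulation
fixtures tuned to the three phenotypes of the study this package models —
high-overflow K-12, lagging K-12 (6 h lag, μ_max 0.70 h⁻¹), and a B strain
(μ_max 0.73 h⁻¹, Y 0.45 g/g) with acetate control near 1 g/L that exhausts
40 g/L glucose in ≈ 5–6 h. They are not parameter estimates for the real
strains.

## Process metrics

- Growth rate: OLS slope of ln CDM on time within a window (primary), plus
  the endpoint formula ln(X_end/X_start)/Δt. Both are exposed because
  "average growth rate" in process reports is ambiguous between them.
- Replicate summaries: mean and SEM with the sample (n−1) standard
  deviation — this convention reproduces the printed ±0.34 and ±0.21 of
  the study's process table exactly.
- Carbon fractions from stoichiometric formulas with standard atomic
  masses; biomass is the generalized one-carbon formula CH₁.₇₇O₀.₄₉N₀.₂₄
  and the organic acids enter as their anions (the species present at
  pH 7); electron mass of charged species is neglected.
- Acetate→glucose equivalent uses homoacetate stoichiometry
  (1 glucose → 2 acetic acid), factor M_glc/2M_HAc ≈ 1.5 on the
  neutral-acid mass basis on which HPLC concentrations are reported.
- The carbon-balance denominator (total input carbon) is a caller input:
  it depends on consumed glucose and complex-media carbon, which the
  series alone cannot determine. The raw (uncorrected) yield is computed
  on the anhydrous-glucose basis of the stated 40 g/L medium.
- All operations return full precision; the 2-decimal convention of
  process reports is applied only in the reporting layer.

## Two-color microarray analysis

Only foreground intensities are used (no background correction); spots
with a non-positive channel are flagged unusable and excluded, never
floored. M and A are computed in sample-over-reference orientation.

Print-tip loess: local-linear tricube-weighted regression of M on A per
print-tip group (statsmodels lowess), span 0.4 with 3 robustifying
iterations by default — the method is standard, the parameters are this
package's defaults since none are canonical. Groups with fewer than 10
usable spots fall back to median-centering with a warning.

Dye-swap consolidation averages replicate spots per probe, maps probes to
genes, and averages the sample-oriented M across the pair; the
intensity-dependent dye bias follows the dyes and therefore cancels in the
pair mean (an exact identity on noiseless data, asserted in tests).

Moderated t: the hierarchical-variance model s²_g ~ scaled inv-χ²(d₀, s₀²)
with posterior s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g),
t = mean/(s̃_g/√n), df = d₀ + d_g. The prior is estimated by moment
matching on z = log s²: E[z] and Var[z] are digamma/trigamma expressions
in (d_g/2, d₀/2), and the trigamma inverse is solved by Newton iteration.
An excess of Var[z] below trigamma(d_g/2) yields d₀ = ∞ (complete
pooling). A test cross-checks the implementation against an independent
reference implementation on a shared matrix: t and p agree to ~1e-15.
p-values are unadjusted, as in the filter convention this package
reproduces; BH-adjusted values are emitted informationally.

Filtering is strict: A > 7.5, |M| > 1.0, p < 0.05, DE in a strain iff all
three hold, in the union iff DE in ≥ 1 strain. "Fold change larger ±1.0"
is read as |M| > 1.0. The Venn partition is computed over the commonset
(the case-normalized intersection of the two platform gene lists) and its
region counts always sum to the universe size.

## Synthetic array design

The default truth plants log₂ fold changes of ±2 in a Venn-structured
subset of the 3882-gene commonset — unique counts (50, 29, 155), pairwise
(13, 14, 9), triple 77, union 347 — with per-gene random sign, spot noise
sd 0.3 log₂ units, and 6 arrays per strain (3 replicate cultivations ×
dye swap). Pairwise-only counts are a constructed split: only their sum is
identifiable from the study's reported figures. Planted genes receive
bright baselines (log₂ intensity 9–13, vs 7–13 for nulls) so they are
quantifiable above the A filter; dye bias is linear in A per print-tip
group with coefficients drawn once per truth. When a small commonset is
requested the design scales down proportionally.

What the generator does *not* emulate: spatial artifacts, saturation,
print-run batch effects, probe-specific affinity, or correlated gene
modules. Passing tests therefore demonstrate correctness of the analysis
chain under an idealized noise model, not robustness to real-array
pathologies.

## DIGE analysis

Each gel carries two samples (Cy3/Cy5) and the pooled internal standard
(Cy2); standardized abundance is the per-spot volume ratio to Cy2, which
cancels spot- and gel-level volume effects. Fold changes are computed from
group means of standardized abundance (not means of per-gel ratios) —
a DeCyder-like convention chosen here and documented as such — and
reported signed: r if r ≥ 1, else −1/r. Alteration requires |fold| > 2.0
and two-sided Student's t p < 0.01, both strict, so a spot at exactly
2.0-fold is not altered. The equal-variance Student test is the default
(matching the named test of the convention reproduced); Welch and
per-gel-paired variants are options since the original pairing is not
inferable. The default synthetic truth plants ±2 log₂ effects in 80 B-vs-K
and 12 K-vs-K spots of 400, 85 % acidic — the *shape* of the study's
altered-protein table (acidic ≫ basic, B-vs-K ≫ K-vs-K), not its absolute
counts, which require the original gels.

## Integration and annotation

Gene-side pair contrasts are differences of reference-relative M values
and satisfy the cycle identity exactly. Concordance is a declared
convention (the underlying study gives examples, not a rule): with both
values present, a moved transcript (|Δ| ≥ 0.5 log₂ by default) is
concordant iff signs agree; a flat transcript with a protein fold beyond
2.0 is discordant, and flat/flat is concordant. The call is invariant
under simultaneous pair reversal. Spots identified as two co-migrating
proteins produce one row per constituent. Annotation tallies are raw
per-term gene counts against a user-supplied gene→term map; no enrichment
statistic is applied by default and no ontology release is bundled or
downloaded.

## Pipeline and determinism

All stages derive their randomness from a single configured seed; a run
writes a manifest of SHA-256 hashes, and identical config + seed give
byte-identical artifacts. Problem sizes used by the default pipeline and
the acceptance script — 3882 commonset genes, 18 arrays, 400 spots × 10
gels, 5000-gene null simulations — were chosen to match the modeled study
design while keeping a full run in seconds on one core.

## Known limitations

- The simulator's yield formalism routes overflow carbon out of CO2, not
  biomass, so the final CDM of a glucose-exhausted run is X₀ + Y·S₀
  regardless of overflow; strain presets encode yield differences directly
  in Y_X/S.
- Carbon-balance absolute gram values of the modeled study are not
  reproducible from printed data (the input-carbon totals are strain-
  specific and unpublished); only internal consistency is checked.
- Printed per-strain growth-rate tables and their prose means disagree in
  places (e.g. one strain's mean 0.42 vs per-run values averaging 0.433);
  the package recomputes summaries from per-run values and leaves such
  discrepancies visible rather than reconciling them.
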