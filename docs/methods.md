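# Methods

## Model and assumptions

The community is modelled by seven species-attributed overall reactions on
ten tracked metabolites. Stoichiometries are written per mole of extent on
the tracked-metabolite basis; water, protons and charge are untracked
(unmeasured, and they cancel out of every fitted observable):

| reaction | stoichiometry |
|---|---|
| Rc lactate fermentation | glucose → 2 lactate |
| Rc hydrogenic acetogenesis | glucose → 2 acetate + 2 CO₂ + 4 H₂ |
| Dv hydrogenic lactate oxidation | lactate → acetate + CO₂ + 2 H₂ |
| Dv sulfidogenic lactate oxidation | 2 lactate + SO₄²⁻ → 2 acetate + 2 CO₂ + H₂S |
| Dv sulfidogenic H₂ oxidation | 4 H₂ + SO₄²⁻ → H₂S |
| Mh hydrogenotrophic methanogenesis | 4 H₂ + CO₂ → CH₄ |
| Mc acetoclastic methanogenesis | acetate → CH₄ + CO₂ |

Every reaction conserves carbon atoms and electron equivalents (electrons
released on complete oxidation to CO₂; the sulfate→sulfide couple carries
8), and these conservation laws are enforced at construction, so they hold
for every non-negative linear combination — i.e. for every fitted
prediction. Ethanol is excluded from the reaction set (its carbon flux in
these cultures is negligible) but retained as a metabolite for balance
accounting. There is no biomass reaction: carbon assimilated into cells is
absorbed by the fit residuals, which is the main reason CO₂ — carried by
the stoichiometry but deliberately *not* fitted — is over-predicted
relative to its measurement.

Model assembly removes reactions by genetic or nutrient availability:
sulfidogenic reactions require sulfate, acetoclastic methanogenesis
requires Mc, and Rc must always be present because cellulose is the only
substrate. Extracellular cellulose hydrolysis is folded into the glucose
node: cellulose mass converts to glucose equivalents at 162.14 mg/mmol
(anhydroglucose monomer — the model's glucose is a proxy for cellulose
carbon; the free-glucose basis 180.16 is available as a parameter).

## Estimation

Extents are estimated by weighted non-negative least squares over the six
fitted metabolites (glucose, acetate, lactate, H₂, CH₄, H₂S), solved with
the Lawson–Hanson active-set algorithm. The problem is convex and the
solver deterministic, so fitting needs no seed. Weights default to 1 on
fitted metabolites and 0 on carried ones; 1/SE² weighting from replicate
standard errors is available.

Two routes through the network are stoichiometrically identical
(glucose → 2 lactate plus hydrogenic lactate oxidation ≡ direct
acetogenesis, including CO₂), so the least-squares optimum is generally a
face of the feasible cone, not a point. The active-set solver returns a
*vertex* of that face, which makes the degeneracy analysis well defined:

* **Exclusion scan** — each reaction is sequentially forced to zero and the
  model refit; a refit whose NRMSE is within a relative tolerance
  (default 5%) of the best fit, and whose extent vector is distinct
  (dedup at 10⁻⁶ mmol), is an alternative equal-fit distribution. With
  vertex solutions this enumerates the corners of the optimal face. On the
  bundled quad-culture data this yields 2 distributions in the control
  condition and 3 under sulfate. Per-reaction ranges are the min/max over
  the set.
* **Flux ranges** — any linear functional of extents (a single extent, or
  a species' production/consumption of a metabolite) is minimised and
  maximised over `{x ≥ 0 : ‖W(Sx−y)‖ ≤ (1+slack)·best}`. At zero slack the
  feasible set is the optimal face, characterised exactly by `WSx = WSx*`
  (the projection is unique even when x* is not), and the bounds are two
  linear programs (HiGHS); at positive slack the quadratic constraint is
  handled by SLSQP started from the best fit.

Goodness of fit: R² = 1 − SS_res/SS_tot over fitted metabolites, and NRMSE
= RMSE/denominator with a convention menu for the denominator — mean |y|
(library default: stable when one metabolite's change is near zero), range
(max−min), max |y|, and standard deviation. All four are reported wherever
NRMSE appears; the reproduction script reports the max-|y| convention.
NRMSE is also available per metabolite (pooled is the default view).

Endpoint (cumulative net change over the incubation) fitting is the
default, because only endpoint values are tabulated with uncertainties in
the bundled data. Daily-cumulative observations are supported end to end:
the generator produces them, and `fit_daily_extents` fits each day's
increment independently (non-negative daily extents, hence monotone
cumulative extents) and sums the days.

## Cross-feeding attribution

A fitted distribution fixes each species' gross production and consumption
of every metabolite. In a well-mixed bottle each exchanged intermediate
(H₂, acetate, lactate, CO₂) passes through one shared pool, so intake is
attributed to producers proportionally to production shares — the unique
symmetric allocation. Within-species recycling is netted out first, which
guarantees producer ≠ consumer and makes per-metabolite conservation exact:
net production entering the pool equals net consumption plus the surplus
routed to an `environment` node; externally supplied substrates (glucose,
sulfate, or any declared initial pool) enter from that node. Consumption
exceeding production plus availability flags an infeasible extent vector.
CO₂ edges are model-derived (CO₂ is not fitted) and labelled as such. Over
an equal-fit distribution set, per-edge ranges are reported rather than a
single graph.

## Synergy and balances

Tertiary-interaction comparisons use two explicit additive schemes, chosen
per phenotype because they answer different questions and are not
interchangeable: *sum-of-values* (methane of the four-species culture vs
the summed methane of the two Dv-containing three-species cultures) and
*sum-of-increments* (cellulose degraded by the four-species culture vs the
mono-culture baseline plus the three bi-culture increments). Uncertainties
propagate by root-sum-square of the standard errors of independent
cultures; a difference within its propagated uncertainty classifies as
additive. Balance sheets multiply product amounts by carbon atoms or
electron equivalents and normalise over *recovered products only* — no
biomass or unmeasured sink enters the denominator, so fractions are
comparable across cultures but do not close against the substrate (a
fraction-of-substrate mode would change only the denominator).

## Synthetic data generator

The generator emulates the study's observation process: endpoint vectors
`y = S x* + ε` with independent Gaussian noise per metabolite and
replicate, cellulose mass back-computed from the glucose entry, and
optional daily-cumulative trajectories driven by per-reaction extent
schedules (7 non-negative fractions summing to 1), which reproduce lag
phenomenology such as late acetate consumption. Default noise standard
deviations are the replicate SEs of the four-species culture rows of the
bundled table (0.01–0.03 mmol for products, 10⁻⁴ mmol for residual
glucose); default replicate count is 3, matching the study design. Noised
product amounts are floored at zero with the flooring count recorded.
All randomness flows from one recorded seed.

What the generator does **not** emulate: growth kinetics (no Monod terms —
schedules are imposed, not emergent), headspace venting and pressure
artifacts, pH/carbonate speciation, and any replicate correlation. Passing
recovery tests therefore demonstrates correctness of the estimator under
the stated noise model, not robustness to those real-data effects.

The recovery experiment (generate → fit, repeated) reports per-reaction
bias and RMSE and the fraction of runs whose equal-fit range brackets the
truth. Per-extent bias is only meaningful for identifiable models (e.g.
the Rc+Mh+Mc community); in the degenerate 5-reaction control model the
vertex solver parks the redundant flux on one route, so only identifiable
combinations (the summed glucose routes, the methanogen extents) are
recovered without bias — the tests check exactly that.

## Numerical choices and problem sizes

* NNLS on the weighted reduced system; excluded reactions are dropped
  columns, re-embedded as exact zeros.
* Equal-fit dedup tolerance 10⁻⁶ mmol; LP face-membership slack 10⁻⁹
  (relative to the projection norm) to absorb floating-point error.
* Zero-slack flux ranges use LPs on the optimal face rather than the
  quadratic constraint, which is exact and robust for degenerate optima
  (duplicated columns give the full [0, c] range analytically and in the
  implementation).
* Monte-Carlo checks use 50–100 runs at 0.02 mmol noise with 3 replicates;
  at these sizes the whole suite and the reproduction script each run in
  seconds on one CPU.
* Degenerate inputs: empty observation tables, all-zero weight vectors,
  fewer than two fitted metabolites, negative slack, and consumption
  without a source all raise descriptive errors rather than returning
  silently wrong numbers.

## Known limitations

* The Rc/Dv carbon split in sulfate-free conditions is structurally
  unidentifiable from endpoint metabolite data; only ranges are meaningful.
* Fitting daily trajectories (rather than endpoints) can shift the optimum
  on real data; the bundled table carries endpoints only, so the daily mode
  is exercised against synthetic trajectories.
* The H₂S observation is inferred from sulfate consumption (1:1), so
  sulfide losses to precipitation or headspace partitioning fold into the
  fit residual.
* Trace medium sulfate (~0.1 µmol from FeSO₄) is treated as zero in
  sulfate-free conditions.
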