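# Methods

This note documents the models and procedures implemented in `fluxsense`,
the parameters that matter, the synthetic-data design, and the numerical
and design choices made where the problem was genuinely open.

## Flux balance analysis and the condition scan

The core computation is the linear program

max cᵀv s.t. S v = 0, LB ≤ v ≤ UB,

with S the stoichiometric matrix (rows metabolites, columns reactions,
exact rational coefficients internally; floats only at the solver
boundary) and c selecting the biomass drain. Units are mmol·gDW⁻¹·h⁻¹ for
material fluxes, mE·gDW⁻¹·h⁻¹ for photons, h⁻¹ for biomass. The solver is
scipy's HiGHS backend, which is deterministic with fixed inputs; status is
always surfaced (`optimal` / `infeasible` / `unbounded`), never swallowed.
Feasibility tolerance is 1e-9 and an optimal solution is rejected if
‖Sv‖∞ > 1e-6.

**Degeneracy policy.** Genome-scale LPs generally have alternate optima,
and a per-reaction dispersion statistic is meaningless if the reported
flux vector is solver-arbitrary. Every scanned condition is therefore
resolved parsimoniously: stage 1 finds the biomass maximum z\*; stage 2
minimizes Σ|vⱼ| subject to the original constraints plus cᵀv = z\*
(formulated with auxiliary variables t ≥ |v|). If fixing z\* exactly is
numerically borderline the equality is retried with 1e-9 relative slack.
The parsimonious optimum is unique on all networks the generator builds,
making the scan deterministic.

**Conditions.** Autotrophy is imposed by pinning the photon exchange at
57.54 mE·gDW⁻¹·h⁻¹ (cool-white light, equivalent to 400 µE·m⁻²·s⁻¹) and
capping the CO₂ exchange. The default scan covers 0.04 (air), 2.5, 5, 8
and 10 % CO₂. The mapping from percent CO₂ to an exchange bound is not
physically derivable at desk scale; the default is linear,
1.0 mmol·gDW⁻¹·h⁻¹ per percent, chosen once so that the 10 % level permits
about 10 mmol·gDW⁻¹·h⁻¹ of carbon uptake — the order of magnitude of
measured microalgal carbon fluxes. Both the levels and the scaling are
config values.

**Sensitivity.** ρ = sd(v)/max(|mean(v)|, 1e-9) with the sample standard
deviation; the ε guard makes all-zero profiles come out 0. The threshold
is ρ ≥ 0.01, inclusive. ρ is named in the source workflow but not defined
there; the coefficient of variation with an ε guard is our interpretation,
chosen because it is dimensionless, scale-invariant (ρ(kv) = ρ(v) for
k ≠ 0), and reduces to "fraction of flux that moves" for near-constant
profiles. Sensitive counts are aggregated by pathway annotation and by
compartment (a reaction spanning compartments is labelled with the joined
set, e.g. `c+m` for a mitochondrial transporter).

**Net-flux reconciliation.** For a metabolite i, Φ(cond) = Σⱼ S[i,j]·vⱼ
over *sensitive* j only; the ratio Φ(low)/Φ(high) is reported, undefined
when |Φ(high)| ≤ 1e-9 (undefined is a value, not an error). Concordance
with metabolomics compares sign(log₂(Φ_high/Φ_low)) with the measured
log₂ fold change's sign; records with undefined ratios or non-positive
net fluxes are unevaluable.

## Network complementation

Stages run strictly in the order associate → dedupe → reactant filter →
compartmentalize → gap fill; every candidate carries an ordered verdict
trail and the report's stage counts are non-increasing through dedupe and
the reactant filter. Determinism everywhere: candidates sort by
catalog id, ties in gap filling break lexicographically.

- **Associate**: homology hits (outfmt-6 style with an EC column, or a
  bare protein→EC map) pull catalog reactions by EC. Default e-value
  cutoff 1e-10 (the homology search itself is out of scope; hits are
  inputs). Unmatched ECs are recorded, not errors.
- **Dedupe**: a candidate is dropped when its compartment-stripped
  stoichiometry equals an existing reaction's; for reversible base
  reactions both orientations count.
- **Reactant filter**: every species name must already occur in the base
  model. Generic database names that can never match model species
  ("an_alcohol", …) are a configurable blacklist.
- **Compartmentalize**: a candidate is placed in every compartment where
  all its species exist (ids suffixed `__<comp>`); optionally a single
  placement with cytosol-first preference. No viable compartment ⇒
  dropped with a verdict.
- **Gap fill**: for each dead-end metabolite (only produced or only
  consumed, reversibility supplying both roles), the catalog restricted to
  already-known species is searched for the missing role in the dead end's
  own compartment; newly introduced dead ends are resolved recursively up
  to depth 3, after which a boundary reaction `SK_<met>` guarantees
  resolution.

## Thermodynamic directionality

Formation energies are the group-contribution linear form ΔG_f = origin +
Σ count·contribution at 27 °C and pH 7; reaction energies follow by
stoichiometric summation. Verdicts partition at τ = 30 kJ/mol (a common
constraint-based-modelling heuristic; no threshold is stated in the source
workflow): ΔG_r < −τ forward irreversible, ΔG_r > τ reverse irreversible
(the written orientation is flipped), |ΔG_r| ≤ τ reversible
(lb = −1000). Group decompositions are input tables, not computed from
structures; no concentration or ionic-strength corrections are applied. A
per-reaction override table accommodates curated calls from prior
studies. Exchange and sink reactions are never reoriented — they are
boundary pseudo-reactions without reaction chemistry, and reorienting a
gap-fill sink can fabricate a nutrient source.

## qPCR analysis

**Efficiency.** The amplification factor per cycle E is fitted from the
fluorescence curve: the baseline (median of the first five readings) is
subtracted, log₁₀ of the signal is regressed on cycle over sliding windows
of width 6, 5, then 4, and the best window with R² ≥ 0.99 and positive
slope gives E = 10^slope, clipped into (1, 2.2]. Windows are restricted
to the part of the curve where amplification dominates the baseline
(signal > 2× baseline, where subtraction noise no longer dominates the
log) and below the saturation shoulder (signal < ½ of the curve maximum,
where plateau truncation would bias the slope). Wider windows are
preferred because more cycles in the fit give a lower-variance slope;
narrower widths are only a fallback. A curve with no qualifying window
(flat, erratic) raises an efficiency failure.

**Relative expression.** ratio = E_t^ΔCt_t / E_ref^ΔCt_ref with
ΔCt = Ct(high CO₂) − Ct(low CO₂), so ratio > 1 means higher expression at
low CO₂ — the orientation in which carbon-concentrating-mechanism genes
(CAH5, LCIA, …) are induced. The contrast is configurable. With several
reference genes the geometric mean of their correction factors is used;
the default is Actin alone, with Ubiquitin available. Records flagged by
melt-curve failure are excluded with a warning. With all efficiencies
equal to 2 the ratio reduces algebraically to the classical 2^(−ΔΔCt),
which the tests verify numerically to 1e-12.

## Metabolomics analysis

Intensities are divided by the sample's cell count, then by the sample's
total ion content, so each sample's analyte values sum to 1 and the result
is invariant to per-sample rescaling. Fold changes are log₂ of the ratio
of condition means on the normalized scale; per-analyte Welch tests on
log₂ replicate values are adjusted by Benjamini–Hochberg at α = 0.05.
Analytes with zero intensity in a condition are flagged, never silently
dropped.

## Synthetic data: what it emulates and what it does not

The generators are pure functions of blueprint + seed.

**Network.** Three compartments (cytosol, chloroplast, mitochondrion) by
default. A scaffold of four reactions (CO₂ exchange, pinned photon
exchange, photon dissipation, biomass drain) surrounds (i) a CO₂-limited
linear pathway threading all compartments whose optimal fluxes equal the
CO₂ bound — the planted sensitive set, with ρ ≈ 0.79 across the default
levels, far above threshold; (ii) pinned chains driven by fixed-rate
exchanges, whose fluxes are condition-independent constants (ρ = 0); and
(iii) orphan metabolites fed off the biomass precursor, giving planted
dead ends whose producers carry zero flux. The CO₂ exchange and biomass
drain co-vary with the bound by construction — they are the perturbation
and its readout — so recovery is scored over non-scaffold reactions, and
the manifest records the scaffold ids. Default scale is 60 reactions /
~50 metabolites; the reaction budget is met exactly by sizing the pinned
chains. What this network does not emulate: genome-scale topology,
cofactor coupling, elemental balance, or realistic degeneracy patterns —
recovery results on it demonstrate correctness of the classifier under
its stated model, not performance on a curated reconstruction.

**Homology bundle.** The catalog plants one candidate class per
complementation stage: pass-through carbon-recycling conversions
(cytosolic chain species → CO₂, never forward shortcuts — a shortcut
would let parsimonious FBA bypass the planted chain), duplicates of base
reactions (including the reverse of a reversible one), novel-species and
generic-species candidates, and orphan-feeding candidates whose dead ends
are closed either by a gap-only catalog reaction or by a sink fallback.
The manifest states the intended verdict of every candidate and the exact
expected stage counts.

**Group tables.** Each species gets a single surrogate group whose
contribution encodes a consistent chemical potential (CO₂ far downhill,
biomass precursor uphill, < 2 kJ/mol seeded jitter). Consistency matters:
with arbitrary energies, reorientation in a model without elemental
balance can assemble carbon-creating cycles; the potential plays the role
elemental bookkeeping plays in a curated model.

**qPCR.** Curves are baseline + min(F₀·E^c, plateau) over 40 cycles
(baseline 50, plateau 10⁴, threshold 10³); Ct is the threshold crossing
and the low/high Ct offset encodes the true ratio via ΔCt = log_E(ratio).
Gaussian Ct noise (sd 0.15 cycles) and multiplicative curve noise are
plausible defaults, not measured values. Replicates: 3 low / 2 high.

**Metabolites.** 67 analytes — 13 planted changes (xylose 5.5-fold up at
high CO₂; sucrose, glycine, asparagine, isocitrate down; amino acids
shifted) and 54 nulls — under multiplicative log-normal noise (CV 10 %),
per-sample capture scales (cancelled by TIC normalization), and cell
counts 3× higher at high CO₂. Responding analytes are trace species
relative to the stable bulk: that is the regime in which TIC normalization
is valid at all, and it keeps planted fold changes intact through
normalization. The concordance scenario pairs the 13 planted analytes with
model net-flux records agreeing in direction for 10 and disagreeing for 3
(glycine, isocitrate, sucrose).

## Verification strategy and problem sizes

The LP solver is checked against an exhaustive basic-feasible-solution
enumerator (shared no code with the HiGHS path) on 100 seeded random
networks of ≤ 8 reactions with finite bounds bracketing zero, to 1e-9; one
fixture is additionally cross-checked against cobrapy. Planted-sensitivity
recovery runs 20 blueprints of 40–97 reactions; biomass monotonicity in
the CO₂ bound is checked on a 20-point grid over 5 blueprints; efficiency
recovery uses 50 noisy seeds; fold-change recovery 100 seeds and the null
false-positive control 200 seeds of a 10-analyte null panel. These sizes
keep the default test run and the acceptance script fast while leaving
each check statistically meaningful.

## Known limitations

- Reported headline counts of the original *Chlamydomonas* study
  (enzymes found, reactions added, sensitive-reaction totals) depend on a
  specific base model, database snapshots, and condition fluxes that are
  not distributable inputs; they are treated as descriptive and are not
  reproduction targets.
- Orientation-insensitive deduplication uses species multisets; two
  reactions differing only in compartment placement are considered
  duplicates at the dedupe stage (placement is decided later).
- The SBML interface is core-only (species, reactions, bounds via local
  parameters, objective via a model parameter) — no fbc/groups/layout
  packages.
- The gap filler is greedy shortest-first per dead end, not a global
  minimal-addition optimizer.
- Welch tests on 3-vs-2 replicates have low power; the null simulations
  verify type-I control, not power, at that design.
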