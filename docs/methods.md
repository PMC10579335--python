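# Methods

This note documents the models implemented in `methanesource`, the defaults
they ship with, and what the synthetic-data validation does and does not
demonstrate about real drill-core data.

## Isotopologue bookkeeping

Bulk deltas are interpreted as atom-ratio deltas against VPDB
(¹³C/¹²C = 0.011180) and VSMOW (D/H = 0.00015576). Molecular isotopologue
abundances follow from random assembly of atoms over methane's one carbon
and four equivalent hydrogen sites, giving stochastic relative abundances
(per ¹²CH₄) of R13, 4·RD, 4·R13·RD and 6·RD² for ¹³CH₄, ¹²CH₃D, ¹³CH₃D and
¹²CH₂D₂; the clumped anomalies multiply the doubly substituted terms by
(Δ/1000 + 1). The five tracked species are renormalized to mole fractions;
isotopologues with ≥3 rare substitutions (relative abundance ≲10⁻¹⁰) are
carried only as an implicit remainder. The conversion and its inverse are
exact by construction; round-trip error is below 10⁻⁹ ‰ (property-tested on
1000 random natural compositions).

## Equilibrium calibration

The temperature dependence of equilibrium Δ¹³CH₃D and Δ¹²CH₂D₂ is shipped as
polynomial fits in 1/T (Eldridge et al. 2019, ACS Earth Space Chem.
3:2747–2764), stored in `data/equilibrium_calibrations.yaml` and pluggable:
any calibration supplying coefficients and a validity range can be
substituted. The file is audited at load — curves must be positive and
strictly decreasing on the declared range (273.15–1273.15 K; values above
1000 K are a smooth extrapolation of the published fit). The inverse
thermometer brackets the unique root on the validity range and bisects to
< 0.01 K; forward-then-inverse closes within 0.1 K everywhere.

## Mixing model and PMM inversion

Mixing is performed in isotopologue mole-fraction space, where it is exactly
linear; δ and Δ of mixtures are read off the mixed fractions. This captures
the physically real nonlinearity of clumped values under mixing (a 200‰ δD
contrast between Δ=0 endmembers yields a ≈ +18‰ Δ¹²CH₂D₂ anomaly at 50:50).

The inversion minimizes the σ-weighted sum of squared residuals over
whichever of the four isotope quantities are finite (at least two are
required), using a dense grid (step 10⁻³) and a three-point parabolic
refinement, clamped to [0, 1]. The estimator is deterministic, global on the
grid, and transparent; forward–inverse consistency is better than 10⁻³ in f.

Uncertainty is propagated by Monte Carlo: per draw, each endmember is
sampled uniformly within its low/high box and each observed quantity from a
Gaussian at its stored 1σ; the point inversion runs per draw. Two models —
microbial–thermogenic and microbial–abiotic — are fitted and their draws
pooled with equal weight. The reported PMM is the pooled mean × 100 with the
pooled extremes as the full range; per-model means are retained in the
output so the pooling is auditable. Equal pooling is the right estimator
precisely when the non-microbial source is ambiguous: if the data are known
to come from a single non-microbial source, the matched single-model result
should be read instead, since the mismatched model shifts the pooled mean by
up to ~10 percentage points. A residual-weighted (χ²) model average was
evaluated and rejected: with realistic endmember boxes the per-draw residual
is dominated by box jitter rather than model fit, making the weights noisy.

Defaults: n_draws = 1000, explicit integer seed (a fixed seed gives
bit-identical tables), measurement σ of 0.1, 0.5, 0.3 and 1.5‰ for δ¹³C, δD,
Δ¹³CH₃D and Δ¹²CH₂D₂ — the scale of current high-resolution isotope-ratio
mass spectrometry. Samples whose clumped values fall outside plausibility
limits for natural methane (Δ¹³CH₃D ∉ [−10, 10]‰, Δ¹²CH₂D₂ ∉ [−60, 60]‰) are
flagged and skipped by an optional validity filter rather than inverted.

Shipped endmembers (`data/endmembers.yaml`) are reconstructions placed at
the centroids of published genetic source fields — microbial sedimentary
methane, early-to-late-maturity thermogenic gas, and
serpentinization/geothermal abiotic gas — with boxes wide enough to span the
fields. They are configuration, not code, and real applications should
replace them with site-specific values.

## Energetics

Reactions 1–9 cover hydrogenotrophic (4H₂ + CO₂ → CH₄ + 2H₂O), acetoclastic,
formatotrophic, methanol reduction with H₂, and disproportionation of
methanol, the three methylamines, and DMS. Three stoichiometries are
corrected relative to commonly printed forms so that every reaction passes
an automated element/charge audit: formate disproportionation takes 2 H₂O on
the product side, methanol reduction yields H₂O (not H₂), and the
methylamine substrates are the neutral aqueous amines CH₃NH₂, (CH₃)₂NH and
(CH₃)₃N, under which the printed coefficients balance exactly. Because
several pathways are disproportionations, all energies are normalized per
mole of carbon transferred (n_C = 1, 2, 4, 1, 4, 4, 4, 12, 4).

ΔG°(25 °C) comes from Hess's law over `data/species_thermo.csv` (Amend &
Shock 2001, CODATA and NBS values; the di-/trimethylamine and DMS aqueous
entries are tagged `est` — estimated from gas-phase values — and contribute
a few kJ/mol C of systematic uncertainty to reactions 7–9). Temperature
correction uses the Gibbs–Helmholtz relation with constant reaction
enthalpy, supported on 273–473 K; the pressure correction (a ΔV·ΔP term of
second order against the substrate-range envelopes at a few hundred bar) is
deliberately omitted, with the `P` argument kept as the hook.

Activities are molal concentrations times Davies activity coefficients,
log₁₀γ = −A z² (√I/(1+√I) − 0.3 I), with A(T) from a standard polynomial fit
(0.509 at 25 °C); neutral species take γ = 1. The Davies form is used
slightly beyond its nominal range at seawater ionic strength (0.7 mol/kg) —
adequate for the ±1-charged species involved, and a deliberate simplification
versus a full speciation code. ΣCO₂ is converted to CO₂(aq) by pH speciation
with pK₁ = 6.35, pK₂ = 10.33 (25 °C constants, configurable). Methane below
the detection limit takes a stand-in activity of 10⁻⁷ (configurable) and
flags the output row as imputed.

Unmeasured substrates are spanned by `data/substrate_ranges.yaml`: detection
limits as minima and published porewater maxima from organic-rich marine
sediments as maxima (acetate 1 µM–4 mM, formate 0.1–100 µM, methanol
0.01–69 µM, each methylamine 0.01–10 µM, DMS 1 nM–1 µM). The envelope
evaluates ΔG at the box minimum, geometric mean (log-uniform centre;
arithmetic available via `mean_rule`) and maximum. Since substrates are
reactants, the maximum concentration gives the most negative ΔG; envelope
ordering and monotone widening with range width are property-tested.

## Synthetic sites

Three templates emulate archetypes of sill-driven thermal alteration:
`no_sill` (SMTZ 45 mbsf, 220 °C/km), `deep_cooled_sill` (SMTZ 80 mbsf,
230 °C/km, sill at 350 mbsf, two methane peaks with the middle one largest)
and `shallow_hot_sill` (SMTZ 100 mbsf, 700 °C/km, sill at 130 mbsf, large
deep methane peaks). Functional forms are the simplest shapes consistent
with real down-core structure, not fits to any dataset: logistic sulfate
decay reaching < 5% of the seawater value at the SMTZ, Gaussian methane
peaks on a logistic rise that begins just below the SMTZ (1.2 × SMTZ depth —
anaerobic methane oxidation keeps the sulfate zone at trace levels), a
Gaussian sulfide peak at the SMTZ, linear temperature, and dissolved H₂
rising log-linearly with temperature from 1 nM at the seafloor (thermodynamic
poise plus thermogenic H₂ production at depth). Concentrations carry
multiplicative lognormal noise (log-σ 0.05) from a single seeded PCG64
generator; σ = 0 recovers the analytic curves exactly. The porewater methane
detection limit is 2×10⁻⁵ mol/kg.

The forward isotope simulator mixes the microbial endmember with a
*composite* non-microbial endmember — the exact 50:50 isotopologue blend of
the thermogenic and abiotic endmembers — using a ground-truth microbial
fraction that declines linearly through the methanogenic zone. The composite
default mirrors the ambiguity the pooled two-model estimator is designed
for; a single-source truth can be requested by passing either parent
endmember directly. Every generated table carries a truth record (depths,
fractions, endmembers, noise, seed) sufficient to regenerate it exactly.

What passing tests show — and what they do not. Parameter recovery on these
synthetics (means within ~2 points of truth, full-range coverage 100% at
20 depths × 1000 draws) validates the estimator under its own assumptions:
endmembers known up to a box, Gaussian measurement noise, two-source mixing.
Real profiles violate these in ways the generator does not emulate — AOM
overprints on the clumped values, diffusive isotope fractionation,
depth-dependent endmembers, three-source mixing — so real-data PMM
uncertainties are larger than the synthetic ranges suggest.

## Numerical choices and edge cases

- Grid step 10⁻³ in f with parabolic refinement; the grid point wins
  whenever the parabola is degenerate or worse.
- Bisection tolerance 0.005 K for the thermometer (reported: < 0.01 K).
- Zero-crossing of down-core ΔG series: shallowest negative-to-positive sign
  change, linearly interpolated; an exact zero followed by positive values
  counts as a crossing at that sample.
- Per-row failures in profile computations (missing columns, bad values) are
  recorded as flagged rows with a reason, never aborts; empty inputs yield
  empty outputs with success status.
- Outputs are written with `float_format="%.10g"`, making identical
  configuration + seed byte-identical on disk.

## Problem sizes

Default validation sizes — 20-depth profiles, 1000 Monte-Carlo draws per
model and depth, 100 random forward–inverse problems — were chosen as the
smallest sizes at which the Monte-Carlo summaries are stable to well under
the tolerances being checked; the full suite and the acceptance script each
run in well under a minute on one CPU.

## Known limitations

- The thermodynamic table is small and partly estimated; swap in a curated
  table via the `table` argument for publication-grade absolute energies.
- No pressure correction, no Setchenow salting-out for neutral species, no
  multi-component speciation.
- Source-field polygons are coarse rectangular reconstructions for
  classification, not display-accurate digitizations.
- Three-endmember simultaneous unmixing and kinetic-overprint modelling are
  out of scope; the validity filter only flags, it does not correct.
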