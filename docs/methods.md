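# Methods

## Scope and model chain

The package chains five computational stages, each consuming only the
outputs of the previous one:

sigma profiles → activity coefficients → (a) liquid–liquid equilibrium →
partition ratios → solvent-system selection, and (b) infinite-dilution
screening of NADES formulations → ranking and correlation with extraction
contents. Around this core sit the CCC retention arithmetic and the
calibration/annotation utilities, which are exact bookkeeping rather than
modelling.

## Activity-coefficient engine

**Formulation.** Single-reference COSMO-SAC (Lin–Sandler family), one
sigma profile per species on the canonical 51-bin lattice (−0.025 …
+0.025 e/Å², step 0.001). The exchange energy combines the electrostatic
misfit (α′/2)(σ_m+σ_n)² with a donor/acceptor hydrogen-bond term gated by
the cutoff σ_hb; the hb term can be switched off in `EngineParams`
(default on, because the target solutes are polyphenols whose polar
surface is hb-active). Defaults: α′ = 16466.72 and c_hb = 85580
kcal·Å⁴·mol⁻¹·e⁻², σ_hb = 0.0084 e/Å², a_eff = 7.5 Å², z = 10,
r_norm = 66.69 Å³, q_norm = 79.53 Å² — the widely used open constant set,
kept as a versioned dataclass so a different parameterisation is one
object away.

**What the engine is not.** It is not a reparameterisation of any
commercial COSMO-RS solver, and no attempt is made to reproduce such
floats (different parameterisations, conformer ensembles and cavity
levels make that meaningless for an open stand-in). Worked-example
partition ratios therefore enter the selection stage as bundled reference
*inputs*, while the engine itself is validated by properties: exact pure
and ideal-mixture limits, Gibbs–Duhem consistency on random binaries
(residual < 1e−5 by central differences), equality with an independently
coded dense fixed point on small grids, and monotone trends across a
polarity-ordered synthetic solvent family.

**Numerics.** The segment self-consistency is solved by 50 damped
successive-substitution sweeps (damping 0.5) as a warm start, followed by
Newton iterations on F(ln Γ) = ln Γ + ln Σ p Γ W with the dense analytic
Jacobian, batched over liquids; pure successive substitution alone was
found to contract with a factor ≈ 0.99 for strongly hydrogen-bonding
liquids (thousands of sweeps to 1e−10), while the Newton polish converges
in a handful of steps. Newton steps are capped at ±2 in ln Γ to preserve
the warm start's basin. Tolerance 1e−10 on max |F|, iteration cap 500;
non-convergence raises, carrying the residual.

**Infinite dilution** is evaluated exactly at x_solute = 0 — the solute is
appended to the solvent state with zero mole fraction, so the solvent
ensemble is unperturbed. The Staverman–Guggenheim term is written in
ratio form (φ_i/x_i = r_i/Σx_jr_j, etc.), which is finite at x_i = 0; no
small-x extrapolation or its tolerance enters any screen. Temperatures
are explicit arguments everywhere; the workflow convention (equilibrate
the solvent system at 20 °C, run the separation at 28 °C, screen NADES at
25 °C) lives in the calling code and datasets, not in the engine.

**Electrolytes and acids.** Choline chloride is treated as one neutral,
undissociated ion-pair species with a single profile; no Debye–Hückel
term. Organic acids are their protonated neutral forms.

## Liquid–liquid flash

Two-phase isoactivity flash: distribution coefficients K_i = γ_l,i/γ_u,i
updated by successive substitution (log-damped, 0.5) around a
Rachford–Rice solve for the phase fraction; convergence when
max_i |x_u γ_u − x_l γ_l| < 1e−8. Two seeds are tried — a phase enriched
in the most apolar component (lowest polar surface fraction) and one in
the most polar — and the lower-Gibbs solution is kept; a returned split
must also strictly lower the Gibbs energy of mixing versus the single
phase, otherwise "no phase split" is reported (so is convergence to
identical phases, composition distance < 1e−6). Phase labels follow CCC
practice: the phase with the lower ideal-mixing mass density is "upper".
Mixing volumes are ideal (v = Σx_i v_i from the registry's liquid molar
volumes); no excess-volume model is applied because none is specified by
the workflow being automated. The flash is cross-checked against a
2001-point dense Gibbs-energy scan with a convex-hull common-tangent
construction on demixing binaries (agreement to 1e−3 in mole fraction).

## Partition ratios and selection

K_D = (γ^∞_lower/γ^∞_upper)·(v_lower/v_upper), stationary-upper over
mobile-lower (head-to-tail). Phase swapping is an explicit operation and
inverts K_D exactly. Selection applies the sweet-spot window
0.4 ≤ K_D ≤ 2.5 to every target, then a minimum separation factor
(default `min_alpha = 1.3` — a package choice, documented as such, since
the workflow's own threshold is only implied by rejecting a pair at
1.07), then ranks by the larger minimum target K_D with α as tie-break.
That ranking key generalises the practical argument that a more strongly
retained earliest target leaves less room for co-elution of polar matrix
components at the solvent front. Values are rounded to two decimals only
at reporting; internal math is unrounded.

## NADES screening

Formulations are (HBA, HBD, molar ratio, water wt%). The canonical ratio
set is {3/1, 2/1, 1/1, 1/2, 1/3}; other ratios (e.g. the prepared 1/5
system) must be explicitly flagged, which catches typos in bulk lattices.
Water content is mass of water over total mixture mass; the default water
lattice is 0–70 wt% in steps of 10 (the screen's stated span, with the
step a package choice). The screen is deterministic, caches cells by
(spec, solute, T), and records per-cell engine failures in-grid rather
than aborting. Whether a formulation is actually *preparable* (some
recrystallise) is an experimental annotation carried on the bundled
specs, never predicted. The bundled overview slice (`heatmap_specs`) puts
choline chloride and betaine systems at 3/1, sugar HBAs at 1/3, all
anhydrous.

Correlation of predicted ln γ with measured contents uses Pearson r with
the two-sided t-test p-value; pairing is by spec identity with unpaired
specs dropped and reported, and zero variance raises.

## CCC bookkeeping

S_F = V_S/V_C·100; V_M = (1 − S_F/100)·V_C + V_ext; V_R = V_M + K_D·V_S
and its exact inverse. The periphery volume V_ext defaults to 0 and is an
explicit optional correction — bench values are rig-specific and no
default can be justified. Fraction indices are 1-based with half-open
volume intervals [start, end), so a boundary volume belongs to the later
fraction. Peak widths exist only for simulated chromatograms (plate
model, σ = V_R/√N, baseline width 4σ); the planner never invents widths
for real peaks. Resolution R_S = 2|ΔV_R|/(w_a + w_b).

## Quantification and annotation

Calibration is ordinary least squares of response on concentration (≥5
distinct levels); LOD = 3.3·s_res/slope and LOQ = 10·s_res/slope from the
residual standard deviation — the ICH-style convention, adopted because
published limit values rarely state their formula. Contents are
c·V·dilution/m in mg/g dry weight; out-of-range responses warn, negative
back-calculated concentrations raise. Annotation matches measured m/z
against neutral monoisotopic masses minus one proton (1.00728 Da) at a
0.5 Da default tolerance (nominal-resolution ion-trap data); ties go to
the nearest mass, and the assignment count is monotone in the tolerance.

## Synthetic data

Every input is generated by seeded pure functions of (spec, seed) with
`numpy.random.default_rng` — no global state.

* **Profiles** are sums of Gaussian bumps discretised on the canonical
  lattice, renormalised so each bump contributes its area exactly; bins
  beyond the hb cutoff populate the hb sub-profile. The stilbenoid-like
  default carries an apolar bulk within ±0.01 e/Å² and hb wings at −0.017
  (phenolic donors) and +0.012 e/Å² (acceptor oxygens); the dimer
  analogue is the same shape on a larger cavity surface. Wing areas were
  fixed once so that, with the default engine constants, the solvent
  ordering is chemically sensible (polyalcohol NADES ≪ water < hexane for
  the stilbenoids, ln γ rising monotonically with water content); they
  were not revisited afterwards.
* **Registry profiles** for the HEMWat solvents, HBAs and HBDs follow the
  same recipe, with cavity volumes tied to the registry's liquid molar
  volumes. Registry molar masses and densities are handbook-style values;
  molar volumes of room-temperature solids are subcooled-liquid estimates,
  flagged in the provenance column.
* **Chromatograms** place Gaussian peaks at the retention volumes implied
  by their K_D; fraction masses integrate the exact Gaussian CDF, so mass
  conservation holds to truncation at the run end.
* **Extraction studies** draw content = a − b·ln γ + ε, ε ~ N(0, σ²),
  defaults a = 1.0 mg/g DW, b = 0.4 mg/g DW per ln-unit, σ = 0.15 mg/g DW,
  triplicates — magnitudes matching bench extraction contents of a few
  mg/g DW with replicate scatter of a few percent. Negative draws clip to
  zero with a warning.

## What passing tests do and do not show

The synthetic generators emulate the *structure* of the real inputs —
polarity-ordered solvents, bimodal stilbenoid profiles, plate-shaped
peaks, linear content-vs-ln γ studies with replicate noise — not their
quantum-chemical or instrumental detail: no conformer ensembles, no
temperature-dependent hb damping, no detector response curves, no matrix
interferences. Green property suites therefore certify that the
*pipeline arithmetic and trends* are right (limits, conservation laws,
oracle equality, monotone orderings, planted-truth recovery), and that
the worked-example bookkeeping reproduces its reference values exactly;
they do not certify absolute activity coefficients or partition ratios
for real molecules, which require externally computed sigma profiles
dropped into the same interfaces.

## Problem sizes

Default test and acceptance runs use: 51-bin profiles throughout; ≤5-bin
toy grids for dense-oracle equality; 100 random binaries for
Gibbs–Duhem; one 2001-point Gibbs scan per oracle flash; screening
lattices of ≤64 cells in tests and 52 specs in the overview slice; and
200 seeded repeats for the extraction-study null and spread checks.
These sizes keep the full suite in seconds while exercising every code
path at the dimensions the real workflow uses.
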