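# Methods

This note documents the models, numerical choices and limitations behind
`quenchbind`. It is the package's own account of its science; every number
quoted here is computed by the test suite or `scripts/acceptance.py`.

## Fluorescence titration model

A fixed concentration of human serum albumin (1×10⁻⁵ mol/L in the reference
design) is titrated with ligand over the eight-point grid
0, 0.40, 0.80, 1.00, 1.60, 2.40, 3.20, 4.00 ×10⁻⁵ mol/L. The zero-ligand
point defines F0; all analyses work on the ratio F0/F and are therefore
invariant under uniform intensity rescaling (tested property).

**Inner-filter correction.** `F_corr = F_meas · base^((A_ex + A_em)/2)`.
The conventional correction uses decadic absorbances (base 10), and that is
the default. Some sources write the same formula with base e; because the
two differ materially (10^0.1 = 1.259 vs e^0.1 = 1.105 at total absorbance
0.2), the base is an explicit option, never a silent guess, and is recorded
in every series and report. The correction is exactly inverted by the
simulator's distortion operator with the same base (round-trip tested to
1e-9 relative).

**Stern–Volmer.** OLS of F0/F on [Q] over the quenched points (q > 0); the
zero point serves only as the F0 reference, so a two-point design reduces to
the exact two-point slope. The free-intercept fit is the default — real
data carry small offsets — with a warning when the intercept leaves
1 ± 10%; a through-origin variant regresses (F0/F − 1) on [Q]. R² is
1 − SS_res/SS_tot on the regressed variable, clamped to [0, 1], and defined
as 1 for an exactly flat, exactly fitted response. Kq = Ksv/τ0 with
τ0 = 1×10⁻⁸ s (configurable). Mechanism: Kq strictly above the diffusion
limit 2×10¹⁰ L mol⁻¹ s⁻¹ ⇒ static; the boundary itself is classified
dynamic because the criterion is "significantly greater". A strictly
decreasing Ksv(T) corroborates static quenching.

**Double-log binding.** OLS of log10((F0−F)/F) on log10[Q]. Kb is always
10^intercept; n is the slope. Kb is reported in L/mol even when n ≠ 1 —
the field's convention, dimensionally inconsistent, and noted as such.
Points with F ≥ F0 at q > 0 (no quenching signal, undefined log) are
dropped with a warning; at least three usable points are required.
Affinity classes: weak < 10⁵ ≤ good ≤ 10⁶ < strong (boundaries inclusive on
the "good" side), monotone in Kb by construction.

Note that the fitted intercept is an extrapolation of 4–5 decades from the
measured concentration range (log10 Q ∈ [−5.4, −4.4]) to log10 Q = 0. Small
slope noise therefore produces large scatter in recovered Kb — see
*Parameter recovery* below.

**Van't Hoff thermodynamics.** ΔG = −RT ln K with R = 8.314 J mol⁻¹ K⁻¹;
ΔH from the two-point relation on the extreme temperature pair, or, with
more than two temperatures, from OLS of ln K on 1/T (flagged as an
extension beyond the two-temperature design). ΔS = (ΔH − ΔG)/T, so
ΔG = ΔH − TΔS holds to machine precision by construction (tested). Force
typing from the signs: ΔH>0 ∧ ΔS>0 ⇒ hydrophobic; ΔH<0 ∧ ΔS<0 ⇒ hydrogen
bond + van der Waals; ΔS>0 with ΔH≤0 ⇒ hydrophobic + electrostatic; ΔS<0
with ΔH≥0 ⇒ hydrogen bond + van der Waals; an exactly zero ΔH or ΔS leaves
the profile unclassified rather than forcing a call.

When externally reported ΔH/ΔS are supplied alongside the K(T) values, the
module reports both and warns on sign or >25% magnitude disagreement; the
computed values remain authoritative for classification. This matters for
the reference system: the published K values rise from 298 K to 310 K,
which forces ΔH > 0 through the Van't Hoff relation, while the published
table prints ΔH < 0. The package deliberately does not reverse-engineer the
published numbers.

**Site-marker competition.** Relative change |K_free − K_marker|/K_free per
marker; the site of the largest change is assigned unless the top two
changes differ by ≤ tie_margin (default 0.02 relative), in which case the
call is *indeterminate*. The reference system's constants produce changes
0.977 (warfarin) vs 0.962 (ibuprofen): a 0.015 gap, flagged as a near-tie
at the default margin and assigned to Sudlow site I at margin 0.01. A
marker constant above K_free (apparent enhancement) is allowed but flagged.

## Cocrystal physicochemistry

**Elemental composition.** Mass fractions from IUPAC standard atomic
weights via RDKit's periodic table (C 12.011, H 1.008, N 14.007, O 15.999);
fractions sum to 100% within 0.01 (tested). Relative error
|measured − theoretical|/theoretical ×100 against a default 5% tolerance.
The published theoretical H for apigenin (3.70%) is reproducible only with
H = 1.000 while the cocrystal's 4.11% requires H = 1.008; standard weights
are used throughout (giving 3.73% for apigenin) and the measured values
still pass at 5%.

**Cumulative release.** Q_n = [A_n + (V₁/V₂)·Σ_{i<n} A_i]·100, where A_i is
the dose fraction measured at draw i, V₁ the sampled volume and V₂ the
medium volume (medium replaced after each draw). This reading makes
Q₁ = A₁ and corrects later draws for previously removed analyte, matching
standard dissolution practice; with V₁ = 0 the profile is the raw
fractions. A_i as an absorbance reading was considered and rejected — the
package takes concentrations as pre-converted (no UV calibration fitting).

**Solubility.** Enhancement as the product/parent ratio with a
nearest-integer fold label (0.81/0.28 ×10⁻⁵ mol/L ⇒ 2.89, "3-fold"). The
published solubility table labels its low-temperature row 278 K while the
surrounding text says 298 K; the preset stores 298 K and documents the
conflict.

**PXRD.** A product peak with no parent peak within the angular tolerance
(default 0.2° 2θ; ten instrument steps of 0.02°) is new; ≥1 new peak ⇒
new crystalline phase, else superposition (physical mixture). Widening the
tolerance can only shrink the new-peak set (tested monotonicity). Peak-list
comparison only — no profile fitting, background subtraction or indexing.

## Synthetic data

The simulators define the package's study conditions:

* grid: the eight-point design above; F0 = 1000 a.u. (arbitrary — analyses
  are scale-invariant);
* noise: multiplicative Gaussian, F ← F·N(1, sd), default sd = 1%, applied
  to every intensity including the reference point and never to
  concentrations (volumetric preparation assumed exact); intensities are
  floored at a tiny positive value;
* optional inner-filter distortion with per-concentration absorbance
  coefficients, the exact inverse of the correction;
* dissolution: first-order release C(t) = q_inf(1 − e^(−kt)) — a stand-in
  kinetic model whose only job is exercising the release arithmetic — with
  per-draw fractions constructed so the release formula recovers C(t)
  exactly in the noiseless case;
* determinism: every simulator is a pure function of its scenario,
  including the seed.

What the simulator does **not** emulate: photobleaching, drift, scattering,
emission band shapes or blue shifts, combined static+dynamic (upward-curved)
Stern–Volmer behaviour, or real dissolution kinetics. Passing tests
therefore demonstrate the correctness of the analysis chain on its own
model assumptions, not robustness to instrument artefacts.

**Parameter recovery.** The standard recovery experiment
(`synthetic_data.recovery_medians`) simulates 200 replicates at 1% noise
and reports median recovered (K, n). Per-replicate recovered K scatters
widely (sd of log10 K ≈ 0.57 at K = 4.57×10⁶, n = 1.48) because the
intercept extrapolates far outside the data range, so even the 200-replicate
median carries ≈±10% sampling scatter; the experiment is defined with
master seed 42 so the reported medians are a fixed, reproducible summary.
At that definition the medians recover K within 10% and n within 5% for
both reference parameter sets (4.57×10⁶, 1.48) and (0.67×10⁶, 1.36).

## Pipeline and reports

`run_pipeline` executes any subset of stages from one config mapping;
stages are independent and a failure in one is recorded without aborting
the others. All randomness derives from the single top-level seed. Reports
serialize to schema-versioned JSON (`quenchbind.report/1`) with units in
every field name; unknown fields are rejected on read; reports contain no
timestamp, so identical configs give byte-identical output. Known
inconsistencies of the reference tables (intercept vs reported Kb factor
~10, irreproducible ΔH/ΔS, the 278/298 K label) are asserted as warnings,
never reproduced as numbers.

## Limitations

* Single-site double-log model only; no Scatchard/Hill or global
  multi-temperature fits.
* Two-point Van't Hoff by design; no heat-capacity (curved) models.
* Intensities at a single analysis wavelength; no spectral processing or
  instrument formats.
* Formula parser handles plain element–count strings (no parentheses,
  hydrates or isotopes).
* The recovery experiment's ±10% median tolerance on K is close to its own
  sampling noise at the study's noise level; conclusions about K from a
  single eight-point titration at 1% noise carry much larger uncertainty
  than the point estimate suggests.
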