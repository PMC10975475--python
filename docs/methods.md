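# Methods

This note documents the models and procedures implemented in `pktranslate`,
the defaults and units of the parameters that matter, the numerical
choices, and the known limitations — in particular where the whole-body
model deliberately departs from the commercial simulator used in the
original study.

## Units and conventions

Concentration ng/mL, time h, dose mg/kg (`per_kg` basis) or mg
(`absolute`), clearance L/h with explicit per-kg variants, volume L.
Conversions happen only at I/O boundaries; a unit mismatch inside a dataset
is a raised error, never a silent rescale. Report tables render at 3
significant figures. Below-LLOQ records are flagged and excluded from AUC
and regression, never dropped from the dataset.

## Non-compartmental analysis

AUC uses the trapezoidal rule; the default is the linear method, with
linear-up/log-down selectable (log interpolation on strictly decreasing
positive segments). For IV bolus profiles C0 is back-extrapolated
log-linearly from the first two samples before integration; without this,
sparse early sampling of a steeply decaying profile loses the 0→t₁ area
(for the rat kinetics here, elimination half-life ≈ 0.3 h, that loss is
~5–8% of AUC, which is also why the linear method on the study's sparse
schedule biases CL low by a few percent — the analysis driver uses
linear-up/log-down for the IV arms).

λ_z is the slope of a log-linear regression over the last k points after
(and excluding) Tmax; k is chosen to maximize adjusted R² with k ≥ 3, ties
going to more points. The AUC tail is C_last/λ_z; results where the tail
exceeds 20% of AUC₀₋∞ are flagged. CL = Dose/AUC₀₋∞; MRT = AUMC/AUC for a
bolus; Vss = CL·MRT. Group summaries are mean ± sd per sex, and Tmax ties
report the earliest time.

Bioavailability policy: the species mean of per-group F values; the dog
mean (57.4%) is the typical human prediction and the rat mean (14.7%) the
lower bound, reflecting the closer dog–human hepatocyte stability.

## Absorption-rate estimation

A one-compartment first-order absorption model (Bateman function) is fitted
to mean oral concentration–time data by least squares on log
concentrations: concentrations span orders of magnitude, and the original
estimation tool's error model is unstated, so log-scale residuals are the
package's choice. Multi-start: Ka ∈ {0.1, 0.5, 1, 2, 5}/h crossed with a
terminal-slope initialisation of Ke, Nelder–Mead local search, 1e-9
parameter tolerance. The Bateman curve is exactly invariant under
(Ka, Ke, V/F) → (Ke, Ka, V·Ke/Ka), so every fit has a flip-flop twin;
estimates are canonicalised to Ka > Ke and the ambiguity is flagged. The
human policy takes the species minimum and maximum as the range and their
midpoint as the typical value (1.46 h⁻¹ from rat 2.34 and dog 0.589).

## Allometric scaling

Per-animal clearances for extrapolation are the sex-averaged per-kg study
means times the representative body weights (rat 0.245 kg, dog 7.21 kg,
human 60 kg). The SSS default exponent is 0.66, back-calculated so the rat
entry of the study's prediction table reproduces to 3 figures (0.75
selectable); SSAS fixes 0.75 on unbound clearance; TSAS is an ordinary
log-log regression; FCIM uses the published Tang–Mayersohn form
33.35·(a/Rfu)^0.77; HBF transfers the extraction ratio CL_a/Q_h,a onto the
target hepatic blood flow.

The study's own TSAS, FCIM and HBF entries are not reproducible from its
printed inputs with these standard forms (its appendix equations were not
available), so those printed values are treated as reference inputs, not
reproduction targets. The headline human values are produced by the
aggregation operation — the dog-based single-species mean for CL
(138 mL/min ≙ 8.3 L/h) and the all-method mean for Vss (41.8 L) — which is
deliberately insensitive to the method-variant ambiguity.

Øie–Tozer: f_ut = f_up·V_r / (Vss/BW − V_p − f_up·V_e − (1−f_up)·(RE/I)·V_p)
per source species, and the human Vss/kg rebuilds the same decomposition
with the cross-species mean f_ut. With the physiology-library volumes
(Davies & Morris/Obach compilation) the rat/dog mean f_ut is 0.0040 and the
human prediction 17.6 L, within 5% of the study's 17.1 L; the difference is
constant sensitivity, and all volumes are config-overridable.

## First-in-human dose

BSA method: HED = NOAEL·(Km_a/Km_h)·BW_h with Km factors 3/6/20/37
(mouse/rat/dog/human, FDA 2005 table); the dog row reproduces exactly
(1.62 mg), while the reported rat HED (14.4 mg) implies Km_rat ≈ 5.9 — the
library keeps 6 and the discrepancy is recorded rather than fitted.
Exposure method: human-equivalent AUC = AUC_a·f_up,a/f_up,h (unbound
exposure matching), then Dose = AUC·CL/F with AUC in ng·h/mL ≡ µg·h/L.
A 10-fold safety factor yields the MRSD. Steady-state AUC₀₋₂₄ values are
inputs (toxicokinetic summaries), not recomputed.

The dose plan takes the minimum MRSD over all recommendations, rounded down
to a 0.01 mg granularity (0.16 mg here); the adopted starting dose
(0.15 mg), anticipated-effect level (2 mg) and maximum dose (3 mg) are
judgment values pinned by configuration, with the computed ranges
(exposure-method HEDs 2.77–7.07 mg, BSA extrapolation of the minimum
effective animal doses ≈ 4.86 mg) attached as provenance.

## Whole-body PBPK model

Structure: lung, heart, brain, muscle, adipose, skin, bone, kidney, spleen,
gut, liver, a lumped rest compartment, arterial and venous blood, an oral
depot and a gut lumen. All tissues are perfusion-limited; gut and spleen
drain into the portal vein. Organ volumes and perfusion fractions follow
the Brown et al. compilation, with the rest compartment closing both the
volume and the flow balance exactly (construction fails if flows do not sum
to cardiac output within 1e-9). Cardiac output is anchored so that hepatic
blood flow matches the library values (rat 55.2, human 20.7 mL/min/kg).

Partitioning: Rodgers–Rowland acids/neutrals composition equations at
plasma pH 7.4 and intracellular pH 7.0 — extracellular and intracellular
water with a Henderson–Hasselbalch ionization correction (XZP-5610 is a
diprotic acid, pKa 3.39 and 10.13, >99.99% ionized at pH 7.4),
neutral-lipid and neutral-phospholipid terms in 10^logP, and albumin-type
binding inferred from f_up through the tissue:plasma albumin ratio (clamped
at zero association for weak binders). Kp = Kpu·f_up. The liver coefficient
is overridden by the calibrated K_P,L = 37.0, applied to both species
(the source gives no species annotation).

Clearances: the measured systemic plasma clearance (rat 1.93, human
0.138 L/h/kg) acts on the liver outflow plasma-equivalent concentration
C_liver/K_P,L (well-stirred placement); renal clearance is zero (biliary
dominance). Biliary clearance (0.18 L/h/kg) acts on the liver tissue
concentration — the parameter is labelled like an intrinsic clearance in
the source — and transfers drug to the gut lumen; a plasma-concentration
basis is selectable. The lumen reabsorbs at the absorption rate constant
with reabsorption fraction 0.9 by default (most of the dose is excreted in
bile and recirculates; both knobs are config-exposed), the remainder going
to faeces.

Absorption: first-order depot → portal inflow with an absorbed fraction
f_abs. `calibrate_f_abs` sets f_abs so the model's oral bioavailability
matches the species NCA value — computed from one probe simulation (the
model is linear in f_abs), not double-counted against hepatic extraction.
For the human model the target F (57.4%) exceeds the maximum the model can
produce under its hepatic extraction (~47%), so f_abs clips at 1; the
residual gap is reported, not hidden.

Numerics: the system is linear time-invariant between dose events, so the
integrator (BDF, rtol 1e-8, atol 1e-10 mg) is given the constant Jacobian;
output on a 0.05 h grid augmented with geometrically refined points after
each dose (venous mixing is ~100× faster than the output step; without the
refinement the trapezoidal AUC of an IV bolus is overstated). Mass balance
— cumulative input versus in-system plus eliminated amounts — is checked
at every output time and stays below 1e-6 relative; dose linearity is exact
up to integrator tolerance. The time-domain solution was verified against
the exact stationary integrals −M⁻¹y₀ of the rate matrix.

Virtual population: lognormal multipliers with median 1 on CL, the Kp set,
and Ka (default CVs 30/30/50%; the original figure's band parameters are
unstated, so these are documented substitutes), pointwise percentile bands,
fully seeded.

### Known structural limitation: oral liver:plasma ratio

With a flow-limited liver and all elimination hepatic, the oral-dose
liver:plasma AUC ratio equals K_P,L exactly — the total hepatic elimination
integral must equal the absorbed dose, which pins liver AUC, while F and
emergent CL rescale plasma AUC by the same factor. A simulator with finite
cellular permeability (as used in the original study) is not bound by this
identity, which is how it can predict an oral ratio of ~11.8 with
K_P,L = 37. This package therefore reports the model's *systemic*
(IV-disposition) liver:plasma AUC ratio — 15.7 in rat and 17.5 in human,
both within 2-fold of the observed/reported values (12.9; 10.3/13.5) — and
discloses that the oral ratio is structurally fixed at K_P,L. Relatedly,
because the measured rat plasma clearance corresponds to blood clearance at
essentially hepatic blood flow, the emergent systemic clearance of the
flow-limited model (1.10 L/h/kg) is below the measured 1.9 L/h/kg; all
resulting plasma Cmax/AUC fold errors stay inside the 0.5–2.0 validation
band used by the study.

## Synthetic data generator

The generators emulate the study designs: single-dose PK studies (one IV
arm plus three oral dose arms, three males and three females each, default
sampling 0.083–24 h), the radiolabel tissue-distribution study (24 rats,
destructive sampling, six animals per 0.5/2/8/24 h timepoint), transwell
transport at 1/5/30 µM, equilibrium dialysis at 0.2/2/10 µM, and
0–120 min hepatocyte depletion. Between-subject variability is lognormal
(default CV 20%) on CL, V and Ka; residual error is lognormal (default CV
15%, typical bioanalytical variability — the study reports only mean ± sd
summaries, so these are loosely calibrated defaults). Both multipliers use
the mean-1 convention. Every generator records its truth parameters and
seed in a manifest, and every downstream estimator inverts its zero-noise
output exactly.

What passing the zero-noise inversion tests shows is internal consistency
of the estimator/generator pair; it does not validate assay-specific
artifacts absent from the generator (nonspecific binding in transwells,
destructive-sampling correlation structure, radioactivity counting error),
so real-data performance can differ.

## Problem sizes used in tests and drivers

The test suite and acceptance checks run at desk scale by design: NCA
oracles on dense grids (Δt = 0.02–0.05 h), the absorption-rate noise study
at 200 seeds × 8 timepoints, PBPK simulations over 24–96 h on the default
grid, and a 100–200-subject virtual population at a coarsened 0.2 h grid.
These sizes keep every check under a minute while leaving the measured
quantities well inside their tolerance bands.
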