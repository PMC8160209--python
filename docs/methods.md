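# Methods

## Whole-body model

The subject is a closed circulatory loop of 14 well-mixed compartments.
Venous blood feeds the lung (flow = cardiac output), the lung feeds arterial
blood, and arterial blood distributes to eleven systemic tissues whose flows
sum exactly to cardiac output. Gut and spleen drain portally into the liver,
whose total inflow is hepatic artery + portal flow; all other tissues drain
to venous blood. The liver flow in the physiology table is the hepatic
artery only.

Tissue uptake is perfusion-limited: each tissue equilibrates instantaneously
at its total tissue:plasma coefficient Kp, so the venous outflow of tissue t
carries blood concentration C_t·B:P/Kp_t. Elimination is a separate term
−CL_organ·C_out,blood for liver (a single parameter lumping hepatic
metabolism and biliary excretion) and kidney. Writing elimination as a
separate flow-independent term keeps units consistent (L/h × µg/L) and makes
Dose/AUC_blood approach CL_hepatic + CL_renal in the low-extraction limit;
an alternative printed form that places the clearance term inside the
perfusion parentheses is dimensionally inconsistent and was not used.

Dosing: IV boluses are initial conditions in venous blood; infusions are a
constant-rate venous input over their duration; oral doses enter a gut-lumen
depot absorbed at first-order rate k_a with fraction f_oral reaching gut
tissue (the remainder is tallied as unabsorbed). Because absorbed drug
enters gut tissue and transits the liver, hepatic first pass emerges from
the mass balance — f_oral means fraction absorbed × gut escape only.

All mechanisms are linear, so the state equations are dA/dt = M·A + u(t) on
an amount basis with constant M. Integration uses LSODA with the exact
Jacobian at rtol 1e-8 / atol 1e-10 (defaults; fits use 1e-6/1e-9), sampled
at requested output times. A fixed-step RK4 mode exists for parity with
legacy fixed-step runs and is not the default. Cumulative hepatic, renal and
unabsorbed amounts are integrated as extra states so the mass-balance
residual |dose − (body + depot + eliminated)|/dose is directly observable;
it stays below 1e-9 in routine runs and below 1e-6 under fit tolerances.

Note one consequence of dosing into venous blood: immediately after an IV
bolus the venous concentration spikes above the well-mixed value until the
dose has circulated (time constant V_ven/CO ≈ 40 s for the default adult).
Profiles sampled from ~5 minutes onward — the convention of the bundled
sampling designs — are unaffected, but integrals started at t = 0 on a
coarse grid would overweight the spike.

## Physiology

One human-adult reference subject ships as data (tissue CSV + global YAML):
70 kg, cardiac output 336 L/h, hematocrit 0.45, blood volume 5.6 L, organ
volumes summing to 70 L with rest-of-body closing both volume and flow
balances. Tissue composition (water/lipid fractions, acidic phospholipid,
intracellular pH 7.0, tissue:plasma protein ratios) follows the
Rodgers–Rowland tabulations; plasma lipid fractions and the erythrocyte
record (f_iw 0.603, AP 0.5 mg/g, pH 7.22) likewise. Other species or
subjects are additional tables, not code.

Pre-fit data-consistency rules (validation reports, never exceptions):
total clearance must lie below cardiac output; B:P ≥ 1 − hematocrit; an
*observed* NCA Vd_ss below blood volume flags impossible data. The Vd_ss
floor applies to observed data curation only, never to simulated outputs,
and violations are flagged rather than auto-corrected since the upstream
handling of such records is a data-curation policy, not a model property.

## Partition coefficients

The mechanistic route predicts Kpu (tissue : unbound plasma); Kp = Kpu·fu_p.
Moderate-to-strong monoprotic bases (pKa ≥ 7, the conventional class split)
use the acidic-phospholipid form with ionization ratios X = 10^(pKa−pH_iw),
Y = 10^(pKa−pH_p); the affinity constant ka_AP is back-calculated from B:P
through the erythrocyte equation and clamped at zero. Acids, weak bases,
neutrals and zwitterions use the albumin-type form with the protein
association back-calculated from fu_p and plasma lipid composition, scaled
by the tissue:plasma protein ratio, clamped at zero. Neutral phospholipid
acts as 30% neutral lipid + 70% water. Adipose substitutes the
vegetable-oil lipophilicity log P_vo:w = 1.115·logP − 1.35 for the
neutral-lipid term only.

A physiological cap truncates runaway predictions: Kp > cap is replaced by
the cap (default 50; max(50, 5·Vd_ss,obs/V_body) when an observed Vd_ss
exists) and the affected tissues recorded. The direct-Kp configuration
applies one scalar to all 12 tissue compartments including the eliminating
organs (a flag reverts liver/kidney to mechanistic values, since published
descriptions of single-Kp optimizations leave this choice open).

A caveat on monotonicity: at fixed composition and fixed binding constants,
Kp is non-decreasing in logP. When ka_AP is re-derived from a fixed B:P at
each logP (as the hybrid fit does for bases), rising lipid partitioning
lowers the inferred phospholipid affinity, and Kp of phospholipid-rich
tissues can dip slightly before the lipid term dominates.

## Non-compartmental analysis

Linear trapezoid AUC/AUMC; Cmax/Tmax by scan with ties broken to the
earliest time; λ_z by log-linear least squares on the last 3 points after
Tmax, extended one point at a time (max 6) while r² improves, requiring a
positive decline. Terminal sufficiency is the OR of two clauses — last
concentration < 0.25·Cmax, or observed post-peak span ≥ 2·ln2/λ_z — the
permissive reading when both are listed; the clauses that fired are recorded
in the output. When sufficient, AUC_∞ = AUC_0t + C_last/λ_z,
AUMC_∞ = AUMC_0t + C_last·t_last/λ_z + C_last/λ_z², MRT = AUMC_∞/AUC_∞,
Vd_ss = Dose·MRT/AUC_∞. The Vd_ss formula is applied to oral profiles
unchanged (no bioavailability or absorption-time correction), so oral MRT
contains mean absorption time and oral Vd_ss overestimates the
distributional volume; outputs carry the route tag so reports can separate
them. Zero concentrations are allowed in the trapezoid and excluded from
the log-linear fit.

## Fitting

Free parameters are those without experimental values: always k_a, plus
logP (hybrid) or the effective Kp (direct); B:P joins when unmeasured.
Bounds: logP ∈ [−2, 7], Kp ∈ [0.05, 50] (pre-cap), k_a ∈ [0.01, 10] h⁻¹,
B:P ∈ [1 − Hct, 5]. The cost is
10^(mean over {Cmax, Tmax, AUC_0–t} × arms of |log10(pred/obs)|), evaluated
with the simulated profile sampled at the observed times so that both sides
are summarized identically and perfect parameters score exactly 1. Datasets
whose observed profile is all zero are skipped with a warning.

Phase 1 is a deterministic full-factorial grid (default 8 points per free
dimension; k_a and Kp on a log scale, logP and B:P linear — logP is already
a logarithmic quantity and its range spans zero). Failed evaluations score
+∞ without aborting the grid. Phase 2 runs bounded Nelder–Mead (scipy) in
the same transformed space from the best 3 grid points (fatol 1e-6,
xatol 1e-4 in transformed units, max 500 iterations — the scaled studies
below use 300). The Kp cap applies inside every evaluation. The full
evaluation trajectory is kept with the grid/descent boundary marked, and
compounds are fitted independently (optionally via a process pool; results
are worker-count independent).

## Synthetic studies

The generator emulates a multi-compound literature PK corpus: compounds
drawn across acid / strong-base / weak-base / neutral / zwitterion classes
(default mix 25/30/15/15/15%), logP ~ U[−1, 5], class-specific pKa ranges
(acid 3–6, strong base 7.5–10.5, weak base 4–7), fu_p ~ U[0.01, 1],
B:P ≥ 1 − Hct, k_a ~ LogUniform[0.1, 3] h⁻¹, f_oral ~ U[0.5, 1]. Clearance
is drawn so the data-generating terminal half-life lands in 4–12 h (blood
clearance 1–70 L/h, well below cardiac output); every compound passes the
consistency checks by construction. The hidden truth record is either a
global effective Kp ~ LogUniform[0.5, 8] (default — the regime in which the
three fitting configurations are strictly nested in flexibility) or a true
logP driving the mechanistic equations. Sampling designs: 12 log-spaced
points, IV 0.083–48 h and oral 0.25–48 h. Residual error is multiplicative
log-normal with σ = sqrt(ln(1+cv²)), default CV 15%, the standard
proportional PK residual model; cv = 0 reproduces the noiseless curve
bit-for-bit. Truth records are written to a separate file that the fitting
interface never reads.

What the generator does not emulate: inter-study heterogeneity between
literature sources, digitization error structure, assay quantification
limits, nonlinear kinetics, and inter-subject variability. Passing recovery
tests therefore demonstrates correctness and identifiability of the
estimation machinery under the stated error model, not performance on
heterogeneous literature data.

## Study sizes and observed behavior

The bundled end-to-end study uses 10 compounds × 2 arms (IV + oral) at CV
15% with the optimizer settings above; it completes in about 90 s on one
CPU. On noiseless bundles the fits recover the generating parameters
essentially exactly (cost 1 at the optimum). Under 15% noise the fitted
cost typically lands *below* the cost at the true parameters — two free
parameters against six noisy summary statistics leave room for benign
overfitting — and parameter error is estimation noise rather than optimizer
failure. Median recovery error for the effective Kp is usually well inside
25% but single-study medians over 10 compounds scatter widely (±8–10
percentage points); k_a error is bounded below by the sampling design, since
the cost sees k_a mainly through oral Tmax, which a 12-point log-spaced
design quantizes in ×1.6 steps. The mean GMFE ordering
direct-Kp ≤ hybrid-logP ≤ fixed-mechanistic follows from model nesting and
is reproduced robustly.

## Numerical choices and degenerate inputs

Solver tolerances as above; amounts may dip to −1e-9·dose from round-off
and are clipped only in reported concentration series. Cost evaluations that
fail to simulate score +∞; an entirely infeasible grid raises. λ_z is absent
(not an error) when fewer than 3 positive post-peak points exist or the
slope is non-negative; extrapolated NCA outputs are then absent and the
profile is excluded from extrapolated accuracy rows only. r² is computed on
raw values (a log-scale variant is available by flag). Identical inputs and
seed give bit-identical fits; the grid order is fixed and Nelder–Mead is
deterministic.

## Known limitations

Perfusion-limited tissues only (no permeability-limited sub-compartments or
transporter kinetics); linear clearance; no enterohepatic recirculation; no
dissolution/solubility model for oral absorption; one subject per study (no
population variability); the erythrocyte and tissue composition tables are
adult-human reference values, not subject-specific.
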