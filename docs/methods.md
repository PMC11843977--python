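# Methods

## Model structure

The package implements a linear, time-invariant compartmental system in
antibody amounts (nmol). Canonical units are hours, litres and nanomoles;
tables printed in L/min are converted on ingestion.

**Circulation.** A plasma pool feeds the lung; the lung feeds 14 platform
organs (heart, kidney, muscle, skin, brain, adipose, thymus, liver, spleen,
pancreas, small/large intestine, bone, "other") and the five reproductive
organs in parallel. Splanchnic organs drain through the liver. Venous
outflow is organ plasma flow minus lymph flow; all interstitial lymph
(filtered with reflection coefficient σ_IS = 0.2) collects in a lymph-node
pool that empties into plasma at the total lymph flow. The lung's plasma
flow is derived at load time as Σ_organs Q_i/(1 − 1/200), which closes the
circulatory fluid balance exactly. A parallel blood-cell circulation is
carried for structural completeness; with no plasma↔cell partitioning it
stays empty after an IV dose.

**Organ disposition.** Per organ: transcapillary filtrate
(1−σ_V)·L·C_V into the interstitium; pinocytosis CLup·C from both the
vascular and interstitial sides into a shared endosomal space; linear FcRn
binding at fixed free-receptor concentration; degradation (kdeg) of unbound
endosomal antibody; bound antibody exits at the pinocytosis rate, a fraction
FR recycling to the vascular side and 1−FR transcytosed to the
interstitium. Holding free FcRn constant (no receptor depletion, no
competition by endogenous IgG) keeps the system linear; dose-doubling
doubles every trajectory, which the test suite asserts at 1e-8 relative.

**Reproductive organs.** Each adds an epithelial-barrier endosome fed from
the interstitium, with FcRn binding and kdeg as above; the transcytosed
(1−FR) fraction is delivered to the lumen. The testis barrier is the BTB:
its FcRn is ten-fold lower (4.98e-6 M) and its uptake rate (CLup_BTB) and
the testis endothelial uptake rate (CLup_E) are organ-specific estimates;
all other epithelia share the global CLup and endothelial FcRn. The
epididymal barrier (BEB) volume is itself an estimated parameter and
supersedes the literature epithelial volume inside the model. A paracellular
interstitium→lumen convection (1−σ_ep)·L·C_IS with σ_ep = 0.95 (the source
equations name the term but give no value; the driving concentration was
ambiguous between interstitial and epithelial and is implemented as
interstitial) completes the luminal input.

Vas deferens, seminal vesicle and prostate interpose a smooth-muscle layer
between interstitium and epithelium. No ODE for it is printed anywhere we
know of, so it is modelled as a well-mixed transit compartment: forward
uptake IS→Mu→Ep and recycle Ep→Mu→IS, all at the organ's epithelial uptake
clearance; `ModelOptions(muscular_transit=False)` collapses it to a
pass-through. The seminal vesicle keeps an interstitial sub-compartment
(its tabulated volume exists) for structural uniformity even though some
anatomical descriptions list only four compartments.

**Luminal chain.** Testis lumen → rete testis transfer is pinocytotic
(CLup_BTB × rete-testis volume): the printed rete-testis equation is
self-referential and was rewritten from flux consistency with the
surrounding prose. The rete testis empties into the epididymis lumen at
Q_retetestis, then Q_ep, Q_vd, Q_sv carry fluid down the chain and Q_pg
leaves the body — the only route out other than endosomal degradation. Both
sinks are explicit model states, so the audit dose = remaining + degraded +
excreted holds to < 1e-6 relative (measured ~1e-11).

The interstitial balance in the source material contains duplicated uptake
terms and mixed subscripts; rather than transcribing it, every compartment's
balance here is assembled from conservative transfer primitives (each efflux
is some other state's influx), and global conservation is enforced exactly
by absorbing ~1e-11 assembly round-off into the matrix diagonal.

## Parameters

| parameter | default | units | origin |
|---|---|---|---|
| CLup | 0.55 | L/h per L endosome | platform-style default, editable YAML |
| kon_FcRn | 8.06e7 | 1/(M·h) | platform-style default |
| koff_FcRn | 6.55 | 1/h | platform-style default |
| kdeg | 42.9 | 1/h | platform-style default |
| FR | 0.715 | – | platform-style default |
| FcRn (endothelium) | 4.98e-5 | M | fixes the BTB value ten-fold lower |
| FcRn (BTB) | 4.98e-6 | M | literature assumption |
| σ_V / σ_IS / σ_ep | 0.95 / 0.2 / 0.95 | – | tight-junction convention; brain σ_V = 0.99 |
| CLup_BTB | 6.78e-2 | L/h/L | literature estimate (mouse fit) |
| CLup_E (testis) | 1.27e2 | L/h/L | literature estimate; implausibly precise SE as printed, used as-is |
| Q_retetestis | 1.2e-8 | L/h | literature estimate, CV% 283 (poorly identified) |
| Q_ep / Q_vd / Q_sv / Q_pg | 1.6e-4 / 2e-5 / 9.4e-5 / 1.6e-5 | L/h | literature estimates |
| BEB volume | 2.8e-4 | L | literature estimate |
| body weight | 0.028 / 0.25 / 6.2 / 71 | kg | mouse/rat/monkey/human defaults, config-exposed |
| antibody MW | 150 | kDa | intact IgG, config-exposed |

MRT physiology for all four species ships cell-for-cell from the published
tables (the mouse table's "Blood Flow" column is read as blood-cell flow:
its ratio to the plasma-flow column is exactly 0.45/0.55, i.e. hematocrit
0.45). Several printed values are anatomically implausible (epididymal
plasma flow of 0.23 L/h in a mouse; a human testis whose epithelial volume
is ~80% of the organ); they are ingested as printed and flagged by
`validate_physiology` as warnings, never silently altered. Lymph flow and
endosomal volume are derived by the Q/200 and 0.5%-of-organ rules where not
tabulated.

**Platform physiology is a synthetic stand-in.** The non-reproductive organ
tables of the published platform model are not redistributable here, so
`platform_mouse_synthetic.csv` is constructed from standard rodent
physiology conventions (representative organ volumes and plasma flows, 5%
vascular volume, hematocrit 0.45, endosomal 0.5%, literature-typical
interstitial fractions) and is fully overridable. Consequence: absolute
simulated exposures are not expected to match published mouse values
(reported plasma AUC ~87,500 h·nM vs ~62,000 here), and the very high
simulated testis exposure mostly reflects the extreme printed CLup_E
estimate interacting with this stand-in. Relative and structural results —
conservation, linearity, causal ordering, sensitivity rankings, parameter
recovery — do not depend on this substitution.

**Allometric translation.** Flows scale with body weight^0.75 and volumes
with body weight^1 (multiplicative, so mouse→rat→human equals mouse→human).
Cross-species MRT values present in the packaged tables are used as printed;
platform organs and blood pools are scaled.

## Numerics

The system is linear, so two solution paths coexist: `solve_ivp`
(BDF/LSODA, analytic constant Jacobian, rtol 1e-8 / atol 1e-10 defaults)
and an exact matrix-exponential propagator (`method="expm"`) that steps
through the requested grid reusing per-Δt kernels. The two agree to
~1e-6 relative; estimation and sensitivity default to the propagator
(~10 ms per full solve at 124 states), simulation to the stiff solver.
IV boluses are instantaneous plasma-amount jumps at segment boundaries;
the integration restarts rather than smoothing the discontinuity.
Stiffness comes from FcRn binding (kon·FcRn ≈ 4000/h) and the testis
endothelial uptake (127/h); states are amounts, not concentrations, so
tiny sub-compartment volumes do not stiffen the system further.

AUCs use the linear trapezoid with no terminal extrapolation (a
log-trapezoid variant exists behind a flag). ABC is implemented as ×100:
the source's printed defining equation says ×10, but every value it reports
is consistent only with ×100. The reported testis ABC (1.70) differs in the
second decimal from the ratio of the printed rounded AUCs (1.7085); the
printed %PE values for seminal vesicle and prostate are not reproducible
from the printed AUCs under the stated formula in either orientation. The
worked-example checks therefore pin the internally consistent entries
(plasma, testis, epididymis, vas deferens %PE; epididymis, vas deferens,
seminal vesicle ABC) and carry the rest at computed values.

## Estimation

Naive-pooled maximum likelihood: all records enter one Gaussian likelihood
with SD(t) = δ_intercept + δ_slope·Y(t) evaluated at the model prediction.
With one measurement per animal (destructive sampling) there is no
within-animal replication to support random effects, so no population model
is attempted. Optimisation is L-BFGS-B on log-parameters with box bounds
(default ×100 both sides of the initial value); staged fits (barrier
parameters first, then luminal flows) are supported. Standard errors come
from the inverse observed information (central finite-difference Hessian in
log space, relative step 1e-3) with delta-method back-transformation;
95% CIs are log-normal. Non-simulable parameter proposals return a penalized
objective instead of raising.

Known property: because the residual SD depends on the prediction, the
likelihood's log-SD term slightly rewards parameter values that lower
predictions. At the study's design size (75 records) this produces a
finite-sample bias of roughly +0.5 SD on log CLup_BTB (which lowers testis
predictions), and the asymptotic 95% CIs then cover the generating values
at ≈90–97% per parameter (aggregate ≈92%, measured over 60 simulation
seeds) rather than the nominal 95%. This is a property of the estimator-plus-design, not
an implementation defect; the Monte-Carlo recovery check therefore assesses
coverage in aggregate across the five identifiable parameters, where the
binomial noise of 20 replicates does not dominate the verdict.
Q_retetestis is structurally near-unidentifiable under this design (its
reported CV% is 283) and the fitting API warns when it is requested.

## Synthetic data

The generator reproduces the study design: single 10 mg/kg IV bolus, plasma
sampled at 5 min, 6, 24, 96, 168 h; five MRT tissues at 6, 24, 96, 168 h;
three replicates per point; perfused tissue reconstruction. Noise is
Normal(0, SD(t)²) with the combined error model, truncated at zero
(truncation affects <0.5% of records at default noise; it introduces a
small positive bias only where SD is large relative to the signal). The
fitted residual magnitudes were never published, so the defaults
δ_slope = 0.2, δ_intercept = 0.1 nM are package test settings. What passing
recovery tests show is that the estimator recovers parameters from data the
model itself generated — they cannot certify the model against real tissue
data, inter-animal variability, assay censoring (LLOQ ~1 ng/mL is not
simulated) or model misspecification.

## Problem sizes used in checks

Conservation and linearity checks run the full 124-state mouse model over
0–168 h; sensitivity uses a 0.5 h AUC grid (ordinal conclusions are
unchanged at 1 h or 0.1 h); the recovery experiment uses 20 replicates of
the 75-record study design. These sizes were chosen so the whole
verification cycle completes in minutes on a laptop while keeping every
Monte-Carlo margin well away from its threshold.

## Known limitations

- No target binding (TMDD), no subcutaneous or intratesticular routes, no
  FcRn saturation, no female physiology, no ontogeny.
- Whether lymph from MRT organs should carry luminal content is unstated in
  the source anatomy; assumed not.
- Cross-species predictions for reproductive tissues are unvalidated —
  no tissue PK data exist in rat/monkey/human; only the workflow (not its
  accuracy) is exercised for species plasma validation, which requires
  user-supplied digitized datasets.
- The muscular transit layer halves forward flux at quasi-steady state by
  construction; its pass-through alternative bounds the effect.
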