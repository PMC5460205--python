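# Methods

## The model

`mapkqsp` simulates BRAF^V600E-mutant colorectal tumors as a
differential-algebraic system with three layers.

**Signaling (quasi-steady-state algebra).** On the day-to-week time scales
that matter for tumor growth, phosphorylation cascades equilibrate almost
instantly, so the eleven signaling nodes — RTK1 (EGFR), RTK2 (lumped
MET/FGFR-class receptors feeding MAPK), RTK3 (lumped IGF1R/ERBB3-class
receptors feeding PI3K), RAS, BRAF, CRAF, MEK, ERK, PI3K, AKT and the
growth-integrating surrogate S6 — are algebraic Hill functions of their
upstream inputs, re-evaluated at every integrator step.  Each node has a
basal activity `Nb` and a maximal activity `Nt`; genetics enter as parameter
overrides (V600E sets `BRAFb = 0.9`, i.e. 90% of maximal activity without
RAS input; amplifications set `Nt = 5`; activating mutations set `Nb = 0.9`;
melanoma vs colorectal context sets maximal EGFR activity `RTK1t` to 0.1 vs
1).  MEK integrates BRAF + CRAF, so although CRAF is listed after ERK in the
field's conventional ordering, it is evaluated right after RAS — the only
topologically consistent order.

Drugs multiply their cognate node's *whole* activity by
`1 − C^k/(τ_i^k + C^k)`.  Multiplying the whole node rather than only the
RAS-driven increment is essential: a V600E BRAF signals from its basal
activity, and BRAF inhibitors do inhibit it.  A second exposure mode
("generic inhibitor") multiplies the node by a constant `1 − s` (default
`s = 0.95`), used for calibration experiments where only the degree of
target suppression is known.

**Feedback and growth (ODEs).**  Four first-order transit compartments
carry the delayed negative feedbacks (DUSP on ERK, SPRY on RAS, MYC-type
transcriptional feedback on the receptors, FOXO on RTK3), `dFBj/dt =
rj·(driver − FBj)` with drivers ERK (FB1–3) and AKT (FB4).  The DUSP and
SPRY Hill terms carry gains `Gdusp`, `Gspry` mirroring the receptor-feedback
gain `G13`: the population tables randomize these gains, so they must appear
multiplicatively in the ERK and RAS equations to have any effect.  A fifth
transit state TD1 delays S6 into growth, and cell number follows logistic
growth `dCELLS/dt = (µMAX·Hill(TD1; τg, kg) − δMAX)·(1 − CELLS/VMAX)·CELLS`.
`VMAX` is 10× the baseline tumor burden in vivo (tumors are considered
lethal long before unbounded growth) and 10⁶ in vitro so the logistic term
is inert over 3–4 day cultures.

**PK.**  Cetuximab is IV one-compartment; vemurafenib oral two-compartment
(the parameter table lists V2/F and Q/F for it, which takes precedence over
the one-compartment appearance of its printed ODE); cobimetinib and
GDC-0994 oral one-compartment.  All systems are linear, so trajectories are
propagated by exact matrix exponentials between bolus dose events; tumor
exposure is `partition × blood concentration` with partition 1 by default.
Murine parameterizations multiply `Ka` by the tabulated murine/human factor
and volumes/clearances by factor × (body weight / 70 kg); the tabulated
factors are residuals after linear body-weight scaling, and this
interpretation yields pharmacologically sensible murine exposures
(e.g. monoclonal-antibody-like clearance for cetuximab at ~10 mL/day/kg).
Cetuximab prints no factors and no between-subject variability; it uses
weight scaling alone and fixed parameters.  Dosing conventions: BID = every
12 h, Q1W = every 168 h, 21/7 cycles gate dosing on the first 21 days of
each 28-day cycle, cycle clock starting at the first dose.

## Numerics

Two integration paths exist deliberately.  `simulate_system` is the
reference: LSODA with rtol 1e-6 / atol 1e-9, the algebraic cascade evaluated
inside the right-hand side.  Population-scale work (1000-tumor cohorts, PSO
swarms, sensitivity scans) uses a classical RK4 with fixed step 0.02 days,
vectorized across ensemble members; with PK handled exactly by per-step
matrix exponentials, the remaining six states relax on ≥0.5-day time scales
and the fixed step is far inside the stability and accuracy region.  The
test suite asserts agreement between the two paths both on raw trajectories
(≤1e-6 scale differences) and through the full PK-coupled response chain.

Pre-equilibration matters: with steep negative feedback the naive damped
fixed-point map of the stationarity conditions can oscillate or select the
wrong branch.  Initial states are therefore obtained by *integrating* the
drug-free dynamics (a damped fixed-point pass only provides the initial
guess), which by construction agrees with the reference solver's notion of
baseline.

The prevalence-weighting quadratic program (min ½‖x‖² subject to
bin-membership equalities, Σx = 1, x ≥ 0) is solved in its slack-penalized
form min ‖x‖² + ρ‖Ax − b‖² over x ≥ 0 with ρ = 1e8, which is a
non-negative least-squares problem; exact equality is recovered in the
ρ → ∞ limit and the achieved residuals are reported alongside the weights.
Nonnegativity and normalization are imposed because the weights are
prevalence *probabilities*.  The published bin table's bottom row overlaps
its neighbor as printed; it is read as −100:−50 so the seven bins partition
[−100, ∞).  A clinically populated bin containing no virtual tumor is a
hard error naming the offending (arm, bin) cells.

## Calibration and the shipped parameter ensemble

Most of the 100+ signaling parameters are not individually identifiable.
The package therefore ships an ensemble of 10 seeded particle-swarm
solutions (constriction PSO, w = 0.729, c1 = c2 = 1.49; produced by
`scripts/fit_defaults.py`) calibrated against reference targets encoding
the required cell-line behavior: (i) normalized pERK under 95% BRAF
suppression falling fast and rebounding to ~40% of baseline by 48 h in
EGFR-high (CRC) context but staying suppressed in EGFR-low (melanoma)
context, and (ii) a 72-h growth-phenotype matrix — BRAFi inert in EGFR-high
cells yet effective in EGFR-low cells, MEKi effective in EGFR-high cells
but blunted by MEK mutation/amplification, ERKi effective across all
genetic backgrounds, and the BRAFi+MEKi doublet potent except in MEK-mutant
cells.  The pERK targets use post-treatment times only (2–48 h): the
quasi-steady-state cascade responds to suppression instantaneously, so the
pre-drug baseline is not a point on the treated trajectory.

Calibration is staged.  Stage A fits the cascade and feedback parameters
(19 of them; 60 particles × 300 iterations × 12 runs) to the pERK dynamics
alone, with each swarm seeded by one mechanistically constructed
rebound-capable candidate — the dip-then-rebound basin is narrow, and
unseeded joint fits reliably collapse into flat compromise curves.  Stage B
then fits the growth mapping (tau6, k6, taug, kg, µMAX; 40 × 200) to the
growth-phenotype matrix with the stage-A cascade frozen.  The 10 best of 12
staged solutions by combined MSE form the shipped ensemble.  Search is
log-scaled inside bounds of [1e-3, 10] for Hill half-maxes, [0.5, 6] for
cascade Hill coefficients and [0.1, 20]/day for transit rates; solutions
within 0.1% of a bound are flagged.  The growth-mapping coefficients k6
and kg are capped at 4: the targets do not demand steeper values (the fit
error is essentially unchanged), while steeper solutions turn viability
dose–response into step functions and empty the mid-range response bins —
an unidentified corner of parameter space with pathological side effects.  The feedback gains G13/Gdusp/Gspry are held
at the published population central value (0.5) rather than fitted, since
the population tables randomize them around that value.

Drug-target IC50s (τ_i, k_i) are estimated by pooled nonlinear least
squares on 96-h viability curves of the *sensitive* (fully MAPK-dependent)
cell lines, treating lines as replicates; per-line refits give a %CV, flat
mean curves return an explicit "not estimable" status instead of a number.
When the viability transition spans only one or two dose levels, τ and k
are jointly weakly identified (a steeper Hill with a larger half-max fits
equally well); the estimator therefore accepts a fixed Hill coefficient
when it is known by assay design, and otherwise reports boundary flags and
the per-line spread as identifiability diagnostics.
Xenograft adaptation re-estimates only (µMAX, δMAX, RTK2t) by least squares
on 21-day mean tumor-volume kinetics of control + monotherapies + one
doublet, all signaling and IC50 parameters frozen.

**Clinical growth scale.** The proliferation rate of virtual patients is
not derivable from xenografts: at the xenograft scale (µMAX ≈ 0.23/day)
every treated 8-week outcome is either deep regression or capped growth,
the clinically observed middle response bins are unreachable, and the
prevalence-weighting program becomes infeasible.  The clinical baseline
instead sets µMAX = 0.048/day — from the rule
µMAX · Hill(S6_ss at the population medians) = median death rate +
ln 2 / 120 days, i.e. a typical untreated virtual tumor doubles on the
~4-month time scale, clinically realistic for metastatic colorectal
cancer — with δMAX = 0.04/day (the published population median death
rate).  Full ERK suppression then drives regression at up to the death
rate (≈ −89% over 8 weeks), while partial suppression produces the
near-stasis changes that fill the middle bins.

## Virtual population and trial simulation

Cohorts sample 16 cellular parameters log-normally around published central
values, `P = median·10^η` with η ~ N(0, stated log10 variance).  The
published distributions are unbounded, so three admissibility rules make
every draw a valid tumor: pathway weights *and* feedback gains are clipped
to [0, 1] (a gain above 1 would drive node activities negative); the basal ≤
maximal activity constraint is enforced by raising the maximum to the
sampled basal, preserving the V600E basal BRAF drive when BRAFt samples
low; and candidates whose untreated net growth rate is not positive are
rejected and redrawn (seeded rejection sampling) — a tumor that shrinks
spontaneously could not have presented clinically, and without the screen
drug-independent "responses" contaminate every arm's ORR.  Each tumor also
receives one draw of the 11 PK
random-effect parameters (log-normal, diagonal OMEGA from the published
%CV; the full covariance matrices are not public).  Replicate trials
resample (biology, PK) pairs jointly — a simplification of resampling PK
per patient independently, adopted because responses are precomputed per
tumor.

Tumors are scanned at the end of each 28-day cycle; the primary endpoint is
the best change from baseline across the first two scans (how clinical
waterfalls report "best response within 8 weeks"), and a response (≤ −30%)
is *confirmed* only if still ≤ −30% at the end of cycle 2.  ORR is the
(prevalence-weighted) fraction of responders.  Dose surfaces exploit PK
linearity: the MTD concentration grids are rescaled per dose cell rather
than re-simulated.  Biomarker selection keeps tumors above a weighted
percentile of a parameter and renormalizes weights; the death-boost
scenario multiplies every tumor's δMAX by 1.1.  Biomarker regression fits
per-arm OLS of the simulated % change on z-scored predictors (16 cellular +
11 PK), ranking standardized coefficients.

## Synthetic data: what it does and does not emulate

Every pipeline input has a seeded generator returning (data, truth): pERK
time courses (additive noise, 5% of baseline), 96-h viability curves
(multiplicative 2%; sensitive lines wOR = 1, resistant wOR = 0.85),
21-day xenograft volume series (multiplicative 10%; 13 treatment arms +
control, 8 animals per arm and 10 controls, measured every 3 days), and
binned clinical waterfalls simulated from a ground-truth population.  The
three xenograft truths follow the narrative that distinguishes the in vivo
models: HT29-like (µMAX = 0.23/day, RTK2 at 3.9% of EGFR), CR1472-like
(µMAX = 0.28, RTK2 at 39%, wOR = 0.78) and CRC15-like (µMAX = 0.17).  The
shared in vivo death rate and growth half-max are anchored analytically so
the untreated HT29-like and CRC15-like tumors grow 4-fold and 2.7-fold over
21 days (inverting the logistic closed form).

The generators draw from the same model family they are used to calibrate,
so recovery tests demonstrate estimator correctness and pipeline
consistency — not robustness to structural misspecification, assay
artifacts, or real biological heterogeneity beyond the sampled parameters.
Passing them says the machinery is right, not that the biology is complete.

## Known limitations

* The fitted ensemble is calibrated against reference phenomenology, not
  transcribed from any previously published parameter listing; headline
  clinical predictions (weighted ORRs) therefore carry calibration
  uncertainty beyond Monte Carlo noise, and exact reproduction of published
  point predictions is not guaranteed.
* No time-to-event endpoints, toxicity, dose reductions, or acquired
  (clonal) resistance; the confirmation assessment stops at cycle 2.
* Cetuximab PK is linear (no target-mediated disposition) and its
  population variability is not modeled.
* OMEGA is diagonal; correlations between PK parameters are ignored.
* The quadratic program's H is the identity and weights are unbounded
  above, so a few tumors can carry large prevalence mass when the cohort
  under-represents a clinical bin.
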