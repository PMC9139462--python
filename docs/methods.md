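# Methods

## The signaling model

The model describes growth-factor signaling through the ERBB receptor
family in breast cancer cell lines as a mass-action ODE system
`x'(t) = f(x(t), u(t), p)` with 22 states and 44 reactions.

**Receptor module.** The monomers EGFR, ERBB2 and ERBB3 are synthesized
and degraded (zeroth/first order), and form four signaling-competent
dimers — D_EE (EGFR:EGFR), D_E2 (EGFR:ERBB2), D_E3 (EGFR:ERBB3) and
D_23 (ERBB2:ERBB3) — in one lumped dimerization-plus-activation step.
Ligand binding and receptor activation are not resolved separately:
each ligand input (EGF, TGFa, BTC on the EGFR-containing dimers; NRG1
on the ERBB3-containing dimers) switches on a ligand-specific
dimerization rate constant.  A small basal, ligand-independent
dimerization runs at all times; active dimers are degraded first order.
ERBB4 is not modeled (negligible expression in the four lines the study
conditions represent), and there are no trafficking compartments.

**Drug effects.** The five inhibitors act multiplicatively on the
formation of dimers containing their target receptor (cetuximab,
erlotinib → EGFR; trastuzumab, pertuzumab → ERBB2; lumretuzumab →
ERBB3) through the inhibition factor `1/(1 + k_drug)`; for
co-treatments the single-drug factors multiply.  Two drug activities
beyond plain inhibition are modeled: (i) the ERBB2 antibodies
trastuzumab and pertuzumab induce phosphorylation of the receptor
monomers into signaling-*inactive* phospho states (pEGFR_i, pERBB2_i,
pERBB3_i), a dead-end pool that only dephosphorylates back — these
states contribute to the phospho-receptor observables but not to
downstream signaling; (ii) lumretuzumab induces first-order ERBB3
degradation, enhanced by a factor `1 + e·u_NRG1` in the presence of
NRG1.  Whether the antibody-induced phospho pool feeds a degradation
route is unknown; here it does not.

**Downstream module.** Active dimers drive the two canonical branches.
PI3K activation keeps a per-dimer rate constant (ERBB3-containing
dimers carry the p85 docking sites, so dimer identity matters for the
PI3K/MAPK asymmetry), while c-RAF activation pools the four dimers into
one summed signal with unit weights (per-dimer c-RAF rates would not be
identifiable).  Both branches are chains of catalytic phosphorylation
cycles written in mass action, with the activating kinase as a
catalytic educt: cRAF→pcRAF (dimer pool + basal), MEK→pMEK (by pcRAF +
basal), ERK→ppERK (by pMEK), PI3K→aPI3K (per dimer + basal),
AKT→pAKT (by aPI3K), and the convergence point S6K→pS6K by *both* pAKT
(`phos_S6K_AKT · S6K · pAKT`) and ppERK (`phos_S6K_ERK · S6K · ppERK`),
each with a first-order reverse reaction.  MEK and ERK are single
phosphorylation steps (only the doubly-phosphorylated ERK form is
observed and used downstream).  Mutation states enter as parameter
differences, not extra species: PIK3CA hotspot mutations (MCF7, T47D)
as an elevated basal PI3K activation rate; the KRAS/b-RAF lesions of
MDA-MB-231 are expected to surface as fold changes on basal MEK
phosphorylation and the c-RAF activation ratio.

**Conditions and timing.** Time is in minutes, concentrations in
arbitrary units.  Drugs are present from t = 0, the ligand is a unit
step at t = 60 min (phase I: inhibition only; phase II: stimulation),
and the horizon is 240 min.  Because the rates are piecewise constant,
each condition is integrated in two constant-rate legs and the ligand
switch needs no event handling.

**Initial values.** Cells are assumed at steady state before treatment.
Each downstream pair (and the PI3K pair) is a conserved pool whose
total abundance is a parameter; the steady-state system replaces one
rate equation per pool with the conservation constraint and is solved
by damped Newton iteration (integration fallback), to residual
`< 1e-10 · max(1, max x)`.  Receptor synthesis rates are calibrated so
the steady-state receptor-containing material matches the per-line
abundance targets.  Steady-state parameter sensitivities follow from
the implicit-function theorem at the solved fixed point.

**Observation model.** Fifteen observables per cell line mirror an RPPA
panel: eight phospho readouts (pEGFR, pERBB2, pERBB3 summing the
receptor's active dimers plus its inactive phospho state; pcRAF, pMEK,
ppERK, pAKT, pS6K) and seven totals (tEGFR, tERBB2, tERBB3, tMEK, tERK,
tAKT, tS6K summing every state containing the protein; total c-RAF is
the omitted total).  Each observable is
`y = log10(scale · Σ states + offset)` with scale > 0, offset ≥ 0 and
Gaussian noise of standard deviation σ per observable on the log10
scale.  Totals weight each state once (the antibody binds the complex);
material bookkeeping (where D_EE counts two EGFR) is a separate notion
used for conservation checks.

## The synthetic study

The generator emulates the study design: MCF7, T47D and MDA-MB-231
panels of 4 ligands × (5 drugs + control) = 24 conditions sampled at
{0, 15, 30, 60, 65, 75, 90, 120, 180, 240} min, and a reduced SKBR3
panel of 2 ligands (EGF, NRG1) × (pertuzumab, trastuzumab, lumretuzumab
+ control) = 8 conditions at {0, 60, 75, 120, 240} min — 80 conditions
in total; one luminal panel yields 24 × 10 × 15 = 3600 merged records.
Three replicates receive i.i.d. Gaussian noise (default sd 0.05) on the
log10 scale and are merged by the arithmetic mean.

Ground-truth kinetics are drawn log-uniformly within ±0.1 decades of a
curated baseline (shared across cell lines, mirroring the finding that
most kinetic rates are common), with subtype structure on top: receptor
abundances follow the qualitative pattern luminal = ERBB2/ERBB3-rich,
MDA-MB-231 = EGFR-dominant, SKBR3 = ERBB2-amplified (representative
values in arbitrary units, not absolute per-cell protein amounts), and
mutation-state multipliers give the luminal lines
elevated basal PI3K activation, MDA-MB-231 a strongly elevated basal
MEK phosphorylation with a reduced c-RAF activation ratio, and SKBR3
PI3K-biased downstream kinetics.  The configuration is designed so the
flux phenotypes of the subtypes (AKT-dominant luminal steady state with
a transient MAPK shift under EGF; MAPK-dominant MDA-MB-231; strongly
AKT-dominant SKBR3) emerge from the drawn truths; the tests verify them
at the default seed, and individual draws near the regime margins can
blur single features (the 0.1-decade jitter accumulates multiplicative
spread along the cascades).

The generator does **not** emulate spot-level RPPA structure, slide or
batch effects, dilution series, replicate-specific scaling (the
BlotIt-style harmonization of real RPPA data), receptor trafficking, or
ligand depletion (inputs are unit steps).  Passing tests therefore
demonstrate correctness of the estimation machinery under the model's
own error assumptions, not robustness to RPPA artifacts.

Viability data follow the affine law
`y = α1 + β1·AUC_pAKT + β2·AUC_pS6K` on the log2 fold-change scale
(defaults α1 = −0.8, β1 = 0.005, β2 = 0.004, chosen so responses span
roughly one log2 unit); ligand-only reference rows are zero by
construction and the intercept absorbs the control level.

## Estimation

The objective is `−2 log L = Σ_i [((yD_i − y_i(p))/σ_i)² + 2 ln σ_i]`
with one σ per observable.  All parameters are estimated as log10
values (default bounds [−5, 3]).  The σ are free parameters; the fitter
concentrates them out analytically (per-observable closed-form argmin,
floored at 1e-6), which is exactly equivalent to joint estimation and
removes 15 coordinates from the optimizer.

Gradients come from forward sensitivities: the augmented system
(states plus one 22-vector per free parameter, parameter-major) is
integrated by LSODA with an analytic block-diagonal Jacobian; the
sensitivity components use a relaxed absolute tolerance (1e-5 against
1e-9 for states, relative tolerance 1e-6) — gradient components need
far less resolution than trajectories, and the residual gradient error
(~1e-4 relative) is below the optimizer's termination resolution.
Within one objective evaluation the phase-I leg is shared across
conditions with the same drug set.  Local fits use L-BFGS-B; multistart
draws log-uniform starts within the bounds, is deterministic given the
seed, and returns the best start (best-of-k is non-increasing in k for
nested start sequences).  Failed simulations map to a large finite
objective so the optimizer retreats rather than crashing.

**Profile likelihood.** Each parameter is stepped in both directions,
re-optimizing the rest; the 95% CI is the crossing of
optimum + 3.84 (χ², 1 df).  The public default targets an objective
increase of 0.1–0.5 per step (max 100 steps per direction); the
recovery experiment widens the band to 0.4–1.2 — with the threshold at
3.84 a finer band buys resolution the CI does not need at several times
the cost.  Steps are *accepted* and the next step adapted (rather than
rejected and re-computed); the initial step is scaled from the profile
curvature; and when a finite-difference Hessian of the objective is
supplied (one gradient evaluation per parameter), each re-optimization
is warm-started at the Schur-complement prediction of the compensating
parameters.  Identifiability labels: crossing on both sides →
identifiable; no crossing with the bulk of profile points
indistinguishable from the optimum (within 0.05) → structurally
non-identifiable (the tails may still rise where a compensating partner
saturates at its bound); anything else → practically non-identifiable.
The reduction report lists non-identifiable parameters with suggested
actions and never edits the model.

## Cell-line adaptation (L1)

A new cell line inherits the base parameters p_i with multiplicative
fold changes r_i (p_i* = p_i·r_i) penalized by λ·Σ|log10 r_i| (penalty
on the log10 scale, consistent with the parameter transform); receptor
abundance parameters stay unpenalized.  The non-smooth problem is
solved exactly by the positive/negative split (ρ = z⁺ − z⁻, z± ≥ 0),
which is smooth with bound constraints.  Per λ (default grid: 20 points
log-spaced over [1e-2, 1e3]): penalized fit warm-started from the
previous path point; exact L1 zeros (|log10 r| < 1e-3) fixed;
unpenalized refit of the survivors; then fold changes whose *refit*
estimate stays below 0.05 in |log10 r| (≈12%, the measurement-noise
scale) are also judged compatible with zero and the refit is iterated
to a fixed point.  The second rule matters: L1 shrinkage bias on a true
effect is otherwise compensated by small nonzero values on correlated
null candidates at every λ, and the exact active set never appears on
the path.  λ is selected by AIC = (refit −2 log L) + 2·(active + other
free parameters), ties toward larger λ.

Candidate choice is an identifiability question: forward and backward
rates of one phosphorylation cycle are quasi-equilibrated at the RPPA
sampling resolution (their residual-sensitivity correlations on a
four-ligand panel are 0.92–1.00), so only their ratio is recoverable
and exact set recovery among such pairs is impossible.  The planted
fold-change study therefore scans eight mutually separable candidates
(one rate per cycle plus dimer-layer turnover rates, pairwise
sensitivity correlation < 0.85), while the mutation-state parameters of
the subtype narrative (basal MEK phosphorylation, c-RAF activation
ratio, …) are exercised as a sign-recovery check: adapting the luminal
model to TNBC-like or HER2-positive-like synthetic kinetics must select
no wrong-sign fold change and must recover the defining features
(elevated basal MEK for the TNBC regime; reduced c-RAF activation ratio
for the HER2-positive regime).

## Proliferation regression

Signaling features are computed per condition from simulated
trajectories resampled to a canonical 1-min grid over the stimulation
phase [60, 240] min, for pAKT, ppERK, pS6K and the pooled active
dimers: AUC (trapezoid), peak height, half-life (first time after the
peak at which the signal drops to half of it, capped at the phase end
with a flag), and maximal upward slope (largest forward difference).
Feature selection standardizes the features and runs a 5-fold
cross-validated lasso path with the 1-SE rule; the final reduced model
`y = α1 + β1·AUC_pAKT + β2·AUC_pS6K` is ordinary least squares on the
two unstandardized AUC features.  Co-treatment predictions simulate the
two-drug condition (whose dimer-formation rates carry the product of
the single-drug inhibition factors), extract the two AUCs and apply the
fitted affine law with no refitting.

## Flux analysis

The flux of a reaction is `v = k_eff · Π educts` (condition modifiers
included).  The S6K dominance score is
`log10(v_ERK→S6K / v_AKT→S6K) = log10(phos_S6K_ERK·ppERK) −
log10(phos_S6K_AKT·pAKT)` (the shared S6K educt cancels); positive
means MAPK-dominant, negative PI3K-dominant — the ratio is oriented so
that this sign convention holds.  Points where either flux vanishes are
flagged NaN rather than raising.

## Verification experiments and problem sizes

* Parameter recovery: one merged MCF7 panel (3600 records, noise sd
  0.05), 15 free parameters spanning all parameter classes (others
  fixed at truth), bounds = baseline configuration ±2 decades, single
  L-BFGS-B start at the baseline configuration (the jittered truth is
  never shown to the optimizer), then profiles of all 15 with the
  Hessian-guided settings.  Runs in roughly ten minutes on one CPU.
* Planted fold-change recovery: per seed, three of the eight separable
  candidates receive fold changes of 0.5–0.7 decades with random sign;
  data are a four-ligand no-drug panel (600 merged records); λ grid
  8 points over [10^-0.5, 10^2.5]; exact active-set agreement is scored
  over ten seeds.  Runs in roughly five minutes.

## Numerical choices, degenerate inputs, limitations

* ODE tolerances: rtol 1e-6 / atol 1e-9 for trajectories (1e-8/1e-10
  in the plain simulation API); see above for sensitivity components.
  State non-negativity is enforced by clipping at output (mass action
  cannot cross zero exactly; integrator undershoot is at tolerance
  level).
* Zero rate constants are legal everywhere (reactions switch off);
  a zero-synthesis network settles to an empty receptor layer.
* The steady-state solver raises when Newton plus three
  relaxation-by-integration attempts fail; objective evaluations map
  such failures to a large finite value.
* Exact AIC ties break toward the sparser (larger-λ) model.
* Lasso coefficients below 1e-10 after coordinate descent are treated
  as zeros; constant feature columns are dropped with a warning; a
  constant response yields an intercept-only model.
* The model inherits the study's scope: no ERBB4, no SRC species, no
  receptor trafficking, no stochastic kinetics, no in-vivo/ADCC
  effects, no IGF-R/cMET crosstalk.  Calibration on the real deposited
  RPPA dataset is out of scope here; all statistical guarantees are
  demonstrated on synthetic data generated by the model itself.
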