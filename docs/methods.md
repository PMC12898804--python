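# Model and methods

`bbbqsp` is a quantitative-systems-pharmacology simulator of blood–brain
barrier (BBB) integrity and relapse dynamics in relapsing–remitting
multiple sclerosis (RRMS), built to evaluate the SCO-spondin-derived
peptide NX210c as a barrier-restoring therapy, alone or combined with
standard-of-care (SoC) immunotherapies.

## Barrier model

The barrier is summarised by a tight-junction-protein (TJP) composite
`tjp ∈ [0,1]` (claudin-5/occludin, 1 = healthy age-40 baseline), an
endothelial density, pericyte coverage, and an accumulated inflammatory
damage burden `d ≥ 0`.

**Ageing/disease decline.** `tjp` follows first-order decay toward a floor,

    tjp'(t) = −k (tjp − tjp_floor),   k = k_h · (m if RRMS else 1),

with `k_h = 0.010 /yr`, floor fraction 0.30, and disease multiplier
`m = 1.9004`. The law is a modelling choice — the decline could equally be
linear or saturating at these horizons — picked because it is bounded,
analytically integrable (the discrete stepper uses the exact exponential
update and is tested against the closed form), and calibratable: `m` is
fixed so the untreated RRMS TJP endpoint after 30 years sits 15% below the
untreated healthy endpoint (interpreted as the relative difference of
endpoint values, the natural reading of the published contrast).

**Readouts.**

    TEER = f_T + (1 − f_T) · tjp^α · bmec^β · pericyte^γ,   perm = 1 / TEER,

normalised to 1 at the healthy baseline, with leak floor `f_T = 0.10`,
`β = 1`, `γ = 0.25`, and `α = 1.3335`. α is calibrated jointly with the
repair gain so one 10 mg/kg NX210c cycle yields +7% final TJP *and* +8%
final TEER at 30 years in RRMS; α = 1 would force the two percentages to
be equal and cannot reproduce both. The permeability–TEER inverse coupling
makes any TEER ordering reverse exactly in permeability.

**Persistent repair.** NX210c repair input does two things: it clears the
damage burden (rate 12 per unit repair·day — one infusion cycle clears
essentially all accumulated damage) and raises the decay set point
permanently (gain 0.09916 per unit repair·day, capped at 0.65 of the
subject baseline). A transient synthesis boost cannot produce a
treated/untreated separation that persists for decades after a single
4-week cycle; a raised set point does. With this single mechanism the
healthy-cohort treatment effect comes out at +3.5% TJP / +4.2% TEER —
somewhat above the ~2% TJP reported for healthy subjects; matching both
the RRMS and healthy deltas exactly would require disease-dependent repair
efficacy for which there is no evidential basis, so the RRMS numbers were
chosen as the calibration anchors.

**Infiltration gate.** The probability that a circulating effector cell
crosses into the CNS responds steeply (Hill coefficient 8, midpoint 1.8 on
the leak–adhesion product) to `x = perm · adhesion`, where

    adhesion = 1 + 1.3·d + 0.42·activity²,   activity = p_act · antigen-rate multiplier.

The damage term is what NX210c removes; the activity² term is chronic
adhesion-molecule upregulation from ongoing subthreshold autoimmunity that
a TJP-targeted peptide does not touch. This split is the mechanism behind
the responder/non-responder structure: patients whose relapses are driven
by barrier leak are protected nearly completely, patients with strong
intrinsic activation keep relapsing under treatment.

## Pharmacokinetics

One compartment per species with first-order cyclization
(NX210 → NX210c at 1.2 /h), non-cyclization loss of the linear peptide
(10.8 /h), mono-exponential elimination of the cyclic form (0.7 /h) and
V = 0.15 L/kg. Only profile shapes and the exposure contrast are published,
so the rates are fixed by two anchors: the cyclic metabolite appears well
within a 180-minute sampling window, and the NX210c AUC from direct
NX210c dosing is 10× that from equal-dose NX210 — structurally,
`(k_cyc + k_lin)/k_cyc = 10`. Piecewise inputs are propagated with the
closed-form solution per interval, so superposition and dose linearity
hold to machine precision; per-kg dosing with per-kg volume makes
concentrations weight-independent.

## Pharmacodynamics

Repair input is a sigmoidal Emax function of NX210c concentration
(EC50 15 mg/L ≈ 12.5 µM, Hill 1.5, Emax 1 /day), placed in the middle of
the 1–100 µM range of the monolayer experiments so that 5 and 10 mg/kg
regimens sit on the rising limb (their cycle-integrated repair differs by
×0.62). The in vitro mode holds a constant bath concentration for 4 h–5
days (PK bypassed, mirroring the experiment design) and reports claudin-5,
TEER and dextran-permeability fold-changes versus vehicle; since the
source magnitudes are figure-only, the in vitro surface is validated on
orderings and monotonicity, not values.

## Immune/disease layer

Counts are population-level (cells/µL) stochastic difference equations at
a 6-hour step, not per-cell agents: desk-scale 10-year × 100-patient × 18-arm
runs require aggregation. Self-antigen exposures arrive as a Poisson
process (base 6 /yr × patient multiplier). Each exposure activates an
autoreactive clone with probability
`p_act · pool · (DC mult) · (B-cell presentation) `; an activation consumes
an absolute share (0.25) of the autoreactive pool, which thymic output
replenishes at 0.4 /yr × thymus efficiency. Activation expands
Th1/Th17/CTL effectors (clone size 1500 cells/µL × log-normal severity,
σ = 0.35); effectors contract at 0.18 /day and cross the barrier at the
infiltration-gate probability × 0.5 /day. Infiltrated cells clear at
0.18 /day, kill oligodendrocytes (ODC) at 4.5 cells/µL per infiltrated
cell·day against logistic recovery (0.075 /day, baseline 50,000 cells/µL),
and re-injure the barrier (damage gain 4.5e-4 per crossing cell) — a
positive feedback that re-opens the gate in patients with frequent events.
Th2 and antibody arms are carried for structural fidelity but have neutral
effect on ODC loss; Treg suppression is exposed with a neutral default.

Three structural choices deserve emphasis:

* **Absolute pool consumption.** Fractional consumption makes depletion
  self-limiting (consumption ∝ pool²) and the long-run relapse rate far
  too high; absolute consumption gives a front-loaded transient (~3–4
  activations) plus a replenishment-limited steady rate (~0.4–0.5 /yr in
  the highly active profile). This is also what reconciles the 2-year
  (≈4 clinical) and 10-year (≈7 clinical) untreated counts of the highly
  active population within one parameterisation.
* **Mean-field trafficking.** Conditional on the event draws (times,
  activation Bernoullis, severities), crossing and killing are expectation
  updates. Arms of one scenario share the per-patient draws, so paired
  comparisons (dose monotonicity, add-on benefit) are exact rather than
  statistical, and an 18-arm 2-year scenario runs in ~15 s.
* **B-cell support of expansion** (weight 0.5): B-cell depletion shrinks
  both activation and burst size. Without the expansion term,
  pool homeostasis blunts pure activation-suppressors and ocrelizumab
  cannot reach its observed rank next to natalizumab.

**ODC baseline 50,000 cells/µL** is the unique value making the two
published relapse thresholds agree: a 15% drop lands exactly at the
42,500 cells/µL clinical boundary. Relapse detection segments excursions
below 95% of baseline (the 5% detection threshold is a choice separating
events from recovery noise; config-exposed) and classifies by nadir
against the 15% rule. ODC recovery between relapses is complete by
construction (logistic to baseline); permanent deficits are out of scope.

## Standard-of-care representation

SoC drugs are effect windows over their registered schedules (no SoC
plasma PK): interferon β-1a 22 µg SC thrice weekly (DC-activation ×0.55);
teriflunomide 14 mg daily (proliferation ×0.70); natalizumab 300 mg IV
q4w (infiltration block 0.90, receptor saturation covering the interval);
ocrelizumab 600 mg IV q6m (B-cell depletion 0.95 persisting across the
interval); cladribine 3.5 mg/kg oral on the first 5 days of months 1, 2,
13, 14 (lymphodepletion 0.62, reconstitution carrying the effect ~a year
past each course). Whether the source platform drives SoC effects by PK
or by windows is not documented; windows were chosen as the weaker
assumption. Magnitudes are calibrated to the known 2-year efficacy
hierarchy in the highly active population, which the shipped defaults
reproduce (clinical means: natalizumab 0.10 ≈ ocrelizumab 0.49 <
cladribine 0.95 < teriflunomide 2.57 ≈ interferon 2.82 < untreated 3.16).

## Virtual populations

Per-patient parameters: thymus efficiency ~ Beta, activation probability
~ Beta × an HLA factor, antigen-rate multiplier ~ log-normal, baseline
barrier integrity ~ truncated normal, pre-existing damage ~ log-normal;
demographics uniform over typical RRMS trial ranges (age 18–55, weight
50–100 kg, ~70% female). The highly active profile shifts thymic output
down and activation/event-rate/damage up. The HLA repertoire is an
abstraction (16 random bits per locus A, B, C, DM, DO, DP, DQ, DR): the
DQ+DR popcount maps deterministically to an activation factor in
[0.85, 1.15], so class-II variation has phenotypic effect while class-I
permutations are neutral. Per-patient seeds derive from the master seed
by index (roster prefixes are stable under cohort growth), and simulation
substreams are keyed separately from sampling substreams.

What the generator does *not* emulate: real HLA allele frequencies,
age-dependent event rates, measurement noise on any readout, dropout, or
relapses triggered by anything other than discrete inflammatory events.
Passing tests therefore show internal consistency with the published
population summaries of the source model, not predictive validity on
clinical data.

## Numerical choices

Time unit is the day (365-day year); multi-year barrier-only scenarios
step daily, coupled scenarios at 6 h with daily barrier updates and
daily-resolution outputs. PK uses exact per-interval propagation on
1-minute grids; the within-day PD profile of one infusion is computed
once and re-used across dosing days (infusions are ≥48 h apart and the
concentration decays to nothing within hours). ODC is clamped to
[1, baseline]; out-of-range barrier states raise instead of clipping, so
calibration errors surface. Degenerate cases: dt = 0 is the identity;
zero dose gives identically zero concentrations; equal elimination and
conversion rates fall back to the L'Hôpital branch of the propagator.

## Reference scenario sizes

The shipped presets use the study sizes of the source scenarios: 100
subjects per cohort, 30 years (fig5), 2 years × 3 arms (fig6), 10 years ×
2 arms (fig7), 2 years × 18 arms (fig8); on one CPU they run in roughly
2 s, 4 s, 9 s and 15 s respectively. Stochastic endpoints are reported as
population means with across-patient SD (the dispersion measure of the
source figures is not further specified).

## Known limitations

* Relapses are triggered by discrete inflammatory events only — the model
  inherits this stated limitation of the source platform.
* Absolute PK concentration scales are not anchored (profiles and the
  10-fold AUC contrast are); EC50 in absolute units is therefore
  conventional.
* The healthy-cohort treatment deltas overshoot the published ~2% TJP
  figure (see Barrier model above).
* No EDSS/MRI endpoints, no spatial vasculature, no adverse events, no
  inter-individual PK variability.
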