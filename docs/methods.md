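# Methods

This note documents the model implemented in `captopbpk`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate.

## Drug model

Captopril is parameterized by its physicochemistry (MW 217.29 g/mol,
logP 0.34, pKa 4.02 as a monoprotic acid), first-order absorption
(ka 1.75 h⁻¹, lag 0.2 h, fraction absorbed fa 0.7), minimal-PBPK
distribution (kin = kout = 0.25 h⁻¹, B/P 1, fu 0.73, Vss 0.267 L/kg) and
empirical clearances (total CLiv 49.5 L/h, renal CLR 22.2 L/h; the hepatic
component is the difference, 27.3 L/h). The configuration stores Vss at the
model precision 0.267 L/kg; display tables round it to 0.26.

### Tissue partitioning

Steady-state distribution is predicted with the tissue-composition method
of Rodgers and Rowland, using its acids / very weak bases / neutrals
branch ("method 2"). Per tissue the unbound partition coefficient is

    Kpu = f_EW + X·f_IW + Y·(P·f_NL + (0.3P + 0.7)·f_NP) + KaPR·(PR_t/PR_p)

with P = 10^logP, X the intracellular-to-plasma total-drug water ratio at
intracellular pH 7.0 vs plasma pH 7.4 (monoprotic acid: ionized:neutral =
10^(pH − pKa)), Y the neutral fraction in plasma, and the albumin
association term recovered from the plasma unbound fraction
(KaPR = 1/fu − 1 − lipid partitioning of plasma). Kp = fu·Kpu, and

    Vss = V_plasma + V_E·(E:P) + Σ_t V_t·Kp_t   (all L/kg)

with the erythrocyte:plasma ratio derived from B/P and hematocrit,
E:P = (B/P − (1 − Hct))/Hct = 1 for captopril. The packaged composition
table transcribes the published method's tissue water/lipid fractions and
albumin ratios with standard adult human organ volumes; because the exact
composition vintage used by commercial simulators is unpublished, the Vss
check carries a documented ±15 % tolerance. The packaged table gives
0.279 L/kg against the reference prediction 0.267 L/kg (≈4 % apart).
Only the acid/neutral branch is exact by design; moderate-to-strong bases
would need the acidic-phospholipid branch and raise `DomainError`.

### First-pass loss and bioavailability

The liver is well-stirred: Fh = 1 − CLh/Qh with hepatic blood clearance
equal to plasma clearance (B/P = 1), and oral bioavailability F = fa·Fh
with gut availability fixed at 1 (the absorbed fraction already subsumes
gut-wall loss). Typical healthy values (Qh = 90 L/h) give Fh ≈ 0.70 and
F ≈ 0.49, i.e. 0.5 at one decimal.

## Minimal-PBPK system

Amounts (mg) move between a depot, a central/systemic compartment, a
single adjusting compartment (SAC) and an elimination sink:

    dA_depot/dt   = −ka·A_depot                      (zero before tlag)
    dA_central/dt = ka·Fh·A_depot − (CL/Vc)·A_central − kin·A_central + kout·A_sac
    dA_sac/dt     = kin·A_central − kout·A_sac

with C = A_central/Vc in ng/mL and Vc = Vss_total/(1 + kin/kout), the
steady-state amount split between central and SAC. This collapses to a
one-compartment model when kin = 0 and returns exactly the configured Vss
at steady state. First-pass loss is applied multiplicatively on the
absorption flux (no explicit liver compartment: the source model provides
no liver volume or intrinsic clearance) and accumulated separately so
`depot + central + SAC + eliminated + first-pass loss` equals the
delivered dose; an iv bolus starts with the dose in the central
compartment (C(0) = dose/Vc), an oral dose with fa·dose in the depot and
absorption starting at the lag time. Integration uses LSODA with
rtol 1e−8 / atol 1e−10 mg; the mass balance is asserted at every output
point within 10× those tolerances. The system is linear, so profiles
superpose with dose and AUC0–∞ = F_route·dose/CL independent of kin/kout.

## Virtual populations

Subjects draw demographics uniformly within study ranges and
median-preserving lognormal variability elsewhere. Defaults: CV 30 % on
clearance (one multiplier shared by the hepatic and renal components, so
total clearance carries exactly the configured CV), 25 % on Vss, 30 % on
ka, 30 % on fa (capped at 1), 15 % on hepatic blood flow around a typical
90 L/h; healthy GFR uniform in 100–140 mL/min. A sampled hepatic clearance
is clamped below 95 % of the subject's hepatic flow: extraction cannot
exceed flow under the well-stirred contract, and without the clamp extreme
clearance draws combined with disease flow reductions would be physically
inconsistent.

Disease scaling applies once per subject (re-scaling raises an error):

* **CKD** — hepatic (non-renal) clearance × 0.80 / 0.55 / 0.35 in mild /
  moderate / severe disease; renal clearance proportional to the sampled
  GFR relative to the healthy reference 120 mL/min (bands: mild 60–90,
  moderate 30–60, severe 15–30 mL/min); Vss (and Kp's) × 2.51 in all three
  severities.
* **CHF** — hepatic blood flow reduced to 76 / 54 / 46 % of normal in
  mild / moderate / severe failure; hepatic clearance × 0.55; renal
  (78/55/63 %) and peripheral (57/44/28 %) flow fractions are recorded on
  the subject but renal clearance is left unscaled by default (the renal
  input is an empirical clearance, not flow-limited; a config switch
  propagates the renal fraction for sensitivity analyses). The evaluation
  population is a 50:50 moderate:severe mix, matching the mixed cohort it
  emulates.
* **Geriatric** — GFR, both metabolic clearances and cardiac output (hence
  hepatic flow) decline 1 %/year above age 40 with a floor at 50 %.
  Scaling flow and hepatic clearance together keeps first-pass
  availability age-invariant while apparent oral clearance falls, which is
  the direction of the reference geriatric data; scaling only the flow
  would instead raise CL/F through a lower Fh.

CKD fu/hematocrit shifts are deliberately not propagated into clearance:
the clearances are specified empirically, and re-deriving them from
fu·CLint would double-count the hepatic scaling factors.

## Non-compartmental analysis

λz comes from log-linear regression over the best terminal window: all
contiguous terminal windows of ≥3 positive concentrations (strictly after
Tmax for extravascular routes), maximum adjusted R², ties resolved to the
longer window. AUC uses linear trapezoids throughout (zeros kept as
zeros) with a Clast/λz tail; CL = dose/AUC0–∞ with mg→ng and mL→L
conversions. Extrapolated fractions above 20 % raise a warning. For
iv-bolus records whose first sample is post-dose — the clinical situation —
C0 is back-extrapolated log-linearly from the first two positive samples
and used for the initial AUC segment only, while Cmax stays the maximum
observed sample (the usual iv reporting convention). The scenario runner
feeds NCA clinical-style grids whose first iv draw is 10 minutes
post-dose, because the reference predicted iv Cmax values correspond to a
first blood draw, not to the instantaneous C(0) = dose/Vc. The lin-log
trapezoid variant is deliberately not used; linear trapezoids are the
simplest defensible reading of the source analysis.

## Evaluation statistics

Per observed/predicted pair the ratio R = obs/pred; the fold-error is the
same quotient (the two published formulas coincide and share one
implementation). AFE = 10^(mean log10 fold-error) is the geometric mean
of signed ratios. Mean ratios carry Student-t 95 % CIs
(mean ± t(0.975, N−1)·sd/√N) computed on unrounded ratios; rounding
happens only at display. The twofold criterion uses the closed interval
[0.5, 2]. VPC summaries report per-timepoint mean, 5th/95th percentile
(linear-interpolation convention), minimum and maximum over profiles on a
common schedule.

Two transcription caveats are preserved in the packaged tables and
asserted by the tests: one printed per-row ratio (severe-CKD apparent
clearance) is inconsistent with its own row at 2 dp (print 0.69, quotient
0.68), and the printed CI bounds scatter within 0.01 of the exact t-based
computation (consistent with CIs having been computed from
display-rounded ratios, which the unrounded-arithmetic rule here does not
reproduce); all 18 group mean-ratio/AFE cells reproduce exactly at 2 dp.
Across the 57 packaged pairs exactly one (the fed-state Cmax, ratio 0.43)
falls outside twofold — the signature of the food effect the model does
not attempt to describe.

## Synthetic observed data

The original concentration measurements exist only as digitized figures,
so observed-like data are synthesized: the simulator runs under optionally
perturbed subject parameters (clearance / volume / ka multipliers) with
multiplicative lognormal residual error per observation
(median-preserving), and returns the ground truth alongside. Closed-loop
tests (no perturbation, no noise) must return all ratios and the AFE at
exactly 1; clearance perturbations of 0.5/1/2 must be recovered as mean
clearance ratios within 10 % over a 10×10 trial design. Recovery uses the
iv route: an oral clearance perturbation also shifts first-pass
availability, so the apparent-clearance ratio would no longer equal the
injected multiplier. What these tests show is that the pipeline is
self-consistent and unbiased under its own model family; they cannot show
that the model family captures real captopril disposition — that evidence
lives in the printed observed/predicted tables the evaluation module
regenerates.

## Reproduction problem sizes and numerical choices

Virtual trials use the 10 trials × 10 subjects design throughout. Scenario
grids sample 19–22 points out to 12 h (healthy) or 24 h (disease, whose
terminal half-life is longer); dense grids (0.01 h early steps) are used
wherever an NCA quantity is compared against a closed form, because
linear trapezoids on sparse clinical grids carry a few percent of
curvature error. Percentile and CI conventions are noted above;
tie-breaks in the λz window search prefer more points; degenerate inputs
(all-zero profiles, fewer than three terminal points, GFR outside a
severity band, re-applied disease scaling, extraction above flow) raise
typed errors rather than propagating silently.

## Known limitations

* The simulated bioavailability's population *median* reproduces the
  reference value (0.5), but with independent lognormal variability the
  per-subject spread over 100 subjects typically reaches ~0.2–0.83 rather
  than the full reported 0.3–0.9 envelope: F = fa·Fh is capped by fa ≤ 1,
  and the upper end requires one subject to sit simultaneously in the
  upper tails of fa and Fh — a sub-percent joint event per subject under
  the default CVs. A wider envelope would require correlated absorption
  and extraction extremes or a much larger population, neither of which
  the source analysis documents.
* The CHF model reduces clearance only through the hepatic scaling factor
  and flow; the reference predictions imply a stronger clearance reduction
  (their apparent clearance is ~40 % below this package's), though all
  scenario medians remain within twofold.
* The food effect is out of scope; fed scenarios are simulated as fasted
  and their printed rows retained for evaluation.
* Single doses only; no infusions, multiple dosing, nonlinear clearance or
  mechanistic absorption models.
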