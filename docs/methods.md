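# Methods

## The decision problem

`cathcea` evaluates, from a health-care payer perspective (2006 Canadian
dollars), whether raising the population rate of diagnostic cardiac
catheterization is good value for money. The marginal unit of analysis is
one additional potentially-eligible patient undergoing catheterization. The
benefit of catheterizing is the detection — and, in suitable patients,
revascularization — of high-risk coronary anatomy (left-main or 3-vessel
disease), which carries a survival and quality-of-life advantage over
undetected, medically managed disease. The harm is the small procedural
mortality of the catheterization and the cost of the procedure and of any
subsequent CABG or PCI.

## Model structure

A deterministic Markov cohort model runs two arms for the same latent
patient:

* **Catheterize.** Cycle 0: the patient pays the catheterization cost
  `c_cath`, dies with probability `p_cath` (sex- and age-specific), and
  survivors are distributed over anatomy {left-main, 3-vessel, 1–2-vessel,
  normal} by the marginal anatomy mix π. Within each disease anatomy the
  patient is revascularized with the observed practice probability (CABG vs
  PCI split per observed shares, incurring `c_CABG` = 17,958 or `c_PCI` =
  7,927) or managed medically.
* **Do not catheterize.** The same anatomy distribution, no procedure cost
  or risk, all managed medically. The patients who *would have been*
  revascularized follow a counterfactual mortality curve (below) and, for
  left-main/3-vessel disease, carry a utility decrement δ = 0.03 relative
  to the revascularized utility; undetected 1–2-vessel would-be-revascularized
  patients keep the revascularized utility (no quality-of-life benefit is
  assumed for revascularization in 1–2-vessel disease).

Annual cycles. State occupancy is valued at cycle start; there is no
half-cycle correction by default (`half_cycle=True` implements trapezoidal
accrual). Cycle *t* accrues the year-(*t*+1) annual cost (the year-3 value
persists beyond year 3) and utility, discounted by (1+r)^-t with r = 0.05;
cycle-0 procedure events are undiscounted, so two years lived at utility 1
are worth 1 + 1/1.05 QALYs. Both arms accrue the same annual-cost profile
per management category (the RITA-2 equal-annual-cost assumption), so annual
costs differ between arms only through survival. Normal-coronary patients
follow population mortality in both arms with identical utility and zero
incremental annual cost; the catheterization arm still pays `c_cath` and
bears `p_cath` for them. The run terminates at age 100 (life table extends
to 105) or when alive occupancy falls below 1e-8.

ΔC and ΔE are the differences in total discounted cost and QALYs between
the arms; the ICER is ΔC/ΔE with the usual dominance classification
(dominated: ΔC ≥ 0 and ΔE ≤ 0, not both zero; dominant: the mirror case).
Subgroup cells (sex × age band) are aggregated by the registry cohort
composition (n = 11,527; male/female 7,885/3,642; the ACS share of the
overall row is a configurable parameter, default 0.5, since no mixing
weights are published).

## Mortality curves

Registry survival is estimated per (indication, sex, age band, anatomy,
revascularized-vs-medical) cell by Kaplan–Meier over the 10 observed years,
discretized to annual death probabilities q_t = 1 − S(t)/S(t−1), and
extrapolated beyond year 10 with the population age increment:
h(t) = h(10) · m(a₀+t)/m(a₀+10), where m is the life-table annual mortality
and a₀ the representative starting age of the band (57 / 70 / 80;
configurable — only bands are published). Probabilities are capped at
0.999.

The counterfactual for undetected would-be-revascularized patients applies
window-specific relative risks on the hazard scale to the *extended*
revascularized curve: h_med(t) = RR(t) · h_rev(t). Two efficacy scenarios
are supported: anatomy-specific RRs for stable (non-ACS) disease (left-main
2.33 then 0.74; 3-vessel 1.59 then 1.00; 1–2-vessel 1.27 then 0.80 over
years 0–5 and 5–10, then 1.00 assumed), and a pooled ACS schedule (1.47
over years 0–2, 0.88 over 2–5, then 1.00 assumed). The window boundaries of
the pooled schedule are taken as (0,2], (2,5] as tabulated. Applying RRs on
the hazard scale keeps q in [0,1] and makes the 5-year cumulative-hazard
ratio exactly the first-window RR. Supporting algebra: the odds-ratio to
relative-risk conversion RR = OR/(1−p₀+p₀·OR), and window-RR imputation on
the cumulative-hazard scale,
RR_(a,b] = (RR_{0b}H(b) − RR_{0a}H(a)) / (H(b) − H(a)); the tabulated
5–10-year values are nonetheless used as printed inputs rather than
re-derived, since the original imputation method is not stated.

## Yield of the marginal catheterization

A hierarchical linear model with a region random intercept regresses the
regional high-risk detection rate (cases per 100,000 adults) on the
regional catheterization rate, weighted by regional adult population
(implemented by row-scaling: Var(e_i) = σ²/w_i). A refit with a quadratic
term (centred and scaled for conditioning) provides a Wald test for a
plateau at α = 0.05. The slope is the extra high-risk yield per unit of
catheterization rate; headline ratios — 1 high-risk case per 3
catheterizations in males, per 5 in females (base case) — convert to the
marginal anatomy mix:
π(LM)+π(3VD) = 1/ratio, split between left-main and 3-vessel by the
published prevalence within the (sex, age band) cell (e.g. 5.3 : 21.3 for
males under 65); the remainder is split between 1–2-vessel disease and
normal coronaries by a `normal_fraction` parameter (default 0.15 — the
normal share of the marginal catheterization is not published and is
deliberately exposed rather than asserted).

## Synthetic registry

No registry data are distributable, so `registry_synth` generates a
cohort with the structure the analysis assumes: multinomial subgroup
composition from the published cohort counts, anatomy drawn from the
published prevalences (normalized per cell; registry normal-coronary
fraction defaults to 0 because the published prevalences leave it no room),
treatment assignment from the published revascularization/CABG
probabilities, and survival from piecewise-exponential hazards with
administrative censoring at 10 years and no loss to follow-up.

The published survival exists only as curves, so the generating hazards are
explicit free parameters. The defaults (annual hazards for years 0–5 / 5–10,
non-ACS male under-65 baseline) are: left-main 0.035/0.045 revascularized
vs 0.075/0.080 medical; 3-vessel 0.032/0.042 vs 0.055/0.060; 1–2-vessel
0.022/0.032 vs 0.025/0.034; multipliers ×1.35 for ACS, ×0.85 for females,
×1.9 / ×3.4 for ages 65–75 / over 75. They were chosen once so that
revascularized high-risk survival exceeds medical at 10 years (the
qualitative ordering reported for such registries), 1–2-vessel survival is
nearly treatment-independent, and 10-year survival levels are plausible for
a catheterization cohort. Regional records draw catheterization rates
uniformly on the observed 347–542 range with a Normal region effect
(SD 5 per 100,000) and residual noise (SD 5) around the configured yield
line; utilities are truncated normals on [0,1]; costs are gamma with the
published means (shape 1.5).

What the generator does **not** emulate: informative censoring, secular
trends, comorbidity covariates, repeat procedures, referral pathways, or
correlation between survival, costs and utilities within patients. Passing
tests therefore demonstrate the correctness of the estimators and
accounting on data satisfying the model's assumptions — not that the
published point estimates are recovered, which would require the
unpublished registry curves. The deterministic scenario grid reproduces the
published *directional* patterns (ICERs increase with the discount rate and
with weaker efficacy, decrease with stronger yields, SAQ utilities and
cheaper procedures; a 25% efficacy reduction is dominated), and this is
what the acceptance suite asserts.

## Probabilistic sensitivity analysis

Inputs are drawn independently: Normal for relative risks (SE from the
published 95% CIs, (hi−lo)/3.92, truncated at 0.01), utilities (SE =
SD/√n, clipped to [0,1]) and the high-risk yield probability (SE = 10% of
the mean by default — no variance is published, so this is flagged
configuration, not data); Gamma for all costs (method-of-moments from mean
and 95% CI; procedure costs use a 10% CV). Each draw reruns both arms for
every subgroup cell of the chosen family. Draw *i* uses child stream
(seed, i), so extending the draw count preserves earlier draws. Summaries:
CE-plane quadrant shares (boundaries assigned by strict positivity),
a 95% bivariate-normal confidence ellipse (χ²₂ = 5.991), and
cost-effectiveness acceptability curves P(λ) = Pr(λΔE − ΔC > 0) on a
0–200,000 grid. A lognormal option for RRs exists behind
`DistributionSpec(family=...)` composition for robustness checks but the
default follows the stated Normal family.

## Numerical choices and degenerate inputs

* Noise-free yield data short-circuit to exact weighted least squares
  (REML is singular there); the exact-fit threshold is a residual below
  1e-8 of the response scale.
* Kaplan–Meier ties: deaths processed before censorings; Greenwood
  variance for the pointwise bands.
* q = 1 cells are absorbing; a protective RR applied to an absorbing state
  stays absorbing (with a warning).
* Anatomy-mix probabilities are validated to sum to 1 within 1e-12;
  cohort-trace occupancy is validated to sum to 1 within 1e-10 per cycle.
* The microsimulation oracle samples each patient's death cycle by
  inverse-CDF on the state's discrete lifetime law — the same distribution
  as sequential annual Bernoulli draws, at a fraction of the cost.

## Problem sizes

Defaults were chosen to make every stochastic check well-resolved while
keeping a full run interactive: 100,000 synthetic patients for the
registry (the rarest survival cell, ACS female under-65 left-main medical,
then holds ≈13 patients), 9 regions × 10 years of regional records, 3,000
PSA draws in the acceptance script (the library default is 10,000), and a
10⁶-patient microsimulation for oracle comparisons. The test suite uses a
60,000-patient shared registry.

## Known limitations

* The registry→model survival link inherits the registry's confounding by
  indication: the revascularized-vs-medical contrast is not causal, which
  is precisely why efficacy enters through external trial relative risks.
* Efficacy RRs are dated (stable-angina trials) or indirect (an
  early-invasive-strategy trial for ACS); the PSA shows the model is most
  sensitive to them.
* No repeat revascularization, non-fatal events, capacity constraints or
  capital costs; no EVPI; inputs are sampled independently in the PSA.
* Printed base-case ICERs depend on unpublished registry survival curves
  and are not exactly reproducible from the synthetic calibration; the
  package reproduces the self-contained arithmetic exactly and the
  sensitivity structure directionally.
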