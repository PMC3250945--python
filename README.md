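# cathcea

Cost-effectiveness modelling of raising population cardiac-catheterization
rates, for health economists and cardiovascular health-services
researchers.

Diagnostic cardiac catheterization finds patients with high-risk coronary
anatomy (left-main or 3-vessel disease) who can benefit from
revascularization by CABG or PCI. Raising the population catheterization
rate detects more such patients — at the price of more procedures, more
procedural deaths and more spending. `cathcea` implements the full economic
evaluation of that trade-off as a tested, reusable pipeline:

1. **Synthetic registry** (`registry_synth`) — patient-level survival by
   indication (ACS/non-ACS), sex, age band, anatomy and treatment;
   regional catheterization/detection rates; EQ-5D surveys; annual cost
   records; a Gompertz life table. Everything downstream is testable
   without any proprietary data.
2. **Yield regression** (`yield_model`) — a region-random-intercept linear
   model of high-risk detection rate on catheterization rate, a quadratic
   plateau test, and the anatomy mix of the *marginal* catheterization
   (base case: 1 high-risk case per 3 catheterizations in males, per 5 in
   females).
3. **Survival machinery** (`survival_model`) — Kaplan–Meier per subgroup,
   annual death probabilities `q_t = 1 − S(t)/S(t−1)`, life-table
   extrapolation `h(t) = h(10)·m(a₀+t)/m(a₀+10)` beyond the observed 10
   years, odds-ratio→relative-risk conversion `RR = OR/(1−p₀+p₀·OR)`, and
   the counterfactual mortality of undetected patients,
   `h_med(t) = RR(t)·h_rev(t)` with window-specific RRs.
4. **Markov cohort engine** (`markov_engine`) — annual-cycle two-arm model
   (catheterize vs not) per subgroup, discounted at r = 5%, with a
   patient-level microsimulation oracle.
5. **CEA accounting** (`cea`) — ICER = ΔC/ΔE with dominance handling,
   subgroup aggregation, and the deterministic sensitivity grid (yield
   ranges, RR ±25%, SAQ utilities, cost factors, discount rates).
6. **PSA** (`psa`) — Monte-Carlo input sampling (Normal for RRs, utilities
   and yield; Gamma for costs), CE-plane scatter with a 95% confidence
   ellipse, quadrant shares and cost-effectiveness acceptability curves
   P(λ) = Pr(λ·ΔE − ΔC > 0).

All costs are 2006 Canadian dollars from a payer perspective.

## Worked example

Run the full pipeline on a 100,000-patient synthetic registry:

```sh
cath-cea run --seed 1 --n-patients 100000 --outdir demo_out
cath-cea report --outdir demo_out
```

which prints (abridged):

```
Base case:
  overall      all      dC=    8,501  dE=  0.265  ICER=      32,047
  acs_yusuf    all      dC=    8,540  dE=  0.278  ICER=      30,746
  acs_frisc2   all      dC=    8,216  dE=  0.158  ICER=      52,161
  nonacs       all      dC=    8,462  dE=  0.253  ICER=      33,477

Sensitivity analyses (ICER by scenario and family):
  base                     acs_yusuf=30,746  acs_frisc2=52,161  nonacs=33,477
  rr_increase_25pct        acs_yusuf=17,251  acs_frisc2=26,868  nonacs=18,578
  rr_decrease_25pct        acs_yusuf=dominated  acs_frisc2=dominated  nonacs=dominated
  saq_utilities            acs_yusuf=19,731  acs_frisc2=25,587  nonacs=19,573
  no_discounting           acs_yusuf=21,946  acs_frisc2=37,414  nonacs=23,085
  discount_6pct            acs_yusuf=32,632  acs_frisc2=55,207  nonacs=35,716
```

Reading the overall row: catheterizing one additional eligible patient
costs ΔC ≈ $8,501 more than not catheterizing (procedure plus downstream
revascularization and care), gains ΔE ≈ 0.265 discounted QALYs (≈ 97
healthy days), for an incremental cost-effectiveness ratio of about
$32,000 per QALY under this synthetic calibration — and the grid shows the
familiar structure: the answer is most sensitive to the efficacy of
revascularization (a 25% weaker effect makes the strategy dominated),
while stronger yields, disease-specific (SAQ) utilities and lower discount
rates all make it more attractive. `cath-cea psa --n 10000 --seed 42
--scenario acs_yusuf` adds the probabilistic analysis (scatter, ellipse,
CEAC).

Every stage is also available as a library call; see the module docstrings
(`cathcea.markov_engine.run_cohort`, `cathcea.psa.run_psa`, …) and
`docs/methods.md` for the model's assumptions, parameter defaults and
limitations.

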