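# Methods

This note documents the model structure, the numerical choices, and the
boundaries of what the bundled synthetic inputs can and cannot show.

## Within-trial evaluation

Programme costing is exact decimal arithmetic to the cent
(`decimal.Decimal`, half-up rounding): one-off training (9 h × NZ$125) and
the support-person salary (NZ$150,000 incl. 25% overhead) are amortised over
all 455 intervention participants; per-participant items (GP referral
NZ$65.00, pedometer NZ$30.44, Quitline NZ$195.33) are added directly. Only
programme costs enter the 24-week ICERs — wider health-sector resource use
was not collected at this stage, so there are no cost offsets.

ICERs divide the incremental cost by the difference in quit rates.
Computed from the rounded published summary rates, the intention-to-treat
ratio is ≈NZ$30,541 per quitter and the adherent-subgroup ratio ≈NZ$4,072;
values computed from unrounded individual data differ by a few percent
(the unrounded effect differences are not recoverable from printed tables),
which is why downstream checks use a tolerance rather than equality. The
adherent subgroup is assumed to incur the full-arm per-participant cost of
NZ$622.91 (its realised per-head cost is not separately reported).

QALYs over the 24-week window are trapezoids of the baseline and follow-up
EQ-5D utilities. The between-arm difference is estimated by an ANCOVA-style
linear model (`statsmodels` OLS) of individual QALYs on arm and baseline
utility; the estimator behind the published "adjusted for baseline HRQoL"
phrase is not specified, and linear covariate adjustment is the standard
choice. Records missing either utility are dropped listwise. Missing
smoking status is counted as smoking, matching the trial's stated rule.

## Lifetime Markov cohort model

**States.** Well-smoking; well-quit expanded into 16 sub-states by years
since quitting (the 16th collects everyone ≥15 years post-quit, where the
lung-cancer relative risk has fully decayed to 1.0); early- and
advanced-stage lung cancer, each a 5-year tunnel indexed by years since
diagnosis with the final sub-state holding long-term survivors; a single
chronic CVD state; and three absorbing dead states split by cause (other /
lung cancer / CVD) for cost bookkeeping. CVD and lung cancer are mutually
exclusive: an occupant of one never transitions to the other.

**Cycle order.** One-year cycles. Within a cycle: background mortality →
disease-specific mortality/progression → disease incidence → quit/relapse
flows. Deaths therefore cannot acquire disease in the same cycle. No
half-cycle correction by default (`accumulate(..., half_cycle=True)` is
available); occupancy is evaluated at cycle start, so the quit-utility gain
of 0.03 first accrues in the first post-quit cycle.

**Quitting and relapse.** At cycle 0 the arm- and sex-specific 24-week quit
probability applies, immediately thinned by the 21% relapse observed
between trial end and 12 months. Over the next three years sustained
quitters relapse at the constant annual hazard `1 − 0.70^(1/3) ≈ 0.1121`,
whose cumulative effect is the reported 30%; relapse is zero afterwards.
How the 30% distributes across the three years is not reported; a constant
hazard is the least-informative choice. Relapsers return to the full smoker
risk profile (the risk clock resets) and to utility 0.800.

**Risks.** Incidence curves are population-level; smokers face relative
risks of 1.771 (lung cancer) and 1.42 (CVD). After quitting, the CVD risk
drops immediately and permanently to 1.42 × 0.71 ≈ 1.01 (no decay horizon is
given for CVD), while the lung-cancer RR decays linearly from 1.771 to 1.0
over 15 years. The published RR example (1.771) is stated "15 years after
quitting", which is ambiguous about the quit-duration it belongs to; it is
treated here as the value *at* quitting, since a decayed RR would be 1.0 by
definition at 15 years. New lung cancers split 20%/80% into early/advanced
stage. CVD events split 18.1% pre-hospital deaths; 7.1% of the hospitalised
81.9% die within 28 days; survivors enter the chronic CVD state for life
(overall event fatality ≈ 23.9%).

**Cause attribution.** Background-mortality deaths of CVD-state occupants
are attributed to CVD — these people die with CVD and trigger its
terminal-care cost; no separate post-event excess mortality is reported, so
this keeps CVD mortality conservative while still costing CVD deaths.
Background-mortality deaths in lung-cancer states go to "other" (only
tunnel-specific deaths are lung-cancer deaths); lung-cancer terminal costs
attach to the latter.

**Lung-cancer tunnels.** Stage-specific annual death (and early→advanced
progression) probabilities per tunnel year are configuration inputs; the
published model inherits them from an earlier lung-cancer model whose
values are not printed. The bundled defaults (early-stage death
0.10→0.04/yr with 5%/yr progression; advanced-stage death 0.45→0.15/yr) are
synthetic, chosen once so that 5-year survival is clearly worse for
advanced than early disease. Progression restarts the advanced tunnel
without re-charging the first-year diagnosis cost.

**Costs and QALYs.** Per cycle: state utilities weight occupancy; costs sum
the strategy's programme cost at cycle 0, first-year excess costs on
incident lung cancer and on hospitalised CVD events, continuing annual
lung-cancer costs on prevalent lung-cancer occupancy, and terminal
six-month costs charged as a lump sum in the cycle of cause-specific death
(annual resolution cannot place half-years). Both streams discount by
`(1+r)^−t`, r = 3.5% (0% and 5% in scenarios). All amounts are 2012 NZ$;
PPP conversion (US$0.68, €0.53 per NZ$) is display-only.

## Sensitivity analyses

PSA draws every uncertain scalar independently (no correlation structure is
reported): arm/sex quit rates (beta), CVD relative risks (lognormal),
lung-cancer utilities (beta). Method-of-moments fitting on the natural
scale: beta `ν = m(1−m)/se² − 1`; gamma `shape = m²/se², scale = se²/m`;
lognormal `σ² = ln(1+cv²), μ = ln m − σ²/2`. Numerically degenerate beta
draws are clipped into (0,1) with a logged warning rather than redrawn, so
draw counts stay exact. One root seed spawns per-repetition child streams
(`numpy.random.SeedSequence`), so increasing the repetition count extends
rather than reshuffles a run. Age curves are not sampled by default
(whether the original analysis sampled them is unstated); `curve_cv`
applies a common gamma factor per curve group for exploration.

One-way analysis brackets each registered parameter at mean ± 2 se when an
se is reported and mean × 0.8/1.2 otherwise, holding everything else at
base values. Scenarios rerun the comparison at 0%/3.5%/5% discount rates
and start ages 30/40/50/60 for both sexes.

## Synthetic inputs: what they are and are not

The age–sex curves for incidence, mortality and excess costs emulate shapes
only: exponential in age (Gompertz-like) for background mortality
(slope 0.09/yr), lung-cancer incidence (0.085/yr) and CVD incidence
(0.07/yr), flat for costs, each anchored exactly at the published age-65
example values (e.g. male background mortality 0.01071, male CVD incidence
0.03095). They are fixtures for testing the machinery, not estimates of the
national curves, and results that depend on the *age gradient* of risk
inherit this limitation directly. In particular, with these fixtures the
discounted benefit of quitting is dominated by the 0.03 utility gain, which
scales with discounted life expectancy and therefore *falls* with cohort
start age, so ICERs worsen slightly for older cohorts — the published
analysis, driven by the much steeper real-world age gradients below 65,
found the opposite ordering. Passing tests demonstrate correct model
mechanics and the published trial-stage arithmetic; lifetime magnitudes
(ΔQALY ≈ 0.057 male at the base case, ICERs far below NZ$20,000/QALY,
probability cost-effective ≈ 0.9) land near the published values but should
not be read as a validation against the real national inputs.

The trial-record generator draws quit status Bernoulli at the arm rates
(the adherent subgroup at its own rate, the non-adherent rate solved to
preserve the arm total) and EQ-5D utilities from beta marginals on [0, 1]
matched to the published means with individual-level sd `se·√n`; negative
EQ-5D states are not generated. Baseline and follow-up utilities are linked
by a Gaussian copula with ρ = 0.75 — repeated HRQoL measurements are
strongly correlated, and without this the baseline-adjusted contrast would
be pure noise. Quit status and utility are independent (their joint
distribution is not reported).

## Problem sizes and tolerances

Cohort traces use 60 annual cycles (age 40→100) over ~31 states and must
conserve occupancy to 1e−9 per row (closed-form degenerate reductions to
1e−12). The microsimulation cross-check replays the annual rules for 10⁵
individuals over a 20-year window and agrees with the cohort trace within
4 binomial standard errors per state and cycle. PSA checks use 2,000
repetitions against the deterministic base case (4 Monte-Carlo se);
reported PSA results use 1,000 repetitions. The adjusted QALY contrast in
the acceptance script uses 20,000 records per arm because at the trial's
n ≈ 455 the estimate (≈0.001, CI −0.006 to 0.008) is sign-unstable by
construction.

## Known limitations

* Synthetic age curves (above): age-gradient-dependent conclusions are
  fixture-dependent.
* No non-lung cancers, respiratory disease, or productivity effects; no
  individual heterogeneity beyond sex — matching the source model's scope.
* CVD-state occupants face no excess mortality beyond cause re-attribution.
* Within-trial ICERs from printed inputs differ by a few percent from
  values computed on unrounded data (not recoverable).
* The lifetime analysis applies to the adherent subgroup, which was not
  prospectively defined; results are hypothesis-generating, not a basis
  for blanket provision.
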