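# quitcea

Cost-effectiveness analysis of an exercise-counselling programme added to
telephone smoking-cessation support (Quitline), from a New Zealand health-system
perspective. The package implements two linked analyses:

1. **Within-trial (24-week) evaluation** — exact per-participant programme
   costing, the incremental cost per additional quitter (intention-to-treat and
   for the adherent subgroup who completed ≥7 of 10 counselling calls), and the
   baseline-adjusted QALY difference from EQ-5D utilities.
2. **Lifetime Markov cohort model** — sex-specific cohorts followed in annual
   cycles from age 40 to 100 through *well-smoking*, *well-quit* (years since
   quitting tracked), *CVD*, *early/advanced lung cancer* (tunnel states indexed
   by years since diagnosis) and cause-split *dead* states, with relapse
   dynamics, decaying ex-smoker lung-cancer risk, CVD event fatality splits,
   excess health-system costs, and 3.5%/yr discounting.

It is aimed at health economists and modellers who want a tested, scriptable
re-implementation of this class of smoking-cessation decision model, rather
than a spreadsheet or proprietary decision-tree software.

## The model in brief

For strategies *i* (intervention) and *c* (usual care), the incremental
cost-effectiveness ratio is

```
ICER = (C_i − C_c) / (E_i − E_c)
```

with costs `C` in 2012 NZ$ and effects `E` in quitters (trial stage) or
discounted QALYs (lifetime stage). Lifetime QALYs and costs accrue per cycle
`t` as `Σ_s occupancy_s(t)·u_s / (1+r)^t` and analogously for state/event
costs, with `u_s` the state utility (well-smoking 0.800, well-quit 0.830,
early/advanced lung cancer 0.73/0.56, CVD 0.611 — an admission-share-weighted
composite) and `r = 0.035`. Quitting follows the trial rates (e.g. adherent
males 35.2% vs 24.2% usual care), reduced by 21% relapse to 12 months and a
further 30% cumulative relapse over the next three years. Smokers face
relative risks of 1.42 (CVD) and 1.771 (lung cancer) that fall after quitting
— immediately to 1.42×0.71 for CVD, linearly to 1.0 over 15 years for lung
cancer. Uncertain parameters carry (mean, se) pairs with beta / gamma /
lognormal sampling distributions fitted by method of moments; probabilistic
sensitivity analysis summarises 1000 Monte-Carlo repetitions as a
cost-effectiveness acceptability curve (fraction of draws with positive net
monetary benefit `λ·ΔQALY − ΔCost`).

Age-dependent inputs (disease incidence, background mortality, excess costs)
are curve *inputs*; the bundled defaults are synthetic curves anchored exactly
at published age-65 values (see `docs/methods.md` for what they do and do not
represent).

## Worked example

```
$ quitcea trial-cea
Within-trial (24-week) cost-effectiveness [2012 NZ$]

intervention cost per participant:
  psp_training                 2.47
  psp_salary                 329.67
  gp_visit                    65.00
  pedometer                   30.44
  quitline                   195.33
  total                      622.91
...
Incremental programme cost: 427.58
ICER per quitter (ITT):      30,541
ICER per quitter (adherent): 4,072
```

The intervention costs NZ$622.91 per participant (training and salary
amortised over the whole arm) versus NZ$195.33 for Quitline alone — an
incremental NZ$427.58. At the observed quit rates that is ≈NZ$30,541 per
additional quitter on an intention-to-treat basis, but ≈NZ$4,072 within the
adherent subgroup, whose quit rate (32.2%) is much higher.

```
$ quitcea run-model --sex male --start-age 40
intervention: cost NZ$ 8,684, QALYs 15.866, life-years 38.75
usual_care:   cost NZ$ 8,336, QALYs 15.810, life-years 38.70
incremental:  cost NZ$ 348, QALYs 0.0569, ICER 6,115
```

Over a 40-year-old male cohort's remaining lifetime, the adherent-group quit
rates yield 0.0569 extra discounted QALYs per person for NZ$348 extra
discounted cost (the programme cost partly offset by averted disease costs):
an ICER of ≈NZ$6,100 per QALY, well under a NZ$20,000/QALY willingness-to-pay
threshold. `quitcea psa`, `quitcea one-way` and `quitcea scenarios` add the
probabilistic, one-way (±2 se or ±20%) and discount-rate/start-age
sensitivity analyses; `quitcea gen-params` and `quitcea gen-trial` write the
default parameter bundle and a synthetic individual-level trial file.

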