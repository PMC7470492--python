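# tbicea

A decision-analytic cost-effectiveness model of tranexamic acid for
patients with mild (with intracranial bleeding) or moderate traumatic
brain injury (TBI), in the UK and Pakistan, from a health-service
perspective over a lifetime horizon.

Tranexamic acid given within 3 hours of a TBI reduces head-injury deaths
(risk ratio 0.78 for mild/moderate injury). Because the drug is cheap but
the survivors it creates go on to accrue lifelong care costs, whether
treatment is *cost-effective* is a genuine quantitative question. This
package answers it with a two-state (alive/dead) Markov cohort model and
is aimed at health economists and methods researchers who want a tested,
scriptable implementation of the full analysis rather than a spreadsheet.

## Model

A cohort enters alive at age 42 and is followed with **daily cycles for
the first year** and **annual cycles thereafter**:

- **Days 1–28 (trial window):** cumulative 28-day risks of head-injury
  death `p_h` and non-head-injury death `p_nh` are converted to constant
  daily hazards `1 − (1 − p)^{1/28}`. The treated arm's head-injury risk
  is `RR · p_h`; non-head-injury risk is identical across arms.
- **Day 29 onward:** all-cause background mortality from an age-indexed
  life table `q_x`, multiplied by a standardised mortality ratio —
  SMR = 4.00 in the first year after injury, 2.26 thereafter — capped at 1.
- **Valuation:** discounted (3.5%/yr UK, 3%/yr Pakistan, continuous-time
  `(1+r)^{−t}`) life-years, QALYs (weighted Glasgow Outcome Scale utility
  0.75 at entry, declining with age; trial decedents accrue zero utility)
  and costs (treatment components in the treated arm; hospital stay;
  survivor-conditioned monitoring costs, UK only).
- **Outputs:** incremental cost-effectiveness ratios
  ICER = ΔC/ΔE, net monetary benefit `λ·ΔE − ΔC`, probabilistic
  sensitivity analysis (1000 Monte Carlo parameter draws),
  cost-effectiveness acceptability curves, a one-way scenario/tornado
  set, and a time-to-treatment scan.

All base-case parameters ship as a built-in catalogue
(`tbicea/data/base_case_parameters.yaml`) of tagged distributions —
beta for risks and utilities, lognormal for the treatment-effect risk
ratio, normal for the SMRs, gamma for hospital length of stay. Bundled
synthetic Gompertz–Makeham life tables stand in for the national life
tables (see `docs/methods.md`), and a synthetic two-arm trial generator
supports parameter-recovery testing of the whole chain.

## Worked example

```python
from tbicea import build_base_case, bundled_life_table, run_deterministic, run_psa

params = build_base_case("UK")
table = bundled_life_table("UK")

det = run_deterministic(params, table)
print(f"dCost={det.delta_cost:.0f} dQALY={det.delta_qaly:.3f} "
      f"ICER={det.icer_per_qaly:.0f}/QALY")

psa = run_psa(params, table, n_sims=1000, seed=1)
print(f"P(cost-effective at 20000/QALY) = {psa.prob_ce_at_threshold:.3f}")
```

prints

```
dCost=775 dQALY=0.179 ICER=4331/QALY
P(cost-effective at 20000/QALY) = 0.995
```

Treating 1 patient costs the UK health service an extra £775 (≈3% drug
and administration, ≈97% monitoring costs of the additional survivors)
and yields 0.179 extra QALYs — about £4331 per QALY, far below the
£20 000/QALY threshold, and cost-effective in 99.5% of probabilistic
simulations. The Pakistan base case gives ≈US$22 per QALY against a
US$158 threshold.

The same analyses are available from the shell:

```bash
tbicea base-case --country UK
tbicea psa --country Pakistan --n-sims 1000 --seed 7 --out runs/pk
tbicea tornado --country UK --plot --out runs/uk
tbicea delay-scan --country UK
tbicea synth-trial --country UK --n-per-arm 10000 --seed 3
```

Each run writes CSV outputs and a JSON manifest that reproduces it
byte-for-byte.

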