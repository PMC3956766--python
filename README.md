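# menomark

A Markov cohort cost-utility model comparing the levonorgestrel-releasing
intrauterine system (LNG-IUS) with usual medical treatment (tranexamic or
mefenamic acid, norethisterone, oral contraceptives, depot injection) for
menorrhagia — heavy menstrual bleeding — in UK primary care.

The package is for health economists and methodologists who want a tested,
fully reproducible implementation of this trial-derived decision model: the
deterministic base case, its deterministic sensitivity analyses, a
probabilistic sensitivity analysis with acceptability curves, and — because
the original per-woman data are not public — a synthetic trial generator so
the whole estimation pipeline can be exercised and validated end to end.

## The model

Each randomised arm follows a cohort of women through eight
treatment-pathway health states in monthly cycles over a 24-month horizon:

    initial allocated treatment → well with allocated treatment (absorbing)
                                → symptomatic with allocated treatment
                                → change to the other treatment → well with other (absorbing)
                                → no treatment
                                → surgery (one cycle) → post-surgery (absorbing)

with the structural rules that a woman who leaves her allocated treatment
never returns to it, a well woman does not spontaneously become
symptomatic, and a treatment change requires at least one cycle before she
can be well on the new treatment.

For state occupancy vector `π_t` and transition matrix `P` (a dedicated row
governs the first transition out of the initial state), the cohort evolves
as `π_{t+1} = π_t P`. Discounted QALYs and costs per woman are

    QALY = Σ_t (1.035)^(−t/12) · (π_t u) / 12 ,
    Cost = Σ_t (1.035)^(−t/12) · [ event costs · flows_t + scheduled + recurring · π_t ] ,

where `u` holds per-state annual utilities (EQ-5D-3L or SF-6D), event costs
(device insertion, discontinuation, surgery at £1720.18, switching
treatment) attach to the probability mass flowing through the corresponding
transitions, and recurring prescription costs attach to occupancy of
medical-treatment states. Arms are compared by the incremental
cost-effectiveness ratio ICER = ΔCost/ΔQALY or by dominance when one arm is
cheaper and at least as effective. The probabilistic sensitivity analysis
jointly redraws every transition row from a Dirichlet distribution (observed
counts as concentrations) and every utility from its Beta distribution, and
summarises decision uncertainty as cost-effectiveness acceptability curves
based on net monetary benefit `λ·QALY − Cost`.

All parameters ship with the package
(`src/menomark/data/reference_parameters.yaml`) and every modelling
convention left open by the source tables is an explicit, documented switch
(`docs/methods.md`).

## A worked example

```python
import menomark as mm

spec = mm.load_reference_spec("eq5d")   # packaged tables, EQ-5D utilities
result = mm.evaluate_spec(spec)
print(result.cost_per_arm, result.qaly_per_arm, str(result.verdict))
```

prints (costs in 2011 GBP per woman, discounted at 3.5%/year):

```
{'lng_ius': 441.31, 'usual_medical': 337.02}
{'lng_ius': 1.5796, 'usual_medical': 1.5136}
ICER 1580 per QALY
```

LNG-IUS costs about £104 more per woman over two years but yields 0.066
additional QALYs, so each extra QALY costs roughly £1,580 — far below
conventional willingness-to-pay thresholds. Swapping the instrument
(`mm.load_reference_spec("sf6d")`) flips the QALY difference to −0.0009, and
usual medical treatment dominates: the cost-effectiveness verdict hinges on
which quality-of-life instrument is used.

The scripts in `examples/` walk through each capability: the base case,
the deterministic sensitivity analyses, the probabilistic analysis with
acceptability curves, and parameter recovery from a synthetic trial. A thin
CLI wraps the same functions, e.g.

```sh
menomark base-case --instrument eq5d --out-dir results
menomark psa --n-draws 1000 --seed 1 --out-dir results
```

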