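# sabd — stratified adaptive Bryant & Day phase II designs

`sabd` designs and evaluates two-stage single-arm phase II oncology
trials with **co-primary endpoints** (response and non-toxicity) in
**two pre-defined subgroups** — for example frail and fit older
patients, or biomarker-negative and biomarker-positive patients.

A classical Bryant & Day (BD) design monitors both endpoints in a single
population: after `N1` patients the trial stops for futility unless both
the response count and the non-toxicity count reach their stage-1
boundaries (`X_R1 ≥ k_R1` and `X_T1 ≥ k_T1`); the treatment is declared
promising if the final counts over `N` patients also clear their
boundaries (`X_R ≥ k_R` and `X_T ≥ k_T`).

The stratified adaptive BD (SABD) design runs this logic in two strata
under a hierarchy assumption (true rates in the positive subgroup are at
least those in the negative subgroup).  After stage 1 (`N1⁻` and `N1⁺`
patients):

* negative subgroup passes → accrual continues in the unselected
  population; a go-decision in the unselected population (**S1**)
  requires the negative subgroup's final counts to pass, and failing
  that a go restricted to the positive subgroup (**S2**) requires the
  positive totals over `N⁺` patients to pass;
* only the positive subgroup passes → accrual continues in that
  subgroup alone up to `Ne⁺` patients (**enrichment**), and a
  positive-subgroup-only go (**S3**) requires the enrichment totals to
  pass;
* neither passes → stop for futility.

With independent endpoints every pathway probability factorises into
binomial tails and two-stage joint pass probabilities, so type I error
rates (α under H00, α_R under H01, α_T under H10), power
(`min{P(S1|H11⁻), P(S2)+P(S3) at the heterogeneity state}`), expected
sample size (ESS) and probability of early termination (PET) are all
computed **exactly**.  The package provides:

* `sabd.core` — the binomial pass-probability calculus;
* `sabd.bryant_day` — BD operating characteristics and the optimal /
  minimax design search;
* `sabd.design` — exact SABD operating characteristics;
* `sabd.search` — the reduced optimal SABD search (9 of the 15
  parameters fixed by two inner BD searches at halved type I error
  rates, the remaining 6 enumerated);
* `sabd.simulate` — a vectorised Monte Carlo simulator and the
  parallel-BD comparison (two independent BD trials, one per subgroup);
* `sabd.oracle` — a brute-force enumeration oracle for tiny designs,
  used as the test reference;
* a `sabd` command-line interface, and three shipped case-study
  fixtures.

## Worked example

```python
from sabd import load_case, sabd_operating_characteristics

case = load_case(1)          # hypotheses p0 = 0.70, p1 = 0.90 for both
oc = sabd_operating_characteristics(case.design, case.hypotheses)
print(f"alpha_R = {oc.alpha_r:.3f}  alpha_T = {oc.alpha_t:.3f}  "
      f"power = {oc.power:.3f}")
print(f"max ESS = {oc.max_ess:.1f}  min PET = {oc.min_pet:.3f}  "
      f"max N = {oc.max_sample_size}")
```

prints

```
alpha_R = 0.094  alpha_T = 0.094  power = 0.800
max ESS = 42.5  min PET = 0.415  max N = 67
```

i.e. this 67-patient design falsely declares the treatment promising
with probability 0.094 when response (or non-toxicity) is at its
unacceptable 70% level, detects a truly acceptable 90%/90% treatment
with probability 0.800, enrols on average at most 42.5 patients over the
mixed hypothesis states, and stops at the interim with probability at
least 0.415 when one endpoint is unacceptable.

The same numbers from the shell:

```sh
sabd sabd-oc --case 1
sabd bd-search --pr0 0.7 --pr1 0.9 --pt0 0.7 --pt1 0.9 \
     --alpha-r 0.05 --alpha-t 0.05 --beta 0.2
sabd simulate --case 2 --scenario 3 --reps 100000 --seed 1 --format json
```

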