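# rivapk

Population pharmacokinetics and renal-function-based dose optimization of
once-daily oral rivaroxaban in non-valvular atrial-fibrillation (AF)
patients.

Rivaroxaban is dosed by renal function, and Asian AF cohorts reach higher
exposures than the Western populations the approved doses were developed
in.  `rivapk` implements the full modeling workflow used to ask "which dose
puts the most patients inside the typical exposure window?" for a sparse
real-world study: steady-state peak (2–4 h) and trough (22–24 h) anti-Xa
derived concentrations from 60 patients in a two-period crossover (standard
dose, then the reduced Japan-specific dose, assigned at the CrCl 50 mL/min
cut-off).

## The model

One-compartment kinetics with first-order absorption and elimination at
steady state,

    C(t) = (D·ka)/(V·(ka−ke)) · [ e^(−ke·t)/(1−e^(−ke·τ))
                                 − e^(−ka·t)/(1−e^(−ka·τ)) ],  ke = CL/V,

with power-law covariate effects on the typical parameters,

    CL/F = 4.19·(CrCl/57.5)^0.277 L/h,   V/F = 37.5·(WT/63)^0.412 L,
    ka = 0.697 h⁻¹,

log-normal interindividual variability on CL/F (21.94 %CV) and ka
(75.91 %CV), and additive residual error (SD 0.092 on the log scale by
default; a linear mg/L mode is configurable).  Estimation is first-order
conditional (FOCE) with a frequentist prior anchoring the weakly identified
absorption constant.  See `docs/methods.md` for the complete account.

## What the package does

| capability | entry points |
| --- | --- |
| structural/covariate model, exposures, Cockcroft–Gault | `rivapk.model` |
| synthetic cohort & crossover study generator | `rivapk.cohort` |
| NONMEM-dialect event-record CSV I/O | `rivapk.data` |
| FOCE estimation with ka prior, SEs, shrinkage | `rivapk.estimate` |
| stepwise covariate search (ΔOFV 3.84 / 6.63) | `rivapk.scm` |
| residuals (CWRES), VPC, nonparametric bootstrap | `rivapk.diagnostics` |
| Monte Carlo dose–exposure simulation & target attainment | `rivapk.dosing` |
| reproducible end-to-end pipeline + CLI | `rivapk.pipeline`, `rivapk` CLI |

## Worked example

```python
import rivapk as rp

# simulate the 60-patient crossover study from the final model
ds = rp.simulate_study(rp.CohortConfig(), rp.FINAL_MODEL, seed=2022)
fr = rp.fit(ds)                      # FOCE + ka prior
print(fr.theta["tv_cl"], fr.iiv_cv["cl"], fr.eta_shrinkage["cl"])
```

Running `python examples/02_simulate_and_fit.py` prints:

```
dataset: 60 subjects, 240 observations
converged: True   OFV: -109.44

parameter     estimate   RSE%    truth
tv_cl            4.204    2.7     4.19
tv_v             38.88    2.1     37.5
tv_ka            0.673    9.9    0.697
crcl_on_cl      0.3172   22.8    0.277
wt_on_v         0.3947   22.8    0.412
omega2_cl        0.038   18.8  0.04814
omega2_ka        0.469   24.1   0.5762
sigma          0.08964    6.2    0.092

IIV CL/F: 19.5 %CV   eta shrinkage CL/F: -0.5 %   eps shrinkage: 23.2 %
```

The estimates sit close to the generating values: the sparse peak/trough
design identifies the model once the absorption constant is anchored by
its prior.  The other scripts in `examples/` each demonstrate one
capability (structural model, covariate search, diagnostics, dose
optimization) and print a line explaining their numbers.

A thin CLI mirrors the pipeline stages:

```bash
rivapk simulate-cohort --n 60 --seed 1 --out dataset.csv
rivapk fit --data dataset.csv
rivapk dose-sim --seed 1 --out doses.csv
rivapk run --seed 1 --outdir run_artifacts
```

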