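"""Simulate the sparse crossover study and re-estimate the model.

Generates the 60-patient design (peak/trough sampling under standard then
reduced doses), fits the one-compartment model by FOCE with the ka prior,
and compares the estimates with the generating values.
"""

import rivapk as rp

truth = rp.FINAL_MODEL
ds = rp.simulate_study(rp.CohortConfig(), truth, seed=2022)
print(f"dataset: {ds.n_subjects} subjects, {ds.n_observations} observations")

fr = rp.fit(ds)
print(f"converged: {fr.converged}   OFV: {fr.ofv:.2f}\n")
print(f"{'parameter':12s} {'estimate':>9s} {'RSE%':>6s} {'truth':>8s}")
gen = rp.estimate.theta_from_popparams(truth, fr.config)
for k, v in fr.theta.items():
    print(f"{k:12s} {v:9.4g} {fr.rse[k]:6.1f} {gen[k]:8.4g}")
print(f"\nIIV CL/F: {fr.iiv_cv['cl']:.1f} %CV   "
      f"eta shrinkage CL/F: {fr.eta_shrinkage['cl']:.1f} %   "
      f"eps shrinkage: {fr.eps_shrinkage:.1f} %")
print("Estimates close to the generating values (and CL/F eta shrinkage")
print("below 20%) show the sparse peak/trough design still identifies the")
print("model once the absorption constant is anchored by its prior.")
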