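"""Internal model evaluation: nonparametric bootstrap and VPC.

Bootstraps a synthetic cohort (resampling subjects with replacement,
refitting each replicate) and runs a visual predictive check over the same
design.  Scaled-down replicate counts keep the run short; scale `n_reps`
and `n_sim_cohorts` up for production use (2,000 / 1,000 are conventional).
"""

import vancopk as v

cohort = v.simulate_cohort(v.CohortSpec(n_subjects=100, seed=21))
fit = v.fit(v.FINAL_MODEL, cohort, compute_se=False)

boot = v.bootstrap(v.FINAL_MODEL, cohort, n_reps=50, seed=5, original_fit=fit)
cols = ["parameter", "original", "median", "se", "ci95_lo", "ci95_hi"]
print(boot.table[cols].round(4).to_string(index=False))
print(f"{boot.n_converged}/{boot.n_attempted} replicates converged; "
      "medians should sit close to the original estimates (a stable model).")

res = v.vpc(fit.model, cohort, n_sim_cohorts=100, seed=5)
print(res.bins.round(2).to_string(index=False))
print(f"fraction of observations inside the simulated 5-95% band: "
      f"{res.fraction_inside:.2f} (expect ~0.90 when the model is adequate)")
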