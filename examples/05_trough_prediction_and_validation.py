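"""Individual trough prediction and external-validation metrics.

Predicts steady troughs for two neonates from demographics and prescription
alone (population prediction, eta = 0), shows how a measured level updates
the prediction (MAP via the empirical Bayes eta), and summarises
prediction-error metrics.
"""

import vancopk as v

cases = [
    # (birth weight kg, postnatal age d, dose mg q8h, measured trough)
    (3.9, 23.0, 35.0, 4.26),
    (4.5, 25.0, 60.0, 9.03),
]

pred = []
for bbw, pna, dose, measured in cases:
    regimen = [v.DoseEvent(8.0 * k, dose, 1.0) for k in range(6)]
    cov = v.Covariates(BBW=bbw, PNA=pna)
    c = v.predict_trough(v.FINAL_MODEL, cov, regimen, at_dose_index=6)
    pe = v.case_prediction_error(c, measured)
    pred.append(c)
    print(f"BBW {bbw} kg, PNA {pna:.0f} d, {dose:.0f} mg q8h: "
          f"predicted trough {c:.2f} ug/mL vs measured {measured} "
          f"({pe:.1f}% prediction error)")

    # conditioning on the measured level individualises the prediction
    prior = [v.Observation(39.8, measured)]
    c_map = v.predict_trough(v.FINAL_MODEL, cov, regimen, 6, prior_obs=prior)
    print(f"  after one measured level the MAP prediction moves to "
          f"{c_map:.2f} ug/mL")

m = v.external_metrics(pred, [c[3] for c in cases])
print(f"MPE {m.mpe:+.3f} ug/mL (bias), MAE {m.mae:.3f} ug/mL, "
      f"MSPE {m.mspe:.3f} (ug/mL)^2 over {m.n} predictions")
print("Population predictions assume nominal regimens and 1-h infusions; "
      "they individualise further as measured levels accrue.")
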