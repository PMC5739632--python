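"""The published final model: typical values, covariate effects, disposition.

Evaluates the packaged neonatal vancomycin model at its reference
covariates and for an individual patient, and derives the two-compartment
disposition constants.
"""

import vancopk as v

# typical clearance at the reference covariates (median birth weight and
# postnatal age of the modelled cohort)
ref = v.Covariates(BBW=3.22, PNA=29.0)
cl = v.individual_param(v.FINAL_MODEL, "CL", ref)
vd = v.FINAL_MODEL.typical["V1"] + v.FINAL_MODEL.typical["V2"]
print(f"typical CL            : {cl:.3f} L/h "
      f"({v.weight_normalized(cl, 3.95):.3f} L/h/kg at the 3.95-kg median weight)")
print(f"total Vd (V1+V2)      : {vd:.3f} L "
      f"({v.weight_normalized(vd, 3.95):.3f} L/kg)")

# an individual: 3.9-kg birth weight, 23 days old -> higher clearance
case = v.Covariates(BBW=3.9, PNA=23.0)
cl_case = v.individual_param(v.FINAL_MODEL, "CL", case)
print(f"case CL (BBW 3.9, PNA 23): {cl_case:.4f} L/h "
      "(birth weight raises CL, younger age lowers it)")

# disposition constants of the two-compartment model at that clearance
sp = v.StructuralParams(V1=1.27, V2=2.422, CL=cl_case, Q=1.161)
alpha, beta, A, B = v.disposition(sp)
print(f"disposition           : alpha {alpha:.3f}/h (fast distribution), "
      f"beta {beta:.3f}/h (terminal half-life {0.693 / beta:.1f} h)")
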