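"""Structural and statistical model for vancomycin population pharmacokinetics.

The structural model is a one- or two-compartment open model with first-order
elimination, dosed by constant-rate intravenous infusion.  Concentrations are
obtained in closed form as a superposition of the standard bi-exponential
infusion solution, so no ODE integration is needed at fit time.

The statistical model layers three components on top of the kinetics:

* covariate effects on the typical parameter values — power ("allometric")
  functions of continuous covariates normalised to a reference (median) value,
  and log-linear effects of 0/1 categorical covariates;
* inter-individual variability — a log-normal (exponential) random effect
  ``P_i = P_pop * exp(eta_i)`` with ``eta_i ~ N(0, omega^2)``;
* residual error — additive, proportional or combined Gaussian noise on the
  predicted concentration.

Units: concentrations in ug/mL (identically mg/L), doses in mg, volumes in L,
clearances in L/h, times in hours.  ``FINAL_MODEL`` is the published neonatal
vancomycin model (two compartments, birth-body-weight and postnatal-age
effects on clearance, additive residual error) and is also shipped as a YAML
spec file under :mod:`vancopk.specs`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Literal, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "DoseEvent",
    "Observation",
    "Covariates",
    "CovariateEffect",
    "ResidualModel",
    "PopulationModel",
    "StructuralParams",
    "FINAL_MODEL",
    "LLOQ",
    "individual_param",
    "disposition",
    "concentration",
    "apply_residual",
    "weight_normalized",
    "load_model_spec",
    "save_model_spec",
    "final_model",
]

#: Lower limit of quantification of the vancomycin assay, ug/mL.
LLOQ = 1.0

#: Default infusion duration, hours.  Dosing records rarely state the actual
#: duration; 1 h is standard neonatal vancomycin practice.
DEFAULT_INFUSION_HOURS = 1.0


class MissingCovariateError(KeyError):
    """A covariate required by a model effect is absent from the record."""


@dataclass(frozen=True)
class DoseEvent:
    """A single constant-rate intravenous infusion.

    Parameters
    ----------
    start_time : hours since the subject's first dose (>= 0).
    amount : dose in mg (> 0).
    infusion_duration : infusion length in hours (> 0).
    """

    start_time: float
    amount: float
    infusion_duration: float = DEFAULT_INFUSION_HOURS

    def __post_init__(self) -> None:
        if self.start_time < 0:
            raise ValueError(f"dose start_time must be >= 0, got {self.start_time}")
        if self.amount <= 0:
            raise ValueError(f"dose amount must be > 0, got {self.amount}")
        if self.infusion_duration <= 0:
            raise ValueError(
                f"infusion_duration must be > 0, got {self.infusion_duration}"
            )


@dataclass(frozen=True)
class Observation:
    """A measured serum concentration.

    ``below_lloq`` flags values under the assay's lower limit of
    quantification (1 ug/mL); such records are excluded from likelihoods.
    """

    time: float
    conc: float
    below_lloq: bool = False

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"observation time must be >= 0, got {self.time}")
        if not self.below_lloq and self.conc < LLOQ:
            raise ValueError(
                f"conc {self.conc} is below the LLOQ ({LLOQ}) but not flagged"
            )


_CONTINUOUS_COVARIATES = (
    "GA", "PNA", "PMA", "BBW", "BW", "HT", "BSA", "SCr", "GFR",
    "BUN", "ALT", "ALB",
)
_CATEGORICAL_COVARIATES = ("sex", "preterm", "panipenem", "furosemide")


@dataclass(frozen=True)
class Covariates:
    """Per-subject covariate record.

    Continuous covariates: GA (weeks), PNA (days, at concentration
    determination), PMA (weeks), BBW and BW (kg), HT (cm), BSA (m^2),
    SCr (umol/L), GFR (mL/min/1.73 m^2), BUN (mmol/L), ALT (U/L), ALB (g/L).
    Categorical (0/1): sex (1 = male), preterm, panipenem, furosemide.
    Unused covariates may be left as ``None``.
    """

    sex: float | None = None
    GA: float | None = None
    PNA: float | None = None
    PMA: float | None = None
    BBW: float | None = None
    BW: float | None = None
    HT: float | None = None
    BSA: float | None = None
    SCr: float | None = None
    GFR: float | None = None
    BUN: float | None = None
    ALT: float | None = None
    ALB: float | None = None
    preterm: float | None = None
    panipenem: float | None = None
    furosemide: float | None = None

    def get(self, name: str, *, continuous: bool = True) -> float:
        try:
            value = getattr(self, name)
        except AttributeError:
            raise MissingCovariateError(f"unknown covariate {name!r}") from None
        if value is None:
            raise MissingCovariateError(f"covariate {name!r} is missing")
        value = float(value)
        if continuous and value <= 0:
            raise ValueError(f"continuous covariate {name!r} must be > 0, got {value}")
        return value

    def as_dict(self) -> dict[str, float | None]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class CovariateEffect:
    """One covariate–parameter relation.

    Continuous effects are power functions normalised at a reference value
    (typically the dataset median): ``P = tvP * (cov / reference)**exponent``.
    Categorical effects are log-linear in a 0/1 dummy:
    ``P = tvP * exp(exponent * cov)``.
    """

    parameter: str
    covariate: str
    exponent: float
    reference: float | None = None
    kind: Literal["continuous", "categorical"] = "continuous"

    def __post_init__(self) -> None:
        if self.kind == "continuous":
            if self.reference is None or self.reference <= 0:
                raise ValueError(
                    f"continuous effect on {self.covariate!r} needs a positive "
                    f"reference value, got {self.reference}"
                )
        elif self.kind != "categorical":
            raise ValueError(f"unknown effect kind {self.kind!r}")

    def factor(self, cov: Covariates) -> float:
        if self.kind == "continuous":
            value = cov.get(self.covariate, continuous=True)
            return (value / self.reference) ** self.exponent
        value = cov.get(self.covariate, continuous=False)
        return math.exp(self.exponent * value)


@dataclass(frozen=True)
class ResidualModel:
    """Residual (within-subject) error model.

    kind: ``"additive"`` (sd0, ug/mL), ``"proportional"`` (cv, fraction) or
    ``"combined"`` (both, with independent epsilons).  ``variance`` is the
    error variance as a function of the predicted concentration, used by the
    marginal likelihood.
    """

    kind: Literal["additive", "proportional", "combined"] = "additive"
    sd0: float = 0.0
    cv: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("additive", "proportional", "combined"):
            raise ValueError(f"unknown residual model {self.kind!r}")
        if self.sd0 < 0 or self.cv < 0:
            raise ValueError("residual parameters must be >= 0")

    def variance(self, c_pred):
        c_pred = np.asarray(c_pred, dtype=float)
        if self.kind == "additive":
            return np.broadcast_to(self.sd0**2, c_pred.shape).copy()
        if self.kind == "proportional":
            return (self.cv * c_pred) ** 2
        return (self.cv * c_pred) ** 2 + self.sd0**2

    def param_names(self) -> tuple[str, ...]:
        if self.kind == "additive":
            return ("sd0",)
        if self.kind == "proportional":
            return ("cv",)
        return ("cv", "sd0")


def apply_residual(c_pred, residual: ResidualModel, eps, eps2=None):
    """Perturb a predicted concentration with residual error.

    ``eps`` (and ``eps2`` for the combined model's additive component) are
    standard-normal draws.  For the combined model with ``eps2=None`` the same
    draw is reused for both components — pass independent draws for
    simulation.  Simulated concentrations may be negative; truncation to zero
    is the caller's choice (simulation output truncates, likelihoods do not).
    """
    c_pred = np.asarray(c_pred, dtype=float)
    eps = np.asarray(eps, dtype=float)
    if residual.kind == "additive":
        return c_pred + eps * residual.sd0
    if residual.kind == "proportional":
        return c_pred * (1.0 + eps * residual.cv)
    e2 = eps if eps2 is None else np.asarray(eps2, dtype=float)
    return c_pred * (1.0 + eps * residual.cv) + e2 * residual.sd0


@dataclass(frozen=True)
class StructuralParams:
    """Individual structural parameters of the (one- or) two-compartment model.

    V1, V2 in L; CL, Q in L/h.  Micro rate constants k10 = CL/V1,
    k12 = Q/V1, k21 = Q/V2 (1/h).  ``Q = 0`` degenerates gracefully to the
    one-compartment model.
    """

    V1: float
    V2: float
    CL: float
    Q: float

    def __post_init__(self) -> None:
        if self.V1 <= 0 or self.CL <= 0:
            raise ValueError("V1 and CL must be > 0")
        if self.Q < 0 or self.V2 < 0:
            raise ValueError("Q and V2 must be >= 0")
        if self.Q > 0 and self.V2 <= 0:
            raise ValueError("V2 must be > 0 when Q > 0")

    @property
    def k10(self) -> float:
        return self.CL / self.V1

    @property
    def k12(self) -> float:
        return self.Q / self.V1

    @property
    def k21(self) -> float:
        return self.Q / self.V2 if self.V2 > 0 else 0.0


def disposition(sp: StructuralParams) -> tuple[float, float, float, float]:
    """Hybrid disposition constants (alpha, beta, A, B) of the model.

    alpha and beta (1/h) are the roots of
    ``x**2 - (k10 + k12 + k21) x + k10*k21`` with alpha >= beta; A and B (1/L)
    are the unit-bolus macro coefficients, ``A + B = 1/V1``.  With ``Q = 0``
    the kinetics collapse to a single exponential ``k10`` carried by the
    A/alpha term (B = 0, beta = 0).
    """
    k10, k12, k21 = sp.k10, sp.k12, sp.k21
    if sp.Q == 0.0:
        return k10, 0.0, 1.0 / sp.V1, 0.0
    s = k10 + k12 + k21
    p = k10 * k21
    disc = math.sqrt(max(s * s - 4.0 * p, 0.0))
    alpha = 0.5 * (s + disc)
    beta = p / alpha  # Vieta; numerically stabler than (s - disc) / 2
    A = (alpha - k21) / (sp.V1 * (alpha - beta))
    B = (k21 - beta) / (sp.V1 * (alpha - beta))
    return alpha, beta, A, B


def _infusion_phi(te, dur, lam):
    """Unit-rate infusion response ``(1 - e^{-lam*min(te,T)}) e^{-lam*(te-T)+} / lam``."""
    te = np.asarray(te, dtype=float)
    up = -np.expm1(-lam * np.minimum(te, dur))
    decay = np.exp(-lam * np.maximum(te - dur, 0.0))
    return up * decay / lam


def concentration(t, doses: Sequence[DoseEvent], sp: StructuralParams):
    """Concentration (ug/mL) at time(s) ``t`` under a multi-dose regimen.

    Closed-form superposition of constant-rate infusion responses; linear in
    dose amounts, continuous in ``t``, and exactly equal to the solution of
    the two-compartment ODE system.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    out = np.zeros_like(t_arr, dtype=float)
    if doses:
        alpha, beta, A, B = disposition(sp)
        for d in doses:
            te = t_arr - d.start_time
            active = te > 0
            if not np.any(active):
                continue
            rate = d.amount / d.infusion_duration
            contrib = A * _infusion_phi(te[active], d.infusion_duration, alpha)
            if B > 0.0 and beta > 0.0:
                contrib = contrib + B * _infusion_phi(te[active], d.infusion_duration, beta)
            out[active] += rate * contrib
    return float(out) if np.isscalar(t) or np.ndim(t) == 0 else out


_STRUCTURAL_PARAMS = {"1cmt": ("V1", "CL"), "2cmt": ("V1", "V2", "CL", "Q")}


@dataclass(frozen=True)
class PopulationModel:
    """A population PK model: typical values, covariate effects, IIV, residual.

    ``typical`` maps structural parameter names to population typical values;
    ``iiv`` maps parameter names to omega (the standard deviation of the
    log-normal random effect); ``residual`` is the residual-error model.
    """

    structural: Literal["1cmt", "2cmt"] = "2cmt"
    typical: Mapping[str, float] = field(default_factory=dict)
    effects: tuple[CovariateEffect, ...] = ()
    iiv: Mapping[str, float] = field(default_factory=dict)
    residual: ResidualModel = field(default_factory=ResidualModel)
    infusion_duration_default: float = DEFAULT_INFUSION_HOURS

    def __post_init__(self) -> None:
        if self.structural not in _STRUCTURAL_PARAMS:
            raise ValueError(f"unknown structural model {self.structural!r}")
        needed = _STRUCTURAL_PARAMS[self.structural]
        for p in needed:
            if p not in self.typical:
                raise ValueError(f"typical value for {p!r} missing")
            if self.typical[p] <= 0:
                raise ValueError(f"typical value for {p!r} must be > 0")
        for eff in self.effects:
            if eff.parameter not in needed:
                raise ValueError(
                    f"effect on unknown structural parameter {eff.parameter!r}"
                )
        for p, om in self.iiv.items():
            if p not in needed:
                raise ValueError(f"IIV on unknown structural parameter {p!r}")
            if om < 0:
                raise ValueError("omega must be >= 0")
        object.__setattr__(self, "typical", dict(self.typical))
        object.__setattr__(self, "iiv", dict(self.iiv))
        object.__setattr__(self, "effects", tuple(self.effects))

    @property
    def structural_names(self) -> tuple[str, ...]:
        return _STRUCTURAL_PARAMS[self.structural]

    def effects_on(self, param: str) -> tuple[CovariateEffect, ...]:
        return tuple(e for e in self.effects if e.parameter == param)

    def typical_param(self, param: str, cov: Covariates) -> float:
        """Typical (eta = 0) value of ``param`` for a subject's covariates."""
        return individual_param(self, param, cov, eta=0.0)

    def structural_params(
        self, cov: Covariates, etas: Mapping[str, float] | None = None
    ) -> StructuralParams:
        etas = etas or {}
        vals = {
            p: individual_param(self, p, cov, eta=etas.get(p, 0.0))
            for p in self.structural_names
        }
        if self.structural == "1cmt":
            return StructuralParams(V1=vals["V1"], V2=0.0, CL=vals["CL"], Q=0.0)
        return StructuralParams(**vals)

    def with_values(self, **updates: float) -> "PopulationModel":
        """Copy with updated typical values / exponents / omegas / residual params.

        Accepts keys in the flat naming used by the estimation engine:
        ``tvV1``, ``dCLdBBW``, ``omCL``, ``sd0``, ``cv``.
        """
        typical = dict(self.typical)
        iiv = dict(self.iiv)
        effects = list(self.effects)
        res = {"sd0": self.residual.sd0, "cv": self.residual.cv}
        for key, value in updates.items():
            if key.startswith("tv") and key[2:] in typical:
                typical[key[2:]] = value
            elif key.startswith("om") and key[2:] in iiv:
                iiv[key[2:]] = value
            elif key in ("sd0", "cv"):
                res[key] = value
            elif key.startswith("d") and "d" in key[1:]:
                pname, cname = key[1:].split("d", 1)
                for i, eff in enumerate(effects):
                    if eff.parameter == pname and eff.covariate == cname:
                        effects[i] = replace(eff, exponent=value)
                        break
                else:
                    raise KeyError(f"no effect matching {key!r}")
            else:
                raise KeyError(f"unknown parameter {key!r}")
        return replace(
            self,
            typical=typical,
            iiv=iiv,
            effects=tuple(effects),
            residual=replace(self.residual, **res),
        )

    def param_value(self, name: str) -> float:
        """Value of a flat-named parameter (``tvCL``, ``dCLdBBW``, ``omCL``...)."""
        if name.startswith("tv") and name[2:] in self.typical:
            return self.typical[name[2:]]
        if name.startswith("om") and name[2:] in self.iiv:
            return self.iiv[name[2:]]
        if name in ("sd0", "cv"):
            return getattr(self.residual, name)
        if name.startswith("d"):
            pname, cname = name[1:].split("d", 1)
            for eff in self.effects:
                if eff.parameter == pname and eff.covariate == cname:
                    return eff.exponent
        raise KeyError(name)


def individual_param(
    pop: PopulationModel, param: str, cov: Covariates, eta: float = 0.0
) -> float:
    """Individual value of a structural parameter.

    ``P_i = tvP * prod_continuous (cov/ref)**exp * prod_categorical
    exp(exp * cov) * exp(eta)``.  With no effects and ``eta = 0`` this is the
    population typical value.
    """
    if param not in pop.typical:
        raise KeyError(f"model has no parameter {param!r}")
    value = pop.typical[param]
    for eff in pop.effects_on(param):
        value *= eff.factor(cov)
    return value * math.exp(eta)


def weight_normalized(value: float, weight: float) -> float:
    """Scale a clearance or volume to a per-kg value."""
    if weight <= 0:
        raise ValueError(f"weight must be > 0, got {weight}")
    return value / weight


# --------------------------------------------------------------------------
# Model spec files (YAML)

def _effect_to_dict(eff: CovariateEffect) -> dict:
    d = {
        "parameter": eff.parameter,
        "covariate": eff.covariate,
        "exponent": float(eff.exponent),
        "kind": eff.kind,
    }
    if eff.reference is not None:
        d["reference"] = float(eff.reference)
    return d


def save_model_spec(model: PopulationModel, path) -> None:
    doc = {
        "structural": model.structural,
        "typical": {k: float(v) for k, v in model.typical.items()},
        "effects": [_effect_to_dict(e) for e in model.effects],
        "iiv": {k: float(v) for k, v in model.iiv.items()},
        "residual": {
            "kind": model.residual.kind,
            "sd0": float(model.residual.sd0),
            "cv": float(model.residual.cv),
        },
        "infusion_duration_default": float(model.infusion_duration_default),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_model_spec(path_or_stream) -> PopulationModel:
    if hasattr(path_or_stream, "read"):
        doc = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream) as fh:
            doc = yaml.safe_load(fh)
    effects = tuple(
        CovariateEffect(
            parameter=e["parameter"],
            covariate=e["covariate"],
            exponent=float(e["exponent"]),
            reference=e.get("reference"),
            kind=e.get("kind", "continuous"),
        )
        for e in doc.get("effects", [])
    )
    res = doc.get("residual", {})
    return PopulationModel(
        structural=doc.get("structural", "2cmt"),
        typical=doc.get("typical", {}),
        effects=effects,
        iiv=doc.get("iiv", {}),
        residual=ResidualModel(
            kind=res.get("kind", "additive"),
            sd0=float(res.get("sd0", 0.0)),
            cv=float(res.get("cv", 0.0)),
        ),
        infusion_duration_default=float(doc.get("infusion_duration_default", 1.0)),
    )


def final_model() -> PopulationModel:
    """Load the published final model from its packaged spec file."""
    with resources.files("vancopk.specs").joinpath("final_model.yaml").open() as fh:
        return load_model_spec(fh)


#: The published final model: two compartments; CL scales with birth body
#: weight (reference 3.22 kg, exponent 0.888) and postnatal age (reference
#: 29 d, exponent 0.449); log-normal IIV on CL (omega 0.317); additive
#: residual error with SD 2.187 ug/mL.
FINAL_MODEL = PopulationModel(
    structural="2cmt",
    typical={"V1": 1.27, "V2": 2.422, "CL": 0.42, "Q": 1.161},
    effects=(
        CovariateEffect("CL", "BBW", 0.888, reference=3.22),
        CovariateEffect("CL", "PNA", 0.449, reference=29.0),
    ),
    iiv={"CL": 0.317},
    residual=ResidualModel(kind="additive", sd0=2.187),
)
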