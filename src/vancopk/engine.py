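"""Nonlinear mixed-effects estimation (FOCE) for sparse concentration data.

The marginal likelihood of each subject's data is approximated by expanding
the model around the subject's conditional mode ``eta_hat`` (the empirical
Bayes estimate).  With ``f_i(eta)`` the structural prediction vector,
``G_i = df_i/deta`` at the mode, ``Sigma_i`` the diagonal residual-variance
matrix evaluated at the conditional prediction (the "interaction" form) and
``Omega`` the diagonal IIV covariance, the default FOCE objective per subject
is the linearised marginal Gaussian

    -2 l_i = n_i log(2 pi) + log|V_i| + r_i' V_i^{-1} r_i,
    V_i = G_i Omega G_i' + Sigma_i,   r_i = y_i - f_i(eta_hat) + G_i eta_hat,

summed over subjects (the OFV).  A Laplacian alternative (same conditional
mode, Gauss-Newton curvature) is available via ``method="laplace"``; the two
coincide exactly when the prediction is linear in eta and the error is
additive.  Inner problems are solved by damped Newton iterations, vectorised
across all subjects at once; the outer problem is quasi-Newton (L-BFGS-B) on
log-transformed positive parameters.  Everything is deterministic: the
engine draws no random numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import log_ndtr

from .dataset import EventTable, SubjectData
from .model import LLOQ, Covariates, PopulationModel, ResidualModel

__all__ = [
    "FitResult",
    "IdentifiabilityError",
    "ParameterSpace",
    "compile_dataset",
    "ofv",
    "fit",
    "ebe",
    "shrinkage",
    "cwres",
]

_VAR_FLOOR = 1e-10
_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
# Inner gradient tolerance: the OFV error is quadratic in the residual inner
# gradient, so 1e-6 keeps the OFV accurate to ~1e-12 while the Gauss-Newton
# iterations stay cheap.
_INNER_GTOL = 1e-6
_INNER_MAXITER = 60


class IdentifiabilityError(ValueError):
    """Fewer observations than fixed effects: the fit is not identifiable."""


# --------------------------------------------------------------------------
# Parameter naming and transforms


def _effect_name(parameter: str, covariate: str) -> str:
    return f"d{parameter}d{covariate}"


@dataclass(frozen=True)
class ParameterSpace:
    """Flat naming and log/identity transforms of a model's free parameters.

    Typical values, omegas and residual scales live on the log scale (they
    are positive); covariate exponents are unconstrained.  ``fixed`` names
    are excluded from the optimisation vector.
    """

    names: tuple[str, ...]
    transforms: tuple[str, ...]

    @classmethod
    def from_model(
        cls, model: PopulationModel, fixed: Sequence[str] = ()
    ) -> "ParameterSpace":
        names: list[str] = []
        transforms: list[str] = []
        for p in model.structural_names:
            names.append(f"tv{p}")
            transforms.append("log")
        for eff in model.effects:
            names.append(_effect_name(eff.parameter, eff.covariate))
            transforms.append("identity")
        for p in model.iiv:
            names.append(f"om{p}")
            transforms.append("log")
        for rp in model.residual.param_names():
            names.append(rp)
            transforms.append("log")
        keep = [i for i, n in enumerate(names) if n not in set(fixed)]
        return cls(
            tuple(names[i] for i in keep), tuple(transforms[i] for i in keep)
        )

    @property
    def n_fixed_effects(self) -> int:
        """Number of mean-structure parameters (typical values + exponents)."""
        return sum(
            1 for n, t in zip(self.names, self.transforms)
            if not n.startswith("om") and n not in ("sd0", "cv")
        )

    def pack(self, model: PopulationModel) -> np.ndarray:
        x = np.empty(len(self.names))
        for i, (name, tr) in enumerate(zip(self.names, self.transforms)):
            v = model.param_value(name)
            if tr == "log":
                v = math.log(max(v, 1e-8))
            x[i] = v
        return x

    def unpack(self, x: np.ndarray) -> dict[str, float]:
        out = {}
        for name, tr, v in zip(self.names, self.transforms, x):
            out[name] = math.exp(v) if tr == "log" else float(v)
        return out

    def natural_se(self, x: np.ndarray, se_t: np.ndarray) -> dict[str, float]:
        """Delta-method SEs on the natural scale."""
        out = {}
        for name, tr, v, s in zip(self.names, self.transforms, x, se_t):
            out[name] = float(math.exp(v) * s) if tr == "log" else float(s)
        return out


# --------------------------------------------------------------------------
# Compiled dataset: flat arrays for vectorised prediction


@dataclass
class CompiledDataset:
    """Flat, subject-indexed arrays for fast repeated prediction.

    Observation rows are sorted by subject; BQL rows are excluded (M1).
    ``pairs`` hold every (observation, prior dose) combination so a full
    prediction pass is a handful of vectorised operations.
    """

    subject_ids: list[str]
    covariates: list[Covariates]
    y: np.ndarray              # (N,) observed concentrations
    obs_subj: np.ndarray       # (N,) subject index per observation
    obs_time: np.ndarray       # (N,)
    n_obs: np.ndarray          # (S,)
    p_obs: np.ndarray          # (P,) observation index per pair
    p_subj: np.ndarray         # (P,)
    p_dt: np.ndarray           # (P,) time since dose start (> 0)
    p_rate: np.ndarray         # (P,) mg/h
    p_dur: np.ndarray          # (P,) h
    n_bql_dropped: int

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_observations(self) -> int:
        return len(self.y)


def compile_dataset(data: EventTable) -> CompiledDataset:
    subject_ids, covs = [], []
    y, obs_subj, obs_time = [], [], []
    p_obs, p_subj, p_dt, p_rate, p_dur = [], [], [], [], []
    n_bql = 0
    empty = []
    obs_counter = 0
    for s_idx, subj in enumerate(data.iter_subjects()):
        subject_ids.append(subj.subject_id)
        covs.append(subj.covariates)
        usable = [o for o in subj.observations if not o.below_lloq]
        n_bql += len(subj.observations) - len(usable)
        if not usable:
            empty.append(subj.subject_id)
        for o in usable:
            for d in subj.doses:
                dt = o.time - d.start_time
                if dt > 0:
                    p_obs.append(obs_counter)
                    p_subj.append(s_idx)
                    p_dt.append(dt)
                    p_rate.append(d.amount / d.infusion_duration)
                    p_dur.append(d.infusion_duration)
            y.append(o.conc)
            obs_subj.append(s_idx)
            obs_time.append(o.time)
            obs_counter += 1
    if empty:
        raise ValueError(
            f"subjects with no usable observations: {empty[:5]}"
            + ("..." if len(empty) > 5 else "")
        )
    S = len(subject_ids)
    obs_subj_arr = np.asarray(obs_subj, dtype=np.intp)
    return CompiledDataset(
        subject_ids=subject_ids,
        covariates=covs,
        y=np.asarray(y, dtype=float),
        obs_subj=obs_subj_arr,
        obs_time=np.asarray(obs_time, dtype=float),
        n_obs=np.bincount(obs_subj_arr, minlength=S).astype(float),
        p_obs=np.asarray(p_obs, dtype=np.intp),
        p_subj=np.asarray(p_subj, dtype=np.intp),
        p_dt=np.asarray(p_dt, dtype=float),
        p_rate=np.asarray(p_rate, dtype=float),
        p_dur=np.asarray(p_dur, dtype=float),
        n_bql_dropped=n_bql,
    )


class _Predictor:
    """Maps (parameter values, eta matrix) -> per-observation predictions."""

    def __init__(self, model: PopulationModel, cd: CompiledDataset):
        self.model = model
        self.cd = cd
        self.iiv_params = tuple(model.iiv)
        S = cd.n_subjects
        # per-parameter covariate design: log P_i = log tv + sum_k exp_k * x_ik
        self.design: dict[str, list[tuple[str, np.ndarray]]] = {
            p: [] for p in model.structural_names
        }
        for eff in model.effects:
            name = _effect_name(eff.parameter, eff.covariate)
            x = np.empty(S)
            for i, cov in enumerate(cd.covariates):
                if eff.kind == "continuous":
                    x[i] = math.log(cov.get(eff.covariate) / eff.reference)
                else:
                    x[i] = cov.get(eff.covariate, continuous=False)
            self.design[eff.parameter].append((name, x))

    def subject_params(
        self, values: Mapping[str, float], eta: np.ndarray
    ) -> dict[str, np.ndarray]:
        cd = self.cd
        S = cd.n_subjects
        out = {}
        for p in self.model.structural_names:
            logp = np.full(S, math.log(values[f"tv{p}"]))
            for name, x in self.design[p]:
                logp += values[name] * x
            if p in self.iiv_params:
                logp = logp + eta[:, self.iiv_params.index(p)]
            out[p] = np.exp(logp)
        return out

    def predict(self, values: Mapping[str, float], eta: np.ndarray) -> np.ndarray:
        cd = self.cd
        pars = self.subject_params(values, eta)
        V1 = pars["V1"]
        CL = pars["CL"]
        if self.model.structural == "1cmt":
            alpha = CL / V1
            A = 1.0 / V1
            two_phase = False
        else:
            V2, Q = pars["V2"], pars["Q"]
            k10 = CL / V1
            k12 = Q / V1
            k21 = Q / V2
            s = k10 + k12 + k21
            prod = k10 * k21
            disc = np.sqrt(np.maximum(s * s - 4.0 * prod, 0.0))
            alpha = 0.5 * (s + disc)
            beta = prod / alpha
            denom = V1 * (alpha - beta)
            A = (alpha - k21) / denom
            B = (k21 - beta) / denom
            two_phase = True
        ps = cd.p_subj
        contrib = cd.p_rate * A[ps] * _phi(cd.p_dt, cd.p_dur, alpha[ps])
        if two_phase:
            contrib = contrib + cd.p_rate * B[ps] * _phi(cd.p_dt, cd.p_dur, beta[ps])
        return np.bincount(cd.p_obs, weights=contrib, minlength=cd.n_observations)


def _phi(dt: np.ndarray, dur: np.ndarray, lam: np.ndarray) -> np.ndarray:
    up = -np.expm1(-lam * np.minimum(dt, dur))
    decay = np.exp(-lam * np.maximum(dt - dur, 0.0))
    return up * decay / lam


# --------------------------------------------------------------------------
# Inner problem: conditional modes (empirical Bayes), vectorised over subjects


def _residual_variance(residual: ResidualModel, f: np.ndarray) -> np.ndarray:
    return np.maximum(residual.variance(f), _VAR_FLOOR)


def _seg_sum(values: np.ndarray, subj: np.ndarray, S: int) -> np.ndarray:
    return np.bincount(subj, weights=values, minlength=S)


def conditional_modes(
    predict: Callable[[np.ndarray], np.ndarray],
    y: np.ndarray,
    obs_subj: np.ndarray,
    n_subjects: int,
    omega2: np.ndarray,
    residual: ResidualModel,
    eta0: np.ndarray | None = None,
    gtol: float = _INNER_GTOL,
    max_iter: int = _INNER_MAXITER,
    fd_step: float = 1e-5,
    lloq: float | None = None,
):
    """Solve every subject's penalised inner problem simultaneously.

    Minimises, per subject, ``sum_j [(y - f(eta))^2 / var + log var] +
    eta' Omega^-1 eta`` by damped Gauss-Newton with exact (finite-difference)
    gradients.  With ``lloq`` set, each observation's density is conditioned
    on being quantifiable (``y >= lloq``), adding ``-2 log Phi((f - lloq) /
    sd)`` per observation.  Returns ``(eta, f, G, var, converged)`` where
    ``G`` holds ``df/deta`` at the solution.
    """
    S, q = n_subjects, len(omega2)
    eta = np.zeros((S, q)) if eta0 is None else np.array(eta0, dtype=float)
    inv_om = 1.0 / omega2

    def objective(eta_m: np.ndarray, f: np.ndarray | None = None) -> np.ndarray:
        if f is None:
            f = predict(eta_m)
        var = _residual_variance(residual, f)
        dev = (y - f) ** 2 / var + np.log(var)
        if lloq is not None:
            # quantifiability normaliser Phi(z) sits in the denominator of
            # the conditional density, hence the +2 log Phi term here
            dev = dev + 2.0 * log_ndtr((f - lloq) / np.sqrt(var))
        return _seg_sum(dev, obs_subj, S) + (eta_m**2 * inv_om).sum(axis=1)

    def gradient_pieces(eta_m: np.ndarray):
        f = predict(eta_m)
        G = np.empty((len(y), q))
        for c in range(q):
            step = np.zeros_like(eta_m)
            step[:, c] = fd_step
            G[:, c] = (predict(eta_m + step) - predict(eta_m - step)) / (2 * fd_step)
        var = _residual_variance(residual, f)
        r = y - f
        w = 1.0 / var
        grad = np.empty((S, q))
        # d/df of the per-observation deviance, including the log-var
        # (interaction) term for proportional/combined errors
        dvar_df = np.zeros_like(f)
        if residual.kind in ("proportional", "combined"):
            dvar_df = 2.0 * residual.cv**2 * f
        ddev_df = -2.0 * r * w + (1.0 - r**2 * w) * w * dvar_df
        if lloq is not None:
            sd = np.sqrt(var)
            z = (f - lloq) / sd
            hazard = np.exp(-0.5 * z * z - _LOG_SQRT_2PI - log_ndtr(z))
            ddev_df = ddev_df + 2.0 * hazard / sd
        for c in range(q):
            grad[:, c] = _seg_sum(ddev_df * G[:, c], obs_subj, S)
        grad += 2.0 * eta_m * inv_om
        return f, G, var, r, w, grad

    h = objective(eta)
    converged = np.zeros(S, dtype=bool)
    f = G = var = None
    for _ in range(max_iter):
        f, G, var, r, w, grad = gradient_pieces(eta)
        converged = np.max(np.abs(grad), axis=1) < gtol
        if converged.all():
            break
        # Gauss-Newton curvature: H/2 = G'WG + Omega^-1
        if q == 1:
            h11 = _seg_sum(G[:, 0] ** 2 * w, obs_subj, S) + inv_om[0]
            step = (-grad / 2.0) / h11[:, None]
        else:
            H = np.zeros((S, q, q))
            for a in range(q):
                for b in range(a, q):
                    hab = _seg_sum(G[:, a] * G[:, b] * w, obs_subj, S)
                    H[:, a, b] = hab
                    H[:, b, a] = hab
            H[:, np.arange(q), np.arange(q)] += inv_om
            step = np.linalg.solve(H, (-grad / 2.0)[..., None])[..., 0]
        scale = np.where(converged, 0.0, 1.0)
        improved = converged.copy()
        for _half in range(12):
            cand = eta + scale[:, None] * step
            h_new = objective(cand)
            better = h_new <= h + 1e-12
            accept = better & ~improved
            eta[accept] = cand[accept]
            h[accept] = h_new[accept]
            improved |= better
            if improved.all():
                break
            scale = np.where(improved, scale, scale / 2.0)
        if not improved.any():
            break
    if f is None or not converged.all():
        f = predict(eta)
        G = np.empty((len(y), q))
        for c in range(q):
            step = np.zeros_like(eta)
            step[:, c] = fd_step
            G[:, c] = (predict(eta + step) - predict(eta - step)) / (2 * fd_step)
        var = _residual_variance(residual, f)
    return eta, f, G, var, converged


def foce_ofv_terms(
    y: np.ndarray,
    f: np.ndarray,
    G: np.ndarray,
    var: np.ndarray,
    eta: np.ndarray,
    obs_subj: np.ndarray,
    n_subjects: int,
    omega2: np.ndarray,
) -> np.ndarray:
    """Per-subject -2 log-likelihood of the linearised (FOCE) marginal model.

    Uses the Woodbury identity on ``V = Sigma + G Omega G'`` so the whole
    cohort is handled with batched q x q linear algebra.  Exact for models
    linear in eta with additive error.
    """
    S, q = n_subjects, len(omega2)
    w = 1.0 / var
    if q == 1:
        r = y - f + G[:, 0] * eta[obs_subj, 0]
        gw = G[:, 0] * w
        a11 = _seg_sum(G[:, 0] * gw, obs_subj, S)
        b1 = _seg_sum(gw * r, obs_subj, S)
        n_i = np.bincount(obs_subj, minlength=S).astype(float)
        log_var_sum = _seg_sum(np.log(var), obs_subj, S)
        logdet_M = np.log1p(a11 * omega2[0])
        quad = _seg_sum(r * r * w, obs_subj, S) - b1**2 / (a11 + 1.0 / omega2[0])
        return n_i * math.log(2.0 * math.pi) + log_var_sum + logdet_M + quad
    r = y - f + np.einsum("nq,nq->n", G, eta[obs_subj])
    A = np.zeros((S, q, q))
    b = np.zeros((S, q))
    for a_ in range(q):
        b[:, a_] = _seg_sum(G[:, a_] * w * r, obs_subj, S)
        for b_ in range(a_, q):
            hab = _seg_sum(G[:, a_] * G[:, b_] * w, obs_subj, S)
            A[:, a_, b_] = hab
            A[:, b_, a_] = hab
    n_i = np.bincount(obs_subj, minlength=S).astype(float)
    log_var_sum = _seg_sum(np.log(var), obs_subj, S)
    M = np.broadcast_to(np.eye(q), (S, q, q)).copy()
    M += A * omega2[None, None, :]  # I + A Omega (Omega diagonal, right-mult)
    sign, logdet_M = np.linalg.slogdet(M)
    C = A.copy()
    C[:, np.arange(q), np.arange(q)] += 1.0 / omega2
    quad_corr = np.einsum("sq,sq->s", b, np.linalg.solve(C, b[..., None])[..., 0])
    quad = _seg_sum(r * r * w, obs_subj, S) - quad_corr
    return n_i * math.log(2.0 * math.pi) + log_var_sum + logdet_M + quad


def laplace_ofv_terms(
    y, f, G, var, eta, obs_subj, n_subjects, omega2
) -> np.ndarray:
    """Per-subject -2 log-likelihood, Laplacian form (Gauss-Newton curvature)."""
    S, q = n_subjects, len(omega2)
    w = 1.0 / var
    r = y - f
    A = np.zeros((S, q, q))
    for a_ in range(q):
        for b_ in range(a_, q):
            hab = _seg_sum(G[:, a_] * G[:, b_] * w, obs_subj, S)
            A[:, a_, b_] = hab
            A[:, b_, a_] = hab
    n_i = np.bincount(obs_subj, minlength=S).astype(float)
    dev = _seg_sum(r * r * w + np.log(var), obs_subj, S)
    C = A.copy()
    C[:, np.arange(q), np.arange(q)] += 1.0 / omega2
    sign, logdet_C = np.linalg.slogdet(C)
    prior = (eta**2 / omega2).sum(axis=1)
    return (
        n_i * math.log(2.0 * math.pi)
        + dev
        + prior
        + float(np.log(omega2).sum())
        + logdet_C
    )


# --------------------------------------------------------------------------
# Objective function and fitting


class _Objective:
    """OFV as a function of the transformed parameter vector, with eta warm
    starts carried between evaluations."""

    def __init__(
        self,
        model: PopulationModel,
        cd: CompiledDataset,
        space: ParameterSpace,
        method: str = "foce",
        lloq: float | None = LLOQ,
    ):
        self.model = model
        self.cd = cd
        self.space = space
        self.method = method
        self.lloq = lloq
        self.predictor = _Predictor(model, cd)
        self.iiv_params = tuple(model.iiv)
        self.eta_warm = np.zeros((cd.n_subjects, len(self.iiv_params)))
        self.base_values = {
            name: model.param_value(name)
            for name in ParameterSpace.from_model(model).names
        }

    def values_from_x(self, x: np.ndarray) -> dict[str, float]:
        values = dict(self.base_values)
        values.update(self.space.unpack(x))
        return values

    def residual_from_values(self, values) -> ResidualModel:
        return ResidualModel(
            kind=self.model.residual.kind,
            sd0=values.get("sd0", self.model.residual.sd0),
            cv=values.get("cv", self.model.residual.cv),
        )

    def evaluate(self, x: np.ndarray, details: bool = False):
        cd = self.cd
        values = self.values_from_x(x)
        residual = self.residual_from_values(values)
        omega2 = np.array(
            [max(values[f"om{p}"], 1e-6) ** 2 for p in self.iiv_params]
        )
        predict = lambda eta: self.predictor.predict(values, eta)
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            eta, f, G, var, conv = conditional_modes(
                predict, cd.y, cd.obs_subj, cd.n_subjects, omega2, residual,
                eta0=self.eta_warm, lloq=self.lloq,
            )
            terms_fn = laplace_ofv_terms if self.method == "laplace" else foce_ofv_terms
            terms = terms_fn(
                cd.y, f, G, var, eta, cd.obs_subj, cd.n_subjects, omega2
            )
            if self.lloq is not None:
                corr = 2.0 * log_ndtr((f - self.lloq) / np.sqrt(var))
                terms = terms + _seg_sum(corr, cd.obs_subj, cd.n_subjects)
            total = float(np.sum(terms))
        if not np.isfinite(total):
            total = 1e12 + float(np.nansum(x**2))
            if details:
                raise FloatingPointError("non-finite OFV at requested parameters")
            return total
        self.eta_warm = eta
        if not details:
            return total
        pred_pop = self.predictor.predict(values, np.zeros_like(eta))
        return total, {
            "values": values,
            "eta": eta,
            "f": f,
            "G": G,
            "var": var,
            "omega2": omega2,
            "inner_converged": conv,
            "PRED": pred_pop,
            "terms": terms,
        }


@dataclass
class FitResult:
    """Estimates, uncertainties and diagnostics of one NLME fit."""

    model: PopulationModel
    estimates: dict[str, float]
    se: dict[str, float]
    ofv: float
    eta: pd.DataFrame
    shrinkage: dict[str, float]
    predictions: pd.DataFrame
    converged: bool
    n_iter: int
    n_subjects: int
    n_observations: int
    message: str = ""
    trace: list = field(default_factory=list)
    se_ok: bool = True

    def to_table(self) -> pd.DataFrame:
        """Estimates with SEs and Wald 95% CIs (estimate +/- 1.96 SE)."""
        rows = []
        for name, est in self.estimates.items():
            s = self.se.get(name, float("nan"))
            rows.append({
                "parameter": name,
                "estimate": est,
                "se": s,
                "ci95_lo": est - 1.96 * s,
                "ci95_hi": est + 1.96 * s,
            })
        return pd.DataFrame(rows)


def ofv(
    model: PopulationModel,
    data: EventTable | CompiledDataset,
    params: Mapping[str, float] | None = None,
    method: Literal["foce", "laplace"] = "foce",
    condition_on_quantifiable: bool = True,
) -> float:
    """-2 x approximate marginal log-likelihood at the given parameter values.

    ``params`` (flat names, e.g. ``{"tvCL": 0.5}``) override the model's own
    values.  By default every observation's density is conditioned on being
    quantifiable (>= the 1 ug/mL LLOQ), matching how event tables are
    assembled; pass ``condition_on_quantifiable=False`` for the plain
    Gaussian likelihood.  Deterministic given data and parameters.
    """
    if params:
        model = model.with_values(**params)
    cd = data if isinstance(data, CompiledDataset) else compile_dataset(data)
    space = ParameterSpace.from_model(model)
    obj = _Objective(model, cd, space, method=method,
                     lloq=LLOQ if condition_on_quantifiable else None)
    return obj.evaluate(space.pack(model))


def fit(
    model: PopulationModel,
    data: EventTable | CompiledDataset,
    inits: Mapping[str, float] | None = None,
    method: Literal["foce", "laplace"] = "foce",
    fixed: Sequence[str] = (),
    compute_se: bool = True,
    maxiter: int = 500,
    se_step: float = 1e-4,
    condition_on_quantifiable: bool = True,
) -> FitResult:
    """Estimate a population model from an event table by FOCE.

    The model skeleton supplies the structure and the default initial values;
    ``inits`` overrides them.  SEs come from the inverse central-difference
    Hessian of OFV/2 on the transformed scale (delta method back to the
    natural scale); if the Hessian cannot be inverted the fit is returned
    with missing SEs and ``se_ok=False``.
    """
    cd = data if isinstance(data, CompiledDataset) else compile_dataset(data)
    if inits:
        model = model.with_values(**inits)
    space = ParameterSpace.from_model(model, fixed=fixed)
    if cd.n_observations < space.n_fixed_effects:
        raise IdentifiabilityError(
            f"{cd.n_observations} observations cannot identify "
            f"{space.n_fixed_effects} fixed effects"
        )
    obj = _Objective(model, cd, space, method=method,
                     lloq=LLOQ if condition_on_quantifiable else None)
    x0 = space.pack(model)
    trace: list[tuple[int, float]] = []

    def func(x):
        value = obj.evaluate(x)
        trace.append((len(trace), value))
        return value

    res = optimize.minimize(
        func, x0, method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-9, "gtol": 1e-4, "eps": 1e-6},
    )
    final_ofv, det = obj.evaluate(res.x, details=True)
    estimates = space.unpack(res.x)
    fitted = model.with_values(**estimates)

    se: dict[str, float] = {name: float("nan") for name in space.names}
    se_ok = False
    if compute_se:
        se_t, se_ok = _hessian_se(obj, res.x, se_step)
        if se_ok:
            se = space.natural_se(res.x, se_t)

    iiv_params = tuple(model.iiv)
    eta_df = pd.DataFrame(
        det["eta"], index=pd.Index(cd.subject_ids, name="subject_id"),
        columns=list(iiv_params),
    )
    shr = {
        p: shrinkage(det["eta"][:, j], estimates.get(f"om{p}", model.iiv[p]))
        for j, p in enumerate(iiv_params)
    }
    predictions = _prediction_table(cd, det, iiv_params)
    return FitResult(
        model=fitted,
        estimates=estimates,
        se=se,
        ofv=final_ofv,
        eta=eta_df,
        shrinkage=shr,
        predictions=predictions,
        converged=bool(res.success) and bool(det["inner_converged"].all()),
        n_iter=int(res.nit),
        n_subjects=cd.n_subjects,
        n_observations=cd.n_observations,
        message=str(res.message),
        trace=trace,
        se_ok=se_ok,
    )


def _hessian_se(obj: _Objective, x: np.ndarray, step: float):
    n = len(x)
    H = np.empty((n, n))
    f0 = obj.evaluate(x) / 2.0

    def g(xx):
        return obj.evaluate(xx) / 2.0

    for i in range(n):
        for j in range(i, n):
            if i == j:
                xp = x.copy(); xp[i] += step
                xm = x.copy(); xm[i] -= step
                H[i, i] = (g(xp) - 2 * f0 + g(xm)) / step**2
            else:
                xpp = x.copy(); xpp[i] += step; xpp[j] += step
                xpm = x.copy(); xpm[i] += step; xpm[j] -= step
                xmp = x.copy(); xmp[i] -= step; xmp[j] += step
                xmm = x.copy(); xmm[i] -= step; xmm[j] -= step
                H[i, j] = H[j, i] = (
                    g(xpp) - g(xpm) - g(xmp) + g(xmm)
                ) / (4 * step**2)
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        if np.any(diag <= 0) or not np.all(np.isfinite(diag)):
            return np.full(n, np.nan), False
        return np.sqrt(diag), True
    except np.linalg.LinAlgError:
        return np.full(n, np.nan), False


def _prediction_table(
    cd: CompiledDataset, det: dict, iiv_params: tuple[str, ...]
) -> pd.DataFrame:
    y, f, G, var = cd.y, det["f"], det["G"], det["var"]
    eta, omega2 = det["eta"], det["omega2"]
    cw = _cwres_values(y, f, G, var, eta, cd.obs_subj, cd.n_subjects, omega2)
    return pd.DataFrame({
        "subject_id": [cd.subject_ids[i] for i in cd.obs_subj],
        "time": cd.obs_time,
        "DV": y,
        "PRED": det["PRED"],
        "IPRED": f,
        "CWRES": cw,
    })


def _cwres_values(y, f, G, var, eta, obs_subj, S, omega2) -> np.ndarray:
    """Conditional weighted residuals: the linearised residual whitened by the
    Cholesky factor of ``V_i = G Omega G' + Sigma``; ~N(0, I) under the model."""
    r = y - f + np.einsum("nq,nq->n", G, eta[obs_subj])
    out = np.empty_like(r)
    omega = np.diag(omega2)
    for s in range(S):
        idx = np.where(obs_subj == s)[0]
        if len(idx) == 0:
            continue
        Gs = G[idx]
        V = Gs @ omega @ Gs.T + np.diag(var[idx])
        L = np.linalg.cholesky(V)
        out[idx] = np.linalg.solve(L, r[idx])
    return out


def cwres(fit_result: FitResult, data: EventTable | None = None) -> np.ndarray:
    """Conditional weighted residuals of a fit (one value per observation)."""
    return fit_result.predictions["CWRES"].to_numpy().copy()


def ebe(
    model: PopulationModel,
    subject: SubjectData,
    params: Mapping[str, float] | None = None,
    condition_on_quantifiable: bool = True,
) -> dict[str, float]:
    """Empirical Bayes (MAP) estimate of a subject's random effects.

    With no usable observations the prior mode (all zeros) is returned.
    """
    if params:
        model = model.with_values(**params)
    iiv_params = tuple(model.iiv)
    usable = [o for o in subject.observations if not o.below_lloq]
    if not usable:
        return {p: 0.0 for p in iiv_params}
    table = EventTable.from_subjects([subject])
    cd = compile_dataset(table)
    space = ParameterSpace.from_model(model)
    obj = _Objective(model, cd, space, method="foce",
                     lloq=LLOQ if condition_on_quantifiable else None)
    _, det = obj.evaluate(space.pack(model), details=True)
    return {p: float(det["eta"][0, j]) for j, p in enumerate(iiv_params)}


def ebes(model: PopulationModel, data: EventTable | CompiledDataset) -> pd.DataFrame:
    """Empirical Bayes etas of every subject at the model's current values."""
    cd = data if isinstance(data, CompiledDataset) else compile_dataset(data)
    space = ParameterSpace.from_model(model)
    obj = _Objective(model, cd, space)
    _, det = obj.evaluate(space.pack(model), details=True)
    return pd.DataFrame(
        det["eta"], index=pd.Index(cd.subject_ids, name="subject_id"),
        columns=list(model.iiv),
    )


def shrinkage(eta_hats: np.ndarray, omega: float) -> float:
    """Eta-shrinkage ``1 - SD(eta_hat) / omega`` (sample SD over subjects)."""
    eta_hats = np.asarray(eta_hats, dtype=float)
    if omega <= 0:
        return float("nan")
    sd = float(np.std(eta_hats, ddof=1)) if len(eta_hats) > 1 else 0.0
    return 1.0 - sd / omega
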