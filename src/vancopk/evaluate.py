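"""Model evaluation: bootstrap, visual predictive check, external-validation
metrics and individual trough prediction.

Internal evaluation resamples subjects (the exchangeable unit of a
hierarchical dataset) with replacement and refits each replicate, and runs a
Monte Carlo visual predictive check over the study's own design.  External
evaluation reports mean (MPE), mean absolute (MAE) and mean squared (MSPE)
prediction errors in ug/mL and (ug/mL)^2.  Trough prediction evaluates the
model just before a scheduled dose, either as a population prediction
(eta = 0) or conditioned on prior concentrations through the empirical Bayes
estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import EventTable, SubjectData
from .engine import FitResult, ebe, fit
from .model import (
    Covariates,
    DoseEvent,
    Observation,
    PopulationModel,
    apply_residual,
    concentration,
)

__all__ = [
    "BootstrapResult",
    "VPCResult",
    "ValidationMetrics",
    "bootstrap",
    "wald_ci",
    "vpc",
    "external_metrics",
    "case_prediction_error",
    "predict_trough",
    "diagnostics_table",
]


def wald_ci(estimate: float, se: float) -> tuple[float, float]:
    """95% Wald confidence interval, ``estimate +/- 1.96 * SE``."""
    if se < 0:
        raise ValueError("SE must be >= 0")
    return estimate - 1.96 * se, estimate + 1.96 * se


@dataclass
class BootstrapResult:
    """Summary of a nonparametric (subject-resampling) bootstrap."""

    table: pd.DataFrame          # per parameter: median, se, percentile and Wald CIs
    replicates: pd.DataFrame     # converged replicate estimates, one row each
    n_attempted: int
    n_converged: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_converged > self.n_attempted:
            raise ValueError("converged count exceeds attempted count")


def bootstrap(
    model: PopulationModel,
    data: EventTable,
    n_reps: int = 2000,
    seed: int = 0,
    original_fit: FitResult | None = None,
) -> BootstrapResult:
    """Refit the model to ``n_reps`` subject-resampled datasets.

    Each replicate draws subjects with replacement (same cohort size),
    refits starting from the original estimates, and contributes one row of
    estimates; non-converged replicates are excluded and counted.  Reported
    per parameter: the replicate median, SE (SD across replicates), the
    2.5-97.5 percentile interval and the Wald interval ``median +/- 1.96 SE``.
    Deterministic given the seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    if original_fit is None:
        original_fit = fit(model, data, compute_se=False)
    ids = data.subject_ids
    rows = []
    n_conv = 0
    for _ in range(n_reps):
        sample = [ids[i] for i in rng.integers(0, len(ids), size=len(ids))]
        rep_data = data.subset(sample)
        try:
            rep = fit(original_fit.model, rep_data, compute_se=False)
        except (ValueError, np.linalg.LinAlgError):
            continue
        if not rep.converged:
            continue
        n_conv += 1
        rows.append(rep.estimates)
    replicates = pd.DataFrame(rows)
    summary = []
    for name in replicates.columns:
        v = replicates[name].to_numpy()
        med = float(np.median(v))
        se = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
        lo_p, hi_p = (np.percentile(v, [2.5, 97.5]) if len(v) else (np.nan,) * 2)
        lo_w, hi_w = wald_ci(med, se)
        summary.append({
            "parameter": name, "median": med, "se": se,
            "ci95_lo": lo_w, "ci95_hi": hi_w,
            "pctl95_lo": float(lo_p), "pctl95_hi": float(hi_p),
            "original": original_fit.estimates.get(name, np.nan),
        })
    return BootstrapResult(
        table=pd.DataFrame(summary),
        replicates=replicates,
        n_attempted=n_reps,
        n_converged=n_conv,
        seed=seed,
    )


@dataclass
class VPCResult:
    """Visual-predictive-check bands and observed coverage."""

    bins: pd.DataFrame        # per bin: edges, p5, p50, p95 of simulations
    observed: pd.DataFrame    # per observation: binned time, DV, inside flag
    fraction_inside: float
    n_sim_cohorts: int
    seed: int

    def __post_init__(self) -> None:
        b = self.bins
        if not ((b["p5"] <= b["p50"] + 1e-12).all() and (b["p50"] <= b["p95"] + 1e-12).all()):
            raise ValueError("percentile bands out of order")
        if not 0.0 <= self.fraction_inside <= 1.0:
            raise ValueError("fraction_inside must be in [0, 1]")


def _time_after_dose(subject: SubjectData, times: np.ndarray) -> np.ndarray:
    starts = np.array([d.start_time for d in subject.doses])
    out = np.empty(len(times))
    for i, t in enumerate(times):
        prior = starts[starts <= t]
        out[i] = t - prior.max() if prior.size else t
    return out


def vpc(
    model: PopulationModel,
    data: EventTable,
    n_sim_cohorts: int = 1000,
    seed: int = 0,
    n_bins: int = 8,
) -> VPCResult:
    """Monte Carlo visual predictive check over the study's own design.

    The observed design (each subject's doses, covariates and sampling
    times) is re-simulated ``n_sim_cohorts`` times with fresh random effects
    and residual errors; the 5th/50th/95th percentiles of the simulated
    concentrations are summarised per quantile bin of time-after-most-recent-
    dose, and each observation is scored against its bin's 5-95% band.
    """
    rng = np.random.default_rng(seed)
    subjects = list(data.iter_subjects())
    obs_rows = []
    sims = []
    tad_all = []
    dv_all = []
    for subj in subjects:
        kept = [o for o in subj.observations if not o.below_lloq]
        if not kept:
            continue
        times = np.array([o.time for o in kept])
        tad_all.append(_time_after_dose(subj, times))
        dv_all.append(np.array([o.conc for o in kept]))
        obs_rows.append((subj, times))
    tad = np.concatenate(tad_all)
    dv = np.concatenate(dv_all)
    n_obs = len(dv)
    iiv = tuple(model.iiv)
    sim_matrix = np.empty((n_sim_cohorts, n_obs))
    for s in range(n_sim_cohorts):
        col = 0
        for subj, times in obs_rows:
            etas = {p: float(rng.normal(0.0, model.iiv[p])) for p in iiv}
            sp = model.structural_params(subj.covariates, etas)
            c = np.atleast_1d(concentration(times, list(subj.doses), sp))
            eps = rng.standard_normal(len(times))
            eps2 = rng.standard_normal(len(times))
            c = np.maximum(apply_residual(c, model.residual, eps, eps2), 0.0)
            sim_matrix[s, col:col + len(times)] = c
            col += len(times)
    # quantile bins on time after most recent dose
    edges = np.unique(np.quantile(tad, np.linspace(0, 1, n_bins + 1)))
    bin_idx = np.clip(np.searchsorted(edges, tad, side="right") - 1, 0, len(edges) - 2)
    rows = []
    inside = np.zeros(n_obs, dtype=bool)
    for b in range(len(edges) - 1):
        mask = bin_idx == b
        if not mask.any():
            continue
        pooled = sim_matrix[:, mask].ravel()
        p5, p50, p95 = np.percentile(pooled, [5, 50, 95])
        inside[mask] = (dv[mask] >= p5) & (dv[mask] <= p95)
        rows.append({
            "bin": b, "tad_lo": edges[b], "tad_hi": edges[b + 1],
            "n_obs": int(mask.sum()), "p5": p5, "p50": p50, "p95": p95,
        })
    observed = pd.DataFrame({
        "tad": tad, "DV": dv, "bin": bin_idx, "inside": inside,
    })
    return VPCResult(
        bins=pd.DataFrame(rows),
        observed=observed,
        fraction_inside=float(inside.mean()),
        n_sim_cohorts=n_sim_cohorts,
        seed=seed,
    )


@dataclass(frozen=True)
class ValidationMetrics:
    """External-validation prediction-error summary.

    MPE and MAE in ug/mL, MSPE in (ug/mL)^2; SDs are across prediction
    pairs.  On any input ``MAE >= |MPE|`` and ``MSPE >= MPE^2``.
    """

    mpe: float
    mae: float
    mspe: float
    sd_pe: float
    sd_ape: float
    sd_spe: float
    n: int


def external_metrics(pred: Sequence[float], obs: Sequence[float]) -> ValidationMetrics:
    """MPE, MAE and MSPE of predicted vs observed concentrations.

    ``MPE = mean(pred - obs)``, ``MAE = mean(|pred - obs|)``,
    ``MSPE = mean((obs - pred)^2)``.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1 or len(pred) == 0:
        raise ValueError("pred and obs must be equal-length, non-empty 1-D")
    pe = pred - obs
    ape = np.abs(pe)
    spe = pe**2
    sd = lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
    return ValidationMetrics(
        mpe=float(pe.mean()), mae=float(ape.mean()), mspe=float(spe.mean()),
        sd_pe=sd(pe), sd_ape=sd(ape), sd_spe=sd(spe), n=len(pe),
    )


def case_prediction_error(pred: float, obs: float) -> float:
    """Per-case prediction error, percent of the observed value."""
    if obs <= 0:
        raise ValueError("observed concentration must be > 0")
    return 100.0 * abs(pred - obs) / obs


def predict_trough(
    model: PopulationModel,
    cov: Covariates,
    regimen: Sequence[DoseEvent],
    at_dose_index: int,
    prior_obs: Sequence[Observation] | None = None,
) -> float:
    """Predicted concentration immediately before the ``at_dose_index``-th dose.

    ``at_dose_index`` is 1-based; it must be >= 2 so at least one dose has
    been given.  Without ``prior_obs`` this is the population prediction
    (eta = 0); with prior concentrations the subject's empirical Bayes etas
    are estimated first (MAP prediction).
    """
    regimen = sorted(regimen, key=lambda d: d.start_time)
    if at_dose_index < 2:
        raise ValueError("at_dose_index must be >= 2")
    if at_dose_index > len(regimen):
        raise ValueError(
            f"at_dose_index {at_dose_index} exceeds the {len(regimen)}-dose regimen"
        )
    t = regimen[at_dose_index - 1].start_time
    prior_doses = [d for d in regimen if d.start_time < t]
    etas: Mapping[str, float] = {}
    if prior_obs:
        subject = SubjectData("case", tuple(prior_doses), tuple(prior_obs), cov)
        etas = ebe(model, subject)
    sp = model.structural_params(cov, dict(etas))
    return float(concentration(t, prior_doses, sp))


def diagnostics_table(fit_result: FitResult, data: EventTable | None = None) -> pd.DataFrame:
    """Per-observation table (subject, time, DV, PRED, IPRED, CWRES).

    Enough to render the usual goodness-of-fit panels; one row per non-BQL
    observation.
    """
    return fit_result.predictions.copy()
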