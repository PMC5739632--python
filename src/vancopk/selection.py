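"""Stepwise covariate model building on OFV (likelihood-ratio) thresholds.

Forward inclusion adds, one at a time, the candidate covariate-parameter
relation with the largest OFV drop, as long as that drop exceeds 6.635
(chi-square, 1 df, p < 0.01).  Backward elimination then removes, one at a
time, the effect whose single removal raises the OFV least, unless every
remaining effect's removal raises the OFV by more than 10.828 (p < 0.001).
Candidate fits that fail to converge are skipped with a warning.  Continuous
candidates are centred at the dataset median of their covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .dataset import EventTable
from .engine import CompiledDataset, FitResult, compile_dataset, fit
from .model import CovariateEffect, PopulationModel

__all__ = [
    "FORWARD_DOFV",
    "BACKWARD_DOFV",
    "Candidate",
    "StepRecord",
    "StepwiseTrace",
    "forward_step",
    "backward_step",
    "stepwise",
]

#: OFV drop required to accept a covariate at forward inclusion
#: (chi-square 1 df, p < 0.01).
FORWARD_DOFV = 6.635
#: OFV rise required to retain a covariate at backward elimination
#: (chi-square 1 df, p < 0.001).
BACKWARD_DOFV = 10.828


@dataclass(frozen=True)
class Candidate:
    """A candidate covariate-parameter relation (exponent to be estimated)."""

    covariate: str
    parameter: str = "CL"
    kind: Literal["continuous", "categorical"] = "continuous"

    def key(self) -> tuple[str, str]:
        return (self.parameter, self.covariate)


@dataclass(frozen=True)
class StepRecord:
    """One row of the stepwise ledger."""

    step: int
    action: Literal["add", "remove", "stop"]
    parameter: str
    covariate: str
    ofv: float
    delta_ofv: float
    decision: str


@dataclass
class StepwiseTrace:
    """Ordered stepwise ledger plus the final model and fit."""

    records: list[StepRecord] = field(default_factory=list)
    final_model: PopulationModel | None = None
    final_fit: FitResult | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @property
    def selected(self) -> set[tuple[str, str]]:
        return {
            (e.parameter, e.covariate) for e in (self.final_model.effects if self.final_model else ())
        }


def _median_reference(cd: CompiledDataset, covariate: str) -> float:
    values = [c.get(covariate, continuous=True) for c in cd.covariates]
    return float(np.median(values))


def _candidate_effect(cand: Candidate, cd: CompiledDataset) -> CovariateEffect:
    if cand.kind == "continuous":
        return CovariateEffect(
            cand.parameter, cand.covariate, 0.0,
            reference=_median_reference(cd, cand.covariate),
        )
    return CovariateEffect(cand.parameter, cand.covariate, 0.0, kind="categorical")


def _with_effect(model: PopulationModel, eff: CovariateEffect) -> PopulationModel:
    return replace(model, effects=model.effects + (eff,))


def _without_effect(model: PopulationModel, eff: CovariateEffect) -> PopulationModel:
    return replace(model, effects=tuple(e for e in model.effects if e is not eff))


def _fit_quiet(model, cd, **kw):
    return fit(model, cd, compute_se=False, **kw)


def forward_step(
    model: PopulationModel,
    data: EventTable | CompiledDataset,
    candidates: Sequence[Candidate],
    current_fit: FitResult | None = None,
    threshold: float = FORWARD_DOFV,
    step_index: int = 0,
):
    """Try each remaining candidate singly; accept the largest OFV drop.

    Returns ``(accepted_candidate_or_None, new_fit_or_None, records)``.
    Candidate fits warm-start at the current optimum with a zero exponent, so
    a candidate can never appear to worsen the OFV (nested-model dominance).
    """
    cd = data if isinstance(data, CompiledDataset) else compile_dataset(data)
    if current_fit is None:
        current_fit = _fit_quiet(model, cd)
    base_ofv = current_fit.ofv
    in_model = {(e.parameter, e.covariate) for e in model.effects}
    records: list[StepRecord] = []
    best: tuple[Candidate, FitResult] | None = None
    for cand in sorted(candidates, key=lambda c: (c.parameter, c.covariate)):
        if cand.key() in in_model:
            raise ValueError(f"candidate {cand} already in the model")
        eff = _candidate_effect(cand, cd)
        trial_model = _with_effect(current_fit.model, eff)
        try:
            trial = _fit_quiet(trial_model, cd)
        except (FloatingPointError, np.linalg.LinAlgError, ValueError) as exc:
            warnings.warn(f"candidate {cand.covariate} on {cand.parameter} "
                          f"failed to fit: {exc}")
            continue
        if not trial.converged:
            warnings.warn(
                f"candidate {cand.covariate} on {cand.parameter} did not "
                "converge; skipped"
            )
            continue
        d = trial.ofv - base_ofv
        records.append(StepRecord(
            step_index, "add", cand.parameter, cand.covariate, trial.ofv, d,
            "candidate",
        ))
        if d < -threshold and (best is None or trial.ofv < best[1].ofv):
            best = (cand, trial)
    if best is None:
        return None, None, records
    cand, bfit = best
    records = [
        r if (r.parameter, r.covariate) != cand.key()
        else replace(r, decision="added")
        for r in records
    ]
    return cand, bfit, records


def backward_step(
    model: PopulationModel,
    data: EventTable | CompiledDataset,
    current_fit: FitResult | None = None,
    threshold: float = BACKWARD_DOFV,
    step_index: int = 0,
    removable: Sequence[tuple[str, str]] | None = None,
):
    """Remove each effect singly; drop the one the OFV misses least.

    An effect is retained only if its removal raises the OFV by more than the
    threshold.  Returns ``(removed_effect_or_None, new_fit_or_None, records)``.
    """
    cd = data if isinstance(data, CompiledDataset) else compile_dataset(data)
    if current_fit is None:
        current_fit = _fit_quiet(model, cd)
    model = current_fit.model
    base_ofv = current_fit.ofv
    records: list[StepRecord] = []
    best: tuple[CovariateEffect, FitResult] | None = None
    effects = model.effects
    if removable is not None:
        allowed = set(removable)
        effects = tuple(e for e in effects if (e.parameter, e.covariate) in allowed)
    for eff in sorted(effects, key=lambda e: (e.parameter, e.covariate)):
        trial_model = _without_effect(model, eff)
        try:
            trial = _fit_quiet(trial_model, cd)
        except (FloatingPointError, np.linalg.LinAlgError, ValueError) as exc:
            warnings.warn(f"removal of {eff.covariate} from {eff.parameter} "
                          f"failed to fit: {exc}")
            continue
        d = trial.ofv - base_ofv
        records.append(StepRecord(
            step_index, "remove", eff.parameter, eff.covariate, trial.ofv, d,
            "retained" if d > threshold else "candidate",
        ))
        if d <= threshold and (best is None or trial.ofv < best[1].ofv):
            best = (eff, trial)
    if best is None:
        return None, None, records
    eff, bfit = best
    records = [
        r if (r.parameter, r.covariate) != (eff.parameter, eff.covariate)
        else replace(r, decision="removed")
        for r in records
    ]
    return eff, bfit, records


def stepwise(
    base_model: PopulationModel,
    data: EventTable | CompiledDataset,
    candidates: Sequence[Candidate],
    forward_threshold: float = FORWARD_DOFV,
    backward_threshold: float = BACKWARD_DOFV,
) -> StepwiseTrace:
    """Forward inclusion to exhaustion, then backward elimination to stability.

    Only effects added during the forward phase are eligible for removal;
    effects present in the base model are kept.  Deterministic given the data
    (ties break lexicographically on covariate name via the candidate scan
    order).
    """
    cd = data if isinstance(data, CompiledDataset) else compile_dataset(data)
    trace = StepwiseTrace()
    current = _fit_quiet(base_model, cd)
    trace.records.append(StepRecord(
        0, "stop", "", "", current.ofv, 0.0, "base model"
    ))
    remaining = list(candidates)
    step = 0
    while remaining:
        step += 1
        cand, new_fit, records = forward_step(
            current.model, cd, remaining, current_fit=current,
            threshold=forward_threshold, step_index=step,
        )
        trace.records.extend(records)
        if cand is None:
            break
        remaining = [c for c in remaining if c.key() != cand.key()]
        current = new_fit
    added = {c.key() for c in candidates} & {
        (e.parameter, e.covariate) for e in current.model.effects
    }
    while added:
        step += 1
        eff, new_fit, records = backward_step(
            current.model, cd, current_fit=current,
            threshold=backward_threshold, step_index=step,
            removable=sorted(added),
        )
        trace.records.extend(records)
        if eff is None:
            break
        added.discard((eff.parameter, eff.covariate))
        current = new_fit
    trace.final_model = current.model
    trace.final_fit = current
    return trace
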