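"""Event-record tables: the CSV dialect, validation and subject iteration.

The on-disk format is a NONMEM-style long table, one row per event, UTF-8,
comma-separated, ``.`` decimal.  Columns:

``subject_id, time, event, amount, infusion_duration, conc, below_lloq``
followed by the covariate columns of :class:`vancopk.model.Covariates`.
``event`` is ``dose`` or ``obs``; dose rows carry ``amount`` (mg) and
``infusion_duration`` (h), observation rows carry ``conc`` (ug/mL) and the
``below_lloq`` flag.  Times are hours since the subject's first dose.
Covariates are per-subject scalars repeated on every row.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .model import Covariates, DoseEvent, Observation

__all__ = [
    "EventTable",
    "EventTableError",
    "SubjectData",
    "read_events",
    "write_events",
]

_EVENT_COLUMNS = [
    "subject_id", "time", "event", "amount", "infusion_duration",
    "conc", "below_lloq",
]
_COVARIATE_COLUMNS = list(Covariates.__dataclass_fields__)


class EventTableError(ValueError):
    """Validation failure; the message carries offending row numbers."""


@dataclass(frozen=True)
class SubjectData:
    """One subject's dosing history, observations and covariates."""

    subject_id: str
    doses: tuple[DoseEvent, ...]
    observations: tuple[Observation, ...]
    covariates: Covariates

    @property
    def times(self) -> np.ndarray:
        return np.array([o.time for o in self.observations])

    @property
    def concs(self) -> np.ndarray:
        return np.array([o.conc for o in self.observations])


class EventTable:
    """A validated event-record dataset wrapping a pandas DataFrame."""

    def __init__(self, frame: pd.DataFrame, validate: bool = True, strict: bool = True):
        frame = frame.copy()
        missing = [c for c in _EVENT_COLUMNS if c not in frame.columns]
        if missing:
            raise EventTableError(f"missing required columns: {missing}")
        for c in _COVARIATE_COLUMNS:
            if c not in frame.columns:
                frame[c] = np.nan
        frame = frame[_EVENT_COLUMNS + _COVARIATE_COLUMNS]
        frame["subject_id"] = frame["subject_id"].astype(str)
        frame["below_lloq"] = frame["below_lloq"].fillna(False).astype(bool)
        numeric = ["time", "amount", "infusion_duration", "conc"] + _COVARIATE_COLUMNS
        frame[numeric] = frame[numeric].astype(float)
        self.frame = frame.reset_index(drop=True)
        if validate:
            self.validate(strict=strict)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        return isinstance(other, EventTable) and self.frame.equals(other.frame)

    @property
    def subject_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["subject_id"]))

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_observations(self) -> int:
        return int((self.frame["event"] == "obs").sum())

    def validate(self, strict: bool = True) -> None:
        """Check structural invariants; raise :class:`EventTableError` on failure.

        In lenient mode (``strict=False``) ordering problems and
        missing-dose-before-observation problems are downgraded to warnings;
        impossible values (negative times or amounts, unknown event types)
        always raise.
        """
        df = self.frame
        errors: list[str] = []
        soft: list[str] = []
        bad_event = ~df["event"].isin(["dose", "obs"])
        for i in df.index[bad_event]:
            errors.append(f"row {i}: unknown event type {df.at[i, 'event']!r}")
        if (df["time"] < 0).any():
            for i in df.index[df["time"] < 0]:
                errors.append(f"row {i}: negative time {df.at[i, 'time']}")
        dose = df["event"] == "dose"
        obs = df["event"] == "obs"
        for i in df.index[dose]:
            amt = df.at[i, "amount"]
            dur = df.at[i, "infusion_duration"]
            if not np.isfinite(amt) or amt <= 0:
                errors.append(f"row {i}: dose amount must be > 0, got {amt}")
            if not np.isfinite(dur) or dur <= 0:
                errors.append(f"row {i}: infusion_duration must be > 0, got {dur}")
            if np.isfinite(df.at[i, "conc"]):
                errors.append(f"row {i}: dose row carries a concentration")
        for i in df.index[obs]:
            conc = df.at[i, "conc"]
            if not np.isfinite(conc) or conc < 0:
                errors.append(f"row {i}: observation conc must be >= 0, got {conc}")
            if np.isfinite(df.at[i, "amount"]):
                errors.append(f"row {i}: observation row carries a dose amount")
        for sid, g in df.groupby("subject_id", sort=False):
            t = g["time"].to_numpy()
            if np.any(np.diff(t) < 0):
                soft.append(f"subject {sid}: times are not non-decreasing")
            g_dose = g[g["event"] == "dose"]
            g_obs = g[g["event"] == "obs"]
            if len(g_obs) and not len(g_dose):
                soft.append(f"subject {sid}: observations but no dose records")
            elif len(g_obs):
                first_dose = g_dose["time"].min()
                early = g_obs[g_obs["time"] < first_dose]
                for i in early.index:
                    soft.append(
                        f"subject {sid} row {i}: observation at t="
                        f"{df.at[i, 'time']} precedes the first dose (t={first_dose})"
                    )
        if strict:
            errors += soft
            soft = []
        for msg in soft:
            warnings.warn(msg, stacklevel=2)
        if errors:
            raise EventTableError("; ".join(errors))

    # -- construction -----------------------------------------------------

    @classmethod
    def from_subjects(cls, subjects: Sequence[SubjectData]) -> "EventTable":
        rows = []
        for s in subjects:
            cov = s.covariates.as_dict()
            for d in s.doses:
                rows.append({
                    "subject_id": s.subject_id, "time": d.start_time,
                    "event": "dose", "amount": d.amount,
                    "infusion_duration": d.infusion_duration,
                    "conc": np.nan, "below_lloq": False, **cov,
                })
            for o in s.observations:
                rows.append({
                    "subject_id": s.subject_id, "time": o.time, "event": "obs",
                    "amount": np.nan, "infusion_duration": np.nan,
                    "conc": o.conc, "below_lloq": o.below_lloq, **cov,
                })
        frame = pd.DataFrame(rows)
        frame = frame.sort_values(
            ["subject_id", "time", "event"], kind="stable"
        ).reset_index(drop=True)
        # keep original subject order, not lexicographic
        order = {s.subject_id: i for i, s in enumerate(subjects)}
        frame["_ord"] = frame["subject_id"].map(order)
        frame = frame.sort_values(["_ord", "time"], kind="stable").drop(columns="_ord")
        return cls(frame.reset_index(drop=True))

    # -- iteration ---------------------------------------------------------

    def iter_subjects(self) -> Iterator[SubjectData]:
        for sid, g in self.frame.groupby("subject_id", sort=False):
            doses = tuple(
                DoseEvent(r.time, r.amount, r.infusion_duration)
                for r in g[g["event"] == "dose"].itertuples()
            )
            observations = tuple(
                Observation(r.time, r.conc, bool(r.below_lloq))
                for r in g[g["event"] == "obs"].itertuples()
            )
            first = g.iloc[0]
            cov = Covariates(**{
                c: (None if pd.isna(first[c]) else float(first[c]))
                for c in _COVARIATE_COLUMNS
            })
            yield SubjectData(sid, doses, observations, cov)

    def subset(self, subject_ids: Sequence[str]) -> "EventTable":
        """Rows of the listed subjects, in the listed order (duplicates allowed
        and re-labelled ``<id>#<k>`` — the form needed by bootstrap resampling)."""
        parts = []
        counts: dict[str, int] = {}
        for sid in subject_ids:
            g = self.frame[self.frame["subject_id"] == sid]
            if g.empty:
                raise KeyError(f"unknown subject {sid!r}")
            k = counts.get(sid, 0)
            counts[sid] = k + 1
            g = g.copy()
            if k:
                g["subject_id"] = f"{sid}#{k}"
            parts.append(g)
        return EventTable(pd.concat(parts, ignore_index=True))

    # -- persistence -------------------------------------------------------

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def to_json(self, path) -> None:
        doc = json.loads(self.frame.to_json(orient="records"))
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_csv(cls, path, strict: bool = True) -> "EventTable":
        frame = pd.read_csv(path, float_precision="round_trip")
        return cls(frame, strict=strict)


def read_events(path, strict: bool = True) -> EventTable:
    """Read an event-record CSV, validating on load."""
    return EventTable.from_csv(path, strict=strict)


def write_events(table: EventTable, path) -> None:
    """Write an event-record CSV (round-trips through :func:`read_events`)."""
    table.to_csv(path)
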