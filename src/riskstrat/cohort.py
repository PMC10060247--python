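"""Study-design data model and construction of analysis-ready populations.

A comparative cohort study contrasts a target treatment ``T`` against a
comparator ``C`` with respect to one or more outcomes ``O_1..O_n``.  Input is
a person-level cohort table (one row per subject: arm, end of observation,
baseline covariates) and an outcome event table (subject, outcome, event time
in days relative to treatment initiation; non-positive times are medical
history).  The constructed :class:`StudyPopulation` holds, per outcome, a
time-to-event and event indicator truncated at the end of observation and at
the time-at-risk horizon, with subjects who had the outcome at any time prior
to treatment initiation excluded from that outcome's analysis set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

ARM_TARGET = "target"
ARM_COMPARATOR = "comparator"


@dataclass(frozen=True)
class StudySpec:
    """Definition of the research aim: cohorts, outcomes and time windows.

    Parameters
    ----------
    treatment_id, comparator_id:
        Labels of the target and comparator treatment cohorts.
    outcome_ids:
        Outcome labels ``O_1..O_n``; non-empty and unique.
    lookback:
        Days of required pre-index observation (covariate assessment window).
    horizon:
        Time-at-risk in days after treatment initiation (index).
    exclusion_window:
        ``"all_time"`` excludes subjects with the outcome at any time prior
        to index; ``"lookback"`` restricts the exclusion to the lookback
        window.
    """

    treatment_id: str
    comparator_id: str
    outcome_ids: tuple[str, ...]
    lookback: int = 365
    horizon: int = 730
    exclusion_window: str = "all_time"

    def __post_init__(self):
        object.__setattr__(self, "outcome_ids", tuple(self.outcome_ids))
        if self.treatment_id == self.comparator_id:
            raise ConfigError("bad_spec", "treatment_id equals comparator_id")
        if not self.outcome_ids:
            raise ConfigError("bad_spec", "outcome_ids is empty")
        if len(set(self.outcome_ids)) != len(self.outcome_ids):
            raise ConfigError("bad_spec", "outcome_ids not unique")
        if self.lookback <= 0 or self.horizon <= 0:
            raise ConfigError("bad_spec", "lookback and horizon must be > 0")
        if self.exclusion_window not in ("all_time", "lookback"):
            raise ConfigError("bad_spec", f"unknown exclusion_window {self.exclusion_window!r}")


@dataclass
class StudyPopulation:
    """Analysis-ready population with per-outcome time-to-event data.

    Attributes
    ----------
    subjects:
        DataFrame indexed by subject id with columns ``arm`` and ``obs_end``.
    covariates:
        Numeric covariate frame on the same index (absent entries are 0).
    tte, event, included:
        Frames indexed by subject id with one column per outcome: truncated
        time-to-event (days), the event indicator, and whether the subject
        belongs to the outcome's analysis set (prior-outcome exclusion).
    """

    subjects: pd.DataFrame
    covariates: pd.DataFrame
    tte: pd.DataFrame
    event: pd.DataFrame
    included: pd.DataFrame
    spec: StudySpec

    @property
    def subject_ids(self) -> pd.Index:
        return self.subjects.index

    @property
    def arm(self) -> pd.Series:
        return self.subjects["arm"]

    def __len__(self) -> int:
        return len(self.subjects)

    def analysis_set(self, outcome_id: str, subject_ids=None) -> pd.DataFrame:
        """Return (arm, tte, event) for subjects in the outcome's analysis set."""
        if outcome_id not in self.tte.columns:
            raise DataError("unknown_outcome", outcome_id)
        mask = self.included[outcome_id]
        out = pd.DataFrame(
            {
                "arm": self.subjects["arm"][mask],
                "tte": self.tte[outcome_id][mask],
                "event": self.event[outcome_id][mask],
            }
        )
        if subject_ids is not None:
            out = out.loc[out.index.intersection(pd.Index(subject_ids))]
        return out

    def subset(self, subject_ids) -> "StudyPopulation":
        """Restrict the population to ``subject_ids`` (order-preserving)."""
        idx = self.subjects.index.intersection(pd.Index(subject_ids))
        return StudyPopulation(
            subjects=self.subjects.loc[idx],
            covariates=self.covariates.loc[idx],
            tte=self.tte.loc[idx],
            event=self.event.loc[idx],
            included=self.included.loc[idx],
            spec=self.spec,
        )


def _validate_cohorts(cohorts: pd.DataFrame) -> pd.DataFrame:
    required = {"subject_id", "arm", "obs_end"}
    missing = required - set(cohorts.columns)
    if missing:
        raise DataError("bad_columns", f"cohort table missing {sorted(missing)}")
    if cohorts.empty:
        raise DataError("arm_empty", "cohort table is empty")
    if cohorts["subject_id"].duplicated().any():
        dup = cohorts.loc[cohorts["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise DataError("duplicate_subject", f"subject {dup!r} appears more than once")
    arms = set(cohorts["arm"].unique())
    if not arms <= {ARM_TARGET, ARM_COMPARATOR}:
        raise DataError("bad_arm", f"arm labels must be {ARM_TARGET!r}/{ARM_COMPARATOR!r}, got {sorted(arms)}")
    for a in (ARM_TARGET, ARM_COMPARATOR):
        if a not in arms:
            raise DataError("arm_empty", f"no subjects in arm {a!r}")
    if (cohorts["obs_end"] < 0).any():
        raise DataError("bad_obs_end", "obs_end must be >= 0")
    return cohorts


def build_study_population(
    cohorts: pd.DataFrame,
    outcomes: pd.DataFrame,
    spec: StudySpec,
) -> StudyPopulation:
    """Construct a :class:`StudyPopulation` from raw cohort and outcome tables.

    For each outcome, subjects with an event at any time at or before index
    (``event_time <= 0``; restricted to the lookback window when
    ``spec.exclusion_window == "lookback"``) are excluded from that outcome's
    analysis set.  Remaining subjects get
    ``tte = min(first post-index event time, obs_end, horizon)`` and
    ``event = 1`` iff the first post-index event occurs at or before both
    truncations.
    """
    cohorts = _validate_cohorts(cohorts)
    subj = cohorts.set_index("subject_id")
    subjects = subj[["arm", "obs_end"]].copy()
    cov_cols = [c for c in subj.columns if c not in ("arm", "obs_end", "index_time")]
    covariates = subj[cov_cols].astype(float).fillna(0.0)

    idx = subjects.index
    n = len(idx)
    horizon = float(spec.horizon)
    obs_end = subjects["obs_end"].to_numpy(float)
    base_tte = np.minimum(obs_end, horizon)

    tte = pd.DataFrame(index=idx)
    event = pd.DataFrame(index=idx)
    included = pd.DataFrame(index=idx)

    if not outcomes.empty:
        missing = {"subject_id", "outcome_id", "event_time"} - set(outcomes.columns)
        if missing:
            raise DataError("bad_columns", f"outcome table missing {sorted(missing)}")
        if not np.isfinite(outcomes["event_time"].to_numpy(float)).all():
            raise DataError("bad_event_time", "event times must be finite")
        outcomes = outcomes[outcomes["subject_id"].isin(idx)]
        grouped = dict(iter(outcomes.groupby("outcome_id")))
    else:
        grouped = {}

    for oid in spec.outcome_ids:
        occ = grouped.get(oid)
        o_tte = base_tte.copy()
        o_event = np.zeros(n, dtype=int)
        o_incl = np.ones(n, dtype=bool)
        if occ is not None and not occ.empty:
            t = occ["event_time"].to_numpy(float)
            prior_mask = t <= 0
            if spec.exclusion_window == "lookback":
                prior_mask &= t >= -float(spec.lookback)
            prior_ids = occ.loc[prior_mask, "subject_id"].unique()
            o_incl = ~idx.isin(prior_ids)
            post = occ[t > 0]
            if not post.empty:
                first = post.groupby("subject_id")["event_time"].min()
                first = first.reindex(idx)
                fe = first.to_numpy(float)
                has = ~np.isnan(fe)
                hit = has & (fe <= o_tte)
                o_event[hit] = 1
                o_tte[hit] = fe[hit]
        tte[oid] = o_tte
        event[oid] = o_event
        included[oid] = o_incl

    return StudyPopulation(subjects, covariates, tte, event, included, spec)


def filter_subgroup(
    pop: StudyPopulation,
    predicate: "str | Callable[[pd.DataFrame], pd.Series]",
) -> StudyPopulation:
    """Restrict the population to subjects satisfying a covariate predicate.

    ``predicate`` is either a pandas query string over covariate columns
    (e.g. ``"prior_cvd == 0"``) or a callable mapping the covariate frame to
    a boolean Series.  Per-outcome tte/event fields are unchanged.
    """
    if callable(predicate):
        mask = predicate(pop.covariates)
    else:
        try:
            mask = pop.covariates.eval(predicate)
        except pd.errors.UndefinedVariableError as exc:
            raise DataError("unknown_covariate", str(exc)) from exc
    mask = pd.Series(np.asarray(mask, dtype=bool), index=pop.covariates.index)
    return pop.subset(pop.subject_ids[mask])


def summarize_population(pop: StudyPopulation, outcome_ids=None) -> pd.DataFrame:
    """Per-outcome sample sizes: patients, person-years and events by arm."""
    rows = []
    for oid in outcome_ids if outcome_ids is not None else pop.spec.outcome_ids:
        aset = pop.analysis_set(oid)
        for arm in (ARM_TARGET, ARM_COMPARATOR):
            sub = aset[aset["arm"] == arm]
            rows.append(
                {
                    "outcome_id": oid,
                    "arm": arm,
                    "patients": len(sub),
                    "person_years": float(sub["tte"].sum()) / 365.25,
                    "events": int(sub["event"].sum()),
                }
            )
    return pd.DataFrame(rows)
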