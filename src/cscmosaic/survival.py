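"""Kaplan-Meier estimation and log-rank comparison of stratified cohorts.

Thin, validated wrappers around lifelines that fix the conventions used
throughout the pipeline: deaths processed before censorings at tied times,
hypergeometric log-rank variance with tie correction, two-sided p from the
chi-square(1) tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .io import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject: follow-up time, event flag (1 = death observed) and stratum."""

    sample_id: str
    time: float
    event: int
    stratum: str = ""

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValidationError(f"{self.sample_id}: negative survival time")
        if self.event not in (0, 1):
            raise ValidationError(f"{self.sample_id}: event must be 0 or 1")


@dataclass
class KmCurve:
    """Product-limit estimate: survival after each ordered event time."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValidationError("survival must be non-increasing")
        if self.survival.size and not (0 <= self.survival.min() and self.survival.max() <= 1):
            raise ValidationError("survival must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival, "at_risk": self.at_risk})

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _clean(records: list[SurvivalRecord]) -> list[SurvivalRecord]:
    kept = [r for r in records if not (r.time == 0 and r.event == 0)]
    if len(kept) < len(records):
        logger.warning("dropped %d record(s) censored at time 0", len(records) - len(kept))
    return kept


def km_estimate(records: list[SurvivalRecord]) -> KmCurve:
    """Kaplan-Meier product-limit estimator over all records.

    At tied times deaths are processed before censorings, so a subject
    censored at an event time still counts in that event's risk set.
    """
    records = _clean(records)
    if not records:
        raise ValidationError("no informative records")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    ev = kmf.event_table
    # keep rows where something happens; survival reported after each time
    surv = kmf.survival_function_["KM_estimate"].to_numpy()
    t = kmf.survival_function_.index.to_numpy(dtype=float)
    at_risk = ev["at_risk"].to_numpy(dtype=float)
    # drop the leading time-0 row when no subject enters there
    return KmCurve(t, surv, at_risk)


def logrank_test(records: list[SurvivalRecord]) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) with two-sided p.

    Records must carry exactly two distinct stratum labels, each stratum
    contributing at least one observed event.
    """
    records = _clean(records)
    strata = sorted({r.stratum for r in records})
    if len(strata) != 2:
        raise ValidationError(f"log-rank needs exactly 2 strata, got {strata}")
    groups = {s: [r for r in records if r.stratum == s] for s in strata}
    for s, rs in groups.items():
        if not rs:
            raise ValidationError(f"stratum {s!r} is empty")
        if not any(r.event == 1 for r in rs):
            raise ValidationError(f"stratum {s!r} has no observed event")
    a, b = (groups[s] for s in strata)
    res = _ll_logrank(
        np.array([r.time for r in a]),
        np.array([r.time for r in b]),
        event_observed_A=np.array([r.event for r in a]),
        event_observed_B=np.array([r.event for r in b]),
    )
    return float(res.test_statistic), float(res.p_value)


def records_from_table(
    clinical: pd.DataFrame,
    strata: pd.Series | None = None,
    time_col: str = "time",
    event_col: str = "event",
    sample_col: str = "sample_id",
) -> list[SurvivalRecord]:
    """Build records from a clinical table, optionally joining stratum labels."""
    recs = []
    for _, row in clinical.iterrows():
        sid = str(row[sample_col])
        stratum = str(strata.loc[sid]) if strata is not None and sid in strata.index else ""
        recs.append(SurvivalRecord(sid, float(row[time_col]), int(row[event_col]), stratum))
    return recs
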