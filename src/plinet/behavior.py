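"""Behavioral scoring: detection-task responses, d', and recognition.

Responses to the detection task are matched to events within a 0-5000 ms
window from event onset; a response covered by several event windows is
credited to the event with the latest onset (a response is most plausibly
triggered by the most recent event).  Reaction times are trimmed at the
5th/95th percentiles of the pooled task-level distribution before hits
are counted.  Sensitivity is d' = z(hit rate) - z(false-alarm rate) with
extreme rates corrected by 1/(2N).  Recognition performance excludes
items whose pooled accuracy is above 95% or below 30% (chance on
4-alternative items being 25%) and answers attributed to outside
knowledge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "EventLog",
    "BehavioralIndices",
    "match_responses",
    "trim_rts",
    "dprime",
    "distractor_ratio",
    "score_recognition",
    "detection_indices",
    "read_event_log",
    "write_event_log",
]

EVENT_TYPES = ("target", "distractor", "irrelevant")

#: Confidence label whose answers are excluded from recognition scoring.
OTHER_SOURCE = "other_source"


@dataclass
class EventLog:
    """Events and button presses of one subject/condition block."""

    events: Sequence[tuple[str, str, float]]   # (type, stream, onset ms)
    responses: Sequence[float]                 # times in ms
    subject: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.events = [(str(t), str(s), float(o)) for t, s, o in self.events]
        self.responses = sorted(float(r) for r in self.responses)
        for t, _, onset in self.events:
            if t not in EVENT_TYPES:
                raise ValueError(f"unknown event type {t!r}")
            if onset < 0:
                raise ValueError("event onsets must be non-negative")
        if any(r < 0 for r in self.responses):
            raise ValueError("response times must be non-negative")
        self.events.sort(key=lambda e: e[2])

    def onsets(self, event_type: str) -> np.ndarray:
        return np.array([o for t, _, o in self.events if t == event_type])


@dataclass
class BehavioralIndices:
    """Per subject/condition summary indices."""

    d_prime: float
    mean_rt_ms: float
    distractor_ratio: float
    recognition_pct: float = float("nan")
    counts: dict = field(default_factory=dict)


def match_responses(log: EventLog, window_ms: float = 5000.0) -> pd.DataFrame:
    """Label every response as hit / false_alarm / other.

    A response at time ``t`` is assigned to the event with the latest
    onset among those with ``onset <= t <= onset + window_ms``; responses
    covered by no window are 'other'.  Each response receives exactly one
    label.
    """
    rows = []
    for t in log.responses:
        best = None
        for ev_type, _, onset in log.events:
            if onset <= t <= onset + window_ms:
                if best is None or onset >= best[1]:
                    best = (ev_type, onset)
        if best is None:
            rows.append((t, "other", np.nan, np.nan))
        else:
            ev_type, onset = best
            label = {"target": "hit", "distractor": "false_alarm"}.get(
                ev_type, "other")
            rows.append((t, label, onset, t - onset))
    return pd.DataFrame(rows, columns=["response_ms", "label",
                                       "event_onset_ms", "rt_ms"])


def trim_rts(all_rts, lower_pct: float = 5.0, upper_pct: float = 95.0):
    """Reject RTs outside the pooled (p5, p95) percentile cutoffs.

    Returns (retained RTs, (lower cutoff, upper cutoff)).  An RT is
    rejected iff it is strictly below the lower or strictly above the
    upper cutoff, so degenerate distributions retain everything.
    """
    rts = np.asarray(list(all_rts), dtype=float)
    if rts.size == 0:
        raise ValueError("need at least one RT")
    lo, hi = np.percentile(rts, [lower_pct, upper_pct])
    kept = rts[(rts >= lo) & (rts <= hi)]
    return kept, (float(lo), float(hi))


def dprime(hits: int, misses: int, false_alarms: int,
           correct_rejections: int) -> float:
    """Signal-detection sensitivity with the 1/(2N) extreme-rate correction."""
    n_sig = hits + misses
    n_noise = false_alarms + correct_rejections
    if n_sig < 1 or n_noise < 1:
        raise ValueError("need at least one signal and one noise trial")

    def rate(k: int, n: int) -> float:
        r = k / n
        if r == 0.0:
            r = 1.0 / (2 * n)
        elif r == 1.0:
            r = 1.0 - 1.0 / (2 * n)
        return r

    return float(norm.ppf(rate(hits, n_sig)) - norm.ppf(rate(false_alarms, n_noise)))


def distractor_ratio(fa_count: int, nontarget_response_count: int,
                     denominator: str = "fa_plus_other") -> float:
    """Share of false alarms among non-target responses.

    ``denominator="fa_plus_other"`` (default): FA / (FA + other non-target
    responses).  ``denominator="other_only"`` divides by the non-target
    responses excluding false alarms, the alternative literal reading.
    Returns NaN when the denominator is zero.
    """
    if denominator == "fa_plus_other":
        den = fa_count + nontarget_response_count
    elif denominator == "other_only":
        den = nontarget_response_count
    else:
        raise ValueError("denominator must be 'fa_plus_other' or 'other_only'")
    if den == 0:
        return float("nan")
    return fa_count / den


def score_recognition(answers: pd.DataFrame,
                      item_stats: Mapping[object, float],
                      low: float = 0.30, high: float = 0.95) -> float:
    """Percent correct over items surviving the pooled-accuracy exclusions.

    ``answers`` needs columns ``item``, ``correct`` and optionally
    ``confidence``; ``item_stats`` maps item -> pooled accuracy in [0, 1].
    Items with pooled accuracy > ``high`` or < ``low`` are excluded, as
    are answers whose confidence equals ``OTHER_SOURCE``.  Returns NaN if
    no item survives.
    """
    df = answers.drop_duplicates(subset="item")
    keep_items = [it for it in df["item"]
                  if low <= float(item_stats[it]) <= high]
    df = df[df["item"].isin(keep_items)]
    if "confidence" in df.columns:
        df = df[df["confidence"] != OTHER_SOURCE]
    if len(df) == 0:
        return float("nan")
    return 100.0 * float(df["correct"].astype(bool).mean())


def detection_indices(log: EventLog, window_ms: float = 5000.0,
                      rt_cutoffs: tuple[float, float] | None = None,
                      denominator: str = "fa_plus_other") -> BehavioralIndices:
    """Full detection-task scoring of one log.

    ``rt_cutoffs`` are the pooled task-level percentile cutoffs; pass the
    cutoffs from :func:`trim_rts` over all subjects' hit RTs, or None to
    trim within this log alone.
    """
    labeled = match_responses(log, window_ms)
    hit_rows = labeled[labeled["label"] == "hit"]
    if len(hit_rows):
        if rt_cutoffs is None:
            _, rt_cutoffs = trim_rts(hit_rows["rt_ms"])
        lo, hi = rt_cutoffs
        valid = hit_rows[(hit_rows["rt_ms"] >= lo) & (hit_rows["rt_ms"] <= hi)]
    else:
        valid = hit_rows
    hit_onsets = set(valid["event_onset_ms"])
    n_targets = len(log.onsets("target"))
    n_distractors = len(log.onsets("distractor"))
    hits = len(hit_onsets)
    misses = n_targets - hits
    fa_onsets = set(labeled.loc[labeled["label"] == "false_alarm",
                                "event_onset_ms"])
    fas = len(fa_onsets)
    crs = n_distractors - fas
    other = int((labeled["label"] == "other").sum())
    rejected_hits = len(hit_rows) - len(valid)
    d = dprime(hits, misses, fas, crs) if n_targets and n_distractors else float("nan")
    # responses that are neither hits nor false alarms: unmatched/irrelevant
    # responses plus RT-rejected hit candidates
    nontarget_other = other + rejected_hits
    ratio = distractor_ratio(fas, nontarget_other, denominator=denominator)
    return BehavioralIndices(
        d_prime=d,
        mean_rt_ms=float(valid["rt_ms"].mean()) if len(valid) else float("nan"),
        distractor_ratio=ratio,
        counts={"hits": hits, "misses": misses, "false_alarms": fas,
                "correct_rejections": crs, "other_responses": other,
                "rt_rejected": rejected_hits},
    )


def write_event_log(log: EventLog, path) -> None:
    """Delimited-text round-trip: one row per event and per response."""
    rows = [
        {"subject": log.subject, "condition": log.condition, "kind": "event",
         "event_type": t, "stream": s, "time_ms": o}
        for t, s, o in log.events
    ] + [
        {"subject": log.subject, "condition": log.condition, "kind": "response",
         "event_type": "", "stream": "", "time_ms": r}
        for r in log.responses
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_event_log(path) -> EventLog:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    ev = df[df["kind"] == "event"]
    resp = df[df["kind"] == "response"]
    subject = str(df["subject"].iloc[0]) if len(df) else ""
    condition = str(df["condition"].iloc[0]) if len(df) else ""
    return EventLog(
        events=list(zip(ev["event_type"], ev["stream"],
                        ev["time_ms"].astype(float))),
        responses=list(resp["time_ms"].astype(float)),
        subject=subject, condition=condition,
    )
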