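"""Episode segmentation and residence-time estimation.

A taxon's detection record on an irregular sampling schedule is segmented
into *episodes*: maximal runs of presence observations in which the day-gap
between consecutive detections never exceeds the gap limit (default 30
days). A gap beyond the limit means the taxon is presumed lost; if it
reappears it starts a new episode and must meet the residency threshold
again.

Because stool sampling is discrete, an episode's true duration is only
bracketed by the observations. Three estimators convert an episode's
endpoints into a residence span:

``min``
    last detection − first detection (the taxon was certainly there).
``ave``
    sample immediately after the last detection − first detection.
``max``
    sample after the last detection − sample before the first detection
    (the taxon could have been there the whole time it was undetectable).

When a flanking sample does not exist (the episode touches the study
boundary) the observed boundary date is used, so ``ave``/``max`` degrade
gracefully toward ``min`` and never extrapolate beyond sampled time. A
taxon is *resident* if any episode's span under the chosen estimator
reaches the residency threshold (default 14 days, >= 3x the maximal gut
transit time), *always resident* if a single episode's residence interval
covers the subject's entire sampled study period.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import ESTIMATORS, AnalysisConfig
from .datamodel import CountMatrix, PresenceSeries, presence_series, validate_metadata


@dataclass(frozen=True)
class Episode:
    """One maximal run of detections without an over-limit gap."""

    first_obs: int
    last_obs: int
    prior_sample: int | None  # latest sample date strictly before first_obs
    next_sample: int | None   # earliest sample date strictly after last_obs

    def __post_init__(self) -> None:
        if self.first_obs > self.last_obs:
            raise ValueError("first_obs must be <= last_obs")
        if self.prior_sample is not None and self.prior_sample >= self.first_obs:
            raise ValueError("prior_sample must precede first_obs")
        if self.next_sample is not None and self.next_sample <= self.last_obs:
            raise ValueError("next_sample must follow last_obs")

    @property
    def left_censored(self) -> bool:
        return self.prior_sample is None

    @property
    def right_censored(self) -> bool:
        return self.next_sample is None

    def interval(self, estimator: str) -> tuple[int, int]:
        """Residence interval [start, end] under an estimator.

        Start is the prior sample for ``max`` (falling back to the first
        detection when censored), the first detection otherwise; end is the
        next sample for ``ave``/``max`` (falling back to the last
        detection), the last detection for ``min``.
        """
        if estimator not in ESTIMATORS:
            raise ValueError(f"unknown estimator {estimator!r}; use one of {ESTIMATORS}")
        start = self.first_obs
        end = self.last_obs
        if estimator == "max" and self.prior_sample is not None:
            start = self.prior_sample
        if estimator in ("ave", "max") and self.next_sample is not None:
            end = self.next_sample
        return start, end


def episode_span(e: Episode, estimator: str) -> int:
    """Residence span (days) of one episode under an estimator."""
    start, end = e.interval(estimator)
    return end - start


@dataclass(frozen=True)
class ResidencyCall:
    """Residency classification of one taxon in one subject, one estimator."""

    taxon_id: str
    subject_id: str
    estimator: str
    episodes: tuple[Episode, ...]
    status: str                 # "resident" | "transient"
    always_resident: bool
    total_residence_days: int   # sum of spans over episodes meeting threshold
    fraction_of_study: float

    def __post_init__(self) -> None:
        if self.status not in ("resident", "transient"):
            raise ValueError(f"bad status {self.status!r}")
        if self.always_resident and self.status != "resident":
            raise ValueError("always_resident implies resident")


def segment_episodes(s: PresenceSeries, gap_limit_days: int = 30) -> list[Episode]:
    """Split a presence series into maximal episodes under the gap rule.

    The rule looks only at day-gaps between consecutive *detections*; what
    intervening samples showed (or whether they exist) does not break an
    episode, since a missing detection may simply be an uncollected stool.
    """
    if gap_limit_days <= 0:
        raise ValueError("gap_limit_days must be positive")
    pdates = s.presence_dates
    if not pdates:
        return []
    all_dates = s.schedule.dates
    runs: list[list[int]] = [[pdates[0]]]
    for d in pdates[1:]:
        if d - runs[-1][-1] <= gap_limit_days:
            runs[-1].append(d)
        else:
            runs.append([d])
    episodes = []
    for run in runs:
        first, last = run[0], run[-1]
        prior = max((d for d in all_dates if d < first), default=None)
        nxt = min((d for d in all_dates if d > last), default=None)
        episodes.append(Episode(first, last, prior, nxt))
    return episodes


def call_residency(s: PresenceSeries, cfg: AnalysisConfig, estimator: str) -> ResidencyCall:
    """Classify one presence series under one estimator.

    Resident iff some episode's span reaches the threshold; total residence
    time sums the spans of all threshold-meeting episodes. Always-resident
    requires a *single* episode (an interior loss disqualifies) whose
    estimator-specific residence interval covers the full study period —
    under ``max`` an absence at the very first sample is forgiven because
    the interval starts at the prior sample, which reproduces the
    characteristic ordering min <= ave <= max of always-resident counts.
    """
    episodes = tuple(segment_episodes(s, cfg.gap_limit_days))
    spans = [episode_span(e, estimator) for e in episodes]
    resident_spans = [sp for sp in spans if sp >= cfg.residency_threshold_days]
    status = "resident" if resident_spans else "transient"
    total = int(sum(resident_spans))

    always = False
    if status == "resident" and len(episodes) == 1:
        start, end = episodes[0].interval(estimator)
        sched = s.schedule
        always = start <= sched.dates[0] and end >= sched.dates[-1]

    span = s.schedule.study_span
    frac = total / span if span > 0 else 0.0
    return ResidencyCall(
        taxon_id=s.taxon_id,
        subject_id=s.schedule.subject_id,
        estimator=estimator,
        episodes=episodes,
        status=status,
        always_resident=always,
        total_residence_days=total,
        fraction_of_study=frac,
    )


def residency_matrix(m: CountMatrix, meta: pd.DataFrame,
                     cfg: AnalysisConfig | None = None,
                     estimators: tuple[str, ...] = ESTIMATORS,
                     min_count: int | None = None) -> list[ResidencyCall]:
    """Batch residency calls: every observed (taxon, subject) x estimator.

    Taxa never detected in a subject are excluded from that subject's
    calls (and hence from its denominators downstream).
    """
    cfg = cfg or AnalysisConfig()
    meta = validate_metadata(meta)
    calls: list[ResidencyCall] = []
    sample_set = set(m.sample_ids)
    for subject in sorted(meta["subject_id"].unique()):
        sub = meta[meta["subject_id"] == subject]
        if not any(s in sample_set for s in sub["sample_id"]):
            continue
        series = presence_series(
            m, meta, subject,
            min_count=cfg.presence_min_count if min_count is None else min_count,
        )
        for taxon, s in series.items():
            if not any(s.present):
                continue
            for est in estimators:
                calls.append(call_residency(s, cfg, est))
    return calls


def calls_to_frame(calls: list[ResidencyCall]) -> pd.DataFrame:
    """Tidy table of residency calls (one row per taxon x subject x estimator)."""
    return pd.DataFrame(
        {
            "taxon_id": c.taxon_id,
            "subject_id": c.subject_id,
            "estimator": c.estimator,
            "status": c.status,
            "always_resident": c.always_resident,
            "n_episodes": len(c.episodes),
            "total_days": c.total_residence_days,
            "fraction_of_study": c.fraction_of_study,
        }
        for c in calls
    )
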