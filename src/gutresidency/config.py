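"""Analysis configuration.

The residency definition rests on two durations: a *residency threshold*
(how long a taxon must be observed before it is considered established,
default 14 days, i.e. at least three times the upper bound of healthy adult
gut transit time, 0.7-4 days) and a *gap limit* (how long a taxon may go
unobserved before it is presumed lost, default 30 days). The two are
independent knobs: after a loss gap, a taxon must meet the residency
threshold again from scratch.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class AnalysisConfig:
    """Parameters shared across the residency pipeline.

    Attributes
    ----------
    residency_threshold_days:
        Minimum episode span (under the chosen estimator) for a taxon or
        clone to be called resident. Days.
    gap_limit_days:
        Maximum allowed gap between consecutive presence observations within
        one residence episode. Days.
    rarefaction_depth:
        Reads each sample is subsampled to (without replacement) before
        presence and dissimilarity computations.
    min_total_reads:
        Taxa with fewer total reads than this across the whole dataset are
        discarded as likely spurious.
    presence_min_count:
        Minimum post-processing count for a taxon to be scored "present"
        in a sample.
    transit_time_days:
        Published healthy-adult gut transit time range; documentation only,
        it motivates the 14-day default but is not used in computation.
    random_seed:
        Seed for stochastic steps (rarefaction).
    """

    residency_threshold_days: int = 14
    gap_limit_days: int = 30
    rarefaction_depth: int = 10_000
    min_total_reads: int = 100
    presence_min_count: int = 1
    transit_time_days: tuple[float, float] = (0.7, 4.0)
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.residency_threshold_days <= 0:
            raise ValueError("residency_threshold_days must be positive")
        if self.gap_limit_days <= 0:
            raise ValueError("gap_limit_days must be positive")
        if self.rarefaction_depth <= 0:
            raise ValueError("rarefaction_depth must be positive")
        if self.min_total_reads < 0:
            raise ValueError("min_total_reads must be non-negative")
        if self.presence_min_count < 1:
            raise ValueError("presence_min_count must be >= 1")


ESTIMATORS = ("min", "ave", "max")
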