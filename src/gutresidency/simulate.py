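"""Synthetic longitudinal cohort generator with exported ground truth.

Emulates the statistical structure the residency analysis assumes: eight
subjects sampled roughly every week or two over spans of 245-849 days,
180-250 taxa per subject partitioned into always-resident, episodic and
transient members, compositional read counts driven by autocorrelated
log-abundances, and cultured-clone series whose residence times differ by
group. Every stochastic step draws from one explicitly threaded numpy
Generator; the same seed reproduces the cohort bit-for-bit.

Detection is idealised: a taxon present on a sampled day yields at least
one read unless it is hit by the per-observation false-negative
probability, so with that probability at zero the observed presence
pattern equals the ground-truth colonization intervals restricted to
sampled days. That makes label-recovery tests sharp; real 16S data adds
abundance-dependent dropout the generator does not model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clones import CloneRecord
from .datamodel import CountMatrix, SamplingSchedule


@dataclass(frozen=True)
class CloneGroupSpec:
    """Residence-time distribution of one clone group (phylogroup/species)."""

    n_clones: int
    mean_log10_days: float
    sd_log10_days: float


DEFAULT_CLONE_GROUPS: dict[str, CloneGroupSpec] = {
    # long-lived phylogroups
    "A": CloneGroupSpec(8, 2.0, 0.4),
    "B2.3": CloneGroupSpec(7, 1.9, 0.4),
    "F": CloneGroupSpec(7, 1.8, 0.4),
    # short-lived phylogroups
    "A.1": CloneGroupSpec(10, 0.9, 0.4),
    "B1": CloneGroupSpec(12, 1.0, 0.4),
    "E": CloneGroupSpec(4, 0.8, 0.4),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-generator settings; the defaults are the study conditions.

    Schedules: spans uniform over ``span_days_range`` (245-849 d), target
    inter-sample interval ``median_interval_days`` with integer jitter of
    +/- ``interval_jitter`` days, each planned collection missed with
    probability ``missed_sample_prob``. Community: taxon count uniform
    over ``n_taxa_range``; membership classes drawn with the three
    ``fraction_*`` simplex weights; episodic colonization durations are
    lognormal (natural-log parameters); per-taxon log-abundances follow an
    AR(1) with autocorrelation ``abundance_rho``. ``core_taxa_count``
    always-resident taxa share identifiers across subjects (a planted core
    resident microbiome); all other taxa are subject-private.
    """

    n_subjects: int = 8
    span_days_range: tuple[int, int] = (245, 849)
    median_interval_days: int = 8
    interval_jitter: int = 2
    missed_sample_prob: float = 0.1
    n_taxa_range: tuple[int, int] = (180, 250)
    fraction_always_resident: float = 0.35
    fraction_episodic: float = 0.45
    fraction_transient: float = 0.20
    episode_duration_mean_log: float = 4.0   # exp(4) ~ 55 days
    episode_duration_sd_log: float = 1.0
    abundance_mu_sd: float = 1.5
    abundance_rho: float = 0.8
    abundance_innovation_sd: float = 0.5
    reads_per_sample: int = 20_000
    detection_false_negative_prob: float = 0.0
    core_taxa_count: int = 0
    clone_groups: dict[str, CloneGroupSpec] = field(
        default_factory=lambda: dict(DEFAULT_CLONE_GROUPS))
    clone_pick_prob: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        w = (self.fraction_always_resident, self.fraction_episodic,
             self.fraction_transient)
        if any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ValueError(f"membership fractions must be a simplex, got {w}")
        if self.span_days_range[0] <= 0 or self.span_days_range[0] > self.span_days_range[1]:
            raise ValueError("bad span_days_range")
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be positive")


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    # taxon -> ordered non-overlapping (start_day, end_day) colonization intervals
    intervals: dict[str, tuple[tuple[int, int], ...]] = field(default_factory=dict)
    # taxon -> membership class: "always" | "episodic" | "transient"
    classes: dict[str, str] = field(default_factory=dict)
    always_resident: set[str] = field(default_factory=set)
    # clone_id -> (group_label, (start_day, end_day)); includes unobserved clones
    clones: dict[str, tuple[str, tuple[int, int]]] = field(default_factory=dict)


def simulate_schedule(cfg: SimulationConfig, subject_index: int,
                      rng: np.random.Generator) -> SamplingSchedule:
    """One subject's collection days: jittered grid with missed collections."""
    span = int(rng.integers(cfg.span_days_range[0], cfg.span_days_range[1] + 1))
    planned = [0]
    while planned[-1] < span:
        gap = cfg.median_interval_days + int(
            rng.integers(-cfg.interval_jitter, cfg.interval_jitter + 1))
        planned.append(planned[-1] + max(1, gap))
    planned[-1] = span
    kept = [d for d in planned if rng.random() >= cfg.missed_sample_prob]
    if len(kept) < 2:
        raise ValueError(
            f"subject {subject_index}: fewer than 2 samples survived "
            f"missed_sample_prob={cfg.missed_sample_prob}"
        )
    return SamplingSchedule(f"S{subject_index + 1}", tuple(sorted(set(kept))))


def _episodic_intervals(cfg: SimulationConfig, lo: int, hi: int,
                        rng: np.random.Generator) -> tuple[tuple[int, int], ...]:
    n_int = 1 + int(rng.random() < 0.3)
    intervals: list[tuple[int, int]] = []
    for _ in range(n_int):
        dur = max(1, int(round(rng.lognormal(cfg.episode_duration_mean_log,
                                             cfg.episode_duration_sd_log))))
        dur = min(dur, hi - lo)
        for _ in range(10):  # retry placement to avoid overlap
            start = int(rng.integers(lo, hi - dur + 1))
            cand = (start, start + dur)
            if all(cand[1] < s or cand[0] > e for s, e in intervals):
                intervals.append(cand)
                break
    return tuple(sorted(intervals))


def simulate_community(cfg: SimulationConfig, schedule: SamplingSchedule,
                       rng: np.random.Generator,
                       taxon_prefix: str | None = None
                       ) -> tuple[CountMatrix, GroundTruth, pd.DataFrame]:
    """Counts, ground truth and metadata for one subject.

    Returns the taxon-by-sample CountMatrix (columns in schedule order),
    the planted truth, and a metadata frame (sample_id, subject_id, date).
    """
    prefix = taxon_prefix or schedule.subject_id
    days = np.array(schedule.dates)
    lo, hi = int(days[0]), int(days[-1])  # sampled study period
    n_taxa = int(rng.integers(cfg.n_taxa_range[0], cfg.n_taxa_range[1] + 1))
    truth = GroundTruth()

    n_core = min(cfg.core_taxa_count, n_taxa)
    classes = ["always"] * n_core + list(rng.choice(
        ["always", "episodic", "transient"],
        size=n_taxa - n_core,
        p=[cfg.fraction_always_resident, cfg.fraction_episodic,
           cfg.fraction_transient],
    ))
    taxa = [f"CORE_{i + 1}" if i < n_core else f"{prefix}_T{i + 1:04d}"
            for i in range(n_taxa)]

    present = np.zeros((n_taxa, len(days)), dtype=bool)
    for i, (taxon, cls) in enumerate(zip(taxa, classes)):
        if cls == "always":
            ivs: tuple[tuple[int, int], ...] = ((lo, hi),)
        elif cls == "episodic":
            ivs = _episodic_intervals(cfg, lo, hi, rng)
        else:
            d = int(days[rng.integers(0, len(days))])
            ivs = ((d, d),)
        truth.intervals[taxon] = ivs
        truth.classes[taxon] = cls
        if cls == "always":
            truth.always_resident.add(taxon)
        for s, e in ivs:
            present[i] |= (days >= s) & (days <= e)

    # AR(1) log-abundance dynamics around a per-taxon baseline
    mu = rng.normal(0.0, cfg.abundance_mu_sd, size=n_taxa)
    z = rng.normal(0.0, cfg.abundance_innovation_sd, size=n_taxa)
    counts = np.zeros((n_taxa, len(days)), dtype=np.int64)
    for j in range(len(days)):
        if j > 0:
            z = (cfg.abundance_rho * z
                 + np.sqrt(1 - cfg.abundance_rho**2)
                 * rng.normal(0.0, cfg.abundance_innovation_sd, size=n_taxa))
        detected = present[:, j].copy()
        if cfg.detection_false_negative_prob > 0:
            dropout = rng.random(n_taxa) < cfg.detection_false_negative_prob
            detected &= ~dropout
        if not detected.any():
            continue
        w = np.where(detected, np.exp(mu + z), 0.0)
        p = w / w.sum()
        col = rng.multinomial(cfg.reads_per_sample, p)
        # idealised detection: every detected taxon leaves >= 1 read
        zero = detected & (col == 0)
        if zero.any():
            donor = int(np.argmax(col))
            col[zero] = 1
            col[donor] -= int(zero.sum())
        counts[:, j] = col

    sample_ids = [f"{schedule.subject_id}_D{d:04d}" for d in days]
    m = CountMatrix(pd.DataFrame(counts, index=taxa, columns=sample_ids))
    meta = pd.DataFrame({
        "sample_id": sample_ids,
        "subject_id": schedule.subject_id,
        "date": days,
    })
    return m, truth, meta


def simulate_clones(cfg: SimulationConfig, schedule: SamplingSchedule,
                    rng: np.random.Generator) -> tuple[list[CloneRecord], GroundTruth]:
    """Clone series for one subject with group-specific residence times.

    Each clone's residence duration is 10**Normal(mean_log10, sd_log10)
    days; the residence window is placed uniformly, and each sampled day
    inside it is observed with ``clone_pick_prob`` (a colony of the clone
    picked from the plate). Clones never observed are omitted from the
    records but retained in the truth.
    """
    if len(cfg.clone_groups) < 2:
        raise ValueError("need >= 2 clone groups")
    days = np.array(schedule.dates)
    lo, hi = int(days[0]), int(days[-1])
    truth = GroundTruth()
    records = []
    for label, spec in sorted(cfg.clone_groups.items()):
        for i in range(spec.n_clones):
            dur = int(round(10 ** rng.normal(spec.mean_log10_days,
                                             spec.sd_log10_days)))
            dur = min(dur, hi - lo)
            start = int(rng.integers(lo, hi - dur + 1))
            interval = (start, start + dur)
            clone_id = f"{schedule.subject_id}:{label}:{i + 1}"
            truth.clones[clone_id] = (label, interval)
            inside = days[(days >= interval[0]) & (days <= interval[1])]
            observed = tuple(int(d) for d in inside
                             if rng.random() < cfg.clone_pick_prob)
            if observed:
                records.append(CloneRecord(clone_id, schedule.subject_id,
                                           label, observed))
    return records, truth


@dataclass
class Cohort:
    """A complete simulated cohort with its ground truth."""

    counts: CountMatrix
    metadata: pd.DataFrame
    schedules: dict[str, SamplingSchedule]
    clones: list[CloneRecord]
    truth: dict[str, GroundTruth]        # per subject (community truth)
    clone_truth: dict[str, GroundTruth]  # per subject (clone truth)


def simulate_cohort(cfg: SimulationConfig | None = None,
                    seed: int | None = None) -> Cohort:
    """Generate the full multi-subject cohort (counts, metadata, clones)."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    frames, metas, schedules = [], [], {}
    truth: dict[str, GroundTruth] = {}
    clone_truth: dict[str, GroundTruth] = {}
    clones: list[CloneRecord] = []
    for i in range(cfg.n_subjects):
        sched = simulate_schedule(cfg, i, rng)
        schedules[sched.subject_id] = sched
        m, t, meta = simulate_community(cfg, sched, rng)
        frames.append(m.to_frame())
        metas.append(meta)
        truth[sched.subject_id] = t
        recs, ct = simulate_clones(cfg, sched, rng)
        clones.extend(recs)
        clone_truth[sched.subject_id] = ct
    combined = pd.concat(frames, axis=1).fillna(0).astype(np.int64)
    # stable taxon order: core ids first, then per-subject blocks
    return Cohort(
        counts=CountMatrix(combined),
        metadata=pd.concat(metas, ignore_index=True),
        schedules=schedules,
        clones=clones,
        truth=truth,
        clone_truth=clone_truth,
    )
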