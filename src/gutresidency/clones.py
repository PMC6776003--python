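"""Clone-level residency of cultured isolates.

Clones are fingerprint-defined bacterial lineages, scoped to one subject
(identical ids in different subjects are different clones). Each clone's
observation dates form a presence series on its subject's sampling
schedule, so residency reuses the exact episode machinery applied to
sequence taxa. Residence times are compared across phylogroups / species
on a log10 scale, and clones observed at the study boundary are flagged
"beyond study" (presumed to reside outside the observation window).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .datamodel import PresenceSeries, SamplingSchedule
from .residency import ResidencyCall, call_residency


@dataclass(frozen=True)
class CloneRecord:
    """One fingerprint-defined clone and its observation dates."""

    clone_id: str
    subject_id: str
    group_label: str
    observation_dates: tuple[int, ...]
    lactose_fermenter: bool | None = None

    def __post_init__(self) -> None:
        d = self.observation_dates
        if not d:
            raise ValueError(f"clone {self.clone_id!r} has no observations")
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError(f"clone {self.clone_id!r} dates not strictly increasing")


@dataclass(frozen=True)
class CloneResidency:
    """Residency classification of one clone (all three estimators)."""

    clone: CloneRecord
    calls: dict[str, ResidencyCall]    # estimator -> call
    beyond_study: bool

    def observed_days(self, estimator: str) -> int:
        """Total observed residence span over all episodes (no threshold).

        Transient clones keep their short spans here — residence-time
        comparisons plot every clone, not just the residents.
        """
        from .residency import episode_span
        return sum(episode_span(e, estimator) for e in self.calls[estimator].episodes)

    def log10_days(self, estimator: str, offset: float = 1.0) -> float:
        """log10(observed residence days + offset).

        A single-observation clone has 0 observed days under ``min``; the
        default +1 offset keeps it on the scale rather than at -inf.
        """
        return math.log10(self.observed_days(estimator) + offset)


def clones_from_table(df: pd.DataFrame) -> list[CloneRecord]:
    """Collapse an isolate table (with clone_id column) into CloneRecords."""
    if "clone_id" not in df.columns:
        raise ValueError("isolate table has no clone_id column")
    records = []
    for (subject, clone), grp in df.groupby(["subject_id", "clone_id"], sort=True):
        dates = tuple(sorted({int(d) for d in grp["day"]}))
        labels = set(grp["group_label"])
        if len(labels) > 1:
            raise ValueError(f"clone {clone!r} in {subject!r} has mixed labels {labels}")
        lac = None
        if "lactose" in grp.columns:
            vals = set(grp["lactose"].dropna().astype(str).str.lower())
            if vals <= {"true", "1", "yes"}:
                lac = True
            elif vals <= {"false", "0", "no"}:
                lac = False
        records.append(CloneRecord(str(clone), str(subject), labels.pop(), dates, lac))
    return records


def screen_candidate_residents(isolates: pd.DataFrame,
                               cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Step-wise screen: which phylogroup/species labels could harbour residents?

    Groups isolates by (subject, group_label). A label whose observations
    span at least the residency threshold is a *candidate resident* — its
    isolates deserve fingerprinting to confirm clone identity. A label
    confined to a shorter span is provisionally transient, and
    conservatively all its same-sample isolates are counted as one clone
    (distinct observation dates = provisional transient clone count).
    """
    cfg = cfg or AnalysisConfig()
    if isolates.empty:
        return pd.DataFrame(columns=["subject_id", "group_label", "first_day",
                                     "last_day", "span_days", "n_isolates",
                                     "candidate_resident", "n_provisional_transient_clones"])
    rows = []
    for (subject, label), grp in isolates.groupby(["subject_id", "group_label"], sort=True):
        days = sorted(int(d) for d in grp["day"])
        span = days[-1] - days[0]
        candidate = span >= cfg.residency_threshold_days
        rows.append({
            "subject_id": subject,
            "group_label": label,
            "first_day": days[0],
            "last_day": days[-1],
            "span_days": span,
            "n_isolates": len(grp),
            "candidate_resident": candidate,
            "n_provisional_transient_clones": 0 if candidate else len(set(days)),
        })
    return pd.DataFrame(rows)


def clone_residency(clones: list[CloneRecord],
                    schedules: dict[str, SamplingSchedule],
                    cfg: AnalysisConfig | None = None) -> list[CloneResidency]:
    """Apply the episode/estimator machinery to each clone.

    ``beyond_study`` is true when the clone was observed at the subject's
    first sample, last sample, or throughout the study — it presumably
    colonised outside the observation window.
    """
    cfg = cfg or AnalysisConfig()
    out = []
    for clone in clones:
        sched = schedules[clone.subject_id]
        date_set = set(sched.dates)
        stray = [d for d in clone.observation_dates if d not in date_set]
        if stray:
            raise ValueError(
                f"clone {clone.clone_id!r}: observation dates {stray} not in "
                f"subject {clone.subject_id!r} schedule"
            )
        present = tuple(d in set(clone.observation_dates) for d in sched.dates)
        series = PresenceSeries(clone.clone_id, sched, present)
        calls = {est: call_residency(series, cfg, est) for est in ("min", "ave", "max")}
        beyond = (clone.observation_dates[0] == sched.dates[0]
                  or clone.observation_dates[-1] == sched.dates[-1])
        out.append(CloneResidency(clone, calls, beyond))
    return out


def pool_small_groups(cr: list[CloneResidency], min_group_size: int = 6,
                      other_label: str = "Other") -> dict[str, list[CloneResidency]]:
    """Group clones by label, pooling labels with <= min_group_size members."""
    by_label: dict[str, list[CloneResidency]] = {}
    for c in cr:
        by_label.setdefault(c.clone.group_label, []).append(c)
    pooled: dict[str, list[CloneResidency]] = {}
    for label, members in sorted(by_label.items()):
        key = label if len(members) > min_group_size else other_label
        pooled.setdefault(key, []).extend(members)
    return pooled


def group_residence_comparison(cr: list[CloneResidency], estimator: str = "ave",
                               min_group_size: int = 6, log_offset: float = 1.0):
    """One-way ANOVA of log10 residence time across clone groups.

    Small groups pool into "Other" first. Pairwise contrasts use t tests on
    the pooled within-group variance with Holm-Sidak adjustment. Returns
    (F, p, group means, pairwise table).
    """
    groups = pool_small_groups(cr, min_group_size)
    groups = {g: np.array([c.log10_days(estimator, log_offset) for c in members])
              for g, members in groups.items()}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups after pooling")
    f, p = stats.f_oneway(*groups.values())
    means = {g: float(v.mean()) for g, v in groups.items()}

    # pooled-error pairwise t (Fisher LSD statistics, Holm-Sidak adjusted)
    n_total = sum(len(v) for v in groups.values())
    k = len(groups)
    mse = sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / (n_total - k)
    rows = []
    for ga, gb in itertools.combinations(groups, 2):
        na, nb = len(groups[ga]), len(groups[gb])
        se = np.sqrt(mse * (1 / na + 1 / nb))
        t = (means[ga] - means[gb]) / se
        praw = 2 * stats.t.sf(abs(t), df=n_total - k)
        rows.append({"group_a": ga, "group_b": gb, "t": t, "p_raw": praw})
    pairs = pd.DataFrame(rows)
    pairs["p_adj"] = multipletests(pairs["p_raw"], method="holm-sidak")[1]
    return float(f), float(p), means, pairs


# ---------------------------------------------------------------------------
# contingency analyses
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher's exact p by hypergeometric enumeration.

    Works in exact integer arithmetic (binomial-coefficient products share
    the denominator C(n, c1)), summing the probabilities of all tables with
    the observed margins that are no more probable than the observed one.
    """
    (a, b), (c, d) = np.asarray(table, dtype=np.int64)
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        raise ValueError("Fisher's exact undefined with an empty margin")
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
    observed = weights[a - lo]
    num = sum(w for w in weights if w <= observed)
    return num / math.comb(n, c1)


def beyond_study_contingency(cr: list[CloneResidency],
                             long_lived_groups: set[str] = frozenset({"A", "B2.3", "F"}),
                             estimator: str = "ave",
                             yates: bool = False):
    """Are the long-lived clone groups over-represented among boundary and
    resident clones?

    Builds two 2x2 tables partitioning clones into long-lived groups vs
    all others: (i) beyond-study vs within-study, tested by chi-square
    (optionally Yates-corrected; warns when an expected count is < 5), and
    (ii) resident vs transient under the given estimator, tested by
    Fisher's exact test. Returns
    (chi2, chi2_p, beyond_table, fisher_p, resident_table).
    """
    in_set = np.array([c.clone.group_label in long_lived_groups for c in cr])
    beyond = np.array([c.beyond_study for c in cr])
    resident = np.array([c.calls[estimator].status == "resident" for c in cr])

    def table(flag):
        return np.array([
            [int((in_set & flag).sum()), int((in_set & ~flag).sum())],
            [int((~in_set & flag).sum()), int((~in_set & ~flag).sum())],
        ])

    t_beyond = table(beyond)
    if t_beyond.sum(axis=0).min() == 0 or t_beyond.sum(axis=1).min() == 0:
        raise ValueError("empty margin in beyond-study table")
    expected = stats.contingency.expected_freq(t_beyond)
    if (expected < 5).any():
        warnings.warn("chi-square expected count < 5; consider Fisher's exact")
    chi2, chi2_p, _, _ = stats.chi2_contingency(t_beyond, correction=yates)

    t_resident = table(resident)
    fisher_p = fisher_exact_2x2(t_resident)
    return float(chi2), float(chi2_p), t_beyond, float(fisher_p), t_resident
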