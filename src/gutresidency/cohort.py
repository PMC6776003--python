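"""Cohort-level residency summaries and the core-resident-microbiome test.

Produces the per-subject summary table (counts and percentages of
resident / transient / always-resident taxa under each estimator, plus a
cohort Average row), percentile-rank residency profiles, and the
exponential-decay test of whether a shared "core resident microbiome"
exists: the number of taxa always-resident in at least x subjects, N(x),
is fit with a one-phase decay N(x) = (y0 - plateau)*exp(-k*(x-1)) + plateau
and the plateau is tested against zero. A plateau indistinguishable from
zero means no taxon set is shared as a permanent resident by arbitrarily
many people.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import ESTIMATORS
from .datamodel import SamplingSchedule
from .residency import ResidencyCall


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (not banker's)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class SubjectSummary:
    """Residency tallies for one subject (or the cohort average)."""

    subject_id: str
    n_samples: int
    span_days: int
    n_taxa_observed: int
    # per estimator: (n_resident, n_transient, n_always_resident)
    tallies: dict[str, tuple[int, int, int]]

    def __post_init__(self) -> None:
        for est, (r, t, a) in self.tallies.items():
            if r + t != self.n_taxa_observed:
                raise ValueError(
                    f"{self.subject_id}/{est}: resident {r} + transient {t} "
                    f"!= observed {self.n_taxa_observed}"
                )
            if a > r:
                raise ValueError(f"{self.subject_id}/{est}: always-resident {a} > resident {r}")


def summarize_subjects(calls: list[ResidencyCall],
                       schedules: dict[str, SamplingSchedule]) -> list[SubjectSummary]:
    """One SubjectSummary per subject from a batch of residency calls."""
    rows = []
    subjects = sorted({c.subject_id for c in calls})
    for subject in subjects:
        sched = schedules[subject]
        sub = [c for c in calls if c.subject_id == subject]
        taxa = {c.taxon_id for c in sub}
        tallies = {}
        for est in ESTIMATORS:
            byest = [c for c in sub if c.estimator == est]
            if {c.taxon_id for c in byest} != taxa:
                raise ValueError(f"calls for {subject} missing estimator {est}")
            r = sum(c.status == "resident" for c in byest)
            a = sum(c.always_resident for c in byest)
            tallies[est] = (r, len(taxa) - r, a)
        rows.append(SubjectSummary(subject, len(sched.dates), sched.study_span,
                                   len(taxa), tallies))
    return rows


def average_summary(rows: list[SubjectSummary]) -> SubjectSummary:
    """Cohort Average row: arithmetic means of the count cells, rounded to
    the nearest integer (ties away from zero)."""
    if not rows:
        raise ValueError("no subject rows to average")
    n = len(rows)

    def avg(vals):
        return round_half_away(sum(vals) / n)

    tallies = {}
    n_taxa = avg([r.n_taxa_observed for r in rows])
    for est in ESTIMATORS:
        res = avg([r.tallies[est][0] for r in rows])
        alw = avg([r.tallies[est][2] for r in rows])
        tallies[est] = (res, n_taxa - res, alw)
    return SubjectSummary(
        "Average",
        avg([r.n_samples for r in rows]),
        avg([r.span_days for r in rows]),
        n_taxa,
        tallies,
    )


def summary_table(rows: list[SubjectSummary], include_average: bool = True) -> pd.DataFrame:
    """Wide summary table: one row per subject plus an Average row.

    Percentages are computed from the (rounded) counts in the same row,
    i.e. the Average percentages are ratios of averaged counts.
    """
    all_rows = list(rows) + ([average_summary(rows)] if include_average else [])
    out = []
    for r in all_rows:
        rec: dict[str, object] = {
            "subject_id": r.subject_id,
            "n_samples": r.n_samples,
            "span_days": r.span_days,
            "n_taxa": r.n_taxa_observed,
        }
        for est in ESTIMATORS:
            nres, ntr, nalw = r.tallies[est]
            denom = r.n_taxa_observed
            rec[f"{est}_resident"] = nres
            rec[f"{est}_resident_pct"] = round_half_away(100 * nres / denom)
            rec[f"{est}_transient"] = ntr
            rec[f"{est}_transient_pct"] = round_half_away(100 * ntr / denom)
            rec[f"{est}_always_resident"] = nalw
            rec[f"{est}_always_resident_pct"] = round_half_away(100 * nalw / denom)
        out.append(rec)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# percentile-rank residency profile
# ---------------------------------------------------------------------------

def residency_rank_profile(calls: list[ResidencyCall], subject: str,
                           estimator: str = "ave") -> pd.Series:
    """Histogram of a subject's taxa by percent-of-study residence decile.

    Resident taxa are binned by 100 * fraction_of_study into deciles
    0-10, ..., 90-100 (fractions above 1, possible under ``max``, land in
    the top bin); never-resident taxa go to a separate "transient" bucket.
    """
    sub = [c for c in calls if c.subject_id == subject and c.estimator == estimator]
    if not sub:
        raise KeyError(f"no calls for subject {subject!r} / estimator {estimator!r}")
    labels = [f"{10*i}-{10*(i+1)}%" for i in range(10)]
    counts = dict.fromkeys(["transient"] + labels, 0)
    for c in sub:
        if c.status == "transient":
            counts["transient"] += 1
        else:
            i = min(int(100 * c.fraction_of_study // 10), 9)
            counts[labels[i]] += 1
    return pd.Series(counts, name=f"{subject}:{estimator}")


# ---------------------------------------------------------------------------
# core resident microbiome
# ---------------------------------------------------------------------------

def core_resident_curve(calls: list[ResidencyCall], estimator: str = "ave") -> np.ndarray:
    """N(x) = number of taxa always-resident in at least x subjects, x=1..S."""
    sub = [c for c in calls if c.estimator == estimator]
    subjects = sorted({c.subject_id for c in sub})
    if len(subjects) < 2:
        raise ValueError("core curve needs >= 2 subjects")
    per_taxon: dict[str, int] = {}
    for c in sub:
        if c.always_resident:
            per_taxon[c.taxon_id] = per_taxon.get(c.taxon_id, 0) + 1
    n_subjects = len(subjects)
    counts = np.array(list(per_taxon.values()), dtype=int)
    return np.array([(counts >= x).sum() for x in range(1, n_subjects + 1)])


@dataclass(frozen=True)
class DecayFit:
    """One-phase exponential-decay fit of a core-microbiome curve."""

    y0: float
    k: float
    plateau: float
    r_squared: float
    plateau_se: float
    plateau_p: float
    identifiable: bool = True


class DecayFitError(RuntimeError):
    """Nonlinear fit failed; carries the initialisation used."""


def fit_decay_plateau(curve: np.ndarray) -> DecayFit:
    """Fit N(x) = (y0 - plateau) * exp(-k*(x-1)) + plateau and test plateau=0.

    Anchored at x = 1 so y0 is the fitted N(1). The plateau (the predicted
    number of shared always-resident taxa for infinitely many subjects) is
    tested with a Wald t statistic, plateau / SE(plateau), on n-3 degrees
    of freedom. A constant curve leaves k unidentifiable; the fit is then
    flagged rather than fabricated.
    """
    y = np.asarray(curve, dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError("need >= 4 points (3 parameters + 1 df)")
    x = np.arange(1, n + 1, dtype=float)

    if np.ptp(y) == 0:  # constant: plateau = c, decay rate meaningless
        warnings.warn("constant core curve: decay rate unidentifiable")
        return DecayFit(y0=y[0], k=np.nan, plateau=y[0], r_squared=1.0,
                        plateau_se=np.nan, plateau_p=np.nan, identifiable=False)

    def model(x, y0, k, plateau):
        return (y0 - plateau) * np.exp(-k * (x - 1)) + plateau

    p0 = (y[0], 1.0, y[-1])
    try:
        popt, pcov = optimize.curve_fit(model, x, y, p0=p0, maxfev=20_000)
    except RuntimeError as exc:
        raise DecayFitError(f"decay fit did not converge (p0={p0})") from exc
    y0_hat, k_hat, plateau_hat = popt
    resid = y - model(x, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    se = float(np.sqrt(pcov[2, 2]))
    if not np.isfinite(se) or se == 0:
        warnings.warn("plateau standard error not estimable; flagging fit")
        return DecayFit(y0_hat, k_hat, plateau_hat, r2, np.nan, np.nan, False)
    t = plateau_hat / se
    p = 2 * stats.t.sf(abs(t), df=n - 3)
    return DecayFit(float(y0_hat), float(k_hat), float(plateau_hat), r2,
                    se, float(p), True)
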