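"""Culture-vs-sequencing diagnostic concordance and colony-sampling power.

Culture on selective medium is treated as the gold standard for whether a
family/genus is in a stool sample; sequence-based presence calls are the
diagnostic under evaluation. The power calculation answers how many
colonies must be picked per sample to detect a clone at a given relative
abundance: with n picks and per-pick event rate p, the chance of seeing at
least m events is a binomial (exact) or Poisson (rare-events, mean n*p)
tail probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ConfusionStats:
    """2x2 agreement of a diagnostic call against a gold standard.

    Undefined ratios (zero denominator) are None, never coerced to 0 or 1.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    ppv: float | None
    npv: float | None
    accuracy: float | None

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def concordance(seq_presence, culture_presence) -> ConfusionStats:
    """Confusion counts and predictive values, culture as gold standard."""
    seq = np.asarray(seq_presence, dtype=bool)
    cult = np.asarray(culture_presence, dtype=bool)
    if seq.shape != cult.shape:
        raise ValueError(
            f"length mismatch: {seq.shape} sequencing vs {cult.shape} culture"
        )
    tp = int((seq & cult).sum())
    fp = int((seq & ~cult).sum())
    fn = int((~seq & cult).sum())
    tn = int((~seq & ~cult).sum())

    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reported as missing")
            return None
        return num / den

    return ConfusionStats(
        tp, fp, fn, tn,
        ppv=ratio(tp, tp + fp, "PPV"),
        npv=ratio(tn, tn + fn, "NPV"),
        accuracy=ratio(tp + tn, tp + fp + fn + tn, "accuracy"),
    )


def detection_power(n_picks: int, event_rate: float, min_events: int = 1,
                    model: str = "binomial") -> float:
    """P(at least ``min_events`` occurrences among ``n_picks`` colonies).

    ``binomial`` is exact; ``poisson`` is the rare-events approximation
    with mean n_picks * event_rate. With the study's 84 picks per sample
    and a 2% clone, either model gives power > 0.8 for a single event.
    """
    if not 0.0 <= event_rate <= 1.0:
        raise ValueError("event_rate must be a probability in [0, 1]")
    if n_picks < 1:
        raise ValueError("n_picks must be >= 1")
    if min_events < 1:
        raise ValueError("min_events must be >= 1")
    if model == "binomial":
        return float(stats.binom.sf(min_events - 1, n_picks, event_rate))
    if model == "poisson":
        return float(stats.poisson.sf(min_events - 1, n_picks * event_rate))
    raise ValueError(f"unknown model {model!r}; use 'binomial' or 'poisson'")


def required_picks(target_power: float, event_rate: float, min_events: int = 1,
                   model: str = "binomial", n_max: int = 1_000_000) -> int:
    """Smallest number of colony picks reaching the target power."""
    if not 0.0 < target_power < 1.0:
        raise ValueError("target_power must be in (0, 1)")
    if event_rate <= 0.0:
        raise ValueError("power is unreachable with event_rate = 0")
    lo, hi = 1, 1
    while detection_power(hi, event_rate, min_events, model) < target_power:
        hi *= 2
        if hi > n_max:
            raise RuntimeError(f"no n <= {n_max} reaches power {target_power}")
    while lo < hi:  # power is monotone in n: bisect for the threshold
        mid = (lo + hi) // 2
        if detection_power(mid, event_rate, min_events, model) >= target_power:
            hi = mid
        else:
            lo = mid + 1
    return lo
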