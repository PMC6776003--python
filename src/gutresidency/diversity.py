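"""Community dissimilarity and diversity: Bray-Curtis, inverse Simpson,
consecutive-sample series, time trends, within/between-subject contrasts,
and the participant-wise Kruskal-Wallis + Dunn post-hoc comparison."""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import CountMatrix, validate_metadata


def bray_curtis(a: np.ndarray, b: np.ndarray) -> float:
    """Bray-Curtis dissimilarity, 1 - 2*sum(min)/(sum(a)+sum(b)), in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("count vectors must have equal length")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be non-negative")
    denom = a.sum() + b.sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(1.0 - 2.0 * np.minimum(a, b).sum() / denom)


def inverse_simpson(a: np.ndarray) -> float:
    """Inverse Simpson diversity 1 / sum(p_i^2); equals k for k even taxa."""
    a = np.asarray(a, dtype=float)
    total = a.sum()
    if total <= 0:
        raise ValueError("inverse Simpson undefined for an all-zero vector")
    p = a / total
    return float(1.0 / np.sum(p**2))


@dataclass(frozen=True)
class DissimilaritySeries:
    """Consecutive-sample Bray-Curtis values for one subject."""

    subject_id: str
    pairs: tuple[tuple[int, int, float], ...]  # (day_i, day_{i+1}, dissimilarity)

    @property
    def values(self) -> np.ndarray:
        return np.array([v for _, _, v in self.pairs])


def _subject_columns(m: CountMatrix, meta: pd.DataFrame, subject: str):
    meta = validate_metadata(meta)
    sub = meta[meta["subject_id"] == str(subject)].sort_values("day")
    if sub.empty:
        raise KeyError(f"subject {subject!r} not in metadata")
    have = set(m.sample_ids)
    sub = sub[sub["sample_id"].isin(have)]
    df = m.to_frame()
    days = sub["day"].tolist()
    cols = [df[s].to_numpy() for s in sub["sample_id"]]
    return days, cols


def consecutive_series(m: CountMatrix, meta: pd.DataFrame, subject: str) -> DissimilaritySeries:
    """Bray-Curtis between each pair of date-consecutive samples of a subject."""
    days, cols = _subject_columns(m, meta, subject)
    if len(days) < 2:
        raise ValueError(f"subject {subject!r} needs >= 2 samples")
    pairs = tuple(
        (int(days[i]), int(days[i + 1]), bray_curtis(cols[i], cols[i + 1]))
        for i in range(len(days) - 1)
    )
    return DissimilaritySeries(str(subject), pairs)


def beta_time_trend(m: CountMatrix, meta: pd.DataFrame, subject: str,
                    anchor_first: bool = False) -> tuple[float, float, float]:
    """Pearson correlation of Bray-Curtis dissimilarity with day lag.

    Default uses all sample pairs (lag = day difference); with
    ``anchor_first`` only first-sample-vs-later pairs are used. Returns
    (r, p, slope of the least-squares line).
    """
    days, cols = _subject_columns(m, meta, subject)
    if anchor_first:
        idx_pairs = [(0, j) for j in range(1, len(days))]
    else:
        idx_pairs = list(itertools.combinations(range(len(days)), 2))
    if len(idx_pairs) < 3:
        raise ValueError("need >= 3 sample pairs for a trend")
    lags = np.array([days[j] - days[i] for i, j in idx_pairs], dtype=float)
    dis = np.array([bray_curtis(cols[i], cols[j]) for i, j in idx_pairs])
    if np.ptp(lags) == 0:
        raise ValueError("zero variance in day lags")
    if np.ptp(dis) == 0:  # flat dissimilarity: no trend by construction
        return 0.0, 1.0, 0.0
    r, p = stats.pearsonr(lags, dis)
    slope = float(np.polyfit(lags, dis, 1)[0])
    return float(r), float(p), slope


def within_between_comparison(m: CountMatrix, meta: pd.DataFrame,
                              subject_a: str, subject_b: str
                              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Within-subject vs between-subject Bray-Curtis distributions.

    Pools all within-subject pairwise dissimilarities of the two subjects,
    contrasts them against all between-subject pairs with a two-sided
    Wilcoxon rank-sum test. Returns (within, between, p).
    """
    days_a, cols_a = _subject_columns(m, meta, subject_a)
    days_b, cols_b = _subject_columns(m, meta, subject_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("both subjects need >= 2 samples")
    within = np.array(
        [bray_curtis(x, y) for cols in (cols_a, cols_b)
         for x, y in itertools.combinations(cols, 2)]
    )
    between = np.array([bray_curtis(x, y) for x in cols_a for y in cols_b])
    if np.ptp(np.concatenate([within, between])) == 0:
        return within, between, 1.0  # identical distributions, nothing to test
    stat = stats.mannwhitneyu(within, between, alternative="two-sided")
    return within, between, float(stat.pvalue)


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn's post-hoc with compact letter display
# ---------------------------------------------------------------------------

def dunn_test(groups: dict[str, np.ndarray], method: str = "holm") -> pd.DataFrame:
    """Dunn's pairwise z-tests on pooled mid-ranks with tie correction.

    Returns a table of pairwise comparisons with raw and adjusted p-values
    (adjustment method as accepted by statsmodels ``multipletests``).
    """
    names = list(groups)
    pooled = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes, i0 = {}, {}, 0
    for g in names:
        n_g = len(groups[g])
        mean_ranks[g] = ranks[i0:i0 + n_g].mean()
        sizes[g] = n_g
        i0 += n_g
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for ga, gb in itertools.combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / sizes[ga] + 1.0 / sizes[gb]))
        z = (mean_ranks[ga] - mean_ranks[gb]) / se
        p = 2 * stats.norm.sf(abs(z))
        rows.append({"group_a": ga, "group_b": gb, "z": z, "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p_raw"], method=method)[1]
    return out


def compact_letter_display(names: list[str], pairs: pd.DataFrame,
                           alpha: float = 0.05,
                           order_by: dict[str, float] | None = None) -> dict[str, str]:
    """Assign letters so that groups share a letter iff not significantly different.

    Letters are the maximal cliques of the graph whose edges connect
    non-significant pairs, ordered by group means when provided.
    """
    g = nx.Graph()
    g.add_nodes_from(names)
    for _, row in pairs.iterrows():
        if row["p_adj"] >= alpha:
            g.add_edge(row["group_a"], row["group_b"])
    cliques = list(nx.find_cliques(g))
    if order_by:
        cliques.sort(key=lambda c: min(order_by.get(n, 0.0) for n in c))
    letters = {n: "" for n in names}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for i, clique in enumerate(cliques):
        for n in clique:
            letters[n] += alphabet[i % len(alphabet)]
    return {n: "".join(sorted(s)) for n, s in letters.items()}


def participant_dissimilarity_test(series: list[DissimilaritySeries],
                                   method: str = "holm",
                                   alpha: float = 0.05):
    """Do subjects differ in consecutive-sample turnover?

    Global Kruskal-Wallis on the consecutive Bray-Curtis distributions,
    Dunn's pairwise post-hoc with multiple-comparison correction, and a
    compact letter display (subjects sharing a letter are not
    significantly different). Returns (H, p, pairwise table, letters).
    """
    usable = [s for s in series if len(s.pairs) >= 2]
    if len(usable) < 2:
        raise ValueError("need >= 2 subjects with >= 2 consecutive pairs")
    groups = {s.subject_id: s.values for s in usable}
    h, p = stats.kruskal(*groups.values())
    pairs = dunn_test(groups, method=method)
    means = {g: float(np.mean(v)) for g, v in groups.items()}
    letters = compact_letter_display(list(groups), pairs, alpha=alpha, order_by=means)
    return float(h), float(p), pairs, letters
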