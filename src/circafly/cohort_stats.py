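"""Cohort-level rhythm summaries and the study's statistical toolkit.

Covers: percentage rhythmicity per genotype per age window with the
n < 10 exclusion rule, arcsine-square-root aggregation of rhythmicity
across runs, Fisher exact tests (2x2 exact; m x n by Monte-Carlo with
fixed margins), Benjamini-Hochberg step-up FDR control, Cochran Q and
McNemar tests for repeated dichotomous rhythmicity, two-sample
Kolmogorov-Smirnov comparisons of LNv-count distributions, and thin
delegation to standard rank tests (Kruskal-Wallis, Friedman, Wilcoxon).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .dam_io import AgeWindow
from .periodogram import RhythmCall

logger = logging.getLogger(__name__)


class DegenerateTableError(ValueError):
    """Contingency table with an all-zero row or column."""


# ---------------------------------------------------------------------------
# Window summaries and run aggregation


@dataclass
class WindowSummary:
    """Rhythmicity of one genotype in one age window.

    ``excluded`` marks groups that the study's practice removes from
    between-genotype period/robustness statistics: fewer than ``min_n``
    flies alive through the window, or fewer than ``min_n`` rhythmic
    flies. Excluded groups still carry their summary numbers.
    """

    genotype: str
    run_id: str
    window_label: str
    n_alive: int
    n_rhythmic: int
    pct_rhythmic: float
    excluded: bool
    exclusion_reason: Optional[str] = None


def summarize_window(
    calls: Sequence[RhythmCall],
    death_days: Mapping[str, Optional[float]],
    window: AgeWindow,
    min_n: int = 10,
) -> list[WindowSummary]:
    """Percentage rhythmicity per genotype among flies alive through a window.

    A fly counts as alive if its death day is unknown or later than the
    window's last day. Groups with ``n_alive < min_n`` (or with fewer
    than ``min_n`` rhythmic flies) are flagged excluded for downstream
    period/robustness comparisons.
    """
    window_calls = [c for c in calls if c.window_label == window.label]
    if not window_calls:
        logger.warning("summarize_window: no calls for window %s", window.label)
        return []
    out = []
    for (genotype, run_id), group in _group_by(window_calls):
        alive = [
            c
            for c in group
            if death_days.get(c.fly_id) is None or death_days[c.fly_id] > window.end_day
        ]
        n_alive = len(alive)
        n_rhythmic = sum(1 for c in alive if c.effective_rhythmic)
        pct = 100.0 * n_rhythmic / n_alive if n_alive else float("nan")
        excluded, reason = False, None
        if n_alive < min_n:
            excluded, reason = True, f"n<{min_n}"
        elif n_rhythmic < min_n:
            excluded, reason = True, f"n_rhythmic<{min_n}"
        out.append(
            WindowSummary(
                genotype=genotype,
                run_id=run_id,
                window_label=window.label,
                n_alive=n_alive,
                n_rhythmic=n_rhythmic,
                pct_rhythmic=pct,
                excluded=excluded,
                exclusion_reason=reason,
            )
        )
    return out


def _group_by(calls: Sequence[RhythmCall]):
    keys = sorted({(c.genotype, c.run_id) for c in calls})
    for key in keys:
        yield key, [c for c in calls if (c.genotype, c.run_id) == key]


@dataclass
class RunAggregate:
    """Mean rhythmicity over independent runs, with the arcsine transform
    used before repeated-measures testing."""

    mean_pct: float
    sem_pct: Optional[float]
    transformed: np.ndarray  # arcsin(sqrt(p/100)) per run, radians


def aggregate_runs(pct_rhythmic: Sequence[float]) -> RunAggregate:
    p = np.asarray(pct_rhythmic, dtype=float)
    if p.size == 0:
        raise ValueError("at least one run is required")
    if np.any((p < 0) | (p > 100)):
        raise ValueError("percentages must lie in [0, 100]")
    sem = float(p.std(ddof=1) / math.sqrt(p.size)) if p.size > 1 else None
    return RunAggregate(
        mean_pct=float(p.mean()),
        sem_pct=sem,
        transformed=np.arcsin(np.sqrt(p / 100.0)),
    )


# ---------------------------------------------------------------------------
# Fisher exact tests


@dataclass
class FisherResult:
    p_value: float
    method: str  # "exact" or "monte_carlo"
    mc_se: float = 0.0
    n_mc: int = 0


def fisher_mxn(
    table,
    n_mc: int = 100_000,
    seed: Optional[int] = None,
    force_mc: bool = False,
) -> FisherResult:
    """Two-sided Fisher exact test for an m x n contingency table.

    Uses the probability-ordering criterion: the p-value is the total
    probability, under fixed margins, of tables whose point probability
    does not exceed that of the observed table. 2x2 tables are computed
    exactly (hypergeometric); larger tables by Monte-Carlo sampling of
    tables with the observed margins (label permutation), reporting the
    binomial standard error of the estimate.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (t < 0).any():
        raise ValueError("cell counts must be non-negative")
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    if (row_sums == 0).any() or (col_sums == 0).any():
        raise DegenerateTableError("table has an all-zero row or column")
    if n_mc < 10_000:
        raise ValueError("n_mc must be at least 10000")

    if t.shape == (2, 2) and not force_mc:
        _, p = stats.fisher_exact(t, alternative="two-sided")
        return FisherResult(p_value=float(min(p, 1.0)), method="exact")

    rng = np.random.default_rng(seed)
    n_total = int(t.sum())
    row_labels = np.repeat(np.arange(t.shape[0]), row_sums)
    col_labels = np.repeat(np.arange(t.shape[1]), col_sums)
    # point probability ranking reduces to sum of log-factorials of cells
    obs_stat = gammaln(t + 1).sum()
    n_cells = t.shape[0] * t.shape[1]
    flat_obs_index = row_labels * t.shape[1]  # reused below per permutation
    hits = 0
    batch = max(1, min(2000, n_mc))
    done = 0
    while done < n_mc:
        b = min(batch, n_mc - done)
        perms = rng.permuted(np.tile(col_labels, (b, 1)), axis=1)
        flat = flat_obs_index[None, :] + perms
        counts = np.zeros((b, n_cells), dtype=np.int64)
        for i in range(b):
            counts[i] = np.bincount(flat[i], minlength=n_cells)
        sim_stat = gammaln(counts + 1).sum(axis=1)
        # P(table) <= P(obs)  <=>  sum log n_ij! >= observed sum
        hits += int((sim_stat >= obs_stat - 1e-7).sum())
        done += b
    p = (hits + 1) / (n_mc + 1)
    se = math.sqrt(p * (1 - p) / n_mc)
    return FisherResult(p_value=float(min(p, 1.0)), method="monte_carlo", mc_se=se, n_mc=n_mc)


# ---------------------------------------------------------------------------
# Multiple testing


def bh_adjust(p_values: Sequence[float], fdr: float = 0.05):
    """Benjamini-Hochberg step-up adjusted p-values and rejection flags.

    ``adj_(i) = min_{j >= i} (m * p_(j) / j)`` on the ascending sort,
    capped at 1; a hypothesis is rejected when its adjusted p is at most
    ``fdr``.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj, adj <= fdr


def bonferroni(p_value: float, n_comparisons: int) -> float:
    """Bonferroni-corrected p for a planned family of comparisons."""
    return float(min(1.0, p_value * n_comparisons))


# ---------------------------------------------------------------------------
# Repeated dichotomous rhythmicity


@dataclass
class QTestResult:
    statistic: Optional[float]
    p_value: Optional[float]
    df: Optional[int] = None
    note: Optional[str] = None


def cochran_q(binary_matrix) -> QTestResult:
    """Cochran Q test across k related binary conditions (flies x windows).

    Rows with any missing value are dropped (complete cases only). With
    column totals C_j, row totals R_i and grand total N::

        Q = (k - 1) * (k * sum C_j^2 - N^2) / (k * N - sum R_i^2)

    Q is compared to chi-square with k-1 degrees of freedom. When every
    row is all-success or all-failure the statistic is undefined and a
    missing result with a note is returned. With k = 2 conditions, Q
    equals the McNemar statistic without continuity correction.
    """
    x = np.asarray(binary_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a flies x windows matrix with at least 2 windows")
    x = x[~np.isnan(x).any(axis=1)]
    if x.shape[0] == 0:
        return QTestResult(None, None, note="no complete cases")
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError("matrix entries must be 0/1 (or NaN for missing)")
    k = x.shape[1]
    col = x.sum(axis=0)
    row = x.sum(axis=1)
    n_total = x.sum()
    denom = k * n_total - (row**2).sum()
    if denom == 0:
        return QTestResult(None, None, note="all rows constant; Q undefined")
    q = (k - 1) * (k * (col**2).sum() - n_total**2) / denom
    p = float(stats.chi2.sf(q, k - 1))
    return QTestResult(float(q), p, df=k - 1)


def mcnemar(b_discordant: int, c_discordant: int, continuity: bool = False) -> QTestResult:
    """McNemar chi-square test on the two discordant cell counts.

    ``chi2 = (b - c)^2 / (b + c)``; with the continuity correction, 1 is
    subtracted from ``|b - c|`` before squaring. Undefined (missing, with
    a note) when there are no discordant pairs.
    """
    b, c = int(b_discordant), int(c_discordant)
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    if b + c == 0:
        return QTestResult(None, None, note="no discordant pairs; statistic undefined")
    diff = abs(b - c) - 1 if continuity else b - c
    diff = max(diff, 0) if continuity else diff
    statistic = diff**2 / (b + c)
    return QTestResult(float(statistic), float(stats.chi2.sf(statistic, 1)), df=1)


# ---------------------------------------------------------------------------
# LNv count distributions


@dataclass
class KSResult:
    d_statistic: float
    p_value: float
    note: str = (
        "two-sample KS on discrete 0-5 counts; the asymptotic p-value is conservative"
    )


def ks_two_sample(counts_a: Sequence[int], counts_b: Sequence[int]) -> KSResult:
    """Two-sample Kolmogorov-Smirnov comparison of per-hemisphere LNv counts.

    D is the maximum ECDF difference over the 0-5 support; the p-value is
    the asymptotic two-sample value. Combine with :func:`bonferroni` for
    a planned family of pairwise comparisons.
    """
    a = np.asarray(counts_a)
    b = np.asarray(counts_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return KSResult(float(res.statistic), float(min(res.pvalue, 1.0)))


def lnv_count_proportions(counts: Sequence[int]) -> np.ndarray:
    """Proportion of hemispheres with 0..5 LNv, as a length-6 vector."""
    c = np.asarray(counts, dtype=int)
    if c.size == 0:
        raise ValueError("no hemisphere counts supplied")
    if np.any((c < 0) | (c > 5)):
        raise ValueError("LNv counts must lie in 0..5")
    return np.bincount(c, minlength=6) / c.size


# ---------------------------------------------------------------------------
# Delegated rank tests


@dataclass
class RankTestReport:
    method: str
    statistic: float
    p_value: float
    posthoc: Optional[pd.DataFrame] = None
    metadata: dict = field(default_factory=dict)


def rank_test_suite(
    values_by_group: Mapping[str, Sequence[float]],
    design: str = "independent",
    correction: str = "bh",
    fdr: float = 0.05,
) -> RankTestReport:
    """Delegated omnibus rank test plus pairwise post-hoc comparisons.

    ``design="independent"`` runs Kruskal-Wallis with Dunn-type mean-rank
    pairwise z tests; ``design="repeated"`` runs Friedman with pairwise
    Wilcoxon matched-pairs tests (groups must be equal-length, paired by
    position). ``correction`` is ``"bh"`` or ``"bonferroni"`` on the
    pairwise p-values. The method names are recorded in the report
    metadata so downstream tables state exactly what was run.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    names = list(groups)
    if design == "independent":
        stat, p = stats.kruskal(*groups.values())
        posthoc = _dunn_mean_rank(groups)
        method = "kruskal-wallis + dunn-mean-rank"
    elif design == "repeated":
        lengths = {len(v) for v in groups.values()}
        if len(lengths) != 1:
            raise ValueError("repeated design requires equal-length paired groups")
        stat, p = stats.friedmanchisquare(*groups.values())
        rows = []
        for a, b in combinations(names, 2):
            res = stats.wilcoxon(groups[a], groups[b], zero_method="wilcox")
            rows.append({"group_a": a, "group_b": b, "p_raw": float(res.pvalue)})
        posthoc = pd.DataFrame(rows)
        method = "friedman + wilcoxon-matched-pairs"
    else:
        raise ValueError(f"unknown design {design!r}")

    if correction == "bh":
        adj, reject = bh_adjust(posthoc["p_raw"].to_numpy(), fdr=fdr)
    elif correction == "bonferroni":
        adj = np.minimum(posthoc["p_raw"].to_numpy() * len(posthoc), 1.0)
        reject = adj <= fdr
    else:
        raise ValueError(f"unknown correction {correction!r}")
    posthoc = posthoc.assign(p_adjusted=adj, reject=reject)
    return RankTestReport(
        method=method,
        statistic=float(stat),
        p_value=float(p),
        posthoc=posthoc,
        metadata={"correction": correction, "fdr": fdr},
    )


def _dunn_mean_rank(groups: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's multiple comparisons of mean ranks with tie correction."""
    pooled = np.concatenate(list(groups.values()))
    ranks = stats.rankdata(pooled)
    n = pooled.size
    mean_ranks, sizes = {}, {}
    start = 0
    for name, vals in groups.items():
        mean_ranks[name] = ranks[start : start + vals.size].mean()
        sizes[name] = vals.size
        start += vals.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1)) if n > 1 else 0.0
    variance_base = n * (n + 1) / 12.0 - tie_term
    rows = []
    for a, b in combinations(groups, 2):
        se = math.sqrt(variance_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        if se == 0:
            z, p_raw = 0.0, 1.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p_raw = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": min(p_raw, 1.0)})
    return pd.DataFrame(rows)
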