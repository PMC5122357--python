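"""Paired pre/post-treatment repertoire comparison.

Clonotype turnover (shared / gained / lost by (V, J, junction) identity),
per-clonotype fold changes with a detection-limit pseudo-floor for clones
absent on one side, diversity deltas, V/J usage shifts, and a Mann-Whitney
rank-sum test (exact enumeration for small groups, normal approximation
with tie correction otherwise) for cross-sample group comparisons.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import ClonotypeTable
from .germline import NUCLEOTIDES
from .metrics import (
    MarkerBias,
    MetricsError,
    RepertoireSummary,
    clonotype_frequencies,
    marker_bias,
    summarize,
    usage_matrix,
)

#: combined sample size up to which the rank-sum test enumerates exactly
EXACT_RANK_SUM_LIMIT = 12

ClonotypeKey = tuple[str, str, str]


class ComparisonError(ValueError):
    """Invalid input to a paired comparison."""


# ---------------------------------------------------------------------------
# Turnover
# ---------------------------------------------------------------------------

def _check_nt_keys(table: ClonotypeTable) -> None:
    nts = set(NUCLEOTIDES)
    for c in table.clonotypes:
        if not nts.issuperset(c.junction_nt):
            raise ComparisonError(
                f"{table.sample_id}: junction {c.junction_nt!r} is not a nucleotide "
                "sequence; pre/post tables must share the nucleotide-level key convention"
            )


def overlap_partition(
    pre: ClonotypeTable, post: ClonotypeTable
) -> tuple[set[ClonotypeKey], set[ClonotypeKey], set[ClonotypeKey]]:
    """(shared, gained, lost) clonotype-key sets between two timepoints."""
    if not pre.clonotypes or not post.clonotypes:
        raise ComparisonError("both tables must be non-empty")
    _check_nt_keys(pre)
    _check_nt_keys(post)
    pre_keys = {c.key for c in pre.clonotypes}
    post_keys = {c.key for c in post.clonotypes}
    return pre_keys & post_keys, post_keys - pre_keys, pre_keys - post_keys


# ---------------------------------------------------------------------------
# Fold changes
# ---------------------------------------------------------------------------

def fold_changes(
    pre: ClonotypeTable,
    post: ClonotypeTable,
    pseudo: float | None = None,
    productive_only: bool = True,
) -> pd.DataFrame:
    """Per-clonotype frequency fold changes (post / pre).

    Clones absent on one side have that side's frequency floored at
    ``pseudo`` (default: 1/assigned_reads of the sample in which they are
    absent, the one-read detection limit) and are flagged ``censored``.
    Columns: v_call, j_call, junction, pre_freq, post_freq, fold, status,
    censored; sorted by descending fold.
    """
    if pseudo is not None and pseudo <= 0:
        raise ComparisonError("pseudo floor must be > 0")
    pre_f, pre_clones = clonotype_frequencies(pre, productive_only)
    post_f, post_clones = clonotype_frequencies(post, productive_only)
    pre_map = {c.key: f for c, f in zip(pre_clones, pre_f)}
    post_map = {c.key: f for c, f in zip(post_clones, post_f)}
    pre_floor = pseudo if pseudo is not None else 1.0 / pre.assigned_reads
    post_floor = pseudo if pseudo is not None else 1.0 / post.assigned_reads

    rows = []
    for key in sorted(set(pre_map) | set(post_map)):
        in_pre, in_post = key in pre_map, key in post_map
        status = "shared" if in_pre and in_post else ("gained" if in_post else "lost")
        p0 = pre_map.get(key, pre_floor)
        p1 = post_map.get(key, post_floor)
        rows.append(
            {
                "v_call": key[0],
                "j_call": key[1],
                "junction": key[2],
                "pre_freq": p0,
                "post_freq": p1,
                "fold": p1 / p0,
                "status": status,
                "censored": status != "shared",
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["fold", "v_call", "j_call", "junction"], ascending=[False, True, True, True]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Diversity deltas
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiversityDelta:
    """post - pre diversity differences (and post/pre ratios)."""

    d_inverse_simpson: float
    d_shannon: float
    inverse_simpson_ratio: float
    shannon_ratio: float


def diversity_delta(
    pre_summary: RepertoireSummary, post_summary: RepertoireSummary
) -> DiversityDelta:
    return DiversityDelta(
        d_inverse_simpson=post_summary.inverse_simpson - pre_summary.inverse_simpson,
        d_shannon=post_summary.shannon - pre_summary.shannon,
        inverse_simpson_ratio=post_summary.inverse_simpson / pre_summary.inverse_simpson,
        shannon_ratio=(
            post_summary.shannon / pre_summary.shannon
            if pre_summary.shannon != 0
            else math.inf
        ),
    )


# ---------------------------------------------------------------------------
# Mann-Whitney rank-sum test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankSumResult:
    p_value: float
    u_statistic: float
    method: str  # "exact" or "normal"
    degenerate: bool  # all pooled values identical


def _u_statistic(ranks: np.ndarray, idx: Sequence[int], n_a: int) -> float:
    return float(ranks[list(idx)].sum() - n_a * (n_a + 1) / 2.0)


def rank_sum_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> RankSumResult:
    """Two-sided Mann-Whitney U test.

    For combined n <= 12 the null distribution of U is enumerated exactly
    over all C(n, n_a) relabelings of the pooled observations (midranks, so
    ties are handled); larger samples use the normal approximation with tie
    correction and continuity correction.  Deterministic.  When every pooled
    value is identical the test is degenerate and p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ComparisonError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    n, n_a, n_b = pooled.size, a.size, b.size
    ranks = stats.rankdata(pooled)
    u_obs = _u_statistic(ranks, range(n_a), n_a)

    if np.ptp(pooled) == 0.0:
        return RankSumResult(p_value=1.0, u_statistic=u_obs, method="exact", degenerate=True)

    mu = n_a * n_b / 2.0
    if n <= EXACT_RANK_SUM_LIMIT:
        dev_obs = abs(u_obs - mu)
        hits = 0
        total = 0
        for idx in itertools.combinations(range(n), n_a):
            total += 1
            if abs(_u_statistic(ranks, idx, n_a) - mu) >= dev_obs - 1e-12:
                hits += 1
        return RankSumResult(
            p_value=hits / total, u_statistic=u_obs, method="exact", degenerate=False
        )
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return RankSumResult(
        p_value=float(res.pvalue), u_statistic=u_obs, method="normal", degenerate=False
    )


# ---------------------------------------------------------------------------
# Full paired comparison
# ---------------------------------------------------------------------------

@dataclass
class PairedComparison:
    """Everything one pre/post pair yields."""

    subject_id: str
    shared: set[ClonotypeKey]
    gained: set[ClonotypeKey]
    lost: set[ClonotypeKey]
    fold_table: pd.DataFrame
    pre_summary: RepertoireSummary
    post_summary: RepertoireSummary
    diversity: DiversityDelta
    v_usage_shift: pd.Series  # post - pre V marginal usage
    j_usage_shift: pd.Series
    marker_bias_delta: float | None  # None when undefined on either side
    highest_expansion: dict | None  # argmax fold among shared clones
    highest_expansion_censored: dict | None  # argmax fold among gained clones


def _top_fold_row(df: pd.DataFrame, status: str) -> dict | None:
    sub = df[df["status"] == status]
    if sub.empty:
        return None
    return sub.iloc[0].to_dict()  # df is sorted by descending fold


def compare_repertoires(
    pre: ClonotypeTable,
    post: ClonotypeTable,
    subject_id: str | None = None,
    productive_only: bool = True,
    pseudo: float | None = None,
    thresholds: Sequence[float] = (0.01,),
    top_ns: Sequence[int] = (10,),
) -> PairedComparison:
    """Full paired comparison of one subject's pre and post repertoires."""
    shared, gained, lost = overlap_partition(pre, post)
    folds = fold_changes(pre, post, pseudo=pseudo, productive_only=productive_only)
    pre_summary = summarize(pre, productive_only, thresholds, top_ns)
    post_summary = summarize(post, productive_only, thresholds, top_ns)

    pre_usage = usage_matrix(pre, productive_only)
    post_usage = usage_matrix(post, productive_only)
    v_shift = post_usage.v_usage.sub(pre_usage.v_usage, fill_value=0.0).sort_index()
    j_shift = post_usage.j_usage.sub(pre_usage.j_usage, fill_value=0.0).sort_index()

    bias_delta: float | None
    try:
        pre_bias: MarkerBias = marker_bias(pre_usage)
        post_bias: MarkerBias = marker_bias(post_usage)
        bias_delta = (
            post_bias.value - pre_bias.value
            if pre_bias.defined and post_bias.defined
            else None
        )
    except MetricsError:
        bias_delta = None  # marker genes outside this reference's gene space

    return PairedComparison(
        subject_id=subject_id or f"{pre.sample_id}_vs_{post.sample_id}",
        shared=shared,
        gained=gained,
        lost=lost,
        fold_table=folds,
        pre_summary=pre_summary,
        post_summary=post_summary,
        diversity=diversity_delta(pre_summary, post_summary),
        v_usage_shift=v_shift,
        j_usage_shift=j_shift,
        marker_bias_delta=bias_delta,
        highest_expansion=_top_fold_row(folds, "shared"),
        highest_expansion_censored=_top_fold_row(folds, "gained"),
    )
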