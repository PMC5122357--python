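"""Per-sample repertoire statistics.

Clonotype frequencies are read-weighted (fractions of assigned reads) and by
default computed over productive clonotypes only.  Diversity is quantified
by the plug-in inverse Simpson index 1/Ds = 1/sum(p_i^2), which ranges from
1 (monoclonal) to the clone count (perfectly even), and the Shannon entropy
H = -sum(p_i ln p_i) in natural log units.  Spectratypes are read-weighted
CDR3 nucleotide length histograms; V-J usage matrices are read-weighted
joint frequencies with V and J marginals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .calling import Clonotype, ClonotypeTable
from .germline import SegmentSet

#: V genes reported as CD4-characteristic vs CD8-characteristic
CD4_MARKER_GENES = ("TRBV5-4", "TRBV7-2", "TRBV18")
CD8_MARKER_GENE = "TRBV7-9"

_FREQ_TOL = 1e-8


class MetricsError(ValueError):
    """Invalid input to a repertoire metric."""


def _as_frequencies(p: Sequence[float] | np.ndarray) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        raise MetricsError("empty frequency vector")
    if np.any(arr < 0):
        raise MetricsError("frequencies must be non-negative")
    if abs(arr.sum() - 1.0) > _FREQ_TOL:
        raise MetricsError(f"frequencies sum to {arr.sum()!r}, expected 1")
    return arr


# ---------------------------------------------------------------------------
# Frequencies
# ---------------------------------------------------------------------------

def clonotype_frequencies(
    table: ClonotypeTable, productive_only: bool = True
) -> tuple[np.ndarray, list[Clonotype]]:
    """Descending read-fraction vector plus the matching clone order.

    Ties in count break stably by (v_call, j_call, junction_nt).
    """
    clones = [c for c in table.clonotypes if c.productive or not productive_only]
    total = sum(c.read_count for c in clones)
    if total == 0:
        raise MetricsError(
            f"{table.sample_id}: no {'productive ' if productive_only else ''}reads selected"
        )
    clones.sort(key=lambda c: (-c.read_count, c.key))
    freqs = np.array([c.read_count for c in clones], dtype=float) / total
    return freqs, clones


# ---------------------------------------------------------------------------
# Diversity indices
# ---------------------------------------------------------------------------

def inverse_simpson(p: Sequence[float] | np.ndarray) -> float:
    """Plug-in inverse Simpson diversity 1 / sum(p_i^2)."""
    arr = _as_frequencies(p)
    return float(1.0 / np.sum(arr * arr))


def inverse_simpson_unbiased(counts: Sequence[int] | np.ndarray) -> float:
    """Bias-corrected inverse Simpson from integer counts.

    Uses the unbiased estimator of sum(p^2), sum n_i(n_i-1) / (N(N-1)).
    """
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0:
        raise MetricsError("empty count vector")
    total = arr.sum()
    if total < 2:
        raise MetricsError("bias-corrected Simpson requires at least 2 reads")
    ds = np.sum(arr * (arr - 1.0)) / (total * (total - 1.0))
    if ds == 0:
        return math.inf
    return float(1.0 / ds)


def shannon(p: Sequence[float] | np.ndarray) -> float:
    """Shannon entropy H = -sum(p_i ln p_i), natural log; 0 ln 0 := 0."""
    arr = _as_frequencies(p)
    nz = arr[arr > 0]
    return float(-np.sum(nz * np.log(nz)))


def top_n_cumulative(p: Sequence[float] | np.ndarray, n: int) -> float:
    """Cumulative frequency of the n most abundant clones."""
    if n < 1:
        raise MetricsError("n must be >= 1")
    arr = np.sort(_as_frequencies(p))[::-1]
    return float(arr[:n].sum())


def clones_above_threshold(
    p: Sequence[float] | np.ndarray, threshold: float
) -> tuple[int, float]:
    """(count, cumulative frequency) of clones strictly above ``threshold``."""
    if not (0.0 < threshold < 1.0):
        raise MetricsError("threshold must lie in (0, 1)")
    arr = _as_frequencies(p)
    mask = arr > threshold
    return int(mask.sum()), float(arr[mask].sum())


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------

@dataclass
class RepertoireSummary:
    """Diversity and clonality statistics for one sample."""

    sample_id: str
    n_unique_clonotypes: int
    frequencies: np.ndarray  # descending
    inverse_simpson: float
    shannon: float
    exp_shannon: float  # e^H, a base-free effective clone count
    top_n_cumulative: dict[int, float]
    above_threshold: dict[float, tuple[int, float]]
    max_clone_freq: float
    productive_only: bool = True

    def to_records(self) -> list[tuple[str, float]]:
        rows: list[tuple[str, float]] = [
            ("n_unique_clonotypes", float(self.n_unique_clonotypes)),
            ("inverse_simpson", self.inverse_simpson),
            ("shannon", self.shannon),
            ("exp_shannon", self.exp_shannon),
            ("max_clone_freq", self.max_clone_freq),
        ]
        for n, cum in sorted(self.top_n_cumulative.items()):
            rows.append((f"top{n}_cumulative_freq", cum))
        for theta, (count, cum) in sorted(self.above_threshold.items()):
            rows.append((f"clones_above_{theta:g}", float(count)))
            rows.append((f"clones_above_{theta:g}_cumulative_freq", cum))
        return rows


def summarize(
    table: ClonotypeTable,
    productive_only: bool = True,
    thresholds: Sequence[float] = (0.01,),
    top_ns: Sequence[int] = (10,),
) -> RepertoireSummary:
    """Compute the full :class:`RepertoireSummary` for one sample."""
    freqs, _clones = clonotype_frequencies(table, productive_only)
    h = shannon(freqs)
    return RepertoireSummary(
        sample_id=table.sample_id,
        n_unique_clonotypes=freqs.size,
        frequencies=freqs,
        inverse_simpson=inverse_simpson(freqs),
        shannon=h,
        exp_shannon=math.exp(h),
        top_n_cumulative={int(n): top_n_cumulative(freqs, int(n)) for n in top_ns},
        above_threshold={float(t): clones_above_threshold(freqs, float(t)) for t in thresholds},
        max_clone_freq=float(freqs[0]),
        productive_only=productive_only,
    )


# ---------------------------------------------------------------------------
# Spectratype
# ---------------------------------------------------------------------------

@dataclass
class SpectratypeProfile:
    """CDR3 nucleotide length distribution of one sample."""

    sample_id: str
    fractions: dict[int, float]  # length -> fraction, sums to 1
    modal_length: int
    productive_only: bool
    weight: str  # "reads" or "clones"

    def mass_between(self, lo: int, hi: int) -> float:
        """Total fraction on lengths in [lo, hi] inclusive."""
        return sum(f for length, f in self.fractions.items() if lo <= length <= hi)

    def to_frame(self) -> pd.DataFrame:
        lengths = sorted(self.fractions)
        return pd.DataFrame(
            {"length": lengths, "fraction": [self.fractions[l] for l in lengths]}
        )


def spectratype(
    table: ClonotypeTable, productive_only: bool = True, weight: str = "reads"
) -> SpectratypeProfile:
    """CDR3 length histogram, read-weighted by default.

    ``weight="clones"`` counts each unique clonotype once, the convention of
    classic electrophoretic spectratyping.
    """
    if weight not in ("reads", "clones"):
        raise MetricsError(f"unknown weight {weight!r}")
    clones = [c for c in table.clonotypes if c.productive or not productive_only]
    if not clones:
        raise MetricsError(f"{table.sample_id}: no clonotypes selected")
    masses: dict[int, float] = {}
    for c in clones:
        w = c.read_count if weight == "reads" else 1
        masses[len(c.junction_nt)] = masses.get(len(c.junction_nt), 0.0) + w
    total = sum(masses.values())
    fractions = {length: m / total for length, m in sorted(masses.items())}
    modal = max(fractions, key=lambda length: (fractions[length], -length))
    return SpectratypeProfile(
        sample_id=table.sample_id,
        fractions=fractions,
        modal_length=modal,
        productive_only=productive_only,
        weight=weight,
    )


# ---------------------------------------------------------------------------
# V-J usage
# ---------------------------------------------------------------------------

@dataclass
class UsageMatrix:
    """Read-weighted V x J combination frequencies with marginals."""

    sample_id: str
    matrix: pd.DataFrame  # V genes as rows, J genes as columns; sums to 1
    v_usage: pd.Series = field(init=False)
    j_usage: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.v_usage = self.matrix.sum(axis=1)
        self.j_usage = self.matrix.sum(axis=0)


def usage_matrix(
    table: ClonotypeTable,
    productive_only: bool = True,
    segment_set: SegmentSet | None = None,
) -> UsageMatrix:
    """V x J read-fraction matrix.

    With ``segment_set`` the row/column space is the full reference gene
    space (absent combinations are 0); otherwise only observed genes appear.
    """
    clones = [c for c in table.clonotypes if c.productive or not productive_only]
    if not clones:
        raise MetricsError(f"{table.sample_id}: no clonotypes selected")
    df = pd.DataFrame(
        {
            "v_call": [c.v_call for c in clones],
            "j_call": [c.j_call for c in clones],
            "count": [c.read_count for c in clones],
        }
    )
    pivot = df.pivot_table(
        index="v_call", columns="j_call", values="count", aggfunc="sum", fill_value=0
    ).astype(float)
    if segment_set is not None:
        v_space = [s.segment_id for s in segment_set.v_segments]
        j_space = [s.segment_id for s in segment_set.j_segments]
        pivot = pivot.reindex(index=v_space, columns=j_space, fill_value=0.0)
    pivot /= pivot.values.sum()
    pivot = pivot.sort_index(axis=0).sort_index(axis=1)
    return UsageMatrix(sample_id=table.sample_id, matrix=pivot)


@dataclass(frozen=True)
class MarkerBias:
    """CD4/CD8 V-gene bias: (fV5-4 + fV7-2 + fV18) / fV7-9."""

    value: float
    defined: bool  # False when the CD8 marker has zero usage


def marker_bias(usage: UsageMatrix) -> MarkerBias:
    """CD4-vs-CD8 characteristic V-gene usage ratio.

    Raises :class:`MetricsError` naming any marker gene absent from the
    matrix's gene space; a present-but-unused CD8 marker yields a flagged
    undefined result (NaN), not an exception.
    """
    needed = (*CD4_MARKER_GENES, CD8_MARKER_GENE)
    missing = [g for g in needed if g not in usage.v_usage.index]
    if missing:
        raise MetricsError(f"marker genes missing from gene space: {', '.join(missing)}")
    cd8 = float(usage.v_usage[CD8_MARKER_GENE])
    cd4 = float(sum(usage.v_usage[g] for g in CD4_MARKER_GENES))
    if cd8 == 0.0:
        return MarkerBias(value=math.nan, defined=False)
    return MarkerBias(value=cd4 / cd8, defined=True)
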