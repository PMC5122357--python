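"""CDR3 junction calling: V/J assignment, anchor-bounded junction extraction,
productivity classification, and aggregation of reads into clonotypes.

The junction (CDR3 nucleotide sequence) runs from the first base of the V
segment's second conserved cysteine codon through the last base of the J
segment's conserved phenylalanine codon, both codons included.  A clonotype
is a unique (V gene, J gene, junction nucleotide sequence) triple; amino-acid
level grouping is a view, not the key.

Segment assignment is exact-seed + ungapped extension: k-mer seeds vote for
an alignment diagonal, the best diagonal is rescored base-by-base, and a
candidate is accepted only if its longest contiguous run of matching bases
reaches a minimum (default 20 for V, 12 for J).  Ties are broken by
lexicographically smaller segment_id.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .germline import (
    CODON_TABLE,
    GermlineSegment,
    SegmentSet,
    STOP_SYMBOL,
    translate_nt,
)

logger = logging.getLogger(__name__)

#: minimum contiguous matching bases for an accepted segment call
MIN_V_MATCH_RUN = 20
MIN_J_MATCH_RUN = 12
#: seed k-mer sizes
V_SEED_K = 12
J_SEED_K = 8


class CallerError(ValueError):
    """Invalid input to the clonotype caller."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Clonotype:
    """A unique (v_call, j_call, junction_nt) with its read support."""

    v_call: str
    j_call: str
    junction_nt: str
    junction_aa: str | None
    productive: bool
    read_count: int

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise CallerError(f"clonotype {self.key}: read_count must be >= 1")
        if self.productive:
            if len(self.junction_nt) % 3:
                raise CallerError(f"clonotype {self.key}: productive but out of frame")
            aa = self.junction_aa
            if aa is None or not aa.startswith("C") or not aa.endswith("F") or STOP_SYMBOL in aa:
                raise CallerError(
                    f"clonotype {self.key}: productive junction must translate C...F without stops"
                )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.v_call, self.j_call, self.junction_nt)


@dataclass
class ClonotypeTable:
    """One sample's clonotypes plus read-accounting totals."""

    sample_id: str
    clonotypes: list[Clonotype]
    total_reads: int
    assigned_reads: int
    unassigned_reads: int
    attrition: dict[str, int] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        counted = sum(c.read_count for c in self.clonotypes)
        if counted != self.assigned_reads:
            raise CallerError(
                f"{self.sample_id}: clonotype counts sum to {counted}, "
                f"assigned_reads is {self.assigned_reads}"
            )
        if self.assigned_reads + self.unassigned_reads != self.total_reads:
            raise CallerError(
                f"{self.sample_id}: assigned ({self.assigned_reads}) + unassigned "
                f"({self.unassigned_reads}) != total ({self.total_reads})"
            )
        keys = [c.key for c in self.clonotypes]
        if len(set(keys)) != len(keys):
            raise CallerError(f"{self.sample_id}: duplicate clonotype keys")

    def __len__(self) -> int:
        return len(self.clonotypes)

    def counts_by_key(self) -> dict[tuple[str, str, str], int]:
        return {c.key: c.read_count for c in self.clonotypes}

    def to_frame(self) -> pd.DataFrame:
        """AIRR-style DataFrame view (one row per clonotype)."""
        return pd.DataFrame(
            {
                "repertoire_id": self.sample_id,
                "v_call": [c.v_call for c in self.clonotypes],
                "j_call": [c.j_call for c in self.clonotypes],
                "junction": [c.junction_nt for c in self.clonotypes],
                "junction_aa": [c.junction_aa if c.junction_aa is not None else "" for c in self.clonotypes],
                "productive": [c.productive for c in self.clonotypes],
                "duplicate_count": [c.read_count for c in self.clonotypes],
            }
        )


@dataclass(frozen=True)
class SegmentAssignment:
    """Best-matching germline segment for one read."""

    segment_id: str
    score: int  # matching bases in the ungapped overlap
    longest_run: int  # longest contiguous stretch of matches
    diagonal: int  # read_pos - segment_pos of the ungapped alignment
    anchor_read_pos: int  # anchor codon start projected onto the read


# ---------------------------------------------------------------------------
# Seed-and-extend assignment
# ---------------------------------------------------------------------------

_SEG_KMER_CACHE: dict[tuple[str, int], dict[str, list[int]]] = {}


def _segment_kmers(sequence: str, k: int) -> dict[str, list[int]]:
    key = (sequence, k)
    idx = _SEG_KMER_CACHE.get(key)
    if idx is None:
        idx = {}
        for q in range(len(sequence) - k + 1):
            idx.setdefault(sequence[q : q + k], []).append(q)
        _SEG_KMER_CACHE[key] = idx
    return idx


def _read_kmers(read: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for p in range(len(read) - k + 1):
        idx.setdefault(read[p : p + k], []).append(p)
    return idx


def _overlap_stats(read: str, seg: str, diag: int) -> tuple[int, int]:
    """(matches, longest contiguous match run) of the ungapped alignment."""
    q0 = max(0, -diag)
    q1 = min(len(seg), len(read) - diag)
    matches = 0
    run = 0
    best_run = 0
    for q in range(q0, q1):
        if read[diag + q] == seg[q]:
            matches += 1
            run += 1
            if run > best_run:
                best_run = run
        else:
            run = 0
    return matches, best_run


def assign_segment(
    read: str,
    candidates: Sequence[GermlineSegment],
    min_run: int | None = None,
    seed_k: int | None = None,
) -> SegmentAssignment | None:
    """Best germline segment for ``read`` among ``candidates`` (one kind).

    Returns ``None`` when no candidate reaches the minimum contiguous-match
    threshold ("unassigned").  Deterministic: score ties break to the
    lexicographically smaller segment_id.
    """
    if not read:
        raise CallerError("empty read")
    if not candidates:
        raise CallerError("no candidate segments")
    kind = candidates[0].kind
    if min_run is None:
        min_run = MIN_V_MATCH_RUN if kind == "V" else MIN_J_MATCH_RUN
    if seed_k is None:
        seed_k = V_SEED_K if kind == "V" else J_SEED_K

    read_idx = _read_kmers(read, seed_k)
    best: SegmentAssignment | None = None
    for seg in sorted(candidates, key=lambda s: s.segment_id):
        votes: Counter[int] = Counter()
        for kmer, seg_positions in _segment_kmers(seg.sequence, seed_k).items():
            read_positions = read_idx.get(kmer)
            if read_positions:
                for q in seg_positions:
                    for p in read_positions:
                        votes[p - q] += 1
        if not votes:
            continue
        # most-supported diagonal; ties to the smallest diagonal for determinism
        diag = min(votes, key=lambda d: (-votes[d], d))
        score, longest = _overlap_stats(read, seg.sequence, diag)
        if longest < min_run:
            continue
        if seg.anchor_offset is None:
            anchor_pos = -1
        else:
            anchor_pos = diag + seg.anchor_offset
            if not (0 <= anchor_pos <= len(read) - 3):
                continue  # anchor codon not on the read
        cand = SegmentAssignment(seg.segment_id, score, longest, diag, anchor_pos)
        if best is None or cand.score > best.score:
            best = cand
    return best


# ---------------------------------------------------------------------------
# Junction extraction & productivity
# ---------------------------------------------------------------------------

def extract_junction(read: str, v_anchor_pos: int, j_anchor_pos: int) -> str | None:
    """CDR3 nucleotides: read[v_anchor_pos : j_anchor_pos + 3].

    First base of the Cys codon through the last base of the Phe codon,
    inclusive.  Returns ``None`` ("no junction") when the anchors are
    crossed or out of bounds.
    """
    if v_anchor_pos < 0 or j_anchor_pos < v_anchor_pos:
        return None
    if j_anchor_pos + 3 > len(read):
        return None
    return read[v_anchor_pos : j_anchor_pos + 3]


def classify_productivity(junction_nt: str) -> tuple[bool, str | None]:
    """(productive, junction_aa).

    Productive iff the junction is in frame (length divisible by 3), its
    translation contains no stop, and it begins with C and ends with F.
    The amino-acid string is returned whenever the junction is in frame,
    stops rendered as ``*``; out-of-frame junctions have no translation.
    """
    if len(junction_nt) % 3:
        return False, None
    aa = translate_nt(junction_nt)
    productive = (
        bool(aa)
        and aa.startswith("C")
        and aa.endswith("F")
        and STOP_SYMBOL not in aa
    )
    return productive, aa


# ---------------------------------------------------------------------------
# Read -> clonotype table
# ---------------------------------------------------------------------------

def _iter_read_sequences(reads: str | Path | Iterable[str]) -> Iterable[str]:
    if isinstance(reads, (str, Path)):
        path = Path(reads)
        with open(path) as fh:
            first = fh.read(1)
        fmt = "fastq" if first == "@" else "fasta"
        for rec in SeqIO.parse(str(path), fmt):
            yield str(rec.seq).upper()
    else:
        yield from reads


def build_clonotype_table(
    reads: str | Path | Iterable[str],
    segment_set: SegmentSet,
    sample_id: str,
    *,
    min_v_run: int = MIN_V_MATCH_RUN,
    min_j_run: int = MIN_J_MATCH_RUN,
) -> ClonotypeTable:
    """Call every read and aggregate into a :class:`ClonotypeTable`.

    Per read: assign V, assign J, extract the anchor-bounded junction,
    classify productivity; identical (v_call, j_call, junction) calls are
    aggregated with summed read counts.  Reads failing any step are counted
    as unassigned, with per-step attrition logged.

    ``reads`` may be a FASTQ/FASTA path or an iterable of sequences.
    Identical read sequences are called once (substitution-error-free
    duplicates are common at depth) and their counts pooled.
    """
    v_candidates = segment_set.v_segments
    j_candidates = segment_set.j_segments
    if not v_candidates or not j_candidates:
        raise CallerError("reference must contain at least one V and one J segment")

    read_counter: Counter[str] = Counter()
    for seq in _iter_read_sequences(reads):
        read_counter[seq] += 1
    total = sum(read_counter.values())
    if total == 0:
        raise CallerError("no reads supplied")

    attrition = {"total": total, "no_v": 0, "no_j": 0, "no_junction": 0}
    clone_counts: dict[tuple[str, str, str], int] = {}
    clone_info: dict[tuple[str, str, str], tuple[str | None, bool]] = {}

    for seq, n in read_counter.items():
        v = assign_segment(seq, v_candidates, min_run=min_v_run)
        if v is None:
            attrition["no_v"] += n
            continue
        j = assign_segment(seq, j_candidates, min_run=min_j_run)
        if j is None:
            attrition["no_j"] += n
            continue
        junction = extract_junction(seq, v.anchor_read_pos, j.anchor_read_pos)
        if junction is None:
            attrition["no_junction"] += n
            continue
        key = (v.segment_id, j.segment_id, junction)
        if key in clone_counts:
            clone_counts[key] += n
        else:
            clone_counts[key] = n
            clone_info[key] = classify_productivity(junction)  # (productive, aa)

    clonotypes = [
        Clonotype(
            v_call=v_call,
            j_call=j_call,
            junction_nt=junction,
            junction_aa=clone_info[(v_call, j_call, junction)][1],
            productive=clone_info[(v_call, j_call, junction)][0],
            read_count=count,
        )
        for (v_call, j_call, junction), count in clone_counts.items()
    ]
    # deterministic order: descending count, then key
    clonotypes.sort(key=lambda c: (-c.read_count, c.key))

    assigned = sum(clone_counts.values())
    unassigned = total - assigned
    attrition["assigned"] = assigned
    attrition["unassigned"] = unassigned
    logger.info(
        "%s: %d reads, %d assigned, %d unassigned (no_v=%d no_j=%d no_junction=%d)",
        sample_id, total, assigned, unassigned,
        attrition["no_v"], attrition["no_j"], attrition["no_junction"],
    )
    return ClonotypeTable(
        sample_id=sample_id,
        clonotypes=clonotypes,
        total_reads=total,
        assigned_reads=assigned,
        unassigned_reads=unassigned,
        attrition=attrition,
    )
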