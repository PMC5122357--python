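"""Germline TRBV/TRBD/TRBJ reference segments with CDR3 anchor annotations.

The CDR3 of a rearranged TCRbeta chain is delimited by two conserved anchor
residues: the second conserved cysteine near the 3' end of the V region
(IMGT 2nd-CYS) and the conserved phenylalanine of the J region's FG-X-G
motif.  Every V and J segment in a :class:`SegmentSet` therefore carries an
``anchor_offset`` — the 0-based position of the first base of its anchor
codon — which is verified by translation at load time.  D segments carry no
anchor; they participate only in simulation.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"
_NT_SET = frozenset(NUCLEOTIDES)
STOP_SYMBOL = "*"

#: codon -> amino acid (one letter), stops mapped to "*"
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
CODON_TABLE.update({c: STOP_SYMBOL for c in standard_dna_table.stop_codons})

_CYS_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "C")
_PHE_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "F")
_GLY_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "G")

SEGMENT_KINDS = ("V", "D", "J")


class GermlineError(ValueError):
    """A germline segment or reference file failed validation."""


def translate_nt(sequence: str) -> str:
    """Codon-wise translation; stop codons become ``*``.

    Raises ``GermlineError`` if the sequence length is not a multiple of 3.
    """
    if len(sequence) % 3:
        raise GermlineError(
            f"cannot translate sequence of length {len(sequence)} (not a codon multiple)"
        )
    try:
        return "".join(CODON_TABLE[sequence[i : i + 3]] for i in range(0, len(sequence), 3))
    except KeyError as exc:  # non-ACGT codon
        raise GermlineError(f"untranslatable codon {exc.args[0]!r}") from exc


@dataclass(frozen=True)
class GermlineSegment:
    """One germline V, D or J gene segment.

    Parameters
    ----------
    segment_id
        Gene name, e.g. ``"TRBV7-9"`` or ``"TRBJ2-7"``.
    kind
        One of ``"V"``, ``"D"``, ``"J"``.
    sequence
        Nucleotide sequence over A/C/G/T.
    anchor_offset
        0-based index of the first base of the anchor codon (2nd-CYS for V,
        conserved Phe for J).  ``None`` for D segments.
    """

    segment_id: str
    kind: str
    sequence: str
    anchor_offset: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise GermlineError(f"{self.segment_id}: unknown segment kind {self.kind!r}")
        if not self.sequence:
            raise GermlineError(f"{self.segment_id}: empty sequence")
        if not _NT_SET.issuperset(self.sequence):
            bad = sorted(set(self.sequence) - _NT_SET)
            raise GermlineError(f"{self.segment_id}: non-ACGT characters {bad}")
        if self.kind == "D":
            if self.anchor_offset is not None:
                raise GermlineError(f"{self.segment_id}: D segments carry no anchor")
            return
        if self.anchor_offset is None:
            raise GermlineError(f"{self.segment_id}: {self.kind} segment requires an anchor")
        if not (0 <= self.anchor_offset and self.anchor_offset + 3 <= len(self.sequence)):
            raise GermlineError(
                f"{self.segment_id}: anchor_offset {self.anchor_offset} out of bounds"
            )
        codon = self.anchor_codon
        if self.kind == "V" and codon not in _CYS_CODONS:
            raise GermlineError(
                f"{self.segment_id}: V anchor codon {codon} translates to "
                f"{CODON_TABLE.get(codon, '?')}, expected C (cysteine)"
            )
        if self.kind == "J" and codon not in _PHE_CODONS:
            raise GermlineError(
                f"{self.segment_id}: J anchor codon {codon} translates to "
                f"{CODON_TABLE.get(codon, '?')}, expected F (phenylalanine)"
            )

    @property
    def anchor_codon(self) -> str | None:
        if self.anchor_offset is None:
            return None
        return self.sequence[self.anchor_offset : self.anchor_offset + 3]

    @property
    def reading_frame(self) -> int | None:
        """Frame of the anchor codon within the stated sequence."""
        if self.anchor_offset is None:
            return None
        return self.anchor_offset % 3

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SegmentSet:
    """A validated collection of germline segments, indexed by name."""

    segments: dict[str, GermlineSegment] = field(default_factory=dict)

    @classmethod
    def from_segments(cls, segments: Iterable[GermlineSegment]) -> "SegmentSet":
        index: dict[str, GermlineSegment] = {}
        for seg in segments:
            if seg.segment_id in index:
                raise GermlineError(f"duplicate segment_id {seg.segment_id!r}")
            index[seg.segment_id] = seg
        obj = cls(index)
        obj.validate()
        return obj

    def validate(self) -> None:
        if not self.by_kind("V"):
            raise GermlineError("reference contains no V segment")
        if not self.by_kind("J"):
            raise GermlineError("reference contains no J segment")

    def by_kind(self, kind: str) -> list[GermlineSegment]:
        """Segments of one kind, sorted by segment_id (deterministic order)."""
        return sorted(
            (s for s in self.segments.values() if s.kind == kind),
            key=lambda s: s.segment_id,
        )

    @property
    def v_segments(self) -> list[GermlineSegment]:
        return self.by_kind("V")

    @property
    def d_segments(self) -> list[GermlineSegment]:
        return self.by_kind("D")

    @property
    def j_segments(self) -> list[GermlineSegment]:
        return self.by_kind("J")

    def counts(self) -> dict[str, int]:
        return {k: len(self.by_kind(k)) for k in SEGMENT_KINDS}

    def __getitem__(self, segment_id: str) -> GermlineSegment:
        return self.segments[segment_id]

    def __contains__(self, segment_id: str) -> bool:
        return segment_id in self.segments

    def __len__(self) -> int:
        return len(self.segments)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SegmentSet):
            return NotImplemented
        return self.segments == other.segments


# ---------------------------------------------------------------------------
# Anchor location
# ---------------------------------------------------------------------------

def locate_v_anchor(sequence: str, frame: int = 0) -> int | None:
    """Offset of the 3'-most in-frame Cys codon (the 2nd-CYS by convention).

    Returns ``None`` when no in-frame TGT/TGC codon exists.
    """
    best = None
    for off in range(frame, len(sequence) - 2, 3):
        if sequence[off : off + 3] in _CYS_CODONS:
            best = off
    return best


def locate_j_anchor(sequence: str, frame: int = 0) -> int | None:
    """Offset of the conserved Phe codon of the J region.

    Prefers the first in-frame TTT/TTC that begins the canonical FG-X-G motif
    (Phe followed by Gly, any residue, Gly); falls back to the first in-frame
    Phe codon.  Returns ``None`` when no in-frame Phe codon exists.
    """
    first_phe = None
    for off in range(frame, len(sequence) - 2, 3):
        if sequence[off : off + 3] in _PHE_CODONS:
            if first_phe is None:
                first_phe = off
            g1 = sequence[off + 3 : off + 6]
            g2 = sequence[off + 9 : off + 12]
            if g1 in _GLY_CODONS and g2 in _GLY_CODONS:
                return off
    return first_phe


def _fallback_anchor(seg_id: str, kind: str, sequence: str) -> int:
    locate = locate_v_anchor if kind == "V" else locate_j_anchor
    for frame in (0, 1, 2):
        off = locate(sequence, frame)
        if off is not None:
            return off
    raise GermlineError(f"{seg_id}: no anchor annotation and no anchor motif found")


# ---------------------------------------------------------------------------
# FASTA + anchor-table I/O
# ---------------------------------------------------------------------------

def _parse_header(description: str) -> tuple[str, str, int | None]:
    """Parse ``"segment_id|kind [anchor=<int>]"`` FASTA headers."""
    tokens = description.split()
    head = tokens[0]
    if "|" not in head:
        raise GermlineError(f"malformed FASTA header {description!r}: expected 'id|kind'")
    segment_id, _, kind = head.partition("|")
    anchor = None
    for tok in tokens[1:]:
        if tok.startswith("anchor="):
            try:
                anchor = int(tok.split("=", 1)[1])
            except ValueError as exc:
                raise GermlineError(f"{segment_id}: bad anchor tag {tok!r}") from exc
    return segment_id, kind, anchor


def read_anchor_table(path: str | Path) -> dict[str, int]:
    """Two-column TSV (segment_id, anchor_offset) -> mapping."""
    anchors: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise GermlineError(f"{path}:{lineno}: expected 2 tab-separated columns")
            try:
                anchors[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise GermlineError(f"{path}:{lineno}: non-integer anchor {parts[1]!r}") from exc
    return anchors


def load_segments(
    fasta_path: str | Path,
    anchors: Mapping[str, int] | str | Path | None = None,
) -> SegmentSet:
    """Load a germline reference from FASTA (headers ``id|kind [anchor=N]``).

    ``anchors`` may be a mapping or the path of a two-column TSV; it takes
    precedence over ``anchor=`` header tags.  V/J segments lacking either
    annotation have their anchor located by motif as a fallback.  Every
    anchor is verified by translation (V: Cys, J: Phe); violations are
    rejected with the offending segment named.
    """
    if anchors is not None and not isinstance(anchors, Mapping):
        anchors = read_anchor_table(anchors)
    table: Mapping[str, int] = anchors or {}

    segments: list[GermlineSegment] = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        segment_id, kind, header_anchor = _parse_header(record.description)
        sequence = str(record.seq).upper()
        if kind == "D":
            anchor = None
        elif segment_id in table:
            anchor = table[segment_id]
        elif header_anchor is not None:
            anchor = header_anchor
        else:
            anchor = _fallback_anchor(segment_id, kind, sequence)
            logger.info("%s: anchor located by motif at offset %d", segment_id, anchor)
        segments.append(GermlineSegment(segment_id, kind, sequence, anchor))
    if not segments:
        raise GermlineError(f"no FASTA records in {fasta_path}")
    return SegmentSet.from_segments(segments)


def write_segments(
    segment_set: SegmentSet,
    fasta_path: str | Path,
    anchor_table_path: str | Path | None = None,
) -> None:
    """Write a SegmentSet as FASTA with ``anchor=`` tags (+ optional TSV)."""
    records = []
    for kind in SEGMENT_KINDS:
        for seg in segment_set.by_kind(kind):
            desc = f"{seg.segment_id}|{seg.kind}"
            if seg.anchor_offset is not None:
                desc += f" anchor={seg.anchor_offset}"
            records.append(SeqRecord(Seq(seg.sequence), id=desc.split()[0], description=desc))
    # SeqIO prepends record.id to description unless they coincide; write manually
    with open(fasta_path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.description}\n{rec.seq}\n")
    if anchor_table_path is not None:
        with open(anchor_table_path, "w") as fh:
            for kind in ("V", "J"):
                for seg in segment_set.by_kind(kind):
                    fh.write(f"{seg.segment_id}\t{seg.anchor_offset}\n")


# ---------------------------------------------------------------------------
# Built-in toy reference
# ---------------------------------------------------------------------------

# Hand-built miniature TRB reference for tests and simulation.  Six V genes
# (including the four CD4/CD8-informative markers TRBV5-4, TRBV7-2, TRBV18,
# TRBV7-9), both D genes, three J genes.  V: 45 nt, 2nd-CYS at offset 30
# (15 nt contributed to the CDR3); J: 48 nt, conserved Phe at offset 15
# (18 nt contributed through the Phe codon).  5' V prefixes and 3' J
# suffixes are mutually divergent so segment assignment is unambiguous.
_TOY_SEGMENTS: tuple[tuple[str, str, str, int | None], ...] = (
    ("TRBV5-4", "V", "GAAACCGGGGTGACCCAAAGCCCGAGACAC" "TGCGCCAGCAGCTTG", 30),
    ("TRBV7-2", "V", "GGAGCTGGAGTCTCCCAGTCCCCAAGACAC" "TGTGCCAGCAGCCAA", 30),
    ("TRBV7-9", "V", "GATACTGGAATCACCCAGGCCCCAACGAGC" "TGCGCCAGCAGTCTC", 30),
    ("TRBV18", "V", "AATGCCGGCGTCATGCAGAACCCAAGCCAG" "TGTGCCAGCTCACCG", 30),
    ("TRBV20-1", "V", "GGTGCTGTCGTCTCTCAACATCCGAGCTGG" "TGCGCTTGGAGTGAA", 30),
    ("TRBV28", "V", "GATGTGAAAGTAACCCAGAGCTCGAGATAT" "TGTGCCAGCAGTTTA", 30),
    ("TRBD1", "D", "GGGACAGGGGGC", None),
    ("TRBD2", "D", "GGGACTAGCGGGGGG", None),
    ("TRBJ1-1", "J", "AACACTGAAGCTAGC" "TTC" "GGACAAGGCACCAGACTCACAGTTGTAGAG", 15),
    ("TRBJ2-1", "J", "TCTAACTATGGCTAC" "TTC" "GGGACCGGGCTGACCGTGCTAGGTAAACAA", 15),
    ("TRBJ2-7", "J", "TCCTACGAGCAGTAC" "TTC" "GGGCCGGGCACCAGGCTCACGGTCACAGAG", 15),
)


def toy_reference() -> SegmentSet:
    """Deterministic built-in miniature TRB reference (6 V, 2 D, 3 J)."""
    return SegmentSet.from_segments(
        GermlineSegment(sid, kind, seq, anchor) for sid, kind, seq, anchor in _TOY_SEGMENTS
    )
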