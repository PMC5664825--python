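"""Core domain types and interval arithmetic shared by every pipeline stage.

All coordinates are 0-based half-open on the forward strand of the chromosome,
regardless of feature strand; conversion from the 1-based inclusive convention
of GFF3 / RepeatMasker happens at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "RepeatFeature",
    "LtrElement",
    "ParentMatch",
    "RetroCall",
    "AnnotationBundle",
    "overlap_fraction",
    "contains",
    "merge_intervals",
    "union_coverage",
]

REPEAT_ORDERS = frozenset({"LTR", "DNA", "RC", "LINE", "SINE", "Unknown"})

VERDICT_RETRO = "retro"
VERDICT_TE_CONFLICT = "rejected_te_conflict"
VERDICT_ORPHAN = "rejected_orphan_multiexon"
VERDICT_MULTI_GENE = "rejected_multi_gene_rule"
VERDICTS = (VERDICT_RETRO, VERDICT_TE_CONFLICT, VERDICT_ORPHAN, VERDICT_MULTI_GENE)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise ValueError("seq_id must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def overlap_fraction(a: GenomicInterval, b: GenomicInterval) -> float:
    """Fraction of ``a`` covered by ``b`` (0 when on different sequences).

    Symmetric only when the two intervals have equal length; the shared
    overlap length equals ``overlap_fraction(a, b) * len(a)``.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("zero-length interval")
    if a.seq_id != b.seq_id:
        return 0.0
    shared = min(a.end, b.end) - max(a.start, b.start)
    return max(shared, 0) / len(a)


def contains(outer: GenomicInterval, inner: GenomicInterval) -> bool:
    """True iff ``inner`` lies fully within ``outer`` (strand-agnostic)."""
    return (
        outer.seq_id == inner.seq_id
        and outer.start <= inner.start
        and inner.end <= outer.end
    )


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or book-ended intervals per sequence; strand dropped."""
    out: list[GenomicInterval] = []
    by_seq: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_seq.setdefault(iv.seq_id, []).append(iv)
    for seq_id in sorted(by_seq):
        ivs = sorted(by_seq[seq_id], key=lambda i: (i.start, i.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(seq_id, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(seq_id, cur_start, cur_end))
    return out


def union_coverage(target: GenomicInterval, intervals: Iterable[GenomicInterval]) -> float:
    """Fraction of ``target`` covered by the union of ``intervals``."""
    covered = 0
    for iv in merge_intervals(list(intervals) or []):
        if iv.seq_id != target.seq_id:
            continue
        covered += max(0, min(iv.end, target.end) - max(iv.start, target.start))
    return covered / len(target)


@dataclass
class GeneModel:
    """A protein-coding gene: ordered exons, spliced CDS, optional family label.

    ``exons`` are in transcription order (5'->3' on the coding strand), i.e.
    ascending genomic start on '+', descending on '-'. ``cds_seq`` is the
    spliced, strand-corrected coding sequence ('' when no genome was given).
    """

    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval]
    cds_seq: str = ""
    family: Optional[str] = None
    is_nlr: bool = False

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: at least one exon required")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for prev, nxt in zip(genomic, genomic[1:]):
            if nxt.start < prev.end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        for e in self.exons:
            if not contains(self.interval, e):
                raise ValueError(f"gene {self.gene_id}: exon outside gene span")

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def total_exon_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def longest_exon_length(self) -> int:
        return max(len(e) for e in self.exons)


@dataclass(frozen=True)
class RepeatFeature:
    """One repeat-annotation row (RepeatMasker-style), e.g. a partial LTR."""

    interval: GenomicInterval
    name: str
    order: str
    superfamily: str = ""

    def __post_init__(self) -> None:
        if self.order not in REPEAT_ORDERS:
            raise ValueError(f"unknown repeat order {self.order!r}")


@dataclass
class LtrElement:
    """A full-length LTR retrotransposon with paired 5'/3' LTRs.

    The internal region is everything between the inner LTR edges. Autonomy
    is 'autonomous' when the internal region retains gag/pol-scale coding
    potential, 'non_autonomous' when it does not, 'unknown' before
    classification (or without sequence).
    """

    element_id: str
    span: GenomicInterval
    ltr5: GenomicInterval
    ltr3: GenomicInterval
    tsd: Optional[tuple[GenomicInterval, GenomicInterval]] = None
    autonomy: str = "unknown"

    def __post_init__(self) -> None:
        if self.autonomy not in ("autonomous", "non_autonomous", "unknown"):
            raise ValueError(f"invalid autonomy {self.autonomy!r}")
        if not (contains(self.span, self.ltr5) and contains(self.span, self.ltr3)):
            raise ValueError(f"element {self.element_id}: LTRs outside span")
        if self.ltr5.end > self.ltr3.start:
            raise ValueError(f"element {self.element_id}: LTRs out of order")
        if self.span.start != self.ltr5.start or self.span.end != self.ltr3.end:
            raise ValueError(f"element {self.element_id}: span must equal LTR bounds")

    @property
    def internal_region(self) -> GenomicInterval:
        return GenomicInterval(self.span.seq_id, self.ltr5.end, self.ltr3.start)


@dataclass(frozen=True)
class ParentMatch:
    """Best parental-gene hit for a retrocopy candidate."""

    parent_id: str
    query_coverage: float
    identity: float
    parent_exon_count: int
    candidate_exon_count: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.query_coverage <= 1.0 and 0.0 <= self.identity <= 1.0):
            raise ValueError("coverage and identity must lie in [0, 1]")

    @property
    def introns_lost(self) -> int:
        return self.parent_exon_count - self.candidate_exon_count


@dataclass
class RetroCall:
    """A classified retroduplication event (or rejected candidate)."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    evidence_pass: str  # full_length | partial
    verdict: str
    element_id: Optional[str] = None
    repeat_ids: tuple[str, ...] = ()
    parent_id: Optional[str] = None
    parent_coverage: float = 0.0
    introns_lost: int = 0
    polyA: bool = False
    direct_repeats: bool = False
    autonomy: str = "unknown"
    insertion_age_my: Optional[float] = None
    ka: Optional[float] = None
    ks: Optional[float] = None
    duplication_age_my: Optional[float] = None

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"invalid verdict {self.verdict!r}")
        if self.evidence_pass not in ("full_length", "partial"):
            raise ValueError(f"invalid evidence pass {self.evidence_pass!r}")


@dataclass
class AnnotationBundle:
    """Everything the pipeline knows about one genome."""

    genes: list[GeneModel] = field(default_factory=list)
    repeats: list[RepeatFeature] = field(default_factory=list)
    ltr_elements: list[LtrElement] = field(default_factory=list)
    sequences: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        """Check that every feature fits on a provided sequence."""
        if not self.sequences:
            return
        feats: list[tuple[str, GenomicInterval]] = []
        feats += [(g.gene_id, g.interval) for g in self.genes]
        feats += [(r.name, r.interval) for r in self.repeats]
        feats += [(e.element_id, e.span) for e in self.ltr_elements]
        for name, iv in feats:
            if iv.seq_id not in self.sequences:
                raise ValueError(f"{name}: unknown seq_id {iv.seq_id}")
            if iv.end > len(self.sequences[iv.seq_id]):
                raise ValueError(f"{name}: interval beyond end of {iv.seq_id}")
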