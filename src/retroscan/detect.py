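"""Candidate retrogene detection inside LTR elements, parental verification,
autonomy classification, and retro-signature scanning.

A retroduplicated gene is expected to (i) lie fully inside a full-length LTR
element (or inside merged partial LTR fragments after element decay), (ii)
have a multi-exon parental gene whose spliced CDS covers >95% of the
candidate CDS, and (iii) often show a 3' poly(A) tract and flanking direct
repeats at the insertion site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .model import (
    GeneModel,
    GenomicInterval,
    LtrElement,
    ParentMatch,
    RepeatFeature,
    contains,
    merge_intervals,
    union_coverage,
)

__all__ = [
    "CandidateRecord",
    "detect_candidates_full_ltr",
    "detect_candidates_partial_ltr",
    "remove_te_conflicts",
    "find_parent",
    "classify_autonomy",
    "retro_signature_scan",
]

CONFLICT_ORDERS = ("DNA", "RC")  # orders whose overlap invalidates an element call


@dataclass
class CandidateRecord:
    """A draft retro call flowing through the filter stages."""

    gene: GeneModel
    evidence_pass: str  # full_length | partial
    element: Optional[LtrElement] = None
    repeat_ids: tuple[str, ...] = ()
    parent: Optional[ParentMatch] = None
    signatures: dict = field(default_factory=lambda: {"polyA": False, "direct_repeats": False})
    verdict: Optional[str] = None


def detect_candidates_full_ltr(
    genes: Sequence[GeneModel], ltr_elements: Sequence[LtrElement]
) -> list[CandidateRecord]:
    """Genes whose full span lies inside a full-length LTR element.

    A gene contained in several (nested) elements is attached to the
    smallest containing element.
    """
    trees: dict[str, IntervalTree] = {}
    for elem in ltr_elements:
        trees.setdefault(elem.span.seq_id, IntervalTree()).addi(
            elem.span.start, elem.span.end, elem
        )
    out: list[CandidateRecord] = []
    for gene in sorted(genes, key=lambda g: (g.interval.seq_id, g.interval.start)):
        tree = trees.get(gene.interval.seq_id)
        if tree is None:
            continue
        hits = [
            iv.data
            for iv in tree.overlap(gene.interval.start, gene.interval.end)
            if contains(iv.data.span, gene.interval)
        ]
        if not hits:
            continue
        best = min(hits, key=lambda e: (len(e.span), e.span.start, e.element_id))
        out.append(CandidateRecord(gene=gene, evidence_pass="full_length", element=best))
    return out


def detect_candidates_partial_ltr(
    genes: Sequence[GeneModel], repeats: Sequence[RepeatFeature]
) -> list[CandidateRecord]:
    """Genes fully covered by merged partial-LTR fragments, with LTR material
    extending beyond both gene edges (direct-repeat geometry degraded by
    deletion)."""
    ltr_repeats = [r for r in repeats if r.order == "LTR"]
    blocks = merge_intervals([r.interval for r in ltr_repeats])
    out: list[CandidateRecord] = []
    for gene in sorted(genes, key=lambda g: (g.interval.seq_id, g.interval.start)):
        iv = gene.interval
        for block in blocks:
            if block.seq_id == iv.seq_id and block.start < iv.start and iv.end < block.end:
                names = tuple(
                    r.name
                    for r in ltr_repeats
                    if r.interval.seq_id == block.seq_id
                    and r.interval.start < block.end
                    and r.interval.end > block.start
                )
                out.append(
                    CandidateRecord(gene=gene, evidence_pass="partial", repeat_ids=names)
                )
                break
    return out


def remove_te_conflicts(
    candidates: Sequence[CandidateRecord],
    repeats: Sequence[RepeatFeature],
    threshold: float = 0.5,
) -> tuple[list[CandidateRecord], list[CandidateRecord]]:
    """Drop full-length candidates whose gene overlaps a class II TE.

    A candidate conflicts when the union of DNA-transposon/Helitron (orders
    DNA, RC) repeat intervals covers more than ``threshold`` of the gene span
    — evidence that the element prediction was wrong. LINE/SINE overlaps do
    not trigger rejection. Returns (kept, rejected).
    """
    conflict_ivs = [r.interval for r in repeats if r.order in CONFLICT_ORDERS]
    kept: list[CandidateRecord] = []
    rejected: list[CandidateRecord] = []
    for cand in candidates:
        if cand.evidence_pass == "full_length" and conflict_ivs:
            if union_coverage(cand.gene.interval, conflict_ivs) > threshold:
                cand.verdict = "rejected_te_conflict"
                rejected.append(cand)
                continue
        kept.append(cand)
    return kept, rejected


def _local_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def find_parent(
    candidate: GeneModel,
    gene_pool: Iterable[GeneModel],
    min_coverage: float = 0.95,
) -> Optional[ParentMatch]:
    """Best parental gene for a candidate retrocopy, or None.

    The candidate CDS (query) is locally aligned against each pool gene's
    spliced CDS. A valid parent must be multi-exon, have more exons than the
    candidate, and cover strictly more than ``min_coverage`` of the query.
    Ranking is by alignment score, then identity, then parent id.
    """
    query = candidate.cds_seq
    if not query:
        return None
    aligner = _local_aligner()
    best: Optional[tuple[float, float, str, float, GeneModel]] = None
    for pool_gene in gene_pool:
        if (
            pool_gene.gene_id == candidate.gene_id
            or pool_gene.exon_count < 2
            or pool_gene.exon_count <= candidate.exon_count
            or not pool_gene.cds_seq
        ):
            continue
        alignments = aligner.align(pool_gene.cds_seq, query)
        try:
            aln = alignments[0]
        except IndexError:
            continue
        target_blocks, query_blocks = aln.aligned
        covered = sum(e - s for s, e in query_blocks)
        coverage = covered / len(query)
        if coverage <= min_coverage:
            continue
        matches = aligned_cols = 0
        for (ts, te), (qs, qe) in zip(target_blocks, query_blocks):
            for t_base, q_base in zip(pool_gene.cds_seq[ts:te], query[qs:qe]):
                aligned_cols += 1
                if t_base == q_base:
                    matches += 1
        identity = matches / aligned_cols if aligned_cols else 0.0
        key = (aln.score, identity, pool_gene.gene_id)
        if best is None or (key[0], key[1]) > (best[0], best[1]) or (
            (key[0], key[1]) == (best[0], best[1]) and key[2] < best[2]
        ):
            best = (aln.score, identity, pool_gene.gene_id, coverage, pool_gene)
    if best is None:
        return None
    _, identity, parent_id, coverage, parent = best
    return ParentMatch(
        parent_id=parent_id,
        query_coverage=min(coverage, 1.0),
        identity=identity,
        parent_exon_count=parent.exon_count,
        candidate_exon_count=candidate.exon_count,
    )


_STOPS = {"TAA", "TAG", "TGA"}


def _longest_orf(seq: str) -> int:
    """Longest ATG-to-stop open reading frame (nt, stop excluded), one strand."""
    best = 0
    n = len(seq)
    for frame in range(3):
        start: Optional[int] = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in _STOPS:
                if start is not None:
                    best = max(best, pos - start)
                    start = None
            elif codon == "ATG" and start is None:
                start = pos
    return best


def classify_autonomy(
    element: LtrElement,
    sequences: Mapping[str, str],
    exclude: Optional[GenomicInterval] = None,
    min_orf_nt: int = 900,
) -> str:
    """Classify an element as autonomous / non_autonomous / unknown.

    Autonomous means its internal region (minus the contained candidate gene
    span, if given) retains an open reading frame of at least ``min_orf_nt``
    on either strand — a proxy for gag/pol coding potential. Returns
    ``unknown`` without sequence.
    """
    chrom = sequences.get(element.span.seq_id)
    if chrom is None:
        return "unknown"
    internal = element.internal_region
    segments: list[tuple[int, int]] = []
    if exclude is not None and exclude.seq_id == internal.seq_id:
        left = (internal.start, min(exclude.start, internal.end))
        right = (max(exclude.end, internal.start), internal.end)
        segments = [seg for seg in (left, right) if seg[1] - seg[0] > 0]
    else:
        segments = [(internal.start, internal.end)]
    for s, e in segments:
        seg = chrom[s:e]
        if _longest_orf(seg) >= min_orf_nt:
            return "autonomous"
        if _longest_orf(str(Seq(seg).reverse_complement())) >= min_orf_nt:
            return "autonomous"
    return "non_autonomous"


def _has_homopolymer_run(region: str, base: str, min_len: int = 10, max_mismatch: int = 1) -> bool:
    """True when some stretch holds >= min_len copies of ``base`` with at most
    ``max_mismatch`` interruptions (mismatches do not count toward the run)."""
    if len(region) < min_len:
        return False
    hits = [1 if c == base else 0 for c in region]
    for width in (min_len, min_len + max_mismatch):
        if len(region) < width:
            continue
        window = sum(hits[:width])
        if window >= min_len:
            return True
        for i in range(width, len(region)):
            window += hits[i] - hits[i - width]
            if window >= min_len:
                return True
    return False


def retro_signature_scan(
    gene: GeneModel,
    sequences: Mapping[str, str],
    window: int = 200,
    insertion_span: Optional[GenomicInterval] = None,
    max_offset: int = 5,
) -> dict:
    """Scan for the two genomic hallmarks of a retrocopy.

    * ``polyA``: a run of >= 10 A (coding-strand sense; T on the minus
      strand) with at most one mismatch within ``window`` nt downstream of
      the CDS end.
    * ``direct_repeats``: a pair of near-identical (>= 90% identity, exact
      below 10 nt) 4-20-nt substrings flanking the insertion at mirrored
      offsets within ``max_offset`` nt. The insertion is the containing LTR
      element's span when provided, else the gene span (target-site
      duplications arise at the element boundary, not the gene's).

    Windows truncated by a contig edge are scanned on the remaining side.
    """
    chrom = sequences.get(gene.interval.seq_id, "")
    result = {"polyA": False, "direct_repeats": False}
    if not chrom:
        return result
    iv = gene.interval
    if iv.strand == "-":
        region = chrom[max(0, iv.start - window) : iv.start]
        result["polyA"] = _has_homopolymer_run(region, "T")
    else:
        region = chrom[iv.end : iv.end + window]
        result["polyA"] = _has_homopolymer_run(region, "A")

    span = insertion_span if insertion_span is not None else iv
    for d in range(max_offset + 1):
        found = False
        for k in range(20, 3, -1):
            u_start = span.start - d - k
            if u_start < 0:
                continue
            up = chrom[u_start : span.start - d]
            down = chrom[span.end + d : span.end + d + k]
            if len(up) < k or len(down) < k:
                continue
            mismatches = sum(1 for a, b in zip(up, down) if a != b)
            allowed = 0 if k < 10 else int(k * 0.1)
            if mismatches <= allowed:
                found = True
                break
        if found:
            result["direct_repeats"] = True
            break
    return result
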