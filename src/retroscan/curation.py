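"""False-positive / false-negative curation of draft retro calls.

Three deterministic rules replace manual confirmation:

* when several genes share one LTR element, exon-structure rules pick the
  single most retrogene-like one;
* multi-exon candidates without any parental gene are unclear cases and are
  dropped; single-exon parentless candidates survive only with a retro
  signature (poly(A) or flanking direct repeats);
* the remaining family members are split into ``normal`` genes and
  ``ambiguous`` genes (>80% of the span covered by LTR-order repeats), the
  comparison classes for downstream statistics.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

from .detect import CandidateRecord
from .model import (
    GeneModel,
    RepeatFeature,
    RetroCall,
    union_coverage,
)

__all__ = [
    "resolve_multi_gene_element",
    "drop_orphan_multiexon",
    "classify_normal_genes",
]


def resolve_multi_gene_element(
    genes_in_element: Sequence[GeneModel],
    parent_status: Mapping[str, bool],
) -> tuple[Optional[str], list[str]]:
    """Select the single retrogene among multiple genes in one LTR element.

    Genes without parental sequences are set aside first. Among the rest,
    in order: (1) equal exon counts -> the gene with the longest total exon
    length; (2) differing counts and one gene's longest exon is >1.5-fold
    larger than every exon of every neighboring gene -> that gene;
    (3) otherwise -> the gene with the smallest exon count. Ties break by
    longer CDS, then smaller start. Returns ``(selected_id, rejected_ids)``;
    the selection is invariant under input ordering.
    """
    if not genes_in_element:
        raise ValueError("no genes supplied")
    if len(genes_in_element) == 1:
        return genes_in_element[0].gene_id, []
    eligible = [g for g in genes_in_element if parent_status.get(g.gene_id, False)]
    selected: Optional[str] = None
    if len(eligible) == 1:
        selected = eligible[0].gene_id
    elif len(eligible) > 1:
        counts = {g.exon_count for g in eligible}
        if len(counts) == 1:
            selected = min(
                eligible,
                key=lambda g: (
                    -g.total_exon_length,
                    -len(g.cds_seq),
                    g.interval.start,
                    g.gene_id,
                ),
            ).gene_id
        else:
            dominant = [
                g
                for g in eligible
                if all(
                    g.longest_exon_length > 1.5 * len(exon)
                    for other in eligible
                    if other.gene_id != g.gene_id
                    for exon in other.exons
                )
            ]
            if dominant:
                # mutual >1.5-fold dominance is impossible, so at most one
                selected = dominant[0].gene_id
            else:
                selected = min(
                    eligible,
                    key=lambda g: (
                        g.exon_count,
                        -len(g.cds_seq),
                        g.interval.start,
                        g.gene_id,
                    ),
                ).gene_id
    rejected = sorted(
        g.gene_id for g in genes_in_element if g.gene_id != selected
    )
    return selected, rejected


def drop_orphan_multiexon(
    candidates: Sequence[CandidateRecord],
) -> tuple[list[CandidateRecord], list[CandidateRecord]]:
    """Drop parentless candidates as unclear cases.

    Multi-exon candidates without a parent are always rejected. Single-exon
    candidates without a parent are kept only when a retro signature
    (poly(A) or direct repeats) supports them. Returns (kept, rejected).
    """
    kept: list[CandidateRecord] = []
    rejected: list[CandidateRecord] = []
    for cand in candidates:
        if cand.parent is not None:
            kept.append(cand)
            continue
        if cand.gene.exon_count == 1 and (
            cand.signatures.get("polyA") or cand.signatures.get("direct_repeats")
        ):
            kept.append(cand)
            continue
        cand.verdict = "rejected_orphan_multiexon"
        rejected.append(cand)
    return kept, rejected


def classify_normal_genes(
    all_family_genes: Sequence[GeneModel],
    retro_calls: Iterable[RetroCall],
    repeats: Sequence[RepeatFeature],
    ltr_overlap_threshold: float = 0.8,
) -> dict[str, set[str]]:
    """Partition family genes into retro / ambiguous / normal gene-id sets.

    Finalized retro calls are excluded first; of the remainder, genes whose
    span is covered >``ltr_overlap_threshold`` by LTR-order repeat
    annotations are ambiguous; everything else is normal. The three sets are
    disjoint and exhaustive.
    """
    retro_ids = {c.gene_id for c in retro_calls if c.verdict == "retro"}
    ltr_ivs = [r.interval for r in repeats if r.order == "LTR"]
    partition = {"retro": set(), "ambiguous": set(), "normal": set()}
    for gene in all_family_genes:
        if gene.gene_id in retro_ids:
            partition["retro"].add(gene.gene_id)
        elif ltr_ivs and union_coverage(gene.interval, ltr_ivs) > ltr_overlap_threshold:
            partition["ambiguous"].add(gene.gene_id)
        else:
            partition["normal"].add(gene.gene_id)
    return partition
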