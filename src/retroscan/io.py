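"""Readers and writers for the annotation formats the pipeline touches.

GFF3 gene models and LTR-element records are parsed through :mod:`gffutils`
(in-memory database); RepeatMasker ``.out``-style tables and the TSV reports
are plain tabular text. All conversion between the 1-based inclusive file
conventions and the internal 0-based half-open convention happens here.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Optional

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    AnnotationBundle,
    GeneModel,
    GenomicInterval,
    LtrElement,
    REPEAT_ORDERS,
    RepeatFeature,
    RetroCall,
)

logger = logging.getLogger("retroscan")

__all__ = [
    "GffParseError",
    "read_fasta",
    "write_fasta",
    "read_gene_models",
    "write_gene_models",
    "read_repeat_annotations",
    "write_repeat_annotations",
    "read_ltr_elements",
    "write_ltr_elements",
    "read_retro_calls",
    "write_retro_calls",
    "read_bundle",
]


class GffParseError(ValueError):
    """Structural problem in a GFF3 file, pointing at the offending line."""

    def __init__(self, path, line_no: int, message: str):
        self.path = str(path)
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


# --------------------------------------------------------------------------- FASTA

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# --------------------------------------------------------------------------- GFF3 genes

def _check_hierarchy(path) -> int:
    """Fail fast, naming the line, when a child references an undefined Parent.

    Returns the number of feature lines (0 for a header-only file).
    """
    ids: set[str] = set()
    parents: list[tuple[int, str]] = []
    n_features = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GffParseError(path, line_no, f"expected 9 columns, got {len(fields)}")
            n_features += 1
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            if "ID" in attrs:
                ids.add(attrs["ID"])
            if "Parent" in attrs:
                for p in attrs["Parent"].split(","):
                    parents.append((line_no, p))
    for line_no, parent in parents:
        if parent not in ids:
            raise GffParseError(
                path, line_no, f"{parent!r} referenced as Parent but never defined"
            )
    return n_features


def _exons_overlap(intervals: list[tuple[int, int]]) -> bool:
    ordered = sorted(intervals)
    return any(b[0] < a[1] for a, b in zip(ordered, ordered[1:]))


def _spliced_seq(seq: str, parts: list[tuple[int, int]], strand: str) -> str:
    chunks = [seq[s:e] for s, e in sorted(parts)]
    spliced = "".join(chunks)
    if strand == "-":
        spliced = str(Seq(spliced).reverse_complement())
    return spliced


def read_gene_models(path, sequences: Optional[dict[str, str]] = None) -> list[GeneModel]:
    """Read gene models from GFF3, keeping one representative transcript per gene.

    The representative is the transcript with the longest summed CDS (ties:
    smallest start). Transcripts with internally overlapping exons are
    rejected with a warning; a gene whose transcripts are all rejected is
    dropped. An optional ``family`` attribute on the gene line is carried
    through, as is ``is_nlr=1``.
    """
    if _check_hierarchy(path) == 0:
        return []
    db = gffutils.create_db(
        str(path), dbfn=":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        best = None  # (cds_len, start, exons, cds_parts, strand)
        for t in db.children(g, featuretype=("mRNA", "transcript"), order_by="start"):
            exon_parts = [(f.start - 1, f.end) for f in db.children(t, featuretype="exon")]
            cds_parts = [(f.start - 1, f.end) for f in db.children(t, featuretype="CDS")]
            if not exon_parts:
                exon_parts = list(cds_parts)
            if not cds_parts:
                cds_parts = list(exon_parts)
            if not exon_parts:
                logger.warning("transcript %s has no exons; rejected", t.id)
                continue
            if _exons_overlap(exon_parts):
                logger.warning("transcript %s has overlapping exons; rejected", t.id)
                continue
            cds_len = sum(e - s for s, e in cds_parts)
            key = (-cds_len, t.start)
            if best is None or key < best[0]:
                best = (key, exon_parts, cds_parts, t.strand)
        if best is None:
            logger.warning("gene %s has no usable transcript; dropped", g.id)
            continue
        _, exon_parts, cds_parts, strand = best
        strand = strand if strand in ("+", "-") else "."
        exon_parts = sorted(exon_parts, reverse=(strand == "-"))
        exons = [GenomicInterval(g.seqid, s, e, strand) for s, e in exon_parts]
        interval = GenomicInterval(g.seqid, g.start - 1, g.end, strand)
        cds_seq = ""
        if sequences is not None and g.seqid in sequences:
            cds_seq = _spliced_seq(sequences[g.seqid], cds_parts, strand)
        family = g.attributes.get("family", [None])[0]
        is_nlr = g.attributes.get("is_nlr", ["0"])[0] in ("1", "true", "True")
        genes.append(
            GeneModel(
                gene_id=g.id,
                interval=interval,
                exons=exons,
                cds_seq=cds_seq,
                family=family,
                is_nlr=is_nlr,
            )
        )
    return genes


def write_gene_models(genes: Iterable[GeneModel], path) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/CDS, one transcript per gene)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda x: (x.interval.seq_id, x.interval.start)):
            iv = g.interval
            strand = iv.strand if iv.strand in ("+", "-") else "."
            attrs = [f"ID={g.gene_id}"]
            if g.family:
                attrs.append(f"family={g.family}")
            if g.is_nlr:
                attrs.append("is_nlr=1")
            fh.write(
                f"{iv.seq_id}\tretroscan\tgene\t{iv.start + 1}\t{iv.end}\t.\t{strand}\t.\t"
                + ";".join(attrs)
                + "\n"
            )
            tid = f"{g.gene_id}.t1"
            fh.write(
                f"{iv.seq_id}\tretroscan\tmRNA\t{iv.start + 1}\t{iv.end}\t.\t{strand}\t.\t"
                f"ID={tid};Parent={g.gene_id}\n"
            )
            for e in sorted(g.exons, key=lambda x: x.start):
                for ftype in ("exon", "CDS"):
                    fh.write(
                        f"{iv.seq_id}\tretroscan\t{ftype}\t{e.start + 1}\t{e.end}\t.\t"
                        f"{strand}\t{'0' if ftype == 'CDS' else '.'}\tParent={tid}\n"
                    )


# --------------------------------------------------------------------------- repeats

def parse_repeat_class(class_family: str) -> tuple[str, str]:
    """Split a RepeatMasker class/family string into (order, superfamily)."""
    order, _, superfamily = class_family.partition("/")
    if order not in REPEAT_ORDERS:
        return "Unknown", class_family
    return order, superfamily


def read_repeat_annotations(path) -> list[RepeatFeature]:
    """Read a RepeatMasker ``.out``-style table (full or 5-column layout).

    Unknown class strings are kept with order ``Unknown`` and a warning.
    """
    repeats: list[RepeatFeature] = []
    with open(path) as fh:
        for line in fh:
            tokens = line.split()
            if not tokens or tokens[0] in ("SW", "score") or not tokens[0][0].isdigit():
                # header / banner lines of .out files
                if tokens and tokens[0] not in ("SW", "score"):
                    # 5-column layout with non-numeric first field: query begin end name class
                    if len(tokens) >= 5 and tokens[1].isdigit() and tokens[2].isdigit():
                        query, begin, end, name, cls = tokens[:5]
                        repeats.append(_make_repeat(query, begin, end, name, cls))
                continue
            if len(tokens) >= 11:  # full .out layout
                query, begin, end = tokens[4], tokens[5], tokens[6]
                strand = "+" if tokens[8] == "+" else "-"
                name, cls = tokens[9], tokens[10]
                repeats.append(_make_repeat(query, begin, end, name, cls, strand))
            elif len(tokens) >= 5:
                logger.warning("unrecognised repeat row skipped: %s", line.strip())
    return repeats


def _make_repeat(query, begin, end, name, cls, strand=".") -> RepeatFeature:
    order, superfamily = parse_repeat_class(cls)
    if order == "Unknown" and cls not in ("Unknown",):
        logger.warning("unknown repeat class %r for %s; kept as Unknown", cls, name)
    return RepeatFeature(
        interval=GenomicInterval(query, int(begin) - 1, int(end), strand),
        name=name,
        order=order,
        superfamily=superfamily,
    )


def write_repeat_annotations(repeats: Iterable[RepeatFeature], path) -> None:
    """Write repeats in the full ``.out`` column layout (filler scores)."""
    with open(path, "w") as fh:
        fh.write(
            "   SW   perc perc perc  query      position in query           matching"
            "       repeat              position in repeat\n"
            "score   div. del. ins.  sequence   begin end          (left)   repeat"
            "         class/family      begin  end    (left)   ID\n\n"
        )
        for i, r in enumerate(
            sorted(repeats, key=lambda x: (x.interval.seq_id, x.interval.start)), 1
        ):
            iv = r.interval
            cls = f"{r.order}/{r.superfamily}" if r.superfamily else r.order
            strand = "+" if iv.strand != "-" else "C"
            fh.write(
                f"1000 0.0 0.0 0.0 {iv.seq_id} {iv.start + 1} {iv.end} (0) {strand} "
                f"{r.name} {cls} 1 {len(iv)} (0) {i}\n"
            )


# --------------------------------------------------------------------------- LTR elements

def read_ltr_elements(path) -> list[LtrElement]:
    """Read full-length LTR-element predictions from a GFF3-like file.

    Records of type ``LTR_retrotransposon`` (or top-level ``repeat_region``)
    with exactly two ``long_terminal_repeat`` children become
    :class:`LtrElement`; records with fewer LTR children are logged and
    skipped (they may still be present in the repeat table as fragments).
    Optional ``target_site_duplication`` children are attached.
    """
    if _check_hierarchy(path) == 0:
        return []
    db = gffutils.create_db(
        str(path), dbfn=":memory:", merge_strategy="create_unique", keep_order=True
    )
    elements: list[LtrElement] = []
    types = set(db.featuretypes())
    element_type = "LTR_retrotransposon" if "LTR_retrotransposon" in types else "repeat_region"
    for rec in db.features_of_type(element_type, order_by=("seqid", "start")):
        ltrs = sorted(
            db.children(rec, featuretype="long_terminal_repeat"), key=lambda f: f.start
        )
        if len(ltrs) != 2:
            logger.warning(
                "element %s has %d LTR children; not a full-length element", rec.id, len(ltrs)
            )
            continue
        tsds = sorted(
            db.children(rec, featuretype="target_site_duplication"), key=lambda f: f.start
        )
        strand = rec.strand if rec.strand in ("+", "-") else "."
        ltr5 = GenomicInterval(rec.seqid, ltrs[0].start - 1, ltrs[0].end, strand)
        ltr3 = GenomicInterval(rec.seqid, ltrs[1].start - 1, ltrs[1].end, strand)
        span = GenomicInterval(rec.seqid, ltr5.start, ltr3.end, strand)
        tsd = None
        if len(tsds) == 2:
            tsd = (
                GenomicInterval(rec.seqid, tsds[0].start - 1, tsds[0].end),
                GenomicInterval(rec.seqid, tsds[1].start - 1, tsds[1].end),
            )
        elements.append(
            LtrElement(element_id=rec.id, span=span, ltr5=ltr5, ltr3=ltr3, tsd=tsd)
        )
    return elements


def write_ltr_elements(elements: Iterable[LtrElement], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for e in sorted(elements, key=lambda x: (x.span.seq_id, x.span.start)):
            s = e.span
            strand = s.strand if s.strand in ("+", "-") else "."
            fh.write(
                f"{s.seq_id}\tretroscan\tLTR_retrotransposon\t{s.start + 1}\t{s.end}\t.\t"
                f"{strand}\t.\tID={e.element_id}\n"
            )
            for ltr in (e.ltr5, e.ltr3):
                fh.write(
                    f"{s.seq_id}\tretroscan\tlong_terminal_repeat\t{ltr.start + 1}\t"
                    f"{ltr.end}\t.\t{strand}\t.\tParent={e.element_id}\n"
                )
            if e.tsd is not None:
                for t in e.tsd:
                    fh.write(
                        f"{s.seq_id}\tretroscan\ttarget_site_duplication\t{t.start + 1}\t"
                        f"{t.end}\t.\t{strand}\t.\tParent={e.element_id}\n"
                    )


# --------------------------------------------------------------------------- call reports

_CALL_COLUMNS = [
    "gene_id", "seq_id", "start", "end", "element_id", "evidence_pass", "parent_id",
    "parent_coverage", "introns_lost", "autonomy", "polyA", "direct_repeats",
    "insertion_age_my", "ka", "ks", "duplication_age_my", "verdict", "repeat_ids",
]


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_retro_calls(calls: Iterable[RetroCall], path) -> None:
    """Write finalized calls as a TSV report in (seq_id, start) order."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_CALL_COLUMNS)
        for c in sorted(calls, key=lambda x: (x.seq_id, x.start, x.gene_id)):
            writer.writerow(
                [
                    c.gene_id, c.seq_id, c.start, c.end, _fmt(c.element_id),
                    c.evidence_pass, _fmt(c.parent_id), _fmt(round(c.parent_coverage, 6)),
                    c.introns_lost, c.autonomy, _fmt(c.polyA), _fmt(c.direct_repeats),
                    _fmt(c.insertion_age_my), _fmt(c.ka), _fmt(c.ks),
                    _fmt(c.duplication_age_my), c.verdict, ",".join(c.repeat_ids) or "NA",
                ]
            )


def read_retro_calls(path) -> list[RetroCall]:
    def opt(v):
        return None if v == "NA" else v

    def optf(v):
        return None if v == "NA" else float(v)

    calls = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            calls.append(
                RetroCall(
                    gene_id=row["gene_id"],
                    seq_id=row["seq_id"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    element_id=opt(row["element_id"]),
                    evidence_pass=row["evidence_pass"],
                    parent_id=opt(row["parent_id"]),
                    parent_coverage=float(row["parent_coverage"]),
                    introns_lost=int(row["introns_lost"]),
                    autonomy=row["autonomy"],
                    polyA=row["polyA"] == "1",
                    direct_repeats=row["direct_repeats"] == "1",
                    insertion_age_my=optf(row["insertion_age_my"]),
                    ka=optf(row["ka"]),
                    ks=optf(row["ks"]),
                    duplication_age_my=optf(row["duplication_age_my"]),
                    verdict=row["verdict"],
                    repeat_ids=tuple(
                        row["repeat_ids"].split(",") if row["repeat_ids"] != "NA" else ()
                    ),
                )
            )
    return calls


# --------------------------------------------------------------------------- bundles

def read_bundle(
    genes_path=None, repeats_path=None, ltr_path=None, fasta_path=None
) -> AnnotationBundle:
    """Load any combination of inputs into an :class:`AnnotationBundle`."""
    sequences = read_fasta(fasta_path) if fasta_path else {}
    bundle = AnnotationBundle(
        genes=read_gene_models(genes_path, sequences or None) if genes_path else [],
        repeats=read_repeat_annotations(repeats_path) if repeats_path else [],
        ltr_elements=read_ltr_elements(ltr_path) if ltr_path else [],
        sequences=sequences,
    )
    bundle.validate()
    return bundle
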