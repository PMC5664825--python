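"""Candidate detection, TE-conflict filtering, parent search, signatures."""

import numpy as np
import pytest

from conftest import make_gene
from retroscan.detect import (
    classify_autonomy,
    detect_candidates_full_ltr,
    detect_candidates_partial_ltr,
    find_parent,
    remove_te_conflicts,
    retro_signature_scan,
)
from retroscan.model import GenomicInterval, LtrElement, RepeatFeature
from retroscan.simulate import _random_cds, _random_seq  # deliberate reuse of primitives


def element(eid, start, end, ltr=400, seq="chr1"):
    return LtrElement(
        element_id=eid,
        span=GenomicInterval(seq, start, end),
        ltr5=GenomicInterval(seq, start, start + ltr),
        ltr3=GenomicInterval(seq, end - ltr, end),
    )


def repeat(start, end, order="LTR", name="rep", superfamily="Gypsy", seq="chr1"):
    return RepeatFeature(
        interval=GenomicInterval(seq, start, end), name=name, order=order,
        superfamily=superfamily,
    )


# --------------------------------------------------------------------------- full pass


def test_full_pass_containment_and_straddle():
    elems = [element("e1", 1000, 9000)]
    inside = make_gene("inside", exons=[(2000, 5000)])
    straddle = make_gene("straddle", exons=[(500, 1500)])
    cands = detect_candidates_full_ltr([inside, straddle], elems)
    assert [c.gene.gene_id for c in cands] == ["inside"]
    assert cands[0].evidence_pass == "full_length"
    assert cands[0].element.element_id == "e1"


def test_full_pass_prefers_smallest_nested_element():
    elems = [element("outer", 0, 20000, ltr=300), element("inner", 1500, 8000, ltr=300)]
    gene = make_gene("g", exons=[(3000, 4000)])
    (cand,) = detect_candidates_full_ltr([gene], elems)
    assert cand.element.element_id == "inner"


def test_full_pass_recovers_planted_genes(default_sim):
    bundle, truth = default_sim
    cands = detect_candidates_full_ltr(bundle.genes, bundle.ltr_elements)
    found = {c.gene.gene_id for c in cands}
    planted_full = {
        t.retro_gene_id for t in truth if t.element_id is not None and t.retro_gene_id
    }
    assert planted_full <= found


# --------------------------------------------------------------------------- partial pass


def test_partial_pass_requires_full_coverage_and_both_flanks():
    gene = make_gene("g", exons=[(3000, 4000)])
    covered = [
        repeat(1000, 3000),
        repeat(2990, 4010),
        repeat(4000, 6000),
    ]
    (cand,) = detect_candidates_partial_ltr([gene], covered)
    assert cand.evidence_pass == "partial"
    assert cand.repeat_ids

    seventy_percent = [repeat(1000, 3000), repeat(2990, 3700)]
    assert detect_candidates_partial_ltr([gene], seventy_percent) == []

    dna_flanks = [
        repeat(1000, 3000, order="DNA"),
        repeat(2990, 4010, order="DNA"),
        repeat(4000, 6000, order="DNA"),
    ]
    assert detect_candidates_partial_ltr([gene], dna_flanks) == []


# --------------------------------------------------------------------------- conflicts


def test_te_conflict_rules():
    elems = [element("e1", 0, 10000, ltr=400)]
    gene = make_gene("g", exons=[(2000, 3000)])
    (cand,) = detect_candidates_full_ltr([gene], elems)

    helitron = [repeat(2000, 2800, order="RC", superfamily="Helitron")]
    kept, rejected = remove_te_conflicts([cand], helitron)
    assert not kept and rejected[0].verdict == "rejected_te_conflict"

    cand.verdict = None
    line = [repeat(2000, 2600, order="LINE", superfamily="L1")]
    kept, rejected = remove_te_conflicts([cand], line)
    assert kept and not rejected  # only DNA/RC orders trigger conflicts

    kept, rejected = remove_te_conflicts([cand], [])
    assert kept and not rejected


# --------------------------------------------------------------------------- parent search


def _parent_with_exons(gene_id, cds, n_exons, offset=0):
    bounds = np.linspace(0, len(cds), n_exons + 1).astype(int)
    exons = []
    pos = offset
    for a, b in zip(bounds, bounds[1:]):
        exons.append((pos, pos + (b - a)))
        pos += (b - a) + 100  # intron
    return make_gene(gene_id, exons=exons, cds=cds)


def test_find_parent_identical_cds_full_coverage():
    rng = np.random.default_rng(0)
    cds = _random_cds(rng, 200)
    parent = _parent_with_exons("parent", cds, 6)
    candidate = make_gene("cand", start=50_000, cds=cds)
    match = find_parent(candidate, [parent, candidate])
    assert match is not None
    assert match.parent_id == "parent"
    assert match.query_coverage == pytest.approx(1.0)
    assert match.introns_lost == 5


def test_find_parent_rejects_low_coverage():
    rng = np.random.default_rng(1)
    cds = _random_cds(rng, 200)
    # only 90% of the query matches anything in the pool
    query = cds[: int(len(cds) * 0.9)] + _random_seq(rng, len(cds) - int(len(cds) * 0.9))
    parent = _parent_with_exons("parent", cds, 4)
    candidate = make_gene("cand", start=50_000, cds=query)
    assert find_parent(candidate, [parent]) is None


def test_find_parent_requires_multi_exon_pool():
    rng = np.random.default_rng(2)
    cds = _random_cds(rng, 150)
    single = make_gene("single", cds=cds)
    candidate = make_gene("cand", start=50_000, cds=cds)
    assert find_parent(candidate, [single]) is None


def test_find_parent_never_matches_itself():
    rng = np.random.default_rng(3)
    cds = _random_cds(rng, 150)
    candidate = _parent_with_exons("cand", cds, 3)
    assert find_parent(candidate, [candidate]) is None


# --------------------------------------------------------------------------- autonomy


def test_autonomy_classification():
    rng = np.random.default_rng(4)
    ltr = _random_seq(rng, 400)
    orf = _random_cds(rng, 1000)  # 3000 nt pol-like ORF
    internal = _random_seq(rng, 300) + orf + _random_seq(rng, 300)
    chrom = _random_seq(rng, 1000) + ltr + internal + ltr + _random_seq(rng, 1000)
    start = 1000
    end = start + 400 + len(internal) + 400
    elem = LtrElement(
        element_id="e",
        span=GenomicInterval("chr1", start, end),
        ltr5=GenomicInterval("chr1", start, start + 400),
        ltr3=GenomicInterval("chr1", end - 400, end),
    )
    assert classify_autonomy(elem, {"chr1": chrom}) == "autonomous"
    assert classify_autonomy(elem, {}) == "unknown"

    # excluding the ORF span leaves only short random ORFs
    orf_iv = GenomicInterval("chr1", start + 400 + 300, start + 400 + 300 + len(orf))
    assert classify_autonomy(elem, {"chr1": chrom}, exclude=orf_iv) == "non_autonomous"


def test_autonomy_on_planted_elements(default_sim):
    bundle, truth = default_sim
    by_id = {e.element_id: e for e in bundle.ltr_elements}
    genes = {g.gene_id: g for g in bundle.genes}
    for t in truth:
        if t.element_id in by_id and t.autonomy != "unknown" and t.decoy_class is None:
            got = classify_autonomy(
                by_id[t.element_id], bundle.sequences,
                exclude=genes[t.retro_gene_id].interval,
            )
            assert got == t.autonomy, t.event_id


# --------------------------------------------------------------------------- signatures


def test_signature_scan_detects_planted_polya_and_tsd():
    rng = np.random.default_rng(5)
    tsd = _random_seq(rng, 8)
    cds = _random_cds(rng, 100)
    left, right = _random_seq(rng, 500), _random_seq(rng, 500)
    inner_pad = _random_seq(rng, 120)
    chrom = left + tsd + inner_pad + cds + "A" * 15 + inner_pad + tsd + right
    g_start = len(left) + 8 + 120
    gene = make_gene("g", exons=[(g_start, g_start + len(cds))], cds=cds)
    span = GenomicInterval("chr1", len(left) + 8, len(chrom) - len(right) - 8)
    sig = retro_signature_scan(gene, {"chr1": chrom}, insertion_span=span)
    assert sig == {"polyA": True, "direct_repeats": True}


def test_signature_scan_null_sequence_is_clean():
    rng = np.random.default_rng(6)
    chrom = _random_seq(rng, 4000)
    gene = make_gene("g", exons=[(1500, 1800), (2000, 2400)], cds="ATGAAATGA")
    sig = retro_signature_scan(gene, {"chr1": chrom})
    assert sig == {"polyA": False, "direct_repeats": False}


def test_short_polya_run_is_ignored():
    rng = np.random.default_rng(7)
    cds = _random_cds(rng, 50)
    # two non-A bases stop the run from borrowing downstream A's
    chrom = _random_seq(rng, 300) + cds + "A" * 9 + "CC" + _random_seq(rng, 300)
    gene = make_gene("g", exons=[(300, 300 + len(cds))], cds=cds)
    sig = retro_signature_scan(gene, {"chr1": chrom})
    assert sig["polyA"] is False


def test_minus_strand_polya_is_t_run_upstream():
    rng = np.random.default_rng(8)
    cds = _random_cds(rng, 50)
    from retroscan.simulate import _revcomp

    chrom = _random_seq(rng, 300) + "T" * 15 + _revcomp(cds) + _random_seq(rng, 300)
    gene = make_gene("g", exons=[(315, 315 + len(cds))], strand="-", cds=cds)
    sig = retro_signature_scan(gene, {"chr1": chrom})
    assert sig["polyA"] is True


def test_contig_edge_truncates_window():
    cds = "ATG" + "GGG" * 20 + "TAA"
    chrom = cds + "A" * 12
    gene = make_gene("g", exons=[(0, len(cds))], cds=cds)
    sig = retro_signature_scan(gene, {"chr1": chrom})
    assert sig["polyA"] is True
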