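"""Curation rules: multi-gene discrimination, orphan filtering, partition."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_gene
from retroscan.curation import (
    classify_normal_genes,
    drop_orphan_multiexon,
    resolve_multi_gene_element,
)
from retroscan.detect import CandidateRecord
from retroscan.model import GenomicInterval, ParentMatch, RepeatFeature, RetroCall


def gene_with_exons(gene_id, exon_lengths, start=0):
    exons = []
    pos = start
    for n in exon_lengths:
        exons.append((pos, pos + n))
        pos += n + 100
    return make_gene(gene_id, exons=exons, cds="A" * sum(exon_lengths))


# --------------------------------------------------------------------------- multi-gene rules


@pytest.mark.parametrize(
    "spec_a, spec_b, winner",
    [
        # equal exon counts -> longest total exon length
        (((600, 600), "a"), ((400, 400), "b"), "a"),
        # one dominant exon >1.5x every neighbor exon
        (((3000,), "a"), ((1500, 1200, 900), "b"), "a"),
        # no dominant exon -> smallest exon count
        (((600, 650), "a"), ((500, 480, 520), "b"), "a"),
    ],
)
def test_discrimination_branches(spec_a, spec_b, winner):
    g1 = gene_with_exons(spec_a[1], spec_a[0], start=0)
    g2 = gene_with_exons(spec_b[1], spec_b[0], start=10_000)
    parents = {"a": True, "b": True}
    for ordering in itertools.permutations([g1, g2]):
        selected, rejected = resolve_multi_gene_element(list(ordering), parents)
        assert selected == winner
        assert rejected == [g for g in ("a", "b") if g != winner]


def test_parentless_genes_are_set_aside_first():
    g1 = gene_with_exons("a", (300,), start=0)
    g2 = gene_with_exons("b", (900,), start=10_000)  # longer, but no parent
    selected, rejected = resolve_multi_gene_element([g1, g2], {"a": True, "b": False})
    assert selected == "a"
    assert rejected == ["b"]


def test_three_genes_neighbors_are_all_others():
    dominant = gene_with_exons("dom", (4000,), start=0)
    n1 = gene_with_exons("n1", (2000, 300), start=10_000)
    n2 = gene_with_exons("n2", (1000, 800, 200), start=20_000)
    parents = dict.fromkeys(("dom", "n1", "n2"), True)
    selected, rejected = resolve_multi_gene_element([n1, dominant, n2], parents)
    assert selected == "dom"
    assert rejected == ["n1", "n2"]


def test_single_gene_and_empty_input():
    g = gene_with_exons("only", (500,))
    assert resolve_multi_gene_element([g], {}) == ("only", [])
    with pytest.raises(ValueError):
        resolve_multi_gene_element([], {})


# --------------------------------------------------------------------------- orphan filter


def _candidate(gene, parent=None, polyA=False, direct_repeats=False):
    return CandidateRecord(
        gene=gene,
        evidence_pass="full_length",
        parent=parent,
        signatures={"polyA": polyA, "direct_repeats": direct_repeats},
    )


def test_orphan_rules():
    three_exon = _candidate(gene_with_exons("orphan3", (200, 200, 200)))
    with_parent = _candidate(
        gene_with_exons("ok2", (300, 300), start=5000),
        parent=ParentMatch("p", 0.99, 0.99, 6, 2),
    )
    one_no_sig = _candidate(gene_with_exons("orphan1", (300,), start=10_000))
    one_sig = _candidate(
        gene_with_exons("sig1", (300,), start=15_000), polyA=True
    )
    kept, rejected = drop_orphan_multiexon(
        [three_exon, with_parent, one_no_sig, one_sig]
    )
    assert {c.gene.gene_id for c in kept} == {"ok2", "sig1"}
    assert {c.gene.gene_id for c in rejected} == {"orphan3", "orphan1"}
    assert all(c.verdict == "rejected_orphan_multiexon" for c in rejected)


# --------------------------------------------------------------------------- partition


def _retro_call(gene_id, verdict="retro"):
    return RetroCall(
        gene_id=gene_id, seq_id="chr1", start=0, end=10,
        evidence_pass="full_length", verdict=verdict,
    )


def test_partition_examples():
    retro = gene_with_exons("retro", (300,), start=0)
    covered = gene_with_exons("covered", (300,), start=10_000)
    clean = gene_with_exons("clean", (300,), start=50_000)
    repeats = [
        RepeatFeature(
            interval=GenomicInterval("chr1", 9_900, 10_270), name="frag",
            order="LTR", superfamily="Gypsy",
        )
    ]
    part = classify_normal_genes([retro, covered, clean], [_retro_call("retro")], repeats)
    assert part["retro"] == {"retro"}
    assert part["ambiguous"] == {"covered"}  # 270/300 = 90% LTR coverage
    assert part["normal"] == {"clean"}


@given(
    st.lists(
        st.tuples(
            st.integers(0, 50),  # gene slot
            st.booleans(),  # is retro call
        ),
        min_size=1,
        max_size=25,
        unique_by=lambda t: t[0],
    ),
    st.lists(st.integers(0, 50), max_size=10),
)
@settings(max_examples=60, derandomize=True)
def test_partition_is_exhaustive_and_disjoint(gene_specs, repeat_slots):
    genes = [
        gene_with_exons(f"g{slot}", (300,), start=slot * 1000) for slot, _ in gene_specs
    ]
    calls = [_retro_call(f"g{slot}") for slot, retro in gene_specs if retro]
    repeats = [
        RepeatFeature(
            interval=GenomicInterval("chr1", slot * 1000, slot * 1000 + 400),
            name="frag", order="LTR", superfamily="Gypsy",
        )
        for slot in repeat_slots
    ]
    part = classify_normal_genes(genes, calls, repeats)
    ids = {g.gene_id for g in genes}
    assert part["retro"] | part["ambiguous"] | part["normal"] == ids
    assert len(part["retro"]) + len(part["ambiguous"]) + len(part["normal"]) == len(ids)
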