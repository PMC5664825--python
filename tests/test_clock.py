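"""Clock formulas: K2P, K/2r and Ks/2r arithmetic, NG86, Ks clustering."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retroscan.clock import (
    ClockParams,
    SaturationError,
    duplication_time,
    insertion_age,
    k2p_distance,
    ks_single_linkage,
    ltr_insertion_time,
    ng86_ka_ks,
)
from retroscan.model import GenomicInterval, LtrElement
from retroscan.simulate import evolve_sequence

# --------------------------------------------------------------------------- K2P


def test_k2p_identity_and_hand_value():
    assert k2p_distance("ACGTACGTAC", "ACGTACGTAC") == 0.0
    # 10 sites, one transition: P=0.1, Q=0
    k = k2p_distance("A" * 9 + "G", "A" * 10)
    assert k == pytest.approx(-0.5 * math.log(0.8), abs=1e-12)


def test_k2p_excludes_gap_columns():
    assert k2p_distance("ACGT-", "ACGTA") == 0.0


def test_k2p_saturation_raises():
    with pytest.raises(SaturationError):
        k2p_distance("A" * 10, "G" * 10)


def test_k2p_recovers_simulated_divergence():
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=10_000))
    a = evolve_sequence(seq, 0.025, 2.0, seed=1)
    b = evolve_sequence(seq, 0.025, 2.0, seed=2)
    k = k2p_distance(a, b)
    se = math.sqrt(0.05 / 10_000)
    assert abs(k - 0.05) < 3 * se + 0.003  # small single-hit bias allowance


dna = st.text(alphabet="ACGT", min_size=20, max_size=60)


@given(dna)
@settings(max_examples=50, derandomize=True)
def test_k2p_symmetry(seq):
    other = evolve_sequence(seq, 0.1, 2.0, seed=7)
    if any(x != y for x, y in zip(seq, other)):
        assert k2p_distance(seq, other) == pytest.approx(k2p_distance(other, seq))


# --------------------------------------------------------------------------- age arithmetic


def test_insertion_age_arithmetic():
    assert insertion_age(0.026) == pytest.approx(1.0e6)
    assert insertion_age(0.0) == 0.0


def test_duplication_age_arithmetic():
    assert duplication_time(0.01392) == pytest.approx(1.0e6)
    assert duplication_time(0.0) == 0.0


def test_doubling_rate_halves_age():
    base = ClockParams()
    double = ClockParams(base.r_intergenic * 2, base.r_synonymous * 2)
    assert insertion_age(0.04, double) == pytest.approx(insertion_age(0.04, base) / 2)
    assert duplication_time(0.04, double) == pytest.approx(duplication_time(0.04, base) / 2)


def test_identical_ltrs_give_age_zero():
    ltr = "ACGTAC" * 50
    chrom = "T" * 100 + ltr + "G" * 500 + ltr + "C" * 100
    elem = LtrElement(
        element_id="e1",
        span=GenomicInterval("chr1", 100, 100 + 300 + 500 + 300),
        ltr5=GenomicInterval("chr1", 100, 400),
        ltr3=GenomicInterval("chr1", 900, 1200),
    )
    assert ltr_insertion_time(elem, {"chr1": chrom}) == 0.0


# --------------------------------------------------------------------------- NG86

CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
]
from Bio.Data.CodonTable import standard_dna_table

AA = dict(standard_dna_table.forward_table)
for stop in standard_dna_table.stop_codons:
    AA[stop] = "*"
NON_STOP = [c for c in CODONS if AA[c] != "*"]


def oracle_sites(codon):
    """Brute-force synonymous site count: stop-creating changes count nonsynonymous."""
    syn = 0.0
    for pos, base in itertools.product(range(3), "ACGT"):
        if base == codon[pos]:
            continue
        mut = codon[:pos] + base + codon[pos + 1 :]
        if AA[mut] == AA[codon] != "*":
            syn += 1 / 3
    return syn


def oracle_diffs(c1, c2):
    """Brute-force pathway enumeration, excluding paths through stop codons."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur, sd, nd, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if AA[cur] == AA[nxt] != "*":
                sd += 1
            else:
                nd += 1
            if AA[nxt] == "*" and nxt != c2:
                ok = False
            cur = nxt
        paths.append((sd, nd, ok))
    valid = [p for p in paths if p[2]] or paths
    return (
        sum(p[0] for p in valid) / len(valid),
        sum(p[1] for p in valid) / len(valid),
    )


def oracle_ng86_counts(seq_a, seq_b):
    S = sum(oracle_sites(c) for c in _codons(seq_a)) / 2 + sum(
        oracle_sites(c) for c in _codons(seq_b)
    ) / 2
    sd = nd = 0.0
    for ca, cb in zip(_codons(seq_a), _codons(seq_b)):
        s, n = oracle_diffs(ca, cb)
        sd += s
        nd += n
    return S, sd, nd


def _codons(seq):
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def test_ng86_identical_sequences():
    cds = "ATGGGGCCCAAA"
    rates = ng86_ka_ks(cds, cds)
    assert rates.Ka == rates.Ks == 0.0


def test_ng86_pure_synonymous_change():
    # GGG->GGA is third-position synonymous (both Gly)
    a = "ATG" + "GGG" * 9
    b = "ATG" + "GGA" + "GGG" * 8
    rates = ng86_ka_ks(a, b)
    assert rates.Ka == 0.0
    assert rates.Ks > 0.0
    assert rates.ka_ks == 0.0


def test_ng86_pure_nonsynonymous_change():
    a = "ATG" + "AAA" * 9  # Lys
    b = "ATG" + "GAA" + "AAA" * 8  # Glu at codon 2
    rates = ng86_ka_ks(a, b)
    assert rates.Ks == 0.0
    assert rates.Ka > 0.0


def test_ng86_sites_sum_to_sequence_length():
    rng = np.random.default_rng(3)
    cds = "".join(rng.choice(NON_STOP, size=40))
    rates = ng86_ka_ks(cds, cds)
    assert rates.syn_sites + rates.nonsyn_sites == pytest.approx(len(cds))


def test_ng86_internal_stop_raises_unless_skipped():
    a = "ATG" + "TAA" + "AAA"
    b = "ATG" + "TAA" + "AAA"
    with pytest.raises(ValueError):
        ng86_ka_ks(a, b)
    rates = ng86_ka_ks(a, b, skip_stops=True)
    assert rates.codons_compared == 2


def test_ng86_counts_match_bruteforce_oracle():
    rng = np.random.default_rng(12)
    for _ in range(20):
        a = "".join(rng.choice(NON_STOP, size=30))
        b = evolve_sequence(a, 0.08, 2.0, rng=rng)
        if any(AA[c] == "*" for c in _codons(b)):
            continue
        rates = ng86_ka_ks(a, b)
        S, sd, nd = oracle_ng86_counts(a, b)
        assert rates.syn_sites == pytest.approx(S)
        assert rates.syn_diffs == pytest.approx(sd)
        assert rates.nonsyn_diffs == pytest.approx(nd)


def test_ng86_dnds_cross_checks_against_biopython():
    """Independent library check on single-position codon differences."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
    rng = np.random.default_rng(5)
    a = "".join(rng.choice(NON_STOP, size=40))
    codons = _codons(a)
    mutated = []
    for c in codons:  # at most one substitution per codon
        if rng.random() < 0.4:
            pos = int(rng.integers(3))
            base = str(rng.choice([x for x in "ACGT" if x != c[pos]]))
            new = c[:pos] + base + c[pos + 1 :]
            c = new if AA[new] != "*" else c
        mutated.append(c)
    b = "".join(mutated)
    dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
    rates = ng86_ka_ks(a, b)
    assert rates.Ka == pytest.approx(dn, abs=1e-9)
    assert rates.Ks == pytest.approx(ds, abs=1e-9)


# --------------------------------------------------------------------------- Ks clustering


def union_find_oracle(pairs, cutoff, genes):
    parent = {g: g for g in genes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (a, b), ks in pairs.items():
        if ks <= cutoff and a != b:
            parent[find(a)] = find(b)
    groups = {}
    for g in genes:
        groups.setdefault(find(g), set()).add(g)
    return sorted(tuple(sorted(s)) for s in groups.values())


def test_single_linkage_examples():
    assert ks_single_linkage({}, 0.02, genes=["a"])[0]["members"] == ("a",)
    clusters = ks_single_linkage(
        {("a", "b"): 0.01, ("b", "c"): 0.01, ("a", "c"): 0.5}, 0.02
    )
    assert len(clusters) == 1
    assert clusters[0]["members"] == ("a", "b", "c")
    assert clusters[0]["min_ks"] == 0.01


def test_single_linkage_matches_union_find_oracle():
    rng = np.random.default_rng(8)
    for _ in range(100):
        n = int(rng.integers(1, 13))
        genes = [f"g{i}" for i in range(n)]
        pairs = {}
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.5:
                    pairs[(genes[i], genes[j])] = float(rng.random())
        cutoff = float(rng.random() * 0.5)
        result = ks_single_linkage(pairs, cutoff, genes=genes)
        assert sorted(c["members"] for c in result) == union_find_oracle(
            pairs, cutoff, genes
        )
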