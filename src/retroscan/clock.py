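"""Molecular-clock dating of LTR-element insertions and gene duplications.

Two clocks are used, following common practice for plant genomes:

* insertion age of a full-length LTR element = K / (2 r), where K is the
  Kimura two-parameter (K2P) distance between its 5' and 3' LTRs, which are
  identical at integration, and r = 1.3e-8 substitutions/site/year, the
  faster intergenic rate;
* duplication age of a gene pair = Ks / (2 r), with Ks the synonymous
  substitution rate (Nei-Gojobori 1986 with Jukes-Cantor correction) and
  r = 6.96e-9 substitutions per synonymous site per year.

Duplication events within a family are grouped by single-linkage clustering
of pairwise Ks values under a cutoff.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from math import log
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
from Bio import Align
from Bio.Data.CodonTable import standard_dna_table

from .model import LtrElement

__all__ = [
    "ClockParams",
    "PairwiseRates",
    "SaturationError",
    "k2p_distance",
    "insertion_age",
    "ltr_insertion_time",
    "ng86_ka_ks",
    "duplication_time",
    "ks_single_linkage",
    "align_pair",
]

YEARS_PER_MY = 1e6

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_BASES = "ACGT"

_CODON_AA: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_AA[_stop] = "*"


class SaturationError(ValueError):
    """Observed divergence too high for the distance correction to be defined."""


@dataclass(frozen=True)
class ClockParams:
    """Substitution rates (substitutions/site/year) for the two clocks."""

    r_intergenic: float = 1.3e-8
    r_synonymous: float = 6.96e-9

    def __post_init__(self) -> None:
        if self.r_intergenic <= 0 or self.r_synonymous <= 0:
            raise ValueError("clock rates must be positive")


DEFAULT_CLOCK = ClockParams()


@dataclass(frozen=True)
class PairwiseRates:
    """Pairwise substitution statistics for one coding-sequence pair."""

    K: Optional[float]
    Ka: float
    Ks: float
    ka_ks: Optional[float]
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    codons_compared: int


def _is_transition(x: str, y: str) -> bool:
    return (x in _PURINES and y in _PURINES) or (x in _PYRIMIDINES and y in _PYRIMIDINES)


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """Kimura two-parameter distance between two aligned nucleotide sequences.

    Gap columns and ambiguous bases are excluded from the site counts.
    Raises :class:`SaturationError` when the log arguments are non-positive.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    sites = transitions = transversions = 0
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        if x not in _BASES or y not in _BASES:
            continue
        sites += 1
        if x == y:
            continue
        if _is_transition(x, y):
            transitions += 1
        else:
            transversions += 1
    if sites == 0:
        raise ValueError("no comparable (ungapped) sites")
    P = transitions / sites
    Q = transversions / sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"K2P undefined for P={P:.3f}, Q={Q:.3f}")
    return -0.5 * log(w1) - 0.25 * log(w2)


def align_pair(seq_a: str, seq_b: str, *, local: bool = False) -> tuple[str, str]:
    """Align two sequences and return the two gapped rows.

    Global alignments leave end gaps free, which suits LTR pairs whose
    boundaries are approximate.
    """
    aligner = Align.PairwiseAligner()
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    if local:
        aligner.mode = "local"
    else:
        aligner.mode = "global"
        try:
            aligner.end_insertion_score = 0
            aligner.end_deletion_score = 0
        except AttributeError:  # older PairwiseAligner API
            aligner.target_end_gap_score = 0
            aligner.query_end_gap_score = 0
    alignment = aligner.align(seq_a, seq_b)[0]
    return str(alignment[0]), str(alignment[1])


def insertion_age(k: float, params: ClockParams = DEFAULT_CLOCK) -> float:
    """Insertion age in years from an LTR-pair distance, K / (2 r_intergenic)."""
    if k < 0:
        raise ValueError("K must be non-negative")
    return k / (2.0 * params.r_intergenic)


def ltr_insertion_time(
    element: LtrElement,
    sequences: Mapping[str, str],
    params: ClockParams = DEFAULT_CLOCK,
) -> float:
    """Insertion age of a full-length element in years, K / (2 r_intergenic).

    The 5' and 3' LTR sequences are extracted, globally aligned (free end
    gaps), and their K2P distance converted to years. Saturation propagates
    as :class:`SaturationError` ("age not estimable").
    """
    chrom = sequences.get(element.span.seq_id)
    if chrom is None:
        raise ValueError(f"no sequence for {element.span.seq_id}")
    ltr5 = chrom[element.ltr5.start : element.ltr5.end]
    ltr3 = chrom[element.ltr3.start : element.ltr3.end]
    row5, row3 = align_pair(ltr5, ltr3)
    return insertion_age(k2p_distance(row5, row3), params)


def duplication_time(ks: float, params: ClockParams = DEFAULT_CLOCK) -> float:
    """Duplication age of a gene pair in years, Ks / (2 r_synonymous)."""
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    return ks / (2.0 * params.r_synonymous)


# --------------------------------------------------------------------------- NG86

@lru_cache(maxsize=None)
def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon.

    Each position contributes its fraction of synonymous single-nucleotide
    neighbours out of three; changes creating a stop codon count as
    nonsynonymous, keeping the per-codon total at exactly 3.
    """
    aa = _CODON_AA[codon]
    syn = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            neighbor = codon[:pos] + base + codon[pos + 1 :]
            if _CODON_AA[neighbor] == aa and aa != "*":
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _codon_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences for a codon pair.

    All mutational orderings between the codons are enumerated; pathways
    passing through a stop codon are excluded (when every pathway is blocked,
    all are used, stop steps counting as nonsynonymous).
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths: list[tuple[float, float, bool]] = []  # (sd, nd, passes_through_stop)
    for order in itertools.permutations(diff_pos):
        current = codon_a
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if _CODON_AA[current] == _CODON_AA[nxt] and _CODON_AA[current] != "*":
                sd += 1.0
            else:
                nd += 1.0
            if _CODON_AA[nxt] == "*" and nxt != codon_b:
                blocked = True
            current = nxt
        paths.append((sd, nd, blocked))
    valid = [p for p in paths if not p[2]] or paths
    sd = sum(p[0] for p in valid) / len(valid)
    nd = sum(p[1] for p in valid) / len(valid)
    return sd, nd


def _jc_correct(p: float, label: str) -> float:
    if p >= 0.75:
        raise SaturationError(f"{label} proportion {p:.3f} beyond Jukes-Cantor domain")
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


def ng86_ka_ks(cds_a: str, cds_b: str, *, skip_stops: bool = False) -> PairwiseRates:
    """Nei-Gojobori (1986) Ka/Ks for a pair of aligned coding sequences.

    Site counts are averaged over both sequences; pathway-averaged
    differences receive the Jukes-Cantor correction per class. Codon columns
    containing a gap are skipped; columns containing a stop codon raise
    unless ``skip_stops`` is set (useful for possibly pseudogenized
    retrocopies), in which case they are skipped too.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError("coding sequences must be aligned to equal length")
    if len(cds_a) % 3 != 0:
        raise ValueError("aligned length must be a multiple of 3")
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    syn_sites_a = syn_sites_b = 0.0
    syn_diffs = nonsyn_diffs = 0.0
    codons = 0
    n_codons = len(cds_a) // 3
    for i in range(n_codons):
        ca = cds_a[3 * i : 3 * i + 3]
        cb = cds_b[3 * i : 3 * i + 3]
        if any(c not in _BASES for c in ca + cb):
            continue
        is_stop = _CODON_AA[ca] == "*" or _CODON_AA[cb] == "*"
        internal = i < n_codons - 1
        if is_stop and internal and not skip_stops:
            raise ValueError(f"internal stop codon at codon {i}")
        if is_stop:
            continue
        codons += 1
        syn_sites_a += _codon_sites(ca)[0]
        syn_sites_b += _codon_sites(cb)[0]
        sd, nd = _codon_diffs(ca, cb)
        syn_diffs += sd
        nonsyn_diffs += nd
    if codons == 0:
        raise ValueError("no comparable codons")
    S = (syn_sites_a + syn_sites_b) / 2.0
    N = 3.0 * codons - S
    ks = _jc_correct(syn_diffs / S, "synonymous") if S > 0 else 0.0
    ka = _jc_correct(nonsyn_diffs / N, "nonsynonymous") if N > 0 else 0.0
    try:
        K = k2p_distance(cds_a, cds_b)
    except (SaturationError, ValueError):
        K = None
    return PairwiseRates(
        K=K,
        Ka=ka,
        Ks=ks,
        ka_ks=(ka / ks) if ks > 0 else None,
        syn_sites=S,
        nonsyn_sites=N,
        syn_diffs=syn_diffs,
        nonsyn_diffs=nonsyn_diffs,
        codons_compared=codons,
    )


# --------------------------------------------------------------------------- Ks clustering

def ks_single_linkage(
    ks_pairs: Mapping[tuple[str, str], float],
    cutoff: float,
    genes: Optional[Iterable[str]] = None,
    params: ClockParams = DEFAULT_CLOCK,
) -> list[dict]:
    """Group genes into duplication events by single-linkage Ks clustering.

    Connected components of the graph joining pairs with Ks <= cutoff;
    missing pairs are treated as infinitely distant. Each cluster reports the
    event age from its smallest Ks (``None`` for singletons).

    Returns a list of ``{"members", "min_ks", "age_years"}`` dicts sorted by
    first member.
    """
    graph = nx.Graph()
    if genes is not None:
        graph.add_nodes_from(genes)
    for (a, b), ks in ks_pairs.items():
        graph.add_node(a)
        graph.add_node(b)
        if a != b and ks <= cutoff:
            graph.add_edge(a, b)
    clusters = []
    for component in nx.connected_components(graph):
        members = tuple(sorted(component))
        intra = [
            ks
            for (a, b), ks in ks_pairs.items()
            if a in component and b in component and a != b
        ]
        min_ks = min(intra) if intra else None
        clusters.append(
            {
                "members": members,
                "min_ks": min_ks,
                "age_years": duplication_time(min_ks, params) if min_ks is not None else None,
            }
        )
    return sorted(clusters, key=lambda c: c["members"][0])
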