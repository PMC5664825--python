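"""Synthetic genomes with planted retroduplication events and known truth.

The generator emulates the genomic structures the detection pipeline relies
on: multi-exon parent genes, intron-less (or intron-reduced) retrocopies
inserted between freshly duplicated LTR pairs, poly(A) tracts, target-site
duplications, autonomous elements with a long pol-like ORF, decayed elements
reduced to partial LTR fragments, and the decoy configurations that each
curation rule must reject (class II TE conflicts, parentless multi-exon
genes, multi-gene elements, solo LTRs). LTR pairs are identical at
insertion and each copy then accumulates substitutions at the intergenic
rate times the target age, so K2P dating can recover the planted ages.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .clock import DEFAULT_CLOCK
from .model import (
    AnnotationBundle,
    GeneModel,
    GenomicInterval,
    LtrElement,
    RepeatFeature,
)

__all__ = [
    "SimConfig",
    "TruthRecord",
    "SimulationSizeError",
    "evolve_sequence",
    "simulate_genome",
    "write_outputs",
    "write_truth",
    "read_truth",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_STOPS = ("TAA", "TAG", "TGA")


class SimulationSizeError(ValueError):
    """Planted events do not fit in the configured chromosome length."""


@dataclass
class SimConfig:
    """Study conditions for one synthetic genome.

    Counts and fractions mirror the structures the analysis assumes:
    ~28% of elements autonomous (the field reports ~72% non-autonomous),
    ~30% of retrocopies keeping one intron (intron retention), retrocopy
    CDS divergence 0.02/site from the parent, insertion ages cycling
    0.2-1.8 MY so LTR pairs stay below ~5% divergence.
    """

    n_chromosomes: int = 2
    chromosome_length: int = 300_000
    n_parent_genes: int = 12
    exons_per_parent: tuple[int, int] = (2, 8)
    parent_cds_codons: tuple[int, int] = (300, 500)
    n_retro_events: int = 20
    fraction_autonomous: float = 0.28
    fraction_partial_elements: float = 0.2
    fraction_multi_exon_retro: float = 0.3
    target_ages_my: tuple[float, ...] = (0.2, 0.6, 1.0, 1.4, 1.8)
    mutation_rate: float = 0.02
    ts_tv_ratio: float = 2.0
    polyA_length: int = 15
    tsd_length: int = 8
    ltr_length: int = 500
    orf_length: int = 3000
    n_decoys: dict = field(
        default_factory=lambda: {
            "te_conflict": 2,
            "orphan_multiexon": 2,
            "multi_gene_element": 3,
            "solo_ltr": 3,
            "background_te": 4,
        }
    )
    family_label: str = "CNL-G2"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chromosomes, self.n_parent_genes, self.n_retro_events) < 0:
            raise ValueError("counts must be non-negative")
        for frac in (
            self.fraction_autonomous,
            self.fraction_partial_elements,
            self.fraction_multi_exon_retro,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.mutation_rate < 0:
            raise ValueError("mutation rate must be non-negative")


@dataclass
class TruthRecord:
    """One planted event (or decoy) for recovery scoring."""

    event_id: str
    parent_gene_id: Optional[str]
    retro_gene_id: Optional[str]
    element_id: Optional[str]
    introns_lost: int
    autonomy: str
    planted_age_my: float
    polyA: bool
    direct_repeats: bool
    decoy_class: Optional[str] = None

    @property
    def is_true_retro(self) -> bool:
        return self.decoy_class is None


# --------------------------------------------------------------------------- primitives

def _random_seq(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, 4, size=n)
    return _BASES[idx].tobytes().decode()


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def evolve_sequence(
    seq: str,
    rate: float,
    ts_tv_ratio: float = 2.0,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> str:
    """Apply independent per-site substitutions with transition bias.

    Each site mutates with probability ``rate``; a mutated site becomes the
    transition partner with probability ts_tv_ratio/(ts_tv_ratio+1), else
    one of its two transversion partners. Non-ACGT characters are left
    untouched.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    if rate == 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    idx = np.full(arr.shape, -1, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        idx[arr == bytes([b])] = i
    hit = (rng.random(arr.shape) < rate) & (idx >= 0)
    n_hit = int(hit.sum())
    if n_hit == 0:
        return seq
    p_transition = ts_tv_ratio / (ts_tv_ratio + 1.0)
    is_ts = rng.random(n_hit) < p_transition
    coin = rng.integers(0, 2, size=n_hit)
    old = idx[hit]
    new = np.where(is_ts, (old + 2) % 4, (old + 1 + 2 * coin) % 4)
    arr[hit] = _BASES[new]
    return arr.tobytes().decode()


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random CDS: ATG start, non-stop internal codons, one stop at the end."""
    non_stop = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in _STOPS
    ]
    body = [non_stop[i] for i in rng.integers(0, len(non_stop), size=n_codons - 2)]
    stop = _STOPS[rng.integers(0, 3)]
    return "ATG" + "".join(body) + stop


def _split_exons(
    rng: np.random.Generator, cds: str, n_exons: int, min_exon: int = 60
) -> list[str]:
    """Split a CDS into n_exons pieces, each at least ``min_exon`` nt.

    Cut points are near-even with random jitter, which guarantees validity
    for any feasible exon count.
    """
    n = len(cds)
    if n_exons * min_exon > n:
        n_exons = max(1, n // min_exon)
    if n_exons == 1:
        return [cds]
    base = n / n_exons
    jitter_max = max(1, min(20, int(base / 4)))
    cuts = []
    for i in range(1, n_exons):
        jitter = int(rng.integers(-jitter_max, jitter_max + 1))
        cuts.append(int(round(i * base)) + jitter)
    bounds = [0, *cuts, n]
    return [cds[a:b] for a, b in zip(bounds, bounds[1:])]


def _intron(rng: np.random.Generator, lo: int = 80, hi: int = 800) -> str:
    # log-uniform length, canonical GT..AG boundaries
    length = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return "GT" + _random_seq(rng, max(length - 4, 1)) + "AG"


def _orf_seq(rng: np.random.Generator, length_nt: int) -> str:
    return _random_cds(rng, max(length_nt // 3, 3))


# --------------------------------------------------------------------------- block builders

@dataclass
class _GeneSpec:
    gene_id: str
    strand: str
    exon_offsets: list[tuple[int, int]]  # relative, ascending genomic order
    cds: str  # transcript sense
    family: Optional[str]
    is_nlr: bool


@dataclass
class _Block:
    """A sequence block plus relative annotations, placed later."""

    seq: str
    genes: list[_GeneSpec] = field(default_factory=list)
    element: Optional[dict] = None  # id, ltr5, ltr3, tsd offsets
    repeats: list[tuple[int, int, str, str, str]] = field(default_factory=list)
    # (rel_start, rel_end, name, class/family, strand)


def _gene_block(
    rng: np.random.Generator,
    gene_id: str,
    cds: str,
    n_exons: int,
    family: Optional[str],
    is_nlr: bool,
    strand: Optional[str] = None,
    polyA: int = 0,
    split_points: Optional[list[int]] = None,
) -> _Block:
    """Build a gene (optionally with introns and a trailing poly(A) tract)."""
    if split_points is not None:
        bounds = [0, *split_points, len(cds)]
        exon_seqs = [cds[a:b] for a, b in zip(bounds, bounds[1:])]
    else:
        exon_seqs = _split_exons(rng, cds, n_exons)
    parts: list[str] = []
    offsets: list[tuple[int, int]] = []
    pos = 0
    for i, exon in enumerate(exon_seqs):
        offsets.append((pos, pos + len(exon)))
        parts.append(exon)
        pos += len(exon)
        if i < len(exon_seqs) - 1:
            intron = _intron(rng)
            parts.append(intron)
            pos += len(intron)
    fwd = "".join(parts)
    if polyA:
        fwd += "A" * polyA
    if strand is None:
        strand = "+" if rng.integers(0, 2) == 0 else "-"
    if strand == "-":
        total = len(fwd)
        offsets = [(total - e, total - s) for s, e in offsets][::-1]
        fwd = _revcomp(fwd)
    return _Block(seq=fwd, genes=[_GeneSpec(gene_id, strand, sorted(offsets), cds, family, is_nlr)])


def _element_block(
    rng: np.random.Generator,
    element_id: str,
    inner_blocks: list[_Block],
    cfg: SimConfig,
    age_my: float,
    autonomous: bool,
    superfamily: str = "Gypsy",
) -> _Block:
    """Assemble TSD + 5'LTR + internal region (genes, optional ORF) + 3'LTR + TSD."""
    ltr = _random_seq(rng, cfg.ltr_length)
    per_ltr_rate = DEFAULT_CLOCK.r_intergenic * age_my * 1e6
    ltr5 = evolve_sequence(ltr, per_ltr_rate, cfg.ts_tv_ratio, rng=rng)
    ltr3 = evolve_sequence(ltr, per_ltr_rate, cfg.ts_tv_ratio, rng=rng)
    tsd = _random_seq(rng, cfg.tsd_length)

    parts: list[str] = [tsd, ltr5]
    pos = len(tsd) + len(ltr5)
    out = _Block(seq="")
    spacer = _random_seq(rng, int(rng.integers(150, 400)))
    parts.append(spacer)
    pos += len(spacer)
    for inner in inner_blocks:
        for gs in inner.genes:
            out.genes.append(
                _GeneSpec(
                    gs.gene_id,
                    gs.strand,
                    [(s + pos, e + pos) for s, e in gs.exon_offsets],
                    gs.cds,
                    gs.family,
                    gs.is_nlr,
                )
            )
        for rs, re_, name, cls, strand in inner.repeats:
            out.repeats.append((rs + pos, re_ + pos, name, cls, strand))
        parts.append(inner.seq)
        pos += len(inner.seq)
        spacer = _random_seq(rng, int(rng.integers(150, 400)))
        parts.append(spacer)
        pos += len(spacer)
    if autonomous:
        orf = _orf_seq(rng, cfg.orf_length)
        parts.append(orf)
        pos += len(orf)
        spacer = _random_seq(rng, int(rng.integers(100, 250)))
        parts.append(spacer)
        pos += len(spacer)
    ltr3_start = pos
    parts.append(ltr3)
    pos += len(ltr3)
    parts.append(tsd)

    t = cfg.tsd_length
    out.seq = "".join(parts)
    out.element = {
        "id": element_id,
        "ltr5": (t, t + len(ltr5)),
        "ltr3": (ltr3_start, ltr3_start + len(ltr3)),
        "tsd": ((0, t), (pos, pos + t)) if t else None,
    }
    cls = f"LTR/{superfamily}"
    out.repeats = [
        (t, t + len(ltr5), f"{element_id}_LTR", cls, "+"),
        (t + len(ltr5), ltr3_start, f"{element_id}_INT", cls, "+"),
        (ltr3_start, ltr3_start + len(ltr3), f"{element_id}_LTR", cls, "+"),
    ] + out.repeats
    return out


def _partial_block(
    rng: np.random.Generator,
    name: str,
    inner: _Block,
    cfg: SimConfig,
    age_my: float,
) -> _Block:
    """A decayed element: LTR fragments flanking the retrocopy, no full element."""
    ltr = _random_seq(rng, cfg.ltr_length)
    per_ltr_rate = DEFAULT_CLOCK.r_intergenic * age_my * 1e6
    frag_len = int(cfg.ltr_length * 0.6)
    left = evolve_sequence(ltr, per_ltr_rate, cfg.ts_tv_ratio, rng=rng)[:frag_len]
    right = evolve_sequence(ltr, per_ltr_rate, cfg.ts_tv_ratio, rng=rng)[-frag_len:]
    pad = _random_seq(rng, 40)
    pad2 = _random_seq(rng, 40)
    seq = left + pad + inner.seq + pad2 + right
    gene_off = len(left) + len(pad)
    out = _Block(seq=seq)
    for gs in inner.genes:
        out.genes.append(
            _GeneSpec(
                gs.gene_id,
                gs.strand,
                [(s + gene_off, e + gene_off) for s, e in gs.exon_offsets],
                gs.cds,
                gs.family,
                gs.is_nlr,
            )
        )
    cls = "LTR/Copia"
    out.repeats = [
        (0, frag_len, f"{name}_L", cls, "+"),
        (frag_len, frag_len + len(pad) + len(inner.seq) + len(pad2), f"{name}_I", cls, "+"),
        (frag_len + len(pad) + len(inner.seq) + len(pad2), len(seq), f"{name}_R", cls, "+"),
    ]
    return out


# --------------------------------------------------------------------------- placement

class _ChromBuilder:
    def __init__(self, name: str, length: int, rng: np.random.Generator):
        self.name = name
        self.length = length
        self.rng = rng
        self.chunks: list[str] = []
        self.cursor = 0

    def gap(self, lo: int = 500, hi: int = 2000) -> None:
        n = int(self.rng.integers(lo, hi))
        self.chunks.append(_random_seq(self.rng, n))
        self.cursor += n

    def place(self, block: _Block) -> int:
        start = self.cursor
        if start + len(block.seq) > self.length:
            raise SimulationSizeError(
                f"block of {len(block.seq)} nt does not fit on {self.name} "
                f"(cursor {start}, length {self.length}); increase "
                f"chromosome_length or reduce planted events"
            )
        self.chunks.append(block.seq)
        self.cursor += len(block.seq)
        return start

    def finish(self) -> str:
        if self.cursor < self.length:
            self.chunks.append(_random_seq(self.rng, self.length - self.cursor))
        return "".join(self.chunks)


# --------------------------------------------------------------------------- main generator

def simulate_genome(config: SimConfig) -> tuple[AnnotationBundle, list[TruthRecord]]:
    """Generate a genome, annotations, and the truth table, from the seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    chroms = [
        _ChromBuilder(f"chr{i + 1}", cfg.chromosome_length, rng)
        for i in range(cfg.n_chromosomes)
    ]
    placements: list[tuple[_Block, _ChromBuilder, int]] = []

    def place(block: _Block) -> tuple[str, int]:
        builder = min(chroms, key=lambda c: (c.cursor, c.name))
        builder.gap()
        start = builder.place(block)
        placements.append((block, builder, start))
        return builder.name, start

    truth: list[TruthRecord] = []
    parent_specs: list[tuple[str, str, int]] = []  # (gene_id, cds, exon_count)

    # ---- background parent genes (the "normal" family members)
    lo_e, hi_e = cfg.exons_per_parent
    lo_c, hi_c = cfg.parent_cds_codons
    for i in range(cfg.n_parent_genes):
        gid = f"P{i + 1:03d}"
        cds = _random_cds(rng, int(rng.integers(lo_c, hi_c + 1)))
        n_exons = int(rng.integers(max(lo_e, 2), hi_e + 1))
        block = _gene_block(rng, gid, cds, n_exons, cfg.family_label, True)
        n_exons = len(block.genes[0].exon_offsets)
        parent_specs.append((gid, cds, n_exons))
        place(block)

    def make_parent(gid: str, n_codons: int, n_exons: int) -> tuple[str, int]:
        cds = _random_cds(rng, n_codons)
        block = _gene_block(rng, gid, cds, n_exons, cfg.family_label, True)
        place(block)
        return cds, len(block.genes[0].exon_offsets)

    # ---- planted retro events (full-length and decayed elements)
    n_partial = int(round(cfg.fraction_partial_elements * cfg.n_retro_events))
    n_full = cfg.n_retro_events - n_partial
    n_auto = int(round(cfg.fraction_autonomous * n_full))
    auto_flags = np.zeros(n_full, dtype=bool)
    if n_full:
        auto_flags[rng.choice(n_full, size=n_auto, replace=False)] = True
    n_multi = int(round(cfg.fraction_multi_exon_retro * cfg.n_retro_events))
    multi_flags = np.zeros(cfg.n_retro_events, dtype=bool)
    if cfg.n_retro_events:
        multi_flags[rng.choice(cfg.n_retro_events, size=n_multi, replace=False)] = True

    ages = list(cfg.target_ages_my) or [0.0]
    for i in range(cfg.n_retro_events):
        is_partial = i >= n_full
        parent_id, parent_cds, parent_exons = parent_specs[i % len(parent_specs)]
        age = ages[i % len(ages)]
        retro_id = f"R{i + 1:03d}"
        retro_cds = evolve_sequence(parent_cds, cfg.mutation_rate, cfg.ts_tv_ratio, rng=rng)
        n_exons = 2 if (multi_flags[i] and parent_exons > 2) else 1
        gene = _gene_block(
            rng, retro_id, retro_cds, n_exons, cfg.family_label, True, polyA=cfg.polyA_length
        )
        if is_partial:
            block = _partial_block(rng, f"PF{i + 1:03d}", gene, cfg, age)
            place(block)
            truth.append(
                TruthRecord(
                    event_id=f"EV{i + 1:03d}",
                    parent_gene_id=parent_id,
                    retro_gene_id=retro_id,
                    element_id=None,
                    introns_lost=parent_exons - n_exons,
                    autonomy="unknown",
                    planted_age_my=age,
                    polyA=True,
                    direct_repeats=False,
                )
            )
        else:
            autonomous = bool(auto_flags[i])
            eid = f"E{i + 1:03d}"
            block = _element_block(rng, eid, [gene], cfg, age, autonomous)
            place(block)
            truth.append(
                TruthRecord(
                    event_id=f"EV{i + 1:03d}",
                    parent_gene_id=parent_id,
                    retro_gene_id=retro_id,
                    element_id=eid,
                    introns_lost=parent_exons - n_exons,
                    autonomy="autonomous" if autonomous else "non_autonomous",
                    planted_age_my=age,
                    polyA=True,
                    direct_repeats=cfg.tsd_length >= 4,
                )
            )

    # ---- decoys
    decoys = cfg.n_decoys
    # class II TE conflict: a retro-like gene inside an element, but the gene
    # is (mis)annotated as a DNA transposon / Helitron -> element prediction wrong
    for j in range(decoys.get("te_conflict", 0)):
        parent_id, parent_cds, parent_exons = parent_specs[j % len(parent_specs)]
        gid = f"DC{j + 1:03d}"
        gene = _gene_block(rng, gid, parent_cds, 1, cfg.family_label, True, polyA=0)
        gene_span = (
            min(s for s, _ in gene.genes[0].exon_offsets),
            max(e for _, e in gene.genes[0].exon_offsets),
        )
        gene_len = gene_span[1] - gene_span[0]
        cls = "DNA/hAT" if j % 2 == 0 else "RC/Helitron"
        gene.repeats.append(
            (
                gene_span[0] + int(0.1 * gene_len),
                gene_span[0] + int(0.9 * gene_len),
                f"{gid}_TE",
                cls,
                "+",
            )
        )
        block = _element_block(rng, f"EC{j + 1:03d}", [gene], cfg, ages[j % len(ages)], False)
        place(block)
        truth.append(
            TruthRecord(
                event_id=f"DTC{j + 1:03d}",
                parent_gene_id=parent_id,
                retro_gene_id=gid,
                element_id=f"EC{j + 1:03d}",
                introns_lost=parent_exons - 1,
                autonomy="non_autonomous",
                planted_age_my=ages[j % len(ages)],
                polyA=False,
                direct_repeats=True,
                decoy_class="te_conflict",
            )
        )
    # parentless multi-exon gene inside an element (unclear case)
    for j in range(decoys.get("orphan_multiexon", 0)):
        gid = f"DO{j + 1:03d}"
        cds = _random_cds(rng, int(rng.integers(lo_c, hi_c + 1)))
        gene = _gene_block(rng, gid, cds, 3, cfg.family_label, True, polyA=0)
        block = _element_block(rng, f"EO{j + 1:03d}", [gene], cfg, ages[j % len(ages)], False)
        place(block)
        truth.append(
            TruthRecord(
                event_id=f"DOR{j + 1:03d}",
                parent_gene_id=None,
                retro_gene_id=gid,
                element_id=f"EO{j + 1:03d}",
                introns_lost=0,
                autonomy="non_autonomous",
                planted_age_my=ages[j % len(ages)],
                polyA=False,
                direct_repeats=True,
                decoy_class="orphan_multiexon",
            )
        )
    # multi-gene elements exercising each discrimination branch
    n_event = cfg.n_retro_events
    for j in range(decoys.get("multi_gene_element", 0)):
        branch = j % 3 + 1
        pid_a = f"PM{2 * j + 1:03d}"
        pid_b = f"PM{2 * j + 2:03d}"
        eid = f"EM{j + 1:03d}"
        retro_id = f"RM{j + 1:03d}"
        decoy_id = f"DM{j + 1:03d}"
        age = ages[j % len(ages)]
        if branch == 1:  # equal exon counts: planted retro has the longer exon
            cds_a, exons_a = make_parent(pid_a, 400, 4)
            cds_b, exons_b = make_parent(pid_b, 200, 3)
            retro = _gene_block(rng, retro_id, cds_a, 1, cfg.family_label, True, polyA=cfg.polyA_length)
            decoy = _gene_block(rng, decoy_id, cds_b, 1, cfg.family_label, True, polyA=cfg.polyA_length)
            decoy_exons = 1
        elif branch == 2:  # dominant long exon vs a 3-exon neighbor
            cds_a, exons_a = make_parent(pid_a, 500, 4)
            cds_b, exons_b = make_parent(pid_b, 200, 6)
            retro = _gene_block(rng, retro_id, cds_a, 1, cfg.family_label, True, polyA=cfg.polyA_length)
            decoy = _gene_block(rng, decoy_id, cds_b, 3, cfg.family_label, True, polyA=cfg.polyA_length)
            decoy_exons = 3
        else:  # no dominant exon: smallest exon count wins
            cds_a, exons_a = make_parent(pid_a, 200, 3)
            cds_b, exons_b = make_parent(pid_b, 330, 4)
            retro = _gene_block(rng, retro_id, cds_a, 1, cfg.family_label, True, polyA=cfg.polyA_length)
            # exact half split keeps both decoy exons below the 1.5-fold
            # dominance bound in either direction
            decoy = _gene_block(
                rng, decoy_id, cds_b, 2, cfg.family_label, True,
                polyA=cfg.polyA_length, split_points=[len(cds_b) // 2],
            )
            decoy_exons = 2
        block = _element_block(rng, eid, [retro, decoy], cfg, age, False)
        place(block)
        n_event += 1
        truth.append(
            TruthRecord(
                event_id=f"EV{n_event:03d}",
                parent_gene_id=pid_a,
                retro_gene_id=retro_id,
                element_id=eid,
                introns_lost=exons_a - 1,
                autonomy="non_autonomous",
                planted_age_my=age,
                polyA=True,
                direct_repeats=cfg.tsd_length >= 4,
            )
        )
        truth.append(
            TruthRecord(
                event_id=f"DMG{j + 1:03d}",
                parent_gene_id=pid_b,
                retro_gene_id=decoy_id,
                element_id=eid,
                introns_lost=exons_b - decoy_exons,
                autonomy="non_autonomous",
                planted_age_my=age,
                polyA=True,
                direct_repeats=cfg.tsd_length >= 4,
                decoy_class="multi_gene_element",
            )
        )
    # solo LTRs and scattered background class II / LINE repeats
    for j in range(decoys.get("solo_ltr", 0)):
        frag = _random_seq(rng, cfg.ltr_length)
        block = _Block(seq=frag, repeats=[(0, len(frag), f"SOLO{j + 1:03d}", "LTR/Gypsy", "+")])
        place(block)
        truth.append(
            TruthRecord(
                event_id=f"DSL{j + 1:03d}",
                parent_gene_id=None,
                retro_gene_id=None,
                element_id=None,
                introns_lost=0,
                autonomy="unknown",
                planted_age_my=0.0,
                polyA=False,
                direct_repeats=False,
                decoy_class="solo_ltr",
            )
        )
    bg_classes = ["DNA/hAT", "RC/Helitron", "LINE/L1", "DNA/MULE"]
    for j in range(decoys.get("background_te", 0)):
        n = int(rng.integers(300, 1500))
        frag = _random_seq(rng, n)
        cls = bg_classes[j % len(bg_classes)]
        block = _Block(seq=frag, repeats=[(0, n, f"BG{j + 1:03d}", cls, "+")])
        place(block)

    # ---- materialize coordinates
    sequences = {c.name: c.finish() for c in chroms}
    genes: list[GeneModel] = []
    repeats: list[RepeatFeature] = []
    elements: list[LtrElement] = []
    for block, builder, start in placements:
        seq_id = builder.name
        for gs in block.genes:
            exon_ivs = [
                GenomicInterval(seq_id, start + s, start + e, gs.strand)
                for s, e in gs.exon_offsets
            ]
            if gs.strand == "-":
                exon_ivs = exon_ivs[::-1]  # transcription order
            interval = GenomicInterval(
                seq_id,
                start + min(s for s, _ in gs.exon_offsets),
                start + max(e for _, e in gs.exon_offsets),
                gs.strand,
            )
            genes.append(
                GeneModel(
                    gene_id=gs.gene_id,
                    interval=interval,
                    exons=exon_ivs,
                    cds_seq=gs.cds,
                    family=gs.family,
                    is_nlr=gs.is_nlr,
                )
            )
        for rs, re_, name, cls, strand in block.repeats:
            order, _, superfamily = cls.partition("/")
            repeats.append(
                RepeatFeature(
                    interval=GenomicInterval(seq_id, start + rs, start + re_, strand),
                    name=name,
                    order=order,
                    superfamily=superfamily,
                )
            )
        if block.element is not None:
            el = block.element
            ltr5 = GenomicInterval(seq_id, start + el["ltr5"][0], start + el["ltr5"][1], "+")
            ltr3 = GenomicInterval(seq_id, start + el["ltr3"][0], start + el["ltr3"][1], "+")
            tsd = None
            if el["tsd"] is not None:
                tsd = (
                    GenomicInterval(seq_id, start + el["tsd"][0][0], start + el["tsd"][0][1]),
                    GenomicInterval(seq_id, start + el["tsd"][1][0], start + el["tsd"][1][1]),
                )
            elements.append(
                LtrElement(
                    element_id=el["id"],
                    span=GenomicInterval(seq_id, ltr5.start, ltr3.end, "+"),
                    ltr5=ltr5,
                    ltr3=ltr3,
                    tsd=tsd,
                )
            )
    bundle = AnnotationBundle(
        genes=sorted(genes, key=lambda g: (g.interval.seq_id, g.interval.start)),
        repeats=sorted(repeats, key=lambda r: (r.interval.seq_id, r.interval.start)),
        ltr_elements=sorted(elements, key=lambda e: (e.span.seq_id, e.span.start)),
        sequences=sequences,
    )
    bundle.validate()
    return bundle, truth


# --------------------------------------------------------------------------- truth I/O

_TRUTH_COLUMNS = [
    "event_id", "parent_gene_id", "retro_gene_id", "element_id", "introns_lost",
    "autonomy", "planted_age_my", "polyA", "direct_repeats", "decoy_class",
]


def write_truth(truth: list[TruthRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TRUTH_COLUMNS)
        for t in truth:
            writer.writerow(
                [
                    t.event_id,
                    t.parent_gene_id or "NA",
                    t.retro_gene_id or "NA",
                    t.element_id or "NA",
                    t.introns_lost,
                    t.autonomy,
                    f"{t.planted_age_my:.6g}",
                    int(t.polyA),
                    int(t.direct_repeats),
                    t.decoy_class or "NA",
                ]
            )


def read_truth(path) -> list[TruthRecord]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                TruthRecord(
                    event_id=row["event_id"],
                    parent_gene_id=None if row["parent_gene_id"] == "NA" else row["parent_gene_id"],
                    retro_gene_id=None if row["retro_gene_id"] == "NA" else row["retro_gene_id"],
                    element_id=None if row["element_id"] == "NA" else row["element_id"],
                    introns_lost=int(row["introns_lost"]),
                    autonomy=row["autonomy"],
                    planted_age_my=float(row["planted_age_my"]),
                    polyA=row["polyA"] == "1",
                    direct_repeats=row["direct_repeats"] == "1",
                    decoy_class=None if row["decoy_class"] == "NA" else row["decoy_class"],
                )
            )
    return out


def write_outputs(bundle: AnnotationBundle, truth: list[TruthRecord], outdir) -> dict[str, Path]:
    """Write FASTA + GFF3 + repeat table + LTR GFF3 + truth TSV to a directory."""
    from . import io as rio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fa",
        "genes": outdir / "genes.gff3",
        "repeats": outdir / "repeats.out",
        "ltr": outdir / "ltr_elements.gff3",
        "truth": outdir / "truth.tsv",
    }
    rio.write_fasta(bundle.sequences, paths["fasta"])
    rio.write_gene_models(bundle.genes, paths["genes"])
    rio.write_repeat_annotations(bundle.repeats, paths["repeats"])
    rio.write_ltr_elements(bundle.ltr_elements, paths["ltr"])
    write_truth(truth, paths["truth"])
    return paths
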