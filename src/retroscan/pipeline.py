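"""End-to-end orchestration: detect -> curate -> date -> report.

The stage order mirrors the analysis this package implements: candidate
detection inside full-length elements and partial LTR fragments, removal of
class II TE conflicts, parental verification, multi-gene-element
discrimination, orphan filtering, the retro/ambiguous/normal partition,
signature scanning, and molecular-clock dating. Every filter reports
in = out + rejected so the run log reconciles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from . import io as rio
from .clock import (
    ClockParams,
    SaturationError,
    ks_single_linkage,
    ltr_insertion_time,
    ng86_ka_ks,
    duplication_time,
)
from .curation import classify_normal_genes, drop_orphan_multiexon, resolve_multi_gene_element
from .detect import (
    CandidateRecord,
    classify_autonomy,
    detect_candidates_full_ltr,
    detect_candidates_partial_ltr,
    find_parent,
    remove_te_conflicts,
    retro_signature_scan,
)
from .model import AnnotationBundle, RetroCall

logger = logging.getLogger("retroscan")

__all__ = ["PipelineSettings", "PipelineResult", "run_on_bundle", "run_pipeline"]


@dataclass
class PipelineSettings:
    """All tunable thresholds, pre-filled with the pipeline defaults."""

    parent_min_coverage: float = 0.95
    normal_ltr_overlap: float = 0.8
    te_conflict_fraction: float = 0.5
    min_orf_nt: int = 900
    signature_window: int = 200
    ks_cluster_cutoff: float = 0.1
    r_intergenic: float = 1.3e-8
    r_synonymous: float = 6.96e-9
    seed: int = 0

    @property
    def clock(self) -> ClockParams:
        return ClockParams(self.r_intergenic, self.r_synonymous)


@dataclass
class PipelineResult:
    calls: list[RetroCall]
    partition: dict[str, set[str]]
    clusters: list[dict]
    stage_counts: dict[str, int]
    family_counts: dict[str, int]
    settings: PipelineSettings

    def summary(self) -> dict:
        return {
            "version": __version__,
            "settings": asdict(self.settings),
            "stage_counts": dict(sorted(self.stage_counts.items())),
            "family_counts": dict(sorted(self.family_counts.items())),
            "partition_sizes": {k: len(v) for k, v in sorted(self.partition.items())},
            "n_retro": sum(1 for c in self.calls if c.verdict == "retro"),
            "n_rejected": sum(1 for c in self.calls if c.verdict != "retro"),
        }


def _candidate_to_call(cand: CandidateRecord, verdict: str) -> RetroCall:
    iv = cand.gene.interval
    return RetroCall(
        gene_id=cand.gene.gene_id,
        seq_id=iv.seq_id,
        start=iv.start,
        end=iv.end,
        evidence_pass=cand.evidence_pass,
        verdict=verdict,
        element_id=cand.element.element_id if cand.element else None,
        repeat_ids=cand.repeat_ids,
        parent_id=cand.parent.parent_id if cand.parent else None,
        parent_coverage=cand.parent.query_coverage if cand.parent else 0.0,
        introns_lost=cand.parent.introns_lost if cand.parent else 0,
        polyA=bool(cand.signatures.get("polyA")),
        direct_repeats=bool(cand.signatures.get("direct_repeats")),
    )


def run_on_bundle(
    bundle: AnnotationBundle, settings: Optional[PipelineSettings] = None
) -> PipelineResult:
    """Run the full analysis on an in-memory annotation bundle."""
    st = settings or PipelineSettings()
    bundle.validate()
    genes = bundle.genes
    counts: dict[str, int] = {"genes_total": len(genes)}

    # --- detection
    full = detect_candidates_full_ltr(genes, bundle.ltr_elements)
    partial = detect_candidates_partial_ltr(genes, bundle.repeats)
    counts["candidates_full"] = len(full)
    counts["candidates_partial_raw"] = len(partial)
    seen = {c.gene.gene_id for c in full}
    merged = full + [c for c in partial if c.gene.gene_id not in seen]
    counts["candidates_merged"] = len(merged)

    # --- class II TE conflicts
    kept, te_rejected = remove_te_conflicts(merged, bundle.repeats, st.te_conflict_fraction)
    counts["rejected_te_conflict"] = len(te_rejected)

    # --- parental verification
    candidate_ids = {c.gene.gene_id for c in merged}
    pool = [g for g in genes if g.gene_id not in candidate_ids]
    have_families = any(g.family for g in genes)
    for cand in kept:
        cand_pool = pool
        if have_families and cand.gene.family:
            cand_pool = [g for g in pool if g.family == cand.gene.family]
        cand.parent = find_parent(cand.gene, cand_pool, st.parent_min_coverage)
    counts["parent_found"] = sum(1 for c in kept if c.parent is not None)
    parent_status = {c.gene.gene_id: c.parent is not None for c in kept}

    # --- multi-gene-element discrimination (among candidates with parents)
    by_element: dict[str, list[CandidateRecord]] = {}
    for cand in kept:
        if cand.element is not None:
            by_element.setdefault(cand.element.element_id, []).append(cand)
    multi_rejected: list[CandidateRecord] = []
    multi_rejected_ids: set[str] = set()
    for element_id, cands in sorted(by_element.items()):
        if len(cands) < 2:
            continue
        _, rejected_ids = resolve_multi_gene_element(
            [c.gene for c in cands], parent_status
        )
        for cand in cands:
            # parentless co-residents fall through to the orphan filter instead
            if cand.gene.gene_id in rejected_ids and parent_status[cand.gene.gene_id]:
                cand.verdict = "rejected_multi_gene_rule"
                multi_rejected.append(cand)
                multi_rejected_ids.add(cand.gene.gene_id)
    kept = [c for c in kept if c.gene.gene_id not in multi_rejected_ids]
    counts["rejected_multi_gene_rule"] = len(multi_rejected)

    # --- signatures (needed by the orphan rule for single-exon candidates)
    for cand in kept:
        cand.signatures = retro_signature_scan(
            cand.gene,
            bundle.sequences,
            window=st.signature_window,
            insertion_span=cand.element.span if cand.element else None,
        )

    # --- orphan filter
    kept, orphan_rejected = drop_orphan_multiexon(kept)
    counts["rejected_orphan_multiexon"] = len(orphan_rejected)
    counts["retro_final"] = len(kept)

    # --- final calls with autonomy, signatures of rejects, and clocks
    calls: list[RetroCall] = []
    for cand in te_rejected + multi_rejected + orphan_rejected:
        calls.append(_candidate_to_call(cand, cand.verdict))
    ks_pairs: dict[tuple[str, str], float] = {}
    for cand in kept:
        call = _candidate_to_call(cand, "retro")
        if cand.element is not None and bundle.sequences:
            call.autonomy = classify_autonomy(
                cand.element, bundle.sequences, exclude=cand.gene.interval,
                min_orf_nt=st.min_orf_nt,
            )
            try:
                call.insertion_age_my = (
                    ltr_insertion_time(cand.element, bundle.sequences, st.clock) / 1e6
                )
            except (SaturationError, ValueError):
                call.insertion_age_my = None
        if cand.parent is not None:
            parent = next(g for g in genes if g.gene_id == cand.parent.parent_id)
            if (
                parent.cds_seq
                and cand.gene.cds_seq
                and len(parent.cds_seq) == len(cand.gene.cds_seq)
                and len(parent.cds_seq) % 3 == 0
            ):
                try:
                    rates = ng86_ka_ks(cand.gene.cds_seq, parent.cds_seq, skip_stops=True)
                    call.ka, call.ks = rates.Ka, rates.Ks
                    call.duplication_age_my = duplication_time(rates.Ks, st.clock) / 1e6
                    ks_pairs[(cand.gene.gene_id, parent.gene_id)] = rates.Ks
                except (SaturationError, ValueError):
                    pass
        calls.append(call)

    # --- normal / ambiguous partition over the gene family
    family_genes = [g for g in genes if g.is_nlr or g.family] or list(genes)
    partition = classify_normal_genes(
        family_genes, calls, bundle.repeats, st.normal_ltr_overlap
    )
    counts["partition_retro"] = len(partition["retro"])
    counts["partition_ambiguous"] = len(partition["ambiguous"])
    counts["partition_normal"] = len(partition["normal"])

    # --- duplication-history clustering of the retro-parent Ks values
    clusters = ks_single_linkage(
        ks_pairs, st.ks_cluster_cutoff,
        genes=sorted({g for pair in ks_pairs for g in pair}),
        params=st.clock,
    )

    family_counts: dict[str, int] = {}
    for call in calls:
        if call.verdict != "retro":
            continue
        gene = next(g for g in genes if g.gene_id == call.gene_id)
        family_counts[gene.family or "unlabeled"] = (
            family_counts.get(gene.family or "unlabeled", 0) + 1
        )

    return PipelineResult(
        calls=sorted(calls, key=lambda c: (c.seq_id, c.start, c.gene_id)),
        partition=partition,
        clusters=clusters,
        stage_counts=counts,
        family_counts=family_counts,
        settings=st,
    )


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh) or {}
    return dict(config)


def run_pipeline(config) -> PipelineResult:
    """Run from a config mapping/YAML path naming the input files.

    Recognized keys: ``genes``, ``repeats``, ``ltr``, ``fasta`` (paths;
    ``genes`` is required), ``outdir`` (optional; reports written when
    given), plus any :class:`PipelineSettings` field.
    """
    cfg = _load_config(config)
    for key in ("genes",):
        if key not in cfg:
            raise KeyError(f"missing required config key: {key!r}")
    setting_fields = set(PipelineSettings.__dataclass_fields__)
    st = PipelineSettings(**{k: v for k, v in cfg.items() if k in setting_fields})
    bundle = rio.read_bundle(
        genes_path=cfg.get("genes"),
        repeats_path=cfg.get("repeats"),
        ltr_path=cfg.get("ltr"),
        fasta_path=cfg.get("fasta"),
    )
    _check_seq_ids(bundle)
    result = run_on_bundle(bundle, st)
    if cfg.get("outdir"):
        write_report(result, cfg["outdir"], resolved_config=cfg)
    return result


def _check_seq_ids(bundle: AnnotationBundle) -> None:
    if not bundle.sequences:
        return
    table = {
        "genes": {g.interval.seq_id for g in bundle.genes},
        "repeats": {r.interval.seq_id for r in bundle.repeats},
        "ltr_elements": {e.span.seq_id for e in bundle.ltr_elements},
    }
    known = set(bundle.sequences)
    missing = {k: sorted(v - known) for k, v in table.items() if v - known}
    if missing:
        lines = "; ".join(f"{k}: {', '.join(v)}" for k, v in missing.items())
        raise ValueError(f"seq_ids absent from FASTA -> {lines}")


def write_report(result: PipelineResult, outdir, resolved_config: Optional[dict] = None) -> dict:
    """Write the TSV/JSON report bundle; deterministic for identical inputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "calls": outdir / "retro_calls.tsv",
        "partition": outdir / "gene_partition.tsv",
        "clusters": outdir / "duplication_clusters.tsv",
        "summary": outdir / "summary.json",
        "config": outdir / "resolved_config.yaml",
        "log": outdir / "run.log",
    }
    rio.write_retro_calls(result.calls, paths["calls"])
    with open(paths["partition"], "w") as fh:
        fh.write("gene_id\tclass\n")
        for cls in ("retro", "ambiguous", "normal"):
            for gid in sorted(result.partition[cls]):
                fh.write(f"{gid}\t{cls}\n")
    with open(paths["clusters"], "w") as fh:
        fh.write("cluster\tmembers\tmin_ks\tage_my\n")
        for i, cl in enumerate(result.clusters, 1):
            ks = "NA" if cl["min_ks"] is None else f"{cl['min_ks']:.6g}"
            age = "NA" if cl["age_years"] is None else f"{cl['age_years'] / 1e6:.6g}"
            fh.write(f"{i}\t{','.join(cl['members'])}\t{ks}\t{age}\n")
    with open(paths["summary"], "w") as fh:
        json.dump(result.summary(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(paths["config"], "w") as fh:
        resolved = dict(resolved_config or {})
        resolved.pop("outdir", None)  # the report's own location, not a parameter
        resolved.update(asdict(result.settings))
        yaml.safe_dump(resolved, fh, sort_keys=True)
    with open(paths["log"], "w") as fh:
        fh.write(f"retroscan {__version__}\n")
        fh.write(f"seed: {result.settings.seed}\n")
        for key, value in sorted(result.stage_counts.items()):
            fh.write(f"{key}: {value}\n")
    return paths
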