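import pytest

from retroscan import run_on_bundle
from retroscan.model import GeneModel, GenomicInterval
from retroscan.simulate import SimConfig, simulate_genome


def make_gene(
    gene_id="g1",
    seq_id="chr1",
    start=0,
    end=None,
    strand="+",
    exons=None,
    cds="ATGAAATGA",
    family=None,
):
    """Small helper for hand-built gene fixtures."""
    if exons is None:
        end = end if end is not None else start + len(cds)
        exons = [(start, end)]
    end = end if end is not None else max(e for _, e in exons)
    start = min(s for s, _ in exons) if exons else start
    exon_ivs = [GenomicInterval(seq_id, s, e, strand) for s, e in sorted(exons)]
    if strand == "-":
        exon_ivs = exon_ivs[::-1]
    return GeneModel(
        gene_id=gene_id,
        interval=GenomicInterval(seq_id, start, end, strand),
        exons=exon_ivs,
        cds_seq=cds,
        family=family,
        is_nlr=True,
    )


@pytest.fixture(scope="session")
def default_sim():
    """Default-condition synthetic genome with all decoy classes."""
    return simulate_genome(SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_result(default_sim):
    bundle, _ = default_sim
    return run_on_bundle(bundle)
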