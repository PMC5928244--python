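import numpy as np
import pandas as pd
import pytest

from ipa_atlas import simulate as sm
from ipa_atlas.annotation import GeneModel, GenomeAnnotation
from ipa_atlas.atlas import PeakSet


def make_gene(
    gene_id="gX",
    chrom="chr1",
    strand="+",
    exons=((0, 100), (200, 300), (400, 520)),
    cds=((30, 100), (200, 300), (400, 430)),
    utr3=((430, 520),),
):
    exons = [tuple(e) for e in exons]
    cds = [tuple(c) for c in cds]
    if strand == "-":
        # caller supplies genomic-sorted intervals either way
        pass
    introns = [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        start=exons[0][0],
        end=exons[-1][1],
        transcripts={f"{gene_id}.t1": exons},
        exons=exons,
        introns=introns,
        cds=cds,
        cds_transcript=f"{gene_id}.t1",
        utr3=[tuple(u) for u in utr3],
    )


def make_annotation(*genes):
    ann = GenomeAnnotation(genes={g.gene_id: g for g in genes})
    return ann


def make_peakset(rows, counts, starts=None):
    """rows: list of dicts with peak_id/chrom/start/end/strand;
    counts: dict peak_id -> {sample: count}."""
    peaks = pd.DataFrame(rows).set_index("peak_id")
    cdf = pd.DataFrame(counts).T
    cdf = cdf.reindex(peaks.index)
    return PeakSet(peaks=peaks, counts=cdf, starts=starts or {})


@pytest.fixture(scope="session")
def small_sim():
    """Moderate simulated dataset shared across test modules."""
    cfg = sm.SimConfig(n_genes=40, seed=5, intron_background=2.0)
    rng = np.random.default_rng(cfg.seed)
    ann, genome, truth = sm.simulate_annotation(cfg, rng)
    peakset, raw = sm.simulate_threeprime(ann, truth, cfg, rng)
    return cfg, ann, genome, truth, peakset, raw


@pytest.fixture(scope="session")
def small_atlas(small_sim):
    from ipa_atlas.atlas import build_atlas

    cfg, ann, genome, truth, peakset, raw = small_sim
    atl, lib = build_atlas(peakset, ann, genome, raw, truth.blacklist, truth.ig_intervals)
    return atl, lib
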