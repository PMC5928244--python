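"""Intron-retention calling and IpA co-occurrence.

Per-sample retention calls from coverage and junction evidence (four
criteria), cell-type aggregation by the 66%/33% rule, and the chance
co-occurrence expectation of IpA and retained introns over the
expressed-introns-with-PAS universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel
from .seqfeat import MotifConfig, revcomp, scan_motifs

RETAINED, NOT_RETAINED, UNTESTABLE, AMBIGUOUS = (
    "RETAINED",
    "NOT_RETAINED",
    "UNTESTABLE",
    "AMBIGUOUS",
)


@dataclass
class RetentionCriteria:
    min_junction_reads: int = 3
    min_covered_fraction: float = 0.5
    min_coverage: int = 3
    min_mappable_fraction: float = 0.5
    min_exon_median: float = 10.0
    min_intron_exon_ratio: float = 0.1
    gene_ratio_cutoff: float = 0.2


def call_retained_introns_sample(
    gene: GeneModel,
    coverage: np.ndarray,
    junctions: Mapping[int, tuple[int, int]] | None,
    mappability: np.ndarray | None = None,
    criteria: RetentionCriteria | None = None,
) -> dict[int, str]:
    """Per-intron retention status for one sample.

    ``junctions`` maps transcription-order intron index to (upstream,
    downstream) boundary-spanning read counts; a missing table fails
    criterion (i) rather than making introns untestable. Criterion (ii) and
    the intron median use mappable positions only; introns under 50%
    mappable are UNTESTABLE.
    """
    crit = criteria or RetentionCriteria()
    out: dict[int, str] = {}
    for gidx, (s, e) in enumerate(gene.introns):
        tidx = gene.intron_index(gidx)
        if mappability is not None:
            mappable = mappability[s:e] > 0.5
        else:
            mappable = np.ones(e - s, dtype=bool)
        if mappable.mean() < crit.min_mappable_fraction:
            out[tidx] = UNTESTABLE
            continue
        j = junctions.get(tidx, (0, 0)) if junctions else (0, 0)
        c1 = min(j) >= crit.min_junction_reads
        intron_cov = coverage[s:e][mappable]
        c2 = np.mean(intron_cov >= crit.min_coverage) >= crit.min_covered_fraction
        flank = _flanking_exon_coverage(gene, gidx, coverage)
        exon_median = float(np.median(flank)) if flank.size else 0.0
        c3 = exon_median >= crit.min_exon_median
        intron_median = float(np.median(intron_cov)) if intron_cov.size else 0.0
        c4 = exon_median > 0 and intron_median / exon_median >= crit.min_intron_exon_ratio
        out[tidx] = RETAINED if (c1 and c2 and c3 and c4) else NOT_RETAINED
    return out


def _flanking_exon_coverage(gene: GeneModel, gidx: int, coverage: np.ndarray) -> np.ndarray:
    # pooled base-level coverage of both exons flanking intron gidx
    up = gene.exons[gidx]
    down = gene.exons[gidx + 1]
    return np.concatenate([coverage[up[0] : up[1]], coverage[down[0] : down[1]]])


def gene_intron_exon_ratio(gene: GeneModel, coverage: np.ndarray) -> float:
    """(median coverage over all introns) / (median over all exons)."""
    if not gene.introns:
        return 0.0
    intron = np.concatenate([coverage[s:e] for s, e in gene.introns])
    exon = np.concatenate([coverage[s:e] for s, e in gene.exons])
    exon_med = float(np.median(exon))
    if exon_med == 0:
        return np.inf
    return float(np.median(intron)) / exon_med


def intron_has_pas(
    gene: GeneModel, gidx: int, genome: Mapping[str, str], motifs: MotifConfig | None = None
) -> bool:
    motifs = motifs or MotifConfig()
    s, e = gene.introns[gidx]
    seq = genome[gene.chrom][s:e]
    sense = seq if gene.strand == "+" else revcomp(seq)
    return bool(scan_motifs(sense, motifs.pas_variants))


def aggregate_retention(
    per_sample_calls: Mapping[str, Mapping[str, dict[int, str]]],
    genes: Mapping[str, GeneModel],
    genome: Mapping[str, str],
    coverage_by_sample: Mapping[str, Mapping[str, np.ndarray]] | None = None,
    motifs: MotifConfig | None = None,
    criteria: RetentionCriteria | None = None,
    retained_fraction: float = 0.66,
    not_retained_fraction: float = 0.33,
) -> pd.DataFrame:
    """Aggregate one cell type's per-sample calls into final IRCall rows.

    ``per_sample_calls`` maps sample -> gene -> {intron index: status}.
    Fractions are computed over testable samples: >=66% retained -> RETAINED,
    <=33% -> NOT_RETAINED, in between -> AMBIGUOUS (removed downstream).
    Each row also records whether the intron carries a PAS and whether the
    gene trips the global intron/exon coverage-ratio flag."""
    crit = criteria or RetentionCriteria()
    samples = sorted(per_sample_calls)
    if len(samples) < 2:
        raise ValueError("need >=2 samples per cell type")
    flagged_genes: set[str] = set()
    if coverage_by_sample is not None:
        for gid, gene in genes.items():
            ratios = [
                gene_intron_exon_ratio(gene, coverage_by_sample[s][gene.chrom])
                for s in samples
            ]
            if float(np.median(ratios)) >= crit.gene_ratio_cutoff:
                flagged_genes.add(gid)
    rows = []
    for gid, gene in sorted(genes.items()):
        n_introns = len(gene.introns)
        for tidx in range(n_introns):
            statuses = [per_sample_calls[s].get(gid, {}).get(tidx, UNTESTABLE) for s in samples]
            testable = [st for st in statuses if st != UNTESTABLE]
            if not testable:
                agg = UNTESTABLE
            else:
                frac = sum(st == RETAINED for st in testable) / len(testable)
                if frac >= retained_fraction:
                    agg = RETAINED
                elif frac <= not_retained_fraction:
                    agg = NOT_RETAINED
                else:
                    agg = AMBIGUOUS
            gidx = gene.intron_index(tidx)  # involution back to genomic order
            rows.append(
                {
                    "gene_id": gid,
                    "intron_index": tidx,
                    "status": agg,
                    "retained_fraction": (
                        sum(st == RETAINED for st in testable) / len(testable)
                        if testable
                        else np.nan
                    ),
                    "has_pas": intron_has_pas(gene, gidx, genome, motifs),
                    "gene_flagged_high_intron": gid in flagged_genes,
                }
            )
    return pd.DataFrame(rows)


def ipa_ir_overlap(
    ipa_introns: set[tuple[str, int]],
    ir_calls: pd.DataFrame,
    ipa_usage: pd.Series | None = None,
) -> dict:
    """Observed vs expected co-occurrence of IpA and retained introns.

    The universe is the set of testable introns with a PAS from unflagged
    genes; expected = p(IpA) * p(IR) * N; a two-sided binomial test compares
    observed to expected. When per-event usage is supplied, IpA usage in
    non-retained vs retained introns is compared by one-sided rank-sum."""
    uni = ir_calls[
        ir_calls["has_pas"]
        & ~ir_calls["gene_flagged_high_intron"]
        & ir_calls["status"].isin([RETAINED, NOT_RETAINED])
    ]
    n = len(uni)
    if n == 0:
        raise ValueError("empty intron universe")
    keys = list(zip(uni["gene_id"], uni["intron_index"]))
    is_ipa = np.array([k in ipa_introns for k in keys])
    is_ir = (uni["status"] == RETAINED).to_numpy()
    p_ipa = is_ipa.mean()
    p_ir = is_ir.mean()
    expected = p_ipa * p_ir * n
    observed = int(np.sum(is_ipa & is_ir))
    binom_p = float(stats.binomtest(observed, n, p_ipa * p_ir).pvalue) if 0 < p_ipa * p_ir < 1 else np.nan
    result = {
        "n_universe": n,
        "p_ipa": float(p_ipa),
        "p_ir": float(p_ir),
        "expected": float(expected),
        "observed": observed,
        "binom_p": binom_p,
    }
    if ipa_usage is not None:
        ir_keys = {k for k, r in zip(keys, is_ir) if r}
        in_ir, not_ir = [], []
        for key, u in ipa_usage.items():
            (not_ir, in_ir)[key in ir_keys].append(u)
        if len(in_ir) >= 2 and len(not_ir) >= 2:
            stat, pval = stats.mannwhitneyu(not_ir, in_ir, alternative="greater")
            result["usage_rank_sum_p"] = float(pval)
    return result


def brute_force_retention_call(
    junction_counts: tuple[int, int],
    intron_coverage: Sequence[float],
    intron_mappable: Sequence[bool],
    exon_coverage: Sequence[float],
    criteria: RetentionCriteria | None = None,
) -> str:
    """Direct restatement of the four criteria on raw vectors; the oracle
    counterpart of :func:`call_retained_introns_sample` for equivalence
    testing."""
    crit = criteria or RetentionCriteria()
    mappable = np.asarray(intron_mappable, dtype=bool)
    cov = np.asarray(intron_coverage, dtype=float)
    if mappable.mean() < crit.min_mappable_fraction:
        return UNTESTABLE
    ok = (
        min(junction_counts) >= crit.min_junction_reads
        and np.mean(cov[mappable] >= crit.min_coverage) >= crit.min_covered_fraction
        and np.median(exon_coverage) >= crit.min_exon_median
        and np.median(exon_coverage) > 0
        and np.median(cov[mappable]) / np.median(exon_coverage) >= crit.min_intron_exon_ratio
    )
    return RETAINED if ok else NOT_RETAINED
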