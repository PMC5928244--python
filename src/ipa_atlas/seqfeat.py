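"""Motif and conservation analyses.

Polyadenylation-signal (PAS) and U1 motif scanning, per-gene signal densities
with AT-content stratification, conservation profiles around cleavage sites,
and CLIP binding-site enrichment over exonized introns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel

# Canonical PAS plus the single-substitution variant set commonly used for
# human polyA-site annotation (13 hexamers).
DEFAULT_PAS_VARIANTS = (
    "AATAAA",
    "ATTAAA",
    "AGTAAA",
    "TATAAA",
    "CATAAA",
    "GATAAA",
    "AATATA",
    "AATACA",
    "AATAGA",
    "AAAAAG",
    "ACTAAA",
    "AAGAAA",
    "AATGAA",
)

# 5' splice-site consensus motifs standing in for U1 snRNP binding signals.
DEFAULT_U1_MOTIFS = ("GTAAGT", "GTGAGT", "GTAAGG")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MotifConfig:
    pas_variants: tuple[str, ...] = DEFAULT_PAS_VARIANTS
    u1_motifs: tuple[str, ...] = DEFAULT_U1_MOTIFS

    def __post_init__(self):
        for m in tuple(self.pas_variants) + tuple(self.u1_motifs):
            if len(m) < 5 or set(m) - set("ACGT"):
                raise ValueError(f"invalid motif {m!r}")


def scan_motifs(sequence: str, motifs: Sequence[str]) -> list[int]:
    """All exact-match start positions of any motif (overlaps included)."""
    seq = sequence.upper()
    if set(seq) - set("ACGTN"):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"non-ACGTN characters in sequence: {bad}")
    hits: list[int] = []
    for motif in motifs:
        start = 0
        while True:
            i = seq.find(motif, start)
            if i < 0:
                break
            hits.append(i)
            start = i + 1
    return sorted(hits)


def at_content(sequence: str) -> float:
    """(A+T)/(A+C+G+T); N excluded from the denominator."""
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("sequence contains no ACGT bases")
    return (counts["A"] + counts["T"]) / denom


def gene_sense_sequence(gene: GeneModel, genome: Mapping[str, str], start: int, end: int) -> str:
    """Genomic slice [start,end) in transcription orientation."""
    seq = genome[gene.chrom][start:end]
    return seq if gene.strand == "+" else revcomp(seq)


def pas_upstream(
    gene_strand: str,
    end_pos: int,
    chrom_seq: str,
    motifs: MotifConfig | None = None,
    window: int = 50,
) -> bool:
    """Is a PAS hexamer present within ``window`` nt upstream of a 3' end?"""
    motifs = motifs or MotifConfig()
    if gene_strand == "+":
        seq = chrom_seq[max(0, end_pos - window) : end_pos]
    else:
        seq = revcomp(chrom_seq[end_pos + 1 : end_pos + 1 + window])
    return bool(scan_motifs(seq, motifs.pas_variants))


# ---------------------------------------------------------------------------
# Signal densities
# ---------------------------------------------------------------------------


def signal_density(
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
    motifs: MotifConfig | None = None,
) -> pd.DataFrame:
    """Per-gene PAS and U1 densities per kb from the TSS to the 3'UTR start.

    Genes without an annotated 3'UTR, or with a zero-length region, are
    omitted. Densities are computed on the sense-strand sequence.
    """
    motifs = motifs or MotifConfig()
    rows = []
    for gene in genes:
        u3s = gene.utr3_start
        if u3s is None:
            continue
        if gene.strand == "+":
            start, end = gene.start, u3s
        else:
            start, end = u3s + 1, gene.end
        if end <= start:
            continue
        seq = gene_sense_sequence(gene, genome, start, end)
        kb = (end - start) / 1000.0
        rows.append(
            {
                "gene_id": gene.gene_id,
                "region_length": end - start,
                "pas_per_kb": len(scan_motifs(seq, motifs.pas_variants)) / kb,
                "u1_per_kb": len(scan_motifs(seq, motifs.u1_motifs)) / kb,
                "at_content": at_content(seq),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame(
        columns=["region_length", "pas_per_kb", "u1_per_kb", "at_content"]
    )


def compare_densities(
    density: pd.DataFrame,
    ipa_genes: set[str],
    column: str = "pas_per_kb",
    at_threshold: float = 0.5,
) -> pd.DataFrame:
    """One-sided rank-sum comparisons of a density column, IpA vs non-IpA,
    overall and within high/low AT strata."""
    is_ipa = density.index.isin(ipa_genes)
    strata = {
        "all": np.ones(len(density), dtype=bool),
        "high_at": density["at_content"].to_numpy() > at_threshold,
        "low_at": density["at_content"].to_numpy() < at_threshold,
    }
    rows = []
    for name, mask in strata.items():
        a = density.loc[mask & is_ipa, column]
        b = density.loc[mask & ~is_ipa, column]
        if len(a) < 2 or len(b) < 2:
            rows.append({"stratum": name, "n_ipa": len(a), "n_other": len(b), "p": np.nan})
            continue
        stat, p = stats.mannwhitneyu(a, b, alternative="greater")
        rows.append(
            {
                "stratum": name,
                "n_ipa": len(a),
                "n_other": len(b),
                "statistic": stat,
                "p": p,
                "median_ipa": float(np.median(a)),
                "median_other": float(np.median(b)),
            }
        )
    return pd.DataFrame(rows).set_index("stratum")


# ---------------------------------------------------------------------------
# Conservation
# ---------------------------------------------------------------------------


def conservation_profile(
    positions: Sequence[tuple[str, int, str]],
    track: Mapping[str, np.ndarray],
    flank: int = 200,
) -> tuple[np.ndarray, int]:
    """Mean track value per offset in [-flank, +flank] around oriented 3' ends.

    ``positions`` holds (chrom, position, strand); offsets run 5'->3' in
    transcription orientation. Returns (profile of length 2*flank+1, number of
    positions skipped for falling off the chromosome).
    """
    width = 2 * flank + 1
    total = np.zeros(width)
    n = 0
    skipped = 0
    for chrom, pos, strand in positions:
        arr = track[chrom]
        if pos - flank < 0 or pos + flank + 1 > arr.size:
            skipped += 1
            continue
        window = arr[pos - flank : pos + flank + 1].astype(float)
        if strand == "-":
            window = window[::-1]
        total += window
        n += 1
    if n == 0:
        return np.full(width, np.nan), skipped
    return total / n, skipped


def random_intronic_pas_control(
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
    exclude_introns: set[tuple[str, int]],
    rng: np.random.Generator,
    n: int = 5000,
    motif: str = "AATAAA",
) -> list[tuple[str, int, str]]:
    """Random intronic PAS positions from IpA genes, avoiding introns that
    carry real events: one candidate intron per draw, one of its canonical-PAS
    hexamer starts selected at random."""
    candidates: list[tuple[str, int, str]] = []
    for gene in genes:
        for gidx, (s, e) in enumerate(gene.introns):
            tidx = gene.intron_index(gidx)
            if (gene.gene_id, tidx) in exclude_introns:
                continue
            seq = genome[gene.chrom][s:e]
            sense = seq if gene.strand == "+" else revcomp(seq)
            hits = scan_motifs(sense, [motif])
            if not hits:
                continue
            hit = hits[rng.integers(len(hits))]
            if gene.strand == "+":
                pos = s + hit
            else:
                pos = e - 1 - hit
            candidates.append((gene.chrom, pos, gene.strand))
    if not candidates:
        return []
    idx = rng.choice(len(candidates), size=min(n, len(candidates)), replace=False)
    return [candidates[i] for i in idx]


# ---------------------------------------------------------------------------
# CLIP enrichment
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    rbp: str
    background: str
    observed: int
    expected: float
    z: float
    site_probability: float


def _sites_in(intervals: list[tuple[str, int, int]], sites: pd.DataFrame) -> int:
    count = 0
    mid = ((sites["start"] + sites["end"]) // 2).to_numpy()
    chroms = sites["chrom"].to_numpy()
    for chrom, s, e in intervals:
        count += int(np.sum((chroms == chrom) & (mid >= s) & (mid < e)))
    return count


def clip_enrichment(
    exonized_introns: list[tuple[str, int, int]],
    clip_peaks: Mapping[str, pd.DataFrame],
    backgrounds: Mapping[str, list[tuple[str, int, int]]],
    min_length: int = 50,
) -> list[EnrichmentResult]:
    """Binomial Z-score of CLIP sites in exonized introns versus background
    region classes. Exonized introns of ``min_length`` nt or shorter are
    excluded; a site is counted in a region when its midpoint falls inside."""
    kept = [iv for iv in exonized_introns if iv[2] - iv[1] > min_length]
    total_len = sum(e - s for _, s, e in kept)
    results: list[EnrichmentResult] = []
    for rbp, sites in clip_peaks.items():
        obs = _sites_in(kept, sites)
        for bg_name, bg_ivs in backgrounds.items():
            bg_len = sum(e - s for _, s, e in bg_ivs)
            if bg_len == 0 or total_len == 0:
                continue
            p = _sites_in(bg_ivs, sites) / bg_len
            expected = p * total_len
            if expected == 0 or p >= 1:
                continue
            z = (obs - expected) / np.sqrt(expected * (1 - p))
            results.append(EnrichmentResult(rbp, bg_name, obs, expected, float(z), p))
    return results
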