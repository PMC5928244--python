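"""Molecular consequences of IpA events.

Retained coding fraction and 5'/3' classification, assembled-transcript
assignment, composite vs skipped terminal-exon typing, coding-potential
calls, and protein-domain / transmembrane-domain retention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel, upstream_cds_length

DOMAIN_CATEGORIES = (
    "ACTIVE_SITE",
    "DNA_BINDING",
    "PPI",
    "RNA_BINDING",
    "TMD",
    "REPEATED",
    "OTHER",
)


@dataclass
class DomainRecord:
    """Protein domain on the longest isoform, amino-acid half-open interval."""

    protein_id: str
    domain: str
    category: str
    aa_start: int
    aa_end: int

    def __post_init__(self):
        if self.category not in DOMAIN_CATEGORIES:
            raise ValueError(f"unknown domain category {self.category!r}")
        if self.aa_start < 0 or self.aa_end <= self.aa_start:
            raise ValueError(f"invalid domain interval {self.aa_start}..{self.aa_end}")


@dataclass
class AssembledTranscript:
    """A de-novo assembled transcript model (genomic exon intervals)."""

    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def end3(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def start5(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def last_exon(self) -> tuple[int, int]:
        return self.exons[-1] if self.strand == "+" else self.exons[0]


# ---------------------------------------------------------------------------
# retained coding fraction
# ---------------------------------------------------------------------------


def retained_cdr_fraction(gene: GeneModel, pos: int) -> tuple[float, str]:
    """Fraction of the longest-ORF coding region retained by an intronic
    cleavage at ``pos``, and the 5'/3' class (IPA_5P strictly below 0.25)."""
    if not gene.is_coding:
        raise ValueError(f"gene {gene.gene_id} is non-coding")
    frac = upstream_cds_length(gene, pos) / gene.cds_length
    return frac, ("IPA_5P" if frac < 0.25 else "IPA_3P")


# ---------------------------------------------------------------------------
# transcript assignment
# ---------------------------------------------------------------------------


def assign_transcript(
    pos: int,
    gene: GeneModel,
    assembled: Sequence[AssembledTranscript],
    end_tolerance: int = 50,
    near_tolerance: int = 500,
    overlap_tolerance: int = 5000,
    tss_tolerance: int = 100,
) -> AssembledTranscript | None:
    """Pick the assembled transcript representing the IpA isoform at ``pos``.

    Candidates overlap the gene; single-exon models are admitted only when an
    endpoint lies within ``tss_tolerance`` of the TSS. Match order: transcripts
    ending within ``end_tolerance`` of the event (ties: most exons, then TSS
    proximity), else the nearest-ending transcript within ``near_tolerance``,
    else an overlapping transcript ending within ``overlap_tolerance``."""
    cands = [
        t
        for t in assembled
        if t.chrom == gene.chrom
        and t.strand == gene.strand
        and t.start < gene.end
        and t.end > gene.start
    ]
    multi = [t for t in cands if t.n_exons > 1]
    single = [
        t
        for t in cands
        if t.n_exons == 1
        and min(abs(t.start - gene.tss), abs(t.end - 1 - gene.tss)) <= tss_tolerance
    ]
    pool = multi if multi else single
    if not pool:
        return None

    def _dist(t):
        return abs(t.end3 - pos)

    close = [t for t in pool if _dist(t) <= end_tolerance]
    if close:
        close.sort(key=lambda t: (-t.n_exons, abs(t.start5 - gene.tss), t.transcript_id))
        return close[0]
    nearest = min(pool, key=lambda t: (_dist(t), t.transcript_id))
    if _dist(nearest) <= near_tolerance:
        return nearest
    overlapping = [
        t for t in pool if t.start <= pos < t.end and _dist(t) <= overlap_tolerance
    ]
    if overlapping:
        overlapping.sort(key=lambda t: (_dist(t), t.transcript_id))
        return overlapping[0]
    return None


def truncate_to_event(t: AssembledTranscript, pos: int) -> AssembledTranscript:
    """Replace the transcript 3' end with the 3'-seq position (the cleavage
    site is single-nucleotide accurate; the assembly is not)."""
    exons = [list(e) for e in t.exons]
    if t.strand == "+":
        exons = [e for e in exons if e[0] <= pos]
        exons[-1][1] = pos + 1
    else:
        exons = [e for e in exons if e[1] > pos]
        exons[0][0] = pos
    return AssembledTranscript(t.transcript_id, t.chrom, t.strand, [tuple(e) for e in exons])


def classify_terminal_exon(
    pos: int,
    transcript: AssembledTranscript | None,
    gene: GeneModel,
    tolerance: int = 5,
) -> str:
    """COMPOSITE when the isoform's last exon starts at an annotated exon's
    start (within ``tolerance``) and reads through its donor site into the
    intron; SKIPPED when the last exon starts inside the intron (novel
    acceptor); UNRESOLVED otherwise."""
    if transcript is None:
        return "UNRESOLVED"
    t = truncate_to_event(transcript, pos)
    ls, le = t.last_exon
    # 5' start of the last exon in transcription orientation
    exon_start5 = ls if gene.strand == "+" else le - 1
    for s, e in gene.exons:
        anno_start5 = s if gene.strand == "+" else e - 1
        if abs(exon_start5 - anno_start5) <= tolerance:
            # read-through: must extend past the annotated donor site
            if (gene.strand == "+" and le > e) or (gene.strand == "-" and ls < s):
                return "COMPOSITE"
            return "UNRESOLVED"
    for s, e in gene.introns:
        if s <= exon_start5 < e:
            return "SKIPPED"
    return "UNRESOLVED"


# ---------------------------------------------------------------------------
# coding potential
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


def longest_orf(sequence: str) -> int:
    """Length in nt of the longest ATG-initiated ORF across the three forward
    frames (stop codon excluded; unterminated ORFs run to the end)."""
    seq = sequence.upper()
    best = 0
    n = len(seq)
    for frame in range(3):
        i = frame
        open_start = None
        while i + 3 <= n:
            codon = seq[i : i + 3]
            if open_start is None and codon == "ATG":
                open_start = i
            elif open_start is not None and codon in _STOPS:
                best = max(best, i - open_start)
                open_start = None
            i += 3
        if open_start is not None:
            best = max(best, (n - open_start) // 3 * 3)
    return best


def call_noncoding(
    transcript_sequence: str | None,
    coding_potential_prob: float | None,
    retained_fraction: float,
    prob_threshold: float = 0.3,
    fraction_threshold: float = 0.25,
    orf_threshold: int = 300,
) -> bool | None:
    """Non-coding iff coding-potential probability < 0.3, retained coding
    fraction < 0.25, and longest ORF <= 300 nt. None when the probability is
    missing (call deferred)."""
    if coding_potential_prob is None or (
        isinstance(coding_potential_prob, float) and np.isnan(coding_potential_prob)
    ):
        return None
    orf = longest_orf(transcript_sequence) if transcript_sequence else 0
    return (
        coding_potential_prob < prob_threshold
        and retained_fraction < fraction_threshold
        and orf <= orf_threshold
    )


def coding_potential_stub(orf_length_nt: int, midpoint: int = 300, scale: float = 60.0) -> float:
    """Logistic stand-in for an external coding-potential probability,
    driven by ORF length only; for synthetic tests."""
    return float(1.0 / (1.0 + np.exp(-(orf_length_nt - midpoint) / scale)))


# ---------------------------------------------------------------------------
# domains
# ---------------------------------------------------------------------------


def truncation_aa(gene: GeneModel, pos: int) -> int:
    """Truncation point in amino acids: floor(upstream coding nt / 3)."""
    return upstream_cds_length(gene, pos) // 3


def domain_retention(
    gene: GeneModel,
    pos: int,
    domains: Sequence[DomainRecord],
) -> tuple[list[DomainRecord], list[DomainRecord]]:
    """Partition domains into (retained, lost) at the truncation point.

    A domain is retained only when wholly within the retained amino acids;
    partially truncated domains count as lost."""
    cut = truncation_aa(gene, pos)
    retained = [d for d in domains if d.aa_end <= cut]
    lost = [d for d in domains if d.aa_end > cut]
    return retained, lost


def tmd_analysis(
    gene: GeneModel,
    pos: int,
    domains: Sequence[DomainRecord],
) -> tuple[str, float | None]:
    """Transmembrane-domain status and, for complete TMD loss, the signed
    distance in amino acids from the truncation point to the first TMD:
    (upstream coding nt at the IpA - upstream coding nt at the intron before
    the first TMD) / 3; negative means the protein ends upstream of the TMD."""
    tmds = sorted((d for d in domains if d.category == "TMD"), key=lambda d: d.aa_start)
    if not tmds:
        return "NONE", None
    cut = truncation_aa(gene, pos)
    if all(d.aa_end <= cut for d in tmds):
        return "RETAINED", None
    # any incompletely retained TMD (including partial truncation) -> LOST;
    # distance reported against the first TMD, negative = upstream of it
    first = tmds[0]
    return "LOST", float(cut - first.aa_start)


def size_and_domain_contrast(
    protein_lengths: Mapping[str, int],
    domains_by_protein: Mapping[str, Sequence[DomainRecord]],
    ipa_proteins: set[str],
) -> pd.DataFrame:
    """IpA vs non-IpA summary: one-sided rank-sum on protein length and
    domain count, plus per-category Fisher odds ratios."""
    ids = sorted(protein_lengths)
    ipa = [p for p in ids if p in ipa_proteins]
    non = [p for p in ids if p not in ipa_proteins]
    if not ipa or not non:
        raise ValueError("both partitions must be non-empty")
    rows = []
    for name, value_of in (
        ("protein_length", lambda p: protein_lengths[p]),
        ("domain_count", lambda p: len(domains_by_protein.get(p, ()))),
    ):
        a = [value_of(p) for p in ipa]
        b = [value_of(p) for p in non]
        stat, pval = stats.mannwhitneyu(a, b, alternative="greater")
        rows.append(
            {
                "metric": name,
                "median_ipa": float(np.median(a)),
                "median_other": float(np.median(b)),
                "statistic": float(stat),
                "p": float(pval),
            }
        )
    for cat in DOMAIN_CATEGORIES:
        def _has(p):
            return any(d.category == cat for d in domains_by_protein.get(p, ()))

        a_yes = sum(_has(p) for p in ipa)
        b_yes = sum(_has(p) for p in non)
        if a_yes + b_yes == 0:
            rows.append({"metric": f"category_{cat}", "p": np.nan})
            continue
        table = [[a_yes, len(ipa) - a_yes], [b_yes, len(non) - b_yes]]
        odds, pval = stats.fisher_exact(table)
        rows.append(
            {
                "metric": f"category_{cat}",
                "odds_ratio": float(odds),
                "p": float(pval),
            }
        )
    return pd.DataFrame(rows).set_index("metric")


# ---------------------------------------------------------------------------
# assembled-transcript GTF I/O
# ---------------------------------------------------------------------------


def read_assembled_gtf(path) -> list[AssembledTranscript]:
    """Read assembled transcript models (exon features grouped by
    transcript_id) from a GTF file."""
    exons: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] != "exon":
                continue
            attrs = dict(
                kv.strip().split(" ", 1) for kv in f[8].strip().split(";") if kv.strip()
            )
            tid = attrs["transcript_id"].strip('"')
            rec = exons.setdefault(tid, {"chrom": f[0], "strand": f[6], "exons": []})
            rec["exons"].append((int(f[3]) - 1, int(f[4])))
    return [
        AssembledTranscript(tid, rec["chrom"], rec["strand"], sorted(rec["exons"]))
        for tid, rec in sorted(exons.items())
    ]


def read_domain_table(path) -> dict[str, list[DomainRecord]]:
    """TSV with columns protein_id, domain, category, aa_start, aa_end."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[DomainRecord]] = {}
    for _, r in df.iterrows():
        out.setdefault(r["protein_id"], []).append(
            DomainRecord(
                r["protein_id"], r["domain"], r["category"], int(r["aa_start"]), int(r["aa_end"])
            )
        )
    return out
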