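"""Gene-annotation model.

Parses GTF into queryable per-gene models (transcription unit, exon union,
derived introns, CDS of the longest annotated ORF, 3'UTR, TSS) and provides
the region classification used by every downstream filter.

Coordinate conventions: GTF input is 1-based inclusive and converted to
0-based half-open internally; all BED-style I/O stays 0-based half-open.
Intron/exon indices are counted in transcription (5'->3') order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

Interval = tuple[int, int]

#: gene biotypes routed to the small-RNA interval list instead of the gene set
SMALLRNA_BIOTYPES = frozenset(
    {"miRNA", "snoRNA", "snRNA", "scaRNA", "retrotransposon", "rRNA"}
)


class RegionLabel(NamedTuple):
    """Region classification of a genomic position within a gene."""

    kind: str  # UTR3 | INTRON | EXON | OUTSIDE
    index: int | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.kind if self.index is None else f"{self.kind}({self.index})"


class GtfParseError(ValueError):
    """Malformed GTF record; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"GTF line {lineno}: {message}")
        self.lineno = lineno


@dataclass
class GeneModel:
    """One gene in internal 0-based half-open coordinates.

    ``exons`` is the union of exons over all transcripts (sorted genomically);
    ``introns`` is its complement within the transcription unit. ``cds`` holds
    the CDS intervals of the transcript with the longest annotated ORF and
    ``utr3`` the exonic intervals of that transcript 3' of the CDS.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str = "protein_coding"
    transcripts: dict[str, list[Interval]] = field(default_factory=dict)
    exons: list[Interval] = field(default_factory=list)
    introns: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    cds_transcript: str | None = None
    utr3: list[Interval] = field(default_factory=list)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """3'-most position of the transcription unit (inclusive)."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def utr3_end(self) -> int | None:
        """3'-most genomic position of the annotated 3'UTR (inclusive)."""
        if not self.utr3:
            return None
        if self.strand == "+":
            return max(e for _, e in self.utr3) - 1
        return min(s for s, _ in self.utr3)

    @property
    def utr3_start(self) -> int | None:
        """5'-most genomic position of the annotated 3'UTR (inclusive)."""
        if not self.utr3:
            return None
        if self.strand == "+":
            return min(s for s, _ in self.utr3)
        return max(e for _, e in self.utr3) - 1

    def intron_index(self, genomic_idx: int) -> int:
        """Map a genomically ordered intron index to transcription order."""
        if self.strand == "+":
            return genomic_idx
        return len(self.introns) - 1 - genomic_idx

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class GenomeAnnotation:
    """All genes plus the ambiguity metadata shared by the filter cascade."""

    genes: dict[str, GeneModel]
    overlap_flags: set[str] = field(default_factory=set)
    smallrna_intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return [g for g in self.genes.values() if g.chrom == chrom]

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        return [
            g
            for g in self.genes.values()
            if g.chrom == chrom and g.start < end and g.end > start
        ]


# ---------------------------------------------------------------------------
# GTF parsing
# ---------------------------------------------------------------------------


def _parse_attributes(raw: str, lineno: int) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        try:
            key, value = chunk.split(" ", 1)
        except ValueError:
            raise GtfParseError(lineno, f"bad attribute {chunk!r}")
        out[key] = value.strip().strip('"')
    return out


def _merge_intervals(ivs: Iterable[Interval]) -> list[Interval]:
    ivs = sorted(ivs)
    merged: list[Interval] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def load_annotation(
    gtf_source,
    smallrna_biotypes: frozenset[str] = SMALLRNA_BIOTYPES,
) -> GenomeAnnotation:
    """Load a GTF (path or iterable of lines) into a :class:`GenomeAnnotation`.

    Genes whose transcription units overlap any other gene on either strand
    are recorded in ``overlap_flags``. Genes with small-RNA biotypes are
    routed to ``smallrna_intervals`` rather than the gene collection, so they
    neither acquire nor trigger overlap flags.
    """
    if isinstance(gtf_source, (str, bytes)) or hasattr(gtf_source, "__fspath__"):
        with open(gtf_source) as fh:
            lines = fh.readlines()
    else:
        lines = list(gtf_source)

    exon_by_tx: dict[tuple[str, str], list[Interval]] = {}
    cds_by_tx: dict[tuple[str, str], list[Interval]] = {}
    gene_meta: dict[str, dict] = {}

    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GtfParseError(lineno, f"expected 9 fields, got {len(fields)}")
        chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError:
            raise GtfParseError(lineno, f"non-integer coordinates {start_s}..{end_s}")
        if start1 < 1 or end1 < start1:
            raise GtfParseError(lineno, f"invalid interval {start1}..{end1}")
        if strand not in "+-":
            raise GtfParseError(lineno, f"invalid strand {strand!r}")
        attrs = _parse_attributes(attrs_s, lineno)
        if "gene_id" not in attrs:
            raise GtfParseError(lineno, "missing gene_id attribute")
        gid = attrs["gene_id"]
        # GTF 1-based inclusive -> 0-based half-open
        iv = (start1 - 1, end1)
        meta = gene_meta.setdefault(
            gid,
            {
                "chrom": chrom,
                "strand": strand,
                "biotype": attrs.get("gene_biotype", attrs.get("biotype", "protein_coding")),
                "tx_ids": set(),
            },
        )
        if feature in ("gene", "transcript"):
            if "gene_biotype" in attrs or "biotype" in attrs:
                meta["biotype"] = attrs.get("gene_biotype", attrs.get("biotype"))
            if feature == "transcript" and "transcript_id" in attrs:
                meta["tx_ids"].add(attrs["transcript_id"])
            continue
        if feature not in ("exon", "CDS"):
            continue
        tid = attrs.get("transcript_id")
        if tid is None:
            raise GtfParseError(lineno, f"{feature} record without transcript_id")
        meta["tx_ids"].add(tid)
        target = exon_by_tx if feature == "exon" else cds_by_tx
        target.setdefault((gid, tid), []).append(iv)

    genes: dict[str, GeneModel] = {}
    smallrna: list[tuple[str, int, int]] = []
    for gid, meta in gene_meta.items():
        tx_exons = {
            tid: sorted(exon_by_tx[(gid, tid)])
            for tid in sorted(meta["tx_ids"])
            if (gid, tid) in exon_by_tx
        }
        skipped = [t for t in meta["tx_ids"] if (gid, t) not in exon_by_tx]
        for tid in skipped:
            warnings.warn(f"transcript {tid} of gene {gid} has no exons; skipped")
        if not tx_exons:
            continue
        exon_union = _merge_intervals(iv for ivs in tx_exons.values() for iv in ivs)
        tu_start = exon_union[0][0]
        tu_end = exon_union[-1][1]
        if meta["biotype"] in smallrna_biotypes:
            smallrna.append((meta["chrom"], tu_start, tu_end))
            continue
        introns = [
            (exon_union[i][1], exon_union[i + 1][0]) for i in range(len(exon_union) - 1)
        ]
        # longest annotated ORF: max summed CDS length, ties by transcript id
        cds_tx = None
        best = (-1, "")
        for tid in sorted(tx_exons):
            length = sum(e - s for s, e in cds_by_tx.get((gid, tid), []))
            if length > best[0]:
                best = (length, tid)
                cds_tx = tid if length > 0 else None
        cds = sorted(cds_by_tx.get((gid, cds_tx), [])) if cds_tx else []
        utr3 = _derive_utr3(tx_exons.get(cds_tx, []), cds, meta["strand"]) if cds else []
        genes[gid] = GeneModel(
            gene_id=gid,
            chrom=meta["chrom"],
            strand=meta["strand"],
            start=tu_start,
            end=tu_end,
            biotype=meta["biotype"],
            transcripts=tx_exons,
            exons=exon_union,
            introns=introns,
            cds=cds,
            cds_transcript=cds_tx,
            utr3=utr3,
        )

    ann = GenomeAnnotation(genes=genes, smallrna_intervals=smallrna)
    ann.overlap_flags = _flag_overlapping_genes(genes)
    return ann


def _derive_utr3(exons: list[Interval], cds: list[Interval], strand: str) -> list[Interval]:
    """Exonic intervals of the ORF transcript 3' of the CDS stop."""
    if not cds:
        return []
    out: list[Interval] = []
    if strand == "+":
        stop = max(e for _, e in cds)
        for s, e in exons:
            if e > stop:
                out.append((max(s, stop), e))
    else:
        stop = min(s for s, _ in cds)
        for s, e in exons:
            if s < stop:
                out.append((s, min(e, stop)))
    return sorted(out)


def _flag_overlapping_genes(genes: dict[str, GeneModel]) -> set[str]:
    flags: set[str] = set()
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes.values():
        by_chrom.setdefault(g.chrom, []).append(g)
    for glist in by_chrom.values():
        glist.sort(key=lambda g: g.start)
        active: list[GeneModel] = []
        for g in glist:
            active = [a for a in active if a.end > g.start]
            for a in active:
                flags.add(a.gene_id)
                flags.add(g.gene_id)
            active.append(g)
    return flags


# ---------------------------------------------------------------------------
# Region queries
# ---------------------------------------------------------------------------


def classify_position(gene: GeneModel, pos: int) -> RegionLabel:
    """Classify ``pos`` relative to ``gene`` as UTR3/INTRON(i)/EXON(i)/OUTSIDE."""
    if not gene.contains(pos):
        return RegionLabel("OUTSIDE")
    for s, e in gene.utr3:
        if s <= pos < e:
            return RegionLabel("UTR3")
    for gidx, (s, e) in enumerate(gene.introns):
        if s <= pos < e:
            return RegionLabel("INTRON", gene.intron_index(gidx))
    for gidx, (s, e) in enumerate(gene.exons):
        if s <= pos < e:
            tidx = gidx if gene.strand == "+" else len(gene.exons) - 1 - gidx
            return RegionLabel("EXON", tidx)
    return RegionLabel("OUTSIDE")  # pragma: no cover - TU is exon+intron tiled


def upstream_cds_length(gene: GeneModel, pos: int) -> int:
    """Coding nucleotides from the start codon through the end of the last
    coding exon 5' of an intronic position; 0 when the position precedes the
    start codon."""
    label = classify_position(gene, pos)
    if label.kind != "INTRON":
        raise ValueError(f"position {pos} is {label}, not intronic, in {gene.gene_id}")
    if gene.strand == "+":
        return sum(e - s for s, e in gene.cds if e <= pos)
    return sum(e - s for s, e in gene.cds if s >= pos)
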