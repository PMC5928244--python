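"""Synthetic-data generator with planted ground truth.

Emits a small artificial genome, gene annotation, per-sample 3'-seq peak
tables, RNA-seq coverage/junction/mappability/conservation tracks, unmapped
polyA-tail reads, and a two-group survival cohort. Every record is covered by
a :class:`SimTruth` entry so downstream stages can be tested without any
external data. All randomness flows from a single seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomeAnnotation
from .atlas import PeakSet

_CHROM_CAPACITY = 1_000_000
_GENE_GAP = 5_200  # keeps planted events clear of the 5000-nt upstream-gene rule
_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Knobs for the synthetic dataset; defaults give a desk-scale run."""

    n_genes: int = 60
    n_samples: int = 3  # per condition
    condition_names: tuple[str, ...] = ("A", "B")
    seed: int = 0
    ipa_fraction: float = 0.3
    ipa_usage_range: tuple[float, float] = (0.25, 0.75)
    diff_fraction: float = 0.0  # fraction of IpA genes with a usage shift in condition 2
    diff_shift: float = 0.4
    n_internal_priming: int = 3
    n_antisense: int = 3
    n_blacklist: int = 2
    n_pcr_duplicate: int = 1
    n_subthreshold: int = 3
    subthreshold_usage: float = 0.04
    nb_dispersion: float = 0.05
    clean_library_size: int = 500_000
    coverage_depth: float = 20.0
    intron_background: float = 1.0
    read_length: int = 50
    ir_fraction: float = 0.1
    at_content: float = 0.55
    external_support_fraction: float = 0.5
    polya_support_fraction: float = 0.5
    # cohort
    cohort_n: tuple[int, int] = (100, 100)
    hazard_ratio: float = 2.5
    baseline_hazard: float = 1.0 / 500.0
    censor_horizon: float = 2000.0
    hetero_fraction: float = 0.1
    n_signature: int = 10
    usage_low: float = 0.2
    usage_high: float = 0.6
    usage_sd: float = 0.07

    def validate(self) -> None:
        for name in (
            "ipa_fraction",
            "diff_fraction",
            "ir_fraction",
            "at_content",
            "hetero_fraction",
            "external_support_fraction",
            "polya_support_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        lo, hi = self.ipa_usage_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"ipa_usage_range {self.ipa_usage_range} invalid")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")

    @property
    def samples(self) -> list[str]:
        return [
            f"{cond}{i + 1}"
            for cond in self.condition_names
            for i in range(self.n_samples)
        ]

    def condition_of(self, sample: str) -> str:
        return sample.rstrip("0123456789")


@dataclass
class IpaEventTruth:
    gene_id: str
    chrom: str
    strand: str
    pos: int  # genomic 3'-end base (0-based)
    intron_index: int  # transcription order
    usage: dict[str, float]  # condition -> planted usage
    above_threshold: bool
    expected_tpm: dict[str, float] = field(default_factory=dict)
    external_support: bool = False
    polya_support: bool = False
    differential: bool = False


@dataclass
class ArtifactTruth:
    kind: str  # internal_priming | antisense | blacklist | immunoglobulin | pcr_duplicate
    chrom: str
    start: int
    end: int
    strand: str
    peak_id: str | None = None


@dataclass
class SimTruth:
    ipa_events: dict[str, IpaEventTruth] = field(default_factory=dict)
    artifacts: list[ArtifactTruth] = field(default_factory=list)
    gene_share: dict[str, float] = field(default_factory=dict)  # fraction of clean library
    ir_introns: set[tuple[str, int]] = field(default_factory=set)
    low_mappability_introns: set[tuple[str, int]] = field(default_factory=set)
    blacklist: pd.DataFrame | None = None
    ig_intervals: pd.DataFrame | None = None

    @property
    def artifact_peak_ids(self) -> set[str]:
        return {a.peak_id for a in self.artifacts if a.peak_id is not None}

    def event_key(self, gene_id: str, pos: int) -> str:
        return f"{gene_id}:{pos}"


# ---------------------------------------------------------------------------
# annotation + genome
# ---------------------------------------------------------------------------


def _tx_to_genomic(
    exons: list[tuple[int, int]], strand: str, a: int, b: int
) -> list[tuple[int, int]]:
    """Map transcription-coordinate interval [a,b) onto genomic intervals."""
    out = []
    offset = 0
    ordered = exons if strand == "+" else exons[::-1]
    for s, e in ordered:
        length = e - s
        lo, hi = max(a, offset), min(b, offset + length)
        if lo < hi:
            if strand == "+":
                out.append((s + (lo - offset), s + (hi - offset)))
            else:
                out.append((e - (hi - offset), e - (lo - offset)))
        offset += length
    return sorted(out)


def _random_sequence(rng: np.random.Generator, n: int, at: float) -> np.ndarray:
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return rng.choice(_BASES, size=n, p=p)


def _plant(seq: np.ndarray, pos: int, motif: str) -> None:
    seq[pos : pos + len(motif)] = np.frombuffer(motif.encode(), dtype="S1")


def simulate_annotation(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[GenomeAnnotation, dict[str, str], SimTruth]:
    """Build gene models and genome with planted IpA events and artifacts.

    IpA-designated genes receive a longer event intron (about twice the
    baseline), a PAS hexamer 25 nt upstream of the planted cleavage site, and
    an A-depleted tract downstream of it so the internal-priming filter never
    fires on true events. Every intron gets one canonical PAS at its midpoint
    (the expressed-intron universe for retention co-occurrence).
    """
    cfg.validate()
    truth = SimTruth()

    n_ipa = round(cfg.ipa_fraction * cfg.n_genes)
    order = rng.permutation(cfg.n_genes)
    ipa_set = set(order[:n_ipa])
    weak_set = set(order[n_ipa : n_ipa + cfg.n_subthreshold])
    pool = list(order[n_ipa + cfg.n_subthreshold :])
    ip_hosts = set(pool[: cfg.n_internal_priming])
    as_hosts = set(pool[cfg.n_internal_priming : cfg.n_internal_priming + cfg.n_antisense])
    pcr_hosts = set(
        pool[
            cfg.n_internal_priming
            + cfg.n_antisense : cfg.n_internal_priming
            + cfg.n_antisense
            + cfg.n_pcr_duplicate
        ]
    )

    n_diff = round(cfg.diff_fraction * n_ipa)
    diff_set = set(list(ipa_set)[:n_diff])

    genes: dict[str, GeneModel] = {}
    plans: list[dict] = []
    chrom_cursor: dict[str, int] = {}
    chrom_idx = 1

    for i in range(cfg.n_genes):
        gid = f"g{i:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(3, 7))
        exon_lens = rng.integers(150, 301, n_exons)
        intron_lens = rng.integers(500, 1200, n_exons - 1)
        is_ipa = i in ipa_set or i in weak_set
        ipa_intron = None
        if is_ipa or i in ip_hosts or i in as_hosts or i in pcr_hosts:
            ipa_intron = int(rng.integers(0, n_exons - 1))
        if is_ipa:
            intron_lens[ipa_intron] = int(rng.integers(1400, 2600))
        else:
            if ipa_intron is not None:
                intron_lens[ipa_intron] = max(intron_lens[ipa_intron], 900)
        span = int(exon_lens.sum() + intron_lens.sum())

        chrom = f"chrS{chrom_idx}"
        cursor = chrom_cursor.get(chrom, 1000)
        if cursor + span + _GENE_GAP > _CHROM_CAPACITY:
            chrom_idx += 1
            chrom = f"chrS{chrom_idx}"
            cursor = 1000
        gstart = cursor
        chrom_cursor[chrom] = cursor + span + _GENE_GAP

        exons = []
        pos = gstart
        for k in range(n_exons):
            exons.append((pos, pos + int(exon_lens[k])))
            pos += int(exon_lens[k])
            if k < n_exons - 1:
                pos += int(intron_lens[k])
        introns = [(exons[k][1], exons[k + 1][0]) for k in range(n_exons - 1)]

        total_exonic = int(exon_lens.sum())
        cds_start_t, utr3_len = 30, 150
        cds_end_t = total_exonic - utr3_len
        cds_end_t -= (cds_end_t - cds_start_t) % 3
        cds = _tx_to_genomic(exons, strand, cds_start_t, cds_end_t)
        utr3 = _tx_to_genomic(exons, strand, cds_end_t, total_exonic)
        # 5'UTR exonic fragment before the start codon is tiny (30 nt)

        genes[gid] = GeneModel(
            gene_id=gid,
            chrom=chrom,
            strand=strand,
            start=gstart,
            end=pos,
            transcripts={f"{gid}.t1": exons},
            exons=exons,
            introns=introns,
            cds=cds,
            cds_transcript=f"{gid}.t1",
            utr3=utr3,
        )
        plans.append(
            {
                "gid": gid,
                "idx": i,
                "chrom": chrom,
                "ipa_intron": ipa_intron,
                "is_strong": i in ipa_set,
                "is_weak": i in weak_set,
                "ip_host": i in ip_hosts,
                "as_host": i in as_hosts,
                "pcr_host": i in pcr_hosts,
                "differential": i in diff_set,
            }
        )

    # raw sequence
    chrom_len = {c: cur + 10_000 for c, cur in chrom_cursor.items()}
    genome_arr = {c: _random_sequence(rng, n, cfg.at_content) for c, n in chrom_len.items()}

    # one canonical PAS mid-intron everywhere (retention/conservation universe)
    for g in genes.values():
        arr = genome_arr[g.chrom]
        for s, e in g.introns:
            mid = (s + e) // 2
            _plant(arr, mid, "AATAAA" if g.strand == "+" else "TTTATT")

    def _plant_cleavage_site(g: GeneModel, p: int) -> None:
        # PAS 25 nt upstream, A-depleted downstream (internal-priming guard),
        # non-A sense bases at the cleavage site (polyA-trimming guard)
        arr = genome_arr[g.chrom]
        if g.strand == "+":
            _plant(arr, p - 30, "AATAAA")
            _plant(arr, p - 1, "GC")
            _plant(arr, p + 1, "CGTCGCGTCG")
        else:
            _plant(arr, p + 25, "TTTATT")
            _plant(arr, p, "GC")
            _plant(arr, p - 10, "CGCGCGCGCG")

    def _sanitize_utr_end(g: GeneModel) -> None:
        arr = genome_arr[g.chrom]
        end = g.utr3_end
        if g.strand == "+":
            _plant(arr, end + 1, "CGTCGCGTCG")
        else:
            _plant(arr, end - 10, "CGCGCGCGCG")

    conditions = cfg.condition_names
    for plan in plans:
        g = genes[plan["gid"]]
        _sanitize_utr_end(g)
        if plan["is_strong"] or plan["is_weak"]:
            s, e = g.introns[plan["ipa_intron"]]
            p = int(rng.integers(s + 320, e - 320))
            _plant_cleavage_site(g, p)
            if plan["is_weak"]:
                usage = {c: cfg.subthreshold_usage for c in conditions}
            else:
                base = float(rng.uniform(*cfg.ipa_usage_range))
                usage = {c: base for c in conditions}
                if plan["differential"] and len(conditions) > 1:
                    shifted = base + cfg.diff_shift * (1 if base < 0.5 else -1)
                    usage[conditions[1]] = float(np.clip(shifted, 0.02, 0.95))
            truth.ipa_events[truth.event_key(g.gene_id, p)] = IpaEventTruth(
                gene_id=g.gene_id,
                chrom=g.chrom,
                strand=g.strand,
                pos=p,
                intron_index=g.intron_index(plan["ipa_intron"]),
                usage=usage,
                above_threshold=plan["is_strong"],
                external_support=bool(rng.random() < cfg.external_support_fraction),
                polya_support=bool(rng.random() < cfg.polya_support_fraction),
                differential=plan["differential"],
            )
        elif plan["ip_host"]:
            s, e = g.introns[plan["ipa_intron"]]
            p = int(rng.integers(s + 320, e - 320))
            arr = genome_arr[g.chrom]
            if g.strand == "+":
                _plant(arr, p + 1, "AAAAAAA")
            else:
                _plant(arr, p - 7, "TTTTTTT")
            truth.artifacts.append(
                ArtifactTruth("internal_priming", g.chrom, p - 24, p + 1, g.strand)
            )
        elif plan["as_host"]:
            s, e = g.introns[plan["ipa_intron"]]
            p = int(rng.integers(s + 320, e - 320))
            anti = "-" if g.strand == "+" else "+"
            truth.artifacts.append(
                ArtifactTruth("antisense", g.chrom, p - 24, p + 1, anti)
            )
        elif plan["pcr_host"]:
            s, e = g.introns[plan["ipa_intron"]]
            p = int(rng.integers(s + 320, e - 320))
            _plant_cleavage_site(g, p)
            truth.artifacts.append(
                ArtifactTruth("pcr_duplicate", g.chrom, p - 24, p + 1, g.strand)
            )

    # retained introns, planted independently of IpA status
    for g in genes.values():
        for gidx in range(len(g.introns)):
            if rng.random() < cfg.ir_fraction:
                truth.ir_introns.add((g.gene_id, g.intron_index(gidx)))

    # blacklist intervals + an immunoglobulin-like locus in intergenic space
    first_chrom = "chrS1"
    tail = chrom_cursor[first_chrom]
    bl_rows = []
    for b in range(cfg.n_blacklist):
        s = tail + 500 + b * 1200
        bl_rows.append({"chrom": first_chrom, "start": s, "end": s + 200})
        truth.artifacts.append(ArtifactTruth("blacklist", first_chrom, s + 50, s + 75, "+"))
    truth.blacklist = pd.DataFrame(bl_rows, columns=["chrom", "start", "end"])
    ig_start = tail + 500 + cfg.n_blacklist * 1200 + 1000
    truth.ig_intervals = pd.DataFrame(
        [{"chrom": first_chrom, "start": ig_start, "end": ig_start + 2000}]
    )
    truth.artifacts.append(
        ArtifactTruth("immunoglobulin", first_chrom, ig_start + 900, ig_start + 925, "+")
    )

    genome = {c: genome_arr[c].tobytes().decode() for c in sorted(genome_arr)}
    ann = GenomeAnnotation(genes=genes, overlap_flags=set(), smallrna_intervals=[])
    return ann, genome, truth


# ---------------------------------------------------------------------------
# 3'-seq peaks
# ---------------------------------------------------------------------------


def _nb(rng: np.random.Generator, mean: float, alpha: float) -> int:
    if mean <= 0:
        return 0
    r = 1.0 / alpha
    return int(rng.negative_binomial(r, r / (r + mean)))


def simulate_threeprime(
    ann: GenomeAnnotation,
    truth: SimTruth,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[PeakSet, pd.Series]:
    """Emit per-sample peak tables with NB counts and read-start multisets.

    Returns the peak set and the raw per-sample library sizes (total counts
    including artifact and immunoglobulin peaks).
    """
    samples = cfg.samples
    weights = {gid: float(rng.uniform(0.5, 1.5)) for gid in sorted(ann.genes)}
    total_w = sum(weights.values())
    truth.gene_share = {gid: w / total_w for gid, w in weights.items()}
    libfactor = {s: float(rng.uniform(0.85, 1.15)) for s in samples}

    events_by_gene: dict[str, list[IpaEventTruth]] = {}
    for ev in truth.ipa_events.values():
        events_by_gene.setdefault(ev.gene_id, []).append(ev)

    rows, counts_rows, starts = [], [], {}
    pid_n = 0

    def _new_peak(chrom, end_pos, strand, mean_by_sample, duplicate_starts=False):
        nonlocal pid_n
        pid = f"pk{pid_n:05d}"
        pid_n += 1
        rows.append(
            {
                "peak_id": pid,
                "chrom": chrom,
                "start": end_pos - 24 if strand == "+" else end_pos,
                "end": end_pos + 1 if strand == "+" else end_pos + 25,
                "strand": strand,
            }
        )
        cnt = {}
        for s in samples:
            c = _nb(rng, mean_by_sample[s], cfg.nb_dispersion)
            cnt[s] = c
            if c > 0:
                n_draw = min(c, 40)
                if duplicate_starts:
                    st = np.full(n_draw, end_pos - 20 if strand == "+" else end_pos + 20)
                else:
                    offs = rng.integers(5, 46, n_draw)
                    st = end_pos - offs if strand == "+" else end_pos + offs
                starts[(pid, s)] = np.sort(st.astype(np.int64))
        counts_rows.append(cnt)
        return pid

    for gid in sorted(ann.genes):
        g = ann.genes[gid]
        share = truth.gene_share[gid]
        gene_events = sorted(events_by_gene.get(gid, []), key=lambda e: e.pos)
        ipa_usage_total = {
            s: sum(e.usage[cfg.condition_of(s)] for e in gene_events) for s in samples
        }
        for ev in gene_events:
            mean = {
                s: share
                * ev.usage[cfg.condition_of(s)]
                * cfg.clean_library_size
                * libfactor[s]
                for s in samples
            }
            _new_peak(g.chrom, ev.pos, g.strand, mean)
            ev.expected_tpm = {
                s: share * ev.usage[cfg.condition_of(s)] * 1e6 for s in samples
            }
        # distal 3'UTR peak carries the full-length share
        mean = {
            s: share
            * max(0.02, 1.0 - ipa_usage_total[s])
            * cfg.clean_library_size
            * libfactor[s]
            for s in samples
        }
        _new_peak(g.chrom, g.utr3_end, g.strand, mean)

    clean_total = {s: sum(c[s] for c in counts_rows) for s in samples}

    for art in truth.artifacts:
        end_pos = art.end - 1 if art.strand == "+" else art.start
        if art.kind == "immunoglobulin":
            mean = {s: 2.0 * clean_total[s] for s in samples}
        else:
            mean = {s: 40.0 * cfg.clean_library_size / 1e6 * libfactor[s] for s in samples}
        art.peak_id = _new_peak(
            art.chrom,
            end_pos,
            art.strand,
            mean,
            duplicate_starts=(art.kind == "pcr_duplicate"),
        )

    peaks = pd.DataFrame(rows).set_index("peak_id")
    counts = pd.DataFrame(counts_rows, index=peaks.index, columns=samples)
    raw_library = counts.sum(axis=0)
    return PeakSet(peaks=peaks, counts=counts, starts=starts), raw_library


def external_peaks_bed(truth: SimTruth) -> pd.DataFrame:
    """BED of externally supported planted 3' ends (other 3'-seq protocols)."""
    rows = []
    for key, ev in truth.ipa_events.items():
        if ev.external_support:
            rows.append(
                {
                    "chrom": ev.chrom,
                    "start": ev.pos - 10,
                    "end": ev.pos + 10,
                    "name": key,
                    "score": 0,
                    "strand": ev.strand,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


# ---------------------------------------------------------------------------
# RNA-seq
# ---------------------------------------------------------------------------


@dataclass
class RnaSeqSim:
    coverage: dict[str, dict[str, np.ndarray]]  # sample -> chrom -> per-base reads
    junctions: pd.DataFrame
    mappability: dict[str, np.ndarray]
    conservation: dict[str, np.ndarray]
    polya_reads: dict[str, str]


def _add_reads(
    cov: np.ndarray, rng: np.random.Generator, s: int, e: int, lam: float, read_length: int
) -> None:
    """Drop Poisson read-sized coverage blocks fully inside [s,e).

    Interior per-base coverage averages ``lam``; window sums divided by the
    read length then behave like (near-)Poisson read counts, which is what
    the coverage-drop test models. The segment 3' edge stays sharp."""
    L = read_length
    if e - s <= L or lam <= 0:
        return
    n = int(rng.poisson(lam * (e - s - L) / L))
    if n == 0:
        return
    starts = rng.integers(s, e - L, n)
    binc = np.bincount(starts - s, minlength=e - s)
    cs = np.cumsum(binc)
    window = cs.copy()
    window[L:] = cs[L:] - cs[:-L]
    cov[s:e] += window.astype(cov.dtype)


def simulate_rnaseq(
    ann: GenomeAnnotation,
    genome: Mapping[str, str],
    truth: SimTruth,
    cfg: SimConfig,
    rng: np.random.Generator,
    samples: list[str] | None = None,
) -> RnaSeqSim:
    """Poisson per-base coverage, junction counts, mappability/conservation
    tracks, and untemplated-A reads for planted cleavage sites.

    Intronic coverage upstream of a planted IpA end scales with usage and
    drops to background downstream; retained introns get uniform coverage at
    30% of the exon rate plus boundary-spanning junction reads.
    """
    samples = samples or cfg.samples
    chrom_len = {c: len(genome[c]) for c in genome}
    coverage = {
        s: {c: np.zeros(n, dtype=np.float32) for c, n in chrom_len.items()}
        for s in samples
    }
    mappability = {c: np.ones(n, dtype=np.float32) for c, n in chrom_len.items()}
    conservation = {c: np.full(n, 0.1, dtype=np.float32) for c, n in chrom_len.items()}

    events_by_intron: dict[tuple[str, int], IpaEventTruth] = {
        (ev.gene_id, ev.intron_index): ev for ev in truth.ipa_events.values()
    }

    # low-mappability introns: a few IpA-free, IR-free introns
    candidates = []
    for gid in sorted(ann.genes):
        g = ann.genes[gid]
        for gidx in range(len(g.introns)):
            key = (gid, g.intron_index(gidx))
            if key not in events_by_intron and key not in truth.ir_introns:
                candidates.append(key)
    if candidates and not truth.low_mappability_introns:
        picks = rng.choice(len(candidates), size=min(2, len(candidates)), replace=False)
        truth.low_mappability_introns = {candidates[i] for i in picks}
    for gid, tidx in sorted(truth.low_mappability_introns):
        g = ann.genes[gid]
        gidx = g.intron_index(tidx)  # involution
        s, e = g.introns[gidx]
        span = int(0.6 * (e - s))
        mappability[g.chrom][s : s + span] = 0.0

    junc_rows = []
    for sample in samples:
        for gid in sorted(ann.genes):
            g = ann.genes[gid]
            cov = coverage[sample][g.chrom]
            f = cfg.coverage_depth * float(rng.uniform(0.7, 1.3))
            for s, e in g.exons:
                _add_reads(cov, rng, s, e, f, cfg.read_length)
            for gidx, (s, e) in enumerate(g.introns):
                tidx = g.intron_index(gidx)
                _add_reads(cov, rng, s, e, cfg.intron_background, cfg.read_length)
                retained = (gid, tidx) in truth.ir_introns
                if retained:
                    _add_reads(cov, rng, s, e, 0.3 * f, cfg.read_length)
                ev = events_by_intron.get((gid, tidx))
                if ev is not None:
                    cond = cfg.condition_of(sample) if sample in cfg.samples else None
                    u = ev.usage.get(cond, next(iter(ev.usage.values())))
                    if g.strand == "+":
                        _add_reads(cov, rng, s, ev.pos + 1, f * u, cfg.read_length)
                    else:
                        _add_reads(cov, rng, ev.pos, e, f * u, cfg.read_length)
                span_mean = max(6.0, 0.3 * f * 0.4) if retained else 0.3
                junc_rows.append(
                    {
                        "gene_id": gid,
                        "intron_index": tidx,
                        "chrom": g.chrom,
                        "start": s,
                        "end": e,
                        "strand": g.strand,
                        "sample": sample,
                        "left_count": int(rng.poisson(span_mean)),
                        "right_count": int(rng.poisson(span_mean)),
                    }
                )

    # conserved block around every planted cleavage site
    for ev in truth.ipa_events.values():
        conservation[ev.chrom][max(0, ev.pos - 25) : ev.pos + 26] = 0.7

    polya_reads: dict[str, str] = {}
    n_read = 0
    for key in sorted(truth.ipa_events):
        ev = truth.ipa_events[key]
        if not ev.polya_support:
            continue
        seq = genome[ev.chrom]
        for j in range(6):
            length = 25 + j
            if ev.strand == "+":
                core = seq[ev.pos + 1 - length : ev.pos + 1]
            else:
                from .seqfeat import revcomp

                core = revcomp(seq[ev.pos : ev.pos + length])
            polya_reads[f"pa{n_read:05d}"] = core + "A" * 5
            n_read += 1
    # decoys: a too-short trimmed read and a read without an A tail
    anychrom = next(iter(genome))
    polya_reads[f"pa{n_read:05d}"] = genome[anychrom][500:515] + "AAAAA"
    polya_reads[f"pa{n_read + 1:05d}"] = genome[anychrom][600:640]

    junctions = pd.DataFrame(junc_rows)
    return RnaSeqSim(coverage, junctions, mappability, conservation, polya_reads)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def simulate_cohort(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Two-group patient cohort with signature usage, PFS and censoring.

    Group A (low usage) carries ``hazard_ratio`` times the baseline hazard of
    group B (high usage). Heterogeneous patients draw each signature event
    from the low or high regime at random, placing them between the groups.
    """
    cfg.validate()
    n_a, n_b = cfg.cohort_n
    k = cfg.n_signature
    rows = []
    usage_rows = []
    for i in range(n_a + n_b):
        group = "A" if i < n_a else "B"
        hetero = bool(rng.random() < cfg.hetero_fraction)
        if hetero:
            mask = rng.random(k) < 0.5
            mu = np.where(mask, cfg.usage_low, cfg.usage_high)
        else:
            mu = np.full(k, cfg.usage_low if group == "A" else cfg.usage_high)
        usage = np.clip(rng.normal(mu, cfg.usage_sd), 0.0, 1.0)
        hazard = cfg.baseline_hazard * (cfg.hazard_ratio if group == "A" else 1.0)
        if hetero:
            hazard = cfg.baseline_hazard * np.sqrt(cfg.hazard_ratio)
        t = float(rng.exponential(1.0 / hazard))
        c = float(rng.uniform(0, cfg.censor_horizon))
        rows.append(
            {
                "patient": f"p{i:04d}",
                "true_group": group,
                "hetero": hetero,
                "pfs_days": min(t, c),
                "event": int(t <= c),
            }
        )
        usage_rows.append(usage)
    cohort = pd.DataFrame(rows)
    usage_df = pd.DataFrame(
        np.vstack(usage_rows),
        columns=[f"ev{j:02d}" for j in range(k)],
        index=cohort["patient"],
    )
    return pd.concat([cohort.set_index("patient"), usage_df], axis=1).reset_index()
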