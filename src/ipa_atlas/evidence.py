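"""Five-tier validation of candidate IpA events.

Each intronic event is checked against (1) annotated last exons, (2) an
upstream-vs-downstream RNA-seq coverage test, (3) external 3'-end peak sets,
(4) untemplated-A read support, and (5) a stringent expression cutoff; the
confident atlas keeps events matching at least one source, labelled by the
first matching tier in that precedence order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import binom, nbinom

from ._stats import bh_adjust
from .annotation import GenomeAnnotation
from .atlas import Atlas
from .seqfeat import MotifConfig, pas_upstream, revcomp

TIER_ORDER = ["ANNOTATED", "RNASEQ_GLM", "EXTERNAL_3P", "POLYA_READS", "HIGH_EXPRESSION"]


# ---------------------------------------------------------------------------
# NB exact test
# ---------------------------------------------------------------------------


def _raw_dispersion_mom(up: np.ndarray, down: np.ndarray) -> float | None:
    """Unclipped within-side moment estimate of the NB dispersion (the
    up/down signal does not inflate it); may be negative, None when both
    sides are empty of signal."""
    vals = []
    for side in (np.asarray(up, float), np.asarray(down, float)):
        m = side.mean()
        if m <= 0 or side.size < 2:
            continue
        vals.append((side.var(ddof=1) - m) / (m * m))
    if not vals:
        return None
    return float(np.mean(vals))


def estimate_dispersion_mom(
    up: np.ndarray, down: np.ndarray, floor: float = 0.01
) -> float:
    """Per-event method-of-moments NB dispersion, floored. Note that with two
    replicate windows per side this is noisy and clipping makes the exact
    test conservative; :func:`glm_test_positions` therefore pools the raw
    estimates across events (as DESeq shares dispersion information)."""
    raw = _raw_dispersion_mom(up, down)
    return floor if raw is None else max(raw, floor)


def nb_exact_test(
    up: Iterable[int],
    down: Iterable[int],
    alpha: float | None = None,
    midp: bool = True,
    floor: float = 0.01,
) -> float:
    """One-sided (upstream > downstream) NB exact test conditional on the
    total count, with per-event moment dispersion.

    The two replicate windows per side are pooled; each side total is modelled
    NB with mean T/2 and size 2/alpha, and the p-value is the conditional tail
    probability of a split at least as extreme as observed. ``midp`` subtracts
    half the observed atom, which keeps the null distribution close to
    uniform despite the discrete support.
    """
    up = np.asarray(list(up), dtype=np.int64)
    down = np.asarray(list(down), dtype=np.int64)
    if alpha is None:
        alpha = estimate_dispersion_mom(up, down, floor=floor)
    a_obs = int(up.sum())
    total = a_obs + int(down.sum())
    if total == 0:
        return 1.0
    support = np.arange(total + 1)
    if alpha < 1e-8:
        # Poisson limit: conditional law is Binomial(total, 1/2)
        logw = binom.logpmf(support, total, 0.5)
    else:
        r = 2.0 / alpha  # two replicate windows per side
        mu = total / 2.0
        p = r / (r + mu)
        logf = nbinom.logpmf(support, r, p)
        logw = logf + logf[::-1]
    logw = logw - logw.max()
    w = np.exp(logw)
    w /= w.sum()
    tail = float(w[a_obs:].sum())
    if midp:
        tail -= 0.5 * float(w[a_obs])
    return min(max(tail, 0.0), 1.0)


# ---------------------------------------------------------------------------
# window geometry
# ---------------------------------------------------------------------------


def _win(pos: int, strand: str, a: int, b: int) -> tuple[int, int]:
    """Genomic interval for transcription offsets [a,b) around the 3' end."""
    if strand == "+":
        return pos + a, pos + b
    return pos - b + 1, pos - a + 1


def glm_windows(pos: int, strand: str, width: int = 100, gap: int = 51):
    """Two upstream and two downstream windows flanking the cleavage base.

    The proximal windows abut the 3' end; the distal ones sit ``gap`` nt
    further out. Returned as (up1, up2, down1, down2) genomic intervals."""
    up2 = _win(pos, strand, -width, 0)
    up1 = _win(pos, strand, -(2 * width + gap), -(width + gap))
    down1 = _win(pos, strand, 1, width + 1)
    down2 = _win(pos, strand, width + gap + 1, 2 * width + gap + 1)
    return up1, up2, down1, down2


def window_counts(
    coverage: np.ndarray, windows, read_length: int
) -> np.ndarray | None:
    """Rounded per-window coverage sums divided by the read length; None when
    a window runs off the chromosome."""
    out = []
    for s, e in windows:
        if s < 0 or e > coverage.size:
            return None
        out.append(int(round(float(coverage[s:e].sum()) / read_length)))
    return np.array(out, dtype=np.int64)


def test_event_glm(
    pos: int,
    strand: str,
    coverage: np.ndarray,
    read_length: int = 50,
    width: int = 100,
    gap: int = 51,
    alpha: float | None = None,
    midp: bool = True,
) -> float | None:
    """Coverage drop test at one putative 3' end; None when untestable."""
    wins = glm_windows(pos, strand, width, gap)
    counts = window_counts(coverage, wins, read_length)
    if counts is None:
        return None
    return nb_exact_test(counts[:2], counts[2:], alpha=alpha, midp=midp)


def glm_test_positions(
    positions,
    coverage: Mapping[str, np.ndarray],
    read_length: int = 50,
    width: int = 100,
    gap: int = 51,
    alpha: float | None = None,
    midp: bool = True,
    dispersion_floor: float = 0.0,
) -> np.ndarray:
    """Coverage-drop p-values for (chrom, pos, strand) tuples in one sample.

    When ``alpha`` is None, a single dispersion is pooled across all testable
    positions from the unclipped per-position moment estimates — dispersion
    sharing in the spirit of DESeq; a per-position clipped estimate would be
    badly conservative with only two replicate windows per side. Returns NaN
    for positions whose windows leave the chromosome."""
    all_counts: list[np.ndarray | None] = []
    for chrom, pos, strand in positions:
        cov = coverage.get(chrom)
        counts = (
            None
            if cov is None
            else window_counts(cov, glm_windows(pos, strand, width, gap), read_length)
        )
        all_counts.append(counts)
    if alpha is None:
        raws = [
            _raw_dispersion_mom(c[:2], c[2:]) for c in all_counts if c is not None
        ]
        raws = [r for r in raws if r is not None]
        alpha = max(float(np.mean(raws)) if raws else 0.0, dispersion_floor)
    return np.array(
        [
            np.nan
            if c is None
            else nb_exact_test(c[:2], c[2:], alpha=alpha, midp=midp)
            for c in all_counts
        ]
    )


def _exons_by_chrom(annotation: GenomeAnnotation) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for g in annotation.genes.values():
        out.setdefault(g.chrom, []).extend(g.exons)
    for c in out:
        out[c].sort()
    return out


def _overlaps_any(ivs: list[tuple[int, int]], s: int, e: int) -> bool:
    return any(s < ie and e > is_ for is_, ie in ivs)


def evidence_rnaseq_glm(
    atlas: Atlas,
    annotation: GenomeAnnotation,
    coverage_by_sample: Mapping[str, Mapping[str, np.ndarray]],
    read_length: int = 50,
    fdr_threshold: float = 0.1,
    midp: bool = True,
) -> pd.DataFrame:
    """Upstream>downstream coverage test for every IpA event, per sample.

    Events whose windows overlap an annotated exon (or fall off the
    chromosome) are untestable. P-values are BH-adjusted per sample across
    tested events; an event is validated when any sample reaches the FDR
    threshold. Returns a frame indexed by event id with glm_p / glm_fdr
    (best across samples), testable and validated columns."""
    exons = _exons_by_chrom(annotation)
    ipa = atlas.events[atlas.events["klass"] == "IPA"]
    samples = list(coverage_by_sample)
    pvals = pd.DataFrame(np.nan, index=ipa.index, columns=samples)
    testable_ids = []
    for eid, row in ipa.iterrows():
        pos, strand, chrom = int(row["rep_pos"]), row["strand"], row["chrom"]
        wins = glm_windows(pos, strand)
        if not any(_overlaps_any(exons.get(chrom, []), s, e) for s, e in wins):
            testable_ids.append(eid)
    positions = [
        (ipa.loc[eid, "chrom"], int(ipa.loc[eid, "rep_pos"]), ipa.loc[eid, "strand"])
        for eid in testable_ids
    ]
    for sample in samples:
        if not positions:
            break
        ps = glm_test_positions(
            positions, coverage_by_sample[sample], read_length=read_length, midp=midp
        )
        pvals.loc[testable_ids, sample] = ps
    testable = pd.Series(False, index=ipa.index)
    testable[pvals.notna().any(axis=1)] = True
    fdr = pd.DataFrame(
        {s: bh_adjust(pvals[s].to_numpy()) for s in samples}, index=pvals.index
    )
    best_fdr = fdr.min(axis=1)
    out = pd.DataFrame(
        {
            "glm_p": pvals.min(axis=1),
            "glm_fdr": best_fdr,
            "glm_testable": testable,
            "glm_validated": testable & (best_fdr < fdr_threshold),
        }
    )
    return out


# ---------------------------------------------------------------------------
# other evidence sources
# ---------------------------------------------------------------------------


def evidence_annotation(
    atlas: Atlas,
    annotations: Iterable[GenomeAnnotation],
    extension: int = 100,
) -> set[str]:
    """Events whose representative 3' end overlaps any annotated transcript's
    last exon extended ``extension`` nt downstream."""
    matched: set[str] = set()
    windows: dict[str, list[tuple[int, int]]] = {}
    for ann in annotations:
        for g in ann.genes.values():
            for exons in g.transcripts.values():
                if g.strand == "+":
                    s, e = exons[-1]
                    iv = (s, e + extension)
                else:
                    s, e = exons[0]
                    iv = (s - extension, e)
                windows.setdefault(g.chrom, []).append(iv)
    ipa = atlas.events[atlas.events["klass"] == "IPA"]
    for eid, row in ipa.iterrows():
        pos = int(row["rep_pos"])
        if any(s <= pos < e for s, e in windows.get(row["chrom"], [])):
            matched.add(eid)
    return matched


def evidence_external_3p(atlas: Atlas, external_peaks: pd.DataFrame | None) -> set[str]:
    """Events whose 3' end overlaps an external peak resized to 75 nt (25 nt
    upstream, 50 nt downstream of the original start, strand-aware)."""
    matched: set[str] = set()
    if external_peaks is None or len(external_peaks) == 0:
        return matched
    resized = []
    for _, r in external_peaks.iterrows():
        if r["strand"] == "+":
            resized.append((r["chrom"], int(r["start"]) - 25, int(r["start"]) + 50, "+"))
        else:
            resized.append((r["chrom"], int(r["end"]) - 50, int(r["end"]) + 25, "-"))
    ipa = atlas.events[atlas.events["klass"] == "IPA"]
    for eid, row in ipa.iterrows():
        pos = int(row["rep_pos"])
        for chrom, s, e, strand in resized:
            if chrom == row["chrom"] and strand == row["strand"] and s <= pos < e:
                matched.add(eid)
                break
    return matched


def trim_polya(read: str, min_run: int = 4) -> str | None:
    """Strip the terminal A-run when it is ``min_run`` or longer."""
    seq = read.upper()
    n = len(seq)
    i = n
    while i > 0 and seq[i - 1] == "A":
        i -= 1
    if n - i < min_run:
        return None
    return seq[:i]


@dataclass
class AlignedRead:
    chrom: str
    start: int
    end: int
    strand: str

    @property
    def end3(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


def align_trimmed_reads(
    reads: Mapping[str, str],
    genome: Mapping[str, str],
    min_length: int = 21,
) -> list[AlignedRead]:
    """Exact-substring alignment of trimmed polyA reads; reads at or below
    ``min_length`` nt after trimming, unalignable reads, and duplicate mapped
    coordinates are dropped."""
    seen: set[tuple[str, int, int, str]] = set()
    out: list[AlignedRead] = []
    for name in sorted(reads):
        trimmed = trim_polya(reads[name])
        if trimmed is None or len(trimmed) <= min_length:
            continue
        hit = None
        for chrom in sorted(genome):
            i = genome[chrom].find(trimmed)
            if i >= 0:
                hit = (chrom, i, i + len(trimmed), "+")
                break
            j = genome[chrom].find(revcomp(trimmed))
            if j >= 0:
                hit = (chrom, j, j + len(trimmed), "-")
                break
        if hit is None or hit in seen:
            continue
        seen.add(hit)
        out.append(AlignedRead(*hit))
    return out


def evidence_polya_reads(
    atlas: Atlas,
    unmapped_reads: Mapping[str, str],
    genome: Mapping[str, str],
    motifs: MotifConfig | None = None,
    min_reads: int = 4,
    extend: int = 20,
    pas_window: int = 50,
) -> pd.DataFrame:
    """Untemplated-A read support: trimmed reads whose mapped 3' end falls in
    the event peak extended +/-``extend`` nt; validated at ``min_reads`` or
    more together with an upstream PAS."""
    aligned = align_trimmed_reads(unmapped_reads, genome)
    ipa = atlas.events[atlas.events["klass"] == "IPA"]
    counts, pas_flags = {}, {}
    for eid, row in ipa.iterrows():
        lo, hi = int(row["start"]) - extend, int(row["end"]) + extend
        n = sum(
            1
            for r in aligned
            if r.chrom == row["chrom"] and r.strand == row["strand"] and lo <= r.end3 < hi
        )
        counts[eid] = n
        pas_flags[eid] = pas_upstream(
            row["strand"], int(row["rep_pos"]), genome[row["chrom"]], motifs, pas_window
        )
    out = pd.DataFrame({"polya_reads": pd.Series(counts), "pas": pd.Series(pas_flags)})
    out["polya_validated"] = (out["polya_reads"] >= min_reads) & out["pas"]
    return out


def evidence_high_expression(
    atlas: Atlas,
    genome: Mapping[str, str],
    motifs: MotifConfig | None = None,
    tpm_min: float = 10.0,
    usage_min: float = 0.1,
    pas_window: int = 50,
) -> set[str]:
    """Stringent rescue: >=10 TPM and >=0.1 usage in the same sample for some
    sample, plus an upstream PAS."""
    if atlas.usage is None:
        raise ValueError("compute_usage must run before high-expression evidence")
    matched: set[str] = set()
    ipa = atlas.events[atlas.events["klass"] == "IPA"]
    for eid, row in ipa.iterrows():
        hit = (
            (atlas.tpm.loc[eid] >= tpm_min) & (atlas.usage.loc[eid].fillna(-1) >= usage_min)
        ).any()
        if not hit:
            continue
        if pas_upstream(
            row["strand"], int(row["rep_pos"]), genome[row["chrom"]], motifs, pas_window
        ):
            matched.add(eid)
    return matched


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def build_evidence_table(
    atlas: Atlas,
    annotated: set[str],
    glm: pd.DataFrame | None,
    external: set[str],
    polya: pd.DataFrame | None,
    high_expr: set[str],
) -> pd.DataFrame:
    """Combine the five passes into one tier per IpA event (precedence
    ANNOTATED > RNASEQ_GLM > EXTERNAL_3P > POLYA_READS > HIGH_EXPRESSION)."""
    ipa = atlas.events[atlas.events["klass"] == "IPA"]
    rows = []
    for eid in ipa.index:
        glm_ok = bool(glm is not None and eid in glm.index and glm.loc[eid, "glm_validated"])
        polya_ok = bool(
            polya is not None and eid in polya.index and polya.loc[eid, "polya_validated"]
        )
        flags = {
            "ANNOTATED": eid in annotated,
            "RNASEQ_GLM": glm_ok,
            "EXTERNAL_3P": eid in external,
            "POLYA_READS": polya_ok,
            "HIGH_EXPRESSION": eid in high_expr,
        }
        tier = next((t for t in TIER_ORDER if flags[t]), "UNVALIDATED")
        rows.append(
            {
                "event_id": eid,
                "tier": tier,
                "annotated": eid in annotated,
                "glm_p": glm.loc[eid, "glm_p"] if glm is not None and eid in glm.index else np.nan,
                "glm_fdr": glm.loc[eid, "glm_fdr"] if glm is not None and eid in glm.index else np.nan,
                "polya_reads": int(polya.loc[eid, "polya_reads"]) if polya is not None and eid in polya.index else 0,
                "pas": bool(polya.loc[eid, "pas"]) if polya is not None and eid in polya.index else False,
            }
        )
    return pd.DataFrame(rows).set_index("event_id")


def build_confident_atlas(atlas: Atlas, evidence: pd.DataFrame) -> Atlas:
    """Drop UNVALIDATED IpA events; 3'UTR events always stay."""
    keep_ipa = evidence.index[evidence["tier"] != "UNVALIDATED"]
    utr = atlas.events.index[atlas.events["klass"] == "UTR3"]
    keep = atlas.events.index[atlas.events.index.isin(set(keep_ipa) | set(utr))]
    out = atlas.subset(keep)
    if atlas.usage is not None:
        out.usage = atlas.usage.loc[keep]
    return out
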