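"""Peak filter cascade, clustering and usage statistics.

Turns raw per-sample 3'-seq peak tables into a quantified atlas of intronic
(IpA) and 3'UTR cleavage events: artifact and ambiguity flags, library-size
adjustment, TPM quantification, 200-nt single-linkage clustering, relative
usage, robustness filters, and per-cell-type expression calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import ceil
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation, classify_position
from .seqfeat import revcomp

FLAG_COLUMNS = [
    "blacklist",
    "internal_priming",
    "antisense",
    "immunoglobulin",
    "ambiguous_gene",
    "smallrna",
    "convergent_3utr_proximal",
    "upstream_gene_proximal",
]


@dataclass
class PeakSet:
    """Raw peaks with per-sample counts and read-start multisets.

    ``peaks`` is indexed by peak id with columns chrom/start/end/strand plus,
    after gene assignment, gene_id/region/intron_index, plus boolean flag
    columns. Flags are monotone: operations only ever set them.
    """

    peaks: pd.DataFrame
    counts: pd.DataFrame
    starts: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def copy(self) -> "PeakSet":
        return PeakSet(self.peaks.copy(), self.counts.copy(), dict(self.starts))

    def ensure_flags(self) -> None:
        for col in FLAG_COLUMNS:
            if col not in self.peaks.columns:
                self.peaks[col] = False

    @property
    def flagged(self) -> pd.Series:
        self.ensure_flags()
        return self.peaks[FLAG_COLUMNS].any(axis=1)

    def end3(self, pid: str) -> int:
        row = self.peaks.loc[pid]
        return int(row["end"]) - 1 if row["strand"] == "+" else int(row["start"])

    def end3_series(self) -> pd.Series:
        plus = self.peaks["strand"] == "+"
        return (self.peaks["end"] - 1).where(plus, self.peaks["start"])


@dataclass
class LibraryInfo:
    """Per-sample raw and artifact-adjusted library sizes."""

    table: pd.DataFrame  # index sample; columns raw, adjusted

    @property
    def adjusted(self) -> pd.Series:
        return self.table["adjusted"]


@dataclass
class Atlas:
    """Clustered cleavage events with per-sample quantities."""

    events: pd.DataFrame  # index event_id
    counts: pd.DataFrame
    tpm: pd.DataFrame
    iqr: pd.DataFrame
    starts: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    usage: pd.DataFrame | None = None

    def subset(self, event_ids) -> "Atlas":
        idx = self.events.index.intersection(event_ids)
        return Atlas(
            events=self.events.loc[idx],
            counts=self.counts.loc[idx],
            tpm=self.tpm.loc[idx],
            iqr=self.iqr.loc[idx],
            starts={k: v for k, v in self.starts.items() if k[0] in set(idx)},
            usage=None if self.usage is None else self.usage.loc[idx],
        )

    def as_peakset(self) -> PeakSet:
        """Re-express events as a peak table (3' end at the representative
        position), e.g. to check clustering idempotence."""
        rows = []
        starts = {}
        for eid, row in self.events.iterrows():
            if row["strand"] == "+":
                s, e = int(row["start"]), int(row["rep_pos"]) + 1
            else:
                s, e = int(row["rep_pos"]), int(row["end"])
            rows.append(
                {
                    "peak_id": eid,
                    "chrom": row["chrom"],
                    "start": s,
                    "end": e,
                    "strand": row["strand"],
                    "gene_id": row["gene_id"],
                    "region": "UTR3" if row["klass"] == "UTR3" else "INTRON",
                    "intron_index": row["intron_index"],
                }
            )
        for (eid, sample), arr in self.starts.items():
            starts[(eid, sample)] = arr
        peaks = pd.DataFrame(rows).set_index("peak_id")
        return PeakSet(peaks=peaks, counts=self.counts.copy(), starts=starts)


# ---------------------------------------------------------------------------
# gene assignment
# ---------------------------------------------------------------------------


def assign_genes(peakset: PeakSet, annotation: GenomeAnnotation) -> PeakSet:
    """Attach gene_id / region / intron_index by the peak's 3'-end position.

    A peak is assigned to the same-strand gene whose transcription unit
    contains its 3' end; peaks matching no same-strand gene stay unassigned
    (the antisense filter deals with opposite-strand overlaps)."""
    ps = peakset.copy()
    gene_ids, regions, intron_idx = [], [], []
    for pid, row in ps.peaks.iterrows():
        pos3 = ps.end3(pid)
        hits = [
            g
            for g in annotation.overlapping(row["chrom"], pos3, pos3 + 1)
            if g.strand == row["strand"]
        ]
        if hits:
            gene = sorted(hits, key=lambda g: g.gene_id)[0]
            label = classify_position(gene, pos3)
            gene_ids.append(gene.gene_id)
            regions.append(label.kind)
            intron_idx.append(label.index if label.kind == "INTRON" else -1)
        else:
            gene_ids.append(None)
            regions.append("UNASSIGNED")
            intron_idx.append(-1)
    ps.peaks["gene_id"] = gene_ids
    ps.peaks["region"] = regions
    ps.peaks["intron_index"] = intron_idx
    return ps


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def _a_rich(seq: str, min_run: int, min_count: int) -> bool:
    best = run = 0
    for b in seq:
        run = run + 1 if b == "A" else 0
        best = max(best, run)
    return best >= min_run or seq.count("A") >= min_count


def filter_artifact_peaks(
    peakset: PeakSet,
    blacklist: pd.DataFrame | None,
    genome: Mapping[str, str],
    annotation: GenomeAnnotation,
    a_run: int = 6,
    a_count: int = 7,
    window: int = 10,
) -> PeakSet:
    """Flag blacklist-overlapping, internally primed, and antisense peaks.

    Internal priming: the ``window`` nt of genomic sequence downstream of the
    3' end (sense strand) contains a run of >=``a_run`` A or >=``a_count`` A
    in total. Antisense: the peak overlaps exactly one gene and sits on the
    opposite strand.
    """
    ps = peakset.copy()
    ps.ensure_flags()
    bl_by_chrom: dict[str, list[tuple[int, int]]] = {}
    if blacklist is not None and len(blacklist):
        for _, r in blacklist.iterrows():
            bl_by_chrom.setdefault(r["chrom"], []).append((int(r["start"]), int(r["end"])))
    for pid, row in ps.peaks.iterrows():
        chrom, start, end, strand = row["chrom"], int(row["start"]), int(row["end"]), row["strand"]
        seq = genome[chrom]
        if end > len(seq) or start < 0:
            raise ValueError(f"peak {pid} [{start},{end}) beyond chromosome {chrom}")
        for s, e in bl_by_chrom.get(chrom, []):
            if start < e and end > s:
                ps.peaks.loc[pid, "blacklist"] = True
                break
        pos3 = ps.end3(pid)
        if strand == "+":
            down = seq[pos3 + 1 : pos3 + 1 + window]
        else:
            down = revcomp(seq[max(0, pos3 - window) : pos3])
        if _a_rich(down.upper(), a_run, a_count):
            ps.peaks.loc[pid, "internal_priming"] = True
        overlapping = annotation.overlapping(chrom, start, end)
        if len(overlapping) == 1 and overlapping[0].strand != strand:
            ps.peaks.loc[pid, "antisense"] = True
    return ps


def mask_ig_adjust_library(
    peakset: PeakSet,
    ig_intervals: pd.DataFrame | None,
    raw_library: pd.Series,
) -> tuple[PeakSet, LibraryInfo]:
    """Flag immunoglobulin-region peaks and derive adjusted library sizes:
    raw minus the counts of every flagged peak (artifacts + Ig)."""
    ps = peakset.copy()
    ps.ensure_flags()
    if ig_intervals is not None and len(ig_intervals):
        for pid, row in ps.peaks.iterrows():
            for _, r in ig_intervals.iterrows():
                if (
                    row["chrom"] == r["chrom"]
                    and int(row["start"]) < int(r["end"])
                    and int(row["end"]) > int(r["start"])
                ):
                    ps.peaks.loc[pid, "immunoglobulin"] = True
                    break
    flagged_counts = ps.counts.loc[ps.flagged].sum(axis=0)
    adjusted = raw_library - flagged_counts.reindex(raw_library.index, fill_value=0)
    if (adjusted <= 0).any():
        raise ValueError("adjusted library size non-positive for some sample")
    lib = LibraryInfo(pd.DataFrame({"raw": raw_library, "adjusted": adjusted}))
    return ps, lib


def filter_gene_context(
    peakset: PeakSet,
    annotation: GenomeAnnotation,
    convergent_nt: int = 100,
    upstream_nt: int = 5000,
) -> PeakSet:
    """Flag peaks with ambiguous gene context.

    Removes (by flagging) peaks in overlap-flagged genes, intronic peaks over
    small-RNA loci, intronic peaks within ``convergent_nt`` of a convergent
    (opposite-strand) gene's 3'UTR end, and intronic peaks within
    ``upstream_nt`` downstream of the 3'UTR end of the upstream same-strand
    gene."""
    ps = peakset.copy()
    ps.ensure_flags()
    if "gene_id" not in ps.peaks.columns:
        raise ValueError("run assign_genes before filter_gene_context")
    utr_ends: list[tuple[str, str, int, str]] = []  # chrom, strand, end, gene
    for g in annotation.genes.values():
        if g.utr3_end is not None:
            utr_ends.append((g.chrom, g.strand, g.utr3_end, g.gene_id))
    for pid, row in ps.peaks.iterrows():
        gid = row["gene_id"]
        if gid is not None and gid in annotation.overlap_flags:
            ps.peaks.loc[pid, "ambiguous_gene"] = True
        if row["region"] != "INTRON":
            continue
        pos3 = ps.end3(pid)
        for chrom, s, e in annotation.smallrna_intervals:
            if chrom == row["chrom"] and s <= pos3 < e:
                ps.peaks.loc[pid, "smallrna"] = True
                break
        for chrom, strand, uend, ugene in utr_ends:
            if chrom != row["chrom"] or ugene == gid:
                continue
            if strand != row["strand"]:
                if abs(pos3 - uend) <= convergent_nt:
                    ps.peaks.loc[pid, "convergent_3utr_proximal"] = True
            else:
                dist = pos3 - uend if strand == "+" else uend - pos3
                if 0 < dist <= upstream_nt:
                    ps.peaks.loc[pid, "upstream_gene_proximal"] = True
    return ps


# ---------------------------------------------------------------------------
# quantification / clustering / usage
# ---------------------------------------------------------------------------


def quantify_tpm(counts: pd.DataFrame, libinfo: LibraryInfo) -> pd.DataFrame:
    """Tags-per-million: count / (adjusted library size / 1e6)."""
    adjusted = libinfo.adjusted.reindex(counts.columns)
    if (adjusted <= 0).any() or adjusted.isna().any():
        raise ValueError("adjusted library size must be positive for all samples")
    return counts / (adjusted / 1e6)


def cluster_peaks(
    peakset: PeakSet,
    libinfo: LibraryInfo,
    max_gap: int = 200,
) -> Atlas:
    """Single-linkage clustering of surviving peaks into cleavage events.

    Peaks of the same gene and region class whose 3' ends are within
    ``max_gap`` nt chain into one event. Cluster counts are summed over
    members; the representative 3'-end position is the member with the
    highest pooled count (ties to the most distal 3' end)."""
    ps = peakset
    ps.ensure_flags()
    keep = (~ps.flagged) & ps.peaks["region"].isin(["INTRON", "UTR3"])
    peaks = ps.peaks.loc[keep]
    samples = list(ps.counts.columns)
    pooled = ps.counts.sum(axis=1)
    rows, count_rows, iqr_rows, starts = [], [], [], {}

    for (gid, region), sub in peaks.groupby(["gene_id", "region"], sort=True):
        klass = "IPA" if region == "INTRON" else "UTR3"
        strand = sub["strand"].iloc[0]
        end3 = PeakSet(sub, ps.counts.loc[sub.index]).end3_series().sort_values()
        members: list[list[str]] = [[end3.index[0]]]
        prev = end3.iloc[0]
        for pid, pos in list(end3.items())[1:]:
            if pos - prev <= max_gap:
                members[-1].append(pid)
            else:
                members.append([pid])
            prev = pos
        for group in members:
            gsub = sub.loc[group]
            g3 = end3.loc[group]
            pool = pooled.loc[group]
            distal = g3 if strand == "+" else -g3
            rep = pool.to_frame("c").assign(d=distal).sort_values(
                ["c", "d"], ascending=[False, False]
            ).index[0]
            rep_pos = int(g3.loc[rep])
            eid = f"{gid}:{klass}:{rep_pos}"
            rows.append(
                {
                    "event_id": eid,
                    "gene_id": gid,
                    "chrom": gsub["chrom"].iloc[0],
                    "start": int(gsub["start"].min()),
                    "end": int(gsub["end"].max()),
                    "strand": strand,
                    "klass": klass,
                    "rep_pos": rep_pos,
                    "intron_index": int(gsub.loc[rep, "intron_index"]),
                }
            )
            count_rows.append(ps.counts.loc[group].sum(axis=0))
            iqrs = {}
            for sample in samples:
                merged = np.concatenate(
                    [ps.starts.get((pid, sample), np.array([], dtype=np.int64)) for pid in group]
                )
                if merged.size:
                    starts[(eid, sample)] = np.sort(merged)
                    q75, q25 = np.percentile(merged, [75, 25])
                    iqrs[sample] = float(q75 - q25)
                else:
                    iqrs[sample] = np.nan
            iqr_rows.append(iqrs)

    events = pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "gene_id",
            "chrom",
            "start",
            "end",
            "strand",
            "klass",
            "rep_pos",
            "intron_index",
        ],
    ).set_index("event_id")
    counts = pd.DataFrame(count_rows, index=events.index, columns=samples)
    iqr = pd.DataFrame(iqr_rows, index=events.index, columns=samples)
    tpm = quantify_tpm(counts, libinfo)
    return Atlas(events=events, counts=counts, tpm=tpm, iqr=iqr, starts=starts)


def compute_usage(atlas: Atlas) -> pd.DataFrame:
    """Relative usage per event and sample.

    IpA events: TPM over the summed TPM of all IpA + 3'UTR events of the
    gene. 3'UTR events: TPM over the summed TPM of 3'UTR events only. A zero
    denominator yields a missing value, not 0."""
    usage = pd.DataFrame(np.nan, index=atlas.events.index, columns=atlas.tpm.columns)
    for gid, sub in atlas.events.groupby("gene_id"):
        all_tpm = atlas.tpm.loc[sub.index]
        denom_all = all_tpm.sum(axis=0)
        utr_ids = sub.index[sub["klass"] == "UTR3"]
        denom_utr = atlas.tpm.loc[utr_ids].sum(axis=0)
        for eid in sub.index:
            denom = denom_all if sub.loc[eid, "klass"] == "IPA" else denom_utr
            with np.errstate(invalid="ignore", divide="ignore"):
                vals = atlas.tpm.loc[eid] / denom
            usage.loc[eid] = vals.where(denom > 0)
    atlas.usage = usage
    return usage


def apply_robustness_filters(
    atlas: Atlas,
    usage: pd.DataFrame | None = None,
    utr_tpm_min: float = 3.0,
    utr_usage_min: float = 0.1,
    ipa_tpm_min: float = 5.0,
    ipa_usage_min: float = 0.1,
    iqr_min: float = 5.0,
) -> Atlas:
    """Keep 3'UTR events with >=3 TPM and >=0.1 usage in some sample, and IpA
    events with >=5 TPM, >=0.1 usage and read-start IQR >=5 in the same
    sample for at least one sample."""
    usage = atlas.usage if usage is None else usage
    if usage is None:
        raise ValueError("compute_usage must run before the robustness filters")
    is_ipa = atlas.events["klass"] == "IPA"
    u = usage.fillna(-1.0)
    iqr = atlas.iqr.fillna(-1.0)
    ipa_ok = ((atlas.tpm >= ipa_tpm_min) & (u >= ipa_usage_min) & (iqr >= iqr_min)).any(axis=1)
    utr_ok = ((atlas.tpm >= utr_tpm_min) & (u >= utr_usage_min)).any(axis=1)
    keep = atlas.events.index[(is_ipa & ipa_ok) | (~is_ipa & utr_ok)]
    out = atlas.subset(keep)
    out.usage = usage.loc[keep]
    return out


# ---------------------------------------------------------------------------
# expression calls
# ---------------------------------------------------------------------------


def expression_calls(
    atlas: Atlas,
    celltype_of: Mapping[str, str],
    ipa_tpm: float = 5.0,
    fl_tpm: float = 5.5,
    sample_fraction: float = 0.75,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene, per-cell-type expression calls and IpA prevalence.

    A gene is IPA_EXPRESSED in a cell type when some IpA event reaches
    ``ipa_tpm`` in at least ceil(75%) of that type's samples; FL_ONLY when
    only the pooled 3'UTR signal reaches ``fl_tpm`` by the same rule.
    Prevalence = IPA_EXPRESSED genes / expressed genes."""
    celltypes: dict[str, list[str]] = {}
    for sample, ct in celltype_of.items():
        celltypes.setdefault(ct, []).append(sample)
    rows = []
    for gid, sub in atlas.events.groupby("gene_id"):
        ipa_ids = sub.index[sub["klass"] == "IPA"]
        utr_ids = sub.index[sub["klass"] == "UTR3"]
        fl_tpm_series = atlas.tpm.loc[utr_ids].sum(axis=0)
        for ct, ct_samples in sorted(celltypes.items()):
            need = ceil(sample_fraction * len(ct_samples))
            ipa_hit = any(
                int((atlas.tpm.loc[eid, ct_samples] >= ipa_tpm).sum()) >= need
                for eid in ipa_ids
            )
            fl_hit = int((fl_tpm_series[ct_samples] >= fl_tpm).sum()) >= need
            if ipa_hit:
                call = "IPA_EXPRESSED"
            elif fl_hit:
                call = "FL_ONLY"
            else:
                call = "NOT_EXPRESSED"
            rows.append({"gene_id": gid, "cell_type": ct, "call": call})
    calls = pd.DataFrame(rows)
    prev = {}
    for ct, sub in calls.groupby("cell_type"):
        expressed = sub["call"].isin(["IPA_EXPRESSED", "FL_ONLY"]).sum()
        prev[ct] = (sub["call"] == "IPA_EXPRESSED").sum() / expressed if expressed else np.nan
    return calls, pd.Series(prev, name="ipa_prevalence")


def distal_utr_usage(atlas: Atlas) -> pd.DataFrame:
    """Usage of the 3'-most 3'UTR event of each gene relative to all of the
    gene's 3'UTR events; genes without a 3'UTR event are omitted."""
    rows = {}
    for gid, sub in atlas.events.groupby("gene_id"):
        utr = sub[sub["klass"] == "UTR3"]
        if utr.empty:
            continue
        if utr["strand"].iloc[0] == "+":
            distal = utr["rep_pos"].idxmax()
        else:
            distal = utr["rep_pos"].idxmin()
        denom = atlas.tpm.loc[utr.index].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = atlas.tpm.loc[distal] / denom
        rows[gid] = vals.where(denom > 0)
    return pd.DataFrame(rows).T


def build_atlas(
    peakset: PeakSet,
    annotation: GenomeAnnotation,
    genome: Mapping[str, str],
    raw_library: pd.Series,
    blacklist: pd.DataFrame | None = None,
    ig_intervals: pd.DataFrame | None = None,
) -> tuple[Atlas, LibraryInfo]:
    """Full cascade: flags -> library adjustment -> clustering -> usage ->
    robustness filters. Returns the filtered atlas and library info."""
    ps = assign_genes(peakset, annotation)
    ps = filter_artifact_peaks(ps, blacklist, genome, annotation)
    ps, lib = mask_ig_adjust_library(ps, ig_intervals, raw_library)
    ps = filter_gene_context(ps, annotation)
    atlas = cluster_peaks(ps, lib)
    compute_usage(atlas)
    atlas = apply_robustness_filters(atlas)
    return atlas, lib
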