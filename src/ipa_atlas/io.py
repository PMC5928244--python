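"""Readers and writers for the plain-text formats the pipeline exchanges.

Genomes are handled as ``dict[chrom -> str]``; per-base tracks (coverage,
conservation, mappability) as ``dict[chrom -> numpy array]``. All BED-style
output is 0-based half-open; GTF output is 1-based inclusive.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd
from pyfaidx import Fasta

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


# -- FASTA ------------------------------------------------------------------


def write_fasta(genome: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    fa = Fasta(str(path), rebuild=True, build_index=True)
    genome = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    for ext in (".fai",):
        try:
            os.remove(str(path) + ext)
        except OSError:
            pass
    return genome


# -- GTF --------------------------------------------------------------------


def write_gtf(annotation, path) -> None:
    """Serialize a :class:`~ipa_atlas.annotation.GenomeAnnotation` to GTF."""
    with open(path, "w") as fh:
        for gid in sorted(annotation.genes):
            g = annotation.genes[gid]
            attrs = f'gene_id "{gid}"; gene_biotype "{g.biotype}";'
            fh.write(
                f"{g.chrom}\tipa_atlas\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for tid in sorted(g.transcripts):
                exons = g.transcripts[tid]
                tattrs = f'gene_id "{gid}"; transcript_id "{tid}";'
                fh.write(
                    f"{g.chrom}\tipa_atlas\ttranscript\t{exons[0][0] + 1}\t{exons[-1][1]}"
                    f"\t.\t{g.strand}\t.\t{tattrs}\n"
                )
                for s, e in exons:
                    fh.write(
                        f"{g.chrom}\tipa_atlas\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{tattrs}\n"
                    )
                if tid == g.cds_transcript:
                    for s, e in g.cds:
                        fh.write(
                            f"{g.chrom}\tipa_atlas\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t{tattrs}\n"
                        )
        for chrom, s, e in annotation.smallrna_intervals:
            attrs = f'gene_id "smallrna_{chrom}_{s}"; gene_biotype "snoRNA"; transcript_id "smallrna_{chrom}_{s}.t1";'
            fh.write(f"{chrom}\tipa_atlas\texon\t{s + 1}\t{e}\t.\t+\t.\t{attrs}\n")


# -- BED --------------------------------------------------------------------


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in BED6_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", columns=cols, header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED6_COLUMNS[: df.shape[1]]
    return df


# -- bedGraph ---------------------------------------------------------------


def write_bedgraph(track: Mapping[str, np.ndarray], path) -> None:
    """Run-length encode per-base arrays into bedGraph."""
    with open(path, "w") as fh:
        for chrom in track:
            arr = np.asarray(track[chrom])
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    v = float(v)
                    vs = str(int(v)) if v.is_integer() else f"{v:g}"
                    fh.write(f"{chrom}\t{s}\t{e}\t{vs}\n")


def read_bedgraph(path, chrom_sizes: Mapping[str, int], dtype=np.float64) -> dict[str, np.ndarray]:
    track = {c: np.zeros(n, dtype=dtype) for c, n in chrom_sizes.items()}
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"]
    )
    for chrom, sub in df.groupby("chrom"):
        if chrom not in track:
            continue
        arr = track[chrom]
        for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
            arr[s:e] = v
    return track


# -- peak tables ------------------------------------------------------------


def write_peak_tables(peakset, outdir, prefix: str = "peaks") -> None:
    """Write a PeakSet as BED6 + counts TSV + read-start TSV."""
    os.makedirs(outdir, exist_ok=True)
    bed = peakset.peaks.reset_index()[["chrom", "start", "end", "peak_id", "strand"]]
    bed.insert(4, "score", 0)
    bed.columns = BED6_COLUMNS
    write_bed(bed, os.path.join(outdir, f"{prefix}.bed"))
    peakset.counts.to_csv(os.path.join(outdir, f"{prefix}_counts.tsv"), sep="\t")
    with open(os.path.join(outdir, f"{prefix}_read_starts.tsv"), "w") as fh:
        fh.write("peak_id\tsample\tstarts\n")
        for (pid, sample), starts in sorted(peakset.starts.items()):
            joined = ",".join(str(int(x)) for x in starts)
            fh.write(f"{pid}\t{sample}\t{joined}\n")


def read_peak_tables(outdir, prefix: str = "peaks"):
    from .atlas import PeakSet

    bed = read_bed(os.path.join(outdir, f"{prefix}.bed"))
    peaks = bed.rename(columns={"name": "peak_id"}).set_index("peak_id")
    peaks = peaks[["chrom", "start", "end", "strand"]]
    counts = pd.read_csv(
        os.path.join(outdir, f"{prefix}_counts.tsv"), sep="\t", index_col=0
    )
    starts = {}
    sdf = pd.read_csv(os.path.join(outdir, f"{prefix}_read_starts.tsv"), sep="\t")
    for pid, sample, raw in zip(sdf["peak_id"], sdf["sample"], sdf["starts"]):
        starts[(pid, str(sample))] = np.array(
            [int(x) for x in str(raw).split(",")], dtype=np.int64
        )
    return PeakSet(peaks=peaks, counts=counts, starts=starts)


# -- junction / clinical TSV -------------------------------------------------


def write_junctions(junctions: pd.DataFrame, path) -> None:
    junctions.to_csv(path, sep="\t", index=False)


def read_junctions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_clinical(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_clinical(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
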