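"""Readers and writers for the small text formats the pipeline exchanges.

GTF is parsed through pyranges (which converts 1-based closed coordinates to
the 0-based half-open convention used internally). bedGraph tracks are stored
as strand pairs with ``.plus`` / ``.minus`` suffixes before the extension.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pyranges as pr

from .intervals import Gene, GenomeAnnotation, GenomicInterval
from .tracks import CoverageTrack, _n_bins

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def write_chrom_sizes(chrom_sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, size in chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_gtf(path, chrom_sizes: dict[str, int] | None = None) -> GenomeAnnotation:
    """Read gene/exon features from a GTF into a :class:`GenomeAnnotation`."""
    df = pr.read_gtf(str(path)).df
    genes: list[Gene] = []
    gene_rows = df[df["Feature"] == "gene"]
    exon_rows = df[df["Feature"] == "exon"]
    for row in gene_rows.itertuples(index=False):
        iv = GenomicInterval(str(row.Chromosome), int(row.Start), int(row.End), str(row.Strand))
        mask = exon_rows["gene_id"] == row.gene_id
        exons = [
            GenomicInterval(str(e.Chromosome), int(e.Start), int(e.End), str(e.Strand))
            for e in exon_rows[mask].itertuples(index=False)
        ]
        biotype = getattr(row, "gene_biotype", None) or "protein_coding"
        genes.append(Gene(str(row.gene_id), iv, exons, str(biotype)))
    return GenomeAnnotation(genes, chrom_sizes or {})


def write_gtf(annotation: GenomeAnnotation, path) -> None:
    """Write genes and exons as GTF (converting back to 1-based closed)."""
    with open(path, "w") as fh:
        for gene in annotation:
            attrs = f'gene_id "{gene.gene_id}"; gene_biotype "{gene.biotype}";'
            iv = gene.interval
            fh.write(
                f"{iv.chrom}\tttkinetics\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
            )
            for ex in gene.exons:
                fh.write(
                    f"{ex.chrom}\tttkinetics\texon\t{ex.start + 1}\t{ex.end}\t.\t{ex.strand}\t.\t{attrs}\n"
                )


def read_bed6(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS)
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_bed6(df: pd.DataFrame, path) -> None:
    df[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def _strand_paths(path) -> dict[str, Path]:
    """Map '+'/'-' to the .plus/.minus sibling files of ``path``."""
    p = Path(path)
    stem, suffix = p.stem, p.suffix
    for tag in (".plus", ".minus"):
        if stem.endswith(tag):
            stem = stem[: -len(tag)]
    return {
        "+": p.with_name(f"{stem}.plus{suffix}"),
        "-": p.with_name(f"{stem}.minus{suffix}"),
        ".": p,
    }


def write_bedgraph(track: CoverageTrack, path) -> list[Path]:
    """Write a track as bedGraph, one file per strand (``.plus``/``.minus``).

    Zero runs are compressed into single intervals; unstranded tracks go to
    ``path`` itself. Returns the written paths.
    """
    paths = _strand_paths(path)
    written = []
    for strand in track.strands:
        out = paths[strand]
        with open(out, "w") as fh:
            for chrom, arr in track.values[strand].items():
                size = track.chrom_sizes[chrom]
                # run-length encode equal consecutive bin values
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [len(arr)]))
                for b0, b1 in zip(starts, ends):
                    val = arr[b0]
                    if val == 0:
                        continue
                    lo = b0 * track.bin_size
                    hi = min(b1 * track.bin_size, size)
                    fh.write(f"{chrom}\t{lo}\t{hi}\t{val:.10g}\n")
        written.append(out)
    return written


def read_bedgraph(
    path,
    chrom_sizes: dict[str, int],
    bin_size: int,
    library: str = "other",
    stranded: bool = True,
) -> CoverageTrack:
    """Read a bedGraph strand pair (or a single unstranded file) into a track.

    Interval values are distributed to bins by overlap fraction, so a file
    written by :func:`write_bedgraph` at the same ``bin_size`` round-trips
    exactly.
    """
    paths = _strand_paths(path)
    strands = ("+", "-") if stranded else (".",)
    track = CoverageTrack.zeros(chrom_sizes, bin_size, strands=strands, library=library)
    for strand in strands:
        p = paths[strand]
        if not Path(p).exists():
            raise FileNotFoundError(str(p))
        df = pd.read_csv(p, sep="\t", header=None, names=["chrom", "start", "end", "value"])
        for row in df.itertuples(index=False):
            chrom = str(row.chrom)
            arr = track.values[strand][chrom]
            csize = chrom_sizes[chrom]
            first, last = int(row.start) // bin_size, (int(row.end) - 1) // bin_size
            for b in range(first, last + 1):
                lo = b * bin_size
                hi = min((b + 1) * bin_size, csize)  # last bin may be short
                frac = (min(int(row.end), hi) - max(int(row.start), lo)) / (hi - lo)
                arr[b] += row.value * frac
    return track
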