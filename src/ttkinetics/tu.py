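"""Transcription-unit calling, aggregation and positional classification.

Workflow: binned labeled-RNA coverage (replicates summed) -> two-state
Poisson HMM segmentation -> maximal active runs become raw TU fragments ->
fragments overlapping a gene's exons are joined into one mRNA TU per gene ->
remaining fragments are classified by the position of their 5' end relative
to nearby genes:

- uaRNA: antisense, 5' end within 1 kb upstream of a gene TSS
- conRNA: antisense, 5' end within 1 kb downstream of a gene TSS
- asRNA: antisense, 5' end inside the gene body
- daRNA: antisense, 5' end within 1 kb downstream of the TES
- dsRNA: sense, 5' end within 1 kb downstream of the TES
- intergenic: everything else

Distances are measured in the host gene's orientation. A TU qualifying for
several genes is assigned to the gene with the nearest TSS (ties broken by
gene_id, so classification is deterministic and total).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .hmm import PoissonHMM
from .intervals import Gene, GenomeAnnotation, GenomicInterval
from .tracks import CoverageTrack, interval_density

TU_CLASSES = ("mRNA", "uaRNA", "conRNA", "asRNA", "dsRNA", "daRNA", "intergenic")
TUSET_COLUMNS = ["tu_id", "chrom", "start", "end", "strand", "tu_class", "host_gene_id"]


def fit_hmm(
    track: CoverageTrack,
    model: PoissonHMM | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[PoissonHMM, dict]:
    """Fit one binary HMM jointly on all chrom/strand sequences of a track.

    Counts should be raw (integer) binned reads, replicates summed. Returns
    the fitted model and per-(strand, chrom) active-state posteriors.
    """
    model = model or PoissonHMM()
    keys = [
        (s, c) for s in track.strands for c in sorted(track.values[s])
    ]
    sequences = [np.round(track.values[s][c]) for s, c in keys]
    model.fit(sequences, max_iter=max_iter, tol=tol)
    posteriors = {key: model.posterior(seq) for key, seq in zip(keys, sequences)}
    return model, posteriors


def call_tus(
    posteriors: dict,
    bin_size: int,
    min_bins: int = 1,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Maximal runs of active bins (posterior >= threshold) as raw TU fragments.

    ``posteriors`` maps (strand, chrom) to per-bin active probabilities. Runs
    shorter than ``min_bins`` are dropped; no gap bridging is performed.
    """
    rows = []
    for (strand, chrom), post in sorted(posteriors.items()):
        active = np.asarray(post) >= threshold
        # run starts/ends of True stretches
        padded = np.concatenate(([False], active, [False]))
        starts = np.flatnonzero(~padded[:-1] & padded[1:])
        ends = np.flatnonzero(padded[:-1] & ~padded[1:])
        for b0, b1 in zip(starts, ends):
            if b1 - b0 >= min_bins:
                rows.append((chrom, b0 * bin_size, b1 * bin_size, strand))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])


def _fragment_iv(row) -> GenomicInterval:
    return GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand)


def join_by_exons(raw_tus: pd.DataFrame, annotation: GenomeAnnotation) -> pd.DataFrame:
    """Merge same-strand fragments overlapping a gene's exons into one mRNA TU.

    The merged TU spans from the first to the last such fragment. Fragments
    overlapping exons of two same-strand genes go to the gene with the larger
    overlap (tie: nearest TSS). Non-exonic fragments pass through unlabeled
    (host_gene_id None) for positional classification.
    """
    assigned: dict[str, list] = {}
    passthrough = []
    for row in raw_tus.itertuples(index=False):
        frag = _fragment_iv(row)
        best = None  # (overlap, -|tss dist|, gene)
        for gene in annotation:
            if gene.strand != frag.strand or gene.chrom != frag.chrom:
                continue
            ov = sum(frag.overlap_bp(ex) for ex in gene.exons)
            if ov > 0:
                mid = (frag.start + frag.end) // 2
                key = (ov, -abs(gene.tss - mid), gene.gene_id)
                if best is None or key > best[0]:
                    best = (key, gene)
        if best is None:
            passthrough.append(row)
        else:
            assigned.setdefault(best[1].gene_id, []).append(frag)
    rows = []
    for gene_id, frags in assigned.items():
        gene = annotation[gene_id]
        rows.append(
            (
                f"TU_{gene_id}",
                gene.chrom,
                min(f.start for f in frags),
                max(f.end for f in frags),
                gene.strand,
                "mRNA",
                gene_id,
            )
        )
    for i, row in enumerate(passthrough):
        rows.append((f"TU_nc{i:04d}", row.chrom, int(row.start), int(row.end), row.strand, None, None))
    return pd.DataFrame(rows, columns=TUSET_COLUMNS)


def _classify_one(tu: GenomicInterval, genes: list[Gene], window: int = 1000):
    """Class and host gene for one non-mRNA TU (see module docstring)."""
    candidates = []
    p = tu.five_prime
    for gene in genes:
        if gene.chrom != tu.chrom:
            continue
        sign = 1 if gene.strand != "-" else -1
        d_tss = sign * (p - gene.tss)
        d_tes = sign * (p - gene.tes)
        antisense = tu.strand != gene.strand and tu.strand != "." and gene.strand != "."
        label = None
        if antisense:
            if -window < d_tss < 0:
                label = "uaRNA"
            elif 0 < d_tss < window:
                label = "conRNA"
            elif gene.interval.start <= p < gene.interval.end:
                label = "asRNA"
            elif 0 < d_tes < window:
                label = "daRNA"
        else:
            if 0 < d_tes <= window:
                label = "dsRNA"
        if label is not None:
            candidates.append((abs(d_tss), gene.gene_id, label))
    if not candidates:
        return "intergenic", None
    _, gene_id, label = min(candidates)
    return label, gene_id


def classify_tus(
    tus: pd.DataFrame, annotation: GenomeAnnotation, window: int = 1000
) -> pd.DataFrame:
    """Assign a positional class to every TU lacking one; total and deterministic."""
    out = tus.copy()
    genes = list(annotation)
    for idx in out.index:
        if pd.notna(out.at[idx, "tu_class"]) and out.at[idx, "tu_class"] is not None:
            continue
        tu = GenomicInterval(
            out.at[idx, "chrom"],
            int(out.at[idx, "start"]),
            int(out.at[idx, "end"]),
            out.at[idx, "strand"],
        )
        label, host = _classify_one(tu, genes, window)
        out.at[idx, "tu_class"] = label
        out.at[idx, "host_gene_id"] = host
    return out


def annotate_tus(
    track: CoverageTrack,
    annotation: GenomeAnnotation,
    min_bins: int = 1,
    threshold: float = 0.5,
    model: PoissonHMM | None = None,
) -> tuple[pd.DataFrame, PoissonHMM]:
    """Full TU annotation: fit HMM, call fragments, join by exons, classify."""
    model, posteriors = fit_hmm(track, model=model)
    raw = call_tus(posteriors, track.bin_size, min_bins=min_bins, threshold=threshold)
    tus = join_by_exons(raw, annotation)
    return classify_tus(tus, annotation), model


def quantify_tus(tus: pd.DataFrame, tracks: dict[str, CoverageTrack]) -> pd.DataFrame:
    """Add per-sample RPK columns (``rpk_<name>``) to a TU table."""
    out = tus.copy()
    for name, track in tracks.items():
        out[f"rpk_{name}"] = [
            interval_density(track, _fragment_iv(row))
            for row in out.itertuples(index=False)
        ]
    return out


def _merged_bp(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def jaccard(tus_a: pd.DataFrame, tus_b: pd.DataFrame, tu_class: str | None = None):
    """Base-pair Jaccard index between two TU sets, optionally one class only.

    Computed per (chrom, strand) and pooled. Two empty sets are defined as
    identical (index 1) and flagged via the second return value.
    """
    def select(df):
        if tu_class is not None:
            df = df[df["tu_class"] == tu_class]
        return df

    a, b = select(tus_a), select(tus_b)
    if a.empty and b.empty:
        return 1.0, True
    inter = union = 0
    keys = set(map(tuple, a[["chrom", "strand"]].values)) | set(
        map(tuple, b[["chrom", "strand"]].values)
    )
    for chrom, strand in keys:
        ia = _merged_bp(
            [(int(r.start), int(r.end)) for r in a[(a.chrom == chrom) & (a.strand == strand)].itertuples()]
        )
        ib = _merged_bp(
            [(int(r.start), int(r.end)) for r in b[(b.chrom == chrom) & (b.strand == strand)].itertuples()]
        )
        union_ivs = _merged_bp(ia + ib)
        union += sum(e - s for s, e in union_ivs)
        for (s1, e1), (s2, e2) in itertools.product(ia, ib):
            inter += max(0, min(e1, e2) - max(s1, s2))
    return (inter / union if union else 1.0), union == 0
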