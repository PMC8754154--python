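"""Termination-site calling by maximum-contrast change-point detection.

Transcription runs past the annotated transcript end site (TES) until the
polymerase terminates; labeled-RNA signal decays over that read-through
region. For each gene a potential termination window extends up to 15 kb
past the last exon end (clipped at the next downstream gene TSS). Within
the window, log-transformed labeled-RNA coverage is mean-centered and the
maximum of its cumulative sum marks the position of the strongest
before/after density contrast: the called termination site.

Change classes across two conditions use a +/-500 bp rule on the
termination distance (site - TES): shortening below -500 bp, extending
above +500 bp, otherwise unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import Gene, GenomeAnnotation, GenomicInterval
from .tracks import CoverageTrack, interval_signal

DEFAULT_WINDOW_LEN = 15_000  # bp scanned past the last exon end
DEFAULT_SCAN_BIN = 50  # bp resolution of the CUSUM scan
CHANGE_THRESHOLD = 500  # bp; +/- band for the unchanged class


def termination_window(
    gene: Gene,
    annotation: GenomeAnnotation,
    max_len: int = DEFAULT_WINDOW_LEN,
    min_len: int = 1000,
    same_strand_only: bool = False,
) -> GenomicInterval | None:
    """Potential termination window: last exon end to +``max_len``, clipped.

    The window stops at the next downstream gene TSS (either strand by
    default, to avoid bleed-through from convergent genes) and at the
    chromosome end. Windows shorter than ``min_len`` exclude the gene
    (returns None).
    """
    start3 = gene.last_exon_end
    length = max_len
    nxt = annotation.next_downstream_tss(gene, same_strand_only=same_strand_only)
    if nxt is not None:
        d = (nxt[0].tss - start3) if gene.strand != "-" else (start3 - nxt[0].tss)
        length = min(length, d)
    if gene.strand == "-":
        lo, hi = max(0, start3 - length), start3
    else:
        size = annotation.chrom_sizes.get(gene.chrom)
        hi = start3 + length if size is None else min(start3 + length, size)
        lo = start3
    if hi - lo < min_len:
        return None
    return GenomicInterval(gene.chrom, lo, hi, gene.strand)


def window_values(
    track: CoverageTrack,
    window: GenomicInterval,
    scan_bin: int = DEFAULT_SCAN_BIN,
) -> np.ndarray:
    """Coverage re-binned onto ``scan_bin`` positions, oriented 5'->3'.

    The window is truncated to whole scan bins; partial track-bin overlap is
    pro-rated linearly.
    """
    n = len(window) // scan_bin
    if n < 2:
        raise ValueError("window shorter than two scan bins")
    vals = np.empty(n)
    for j in range(n):
        lo = window.start + j * scan_bin
        vals[j] = interval_signal(
            track, GenomicInterval(window.chrom, lo, lo + scan_bin, window.strand)
        )
    return vals[::-1] if window.strand == "-" else vals


def call_termination_site(
    values: np.ndarray,
    scan_bin: int = DEFAULT_SCAN_BIN,
    pseudocount: float = 1.0,
    log: bool = True,
) -> tuple[float, np.ndarray, bool]:
    """CUSUM change point on one oriented window coverage vector.

    x = log(values + pseudocount) (or raw with ``log=False``) is centered to
    mean zero; the cumulative sum S_k is maximal at the split with the
    largest before/after mean contrast. Returns (distance in bp from the
    window start to the site, the CUSUM curve, no-signal flag). Ties take
    the earliest index; an all-constant window returns the first boundary,
    flagged.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least two scan bins")
    x = np.log(values + pseudocount) if log else values.copy()
    no_signal = bool(np.allclose(values, values[0]))
    x -= x.mean()
    cusum = np.cumsum(x)
    if no_signal:
        return 0.0, cusum, True
    k = int(np.argmax(cusum))  # argmax takes the earliest maximal index
    return float((k + 1) * scan_bin), cusum, no_signal


def call_gene_termination(
    track: CoverageTrack,
    annotation: GenomeAnnotation,
    scan_bin: int = DEFAULT_SCAN_BIN,
    pseudocount: float = 1.0,
    log: bool = True,
    max_len: int = DEFAULT_WINDOW_LEN,
) -> pd.DataFrame:
    """Call one termination site per gene; distance is site - TES (bp, >= 0)."""
    rows, excluded = [], 0
    for gene in annotation:
        window = termination_window(gene, annotation, max_len=max_len)
        if window is None:
            excluded += 1
            continue
        vals = window_values(track, window, scan_bin)
        dist, _, flag = call_termination_site(vals, scan_bin, pseudocount, log)
        site = (
            gene.last_exon_end + int(dist)
            if gene.strand != "-"
            else gene.last_exon_end - int(dist)
        )
        rows.append(
            (gene.gene_id, window.start, window.end, site, dist, flag)
        )
    out = pd.DataFrame(
        rows,
        columns=["gene_id", "window_start", "window_end", "site", "distance", "no_signal"],
    )
    out.attrs["n_excluded"] = excluded
    return out


def classify_changes(
    calls_ref: pd.DataFrame,
    calls_alt: pd.DataFrame,
    threshold: float = CHANGE_THRESHOLD,
) -> pd.DataFrame:
    """Shortening / extending / unchanged per gene, by the +/-500 bp rule.

    delta = distance_alt - distance_ref; below -threshold is shortening,
    above +threshold extending, otherwise unchanged. Genes missing in either
    condition are excluded (counted in ``df.attrs['n_excluded']``).
    """
    merged = calls_ref[["gene_id", "distance"]].merge(
        calls_alt[["gene_id", "distance"]], on="gene_id", suffixes=("_ref", "_alt")
    )
    delta = merged["distance_alt"] - merged["distance_ref"]
    cls = np.where(
        delta < -threshold, "shortening", np.where(delta > threshold, "extending", "unchanged")
    )
    out = pd.DataFrame(
        {
            "gene_id": merged["gene_id"],
            "distance_ref": merged["distance_ref"],
            "distance_alt": merged["distance_alt"],
            "delta": delta,
            "change_class": cls,
        }
    )
    out.attrs["n_excluded"] = (
        len(set(calls_ref.gene_id) ^ set(calls_alt.gene_id))
    )
    return out


def gc_contrast(sequence: str, site: int, flank: int = 100) -> float:
    """GC minus AT mean frequency in the +/-``flank`` bp around ``site``.

    +1 for an all-G/C flank, 0 at 50% GC; NaN when no sequence is available.
    """
    lo, hi = max(0, site - flank), min(len(sequence), site + flank)
    if hi <= lo:
        return float("nan")
    region = sequence[lo:hi].upper()
    gc = sum(region.count(b) for b in "GC")
    at = sum(region.count(b) for b in "AT")
    n = gc + at
    if n == 0:
        return float("nan")
    return (gc - at) / n


def r2_decomposition(
    response: np.ndarray,
    features: pd.DataFrame,
    condition_limit: float = 1e8,
    ridge: float = 1e-6,
) -> tuple[pd.Series, float]:
    """Per-feature R-squared shares from regression through the origin.

    Inputs are expected standardized (zero mean, unit variance; see
    :func:`standardize_features`). With OLS through the origin the explained
    sum of squares is beta' X'y, so share_j = beta_j * <x_j, y> / <y, y>
    sums exactly to the total R-squared. Negative shares (suppressor
    features) are reported as-is. Near-collinear designs fall back to a tiny
    ridge penalty.
    """
    y = np.asarray(response, dtype=float)
    X = features.to_numpy(dtype=float)
    if np.linalg.cond(X) > condition_limit:
        beta = np.linalg.solve(X.T @ X + ridge * np.eye(X.shape[1]), X.T @ y)
    else:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    yy = float(y @ y)
    shares = pd.Series(beta * (X.T @ y) / yy, index=features.columns)
    yhat = X @ beta
    return shares, float(yhat @ yhat / yy)


def standardize_features(
    features: pd.DataFrame, quantile: float = 0.995, log1p: bool = True
) -> pd.DataFrame:
    """log1p, trim at the 99.5% quantile, standardize to N(0, 1) per column."""
    out = features.astype(float)
    if log1p:
        out = np.log1p(out)
    for col in out.columns:
        cap = out[col].quantile(quantile)
        out[col] = out[col].clip(upper=cap)
        sd = out[col].std(ddof=0)
        out[col] = (out[col] - out[col].mean()) / (sd if sd > 0 else 1.0)
    return out
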