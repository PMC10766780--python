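"""Post-peak-calling ChIP-seq computations.

Given called peaks (BED/narrowPeak), a transcript annotation (GTF) and the
genome sequence, this module computes:

* the peak-density profile around transcription start sites (raw and
  smoothed histogram of signed summit-to-TSS offsets);
* the genomic-region distribution of peaks (promoter / gene body / distal);
* the fraction of peaks carrying a motif site at an exact-null p threshold;
* the candidate-gene filter: a gene is a candidate when at least one
  motif-bearing peak lies within a signed TSS window (default -20 kb
  upstream to +0.5 kb downstream, transcription-orientation-aware);
* a per-peak read-depth comparison between two coverage tracks.

Coordinates: peaks are 0-based half-open (BED convention), annotation is
1-based inclusive (GTF convention); signed offsets are negative upstream of
the TSS in the gene's transcriptional orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .motif import MotifModel, best_hit, motif_score_threshold


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Peak:
    """A called peak, 0-based half-open; ``summit_offset`` is relative to ``start``."""

    chrom: str
    start: int
    end: int
    summit_offset: int | None = None
    score: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValidationError(f"peak {self.name or ''}: need 0 <= start < end, "
                                  f"got [{self.start}, {self.end})")
        if self.summit_offset is not None and not 0 <= self.summit_offset < self.end - self.start:
            raise ValidationError(
                f"peak {self.name or ''}: summit_offset {self.summit_offset} outside the interval"
            )

    @property
    def anchor(self) -> int:
        """Summit position (0-based genomic) when known, else the interval midpoint."""
        if self.summit_offset is not None:
            return self.start + self.summit_offset
        return (self.start + self.end) // 2

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class Gene:
    """Gene record in GTF convention: 1-based inclusive interval, stranded."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        if not 1 <= self.start <= self.end:
            raise ValidationError(f"gene {self.gene_id}: need 1 <= start <= end")

    @property
    def tss(self) -> int:
        """1-based transcription start: ``start`` on +, ``end`` on -."""
        return self.start if self.strand == "+" else self.end


class TranscriptAnnotation:
    """Gene collection with per-chromosome TSS lookup."""

    def __init__(self, genes: Iterable[Gene]):
        self.genes = list(genes)
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValidationError("annotation: gene_ids must be unique")
        self._by_chrom: dict[str, list[Gene]] = {}
        for g in self.genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        self._tss_arrays: dict[str, tuple[np.ndarray, list[Gene]]] = {}
        for chrom, gs in self._by_chrom.items():
            gs_sorted = sorted(gs, key=lambda g: (g.tss, g.gene_id))
            self._tss_arrays[chrom] = (
                np.array([g.tss - 1 for g in gs_sorted]),  # 0-based TSS positions
                gs_sorted,
            )

    def __len__(self) -> int:
        return len(self.genes)

    def genes_on(self, chrom: str) -> list[Gene]:
        return self._by_chrom.get(chrom, [])

    def nearest_tss(self, chrom: str, pos0: int) -> Gene | None:
        """Gene whose TSS is closest to the 0-based position (ties: smaller gene_id)."""
        entry = self._tss_arrays.get(chrom)
        if entry is None:
            return None
        tss0, gs = entry
        dists = np.abs(tss0 - pos0)
        dmin = dists.min()
        best = [gs[i] for i in np.flatnonzero(dists == dmin)]
        return min(best, key=lambda g: g.gene_id)


def signed_tss_offset(pos0: int, gene: Gene) -> int:
    """Signed distance from the gene's TSS, negative upstream in transcription orientation."""
    delta = pos0 - (gene.tss - 1)
    return delta if gene.strand == "+" else -delta


# ---------------------------------------------------------------------------
# TSS density profile (Fig-5A-style)
# ---------------------------------------------------------------------------


def tss_density_profile(
    peaks: Sequence[Peak],
    tx: TranscriptAnnotation,
    window: int = 20_000,
    bin_size: int = 200,
    smooth_bins: int = 5,
) -> pd.DataFrame:
    """Histogram of signed summit-to-nearest-TSS offsets, raw and smoothed.

    Each peak is assigned the signed offset of its anchor to the nearest TSS;
    counts are binned over [-window, +window] and smoothed with a centered
    moving average of ``smooth_bins`` bins (odd; 1 = identity, edge bins
    averaged over the available neighbors). Peaks on chromosomes without any
    TSS are skipped with a warning.
    """
    if window <= 0 or bin_size < 1:
        raise ValidationError("window/bin_size: must be positive")
    if smooth_bins < 1 or smooth_bins % 2 == 0:
        raise ValidationError(f"smooth_bins: must be odd and >= 1, got {smooth_bins}")
    offsets = []
    for pk in peaks:
        gene = tx.nearest_tss(pk.chrom, pk.anchor)
        if gene is None:
            warnings.warn(f"peak {pk.name or pk.chrom}: no TSS on chromosome {pk.chrom}; skipped",
                          stacklevel=2)
            continue
        offsets.append(signed_tss_offset(pk.anchor, gene))
    edges = np.arange(-window, window + bin_size, bin_size)
    raw, _ = np.histogram(offsets, bins=edges)
    kernel = np.ones(smooth_bins)
    smoothed = np.convolve(raw, kernel, mode="same") / np.convolve(
        np.ones(len(raw)), kernel, mode="same"
    )
    centers = edges[:-1] + bin_size / 2.0
    return pd.DataFrame({"bin_center": centers, "raw": raw, "smoothed": smoothed})


# ---------------------------------------------------------------------------
# Genomic-region classification (Fig-5B-style)
# ---------------------------------------------------------------------------

REGION_LABELS = ("promoter", "gene_body", "distal")


def classify_peak_regions(
    peaks: Sequence[Peak],
    tx: TranscriptAnnotation,
    promoter_window: tuple[int, int] = (2000, 500),
) -> tuple[list[str], pd.Series]:
    """Label every peak promoter / gene_body / distal by its anchor position.

    ``promoter_window`` = (upstream bp, downstream bp) around the TSS in
    transcription orientation; precedence promoter > gene body > distal.
    Returns (per-peak labels, fractions over all peaks).
    """
    up, down = promoter_window
    if up <= 0 or down <= 0:
        raise ValidationError("promoter_window: both extents must be positive")
    labels = []
    for pk in peaks:
        pos0 = pk.anchor
        label = "distal"
        for gene in tx.genes_on(pk.chrom):
            off = signed_tss_offset(pos0, gene)
            if -up <= off <= down:
                label = "promoter"
                break
            if gene.start - 1 <= pos0 <= gene.end - 1:
                label = "gene_body"
        labels.append(label)
    counts = pd.Series(labels).value_counts()
    fractions = pd.Series(
        {lab: counts.get(lab, 0) / len(peaks) for lab in REGION_LABELS}, name="fraction"
    )
    return labels, fractions


# ---------------------------------------------------------------------------
# Motif scanning over peaks (Fig-5C-style)
# ---------------------------------------------------------------------------


def _fetch(genome, chrom: str, start: int, end: int, peak_name: str) -> str:
    """Peak sequence from a dict of strings or a pyfaidx.Fasta, 0-based half-open."""
    if isinstance(genome, Mapping):
        seq = genome[chrom]
        if start < 0 or end > len(seq):
            raise ValidationError(
                f"peak {peak_name}: [{start}, {end}) outside chromosome {chrom} "
                f"(length {len(seq)})"
            )
        return seq[start:end]
    if chrom not in genome:
        raise ValidationError(f"peak {peak_name}: chromosome {chrom} absent from FASTA")
    chrom_len = len(genome[chrom])
    if start < 0 or end > chrom_len:
        raise ValidationError(
            f"peak {peak_name}: [{start}, {end}) outside chromosome {chrom} (length {chrom_len})"
        )
    return str(genome[chrom][start:end])


def scan_peaks_for_motif(
    peaks: Sequence[Peak],
    genome,
    m: MotifModel,
    p_threshold: float = 1e-4,
    precision: float = 0.01,
) -> tuple[pd.DataFrame, float]:
    """Best motif hit per peak and the fraction of peaks with a site.

    Both strands are scanned at every offset; a peak contains a site iff its
    best log-odds score reaches the exact-null threshold at ``p_threshold``.
    Peaks shorter than the motif are site-free. Returns (per-peak table,
    fraction of peaks with a site).
    """
    threshold = motif_score_threshold(m, p_threshold, precision=precision)
    rows = []
    for i, pk in enumerate(peaks):
        name = pk.name or f"peak{i}"
        seq = _fetch(genome, pk.chrom, pk.start, pk.end, name)
        hit = best_hit(seq, m)
        if hit is None:
            rows.append((name, pk.chrom, pk.start, pk.end, -1, ".", np.nan, False))
            continue
        pos, strand, score = hit
        rows.append(
            (name, pk.chrom, pk.start, pk.end, pos, strand, score, bool(score >= threshold))
        )
    df = pd.DataFrame(
        rows,
        columns=["peak", "chrom", "start", "end", "position", "strand", "score", "has_site"],
    )
    fraction = float(df["has_site"].mean()) if len(df) else 0.0
    df.attrs["score_threshold"] = threshold
    df.attrs["p_threshold"] = p_threshold
    return df, fraction


# ---------------------------------------------------------------------------
# Candidate-gene filter
# ---------------------------------------------------------------------------


def select_candidate_genes(
    peaks: Sequence[Peak],
    hits: pd.DataFrame,
    tx: TranscriptAnnotation,
    window: tuple[int, int] = (-20_000, 500),
    strand_aware: bool = True,
) -> pd.DataFrame:
    """Genes with >= 1 motif-bearing peak in the signed TSS window.

    ``window`` = (most-upstream, most-downstream) signed offsets, negative
    upstream in transcription orientation (default -20 kb to +0.5 kb). With
    ``strand_aware=False`` offsets are plain genomic summit - TSS distances.
    Returns one row per candidate gene (gene_id, n_supporting_peaks,
    best_offset, best_motif_score), sorted by gene_id.
    """
    low, high = window
    if low > high:
        raise ValidationError(f"window: lower bound {low} exceeds upper bound {high}")
    hit_info = {row.peak: row for row in hits.itertuples()}
    support: dict[str, list[tuple[int, float, str]]] = {}
    for i, pk in enumerate(peaks):
        name = pk.name or f"peak{i}"
        info = hit_info.get(name)
        if info is None or not info.has_site:
            continue
        for gene in tx.genes_on(pk.chrom):
            if strand_aware:
                off = signed_tss_offset(pk.anchor, gene)
            else:
                off = pk.anchor - (gene.tss - 1)
            if low <= off <= high:
                support.setdefault(gene.gene_id, []).append((off, float(info.score), name))
    rows = []
    for gene_id in sorted(support):
        entries = support[gene_id]
        best_off = min(entries, key=lambda e: (abs(e[0]), e[0]))[0]
        rows.append(
            {
                "gene_id": gene_id,
                "n_supporting_peaks": len(entries),
                "best_offset": best_off,
                "best_motif_score": max(e[1] for e in entries),
                "supporting_peaks": ",".join(sorted(e[2] for e in entries)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "n_supporting_peaks", "best_offset",
                 "best_motif_score", "supporting_peaks"],
    )


# ---------------------------------------------------------------------------
# Read-depth comparison (Fig-5D-style)
# ---------------------------------------------------------------------------


def _peak_mean_depth(cov: pd.DataFrame, peaks: Sequence[Peak]) -> np.ndarray:
    """Overlap-weighted mean depth per peak from a bedGraph-style frame."""
    means = np.zeros(len(peaks))
    by_chrom = {c: g for c, g in cov.groupby(cov.columns[0])}
    for i, pk in enumerate(peaks):
        g = by_chrom.get(pk.chrom)
        if g is None:
            continue
        s = g.iloc[:, 1].to_numpy()
        e = g.iloc[:, 2].to_numpy()
        v = g.iloc[:, 3].to_numpy(dtype=float)
        overlap = np.minimum(e, pk.end) - np.maximum(s, pk.start)
        mask = overlap > 0
        means[i] = float((overlap[mask] * v[mask]).sum()) / pk.width
    return means


def compare_peak_depth(
    control_cov: pd.DataFrame,
    treated_cov: pd.DataFrame,
    peaks: Sequence[Peak],
    control_total: float | None = None,
    treated_total: float | None = None,
    pseudocount: float = 0.5,
    n_bins: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Per-peak normalized depth in two samples and the log2-ratio histogram.

    Coverage is bedGraph-style (chrom, start, end, value). Per-peak mean
    depth is scaled to depth per million: by the supplied library totals
    when given, else by each track's total coverage mass. Peaks with zero
    raw coverage in both samples are excluded (count reported). Returns
    (per-peak table, histogram table, summary with the median log2 ratio).
    """
    if pseudocount <= 0:
        raise ValidationError("pseudocount: must be > 0")
    c_raw = _peak_mean_depth(control_cov, peaks)
    t_raw = _peak_mean_depth(treated_cov, peaks)

    def total(cov: pd.DataFrame) -> float:
        return float(
            (
                (cov.iloc[:, 2] - cov.iloc[:, 1]).to_numpy()
                * cov.iloc[:, 3].to_numpy(dtype=float)
            ).sum()
        )

    c_total = control_total if control_total is not None else total(control_cov)
    t_total = treated_total if treated_total is not None else total(treated_cov)
    if c_total <= 0 or t_total <= 0:
        raise ValidationError("coverage totals must be positive")
    c_norm = c_raw * 1e6 / c_total
    t_norm = t_raw * 1e6 / t_total

    keep = ~((c_raw == 0) & (t_raw == 0))
    n_excluded = int((~keep).sum())
    names = [pk.name or f"peak{i}" for i, pk in enumerate(peaks)]
    log_ratio = np.log2((t_norm + pseudocount) / (c_norm + pseudocount))
    per_peak = pd.DataFrame(
        {
            "peak": np.asarray(names, dtype=object)[keep],
            "control_depth": c_norm[keep],
            "treated_depth": t_norm[keep],
            "log2_ratio": log_ratio[keep],
        }
    )
    counts, edges = np.histogram(per_peak["log2_ratio"], bins=n_bins)
    hist = pd.DataFrame(
        {"bin_center": (edges[:-1] + edges[1:]) / 2.0, "count": counts}
    )
    summary = {
        "n_peaks": int(keep.sum()),
        "n_excluded": n_excluded,
        "median_log2_ratio": float(np.median(per_peak["log2_ratio"])) if keep.any() else np.nan,
    }
    return per_peak, hist, summary
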