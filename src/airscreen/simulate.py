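"""Synthetic inputs with planted ground truth for every pipeline stage.

Three generators:

* :func:`simulate_screen_inputs` — a labeled single-cell count matrix
  (negative binomial with Bernoulli dropout), a gene-set annotation marking
  TF genes, and a weighted interaction network in which one TF's neighborhood
  is planted as differentially expressed in non-basal cells.
* :func:`simulate_genome_inputs` — a small genome, gene annotation and ChIP
  peak set in which a chosen fraction of peaks carries an exact motif
  consensus at the summit and peak positions follow a configurable
  TSS-offset distribution.
* :func:`simulate_trace` — a bead-displacement trace: sinusoid + linear
  drift + Gaussian noise at a fixed frame rate.

Every generator is bit-reproducible from its config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .cbf import BeadTrace
from .chip import Gene, Peak, TranscriptAnnotation
from .errors import ValidationError
from .screen import GeneSetAnnotation, InteractionNetwork, LabeledExpressionMatrix

TF_TERM = "GO:0043565"  # sequence-specific DNA binding


# ---------------------------------------------------------------------------
# Screen inputs
# ---------------------------------------------------------------------------


@dataclass
class ScreenSimConfig:
    """Study conditions for the planted-interactome screen simulation.

    Defaults emulate a modest airway scRNA-seq experiment: three cell classes
    (basal stem cells plus two differentiated classes), 200 cells per class,
    1,000 genes of which 100 carry the DNA-binding term, and one planted TF
    whose 50 interactors are upregulated 4-fold (log2fc = 2) in non-basal
    cells. The 20,000 background edges give a mean degree of 40, a sparse but
    interactome-like density: the screen averages fold changes over a TF's
    neighbor set, which is only meaningful when neighbor sets are sizable, as
    they are in the confidence-filtered interaction databases this emulates.
    Degenerate one-gene "interactomes" that a near-empty network would produce
    are not a regime the method targets.
    """

    n_cells_per_class: int = 200
    n_genes: int = 1000
    class_labels: tuple[str, ...] = ("BSC", "SC", "MCC")
    basal_label: str = "BSC"
    n_tfs: int = 100
    planted_tf: str | None = None
    planted_interactors: int = 50
    planted_log2fc: float = 2.0
    mean_expression: float = 1.0
    dispersion: float = 2.0
    dropout_rate: float = 0.3
    background_edges: int = 20_000
    tf_term: str = TF_TERM
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_cells_per_class", "n_genes", "n_tfs",
                     "planted_interactors", "background_edges"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name}: must be > 0, got {getattr(self, name)}")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValidationError(f"dropout_rate: must be in [0, 1], got {self.dropout_rate}")
        if self.planted_interactors > self.n_genes - 1:
            raise ValidationError(
                f"planted_interactors: {self.planted_interactors} exceeds n_genes - 1"
            )
        if self.n_tfs > self.n_genes:
            raise ValidationError(f"n_tfs: {self.n_tfs} exceeds n_genes")
        if len(self.class_labels) < 2:
            raise ValidationError("class_labels: need the basal class plus at least one other")
        if self.basal_label not in self.class_labels:
            raise ValidationError(f"basal_label: {self.basal_label!r} not in class_labels")
        if self.mean_expression <= 0:
            raise ValidationError(f"mean_expression: must be > 0, got {self.mean_expression}")
        if self.dispersion <= 0:
            raise ValidationError(f"dispersion: must be > 0, got {self.dispersion}")


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"G{i:0{width}d}" for i in range(n)]


def simulate_screen_inputs(
    cfg: ScreenSimConfig,
) -> tuple[LabeledExpressionMatrix, GeneSetAnnotation, InteractionNetwork, dict]:
    """Generate (matrix, annotation, network, ground_truth) with a planted TF.

    Counts are negative binomial (gamma-Poisson) around per-gene baseline
    means drawn lognormally about ``mean_expression``; planted interactors
    have their mean multiplied by ``2**planted_log2fc`` in every non-basal
    cell; dropout zeroes each entry independently with ``dropout_rate``.
    The network links the planted TF to exactly its planted interactors and
    adds ``background_edges`` random edges (collisions dropped and counted).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_ids(cfg.n_genes)

    tf_idx = sorted(rng.choice(cfg.n_genes, size=cfg.n_tfs, replace=False).tolist())
    tf_genes = [genes[i] for i in tf_idx]
    if cfg.planted_tf is None:
        planted_tf = tf_genes[0]
    else:
        if cfg.planted_tf not in genes:
            raise ValidationError(f"planted_tf: {cfg.planted_tf!r} is not a generated gene id")
        planted_tf = cfg.planted_tf
        if planted_tf not in tf_genes:
            tf_genes[0] = planted_tf  # force the planted TF into the annotated set
            tf_genes.sort()

    candidates = [g for g in genes if g != planted_tf]
    planted = sorted(
        rng.choice(len(candidates), size=cfg.planted_interactors, replace=False).tolist()
    )
    interactors = [candidates[i] for i in planted]

    # expression: per-gene lognormal baselines, multiplicative planted effect
    base_means = rng.lognormal(mean=np.log(cfg.mean_expression), sigma=0.6, size=cfg.n_genes)
    labels = np.repeat(list(cfg.class_labels), cfg.n_cells_per_class)
    n_cells = len(labels)
    mean_mat = np.tile(base_means, (n_cells, 1))
    nonbasal = labels != cfg.basal_label
    int_cols = np.array([genes.index(g) for g in interactors])
    mean_mat[np.ix_(nonbasal, int_cols)] *= 2.0 ** cfg.planted_log2fc

    lam = rng.gamma(shape=cfg.dispersion, scale=mean_mat / cfg.dispersion)
    counts = rng.poisson(lam).astype(float)
    if cfg.dropout_rate > 0:
        counts *= rng.random(counts.shape) >= cfg.dropout_rate

    cell_ids = [f"{lab}_{i:04d}" for i, lab in enumerate(labels)]
    matrix = LabeledExpressionMatrix(
        values=counts,
        gene_ids=genes,
        cell_ids=cell_ids,
        cell_class=np.asarray(labels, dtype=object),
        basal_label=cfg.basal_label,
    )
    annotation = GeneSetAnnotation({g: {cfg.tf_term} for g in tf_genes})

    edges: list[tuple[str, str, float]] = [
        (planted_tf, g, float(c))
        for g, c in zip(interactors, rng.uniform(0.7, 1.0, size=len(interactors)))
    ]
    seen = {frozenset(e[:2]) for e in edges}
    n_dropped = 0
    a_idx = rng.integers(0, cfg.n_genes, size=cfg.background_edges)
    b_idx = rng.integers(0, cfg.n_genes, size=cfg.background_edges)
    confs = rng.uniform(0.4, 1.0, size=cfg.background_edges)
    for a, b, c in zip(a_idx, b_idx, confs):
        if a == b:
            n_dropped += 1
            continue
        key = frozenset((genes[a], genes[b]))
        if key in seen:
            n_dropped += 1
            continue
        seen.add(key)
        edges.append((genes[a], genes[b], float(c)))
    network = InteractionNetwork(edges)

    ground_truth = {
        "planted_tf": planted_tf,
        "planted_interactors": interactors,
        "planted_log2fc": cfg.planted_log2fc,
        "tf_genes": tf_genes,
        "tf_term": cfg.tf_term,
        "n_edges": network.n_edges,
        "n_dropped_edges": n_dropped,
        "seed": cfg.seed,
    }
    return matrix, annotation, network, ground_truth


# ---------------------------------------------------------------------------
# Genome / ChIP inputs
# ---------------------------------------------------------------------------


@dataclass
class GenomeSimConfig:
    """Study conditions for the synthetic ChIP-seq input generator.

    Peak summits are offset from the TSS of a random gene by a draw from
    ``tss_offset_distribution`` (kind, *params*): ``("laplace", scale)``,
    ``("normal", sd)`` or ``("uniform", low, high)``; the default
    double-exponential with a 5 kb scale mimics the TSS-peaked, heavy-tailed
    profile of real peak sets. ``planted_site_fraction`` of peaks receive the
    exact ``motif_consensus`` centered on the summit (about 30% of real peaks
    carried a canonical site).
    """

    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 100
    gene_length: int = 10_000
    n_peaks: int = 500
    peak_width: int = 200
    motif_consensus: str = "TGATGCAA"
    planted_site_fraction: float = 0.3
    tss_offset_distribution: tuple = ("laplace", 5000.0)
    gc_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_chromosomes", "chrom_length", "n_genes", "gene_length",
                     "n_peaks", "peak_width"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name}: must be > 0, got {getattr(self, name)}")
        if not 0.0 <= self.planted_site_fraction <= 1.0:
            raise ValidationError(
                f"planted_site_fraction: must be in [0, 1], got {self.planted_site_fraction}"
            )
        if self.chrom_length <= self.gene_length:
            raise ValidationError("chrom_length: must exceed gene_length")
        if len(self.motif_consensus) > self.peak_width:
            raise ValidationError("motif_consensus: longer than peak_width")
        if set(self.motif_consensus.upper()) - set("ACGT"):
            raise ValidationError("motif_consensus: must be an A/C/G/T string")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValidationError(f"gc_fraction: must be in (0, 1), got {self.gc_fraction}")
        kind = self.tss_offset_distribution[0]
        if kind not in ("laplace", "normal", "uniform"):
            raise ValidationError(f"tss_offset_distribution: unknown kind {kind!r}")


def _draw_offsets(rng: np.random.Generator, spec: tuple, n: int) -> np.ndarray:
    kind = spec[0]
    if kind == "laplace":
        return rng.laplace(0.0, spec[1], size=n)
    if kind == "normal":
        return rng.normal(0.0, spec[1], size=n)
    return rng.uniform(spec[1], spec[2], size=n)


def simulate_genome_inputs(
    cfg: GenomeSimConfig,
) -> tuple[dict[str, str], TranscriptAnnotation, list[Peak], dict]:
    """Generate (genome, transcript annotation, peaks, ground_truth).

    The genome is i.i.d. with the configured GC fraction. Each peak's summit
    is placed at a signed offset (transcription-orientation-aware) from a
    random gene's TSS; a ``planted_site_fraction`` subset of peaks has the
    consensus written on the forward strand at the summit.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    p_gc = cfg.gc_fraction / 2.0
    p_at = (1.0 - cfg.gc_fraction) / 2.0
    alphabet = np.array(list("ACGT"))
    probs = [p_at, p_gc, p_gc, p_at]

    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    seqs = {
        c: rng.choice(4, size=cfg.chrom_length, p=probs).astype(np.int8) for c in chroms
    }

    width = max(4, len(str(cfg.n_genes - 1)))
    gene_list: list[Gene] = []
    for i in range(cfg.n_genes):
        chrom = chroms[int(rng.integers(cfg.n_chromosomes))]
        start = int(rng.integers(1, cfg.chrom_length - cfg.gene_length))  # 1-based
        strand = "+" if rng.random() < 0.5 else "-"
        gene_list.append(
            Gene(
                gene_id=f"gene{i:0{width}d}",
                chrom=chrom,
                strand=strand,
                start=start,
                end=start + cfg.gene_length - 1,
            )
        )
    tx = TranscriptAnnotation(gene_list)

    motif = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[b] for b in cfg.motif_consensus.upper()],
                     dtype=np.int8)
    half = cfg.peak_width // 2
    n_planted = int(round(cfg.planted_site_fraction * cfg.n_peaks))
    planted_flags = np.zeros(cfg.n_peaks, dtype=bool)
    planted_flags[rng.choice(cfg.n_peaks, size=n_planted, replace=False)] = True

    gene_pick = rng.integers(0, cfg.n_genes, size=cfg.n_peaks)
    offsets = np.rint(_draw_offsets(rng, cfg.tss_offset_distribution, cfg.n_peaks)).astype(int)

    peaks: list[Peak] = []
    truth_rows = []
    for i in range(cfg.n_peaks):
        gene = gene_list[int(gene_pick[i])]
        tss0 = gene.tss - 1  # 0-based
        signed = int(offsets[i])
        summit = tss0 + signed if gene.strand == "+" else tss0 - signed
        summit = int(np.clip(summit, half, cfg.chrom_length - half - 1))
        start = summit - half
        end = start + cfg.peak_width
        if planted_flags[i]:
            site_start = summit - len(motif) // 2
            seqs[gene.chrom][site_start:site_start + len(motif)] = motif
        peaks.append(
            Peak(
                chrom=gene.chrom,
                start=start,
                end=end,
                summit_offset=summit - start,
                name=f"peak{i:04d}",
            )
        )
        truth_rows.append(
            {
                "peak": f"peak{i:04d}",
                "gene_id": gene.gene_id,
                "has_site": bool(planted_flags[i]),
                "tss_offset": signed,
            }
        )

    genome = {c: "".join(alphabet[s]) for c, s in seqs.items()}
    ground_truth = {
        "peaks": truth_rows,
        "n_planted": int(n_planted),
        "motif_consensus": cfg.motif_consensus.upper(),
        "seed": cfg.seed,
    }
    return genome, tx, peaks, ground_truth


# ---------------------------------------------------------------------------
# Bead traces
# ---------------------------------------------------------------------------


@dataclass
class TraceSimConfig:
    """A bead oscillating at the ciliary beat frequency, filmed at ``fs`` frames/s."""

    fs: float = 240.0
    duration: float = 10.0
    true_frequency: float = 10.0
    amplitude: float = 3.0
    noise_sd: float = 0.5
    drift_slope: float = 0.0
    bead_id: str = "bead0"
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValidationError(f"fs: must be > 0, got {self.fs}")
        if not 0.0 < self.true_frequency < self.fs / 2.0:
            raise ValidationError(
                f"true_frequency: {self.true_frequency} Hz not in (0, fs/2); "
                f"frequencies at or above Nyquist ({self.fs / 2.0} Hz) alias"
            )
        if round(self.duration * self.fs) < 64:
            raise ValidationError("duration: duration*fs must be >= 64 samples")
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ValidationError("amplitude/noise_sd: must be >= 0")


def simulate_trace(cfg: TraceSimConfig) -> BeadTrace:
    """amplitude*sin(2*pi*f*t) + drift_slope*t + N(0, noise_sd) at fs frames/s."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.fs))
    t = np.arange(n) / cfg.fs
    disp = cfg.amplitude * np.sin(2.0 * np.pi * cfg.true_frequency * t)
    disp += cfg.drift_slope * t
    if cfg.noise_sd > 0:
        disp += rng.normal(0.0, cfg.noise_sd, size=n)
    return BeadTrace(displacement=disp, fs=cfg.fs, bead_id=cfg.bead_id)
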