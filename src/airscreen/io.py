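"""Readers and writers for the package's file contracts.

Formats: MatrixMarket + TSV sidecars (expression), 2-column TSV (gene-set
annotation), 3-column TSV (network edge list), FASTA (genome), GTF (genes),
BED6/narrowPeak (peaks), bedGraph (coverage), 2-column CSV (bead traces),
JSON (ground truth and run metadata).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .cbf import BeadTrace
from .chip import Gene, Peak, TranscriptAnnotation
from .errors import ValidationError
from .motif import MotifModel
from .screen import GeneSetAnnotation, InteractionNetwork, LabeledExpressionMatrix


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------


def write_matrix_mtx(matrix: LabeledExpressionMatrix, outdir: str | Path) -> None:
    """Write matrix.mtx (cells x genes), genes.tsv, cells.tsv and metadata.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(outdir / "matrix.mtx"), sparse.csr_matrix(matrix.values))
    pd.Series(matrix.gene_ids).to_csv(outdir / "genes.tsv", sep="\t",
                                      index=False, header=False)
    pd.DataFrame(
        {"cell_id": matrix.cell_ids, "cell_class": matrix.cell_class}
    ).to_csv(outdir / "cells.tsv", sep="\t", index=False)
    write_json({"basal_label": matrix.basal_label, "orientation": "cells_x_genes"},
               outdir / "metadata.json")


def read_matrix_mtx(indir: str | Path, basal_label: str | None = None) -> LabeledExpressionMatrix:
    indir = Path(indir)
    values = np.asarray(spio.mmread(str(indir / "matrix.mtx")).todense(), dtype=float)
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    cells = pd.read_csv(indir / "cells.tsv", sep="\t")
    if basal_label is None:
        meta = json.loads((indir / "metadata.json").read_text())
        basal_label = meta["basal_label"]
    return LabeledExpressionMatrix(
        values=values,
        gene_ids=genes,
        cell_ids=cells["cell_id"].astype(str).tolist(),
        cell_class=cells["cell_class"].astype(str).to_numpy(dtype=object),
        basal_label=basal_label,
    )


def write_matrix_tsv(matrix: LabeledExpressionMatrix, path: str | Path) -> None:
    """Dense single-file option: cell_id, cell_class, then one column per gene."""
    df = pd.DataFrame(matrix.values, columns=matrix.gene_ids)
    df.insert(0, "cell_class", matrix.cell_class)
    df.insert(0, "cell_id", matrix.cell_ids)
    df.to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path: str | Path, basal_label: str) -> LabeledExpressionMatrix:
    df = pd.read_csv(path, sep="\t")
    return LabeledExpressionMatrix(
        values=df.iloc[:, 2:].to_numpy(dtype=float),
        gene_ids=[str(c) for c in df.columns[2:]],
        cell_ids=df["cell_id"].astype(str).tolist(),
        cell_class=df["cell_class"].astype(str).to_numpy(dtype=object),
        basal_label=basal_label,
    )


# ---------------------------------------------------------------------------
# Annotation and network
# ---------------------------------------------------------------------------


def write_annotation_tsv(ann: GeneSetAnnotation, path: str | Path) -> None:
    rows = [(g, t) for g, terms in sorted(ann.items()) for t in sorted(terms)]
    pd.DataFrame(rows, columns=["gene", "term"]).to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path: str | Path) -> GeneSetAnnotation:
    df = pd.read_csv(path, sep="\t", comment="#")
    mapping: dict[str, set[str]] = {}
    for gene, term in zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)):
        mapping.setdefault(gene, set()).add(term)
    return GeneSetAnnotation(mapping)


def write_network_tsv(net: InteractionNetwork, path: str | Path) -> None:
    rows = sorted(
        (min(a, b), max(a, b), d["confidence"])
        for a, b, d in net.graph.edges(data=True)
    )
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "confidence"]).to_csv(
        path, sep="\t", index=False
    )


def read_network_tsv(path: str | Path) -> InteractionNetwork:
    """3-column TSV (gene_a, gene_b, confidence); '#' comments skipped;
    STRING 0-1000 scores normalized to [0, 1]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 3:
        raise ValidationError(f"network file {path}: expected 3 columns, got {df.shape[1]}")
    return InteractionNetwork.from_dataframe(df)


# ---------------------------------------------------------------------------
# Genome, annotation, peaks, coverage
# ---------------------------------------------------------------------------


def write_fasta(genome: dict[str, str], path: str | Path, line_width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


def read_fasta(path: str | Path):
    """Indexed FASTA handle (pyfaidx) for random access during scanning."""
    import pyfaidx

    return pyfaidx.Fasta(str(path))


def write_gtf(tx: TranscriptAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(tx.genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\tairscreen\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def read_gtf(path: str | Path) -> TranscriptAnnotation:
    """Gene-level records from a GTF, via an in-memory gffutils database."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes = []
    for feat in db.features_of_type("gene"):
        genes.append(
            Gene(
                gene_id=feat.attributes["gene_id"][0],
                chrom=feat.seqid,
                strand=feat.strand,
                start=feat.start,
                end=feat.end,
            )
        )
    return TranscriptAnnotation(genes)


def write_peaks_bed(peaks: Sequence[Peak], path: str | Path, narrowpeak: bool = False) -> None:
    """BED6 by default; narrowPeak adds signal/p/q placeholders and the summit column."""
    with open(path, "w") as fh:
        for i, pk in enumerate(peaks):
            name = pk.name or f"peak{i}"
            score = int(pk.score) if pk.score is not None else 0
            if narrowpeak:
                summit = pk.summit_offset if pk.summit_offset is not None else -1
                fh.write(
                    f"{pk.chrom}\t{pk.start}\t{pk.end}\t{name}\t{score}\t.\t0\t-1\t-1\t{summit}\n"
                )
            else:
                fh.write(f"{pk.chrom}\t{pk.start}\t{pk.end}\t{name}\t{score}\t.\n")


def read_peaks_bed(path: str | Path) -> list[Peak]:
    """BED6 or narrowPeak (10 columns; column 10 is the summit offset, -1 if absent)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    peaks = []
    for row in df.itertuples(index=False):
        summit = None
        if len(row) >= 10 and int(row[9]) >= 0:
            summit = int(row[9])
        peaks.append(
            Peak(
                chrom=str(row[0]),
                start=int(row[1]),
                end=int(row[2]),
                summit_offset=summit,
                score=float(row[4]) if len(row) >= 5 else None,
                name=str(row[3]) if len(row) >= 4 else None,
            )
        )
    return peaks


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
    )
    return df


def read_motif_jaspar(path: str | Path, pseudocount: float = 0.5) -> MotifModel:
    """JASPAR-format PFM via Bio.motifs, converted to a pseudocounted PWM."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        mot = bio_motifs.read(fh, "jaspar")
    counts = np.array([mot.counts[b] for b in "ACGT"]).T  # L x 4
    return MotifModel.from_counts(counts, pseudocount=pseudocount,
                                  name=mot.name or mot.matrix_id or "motif")


# ---------------------------------------------------------------------------
# Traces and JSON
# ---------------------------------------------------------------------------


def write_trace_csv(trace: BeadTrace, path: str | Path) -> None:
    t = np.arange(len(trace)) / trace.fs
    pd.DataFrame({"time_s": t, "displacement_px": trace.displacement}).to_csv(
        path, index=False
    )


def read_trace_csv(path: str | Path, fs: float | None = None,
                   bead_id: str | None = None) -> BeadTrace:
    """(time_s, displacement_px) CSV, or (frame, displacement_px) with an fs argument."""
    df = pd.read_csv(path)
    cols = [c.lower() for c in df.columns]
    disp = df.iloc[:, 1].to_numpy(dtype=float)
    if "time_s" in cols:
        t = df.iloc[:, cols.index("time_s")].to_numpy(dtype=float)
        dt = np.diff(t)
        if len(dt) and (dt.max() - dt.min()) > 1e-6 * dt.mean():
            raise ValidationError(f"trace {path}: non-uniform sampling; interpolate first")
        fs_eff = 1.0 / dt.mean() if len(dt) else (fs or 0.0)
    else:
        if fs is None:
            raise ValidationError(f"trace {path}: frame-indexed CSV needs an fs argument")
        fs_eff = fs
    return BeadTrace(displacement=disp, fs=float(fs_eff),
                     bead_id=bead_id or Path(path).stem)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
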