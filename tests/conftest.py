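import numpy as np
import pytest

from airscreen.chip import Gene, Peak, TranscriptAnnotation
from airscreen.screen import (GeneSetAnnotation, InteractionNetwork,
                              LabeledExpressionMatrix)


@pytest.fixture
def toy_matrix():
    """6 cells (3 basal, 3 non-basal) x 4 genes with hand-checkable counts.

    Per-gene basal / non-basal means:
      g1: 2 / 4      g2: 1 / 1     g3: 0 / 3      g4: 0 / 0
    """
    values = np.array(
        [
            # g1  g2  g3  g4
            [1.0, 1.0, 0.0, 0.0],  # basal
            [2.0, 1.0, 0.0, 0.0],  # basal
            [3.0, 1.0, 0.0, 0.0],  # basal
            [4.0, 1.0, 3.0, 0.0],  # secretory
            [5.0, 1.0, 6.0, 0.0],  # secretory
            [3.0, 1.0, 0.0, 0.0],  # ciliated
        ]
    )
    return LabeledExpressionMatrix(
        values=values,
        gene_ids=["g1", "g2", "g3", "g4"],
        cell_ids=[f"c{i}" for i in range(6)],
        cell_class=np.array(["B", "B", "B", "S", "S", "M"], dtype=object),
        basal_label="B",
    )


@pytest.fixture
def toy_annotation():
    return GeneSetAnnotation({"g1": {"TF"}, "g2": {"TF", "other"}, "g3": {"other"}})


@pytest.fixture
def toy_network():
    return InteractionNetwork(
        [("g1", "g2", 0.9), ("g1", "g3", 0.5), ("g2", "g3", 0.7), ("g2", "g4", 0.4)]
    )


def random_small_matrix(rng, max_cells=20, max_genes=20):
    """A random labeled matrix for oracle-equivalence checks."""
    n_b = int(rng.integers(2, max_cells // 2))
    n_nb = int(rng.integers(2, max_cells // 2))
    n_genes = int(rng.integers(2, max_genes + 1))
    values = rng.poisson(1.5, size=(n_b + n_nb, n_genes)).astype(float)
    classes = np.array(["B"] * n_b + ["X"] * n_nb, dtype=object)
    return LabeledExpressionMatrix(
        values=values,
        gene_ids=[f"g{i}" for i in range(n_genes)],
        cell_ids=[f"c{i}" for i in range(n_b + n_nb)],
        cell_class=classes,
        basal_label="B",
    )


@pytest.fixture
def candidate_fixture():
    """6 peaks (4 motif-bearing) around 3 genes at printed signed offsets.

    geneA (+, TSS 50000), geneB (-, TSS 130000), geneC (+, TSS 250000):
      pk1 site, offset -10000 from geneA  -> geneA candidate
      pk2 site, offset +200 from geneA    -> geneA candidate (downstream, in window)
      pk3 NO site, offset -500 from geneB -> does not count
      pk4 site, offset -25000 from geneB  -> outside [-20000, +500]
      pk5 site, offset +2000 from geneC   -> downstream of +500, excluded
      pk6 NO site, offset 0 from geneC    -> does not count
    Expected candidates under [-20000, +500]: geneA only.
    """
    genes = [
        Gene("geneA", "chr1", "+", 50_001, 60_000),   # TSS at 0-based 50000
        Gene("geneB", "chr1", "-", 120_001, 130_001),  # TSS at 0-based 130000
        Gene("geneC", "chr1", "+", 250_001, 260_000),  # TSS at 0-based 250000
    ]
    tx = TranscriptAnnotation(genes)

    def peak_at(summit, name):
        return Peak("chr1", summit - 100, summit + 100, summit_offset=100, name=name)

    peaks = [
        peak_at(50_000 - 10_000, "pk1"),
        peak_at(50_000 + 200, "pk2"),
        peak_at(130_000 + 500, "pk3"),    # - strand: genomic +500 => signed -500
        peak_at(130_000 + 25_000, "pk4"),  # - strand: genomic +25000 => signed -25000
        peak_at(250_000 + 2_000, "pk5"),
        peak_at(250_000, "pk6"),
    ]
    has_site = {"pk1": True, "pk2": True, "pk3": False,
                "pk4": True, "pk5": True, "pk6": False}
    return tx, peaks, has_site
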