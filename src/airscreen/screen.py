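"""In-silico transcription-factor screen over interaction-network neighborhoods.

The screen ranks transcription factors (TFs) by how differentially expressed
their protein-interaction neighborhood is between a basal reference cell class
and all other ("non-basal") classes of a labeled single-cell expression matrix:

1.  the TF universe is the set of genes carrying a DNA-binding gene-set term
    (GO:0043565 by convention) that are present in the matrix;
2.  the top-k universe genes by maximum per-class mean expression are kept
    ("expressed in at least one class");
3.  each TF's interactome is its confidence-capped network neighborhood
    (at most ``cap`` interactors, highest confidence first);
4.  per interactor, a pseudocounted fold change of non-basal over basal cells
    is computed from mean expression (combined score) or from the fraction of
    cells with expression > 0 (aggregated score);
5.  each TF's score is the average interactor fold change, and its p-value
    comes from a permutation null over random gene sets of matched size.

All tie-breaks are lexicographic on gene id so results are deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyUniverseError, UndefinedScoreError, ValidationError

logger = logging.getLogger(__name__)

FoldChangeMode = Literal["mean", "positive_fraction"]
Alternative = Literal["greater", "less", "two_sided"]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class LabeledExpressionMatrix:
    """Cells x genes expression values with one class label per cell.

    ``basal_label`` designates the reference class; every other label is
    treated as "non-basal" in fold-change statistics.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_class: np.ndarray
    basal_label: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_class = np.asarray(self.cell_class, dtype=object)
        n_cells, n_genes = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValidationError(f"gene_ids: expected {n_genes} ids, got {len(self.gene_ids)}")
        if len(self.cell_ids) != n_cells:
            raise ValidationError(f"cell_ids: expected {n_cells} ids, got {len(self.cell_ids)}")
        if len(self.cell_class) != n_cells:
            raise ValidationError("cell_class: one label per cell required")
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("gene_ids: identifiers must be unique")
        if np.any(self.values < 0):
            raise ValidationError("values: negative expression not allowed")
        labels = set(self.cell_class.tolist())
        if self.basal_label not in labels:
            raise ValidationError(f"basal_label: {self.basal_label!r} not present among cell classes")
        if labels == {self.basal_label}:
            raise ValidationError("cell_class: at least one non-basal class required")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def class_labels(self) -> list[str]:
        return sorted(set(self.cell_class.tolist()))

    @property
    def basal_mask(self) -> np.ndarray:
        return self.cell_class == self.basal_label

    def gene_index(self, gene: str) -> int:
        try:
            return self._gene_index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def __contains__(self, gene: str) -> bool:
        return gene in self._gene_index


class GeneSetAnnotation:
    """Mapping from gene id to a set of term identifiers.

    Lookups for unannotated genes return the empty set.
    """

    def __init__(self, mapping: dict[str, Iterable[str]]):
        self._mapping: dict[str, frozenset[str]] = {}
        for gene, terms in mapping.items():
            terms = frozenset(terms)
            if any(not t for t in terms):
                raise ValidationError(f"annotation: empty term identifier for gene {gene!r}")
            self._mapping[gene] = terms

    def terms(self, gene: str) -> frozenset[str]:
        return self._mapping.get(gene, frozenset())

    def genes_with_term(self, term: str) -> list[str]:
        return sorted(g for g, ts in self._mapping.items() if term in ts)

    def __len__(self) -> int:
        return len(self._mapping)

    def items(self):
        return self._mapping.items()


class InteractionNetwork:
    """Weighted undirected gene-interaction graph (STRING-style).

    Confidences are normalized to [0, 1]; self-loops are dropped and duplicate
    edges keep the maximum confidence, mirroring how STRING edge lists are
    typically consumed.
    """

    def __init__(self, edges: Iterable[tuple[str, str, float]]):
        g = nx.Graph()
        for a, b, conf in edges:
            conf = float(conf)
            if a == b:
                continue
            if not 0.0 <= conf <= 1.0:
                raise ValidationError(f"confidence: {conf} for edge ({a}, {b}) outside [0, 1]")
            if g.has_edge(a, b):
                g[a][b]["confidence"] = max(g[a][b]["confidence"], conf)
            else:
                g.add_edge(a, b, confidence=conf)
        self.graph = g

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "InteractionNetwork":
        """Build from a (gene_a, gene_b, confidence) frame.

        STRING distributes combined scores on a 0-1000 scale; if any confidence
        exceeds 1 the whole column is divided by 1000.
        """
        conf = df.iloc[:, 2].astype(float)
        if (conf > 1.0).any():
            conf = conf / 1000.0
        return cls(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str), conf))

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph

    def neighbors(self, gene: str) -> list[tuple[str, float]]:
        if gene not in self.graph:
            return []
        return [(nbr, d["confidence"]) for nbr, d in self.graph[gene].items()]


@dataclass
class ScreenParams:
    """Parameters of a full screen run."""

    term: str = "GO:0043565"
    k: int = 100
    cap: int = 250
    min_confidence: float = 0.0
    pseudocount: float = 0.01
    n_perm: int = 999
    seed: int = 0
    alternative: Alternative = "two_sided"
    aggregation: Literal["mean", "sum"] = "mean"
    restrict_universe_positive: bool = False

    def validate(self) -> None:
        if not self.term:
            raise ValidationError("term: must be non-empty")
        for name in ("k", "cap", "n_perm"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name}: must be >= 1, got {getattr(self, name)}")
        if self.pseudocount <= 0:
            raise ValidationError(f"pseudocount: must be > 0, got {self.pseudocount}")
        if not 0.0 <= self.min_confidence <= 1.0:
            raise ValidationError(f"min_confidence: must be in [0, 1], got {self.min_confidence}")
        if self.alternative not in ("greater", "less", "two_sided"):
            raise ValidationError(f"alternative: unknown value {self.alternative!r}")
        if self.aggregation not in ("mean", "sum"):
            raise ValidationError(f"aggregation: unknown value {self.aggregation!r}")


# ---------------------------------------------------------------------------
# Screen stages
# ---------------------------------------------------------------------------


def select_tf_universe(
    ann: GeneSetAnnotation, matrix: LabeledExpressionMatrix, term: str
) -> list[str]:
    """Genes annotated with ``term`` and present in the matrix, sorted lexicographically."""
    if not term:
        raise ValidationError("term: must be non-empty")
    universe = [g for g in ann.genes_with_term(term) if g in matrix]
    if not universe:
        raise EmptyUniverseError(
            f"no gene annotated with {term!r} is present in the expression matrix"
        )
    logger.info("TF universe for %s: %d genes present in matrix", term, len(universe))
    return universe


def rank_top_expressed(
    matrix: LabeledExpressionMatrix,
    genes: Sequence[str],
    k: int,
    metric: Literal["mean", "positive_fraction"] = "mean",
) -> list[str]:
    """Top-k genes by their maximum per-class summary ("expressed in at least one class").

    The per-class summary is the class mean by default (positive-cell fraction
    as an alternative). Ties are broken lexicographically.
    """
    if k < 1:
        raise ValidationError(f"k: must be >= 1, got {k}")
    missing = [g for g in genes if g not in matrix]
    if missing:
        raise KeyError(f"genes not in matrix: {missing[:5]}")
    genes = sorted(genes)
    if len(genes) <= k:
        return list(genes)
    cols = [matrix.gene_index(g) for g in genes]
    sub = matrix.values[:, cols]
    if metric == "positive_fraction":
        sub = (sub > 0).astype(float)
    class_max = np.full(len(genes), -np.inf)
    for label in matrix.class_labels:
        mask = matrix.cell_class == label
        class_max = np.maximum(class_max, sub[mask].mean(axis=0))
    # stable sort on lexicographically pre-sorted genes => lexicographic ties
    order = np.argsort(-class_max, kind="stable")[:k]
    return [genes[i] for i in order]


def get_interactors(
    net: InteractionNetwork,
    tf: str,
    cap: int = 250,
    min_confidence: float = 0.0,
    matrix: LabeledExpressionMatrix | None = None,
) -> list[str]:
    """Confidence-filtered neighbors of ``tf``, capped at the ``cap`` highest confidences.

    When a matrix is supplied, neighbors absent from it are discarded before
    capping. A TF absent from the network yields an empty list with a warning
    so that screens over many TFs proceed.
    """
    if cap < 1:
        raise ValidationError(f"cap: must be >= 1, got {cap}")
    if tf not in net:
        warnings.warn(f"TF {tf!r} absent from interaction network", stacklevel=2)
        return []
    nbrs = [
        (name, conf)
        for name, conf in net.neighbors(tf)
        if conf >= min_confidence and name != tf and (matrix is None or name in matrix)
    ]
    # highest confidence first, lexicographic gene id on ties
    nbrs.sort(key=lambda nc: (-nc[1], nc[0]))
    return [name for name, _ in nbrs[:cap]]


def _group_stats(
    matrix: LabeledExpressionMatrix, mode: FoldChangeMode
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene (non-basal, basal) summaries: means or positive-cell fractions."""
    basal = matrix.basal_mask
    vals = matrix.values if mode == "mean" else (matrix.values > 0)
    nb = vals[~basal].mean(axis=0)
    b = vals[basal].mean(axis=0)
    return np.asarray(nb, dtype=float), np.asarray(b, dtype=float)


def fold_change_vector(
    matrix: LabeledExpressionMatrix, mode: FoldChangeMode = "mean", pseudocount: float = 0.01
) -> np.ndarray:
    """Pseudocounted non-basal/basal fold change for every gene in matrix order."""
    if pseudocount <= 0:
        raise ValidationError(f"pseudocount: must be > 0, got {pseudocount}")
    nb, b = _group_stats(matrix, mode)
    return (nb + pseudocount) / (b + pseudocount)


def gene_fold_change(
    matrix: LabeledExpressionMatrix,
    gene: str,
    mode: FoldChangeMode = "mean",
    pseudocount: float = 0.01,
) -> float:
    """(non-basal summary + eps) / (basal summary + eps) for a single gene."""
    if pseudocount <= 0:
        raise ValidationError(f"pseudocount: must be > 0, got {pseudocount}")
    j = matrix.gene_index(gene)
    basal = matrix.basal_mask
    col = matrix.values[:, j]
    vals = col if mode == "mean" else (col > 0).astype(float)
    nb = vals[~basal].mean()
    b = vals[basal].mean()
    return float((nb + pseudocount) / (b + pseudocount))


def combined_score(
    matrix: LabeledExpressionMatrix, interactors: Sequence[str], pseudocount: float = 0.01
) -> float:
    """Mean interactor fold change of mean expression (non-basal vs basal)."""
    if len(interactors) == 0:
        raise UndefinedScoreError("combined score undefined for an empty interactor set")
    return float(
        np.mean([gene_fold_change(matrix, g, "mean", pseudocount) for g in interactors])
    )


def aggregated_score(
    matrix: LabeledExpressionMatrix,
    interactors: Sequence[str],
    aggregation: Literal["mean", "sum"] = "mean",
    pseudocount: float = 0.01,
) -> float:
    """Aggregate of interactor positive-cell-fraction fold changes.

    Mean by default; ``sum`` is offered as an alternative aggregation.
    """
    if len(interactors) == 0:
        raise UndefinedScoreError("aggregated score undefined for an empty interactor set")
    fcs = [gene_fold_change(matrix, g, "positive_fraction", pseudocount) for g in interactors]
    return float(np.sum(fcs) if aggregation == "sum" else np.mean(fcs))


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------


def _draw_null_sets(
    rng: np.random.Generator, n_universe: int, set_size: int, n_perm: int
) -> np.ndarray:
    """(n_perm, set_size) index array of uniform random subsets without replacement.

    Each row is sorted so a drawn set is always scored in a canonical gene
    order: floating-point summation then depends only on the set, not on the
    draw order, and tied scores compare identically across implementations.
    """
    u = rng.random((n_perm, n_universe))
    return np.sort(np.argpartition(u, set_size - 1, axis=1)[:, :set_size], axis=1)


def _pvalue_from_null(
    observed: float, null: np.ndarray, alternative: Alternative
) -> tuple[float, float, float]:
    """Add-one permutation p-values (greater, less, selected)."""
    n = len(null)
    p_greater = (1.0 + np.sum(null >= observed)) / (1.0 + n)
    p_less = (1.0 + np.sum(null <= observed)) / (1.0 + n)
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    else:
        p = min(1.0, 2.0 * min(p_greater, p_less))
    return float(p_greater), float(p_less), float(p)


def permutation_pvalue(
    matrix: LabeledExpressionMatrix,
    observed_score: float,
    n_interactors: int,
    universe: Sequence[str],
    score_fn: Callable[[LabeledExpressionMatrix, Sequence[str]], float],
    n_perm: int,
    seed: int | np.random.Generator = 0,
    alternative: Alternative = "two_sided",
) -> tuple[float, np.ndarray]:
    """Permutation p-value of ``observed_score`` against random matched-size gene sets.

    Draws ``n_perm`` sets of ``n_interactors`` genes uniformly without
    replacement from ``universe`` (sorted internally so the null is invariant
    to input gene order), scores each with ``score_fn``, and applies the
    add-one estimator: p_greater = (1 + #{null >= obs}) / (1 + n_perm).

    Returns (p-value for ``alternative``, null score sample).
    """
    if n_perm < 1:
        raise ValidationError(f"n_perm: must be >= 1, got {n_perm}")
    universe = sorted(universe)
    if n_interactors > len(universe):
        raise ValidationError(
            f"n_interactors: {n_interactors} exceeds universe size {len(universe)}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = _draw_null_sets(rng, len(universe), n_interactors, n_perm)
    null = np.array(
        [score_fn(matrix, [universe[j] for j in row]) for row in idx], dtype=float
    )
    _, _, p = _pvalue_from_null(observed_score, null, alternative)
    return p, null


# ---------------------------------------------------------------------------
# Full screen
# ---------------------------------------------------------------------------

RESULT_COLUMNS = [
    "tf_id",
    "n_interactors",
    "combined_score",
    "aggregated_score",
    "p_combined",
    "p_aggregated",
    "q_combined",
    "q_aggregated",
]


def run_screen(
    matrix: LabeledExpressionMatrix,
    ann: GeneSetAnnotation,
    net: InteractionNetwork,
    params: ScreenParams | None = None,
) -> pd.DataFrame:
    """Execute the full TF screen and return one row per tested TF.

    Pipeline: TF universe -> top-k by expression -> per-TF capped interactome
    -> combined and aggregated scores -> permutation p-values against random
    gene sets drawn from all matrix genes -> Benjamini-Hochberg adjustment
    across the TFs that received a p-value. TFs with zero usable interactors
    are carried through with missing scores. Output is sorted by p_combined
    (missing last), ties broken by tf_id.
    """
    params = params or ScreenParams()
    params.validate()

    universe_tfs = select_tf_universe(ann, matrix, params.term)
    tested = rank_top_expressed(matrix, universe_tfs, params.k)

    eps = params.pseudocount
    fc_mean = fold_change_vector(matrix, "mean", eps)
    fc_pos = fold_change_vector(matrix, "positive_fraction", eps)

    # Null universe: all matrix genes, optionally restricted to genes with
    # at least one positive cell; sorted for gene-order invariance.
    null_genes = list(matrix.gene_ids)
    if params.restrict_universe_positive:
        pos_any = (matrix.values > 0).any(axis=0)
        null_genes = [g for g, ok in zip(matrix.gene_ids, pos_any) if ok]
    null_genes = sorted(null_genes)
    null_cols = np.array([matrix.gene_index(g) for g in null_genes])
    null_fc_mean = fc_mean[null_cols]
    null_fc_pos = fc_pos[null_cols]

    rng = np.random.default_rng(params.seed)
    rows = []
    for tf in tested:
        interactors = get_interactors(
            net, tf, cap=params.cap, min_confidence=params.min_confidence, matrix=matrix
        )
        n_int = len(interactors)
        if n_int == 0:
            rows.append((tf, 0, np.nan, np.nan, np.nan, np.nan))
            continue
        cols = np.array([matrix.gene_index(g) for g in interactors])
        comb = float(fc_mean[cols].mean())
        if params.aggregation == "sum":
            agg = float(fc_pos[cols].sum())
        else:
            agg = float(fc_pos[cols].mean())
        idx = _draw_null_sets(rng, len(null_genes), n_int, params.n_perm)
        null_comb = null_fc_mean[idx].mean(axis=1)
        if params.aggregation == "sum":
            null_agg = null_fc_pos[idx].sum(axis=1)
        else:
            null_agg = null_fc_pos[idx].mean(axis=1)
        *_, p_comb = _pvalue_from_null(comb, null_comb, params.alternative)
        *_, p_agg = _pvalue_from_null(agg, null_agg, params.alternative)
        rows.append((tf, n_int, comb, agg, p_comb, p_agg))

    df = pd.DataFrame(
        rows,
        columns=["tf_id", "n_interactors", "combined_score", "aggregated_score",
                 "p_combined", "p_aggregated"],
    )
    for raw, adj in (("p_combined", "q_combined"), ("p_aggregated", "q_aggregated")):
        q = np.full(len(df), np.nan)
        mask = df[raw].notna().to_numpy()
        if mask.any():
            q[mask] = stats.false_discovery_control(df.loc[mask, raw].to_numpy())
        df[adj] = q
    df = df.sort_values(
        ["p_combined", "tf_id"], na_position="last", kind="stable"
    ).reset_index(drop=True)
    return df[RESULT_COLUMNS]
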