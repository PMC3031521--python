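"""The coexpression predictor: N50 neighbor counts plus a decision tree.

The N50 metric scores each gene's transcriptional coexpression with known
mitochondrial genes: for every expression dataset, count how many
gold-standard mitochondrial genes appear among the gene's k (=50) nearest
neighbors by Euclidean distance over the dataset's samples.  A binary
decision-tree classifier trained on the per-dataset count vectors then calls
each gene mitochondrial or not.

Conventions (the published description is silent on both): the query gene is
excluded from its own neighbor list, and distance ties break by ascending
gene id so counts are deterministic.  Genes absent from a dataset contribute
a missing count; the classifier substitutes -1 for missing counts (an
impossible count value, so the tree can learn to branch on absence).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .evaluation import ConfusionMatrix, MetricsReport, confusion_metrics
from .io_model import (
    ExpressionDataset,
    FeatureMatrix,
    Label,
    ProteinCatalog,
    ValidationError,
)

__all__ = [
    "N50CountMatrix",
    "TreeParams",
    "n50_counts",
    "train_coexpression_classifier",
    "predict_coexpression",
    "CoexpressionClassifier",
]

#: surrogate fed to the tree for a missing count (counts are always >= 0)
MISSING_SURROGATE = -1.0


@dataclass
class N50CountMatrix:
    """Gene x dataset neighbor counts; NaN marks a gene absent from a dataset."""

    gene_ids: list[str]
    dataset_ids: list[str]
    counts: np.ndarray  # float, integer-valued or NaN
    k: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.gene_ids), len(self.dataset_ids)):
            raise ValidationError("count matrix shape mismatch")
        finite = self.counts[~np.isnan(self.counts)]
        if finite.size and (finite.min() < 0 or finite.max() > self.k):
            raise ValidationError(f"counts must lie in [0, {self.k}]")


@dataclass(frozen=True)
class TreeParams:
    """Decision-tree training knobs.

    ``confidence_factor`` plays the role of C4.5's pruning confidence: lower
    values prune harder.  It maps onto cost-complexity pruning as
    ``ccp_alpha = 0.01 * (1 - confidence_factor)``, so the default 0.25 gives
    mild pruning and 1.0 disables it.  ``min_leaf`` is the minimum number of
    training instances per leaf.
    """

    confidence_factor: float = 0.25
    min_leaf: int = 2
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.confidence_factor < 1.0:
            raise ValidationError("confidence_factor must be in (0,1)")
        if self.min_leaf < 1:
            raise ValidationError("min_leaf must be >= 1")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")

    @property
    def ccp_alpha(self) -> float:
        return 0.01 * (1.0 - self.confidence_factor)


@dataclass
class CoexpressionClassifier:
    """A trained tree together with the dataset columns it expects."""

    tree: DecisionTreeClassifier
    dataset_ids: list[str]


def n50_counts(
    datasets: list[ExpressionDataset],
    gsp_ids: set[str],
    k: int = 50,
) -> N50CountMatrix:
    """Count gold-standard genes among each gene's k nearest coexpression neighbors.

    For gene g and dataset d the count is ``|knn(g, d) ∩ gsp_ids|`` where
    knn(g, d) holds the k genes closest to g by Euclidean distance over d's
    samples, excluding g itself, with ties broken by ascending gene id.
    Genes absent from a dataset get NaN in that column.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if not datasets:
        raise ValidationError("need at least one expression dataset")
    all_genes = sorted({g for ds in datasets for g in ds.gene_ids})
    gene_index = {g: i for i, g in enumerate(all_genes)}
    counts = np.full((len(all_genes), len(datasets)), np.nan)
    for d, ds in enumerate(datasets):
        n = len(ds.gene_ids)
        if n < k + 1:
            raise ValidationError(
                f"dataset {ds.dataset_id!r} has {n} genes, need >= {k + 1}"
            )
        # squared Euclidean distances via the Gram expansion (monotone in
        # distance, so ranks are unaffected)
        sq = np.einsum("ij,ij->i", ds.values, ds.values)
        d2 = sq[:, None] + sq[None, :] - 2.0 * ds.values @ ds.values.T
        np.fill_diagonal(d2, np.inf)  # exclude the query gene itself
        d2 = np.maximum(d2, 0.0, where=np.isfinite(d2), out=d2)
        # deterministic tie-break: secondary key = rank of gene id
        id_rank = np.argsort(np.argsort(ds.gene_ids))
        is_gsp = np.array([g in gsp_ids for g in ds.gene_ids])
        for i in range(n):
            order = np.lexsort((id_rank, d2[i]))
            neighbors = order[:k]
            counts[gene_index[ds.gene_ids[i]], d] = int(is_gsp[neighbors].sum())
    return N50CountMatrix(
        gene_ids=all_genes,
        dataset_ids=[ds.dataset_id for ds in datasets],
        counts=counts,
        k=k,
    )


def _design_matrix(counts: N50CountMatrix) -> np.ndarray:
    x = counts.counts.copy()
    x[np.isnan(x)] = MISSING_SURROGATE
    return x


def train_coexpression_classifier(
    counts: N50CountMatrix,
    catalog: ProteinCatalog,
    params: TreeParams = TreeParams(),
) -> tuple[CoexpressionClassifier, MetricsReport]:
    """Fit the tree on labelled genes and report stratified k-fold CV metrics.

    Only genes with a positive or negative gold-standard label train the
    classifier.  The cross-validated report pools held-out predictions over
    all folds into one confusion matrix; fold assignment is deterministic
    given ``params.seed``.
    """
    labels = catalog.labels
    rows, y = [], []
    for i, g in enumerate(counts.gene_ids):
        lab = labels.get(g)
        if lab is Label.POSITIVE:
            rows.append(i)
            y.append(1)
        elif lab is Label.NEGATIVE:
            rows.append(i)
            y.append(0)
    y_arr = np.array(y)
    if len(set(y)) < 2:
        raise ValidationError("training set must contain both classes")
    x = _design_matrix(counts)[rows]

    def make_tree() -> DecisionTreeClassifier:
        return DecisionTreeClassifier(
            criterion="entropy",
            min_samples_leaf=params.min_leaf,
            ccp_alpha=params.ccp_alpha,
            random_state=params.seed,
        )

    skf = StratifiedKFold(
        n_splits=params.cv_folds, shuffle=True, random_state=params.seed
    )
    tp = fp = fn = tn = 0
    for train_idx, test_idx in skf.split(x, y_arr):
        fold_tree = make_tree().fit(x[train_idx], y_arr[train_idx])
        pred = fold_tree.predict(x[test_idx])
        truth = y_arr[test_idx]
        tp += int(((pred == 1) & (truth == 1)).sum())
        fp += int(((pred == 1) & (truth == 0)).sum())
        fn += int(((pred == 0) & (truth == 1)).sum())
        tn += int(((pred == 0) & (truth == 0)).sum())
    report = confusion_metrics(ConfusionMatrix(tp, fp, fn, tn))

    final = make_tree().fit(x, y_arr)
    return CoexpressionClassifier(final, list(counts.dataset_ids)), report


def predict_coexpression(
    classifier: CoexpressionClassifier,
    counts: N50CountMatrix,
    predictor_id: str = "s14",
) -> FeatureMatrix:
    """Score genes with the trained tree; all-missing rows get a missing call.

    Returns a one-column :class:`FeatureMatrix` so the result plugs directly
    into the evidence-integration stage.
    """
    if list(counts.dataset_ids) != classifier.dataset_ids:
        raise ValidationError(
            "count matrix datasets do not match the classifier's training columns"
        )
    x = _design_matrix(counts)
    calls = classifier.tree.predict(x).astype(float)
    all_missing = np.isnan(counts.counts).all(axis=1)
    calls[all_missing] = np.nan
    return FeatureMatrix(list(counts.gene_ids), [predictor_id], calls[:, None])
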