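"""Residual-correlation analysis and hierarchical ordering of submissions.

Modern ML fields exhibit a strong Rashomon effect: many near-equally
accurate models that err in different places.  This module quantifies that
structure by correlating submissions' *residuals* (prediction - truth):
raw predictions are dominated by the shared truth signal and would be
near-perfectly correlated for every competent pair, so residual correlation
is the substrate that exposes which teams' approaches are actually related.

Pairwise Pearson r over residual vectors gives a similarity matrix;
agglomerative clustering (default average linkage) on the distance 1 - r
orders the teams into a dendrogram, and the mean off-diagonal correlation
ranks teams by how distinct their error pattern is from the rest of the
field (the "lone architecture" signature).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ConfigurationError, DegenerateInputError, IncompleteSubmissionError
from .types import CouplingDataset, SubmissionSet

LINKAGES = ("average", "single", "complete")


@dataclass
class SimilarityResult:
    """Correlation matrix, linkage tree and dendrogram ordering of teams."""

    labels: list[str]
    correlation: np.ndarray            # symmetric, unit diagonal
    linkage: np.ndarray | None = None  # scipy linkage matrix
    leaf_order: list[str] | None = None

    @property
    def distance(self) -> np.ndarray:
        return 1.0 - self.correlation

    def correlation_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.correlation, index=self.labels, columns=self.labels)

    def to_newick(self) -> str:
        """The linkage tree as a nested-parenthesis string with merge heights."""
        if self.linkage is None:
            raise ConfigurationError("cluster() has not been run")
        tree = hierarchy.to_tree(self.linkage)

        def render(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                length = parent_height
                return f"{self.labels[node.id]}:{length:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{parent_height - node.dist:.6g}"

        return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"


def residuals(
    submission: SubmissionSet, truth: CouplingDataset, split: str = "test"
) -> np.ndarray:
    """Per-record residual (prediction - truth) in record-id order."""
    ids = truth.record_ids(split)
    preds = submission.predictions.reindex(ids).to_numpy(dtype=float)
    if np.isnan(preds).any():
        missing = ids[np.isnan(preds)]
        raise IncompleteSubmissionError(
            f"submission {submission.team_id} missing record id {missing[0]}")
    return preds - truth.truth(split).reindex(ids).to_numpy(dtype=float)


def correlation_matrix(
    residual_vectors: Mapping[str, np.ndarray] | Sequence[SubmissionSet],
    truth: CouplingDataset | None = None,
    split: str = "test",
) -> SimilarityResult:
    """Pairwise Pearson correlation of residual vectors.

    Accepts either a mapping team -> residual vector, or a sequence of
    submissions together with ``truth`` (residuals computed internally).
    A zero-variance residual vector (e.g. a perfect submission) has no
    defined correlation and raises :class:`DegenerateInputError`.
    """
    if isinstance(residual_vectors, Mapping):
        vectors = {k: np.asarray(v, dtype=float) for k, v in residual_vectors.items()}
    else:
        if truth is None:
            raise ConfigurationError("truth dataset required to compute residuals")
        vectors = {s.team_id: residuals(s, truth, split) for s in residual_vectors}
    labels = list(vectors)
    if len(labels) < 2:
        raise ConfigurationError("need at least 2 submissions to correlate")
    lengths = {len(v) for v in vectors.values()}
    if len(lengths) != 1 or lengths.pop() < 3:
        raise ConfigurationError("residual vectors must share a length >= 3")
    matrix = np.vstack([vectors[l] for l in labels])
    stds = matrix.std(axis=1)
    for label, s in zip(labels, stds):
        if s == 0.0:
            raise DegenerateInputError(
                f"team {label} has zero-variance residuals; correlation undefined")
    corr = np.corrcoef(matrix)
    np.fill_diagonal(corr, 1.0)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    return SimilarityResult(labels=labels, correlation=corr)


def cluster(
    similarity: SimilarityResult, linkage: str = "average"
) -> SimilarityResult:
    """Agglomerative clustering on distance 1 - r; fills linkage and leaf order.

    Deterministic: scipy's linkage breaks ties by observation order, so
    relabelling teams permutes the leaf order equivariantly.
    """
    if linkage not in LINKAGES:
        raise ConfigurationError(f"linkage must be one of {LINKAGES}")
    dist = similarity.distance
    if not np.all(np.isfinite(dist)):
        raise ConfigurationError("non-finite distances; check the correlation matrix")
    condensed = squareform(np.clip(dist, 0.0, None), checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    order = hierarchy.leaves_list(Z)
    return SimilarityResult(
        labels=similarity.labels,
        correlation=similarity.correlation,
        linkage=Z,
        leaf_order=[similarity.labels[i] for i in order],
    )


def cut_clusters(similarity: SimilarityResult, n_clusters: int) -> dict[str, int]:
    """Cut the linkage tree into ``n_clusters`` flat groups (team -> group)."""
    if similarity.linkage is None:
        raise ConfigurationError("cluster() has not been run")
    flat = hierarchy.fcluster(similarity.linkage, t=n_clusters, criterion="maxclust")
    return dict(zip(similarity.labels, (int(c) for c in flat)))


def outlier_score(similarity: SimilarityResult) -> pd.Series:
    """Mean off-diagonal correlation per team, ascending (most distinct first)."""
    corr = similarity.correlation
    n = corr.shape[0]
    means = (corr.sum(axis=1) - np.diag(corr)) / (n - 1)
    return pd.Series(means, index=similarity.labels).sort_values(kind="stable")
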