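"""Population structure from presence/absence matrices and genotype PCA.

Carriage of structural variants and non-reference insertions is summarized
per sample as a binary presence/absence (PAV) matrix.  Samples are then
clustered hierarchically on Jaccard distance (shared absences carry no
signal for presence data) with complete linkage, and flat breed-level
labels are obtained by cutting the tree at the number of breeds.  Genotype
dosage matrices are additionally examined by PCA on centered, unit-variance
markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

logger = logging.getLogger("pangraphsv")


@dataclass
class PAVMatrix:
    """Samples x features binary carriage matrix."""

    matrix: pd.DataFrame        # index = samples, columns = features, values 0/1
    kind: str = "SV"            # SV | NRUI

    @property
    def samples(self) -> list[str]:
        return list(self.matrix.index)

    def uninformative_features(self) -> list[str]:
        """All-0 or all-1 columns (permitted but carrying no signal)."""
        col = self.matrix.sum(axis=0)
        n = len(self.matrix)
        return [c for c in self.matrix.columns if col[c] in (0, n)]

    def filter_carriers(self, min_carriers: int = 1,
                        max_carriers: int | None = None) -> "PAVMatrix":
        """Informativeness filter on per-feature carrier counts."""
        col = self.matrix.sum(axis=0)
        hi = len(self.matrix) if max_carriers is None else max_carriers
        keep = [c for c in self.matrix.columns if min_carriers <= col[c] <= hi]
        return PAVMatrix(matrix=self.matrix[keep], kind=self.kind)


def build_pav(feature_carriers: Mapping[str, Iterable[str]],
              samples: Sequence[str], kind: str = "SV") -> PAVMatrix:
    """M[i, j] = 1 iff sample i carries feature j."""
    samples = list(samples)
    index = {s: i for i, s in enumerate(samples)}
    features = sorted(feature_carriers)
    m = np.zeros((len(samples), len(features)), dtype=np.int8)
    for j, f in enumerate(features):
        for s in feature_carriers[f]:
            if s in index:
                m[index[s], j] = 1
    return PAVMatrix(matrix=pd.DataFrame(m, index=samples, columns=features),
                     kind=kind)


@dataclass
class ClusterResult:
    linkage: np.ndarray
    samples: list[str]          # lexicographic order used for clustering
    labels: dict[str, int]      # flat cluster labels at k

    def newick(self) -> str:
        """Dendrogram in newick form with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.samples[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def hcluster(pav: PAVMatrix, k: int, distance: str = "jaccard",
             linkage: str = "complete") -> ClusterResult:
    """Hierarchical clustering of samples with deterministic tie-breaking.

    Samples are sorted lexicographically before distance computation, so
    the tree and the flat labels at ``k`` do not depend on input order.
    Degenerate all-identical rows collapse to a single cluster (warned).
    """
    if len(pav.matrix) < 2:
        raise ValueError("clustering needs at least two samples")
    ordered = sorted(pav.matrix.index)
    X = pav.matrix.loc[ordered].to_numpy(dtype=float)
    D = pdist(X, metric=distance)
    if np.all(D == 0):
        logger.warning("all samples identical under %s distance; single cluster",
                       distance)
    Z = hierarchy.linkage(D, method=linkage)
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(linkage=Z, samples=ordered,
                         labels=dict(zip(ordered, (int(x) for x in flat))))


@dataclass
class PCAResult:
    scores: pd.DataFrame            # samples x components
    loadings: pd.DataFrame          # markers x components
    explained_variance: np.ndarray  # per retained component
    total_variance: float           # sum over ALL components (= n markers kept)
    dropped_markers: list[str]


def pca(dosages: pd.DataFrame, k: int = 10) -> PCAResult:
    """PCA of a samples x markers dosage matrix.

    Missing dosages are mean-imputed per marker; zero-variance markers are
    dropped (logged); markers are centered and scaled to unit variance
    before decomposition, so total variance equals the retained marker
    count.  Scores are sign-fixed by making the largest-magnitude loading
    of each component positive, giving order-invariant output.
    """
    X = dosages.to_numpy(dtype=float).copy()
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least two samples")
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.where(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [m for m, ok in zip(dosages.columns, keep) if not ok]
    if dropped:
        logger.info("PCA: dropped %d zero-variance markers", len(dropped))
    if not keep.any():
        raise ValueError("no polymorphic markers for PCA")
    markers = [m for m, ok in zip(dosages.columns, keep) if ok]
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]

    n, m = Xs.shape
    k = min(k, n - 1, m)
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    expl = S ** 2 / (n - 1)
    # deterministic sign: dominant loading of each component positive
    for i in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    scores = U[:, :k] * S[:k]
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=dosages.index, columns=comp_names),
        loadings=pd.DataFrame(Vt[:k].T, index=markers, columns=comp_names),
        explained_variance=expl[:k],
        total_variance=float(expl.sum()),
        dropped_markers=dropped)


def adjusted_rand_index(labels_a: Mapping[str, object],
                        labels_b: Mapping[str, object]) -> float:
    """ARI between two labelings given as sample -> label maps."""
    from sklearn.metrics import adjusted_rand_score

    common = sorted(set(labels_a) & set(labels_b))
    if not common:
        raise ValueError("no samples in common")
    a = [labels_a[s] for s in common]
    b = [labels_b[s] for s in common]
    return float(adjusted_rand_score(a, b))
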