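"""Exploratory quality control: sample PCA, sample-to-sample correlation,
bootstrap-supported hierarchical clustering, and marker z-score matrices.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .exceptions import ValidationError
from .io import AnnotationTable, ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class PcaResult:
    """Sample-space principal components of an expression matrix.

    ``scores`` is samples x components; ``variance_fraction`` the per-
    component share of total variance ("contribution rate");
    ``components`` the orthonormal probe-space loadings (components x
    probes).
    """

    sample_ids: list[str]
    scores: np.ndarray
    variance_fraction: np.ndarray
    components: np.ndarray = field(repr=False)

    @property
    def cumulative_fraction(self) -> np.ndarray:
        return np.cumsum(self.variance_fraction)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.sample_ids, columns=cols)


@dataclass
class ClusterTree:
    """Average-linkage sample dendrogram with per-node bootstrap support.

    ``node_leafsets[i]`` is the leaf set created by merge ``i`` of the
    scipy linkage matrix; ``bootstrap_prob[i]`` the fraction of probe
    resamples whose tree contains exactly that leaf set.
    """

    sample_ids: list[str]
    linkage: np.ndarray = field(repr=False)
    node_leafsets: list[frozenset] = field(repr=False)
    bootstrap_prob: np.ndarray = field(default=None)
    distance: str = "correlation"
    linkage_method: str = "average"
    n_boot: int = 0

    def support_of(self, leaves: set[str]) -> float:
        """Bootstrap probability of the node whose leaf set equals
        ``leaves`` (raises if no such node exists in the base tree)."""
        target = frozenset(leaves)
        for s, bp in zip(self.node_leafsets, self.bootstrap_prob):
            if {self.sample_ids[i] for i in s} == target:
                return float(bp)
        raise ValidationError(f"no node with leaf set {sorted(leaves)}")

    def to_newick(self) -> str:
        """Newick string with bootstrap probabilities as internal node
        labels and linkage heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)
        n = len(self.sample_ids)

        def render(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.sample_ids[node.id]}:{length:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            bp = self.bootstrap_prob[node.id - n]
            return f"({left},{right}){bp:.3g}:{length:.6g}"

        root = tree
        left = render(root.left, root.dist)
        right = render(root.right, root.dist)
        return f"({left},{right});"


# ---------------------------------------------------------------------------

def pca_samples(matrix: ExpressionMatrix, n_components: int | None = None) -> PcaResult:
    """PCA of samples in probe space (samples are observations, probes are
    variables; variables centered, not scaled), via SVD of the centered
    data."""
    if matrix.n_samples < 2:
        raise ValidationError("PCA needs at least 2 samples")
    X = matrix.values.T.astype(float)              # samples x probes
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for i in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    var = s ** 2
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    k = n_components or len(s)
    return PcaResult(
        sample_ids=list(matrix.sample_ids),
        scores=(U[:, :k] * s[:k]),
        variance_fraction=frac[:k],
        components=Vt[:k],
    )


def sample_correlation(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Pairwise Pearson correlation of the sample expression vectors.

    Symmetric with unit diagonal; a zero-variance sample yields NaN in its
    row/column with a warning.
    """
    if matrix.n_samples < 2:
        raise ValidationError("correlation needs at least 2 samples")
    values = matrix.values
    sd = values.std(axis=0)
    zero = sd < 1e-12
    if zero.any():
        bad = [matrix.sample_ids[i] for i in np.flatnonzero(zero)]
        warnings.warn(f"zero-variance sample(s): {bad}", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values, rowvar=False)
    corr = np.asarray(corr, dtype=float)
    np.fill_diagonal(corr, np.where(zero, np.nan, 1.0))
    return pd.DataFrame(corr, index=matrix.sample_ids, columns=matrix.sample_ids)


def _linkage_of(values: np.ndarray, distance: str, method: str) -> np.ndarray:
    if distance == "correlation":
        corr = np.corrcoef(values, rowvar=False)
        d = 1.0 - corr
        np.fill_diagonal(d, 0.0)
        d = np.clip((d + d.T) / 2.0, 0.0, None)   # enforce exact symmetry
        condensed = squareform(d, checks=False)
    elif distance == "euclidean":
        from scipy.spatial.distance import pdist
        condensed = pdist(values.T)
    else:
        raise ValidationError(f"unknown distance {distance!r}")
    return hierarchy.linkage(condensed, method=method)


def _leafsets(Z: np.ndarray, n: int) -> list[frozenset]:
    sets: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    out = []
    for i, (a, b, *_rest) in enumerate(Z):
        s = sets[int(a)] | sets[int(b)]
        sets[n + i] = s
        out.append(s)
    return out


def bootstrap_cluster(
    matrix: ExpressionMatrix,
    n_boot: int = 1000,
    seed: int | None = None,
    distance: str = "correlation",
    linkage_method: str = "average",
) -> ClusterTree:
    """Hierarchical clustering of samples with ordinary bootstrap support.

    The base tree clusters samples with distance 1 - Pearson and average
    linkage (both configurable).  Probes are then resampled with
    replacement ``n_boot`` times; the support of each internal node is the
    fraction of resampled trees containing exactly that node's leaf set.
    """
    if matrix.n_samples < 3:
        raise ValidationError("clustering needs at least 3 samples")
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    values = matrix.values
    n = matrix.n_samples
    Z = _linkage_of(values, distance, linkage_method)
    base_sets = _leafsets(Z, n)
    counts = np.zeros(len(base_sets))
    rng = np.random.default_rng(seed)
    n_probes = values.shape[0]
    for _ in range(n_boot):
        idx = rng.integers(0, n_probes, size=n_probes)
        Zb = _linkage_of(values[idx], distance, linkage_method)
        boot_sets = set(_leafsets(Zb, n))
        for i, s in enumerate(base_sets):
            if s in boot_sets:
                counts[i] += 1
    return ClusterTree(
        sample_ids=list(matrix.sample_ids),
        linkage=Z,
        node_leafsets=base_sets,
        bootstrap_prob=counts / n_boot,
        distance=distance,
        linkage_method=linkage_method,
        n_boot=n_boot,
    )


def zscore_matrix(
    matrix: ExpressionMatrix,
    gene_list: list[str],
    annotation: AnnotationTable,
) -> pd.DataFrame:
    """Marker-gene z-score matrix (probes of the listed genes x samples).

    Each probe row is standardized with its own mean and population (n)
    standard deviation; constant rows are zero-filled and flagged in the
    returned frame's ``zero_variance`` attribute.
    """
    rows: list[tuple[str, str]] = []
    for gene in gene_list:
        for probe in annotation.probes_of_gene(gene):
            if probe in matrix.probe_ids:
                rows.append((gene, probe))
    if not rows:
        raise ValidationError("none of the listed genes map to matrix probes")
    idx_of = {p: i for i, p in enumerate(matrix.probe_ids)}
    sub = np.stack([matrix.values[idx_of[p]] for _, p in rows])
    mean = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True)            # population sd
    zero = sd[:, 0] < 1e-12
    if zero.any():
        logger.warning("zscore_matrix: %d constant probe row(s) zero-filled",
                       int(zero.sum()))
    z = np.where(zero[:, None], 0.0, (sub - mean) / np.where(sd == 0, 1, sd))
    out = pd.DataFrame(
        z,
        index=pd.MultiIndex.from_tuples(rows, names=["gene_symbol", "probe_id"]),
        columns=matrix.sample_ids,
    )
    out.attrs["zero_variance"] = [rows[i][1] for i in np.flatnonzero(zero)]
    return out
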