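"""Control-sample similarity, clustering, correlation classes and the pooling call.

Similarity between two control samples is the Pearson correlation of their
bin-level read count vectors restricted to ChIP-enriched (master list)
regions; dissimilarity is one minus that correlation.  Empirically, the
distribution of pairwise correlations within groups of multiplexed
controls is bi-modal: a high class, where in-silico pooling behaves like
extra sequencing of the same background, and a low class, where it does
not.  The decision band between the classes sits around correlation
0.6-0.8; this module classifies pairs against a fixed threshold (default
0.7, the band midpoint) or by fitting a two-component Gaussian mixture to
the Fisher-z transformed correlations, and turns the class labels into a
pool / sequence-deeper recommendation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.mixture import GaussianMixture

from .enrichment import MasterList, restrict_counts
from .read_io import BinCounts

__all__ = [
    "UndefinedCorrelationError",
    "CorrelationReport",
    "Dendrogram",
    "Recommendation",
    "pearson",
    "normalized_euclidean",
    "pairwise_report",
    "hcluster",
    "classify_pairs",
    "recommend",
]


class UndefinedCorrelationError(ValueError):
    """Correlation is undefined (zero-variance vector)."""


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation between two equal-length count vectors."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 bins to correlate")
    if np.var(x) == 0 or np.var(y) == 0:
        raise UndefinedCorrelationError("zero-variance vector")
    return float(np.corrcoef(x, y)[0, 1])


def normalized_euclidean(x: np.ndarray, y: np.ndarray) -> float:
    """Euclidean distance after scaling each vector to unit total.

    Zero iff the two vectors are proportional, making the distance
    invariant to sequencing depth.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    sx, sy = x.sum(), y.sum()
    if sx == 0 or sy == 0:
        raise ValueError("cannot normalize a zero-total vector")
    return float(np.linalg.norm(x / sx - y / sy))


@dataclass
class CorrelationReport:
    """Pairwise similarity over control samples plus class labels.

    Pairs are keyed by index tuples ``(i, j)`` with ``i < j``.  Undefined
    correlations (a zero-variance restricted vector, symptomatic of
    insufficient depth) are stored as NaN, flagged, and always classified
    low.
    """

    sample_labels: list[str]
    pearson: np.ndarray
    group_labels: dict[tuple[int, int], str]
    vectors: np.ndarray | None = None
    class_labels: dict[tuple[int, int], str] | None = None
    threshold_used: float | None = None
    method: str | None = None
    undefined: set = field(default_factory=set)

    @property
    def n(self) -> int:
        return len(self.sample_labels)

    @property
    def dissimilarity(self) -> np.ndarray:
        return 1.0 - self.pearson

    def pairs(self):
        for i in range(self.n):
            for j in range(i + 1, self.n):
                yield (i, j)

    def pair_r(self, i: int, j: int) -> float:
        return float(self.pearson[i, j])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, j in self.pairs():
            rows.append(
                {
                    "sample_a": self.sample_labels[i],
                    "sample_b": self.sample_labels[j],
                    "group": self.group_labels.get((i, j), "other"),
                    "pearson": self.pair_r(i, j),
                    "class": (self.class_labels or {}).get((i, j), ""),
                    "undefined": (i, j) in self.undefined,
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def pairwise_report(
    samples: list[BinCounts],
    master: MasterList,
    labels: list[str] | None = None,
    groups: dict[tuple[int, int], str] | None = None,
    transform: str = "raw",
) -> CorrelationReport:
    """All pairwise Pearson correlations over master-list bins.

    ``transform="log1p"`` correlates ``log(1 + count)`` instead of raw
    counts, a useful option for heavy-tailed backgrounds.
    """
    if labels is None:
        labels = [f"sample_{i}" for i in range(len(samples))]
    if len(labels) != len(samples):
        raise ValueError("labels must be parallel to samples")
    if transform not in ("raw", "log1p"):
        raise ValueError(f"unknown transform {transform!r}")
    vecs = []
    for s in samples:
        v = restrict_counts(s, master).astype(np.float64)
        vecs.append(np.log1p(v) if transform == "log1p" else v)
    V = np.vstack(vecs) if vecs else np.empty((0, 0))
    n = len(samples)
    R = np.eye(n)
    undefined: set = set()
    for i in range(n):
        for j in range(i + 1, n):
            try:
                r = pearson(V[i], V[j])
            except UndefinedCorrelationError:
                r = np.nan
                undefined.add((i, j))
            R[i, j] = R[j, i] = r
    return CorrelationReport(
        sample_labels=list(labels),
        pearson=R,
        group_labels=dict(groups or {}),
        vectors=V,
        undefined=undefined,
    )


@dataclass
class Dendrogram:
    """Agglomerative merge tree over sample labels (scipy linkage encoding)."""

    linkage: np.ndarray
    labels: list[str]

    def to_newick(self) -> str:
        if len(self.labels) == 1:
            return f"{self.labels[0]};"
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_dist):
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def hcluster(
    report: CorrelationReport,
    metric: str = "one_minus_pearson",
    linkage: str = "average",
) -> Dendrogram:
    """Hierarchical clustering of samples on the chosen dissimilarity."""
    if metric not in ("one_minus_pearson", "normalized_euclidean"):
        raise ValueError(f"unknown metric {metric!r}")
    if linkage not in ("average", "complete"):
        raise ValueError(f"unknown linkage {linkage!r}")
    n = report.n
    if n == 1:
        return Dendrogram(np.empty((0, 4)), list(report.sample_labels))
    condensed = []
    for i, j in report.pairs():
        if metric == "one_minus_pearson":
            r = report.pair_r(i, j)
            d = 2.0 if np.isnan(r) else 1.0 - r
        else:
            if report.vectors is None:
                raise ValueError("report carries no vectors for the euclidean metric")
            d = normalized_euclidean(report.vectors[i], report.vectors[j])
        condensed.append(d)
    Z = hierarchy.linkage(np.asarray(condensed), method=linkage)
    return Dendrogram(Z, list(report.sample_labels))


def _mixture_threshold(r_values: np.ndarray, fixed_threshold: float):
    """Two-component Gaussian mixture on Fisher-z correlations.

    Returns (threshold_r, method_string).  Falls back to the fixed
    threshold when the fitted component means are closer than 0.1 in
    z-space (no separable bi-modality).
    """
    z = np.arctanh(np.clip(r_values, -0.999999, 0.999999)).reshape(-1, 1)
    gm = GaussianMixture(n_components=2, n_init=5, random_state=0).fit(z)
    means = gm.means_.ravel()
    order = np.argsort(means)
    m_lo, m_hi = means[order]
    if m_hi - m_lo < 0.1:
        return fixed_threshold, "fixed_threshold(mixture_fallback)"
    sd = np.sqrt(gm.covariances_.ravel())[order]
    w = gm.weights_[order]
    grid = np.linspace(m_lo, m_hi, 2001)
    lo_pdf = w[0] * stats.norm.pdf(grid, m_lo, sd[0])
    hi_pdf = w[1] * stats.norm.pdf(grid, m_hi, sd[1])
    diff = lo_pdf - hi_pdf
    sign_change = np.flatnonzero(np.diff(np.sign(diff)) != 0)
    z_star = grid[sign_change[0] + 1] if sign_change.size else (m_lo + m_hi) / 2
    return float(np.tanh(z_star)), "mixture"


def classify_pairs(
    report: CorrelationReport,
    method: str = "fixed_threshold",
    fixed_threshold: float = 0.7,
) -> CorrelationReport:
    """Label every pair high or low correlation class.

    ``fixed_threshold``: high iff r >= threshold (default 0.7, the midpoint
    of the empirical 0.6-0.8 decision band).  ``mixture``: fit a
    two-component Gaussian mixture to the Fisher-z correlations and place
    the threshold at the density crossing point between the component
    means.  Undefined pairs are classified low.
    """
    if method not in ("fixed_threshold", "mixture"):
        raise ValueError(f"unknown method {method!r}")
    finite = [report.pair_r(i, j) for i, j in report.pairs()
              if (i, j) not in report.undefined]
    if method == "mixture":
        if len(finite) < 6:
            raise ValueError(
                "mixture classification needs at least 6 defined pairs; "
                "use method='fixed_threshold'"
            )
        threshold, method_used = _mixture_threshold(np.asarray(finite), fixed_threshold)
    else:
        threshold, method_used = float(fixed_threshold), "fixed_threshold"
    labels = {}
    for i, j in report.pairs():
        if (i, j) in report.undefined:
            labels[(i, j)] = "low"
        else:
            labels[(i, j)] = "high" if report.pair_r(i, j) >= threshold else "low"
    report.class_labels = labels
    report.threshold_used = threshold
    report.method = method_used
    return report


@dataclass
class Recommendation:
    """Pooling decision for one candidate group of multiplexed controls."""

    decision: str  # "pool" | "sequence_deeper"
    min_pearson: float
    min_pair: tuple[str, str]
    low_pairs: list[tuple[str, str]]


def recommend(report: CorrelationReport, group: list[str] | None = None) -> Recommendation:
    """Pool iff every within-group pair is in the high correlation class.

    The minimum pairwise correlation is reported as the deciding statistic;
    if any pair is low, the recommendation is to sequence the individual
    controls deeper instead of pooling.
    """
    if report.class_labels is None:
        classify_pairs(report)
    labels = report.sample_labels
    if group is None:
        members = list(range(report.n))
    else:
        members = [labels.index(g) for g in group]
    if len(members) < 2:
        raise ValueError("a pooling candidate group needs at least 2 samples")
    pair_idx = [(i, j) for a, i in enumerate(members) for j in members[a + 1:]]
    pair_idx = [(min(i, j), max(i, j)) for i, j in pair_idx]
    rs = [report.pair_r(i, j) for i, j in pair_idx]
    low = [
        (labels[i], labels[j])
        for (i, j) in pair_idx
        if report.class_labels[(i, j)] == "low"
    ]
    k = int(np.nanargmin(rs)) if not all(np.isnan(rs)) else 0
    i, j = pair_idx[k]
    return Recommendation(
        decision="pool" if not low else "sequence_deeper",
        min_pearson=float(rs[k]),
        min_pair=(labels[i], labels[j]),
        low_pairs=low,
    )
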