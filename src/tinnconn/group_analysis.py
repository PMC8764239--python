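"""Group-level statistics: per-entry difference maps, classifier ANOVA /
Kruskal-Wallis, and channel clustering via classical MDS of a connectivity
matrix ("multidimensional cluster statistics").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .classify import ClassifierConfig, repeated_evaluation
from .types import ConnectivityMatrix, EstimationError, InputError

__all__ = [
    "DifferenceMap",
    "difference_map",
    "common_difference_mask",
    "EmbeddingResult",
    "mds_embed",
    "ClusterAssignment",
    "cluster_channels",
    "StatTestResult",
    "anova_models",
    "kruskal_times",
    "lft_hft_comparison",
]


@dataclass
class DifferenceMap:
    """Per-channel-pair p-values and significance mask at level alpha."""

    p_values: np.ndarray
    mask: np.ndarray
    alpha: float
    channel_labels: list
    correction: Optional[str] = None

    def significant_fraction(self) -> float:
        """Fraction of off-diagonal upper-triangle entries flagged."""
        n = self.mask.shape[0]
        iu = np.triu_indices(n, k=1)
        return float(self.mask[iu].mean())


def _stack(matrices) -> np.ndarray:
    if isinstance(matrices, np.ndarray) and matrices.ndim == 3:
        return matrices
    arrs = [m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m)
            for m in matrices]
    return np.stack(arrs)


def difference_map(
    group_a,
    group_b,
    alpha: float = 0.05,
    correction: Optional[str] = None,
    channel_labels: Optional[Sequence[str]] = None,
) -> DifferenceMap:
    """Welch two-sample t-test per matrix entry across epochs.

    ``group_a`` / ``group_b`` are stacks of per-epoch connectivity matrices
    (sequences of :class:`ConnectivityMatrix` or a 3-D array).  Constant
    entries yield p = 1 with a warning.  ``correction='bh'`` applies
    Benjamini-Hochberg across the upper triangle.
    """
    a = _stack(group_a)
    b = _stack(group_b)
    if a.shape[1:] != b.shape[1:]:
        raise InputError(f"matrix shapes differ: {a.shape[1:]} vs {b.shape[1:]}")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise InputError("need at least 2 epochs per group")
    if channel_labels is None:
        first = group_a[0] if not isinstance(group_a, np.ndarray) else None
        if isinstance(first, ConnectivityMatrix):
            channel_labels = first.channel_labels
        else:
            channel_labels = [f"ch{i}" for i in range(a.shape[1])]
    n = a.shape[1]
    p = np.ones((n, n))
    degenerate = 0
    for i in range(n):
        for k in range(n):
            if i == k:
                continue
            va, vb = a[:, i, k], b[:, i, k]
            if va.std() == 0 and vb.std() == 0:
                degenerate += 1
                continue  # p stays 1
            res = stats.ttest_ind(va, vb, equal_var=False)
            p[i, k] = res.pvalue if np.isfinite(res.pvalue) else 1.0
    if degenerate:
        warnings.warn(
            f"difference_map: {degenerate} constant entries set to p=1",
            RuntimeWarning, stacklevel=2,
        )
    if correction == "bh":
        iu = np.triu_indices(n, k=1)
        adj = _benjamini_hochberg(p[iu])
        p[iu] = adj
        p[(iu[1], iu[0])] = adj
    elif correction is not None:
        raise InputError(f"unknown correction {correction!r}")
    mask = p < alpha
    np.fill_diagonal(mask, False)
    return DifferenceMap(
        p_values=p, mask=mask, alpha=alpha,
        channel_labels=list(channel_labels), correction=correction,
    )


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.clip(adj, 0, 1)
    return out


def common_difference_mask(maps: Sequence) -> np.ndarray:
    """Element-wise AND of the significance masks (the shared-difference area)."""
    masks = [m.mask if isinstance(m, DifferenceMap) else np.asarray(m, dtype=bool)
             for m in maps]
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise InputError(f"mask shapes differ: {sorted(shapes)}")
    out = masks[0].copy()
    for m in masks[1:]:
        out &= m
    return out


@dataclass
class EmbeddingResult:
    """2-D (by default) channel coordinates from classical MDS, plus stress."""

    coordinates: np.ndarray
    stress: float
    channel_labels: list
    measure: Optional[str] = None


def mds_embed(matrix, dims: int = 2) -> EmbeddingResult:
    """Classical (Torgerson) MDS of channel dissimilarities.

    Dissimilarity d(i,j) = 1 − min-max-normalized connectivity (off-diagonal
    normalization; an all-equal matrix maps to zero dissimilarity, so all
    channels embed at the origin).  Directed matrices are symmetrized by
    averaging both directions first.
    """
    if isinstance(matrix, ConnectivityMatrix):
        vals = matrix.values
        labels = list(matrix.channel_labels)
        measure = matrix.measure
    else:
        vals = np.asarray(matrix, dtype=float)
        labels = [f"ch{i}" for i in range(vals.shape[0])]
        measure = None
    if not np.all(np.isfinite(vals)):
        raise InputError("connectivity matrix contains non-finite entries")
    vals = (vals + vals.T) / 2.0
    n = vals.shape[0]
    off = ~np.eye(n, dtype=bool)
    lo, hi = vals[off].min(), vals[off].max()
    d = np.zeros((n, n))
    if hi > lo:
        d[off] = 1.0 - (vals[off] - lo) / (hi - lo)
    # classical MDS: double-center the squared dissimilarities
    d2 = d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh(b)
    idx = np.argsort(w)[::-1][:dims]
    lam = np.clip(w[idx], 0.0, None)
    coords = v[:, idx] * np.sqrt(lam)
    emb_d = squareform(pdist(coords))
    denom = np.sum(d[off] ** 2)
    stress = float(np.sqrt(np.sum((emb_d[off] - d[off]) ** 2) / denom)) if denom > 0 else 0.0
    return EmbeddingResult(coordinates=coords, stress=stress,
                           channel_labels=labels, measure=measure)


@dataclass
class ClusterAssignment:
    """channel → cluster id (contiguous ints from 0) or None (unclustered)."""

    assignment: dict
    threshold: float

    @property
    def n_clusters(self) -> int:
        ids = {v for v in self.assignment.values() if v is not None}
        return len(ids)

    def members(self, cluster_id: int) -> list:
        return [c for c, v in self.assignment.items() if v == cluster_id]


def cluster_channels(
    embedding: EmbeddingResult, threshold_fraction: float = 0.3
) -> ClusterAssignment:
    """Single-linkage clusters of the embedded channels.

    The dendrogram is cut at ``threshold_fraction × max pairwise distance``;
    links with cophenetic distance strictly above the cut are severed
    (deterministic tie rule), and singleton clusters are reported as
    unclustered (id None).
    """
    if not (0 < threshold_fraction < 1):
        raise InputError("threshold_fraction must lie in (0, 1)")
    coords = np.asarray(embedding.coordinates, dtype=float)
    if coords.shape[0] < 2:
        raise InputError("need at least 2 channels to cluster")
    dists = pdist(coords)
    dmax = dists.max()
    if dmax == 0:
        # all channels coincide: one cluster containing everything
        assignment = {c: 0 for c in embedding.channel_labels}
        return ClusterAssignment(assignment=assignment, threshold=0.0)
    threshold = threshold_fraction * dmax
    z = linkage(dists, method="single")
    raw = fcluster(z, t=threshold, criterion="distance")
    # renumber: clusters of size >= 2 get contiguous ids, singletons -> None
    sizes = {cid: int(np.sum(raw == cid)) for cid in np.unique(raw)}
    kept = sorted(cid for cid, s in sizes.items() if s >= 2)
    remap = {cid: i for i, cid in enumerate(kept)}
    assignment = {
        ch: remap.get(cid) for ch, cid in zip(embedding.channel_labels, raw)
    }
    return ClusterAssignment(assignment=assignment, threshold=float(threshold))


@dataclass
class StatTestResult:
    statistic: float
    p_value: float
    flagged: bool = False


def _validate_groups(groups) -> list:
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise InputError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise InputError("each group needs at least 2 values")
    return groups


def anova_models(per_group_accuracies) -> StatTestResult:
    """One-way ANOVA across classifier accuracy lists.

    Degenerate cases (zero within-group variance) are flagged: identical
    groups give (F=0, p=1); separated constant groups give (inf, 0).
    """
    groups = _validate_groups(per_group_accuracies)
    pooled = np.concatenate(groups)
    if pooled.std() == 0:
        return StatTestResult(0.0, 1.0, flagged=True)
    if all(g.std() == 0 for g in groups):
        return StatTestResult(float("inf"), 0.0, flagged=True)
    f, p = stats.f_oneway(*groups)
    return StatTestResult(float(f), float(p))


def kruskal_times(per_group_times) -> StatTestResult:
    """Kruskal-Wallis H across per-repeat computing-time lists (rank-based)."""
    groups = _validate_groups(per_group_times)
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return StatTestResult(0.0, 1.0, flagged=True)
    h, p = stats.kruskal(*groups)
    return StatTestResult(float(h), float(p))


def lft_hft_comparison(
    X: np.ndarray,
    y: np.ndarray,
    feature_name: str = "features",
    configs: Optional[Sequence[ClassifierConfig]] = None,
    n_repeats: int = 10,
    seed: int = 0,
    healthy_label: str = "healthy",
    lft_label: str = "left_lft",
    hft_label: str = "left_hft",
) -> list:
    """Compare recognizability of low- vs high-frequency sub-variants.

    Runs {LFT vs healthy} and {HFT vs healthy} binary classification per
    classifier config and tests the per-repeat accuracy difference with a
    one-way ANOVA.  Returns one record per config with both accuracy lists,
    their means, and the ANOVA result.
    """
    y = np.asarray(y)
    for lbl in (healthy_label, lft_label, hft_label):
        if lbl not in y:
            raise InputError(f"sub-label {lbl!r} missing from the dataset")
    configs = list(configs) if configs is not None else [ClassifierConfig("svm_10cv")]
    records = []
    for config in configs:
        accs = {}
        for name, sub in (("lft", lft_label), ("hft", hft_label)):
            sel = np.isin(y, [healthy_label, sub])
            res = repeated_evaluation(
                X[sel], y[sel], feature_name, [config],
                n_repeats=n_repeats, seed=seed,
            )[0]
            accs[name] = res.accuracies
        test = anova_models([accs["lft"], accs["hft"]])
        records.append({
            "feature": feature_name,
            "classifier": config.kind,
            "lft_accuracies": accs["lft"],
            "hft_accuracies": accs["hft"],
            "lft_mean": float(np.mean(accs["lft"])),
            "hft_mean": float(np.mean(accs["hft"])),
            "difference": float(np.mean(accs["hft"]) - np.mean(accs["lft"])),
            "anova": test,
        })
    return records
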