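"""Redundancy reduction of the texture battery by hierarchical clustering.

Features are clustered (agglomeratively, "ascendant") on the distance
d(f, g) = 1 − |Pearson r(f, g)| computed across subjects, average linkage
by default.  Cutting the tree at k clusters groups near-duplicate features;
each cluster is then represented by the member that best explains its
co-members — operationalized as the highest mean squared correlation with
the other members (singletons represent themselves).  Ties break
lexicographically by feature name so the reduction is deterministic.

The |r| distance makes the grouping blind to feature sign and affine
rescaling, which is the right notion of redundancy for de-duplicating
texture indices before survival modeling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "ClusterResult",
    "standardize",
    "cluster_features",
    "select_representatives",
    "render_heatmap",
]


@dataclass
class ClusterResult:
    """Merge tree, flat assignment at k clusters, and representatives."""

    linkage_matrix: np.ndarray  # scipy linkage format
    feature_names: tuple[str, ...]
    assignments: dict[str, int]  # feature -> cluster id (1..k)
    k: int
    linkage_method: str
    representatives: dict[int, tuple[str, float]] = field(default_factory=dict)

    @property
    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for name, cid in self.assignments.items():
            out.setdefault(cid, []).append(name)
        return {cid: sorted(members) for cid, members in out.items()}

    @property
    def leaf_order(self) -> list[str]:
        leaves = hierarchy.leaves_list(self.linkage_matrix)
        return [self.feature_names[i] for i in leaves]

    def to_dict(self) -> dict:
        return {
            "linkage_method": self.linkage_method,
            "k": self.k,
            "clusters": {str(c): m for c, m in self.clusters.items()},
            "representatives": {
                str(c): {"feature": f, "score": s} for c, (f, s) in self.representatives.items()
            },
            "leaf_order": self.leaf_order,
            "linkage_matrix": self.linkage_matrix.tolist(),
        }


def standardize(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score each feature column; zero-variance columns dropped with a warning."""
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("feature table needs at least 2 subjects and 2 features")
    sd = table.std(axis=0, ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        if len(constant) == table.shape[1]:
            raise ValueError("all features have zero variance")
        warnings.warn(f"dropping zero-variance features: {constant}", stacklevel=2)
        table = table.drop(columns=constant)
        sd = sd.drop(constant)
    return (table - table.mean(axis=0)) / sd


def cluster_features(table: pd.DataFrame, linkage: str = "average", k: int = 6) -> ClusterResult:
    """Agglomerative clustering of features on d = 1 − |Pearson r|."""
    names = tuple(table.columns)
    if k > len(names):
        raise ValueError(f"k={k} exceeds the number of features ({len(names)})")
    if k < 1:
        raise ValueError("k must be >= 1")
    corr = np.corrcoef(table.to_numpy(), rowvar=False)
    dist = np.clip(1.0 - np.abs(corr), 0.0, None)
    np.fill_diagonal(dist, 0.0)
    z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    flat = hierarchy.fcluster(z, t=k, criterion="maxclust")
    assignments = {name: int(c) for name, c in zip(names, flat)}
    return ClusterResult(
        linkage_matrix=z,
        feature_names=names,
        assignments=assignments,
        k=k,
        linkage_method=linkage,
    )


def select_representatives(cr: ClusterResult, table: pd.DataFrame) -> ClusterResult:
    """Pick, per cluster, the member with the highest mean r² to co-members.

    The mean squared Pearson correlation with the other cluster members is
    the fraction-of-cluster-variation score; singletons score 1.  Ties break
    lexicographically.
    """
    corr = pd.DataFrame(
        np.corrcoef(table.to_numpy(), rowvar=False), index=table.columns, columns=table.columns
    )
    reps: dict[int, tuple[str, float]] = {}
    for cid, members in cr.clusters.items():
        if len(members) == 1:
            reps[cid] = (members[0], 1.0)
            continue
        scores = {}
        for f in members:
            others = [m for m in members if m != f]
            scores[f] = float((corr.loc[f, others] ** 2).mean())
        best = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        reps[cid] = best
    cr.representatives = reps
    return cr


def render_heatmap(table: pd.DataFrame, cr: ClusterResult, path: str | Path) -> Path:
    """Subject-by-feature heat map with columns in dendrogram leaf order."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram

    order = cr.leaf_order
    data = table[order].to_numpy()
    fig, (ax_d, ax_h) = plt.subplots(
        2, 1, figsize=(max(6, 0.25 * len(order)), 8), height_ratios=[1, 4], sharex=False
    )
    dendrogram(cr.linkage_matrix, ax=ax_d, no_labels=True, color_threshold=None)
    ax_d.set_yticks([])
    lim = np.nanmax(np.abs(data)) or 1.0
    im = ax_h.imshow(data, aspect="auto", cmap="RdBu_r", vmin=-lim, vmax=lim)
    ax_h.set_xticks(range(len(order)))
    ax_h.set_xticklabels(order, rotation=90, fontsize=6)
    ax_h.set_ylabel("subject")
    fig.colorbar(im, ax=ax_h, label="z-score")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
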