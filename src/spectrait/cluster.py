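"""Genotype grouping by trait means: UPGMA on Euclidean distances.

Genotypes are summarized by their mean DW, WC, and GY over all plots in a
treatment scope, z-scored by default (the three traits live on incommensurate
scales), and merged by average linkage.  Clusters are numbered by descending
mean grain yield, so cluster 1 is always the best-performing group, and
between-cluster contrasts are reported as relative decreases in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

TRAITS = ("DW", "WC", "GY")


def genotype_profiles(traits: pd.DataFrame, scope: str | None = None) -> pd.DataFrame:
    """Per-genotype trait means over replicates and years within a scope.

    ``scope`` is a treatment label, or None / "FL+LM" for all plots pooled.
    """
    frame = traits
    if scope and scope != "FL+LM":
        frame = frame[frame["treatment"] == scope]
        if frame.empty:
            raise ValueError(f"no plots in scope {scope!r}")
    prof = frame.groupby("genotype")[list(TRAITS)].mean()
    if prof.index.duplicated().any():
        raise ValueError("duplicate genotype labels")
    return prof


def upgma(profiles: pd.DataFrame, standardize: bool = True) -> np.ndarray:
    """Average-linkage merge tree on (optionally z-scored) trait vectors.

    Returns a scipy linkage matrix; merge heights are nondecreasing.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two genotypes")
    if profiles.index.duplicated().any():
        raise ValueError("duplicate genotype labels")
    X = profiles[list(TRAITS)].to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    return hierarchy.linkage(pdist(X), method="average")


def cut_clusters(linkage: np.ndarray, k: int = 3) -> np.ndarray:
    """Flat assignments with exactly k clusters (labels 1..k, scipy order)."""
    n_leaves = linkage.shape[0] + 1
    if not (1 <= k <= n_leaves):
        raise ValueError(f"k must be in [1, {n_leaves}]")
    return hierarchy.fcluster(linkage, t=k, criterion="maxclust")


def cluster_summary(assignments: np.ndarray, profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster n and mean +/- sd per trait, ordered by descending GY.

    Output cluster ids are renumbered so cluster 1 has the highest mean
    grain yield.
    """
    frame = profiles.copy()
    frame["_cluster"] = np.asarray(assignments)
    rows = []
    for label, grp in frame.groupby("_cluster"):
        row = {"raw_label": label, "n": len(grp)}
        for t in TRAITS:
            row[f"{t}_mean"] = grp[t].mean()
            row[f"{t}_sd"] = grp[t].std(ddof=1) if len(grp) > 1 else 0.0
        rows.append(row)
    out = pd.DataFrame(rows).sort_values("GY_mean", ascending=False).reset_index(drop=True)
    out.insert(0, "cluster", np.arange(1, len(out) + 1))
    return out


def relative_decrease(
    summary: pd.DataFrame, reference_cluster: int, comparison_cluster: int, trait: str
) -> float:
    """Percent decrease of a trait mean from reference to comparison cluster.

    Returns the unrounded value; report at one decimal.
    """
    ref = summary.loc[summary["cluster"] == reference_cluster, f"{trait}_mean"]
    cmp_ = summary.loc[summary["cluster"] == comparison_cluster, f"{trait}_mean"]
    if ref.empty or cmp_.empty:
        raise ValueError("cluster not present in summary")
    ref_v = float(ref.iloc[0])
    if ref_v == 0:
        raise ValueError("reference mean is zero; relative decrease undefined")
    return 100.0 * (ref_v - float(cmp_.iloc[0])) / ref_v


def to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Merge tree in Newick format with branch lengths from merge heights."""
    tree = hierarchy.to_tree(linkage)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return render(tree, tree.dist) + ";"
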