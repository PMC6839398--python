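"""Dimensional reduction and hierarchical clustering of angle profiles,
with per-cluster sex-chromosome composition summaries.

Profiles are embedded with Barnes-Hut t-SNE (for visualization and,
optionally, as the clustering input, matching the original analysis) and
partitioned by agglomerative Ward clustering. Clustering directly on the
raw 100-vector profiles is also supported and is seed-free; the mode is
recorded on the assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .stats import holm_bonferroni, one_sample_ztest, se_proportion

__all__ = ["ClusterAssignment", "embed_profiles", "cluster_profiles",
           "cluster_sex_composition", "rank_clusters_by_reference"]


@dataclass
class ClusterAssignment:
    labels: np.ndarray                 # cluster label per cell, 1..k
    k: int
    linkage_method: str = "ward"
    feature_space: str = "profiles"    # "profiles" or "tsne"
    embedding: np.ndarray | None = field(default=None, repr=False)
    seed: int | None = None


def embed_profiles(profiles: np.ndarray, perplexity: float = 100.0,
                   max_iter: int = 1000, seed: int = 0) -> np.ndarray:
    """2D Barnes-Hut t-SNE embedding of angle profiles.

    Deterministic for a fixed seed and input. Requires at least
    3*perplexity profiles so the perplexity is meaningful.
    """
    profiles = np.asarray(profiles, dtype=float)
    n = profiles.shape[0]
    minimum = int(np.ceil(3 * perplexity))
    if n < minimum:
        raise ValueError(
            f"need at least {minimum} profiles for perplexity {perplexity}, "
            f"got {n}")
    tsne = TSNE(n_components=2, perplexity=perplexity, max_iter=max_iter,
                random_state=seed, init="pca", method="barnes_hut")
    return tsne.fit_transform(profiles)


def cluster_profiles(features: np.ndarray, k: int | None = None,
                     method: str = "ward",
                     feature_space: str = "profiles",
                     seed: int | None = None,
                     k_range: tuple[int, int] = (2, 8)) -> ClusterAssignment:
    """Agglomerative clustering of profile features, dendrogram cut at k.

    With ``k=None`` the cut maximizing the mean silhouette over
    ``k_range`` is chosen (an explicit rule standing in for cutting by
    eye). All-identical inputs have a degenerate distance matrix and are
    rejected.
    """
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if np.ptp(features, axis=0).max() == 0:
        raise ValueError("degenerate input: all profiles identical")
    if k is not None and (k < 2 or k > n):
        raise ValueError(f"k must lie in [2, {n}]")
    z = linkage(features, method=method)
    if k is None:
        best_k, best_score = None, -np.inf
        for kk in range(k_range[0], min(k_range[1], n - 1) + 1):
            lab = fcluster(z, kk, criterion="maxclust")
            if len(np.unique(lab)) < 2:
                continue
            score = silhouette_score(features, lab)
            if score > best_score:
                best_k, best_score = kk, score
        k = best_k
    labels = fcluster(z, k, criterion="maxclust")
    return ClusterAssignment(labels=labels, k=int(len(np.unique(labels))),
                             linkage_method=method,
                             feature_space=feature_space, seed=seed)


def cluster_sex_composition(assignment: ClusterAssignment,
                            sex_labels: np.ndarray,
                            alpha: float = 0.05) -> pd.DataFrame:
    """Per-cluster X/Y composition with SE of proportion and Z-tests.

    Cells whose sex label is unknown (anything other than "X"/"Y") are
    excluded from the proportion and counted in ``n_unknown``. Each
    cluster's X proportion is tested against 0.5 with a one-sample Z-test,
    Holm-corrected across clusters.
    """
    labels = np.asarray(assignment.labels)
    sex = np.asarray(sex_labels)
    if labels.shape[0] != sex.shape[0]:
        raise ValueError("one sex label required per cell")
    rows = []
    for cl in np.unique(labels):
        in_cl = labels == cl
        if not in_cl.any():
            raise ValueError(f"cluster {cl} is empty")
        n_x = int(np.sum(sex[in_cl] == "X"))
        n_y = int(np.sum(sex[in_cl] == "Y"))
        n_unknown = int(in_cl.sum() - n_x - n_y)
        n = n_x + n_y
        if n == 0:
            raise ValueError(f"cluster {cl} has no sexed cells")
        p_hat = n_x / n
        _, p = one_sample_ztest(n_x, n, 0.5)
        rows.append({"cluster": int(cl), "n_x": n_x, "n_y": n_y,
                     "n_unknown": n_unknown, "x_proportion": p_hat,
                     "se_proportion": se_proportion(n_x, n), "p": p})
    out = pd.DataFrame(rows)
    adjusted, reject = holm_bonferroni(out["p"].to_numpy(), alpha=alpha)
    out["p_holm"] = adjusted
    out["differs_from_half"] = reject
    return out


def rank_clusters_by_reference(assignment: ClusterAssignment,
                               profiles: np.ndarray,
                               reference_profile: np.ndarray) -> pd.DataFrame:
    """Order clusters by how far their mean angle profile sits from a
    reference profile (e.g. the wild-type consensus); distance 0 = most
    normal-shaped cluster."""
    profiles = np.asarray(profiles, dtype=float)
    ref = np.asarray(reference_profile, dtype=float)
    rows = []
    for cl in np.unique(assignment.labels):
        mean_prof = profiles[assignment.labels == cl].mean(axis=0)
        rows.append({"cluster": int(cl),
                     "distance_to_reference":
                         float(np.linalg.norm(mean_prof - ref))})
    return pd.DataFrame(rows).sort_values(
        "distance_to_reference", ignore_index=True)
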