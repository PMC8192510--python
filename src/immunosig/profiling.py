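"""Immune-activation profile recovery by two-way hierarchical clustering.

Markers are standardized (z-score by default), subjects are clustered with
Ward linkage on Euclidean distances and the tree is cut into ``k_profiles``
groups; markers are clustered separately (average linkage on correlation
distances) for heatmap ordering. Recovered clusters are then *named* by
matching each cluster's mean z-score pattern against the five known
profile signatures (naive-T-cell-high, CD4-senescent/inflammatory,
CD8-senescent, NK-activated, monocyte-high) via a 5x5 linear assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_score
from sklearn.utils.validation import check_is_fitted

from .synthetic import PROFILE_SIGNATURES, Cohort

__all__ = [
    "standardize_markers",
    "ProfileClusterer",
    "NamingResult",
    "name_profiles",
    "double_hierarchical_cluster",
]


def standardize_markers(markers: pd.DataFrame, mode: str = "zscore") -> pd.DataFrame:
    """Column-wise standardization of a subject x marker table.

    ``zscore``: (x - mean) / sd (sample SD, ddof=1). ``robust``:
    (x - median) / (1.4826 * MAD). A constant column is degenerate input
    and raises, naming the marker.
    """
    X = markers.astype(float)
    if mode == "zscore":
        center = X.mean()
        scale = X.std(ddof=1)
    elif mode == "robust":
        center = X.median()
        scale = 1.4826 * (X - X.median()).abs().median()
    else:
        raise ValueError(f"unknown standardization mode {mode!r}")
    bad = scale[(scale == 0) | scale.isna()].index.tolist()
    if bad:
        raise ValueError(f"constant marker column(s): {bad}")
    return (X - center) / scale


class ProfileClusterer(BaseEstimator, ClusterMixin):
    """Two-way agglomerative clustering of a subject x marker matrix.

    Parameters
    ----------
    k_profiles : number of subject clusters to cut (default 5).
    subject_linkage, marker_linkage : ``ward``, ``average`` or ``complete``.
    subject_metric, marker_metric : ``euclidean`` or ``correlation``.
    standardize : ``zscore``, ``robust`` or ``none`` (input already scaled).

    Fitted attributes
    -----------------
    labels_ : per-subject cluster id in 1..k_profiles.
    subject_linkage_, marker_linkage_ : scipy linkage matrices (n-1 merges).
    silhouette_ : mean silhouette of the subject partition.
    """

    def __init__(self, k_profiles: int = 5, subject_linkage: str = "ward",
                 marker_linkage: str = "average", subject_metric: str = "euclidean",
                 marker_metric: str = "correlation", standardize: str = "zscore"):
        self.k_profiles = k_profiles
        self.subject_linkage = subject_linkage
        self.marker_linkage = marker_linkage
        self.subject_metric = subject_metric
        self.marker_metric = marker_metric
        self.standardize = standardize

    def fit(self, X, y=None):
        if isinstance(X, Cohort):
            X = X.markers
        X = pd.DataFrame(X)
        n = len(X)
        if not 2 <= self.k_profiles <= n:
            raise ValueError(f"k_profiles must be in [2, {n}]")
        if X.isna().any().any():
            raise ValueError("missing values in marker matrix")
        Z = X if self.standardize == "none" else standardize_markers(X, self.standardize)
        values = Z.to_numpy()
        if len(np.unique(values, axis=0)) < self.k_profiles:
            raise ValueError("fewer distinct rows than k_profiles")
        if self.subject_linkage == "ward" and self.subject_metric != "euclidean":
            raise ValueError("ward linkage requires euclidean distances")

        subj_d = pdist(values, metric=self.subject_metric)
        self.subject_linkage_ = hierarchy.linkage(subj_d, method=self.subject_linkage)
        self.labels_ = hierarchy.fcluster(
            self.subject_linkage_, t=self.k_profiles, criterion="maxclust"
        )
        marker_d = pdist(values.T, metric=self.marker_metric)
        self.marker_linkage_ = hierarchy.linkage(marker_d, method=self.marker_linkage)
        self.marker_order_ = hierarchy.leaves_list(self.marker_linkage_)
        self.feature_names_in_ = np.asarray(X.columns)
        self.standardized_ = Z
        self.silhouette_ = (
            float(silhouette_score(values, self.labels_))
            if len(np.unique(self.labels_)) > 1
            else float("nan")
        )
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


@dataclass(frozen=True)
class NamingResult:
    """cluster id -> profile name assignment with its evidence."""

    mapping: dict[int, int]  # cluster id -> profile number 1..5
    scores: pd.DataFrame  # cluster x profile mean signature z-scores
    confidence: float  # optimal-vs-runner-up total-score margin
    low_confidence: bool

    def relabel(self, labels) -> np.ndarray:
        """Map raw cluster ids to profile numbers."""
        labels = np.asarray(labels)
        out = np.empty_like(labels)
        for c, p in self.mapping.items():
            out[labels == c] = p
        return out


def name_profiles(
    labels,
    cohort: Cohort | pd.DataFrame,
    signatures: dict[int, dict[str, int]] | None = None,
    confidence_threshold: float = 0.25,
) -> NamingResult:
    """Assign each recovered cluster the profile whose signature markers
    score highest in it.

    The cluster x profile score is the mean signed z-score of the profile's
    signature markers within the cluster; the bijective cluster -> profile
    map maximizes the total score (linear assignment). An exact tie between
    two optimal assignments (within 1e-9) raises; a small optimal-vs-
    runner-up margin is flagged as low confidence instead.
    """
    if signatures is None:
        signatures = PROFILE_SIGNATURES
    markers = cohort.markers if isinstance(cohort, Cohort) else cohort
    z = standardize_markers(markers)
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    profiles = sorted(signatures)
    if len(clusters) != len(profiles):
        raise ValueError(
            f"{len(clusters)} clusters but {len(profiles)} profile signatures"
        )
    missing = {
        m for sig in signatures.values() for m in sig if m not in z.columns
    }
    if missing:
        raise ValueError(f"signature markers absent from cohort: {sorted(missing)}")

    score = np.zeros((len(clusters), len(profiles)))
    for i, c in enumerate(clusters):
        zc = z.loc[labels == c].mean()
        for j, p in enumerate(profiles):
            sig = signatures[p]
            score[i, j] = float(np.mean([sign * zc[m] for m, sign in sig.items()]))

    row, col = linear_sum_assignment(-score)
    best_total = score[row, col].sum()
    # margin over all non-optimal bijections (5! = 120, trivially enumerable)
    runner_up = -np.inf
    best_perm = tuple(col[np.argsort(row)])
    for perm in permutations(range(len(profiles))):
        if perm == best_perm:
            continue
        total = score[np.arange(len(clusters)), perm].sum()
        runner_up = max(runner_up, total)
    margin = float(best_total - runner_up)
    if margin < 1e-9:
        raise ValueError(
            "ambiguous profile naming: two assignments tie at total score "
            f"{best_total:.6f}"
        )
    mapping = {int(clusters[r]): int(profiles[c]) for r, c in zip(row, col)}
    return NamingResult(
        mapping=mapping,
        scores=pd.DataFrame(score, index=clusters, columns=profiles),
        confidence=margin,
        low_confidence=margin < confidence_threshold,
    )


def double_hierarchical_cluster(matrix, k_profiles: int = 5, **params) -> ProfileClusterer:
    """Functional wrapper: fit a :class:`ProfileClusterer` and return it."""
    return ProfileClusterer(k_profiles=k_profiles, **params).fit(matrix)


def plot_profile_heatmap(clusterer: ProfileClusterer, path=None):
    """Diagnostic two-way-ordered heatmap (optional; needs matplotlib)."""
    check_is_fitted(clusterer, "labels_")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    Z = clusterer.standardized_
    subj_order = hierarchy.leaves_list(clusterer.subject_linkage_)
    data = Z.to_numpy()[np.ix_(subj_order, clusterer.marker_order_)]
    fig, ax = plt.subplots(figsize=(10, 6))
    im = ax.imshow(data, aspect="auto", cmap="RdBu_r", vmin=-3, vmax=3)
    ax.set_xlabel("markers (tree order)")
    ax.set_ylabel("subjects (tree order)")
    fig.colorbar(im, ax=ax, label="z-score")
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
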