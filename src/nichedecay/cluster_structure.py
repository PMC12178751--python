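"""Discovery of community states from the abundance ordination.

Sites are ordinated by PCA on mean-centred relative abundances (no
unit-variance scaling: all features share the relative-abundance scale),
clustered with DBSCAN in the leading score space, and binarised into the
dominant state (label 1) versus everything else including outliers
(label 2).  A 95% confidence ellipse per binary cluster summarises the
score-space footprint, and 16S co-occurrence-network read fractions can be
tested against the binary states.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.cluster import DBSCAN
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .differential_abundance import kw_test
from .io_formats import OUTLIER, AbundanceMatrix, SiteRecord


@dataclass
class PcaModel:
    """PCA of sites over MAG features: ``scores @ loadings.T + center``
    reconstructs the centred-then-shifted input."""

    site_ids: list[str]
    mag_ids: list[str]
    scores: np.ndarray  # sites x components
    loadings: np.ndarray  # mags x components, columns orthonormal
    explained_variance_fraction: np.ndarray
    center: np.ndarray  # per-MAG mean


@dataclass
class ClusterAssignment:
    """Raw DBSCAN labels (int >= 0, or OUTLIER) plus binarised {1, 2} states."""

    site_ids: list[str]
    raw_labels: np.ndarray
    binary_labels: np.ndarray | None
    eps_used: float
    min_pts: int

    def members(self, binary_label: int) -> np.ndarray:
        if self.binary_labels is None:
            raise ValueError("assignment not binarised yet")
        return np.where(self.binary_labels == binary_label)[0]


@dataclass
class Ellipse:
    """Confidence ellipse in 2-D score space."""

    center: np.ndarray
    axes: tuple[float, float]  # half-lengths, major first
    angle: float  # radians, major axis vs first score axis
    level: float


def pca_fit(matrix: AbundanceMatrix, n_components: int = 2) -> PcaModel:
    """Fit PCA to the site x MAG matrix (mean-centring only)."""
    X = matrix.values
    n_sites, n_mags = X.shape
    if n_sites < 2 or n_mags < 2:
        raise ValueError("PCA needs at least 2 sites and 2 MAGs")
    if n_components > min(n_sites - 1, n_mags):
        raise ValueError("n_components exceeds min(sites-1, MAGs)")
    center = X.mean(axis=0)
    if np.allclose(X - center, 0):
        raise ValueError("matrix has no variance; PCA undefined")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return PcaModel(
        site_ids=list(matrix.site_ids),
        mag_ids=list(matrix.mag_ids),
        scores=scores,
        loadings=pca.components_.T.copy(),
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
        center=pca.mean_.copy(),
    )


def orient_signs(model: PcaModel, raw_labels: np.ndarray) -> PcaModel:
    """Fix component signs so the largest raw cluster has negative mean scores.

    Sign flips leave distances, clustering and explained variance untouched;
    the convention only pins the ordination orientation (the dominant state
    sits at negative PC1).
    """
    labels = [l for l in np.unique(raw_labels) if l != OUTLIER]
    if not labels:
        return model
    sizes = {l: int((raw_labels == l).sum()) for l in labels}
    top = max(labels, key=lambda l: (sizes[l], -l))
    member_mean = model.scores[raw_labels == top].mean(axis=0)
    flip = np.where(member_mean > 0, -1.0, 1.0)
    return replace(model, scores=model.scores * flip, loadings=model.loadings * flip)


def auto_eps(scores: np.ndarray, min_pts: int = 2) -> float:
    """Pick the DBSCAN radius from the knee of the sorted kNN-distance curve.

    For each point the distance to its min_pts-th nearest other point is
    computed; the curve of sorted distances is reduced to its knee, the
    point of maximum perpendicular distance to the chord joining the
    curve's endpoints.
    """
    n = scores.shape[0]
    if n < min_pts + 1:
        raise ValueError(f"need at least min_pts+1={min_pts + 1} points")
    nn = NearestNeighbors(n_neighbors=min_pts + 1).fit(scores)
    dist, _ = nn.kneighbors(scores)
    curve = np.sort(dist[:, -1])  # distance to the min_pts-th other point
    if curve[-1] <= 0:
        raise ValueError("all points identical; eps undefined")
    if np.isclose(curve[0], curve[-1]):
        return float(curve[-1])
    x = np.arange(n, dtype=float)
    # perpendicular distance from (x_i, y_i) to the chord endpoint->endpoint
    dx, dy = x[-1] - x[0], curve[-1] - curve[0]
    norm = np.hypot(dx, dy)
    perp = np.abs(dy * (x - x[0]) - dx * (curve - curve[0])) / norm
    eps = float(curve[int(np.argmax(perp))])
    if eps <= 0:
        # knee landed on a zero-distance duplicate pair; use the smallest
        # positive kNN distance instead so DBSCAN remains well defined
        eps = float(curve[curve > 0][0])
    return eps


def dbscan(scores: np.ndarray, eps: float, min_pts: int = 2,
           site_ids: Sequence[str] | None = None) -> ClusterAssignment:
    """Density clustering of score-space points.

    A core point needs ``min_pts`` neighbours within ``eps`` including
    itself, so ``min_pts=2`` means a mutually close pair already forms a
    class; unreachable points get the OUTLIER label.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(scores)
    if site_ids is None:
        site_ids = [str(i) for i in range(scores.shape[0])]
    return ClusterAssignment(list(site_ids), labels, None, float(eps), min_pts)


def binarise(assignment: ClusterAssignment) -> ClusterAssignment:
    """Collapse raw DBSCAN labels to two states.

    The largest raw cluster becomes state 1; all smaller clusters and all
    outliers are pooled into state 2.  Size ties break toward the lower raw
    label.
    """
    raw = assignment.raw_labels
    labels = [l for l in np.unique(raw) if l != OUTLIER]
    if not labels:
        raise ValueError("no clusters found (all sites are outliers); cannot binarise")
    sizes = {l: int((raw == l).sum()) for l in labels}
    top = max(labels, key=lambda l: (sizes[l], -l))
    binary = np.where(raw == top, 1, 2)
    return replace(assignment, binary_labels=binary)


def confidence_ellipse(scores2d: np.ndarray, level: float = 0.95) -> Ellipse:
    """Confidence ellipse of a 2-D score cloud.

    The sample covariance is scaled by the chi-square quantile at ``level``
    with 2 degrees of freedom; half-axis lengths are
    ``sqrt(eigenvalue * quantile)``.
    """
    if scores2d.ndim != 2 or scores2d.shape[1] != 2:
        raise ValueError("expected an n x 2 score array")
    if scores2d.shape[0] < 3:
        raise ValueError("need at least 3 member sites for an ellipse")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    cov = np.cov(scores2d, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals[0] <= 1e-12 * max(eigvals[-1], 1.0):
        raise ValueError("singular score covariance; ellipse undefined")
    q = stats.chi2.ppf(level, df=2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    angle = float(np.arctan2(eigvecs[1, 0], eigvecs[0, 0]))
    axes = (float(np.sqrt(eigvals[0] * q)), float(np.sqrt(eigvals[1] * q)))
    return Ellipse(center=scores2d.mean(axis=0), axes=axes, angle=angle, level=level)


def network_association(assignment: ClusterAssignment, sites: Sequence[SiteRecord],
                        network: str) -> tuple[float, float]:
    """Kruskal-Wallis test of a 16S network read fraction between states."""
    if assignment.binary_labels is None:
        raise ValueError("assignment must be binarised first")
    by_id = {s.site_id: s for s in sites}
    missing = [sid for sid in assignment.site_ids
               if sid not in by_id or network not in by_id[sid].network_fractions]
    if missing:
        raise ValueError(f"sites missing fraction for network {network!r}: {missing[:5]}")
    fractions = np.array([by_id[sid].network_fractions[network]
                          for sid in assignment.site_ids])
    return kw_test(fractions, assignment.binary_labels)
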