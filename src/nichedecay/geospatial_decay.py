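"""Per-MAG geographic distance decay and cluster geography.

The decay statistic for one MAG over a set of sites is the Spearman
correlation between the absolute pairwise differences in its relative
abundance and the matching great-circle distances, over the upper triangle
of unordered site pairs.  A positive rank correlation means the MAG's
abundance pattern becomes more dissimilar with distance — distance decay;
a correlation near zero marks a spatially unstructured (cosmopolitan)
distribution.

Decay is computed over all sites and separately within the sites of each
binary community state, then summarised per MAG association class and
correlated with the state log2 ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cluster_structure import ClusterAssignment
from .io_formats import AbundanceMatrix, SiteRecord

#: IUGG mean Earth radius, km.
EARTH_RADIUS_KM = 6371.0088

SUBSET_ALL = "ALL"
SUBSET_CLUSTER1 = "CLUSTER1_SITES"
SUBSET_CLUSTER2 = "CLUSTER2_SITES"

DECAY_COLUMNS = ["mag_id", "site_subset", "rho", "n_pairs", "defined"]


@dataclass
class DistanceMatrix:
    """Symmetric great-circle distance matrix in km, zero diagonal."""

    site_ids: list[str]
    values: np.ndarray

    def submatrix(self, idx: np.ndarray) -> np.ndarray:
        return self.values[np.ix_(idx, idx)]


@dataclass
class DecayCorrelation:
    """Spearman correlation of per-MAG decay against another per-MAG score."""

    rho: float
    p: float
    n_mags: int
    defined: bool


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance between coordinate pairs, in km (vectorised)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))
    return float(d) if np.ndim(d) == 0 else d


def pairwise_distances(sites: Sequence[SiteRecord]) -> DistanceMatrix:
    """All great-circle distances between the sites."""
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")
    lat = np.array([s.lat for s in sites])
    lon = np.array([s.lon for s in sites])
    values = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    np.fill_diagonal(values, 0.0)
    values = (values + values.T) / 2  # enforce exact symmetry
    return DistanceMatrix([s.site_id for s in sites], values)


def _pair_vectors(abundances: np.ndarray, dists: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(len(abundances), k=1)
    return np.abs(abundances[iu[0]] - abundances[iu[1]]), dists[iu]


def mag_decay(abundances: np.ndarray, dists: np.ndarray, mag_id: str = "",
              site_subset: str = SUBSET_ALL) -> dict:
    """Distance-decay row for one MAG over one site subset.

    ``abundances`` and ``dists`` must already be restricted to the subset.
    Fewer than 3 sites, or zero variance in either pair vector (e.g. a MAG
    with identical abundance everywhere), yields a flagged-undefined rho
    rather than silent NaN.
    """
    k = len(abundances)
    n_pairs = k * (k - 1) // 2
    row = {"mag_id": mag_id, "site_subset": site_subset, "rho": np.nan,
           "n_pairs": n_pairs, "defined": False}
    if k < 3:
        return row
    v_abund, v_dist = _pair_vectors(np.asarray(abundances, dtype=float), dists)
    if np.all(v_abund == v_abund[0]) or np.all(v_dist == v_dist[0]):
        return row
    rho, _ = stats.spearmanr(v_abund, v_dist)
    row.update(rho=float(rho), defined=True)
    return row


def decay_table(matrix: AbundanceMatrix, dists: DistanceMatrix,
                assignment: ClusterAssignment,
                subsets: Sequence[str] = (SUBSET_ALL, SUBSET_CLUSTER1, SUBSET_CLUSTER2),
                ) -> pd.DataFrame:
    """Per-MAG decay over all sites and within each binary state's sites."""
    if dists.site_ids != matrix.site_ids:
        raise ValueError("distance matrix and abundance matrix site order differ")
    subset_idx = {SUBSET_ALL: np.arange(matrix.n_sites)}
    if assignment.binary_labels is not None:
        subset_idx[SUBSET_CLUSTER1] = assignment.members(1)
        subset_idx[SUBSET_CLUSTER2] = assignment.members(2)
    rows = []
    for subset in subsets:
        idx = subset_idx[subset]
        sub_d = dists.submatrix(idx)
        for j, mag_id in enumerate(matrix.mag_ids):
            rows.append(mag_decay(matrix.values[idx, j], sub_d, mag_id, subset))
    return pd.DataFrame(rows, columns=DECAY_COLUMNS)


def decay_by_class(decay_df: pd.DataFrame, stats_df: pd.DataFrame) -> pd.DataFrame:
    """Mean decay per (association class, site subset); undefined rhos are
    excluded from the mean and counted."""
    merged = decay_df.merge(stats_df[["mag_id", "assoc_class"]], on="mag_id")
    rows = []
    for (cls, subset), grp in merged.groupby(["assoc_class", "site_subset"], sort=True):
        defined = grp[grp["defined"]]
        rows.append((cls, subset,
                     float(defined["rho"].mean()) if len(defined) else np.nan,
                     float(defined["rho"].std(ddof=1)) if len(defined) > 1 else np.nan,
                     len(defined), int((~grp["defined"]).sum())))
    return pd.DataFrame(rows, columns=["assoc_class", "site_subset", "mean_rho",
                                       "sd_rho", "n_defined", "n_undefined"])


def decay_vs_logratio(decay_df: pd.DataFrame, stats_df: pd.DataFrame,
                      site_subset: str) -> DecayCorrelation:
    """Spearman correlation of per-MAG decay rho against the state log2 ratio.

    Measures whether the MAGs most overrepresented in a state are also the
    least spatially structured within that state's sites.
    """
    sub = decay_df[(decay_df["site_subset"] == site_subset) & decay_df["defined"]]
    merged = sub.merge(stats_df[["mag_id", "log2_ratio"]], on="mag_id")
    n = len(merged)
    rho_vals = merged["rho"].to_numpy()
    lr_vals = merged["log2_ratio"].to_numpy()
    if n < 3 or np.all(rho_vals == rho_vals[0]) or np.all(lr_vals == lr_vals[0]):
        return DecayCorrelation(np.nan, np.nan, n, False)
    rho, p = stats.spearmanr(lr_vals, rho_vals)
    return DecayCorrelation(float(rho), float(p), n, True)


def nearest_other_cluster(sites: Sequence[SiteRecord],
                          assignment: ClusterAssignment) -> pd.DataFrame:
    """For each site, the distance to the closest site of the other state."""
    if assignment.binary_labels is None:
        raise ValueError("assignment must be binarised first")
    by_id = {s.site_id: s for s in sites}
    missing = [sid for sid in assignment.site_ids if sid not in by_id]
    if missing:
        raise ValueError(f"sites without coordinates: {missing[:5]}")
    ordered = [by_id[sid] for sid in assignment.site_ids]
    dists = pairwise_distances(ordered).values
    labels = assignment.binary_labels
    for lab in (1, 2):
        if not np.any(labels == lab):
            raise ValueError(f"state {lab} has no sites")
    rows = []
    for i, sid in enumerate(assignment.site_ids):
        other = np.where(labels != labels[i])[0]
        rows.append((sid, int(labels[i]), float(dists[i, other].min())))
    return pd.DataFrame(rows, columns=["site_id", "binary_label", "km"])
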