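"""Per-MAG and per-phylum differential abundance between community states.

Each MAG is scored by the log2 ratio of its mean relative abundance in
state 2 over state 1 and a Kruskal-Wallis test between states; p-values
are Benjamini-Hochberg adjusted across the MAG family, and a MAG is called
state-associated when it is at least ``fold_threshold``-fold enriched and
significant after FDR correction.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import AbundanceMatrix, MagRecord

CLUSTER1 = "CLUSTER1"
CLUSTER2 = "CLUSTER2"
UNASSIGNED = "UNASSIGNED"

VOLCANO_COLUMNS = ["mag_id", "log2_ratio", "H", "p", "q", "assoc_class"]


def kw_test(values: np.ndarray, groups: np.ndarray,
            exact: bool = False) -> tuple[float, float]:
    """Kruskal-Wallis H and p between the groups in ``groups``.

    Uses the standard tie-corrected rank statistic with a chi-square
    p-value; a degenerate sample in which every value is identical yields
    (0, 1) rather than an error.  With ``exact=True`` (allowed only for
    n <= 10) the p-value is instead the exact permutation tail
    probability P(H_perm >= H) over all assignments of values to groups.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in uniq]
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group in Kruskal-Wallis test")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    if exact:
        n = len(values)
        if n > 10:
            raise ValueError("exact permutation p only supported for n <= 10")
        from itertools import permutations

        def h_of(perm_values):
            perm_samples = [np.array(perm_values)[groups == g] for g in uniq]
            if len(set(perm_values)) == 1:
                return 0.0
            return stats.kruskal(*perm_samples)[0]

        hits = total = 0
        for perm in set(permutations(values.tolist())):
            total += 1
            hits += h_of(perm) >= h - 1e-12
        p = hits / total
    return float(h), float(p)


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped to 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def default_pseudocount(matrix: AbundanceMatrix) -> float:
    """Smallest non-zero abundance divided by 10 (keeps log ratios finite
    without drowning real signal)."""
    nonzero = matrix.values[matrix.values > 0]
    if nonzero.size == 0:
        raise ValueError("matrix is all zeros; pseudocount undefined")
    return float(nonzero.min()) / 10.0


def log2_ratio(matrix: AbundanceMatrix, binary_labels: np.ndarray, mag_id: str,
               pseudocount: float | None = None) -> float:
    """log2((mean state-2 abundance + eps) / (mean state-1 abundance + eps))."""
    eps = default_pseudocount(matrix) if pseudocount is None else float(pseudocount)
    col = matrix.column(mag_id)
    m1 = col[binary_labels == 1].mean()
    m2 = col[binary_labels == 2].mean()
    return float(np.log2((m2 + eps) / (m1 + eps)))


def classify_mag(log2r: float, q: float, fold_threshold: float = 2.0,
                 alpha: float = 0.05) -> str:
    """Associate a MAG with a state by fold change plus FDR significance.

    State 1 needs at least ``fold_threshold``-fold higher abundance there
    (log2 ratio <= -log2(threshold)) and q < alpha; state 2 symmetric;
    anything else is unassigned.
    """
    cut = np.log2(fold_threshold)
    if q < alpha and log2r <= -cut:
        return CLUSTER1
    if q < alpha and log2r >= cut:
        return CLUSTER2
    return UNASSIGNED


def volcano_table(matrix: AbundanceMatrix, binary_labels: np.ndarray,
                  fold_threshold: float = 2.0, alpha: float = 0.05,
                  pseudocount: float | None = None,
                  ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Differential-abundance table over all MAGs, BH-corrected as one family.

    Returns the per-MAG stats frame (mag_id, log2_ratio, H, p, q,
    assoc_class) and the class counts, which always sum to the MAG total.
    """
    binary_labels = np.asarray(binary_labels)
    if binary_labels.shape[0] != matrix.n_sites:
        raise ValueError("binary labels must cover all sites")
    for lab in (1, 2):
        if not np.any(binary_labels == lab):
            raise ValueError(f"state {lab} has no sites")
    eps = default_pseudocount(matrix) if pseudocount is None else float(pseudocount)
    m1 = matrix.values[binary_labels == 1].mean(axis=0)
    m2 = matrix.values[binary_labels == 2].mean(axis=0)
    log2r = np.log2((m2 + eps) / (m1 + eps))
    hp = np.array([kw_test(matrix.values[:, j], binary_labels)
                   for j in range(matrix.n_mags)])
    q = bh_fdr(hp[:, 1])
    classes = [classify_mag(lr, qv, fold_threshold, alpha)
               for lr, qv in zip(log2r, q)]
    df = pd.DataFrame({"mag_id": matrix.mag_ids, "log2_ratio": log2r,
                       "H": hp[:, 0], "p": hp[:, 1], "q": q, "assoc_class": classes})
    counts = {c: int((df["assoc_class"] == c).sum())
              for c in (CLUSTER1, CLUSTER2, UNASSIGNED)}
    return df, counts


def phylum_volcano(matrix: AbundanceMatrix, records: Sequence[MagRecord],
                   binary_labels: np.ndarray, fold_threshold: float = 2.0,
                   alpha: float = 0.05, pseudocount: float | None = None,
                   ) -> pd.DataFrame:
    """Volcano statistics after summing member-MAG abundances per phylum.

    Unnamed phyla pool into "Unclassified"; BH correction runs across the
    phylum family only.
    """
    by_id = {r.mag_id: r for r in records}
    missing = [m for m in matrix.mag_ids if m not in by_id]
    if missing:
        raise ValueError(f"MAGs without metadata record: {missing[:5]}")
    phyla = [by_id[m].name_at("phylum") or "Unclassified" for m in matrix.mag_ids]
    agg = pd.DataFrame(matrix.values, columns=phyla).T.groupby(level=0).sum().T
    eps = default_pseudocount(matrix) if pseudocount is None else float(pseudocount)
    rows = []
    for phylum in agg.columns:
        vals = agg[phylum].to_numpy()
        m1 = vals[binary_labels == 1].mean()
        m2 = vals[binary_labels == 2].mean()
        h, p = kw_test(vals, binary_labels)
        rows.append((phylum, float(np.log2((m2 + eps) / (m1 + eps))), h, p,
                     sum(ph == phylum for ph in phyla)))
    df = pd.DataFrame(rows, columns=["phylum", "log2_ratio", "H", "p", "mag_count"])
    df["q"] = bh_fdr(df["p"].to_numpy())
    df["assoc_class"] = [classify_mag(lr, qv, fold_threshold, alpha)
                         for lr, qv in zip(df["log2_ratio"], df["q"])]
    return df[["phylum", "log2_ratio", "H", "p", "q", "assoc_class", "mag_count"]]


def contamination_correlation(stats_df: pd.DataFrame,
                              records: Sequence[MagRecord]) -> tuple[float, float]:
    """Spearman correlation between MAG contamination and log2 ratio.

    Used as an artefact check: binning contamination should not predict
    state association.  A constant contamination vector makes the rank
    correlation undefined and raises rather than returning silent NaN.
    """
    by_id = {r.mag_id: r for r in records}
    mismatched = [m for m in stats_df["mag_id"] if m not in by_id]
    if mismatched:
        raise ValueError(f"stats MAGs without records: {mismatched[:5]}")
    contamination = np.array([by_id[m].contamination for m in stats_df["mag_id"]])
    log2r = stats_df["log2_ratio"].to_numpy()
    if np.all(contamination == contamination[0]) or np.all(log2r == log2r[0]):
        raise ValueError("constant input; Spearman correlation undefined")
    rho, p = stats.spearmanr(contamination, log2r)
    return float(rho), float(p)
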