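"""Functional enrichment between state-associated MAG classes.

Binary DRAM-distill traits are compared with 2x2 odds ratios and log-scale
Wald (Altman) confidence intervals; fractional module coverages are
compared with Kruskal-Wallis plus BH-FDR across modules.  Unassigned MAGs
take part in neither comparison.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .differential_abundance import CLUSTER1, CLUSTER2, bh_fdr, kw_test
from .io_formats import TraitTable

NEITHER = "NEITHER"

ENRICHMENT_COLUMNS = ["trait_id", "a", "b", "c", "d", "odds_ratio",
                      "ci_low", "ci_high", "enriched_in", "degenerate"]


def odds_ratio_ci(a: float, b: float, c: float, d: float,
                  level: float = 0.95) -> tuple[float, float, float]:
    """Odds ratio (a*d)/(b*c) with a log-scale Wald confidence interval.

    Any zero cell triggers the Haldane-Anscombe correction (0.5 added to
    every cell).  The interval is exp(ln OR +/- z * sqrt(1/a+1/b+1/c+1/d)).
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any():
        raise ValueError("negative cell count")
    if cells.sum() == 0:
        raise ValueError("empty 2x2 table")
    if (cells == 0).any():
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    or_ = (a_ * d_) / (b_ * c_)
    z = stats.norm.ppf(0.5 + level / 2)
    se = np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    return float(or_), float(or_ * np.exp(-z * se)), float(or_ * np.exp(z * se))


def trait_enrichment_table(traits: TraitTable, stats_df: pd.DataFrame,
                           level: float = 0.95,
                           ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Odds-ratio enrichment of every binary trait between MAG classes.

    Orientation: a = state-2-associated MAGs with the trait, so OR > 1
    means the trait favours state 2 (same direction as the log2 ratio).
    A trait is called enriched when the CI excludes 1; traits present in
    no MAG (or in every MAG of neither margin) are emitted as degenerate.
    """
    c2_ids = [m for m in stats_df.loc[stats_df["assoc_class"] == CLUSTER2, "mag_id"]
              if m in traits.binary.index]
    c1_ids = [m for m in stats_df.loc[stats_df["assoc_class"] == CLUSTER1, "mag_id"]
              if m in traits.binary.index]
    if not c1_ids or not c2_ids:
        raise ValueError("both MAG classes must be non-empty for enrichment")
    rows = []
    for trait in traits.binary.columns:
        a = int(traits.binary.loc[c2_ids, trait].sum())
        b = len(c2_ids) - a
        c = int(traits.binary.loc[c1_ids, trait].sum())
        d = len(c1_ids) - c
        degenerate = (a + c == 0) or (b + d == 0)
        or_, lo, hi = odds_ratio_ci(a, b, c, d, level=level)
        if degenerate:
            enriched = NEITHER
        elif lo > 1:
            enriched = CLUSTER2
        elif hi < 1:
            enriched = CLUSTER1
        else:
            enriched = NEITHER
        rows.append((trait, a, b, c, d, or_, lo, hi, enriched, degenerate))
    df = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)
    counts = {CLUSTER1: int((df["enriched_in"] == CLUSTER1).sum()),
              CLUSTER2: int((df["enriched_in"] == CLUSTER2).sum()),
              NEITHER: int((df["enriched_in"] == NEITHER).sum())}
    return df, counts


def module_coverage_comparison(traits: TraitTable, stats_df: pd.DataFrame,
                               alpha: float = 0.05) -> pd.DataFrame:
    """Kruskal-Wallis of module coverage between MAG classes, BH across modules."""
    c1_ids = [m for m in stats_df.loc[stats_df["assoc_class"] == CLUSTER1, "mag_id"]
              if m in traits.coverage.index]
    c2_ids = [m for m in stats_df.loc[stats_df["assoc_class"] == CLUSTER2, "mag_id"]
              if m in traits.coverage.index]
    if not c1_ids or not c2_ids:
        raise ValueError("both MAG classes must be non-empty for module comparison")
    rows = []
    for module in traits.coverage.columns:
        v1 = traits.coverage.loc[c1_ids, module].to_numpy(dtype=float)
        v2 = traits.coverage.loc[c2_ids, module].to_numpy(dtype=float)
        values = np.concatenate([v1, v2])
        groups = np.concatenate([np.ones_like(v1), 2 * np.ones_like(v2)])
        h, p = kw_test(values, groups)
        rows.append((module, float(v1.mean()), float(v2.mean()), h, p))
    df = pd.DataFrame(rows, columns=["module_id", "mean_cluster1", "mean_cluster2",
                                     "H", "p"])
    df["q"] = bh_fdr(df["p"].to_numpy())
    df["significant"] = df["q"] < alpha
    return df
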