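"""Physical/chemical covariates versus binary community state.

One Kruskal-Wallis test per covariate (depth, distance to aquaculture,
TOC, nitrogen, pH, redox), missing values dropped per covariate, raw
p-values by default (an optional BH toggle is available for callers who
prefer a corrected family).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .cluster_structure import ClusterAssignment
from .differential_abundance import bh_fdr, kw_test
from .io_formats import COVARIATE_COLUMNS, SiteRecord, sites_frame

RESULT_COLUMNS = ["covariate", "mean_c1", "mean_c2", "n1", "n2", "H", "p",
                  "significant", "insufficient"]


def covariate_tests(sites: Sequence[SiteRecord], assignment: ClusterAssignment,
                    covariates: Sequence[str] | None = None, alpha: float = 0.05,
                    min_per_cluster: int = 3, apply_fdr: bool = False,
                    ) -> pd.DataFrame:
    """Test each covariate for a distribution shift between the two states.

    Covariates with fewer than ``min_per_cluster`` values in either state
    are flagged insufficient (H and p left NaN) instead of tested.
    """
    if assignment.binary_labels is None:
        raise ValueError("assignment must be binarised first")
    if covariates is None:
        covariates = list(COVARIATE_COLUMNS)
    frame = sites_frame(sites).reindex(assignment.site_ids)
    unknown = [c for c in covariates if c not in frame.columns]
    if unknown:
        raise ValueError(f"unknown covariates: {unknown}")
    labels = np.asarray(assignment.binary_labels)
    rows = []
    for cov in covariates:
        vals = frame[cov].to_numpy(dtype=float)
        present = ~np.isnan(vals)
        v, g = vals[present], labels[present]
        n1, n2 = int((g == 1).sum()), int((g == 2).sum())
        mean1 = float(v[g == 1].mean()) if n1 else np.nan
        mean2 = float(v[g == 2].mean()) if n2 else np.nan
        if n1 < min_per_cluster or n2 < min_per_cluster:
            rows.append((cov, mean1, mean2, n1, n2, np.nan, np.nan, False, True))
            continue
        h, p = kw_test(v, g)
        rows.append((cov, mean1, mean2, n1, n2, h, p, p < alpha, False))
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if apply_fdr:
        tested = ~df["insufficient"]
        q = np.full(len(df), np.nan)
        q[tested.to_numpy()] = bh_fdr(df.loc[tested, "p"].to_numpy())
        df["q"] = q
        df["significant"] = df["q"] < alpha
    return df
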