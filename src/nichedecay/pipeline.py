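"""End-to-end orchestration: load -> filter -> ordinate -> cluster ->
differential abundance -> enrichment -> covariates -> decay.

``run_analysis`` is a pure function of (input files, config): identical
bytes in give identical tables out.  Every intermediate is written as TSV
and the run summary as JSON.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import (cluster_structure as cs, covariate_association as ca,
               differential_abundance as da, geospatial_decay as gd,
               io_formats as io, trait_enrichment as te)

logger = logging.getLogger("nichedecay")

DEFAULT_CONFIG: dict[str, Any] = {
    "inputs": {},  # abundance, mags, sites, traits_binary, module_coverage
    "renormalise": False,
    "filter": {"min_completeness": 75.0, "max_contamination": 25.0},
    "cluster": {"n_components": 2, "min_pts": 2, "eps": None},
    "stats": {"fold_threshold": 2.0, "alpha": 0.05, "pseudocount": None},
    "stages": {"enrichment": True, "covariates": True, "decay": True},
    "networks": [],
    "out_dir": "nichedecay_out",
}


def load_config(path: str | Path) -> dict[str, Any]:
    """Read a YAML or JSON config and merge it over the defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge_defaults(user)


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _merge_defaults(config: Mapping[str, Any]) -> dict[str, Any]:
    merged = {k: (dict(v) if isinstance(v, dict) else v)
              for k, v in DEFAULT_CONFIG.items()}
    for key, value in config.items():
        if isinstance(value, Mapping) and isinstance(merged.get(key), dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def run_analysis(config: Mapping[str, Any]) -> dict[str, Any]:
    """Execute the full analysis described by ``config`` (missing keys take
    the documented defaults); returns the run summary (also written to
    ``<out_dir>/run_summary.json``)."""
    config = _merge_defaults(config)
    inputs = config["inputs"]
    for name in ("abundance", "mags", "sites"):
        if name not in inputs:
            raise ValueError(f"config inputs missing {name!r}")
        if not Path(inputs[name]).exists():
            raise FileNotFoundError(f"input file for {name!r} not found: {inputs[name]}")
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {
        "config": {k: v for k, v in config.items()},
        "input_hashes": {k: _sha256(v) for k, v in inputs.items()
                         if Path(v).exists()},
        "warnings": [],
    }

    # --- load and filter -------------------------------------------------
    matrix = io.read_abundance(inputs["abundance"], renormalise=config["renormalise"])
    records = io.read_mags(inputs["mags"])
    sites = io.read_sites(inputs["sites"])
    kept = io.filter_mags(records, config["filter"]["min_completeness"],
                          config["filter"]["max_contamination"])
    kept_ids = {r.mag_id for r in kept}
    keep_cols = [j for j, m in enumerate(matrix.mag_ids) if m in kept_ids]
    if not keep_cols:
        raise ValueError("no MAGs pass the quality filter")
    matrix = io.AbundanceMatrix(
        matrix.site_ids, [matrix.mag_ids[j] for j in keep_cols],
        matrix.values[:, keep_cols], matrix.renormalised)
    summary["mags"] = {"loaded": len(records), "passing_filter": len(kept_ids),
                       "in_matrix": matrix.n_mags}
    summary["renormalised"] = bool(config["renormalise"])
    logger.info("loaded %d sites x %d MAGs (%d passed filter)",
                matrix.n_sites, matrix.n_mags, len(kept_ids))

    # --- ordination and clustering --------------------------------------
    ccfg = config["cluster"]
    model = cs.pca_fit(matrix, n_components=ccfg["n_components"])
    eps = ccfg.get("eps")
    if eps is None:
        eps = cs.auto_eps(model.scores, min_pts=ccfg["min_pts"])
    assignment = cs.dbscan(model.scores, eps=eps, min_pts=ccfg["min_pts"],
                           site_ids=matrix.site_ids)
    model = cs.orient_signs(model, assignment.raw_labels)
    assignment = cs.binarise(assignment)
    raw_sizes = {int(l): int((assignment.raw_labels == l).sum())
                 for l in np.unique(assignment.raw_labels)}
    n1 = int((assignment.binary_labels == 1).sum())
    n2 = int((assignment.binary_labels == 2).sum())
    summary["clustering"] = {
        "eps_used": float(eps), "min_pts": ccfg["min_pts"],
        "raw_cluster_sizes": raw_sizes,
        "n_outliers": raw_sizes.get(io.OUTLIER, 0),
        "cluster_sizes": {"1": n1, "2": n2},
        "cluster1_fraction": n1 / matrix.n_sites,
        "explained_variance_fraction": model.explained_variance_fraction.tolist(),
    }
    ellipses = {}
    for lab in (1, 2):
        pts = model.scores[assignment.members(lab), :2]
        try:
            ell = cs.confidence_ellipse(pts)
            ellipses[str(lab)] = {"center": ell.center.tolist(), "axes": list(ell.axes),
                                  "angle": ell.angle, "level": ell.level}
        except ValueError as exc:
            summary["warnings"].append(f"ellipse for cluster {lab}: {exc}")
    summary["ellipses"] = ellipses

    scores_df = pd.DataFrame(
        model.scores, columns=[f"PC{i + 1}" for i in range(model.scores.shape[1])])
    scores_df.insert(0, "site_id", matrix.site_ids)
    io.write_stats_table(scores_df, out_dir / "pca_scores.tsv")
    assign_df = pd.DataFrame({
        "site_id": assignment.site_ids,
        "raw_label": assignment.raw_labels,
        "binary_label": assignment.binary_labels,
    })
    io.write_stats_table(assign_df, out_dir / "assignment.tsv")

    networks = config.get("networks") or []
    summary["network_association"] = {}
    for network in networks:
        try:
            h, p = cs.network_association(assignment, sites, network)
            summary["network_association"][network] = {"H": h, "p": p}
        except ValueError as exc:
            summary["warnings"].append(f"network {network!r}: {exc}")

    # --- differential abundance -----------------------------------------
    scfg = config["stats"]
    stats_df, class_counts = da.volcano_table(
        matrix, assignment.binary_labels, fold_threshold=scfg["fold_threshold"],
        alpha=scfg["alpha"], pseudocount=scfg["pseudocount"])
    io.write_stats_table(stats_df, out_dir / "volcano.tsv")
    phylum_df = da.phylum_volcano(matrix, records, assignment.binary_labels,
                                  fold_threshold=scfg["fold_threshold"],
                                  alpha=scfg["alpha"], pseudocount=scfg["pseudocount"])
    io.write_stats_table(phylum_df, out_dir / "phylum_volcano.tsv")
    summary["mag_classes"] = class_counts
    try:
        rho, p = da.contamination_correlation(stats_df, records)
        summary["contamination_correlation"] = {"rho": rho, "p": p}
    except ValueError as exc:
        summary["warnings"].append(f"contamination correlation: {exc}")

    # --- trait enrichment (optional stage) ------------------------------
    stages = config["stages"]
    if stages.get("enrichment") and "traits_binary" in inputs:
        traits = io.read_traits(inputs["traits_binary"], inputs["module_coverage"])
        enrich_df, enrich_counts = te.trait_enrichment_table(traits, stats_df)
        io.write_stats_table(enrich_df, out_dir / "trait_enrichment.tsv")
        module_df = te.module_coverage_comparison(traits, stats_df,
                                                  alpha=scfg["alpha"])
        io.write_stats_table(module_df, out_dir / "module_comparison.tsv")
        n_degenerate = int(enrich_df["degenerate"].sum())
        if n_degenerate:
            summary["warnings"].append(f"{n_degenerate} degenerate traits")
        summary["trait_enrichment"] = {
            "enriched_counts": enrich_counts,
            "significant_modules": int(module_df["significant"].sum()),
        }
    else:
        logger.info("trait enrichment skipped")
        summary["trait_enrichment"] = None

    # --- covariates (optional stage) ------------------------------------
    if stages.get("covariates"):
        cov_df = ca.covariate_tests(sites, assignment, alpha=scfg["alpha"])
        io.write_stats_table(cov_df, out_dir / "covariates.tsv")
        summary["covariates"] = {
            row.covariate: {"p": None if np.isnan(row.p) else float(row.p),
                            "mean_c1": row.mean_c1, "mean_c2": row.mean_c2}
            for row in cov_df.itertuples()}
    else:
        summary["covariates"] = None

    # --- distance decay (optional stage) --------------------------------
    if stages.get("decay"):
        by_id = {s.site_id: s for s in sites}
        ordered = [by_id[sid] for sid in matrix.site_ids]
        dists = gd.pairwise_distances(ordered)
        decay_df = gd.decay_table(matrix, dists, assignment)
        io.write_stats_table(decay_df, out_dir / "decay.tsv")
        summary_df = gd.decay_by_class(decay_df, stats_df)
        io.write_stats_table(summary_df, out_dir / "decay_summary.tsv")
        nearest = gd.nearest_other_cluster(sites, assignment)
        io.write_stats_table(nearest, out_dir / "nearest_other_cluster.tsv")
        n_undef = int((~decay_df["defined"]).sum())
        if n_undef:
            summary["warnings"].append(f"{n_undef} undefined decay correlations")
        summary["decay"] = {
            "by_class": summary_df.to_dict(orient="records"),
            "vs_logratio": {},
        }
        for subset in (gd.SUBSET_CLUSTER1, gd.SUBSET_CLUSTER2):
            corr = gd.decay_vs_logratio(decay_df, stats_df, subset)
            summary["decay"]["vs_logratio"][subset] = {
                "rho": None if not corr.defined else corr.rho,
                "p": None if not corr.defined else corr.p,
                "n_mags": corr.n_mags}
    else:
        summary["decay"] = None

    io.write_run_summary(summary, out_dir / "run_summary.json")
    return summary


def run_simulate(config_path: str | Path | None = None, seed: int | None = None,
                 out_dir: str | Path = "nichedecay_sim", **overrides):
    """Generate a synthetic bundle from a YAML/JSON config file or kwargs."""
    from .synthetic_data import SimulationConfig, generate_bundle

    kwargs: dict[str, Any] = {}
    if config_path is not None:
        with open(config_path) as fh:
            kwargs.update(yaml.safe_load(fh) or {})
    if seed is not None:
        kwargs["seed"] = seed
    kwargs.update(overrides)
    if "seed" not in kwargs:
        raise ValueError("a seed is required")
    sim_config = SimulationConfig(**kwargs)
    bundle, truth = generate_bundle(sim_config, out_dir=out_dir)
    logger.info("bundle written to %s (config: %s)", out_dir, asdict(sim_config))
    return bundle, truth
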