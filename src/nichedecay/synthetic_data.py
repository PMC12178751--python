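"""Synthetic input bundles with planted ecological structure.

The generator emulates the derived data of a two-state coastal seafloor
survey: sites strung along a long mainland coast plus a distant island
patch, two community states (the island holds only the minority state),
and three kinds of MAGs:

* ``CENTRAL_1`` / ``CENTRAL_2`` — niche-selected cosmopolitan MAGs whose
  log abundance gains ``ln(selection_fold)`` in their own state.  Within
  own-state sites their residuals are iid (no spatial structure: selection
  overrides dispersal), while at other-state sites — where no positive
  selection acts — residuals follow the same spatially autocorrelated
  field as neutral MAGs, so they show distance decay exactly where they
  are underrepresented.
* ``NEUTRAL`` — dispersal-limited MAGs whose log abundance is a Gaussian
  field with exponential covariance ``exp(-d_ij / L)`` over great-circle
  distances, producing distance decay everywhere.

Binary traits are planted with a chosen odds ratio between the two
central classes, module coverages with a mean shift, and covariates with
state effects (deeper state-1 sites; organically enriched, higher-pH
state-2 sites; null redox).  Every draw flows through one seeded
generator, so a seed fully determines the bundle on disk.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geospatial_decay import haversine_km, pairwise_distances
from .io_formats import (AbundanceMatrix, Lineage, MagRecord, RANKS, SiteRecord,
                         TraitTable, format_gtdb_lineage, parse_gtdb_lineage,
                         write_abundance, write_mags, write_sites, write_traits)

CENTRAL_1 = "CENTRAL_1"
CENTRAL_2 = "CENTRAL_2"
NEUTRAL = "NEUTRAL"

#: Waypoints (lat, lon) of the mainland coast segment, south to north.
MAINLAND_COAST = ((58.0, 6.5), (59.0, 5.5), (60.5, 5.0), (62.0, 5.5),
                  (63.5, 8.5), (64.5, 11.0), (66.0, 12.5), (67.5, 14.5),
                  (68.7, 16.5), (69.7, 19.0), (70.5, 23.0), (71.0, 26.0))

#: Bounding box (lat_min, lat_max, lon_min, lon_max) of the island patch.
ISLAND_PATCH = (64.3, 66.0, -23.5, -18.0)

#: DRAM-distill-style binary module catalogue: family -> module count.
DEFAULT_BINARY_CATALOG = {
    "polysaccharide_degradation": 19,
    "nitrogen_metabolism": 12,
    "sulphur_metabolism": 4,
    "methanogenesis_methanotrophy": 11,
    "scfa_alcohol_conversion": 13,
    "other_reductases": 5,
}

#: Fractional-coverage catalogue (pathways and electron-transport complexes).
DEFAULT_COVERAGE_CATALOG = {
    "metabolic_pathway": 13,
    "electron_transport": 5,
}

# (state1, state2, sigma, family): lognormal params are medians, normal are means
DEFAULT_COVARIATE_EFFECTS = {
    "depth": (150.0, 60.0, 0.35, "lognormal"),
    "toc": (12.0, 28.0, 0.40, "lognormal"),
    "nitrogen": (1.2, 2.6, 0.40, "lognormal"),
    "ph": (7.3, 7.6, 0.15, "normal"),
    "redox": (40.0, 40.0, 80.0, "normal"),
    "farm_distance": (1100.0, 700.0, 0.80, "lognormal"),
}

DEFAULT_NETWORK_EFFECTS = {
    "Nitrosopumilus": (0.42, 0.18, 0.07),
    "Sulfurovum": (0.12, 0.35, 0.07),
}

_LINEAGE_POOL = {
    CENTRAL_1: (
        ("d__Archaea;p__Thermoproteota;c__Nitrososphaeria", 0.40),
        ("d__Bacteria;p__Proteobacteria;c__Gammaproteobacteria", 0.35),
        ("d__Bacteria;p__Actinomycetota;c__Acidimicrobiia", 0.25),
    ),
    CENTRAL_2: (
        ("d__Bacteria;p__Campylobacterota;c__Campylobacteria", 0.40),
        ("d__Bacteria;p__Bacteroidota;c__Bacteroidia", 0.35),
        ("d__Bacteria;p__Proteobacteria;c__Gammaproteobacteria", 0.25),
    ),
    NEUTRAL: (
        ("d__Bacteria;p__Proteobacteria;c__Alphaproteobacteria", 0.30),
        ("d__Bacteria;p__Desulfobacterota;c__Desulfobacteria", 0.30),
        ("d__Bacteria;p__Planctomycetota;c__Planctomycetia", 0.20),
        ("d__Bacteria;p__Chloroflexota;c__Anaerolineae", 0.20),
    ),
}


@dataclass
class SimulationConfig:
    """All dials of the generator; a seed is mandatory."""

    seed: int
    n_sites: int = 94
    n_island_sites: int = 8
    state1_probability: float = 0.69
    n_central_1: int = 150
    n_central_2: int = 150
    n_neutral: int = 56
    n_mainland_groups: int = 18
    selection_fold: float = 8.0
    overdispersion: float = 1.0  # lognormal sigma of per-site residuals
    spatial_correlation_km: float = 200.0  # exponential covariance length; <= 0 = iid
    coordinate_jitter_deg: float = 0.08
    binary_catalog: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_BINARY_CATALOG))
    coverage_catalog: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_COVERAGE_CATALOG))
    planted_trait_or: float = 8.0
    trait_baseline_p: float = 0.4
    n_enriched_traits_c1: int = 6
    n_enriched_traits_c2: int = 19
    module_mean_shift: float = 0.2  # class means 0.5 -/+ shift for shifted modules
    n_shifted_modules_c1: int = 3
    n_shifted_modules_c2: int = 5
    module_concentration: float = 10.0
    covariate_effects: dict[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    network_effects: dict[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_NETWORK_EFFECTS))

    def __post_init__(self) -> None:
        if not (0 < self.state1_probability < 1):
            raise ValueError("state1_probability must be in (0, 1)")
        for name in ("n_sites", "n_central_1", "n_central_2", "n_neutral"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.n_island_sites < self.n_sites):
            raise ValueError("n_island_sites must be in [0, n_sites)")
        if self.selection_fold < 1:
            raise ValueError("selection_fold must be >= 1")

    @property
    def n_mags(self) -> int:
        return self.n_central_1 + self.n_central_2 + self.n_neutral

    @classmethod
    def null(cls, seed: int, **overrides) -> "SimulationConfig":
        """All effects off: no selection, no trait/module/covariate/network
        effects, iid residuals — the calibration target for false-call rates."""
        null_cov = {name: (p1, p1, sigma, fam)
                    for name, (p1, _, sigma, fam) in DEFAULT_COVARIATE_EFFECTS.items()}
        null_net = {name: (m1, m1, sd)
                    for name, (m1, _, sd) in DEFAULT_NETWORK_EFFECTS.items()}
        kwargs = dict(seed=seed, selection_fold=1.0, planted_trait_or=1.0,
                      module_mean_shift=0.0, spatial_correlation_km=0.0,
                      covariate_effects=null_cov, network_effects=null_net)
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class SimulationTruth:
    """Planted ground truth accompanying a generated bundle."""

    site_states: pd.Series  # site_id -> 1 or 2
    mag_classes: pd.Series  # mag_id -> CENTRAL_1 | CENTRAL_2 | NEUTRAL
    trait_or: pd.DataFrame  # trait_id, true_or (state-2 class in the numerator)
    module_shift: pd.DataFrame  # module_id, mean_c1, mean_c2


def _clip01(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, 1.0)


def _coast_points(n: int, n_groups: int, rng: np.random.Generator,
                  jitter: float) -> np.ndarray:
    """Random points in sampling groups along the mainland polyline.

    Monitoring surveys sample several stations within a few km of each
    facility, so sites come in local groups whose centres are spread
    arc-length-uniformly along the coast; within a group, sites scatter by
    ``jitter`` degrees (order 10 km), putting many site pairs at
    within-group distances while groups remain 10s-100s of km apart.
    """
    wp = np.array(MAINLAND_COAST)
    seg = np.array([haversine_km(wp[i, 0], wp[i, 1], wp[i + 1, 0], wp[i + 1, 1])
                    for i in range(len(wp) - 1)])
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    pos = np.sort(rng.uniform(0, cum[-1], size=n_groups))
    idx = np.clip(np.searchsorted(cum, pos, side="right") - 1, 0, len(seg) - 1)
    frac = (pos - cum[idx]) / seg[idx]
    centres = wp[idx] + frac[:, None] * (wp[idx + 1] - wp[idx])
    membership = rng.integers(0, n_groups, size=n)
    return centres[membership] + rng.normal(0, jitter, size=(n, 2))


def generate_sites(config: SimulationConfig,
                   rng: np.random.Generator | None = None,
                   ) -> tuple[list[SiteRecord], np.ndarray]:
    """Draw site coordinates, true states, covariates and network fractions.

    Island sites are forced to state 2 regardless of state1_probability;
    mainland states are iid Bernoulli.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_main = config.n_sites - config.n_island_sites
    coast = _coast_points(n_main, config.n_mainland_groups, rng,
                          config.coordinate_jitter_deg)
    lat_min, lat_max, lon_min, lon_max = ISLAND_PATCH
    island = np.column_stack([rng.uniform(lat_min, lat_max, config.n_island_sites),
                              rng.uniform(lon_min, lon_max, config.n_island_sites)])
    coords = np.vstack([coast, island])
    states = np.where(rng.random(config.n_sites) < config.state1_probability, 1, 2)
    states[n_main:] = 2  # the island holds only the minority state
    width = len(str(config.n_sites))
    records = []
    cov_draws = {}
    for name, (p1, p2, sigma, fam) in config.covariate_effects.items():
        loc = np.where(states == 1, p1, p2).astype(float)
        if fam == "lognormal":
            cov_draws[name] = loc * np.exp(rng.normal(0, sigma, config.n_sites))
        else:
            cov_draws[name] = loc + rng.normal(0, sigma, config.n_sites)
    net_draws = {}
    for name, (m1, m2, sd) in config.network_effects.items():
        loc = np.where(states == 1, m1, m2).astype(float)
        net_draws[name] = _clip01(loc + rng.normal(0, sd, config.n_sites))
    for i in range(config.n_sites):
        records.append(SiteRecord(
            site_id=f"S{i + 1:0{width}d}",
            lat=float(np.clip(coords[i, 0], -90, 90)),
            lon=float(np.clip(coords[i, 1], -180, 180)),
            depth=float(max(cov_draws["depth"][i], 1.0)),
            toc=float(cov_draws["toc"][i]),
            nitrogen=float(cov_draws["nitrogen"][i]),
            ph=float(cov_draws["ph"][i]),
            redox=float(cov_draws["redox"][i]),
            farm_distance=float(max(cov_draws["farm_distance"][i], 0.0)),
            network_fractions={name: float(net_draws[name][i]) for name in net_draws},
        ))
    return records, states


def _spatial_factor(sites: Sequence[SiteRecord], length_km: float) -> np.ndarray:
    """Cholesky factor of the exponential-covariance kernel over the sites."""
    n = len(sites)
    if length_km <= 0:
        return np.eye(n)
    dists = pairwise_distances(sites).values
    cov = np.exp(-dists / length_km) + 1e-8 * np.eye(n)
    return np.linalg.cholesky(cov)


def generate_abundances(config: SimulationConfig, sites: Sequence[SiteRecord],
                        states: np.ndarray,
                        rng: np.random.Generator | None = None,
                        ) -> tuple[AbundanceMatrix, list[str]]:
    """Draw the relative-abundance matrix and the true per-MAG classes."""
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n = len(sites)
    classes = ([CENTRAL_1] * config.n_central_1 + [CENTRAL_2] * config.n_central_2
               + [NEUTRAL] * config.n_neutral)
    mag_ids = [f"MAG{j + 1:04d}" for j in range(len(classes))]
    chol = _spatial_factor(sites, config.spatial_correlation_km)
    sigma = config.overdispersion
    log_fold = np.log(config.selection_fold)
    log_abund = np.empty((n, len(classes)))
    for j, cls in enumerate(classes):
        field_resid = chol @ rng.normal(0, 1, size=n)
        iid_resid = rng.normal(0, 1, size=n)
        if cls == NEUTRAL:
            resid = field_resid
            boost = 0.0
        else:
            own = states == (1 if cls == CENTRAL_1 else 2)
            # selection overrides dispersal in the selected niche (iid there);
            # elsewhere the MAG drifts like a neutral one (spatial field)
            resid = np.where(own, iid_resid, field_resid)
            boost = log_fold * own
        log_abund[:, j] = boost + sigma * resid
    raw = np.exp(log_abund)
    values = raw / raw.sum(axis=1, keepdims=True)
    matrix = AbundanceMatrix([s.site_id for s in sites], mag_ids, values,
                             renormalised=True)
    return matrix, classes


def generate_mag_records(config: SimulationConfig, classes: Sequence[str],
                         rng: np.random.Generator | None = None) -> list[MagRecord]:
    """Lineages drawn from class-typical pools; completeness ~ U[75,100] and
    contamination ~ U[0,25) independent of class (a true-null artefact check)."""
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    records = []
    for j, cls in enumerate(classes):
        pool = _LINEAGE_POOL[cls]
        weights = np.array([w for _, w in pool])
        pick = rng.choice(len(pool), p=weights / weights.sum())
        records.append(MagRecord(
            mag_id=f"MAG{j + 1:04d}",
            lineage=parse_gtdb_lineage(pool[pick][0]),
            completeness=float(rng.uniform(75, 100)),
            contamination=float(rng.uniform(0, 25)),
        ))
    return records


def _odds_to_p(odds: float) -> float:
    return odds / (1 + odds)


def generate_traits(config: SimulationConfig, classes: Sequence[str],
                    rng: np.random.Generator | None = None,
                    ) -> tuple[TraitTable, pd.DataFrame, pd.DataFrame]:
    """Draw binary traits with planted odds ratios and Beta module coverages.

    The planted odds ratio is split symmetrically on the log-odds scale
    around the baseline presence probability, so both class probabilities
    stay away from the {0,1} boundary.  Returns the trait table plus the
    per-trait and per-module truth frames.
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    mag_ids = [f"MAG{j + 1:04d}" for j in range(len(classes))]
    cls_arr = np.array(classes)

    trait_ids = [f"{family}_{i + 1:02d}"
                 for family, count in config.binary_catalog.items()
                 for i in range(count)]
    n_traits = len(trait_ids)
    n_c2, n_c1 = config.n_enriched_traits_c2, config.n_enriched_traits_c1
    if n_c1 + n_c2 > n_traits:
        raise ValueError("more enriched traits requested than the catalogue holds")
    order = rng.permutation(n_traits)
    toward_c2 = set(order[:n_c2])
    toward_c1 = set(order[n_c2:n_c2 + n_c1])

    base_odds = config.trait_baseline_p / (1 - config.trait_baseline_p)
    root = np.sqrt(config.planted_trait_or)
    presence = np.zeros((len(classes), n_traits), dtype=int)
    truth_rows = []
    for t in range(n_traits):
        if t in toward_c2:
            p1, p2, true_or = (_odds_to_p(base_odds / root), _odds_to_p(base_odds * root),
                               config.planted_trait_or)
        elif t in toward_c1:
            p1, p2, true_or = (_odds_to_p(base_odds * root), _odds_to_p(base_odds / root),
                               1 / config.planted_trait_or)
        else:
            p1 = p2 = config.trait_baseline_p
            true_or = 1.0
        p = np.where(cls_arr == CENTRAL_1, p1,
                     np.where(cls_arr == CENTRAL_2, p2, config.trait_baseline_p))
        presence[:, t] = rng.random(len(classes)) < p
        truth_rows.append((trait_ids[t], true_or))
    binary = pd.DataFrame(presence, index=pd.Index(mag_ids, name="mag_id"),
                          columns=trait_ids)

    module_ids = [f"{family}_{i + 1:02d}"
                  for family, count in config.coverage_catalog.items()
                  for i in range(count)]
    n_modules = len(module_ids)
    m_order = rng.permutation(n_modules)
    m_toward_c2 = set(m_order[:config.n_shifted_modules_c2])
    m_toward_c1 = set(m_order[config.n_shifted_modules_c2:
                              config.n_shifted_modules_c2 + config.n_shifted_modules_c1])
    shift = config.module_mean_shift
    conc = config.module_concentration
    coverage = np.zeros((len(classes), n_modules))
    module_rows = []
    for t in range(n_modules):
        if t in m_toward_c2:
            mean1, mean2 = 0.5 - shift, 0.5 + shift
        elif t in m_toward_c1:
            mean1, mean2 = 0.5 + shift, 0.5 - shift
        else:
            mean1 = mean2 = 0.5
        mean = np.where(cls_arr == CENTRAL_1, mean1,
                        np.where(cls_arr == CENTRAL_2, mean2, 0.5))
        coverage[:, t] = rng.beta(mean * conc, (1 - mean) * conc)
        module_rows.append((module_ids[t], mean1, mean2))
    cov_df = pd.DataFrame(coverage, index=pd.Index(mag_ids, name="mag_id"),
                          columns=module_ids)
    return (TraitTable(binary=binary, coverage=cov_df),
            pd.DataFrame(truth_rows, columns=["trait_id", "true_or"]),
            pd.DataFrame(module_rows, columns=["module_id", "mean_c1", "mean_c2"]))


def generate_bundle(config: SimulationConfig, out_dir: str | Path | None = None,
                    ) -> tuple[dict, SimulationTruth]:
    """Generate a full input bundle (optionally written to ``out_dir``).

    Returns the in-memory objects plus the planted truth; when ``out_dir``
    is given every table the pipeline reads is written there as TSV along
    with the truth tables and a JSON echo of the configuration.  The same
    seed always yields byte-identical files.
    """
    rng = np.random.default_rng(config.seed)
    sites, states = generate_sites(config, rng)
    matrix, classes = generate_abundances(config, sites, states, rng)
    records = generate_mag_records(config, classes, rng)
    traits, trait_truth, module_truth = generate_traits(config, classes, rng)
    truth = SimulationTruth(
        site_states=pd.Series(states, index=[s.site_id for s in sites], name="state"),
        mag_classes=pd.Series(classes, index=matrix.mag_ids, name="true_class"),
        trait_or=trait_truth,
        module_shift=module_truth,
    )
    bundle = {"sites": sites, "states": states, "matrix": matrix,
              "mag_records": records, "traits": traits}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_abundance(matrix, out / "abundance.tsv")
        write_mags(records, out / "mags.tsv")
        write_sites(sites, out / "sites.tsv")
        write_traits(traits, out / "traits_binary.tsv", out / "module_coverage.tsv")
        truth.site_states.rename_axis("site_id").reset_index().to_csv(
            out / "truth_sites.tsv", sep="\t", index=False)
        truth.mag_classes.rename_axis("mag_id").reset_index().to_csv(
            out / "truth_mags.tsv", sep="\t", index=False)
        truth.trait_or.to_csv(out / "truth_traits.tsv", sep="\t", index=False)
        truth.module_shift.to_csv(out / "truth_modules.tsv", sep="\t", index=False)
        cfg = dataclasses.asdict(config)
        (out / "config.json").write_text(json.dumps(cfg, indent=2, sort_keys=True) + "\n")
        bundle["paths"] = {name: str(out / f"{name}.tsv") for name in
                           ("abundance", "mags", "sites", "traits_binary",
                            "module_coverage")}
    return bundle, truth
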