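"""Readers, writers and validators for the tabular artifacts of the pipeline.

All tables are tab-delimited UTF-8 with ``.`` as the decimal separator.
Floats are written with :func:`repr`-style formatting, so every
write-then-read round trip reproduces values bit-exactly.

Missing optional site fields are empty cells and surface as explicit
``None`` / absent keys — never as zero, because 0 is a real value for
e.g. redox potential.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: DBSCAN noise label used throughout the package.
OUTLIER = -1

#: The seven GTDB ranks, domain to species.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

_RANK_PREFIX = {"d": "domain", "p": "phylum", "c": "class", "o": "order",
                "f": "family", "g": "genus", "s": "species"}

#: Site-table columns holding physical/chemical covariates.
COVARIATE_COLUMNS = ("depth", "toc", "nitrogen", "ph", "redox", "farm_distance")

_NETWORK_PREFIX = "network_"


class TableFormatError(ValueError):
    """A table violated its schema or an invariant of its domain type."""


@dataclass
class Lineage:
    """One taxonomic rank of a GTDB lineage; ``name`` may be empty."""

    rank: str
    name: str


@dataclass
class MagRecord:
    """Quality and taxonomy metadata for one metagenome-assembled genome."""

    mag_id: str
    lineage: tuple[Lineage, ...]
    completeness: float  # percent, [0, 100]
    contamination: float  # percent, >= 0

    def name_at(self, rank: str) -> str:
        for entry in self.lineage:
            if entry.rank == rank:
                return entry.name
        raise KeyError(rank)


@dataclass
class SiteRecord:
    """One sampling site: coordinates plus optional covariates.

    Optional fields are ``None`` when absent; ``network_fractions`` maps a
    co-occurrence-network name to the fraction of 16S reads it holds.
    """

    site_id: str
    lat: float
    lon: float
    depth: float | None = None
    toc: float | None = None
    nitrogen: float | None = None
    ph: float | None = None
    redox: float | None = None
    farm_distance: float | None = None
    network_fractions: dict[str, float] = field(default_factory=dict)


@dataclass
class AbundanceMatrix:
    """Sites x MAGs relative-abundance matrix, rows summing to at most 1."""

    site_ids: list[str]
    mag_ids: list[str]
    values: np.ndarray  # shape (n_sites, n_mags)
    renormalised: bool = False

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_mags(self) -> int:
        return len(self.mag_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.site_ids, name="site_id"),
                            columns=self.mag_ids)

    def column(self, mag_id: str) -> np.ndarray:
        return self.values[:, self.mag_ids.index(mag_id)]


@dataclass
class TraitTable:
    """DRAM-distill style functional content per MAG.

    ``binary`` holds strict 0/1 module presence (MAGs x traits);
    ``coverage`` holds pathway/complex coverage fractions in [0, 1]
    (MAGs x modules).
    """

    binary: pd.DataFrame
    coverage: pd.DataFrame


def _check_unique(ids: Iterable[str], what: str) -> None:
    ids = list(ids)
    seen: set[str] = set()
    dupes = sorted({i for i in ids if i in seen or seen.add(i)})  # type: ignore[func-returns-value]
    if dupes:
        raise TableFormatError(f"duplicate {what}: {dupes[:5]}")


def validate_abundance(matrix: AbundanceMatrix) -> None:
    """Raise :class:`TableFormatError` if any invariant is violated."""
    _check_unique(matrix.site_ids, "site ids")
    _check_unique(matrix.mag_ids, "MAG ids")
    if matrix.values.shape != (matrix.n_sites, matrix.n_mags):
        raise TableFormatError("value shape does not match id lists")
    neg = np.argwhere(matrix.values < 0)
    if neg.size:
        i, j = neg[0]
        raise TableFormatError(
            f"negative abundance at site {matrix.site_ids[i]!r}, MAG {matrix.mag_ids[j]!r}")
    sums = matrix.values.sum(axis=1)
    bad = np.where((sums <= 0) | (sums > 1 + 1e-6))[0]
    if bad.size:
        i = bad[0]
        raise TableFormatError(
            f"row sum {sums[i]:.6g} for site {matrix.site_ids[i]!r} outside (0, 1]")


def read_abundance(path: str | Path, renormalise: bool = False) -> AbundanceMatrix:
    """Load a site x MAG relative-abundance TSV.

    The first column holds site ids, the header row MAG ids.  With
    ``renormalise`` each row is divided by its sum so it sums to exactly 1;
    otherwise row sums must already lie in (0, 1 + 1e-6].
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_unique(header[1:], "MAG ids")  # pandas would mangle duplicates
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    site_ids = [str(s) for s in df.index]
    mag_ids = [str(m) for m in df.columns]
    _check_unique(site_ids, "site ids")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise TableFormatError(
            f"non-numeric/missing cell at site {site_ids[i]!r}, MAG {mag_ids[j]!r}")
    neg = np.argwhere(values < 0)
    if neg.size:
        i, j = neg[0]
        raise TableFormatError(
            f"negative abundance at site {site_ids[i]!r}, MAG {mag_ids[j]!r}")
    if renormalise:
        sums = values.sum(axis=1)
        zero = np.where(sums <= 0)[0]
        if zero.size:
            raise TableFormatError(f"site {site_ids[zero[0]]!r} has zero total abundance")
        values = values / sums[:, None]
    matrix = AbundanceMatrix(site_ids, mag_ids, values, renormalised=renormalise)
    validate_abundance(matrix)
    return matrix


def write_abundance(matrix: AbundanceMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t")


def parse_gtdb_lineage(text: str) -> tuple[Lineage, ...]:
    """Parse a GTDB lineage string like ``d__Bacteria;p__Proteobacteria;...``.

    Always returns 7 entries (domain..species); ranks missing from the
    string get empty names.  Prefixes must appear in rank order.
    """
    entries = {rank: "" for rank in RANKS}
    parts = [p.strip() for p in text.split(";")] if text.strip() else []
    last_idx = -1
    for part in parts:
        if part == "":
            continue
        if len(part) < 3 or part[1:3] != "__" or part[0] not in _RANK_PREFIX:
            raise TableFormatError(f"unknown rank prefix in lineage part {part!r}")
        rank = _RANK_PREFIX[part[0]]
        idx = RANKS.index(rank)
        if idx <= last_idx:
            raise TableFormatError(f"lineage ranks out of order at {part!r}")
        last_idx = idx
        entries[rank] = part[3:]
    return tuple(Lineage(rank, entries[rank]) for rank in RANKS)


def format_gtdb_lineage(lineage: Sequence[Lineage]) -> str:
    return ";".join(f"{rank[0]}__{entry.name}" for rank, entry in zip(RANKS, lineage))


def filter_mags(records: Sequence[MagRecord],
                min_completeness: float = 75.0,
                max_contamination: float = 25.0) -> list[MagRecord]:
    """Keep MAGs with completeness >= threshold and contamination strictly
    below threshold (inclusive/exclusive boundaries deliberate)."""
    return [r for r in records
            if r.completeness >= min_completeness and r.contamination < max_contamination]


def read_mags(path: str | Path) -> list[MagRecord]:
    """Read a MAG metadata TSV: mag_id, lineage, completeness, contamination."""
    df = pd.read_csv(path, sep="\t", dtype={"mag_id": str, "lineage": str},
                     float_precision="round_trip")
    for col in ("mag_id", "lineage", "completeness", "contamination"):
        if col not in df.columns:
            raise TableFormatError(f"MAG table missing column {col!r}")
    _check_unique(df["mag_id"], "MAG ids")
    records = []
    for row in df.itertuples(index=False):
        completeness = float(row.completeness)
        contamination = float(row.contamination)
        if not (0 <= completeness <= 100):
            raise TableFormatError(f"completeness {completeness} out of [0,100] for {row.mag_id}")
        if contamination < 0:
            raise TableFormatError(f"negative contamination for {row.mag_id}")
        lineage_str = "" if pd.isna(row.lineage) else str(row.lineage)
        records.append(MagRecord(str(row.mag_id), parse_gtdb_lineage(lineage_str),
                                 completeness, contamination))
    return records


def write_mags(records: Sequence[MagRecord], path: str | Path) -> None:
    df = pd.DataFrame({
        "mag_id": [r.mag_id for r in records],
        "lineage": [format_gtdb_lineage(r.lineage) for r in records],
        "completeness": [r.completeness for r in records],
        "contamination": [r.contamination for r in records],
    })
    df.to_csv(path, sep="\t", index=False)


def taxonomic_summary(matrix: AbundanceMatrix, records: Sequence[MagRecord],
                      level: str) -> pd.DataFrame:
    """Aggregate MAG counts and mean relative abundance per taxon at ``level``.

    Only MAGs with a non-empty name at that rank contribute; the returned
    frame has columns taxon, mean_abundance, mag_count and conserves both
    the MAG count and the summed abundance of the named MAGs.
    """
    if level not in RANKS:
        raise TableFormatError(f"unknown rank {level!r}")
    by_id = {r.mag_id: r for r in records}
    missing = [m for m in matrix.mag_ids if m not in by_id]
    if missing:
        raise TableFormatError(f"MAGs without metadata record: {missing[:5]}")
    groups: dict[str, list[int]] = {}
    for j, mag_id in enumerate(matrix.mag_ids):
        name = by_id[mag_id].name_at(level)
        if name:
            groups.setdefault(name, []).append(j)
    rows = [(taxon, float(matrix.values[:, cols].sum(axis=1).mean()), len(cols))
            for taxon, cols in sorted(groups.items())]
    return pd.DataFrame(rows, columns=["taxon", "mean_abundance", "mag_count"])


def read_sites(path: str | Path) -> list[SiteRecord]:
    """Read the site metadata TSV.

    Required columns: site_id, lat, lon.  Optional: the covariates in
    :data:`COVARIATE_COLUMNS` and any number of ``network_<name>`` columns
    with 16S read fractions.  Empty cells mean the value is absent.
    """
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str},
                     float_precision="round_trip")
    for col in ("site_id", "lat", "lon"):
        if col not in df.columns:
            raise TableFormatError(f"site table missing column {col!r}")
    _check_unique(df["site_id"], "site ids")
    network_cols = [c for c in df.columns if c.startswith(_NETWORK_PREFIX)]
    records = []
    for _, row in df.iterrows():
        lat, lon = float(row["lat"]), float(row["lon"])
        if not (-90 <= lat <= 90) or not (-180 <= lon <= 180):
            raise TableFormatError(f"coordinates out of bounds for site {row['site_id']!r}")

        def opt(col: str) -> float | None:
            if col not in df.columns or pd.isna(row[col]):
                return None
            return float(row[col])

        depth = opt("depth")
        if depth is not None and depth < 0:
            raise TableFormatError(f"negative depth for site {row['site_id']!r}")
        farm = opt("farm_distance")
        if farm is not None and farm < 0:
            raise TableFormatError(f"negative farm_distance for site {row['site_id']!r}")
        networks = {}
        for col in network_cols:
            if not pd.isna(row[col]):
                frac = float(row[col])
                if not (0 <= frac <= 1):
                    raise TableFormatError(
                        f"network fraction {frac} out of [0,1] for site {row['site_id']!r}")
                networks[col[len(_NETWORK_PREFIX):]] = frac
        records.append(SiteRecord(str(row["site_id"]), lat, lon, depth, opt("toc"),
                                  opt("nitrogen"), opt("ph"), opt("redox"), farm, networks))
    return records


def write_sites(records: Sequence[SiteRecord], path: str | Path) -> None:
    network_names = sorted({n for r in records for n in r.network_fractions})
    rows = []
    for r in records:
        row: dict[str, object] = {"site_id": r.site_id, "lat": r.lat, "lon": r.lon}
        for col in COVARIATE_COLUMNS:
            row[col] = getattr(r, col)
        for name in network_names:
            row[_NETWORK_PREFIX + name] = r.network_fractions.get(name)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def sites_frame(records: Sequence[SiteRecord]) -> pd.DataFrame:
    """Covariate view of the site records, indexed by site_id (NaN = absent)."""
    rows = {r.site_id: {c: getattr(r, c) for c in COVARIATE_COLUMNS} for r in records}
    df = pd.DataFrame.from_dict(rows, orient="index").astype(float)
    df.index.name = "site_id"
    return df


def read_traits(binary_path: str | Path, coverage_path: str | Path) -> TraitTable:
    """Read the binary trait table and the fractional module-coverage table."""
    binary = pd.read_csv(binary_path, sep="\t", index_col=0,
                         float_precision="round_trip")
    binary.index = binary.index.astype(str)
    _check_unique(binary.index, "MAG ids")
    vals = binary.to_numpy(dtype=float)
    if not np.isin(vals, (0.0, 1.0)).all():
        i, j = np.argwhere(~np.isin(vals, (0.0, 1.0)))[0]
        raise TableFormatError(
            f"non-binary presence {vals[i, j]!r} for MAG {binary.index[i]!r}, "
            f"trait {binary.columns[j]!r}")
    binary = binary.astype(int)

    coverage = pd.read_csv(coverage_path, sep="\t", index_col=0,
                           float_precision="round_trip")
    coverage.index = coverage.index.astype(str)
    _check_unique(coverage.index, "MAG ids")
    cov = coverage.to_numpy(dtype=float)
    if ((cov < 0) | (cov > 1)).any():
        i, j = np.argwhere((cov < 0) | (cov > 1))[0]
        raise TableFormatError(
            f"coverage {cov[i, j]} out of [0,1] for MAG {coverage.index[i]!r}, "
            f"module {coverage.columns[j]!r}")
    return TraitTable(binary=binary, coverage=coverage)


def write_traits(table: TraitTable, binary_path: str | Path,
                 coverage_path: str | Path) -> None:
    table.binary.to_csv(binary_path, sep="\t")
    table.coverage.to_csv(coverage_path, sep="\t")


def write_stats_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write any downstream result table as TSV (no index column)."""
    df.to_csv(path, sep="\t", index=False)


def read_stats_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_run_summary(summary: Mapping[str, object], path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True, default=float) + "\n")
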