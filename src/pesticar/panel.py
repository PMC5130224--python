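"""County-year panel data: reading, validation, and preprocessing.

The analysis panel holds one row per county per census year with a
proportion-valued response (relative insecticide use, the share of harvested
cropland treated with insecticide at least once in a season) and seven
covariates: three crop-composition shares, net farm income, average farm
size, annual growing degree days, and the proportion of county land in
harvested cropland ("landscape simplification").

Preprocessing follows a fixed order: censored-value imputation, the minimum
cropland filter, then grand-mean centering of the covariates.  The response
is never centered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "COVARIATES",
    "PROPORTION_FIELDS",
    "IMPUTABLE_FIELDS",
    "DEFAULT_CENSUS_YEARS",
    "PanelSchemaError",
    "PanelValueError",
    "PanelDataset",
    "AdjacencyGraph",
    "read_panel",
    "write_panel",
    "read_centroids",
    "impute_censored",
    "filter_min_cropland",
    "center_covariates",
    "preprocess",
    "build_adjacency",
]

#: Canonical covariate columns, in the order they enter design matrices.
COVARIATES: tuple[str, ...] = (
    "x_corn", "x_cov", "x_sw", "x_income", "x_size", "x_gdd", "x_crop",
)

#: Fields constrained to [0, 1].
PROPORTION_FIELDS: tuple[str, ...] = ("y", "x_corn", "x_cov", "x_sw", "x_crop")

#: Fields that may be censored (withheld) in the source data and are
#: therefore subject to the county-mean / zero-fallback imputation rule.
IMPUTABLE_FIELDS: tuple[str, ...] = ("y",) + COVARIATES

DEFAULT_CENSUS_YEARS: tuple[int, ...] = (1997, 2002, 2007, 2012)

_ID_COLUMNS = ("county_id", "state_id", "year")
_VALUE_COLUMNS = ("y",) + COVARIATES


def _flag(name: str) -> str:
    return f"cens_{name}"


class PanelSchemaError(ValueError):
    """A required column is missing or the file layout is unusable."""


class PanelValueError(ValueError):
    """A cell could not be parsed; the row index is reported."""


@dataclass
class PanelDataset:
    """A county-year panel with optional centroids and centering metadata.

    Attributes
    ----------
    data:
        One row per (county_id, year).  Columns: ``county_id``, ``state_id``,
        ``year``, ``y``, the seven covariates, and one boolean ``cens_*``
        flag per imputable field.
    years:
        The configured census years, ordered.
    centroids:
        Planar county centroid coordinates in kilometres, indexed by
        county id, columns ``x_km`` and ``y_km``.  Optional.
    covariate_means:
        Grand means subtracted by :func:`center_covariates`; empty until
        centering has been applied.
    """

    data: pd.DataFrame
    years: tuple[int, ...] = DEFAULT_CENSUS_YEARS
    centroids: pd.DataFrame | None = None
    covariate_means: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.years = tuple(int(y) for y in self.years)
        dup = self.data.duplicated(subset=["county_id", "year"])
        if dup.any():
            raise PanelValueError(
                f"duplicate (county_id, year) pairs at rows {list(self.data.index[dup])}"
            )
        bad_years = set(self.data["year"]) - set(self.years)
        if bad_years:
            raise PanelValueError(f"years outside the configured censuses: {sorted(bad_years)}")

    @property
    def county_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.data["county_id"].unique()))

    @property
    def county_index(self) -> dict[str, int]:
        """Bijection county_id -> 0..n_counties-1 (sorted id order)."""
        return {cid: i for i, cid in enumerate(self.county_ids)}

    @property
    def n_counties(self) -> int:
        return len(self.county_ids)

    @property
    def n_records(self) -> int:
        return len(self.data)

    @property
    def is_centered(self) -> bool:
        return bool(self.covariate_means)

    def copy(self) -> "PanelDataset":
        return PanelDataset(
            data=self.data.copy(),
            years=self.years,
            centroids=None if self.centroids is None else self.centroids.copy(),
            covariate_means=dict(self.covariate_means),
        )

    def validate_values(self) -> None:
        """Check the value invariants that hold after imputation."""
        df = self.data
        for col in PROPORTION_FIELDS:
            vals = df[col].to_numpy(dtype=float)
            ok = np.isnan(vals) | ((vals >= 0.0) & (vals <= 1.0))
            if not ok.all():
                bad = df.index[~ok][:5].tolist()
                raise PanelValueError(f"{col} outside [0, 1] at rows {bad}")
        share = df[["x_corn", "x_cov", "x_sw"]].sum(axis=1).to_numpy(dtype=float)
        over = share > 1.0 + 1e-6
        if np.any(over & ~np.isnan(share)):
            bad = df.index[over][:5].tolist()
            raise PanelValueError(f"crop shares exceed 1 at rows {bad}")
        if self.centroids is not None:
            missing = set(self.county_ids) - set(self.centroids.index)
            if missing:
                raise PanelValueError(f"counties without centroids: {sorted(missing)[:5]}")


def _default_schema() -> dict[str, str]:
    return {c: c for c in _ID_COLUMNS + _VALUE_COLUMNS}


def read_panel(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    *,
    years: Sequence[int] = DEFAULT_CENSUS_YEARS,
    sentinel: str = "",
    centroids: pd.DataFrame | None = None,
) -> PanelDataset:
    """Read a delimited county-year panel.

    Parameters
    ----------
    path:
        Comma-delimited file with a header row, one county-year per line.
    schema:
        Mapping from canonical column name (``county_id``, ``y``,
        ``x_corn``, ...) to the column name used in the file.  Defaults to
        the identity mapping.
    sentinel:
        Token marking a censored (withheld) value.  The empty string also
        always counts as censored.  Sentinels are never silently coerced to
        numbers: they become NaN with the corresponding ``cens_*`` flag set.
    """
    full_schema = _default_schema()
    if schema:
        full_schema.update(schema)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [full_schema[c] for c in _ID_COLUMNS + _VALUE_COLUMNS
               if full_schema[c] not in raw.columns]
    if missing:
        raise PanelSchemaError(f"missing required column(s): {missing}")

    out = pd.DataFrame(index=raw.index)
    out["county_id"] = raw[full_schema["county_id"]].str.strip()
    out["state_id"] = raw[full_schema["state_id"]].str.strip()
    out["year"] = _parse_numeric(raw[full_schema["year"]], "year", allow_missing=False).astype(int)
    for canon in _VALUE_COLUMNS:
        col = raw[full_schema[canon]].str.strip()
        censored = (col == "") | (col == sentinel)
        vals = _parse_numeric(col.where(~censored, other="nan"), canon, allow_missing=True)
        out[canon] = vals
        if canon in IMPUTABLE_FIELDS:
            out[_flag(canon)] = censored.to_numpy()
    return PanelDataset(data=out, years=tuple(years), centroids=centroids)


def _parse_numeric(col: pd.Series, name: str, *, allow_missing: bool) -> np.ndarray:
    vals = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
    blank = col.astype(str).str.strip().isin(["", "nan"])
    bad = np.isnan(vals) & ~blank.to_numpy()
    if not allow_missing:
        bad |= np.isnan(vals)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise PanelValueError(f"unparseable value for {name!r} at row {row}: {col.iloc[row]!r}")
    return vals


def write_panel(panel: PanelDataset, path: str | Path) -> None:
    """Write a panel back to delimited text (round-trips :func:`read_panel`)."""
    cols = list(_ID_COLUMNS + _VALUE_COLUMNS) + [_flag(f) for f in IMPUTABLE_FIELDS]
    df = panel.data[cols].copy()
    df.to_csv(path, index=False)


def read_centroids(path: str | Path) -> pd.DataFrame:
    """Read a three-column centroid file (county id, x_km, y_km)."""
    df = pd.read_csv(path)
    expected = ["county_id", "x_km", "y_km"]
    if list(df.columns[:3]) != expected:
        raise PanelSchemaError(f"centroid file must have columns {expected}, got {list(df.columns)}")
    return df.set_index("county_id")[["x_km", "y_km"]].astype(float)


# ---------------------------------------------------------------------------
# Preprocessing operations (canonical order: impute -> filter -> center)
# ---------------------------------------------------------------------------

def impute_censored(panel: PanelDataset) -> PanelDataset:
    """Replace censored values by the county's mean over observed censuses.

    A value withheld in every census year falls back to zero, on the
    rationale that suppressed metrics derive from a single farm and would
    be relatively small.  Flags are cleared once values are filled.
    """
    out = panel.copy()
    df = out.data
    for fieldname in IMPUTABLE_FIELDS:
        fl = _flag(fieldname)
        if not df[fl].any():
            continue
        vals = df[fieldname].where(~df[fl])  # NaN where censored
        county_mean = vals.groupby(df["county_id"]).transform("mean")
        filled = vals.fillna(county_mean).fillna(0.0)
        df[fieldname] = filled
        df[fl] = False
    return out


def filter_min_cropland(
    panel: PanelDataset,
    threshold: float = 0.03,
    *,
    mode: str = "county",
    return_report: bool = False,
):
    """Drop observations from counties with < ``threshold`` of land in crops.

    ``mode="county"`` (default) removes a county from *all* years when its
    mean proportion cropland across the census years is strictly below the
    threshold.  ``mode="record"`` removes individual county-years instead.
    Run after imputation so that censored cropland values do not decide the
    rule.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if mode not in ("county", "record"):
        raise ValueError(f"mode must be 'county' or 'record', got {mode!r}")
    out = panel.copy()
    df = out.data
    if mode == "county":
        county_mean = df.groupby("county_id")["x_crop"].transform("mean")
        keep = ~(county_mean < threshold)
    else:
        keep = ~(df["x_crop"] < threshold)
    removed = df.loc[~keep]
    report = (
        removed.groupby("county_id")
        .agg(n_records=("year", "size"), mean_x_crop=("x_crop", "mean"))
        .reset_index()
    )
    out.data = df.loc[keep].reset_index(drop=True)
    if out.centroids is not None:
        out.centroids = out.centroids.loc[out.centroids.index.isin(out.data["county_id"])]
    if return_report:
        return out, report
    return out


def center_covariates(panel: PanelDataset) -> PanelDataset:
    """Subtract each covariate's grand mean over all surviving records.

    The response is left untouched.  Centering is idempotent: a second pass
    subtracts means that are already zero.  The means removed are recorded
    in ``covariate_means`` (cumulative across passes).
    """
    if panel.n_records == 0:
        raise ValueError("cannot center an empty panel")
    out = panel.copy()
    df = out.data
    for cov in COVARIATES:
        m = float(df[cov].mean())
        df[cov] = df[cov] - m
        out.covariate_means[cov] = out.covariate_means.get(cov, 0.0) + m
    return out


def preprocess(
    panel: PanelDataset,
    *,
    threshold: float = 0.03,
    filter_mode: str = "county",
) -> PanelDataset:
    """Run the canonical impute -> filter -> center pipeline."""
    return center_covariates(
        filter_min_cropland(impute_censored(panel), threshold, mode=filter_mode)
    )


# ---------------------------------------------------------------------------
# Adjacency
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric, simple county neighbour graph over an indexed node set.

    ``node_ids`` fixes the node ordering used by every structure matrix
    downstream; ``edges`` holds unordered index pairs (i < j);
    ``components`` partitions node indices into connected components.
    """

    node_ids: tuple[str, ...]
    edges: tuple[tuple[int, int], ...]
    components: tuple[tuple[int, ...], ...]

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def index(self) -> dict[str, int]:
        return {cid: i for i, cid in enumerate(self.node_ids)}

    @property
    def isolated(self) -> tuple[int, ...]:
        """Indices of nodes with no neighbours."""
        deg = np.zeros(self.n_nodes, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return tuple(int(i) for i in np.flatnonzero(deg == 0))

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg


def _graph_from_nx(g: nx.Graph, node_ids: Sequence[str]) -> AdjacencyGraph:
    idx = {cid: i for i, cid in enumerate(node_ids)}
    edges = sorted(
        tuple(sorted((idx[a], idx[b]))) for a, b in g.edges()
    )
    comps = tuple(
        tuple(sorted(idx[c] for c in comp))
        for comp in sorted(nx.connected_components(g), key=lambda s: min(idx[c] for c in s))
    )
    return AdjacencyGraph(node_ids=tuple(node_ids), edges=tuple(edges), components=comps)


def build_adjacency(
    edges: str | Path | Iterable[tuple[str, str]],
    panel: PanelDataset,
    *,
    restrict: bool = False,
) -> AdjacencyGraph:
    """Build the county neighbour graph restricted to the panel's counties.

    ``edges`` is either a two-column delimited edge-list file of county ids
    or an iterable of id pairs.  Duplicate and reversed edges collapse to a
    single undirected edge; self-loops are rejected.  Edges naming counties
    absent from the panel are an error by default; with ``restrict=True``
    they are dropped instead (useful when the panel has been filtered after
    the edge list was written).
    """
    if isinstance(edges, (str, Path)):
        df = pd.read_csv(edges, dtype=str)
        if df.shape[1] < 2:
            raise PanelSchemaError("edge list must have two columns of county ids")
        pairs = list(zip(df.iloc[:, 0].str.strip(), df.iloc[:, 1].str.strip()))
    else:
        pairs = [(str(a), str(b)) for a, b in edges]

    node_ids = panel.county_ids
    known = set(node_ids)
    g = nx.Graph()
    g.add_nodes_from(node_ids)
    for a, b in pairs:
        if a == b:
            raise PanelValueError(f"self-loop on county {a!r} rejected")
        unknown = {a, b} - known
        if unknown:
            if restrict:
                continue
            raise PanelValueError(f"edge references unknown county id(s): {sorted(unknown)}")
        g.add_edge(a, b)
    return _graph_from_nx(g, node_ids)
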