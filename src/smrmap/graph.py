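"""Spatial adjacency structures over small-area analysis units.

Disease-mapping models with conditional autoregressive (CAR) priors need a
symmetric neighbour graph over the spatial units (here: municipality-style
areas).  This module builds such graphs from polygon collections (queen or
rook contiguity), from explicit edge lists, or as regular lattices used as a
test geography, and validates the invariants the CAR machinery relies on:
symmetry, no self-loops, and consistent connected-component labels.
"""

from __future__ import annotations

import csv
import json
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from shapely.geometry import mapping as _shp_mapping
from shapely.geometry import shape as _shp_shape
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

__all__ = [
    "LANGUAGE_LEVELS",
    "URBANISATION_LEVELS",
    "SpatialUnit",
    "AdjacencyGraph",
    "GraphBuildError",
    "build_adjacency_from_polygons",
    "build_adjacency_from_edgelist",
    "generate_lattice_graph",
    "read_geojson_polygons",
    "read_edgelist",
    "write_edgelist",
]

#: Language-region levels; the first entry is the analysis reference level.
LANGUAGE_LEVELS = ("German", "French", "ItalianRomansh")
#: Urbanisation levels; the first entry is the analysis reference level.
URBANISATION_LEVELS = ("rural", "urban")


class GraphBuildError(ValueError):
    """Raised when an adjacency structure cannot be constructed."""


@dataclass(frozen=True)
class SpatialUnit:
    """One analysis unit with its two time-fixed categorical covariates."""

    unit_id: str
    name: str = ""
    language: str = "German"
    urbanisation: str = "rural"

    def __post_init__(self) -> None:
        if self.language not in LANGUAGE_LEVELS:
            raise ValueError(
                f"language must be one of {LANGUAGE_LEVELS}, got {self.language!r}"
            )
        if self.urbanisation not in URBANISATION_LEVELS:
            raise ValueError(
                f"urbanisation must be one of {URBANISATION_LEVELS}, "
                f"got {self.urbanisation!r}"
            )


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric, loop-free neighbour structure over ordered spatial units.

    Units are ordered lexicographically by ``unit_id`` so every downstream
    array (random effects, covariates, counts) shares one reproducible
    ordering.  Neighbour sets are stored as index tuples into ``units``.
    """

    units: tuple[str, ...]
    neighbors: tuple[tuple[int, ...], ...]
    component_label: np.ndarray = field(repr=False)
    n_components: int

    # -- construction -----------------------------------------------------

    @classmethod
    def from_edges(
        cls, units: Sequence[str], edges: Iterable[tuple[str, str]]
    ) -> "AdjacencyGraph":
        """Build from unit ids and undirected id pairs (symmetrized, deduped)."""
        unit_list = sorted(str(u) for u in units)
        if len(set(unit_list)) != len(unit_list):
            dupes = sorted({u for u in unit_list if unit_list.count(u) > 1})
            raise GraphBuildError(f"duplicate unit ids: {dupes}")
        index = {u: i for i, u in enumerate(unit_list)}
        nbr: list[set[int]] = [set() for _ in unit_list]
        for a, b in edges:
            try:
                ia, ib = index[str(a)], index[str(b)]
            except KeyError as exc:
                raise GraphBuildError(
                    f"edge endpoint {exc.args[0]!r} is not a declared unit"
                ) from None
            if ia == ib:
                continue  # self-loops are meaningless for contiguity
            nbr[ia].add(ib)
            nbr[ib].add(ia)
        neighbors = tuple(tuple(sorted(s)) for s in nbr)
        labels, n_comp = cls._label_components(len(unit_list), neighbors)
        return cls(tuple(unit_list), neighbors, labels, n_comp)

    @staticmethod
    def _label_components(
        n: int, neighbors: tuple[tuple[int, ...], ...]
    ) -> tuple[np.ndarray, int]:
        if n == 0:
            return np.zeros(0, dtype=np.int64), 0
        rows = [i for i, ns in enumerate(neighbors) for _ in ns]
        cols = [j for ns in neighbors for j in ns]
        mat = sparse.coo_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, n)
        ).tocsr()
        n_comp, labels = connected_components(mat, directed=False)
        return labels.astype(np.int64), int(n_comp)

    # -- views ------------------------------------------------------------

    @property
    def n_units(self) -> int:
        return len(self.units)

    def index(self, unit_id: str) -> int:
        return self.units.index(unit_id)

    @property
    def degrees(self) -> np.ndarray:
        return np.array([len(ns) for ns in self.neighbors], dtype=np.int64)

    def edges(self) -> list[tuple[int, int]]:
        """Undirected edges as (i, j) index pairs with i < j."""
        return [
            (i, j) for i, ns in enumerate(self.neighbors) for j in ns if i < j
        ]

    @property
    def n_edges(self) -> int:
        return sum(len(ns) for ns in self.neighbors) // 2

    def adjacency_matrix(self) -> sparse.csr_matrix:
        rows = [i for i, ns in enumerate(self.neighbors) for _ in ns]
        cols = [j for ns in self.neighbors for j in ns]
        return sparse.coo_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(self.n_units,) * 2
        ).tocsr()

    def components(self) -> list[np.ndarray]:
        """Unit-index arrays, one per connected component."""
        return [
            np.flatnonzero(self.component_label == c)
            for c in range(self.n_components)
        ]

    def validate(self) -> None:
        """Assert symmetry, irreflexivity, and component-label consistency."""
        for i, ns in enumerate(self.neighbors):
            if i in ns:
                raise GraphBuildError(f"self-loop at unit {self.units[i]!r}")
            for j in ns:
                if i not in self.neighbors[j]:
                    raise GraphBuildError(
                        f"asymmetric edge {self.units[i]!r}->{self.units[j]!r}"
                    )
            for j in ns:
                if self.component_label[i] != self.component_label[j]:
                    raise GraphBuildError("component labels split an edge")


def build_adjacency_from_polygons(
    geometries: Mapping[str, BaseGeometry], rule: str = "queen"
) -> AdjacencyGraph:
    """Contiguity graph from (multi)polygons keyed by unit id.

    Parameters
    ----------
    geometries
        Mapping unit_id -> shapely (Multi)Polygon.
    rule
        ``"queen"`` (default): any shared boundary point makes two units
        neighbours, including corner touches.  ``"rook"``: a shared boundary
        segment of positive length is required.
    """
    if rule not in ("queen", "rook"):
        raise GraphBuildError(f"unknown contiguity rule {rule!r}")
    ids = sorted(str(k) for k in geometries)
    if len(set(ids)) != len(ids):
        raise GraphBuildError("duplicate unit ids in geometry collection")
    geoms = []
    for uid in ids:
        g = geometries[uid]
        if g is None or not isinstance(g, BaseGeometry) or g.is_empty:
            raise GraphBuildError(f"empty or missing geometry for unit {uid!r}")
        if not g.is_valid:
            raise GraphBuildError(f"invalid geometry for unit {uid!r}")
        if g.geom_type not in ("Polygon", "MultiPolygon"):
            raise GraphBuildError(
                f"unit {uid!r}: expected (Multi)Polygon, got {g.geom_type}"
            )
        geoms.append(g)

    tree = STRtree(geoms)
    edges: list[tuple[str, str]] = []
    for i, g in enumerate(geoms):
        for j in tree.query(g, predicate="intersects"):
            j = int(j)
            if j <= i:
                continue
            if rule == "rook":
                inter = g.intersection(geoms[j])
                if inter.length <= 0.0:  # point touches have zero length
                    continue
            edges.append((ids[i], ids[j]))
    return AdjacencyGraph.from_edges(ids, edges)


def build_adjacency_from_edgelist(
    edges: Iterable[tuple[str, str]], units: Sequence[str]
) -> AdjacencyGraph:
    """Graph from explicit undirected id pairs over a declared unit list.

    Duplicate and reversed pairs collapse to one edge; units absent from all
    edges are retained as isolated (degree-0) vertices.
    """
    return AdjacencyGraph.from_edges(units, edges)


def generate_lattice_graph(rows: int, cols: int) -> AdjacencyGraph:
    """Rook-adjacent ``rows x cols`` lattice used as a test geography.

    Unit ids are zero-padded ``r{row}c{col}`` strings, so lexicographic unit
    order equals row-major grid order and the layout is reproducible.
    """
    if rows < 1 or cols < 1:
        raise GraphBuildError(f"lattice dimensions must be >= 1, got {rows}x{cols}")
    rw, cw = len(str(rows - 1)), len(str(cols - 1))

    def uid(r: int, c: int) -> str:
        return f"r{r:0{rw}d}c{c:0{cw}d}"

    units = [uid(r, c) for r in range(rows) for c in range(cols)]
    edges = []
    for r in range(rows):
        for c in range(cols):
            if c + 1 < cols:
                edges.append((uid(r, c), uid(r, c + 1)))
            if r + 1 < rows:
                edges.append((uid(r, c), uid(r + 1, c)))
    return AdjacencyGraph.from_edges(units, edges)


# -- file formats ---------------------------------------------------------


def read_geojson_polygons(path) -> dict[str, BaseGeometry]:
    """Read a GeoJSON FeatureCollection; features must carry a ``unit_id`` property."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise GraphBuildError("expected a GeoJSON FeatureCollection")
    out: dict[str, BaseGeometry] = {}
    for feat in doc.get("features", []):
        props = feat.get("properties") or {}
        if "unit_id" not in props:
            raise GraphBuildError("feature without a 'unit_id' property")
        uid = str(props["unit_id"])
        if uid in out:
            raise GraphBuildError(f"duplicate unit_id {uid!r} in GeoJSON")
        out[uid] = _shp_shape(feat["geometry"])
    return out


def geometry_to_geojson(geom: BaseGeometry) -> dict:
    return _shp_mapping(geom)


def read_edgelist(path) -> tuple[list[str], list[tuple[str, str]]]:
    """Read a two-column delimited edge list (header row required).

    Returns the unit list implied by the endpoints and the edge pairs; pass
    an explicit unit list to :func:`build_adjacency_from_edgelist` to keep
    isolated units.
    """
    with open(path, encoding="utf-8", newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        try:
            dialect = csv.Sniffer().sniff(sample, delimiters=",;\t ")
        except csv.Error:
            dialect = csv.excel
        reader = csv.reader(fh, dialect)
        header = next(reader, None)
        if header is None or len(header) < 2:
            raise GraphBuildError("edge list needs a two-column header row")
        edges = []
        for row in reader:
            if not row or not "".join(row).strip():
                continue
            if len(row) < 2:
                raise GraphBuildError(f"malformed edge row: {row!r}")
            edges.append((row[0].strip(), row[1].strip()))
    units = sorted({u for e in edges for u in e})
    return units, edges


def write_edgelist(graph: AdjacencyGraph, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["unit_id_a", "unit_id_b"])
        for i, j in graph.edges():
            writer.writerow([graph.units[i], graph.units[j]])
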