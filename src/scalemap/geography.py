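"""Two-level nested areal structure: adjacency, nesting, aggregation.

The package models data observed on a fine partition of a study region
(e.g. counties) that nests exactly into a coarse partition (e.g. public
health districts).  Spatial neighbourhood graphs are kept per level; the
nesting map sends every fine unit to exactly one coarse unit.  Coarse
outcomes arise by summing fine outcomes and coarse covariates by
averaging fine covariates within each parent, which is how aggregated
public-health surveillance data are produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import (
    AdjacencyParseError,
    AsymmetricAdjacencyError,
    MissingDataError,
    NestingConflictError,
)

__all__ = [
    "MultiscaleGeography",
    "ValidationReport",
    "read_adjacency",
    "write_adjacency",
    "read_nesting",
    "validate_geography",
    "aggregate",
]


# ---------------------------------------------------------------------------
# adjacency files


def _parse_gal(text: str) -> dict[str, set[str]]:
    lines = text.splitlines()
    # skip blank/comment leading lines; first payload line is the unit count
    pos = 0
    while pos < len(lines) and (not lines[pos].strip() or lines[pos].lstrip().startswith("#")):
        pos += 1
    if pos >= len(lines):
        raise AdjacencyParseError("empty GAL file")
    header = lines[pos].split()
    # GeoDa-style headers may carry extra tokens; the unit count is the first
    # integer token
    try:
        count = int(header[0])
    except ValueError as exc:
        raise AdjacencyParseError(f"line {pos + 1}: expected unit count, got {lines[pos]!r}") from exc
    pos += 1
    adj: dict[str, set[str]] = {}
    for _ in range(count):
        while pos < len(lines) and lines[pos].lstrip().startswith("#"):
            pos += 1
        if pos >= len(lines):
            raise AdjacencyParseError(f"line {len(lines)}: truncated file, expected {count} records")
        rec = lines[pos].split()
        if len(rec) != 2:
            raise AdjacencyParseError(
                f"line {pos + 1}: expected 'id degree', got {lines[pos]!r}"
            )
        unit, deg_s = rec
        try:
            deg = int(deg_s)
        except ValueError as exc:
            raise AdjacencyParseError(f"line {pos + 1}: degree {deg_s!r} is not an integer") from exc
        if unit in adj:
            raise AdjacencyParseError(f"line {pos + 1}: duplicate unit {unit!r}")
        pos += 1
        if deg == 0:
            # islands: a blank neighbour line is optional
            if pos < len(lines) and not lines[pos].strip():
                pos += 1
            adj[unit] = set()
            continue
        if pos >= len(lines):
            raise AdjacencyParseError(f"line {len(lines)}: missing neighbour line for {unit!r}")
        nbrs = lines[pos].split()
        if len(nbrs) != deg:
            raise AdjacencyParseError(
                f"line {pos + 1}: unit {unit!r} declares degree {deg} but lists {len(nbrs)} neighbours"
            )
        pos += 1
        adj[unit] = set(nbrs)
    return adj


def _parse_neighbor_csv(text: str) -> dict[str, set[str]]:
    lines = text.splitlines()
    if not lines:
        raise AdjacencyParseError("empty neighbour CSV")
    adj: dict[str, set[str]] = {}
    for lineno, line in enumerate(lines[1:], start=2):  # line 1 is the header
        if not line.strip():
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != 2:
            raise AdjacencyParseError(f"line {lineno}: expected 'unit_a,unit_b', got {line!r}")
        a, b = parts
        if not a:
            raise AdjacencyParseError(f"line {lineno}: empty unit label")
        adj.setdefault(a, set())
        if b:  # an empty second column declares an island
            adj.setdefault(b, set())
            adj[a].add(b)
            adj[b].add(a)
    return adj


def _check_symmetric_irreflexive(adj: Mapping[str, set[str]]) -> None:
    bad_pairs = []
    for i, nbrs in adj.items():
        if i in nbrs:
            raise AdjacencyParseError(f"unit {i!r} lists itself as a neighbour")
        for j in nbrs:
            if j not in adj:
                bad_pairs.append((i, j))
            elif i not in adj[j]:
                bad_pairs.append((i, j))
    if bad_pairs:
        listing = ", ".join(f"{i}->{j}" for i, j in sorted(bad_pairs))
        raise AsymmetricAdjacencyError(
            f"adjacency is not symmetric; one-directional pairs: {listing}"
        )


def read_adjacency(path, dialect: str = "gal") -> dict[str, set[str]]:
    """Read per-unit neighbour sets from a text file.

    ``dialect='gal'`` reads the GeoDa-style GAL text format: a header line
    holding the unit count, then per unit a record line ``id degree``
    followed by one whitespace-delimited line of neighbour ids (blank or
    absent for islands).  ``dialect='neighbor_csv'`` reads an undirected
    pair list ``unit_a,unit_b`` with a header row; a blank second column
    declares an island.

    The result is validated to be symmetric and irreflexive; asymmetric
    input is refused with the offending pairs listed, never silently
    symmetrized.  Units with no neighbours are preserved (see
    :func:`validate_geography`, which flags them).
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    if dialect == "gal":
        adj = _parse_gal(text)
    elif dialect == "neighbor_csv":
        adj = _parse_neighbor_csv(text)
    else:
        raise ValueError(f"unknown adjacency dialect {dialect!r}")
    _check_symmetric_irreflexive(adj)
    return adj


def write_adjacency(adj: Mapping[str, Iterable[str]], path, dialect: str = "gal") -> None:
    """Write neighbour sets in the chosen dialect (inverse of :func:`read_adjacency`)."""
    _check_symmetric_irreflexive({k: set(v) for k, v in adj.items()})
    with open(path, "w", encoding="utf-8") as fh:
        if dialect == "gal":
            fh.write(f"{len(adj)}\n")
            for unit, nbrs in adj.items():
                nbrs = sorted(nbrs)
                fh.write(f"{unit} {len(nbrs)}\n")
                fh.write(" ".join(nbrs) + "\n")
        elif dialect == "neighbor_csv":
            fh.write("unit_a,unit_b\n")
            written = set()
            for unit, nbrs in adj.items():
                if not nbrs:
                    fh.write(f"{unit},\n")
                for j in sorted(nbrs):
                    if (j, unit) not in written:
                        fh.write(f"{unit},{j}\n")
                        written.add((unit, j))
        else:
            raise ValueError(f"unknown adjacency dialect {dialect!r}")


def read_nesting(path) -> dict[str, str]:
    """Read the fine→coarse nesting map from a two-column CSV (header required).

    A fine unit listed more than once is an error, even with the same
    parent; conflicting parents are reported explicitly.
    """
    df = pd.read_csv(path, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise AdjacencyParseError("nesting CSV must have two columns (fine_id, coarse_id)")
    fine = df.iloc[:, 0]
    coarse = df.iloc[:, 1]
    parent: dict[str, str] = {}
    for lineno, (f, c) in enumerate(zip(fine, coarse), start=2):
        if f in parent:
            if parent[f] != c:
                raise NestingConflictError(
                    f"line {lineno}: fine unit {f!r} assigned to both {parent[f]!r} and {c!r}"
                )
            raise NestingConflictError(f"line {lineno}: fine unit {f!r} listed twice")
        parent[f] = c
    return parent


# ---------------------------------------------------------------------------
# the geography container


def _as_graph(ids: Sequence[str], adj: Mapping[str, set[str]]) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i, nbrs in adj.items():
        for j in nbrs:
            g.add_edge(i, j)
    return g


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_geography`: violations plus graph facts."""

    violations: list[str]
    n_components: tuple[int, int]
    islands: tuple[tuple[str, ...], tuple[str, ...]]

    @property
    def ok(self) -> bool:
        return not self.violations


@dataclass
class MultiscaleGeography:
    """Fine and coarse unit labels, per-level adjacency and the nesting map.

    Unit order is the canonical index order used by every vector in the
    package (file order of first appearance when read from disk).
    """

    fine_ids: list[str]
    coarse_ids: list[str]
    parent: dict[str, str]
    fine_adjacency: dict[str, set[str]]
    coarse_adjacency: dict[str, set[str]]

    # derived index structures, built in __post_init__
    parent_index: np.ndarray = field(init=False, repr=False)
    children: dict[str, list[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        fine_pos = {u: i for i, u in enumerate(self.fine_ids)}
        coarse_pos = {u: i for i, u in enumerate(self.coarse_ids)}
        if len(fine_pos) != len(self.fine_ids):
            raise NestingConflictError("duplicate fine unit labels")
        if len(coarse_pos) != len(self.coarse_ids):
            raise NestingConflictError("duplicate coarse unit labels")
        self.parent_index = np.array(
            [coarse_pos[self.parent[u]] for u in self.fine_ids], dtype=np.intp
        )
        self.children = {c: [] for c in self.coarse_ids}
        for u in self.fine_ids:
            self.children[self.parent[u]].append(u)
        self._fine_pos = fine_pos
        self._coarse_pos = coarse_pos

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_files(
        cls,
        fine_adjacency_path,
        coarse_adjacency_path,
        nesting_path,
        dialect: str = "gal",
    ) -> "MultiscaleGeography":
        """Build a geography from adjacency files and a nesting CSV.

        Coarse adjacency is always read from its own file, never derived
        from fine adjacency: aggregated administrative neighbourhoods are
        treated as given.
        """
        fine_adj = read_adjacency(fine_adjacency_path, dialect)
        coarse_adj = read_adjacency(coarse_adjacency_path, dialect)
        parent = read_nesting(nesting_path)
        fine_ids = list(parent)  # nesting-file order of first appearance
        seen: dict[str, None] = {}
        for u in fine_ids:
            seen.setdefault(parent[u], None)
        coarse_ids = list(seen)
        for u in fine_ids:
            fine_adj.setdefault(u, set())
        for c in coarse_ids:
            coarse_adj.setdefault(c, set())
        return cls(fine_ids, coarse_ids, parent, fine_adj, coarse_adj)

    # -- sizes and index helpers -------------------------------------------

    @property
    def n_fine(self) -> int:
        return len(self.fine_ids)

    @property
    def n_coarse(self) -> int:
        return len(self.coarse_ids)

    def ids(self, level: int) -> list[str]:
        return self.fine_ids if level == 1 else self.coarse_ids

    def adjacency(self, level: int) -> dict[str, set[str]]:
        return self.fine_adjacency if level == 1 else self.coarse_adjacency

    def n_units(self, level: int) -> int:
        return self.n_fine if level == 1 else self.n_coarse

    def graph(self, level: int) -> nx.Graph:
        return _as_graph(self.ids(level), self.adjacency(level))

    def edge_index(self, level: int) -> tuple[np.ndarray, np.ndarray]:
        """Undirected edges as two aligned index arrays (i < j)."""
        pos = self._fine_pos if level == 1 else self._coarse_pos
        ii, jj = [], []
        for a, nbrs in self.adjacency(level).items():
            for b in nbrs:
                if pos[a] < pos[b]:
                    ii.append(pos[a])
                    jj.append(pos[b])
        order = np.lexsort((jj, ii)) if ii else np.array([], dtype=np.intp)
        return (
            np.asarray(ii, dtype=np.intp)[order],
            np.asarray(jj, dtype=np.intp)[order],
        )

    def degrees(self, level: int) -> np.ndarray:
        ids = self.ids(level)
        adj = self.adjacency(level)
        return np.array([len(adj[u]) for u in ids], dtype=np.intp)

    def islands(self, level: int) -> np.ndarray:
        return np.flatnonzero(self.degrees(level) == 0)

    def n_components(self, level: int) -> int:
        return nx.number_connected_components(self.graph(level))

    # -- aggregation --------------------------------------------------------

    def aggregate(self, values, mode: str = "sum") -> pd.Series:
        """County→district style aggregation (see module docstring)."""
        return aggregate(values, self.parent, mode, coarse_order=self.coarse_ids)


def aggregate(
    values,
    parent: Mapping[str, str],
    mode: str = "sum",
    coarse_order: Sequence[str] | None = None,
) -> pd.Series:
    """Aggregate per-fine-unit values to the coarse level.

    ``mode='sum'`` gives the within-parent total (counts: births, cases);
    ``mode='mean'`` the within-parent average (covariates: income).
    ``values`` may be a mapping, a pandas Series indexed by fine id, or a
    sequence aligned with ``parent``'s key order.
    """
    if mode not in ("sum", "mean"):
        raise ValueError(f"mode must be 'sum' or 'mean', got {mode!r}")
    fine_ids = list(parent)
    if isinstance(values, pd.Series):
        vmap = values.to_dict()
    elif isinstance(values, Mapping):
        vmap = dict(values)
    else:
        seq = list(values)
        if len(seq) != len(fine_ids):
            raise MissingDataError(
                f"got {len(seq)} values for {len(fine_ids)} fine units"
            )
        vmap = dict(zip(fine_ids, seq))
    missing = [u for u in fine_ids if u not in vmap or pd.isna(vmap[u])]
    if missing:
        raise MissingDataError(f"no value for fine unit(s): {', '.join(map(str, missing))}")
    ser = pd.Series({u: vmap[u] for u in fine_ids}, dtype=float)
    grouped = ser.groupby(pd.Series(parent))
    out = grouped.sum() if mode == "sum" else grouped.mean()
    if coarse_order is None:
        seen: dict[str, None] = {}
        for u in fine_ids:
            seen.setdefault(parent[u], None)
        coarse_order = list(seen)
    return out.reindex(list(coarse_order))


def validate_geography(geog: MultiscaleGeography) -> ValidationReport:
    """Check every structural invariant; an empty violation list means valid.

    Reported facts include connected components per level (the ICAR prior's
    rank deficiency equals the component count) and island units.
    """
    violations: list[str] = []
    for level, name in ((1, "fine"), (2, "coarse")):
        ids = set(geog.ids(level))
        adj = geog.adjacency(level)
        for i, nbrs in adj.items():
            if i in nbrs:
                violations.append(f"{name}: unit {i!r} is its own neighbour")
            for j in nbrs:
                if j not in adj or i not in adj.get(j, set()):
                    violations.append(f"{name}: asymmetric pair {i!r}->{j!r}")
            if i not in ids:
                violations.append(f"{name}: adjacency unit {i!r} not in unit list")
        for u in ids:
            if u not in adj:
                violations.append(f"{name}: unit {u!r} missing from adjacency")
    for u in geog.fine_ids:
        if u not in geog.parent:
            violations.append(f"nesting: fine unit {u!r} has no parent")
        elif geog.parent[u] not in set(geog.coarse_ids):
            violations.append(f"nesting: parent {geog.parent[u]!r} of {u!r} is not a coarse unit")
    for c in geog.coarse_ids:
        if not geog.children.get(c):
            violations.append(f"nesting: coarse unit {c!r} has no children")
    if not (geog.n_fine >= geog.n_coarse >= 1):
        violations.append(
            f"sizes: need n_fine >= n_coarse >= 1, got {geog.n_fine} and {geog.n_coarse}"
        )
    islands = tuple(
        tuple(np.asarray(geog.ids(level))[geog.islands(level)]) for level in (1, 2)
    )
    report = ValidationReport(
        violations=violations,
        n_components=(geog.n_components(1), geog.n_components(2)),
        islands=islands,  # flagged, not rejected
    )
    return report
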