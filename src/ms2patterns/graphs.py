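"""Per-spectrum fragmentation graphs over the shared label alphabet.

Each reduced spectrum becomes an edge-labeled DAG: one vertex per fragment
peak, and an edge from the heavier to the lighter peak whenever their m/z
difference falls inside one of the library-wide bins.  Because every edge
points down the mass axis the graph is structurally acyclic.  Conflicting
duplicate edges (same label sharing a source or a target) are resolved by
keeping the edge closest to the bin center, after which the out-edges (and
in-edges) of any vertex carry pairwise distinct labels — the property the
miner's vertex identification rests on.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import networkx as nx

from .binning import BinningParams, EdgeLabel, assign_label
from .binning import _fmt as _fmt_formula
from .spectra import Spectrum

log = logging.getLogger(__name__)


class Edge(NamedTuple):
    source: int     # heavier vertex
    target: int     # lighter vertex
    label: int      # EdgeLabel id
    diff: float     # observed m/z difference


@dataclass
class FragmentationGraph:
    """Edge-labeled DAG of one spectrum (vertices = peaks, ascending m/z)."""

    spectrum_id: str
    mz: list[float]
    intensity: list[float]
    edges: list[Edge] = field(default_factory=list)

    def __post_init__(self) -> None:
        for e in self.edges:
            if not self.mz[e.source] > self.mz[e.target]:
                raise ValueError(f"edge {e} does not point heavier -> lighter")

    @property
    def n_vertices(self) -> int:
        return len(self.mz)

    def out_map(self) -> dict[int, dict[int, int]]:
        """vertex -> {label -> target}; labels unique after deduplication."""
        out: dict[int, dict[int, int]] = {v: {} for v in range(self.n_vertices)}
        for e in self.edges:
            out[e.source][e.label] = e.target
        return out

    def in_map(self) -> dict[int, dict[int, int]]:
        inn: dict[int, dict[int, int]] = {v: {} for v in range(self.n_vertices)}
        for e in self.edges:
            inn[e.target][e.label] = e.source
        return inn

    def edge_label(self) -> dict[tuple[int, int], int]:
        return {(e.source, e.target): e.label for e in self.edges}


@dataclass
class GraphDB:
    """The library as a set of fragmentation graphs plus its alphabet."""

    graphs: list[FragmentationGraph]
    labels: list[EdgeLabel]
    params: BinningParams = field(default_factory=BinningParams)

    def __post_init__(self) -> None:
        ids = {l.id for l in self.labels}
        for g in self.graphs:
            for e in g.edges:
                if e.label not in ids:
                    raise ValueError(
                        f"graph {g.spectrum_id}: unknown label {e.label}")

    def __len__(self) -> int:
        return len(self.graphs)


def build_graph(s: Spectrum, labels: Sequence[EdgeLabel]) -> FragmentationGraph:
    """Convert one reduced spectrum into its fragmentation graph.

    For every ordered peak pair (heavier, lighter) an edge is created when
    the m/z difference falls inside a bin; duplicate-label conflicts are
    then resolved.  A spectrum may legitimately yield an edgeless graph.
    """
    mz = [p.mz for p in s.peaks]
    inten = [p.intensity for p in s.peaks]
    edges: list[Edge] = []
    for j in range(len(mz)):
        for i in range(j + 1, len(mz)):
            d = mz[i] - mz[j]
            lab = assign_label(labels, d)
            if lab is not None:
                edges.append(Edge(i, j, lab.id, d))
    g = FragmentationGraph(s.id, mz, inten, edges)
    return deduplicate_edges(g, labels)


def deduplicate_edges(g: FragmentationGraph,
                      labels: Sequence[EdgeLabel]) -> FragmentationGraph:
    """Resolve duplicate-label conflicts around a common source or target.

    Within every (source, label) and every (target, label) group only the
    edge whose observed difference is closest to the bin center survives;
    exact ties go to the smaller target m/z, then the smaller source m/z.
    Such conflicts typically betray poor MS/MS extraction.
    """
    center = {l.id: l.center for l in labels}

    def rank(e: Edge) -> tuple:
        return (abs(e.diff - center[e.label]), g.mz[e.target], g.mz[e.source])

    kept = list(g.edges)
    for grouper in (lambda e: (e.source, e.label),
                    lambda e: (e.target, e.label)):
        groups: dict[tuple, list[Edge]] = {}
        for e in kept:
            groups.setdefault(grouper(e), []).append(e)
        kept = [min(gr, key=rank) for gr in groups.values()]
    kept.sort()
    return FragmentationGraph(g.spectrum_id, g.mz, g.intensity, kept)


@dataclass
class ConsistencyReport:
    """Triangle-closure audit of a graph database.

    For every 2-path u -> v -> w the direct edge u -> w should exist and
    its bin should contain mz(u) - mz(w); deviations count as labeling
    errors.  On exact data the rate is zero by arithmetic.
    """

    triangles: int
    errors: int
    error_detail: list[tuple[str, int, int, int]] = field(default_factory=list)

    @property
    def error_rate(self) -> float:
        return self.errors / self.triangles if self.triangles else 0.0


def check_label_consistency(db: GraphDB, *, repair: bool = False,
                            min_path_support: int = 1
                            ) -> tuple[ConsistencyReport, GraphDB]:
    """Audit (and optionally repair) triangle closure across the database.

    With the default ``min_path_support=1`` every 2-path is inspected.
    Setting it to the mining support threshold restricts the audit to
    frequent 2-paths — the paths the closure property (and hence the
    miner's vertex identification) actually relies on.

    In repair mode a missing or mislabeled closing edge (u, w) is added or
    relabeled when mz(u) - mz(w) falls inside an existing bin; otherwise
    the database is returned unchanged and only the report is produced.
    """
    path_graphs: dict[tuple[int, int], set[int]] = {}
    if min_path_support > 1:
        for gi, g in enumerate(db.graphs):
            out = g.out_map()
            for u in range(g.n_vertices):
                for l1, v in out[u].items():
                    for l2 in out[v]:
                        path_graphs.setdefault((l1, l2), set()).add(gi)

    triangles = errors = 0
    detail: list[tuple[str, int, int, int]] = []
    new_graphs: list[FragmentationGraph] = []
    for g in db.graphs:
        out = g.out_map()
        elab = g.edge_label()
        labels_by_id = {l.id: l for l in db.labels}
        lab_of = {(e.source, e.target): e.label for e in g.edges}
        extra: dict[tuple[int, int], Edge] = {}
        for u in range(g.n_vertices):
            for v in out[u].values():
                for w in out[v].values():
                    if min_path_support > 1:
                        key = (lab_of[(u, v)], lab_of[(v, w)])
                        if len(path_graphs.get(key, ())) < min_path_support:
                            continue
                    triangles += 1
                    d = g.mz[u] - g.mz[w]
                    lab = elab.get((u, w))
                    if lab is not None and d in labels_by_id[lab]:
                        continue
                    errors += 1
                    detail.append((g.spectrum_id, u, v, w))
                    if repair:
                        fix = assign_label(db.labels, d)
                        if fix is not None:
                            extra[(u, w)] = Edge(u, w, fix.id, d)
        if repair and extra:
            edges = [e for e in g.edges
                     if (e.source, e.target) not in extra]
            edges.extend(extra.values())
            edges.sort()
            new_graphs.append(deduplicate_edges(
                FragmentationGraph(g.spectrum_id, g.mz, g.intensity, edges),
                db.labels))
        else:
            new_graphs.append(g)
    report = ConsistencyReport(triangles, errors, detail)
    out_db = GraphDB(new_graphs, db.labels, db.params) if repair else db
    return report, out_db


def build_graphdb(spectra: Sequence[Spectrum], labels: Sequence[EdgeLabel],
                  params: BinningParams | None = None) -> GraphDB:
    return GraphDB([build_graph(s, labels) for s in spectra], list(labels),
                   params or BinningParams())


# ---------------------------------------------------------------------------
# export

def to_networkx(g: FragmentationGraph, labels: Sequence[EdgeLabel]) -> nx.DiGraph:
    by_id = {l.id: l for l in labels}
    G = nx.DiGraph(spectrum_id=g.spectrum_id)
    for v, (m, h) in enumerate(zip(g.mz, g.intensity)):
        G.add_node(v, mz=m, intensity=h)
    for e in g.edges:
        lab = by_id[e.label]
        best = lab.best_formula
        G.add_edge(e.source, e.target, label=e.label, diff=e.diff,
                   formula="" if best is None else str(best))
    return G


def write_graphml(db: GraphDB, directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for i, g in enumerate(db.graphs):
        p = directory / f"graph_{i:04d}.graphml"
        nx.write_graphml(to_networkx(g, db.labels), p)
        written.append(p)
    return written


def db_to_json(db: GraphDB) -> dict:
    return {
        "params": {
            "ppm": db.params.ppm, "dmz": db.params.dmz,
            "min_count": db.params.min_count,
            "formula_window": list(db.params.formula_window),
            "max_combination": db.params.max_combination,
            "elements": list(db.params.elements),
        },
        "labels": [{
            "id": l.id, "lower": l.lower, "upper": l.upper,
            "center": l.center, "count": l.count,
            "formulas": [_fmt_formula(f) for f in l.formulas],
        } for l in db.labels],
        "graphs": [{
            "spectrum_id": g.spectrum_id, "mz": g.mz,
            "intensity": g.intensity,
            "edges": [list(e) for e in g.edges],
        } for g in db.graphs],
    }


def write_db_json(db: GraphDB, path: str | Path) -> None:
    Path(path).write_text(json.dumps(db_to_json(db)))
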