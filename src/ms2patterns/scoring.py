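"""Scoring patterns against labeled spectrum sets and molecular networks.

A pattern's support D(P) — the spectra containing it — is treated as a
binary classifier for a target set of spectra (an ontology concept D(T) or
a molecular-network component): precision = |D(P) ∩ D(T)| / |D(P)|,
recall = |D(P) ∩ D(T)| / |D(T)|, combined as the F1 harmonic mean.  The
molecular network itself (e.g. a GNPS export) is consumed as a plain edge
list; this module never computes spectral similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConceptSet:
    """A named set of spectrum ids, e.g. the members of an ontology term.

    Singleton concepts carry no group signal and are rejected.
    """

    name: str
    members: frozenset[str]
    depth: int | None = None

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError(f"concept {self.name}: needs >= 2 members")


@dataclass(frozen=True)
class ExplanationScore:
    precision: float
    recall: float
    f1: float
    pattern_id: int | str
    target: str


@dataclass(frozen=True)
class NetworkComponent:
    kind: str  # connected_component | clique | pair
    members: frozenset[str]
    source_similarity: float | None = None

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("component needs >= 2 members")
        if self.kind not in ("connected_component", "clique", "pair"):
            raise ValueError(f"unknown component kind {self.kind}")


def score_pattern(support: Iterable[str], target: ConceptSet,
                  pattern_id: int | str = "") -> ExplanationScore:
    """Precision / recall / F1 of a pattern's support against a target set."""
    dp = frozenset(support)
    if not dp:
        raise ValueError("empty pattern support")
    hit = len(dp & target.members)
    precision = hit / len(dp)
    recall = hit / len(target.members)
    denom = precision + recall
    f1 = 2 * precision * recall / denom if denom > 0 else 0.0
    return ExplanationScore(precision, recall, f1, pattern_id, target.name)


def read_concepts(path: str | Path) -> list[ConceptSet]:
    """Concept membership TSV: spectrum id, concept name[, depth].

    Concepts sharing an identical member set are collapsed to the most
    specific (deepest) one when depth is given; without depth metadata all
    are retained and a warning flags the redundancy.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    has_depth = df.shape[1] >= 3
    grouped: dict[str, set[str]] = {}
    depths: dict[str, int] = {}
    for _, row in df.iterrows():
        grouped.setdefault(str(row[1]), set()).add(str(row[0]))
        if has_depth and not pd.isna(row[2]):
            depths[str(row[1])] = int(row[2])
    by_members: dict[frozenset, list[str]] = {}
    for name, members in grouped.items():
        if len(members) < 2:
            log.warning("concept %s: singleton, discarded", name)
            continue
        by_members.setdefault(frozenset(members), []).append(name)
    out: list[ConceptSet] = []
    for members, names in sorted(by_members.items(), key=lambda kv: sorted(kv[0])):
        if len(names) > 1 and all(n in depths for n in names):
            keep = max(names, key=lambda n: (depths[n], n))
            names = [keep]
        elif len(names) > 1:
            log.warning("concepts %s share one member set (no depth given); "
                        "all retained", names)
        out.extend(ConceptSet(n, members, depths.get(n)) for n in sorted(names))
    return out


def read_network(path: str | Path) -> nx.Graph:
    """3-column edge list (id1, id2, similarity) or GraphML."""
    path = Path(path)
    if path.suffix == ".graphml":
        return nx.read_graphml(path)
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    G = nx.Graph()
    for _, row in df.iterrows():
        G.add_edge(str(row[0]), str(row[1]), weight=float(row[2]))
    return G


def find_components(network: nx.Graph, min_clique_size: int = 3,
                    min_pair_similarity: float = 0.9
                    ) -> list[NetworkComponent]:
    """Extract the units of a molecular network worth explaining.

    Returns all connected components (>= 2 nodes), a maximal set of
    pairwise-disjoint cliques of at least ``min_clique_size`` nodes picked
    greedily (largest first, lexicographic member order on ties, re-run on
    the residual graph after each pick), and connected pairs with
    similarity >= ``min_pair_similarity``.
    """
    comps: list[NetworkComponent] = []
    for cc in nx.connected_components(network):
        if len(cc) >= 2:
            comps.append(NetworkComponent("connected_component",
                                          frozenset(str(n) for n in cc)))
    comps.sort(key=lambda c: sorted(c.members))

    residual = network.copy()
    cliques: list[NetworkComponent] = []
    while True:
        found = [sorted(str(n) for n in c)
                 for c in nx.find_cliques(residual)
                 if len(c) >= min_clique_size]
        if not found:
            break
        found.sort(key=lambda c: (-len(c), c))
        best = found[0]
        cliques.append(NetworkComponent("clique", frozenset(best)))
        residual.remove_nodes_from(best)
    comps.extend(cliques)

    for u, v, data in sorted(network.edges(data=True)):
        w = float(data.get("weight", 1.0))
        if w >= min_pair_similarity:
            comps.append(NetworkComponent(
                "pair", frozenset((str(u), str(v))), w))
    return comps


def explain_components(pattern_supports: dict[int | str, Iterable[str]],
                       components: Sequence[NetworkComponent]
                       ) -> list[tuple[NetworkComponent, list[ExplanationScore]]]:
    """Rank the patterns explaining each network component.

    Ranking: recall desc, precision desc, pattern edge count desc (passed
    through the optional ``(support, n_edges)`` tuple values), pattern id
    asc; the head of each list is the component's best explanation.
    """
    normalized: dict[int | str, tuple[frozenset[str], int]] = {}
    for pid, supp in pattern_supports.items():
        if isinstance(supp, tuple) and len(supp) == 2:
            ids, n_edges = supp
        else:
            ids, n_edges = supp, 0
        normalized[pid] = (frozenset(ids), int(n_edges))

    out = []
    for comp in components:
        target = ConceptSet(f"component:{'|'.join(sorted(comp.members))}",
                            comp.members)
        scored = []
        for pid, (ids, n_edges) in normalized.items():
            if not ids:
                continue
            s = score_pattern(ids, target, pid)
            scored.append((s, n_edges))
        scored.sort(key=lambda t: (-t[0].recall, -t[0].precision, -t[1],
                                   str(t[0].pattern_id)))
        out.append((comp, [s for s, _ in scored]))
    return out
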