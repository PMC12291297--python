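"""Closed frequent subgraph mining of fragmentation graphs.

The mined patterns are Acyclic Flow Graphs (AFGs): rooted DAGs with a
directed path from the root to every vertex.  Two structural properties of
fragmentation graphs make the search tractable.  Because edge labels are
m/z differences, the two edges of any frequent 2-path force a third,
closing edge between its endpoints (the differences add up), so every
frequent AFG contains the depth-1 star of edges leaving its root, and a
pattern is fully determined by any of its spanning trees.  Mining therefore
reduces to enumerating spanning trees:

* the *k-path tree* indexes every potentially frequent directed path of
  length <= k as a prefix-tree node annotated with its last edge label
  (``l``), the label of the closing root-to-endpoint edge (``h``) and its
  occurrence list (``o``);
* candidate patterns are subtrees of the k-path tree, generated exactly
  once via right-most path extension, and kept when they (1) map to a
  proper spanning tree — no two subtree vertices share an ``h`` label,
  (2) are the k-LMDF canonical spanning tree of the AFG they induce, and
  (3) reach the minimum support;
* each surviving subtree is reconstructed into the full AFG from its first
  occurrence (closure edges added back) and reported when closed, i.e.
  when no common one-edge root extension with identical support exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

from .graphs import FragmentationGraph, GraphDB

log = logging.getLogger(__name__)

Occurrence = tuple[int, int]  # (graph index, root vertex)


@dataclass(frozen=True)
class MiningParams:
    """min_support is an absolute number of graphs (epsilon); k caps the
    path length indexed by the k-path tree (any value >= 1 yields the same
    pattern set, deeper trees just prune harder); max_pattern_size
    optionally caps the edge count of reported patterns."""

    min_support: int = 2
    k: int | None = None
    max_pattern_size: int | None = None

    def __post_init__(self) -> None:
        if self.min_support < 2:
            raise ValueError("min_support must be >= 2")
        if self.k is not None and not 1 <= self.k <= 14:
            raise ValueError("k must be in [1, 14]")

    def resolve_k(self, db: GraphDB) -> int:
        if self.k is not None:
            return self.k
        return max(1, min(14, max((_longest_path(g) for g in db.graphs),
                                  default=1)))


def _longest_path(g: FragmentationGraph) -> int:
    # vertices ascending by mz and edges pointing to lower mz: descending
    # vertex index is a topological order
    dist = [0] * g.n_vertices
    for v in range(g.n_vertices - 1, -1, -1):
        for e in g.edges:
            if e.source == v:
                dist[e.target] = max(dist[e.target], dist[v] + 1)
    return max(dist, default=0)


@dataclass
class KPathNode:
    """One potentially frequent directed path of the database.

    ``label`` (l) is the path's last edge label, ``h`` the label of the
    unique edge joining the path's endpoints, and ``occ_end`` maps each
    occurrence (graph, path root) to the path's endpoint vertex there.
    """

    label: int | None
    h: int | None
    depth: int
    occ_end: dict[Occurrence, int] = field(default_factory=dict)
    children: dict[int, "KPathNode"] = field(default_factory=dict)

    @property
    def occ(self) -> set[Occurrence]:
        return set(self.occ_end)

    def n_nodes(self) -> int:
        return 1 + sum(c.n_nodes() for c in self.children.values())


@dataclass
class KPathTree:
    root: KPathNode
    k: int
    min_support: int

    def n_paths(self) -> int:
        """Number of frequent paths indexed (tree nodes minus the root)."""
        return self.root.n_nodes() - 1

    def iter_nodes(self) -> Iterator[KPathNode]:
        stack = [self.root]
        while stack:
            n = stack.pop()
            if n.label is not None:
                yield n
            stack.extend(n.children[c] for c in sorted(n.children, reverse=True))


def _adjacency(db: GraphDB):
    outs, inns, elabs = [], [], []
    for g in db.graphs:
        outs.append(g.out_map())
        inns.append(g.in_map())
        elabs.append(g.edge_label())
    return outs, inns, elabs


def _n_graphs(occ) -> int:
    return len({g for g, _ in occ})


def build_k_path_tree(db: GraphDB, params: MiningParams) -> KPathTree:
    """Index all potentially frequent directed paths of length <= k.

    A path occurrence is retained only when the closing edge between its
    endpoints exists (the paths "satisfying Property 2"); if — on noisy
    data — occurrences of one path disagree on the closing label, the
    variant supported by most graphs is kept and the rest dropped with a
    warning.  A path survives when its occurrences span at least
    ``min_support`` distinct graphs.
    """
    k = params.resolve_k(db)
    outs, _, elabs = _adjacency(db)
    root = KPathNode(label=None, h=None, depth=0)

    # depth 1: every edge label, occurrences keyed by source vertex
    depth1: dict[int, KPathNode] = {}
    for gi, out in enumerate(outs):
        for u, by_label in out.items():
            for a, t in by_label.items():
                node = depth1.setdefault(a, KPathNode(a, a, 1))
                node.occ_end[(gi, u)] = t
    root.children = {a: n for a, n in sorted(depth1.items())
                     if _n_graphs(n.occ_end) >= params.min_support}

    frontier = list(root.children.values())
    while frontier:
        nxt: list[KPathNode] = []
        for node in frontier:
            if node.depth >= k:
                continue
            # group candidate extensions by (next label, closing label)
            cand: dict[tuple[int, int], dict[Occurrence, int]] = {}
            for (gi, v1), ve in node.occ_end.items():
                for b, t in outs[gi][ve].items():
                    c = elabs[gi].get((v1, t))
                    if c is None:
                        continue  # path does not close: not an AFG path here
                    cand.setdefault((b, c), {})[(gi, v1)] = t
            by_label: dict[int, list[tuple[int, dict[Occurrence, int]]]] = {}
            for (b, c), occ in cand.items():
                by_label.setdefault(b, []).append((c, occ))
            for b, variants in sorted(by_label.items()):
                variants.sort(key=lambda v: (-_n_graphs(v[1]), v[0]))
                c, occ = variants[0]
                if len(variants) > 1:
                    log.warning(
                        "path extension label %d: closing label ambiguous "
                        "(%d variants), keeping label %d",
                        b, len(variants), c)
                if _n_graphs(occ) >= params.min_support:
                    child = KPathNode(b, c, node.depth + 1, occ)
                    node.children[b] = child
                    nxt.append(child)
        frontier = nxt
    return KPathTree(root, k, params.min_support)


# ---------------------------------------------------------------------------
# patterns


@dataclass
class Pattern:
    """A closed frequent AFG.  Vertex 0 is the root; every other vertex is
    identified by the label of its root edge (its ``h`` label)."""

    root: int
    vertices: list[int]
    edges: list[tuple[int, int, int]]  # (source, target, label)
    support: frozenset[int]
    occurrences: list[tuple[int, int, dict[int, int]]]
    canonical_code: tuple = ()

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def out_adj(self) -> dict[int, dict[int, int]]:
        adj: dict[int, dict[int, int]] = {v: {} for v in self.vertices}
        for u, v, lab in self.edges:
            if lab in adj[u]:
                raise ValueError("duplicate out-edge label: not an AFG here")
            adj[u][lab] = v
        return adj

    def h_labels(self) -> dict[int, int]:
        """non-root vertex -> label of its root edge."""
        return {v: lab for u, v, lab in self.edges if u == self.root}


def _check_afg(root: int, vertices: Sequence[int],
               edges: Sequence[tuple[int, int, int]]) -> dict[int, dict[int, int]]:
    adj: dict[int, dict[int, int]] = {v: {} for v in vertices}
    for u, v, lab in edges:
        if v == root:
            raise ValueError("root has an incoming edge: not an AFG")
        if lab in adj[u]:
            raise ValueError("duplicate out-edge label: not an AFG")
        adj[u][lab] = v
    seen = {root}
    stack = [root]
    while stack:
        for t in adj[stack.pop()].values():
            if t not in seen:
                seen.add(t)
                stack.append(t)
    if seen != set(vertices):
        raise ValueError("not a flow graph: some vertex unreachable from root")
    return adj


def _min_paths(root: int, adj: dict[int, dict[int, int]]) -> dict[int, tuple]:
    """Lexicographically smallest label path from the root to each vertex."""
    names: dict[int, tuple] = {root: ()}
    frontier = [root]
    while frontier:
        nxt = []
        for u in frontier:
            for lab in sorted(adj[u]):
                t = adj[u][lab]
                cand = names[u] + (lab,)
                if t not in names or cand < names[t]:
                    names[t] = cand
                    nxt.append(t)
        frontier = nxt
    return names


def canonical_key(root: int, vertices: Sequence[int],
                  edges: Sequence[tuple[int, int, int]]) -> tuple:
    """Isomorphism-invariant key of an AFG: edges written on min-path vertex
    names.  Independent of the k-LMDF code; used for cross-checking."""
    adj = _check_afg(root, vertices, edges)
    names = _min_paths(root, adj)
    return tuple(sorted((names[u], names[v], lab) for u, v, lab in edges))


def lmdf_encode(p: Pattern, k: int = 14) -> tuple:
    """k-LMDF canonical code of an AFG.

    A depth-first search from the root explores out-edges in ascending
    label order, descending only into unvisited vertices and never below
    depth ``k``; the resulting spanning tree N(G) is emitted as a token
    sequence (("d", label) on descent, ("u", -1) on backtrack).  The full
    edge list written on min-path vertex names (itself a canonical edge
    list) is appended, which makes the code a complete isomorphism
    invariant — equal codes iff isomorphic AFGs — even across databases
    where the closure property linking tree and non-tree edges does not
    hold.
    """
    adj = _check_afg(p.root, p.vertices, p.edges)
    tokens: list = []
    visited = {p.root}

    def dfs(v: int, depth: int) -> None:
        for lab in sorted(adj[v]):
            t = adj[v][lab]
            if t not in visited and depth < k:
                visited.add(t)
                tokens.append(("d", lab))
                dfs(t, depth + 1)
                tokens.append(("u", -1))

    dfs(p.root, 0)
    names = _min_paths(p.root, adj)
    edges = tuple(sorted((names[u], names[v], lab) for u, v, lab in p.edges))
    return (tuple(tokens), edges)


def lmdf_tree(p: Pattern, k: int) -> set[tuple[int, int, int]]:
    """Edge set of the k-LMDF spanning tree N(G) of an AFG."""
    adj = _check_afg(p.root, p.vertices, p.edges)
    visited = {p.root}
    tree: set[tuple[int, int, int]] = set()

    def dfs(v: int, depth: int) -> None:
        for lab in sorted(adj[v]):
            t = adj[v][lab]
            if t not in visited and depth < k:
                visited.add(t)
                tree.add((v, t, lab))
                dfs(t, depth + 1)

    dfs(p.root, 0)
    return tree


# ---------------------------------------------------------------------------
# subtree enumeration


@dataclass
class Subtree:
    """A candidate subtree of the k-path tree.

    ``nodes[i]`` is a k-path-tree node; its tree parent is ``parents[i]``
    (-1 for the subtree root).  Pattern vertex i+1 corresponds to
    ``nodes[i]`` (vertex 0 is the root).  ``occ`` is the set of common
    occurrences, i.e. the intersection of the nodes' occurrence lists on
    (graph, root vertex) couples — legitimate because all paths of the
    subtree start at the same root vertex.
    """

    nodes: list[KPathNode]
    parents: list[int]
    occ: set[Occurrence]

    @property
    def h_labels(self) -> list[int]:
        return [n.h for n in self.nodes]

    def tree_edges(self) -> set[tuple[int, int, int]]:
        """Tree edges in pattern-vertex space (root = 0, node i = i+1)."""
        return {(self.parents[i] + 1, i + 1, n.label)
                for i, n in enumerate(self.nodes)}

    def rightmost_path(self) -> list[int]:
        """Indices of the nodes on the right-most root-to-leaf path."""
        path: list[int] = []
        child_of: dict[int, int] = {}
        for i, p in enumerate(self.parents):
            child_of[p] = i  # later children overwrite: rightmost survives
        cur = -1
        while cur in child_of:
            cur = child_of[cur]
            path.append(cur)
        return path


def reconstruct_pattern(subtree: Subtree, db: GraphDB) -> Pattern:
    """Rebuild the full AFG of a subtree from its first occurrence.

    The subtree is mapped onto its lexicographically first occurrence and
    every edge present between the mapped vertices is added: by the
    closure property these edges recur in every other occurrence (a debug
    check of that claim is available via ``verify_occurrences``).
    """
    if not subtree.occ:
        raise ValueError("subtree has no occurrences")
    gi, v1 = min(subtree.occ)
    g = db.graphs[gi]
    out = g.out_map()
    elab = g.edge_label()
    images = [v1]
    for n in subtree.nodes:
        target = out[v1].get(n.h)
        if target is None:
            raise RuntimeError(
                "subtree maps to no closing edge: criterion-1 bookkeeping bug")
        images.append(target)
    if len(set(images)) != len(images):
        raise RuntimeError(
            "subtree vertices collide in the graph: criterion-1 bookkeeping bug")
    vertices = list(range(len(images)))
    edges = []
    index = {img: i for i, img in enumerate(images)}
    for (u, v), lab in elab.items():
        if u in index and v in index:
            edges.append((index[u], index[v], lab))
    edges.sort()
    occurrences = _occurrence_maps(subtree, db)
    support = frozenset(gq for gq, _ in subtree.occ)
    return Pattern(0, vertices, edges, support, occurrences)


def _occurrence_maps(subtree: Subtree, db: GraphDB
                     ) -> list[tuple[int, int, dict[int, int]]]:
    occs = []
    for gi, v1 in sorted(subtree.occ):
        out = db.graphs[gi].out_map()
        mapping = {0: v1}
        for i, n in enumerate(subtree.nodes):
            mapping[i + 1] = out[v1][n.h]
        occs.append((gi, v1, mapping))
    return occs


def verify_occurrences(p: Pattern, db: GraphDB) -> list[tuple[int, int]]:
    """Occurrences where some reconstructed edge is missing or relabeled
    (closure-property violations; empty on exact data)."""
    bad = []
    for gi, v1, mapping in p.occurrences:
        elab = db.graphs[gi].edge_label()
        for u, v, lab in p.edges:
            if elab.get((mapping[u], mapping[v])) != lab:
                bad.append((gi, v1))
                break
    return bad


def is_closed(p: Pattern, db: GraphDB) -> bool:
    """Closeness via common one-edge root extensions (E_in / E_out).

    E_out gathers, within each supporting graph, the labels of edges
    leaving any mapped root beyond the pattern's own root star, and
    intersects these sets across graphs; E_in does the same for edges
    entering the mapped root.  A non-empty set exhibits a strict supergraph
    with identical (graph-counted) support, so the pattern is closed iff
    both are empty.
    """
    if not p.occurrences:
        raise ValueError("pattern has an empty occurrence list")
    own = set(p.h_labels().values())
    e_out: dict[int, set[int]] = {}
    e_in: dict[int, set[int]] = {}
    for gi, v1, _ in p.occurrences:
        out = db.graphs[gi].out_map()
        inn = db.graphs[gi].in_map()
        e_out.setdefault(gi, set()).update(set(out[v1]) - own)
        e_in.setdefault(gi, set()).update(inn[v1])
    out_common = set.intersection(*e_out.values())
    in_common = set.intersection(*e_in.values())
    return not out_common and not in_common


@dataclass
class MiningStats:
    """Candidate bookkeeping: how many subtrees each criterion removed."""

    candidates: int = 0
    failed_support: int = 0
    failed_spanning: int = 0
    failed_canonical: int = 0
    not_closed: int = 0
    patterns: int = 0


def mine_closed_patterns(db: GraphDB, params: MiningParams | None = None,
                         *, tree: KPathTree | None = None,
                         stats: MiningStats | None = None) -> list[Pattern]:
    """All closed frequent AFG patterns of the database.

    Subtrees of the k-path tree are enumerated once each by right-most
    path extension; the support, spanning-tree and canonical-form criteria
    all prune entire enumeration branches (each is inherited by every
    extension of a failing subtree), and surviving subtrees are
    reconstructed and reported when closed.
    """
    params = params or MiningParams()
    if tree is None:
        tree = build_k_path_tree(db, params)
    k = tree.k
    stats = stats if stats is not None else MiningStats()
    results: list[Pattern] = []
    max_vertices = (None if params.max_pattern_size is None
                    else params.max_pattern_size + 1)

    def consider(subtree: Subtree) -> Subtree | None:
        """Apply criteria 1-3; return the subtree if it survives."""
        stats.candidates += 1
        if _n_graphs(subtree.occ) < params.min_support:
            stats.failed_support += 1
            return None
        h = subtree.h_labels
        if len(set(h)) != len(h):
            stats.failed_spanning += 1
            return None
        pattern = reconstruct_pattern(subtree, db)
        if lmdf_tree(pattern, k) != subtree.tree_edges():
            stats.failed_canonical += 1
            return None
        pattern.canonical_code = lmdf_encode(pattern, k)
        if is_closed(pattern, db):
            if (params.max_pattern_size is None
                    or pattern.n_edges <= params.max_pattern_size):
                stats.patterns += 1
                results.append(pattern)
        else:
            stats.not_closed += 1
        return subtree

    def grow(subtree: Subtree) -> None:
        if max_vertices is not None and len(subtree.nodes) + 1 >= max_vertices:
            return
        rm = subtree.rightmost_path()
        positions = [-1] + rm
        for pos_i, pos in enumerate(positions):
            kp_node = tree.root if pos == -1 else subtree.nodes[pos]
            # when attaching above the right-most leaf, the new sibling must
            # sort after the existing right-most child
            bound = (subtree.nodes[positions[pos_i + 1]].label
                     if pos_i + 1 < len(positions) else -1)
            for b in sorted(kp_node.children):
                if b <= bound:
                    continue
                child = kp_node.children[b]
                new_occ = subtree.occ & child.occ
                ext = Subtree(subtree.nodes + [child],
                              subtree.parents + [pos], new_occ)
                survivor = consider(ext)
                if survivor is not None:
                    grow(survivor)

    for a in sorted(tree.root.children):
        node = tree.root.children[a]
        seed = Subtree([node], [-1], node.occ)
        survivor = consider(seed)
        if survivor is not None:
            grow(survivor)

    results.sort(key=lambda p: p.canonical_code)
    return results
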