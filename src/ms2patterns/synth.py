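"""Synthetic spectral libraries with known planted structure, plus
independent brute-force oracles.

The generator emulates what a small MS/MS library looks like to the
m/z-difference pipeline: each spectrum is a peak list obtained by
subtracting subset-sums of neutral losses from a precursor mass, with
ppm-scale Gaussian mass jitter and uniform noise peaks.  A *planted* AFG is
realized in a chosen subset of carrier spectra, whose ground truth (carrier
ids and exact edge masses) is returned alongside the library.  Background
mass draws are rejection-sampled away from the planted loss values so that
the planted support is exact and recovery can be asserted without slack;
real libraries of course do share losses between unrelated compounds, which
is precisely the situation the planted carriers model.

The brute-force miner enumerates every rooted induced sub-AFG of every
graph directly from the definitions (induced subgraph, graph-counted
support, closedness) and is the oracle against which the k-path-tree miner
is validated on small databases.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .binning import BinningParams, EdgeLabel
from .chem import Formula, combination_formulas, generate_formulas
from .graphs import GraphDB, build_graph
from .mining import Pattern, canonical_key
from .spectra import Peak, Spectrum

# exact monoisotopic masses of the default neutral-loss vocabulary
_LOSS_DEFS = [
    ("H2O", {"H": 2, "O": 1}),
    ("NH3", {"N": 1, "H": 3}),
    ("CO", {"C": 1, "O": 1}),
    ("C2H4", {"C": 2, "H": 4}),
    ("CH2O2", {"C": 1, "H": 2, "O": 2}),
    ("CO2", {"C": 1, "O": 2}),
    ("CH4S", {"C": 1, "H": 4, "S": 1}),
    ("C2H2O", {"C": 2, "H": 2, "O": 1}),
]


@dataclass(frozen=True)
class LossAlphabet:
    """Neutral-loss vocabulary available to the generator.

    Loss masses must be separated by more than 0.02 Da so that distinct
    losses can never share a bin at the default tolerances.
    """

    losses: tuple[tuple[Formula, float], ...]
    weights: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        masses = sorted(m for _, m in self.losses)
        for a, b in zip(masses, masses[1:]):
            if b - a <= 0.02:
                raise ValueError("loss masses closer than 0.02 Da")
        if self.weights and len(self.weights) != len(self.losses):
            raise ValueError("one weight per loss required")

    @classmethod
    def default(cls) -> "LossAlphabet":
        losses = tuple((Formula.from_counts(c), Formula.from_counts(c).mono_mass)
                       for _, c in _LOSS_DEFS)
        return cls(losses)


@dataclass(frozen=True)
class PlantedAFG:
    """A planted fragmentation pattern given by its vertex offsets.

    ``offsets`` are the exact root-to-vertex mass differences (Da below the
    pattern root); ``edges`` lists the pattern's edges as offset pairs
    (root = offset 0.0), whose losses are the offset differences.
    """

    name: str
    offsets: tuple[float, ...]
    edges: tuple[tuple[float, float], ...]

    def all_masses(self) -> set[float]:
        vals = {round(b - a, 6) for a, b in self.edges}
        vals.update(round(o, 6) for o in self.offsets)
        return vals


_H2O = 18.010565
_NH3 = 17.026549
_CO = 27.994915
_CO2 = 43.989829
_VAL = 99.068414  # C5H9NO, valine residue

#: planted-pattern templates cycled by the benchmark (all offset
#: differences are either formula-feasible in 14-200 Da or below 14 Da)
TEMPLATES: tuple[PlantedAFG, ...] = (
    PlantedAFG("double-water", (_H2O, 2 * _H2O),
               ((0.0, _H2O), (0.0, 2 * _H2O), (_H2O, 2 * _H2O))),
    PlantedAFG("amine-star", (_NH3, _CO),
               ((0.0, _NH3), (0.0, _CO))),
    PlantedAFG("water-co2", (_H2O, _H2O + _CO2),
               ((0.0, _H2O), (0.0, _H2O + _CO2), (_H2O, _H2O + _CO2))),
    PlantedAFG("peptide-like", (_NH3, _NH3 + _CO, _VAL),
               ((0.0, _NH3), (0.0, _NH3 + _CO), (0.0, _VAL),
                (_NH3, _NH3 + _CO), (_NH3, _VAL), (_NH3 + _CO, _VAL))),
    # sequential H2O / CO / CO2 / H2O losses: a 5-vertex complete DAG whose
    # every pairwise difference is formula-feasible (sugar-acid style)
    PlantedAFG("acid-cascade",
               tuple(_ACID := (_H2O, _H2O + _CO, _H2O + _CO + _CO2,
                               2 * _H2O + _CO + _CO2)),
               tuple((a, b)
                     for i, a in enumerate((0.0,) + _ACID)
                     for b in _ACID[i:])),
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions of one synthetic library.

    Defaults describe a small de-novo style collection: 20 compounds in the
    350-900 Da precursor range, one pattern planted in 5 of them, 5 noise
    peaks per spectrum and 3 ppm mass jitter (Orbitrap-scale accuracy).
    """

    n_spectra: int = 20
    precursor_range: tuple[float, float] = (350.0, 900.0)
    planted_patterns: tuple[tuple[PlantedAFG, int], ...] = ((TEMPLATES[0], 5),)
    noise_peaks: int = 5
    mass_jitter_ppm: float = 3.0
    seed: int = 0
    background: str = "private"  # or "families"
    background_losses: int = 3
    background_peaks: int = 4
    family_size: int = 3
    family_depth: int = 4
    planted_intensity_band: tuple[float, float] = (60.0, 100.0)

    def __post_init__(self) -> None:
        lo = self.precursor_range[0]
        for afg, n in self.planted_patterns:
            if lo - max(afg.offsets, default=0.0) <= 50.0:
                raise ValueError(
                    f"planted pattern {afg.name}: fragment masses would fall "
                    "below 50 Da at the lower precursor bound")
            if n > self.n_spectra:
                raise ValueError("more carriers than spectra")
        if self.background not in ("private", "families"):
            raise ValueError("background must be 'private' or 'families'")


@dataclass
class GroundTruth:
    carriers: dict[str, list[str]] = field(default_factory=dict)
    patterns: dict[str, PlantedAFG] = field(default_factory=dict)


def _safe_draw(rng: np.random.Generator, draw, existing_mzs: list[float],
               forbidden: set[float], margin: float = 0.05) -> float:
    """Draw until no difference to an existing peak sits within ``margin``
    of a planted loss value (keeps the planted ground truth exact)."""
    for _ in range(200):
        x = draw()
        ok = True
        for m in existing_mzs:
            d = abs(m - x)
            if any(abs(d - f) < margin for f in forbidden):
                ok = False
                break
        if ok:
            return x
    raise RuntimeError("could not place a background mass away from the "
                       "planted alphabet")


def _feasible_cascade(rng: np.random.Generator, masses: list[float],
                      depth: int) -> tuple[float, ...]:
    """Offsets of a sequential loss cascade whose every pairwise mass
    difference is formula-feasible (as real fragment cascades are)."""
    for _ in range(100):
        losses = [masses[i] for i in rng.integers(0, len(masses), depth)]
        pts = [0.0]
        for l in losses:
            pts.append(pts[-1] + l)
        ok = True
        for i, a in enumerate(pts):
            for b in pts[i + 1:]:
                d = b - a
                if 14.0 <= d <= 200.0:
                    tol = max(0.005, d * 15e-6)
                    if not (generate_formulas(d, tol)
                            or combination_formulas(d, tol)):
                        ok = False
                        break
            if not ok:
                break
        if ok:
            return tuple(pts[1:])
    raise RuntimeError("no feasible loss cascade found")


def generate_library(spec: SyntheticSpec) -> tuple[list[Spectrum], GroundTruth]:
    """Simulate a spectral library with the planted structure of ``spec``.

    Background (non-carrier) spectra come in two flavours.  ``private``
    gives every background compound its own random losses, rejection-
    sampled away from the planted alphabet: no structure is shared outside
    the carriers, so the planted support is exact (used by the recovery
    benchmark).  ``families`` groups backgrounds into small families
    sharing one feasible loss cascade, emulating the shared fragmentation
    chemistry of related compounds in real libraries (used to study
    triangle closure at realistic graph density).
    """
    rng = np.random.default_rng(spec.seed)
    truth = GroundTruth()
    ids = [f"S{i:03d}" for i in range(spec.n_spectra)]

    forbidden: set[float] = set()
    for afg, _ in spec.planted_patterns:
        forbidden |= afg.all_masses()

    # assign disjoint carrier sets
    free = list(range(spec.n_spectra))
    carrier_of: dict[int, PlantedAFG] = {}
    for afg, n in spec.planted_patterns:
        chosen = rng.choice(len(free), size=n, replace=False)
        members = sorted(free[c] for c in chosen)
        truth.carriers[afg.name] = [ids[m] for m in members]
        truth.patterns[afg.name] = afg
        for m in members:
            carrier_of[m] = afg
        free = [f for f in free if f not in members]

    family_offsets: dict[int, tuple[float, ...]] = {}
    if spec.background == "families":
        masses = [m for _, m in LossAlphabet.default().losses]
        for start in range(0, len(free), spec.family_size):
            cascade = _feasible_cascade(rng, masses, spec.family_depth)
            for m in free[start:start + spec.family_size]:
                family_offsets[m] = cascade

    lo_i, hi_i = spec.planted_intensity_band
    spectra: list[Spectrum] = []
    for i in range(spec.n_spectra):
        precursor = float(rng.uniform(*spec.precursor_range))
        mzs: list[float] = [precursor]
        intens: list[float] = [float(rng.uniform(lo_i, hi_i))]
        if i in carrier_of:
            for off in carrier_of[i].offsets:
                mzs.append(precursor - off)
                intens.append(float(rng.uniform(lo_i, hi_i)))
        elif i in family_offsets:
            for off in family_offsets[i]:
                mzs.append(precursor - off)
                intens.append(float(rng.uniform(lo_i, hi_i)))
        else:
            # unstructured compound: subset-sums of its own random losses
            losses = []
            for _ in range(spec.background_losses):
                losses.append(_safe_draw(
                    rng, lambda: float(rng.uniform(15.0, 120.0)), mzs,
                    forbidden))
            sums = sorted({round(sum(c), 6)
                           for r in range(1, len(losses) + 1)
                           for c in itertools.combinations(losses, r)})
            take = min(spec.background_peaks, len(sums))
            for off in rng.choice(len(sums), size=take, replace=False):
                m = precursor - sums[off]
                if m > 50 and not any(
                        any(abs(abs(m - e) - f) < 0.05 for f in forbidden)
                        for e in mzs):
                    mzs.append(m)
                    intens.append(float(rng.uniform(lo_i, hi_i)))
        for _ in range(spec.noise_peaks):
            m = _safe_draw(
                rng, lambda: float(rng.uniform(50.0, precursor - 5.0)), mzs,
                forbidden)
            mzs.append(m)
            intens.append(float(rng.uniform(5.0, 40.0)))
        if spec.mass_jitter_ppm > 0:
            mzs = [m + float(rng.normal(0.0, m * spec.mass_jitter_ppm * 1e-6))
                   for m in mzs]
        spectra.append(Spectrum(
            id=ids[i], precursor_mz=precursor,
            peaks=[Peak(m, h) for m, h in zip(mzs, intens)],
            metadata={"synthetic": True}))
    return spectra, truth


# ---------------------------------------------------------------------------
# random small databases with exact arithmetic (oracle fodder)


def random_graphdb(rng: np.random.Generator, *, max_graphs: int = 8,
                   max_vertices: int = 8, min_count: int = 2) -> GraphDB:
    """A random database of small, exactly valid fragmentation graphs.

    Vertices live on an integer mass lattice (step 25 Da) so that all
    differences are exact; labels are the lattice differences of at least
    3 steps (mirroring the low-mass discard) present in at least
    ``min_count`` spectra.  On such databases the closure property holds
    exactly, which is the regime the k-path-tree miner is defined for,
    while graph topologies still vary freely.
    """
    step, floor_steps, levels = 25.0, 3, 9
    n_graphs = int(rng.integers(3, max_graphs + 1))
    vertex_sets = []
    for _ in range(n_graphs):
        n_v = int(rng.integers(3, min(max_vertices, levels) + 1))
        vs = sorted(rng.choice(levels, size=n_v, replace=False).tolist())
        vertex_sets.append(vs)

    diff_spectra: dict[int, set[int]] = {}
    for gi, vs in enumerate(vertex_sets):
        for a, b in itertools.combinations(vs, 2):
            if b - a >= floor_steps:
                diff_spectra.setdefault(b - a, set()).add(gi)
    labels = []
    for d in sorted(diff_spectra):
        if len(diff_spectra[d]) >= min_count:
            labels.append(EdgeLabel(len(labels), d * step - 0.5,
                                    d * step + 0.5, d * step,
                                    len(diff_spectra[d])))
    spectra = [
        Spectrum(id=f"G{gi}", precursor_mz=200.0 + step * max(vs),
                 peaks=[Peak(200.0 + step * v, 100.0) for v in vs])
        for gi, vs in enumerate(vertex_sets)
    ]
    return GraphDB([build_graph(s, labels) for s in spectra], labels,
                   BinningParams())


# ---------------------------------------------------------------------------
# brute-force oracles


@dataclass(frozen=True)
class _Candidate:
    key: tuple                      # canonical min-path code
    names: tuple[tuple, ...]        # vertex names (min label paths)
    edges: tuple[tuple[tuple, tuple, int], ...]  # edges on names


def _enumerate_afgs(g, gi: int):
    """All induced sub-AFGs (>= 1 edge) of one graph, canonically named."""
    elab = g.edge_label()
    for r in range(2, g.n_vertices + 1):
        for subset in itertools.combinations(range(g.n_vertices), r):
            sv = set(subset)
            edges = [(u, v, lab) for (u, v), lab in elab.items()
                     if u in sv and v in sv]
            if len(edges) < r - 1:
                continue
            targets = {v for _, v, _ in edges}
            roots = [v for v in subset if v not in targets]
            if len(roots) != 1:
                continue
            root = roots[0]
            # flow check: reach everything from the root
            adj: dict[int, list[tuple[int, int]]] = {v: [] for v in subset}
            for u, v, lab in edges:
                adj[u].append((lab, v))
            seen = {root}
            stack = [root]
            while stack:
                for _, t in adj[stack.pop()]:
                    if t not in seen:
                        seen.add(t)
                        stack.append(t)
            if seen != sv:
                continue
            key = canonical_key(root, list(subset), edges)
            yield key, root, subset, edges


def _embeds(small: _Candidate, big: _Candidate) -> bool:
    """Subgraph embedding test between canonically named AFGs; vertex
    images are forced by the unique out-edge labels once the root image is
    chosen."""
    out: dict[tuple, dict[int, tuple]] = {n: {} for n in big.names}
    for u, v, lab in big.edges:
        out[u][lab] = v
    order = sorted(small.edges, key=lambda e: (len(e[0]), e[0]))
    for start in big.names:
        mapping: dict[tuple, tuple] = {(): start}  # root has the empty name
        ok = True
        for u, v, lab in order:
            mu = mapping.get(u)
            if mu is None:
                ok = False
                break
            mv = out[mu].get(lab)
            if mv is None or (v in mapping and mapping[v] != mv):
                ok = False
                break
            mapping[v] = mv
        if ok and len(set(mapping.values())) == len(mapping):
            return True
    return False


def brute_force_mine(db: GraphDB, min_supp: int) -> dict[tuple, frozenset[int]]:
    """Closed frequent induced sub-AFGs straight from the definitions.

    Enumerates every rooted induced flow subgraph of every graph, groups by
    exhaustive canonical naming, keeps those supported by at least
    ``min_supp`` distinct graphs, and discards any pattern for which a
    strictly larger frequent pattern with identical support embeds it.
    Intended purely as a test oracle; refuses graphs above 8 vertices.
    """
    for g in db.graphs:
        if g.n_vertices > 8:
            raise ValueError("brute-force oracle limited to <= 8 vertices")
    support: dict[tuple, set[int]] = {}
    shape: dict[tuple, _Candidate] = {}
    for gi, g in enumerate(db.graphs):
        for key, root, subset, edges in _enumerate_afgs(g, gi):
            support.setdefault(key, set()).add(gi)
            if key not in shape:
                shape[key] = _shape_from(root, subset, edges)
    frequent = {k: frozenset(v) for k, v in support.items()
                if len(v) >= min_supp}
    closed: dict[tuple, frozenset[int]] = {}
    for k, supp in frequent.items():
        cand = shape[k]
        dominated = any(
            ko != k and so == supp
            and (len(shape[ko].names) > len(cand.names)
                 or len(shape[ko].edges) > len(cand.edges))
            and _embeds(cand, shape[ko])
            for ko, so in frequent.items())
        if not dominated:
            closed[k] = supp
    return closed


def _shape_from(root: int, subset, edges) -> _Candidate:
    from .mining import _check_afg, _min_paths
    adj = _check_afg(root, list(subset), edges)
    names = _min_paths(root, adj)
    e = tuple(sorted((names[u], names[v], lab) for u, v, lab in edges))
    return _Candidate(e, tuple(sorted(names.values())), e)


def pattern_covers_planted(p: Pattern, db: GraphDB, planted: PlantedAFG,
                           tol: float = 0.02) -> bool:
    """Does a mined pattern contain the planted AFG?

    Pattern vertices are matched to planted offsets through their root-edge
    label bins; every planted edge must then map to a pattern edge whose
    bin covers the edge's loss mass (within bin bounds or ``tol`` of the
    bin center, absorbing mass jitter at bin edges).
    """
    labs = {l.id: l for l in db.labels}

    def hits(lab: int, value: float) -> bool:
        l = labs[lab]
        return value in l or abs(l.center - value) < tol

    vmap: dict[float, int] = {0.0: 0}
    for off, (v, lab) in itertools.product(
            planted.offsets, p.h_labels().items()):
        if hits(lab, off):
            vmap.setdefault(round(off, 6), v)
    if len(vmap) != len(planted.offsets) + 1:
        return False
    edge_map = {(u, v): lab for u, v, lab in p.edges}
    for a, b in planted.edges:
        u, v = vmap.get(round(a, 6)), vmap.get(round(b, 6))
        lab = edge_map.get((u, v))
        if lab is None or not hits(lab, b - a):
            return False
    return True


def recover_planted(db: GraphDB, patterns: list[Pattern],
                    planted: PlantedAFG, carrier_ids: set[str]
                    ) -> Pattern | None:
    """The mined pattern recovering the planted AFG with exactly the
    carrier support, or None."""
    ids = [g.spectrum_id for g in db.graphs]
    for p in patterns:
        if {ids[g] for g in p.support} == set(carrier_ids) \
                and pattern_covers_planted(p, db, planted):
            return p
    return None


def miner_output_keys(patterns: list[Pattern]) -> dict[tuple, frozenset[int]]:
    """Canonical min-path keys of a miner result, for oracle comparison."""
    return {canonical_key(p.root, p.vertices, p.edges): p.support
            for p in patterns}


def are_isomorphic(g1: tuple[int, list, list], g2: tuple[int, list, list]
                   ) -> bool:
    """Exhaustive label-preserving isomorphism test between rooted graphs
    given as (root, vertices, edges); independent of any canonical code."""
    r1, v1, e1 = g1
    r2, v2, e2 = g2
    if len(v1) != len(v2) or len(e1) != len(e2):
        return False
    others1 = [v for v in v1 if v != r1]
    others2 = [v for v in v2 if v != r2]
    set2 = {(u, v, lab) for u, v, lab in e2}
    for perm in itertools.permutations(others2):
        f = dict(zip(others1, perm))
        f[r1] = r2
        if all((f[u], f[v], lab) in set2 for u, v, lab in e1):
            return True
    return False
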