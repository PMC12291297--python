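"""Molecular formulas for neutral losses.

Candidate neutral formulas are enumerated exhaustively over a configurable
element set (CHNOPS by default) within a mass tolerance, and filtered by the
Senior graph-realizability conditions: the sum of valences must be even
(handshake lemma) and at least ``2 * (atom count - 1)`` (a connected
multigraph on n atoms needs n - 1 edges).  An m/z difference may also span
two consecutive or parallel fragmentation steps, so sums of two realizable
formulas are reported as *combination* formulas (e.g. H4O2 = H2O + H2O),
even when the summed formula is not realizable by itself.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

# Monoisotopic atomic masses (Da), CODATA-derived, 6+ decimals.
MONO_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.007825,
    "N": 14.003074,
    "O": 15.994915,
    "P": 30.973762,
    "S": 31.972071,
    "F": 18.998403,
    "Cl": 34.968853,
    "Br": 78.918338,
    "I": 126.904473,
}

# Standard maximum valences used by the Senior conditions.
VALENCE: dict[str, int] = {
    "C": 4, "H": 1, "N": 3, "O": 2, "P": 5, "S": 6,
    "F": 1, "Cl": 1, "Br": 1, "I": 1,
}

DEFAULT_ELEMENTS: tuple[str, ...] = ("C", "H", "N", "O", "P", "S")

# Hill-ish display order: C, H, then alphabetical.
_DISPLAY_ORDER = ("C", "H", "Br", "Cl", "F", "I", "N", "O", "P", "S")


@dataclass(frozen=True)
class Formula:
    """A neutral molecular formula with its monoisotopic mass.

    ``is_combination`` flags formulas obtained as a sum of two simpler
    realizable formulas; ``parts`` then holds the summands.
    """

    counts: tuple[tuple[str, int], ...]
    mono_mass: float
    is_combination: bool = False
    parts: tuple["Formula", ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if not any(n > 0 for _, n in self.counts):
            raise ValueError("formula must contain at least one atom")

    @classmethod
    def from_counts(cls, counts: dict[str, int], *, is_combination: bool = False,
                    parts: tuple["Formula", ...] = ()) -> "Formula":
        items = tuple(sorted((e, n) for e, n in counts.items() if n > 0))
        mass = sum(n * MONO_MASS[e] for e, n in items)
        return cls(items, mass, is_combination, parts)

    @property
    def count_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __add__(self, other: "Formula") -> "Formula":
        merged = self.count_dict
        for e, n in other.counts:
            merged[e] = merged.get(e, 0) + n
        return Formula.from_counts(merged, is_combination=True, parts=(self, other))

    def __str__(self) -> str:
        d = self.count_dict
        out = []
        for e in _DISPLAY_ORDER:
            n = d.get(e, 0)
            if n == 1:
                out.append(e)
            elif n > 1:
                out.append(f"{e}{n}")
        return "".join(out)

    def __repr__(self) -> str:  # pragma: no cover - debugging nicety
        return f"Formula({self!s}, {self.mono_mass:.6f})"


def senior_ok(counts: dict[str, int]) -> bool:
    """Senior's necessary conditions for a connected molecular (multi)graph."""
    atoms = sum(counts.values())
    if atoms == 0:
        return False
    vsum = sum(VALENCE[e] * n for e, n in counts.items())
    return vsum % 2 == 0 and vsum >= 2 * (atoms - 1)


def generate_formulas(mass: float, tol: float,
                      elements: tuple[str, ...] = DEFAULT_ELEMENTS) -> list[Formula]:
    """All Senior-realizable formulas with |mono_mass - mass| <= tol.

    Exhaustive enumeration over element-count vectors; hydrogen (when in the
    element set) is solved last against the residual mass, which keeps the
    loop over the heavy elements only.  Results are sorted by increasing
    |mono_mass - mass|, ties by formula string.
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    heavy = [e for e in elements if e != "H"]
    has_h = "H" in elements
    mh = MONO_MASS["H"]
    found: list[Formula] = []
    ranges = [range(int((mass + tol) // MONO_MASS[e]) + 1) for e in heavy]
    for combo in itertools.product(*ranges):
        m0 = sum(n * MONO_MASS[e] for e, n in zip(heavy, combo))
        if m0 > mass + tol:
            continue
        if has_h:
            lo = int(np.ceil((mass - tol - m0) / mh))
            hi = int(np.floor((mass + tol - m0) / mh))
            h_counts = range(max(lo, 0), hi + 1)
        else:
            h_counts = (0,) if abs(m0 - mass) <= tol else ()
        for nh in h_counts:
            counts = {e: n for e, n in zip(heavy, combo) if n > 0}
            if nh:
                counts["H"] = nh
            if not counts or not senior_ok(counts):
                continue
            found.append(Formula.from_counts(counts))
    found.sort(key=lambda f: (abs(f.mono_mass - mass), str(f)))
    return found


@lru_cache(maxsize=8)
def _formula_table(max_mass: float, elements: tuple[str, ...]) -> tuple[np.ndarray, tuple[Formula, ...]]:
    """All realizable formulas up to ``max_mass``, sorted by mass.

    Shared cache for combination search; built once per (mass bound,
    element set).
    """
    formulas = generate_formulas(max_mass / 2 + 0.5, max_mass / 2 + 0.5, elements)
    formulas = [f for f in formulas if f.mono_mass <= max_mass]
    formulas.sort(key=lambda f: (f.mono_mass, str(f)))
    masses = np.array([f.mono_mass for f in formulas])
    return masses, tuple(formulas)


def combination_formulas(mass: float, tol: float,
                         elements: tuple[str, ...] = DEFAULT_ELEMENTS,
                         max_combination: int = 2) -> list[Formula]:
    """Sums of up to ``max_combination`` realizable formulas matching ``mass``.

    Only depth-2 sums are enumerated (pairs); deeper nesting explodes
    combinatorially and two steps already cover consecutive/parallel losses
    such as H2O + H2O or CO + H2O.  The same summed formula may be returned
    once per distinct decomposition (e.g. CH2O2 as CO + H2O and as H2 + CO2),
    since the decomposition is what carries the chemical reading.
    """
    if max_combination < 2:
        return []
    # Round the table bound up to a multiple of 100 Da so the cached table is
    # shared across bins instead of being rebuilt per query mass.
    bound = 100.0 * float(np.ceil((mass + 1.0) / 100.0))
    masses, formulas = _formula_table(bound, elements)
    out: dict[tuple, Formula] = {}
    for i, f1 in enumerate(formulas):
        if f1.mono_mass > mass / 2 + tol:
            break
        lo = np.searchsorted(masses, mass - tol - f1.mono_mass, side="left")
        hi = np.searchsorted(masses, mass + tol - f1.mono_mass, side="right")
        for j in range(max(lo, i), hi):
            combo = f1 + formulas[j]
            key = (combo.counts, f1.counts, formulas[j].counts)
            out.setdefault(key, combo)
    res = list(out.values())
    res.sort(key=lambda f: (abs(f.mono_mass - mass), str(f)))
    return res
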