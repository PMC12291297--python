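"""The shared edge-label alphabet: binned m/z differences.

All pairwise m/z differences of the reduced library are pooled and binned by
a Gaussian kernel density estimate whose bandwidth follows the instrument
accuracy, h(d) = max(dmz, d * ppm * 1e-6): relative (ppm) at high mass with
an absolute floor (dmz) at low mass.  Bins are delimited by consecutive
local minima of the density, filtered by the number of distinct spectra
contributing to them (f), merged when nearly touching, and finally annotated
with candidate neutral formulas inside the chemically interpretable 14-200
Da window.  The resulting labels are the alphabet shared by every
fragmentation graph of the library.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .chem import DEFAULT_ELEMENTS, Formula, combination_formulas, generate_formulas
from .spectra import Spectrum

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BinningParams:
    """Parameters of the difference-binning stage.

    ppm: relative kernel bandwidth / formula tolerance (paper default 15).
    dmz: absolute bandwidth floor in Da for low m/z differences.
    min_count: minimum number of distinct spectra per label (f).
    formula_window: mass window (Da) in which a label must carry at least
        one candidate formula to be retained; differences above the window
        are kept unannotated, below it discarded.
    max_combination: maximum number of summands in combination formulas.
    """

    ppm: float = 15.0
    dmz: float = 0.005
    min_count: int = 2
    formula_window: tuple[float, float] = (14.0, 200.0)
    max_combination: int = 2
    elements: tuple[str, ...] = DEFAULT_ELEMENTS

    def __post_init__(self) -> None:
        if self.ppm <= 0 or self.dmz <= 0 or self.min_count < 1:
            raise ValueError("require ppm > 0, dmz > 0, min_count >= 1")

    def bandwidth(self, d: float | np.ndarray) -> float | np.ndarray:
        return np.maximum(self.dmz, np.asarray(d) * self.ppm * 1e-6)


@dataclass(frozen=True)
class EdgeLabel:
    """A binned m/z difference: one symbol of the edge-label alphabet.

    The half-open interval [lower, upper) makes assignment of a difference
    to a label unambiguous; ``center`` is the density mode of the bin and
    ``count`` the number of distinct spectra contributing to it.
    """

    id: int
    lower: float
    upper: float
    center: float
    count: int
    formulas: tuple[Formula, ...] = ()

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("require lower < upper")

    def __contains__(self, value: float) -> bool:
        return self.lower <= value < self.upper

    @property
    def best_formula(self) -> Formula | None:
        """Formula whose mass is closest to the bin center (display pick)."""
        if not self.formulas:
            return None
        return min(self.formulas, key=lambda f: (abs(f.mono_mass - self.center),
                                                 str(f)))


class Difference(NamedTuple):
    """One observed m/z difference between two peaks of one spectrum."""

    value: float
    spectrum_id: str
    source_peak: int  # index of the heavier peak
    target_peak: int  # index of the lighter peak


def collect_differences(spectra: Sequence[Spectrum]) -> list[Difference]:
    """All ordered-pair (heavier - lighter) differences, per spectrum.

    A spectrum with p peaks contributes p*(p-1)/2 differences.  Spectra are
    expected to have gone through peak selection already.
    """
    out: list[Difference] = []
    for s in spectra:
        mz = s.mzs
        for j in range(len(mz)):          # j: lighter
            for i in range(j + 1, len(mz)):  # i: heavier
                out.append(Difference(float(mz[i] - mz[j]), s.id, i, j))
    return out


def _kde_bins(values: np.ndarray, spectra_ids: list, params: BinningParams
              ) -> list[tuple[float, float, float, set]]:
    """Variable-bandwidth Gaussian KDE binning of difference values.

    Returns (lower, upper, center, spectrum-id set) per bin.  The data are
    first split into well-separated chunks (gap > 4 bandwidths, where the
    density is numerically zero) so the KDE grid stays local; within a
    chunk, bins are delimited by the interior local minima of the density
    and the mode of each bin is its center.
    """
    order = np.argsort(values, kind="stable")
    v = values[order]
    ids = [spectra_ids[i] for i in order]
    bw = np.asarray(params.bandwidth(v), dtype=float)

    # chunk split where the gap exceeds 4x the larger neighbouring bandwidth
    gaps = np.diff(v)
    split = np.where(gaps > 4.0 * np.maximum(bw[:-1], bw[1:]))[0] + 1
    bins: list[tuple[float, float, float, set]] = []
    for lo, hi in zip(np.r_[0, split], np.r_[split, len(v)]):
        cv, cbw, cids = v[lo:hi], bw[lo:hi], ids[lo:hi]
        hmin = float(cbw.min())
        grid = np.arange(cv[0] - 3 * cbw[0], cv[-1] + 3 * cbw[-1] + hmin / 5,
                         hmin / 5)
        dens = np.zeros_like(grid)
        for x, h in zip(cv, cbw):
            dens += np.exp(-0.5 * ((grid - x) / h) ** 2) / h
        interior = np.arange(1, len(grid) - 1)
        minima = interior[(dens[interior] < dens[interior - 1])
                          & (dens[interior] <= dens[interior + 1])]
        cuts = [grid[0]] + [float(grid[m]) for m in minima] + [float(grid[-1]) + hmin]
        for a, b in zip(cuts, cuts[1:]):
            mask = (cv >= a) & (cv < b)
            if not mask.any():
                continue
            sub = (grid >= a) & (grid < b)
            center = float(grid[sub][np.argmax(dens[sub])])
            members = {cids[k] for k in np.where(mask)[0]}
            # interval bounds hug the member data (one bandwidth of slack)
            mvals = cv[mask]
            lo_b = max(float(a), float(mvals[0] - params.bandwidth(mvals[0])))
            up_b = min(float(b), float(mvals[-1] + params.bandwidth(mvals[-1])))
            bins.append((lo_b, up_b, center, members))
    return bins


def estimate_bins(diffs: Sequence[Difference], params: BinningParams
                  ) -> list[EdgeLabel]:
    """Bin raw differences into disjoint, frequency-filtered edge labels.

    Bins supported by fewer than ``params.min_count`` distinct spectra are
    dropped; adjacent surviving bins whose boundary gap is below the local
    bandwidth are merged (counts pooled, center re-estimated as the
    count-weighted mean of the merged modes).
    """
    if not diffs:
        return []
    values = np.array([d.value for d in diffs])
    ids = [d.spectrum_id for d in diffs]
    raw = _kde_bins(values, ids, params)
    raw = [b for b in raw if len(b[3]) >= params.min_count]
    raw.sort(key=lambda b: b[2])

    merged: list[tuple[float, float, float, set]] = []
    for b in raw:
        if merged:
            lo_p, up_p, c_p, m_p = merged[-1]
            gap = b[0] - up_p
            if gap < params.bandwidth((up_p + b[0]) / 2):
                n_p, n_b = len(m_p), len(b[3])
                center = (c_p * n_p + b[2] * n_b) / (n_p + n_b)
                merged[-1] = (lo_p, b[1], center, m_p | b[3])
                continue
        merged.append(b)

    return [EdgeLabel(i, lo, up, c, len(m))
            for i, (lo, up, c, m) in enumerate(merged)]


def annotate_labels(bins: Sequence[EdgeLabel], params: BinningParams
                    ) -> list[EdgeLabel]:
    """Attach candidate neutral formulas and apply the feasibility filter.

    Inside the formula window a label keeps single formulas plus
    combination sums within the local bandwidth tolerance, and is discarded
    when none exists; below the window it is discarded; above the window it
    is kept without formulas.  Ids are reassigned densely by ascending
    center.
    """
    lo_w, hi_w = params.formula_window
    kept: list[EdgeLabel] = []
    for b in sorted(bins, key=lambda b: b.center):
        if b.center < lo_w:
            continue
        if b.center > hi_w:
            kept.append(replace(b, id=len(kept), formulas=()))
            continue
        tol = float(params.bandwidth(b.center))
        singles = generate_formulas(b.center, tol, params.elements)
        combos = combination_formulas(b.center, tol, params.elements,
                                      params.max_combination)
        seen = {f.counts for f in singles}
        formulas = tuple(singles) + tuple(
            c for c in combos if c.counts not in seen)
        if not formulas:
            log.debug("label at %.4f Da: no feasible formula, discarded",
                      b.center)
            continue
        kept.append(replace(b, id=len(kept), formulas=formulas))
    return kept


def build_labels(spectra: Sequence[Spectrum], params: BinningParams
                 ) -> list[EdgeLabel]:
    """collect -> estimate -> annotate, the full alphabet construction."""
    return annotate_labels(estimate_bins(collect_differences(spectra), params),
                           params)


def assign_label(labels: Sequence[EdgeLabel], value: float) -> EdgeLabel | None:
    """The unique label whose interval contains ``value``, or None."""
    lows = [l.lower for l in labels]
    i = np.searchsorted(lows, value, side="right") - 1
    if i >= 0 and value < labels[i].upper:
        return labels[i]
    return None


def labels_to_frame(labels: Sequence[EdgeLabel]) -> pd.DataFrame:
    rows = []
    for l in labels:
        rows.append({
            "id": l.id, "lower": l.lower, "upper": l.upper,
            "center": l.center, "count": l.count,
            "formulas": "|".join(_fmt(f) for f in l.formulas),
        })
    return pd.DataFrame(rows, columns=["id", "lower", "upper", "center",
                                       "count", "formulas"])


def _fmt(f: Formula) -> str:
    if f.is_combination and f.parts:
        return "+".join(str(p) for p in f.parts)
    return str(f)


def write_labels(labels: Sequence[EdgeLabel], path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        payload = [{
            "id": l.id, "lower": l.lower, "upper": l.upper,
            "center": l.center, "count": l.count,
            "formulas": [_fmt(f) for f in l.formulas],
        } for l in labels]
        path.write_text(json.dumps(payload, indent=1))
    else:
        labels_to_frame(labels).to_csv(path, sep="\t", index=False)
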