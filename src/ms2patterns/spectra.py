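"""Reading, writing and preprocessing of MS/MS spectral libraries.

A library is a list of :class:`Spectrum` objects (one per compound), read
from Mascot Generic Format (MGF).  Before graph building each spectrum is
reduced to its most intense fragment ions (15 by default), and spectra of
one compound acquired at several collision energies can be merged into a
single enriched peak list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from pyteomics import mgf as _mgf

log = logging.getLogger(__name__)


class Peak(NamedTuple):
    mz: float
    intensity: float


@dataclass
class Spectrum:
    """One MS/MS spectrum: precursor m/z plus a centroided peak list.

    Peaks are kept sorted strictly ascending by m/z; peaks with identical
    m/z are pooled (intensities summed) on construction.
    """

    id: str
    precursor_mz: float
    peaks: list[Peak]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError(f"spectrum {self.id}: precursor_mz must be > 0")
        for p in self.peaks:
            if p.mz <= 0 or p.intensity < 0:
                raise ValueError(f"spectrum {self.id}: invalid peak {p}")
        pooled: dict[float, float] = {}
        for p in self.peaks:
            pooled[p.mz] = pooled.get(p.mz, 0.0) + p.intensity
        self.peaks = [Peak(mz, i) for mz, i in sorted(pooled.items())]

    @property
    def mzs(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])

    def __len__(self) -> int:
        return len(self.peaks)


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF library; one Spectrum per BEGIN/END IONS block.

    Ids are taken from TITLE when present, else the 0-based record index.
    Records without peaks are skipped, records without PEPMASS rejected;
    both with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[Spectrum] = []
    with _mgf.read(str(path), use_index=False) as reader:
        for i, rec in enumerate(reader):
            params = rec.get("params", {})
            pepmass = params.get("pepmass")
            if pepmass is None or pepmass[0] is None:
                log.warning("MGF record %d: missing PEPMASS, rejected", i)
                continue
            mzs = rec.get("m/z array")
            if mzs is None or len(mzs) == 0:
                log.warning("MGF record %d: no peaks, skipped", i)
                continue
            ints = rec["intensity array"]
            title = params.get("title")
            sid = str(title) if title not in (None, "") else str(i)
            meta = {k: v for k, v in params.items() if k not in ("pepmass",)}
            out.append(Spectrum(
                id=sid,
                precursor_mz=float(pepmass[0]),
                peaks=[Peak(float(m), float(h)) for m, h in zip(mzs, ints)],
                metadata=meta,
            ))
    return out


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra to MGF (TITLE = spectrum id, PEPMASS = precursor m/z)."""
    records = []
    for s in spectra:
        params = {"title": s.id, "pepmass": s.precursor_mz}
        charge = s.metadata.get("charge")
        if charge is not None:
            params["charge"] = charge
        records.append({
            "params": params,
            "m/z array": s.mzs,
            "intensity array": s.intensities,
        })
    _mgf.write(records, str(path), file_mode="w")


def select_peaks(s: Spectrum, n: int = 15, *, keep_precursor: bool = False,
                 precursor_ppm: float = 10.0) -> Spectrum:
    """Keep the ``min(n, len(s))`` most intense peaks of ``s``.

    Ties in intensity at the cutoff are broken toward the higher m/z
    (heavier fragments tend to be more structure-specific, and the rule is
    deterministic).  With ``keep_precursor`` the peak matching the precursor
    m/z (within ``precursor_ppm``) is forced into the selection.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    ranked = sorted(s.peaks, key=lambda p: (-p.intensity, -p.mz))
    kept = ranked[:n]
    if keep_precursor:
        tol = s.precursor_mz * precursor_ppm * 1e-6
        near = [p for p in s.peaks if abs(p.mz - s.precursor_mz) <= tol]
        if near:
            prec = max(near, key=lambda p: p.intensity)
            if prec not in kept:
                kept = kept[: n - 1] + [prec]
    return Spectrum(id=s.id, precursor_mz=s.precursor_mz,
                    peaks=sorted(kept), metadata=dict(s.metadata))


def merge_spectra(group: Sequence[Spectrum], ppm: float = 10.0,
                  dmz: float = 0.001) -> Spectrum:
    """Merge spectra of one compound (e.g. several collision energies).

    The pooled peak list is clustered by single linkage on ascending m/z:
    the chain breaks where the gap to the previous peak exceeds
    ``max(ppm * mz * 1e-6, dmz)`` (the bound itself still merges).  Each
    cluster becomes one peak with summed intensity and intensity-weighted
    mean m/z.  The precursor m/z is that of the first spectrum.
    """
    if not group:
        raise ValueError("empty spectrum group")
    pooled = sorted(p for s in group for p in s.peaks)
    clusters: list[list[Peak]] = [[pooled[0]]]
    for prev, cur in zip(pooled, pooled[1:]):
        tol = max(cur.mz * ppm * 1e-6, dmz)
        if cur.mz - prev.mz <= tol:
            clusters[-1].append(cur)
        else:
            clusters.append([cur])
    peaks = []
    for cl in clusters:
        tot = sum(p.intensity for p in cl)
        if tot > 0:
            mz = sum(p.mz * p.intensity for p in cl) / tot
        else:  # all-zero intensities: plain mean
            mz = sum(p.mz for p in cl) / len(cl)
        peaks.append(Peak(mz, tot))
    meta = dict(group[0].metadata)
    meta["n_merged"] = len(group)
    return Spectrum(id=group[0].id, precursor_mz=group[0].precursor_mz,
                    peaks=peaks, metadata=meta)
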