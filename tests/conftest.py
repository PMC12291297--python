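"""Shared fixtures: tiny exact libraries with known graph structure."""

import pytest

from ms2patterns.binning import BinningParams, build_labels
from ms2patterns.graphs import build_graphdb
from ms2patterns.spectra import Peak, Spectrum

H2O = 18.010565
CO2 = 43.989829
CH2O3 = H2O + CO2  # 62.000394
H4O2 = 2 * H2O


def _spectrum(sid: str, precursor: float, offsets: list[float]) -> Spectrum:
    """Peaks at precursor minus each offset (offset 0 = the precursor peak)."""
    peaks = [Peak(precursor - off, 100.0 - i) for i, off in enumerate(offsets)]
    return Spectrum(id=sid, precursor_mz=precursor, peaks=peaks)


@pytest.fixture
def diamond_spectra() -> list[Spectrum]:
    """Two exact spectra realizing the same 'diamond': root with losses
    H2O, CO2 and their sum, so both loss orders (H2O then CO2, CO2 then
    H2O) appear with a common endpoint."""
    offsets = [0.0, H2O, CO2, CH2O3]
    return [_spectrum("A", 320.2, offsets), _spectrum("B", 410.7, offsets)]


@pytest.fixture
def diamond_db(diamond_spectra):
    params = BinningParams()
    labels = build_labels(diamond_spectra, params)
    return build_graphdb(diamond_spectra, labels, params)


@pytest.fixture
def triangle_spectra() -> list[Spectrum]:
    """Two exact spectra with a double-water loss chain (the homoserine-style
    H2O / H2O / H4O2 triangle)."""
    offsets = [0.0, H2O, H4O2]
    return [_spectrum("A", 236.1, offsets), _spectrum("B", 318.4, offsets)]


@pytest.fixture
def triangle_db(triangle_spectra):
    params = BinningParams()
    labels = build_labels(triangle_spectra, params)
    return build_graphdb(triangle_spectra, labels, params)
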