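"""End-to-end runs: read spectra, build the alphabet and graphs, mine,
score — with the resolved configuration embedded in every output bundle."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

from .binning import BinningParams, build_labels
from .binning import _fmt as _fmt_formula
from .graphs import GraphDB, build_graphdb
from .mining import MiningParams, MiningStats, Pattern, mine_closed_patterns
from .scoring import explain_components, find_components, read_network
from .spectra import Spectrum, merge_spectra, read_mgf, select_peaks

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one run depends on; serialized into output bundles."""

    input_path: str = ""
    output_path: str = ""
    top_peaks: int = 15
    keep_precursor: bool = False
    merge: bool = False
    merge_ppm: float = 10.0
    merge_dmz: float = 0.001
    binning: BinningParams = field(default_factory=BinningParams)
    mining: MiningParams = field(default_factory=MiningParams)
    network_path: str = ""
    min_clique_size: int = 3
    min_pair_similarity: float = 0.9
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["binning"]["elements"] = list(self.binning.elements)
        d["binning"]["formula_window"] = list(self.binning.formula_window)
        return d


def prepare_spectra(spectra: Sequence[Spectrum], config: RunConfig
                    ) -> list[Spectrum]:
    """Optional multi-energy merging, then peak selection."""
    if config.merge:
        groups: dict[str, list[Spectrum]] = {}
        for s in spectra:
            groups.setdefault(s.id, []).append(s)
        spectra = [merge_spectra(g, config.merge_ppm, config.merge_dmz)
                   for g in groups.values()]
    return [select_peaks(s, config.top_peaks,
                         keep_precursor=config.keep_precursor)
            for s in spectra]


def run_pipeline(spectra: Sequence[Spectrum], config: RunConfig | None = None
                 ) -> tuple[GraphDB, list[Pattern], MiningStats]:
    """reduce -> bin/annotate -> build graphs -> mine, from in-memory spectra."""
    config = config or RunConfig()
    reduced = prepare_spectra(spectra, config)
    labels = build_labels(reduced, config.binning)
    log.info("alphabet: %d labels", len(labels))
    db = build_graphdb(reduced, labels, config.binning)
    log.info("graphs: %d, edges: %d", len(db),
             sum(len(g.edges) for g in db.graphs))
    stats = MiningStats()
    patterns = mine_closed_patterns(db, config.mining, stats=stats)
    log.info("mining: %d candidates, %d infrequent, %d non-spanning, "
             "%d non-canonical, %d non-closed, %d patterns",
             stats.candidates, stats.failed_support, stats.failed_spanning,
             stats.failed_canonical, stats.not_closed, stats.patterns)
    return db, patterns, stats


def patterns_to_bundle(db: GraphDB, patterns: Sequence[Pattern],
                       config: RunConfig) -> dict:
    spectrum_ids = [g.spectrum_id for g in db.graphs]
    by_id = {l.id: l for l in db.labels}

    def fmt(lab: int) -> str:
        best = by_id[lab].best_formula
        return "" if best is None else str(best)

    return {
        "config": config.to_dict(),
        "spectrum_ids": spectrum_ids,
        "labels": [{
            "id": l.id, "lower": l.lower, "upper": l.upper,
            "center": l.center, "count": l.count,
            "formulas": [_fmt_formula(f) for f in l.formulas],
        } for l in db.labels],
        "patterns": [{
            "id": i,
            "edges": [{"source": u, "target": v, "label": lab,
                       "center": by_id[lab].center, "formula": fmt(lab)}
                      for u, v, lab in p.edges],
            "support": sorted(spectrum_ids[g] for g in p.support),
            "occurrences": [{"graph": spectrum_ids[g], "root": r}
                            for g, r, _ in p.occurrences],
            "canonical_code": repr(p.canonical_code),
        } for i, p in enumerate(patterns)],
    }


def run_mine(config: RunConfig) -> dict:
    """Full mining run from an MGF file; returns the pattern bundle."""
    spectra = read_mgf(config.input_path)
    log.info("read %d spectra from %s", len(spectra), config.input_path)
    db, patterns, _ = run_pipeline(spectra, config)
    bundle = patterns_to_bundle(db, patterns, config)
    if config.output_path:
        Path(config.output_path).write_text(json.dumps(bundle, indent=1))
        log.info("wrote %d patterns to %s", len(patterns), config.output_path)
    return bundle


def run_explain(config: RunConfig, bundle: dict) -> list[dict]:
    """Explain molecular-network components with a mined pattern bundle."""
    network = read_network(config.network_path)
    library_ids = set(bundle["spectrum_ids"])
    unknown = [n for n in network.nodes if str(n) not in library_ids]
    if unknown:
        log.warning("%d network ids missing from the library, skipped: %s",
                    len(unknown), sorted(map(str, unknown))[:10])
        network = network.subgraph(
            [n for n in network.nodes if str(n) in library_ids]).copy()
    components = find_components(network, config.min_clique_size,
                                 config.min_pair_similarity)
    supports = {p["id"]: (p["support"], len(p["edges"]))
                for p in bundle["patterns"]}
    report = []
    for comp, ranking in explain_components(supports, components):
        entry = {
            "kind": comp.kind,
            "members": sorted(comp.members),
        }
        if comp.source_similarity is not None:
            entry["similarity"] = comp.source_similarity
        if ranking:
            best = ranking[0]
            entry["best_pattern"] = best.pattern_id
            entry["precision"] = best.precision
            entry["recall"] = best.recall
            entry["f1"] = best.f1
        report.append(entry)
    return report
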