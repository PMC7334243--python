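"""End-to-end analysis and multi-species comparison.

``analyze_dataset`` runs measurements + markers through the morphometric,
marker and idiogram stages and bundles the results; ``write_bundle``
serializes a bundle (report.json, comparative-table TSVs, idiogram.svg);
``compare_reports`` assembles the one-row-per-species comparative table
with cross-species ratios.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import idiogram as idiogram_mod
from . import io as kio
from . import markers as marker_mod
from . import metrics
from .config import DEFAULT_CONFIG, AnalysisConfig
from .io import (ChromosomeRecord, KaryoError, KaryotypeSummary, MarkerSite,
                 PairSummary)


@dataclass(frozen=True)
class KaryotypeReport:
    """Complete analysis bundle for one species."""

    summary: KaryotypeSummary
    pairs: tuple[PairSummary, ...]
    markers: tuple[MarkerSite, ...]          # annotated (di, class, sizes)
    band_totals: marker_mod.BandTotals
    locus_counts: Mapping[str, int]
    syntenic_pairs: tuple[int, ...]
    colocalizations: tuple[marker_mod.Colocalization, ...]
    config: AnalysisConfig


def analyze_dataset(records: Sequence[ChromosomeRecord],
                    sites: Sequence[MarkerSite] = (),
                    species: str = "",
                    config: AnalysisConfig = DEFAULT_CONFIG) -> KaryotypeReport:
    """Run the full pipeline on one species' measurement + marker tables."""
    summary, pairs = metrics.summarize_karyotype(records, species, config)
    annotated = marker_mod.annotate_markers(sites, pairs, summary.tcl_um, config)
    totals = marker_mod.band_amounts(sites, pairs, summary.tcl_um, config)
    return KaryotypeReport(
        summary=summary,
        pairs=tuple(pairs),
        markers=tuple(annotated),
        band_totals=totals,
        locus_counts=marker_mod.locus_counts(sites),
        syntenic_pairs=tuple(marker_mod.syntenic_pairs(sites)),
        colocalizations=tuple(marker_mod.colocalization_report(annotated)),
        config=config,
    )


def write_bundle(report: KaryotypeReport, out_dir: str | Path,
                 render_idiogram: bool = True) -> dict[str, Path]:
    """Write the full report bundle (JSON + TSV tables + idiogram SVG)."""
    out_dir = Path(out_dir)
    extras = {
        "band_totals": dict(report.band_totals.totals),
        "cpd_including_rdna": report.band_totals.cpd_including_rdna,
        "locus_counts": dict(report.locus_counts),
        "syntenic_pairs": list(report.syntenic_pairs),
        "colocalizations": [
            {"rdna_pair": c.rdna.pair_id, "rdna_arm": c.rdna.arm,
             "rdna_type": c.rdna.marker_type, "band_type": c.band.marker_type,
             "overlap_frac": c.overlap_frac}
            for c in report.colocalizations],
        "config": report.config.to_dict(),
    }
    paths = kio.write_report(report.summary, report.pairs, report.markers,
                             out_dir, dp=report.config.round_dp, extras=extras)
    if render_idiogram:
        spec = idiogram_mod.build_idiogram(report.pairs, report.markers,
                                           species=report.summary.species,
                                           config=report.config)
        svg_path = out_dir / "idiogram.svg"
        idiogram_mod.render_svg(spec, svg_path)
        paths["idiogram"] = svg_path
    return paths


# ---------------------------------------------------------------------------
# multi-species comparison


def compare_summaries(summaries: Sequence[KaryotypeSummary], dp: int = 2
                      ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Comparative one-row-per-species table plus cross-species ratios.

    Ratios: ``tcl_ratio_max_min`` (longest / shortest complement) and
    ``c_ratio_max_min``.  Duplicate species names raise
    :class:`~karyostat.io.KaryoError`.
    """
    if len(summaries) < 2:
        raise KaryoError("comparison needs at least two species reports")
    names = [s.species for s in summaries]
    if len(set(names)) != len(names):
        raise KaryoError(f"duplicate species names in comparison: {names}")
    table = pd.DataFrame([kio.karyotype_table_row(s, dp) for s in summaries])
    tcls = {s.species: s.tcl_um for s in summaries}
    ratios = {
        "tcl_ratio_max_min": max(tcls.values()) / min(tcls.values()),
        "c_ratio_max_min": (max(s.c_um for s in summaries)
                            / min(s.c_um for s in summaries)),
    }
    return table, ratios


def load_summary(report_json: str | Path) -> KaryotypeSummary:
    """Summary from a previously written report.json."""
    payload = json.loads(Path(report_json).read_text())
    return kio.summary_from_dict(payload["summary"])


def compare_report_files(paths: Sequence[str | Path], dp: int = 2
                         ) -> tuple[pd.DataFrame, dict[str, float]]:
    return compare_summaries([load_summary(p) for p in paths], dp)
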