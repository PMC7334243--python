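"""Quantification of fluorochrome bands and rDNA FISH sites.

The central statistic is di = 100·d/a: the percent distance from the
centromere to a marker site along its arm, where a is the arm length and
d is measured to the *starting point* of a terminal site but to the
*center* of a non-terminal site.  Position classes: CEN (spans the
centromere), TER (reaches the telomere), PCEN (di below the
pericentromeric cut-off), INT otherwise.

Band amounts are expressed on the haploid complement: one homolog per
pair, band physical size (end−start)·a µm, totals as a percentage of the
karyotype length (TCL).  Following the convention of CPD/rDNA studies the
headline CPD total excludes bands that colocalize with 45S rDNA sites
(rDNA-associated CPD chromatin); the including-rDNA total is reported
alongside.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .config import DEFAULT_CONFIG, AnalysisConfig
from .io import LinkageError, MarkerSite, PairSummary


def _pair_index(pairs: Sequence[PairSummary]) -> dict[int, PairSummary]:
    """Index pairs by the identifier markers refer to (the input pair id)."""
    return {p.orig_pair_id: p for p in pairs}


def _arm_length(site: MarkerSite, pair: PairSummary) -> float:
    if site.arm == "short":
        return pair.b
    if site.arm == "long":
        return pair.B
    return pair.b + pair.B  # centromere-spanning: extends into both arms


def is_terminal(site: MarkerSite, config: AnalysisConfig = DEFAULT_CONFIG) -> bool:
    return site.arm != "centromere-spanning" and site.end_frac >= config.ter_min_end_frac


def compute_di(site: MarkerSite, pair: PairSummary,
               config: AnalysisConfig = DEFAULT_CONFIG) -> float | None:
    """Percent distance from the centromere to the site (di = 100·d/a).

    d is the distance to the start of a terminal site, to the center of a
    non-terminal site.  Undefined (None) for centromere-spanning sites.
    """
    if site.arm == "centromere-spanning":
        return None
    if is_terminal(site, config):
        frac = site.start_frac
    else:
        frac = 0.5 * (site.start_frac + site.end_frac)
    return 100.0 * frac


def classify_position(site: MarkerSite, pair: PairSummary,
                      config: AnalysisConfig = DEFAULT_CONFIG) -> str:
    """CEN / PCEN / INT / TER position class for a marker site."""
    if site.arm == "centromere-spanning":
        return "CEN"
    if is_terminal(site, config):
        return "TER"
    di = compute_di(site, pair, config)
    return "PCEN" if di <= config.pcen_max_di else "INT"


def annotate_markers(sites: Sequence[MarkerSite],
                     pairs: Sequence[PairSummary],
                     tcl_um: float,
                     config: AnalysisConfig = DEFAULT_CONFIG) -> list[MarkerSite]:
    """Fill every derived marker field (d_um, a_um, di, class, size % TCL).

    Sites keep their order; a site referencing a pair absent from the
    measurement summaries raises :class:`LinkageError`.
    """
    index = _pair_index(pairs)
    out = []
    for site in sites:
        if site.pair_id not in index:
            raise LinkageError(
                f"marker references unknown pair {site.pair_id} "
                f"(known: {sorted(index)})")
        pair = index[site.pair_id]
        a = _arm_length(site, pair)
        di = compute_di(site, pair, config)
        out.append(replace(
            site,
            a_um=a,
            d_um=None if di is None else di / 100.0 * a,
            di=di,
            position_class=classify_position(site, pair, config),
            size_percent_tcl=100.0 * site.width_frac * a / tcl_um,
        ))
    return out


# ---------------------------------------------------------------------------
# band amounts


@dataclass(frozen=True)
class BandTotals:
    """Genome-wide band amounts as percentages of the karyotype length."""

    #: headline totals per marker type; CPD excludes 45S-colocalized bands.
    totals: Mapping[str, float]
    #: CPD total with rDNA-associated bands included.
    cpd_including_rdna: float
    #: per-(pair, marker_type) band sizes (% of TCL), haploid accounting.
    per_pair: Mapping[tuple[int, str], float]


def _overlap_frac(a: MarkerSite, b: MarkerSite) -> float:
    """Fraction of site *a*'s interval covered by site *b* (same pair+arm)."""
    lo = max(a.start_frac, b.start_frac)
    hi = min(a.end_frac, b.end_frac)
    return max(0.0, hi - lo) / a.width_frac


def band_amounts(sites: Sequence[MarkerSite],
                 pairs: Sequence[PairSummary],
                 tcl_um: float,
                 config: AnalysisConfig = DEFAULT_CONFIG) -> BandTotals:
    """Total and per-pair band sizes as percentages of the karyotype length.

    Haploid accounting: one homolog per pair against the haploid TCL.
    The headline CPD total excludes CPD bands overlapping a 45S site on
    the same pair and arm (rDNA-associated heterochromatin).
    """
    annotated = annotate_markers(sites, pairs, tcl_um, config)
    rdna_45s = [s for s in annotated if s.marker_type == "45S"]
    totals: dict[str, float] = defaultdict(float)
    per_pair: dict[tuple[int, str], float] = defaultdict(float)
    cpd_incl = 0.0
    for s in annotated:
        size = s.size_percent_tcl
        if s.marker_type == "CPD":
            cpd_incl += size
            colocal = any(r.pair_id == s.pair_id and r.arm == s.arm
                          and _overlap_frac(s, r) > 0.0 for r in rdna_45s)
            if colocal:
                continue
        totals[s.marker_type] += size
        per_pair[(s.pair_id, s.marker_type)] += size
    return BandTotals(totals=dict(totals), cpd_including_rdna=cpd_incl,
                      per_pair=dict(per_pair))


# ---------------------------------------------------------------------------
# locus counts and colocalization


def locus_counts(sites: Sequence[MarkerSite]) -> dict[str, int]:
    """Number of chromosome pairs bearing each rDNA type (5S, 45S)."""
    by_type: dict[str, set[int]] = {"5S": set(), "45S": set()}
    for s in sites:
        if s.marker_type in by_type:
            by_type[s.marker_type].add(s.pair_id)
    return {t: len(p) for t, p in by_type.items()}


def syntenic_pairs(sites: Sequence[MarkerSite]) -> list[int]:
    """Pairs carrying both 5S and 45S sites (syntenic rDNA loci)."""
    by_type: dict[str, set[int]] = defaultdict(set)
    for s in sites:
        if s.marker_type in ("5S", "45S"):
            by_type[s.marker_type].add(s.pair_id)
    return sorted(by_type["5S"] & by_type["45S"])


@dataclass(frozen=True)
class Colocalization:
    rdna: MarkerSite
    band: MarkerSite
    #: fraction of the rDNA site's interval covered by the band.
    overlap_frac: float


def colocalization_report(sites: Sequence[MarkerSite]) -> list[Colocalization]:
    """For each rDNA site, the fluorochrome bands overlapping it.

    Overlap is evaluated on the same pair and arm; the reported fraction is
    the proportion of the rDNA interval covered by the band.
    """
    rdna = [s for s in sites if s.marker_type in ("5S", "45S")]
    bands = [s for s in sites if s.marker_type in ("CPD", "DAPI")]
    report = []
    for r in rdna:
        for b in bands:
            if b.pair_id != r.pair_id or b.arm != r.arm:
                continue
            frac = _overlap_frac(r, b)
            if frac > 0.0:
                report.append(Colocalization(rdna=r, band=b, overlap_frac=frac))
    return report
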