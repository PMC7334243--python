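"""Per-pair morphometrics, Levan classes, karyotype formula and asymmetry indices.

The asymmetry suite covers the indices standard in comparative plant
cytogenetics:

* CI — mean centromeric index over pairs, with its (sample) SD;
* A1 — Romero Zarco intrachromosomal index, 1 − mean(b_i/B_i);
* A2 — Romero Zarco interchromosomal index, CV of pair lengths (SD/mean);
* AsK% — Arano's index, total long-arm length as % of complement length;
* AI — Paszko's index, CVcl·CVci/100 where CVcl = 100·A2 and
  CVci = 100·SD(CI)/mean(CI);
* Stebbins category — digit (proportion of pairs with AR > 2) + letter
  (largest/smallest chromosome ratio).

All dispersion statistics are sample (n−1) standard deviations.  The ±
value attached to TCL is the standard error over metaphase cells.
"""
from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .config import DEFAULT_CONFIG, AnalysisConfig
from .io import (ChromosomeRecord, KaryoError, KaryotypeSummary, PairSummary,
                 ValidationError, orient_records)


class MissingPairError(KaryoError):
    """A chromosome pair has no measurement records."""


# ---------------------------------------------------------------------------
# per-pair morphometrics


def _grouped(records: Sequence[ChromosomeRecord]) -> dict[int, list[ChromosomeRecord]]:
    by_pair: dict[int, list[ChromosomeRecord]] = defaultdict(list)
    for r in records:
        by_pair[r.pair_id].append(r)
    return by_pair


def summarize_pairs(records: Sequence[ChromosomeRecord],
                    config: AnalysisConfig = DEFAULT_CONFIG) -> list[PairSummary]:
    """Average homolog measurements into per-pair morphometrics.

    b and B are means over all homologs and cells; AR = B/b;
    CI = 100·b/(b+B).  RL is computed within each cell (pair length as a
    percentage of that cell's haploid complement length) and then averaged
    across cells, which removes the cell-level condensation factor.  Pairs
    are returned sorted by decreasing RL and renumbered 1..n (ties broken
    by the lower input pair_id); the input identifier is kept in
    ``orig_pair_id``.
    """
    if not records:
        raise MissingPairError("no measurement records")
    records = orient_records(records, config.include_satellite)
    by_pair = _grouped(records)

    # mean homolog length per (cell, pair), for per-cell RL
    cell_pair_len: dict[str, dict[int, float]] = defaultdict(dict)
    for pid, recs in by_pair.items():
        per_cell: dict[str, list[float]] = defaultdict(list)
        for r in recs:
            s, l = r.arm_lengths(config.include_satellite)
            per_cell[r.cell_id].append(s + l)
        for cid, lens in per_cell.items():
            cell_pair_len[cid][pid] = float(np.mean(lens))

    cell_totals = {cid: sum(d.values()) for cid, d in cell_pair_len.items()}

    rows = []
    for pid, recs in sorted(by_pair.items()):
        arms = np.array([r.arm_lengths(config.include_satellite) for r in recs])
        b = float(arms[:, 0].mean())
        B = float(arms[:, 1].mean())
        rls = [100.0 * cell_pair_len[cid][pid] / cell_totals[cid]
               for cid in sorted(cell_pair_len)
               if pid in cell_pair_len[cid]]
        rl = float(np.mean(rls))
        has_sat = any(r.sat_um > 0 for r in recs)
        rows.append((pid, b, B, rl, has_sat))

    rows.sort(key=lambda t: (-t[3], t[0]))
    pairs = []
    for new_id, (pid, b, B, rl, has_sat) in enumerate(rows, start=1):
        ar = B / b
        pairs.append(PairSummary(
            pair_id=new_id, orig_pair_id=pid, b=b, B=B, AR=ar,
            CI=100.0 * b / (b + B), RL=rl,
            levan_class=classify_levan(ar, config), has_satellite=has_sat))
    return pairs


# ---------------------------------------------------------------------------
# Levan classification and karyotype formula


def classify_levan(ar: float, config: AnalysisConfig = DEFAULT_CONFIG) -> str:
    """Levan morphology class from the arm ratio.

    M at AR = 1.00 exactly (median centromere); then left-open intervals
    m (1, 1.70], sm (1.70, 3.00], st (3.00, 7.00], t (7.00, ∞).
    """
    if ar < 1.0:
        raise ValidationError(f"AR must be >= 1 (orient records first), got {ar}")
    if ar == 1.0:
        return "M"
    if ar <= config.levan_m_max:
        return "m"
    if ar <= config.levan_sm_max:
        return "sm"
    if ar <= config.levan_st_max:
        return "st"
    return "t"


KF_CLASS_ORDER = ("m", "sm", "st", "t")


def karyotype_formula(pairs: Sequence[PairSummary]) -> str:
    """Haploid karyotype formula, e.g. ``"10m (1SAT) + 1sm"``.

    M (median) pairs are counted with m; classes appear in the order
    m, sm, st, t, zero-count classes omitted; satellited pairs are
    annotated ``(kSAT)`` inside their class term.
    """
    counts: dict[str, int] = defaultdict(int)
    sats: dict[str, int] = defaultdict(int)
    for p in pairs:
        cls = "m" if p.levan_class == "M" else p.levan_class
        counts[cls] += 1
        if p.has_satellite:
            sats[cls] += 1
    terms = []
    for cls in KF_CLASS_ORDER:
        if counts[cls]:
            term = f"{counts[cls]}{cls}"
            if sats[cls]:
                term += f" ({sats[cls]}SAT)"
            terms.append(term)
    return " + ".join(terms)


# ---------------------------------------------------------------------------
# complement length


def karyotype_length(records: Sequence[ChromosomeRecord],
                     config: AnalysisConfig = DEFAULT_CONFIG
                     ) -> tuple[float, float, float]:
    """(TCL, SE, C): haploid complement length statistics over cells.

    Each cell contributes one haploid total (sum over pairs of the mean
    homolog length); TCL is the mean over cells and the SE its standard
    error (sample SD / √cells).  C = TCL / n_pairs is the mean chromosome
    length.  With a single cell the SE is 0 and a warning is issued.
    """
    if not records:
        raise MissingPairError("no measurement records")
    records = orient_records(records, config.include_satellite)
    per_cell: dict[str, dict[int, list[float]]] = defaultdict(lambda: defaultdict(list))
    for r in records:
        s, l = r.arm_lengths(config.include_satellite)
        per_cell[r.cell_id][r.pair_id].append(s + l)
    totals = np.array([sum(float(np.mean(v)) for v in pairs.values())
                       for _, pairs in sorted(per_cell.items())])
    n_pairs = len({r.pair_id for r in records})
    tcl = float(totals.mean())
    if len(totals) < 2:
        warnings.warn("single metaphase cell: TCL standard error reported as 0",
                      stacklevel=2)
        se = 0.0
    else:
        se = float(totals.std(ddof=1) / np.sqrt(len(totals)))
    return tcl, se, tcl / n_pairs


# ---------------------------------------------------------------------------
# asymmetry suite


@dataclass(frozen=True)
class AsymmetryStats:
    ci_mean: float
    ci_sd: float
    a1: float
    a2: float
    ask_percent: float
    cv_cl: float
    cv_ci: float
    ai: float


def paszko_ai(cv_cl: float, cv_ci: float) -> float:
    """Paszko's asymmetry index AI = CVcl · CVci / 100."""
    return cv_cl * cv_ci / 100.0


def ai_from_table_stats(a2: float, ci_mean: float, ci_sd: float) -> float:
    """AI recomputed from table-level statistics.

    CVcl = 100·A2 (A2 is already the CV of chromosome length) and
    CVci = 100·SD(CI)/mean(CI); AI = CVcl·CVci/100.
    """
    return paszko_ai(100.0 * a2, 100.0 * ci_sd / ci_mean)


def asymmetry_suite(pairs: Sequence[PairSummary]) -> AsymmetryStats:
    """The full asymmetry-index suite over per-pair values.

    Requires at least two pairs (the dispersion statistics are otherwise
    undefined).
    """
    if len(pairs) < 2:
        raise ValidationError("asymmetry dispersion statistics need >= 2 pairs")
    b = np.array([p.b for p in pairs])
    B = np.array([p.B for p in pairs])
    L = b + B
    ci = 100.0 * b / L
    ci_mean = float(ci.mean())
    ci_sd = float(ci.std(ddof=1))
    a1 = float(1.0 - np.mean(b / B))
    a2 = float(L.std(ddof=1) / L.mean())
    ask = float(100.0 * B.sum() / L.sum())
    cv_cl = 100.0 * a2
    cv_ci = 100.0 * ci_sd / ci_mean
    return AsymmetryStats(ci_mean=ci_mean, ci_sd=ci_sd, a1=a1, a2=a2,
                          ask_percent=ask, cv_cl=cv_cl, cv_ci=cv_ci,
                          ai=paszko_ai(cv_cl, cv_ci))


# ---------------------------------------------------------------------------
# Stebbins category


def stebbins_category(pairs: Sequence[PairSummary],
                      config: AnalysisConfig = DEFAULT_CONFIG) -> str:
    """Two-way Stebbins symmetry category, e.g. ``"1A"``.

    Digit from the proportion p of pairs with AR strictly above the
    threshold (2.0): 1 if p = 0, 2 if 0 < p <= 0.5, 3 if 0.5 < p < 1,
    4 if p = 1.  Letter from the ratio r of largest to smallest relative
    length: A if r < 2, B if 2 <= r <= 4, C if r > 4.
    """
    if not pairs:
        raise ValidationError("no pairs")
    ars = np.array([p.AR for p in pairs])
    p = float(np.mean(ars > config.stebbins_ar_threshold))
    if p == 0.0:
        digit = "1"
    elif p <= 0.5:
        digit = "2"
    elif p < 1.0:
        digit = "3"
    else:
        digit = "4"
    rls = np.array([p_.RL for p_ in pairs])
    r = float(rls.max() / rls.min())
    letter = "A" if r < 2.0 else ("B" if r <= 4.0 else "C")
    return digit + letter


# ---------------------------------------------------------------------------
# whole-karyotype summary


def summarize_karyotype(records: Sequence[ChromosomeRecord],
                        species: str = "",
                        config: AnalysisConfig = DEFAULT_CONFIG
                        ) -> tuple[KaryotypeSummary, list[PairSummary]]:
    """Run the full morphometric pipeline on one species' measurements."""
    pairs = summarize_pairs(records, config)
    tcl, se, c = karyotype_length(records, config)
    asym = asymmetry_suite(pairs)
    rls = [p.RL for p in pairs]
    summary = KaryotypeSummary(
        species=species,
        two_n=2 * len(pairs),
        n_pairs=len(pairs),
        kf=karyotype_formula(pairs),
        tcl_um=tcl,
        tcl_se_um=se,
        c_um=c,
        rrl_min=min(rls),
        rrl_max=max(rls),
        ci_mean=asym.ci_mean,
        ci_sd=asym.ci_sd,
        a1=asym.a1,
        a2=asym.a2,
        ask_percent=asym.ask_percent,
        cv_cl=asym.cv_cl,
        cv_ci=asym.cv_ci,
        ai=asym.ai,
        stebbins=stebbins_category(pairs, config),
    )
    return summary, pairs
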