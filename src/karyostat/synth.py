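"""Synthetic karyotype generator and built-in species templates.

The generator emulates the measurement design of a molecular-cytogenetic
karyotype study: a diploid complement measured over a handful of metaphase
plates, with a cell-level condensation factor (chromosomes in different
spreads are uniformly more or less contracted) and independent
multiplicative measurement noise on every homolog arm in every cell.
Both factors are lognormal, so lengths stay positive; dimensionless
statistics (RL, AR, CI and all asymmetry indices) are invariant to the
condensation factor by construction.

Built-in templates parameterize the five wild *Vigna* species from their
published comparative tables: karyotype formula, complement length,
relative-length extremes, satellite, rDNA locus layout and fluorochrome
band amounts.  Per-pair relative lengths between the published extremes
are interpolated with a warped geometric profile (only the extremes were
published); per-pair arm ratios are chosen within the published Levan
classes — the templates reproduce formulae and marker layouts exactly but
are not authoritative for per-pair values.
"""
from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.optimize import brentq

from .io import (ChromosomeRecord, MarkerSite, SatelliteSpec, SpeciesTemplate,
                 TemplateError)
from .reference import N_PAIRS, REFERENCE, ReferenceKaryotype

# distal fraction of the short arm occupied by the satellite in the
# satellited template (secondary constriction position is not published).
SATELLITE_FRAC = 0.15
# half-width (arm fraction) used for point-like published rDNA loci.
RDNA_HALF_WIDTH = 0.03


# ---------------------------------------------------------------------------
# relative-length profiles


def rl_profile_from_extremes(rl_max: float, rl_min: float, n: int) -> tuple[float, ...]:
    """Monotone RL profile with exact extremes summing to exactly 100.

    A geometric interpolation rl_i = rl_max·(rl_min/rl_max)^{(i/(n−1))}
    keeps the extremes but does not generally sum to 100, so the exponent
    is warped by a single shape parameter γ,
    rl_i = rl_max·(rl_min/rl_max)^{((i/(n−1))^γ)}, and γ is solved so the
    profile sums to 100.  The result is strictly decreasing with first and
    last entries exactly rl_max and rl_min.
    """
    if not (0 < rl_min < rl_max):
        raise TemplateError("need 0 < rl_min < rl_max")
    lo, hi = rl_max + (n - 1) * rl_min, (n - 1) * rl_max + rl_min
    if not (lo < 100.0 < hi):
        raise TemplateError(
            f"extremes ({rl_max}, {rl_min}) cannot bracket a sum of 100 for n={n}")
    ratio = rl_min / rl_max
    t = np.arange(n) / (n - 1)

    def total(gamma: float) -> float:
        return float(np.sum(rl_max * ratio ** (t ** gamma))) - 100.0

    gamma = brentq(total, 1e-3, 60.0, xtol=1e-13, rtol=1e-15)
    profile = rl_max * ratio ** (t ** gamma)
    # pin the floating-point sum to 100 exactly via the interior entries
    profile[1:-1] *= (100.0 - profile[0] - profile[-1]) / profile[1:-1].sum()
    return tuple(float(x) for x in profile)


# ---------------------------------------------------------------------------
# dataset generation


def _lognormal_factors(rng: np.random.Generator, cv_percent: float,
                       size: int | tuple[int, ...]) -> np.ndarray:
    """Unit-mean lognormal multipliers with the given CV (percent)."""
    if cv_percent <= 0:
        return np.ones(size)
    sigma2 = math.log1p((cv_percent / 100.0) ** 2)
    sigma = math.sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=size)


def generate_dataset(template: SpeciesTemplate, seed: int | None = None
                     ) -> tuple[list[ChromosomeRecord], list[MarkerSite]]:
    """Generate measurement records and marker sites from a template.

    For each metaphase cell a condensation factor is drawn
    (CV = ``condensation_cv``); pair base lengths come from
    ``rl_profile``·``target_tcl_um``, split into arms by ``ar_profile``;
    each homolog arm is then perturbed by independent unit-mean lognormal
    noise with CV ``noise_cv`` (the satellite scales with its host arm's
    factor).  Marker layouts are copied noise-free.  Fully reproducible
    from the seed (``template.seed`` unless overridden).
    """
    rng = np.random.default_rng(template.seed if seed is None else seed)
    n = template.n_pairs
    rl = np.asarray(template.rl_profile)
    ar = np.asarray(template.ar_profile)
    L = rl / 100.0 * template.target_tcl_um
    b = L / (1.0 + ar)            # satellite-inclusive short arm
    B = L - b

    sat_len = np.zeros(n)
    sat_arm = ["none"] * n
    if template.satellite is not None:
        s = template.satellite
        if not 1 <= s.pair_id <= n:
            raise TemplateError(f"satellite pair {s.pair_id} outside 1..{n}")
        i = s.pair_id - 1
        host = b[i] if s.arm == "short" else B[i]
        sat_len[i] = s.frac * host
        sat_arm[i] = s.arm

    base_short = b - np.where(np.array(sat_arm) == "short", sat_len, 0.0)
    base_long = B - np.where(np.array(sat_arm) == "long", sat_len, 0.0)

    records: list[ChromosomeRecord] = []
    for c in range(template.n_cells):
        kappa = float(_lognormal_factors(rng, template.condensation_cv, 1)[0])
        noise = _lognormal_factors(rng, template.noise_cv, (n, 2, 2))
        for i in range(n):
            for h in (1, 2):
                fs, fl = noise[i, h - 1]
                sat = sat_len[i] * kappa * (fs if sat_arm[i] == "short" else fl)
                records.append(ChromosomeRecord(
                    cell_id=f"cell{c + 1}",
                    pair_id=i + 1,
                    homolog_id=h,
                    short_um=base_short[i] * kappa * fs,
                    long_um=base_long[i] * kappa * fl,
                    sat_um=sat if sat_arm[i] != "none" else 0.0,
                    sat_arm=sat_arm[i],
                ))
    return records, list(template.markers)


# ---------------------------------------------------------------------------
# built-in species templates

# per-pair arm ratios (unpublished; chosen within the published Levan
# classes and below the Stebbins cut-off of 2, with the mean centromeric
# index near the published complement mean).
_AR_PROFILES: dict[str, tuple[float, ...]] = {
    "luteola": (1.15, 1.18, 1.21, 1.24, 1.26, 1.28, 1.30, 1.32, 1.35, 1.38, 1.42),
    "vexillata": (1.18, 1.22, 1.26, 1.29, 1.31, 1.33, 1.35, 1.38, 1.41, 1.45, 1.50),
    "minima": (1.14, 1.17, 1.20, 1.23, 1.25, 1.27, 1.29, 1.31, 1.33, 1.36, 1.40),
    # submetacentric pairs 2 and 5
    "trilobata": (1.20, 1.85, 1.25, 1.30, 1.95, 1.32, 1.35, 1.38, 1.42, 1.46, 1.52),
    # satellited pair 1 (metacentric), submetacentric pair 7
    "caracalla": (1.25, 1.20, 1.22, 1.24, 1.26, 1.28, 1.90, 1.30, 1.33, 1.36, 1.40),
}


def _arm_percent_lengths(rl: Sequence[float], ar: Sequence[float]
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Arm lengths in percent-of-TCL units from RL and AR profiles."""
    rl = np.asarray(rl)
    ar = np.asarray(ar)
    b = rl / (1.0 + ar)
    return b, rl - b


def _rdna_markers(ref: ReferenceKaryotype, sat_frac: float) -> list[MarkerSite]:
    sites = []
    for row in ref.rdna:
        if row.full_arm:
            end = 1.0
            if ref.slug == "caracalla" and row.marker_type == "45S":
                # the 45S chromatin fills the short arm up to the satellite
                end = 1.0 - sat_frac
            sites.append(MarkerSite(row.pair_id, row.arm, row.marker_type,
                                    0.0, end))
        elif row.position_class == "TER":
            sites.append(MarkerSite(row.pair_id, row.arm, row.marker_type,
                                    row.di / 100.0, 1.0))
        else:  # PCEN / INT: published di is the band center
            c = row.di / 100.0
            sites.append(MarkerSite(row.pair_id, row.arm, row.marker_type,
                                    c - RDNA_HALF_WIDTH, c + RDNA_HALF_WIDTH))
    return sites


def _build_markers(ref: ReferenceKaryotype,
                   rl: Sequence[float], ar: Sequence[float],
                   sat_frac: float) -> tuple[MarkerSite, ...]:
    """Marker layout reproducing the published locus table and band amounts."""
    b_pct, B_pct = _arm_percent_lengths(rl, ar)
    sites = _rdna_markers(ref, sat_frac)

    def arm_pct(pair: int, arm: str) -> float:
        return float(b_pct[pair - 1] if arm == "short" else B_pct[pair - 1])

    rdna_45s = [s for s in sites if s.marker_type == "45S"]
    # CPD chromatin coincides with every 45S site (and, in V. minima, the 5S)
    cpd_on = list(rdna_45s)
    if ref.slug == "minima":
        cpd_on += [s for s in sites if s.marker_type == "5S"]
    for s in cpd_on:
        sites.append(dataclasses.replace(s, marker_type="CPD"))

    if ref.cpd_pericen_amount:
        # (peri)centromeric CPD on every arm not already filled by a 45S
        # locus, sized so the non-rDNA total matches the published amount
        blocked = {(s.pair_id, s.arm) for s in rdna_45s}
        arms = [(p, a) for p in range(1, len(rl) + 1) for a in ("short", "long")
                if (p, a) not in blocked]
        f = ref.cpd_pericen_amount / sum(arm_pct(p, a) for p, a in arms)
        for p, a in arms:
            end = f
            # keep clear of a 45S band sitting higher on the same arm
            for s in rdna_45s:
                if s.pair_id == p and s.arm == a and s.start_frac < end + 0.005:
                    end = s.start_frac - 0.005
            if end > 0:
                sites.append(MarkerSite(p, a, "CPD", 0.0, end))

    if ref.cpd_interstitial_amount:
        per_band = ref.cpd_interstitial_amount / len(ref.cpd_interstitial_arms)
        for p, a in ref.cpd_interstitial_arms:
            w = per_band / arm_pct(p, a)
            sites.append(MarkerSite(p, a, "CPD", 0.55 - w / 2, 0.55 + w / 2))

    if ref.dapi_amount:
        g = ref.dapi_amount / sum(arm_pct(p, a) for p, a in ref.dapi_arms)
        for p, a in ref.dapi_arms:
            sites.append(MarkerSite(p, a, "DAPI", 0.0, g))

    return tuple(sites)


def builtin_templates(noise_cv: float = 5.0, condensation_cv: float = 5.0,
                      n_cells: int = 5, seed: int = 0
                      ) -> dict[str, SpeciesTemplate]:
    """The five built-in species templates, keyed by slug.

    Noiseless instances (``template.noiseless()``) reproduce the published
    karyotype formula, relative-length extremes, satellite, rDNA locus
    counts and position classes exactly.
    """
    templates = {}
    for slug, ref in REFERENCE.items():
        rl = rl_profile_from_extremes(ref.rrl_max, ref.rrl_min, N_PAIRS)
        ar = _AR_PROFILES[slug]
        sat = SatelliteSpec(pair_id=1, arm="short", frac=SATELLITE_FRAC) \
            if slug == "caracalla" else None
        templates[slug] = SpeciesTemplate(
            name=ref.name,
            n_pairs=N_PAIRS,
            target_tcl_um=ref.tcl_um,
            rl_profile=rl,
            ar_profile=ar,
            satellite=sat,
            markers=_build_markers(ref, rl, ar, SATELLITE_FRAC),
            noise_cv=noise_cv,
            condensation_cv=condensation_cv,
            n_cells=n_cells,
            seed=seed,
        )
    return templates


# ---------------------------------------------------------------------------
# template YAML round-trip


def template_to_yaml(template: SpeciesTemplate, path: str | Path) -> None:
    d = dataclasses.asdict(template)
    d["rl_profile"] = [float(x) for x in d["rl_profile"]]
    d["ar_profile"] = [float(x) for x in d["ar_profile"]]
    d["markers"] = [{k: m[k] for k in
                     ("pair_id", "arm", "marker_type", "start_frac", "end_frac")}
                    for m in d["markers"]]
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def template_from_yaml(path: str | Path) -> SpeciesTemplate:
    d = yaml.safe_load(Path(path).read_text())
    if d.get("satellite"):
        d["satellite"] = SatelliteSpec(**d["satellite"])
    d["markers"] = tuple(MarkerSite(**m) for m in d.get("markers", ()))
    d["rl_profile"] = tuple(d["rl_profile"])
    d["ar_profile"] = tuple(d["ar_profile"])
    return SpeciesTemplate(**d)
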