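"""Published comparative reference values for five wild *Vigna* karyotypes.

These constants transcribe the comparative molecular-cytogenetic
characterization of *V. luteola*, *V. vexillata*, *V. minima*,
*V. trilobata* and *V. caracalla* (all 2n = 2x = 22): karyotype formulae,
complement lengths, relative-length ranges, asymmetry indices, Stebbins
categories, rDNA locus layouts and fluorochrome-band amounts.  They
parameterize the built-in synthetic species templates and serve as the
expected values in desk-check computations; per-pair raw measurements were
not published, so indices that need them (A1, A2, CI dispersion, band
totals) are template inputs only, not fidelity targets.
"""
from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class RdnaRow:
    """One published rDNA locus: position class / di are None when unprinted
    (loci described only as occupying an entire arm)."""

    pair_id: int
    arm: str                    # "short" | "long"
    marker_type: str            # "5S" | "45S"
    position_class: str | None
    di: float | None
    full_arm: bool = False


@dataclass(frozen=True)
class ReferenceKaryotype:
    name: str
    slug: str
    kf: str
    tcl_um: float
    tcl_se_um: float
    c_um: float
    rrl_min: float
    rrl_max: float
    ci_mean: float
    ci_sd: float
    a1: float
    a2: float
    ask_percent: float
    ai: float
    stebbins: str
    rdna: tuple[RdnaRow, ...] = ()
    #: headline non-rDNA CPD amount (% of karyotype length), None if no
    #: non-rDNA CPD bands were reported.
    cpd_amount: float | None = None
    #: of which pericentromeric / interstitial split, when reported.
    cpd_pericen_amount: float | None = None
    cpd_interstitial_amount: float | None = None
    #: arms carrying interstitial CPD bands, as (pair, arm).
    cpd_interstitial_arms: tuple[tuple[int, str], ...] = ()
    #: DAPI+ band amount and arms, when reported.
    dapi_amount: float | None = None
    dapi_arms: tuple[tuple[int, str], ...] = ()


N_PAIRS = 11
TWO_N = 22

REFERENCE: dict[str, ReferenceKaryotype] = {
    "luteola": ReferenceKaryotype(
        name="V. luteola", slug="luteola", kf="11m",
        tcl_um=33.81, tcl_se_um=1.56, c_um=3.07,
        rrl_min=6.88, rrl_max=12.40,
        ci_mean=44.35, ci_sd=2.45, a1=0.20, a2=0.21,
        ask_percent=55.97, ai=1.15, stebbins="1A",
        rdna=(
            RdnaRow(11, "short", "5S", "PCEN", 16.55),
            RdnaRow(3, "short", "45S", None, None, full_arm=True),
        ),
        cpd_amount=29.19, cpd_pericen_amount=29.19,
    ),
    "vexillata": ReferenceKaryotype(
        name="V. vexillata", slug="vexillata", kf="11m",
        tcl_um=25.67, tcl_se_um=2.02, c_um=2.33,
        rrl_min=6.99, rrl_max=12.66,
        ci_mean=43.24, ci_sd=3.45, a1=0.23, a2=0.19,
        ask_percent=57.01, ai=1.52, stebbins="1A",
        rdna=(
            RdnaRow(8, "long", "5S", "INT", 52.29),
            RdnaRow(2, "short", "45S", "TER", 20.53),
            RdnaRow(3, "short", "45S", "TER", 16.73),
        ),
    ),
    "minima": ReferenceKaryotype(
        name="V. minima", slug="minima", kf="11m",
        tcl_um=38.29, tcl_se_um=1.04, c_um=3.48,
        rrl_min=7.37, rrl_max=12.14,
        ci_mean=44.55, ci_sd=2.03, a1=0.19, a2=0.14,
        ask_percent=55.53, ai=0.66, stebbins="1A",
        rdna=(
            RdnaRow(2, "short", "5S", "INT", 30.86),
            RdnaRow(2, "long", "45S", "TER", 58.64),
            RdnaRow(4, "long", "45S", "TER", 59.42),
            RdnaRow(6, "short", "45S", "TER", 38.91),
            RdnaRow(7, "short", "45S", "TER", 50.74),
            RdnaRow(9, "short", "45S", "TER", 67.94),
        ),
    ),
    "trilobata": ReferenceKaryotype(
        name="V. trilobata", slug="trilobata", kf="9m + 2sm",
        tcl_um=36.56, tcl_se_um=2.73, c_um=3.32,
        rrl_min=7.20, rrl_max=13.48,
        ci_mean=42.15, ci_sd=3.87, a1=0.27, a2=0.19,
        ask_percent=58.00, ai=1.76, stebbins="1A",
        rdna=(
            RdnaRow(4, "long", "5S", "PCEN", 14.95),
            RdnaRow(6, "short", "45S", "PCEN", 25.05),
            RdnaRow(7, "short", "45S", None, None, full_arm=True),
        ),
        cpd_amount=20.04, cpd_pericen_amount=20.04,
    ),
    "caracalla": ReferenceKaryotype(
        name="V. caracalla", slug="caracalla", kf="10m (1SAT) + 1sm",
        tcl_um=46.62, tcl_se_um=1.71, c_um=4.24,
        rrl_min=5.61, rrl_max=12.80,
        ci_mean=44.37, ci_sd=3.13, a1=0.20, a2=0.20,
        ask_percent=55.39, ai=1.41, stebbins="1B",
        rdna=(
            RdnaRow(2, "long", "5S", "INT", 34.32),
            RdnaRow(5, "short", "5S", "INT", 56.7),
            RdnaRow(1, "short", "45S", None, None, full_arm=True),
        ),
        cpd_amount=21.68, cpd_pericen_amount=18.29,
        cpd_interstitial_amount=3.39,
        cpd_interstitial_arms=((4, "short"), (4, "long"), (5, "long")),
        dapi_amount=8.19,
        dapi_arms=((2, "short"), (3, "short"), (4, "short"), (5, "short"),
                   (4, "long"), (5, "long"), (6, "long"), (8, "long")),
    ),
}

SPECIES_SLUGS = tuple(REFERENCE)
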