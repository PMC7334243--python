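"""Data model, readers/writers and validation for karyotype tables.

The raw input atom is one chromosome homolog measured in one metaphase cell
(short arm, long arm and satellite lengths in micrometres).  Chromosomal
markers — fluorochrome bands (CPD, DAPI+) and rDNA FISH sites (5S, 45S) —
are fractional intervals along an arm: coordinate 0 at the centromere,
1 at the telomere, both arms independently.

File formats are plain UTF-8 tables, tab- or comma-separated (detected by
extension, ``.csv`` = comma), decimal point only.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

ARMS = ("short", "long", "centromere-spanning")
SAT_ARMS = ("short", "long", "none")
MARKER_TYPES = ("CPD", "DAPI", "5S", "45S")
POSITION_CLASSES = ("CEN", "PCEN", "INT", "TER")

MEASUREMENT_COLUMNS = ("cell_id", "pair_id", "homolog_id",
                       "short_um", "long_um", "sat_um", "sat_arm")
MARKER_COLUMNS = ("pair_id", "arm", "marker_type", "start_frac", "end_frac")


class KaryoError(Exception):
    """Base class for all karyostat errors."""


class SchemaError(KaryoError):
    """A table is missing a required column or holds an unknown category."""


class ValidationError(KaryoError):
    """A value violates a domain invariant (non-positive length, bad fraction...)."""


class PairingError(KaryoError):
    """Homolog bookkeeping is inconsistent within a cell."""


class LinkageError(KaryoError):
    """A marker references a chromosome pair absent from the measurements."""


class TemplateError(KaryoError):
    """A synthetic species template violates its own invariants."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ChromosomeRecord:
    """One homolog's arm measurements in one metaphase cell (lengths in µm)."""

    cell_id: str
    pair_id: int
    homolog_id: int
    short_um: float
    long_um: float
    sat_um: float = 0.0
    sat_arm: str = "none"

    def __post_init__(self) -> None:
        if self.homolog_id not in (1, 2):
            raise ValidationError(f"homolog_id must be 1 or 2, got {self.homolog_id}")
        if self.short_um <= 0 or self.long_um <= 0:
            raise ValidationError(
                f"arm lengths must be > 0 (cell {self.cell_id}, pair {self.pair_id}: "
                f"short={self.short_um}, long={self.long_um})")
        if self.sat_arm not in SAT_ARMS:
            raise ValidationError(f"sat_arm must be one of {SAT_ARMS}, got {self.sat_arm!r}")
        if self.sat_um < 0:
            raise ValidationError("sat_um must be >= 0")
        if (self.sat_um > 0) != (self.sat_arm != "none"):
            raise ValidationError(
                f"sat_um > 0 iff sat_arm != 'none' (cell {self.cell_id}, pair "
                f"{self.pair_id}: sat_um={self.sat_um}, sat_arm={self.sat_arm!r})")

    def arm_lengths(self, include_satellite: bool = True) -> tuple[float, float]:
        """(short, long) arm lengths, satellite folded into its arm if requested."""
        s, l = self.short_um, self.long_um
        if include_satellite:
            if self.sat_arm == "short":
                s += self.sat_um
            elif self.sat_arm == "long":
                l += self.sat_um
        return s, l


@dataclass(frozen=True)
class PairSummary:
    """Averaged morphometrics of one chromosome pair.

    ``pair_id`` is the karyotype number after re-ordering by decreasing
    relative length; ``orig_pair_id`` is the identifier used in the input
    tables.  ``b``/``B`` are mean short/long arm lengths (µm, satellite
    included per configuration), AR = B/b, CI = 100·b/(b+B), RL the pair's
    percentage of the haploid complement length.
    """

    pair_id: int
    orig_pair_id: int
    b: float
    B: float
    AR: float
    CI: float
    RL: float
    levan_class: str
    has_satellite: bool = False

    @property
    def L(self) -> float:
        """Total chromosome length b + B (µm)."""
        return self.b + self.B


@dataclass(frozen=True)
class KaryotypeSummary:
    """Complement-level karyotype statistics (one species)."""

    species: str
    two_n: int
    n_pairs: int
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
    cv_cl: float
    cv_ci: float
    ai: float
    stebbins: str


@dataclass(frozen=True)
class MarkerSite:
    """A fluorochrome band or rDNA site on one arm of a chromosome pair.

    ``start_frac``/``end_frac`` are fractions of the arm length, 0 at the
    centromere.  Derived fields (``d_um``, ``a_um``, ``di``,
    ``position_class``, ``size_percent_tcl``) are ``None`` until the marker
    analysis has been run against a set of pair summaries.  For
    centromere-spanning sites the fractions are read symmetrically into both
    arms and ``di`` is undefined.
    """

    pair_id: int
    arm: str
    marker_type: str
    start_frac: float
    end_frac: float
    d_um: float | None = None
    a_um: float | None = None
    di: float | None = None
    position_class: str | None = None
    size_percent_tcl: float | None = None

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise SchemaError(f"arm must be one of {ARMS}, got {self.arm!r}")
        if self.marker_type not in MARKER_TYPES:
            raise SchemaError(
                f"marker_type must be one of {MARKER_TYPES}, got {self.marker_type!r}")
        if not (0.0 <= self.start_frac < self.end_frac <= 1.0):
            raise ValidationError(
                f"need 0 <= start_frac < end_frac <= 1, got "
                f"[{self.start_frac}, {self.end_frac}] (pair {self.pair_id})")

    @property
    def width_frac(self) -> float:
        return self.end_frac - self.start_frac


@dataclass(frozen=True)
class SatelliteSpec:
    """Satellite placement in a template: distal fraction of one arm."""

    pair_id: int
    arm: str = "short"
    frac: float = 0.15

    def __post_init__(self) -> None:
        if self.arm not in ("short", "long"):
            raise TemplateError("satellite arm must be 'short' or 'long'")
        if not 0.0 < self.frac < 1.0:
            raise TemplateError("satellite fraction must lie in (0, 1)")


@dataclass(frozen=True)
class SpeciesTemplate:
    """Generative parameters for a synthetic diploid karyotype.

    ``rl_profile`` holds per-pair relative lengths (percent of the haploid
    complement, non-increasing, summing to 100); ``ar_profile`` per-pair arm
    ratios.  ``noise_cv`` is the coefficient of variation (percent) of the
    multiplicative measurement noise applied independently per homolog arm
    per cell; ``condensation_cv`` the CV of the cell-level condensation
    factor.  The marker layout is noise-free.
    """

    name: str
    n_pairs: int
    target_tcl_um: float
    rl_profile: tuple[float, ...]
    ar_profile: tuple[float, ...]
    satellite: SatelliteSpec | None = None
    markers: tuple[MarkerSite, ...] = ()
    noise_cv: float = 5.0
    condensation_cv: float = 5.0
    n_cells: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.rl_profile) != self.n_pairs or len(self.ar_profile) != self.n_pairs:
            raise TemplateError("rl_profile and ar_profile must have n_pairs entries")
        if abs(sum(self.rl_profile) - 100.0) > 1e-6:
            raise TemplateError(
                f"rl_profile must sum to 100, got {sum(self.rl_profile):.8f}")
        for a, b in zip(self.rl_profile, self.rl_profile[1:]):
            if b > a + 1e-12:
                raise TemplateError("rl_profile must be non-increasing")
        if any(ar < 1.0 for ar in self.ar_profile):
            raise TemplateError("ar_profile entries must be >= 1")
        if self.noise_cv < 0 or self.condensation_cv < 0:
            raise TemplateError("noise CVs must be >= 0")
        if self.n_cells < 1:
            raise TemplateError("n_cells must be >= 1")

    def noiseless(self) -> "SpeciesTemplate":
        """Copy of the template with all measurement noise switched off."""
        return replace(self, noise_cv=0.0, condensation_cv=0.0)


# ---------------------------------------------------------------------------
# orientation


def orient_record(rec: ChromosomeRecord, include_satellite: bool = True) -> ChromosomeRecord:
    """Swap arms (and the satellite label) so that short <= long.

    Comparison uses satellite-inclusive arm lengths when the satellite is
    counted in the arm, so AR >= 1 holds downstream.  Idempotent.
    """
    s, l = rec.arm_lengths(include_satellite)
    if s <= l:
        return rec
    swap = {"short": "long", "long": "short", "none": "none"}
    return replace(rec, short_um=rec.long_um, long_um=rec.short_um,
                   sat_arm=swap[rec.sat_arm])


def orient_records(records: Iterable[ChromosomeRecord],
                   include_satellite: bool = True) -> list[ChromosomeRecord]:
    return [orient_record(r, include_satellite) for r in records]


# ---------------------------------------------------------------------------
# readers / writers


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_measurements(path: str | Path, *, orient: bool = True,
                      include_satellite: bool = True) -> list[ChromosomeRecord]:
    """Read a measurement table into validated, oriented ChromosomeRecords.

    Required columns: cell_id, pair_id, homolog_id, short_um, long_um;
    sat_um / sat_arm are optional (default: no satellite).  Raises
    :class:`SchemaError` for missing columns, :class:`ValidationError` for
    bad values (with the offending row index) and :class:`PairingError`
    when a pair has an odd number of homolog rows within a cell or a
    duplicated (cell, pair, homolog) key.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    _require_columns(df, ("cell_id", "pair_id", "homolog_id", "short_um", "long_um"), path)
    if "sat_um" not in df.columns:
        df["sat_um"] = 0.0
    if "sat_arm" not in df.columns:
        df["sat_arm"] = "none"
    df["sat_um"] = df["sat_um"].fillna(0.0)
    df["sat_arm"] = df["sat_arm"].fillna("none")

    records: list[ChromosomeRecord] = []
    for idx, row in df.iterrows():
        try:
            rec = ChromosomeRecord(
                cell_id=str(row["cell_id"]),
                pair_id=int(row["pair_id"]),
                homolog_id=int(row["homolog_id"]),
                short_um=float(row["short_um"]),
                long_um=float(row["long_um"]),
                sat_um=float(row["sat_um"]),
                sat_arm=str(row["sat_arm"]),
            )
        except KaryoError as err:
            raise type(err)(f"{path}, row {idx}: {err}") from err
        records.append(rec)

    seen: set[tuple[str, int, int]] = set()
    for rec in records:
        key = (rec.cell_id, rec.pair_id, rec.homolog_id)
        if key in seen:
            raise PairingError(f"{path}: duplicate (cell, pair, homolog) {key}")
        seen.add(key)
    counts: dict[tuple[str, int], int] = {}
    for rec in records:
        counts[(rec.cell_id, rec.pair_id)] = counts.get((rec.cell_id, rec.pair_id), 0) + 1
    odd = [k for k, v in counts.items() if v % 2]
    if odd:
        raise PairingError(f"{path}: odd homolog count for (cell, pair) {odd[0]}")

    if orient:
        records = orient_records(records, include_satellite)
    return records


def write_measurements(records: Iterable[ChromosomeRecord], path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame([dataclasses.asdict(r) for r in records],
                      columns=list(MEASUREMENT_COLUMNS))
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_markers(path: str | Path) -> list[MarkerSite]:
    """Read a marker table into validated MarkerSites (derived fields unset).

    An empty table (header only) yields an empty list.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    _require_columns(df, MARKER_COLUMNS, path)
    sites: list[MarkerSite] = []
    for idx, row in df.iterrows():
        try:
            sites.append(MarkerSite(
                pair_id=int(row["pair_id"]),
                arm=str(row["arm"]),
                marker_type=str(row["marker_type"]),
                start_frac=float(row["start_frac"]),
                end_frac=float(row["end_frac"]),
            ))
        except KaryoError as err:
            raise type(err)(f"{path}, row {idx}: {err}") from err
    return sites


def write_markers(sites: Iterable[MarkerSite], path: str | Path) -> None:
    path = Path(path)
    rows = [{c: getattr(s, c) for c in MARKER_COLUMNS} for s in sites]
    pd.DataFrame(rows, columns=list(MARKER_COLUMNS)).to_csv(
        path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# report output


def _round(x: float | None, dp: int) -> float | None:
    return None if x is None else round(float(x), dp)


def summary_to_dict(summary: KaryotypeSummary) -> dict:
    return dataclasses.asdict(summary)


def summary_from_dict(d: dict) -> KaryotypeSummary:
    return KaryotypeSummary(**d)


def karyotype_table_row(summary: KaryotypeSummary, dp: int = 2) -> dict:
    """One comparative-table row (printed layout) from a summary."""
    return {
        "species": summary.species,
        "2n": summary.two_n,
        "KF": summary.kf,
        "TCL_um": _round(summary.tcl_um, dp),
        "TCL_SE_um": _round(summary.tcl_se_um, dp),
        "C_um": _round(summary.c_um, dp),
        "RRL": f"{summary.rrl_min:.{dp}f}-{summary.rrl_max:.{dp}f}",
        "CI_mean": _round(summary.ci_mean, dp),
        "CI_SD": _round(summary.ci_sd, dp),
        "A1": _round(summary.a1, dp),
        "A2": _round(summary.a2, dp),
        "AsK_percent": _round(summary.ask_percent, dp),
        "AI": _round(summary.ai, dp),
        "Stebbins": summary.stebbins,
    }


def write_report(summary: KaryotypeSummary,
                 pairs: Sequence[PairSummary],
                 markers: Sequence[MarkerSite],
                 out_dir: str | Path,
                 *,
                 dp: int = 2,
                 extras: dict | None = None) -> dict[str, Path]:
    """Write report.json plus comparative-table-style TSVs into *out_dir*.

    report.json mirrors the KaryotypeSummary fields at full precision (JSON
    floats round-trip exactly); the TSV tables are rounded to *dp* decimals
    for display.  Returns the paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    payload = {
        "summary": summary_to_dict(summary),
        "pairs": [dataclasses.asdict(p) for p in pairs],
        "markers": [dataclasses.asdict(m) for m in markers],
    }
    if extras:
        payload.update(extras)
    report_json = out_dir / "report.json"
    report_json.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    karyotype_tsv = out_dir / "karyotype_table.tsv"
    pd.DataFrame([karyotype_table_row(summary, dp)]).to_csv(
        karyotype_tsv, sep="\t", index=False)

    marker_tsv = out_dir / "marker_table.tsv"
    marker_rows = [{
        "pair": m.pair_id,
        "arm": m.arm,
        "type": m.marker_type,
        "position_class": m.position_class,
        "di": _round(m.di, dp),
        "size_percent_tcl": _round(m.size_percent_tcl, dp),
        "start_frac": m.start_frac,
        "end_frac": m.end_frac,
    } for m in markers]
    pd.DataFrame(marker_rows, columns=["pair", "arm", "type", "position_class",
                                       "di", "size_percent_tcl",
                                       "start_frac", "end_frac"]).to_csv(
        marker_tsv, sep="\t", index=False)

    return {"report": report_json, "karyotype_table": karyotype_tsv,
            "marker_table": marker_tsv}


def read_report(path: str | Path) -> dict:
    """Read back a report.json written by :func:`write_report`."""
    return json.loads(Path(path).read_text())
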