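"""di statistic, position classes, band amounts and rDNA locus counts."""
import numpy as np
import pytest

import karyostat as ks
from karyostat.markers import annotate_markers, band_amounts
from karyostat.metrics import summarize_pairs
from karyostat.reference import REFERENCE

from conftest import records_from_arms


@pytest.fixture
def two_pairs():
    # pair 1: arms 2.0/2.0; pair 2: arms 1.5/2.5 (equal total lengths)
    return summarize_pairs(records_from_arms([2.0, 1.5], [2.0, 2.5]))


def _site(pair=1, arm="short", mtype="45S", start=0.0, end=1.0):
    return ks.MarkerSite(pair, arm, mtype, start, end)


class TestDi:
    def test_centromeric_limit(self, two_pairs):
        site = _site(start=0.0, end=1.0)
        assert ks.compute_di(site, two_pairs[0]) == pytest.approx(0.0)

    def test_terminal_site_uses_start(self, two_pairs):
        site = _site(start=0.6794, end=1.0)
        assert ks.compute_di(site, two_pairs[0]) == pytest.approx(67.94)

    def test_interstitial_site_uses_midpoint(self, two_pairs):
        site = _site(start=0.25, end=0.35)
        assert ks.compute_di(site, two_pairs[0]) == pytest.approx(30.0)

    def test_centromere_spanning_has_no_di(self, two_pairs):
        site = _site(arm="centromere-spanning", start=0.0, end=0.05)
        assert ks.compute_di(site, two_pairs[0]) is None

    def test_di_invariant_under_arm_scaling(self):
        site = _site(start=0.30, end=0.42)
        small = summarize_pairs(records_from_arms([1.0, 1.1], [1.5, 1.2]))
        big = summarize_pairs(records_from_arms([3.0, 3.3], [4.5, 3.6]))
        assert ks.compute_di(site, small[0]) == ks.compute_di(site, big[0])


class TestPositionClass:
    def test_pericentromeric(self, two_pairs):
        assert ks.classify_position(_site(start=0.0, end=0.05), two_pairs[0]) == "PCEN"

    def test_terminal(self, two_pairs):
        assert ks.classify_position(_site(start=0.95, end=1.0), two_pairs[0]) == "TER"

    def test_interstitial(self, two_pairs):
        site = _site(start=0.4929, end=0.5529)   # center di 52.29
        assert ks.classify_position(site, two_pairs[0]) == "INT"

    def test_centromere_spanning_is_cen(self, two_pairs):
        site = _site(arm="centromere-spanning", start=0.0, end=0.05)
        assert ks.classify_position(site, two_pairs[0]) == "CEN"

    def test_threshold_separates_pcen_from_int(self, two_pairs):
        below = _site(start=0.2, end=0.3)     # di 25 -> PCEN
        above = _site(start=0.25, end=0.35)   # di 30 -> INT
        assert ks.classify_position(below, two_pairs[0]) == "PCEN"
        assert ks.classify_position(above, two_pairs[0]) == "INT"


class TestAnnotateAndBandAmounts:
    def test_no_bands_all_totals_zero(self, two_pairs):
        totals = band_amounts([], two_pairs, tcl_um=8.0)
        assert totals.totals == {}
        assert totals.cpd_including_rdna == 0.0

    def test_full_arm_band_identity(self):
        # one band covering an entire arm that is 10% of TCL
        pairs = summarize_pairs(records_from_arms([1.0, 4.0], [1.0, 4.0]))
        tcl = 10.0
        totals = band_amounts([_site(pair=1, mtype="CPD", start=0.0, end=1.0)],
                              pairs, tcl)
        assert totals.totals["CPD"] == pytest.approx(10.0)

    def test_arithmetic_oracle(self):
        # two 0-0.1 bands on 2 um arms, TCL 20 um -> 2 * 0.1*2/20 = 2%
        pairs = summarize_pairs(records_from_arms([2.0, 2.0], [8.0, 8.0]))
        sites = [_site(pair=1, mtype="DAPI", start=0.0, end=0.1),
                 _site(pair=2, mtype="DAPI", start=0.0, end=0.1)]
        totals = band_amounts(sites, pairs, tcl_um=20.0)
        assert totals.totals["DAPI"] == pytest.approx(2.0)

    def test_per_pair_sizes_sum_to_totals(self, noiseless_reports):
        for rep in noiseless_reports.values():
            bt = rep.band_totals
            for mtype, total in bt.totals.items():
                per_pair = sum(v for (p, t), v in bt.per_pair.items() if t == mtype)
                assert per_pair == pytest.approx(total, abs=1e-12)

    def test_headline_cpd_excludes_45s_bands(self):
        pairs = summarize_pairs(records_from_arms([2.0, 2.0], [2.0, 2.0]))
        sites = [_site(pair=1, mtype="45S", start=0.2, end=1.0),
                 _site(pair=1, mtype="CPD", start=0.2, end=1.0),   # rDNA-CPD
                 _site(pair=2, mtype="CPD", start=0.0, end=0.3)]   # pericen
        totals = band_amounts(sites, pairs, tcl_um=8.0)
        assert totals.totals["CPD"] == pytest.approx(100 * 0.3 * 2 / 8)
        assert totals.cpd_including_rdna == pytest.approx(
            100 * (0.8 * 2 + 0.3 * 2) / 8)

    def test_unknown_pair_is_linkage_error(self, two_pairs):
        with pytest.raises(ks.LinkageError):
            annotate_markers([_site(pair=9)], two_pairs, tcl_um=8.0)


class TestLocusCounts:
    def test_counts_from_builtin_layouts(self, templates):
        counts = {slug: ks.locus_counts(t.markers) for slug, t in templates.items()}
        assert counts["minima"]["45S"] == 5
        assert counts["caracalla"]["5S"] == 2
        assert counts["luteola"] == {"5S": 1, "45S": 1}
        assert counts["vexillata"] == {"5S": 1, "45S": 2}
        assert counts["trilobata"] == {"5S": 1, "45S": 2}

    def test_empty_marker_set(self):
        assert ks.locus_counts([]) == {"5S": 0, "45S": 0}

    def test_syntenic_rdna_pair_in_minima(self, templates):
        # the 45S on pair 2 long arm is syntenic to the 5S on pair 2 short arm
        assert ks.syntenic_pairs(templates["minima"].markers) == [2]


class TestColocalization:
    def test_identical_intervals_full_overlap(self):
        sites = [_site(mtype="45S", start=0.0, end=1.0),
                 _site(mtype="CPD", start=0.0, end=1.0)]
        rep = ks.colocalization_report(sites)
        assert len(rep) == 1 and rep[0].overlap_frac == pytest.approx(1.0)

    def test_partial_overlap_fraction(self):
        sites = [_site(mtype="5S", start=0.10, end=0.20),
                 _site(mtype="CPD", start=0.0, end=0.15)]
        rep = ks.colocalization_report(sites)
        assert rep[0].overlap_frac == pytest.approx(0.5)

    def test_different_arms_no_overlap(self):
        sites = [_site(arm="short", mtype="5S", start=0.1, end=0.2),
                 _site(arm="long", mtype="CPD", start=0.1, end=0.2)]
        assert ks.colocalization_report(sites) == []

    def test_trilobata_5s_colocalizes_with_pericen_cpd(self, noiseless_reports):
        cases = [c for c in noiseless_reports["trilobata"].colocalizations
                 if c.rdna.marker_type == "5S" and c.band.marker_type == "CPD"]
        assert cases and all(0 < c.overlap_frac <= 1 for c in cases)


class TestPublishedTranscription:
    def test_every_printed_class_di_pair_reproduced(self, noiseless_reports):
        """classify_position ∘ compute_di matches all published rDNA rows."""
        checked = 0
        for slug, rep in noiseless_reports.items():
            for row in REFERENCE[slug].rdna:
                if row.position_class is None:
                    continue
                match = [m for m in rep.markers
                         if (m.pair_id, m.arm, m.marker_type)
                         == (row.pair_id, row.arm, row.marker_type)]
                assert len(match) == 1
                m = match[0]
                assert m.position_class == row.position_class
                assert round(m.di, 2) == pytest.approx(row.di, abs=5e-3)
                checked += 1
        assert checked == 14   # all printed 5S/45S (class, di) rows
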