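import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pollenrisk.core import (
    ExposureParams,
    RegulatoryThresholds,
    ResidueRecord,
    round_half_up,
)
from pollenrisk import hazard as hz

from oracles import (
    brute_compound_summary,
    brute_nonspray_fractions,
    brute_pui,
    brute_site_totals,
)
from conftest import make_small_study


class TestPhqRaw:
    @pytest.mark.parametrize(
        "conc,ld50,expected",
        [
            (557.1, 0.118, 4721.2),  # high-toxicity insecticide, contact
            (69.9, 0.15, 466.0),  # carbamate insecticide, oral
            (0.0, 0.118, 0.0),
        ],
    )
    def test_raw_quotient_is_residue_over_ld50(self, conc, ld50, expected):
        assert round_half_up(hz.phq_raw(conc, ld50), 1) == expected

    def test_missing_ld50_is_route_skip_not_exception(self):
        assert hz.phq_raw(100.0, None) is None

    @given(
        conc=st.floats(0, 1e5),
        ld50=st.floats(1e-3, 500, exclude_min=True),
        c=st.floats(0.01, 100),
    )
    @settings(max_examples=100, deadline=None)
    def test_linear_in_concentration(self, conc, ld50, c):
        assert hz.phq_raw(c * conc, ld50) == pytest.approx(c * hz.phq_raw(conc, ld50))


class TestPctOfLd50:
    """Unit-conversion oracle: ppb x grams pollen / 1000 = fraction of LD50."""

    def test_zero_phq_gives_zero_percent(self):
        assert hz.pct_of_ld50(0.0, "contact") == 0.0

    def test_contact_phq_4000_is_exactly_the_epa_boundary(self):
        # 4000 x 0.1 g / 1000 = 0.4 = the Tier 1 risk quotient
        assert hz.pct_of_ld50(4000.0, "contact") == pytest.approx(40.0)

    def test_oral_boundary_phq_for_efsa_chronic(self):
        # 0.03 / (0.094 g / 1000) = 319.1489...
        phq = 0.03 / 9.4e-5
        assert hz.pct_of_ld50(phq, "oral") == pytest.approx(3.0)

    def test_unknown_route_is_hard_error(self):
        with pytest.raises(ValueError):
            hz.pct_of_ld50(1.0, "dermal")

    def test_scales_with_exposure_params(self):
        heavy = ExposureParams(contact_mass_mg=200.0)
        assert hz.pct_of_ld50(100.0, "contact", heavy) == pytest.approx(
            2 * hz.pct_of_ld50(100.0, "contact")
        )


class TestClassifyLoc:
    def test_between_efsa_and_epa_acute_thresholds(self):
        flags = hz.classify_loc(30.0, 0.0)
        assert flags == {
            "epa_acute_contact": False,
            "efsa_acute_contact": True,
            "efsa_chronic_oral": False,
        }

    def test_above_both_acute_thresholds(self):
        flags = hz.classify_loc(47.2, 0.0)
        assert flags["epa_acute_contact"] and flags["efsa_acute_contact"]

    def test_oral_just_below_threshold(self):
        assert not hz.classify_loc(0.0, 2.9)["efsa_chronic_oral"]

    def test_all_zero_gives_no_flags(self):
        assert not any(hz.classify_loc(0.0, 0.0).values())

    def test_boundary_equality_is_non_exceedance(self):
        flags = hz.classify_loc(40.0, 3.0)
        assert not flags["epa_acute_contact"] and not flags["efsa_chronic_oral"]

    @pytest.mark.parametrize(
        "flag,route,boundary_phq",
        [
            ("epa_acute_contact", "contact", 4000.0),
            ("efsa_acute_contact", "contact", 2000.0),
            ("efsa_chronic_oral", "oral", 0.03 / 9.4e-5),
        ],
    )
    def test_flags_flip_exactly_at_closed_form_phq(self, flag, route, boundary_phq):
        """classify_loc(pct_of_ld50(x)) flips exactly at the inverted total
        PHQ under default exposure assumptions."""
        eps = 1e-9
        for phq, expect in [(boundary_phq * (1 - eps), False), (boundary_phq * (1 + eps), True)]:
            pct = hz.pct_of_ld50(phq, route)
            flags = hz.classify_loc(
                pct if route == "contact" else 0.0,
                pct if route == "oral" else 0.0,
            )
            assert flags[flag] is expect


class TestSiteRisk:
    def test_single_compound_total(self, toxdb):
        recs = [ResidueRecord.from_measurement("S1", "Indoxacarb", 557.1, 35.5)]
        sr = hz.site_risk(recs, toxdb)
        assert round_half_up(sr.total_contact_phq, 1) == 4721.2

    def test_no_detections_gives_zero_totals_and_no_flags(self, toxdb):
        recs = [ResidueRecord.from_measurement("S1", "Boscalid", 0.0, 35.5)]
        sr = hz.site_risk(recs, toxdb)
        assert sr.total_contact_phq == 0 and sr.total_oral_phq == 0
        assert not any(sr.loc_flags.values())

    def test_additivity_of_compound_quotients(self, toxdb):
        recs = [
            ResidueRecord.from_measurement("S1", "Cyprodinil", 100 * 100.0, 0.4),
            ResidueRecord.from_measurement("S1", "Difenoconazole", 200 * 101.0, 1.4),
        ]
        sr = hz.site_risk(recs, toxdb)
        assert sr.total_contact_phq == pytest.approx(300.0)
        assert sr.total_contact_phq == pytest.approx(
            sum(cp.contact_phq for cp in sr.compound_phq.values())
        )

    def test_missing_ld50_route_is_skipped_and_flagged(self, toxdb):
        recs = [ResidueRecord.from_measurement("S1", "Abamectin", 21.9, 3.6)]
        sr = hz.site_risk(recs, toxdb)
        assert sr.compound_phq["Abamectin"].skipped_routes == {"oral"}
        assert sr.total_oral_phq == 0.0
        assert sr.total_contact_phq == pytest.approx(21.9 / 0.03)

    def test_unknown_compound_is_hard_error(self, toxdb):
        recs = [ResidueRecord.from_measurement("S1", "Captan", 10.0, 1.0)]
        with pytest.raises(ValueError, match="Captan"):
            hz.site_risk(recs, toxdb)

    def test_adding_a_residue_never_decreases_totals(self, toxdb):
        """Monotonicity: one more detected residue can only raise risk."""
        base = [ResidueRecord.from_measurement("S1", "Carbaryl", 69.9, 3.6)]
        more = base + [ResidueRecord.from_measurement("S1", "Acetamiprid", 160.5, 1.4)]
        a, b = hz.site_risk(base, toxdb), hz.site_risk(more, toxdb)
        assert b.total_contact_phq >= a.total_contact_phq
        assert b.total_oral_phq >= a.total_oral_phq
        for k in a.loc_flags:
            assert b.loc_flags[k] >= a.loc_flags[k]


class TestAttribution:
    def _phqs(self, **kw):
        return {
            name: hz.CompoundPhq(contact_phq=v, oral_phq=v)
            for name, v in kw.items()
        }

    def _spray(self, compound, bloom=True):
        from datetime import date
        from pollenrisk.core import SprayEvent

        return SprayEvent("S1", compound, date(2015, 5, 10), 50.0, 1.0, bloom)

    def test_simple_split(self):
        frac_c, _ = hz.attribute_spray_status(
            self._phqs(A=30.0, B=70.0), [self._spray("A")], "S1"
        )
        assert frac_c == pytest.approx(0.70)

    def test_no_spray_events_attributes_everything_to_nonspray(self):
        frac_c, frac_o = hz.attribute_spray_status(self._phqs(A=30.0), [], "S1")
        assert frac_c == frac_o == 1.0

    def test_all_sprayed_gives_zero(self):
        frac_c, _ = hz.attribute_spray_status(
            self._phqs(A=30.0, B=70.0), [self._spray("A"), self._spray("B")], "S1"
        )
        assert frac_c == 0.0

    def test_out_of_bloom_spray_does_not_count(self):
        frac_c, _ = hz.attribute_spray_status(
            self._phqs(A=100.0), [self._spray("A", bloom=False)], "S1"
        )
        assert frac_c == 1.0

    def test_zero_total_defined_as_zero(self):
        assert hz.attribute_spray_status({}, [], "S1") == (0.0, 0.0)


class TestPui:
    def _ev(self, ld50_compound, pct_ai, rate, bloom=True, site="S1"):
        from datetime import date
        from pollenrisk.core import SprayEvent

        return SprayEvent(site, ld50_compound, date(2015, 5, 10), pct_ai, rate, bloom)

    def test_single_event_formula(self, toxdb):
        # spinosyn insecticide: contact LD50 0.003 µg/bee, 100% a.i., 1 kg/ha
        r = hz.pui([self._ev("Spinosad", 100.0, 1.0)], toxdb)
        assert r.pui_all == pytest.approx(1 / 0.003)

    def test_empty_event_list_is_valid_zero(self, toxdb):
        assert hz.pui([], toxdb).pui_all == 0.0

    def test_two_identical_events_double_the_index(self, toxdb):
        e = self._ev("Spinosad", 50.0, 2.0)
        assert hz.pui([e, e], toxdb).pui_all == pytest.approx(
            2 * hz.pui([e], toxdb).pui_all
        )

    def test_panel_restriction_is_a_lower_bound(self, toxdb):
        evs = [self._ev("Spinosad", 100, 1.0), self._ev("Carbaryl", 50, 2.0)]
        r = hz.pui(evs, toxdb, panel={"Spinosad"})
        assert r.pui_panel == pytest.approx(1 / 0.003)
        assert r.pui_panel <= r.pui_all

    def test_compound_without_contact_ld50_skipped_with_warning(self, toxdb, caplog):
        evs = [self._ev("NotInDb", 100, 1.0)]
        with caplog.at_level("WARNING"):
            r = hz.pui(evs, toxdb)
        assert r.pui_all == 0.0 and "NotInDb" in caplog.text

    def test_non_bloom_events_excluded(self, toxdb):
        assert hz.pui([self._ev("Spinosad", 100, 1.0, bloom=False)], toxdb).pui_all == 0.0


class TestCompoundSummary:
    def test_mean_of_positive_detections(self, toxdb):
        recs = [
            ResidueRecord.from_measurement("S1", "Indoxacarb", 500.0, 35.5),
            ResidueRecord.from_measurement("S2", "Indoxacarb", 614.2, 35.5),
            ResidueRecord.from_measurement("S3", "Indoxacarb", 0.0, 35.5),
        ]
        (row,) = hz.summarize_compounds(recs, toxdb)
        assert row.mean_residue == pytest.approx(557.1)
        assert row.n_detections == 2
        assert round_half_up(row.mean_contact_phq, 1) == 4721.2

    def test_never_detected_compound_is_all_zero(self, toxdb):
        recs = [ResidueRecord.from_measurement("S1", "Boscalid", 0.0, 35.5)]
        (row,) = hz.summarize_compounds(recs, toxdb)
        assert (row.mean_residue, row.n_detections, row.mean_contact_phq, row.mean_oral_phq) == (0.0, 0, 0.0, 0.0)

    def test_single_site_mean_is_that_value(self, toxdb):
        recs = [ResidueRecord.from_measurement("S1", "Carbaryl", 69.9, 3.6)]
        (row,) = hz.summarize_compounds(recs, toxdb)
        assert row.mean_residue == 69.9

    def test_sorted_descending_contact_phq_missing_last(self, toxdb):
        recs = [
            ResidueRecord.from_measurement("S1", "Cyprodinil", 1216.4, 0.4),
            ResidueRecord.from_measurement("S1", "Indoxacarb", 557.1, 35.5),
            ResidueRecord.from_measurement("S1", "Abamectin", 21.9, 3.6),
        ]
        rows = hz.summarize_compounds(recs, toxdb)
        names = [r.compound for r in rows]
        # contact PHQs: indoxacarb 4721.2, abamectin 729.97, cyprodinil 12.2
        assert names == ["Indoxacarb", "Abamectin", "Cyprodinil"]

    def test_missing_contact_ld50_sorts_last(self, toxdb):
        recs = [
            ResidueRecord.from_measurement("S1", "Atrazine", 28.2, 3.6),
            ResidueRecord.from_measurement("S1", "Thiacloprid", 9.6, 3.6),
        ]
        # give atrazine a residue but strip its contact LD50 via a local db
        from pollenrisk.core import CompoundTox

        db = dict(toxdb)
        db["Atrazine"] = CompoundTox("Atrazine", "herbicide", None, None)
        rows = hz.summarize_compounds(recs, db)
        assert rows[-1].compound == "Atrazine"
        assert rows[-1].mean_contact_phq is None


class TestOracleEquivalence:
    """Brute-force double loops reproduce the hazard aggregations exactly
    on random small studies (<= 5 sites x <= 5 compounds)."""

    def test_random_small_studies(self):
        rng = random.Random(42)
        for _ in range(100):
            residues, tox, sprays = make_small_study(rng)
            sites = sorted({r.site_id for r in residues})
            for sid in sites:
                site_res = [r for r in residues if r.site_id == sid]
                sr = hz.site_risk(site_res, tox, sprays)
                tot_c, tot_o = brute_site_totals(residues, tox, sid)
                assert sr.total_contact_phq == pytest.approx(tot_c, abs=1e-12)
                assert sr.total_oral_phq == pytest.approx(tot_o, abs=1e-12)
                ns = brute_nonspray_fractions(residues, tox, sprays, sid)
                assert (sr.nonspray_fraction_contact, sr.nonspray_fraction_oral) == pytest.approx(ns)
                site_evs = [e for e in sprays if e.site_id == sid]
                panel = {r.compound for r in site_res if r.detected}
                p = hz.pui(site_evs, tox, panel=panel)
                bp = brute_pui(sprays, tox, sid, panel)
                assert (p.pui_all, p.pui_panel) == pytest.approx(bp)
            for comp in tox:
                row = next(
                    r for r in hz.summarize_compounds(residues, tox) if r.compound == comp
                )
                mean, n, c, o = brute_compound_summary(residues, tox, comp)
                assert row.mean_residue == pytest.approx(mean)
                assert row.n_detections == n
                for got, want in ((row.mean_contact_phq, c), (row.mean_oral_phq, o)):
                    if want is None:
                        assert got is None
                    else:
                        assert got == pytest.approx(want)


@given(c=st.floats(0.01, 50))
@settings(max_examples=50, deadline=None)
def test_scaling_all_concentrations_scales_risk_linearly(toxdb, c):
    """Scaling every residue by c scales totals and percents by c."""
    base = [
        ResidueRecord.from_measurement("S1", "Carbaryl", 69.9, 1e-9),
        ResidueRecord.from_measurement("S1", "Cyprodinil", 1216.4, 1e-9),
    ]
    scaled = [
        ResidueRecord.from_measurement(r.site_id, r.compound, c * r.concentration, r.lod)
        for r in base
    ]
    a, b = hz.site_risk(base, toxdb), hz.site_risk(scaled, toxdb)
    assert b.total_contact_phq == pytest.approx(c * a.total_contact_phq)
    assert b.pct_ld50_oral == pytest.approx(c * a.pct_ld50_oral)
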