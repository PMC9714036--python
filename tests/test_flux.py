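"""Slope fitting, relative V_CS, steady-state decision, dilution indices."""

import numpy as np
import pandas as pd
import pytest

import tcaflux as tf
from tcaflux.errors import DataError, DomainError
from tcaflux.timecourse import LabelTimeCourse


def _tc_from_enrichments(points, metabolite="citrate", n_carbons=6):
    """Build a time course whose atom-fraction enrichment hits given values.

    Places mass at M0 and Mn only: enrichment e needs fraction e at Mn.
    """
    records = []
    for t, e, rep in points:
        frac = np.zeros(n_carbons + 1)
        frac[0], frac[-1] = 1.0 - e, e
        records.append(
            (
                {"condition": "c", "tracer": "glucose_U13C6", "time_min": t,
                 "replicate": rep},
                tf.MIDVector(metabolite, frac),
            )
        )
    return LabelTimeCourse.from_mids(records)


class TestFitLabelSlope:
    def test_exact_line_through_origin(self):
        tc = _tc_from_enrichments([(0, 0, 0), (10, 0.1, 0), (20, 0.2, 0), (30, 0.3, 0)])
        fit = tf.fit_label_slope(tc)
        assert fit.slope == pytest.approx(0.01)
        assert fit.stderr == pytest.approx(0.0, abs=1e-12)

    def test_single_timepoint_origin_ratio(self):
        # the in vivo convention: one measurement at 60 min vs the origin
        tc = _tc_from_enrichments([(60, 0.12, 0)])
        fit = tf.fit_label_slope(tc, window=(0, 60))
        assert fit.slope == pytest.approx(0.002)
        assert fit.n_points == 1

    def test_empty_window_rejected(self):
        tc = _tc_from_enrichments([(60, 0.12, 0)])
        with pytest.raises(DataError):
            tf.fit_label_slope(tc, window=(0, 30))

    def test_matches_finite_difference_in_linear_regime(self):
        """In the slope readout's validity regime (citrate turnover much
        slower than the window, fast tracer entry) the fitted slope agrees
        with a central finite-difference derivative at the window midpoint."""
        from tcaflux.experiments import VCS_RECOVERY_FLUXES, VCS_RECOVERY_POOLS

        pools = dict(VCS_RECOVERY_POOLS, pyruvate=0.2, acetyl_coa=0.2)
        model = tf.build_network(
            {"pools": pools, "fluxes": dict(VCS_RECOVERY_FLUXES, v_cs=1.0)}
        )
        tc = tf.simulate_timecourse(
            model, tf.TracerSpec.constant("glucose_U13C6", 0.99),
            [0.0, 5.0, 10.0, 14.0, 15.0, 16.0, 20.0, 25.0, 30.0],
        )
        e = tc.enrichments()
        cit = e[e["metabolite"] == "citrate"].set_index("time_min")["enrichment"]
        fd = (cit.loc[16.0] - cit.loc[14.0]) / 2.0
        fit = tf.fit_label_slope(tc, window=(0.0, 30.0))
        assert fit.slope == pytest.approx(fd, rel=0.05)
        m2 = {
            t: tf.isotopologue_fraction(tc.mid("citrate", t), 2)
            for t in (14.0, 16.0)
        }
        fd_m2 = (m2[16.0] - m2[14.0]) / 2.0
        fit_m2 = tf.fit_label_slope(tc, window=(0.0, 30.0), shift=2)
        assert fit_m2.slope == pytest.approx(fd_m2, rel=0.05)

    def test_sigmoid_lag_bounds_slope_at_infusion_defaults(self, glucose_infusion_tc):
        """At in vivo defaults the rise has a lag, so the average slope lies
        strictly inside the pointwise-derivative envelope rather than
        matching the midpoint derivative."""
        e = glucose_infusion_tc.enrichments()
        cit = e[e["metabolite"] == "citrate"].set_index("time_min")["enrichment"]
        grid = cit.loc[[0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0]].to_numpy()
        derivs = np.diff(grid) / 5.0
        fit = tf.fit_label_slope(glucose_infusion_tc)
        assert derivs.min() < fit.slope < derivs.max()


class TestRelativeVcs:
    def test_reference_against_itself_is_one(self):
        assert tf.relative_vcs(0.01, 0.01) == 1.0

    def test_doubled_slope(self):
        assert tf.relative_vcs(0.02, 0.01) == 2.0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(DomainError):
            tf.relative_vcs(0.01, 0.0)

    def test_scale_invariance(self):
        """Multiplying every enrichment in both conditions by c > 0 leaves
        relative V_CS unchanged."""
        pts_ref = [(t, 0.004 * t, 0) for t in (0, 10, 20, 30)]
        pts_test = [(t, 0.007 * t, 0) for t in (0, 10, 20, 30)]
        for c in (0.5, 1.0, 2.0):
            s_ref = tf.fit_label_slope(
                _tc_from_enrichments([(t, c * e, r) for t, e, r in pts_ref])
            ).slope
            s_test = tf.fit_label_slope(
                _tc_from_enrichments([(t, c * e, r) for t, e, r in pts_test])
            ).slope
            assert tf.relative_vcs(s_test, s_ref) == pytest.approx(1.75)


class TestSteadyStateCheck:
    def test_identical_replicates_are_steady(self):
        pts = [(60, e, r) for r, e in enumerate((0.10, 0.11, 0.12))]
        pts += [(150, e, r) for r, e in enumerate((0.10, 0.11, 0.12))]
        dec = tf.steady_state_check(_tc_from_enrichments(pts))
        assert dec.steady and dec.p_value == pytest.approx(1.0)

    def test_clearly_rising_enrichment_is_not_steady(self):
        # textbook pooled t: means 0.10 vs 0.30, sd 0.01, n = 5 per group
        # => t = 0.2 / (0.01 * sqrt(2/5)) ~ 31.6, p far below alpha
        rng = np.random.default_rng(1)
        a = 0.10 + 0.01 * (rng.standard_normal(5))
        b = 0.30 + 0.01 * (rng.standard_normal(5))
        pts = [(60, e, r) for r, e in enumerate(a)]
        pts += [(150, e, r) for r, e in enumerate(b)]
        dec = tf.steady_state_check(_tc_from_enrichments(pts))
        assert not dec.steady
        assert dec.p_value < 1e-6

    def test_alpha_zero_always_steady(self):
        pts = [(60, 0.1 + 0.01 * r, r) for r in range(3)]
        pts += [(150, 0.5 + 0.01 * r, r) for r in range(3)]
        dec = tf.steady_state_check(_tc_from_enrichments(pts), alpha=0.0)
        assert dec.steady

    def test_insufficient_replicates_rejected(self):
        pts = [(60, 0.1, 0), (150, 0.1, 0), (150, 0.12, 1)]
        with pytest.raises(DataError):
            tf.steady_state_check(_tc_from_enrichments(pts))


class TestGlycolysisAndLactate:
    @pytest.mark.parametrize("m3,m6,expected", [(0.0, 0.5, 0.0), (0.25, 0.5, 0.5)])
    def test_glycolysis_index(self, m3, m6, expected):
        assert tf.glycolysis_index(m3, m6) == pytest.approx(expected)

    def test_zero_glucose_rejected(self):
        with pytest.raises(DomainError):
            tf.glycolysis_index(0.1, 0.0)

    def test_lactate_rate(self):
        assert tf.lactate_production_rate(0.0, 6.0, 6.0, 1.0) == pytest.approx(1.0)
        assert tf.lactate_production_rate(2.0, 2.0, 6.0, 1.0) == 0.0
        with pytest.raises(DomainError):
            tf.lactate_production_rate(0.0, 6.0, 6.0, 0.0)


class TestDilutionProfile:
    def _tc(self, enrichments, time=60.0):
        records = []
        carbons = {"citrate": 6, "glutamate": 5, "succinate": 4, "malate": 4}
        for met, e in enrichments.items():
            n = carbons[met]
            frac = np.zeros(n + 1)
            frac[0], frac[-1] = 1 - e, e
            records.append(
                (
                    {"condition": "c", "tracer": "glucose_U13C6",
                     "time_min": time, "replicate": 0},
                    tf.MIDVector(met, frac),
                )
            )
        return LabelTimeCourse.from_mids(records)

    def test_equal_enrichment_gives_zero_dilution(self):
        tc = self._tc({m: 0.3 for m in ("citrate", "glutamate", "succinate", "malate")})
        prof = tf.dilution_profile(tc, steady_state_checked=True)
        assert all(v == pytest.approx(0.0) for v in prof.dilution_index.values())

    def test_unlabeled_malate_is_fully_diluted(self):
        tc = self._tc({"citrate": 0.3, "malate": 0.0})
        prof = tf.dilution_profile(tc, steady_state_checked=True,
                                   metabolites=("citrate", "malate"))
        assert prof.dilution_index["malate"] == pytest.approx(1.0)

    def test_dilution_is_antitone_in_downstream_enrichment(self):
        idx = []
        for e_mal in (0.05, 0.15, 0.25):
            tc = self._tc({"citrate": 0.3, "malate": e_mal})
            prof = tf.dilution_profile(tc, steady_state_checked=True,
                                       metabolites=("citrate", "malate"))
            idx.append(prof.dilution_index["malate"])
        assert idx[0] > idx[1] > idx[2]

    def test_glutamine_tracer_references_glutamate(self):
        records = []
        for met, n, e in [("citrate", 6, 0.1), ("glutamate", 5, 0.4)]:
            frac = np.zeros(n + 1)
            frac[0], frac[-1] = 1 - e, e
            records.append(
                (
                    {"condition": "c", "tracer": "glutamine_U13C5",
                     "time_min": 60.0, "replicate": 0},
                    tf.MIDVector(met, frac),
                )
            )
        prof = tf.dilution_profile(
            LabelTimeCourse.from_mids(records), steady_state_checked=True,
            metabolites=("citrate", "glutamate"),
        )
        assert prof.reference_metabolite == "glutamate"

    def test_zero_reference_rejected(self):
        tc = self._tc({"citrate": 0.0, "malate": 0.1})
        with pytest.raises(DomainError):
            tf.dilution_profile(tc, steady_state_checked=True)
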