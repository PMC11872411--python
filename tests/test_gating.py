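"""Gate placement, gated frequency, cGPS scoring and risk classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from cgps.gating import (GateSpec, cgps_score, classify_risk, fit_gates,
                         gated_frequency, score_cohort)
from cgps.simulate import SimConfig, generate_cohort

from conftest import make_cohort, make_sample


def reference_cohort(rng, values_by_marker, n=4000):
    """HD cohort with one sample whose marker columns are given arrays."""
    markers = list(values_by_marker)
    values = np.column_stack([values_by_marker[m] for m in markers])
    return make_cohort([make_sample(values, markers, sid="hd")], ["HD"])


class TestFitGates:
    def test_bimodal_marker_cut_falls_between_the_modes(self, rng):
        n = 4000
        x = np.where(rng.random(n) < 0.9, rng.normal(0.5, 0.45, n),
                     rng.normal(3.0, 0.45, n))
        cohort = reference_cohort(rng, {"CD86": x, "CD19": np.full(n, 3.0)})
        gates = fit_gates(cohort, ["CD86"], seed=0)
        cut, side = gates.cuts["CD86"]
        assert 1.0 < cut < 2.5
        assert gates.fallback["CD86"] is False

    def test_unimodal_marker_falls_back_to_reference_percentile(self, rng):
        n = 4000
        x = rng.normal(2.0, 0.4, n)
        cohort = reference_cohort(rng, {"CD86": x, "CD19": np.full(n, 3.0)})
        gates = fit_gates(cohort, ["CD86"], seed=0)
        assert gates.fallback["CD86"] is True
        assert gates.cuts["CD86"][0] == pytest.approx(
            np.percentile(x, 99.5), abs=1e-9)

    def test_b_cell_marker_fallback_keeps_the_positive_bulk(self, rng):
        n = 4000
        cd19 = rng.normal(3.0, 0.4, n)
        x = np.where(rng.random(n) < 0.9, rng.normal(0.5, 0.45, n),
                     rng.normal(3.0, 0.45, n))
        cohort = reference_cohort(rng, {"CD86": x, "CD19": cd19})
        gates = fit_gates(cohort, ["CD86"], seed=0)
        marker, side, cut = gates.b_cell_gate
        assert marker == "CD19" and side == "+"
        assert (cd19 > cut).mean() > 0.99

    def test_translation_equivariance(self, rng):
        n = 4000
        x = np.where(rng.random(n) < 0.85, rng.normal(0.5, 0.45, n),
                     rng.normal(3.0, 0.45, n))
        base = fit_gates(reference_cohort(
            rng, {"CD86": x, "CD19": np.full(n, 3.0)}), ["CD86"], seed=0)
        shifted = fit_gates(reference_cohort(
            rng, {"CD86": x + 1.7, "CD19": np.full(n, 3.0)}), ["CD86"],
            seed=0)
        assert shifted.cuts["CD86"][0] - base.cuts["CD86"][0] == \
            pytest.approx(1.7, abs=1e-6)

    def test_too_few_reference_cells_is_an_error(self, rng):
        cohort = reference_cohort(
            rng, {"CD86": rng.normal(size=50), "CD19": np.full(50, 3.0)})
        with pytest.raises(ValueError, match="reference cells"):
            fit_gates(cohort, ["CD86"], seed=0)

    def test_no_healthy_donors_is_an_error(self, rng):
        sample = make_sample(rng.normal(size=(200, 1)), ["CD86"], sid="p")
        cohort = make_cohort([sample], ["cGVHD"])
        with pytest.raises(ValueError, match="no 'HD'"):
            fit_gates(cohort, ["CD86"], seed=0)


def manual_gates():
    return GateSpec(cuts={"CD27": (2.0, "+"), "CD86": (2.0, "+"),
                          "CD20": (2.0, "-")},
                    b_cell_gate=("CD19", "+", 1.0))


def gate_sample(rows):
    markers = ["CD19", "CD20", "CD27", "CD86"]
    return make_sample(np.array(rows, dtype=float), markers, sid="s0")


class TestGatedFrequency:
    def test_direct_count(self):
        rows = [[3, 0.5, 3, 3]] * 3 + [[3, 3, 3, 3]] * 7  # 3 of 10 pass
        assert gated_frequency(gate_sample(rows),
                               manual_gates()) == pytest.approx(30.0)

    def test_no_cell_passing_one_marker_gives_zero(self):
        rows = [[3, 0.5, 3, 0.5]] * 10  # CD86 below its cut everywhere
        assert gated_frequency(gate_sample(rows), manual_gates()) == 0.0

    def test_all_cells_passing_gives_hundred(self):
        rows = [[3, 0.5, 3, 3]] * 10
        assert gated_frequency(gate_sample(rows), manual_gates()) == 100.0

    def test_empty_denominator_is_an_error(self):
        rows = [[0.2, 3, 3, 3]] * 5  # everyone below the B-cell gate
        with pytest.raises(ValueError, match="no B cells"):
            gated_frequency(gate_sample(rows), manual_gates())

    def test_untransformed_sample_is_rejected(self):
        s = gate_sample([[3, 0.5, 3, 3]])
        s.transformed = False
        with pytest.raises(ValueError, match="transformed"):
            gated_frequency(s, manual_gates())

    def test_adding_a_passing_cell_never_decreases_frequency(self):
        rows = [[3, 0.5, 3, 3]] * 2 + [[3, 3, 3, 3]] * 8
        before = gated_frequency(gate_sample(rows), manual_gates())
        after = gated_frequency(gate_sample(rows + [[3, 0.5, 3, 3]]),
                                manual_gates())
        assert after >= before


class TestCGPS:
    def test_fixed_points_and_identity_default(self):
        assert cgps_score(0.0) == 0.0
        assert cgps_score(1.5) == 1.5
        assert cgps_score(100.0) == 100.0

    def test_out_of_range_frequency_rejected(self):
        with pytest.raises(ValueError):
            cgps_score(-0.1)
        with pytest.raises(ValueError):
            cgps_score(100.1)

    def test_transform_output_is_clamped_to_0_100(self):
        assert cgps_score(2.0, transform=lambda f: 50 * f + 60) == 100.0
        assert cgps_score(2.0, transform=lambda f: f - 10) == 0.0

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0, 100), st.floats(0, 100))
    def test_any_monotone_transform_preserves_order(self, f1, f2):
        lo, hi = sorted([f1, f2])
        for tf in (None, np.sqrt, lambda f: 10 * np.log1p(f)):
            assert cgps_score(lo, tf) <= cgps_score(hi, tf)


class TestClassifyRisk:
    @pytest.mark.parametrize("score,context,expected", [
        (1.15, "nonGVHD", "low"),
        (1.16, "nonGVHD", "high"),
        (1.1500000001, "nonGVHD", "high"),
        (1.51, "cGVHD", "low"),
        (1.52, "cGVHD", "high"),
        (0.0, "nonGVHD", "low"),
        (100.0, "cGVHD", "high"),
    ])
    def test_boundary_is_low_risk(self, score, context, expected):
        assert classify_risk(score, context) == expected

    def test_unknown_context_is_an_error(self):
        with pytest.raises(ValueError, match="unknown context"):
            classify_risk(1.0, "aGVHD")

    def test_thresholds_are_overridable(self):
        assert classify_risk(1.3, "nonGVHD",
                             thresholds={"nonGVHD": 2.0}) == "low"


class TestEndToEndRecovery:
    def test_gated_frequency_tracks_planted_frequency(self):
        """Spearman rho >= 0.95 between gated and planted frequencies.

        Frequencies span a wide band so that the binomial counting noise of
        500-cell samples (~±1 pp) stays small against the between-subject
        spread; within the narrow clinical band that noise floor, not the
        gating, limits rank agreement.
        """
        from cgps.simulate import DEFAULT_FREQ
        cohort = generate_cohort(SimConfig(
            n_subjects={"HD": 4, "cGVHD_DP": 16},
            cells_per_subject=500,
            disease_freq={**DEFAULT_FREQ, "cGVHD_DP": (10.0, 5.0)},
            seed=17))
        gates = fit_gates(cohort, ["CD20", "CD27", "CD86"], seed=0)
        records = score_cohort(cohort, gates)
        merged = records.merge(cohort.subjects, on="subject_id")
        rho = sps.spearmanr(merged["frequency"], merged["truth"])[0]
        assert rho >= 0.95
        assert ((merged["score"] >= 0) & (merged["score"] <= 100)).all()

    def test_risk_class_matches_threshold_rule(self):
        cohort = generate_cohort(SimConfig(
            n_subjects={"HD": 3, "cGVHD_DP": 3}, cells_per_subject=400,
            seed=23))
        gates = fit_gates(cohort, ["CD20", "CD27", "CD86"], seed=0)
        records = score_cohort(cohort, gates)
        gvhd = records[records["context"] == "cGVHD"]
        assert ((gvhd["risk_class"] == "high")
                == (gvhd["score"] > 1.51)).all()
        hd = records[records["context"].isna()]
        assert hd["risk_class"].isna().all()
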