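"""Viability normalization, dose-response assembly and CV75 estimation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from respsens.errors import DegenerateControlError, DoseRangeError, StructuralError
from respsens.synthetic import CompartmentResponse, ViabilitySimConfig, simulate_viability_plate
from respsens.types import AVERAGE_CURVE, COMPARTMENTS, DoseResponsePoint, WellReading
from respsens.viability import (
    build_dose_response,
    compute_cv75,
    relative_viability,
    select_exposure_doses,
)


def log_linear_crossing_oracle(a, b, c, d):
    """Brute-force root of the 75% crossing, viability linear in log10(dose).

    Independent of the closed-form estimator: interpolates between
    (log10 b, a) and (log10 d, c) and root-finds numerically.
    """
    lo, hi = sorted((math.log10(b), math.log10(d)))

    def f(x):
        t = (x - math.log10(b)) / (math.log10(d) - math.log10(b))
        return a + t * (c - a) - 75.0

    return 10.0 ** brentq(f, lo, hi, xtol=1e-14)


class TestRelativeViability:
    @pytest.mark.parametrize(
        "sample,blank,vehicle,expected",
        [
            (1100.0, 100.0, 1100.0, 100.0),  # sample equals vehicle
            (100.0, 100.0, 1100.0, 0.0),  # sample equals blank
            (800.0, 100.0, 1100.0, 70.0),  # hand-evaluated normalization
        ],
    )
    def test_definition(self, sample, blank, vehicle, expected):
        assert relative_viability(sample, blank, vehicle) == pytest.approx(expected)

    @given(
        offset=st.floats(-1e4, 1e4),
        sample=st.floats(0, 5000),
        blank=st.floats(0, 500),
        span=st.floats(10, 5000),
    )
    @settings(derandomize=True, max_examples=100)
    def test_affine_invariance(self, offset, sample, blank, span):
        base = relative_viability(sample, blank, blank + span)
        shifted = relative_viability(sample + offset, blank + offset, blank + span + offset)
        assert shifted == pytest.approx(base, rel=1e-9, abs=1e-9)

    def test_degenerate_controls_rejected(self):
        with pytest.raises(DegenerateControlError):
            relative_viability(500.0, 1100.0, 1100.0)


class TestBuildDoseResponse:
    def test_average_curve_is_arithmetic_mean(self, make_wells):
        doses = (10.0, 100.0)
        wells = make_wells(doses, {
            "apical": [90.0, 50.0], "endothelial": [80.0, 40.0], "dendritic": [70.0, 30.0],
        })
        curves = build_dose_response(wells)
        assert [p.viability for p in curves[AVERAGE_CURVE]] == pytest.approx([80.0, 40.0])
        assert [p.dose for p in curves[AVERAGE_CURVE]] == list(doses)

    def test_identical_compartments_average_to_themselves(self, make_wells):
        wells = make_wells((5.0, 50.0), {c: [95.0, 60.0] for c in COMPARTMENTS})
        curves = build_dose_response(wells)
        for comp in COMPARTMENTS:
            assert [p.viability for p in curves[comp]] == pytest.approx(
                [p.viability for p in curves[AVERAGE_CURVE]]
            )

    def test_replicates_are_averaged(self, make_wells):
        wells = make_wells((5.0, 50.0), {c: [95.0, 60.0] for c in COMPARTMENTS})
        # perturb one replicate pair by constructing two replicates by hand
        extra = [WellReading(compartment="apical", role="sample",
                             raw_fluorescence=100.0 + 1000.0 * 85.0 / 100.0,
                             dose=5.0, replicate_id="r2")]
        curves = build_dose_response(wells + extra)
        assert curves["apical"][0].viability == pytest.approx((95.0 + 85.0) / 2)

    def test_missing_compartment_rejected(self, make_wells):
        wells = make_wells((5.0, 50.0), {"apical": [95.0, 60.0], "endothelial": [90.0, 55.0]})
        with pytest.raises(StructuralError, match="dendritic"):
            build_dose_response(wells)

    def test_mismatched_dose_grids_rejected(self, make_wells):
        wells = make_wells((5.0, 50.0), {c: [95.0, 60.0] for c in COMPARTMENTS[:2]})
        wells += make_wells((6.0, 60.0), {"dendritic": [90.0, 55.0]})
        with pytest.raises(StructuralError, match="grid"):
            build_dose_response(wells)

    def test_noise_free_generator_round_trip(self):
        config = ViabilitySimConfig(
            doses=(5.0, 10.0, 20.0, 40.0, 80.0, 160.0),
            responses={c: CompartmentResponse(true_cv75=30.0) for c in COMPARTMENTS},
            noise_sd=0.0,
        )
        curves = build_dose_response(simulate_viability_plate(config))
        for comp in COMPARTMENTS:
            expected = [config.responses[comp].viability(d) for d in config.doses]
            assert [p.viability for p in curves[comp]] == pytest.approx(expected, rel=1e-12)


class TestComputeCv75:
    def test_two_point_interpolation(self):
        curve = [DoseResponsePoint(10.0, 90.0, "x"), DoseResponsePoint(100.0, 50.0, "x")]
        result = compute_cv75(curve)
        assert result.cv75 == pytest.approx(10.0 ** 1.375)
        assert result.bracket.a == 90.0 and result.bracket.d == 100.0
        # closed form agrees with the numeric root of the log-linear interpolant
        oracle = log_linear_crossing_oracle(90.0, 10.0, 50.0, 100.0)
        assert result.cv75 == pytest.approx(oracle, rel=1e-12)

    def test_exact_crossing_returns_dose(self):
        curve = [
            DoseResponsePoint(5.0, 90.0, "x"),
            DoseResponsePoint(20.0, 75.0, "x"),
            DoseResponsePoint(80.0, 40.0, "x"),
        ]
        result = compute_cv75(curve)
        assert result.cv75 == 20.0
        assert not result.fallback

    def test_no_crossing_sets_fallback(self):
        curve = [DoseResponsePoint(d, v, "x") for d, v in [(10, 99), (100, 97), (750, 95)]]
        result = compute_cv75(curve)
        assert result.fallback and result.cv75 is None

    def test_all_below_75_is_an_error(self):
        curve = [DoseResponsePoint(10.0, 60.0, "x"), DoseResponsePoint(100.0, 30.0, "x")]
        with pytest.raises(DoseRangeError, match="downward"):
            compute_cv75(curve)

    def test_oracle_agreement_on_random_monotone_curves(self, rng):
        for _ in range(300):
            n = rng.integers(2, 9)
            start = 10.0 ** rng.uniform(-1, 2)
            doses = start * (10.0 ** rng.uniform(0.15, 0.5)) ** np.arange(n)
            # strictly decreasing viabilities straddling 75, never exactly 75
            hi = sorted(rng.uniform(75.5, 120.0, size=int(rng.integers(1, n))), reverse=True)
            lo = sorted(rng.uniform(1.0, 74.5, size=n - len(hi)), reverse=True)
            vs = hi + lo
            if not (hi and lo):
                continue
            curve = [DoseResponsePoint(d, v, "x") for d, v in zip(doses, vs)]
            result = compute_cv75(curve)
            br = result.bracket
            oracle = log_linear_crossing_oracle(br.a, br.b, br.c, br.d)
            assert abs(result.cv75 - oracle) / oracle < 1e-9
            assert br.a > 75.0 > br.c

    @given(k=st.floats(0.01, 100.0))
    @settings(derandomize=True, max_examples=60)
    def test_scale_property(self, k):
        base = [DoseResponsePoint(10.0, 92.0, "x"), DoseResponsePoint(40.0, 80.0, "x"),
                DoseResponsePoint(160.0, 55.0, "x")]
        scaled = [DoseResponsePoint(p.dose * k, p.viability, "x") for p in base]
        assert compute_cv75(scaled).cv75 == pytest.approx(compute_cv75(base).cv75 * k, rel=1e-12)


class TestSelectExposureDoses:
    def test_halving_published_cv75(self):
        from respsens.types import Cv75Result

        result = Cv75Result(cv75=41.4, bracket=None, fallback=False, curve_id="ali_average")
        plan = select_exposure_doses(result, max_tested_dose=250.0)
        assert plan.high_dose == 41.4
        assert plan.low_dose == pytest.approx(20.7)
        assert plan.source == "cv75"

    def test_fallback_uses_max_tested_dose(self):
        from respsens.types import Cv75Result

        result = Cv75Result(cv75=None, bracket=None, fallback=True, curve_id="ali_average")
        plan = select_exposure_doses(result, max_tested_dose=750.0)
        assert (plan.high_dose, plan.low_dose) == (750.0, 375.0)
        assert plan.source == "max_dose_fallback"

    def test_low_dose_is_exact_half(self):
        from respsens.types import Cv75Result

        result = Cv75Result(cv75=1.0, bracket=None, fallback=False, curve_id="x")
        plan = select_exposure_doses(result, max_tested_dose=10.0)
        assert plan.low_dose == plan.high_dose / 2.0 == 0.5

    def test_extrapolated_plan_warns(self):
        from respsens.types import Cv75Result

        result = Cv75Result(cv75=300.0, bracket=None, fallback=False, curve_id="x")
        with pytest.warns(UserWarning, match="extrapolated"):
            plan = select_exposure_doses(result, max_tested_dose=250.0)
        assert plan.high_dose == 300.0
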