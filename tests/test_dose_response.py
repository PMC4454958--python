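"""Worker-adjusted unit risk and reference-concentration derivations."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from workrisk.dose_response import (
    AGENCY_SCHEMAS,
    CorrectionSchema,
    Endpoint,
    PodType,
    PointOfDeparture,
    ReferenceProfile,
    Route,
    RouteConversionError,
    UnsupportedStudyError,
    WorkerProfile,
    derive_unit_risk,
    duration_factor,
    iur_from_slope_factor,
    rfc_work,
    round_half_up,
    round_sig,
    route_to_route,
    severity_factor,
    unit_risk_work,
    worker_correction_factor,
)

REF = ReferenceProfile()
WORKER = WorkerProfile()
KOSHA = AGENCY_SCHEMAS["KOSHA"]


class TestRounding:
    @pytest.mark.parametrize(
        "x, nd, expected",
        [(0.525833, 2, 0.53), (0.308888, 2, 0.31), (0.005, 2, 0.01),
         (2.131333, 2, 2.13), (4.85, 1, 4.9)],
    )
    def test_half_up_decimals(self, x, nd, expected):
        assert round_half_up(x, nd) == expected

    @pytest.mark.parametrize(
        "x, sig, expected",
        [(4.91346, 2, 4.9), (2.342857e-3, 2, 2.3e-3), (4.69388e-4, 2, 4.7e-4),
         (0.0, 2, 0.0), (19.5, 2, 20.0)],
    )
    def test_half_up_significant_figures(self, x, sig, expected):
        assert round_sig(x, sig) == pytest.approx(expected, rel=1e-12)


class TestCorrectionFactor:
    def test_identity_for_identical_profiles(self):
        w = WorkerProfile(20, 365, 70, 70)
        assert worker_correction_factor(REF, w) == pytest.approx(1.0)

    def test_default_profiles_give_4_9(self):
        cf = worker_correction_factor(REF, WORKER)
        assert cf == pytest.approx((20 / 10) * (365 / 260) * (70 / 40))
        assert round_sig(cf, 2) == 4.9

    def test_single_ratio_case(self):
        w = WorkerProfile(10, 365, 70, 70)
        assert worker_correction_factor(REF, w) == pytest.approx(2.0)

    @given(
        iv=st.floats(5, 30), days=st.floats(100, 365),
        years=st.floats(10, 80), bw=st.floats(40, 100),
    )
    @settings(max_examples=60, deadline=None)
    def test_reciprocity(self, iv, days, years, bw):
        # CF(ref, worker) * CF(worker, ref) = 1: swapping the roles of the
        # two profiles inverts every ratio
        a = dataclasses.replace(
            WorkerProfile(), inhalation_volume=iv, exposure_days=days,
            exposure_years=years, body_weight=bw,
        )
        fwd = worker_correction_factor(REF, a)
        rev = (
            (a.inhalation_volume / REF.inhalation_volume)
            * (a.exposure_days / REF.exposure_days)
            * (a.exposure_years / REF.exposure_years)
        )
        assert fwd * rev == pytest.approx(1.0, rel=1e-12)


class TestUnitRiskChain:
    def test_iur_from_published_slope_factor(self):
        iur = iur_from_slope_factor(8.2e-3, REF)
        assert round_sig(iur, 2) == pytest.approx(2.3e-3)

    def test_iur_identity_when_ir_equals_bw(self):
        ref = ReferenceProfile(inhalation_volume=70.0, body_weight=70.0)
        assert iur_from_slope_factor(5e-3, ref) == pytest.approx(5e-3)

    def test_iur_hand_arithmetic(self):
        assert round_sig(iur_from_slope_factor(7e-2, REF), 2) == pytest.approx(2.0e-2)

    @pytest.mark.parametrize(
        "iur, cf, expected",
        [(2.3e-3, 4.9, 4.7e-4), (1e-2, 4.0, 2.5e-3), (3.7e-3, 1.0, 3.7e-3)],
    )
    def test_ur_work_staged_rounding(self, iur, cf, expected):
        assert unit_risk_work(iur, cf).ur_work == pytest.approx(expected, rel=1e-12)

    def test_full_chain_keeps_unrounded_audit_values(self):
        ur = derive_unit_risk(8.2e-3)
        assert (ur.iur, ur.cf, ur.ur_work) == (2.3e-3, 4.9, 4.7e-4)
        assert ur.iur_unrounded == pytest.approx(8.2e-3 * 20 / 70, rel=1e-12)
        assert ur.cf_unrounded == pytest.approx(4.913461538, rel=1e-9)
        assert ur.ur_work_unrounded == pytest.approx(ur.iur_unrounded / ur.cf_unrounded)


class TestFactorRules:
    @pytest.mark.parametrize(
        "weeks, expected", [(104, 1), (26, 1), (13, 2), (12.9, 6), (9, 6), (4, 6)]
    )
    def test_duration_bands_longest_match_wins(self, weeks, expected):
        assert duration_factor(weeks, KOSHA) == expected

    def test_below_shortest_band_unsupported(self):
        with pytest.raises(UnsupportedStudyError):
            duration_factor(2, KOSHA)

    @pytest.mark.parametrize(
        "pod_type, expected",
        [(PodType.BMDL, 1), (PodType.NOAEL, 1), (PodType.LOAEL, 5)],
    )
    def test_severity(self, pod_type, expected):
        assert severity_factor(pod_type) == expected


ORAL_STO = PointOfDeparture(23.0, PodType.BMDL, Route.ORAL,
                            Endpoint.ORAL_STO, "rat", 104)
INHAL_STO = PointOfDeparture(157.75, PodType.LOAEL, Route.INHALATION,
                             Endpoint.INHALATION_STO, "mouse", 13)
REPRO = PointOfDeparture(20.0, PodType.BMDL, Route.ORAL,
                         Endpoint.REPRODUCTIVE, "rat", 9)


class TestRouteToRoute:
    def test_inhalation_pod_passes_through(self):
        assert route_to_route(INHAL_STO) == 157.75

    @pytest.mark.parametrize(
        "pod, expected", [(ORAL_STO, 23 * 2.78), (REPRO, 20 * 2.78)]
    )
    def test_oral_pod_scaled_by_composite_multiplier(self, pod, expected):
        assert route_to_route(pod, conversion=2.78) == pytest.approx(expected)

    def test_oral_pod_without_conversion_is_config_error(self):
        with pytest.raises(RouteConversionError):
            route_to_route(ORAL_STO)


class TestRfCWork:
    @pytest.mark.parametrize(
        "pod, expected",
        [(INHAL_STO, 0.53), (ORAL_STO, 2.13), (REPRO, 0.31)],
        ids=["inhalation", "oral", "reproductive"],
    )
    def test_reference_chains(self, pod, expected, kosha):
        result = rfc_work(pod, kosha, oral_to_air=2.78)
        assert result.rfc_work == expected

    def test_inhalation_chain_unrounded_value(self, kosha):
        result = rfc_work(INHAL_STO, kosha)
        assert result.rfc_work_unrounded == pytest.approx(
            157.75 * 0.5 / (3 * 5 * 2 * 5 * 1), rel=1e-12
        )

    @pytest.mark.parametrize("pod", [INHAL_STO, ORAL_STO, REPRO])
    def test_audit_trail_reconstructs_unrounded_value(self, pod, kosha):
        r = rfc_work(pod, kosha, oral_to_air=2.78)
        assert r.reconstruct() == pytest.approx(r.rfc_work_unrounded, rel=1e-12)

    @pytest.mark.parametrize("pod", [INHAL_STO, ORAL_STO, REPRO])
    def test_monotonicity_under_perturbation(self, pod, kosha):
        base = rfc_work(pod, kosha, oral_to_air=2.78).rfc_work_unrounded
        bigger_pod = dataclasses.replace(pod, value=pod.value * 1.3)
        assert rfc_work(bigger_pod, kosha, oral_to_air=2.78).rfc_work_unrounded > base
        for field in ("uf_interspecies", "uf_intraspecies", "uf_quality"):
            harsher = dataclasses.replace(kosha, **{field: getattr(kosha, field) * 2})
            assert (
                rfc_work(pod, harsher, oral_to_air=2.78).rfc_work_unrounded < base
            )


class TestSchemaTable:
    # (noael_adj, noael_hec, inter, intra, duration, severity, quality)
    EXPECTED = {
        "KOSHA": (0.5, 1, 3, 5, 2, 1, 1),
        "EPA": (0.17, 1, 3, 10, 3, 1, 1),
        "ECHA": (0.5, 1, 2.5, 5, 2, 1, 1),
        "MHLW": (0.5, 1, 10, 1, 1, 1, 1),
    }

    @pytest.mark.parametrize("agency", sorted(EXPECTED))
    def test_builtin_schema_cells(self, agency):
        s = AGENCY_SCHEMAS[agency]
        assert (
            s.noael_adj, s.noael_hec, s.uf_interspecies, s.uf_intraspecies,
            s.uf_duration_default, s.uf_severity_default, s.uf_quality,
        ) == self.EXPECTED[agency]

    def test_schema_validation(self):
        with pytest.raises(ValueError):
            CorrectionSchema("X", 1.5, 1, 3, 5, 2, 1, 1)  # adj > 1
        with pytest.raises(ValueError):
            CorrectionSchema("X", 0.5, 1, 0.5, 5, 2, 1, 1)  # divisor < 1
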