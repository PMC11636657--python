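"""Unit and property tests for the per-session extraction chain, checked
against independent straight-line arithmetic oracles."""

import math

import numpy as np
import pytest

from reox.errors import SessionValidationError
from reox.extraction import (
    compute_session_extraction,
    correct_vessel_saturation,
    cra_saturation,
    crv_saturation,
    oxygen_content,
    oxygen_extraction,
    po2_from_saturation,
    saturation_loss,
    severinghaus_saturation,
)
from reox.model import PhysicalConstants, Po2Source, RunConfig, VesselType

from conftest import make_bundle, make_vessel, random_session


def po2_oracle(sat, tol=1e-13):
    """Independent bisection inverse of the forward dissociation curve."""
    lo, hi = 0.1, 700.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if severinghaus_saturation(mid) < sat:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


class TestSaturationLoss:
    def test_zero_flux_gives_zero_loss(self):
        assert saturation_loss(q=30, hb=15, radius=50, length=1500, jo2=0.0) == 0.0

    def test_unit_case_matches_direct_arithmetic(self):
        # dS = -(2 pi * 1 * 1 * -1) / (1.35 * 1 * 1) = 2 pi / 1.35
        ds = saturation_loss(q=1, hb=1, radius=1, length=1, jo2=-1.0)
        assert ds == pytest.approx(2 * math.pi / 1.35, rel=1e-12)

    def test_linearity_in_length_and_inverse_flow(self):
        base = saturation_loss(q=20, hb=14, radius=40, length=1000, jo2=-1e-5)
        assert saturation_loss(q=20, hb=14, radius=40, length=2000, jo2=-1e-5) == pytest.approx(2 * base, rel=1e-12)
        assert saturation_loss(q=40, hb=14, radius=40, length=1000, jo2=-1e-5) == pytest.approx(base / 2, rel=1e-12)

    def test_outward_flux_gives_nonnegative_loss(self):
        assert saturation_loss(q=30, hb=15, radius=50, length=1500, jo2=-7e-6) > 0

    @pytest.mark.parametrize("q,hb", [(0.0, 15.0), (30.0, 0.0)])
    def test_degenerate_denominator_raises(self, q, hb):
        with pytest.raises(SessionValidationError):
            saturation_loss(q=q, hb=hb, radius=50, length=1500, jo2=-1e-6)


class TestVesselCorrection:
    def test_artery_adds_and_vein_subtracts(self):
        a = make_vessel("A1", VesselType.ARTERY, sat=0.96)
        v = make_vessel("V1", VesselType.VEIN, sat=0.64)
        assert correct_vessel_saturation(a, 0.01) == pytest.approx(0.97)
        assert correct_vessel_saturation(v, 0.01) == pytest.approx(0.63)

    def test_clip_to_zero_with_warning(self, caplog):
        v = make_vessel("V1", VesselType.VEIN, sat=0.005)
        with caplog.at_level("WARNING"):
            out = correct_vessel_saturation(v, 0.01)
        assert out == 0.0
        assert any("clipped" in r.message for r in caplog.records)


class TestMergedSaturations:
    def test_cra_is_unweighted_mean(self):
        assert cra_saturation([0.97]) == pytest.approx(0.97)
        assert cra_saturation([0.95, 0.97, 0.96]) == pytest.approx(0.96, rel=1e-12)

    def test_cra_permutation_invariant(self, rng):
        sats = rng.uniform(0.9, 1.0, size=6)
        assert cra_saturation(sats) == pytest.approx(cra_saturation(sats[::-1]), rel=1e-14)

    def test_crv_flow_weighted_mean(self):
        assert crv_saturation([0.6, 0.7], [1.0, 3.0]) == pytest.approx(0.675, rel=1e-12)

    def test_crv_equal_flows_is_plain_mean(self):
        assert crv_saturation([0.6, 0.7, 0.65], [2, 2, 2]) == pytest.approx(np.mean([0.6, 0.7, 0.65]), rel=1e-12)

    def test_crv_single_flow_dominates(self):
        assert crv_saturation([0.6, 0.7], [5.0, 0.0]) == pytest.approx(0.6, rel=1e-12)

    def test_crv_zero_total_flow_raises(self):
        with pytest.raises(SessionValidationError):
            crv_saturation([0.6, 0.7], [0.0, 0.0])

    def test_crv_within_hull_of_inputs(self, rng):
        for _ in range(50):
            sats = rng.uniform(0.4, 0.8, 5)
            q = rng.uniform(0.1, 10, 5)
            out = crv_saturation(sats, q)
            assert sats.min() - 1e-12 <= out <= sats.max() + 1e-12


class TestDissociationCurve:
    def test_half_saturation_point(self):
        # P50 of the adult curve, from an independent bisection oracle
        assert po2_from_saturation(0.5) == pytest.approx(po2_oracle(0.5), abs=1e-6)
        assert po2_from_saturation(0.5) == pytest.approx(26.86, abs=0.01)

    @pytest.mark.parametrize("s", [0.3, 0.65, 0.97])
    def test_forward_inverse_roundtrip(self, s):
        assert severinghaus_saturation(po2_from_saturation(s)) == pytest.approx(s, abs=1e-6)

    def test_monotone_increasing(self):
        sats = np.linspace(0.05, 0.99, 40)
        po2 = [po2_from_saturation(s) for s in sats]
        assert np.all(np.diff(po2) > 0)

    @pytest.mark.parametrize("s", [0.0, 1.0, -0.1, 1.5])
    def test_out_of_domain_raises(self, s):
        with pytest.raises(SessionValidationError):
            po2_from_saturation(s)


class TestContentAndExtraction:
    def test_content_direct_arithmetic(self):
        assert oxygen_content(hb=15, sat=0.97, po2=95) == pytest.approx(
            1.35 * 15 * 0.97 + 0.003 * 95, rel=1e-14
        )
        assert oxygen_content(hb=15, sat=0.97, po2=95) == pytest.approx(19.9275, rel=1e-12)

    def test_content_zero_case(self):
        assert oxygen_content(hb=15, sat=0.0, po2=0.0) == 0.0

    def test_content_linear_in_hb(self):
        c1 = oxygen_content(hb=10, sat=0.9, po2=80)
        c2 = oxygen_content(hb=20, sat=0.9, po2=80)
        bound1, dissolved = 1.35 * 10 * 0.9, 0.003 * 80
        assert c2 - c1 == pytest.approx(bound1, rel=1e-12)
        assert c1 == pytest.approx(bound1 + dissolved, rel=1e-12)

    def test_extraction_zero_av_difference(self):
        assert oxygen_extraction(13.3, 13.3, 71.0) == 0.0

    def test_extraction_direct_arithmetic(self):
        assert oxygen_extraction(19.9, 13.3, 71.0) == pytest.approx(468.6, rel=1e-12)

    def test_extraction_scales_with_mv(self):
        assert oxygen_extraction(19.9, 13.3, 142.0) == pytest.approx(2 * 468.6, rel=1e-12)


def straight_line_chain(bundle, config):
    """Independent re-implementation of the whole chain, no shared code
    path with compute_session_extraction beyond the leaf formulas."""
    consts = config.constants
    hb = bundle.physiology.hb
    a_sats, v_sats, v_q = [], [], []
    for v in bundle.vessels:
        ds = -(2 * math.pi * (v.diameter / 2) * v.distance_L * consts.jo2_wall) / (
            consts.huefner * v.mbr_Q * hb
        ) if consts.jo2_wall != 0 else 0.0
        if v.vessel_type is VesselType.ARTERY:
            a_sats.append(min(1.0, max(0.0, v.sat_measured + ds)))
        else:
            v_sats.append(min(1.0, max(0.0, v.sat_measured - ds)))
            v_q.append(v.mbr_Q)
    s_cra = sum(a_sats) / len(a_sats)
    s_crv = sum(s * q for s, q in zip(v_sats, v_q)) / sum(v_q)
    if config.po2_cra_source is Po2Source.FROM_SYSTEMIC:
        p_cra = bundle.physiology.po2_systemic
    else:
        p_cra = po2_oracle(s_cra)
    p_crv = po2_oracle(s_crv)
    c_cra = consts.huefner * hb * s_cra + consts.o2_solubility * p_cra
    c_crv = consts.huefner * hb * s_crv + consts.o2_solubility * p_crv
    return (c_cra - c_crv) * bundle.flow.mv


class TestSessionChain:
    def test_hand_computed_minimal_session(self, one_artery_one_vein_bundle):
        """Every intermediate of the 1-artery/1-vein session checked by
        hand (systemic arterial pO2 so the arterial side is closed-form)."""
        cfg = RunConfig(po2_cra_source=Po2Source.FROM_SYSTEMIC)
        res = compute_session_extraction(one_artery_one_vein_bundle, cfg)
        assert res.corrected.sat_cra == pytest.approx(0.96, rel=1e-14)
        assert res.corrected.sat_crv == pytest.approx(0.64, rel=1e-14)
        assert res.contents.po2_cra == pytest.approx(95.0, rel=1e-14)
        c_cra = 1.35 * 15 * 0.96 + 0.003 * 95  # = 19.725
        assert res.contents.c_cra == pytest.approx(c_cra, rel=1e-12)
        p_crv = po2_oracle(0.64)
        c_crv = 1.35 * 15 * 0.64 + 0.003 * p_crv
        assert res.contents.c_crv == pytest.approx(c_crv, rel=1e-10)
        assert res.ext_o2 == pytest.approx((c_cra - c_crv) * 71.0, rel=1e-10)
        # pure-arithmetic stages are exact to 1e-12
        assert res.ext_o2 == pytest.approx(
            (res.contents.c_cra - res.contents.c_crv) * res.mv, rel=1e-12
        )

    def test_wall_correction_changes_only_through_delta_s(self, one_artery_one_vein_bundle):
        cfg0 = RunConfig(po2_cra_source=Po2Source.FROM_SYSTEMIC)
        cfg1 = RunConfig(
            constants=PhysicalConstants(jo2_wall=-7e-6),
            po2_cra_source=Po2Source.FROM_SYSTEMIC,
        )
        r0 = compute_session_extraction(one_artery_one_vein_bundle, cfg0)
        r1 = compute_session_extraction(one_artery_one_vein_bundle, cfg1)
        ds = saturation_loss(q=30, hb=15, radius=50, length=1500, jo2=-7e-6)
        assert r1.corrected.sat_cra == pytest.approx(r0.corrected.sat_cra + ds, rel=1e-12)
        assert r1.corrected.sat_crv == pytest.approx(r0.corrected.sat_crv - ds, rel=1e-12)

    def test_equals_straight_line_reimplementation(self, rng):
        """Composition property: the session function equals the
        independent straight-line chain on randomized sessions, with and
        without the wall correction."""
        for k in range(25):
            bundle = random_session(rng)
            jo2 = 0.0 if k % 2 == 0 else -7e-6
            src = Po2Source.FROM_SYSTEMIC if k % 3 == 0 else Po2Source.FROM_SATURATION
            cfg = RunConfig(constants=PhysicalConstants(jo2_wall=jo2), po2_cra_source=src)
            res = compute_session_extraction(bundle, cfg)
            assert res.ext_o2 == pytest.approx(straight_line_chain(bundle, cfg), rel=1e-9)

    def test_uniform_saturation_leaves_only_dissolved_difference(self):
        """If every vessel has the same saturation, extraction reduces to
        the dissolved-gas difference times MV."""
        vessels = [
            make_vessel("A1", VesselType.ARTERY, sat=0.80, q=20.0),
            make_vessel("V1", VesselType.VEIN, sat=0.80, q=25.0),
        ]
        bundle = make_bundle(vessels, hb=14.0, po2=95.0, mv=70.0)
        cfg = RunConfig(po2_cra_source=Po2Source.FROM_SYSTEMIC)
        res = compute_session_extraction(bundle, cfg)
        expected = 70.0 * 0.003 * (95.0 - po2_oracle(0.80))
        assert res.ext_o2 == pytest.approx(expected, rel=1e-9)

    def test_invariant_under_vessel_relabeling(self, rng):
        bundle = random_session(rng, n_art=4, n_vein=4)
        relabeled = make_bundle(
            [
                make_vessel(
                    f"X{j}", v.vessel_type, sat=v.sat_measured, diameter=v.diameter,
                    distance=v.distance_L, q=v.mbr_Q,
                )
                for j, v in enumerate(reversed(bundle.vessels))
            ],
            hb=bundle.physiology.hb, po2=bundle.physiology.po2_systemic, mv=bundle.flow.mv,
        )
        r1 = compute_session_extraction(bundle)
        r2 = compute_session_extraction(relabeled)
        assert r1.ext_o2 == pytest.approx(r2.ext_o2, rel=1e-12)

    def test_percent_change_invariant_under_flow_rescaling(self, rng):
        """Arbitrary-unit scale freedom: rescaling every flow index by a
        common factor rescales extraction but leaves percent changes
        between sessions untouched."""
        b1 = random_session(rng, session_id="d1b1")
        b2 = random_session(rng, session_id="d1g")
        k = 3.7
        def rescaled(b, sess):
            return make_bundle(
                [
                    make_vessel(v.vessel_id, v.vessel_type, sat=v.sat_measured,
                                diameter=v.diameter, distance=v.distance_L, q=v.mbr_Q * k,
                                session_id=sess)
                    for v in b.vessels
                ],
                hb=b.physiology.hb, po2=b.physiology.po2_systemic, mv=b.flow.mv * k,
                session_id=sess,
            )
        e1, e2 = (compute_session_extraction(x).ext_o2 for x in (b1, b2))
        s1, s2 = (compute_session_extraction(rescaled(x, s)).ext_o2 for x, s in ((b1, "d1b1"), (b2, "d1g")))
        assert s1 == pytest.approx(k * e1, rel=1e-9)
        assert 100 * (s2 - s1) / s1 == pytest.approx(100 * (e2 - e1) / e1, rel=1e-7)
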