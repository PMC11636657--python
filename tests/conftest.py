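import numpy as np
import pytest

from reox.model import (
    OnhFlowMetrics,
    SubjectPhysiology,
    VesselMeasurement,
    VesselType,
    validate_session,
)


def make_vessel(
    vessel_id="A1",
    vessel_type=VesselType.ARTERY,
    sat=0.96,
    diameter=100.0,
    distance=1500.0,
    q=35.0,
    subject_id="S001",
    session_id="d1b1",
):
    return VesselMeasurement(
        subject_id=subject_id,
        session_id=session_id,
        vessel_id=vessel_id,
        vessel_type=vessel_type,
        sat_measured=sat,
        diameter=diameter,
        distance_L=distance,
        mbr_Q=q,
    )


def make_bundle(vessels, hb=15.0, po2=95.0, mv=71.0, subject_id="S001", session_id="d1b1"):
    phys = SubjectPhysiology(subject_id=subject_id, hb=hb, po2_systemic=po2, so2_systemic=0.97)
    flow = OnhFlowMetrics(subject_id=subject_id, session_id=session_id, mv=mv, mt=25.0, ma=38.0)
    return validate_session(vessels, phys, flow)


@pytest.fixture
def one_artery_one_vein_bundle():
    """The minimal hand-checkable session: one artery at 96%, one vein at
    64%, equal flows, Hb 15 g/dL, capillary pO2 95 mmHg, MV 71 a.u."""
    vessels = [
        make_vessel("A1", VesselType.ARTERY, sat=0.96, q=30.0),
        make_vessel("V1", VesselType.VEIN, sat=0.64, q=30.0),
    ]
    return make_bundle(vessels)


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


def random_session(rng, subject_id="S001", session_id="d1b1", n_art=None, n_vein=None):
    """A random but always-valid session for property tests."""
    n_art = n_art or int(rng.integers(1, 6))
    n_vein = n_vein or int(rng.integers(1, 6))
    vessels = []
    for j in range(n_art):
        vessels.append(
            make_vessel(
                f"A{j}", VesselType.ARTERY,
                sat=float(rng.uniform(0.85, 0.99)),
                diameter=float(rng.uniform(60, 140)),
                distance=float(rng.uniform(500, 3000)),
                q=float(rng.uniform(10, 60)),
                subject_id=subject_id, session_id=session_id,
            )
        )
    for j in range(n_vein):
        vessels.append(
            make_vessel(
                f"V{j}", VesselType.VEIN,
                sat=float(rng.uniform(0.45, 0.80)),
                diameter=float(rng.uniform(80, 180)),
                distance=float(rng.uniform(500, 3000)),
                q=float(rng.uniform(10, 60)),
                subject_id=subject_id, session_id=session_id,
            )
        )
    return make_bundle(
        vessels,
        hb=float(rng.uniform(11, 17)),
        po2=float(rng.uniform(70, 110)),
        mv=float(rng.uniform(50, 95)),
        subject_id=subject_id,
        session_id=session_id,
    )
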