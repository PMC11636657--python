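"""Oxygen extraction for one hand-built measurement session.

Builds the smallest meaningful session — two arteries and two veins with
paired oximetry (saturation, diameter, distance to the optic nerve head)
and speckle-flow (mean blur rate) readings — and walks through the
computed intermediates: merged central-artery/vein saturations, oxygen
contents and the extraction value.
"""

from reox import (
    OnhFlowMetrics,
    RunConfig,
    SubjectPhysiology,
    VesselMeasurement,
    VesselType,
    compute_session_extraction,
    validate_session,
)

vessels = [
    VesselMeasurement("S1", "visit1", "A1", VesselType.ARTERY, 0.97, 98.0, 1450.0, 34.0),
    VesselMeasurement("S1", "visit1", "A2", VesselType.ARTERY, 0.95, 104.0, 1600.0, 38.0),
    VesselMeasurement("S1", "visit1", "V1", VesselType.VEIN, 0.61, 128.0, 1380.0, 44.0),
    VesselMeasurement("S1", "visit1", "V2", VesselType.VEIN, 0.66, 141.0, 1520.0, 36.0),
]
physiology = SubjectPhysiology("S1", hb=14.3, po2_systemic=96.0, so2_systemic=0.975)
flow = OnhFlowMetrics("S1", "visit1", mv=72.5, mt=24.8, ma=37.9)

bundle = validate_session(vessels, physiology, flow)
result = compute_session_extraction(bundle, RunConfig())

print(f"CRA saturation : {result.corrected.sat_cra * 100:.1f} %  (mean over arteries)")
print(f"CRV saturation : {result.corrected.sat_crv * 100:.1f} %  (flow-weighted over veins)")
print(f"pO2 CRA / CRV  : {result.contents.po2_cra:.1f} / {result.contents.po2_crv:.1f} mmHg")
print(f"content CRA    : {result.contents.c_cra:.2f} mL O2/dL")
print(f"content CRV    : {result.contents.c_crv:.2f} mL O2/dL")
print(f"AV difference  : {result.av_content_difference:.2f} mL O2/dL")
print(f"extraction     : {result.ext_o2:.1f} a.u.  (AV difference x MV {result.mv:.1f})")
print()
print("The extraction value is in arbitrary units because the speckle flow")
print("index is; only percent changes and ratios of it are interpretable.")
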