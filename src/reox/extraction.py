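"""Retinal oxygen extraction from paired oximetry and speckle-flow data.

The computation for one session proceeds in a fixed order:

1. For each vessel, the saturation loss across the vascular wall between
   the measurement point and the vessel origin at the optic nerve head,

       dS = -(2 pi R L J) / (1.35 Hb Q),

   with R the vessel radius, L the distance to the ONH, J the (signed)
   trans-wall oxygen flux and Q the per-vessel mean blur rate. With the
   default flux 0 the correction vanishes and measured saturations are
   used as-is.
2. dS is added to measured arterial saturations and subtracted from
   venous ones (oxygen has been lost on the way out, gained back-tracking
   toward the vein's merge point).
3. The central-retinal-artery saturation is the unweighted mean over
   arteries; the central-retinal-vein saturation is the flow-weighted
   mean over veins (each vein contributes in proportion to its flow Q).
4. Oxygen contents at the CRA/CRV level combine bound and dissolved
   oxygen, c = 1.35 Hb S + 0.003 pO2; venous pO2 is recovered from the
   venous saturation by inverting the Severinghaus dissociation curve.
5. Extraction is the arteriovenous content difference times the
   optic-nerve-head large-vessel flow index MV:  extO2 = (cA - cV) MV.

Because MV is in arbitrary speckle units extO2 is too; downstream
analyses use only percent changes and ratios of it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import SessionValidationError
from .model import (
    PhysicalConstants,
    Po2Source,
    RunConfig,
    SessionBundle,
    SessionLabel,
    VesselMeasurement,
    VesselType,
)

logger = logging.getLogger(__name__)

__all__ = [
    "saturation_loss",
    "correct_vessel_saturation",
    "cra_saturation",
    "crv_saturation",
    "severinghaus_saturation",
    "po2_from_saturation",
    "oxygen_content",
    "oxygen_extraction",
    "compute_session_extraction",
    "CorrectedSaturations",
    "OxygenContents",
    "ExtractionResult",
]


def saturation_loss(
    q: float,
    hb: float,
    radius: float,
    length: float,
    jo2: float,
    constants: PhysicalConstants | None = None,
) -> float:
    """Saturation drop dS across the wall of one vessel segment.

    dS = -(2 pi * radius * length * jo2) / (huefner * q * hb).
    A negative (outward) flux gives dS >= 0.
    """
    constants = constants or PhysicalConstants()
    if q <= 0 or hb <= 0:
        raise SessionValidationError(
            f"saturation_loss needs q > 0 and hb > 0 (got q={q}, hb={hb})"
        )
    return -(2.0 * math.pi * radius * length * jo2) / (constants.huefner * q * hb)


def correct_vessel_saturation(v: VesselMeasurement, delta_s: float) -> float:
    """Back-project a measured saturation to the vessel origin.

    Arteries have lost dS on the way out, so it is added back; venous
    blood gains dS tracking back toward the merge point, so it is
    subtracted. Results are clipped to [0, 1] with a warning."""
    if v.vessel_type is VesselType.ARTERY:
        corrected = v.sat_measured + delta_s
    else:
        corrected = v.sat_measured - delta_s
    if corrected < 0.0 or corrected > 1.0:
        logger.warning(
            "corrected saturation %.4f for vessel %s clipped to [0, 1]",
            corrected,
            v.vessel_id,
        )
        corrected = min(1.0, max(0.0, corrected))
    return corrected


def cra_saturation(c_sat_arteries: Sequence[float]) -> float:
    """Central-retinal-artery saturation: unweighted mean over all
    corrected arterial saturations."""
    if len(c_sat_arteries) == 0:
        raise SessionValidationError("no arterial saturations to average")
    return float(np.mean(c_sat_arteries))


def crv_saturation(c_sat_veins: Sequence[float], q_veins: Sequence[float]) -> float:
    """Central-retinal-vein saturation: flow-weighted mean of corrected
    venous saturations, weights q_j / sum(q)."""
    sats = np.asarray(c_sat_veins, dtype=float)
    q = np.asarray(q_veins, dtype=float)
    if sats.shape != q.shape or sats.size == 0:
        raise SessionValidationError(
            "venous saturations and flows must be non-empty and aligned"
        )
    q_total = float(q.sum())
    if q_total <= 0:
        raise SessionValidationError("total venous flow must be > 0")
    return float(np.dot(sats, q) / q_total)


def severinghaus_saturation(po2: float) -> float:
    """Forward adult oxygen-hemoglobin dissociation curve
    S(P) = (23400 (P^3 + 150 P)^-1 + 1)^-1."""
    return 1.0 / (23400.0 / (po2**3 + 150.0 * po2) + 1.0)


_PO2_BRACKET = (0.1, 700.0)
_PO2_XTOL = 1e-10


def po2_from_saturation(sat: float) -> float:
    """Invert the Severinghaus curve: the pO2 (mmHg) at which hemoglobin
    is ``sat`` saturated. Bracketed root finding on [0.1, 700] mmHg to
    1e-10 mmHg, so the dissolved-oxygen term it feeds is exact to well
    below every downstream tolerance."""
    if not 0.0 < sat < 1.0:
        raise SessionValidationError(
            f"saturation must lie strictly in (0, 1) to invert the "
            f"dissociation curve, got {sat}"
        )
    lo, hi = _PO2_BRACKET
    if sat <= severinghaus_saturation(lo):
        return lo
    if sat >= severinghaus_saturation(hi):
        return hi
    return float(brentq(lambda p: severinghaus_saturation(p) - sat, lo, hi, xtol=_PO2_XTOL))


def oxygen_content(
    hb: float,
    sat: float,
    po2: float,
    constants: PhysicalConstants | None = None,
) -> float:
    """Blood oxygen content in mL O2/dL: bound (huefner * Hb * S) plus
    dissolved (solubility * pO2)."""
    constants = constants or PhysicalConstants()
    return constants.huefner * hb * sat + constants.o2_solubility * po2


def oxygen_extraction(c_cra: float, c_crv: float, mv: float) -> float:
    """Retinal oxygen extraction: arteriovenous content difference times
    the large-vessel flow index MV (a.u.)."""
    if mv < 0:
        raise SessionValidationError(f"mv must be >= 0, got {mv}")
    return (c_cra - c_crv) * mv


@dataclass(frozen=True)
class CorrectedSaturations:
    """Per-vessel and merged saturations after the wall-loss correction."""

    delta_s_per_vessel: dict[str, float]
    c_sat_arteries: tuple[float, ...]
    c_sat_veins: tuple[float, ...]
    sat_cra: float
    sat_crv: float
    q_v_total: float


@dataclass(frozen=True)
class OxygenContents:
    c_cra: float  # mL O2/dL
    c_crv: float
    po2_cra: float  # mmHg
    po2_crv: float


@dataclass(frozen=True)
class ExtractionResult:
    """All intermediates and the final extraction value for one session."""

    subject_id: str
    session_id: str
    corrected: CorrectedSaturations
    contents: OxygenContents
    mv: float
    ext_o2: float
    label: SessionLabel | None = None

    @property
    def av_content_difference(self) -> float:
        return self.contents.c_cra - self.contents.c_crv


def compute_session_extraction(
    bundle: SessionBundle,
    config: RunConfig | None = None,
) -> ExtractionResult:
    """Run the full per-session chain on a validated bundle.

    All intermediates (per-vessel corrections, merged saturations,
    contents, pO2 values) are retained in the result. Vessel iteration
    order never affects the outcome: both merges are symmetric
    aggregations.
    """
    config = config or RunConfig()
    constants = config.constants
    phys = bundle.physiology

    delta_s: dict[str, float] = {}
    c_sat_a: list[float] = []
    c_sat_v: list[float] = []
    q_v: list[float] = []
    for v in bundle.vessels:
        if constants.jo2_wall == 0.0:
            ds = 0.0
        else:
            ds = saturation_loss(
                v.mbr_Q, phys.hb, v.radius, v.distance_L, constants.jo2_wall, constants
            )
        delta_s[v.vessel_id] = ds
        corrected = correct_vessel_saturation(v, ds)
        if v.vessel_type is VesselType.ARTERY:
            c_sat_a.append(corrected)
        else:
            c_sat_v.append(corrected)
            q_v.append(v.mbr_Q)

    sat_cra = cra_saturation(c_sat_a)
    sat_crv = crv_saturation(c_sat_v, q_v)
    corrected_block = CorrectedSaturations(
        delta_s_per_vessel=delta_s,
        c_sat_arteries=tuple(c_sat_a),
        c_sat_veins=tuple(c_sat_v),
        sat_cra=sat_cra,
        sat_crv=sat_crv,
        q_v_total=float(sum(q_v)),
    )

    if config.po2_cra_source is Po2Source.FROM_SYSTEMIC:
        po2_cra = phys.po2_systemic
    elif config.po2_cra_source is Po2Source.CONSTANT:
        po2_cra = config.po2_cra_constant
    else:
        po2_cra = po2_from_saturation(sat_cra)
    po2_crv = po2_from_saturation(sat_crv)

    contents = OxygenContents(
        c_cra=oxygen_content(phys.hb, sat_cra, po2_cra, constants),
        c_crv=oxygen_content(phys.hb, sat_crv, po2_crv, constants),
        po2_cra=po2_cra,
        po2_crv=po2_crv,
    )
    ext = oxygen_extraction(contents.c_cra, contents.c_crv, bundle.flow.mv)

    first = bundle.vessels[0]
    return ExtractionResult(
        subject_id=first.subject_id,
        session_id=first.session_id,
        corrected=corrected_block,
        contents=contents,
        mv=bundle.flow.mv,
        ext_o2=ext,
        label=bundle.label,
    )
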