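"""Domain types and physical constants.

Unit conventions, used consistently everywhere:

* oxygen saturation — fraction in [0, 1] in memory, percent at every file
  boundary;
* vessel geometry (radius, distance to the optic nerve head) — µm;
* hemoglobin — g/dL; oxygen content — mL O2/dL; partial pressures — mmHg;
* all laser-speckle flow indices (per-vessel mean blur rate Q, and the
  optic-nerve-head summaries MV/MT/MA) — dimensionless arbitrary units.

Because flow is in arbitrary units, the oxygen-extraction value
(content difference x MV) is itself in arbitrary units; only ratios and
percent changes of it are meaningful.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .errors import SessionValidationError

__all__ = [
    "VesselType",
    "StudyDay",
    "Timepoint",
    "Gas",
    "PhysicalConstants",
    "EXAMPLE_WALL_FLUX",
    "VesselMeasurement",
    "SubjectPhysiology",
    "OnhFlowMetrics",
    "SessionLabel",
    "SessionBundle",
    "Po2Source",
    "BaselinePolicy",
    "RunConfig",
    "validate_session",
]


class VesselType(str, enum.Enum):
    ARTERY = "A"
    VEIN = "V"


class StudyDay(str, enum.Enum):
    HYPEROXIA_DAY = "hyperoxia_day"
    HYPOXIA_DAY = "hypoxia_day"


class Timepoint(str, enum.Enum):
    BASELINE1 = "baseline1"
    BASELINE2 = "baseline2"
    GAS = "gas"


class Gas(str, enum.Enum):
    ROOM_AIR = "room_air"
    OXYGEN_100 = "oxygen_100"
    NITROGEN_88 = "nitrogen_88"


#: Illustrative non-zero trans-wall oxygen flux. Because per-vessel flow Q is
#: in arbitrary speckle units, the absolute scale of the flux is a unit
#: convention, not a physical constant; this value yields a saturation loss
#: of roughly half a percentage point for a typical artery (radius 50 µm,
#: distance 1500 µm, Q 35 a.u., Hb 14 g/dL). The wall correction is off
#: (flux 0) unless explicitly configured.
EXAMPLE_WALL_FLUX = -7.0e-6


@dataclass(frozen=True)
class PhysicalConstants:
    """Constants of the oxygen-content model.

    huefner
        mL O2 bound per gram of fully saturated hemoglobin.
    o2_solubility
        mL O2 physically dissolved per dL blood per mmHg.
    jo2_wall
        Trans-wall oxygen flux (signed; negative means oxygen leaves the
        vessel). Default 0 disables the wall-loss saturation correction.
    """

    huefner: float = 1.35
    o2_solubility: float = 0.003
    jo2_wall: float = 0.0

    def __post_init__(self) -> None:
        if self.huefner <= 0:
            raise ValueError("huefner must be > 0")
        if self.o2_solubility < 0:
            raise ValueError("o2_solubility must be >= 0")


@dataclass(frozen=True)
class VesselMeasurement:
    """One paired oximetry + speckle-flow reading of one vessel segment."""

    subject_id: str
    session_id: str
    vessel_id: str
    vessel_type: VesselType
    sat_measured: float  # fraction in [0, 1]
    diameter: float  # µm
    distance_L: float  # µm, vessel origin at ONH to nearest measurement point
    mbr_Q: float  # a.u., per-vessel mean blur rate

    def __post_init__(self) -> None:
        if not 0.0 <= self.sat_measured <= 1.0:
            raise ValueError(
                f"sat_measured must be in [0, 1], got {self.sat_measured}"
            )
        if self.diameter <= 0:
            raise ValueError(f"diameter must be > 0, got {self.diameter}")
        if self.distance_L < 0:
            raise ValueError(f"distance_L must be >= 0, got {self.distance_L}")
        if self.mbr_Q < 0:
            raise ValueError(f"mbr_Q must be >= 0, got {self.mbr_Q}")

    @property
    def radius(self) -> float:
        """Vessel radius in µm (half the measured diameter)."""
        return self.diameter / 2.0


@dataclass(frozen=True)
class SubjectPhysiology:
    """Systemic blood values of one subject at one measurement state."""

    subject_id: str
    hb: float  # g/dL
    po2_systemic: float  # mmHg, arterialized capillary pO2
    so2_systemic: float = float("nan")  # fraction, finger pulse oximetry

    def __post_init__(self) -> None:
        if not 5.0 < self.hb < 25.0:
            raise ValueError(f"hb out of plausible range (5, 25): {self.hb}")
        if self.po2_systemic <= 0:
            raise ValueError(f"po2_systemic must be > 0: {self.po2_systemic}")


@dataclass(frozen=True)
class OnhFlowMetrics:
    """Optic-nerve-head speckle-flow summaries: MV (large vessels),
    MT (microvascular tissue), MA (entire ONH area), all in a.u."""

    subject_id: str
    session_id: str
    mv: float
    mt: float
    ma: float

    def __post_init__(self) -> None:
        for name in ("mv", "mt", "ma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SessionLabel:
    """Where a session sits in the two-day, two-gas, repeated-baseline
    design. Gas breathing only happens at the 'gas' timepoint."""

    subject_id: str
    session_id: str
    study_day: StudyDay
    timepoint: Timepoint
    gas: Gas

    def __post_init__(self) -> None:
        is_baseline = self.timepoint in (Timepoint.BASELINE1, Timepoint.BASELINE2)
        if is_baseline != (self.gas == Gas.ROOM_AIR):
            raise ValueError(
                "gas must be room_air at baseline timepoints and a challenge "
                f"gas at the gas timepoint (got {self.timepoint.value}, "
                f"{self.gas.value})"
            )


@dataclass(frozen=True)
class SessionBundle:
    """All inputs needed to compute oxygen extraction for one session.
    Construct through :func:`validate_session`."""

    vessels: tuple[VesselMeasurement, ...]
    physiology: SubjectPhysiology
    flow: OnhFlowMetrics
    label: SessionLabel | None = None

    @property
    def arteries(self) -> tuple[VesselMeasurement, ...]:
        return tuple(v for v in self.vessels if v.vessel_type is VesselType.ARTERY)

    @property
    def veins(self) -> tuple[VesselMeasurement, ...]:
        return tuple(v for v in self.vessels if v.vessel_type is VesselType.VEIN)


def validate_session(
    vessels,
    physiology: SubjectPhysiology,
    flow: OnhFlowMetrics,
    label: SessionLabel | None = None,
) -> SessionBundle:
    """Check a session's structural preconditions and return an immutable
    bundle. Never mutates its inputs: it either passes them through or
    raises :class:`SessionValidationError`.

    Requires at least one artery and one vein, a strictly positive total
    venous flow (the venous merge is a flow-weighted mean), and physiology
    for the right subject.
    """
    vessels = tuple(vessels)
    if not vessels:
        raise SessionValidationError("session has no vessel measurements")
    subject_ids = {v.subject_id for v in vessels}
    session_ids = {v.session_id for v in vessels}
    if len(subject_ids) != 1 or len(session_ids) != 1:
        raise SessionValidationError(
            f"vessels span multiple subjects/sessions: {subject_ids}, {session_ids}"
        )
    keys = [(v.subject_id, v.session_id, v.vessel_id) for v in vessels]
    if len(set(keys)) != len(keys):
        raise SessionValidationError("duplicate vessel_id within session")
    arteries = [v for v in vessels if v.vessel_type is VesselType.ARTERY]
    veins = [v for v in vessels if v.vessel_type is VesselType.VEIN]
    if not arteries:
        raise SessionValidationError("no arterial segments in session")
    if not veins:
        raise SessionValidationError(
            "no venous segments: venous merge saturation is undefined"
        )
    if sum(v.mbr_Q for v in veins) <= 0:
        raise SessionValidationError(
            "total venous flow is zero: flow weights of the venous merge "
            "are degenerate"
        )
    if physiology.subject_id not in subject_ids:
        raise SessionValidationError(
            f"physiology subject {physiology.subject_id!r} does not match "
            f"vessel subject {next(iter(subject_ids))!r}"
        )
    if flow.subject_id not in subject_ids or flow.session_id not in session_ids:
        raise SessionValidationError("ONH flow metrics do not match session")
    return SessionBundle(vessels=vessels, physiology=physiology, flow=flow, label=label)


class Po2Source(str, enum.Enum):
    """Where the central-retinal-artery pO2 of the content formula comes
    from. ``from_saturation`` inverts the dissociation curve at the
    corrected arterial saturation (default; keeps the dissolved term on the
    same physiological scale as the bound term). ``from_systemic`` uses the
    subject's measured capillary pO2. ``constant`` uses a user value."""

    FROM_SATURATION = "from_saturation"
    FROM_SYSTEMIC = "from_systemic"
    CONSTANT = "constant"


class BaselinePolicy(str, enum.Enum):
    """Which same-day baseline value anchors contrasts and the long-term
    reproducibility comparison."""

    MEAN_OF_TWO = "mean_of_two"
    FIRST = "first"
    SECOND = "second"


class IccModel(str, enum.Enum):
    TWO_WAY_MIXED_ABSOLUTE = "two_way_mixed_absolute"
    ONE_WAY_RANDOM = "one_way_random"


@dataclass(frozen=True)
class RunConfig:
    """End-to-end run configuration (constants, estimator choices, seed)."""

    constants: PhysicalConstants = field(default_factory=PhysicalConstants)
    po2_cra_source: Po2Source = Po2Source.FROM_SATURATION
    po2_cra_constant: float = 95.0  # mmHg, used only with Po2Source.CONSTANT
    icc_model: IccModel = IccModel.TWO_WAY_MIXED_ABSOLUTE
    baseline_policy: BaselinePolicy = BaselinePolicy.MEAN_OF_TWO
    seed: int = 0
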