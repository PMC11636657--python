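"""Seeded synthetic study-cohort generator.

Emulates the tabular measurement layer of a two-day, two-gas,
repeated-baseline crossover in healthy adults: each subject is measured
at two room-air baselines and once during gas breathing on both study
days (100% oxygen on one day, 12% oxygen in 88% nitrogen on the other).

What is modelled
----------------
* Per subject: hemoglobin, capillary blood gases, true arterial and
  venous retinal saturations (venous always below arterial), vessel
  counts (4-7 arteries and veins), per-vessel geometry and flow.
* Gas response: one multiplicative flow factor per subject (drawn from
  the preset's percent-change distribution) applied coherently to MV,
  MT, MA and every per-vessel mean blur rate, plus additive
  percentage-point shifts to arterial and venous saturations. All
  challenge parameters are the group mean +/- SD values of the study
  the presets encode.
* Measurement noise: a shared per-session flow factor, per-vessel flow
  scatter, session-level and per-vessel saturation scatter, and a
  smaller per-day component that makes across-day baselines noisier
  than same-day ones.

Distributions are normal for saturations, hemoglobin and blood gases
(truncated to physiologic ranges) and moment-matched log-normal for
flows and diameters (positivity). All randomness flows from one master
seed through a counter-based Philox stream, so generated tables are
byte-identical across platforms for a given seed.

The repeatability-pair generator is separate and direct: it draws a
positive per-subject true value and two multiplicative noisy readings,
with the noise magnitude back-solved from a target mean within-subject
CoV and the between-subject spread back-solved from a target intraclass
correlation (see :func:`implied_icc`).
"""

from __future__ import annotations

import dataclasses
import functools
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .errors import StatisticsError
from .model import Gas, StudyDay

__all__ = [
    "CohortPreset",
    "CohortTables",
    "preset_library",
    "generate_cohort",
    "generate_repeatability_pairs",
    "implied_icc",
    "within_relative_sd",
]

_HALF_NORMAL_MEAN = math.sqrt(2.0 / math.pi)  # E|N(0,1)|


@dataclass(frozen=True)
class CohortPreset:
    """All parameters of one simulated study condition.

    Group-level means/SDs of flows, saturations and responses encode the
    study condition the preset is named after; per-vessel dispersions and
    the split of measurement noise into session/vessel/day components are
    documented estimates (no per-vessel dispersions are published) chosen
    so the implied test-retest CoV of the extraction value matches the
    preset's ``within_subject_cov``.
    """

    name: str
    n_subjects: int
    study_day: StudyDay
    gas: Gas
    # flow indices (a.u.)
    mv_baseline_mean: float
    mv_baseline_sd: float
    mt_baseline_mean: float
    mt_baseline_sd: float
    ma_baseline_mean: float
    ma_baseline_sd: float
    # per-subject gas response
    pct_change_mean: float  # % change of all flow indices during gas
    pct_change_sd: float
    sat_artery_shift_mean: float  # additive fraction shift during gas
    sat_artery_shift_sd: float
    sat_vein_shift_mean: float
    sat_vein_shift_sd: float
    # baseline saturations (fractions)
    sat_artery_mean: float = 0.96
    sat_artery_sd: float = 0.04
    sat_vein_mean: float = 0.64
    sat_vein_sd: float = 0.08
    # physiology
    hb_mean: float = 14.0
    hb_sd: float = 1.2
    po2_mean: float = 95.0
    po2_sd: float = 8.0
    po2_gas_mean: float = 95.0
    po2_gas_sd: float = 8.0
    so2_mean: float = 0.974
    so2_sd: float = 0.009
    # vessel structure
    arteries_per_eye: tuple[int, int] = (4, 7)
    veins_per_eye: tuple[int, int] = (4, 7)
    diameter_artery_mean: float = 95.0  # µm
    diameter_artery_sd: float = 12.0
    diameter_vein_mean: float = 125.0
    diameter_vein_sd: float = 15.0
    distance_mean: float = 1500.0  # µm to the ONH
    distance_sd: float = 400.0
    vessel_q_artery_mean: float = 35.0  # a.u.
    vessel_q_artery_sd: float = 8.0
    vessel_q_vein_mean: float = 38.0
    vessel_q_vein_sd: float = 9.0
    # measurement-noise components
    session_flow_cov: float = 0.08  # shared multiplicative, per session
    vessel_flow_cov: float = 0.05  # per vessel per session
    day_flow_cov: float = 0.04  # per day, drives long-term > short-term noise
    sat_session_sd_artery: float = 0.014  # shared additive, per session
    sat_session_sd_vein: float = 0.022
    vessel_sat_sd_artery: float = 0.015  # per vessel per session
    vessel_sat_sd_vein: float = 0.030
    day_sat_sd: float = 0.006
    # repeatability-pair generator targets
    baseline_ext_mean: float = 43.0  # a.u.
    baseline_ext_sd: float = 10.0
    within_subject_cov: float = 9.8  # target mean per-subject CoV, %
    between_within_variance_ratio: float = 0.910 / 0.090

    def zero_noise(self, zero_response: bool = False) -> "CohortPreset":
        """Copy with every measurement-noise SD set to zero (between-
        subject spread is kept). With ``zero_response`` the gas response
        is removed as well, making all six sessions identical."""
        fields = dict(
            pct_change_sd=0.0,
            sat_artery_shift_sd=0.0,
            sat_vein_shift_sd=0.0,
            session_flow_cov=0.0,
            vessel_flow_cov=0.0,
            day_flow_cov=0.0,
            sat_session_sd_artery=0.0,
            sat_session_sd_vein=0.0,
            vessel_sat_sd_artery=0.0,
            vessel_sat_sd_vein=0.0,
            day_sat_sd=0.0,
            within_subject_cov=0.0,
        )
        if zero_response:
            fields.update(
                pct_change_mean=0.0,
                sat_artery_shift_mean=0.0,
                sat_vein_shift_mean=0.0,
                po2_gas_mean=self.po2_mean,
                po2_gas_sd=self.po2_sd,
            )
        return dataclasses.replace(self, **fields)


def preset_library() -> dict[str, CohortPreset]:
    """Named study conditions.

    ``hyperoxia``/``hypoxia`` carry the published group values of the
    gas-challenge arms (flow indices 71->52 and 73->79 a.u., saturation
    pairs 96/64 -> 97/69 and 96/66 -> 94/65 percent, blood-gas tables);
    ``short_term``/``long_term`` carry the published repeatability
    targets (ICC 0.910, CoV 9.8% same-day; ICC 0.897, CoV 10.4%
    across days); ``null_effect`` has zero true response everywhere and
    exists for type-I-error calibration.
    """
    lib = {}
    lib["hyperoxia"] = CohortPreset(
        name="hyperoxia",
        n_subjects=21,
        study_day=StudyDay.HYPEROXIA_DAY,
        gas=Gas.OXYGEN_100,
        mv_baseline_mean=71.0,
        mv_baseline_sd=11.0,
        mt_baseline_mean=25.0,
        mt_baseline_sd=5.0,
        ma_baseline_mean=38.0,
        ma_baseline_sd=6.0,
        pct_change_mean=-26.0,
        pct_change_sd=12.0,
        sat_artery_shift_mean=0.01,
        sat_artery_shift_sd=0.02,
        sat_vein_shift_mean=0.05,
        sat_vein_shift_sd=0.05,
        sat_artery_mean=0.96,
        sat_artery_sd=0.04,
        sat_vein_mean=0.64,
        sat_vein_sd=0.08,
        po2_mean=95.0,
        po2_sd=8.0,
        po2_gas_mean=338.0,
        po2_gas_sd=44.0,
        so2_mean=0.974,
        so2_sd=0.009,
        baseline_ext_mean=43.0,
        baseline_ext_sd=10.0,
        within_subject_cov=9.8,
        between_within_variance_ratio=0.910 / 0.090,
    )
    lib["hypoxia"] = CohortPreset(
        name="hypoxia",
        n_subjects=22,
        study_day=StudyDay.HYPOXIA_DAY,
        gas=Gas.NITROGEN_88,
        mv_baseline_mean=73.0,
        mv_baseline_sd=9.0,
        mt_baseline_mean=26.0,
        mt_baseline_sd=5.0,
        ma_baseline_mean=38.0,
        ma_baseline_sd=6.0,
        pct_change_mean=9.0,
        pct_change_sd=10.0,
        # shifts sit inside the rounding bands of the printed integer
        # saturation levels (96->94, 66->65) and jointly reproduce the
        # printed per-subject content-difference change of about -2%
        sat_artery_shift_mean=-0.018,
        sat_artery_shift_sd=0.04,
        sat_vein_shift_mean=-0.012,
        sat_vein_shift_sd=0.04,
        sat_artery_mean=0.96,
        sat_artery_sd=0.03,
        sat_vein_mean=0.66,
        sat_vein_sd=0.06,
        po2_mean=96.0,
        po2_sd=15.0,
        po2_gas_mean=55.0,
        po2_gas_sd=4.0,
        so2_mean=0.976,
        so2_sd=0.008,
        baseline_ext_mean=42.0,
        baseline_ext_sd=10.0,
        within_subject_cov=9.8,
        between_within_variance_ratio=0.910 / 0.090,
    )
    _baseline_like = dict(
        mv_baseline_mean=71.0,
        mv_baseline_sd=11.0,
        mt_baseline_mean=25.0,
        mt_baseline_sd=5.0,
        ma_baseline_mean=38.0,
        ma_baseline_sd=6.0,
        pct_change_mean=0.0,
        pct_change_sd=0.0,
        sat_artery_shift_mean=0.0,
        sat_artery_shift_sd=0.0,
        sat_vein_shift_mean=0.0,
        sat_vein_shift_sd=0.0,
    )
    lib["short_term"] = CohortPreset(
        name="short_term",
        n_subjects=18,
        study_day=StudyDay.HYPEROXIA_DAY,
        gas=Gas.OXYGEN_100,
        baseline_ext_mean=43.0,
        baseline_ext_sd=10.0,
        within_subject_cov=9.8,
        between_within_variance_ratio=0.910 / 0.090,
        **_baseline_like,
    )
    lib["long_term"] = CohortPreset(
        name="long_term",
        n_subjects=18,
        study_day=StudyDay.HYPEROXIA_DAY,
        gas=Gas.OXYGEN_100,
        baseline_ext_mean=43.0,
        baseline_ext_sd=10.0,
        within_subject_cov=10.4,
        between_within_variance_ratio=0.897 / 0.103,
        **_baseline_like,
    )
    lib["null_effect"] = CohortPreset(
        name="null_effect",
        n_subjects=22,
        study_day=StudyDay.HYPEROXIA_DAY,
        gas=Gas.OXYGEN_100,
        baseline_ext_mean=43.0,
        baseline_ext_sd=10.0,
        within_subject_cov=9.8,
        between_within_variance_ratio=0.910 / 0.090,
        **_baseline_like,
    )
    return lib


def get_preset(name: str) -> CohortPreset:
    lib = preset_library()
    if name not in lib:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(lib)}")
    return lib[name]


_COMPANION = {"hyperoxia": "hypoxia", "hypoxia": "hyperoxia"}


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    """Normal draw(s) truncated to [lo, hi] by rejection; sd = 0 returns
    the mean (which must lie inside the bounds)."""
    if sd == 0.0:
        if not lo <= mean <= hi:
            raise StatisticsError(f"infeasible preset: fixed value {mean} outside [{lo}, {hi}]")
        return np.full(size, float(mean)) if size is not None else float(mean)
    n = int(np.prod(size)) if size is not None else 1
    out = np.empty(n)
    filled = 0
    for _ in range(200):
        draw = rng.normal(mean, sd, size=n - filled)
        ok = draw[(draw >= lo) & (draw <= hi)]
        out[filled : filled + ok.size] = ok
        filled += ok.size
        if filled == n:
            break
    else:
        raise StatisticsError(
            f"infeasible preset: cannot draw N({mean}, {sd}) within [{lo}, {hi}]"
        )
    if size is None:
        return float(out[0])
    return out.reshape(size)


def _mean_matched_truncnorm(rng, mean, sd, lo, hi, size=None):
    """Truncated-normal draw whose TRUNCATED mean equals ``mean``: the
    pre-truncation location is solved for, so piling mass against a
    physiologic ceiling (e.g. arterial saturation near 1) does not drag
    the realized group mean below the intended one. The realized SD is
    smaller than ``sd`` when the bounds bind; this is the price of a
    hard physical range."""
    if sd == 0.0:
        return _truncated_normal(rng, mean, sd, lo, hi, size)
    if not lo < mean < hi:
        raise StatisticsError(f"infeasible preset: target mean {mean} outside ({lo}, {hi})")
    loc = _solve_truncnorm_loc(mean, sd, lo, hi)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    draw = sps.truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)
    return draw if size is not None else float(draw)


@functools.lru_cache(maxsize=256)
def _solve_truncnorm_loc(mean: float, sd: float, lo: float, hi: float) -> float:
    def trunc_mean(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return float(sps.truncnorm.mean(a, b, loc=loc, scale=sd))

    return float(
        optimize.brentq(lambda m: trunc_mean(m) - mean, mean - 6.0 * sd, hi + 6.0 * sd, xtol=1e-10)
    )


def _lognormal(rng, mean, sd, size=None):
    """Log-normal draw(s) with the given arithmetic mean and SD; sd = 0
    returns the mean exactly."""
    if mean <= 0:
        raise StatisticsError(f"log-normal mean must be > 0, got {mean}")
    if sd == 0.0:
        return np.full(size, float(mean)) if size is not None else float(mean)
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    draw = rng.lognormal(mu, math.sqrt(sigma2), size=size)
    return draw if size is not None else float(draw)


class CohortTables(NamedTuple):
    """The four input tables, in the on-disk schemas (saturations in
    percent)."""

    vessels: pd.DataFrame
    subjects: pd.DataFrame
    onh: pd.DataFrame
    sessions: pd.DataFrame


_MIN_AV_GAP_BASE = 0.12  # minimum arteriovenous saturation gap, baseline
_MIN_AV_GAP_GAS = 0.02
_SAT_LO, _SAT_HI = 0.05, 0.995


def _draw_subject_sats(rng, preset: CohortPreset) -> tuple[float, float]:
    for _ in range(500):
        sa = _mean_matched_truncnorm(rng, preset.sat_artery_mean, preset.sat_artery_sd, 0.5, _SAT_HI)
        sv = _mean_matched_truncnorm(rng, preset.sat_vein_mean, preset.sat_vein_sd, 0.2, 0.92)
        if sa - sv >= _MIN_AV_GAP_BASE:
            return sa, sv
    raise StatisticsError("infeasible preset: arteriovenous saturation gap cannot be met")


def _draw_shifts(rng, preset: CohortPreset, sat_a: float, sat_v: float) -> tuple[float, float]:
    """Per-subject gas-response saturation shifts, drawn independently of
    the subject's baseline level (conditioning the draw on the baseline
    would correlate response and level and bias the cohort-mean percent
    change). The only constraint kept is a positive arteriovenous gap
    during gas; the rare ceiling overshoot is clipped later at the
    per-vessel stage."""
    deterministic = preset.sat_artery_shift_sd == 0.0 and preset.sat_vein_shift_sd == 0.0
    for _ in range(500):
        da = rng.normal(preset.sat_artery_shift_mean, preset.sat_artery_shift_sd)
        dv = rng.normal(preset.sat_vein_shift_mean, preset.sat_vein_shift_sd)
        if (sat_a + da) - (sat_v + dv) >= _MIN_AV_GAP_GAS:
            return da, dv
        if deterministic:
            raise StatisticsError(
                "infeasible preset: deterministic saturation shifts leave no "
                "valid arteriovenous gap"
            )
    raise StatisticsError("infeasible preset: saturation shifts cannot satisfy constraints")


_TIMEPOINTS = ("baseline1", "baseline2", "gas")
_SESSION_CODE = {"baseline1": "b1", "baseline2": "b2", "gas": "g"}


def generate_cohort(
    preset: CohortPreset,
    seed: int | np.random.Generator | None = 0,
    n_subjects: int | None = None,
    n_days: int = 2,
    companion: CohortPreset | None = None,
) -> CohortTables:
    """Generate a complete synthetic study dataset.

    Day 1 carries the preset's own gas challenge. With ``n_days=2``
    (the full crossover) day 2 carries the companion challenge — the
    opposite gas for the hyperoxia/hypoxia presets, the preset itself
    otherwise — applied to the same subjects. Deterministic given the
    seed.
    """
    rng = _rng(seed)
    n = n_subjects if n_subjects is not None else preset.n_subjects
    if n < 1:
        raise StatisticsError("n_subjects must be >= 1")
    if n_days not in (1, 2):
        raise StatisticsError("n_days must be 1 or 2")
    if companion is None:
        if preset.name in _COMPANION:
            companion = preset_library()[_COMPANION[preset.name]]
        else:
            companion = preset
    day_presets = [preset, companion][:n_days]

    vessel_rows: list[tuple] = []
    subject_rows: list[tuple] = []
    onh_rows: list[tuple] = []
    session_rows: list[tuple] = []

    for i in range(n):
        sid = f"S{i + 1:03d}"
        hb = _truncated_normal(rng, preset.hb_mean, preset.hb_sd, 8.0, 22.0)
        po2 = _truncated_normal(rng, preset.po2_mean, preset.po2_sd, 30.0, 600.0)
        so2 = _truncated_normal(rng, preset.so2_mean, preset.so2_sd, 0.5, 1.0)
        subject_rows.append((sid, hb, po2, so2 * 100.0))

        sat_a, sat_v = _draw_subject_sats(rng, preset)
        lo_a, hi_a = preset.arteries_per_eye
        lo_v, hi_v = preset.veins_per_eye
        n_art = int(rng.integers(lo_a, hi_a + 1))
        n_vein = int(rng.integers(lo_v, hi_v + 1))

        # persistent per-vessel traits
        dia_a = _lognormal(rng, preset.diameter_artery_mean, preset.diameter_artery_sd, n_art)
        dia_v = _lognormal(rng, preset.diameter_vein_mean, preset.diameter_vein_sd, n_vein)
        dist_a = _lognormal(rng, preset.distance_mean, preset.distance_sd, n_art)
        dist_v = _lognormal(rng, preset.distance_mean, preset.distance_sd, n_vein)
        q_a = _lognormal(rng, preset.vessel_q_artery_mean, preset.vessel_q_artery_sd, n_art)
        q_v = _lognormal(rng, preset.vessel_q_vein_mean, preset.vessel_q_vein_sd, n_vein)
        mv0 = _lognormal(rng, preset.mv_baseline_mean, preset.mv_baseline_sd)
        mt0 = _lognormal(rng, preset.mt_baseline_mean, preset.mt_baseline_sd)
        ma0 = _lognormal(rng, preset.ma_baseline_mean, preset.ma_baseline_sd)

        for d, dp in enumerate(day_presets, start=1):
            flow_factor = 1.0 + _truncated_normal(rng, dp.pct_change_mean, dp.pct_change_sd, -95.0, 400.0) / 100.0
            da, dv = _draw_shifts(rng, dp, sat_a, sat_v)
            day_flow = 1.0 + rng.normal(0.0, dp.day_flow_cov) if dp.day_flow_cov else 1.0
            day_sat = rng.normal(0.0, dp.day_sat_sd) if dp.day_sat_sd else 0.0

            for tp in _TIMEPOINTS:
                sess = f"d{d}{_SESSION_CODE[tp]}"
                is_gas = tp == "gas"
                f_resp = flow_factor if is_gas else 1.0
                sess_flow = 1.0 + rng.normal(0.0, dp.session_flow_cov) if dp.session_flow_cov else 1.0
                state = day_flow * sess_flow * f_resp
                sat_a_state = sat_a + day_sat + (da if is_gas else 0.0)
                sat_v_state = sat_v + day_sat + (dv if is_gas else 0.0)
                if dp.sat_session_sd_artery:
                    sat_a_state += rng.normal(0.0, dp.sat_session_sd_artery)
                if dp.sat_session_sd_vein:
                    sat_v_state += rng.normal(0.0, dp.sat_session_sd_vein)

                sats_art = sat_a_state + (
                    rng.normal(0.0, dp.vessel_sat_sd_artery, n_art)
                    if dp.vessel_sat_sd_artery
                    else np.zeros(n_art)
                )
                sats_vei = sat_v_state + (
                    rng.normal(0.0, dp.vessel_sat_sd_vein, n_vein)
                    if dp.vessel_sat_sd_vein
                    else np.zeros(n_vein)
                )
                sats_art = np.clip(sats_art, _SAT_LO, _SAT_HI)
                sats_vei = np.clip(sats_vei, _SAT_LO, _SAT_HI)
                # venous saturations stay strictly below arterial ones
                ceiling = sats_art.min() - 0.005
                sats_vei = np.minimum(sats_vei, ceiling)

                qs_art = q_a * state
                qs_vei = q_v * state
                if dp.vessel_flow_cov:
                    qs_art = qs_art * (1.0 + rng.normal(0.0, dp.vessel_flow_cov, n_art))
                    qs_vei = qs_vei * (1.0 + rng.normal(0.0, dp.vessel_flow_cov, n_vein))
                qs_art = np.maximum(qs_art, 0.5)
                qs_vei = np.maximum(qs_vei, 0.5)

                for j in range(n_art):
                    vessel_rows.append(
                        (sid, sess, f"A{j + 1}", "A", sats_art[j] * 100.0, dia_a[j], dist_a[j], qs_art[j])
                    )
                for j in range(n_vein):
                    vessel_rows.append(
                        (sid, sess, f"V{j + 1}", "V", sats_vei[j] * 100.0, dia_v[j], dist_v[j], qs_vei[j])
                    )
                onh_rows.append((sid, sess, mv0 * state, mt0 * state, ma0 * state))
                session_rows.append(
                    (sid, sess, dp.study_day.value, tp, dp.gas.value if is_gas else Gas.ROOM_AIR.value)
                )

    vessels = pd.DataFrame(
        vessel_rows,
        columns=["subject_id", "session_id", "vessel_id", "vessel_type", "sat_pct", "diameter_um", "distance_um", "mbr_au"],
    )
    subjects = pd.DataFrame(subject_rows, columns=["subject_id", "hb_g_dl", "po2_mmhg", "so2_pct"])
    onh = pd.DataFrame(onh_rows, columns=["subject_id", "session_id", "mv_au", "mt_au", "ma_au"])
    sessions = pd.DataFrame(session_rows, columns=["subject_id", "session_id", "study_day", "timepoint", "gas"])
    return CohortTables(vessels=vessels, subjects=subjects, onh=onh, sessions=sessions)


def within_relative_sd(cov_target_pct: float) -> float:
    """Relative within-subject SD c such that duplicate readings
    x = t (1 + e), e ~ N(0, c), have expected mean per-subject CoV equal
    to the target.

    The per-subject CoV estimate from a pair, |x1 - x2| / sqrt(2) over
    the pair mean, has expectation c * sqrt(2/pi) * (1 + c^2/2) to
    second order (half-normal mean, plus the Jensen term of the noisy
    denominator); this is inverted by fixed-point iteration."""
    target = cov_target_pct / 100.0
    if target < 0:
        raise StatisticsError("CoV target must be >= 0")
    if target == 0.0:
        return 0.0
    c = target / _HALF_NORMAL_MEAN
    for _ in range(50):
        c = target / (_HALF_NORMAL_MEAN * (1.0 + c * c / 2.0))
    return c


def _between_sd(preset: CohortPreset, c_within: float) -> float:
    """Between-subject SD of the true value solving the preset's target
    intraclass correlation under multiplicative within-subject noise
    (within-variance E[t^2] c^2 depends on the between-spread itself)."""
    if c_within == 0.0:
        return preset.baseline_ext_sd
    r = preset.between_within_variance_ratio
    mu = preset.baseline_ext_mean
    denom = 1.0 - r * c_within**2
    if denom <= 0:
        raise StatisticsError(
            "infeasible preset: variance ratio and within-subject CoV imply "
            "unbounded between-subject variance"
        )
    return math.sqrt(r * mu**2 * c_within**2 / denom)


def implied_icc(preset: CohortPreset) -> float:
    """Population intraclass correlation of repeatability pairs generated
    from the preset: Corr(x1, x2) = var(t) / (var(t) + E[t^2] c^2) =
    ratio / (1 + ratio), by construction of the between-subject spread."""
    c = within_relative_sd(preset.within_subject_cov)
    if c == 0.0:
        return 1.0
    r = preset.between_within_variance_ratio
    return r / (1.0 + r)


def generate_repeatability_pairs(
    preset: CohortPreset,
    seed: int | np.random.Generator | None = 0,
    n_subjects: int | None = None,
) -> pd.DataFrame:
    """Two measurements per subject with the preset's between-subject
    spread and within-subject CoV. True values are moment-matched
    log-normal (strictly positive); readings are t (1 + e) with
    independent Gaussian relative errors. Returns a table with columns
    subject_id, measurement_1, measurement_2."""
    rng = _rng(seed)
    n = n_subjects if n_subjects is not None else preset.n_subjects
    c = within_relative_sd(preset.within_subject_cov)
    sigma_b = _between_sd(preset, c)
    t = _lognormal(rng, preset.baseline_ext_mean, sigma_b, n)
    if c > 0.0:
        eps = rng.normal(0.0, c, size=(n, 2))
    else:
        eps = np.zeros((n, 2))
    x = t[:, None] * (1.0 + eps)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:03d}" for i in range(n)],
            "measurement_1": x[:, 0],
            "measurement_2": x[:, 1],
        }
    )
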