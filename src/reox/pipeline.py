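"""End-to-end orchestration: tables -> per-session extraction ->
gas-challenge contrasts and reproducibility reports, plus the seeded
Monte-Carlo replication engines used to check that the full pipeline
recovers the study conditions its presets encode."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .cohort import (
    CohortPreset,
    CohortTables,
    generate_cohort,
    generate_repeatability_pairs,
    get_preset,
)
from .errors import SessionValidationError, StatisticsError
from .extraction import ExtractionResult, compute_session_extraction
from .io import results_to_frame
from .model import (
    BaselinePolicy,
    OnhFlowMetrics,
    RunConfig,
    SubjectPhysiology,
    VesselMeasurement,
    VesselType,
    validate_session,
)

logger = logging.getLogger(__name__)

__all__ = [
    "extract_tables",
    "AnalysisResult",
    "analyze_results",
    "replicate_gas_challenge",
    "replicate_repeatability",
    "replicate_null_type1",
]

#: Variables contrasted between baseline and gas breathing.
CONTRAST_VARIABLES = ("ext_o2_au", "mv_au", "av_diff", "sat_cra_pct", "sat_crv_pct")


def extract_tables(
    tables: CohortTables,
    config: RunConfig | None = None,
    strict: bool = True,
) -> tuple[pd.DataFrame, list[ExtractionResult]]:
    """Run per-session extraction over a full set of input tables.

    Groups vessel rows by (subject, session), validates each session and
    computes the extraction chain. With ``strict`` any failing session
    raises; otherwise failures are logged and skipped (an all-failed run
    still raises)."""
    config = config or RunConfig()
    phys = {
        str(r.subject_id): SubjectPhysiology(
            subject_id=str(r.subject_id),
            hb=float(r.hb_g_dl),
            po2_systemic=float(r.po2_mmhg),
            so2_systemic=float(r.so2_pct) / 100.0,
        )
        for r in tables.subjects.itertuples(index=False)
    }
    onh = {
        (str(r.subject_id), str(r.session_id)): OnhFlowMetrics(
            subject_id=str(r.subject_id),
            session_id=str(r.session_id),
            mv=float(r.mv_au),
            mt=float(r.mt_au),
            ma=float(r.ma_au),
        )
        for r in tables.onh.itertuples(index=False)
    }

    v = tables.vessels
    cols = {
        "vessel_id": v["vessel_id"].to_numpy(),
        "vessel_type": v["vessel_type"].to_numpy(),
        "sat_pct": v["sat_pct"].to_numpy(dtype=float),
        "diameter_um": v["diameter_um"].to_numpy(dtype=float),
        "distance_um": v["distance_um"].to_numpy(dtype=float),
        "mbr_au": v["mbr_au"].to_numpy(dtype=float),
    }
    groups = v.groupby(["subject_id", "session_id"], sort=True).indices

    results: list[ExtractionResult] = []
    errors: list[str] = []
    for (sid, sess), idx in groups.items():
        sid, sess = str(sid), str(sess)
        try:
            vessels = [
                VesselMeasurement(
                    subject_id=sid,
                    session_id=sess,
                    vessel_id=str(cols["vessel_id"][i]),
                    vessel_type=VesselType(cols["vessel_type"][i]),
                    sat_measured=cols["sat_pct"][i] / 100.0,
                    diameter=cols["diameter_um"][i],
                    distance_L=cols["distance_um"][i],
                    mbr_Q=cols["mbr_au"][i],
                )
                for i in idx
            ]
            if sid not in phys:
                raise SessionValidationError(f"no physiology for subject {sid}")
            if (sid, sess) not in onh:
                raise SessionValidationError(f"no ONH flow metrics for {sid}/{sess}")
            bundle = validate_session(vessels, phys[sid], onh[(sid, sess)])
            results.append(compute_session_extraction(bundle, config))
        except (SessionValidationError, ValueError) as exc:
            if strict:
                raise
            errors.append(f"{sid}/{sess}: {exc}")
            logger.warning("skipping session %s/%s: %s", sid, sess, exc)
    if not results:
        raise SessionValidationError(
            "no session could be extracted" + (f"; first error: {errors[0]}" if errors else "")
        )
    return results_to_frame(results), results


def _baseline_value(b1: pd.Series, b2: pd.Series, policy: BaselinePolicy) -> pd.Series:
    if policy is BaselinePolicy.FIRST:
        return b1
    if policy is BaselinePolicy.SECOND:
        return b2
    return (b1 + b2) / 2.0


@dataclass
class AnalysisResult:
    """Outputs of the statistical surface for one extracted cohort."""

    contrasts: pd.DataFrame  # per (study_day, variable) baseline-vs-gas contrast
    interaction: pd.DataFrame  # per variable day-by-time interaction
    reproducibility: pd.DataFrame  # short/long-term ICC, CoV, Bland-Altman
    bland_altman_coordinates: pd.DataFrame  # per-pair (average, difference)
    per_subject_changes: pd.DataFrame  # tidy per-subject percent changes


def _wide_by_timepoint(merged: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Pivot all contrast variables at once to subject x
    (study_day, timepoint) tables, one per variable."""
    wide_all = merged.pivot_table(
        index="subject_id",
        columns=["study_day", "timepoint"],
        values=list(CONTRAST_VARIABLES),
        aggfunc="first",
    )
    return {var: wide_all[var] for var in CONTRAST_VARIABLES if var in wide_all.columns.get_level_values(0)}


def analyze_results(
    results: pd.DataFrame,
    sessions: pd.DataFrame,
    config: RunConfig | None = None,
    repro_variable: str = "ext_o2_au",
) -> AnalysisResult:
    """Compute the study's statistical surface from extracted sessions.

    Contrasts: per study day, each variable's same-day baseline
    (per the configured baseline policy, default the mean of the two
    room-air baselines) against the gas session, with the mean +/- SD of
    per-subject percent changes and a two-sided paired test.

    Reproducibility of ``repro_variable`` (default the extraction value):
    short-term pairs are the two same-day baselines pooled over study
    days; long-term pairs compare the two days' baseline representatives.
    """
    config = config or RunConfig()
    merged = results.merge(sessions, on=["subject_id", "session_id"], how="inner", validate="one_to_one")
    if merged.empty:
        raise StatisticsError("no overlap between results and session labels")

    contrast_rows = []
    change_rows = []
    interaction_rows = []
    per_day_diffs: dict[str, dict[str, pd.Series]] = {}

    wide_by_var = _wide_by_timepoint(merged)
    for variable, wide in wide_by_var.items():
        for day in sorted({d for d, _ in wide.columns}):
            sub = wide[day].dropna(subset=["baseline1", "baseline2", "gas"])
            if len(sub) < 2:
                continue
            base = _baseline_value(sub["baseline1"], sub["baseline2"], config.baseline_policy)
            res = stats.gas_contrast(base.to_numpy(), sub["gas"].to_numpy())
            changes = stats.percent_change(base.to_numpy(), sub["gas"].to_numpy())
            try:
                _, shapiro_p = stats.shapiro_diagnostic(changes)
            except StatisticsError:
                shapiro_p = float("nan")
            contrast_rows.append(
                {
                    "study_day": day,
                    "variable": variable,
                    "mean_baseline": res.mean_baseline,
                    "mean_gas": res.mean_gas,
                    "mean_pct_change": res.mean_pct_change,
                    "sd_pct_change": res.sd_pct_change,
                    "p_value": res.p_value,
                    "n": res.n,
                    "shapiro_p_changes": shapiro_p,
                }
            )
            for subject, ch in zip(sub.index, changes):
                change_rows.append(
                    {"subject_id": subject, "study_day": day, "variable": variable, "pct_change": ch}
                )
            per_day_diffs.setdefault(variable, {})[day] = sub["gas"] - base

        days = per_day_diffs.get(variable, {})
        if len(days) == 2:
            d1, d2 = (days[k] for k in sorted(days))
            common = d1.index.intersection(d2.index)
            if len(common) >= 2:
                mean_dod, p = stats.day_interaction(d1.loc[common].to_numpy(), d2.loc[common].to_numpy())
                interaction_rows.append(
                    {"variable": variable, "mean_diff_of_diffs": mean_dod, "p_value": p, "n": len(common)}
                )

    # reproducibility of the chosen variable
    if repro_variable in wide_by_var:
        wide = wide_by_var[repro_variable]
    else:
        wide = merged.pivot_table(
            index="subject_id", columns=["study_day", "timepoint"], values=repro_variable, aggfunc="first"
        )
    repro_rows = []
    ba_rows = []
    short_pairs = []
    for day in sorted({d for d, _ in wide.columns}):
        sub = wide[day].dropna(subset=["baseline1", "baseline2"])
        short_pairs.append(sub[["baseline1", "baseline2"]].to_numpy())
    short = np.vstack(short_pairs) if short_pairs else np.empty((0, 2))

    day_levels = sorted({d for d, _ in wide.columns})
    long = np.empty((0, 2))
    if len(day_levels) == 2:
        reps = {}
        for day in day_levels:
            sub = wide[day].dropna(subset=["baseline1", "baseline2"])
            reps[day] = _baseline_value(sub["baseline1"], sub["baseline2"], config.baseline_policy)
        common = reps[day_levels[0]].index.intersection(reps[day_levels[1]].index)
        long = np.column_stack(
            [reps[day_levels[0]].loc[common].to_numpy(), reps[day_levels[1]].loc[common].to_numpy()]
        )

    for name, pairs in (("short_term", short), ("long_term", long)):
        if pairs.shape[0] < 3:
            continue
        rep = stats.reproducibility_report(pairs, config.icc_model)
        repro_rows.append(
            {
                "comparison": name,
                "variable": repro_variable,
                "icc": rep.icc,
                "icc_model": rep.icc_model.value,
                "icc_band": rep.icc_band,
                "cov_mean_pct": rep.cov_mean,
                "cov_sd_pct": rep.cov_sd,
                "ba_bias": rep.bland_altman_bias,
                "ba_loa_low": rep.bland_altman_loa_low,
                "ba_loa_high": rep.bland_altman_loa_high,
                "n_pairs": rep.n_pairs,
            }
        )
        ba = stats.bland_altman(pairs)
        for m, d in zip(ba.means, ba.differences):
            ba_rows.append({"comparison": name, "average": m, "difference": d})

    if not contrast_rows and not repro_rows:
        raise StatisticsError(
            "too few subjects: neither a paired contrast (needs >= 2) nor a "
            "reproducibility report (needs >= 3 baseline pairs) is defined"
        )
    return AnalysisResult(
        contrasts=pd.DataFrame(contrast_rows),
        interaction=pd.DataFrame(interaction_rows),
        reproducibility=pd.DataFrame(repro_rows),
        bland_altman_coordinates=pd.DataFrame(ba_rows),
        per_subject_changes=pd.DataFrame(change_rows),
    )


# ---------------------------------------------------------------------------
# Monte-Carlo replication engines
# ---------------------------------------------------------------------------


def _spawn_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def replicate_gas_challenge(
    preset: CohortPreset | str,
    n_reps: int,
    seed: int = 0,
    config: RunConfig | None = None,
    n_subjects: int | None = None,
    n_days: int = 1,
) -> pd.DataFrame:
    """Simulate -> extract -> contrast, ``n_reps`` times.

    Each replicate generates a fresh cohort from the preset, runs the
    full extraction pipeline and the contrast analysis on the preset's
    own study day, and records the cohort mean/SD of per-subject percent
    changes and the contrast p-value per variable. Returns one tidy row
    per (replicate, variable)."""
    if isinstance(preset, str):
        preset = get_preset(preset)
    config = config or RunConfig()
    rows = []
    for r, ss in enumerate(_spawn_seeds(seed, n_reps)):
        rng = np.random.Generator(np.random.Philox(ss))
        tables = generate_cohort(preset, rng, n_subjects=n_subjects, n_days=n_days)
        results, _ = extract_tables(tables, config)
        analysis = analyze_results(results, tables.sessions, config)
        day = preset.study_day.value
        sub = analysis.contrasts[analysis.contrasts["study_day"] == day]
        for rec in sub.itertuples(index=False):
            rows.append(
                {
                    "replicate": r,
                    "variable": rec.variable,
                    "mean_pct_change": rec.mean_pct_change,
                    "sd_pct_change": rec.sd_pct_change,
                    "p_value": rec.p_value,
                    "n": rec.n,
                }
            )
    return pd.DataFrame(rows)


def replicate_repeatability(
    preset: CohortPreset | str,
    n_reps: int,
    seed: int = 0,
    n_subjects: int = 500,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Generate duplicate-measurement tables and estimate ICC and
    within-subject CoV, ``n_reps`` times. One row per replicate."""
    if isinstance(preset, str):
        preset = get_preset(preset)
    config = config or RunConfig()
    rows = []
    for r, ss in enumerate(_spawn_seeds(seed, n_reps)):
        rng = np.random.Generator(np.random.Philox(ss))
        pairs_df = generate_repeatability_pairs(preset, rng, n_subjects=n_subjects)
        pairs = pairs_df[["measurement_1", "measurement_2"]].to_numpy()
        icc_hat = stats.icc(pairs, config.icc_model)
        cov_mean, cov_sd, _ = stats.cov_within_subject(pairs)
        rows.append({"replicate": r, "icc": icc_hat, "cov_mean_pct": cov_mean, "cov_sd_pct": cov_sd})
    return pd.DataFrame(rows)


def replicate_null_type1(
    n_reps: int,
    seed: int = 0,
    alpha: float = 0.05,
    config: RunConfig | None = None,
    variable: str = "ext_o2_au",
) -> tuple[float, np.ndarray]:
    """Type-I-error calibration: run the full pipeline on the zero-
    response preset ``n_reps`` times and return the fraction of
    replicates whose baseline-vs-gas contrast on ``variable`` is
    significant at ``alpha``, plus the p-values."""
    df = replicate_gas_challenge("null_effect", n_reps, seed=seed, config=config, n_days=1)
    p = df.loc[df["variable"] == variable, "p_value"].to_numpy()
    return float(np.mean(p < alpha)), p
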