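"""End-to-end orchestration: phantoms -> segmentation -> morphometry -> biomarkers.

Mirrors the shape of a longitudinal brain-metastasis imaging study: every
lesion contributes a pre-treatment scan and a first post-treatment follow-up;
morphological features are extracted per scan, treatment response is summarized
by the post/pre volume ratio and the TVN composite, and each candidate variable
is screened with the threshold-sweep Kaplan-Meier analysis and Cox models.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import phantoms
from .cohort import CohortRecord
from .morphometry import extract_features
from .segmentation import ImageVolume, detect_necrosis, read_image, segment_ce
from .survival import (
    ProgressionCriterion,
    TVNCoefficients,
    cox_stepwise,
    cox_univariate,
    km_estimate,
    logrank,
    median_difference,
    threshold_sweep,
    tvn_score,
)

logger = logging.getLogger("metmorph")

__all__ = [
    "BiomarkerConfig",
    "run_feature_stage",
    "assemble_cohort",
    "run_biomarker_stage",
    "run_demo",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = [
    "total_volume_cm3",
    "necrotic_volume_cm3",
    "ce_volume_cm3",
    "surface_area_cm2",
    "surface_regularity",
    "rim_width_cm",
    "has_necrosis",
]


@dataclass(frozen=True)
class BiomarkerConfig:
    """Knobs of the biomarker screening battery (all logged in reports)."""

    sweep_grid: int | str = "observed"
    min_group_fraction: float = 0.10
    alpha: float = 0.05
    removal_alpha: float = 0.10
    tvn: TVNCoefficients = TVNCoefficients()
    progression: ProgressionCriterion = ProgressionCriterion()
    min_cohort_size: int = 10


def run_feature_stage(timepoints, threshold, component_policy: str = "largest"):
    """Segment and featurize a set of lesion timepoints.

    Parameters
    ----------
    timepoints : iterable of (lesion_id, patient_id, time_months, image)
        ``image`` is an :class:`ImageVolume` or a path to a NIfTI file.
    threshold : float or callable
        Gray-level segmentation threshold, or a callable mapping an
        ``ImageVolume`` to one (e.g. :func:`metmorph.segmentation.otsu_threshold`).

    Returns ``(feature_table, exclusions)``: one feature row per timepoint
    that segmented successfully, and a list of ``(lesion_id, time, reason)``
    for those that did not (the run continues past failures).
    """
    rows, exclusions = [], []
    n_lesions = set()
    for lesion_id, patient_id, time_months, image in timepoints:
        try:
            if not isinstance(image, ImageVolume):
                image = read_image(image)
            thr = threshold(image) if callable(threshold) else float(threshold)
            mask = detect_necrosis(segment_ce(image, thr, component_policy))
            feats = extract_features(mask)
        except Exception as exc:  # unreadable file, empty lesion, bad header, ...
            logger.warning("excluding lesion %s @ %s months: %s", lesion_id, time_months, exc)
            exclusions.append((lesion_id, time_months, str(exc)))
            continue
        n_lesions.add(lesion_id)
        rows.append(
            {
                "lesion_id": lesion_id,
                "patient_id": patient_id,
                "time_months": float(time_months),
                "total_volume_cm3": feats.total_volume,
                "necrotic_volume_cm3": feats.necrotic_volume,
                "ce_volume_cm3": feats.ce_volume,
                "surface_area_cm2": feats.surface_area,
                "surface_regularity": feats.surface_regularity,
                "rim_width_cm": feats.rim_width,
                "has_necrosis": int(feats.has_necrosis),
            }
        )
    logger.info(
        "feature stage: %d timepoints examined for %d lesions (%d excluded)",
        len(rows), len(n_lesions), len(exclusions),
    )
    return pd.DataFrame(rows), exclusions


def assemble_cohort(features: pd.DataFrame, tvn: TVNCoefficients = TVNCoefficients()) -> pd.DataFrame:
    """Pivot a per-timepoint feature table into one row per lesion.

    The pre-treatment scan is the latest with time < 0 and the first
    follow-up the earliest with time >= 0.  Adds the post/pre total-volume
    ratio and the TVN composite; lesions missing either scan are dropped
    with a warning.
    """
    out = []
    for lesion_id, grp in features.groupby("lesion_id", sort=True):
        pre = grp[grp["time_months"] < 0].sort_values("time_months")
        post = grp[grp["time_months"] >= 0].sort_values("time_months")
        if pre.empty or post.empty:
            logger.warning("lesion %s lacks a pre or post scan; dropped from cohort", lesion_id)
            continue
        p, q = pre.iloc[-1], post.iloc[0]
        row = {"lesion_id": lesion_id, "patient_id": p["patient_id"]}
        for col in FEATURE_COLUMNS:
            row[col.replace("_cm3", "").replace("_cm2", "").replace("_cm", "") + "_pre"] = p[col]
            row[col.replace("_cm3", "").replace("_cm2", "").replace("_cm", "") + "_post"] = q[col]
        ratio = q["total_volume_cm3"] / p["total_volume_cm3"]
        row["volume_ratio"] = ratio
        row["tvn"] = tvn_score(ratio, bool(q["has_necrosis"]), tvn)
        out.append(row)
    return pd.DataFrame(out)


def _records_from_tables(covariates: pd.DataFrame, survival: pd.DataFrame, variables):
    merged = covariates.merge(survival[["lesion_id", "time_months", "event"]], on="lesion_id", how="inner")
    orphans = {
        "features_only": sorted(set(covariates["lesion_id"]) - set(survival["lesion_id"])),
        "survival_only": sorted(set(survival["lesion_id"]) - set(covariates["lesion_id"])),
    }
    records = [
        CohortRecord(
            lesion_id=str(r["lesion_id"]),
            patient_id=str(r.get("patient_id", "")),
            covariates={v: float(r[v]) for v in variables},
            time=float(r["time_months"]),
            event=bool(r["event"]),
        )
        for _, r in merged.iterrows()
    ]
    return records, orphans


def _analyze_variable(records, variable, config: BiomarkerConfig):
    """One report row: sweep (or direct binary split), KM medians, Cox HR."""
    x = np.array([r.covariates[variable] for r in records])
    distinct = np.unique(x)
    row = {"variable": variable}
    details = {}
    if distinct.size < 2:
        raise ValueError(f"covariate {variable!r} is constant")
    if distinct.size == 2:
        # binary variable: single natural split, no sweep
        cut = float(distinct[:2].mean())
        low = [r for r in records if r.covariates[variable] <= cut]
        high = [r for r in records if r.covariates[variable] > cut]
        stat, p = logrank(low, high)
        km_low, km_high = km_estimate(low), km_estimate(high)
        row.update(
            best_threshold=np.nan,
            logrank_p=p,
            n_low=len(low),
            n_high=len(high),
            median_diff_months=median_difference(km_low, km_high),
            significant=p < config.alpha,
        )
        indicator = variable
    else:
        sweep = threshold_sweep(
            records, variable,
            grid=config.sweep_grid,
            min_group_fraction=config.min_group_fraction,
            alpha=config.alpha,
        )
        details["sweep"] = {
            "candidates": sweep.candidates.tolist(),
            "p_values": sweep.p_values.tolist(),
            "group_sizes": sweep.group_sizes.tolist(),
        }
        row.update(
            best_threshold=sweep.selected_threshold if sweep.significant else np.nan,
            logrank_p=sweep.selected_p if sweep.significant else float(np.min(sweep.p_values)) if len(sweep.p_values) else np.nan,
            n_low=int(sweep.group_sizes[np.argmin(sweep.p_values)][0]) if len(sweep.p_values) else 0,
            n_high=int(sweep.group_sizes[np.argmin(sweep.p_values)][1]) if len(sweep.p_values) else 0,
            median_diff_months=sweep.median_diff,
            significant=sweep.significant,
        )
        indicator = None
    # hazard ratio: for a dichotomized variable use the indicator group, else
    # the continuous covariate (reported per unit increase)
    if indicator is not None:
        cox = cox_univariate(records, indicator)
        key = indicator
    elif row["significant"]:
        cut = row["best_threshold"]
        dich = [
            CohortRecord(r.lesion_id, {**r.covariates, "_above": float(r.covariates[variable] > cut)},
                         r.time, r.event, r.patient_id)
            for r in records
        ]
        cox = cox_univariate(dich, "_above")
        key = "_above"
    else:
        cox = cox_univariate(records, variable)
        key = variable
    row.update(
        hr=cox.hazard_ratio[key],
        ci_low=cox.ci_lower[key],
        ci_high=cox.ci_upper[key],
        cox_p=cox.p[key],
    )
    return row, details


def run_biomarker_stage(covariates: pd.DataFrame, survival: pd.DataFrame, variables, config: BiomarkerConfig = BiomarkerConfig()):
    """Screen each variable as a recurrence biomarker and build the report.

    ``covariates`` has one row per lesion (see :func:`assemble_cohort`);
    ``survival`` carries ``lesion_id, time_months, event``.  Tables are
    joined on ``lesion_id`` and orphan ids on either side are reported.

    For each variable: log-rank threshold sweep (or the natural split for a
    binary variable), KM median difference between the resulting groups and
    a univariate Cox hazard ratio; finally a backward stepwise-Wald Cox
    model over the dichotomized significant variables.

    Returns ``(report_table, details)``.
    """
    records, orphans = _records_from_tables(covariates, survival, variables)
    if orphans["features_only"] or orphans["survival_only"]:
        logger.warning("unmatched lesion ids in join: %s", orphans)
    if len(records) < config.min_cohort_size:
        raise ValueError(
            f"cohort of {len(records)} lesions is too small for the biomarker battery "
            f"(minimum {config.min_cohort_size})"
        )
    rows, details = [], {"orphans": orphans, "variables": {}, "n": len(records)}
    for v in variables:
        try:
            row, det = _analyze_variable(records, v, config)
        except ValueError as exc:
            logger.warning("variable %s skipped: %s", v, exc)
            details["variables"][v] = {"error": str(exc)}
            continue
        rows.append(row)
        details["variables"][v] = det
    report = pd.DataFrame(rows)
    # multivariate stepwise over the dichotomized significant variables
    sig = [r for r in rows if r["significant"]]
    details["stepwise"] = None
    if len(sig) >= 2:
        columns = {}
        for r in sig:
            v, cut = r["variable"], r["best_threshold"]
            x = np.array([rec.covariates[v] for rec in records])
            columns[v] = x if np.isnan(cut) else (x > cut).astype(float)
        # exactly collinear dichotomizations (e.g. necrotic volume > 0 vs the
        # necrosis flag) make the information matrix singular; keep the first
        seen, kept = {}, []
        for v, x in columns.items():
            key = tuple(x)
            if key in seen:
                logger.info("dropping %s from stepwise model: identical to %s", v, seen[key])
                continue
            seen[key] = v
            kept.append(v)
        details["stepwise_dropped_duplicates"] = [v for v in columns if v not in kept]
        dich_records = [
            CohortRecord(rec.lesion_id, {v: float(columns[v][i]) for v in kept},
                         rec.time, rec.event, rec.patient_id)
            for i, rec in enumerate(records)
        ]
        try:
            step = cox_stepwise(dich_records, kept, config.removal_alpha) if len(kept) >= 2 else cox_univariate(dich_records, kept[0])
            details["stepwise"] = {
                "retained": step.covariates,
                "eliminated": step.eliminated,
                "hazard_ratio": step.hazard_ratio,
                "p": step.p,
            }
        except ValueError as exc:
            logger.warning("stepwise model failed: %s", exc)
            details["stepwise"] = {"error": str(exc)}
    return report, details


# ---------------------------------------------------------------------------
# one-command demonstration on packaged synthetics
# ---------------------------------------------------------------------------

def _sample_phantom(rng: np.random.Generator, radius: float, irregularity: float, core_fraction: float, seed: int):
    """Draw a valid random phantom; resample amplitudes until positivity holds."""
    for _ in range(50):
        pert = []
        for _ in range(4):
            l = int(rng.integers(2, 5))
            m = int(rng.integers(-l, l + 1))
            pert.append((l, m, float(rng.normal(0.0, irregularity))))
        try:
            return phantoms.PhantomSpec(
                base_radius=radius,
                perturbation=tuple(pert),
                core_radius_fraction=core_fraction,
                noise_sd=5.0,
                seed=seed,
            )
        except ValueError:
            irregularity *= 0.8
    raise RuntimeError("could not sample a valid phantom")


#: demo study conditions: a ~100-lesion cohort with one pre-treatment scan and
#: one first follow-up per lesion, voxel spacing in the clinical CE-T1w regime,
#: a planted volume-ratio and necrosis effect on the progression hazard, and a
#: planted null covariate.
DEMO_CONDITIONS = dict(
    n_lesions=100,
    spacing=(0.75, 0.75, 1.25),  # mm; pixel spacing ~0.5-1, slice ~1.3 typical
    radius_log_mean=np.log(0.8),  # cm; median pre-treatment radius 0.8 cm (~2 cm^3)
    radius_log_sd=0.3,
    irregularity_low=0.02,
    irregularity_high=0.10,
    necrosis_prevalence_pre=0.35,
    necrosis_prevalence_post=0.55,
    response_log_mean=np.log(0.55),  # median post/pre volume ratio ~0.55
    response_log_sd=0.55,
    post_amplitude_factor=1.25,  # irradiation makes surfaces more irregular
    baseline_hazard=0.05,  # 1/month
    beta_volume_ratio=0.9,  # log HR of volume_ratio > 0.5
    beta_necrosis=0.8,  # log HR of necrosis at first follow-up
    censoring_rate=0.02,  # 1/month
    max_followup=24.0,  # months, mirroring a two-year follow-up window
    segmentation_threshold=60.0,  # midway between background (20) and rim (100)
)


def run_demo(seed: int = 0, out_dir=None, n_lesions: int | None = None, config: BiomarkerConfig = BiomarkerConfig()):
    """Generate a synthetic lesion cohort, run the full pipeline, write a report.

    Returns a dict with the feature table, per-lesion cohort table, report
    table and details.  With ``out_dir`` set, writes ``features.csv``,
    ``cohort.csv``, ``report.csv``, ``report.txt``, ``details.json`` and
    KM / correlation figures under ``figures/``.
    """
    cond = dict(DEMO_CONDITIONS)
    if n_lesions is not None:
        cond["n_lesions"] = n_lesions
    rng = np.random.default_rng(seed)
    n = cond["n_lesions"]

    timepoints = []
    for i in range(n):
        radius = float(np.clip(rng.lognormal(cond["radius_log_mean"], cond["radius_log_sd"]), 0.4, 1.8))
        irr = float(rng.uniform(cond["irregularity_low"], cond["irregularity_high"]))
        core_pre = float(rng.uniform(0.25, 0.55)) if rng.random() < cond["necrosis_prevalence_pre"] else 0.0
        core_post = float(rng.uniform(0.25, 0.55)) if rng.random() < cond["necrosis_prevalence_post"] else 0.0
        vseed = int(rng.integers(0, 2**31 - 1))
        pre_spec = _sample_phantom(rng, radius, irr, core_pre, vseed)
        factor = float(np.clip(rng.lognormal(cond["response_log_mean"], cond["response_log_sd"]), 0.05, 3.0))
        series = phantoms.simulate_series(
            pre_spec, [1.0, factor], [-0.5, 3.0],
            amplitude_factors=[1.0, cond["post_amplitude_factor"]],
        )
        specs = []
        for k, (t, sp) in enumerate(series):
            core = core_pre if t < 0 else core_post
            try:
                sp = phantoms.PhantomSpec(
                    base_radius=sp.base_radius, perturbation=sp.perturbation,
                    core_radius_fraction=core, noise_sd=sp.noise_sd, seed=vseed + k,
                )
            except ValueError:
                sp = phantoms.PhantomSpec(
                    base_radius=sp.base_radius, perturbation=sp.perturbation,
                    core_radius_fraction=0.0, noise_sd=sp.noise_sd, seed=vseed + k,
                )
            specs.append((t, sp))
        for t, sp in specs:
            img = phantoms.voxelize(sp, cond["spacing"])
            timepoints.append((f"L{i:04d}", f"P{i:04d}", t, img))

    features, exclusions = run_feature_stage(timepoints, cond["segmentation_threshold"])
    cohort = assemble_cohort(features, config.tvn)
    cohort["noise"] = rng.normal(0.0, 1.0, len(cohort))  # planted null covariate

    # planted hazard structure on the measured features
    lp = (
        cond["beta_volume_ratio"] * (cohort["volume_ratio"].to_numpy() > 0.5)
        + cond["beta_necrosis"] * cohort["has_necrosis_post"].to_numpy()
    )
    hazard = cond["baseline_hazard"] * np.exp(lp)
    event_time = rng.exponential(1.0 / hazard)
    censor = np.minimum(rng.exponential(1.0 / cond["censoring_rate"], len(cohort)), cond["max_followup"])
    survival = pd.DataFrame(
        {
            "lesion_id": cohort["lesion_id"],
            "time_months": np.minimum(event_time, censor),
            "event": (event_time <= censor).astype(int),
        }
    )

    variables = [
        "total_volume_pre",
        "surface_regularity_pre",
        "total_volume_post",
        "necrotic_volume_post",
        "has_necrosis_post",
        "surface_regularity_post",
        "rim_width_post",
        "volume_ratio",
        "tvn",
        "noise",
    ]
    report, details = run_biomarker_stage(cohort, survival, variables, config)
    details["exclusions"] = exclusions
    details["conditions"] = {k: (list(v) if isinstance(v, tuple) else v) for k, v in cond.items()}
    details["seed"] = seed
    details["progression_criterion"] = config.progression.describe()

    result = {"features": features, "cohort": cohort, "survival": survival, "report": report, "details": details}
    if out_dir is not None:
        _write_demo_outputs(result, out_dir, config)
    return result


def _format_report_text(report: pd.DataFrame, details: dict) -> str:
    lines = [
        f"Biomarker screening report (n = {details['n']} lesions)",
        "",
        f"{'variable':<24}{'best thr':>10}{'median diff':>13}{'log-rank p':>12}{'HR':>8}{'95% CI':>18}",
    ]
    for _, r in report.iterrows():
        thr = "-" if pd.isna(r["best_threshold"]) else f"{r['best_threshold']:.3g}"
        md = "-" if r["median_diff_months"] is None or pd.isna(r["median_diff_months"]) else f"{r['median_diff_months']:.1f}"
        lines.append(
            f"{r['variable']:<24}{thr:>10}{md:>13}{r['logrank_p']:>12.4g}{r['hr']:>8.3g}"
            f"{'(' + format(r['ci_low'], '.3g') + ', ' + format(r['ci_high'], '.3g') + ')':>18}"
        )
    step = details.get("stepwise")
    lines.append("")
    if isinstance(step, dict) and "retained" in step:
        lines.append(f"stepwise Cox retained: {step['retained']} (eliminated: {step['eliminated']})")
    return "\n".join(lines) + "\n"


def _write_demo_outputs(result: dict, out_dir, config: BiomarkerConfig) -> None:
    import pathlib

    out = pathlib.Path(out_dir)
    (out / "figures").mkdir(parents=True, exist_ok=True)
    result["features"].to_csv(out / "features.csv", index=False, float_format="%.6g")
    result["cohort"].to_csv(out / "cohort.csv", index=False, float_format="%.6g")
    result["survival"].to_csv(out / "survival.csv", index=False, float_format="%.6g")
    result["report"].to_csv(out / "report.csv", index=False, float_format="%.6g")
    (out / "report.txt").write_text(_format_report_text(result["report"], result["details"]))
    with open(out / "details.json", "w") as fh:
        json.dump(result["details"], fh, indent=2, default=float)
    _demo_figures(result, out / "figures", config)


def _demo_figures(result: dict, fig_dir, config: BiomarkerConfig) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from lifelines import KaplanMeierFitter

    cohort, survival, report = result["cohort"], result["survival"], result["report"]
    merged = cohort.merge(survival, on="lesion_id")

    # KM plots for each significant dichotomized variable
    for _, r in report[report["significant"]].iterrows():
        v = r["variable"]
        cut = r["best_threshold"]
        x = merged[v].to_numpy()
        mask = x > (cut if not pd.isna(cut) else np.unique(x)[:2].mean())
        fig, ax = plt.subplots(figsize=(5, 4))
        for sel, lbl in ((~mask, "low"), (mask, "high")):
            sub = merged[sel]
            kmf = KaplanMeierFitter()
            kmf.fit(sub["time_months"], sub["event"], label=f"{v} {lbl} (n={sel.sum()})")
            kmf.plot_survival_function(ax=ax)
        ax.set_xlabel("months since SRT onset")
        ax.set_ylabel("progression-free survival")
        ax.set_title(f"{v}: log-rank p = {r['logrank_p']:.3g}")
        fig.tight_layout()
        fig.savefig(fig_dir / f"km_{v}.png", dpi=110)
        plt.close(fig)

    # Spearman correlation matrix across the analyzed variables
    from .survival import spearman

    variables = [v for v in report["variable"] if merged[v].nunique() > 2]
    mat = np.eye(len(variables))
    for i, a in enumerate(variables):
        for j, b in enumerate(variables):
            if i < j:
                rho, _ = spearman(merged[a], merged[b])
                mat[i, j] = mat[j, i] = rho
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(mat, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(variables)), variables, rotation=45, ha="right", fontsize=7)
    ax.set_yticks(range(len(variables)), variables, fontsize=7)
    for i in range(len(variables)):
        for j in range(len(variables)):
            ax.text(j, i, f"{mat[i, j]:.2f}", ha="center", va="center", fontsize=6)
    fig.colorbar(im, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(fig_dir / "correlation_matrix.png", dpi=110)
    plt.close(fig)
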