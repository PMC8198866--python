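"""End-to-end pipeline: simulate -> preprocess -> train -> classify -> compare.

Ties the stages together into reproducible runs on simulated cohorts:
a development cohort (default n = 38) trains the activPAL+ energy-
expenditure classifier and the ActiGraph+ posture model; an independent
comparison cohort (default n = 62) is then classified with all five
methods and the four single-sensor methods are compared to the POPAI
reference with Bland-Altman statistics, for total sedentary time and for
time accumulated in bouts.

Participants are streamed (simulated, processed, discarded) so cohort
size is not limited by raw-signal memory. Every artifact directory gets
a manifest with the configuration hash and package versions.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from datetime import timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import classification as cl
from . import comparison as cmp
from . import intervals as iv
from . import preprocessing as pp
from . import training as tr
from .config import RunConfig
from .errors import ConfigurationError
from .features import REGISTRY_VERSION, rank_features_rf
from .sensor_io import CountsSeries, EventTimeline, RawRecording
from .synthetic import BehaviourProfile, SimulatedParticipant, iter_cohort

__all__ = [
    "REDUCED_FEATURE_SUBSET",
    "PreprocessedParticipant",
    "preprocess_participant",
    "run_development",
    "run_comparison",
    "run_pipeline",
    "DevelopmentResult",
    "ComparisonResult",
]

#: A small, documented subset of Feature Set 1 for desk-scale runs: the
#: movement-intensity and orientation statistics that carry most of the
#: inactive-vs-active sitting signal. The full 563-feature registry
#: remains the default at study scale (``feature_subset=None``).
REDUCED_FEATURE_SUBSET: tuple[str, ...] = (
    "vm__std",
    "vm__rolling_std_mean",
    "vm__activity_fraction",
    "vm__range",
    "vm__p90",
    "vm__iqr",
    "x__std",
    "x__mean",
    "x__jerk_mean_abs",
    "z__mean",
    "z__std",
    "x__autocorr_lag1",
)

METHODS = ("POPAI", "activPAL", "activPAL+", "ActiGraph", "ActiGraph+")
QUANTITIES = ("sedentary_minutes", "sedentary_bout10_minutes", "sedentary_bout30_minutes")


# ---------------------------------------------------------------------------
# per-participant preprocessing
# ---------------------------------------------------------------------------


@dataclass
class PreprocessedParticipant:
    """One participant after synchronization and wear-time detection."""

    participant: str
    timeline: EventTimeline
    counts: CountsSeries  # synchronized
    raw_thigh: RawRecording
    raw_waist: RawRecording  # synchronized
    bedtime: pp.BedtimeResult
    lag: pp.LagEstimate
    nonwear: list
    wear_mask: pp.WearMask
    valid_days: set


def preprocess_participant(sim: SimulatedParticipant, cfg: RunConfig) -> PreprocessedParticipant:
    """The three pre-processing steps for one recording."""
    bedtime = pp.exclude_bedtime(sim.timeline)
    lag = pp.estimate_lag(sim.raw_thigh, sim.raw_waist, max_lag_s=cfg.lag_max_s)
    counts, raw_waist = pp.synchronize(sim.counts, sim.raw_waist, lag.lag_s)
    nonwear = pp.detect_actigraph_nonwear(
        sim.timeline,
        raw_waist=raw_waist,
        min_const_minutes=cfg.nonwear_min_const_minutes,
        movement_qualifies=cfg.nonwear_movement_qualifies,
    )
    mask = pp.build_wear_mask(sim.timeline, bedtime.intervals, nonwear)
    rules = pp.ValidDayRules(
        min_steps=cfg.min_steps,
        min_waking_hours=cfg.min_waking_hours,
        max_single_posture_fraction=cfg.max_single_posture_fraction,
    )
    valid = pp.detect_valid_days(sim.timeline, bedtime.intervals, rules)
    return PreprocessedParticipant(
        participant=sim.participant,
        timeline=sim.timeline,
        counts=counts,
        raw_thigh=sim.raw_thigh,
        raw_waist=raw_waist,
        bedtime=bedtime,
        lag=lag,
        nonwear=nonwear,
        wear_mask=mask,
        valid_days=valid,
    )


def _feature_subset(cfg: RunConfig) -> tuple[str, ...] | None:
    return tuple(cfg.feature_subset) if cfg.feature_subset is not None else None


# ---------------------------------------------------------------------------
# classification + summarization of one participant
# ---------------------------------------------------------------------------


def classify_participant(
    prep: PreprocessedParticipant,
    cfg: RunConfig,
    ee_model: tr.TrainedAlgorithm | None = None,
    posture_model: tr.PostureModel | None = None,
    methods: Sequence[str] = METHODS,
) -> dict[str, cl.ClassifiedTimeline]:
    bed = prep.bedtime.intervals
    nw = prep.nonwear
    out: dict[str, cl.ClassifiedTimeline] = {}
    if "POPAI" in methods:
        out["POPAI"] = cl.classify_popai(
            prep.timeline, prep.counts, cfg.cutpoint_inactive_cpm,
            cfg.cutpoint_axis, bedtime=bed, nonwear=nw,
        )
    if "activPAL" in methods:
        out["activPAL"] = cl.classify_activpal(prep.timeline, bedtime=bed, nonwear=nw)
    if "activPAL+" in methods:
        if ee_model is None:
            raise ConfigurationError("activPAL+ needs a trained energy-expenditure model")
        out["activPAL+"] = cl.classify_activpal_plus(
            prep.timeline, prep.raw_thigh, ee_model, bedtime=bed, nonwear=nw
        )
    if "ActiGraph" in methods:
        out["ActiGraph"] = cl.classify_actigraph(
            prep.counts, cfg.cutpoint_sedentary_cpm, cfg.cutpoint_axis,
            bedtime=bed, nonwear=nw,
        )
    if "ActiGraph+" in methods:
        if posture_model is None:
            raise ConfigurationError("ActiGraph+ needs a posture model")
        out["ActiGraph+"] = cl.classify_actigraph_plus(
            prep.counts, posture_model, prep.raw_waist,
            cutpoint=cfg.cutpoint_inactive_cpm, axis=cfg.cutpoint_axis,
            bedtime=bed, nonwear=nw,
        )
    return out


def participant_daily_table(
    prep: PreprocessedParticipant,
    classified: Mapping[str, cl.ClassifiedTimeline],
    cfg: RunConfig,
) -> pd.DataFrame:
    """Per-day summaries of every method, restricted to valid days."""
    epoch = prep.timeline.recording_epoch
    valid_dates = {
        (epoch + timedelta(seconds=sum(pp.day_bounds(epoch, d)) / 2)).date().isoformat()
        for d in prep.valid_days
    }
    rows = []
    for method, ct in classified.items():
        for s in cl.summarize_days(ct, prep.wear_mask, prep.participant, cfg.bout_thresholds_min):
            if s.date in valid_dates:
                rows.append(
                    {
                        "participant": s.participant,
                        "method": method,
                        "date": s.date,
                        "wear_minutes": s.wear_minutes,
                        "sedentary_minutes": s.sedentary_minutes,
                        "sedentary_bout10_minutes": s.sedentary_bout10_minutes,
                        "sedentary_bout30_minutes": s.sedentary_bout30_minutes,
                        "sedentary_pct_of_wear": s.sedentary_pct_of_wear,
                    }
                )
    return pd.DataFrame(rows)


def participant_means_table(daily: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Average daily values per participant and method over days with
    at least the minimum wear (default 10 h)."""
    if daily.empty:
        return pd.DataFrame()
    ok = daily[daily["wear_minutes"] >= cfg.min_wear_hours_per_day * 60.0]
    return (
        ok.groupby(["participant", "method"], as_index=False)[
            ["wear_minutes", *QUANTITIES, "sedentary_pct_of_wear"]
        ].mean()
    )


# ---------------------------------------------------------------------------
# development stage
# ---------------------------------------------------------------------------


@dataclass
class DevelopmentResult:
    ee_model: tr.TrainedAlgorithm
    posture_model: tr.PostureModel
    trace: tr.SelectionTrace
    candidates: list[tr.TrainedAlgorithm]
    chosen_index: int
    ranked_features: list[str]


def _training_rows_for(
    prep: PreprocessedParticipant, cfg: RunConfig, rng: np.random.Generator
) -> list[tr.TrainingMinute]:
    minutes = tr.extract_training_minutes(
        prep.timeline,
        prep.counts,
        cutpoint=cfg.cutpoint_inactive_cpm,
        axis=cfg.cutpoint_axis,
        wear=prep.wear_mask.joint_wear(),
        participant=prep.participant,
    )
    cap = cfg.max_training_minutes_per_participant
    if cap is not None and len(minutes) > cap:
        keep = sorted(rng.choice(len(minutes), cap, replace=False))
        minutes = [minutes[i] for i in keep]
    return minutes


def _posture_rows_for(
    prep: PreprocessedParticipant, cfg: RunConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, list[str]]:
    wear = prep.wear_mask.joint_wear()
    starts = [
        t0
        for t0, t1 in ((60.0 * m, 60.0 * (m + 1)) for m in range(int(prep.counts.duration // 60)))
        if iv.total_duration(iv.clip(wear, t0, t1)) >= 60.0 - 1e-6
    ]
    cap = cfg.posture_rows_per_participant
    if len(starts) > cap:
        starts = [starts[i] for i in sorted(rng.choice(len(starts), cap, replace=False))]
    X = tr.minute_feature_table(prep.raw_waist, starts, tr.POSTURE_FEATURES)
    y = cl.minute_posture_labels(prep.timeline, starts)
    return X, y


def run_development(
    cfg: RunConfig,
    profile: BehaviourProfile | None = None,
    preps: Iterable[PreprocessedParticipant] | None = None,
) -> DevelopmentResult:
    """Train the "+" algorithms on the development cohort.

    With the full registry, one candidate per feature set (1, 2, 3) is
    trained and the most accurate/precise against POPAI on the
    development cohort is selected; with a configured feature subset a
    single candidate is trained from it.
    """
    profile = profile or BehaviourProfile()
    rng = np.random.default_rng(cfg.seed)
    subset = _feature_subset(cfg)
    set_plans = [(cfg.feature_set, subset)] if subset is not None else [(1, None), (2, None), (3, None)]

    def dev_source():
        if preps is not None:
            return iter(preps)
        return (
            preprocess_participant(s, cfg)
            for s in iter_cohort(profile, cfg.n_development, cfg.n_days, cfg.seed, prefix="D")
        )

    # stream the cohort once: per-plan training features + posture rows
    parts: list[list[tr.TrainingDataset]] = [[] for _ in set_plans]
    posture_X: list[pd.DataFrame] = []
    posture_y: list[str] = []
    for prep in dev_source():
        minutes = _training_rows_for(prep, cfg, rng)
        for i, (set_id, sub) in enumerate(set_plans):
            parts[i].append(
                tr.assemble_dataset([(minutes, prep.raw_thigh)], set_id=set_id, subset=sub)
            )
        X, y = _posture_rows_for(prep, cfg, rng)
        posture_X.append(X)
        posture_y.extend(y)

    posture_model = tr.fit_posture_model(
        pd.concat(posture_X, ignore_index=True), posture_y, seed=cfg.seed
    )

    candidates: list[tr.TrainedAlgorithm] = []
    traces: list[tr.SelectionTrace] = []
    ranked_all: list[str] = []
    for (set_id, sub), per_part in zip(set_plans, parts):
        ds = tr.TrainingDataset(
            X=pd.concat([p.X for p in per_part], ignore_index=True),
            y=np.concatenate([p.y for p in per_part]),
            groups=np.concatenate([p.groups for p in per_part]),
            provenance=pd.concat([p.provenance for p in per_part], ignore_index=True),
        )
        n_cols = ds.X.shape[1]
        n_keep = min(cfg.n_keep, n_cols)
        # the 52 cross-recurrence features skip the forest screen (already few)
        if set_id == 3 and sub is None:
            ranked = list(ds.X.columns)
        else:
            ranked = rank_features_rf(ds.X, ds.y, n_keep=n_keep, seed=cfg.seed)
        trace = tr.forward_feature_selection(
            ds, ranked, patience=cfg.patience, seed=cfg.seed, budget=cfg.search_budget
        )
        candidates.append(
            tr.TrainedAlgorithm(
                name=f"activPAL+ (set {set_id})",
                model=trace.model,
                features=tuple(trace.selected_features),
                set_id=set_id,
                registry_version=REGISTRY_VERSION,
                loso_score=trace.best_score,
            )
        )
        traces.append(trace)
        if not ranked_all:
            ranked_all = ranked

    if len(candidates) == 1:
        chosen = 0
    else:
        ref, ests = _candidate_daily_estimates(dev_source(), cfg, candidates)
        chosen = tr.select_algorithm(candidates, ests, ref)
    return DevelopmentResult(
        ee_model=candidates[chosen],
        posture_model=posture_model,
        trace=traces[chosen],
        candidates=candidates,
        chosen_index=chosen,
        ranked_features=ranked_all,
    )


def _candidate_daily_estimates(
    preps: Iterable[PreprocessedParticipant],
    cfg: RunConfig,
    candidates: Sequence[tr.TrainedAlgorithm],
):
    """POPAI reference and per-candidate activPAL+ participant means on
    the development cohort (the algorithm-selection comparison)."""
    ref_vals, est_vals = [], [[] for _ in candidates]
    for prep in preps:
        classified = classify_participant(prep, cfg, methods=("POPAI",))
        tables = {"POPAI": classified["POPAI"]}
        for i, cand in enumerate(candidates):
            tables[f"cand{i}"] = cl.classify_activpal_plus(
                prep.timeline, prep.raw_thigh, cand,
                bedtime=prep.bedtime.intervals, nonwear=prep.nonwear,
            )
        daily = participant_daily_table(prep, tables, cfg)
        means = participant_means_table(daily, cfg)
        if means.empty:
            continue
        by = means.set_index("method")["sedentary_minutes"]
        if "POPAI" not in by.index:
            continue
        ref_vals.append(by["POPAI"])
        for i in range(len(candidates)):
            est_vals[i].append(by.get(f"cand{i}", np.nan))
    return np.asarray(ref_vals), [np.asarray(v) for v in est_vals]


# ---------------------------------------------------------------------------
# comparison stage
# ---------------------------------------------------------------------------


@dataclass
class ComparisonResult:
    daily: pd.DataFrame  # per participant-day-method
    means: pd.DataFrame  # per participant-method
    agreement: dict  # quantity -> method -> AgreementStats
    interval_agreement: list = field(default_factory=list)


def run_comparison(
    cfg: RunConfig,
    ee_model: tr.TrainedAlgorithm,
    posture_model: tr.PostureModel,
    profile: BehaviourProfile | None = None,
    preps: Iterable[PreprocessedParticipant] | None = None,
    with_intervals: bool = False,
) -> ComparisonResult:
    """Classify the comparison cohort with all five methods and compare
    the single-sensor methods to POPAI."""
    profile = profile or BehaviourProfile()
    daily_frames = []
    interval_method: dict[str, dict[str, cl.ClassifiedTimeline]] = {m: {} for m in METHODS}
    masks: dict[str, pp.WearMask] = {}
    source = preps if preps is not None else (
        preprocess_participant(s, cfg)
        for s in iter_cohort(profile, cfg.n_comparison, cfg.n_days, cfg.seed + 1, prefix="C")
    )
    for prep in source:
        classified = classify_participant(prep, cfg, ee_model, posture_model)
        daily_frames.append(participant_daily_table(prep, classified, cfg))
        if with_intervals:
            for m, ct in classified.items():
                interval_method[m][prep.participant] = ct
            masks[prep.participant] = prep.wear_mask
    daily = pd.concat(daily_frames, ignore_index=True)
    means = participant_means_table(daily, cfg)

    agreement: dict[str, dict[str, cmp.AgreementStats]] = {}
    wide = {
        q: means.pivot(index="participant", columns="method", values=q)
        for q in QUANTITIES
    }
    for q, tbl in wide.items():
        tbl = tbl.dropna()
        agreement[q] = {}
        for method in METHODS:
            if method == "POPAI" or method not in tbl.columns:
                continue
            agreement[q][method] = cmp.bland_altman(
                tbl[method].to_numpy(), tbl["POPAI"].to_numpy()
            )

    intervals: list = []
    if with_intervals:
        for method in METHODS:
            if method == "POPAI":
                continue
            intervals.extend(
                (method, ia)
                for ia in cmp.daytime_interval_analysis(
                    interval_method[method],
                    interval_method["POPAI"],
                    masks,
                    cohort_size=cfg.n_comparison,
                    bin_minutes=cfg.interval_bin_minutes,
                    min_participation=cfg.interval_min_participation,
                )
            )
    return ComparisonResult(daily=daily, means=means, agreement=agreement, interval_agreement=intervals)


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------


def save_models(
    ee_model: tr.TrainedAlgorithm, posture_model: tr.PostureModel, path: str | Path
) -> None:
    """Persist the trained models (joblib payload + JSON manifest)."""
    import joblib

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    joblib.dump({"ee_model": ee_model, "posture_model": posture_model}, path / "models.joblib")
    manifest = {
        "registry_version": REGISTRY_VERSION,
        "ee_features": list(ee_model.features),
        "ee_set_id": ee_model.set_id,
        "ee_loso_score": ee_model.loso_score,
        "posture_features": list(posture_model.features),
    }
    (path / "models.json").write_text(json.dumps(manifest, indent=2))


def load_models(path: str | Path) -> tuple[tr.TrainedAlgorithm, tr.PostureModel]:
    import joblib

    payload = joblib.load(Path(path) / "models.joblib")
    return payload["ee_model"], payload["posture_model"]


# ---------------------------------------------------------------------------
# full run with artifacts
# ---------------------------------------------------------------------------


def _agreement_record(stats: cmp.AgreementStats) -> dict:
    return {
        "n": stats.n,
        "bias": stats.bias,
        "bias_se": stats.bias_se,
        "loa_lower": stats.loa_lower,
        "loa_upper": stats.loa_upper,
        "loa_se": stats.loa_se,
        "relative_bias_pct": stats.relative_bias_pct,
        "rmse": stats.rmse,
        "pearson_r": stats.pearson_r,
        "pearson_ci": list(stats.pearson_ci),
    }


def run_pipeline(
    cfg: RunConfig,
    outdir: str | Path,
    profile: BehaviourProfile | None = None,
) -> dict:
    """Run the full pipeline and write artifacts + manifest to ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    profile = profile or BehaviourProfile()

    dev = run_development(cfg, profile)
    comp = run_comparison(cfg, dev.ee_model, dev.posture_model, profile)

    save_models(dev.ee_model, dev.posture_model, out / "models")
    comp.daily.to_csv(out / "daily_summaries.csv", index=False)
    comp.means.to_csv(out / "participant_means.csv", index=False)
    trace_rows = [
        {
            "iteration": r.iteration,
            "feature_added": r.feature_added,
            "cross_validity": r.cross_validity,
            "method": r.spec.method,
            "criterion": r.spec.criterion,
            "n_trees": r.spec.n_trees,
            "max_splits": r.spec.max_splits,
            "min_leaf": r.spec.min_leaf,
            "learning_rate": r.spec.learning_rate,
        }
        for r in dev.trace.records
    ]
    pd.DataFrame(trace_rows).to_csv(out / "selection_trace.csv", index=False)
    agreement_json = {
        q: {m: _agreement_record(s) for m, s in per_method.items()}
        for q, per_method in comp.agreement.items()
    }
    (out / "agreement.json").write_text(json.dumps(agreement_json, indent=2))
    manifest = {
        "config_hash": cfg.config_hash(),
        "config": cfg.to_yaml(),
        "registry_version": REGISTRY_VERSION,
        "python": platform.python_version(),
        "selected_features": list(dev.ee_model.features),
        "loso_cross_validity": dev.ee_model.loso_score,
        "artifacts": [
            "daily_summaries.csv",
            "participant_means.csv",
            "selection_trace.csv",
            "agreement.json",
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"development": dev, "comparison": comp, "manifest": manifest}
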