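"""Machine-learning framework for the "+" algorithms.

Builds the energy-expenditure classifier that upgrades the thigh posture
sensor (activPAL+) and the posture classifier that upgrades the waist
movement sensor (ActiGraph+):

* training minutes — from every sitting event of at least 1 min, as many
  integer minutes as fit, centre-aligned within the event (from a 5.5-min
  event, the middle 5 minutes); each labelled inactive/active by the
  synchronized waist counts against a 75 counts-per-minute cut-point;
* cross-validity — mean of sensitivity and specificity under
  leave-one-subject-out (LOSO) cross-validation: no row of a participant
  is ever in its own training fold;
* iterative feature inclusion into tree ensembles with a randomized
  hyperparameter search (learning method boosting/bagging, split
  criterion, tree count, split cap, leaf minimum, learning rate), stopped
  once the running maximum is not beaten for 10 further features;
* algorithm selection — among trained candidates, the one with the lowest
  Bland-Altman bias against the dual-sensor reference, ties broken by the
  narrower limits of agreement, then fewer features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    RandomForestClassifier,
)
from sklearn.tree import DecisionTreeClassifier

from . import intervals as iv
from .errors import ConfigurationError, UndefinedScoreError
from .features import REGISTRY_VERSION, MinuteWindow, extract_features
from .sensor_io import (
    CountsSeries,
    EventTimeline,
    Posture,
    RawRecording,
    counts_in_span,
)

__all__ = [
    "INACTIVE",
    "ACTIVE",
    "TrainingMinute",
    "TrainingDataset",
    "EnsembleSpec",
    "SearchSpace",
    "SelectionRecord",
    "SelectionTrace",
    "TrainedAlgorithm",
    "PostureModel",
    "extract_training_minutes",
    "assemble_dataset",
    "cross_validity",
    "loso_evaluate",
    "optimize_ensemble",
    "forward_feature_selection",
    "select_algorithm",
    "fit_posture_model",
]

INACTIVE, ACTIVE = 0, 1

#: waist-signal features the default posture model consumes (time-domain
#: orientation and movement summaries of a 1-min window)
POSTURE_FEATURES = (
    "x__mean",
    "y__mean",
    "z__mean",
    "vm__std",
    "vm__rolling_std_mean",
    "vm__activity_fraction",
)

#: features with a vectorized whole-recording fast path (values identical
#: to per-window extraction)
FAST_MINUTE_FEATURES = frozenset(
    f"{ch}__{st}"
    for ch in ("x", "y", "z", "vm")
    for st in ("mean", "std", "rolling_std_mean", "rolling_std_max", "activity_fraction")
)


# ---------------------------------------------------------------------------
# training-minute extraction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainingMinute:
    """One 60-s training window traceable to its source sitting event."""

    participant: str
    event_index: int
    window_start: float  # seconds since recording start
    label: int  # INACTIVE (counts below cut-point) or ACTIVE


def extract_training_minutes(
    timeline: EventTimeline,
    counts: CountsSeries,
    cutpoint: float = 75.0,
    axis: str = "axis1",
    wear: Sequence[tuple[float, float]] | None = None,
    participant: str = "P",
    inactive_inclusive: bool = False,
) -> list[TrainingMinute]:
    """Centre-aligned integer training minutes from sitting events.

    A sitting event of duration ``d`` >= 60 s yields ``floor(d/60)``
    abutting 60-s windows offset by ``(d - 60*k)/2`` from the event start
    (the *middle* minutes); shorter events yield none. Each window is
    labelled INACTIVE iff its synchronized counts are below the cut-point
    (``inactive_inclusive=True`` switches the boundary to <=). Windows not
    fully inside the wear mask are dropped.
    """
    out: list[TrainingMinute] = []
    for idx, ev in enumerate(timeline.events):
        if ev.posture is not Posture.SIT or ev.duration < 60.0:
            continue
        k = int(ev.duration // 60.0)
        offset = (ev.duration - 60.0 * k) / 2.0
        for i in range(k):
            w0 = ev.start + offset + 60.0 * i
            if wear is not None:
                inside = iv.total_duration(iv.clip(wear, w0, w0 + 60.0))
                if inside < 60.0 - 1e-6:
                    continue
            c = counts_in_span(counts, w0, w0 + 60.0, axis)
            inactive = c <= cutpoint if inactive_inclusive else c < cutpoint
            out.append(
                TrainingMinute(participant, idx, w0, INACTIVE if inactive else ACTIVE)
            )
    return out


@dataclass
class TrainingDataset:
    """Feature matrix with labels, participant groups and provenance."""

    X: pd.DataFrame
    y: np.ndarray
    groups: np.ndarray
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if not (len(self.X) == len(self.y) == len(self.groups)):
            raise ValueError("X, y and groups must have equal length")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def participants(self) -> list[str]:
        return sorted(set(self.groups))


def assemble_dataset(
    minutes_by_raw: Sequence[tuple[Sequence[TrainingMinute], RawRecording]],
    set_id: int = 1,
    subset: Sequence[str] | None = None,
) -> TrainingDataset:
    """Extract window features for training minutes of many participants."""
    rows, labels, groups, prov = [], [], [], []
    for minutes, raw in minutes_by_raw:
        for tm in minutes:
            win = MinuteWindow.from_raw(raw, tm.window_start)
            rows.append(extract_features(win, set_id=set_id, subset=subset))
            labels.append(tm.label)
            groups.append(tm.participant)
            prov.append(
                {
                    "participant": tm.participant,
                    "event_index": tm.event_index,
                    "window_start": tm.window_start,
                }
            )
    return TrainingDataset(
        X=pd.DataFrame(rows),
        y=np.asarray(labels, dtype=int),
        groups=np.asarray(groups, dtype=object),
        provenance=pd.DataFrame(prov),
    )


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

_CRITERION_MAP = {
    # 'twoing' has no scikit-learn counterpart; gini is the closest
    # impurity and is used as its stand-in (documented approximation).
    "gini": "gini",
    "deviance": "log_loss",
    "twoing": "gini",
}


@dataclass(frozen=True)
class EnsembleSpec:
    """Hyperparameters of a decision-tree ensemble."""

    method: str = "bagging"  # 'bagging' | 'boosting'
    criterion: str = "gini"  # 'gini' | 'deviance' | 'twoing'
    n_trees: int = 30
    max_splits: int = 20
    min_leaf: int = 1
    learning_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.method not in ("bagging", "boosting"):
            raise ConfigurationError(f"unknown method {self.method!r}")
        if self.criterion not in _CRITERION_MAP:
            raise ConfigurationError(f"unknown criterion {self.criterion!r}")
        if self.n_trees < 1 or self.min_leaf < 1 or not 0 < self.learning_rate <= 1:
            raise ConfigurationError("invalid ensemble spec")

    def to_estimator(self, seed: int = 0):
        tree = DecisionTreeClassifier(
            criterion=_CRITERION_MAP[self.criterion],
            max_leaf_nodes=self.max_splits + 1,
            min_samples_leaf=self.min_leaf,
            random_state=seed,
        )
        if self.method == "bagging":
            return BaggingClassifier(
                estimator=tree, n_estimators=self.n_trees, random_state=seed
            )
        return AdaBoostClassifier(
            estimator=tree,
            n_estimators=self.n_trees,
            learning_rate=self.learning_rate,
            random_state=seed,
        )


@dataclass(frozen=True)
class SearchSpace:
    """Sampling ranges of the randomized hyperparameter search."""

    methods: tuple[str, ...] = ("bagging", "boosting")
    criteria: tuple[str, ...] = ("gini", "deviance", "twoing")
    n_trees: tuple[int, int] = (10, 120)
    max_splits: tuple[int, int] = (2, 64)
    min_leaf: tuple[int, int] = (1, 20)
    learning_rate: tuple[float, float] = (0.05, 1.0)

    def sample(self, rng: np.random.Generator) -> EnsembleSpec:
        def log_int(lo, hi):
            return int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))

        return EnsembleSpec(
            method=str(rng.choice(self.methods)),
            criterion=str(rng.choice(self.criteria)),
            n_trees=log_int(*self.n_trees),
            max_splits=log_int(*self.max_splits),
            min_leaf=int(rng.integers(self.min_leaf[0], self.min_leaf[1] + 1)),
            learning_rate=float(rng.uniform(*self.learning_rate)),
        )


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def cross_validity(y_true, y_pred) -> float:
    """Mean of sensitivity and specificity (balanced accuracy)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == ACTIVE
    neg = y_true == INACTIVE
    if not pos.any() or not neg.any():
        raise UndefinedScoreError("both classes must be present in the labels")
    sens = float(np.mean(y_pred[pos] == ACTIVE))
    spec = float(np.mean(y_pred[neg] == INACTIVE))
    return (sens + spec) / 2.0


def _fit_safely(spec: EnsembleSpec, X: np.ndarray, y: np.ndarray, seed: int):
    """Fit the spec's ensemble; if boosting aborts (base learner worse
    than random on this fold), fall back to a majority-class predictor so
    the spec simply scores poorly instead of crashing the search."""
    model = spec.to_estimator(seed)
    try:
        model.fit(X, y)
        return model
    except ValueError:
        from sklearn.dummy import DummyClassifier

        dummy = DummyClassifier(strategy="most_frequent")
        dummy.fit(X, y)
        return dummy


def loso_evaluate(
    dataset: TrainingDataset,
    features: Sequence[str],
    spec: EnsembleSpec,
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Leave-one-subject-out evaluation of one feature subset + spec.

    For each participant a model is trained on everyone else and applied
    to the held-out rows; the score is the cross-validity of the pooled
    held-out predictions. Participants whose own rows contain a single
    class still receive predictions and contribute to the pooled score.
    """
    parts = dataset.participants
    if len(parts) < 2:
        raise ConfigurationError("LOSO needs at least two participants")
    Xall = dataset.X[list(features)].to_numpy()
    preds = np.empty(len(dataset), dtype=int)
    for p in parts:
        held = dataset.groups == p
        train = ~held
        y_tr = dataset.y[train]
        classes = np.unique(y_tr)
        if len(classes) < 2:
            preds[held] = classes[0]
            continue
        model = _fit_safely(spec, Xall[train], y_tr, seed)
        preds[held] = model.predict(Xall[held])
    score = cross_validity(dataset.y, preds)
    out = pd.DataFrame(
        {"participant": dataset.groups, "y_true": dataset.y, "y_pred": preds}
    )
    return score, out


# ---------------------------------------------------------------------------
# hyperparameter optimization
# ---------------------------------------------------------------------------


@dataclass
class OptimizeResult:
    spec: EnsembleSpec
    model: object  # fitted on the full dataset
    score: float  # LOSO cross-validity of the winning spec


def optimize_ensemble(
    dataset: TrainingDataset,
    features: Sequence[str],
    budget: int = 30,
    seed: int = 0,
    space: SearchSpace = SearchSpace(),
) -> OptimizeResult:
    """Seeded randomized search over the ensemble space, LOSO-scored.

    Ties are broken in favour of fewer trees, then a smaller split cap, so
    the selected spec is deterministic for a given seed stream.
    """
    if budget < 1:
        raise ConfigurationError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    best: tuple[float, int, int] | None = None
    best_spec: EnsembleSpec | None = None
    for _ in range(budget):
        spec = space.sample(rng)
        score, _ = loso_evaluate(dataset, features, spec, seed=seed)
        key = (-score, spec.n_trees, spec.max_splits)
        if best is None or key < best:
            best, best_spec = key, spec
    model = _fit_safely(best_spec, dataset.X[list(features)].to_numpy(), dataset.y, seed)
    return OptimizeResult(spec=best_spec, model=model, score=-best[0])


# ---------------------------------------------------------------------------
# forward feature selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SelectionRecord:
    iteration: int
    feature_added: str
    cross_validity: float
    spec: EnsembleSpec


@dataclass
class SelectionTrace:
    records: list[SelectionRecord]
    best_iteration: int  # 1-based iteration whose model is returned
    selected_features: list[str]
    spec: EnsembleSpec
    model: object
    stop_iteration: int

    @property
    def best_score(self) -> float:
        return self.records[self.best_iteration - 1].cross_validity


@dataclass(frozen=True)
class TrainedAlgorithm:
    """A trained "+"-algorithm: model, selected features and provenance."""

    name: str
    model: object
    features: tuple[str, ...]
    set_id: int
    registry_version: str
    loso_score: float

    @property
    def n_features(self) -> int:
        return len(self.features)

    def predict_window(self, window: MinuteWindow) -> int:
        feats = extract_features(window, set_id=self.set_id, subset=self.features)
        row = np.array([[feats[f] for f in self.features]])
        return int(self.model.predict(row)[0])

    def predict_windows(self, windows: Sequence[MinuteWindow]) -> np.ndarray:
        """Batched prediction (one model call for all windows)."""
        rows = [
            [f[name] for name in self.features]
            for f in (
                extract_features(w, set_id=self.set_id, subset=self.features)
                for w in windows
            )
        ]
        if not rows:
            return np.empty(0, dtype=int)
        return self.model.predict(np.asarray(rows)).astype(int)


def forward_feature_selection(
    dataset: TrainingDataset,
    ranked_features: Sequence[str],
    patience: int = 10,
    seed: int = 0,
    budget: int = 30,
    candidate_mode: str = "fixed_spec",
    space: SearchSpace = SearchSpace(),
) -> SelectionTrace:
    """Iterative feature inclusion with per-iteration re-optimization.

    Each iteration scores every remaining candidate feature (added to the
    current subset) by LOSO cross-validity — with the incumbent spec in
    the default ``fixed_spec`` mode, or with a fresh search per candidate
    in ``reoptimize`` mode — adds the winner, and re-optimizes the
    ensemble hyperparameters for the enlarged subset. Selection stops when
    the running maximum has not increased for ``patience`` consecutive
    additions (or candidates run out); the model at the maximum is
    returned.
    """
    if not ranked_features:
        raise ConfigurationError("ranked_features must be non-empty")
    if candidate_mode not in ("fixed_spec", "reoptimize"):
        raise ConfigurationError(f"unknown candidate_mode {candidate_mode!r}")
    remaining = list(ranked_features)
    selected: list[str] = []
    records: list[SelectionRecord] = []
    current_spec = EnsembleSpec()
    best_score, best_iter = -np.inf, 0
    since_best = 0
    it = 0
    while remaining:
        it += 1
        cand_scores: list[float] = []
        for f in remaining:
            feats = selected + [f]
            if candidate_mode == "fixed_spec":
                score, _ = loso_evaluate(dataset, feats, current_spec, seed=seed)
            else:
                score = optimize_ensemble(
                    dataset, feats, budget=budget, seed=seed + it, space=space
                ).score
            cand_scores.append(score)
        winner = int(np.argmax(cand_scores))  # ties: earlier-ranked feature
        chosen = remaining.pop(winner)
        selected.append(chosen)
        spec_before = current_spec
        opt = optimize_ensemble(
            dataset, selected, budget=budget, seed=seed + it, space=space
        )
        # keep whichever spec scored better for the enlarged subset
        if opt.score >= cand_scores[winner]:
            current_spec, score = opt.spec, opt.score
        else:
            current_spec, score = spec_before, cand_scores[winner]
        records.append(SelectionRecord(it, chosen, score, current_spec))
        if score > best_score:
            best_score, best_iter = score, it
            since_best = 0
        else:
            since_best += 1
        if since_best >= patience:
            break
    final_feats = [r.feature_added for r in records[:best_iter]]
    final_spec = records[best_iter - 1].spec
    model = _fit_safely(final_spec, dataset.X[final_feats].to_numpy(), dataset.y, seed)
    return SelectionTrace(
        records=records,
        best_iteration=best_iter,
        selected_features=final_feats,
        spec=final_spec,
        model=model,
        stop_iteration=it,
    )


# ---------------------------------------------------------------------------
# algorithm selection
# ---------------------------------------------------------------------------


def select_algorithm(
    candidates: Sequence[TrainedAlgorithm],
    daily_estimates: Sequence[np.ndarray],
    reference: np.ndarray,
) -> int:
    """Pick the most accurate, then most precise, candidate.

    ``daily_estimates[i]`` holds candidate *i*'s per-participant mean
    daily sedentary minutes on the development cohort; ``reference`` the
    dual-sensor reference values for the same participants. Primary key:
    lowest |Bland-Altman bias|; ties: narrowest 95% limits of agreement,
    then fewer features. Returns the index of the chosen candidate.
    """
    from .comparison import bland_altman

    if not candidates:
        raise ConfigurationError("no candidates to select from")
    keys = []
    for cand, est in zip(candidates, daily_estimates):
        stats = bland_altman(np.asarray(est), np.asarray(reference))
        keys.append((abs(stats.bias), stats.loa_upper - stats.loa_lower, cand.n_features))
    return int(np.lexsort(tuple(np.array([k[i] for k in keys]) for i in (2, 1, 0)))[0])


# ---------------------------------------------------------------------------
# fast per-minute feature tables
# ---------------------------------------------------------------------------


def minute_feature_table(
    raw: RawRecording,
    minute_starts: Sequence[float],
    features: Sequence[str],
) -> pd.DataFrame:
    """Window features for many minute starts.

    When all requested features have a vectorized whole-recording
    equivalent (:data:`FAST_MINUTE_FEATURES`) and the windows lie on a
    regular in-recording grid, the table is computed with array reshapes
    — numerically identical to per-window extraction but orders of
    magnitude faster. Otherwise it falls back to per-window extraction.
    """
    starts = np.asarray(minute_starts, dtype=float)
    fs = int(round(raw.sampling_rate))
    spw = 60 * fs  # samples per window
    idx = np.round(starts * raw.sampling_rate).astype(int)
    fast = (
        set(features) <= FAST_MINUTE_FEATURES
        and len(starts) > 0
        and np.all(idx >= 0)
        and np.all(idx + spw <= len(raw))
    )
    if not fast:
        rows = []
        for t0 in starts:
            win = MinuteWindow.from_raw(raw, float(t0))
            f = extract_features(win, set_id=2, subset=features)
            rows.append([f[name] for name in features])
        return pd.DataFrame(rows, columns=list(features))

    acc = raw.acceleration
    chans: dict[str, np.ndarray] = {}
    need_ch = {f.split("__")[0] for f in features}
    take = idx[:, None] + np.arange(spw)[None, :]
    for i, name in enumerate(("x", "y", "z")):
        if name in need_ch or "vm" in need_ch:
            chans[name] = acc[:, i]
    if "vm" in need_ch:
        chans["vm"] = np.sqrt(chans["x"] ** 2 + chans["y"] ** 2 + chans["z"] ** 2)
    cols: dict[str, np.ndarray] = {}
    for feat in features:
        ch, stat = feat.split("__")
        W = chans[ch][take]  # (n_windows, samples)
        if stat == "mean":
            cols[feat] = W.mean(axis=1)
        elif stat == "std":
            cols[feat] = W.std(axis=1)
        else:
            blk = W.reshape(len(starts), 60, fs).std(axis=2)
            if stat == "rolling_std_mean":
                cols[feat] = blk.mean(axis=1)
            elif stat == "rolling_std_max":
                cols[feat] = blk.max(axis=1)
            elif stat == "activity_fraction":
                cols[feat] = (blk > 0.01).mean(axis=1)
    return pd.DataFrame(cols, columns=list(features)).astype(float)


# ---------------------------------------------------------------------------
# posture model (pluggable component of the ActiGraph+ pipeline)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PostureModel:
    """Per-minute posture classifier for the waist sensor.

    Wraps any fitted scikit-learn classifier over a declared list of
    window features; predicts 'sit' / 'stand' / 'step' per clock minute.
    """

    model: object
    features: tuple[str, ...] = POSTURE_FEATURES
    set_id: int = 2
    registry_version: str = REGISTRY_VERSION

    def predict_minutes(self, raw_waist: RawRecording, minute_starts: Sequence[float]) -> list[str]:
        table = minute_feature_table(raw_waist, minute_starts, self.features)
        return [str(p) for p in self.model.predict(table.to_numpy())]


def fit_posture_model(
    feature_matrix: pd.DataFrame,
    labels: Sequence[str],
    seed: int = 0,
    n_estimators: int = 100,
    features: Sequence[str] = POSTURE_FEATURES,
) -> PostureModel:
    """Train the default random-forest posture model on per-minute waist
    window features labelled 'sit' / 'stand' / 'step'."""
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    rf.fit(feature_matrix[list(features)].to_numpy(), np.asarray(labels))
    return PostureModel(model=rf, features=tuple(features))
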