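"""Patient-specific semi-automated sleep-wake classification.

The workflow mirrors long-term iEEG practice: a handful of manually scored
training days spread evenly across the recording, greedy sequential
forward selection of 8 of the 21 features, a model grid over K-nearest
neighbours (K tuned in 3..50) and Gaussian Naive Bayes with or without
quantile normalisation, 24-h block scoring, and pruning of artefactual or
data-poor epochs and days.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score, confusion_matrix, recall_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import NearestNeighbors

from .core import EPOCH_S, Hypnogram, ParameterError, SchemaError, STAGES
from .features import FEATURE_NAMES, NormalizationParams, quantile_normalize

EPOCHS_PER_DAY = 86400 // EPOCH_S


@dataclass
class StagerConfig:
    n_training_days: int = 9
    n_selected_features: int = 8
    classifier_family: str = "auto"  # "knn", "naive_bayes", or "auto"
    knn_k_range: tuple[int, int] = (3, 50)
    use_normalized: bool | str = "auto"  # True, False, or "auto"
    cv_folds: int = 5

    def __post_init__(self):
        if self.n_selected_features > len(FEATURE_NAMES):
            raise ParameterError("cannot select more features than exist")
        lo, hi = self.knn_k_range
        if lo < 3 or hi > 50 or lo > hi:
            raise ParameterError("knn_k_range must lie within 3..50")
        if self.classifier_family not in ("knn", "naive_bayes", "auto"):
            raise ParameterError("unknown classifier family")


@dataclass
class PruningRules:
    epoch_missing_threshold: float = 0.5
    day_unknown_threshold: float = 0.3
    boundary_hour: int = 12

    def __post_init__(self):
        for name in ("epoch_missing_threshold", "day_unknown_threshold"):
            if not 0 < getattr(self, name) < 1:
                raise ParameterError(f"{name} must lie in (0, 1)")


def select_training_days(usable_day_indices, n: int = 9) -> np.ndarray:
    """Pick ``n`` days at equidistant positions across the usable days.

    Positions are rounded linear spacing over the usable-day list, so the
    first and last usable days are always included.
    """
    idx = np.asarray(sorted(usable_day_indices))
    if idx.size < n:
        raise ParameterError(f"need at least {n} usable days, have {idx.size}")
    pos = np.unique(np.round(np.linspace(0, idx.size - 1, n)).astype(int))
    return idx[pos]


def _stratified_folds(y: np.ndarray, n_folds: int, seed: int):
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ParameterError("training data contains a single class")
    rare = classes[counts < 2]
    if rare.size:
        raise ParameterError(
            f"class {rare[0]!r} has fewer than 2 training epochs"
        )
    n_folds = int(min(n_folds, counts.min()))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros_like(y), y))


def _knn_predict_multi(
    X_tr: np.ndarray, y_tr: np.ndarray, X_te: np.ndarray, ks: list[int]
) -> dict[int, np.ndarray]:
    """KNN predictions for several k from one neighbour search.

    Majority vote with ties broken toward the lowest class index, so
    results are deterministic.
    """
    classes, y_enc = np.unique(y_tr, return_inverse=True)
    kmax = min(max(ks), len(X_tr))
    nn = NearestNeighbors(n_neighbors=kmax).fit(X_tr)
    _, nbr = nn.kneighbors(X_te)
    lab = y_enc[nbr]  # (n_te, kmax)
    onehot = np.zeros((lab.shape[0], kmax, classes.size), dtype=np.int32)
    rows = np.arange(lab.shape[0])[:, None]
    cols = np.arange(kmax)[None, :]
    onehot[rows, cols, lab] = 1
    cum = np.cumsum(onehot, axis=1)  # votes among first k neighbours
    out = {}
    for k in ks:
        kk = min(k, kmax)
        out[k] = classes[np.argmax(cum[:, kk - 1, :], axis=1)]
    return out


def _cv_macro_recall(X, y, clf, folds) -> float:
    scores = []
    for tr, te in folds:
        est = clf.__class__(**clf.get_params())
        est.fit(X[tr], y[tr])
        pred = est.predict(X[te])
        scores.append(recall_score(y[te], pred, average="macro", zero_division=0))
    return float(np.mean(scores))


def sequential_feature_selection(
    features: pd.DataFrame,
    labels: np.ndarray,
    target_count: int = 8,
    classifier=None,
    seed: int = 0,
    cv_folds: int = 5,
) -> list[str]:
    """Greedy forward selection maximising cross-validated macro recall.

    Ties are broken toward the lower canonical feature index. Constant or
    all-NaN columns must be excluded beforehand (they are skipped with a
    warning here).
    """
    labels = np.asarray(labels)
    keep = ~pd.isna(features).any(axis=1).to_numpy() & (labels != "UNKNOWN")
    X_all = features.loc[keep]
    y = labels[keep]
    if np.unique(y).size < 2:
        raise ParameterError("feature selection needs at least two classes")
    clf = classifier if classifier is not None else GaussianNB()
    folds = _stratified_folds(y, cv_folds, seed)

    candidates = []
    for c in features.columns:
        if X_all[c].nunique() <= 1:
            warnings.warn(f"skipping constant feature {c!r}")
            continue
        candidates.append(c)
    if len(candidates) < target_count:
        raise ParameterError("not enough usable features to reach target_count")

    selected: list[str] = []
    while len(selected) < target_count:
        best_score, best_feat = -np.inf, None
        for c in candidates:
            if c in selected:
                continue
            score = _cv_macro_recall(
                X_all[selected + [c]].to_numpy(), y, clf, folds
            )
            if score > best_score + 1e-12:
                best_score, best_feat = score, c
        selected.append(best_feat)
    return selected


@dataclass
class TrainedStager:
    """A fitted patient-specific stager plus everything needed to score."""

    selected_features: list[str]
    family: str  # "knn" or "naive_bayes"
    k: int | None
    use_normalized: bool
    norm_params: NormalizationParams
    cv_macro_recall: float
    cv_accuracy: float
    class_counts: dict[str, int]
    train_X: np.ndarray = field(repr=False)
    train_y: np.ndarray = field(repr=False)

    def to_json(self, path) -> None:
        payload = {
            "selected_features": self.selected_features,
            "family": self.family,
            "k": self.k,
            "use_normalized": self.use_normalized,
            "norm_q05": self.norm_params.q05,
            "norm_q95": self.norm_params.q95,
            "norm_unusable": self.norm_params.unusable,
            "cv_macro_recall": self.cv_macro_recall,
            "cv_accuracy": self.cv_accuracy,
            "class_counts": self.class_counts,
            "train_X": self.train_X.tolist(),
            "train_y": self.train_y.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TrainedStager":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            selected_features=list(d["selected_features"]),
            family=d["family"],
            k=d["k"],
            use_normalized=bool(d["use_normalized"]),
            norm_params=NormalizationParams(
                q05=d["norm_q05"], q95=d["norm_q95"], unusable=list(d["norm_unusable"])
            ),
            cv_macro_recall=d["cv_macro_recall"],
            cv_accuracy=d["cv_accuracy"],
            class_counts=d["class_counts"],
            train_X=np.asarray(d["train_X"], dtype=float),
            train_y=np.asarray(d["train_y"], dtype="U7"),
        )


def train_stager(
    features: pd.DataFrame,
    labels,
    config: StagerConfig | None = None,
    seed: int = 0,
) -> TrainedStager:
    """Select features, tune the classifier grid, and fit the final stager.

    The grid crosses {KNN with k in the configured range, Gaussian Naive
    Bayes} with {normalised, unnormalised} features and keeps the
    configuration with the best cross-validated macro recall. Ties prefer
    the simpler model: Naive Bayes over KNN, then smaller k.
    """
    config = config or StagerConfig()
    labels = np.asarray(labels, dtype="U7")
    if len(labels) != len(features):
        raise SchemaError("labels misaligned with feature rows")
    keep = ~pd.isna(features).any(axis=1).to_numpy() & (labels != "UNKNOWN")
    raw = features.loc[keep].reset_index(drop=True)
    y = labels[keep]
    norm, norm_params = quantile_normalize(raw)
    usable_cols = [c for c in features.columns if c not in norm_params.unusable]

    selection_base = norm if config.use_normalized in (True, "auto") else raw
    selected = sequential_feature_selection(
        selection_base[usable_cols],
        y,
        target_count=config.n_selected_features,
        seed=seed,
        cv_folds=config.cv_folds,
    )

    folds = _stratified_folds(y, config.cv_folds, seed)
    if config.use_normalized == "auto":
        norm_options = [True, False]
    else:
        norm_options = [bool(config.use_normalized)]
    k_lo, k_hi = config.knn_k_range
    ks = list(range(k_lo, k_hi + 1))

    # candidate tuples: (macro_recall, family, k, use_norm, accuracy)
    candidates = []
    for use_norm in norm_options:
        X = (norm if use_norm else raw)[selected].to_numpy()
        if config.classifier_family in ("naive_bayes", "auto"):
            rec, acc = [], []
            for tr, te in folds:
                nb = GaussianNB().fit(X[tr], y[tr])
                pred = nb.predict(X[te])
                rec.append(recall_score(y[te], pred, average="macro", zero_division=0))
                acc.append(float(np.mean(pred == y[te])))
            candidates.append(
                (float(np.mean(rec)), "naive_bayes", None, use_norm, float(np.mean(acc)))
            )
        if config.classifier_family in ("knn", "auto"):
            rec_k = {k: [] for k in ks}
            acc_k = {k: [] for k in ks}
            for tr, te in folds:
                preds = _knn_predict_multi(X[tr], y[tr], X[te], ks)
                for k in ks:
                    rec_k[k].append(
                        recall_score(y[te], preds[k], average="macro", zero_division=0)
                    )
                    acc_k[k].append(float(np.mean(preds[k] == y[te])))
            for k in ks:
                candidates.append(
                    (float(np.mean(rec_k[k])), "knn", k, use_norm, float(np.mean(acc_k[k])))
                )

    def sort_key(c):
        score, family, k, use_norm, _ = c
        # higher score first; then NB before KNN; then smaller k; then
        # normalised first (a fixed, documented tie order)
        return (-score, 0 if family == "naive_bayes" else 1, k or 0, not use_norm)

    best = sorted(candidates, key=sort_key)[0]
    score, family, k, use_norm, acc = best
    X_final = (norm if use_norm else raw)[selected].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    return TrainedStager(
        selected_features=selected,
        family=family,
        k=k,
        use_normalized=use_norm,
        norm_params=norm_params,
        cv_macro_recall=score,
        cv_accuracy=acc,
        class_counts={c: int(n) for c, n in zip(classes, counts)},
        train_X=X_final,
        train_y=y,
    )


def score_epochs(
    stager: TrainedStager,
    features: pd.DataFrame,
    start=None,
    epoch_s: int = EPOCH_S,
) -> Hypnogram:
    """Score epochs with a trained stager, 24-h blocks at a time.

    Rows with missing values in the selected features become UNKNOWN.
    """
    missing_cols = [c for c in stager.selected_features if c not in features.columns]
    if missing_cols:
        raise SchemaError(f"features lack selected columns {missing_cols}")
    if stager.use_normalized:
        X_df, _ = quantile_normalize(features, stager.norm_params)
    else:
        X_df = features
    X = X_df[stager.selected_features].to_numpy()
    labels = np.full(len(X), "UNKNOWN", dtype="U7")
    ok = np.all(np.isfinite(X), axis=1)

    if stager.family == "naive_bayes":
        clf = GaussianNB().fit(stager.train_X, stager.train_y)
    block = EPOCHS_PER_DAY
    for b0 in range(0, len(X), block):
        sel = np.flatnonzero(ok[b0 : b0 + block]) + b0
        if sel.size == 0:
            continue
        if stager.family == "naive_bayes":
            labels[sel] = clf.predict(X[sel])
        else:
            labels[sel] = _knn_predict_multi(
                stager.train_X, stager.train_y, X[sel], [stager.k]
            )[stager.k]
    return Hypnogram(labels, start if start is not None else "2000-01-01", epoch_s)


def prune(
    hypnogram: Hypnogram,
    artifact_flags: np.ndarray | None = None,
    missing_fraction: np.ndarray | None = None,
    rules: PruningRules | None = None,
) -> tuple[Hypnogram, list[pd.Timestamp]]:
    """Apply epoch- and day-level quality rules.

    Artefactual epochs and epochs with more than half their samples
    missing become UNKNOWN; 24-h windows whose UNKNOWN fraction exceeds
    the day threshold are returned as the excluded-day list. Pruning is
    idempotent and never converts UNKNOWN back to a stage.
    """
    rules = rules or PruningRules()
    labels = hypnogram.labels.copy()
    for mask, kind in ((artifact_flags, "artifact"), (missing_fraction, "missing")):
        if mask is None:
            continue
        mask = np.asarray(mask)
        if mask.shape[0] != len(labels):
            raise SchemaError(f"{kind} mask misaligned with hypnogram")
    if artifact_flags is not None:
        labels[np.asarray(artifact_flags, dtype=bool)] = "UNKNOWN"
    if missing_fraction is not None:
        labels[
            np.asarray(missing_fraction, dtype=float) > rules.epoch_missing_threshold
        ] = "UNKNOWN"
    pruned = Hypnogram(labels, hypnogram.start, hypnogram.epoch_s)
    excluded = []
    for t0, sl in pruned.day_slices(rules.boundary_hour):
        frac = float(np.mean(labels[sl] == "UNKNOWN"))
        if frac > rules.day_unknown_threshold:
            excluded.append(t0)
    return pruned, excluded


def evaluate_scoring(predicted: Hypnogram, truth: Hypnogram) -> dict:
    """Accuracy, Cohen's kappa and confusion matrix vs reference labels.

    UNKNOWN epochs on either side are excluded pairwise.
    """
    if len(predicted) != len(truth):
        raise SchemaError("hypnograms have different lengths")
    p, t = predicted.labels, truth.labels
    ok = (p != "UNKNOWN") & (t != "UNKNOWN")
    if not ok.any():
        raise ParameterError("no overlapping labelled epochs")
    p, t = p[ok], t[ok]
    stages = [s for s in STAGES if s != "UNKNOWN"]
    cm = confusion_matrix(t, p, labels=stages)
    present = [s for s in stages if (t == s).any()]
    per_class_recall = {
        s: recall_score(t == s, p == s, zero_division=0) for s in present
    }
    return {
        "accuracy": float(np.mean(p == t)),
        "kappa": float(cohen_kappa_score(t, p)),
        "confusion": pd.DataFrame(cm, index=stages, columns=stages),
        "per_class_recall": per_class_recall,
        "n_epochs": int(ok.sum()),
    }
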