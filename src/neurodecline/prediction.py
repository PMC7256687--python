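"""Multimodal sample assembly and nested cross-validated prediction.

Each EEG segment contributes one sample; participant-constant MRI and
neuropsychological feature vectors are replicated onto every segment of
that participant.  Classification uses a linear 2-norm soft-margin SVM
(squared-hinge loss) after per-column z-standardisation fitted on the
training split only.

The cross-validation is nested with three layers, every split grouped by
participant (all segments of one participant stay in one partition) and
stratified by label:

* **outer** — a single 80/20 division; the 20% is touched exactly once,
  to evaluate the final model;
* **middle** — 5-fold over the 80%; each run performs feature subset
  selection and records the chosen subset, yielding per-feature
  selection frequencies (0..5) as a consistency measure;
* **inner** — 5-fold inside the subset selection: greedy forward
  selection adds, up to a cap of 30 features, whichever feature most
  improves mean inner-fold balanced accuracy.

The final model per outer split uses the features selected in at least
one middle run, ranked by selection frequency and truncated to the cap,
retrained on the full 80%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

logger = logging.getLogger(__name__)

META_COLUMNS = ("participant_id", "label", "condition", "session")


@dataclass(frozen=True)
class CVConfig:
    outer_test_fraction: float = 0.2
    middle_folds: int = 5
    inner_folds: int = 5
    feature_cap: int = 30
    svm_cost: float = 1.0
    min_improvement: float = 1e-4
    class_weight: str | None = None  # or "balanced"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_cap < 1:
            raise ValueError("feature cap must be >= 1")
        if self.middle_folds < 2 or self.inner_folds < 2:
            raise ValueError("need at least 2 folds")


@dataclass
class CVResult:
    config: CVConfig
    feature_names: list[str]
    selected_subsets: list[list[str]]  # one ordered subset per middle run
    selection_frequency: pd.Series  # feature -> 0..middle_folds
    final_features: list[str]
    test_predictions: pd.DataFrame  # participant_id, label, prediction
    fold_assignment: dict[str, int] = field(default_factory=dict)
    train_participants: list[str] = field(default_factory=list)
    test_participants: list[str] = field(default_factory=list)


def assemble(
    eeg_features: pd.DataFrame | None = None,
    mri_features: pd.DataFrame | None = None,
    psy_features: pd.DataFrame | None = None,
    labels: pd.Series | None = None,
) -> pd.DataFrame:
    """Build the per-sample table for one modality combination.

    With EEG present the table has one row per segment and the
    participant-constant MRI/neuropsychology columns are replicated onto
    each of the participant's segments; without EEG it has one row per
    participant.  ``labels`` maps participant_id -> {0, 1}.  Participants
    lacking a label or any requested modality are dropped with a log
    entry; a minority class below 30% of participants logs an imbalance
    warning.
    """
    if labels is None:
        raise ValueError("labels are required")
    if eeg_features is None and mri_features is None and psy_features is None:
        raise ValueError("at least one modality must be supplied")

    if eeg_features is not None:
        base = eeg_features.copy()
        if "participant_id" not in base.columns:
            raise ValueError("EEG feature table needs a participant_id column")
    else:
        per_part = mri_features if mri_features is not None else psy_features
        base = pd.DataFrame({"participant_id": per_part.index.astype(str)})

    for tbl in (mri_features, psy_features):
        if tbl is None:
            continue
        wide = tbl.copy()
        wide.index = wide.index.astype(str)
        keep = base["participant_id"].isin(wide.index)
        if (~keep).any():
            logger.info(
                "dropping %d row(s) lacking per-participant features",
                int((~keep).sum()),
            )
            base = base[keep]
        base = base.join(wide, on="participant_id")

    lab = labels.copy()
    lab.index = lab.index.astype(str)
    keep = base["participant_id"].isin(lab.index)
    if (~keep).any():
        logger.info("dropping %d row(s) without a label", int((~keep).sum()))
        base = base[keep]
    base = base.copy()
    base["label"] = base["participant_id"].map(lab).astype(int)

    if base.isna().any().any():
        raise ValueError("assembled table contains missing values")
    part_labels = base.groupby("participant_id")["label"].first()
    minority = min(part_labels.mean(), 1 - part_labels.mean())
    if minority < 0.30:
        logger.warning(
            "minority class holds only %.0f%% of participants", 100 * minority
        )
    meta = [c for c in META_COLUMNS if c in base.columns]
    feats = [c for c in base.columns if c not in META_COLUMNS]
    return base[meta + feats].reset_index(drop=True)


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def grouped_folds(
    participant_labels: pd.Series, k: int, seed: int
) -> dict[str, int]:
    """Label-stratified k-fold partition of participants (not rows)."""
    pids = np.array(sorted(participant_labels.index.astype(str)))
    y = participant_labels.loc[pids].to_numpy()
    if len(pids) < k:
        raise ValueError(f"only {len(pids)} participants for {k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(pids, y)):
        for i in test_idx:
            assignment[pids[i]] = fold
    return assignment


def train_svm(
    x: np.ndarray, y: np.ndarray, c: float = 1.0, class_weight: str | None = None
) -> Pipeline:
    """Linear 2-norm soft-margin SVM on z-standardised columns.

    The squared-hinge loss is the 2-norm soft margin (slack variables
    penalised quadratically); the kernel is the plain dot product.
    """
    if len(np.unique(y)) < 2:
        raise ValueError("training data contain a single class")
    model = Pipeline([
        ("scale", StandardScaler()),
        ("svm", LinearSVC(
            C=c, loss="squared_hinge", class_weight=class_weight,
            random_state=0, max_iter=5000,
        )),
    ])
    model.fit(x, y)
    return model


def _balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    accs = []
    for cls in (0, 1):
        sel = y_true == cls
        if sel.any():
            accs.append((y_pred[sel] == cls).mean())
    return float(np.mean(accs))


def greedy_fss(
    table: pd.DataFrame,
    cap: int = 30,
    inner_k: int = 5,
    seed: int = 0,
    c: float = 1.0,
    class_weight: str | None = None,
) -> list[str]:
    """Greedy forward feature-subset selection, capped at 30 features.

    Starting from the empty set, each step adds the feature whose
    inclusion maximises mean inner-fold (grouped, stratified) balanced
    accuracy, stopping at the cap or when the best candidate improves the
    score by no more than ``1e-4``.  Ties break toward the lower column
    index, making the procedure deterministic given the seed.

    The inner folds and per-fold column standardisation depend only on
    the training rows, so they are computed once and reused across
    candidate features.
    """
    feats = feature_columns(table)
    x = table[feats].to_numpy(dtype=float)
    y = table["label"].to_numpy(dtype=int)
    pids = table["participant_id"].to_numpy(dtype=str)

    part_labels = pd.Series(y, index=pids).groupby(level=0).first()
    k_eff = min(inner_k, int(part_labels.value_counts().min()), len(part_labels))
    if k_eff < 2:
        raise ValueError("too few participants per class for the inner folds")
    folds = grouped_folds(part_labels, k_eff, seed)
    fold_of_row = np.array([folds[p] for p in pids])

    splits = []  # (xtr_std, ytr, xte_std, yte) with train-fold standardisation
    for fold in range(k_eff):
        tr = fold_of_row != fold
        if len(np.unique(y[tr])) < 2:
            continue
        mu = x[tr].mean(axis=0)
        sd = x[tr].std(axis=0)
        sd[sd == 0] = 1.0
        splits.append(((x[tr] - mu) / sd, y[tr], (x[~tr] - mu) / sd, y[~tr]))
    if not splits:
        return []

    def score(cols: list[int]) -> float:
        accs = []
        for xtr, ytr, xte, yte in splits:
            svm = LinearSVC(
                C=c, loss="squared_hinge", class_weight=class_weight,
                random_state=0, max_iter=5000,
            )
            svm.fit(xtr[:, cols], ytr)
            accs.append(_balanced_accuracy(yte, svm.predict(xte[:, cols])))
        return float(np.mean(accs))

    selected: list[int] = []
    best_score = -np.inf
    while len(selected) < min(cap, len(feats)):
        candidates = [i for i in range(len(feats)) if i not in selected]
        scores = np.array([score(selected + [i]) for i in candidates])
        step_best = int(np.argmax(scores))  # argmax -> lowest index on ties
        if best_score != -np.inf and scores[step_best] <= best_score + 1e-4:
            break
        best_score = float(scores[step_best])
        selected.append(candidates[step_best])
    return [feats[i] for i in selected]


def nested_cv(table: pd.DataFrame, config: CVConfig) -> CVResult:
    """Three-layer nested cross-validation with feature subset selection.

    Outer: grouped stratified 80/20 split.  Middle: 5-fold over the 80%;
    each run selects a subset via :func:`greedy_fss` (which runs the
    inner 5-fold internally) and records it.  The final model retrains
    the frequency-ranked union of the middle-run subsets (truncated to
    the cap) on the full 80% and predicts the held-out 20% once.
    """
    feats = feature_columns(table)
    pids = table["participant_id"].astype(str)
    part_labels = table.groupby(table["participant_id"].astype(str))["label"].first()

    n_outer = max(2, int(round(1.0 / config.outer_test_fraction)))
    outer = grouped_folds(part_labels, n_outer, config.seed)
    test_parts = sorted(p for p, f in outer.items() if f == 0)
    train_parts = sorted(p for p, f in outer.items() if f != 0)
    assert not set(test_parts) & set(train_parts), "participant leakage"

    train_tbl = table[pids.isin(train_parts)].reset_index(drop=True)
    test_tbl = table[pids.isin(test_parts)].reset_index(drop=True)

    middle_labels = part_labels.loc[train_parts]
    k_mid = min(config.middle_folds, int(middle_labels.value_counts().min()))
    if k_mid < 2:
        raise ValueError("too few participants per class for the middle folds")
    middle = grouped_folds(middle_labels, k_mid, config.seed + 1)
    fold_of_row = train_tbl["participant_id"].astype(str).map(middle).to_numpy()

    subsets: list[list[str]] = []
    for fold in range(k_mid):
        run_tbl = train_tbl[fold_of_row != fold]
        held = set(run_tbl["participant_id"]) & set(
            train_tbl.loc[fold_of_row == fold, "participant_id"]
        )
        assert not held, "participant leakage in middle layer"
        subset = greedy_fss(
            run_tbl, cap=config.feature_cap, inner_k=config.inner_folds,
            seed=config.seed + 2 + fold, c=config.svm_cost,
            class_weight=config.class_weight,
        )
        subsets.append(subset)

    counts = pd.Series(0, index=feats, dtype=int)
    first_rank: dict[str, int] = {}
    for run_i, subset in enumerate(subsets):
        for rank, f in enumerate(subset):
            counts[f] += 1
            first_rank.setdefault(f, run_i * 10_000 + rank)
    chosen = [f for f in feats if counts[f] > 0]
    chosen.sort(key=lambda f: (-counts[f], first_rank[f]))
    final_features = chosen[: config.feature_cap]
    if not final_features:
        raise ValueError("no feature was ever selected")

    model = train_svm(
        train_tbl[final_features].to_numpy(dtype=float),
        train_tbl["label"].to_numpy(dtype=int),
        config.svm_cost, config.class_weight,
    )
    preds = model.predict(test_tbl[final_features].to_numpy(dtype=float))
    test_predictions = pd.DataFrame({
        "participant_id": test_tbl["participant_id"].astype(str),
        "label": test_tbl["label"].astype(int),
        "prediction": preds.astype(int),
    })
    return CVResult(
        config=config,
        feature_names=feats,
        selected_subsets=subsets,
        selection_frequency=counts,
        final_features=final_features,
        test_predictions=test_predictions,
        fold_assignment=outer,
        train_participants=train_parts,
        test_participants=test_parts,
    )


def _metrics(y: np.ndarray, yhat: np.ndarray) -> dict[str, float]:
    tp = int(((y == 1) & (yhat == 1)).sum())
    fn = int(((y == 1) & (yhat == 0)).sum())
    tn = int(((y == 0) & (yhat == 0)).sum())
    fp = int(((y == 0) & (yhat == 1)).sum())
    sens = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    spec = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    acc = 100.0 * (tp + tn) / max(tp + tn + fp + fn, 1)
    return {
        "tp": tp, "fn": fn, "tn": tn, "fp": fp,
        "accuracy": acc, "sensitivity": sens, "specificity": spec,
        "balanced_accuracy": (sens + spec) / 2.0,
    }


def evaluate(result: CVResult, benchmark: float = 70.0) -> dict:
    """Segment- and participant-level accuracy / sensitivity / specificity.

    Participant-level predictions are the majority vote over the
    participant's segment predictions (ties go to the positive class and
    are logged).  A result is flagged ``reportable`` only when both
    sensitivity and specificity reach the 70% benchmark at the
    participant level; below that the apparent accuracy is treated as a
    statistical artifact of a classifier biased toward one class.
    """
    tp = result.test_predictions
    seg = _metrics(tp["label"].to_numpy(), tp["prediction"].to_numpy())
    votes = tp.groupby("participant_id").agg(
        label=("label", "first"), mean_pred=("prediction", "mean")
    )
    ties = int((votes["mean_pred"] == 0.5).sum())
    if ties:
        logger.info("%d participant vote tie(s) resolved to the positive class", ties)
    part_pred = (votes["mean_pred"] >= 0.5).astype(int).to_numpy()
    part = _metrics(votes["label"].to_numpy(), part_pred)
    reportable = (
        part["sensitivity"] >= benchmark and part["specificity"] >= benchmark
    )
    return {
        "segment_level": seg,
        "participant_level": part,
        "reportable": bool(reportable),
        "benchmark": benchmark,
    }
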