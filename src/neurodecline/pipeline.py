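"""End-to-end workflows: cohort -> features -> nested-CV prediction.

These functions chain the package's stages for a whole (synthetic or
real) cohort: EEG preprocessing and segmentation, per-segment MVAR
connectivity features, per-participant MRI region features and baseline
neuropsychology, sample assembly and the nested cross-validation.  They
are the programmatic counterpart of the command-line workflow and the
basis of the package's recovery experiments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import mri as ndmri
from . import neuropsych as npsy
from . import prediction, synth
from .connectivity import segment_features
from .preprocess import detect_artifacts, filter_recording, segment


def extract_cohort_features(
    cohort: synth.Cohort,
    condition: str = "rest",
    measures: list[str] | None = None,
    eeg_duration_s: float | None = None,
    mri_include: tuple[str, ...] = ("volumetry",),
    mvar_order: int = 10,
) -> dict[str, pd.DataFrame]:
    """Run preprocessing + feature extraction for every participant.

    Returns a dict with keys ``eeg`` (one row per clean segment of the
    requested condition), ``mri`` and ``psy`` (one row per participant),
    and ``labels`` (participant x domain decline labels).
    """
    measures = measures or ["PDC"]
    eeg_rows, mri_rows = [], {}
    for pid in cohort.participants["participant_id"]:
        rec = cohort.eeg_recording(pid, duration_s=eeg_duration_s)
        rec = filter_recording(rec)
        rec.artifact_mask = detect_artifacts(rec)
        mode = "rest" if condition == "rest" else "event_locked"
        segs = [s for s in segment(rec, mode=mode) if s.condition == condition]
        if segs:
            eeg_rows.append(
                segment_features(
                    segs, measures=measures, order=mvar_order,
                    channel_names=rec.channel_names,
                )
            )
        if mri_include:
            intensity, labels = cohort.labeled_volume(pid)
            mri_rows[pid] = ndmri.region_feature_table(
                intensity, labels, include=mri_include,
            )
    out: dict[str, pd.DataFrame] = {}
    out["eeg"] = pd.concat(eeg_rows, ignore_index=True) if eeg_rows else None
    if mri_rows:
        mri_df = pd.DataFrame(mri_rows).T
        mri_df.index.name = "participant_id"
        out["mri"] = mri_df
    else:
        out["mri"] = None
    out["psy"] = npsy.baseline_features(cohort.baseline)
    out["labels"] = npsy.decline_labels(cohort.baseline, cohort.followup)
    return out


def domain_labels(labels_df: pd.DataFrame, domain: str) -> pd.Series:
    sub = labels_df[labels_df["domain"] == domain]
    return sub.set_index("participant_id")["label"]


def selection_ratio(
    frequency: pd.Series, informative: list[str]
) -> tuple[float, float, float]:
    """Mean selection frequency of informative vs noise features.

    Returns (informative mean, noise mean, ratio); the ratio is ``inf``
    when no noise feature was ever selected.
    """
    informative = [f for f in informative if f in frequency.index]
    noise = [f for f in frequency.index if f not in informative]
    info_mean = float(frequency[informative].mean()) if informative else 0.0
    noise_mean = float(frequency[noise].mean()) if noise else 0.0
    ratio = info_mean / noise_mean if noise_mean > 0 else float("inf")
    return info_mean, noise_mean, ratio


def run_decline_experiment(
    cohort: synth.Cohort,
    domain: str = "executive",
    modalities: tuple[str, ...] = ("eeg", "mri", "psy"),
    cv_config: prediction.CVConfig | None = None,
    features: dict[str, pd.DataFrame] | None = None,
    **extract_kwargs,
) -> dict:
    """Full prediction experiment for one domain and modality mix."""
    cv_config = cv_config or prediction.CVConfig()
    if features is None:
        features = extract_cohort_features(cohort, **extract_kwargs)
    table = prediction.assemble(
        eeg_features=features["eeg"] if "eeg" in modalities else None,
        mri_features=features["mri"] if "mri" in modalities else None,
        psy_features=features["psy"] if "psy" in modalities else None,
        labels=domain_labels(features["labels"], domain),
    )
    result = prediction.nested_cv(table, cv_config)
    report = prediction.evaluate(result)
    informative = cohort.ground_truth.informative_features.get(domain, [])
    info_mean, noise_mean, ratio = selection_ratio(
        result.selection_frequency, informative
    )
    return {
        "table": table,
        "result": result,
        "report": report,
        "informative_features": informative,
        "selection_ratio": ratio,
        "informative_mean_frequency": info_mean,
        "noise_mean_frequency": noise_mean,
    }


def permutation_null(
    table: pd.DataFrame,
    cv_config: prediction.CVConfig,
    n_permutations: int = 5,
    seed: int = 0,
) -> float:
    """Mean held-out balanced accuracy with participant labels permuted.

    Permutes the participant -> label assignment (keeping the class
    balance) before each run; with no true association the expected
    balanced accuracy is 50%.
    """
    rng = np.random.default_rng(seed)
    part_labels = table.groupby("participant_id")["label"].first()
    accs = []
    for rep in range(n_permutations):
        permuted = pd.Series(
            rng.permutation(part_labels.to_numpy()), index=part_labels.index
        )
        shuffled = table.copy()
        shuffled["label"] = shuffled["participant_id"].map(permuted)
        cfg = prediction.CVConfig(
            outer_test_fraction=cv_config.outer_test_fraction,
            middle_folds=cv_config.middle_folds,
            inner_folds=cv_config.inner_folds,
            feature_cap=cv_config.feature_cap,
            svm_cost=cv_config.svm_cost,
            class_weight=cv_config.class_weight,
            seed=cv_config.seed + 1000 + rep,
        )
        result = prediction.nested_cv(shuffled, cfg)
        report = prediction.evaluate(result)
        accs.append(report["participant_level"]["balanced_accuracy"])
    return float(np.mean(accs))
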