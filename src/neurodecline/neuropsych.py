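"""Neuropsychological scoring: normative z-scores, composite domain
decline labels, and baseline feature vectors.

Raw subscale scores from the baseline and 18-month follow-up assessments
are converted to z-scores against test-manual norms.  Scales on which a
higher raw score means *worse* performance (error counts, reaction times,
the Beck Depression Inventory) are sign-flipped so that a larger z is
always better; the decline rule is then uniform across domains: a
participant declines in a domain iff the z-change between sessions is
<= -1 (at least one normative SD) on at least one member subscale.
Improvements and sub-threshold changes count as no decline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SESSIONS = ("baseline", "followup")

#: Default battery: subscale -> (norm mean, norm SD, higher_is_better).
#: Wechsler subscales are IQ-scaled, fluency/memory/attention T-scaled,
#: DCS a percentile rank, BDI and TAP error/miss counts raw.
DEFAULT_NORMS: dict[str, tuple[float, float, bool]] = {
    "wie_matrices": (100.0, 15.0, True),
    "wie_mosaics": (100.0, 15.0, True),
    "wie_repeating_numbers": (100.0, 15.0, True),
    "rwt_verbal_fluency": (50.0, 10.0, True),
    "rwt_categorical_fluency": (50.0, 10.0, True),
    "rwt_semantic_fluency": (50.0, 10.0, True),
    "rwt_category_transition": (50.0, 10.0, True),
    "vlmt_learning": (50.0, 10.0, True),
    "vlmt_consolidation": (50.0, 10.0, True),
    "vlmt_recall": (50.0, 10.0, True),
    "vlmt_recognition": (50.0, 10.0, True),
    "tap_flexibility": (50.0, 10.0, True),
    "tap_acoustic_reaction_1": (50.0, 10.0, True),
    "tap_visual_reaction_1": (50.0, 10.0, True),
    "tap_errors_1": (5.0, 3.0, False),
    "tap_misses_1": (5.0, 3.0, False),
    "tap_acoustic_reaction_2": (50.0, 10.0, True),
    "tap_visual_reaction_2": (50.0, 10.0, True),
    "tap_errors_2": (5.0, 3.0, False),
    "tap_misses_2": (5.0, 3.0, False),
    "tap_divided_attention": (50.0, 10.0, True),
    "mwt_iq": (100.0, 15.0, True),
    "dcs_percentile": (50.0, 28.0, True),
    "bdi": (8.0, 7.0, False),
}


@dataclass(frozen=True)
class DomainDefinition:
    """A cognitive domain and the subscales entering its decline score."""

    name: str
    subscales: tuple[str, ...]


#: Composite domains.  Executive functions rest on 7 scales, visual-verbal
#: memory on 5, divided attention on 3 (the flexibility summary score, its
#: error count and the divided-attention summary), depression on the BDI.
#: Overlap between domains is allowed.
DEFAULT_DOMAINS: dict[str, DomainDefinition] = {
    "executive": DomainDefinition(
        "executive",
        (
            "wie_matrices",
            "wie_repeating_numbers",
            "rwt_verbal_fluency",
            "rwt_categorical_fluency",
            "rwt_semantic_fluency",
            "rwt_category_transition",
            "tap_flexibility",
        ),
    ),
    "visual_verbal_memory": DomainDefinition(
        "visual_verbal_memory",
        (
            "vlmt_learning",
            "vlmt_consolidation",
            "vlmt_recall",
            "vlmt_recognition",
            "dcs_percentile",
        ),
    ),
    "divided_attention": DomainDefinition(
        "divided_attention",
        ("tap_flexibility", "tap_errors_1", "tap_divided_attention"),
    ),
    "depression": DomainDefinition("depression", ("bdi",)),
}

DECLINE_SD_THRESHOLD = 1.0  # "at least one standard deviation"


@dataclass
class NeuropsychTable:
    """Long-format score table plus the normative lookup.

    ``scores``: columns participant_id, group, session, subscale, raw.
    ``norms``: subscale -> (mean, sd, higher_is_better).
    """

    scores: pd.DataFrame
    norms: dict[str, tuple[float, float, bool]] = field(
        default_factory=lambda: dict(DEFAULT_NORMS)
    )

    def __post_init__(self) -> None:
        required = {"participant_id", "group", "session", "subscale", "raw"}
        missing = required - set(self.scores.columns)
        if missing:
            raise ValueError(f"score table missing columns {sorted(missing)}")
        dup = self.scores.duplicated(["participant_id", "subscale", "session"])
        if dup.any():
            raise ValueError("duplicate participant x subscale x session rows")

    def participants(self) -> list[str]:
        return sorted(self.scores["participant_id"].unique())


def zscore(table: NeuropsychTable) -> pd.DataFrame:
    """Normative z-scores, sign-flipped on higher-worse scales.

    Returns the long table with a ``z`` column where larger is always
    better: ``z = (raw - mean) / sd`` for higher-better scales and its
    negative for higher-worse scales (BDI, errors, misses, reaction
    times).
    """
    df = table.scores.copy()
    unknown = set(df["subscale"]) - set(table.norms)
    if unknown:
        raise ValueError(f"no norms for subscale(s) {sorted(unknown)}")
    mean = df["subscale"].map({k: v[0] for k, v in table.norms.items()})
    sd = df["subscale"].map({k: v[1] for k, v in table.norms.items()})
    sign = df["subscale"].map(
        {k: (1.0 if v[2] else -1.0) for k, v in table.norms.items()}
    )
    df["z"] = sign * (df["raw"] - mean) / sd
    return df


def _z_wide(zdf: pd.DataFrame, session: str) -> pd.DataFrame:
    sub = zdf[zdf["session"] == session]
    return sub.pivot(index="participant_id", columns="subscale", values="z")


def decline_labels(
    baseline: NeuropsychTable,
    followup: NeuropsychTable,
    domains: dict[str, DomainDefinition] | None = None,
    threshold_sd: float = DECLINE_SD_THRESHOLD,
) -> pd.DataFrame:
    """Binary decline label per participant and domain.

    Label 1 iff the z-change (followup - baseline) is ``<= -threshold_sd``
    on at least one member subscale of the domain.  Because higher-worse
    scales were sign-flipped during z-scoring, a worsening of depressive
    symptoms by one normative SD on the BDI triggers the depression label
    through the same rule.  Participants without follow-up are excluded
    with a log entry.
    """
    domains = domains or DEFAULT_DOMAINS
    zb = _z_wide(zscore(baseline), "baseline")
    zf = _z_wide(zscore(followup), "followup")
    common = zb.index.intersection(zf.index)
    dropped = zb.index.difference(zf.index)
    if len(dropped):
        logger.info(
            "%d participant(s) without follow-up excluded: %s",
            len(dropped), list(dropped),
        )
    change = zf.loc[common] - zb.loc[common]
    records = []
    for dom in domains.values():
        missing = [s for s in dom.subscales if s not in change.columns]
        if missing:
            raise ValueError(f"domain {dom.name} references unknown {missing}")
        hit = (change[list(dom.subscales)] <= -threshold_sd).any(axis=1)
        for pid, lab in hit.items():
            records.append((pid, dom.name, int(lab)))
    return pd.DataFrame(records, columns=["participant_id", "domain", "label"])


def baseline_features(baseline: NeuropsychTable) -> pd.DataFrame:
    """Per-participant baseline z-score vector, identifiers ``psy:<subscale>``."""
    zb = _z_wide(zscore(baseline), "baseline")
    zb.columns = [f"psy:{c}" for c in zb.columns]
    return zb.sort_index(axis=1)
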