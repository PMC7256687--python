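import numpy as np
import pandas as pd
import pytest

from neurodecline import synth


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny 2-group cohort with one planted domain effect (executive):
    scaled frontal->parietal coupling, shrunken regions 1-2, psy drop."""
    spec = synth.CohortSpec(
        groups={"MCI": 6, "HC": 6},
        decline_spec={
            "executive": synth.DomainEffect(
                fraction=0.5,
                coupling_scale=2.0,
                coupling_edges=(("F3", "P3"), ("F4", "P4")),
                mri_regions=(1, 2),
                mri_volume_scale=0.8,
            ),
            "depression": synth.DomainEffect(fraction=0.15),
        },
        eeg=synth.EEGSpec(
            n_channels=6,
            rest_duration_s=12.0,
            n_trials=4,
            coupling=(("F3", "P3", 2, 0.3), ("F4", "P4", 2, 0.3)),
        ),
        mri=synth.MRISpec(n_regions=8, shape=(24, 24, 20)),
        seed=11,
    )
    return synth.generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_sample_table(
    n_participants=20,
    n_segments=5,
    n_features=30,
    n_informative=3,
    effect=2.0,
    seed=0,
):
    """Participant-grouped feature table with planted informative columns."""
    rng = np.random.default_rng(seed)
    pids = [f"P{i:02d}" for i in range(n_participants)]
    labels = pd.Series([i % 2 for i in range(n_participants)], index=pids)
    rows = []
    for p in pids:
        base = rng.normal(0, 0.5, n_features)  # participant-level variation
        for _ in range(n_segments):
            x = base + rng.normal(0, 1, n_features)
            x[:n_informative] += effect * labels[p]
            rows.append([p, int(labels[p])] + list(x))
    cols = ["participant_id", "label"] + [f"f{j}" for j in range(n_features)]
    return pd.DataFrame(rows, columns=cols), labels
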