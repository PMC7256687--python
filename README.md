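# neurodecline

Multimodal prediction of 18-month decline in cognitive domains —
executive functions, visual-verbal memory, divided attention, and
worsening of depressive symptoms — from EEG connectivity, structural
MRI, and baseline neuropsychological testing.

The package is aimed at researchers studying progressive cognitive
decline across neurological populations (mild cognitive impairment,
subjective cognitive complaints, temporal lobe epilepsy, controls) who
want a tested, leakage-guarded implementation of the full analysis
chain, plus a synthetic-cohort generator so every stage can run and be
validated without access to clinical data.

## What it computes

**EEG → MVAR connectivity.** Recordings are rereferenced to linked
earlobes, filtered (zero-phase 1 Hz high-pass at 48 dB/oct, 50 Hz
notch), screened with three amplitude artifact rules (>50 µV/sample
steps ±100 ms; >200 µV range in 200 ms; <0.5 µV range in 100 ms
±500 ms), and cut into 1000 ms segments. Each segment is fitted with an
order-10 multivariate autoregressive model (Vieira–Morf lattice,
unbiased covariance scaling); from Ā(f) = I − Σₖ Aₖ e^(−i2πfk/fs),
H = Ā⁻¹ and S = H Σ Hᴴ on a 2–125 Hz grid the package derives
coherence (complex/real/imaginary), partial coherence, PDC / PDCF /
gPDC, DTF / ffDTF / dDTF, Geweke–Granger causality and the spectra,
averages them into the six classical bands (delta through high gamma),
and flattens the nonredundant entries into named feature vectors.

**MRI → region features.** From an intensity volume plus co-registered
integer labels: normalized volumetry (region volume / global brain
volume), orthogonal-plane 3D local-binary-pattern histograms (3 × 256
bins per region), and stationary-wavelet texture — each region ×
subband summarised by the (α, β) parameters of a fitted generalized
Gaussian density.

**Neuropsychology → labels and features.** Raw subscale scores become
normative z-scores (higher-worse scales sign-flipped); a participant
declines in a domain iff some member subscale drops by ≥ 1 normative SD
between baseline and 18-month follow-up. Baseline z-scores double as a
feature vector.

**Prediction.** One sample per EEG segment (participant-constant MRI /
neuropsychology columns replicated), linear 2-norm soft-margin SVM, and
a 3-layer nested cross-validation — outer 80/20 holdout, middle 5-fold
yielding feature-selection frequencies, inner 5-fold driving greedy
forward feature-subset selection capped at 30 features — with every
split grouped by participant and stratified by label. Sensitivity and
specificity are reported at segment and participant level; results are
flagged reportable only when both reach 70%.

## Worked example

```python
from neurodecline import synth, pipeline, prediction

spec = synth.CohortSpec(
    groups={"MCI": 8, "HC": 8},
    decline_spec={
        "executive": synth.DomainEffect(
            fraction=0.5, coupling_scale=2.0,
            coupling_edges=(("F3", "P3"), ("F4", "P4")),
            mri_regions=(1, 2), mri_volume_scale=0.8,
        ),
    },
    eeg=synth.EEGSpec(n_channels=6, rest_duration_s=20.0, n_trials=2,
                      coupling=(("F3", "P3", 2, 0.3), ("F4", "P4", 2, 0.3))),
    mri=synth.MRISpec(n_regions=8, shape=(24, 24, 20)),
    seed=101,
)
cohort = synth.generate_cohort(spec)
features = pipeline.extract_cohort_features(cohort, eeg_duration_s=21.0)
exp = pipeline.run_decline_experiment(
    cohort, domain="executive",
    cv_config=prediction.CVConfig(feature_cap=10, seed=5),
    features=features,
)
part = exp["report"]["participant_level"]
print(f"balanced accuracy {part['balanced_accuracy']:.1f}%  "
      f"sens {part['sensitivity']:.1f}%  spec {part['specificity']:.1f}%")
print("selection ratio (informative vs noise):",
      round(exp["selection_ratio"], 1))
print(exp["result"].selection_frequency.sort_values(ascending=False).head(4))
```

Output:

```
balanced accuracy 100.0%  sens 100.0%  spec 100.0%
selection ratio (informative vs noise): 56.6
PDC:gamma:F3->P3    4
PDC:gamma:F4->P4    4
PDC:delta:F4->C4    1
psy:rwt_semantic_fluency    1
dtype: int64
```

The cohort plants an executive-decline signature (doubled F3→P3 and
F4→P4 coupling, shrunken regions 1–2); the nested CV recovers exactly
the planted connectivity edges as its most consistently selected
features (4 of 5 middle runs) and classifies the held-out participants
perfectly, while the mean selection frequency of planted features
exceeds that of the ~200 noise features ~57-fold. Under label
permutation the same pipeline scores ≈ 50% — the leakage guards hold.

A `neurodecline` command-line interface wraps the same workflow
(`simulate`, `features`, `predict`, `report`) driven by one YAML config.

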