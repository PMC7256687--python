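"""Synthetic multimodal cohorts with known ground truth.

Generates, from one root seed, a cohort of participants in five
diagnostic groups (MCI, SCC, right/left temporal lobe epilepsy, healthy
controls) with

* task EEG realised from a stable MVAR process (17 channels at 500 Hz by
  default) with a configurable directed coupling graph and optional
  injected artifacts,
* labeled pseudo-MRI volumes (ellipsoidal parcels on a jittered grid)
  with region-specific intensity textures,
* baseline/follow-up neuropsychological tables with planted >= 1 SD
  declines in configurable domains.

Participants who decline in a domain carry a recoverable multimodal
signature: designated coupling strengths are scaled in their EEG,
designated regions are shrunk and their texture altered in the MRI, and
one domain subscale drops by the planted amount at follow-up.  The
returned :class:`GroundTruth` records the planted labels, the modulated
coupling edges and the affected regions, enabling known-answer tests of
the downstream feature-selection machinery.

All randomness derives from ``CohortSpec.seed`` through a fixed
``numpy.random.SeedSequence`` spawning scheme (one child per modality,
then one grandchild per participant, in participant order), so the same
spec is bit-identical across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import neuropsych as npsy
from .connectivity import MVARStabilityError
from .preprocess import DEFAULT_CHANNELS, EEGRecording, Event

#: Group sizes of the emulated sample (MCI, SCC, TLE right/left, controls).
DEFAULT_GROUPS: dict[str, int] = {
    "MCI": 19, "SCC": 4, "TLEr": 6, "TLEl": 3, "HC": 18,
}

#: Directed coupling graph: (source, target, lag, strength).
DEFAULT_COUPLING: list[tuple[str, str, int, float]] = [
    ("F3", "P3", 2, 0.30),
    ("F4", "P4", 2, 0.30),
    ("Cz", "Pz", 1, 0.25),
]


@dataclass(frozen=True)
class EEGSpec:
    n_channels: int = 17
    fs: float = 500.0
    rest_duration_s: float = 180.0
    n_trials: int = 72
    trial_interval_s: float = 3.0  # stimulus + response + 1 s intertrial gap
    conditions: tuple[str, ...] = ("rest", "learning", "recall", "recognition")
    coupling: tuple[tuple[str, str, int, float], ...] = tuple(DEFAULT_COUPLING)
    ar_resonance_hz: float = 10.0  # alpha-band oscillatory pole per channel
    ar_pole_radius: float = 0.7  # modest resonance, keeps amplitudes in EEG range
    innovation_sd_uv: float = 2.0
    observation_noise_sd_uv: float = 1.0


@dataclass(frozen=True)
class MRISpec:
    n_regions: int = 83
    shape: tuple[int, int, int] = (50, 50, 40)
    voxel_size_mm: float = 1.0
    base_intensity: float = 100.0
    intensity_step: float = 1.0  # per-region mean offset
    noise_sd: float = 8.0
    texture_smoothing: float = 1.0  # voxels; 0 = white noise
    volume_jitter: float = 0.10  # SD of per-participant radius scaling


@dataclass(frozen=True)
class ArtifactSpec:
    rate_per_minute: float = 0.0
    step_amplitude_uv: float = 300.0
    excursion_amplitude_uv: float = 400.0
    flat_duration_ms: float = 150.0
    kinds: tuple[str, ...] = ("step", "excursion", "flat")


@dataclass(frozen=True)
class DomainEffect:
    """How decline in one domain manifests across modalities."""

    fraction: float  # share of participants who decline
    psy_drop_sd: float = 1.5  # planted z-drop on one member subscale
    coupling_scale: float = 1.0  # multiplier on designated EEG edges
    coupling_edges: tuple[tuple[str, str], ...] = ()
    mri_regions: tuple[int, ...] = ()
    mri_volume_scale: float = 1.0  # radius scaling of affected regions
    mri_texture_scale: float = 1.0  # noise-amplitude scaling


def default_decline_spec() -> dict[str, DomainEffect]:
    """Per-domain decliner fractions mirroring the emulated sample
    (executive 27/50, memory 23/50, attention 23/47, depression 7/47),
    each with a moderate multimodal signature."""
    return {
        "executive": DomainEffect(
            fraction=0.54, coupling_scale=1.8,
            coupling_edges=(("F3", "P3"), ("F4", "P4")),
            mri_regions=(1, 2, 3), mri_volume_scale=0.85,
        ),
        "visual_verbal_memory": DomainEffect(
            fraction=0.46, mri_regions=(4, 5), mri_texture_scale=1.6,
        ),
        "divided_attention": DomainEffect(
            fraction=0.49, coupling_scale=1.5,
            coupling_edges=(("Cz", "Pz"),),
            mri_regions=(6, 7), mri_volume_scale=0.9,
        ),
        "depression": DomainEffect(fraction=0.15),
    }


@dataclass(frozen=True)
class CohortSpec:
    groups: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    decline_spec: dict[str, DomainEffect] = field(
        default_factory=default_decline_spec
    )
    eeg: EEGSpec = field(default_factory=EEGSpec)
    mri: MRISpec = field(default_factory=MRISpec)
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, eff in self.decline_spec.items():
            if not 0.0 <= eff.fraction <= 1.0:
                raise ValueError(f"decline fraction for {name} outside [0, 1]")
        if self.eeg.n_trials < 1:
            raise ValueError("need at least one trial per condition")
        if self.eeg.fs <= 2 * 125:
            raise ValueError("sampling rate must exceed twice the top analysis frequency")


@dataclass
class GroundTruth:
    """Planted structure: labels, informative features, coupling graph."""

    decline_labels: pd.DataFrame  # participant_id, domain, label
    informative_features: dict[str, list[str]]  # domain -> feature ids
    coupling: list[tuple[str, str, int, float]]
    planted_subscale: dict[str, str]  # "participant:domain" -> planted subscale


# ---------------------------------------------------------------------------
# EEG

def _build_coefficients(
    coupling: list[tuple[str, str, int, float]],
    channel_names: list[str],
    spec: EEGSpec,
) -> np.ndarray:
    m = len(channel_names)
    order = max([lag for _, _, lag, _ in coupling], default=0)
    order = max(order, 2)
    coeffs = np.zeros((order, m, m))
    theta = 2 * np.pi * spec.ar_resonance_hz / spec.fs
    r = spec.ar_pole_radius
    coeffs[0] += np.eye(m) * 2 * r * np.cos(theta)
    coeffs[1] -= np.eye(m) * r**2
    idx = {ch: i for i, ch in enumerate(channel_names)}
    for src, dst, lag, strength in coupling:
        coeffs[lag - 1, idx[dst], idx[src]] += strength
    return coeffs


def _spectral_radius(coeffs: np.ndarray) -> float:
    p, m, _ = coeffs.shape
    comp = np.zeros((p * m, p * m))
    comp[:m] = np.concatenate(list(coeffs), axis=1)
    if p > 1:
        comp[m:, : (p - 1) * m] = np.eye((p - 1) * m)
    return float(np.abs(np.linalg.eigvals(comp)).max())


def generate_mvar_eeg(
    coupling: list[tuple[str, str, int, float]],
    n_channels: int = 17,
    fs: float = 500.0,
    duration_s: float = 180.0,
    seed: int | np.random.SeedSequence = 0,
    spec: EEGSpec | None = None,
    events: list[Event] | None = None,
    participant_id: str = "",
) -> EEGRecording:
    """Realise a stable MVAR process as a zero-mean multichannel recording.

    Every channel carries an oscillatory AR(2) pole (alpha-band resonance
    by default); the directed ``coupling`` entries add off-diagonal
    coefficients at their lag.  White observation noise is added on top.
    Raises :class:`MVARStabilityError` for unstable coefficient sets.
    """
    spec = spec or EEGSpec(n_channels=n_channels, fs=fs)
    channel_names = (
        DEFAULT_CHANNELS[:n_channels]
        if n_channels <= len(DEFAULT_CHANNELS)
        else [f"ch{i}" for i in range(n_channels)]
    )
    coeffs = _build_coefficients(list(coupling), channel_names, spec)
    rho = _spectral_radius(coeffs)
    if rho >= 1.0:
        raise MVARStabilityError(
            f"coupling yields an unstable process (spectral radius {rho:.3f})"
        )
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    burn = 1000
    p = coeffs.shape[0]
    m = n_channels
    x = np.zeros((m, n + burn))
    e = rng.normal(0.0, spec.innovation_sd_uv, size=(m, n + burn))
    for t in range(p, n + burn):
        acc = e[:, t]
        for k in range(1, p + 1):
            acc = acc + coeffs[k - 1] @ x[:, t - k]
        x[:, t] = acc
    sig = x[:, burn:]
    if spec.observation_noise_sd_uv > 0:
        sig = sig + rng.normal(0.0, spec.observation_noise_sd_uv, size=sig.shape)
    return EEGRecording(
        signal=sig, fs=fs, channel_names=channel_names,
        reference="synthetic", events=events or [], participant_id=participant_id,
    )


def task_events(spec: EEGSpec, session: int = 1) -> tuple[list[Event], float]:
    """Event list and total duration for one session's block structure."""
    events = [Event(sample=0, condition="rest", session=session)]
    t = spec.rest_duration_s
    conditions = [c for c in spec.conditions if c != "rest"]
    if session > 1:
        conditions = [c for c in conditions if c != "learning"]
    for cond in conditions:
        for _ in range(spec.n_trials):
            events.append(
                Event(sample=int(round(t * spec.fs)), condition=cond, session=session)
            )
            t += spec.trial_interval_s
    return events, t + 1.0  # headroom so the last segment fits


def inject_artifacts(
    recording: EEGRecording,
    artifact_spec: ArtifactSpec,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[EEGRecording, list[tuple[int, str]]]:
    """Superimpose step / high-amplitude / flat artifacts at random times.

    Returns the contaminated recording and the ground-truth list of
    (sample, kind) insertion points.  A zero rate returns the recording
    unchanged.  Amplitudes below the detector thresholds trigger a
    warning: such events are undetectable by design.
    """
    if artifact_spec.rate_per_minute <= 0:
        return recording, []
    if artifact_spec.step_amplitude_uv <= 50.0:
        warnings.warn("step amplitude at or below the 50 uV/sample threshold")
    if artifact_spec.excursion_amplitude_uv <= 200.0:
        warnings.warn("excursion amplitude at or below the 200 uV threshold")
    rng = np.random.default_rng(seed)
    fs = recording.fs
    n = recording.n_samples
    n_events = rng.poisson(artifact_spec.rate_per_minute * n / fs / 60.0)
    sig = recording.signal.copy()
    truth: list[tuple[int, str]] = []
    margin = int(fs)  # keep artifacts clear of the recording edges
    for _ in range(n_events):
        kind = artifact_spec.kinds[rng.integers(len(artifact_spec.kinds))]
        t0 = int(rng.integers(margin, max(n - margin, margin + 1)))
        ch = int(rng.integers(sig.shape[0]))
        if kind == "step":
            sig[ch, t0:] += artifact_spec.step_amplitude_uv
        elif kind == "excursion":
            width = int(round(0.150 * fs))
            bump = artifact_spec.excursion_amplitude_uv * np.hanning(width)
            sig[ch, t0 : t0 + width] += bump[: max(0, min(width, n - t0))]
        elif kind == "flat":
            width = int(round(artifact_spec.flat_duration_ms / 1000.0 * fs))
            sig[ch, t0 : t0 + width] = sig[ch, t0]
        truth.append((t0, kind))
    out = EEGRecording(
        signal=sig, fs=fs, channel_names=list(recording.channel_names),
        reference=recording.reference, events=list(recording.events),
        participant_id=recording.participant_id,
    )
    return out, truth


# ---------------------------------------------------------------------------
# MRI

def generate_labeled_volume(
    mri_spec: MRISpec,
    participant_effect: dict[int, tuple[float, float]] | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Ellipsoidal parcels on a jittered grid plus a textured intensity volume.

    ``participant_effect`` maps region id -> (radius_scale, texture_scale);
    decliner participants receive their domain's shrinkage/texture shift
    through it.  Returns (intensity float array, labels int16 array).
    Raises when the requested regions cannot be packed into the grid.
    """
    rng = np.random.default_rng(seed)
    shape = mri_spec.shape
    if min(shape) < 16:
        raise ValueError("volume dimensions must be at least 16 voxels")
    n = mri_spec.n_regions
    if n < 1:
        raise ValueError("label set must be nonempty")
    effect = participant_effect or {}

    # grid dimensioning: enough cells, roughly isotropic
    grid = [1, 1, 1]
    while grid[0] * grid[1] * grid[2] < n:
        ax = int(np.argmax([shape[i] / grid[i] for i in range(3)]))
        grid[ax] += 1
    cell = [shape[i] // grid[i] for i in range(3)]
    if min(cell) < 4:
        raise ValueError(
            f"cannot pack {n} regions into volume of shape {shape}: "
            f"cell size {cell} too small"
        )

    labels = np.zeros(shape, dtype=np.int16)
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    cells = [
        (i, j, k)
        for i in range(grid[0]) for j in range(grid[1]) for k in range(grid[2])
    ][:n]
    for region, (ci, cj, ck) in enumerate(cells, start=1):
        center = np.array([
            (ci + 0.5) * cell[0], (cj + 0.5) * cell[1], (ck + 0.5) * cell[2],
        ])
        center += rng.uniform(-0.08, 0.08, size=3) * np.array(cell)
        radii = np.array(cell) * rng.uniform(0.30, 0.44, size=3)
        rscale, _ = effect.get(region, (1.0, 1.0))
        radii = np.maximum(radii * rscale, 1.0)
        d = (
            ((zz - center[0]) / radii[0]) ** 2
            + ((yy - center[1]) / radii[1]) ** 2
            + ((xx - center[2]) / radii[2]) ** 2
        )
        inside = d <= 1.0
        if (labels[inside] != 0).any():
            raise ValueError(f"region {region} overlaps an existing parcel")
        labels[inside] = region

    intensity = np.zeros(shape, dtype=float)
    noise = rng.normal(0.0, 1.0, size=shape)
    if mri_spec.texture_smoothing > 0:
        from scipy.ndimage import gaussian_filter

        noise = gaussian_filter(noise, mri_spec.texture_smoothing)
        noise /= max(noise.std(), 1e-12)
    background = rng.normal(0.0, 0.25 * mri_spec.noise_sd, size=shape)
    intensity += background
    for region in range(1, n + 1):
        mask = labels == region
        _, tscale = effect.get(region, (1.0, 1.0))
        intensity[mask] = (
            mri_spec.base_intensity
            + region * mri_spec.intensity_step
            + mri_spec.noise_sd * tscale * noise[mask]
        )
    return intensity.astype(np.float32), labels


# ---------------------------------------------------------------------------
# Neuropsychology

def generate_neuropsych(
    participants: pd.DataFrame,
    decline: pd.DataFrame,
    norms: dict[str, tuple[float, float, bool]],
    domains: dict[str, npsy.DomainDefinition],
    seed: int | np.random.SeedSequence = 0,
    psy_drop_sd: dict[str, float] | None = None,
) -> tuple[npsy.NeuropsychTable, npsy.NeuropsychTable, dict[str, str]]:
    """Baseline and follow-up tables realising the requested decline labels.

    Decliners receive a drop of ``psy_drop_sd`` (>= 1) normative SDs on
    one subscale that belongs exclusively to their domain; every other
    change is drawn strictly inside (-1, 1) SD, so computed labels agree
    with the planted ones for all participants.
    """
    rng = np.random.default_rng(seed)
    psy_drop_sd = psy_drop_sd or {}
    subscales = list(norms)
    # subscales usable for planting: unique to their domain
    usage: dict[str, list[str]] = {}
    for dom in domains.values():
        for s in dom.subscales:
            usage.setdefault(s, []).append(dom.name)
    exclusive = {
        d.name: [s for s in d.subscales if len(usage[s]) == 1]
        for d in domains.values()
    }
    for dname, subs in exclusive.items():
        if dname in set(decline["domain"]) and not subs:
            raise ValueError(
                f"domain {dname} has no exclusive subscale to plant a decline on"
            )

    group_offset = {"MCI": -0.8, "SCC": -0.2, "TLEr": -0.5, "TLEl": -0.5, "HC": 0.0}
    rows_b, rows_f = [], []
    planted: dict[str, str] = {}
    lab = decline.pivot(index="participant_id", columns="domain", values="label")
    for _, prow in participants.iterrows():
        pid, group = prow["participant_id"], prow["group"]
        zb = group_offset.get(group, 0.0) + rng.normal(0.0, 0.8, size=len(subscales))
        dz = rng.uniform(-0.6, 0.6, size=len(subscales))
        if pid in lab.index:
            for dname in lab.columns:
                if lab.loc[pid, dname] == 1:
                    choice = exclusive[dname]
                    sub = choice[rng.integers(len(choice))]
                    drop = psy_drop_sd.get(dname, 1.5)
                    if drop < 1.0:
                        raise ValueError("planted drop must be at least 1 SD")
                    dz[subscales.index(sub)] = -drop
                    planted[f"{pid}:{dname}"] = sub
        for si, sub in enumerate(subscales):
            mean, sd, better = norms[sub]
            sign = 1.0 if better else -1.0
            rows_b.append((pid, group, "baseline", sub, mean + sign * zb[si] * sd))
            rows_f.append(
                (pid, group, "followup", sub, mean + sign * (zb[si] + dz[si]) * sd)
            )
    cols = ["participant_id", "group", "session", "subscale", "raw"]
    base = npsy.NeuropsychTable(pd.DataFrame(rows_b, columns=cols), dict(norms))
    follow = npsy.NeuropsychTable(pd.DataFrame(rows_f, columns=cols), dict(norms))
    return base, follow, planted


# ---------------------------------------------------------------------------
# Cohort assembly

@dataclass
class Cohort:
    """A generated cohort; EEG and MRI are realised lazily per participant."""

    spec: CohortSpec
    participants: pd.DataFrame  # participant_id, group
    baseline: npsy.NeuropsychTable
    followup: npsy.NeuropsychTable
    ground_truth: GroundTruth
    _eeg_seeds: dict[str, np.random.SeedSequence] = field(repr=False, default_factory=dict)
    _mri_seeds: dict[str, np.random.SeedSequence] = field(repr=False, default_factory=dict)

    def _labels_of(self, pid: str) -> dict[str, int]:
        gt = self.ground_truth.decline_labels
        sub = gt[gt["participant_id"] == pid]
        return dict(zip(sub["domain"], sub["label"]))

    def participant_coupling(self, pid: str) -> list[tuple[str, str, int, float]]:
        """Coupling graph with decliner edges scaled per the decline spec."""
        labels = self._labels_of(pid)
        scale: dict[tuple[str, str], float] = {}
        for dname, eff in self.spec.decline_spec.items():
            if labels.get(dname, 0) == 1:
                for edge in eff.coupling_edges:
                    scale[edge] = scale.get(edge, 1.0) * eff.coupling_scale
        return [
            (s, d, lag, w * scale.get((s, d), 1.0))
            for s, d, lag, w in self.spec.eeg.coupling
        ]

    def eeg_recording(
        self, pid: str, session: int = 1, duration_s: float | None = None
    ) -> EEGRecording:
        events, total = task_events(self.spec.eeg, session=session)
        if duration_s is not None:
            total = duration_s
            events = [ev for ev in events if ev.sample < int(total * self.spec.eeg.fs)]
        rec = generate_mvar_eeg(
            self.participant_coupling(pid),
            n_channels=self.spec.eeg.n_channels,
            fs=self.spec.eeg.fs,
            duration_s=total,
            seed=self._eeg_seeds[pid],
            spec=self.spec.eeg,
            events=events,
            participant_id=pid,
        )
        if self.spec.artifacts.rate_per_minute > 0:
            rec, _ = inject_artifacts(
                rec, self.spec.artifacts, seed=self._eeg_seeds[pid].spawn(1)[0]
            )
        return rec

    def labeled_volume(self, pid: str) -> tuple[np.ndarray, np.ndarray]:
        labels = self._labels_of(pid)
        effect: dict[int, tuple[float, float]] = {}
        for dname, eff in self.spec.decline_spec.items():
            if labels.get(dname, 0) == 1:
                for region in eff.mri_regions:
                    prev = effect.get(region, (1.0, 1.0))
                    effect[region] = (
                        prev[0] * eff.mri_volume_scale,
                        prev[1] * eff.mri_texture_scale,
                    )
        return generate_labeled_volume(
            self.spec.mri, participant_effect=effect, seed=self._mri_seeds[pid]
        )


def _informative_features(spec: CohortSpec) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for dname, eff in spec.decline_spec.items():
        feats: list[str] = []
        # a scaled coupling edge shifts PDC at every frequency (the
        # coefficient polynomial changes globally), so all bands of the
        # planted ordered pair are informative
        bands = ("delta", "theta", "alpha", "beta", "gamma", "high_gamma")
        for src, dst in eff.coupling_edges:
            for band in bands:
                feats.append(f"PDC:{band}:{src}->{dst}")
        for region in eff.mri_regions:
            if eff.mri_volume_scale != 1.0:
                feats.append(f"vol:{region}")
            if eff.mri_texture_scale != 1.0:
                feats.append(f"swt:{region}:L1:ddd:alpha")
        out[dname] = feats
    return out


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Deterministically realise a full cohort from one root seed."""
    root = np.random.SeedSequence(spec.seed)
    ss_psy, ss_mri, ss_eeg, ss_assign = root.spawn(4)
    rng = np.random.default_rng(ss_assign)

    pids, groups = [], []
    for gname, gsize in spec.groups.items():
        for i in range(gsize):
            pids.append(f"{gname}{i + 1:02d}")
            groups.append(gname)
    participants = pd.DataFrame({"participant_id": pids, "group": groups})

    records = []
    for dname, eff in spec.decline_spec.items():
        n_decl = int(round(eff.fraction * len(pids)))
        chosen = set(rng.permutation(len(pids))[:n_decl])
        for i, pid in enumerate(pids):
            records.append((pid, dname, int(i in chosen)))
    decline = pd.DataFrame(records, columns=["participant_id", "domain", "label"])

    drops = {d: e.psy_drop_sd for d, e in spec.decline_spec.items()}
    base, follow, planted = generate_neuropsych(
        participants, decline, npsy.DEFAULT_NORMS, npsy.DEFAULT_DOMAINS,
        seed=ss_psy, psy_drop_sd=drops,
    )
    gt = GroundTruth(
        decline_labels=decline,
        informative_features=_informative_features(spec),
        coupling=list(spec.eeg.coupling),
        planted_subscale=planted,
    )
    eeg_children = ss_eeg.spawn(len(pids))
    mri_children = ss_mri.spawn(len(pids))
    return Cohort(
        spec=spec,
        participants=participants,
        baseline=base,
        followup=follow,
        ground_truth=gt,
        _eeg_seeds=dict(zip(pids, eeg_children)),
        _mri_seeds=dict(zip(pids, mri_children)),
    )
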