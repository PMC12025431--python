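"""Synthetic resting-state EEG with known microstate structure.

Real microstate sequences have dwell times of roughly 60-100 ms whose
dispersion is far narrower than the geometric dwell of a per-sample Markov
chain, so class labels are generated by an explicit semi-Markov process:
gamma-distributed dwell times per visit (shape 4 by default) and a zero-
diagonal transition matrix between classes. Each segment projects one of K
template topographies onto the sensors, amplitude-modulated by a rectified
10 Hz sinusoid (a GFP-like envelope with a random phase per segment), with a
random polarity flip per segment — so any accidentally polarity-sensitive
analysis code fails loudly — plus i.i.d. Gaussian sensor noise.

Defaults emulate the study conditions this package targets: 64 channels,
120 s records at 500 Hz, four classes with mean dwell times taken from the
sham-condition parameter regime, and an envelope-peak GFP of 10 µV against
2 µV sensor noise (SNR 5). Matched ground truth (templates, label sequence,
parameters, per-segment signs) is retained for every generated recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd

from .clustering import TemplateSet, spatial_correlation
from .recording_io import Montage, Recording, RecordingError
from .segmentation import (LabelSequence, MicrostateParams, change_rate,
                           compute_params)

CLASS_NAMES = ("A", "B", "C", "D")


# ---------------------------------------------------------------------------
# Montage and canonical maps
# ---------------------------------------------------------------------------

def disk_montage(n_channels: int = 64) -> Montage:
    """Sunflower (Fermat spiral) sensor layout on the unit head disk.

    Labels are ``E01 .. E<n>``. Deterministic in ``n_channels``.
    """
    if n_channels < 2:
        raise RecordingError("montage needs >= 2 channels")
    golden = np.pi * (3.0 - np.sqrt(5.0))
    i = np.arange(n_channels)
    r = 0.95 * np.sqrt((i + 0.5) / n_channels)
    theta = i * golden
    width = len(str(n_channels))
    positions = {
        f"E{j + 1:0{width}d}": (float(r[j] * np.cos(theta[j])),
                                float(r[j] * np.sin(theta[j])))
        for j in range(n_channels)
    }
    return Montage(positions=positions)


def mirror_montage(montage: Montage) -> Montage:
    """Left-right mirrored copy (x -> -x) of a montage."""
    return Montage(positions={c: (-x, y)
                              for c, (x, y) in montage.positions.items()})


def _unit_map(values: np.ndarray) -> np.ndarray:
    v = values - values.mean()
    n = np.linalg.norm(v)
    if n == 0:
        raise RecordingError("degenerate canonical map")
    return v / n


# Class A/B gradient axes sit 60 degrees off the anterior-posterior axis:
# steep enough to keep |r| with the pure anterior-posterior class-C map at
# 0.5 on a left-right symmetric montage while remaining diagonal gradients.
_AB_TILT = np.deg2rad(60.0)


def make_canonical_templates(montage: Montage, K: int = 4,
                             seed: int | np.random.Generator | None = 0,
                             channels: list[str] | None = None) -> TemplateSet:
    """Canonical microstate topographies on a montage.

    Class A: right-frontal to left-posterior gradient; Class B its left-right
    mirror; Class C: midline anterior-posterior gradient; Class D: radial
    frontocentral maximum. For K > 4, random smooth maps orthogonalized
    against the existing set are appended. All maps are zero-mean, unit-norm,
    with pairwise |spatial correlation| < 0.6.
    """
    if channels is None:
        channels = sorted(montage.positions)
    coords = montage.coords(channels)
    x, y = coords[:, 0], coords[:, 1]
    if K < 2:
        raise RecordingError("K must be >= 2")

    base = [
        np.sin(_AB_TILT) * x + np.cos(_AB_TILT) * y,    # A
        -np.sin(_AB_TILT) * x + np.cos(_AB_TILT) * y,   # B
        y,                                              # C
        np.exp(-((x - 0.0) ** 2 + (y - 0.25) ** 2) / (2 * 0.4**2)),  # D
    ]
    maps = [_unit_map(m) for m in base[:min(K, 4)]]

    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    while len(maps) < K:
        # random smooth bump mixture, orthogonalized in zero-mean map space
        cand = np.zeros_like(x)
        for _ in range(3):
            cx, cy = rng.uniform(-0.7, 0.7, size=2)
            w = rng.uniform(0.25, 0.5)
            cand += rng.normal() * np.exp(-((x - cx) ** 2 + (y - cy) ** 2)
                                          / (2 * w**2))
        cand = cand - cand.mean()
        for m in maps:
            cand = cand - (cand @ m) * m
        norm = np.linalg.norm(cand)
        if norm < 1e-6:
            continue
        cand = _unit_map(cand / norm)
        if max(abs(spatial_correlation(cand, m)) for m in maps) < 0.6:
            maps.append(cand)

    labels = [CLASS_NAMES[i] if i < 4 else f"X{i - 3}" for i in range(K)]
    return TemplateSet(templates=np.vstack(maps), channels=list(channels),
                       labels=labels)


def orthogonalized_templates(ts: TemplateSet) -> TemplateSet:
    """Gram-Schmidt orthogonalization of a template set in zero-mean space.

    Requires linearly independent rows. Note the canonical maps are NOT
    independent: A, B and C are all linear gradients of the head-plane
    coordinates (A + B is proportional to C), so orthogonalize only
    independent subsets or augmented sets.
    """
    out = []
    for row in ts.templates:
        v = row.copy()
        for m in out:
            v -= (v @ m) * m
        v = v - v.mean()
        n = np.linalg.norm(v)
        if n < 1e-9:
            raise RecordingError("templates not linearly independent")
        out.append(v / n)
    return TemplateSet(templates=np.vstack(out), channels=list(ts.channels),
                       labels=list(ts.labels))


# ---------------------------------------------------------------------------
# Generator specification
# ---------------------------------------------------------------------------

def _uniform_transitions(K: int) -> np.ndarray:
    t = np.full((K, K), 1.0 / (K - 1))
    np.fill_diagonal(t, 0.0)
    return t


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic recording.

    ``mean_durations`` are per-class mean dwell times in ms;
    ``duration_shape`` the gamma shape (dispersion) of the dwell law;
    ``amplitude`` is the envelope-peak GFP of the noiseless signal in µV and
    ``noise_sd`` the per-channel sensor noise SD in µV, so amplitude/noise_sd
    is the peak GFP signal-to-noise ratio.
    """

    n_channels: int = 64
    montage: Montage | None = None
    K: int = 4
    mean_durations: tuple[float, ...] = (70.95, 73.52, 86.90, 79.82)
    duration_shape: float = 4.0
    transition_matrix: np.ndarray | None = None
    envelope_freq: float = 10.0
    noise_sd: float = 2.0
    amplitude: float = 10.0
    length: float = 120.0
    srate: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.montage is None:
            self.montage = disk_montage(self.n_channels)
        if self.transition_matrix is None:
            self.transition_matrix = _uniform_transitions(self.K)
        self.transition_matrix = np.asarray(self.transition_matrix, float)
        t = self.transition_matrix
        if t.shape != (self.K, self.K):
            raise RecordingError("transition matrix must be K x K")
        if np.any(np.abs(np.diag(t)) > 0):
            raise RecordingError("transition matrix diagonal must be zero")
        if np.any(np.abs(t.sum(axis=1) - 1.0) > 1e-9):
            raise RecordingError("transition rows must sum to 1")
        if len(self.mean_durations) != self.K:
            raise RecordingError("one mean duration per class required")
        if any(d <= 0 for d in self.mean_durations):
            raise RecordingError("mean durations must be positive")
        n_samples = self.length * self.srate
        max_dur_samples = max(self.mean_durations) * self.srate / 1000.0
        if n_samples < 10 * max_dur_samples:
            raise RecordingError("record too short for the dwell times")

    @property
    def n_samples(self) -> int:
        return int(round(self.length * self.srate))

    @property
    def channels(self) -> list[str]:
        return sorted(self.montage.positions)[:self.n_channels]


@dataclass
class SyntheticGroundTruth:
    """Everything recovery is scored against."""

    templates: TemplateSet
    labels: LabelSequence
    params: MicrostateParams
    segment_signs: np.ndarray = field(default_factory=lambda: np.array([]))


# ---------------------------------------------------------------------------
# Label and signal generation
# ---------------------------------------------------------------------------

def sample_labels(spec: SyntheticSpec,
                  rng: np.random.Generator | None = None) -> LabelSequence:
    """Draw a semi-Markov label sequence.

    The initial class is uniform; each visit's dwell is gamma-distributed
    with the class mean and ``duration_shape``, discretized to >= 1 sample;
    the successor class follows the transition row. Truncated at
    ``length * srate`` samples.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n = spec.n_samples
    means = np.asarray(spec.mean_durations, float)
    scale_ms = means / spec.duration_shape
    out = np.empty(n, dtype=int)
    pos = 0
    cls = int(rng.integers(spec.K))
    while pos < n:
        dwell_ms = rng.gamma(spec.duration_shape, scale_ms[cls])
        dwell = max(1, int(round(dwell_ms * spec.srate / 1000.0)))
        end = min(n, pos + dwell)
        out[pos:end] = cls
        pos = end
        cls = int(rng.choice(spec.K, p=spec.transition_matrix[cls]))
    return LabelSequence(labels=out, srate=spec.srate, K=spec.K)


def _render(labels: LabelSequence, templates: TemplateSet,
            spec: SyntheticSpec, rng: np.random.Generator
            ) -> tuple[Recording, np.ndarray]:
    from .segmentation import segments_of

    n = len(labels)
    c = templates.templates.shape[1]
    t_sec = np.arange(n) / spec.srate
    envelope = np.empty(n)
    sign = np.empty(n)
    runs = segments_of(labels).runs
    seg_signs = np.empty(len(runs))
    for i, (s, e, _) in enumerate(runs):
        phi = rng.uniform(0.0, 2.0 * np.pi)
        seg_signs[i] = 1.0 if rng.random() < 0.5 else -1.0
        envelope[s:e] = np.abs(np.sin(2.0 * np.pi * spec.envelope_freq
                                      * t_sec[s:e] + phi))
        sign[s:e] = seg_signs[i]
    # scale templates to unit spatial SD so `amplitude` is the signal GFP
    t_gfp = templates.templates * np.sqrt(c)
    signal = (sign * spec.amplitude * envelope)[:, None] * t_gfp[labels.labels]
    noise = (rng.normal(0.0, spec.noise_sd, size=(n, c))
             if spec.noise_sd > 0 else 0.0)
    rec = Recording(data=(signal + noise).T, srate=spec.srate,
                    channels=list(templates.channels),
                    reference="synthetic zero-mean")
    return rec, seg_signs


def render_eeg(labels: LabelSequence, templates: TemplateSet,
               spec: SyntheticSpec,
               rng: np.random.Generator | None = None) -> Recording:
    """Render a label sequence into sensor-space EEG (see module docstring)."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 1)
    rec, _ = _render(labels, templates, spec, rng)
    return rec


def generate_recording(spec: SyntheticSpec,
                       templates: TemplateSet | None = None,
                       rng: np.random.Generator | None = None
                       ) -> tuple[Recording, SyntheticGroundTruth]:
    """One synthetic recording plus its matched ground truth."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    if templates is None:
        templates = make_canonical_templates(spec.montage, spec.K, seed=rng,
                                             channels=spec.channels)
    labels = sample_labels(spec, rng)
    rec, signs = _render(labels, templates, spec, rng)
    truth = SyntheticGroundTruth(templates=templates, labels=labels,
                                 params=compute_params(labels),
                                 segment_signs=signs)
    return rec, truth


# ---------------------------------------------------------------------------
# Full pre/post study
# ---------------------------------------------------------------------------

@dataclass
class BehaviorModel:
    """Generative model of the behavioral table.

    The three-back reaction-time change rate is linearly coupled to the
    participant's Class-C coverage change rate:
    ``delta_rt = rt_slope * delta_cov_C + N(0, rt_noise_sd)``. Accuracy
    improves by ``acc_gain`` on average, independently of the EEG.
    """

    rt_slope: float = 1.0
    rt_noise_sd: float = 0.02
    base_rt: dict = field(default_factory=lambda: {"two-back": 650.0,
                                                   "three-back": 800.0})
    base_acc: dict = field(default_factory=lambda: {"two-back": 0.90,
                                                    "three-back": 0.82})
    acc_gain: float = 0.03
    acc_noise_sd: float = 0.02


@dataclass
class StudyRecord:
    participant: str
    group: str
    stage: str
    recording: Recording | None
    ground_truth: SyntheticGroundTruth


@dataclass
class StudyData:
    records: list[StudyRecord]
    behavior: pd.DataFrame


def default_study_specs() -> tuple[SyntheticSpec, dict[str, SyntheticSpec]]:
    """Baseline spec and per-group post-stimulation specs.

    The baseline uses the sham-condition dwell times; post-stage specs shift
    the per-class means in the directions the study design emulates
    (triangular: Class C shortened, Classes B/D lengthened; sine: Class D
    lengthened).
    """
    pre = SyntheticSpec()
    post = {
        "sham": replace(pre),
        "sine": replace(pre, mean_durations=(65.72, 68.04, 84.84, 96.70)),
        "triangular": replace(pre, mean_durations=(67.92, 73.59, 71.72, 92.92)),
    }
    return pre, post


def generate_study(pre_spec: SyntheticSpec | None = None,
                   post_spec_by_group: dict[str, SyntheticSpec] | None = None,
                   n_per_group: dict[str, int] | int | None = None,
                   behavior_model: BehaviorModel | None = None,
                   seed: int = 0,
                   render: bool = True,
                   participant_jitter_sd: float = 0.05) -> StudyData:
    """Generate the 3-group pre/post synthetic study.

    Per participant, the class mean-dwell times of both stages are jittered
    by a shared lognormal factor (a stable participant trait), one pre and
    one post recording are generated, and behavioral rows for both n-back
    tasks are drawn from :class:`BehaviorModel`. Set ``render=False`` to
    skip sensor-space rendering (label sequences and ground-truth parameters
    are still produced).
    """
    if pre_spec is None or post_spec_by_group is None:
        d_pre, d_post = default_study_specs()
        pre_spec = pre_spec or d_pre
        post_spec_by_group = post_spec_by_group or d_post
    if n_per_group is None:
        n_per_group = {"sham": 38, "sine": 28, "triangular": 38}
    if isinstance(n_per_group, int):
        n_per_group = {g: n_per_group for g in post_spec_by_group}
    unknown = set(n_per_group) - set(post_spec_by_group)
    if unknown:
        raise RecordingError(f"unknown group names: {sorted(unknown)}")
    model = behavior_model or BehaviorModel()
    rng = np.random.default_rng(seed)

    templates = make_canonical_templates(pre_spec.montage, pre_spec.K,
                                         seed=rng,
                                         channels=pre_spec.channels)
    c_idx = min(2, pre_spec.K - 1)  # Class C when K >= 3
    records: list[StudyRecord] = []
    behavior_rows = []
    for group, n in n_per_group.items():
        for i in range(n):
            pid = f"{group}-{i + 1:02d}"
            jitter = np.exp(rng.normal(0.0, participant_jitter_sd,
                                       size=pre_spec.K))
            truths = {}
            for stage, spec in (("pre", pre_spec),
                                ("post", post_spec_by_group[group])):
                pspec = replace(
                    spec,
                    mean_durations=tuple(np.asarray(spec.mean_durations)
                                         * jitter),
                )
                labels = sample_labels(pspec, rng)
                if render:
                    rec, signs = _render(labels, templates, pspec, rng)
                else:
                    rec, signs = None, np.array([])
                truth = SyntheticGroundTruth(
                    templates=templates, labels=labels,
                    params=compute_params(labels), segment_signs=signs)
                truths[stage] = truth
                records.append(StudyRecord(participant=pid, group=group,
                                           stage=stage, recording=rec,
                                           ground_truth=truth))
            d_cov_c = change_rate(truths["pre"].params.coverage[c_idx],
                                  truths["post"].params.coverage[c_idx])
            for task in ("two-back", "three-back"):
                pre_rt = model.base_rt[task] * np.exp(rng.normal(0.0, 0.08))
                pre_acc = float(np.clip(
                    model.base_acc[task] + rng.normal(0.0, 0.04), 0.0, 1.0))
                if task == "three-back":
                    d_rt = (model.rt_slope * d_cov_c
                            + rng.normal(0.0, model.rt_noise_sd))
                else:
                    d_rt = rng.normal(-0.02, model.rt_noise_sd)
                d_acc = model.acc_gain + rng.normal(0.0, model.acc_noise_sd)
                post_rt = pre_rt * (1.0 + d_rt)
                post_acc = float(np.clip(pre_acc * (1.0 + d_acc), 0.0, 1.0))
                behavior_rows.append((pid, group, "pre", task, pre_acc, pre_rt))
                behavior_rows.append((pid, group, "post", task, post_acc,
                                      max(post_rt, 1.0)))
    behavior = pd.DataFrame(
        behavior_rows,
        columns=["participant", "group", "stage", "task", "accuracy", "rt"])
    return StudyData(records=records, behavior=behavior)
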