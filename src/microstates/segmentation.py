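"""Back-fitting, temporal smoothing, and microstate parameters.

Once template maps exist, every sample of the continuous EEG is assigned to
the class whose template it correlates with best (ignoring polarity). Brief
segments — shorter than a minimum duration, conventionally 30 ms — are treated
as noise-induced fragmentation and merged into their neighbors using global
map dissimilarity (GMD). From the resulting label sequence the four standard
microstate parameters are computed per class: mean duration (ms), coverage
(fraction of time), occurrence (segments per second), and the matrix of
transition probabilities between classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import TemplateSet, _center
from .recording_io import Recording


class SegmentationError(ValueError):
    """Raised on invalid label sequences or inconsistent inputs."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class LabelSequence:
    """Per-sample microstate class assignment."""

    labels: np.ndarray
    srate: float
    K: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise SegmentationError("labels must be a nonempty 1-D array")
        if self.labels.min() < 0 or self.labels.max() >= self.K:
            raise SegmentationError("label outside [0, K)")
        if self.srate <= 0:
            raise SegmentationError("srate must be positive")

    def __len__(self) -> int:
        return int(self.labels.size)

    def to_files(self, path: str | Path) -> None:
        path = Path(path)
        np.savetxt(path, self.labels, fmt="%d")
        path.with_suffix(path.suffix + ".meta").write_text(
            f"srate = {self.srate!r}\nK = {self.K}\n"
        )


@dataclass
class SegmentList:
    """Maximal runs of equal labels: (start, end, class), end exclusive."""

    runs: list[tuple[int, int, int]]

    def __iter__(self):
        return iter(self.runs)

    def __len__(self) -> int:
        return len(self.runs)


@dataclass
class MicrostateParams:
    """Per-class duration/coverage/occurrence and transition probabilities.

    ``duration`` is in ms, ``coverage`` a fraction of total time,
    ``occurrence`` in segments per second. ``transition_matrix`` is K x K with
    a structurally zero diagonal; each row with outgoing transitions sums
    to 1, rows without are all-zero.
    """

    duration: np.ndarray
    coverage: np.ndarray
    occurrence: np.ndarray
    transition_matrix: np.ndarray

    @property
    def K(self) -> int:
        return self.duration.size

    def to_frame(self, class_labels: list[str] | None = None) -> pd.DataFrame:
        labels = class_labels or [str(i) for i in range(self.K)]
        return pd.DataFrame(
            {"class": labels, "duration_ms": self.duration,
             "coverage": self.coverage, "occurrence_per_s": self.occurrence}
        )


# ---------------------------------------------------------------------------
# Back-fitting
# ---------------------------------------------------------------------------

_ZERO_VARIANCE_NORM = 1e-12


def backfit(rec: Recording, templates: TemplateSet) -> LabelSequence:
    """Assign each sample to the best-correlating template class.

    The label is the argmax over classes of the polarity-invariant spatial
    correlation between the sample's (spatially centered) topography and the
    template; exact ties break to the lowest class index. Spatially constant
    samples carry the previous sample's label forward (class 0 if first).
    """
    if list(rec.channels) != list(templates.channels):
        raise SegmentationError("recording/template channel mismatch")
    x = _center(rec.data.T)                       # (T, C)
    norms = np.linalg.norm(x, axis=1)
    score = np.abs(x @ templates.templates.T)     # |corr| * ||x_c||
    labels = np.argmax(score, axis=1)
    flat = norms < _ZERO_VARIANCE_NORM
    if np.any(flat):
        labels = labels.copy()
        prev = 0
        for t in range(labels.size):
            if flat[t]:
                labels[t] = prev
            else:
                prev = labels[t]
    return LabelSequence(labels=labels, srate=rec.srate, K=templates.k)


# ---------------------------------------------------------------------------
# Run-length structure
# ---------------------------------------------------------------------------

def segments_of(labels: LabelSequence) -> SegmentList:
    """Decompose a label sequence into maximal constant runs."""
    arr = labels.labels
    boundaries = np.flatnonzero(np.diff(arr)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [arr.size]))
    return SegmentList(runs=[(int(s), int(e), int(arr[s]))
                             for s, e in zip(starts, ends)])


def _labels_from_runs(runs: list[tuple[int, int, int]], srate: float,
                      K: int) -> LabelSequence:
    total = runs[-1][1]
    out = np.empty(total, dtype=int)
    for s, e, c in runs:
        out[s:e] = c
    return LabelSequence(labels=out, srate=srate, K=K)


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

def smooth_segments(labels: LabelSequence, rec: Recording,
                    templates: TemplateSet,
                    min_duration: float = 30.0) -> LabelSequence:
    """Merge interior segments shorter than ``min_duration`` (ms) into
    their neighbors.

    Offending segments are processed shortest first (ties: earliest). Each
    frame of the segment prefers the neighbor class whose template is closer
    in polarity-invariant GMD; contiguity is enforced by the optimal split —
    frames before the split join the left neighbor, the rest the right, with
    the split placed to minimize the summed GMD. Segments touching the record
    boundary are exempt. Each merge strictly reduces the run count, so the
    procedure terminates with every interior segment at least the minimum
    length.
    """
    if min_duration < 0:
        raise SegmentationError("min_duration must be >= 0")
    min_len = int(round(min_duration * labels.srate / 1000.0))
    if min_len > len(labels):
        raise SegmentationError("min_duration exceeds record length")
    if min_len <= 1:
        return LabelSequence(labels=labels.labels.copy(), srate=labels.srate,
                             K=labels.K)
    if rec.n_samples != len(labels):
        raise SegmentationError("recording/labels length mismatch")
    if list(rec.channels) != list(templates.channels):
        raise SegmentationError("recording/template channel mismatch")

    x = _center(rec.data.T)                                  # (T, C)
    norms = np.linalg.norm(x, axis=1)
    ok = norms >= _ZERO_VARIANCE_NORM
    xh = np.zeros_like(x)
    xh[ok] = x[ok] / norms[ok, None]
    # polarity-invariant GMD^2 to template j on unit-GFP maps reduces to
    # 2 - 2|corr|; flat frames score 0 for every class.
    absproj = np.abs(xh @ templates.templates.T)             # (T, K)
    gmd2 = 2.0 - 2.0 * absproj
    gmd2[~ok] = 0.0

    runs = list(segments_of(labels).runs)

    def shortest_offender() -> int | None:
        best_i, best_len = None, None
        for i in range(1, len(runs) - 1):
            s, e, _ = runs[i]
            if e - s < min_len and (best_len is None or e - s < best_len):
                best_i, best_len = i, e - s
        return best_i

    while True:
        i = shortest_offender()
        if i is None:
            break
        s, e, _ = runs[i]
        ls, le, lc = runs[i - 1]
        rs, re, rc = runs[i + 1]
        if lc == rc:
            runs[i - 1:i + 2] = [(ls, re, lc)]
            # the merged run may now sit next to an equal-class neighbor only
            # if the original sequence violated the run invariant; rebuild not
            # needed because segments_of guarantees alternation.
            continue
        cost_l = gmd2[s:e, lc]
        cost_r = gmd2[s:e, rc]
        # split index m in [0, n]: frames [0, m) -> left, [m, n) -> right
        n = e - s
        cum_l = np.concatenate(([0.0], np.cumsum(cost_l)))
        cum_r = np.concatenate(([0.0], np.cumsum(cost_r[::-1])))[::-1]
        m = int(np.argmin(cum_l + cum_r))
        # frames [s, s+m) join the left run, [s+m, e) the right run
        runs[i - 1:i + 2] = [(ls, s + m, lc), (s + m, re, rc)]

    return _labels_from_runs(runs, labels.srate, labels.K)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

def compute_params(labels: LabelSequence,
                   include_boundary_runs: bool = True) -> MicrostateParams:
    """Duration, coverage, occurrence per class, and transition matrix.

    duration(c): mean run length of class-c runs, in ms. coverage(c): fraction
    of samples labeled c. occurrence(c): class-c runs per second. With
    boundary runs included (default) the identity
    coverage = duration * occurrence / 1000 holds exactly; excluding
    boundary-truncated runs from the duration average
    (``include_boundary_runs=False``) breaks it by construction.
    Classes that never occur score 0 on all three.
    """
    runs = segments_of(labels).runs
    K = labels.K
    T = len(labels)
    seconds = T / labels.srate
    covered = np.zeros(K)
    dur_sum = np.zeros(K)      # samples entering the duration average
    dur_count = np.zeros(K)    # runs entering the duration average
    visits = np.zeros(K)       # every run, for occurrence
    for idx, (s, e, c) in enumerate(runs):
        covered[c] += e - s
        visits[c] += 1
        is_boundary = idx == 0 or idx == len(runs) - 1
        if include_boundary_runs or not is_boundary:
            dur_sum[c] += e - s
            dur_count[c] += 1
    coverage = covered / T
    duration = np.where(dur_count > 0,
                        dur_sum / np.maximum(dur_count, 1)
                        * 1000.0 / labels.srate, 0.0)
    occurrence = (dur_count if include_boundary_runs else visits) / seconds

    trans = _transition_matrix_from_runs(runs, K)
    return MicrostateParams(duration=duration, coverage=coverage,
                            occurrence=occurrence, transition_matrix=trans)


def _transition_matrix_from_runs(runs, K: int) -> np.ndarray:
    counts = np.zeros((K, K))
    for (s1, e1, c1), (s2, e2, c2) in zip(runs[:-1], runs[1:]):
        counts[c1, c2] += 1
    out = np.zeros((K, K))
    row_sums = counts.sum(axis=1)
    nz = row_sums > 0
    out[nz] = counts[nz] / row_sums[nz, None]
    return out


def transition_probabilities(labels: LabelSequence) -> np.ndarray:
    """K x K matrix of P(next segment class = j | current class = i).

    Counts adjacent run pairs; each row with outgoing transitions is
    normalized to sum to 1, the diagonal is structurally zero.
    """
    runs = segments_of(labels).runs
    if len(runs) < 2:
        raise SegmentationError("transition probabilities need >= 2 segments")
    return _transition_matrix_from_runs(runs, labels.K)


def change_rate(pre_val: float, post_val: float) -> float:
    """Relative pre-to-post change, (post - pre) / pre."""
    if pre_val == 0:
        raise SegmentationError("change rate undefined for pre value 0")
    return (post_val - pre_val) / pre_val


def params_table(params_by_class: MicrostateParams,
                 class_labels: list[str]) -> pd.DataFrame:
    """Long-format parameter table (one row per class x parameter)."""
    rows = []
    for i, lab in enumerate(class_labels):
        rows.append((lab, "duration_ms", params_by_class.duration[i]))
        rows.append((lab, "coverage", params_by_class.coverage[i]))
        rows.append((lab, "occurrence_per_s", params_by_class.occurrence[i]))
    return pd.DataFrame(rows, columns=["class", "parameter", "value"])
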