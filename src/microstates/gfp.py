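"""Global field power and GFP-peak selection.

GFP at a time point is the spatial standard deviation of the voltage map —
high GFP marks moments of high topographic signal-to-noise, and its local
maxima are the instants clustered into microstate templates. Because GFP
removes the spatial mean, it is invariant to any common-offset re-reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .recording_io import Recording, RecordingError


@dataclass
class GFPSeries:
    """Per-sample global field power (µV) at a known sampling rate."""

    values: np.ndarray
    srate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise RecordingError("GFP series must be one-dimensional")
        if np.any(self.values < 0):
            raise RecordingError("GFP values must be nonnegative")

    def to_file(self, path: str | Path) -> None:
        np.savetxt(path, self.values, fmt="%.10e")


@dataclass
class PeakSet:
    """Strictly increasing sample indices of retained GFP peaks."""

    indices: np.ndarray
    source_srate: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise RecordingError("peak indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.indices.size)

    def to_file(self, path: str | Path) -> None:
        np.savetxt(path, self.indices, fmt="%d")


def compute_gfp(rec: Recording) -> GFPSeries:
    """Spatial standard deviation of each sample's topography.

    GFP(t) = sqrt( (1/C) * sum_i (v_i(t) - vbar(t))^2 ), population form.
    """
    if rec.n_channels < 2:
        raise RecordingError("GFP undefined for single-channel recordings")
    return GFPSeries(values=rec.data.std(axis=0, ddof=0), srate=rec.srate)


def _local_maxima(values: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; the first sample of a plateau counts."""
    n = values.size
    if n < 3:
        return np.array([], dtype=int)
    peaks = []
    i = 1
    while i < n - 1:
        if values[i] > values[i - 1]:
            # scan a possible plateau starting at i
            j = i
            while j + 1 < n and values[j + 1] == values[i]:
                j += 1
            if j + 1 < n and values[j + 1] < values[i]:
                peaks.append(i)
            i = j + 1
        else:
            i += 1
    return np.asarray(peaks, dtype=int)


def select_gfp_peaks(gfp: GFPSeries, min_interval: float = 10.0,
                     outlier_sd: float = 2.0,
                     two_sided: bool = True,
                     outliers_first: bool = True) -> PeakSet:
    """Pick GFP local maxima with spacing and amplitude-outlier constraints.

    Parameters
    ----------
    gfp:
        The GFP series.
    min_interval:
        Minimum spacing between retained peaks, in milliseconds. Conflicts
        are resolved greedily by descending GFP height.
    outlier_sd:
        Peaks whose GFP deviates from the series mean by more than this many
        series standard deviations are excluded.
    two_sided:
        When True (default) exclusion uses |GFP - mean| > outlier_sd * sd;
        when False only abnormally high peaks are excluded.
    outliers_first:
        Order of the two filters; default excludes outliers before
        enforcing the spacing constraint.
    """
    if gfp.values.size == 0:
        raise RecordingError("empty GFP series")
    if min_interval < 0 or outlier_sd <= 0:
        raise RecordingError("min_interval must be >= 0 and outlier_sd > 0")

    candidates = _local_maxima(gfp.values)
    min_gap = int(round(min_interval * gfp.srate / 1000.0))

    def drop_outliers(idx: np.ndarray) -> np.ndarray:
        mu = gfp.values.mean()
        sd = gfp.values.std(ddof=0)
        if sd == 0:
            return idx
        dev = gfp.values[idx] - mu
        keep = (np.abs(dev) if two_sided else dev) <= outlier_sd * sd
        return idx[keep]

    def enforce_spacing(idx: np.ndarray) -> np.ndarray:
        if min_gap <= 1 or idx.size == 0:
            return idx
        # greedy by descending height; stable so earlier index wins ties
        order = idx[np.argsort(-gfp.values[idx], kind="stable")]
        kept: list[int] = []
        for i in order:
            if all(abs(i - j) >= min_gap for j in kept):
                kept.append(int(i))
        return np.sort(np.asarray(kept, dtype=int))

    if outliers_first:
        retained = enforce_spacing(drop_outliers(candidates))
    else:
        retained = drop_outliers(enforce_spacing(candidates))
    return PeakSet(indices=retained, source_srate=gfp.srate)


def peak_maps(rec: Recording, peaks: PeakSet) -> np.ndarray:
    """Extract the (n_peaks, n_channels) topographies at the peak samples."""
    return rec.data[:, peaks.indices].T.copy()
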