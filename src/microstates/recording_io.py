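"""EEG recording container, file I/O, and preprocessing transforms.

The :class:`Recording` is the object every signal-space operation in this
package transforms: a channels x samples voltage matrix in microvolts with a
sampling rate, ordered channel labels, and a free-text description of the
current reference. Readers exist for EDF and BrainVision files (via MNE) and
for a plain delimited-text "matrix" dialect (header row of channel labels, one
column per channel, one row per sample) with a key=value sidecar carrying the
sampling rate and reference.

Preprocessing mirrors a standard resting-state pipeline: re-referencing to the
mean of a set of channels (e.g. linked mastoids), a zero-phase 4th-order
Butterworth band-pass, and anti-aliased downsampling.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal


class RecordingError(ValueError):
    """Raised when a recording, montage, or config violates its invariants."""


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """Multichannel EEG segment.

    Parameters
    ----------
    data:
        Voltage matrix, shape ``(n_channels, n_samples)``, in microvolts.
    srate:
        Sampling rate in Hz.
    channels:
        Ordered, unique channel labels; one per matrix row.
    reference:
        Free-text description of the current reference.
    """

    data: np.ndarray
    srate: float
    channels: list[str]
    reference: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channels = [str(c) for c in self.channels]
        if self.data.ndim != 2:
            raise RecordingError("data must be a 2-D channels x samples matrix")
        if not np.all(np.isfinite(self.data)):
            raise RecordingError("voltage matrix contains non-finite values")
        if self.srate <= 0:
            raise RecordingError(f"sampling rate must be positive, got {self.srate}")
        if len(self.channels) != self.data.shape[0]:
            raise RecordingError(
                f"{len(self.channels)} labels for {self.data.shape[0]} rows"
            )
        if len(set(self.channels)) != len(self.channels):
            raise RecordingError("duplicate channel labels")
        if self.data.shape[0] < 2:
            raise RecordingError("at least 2 channels required (GFP undefined)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.srate


@dataclass
class Montage:
    """Head-plane sensor layout: channel label -> (x, y) on the unit disk.

    x points to the subject's right, y anterior.
    """

    positions: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for label, (x, y) in self.positions.items():
            if not (np.isfinite(x) and np.isfinite(y)):
                raise RecordingError(f"non-finite coordinates for channel {label}")

    def coords(self, channels: list[str]) -> np.ndarray:
        """(n, 2) coordinate array for the given channels, in order."""
        missing = [c for c in channels if c not in self.positions]
        if missing:
            raise RecordingError(f"channels missing from montage: {missing}")
        return np.array([self.positions[c] for c in channels], dtype=float)


@dataclass
class PipelineConfig:
    """Tunable constants of the analysis pipeline.

    Defaults follow the analysis this package implements: 1-40 Hz band-pass,
    downsampling to 500 Hz, GFP peaks at least 10 ms apart with amplitudes
    within 2 SD of the series mean, modified k-means at k = 4-7 with 50
    random restarts and up to 1000 iterations, and 30 ms minimum segment
    duration during smoothing.
    """

    band_low: float = 1.0
    band_high: float = 40.0
    target_srate: float = 500.0
    peak_min_interval: float = 10.0     # ms
    peak_outlier_sd: float = 2.0
    k_range: tuple[int, ...] = (4, 5, 6, 7)
    n_restarts: int = 50
    max_iter: int = 1000
    convergence_tol: float = 1e-6
    smooth_min_duration: float = 30.0   # ms
    n_permutations: int = 500
    alpha: float = 0.05
    seed: int = 0
    # flagged-configurable choices
    ref_labels: tuple[str, ...] = ("M1", "M2")
    outlier_two_sided: bool = True
    include_boundary_runs: bool = True

    def __post_init__(self) -> None:
        if not self.band_low < self.band_high:
            raise RecordingError("band_low must be < band_high")
        self.k_range = tuple(int(k) for k in self.k_range)
        if not self.k_range or any(k < 2 for k in self.k_range):
            raise RecordingError("k_range must be nonempty with each k >= 2")
        if self.n_restarts < 1:
            raise RecordingError("n_restarts must be >= 1")
        if self.smooth_min_duration < 0:
            raise RecordingError("smooth_min_duration must be >= 0")

    # -- flat key=value round-trip (config files) --

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            raw[key.strip()] = val.strip()
        kwargs: dict = {}
        typemap = {f.name: f for f in fields(cls)}
        for key, val in raw.items():
            if key not in typemap:
                raise RecordingError(f"unknown config key: {key}")
            default = getattr(cls(), key)
            if isinstance(default, bool):
                kwargs[key] = val.lower() in {"1", "true", "yes"}
            elif isinstance(default, int):
                kwargs[key] = int(val)
            elif isinstance(default, float):
                kwargs[key] = float(val)
            elif isinstance(default, tuple):
                items = [x for x in val.split(",") if x != ""]
                elem = type(default[0]) if default else str
                kwargs[key] = tuple(elem(x) for x in items)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def content_hash(self) -> str:
        payload = ";".join(
            f"{f.name}={getattr(self, f.name)}" for f in fields(self)
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta")


def write_recording(rec: Recording, path: str | Path, delimiter: str = "\t") -> None:
    """Write the matrix dialect: header of labels, one column per channel.

    A ``<path>.meta`` sidecar stores the sampling rate and reference.
    """
    path = Path(path)
    header = delimiter.join(rec.channels)
    np.savetxt(path, rec.data.T, delimiter=delimiter, header=header,
               comments="", fmt="%.10e")
    _sidecar_path(path).write_text(
        f"srate = {rec.srate!r}\nreference = {rec.reference}\n"
    )


def _read_matrix(path: Path, srate: float | None) -> Recording:
    text = path.read_text()
    lines = text.splitlines()
    if not lines:
        raise RecordingError(f"empty matrix file: {path}")
    delimiter = "\t" if "\t" in lines[0] else ","
    labels = [c.strip() for c in lines[0].split(delimiter)]
    if len(set(labels)) != len(labels):
        raise RecordingError(f"duplicate channel labels in {path}")
    try:
        data = np.loadtxt(path, delimiter=delimiter, skiprows=1, ndmin=2)
    except ValueError as exc:
        raise RecordingError(f"non-numeric cell in {path}: {exc}") from exc
    reference = "unknown"
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        for line in sidecar.read_text().splitlines():
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key == "srate" and srate is None:
                srate = float(val)
            elif key == "reference":
                reference = val
    if srate is None:
        raise RecordingError(
            f"matrix dialect needs a sampling rate (sidecar or argument): {path}"
        )
    return Recording(data=data.T, srate=float(srate), channels=labels,
                     reference=reference)


def read_recording(path: str | Path, format: str | None = None,
                   srate: float | None = None) -> Recording:
    """Read an EEG recording.

    Parameters
    ----------
    path:
        File path (.edf, .vhdr, or delimited text).
    format:
        One of ``{"edf", "brainvision", "matrix"}``; inferred from the file
        extension when omitted.
    srate:
        Sampling rate in Hz, required for the matrix dialect when no sidecar
        metadata file exists.
    """
    path = Path(path)
    if not path.exists():
        raise RecordingError(f"no such file: {path}")
    if format is None:
        ext = path.suffix.lower()
        format = {"edf": "edf", ".edf": "edf", ".vhdr": "brainvision"}.get(
            ext, "matrix")
    if format == "matrix":
        return _read_matrix(path, srate)
    if format in ("edf", "brainvision"):
        import mne  # heavy import deferred

        if format == "edf":
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        else:
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        labels = list(raw.ch_names)
        if len(set(labels)) != len(labels):
            raise RecordingError(f"duplicate channel labels in {path}")
        data_uv = raw.get_data() * 1e6  # MNE returns volts
        return Recording(data=data_uv, srate=float(raw.info["sfreq"]),
                         channels=labels, reference="as recorded")
    raise RecordingError(f"unknown format: {format}")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def rereference(rec: Recording, ref_labels: list[str]) -> Recording:
    """Subtract the mean of the named reference channels from every channel.

    With ``ref_labels = ["M1", "M2"]`` this is the linked-mastoid reference.
    """
    unknown = [c for c in ref_labels if c not in rec.channels]
    if unknown:
        raise RecordingError(f"unknown reference channels: {unknown}")
    idx = [rec.channels.index(c) for c in ref_labels]
    ref = rec.data[idx].mean(axis=0, keepdims=True)
    return replace(rec, data=rec.data - ref,
                   reference="mean(" + ",".join(ref_labels) + ")")


def common_average(rec: Recording) -> Recording:
    """Re-reference to the common average of all channels."""
    return replace(rec, data=rec.data - rec.data.mean(axis=0, keepdims=True),
                   reference="common average")


def bandpass(rec: Recording, low: float, high: float) -> Recording:
    """Zero-phase 4th-order Butterworth band-pass, applied per channel.

    Forward-backward filtering (``sosfiltfilt``) keeps topography timing
    intact, which microstate segmentation depends on.
    """
    nyq = rec.srate / 2.0
    if not (0 < low < high < nyq):
        raise RecordingError(
            f"band ({low}, {high}) Hz invalid for srate {rec.srate} Hz"
        )
    sos = signal.butter(4, [low, high], btype="bandpass", fs=rec.srate,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=filtered)


def downsample(rec: Recording, target: float) -> Recording:
    """Resample to ``target`` Hz with an anti-aliasing low-pass.

    Integer ratios use polyphase decimation; non-integer ratios rational
    polyphase resampling. Duration is preserved to within one sample.
    """
    if target > rec.srate:
        raise RecordingError(
            f"target {target} Hz exceeds source rate {rec.srate} Hz"
        )
    if target == rec.srate:
        return replace(rec, data=rec.data.copy())
    frac = Fraction(target / rec.srate).limit_denominator(10_000)
    out = signal.resample_poly(rec.data, frac.numerator, frac.denominator,
                               axis=1)
    return replace(rec, data=out, srate=float(target))


def preprocess(rec: Recording, config: PipelineConfig) -> Recording:
    """Re-reference (if the configured channels exist), band-pass, downsample."""
    if all(c in rec.channels for c in config.ref_labels):
        rec = rereference(rec, list(config.ref_labels))
    rec = bandpass(rec, config.band_low, config.band_high)
    if rec.srate > config.target_srate:
        rec = downsample(rec, config.target_srate)
    return rec
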