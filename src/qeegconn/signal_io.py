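"""Recordings, montage/region handling and the preprocessing chain.

The in-memory unit is :class:`Recording`: a channels x timepoints matrix in
microvolts plus sampling rate and ordered 10-20 channel labels.  Two on-disk
formats are supported:

* EDF/EDF+ (read via :mod:`mne`; written by a minimal built-in 16-bit EDF
  encoder, sufficient for round-trips of integer-rate recordings), and
* a delimited matrix: TSV with channels as rows and a JSON sidecar
  ``{"rate": ..., "labels": [...]}`` (a ``# rate=...; labels=...`` comment
  header on the first line is accepted as an inline alternative).

Preprocessing follows the usual clinical chain: power-line notch, broadband
band-pass, segmentation into fixed-length epochs, and amplitude-based
artifact rejection.  All filtering is zero-phase (forward-backward) because
downstream phase metrics must not see filter group delay.
"""

from __future__ import annotations

import json
import re
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .errors import (
    EmptyResultError,
    FormatError,
    InputError,
    LabelError,
    ParameterError,
    TooShortError,
)

__all__ = [
    "Recording",
    "RegionMap",
    "EpochSet",
    "normalize_label",
    "read_recording",
    "write_recording",
    "preprocess",
    "epoch_and_reject",
    "bandpass_sos",
    "bandpass_filter",
]

# Canonical 10-20 labels in the capitalization used throughout the package.
CANONICAL_1020 = [
    "Fp1", "Fp2", "F3", "Fz", "F4", "F7", "F8",
    "C3", "Cz", "C4",
    "T3", "T4", "T5", "T6",
    "P3", "Pz", "P4",
    "O1", "Oz", "O2",
]

# The montage in CANONICAL_1020 uses the older temporal naming; the modern
# equivalents are accepted as synonyms and normalized to the older form.
_ALIASES = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}

_CANON_BY_UPPER = {lbl.upper(): lbl for lbl in CANONICAL_1020}


def normalize_label(label: str) -> str:
    """Map a channel label to canonical 10-20 capitalization.

    ``"FP1" -> "Fp1"``, ``"cz" -> "Cz"``, ``"T7" -> "T3"`` (modern temporal
    names are treated as synonyms of the older ones).  Unknown labels are
    returned stripped but otherwise untouched.
    """
    s = label.strip()
    up = s.upper()
    up = _ALIASES.get(up, up)
    return _CANON_BY_UPPER.get(up, _ALIASES.get(s, s))


@dataclass
class Recording:
    """Multichannel EEG samples (channels x timepoints, microvolts)."""

    samples: np.ndarray
    rate: float
    labels: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise FormatError("samples must be a 2-D channels x timepoints array")
        if self.rate <= 0:
            raise FormatError(f"sampling rate must be positive, got {self.rate}")
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != self.samples.shape[0]:
            raise FormatError(
                f"{len(self.labels)} labels for {self.samples.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise FormatError(f"duplicate channel labels: {dupes}")
        if not np.all(np.isfinite(self.samples)):
            raise FormatError("samples contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.rate

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(normalize_label(label))
        except ValueError:
            raise LabelError(f"channel {label!r} not in recording") from None


# Scalp regions exactly as used for regional power summaries.
DEFAULT_REGIONS: dict[str, list[str]] = {
    "frontal": ["Fp1", "Fp2", "F3", "Fz", "F4", "F7", "F8"],
    "central": ["C3", "Cz", "C4"],
    "temporal": ["T3", "T4", "T5", "T6"],
    "parietal": ["P3", "Pz", "P4"],
    "occipital": ["O1", "Oz", "O2"],
}


@dataclass
class RegionMap:
    """Channel -> scalp region assignment plus hemisphere lookup.

    Hemisphere is derived from the 10-20 label suffix: odd terminal digit =
    left, even = right, trailing ``z`` = midline.
    """

    assignment: dict[str, str] = field(
        default_factory=lambda: {
            ch: region for region, chans in DEFAULT_REGIONS.items() for ch in chans
        }
    )

    @classmethod
    def default(cls) -> "RegionMap":
        return cls()

    @property
    def regions(self) -> list[str]:
        seen: list[str] = []
        for r in self.assignment.values():
            if r not in seen:
                seen.append(r)
        return seen

    def channels_in(self, region: str) -> list[str]:
        return [ch for ch, r in self.assignment.items() if r == region]

    def region_of(self, label: str) -> str | None:
        return self.assignment.get(normalize_label(label))

    @staticmethod
    def hemisphere_of(label: str) -> str:
        lbl = normalize_label(label)
        if re.fullmatch(r"[A-Za-z]+z", lbl):
            return "midline"
        m = re.fullmatch(r"[A-Za-z]+(\d+)", lbl)
        if m is None:
            raise LabelError(f"cannot derive hemisphere from label {lbl!r}")
        return "left" if int(m.group(1)) % 2 == 1 else "right"


@dataclass
class EpochSet:
    """Consecutive equal-length epochs surviving artifact rejection."""

    epochs: list[np.ndarray]
    epoch_length_s: float
    kept_mask: np.ndarray
    rate: float
    labels: list[str]

    def __post_init__(self) -> None:
        if self.epochs:
            shape = self.epochs[0].shape
            if any(e.shape != shape for e in self.epochs):
                raise FormatError("epochs differ in shape")
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)

    @property
    def n_channels(self) -> int:
        return self.epochs[0].shape[0]

    @property
    def n_samples(self) -> int:
        return self.epochs[0].shape[1]

    def concatenate(self) -> np.ndarray:
        return np.concatenate(self.epochs, axis=1)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_HEADER_RE = re.compile(r"rate\s*=\s*([0-9.eE+-]+)\s*;\s*labels\s*=\s*(.+)")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _read_matrix(path: Path) -> Recording:
    rate = None
    labels = None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        try:
            info = json.loads(sidecar.read_text())
            rate = float(info["rate"])
            labels = [str(l) for l in info["labels"]]
        except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"bad sidecar {sidecar}: {exc}") from exc
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            m = _HEADER_RE.search(first)
            if m and rate is None:
                rate = float(m.group(1))
                labels = [s.strip() for s in m.group(2).split(",")]
            data_text = fh.read()
        else:
            data_text = first + fh.read()
    if rate is None:
        raise FormatError(f"{path}: no sampling rate (no sidecar, no '#' header)")
    try:
        samples = np.loadtxt(data_text.splitlines(), delimiter="\t", ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: cannot parse matrix: {exc}") from exc
    if labels is None:
        raise FormatError(f"{path}: no channel labels")
    return _finish_recording(samples, rate, labels, {"source": str(path)})


def _write_matrix(rec: Recording, path: Path) -> None:
    header = f"# rate={rec.rate:g}; labels={','.join(rec.labels)}\n"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, rec.samples, delimiter="\t", fmt="%.8e")
    _sidecar_path(path).write_text(
        json.dumps({"rate": rec.rate, "labels": rec.labels}, sort_keys=True)
    )


def _read_edf(path: Path) -> Recording:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    samples = raw.get_data() * 1e6  # mne loads EEG in volts
    return _finish_recording(samples, float(raw.info["sfreq"]), list(raw.ch_names),
                             {"source": str(path)})


def _finish_recording(samples: np.ndarray, rate: float, labels: list[str],
                      meta: dict) -> Recording:
    norm = [normalize_label(l) for l in labels]
    if len(set(norm)) != len(norm):
        dupes = sorted({l for l in norm if norm.count(l) > 1})
        raise FormatError(f"duplicate channel labels after normalization: {dupes}")
    unknown = [l for l in norm if l not in CANONICAL_1020]
    if unknown:
        meta = dict(meta, unknown_labels=unknown)
    return Recording(samples=samples, rate=rate, labels=norm, meta=meta)


def _edf_ascii(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = f"{value:.{max(width - 6, 1)}g}"
    return s.ljust(width)[:width].encode("ascii")


def _write_edf(rec: Recording, path: Path) -> None:
    """Minimal EDF writer: 16-bit, one-second data records.

    Only supports integer sampling rates; the tail shorter than one record
    is zero-padded (EDF has no partial records).
    """
    if abs(rec.rate - round(rec.rate)) > 1e-9:
        raise ParameterError("EDF export requires an integer sampling rate")
    spr = int(round(rec.rate))
    n_rec = int(np.ceil(rec.n_times / spr))
    nchan = rec.n_channels
    data = np.zeros((nchan, n_rec * spr))
    data[:, : rec.n_times] = rec.samples

    pmin = np.floor(data.min(axis=1))
    pmax = np.ceil(data.max(axis=1))
    flat = pmax <= pmin
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.rint((data - pmin[:, None]) / scale[:, None] + dmin).astype("<i2")

    hdr = b"".join([
        _edf_ascii("0", 8),
        _edf_ascii("X", 80),
        _edf_ascii("qeegconn export", 80),
        _edf_ascii("01.01.00", 8),
        _edf_ascii("00.00.00", 8),
        _edf_ascii(256 * (nchan + 1), 8),
        b" " * 44,
        _edf_ascii(n_rec, 8),
        _edf_ascii(1, 8),
        _edf_ascii(nchan, 4),
    ])
    for fn, width in [
        (lambda i: rec.labels[i], 16),
        (lambda i: "", 80),
        (lambda i: "uV", 8),
        (lambda i: f"{pmin[i]:.6g}"[:8], 8),
        (lambda i: f"{pmax[i]:.6g}"[:8], 8),
        (lambda i: dmin, 8),
        (lambda i: dmax, 8),
        (lambda i: "", 80),
        (lambda i: spr, 8),
        (lambda i: "", 32),
    ]:
        hdr += b"".join(_edf_ascii(fn(i), width) for i in range(nchan))

    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(struct.pack(f"<{nchan * spr}h", *block.ravel()))


def read_recording(path, format: str | None = None) -> Recording:
    """Read a recording from EDF or delimited-matrix format.

    ``format`` is ``"edf"`` or ``"matrix"``; if omitted it is inferred from
    the file extension (``.edf`` vs anything else).  Labels are normalized
    to canonical 10-20 capitalization; labels outside the montage are kept
    and listed in ``meta["unknown_labels"]``.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "edf":
        try:
            return _read_edf(path)
        except FormatError:
            raise
        except Exception as exc:  # mne raises assorted types on bad files
            raise InputError(f"cannot read EDF {path}: {exc}") from exc
    if format == "matrix":
        return _read_matrix(path)
    raise ParameterError(f"unknown format {format!r}")


def write_recording(rec: Recording, path, format: str | None = None) -> Path:
    """Write a recording as EDF or as TSV + JSON sidecar. Returns the path."""
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "edf":
        _write_edf(rec, path)
    elif format == "matrix":
        _write_matrix(rec, path)
    else:
        raise ParameterError(f"unknown format {format!r}")
    return path


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

_BP_ORDER = 4
_NOTCH_Q = 30.0


def bandpass_sos(band: tuple[float, float], rate: float) -> np.ndarray:
    """Zero-phase-ready Butterworth band-pass in second-order sections."""
    lo, hi = band
    if not (0 < lo < hi < rate / 2):
        raise ParameterError(
            f"band edges must satisfy 0 < lo < hi < Nyquist; got {band} at rate {rate}"
        )
    return signal.butter(_BP_ORDER, [lo, hi], btype="bandpass", output="sos", fs=rate)


def _min_length(sos: np.ndarray) -> int:
    # sosfiltfilt default pad length; shorter inputs cannot be filtered.
    return 3 * (2 * sos.shape[0] + 1)


def bandpass_filter(x: np.ndarray, band: tuple[float, float], rate: float) -> np.ndarray:
    """Forward-backward band-pass along the last axis."""
    sos = bandpass_sos(band, rate)
    if x.shape[-1] <= _min_length(sos):
        raise TooShortError(
            f"{x.shape[-1]} samples is too short for the {band} Hz filter"
        )
    return signal.sosfiltfilt(sos, x, axis=-1)


def preprocess(
    rec: Recording,
    notch_hz: float = 50.0,
    band: tuple[float, float] = (0.5, 40.0),
) -> Recording:
    """Notch out line interference and band-pass the recording.

    Both stages are zero-phase (``filtfilt``), so no group delay is
    introduced — a prerequisite for the phase-based connectivity metrics.
    Defaults: 50 Hz notch (quality factor 30), 0.5-40 Hz Butterworth
    band-pass of order 4.
    """
    lo, hi = band
    nyq = rec.rate / 2
    if not (0 < lo < hi < nyq):
        raise ParameterError(f"band {band} outside (0, Nyquist={nyq}) or reversed")
    if not (0 < notch_hz < nyq):
        raise ParameterError(f"notch frequency {notch_hz} outside (0, Nyquist={nyq})")

    b_notch, a_notch = signal.iirnotch(notch_hz, _NOTCH_Q, fs=rec.rate)
    sos = bandpass_sos(band, rec.rate)
    need = max(3 * max(len(a_notch), len(b_notch)), _min_length(sos)) + 1
    if rec.n_times < need:
        raise TooShortError(
            f"recording has {rec.n_times} samples; at least {need} needed "
            f"for zero-phase filtering"
        )
    x = signal.filtfilt(b_notch, a_notch, rec.samples, axis=-1)
    x = signal.sosfiltfilt(sos, x, axis=-1)
    meta = dict(rec.meta, preprocess={"notch_hz": notch_hz, "band": list(band)})
    return Recording(samples=x, rate=rec.rate, labels=list(rec.labels), meta=meta)


def epoch_and_reject(
    rec: Recording,
    epoch_length_s: float = 2.0,
    amplitude_limit_uv: float = 100.0,
) -> EpochSet:
    """Cut into consecutive non-overlapping epochs and drop artifact epochs.

    An epoch is rejected when the peak absolute value on *any* channel
    exceeds ``amplitude_limit_uv``.  This deterministic amplitude criterion
    is the package's artifact-rejection stage (component-based artifact
    removal is intentionally out of scope and left to external tooling).
    """
    n_per = int(round(epoch_length_s * rec.rate))
    if n_per < 2:
        raise ParameterError(
            f"epoch length {epoch_length_s}s gives {n_per} samples (< 2)"
        )
    if amplitude_limit_uv <= 0:
        raise ParameterError("amplitude limit must be positive")
    n_raw = rec.n_times // n_per
    if n_raw == 0:
        raise ParameterError(
            f"recording shorter ({rec.duration_s:g}s) than one epoch "
            f"({epoch_length_s:g}s)"
        )
    kept_mask = np.ones(n_raw, dtype=bool)
    epochs = []
    for k in range(n_raw):
        seg = rec.samples[:, k * n_per : (k + 1) * n_per]
        if np.abs(seg).max() > amplitude_limit_uv:
            kept_mask[k] = False
        else:
            epochs.append(seg.copy())
    if not epochs:
        raise EmptyResultError(
            f"all {n_raw} epochs exceeded the {amplitude_limit_uv} uV amplitude limit"
        )
    return EpochSet(
        epochs=epochs,
        epoch_length_s=epoch_length_s,
        kept_mask=kept_mask,
        rate=rec.rate,
        labels=list(rec.labels),
    )
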