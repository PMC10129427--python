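"""Welch spectra, band/region power ratios and the DTABR statistic.

Band powers are integrals of the Welch power spectral density over the four
classical EEG bands (delta 1-3, theta 4-7, alpha 8-13, beta 14-30 Hz).
"Total power" for ratio purposes is the sum over these four bands — the
published regional/band percentages sum to ~100% under exactly that
convention — so the gap frequencies (3-4, 7-8, 13-14 Hz) never enter a
denominator.  DTABR is the slow/fast ratio (delta+theta)/(alpha+beta);
values well above 1 indicate the slowed background activity typical of
disorders of consciousness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import LabelError, MissingChannelError, ParameterError
from .signal_io import EpochSet, RegionMap

__all__ = [
    "BandSet",
    "SpectrumTable",
    "PowerSummary",
    "welch_psd",
    "summarize_power",
    "cohort_power_table",
]

DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 3.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 13.0),
    "beta": (14.0, 30.0),
}


@dataclass
class BandSet:
    """Named, non-overlapping frequency bands (closed intervals, Hz)."""

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )

    def __post_init__(self) -> None:
        items = sorted(self.bands.items(), key=lambda kv: kv[1][0])
        for name, (lo, hi) in items:
            if not lo < hi:
                raise ParameterError(f"band {name}: need lo < hi, got [{lo}, {hi}]")
        for (n1, (_, hi1)), (n2, (lo2, _)) in zip(items, items[1:]):
            if lo2 < hi1:
                raise ParameterError(f"bands {n1} and {n2} overlap")

    @classmethod
    def default(cls) -> "BandSet":
        return cls()

    def __iter__(self):
        return iter(self.bands.items())

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.bands[name]

    @property
    def names(self) -> list[str]:
        return list(self.bands)


@dataclass
class SpectrumTable:
    """Per-channel Welch PSD on a common frequency grid (uV^2/Hz)."""

    freqs: np.ndarray
    psd: np.ndarray  # channels x freqs
    labels: list[str]
    rate: float
    welch_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0):
            raise ParameterError("frequency grid must be strictly increasing")
        if np.any(self.psd < 0):
            raise ParameterError("PSD must be non-negative")
        if self.psd.shape != (len(self.labels), len(self.freqs)):
            raise ParameterError("psd shape inconsistent with labels/freqs")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.psd.T, index=pd.Index(self.freqs, name="freq_hz"),
                            columns=self.labels)


@dataclass
class PowerSummary:
    """Band and region powers with their ratios plus DTABR for one recording."""

    band_power: dict[str, np.ndarray]      # band -> per-channel absolute power
    region_power: dict[str, float]         # region -> absolute power (4-band union)
    band_ratio: dict[str, float]           # shares of the four-band total
    region_ratio: dict[str, float]         # shares of the five-region total
    dtabr: float
    labels: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [("band_ratio", b, v) for b, v in self.band_ratio.items()]
        rows += [("region_ratio", r, v) for r, v in self.region_ratio.items()]
        rows += [("dtabr", "dtabr", self.dtabr)]
        return pd.DataFrame(rows, columns=["quantity", "name", "value"])


def welch_psd(epochs: EpochSet, window_s: float = 2.0, overlap: float = 0.5) -> SpectrumTable:
    """Welch PSD per channel, averaged across epochs.

    Each epoch contributes the mean of its Hann-windowed, ``overlap``-
    overlapped modified periodograms; epochs are averaged with equal weight
    (never concatenated, so no cross-epoch boundary segments are formed).
    Density normalization: the integral of the PSD over [0, rate/2]
    approximates the signal variance.
    """
    if not 0 <= overlap < 1:
        raise ParameterError(f"overlap must be in [0, 1), got {overlap}")
    nperseg = int(round(window_s * epochs.rate))
    if nperseg < 2 or nperseg > epochs.n_samples:
        raise ParameterError(
            f"window of {nperseg} samples invalid for epochs of {epochs.n_samples}"
        )
    noverlap = int(nperseg * overlap)
    psds = []
    freqs = None
    for ep in epochs.epochs:
        freqs, p = sps.welch(
            ep, fs=epochs.rate, window="hann", nperseg=nperseg, noverlap=noverlap,
            detrend="constant", scaling="density", axis=-1,
        )
        psds.append(p)
    psd = np.mean(psds, axis=0)
    return SpectrumTable(
        freqs=freqs, psd=psd, labels=list(epochs.labels), rate=epochs.rate,
        welch_params={"window_s": window_s, "overlap": overlap, "window": "hann"},
    )


def _band_integral(spec: SpectrumTable, lo: float, hi: float) -> np.ndarray:
    """Per-channel trapezoidal integral of the PSD over [lo, hi]."""
    mask = (spec.freqs >= lo) & (spec.freqs <= hi)
    if mask.sum() < 2:
        raise ParameterError(
            f"band [{lo}, {hi}] Hz covers fewer than 2 grid frequencies "
            f"(grid step {np.median(np.diff(spec.freqs)):g} Hz)"
        )
    return np.trapezoid(spec.psd[:, mask], spec.freqs[mask], axis=-1)


def summarize_power(
    spec: SpectrumTable,
    bands: BandSet | None = None,
    regions: RegionMap | None = None,
) -> PowerSummary:
    """Band/region powers, their ratios, and DTABR for one spectrum.

    Band power = PSD integral over the band, per channel; the band ratio
    divides the channel-summed band power by the four-band total.  Region
    power integrates over the union of the four bands and sums the region's
    channels; the region ratio divides by the five-region total.  DTABR =
    (P_delta + P_theta) / (P_alpha + P_beta) over all channels.
    """
    bands = bands or BandSet.default()
    regions = regions or RegionMap.default()
    if bands.bands.keys() < {"delta", "theta", "alpha", "beta"}:
        raise ParameterError("band set must include delta, theta, alpha and beta")
    for name, (lo, hi) in bands:
        if hi > spec.freqs[-1] + 1e-12:
            raise ParameterError(f"band {name} exceeds the frequency grid")

    band_power = {name: _band_integral(spec, lo, hi) for name, (lo, hi) in bands}
    band_tot = {name: float(p.sum()) for name, p in band_power.items()}
    total = sum(band_tot.values())
    band_ratio = {name: (band_tot[name] / total if total > 0 else 0.0)
                  for name in bands.names}

    per_chan_union = np.sum(list(band_power.values()), axis=0)
    region_power: dict[str, float] = {}
    for region in regions.regions:
        present = [ch for ch in regions.channels_in(region) if ch in spec.labels]
        if not present:
            absent = regions.channels_in(region)
            raise MissingChannelError(
                f"region {region!r} has no channels in the recording "
                f"(expected any of {absent})"
            )
        idx = [spec.labels.index(ch) for ch in present]
        region_power[region] = float(per_chan_union[idx].sum())
    region_total = sum(region_power.values())
    region_ratio = {r: (p / region_total if region_total > 0 else 0.0)
                    for r, p in region_power.items()}

    slow = band_tot["delta"] + band_tot["theta"]
    fast = band_tot["alpha"] + band_tot["beta"]
    dtabr = slow / fast if fast > 0 else (0.0 if slow == 0 else np.inf)

    return PowerSummary(
        band_power=band_power, region_power=region_power,
        band_ratio=band_ratio, region_ratio=region_ratio,
        dtabr=float(dtabr), labels=list(spec.labels),
    )


def cohort_power_table(
    summaries: list[PowerSummary],
    group_labels: list[str],
    pooled: bool = False,
) -> pd.DataFrame:
    """Long-format per-group summary of band ratios, region ratios and DTABR.

    By default each subject contributes one value and groups are averaged
    over subjects.  With ``pooled=True`` absolute powers are summed across a
    group's subjects before ratios/DTABR are formed (the two conventions
    coincide only when subjects have equal total power).
    """
    if len(summaries) != len(group_labels):
        raise LabelError("one group label per summary required")
    if not summaries:
        raise LabelError("at least one summary required")
    groups = sorted(set(group_labels))
    rows = []
    for g in groups:
        members = [s for s, lbl in zip(summaries, group_labels) if lbl == g]
        if pooled:
            band_tot = {b: sum(float(m.band_power[b].sum()) for m in members)
                        for b in members[0].band_ratio}
            total = sum(band_tot.values())
            band_ratio = {b: band_tot[b] / total for b in band_tot}
            reg_tot = {r: sum(m.region_power[r] for m in members)
                       for r in members[0].region_power}
            rtotal = sum(reg_tot.values())
            region_ratio = {r: reg_tot[r] / rtotal for r in reg_tot}
            slow = band_tot["delta"] + band_tot["theta"]
            fast = band_tot["alpha"] + band_tot["beta"]
            dtabr = slow / fast
        else:
            band_ratio = {b: float(np.mean([m.band_ratio[b] for m in members]))
                          for b in members[0].band_ratio}
            region_ratio = {r: float(np.mean([m.region_ratio[r] for m in members]))
                            for r in members[0].region_ratio}
            dtabr = float(np.mean([m.dtabr for m in members]))
        rows += [(g, f"band_ratio:{b}", v) for b, v in band_ratio.items()]
        rows += [(g, f"region_ratio:{r}", v) for r, v in region_ratio.items()]
        rows.append((g, "dtabr", dtabr))
    return pd.DataFrame(rows, columns=["group", "quantity", "value"])
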