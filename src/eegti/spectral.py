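"""PSD estimation and band-power extraction.

Spectra are estimated per retained epoch as Hann-windowed, demeaned one-sided
periodograms with window-power (mean-squared-window) compensation, then
averaged across epochs — a non-overlapping Welch estimate whose segmentation
matches the epoching exactly. With this calibration the integral of the
density over [0, Nyquist] equals the mean per-epoch signal variance
(Parseval), so band powers are in µV².

Band integration is a Riemann sum over bins whose *centre* frequency lies in
the half-open interval ``[f_low, f_high)``; DC and Nyquist bins never count
toward any band. Two-second epochs at 250 Hz give 0.5 Hz bins, which aligns
every canonical band edge with a bin centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .bands import BandDefinition, check_nonoverlapping
from .exceptions import (
    DomainError,
    NoCleanEpochsError,
    ParameterError,
    UndefinedRatioError,
)
from .preprocess import EpochSet


@dataclass
class PSDEstimate:
    """Averaged per-channel power spectral density in µV²/Hz."""

    freqs: np.ndarray
    density: np.ndarray  # (n_channels, n_freqs)
    channel_labels: tuple[str, ...]
    fs: float
    epoch_s: float
    n_epochs_averaged: int

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def compute_psd(epochs: EpochSet) -> PSDEstimate:
    """Average Hann periodograms over the retained epochs of one block."""
    if epochs.n_retained == 0:
        raise NoCleanEpochsError(
            f"no clean epochs for {epochs.subject_id}/{epochs.condition}"
        )
    data = epochs.retained_epochs()  # (n_ret, n_ch, n_samp)
    freqs, pxx = signal.periodogram(
        data, fs=epochs.fs, window="hann", detrend="constant",
        scaling="density", axis=-1,
    )
    return PSDEstimate(
        freqs=freqs,
        density=pxx.mean(axis=0),
        channel_labels=epochs.channel_labels,
        fs=epochs.fs,
        epoch_s=epochs.epoch_s,
        n_epochs_averaged=data.shape[0],
    )


def integrate_band(psd: PSDEstimate, band: BandDefinition) -> np.ndarray:
    """Per-channel integrated power (µV²) over ``[f_low, f_high)``."""
    nyq = psd.fs / 2
    if band.f_high > nyq:
        raise ParameterError(
            f"band {band.name!r} [{band.f_low}, {band.f_high}) exceeds "
            f"the Nyquist frequency {nyq} Hz"
        )
    mask = (psd.freqs >= band.f_low) & (psd.freqs < band.f_high)
    mask &= (psd.freqs > 0) & (psd.freqs < nyq)  # DC and Nyquist excluded
    return psd.density[:, mask].sum(axis=1) * psd.df


def total_power(psd: PSDEstimate) -> np.ndarray:
    """Per-channel integral of the density over the full [0, Nyquist] grid."""
    return psd.density.sum(axis=1) * psd.df


def band_power_table(
    psds: Mapping[tuple[str, str], PSDEstimate],
    bands: Sequence[BandDefinition],
    notch_hz: float | None = 50.0,
    bandpass_high: float | None = 70.0,
) -> pd.DataFrame:
    """Long-format band-power table over (subject, condition) → PSD maps.

    A band is flagged ``low_confidence`` when the mains notch or the band-pass
    upper corner lies inside it (for the default chain that is high gamma,
    45–70 Hz, which contains both the 50 Hz notch and the 70 Hz corner — the
    estimate there reflects filter shape as much as physiology).
    """
    check_nonoverlapping(bands)
    rows = []
    for (subject, condition), psd in psds.items():
        for band in bands:
            power = integrate_band(psd, band)
            shaky = (
                notch_hz is not None and band.contains(notch_hz)
            ) or (
                bandpass_high is not None
                and band.f_low < bandpass_high <= band.f_high
            )
            for ch, p in zip(psd.channel_labels, power):
                rows.append(
                    {
                        "subject": subject,
                        "condition": condition,
                        "channel": ch,
                        "band": band.name,
                        "power_uv2": float(p),
                        "low_confidence": bool(shaky),
                    }
                )
    return pd.DataFrame(rows)


def relative_power(table: pd.DataFrame, included_bands: Iterable[str]) -> pd.DataFrame:
    """Add ``relative_power`` normalised over an explicit band set.

    For each (subject, condition, channel), RP_i = P_i / Σ P over the included
    bands; rows outside the set get no relative power. The included relative
    powers sum to 1 per key.
    """
    included = list(included_bands)
    out = table.copy()
    keys = ["subject", "condition", "channel"]
    present = out.groupby(keys)["band"].apply(set)
    for key, bands_here in present.items():
        missing = set(included) - bands_here
        if missing:
            raise ParameterError(
                f"bands {sorted(missing)} missing for key {key}"
            )
    in_set = out["band"].isin(included)
    totals = (
        out[in_set].groupby(keys)["power_uv2"].transform("sum")
    )
    zero = totals[totals <= 0]
    if len(zero) > 0:
        bad_key = tuple(out.loc[zero.index[0], keys])
        raise UndefinedRatioError(
            f"total power over included bands is zero for {bad_key}"
        )
    out["relative_power"] = np.nan
    out.loc[in_set, "relative_power"] = out.loc[in_set, "power_uv2"] / totals
    out["n_bands_included"] = len(included)
    return out


def log_transform(table: pd.DataFrame, base: str = "e") -> pd.DataFrame:
    """Add a ``log_power`` column (natural or base-10 log of absolute power)."""
    if base not in ("e", "10"):
        raise ParameterError(f"log base must be 'e' or '10', got {base!r}")
    if (table["power_uv2"] <= 0).any():
        bad = table.loc[table["power_uv2"] <= 0].iloc[0]
        raise DomainError(
            f"non-positive power for ({bad['subject']}, {bad['condition']}, "
            f"{bad['channel']}, {bad['band']}); log undefined"
        )
    out = table.copy()
    logs = np.log(out["power_uv2"].to_numpy())
    if base == "10":
        logs = logs / math.log(10)
    out["log_power"] = logs
    return out
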