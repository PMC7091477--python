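"""Multielectrode-array spike detection and network-activity statistics.

Extracellular traces sampled at 10 kHz are high-pass filtered at 300 Hz
(4th-order Butterworth, applied forward and backward for zero phase) and
spikes are detected as threshold crossings at +/- 6 noise standard
deviations, treated as point processes.  Channels with a mean firing rate
below 0.1 Hz over the 10-min analysis session are considered nonspiking
and discarded.  Longitudinal effects are expressed as the per-plate
DIV21/DIV14 rate ratio normalized to the mean ratio of control plates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .datatypes import SpikeTrains
from .synthetic import MEARecording

__all__ = [
    "ChannelRates",
    "highpass_filter",
    "detect_spikes",
    "detect_all_channels",
    "channel_rates",
    "normalized_change",
]


@dataclass
class ChannelRates:
    """Per-channel firing rates with the nonspiking-channel flag."""

    rates_hz: np.ndarray
    active: np.ndarray           # rate >= 0.1 Hz (strict < discards)
    network_mean_hz: float       # mean over active channels, NaN if none
    analysis_duration_s: float
    min_rate_hz: float = 0.1

    @property
    def n_active(self) -> int:
        return int(self.active.sum())


def highpass_filter(
    trace: np.ndarray, cutoff_hz: float = 300.0, sampling_rate_hz: float = 10000.0
) -> np.ndarray:
    """Zero-phase 4th-order Butterworth high-pass."""
    if cutoff_hz >= sampling_rate_hz / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    sos = signal.butter(4, cutoff_hz, btype="highpass", fs=sampling_rate_hz, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(trace, dtype=np.float64))


def detect_spikes(
    filtered: np.ndarray,
    threshold_sd: float = 6.0,
    sd_estimator: str = "robust",
    dead_time_ms: float = 1.0,
    sampling_rate_hz: float = 10000.0,
) -> np.ndarray:
    """Detect spikes as +/- ``threshold_sd`` sigma crossings of a filtered trace.

    The noise sd is estimated robustly as median(|x|)/0.6745 by default
    (``sd_estimator='plain'`` uses the sample sd, which spikes inflate).
    Each contiguous supra-threshold excursion yields one event at its
    absolute-amplitude peak; events within ``dead_time_ms`` of an accepted
    event are suppressed.  Returns spike times in seconds.
    """
    if dead_time_ms < 0:
        raise ValueError("dead time must be non-negative")
    x = np.asarray(filtered, dtype=np.float64)
    if sd_estimator == "robust":
        sigma = np.median(np.abs(x)) / 0.6745
    elif sd_estimator == "plain":
        sigma = float(np.std(x))
    else:
        raise ValueError(f"unknown sd_estimator {sd_estimator!r}")
    if sigma == 0:
        return np.empty(0)

    above = np.abs(x) > threshold_sd * sigma
    if not above.any():
        return np.empty(0)
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(x)]

    peaks = np.array(
        [s + int(np.argmax(np.abs(x[s:e]))) for s, e in zip(starts, ends)],
        dtype=np.int64,
    )
    dead = dead_time_ms * 1e-3 * sampling_rate_hz
    accepted = []
    last = -np.inf
    for p in peaks:
        if p - last >= dead:
            accepted.append(p)
            last = p
    return np.array(accepted, dtype=np.float64) / sampling_rate_hz


def detect_all_channels(
    rec: MEARecording,
    threshold_sd: float = 6.0,
    highpass_hz: float = 300.0,
    sd_estimator: str = "robust",
    dead_time_ms: float = 1.0,
) -> SpikeTrains:
    """Filter and detect spikes on every channel of a recording."""
    times = []
    sds = []
    for ch in range(rec.n_channels):
        f = highpass_filter(rec.traces[ch], highpass_hz, rec.sampling_rate_hz)
        if sd_estimator == "robust":
            sds.append(np.median(np.abs(f)) / 0.6745)
        else:
            sds.append(float(np.std(f)))
        times.append(
            detect_spikes(
                f,
                threshold_sd=threshold_sd,
                sd_estimator=sd_estimator,
                dead_time_ms=dead_time_ms,
                sampling_rate_hz=rec.sampling_rate_hz,
            )
        )
    return SpikeTrains(
        times_s=times,
        sampling_rate_hz=rec.sampling_rate_hz,
        analysis_duration_s=rec.duration_s,
        threshold_sd=threshold_sd,
        highpass_hz=highpass_hz,
        dead_time_ms=dead_time_ms,
        sd_estimator=sd_estimator,
        sd_values=np.array(sds),
    )


def channel_rates(st: SpikeTrains, min_rate_hz: float = 0.1) -> ChannelRates:
    """Mean firing rate per channel over the analysis session.

    Channels with rate strictly below ``min_rate_hz`` are flagged
    nonspiking and excluded from the network mean (a channel at exactly the
    threshold is kept).
    """
    duration = st.analysis_duration_s
    if duration <= 0:
        raise ValueError("analysis duration must be positive")
    rates = st.counts() / duration
    active = rates >= min_rate_hz
    network = float(rates[active].mean()) if active.any() else float("nan")
    return ChannelRates(
        rates_hz=rates,
        active=active,
        network_mean_hz=network,
        analysis_duration_s=duration,
        min_rate_hz=min_rate_hz,
    )


def normalized_change(
    rates_div14: dict,
    rates_div21: dict,
    control_plate_ids,
) -> pd.DataFrame:
    """Control-normalized DIV14 -> DIV21 network-rate change per plate.

    ``rates_div14`` / ``rates_div21`` map plate id to the plate's network
    mean firing rate at each time point.  Each plate's ratio
    ``r = rate_21 / rate_14`` is divided by the mean ratio over control
    plates, so the control group averages 1 by construction.  Plates with a
    zero or missing DIV14 rate are excluded and flagged.
    """
    control_plate_ids = list(control_plate_ids)
    if not control_plate_ids:
        raise ValueError("at least one control plate is required")
    plates = sorted(set(rates_div14) & set(rates_div21))
    rows = []
    for p in plates:
        r14, r21 = rates_div14[p], rates_div21[p]
        valid = np.isfinite(r14) and np.isfinite(r21) and r14 > 0
        rows.append(
            {
                "plate": p,
                "rate_div14_hz": r14,
                "rate_div21_hz": r21,
                "ratio": (r21 / r14) if valid else np.nan,
                "is_control": p in control_plate_ids,
                "excluded": not valid,
            }
        )
    df = pd.DataFrame(rows)
    ctrl = df[df["is_control"] & ~df["excluded"]]
    if ctrl.empty:
        raise ValueError("no valid control plate ratio")
    df["normalized_change"] = df["ratio"] / ctrl["ratio"].mean()
    return df
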