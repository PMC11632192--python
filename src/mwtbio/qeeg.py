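"""qEEG: from raw EEG to per-epoch theta/alpha drowsiness ratios.

The chain is band-pass (0.1-55 Hz) and optional 1-Hz-wide notch
filtering, artifact rejection on 2-s analysis windows, multitaper
spectral estimation every 2 s at 0.5 Hz resolution, and aggregation of
theta ([4, 8) Hz) over alpha ([8, 12) Hz) band power into 15-s epochs
anchored at lights-off.  The theta/alpha ratio rises with drowsiness as
posterior alpha drops out and theta activity emerges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import signal

from .epochs import EpochSeries

#: Analysis window length in seconds (step equals length: no overlap).
WINDOW_S = 2.0
#: Multitaper time-bandwidth product and taper count.
MT_NW = 2.0
MT_K = 3

THETA_BAND = (4.0, 8.0)
ALPHA_BAND = (8.0, 12.0)


@dataclass
class EEGRecord:
    """Multichannel EEG in microvolts with lights-off/on markers.

    ``lights_off_s`` and ``lights_on_s`` are seconds relative to the first
    sample; ``t0`` is the clock time of the first sample (informational).
    """

    channels: Dict[str, np.ndarray]
    sampling_rate: float
    lights_off_s: float
    lights_on_s: float
    t0: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        lengths = {name: len(x) for name, x in self.channels.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"channels differ in length: {lengths}")
        self.channels = {
            name: np.asarray(x, dtype=float) for name, x in self.channels.items()
        }
        dur = self.n_samples / self.sampling_rate
        if not (0 <= self.lights_off_s < self.lights_on_s <= dur + 1e-9):
            raise ValueError(
                "require 0 <= lights_off < lights_on <= record duration "
                f"(got {self.lights_off_s}, {self.lights_on_s}, duration {dur:.1f})"
            )

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values()))) if self.channels else 0


@dataclass
class FilterConfig:
    """Band-pass corner frequencies and notch centers (1 Hz bandwidth each)."""

    bandpass_lo: float = 0.1
    bandpass_hi: float = 55.0
    notches: Tuple[float, ...] = ()

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        if not (0 < self.bandpass_lo < self.bandpass_hi < nyq):
            raise ValueError(
                f"need 0 < lo < hi < Nyquist ({nyq} Hz); "
                f"got [{self.bandpass_lo}, {self.bandpass_hi}]"
            )
        for f0 in self.notches:
            if not (self.bandpass_lo < f0 < self.bandpass_hi):
                raise ValueError(f"notch at {f0} Hz outside passband")


@dataclass
class ArtifactThresholds:
    """Window-rejection thresholds.

    ``slew_max_uv`` is the maximum sample-to-sample step in microvolts at a
    256 Hz reference rate (scaled by 256/fs at other rates, i.e. a constant
    slew rate in uV/s); ``ptp_max_uv`` the maximum peak-to-peak amplitude;
    ``flat_run_s`` the flat-line run flagged as missing data;
    ``saturation_run`` the number of consecutive rail-pinned samples
    flagged as saturation.
    """

    slew_max_uv: float = 50.0
    ptp_max_uv: float = 500.0
    flat_run_s: float = 0.5
    saturation_run: int = 10


@dataclass
class ArtifactMask:
    """Per-2-s-window rejection flags with a reason per rejected window."""

    rejected: np.ndarray
    reason: np.ndarray  # '' | 'missing' | 'saturation' | 'slew' | 'artifact'
    window_s: float = WINDOW_S

    def __len__(self) -> int:
        return len(self.rejected)


@dataclass
class Spectrogram:
    """Multitaper power (uV^2/Hz) on a 2-s / 0.5-Hz grid.

    ``times`` are window centers in seconds relative to lights-off.
    """

    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray


def preprocess(eeg: EEGRecord, cfg: FilterConfig) -> EEGRecord:
    """Zero-phase band-pass plus notch filtering of every channel.

    The low edge is a 4th-order Butterworth high-pass; the high edge an
    8th-order Chebyshev-II low-pass whose 30 dB stopband starts at the
    corner, so out-of-band tones (e.g. 60 Hz line noise under a 55 Hz
    corner) are strongly attenuated while the sub-12 Hz bands feeding the
    theta/alpha ratio pass untouched.  Each notch is a 2nd-order IIR
    notch of 1 Hz bandwidth.  Everything is applied forward-backward, so
    band power carries no phase bias.
    """
    cfg.validate(eeg.sampling_rate)
    fs = eeg.sampling_rate
    sos_hp = signal.butter(4, cfg.bandpass_lo, btype="highpass", fs=fs, output="sos")
    sos_lp = signal.cheby2(8, 30, cfg.bandpass_hi, btype="lowpass", fs=fs, output="sos")
    out = {}
    for name, x in eeg.channels.items():
        if len(x) < 3 * (2 * 8 + 1):
            raise ValueError(f"channel {name} too short to filter")
        y = signal.sosfiltfilt(sos_lp, signal.sosfiltfilt(sos_hp, x))
        for f0 in cfg.notches:
            b, a = signal.iirnotch(f0, Q=f0 / 1.0, fs=fs)
            y = signal.filtfilt(b, a, y)
        out[name] = y
    return EEGRecord(
        channels=out,
        sampling_rate=fs,
        lights_off_s=eeg.lights_off_s,
        lights_on_s=eeg.lights_on_s,
        t0=eeg.t0,
    )


def _run_lengths_true(mask: np.ndarray) -> int:
    """Longest run of True in a boolean array."""
    if not mask.any():
        return 0
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return int((edges[1::2] - edges[::2]).max())


def detect_artifacts(
    eeg: EEGRecord,
    thresholds: Optional[ArtifactThresholds] = None,
    channels: Optional[Sequence[str]] = None,
) -> ArtifactMask:
    """Flag 2-s analysis windows with data-quality problems.

    A window is rejected iff any rule fires on any inspected channel, with
    reasons recorded in priority order: ``missing`` (non-finite samples or
    a flat run of at least ``flat_run_s``), ``saturation`` (a run of
    ``saturation_run`` samples within one least-significant quantum of the
    channel's min or max), ``slew`` (sample-to-sample step above the
    scaled threshold), ``artifact`` (peak-to-peak above ``ptp_max_uv``).
    The window grid spans lights-off to lights-on.
    """
    thr = thresholds or ArtifactThresholds()
    fs = eeg.sampling_rate
    names = list(channels) if channels is not None else list(eeg.channels)
    win = int(round(WINDOW_S * fs))
    i0 = int(round(eeg.lights_off_s * fs))
    i1 = int(round(eeg.lights_on_s * fs))
    n_win = max(0, (i1 - i0) // win)
    rejected = np.zeros(n_win, dtype=bool)
    reason = np.array([""] * n_win, dtype=object)
    if n_win == 0:
        return ArtifactMask(rejected, reason)
    slew_thr = thr.slew_max_uv * (256.0 / fs)
    flat_run = int(round(thr.flat_run_s * fs))
    for name in names:
        x = eeg.channels[name]
        finite = x[np.isfinite(x)]
        if finite.size:
            lo, hi = finite.min(), finite.max()
            steps = np.abs(np.diff(finite))
            pos = steps[steps > 0]
            quantum = pos.min() if pos.size else np.finfo(float).eps
        else:
            lo = hi = 0.0
            quantum = np.finfo(float).eps
        for w in range(n_win):
            seg = x[i0 + w * win : i0 + (w + 1) * win]
            why = _classify_window(seg, lo, hi, quantum, slew_thr, flat_run, thr)
            if why and not rejected[w]:
                rejected[w] = True
                reason[w] = why
    return ArtifactMask(rejected, reason)


def _classify_window(seg, lo, hi, quantum, slew_thr, flat_run, thr) -> str:
    if not np.all(np.isfinite(seg)):
        return "missing"
    # saturation outranks the flat-line rule: a rail-pinned run fires both
    at_rail = (np.abs(seg - lo) <= quantum) | (np.abs(seg - hi) <= quantum)
    if _run_lengths_true(at_rail) >= thr.saturation_run:
        return "saturation"
    if flat_run > 1 and len(seg) > 1:
        flat = np.diff(seg) == 0
        if _run_lengths_true(flat) + 1 >= flat_run:
            return "missing"
    if len(seg) > 1 and np.abs(np.diff(seg)).max() > slew_thr:
        return "slew"
    if seg.size and (seg.max() - seg.min()) > thr.ptp_max_uv:
        return "artifact"
    return ""


def multitaper_spectrogram(eeg: EEGRecord, channel: str) -> Spectrogram:
    """Multitaper PSD every 2 s at 0.5 Hz resolution for one channel.

    Non-overlapping 2-s windows between lights-off and lights-on are
    tapered with DPSS tapers (time-bandwidth NW=2, 3 tapers) and the
    eigenvalue-weighted one-sided periodograms averaged.  The frequency
    grid is 0 to Nyquist at the 0.5 Hz spacing implied by the 2-s window.
    """
    if channel not in eeg.channels:
        raise KeyError(f"unknown channel {channel!r}; have {list(eeg.channels)}")
    fs = eeg.sampling_rate
    win = int(round(WINDOW_S * fs))
    x = eeg.channels[channel]
    i0 = int(round(eeg.lights_off_s * fs))
    i1 = int(round(eeg.lights_on_s * fs))
    n_win = (i1 - i0) // win
    if n_win < 1:
        raise ValueError("record shorter than one analysis window")
    seg = x[i0 : i0 + n_win * win].reshape(n_win, win)
    tapers, ratios = signal.windows.dpss(win, MT_NW, Kmax=MT_K, return_ratios=True)
    tapers = tapers / np.sqrt((tapers**2).sum(axis=1, keepdims=True))  # unit energy
    weights = ratios / ratios.sum()
    # (n_win, K, win): taper every window by every taper, then batch rfft
    tapered = seg[:, None, :] * tapers[None, :, :]
    spec = np.fft.rfft(tapered, axis=-1)
    psd = (np.abs(spec) ** 2) / fs
    psd[..., 1:] *= 2.0
    if win % 2 == 0:
        psd[..., -1] /= 2.0
    power = np.tensordot(psd, weights, axes=([1], [0]))
    freqs = np.fft.rfftfreq(win, d=1.0 / fs)
    times = (np.arange(n_win) + 0.5) * WINDOW_S
    return Spectrogram(times=times, freqs=freqs, power=power)


def band_power(spec: Spectrogram, band: Tuple[float, float]) -> np.ndarray:
    """Summed power over a half-open frequency band [lo, hi) per window."""
    lo, hi = band
    sel = (spec.freqs >= lo) & (spec.freqs < hi)
    return spec.power[:, sel].sum(axis=1)


def band_ratio_epochs(
    spec: Spectrogram,
    mask: Optional[ArtifactMask] = None,
    epoch_len: float = 15.0,
    theta: Tuple[float, float] = THETA_BAND,
    alpha: Tuple[float, float] = ALPHA_BAND,
    min_windows: int = 4,
) -> EpochSeries:
    """theta/alpha ratio per 15-s epoch from unrejected analysis windows.

    Windows are assigned to epochs by window start time; each epoch's
    surviving window spectra are averaged, theta power summed over
    [4, 8) Hz and alpha over [8, 12) Hz (half-open so the shared 8 Hz bin
    is counted once).  An epoch is invalid when fewer than ``min_windows``
    of its windows survive or its alpha power is zero.  An all-rejected
    record yields an all-invalid series, not an error.
    """
    n_win = len(spec.times)
    keep = np.ones(n_win, dtype=bool)
    if mask is not None:
        if len(mask) != n_win:
            raise ValueError("mask and spectrogram window grids differ")
        keep = ~mask.rejected
    starts = spec.times - WINDOW_S / 2.0
    epoch_idx = np.floor(starts / epoch_len + 1e-9).astype(int)
    n_epochs = int(epoch_idx.max()) + 1 if n_win else 0
    values = np.full(n_epochs, np.nan)
    valid = np.zeros(n_epochs, dtype=bool)
    sel_t = (spec.freqs >= theta[0]) & (spec.freqs < theta[1])
    sel_a = (spec.freqs >= alpha[0]) & (spec.freqs < alpha[1])
    for e in range(n_epochs):
        rows = keep & (epoch_idx == e)
        if rows.sum() < min_windows:
            continue
        mean_spec = spec.power[rows].mean(axis=0)
        p_theta = mean_spec[sel_t].sum()
        p_alpha = mean_spec[sel_a].sum()
        if p_alpha <= 0:
            continue
        values[e] = p_theta / p_alpha
        valid[e] = True
    return EpochSeries(values=values, epoch_len=epoch_len, valid=valid)


def suggest_notches(
    spec: Spectrogram, threshold_db: float = 10.0, half_window_hz: float = 3.0
) -> np.ndarray:
    """Flag spectral peaks more than ``threshold_db`` above the local median floor.

    A helper for choosing notch frequencies (e.g. line-interference
    harmonics); candidates are reported only, never applied automatically.
    """
    mean_psd = spec.power.mean(axis=0)
    log_p = 10 * np.log10(np.maximum(mean_psd, 1e-30))
    half = max(1, int(round(half_window_hz / (spec.freqs[1] - spec.freqs[0]))))
    flagged = []
    for i in range(1, len(spec.freqs) - 1):
        lo, hi = max(0, i - half), min(len(log_p), i + half + 1)
        local = np.median(np.concatenate([log_p[lo:i], log_p[i + 1 : hi]]))
        if (
            log_p[i] - local > threshold_db
            and log_p[i] >= log_p[i - 1]
            and log_p[i] >= log_p[i + 1]
        ):
            flagged.append(spec.freqs[i])
    return np.asarray(flagged)
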