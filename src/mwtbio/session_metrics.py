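"""Per-session MWT endpoints.

One Maintenance of Wakefulness Test (MWT) trial yields ten endpoints:
sleep onset latency (SOL), microsleep rate and mean duration, the
hypnodensity-derived sleepiness score (average, slope, intercept of a
log-linear fit), the qEEG theta/alpha ratio (average, slope, intercept),
and the interpolated Karolinska Sleepiness Scale (KSS) score.  This module
computes each endpoint from its scored or derived inputs and compiles the
long-format study table consumed by :mod:`mwtbio.stats`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .epochs import LOG_FLOOR, STAGES, EpochSeries

#: Microsleeps are sleep intrusions of at least 3 and strictly less than
#: 15 seconds.
MICROSLEEP_MIN_S = 3.0
MICROSLEEP_MAX_S = 15.0

#: Minimum usable epochs for a trajectory fit (one minute of 15-s epochs).
MIN_FIT_EPOCHS = 4

DEEP_STAGES = frozenset({"N2", "N3", "REM"})


def parse_clock(value: str | float) -> float:
    """Parse an ``HH:MM`` clock string to minutes from midnight."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    parts = str(value).strip().split(":")
    if len(parts) not in (2, 3):
        raise ValueError(f"cannot parse clock time {value!r}")
    h, m = int(parts[0]), int(parts[1])
    s = float(parts[2]) if len(parts) == 3 else 0.0
    return h * 60.0 + m + s / 60.0


@dataclass(frozen=True)
class MicrosleepEvent:
    """A scored microsleep: onset seconds after lights-off, duration seconds."""

    onset_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if not (MICROSLEEP_MIN_S <= self.duration_s < MICROSLEEP_MAX_S):
            raise ValueError(
                f"microsleep duration {self.duration_s} s outside "
                f"[{MICROSLEEP_MIN_S}, {MICROSLEEP_MAX_S}) s"
            )
        if self.onset_s < 0:
            raise ValueError("microsleep onset before lights-off")


@dataclass
class MicrosleepMetrics:
    """Events per 30-s epoch and mean event duration for one session."""

    rate: float
    mean_duration_s: float
    n_events: int = 0


@dataclass
class SOLResult:
    """Scored sleep onset latency.

    ``onset_epoch`` is the first 30-s epoch of unambiguous sleep onset;
    ``trigger_epoch`` the epoch at which the scoring rule is confirmed
    (the third N1 epoch, or the onset epoch itself for N2/N3/REM).
    """

    sol_min: float
    censored: bool
    onset_epoch: Optional[int] = None
    trigger_epoch: Optional[int] = None


@dataclass
class TrajectoryFit:
    """Log-linear fit of an epoch series over the pre-sleep-onset window."""

    slope: float
    intercept: float
    average: float
    n_epochs_used: int
    fit_window_end_min: float
    valid: bool = True


@dataclass
class KSSSeries:
    """Karolinska Sleepiness Scale measurements over a day.

    ``times`` are clock times (``HH:MM`` strings or minutes from midnight),
    strictly increasing; scores lie in [1, 9].
    """

    times: Sequence[str | float]
    scores: Sequence[float]
    times_min: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.times_min = np.array([parse_clock(t) for t in self.times], dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.times_min) != len(self.scores):
            raise ValueError("times and scores must have equal length")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("KSS measurement times must be strictly increasing")
        if np.any((self.scores < 1) | (self.scores > 9)):
            raise ValueError("KSS scores must lie in [1, 9]")


def sleepiness_from_hypnodensity(
    hypnodensity: np.ndarray, epoch_len: float = 15.0, tol: float = 1e-3
) -> EpochSeries:
    """Sleepiness score per epoch: summed non-wake stage probabilities.

    Each hypnodensity row is a probability 5-vector over (W, N1, N2, N3,
    REM); the sleepiness score is ``1 - p_W``, equivalently the sum of the
    four sleep-stage probabilities.

    Raises
    ------
    ValueError
        If any row's probabilities deviate from summing to 1 by more than
        ``tol`` (the offending row index is named).
    """
    h = np.asarray(hypnodensity, dtype=float)
    if h.ndim != 2 or h.shape[1] != 5:
        raise ValueError("hypnodensity must be an (n_epochs, 5) array")
    sums = h.sum(axis=1)
    bad = np.flatnonzero(np.abs(sums - 1.0) > tol)
    if bad.size:
        raise ValueError(
            f"hypnodensity row {bad[0]} sums to {sums[bad[0]]:.6f}, not 1"
        )
    if np.any(h < -tol) or np.any(h > 1 + tol):
        raise ValueError("hypnodensity entries must lie in [0, 1]")
    return EpochSeries(values=h[:, 1:].sum(axis=1), epoch_len=epoch_len)


def score_sol(stages: Sequence[str], max_min: float) -> SOLResult:
    """Score sleep onset latency from a 30-s-epoch hypnogram.

    Unambiguous sleep onset is the earliest epoch ``e`` such that epochs
    ``e, e+1, e+2`` are all N1, or epoch ``e`` is any deeper stage (N2, N3
    or REM).  SOL is ``0.5 * e`` minutes; with no onset the session is
    censored at ``max_min``.
    """
    stages = list(stages)
    if not stages:
        raise ValueError("empty hypnogram")
    for i, s in enumerate(stages):
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r} at epoch {i}")
    n = len(stages)
    for e in range(n):
        if stages[e] in DEEP_STAGES:
            return SOLResult(0.5 * e, censored=False, onset_epoch=e, trigger_epoch=e)
        if (
            e + 2 < n
            and stages[e] == "N1"
            and stages[e + 1] == "N1"
            and stages[e + 2] == "N1"
        ):
            return SOLResult(
                0.5 * e, censored=False, onset_epoch=e, trigger_epoch=e + 2
            )
    return SOLResult(float(max_min), censored=True)


def fit_log_trajectory(
    series: EpochSeries,
    sol: SOLResult,
    floor: float = LOG_FLOOR,
    min_epochs: int = MIN_FIT_EPOCHS,
    window: str = "to_sol",
) -> TrajectoryFit:
    """Ordinary least squares of the log-transformed series on time.

    Values are clipped below at ``floor`` and natural-log-transformed;
    the fit regresses log value on epoch-center time in minutes from
    lights-off, over valid epochs whose centers precede sleep onset
    (the whole session when SOL is censored or ``window == "full"``).
    The ``average`` is the mean of the untransformed values over the same
    window.  Fewer than ``min_epochs`` usable epochs marks the fit invalid.
    """
    if window not in ("to_sol", "full"):
        raise ValueError("window must be 'to_sol' or 'full'")
    t = series.centers_min
    use = series.valid.copy()
    if window == "to_sol" and not sol.censored:
        use &= t < sol.sol_min
        end = float(sol.sol_min)
    else:
        end = series.duration_min
    n_used = int(use.sum())
    if n_used < min_epochs:
        return TrajectoryFit(
            slope=math.nan,
            intercept=math.nan,
            average=float(series.values[use].mean()) if n_used else math.nan,
            n_epochs_used=n_used,
            fit_window_end_min=end,
            valid=False,
        )
    y = np.log(np.clip(series.values[use], floor, None))
    slope, intercept = np.polyfit(t[use], y, 1)
    return TrajectoryFit(
        slope=float(slope),
        intercept=float(intercept),
        average=float(series.values[use].mean()),
        n_epochs_used=n_used,
        fit_window_end_min=end,
        valid=True,
    )


def microsleep_metrics(
    events: Iterable[MicrosleepEvent],
    session_duration_min: float,
    denominator: str = "session",
    sol_min: Optional[float] = None,
) -> MicrosleepMetrics:
    """Microsleep rate (events per 30-s epoch) and mean duration.

    The rate denominator is the number of complete 30-s epochs in the
    session (lights-off to lights-on); ``denominator="pre_sol"`` restricts
    it to epochs before ``sol_min``.  With no events both metrics are 0.
    """
    if session_duration_min <= 0:
        raise ValueError("session_duration_min must be positive")
    events = list(events)
    for ev in events:
        if not (MICROSLEEP_MIN_S <= ev.duration_s < MICROSLEEP_MAX_S):
            raise ValueError(
                f"microsleep duration {ev.duration_s} s outside "
                f"[{MICROSLEEP_MIN_S}, {MICROSLEEP_MAX_S}) s"
            )
    if not events:
        return MicrosleepMetrics(rate=0.0, mean_duration_s=0.0, n_events=0)
    if denominator == "pre_sol":
        if sol_min is None:
            raise ValueError("denominator='pre_sol' requires sol_min")
        span = min(sol_min, session_duration_min)
    elif denominator == "session":
        span = session_duration_min
    else:
        raise ValueError("denominator must be 'session' or 'pre_sol'")
    n_epochs = max(1, math.floor(span * 2))
    durations = np.array([ev.duration_s for ev in events])
    return MicrosleepMetrics(
        rate=len(events) / n_epochs,
        mean_duration_s=float(durations.mean()),
        n_events=len(events),
    )


def interpolate_kss(kss: KSSSeries, session_time: str | float) -> float:
    """KSS score linearly interpolated in clock time to a session start.

    Returns ``nan`` (missing) when the session time falls outside the span
    of the measurements — no extrapolation.
    """
    t = parse_clock(session_time)
    tm = kss.times_min
    if len(tm) == 0 or t < tm[0] or t > tm[-1]:
        return math.nan
    return float(np.interp(t, tm, np.asarray(kss.scores, dtype=float)))


# ---------------------------------------------------------------------------
# Study-level endpoint compilation


ENDPOINT_COLUMNS = [
    "sol_min",
    "sol_censored",
    "inverse_sol",
    "microsleep_rate",
    "microsleep_duration",
    "sleepiness_avg",
    "sleepiness_slope",
    "sleepiness_intercept",
    "theta_alpha_avg",
    "theta_alpha_slope",
    "theta_alpha_intercept",
    "kss",
]


def compile_endpoints(
    study,
    include_qeeg: bool = False,
    siesta_time: str = "14:00",
    window: str = "to_sol",
    qeeg_fs: float = 256.0,
) -> pd.DataFrame:
    """Compile the long-format endpoint table for a simulated study.

    One row per participant x day x session with the ten endpoints, the
    ``isSiesta`` indicator (scheduled 14:00 slot), ``inverse_sol`` (1/min,
    computed on censored values too and flagged), and the
    ``slope_analysis_eligible`` filter (SOL > 1 minute).

    With ``include_qeeg`` the occipital EEG is synthesized for every
    session and pushed through the full qEEG chain; otherwise the
    theta/alpha endpoints are left missing.
    """
    from . import qeeg as _qeeg  # deferred: avoid import cycle at module load

    rows = []
    seen = set()
    for key, session in study.sessions.items():
        participant, day, session_time = key
        if key in seen:
            raise ValueError(f"duplicate session key {key}")
        seen.add(key)
        sleepiness = sleepiness_from_hypnodensity(
            session.hypnodensity, epoch_len=session.epoch_len_fine
        )
        sol = session.sol
        fit = fit_log_trajectory(sleepiness, sol, window=window)
        ms = microsleep_metrics(session.microsleeps, session.duration_min)
        row = {
            "participant": participant,
            "cohort": session.cohort,
            "treatment": session.treatment,
            "day": day,
            "session_time": session_time,
            "isSiesta": int(session_time == siesta_time),
            "sol_min": sol.sol_min,
            "sol_censored": bool(sol.censored),
            "inverse_sol": 1.0 / sol.sol_min if sol.sol_min > 0 else math.nan,
            "microsleep_rate": ms.rate,
            "microsleep_duration": ms.mean_duration_s,
            "sleepiness_avg": fit.average,
            "sleepiness_slope": fit.slope,
            "sleepiness_intercept": fit.intercept,
            "theta_alpha_avg": math.nan,
            "theta_alpha_slope": math.nan,
            "theta_alpha_intercept": math.nan,
            "slope_analysis_eligible": bool(sol.sol_min > 1.0),
        }
        if include_qeeg:
            from .simstudy import synthesize_eeg

            eeg = synthesize_eeg(session, fs=qeeg_fs)
            eeg = _qeeg.preprocess(eeg, _qeeg.FilterConfig())
            mask = _qeeg.detect_artifacts(eeg)
            spec = _qeeg.multitaper_spectrogram(eeg, channel="O2")
            ratio = _qeeg.band_ratio_epochs(spec, mask)
            qfit = fit_log_trajectory(ratio, sol, window=window)
            row["theta_alpha_avg"] = qfit.average
            row["theta_alpha_slope"] = qfit.slope
            row["theta_alpha_intercept"] = qfit.intercept
        kss_table = getattr(study, "kss", None)
        row["kss"] = math.nan
        if kss_table is not None:
            sel = kss_table[
                (kss_table["participant"] == participant) & (kss_table["day"] == day)
            ]
            if len(sel):
                series = KSSSeries(
                    times=sel["clock_time"].tolist(), scores=sel["score"].tolist()
                )
                row["kss"] = interpolate_kss(series, session_time)
        rows.append(row)
    table = pd.DataFrame(rows)
    if len(table) != len(seen):
        raise ValueError("duplicate (participant, day, session) keys")
    return table.sort_values(["participant", "day", "session_time"]).reset_index(
        drop=True
    )
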