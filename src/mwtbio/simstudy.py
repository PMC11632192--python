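"""Synthetic MWT sessions and studies with known ground truth.

The generative model: latent sleepiness during a Maintenance of
Wakefulness Test session is exactly log-linear from lights-off,
``S(t) = clip(exp(a + b*t + eps_t), 1e-3, 1)`` with per-epoch Gaussian
noise on the log scale, so the downstream log-linear trajectory fit is
correctly specified and recovery tests are sharp.  From the latent
trajectory the simulator derives per-15-s-epoch hypnodensities (stage
probability vectors whose non-wake mass equals S), a 30-s hypnogram via
stage thresholds, the scored sleep onset latency, microsleep events as an
inhomogeneous Poisson process during wake, and optionally an occipital
EEG channel whose alpha (10 Hz) and theta (6 Hz) oscillation amplitudes
track wakefulness and sleepiness respectively.

A whole study mirrors a narcolepsy trial: treatment arms whose slope
changes by day, four sessions per day at 10:00/12:00/14:00/16:00, a
siesta slope bump at 14:00, and participant-level random intercepts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .epochs import LOG_FLOOR, EpochSeries
from .qeeg import EEGRecord
from .session_metrics import (
    MICROSLEEP_MAX_S,
    MICROSLEEP_MIN_S,
    MicrosleepEvent,
    SOLResult,
    score_sol,
)

__all__ = [
    "TrajectoryParams",
    "SimSessionConfig",
    "SessionRecord",
    "GroundTruth",
    "CohortSpec",
    "StudyDesign",
    "StudyDataset",
    "simulate_trajectory",
    "simulate_session",
    "synthesize_eeg",
    "simulate_study",
    "default_design",
]


@dataclass(frozen=True)
class TrajectoryParams:
    """Latent log-linear sleepiness trajectory for one session.

    ``intercept_a`` is log-sleepiness at lights-off (so ``exp(a) <= 1``),
    ``slope_b`` the growth rate in 1/minute, ``noise_sd`` the sd of
    additive per-epoch noise on the log scale.
    """

    intercept_a: float
    slope_b: float
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("intercept_a", "slope_b", "noise_sd"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.intercept_a > 0:
            raise ValueError("exp(intercept_a) must be <= 1 (intercept_a <= 0)")


@dataclass(frozen=True)
class SimSessionConfig:
    """Grid and scoring configuration for one simulated session.

    ``theta_n1`` / ``theta_n2`` map mean epoch sleepiness to hypnogram
    stages (N1 above the first, N2 above the second);
    ``microsleep_base_rate`` is the event rate in events/minute when
    sleepiness is 1.
    """

    session_start: str = "10:00"
    max_duration: float = 40.0  # minutes
    epoch_len_fine: float = 15.0  # seconds
    epoch_len_stage: float = 30.0  # seconds
    theta_n1: float = 0.5
    theta_n2: float = 0.9
    microsleep_base_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.theta_n1 < self.theta_n2 <= 1):
            raise ValueError("require 0 < theta_n1 < theta_n2 <= 1")
        if self.max_duration <= 0:
            raise ValueError("max_duration must be positive")
        ratio = self.epoch_len_stage / self.epoch_len_fine
        if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
            raise ValueError("epoch_len_stage must be a multiple of epoch_len_fine")
        if self.microsleep_base_rate < 0:
            raise ValueError("microsleep_base_rate must be non-negative")


@dataclass
class SessionRecord:
    """One simulated MWT trial (times in seconds from lights-off)."""

    session_start: str
    duration_min: float
    epoch_len_fine: float
    epoch_len_stage: float
    hypnodensity: np.ndarray  # (n_fine, 5): p_W, p_N1, p_N2, p_N3, p_REM
    hypnogram: np.ndarray  # (n_stage,) of stage labels
    microsleeps: List[MicrosleepEvent]
    sol: SOLResult
    sleepiness: EpochSeries  # realized latent S per fine epoch
    seed: int = 0
    cohort: str = ""
    treatment: str = ""


@dataclass
class GroundTruth:
    """True parameters behind one simulated session."""

    intercept_a: float
    slope_b: float
    noise_sd: float
    analytic_sol_min: float
    censored: bool
    participant_intercept_offset: float = 0.0
    participant_slope_offset: float = 0.0


def analytic_sol(params: TrajectoryParams, cfg: SimSessionConfig) -> Tuple[float, bool]:
    """Noise-free threshold-crossing SOL: (ln theta_n1 - a) / b, censored at max."""
    ln_thr = math.log(cfg.theta_n1)
    if params.slope_b > 0:
        t = (ln_thr - params.intercept_a) / params.slope_b
        if t <= cfg.max_duration:
            return max(0.0, t), False
        return cfg.max_duration, True
    if params.intercept_a >= ln_thr:
        return 0.0, False
    return cfg.max_duration, True


def simulate_trajectory(
    params: TrajectoryParams,
    cfg: SimSessionConfig,
    rng: Optional[np.random.Generator] = None,
) -> EpochSeries:
    """Realized latent sleepiness on the fine epoch grid up to max duration."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n = int(round(cfg.max_duration * 60.0 / cfg.epoch_len_fine))
    t = (np.arange(n) + 0.5) * cfg.epoch_len_fine / 60.0
    log_s = params.intercept_a + params.slope_b * t
    if params.noise_sd > 0:
        log_s = log_s + rng.normal(0.0, params.noise_sd, size=n)
    return EpochSeries(
        values=np.clip(np.exp(log_s), LOG_FLOOR, 1.0), epoch_len=cfg.epoch_len_fine
    )


def _hypnodensity_from_s(s: np.ndarray) -> np.ndarray:
    """Allocate non-wake probability mass S across stages.

    N1 receives the fraction min(1, 2*(1-S)) of the non-wake mass and N2
    the remainder; N3 and REM stay at zero (MWT naps rarely reach them).
    """
    frac_n1 = np.minimum(1.0, 2.0 * (1.0 - s))
    p_n1 = s * frac_n1
    p_n2 = s - p_n1
    h = np.zeros((len(s), 5))
    h[:, 0] = 1.0 - s
    h[:, 1] = p_n1
    h[:, 2] = p_n2
    return h


def _stage_epochs(s_fine: np.ndarray, ratio: int, theta_n1: float, theta_n2: float):
    n_stage = len(s_fine) // ratio
    mean_s = s_fine[: n_stage * ratio].reshape(n_stage, ratio).mean(axis=1)
    stages = np.where(mean_s > theta_n2, "N2", np.where(mean_s > theta_n1, "N1", "W"))
    return stages.astype(object), mean_s


def _sample_microsleeps(
    s_fine: np.ndarray,
    wake_fine: np.ndarray,
    cfg: SimSessionConfig,
    duration_s: float,
    rng: np.random.Generator,
    max_resample: int = 100,
) -> List[MicrosleepEvent]:
    """Thinning sampler for the inhomogeneous Poisson microsleep process.

    Candidate events arrive at the maximal rate (base rate, events/min)
    and are accepted with probability S(t) restricted to wake epochs;
    overlapping accepted events are redrawn up to ``max_resample`` times.
    """
    if cfg.microsleep_base_rate == 0 or duration_s <= 0:
        return []
    lam_max = cfg.microsleep_base_rate / 60.0  # events per second
    n_cand = rng.poisson(lam_max * duration_s)
    taken: List[Tuple[float, float]] = []

    def admissible(onset: float, dur: float) -> bool:
        if onset + dur > duration_s:
            return False
        for o, d in taken:
            if onset < o + d and o < onset + dur:
                return False
        return True

    def accept(onset: float) -> bool:
        idx = min(int(onset // cfg.epoch_len_fine), len(s_fine) - 1)
        if not wake_fine[idx]:
            return False
        return rng.uniform() < s_fine[idx]

    for _ in range(n_cand):
        for _attempt in range(max_resample):
            onset = rng.uniform(0.0, duration_s)
            if not accept(onset):
                break  # thinning rejection: candidate discarded, not retried
            dur = rng.uniform(MICROSLEEP_MIN_S, MICROSLEEP_MAX_S)
            if admissible(onset, dur):
                taken.append((onset, dur))
                break
            # overlap: resample onset/duration
    taken.sort()
    return [MicrosleepEvent(onset_s=o, duration_s=d) for o, d in taken]


def simulate_session(
    params: TrajectoryParams,
    cfg: SimSessionConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[SessionRecord, GroundTruth]:
    """Simulate one MWT trial: hypnodensity, hypnogram, SOL, microsleeps.

    The trial is truncated one 30-s stage epoch after the sleep-onset rule
    fires (the technician ends the trial at unambiguous sleep onset), or
    at the maximum duration when no onset occurs.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    traj = simulate_trajectory(params, cfg, rng=rng)
    ratio = int(round(cfg.epoch_len_stage / cfg.epoch_len_fine))
    stages, _ = _stage_epochs(traj.values, ratio, cfg.theta_n1, cfg.theta_n2)
    sol = score_sol(stages, max_min=cfg.max_duration)
    if sol.censored:
        end_stage = len(stages)
    else:
        end_stage = min(sol.trigger_epoch + 2, len(stages))
    duration_min = end_stage * cfg.epoch_len_stage / 60.0
    n_fine = end_stage * ratio
    s_fine = traj.values[:n_fine]
    stages = stages[:end_stage]
    hypnodensity = _hypnodensity_from_s(s_fine)
    wake_fine = np.repeat(stages == "W", ratio)[:n_fine]
    events = _sample_microsleeps(
        s_fine, wake_fine, cfg, duration_min * 60.0, rng
    )
    record = SessionRecord(
        session_start=cfg.session_start,
        duration_min=duration_min,
        epoch_len_fine=cfg.epoch_len_fine,
        epoch_len_stage=cfg.epoch_len_stage,
        hypnodensity=hypnodensity,
        hypnogram=stages,
        microsleeps=events,
        sol=sol,
        sleepiness=EpochSeries(values=s_fine, epoch_len=cfg.epoch_len_fine),
        seed=cfg.seed,
    )
    a_sol, censored = analytic_sol(params, cfg)
    truth = GroundTruth(
        intercept_a=params.intercept_a,
        slope_b=params.slope_b,
        noise_sd=params.noise_sd,
        analytic_sol_min=a_sol,
        censored=censored,
    )
    return record, truth


# ---------------------------------------------------------------------------
# EEG synthesis

#: Peak oscillation amplitude (uV) shared by the alpha and theta generators.
OSC_AMP_UV = 40.0
#: RMS of the pink background noise (uV).
PINK_RMS_UV = 5.0
#: Theta boost / alpha suppression factors during microsleep events.
MS_THETA_BOOST = 3.0
MS_ALPHA_SUPPRESS = 0.25

ALPHA_HZ = 10.0
THETA_HZ = 6.0

# 3-pole IIR approximation to a 1/f (pink) amplitude spectrum
_PINK_B = np.array([0.049922035, -0.095993537, 0.050612699, -0.004408786])
_PINK_A = np.array([1.0, -2.494956002, 2.017265875, -0.522189400])


def synthesize_eeg(
    session: SessionRecord,
    fs: float = 256.0,
    channels: Sequence[str] = ("O2",),
    seed: Optional[int] = None,
) -> EEGRecord:
    """Synthesize occipital-style EEG tracking the latent trajectory.

    Each channel is pink background noise plus a 10 Hz alpha oscillation
    with amplitude proportional to wakefulness ``1 - S(t)`` and a 6 Hz
    theta oscillation with amplitude proportional to sleepiness ``S(t)``;
    during microsleep events theta is boosted and alpha suppressed.
    Deterministic given the seed (defaults to the session's own seed).
    """
    from scipy import signal as _sig

    if fs < 128:
        raise ValueError("sampling rate must be >= 128 Hz for 55 Hz content")
    rng = np.random.default_rng(
        np.random.SeedSequence([session.seed if seed is None else seed, 0x5EE6])
    )
    n = int(round(session.duration_min * 60.0 * fs))
    t = np.arange(n) / fs
    s_fine = session.sleepiness.values
    idx = np.minimum((t // session.epoch_len_fine).astype(int), len(s_fine) - 1)
    s_t = s_fine[idx]
    theta_gain = np.ones(n)
    alpha_gain = np.ones(n)
    for ev in session.microsleeps:
        j0 = int(round(ev.onset_s * fs))
        j1 = min(n, int(round((ev.onset_s + ev.duration_s) * fs)))
        theta_gain[j0:j1] = MS_THETA_BOOST
        alpha_gain[j0:j1] = MS_ALPHA_SUPPRESS
    out: Dict[str, np.ndarray] = {}
    for name in channels:
        pink = _sig.lfilter(_PINK_B, _PINK_A, rng.standard_normal(n))
        pink *= PINK_RMS_UV / max(pink.std(), 1e-12)
        phi_a, phi_t = rng.uniform(0, 2 * np.pi, size=2)
        alpha = OSC_AMP_UV * (1.0 - s_t) * alpha_gain * np.sin(
            2 * np.pi * ALPHA_HZ * t + phi_a
        )
        theta = OSC_AMP_UV * s_t * theta_gain * np.sin(2 * np.pi * THETA_HZ * t + phi_t)
        out[name] = pink + alpha + theta
    return EEGRecord(
        channels=out,
        sampling_rate=fs,
        lights_off_s=0.0,
        lights_on_s=n / fs,
        t0=session.session_start,
    )


# ---------------------------------------------------------------------------
# Whole-study simulation


@dataclass(frozen=True)
class CohortSpec:
    """One randomization arm: label, diagnostic group, dose, size, slopes.

    ``slope_by_day`` gives the arm's base log-sleepiness growth rate
    (1/min) for each study day; treatment effects are expressed as reduced
    slopes on post-baseline days.
    """

    label: str
    n_participants: int
    slope_by_day: Dict[str, float]
    group: str = ""
    treatment: str = ""

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("each cohort needs at least one participant")


@dataclass(frozen=True)
class StudyDesign:
    """Design of a simulated MWT study (defaults mirror a narcolepsy trial)."""

    cohorts: Tuple[CohortSpec, ...]
    days: Tuple[str, ...] = ("baseline", "day1", "day7")
    session_times: Tuple[str, ...] = ("10:00", "12:00", "14:00", "16:00")
    siesta_time: str = "14:00"
    intercept_a: float = -2.0
    participant_intercept_sd: float = 0.3
    participant_slope_sd: float = 0.02
    siesta_slope_bump: float = 0.05
    noise_sd: float = 0.2
    session_cfg: SimSessionConfig = field(default_factory=SimSessionConfig)
    simulate_kss: bool = True

    def __post_init__(self) -> None:
        if not self.cohorts:
            raise ValueError("study design needs at least one cohort")
        from .session_metrics import parse_clock

        mins = [parse_clock(t) for t in self.session_times]
        if any(b <= a for a, b in zip(mins, mins[1:])):
            raise ValueError("session clock times must be strictly increasing")
        for c in self.cohorts:
            missing = [d for d in self.days if d not in c.slope_by_day]
            if missing:
                raise ValueError(f"cohort {c.label} lacks slopes for days {missing}")


@dataclass
class StudyDataset:
    """A simulated study: sessions, design table, ground truth, KSS."""

    design: pd.DataFrame
    sessions: Dict[Tuple[str, str, str], SessionRecord]
    ground_truth: pd.DataFrame
    kss: Optional[pd.DataFrame]
    seed: int


def default_design() -> StudyDesign:
    """Trial-mirroring default: NT1 arms Bp/B1/B2, NT2 arms Cp/C1/C2.

    Untreated slopes give SOL around 10 minutes; high doses flatten the
    trajectory so sessions hit the 40-minute ceiling, strongest on day 1.
    """
    return StudyDesign(
        cohorts=(
            CohortSpec("Bp", 4, {"baseline": 0.12, "day1": 0.12, "day7": 0.12},
                       group="NT1", treatment="placebo"),
            CohortSpec("B1", 4, {"baseline": 0.12, "day1": 0.05, "day7": 0.06},
                       group="NT1", treatment="danavorexton-11mg"),
            CohortSpec("B2", 5, {"baseline": 0.12, "day1": 0.02, "day7": 0.03},
                       group="NT1", treatment="danavorexton-44mg"),
            CohortSpec("Cp", 5, {"baseline": 0.10, "day1": 0.09, "day7": 0.09},
                       group="NT2", treatment="placebo"),
            CohortSpec("C1", 4, {"baseline": 0.10, "day1": 0.03, "day7": 0.04},
                       group="NT2", treatment="danavorexton-44mg"),
            CohortSpec("C2", 5, {"baseline": 0.10, "day1": 0.015, "day7": 0.025},
                       group="NT2", treatment="danavorexton-112mg"),
        )
    )


def simulate_study(design: StudyDesign, seed: int = 0) -> StudyDataset:
    """Simulate every session of a study from a single study-level seed.

    Per-session randomness derives from ``SeedSequence(seed, participant
    index, day index, session index)``; each participant draws one random
    intercept offset and one slope offset.  The session slope is the
    cohort/day base slope plus the siesta bump at the siesta slot plus the
    participant's offset.
    """
    design_rows = []
    truth_rows = []
    kss_rows = []
    sessions: Dict[Tuple[str, str, str], SessionRecord] = {}
    p_global = 0
    for cohort in design.cohorts:
        for p_idx in range(cohort.n_participants):
            participant = f"{cohort.label}{p_idx + 1:02d}"
            p_rng = np.random.default_rng(
                np.random.SeedSequence([seed, p_global, 0xA11CE])
            )
            int_off = p_rng.normal(0.0, design.participant_intercept_sd)
            slope_off = p_rng.normal(0.0, design.participant_slope_sd)
            a_p = min(0.0, design.intercept_a + int_off)
            for d_idx, day in enumerate(design.days):
                day_means = []
                for s_idx, s_time in enumerate(design.session_times):
                    is_siesta = int(s_time == design.siesta_time)
                    b = (
                        cohort.slope_by_day[day]
                        + design.siesta_slope_bump * is_siesta
                        + slope_off
                    )
                    params = TrajectoryParams(
                        intercept_a=a_p, slope_b=b, noise_sd=design.noise_sd
                    )
                    ss = np.random.SeedSequence([seed, p_global, d_idx, s_idx])
                    session_seed = int(ss.generate_state(1)[0] % (2**31))
                    cfg = replace(
                        design.session_cfg, session_start=s_time, seed=session_seed
                    )
                    rng = np.random.default_rng(ss)
                    record, truth = simulate_session(params, cfg, rng=rng)
                    record.cohort = cohort.group or cohort.label
                    record.treatment = cohort.treatment or cohort.label
                    truth.participant_intercept_offset = int_off
                    truth.participant_slope_offset = slope_off
                    key = (participant, day, s_time)
                    sessions[key] = record
                    day_means.append(float(record.sleepiness.values.mean()))
                    design_rows.append(
                        {
                            "participant": participant,
                            "cohort": record.cohort,
                            "treatment": record.treatment,
                            "day": day,
                            "session_time": s_time,
                            "isSiesta": is_siesta,
                        }
                    )
                    truth_rows.append(
                        {
                            "participant": participant,
                            "day": day,
                            "session_time": s_time,
                            "true_intercept_a": a_p,
                            "true_slope_b": b,
                            "noise_sd": design.noise_sd,
                            "analytic_sol_min": truth.analytic_sol_min,
                            "sol_censored": truth.censored,
                            "n_microsleeps": len(record.microsleeps),
                            "participant_intercept_offset": int_off,
                            "participant_slope_offset": slope_off,
                        }
                    )
                if design.simulate_kss:
                    k_rng = np.random.default_rng(
                        np.random.SeedSequence([seed, p_global, d_idx, 0xC55])
                    )
                    base = float(np.mean(day_means))
                    for clock in ("09:00", "11:00", "13:00", "15:00", "17:00"):
                        score = 1.0 + 8.0 * base + k_rng.normal(0.0, 0.7)
                        kss_rows.append(
                            {
                                "participant": participant,
                                "day": day,
                                "clock_time": clock,
                                "score": float(np.clip(round(score), 1, 9)),
                            }
                        )
            p_global += 1
    return StudyDataset(
        design=pd.DataFrame(design_rows),
        sessions=sessions,
        ground_truth=pd.DataFrame(truth_rows),
        kss=pd.DataFrame(kss_rows) if design.simulate_kss else None,
        seed=seed,
    )
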