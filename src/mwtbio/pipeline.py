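"""Top-level pipeline: simulation -> qEEG -> endpoints -> statistics.

Each stage reads/writes the formats in :mod:`mwtbio.io`; a run directory
is self-describing via a structured run log (config hash, input hashes,
package version, warnings) so every output is traceable.
"""

from __future__ import annotations

import hashlib
import json
import math
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig, design_from_dict
from .io import (
    read_hypnodensity,
    read_hypnogram,
    read_kss,
    read_microsleeps,
    write_study,
)
from .session_metrics import (
    KSSSeries,
    compile_endpoints,
    fit_log_trajectory,
    interpolate_kss,
    microsleep_metrics,
    score_sol,
    sleepiness_from_hypnodensity,
    SOLResult,
)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def _design_from_config(config: PipelineConfig):
    from dataclasses import replace

    from .simstudy import SimSessionConfig, default_design

    if config.design is None:
        design = default_design()
    else:
        design = design_from_dict(config.design)
    session_cfg = SimSessionConfig(
        max_duration=config.sim.max_duration,
        epoch_len_fine=config.sim.epoch_len_fine,
        epoch_len_stage=config.sim.epoch_len_stage,
        theta_n1=config.sim.theta_n1,
        theta_n2=config.sim.theta_n2,
        microsleep_base_rate=config.sim.microsleep_base_rate,
    )
    return replace(design, session_cfg=session_cfg, siesta_time=config.siesta_time)


def run_pipeline(config: PipelineConfig, out_dir: Optional[str | Path] = None) -> Path:
    """Run simulate -> endpoints (with qEEG) -> statistics into a run directory.

    Deterministic given identical configuration and seed; rerunning into a
    fresh directory reproduces every output byte-for-byte.
    """
    from .simstudy import simulate_study
    from .stats import ModelDesign, PriorSpec, contrasts_change_from_baseline
    from .stats import fit_bayes_shrunk, fit_lmm

    t_start = time.time()
    out = Path(out_dir) if out_dir is not None else Path(config.out_dir)
    warnings_log = []

    try:
        design = _design_from_config(config)
        study = simulate_study(design, seed=config.seed)
        write_study(study, out, write_eeg=config.write_eeg)
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise PipelineError("simulate", str(exc)) from exc

    try:
        endpoints = compile_endpoints(
            study,
            include_qeeg=config.include_qeeg,
            siesta_time=config.siesta_time,
            window=config.fit_window,
            qeeg_fs=config.qeeg_fs,
        )
        endpoints.to_csv(out / "endpoints.csv", index=False, float_format="%.10g")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("endpoints", str(exc)) from exc

    n_censored = int(endpoints["sol_censored"].sum())
    if n_censored:
        warnings_log.append(f"{n_censored} sessions censored at max duration")
    n_invalid = int(endpoints["sleepiness_slope"].isna().sum())
    if n_invalid:
        warnings_log.append(f"{n_invalid} sessions with invalid trajectory fits")

    model_out = {}
    try:
        for endpoint in config.stats.endpoints:
            for cohort, sub in endpoints.groupby("cohort"):
                if sub["treatment"].nunique() < 1 or sub[endpoint].dropna().empty:
                    continue
                md = ModelDesign(response=endpoint)
                key = f"{endpoint}[{cohort}]"
                if config.stats.model == "lmm":
                    fit = fit_lmm(sub, md)
                    if not fit.converged:
                        warnings_log.append(f"{key}: LMM did not converge")
                    contrasts = contrasts_change_from_baseline(fit, md)
                    model_out[key] = {
                        "model": "lmm",
                        "params": fit.params.to_dict(),
                        "bse": fit.bse.to_dict(),
                        "participant_sd": fit.participant_sd,
                        "residual_sd": fit.residual_sd,
                        "converged": fit.converged,
                        "contrasts": contrasts.to_dict(orient="records"),
                    }
                else:
                    post = fit_bayes_shrunk(
                        sub,
                        md,
                        PriorSpec(config.stats.t),
                        chains=config.stats.chains,
                        iters=config.stats.iters,
                        seed=config.seed,
                    )
                    if not post.reliable:
                        warnings_log.append(f"{key}: R-hat > 1.1, fit flagged")
                    model_out[key] = {
                        "model": "bayes",
                        "t": config.stats.t,
                        "posterior_mean": post.posterior_mean().to_dict(),
                        "posterior_sd": post.posterior_sd().to_dict(),
                        "reliable": post.reliable,
                    }
        (out / "models.json").write_text(json.dumps(model_out, indent=1, default=float))
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("fit", str(exc)) from exc

    log = {
        "version": __version__,
        "config_hash": config.digest(),
        "seed": config.seed,
        "elapsed_s": round(time.time() - t_start, 2),
        "n_sessions": len(endpoints),
        "input_hashes": {
            "endpoints.csv": _file_hash(out / "endpoints.csv"),
            "design.csv": _file_hash(out / "design.csv"),
        },
        "warnings": warnings_log,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1))
    return out


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def endpoints_from_dir(
    run_dir: str | Path,
    include_qeeg: str | bool = "auto",
    siesta_time: str = "14:00",
) -> pd.DataFrame:
    """Recompute the endpoint table from a written study directory.

    Sessions are read back from the CSV artifacts (hypnodensity,
    hypnogram, microsleeps, session metadata, study-level KSS); theta/
    alpha endpoints are computed when a session directory contains an
    ``eeg.csv`` (``include_qeeg='auto'``), always (``True``, an error if
    missing), or never (``False``).
    """
    from . import qeeg as _qeeg
    from .io import read_signals_csv

    run_dir = Path(run_dir)
    sess_root = run_dir / "sessions"
    if not sess_root.is_dir():
        raise FileNotFoundError(f"{run_dir}: no sessions/ directory")
    kss_path = run_dir / "kss.csv"
    kss = read_kss(kss_path) if kss_path.exists() else None
    rows = []
    for d in sorted(sess_root.iterdir()):
        if not d.is_dir():
            continue
        meta = json.loads((d / "session.json").read_text())
        h = read_hypnodensity(d / "hypnodensity.csv")
        stages = read_hypnogram(d / "hypnogram.csv")
        events = read_microsleeps(d / "microsleeps.csv")
        duration_min = float(meta["duration_min"])
        sol = SOLResult(
            sol_min=float(meta["sol_min"]), censored=bool(meta["sol_censored"])
        )
        sleepiness = sleepiness_from_hypnodensity(h)
        fit = fit_log_trajectory(sleepiness, sol)
        ms = microsleep_metrics(events, duration_min)
        session_time = meta["session_time"]
        row = {
            "participant": meta["participant"],
            "cohort": meta.get("cohort", ""),
            "treatment": meta.get("treatment", ""),
            "day": meta["day"],
            "session_time": session_time,
            "isSiesta": int(session_time == siesta_time),
            "sol_min": sol.sol_min,
            "sol_censored": sol.censored,
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
            "kss": math.nan,
        }
        eeg_path = d / "eeg.csv"
        want_qeeg = include_qeeg is True or (
            include_qeeg == "auto" and eeg_path.exists()
        )
        if want_qeeg:
            if not eeg_path.exists():
                raise PipelineError("qeeg", f"{d}: eeg.csv missing")
            eeg = read_signals_csv(eeg_path)
            eeg = _qeeg.preprocess(eeg, _qeeg.FilterConfig())
            mask = _qeeg.detect_artifacts(eeg)
            spec = _qeeg.multitaper_spectrogram(eeg, channel=list(eeg.channels)[0])
            ratio = _qeeg.band_ratio_epochs(spec, mask)
            qfit = fit_log_trajectory(ratio, sol)
            row["theta_alpha_avg"] = qfit.average
            row["theta_alpha_slope"] = qfit.slope
            row["theta_alpha_intercept"] = qfit.intercept
        if kss is not None:
            sel = kss[
                (kss["participant"] == meta["participant"]) & (kss["day"] == meta["day"])
            ]
            if len(sel):
                series = KSSSeries(
                    times=sel["clock_time"].tolist(), scores=sel["score"].tolist()
                )
                row["kss"] = interpolate_kss(series, session_time)
        rows.append(row)
    table = pd.DataFrame(rows)
    dupes = table.duplicated(subset=["participant", "day", "session_time"])
    if dupes.any():
        raise ValueError("duplicate (participant, day, session) keys in run dir")
    return table.sort_values(["participant", "day", "session_time"]).reset_index(
        drop=True
    )
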