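"""Readers and writers for the pipeline's file formats.

All tables are plain CSV with documented headers; signals use either EDF
(read-only, via :mod:`mne`, imported lazily) or the package's columnar
CSV dialect, whose comment header carries the sampling rate and
lights-off/on markers.  Times are serialized as seconds relative to
lights-off; epoch indices are 0-based with half-open intervals; clock
times are ``HH:MM``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .epochs import STAGES
from .qeeg import EEGRecord
from .session_metrics import (
    MICROSLEEP_MAX_S,
    MICROSLEEP_MIN_S,
    MicrosleepEvent,
)

SIGNAL_MAGIC = "# mwtbio-signal-v1"


class AnnotationError(ValueError):
    """Raised with every row-level problem found in an annotation file."""


# ---------------------------------------------------------------------------
# Signals


def write_signals_csv(eeg: EEGRecord, path: str | Path, fmt: str = "%.4f") -> None:
    """Write an EEGRecord in the columnar CSV dialect."""
    path = Path(path)
    names = list(eeg.channels)
    data = np.column_stack([eeg.channels[n] for n in names])
    with open(path, "w") as fh:
        fh.write(SIGNAL_MAGIC + "\n")
        fh.write(f"# sampling_rate_hz: {eeg.sampling_rate!r}\n")
        fh.write(f"# lights_off_s: {eeg.lights_off_s!r}\n")
        fh.write(f"# lights_on_s: {eeg.lights_on_s!r}\n")
        if eeg.t0 is not None:
            fh.write(f"# t0: {eeg.t0}\n")
        fh.write(",".join(names) + "\n")
        np.savetxt(fh, data, fmt=fmt, delimiter=",")


def read_signals_csv(path: str | Path) -> EEGRecord:
    """Read the columnar CSV signal dialect back into an EEGRecord."""
    path = Path(path)
    meta = {}
    t0 = None
    n_header = 0
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != SIGNAL_MAGIC:
            raise ValueError(f"{path}: not an mwtbio signal CSV (bad magic line)")
        n_header = 1
        for line in fh:
            if not line.startswith("#"):
                columns = line.strip().split(",")
                n_header += 1
                break
            key, _, val = line[1:].partition(":")
            key = key.strip()
            val = val.strip()
            if key == "t0":
                t0 = val
            else:
                meta[key] = float(val)
            n_header += 1
        else:
            raise ValueError(f"{path}: truncated header (no channel row)")
    try:
        data = np.loadtxt(path, delimiter=",", skiprows=n_header, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"{path}: parse error in sample block: {exc}") from exc
    for key in ("sampling_rate_hz", "lights_off_s", "lights_on_s"):
        if key not in meta:
            raise ValueError(f"{path}: missing header field {key}")
    return EEGRecord(
        channels={name: data[:, i] for i, name in enumerate(columns)},
        sampling_rate=meta["sampling_rate_hz"],
        lights_off_s=meta["lights_off_s"],
        lights_on_s=meta["lights_on_s"],
        t0=t0,
    )


def read_signals(
    path: str | Path, annotations: Optional[str | Path] = None
) -> EEGRecord:
    """Read EEG from EDF or the simulator CSV dialect.

    For EDF, lights-off/on markers come from an annotations CSV with
    columns ``label,onset_s`` containing ``lights_off`` and ``lights_on``
    rows; their absence is an error naming the file.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path, annotations)
    return read_signals_csv(path)


def _read_edf(path: Path, annotations: Optional[str | Path]) -> EEGRecord:
    import mne  # lazy: EDF support is optional

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    channels = {name: data[i] for i, name in enumerate(raw.ch_names)}
    if annotations is None:
        raise ValueError(f"{path}: lights-off/on annotations CSV required for EDF")
    ann = pd.read_csv(annotations)
    marks = dict(zip(ann["label"], ann["onset_s"]))
    for label in ("lights_off", "lights_on"):
        if label not in marks:
            raise ValueError(f"{annotations}: missing {label} annotation for {path}")
    return EEGRecord(
        channels=channels,
        sampling_rate=float(raw.info["sfreq"]),
        lights_off_s=float(marks["lights_off"]),
        lights_on_s=float(marks["lights_on"]),
    )


# ---------------------------------------------------------------------------
# Annotation tables


def write_microsleeps(events: List[MicrosleepEvent], path: str | Path) -> None:
    pd.DataFrame(
        {"onset_s": [e.onset_s for e in events], "duration_s": [e.duration_s for e in events]}
    ).to_csv(path, index=False)


def read_microsleeps(path: str | Path) -> List[MicrosleepEvent]:
    """Read a microsleep annotation CSV (onset_s, duration_s); empty is valid."""
    df = pd.read_csv(path)
    if df.empty:
        return []
    errors = []
    events = []
    for i, row in df.iterrows():
        d = float(row["duration_s"])
        if not (MICROSLEEP_MIN_S <= d < MICROSLEEP_MAX_S):
            errors.append(
                f"row {i}: duration {d} s outside [{MICROSLEEP_MIN_S}, {MICROSLEEP_MAX_S}) s"
            )
            continue
        if float(row["onset_s"]) < 0:
            errors.append(f"row {i}: onset before lights-off")
            continue
        events.append(MicrosleepEvent(onset_s=float(row["onset_s"]), duration_s=d))
    if errors:
        raise AnnotationError(f"{path}: " + "; ".join(errors))
    return events


def write_hypnogram(stages, path: str | Path) -> None:
    pd.DataFrame({"epoch_index": range(len(stages)), "stage": list(stages)}).to_csv(
        path, index=False
    )


def read_hypnogram(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    errors = [
        f"row {i}: unknown stage {s!r}"
        for i, s in enumerate(df["stage"])
        if s not in STAGES
    ]
    if errors:
        raise AnnotationError(f"{path}: " + "; ".join(errors))
    return df["stage"].to_numpy(dtype=object)


HYPNO_COLS = ["p_W", "p_N1", "p_N2", "p_N3", "p_REM"]


def write_hypnodensity(h: np.ndarray, path: str | Path) -> None:
    df = pd.DataFrame(np.asarray(h), columns=HYPNO_COLS)
    df.insert(0, "epoch_index", range(len(df)))
    df.to_csv(path, index=False, float_format="%.10g")


def read_hypnodensity(path: str | Path, tol: float = 1e-3) -> np.ndarray:
    df = pd.read_csv(path)
    h = df[HYPNO_COLS].to_numpy(dtype=float)
    sums = h.sum(axis=1)
    bad = np.flatnonzero(np.abs(sums - 1.0) > tol)
    if bad.size:
        raise AnnotationError(
            f"{path}: " + "; ".join(f"row {i}: probabilities sum to {sums[i]:.6f}" for i in bad)
        )
    return h


def read_kss(path: str | Path) -> pd.DataFrame:
    """KSS CSV: participant, day, clock_time, score (1-9)."""
    df = pd.read_csv(path)
    errors = [
        f"row {i}: score {s} outside [1, 9]"
        for i, s in enumerate(df["score"])
        if not (1 <= float(s) <= 9)
    ]
    if errors:
        raise AnnotationError(f"{path}: " + "; ".join(errors))
    return df


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"participant", "cohort", "treatment", "day", "session_time"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationError(f"{path}: missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Study directory layout


def write_study(study, out_dir: str | Path, write_eeg: bool = False) -> Path:
    """Write a simulated study to a run directory.

    Layout: ``design.csv``, ``kss.csv``, ``ground_truth.json`` at the top
    level and one ``sessions/<participant>_<day>_<HHMM>/`` directory per
    session holding hypnodensity, hypnogram and microsleep CSVs (plus
    ``eeg.csv`` when ``write_eeg``).
    """
    from .simstudy import synthesize_eeg

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study.design.to_csv(out / "design.csv", index=False)
    if study.kss is not None:
        study.kss.to_csv(out / "kss.csv", index=False)
    study.ground_truth.to_json(out / "ground_truth.json", orient="records", indent=1)
    for (participant, day, s_time), session in study.sessions.items():
        d = out / "sessions" / f"{participant}_{day}_{s_time.replace(':', '')}"
        d.mkdir(parents=True, exist_ok=True)
        write_hypnodensity(session.hypnodensity, d / "hypnodensity.csv")
        write_hypnogram(session.hypnogram, d / "hypnogram.csv")
        write_microsleeps(session.microsleeps, d / "microsleeps.csv")
        meta = {
            "participant": participant,
            "day": day,
            "session_time": s_time,
            "cohort": session.cohort,
            "treatment": session.treatment,
            "duration_min": session.duration_min,
            "sol_min": session.sol.sol_min,
            "sol_censored": bool(session.sol.censored),
            "seed": int(session.seed),
        }
        (d / "session.json").write_text(json.dumps(meta, indent=1))
        if write_eeg:
            write_signals_csv(synthesize_eeg(session), d / "eeg.csv")
    return out
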