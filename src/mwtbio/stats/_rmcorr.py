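"""Repeated-measures correlation.

The common within-subject association between two endpoints measured
repeatedly on the same subjects, estimated by the analysis-of-covariance
formulation: regress y on subject indicators plus x, and convert the
sum of squares attributable to x (after subjects) into a correlation
with the sign of the common slope.  Degrees of freedom are
``N - k - 1`` for N paired observations over k subjects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class RmCorrResult:
    """Common within-subject correlation with df and two-sided p-value."""

    r: float
    df: int
    p: float
    n_obs: int
    n_subjects: int
    slope: float


def rmcorr(
    table: pd.DataFrame, x: str, y: str, subject: str = "participant"
) -> RmCorrResult:
    """Repeated-measures correlation between endpoints ``x`` and ``y``.

    Rows with missing x or y are dropped; subjects left with fewer than
    two paired observations are dropped with a warning.  Fitting the
    ANCOVA reduces to OLS of within-subject-centered y on
    within-subject-centered x.
    """
    data = table[[subject, x, y]].dropna()
    counts = data.groupby(subject).size()
    small = counts[counts < 2].index.tolist()
    if small:
        warnings.warn(
            f"dropping {len(small)} subject(s) with < 2 paired observations: {small}",
            stacklevel=2,
        )
        data = data[~data[subject].isin(small)]
    k = data[subject].nunique()
    if k < 2:
        raise ValueError("rmcorr needs at least 2 subjects with >= 2 paired obs")
    xc = data[x] - data.groupby(subject)[x].transform("mean")
    yc = data[y] - data.groupby(subject)[y].transform("mean")
    xc = xc.to_numpy(dtype=float)
    yc = yc.to_numpy(dtype=float)
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValueError("x has no within-subject variation")
    slope = float(xc @ yc) / sxx
    ss_x = slope**2 * sxx
    resid = yc - slope * xc
    ss_err = float(resid @ resid)
    n = len(data)
    df = n - k - 1
    if df <= 0:
        raise ValueError("non-positive error degrees of freedom")
    denom = ss_x + ss_err
    r = 0.0 if denom == 0 else math.copysign(math.sqrt(ss_x / denom), slope)
    if abs(r) >= 1.0:
        p = 0.0
    else:
        tstat = r * math.sqrt(df / (1.0 - r**2))
        p = float(2 * sps.t.sf(abs(tstat), df))
    return RmCorrResult(r=r, df=df, p=p, n_obs=n, n_subjects=k, slope=slope)
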