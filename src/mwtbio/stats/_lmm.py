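"""Random-intercept linear mixed models for MWT endpoints.

The study model regresses an endpoint on categorical day and treatment,
their interaction, and the isSiesta indicator, with a random intercept
per participant.  Fitting is restricted maximum likelihood via
statsmodels; contrast construction and Wald inference live here so the
Bayesian variant can reuse the identical design matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg as spla
from scipy import stats as sps


@dataclass(frozen=True)
class ModelDesign:
    """Fixed/random structure of the endpoint model.

    Fixed effects: day, treatment, isSiesta and day x treatment
    (categorical, reference-coded with ``baseline_day`` and
    ``reference_treatment`` as reference levels); random intercept per
    ``subject``.
    """

    response: str
    subject: str = "participant"
    day: str = "day"
    treatment: str = "treatment"
    siesta: str = "isSiesta"
    baseline_day: str = "baseline"
    reference_treatment: Optional[str] = None  # default: 'placebo' if present
    include_interaction: bool = True


def build_design_matrix(
    table: pd.DataFrame, design: ModelDesign
) -> Tuple[pd.DataFrame, Dict]:
    """Reference-coded fixed-effects matrix for the study model.

    Returns the matrix (with named columns) and an info dict recording
    factor levels and which columns belong to the day x treatment
    interaction.  Raises on rank deficiency, listing aliased columns.
    """
    days = [d for d in pd.unique(table[design.day])]
    if design.baseline_day not in days:
        raise ValueError(
            f"baseline day {design.baseline_day!r} absent from {days}"
        )
    days = [design.baseline_day] + sorted(d for d in days if d != design.baseline_day)
    treatments = sorted(pd.unique(table[design.treatment]).tolist())
    ref_trt = design.reference_treatment
    if ref_trt is None:
        ref_trt = "placebo" if "placebo" in treatments else treatments[0]
    if ref_trt not in treatments:
        raise ValueError(f"reference treatment {ref_trt!r} absent from {treatments}")
    treatments = [ref_trt] + [t for t in treatments if t != ref_trt]

    cols: Dict[str, np.ndarray] = {"Intercept": np.ones(len(table))}
    for d in days[1:]:
        cols[f"day[{d}]"] = (table[design.day] == d).to_numpy(dtype=float)
    for g in treatments[1:]:
        cols[f"treatment[{g}]"] = (table[design.treatment] == g).to_numpy(dtype=float)
    cols[design.siesta] = table[design.siesta].to_numpy(dtype=float)
    interaction_cols: List[str] = []
    if design.include_interaction:
        for d in days[1:]:
            for g in treatments[1:]:
                name = f"day[{d}]:treatment[{g}]"
                cols[name] = cols[f"day[{d}]"] * cols[f"treatment[{g}]"]
                interaction_cols.append(name)
    X = pd.DataFrame(cols, index=table.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        aliased = _aliased_columns(X)
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    info = {
        "days": days,
        "treatments": treatments,
        "reference_treatment": ref_trt,
        "interaction_cols": interaction_cols,
        "columns": list(X.columns),
    }
    return X, info


def _aliased_columns(X: pd.DataFrame) -> List[str]:
    _, r, piv = spla.qr(X.to_numpy(), pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    dropped = piv[np.flatnonzero(diag < tol).min() :] if (diag < tol).any() else []
    return [X.columns[i] for i in dropped]


@dataclass
class LMMFit:
    """REML fit of the random-intercept endpoint model."""

    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    participant_sd: float
    residual_sd: float
    llf: float
    converged: bool
    n_obs: int
    n_subjects: int
    info: Dict = field(default_factory=dict)

    def wald_test(self, L: np.ndarray) -> Tuple[float, float, float]:
        """Wald test of L beta = 0: (estimate or chi2, se or df, p).

        A 1-D ``L`` returns (estimate, se, two-sided normal p); a 2-D
        ``L`` returns the joint chi-square statistic, its df, and p.
        """
        L = np.atleast_2d(np.asarray(L, dtype=float))
        est = L @ self.params.to_numpy()
        cov = L @ self.cov_params.to_numpy() @ L.T
        if L.shape[0] == 1:
            se = float(np.sqrt(cov[0, 0]))
            z = est[0] / se if se > 0 else np.inf
            return float(est[0]), se, float(2 * sps.norm.sf(abs(z)))
        stat = float(est @ np.linalg.solve(cov, est))
        df = L.shape[0]
        return stat, float(df), float(sps.chi2.sf(stat, df))

    def interaction_wald(self) -> Tuple[float, float, float]:
        """Joint Wald chi-square test of all day x treatment terms."""
        cols = self.info["interaction_cols"]
        if not cols:
            raise ValueError("model has no interaction terms")
        names = list(self.params.index)
        L = np.zeros((len(cols), len(names)))
        for i, c in enumerate(cols):
            L[i, names.index(c)] = 1.0
        return self.wald_test(L)


def fit_lmm(
    table: pd.DataFrame, design: ModelDesign, reml: bool = True
) -> LMMFit:
    """REML fit of the Gaussian random-intercept model for one endpoint.

    Rows with a missing response are dropped.  Non-convergence is flagged
    on the returned fit, never silently ignored.
    """
    import statsmodels.api as sm

    data = table.dropna(subset=[design.response])
    counts = data.groupby(design.subject).size()
    if (counts >= 2).sum() < 2:
        raise ValueError("need >= 2 subjects with >= 2 observations each")
    X, info = build_design_matrix(data, design)
    y = data[design.response].to_numpy(dtype=float)
    groups = data[design.subject].to_numpy()
    model = sm.MixedLM(y, X.to_numpy(), groups=groups)
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "powell", "cg"):
            try:
                result = model.fit(reml=reml, method=method)
                break
            except np.linalg.LinAlgError:
                continue
    if result is None:
        raise ValueError("mixed-model fit failed under every optimizer")
    names = list(X.columns)
    fe = result.params[: len(names)]
    return LMMFit(
        params=pd.Series(fe, index=names),
        bse=pd.Series(result.bse[: len(names)], index=names),
        cov_params=pd.DataFrame(
            np.asarray(result.cov_params())[: len(names), : len(names)],
            index=names,
            columns=names,
        ),
        participant_sd=float(np.sqrt(max(np.asarray(result.cov_re)[0, 0], 0.0))),
        residual_sd=float(np.sqrt(result.scale)),
        llf=float(result.llf),
        converged=bool(result.converged),
        n_obs=len(data),
        n_subjects=int(data[design.subject].nunique()),
        info=info,
    )


def contrasts_change_from_baseline(fit: LMMFit, design: ModelDesign) -> pd.DataFrame:
    """Change-from-baseline contrasts per treatment arm and post-baseline day.

    For arm ``g`` on day ``d`` the contrast estimates (day d - baseline)
    within that arm: the ``day[d]`` coefficient plus, for non-reference
    arms, the ``day[d]:treatment[g]`` interaction.  Contrast vectors are
    emitted alongside estimate, SE, Wald z and two-sided p.
    """
    names = list(fit.params.index)
    days = fit.info["days"]
    treatments = fit.info["treatments"]
    ref = fit.info["reference_treatment"]
    rows = []
    for g in treatments:
        for d in days[1:]:
            L = np.zeros(len(names))
            L[names.index(f"day[{d}]")] = 1.0
            if g != ref:
                L[names.index(f"day[{d}]:treatment[{g}]")] = 1.0
            est, se, p = fit.wald_test(L)
            rows.append(
                {
                    "treatment": g,
                    "day": d,
                    "estimate": est,
                    "se": se,
                    "z": est / se if se > 0 else np.inf,
                    "p": p,
                    "contrast": " + ".join(
                        f"{L[i]:+g}*{names[i]}" for i in np.flatnonzero(L)
                    ),
                }
            )
    return pd.DataFrame(rows)
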