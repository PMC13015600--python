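"""Two-wave cross-lagged panel models (CLPM).

Each model relates a brain measure (network controllability) and a
behavioral measure across two waves:

    brain_t2    = ar_brain    * brain_t1    + cl_behavior_to_brain * behavior_t1
    behavior_t2 = ar_behavior * behavior_t1 + cl_brain_to_behavior * brain_t1

with the wave-1 covariance free and the wave-2 residuals correlated. With
observed variables and both equations saturated, the maximum-likelihood path
estimates coincide with per-equation least squares, so the model is
estimated by OLS with Huber-White (HC0) sandwich standard errors. Inputs
are covariate-residualized and z-scored first, making every path a
standardized coefficient. BH-FDR is applied across the pooled set of
cross-lagged p-values only; autoregressive paths are reported uncorrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from ctrlcascade.associations import bh_fdr


@dataclass
class CLPMResult:
    model: str
    ar_brain: float
    ar_behavior: float
    cl_brain_to_behavior: float
    cl_behavior_to_brain: float
    se: dict[str, float]
    p: dict[str, float]
    q: dict[str, float]
    resid_corr_t1: float
    resid_corr_t2: float
    n: int


def residualize(values, covariates) -> np.ndarray:
    """Regress out covariates by OLS and z-score the residuals."""
    y = np.asarray(values, dtype=float)
    if isinstance(covariates, pd.DataFrame):
        c = pd.get_dummies(covariates, drop_first=True, dtype=float).to_numpy(dtype=float)
    else:
        c = np.atleast_2d(np.asarray(covariates, dtype=float))
        if c.shape[0] != len(y):
            c = c.T
    design = np.column_stack([np.ones(len(y)), c])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate design is rank deficient")
    beta = np.linalg.lstsq(design, y, rcond=None)[0]
    resid = y - design @ beta
    sd = resid.std(ddof=1)
    if sd < 1e-12:
        raise ValueError("residual variance is zero (perfect covariate fit)")
    return (resid - resid.mean()) / sd


def fit_clpm(panel: pd.DataFrame, model: str = "clpm") -> CLPMResult:
    """Fit a two-wave CLPM on a residualized panel.

    ``panel`` must have columns ``brain_t1``, ``brain_t2``, ``behavior_t1``,
    ``behavior_t2`` (listwise complete). Point estimates are per-equation
    least squares; standard errors are HC0 sandwich estimates.
    """
    cols = ["brain_t1", "brain_t2", "behavior_t1", "behavior_t2"]
    missing = [c for c in cols if c not in panel.columns]
    if missing:
        raise ValueError(f"panel is missing columns: {missing}")
    df = panel[cols].dropna()
    n = len(df)
    if n < 50:
        raise ValueError("need at least 50 complete panel rows")
    for c in cols:
        if df[c].std() == 0:
            raise ValueError(f"column {c} is constant")
    x = sm.add_constant(df[["brain_t1", "behavior_t1"]].to_numpy())
    eq_brain = sm.OLS(df["brain_t2"].to_numpy(), x).fit(cov_type="HC0")
    eq_behav = sm.OLS(df["behavior_t2"].to_numpy(), x).fit(cov_type="HC0")
    # columns: const, brain_t1, behavior_t1
    se = {
        "ar_brain": float(eq_brain.bse[1]),
        "cl_behavior_to_brain": float(eq_brain.bse[2]),
        "ar_behavior": float(eq_behav.bse[2]),
        "cl_brain_to_behavior": float(eq_behav.bse[1]),
    }
    p = {
        "ar_brain": float(eq_brain.pvalues[1]),
        "cl_behavior_to_brain": float(eq_brain.pvalues[2]),
        "ar_behavior": float(eq_behav.pvalues[2]),
        "cl_brain_to_behavior": float(eq_behav.pvalues[1]),
    }
    r1 = float(np.corrcoef(df["brain_t1"], df["behavior_t1"])[0, 1])
    r2 = float(np.corrcoef(eq_brain.resid, eq_behav.resid)[0, 1])
    return CLPMResult(
        model=model,
        ar_brain=float(eq_brain.params[1]),
        ar_behavior=float(eq_behav.params[2]),
        cl_brain_to_behavior=float(eq_behav.params[1]),
        cl_behavior_to_brain=float(eq_brain.params[2]),
        se=se,
        p=p,
        q={},
        resid_corr_t1=r1,
        resid_corr_t2=r2,
        n=n,
    )


def fdr_crosslagged(results: list[CLPMResult]) -> list[CLPMResult]:
    """BH-FDR across the pooled cross-lagged p-values of all models.

    Both cross-lagged paths of every model form one correction family;
    autoregressive paths are left uncorrected. q-values are written back
    onto each result.
    """
    if not results:
        raise ValueError("no results to correct")
    keys = ("cl_brain_to_behavior", "cl_behavior_to_brain")
    pooled = [r.p[k] for r in results for k in keys]
    q = bh_fdr(pooled)
    it = iter(q)
    for r in results:
        for k in keys:
            r.q[k] = float(next(it))
    return results


class CrossLaggedPanelModel(BaseEstimator):
    """Estimator interface for the two-wave CLPM.

    ``fit(panel)`` accepts a residualized panel DataFrame and exposes the
    fitted paths as ``ar_brain_``, ``ar_behavior_``,
    ``cl_brain_to_behavior_``, ``cl_behavior_to_brain_``, with ``se_``,
    ``p_`` and the full :class:`CLPMResult` as ``result_``.
    """

    def __init__(self, model_name: str = "clpm"):
        self.model_name = model_name

    def fit(self, panel: pd.DataFrame, y=None):
        res = fit_clpm(panel, model=self.model_name)
        self.result_ = res
        self.ar_brain_ = res.ar_brain
        self.ar_behavior_ = res.ar_behavior
        self.cl_brain_to_behavior_ = res.cl_brain_to_behavior
        self.cl_behavior_to_brain_ = res.cl_behavior_to_brain
        self.se_ = res.se
        self.p_ = res.p
        self.resid_corr_t1_ = res.resid_corr_t1
        self.resid_corr_t2_ = res.resid_corr_t2
        return self
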