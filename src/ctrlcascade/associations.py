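"""Covariate-adjusted associations with a study-site random intercept.

Each association model regresses an outcome on one predictor of interest
plus a fixed covariate set, with a random intercept for study site
estimated by REML (statsmodels ``MixedLM``). Continuous variables are
z-scored beforehand so the reported coefficients are standardized betas.
Multiplicity within an analysis family is handled by Benjamini-Hochberg
FDR. Robustness checks re-fit models within strata (sex, ancestry) and
compare effect vectors by Pearson concordance, with explicit interaction
models when concordance is low.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm


@dataclass
class AssociationResult:
    outcome: str
    predictor: str
    beta: float
    se: float
    p: float
    n: int
    site_variance: float
    q: float | None = None


@dataclass
class StratifiedComparison:
    groups: tuple[str, str]
    effects_a: np.ndarray
    effects_b: np.ndarray
    concordance_r: float
    concordance_p: float


def standardize(values) -> np.ndarray:
    """Z-score with the n-1 (sample) standard deviation."""
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / sd


def _dummy_code(covariates: pd.DataFrame | None) -> pd.DataFrame | None:
    """Dummy-code categorical covariates, dropping the first level."""
    if covariates is None or covariates.shape[1] == 0:
        return None
    out = pd.get_dummies(covariates, drop_first=True, dtype=float)
    return out.astype(float)


def _build_design(
    predictor: np.ndarray, covariates: pd.DataFrame | None, extra: dict[str, np.ndarray] | None = None
) -> pd.DataFrame:
    design = pd.DataFrame({"const": np.ones(len(predictor)), "predictor": predictor})
    if extra:
        for name, col in extra.items():
            design[name] = col
    cov = _dummy_code(covariates)
    if cov is not None:
        for col in cov.columns:
            design[str(col)] = cov[col].to_numpy()
    return design


def fit_site_adjusted(
    outcome,
    predictor,
    covariates: pd.DataFrame | None = None,
    site=None,
    outcome_label: str = "outcome",
    predictor_label: str = "predictor",
    term: str = "predictor",
    extra_terms: dict[str, np.ndarray] | None = None,
) -> AssociationResult:
    """Linear model with fixed covariates and a site random intercept (REML).

    Continuous outcome and predictor are standardized internally, so ``beta``
    is a standardized coefficient with a Wald p-value. With fewer than two
    sites the model degenerates to ordinary least squares with
    ``site_variance = 0``.
    """
    y = standardize(outcome)
    x = standardize(predictor)
    design = _build_design(x, covariates, extra_terms)
    n = len(y)
    sites = np.asarray(site) if site is not None else np.zeros(n)
    if len(np.unique(sites)) < 2:
        model = sm.OLS(y, design).fit()
        beta, se, p = model.params[term], model.bse[term], model.pvalues[term]
        site_var = 0.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mixed = MixedLM(y, design, groups=sites)
            fit = mixed.fit(reml=True)
        site_var = float(fit.cov_re.iloc[0, 0])
        if site_var <= 1e-8:
            # REML converged to the boundary: the degenerate model IS ordinary
            # least squares, so refit exactly rather than keep optimizer slack
            model = sm.OLS(y, design).fit()
            beta, se, p = model.params[term], model.bse[term], model.pvalues[term]
            site_var = 0.0
        else:
            beta, se, p = fit.params[term], fit.bse[term], fit.pvalues[term]
    return AssociationResult(
        outcome=outcome_label,
        predictor=predictor_label,
        beta=float(beta),
        se=float(se),
        p=float(p),
        n=n,
        site_variance=site_var,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def apply_fdr(results: list[AssociationResult]) -> list[AssociationResult]:
    """Attach BH q-values to one family of association results in place."""
    q = bh_fdr([r.p for r in results])
    for r, qi in zip(results, q):
        r.q = float(qi)
    return results


def stratified_concordance(effects_a, effects_b, groups=("a", "b")) -> StratifiedComparison:
    """Pearson concordance between aligned per-stratum effect vectors."""
    a = np.asarray(effects_a, dtype=float)
    b = np.asarray(effects_b, dtype=float)
    if a.shape != b.shape or len(a) < 3:
        raise ValueError("effect vectors must align with length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in an effect vector")
    r, p = stats.pearsonr(a, b)
    return StratifiedComparison(tuple(groups), a, b, float(r), float(p))


def interaction_test(
    outcome,
    predictor,
    group,
    covariates: pd.DataFrame | None = None,
    site=None,
    outcome_label: str = "outcome",
    predictor_label: str = "predictor",
) -> AssociationResult:
    """Test whether the predictor's slope differs between two groups.

    Adds the group main effect and the predictor x group product to the
    site-adjusted model and reports the product term's coefficient. ``group``
    is coded 0/1 by sorted label order (first level is the reference).
    """
    g_raw = np.asarray(group)
    levels = np.unique(g_raw)
    if len(levels) != 2:
        raise ValueError("group must have exactly two levels")
    g = (g_raw == levels[1]).astype(float)
    x = standardize(predictor)
    return fit_site_adjusted(
        outcome,
        x,
        covariates=covariates,
        site=site,
        outcome_label=outcome_label,
        predictor_label=f"{predictor_label}:x{levels[1]}",
        term="interaction",
        extra_terms={"group": g, "interaction": x * g},
    )


def pairwise_correlations(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between two variable blocks."""
    out = pd.DataFrame(index=table_a.columns, columns=table_b.columns, dtype=float)
    for ca in table_a.columns:
        for cb in table_b.columns:
            x, y = table_a[ca], table_b[cb]
            ok = x.notna() & y.notna()
            if ok.sum() < 3:
                raise ValueError(f"fewer than 3 complete pairs for ({ca}, {cb})")
            out.loc[ca, cb] = stats.pearsonr(x[ok], y[ok])[0]
    return out
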