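"""Product-of-coefficients mediation with bias-corrected bootstrap intervals.

The mediation model is the standard three-regression decomposition

    M = i1 + a X + (covariates)            (a-path)
    Y = i2 + c' X + b M + (covariates)     (b-path and direct effect)
    Y = i3 + c X + (covariates)            (total effect)

with indirect effect ``a * b`` and, for linear models on a common case set,
the identity ``c = c' + a*b``. Uncertainty in the indirect effect is
assessed by case-resampling bootstrap with bias-corrected (BC) percentile
intervals: the bias constant is the probit of the fraction of bootstrap
draws below the point estimate (ties counted half), and the interval
endpoints are the empirical quantiles at ``Phi(2 z0 +/- z_alpha)``.

Moderated mediation lets a standardized moderator W (here a polygenic risk
score) shift the a- and b-paths through X*W and M*W products; conditional
indirect effects ``(a + a_w w*)(b + b_w w*)`` are reported at
stratum-representative moderator values, with the sample split at the
16th/84th percentiles into low/medium/high strata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class MediationResult:
    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    ci_low: float
    ci_high: float
    n_boot: int
    proportion_mediated: float  # percent
    inconsistent: bool  # indirect and direct effects of opposite sign
    significant: bool
    seed: int
    n: int


@dataclass
class PRSStrata:
    labels: np.ndarray  # per-subject "low" / "medium" / "high"
    cutpoints: tuple[float, float]
    counts: dict[str, int]


@dataclass
class ModeratedMediationResult:
    conditional_indirect: dict[str, float]
    conditional_ci: dict[str, tuple[float, float]]
    a: float
    b: float
    a_int: float
    b_int: float
    eval_points: dict[str, float]
    contrast_high_minus_medium: float
    contrast_ci: tuple[float, float]
    n_boot: int
    seed: int
    n: int


# ---------------------------------------------------------------------------
# Internals: (batched) least squares
# ---------------------------------------------------------------------------

def _lstsq(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.lstsq(x, y, rcond=None)[0]


def _batched_beta(xb: np.ndarray, yb: np.ndarray) -> np.ndarray:
    """OLS coefficients for a stack of resampled designs (B, n, p)."""
    xtx = np.einsum("bni,bnj->bij", xb, xb)
    xty = np.einsum("bni,bn->bi", xb, yb)
    try:
        return np.linalg.solve(xtx, xty[..., None])[..., 0]
    except np.linalg.LinAlgError:
        # rank-deficient resample (or structurally singular design, e.g. a
        # constant moderator column): minimum-norm solution
        return np.einsum("bij,bj->bi", np.linalg.pinv(xtx), xty)


def _covariate_matrix(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.empty((n, 0))
    if isinstance(covariates, pd.DataFrame):
        c = pd.get_dummies(covariates, drop_first=True, dtype=float).to_numpy(dtype=float)
    else:
        c = np.atleast_2d(np.asarray(covariates, dtype=float))
        if c.shape[0] != n:
            c = c.T
    return c


def bc_ci(boot_stats, point: float, level: float = 0.95) -> tuple[float, float]:
    """Bias-corrected bootstrap percentile interval.

    ``z0`` is the probit of the fraction of bootstrap draws strictly below
    the point estimate, counting ties as half; the returned endpoints are
    linearly interpolated (type-7) empirical quantiles at
    ``Phi(2 z0 - z_alpha)`` and ``Phi(2 z0 + z_alpha)``.
    """
    b = np.asarray(boot_stats, dtype=float)
    if len(b) < 100:
        raise ValueError("need at least 100 bootstrap draws")
    below = np.mean(b < point) + 0.5 * np.mean(b == point)
    if below <= 0.0 or below >= 1.0:
        # point estimate outside (or at the edge of) the bootstrap support
        if np.all(b == b[0]) and b[0] != point:
            raise ValueError("degenerate bootstrap distribution excludes the point estimate")
        below = min(max(below, 0.5 / len(b)), 1 - 0.5 / len(b))
    z0 = stats.norm.ppf(below)
    za = stats.norm.ppf(0.5 + level / 2.0)
    lo_p = stats.norm.cdf(2 * z0 - za)
    hi_p = stats.norm.cdf(2 * z0 + za)
    lo, hi = np.quantile(b, [lo_p, hi_p], method="linear")
    return float(lo), float(hi)


def _bootstrap_indices(rng: np.random.Generator, n: int, n_boot: int) -> np.ndarray:
    return rng.integers(0, n, size=(n_boot, n))


def _chunked(idx: np.ndarray, chunk: int):
    for start in range(0, len(idx), chunk):
        yield idx[start : start + chunk]


def mediate(
    x,
    m,
    y,
    covariates=None,
    n_boot: int = 5000,
    level: float = 0.95,
    seed: int = 0,
    chunk: int = 128,
) -> MediationResult:
    """Mediation analysis with a BC bootstrap CI for the indirect effect.

    Proportion mediated is ``indirect / (indirect + c')`` expressed as a
    percentage; when indirect and direct effects have opposite signs the
    result is flagged ``inconsistent`` rather than reported as a negative
    percentage. ``n_boot = 0`` returns point estimates only.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    c_mat = _covariate_matrix(covariates, n)
    if m.std() == 0:
        raise ValueError("mediator has zero variance")
    ones = np.ones((n, 1))
    xm_design = np.column_stack([ones, x, c_mat])  # M ~ X + C
    y_design = np.column_stack([ones, x, m, c_mat])  # Y ~ X + M + C
    t_design = xm_design  # Y ~ X + C

    a = float(_lstsq(xm_design, m)[1])
    beta_y = _lstsq(y_design, y)
    c_prime, b = float(beta_y[1]), float(beta_y[2])
    c_total = float(_lstsq(t_design, y)[1])
    indirect = a * b

    if n_boot == 0:
        prop, incons = _proportion_mediated(indirect, c_prime)
        return MediationResult(a, b, c_total, c_prime, indirect, np.nan, np.nan, 0,
                               prop, incons, False, seed, n)

    rng = np.random.default_rng(seed)
    idx = _bootstrap_indices(rng, n, n_boot)
    boot = np.empty(n_boot)
    pos = 0
    for ii in _chunked(idx, chunk):
        a_b = _batched_beta(xm_design[ii], m[ii])[:, 1]
        b_b = _batched_beta(y_design[ii], y[ii])[:, 2]
        boot[pos : pos + len(ii)] = a_b * b_b
        pos += len(ii)
    lo, hi = bc_ci(boot, indirect, level)
    prop, incons = _proportion_mediated(indirect, c_prime)
    return MediationResult(
        a=a, b=b, c=c_total, c_prime=c_prime, indirect=indirect,
        ci_low=lo, ci_high=hi, n_boot=n_boot,
        proportion_mediated=prop, inconsistent=incons,
        significant=not (lo <= 0.0 <= hi), seed=seed, n=n,
    )


def _proportion_mediated(indirect: float, c_prime: float) -> tuple[float, bool]:
    total = indirect + c_prime
    if total == 0:
        return np.nan, True
    prop = 100.0 * indirect / total
    incons = indirect * c_prime < 0
    return float(prop), bool(incons)


def stratify_prs(prs) -> PRSStrata:
    """Split a polygenic risk score at its 16th and 84th percentiles.

    low: prs <= 16th percentile; high: prs > 84th percentile; medium:
    remainder — approximately a 16/68/16 split.
    """
    p = np.asarray(prs, dtype=float)
    if len(np.unique(p)) < 10:
        raise ValueError("need at least 10 distinct PRS values")
    p16, p84 = np.quantile(p, [0.16, 0.84], method="linear")
    labels = np.where(p <= p16, "low", np.where(p > p84, "high", "medium"))
    counts = {lab: int((labels == lab).sum()) for lab in ("low", "medium", "high")}
    if min(counts.values()) == 0:
        raise ValueError("degenerate strata: ties collapse a stratum")
    return PRSStrata(labels=labels, cutpoints=(float(p16), float(p84)), counts=counts)


def moderated_mediate(
    x,
    m,
    y,
    w,
    covariates=None,
    strata: PRSStrata | None = None,
    n_boot: int = 5000,
    level: float = 0.95,
    seed: int = 0,
    eval_mode: str = "stratum_mean",
    chunk: int = 128,
) -> ModeratedMediationResult:
    """Moderated mediation with W on both the a- and b-paths.

    Fits ``M ~ X + W + X*W + C`` and ``Y ~ X + M + W + X*W + M*W + C`` and
    evaluates the conditional indirect effect ``(a + a_w w*)(b + b_w w*)`` at
    stratum-representative moderator values: within-stratum means
    (``eval_mode="stratum_mean"``, default) or the 16th/50th/84th moderator
    percentiles (``eval_mode="percentile"``). Each conditional effect and the
    high-minus-medium contrast get a BC bootstrap CI from joint case
    resampling. ``w`` is expected on a standardized scale.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    n = len(x)
    c_mat = _covariate_matrix(covariates, n)
    if strata is None:
        strata = stratify_prs(w)
    if eval_mode == "stratum_mean":
        eval_points = {
            lab: float(w[strata.labels == lab].mean()) for lab in ("low", "medium", "high")
        }
    elif eval_mode == "percentile":
        q = np.quantile(w, [0.16, 0.50, 0.84], method="linear")
        eval_points = {"low": float(q[0]), "medium": float(q[1]), "high": float(q[2])}
    else:
        raise ValueError("eval_mode must be 'stratum_mean' or 'percentile'")

    ones = np.ones((n, 1))
    m_design = np.column_stack([ones, x, w, x * w, c_mat])
    y_design = np.column_stack([ones, x, m, w, x * w, m * w, c_mat])

    beta_m = _lstsq(m_design, m)
    beta_y = _lstsq(y_design, y)
    a, a_int = float(beta_m[1]), float(beta_m[3])
    b, b_int = float(beta_y[2]), float(beta_y[5])

    def conditional(av, aiv, bv, biv):
        return {
            lab: (av + aiv * ws) * (bv + biv * ws) for lab, ws in eval_points.items()
        }

    point = conditional(a, a_int, b, b_int)
    contrast = point["high"] - point["medium"]

    if n_boot == 0:
        return ModeratedMediationResult(
            conditional_indirect={k: float(v) for k, v in point.items()},
            conditional_ci={k: (np.nan, np.nan) for k in point},
            a=a, b=b, a_int=a_int, b_int=b_int, eval_points=eval_points,
            contrast_high_minus_medium=float(contrast),
            contrast_ci=(np.nan, np.nan), n_boot=0, seed=seed, n=n,
        )

    rng = np.random.default_rng(seed)
    idx = _bootstrap_indices(rng, n, n_boot)
    boot = {lab: np.empty(n_boot) for lab in eval_points}
    boot_contrast = np.empty(n_boot)
    pos = 0
    for ii in _chunked(idx, chunk):
        bm = _batched_beta(m_design[ii], m[ii])
        by = _batched_beta(y_design[ii], y[ii])
        cond = conditional(bm[:, 1], bm[:, 3], by[:, 2], by[:, 5])
        for lab, vals in cond.items():
            boot[lab][pos : pos + len(ii)] = vals
        boot_contrast[pos : pos + len(ii)] = cond["high"] - cond["medium"]
        pos += len(ii)

    cis = {lab: bc_ci(boot[lab], point[lab], level) for lab in eval_points}
    contrast_ci = bc_ci(boot_contrast, contrast, level)
    return ModeratedMediationResult(
        conditional_indirect={k: float(v) for k, v in point.items()},
        conditional_ci=cis,
        a=a, b=b, a_int=a_int, b_int=b_int, eval_points=eval_points,
        contrast_high_minus_medium=float(contrast),
        contrast_ci=contrast_ci, n_boot=n_boot, seed=seed, n=n,
    )


# ---------------------------------------------------------------------------
# Estimator wrappers
# ---------------------------------------------------------------------------

from sklearn.base import BaseEstimator  # noqa: E402


class BootstrapMediation(BaseEstimator):
    """Estimator interface for :func:`mediate`.

    ``fit(x, m, y, covariates=None)`` stores the fitted paths as
    ``a_``, ``b_``, ``c_``, ``c_prime_``, ``indirect_``, ``ci_``,
    ``proportion_mediated_``, ``significant_`` and the full
    :class:`MediationResult` as ``result_``.
    """

    def __init__(self, n_boot: int = 5000, level: float = 0.95, random_state: int = 0):
        self.n_boot = n_boot
        self.level = level
        self.random_state = random_state

    def fit(self, x, m, y, covariates=None):
        res = mediate(
            x, m, y, covariates=covariates,
            n_boot=self.n_boot, level=self.level, seed=self.random_state,
        )
        self.result_ = res
        self.a_, self.b_, self.c_, self.c_prime_ = res.a, res.b, res.c, res.c_prime
        self.indirect_ = res.indirect
        self.ci_ = (res.ci_low, res.ci_high)
        self.proportion_mediated_ = res.proportion_mediated
        self.significant_ = res.significant
        return self


class ModeratedMediation(BaseEstimator):
    """Estimator interface for :func:`moderated_mediate`."""

    def __init__(
        self,
        n_boot: int = 5000,
        level: float = 0.95,
        random_state: int = 0,
        eval_mode: str = "stratum_mean",
    ):
        self.n_boot = n_boot
        self.level = level
        self.random_state = random_state
        self.eval_mode = eval_mode

    def fit(self, x, m, y, w, covariates=None, strata: PRSStrata | None = None):
        res = moderated_mediate(
            x, m, y, w, covariates=covariates, strata=strata,
            n_boot=self.n_boot, level=self.level, seed=self.random_state,
            eval_mode=self.eval_mode,
        )
        self.result_ = res
        self.conditional_indirect_ = res.conditional_indirect
        self.conditional_ci_ = res.conditional_ci
        self.a_, self.b_ = res.a, res.b
        self.a_int_, self.b_int_ = res.a_int, res.b_int
        return self
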