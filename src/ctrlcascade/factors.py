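"""Latent adversity factors: item QC, imputation, and exploratory factor analysis.

The measurement pipeline mirrors common practice for multidimensional
early-life-adversity batteries:

1. item-level QC — drop items with > 50% missingness, near-zero variance
   (frequency-ratio / unique-fraction rule), or a manual exclude list;
2. 4 x MAD outlier flagging on continuous items (flags set missing);
3. chained-equation imputation (predictive mean matching), with the
   imputed completions averaged cell-wise into one analysis matrix;
4. principal axis factoring with oblimin (direct quartimin) rotation;
   factor count chosen by Velicer's MAP and the VSS criterion;
5. regression (Thurstone) factor scores, with tenfold cross-validated
   score stability (Spearman rho between out-of-sample and full-sample
   scores) as the overfitting check.

Factor order and sign are unidentified; solutions are canonicalized by
sum-of-squared-loadings order and positive dominant sign, and fold
solutions are matched to a reference by maximal absolute Tucker congruence
(Hungarian assignment) with sign alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.model_selection import KFold


# ---------------------------------------------------------------------------
# Item QC
# ---------------------------------------------------------------------------

@dataclass
class ItemQCReport:
    removed: dict[str, str]  # item label -> reason
    outlier_cells: int
    retained: list[str]

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def qc_items(
    items: pd.DataFrame,
    missing_threshold: float = 0.5,
    nzv_freq_ratio: float = 19.0,
    nzv_unique_cut: float = 0.1,
    manual_excludes: list[str] | None = None,
) -> tuple[pd.DataFrame, ItemQCReport]:
    """Remove items with excessive missingness or (near-)zero variance.

    Near-zero variance: ratio of the most-common to second-most-common value
    frequency strictly greater than ``nzv_freq_ratio`` AND unique-value
    fraction strictly below ``nzv_unique_cut``. Constant items are always
    removed. Missingness comparison is strict (> threshold removes).
    """
    if not 0 <= missing_threshold <= 1:
        raise ValueError("missing_threshold must be in [0, 1]")
    removed: dict[str, str] = {}
    for col in items.columns:
        if manual_excludes and col in manual_excludes:
            removed[col] = "manual"
            continue
        x = items[col]
        if x.isna().mean() > missing_threshold:
            removed[col] = "missing_gt_50pct"
            continue
        obs = x.dropna()
        counts = obs.value_counts()
        if len(counts) <= 1:
            removed[col] = "near_zero_variance"
            continue
        ratio = counts.iloc[0] / counts.iloc[1]
        unique_frac = len(counts) / len(obs)
        if ratio > nzv_freq_ratio and unique_frac < nzv_unique_cut:
            removed[col] = "near_zero_variance"
    retained = [c for c in items.columns if c not in removed]
    if not retained:
        raise ValueError("QC removed every item")
    report = ItemQCReport(removed=removed, outlier_cells=0, retained=retained)
    return items[retained].copy(), report


def flag_outliers_mad(values: np.ndarray | pd.Series, c: float = 4.0) -> np.ndarray:
    """Flag values with |x - median| > c * 1.4826 * MAD (missing never flagged).

    The 1.4826 factor makes the MAD a consistent estimator of the normal
    standard deviation. If the MAD is zero the vector is left unflagged and
    a warning is emitted.
    """
    x = np.asarray(values, dtype=float)
    obs = x[~np.isnan(x)]
    if len(obs) < 3:
        raise ValueError("need at least 3 non-missing values")
    med = np.median(obs)
    mad = 1.4826 * np.median(np.abs(obs - med))
    if mad == 0:
        warnings.warn("MAD is zero; no outliers flagged", stacklevel=2)
        return np.zeros_like(x, dtype=bool)
    with np.errstate(invalid="ignore"):
        mask = np.abs(x - med) > c * mad
    return np.where(np.isnan(x), False, mask)


def apply_mad_filter(
    items: pd.DataFrame, c: float = 4.0, continuous: list[str] | None = None
) -> tuple[pd.DataFrame, int]:
    """Set 4xMAD outlier cells to missing on continuous items."""
    out = items.copy()
    if continuous is None:
        continuous = [col for col in out.columns if out[col].dropna().nunique() > 2]
    n_flagged = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for col in continuous:
            mask = flag_outliers_mad(out[col], c=c)
            n_flagged += int(mask.sum())
            out.loc[mask, col] = np.nan
    return out, n_flagged


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def impute_and_average(
    items: pd.DataFrame,
    n_imputations: int = 10,
    n_iter: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Chained-equation imputation averaged cell-wise into one matrix.

    Runs predictive-mean-matching chained equations (statsmodels ``MICEData``)
    ``n_imputations`` times, ``n_iter`` update cycles each, and averages the
    completed matrices. Observed cells are returned unchanged. Donor-based
    PMM keeps binary items on their observed support, though the cross-
    imputation average of a binary cell may be fractional.
    """
    if not items.isna().any().any():
        return items.copy()
    if (items.isna().mean() > 0.5).any():
        raise ValueError("items with > 50% missingness must be removed before imputation")
    from statsmodels.imputation.mice import MICEData

    safe = items.copy()
    safe.columns = [f"v{i}" for i in range(items.shape[1])]
    completions = []
    state = np.random.get_state()
    try:
        np.random.seed(seed % (2**31))
        for _ in range(n_imputations):
            imp = MICEData(safe)
            imp.update_all(n_iter)
            completions.append(imp.data.to_numpy(dtype=float))
    finally:
        np.random.set_state(state)
    avg = np.mean(completions, axis=0)
    out = pd.DataFrame(avg, index=items.index, columns=items.columns)
    obs = ~items.isna()
    out = out.where(~obs, items)
    return out


# ---------------------------------------------------------------------------
# Factorability diagnostics
# ---------------------------------------------------------------------------

def kmo_bartlett(data: pd.DataFrame | np.ndarray) -> tuple[float, float, float]:
    """Overall KMO sampling adequacy and Bartlett's test of sphericity.

    KMO = sum r^2 / (sum r^2 + sum q^2) over off-diagonal correlations r and
    anti-image partial correlations q. Bartlett's chi-square is
    ``-(n - 1 - (2p + 5)/6) ln det(R)`` on p(p-1)/2 degrees of freedom.
    """
    x = np.asarray(data, dtype=float)
    n, p = x.shape
    r = np.corrcoef(x, rowvar=False)
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise ValueError("correlation matrix is singular")
    rinv = np.linalg.inv(r)
    d = np.sqrt(np.diag(rinv))
    partial = -rinv / np.outer(d, d)
    off = ~np.eye(p, dtype=bool)
    ssr = np.sum(r[off] ** 2)
    ssq = np.sum(partial[off] ** 2)
    kmo = ssr / (ssr + ssq)
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) / 2.0
    pval = float(stats.chi2.sf(chi2, df))
    return float(kmo), float(chi2), pval


# ---------------------------------------------------------------------------
# Factor extraction and rotation
# ---------------------------------------------------------------------------

@dataclass
class FactorSolution:
    """Oblique factor solution: pattern loadings, factor correlations, fit."""

    loadings: np.ndarray  # items x k pattern matrix
    factor_corr: np.ndarray  # k x k
    communalities: np.ndarray
    n_iter: int
    converged: bool
    heywood: bool = False
    item_labels: list[str] = field(default_factory=list)

    @property
    def structure(self) -> np.ndarray:
        return self.loadings @ self.factor_corr


def _smc(r: np.ndarray) -> np.ndarray:
    """Squared multiple correlations, the standard initial communalities."""
    try:
        rinv = np.linalg.inv(r)
        smc = 1.0 - 1.0 / np.diag(rinv)
    except np.linalg.LinAlgError:
        smc = np.abs(r - np.eye(len(r))).max(axis=1)
    return np.clip(smc, 0.0, 1.0)


def _principal_axis(r: np.ndarray, k: int, tol: float, max_iter: int):
    p = r.shape[0]
    h2 = _smc(r)
    heywood = False
    converged = False
    loadings = np.zeros((p, k))
    for it in range(1, max_iter + 1):
        rr = r.copy()
        np.fill_diagonal(rr, h2)
        lam, vec = np.linalg.eigh(rr)
        lam, vec = lam[::-1][:k], vec[:, ::-1][:, :k]
        lam = np.clip(lam, 0.0, None)
        loadings = vec * np.sqrt(lam)
        h2_new = np.sum(loadings**2, axis=1)
        if (h2_new > 1.0).any():
            heywood = True
            h2_new = np.clip(h2_new, 0.0, 1.0)
        delta = np.abs(h2_new - h2).max()
        h2 = h2_new
        if delta < tol:
            converged = True
            break
    return loadings, h2, it, converged, heywood


def _oblimin_objective(loadings: np.ndarray, gamma: float):
    """Oblimin criterion value and gradient (gamma=0 is direct quartimin)."""
    p, k = loadings.shape
    l2 = loadings**2
    x = l2 @ (np.ones((k, k)) - np.eye(k))
    if gamma != 0:
        x = (np.eye(p) - np.full((p, p), gamma / p)) @ x
    return np.sum(l2 * x) / 4.0, loadings * x


def _gpa_oblique(a: np.ndarray, gamma: float, tol: float = 1e-6, max_iter: int = 1000):
    """Gradient-projection algorithm for oblique rotation (quartimin family)."""
    k = a.shape[1]
    t = np.eye(k)
    ti = np.linalg.inv(t)
    loadings = a @ ti.T
    f, gq = _oblimin_objective(loadings, gamma)
    g = -(loadings.T @ gq @ ti).T
    al = 1.0
    for _ in range(max_iter):
        gp = g - t @ np.diag(np.sum(t * g, axis=0))
        s = np.linalg.norm(gp)
        if s < tol:
            break
        al *= 2.0
        for _ in range(20):
            x = t - al * gp
            v = 1.0 / np.sqrt(np.sum(x**2, axis=0))
            tt = x @ np.diag(v)
            ti = np.linalg.inv(tt)
            loadings = a @ ti.T
            ft, gq = _oblimin_objective(loadings, gamma)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        t = tt
        f = ft
        g = -(loadings.T @ gq @ ti).T
    phi = t.T @ t
    return loadings, phi


def _canonicalize(loadings: np.ndarray, phi: np.ndarray):
    """Order factors by explained variance, make dominant sign positive."""
    order = np.argsort(-np.sum(loadings**2, axis=0), kind="stable")
    loadings = loadings[:, order]
    phi = phi[np.ix_(order, order)]
    signs = np.sign(np.sum(loadings**3, axis=0))
    signs[signs == 0] = 1.0
    loadings = loadings * signs
    phi = phi * np.outer(signs, signs)
    return loadings, phi


def paf_oblimin(
    r: np.ndarray,
    k: int,
    gamma: float = 0.0,
    tol: float = 1e-4,
    max_iter: int = 100,
    rotate: bool = True,
    item_labels: list[str] | None = None,
) -> FactorSolution:
    """Principal axis factoring with oblimin (gradient-projection) rotation.

    Initial communalities are squared multiple correlations; extraction
    iterates the reduced-matrix eigendecomposition until the communalities
    change by less than ``tol``. Heywood cases (communality > 1) are clipped
    and flagged. ``gamma=0`` gives direct quartimin.
    """
    r = np.asarray(r, dtype=float)
    p = r.shape[0]
    if k < 1 or k >= p:
        raise ValueError("need 1 <= k < number of items")
    loadings, h2, n_iter, converged, heywood = _principal_axis(r, k, tol, max_iter)
    if rotate and k > 1:
        loadings, phi = _gpa_oblique(loadings, gamma)
    else:
        phi = np.eye(k)
    loadings, phi = _canonicalize(loadings, phi)
    return FactorSolution(
        loadings=loadings,
        factor_corr=phi,
        communalities=h2,
        n_iter=n_iter,
        converged=converged,
        heywood=heywood,
        item_labels=list(item_labels) if item_labels is not None else [],
    )


# ---------------------------------------------------------------------------
# Factor-count criteria
# ---------------------------------------------------------------------------

def map_criterion(r: np.ndarray, k_max: int) -> np.ndarray:
    """Velicer's minimum average partial: mean squared partial correlation
    after removing the first k principal components, for k = 0..k_max.

    The selected factor count is the argmin of the returned curve.
    """
    r = np.asarray(r, dtype=float)
    p = r.shape[0]
    if k_max >= p:
        raise ValueError("k_max must be below the matrix dimension")
    lam, vec = np.linalg.eigh(r)
    lam, vec = lam[::-1], vec[:, ::-1]
    off = ~np.eye(p, dtype=bool)
    out = np.full(k_max + 1, np.nan)
    out[0] = np.sum(r[off] ** 2) / (p * (p - 1))
    for k in range(1, k_max + 1):
        a = vec[:, :k] * np.sqrt(np.clip(lam[:k], 0, None))
        c = r - a @ a.T
        d = np.diag(c)
        if (d <= 1e-12).any():
            break  # residual variance exhausted; larger k is degenerate
        partial = c / np.sqrt(np.outer(d, d))
        out[k] = np.sum(partial[off] ** 2) / (p * (p - 1))
    return out


def vss_criterion(r: np.ndarray, k_max: int, complexity: int = 1) -> np.ndarray:
    """Very Simple Structure goodness for k = 1..k_max.

    For each k the oblimin-rotated loading matrix is truncated to its
    ``complexity`` largest absolute entries per item, and VSS is
    ``1 - SS(residual off-diagonals) / SS(R off-diagonals)`` for the implied
    correlation matrix of the truncated model.
    """
    r = np.asarray(r, dtype=float)
    p = r.shape[0]
    if k_max >= p:
        raise ValueError("k_max must be below the matrix dimension")
    off = ~np.eye(p, dtype=bool)
    denom = np.sum(r[off] ** 2)
    if denom < 1e-12:
        warnings.warn("correlation matrix has no off-diagonal variance; VSS degenerate")
        return np.full(k_max, np.nan)
    out = np.full(k_max, np.nan)
    for k in range(1, k_max + 1):
        if k < complexity:
            continue
        sol = paf_oblimin(r, k)
        lam = sol.loadings.copy()
        if k > complexity:
            order = np.argsort(-np.abs(lam), axis=1)
            keep = np.zeros_like(lam, dtype=bool)
            rows = np.arange(p)[:, None]
            keep[rows, order[:, :complexity]] = True
            lam = np.where(keep, lam, 0.0)
        model = lam @ sol.factor_corr @ lam.T
        resid = r - model
        out[k - 1] = 1.0 - np.sum(resid[off] ** 2) / denom
    return out


# ---------------------------------------------------------------------------
# Loadings retention and congruence
# ---------------------------------------------------------------------------

def retain_loadings(sol: FactorSolution, cut: float = 0.45) -> dict[int, int | None]:
    """Assign each item to the factor of its largest |pattern loading|,
    if that loading strictly exceeds ``cut``; otherwise unassigned (None).
    Ties go to the lowest factor index.
    """
    assign: dict[int, int | None] = {}
    for i, row in enumerate(sol.loadings):
        j = int(np.argmax(np.abs(row)))
        assign[i] = j if np.abs(row[j]) > cut else None
    return assign


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Matrix of Tucker congruence coefficients between loading columns."""
    na = np.sqrt(np.sum(a**2, axis=0))
    nb = np.sqrt(np.sum(b**2, axis=0))
    return (a.T @ b) / np.outer(na, nb)


def match_factors(reference: np.ndarray, candidate: np.ndarray):
    """Column permutation and sign flips aligning ``candidate`` to ``reference``
    by maximal absolute Tucker congruence (Hungarian assignment).

    Returns (permutation, signs): candidate column ``perm[j]`` times
    ``signs[j]`` corresponds to reference column ``j``.
    """
    c = tucker_congruence(reference, candidate)
    row, col = linear_sum_assignment(-np.abs(c))
    perm = np.empty(len(row), dtype=int)
    signs = np.empty(len(row))
    for i, j in zip(row, col):
        perm[i] = j
        signs[i] = 1.0 if c[i, j] >= 0 else -1.0
    return perm, signs


# ---------------------------------------------------------------------------
# Estimator and factor scores
# ---------------------------------------------------------------------------

class PrincipalAxisFactorAnalysis(BaseEstimator, TransformerMixin):
    """Exploratory factor analysis: principal axis factoring + oblimin.

    Parameters
    ----------
    n_factors : int
        Number of common factors to extract.
    rotation : {"oblimin", None}
        Oblique rotation of the extracted loadings. ``None`` leaves the
        unrotated principal-axis solution.
    gamma : float, default 0.0
        Oblimin family parameter (0 = direct quartimin).
    tol, max_iter : convergence control for the communality iteration.

    Attributes
    ----------
    loadings_ : (n_items, n_factors) pattern matrix
    factor_corr_ : (n_factors, n_factors) factor correlation matrix
    communalities_ : per-item common variance
    mean_, scale_ : standardization parameters learned from the training data
    corr_ : item correlation matrix of the training data

    ``transform`` returns regression (Thurstone) factor scores computed with
    the training-sample standardization, suitable for out-of-sample scoring.
    """

    def __init__(
        self,
        n_factors: int = 5,
        rotation: str | None = "oblimin",
        gamma: float = 0.0,
        tol: float = 1e-4,
        max_iter: int = 100,
    ):
        self.n_factors = n_factors
        self.rotation = rotation
        self.gamma = gamma
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float)
        if np.isnan(x).any():
            raise ValueError("X must be complete; impute first")
        labels = list(X.columns) if isinstance(X, pd.DataFrame) else [
            f"item{i + 1}" for i in range(x.shape[1])
        ]
        self.mean_ = x.mean(axis=0)
        self.scale_ = x.std(axis=0, ddof=1)
        if (self.scale_ == 0).any():
            raise ValueError("constant item column; remove in QC")
        self.corr_ = np.corrcoef(x, rowvar=False)
        sol = paf_oblimin(
            self.corr_,
            self.n_factors,
            gamma=self.gamma,
            tol=self.tol,
            max_iter=self.max_iter,
            rotate=self.rotation == "oblimin",
            item_labels=labels,
        )
        self.solution_ = sol
        self.loadings_ = sol.loadings
        self.factor_corr_ = sol.factor_corr
        self.communalities_ = sol.communalities
        self.n_iter_ = sol.n_iter
        self.converged_ = sol.converged
        self.n_features_in_ = x.shape[1]
        # regression score weights: R^{-1} S with S the structure matrix
        self.score_weights_ = np.linalg.solve(self.corr_, sol.structure)
        return self

    def transform(self, X) -> np.ndarray:
        """Regression factor scores (training standardization, not re-scaled)."""
        x = np.asarray(X, dtype=float)
        z = (x - self.mean_) / self.scale_
        return z @ self.score_weights_

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)


def factor_scores(model: PrincipalAxisFactorAnalysis, data) -> np.ndarray:
    """Z-scored regression factor scores for a fitted model."""
    s = model.transform(data)
    sd = s.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("degenerate factor score column")
    return (s - s.mean(axis=0)) / sd


def crossval_scores(
    data,
    k: int,
    n_folds: int = 10,
    seed: int = 0,
    folds: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Tenfold cross-validated factor scores and per-factor stability.

    Each fold fits the factor model on 90% of subjects and scores the held-out
    10%, until every subject has an out-of-sample score. Fold factors are
    matched to the full-sample solution by absolute Tucker congruence with
    sign alignment before scoring. Returns the out-of-sample score matrix and
    the per-factor Spearman rho against full-sample scores.
    """
    x = np.asarray(data, dtype=float)
    n = x.shape[0]
    if n < 10 * k:
        raise ValueError("too few subjects for cross-validated scoring")
    full = PrincipalAxisFactorAnalysis(n_factors=k).fit(x)
    full_scores = full.transform(x)
    oos = np.full((n, k), np.nan)
    if folds is not None:
        fold_ids = np.asarray(folds)
        splits = [
            (np.where(fold_ids != f)[0], np.where(fold_ids == f)[0])
            for f in np.unique(fold_ids)
        ]
    else:
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = list(kf.split(x))
    for train_idx, test_idx in splits:
        fold = PrincipalAxisFactorAnalysis(n_factors=k).fit(x[train_idx])
        perm, signs = match_factors(full.loadings_, fold.loadings_)
        s = fold.transform(x[test_idx])
        oos[test_idx] = s[:, perm] * signs
    rho = np.array(
        [stats.spearmanr(oos[:, j], full_scores[:, j]).statistic for j in range(k)]
    )
    return oos, rho
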