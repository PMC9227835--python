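"""The six association-analysis procedures.

Each method maps a (subjects x metabolites) matrix and an outcome to a
per-metabolite importance score and, where the method supports it, a
selected set:

1. univariate regression with Bonferroni or Benjamini-Hochberg (FDR)
   multiple-testing correction;
2. principal component regression (PCR) with importance reallocated to
   metabolites through the component loadings;
3. sparse partial least squares (SPLS) via soft-thresholded direction
   vectors (Chun-Keles formulation);
4. SPLS discriminant analysis (SPLSDA) for binary outcomes;
5. random forest with permutation importance;
6. LASSO (L1-penalized linear / logistic regression).

Scores are |coefficient| for regression-type methods and permutation
importance for the forest.  Tuning parameters of the sparse methods are
chosen by K-fold cross-validation; among grid points within one
standard error of the minimum CV error the sparsest model wins, the
standard resolution of a flat cross-validation curve.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import Lasso, LinearRegression, LogisticRegression, lasso_path
from sklearn.model_selection import KFold, StratifiedKFold
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("metabobench")

SELECTION_METHODS = frozenset({"bonferroni", "fdr", "lasso", "spls", "splsda"})
ALL_METHODS = ("bonferroni", "fdr", "pcr", "lasso", "spls", "splsda", "random_forest")

DEFAULT_ALPHA = 0.05        # family-wise level for Bonferroni
DEFAULT_FDR_Q = 0.1         # Benjamini-Hochberg false discovery rate
DEFAULT_N_FOLDS = 5
DEFAULT_ETA_GRID = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1))
DEFAULT_K_GRID = (1, 2, 3, 4, 5)
DEFAULT_N_ALPHAS = 100      # lasso path length
DEFAULT_ALPHA_DECADES = 4.0  # lasso path span below lambda_max
DEFAULT_N_TREES = 500

__all__ = [
    "MethodOutput",
    "SELECTION_METHODS",
    "ALL_METHODS",
    "univariate_scan",
    "bonferroni_select",
    "bh_select",
    "pcr_importance",
    "lasso_fit",
    "spls_fit",
    "splsda_fit",
    "tune_sparse",
    "rf_importance",
    "top_k",
    "run_method",
]


@dataclass
class MethodOutput:
    """Result of one method on one dataset."""

    method: str
    scores: np.ndarray
    selected: Optional[np.ndarray] = None
    tuning: dict = field(default_factory=dict)
    pvalues: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.selected is not None:
            self.selected = np.asarray(np.sort(self.selected), dtype=int)
        has_sel = self.selected is not None
        if has_sel != (self.method in SELECTION_METHODS):
            raise ValueError(
                f"method {self.method!r} {'must' if not has_sel else 'cannot'} "
                "carry a selected set"
            )

    def to_json_dict(self) -> dict:
        return {
            "method": self.method,
            "tuning": {k: (v.item() if hasattr(v, "item") else v) for k, v in self.tuning.items()},
            "selected": None if self.selected is None else self.selected.tolist(),
            "scores": self.scores.tolist(),
        }


# ---------------------------------------------------------------------------
# univariate scan + multiplicity corrections
# ---------------------------------------------------------------------------


def _residualize(v: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residuals of v on [1, covariates] (Frisch-Waugh partialling)."""
    c = np.column_stack([np.ones(len(v)), covariates])
    coef, *_ = np.linalg.lstsq(c, v, rcond=None)
    return v - c @ coef


def univariate_scan(
    X: np.ndarray,
    y: np.ndarray,
    outcome_type: str = "continuous",
    adjust_covariates: Optional[np.ndarray] = None,
    binary_model: str = "logistic",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-metabolite single-predictor regressions.

    Continuous outcomes: OLS Wald test per metabolite (vectorized via
    the partialled-out closed form).  Binary outcomes: per-metabolite
    logistic maximum likelihood Wald test, or a linear-probability scan
    when ``binary_model='linear'``.  Returns (two-sided p-values,
    coefficient estimates).  Degenerate fits (constant column, perfect
    separation) yield p = 1 conservatively.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    if outcome_type == "binary" and binary_model == "logistic":
        return _logistic_scan(X, y, adjust_covariates)

    n_cov = 0 if adjust_covariates is None else np.atleast_2d(adjust_covariates.T).T.shape[1]
    if adjust_covariates is not None:
        cov = np.atleast_2d(adjust_covariates.T).T
        y = _residualize(y, cov)
        X = X - np.column_stack([np.ones(n), cov]) @ np.linalg.lstsq(
            np.column_stack([np.ones(n), cov]), X, rcond=None
        )[0]
    else:
        X = X - X.mean(axis=0)
        y = y - y.mean()

    df = n - 2 - n_cov
    sxx = np.einsum("ij,ij->j", X, X)
    sxy = X.T @ y
    ok = sxx > 1e-12
    coef = np.zeros(m)
    coef[ok] = sxy[ok] / sxx[ok]
    rss = np.maximum(y @ y - coef**2 * sxx, 0.0)
    pvals = np.ones(m)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / df / np.where(ok, sxx, 1.0))
        t = np.where(se > 0, coef / se, np.inf * np.sign(coef))
    pvals[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df)
    pvals = np.clip(pvals, 0.0, 1.0)
    return pvals, coef


def _logistic_scan(
    X: np.ndarray, y: np.ndarray, adjust_covariates: Optional[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    import statsmodels.api as sm

    n, m = X.shape
    base = np.ones((n, 1))
    if adjust_covariates is not None:
        base = np.column_stack([base, np.atleast_2d(adjust_covariates.T).T])
    pvals = np.ones(m)
    coefs = np.zeros(m)
    for j in range(m):
        xj = X[:, j]
        if np.std(xj) < 1e-12:
            continue
        design = np.column_stack([base, xj])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, design).fit(disp=0, maxiter=100)
            se = res.bse[-1]
            if not np.isfinite(se) or se > 1e3:
                raise ValueError("unstable fit")
            pvals[j] = res.pvalues[-1]
            coefs[j] = res.params[-1]
        except Exception:  # separation / non-convergence: conservative p = 1
            logger.warning("logistic scan: unstable fit for metabolite %d; p set to 1", j)
            pvals[j] = 1.0
            coefs[j] = 0.0
    return np.clip(pvals, 0.0, 1.0), coefs


def bonferroni_select(pvalues: np.ndarray, alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Indices with p <= alpha / M (family-wise error control)."""
    p = np.asarray(pvalues, dtype=float)
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return np.flatnonzero(p <= alpha / p.size)


def bh_select(pvalues: np.ndarray, q: float = DEFAULT_FDR_Q) -> np.ndarray:
    """Benjamini-Hochberg step-up selection at false discovery rate q."""
    p = np.asarray(pvalues, dtype=float)
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return np.flatnonzero(reject)


# ---------------------------------------------------------------------------
# principal component regression
# ---------------------------------------------------------------------------


def pcr_importance(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    outcome_type: str = "continuous",
) -> MethodOutput:
    """PCR with importance reallocated to metabolites via the loadings.

    The outcome is regressed on the leading principal-component scores;
    importance_j = |sum_k V_jk gamma_k| where V are the loadings and
    gamma the fitted component coefficients.  No selected set: PCR only
    rank-orders metabolites.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if not 1 <= n_components <= min(n - 1, m):
        raise ValueError(f"n_components must lie in [1, {min(n - 1, m)}]")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    if outcome_type == "continuous":
        reg = LinearRegression().fit(scores, y)
        gamma = reg.coef_
    else:
        clf = LogisticRegression(penalty=None, max_iter=1000).fit(scores, y)
        gamma = clf.coef_.ravel()
    importance = np.abs(pca.components_.T @ gamma)
    return MethodOutput(
        method="pcr", scores=importance, tuning={"n_components": int(n_components)}
    )


# ---------------------------------------------------------------------------
# LASSO
# ---------------------------------------------------------------------------


def _lasso_alpha_grid(
    X: np.ndarray,
    y: np.ndarray,
    n_alphas: int = DEFAULT_N_ALPHAS,
    decades: float = DEFAULT_ALPHA_DECADES,
) -> np.ndarray:
    n = len(y)
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    alpha_max = np.max(np.abs(xc.T @ yc)) / n
    alpha_max = max(alpha_max, 1e-12)
    return np.geomspace(alpha_max, alpha_max * 10.0 ** (-decades), n_alphas)


def lasso_fit(
    X: np.ndarray,
    y: np.ndarray,
    outcome_type: str = "continuous",
    lam: Optional[float] = None,
    adjust_covariates: Optional[np.ndarray] = None,
    n_folds: int = DEFAULT_N_FOLDS,
    n_alphas: int = DEFAULT_N_ALPHAS,
    alpha_decades: float = DEFAULT_ALPHA_DECADES,
    seed: int = 0,
) -> MethodOutput:
    """L1-penalized regression; selected = support of the fitted coefficients.

    Continuous: minimizes (1/2N) ||y - Xb||^2 + lam * ||b||_1.  Binary:
    the correspondingly scaled penalized logistic likelihood.  When
    ``lam`` is omitted it is chosen by K-fold cross-validation with the
    one-standard-error sparsest rule (see :func:`tune_sparse`).
    Adjustment covariates enter unpenalized: for the linear model they
    are partialled out of X and y (exact for the penalized solution);
    for the logistic model they are appended with zero penalty weight.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if lam is not None and lam < 0:
        raise ValueError("lambda must be nonnegative")

    if adjust_covariates is not None and outcome_type == "continuous":
        cov = np.atleast_2d(adjust_covariates.T).T
        y = _residualize(y, cov)
        X = X - np.column_stack([np.ones(len(y)), cov]) @ np.linalg.lstsq(
            np.column_stack([np.ones(len(y)), cov]), X, rcond=None
        )[0]
        adjust_covariates = None

    if lam is None:
        chosen = tune_sparse(
            X, y, method="lasso", outcome_type=outcome_type,
            lambda_grid=_lasso_alpha_grid(X, y, n_alphas, alpha_decades),
            n_folds=n_folds, seed=seed,
            adjust_covariates=adjust_covariates,
        )
        lam = chosen["lambda"]

    coef = _lasso_solve(X, y, outcome_type, lam, adjust_covariates)
    selected = np.flatnonzero(coef != 0)
    return MethodOutput(
        method="lasso", scores=np.abs(coef), selected=selected, tuning={"lambda": float(lam)}
    )


def _lasso_solve(
    X: np.ndarray,
    y: np.ndarray,
    outcome_type: str,
    lam: float,
    adjust_covariates: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Coefficients of the penalized fit at a fixed penalty weight."""
    n, m = X.shape
    if outcome_type == "continuous":
        if lam == 0:
            reg = LinearRegression().fit(X, y)
            return reg.coef_
        model = Lasso(alpha=lam, fit_intercept=True, max_iter=10000, tol=1e-8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X, y)
        return model.coef_
    if adjust_covariates is not None:
        import statsmodels.api as sm

        cov = np.atleast_2d(adjust_covariates.T).T
        design = np.column_stack([X, cov, np.ones(n)])
        pen = np.concatenate([np.full(m, lam * n), np.zeros(cov.shape[1] + 1)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, design).fit_regularized(
                method="l1", alpha=pen, disp=0, trim_mode="auto", maxiter=500
            )
        return np.asarray(res.params[:m])
    c = np.inf if lam == 0 else 1.0 / (lam * n)
    clf = LogisticRegression(
        penalty="l1" if lam > 0 else None,
        C=c if lam > 0 else 1.0,
        solver="liblinear" if lam > 0 else "lbfgs",
        max_iter=2000,
        tol=1e-8,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, y)
    return clf.coef_.ravel()


# ---------------------------------------------------------------------------
# sparse partial least squares
# ---------------------------------------------------------------------------


def _spls_core(
    X: np.ndarray, y: np.ndarray, eta: float, n_components: int
) -> tuple[np.ndarray, np.ndarray]:
    """Support and refit coefficients of SPLS on a centered response.

    At each component the candidate direction z = X' y_deflated is
    soft-thresholded at eta * max|z|; the accumulated support A is
    refit with a k-component PLS restricted to X[:, A], and the
    response is deflated by the refit prediction.
    """
    n, m = X.shape
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    y_def = yc.copy()
    active = np.zeros(m, dtype=bool)
    coef = np.zeros(m)
    for k in range(1, n_components + 1):
        z = xc.T @ y_def
        zmax = np.max(np.abs(z))
        if zmax <= 1e-12:
            if not active.any():
                warnings.warn("SPLS: response orthogonal to predictors; empty selection")
            break
        w = np.sign(z) * np.maximum(np.abs(z) - eta * zmax, 0.0)
        active |= w != 0
        a_idx = np.flatnonzero(active)
        ncomp = min(k, len(a_idx), n - 1)
        pls = PLSRegression(n_components=ncomp, scale=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pls.fit(xc[:, a_idx], yc)
        beta_a = np.asarray(pls.coef_).reshape(-1)
        coef = np.zeros(m)
        coef[a_idx] = beta_a
        y_def = yc - xc[:, a_idx] @ beta_a
    return np.flatnonzero(active), coef


def spls_fit(
    X: np.ndarray,
    y: np.ndarray,
    eta: Optional[float] = None,
    n_components: Optional[int] = None,
    n_folds: int = DEFAULT_N_FOLDS,
    seed: int = 0,
    eta_grid: Sequence[float] = DEFAULT_ETA_GRID,
    k_grid: Sequence[int] = DEFAULT_K_GRID,
) -> MethodOutput:
    """Sparse PLS regression for a continuous outcome.

    ``eta`` in [0, 1) is the sparsity (thresholding) parameter and
    ``n_components`` the number of latent components K; both are chosen
    by cross-validation with the one-SE sparsest rule when omitted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if eta is not None and not 0.0 <= eta < 1.0:
        raise ValueError("eta must lie in [0, 1)")
    if eta is None or n_components is None:
        chosen = tune_sparse(
            X, y, method="spls", outcome_type="continuous",
            eta_grid=tuple(eta_grid) if eta is None else (eta,),
            k_grid=tuple(k_grid) if n_components is None else (n_components,),
            n_folds=n_folds, seed=seed,
        )
        eta, n_components = chosen["eta"], chosen["n_components"]
    selected, coef = _spls_core(X, y, eta, int(n_components))
    return MethodOutput(
        method="spls",
        scores=np.abs(coef),
        selected=selected,
        tuning={"eta": float(eta), "n_components": int(n_components)},
    )


def splsda_fit(
    X: np.ndarray,
    y_binary: np.ndarray,
    eta: Optional[float] = None,
    n_components: Optional[int] = None,
    n_folds: int = DEFAULT_N_FOLDS,
    seed: int = 0,
    eta_grid: Sequence[float] = DEFAULT_ETA_GRID,
    k_grid: Sequence[int] = DEFAULT_K_GRID,
) -> MethodOutput:
    """Sparse PLS discriminant analysis for a binary outcome.

    The centered class indicator is used as the SPLS response to obtain
    the sparse support and latent components; a logistic classifier on
    the components provides the discriminant fit.  Selection and scores
    are inherited from the sparse directions.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y_binary, dtype=float)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("SPLSDA requires both outcome classes present")
    if not set(classes).issubset({0.0, 1.0}):
        raise ValueError("binary outcome must be coded 0/1")
    if eta is not None and not 0.0 <= eta < 1.0:
        raise ValueError("eta must lie in [0, 1)")
    if eta is None or n_components is None:
        chosen = tune_sparse(
            X, y, method="splsda", outcome_type="binary",
            eta_grid=tuple(eta_grid) if eta is None else (eta,),
            k_grid=tuple(k_grid) if n_components is None else (n_components,),
            n_folds=n_folds, seed=seed,
        )
        eta, n_components = chosen["eta"], chosen["n_components"]
    selected, coef = _spls_core(X, y - y.mean(), eta, int(n_components))
    tuning = {"eta": float(eta), "n_components": int(n_components)}
    if len(selected):
        xc = X - X.mean(axis=0)
        ncomp = min(int(n_components), len(selected), len(y) - 1)
        pls = PLSRegression(n_components=ncomp, scale=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pls.fit(xc[:, selected], y - y.mean())
            latent = pls.x_scores_
            clf = LogisticRegression(penalty=None, max_iter=1000).fit(latent, y)
        tuning["classifier_intercept"] = float(clf.intercept_[0])
    return MethodOutput(method="splsda", scores=np.abs(coef), selected=selected, tuning=tuning)


# ---------------------------------------------------------------------------
# cross-validated tuning with the one-SE sparsest rule
# ---------------------------------------------------------------------------


def _folds(y: np.ndarray, outcome_type: str, n_folds: int, seed: int):
    if outcome_type == "binary":
        return StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed).split(
            np.zeros(len(y)), y
        )
    return KFold(n_splits=n_folds, shuffle=True, random_state=seed).split(np.zeros(len(y)))


def _sparsity_at(X, y, method, outcome_type, point) -> int:
    if method == "lasso":
        coef = _lasso_solve(X, y, outcome_type, point["lambda"])
        return int(np.count_nonzero(coef))
    sel, _ = _spls_core(
        X, y - y.mean() if method == "splsda" else y, point["eta"], point["n_components"]
    )
    return len(sel)


def tune_sparse(
    X: np.ndarray,
    y: np.ndarray,
    method: str,
    outcome_type: str = "continuous",
    eta_grid: Sequence[float] = (),
    k_grid: Sequence[int] = (),
    lambda_grid: Sequence[float] = (),
    n_folds: int = DEFAULT_N_FOLDS,
    seed: int = 0,
    adjust_covariates: Optional[np.ndarray] = None,
) -> dict:
    """Cross-validated tuning with the one-standard-error sparsest rule.

    K-fold CV prediction error (squared error; for binary outcomes the
    Brier score of the linear-predictor-based probability) is computed
    at every grid point.  The minimizing point wins, except that among
    all points whose CV error is within one standard error of the
    minimum the sparsest full-data model (fewest selected metabolites)
    is returned — the resolution of a flat CV curve in favour of
    parsimony.  Deterministic given ``seed`` (fold assignment).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if method == "lasso":
        points = [{"lambda": float(a)} for a in lambda_grid]
    else:
        points = [
            {"eta": float(e), "n_components": int(k)} for e in eta_grid for k in k_grid
        ]
    if not points:
        raise ValueError("tuning grid is empty")
    if len(points) == 1:
        return points[0]

    folds = list(_folds(y, outcome_type, n_folds, seed))
    fold_err = np.zeros((len(folds), len(points)))
    for f, (tr, te) in enumerate(folds):
        xt, yt = X[tr], y[tr]
        if method == "lasso":
            alphas = np.asarray([p["lambda"] for p in points])
            order = np.argsort(alphas)[::-1]
            if outcome_type == "continuous":
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, coefs, _ = lasso_path(xt, yt, alphas=alphas[order])
                icept = yt.mean() - xt.mean(axis=0) @ coefs
                pred = X[te] @ coefs + icept  # (n_te, n_alphas)
                err = np.mean((pred - y[te][:, None]) ** 2, axis=0)
            else:
                err = np.empty(len(points))
                for i, a in enumerate(alphas[order]):
                    coef = _lasso_solve(xt, yt, "binary", a)
                    p_hat = _binary_prob(xt, yt, coef, X[te])
                    err[i] = np.mean((p_hat - y[te]) ** 2)
            inv = np.empty(len(points))
            inv[order] = err
            fold_err[f] = inv
        else:
            yc_t = yt - yt.mean()
            for i, pt in enumerate(points):
                sel, coef = _spls_core(xt, yc_t if method == "splsda" else yt,
                                       pt["eta"], pt["n_components"])
                lin = (X[te] - xt.mean(axis=0)) @ coef
                if outcome_type == "binary":
                    p_hat = np.clip(yt.mean() + lin, 0.0, 1.0)
                    fold_err[f, i] = np.mean((p_hat - y[te]) ** 2)
                else:
                    fold_err[f, i] = np.mean((lin + yt.mean() - y[te]) ** 2)

    cv_mean = fold_err.mean(axis=0)
    cv_se = fold_err.std(axis=0, ddof=1) / np.sqrt(len(folds))
    best = int(np.argmin(cv_mean))
    cutoff = cv_mean[best] + cv_se[best]
    candidates = [i for i in range(len(points)) if cv_mean[i] <= cutoff]
    sparsities = [
        _sparsity_at(X, y, method, outcome_type, points[i]) for i in candidates
    ]
    # sparsest within one SE; ties resolved toward the stronger penalty
    order = sorted(
        range(len(candidates)),
        key=lambda r: (
            sparsities[r],
            -points[candidates[r]].get("lambda", points[candidates[r]].get("eta", 0.0)),
        ),
    )
    chosen = dict(points[candidates[order[0]]])
    chosen["cv_error"] = float(cv_mean[candidates[order[0]]])
    return chosen


def _binary_prob(xt, yt, coef, x_new) -> np.ndarray:
    """Probability for held-out samples from a fitted sparse logistic coefficient."""
    import statsmodels.api as sm

    sel = np.flatnonzero(coef != 0)
    if len(sel) == 0:
        return np.full(len(x_new), yt.mean())
    lin = x_new[:, sel] @ coef[sel]
    lin_t = xt[:, sel] @ coef[sel]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(yt, np.column_stack([np.ones(len(yt)), lin_t])).fit(disp=0)
        from scipy.special import expit

        return expit(res.params[0] + res.params[1] * lin)
    except Exception:
        from scipy.special import expit

        return expit(lin)


# ---------------------------------------------------------------------------
# random forest
# ---------------------------------------------------------------------------


def batched_permutation_importance(
    model,
    X: np.ndarray,
    y: np.ndarray,
    outcome_type: str,
    n_repeats: int = 5,
    seed: int = 0,
    chunk: int = 16,
    max_samples: Optional[int] = None,
) -> np.ndarray:
    """Permutation importance with chunked batch prediction.

    Computes the same statistic as scikit-learn's
    ``permutation_importance`` with the default scorer (drop in R² for
    regression, in accuracy for classification), but stacks the
    permuted copies of many columns into one prediction call per chunk,
    which is far faster for forest models whose per-call overhead
    dominates column-by-column evaluation.  ``max_samples`` scores the
    permutations on a random row subsample, trading Monte-Carlo noise
    for speed.
    """
    rng = np.random.default_rng(seed)
    if max_samples is not None and max_samples < X.shape[0]:
        rows = rng.choice(X.shape[0], size=max_samples, replace=False)
        X, y = X[rows], y[rows]
    n, m = X.shape
    if outcome_type == "continuous":
        ss_tot = np.sum((y - y.mean()) ** 2)

        def score(pred: np.ndarray) -> float:
            return 1.0 - np.sum((y - pred) ** 2) / ss_tot
    else:

        def score(pred: np.ndarray) -> float:
            return float(np.mean(pred == y))

    baseline = score(model.predict(X))
    drops = np.zeros((n_repeats, m))
    for r in range(n_repeats):
        for start in range(0, m, chunk):
            cols = range(start, min(start + chunk, m))
            big = np.concatenate([X] * len(cols), axis=0)
            for b, j in enumerate(cols):
                big[b * n : (b + 1) * n, j] = X[rng.permutation(n), j]
            preds = model.predict(big)
            for b, j in enumerate(cols):
                drops[r, j] = baseline - score(preds[b * n : (b + 1) * n])
    return drops.mean(axis=0)


def rf_importance(
    X: np.ndarray,
    y: np.ndarray,
    outcome_type: str = "continuous",
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    n_permutation_repeats: int = 5,
    permutation_max_samples: Optional[int] = None,
    max_features: Optional[float | str] = None,
) -> MethodOutput:
    """Random forest with permutation variable importance (no selection).

    Permutation importance is used because it is comparable across
    correlated predictors regardless of scale; negative estimates (pure
    permutation noise) are clipped at zero so scores stay nonnegative.
    ``max_features`` defaults to the classic random-forest mtry: p/3
    candidate features per split for regression, sqrt(p) for
    classification.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be positive")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if outcome_type == "continuous":
        model = RandomForestRegressor(
            n_estimators=n_trees, max_features=max_features or 1 / 3,
            random_state=seed, n_jobs=1,
        )
    else:
        model = RandomForestClassifier(
            n_estimators=n_trees, max_features=max_features or "sqrt",
            random_state=seed, n_jobs=1,
        )
    model.fit(X, y)
    imp_mean = batched_permutation_importance(
        model, X, y, outcome_type, n_repeats=n_permutation_repeats, seed=seed,
        max_samples=permutation_max_samples,
    )
    scores = np.clip(imp_mean, 0.0, None)
    return MethodOutput(
        method="random_forest",
        scores=scores,
        tuning={"n_trees": int(n_trees), "n_permutation_repeats": int(n_permutation_repeats)},
    )


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------


def top_k(scores: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest scores, descending; ties by ascending index."""
    scores = np.asarray(scores, dtype=float)
    if k > scores.size:
        raise ValueError("k exceeds the number of metabolites")
    order = np.lexsort((np.arange(scores.size), -scores))
    return order[:k]


# ---------------------------------------------------------------------------
# uniform dispatcher
# ---------------------------------------------------------------------------


def run_method(
    name: str,
    X: np.ndarray,
    y: np.ndarray,
    outcome_type: str = "continuous",
    options: Optional[dict] = None,
) -> MethodOutput:
    """Run one named method through the uniform (X, y, outcome_type, options) surface."""
    opts = dict(options or {})
    if name in ("bonferroni", "fdr"):
        pvals, coef = univariate_scan(
            X, y, outcome_type,
            adjust_covariates=opts.get("adjust_covariates"),
            binary_model=opts.get("binary_model", "logistic"),
        )
        if name == "bonferroni":
            sel = bonferroni_select(pvals, opts.get("alpha", DEFAULT_ALPHA))
            tuning = {"alpha": opts.get("alpha", DEFAULT_ALPHA)}
        else:
            sel = bh_select(pvals, opts.get("q", DEFAULT_FDR_Q))
            tuning = {"q": opts.get("q", DEFAULT_FDR_Q)}
        return MethodOutput(
            method=name, scores=np.abs(coef), selected=sel, tuning=tuning, pvalues=pvals
        )
    if name == "pcr":
        n_comp = opts.get("n_components") or min(10, X.shape[0] - 1, X.shape[1])
        return pcr_importance(X, y, n_components=n_comp, outcome_type=outcome_type)
    if name == "lasso":
        return lasso_fit(
            X, y, outcome_type,
            lam=opts.get("lambda"),
            adjust_covariates=opts.get("adjust_covariates"),
            n_folds=opts.get("n_folds", DEFAULT_N_FOLDS),
            n_alphas=opts.get("n_alphas", DEFAULT_N_ALPHAS),
            alpha_decades=opts.get("alpha_decades", DEFAULT_ALPHA_DECADES),
            seed=opts.get("seed", 0),
        )
    if name in ("spls", "splsda"):
        fit = spls_fit if name == "spls" else splsda_fit
        return fit(
            X, y,
            eta=opts.get("eta"), n_components=opts.get("n_components"),
            n_folds=opts.get("n_folds", DEFAULT_N_FOLDS), seed=opts.get("seed", 0),
            eta_grid=opts.get("eta_grid", DEFAULT_ETA_GRID),
            k_grid=opts.get("k_grid", DEFAULT_K_GRID),
        )
    if name == "random_forest":
        return rf_importance(
            X, y, outcome_type,
            n_trees=opts.get("n_trees", DEFAULT_N_TREES),
            seed=opts.get("seed", 0),
            n_permutation_repeats=opts.get("n_permutation_repeats", 5),
            permutation_max_samples=opts.get("permutation_max_samples"),
            max_features=opts.get("max_features"),
        )
    raise ValueError(f"unknown method {name!r}")
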