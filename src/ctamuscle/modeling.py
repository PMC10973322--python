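"""LASSO feature selection, logistic models, ROC evaluation, and the
published fixed-coefficient PAD-severity predictors.

Selection uses a linear-response LASSO (squared-error loss on the 0/1
outcome, the mean-squared-error criterion radiomics pipelines typically
report) solved by coordinate descent over a descending log-spaced lambda
grid, with outcome-stratified 10-fold cross-validation; the chosen lambda
minimizes mean CV MSE.  A logistic-deviance LASSO is available behind a
flag.  The final models are ordinary maximum-likelihood logistic
regressions with Wald-based odds ratios, a likelihood-ratio omnibus test,
and a 10-group Hosmer-Lemeshow goodness-of-fit test.  ROC analysis reports
the empirical AUC with a DeLong confidence interval and the Youden-optimal
cutoff (ties broken toward the lower, more sensitive cutoff).

Two published logistic equations are frozen here: LRM-I uses two muscle
features (the 10th percentile of muscle HU and the GLDM dependence
non-uniformity, both z-scored) and LRM-II adds the standardized CTA runoff
score; their classification cutoffs are 0.35 and 0.43.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import lasso_path
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "LassoResult",
    "lasso_select",
    "ModelReport",
    "fit_logistic",
    "SeparationError",
    "RocSummary",
    "roc_analysis",
    "PUBLISHED_MODELS",
    "predict_published",
    "build_models",
    "hosmer_lemeshow",
]

FEATURE1 = "histogram_10Percentile"
FEATURE2 = "gldm_DependenceNonUniformityNormalized"

#: published logistic equations (inputs z-scored with the training transform)
PUBLISHED_MODELS = {
    "LRM-I": {
        "coefficients": {FEATURE1: -1.29, FEATURE2: -0.67},
        "constant": -0.85,
        "cutoff": 0.35,
    },
    "LRM-II": {
        "coefficients": {"cta_score": 1.18, FEATURE1: -1.11, FEATURE2: -0.68},
        "constant": -0.90,
        "cutoff": 0.43,
    },
}


class SeparationError(RuntimeError):
    """Raised when the outcome is (quasi-)perfectly separable."""


# ---------------------------------------------------------------------------
# LASSO

@dataclass
class LassoResult:
    lambda_grid: np.ndarray
    cv_mse_mean: np.ndarray
    cv_mse_sd: np.ndarray
    lambda_star: float
    coef_path: np.ndarray  # (n_lambda, n_features), at the full-data fit
    selected: list[str]
    feature_names: list[str]

    @property
    def mse_at_star(self) -> tuple[float, float]:
        k = int(np.argmin(self.cv_mse_mean))
        return float(self.cv_mse_mean[k]), float(self.cv_mse_sd[k])


def _lambda_grid(X: np.ndarray, y: np.ndarray, n_lambda: int, eps: float) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    lam_max = np.abs(Xc.T @ (y - y.mean())).max() / len(y)
    return np.geomspace(lam_max, lam_max * eps, n_lambda)


def lasso_select(
    X: pd.DataFrame,
    y,
    folds: int = 10,
    seed: int = 0,
    n_lambda: int = 60,
    eps: float = 1e-3,
    loss: str = "mse",
) -> LassoResult:
    """Cross-validated LASSO on the 0/1 outcome; returns path and min-MSE lambda."""
    y = np.asarray(y, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("outcome is constant; LASSO selection is undefined")
    names = list(X.columns)
    Xa = np.asarray(X, dtype=float)
    n = len(y)
    if n < folds:
        raise ValueError(f"n={n} smaller than number of folds ({folds})")
    if loss not in ("mse", "logistic"):
        raise ValueError("loss must be 'mse' or 'logistic'")

    import warnings

    from sklearn.exceptions import ConvergenceWarning

    lams = _lambda_grid(Xa, y, n_lambda, eps)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    cv_mse = np.zeros((folds, len(lams)))
    for k, (tr, te) in enumerate(skf.split(Xa, y)):
        Xtr, ytr = Xa[tr], y[tr]
        if loss == "mse":
            # sklearn objective: (1/2n)||y - Xb||^2 + alpha ||b||_1, fitted
            # on fold-centered data (lasso_path itself has no intercept)
            xm, ym = Xtr.mean(axis=0), ytr.mean()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                _, coefs, _ = lasso_path(Xtr - xm, ytr - ym, alphas=lams, max_iter=3000)
            preds = (Xa[te] - xm) @ coefs + ym
        else:
            from sklearn.linear_model import LogisticRegression

            preds = np.empty((len(te), len(lams)))
            for j, lam in enumerate(lams):
                clf = LogisticRegression(
                    penalty="l1", C=1.0 / (lam * len(tr)), solver="liblinear"
                )
                clf.fit(Xtr, ytr)
                preds[:, j] = clf.predict_proba(Xa[te])[:, 1]
        cv_mse[k] = ((preds - y[te][:, None]) ** 2).mean(axis=0)

    mse_mean = cv_mse.mean(axis=0)
    mse_sd = cv_mse.std(axis=0, ddof=1)
    k_star = int(np.argmin(mse_mean))
    lam_star = float(lams[k_star])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        _, full_path, _ = lasso_path(
            Xa - Xa.mean(axis=0), y - y.mean(), alphas=lams, max_iter=3000
        )
    coef_star = full_path[:, k_star]
    selected = [names[i] for i in np.nonzero(coef_star)[0]]
    return LassoResult(
        lambda_grid=lams,
        cv_mse_mean=mse_mean,
        cv_mse_sd=mse_sd,
        lambda_star=lam_star,
        coef_path=full_path.T,
        selected=selected,
        feature_names=names,
    )


# ---------------------------------------------------------------------------
# logistic regression

@dataclass
class RocSummary:
    auc: float
    auc_ci: tuple[float, float]
    auc_p: float
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)


@dataclass
class ModelReport:
    variables: list[str]
    coefficients: dict[str, float]
    constant: float
    std_errors: dict[str, float]
    odds_ratios: dict[str, float]
    or_ci: dict[str, tuple[float, float]]
    p_values: dict[str, float]
    omnibus_p: float
    hosmer_lemeshow_p: float
    roc: RocSummary | None = None
    #: set when a ridge-penalized fallback replaced the ML fit (separated data);
    #: Wald-based quantities are then undefined (NaN)
    penalized: bool = False

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        lp = np.full(len(X), self.constant)
        for v in self.variables:
            lp = lp + self.coefficients[v] * np.asarray(X[v], dtype=float)
        return lp

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(X)))


def hosmer_lemeshow(probs, y, g: int = 10) -> tuple[float, float]:
    """Hosmer-Lemeshow chi-squared over g groups of predicted-risk deciles."""
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(probs, kind="stable")
    splits = np.array_split(order, g)
    chi2 = 0.0
    used = 0
    for idx in splits:
        if idx.size == 0:
            continue
        e1 = probs[idx].sum()
        o1 = y[idx].sum()
        e0 = idx.size - e1
        o0 = idx.size - o1
        if e1 <= 0 or e0 <= 0:
            continue
        chi2 += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
        used += 1
    df = max(used - 2, 1)
    return float(chi2), float(stats.chi2.sf(chi2, df))


def fit_logistic(X: pd.DataFrame, y, compute_hl: bool = True) -> ModelReport:
    """Maximum-likelihood logistic fit with Wald ORs and diagnostics."""
    import warnings

    y = np.asarray(y, dtype=float)
    names = list(X.columns)
    Xd = sm.add_constant(np.asarray(X, dtype=float), has_constant="add")
    with np.errstate(all="ignore"), warnings.catch_warnings():
        # separation is detected and raised below; the fit-time warnings
        # would only duplicate that signal
        warnings.simplefilter("ignore")
        model = sm.Logit(y, Xd)
        try:
            res = model.fit(disp=0, maxiter=200, method="newton")
        except Exception as exc:  # singular hessian etc. under separation
            raise SeparationError(
                "logistic fit failed (likely perfect separation); "
                "consider a penalized fit"
            ) from exc
    params = res.params
    if not res.mle_retvals.get("converged", True) or np.abs(params).max() > 25:
        raise SeparationError(
            "perfect or quasi-perfect separation detected; consider a penalized fit"
        )

    se = res.bse
    coef = dict(zip(names, params[1:]))
    ses = dict(zip(names, se[1:]))
    ors = {v: float(np.exp(coef[v])) for v in names}
    or_ci = {
        v: (
            float(np.exp(coef[v] - 1.96 * ses[v])),
            float(np.exp(coef[v] + 1.96 * ses[v])),
        )
        for v in names
    }
    pvals = dict(zip(names, res.pvalues[1:]))
    probs = res.predict()
    hl_p = hosmer_lemeshow(probs, y)[1] if compute_hl else float("nan")
    return ModelReport(
        variables=names,
        coefficients={v: float(coef[v]) for v in names},
        constant=float(params[0]),
        std_errors={v: float(ses[v]) for v in names},
        odds_ratios=ors,
        or_ci=or_ci,
        p_values={v: float(pvals[v]) for v in names},
        omnibus_p=float(res.llr_pvalue),
        hosmer_lemeshow_p=hl_p,
    )


# ---------------------------------------------------------------------------
# ROC / DeLong

def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x)
    z = x[order]
    n = len(x)
    t = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and z[j] == z[i]:
            j += 1
        t[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n)
    out[order] = t
    return out

def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n
    v10 = 1.0 - (tz[m:] - ty) / m
    var = np.var(v01, ddof=1) / m + np.var(v10, ddof=1) / n
    return float(auc), float(var)


def roc_analysis(scores, labels) -> RocSummary:
    """Empirical ROC with DeLong AUC CI and Youden-optimal cutoff.

    Positive class = label 1 (severe); a subject is called positive when
    its score is >= the cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")

    auc, var = _delong_variance(scores, labels)
    se = np.sqrt(var)
    if se > 0:
        ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))
        auc_p = float(2.0 * stats.norm.sf(abs(auc - 0.5) / se))
    else:
        ci = (auc, auc)
        auc_p = 0.0 if auc != 0.5 else 1.0

    # candidate cutoffs: observed scores (>= rule)
    cand = np.unique(scores)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    best = None
    for c in cand:  # ascending: later candidates only kept on strict improvement,
        pred = scores >= c  # so ties resolve toward the lower cutoff
        tp = int((pred & pos).sum())
        tn = int((~pred & ~pos).sum())
        sens = tp / n_pos
        spec = tn / n_neg
        youden = sens + spec - 1.0
        if best is None or youden > best[0] + 1e-12:
            best = (youden, c, sens, spec, tp, tn)
    _, cutoff, sens, spec, tp, tn = best
    acc = (tp + tn) / (n_pos + n_neg)
    return RocSummary(
        auc=float(auc),
        auc_ci=ci,
        auc_p=auc_p,
        cutoff=float(cutoff),
        sensitivity=float(sens),
        specificity=float(spec),
        accuracy=float(acc),
        counts={
            "sensitivity": (tp, n_pos),
            "specificity": (tn, n_neg),
            "accuracy": (tp + tn, n_pos + n_neg),
        },
    )


# ---------------------------------------------------------------------------
# published equations

def predict_published(features: dict | pd.Series, variant: str, cta_z: float | None = None):
    """Apply a published fixed-coefficient model to z-scored inputs.

    Returns ``{"logit", "probability", "severe"}`` where the class is severe
    iff probability >= the published cutoff.
    """
    if variant not in PUBLISHED_MODELS:
        raise ValueError(f"variant must be one of {sorted(PUBLISHED_MODELS)}")
    spec = PUBLISHED_MODELS[variant]
    logit = spec["constant"]
    for name, coef in spec["coefficients"].items():
        if name == "cta_score":
            if cta_z is None:
                raise ValueError("LRM-II requires the standardized CTA score (cta_z)")
            logit += coef * cta_z
        else:
            if name not in features:
                raise ValueError(f"missing required feature {name!r}")
            logit += coef * float(features[name])
    prob = 1.0 / (1.0 + np.exp(-logit))
    return {
        "logit": float(logit),
        "probability": float(prob),
        "severe": bool(prob >= spec["cutoff"]),
    }


# ---------------------------------------------------------------------------
# model building

@dataclass
class BuiltModels:
    lrm1: ModelReport
    lrm2: ModelReport
    cta_roc: RocSummary
    lasso: LassoResult


def _fit_reducing(X: pd.DataFrame, y, strength: dict[str, float], protected=()) -> ModelReport:
    """Fit a logistic model, dropping the weakest variable on separation.

    Maximum-likelihood logistic regression has no finite estimate under
    perfect separation, which is common when several informative,
    correlated features meet a small sample.  When that happens the
    weakest candidate (smallest selection-stage |coefficient|) is removed
    and the fit retried, mirroring how an analyst would de-escalate.
    """
    cols = list(X.columns)
    while True:
        try:
            return fit_logistic(X[cols], y)
        except SeparationError:
            droppable = [c for c in cols if c not in protected]
            if len(droppable) <= 1:
                # the data remain separable even for a single feature (tiny
                # or extreme cohorts): fall back to a ridge-penalized fit so
                # a usable classifier is still reported
                return _fit_penalized(X[cols], y)
            weakest = min(droppable, key=lambda c: abs(strength.get(c, 0.0)))
            cols.remove(weakest)


def _fit_penalized(X: pd.DataFrame, y) -> ModelReport:
    from sklearn.linear_model import LogisticRegression

    names = list(X.columns)
    clf = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)
    clf.fit(np.asarray(X, dtype=float), np.asarray(y))
    coef = dict(zip(names, clf.coef_[0]))
    nan = float("nan")
    probs = clf.predict_proba(np.asarray(X, dtype=float))[:, 1]
    return ModelReport(
        variables=names,
        coefficients={v: float(coef[v]) for v in names},
        constant=float(clf.intercept_[0]),
        std_errors={v: nan for v in names},
        odds_ratios={v: float(np.exp(coef[v])) for v in names},
        or_ci={v: (nan, nan) for v in names},
        p_values={v: nan for v in names},
        omnibus_p=nan,
        hosmer_lemeshow_p=hosmer_lemeshow(probs, np.asarray(y, dtype=float))[1],
        penalized=True,
    )


def _retain_significant(
    X: pd.DataFrame, y, report: ModelReport, strength, protected=(), alpha: float = 0.05
) -> ModelReport:
    """Backward-eliminate non-significant variables (keeping >= 1 feature).

    The published models report coefficients only for the variables that
    stayed significant in the multivariable fit; this reproduces that
    second selection step.
    """
    cols = list(report.variables)
    while True:
        droppable = [c for c in cols if c not in protected]
        if len(droppable) <= 1:
            return report
        worst = max(droppable, key=lambda c: report.p_values[c])
        if report.p_values[worst] <= alpha:
            return report
        cols.remove(worst)
        report = _fit_reducing(X[cols], y, strength, protected)


def build_models(
    features_z: pd.DataFrame,
    cta_z,
    groups,
    seed: int = 0,
    folds: int = 10,
    retain_alpha: float | None = 0.05,
) -> BuiltModels:
    """LRM-I from LASSO-selected muscle features; LRM-II adds the CTA score.

    ``features_z`` must already be screened and standardized; ``cta_z`` is
    the standardized CTA runoff score; ``groups`` the mild/severe labels.
    With ``retain_alpha`` set (default 0.05), variables that lose
    significance in the multivariable fit are backward-eliminated, which
    reproduces the two-stage selection behind the published two-feature
    equations; pass ``None`` to keep every LASSO-selected feature.
    """
    groups = np.asarray(groups)
    y = (groups == "severe").astype(float)
    min_class = int(min((y == 1).sum(), (y == 0).sum()))
    lasso = lasso_select(features_z, y, folds=min(folds, min_class), seed=seed)
    sel = lasso.selected
    if not sel:
        raise ValueError("LASSO selected no features; cannot build models")
    k_star = int(np.argmin(lasso.cv_mse_mean))
    strength = {
        name: lasso.coef_path[k_star, lasso.feature_names.index(name)] for name in sel
    }

    X1 = features_z[sel]
    lrm1 = _fit_reducing(X1, y, strength)
    if retain_alpha is not None:
        lrm1 = _retain_significant(X1, y, lrm1, strength, alpha=retain_alpha)
    X1_used = features_z[lrm1.variables]
    lrm1.roc = roc_analysis(lrm1.predict_proba(X1_used), y)

    X2 = features_z[sel].copy()
    X2.insert(0, "cta_score", np.asarray(cta_z, dtype=float))
    lrm2 = _fit_reducing(X2, y, strength, protected=("cta_score",))
    if retain_alpha is not None:
        lrm2 = _retain_significant(X2, y, lrm2, strength, protected=("cta_score",), alpha=retain_alpha)
    lrm2.roc = roc_analysis(lrm2.predict_proba(X2[lrm2.variables]), y)

    cta_roc = roc_analysis(np.asarray(cta_z, dtype=float), y)
    return BuiltModels(lrm1=lrm1, lrm2=lrm2, cta_roc=cta_roc, lasso=lasso)
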