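"""Logistic classification of the TaeEum (TE) Sasang type.

The modelling stage follows the study design: binary logistic regression of
TE vs non-TE on BMI and the seven facial metrics, exhaustive Bayesian model
averaging over all 2^8 predictor subsets with BIC weights
w_m ∝ exp(−BIC_m/2) (a uniform model prior and the BIC ≈ −2·log marginal
likelihood approximation), discrimination measured by the c statistic (area
under the ROC curve, estimated by the rank-based Mann–Whitney statistic
with ties counted one half), and internal validation by leave-one-out
cross-validation at a 0.5 probability threshold.

The published predictive equations use the sign convention
probability = 1/(1 + e^x); internal fits use the standard logistic
convention P(y=1) = 1/(1 + e^−η), so a published x corresponds to η = −x.

The user-facing surface is statsmodels-like: :class:`TaeEumClassifier` is
built from a subject DataFrame and its :meth:`~TaeEumClassifier.fit`
returns a :class:`TaeEumResults` carrying estimates, standard errors, BIC,
odds ratios, the c statistic and a ``summary()`` table.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from . import reference as ref
from .metrics import METRIC_NAMES

__all__ = [
    "PerfectSeparationError",
    "LogisticFit",
    "BmaResult",
    "fit_logistic",
    "c_statistic",
    "bma",
    "loocv_correct_rate",
    "predict_printed",
    "interaction_check",
    "TaeEumClassifier",
    "TaeEumResults",
    "CANDIDATE_PREDICTORS",
]

#: The eight candidate predictors of the TE model space.
CANDIDATE_PREDICTORS: tuple[str, ...] = ("bmi",) + METRIC_NAMES


class PerfectSeparationError(RuntimeError):
    """The likelihood is unbounded: a hyperplane separates the classes."""


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit for one predictor subset.

    ``params`` holds the intercept first, then one coefficient per entry of
    ``predictor_names`` (log-odds per unit of the predictor).
    """

    predictor_names: tuple[str, ...]
    params: np.ndarray
    bse: np.ndarray
    loglik: float
    n: int
    converged: bool
    separation: bool = False
    ridge: float = 0.0
    fittedvalues: np.ndarray | None = field(default=None, repr=False)

    @property
    def k(self) -> int:
        """Number of estimated parameters, intercept included."""
        return len(self.params)

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.k * math.log(self.n)

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.params[0] + X @ self.params[1:]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """P(TE) for rows of ``X`` (columns ordered as ``predictor_names``)."""
        return expit(self.linear_predictor(X))

    def odds_ratios(self, units: dict[str, float] | None = None) -> pd.DataFrame:
        """Odds ratios with 95% Wald CIs per stated comparison unit.

        ``units`` maps predictor name to the comparison unit; defaults to
        the published units (1 for BMI, eye size and eyebrow height,
        SD-like units for the ratio metrics).
        """
        units = units or ref.COMPARISON_UNITS
        zcrit = stats.norm.ppf(0.975)
        rows = []
        for i, name in enumerate(self.predictor_names, start=1):
            u = units.get(name, 1.0)
            b, se = self.params[i] * u, self.bse[i] * u
            rows.append({
                "predictor": name,
                "unit": u,
                "odds_ratio": math.exp(b),
                "ci_low": math.exp(b - zcrit * se),
                "ci_high": math.exp(b + zcrit * se),
            })
        return pd.DataFrame(rows).set_index("predictor")


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    y,
    X,
    names=None,
    ridge: float = 0.0,
    max_iter: int = 100,
    tol: float = 1e-10,
    on_separation: str = "raise",
    start_params: np.ndarray | None = None,
) -> LogisticFit:
    """Fit a logistic regression by iteratively reweighted least squares.

    Newton/IRLS with step halving; convergence when the log-likelihood
    change drops below ``tol``.  Wald standard errors come from the inverse
    observed information at the optimum.  Perfect separation raises
    :class:`PerfectSeparationError` (``on_separation="raise"``) or flags the
    fit (``"flag"``); a small ``ridge`` penalty stabilises separated fits.

    ``X`` has one column per predictor (no intercept column); the intercept
    is always estimated.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, m = X.shape
    if len(y) != n:
        raise ValueError("y and X have different lengths")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("y must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome has no variation: all labels identical")
    if n <= m + 1:
        raise ValueError(f"need n > k+1 observations, got n={n}, k={m}")
    const = np.ptp(X, axis=0) == 0
    if const.any():
        raise ValueError(f"constant predictor column(s) at index {np.where(const)[0]}")
    if names is None:
        names = tuple(f"x{i + 1}" for i in range(m))
    names = tuple(names)

    Xd = np.column_stack([np.ones(n), X])
    k = m + 1
    beta = np.zeros(k) if start_params is None else np.asarray(start_params, float).copy()
    pen = lambda b: 0.5 * ridge * float(b @ b)  # noqa: E731
    eta = Xd @ beta
    ll = _loglik(eta, y) - pen(beta)
    converged = False
    for _ in range(max_iter):
        p = expit(eta)
        w = p * (1.0 - p)
        grad = Xd.T @ (y - p) - ridge * beta
        hess = (Xd * np.maximum(w, 1e-12)[:, None]).T @ Xd + ridge * np.eye(k)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular design matrix") from exc
        new_beta = beta + step
        new_eta = Xd @ new_beta
        new_ll = _loglik(new_eta, y) - pen(new_beta)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new_eta = Xd @ new_beta
            new_ll = _loglik(new_eta, y) - pen(new_beta)
            halvings += 1
        beta, eta = new_beta, new_eta
        if abs(new_ll - ll) < tol:
            ll = new_ll
            converged = True
            break
        ll = new_ll

    separated = bool(
        ridge == 0.0
        and (eta[y == 1].min(initial=np.inf) > eta[y == 0].max(initial=-np.inf))
        and np.abs(eta).max() > 20
    )
    if separated and on_separation == "raise":
        raise PerfectSeparationError(
            "perfect separation detected: the classes are linearly separable "
            f"(|linear predictor| up to {np.abs(eta).max():.1f}); "
            "consider a ridge-stabilised fit"
        )

    p = expit(eta)
    w = np.maximum(p * (1.0 - p), 1e-12)
    info = (Xd * w[:, None]).T @ Xd + ridge * np.eye(k)
    cov = np.linalg.inv(info)
    bse = np.sqrt(np.diag(cov))
    return LogisticFit(
        predictor_names=names,
        params=beta,
        bse=bse,
        loglik=_loglik(eta, y),
        n=n,
        converged=converged,
        separation=separated,
        ridge=ridge,
        fittedvalues=p,
    )


def c_statistic(scores, labels) -> float:
    """Area under the ROC curve by the rank (Mann–Whitney) estimator.

    Equals the probability that a random positive case outranks a random
    negative case, with ties counted one half.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(float)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("c statistic requires both classes present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass
class BmaResult:
    """Exhaustively enumerated logistic model space with BIC weights."""

    candidate_names: tuple[str, ...]
    models: list[LogisticFit]
    bics: np.ndarray
    weights: np.ndarray
    inclusion_probs: dict[str, float]
    parsimonious: LogisticFit
    n_failed: int = 0

    def model_table(self) -> pd.DataFrame:
        rows = [
            {
                "predictors": "+".join(m.predictor_names) or "(intercept)",
                "k": m.k,
                "loglik": m.loglik,
                "bic": b,
                "weight": w,
            }
            for m, b, w in zip(self.models, self.bics, self.weights)
        ]
        return pd.DataFrame(rows).sort_values("bic").reset_index(drop=True)


def _intercept_only_fit(y: np.ndarray) -> LogisticFit:
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    phat = y.mean()
    if phat in (0.0, 1.0):
        raise ValueError("outcome has no variation: all labels identical")
    beta0 = math.log(phat / (1 - phat))
    ll = float(np.sum(y * beta0 - np.logaddexp(0.0, beta0)))
    se = 1.0 / math.sqrt(n * phat * (1 - phat))
    return LogisticFit(
        predictor_names=(),
        params=np.array([beta0]),
        bse=np.array([se]),
        loglik=ll,
        n=n,
        converged=True,
        fittedvalues=np.full(n, phat),
    )


def bma(y, X, names=None, max_iter: int = 100, tol: float = 1e-10) -> BmaResult:
    """BIC-based Bayesian model averaging over all predictor subsets.

    Fits every subset of the columns of ``X`` (intercept-only included, so
    2^m models), weights each model by exp(−BIC/2) normalised, and reports
    per-predictor inclusion probabilities and the argmin-BIC (most
    parsimonious) model.  Subsets that fail to converge or separate
    perfectly are excluded with a warning and the weights renormalised.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    m = X.shape[1]
    if names is None:
        names = tuple(f"x{i + 1}" for i in range(m))
    names = tuple(names)

    models: list[LogisticFit] = []
    failed = 0
    for size in range(m + 1):
        for subset in itertools.combinations(range(m), size):
            if size == 0:
                models.append(_intercept_only_fit(y))
                continue
            try:
                fit = fit_logistic(
                    y, X[:, subset], names=tuple(names[j] for j in subset),
                    max_iter=max_iter, tol=tol, on_separation="raise",
                )
            except (PerfectSeparationError, ValueError) as exc:
                warnings.warn(
                    f"excluding subset {tuple(names[j] for j in subset)}: {exc}",
                    stacklevel=2,
                )
                failed += 1
                continue
            if not fit.converged:
                warnings.warn(
                    f"excluding non-converged subset {fit.predictor_names}",
                    stacklevel=2,
                )
                failed += 1
                continue
            models.append(fit)

    bics = np.array([f.bic for f in models])
    rel = -0.5 * (bics - bics.min())
    weights = np.exp(rel)
    weights /= weights.sum()
    inclusion = {
        name: float(weights[[name in f.predictor_names for f in models]].sum())
        for name in names
    }
    parsimonious = models[int(np.argmin(bics))]
    return BmaResult(
        candidate_names=names,
        models=models,
        bics=bics,
        weights=weights,
        inclusion_probs=inclusion,
        parsimonious=parsimonious,
        n_failed=failed,
    )


def loocv_correct_rate(
    y,
    X,
    threshold: float = 0.5,
    ridge_fallback: float = 1e-4,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> float:
    """Leave-one-out cross-validated percent-correct classification rate.

    Each fold refits the model without one subject and classifies it as TE
    when the held-out predicted probability exceeds ``threshold``.  Folds
    whose refit separates perfectly (or fails) fall back to a
    ridge-stabilised fit with penalty ``ridge_fallback``.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(y)
    full = fit_logistic(y, X, max_iter=max_iter, tol=tol, on_separation="flag")
    correct = 0
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        try:
            fit = fit_logistic(
                y[mask], X[mask], max_iter=max_iter, tol=tol,
                on_separation="raise", start_params=full.params,
            )
        except (PerfectSeparationError, ValueError):
            fit = fit_logistic(
                y[mask], X[mask], max_iter=max_iter, tol=tol,
                ridge=ridge_fallback, on_separation="flag",
                start_params=full.params,
            )
        mask[i] = True
        p_i = float(fit.predict(X[i : i + 1])[0])
        correct += int((p_i > threshold) == bool(y[i]))
    return 100.0 * correct / n


def predict_printed(stratum: str, bmi, cjwr):
    """Probability of the TE type from the published predictive equation.

    Evaluates probability = 1/(1 + e^x) with the published coefficients,
    x = b0 + b_bmi·BMI + b_cjwr·CJWR, exactly as printed.  Accepts scalars
    or arrays.
    """
    if stratum not in ref.PRINTED_EQUATIONS:
        raise KeyError(
            f"unknown stratum {stratum!r}; expected one of {tuple(ref.PRINTED_EQUATIONS)}"
        )
    b0, b_bmi, b_cjwr = ref.PRINTED_EQUATIONS[stratum]
    x = b0 + b_bmi * np.asarray(bmi, dtype=float) + b_cjwr * np.asarray(cjwr, dtype=float)
    out = expit(-x)  # 1/(1+e^x), numerically stable
    return float(out) if out.ndim == 0 else out


def interaction_check(y, bmi, cjwr) -> float:
    """Two-sided Wald p-value of the BMI×CJWR interaction term.

    Fits the logistic model {BMI, CJWR, BMI·CJWR} and reports the Wald
    p-value of the product term.
    """
    bmi = np.asarray(bmi, dtype=float)
    cjwr = np.asarray(cjwr, dtype=float)
    X = np.column_stack([bmi, cjwr, bmi * cjwr])
    fit = fit_logistic(y, X, names=("bmi", "CJWR", "bmi:CJWR"), on_separation="flag")
    z = fit.params[3] / fit.bse[3]
    return float(2.0 * stats.norm.sf(abs(z)))


# --------------------------------------------------------------------------
# Model / Results surface
# --------------------------------------------------------------------------


class TaeEumClassifier:
    """Logistic TE-vs-non-TE model built from a subject DataFrame.

    Parameters
    ----------
    data
        One row per subject with a Sasang type column and the predictor
        columns (``bmi`` plus the facial metrics by default).
    predictors
        Candidate predictor columns; defaults to BMI and the seven metrics.
    target
        The type treated as the positive class (default ``"TE"``).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        predictors=None,
        target: str = "TE",
        type_col: str = "sasang_type",
    ) -> None:
        self.data = data.reset_index(drop=True)
        self.predictors = tuple(predictors) if predictors else CANDIDATE_PREDICTORS
        missing = [c for c in self.predictors if c not in data.columns]
        if missing:
            raise KeyError(f"data lacks predictor column(s) {missing}")
        if type_col not in data.columns:
            raise KeyError(f"data lacks type column {type_col!r}")
        self.target = target
        self.endog = (self.data[type_col] == target).to_numpy(dtype=float)
        self.exog = self.data[list(self.predictors)].to_numpy(dtype=float)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "TaeEumClassifier":
        return cls(data, **kwargs)

    def fit(self, predictors=None, **kwargs) -> "TaeEumResults":
        """ML fit on the given predictor subset (all candidates by default)."""
        names = tuple(predictors) if predictors else self.predictors
        idx = [self.predictors.index(p) for p in names]
        fit = fit_logistic(self.endog, self.exog[:, idx], names=names, **kwargs)
        return TaeEumResults(self, fit)

    def fit_bma(self, **kwargs) -> BmaResult:
        """Exhaustive BIC model averaging over all candidate subsets."""
        return bma(self.endog, self.exog, names=self.predictors, **kwargs)

    def interaction_check(self, a: str = "bmi", b: str = "CJWR") -> float:
        """Wald p-value for the a×b interaction in the two-predictor model."""
        return interaction_check(
            self.endog,
            self.data[a].to_numpy(dtype=float),
            self.data[b].to_numpy(dtype=float),
        )


class TaeEumResults:
    """Fit results: estimates, uncertainty, discrimination, validation."""

    def __init__(self, model: TaeEumClassifier, fit: LogisticFit) -> None:
        self.model = model
        self.fit = fit

    # -- estimates -----------------------------------------------------
    @property
    def params(self) -> pd.Series:
        names = ("intercept",) + self.fit.predictor_names
        return pd.Series(self.fit.params, index=names)

    @property
    def bse(self) -> pd.Series:
        names = ("intercept",) + self.fit.predictor_names
        return pd.Series(self.fit.bse, index=names)

    @property
    def loglik(self) -> float:
        return self.fit.loglik

    @property
    def bic(self) -> float:
        return self.fit.bic

    def odds_ratios(self, units: dict[str, float] | None = None) -> pd.DataFrame:
        return self.fit.odds_ratios(units=units)

    # -- diagnostics -----------------------------------------------------
    @property
    def c_statistic(self) -> float:
        """In-sample area under the ROC curve of the fitted probabilities."""
        return c_statistic(self.fit.fittedvalues, self.model.endog)

    def loocv(self, threshold: float = 0.5) -> float:
        """Leave-one-out cross-validated percent-correct rate."""
        idx = [self.model.predictors.index(p) for p in self.fit.predictor_names]
        return loocv_correct_rate(
            self.model.endog, self.model.exog[:, idx], threshold=threshold
        )

    def predict(self, data: pd.DataFrame | None = None) -> np.ndarray:
        """P(TE) for new subjects (or the training subjects by default)."""
        if data is None:
            return self.fit.fittedvalues
        X = data[list(self.fit.predictor_names)].to_numpy(dtype=float)
        return self.fit.predict(X)

    def published_equation_x(self) -> pd.Series:
        """Coefficients in the published sign convention (x = −η)."""
        return -self.params

    def summary(self) -> str:
        """Human-readable fit summary."""
        orat = self.odds_ratios()
        lines = [
            f"TaeEum ({self.model.target}) logistic classification",
            f"  n = {self.fit.n}, positives = {int(self.model.endog.sum())}",
            f"  predictors: {', '.join(self.fit.predictor_names) or '(intercept only)'}",
            f"  log-likelihood = {self.loglik:.4f}   BIC = {self.bic:.4f}",
            f"  c statistic (AUC) = {self.c_statistic:.4f}",
            "",
            f"  {'term':<10}{'coef':>10}{'se':>10}{'unit':>8}{'OR':>8}{'95% CI':>18}",
        ]
        zcrit = stats.norm.ppf(0.975)
        b0, se0 = self.fit.params[0], self.fit.bse[0]
        lines.append(f"  {'intercept':<10}{b0:>10.4f}{se0:>10.4f}{'':>8}{'':>8}{'':>18}")
        for name in self.fit.predictor_names:
            i = 1 + self.fit.predictor_names.index(name)
            row = orat.loc[name]
            ci = f"({row.ci_low:.2f}-{row.ci_high:.2f})"
            lines.append(
                f"  {name:<10}{self.fit.params[i]:>10.4f}{self.fit.bse[i]:>10.4f}"
                f"{row.unit:>8.3g}{row.odds_ratio:>8.2f}{ci:>18}"
            )
        if self.fit.separation:
            lines.append("  WARNING: perfect separation flagged; estimates unstable")
        return "\n".join(lines)
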