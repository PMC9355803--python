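"""Outlier removal and stepwise hierarchical robust regression.

The population word scores are related to the seven word features in a
fixed hierarchy (acoustic before linguistic): each feature is fitted on
the residuals left by the previous ones with a single-predictor,
no-intercept robust (Huber) regression, its prediction is projected out,
and the next feature is fitted on what remains.  Shared variance is
thereby assigned conservatively to the earlier features.  The seven
coefficient p-values are Benjamini-Yekutieli corrected as one family.

Before the regression, words are screened with an isolation forest over
the eight standardized descriptors (seven features + score); points
whose anomaly score 2^(-E[h]/c(n)) exceeds the automatic 0.5 threshold
are removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .trf import by_correct
from .words import FEATURE_ORDER

HUBER_K = 1.345  # 95% Gaussian efficiency
MAD_CONSTANT = 0.6744897501960817  # Phi^-1(0.75)


# ---------------------------------------------------------------- isolation forest

def harmonic_number(n: int) -> float:
    """Exact H(n) = sum_{i=1..n} 1/i (0 for n <= 0)."""
    if n <= 0:
        return 0.0
    return float(np.sum(1.0 / np.arange(1, n + 1)))


def path_length_normalizer(n: int) -> float:
    """c(n) = 2 H(n-1) - 2 (n-1)/n, the average BST search path length."""
    if n <= 1:
        return 0.0
    return 2.0 * harmonic_number(n - 1) - 2.0 * (n - 1) / n


def anomaly_score(mean_path_length: float, n: int) -> float:
    """s(x) = 2^(-E[h(x)] / c(n)) for a subsample of size n."""
    c = path_length_normalizer(n)
    if c == 0:
        return 1.0
    return float(2.0 ** (-mean_path_length / c))


@dataclass(frozen=True)
class OutlierConfig:
    n_trees: int = 1000
    subsample: int = 256
    threshold_rule: str = "auto"  # anomaly score > 0.5 flags an outlier
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.threshold_rule != "auto":
            raise ValueError("only the automatic threshold is supported")


def isolation_forest_outliers(data: np.ndarray, config: OutlierConfig) -> np.ndarray:
    """Inlier mask over the rows of ``data`` (True = keep).

    Random trees isolate anomalous points near the root, so their mean
    path length is short and the anomaly score 2^(-E[h]/c(n)) large; the
    automatic threshold flags scores above 0.5.  Deterministic given the
    config seed.
    """
    from sklearn.ensemble import IsolationForest

    data = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("data must be finite")
    n = data.shape[0]
    if n < 2 or np.allclose(data, data[0]):
        return np.ones(n, dtype=bool)
    forest = IsolationForest(
        n_estimators=config.n_trees,
        max_samples=min(config.subsample, n),
        contamination="auto",
        random_state=config.seed,
    )
    return forest.fit_predict(data) == 1


# ---------------------------------------------------------------- Huber regression

@dataclass
class HuberFit:
    coeff: float
    se: float
    z: float
    p: float
    ci: tuple[float, float]
    n_iter: int
    scale: float

    def __iter__(self):
        return iter((self.coeff, self.se, self.z, self.p, self.ci))


def huber_fit(
    x: np.ndarray,
    y: np.ndarray,
    k: float = HUBER_K,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> HuberFit:
    """Single-predictor, no-intercept Huber regression by IRLS.

    Weights ``w(e) = min(1, k / |e / s|)`` with the MAD scale ``s``
    re-estimated each iteration; convergence when the coefficient moves
    by less than ``tol``.  The standard error is the usual Huber
    asymptotic (sandwich) estimate and the p-value two-sided normal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 observations")
    sxx = float(x @ x)
    if sxx == 0:
        raise ValueError("constant predictor")
    a = float(x @ y) / sxx  # OLS start
    w = np.ones(n)
    n_iter = 0
    scale = 1.0
    for n_iter in range(1, max_iter + 1):
        resid = y - a * x
        mad = np.median(np.abs(resid - np.median(resid)))
        scale = mad / MAD_CONSTANT if mad > 0 else max(np.abs(resid).max(), 1e-12)
        u = np.abs(resid / scale)
        with np.errstate(divide="ignore"):
            w = np.minimum(1.0, np.where(u > 0, k / u, np.inf))
        denom = float((w * x) @ x)
        a_new = float((w * x) @ y) / denom
        if abs(a_new - a) < tol:
            a = a_new
            break
        a = a_new
    else:
        raise RuntimeError(
            f"Huber IRLS did not converge in {max_iter} iterations "
            f"(last coeff {a:.6g}, scale {scale:.6g})"
        )
    resid = y - a * x
    u = resid / scale
    psi = np.clip(u, -k, k)                       # psi(u) = u * w(u)
    psi_prime = (np.abs(u) <= k).astype(float)
    # sandwich (heteroscedasticity-robust) variance: the per-word score
    # noise scales with word length, so the x^2-weighted form matters
    bread = float((psi_prime * x * x).sum())
    meat = (scale**2) * float((psi**2 * x * x).sum()) * n / max(n - 1, 1)
    se = np.sqrt(meat) / bread if bread > 0 else np.inf
    z = a / se if se > 0 else np.inf
    p = 2 * stats.norm.sf(abs(z))
    ci = (a - 1.96 * se, a + 1.96 * se)
    return HuberFit(a, float(se), float(z), float(p), ci, n_iter, float(scale))


# ------------------------------------------------------- stepwise hierarchy

@dataclass
class RegressionResult:
    """Stepwise hierarchical fit: one row per feature in hierarchy order."""

    table: pd.DataFrame  # feature, coeff, se, ci_low, ci_high, z, p_raw, p_fdr
    order: tuple[str, ...]
    n_retained: int
    residual_variance: np.ndarray = field(default=None)

    def summary(self) -> str:
        lines = [
            f"Stepwise hierarchical Huber regression (n = {self.n_retained})",
            f"{'Feature':<22}{'Coeff.':>9}{'SE':>8}{'95% CI':>20}{'z':>9}{'p (FDR)':>11}",
        ]
        for _, r in self.table.iterrows():
            ci = f"({r.ci_low:.3f};{r.ci_high:.3f})"
            star = "(*)" if r.p_fdr < 0.05 else "(n.s.)"
            lines.append(
                f"{r.feature + ' ' + star:<22}{r.coeff:>9.3f}{r.se:>8.3f}"
                f"{ci:>20}{r.z:>9.3f}{r.p_fdr:>11.3g}"
            )
        return "\n".join(lines)


def stepwise_hierarchical(
    features: pd.DataFrame | np.ndarray,
    scores: np.ndarray,
    order: tuple[str, ...] = FEATURE_ORDER,
) -> RegressionResult:
    """Fit the ordered features one at a time on running residuals.

    Features and scores must be standardized.  Step k fits
    ``huber_fit(x_k, residuals)``, records the coefficient statistics and
    subtracts the fitted values before the next step.  The p-values of
    all steps are BY-corrected jointly.
    """
    if isinstance(features, pd.DataFrame):
        X = features[list(order)].to_numpy(dtype=float)
        names = list(order)
    else:
        X = np.asarray(features, dtype=float)
        names = list(order[: X.shape[1]])
    y = np.asarray(scores, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("features and scores must align")
    resid = y.copy()
    rows = []
    res_var = [float(resid.var())]
    for kk, name in enumerate(names):
        fit = huber_fit(X[:, kk], resid)
        rows.append(
            {
                "feature": name,
                "coeff": fit.coeff,
                "se": fit.se,
                "ci_low": fit.ci[0],
                "ci_high": fit.ci[1],
                "z": fit.z,
                "p_raw": fit.p,
            }
        )
        resid = resid - fit.coeff * X[:, kk]
        res_var.append(float(resid.var()))
    table = pd.DataFrame(rows)
    table["p_fdr"] = by_correct(table["p_raw"].to_numpy())
    return RegressionResult(table, tuple(names), int(y.size), np.asarray(res_var))


class StepwiseHierarchicalModel:
    """Population word scores ~ seven word features, the full procedure.

    Standardizes the inputs, optionally removes outliers with an
    isolation forest over (features, score), then runs the stepwise
    hierarchical Huber regression.  ``fit()`` returns a
    :class:`RegressionResult` whose ``summary()`` prints the coefficient
    table.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        scores: np.ndarray,
        order: tuple[str, ...] = FEATURE_ORDER,
        outlier_config: OutlierConfig | None = OutlierConfig(),
    ):
        missing = [c for c in order if c not in features.columns]
        if missing:
            raise ValueError(f"missing feature columns: {missing}")
        self.order = order
        self.outlier_config = outlier_config
        X = features[list(order)].to_numpy(dtype=float)
        y = np.asarray(scores, dtype=float)
        ok = np.all(np.isfinite(X), axis=1) & np.isfinite(y)
        from .lagged import standardize

        self.X = standardize(X[ok])
        self.y = standardize(y[ok]).ravel()

    def fit(self) -> RegressionResult:
        if self.outlier_config is not None:
            mask = isolation_forest_outliers(
                np.column_stack([self.X, self.y]), self.outlier_config
            )
        else:
            mask = np.ones(self.y.size, dtype=bool)
        from .lagged import standardize

        X = standardize(self.X[mask])
        y = standardize(self.y[mask]).ravel()
        result = stepwise_hierarchical(X, y, self.order)
        result.n_retained = int(mask.sum())
        return result
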