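"""Linear dose models, new-observation prediction, and exceedance probabilities.

The planning workflow rests on four ordinary-least-squares regressions of
later-cycle kidney absorbed doses on earlier ones:

* ``simple`` — D2 + D3 + D4 on D1 (four-cycle completers),
* ``joint34`` — D3 + D4 on D1 and D2 (four-cycle completers),
* ``d3`` — D3 on D1 and D2 (patients with at least three cycles),
* ``d4`` — D4 on D1, D2 and D3 (four-cycle completers).

A fitted model predicts the dose a *new* patient will accumulate in the
remaining cycles.  The prediction error for a single new observation is
t-distributed with scale ``s * sqrt(1 + x0' (X'X)^-1 x0)`` (the residual
standard error inflated by the leverage of the query point), so the
probability that the cumulative dose exceeds a safety threshold is an
upper-tail Student-t probability.  That exceedance probability is the
quantity every downstream planning decision consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.sandbox.stats.runs import runstest_1samp

__all__ = [
    "LinearModelFit",
    "ExceedanceResult",
    "fit_linear",
    "fit_reference_models",
    "predict_new_observation",
    "exceedance_probability",
    "lilliefors_normality",
    "runs_test_independence",
    "pearson_correlation",
]

#: relative singular-value cutoff below which a design matrix is declared
#: rank deficient
RANK_TOLERANCE = 1e-10


@dataclass(frozen=True)
class LinearModelFit:
    """An ordinary-least-squares fit with everything prediction needs.

    ``coefficients`` holds the intercept first, then one slope per entry of
    ``predictor_labels``.  ``design_information`` is the (p+1)x(p+1) matrix
    (X'X)^-1 for the design including the intercept column, which is all
    that is required to compute the leverage x0'(X'X)^-1 x0 of a new
    predictor row.
    """

    predictor_labels: tuple[str, ...]
    coefficients: np.ndarray
    residual_scale: float
    design_information: np.ndarray
    n_observations: int
    degrees_of_freedom: int
    pearson_r: float | None = None
    residuals: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.residual_scale < 0:
            raise ValueError("residual_scale must be non-negative")
        if self.degrees_of_freedom < 1:
            raise ValueError("degrees_of_freedom must be at least 1")
        k = len(self.predictor_labels) + 1
        if len(self.coefficients) != k:
            raise ValueError("coefficients must be intercept plus one slope per predictor")
        if self.design_information.shape != (k, k):
            raise ValueError("design_information must be (p+1) x (p+1)")

    @classmethod
    def from_coefficients(
        cls,
        predictor_labels: tuple[str, ...] | list[str],
        coefficients,
        residual_scale: float = 0.0,
        degrees_of_freedom: int = 1000,
        design_information: np.ndarray | None = None,
    ) -> "LinearModelFit":
        """Build a fit directly from known coefficients.

        Useful for deterministic fixtures: with ``residual_scale=0`` and a
        zero ``design_information`` the predictive law degenerates to a
        point mass and exceedance probabilities become 0/1 step functions.
        """
        labels = tuple(predictor_labels)
        k = len(labels) + 1
        if design_information is None:
            design_information = np.zeros((k, k))
        return cls(
            predictor_labels=labels,
            coefficients=np.asarray(coefficients, dtype=float),
            residual_scale=float(residual_scale),
            design_information=np.asarray(design_information, dtype=float),
            n_observations=degrees_of_freedom + k,
            degrees_of_freedom=degrees_of_freedom,
        )


@dataclass(frozen=True)
class ExceedanceResult:
    """Probability that a cumulative dose exceeds a threshold.

    ``point_prediction`` and ``prediction_se`` are on the new-observation
    scale (Gy); ``t_statistic`` is the distance from the remaining safety
    margin to the prediction in prediction-SE units, and
    ``probability_exceed`` its upper-tail Student-t probability.
    """

    point_prediction: float
    prediction_se: float
    t_statistic: float
    probability_exceed: float
    threshold: float
    known_cumulative: float


def _check_full_rank(design: np.ndarray, labels: list[str]) -> None:
    """Raise on rank deficiency, naming the first redundant column."""
    sv = np.linalg.svd(design, compute_uv=False)
    if sv[-1] > RANK_TOLERANCE * sv[0]:
        return
    # walk columns left to right and name the first one that adds no rank
    for j in range(1, design.shape[1]):
        sub = design[:, : j + 1]
        s = np.linalg.svd(sub, compute_uv=False)
        if s[-1] <= RANK_TOLERANCE * s[0]:
            raise ValueError(
                f"design matrix is rank deficient: column {labels[j]!r} is "
                "collinear with the preceding columns"
            )
    raise ValueError("design matrix is rank deficient")


def fit_linear(predictors, response) -> LinearModelFit:
    """Ordinary least squares of a dose response on earlier-cycle doses.

    Parameters
    ----------
    predictors
        A DataFrame (column names become predictor labels) or 2-D array of
        shape (n, p).
    response
        Length-n vector of response doses (Gy).

    Returns
    -------
    LinearModelFit
        With ``residual_scale = sqrt(RSS / (n - p - 1))`` and the exact
        (X'X)^-1 of the intercept-augmented design.
    """
    if isinstance(predictors, pd.DataFrame):
        labels = [str(c) for c in predictors.columns]
        X = predictors.to_numpy(dtype=float)
    else:
        X = np.asarray(predictors, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        labels = [f"x{i + 1}" for i in range(X.shape[1])]
    y = np.asarray(response, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("predictors and response have different lengths")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")
    n, p = X.shape
    if n < p + 3:
        raise ValueError(f"need at least {p + 3} rows to fit {p + 1} coefficients")

    design = np.column_stack([np.ones(n), X])
    _check_full_rank(design, ["intercept"] + labels)

    res = sm.OLS(y, design).fit()
    df = n - p - 1
    s = float(np.sqrt(res.ssr / df))
    r = None
    if p == 1:
        r = pearson_correlation(res.fittedvalues, y)
    return LinearModelFit(
        predictor_labels=tuple(labels),
        coefficients=np.asarray(res.params, dtype=float),
        residual_scale=s,
        design_information=np.linalg.inv(design.T @ design),
        n_observations=n,
        degrees_of_freedom=df,
        pearson_r=r,
        residuals=np.asarray(res.resid, dtype=float),
    )


def fit_reference_models(cohort) -> dict[str, LinearModelFit]:
    """Fit the four planning regressions from a cohort of patient records.

    ``simple`` and ``joint34`` and ``d4`` use four-cycle completers;
    ``d3`` uses every patient with at least three cycles.  Each fit is
    skipped (absent from the result) when too few patients qualify.
    """
    completers = [r.doses for r in cohort if len(r.doses) == 4]
    at_least_3 = [r.doses for r in cohort if len(r.doses) >= 3]
    fits: dict[str, LinearModelFit] = {}
    if len(completers) >= 5:
        d = np.asarray(completers)
        fits["simple"] = fit_linear(
            pd.DataFrame({"D1": d[:, 0]}), d[:, 1] + d[:, 2] + d[:, 3]
        )
        fits["joint34"] = fit_linear(
            pd.DataFrame({"D1": d[:, 0], "D2": d[:, 1]}), d[:, 2] + d[:, 3]
        )
        fits["d4"] = fit_linear(
            pd.DataFrame({"D1": d[:, 0], "D2": d[:, 1], "D3": d[:, 2]}), d[:, 3]
        )
    if len(at_least_3) >= 5:
        d = np.asarray([t[:3] for t in at_least_3])
        fits["d3"] = fit_linear(pd.DataFrame({"D1": d[:, 0], "D2": d[:, 1]}), d[:, 2])
    return fits


def predict_new_observation(fit: LinearModelFit, x0) -> tuple[float, float]:
    """Point prediction and new-single-observation standard error at ``x0``.

    The returned SE is ``s * sqrt(1 + leverage)`` — the scale of the error
    made when predicting one new response, not the (smaller) SE of the
    fitted mean.
    """
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    if x0.shape != (len(fit.predictor_labels),):
        raise ValueError(
            f"x0 must have {len(fit.predictor_labels)} entries "
            f"({', '.join(fit.predictor_labels)})"
        )
    row = np.concatenate([[1.0], x0])
    point = float(row @ fit.coefficients)
    leverage = float(row @ fit.design_information @ row)
    se = fit.residual_scale * float(np.sqrt(1.0 + leverage))
    return point, se


def exceedance_probability(
    fit: LinearModelFit,
    x0,
    known_cumulative: float,
    threshold: float,
) -> ExceedanceResult:
    """Probability that known dose plus the predicted remainder exceeds ``threshold``.

    The margin still available is ``threshold - known_cumulative``; the new
    response falls above it with upper-tail Student-t probability at
    ``t = (margin - point_prediction) / prediction_se`` on the fit's
    residual degrees of freedom.  A zero prediction SE (noiseless fixture)
    degenerates to a step function, with probability 0.5 exactly at the
    margin.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if known_cumulative < 0:
        raise ValueError("known_cumulative must be non-negative")
    point, se = predict_new_observation(fit, x0)
    margin = threshold - known_cumulative
    if se == 0.0:
        if point > margin:
            t, p = -np.inf, 1.0
        elif point < margin:
            t, p = np.inf, 0.0
        else:
            t, p = 0.0, 0.5
    else:
        t = (margin - point) / se
        p = float(stats.t.sf(t, fit.degrees_of_freedom))
    return ExceedanceResult(
        point_prediction=point,
        prediction_se=se,
        t_statistic=float(t),
        probability_exceed=float(p),
        threshold=float(threshold),
        known_cumulative=float(known_cumulative),
    )


def lilliefors_normality(residuals) -> float:
    """Lilliefors (KS with estimated mean and sd) p-value for normality."""
    x = np.asarray(residuals, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 residuals for the Lilliefors test")
    if np.std(x) == 0:
        raise ValueError("residuals have zero variance; normality test is degenerate")
    return float(lilliefors(x, dist="norm", pvalmethod="table")[1])


def runs_test_independence(residuals) -> float:
    """Wald-Wolfowitz runs-test p-value for serial independence.

    Residuals are centred at their median; values exactly on the median are
    dropped.  Two-sided p from the normal approximation to the runs count,
    with continuity correction.
    """
    x = np.asarray(residuals, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 residuals for the runs test")
    centred = x - np.median(x)
    centred = centred[centred != 0]
    if centred.size == 0 or (centred > 0).all() or (centred < 0).all():
        raise ValueError("runs test needs values on both sides of the median")
    _, p = runstest_1samp(centred, cutoff=0, correction=True)
    return float(p)


def pearson_correlation(x, y) -> float:
    """Pearson product-moment correlation of two dose series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length of at least 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y)[0])
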