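"""Per-symptom detrending: LASSO selection of temporal predictors, OLS refit.

The second analysis approach models each symptom series, person by person,
as a function of the seven temporal basis columns.  An L1-penalized
regression first decides which temporal terms carry signal (coefficients
shrunk to zero are dropped); an unpenalized least-squares refit on the
retained terms then yields the reported R^2 and the residual series, which
is treated as the stationary variation entering the residual network.

When no predictor survives selection the symptom's R^2 is recorded as
0.00 and its residuals are simply the centered series — a distinct state
from "not endorsed", which never enters the models at all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LassoCV, LassoLarsIC
from sklearn.model_selection import KFold

from .ema_data import EmaDataset
from .temporal_basis import TemporalBasis

__all__ = [
    "DetrendConfig",
    "DetrendResult",
    "VarianceExplainedTable",
    "select_temporal_predictors",
    "refit_ols",
    "detrend_person",
]

#: Sentinel cell states for the variance-explained grid.
NOT_ENDORSED = "not_endorsed"
NO_PREDICTORS = "no_predictors"


@dataclass(frozen=True)
class DetrendConfig:
    cv_folds: int = 10
    seed: int = 0
    n_alphas: int = 100
    cv_scheme: str = "shuffle"  # "shuffle" | "blocks" (contiguous, autocorrelation-robust)
    min_obs: int = 10


@dataclass
class DetrendResult:
    """Selection + refit summary for one symptom series."""

    symptom: str
    retained: tuple[str, ...]
    beta: dict[str, float]  # retained columns + "intercept", OLS scale
    r_squared: float
    residuals: np.ndarray
    lasso_lambda: float
    n_obs: int

    def to_dict(self) -> dict:
        return {
            "symptom": self.symptom,
            "retained": list(self.retained),
            "beta": self.beta,
            "r_squared": self.r_squared,
            "lasso_lambda": self.lasso_lambda,
            "n_obs": self.n_obs,
        }


def select_temporal_predictors(
    y: np.ndarray,
    basis: TemporalBasis,
    cv_folds: int = 10,
    seed: int = 0,
    n_alphas: int = 100,
    cv_scheme: str = "shuffle",
) -> tuple[tuple[str, ...], float]:
    """Choose temporal basis columns by cross-validated LASSO.

    Minimizes ``(1/2n)||y - Xb||^2 + lambda ||b||_1`` over a log-spaced
    lambda path, with lambda picked at the k-fold cross-validation
    minimum (folds from a seeded shuffle, or contiguous blocks when
    ``cv_scheme="blocks"``).  ``y`` and ``X`` are standardized internally
    so the penalty treats all columns comparably.

    Returns the retained column labels and the selected lambda (on the
    standardized-y scale).  Falls back to BIC selection with a warning if
    cross-validation is degenerate (e.g. too few rows for the folds).
    """
    if not basis.standardized:
        raise ValueError("basis must be standardized before selection")
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("y must be complete-case before selection")
    n = y.size
    if n < 10:
        raise ValueError(f"need >= 10 observations, got {n}")
    sd = y.std(ddof=0)
    if sd < 1e-12:
        raise ValueError("zero-variance series should have been screened out")
    ys = (y - y.mean()) / sd
    X = basis.X

    if n >= 2 * cv_folds:
        shuffle = cv_scheme == "shuffle"
        cv = KFold(
            n_splits=cv_folds, shuffle=shuffle, random_state=seed if shuffle else None
        )
        model = LassoCV(cv=cv, alphas=n_alphas, max_iter=50_000)
        model.fit(X, ys)
        coef, lam = model.coef_, float(model.alpha_)
    else:
        warnings.warn(
            f"n={n} too small for {cv_folds}-fold CV; falling back to BIC selection",
            stacklevel=2,
        )
        model = LassoLarsIC(criterion="bic")
        model.fit(X, ys)
        coef, lam = model.coef_, float(model.alpha_)

    retained = tuple(c for c, b in zip(basis.columns, coef) if b != 0.0)
    return retained, lam


def refit_ols(y: np.ndarray, basis: TemporalBasis, retained, symptom: str = "",
              lasso_lambda: float = float("nan")) -> DetrendResult:
    """Unpenalized least-squares refit on the retained columns.

    With an empty retained set only the intercept is fit: R^2 is recorded
    as 0.0 and the residuals equal the centered series.  Linearly
    redundant retained columns are dropped with a warning; a design that
    stays rank-deficient raises.
    """
    y = np.asarray(y, dtype=float)
    retained = tuple(retained)
    n = y.size
    if not retained:
        resid = y - y.mean()
        return DetrendResult(
            symptom=symptom,
            retained=(),
            beta={"intercept": float(y.mean())},
            r_squared=0.0,
            residuals=resid,
            lasso_lambda=lasso_lambda,
            n_obs=n,
        )

    cols = list(retained)
    Xr = np.column_stack([basis.column(c) for c in cols])
    # greedy drop of columns that do not increase design rank
    keep: list[int] = []
    for j in range(Xr.shape[1]):
        trial = keep + [j]
        if np.linalg.matrix_rank(Xr[:, trial]) == len(trial):
            keep.append(j)
    if len(keep) < len(cols):
        dropped = [cols[j] for j in range(len(cols)) if j not in keep]
        warnings.warn(f"dropping linearly redundant column(s): {dropped}", stacklevel=2)
        cols = [cols[j] for j in keep]
        Xr = Xr[:, keep]
    design = np.column_stack([np.ones(n), Xr])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError(f"rank-deficient design for columns {cols}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    resid = y - fitted
    sst = float(np.sum((y - y.mean()) ** 2))
    ssr = float(np.sum(resid**2))
    r2 = 1.0 - ssr / sst if sst > 0 else 0.0
    coefs = {"intercept": float(beta[0])}
    coefs.update({c: float(b) for c, b in zip(cols, beta[1:])})
    return DetrendResult(
        symptom=symptom,
        retained=tuple(cols),
        beta=coefs,
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        residuals=resid,
        lasso_lambda=lasso_lambda,
        n_obs=n,
    )


def detrend_symptom(
    y: np.ndarray,
    basis: TemporalBasis,
    config: DetrendConfig = DetrendConfig(),
    symptom: str = "",
) -> DetrendResult:
    """LASSO selection followed by OLS refit for one series."""
    retained, lam = select_temporal_predictors(
        y,
        basis,
        cv_folds=config.cv_folds,
        seed=config.seed,
        n_alphas=config.n_alphas,
        cv_scheme=config.cv_scheme,
    )
    return refit_ols(y, basis, retained, symptom=symptom, lasso_lambda=lam)


def detrend_person(
    ds: EmaDataset,
    basis: TemporalBasis,
    config: DetrendConfig = DetrendConfig(),
    all_symptoms=None,
) -> tuple[list[DetrendResult], dict[str, float | str]]:
    """Detrend every symptom of an endorsement-screened, complete-case dataset.

    ``ds`` must already be restricted to endorsed symptoms and complete
    rows, with ``basis`` built on the same timestamps and standardized.
    Returns one :class:`DetrendResult` per endorsed symptom plus a
    variance-explained column over ``all_symptoms`` (default: the full
    analysis schema) in which screened-out symptoms appear as
    ``NOT_ENDORSED`` and empty retained sets as 0.0.
    """
    if basis.X.shape[0] != ds.n_obs:
        raise ValueError("basis rows must align with dataset rows")
    all_symptoms = tuple(all_symptoms) if all_symptoms is not None else ds.schema.analysis_items
    results: list[DetrendResult] = []
    column: dict[str, float | str] = {s: NOT_ENDORSED for s in all_symptoms}
    for j, s in enumerate(ds.symptoms):
        try:
            res = detrend_symptom(ds.Y[:, j], basis, config, symptom=s)
        except Exception as exc:  # tag failures with the symptom label
            raise type(exc)(f"[{s}] {exc}") from exc
        results.append(res)
        column[s] = res.r_squared
    return results, column


@dataclass
class VarianceExplainedTable:
    """Symptoms x persons grid of temporal variance explained.

    Cells hold the post-selection R^2, 0.0 when no predictor was retained
    (rendered "0.00"), or NaN when the symptom was not endorsed (rendered
    with an en-dash).  Row/column means exclude not-endorsed cells while
    no-predictor cells contribute 0.
    """

    values: pd.DataFrame  # float; NaN = not endorsed

    @classmethod
    def from_columns(cls, columns: dict[str, dict[str, float | str]],
                     symptoms=None) -> "VarianceExplainedTable":
        persons = list(columns)
        symptoms = list(symptoms) if symptoms is not None else list(
            next(iter(columns.values()))
        )
        data = np.full((len(symptoms), len(persons)), np.nan)
        for k, p in enumerate(persons):
            for i, s in enumerate(symptoms):
                cell = columns[p].get(s, NOT_ENDORSED)
                if cell != NOT_ENDORSED:
                    data[i, k] = float(cell)
        return cls(values=pd.DataFrame(data, index=symptoms, columns=persons))

    def row_means(self) -> pd.Series:
        return self.values.mean(axis=1, skipna=True)

    def column_means(self) -> pd.Series:
        return self.values.mean(axis=0, skipna=True)

    def render(self, dash: str = "–") -> pd.DataFrame:
        """Format with two decimals, the dash marking not-endorsed, plus
        an ``Avg.`` row and column."""
        body = self.values.map(lambda v: dash if np.isnan(v) else f"{v:.2f}")
        body["Avg."] = self.row_means().map(
            lambda v: dash if np.isnan(v) else f"{v:.2f}"
        )
        avg_row = self.column_means().map(lambda v: f"{v:.2f}")
        avg_row["Avg."] = f"{np.nanmean(self.values.to_numpy()):.2f}"
        body.loc["Avg."] = avg_row
        return body

    def to_csv(self, path, dash: str = "–") -> None:
        out = self.render(dash=dash)
        out.index.name = "symptom"
        out.to_csv(path)
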