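"""Ordinary-least-squares affinity models and their validation statistics.

The response is log10(K_i/nM); predictors are the five LED-derived energy
descriptors. Three named models are conventional:

* M1 — intercept + binding energy (1 parameter),
* M2 — intercept + the four LED components (4 parameters),
* M3 — intercept + all five descriptors (5 parameters).

Fit quality is summarized by the fraction of the total sum of squares about
the mean recovered by the model, %SSQ = 100·(1 − SSQ_residual/SSQ_data), by
MSE = SSQ_residual/N, and by per-complex residuals e = observed − predicted.
Predictivity is assessed with leave-one-out cross-validation:
Q² = 1 − PRESS/SSQ_data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dataset import AffinityDataset, PREDICTOR_COLUMNS
from .errors import (
    FoldSingularityError,
    InsufficientDataError,
    SingularDesignError,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelSpec:
    """Predictor subset for an OLS model (intercept always included)."""

    predictors: tuple[str, ...]
    intercept: bool = True

    def __post_init__(self) -> None:
        if not self.predictors:
            raise ValueError("a model needs at least one predictor")
        unknown = [p for p in self.predictors if p not in PREDICTOR_COLUMNS]
        if unknown:
            raise ValueError(
                f"unknown predictor(s) {', '.join(unknown)}; "
                f"choose from {', '.join(PREDICTOR_COLUMNS)}"
            )

    @property
    def n_parameters(self) -> int:
        """Number of predictor variables (the intercept is not counted)."""
        return len(self.predictors)

    @property
    def n_coefficients(self) -> int:
        return len(self.predictors) + int(self.intercept)

    @classmethod
    def m1(cls) -> "ModelSpec":
        return cls(("binding_energy",))

    @classmethod
    def m2(cls) -> "ModelSpec":
        return cls(("e_elstat", "e_exch", "e_ct", "e_disp"))

    @classmethod
    def m3(cls) -> "ModelSpec":
        return cls(PREDICTOR_COLUMNS)

    @classmethod
    def named(cls, name: str) -> "ModelSpec":
        try:
            return {"m1": cls.m1, "m2": cls.m2, "m3": cls.m3}[name.lower()]()
        except KeyError:
            raise ValueError(f"unknown model name {name!r}; expected m1, m2 or m3")


@dataclass(frozen=True)
class FitResult:
    """An OLS fit with the fit-quality statistics of the model suite."""

    spec: ModelSpec
    coefficients: pd.Series  # index: 'intercept' + predictor names
    predicted: pd.Series  # index: complex_id
    residuals: pd.Series  # observed − predicted, index: complex_id
    ssq_data: float
    ssq_residual: float
    pct_recovered: float
    mse: float
    p_values: pd.Series
    n_data: int
    n_parameters: int

    @property
    def max_abs_residual(self) -> float:
        return float(self.residuals.abs().max())


@dataclass(frozen=True)
class LooResult:
    """Leave-one-out cross-validation of one model."""

    spec: ModelSpec
    table: pd.DataFrame  # complex_id, observed, predicted, sq_error
    press: float
    ssq_data: float
    q2: float


@dataclass(frozen=True)
class SelectionStep:
    action: str  # 'add' | 'drop' | 'stop'
    variable: str | None
    p_value: float | None
    model: tuple[str, ...]


@dataclass(frozen=True)
class SelectionTrace:
    direction: str
    alpha: float
    steps: tuple[SelectionStep, ...]
    selected: tuple[str, ...]


@dataclass(frozen=True)
class ScreenReport:
    """Per-left-out-point fit quality, for detecting incommensurate points."""

    table: pd.DataFrame  # left_out, pct_recovered, max_abs_residual
    margin: float
    flagged: tuple[str, ...]


def _design(dataset: AffinityDataset, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray, list[str]]:
    frame = dataset.to_frame()
    X = frame[list(spec.predictors)].to_numpy(dtype=float)
    if spec.intercept:
        X = np.column_stack([np.ones(len(frame)), X])
    y = frame["log_ki"].to_numpy(dtype=float)
    return X, y, list(frame["complex_id"])


def _check_rank(X: np.ndarray, context: str = "design") -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError(f"{context} matrix is rank deficient")


def fit_mlr(dataset: AffinityDataset, spec: ModelSpec) -> FitResult:
    """Exact OLS fit of log(K_i) on the chosen descriptors.

    Requires strictly more data points than coefficients (residual dof ≥ 1)
    and a full-rank design.
    """
    X, y, ids = _design(dataset, spec)
    n, k = X.shape
    if n <= k:
        raise InsufficientDataError(
            f"{n} data points cannot support {k} coefficients (need n > {k})"
        )
    _check_rank(X)
    model = sm.OLS(y, X).fit()
    names = (["intercept"] if spec.intercept else []) + list(spec.predictors)
    predicted = pd.Series(model.fittedvalues, index=ids, name="predicted")
    residuals = pd.Series(y - model.fittedvalues, index=ids, name="residual")
    ssq_data = float(np.sum((y - y.mean()) ** 2))
    ssq_residual = float(model.ssr)
    return FitResult(
        spec=spec,
        coefficients=pd.Series(model.params, index=names),
        predicted=predicted,
        residuals=residuals,
        ssq_data=ssq_data,
        ssq_residual=ssq_residual,
        pct_recovered=100.0 * (1.0 - ssq_residual / ssq_data),
        mse=ssq_residual / n,
        p_values=pd.Series(model.pvalues, index=names),
        n_data=n,
        n_parameters=spec.n_parameters,
    )


def _solve_fold(X: np.ndarray, y: np.ndarray, fold_id: str) -> np.ndarray:
    # Square training systems (n−1 = n_coefficients) are legitimate in LOO.
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FoldSingularityError(
            f"training design is singular when holding out {fold_id!r}"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def loo_cv(dataset: AffinityDataset, spec: ModelSpec) -> LooResult:
    """Leave-one-out cross-validation by explicit per-fold refits.

    PRESS is the sum of squared held-out prediction errors and
    Q² = 1 − PRESS/SSQ_data, with SSQ_data taken over all n points about the
    all-n mean.
    """
    X, y, ids = _design(dataset, spec)
    n, k = X.shape
    if n - 1 < k:
        raise InsufficientDataError(
            f"leave-one-out needs at least {k + 1} points for {k} coefficients"
        )
    rows = []
    for i in range(n):
        mask = np.arange(n) != i
        beta = _solve_fold(X[mask], y[mask], ids[i])
        pred = float(X[i] @ beta)
        rows.append(
            {
                "complex_id": ids[i],
                "observed": y[i],
                "predicted": pred,
                "sq_error": (y[i] - pred) ** 2,
            }
        )
    table = pd.DataFrame(rows)
    press = float(table["sq_error"].sum())
    ssq_data = float(np.sum((y - y.mean()) ** 2))
    return LooResult(
        spec=spec, table=table, press=press, ssq_data=ssq_data,
        q2=1.0 - press / ssq_data,
    )


def q2_with_exclusion(
    loo: LooResult, dataset: AffinityDataset, excluded_ids: Iterable[str]
) -> float:
    """Q² with some complexes' contributions removed from both PRESS and SSQ.

    The excluded folds' squared errors are dropped from PRESS and the total
    SSQ is recomputed over the remaining points about their own mean. The
    folds themselves are not refitted.
    """
    excluded = set(excluded_ids)
    unknown = excluded - set(dataset.complex_ids)
    if unknown:
        raise KeyError(f"excluded ids not in dataset: {', '.join(sorted(unknown))}")
    keep = loo.table[~loo.table["complex_id"].isin(excluded)]
    if keep.empty:
        raise ValueError("cannot exclude every data point")
    press = float(keep["sq_error"].sum())
    y = keep["observed"].to_numpy()
    ssq = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / ssq


def variable_selection(
    dataset: AffinityDataset,
    candidates: Sequence[str] = PREDICTOR_COLUMNS,
    direction: str = "forward",
    alpha: float = 0.05,
) -> SelectionTrace:
    """Stepwise p-value-driven variable selection.

    Forward: repeatedly add the candidate with the smallest coefficient
    p-value, as long as it is below ``alpha``. Backward: start from the full
    candidate set and repeatedly drop the predictor with the largest
    p-value at or above ``alpha``. An empty final model is a legal outcome.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if direction not in ("forward", "backward"):
        raise ValueError(f"direction must be 'forward' or 'backward', got {direction!r}")
    steps: list[SelectionStep] = []
    if direction == "forward":
        selected: list[str] = []
        remaining = list(candidates)
        while remaining:
            best: tuple[str, float] | None = None
            for cand in remaining:
                fit = fit_mlr(dataset, ModelSpec(tuple(selected + [cand])))
                p = float(fit.p_values[cand])
                if best is None or p < best[1]:
                    best = (cand, p)
            assert best is not None
            if best[1] < alpha:
                selected.append(best[0])
                remaining.remove(best[0])
                steps.append(SelectionStep("add", best[0], best[1], tuple(selected)))
            else:
                steps.append(SelectionStep("stop", best[0], best[1], tuple(selected)))
                break
        return SelectionTrace("forward", alpha, tuple(steps), tuple(selected))

    selected = list(candidates)
    while selected:
        fit = fit_mlr(dataset, ModelSpec(tuple(selected)))
        slope_p = fit.p_values.drop("intercept")
        worst = slope_p.idxmax()
        p = float(slope_p[worst])
        if p >= alpha:
            selected.remove(worst)
            steps.append(SelectionStep("drop", worst, p, tuple(selected)))
        else:
            steps.append(SelectionStep("stop", worst, p, tuple(selected)))
            break
    return SelectionTrace("backward", alpha, tuple(steps), tuple(selected))


def exclusion_scan(dataset: AffinityDataset, spec: ModelSpec) -> pd.DataFrame:
    """Refit the model without each predictor in turn.

    Reports, per excluded variable, the drop in %SSQ recovered relative to
    the full model and the largest absolute residual of the reduced fit.
    """
    if spec.n_parameters < 2:
        raise ValueError("exclusion scan needs a model with at least 2 predictors")
    full = fit_mlr(dataset, spec)
    rows = []
    for var in spec.predictors:
        reduced_spec = ModelSpec(tuple(p for p in spec.predictors if p != var))
        reduced = fit_mlr(dataset, reduced_spec)
        rows.append(
            {
                "excluded": var,
                "pct_recovered": reduced.pct_recovered,
                "pct_drop": full.pct_recovered - reduced.pct_recovered,
                "max_abs_residual": reduced.max_abs_residual,
            }
        )
    return pd.DataFrame(rows)


def commensurability_screen(
    dataset: AffinityDataset, spec: ModelSpec, margin: float = 10.0
) -> ScreenReport:
    """Fit n models, each excluding one point, to detect incompatible points.

    A point is flagged as an outlier when the fit quality without it exceeds
    the median sub-fit %SSQ recovered by more than ``margin`` percentage
    points — i.e. the remaining points agree with each other far better than
    with it.
    """
    n = len(dataset)
    if n < spec.n_coefficients + 2:
        raise InsufficientDataError(
            f"screen needs at least {spec.n_coefficients + 2} points "
            f"for {spec.n_coefficients} coefficients"
        )
    rows = []
    for cid in dataset.complex_ids:
        sub = fit_mlr(dataset.drop([cid]), spec)
        rows.append(
            {
                "left_out": cid,
                "pct_recovered": sub.pct_recovered,
                "max_abs_residual": sub.max_abs_residual,
            }
        )
    table = pd.DataFrame(rows)
    median = float(table["pct_recovered"].median())
    flagged = tuple(
        table.loc[table["pct_recovered"] > median + margin, "left_out"]
    )
    for cid in flagged:
        logger.info(
            "commensurability screen flags %s (sub-fit %%SSQ %.1f vs median %.1f)",
            cid,
            float(table.loc[table["left_out"] == cid, "pct_recovered"].iloc[0]),
            median,
        )
    return ScreenReport(table=table, margin=margin, flagged=flagged)


def led_fraction_table(dataset: AffinityDataset) -> pd.DataFrame:
    """Per-complex fractions E_x/binding energy, with a max−min range row.

    The four fractions characterize the interaction type mix of each complex
    independently of its overall binding strength.
    """
    rows = []
    for r in dataset:
        be = r.components.binding_energy
        if be == 0:
            raise ZeroDivisionError(
                f"binding energy of {r.complex_id} is zero; fractions undefined"
            )
        rows.append(
            {
                "complex_id": r.complex_id,
                "ligand": r.ligand,
                "f_elstat": r.components.e_elstat / be,
                "f_exch": r.components.e_exch / be,
                "f_ct": r.components.e_ct / be,
                "f_disp": r.components.e_disp / be,
            }
        )
    table = pd.DataFrame(rows)
    fractions = table[["f_elstat", "f_exch", "f_ct", "f_disp"]]
    range_row = {
        "complex_id": "range",
        "ligand": "",
        **(fractions.max() - fractions.min()).to_dict(),
    }
    return pd.concat([table, pd.DataFrame([range_row])], ignore_index=True)
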