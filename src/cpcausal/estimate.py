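"""Statistical layer: partial-correlation tests, effect sizes, prediction, CV.

The causal quantities reported are ordinary least-squares coefficients whose
covariate sets come from the graph:

* **total effect** — OLS of the outcome on the exposure plus its chosen
  minimal adjustment set, on the standardized/oriented table; the exposure
  coefficient is the standardized total effect.
* **direct effect** — controlled direct effect under linearity: OLS of the
  outcome on the exposure plus all *other* observed direct causes of the
  outcome.
* **bivariate effect** — OLS on the exposure alone; the non-causal
  association a naive analysis would report, kept for contrast.

Model plausibility is tested through its implied conditional independencies:
each is a partial correlation that must be statistically indistinguishable
from zero (Fisher z test, two-sided, no multiplicity correction — each
statement is a separate claim about the model).

The predictive model is deliberately *not* causal: it regresses the raw
outcome on all observed predictors in per-unit form, including torsions that
carry no direct causal edge, because prediction may exploit any association.
Its out-of-sample performance is measured by k-fold cross-validation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data import VariableTable, standardize_and_orient, to_predictive_units
from .errors import EstimationError
from .identify import CIStatement, adjustment_sets
from .model import ModelConfig

__all__ = [
    "CITestResult",
    "EffectEstimate",
    "PredictiveModel",
    "CVReport",
    "partial_correlation",
    "fisher_z_test",
    "test_implied_independencies",
    "estimate_effect",
    "effect_table",
    "predictive_model",
    "cross_validate",
]

log = logging.getLogger(__name__)

Z95 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass
class CITestResult:
    statement: CIStatement
    r: float
    p: float
    n: int
    alpha: float
    rejected: bool

    def to_dict(self) -> dict:
        return {
            "statement": self.statement.to_dict(),
            "r": self.r, "p": self.p, "n": self.n,
            "alpha": self.alpha, "rejected": self.rejected,
        }


@dataclass
class EffectEstimate:
    """One exposure's effect on the outcome, with its provenance."""

    exposure: str
    effect_type: str  # "total" | "direct" | "bivariate"
    beta: float
    se: float
    ci95: tuple[float, float]
    adjustment: frozenset[str] = frozenset()

    def to_dict(self) -> dict:
        return {
            "exposure": self.exposure, "effect_type": self.effect_type,
            "beta": self.beta, "se": self.se,
            "ci95": list(self.ci95), "adjustment": sorted(self.adjustment),
        }


@dataclass
class PredictiveModel:
    """Per-unit OLS of the outcome on all observed predictors."""

    intercept: float
    beta: pd.Series
    se: pd.Series
    p: pd.Series
    outcome: str

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        x = df[list(self.beta.index)].to_numpy(dtype=float)
        return self.intercept + x @ self.beta.to_numpy()

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "intercept": self.intercept,
            "coefficients": {
                v: {"beta": float(self.beta[v]), "se": float(self.se[v]),
                    "p": float(self.p[v])}
                for v in self.beta.index
            },
        }


@dataclass
class CVReport:
    k: int
    seed: int
    r2_oos: float
    mae: float
    predictions: pd.DataFrame = field(repr=False)  # y_true, y_pred, fold

    def to_dict(self, include_predictions: bool = False) -> dict:
        out = {"k": self.k, "seed": self.seed,
               "r2_oos": self.r2_oos, "mae": self.mae}
        if include_predictions:
            out["predictions"] = self.predictions.to_dict(orient="list")
        return out


# ---------------------------------------------------------------------------
# conditional-independence testing


def _design(table: VariableTable, z: Iterable[str]) -> np.ndarray:
    cols = sorted(z)
    x = np.column_stack(
        [np.ones(table.n)] + [table[c].to_numpy(dtype=float) for c in cols]
    )
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise EstimationError(
            f"rank-deficient conditioning design over {cols}"
        )
    return x


def partial_correlation(
    table: VariableTable, x: str, y: str, z: Iterable[str] = ()
) -> float:
    """Pearson correlation of x and y after projecting out z (with intercept).

    With empty ``z`` this is the plain Pearson r.  Scale- and sign-invariant
    up to orientation, so it may be computed on raw or standardized tables.
    """
    z = set(z)
    if x in z or y in z:
        raise EstimationError("conditioning set must exclude x and y")
    if table.n <= len(z) + 3:
        raise EstimationError(
            f"n={table.n} too small for |z|={len(z)} conditioning variables"
        )
    d = _design(table, z)
    coef, *_ = np.linalg.lstsq(
        d, np.column_stack([table[x], table[y]]), rcond=None
    )
    res = np.column_stack([table[x], table[y]]) - d @ coef
    rx, ry = res[:, 0], res[:, 1]
    denom = np.linalg.norm(rx) * np.linalg.norm(ry)
    if denom == 0:
        raise EstimationError("zero residual variance in partial correlation")
    return float(np.clip(rx @ ry / denom, -1.0, 1.0))


def fisher_z_test(r: float, n: int, k: int = 0) -> float:
    """Two-sided p-value for a (partial) correlation via Fisher's z.

    ``z = atanh(r) * sqrt(n - k - 3)`` referred to the standard normal,
    where ``k`` is the size of the conditioning set.  A degenerate |r| = 1
    returns p = 0 with a warning rather than an error.
    """
    if n - k - 3 <= 0:
        raise EstimationError(f"n - k - 3 must be positive (n={n}, k={k})")
    if abs(r) >= 1.0:
        warnings.warn("degenerate |r| = 1; returning p = 0", stacklevel=2)
        return 0.0
    z = np.arctanh(r) * np.sqrt(n - k - 3)
    return float(2.0 * stats.norm.sf(abs(z)))


def test_implied_independencies(
    table: VariableTable,
    statements: Iterable[CIStatement],
    alpha: float = 0.05,
) -> list[CITestResult]:
    """Run every implied-independence test at level ``alpha``.

    No multiple-comparison adjustment is applied: each statement is an
    individual falsifiable claim of the model, and correcting would only
    make the plausibility check easier to pass.
    """
    if table.state != "standardized":
        raise EstimationError(
            "implied-independence tests expect the standardized/oriented table"
        )
    out = []
    for s in statements:
        try:
            r = partial_correlation(table, s.x, s.y, s.given)
            p = fisher_z_test(r, table.n, len(s.given))
        except EstimationError as err:
            raise EstimationError(f"while testing {s}: {err}") from err
        out.append(CITestResult(s, r, p, table.n, alpha, bool(p < alpha)))
    return out


# ---------------------------------------------------------------------------
# effect estimation


def _ols(y: np.ndarray, x: pd.DataFrame):
    design = sm.add_constant(x, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        bad = list(x.columns)
        raise EstimationError(f"collinear design over {bad}")
    return sm.OLS(y, design).fit()


def _direct_covariates(config: ModelConfig, exposure: str) -> frozenset[str]:
    g = config.graph
    obs_parents = {p for p in g.parents(config.outcome) if not g.is_latent(p)}
    return frozenset(obs_parents - {exposure})


def estimate_effect(
    table: VariableTable,
    config: ModelConfig,
    exposure: str,
    effect_type: str = "total",
) -> EffectEstimate:
    """Standardized effect of one exposure on the outcome.

    ``total`` adjusts for the graph's chosen minimal adjustment set,
    ``direct`` for the other observed direct causes of the outcome, and
    ``bivariate`` for nothing.  Main effects only; the normal 95% interval
    is ``beta +/- 1.96 se``.
    """
    if table.state != "standardized":
        raise EstimationError("effect estimation expects the standardized table")
    if effect_type == "total":
        adj = frozenset(
            adjustment_sets(config.graph, exposure, config.outcome, "total").chosen
        )
    elif effect_type == "direct":
        adj = _direct_covariates(config, exposure)
    elif effect_type == "bivariate":
        adj = frozenset()
    else:
        raise EstimationError(f"unknown effect_type {effect_type!r}")
    cols = [exposure] + sorted(adj)
    fit = _ols(table[config.outcome].to_numpy(), table.data[cols])
    beta = float(fit.params[exposure])
    se = float(fit.bse[exposure])
    return EffectEstimate(
        exposure, effect_type, beta, se, (beta - Z95 * se, beta + Z95 * se), adj
    )


def effect_table(
    table: VariableTable, config: ModelConfig
) -> tuple[list[EffectEstimate], dict[str, float], dict[str, str]]:
    """Total, direct and bivariate estimates for every candidate exposure.

    Returns ``(estimates, overestimation, failures)`` where
    ``overestimation[x] = bivariate - total`` (the inflation a naive
    bivariate analysis would report) and ``failures`` maps exposures to
    error messages instead of aborting the whole table.
    """
    estimates: list[EffectEstimate] = []
    over: dict[str, float] = {}
    failures: dict[str, str] = {}
    for exposure in config.exposures:
        row = {}
        for effect_type in ("total", "direct", "bivariate"):
            try:
                row[effect_type] = estimate_effect(
                    table, config, exposure, effect_type
                )
            except Exception as err:  # recorded, not fatal
                failures[f"{exposure}:{effect_type}"] = str(err)
                log.warning("effect %s/%s failed: %s", exposure, effect_type, err)
        estimates.extend(row.values())
        if "total" in row and "bivariate" in row:
            over[exposure] = row["bivariate"].beta - row["total"].beta
    return estimates, over, failures


# ---------------------------------------------------------------------------
# prediction


def predictive_model(
    raw: VariableTable, config: ModelConfig
) -> PredictiveModel:
    """Fit the per-unit predictive equation: outcome ~ all 12 predictors.

    Expects a raw-state table; predictors are re-expressed in predictive
    units (contractures as limitation degrees) internally, and coefficients
    are per raw unit of each predictor — no z-scoring.
    """
    t = to_predictive_units(raw, config)
    predictors = sorted(config.exposures)
    y = t[config.outcome].to_numpy(dtype=float)
    fit = _ols(y, t.data[predictors])
    return PredictiveModel(
        intercept=float(fit.params["const"]),
        beta=fit.params[predictors],
        se=fit.bse[predictors],
        p=fit.pvalues[predictors],
        outcome=config.outcome,
    )


def cross_validate(
    raw: VariableTable,
    config: ModelConfig,
    k: int = 10,
    seed: int = 0,
) -> CVReport:
    """k-fold cross-validation of the predictive model.

    Simple random fold assignment by ``seed`` (no stratification); fold
    sizes differ by at most one and every subject is predicted exactly once.
    ``r2_oos = 1 - SSE/SST`` pooled over all out-of-sample predictions
    (SST about the full-sample outcome mean); ``mae`` is in outcome points.
    """
    n = raw.n
    if k > n:
        raise EstimationError(f"k={k} folds exceed n={n} subjects")
    if k < 2:
        raise EstimationError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    y = raw[config.outcome].to_numpy(dtype=float)
    y_pred = np.full(n, np.nan)
    fold_id = np.full(n, -1)
    for i, test_idx in enumerate(folds):
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        train = VariableTable(raw.data.iloc[train_mask].reset_index(drop=True),
                              state="raw")
        fitted = predictive_model(train, config)
        test_units = to_predictive_units(
            VariableTable(raw.data.iloc[test_idx].reset_index(drop=True),
                          state="raw"),
            config,
        )
        y_pred[test_idx] = fitted.predict(test_units.data)
        fold_id[test_idx] = i
    sse = float(np.sum((y - y_pred) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    report = pd.DataFrame({"y_true": y, "y_pred": y_pred, "fold": fold_id})
    return CVReport(
        k=k, seed=seed,
        r2_oos=1.0 - sse / sst,
        mae=float(np.mean(np.abs(y - y_pred))),
        predictions=report,
    )
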