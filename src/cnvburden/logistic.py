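"""Binomial logistic regression with a likelihood-ratio (deviance) test.

Both the global burden test and the gene-set enrichment test reduce to the
same machinery: fit case status against a predictor of interest plus
covariates, drop the predictor, and refer the deviance difference to a
chi-square with as many degrees of freedom as columns dropped.  Fitting is
delegated to statsmodels GLM (binomial family, IRLS); this module adds the
degenerate-input diagnostics the pipeline needs so that separation or a
constant predictor surfaces as a flagged result instead of a silent number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["DevianceTestResult", "deviance_test"]

# |beta| beyond this on standardized-ish predictors indicates (quasi-)separation.
_SEPARATION_BETA = 15.0


@dataclass
class DevianceTestResult:
    """Outcome of a deviance test for one predictor of interest."""

    p_value: float
    deviance_diff: float
    df: int
    coef: dict[str, float]
    odds_ratio: float
    n_cases: int
    n_controls: int
    ok: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        if self.ok and not (0 < self.p_value <= 1):
            raise ValueError(f"p-value out of (0,1]: {self.p_value}")


def _flagged(note: str, n_cases: int, n_controls: int) -> DevianceTestResult:
    return DevianceTestResult(
        p_value=np.nan, deviance_diff=np.nan, df=0, coef={},
        odds_ratio=np.nan, n_cases=n_cases, n_controls=n_controls,
        ok=False, note=note,
    )


def deviance_test(
    y: np.ndarray,
    X: pd.DataFrame,
    interest: str | list[str],
) -> DevianceTestResult:
    """LR test of dropping ``interest`` column(s) from case ~ X.

    Parameters
    ----------
    y
        0/1 case status.
    X
        Design matrix WITHOUT intercept (added here); all columns numeric.
    interest
        Column(s) whose joint contribution is tested (1 df per column).
    """
    interest_cols = [interest] if isinstance(interest, str) else list(interest)
    y = np.asarray(y, dtype=float)
    n_cases = int(y.sum())
    n_controls = int(len(y) - n_cases)
    if n_cases < 2 or n_controls < 2:
        return _flagged("need >= 2 cases and >= 2 controls", n_cases, n_controls)
    for col in interest_cols:
        if X[col].nunique() <= 1:
            return _flagged(f"predictor {col!r} is constant", n_cases, n_controls)

    Xf = sm.add_constant(X.astype(float), has_constant="add")
    Xr = Xf.drop(columns=interest_cols)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = sm.GLM(y, Xf, family=sm.families.Binomial()).fit(maxiter=200)
            red = sm.GLM(y, Xr, family=sm.families.Binomial()).fit(maxiter=200)
    except Exception as exc:  # pragma: no cover - statsmodels failure path
        return _flagged(f"model fit failed: {exc}", n_cases, n_controls)

    params = full.params
    if not np.all(np.isfinite(params)) or np.any(
        np.abs(params[interest_cols]) > _SEPARATION_BETA
    ):
        return _flagged("possible complete separation", n_cases, n_controls)

    dev_diff = float(red.deviance - full.deviance)
    df = len(interest_cols)
    # Numerical noise can push the difference a hair below zero.
    p = float(stats.chi2.sf(max(dev_diff, 0.0), df)) if dev_diff > 0 else 1.0
    coef = {k: float(v) for k, v in params.items()}
    primary = interest_cols[0]
    return DevianceTestResult(
        p_value=min(max(p, np.nextafter(0, 1)), 1.0),
        deviance_diff=max(dev_diff, 0.0),
        df=df,
        coef=coef,
        odds_ratio=float(np.exp(coef[primary])),
        n_cases=n_cases,
        n_controls=n_controls,
    )
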