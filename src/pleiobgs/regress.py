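"""Ordinary-least-squares inference for degree-of-pleiotropy analyses.

Two fits are used throughout: the simple regression slope ``b`` of a
response on the degree of pleiotropy, and the partial regression
coefficients ``b'`` from the two-predictor fit of the B statistic on degree
and recombination rate, which separates the direct association of B with
pleiotropy from the shared dependence of both on local recombination.
Recombination enters the partial fit on the log10(cM/Mb) scale by default
(a switch allows the raw rate).  Degree is always a numeric covariate --
one slope per unit degree -- never a factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import (
    CollinearityError,
    DegenerateDesignError,
    InsufficientDataError,
)

__all__ = ["RegressionResult", "ols_simple", "ols_two", "degree_regressions"]


@dataclass
class RegressionResult:
    """Coefficients and fit statistics of an OLS regression.

    Arrays are ordered as ``names`` (intercept first).  ``f`` and
    ``f_pvalue`` are the overall F test with (df_model, df_resid) degrees of
    freedom; in the simple case F equals the slope's squared t statistic and
    the overall p equals the slope's two-sided p.
    """

    n: int
    names: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    r2: float
    f: float
    df_model: int
    df_resid: int
    f_pvalue: float

    def coefficient(self, name: str) -> float:
        return float(self.coef[self.names.index(name)])

    def pvalue(self, name: str) -> float:
        return float(self.p[self.names.index(name)])

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.names,
            "estimate": self.coef,
            "se": self.se,
            "t": self.t,
            "p": self.p,
        })


def _fit(y: np.ndarray, X: np.ndarray, names: tuple[str, ...]) -> RegressionResult:
    model = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    if np.ptp(y) == 0.0:
        # constant response: no variance to explain; R2 = 0 by convention
        k = X.shape[1]
        return RegressionResult(
            n=int(model.nobs), names=("intercept",) + names,
            coef=np.array([float(y[0])] + [0.0] * k),
            se=np.zeros(k + 1), t=np.zeros(k + 1), p=np.ones(k + 1),
            r2=0.0, f=0.0, df_model=int(model.df_model),
            df_resid=int(model.df_resid), f_pvalue=1.0)
    return RegressionResult(
        n=int(model.nobs),
        names=("intercept",) + names,
        coef=np.asarray(model.params, dtype=float),
        se=np.asarray(model.bse, dtype=float),
        t=np.asarray(model.tvalues, dtype=float),
        p=np.asarray(model.pvalues, dtype=float),
        r2=float(model.rsquared),
        f=float(model.fvalue),
        df_model=int(model.df_model),
        df_resid=int(model.df_resid),
        f_pvalue=float(model.f_pvalue),
    )


def ols_simple(y, x, name: str = "x") -> RegressionResult:
    """Simple linear regression of ``y`` on ``x`` with R2, F and p-values."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise DegenerateDesignError("y and x must be equal-length 1-D arrays")
    if len(y) < 3:
        raise InsufficientDataError(f"simple regression needs n >= 3, got n = {len(y)}")
    if np.ptp(x) == 0.0:
        raise DegenerateDesignError("predictor x is constant")
    return _fit(y, x[:, None], (name,))


def ols_two(y, x1, x2, names: tuple[str, str] = ("x1", "x2")) -> RegressionResult:
    """Two-predictor regression giving partial coefficients ``b'``."""
    y = np.asarray(y, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if not (y.shape == x1.shape == x2.shape) or y.ndim != 1:
        raise DegenerateDesignError("y, x1 and x2 must be equal-length 1-D arrays")
    if len(y) < 4:
        raise InsufficientDataError(f"two-predictor regression needs n >= 4, got n = {len(y)}")
    centered = np.column_stack([x1 - x1.mean(), x2 - x2.mean()])
    if np.linalg.matrix_rank(centered) < 2:
        raise CollinearityError("x2 is an affine function of x1 (rank-deficient design)")
    return _fit(y, np.column_stack([x1, x2]), tuple(names))


def degree_regressions(
    annotated: pd.DataFrame,
    rr_log: bool = True,
) -> dict:
    """The B-versus-pleiotropy inference battery on an annotated table.

    Runs, on rows with complete B/RR/degree values:

    * simple regression of B on degree (slope ``b``),
    * simple regression of the recombination covariate on degree,
    * the two-predictor fit of B on degree and recombination (``b'``).

    ``rr_log`` selects log10(RR) (default, matching the scale on which RR is
    analysed) or the raw rate as the recombination covariate.
    """
    rr_col = "log10RR" if rr_log else "RR"
    cols = ["B", "degree", rr_col]
    table = annotated
    if "complete" in table.columns:
        table = table[table["complete"]]
    table = table.dropna(subset=cols)
    n_dropped = len(annotated) - len(table)
    if len(table) < 4:
        raise InsufficientDataError(
            f"degree regressions need >= 4 complete rows, got {len(table)}")
    y = table["B"].to_numpy(dtype=float)
    d = table["degree"].to_numpy(dtype=float)
    r = table[rr_col].to_numpy(dtype=float)
    return {
        "simple_b_degree": ols_simple(y, d, name="degree"),
        "simple_rr_degree": ols_simple(r, d, name="degree"),
        "partial": ols_two(y, d, r, names=("degree", rr_col)),
        "n": int(len(table)),
        "n_dropped": int(n_dropped),
        "rr_covariate": rr_col,
    }
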