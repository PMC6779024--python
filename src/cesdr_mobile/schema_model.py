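"""Inverted-U self-schema model: latency regressed on depression severity.

The self-schema account of depression predicts that people with no
depressive symptoms and people with severe symptoms both hold an organised
(positive resp. negative) self-schema and judge self-referent symptom items
quickly, while mildly depressed people — whose schema is in transition —
respond slowly. On a plot of mean item-centered latency against total
symptom score this is an inverted U: a concave quadratic should beat a
straight line.

:class:`LatencySchemaModel` is the front door: build it from per-participant
(total score, mean centered latency) pairs and call :meth:`fit` to obtain a
:class:`SchemaTestResults` carrying both polynomial fits, the
Kolmogorov-Smirnov normality gate, the nested-model F test for the R-squared
increment, and residual diagnostics. The underlying operations are also
exposed as module functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm


@dataclass(frozen=True)
class KSNormalityResult:
    """One-sample KS test against a normal law.

    ``z`` is sqrt(n) * D, and ``p_value`` comes from the asymptotic
    Kolmogorov distribution of z (legacy SPSS one-sample KS; no Lilliefors
    correction for estimated parameters unless requested).
    """

    stat: float
    z: float
    p_value: float
    n: int
    mean: float
    sd: float


def ks_normality(
    x,
    mean: Optional[float] = None,
    sd: Optional[float] = None,
    lilliefors: bool = False,
) -> KSNormalityResult:
    """KS normality test of ``x`` against Normal(mean, sd).

    Parameters default to the sample mean and SD (ddof=1). With
    ``lilliefors=True`` the p-value instead uses the Lilliefors
    small-sample correction for estimated parameters.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 5:
        raise ValueError(f"ks_normality requires n >= 5, got n={n}")
    if mean is None:
        mean = float(np.mean(x))
    if sd is None:
        sd = float(np.std(x, ddof=1))
    if sd <= 0.0:
        raise ValueError("ks_normality undefined: zero variance")
    d = float(sps.kstest(x, "norm", args=(mean, sd)).statistic)
    z = math.sqrt(n) * d
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        _, p = _lf(x, dist="norm", pvalmethod="table")
        p = float(p)
    else:
        p = float(sps.kstwobign.sf(z))
    return KSNormalityResult(stat=d, z=z, p_value=p, n=n, mean=mean, sd=sd)


@dataclass
class ModelFit:
    """Ordinary least-squares polynomial fit of latency on score."""

    degree: int
    params: np.ndarray  # beta_0 .. beta_degree (intercept first)
    bse: np.ndarray
    r_squared: float
    f_stat: float
    df_model: int
    df_resid: int
    p_value: float
    fitted: np.ndarray
    residuals: np.ndarray

    @property
    def nobs(self) -> int:
        return len(self.fitted)

    @property
    def resid_sd(self) -> float:
        return float(np.sqrt((self.residuals**2).sum() / self.df_resid))

    def standardized_residuals(self) -> np.ndarray:
        sd = self.resid_sd
        if sd == 0.0:  # perfect fit
            return np.zeros_like(self.residuals)
        return self.residuals / sd

    def vertex(self) -> float:
        """Stationary point -b1/(2*b2) of a quadratic fit (score units)."""
        if self.degree != 2:
            raise ValueError("vertex defined only for degree-2 fits")
        return float(-self.params[1] / (2.0 * self.params[2]))


def polyfit_ols(score, rt, degree: int) -> ModelFit:
    """Fit latency on polynomial powers of score by OLS with intercept."""
    score = np.asarray(score, dtype=float)
    rt = np.asarray(rt, dtype=float)
    if degree not in (1, 2):
        raise ValueError(f"degree must be 1 or 2, got {degree!r}")
    if len(score) != len(rt):
        raise ValueError(f"length mismatch: {len(score)} vs {len(rt)}")
    n = len(score)
    if n <= degree + 1:
        raise ValueError(f"need n > degree + 1 = {degree + 1}, got n={n}")
    if len(np.unique(score)) <= degree:
        raise ValueError(
            f"rank-deficient design: only {len(np.unique(score))} distinct scores "
            f"for degree {degree}"
        )
    X = np.vander(score, degree + 1, increasing=True)
    res = sm.OLS(rt, X).fit()
    return ModelFit(
        degree=degree,
        params=np.asarray(res.params, dtype=float),
        bse=np.asarray(res.bse, dtype=float),
        r_squared=float(res.rsquared),
        f_stat=float(res.fvalue),
        df_model=int(res.df_model),
        df_resid=int(res.df_resid),
        p_value=float(res.f_pvalue),
        fitted=np.asarray(res.fittedvalues, dtype=float),
        residuals=np.asarray(res.resid, dtype=float),
    )


@dataclass(frozen=True)
class TrendComparison:
    """Nested comparison of linear and quadratic fits on the same data."""

    delta_r2: float
    delta_r2_f: float
    delta_r2_p: float
    preferred: str  # "linear" | "quadratic"
    quad_coefficient_sign: str  # "negative" | "nonnegative"
    alpha: float


def compare_trends(linear: ModelFit, quadratic: ModelFit, alpha: float = 0.05) -> TrendComparison:
    """Hierarchical F test of the R-squared increment quadratic over linear.

    F(1, n-3) = (R2_q - R2_l) / ((1 - R2_q) / (n - 3)). The quadratic model
    is preferred when the increment is significant at ``alpha``; the sign of
    its squared-score coefficient says whether the curve is concave
    (negative = inverted U).
    """
    if linear.degree != 1 or quadratic.degree != 2:
        raise ValueError("expected a degree-1 and a degree-2 fit")
    if linear.nobs != quadratic.nobs:
        raise ValueError(f"fits use different n: {linear.nobs} vs {quadratic.nobs}")
    n = linear.nobs
    delta = quadratic.r_squared - linear.r_squared
    denom = (1.0 - quadratic.r_squared) / (n - 3)
    if denom <= 0.0:  # perfect quadratic fit
        f_val, p = math.inf, 0.0
    else:
        f_val = delta / denom
        p = float(sps.f.sf(f_val, 1, n - 3))
    preferred = "quadratic" if p < alpha else "linear"
    sign = "negative" if quadratic.params[2] < 0 else "nonnegative"
    return TrendComparison(
        delta_r2=delta,
        delta_r2_f=f_val,
        delta_r2_p=p,
        preferred=preferred,
        quad_coefficient_sign=sign,
        alpha=alpha,
    )


def residual_diagnostics(fit: ModelFit, threshold: float = 3.0) -> pd.DataFrame:
    """Residual-vs-fitted table with potential outliers flagged.

    A point is flagged when its standardized residual exceeds ``threshold``
    in absolute value.
    """
    std = fit.standardized_residuals()
    return pd.DataFrame(
        {
            "fitted": fit.fitted,
            "residual": fit.residuals,
            "std_residual": std,
            "outlier": np.abs(std) > threshold,
        }
    )


@dataclass
class SchemaTestResults:
    """Results of the inverted-U hypothesis test.

    Carries the KS normality checks on both variables, the linear and
    quadratic fits with their own overall F statistics (the headline
    comparison), and the hierarchical delta-R-squared F test that formally
    adjudicates between the nested models.
    """

    ks_score: KSNormalityResult
    ks_rt: KSNormalityResult
    linear: ModelFit
    quadratic: ModelFit
    comparison: TrendComparison
    score: np.ndarray = field(repr=False, default=None)
    rt: np.ndarray = field(repr=False, default=None)

    @property
    def preferred(self) -> str:
        return self.comparison.preferred

    def to_dict(self) -> dict:
        def fit_dict(f: ModelFit) -> dict:
            return {
                "degree": f.degree,
                "coefficients": f.params.tolist(),
                "coefficient_se": f.bse.tolist(),
                "r_squared": f.r_squared,
                "f_stat": f.f_stat,
                "df_model": f.df_model,
                "df_resid": f.df_resid,
                "p_value": f.p_value,
            }

        def ks_dict(k: KSNormalityResult) -> dict:
            return {"stat": k.stat, "z": k.z, "p_value": k.p_value, "n": k.n}

        return {
            "ks": {"score": ks_dict(self.ks_score), "rt": ks_dict(self.ks_rt)},
            "linear": fit_dict(self.linear),
            "quadratic": fit_dict(self.quadratic),
            "delta_r2": self.comparison.delta_r2,
            "delta_r2_f": self.comparison.delta_r2_f,
            "delta_r2_p": self.comparison.delta_r2_p,
            "preferred": self.comparison.preferred,
            "quad_coefficient_sign": self.comparison.quad_coefficient_sign,
            "alpha": self.comparison.alpha,
            "n": self.linear.nobs,
        }

    def summary(self) -> str:
        c = self.comparison
        lines = [
            "Inverted-U latency model",
            "=" * 60,
            f"n participants            {self.linear.nobs:>10d}",
            f"KS normality (score)      Z={self.ks_score.z:.3f}  p={self.ks_score.p_value:.3f}",
            f"KS normality (latency)    Z={self.ks_rt.z:.3f}  p={self.ks_rt.p_value:.3f}",
            "-" * 60,
            (
                f"linear     F({self.linear.df_model},{self.linear.df_resid})="
                f"{self.linear.f_stat:.2f}  p={self.linear.p_value:.4g}  "
                f"R2={self.linear.r_squared:.3f}"
            ),
            (
                f"quadratic  F({self.quadratic.df_model},{self.quadratic.df_resid})="
                f"{self.quadratic.f_stat:.2f}  p={self.quadratic.p_value:.4g}  "
                f"R2={self.quadratic.r_squared:.3f}"
            ),
            (
                f"delta-R2   F(1,{self.linear.nobs - 3})={c.delta_r2_f:.2f}  "
                f"p={c.delta_r2_p:.4g}"
            ),
            "-" * 60,
            f"preferred trend           {c.preferred}",
            f"quadratic coefficient     {c.quad_coefficient_sign}",
        ]
        return "\n".join(lines)

    def residual_table(self, threshold: float = 3.0) -> pd.DataFrame:
        """Side-by-side residual diagnostics for both fits."""
        lin = residual_diagnostics(self.linear, threshold)
        quad = residual_diagnostics(self.quadratic, threshold)
        return pd.DataFrame(
            {
                "fitted_linear": lin["fitted"],
                "residual_linear": lin["residual"],
                "outlier_linear": lin["outlier"],
                "fitted_quadratic": quad["fitted"],
                "residual_quadratic": quad["residual"],
                "outlier_quadratic": quad["outlier"],
            }
        )

    def plot_fit(self, ax=None):
        """Scatter of latency against score with both fitted curves."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.score, self.rt, s=18, alpha=0.7, label="participants")
        grid = np.linspace(self.score.min(), self.score.max(), 200)
        lin = self.linear.params
        quad = self.quadratic.params
        ax.plot(grid, lin[0] + lin[1] * grid, label="linear")
        ax.plot(grid, quad[0] + quad[1] * grid + quad[2] * grid**2, label="quadratic")
        ax.set_xlabel("total mobile score")
        ax.set_ylabel("mean item-centered RT (ms)")
        ax.legend()
        return ax

    def plot_residuals(self, axes=None):
        """Residual-vs-fitted scatter for both models."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
        for ax, fit, label in zip(axes, (self.linear, self.quadratic), ("linear", "quadratic")):
            ax.scatter(fit.fitted, fit.residuals, s=18, alpha=0.7)
            ax.axhline(0.0, lw=0.8, color="k")
            ax.set_title(label)
            ax.set_xlabel("fitted")
        axes[0].set_ylabel("residual (ms)")
        return axes


class LatencySchemaModel:
    """Quadratic-vs-linear latency model on per-participant summaries.

    Parameters
    ----------
    score : array-like
        Total converted mobile score per participant (the explicit measure).
    rt : array-like
        Mean item-centered response latency per participant in ms (the
        implicit measure).
    """

    def __init__(self, score, rt):
        self.score = np.asarray(score, dtype=float)
        self.rt = np.asarray(rt, dtype=float)
        if len(self.score) != len(self.rt):
            raise ValueError(f"length mismatch: {len(self.score)} vs {len(self.rt)}")
        if len(self.score) < 5:
            raise ValueError(f"need at least 5 participants, got {len(self.score)}")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        score_col: str = "total",
        rt_col: str = "mean_centered_rt",
    ) -> "LatencySchemaModel":
        return cls(df[score_col].to_numpy(dtype=float), df[rt_col].to_numpy(dtype=float))

    def fit(self, alpha: float = 0.05) -> SchemaTestResults:
        linear = polyfit_ols(self.score, self.rt, 1)
        quadratic = polyfit_ols(self.score, self.rt, 2)
        return SchemaTestResults(
            ks_score=ks_normality(self.score),
            ks_rt=ks_normality(self.rt),
            linear=linear,
            quadratic=quadratic,
            comparison=compare_trends(linear, quadratic, alpha),
            score=self.score,
            rt=self.rt,
        )
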