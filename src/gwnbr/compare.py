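"""Global-vs-spatial model comparison and interpretation helpers.

Three decisions are supported: (1) an F-type fit test comparing the global
NB deviance per df with the GWNBR deviance per effective df (df2 = n -
tr(S), passed to the continuous F distribution without rounding); (2) the
MLRT simultaneous test, a chi-square deviance-difference test of the
covariates' joint contribution; (3) AIC ranking across Poisson, NB and
GWNBR.  Rate ratios exp(beta) translate log-link coefficients into
multiplicative effects on the expected count.
"""

from __future__ import annotations

import dataclasses
import math

from scipy import stats

__all__ = [
    "ComparisonReport",
    "f_type_test",
    "mlrt_simultaneous",
    "chi2_quantile",
    "f_quantile",
    "rate_ratio",
    "aic_rank",
]


@dataclasses.dataclass(frozen=True)
class ComparisonReport:
    f_test: dict
    mlrt: dict
    aic_table: list
    selected_model: str

    def as_dict(self) -> dict:
        return {
            "f_test": self.f_test,
            "mlrt": self.mlrt,
            "aic_table": [{"model": m, "aic": a, "k": k} for m, a, k in self.aic_table],
            "selected_model": self.selected_model,
        }


def chi2_quantile(prob: float, df: float) -> float:
    """Inverse CDF of the chi-square distribution."""
    if not 0.0 < prob < 1.0:
        raise ValueError("prob must lie in (0, 1)")
    if df <= 0:
        raise ValueError("df must be positive")
    return float(stats.chi2.ppf(prob, df))


def f_quantile(prob: float, df1: float, df2: float) -> float:
    """Inverse CDF of the F distribution (non-integer df allowed)."""
    if not 0.0 < prob < 1.0:
        raise ValueError("prob must lie in (0, 1)")
    if df1 <= 0 or df2 <= 0:
        raise ValueError("degrees of freedom must be positive")
    return float(stats.f.ppf(prob, df1, df2))


def f_type_test(d_global: float, df1: float, d_spatial: float, df2: float,
                alpha: float = 0.05) -> dict:
    """F-type comparison of global and spatial deviances per df.

    F = (D_global/df1) / (D_spatial/df2); rejecting the null of no
    improvement means the spatially varying model fits better.
    """
    if min(d_global, df1, d_spatial, df2) <= 0:
        raise ValueError("deviances and degrees of freedom must be positive")
    f = (d_global / df1) / (d_spatial / df2)
    crit = f_quantile(1.0 - alpha, df1, df2)
    return {
        "test": "f_type_fit",
        "statistic": f,
        "df1": df1,
        "df2": df2,
        "critical_value": crit,
        "p_value": float(stats.f.sf(f, df1, df2)),
        "alpha": alpha,
        "reject": f > crit,
    }


def mlrt_simultaneous(full_loglik: float, restricted_loglik: float, df: int,
                      alpha: float = 0.05) -> dict:
    """Maximum likelihood ratio test of the covariates' joint contribution.

    statistic = 2 [l(full) - l(restricted)], chi-square with df = number of
    covariates dropped in the restricted (intercept-only) model.  A negative
    statistic beyond rounding noise signals a convergence failure in one of
    the fits.
    """
    statistic = 2.0 * (full_loglik - restricted_loglik)
    if statistic < -1e-6:
        raise ValueError(
            f"restricted model fits better than full (statistic {statistic:.3g}); "
            "check convergence of the full fit"
        )
    statistic = max(statistic, 0.0)
    crit = chi2_quantile(1.0 - alpha, df)
    return {
        "test": "mlrt_simultaneous",
        "statistic": statistic,
        "df": df,
        "critical_value": crit,
        "p_value": float(stats.chi2.sf(statistic, df)),
        "alpha": alpha,
        "reject": statistic > crit,
    }


def rate_ratio(coefficient: float) -> tuple[float, str]:
    """exp(beta) with a plain-language interpretation.

    Under the log link, a one-unit covariate increase multiplies the
    expected count by exp(beta), other covariates held constant.
    """
    if not math.isfinite(coefficient):
        raise ValueError("coefficient must be finite")
    rr = math.exp(coefficient)
    if coefficient > 0:
        text = (f"a one-unit increase multiplies the expected count by "
                f"{rr:.4g} (increase), other covariates held constant")
    elif coefficient < 0:
        text = (f"a one-unit increase multiplies the expected count by "
                f"{rr:.4g} (decrease), other covariates held constant")
    else:
        text = "no effect: the expected count is unchanged"
    return rr, text


def aic_rank(models) -> tuple[list, str]:
    """Rank models by AIC = -2 ln L + 2k (ascending).

    ``models`` is an iterable of (name, loglik, k) triples; ties are broken
    by smaller k, then name.  Returns the sorted (name, aic, k) table and
    the selected (minimum-AIC) model name.
    """
    models = list(models)
    if len(models) < 2:
        raise ValueError("need at least two models to rank")
    table = [(name, -2.0 * ll + 2.0 * k, k) for name, ll, k in models]
    table.sort(key=lambda t: (t[1], t[2], t[0]))
    return table, table[0][0]


def build_report(d_global, df1, d_spatial, df2, full_loglik, restricted_loglik,
                 mlrt_df, aic_models, alpha: float = 0.05) -> ComparisonReport:
    """Assemble the full comparison report from precomputed fit summaries."""
    table, selected = aic_rank(aic_models)
    return ComparisonReport(
        f_test=f_type_test(d_global, df1, d_spatial, df2, alpha),
        mlrt=mlrt_simultaneous(full_loglik, restricted_loglik, mlrt_df, alpha),
        aic_table=table,
        selected_model=selected,
    )
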