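"""Relative selection strength (RSS): coefficient exponentiation, prediction
curves over standardized covariate ranges, and moderator categories.

For a fitted selection coefficient beta, RSS = exp(beta) is the ratio of the
probabilities of selecting two otherwise-identical steps whose endpoints
differ by one (standardized) unit in the covariate.  RSS > 1 is selection for,
RSS < 1 selection against, RSS = 1 indifference.  Prediction curves compare a
grid of covariate values against a reference (the period mean, 0 on the
standardized scale):

    log-RSS(x; ref) = b_lin (x - ref) + b_quad (x^2 - ref^2) + m b_int (x - ref)

with m the moderator level in SD units (0 when no moderator is involved).
Confidence bands use the delta method on the log scale with the fit's robust
covariance.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .model import FitResult


def rss_from_coefficient(beta):
    """RSS = exp(beta); vectorised."""
    return np.exp(beta)


def rss_table(fit: FitResult, alpha: float = 0.05) -> pd.DataFrame:
    """Per-term summary: coefficient, robust SE, RSS, p, significance flag."""
    p = fit.pvalues
    return pd.DataFrame({
        "term": fit.beta.index,
        "coefficient": fit.beta.to_numpy(),
        "se_robust": fit.se_robust.to_numpy(),
        "rss": np.exp(fit.beta.to_numpy()),
        "p": p.to_numpy(),
        "significant": p.to_numpy() < alpha,
        "period": fit.period,
        "tier": fit.tier,
    })


def moderator_categories(values) -> np.ndarray:
    """Label standardized moderator values: <= -1 SD -> '-1', inside (-1, 1)
    -> '0', >= +1 SD -> '+1'."""
    v = np.asarray(values, dtype=float)
    return np.where(v <= -1.0, "-1", np.where(v >= 1.0, "+1", "0"))


def log_rss_curve(fit: FitResult, covariate: str, grid,
                  reference: float = 0.0, moderator: str | None = None,
                  moderator_level: float = 0.0, conf: float = 0.95) -> pd.DataFrame:
    """RSS curve for one covariate against a reference value.

    ``grid`` and ``reference`` are on the standardized scale.  When
    ``moderator`` is given, its one-way interaction with the covariate is
    evaluated at ``moderator_level`` SD units (-1/0/+1 are the reporting
    categories).  Returns columns: covariate, x, moderator_level, log_rss,
    rss, lo, hi — bands symmetric on the log scale, exp-transformed.
    """
    cols = list(fit.beta.index)
    if covariate not in cols:
        raise ConfigurationError(f"covariate {covariate!r} not in the fitted roster")
    int_col = None
    if moderator is not None:
        int_col = f"{covariate}:{moderator}"
        if int_col not in cols:
            raise ConfigurationError(f"interaction {int_col!r} not in the fitted roster")
    quad_col = f"{covariate}^2" if f"{covariate}^2" in cols else None

    x = np.asarray(grid, dtype=float)
    D = np.zeros((len(x), len(cols)))
    D[:, cols.index(covariate)] = x - reference
    if quad_col:
        D[:, cols.index(quad_col)] = x ** 2 - reference ** 2
    if int_col:
        D[:, cols.index(int_col)] = moderator_level * (x - reference)

    log_rss = D @ fit.beta.to_numpy()
    var = np.einsum("ij,jk,ik->i", D, fit.cov_robust, D)
    from scipy.stats import norm
    z = norm.ppf(0.5 + conf / 2.0)
    sd = np.sqrt(np.maximum(var, 0.0))
    return pd.DataFrame({
        "covariate": covariate,
        "x": x,
        "moderator_level": moderator_level if moderator else 0.0,
        "log_rss": log_rss,
        "rss": np.exp(log_rss),
        "lo": np.exp(log_rss - z * sd),
        "hi": np.exp(log_rss + z * sd),
    })
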