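"""Candidate habitat-selection models: design construction, conditional
logistic fitting with cluster-robust (sandwich) variance, and AICc selection.

The estimator maximises the stratified conditional (partial) log-likelihood

    l(beta) = sum_s [ beta' x_case(s)  -  log sum_{j in s} exp(beta' x_j) ]

over strata of 1 used + n available steps, by Newton-Raphson with analytic
gradient and observed information.  The naive covariance is the inverse
observed information; the robust covariance is the sandwich A^-1 B A^-1 with B
the outer-product sum of per-cluster (per-animal) score sums, absorbing
within-animal dependence among strata.  B carries the standard CR1
small-sample factor G/(G-1) because the cluster count — the number of
collared animals — is typically small.

Four nested candidate tiers are compared per season by AICc:

* M1 — environmental covariates only (plus the movement correction terms);
* M2 — M1 plus experience interactions;
* M3 — M1 plus group-size interactions;
* M4 — M1 plus both interaction sets.

Experience and group size are constant within a stratum, so their main
effects cancel from the conditional likelihood and are excluded from the
estimable design; they enter only through one-way interactions.  Temperature's
quadratic and its moderator interactions are used in the dry season only,
where thermal stress is the operative constraint.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (ConfigurationError, ConvergenceError, DataError,
                     DegenerateDataError, SeparationError)

MOVEMENT_TERMS = ["sl", "log_sl"]
ENV_MAINS = ["aNDVI", "dNDVI", "elevation", "TRI", "temperature"]
QUADRATIC_BASES = {"dry": ["aNDVI", "dNDVI", "temperature"],
                   "wet": ["aNDVI", "dNDVI"]}
INTERACTION_BASES = {"dry": MOVEMENT_TERMS + ENV_MAINS,
                     "wet": MOVEMENT_TERMS + ["aNDVI", "dNDVI", "elevation", "TRI"]}
MODERATORS = {"M1": [], "M2": ["experience"], "M3": ["group_size"],
              "M4": ["experience", "group_size"]}
TIERS = ["M1", "M2", "M3", "M4"]


def model_columns(period: str, tier: str) -> list[str]:
    """Ordered column roster for one period/tier (the design manifest)."""
    if period not in QUADRATIC_BASES:
        raise ConfigurationError(f"unknown period {period!r}")
    if tier not in MODERATORS:
        raise ConfigurationError(f"unknown tier {tier!r}")
    cols = list(MOVEMENT_TERMS) + list(ENV_MAINS)
    cols += [f"{b}^2" for b in QUADRATIC_BASES[period]]
    for mod in MODERATORS[tier]:
        cols += [f"{b}:{mod}" for b in INTERACTION_BASES[period]]
    return cols


def standardize(df: pd.DataFrame, columns: list[str],
                moments: dict[str, tuple[float, float]] | None = None):
    """Centre and scale columns to mean 0, sample SD 1 (over all rows).

    Returns ``(standardized copy, moments)`` where moments maps column ->
    (mean, SD) for back-transformation and for the -1/0/+1 SD moderator
    categories.  Precomputed moments may be supplied (e.g. to score new data
    on the fitting scale).
    """
    out = df.copy()
    used: dict[str, tuple[float, float]] = {}
    for col in columns:
        vals = out[col].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise DataError(f"non-finite values in column {col!r}")
        if moments is not None and col in moments:
            mean, sd = moments[col]
        else:
            mean, sd = float(vals.mean()), float(vals.std(ddof=1))
        if sd == 0.0 or not np.isfinite(sd):
            raise DegenerateDataError(f"column {col!r} has zero variance")
        out[col] = (vals - mean) / sd
        used[col] = (mean, sd)
    return out, used


@dataclass
class DesignMatrix:
    """Fitting-ready design: standardized columns keyed by stratum/case/cluster."""

    X: np.ndarray
    columns: list[str]
    stratum_id: np.ndarray
    case: np.ndarray
    cluster: np.ndarray
    moments: dict[str, tuple[float, float]] = field(default_factory=dict)
    period: str = ""
    tier: str = ""

    @property
    def n_strata(self) -> int:
        return len(np.unique(self.stratum_id))


def _parse_column(col: str):
    """Split a roster column into (kind, parts): main, quadratic or interaction."""
    if col.endswith("^2"):
        return "quad", (col[:-2],)
    if ":" in col:
        base, mod = col.split(":", 1)
        return "interaction", (base, mod)
    return "main", (col,)


def build_design(strata: pd.DataFrame, period: str, tier: str = "M4",
                 columns: list[str] | None = None,
                 moments: dict | None = None,
                 keep_inestimable: bool = False) -> DesignMatrix:
    """Assemble the design matrix for one period/tier (or a custom roster).

    Base covariates (movement terms, environmental mains, moderators) are
    standardized over all rows of the period's strata; quadratics and
    interactions are products of the standardized bases and are deliberately
    not re-standardized, keeping the -1/0/+1 SD moderator categories
    interpretable.  Stratum-constant moderator main effects are excluded
    (warned about under ``keep_inestimable=True``, which appends them anyway
    for transparency).  ``columns`` overrides the tier roster with arbitrary
    mains, ``base^2`` quadratics and ``base:moderator`` interactions.
    """
    df = strata[strata["period"] == period] if "period" in strata else strata
    if len(df) == 0:
        raise DataError(f"no strata for period {period!r}")
    counts = df.groupby("stratum_id")["case"].sum()
    if (counts != 1).any():
        raise DataError("every stratum must contain exactly one used (case=1) row")

    cols = list(columns) if columns is not None else model_columns(period, tier)
    bases: list[str] = []
    for c in cols:
        _, parts = _parse_column(c)
        bases.extend(parts)
    moderators = MODERATORS[tier] if columns is None else []
    bases = list(dict.fromkeys(bases + moderators))
    missing = [b for b in bases if b not in df.columns]
    if missing:
        raise ConfigurationError(f"design requests missing covariate(s): {missing}")
    std, used_moments = standardize(df, bases, moments=moments)

    mat = {}
    for c in cols:
        kind, parts = _parse_column(c)
        if kind == "main":
            mat[c] = std[parts[0]].to_numpy(dtype=float)
        elif kind == "quad":
            mat[c] = std[parts[0]].to_numpy(dtype=float) ** 2
        else:
            mat[c] = (std[parts[0]].to_numpy(dtype=float)
                      * std[parts[1]].to_numpy(dtype=float))

    # a column constant within every stratum cancels from the conditional
    # likelihood and would make the information matrix singular
    if not keep_inestimable:
        sid = df["stratum_id"].to_numpy()
        order = np.argsort(sid, kind="mergesort")
        for c in cols:
            v = mat[c][order]
            first = np.r_[True, sid[order][1:] != sid[order][:-1]]
            anchor = np.maximum.accumulate(np.where(first, np.arange(len(v)), 0))
            if np.allclose(v, v[anchor]):
                raise ConfigurationError(
                    f"column {c!r} is constant within every stratum and is not "
                    "identifiable in the conditional likelihood")

    if keep_inestimable and moderators:
        warnings.warn(
            "moderator main effects are constant within strata and not "
            "identifiable in the conditional likelihood; keeping them will "
            "yield near-zero estimates with huge standard errors", stacklevel=2)
        for mod in moderators:
            cols = cols + [mod]
            mat[mod] = std[mod].to_numpy(dtype=float)

    X = np.column_stack([mat[c] for c in cols])
    return DesignMatrix(
        X=X, columns=cols,
        stratum_id=df["stratum_id"].to_numpy(),
        case=df["case"].to_numpy(dtype=int),
        cluster=df["animal_id"].to_numpy(),
        moments=used_moments, period=period, tier=tier,
    )


def vif(X: np.ndarray, columns: list[str] | None = None,
        threshold: float = 4.0) -> pd.Series:
    """Variance inflation factor per column: 1 / (1 - R^2_j) from regressing
    column j on the remaining columns (with intercept).

    Perfect collinearity reports ``inf``.  A warning names columns at or above
    ``threshold`` (the screening rule is VIF < 4).
    """
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if k < 2:
        raise ConfigurationError("VIF needs at least 2 columns")
    columns = columns or [f"x{j}" for j in range(k)]
    out = np.empty(k)
    ones = np.ones((n, 1))
    for j in range(k):
        yj = X[:, j]
        Zj = np.concatenate([ones, np.delete(X, j, axis=1)], axis=1)
        coef, *_ = np.linalg.lstsq(Zj, yj, rcond=None)
        resid = yj - Zj @ coef
        sst = ((yj - yj.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / sst if sst > 0 else 1.0
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    result = pd.Series(out, index=columns, name="VIF")
    flagged = result[result >= threshold]
    if len(flagged):
        warnings.warn(f"VIF >= {threshold} for column(s): {list(flagged.index)}",
                      stacklevel=2)
    return result


@dataclass
class FitResult:
    """One fitted candidate model."""

    beta: pd.Series
    cov_naive: np.ndarray
    cov_robust: np.ndarray
    loglik: float
    loglik_null: float
    k: int
    n_strata: int
    n_clusters: int
    converged: bool
    n_iter: int
    period: str = ""
    tier: str = ""
    stratum_ids: np.ndarray | None = None

    @property
    def se_naive(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_naive)), index=self.beta.index)

    @property
    def se_robust(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_robust)), index=self.beta.index)

    @property
    def pvalues(self) -> pd.Series:
        """Two-sided p-values from robust SEs via the normal reference."""
        z = self.beta / self.se_robust
        return pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=self.beta.index)


def _segments(stratum_id_sorted: np.ndarray):
    starts = np.flatnonzero(np.r_[True, stratum_id_sorted[1:] != stratum_id_sorted[:-1]])
    return starts


def clogit_loglik(beta: np.ndarray, X: np.ndarray, starts: np.ndarray,
                  seg: np.ndarray, case_idx: np.ndarray) -> float:
    """Stratified conditional log-likelihood at ``beta`` (rows sorted by stratum)."""
    eta = X @ beta
    mx = np.maximum.reduceat(eta, starts)
    denom = np.add.reduceat(np.exp(eta - mx[seg]), starts)
    lse = mx + np.log(denom)
    return float(eta[case_idx].sum() - lse.sum())


def fit_clogit(design: DesignMatrix, max_iter: int = 200, tol: float = 1e-8,
               beta0: np.ndarray | None = None) -> FitResult:
    """Fit the conditional logistic model by Newton-Raphson.

    Analytic gradient (sum over strata of ``x_case - E[x]``) and observed
    information; step-halving when a full Newton step decreases the
    likelihood.  Convergence requires gradient max-norm below ``tol``.
    Raises :class:`SeparationError` when the step diverges (a covariate
    perfectly separating used from available steps) and
    :class:`ConvergenceError` on iteration exhaustion.
    """
    order = np.argsort(design.stratum_id, kind="mergesort")
    X = np.asarray(design.X, dtype=float)[order]
    sid = np.asarray(design.stratum_id)[order]
    case = np.asarray(design.case)[order]
    clusters = np.asarray(design.cluster)[order]

    starts = _segments(sid)
    n_strata = len(starts)
    sizes = np.diff(np.r_[starts, len(sid)])
    seg = np.repeat(np.arange(n_strata), sizes)
    case_idx = np.flatnonzero(case == 1)
    if len(case_idx) != n_strata:
        raise DataError("each stratum needs exactly one case row")

    n, k = X.shape
    beta = np.zeros(k) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    ll = clogit_loglik(beta, X, starts, seg, case_idx)
    loglik_null = float(-np.log(sizes).sum())

    converged = False
    grad = np.full(k, np.inf)
    it = 0
    for it in range(1, max_iter + 1):
        if np.linalg.norm(beta) > 50.0:
            raise SeparationError(
                "coefficients diverging (norm > 50 on the standardized scale): "
                "a column nearly separates used from available steps")
        eta = X @ beta
        mx = np.maximum.reduceat(eta, starts)
        w = np.exp(eta - mx[seg])
        denom = np.add.reduceat(w, starts)
        p = w / denom[seg]
        M = np.zeros((n_strata, k))
        np.add.reduceat(p[:, None] * X, starts, axis=0, out=M)
        grad = X[case_idx].sum(axis=0) - M.sum(axis=0)
        if np.abs(grad).max() < tol:
            converged = True
            break
        A = X.T @ (p[:, None] * X) - M.T @ M  # observed information
        try:
            delta = np.linalg.solve(A, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                "observed information is singular (collinear or stratum-constant "
                "columns in the design)") from exc
        if not np.isfinite(delta).all() or np.linalg.norm(delta) > 1e3:
            raise SeparationError(
                "unbounded Newton step: a column appears to separate used from "
                "available steps perfectly")
        # trust region: cap the step so ill-conditioned information cannot
        # throw the iterate far outside the quadratic model's validity
        dnorm = np.linalg.norm(delta)
        if dnorm > 5.0:
            delta = delta * (5.0 / dnorm)
        step = 1.0
        ll_slack = 1e-11 * (1.0 + abs(ll))  # floating noise floor of the log-likelihood
        for _ in range(40):
            cand = beta + step * delta
            ll_new = clogit_loglik(cand, X, starts, seg, case_idx)
            if ll_new >= ll - ll_slack:
                break
            step *= 0.5
        else:
            if np.abs(grad).max() < 1e-5:
                converged = True  # at the optimum up to floating noise
                break
            raise ConvergenceError(f"step-halving failed at iteration {it}; "
                                   f"gradient max-norm {np.abs(grad).max():.3g}")
        beta, ll = cand, ll_new

    if not converged:
        raise ConvergenceError(f"no convergence in {max_iter} iterations; "
                               f"last gradient max-norm {np.abs(grad).max():.3g}")
    # the partial likelihood's supremum is 0 (every used step predicted with
    # certainty); attaining it numerically means a column separates the data
    if ll > -1e-8 * n_strata:
        raise SeparationError(
            "partial likelihood reached its supremum: a column separates used "
            "from available steps perfectly")

    # covariance at the optimum
    eta = X @ beta
    mx = np.maximum.reduceat(eta, starts)
    w = np.exp(eta - mx[seg])
    denom = np.add.reduceat(w, starts)
    p = w / denom[seg]
    M = np.zeros((n_strata, k))
    np.add.reduceat(p[:, None] * X, starts, axis=0, out=M)
    A = X.T @ (p[:, None] * X) - M.T @ M
    A_inv = np.linalg.inv(A)

    scores = X[case_idx] - M  # per-stratum score contributions
    strat_cluster = clusters[case_idx]
    cluster_ids, inv = np.unique(strat_cluster, return_inverse=True)
    G = np.zeros((len(cluster_ids), k))
    np.add.at(G, inv, scores)
    B = G.T @ G
    n_clusters = len(cluster_ids)
    if n_clusters > 1:
        # CR1 small-sample factor: the plain sandwich is anticonservative
        # with few clusters (here, few animals)
        B = B * (n_clusters / (n_clusters - 1.0))
    cov_robust = A_inv @ B @ A_inv

    return FitResult(
        beta=pd.Series(beta, index=design.columns),
        cov_naive=A_inv, cov_robust=cov_robust,
        loglik=ll, loglik_null=loglik_null, k=k,
        n_strata=n_strata, n_clusters=len(cluster_ids),
        converged=converged, n_iter=it,
        period=design.period, tier=design.tier,
        stratum_ids=np.unique(sid),
    )


def aicc(fit: FitResult, n: int | None = None) -> float:
    """Small-sample-corrected AIC: -2l + 2k + 2k(k+1)/(n - k - 1).

    ``n`` defaults to the number of strata — the independent contributions to
    the conditional likelihood.
    """
    n = fit.n_strata if n is None else n
    k = fit.k
    if n <= k + 1:
        raise ConfigurationError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * fit.loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def select_model(fits: dict[str, FitResult]) -> pd.DataFrame:
    """Rank candidate fits by AICc (ascending); ties break toward smaller k.

    All candidates must be fitted on identical strata, otherwise their
    likelihoods are not comparable.
    """
    ref = next(iter(fits.values()))
    for f in fits.values():
        if f.n_strata != ref.n_strata or (
                f.stratum_ids is not None and ref.stratum_ids is not None
                and not np.array_equal(f.stratum_ids, ref.stratum_ids)):
            raise DataError("candidates fitted on different strata are not comparable")
    rows = [{"tier": tier, "k": f.k, "loglik": f.loglik, "AICc": aicc(f)}
            for tier, f in fits.items()]
    out = pd.DataFrame(rows).sort_values(["AICc", "k"], kind="mergesort").reset_index(drop=True)
    out["dAICc"] = out["AICc"] - out["AICc"].iloc[0]
    out["rank"] = np.arange(1, len(out) + 1)
    return out
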