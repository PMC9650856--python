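"""Empirical movement kernel: gamma step lengths, von Mises turning angles,
and sampling of available steps to build used/available strata.

The kernel describes movement absent habitat selection.  Step lengths follow a
gamma distribution (maximum-likelihood fit, origin fixed at zero) and turning
angles a von Mises distribution whose concentration solves
``I1(kappa)/I0(kappa) = mean resultant length``.  For every usable observed
step (one with a defined previous heading) a fixed number of available steps
is drawn from the fitted kernel around the previous heading; the observed step
plus its alternatives form one stratum of the conditional likelihood.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .errors import ConfigurationError, DataError, DegenerateDataError
from .tracks import MIN_STEP_LENGTH, wrap_angle

#: Available steps sampled per used step.
N_AVAILABLE = 9


@dataclass(frozen=True)
class GammaParams:
    shape: float
    scale: float

    def __post_init__(self):
        if not (np.isfinite(self.shape) and self.shape > 0
                and np.isfinite(self.scale) and self.scale > 0):
            raise ConfigurationError("gamma shape and scale must be finite and positive")

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def var(self) -> float:
        return self.shape * self.scale ** 2


@dataclass(frozen=True)
class VonMisesParams:
    mu: float
    kappa: float

    def __post_init__(self):
        if not (np.isfinite(self.mu) and np.isfinite(self.kappa) and self.kappa >= 0):
            raise ConfigurationError("von Mises mu must be finite, kappa finite and >= 0")


def fit_gamma(lengths, min_n: int = 30) -> GammaParams:
    """Maximum-likelihood gamma fit to step lengths (location fixed at 0).

    The method-of-moments estimate (shape = mean^2/var, scale = var/mean)
    seeds the optimiser; the returned fit never has lower log-likelihood than
    that start.
    """
    x = np.asarray(lengths, dtype=float)
    if len(x) < min_n:
        raise DataError(f"need >= {min_n} step lengths, got {len(x)}")
    if not np.isfinite(x).all() or (x <= 0).any():
        raise DataError("step lengths must be positive and finite")
    m, v = x.mean(), x.var(ddof=1)
    if v == 0.0:
        raise DegenerateDataError("all step lengths identical; gamma fit is degenerate")
    mom = GammaParams(shape=m * m / v, scale=v / m)
    shape, _, scale = stats.gamma.fit(x, floc=0.0)
    mle = GammaParams(shape=float(shape), scale=float(scale))

    def ll(p: GammaParams) -> float:
        return float(stats.gamma.logpdf(x, p.shape, scale=p.scale).sum())

    return mle if ll(mle) >= ll(mom) else mom


def _a1(kappa: float) -> float:
    """Bessel ratio A1(kappa) = I1(kappa)/I0(kappa), stable for large kappa."""
    return float(special.i1e(kappa) / special.i0e(kappa))


def fit_vonmises(angles, min_n: int = 30) -> VonMisesParams:
    """Fit a von Mises distribution to wrapped angles.

    mu is the circular mean; kappa solves A1(kappa) = R (the mean resultant
    length) by monotone root finding.  R numerically zero yields kappa = 0
    (uniform angles), not an error.
    """
    a = np.asarray(angles, dtype=float)
    if len(a) < min_n:
        raise DataError(f"need >= {min_n} angles, got {len(a)}")
    if not np.isfinite(a).all():
        raise DataError("angles must be finite")
    c, s = np.cos(a).mean(), np.sin(a).mean()
    r = float(np.hypot(c, s))
    mu = float(np.arctan2(s, c))
    if r < 1e-12:
        return VonMisesParams(mu=0.0, kappa=0.0)
    if r >= 1.0 - 1e-12:
        raise DegenerateDataError("all angles identical; kappa is unbounded")
    hi = max(10.0, 2.0 / (1.0 - r))  # A1(k) ~ 1 - 1/(2k) for large k
    kappa = float(optimize.brentq(lambda k: _a1(k) - r, 1e-12, hi, xtol=1e-12))
    return VonMisesParams(mu=mu, kappa=kappa)


def sample_kernel(gamma: GammaParams, vm: VonMisesParams, size: int,
                  rng: np.random.Generator):
    """Draw (lengths, turning angles) from the fitted kernel."""
    lengths = rng.gamma(gamma.shape, gamma.scale, size=size)
    if vm.kappa == 0.0:
        angles = rng.uniform(-np.pi, np.pi, size=size)
    else:
        angles = rng.vonmises(vm.mu, vm.kappa, size=size)
    return lengths, wrap_angle(angles)


#: Stratum table columns as written to disk.
STRATUM_COLUMNS = [
    "stratum_id", "case", "animal_id", "t_start", "t_end",
    "x1", "y1", "x2", "y2", "sl", "log_sl", "ta", "period", "burst_id",
]


def build_strata(steps: pd.DataFrame, gamma: GammaParams, vm: VonMisesParams,
                 n_available: int = N_AVAILABLE,
                 rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Form used/available strata from observed steps.

    Only steps with a defined turning angle (hence a defined previous heading)
    seed strata.  For each such step, ``n_available`` lengths and turning
    angles are drawn from the kernel; each available endpoint lies at the
    sampled length along ``previous heading + sampled angle`` from the step's
    start.  The observed step is the single ``case = 1`` row of its stratum.

    Sampling order is animal-then-time so results are reproducible under
    subsetting; the same seed gives bit-identical output.
    """
    if n_available < 1:
        raise ConfigurationError("n_available must be >= 1")
    rng = np.random.default_rng(rng)

    usable = steps[np.isfinite(steps["ta"].to_numpy(dtype=float))]
    usable = usable.sort_values(["animal_id", "t_start"], kind="mergesort")
    n = len(usable)
    if n == 0:
        return pd.DataFrame(columns=STRATUM_COLUMNS)

    lengths, angles = sample_kernel(gamma, vm, size=(n * n_available), rng=rng)
    lengths = lengths.reshape(n, n_available)
    angles = angles.reshape(n, n_available)

    prev_heading = (usable["heading"] - usable["ta"]).to_numpy()[:, None]
    abs_heading = prev_heading + angles
    x1 = usable["x1"].to_numpy()[:, None]
    y1 = usable["y1"].to_numpy()[:, None]
    x2a = x1 + lengths * np.cos(abs_heading)
    y2a = y1 + lengths * np.sin(abs_heading)

    m = n_available + 1
    rep = np.repeat(np.arange(n), m)
    case = np.tile(np.r_[1, np.zeros(n_available, dtype=int)], n)
    avail_mask = case == 0

    out = pd.DataFrame({
        "stratum_id": rep,
        "case": case,
        "animal_id": usable["animal_id"].to_numpy()[rep],
        "t_start": usable["t_start"].to_numpy()[rep],
        "t_end": usable["t_end"].to_numpy()[rep],
        "x1": usable["x1"].to_numpy()[rep],
        "y1": usable["y1"].to_numpy()[rep],
        "x2": usable["x2"].to_numpy()[rep],
        "y2": usable["y2"].to_numpy()[rep],
        "sl": usable["sl"].to_numpy()[rep],
        "log_sl": usable["log_sl"].to_numpy()[rep],
        "ta": usable["ta"].to_numpy()[rep],
        "period": usable["period"].to_numpy()[rep],
        "burst_id": usable["burst_id"].to_numpy()[rep],
    })
    out.loc[avail_mask, "x2"] = x2a.ravel()
    out.loc[avail_mask, "y2"] = y2a.ravel()
    out.loc[avail_mask, "sl"] = lengths.ravel()
    out.loc[avail_mask, "log_sl"] = np.log(np.maximum(lengths.ravel(), MIN_STEP_LENGTH))
    out.loc[avail_mask, "ta"] = angles.ravel()
    return out[STRATUM_COLUMNS]


def fit_kernel(steps: pd.DataFrame, per_period: bool = True
               ) -> dict[str, tuple[GammaParams, VonMisesParams]]:
    """Fit the movement kernel, by default separately per dry/wet period.

    Uses all usable observed steps of each period (including steps later
    dropped for missing covariates): the kernel describes movement, not
    habitat.  Returns ``{period: (GammaParams, VonMisesParams)}``; with
    ``per_period=False`` the single pooled fit is stored under ``"all"``.
    """
    groups = steps.groupby("period") if per_period else [("all", steps)]
    out = {}
    for period, grp in groups:
        ta = grp["ta"].to_numpy(dtype=float)
        out[str(period)] = (
            fit_gamma(grp["sl"].to_numpy()),
            fit_vonmises(ta[np.isfinite(ta)]),
        )
    return out


def kernel_to_json(fits: dict, path) -> None:
    """Persist fitted kernel parameters as a small JSON document."""
    doc = {
        period: {"gamma": asdict(g), "vonmises": asdict(v)}
        for period, (g, v) in fits.items()
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def kernel_from_json(path) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    return {
        period: (GammaParams(**d["gamma"]), VonMisesParams(**d["vonmises"]))
        for period, d in doc.items()
    }
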