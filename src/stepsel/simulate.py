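"""Synthetic landscapes and step-selection-driven trajectories with known truth.

The generator emulates the study system: a semi-arid reserve observed through
16-day NDVI composites with a strong seasonal cycle, smooth terrain, a
seasonal temperature field, and GPS-collared animals released in cohorts whose
4-h steps follow a known movement kernel (gamma step lengths, von Mises
turning angles) and a known selection rule.  At every step each animal draws
``n_candidates`` candidate steps from the kernel and selects one with
probability proportional to ``exp(beta*' x)``, where x holds standardized
covariate values at the candidate endpoint and, optionally, experience
interactions and a cohesion bias toward the animal's group centroid.  Because
the generating coefficients, kernel and seeds are recorded (:class:`SimTruth`),
every pipeline stage can be tested by parameter recovery.

All randomness flows from one seed through named substreams (landscape,
release, movement) so stages can be exercised in isolation.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError
from .kernel import GammaParams, VonMisesParams
from .landscape import (Grid, GridSeries, LandscapeStack, compute_andvi,
                        compute_dndvi, compute_tri)

DAY = pd.Timedelta(days=1)
STEP = pd.Timedelta(hours=4)


@dataclass
class SimLandscapeConfig:
    """Synthetic landscape parameters.

    The defaults give a 100 x 100 km domain at the 500-m analysis resolution,
    five years of 16-day NDVI composites (so a 4-year anomaly baseline
    exists), elevation spanning the study reserve's 190-461 m range, and a
    hot, seasonally varying temperature field.
    """

    n_rows: int = 200
    n_cols: int = 200
    cell: float = 500.0
    x0: float = 0.0
    start_year: int = 2016
    n_years: int = 5
    corr_length: float = 5000.0        # m, spatial correlation of NDVI fields
    ndvi_mean: float = 0.22
    ndvi_spatial_sd: float = 0.05
    ndvi_amp: float = 0.15             # seasonal amplitude
    ndvi_peak_doy: int = 260           # greenness peaks after the rains
    ndvi_anom_sd: float = 0.04         # per-composite spatially correlated anomaly
    elev_min: float = 190.0
    elev_max: float = 461.0
    elev_corr_length: float = 10000.0  # m, broad dune/plain structure
    elev_rough_frac: float = 0.3       # fine-scale share (wadis, outcrops)
    elev_rough_corr: float = 1500.0    # m
    temp_mean: float = 29.0            # deg C
    temp_amp: float = 6.0
    temp_peak_doy: int = 135           # hottest before the rains
    temp_lapse: float = -0.0065        # deg C per m elevation
    temp_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.corr_length <= self.cell:
            raise ConfigurationError("correlation length must exceed the cell size")

    @property
    def y0(self) -> float:
        return self.n_rows * self.cell


def _grf(shape, corr_cells: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian random field with given correlation length (cells)."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=corr_cells, mode="wrap")
    return (f - f.mean()) / f.std()


def composite_dates(start_year: int, n_years: int) -> list[pd.Timestamp]:
    """16-day composite start dates, 23 per calendar year from 1 January."""
    out = []
    for year in range(start_year, start_year + n_years):
        jan1 = pd.Timestamp(year=year, month=1, day=1)
        out.extend(jan1 + pd.Timedelta(days=16 * k) for k in range(23))
    return out


def simulate_landscape(config: SimLandscapeConfig):
    """Generate (ndvi series, elevation grid, temperature series).

    NDVI(x, t) = clip(mean field + seasonal cycle + composite anomaly field,
    -0.2, 1.0); the anomaly fields are what aNDVI recovers once the seasonal
    cycle is removed.  Temperature follows its own seasonal cycle plus an
    elevational lapse and correlated noise.  Reproducible under the config
    seed.
    """
    rng = np.random.default_rng([config.seed, 11])  # landscape substream
    nr, nc, cell = config.n_rows, config.n_cols, config.cell
    corr_cells = config.corr_length / cell

    mean_field = config.ndvi_mean + config.ndvi_spatial_sd * _grf((nr, nc), corr_cells, rng)
    amp_field = config.ndvi_amp * (1.0 + 0.3 * _grf((nr, nc), corr_cells, rng))

    # terrain mixes broad structure with fine-scale roughness so the
    # ruggedness index is informative everywhere, not only on rare slopes
    w = config.elev_rough_frac
    elev_field = (np.sqrt(1 - w ** 2) * _grf((nr, nc), config.elev_corr_length / cell, rng)
                  + w * _grf((nr, nc), config.elev_rough_corr / cell, rng))
    lo, hi = elev_field.min(), elev_field.max()
    elev = config.elev_min + (elev_field - lo) / (hi - lo) * (config.elev_max - config.elev_min)
    elevation = Grid(elev, x0=config.x0, y0=config.y0, cell=cell)

    dates = composite_dates(config.start_year, config.n_years)
    ndvi_grids, temp_grids = [], []
    for d in dates:
        phase_n = 2.0 * np.pi * (d.dayofyear - config.ndvi_peak_doy) / 365.0
        anom = config.ndvi_anom_sd * _grf((nr, nc), corr_cells, rng) \
            if config.ndvi_anom_sd > 0 else 0.0
        vals = np.clip(mean_field + amp_field * np.cos(phase_n) + anom, -0.2, 1.0)
        ndvi_grids.append(Grid(vals, x0=config.x0, y0=config.y0, cell=cell))

        phase_t = 2.0 * np.pi * (d.dayofyear - config.temp_peak_doy) / 365.0
        tnoise = config.temp_noise_sd * _grf((nr, nc), corr_cells, rng) \
            if config.temp_noise_sd > 0 else 0.0
        tvals = (config.temp_mean + config.temp_amp * np.cos(phase_t)
                 + config.temp_lapse * (elev - elev.mean()) + tnoise)
        temp_grids.append(Grid(tvals, x0=config.x0, y0=config.y0, cell=cell))

    return (GridSeries(dates=dates, grids=ndvi_grids), elevation,
            GridSeries(dates=list(dates), grids=temp_grids))


def build_stack(ndvi: GridSeries, elevation: Grid, temperature: GridSeries,
                baseline_start, baseline_end, andvi_mode: str = "slot") -> LandscapeStack:
    """Derive aNDVI/dNDVI/TRI and assemble the co-registered covariate stack."""
    return LandscapeStack(
        andvi=compute_andvi(ndvi, baseline_start, baseline_end, mode=andvi_mode),
        dndvi=compute_dndvi(ndvi),
        elevation=elevation,
        tri=compute_tri(elevation),
        temperature=temperature,
        ndvi=ndvi,
    )


def landscape_moments(stack: LandscapeStack, dates=None) -> dict[str, tuple[float, float]]:
    """Landscape-wide (mean, SD) per covariate — the simulation's standardization."""
    def series_stats(series: GridSeries):
        sel = series.grids if dates is None else [
            series.grids[int(i)] for i in np.unique(series.layer_index_for(dates))]
        vals = np.concatenate([g.values.ravel() for g in sel])
        return float(np.nanmean(vals)), float(np.nanstd(vals))

    out = {
        "aNDVI": series_stats(stack.andvi),
        "dNDVI": series_stats(stack.dndvi),
        "temperature": series_stats(stack.temperature),
        "elevation": (float(np.nanmean(stack.elevation.values)),
                      float(np.nanstd(stack.elevation.values))),
        "TRI": (float(np.nanmean(stack.tri.values)), float(np.nanstd(stack.tri.values))),
    }
    return out


@dataclass
class SimTruth:
    """The generating parameters of a synthetic dataset — the recovery oracle."""

    beta: dict[str, float]
    gamma: GammaParams
    vonmises: VonMisesParams
    moments: dict[str, tuple[float, float]]
    release_dates: dict[str, pd.Timestamp]
    group_attraction: float = 0.0
    group_of: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path) -> None:
        doc = {
            "beta": self.beta,
            "gamma": asdict(self.gamma),
            "vonmises": asdict(self.vonmises),
            "moments": {k: list(v) for k, v in self.moments.items()},
            "release_dates": {k: str(v) for k, v in self.release_dates.items()},
            "group_attraction": self.group_attraction,
            "group_of": self.group_of,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)


_ENV = ["aNDVI", "dNDVI", "elevation", "TRI", "temperature"]


def _env_at(stack: LandscapeStack, x, y, t) -> dict[str, np.ndarray]:
    """Covariate values at points for one timestamp (most recent composite)."""
    out = {}
    for name, series in (("aNDVI", stack.andvi), ("dNDVI", stack.dndvi),
                         ("temperature", stack.temperature)):
        li = int(series.layer_index_for(t)[0])
        out[name] = series.grids[li].value_at(x, y)
    out["elevation"] = stack.elevation.value_at(x, y)
    out["TRI"] = stack.tri.value_at(x, y)
    return out


def _reflect(v, lo, hi):
    """Reflect coordinates into [lo, hi] (step lengths are << domain size)."""
    v = np.where(v < lo, 2 * lo - v, v)
    v = np.where(v > hi, 2 * hi - v, v)
    return np.clip(v, lo, hi)


def simulate_tracks(stack: LandscapeStack, truth: SimTruth,
                    n_steps: int, n_candidates: int = 500,
                    start_positions: dict[str, tuple[float, float]] | None = None,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Forward-simulate 4-h trajectories under the known selection rule.

    Each animal starts at its release date (animals may be released in
    cohorts), draws ``n_candidates`` kernel steps per 4-h interval and selects
    one with probability proportional to ``exp(u)``,

        u = sum_env beta_env z_env + sum_int beta_int z_mod z_env + cohesion,

    with z values standardized by ``truth.moments``.  The discrete choice
    among ``n_candidates`` kernel draws converges to the continuous
    step-selection density as the candidate count grows; the default of 500
    keeps the residual discretisation bias of the generating process well
    below the sampling error of a fitted coefficient (a few hundred
    candidates is the empirical knee for smooth landscapes).  Off-grid candidates are reflected at the domain boundary.
    Returns a fix table consumable by the tracks stage.
    """
    rng = np.random.default_rng(rng if rng is not None else [truth.seed, 23])
    animals = list(truth.release_dates)
    n_anim = len(animals)
    releases = pd.DatetimeIndex([truth.release_dates[a] for a in animals])
    t0 = releases.min()
    offsets = ((releases - t0) / STEP).to_numpy()
    if not np.allclose(offsets, np.round(offsets)):
        raise ConfigurationError("release dates must be whole 4-h intervals apart")
    offsets = np.round(offsets).astype(int)

    ref = stack.elevation
    xlo, xhi = ref.x0 + ref.cell, ref.x0 + ref.shape[1] * ref.cell - ref.cell
    ylo, yhi = ref.y0 - ref.shape[0] * ref.cell + ref.cell, ref.y0 - ref.cell

    if start_positions is None:
        cx, cy = (xlo + xhi) / 2.0, (ylo + yhi) / 2.0
        pos = np.column_stack([
            cx + rng.uniform(-2000, 2000, n_anim),
            cy + rng.uniform(-2000, 2000, n_anim),
        ])
    else:
        pos = np.array([start_positions[a] for a in animals], dtype=float)
    heading = rng.uniform(-np.pi, np.pi, n_anim)

    env_terms = [c for c in truth.beta if ":" not in c and c in _ENV]
    exp_terms, gs_terms = [], []
    for c in truth.beta:
        if ":" not in c:
            continue
        base, moderator = c.split(":")
        if base not in _ENV:
            raise ConfigurationError(f"unsupported truth interaction base in {c!r}")
        if moderator == "experience":
            exp_terms.append(c)
        elif moderator == "group_size":
            gs_terms.append(c)
        else:
            raise ConfigurationError(f"unsupported truth moderator in {c!r}")
    need_groups = bool(gs_terms) or truth.group_attraction > 0

    group_ids = np.array([truth.group_of.get(a, -1) for a in animals])

    rows = {a: [] for a in animals}
    for i, a in enumerate(animals):
        rows[a].append((releases[i], pos[i, 0], pos[i, 1]))

    total_steps = n_steps + int(offsets.max())
    for step_i in range(total_steps):
        t_end = t0 + (step_i + 1) * STEP
        active = (offsets <= step_i) & (step_i < offsets + n_steps)
        if not active.any():
            continue
        idx = np.flatnonzero(active)
        na = len(idx)

        lengths = rng.gamma(truth.gamma.shape, truth.gamma.scale, size=(na, n_candidates))
        if truth.vonmises.kappa == 0:
            turns = rng.uniform(-np.pi, np.pi, size=(na, n_candidates))
        else:
            turns = rng.vonmises(truth.vonmises.mu, truth.vonmises.kappa,
                                 size=(na, n_candidates))
        head = heading[idx, None] + turns
        ex = _reflect(pos[idx, 0:1] + lengths * np.cos(head), xlo, xhi)
        ey = _reflect(pos[idx, 1:2] + lengths * np.sin(head), ylo, yhi)

        env = _env_at(stack, ex.ravel(), ey.ravel(), t_end)
        u = np.zeros((na, n_candidates))
        exp_days = ((t_end - STEP) - releases[idx]) / DAY  # experience at step start
        e_mean, e_sd = truth.moments.get("experience", (0.0, 1.0))
        e_std = ((np.asarray(exp_days, dtype=float) - e_mean) / e_sd)[:, None]
        gs_std = None
        if gs_terms:
            # chain-rule group size at the step's start positions
            from .social import detect_groups
            g = detect_groups(pd.DataFrame({"animal_id": idx,
                                            "x": pos[idx, 0], "y": pos[idx, 1]}))
            g_mean, g_sd = truth.moments.get("group_size", (1.0, 1.0))
            gs_std = ((g["group_size"].to_numpy(dtype=float) - g_mean) / g_sd)[:, None]
        for c in env_terms:
            mean, sd = truth.moments[c]
            u += truth.beta[c] * (env[c].reshape(na, n_candidates) - mean) / sd
        for c in exp_terms:
            base, _ = c.split(":")
            mean, sd = truth.moments[base]
            z = (env[base].reshape(na, n_candidates) - mean) / sd
            u += truth.beta[c] * e_std * z
        for c in gs_terms:
            base, _ = c.split(":")
            mean, sd = truth.moments[base]
            z = (env[base].reshape(na, n_candidates) - mean) / sd
            u += truth.beta[c] * gs_std * z

        if truth.group_attraction > 0:
            for g in np.unique(group_ids[idx]):
                if g < 0:
                    continue
                members = idx[group_ids[idx] == g]
                if len(members) < 2:
                    continue
                # pull each member toward the centroid of its groupmates
                # (self excluded, so stragglers feel the full gradient)
                total = pos[members].sum(axis=0)
                for m in members:
                    centroid = (total - pos[m]) / (len(members) - 1)
                    sel = idx == m
                    d = np.hypot(ex[sel] - centroid[0], ey[sel] - centroid[1])
                    u[sel] -= truth.group_attraction * d / 1000.0  # per-km cost

        # Gumbel-max trick: softmax sampling in one vectorised draw
        gumbel = -np.log(-np.log(rng.uniform(size=(na, n_candidates))))
        choice = np.argmax(u + gumbel, axis=1)

        ar = np.arange(na)
        newx, newy = ex[ar, choice], ey[ar, choice]
        heading[idx] = np.arctan2(newy - pos[idx, 1], newx - pos[idx, 0])
        pos[idx, 0], pos[idx, 1] = newx, newy
        for j, i_anim in enumerate(idx):
            rows[animals[i_anim]].append((t_end, newx[j], newy[j]))

    parts = []
    for i, a in enumerate(animals):
        df = pd.DataFrame(rows[a], columns=["t", "x", "y"])
        df.insert(0, "animal_id", a)
        df["release_date"] = releases[i]
        parts.append(df)
    return pd.concat(parts, ignore_index=True)


def make_fixture(profile: str, seed: int = 0):
    """Build a named synthetic dataset: ``tiny``, ``recovery`` or ``grouped``.

    * ``tiny`` — 2 animals x 50 steps on a small landscape; fast end-to-end runs.
    * ``recovery`` — 15 animals x 300 steps with known selection coefficients
      over four environmental terms and two experience interactions; the
      coefficient-recovery benchmark.
    * ``grouped`` — 12 animals in 3 cohesive groups of 4; chain-rule tests.
    * ``moderated`` — 9 animals in 3 loose groups whose selection truly
      depends on experience and group size; the M4 candidate is correct.
    * ``null`` — 9 animals with environmental selection only; the
      environment-only candidate M1 is correct.

    Returns ``(fixes, stack, truth)``.
    """
    if profile == "tiny":
        cfg = SimLandscapeConfig(n_rows=40, n_cols=40, n_years=5, seed=seed)
        n_animals, n_steps = 2, 50
        beta = {"aNDVI": 0.5, "TRI": -0.5}
        # loose cohesion so the pair repeatedly splits and rejoins, giving the
        # group-size moderator within-track variation
        attraction = 5.0
        groups = {"oryx00": 0, "oryx01": 0}
    elif profile == "recovery":
        cfg = SimLandscapeConfig(n_rows=80, n_cols=80, n_years=5, seed=seed)
        n_animals, n_steps = 15, 300
        beta = {"aNDVI": 0.5, "dNDVI": -0.3, "elevation": 0.25, "TRI": -0.4,
                "aNDVI:experience": -0.25, "TRI:experience": 0.3}
        attraction, groups = 0.0, {}
    elif profile == "grouped":
        cfg = SimLandscapeConfig(n_rows=60, n_cols=60, n_years=5, seed=seed)
        n_animals, n_steps = 12, 60
        beta = {"aNDVI": 0.3}
        attraction = 25.0
        groups = {f"oryx{i:02d}": i % 3 for i in range(n_animals)}
    elif profile == "moderated":
        # both moderators truly shape selection: the M4 candidate is correct.
        # Unequal planted group sizes (1/3/5) give the group-size moderator
        # between-animal variation on top of split-rejoin dynamics; the
        # moderated covariates (TRI, dNDVI) vary at fine scale, so their
        # interactions carry real within-animal information.
        cfg = SimLandscapeConfig(n_rows=60, n_cols=60, n_years=5, seed=seed,
                                 corr_length=2000.0, elev_corr_length=4000.0)
        n_animals, n_steps = 9, 150
        beta = {"aNDVI": 0.4, "dNDVI": -0.2, "elevation": 0.2, "TRI": -0.4,
                "dNDVI:experience": -0.5, "TRI:experience": 0.6,
                "dNDVI:group_size": -0.25, "TRI:group_size": 0.3}
        attraction = 6.0
        groups = {f"oryx{i:02d}": g
                  for i, g in enumerate([0, 1, 1, 1, 2, 2, 2, 2, 2])}
    elif profile == "null":
        # environmental selection only; any moderator signal is spurious
        cfg = SimLandscapeConfig(n_rows=60, n_cols=60, n_years=5, seed=seed,
                                 corr_length=2000.0, elev_corr_length=4000.0)
        n_animals, n_steps = 9, 150
        beta = {"aNDVI": 0.4, "dNDVI": -0.2, "elevation": 0.2, "TRI": -0.4}
        attraction, groups = 0.0, {}
    else:
        raise ConfigurationError(f"unknown fixture profile {profile!r}")

    ndvi, elevation, temperature = simulate_landscape(cfg)
    last_year = cfg.start_year + cfg.n_years - 1
    stack = build_stack(ndvi, elevation, temperature,
                        baseline_start=f"{cfg.start_year}-01-01",
                        baseline_end=f"{cfg.start_year + 3}-12-31")

    # tracks run in the final simulated year, after the anomaly baseline
    release = pd.Timestamp(f"{last_year}-03-01")
    animals = [f"oryx{i:02d}" for i in range(n_animals)]
    # two release cohorts 20 days apart, as for a staged reintroduction
    releases = {a: release + (0 if i < (n_animals + 1) // 2 else 20) * DAY
                for i, a in enumerate(animals)}
    if profile in ("grouped", "tiny", "moderated"):
        releases = {a: release for a in animals}
    if profile == "null":
        # shared release area so chance encounters give the group-size
        # moderator nonzero variance without any cohesion mechanism
        releases = {a: release for a in animals}

    span_days = n_steps * 4 / 24
    moments = landscape_moments(stack)
    moments["experience"] = (span_days / 2.0, max(span_days / 3.5, 1.0))
    moments["group_size"] = (3.0, 1.6)

    truth = SimTruth(beta=beta, gamma=GammaParams(shape=2.0, scale=300.0),
                     vonmises=VonMisesParams(mu=0.0, kappa=1.0),
                     moments=moments, release_dates=releases,
                     group_attraction=attraction, group_of=groups, seed=seed)

    rng = np.random.default_rng([seed, 23])
    start_positions = None
    if profile == "null":
        ref = stack.elevation
        cx = ref.x0 + ref.shape[1] * ref.cell / 2.0
        cy = ref.y0 - ref.shape[0] * ref.cell / 2.0
        start_positions = {a: (cx + rng.uniform(-800, 800),
                               cy + rng.uniform(-800, 800)) for a in animals}
    if groups:
        ref = stack.elevation
        cx = ref.x0 + ref.shape[1] * ref.cell / 2.0
        cy = ref.y0 - ref.shape[0] * ref.cell / 2.0
        centers = {0: (cx - 6000, cy), 1: (cx + 6000, cy), 2: (cx, cy + 6000)}
        start_positions = {
            a: (centers[groups[a]][0] + rng.uniform(-50, 50),
                centers[groups[a]][1] + rng.uniform(-50, 50))
            for a in animals
        }
    fixes = simulate_tracks(stack, truth, n_steps=n_steps,
                            start_positions=start_positions, rng=rng)
    return fixes, stack, truth


def write_fixture(fixes: pd.DataFrame, stack: LandscapeStack, truth: SimTruth,
                  outdir) -> None:
    """Persist a fixture in the pipeline's input dialects (CSV + ASCII grids +
    JSON truth manifest)."""
    from pathlib import Path

    from .landscape import write_ascii_grid

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fixes.to_csv(outdir / "fixes.csv", index=False)
    if stack.ndvi is not None:
        stack.ndvi.write(outdir / "layers", "ndvi")
    stack.temperature.write(outdir / "layers", "temperature")
    write_ascii_grid(stack.elevation, outdir / "layers" / "elevation.asc")
    truth.to_json(outdir / "truth.json")
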