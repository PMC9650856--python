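"""GPS fix ingestion, regularisation to a fixed interval, and step construction.

A *fix* is a time-stamped projected position for one animal.  Fixes are
regularised onto a common sampling interval (4 h by default, matching a mixed
1/2/4-h collar schedule) by greedy forward selection; contiguous runs at that
interval form *bursts*, and consecutive fixes within a burst form *steps*
carrying step length, absolute heading and turning angle.  The turning angle of
the first step of a burst is undefined (no prior heading) and such steps cannot
seed a used/available stratum.

Calendar seasons follow the Sahelian rainfall regime: months January-June are
the "dry" period, July-December the "wet" period.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

#: Canonical fix-table columns after ingestion.
FIX_COLUMNS = ["animal_id", "t", "x", "y", "release_date"]

#: Canonical step-table column order for on-disk output.
STEP_COLUMNS = [
    "animal_id", "t_start", "t_end", "x1", "y1", "x2", "y2",
    "sl", "log_sl", "heading", "ta", "period", "burst_id",
]

#: Floor (metres) applied to zero step lengths so log step length stays finite.
#: One metre is well below GPS positional error.
MIN_STEP_LENGTH = 1.0


def wrap_angle(a):
    """Wrap angles (radians) into (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    wrapped = -((-a + np.pi) % (2.0 * np.pi) - np.pi)
    return wrapped if wrapped.ndim else float(wrapped)


def assign_period(timestamps) -> np.ndarray | str:
    """Label timestamps 'dry' (Jan-Jun) or 'wet' (Jul-Dec) by calendar month."""
    ts = pd.DatetimeIndex(np.atleast_1d(np.asarray(timestamps, dtype="datetime64[ns]")))
    out = np.where(ts.month <= 6, "dry", "wet")
    return out if out.size > 1 else str(out[0])


def read_fixes(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a delimited fix table into the canonical layout.

    Parameters
    ----------
    path : str or file-like
        CSV with one row per GPS fix.
    column_map : dict, optional
        Maps canonical names (``animal_id``, ``t``, ``x``, ``y``,
        ``release_date``) to the file's column names.

    Returns
    -------
    DataFrame sorted by animal then time, duplicate (animal, timestamp) rows
    collapsed to the first occurrence (one warning reports the count).

    Raises
    ------
    ConfigurationError
        A required column is absent after mapping, or coordinates look like
        unprojected lon/lat degrees.
    DataError
        One or more timestamps failed to parse; the message lists row numbers.
    """
    raw = pd.read_csv(path)
    column_map = column_map or {}
    rename = {v: k for k, v in column_map.items()}
    raw = raw.rename(columns=rename)

    missing = [c for c in FIX_COLUMNS if c not in raw.columns]
    if missing:
        raise ConfigurationError(f"fix table is missing required column(s): {missing}")

    df = raw[FIX_COLUMNS].copy()
    for col in ("t", "release_date"):
        parsed = pd.to_datetime(df[col], errors="coerce", utc=True, format="ISO8601")
        bad = np.flatnonzero(parsed.isna().to_numpy() & df[col].notna().to_numpy())
        if len(bad) or parsed.isna().any():
            rows = np.flatnonzero(parsed.isna().to_numpy())
            raise DataError(
                f"unparseable {col!r} in {len(rows)} row(s): "
                f"{(rows + 2).tolist()[:20]} (1-based file lines incl. header)"
            )
        df[col] = parsed.dt.tz_localize(None)

    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            rows = np.flatnonzero(vals.isna().to_numpy())
            raise DataError(f"non-numeric {col!r} in row(s) {(rows + 2).tolist()[:20]}")
        df[col] = vals.astype(float)
    if not np.isfinite(df[["x", "y"]].to_numpy()).all():
        raise DataError("non-finite coordinates in fix table")

    # Projected metre coordinates expected; lon/lat degrees are rejected rather
    # than silently reprojected.
    if (df["x"].abs() <= 180).all() and (df["y"].abs() <= 90).all():
        raise ConfigurationError(
            "coordinates look like lon/lat degrees; supply projected metres (e.g. UTM)"
        )

    if (df["release_date"] > df["t"]).any():
        raise DataError("fix timestamp precedes the animal's release date")

    df = df.sort_values(["animal_id", "t"], kind="mergesort").reset_index(drop=True)
    n_before = len(df)
    df = df.drop_duplicates(subset=["animal_id", "t"], keep="first").reset_index(drop=True)
    n_dup = n_before - len(df)
    if n_dup:
        warnings.warn(f"dropped {n_dup} duplicate (animal, timestamp) fix(es)", stacklevel=2)
    return df


def resample_to_interval(
    fixes: pd.DataFrame,
    interval: pd.Timedelta = pd.Timedelta(hours=4),
    tolerance: pd.Timedelta = pd.Timedelta(minutes=30),
    min_burst_fixes: int = 3,
) -> pd.DataFrame:
    """Regularise fixes to a fixed interval by greedy forward selection.

    From each anchor fix the fix nearest ``anchor + interval`` within
    ``+- tolerance`` is retained and becomes the next anchor.  When no fix
    falls in the window the burst closes and a new one opens at the next
    unconsumed fix.  Bursts with fewer than ``min_burst_fixes`` fixes are
    dropped (they cannot yield a turning angle) with a logged count.

    Returns the retained fixes with a ``burst_id`` column.
    """
    interval = pd.Timedelta(interval)
    tolerance = pd.Timedelta(tolerance)
    if interval <= pd.Timedelta(0):
        raise ConfigurationError("resampling interval must be positive")
    if tolerance < pd.Timedelta(0) or tolerance >= interval:
        raise ConfigurationError("tolerance must be in [0, interval)")

    kept_parts: list[pd.DataFrame] = []
    burst_id = 0
    n_dropped_bursts = 0

    interval_ns = interval.value
    tolerance_ns = tolerance.value
    for _, grp in fixes.groupby("animal_id", sort=False):
        t = grp["t"].to_numpy("datetime64[ns]").astype(np.int64)
        n = len(grp)
        i = 0
        while i < n:
            members = [i]
            while True:
                target = t[members[-1]] + interval_ns
                lo = np.searchsorted(t, target - tolerance_ns, side="left")
                hi = np.searchsorted(t, target + tolerance_ns, side="right")
                lo = max(lo, members[-1] + 1)
                if lo >= hi:
                    break
                members.append(lo + int(np.argmin(np.abs(t[lo:hi] - target))))
            if len(members) >= min_burst_fixes:
                part = grp.iloc[members].copy()
                part["burst_id"] = burst_id
                kept_parts.append(part)
                burst_id += 1
            else:
                n_dropped_bursts += 1
            # next burst opens at the first fix after the last member
            i = members[-1] + 1

    if n_dropped_bursts:
        logger.info("resample_to_interval: dropped %d burst(s) with < %d fixes",
                    n_dropped_bursts, min_burst_fixes)
    if not kept_parts:
        return fixes.iloc[0:0].assign(burst_id=pd.Series(dtype=int))
    return pd.concat(kept_parts, ignore_index=True)


def build_steps(bursts: pd.DataFrame) -> pd.DataFrame:
    """Convert burst fixes into steps with length, heading and turning angle.

    One step per consecutive fix pair within a burst.  Heading is
    ``atan2(dy, dx)``; the turning angle is the wrapped difference between the
    step's heading and the previous step's heading, undefined (NaN) for the
    first step of each burst.  Zero step lengths are floored at
    :data:`MIN_STEP_LENGTH` so the log transform stays finite.
    """
    parts = []
    for burst_id, grp in bursts.groupby("burst_id", sort=True):
        if len(grp) < 2:
            continue
        x = grp["x"].to_numpy()
        y = grp["y"].to_numpy()
        t = grp["t"].to_numpy()
        dx, dy = np.diff(x), np.diff(y)
        sl = np.hypot(dx, dy)
        sl = np.where(sl <= 0.0, MIN_STEP_LENGTH, sl)
        heading = np.arctan2(dy, dx)
        ta = np.full(len(sl), np.nan)
        ta[1:] = wrap_angle(np.diff(heading))
        parts.append(pd.DataFrame({
            "animal_id": grp["animal_id"].iloc[0],
            "t_start": t[:-1], "t_end": t[1:],
            "x1": x[:-1], "y1": y[:-1], "x2": x[1:], "y2": y[1:],
            "sl": sl, "log_sl": np.log(np.maximum(sl, MIN_STEP_LENGTH)),
            "heading": heading, "ta": ta,
            "period": assign_period(t[:-1]) if len(sl) > 1 else [assign_period(t[0])],
            "burst_id": burst_id,
        }))
    if not parts:
        return pd.DataFrame(columns=STEP_COLUMNS)
    steps = pd.concat(parts, ignore_index=True)
    return steps[STEP_COLUMNS]


def write_steps(steps: pd.DataFrame, path) -> None:
    """Write the step table as CSV in the documented column order."""
    steps[STEP_COLUMNS].to_csv(path, index=False)
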