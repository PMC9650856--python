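"""Social and experience moderators.

Group membership follows the chain rule: within one 4-h time bin, any two
animals at most ``threshold`` metres apart are linked, and groups are the
connected components of that proximity graph, so an animal 150 m from a second
that is itself 150 m from a third belongs to one group of three even if the
outer pair is 300 m apart.  A lone animal is a group of size 1.  Experience is
the (fractional) number of days an animal has spent in the landscape since its
release.  Both moderators are constant within a stratum: they are evaluated at
the stratum's start fix and replicated to the used and all available rows.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .errors import DataError

GROUP_THRESHOLD = 200.0  # metres


def detect_groups(positions: pd.DataFrame, threshold: float = GROUP_THRESHOLD
                  ) -> pd.DataFrame:
    """Partition one time bin's animals into chain-rule groups.

    ``positions`` has one row per animal (``animal_id``, ``x``, ``y``).
    Returns ``animal_id``, ``group_id``, ``group_size``.
    """
    if positions["animal_id"].duplicated().any():
        raise DataError("at most one position per animal per bin")
    n = len(positions)
    if n == 0:
        return pd.DataFrame(columns=["animal_id", "group_id", "group_size"])
    pts = positions[["x", "y"]].to_numpy(dtype=float)
    pairs = cKDTree(pts).query_pairs(r=threshold, output_type="ndarray")
    adj = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels)
    return pd.DataFrame({
        "animal_id": positions["animal_id"].to_numpy(),
        "group_id": labels,
        "group_size": sizes[labels],
    })


def groups_by_bin(fixes: pd.DataFrame, threshold: float = GROUP_THRESHOLD,
                  bin_width: pd.Timedelta = pd.Timedelta(hours=4)) -> pd.DataFrame:
    """Chain-rule grouping for every time bin of a resampled fix table.

    Each animal contributes its single resampled fix per bin; animals with no
    fix in a bin are absent from that bin's graph.  Returns ``bin_start``,
    ``animal_id``, ``group_id``, ``group_size``.
    """
    fx = fixes.copy()
    fx["bin_start"] = fx["t"].dt.floor(bin_width)
    fx = fx.drop_duplicates(subset=["bin_start", "animal_id"], keep="first")
    parts = []
    for bin_start, grp in fx.groupby("bin_start", sort=True):
        g = detect_groups(grp[["animal_id", "x", "y"]], threshold=threshold)
        g.insert(0, "bin_start", bin_start)
        parts.append(g)
    if not parts:
        return pd.DataFrame(columns=["bin_start", "animal_id", "group_id", "group_size"])
    return pd.concat(parts, ignore_index=True)


def experience_days(timestamps, release_dates) -> np.ndarray:
    """Fractional days since release; negative values are a data error."""
    t = pd.DatetimeIndex(np.atleast_1d(timestamps))
    r = pd.DatetimeIndex(np.atleast_1d(release_dates))
    days = (t - r).total_seconds() / 86400.0
    days = np.asarray(days, dtype=float)
    if (days < 0).any():
        raise DataError("fix timestamp precedes release date")
    return days


def attach_moderators(strata: pd.DataFrame, groups: pd.DataFrame,
                      release_dates: pd.Series,
                      bin_width: pd.Timedelta = pd.Timedelta(hours=4)) -> pd.DataFrame:
    """Join group size and experience onto strata (constant within stratum).

    Both moderators come from the stratum's start fix: the group table entry
    for (animal, start bin) and days since the animal's release date.
    ``release_dates`` maps animal_id -> release date.
    """
    out = strata.copy()
    out["_bin"] = pd.DatetimeIndex(out["t_start"]).floor(bin_width)
    key = groups.set_index(["animal_id", "bin_start"])["group_size"]
    idx = pd.MultiIndex.from_frame(out[["animal_id", "_bin"]])
    joined = key.reindex(idx)
    if joined.isna().any():
        missing = out.loc[joined.isna().to_numpy(), ["stratum_id", "animal_id", "_bin"]]
        raise DataError(
            "no group record for strata (animal, bin): "
            f"{missing.drop_duplicates().head(10).to_dict('records')}"
        )
    out["group_size"] = joined.to_numpy(dtype=float)
    rel = out["animal_id"].map(release_dates)
    if rel.isna().any():
        raise DataError("missing release date for some animals")
    out["experience"] = experience_days(out["t_start"].to_numpy(), rel.to_numpy())
    return out.drop(columns=["_bin"])
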