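"""Cluster-survey tables and design-weighted counts.

The working container is a pandas DataFrame with one row per survey cluster
(primary sampling unit).  Required columns:

    cluster_id  text or int identifier
    x, y        planar coordinates (km) of the cluster centroid
    urban       bool strata flag
    n           children with a valid height-for-age Z score
    y_stunted   children stunted (HAZ < -2)
    weight      positive survey weight

Covariate columns follow (any names; the model spec lists which to use).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["cluster_id", "x", "y", "urban", "n", "y_stunted", "weight"]


def validate_cluster_table(table: pd.DataFrame, covariates: list[str] | None = None) -> pd.DataFrame:
    """Validate invariants of a cluster table; returns the table unchanged.

    Raises ValueError on missing columns, y > n, non-positive weights or
    non-finite coordinates.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cluster table missing columns: {missing}")
    if (table["y_stunted"] > table["n"]).any():
        raise ValueError("y_stunted exceeds n in at least one cluster")
    if (table["y_stunted"] < 0).any() or (table["n"] < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table["weight"] <= 0).any():
        raise ValueError("survey weights must be positive")
    if not np.isfinite(table[["x", "y"]].to_numpy(dtype=float)).all():
        raise ValueError("cluster coordinates must be finite")
    for c in covariates or []:
        if c not in table.columns:
            raise ValueError(f"covariate column {c!r} not in table")
    return table


def weighted_counts(data: pd.DataFrame) -> pd.DataFrame:
    """Design-weighted effective counts per cluster.

    Accepts either child-level microdata (columns ``cluster_id``, ``stunted``
    in {0,1}, ``weight``) or a cluster-level table.  For microdata the
    weighted prevalence p_d = sum(w_i * stunted_i) / sum(w_i) is computed per
    cluster, the effective denominator stays at the observed child count n_d,
    and the effective numerator is round(p_d * n_d).  For a cluster-level
    table (a single weight per cluster) the weight cancels within the cluster
    and the counts pass through unchanged.

    Clusters with zero total weight are dropped with a log entry.
    """
    if "stunted" in data.columns:  # child-level microdata
        rows = []
        dropped = 0
        for cid, grp in data.groupby("cluster_id", sort=False):
            w = grp["weight"].to_numpy(dtype=float)
            s = grp["stunted"].to_numpy(dtype=float)
            wsum = w.sum()
            if wsum <= 0:
                dropped += 1
                continue
            n_d = len(grp)
            p_hat = float((w * s).sum() / wsum)
            rows.append({"cluster_id": cid, "n": n_d, "y_stunted": int(round(p_hat * n_d)),
                         "weighted_prevalence": p_hat})
        if dropped:
            logger.warning("weighted_counts: dropped %d clusters with zero total weight", dropped)
        out = pd.DataFrame(rows)
    else:
        out = data.copy()
        bad = out["weight"] <= 0
        if bad.any():
            logger.warning("weighted_counts: dropped %d clusters with non-positive weight", int(bad.sum()))
            out = out[~bad]
        with np.errstate(invalid="ignore"):
            out["weighted_prevalence"] = np.where(out["n"] > 0, out["y_stunted"] / out["n"], np.nan)
    assert ((out["y_stunted"] >= 0) & (out["y_stunted"] <= out["n"])).all()
    return out


def national_weighted_prevalence(y_total, n_total) -> float:
    """National prevalence in percent: 100 * sum(y_eff) / sum(n_eff)."""
    y_total, n_total = float(np.sum(y_total)), float(np.sum(n_total))
    if n_total <= 0:
        raise ValueError("total effective sample size must be positive")
    return 100.0 * y_total / n_total
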