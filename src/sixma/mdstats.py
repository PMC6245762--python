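"""Trajectory statistics for base-pair structural parameters.

Computes per-position, per-parameter means and fluctuations (s.d.) over
snapshots, with standard errors from block averaging: trajectories are
autocorrelated, so naive SEMs underestimate the error; splitting the series
into contiguous blocks and treating block summaries as independent samples
restores an honest error bar. Differences between a modified (6mA-bearing)
and unmodified duplex are reported as distance-from-site profiles, averaged
over the upstream and downstream directions, with errors propagated
root-sum-square.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import StepParameterSeries


def param_stats(series: StepParameterSeries, block_len: int = 100) -> pd.DataFrame:
    """Mean, s.d. (population convention) and block-averaged SEMs.

    Returns a DataFrame with columns parameter, position, mean, sd,
    sem_mean, sem_sd; n_blocks = floor(n_snapshots / block_len), and the
    trailing partial block is dropped.
    """
    if block_len < 2:
        raise ValueError("block_len must be >= 2")
    n = series.n_snapshots
    if n < 2 * block_len:
        raise ValueError("need at least two full blocks of snapshots")
    n_blocks = n // block_len
    vals = series.values[:, :, : n_blocks * block_len]
    blocks = vals.reshape(vals.shape[0], vals.shape[1], n_blocks, block_len)

    mean = vals.mean(axis=2)
    sd = vals.std(axis=2)  # population (divide by n)
    block_means = blocks.mean(axis=3)
    block_sds = blocks.std(axis=3)
    sem_mean = block_means.std(axis=2, ddof=1) / np.sqrt(n_blocks)
    sem_sd = block_sds.std(axis=2, ddof=1) / np.sqrt(n_blocks)

    npar, npos = mean.shape
    par_idx, pos_idx = np.meshgrid(np.arange(npar), np.arange(npos),
                                   indexing="ij")
    return pd.DataFrame({
        "parameter": np.array(series.parameters)[par_idx.ravel()],
        "position": pos_idx.ravel(),
        "mean": mean.ravel(),
        "sd": sd.ravel(),
        "sem_mean": sem_mean.ravel(),
        "sem_sd": sem_sd.ravel(),
    })


def delta_profiles(
    modified: pd.DataFrame,
    unmodified: pd.DataFrame,
    modification_site: int,
) -> pd.DataFrame:
    """Modification-induced changes as a function of distance from the site.

    Per parameter and distance d >= 0: delta_mean and delta_sd (modified -
    unmodified), averaged over the symmetric positions site-d and site+d;
    percent_sd_change relative to the unmodified s.d.; SEM columns propagated
    as root-sum-square. Raises if the two stat tables do not share the same
    (parameter, position) grid.
    """
    key = ["parameter", "position"]
    a = modified.sort_values(key).reset_index(drop=True)
    b = unmodified.sort_values(key).reset_index(drop=True)
    if len(a) != len(b) or not (
        (a["parameter"].to_numpy() == b["parameter"].to_numpy()).all()
        and (a["position"].to_numpy() == b["position"].to_numpy()).all()
    ):
        raise ValueError("modified and unmodified stats on different grids")

    merged = a[key].copy()
    merged["delta_mean"] = a["mean"].to_numpy() - b["mean"].to_numpy()
    merged["delta_sd"] = a["sd"].to_numpy() - b["sd"].to_numpy()
    merged["sd_unmod"] = b["sd"].to_numpy()
    merged["sem_dmean"] = np.hypot(a["sem_mean"], b["sem_mean"])
    merged["sem_dsd"] = np.hypot(a["sem_sd"], b["sem_sd"])
    merged["distance"] = (merged["position"] - modification_site).abs()

    rows = []
    for (param, d), sub in merged.groupby(["parameter", "distance"], sort=True):
        k = len(sub)  # 1 at the site or near an edge, else 2
        dmean = sub["delta_mean"].mean()
        dsd = sub["delta_sd"].mean()
        sd_un = sub["sd_unmod"].mean()
        rows.append({
            "parameter": param,
            "distance": int(d),
            "delta_mean": dmean,
            "delta_sd": dsd,
            "percent_sd_change": 100.0 * dsd / sd_un if sd_un > 0 else np.nan,
            "sem_delta_mean": np.sqrt((sub["sem_dmean"] ** 2).sum()) / k,
            "sem_delta_sd": np.sqrt((sub["sem_dsd"] ** 2).sum()) / k,
            "n_positions": k,
        })
    return pd.DataFrame(rows)


def site_window_average(
    delta: pd.DataFrame, half_width: int = 1
) -> pd.DataFrame:
    """Per-parameter average s.d. change over the (2*half_width+1)-bp window
    centered on the modification site (distance <= half_width, with the
    symmetric distances counted once per flank)."""
    rows = []
    for param, sub in delta.groupby("parameter", sort=True):
        sel = sub[sub["distance"] <= half_width]
        # weight each distance by how many positions it represents
        w = sel["n_positions"].to_numpy(dtype=float)
        rows.append({
            "parameter": param,
            "mean_delta_sd": float(np.average(sel["delta_sd"], weights=w)),
            "mean_percent_sd_change": float(
                np.average(sel["percent_sd_change"], weights=w)
            ),
            "mean_delta_mean": float(np.average(sel["delta_mean"], weights=w)),
        })
    return pd.DataFrame(rows)
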