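"""Nucleosome occupancy, center calling and fuzziness from MNase fragments.

Fragments are reduced to their midpoints (the standard MNase convention: the
midpoint of a ~147-bp protected fragment estimates the dyad). A Gaussian
kernel density over midpoints gives the occupancy track; centers are greedy
local maxima with a minimum mutual spacing; fuzziness is the spread (s.d.,
population convention) of the midpoints assigned to each center — low
fuzziness means a well-phased, consistently positioned nucleosome across the
cell population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import argrelmax

from .model import FragmentSet, Methylome, Track


def occupancy_track(
    fragments: FragmentSet,
    chrom_sizes: dict[str, int],
    bandwidth: float = 30.0,
) -> dict[str, Track]:
    """Gaussian-kernel density of fragment midpoints, per bp.

    Total mass over all chromosomes equals the fragment count (edge losses
    aside, which `mode='constant'` keeps negligible at desk scale).
    """
    if len(fragments) == 0:
        raise ValueError("occupancy_track needs at least one fragment")
    tracks = {}
    for chrom, size in sorted(chrom_sizes.items()):
        hist = np.zeros(size)
        mids = fragments.midpoints(chrom)
        mids = mids[(mids >= 0) & (mids < size)]
        np.add.at(hist, mids, 1.0)
        tracks[chrom] = Track(
            chrom=chrom,
            values=gaussian_filter1d(hist, sigma=bandwidth, mode="constant"),
        )
    return tracks


def call_centers(
    tracks: dict[str, Track] | Track,
    min_spacing: int = 147,
    min_height: float | None = None,
) -> pd.DataFrame:
    """Greedy local-maximum center calling.

    Local maxima are accepted in decreasing height order subject to a
    minimum mutual distance; exact ties break toward the leftmost
    coordinate. Returns a DataFrame (chrom, center, height).
    """
    if isinstance(tracks, Track):
        tracks = {tracks.chrom: tracks}
    rows = []
    for chrom in sorted(tracks):
        v = tracks[chrom].values
        if len(v) < 3 or np.allclose(v, v[0]):
            continue
        # plateau-safe local maxima: strictly greater than one neighbor,
        # at least equal to the other
        cand = argrelmax(v, order=1)[0]
        heights = v[cand]
        if min_height is not None:
            keep = heights >= min_height
            cand, heights = cand[keep], heights[keep]
        # decreasing height, leftmost-first ties
        order = np.lexsort((cand, -heights))
        accepted: list[int] = []
        acc_arr = np.empty(0, dtype=int)
        for i in order:
            c = cand[i]
            if len(accepted) == 0 or np.abs(acc_arr - c).min() >= min_spacing:
                accepted.append(int(c))
                acc_arr = np.array(accepted)
        for c in sorted(accepted):
            rows.append((chrom, c, float(v[c])))
    return pd.DataFrame(rows, columns=["chrom", "center", "height"])


@dataclass
class NucleosomeMap:
    """Called centers with per-nucleosome occupancy and fuzziness."""

    table: pd.DataFrame  # chrom, center, occupancy, fuzziness
    genome_mean_fuzziness: float
    n_undefined: int  # centers with <2 assigned midpoints


def fuzziness(
    fragments: FragmentSet,
    centers: pd.DataFrame,
    half_window: int = 100,
) -> NucleosomeMap:
    """Assign each midpoint to the nearest called center within
    ``half_window`` and measure the per-nucleosome midpoint spread.

    Fuzziness is the population s.d. of assigned midpoints; the genome mean
    is occupancy-weighted. Centers with fewer than two midpoints have
    undefined fuzziness and are excluded from the mean (but counted).
    """
    if len(centers) == 0:
        raise ValueError("fuzziness needs at least one called center")
    rows = []
    n_undef = 0
    for chrom, sub in centers.groupby("chrom", sort=True):
        cs = np.sort(sub["center"].to_numpy(dtype=int))
        mids = fragments.midpoints(chrom)
        if len(mids) == 0:
            n_undef += len(cs)
            for c in cs:
                rows.append((chrom, int(c), 0, np.nan))
            continue
        idx = np.searchsorted(cs, mids)
        left = np.clip(idx - 1, 0, len(cs) - 1)
        right = np.clip(idx, 0, len(cs) - 1)
        nearest = np.where(
            np.abs(mids - cs[left]) <= np.abs(mids - cs[right]), left, right
        )
        dist = np.abs(mids - cs[nearest])
        ok = dist <= half_window
        for ci, c in enumerate(cs):
            members = mids[ok & (nearest == ci)]
            if len(members) < 2:
                n_undef += 1
                rows.append((chrom, int(c), len(members), np.nan))
            else:
                rows.append((chrom, int(c), len(members),
                             float(np.std(members))))
    table = pd.DataFrame(rows, columns=["chrom", "center", "occupancy",
                                        "fuzziness"])
    defined = table.dropna(subset=["fuzziness"])
    if len(defined):
        wmean = float(np.average(defined["fuzziness"],
                                 weights=defined["occupancy"]))
    else:
        wmean = float("nan")
    return NucleosomeMap(table=table, genome_mean_fuzziness=wmean,
                         n_undefined=n_undef)


def protected_6mA_ratio(
    fragments: FragmentSet | dict[str, list[np.ndarray]],
    methylome: Methylome,
    chrom_sizes: dict[str, int],
    footprint: int = 147,
    n_cells: int | None = None,
    regions: dict[str, np.ndarray] | None = None,
) -> dict:
    """Per-bp 6mA level of protected vs unprotected DNA.

    ``fragments`` may be an MNase FragmentSet or per-chromosome lists of
    sampled center arrays from the placement model (coverage = union of
    147-bp footprints per sample).

    For a FragmentSet pooled over many cells, pass ``n_cells`` (e.g. the
    simulated per-nucleosome depth): protected mass is then the
    coverage-weighted level and unprotected mass the flow-through
    (n_cells - coverage)-weighted level, mirroring an assay on protected
    fragments vs digested linker DNA. Without ``n_cells`` the coverage
    union is used, which is only meaningful at low depth.

    ``regions`` (per-chromosome (n, 2) interval arrays) restricts both
    masses to those intervals — use the chromatinized array spans when the
    rest of the toy genome carries no nucleosomes at all, otherwise the
    flow-through is dominated by naked intergenic DNA that no real
    MNase assay would see in quantity.
    """
    inside_sum = outside_sum = 0.0
    inside_bp = outside_bp = 0

    def accumulate(covered: np.ndarray, levels: np.ndarray,
                   mask: np.ndarray) -> None:
        nonlocal inside_sum, outside_sum, inside_bp, outside_bp
        inside = covered & mask
        outside = ~covered & mask
        inside_sum += levels[inside].sum()
        outside_sum += levels[outside].sum()
        inside_bp += int(inside.sum())
        outside_bp += int(outside.sum())

    for chrom, size in sorted(chrom_sizes.items()):
        levels = methylome.level_track(chrom, size)
        if regions is not None:
            mask = np.zeros(size, dtype=bool)
            for s, e in np.asarray(regions.get(chrom, []), dtype=int).reshape(-1, 2):
                mask[max(0, s) : min(size, e)] = True
        else:
            mask = np.ones(size, dtype=bool)
        if isinstance(fragments, FragmentSet):
            sub = fragments.subset(chrom)[["start", "end"]].to_numpy()
            if n_cells is None:
                covered = np.zeros(size, dtype=bool)
                for s, e in sub:
                    covered[max(0, s) : min(size, e)] = True
                accumulate(covered, levels, mask)
            else:
                cov = np.zeros(size)
                for s, e in sub:
                    cov[max(0, s) : min(size, e)] += 1.0
                cov = np.minimum(cov, n_cells) * mask
                flow = (n_cells - cov) * mask
                inside_sum += float((cov * levels).sum())
                outside_sum += float((flow * levels).sum())
                inside_bp += int(round(cov.sum()))
                outside_bp += int(round(flow.sum()))
        else:
            half = footprint // 2
            for centers in fragments.get(chrom, []):
                covered = np.zeros(size, dtype=bool)
                for c in centers:
                    covered[max(0, c - half) : min(size, c - half + footprint)] = True
                accumulate(covered, levels, mask)

    inside = inside_sum / inside_bp if inside_bp else float("nan")
    outside = outside_sum / outside_bp if outside_bp else float("nan")
    if inside_bp == 0 or outside_bp == 0 or outside == 0:
        ratio = float("nan")
    else:
        ratio = inside / outside
    return {
        "inside_per_bp": inside,
        "outside_per_bp": outside,
        "ratio": ratio,
        "inside_bp": inside_bp,
        "outside_bp": outside_bp,
    }
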