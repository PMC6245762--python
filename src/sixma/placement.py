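"""Thermodynamic nucleosome placement with a per-6mA energy penalty.

The model is a 1-D Tonks gas: hard footprints of ``footprint`` bp on an open
lattice, no overlaps, with per-footprint energy

    E(footprint at s) = -mu + w * sum(6mA levels covered by [s, s+footprint))

at unit temperature. ``mu`` (chemical potential) sets the density; ``w`` > 0
operationalizes 6mA-induced duplex stiffening that disfavors wrapping — a
methylated patch raises the energy of every footprint covering it, so
occupancy is repelled from 6mA and attracted to its flanks.

Two routes compute the equilibrium per-bp occupancy:

* :func:`exact_occupancy` — exact transfer-matrix dynamic programming over
  all non-overlapping configurations (forward/backward partition functions,
  log-space);
* :func:`place_mc` — grand-canonical Metropolis Monte Carlo with
  insert/delete/shift moves, returning sampled center sets and the
  post-burn-in average coverage.

The MC sampler must agree with the DP oracle; that agreement is tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Methylome, Track


@dataclass(frozen=True)
class PlacementParams:
    footprint: int = 147
    penalty_w: float = 5.0
    mu: float = 2.0
    n_sweeps: int = 2000
    burn_in_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.footprint < 1:
            raise ValueError("footprint must be >= 1")
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")


def _methyl_track(methylome: Methylome | np.ndarray, length: int,
                  chrom: str | None) -> np.ndarray:
    if isinstance(methylome, Methylome):
        if chrom is None:
            chroms = set(methylome.df["chrom"]) if len(methylome.df) else set()
            if len(chroms) > 1:
                raise ValueError("multi-chromosome methylome needs chrom=")
            chrom = chroms.pop() if chroms else "chr1"
        return methylome.level_track(chrom, length)
    track = np.zeros(length)
    arr = np.asarray(methylome, dtype=float)
    track[: len(arr)] = arr[:length]
    return track


def _site_log_weights(levels: np.ndarray, params: PlacementParams) -> np.ndarray:
    """log Boltzmann weight of a footprint starting at each lattice position."""
    a = params.footprint
    csum = np.concatenate([[0.0], np.cumsum(levels)])
    m = len(levels) - a + 1
    if m <= 0:
        raise ValueError("footprint longer than lattice")
    methyl_sum = csum[a : a + m] - csum[:m]
    return params.mu - params.penalty_w * methyl_sum


def exact_occupancy(
    lattice_length: int,
    methylome: Methylome | np.ndarray,
    params: PlacementParams,
    chrom: str | None = None,
    max_length: int = 2000,
) -> Track:
    """Exact per-bp equilibrium occupancy by forward/backward DP.

    F[i] = partition function of the prefix [0, i); B[i] of the suffix
    [i, N). The probability that a footprint occupies [s, s+a) is
    F[s] * exp(logw[s]) * B[s+a] / F[N]; occupancy is the cumulative sum of
    start probabilities over the covering window. All in log space.
    """
    if lattice_length > max_length:
        raise ValueError(
            f"lattice of {lattice_length} bp exceeds exact-DP guard "
            f"({max_length} bp); use place_mc"
        )
    a = params.footprint
    levels = _methyl_track(methylome, lattice_length, chrom)
    logw = _site_log_weights(levels, params)
    n = lattice_length
    neg_inf = -np.inf

    logF = np.full(n + 1, neg_inf)
    logF[0] = 0.0
    for i in range(1, n + 1):
        best = logF[i - 1]
        if i >= a:
            best = np.logaddexp(best, logF[i - a] + logw[i - a])
        logF[i] = best
    logB = np.full(n + 1, neg_inf)
    logB[n] = 0.0
    for i in range(n - 1, -1, -1):
        best = logB[i + 1]
        if i + a <= n:
            best = np.logaddexp(best, logw[i] + logB[i + a])
        logB[i] = best

    log_pstart = logF[: n - a + 1] + logw + logB[a:] - logF[n]
    pstart = np.exp(log_pstart)
    occupancy = np.convolve(pstart, np.ones(a))[:n]
    return Track(chrom=chrom or "lattice", values=np.clip(occupancy, 0.0, 1.0))


def enumerate_occupancy(
    lattice_length: int,
    methylome: Methylome | np.ndarray,
    params: PlacementParams,
) -> np.ndarray:
    """Brute-force occupancy by exhaustive enumeration of all non-overlapping
    configurations. Exponential; only for tiny lattices (verification)."""
    a = params.footprint
    levels = _methyl_track(methylome, lattice_length, None)
    logw = _site_log_weights(levels, params)
    w = np.exp(logw)
    total = 0.0
    cover = np.zeros(lattice_length)

    def recurse(pos: int, weight: float, starts: list[int]) -> None:
        nonlocal total
        if pos > lattice_length - a:
            total += weight
            for s in starts:
                cover[s : s + a] += weight
            return
        recurse(pos + 1, weight, starts)  # leave pos empty
        recurse(pos + a, weight * w[pos], starts + [pos])

    recurse(0, 1.0, [])
    return cover / total


def place_mc(
    genome_length: int,
    methylome: Methylome | np.ndarray,
    params: PlacementParams,
    seed: int = 0,
    chrom: str | None = None,
    sample_every: int = 1,
    max_shift: int = 10,
) -> tuple[list[np.ndarray], Track]:
    """Grand-canonical Metropolis sampling of non-overlapping footprints.

    One sweep attempts ``genome_length // footprint + 1`` moves (insert,
    delete or shift, chosen uniformly). Returns post-burn-in sampled center
    sets and the average per-bp coverage.
    """
    a = params.footprint
    levels = _methyl_track(methylome, genome_length, chrom)
    logw = _site_log_weights(levels, params)
    m = len(logw)  # number of admissible start positions
    rng = np.random.default_rng(seed)

    occupied = np.zeros(genome_length + a, dtype=bool)  # padded
    starts: list[int] = []

    def free(s: int, ignore: int | None = None) -> bool:
        if ignore is not None:
            occupied[ignore : ignore + a] = False
        ok = not occupied[s : s + a].any()
        if ignore is not None:
            occupied[ignore : ignore + a] = True
        return ok

    n_burn = int(params.n_sweeps * params.burn_in_fraction)
    moves_per_sweep = genome_length // a + 1
    coverage = np.zeros(genome_length)
    samples: list[np.ndarray] = []
    n_avg = 0

    for sweep in range(params.n_sweeps):
        for _ in range(moves_per_sweep):
            kind = rng.integers(3)
            if kind == 0:  # insert
                s = int(rng.integers(m))
                if not free(s):
                    continue
                log_acc = logw[s] + np.log(m) - np.log(len(starts) + 1)
                if np.log(rng.random()) < log_acc:
                    starts.append(s)
                    occupied[s : s + a] = True
            elif kind == 1 and starts:  # delete
                i = int(rng.integers(len(starts)))
                s = starts[i]
                log_acc = -logw[s] + np.log(len(starts)) - np.log(m)
                if np.log(rng.random()) < log_acc:
                    occupied[s : s + a] = False
                    starts[i] = starts[-1]
                    starts.pop()
            elif kind == 2 and starts:  # shift
                i = int(rng.integers(len(starts)))
                s = starts[i]
                delta = int(rng.integers(-max_shift, max_shift + 1))
                t = s + delta
                if delta == 0 or t < 0 or t >= m or not free(t, ignore=s):
                    continue
                if np.log(rng.random()) < logw[t] - logw[s]:
                    occupied[s : s + a] = False
                    occupied[t : t + a] = True
                    starts[i] = t
        if sweep >= n_burn:
            n_avg += 1
            arr = np.array(sorted(starts), dtype=int)
            for s in arr:
                coverage[s : s + a] += 1.0
            if (sweep - n_burn) % sample_every == 0:
                samples.append(arr + a // 2)  # centers

    occ = coverage / max(n_avg, 1)
    return samples, Track(chrom=chrom or "lattice", values=occ)


def protected_methyl_stats(
    center_samples: list[np.ndarray],
    levels: np.ndarray,
    footprint: int = 147,
) -> dict:
    """Per-bp 6mA level inside vs outside sampled footprints, and the ratio —
    the in-silico analogue of assaying nucleosome-protected vs flow-through
    DNA for methylation content."""
    n = len(levels)
    inside_sum = outside_sum = 0.0
    inside_bp = outside_bp = 0
    half = footprint // 2
    for centers in center_samples:
        covered = np.zeros(n, dtype=bool)
        for c in centers:
            covered[max(0, c - half) : min(n, c - half + footprint)] = True
        inside_sum += levels[covered].sum()
        outside_sum += levels[~covered].sum()
        inside_bp += int(covered.sum())
        outside_bp += int(n - covered.sum())
    inside = inside_sum / inside_bp if inside_bp else float("nan")
    outside = outside_sum / outside_bp if outside_bp else float("nan")
    ratio = inside / outside if outside_bp and outside > 0 else float("nan")
    return {"inside": inside, "outside": outside, "ratio": ratio}
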