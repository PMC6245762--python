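"""IP-vs-input enrichment peak calling and genomic-component enrichment.

A deliberately small windowed Poisson caller: fragment midpoints are counted
in fixed windows, the input count (library-size scaled, pseudocount 1) sets
the Poisson expectation for the IP count, upper-tail p-values are corrected
by Benjamini-Hochberg across windows, and runs of significant windows merge
into peaks. This mirrors the role MACS-style callers play for antibody
pull-down data without their local-background machinery.

The enrichment score of a genomic component (first exon / other exon /
intron / intergenic) is the proportion of peak bp falling in the component
divided by the proportion of the genome the component occupies; scores are
bp-weighted, so their component-fraction-weighted mean is exactly 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import FragmentSet, GeneModel, ToyGenome

COMPONENTS = ("first_exon", "other_exon", "intron", "intergenic")


def call_peaks(
    ip: FragmentSet,
    input_: FragmentSet,
    chrom_sizes: dict[str, int],
    window: int = 100,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Windowed Poisson comparison of IP vs input midpoint counts.

    Returns a DataFrame (chrom, start, end, summit, fold_enrichment, p, q)
    of merged significant windows.
    """
    if len(ip) == 0 or len(input_) == 0:
        raise ValueError("both IP and input must be non-empty")
    scale = len(ip) / len(input_)

    windows = []
    for chrom, size in sorted(chrom_sizes.items()):
        n_win = int(np.ceil(size / window))
        ip_mid = ip.midpoints(chrom)
        in_mid = input_.midpoints(chrom)
        ip_counts = np.bincount(ip_mid // window, minlength=n_win)[:n_win]
        in_counts = np.bincount(in_mid // window, minlength=n_win)[:n_win]
        lam = (in_counts + 1.0) * scale
        p = stats.poisson.sf(ip_counts - 1, lam)
        windows.append(pd.DataFrame({
            "chrom": chrom,
            "start": np.arange(n_win) * window,
            "end": np.minimum((np.arange(n_win) + 1) * window, size),
            "ip": ip_counts, "lam": lam, "p": p,
        }))
    table = pd.concat(windows, ignore_index=True)
    reject, q, _, _ = multipletests(table["p"], method="fdr_bh",
                                    alpha=q_threshold)
    table["q"] = q
    table["sig"] = table["q"] <= q_threshold

    peaks = []
    for chrom, sub in table.groupby("chrom", sort=True):
        sub = sub.sort_values("start").reset_index(drop=True)
        sig = sub["sig"].to_numpy()
        if not sig.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate([[0], sig.view(np.int8),
                                                       [0]])))
        ip_mid = ip.midpoints(chrom)
        for lo, hi in zip(edges[::2], edges[1::2]):
            block = sub.iloc[lo:hi]
            start, end = int(block["start"].iloc[0]), int(block["end"].iloc[-1])
            mids = ip_mid[(ip_mid >= start) & (ip_mid < end)]
            if len(mids):
                counts = np.bincount(mids - start, minlength=end - start)
                summit = start + int(np.argmax(counts))
            else:
                summit = (start + end) // 2
            fold = float(block["ip"].sum() / block["lam"].sum())
            peaks.append({
                "chrom": chrom, "start": start, "end": end, "summit": summit,
                "fold_enrichment": fold,
                "p": float(block["p"].min()), "q": float(block["q"].min()),
            })
    return pd.DataFrame(peaks, columns=["chrom", "start", "end", "summit",
                                        "fold_enrichment", "p", "q"])


def component_partition(
    genes: list[GeneModel], chrom_sizes: dict[str, int]
) -> dict[str, dict[str, np.ndarray]]:
    """Label every bp of the genome with exactly one component.

    Returns per-chromosome integer arrays indexed into COMPONENTS.
    """
    code = {name: i for i, name in enumerate(COMPONENTS)}
    labels = {
        chrom: np.full(size, code["intergenic"], dtype=np.int8)
        for chrom, size in chrom_sizes.items()
    }
    for gene in genes:
        arr = labels[gene.chrom]
        arr[gene.start : gene.end] = code["intron"]
        first = gene.first_exon
        for exon in gene.exons:
            which = "first_exon" if exon == first else "other_exon"
            arr[exon[0] : exon[1]] = code[which]
    return labels


def enrichment_score(
    peaks: pd.DataFrame,
    genes: list[GeneModel],
    chrom_sizes: dict[str, int],
) -> pd.DataFrame:
    """Fold enrichment of peak coverage per genomic component.

    score(c) = (peak bp in c / total peak bp) / (bp of c / genome bp).
    """
    labels = component_partition(genes, chrom_sizes)
    genome_bp = np.zeros(len(COMPONENTS))
    peak_bp = np.zeros(len(COMPONENTS))
    for chrom, arr in labels.items():
        genome_bp += np.bincount(arr, minlength=len(COMPONENTS))
        mask = np.zeros(len(arr), dtype=bool)
        if len(peaks):
            for s, e in peaks[peaks["chrom"] == chrom][["start", "end"]].to_numpy():
                mask[max(0, s) : min(len(arr), e)] = True
        peak_bp += np.bincount(arr[mask], minlength=len(COMPONENTS))

    total_genome = genome_bp.sum()
    total_peak = peak_bp.sum()
    rows = []
    for i, name in enumerate(COMPONENTS):
        if genome_bp[i] == 0:
            score = float("nan")  # undefined: component absent from genome
        elif total_peak == 0:
            score = float("nan")
        else:
            score = (peak_bp[i] / total_peak) / (genome_bp[i] / total_genome)
        rows.append({
            "component": name,
            "genome_bp": int(genome_bp[i]),
            "peak_bp": int(peak_bp[i]),
            "genome_fraction": genome_bp[i] / total_genome,
            "score": score,
        })
    return pd.DataFrame(rows)
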