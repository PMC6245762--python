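"""Single-base 6mA calling from methylation-sensitive restriction digests.

Three enzymes with opposite 6mA sensitivity at short palindromes make the
adenine methylation state of each recognition site readable from fragment
geometry:

* DpnI cuts GATC only when the adenine is methylated (evidence = fragment
  boundaries at the cut position);
* DpnII cuts GATC only when unmethylated (evidence = fragments spanning the
  intact site);
* CviAII cuts CATG only when unmethylated (spanning evidence, like DpnII).

Per candidate site, the evidence fraction among molecules observing the site
is tested one-sided against a background rate with a binomial test, and
calls are controlled at FDR ``q_threshold`` by Benjamini-Hochberg across all
candidates. Plus/minus strand evidence is pooled per palindrome, and each
call is reported at the position of the plus-strand adenine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import FragmentSet, ToyGenome

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnzymeSpec:
    """A methylation-sensitive restriction enzyme.

    ``methylatable_A_offset`` is the offset of the plus-strand adenine within
    the recognition sequence; ``paired_A_offset`` the offset of the base whose
    minus-strand partner is the palindrome's other methylatable adenine.
    ``cut_offset`` is where the double-strand break falls, as an offset from
    the site start (boundary between cut_offset-1 and cut_offset).
    """

    name: str
    recognition: str
    cut_offset: int
    sensitivity: str  # requires_6mA | blocked_by_6mA
    methylatable_A_offset: int
    paired_A_offset: int

    def __post_init__(self) -> None:
        if self.recognition[self.methylatable_A_offset] != "A":
            raise ValueError("recognition must hold A at methylatable_A_offset")
        if self.sensitivity not in ("requires_6mA", "blocked_by_6mA"):
            raise ValueError(f"unknown sensitivity {self.sensitivity!r}")


# DpnI is modelled as cutting bluntly between the A and T of G(6mA)TC,
# DpnII 5' of GATC, CviAII between C and A of CATG.
ENZYMES: dict[str, EnzymeSpec] = {
    "DpnI": EnzymeSpec("DpnI", "GATC", cut_offset=2,
                       sensitivity="requires_6mA",
                       methylatable_A_offset=1, paired_A_offset=2),
    "DpnII": EnzymeSpec("DpnII", "GATC", cut_offset=0,
                        sensitivity="blocked_by_6mA",
                        methylatable_A_offset=1, paired_A_offset=2),
    "CviAII": EnzymeSpec("CviAII", "CATG", cut_offset=1,
                         sensitivity="blocked_by_6mA",
                         methylatable_A_offset=1, paired_A_offset=2),
}


def get_enzyme(name: str) -> EnzymeSpec:
    try:
        return ENZYMES[name]
    except KeyError:
        raise KeyError(f"enzyme {name!r} not in registry {sorted(ENZYMES)}") from None


def scan_sites(genome: ToyGenome, enzyme: EnzymeSpec,
               chrom: str | None = None) -> np.ndarray | dict[str, np.ndarray]:
    """Start positions of every exact recognition-site match on the forward
    strand (the palindromic sites cover both strands), in increasing order."""
    def _scan(seq: str) -> np.ndarray:
        hits, i = [], seq.find(enzyme.recognition)
        while i != -1:
            hits.append(i)
            i = seq.find(enzyme.recognition, i + 1)
        return np.array(hits, dtype=int)

    if chrom is not None:
        return _scan(genome[chrom])
    return {c: _scan(genome[c]) for c in sorted(genome.seqs)}


def _site_evidence(
    frag: pd.DataFrame, sites: np.ndarray, enzyme: EnzymeSpec
) -> tuple[np.ndarray, np.ndarray]:
    """(n_cut_ends, n_spanning) per site for one chromosome's fragments.

    A "cut end" is a fragment start at the expected cut position (+-1 bp);
    each realized cut yields exactly one downstream fragment start, so starts
    count cut events without double counting. "Spanning" fragments cover the
    whole recognition site with no boundary at the cut position.
    """
    site_len = len(enzyme.recognition)
    f_start = frag["start"].to_numpy()
    f_end = frag["end"].to_numpy()
    starts_sorted = np.sort(f_start)
    cut_pos = sites + enzyme.cut_offset

    n_cut = np.array([
        int(np.searchsorted(starts_sorted, c + 2) -
            np.searchsorted(starts_sorted, c - 1))
        for c in cut_pos
    ], dtype=int)
    # spanning: an uncut traversal fully covering [site, site+len)
    n_span = np.array([
        int(np.count_nonzero((f_start < s) & (f_end > s + site_len - 1)))
        for s in sites
    ], dtype=int)
    return n_cut, n_span


def call_6mA_sites(
    fragments: FragmentSet,
    candidates: dict[str, np.ndarray],
    enzyme: EnzymeSpec,
    background_rate: float | None = None,
    q_threshold: float = 0.01,
    cut_efficiency: float = 0.9,
) -> pd.DataFrame:
    """Test every candidate recognition site for 6mA.

    The one-sided binomial null is the evidence fraction expected at an
    unmethylated site: a small nonspecific cut rate (default 0.05) for
    cut-evidence enzymes, and the uncut fraction ``1 - cut_efficiency`` of
    an efficient digest for protection-evidence enzymes. Pass
    ``background_rate`` to override either.

    Returns one row per site with columns chrom, pos (plus-strand adenine),
    site_start, motif, n_cut_ends, n_spanning, evidence_mode, p, q, called.
    """
    if background_rate is None:
        background_rate = (0.05 if enzyme.sensitivity == "requires_6mA"
                           else 1.0 - cut_efficiency)
    rows = []
    for chrom in sorted(candidates):
        sites = np.asarray(candidates[chrom], dtype=int)
        if len(sites) == 0:
            continue
        frag = fragments.subset(chrom)
        n_cut, n_span = _site_evidence(frag, sites, enzyme)
        for s, nc, ns in zip(sites, n_cut, n_span):
            if enzyme.sensitivity == "requires_6mA":
                evidence, mode = int(nc), "cut"
            else:
                evidence, mode = int(ns), "protection"
            n_obs = int(nc + ns)
            p = (stats.binom.sf(evidence - 1, n_obs, background_rate)
                 if n_obs > 0 else 1.0)
            rows.append({
                "chrom": chrom,
                "pos": int(s + enzyme.methylatable_A_offset),
                "site_start": int(s),
                "motif": enzyme.recognition,
                "n_cut_ends": int(nc),
                "n_spanning": int(ns),
                "evidence_mode": mode,
                "p": float(p),
            })
    if not rows:
        logger.warning("no candidate sites: returning empty call table")
        return pd.DataFrame(columns=[
            "chrom", "pos", "site_start", "motif", "n_cut_ends",
            "n_spanning", "evidence_mode", "p", "q", "called",
        ])
    calls = pd.DataFrame(rows)
    reject, q, _, _ = multipletests(calls["p"], method="fdr_bh", alpha=q_threshold)
    calls["q"] = q
    calls["called"] = calls["q"] <= q_threshold
    return calls


def motif_context(
    calls: pd.DataFrame, genome: ToyGenome, flank: int = 5
) -> pd.DataFrame:
    """Base-frequency table around called positions (offset 0 = the adenine).

    Positions whose flank runs off the chromosome contribute only their
    in-bounds offsets. Returns a DataFrame indexed by offset with columns
    A, C, G, T summing to 1 per row.
    """
    called = calls[calls["called"]] if "called" in calls else calls
    if len(called) == 0:
        raise ValueError("motif_context needs at least one call")
    offsets = np.arange(-flank, flank + 1)
    counts = {b: np.zeros(len(offsets)) for b in "ACGT"}
    totals = np.zeros(len(offsets))
    for chrom, sub in called.groupby("chrom"):
        seq = genome[chrom]
        for pos in sub["pos"]:
            for oi, off in enumerate(offsets):
                p = pos + off
                if 0 <= p < len(seq):
                    counts[seq[p]][oi] += 1
                    totals[oi] += 1
    freq = pd.DataFrame({b: counts[b] / np.maximum(totals, 1) for b in "ACGT"},
                        index=pd.Index(offsets, name="offset"))
    return freq
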