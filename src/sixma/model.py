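"""Domain containers shared across the pipeline.

Conventions used throughout the package:

* Coordinates are 0-based, half-open ``[start, end)`` internally; GFF3 is
  converted on read/write, BED passes through unchanged.
* "Downstream of the TSS" always means the direction of transcription;
  minus-strand genes are flipped before any TSS-relative accumulation.
* Methylation levels are fractions in ``[0, 1]`` (fraction of molecules
  carrying 6mA at that adenine).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

NUCLEOSOME_CORE_BP = 147

#: Inter-base-pair (step) followed by intra-base-pair parameters, 3DNA naming.
STEP_PARAMETERS = ("roll", "tilt", "twist", "slide", "shift", "rise")
INTRA_PARAMETERS = ("shear", "stretch", "stagger", "buckle", "propeller", "opening")
ALL_PARAMETERS = STEP_PARAMETERS + INTRA_PARAMETERS


@dataclass(frozen=True)
class GenomeSpec:
    """Sizing of the synthetic gene-dense toy genome."""

    n_chrom: int = 5
    chrom_len: int = 220_000
    n_genes: int = 300
    gc_content: float = 0.30
    at_enrichment_in_linkers: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chrom_len < 10_000:
            raise ValueError("chrom_len must be >= 10,000 bp")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        if not 0.0 <= self.at_enrichment_in_linkers < 1.0:
            raise ValueError("at_enrichment_in_linkers must be in [0, 1)")


class ToyGenome:
    """Per-chromosome nucleotide strings over the {A,C,G,T} alphabet."""

    def __init__(self, seqs: dict[str, str]):
        for name, seq in seqs.items():
            bad = set(seq) - set("ACGT")
            if bad:
                raise ValueError(f"{name}: non-ACGT characters {sorted(bad)}")
        self.seqs = dict(seqs)

    @property
    def sizes(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.seqs.items()}

    @property
    def total_bp(self) -> int:
        return sum(self.sizes.values())

    def __getitem__(self, chrom: str) -> str:
        return self.seqs[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self.seqs)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ToyGenome) and self.seqs == other.seqs


@dataclass(frozen=True)
class GeneModel:
    """A gene anchored by its TSS; exons are half-open genome intervals.

    ``tss < tts`` on the plus strand and ``tss > tts`` on the minus strand
    (both are 0-based positions of the first/last transcribed base).
    """

    chrom: str
    strand: str
    tss: int
    tts: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.strand == "+" and not self.tss < self.tts:
            raise ValueError("plus-strand gene needs tss < tts")
        if self.strand == "-" and not self.tss > self.tts:
            raise ValueError("minus-strand gene needs tss > tts")
        prev_end = -1
        for start, end in self.exons:
            if start >= end or start < prev_end:
                raise ValueError("exons must be sorted, non-overlapping")
            prev_end = end
        if not any(s <= self.tss < e for s, e in self.exons):
            raise ValueError("first exon must contain the TSS")

    @property
    def start(self) -> int:
        return min(self.tss, self.tts)

    @property
    def end(self) -> int:
        return max(self.tss, self.tts) + 1

    @property
    def first_exon(self) -> tuple[int, int]:
        for start, end in self.exons:
            if start <= self.tss < end:
                return (start, end)
        raise AssertionError("unreachable: validated in __post_init__")


class Methylome:
    """Strand-resolved 6mA records: (chrom, pos of the A, strand, level)."""

    COLUMNS = ("chrom", "pos", "strand", "level")

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None:
            df = pd.DataFrame({c: [] for c in self.COLUMNS})
        df = df.reset_index(drop=True)
        levels = np.asarray(df["level"], dtype=float)
        if len(levels) and (levels.min() < 0 or levels.max() > 1):
            raise ValueError("methylation levels must lie in [0, 1]")
        self.df = df.astype({"pos": int}) if len(df) else df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def empty(self) -> bool:
        return len(self.df) == 0

    def scaled(self, factor: float) -> "Methylome":
        """Same sites, levels multiplied by ``factor`` (uniform knockdown)."""
        out = self.df.copy()
        out["level"] = out["level"] * factor
        return Methylome(out)

    def level_track(self, chrom: str, length: int) -> np.ndarray:
        """Per-bp summed methylation level (both strands) for one chromosome."""
        track = np.zeros(length)
        sub = self.df[self.df["chrom"] == chrom]
        if len(sub):
            np.add.at(track, sub["pos"].to_numpy(), sub["level"].to_numpy())
        return track

    def positions(self, chrom: str | None = None) -> np.ndarray:
        sub = self.df if chrom is None else self.df[self.df["chrom"] == chrom]
        return np.unique(sub["pos"].to_numpy(dtype=int)) if len(sub) else np.array([], dtype=int)


class FragmentSet:
    """Genomic intervals (chrom, start, end, strand) with a provenance label.

    The common currency of every simulator and caller: MNase-protected
    fragments, IP/input sequencing fragments, and restriction digests all
    travel as FragmentSets.
    """

    COLUMNS = ("chrom", "start", "end", "strand")
    LABELS = ("mnase", "ip", "input", "re_dpnI", "re_dpnII", "re_cviAII")

    def __init__(self, df: pd.DataFrame, label: str = "mnase"):
        df = df.reset_index(drop=True)
        if len(df):
            if (df["start"] >= df["end"]).any():
                raise ValueError("fragments need start < end")
            df = df.astype({"start": int, "end": int})
        self.df = df
        self.label = label

    def __len__(self) -> int:
        return len(self.df)

    def midpoints(self, chrom: str | None = None) -> np.ndarray:
        sub = self.df if chrom is None else self.df[self.df["chrom"] == chrom]
        return ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2).astype(int)

    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy(dtype=int)

    def subset(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]


@dataclass
class GroundTruth:
    """What the generator actually planted, for later recovery checks."""

    condition: str  # in_vivo | ko | in_vitro_native | in_vitro_wga
    repeat_length: int
    nfr_width: int
    jitter_sigma: float
    centers: pd.DataFrame  # columns: chrom, center, gene_idx
    linkers: pd.DataFrame  # columns: chrom, start, end, gene_idx
    methylome: Methylome

    def centers_on(self, chrom: str) -> np.ndarray:
        sub = self.centers[self.centers["chrom"] == chrom]
        return np.sort(sub["center"].to_numpy(dtype=int))

    def footprints_on(self, chrom: str) -> np.ndarray:
        """(n, 2) array of [center-73, center+74) core intervals."""
        c = self.centers_on(chrom)
        return np.stack([c - 73, c + 74], axis=1) if len(c) else np.empty((0, 2), int)

    def array_spans(self) -> dict[str, np.ndarray]:
        """Per-chromosome (n, 2) intervals covering each gene's nucleosome
        array (first footprint start to last footprint end) — the
        chromatinized portion of the toy genome."""
        spans: dict[str, list[list[int]]] = {}
        for (chrom, _), sub in self.centers.groupby(["chrom", "gene_idx"]):
            c = sub["center"].to_numpy()
            spans.setdefault(chrom, []).append(
                [int(c.min()) - 73, int(c.max()) + 74])
        return {k: np.array(v, dtype=int) for k, v in spans.items()}


@dataclass
class StepParameterSeries:
    """Per-snapshot, per-position values of the 12 DNA structural parameters.

    ``values`` has shape (12, n_positions, n_snapshots); angular parameters
    are in degrees and translational ones in Angstrom, 3DNA convention.
    """

    values: np.ndarray
    parameters: tuple[str, ...] = ALL_PARAMETERS
    modification_site: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[0] != len(self.parameters):
            raise ValueError("values must be (n_parameters, n_positions, n_snapshots)")

    @property
    def n_positions(self) -> int:
        return self.values.shape[1]

    @property
    def n_snapshots(self) -> int:
        return self.values.shape[2]

    def index_of(self, parameter: str) -> int:
        return self.parameters.index(parameter)


@dataclass
class Track:
    """Per-bp values for one chromosome (dense array form)."""

    chrom: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge overlapping/adjacent half-open intervals."""
    if not intervals:
        return []
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def complement_intervals(
    intervals: list[tuple[int, int]], length: int
) -> list[tuple[int, int]]:
    """Gaps of [0, length) not covered by the (merged) intervals."""
    out = []
    cursor = 0
    for start, end in merge_intervals(intervals):
        if start > cursor:
            out.append((cursor, start))
        cursor = max(cursor, end)
    if cursor < length:
        out.append((cursor, length))
    return out
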