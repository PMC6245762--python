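"""Shared fixtures: one default wild-type dataset reused across test modules.

Session scope keeps the suite fast — the generators are deterministic for a
fixed seed, so sharing is safe.
"""

import numpy as np
import pytest

from sixma import nuccall, synthio
from sixma.model import GenomeSpec

SEED = 11


@pytest.fixture(scope="session")
def wt_data():
    """Default-scale wild-type dataset: genome, genes, ground truth."""
    spec = GenomeSpec(seed=SEED)
    genome, genes = synthio.gen_genome(spec)
    truth = synthio.gen_ground_truth(genome, genes, mode="in_vivo", seed=SEED)
    return genome, genes, truth


@pytest.fixture(scope="session")
def wt_fragments(wt_data):
    genome, _, truth = wt_data
    return synthio.sim_mnase_fragments(truth, genome, seed=SEED)


@pytest.fixture(scope="session")
def wt_centers(wt_data, wt_fragments):
    genome, _, _ = wt_data
    tracks = nuccall.occupancy_track(wt_fragments, genome.sizes)
    return nuccall.call_centers(tracks)


@pytest.fixture(scope="session")
def tss_anchors(wt_data):
    _, genes, _ = wt_data
    return [(g.chrom, g.tss, g.strand) for g in genes]


@pytest.fixture(scope="session")
def small_data():
    """A lighter dataset for tests that re-generate several conditions."""
    spec = GenomeSpec(n_chrom=3, chrom_len=150_000, n_genes=120, seed=SEED)
    genome, genes = synthio.gen_genome(spec)
    truth = synthio.gen_ground_truth(genome, genes, mode="in_vivo", seed=SEED)
    return genome, genes, truth


def true_positions(truth) -> set:
    """(chrom, pos) of every methylated adenine on either strand."""
    return set(map(tuple,
                   truth.methylome.df[["chrom", "pos"]].itertuples(index=False)))
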