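"""Round-trip identity and coordinate-convention tests for all file formats."""

import numpy as np
import pandas as pd
import pytest

from sixma import formats, synthio
from sixma.model import (
    FragmentSet,
    GeneModel,
    Methylome,
    StepParameterSeries,
    ToyGenome,
    Track,
    complement_intervals,
    merge_intervals,
)


@pytest.fixture()
def toy_genome():
    rng = np.random.default_rng(0)
    return ToyGenome({
        "chrA": "".join(rng.choice(list("ACGT"), 500)),
        "chrB": "".join(rng.choice(list("ACGT"), 300)),
    })


class TestFasta:
    def test_round_trip_identity(self, toy_genome, tmp_path):
        path = tmp_path / "g.fa"
        formats.write_fasta(toy_genome, path)
        assert formats.read_fasta(path) == toy_genome

    def test_empty_file_gives_empty_genome(self, tmp_path):
        path = tmp_path / "empty.fa"
        path.write_text("")
        assert formats.read_fasta(path).seqs == {}

    def test_mixed_case_normalized_upper(self, tmp_path):
        path = tmp_path / "mixed.fa"
        path.write_text(">s1\nacgTGca\n")
        genome = formats.read_fasta(path)
        assert genome["s1"] == "ACGTGCA"

    def test_duplicate_names_rejected(self, tmp_path):
        path = tmp_path / "dup.fa"
        path.write_text(">s1\nACGT\n>s1\nACGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            formats.read_fasta(path)

    def test_line_wrap_at_60(self, toy_genome, tmp_path):
        path = tmp_path / "g.fa"
        formats.write_fasta(toy_genome, path)
        body = [l for l in path.read_text().splitlines()
                if not l.startswith(">")]
        assert max(len(l) for l in body) == 60


class TestBed:
    def test_round_trip_unchanged(self, tmp_path):
        df = pd.DataFrame({
            "chrom": ["chr1", "chr1", "chr2"],
            "start": [5, 100, 0],
            "end": [15, 250, 7],
            "strand": ["+", "-", "."],
        })
        fs = FragmentSet(df, label="mnase")
        path = tmp_path / "f.bed"
        formats.write_bed(fs, path)
        back = formats.read_bed(path)
        assert back.df[["chrom", "start", "end", "strand"]].equals(
            fs.df[["chrom", "start", "end", "strand"]])

    def test_invalid_interval_reported_with_line(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t10\t10\tx\t0\t+\n")
        with pytest.raises(ValueError, match="line 1"):
            formats.read_bed(path)

    def test_methylome_bed_level_scaling(self, tmp_path):
        meth = Methylome(pd.DataFrame({
            "chrom": ["chr1", "chr1"], "pos": [10, 20],
            "strand": ["+", "-"], "level": [0.8, 0.25],
        }))
        path = tmp_path / "m.bed"
        formats.write_methylome_bed(meth, path)
        scores = [int(l.split("\t")[4]) for l in path.read_text().splitlines()]
        assert scores == [800, 250]
        back = formats.read_methylome_bed(path)
        assert np.allclose(back.df["level"], [0.8, 0.25])


class TestGff3:
    def test_coordinate_convention(self, tmp_path):
        """A GFF3 feature 1..10 is internal (0, 10)."""
        path = tmp_path / "g.gff3"
        path.write_text(
            "##gff-version 3\n"
            "chr1\tx\tgene\t1\t10\t.\t+\t.\tID=g1\n"
            "chr1\tx\texon\t1\t10\t.\t+\t.\tID=g1.e1;Parent=g1\n"
        )
        genes = formats.read_gff3(path)
        assert genes[0].exons == ((0, 10),)
        assert genes[0].tss == 0 and genes[0].tts == 9

    def test_round_trip_both_strands(self, tmp_path):
        genes = [
            GeneModel("chr1", "+", tss=100, tts=299,
                      exons=((100, 180), (220, 300))),
            GeneModel("chr1", "-", tss=899, tts=600,
                      exons=((600, 700), (800, 900))),
        ]
        path = tmp_path / "genes.gff3"
        formats.write_gff3(genes, path)
        assert formats.read_gff3(path) == genes


class TestBedGraph:
    def test_constant_track_single_line(self, tmp_path):
        path = tmp_path / "t.bedGraph"
        formats.write_bedgraph([Track("chr1", np.full(100, 2.5))], path)
        assert len(path.read_text().splitlines()) == 1

    def test_round_trip_random_track(self, tmp_path):
        rng = np.random.default_rng(1)
        values = np.round(rng.random(400), 4)
        path = tmp_path / "t.bedGraph"
        formats.write_bedgraph([Track("chr1", values)], path)
        back = formats.read_bedgraph(path)
        assert np.allclose(back[0].values, values)

    def test_rle_expansion_matches_per_bp(self, tmp_path):
        values = np.array([0.0, 0.0, 1.0, 1.0, 1.0, 0.5, 0.0])
        path = tmp_path / "t.bedGraph"
        formats.write_bedgraph([Track("chr1", values)], path)
        expanded = np.zeros(7)
        for line in path.read_text().splitlines():
            _, s, e, v = line.split("\t")
            expanded[int(s):int(e)] = float(v)
        assert np.array_equal(expanded, values)

    def test_overlapping_runs_rejected(self, tmp_path):
        path = tmp_path / "bad.bedGraph"
        path.write_text("chr1\t0\t10\t1\nchr1\t5\t15\t2\n")
        with pytest.raises(ValueError, match="overlap"):
            formats.read_bedgraph(path)


class TestStepSeriesTsv:
    def test_round_trip(self, tmp_path):
        un, _ = synthio.sim_step_series(n_positions=5, n_snapshots=20, seed=2)
        path = tmp_path / "s.tsv"
        formats.write_step_series(un, path)
        back = formats.read_step_series(path, modification_site=2)
        assert back.parameters == un.parameters
        assert np.allclose(back.values, un.values)


class TestGroundTruthJson:
    def test_round_trip(self, tmp_path, small_data):
        _, _, truth = small_data
        path = tmp_path / "gt.json"
        formats.write_ground_truth(truth, path)
        back = formats.read_ground_truth(path)
        assert back.condition == truth.condition
        assert back.centers.equals(truth.centers)
        assert np.allclose(back.methylome.df["level"],
                           truth.methylome.df["level"])


class TestIntervalArithmetic:
    @staticmethod
    def _coverage(intervals, length):
        cov = np.zeros(length, dtype=bool)
        for s, e in intervals:
            cov[s:min(e, length)] = True
        return cov

    def test_merge_complement_partition_property(self):
        """merge(I) and complement(I) partition [0, L) for random I."""
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @settings(derandomize=True, max_examples=50)
        @given(st.lists(st.tuples(st.integers(0, 190),
                                  st.integers(1, 40)), max_size=20))
        def check(pairs):
            intervals = [(s, s + l) for s, l in pairs]
            merged = merge_intervals(intervals)
            comp = complement_intervals(intervals, 200)
            cov_m = self._coverage(merged, 200)
            cov_c = self._coverage(comp, 200)
            assert not (cov_m & cov_c).any()
            assert (cov_m | cov_c).all()
            assert np.array_equal(cov_m, self._coverage(intervals, 200))

        check()

    def test_sorted_merge_matches_sweep_line_oracle(self):
        """Merged random intervals equal an independent sweep-line
        recomputation over per-bp coverage."""
        rng = np.random.default_rng(3)
        starts = rng.integers(0, 900, size=1000)
        intervals = [(int(s), int(s + rng.integers(1, 60))) for s in starts]
        merged = merge_intervals(intervals)
        covered = np.zeros(1000, dtype=bool)
        for s, e in intervals:
            covered[s:min(e, 1000)] = True
        edges = np.flatnonzero(np.diff(np.concatenate(
            [[0], covered.astype(int), [0]])))
        oracle = [(int(a), int(b)) for a, b in zip(edges[::2], edges[1::2])]
        clipped = [(s, min(e, 1000)) for s, e in merged]
        assert clipped == oracle

    def test_complement_is_involution_partner(self):
        intervals = [(5, 10), (20, 30)]
        comp = complement_intervals(intervals, 40)
        assert comp == [(0, 5), (10, 20), (30, 40)]
        assert complement_intervals(comp, 40) == intervals
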