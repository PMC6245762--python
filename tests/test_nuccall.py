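"""Occupancy tracks, center calling, fuzziness, protected-6mA ratio."""

import numpy as np
import pandas as pd
import pytest

from sixma import nuccall, synthio
from sixma.model import FragmentSet, Methylome


def _frags(rows):
    return FragmentSet(pd.DataFrame(rows, columns=FragmentSet.COLUMNS))


class TestOccupancyTrack:
    def test_single_fragment_kernel_at_midpoint(self):
        frags = _frags([("chr1", 400, 550, "+")])
        tracks = nuccall.occupancy_track(frags, {"chr1": 1000})
        assert int(np.argmax(tracks["chr1"].values)) == 475

    def test_mass_conservation(self):
        rng = np.random.default_rng(0)
        rows = [("chr1", int(s), int(s) + 147, "+")
                for s in rng.integers(200, 4000, size=500)]
        tracks = nuccall.occupancy_track(_frags(rows), {"chr1": 5000})
        assert tracks["chr1"].values.sum() == pytest.approx(500, rel=1e-6)

    def test_matches_naive_kernel_sum(self):
        """Track values equal the direct O(n*m) Gaussian kernel sum."""
        rng = np.random.default_rng(1)
        mids = rng.integers(300, 1700, size=50)
        rows = [("chr1", int(m) - 50, int(m) + 50, "+") for m in mids]
        bw = 30.0
        tracks = nuccall.occupancy_track(_frags(rows), {"chr1": 2000},
                                         bandwidth=bw)
        check_at = rng.integers(300, 1700, size=100)
        for x in check_at:
            naive = np.exp(-((x - mids) ** 2) / (2 * bw**2)).sum()
            naive /= bw * np.sqrt(2 * np.pi)
            # the track uses a discretized, truncated kernel: agree to ~0.1%
            assert tracks["chr1"].values[x] == pytest.approx(
                naive, rel=2e-3, abs=1e-6)

    def test_requires_fragments(self):
        with pytest.raises(ValueError):
            nuccall.occupancy_track(
                _frags([]), {"chr1": 100})


class TestCallCenters:
    def test_two_distant_kernels_two_centers(self):
        rows = [("chr1", 400 - 73, 400 + 74, "+"),
                ("chr1", 800 - 73, 800 + 74, "+")]
        tracks = nuccall.occupancy_track(_frags(rows), {"chr1": 1500})
        centers = nuccall.call_centers(tracks)
        assert list(centers["center"]) == [400, 800]

    def test_close_kernels_collapse_under_spacing(self):
        rows = [("chr1", 400 - 73, 400 + 74, "+"),
                ("chr1", 450 - 73, 450 + 74, "+")]
        tracks = nuccall.occupancy_track(_frags(rows), {"chr1": 1000})
        centers = nuccall.call_centers(tracks, min_spacing=147)
        assert len(centers) == 1

    def test_flat_track_zero_centers(self):
        from sixma.model import Track
        centers = nuccall.call_centers(Track("chr1", np.ones(500)))
        assert len(centers) == 0

    def test_noiseless_fragments_recover_true_centers_exactly(self, wt_data):
        genome, genes, _ = wt_data
        truth = synthio.gen_ground_truth(genome, genes, jitter_sigma=0.0,
                                         seed=1)
        frags = synthio.sim_mnase_fragments(truth, genome, depth=3,
                                            overhang_mean=0.0, seed=1)
        tracks = nuccall.occupancy_track(frags, genome.sizes)
        centers = nuccall.call_centers(tracks)
        for chrom in genome.sizes:
            called = centers[centers["chrom"] == chrom]["center"].to_numpy()
            assert np.array_equal(np.sort(called), truth.centers_on(chrom))

    def test_center_recall_and_accuracy_at_default_depth(self, wt_data,
                                                         wt_centers):
        """>=95% of true centers recovered within 10 bp."""
        _, _, truth = wt_data
        n_true = n_found = 0
        for chrom, sub in wt_centers.groupby("chrom"):
            called = np.sort(sub["center"].to_numpy())
            for c in truth.centers_on(chrom):
                n_true += 1
                i = np.searchsorted(called, c)
                near = min(
                    abs(called[j] - c)
                    for j in (max(i - 1, 0), min(i, len(called) - 1)))
                n_found += near <= 10
        assert n_found / n_true >= 0.95


class TestFuzziness:
    def test_identical_midpoints_zero_fuzziness(self):
        rows = [("chr1", 427, 574, "+")] * 5
        centers = pd.DataFrame({"chrom": ["chr1"], "center": [500]})
        numap = nuccall.fuzziness(_frags(rows), centers)
        assert numap.table["fuzziness"].iloc[0] == 0.0

    def test_symmetric_pair_closed_form(self):
        """Midpoints at center +-10 in equal numbers: population s.d. = 10."""
        rows = ([("chr1", 490 - 73, 490 + 74, "+")] * 4
                + [("chr1", 510 - 73, 510 + 74, "+")] * 4)
        centers = pd.DataFrame({"chrom": ["chr1"], "center": [500]})
        numap = nuccall.fuzziness(_frags(rows), centers)
        assert numap.table["fuzziness"].iloc[0] == pytest.approx(10.0)

    def test_sparse_centers_excluded_but_counted(self):
        # center 500: one midpoint (undefined); center 900: two at +-5
        rows = [("chr1", 427, 574, "+"),
                ("chr1", 895 - 73, 895 + 74, "+"),
                ("chr1", 905 - 73, 905 + 74, "+")]
        centers = pd.DataFrame({"chrom": ["chr1", "chr1"],
                                "center": [500, 900]})
        numap = nuccall.fuzziness(_frags(rows), centers)
        assert numap.n_undefined == 1
        assert numap.genome_mean_fuzziness == pytest.approx(5.0)

    def test_recovers_generator_jitter_within_10pct(self, wt_data,
                                                    wt_fragments,
                                                    wt_centers):
        _, _, truth = wt_data
        numap = nuccall.fuzziness(wt_fragments, wt_centers)
        assert abs(numap.genome_mean_fuzziness - truth.jitter_sigma) \
            <= 0.10 * truth.jitter_sigma

    def test_ko_fuzzier_than_wt(self, small_data):
        genome, genes, truth = small_data
        wt_f = synthio.sim_mnase_fragments(truth, genome, seed=21)
        ko = synthio.gen_ground_truth(genome, genes, mode="ko", seed=11)
        ko_f = synthio.sim_mnase_fragments(ko, genome, seed=21)
        res = {}
        for name, fr in (("wt", wt_f), ("ko", ko_f)):
            tracks = nuccall.occupancy_track(fr, genome.sizes)
            centers = nuccall.call_centers(tracks)
            res[name] = nuccall.fuzziness(fr, centers).genome_mean_fuzziness
        assert res["ko"] > res["wt"]


class TestProtectedRatio:
    def test_empty_methylome_undefined_ratio(self, small_data):
        genome, _, truth = small_data
        frags = synthio.sim_mnase_fragments(truth, genome, depth=2, seed=0)
        res = nuccall.protected_6mA_ratio(frags, Methylome(), genome.sizes)
        assert res["inside_per_bp"] == 0 and res["outside_per_bp"] == 0
        assert np.isnan(res["ratio"])

    def test_noiseless_truth_gives_zero_inside(self, wt_data):
        """With zero jitter and no overhang, protected DNA contains no 6mA:
        the sites were planted strictly in linkers."""
        genome, genes, _ = wt_data
        truth = synthio.gen_ground_truth(genome, genes, jitter_sigma=0.0,
                                         seed=2)
        frags = synthio.sim_mnase_fragments(truth, genome, depth=2,
                                            overhang_mean=0.0, seed=2)
        res = nuccall.protected_6mA_ratio(frags, truth.methylome,
                                          genome.sizes)
        assert res["inside_per_bp"] == 0.0
        assert res["ratio"] == 0.0

    def test_jittered_fragments_still_depleted(self, wt_data, wt_fragments):
        """At 30x pooled depth the depth-aware (protected mass vs
        flow-through mass) comparison still shows 6mA depletion."""
        genome, _, truth = wt_data
        res = nuccall.protected_6mA_ratio(wt_fragments, truth.methylome,
                                          genome.sizes, n_cells=30,
                                          regions=truth.array_spans())
        assert res["inside_per_bp"] < res["outside_per_bp"]
        assert res["ratio"] < 1.0
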