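"""Generator correctness: geometry, determinism, methylome placement rules."""

import numpy as np
import pytest
from scipy import stats

from sixma import synthio
from sixma.model import GenomeSpec, Methylome
from sixma.synthio import MethylParams

import pandas as pd


class TestGenGenome:
    def test_zero_genes_gives_empty_gene_list(self):
        spec = GenomeSpec(n_chrom=1, chrom_len=20_000, n_genes=0, seed=0)
        genome, genes = synthio.gen_genome(spec)
        assert genes == []
        assert genome.total_bp == 20_000

    def test_same_seed_is_bit_identical(self):
        spec = GenomeSpec(n_chrom=2, chrom_len=30_000, n_genes=8, seed=4)
        g1, genes1 = synthio.gen_genome(spec)
        g2, genes2 = synthio.gen_genome(spec)
        assert g1.seqs == g2.seqs
        assert genes1 == genes2

    def test_genes_do_not_overlap_brute_force(self):
        spec = GenomeSpec(n_chrom=1, chrom_len=50_000, n_genes=9, seed=1)
        _, genes = synthio.gen_genome(spec)
        assert len(genes) == 9
        for i, a in enumerate(genes):
            for b in genes[i + 1:]:
                if a.chrom != b.chrom:
                    continue
                assert a.end <= b.start or b.end <= a.start

    def test_chrom_too_short_raises(self):
        spec = GenomeSpec(n_chrom=1, chrom_len=10_000, n_genes=50, seed=0)
        with pytest.raises(ValueError, match="too short"):
            synthio.gen_genome(spec)

    def test_gc_content_matches_request(self):
        spec = GenomeSpec(n_chrom=1, chrom_len=100_000, n_genes=0,
                          gc_content=0.3, seed=2)
        genome, _ = synthio.gen_genome(spec)
        seq = genome["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.3) < 0.01


class TestGroundTruth:
    def test_wga_methylome_is_empty(self, wt_data):
        genome, genes, _ = wt_data
        truth = synthio.gen_ground_truth(genome, genes,
                                         mode="in_vitro_wga", seed=0)
        assert truth.methylome.empty

    def test_ko_levels_are_exact_knockdown_of_wt(self, wt_data):
        genome, genes, truth = wt_data
        ko = synthio.gen_ground_truth(genome, genes, mode="ko", seed=11)
        wt_df = truth.methylome.df
        ko_df = ko.methylome.df
        assert len(wt_df) == len(ko_df)
        ratio = ko_df["level"].to_numpy() / wt_df["level"].to_numpy()
        assert np.allclose(ratio, 1.0 - synthio.KO_KNOCKDOWN)

    def test_true_center_spacing_is_exactly_L(self, wt_data):
        _, genes, truth = wt_data
        for gi in range(5):
            sub = truth.centers[truth.centers["gene_idx"] == gi]
            centers = np.sort(sub["center"].to_numpy())
            assert np.all(np.diff(centers) == truth.repeat_length)

    def test_first_footprint_starts_at_nfr_end(self, wt_data):
        _, genes, truth = wt_data
        for gi, gene in enumerate(genes[:10]):
            centers = truth.centers[truth.centers["gene_idx"] == gi]["center"]
            nearest = centers.iloc[(centers - gene.tss).abs().argmin()]
            assert abs(nearest - gene.tss) == truth.nfr_width + 73

    def test_L_below_core_raises(self, wt_data):
        genome, genes, _ = wt_data
        with pytest.raises(ValueError, match="147"):
            synthio.gen_ground_truth(genome, genes, L=140)

    def test_all_6mA_at_apt_dinucleotides(self, wt_data):
        genome, _, truth = wt_data
        for rec in truth.methylome.df.itertuples():
            seq = genome[rec.chrom]
            if rec.strand == "+":
                assert seq[rec.pos : rec.pos + 2] == "AT"
            else:  # minus-strand A pairs with the plus-strand T
                assert seq[rec.pos - 1 : rec.pos + 1] == "AT"

    def test_6mA_confined_to_linkers_in_first_kb(self, wt_data):
        """All generated sites lie in true linkers within 1 kb downstream
        of a TSS (the spec bound is >=95%; construction gives 100%)."""
        _, genes, truth = wt_data
        linkers = truth.linkers
        windows = []
        for g in genes:
            sign = 1 if g.strand == "+" else -1
            lo = min(g.tss, g.tss + sign * 1000)
            windows.append((g.chrom, lo, max(g.tss, g.tss + sign * 1000)))
        n_ok = 0
        for rec in truth.methylome.df.itertuples():
            in_linker = ((linkers["chrom"] == rec.chrom)
                         & (linkers["start"] <= rec.pos)
                         & (rec.pos < linkers["end"])).any()
            in_window = any(c == rec.chrom and lo <= rec.pos < hi
                            for c, lo, hi in windows)
            n_ok += in_linker and in_window
        assert n_ok == len(truth.methylome)

    def test_wga_centers_respect_core_exclusion(self, wt_data):
        genome, genes, _ = wt_data
        truth = synthio.gen_ground_truth(genome, genes,
                                         mode="in_vitro_wga", seed=3)
        for chrom in genome.sizes:
            c = truth.centers_on(chrom)
            assert np.all(np.diff(c) >= 147)


class TestMNase:
    def test_noiseless_fragments_are_exact_cores(self, wt_data):
        genome, genes, _ = wt_data
        truth = synthio.gen_ground_truth(genome, genes, jitter_sigma=0.0,
                                         seed=0)
        frags = synthio.sim_mnase_fragments(truth, genome, depth=2,
                                            overhang_mean=0.0, seed=0)
        true_cores = set()
        for chrom in genome.sizes:
            for c in truth.centers_on(chrom):
                true_cores.add((chrom, c - 73, c + 74))
        for r in frags.df.itertuples():
            assert (r.chrom, r.start, r.end) in true_cores

    def test_modal_length_rounds_to_150(self, wt_fragments):
        lengths = wt_fragments.lengths()
        assert len(lengths) >= 40_000
        mode = np.bincount(lengths).argmax()
        assert round(mode / 10) * 10 == 150

    def test_midpoint_sd_matches_jitter_sigma(self, wt_data, wt_fragments):
        genome, _, truth = wt_data
        chrom = "chr1"
        centers = truth.centers_on(chrom)
        mids = wt_fragments.midpoints(chrom)
        idx = np.searchsorted(centers, mids)
        nearest = centers[np.clip(idx, 0, len(centers) - 1)]
        alt = centers[np.clip(idx - 1, 0, len(centers) - 1)]
        nearest = np.where(np.abs(mids - alt) < np.abs(mids - nearest),
                           alt, nearest)
        dev = (mids - nearest).astype(float)
        dev = dev[np.abs(dev) <= 100]
        assert abs(np.std(dev) - truth.jitter_sigma) < 0.1 * truth.jitter_sigma

    def test_depth_zero_rejected(self, wt_data):
        genome, _, truth = wt_data
        with pytest.raises(ValueError):
            synthio.sim_mnase_fragments(truth, genome, depth=0)


class TestIPReads:
    def test_no_enrichment_matches_input(self, small_data):
        genome, _, truth = small_data
        ip, inp = synthio.sim_ip_reads(genome, truth.methylome,
                                       n_fragments=20_000,
                                       enrich_per_site=0.0, seed=0)
        ks = stats.ks_2samp(ip.midpoints("chr1"), inp.midpoints("chr1"))
        assert ks.pvalue > 0.01

    def test_single_locus_fraction_matches_exact_weights(self):
        genome = synthio.ToyGenome({"chr1": "ACGT" * 2500})  # 10 kb
        locus = 5_000
        meth = Methylome(pd.DataFrame(
            {"chrom": ["chr1"], "pos": [locus], "strand": ["+"],
             "level": [1.0]}))
        flen, enrich = 250, 50.0
        ip, _ = synthio.sim_ip_reads(genome, meth, n_fragments=30_000,
                                     frag_len_mean=flen, frag_len_sd=0.0,
                                     enrich_per_site=enrich, seed=1)
        # exact expected overlap fraction by brute-force weight normalization
        n_starts = 10_000 - flen + 1
        starts = np.arange(n_starts)
        w = np.ones(n_starts)
        covering = (starts <= locus) & (starts + flen > locus)
        w[covering] += enrich
        expected = w[covering].sum() / w.sum()
        df = ip.df
        overlap = ((df["start"] <= locus) & (df["end"] > locus)).mean()
        assert overlap > 0.5
        assert abs(overlap - expected) < 0.02

    def test_determinism(self, small_data):
        genome, _, truth = small_data
        a = synthio.sim_ip_reads(genome, truth.methylome,
                                 n_fragments=5000, seed=9)
        b = synthio.sim_ip_reads(genome, truth.methylome,
                                 n_fragments=5000, seed=9)
        assert a[0].df.equals(b[0].df)
        assert a[1].df.equals(b[1].df)

    def test_unknown_chromosome_raises(self, small_data):
        genome, _, _ = small_data
        meth = Methylome(pd.DataFrame(
            {"chrom": ["chrX"], "pos": [5], "strand": ["+"], "level": [0.5]}))
        with pytest.raises(KeyError):
            synthio.sim_ip_reads(genome, meth, n_fragments=10)


class TestREDigest:
    def _toy_with_sites(self, levels_at_sites):
        """10 GATC sites, 500 bp apart, in an A-rich backbone."""
        seq = list("A" * 6000)
        positions = [500 * (i + 1) for i in range(10)]
        for p in positions:
            seq[p : p + 4] = "GATC"
        genome = synthio.ToyGenome({"chr1": "".join(seq)})
        rows = []
        for p, lev in zip(positions, levels_at_sites):
            rows.append(("chr1", p + 1, "+", lev))
            rows.append(("chr1", p + 2, "-", lev))
        meth = Methylome(pd.DataFrame(
            rows, columns=["chrom", "pos", "strand", "level"]))
        return genome, meth, positions

    def test_dpnII_fully_methylated_never_cut(self):
        from sixma.recall import get_enzyme
        genome, meth, _ = self._toy_with_sites([1.0] * 10)
        frags = synthio.sim_re_digest(genome, meth, get_enzyme("DpnII"),
                                      cut_efficiency=1.0, n_molecules=5,
                                      seed=0)
        assert np.all(frags.lengths() == 6000)  # whole molecules survive

    def test_dpnI_unmethylated_never_cut(self):
        from sixma.recall import get_enzyme
        genome, meth, _ = self._toy_with_sites([0.0] * 10)
        frags = synthio.sim_re_digest(genome, meth, get_enzyme("DpnI"),
                                      cut_efficiency=1.0, n_molecules=5,
                                      seed=0)
        assert np.all(frags.lengths() == 6000)

    def test_dpnI_alternating_levels_cut_exactly_at_methylated(self):
        from sixma.recall import get_enzyme
        levels = [0, 1] * 5
        genome, meth, positions = self._toy_with_sites(levels)
        frags = synthio.sim_re_digest(genome, meth, get_enzyme("DpnI"),
                                      cut_efficiency=1.0, n_molecules=1,
                                      seed=0)
        # DpnI cuts between A and T: boundary at site_start + 2
        expected_cuts = sorted(p + 2 for p, l in zip(positions, levels) if l)
        bounds = sorted(frags.df["start"])[1:]  # drop the chromosome start
        assert bounds == expected_cuts

    def test_determinism(self, small_data):
        from sixma.recall import get_enzyme
        genome, _, truth = small_data
        a = synthio.sim_re_digest(genome, truth.methylome,
                                  get_enzyme("DpnI"), seed=3)
        b = synthio.sim_re_digest(genome, truth.methylome,
                                  get_enzyme("DpnI"), seed=3)
        assert a.df.equals(b.df)


class TestStepSeries:
    def test_zero_effect_gives_identical_trajectories(self):
        """With no modification effect the paired series share innovations,
        so they are bit-identical."""
        eff = synthio.ModificationEffect(delta_mean={}, sd_scale={})
        un, mod = synthio.sim_step_series(n_snapshots=500,
                                          modification_effect=eff, seed=5)
        assert np.array_equal(un.values, mod.values)

    def test_white_noise_sd_matches_closed_form(self):
        un, _ = synthio.sim_step_series(
            n_snapshots=10_000, ar1_rho=0.0,
            base_sd={p: 5.0 for p in synthio.ALL_PARAMETERS}, seed=6)
        sample_sd = un.values[0, 5, :].std()
        se = 5.0 / np.sqrt(2 * 10_000)  # SE of the s.d. for iid normal
        assert abs(sample_sd - 5.0) < 3 * se

    def test_stationary_sd_under_ar1(self):
        un, _ = synthio.sim_step_series(n_snapshots=20_000, ar1_rho=0.8,
                                        seed=7)
        ri = un.index_of("roll")
        sd = un.values[ri, 3, :].std()
        assert abs(sd - synthio.BASE_SD["roll"]) < 0.15

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            synthio.sim_step_series(ar1_rho=1.0)
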