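# sixma

Synthetic-data reimplementation of the analysis chain linking N6-adenine DNA
methylation (6mA) to nucleosome organization in an AT-rich, gene-dense
genome of the kind found in ciliates.

In such genomes 6mA sits on both strands of ApT dinucleotides, concentrated
in the **linkers** between nucleosomes in the first kilobase downstream of
transcription start sites (TSS), where nucleosomes form phased arrays with a
repeat length of roughly 200 bp. Because 6mA stiffens the duplex and
disfavors wrapping, methylation and nucleosome occupancy are anti-phased,
and losing methylation (methyltransferase knockout, or whole-genome
amplification of the substrate) blurs or randomizes the arrays. This package
implements every computational step of that story on synthetic data with
known ground truth, so each estimator can be validated against what was
planted.

## What is implemented

- **`sixma.synthio`** — generators for a toy genome with non-overlapping
  genes, phased nucleosome arrays (repeat `L`, nucleosome-free region of
  width `nfr` downstream of each TSS, `K` nucleosomes per gene), an ApT
  methylome confined to array linkers in the first kb downstream of TSS,
  MNase-protected fragments (147 bp core + Poisson overhang, per-cell
  center jitter), IP/input fragment pairs, methylation-sensitive
  restriction digests, and AR(1) trajectories of the 12 base-pair
  structural parameters. Four condition modes: `in_vivo`, `ko` (levels
  scaled by 1 − 0.378, fuzzier arrays), `in_vitro_native`, `in_vitro_wga`
  (no methylation, randomized positions).
- **`sixma.recall`** — single-base 6mA calling from digests with DpnI
  (cuts G(6mA)TC), DpnII and CviAII (blocked by 6mA at GATC / CATG):
  per-site binomial test of cut-end or spanning evidence against the
  unmethylated-site null, Benjamini–Hochberg FDR across candidates.
- **`sixma.peakcall`** — windowed Poisson IP-vs-input peak calling and the
  genomic-component enrichment score
  `score(c) = (peak bp in c / peak bp) / (bp of c / genome bp)`.
- **`sixma.nuccall`** — Gaussian-kernel occupancy from fragment midpoints,
  greedy center calling with minimum spacing, per-nucleosome **fuzziness**
  (s.d. of assigned midpoints), and the protected-vs-unprotected 6mA ratio.
- **`sixma.metagene`** — strand-aware TSS-anchored profiles, phasing
  periodicity by detrended autocorrelation with a shuffle-permutation
  null, and 6mA/nucleosome cross-correlation (anti-phasing).
- **`sixma.placement`** — a thermodynamic (Tonks-gas) placement model:
  hard 147-bp footprints on a 1-D lattice with per-footprint energy
  `E = −μ + w · Σ(6mA levels under the footprint)` at unit temperature,
  sampled by grand-canonical Metropolis Monte Carlo and solved exactly by
  transfer-matrix dynamic programming (the MC sampler is validated against
  the DP, the DP against brute-force enumeration).
- **`sixma.mdstats`** — block-averaged means/fluctuations of the 12
  structural parameters and modified-minus-unmodified delta profiles vs
  distance from the methylation site.
- **`sixma.qpcr`** — the Input% validation formula
  `ΔCt = Ct_IP − (Ct_input − log2 DF)`, `Input% = 100 / 2^ΔCt` (DF = 7).

## Worked example

```python
from sixma import synthio, nuccall, metagene
from sixma.model import GenomeSpec

spec = GenomeSpec(seed=1)                      # 5 x 220 kb, 300 genes
genome, genes = synthio.gen_genome(spec)
truth = synthio.gen_ground_truth(genome, genes, mode="in_vivo", seed=1)
frags = synthio.sim_mnase_fragments(truth, genome, seed=1)   # 30x depth
tracks = nuccall.occupancy_track(frags, genome.sizes)
centers = nuccall.call_centers(tracks)
feats = {c: centers[centers.chrom == c]["center"].to_numpy()
         for c in genome.sizes}
prof = metagene.anchor_profile(feats, [(g.chrom, g.tss, g.strand)
                                       for g in genes], W=1500)
print(metagene.periodicity(prof, seed=1))
# {'period': 200, 'peak_acf': 0.723..., 'p': 0.00498...}
```

The estimator recovers the planted 200-bp repeat with the smallest p-value
the 200-shuffle permutation null can produce. The numbered drivers under
`analysis/` run the full study; for example `python
analysis/05_metagene_phasing.py` prints, per condition, the nucleosome and
6mA periods (200 bp, p ≈ 0.005 wherever the substrate is methylated; 182 bp
with p ≈ 0.17 on WGA DNA) and the anti-correlation (r₀ ≈ −0.36 with best
alignment shift ≈ ±100 bp ≈ L/2), and `python analysis/02_nucleosome_map.py`
reports the ~150-bp fragment-length mode, ≥99% center recovery at wild-type
depth, and mean fuzziness 19.6 bp (WT, true jitter 20) vs 40.8 bp (KO,
true jitter 45).

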