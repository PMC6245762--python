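# Methods

## The system being modeled

The package studies the interplay of N6-adenine methylation (6mA) and
nucleosome positioning in an AT-rich, gene-dense genome. The empirical
picture it encodes: 6mA occurs on both strands of ApT dinucleotides
(the dinucleotide is its own reverse complement, so full methylation is
symmetric); sites concentrate in inter-nucleosomal linker DNA within the
first kilobase downstream of TSSs; nucleosomes downstream of the TSS form
phased arrays with repeat length L ≈ 200 bp behind a nucleosome-depleted
region; and methylation stiffens the duplex, so nucleosomes avoid
methylated DNA (anti-phasing) and lose positional order when methylation is
reduced (knockout) or absent (whole-genome-amplified substrate).

Everything runs on synthetic data with recorded ground truth. Passing tests
therefore demonstrate that the estimators recover what the generator
planted under the stated noise model — not that any particular real genome
behaves this way.

## Synthetic data generator (`synthio`)

**Genome and genes.** `n_genes` non-overlapping 2-kb genes (400-bp first
exon, 800-bp intron, 800-bp second exon) are spaced evenly with random
offsets on `n_chrom` chromosomes, 2 kb clear of chromosome ends, with
random strand. Sequence is i.i.d. at the requested GC content (default
0.30, an AT-rich genome); in the planned linkers GC is reduced by a further
factor (default 0.10) so the ApT methylation context is mildly enriched
where linkers will fall.

**Array geometry.** True centers sit at
`tss + nfr_offset + k·L` (k = 1..K, transcription direction), with
`nfr_offset = nfr_width − (L − 73)` so that `[tss, tss + nfr_width)` is
exactly footprint-free and the first 147-bp core starts at
`tss + nfr_width`. Defaults: L = 200, nfr_width = 300, K = 5. Linkers are
the L − 147 = 53-bp gaps between consecutive cores.

**Methylome.** Every ApT whose dinucleotide lies inside an
inter-nucleosomal linker *and* within the first kilobase downstream of the
TSS is methylated on both strands at level β = 0.8. The nucleosome-free
region and intergenic DNA stay unmethylated — the generator encodes the
observed confinement of 6mA to the downstream linker kilobase, which also
makes the "≥95% of sites in linkers within 1 kb" property hold by
construction. The knockout scales every level by 1 − 0.378 (uniform
intensity knockdown: the pattern is kept, the intensity drops — the
measured genome-wide reduction). `in_vitro_native` shares the wild-type
methylome; `in_vitro_wga` has an empty one and places the K nucleosomes of
each gene at random non-overlapping positions in the array span instead of
periodically (amplified DNA carries no positioning signal beyond the NFR).

**MNase fragments.** Per true nucleosome, `depth` (default 30) fragments
are drawn: center jittered by Normal(0, σ) per cell (σ = 20 bp WT, 45 bp
KO — the knockout's positional disorder), length 147 + Poisson(3) with the
overhang split binomially between the ends. The modal length is therefore
149–150 bp, i.e. the familiar ~150-bp MNase band.

**IP/input.** Input fragment starts are uniform; IP starts are drawn with
weight `1 + e · Σ(levels inside the fragment)` (e = 8 by default,
level-proportional rather than binary — an explicit modeling choice, kept
as a parameter). Fragment length is Normal(250, 30); weights are computed
at the mean length, which is exact in the sd = 0 case the oracle test uses.

**Restriction digests.** Each of `n_molecules` (default 30) genome copies
is digested independently: a site is cut with probability
`eff · level` (methylation-required, DpnI) or `eff · (1 − level)`
(methylation-blocked, DpnII/CviAII), eff = 0.9; fragments are the
intervals between realized cuts. Pooling molecules is what gives the
caller countable per-site evidence.

**Step-parameter trajectories.** Each (parameter, position) series is a
stationary AR(1) process (ρ = 0.6 between 20-ps snapshots) with B-DNA-like
means and fluctuation magnitudes. The modified duplex applies, with a
linear taper vanishing 4 bp from the site: mean shifts of +3°/−3° for
roll/twist, fluctuation scaling of 0.85 (roll), 0.93 (twist), 0.97 for
most others and 1.02 for tilt/slide/buckle/opening. The paired series
share innovations (common random numbers), so a zero effect gives
bit-identical trajectories and any difference is attributable to the
effect.

All simulators derive child RNG streams from one root seed and are
bit-reproducible.

## Callers and statistics

**6mA restriction caller (`recall`).** Candidates are all forward-strand
matches of the recognition sequence (the palindromes cover both strands;
plus/minus evidence is pooled per site and the call is reported at the
plus-strand adenine). Evidence per site: fragment starts at the expected
cut position ±1 bp (cut evidence, DpnI) or fragments spanning the intact
site (protection evidence, DpnII/CviAII); trials are cut + spanning
observations. The one-sided binomial null rate is the evidence fraction an
*unmethylated* site would give: a nonspecific cut rate (0.05) for cut
evidence, the uncut fraction 1 − eff for protection evidence. BH-FDR at
q ≤ 0.01 across candidates. On default data all three enzymes reach ≥99%
precision and recall and agree on shared sites.

**Peak caller (`peakcall`).** Midpoint counts in 100-bp windows; Poisson
upper tail with expectation = (input count + 1) scaled by the library-size
ratio; BH across windows; runs of significant windows merge, summit = bp
of maximal IP count. Enrichment scores are bp-weighted (peak bp, not peak
count), so the component-fraction-weighted mean score is identically 1.

**Nucleosome caller (`nuccall`).** Occupancy is a Gaussian-kernel density
(bandwidth 30 bp) of fragment midpoints; centers are local maxima accepted
greedily by height with ≥147 bp mutual spacing, ties to the left.
Fuzziness is the population s.d. of midpoints assigned to their nearest
center within ±100 bp; the genome mean is occupancy-weighted, and centers
with <2 midpoints are excluded but counted. The ±100-bp window slightly
truncates the KO's midpoint distribution (recovered 40.8 vs true 45), a
known and documented bias; the WT estimate is essentially unbiased.

**Protected-6mA ratio.** For placement-model samples the spec-simple
union form is used (per-sample footprint coverage). For pooled multi-cell
MNase fragment sets the comparison is mass-weighted: protected mass =
coverage-weighted level, flow-through mass = (depth − coverage)-weighted,
restricted to the chromatinized array spans. The restriction matters
because this toy genome carries no nucleosomes outside gene arrays, so an
unrestricted "flow-through" would be dominated by naked intergenic DNA
that no MNase assay of chromatin would see; within arrays the wild-type
ratio is ≈ 0.14 (strong depletion of 6mA in protected DNA).

**Metagene profiles and periodicity (`metagene`).** Point features
accumulate into offsets relative to anchors; minus-strand anchors flip
sign so positive offsets are downstream in transcription direction.
Periodicity of the [0, 1000]-bp downstream segment: subtract a 301-bp
moving average (reflected boundaries), compute the per-lag Pearson
autocorrelation of the residual (each lag normalized on its own overlap,
so a pure cosine peaks exactly at its period), and take the highest local
maximum in lags 120–300 bp. Significance comes from shuffling the residual
values (500 permutations by default; p has the +1 correction). A
circular-shift null was considered and rejected: the autocorrelation is
invariant under circular shifts, so that null has no power; shuffling
destroys exactly the serial structure being tested while preserving the
marginal distribution. Anti-correlation: Pearson r in the window at shift
0, plus the shift of one profile maximizing r (ties resolve to the
smallest downstream shift); for spike-train profiles both signals can be
Gaussian-smoothed first (σ = 20 bp in the pipeline) to stabilize the
argmax.

## Placement model (`placement`)

A 1-D Tonks gas: hard footprints of a bp (147 by default) on an open
lattice, non-overlapping, with footprint energy
`E(s) = −μ + w · Σ_{i∈[s,s+a)} m_i` at temperature 1, where `m_i` is the
per-bp methylation level. Linearity of the penalty in summed level is the
simplest form producing repulsion and makes the model exactly solvable.

*Exact solution.* Forward/backward partition functions
`F[i] = F[i−1] + w_{i−a} F[i−a]`, `B[i] = B[i+1] + w_i B[i+a]` in log
space; `P(footprint at s) = F[s] w_s B[s+a] / F[N]`; occupancy is the
running sum of start probabilities. Guarded to lattices ≤ 2 kb. Verified
against exhaustive enumeration on 40-bp lattices.

*Monte Carlo.* Grand-canonical Metropolis with insert (uniform start,
acceptance `min(1, w_s M/(N+1))`, M = number of admissible starts), delete
(`min(1, N/(M w_s))`) and local shift (±10 bp, `min(1, w_t/w_s)`) moves;
one sweep = `lattice/a + 1` attempted moves; burn-in 20% of sweeps;
occupancy is the post-burn-in average coverage. Dense hard-rod systems mix
slowly (vacancy diffusion), so the deviation from the exact solution
decays as ~1/√sweeps: ≈ 0.015 absolute at 100k sweeps on the standard
300-bp / footprint-20 / μ=2 / w=5 instance. Tests assert ≤ 0.02 there and
monotone shrinkage across 10×/100× budgets.

## Structural-parameter statistics (`mdstats`)

Per position and parameter: mean and population s.d. over snapshots; SEMs
by block averaging (default block 100 snapshots; the trailing partial
block is dropped), i.e. the s.d. of block means (or block s.d.s) over
√n_blocks — honest errors under temporal autocorrelation, confirmed
against the analytic AR(1) variance of the mean. Delta profiles subtract
unmodified from modified per position, average the symmetric ±d positions,
and propagate SEMs root-sum-square. The planted −15% roll fluctuation at
the site is recovered within ~2% (well inside 3 SEM at 5000 snapshots).

## qPCR Input% (`qpcr`)

`ΔCt = Ct_IP − (Ct_input − log2 DF)`, `Input% = 100/2^ΔCt`, DF = 7 (70 µl
IP fraction vs 10 µl input). The published formula's unbalanced
parenthesis is resolved as this difference, consistent with its worked
restatement. Replicates are averaged on the Input% scale, not the Ct
scale (averaging Cts would compute a geometric-type mean of percentages).

## Problem sizes and defaults

The default study scale is 300 genes on 5 × 220 kb chromosomes (1.1 Mb),
30× MNase depth (45,000 fragments), 100k IP/input fragments, 30 digest
molecules per enzyme, and 5,000-snapshot trajectories in tests (25,000 in
the analysis driver, matching 500 ns at 20 ps/frame). These sizes give
stable estimates (the three headline numbers vary by <5 bp across seeds)
while the full test suite runs in about a minute.

## Known limitations

- No sequence-dependent nucleosome energetics: placement responds to
  methylation only, and the generator's arrays are planted rather than
  emergent (the placement module shows the mechanism; the generator
  provides the geometry).
- No sequencing error, PCR duplication, mappability, or quality model;
  fragment sets are exact intervals.
- The KO is a pure intensity knockdown with increased positional jitter;
  site gain/loss and partial redundancy among methyltransferases are not
  modeled.
- The restriction digest has no nonspecific (star) activity, so caller
  precision on synthetic data is optimistic; the binomial null still
  budgets for a 5% nonspecific rate.
- Periodicity p-values come from a residual-shuffle null, which tests
  serial structure against exchangeability; it is not a test against
  arbitrary smooth non-periodic trends beyond what the 301-bp detrending
  removes.
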