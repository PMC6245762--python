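"""Synthetic data generation for the 6mA / nucleosome analyses.

The generator emulates the statistical structure the downstream analyses
assume for the AT-rich ciliate-like toy genome:

* a gene-dense genome where each TSS is followed by a nucleosome-depleted
  zone and then a phased array of K nucleosomes at repeat length L;
* 6mA placed on both strands of ApT dinucleotides inside the linkers of the
  first kilobase downstream of each TSS;
* MNase-protected ~150-bp fragments around (jittered) nucleosome centers;
* IP/input fragment pairs with methylation-weighted pull-down;
* methylation-sensitive restriction digests (DpnI / DpnII / CviAII);
* AR(1)-correlated trajectories of the 12 base-pair structural parameters
  with a localized 6mA perturbation.

Four condition modes are supported: ``in_vivo`` (wild type), ``ko``
(methyltransferase knockout: uniformly reduced levels, fuzzier arrays),
``in_vitro_native`` (assembly on native methylated DNA) and ``in_vitro_wga``
(assembly on amplification-erased, unmethylated DNA: randomized positions).

All simulators are bit-reproducible for a fixed (spec, seed): a single root
seed spawns one child stream per simulator via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    ALL_PARAMETERS,
    NUCLEOSOME_CORE_BP,
    FragmentSet,
    GeneModel,
    GenomeSpec,
    GroundTruth,
    Methylome,
    StepParameterSeries,
    ToyGenome,
)

MODES = ("in_vivo", "ko", "in_vitro_native", "in_vitro_wga")

#: Measured global 6mA reduction in the methyltransferase knockout.
KO_KNOCKDOWN = 0.378

# Default array geometry (desk-scale but with the observed proportions:
# repeat ~200 bp, core 147 bp, NFR ~300 bp, 6mA confined to the first kb).
DEFAULT_L = 200
DEFAULT_NFR_WIDTH = 300
DEFAULT_K = 5
DEFAULT_JITTER_WT = 20.0
DEFAULT_JITTER_KO = 45.0
DEFAULT_LEVEL = 0.8
DEFAULT_DEPTH = 30
METHYL_WINDOW = 1000  # 6mA restricted to [tss, tss+1000) downstream

GENE_LEN = 2000
FIRST_EXON_LEN = 400
INTRON_LEN = 800
EDGE_MARGIN = 2000  # keeps metagene windows and arrays on-chromosome


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Deterministic child stream named by purpose."""
    tag = int.from_bytes(stream.encode(), "little") % (2**31)
    return np.random.default_rng(np.random.SeedSequence(entropy=(seed, tag)))


@dataclass(frozen=True)
class MethylParams:
    """How 6mA is laid down on the toy genome."""

    level: float = DEFAULT_LEVEL
    knockdown: float = KO_KNOCKDOWN
    apt_mode: bool = True  # restrict sites to ApT dinucleotides


# ---------------------------------------------------------------------------
# genome + genes
# ---------------------------------------------------------------------------

def _planned_gene_layout(
    spec: GenomeSpec, rng: np.random.Generator
) -> list[tuple[str, int, str]]:
    """(chrom, start, strand) for each gene, non-overlapping with margins."""
    per_chrom = [spec.n_genes // spec.n_chrom] * spec.n_chrom
    for i in range(spec.n_genes % spec.n_chrom):
        per_chrom[i] += 1
    usable = spec.chrom_len - 2 * EDGE_MARGIN
    layout = []
    for ci, n in enumerate(per_chrom):
        if n == 0:
            continue
        pitch = usable // n
        if pitch < GENE_LEN + 200:
            raise ValueError(
                f"chromosome of {spec.chrom_len} bp too short for {n} genes"
            )
        slack = pitch - GENE_LEN
        offsets = rng.integers(0, slack, size=n)
        strands = rng.choice(["+", "-"], size=n)
        for gi in range(n):
            start = EDGE_MARGIN + gi * pitch + int(offsets[gi])
            layout.append((f"chr{ci + 1}", start, str(strands[gi])))
    return layout


def _gene_from_span(chrom: str, start: int, strand: str) -> GeneModel:
    end = start + GENE_LEN
    if strand == "+":
        exons = ((start, start + FIRST_EXON_LEN),
                 (start + FIRST_EXON_LEN + INTRON_LEN, end))
        return GeneModel(chrom, "+", tss=start, tts=end - 1, exons=exons)
    exons = ((start, end - FIRST_EXON_LEN - INTRON_LEN),
             (end - FIRST_EXON_LEN, end))
    return GeneModel(chrom, "-", tss=end - 1, tts=start, exons=exons)


def _array_geometry(
    gene: GeneModel, L: int, nfr_width: int, K: int
) -> tuple[np.ndarray, np.ndarray]:
    """True centers and inter-nucleosomal linkers, in genome coordinates.

    Centers sit at ``tss + nfr_offset + k*L`` (k = 1..K) in transcription
    direction, with ``nfr_offset = nfr_width - (L - 73)`` so that
    [tss, tss+nfr_width) is exactly footprint-free and the first footprint
    begins at tss+nfr_width.
    """
    nfr_offset = nfr_width - (L - 73)
    ks = np.arange(1, K + 1)
    sign = 1 if gene.strand == "+" else -1
    centers = gene.tss + sign * (nfr_offset + ks * L)
    centers = np.sort(centers)
    # linkers: gaps between consecutive core footprints
    starts = centers[:-1] + 74
    ends = centers[1:] - 73
    linkers = np.stack([starts, ends], axis=1)
    return centers, linkers


def gen_genome(
    spec: GenomeSpec,
    L: int = DEFAULT_L,
    nfr_width: int = DEFAULT_NFR_WIDTH,
    K: int = DEFAULT_K,
) -> tuple[ToyGenome, list[GeneModel]]:
    """Generate the toy genome and its gene models.

    Sequence composition is i.i.d. with the requested GC content, except in
    the planned downstream linkers, where GC is reduced by
    ``at_enrichment_in_linkers`` so that ApT dinucleotides (the 6mA context)
    are modestly enriched where linkers will fall — the geometry (L,
    nfr_width, K) is therefore needed at generation time and must match the
    one later passed to :func:`gen_ground_truth`.
    """
    rng = _rng(spec.seed, "genome")
    layout = _planned_gene_layout(spec, rng)
    genes = [_gene_from_span(c, s, st) for c, s, st in layout]

    gc = spec.gc_content
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    gc_link = gc * (1 - spec.at_enrichment_in_linkers)
    link_p = np.array(
        [(1 - gc_link) / 2, gc_link / 2, gc_link / 2, (1 - gc_link) / 2]
    )
    alphabet = np.frombuffer(b"ACGT", dtype="S1")

    linker_mask: dict[str, np.ndarray] = {
        f"chr{i + 1}": np.zeros(spec.chrom_len, dtype=bool)
        for i in range(spec.n_chrom)
    }
    for gene in genes:
        _, linkers = _array_geometry(gene, L, nfr_width, K)
        for s, e in linkers:
            lo, hi = max(0, int(s)), min(spec.chrom_len, int(e))
            linker_mask[gene.chrom][lo:hi] = True

    seqs = {}
    for chrom, mask in linker_mask.items():
        idx = rng.choice(4, size=spec.chrom_len, p=base_p)
        if mask.any():
            idx[mask] = rng.choice(4, size=int(mask.sum()), p=link_p)
        seqs[chrom] = alphabet[idx].tobytes().decode()
    return ToyGenome(seqs), genes


# ---------------------------------------------------------------------------
# ground truth: centers, linkers, methylome
# ---------------------------------------------------------------------------

def _apt_positions(seq: str, start: int, end: int) -> np.ndarray:
    """0-based positions p in [start, end-1) with seq[p]=='A', seq[p+1]=='T'."""
    window = seq[start:end]
    arr = np.frombuffer(window.encode(), dtype="S1")
    hits = np.flatnonzero((arr[:-1] == b"A") & (arr[1:] == b"T"))
    return hits + start


def _random_centers(
    gene: GeneModel, L: int, nfr_width: int, K: int, rng: np.random.Generator
) -> np.ndarray:
    """Non-periodic placement for the unmethylated (WGA) substrate: K centers
    dropped sequentially at uniform positions in the array span, keeping the
    147-bp cores disjoint and the NFR clear."""
    sign = 1 if gene.strand == "+" else -1
    lo = gene.tss + sign * (nfr_width + 73)
    hi = gene.tss + sign * (nfr_width + (K + 1) * L)
    lo, hi = min(lo, hi), max(lo, hi)
    centers: list[int] = []
    for _ in range(200):
        if len(centers) == K:
            break
        c = int(rng.integers(lo, hi))
        if all(abs(c - o) >= NUCLEOSOME_CORE_BP for o in centers):
            centers.append(c)
    return np.sort(np.array(centers, dtype=int))


def gen_ground_truth(
    genome: ToyGenome,
    genes: list[GeneModel],
    mode: str = "in_vivo",
    L: int = DEFAULT_L,
    nfr_width: int = DEFAULT_NFR_WIDTH,
    K: int = DEFAULT_K,
    jitter_sigma: float | None = None,
    methyl_params: MethylParams = MethylParams(),
    seed: int = 0,
) -> GroundTruth:
    """Plant true nucleosome centers, linkers and the 6mA methylome.

    6mA is placed on both strands of every ApT dinucleotide lying inside an
    inter-nucleosomal linker within the first kilobase downstream of a TSS;
    levels are ``level`` for in_vivo / in_vitro_native, scaled by
    ``1 - knockdown`` for ko, and the methylome is empty for in_vitro_wga.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if L < NUCLEOSOME_CORE_BP:
        raise ValueError("repeat length L must be >= 147 bp")
    rng = _rng(seed, "truth")
    if jitter_sigma is None:
        jitter_sigma = DEFAULT_JITTER_KO if mode == "ko" else DEFAULT_JITTER_WT

    center_rows, linker_rows, methyl_rows = [], [], []
    for gi, gene in enumerate(genes):
        if mode == "in_vitro_wga":
            centers = _random_centers(gene, L, nfr_width, K, rng)
            linkers = np.empty((0, 2), dtype=int)
        else:
            centers, linkers = _array_geometry(gene, L, nfr_width, K)
        for c in centers:
            center_rows.append((gene.chrom, int(c), gi))
        sign = 1 if gene.strand == "+" else -1
        win_lo = min(gene.tss, gene.tss + sign * METHYL_WINDOW)
        win_hi = max(gene.tss, gene.tss + sign * METHYL_WINDOW)
        for s, e in linkers:
            linker_rows.append((gene.chrom, int(s), int(e), gi))
            lo, hi = max(int(s), win_lo), min(int(e), win_hi)
            if mode == "in_vitro_wga" or hi - lo < 2:
                continue
            if methyl_params.apt_mode:
                sites = _apt_positions(genome[gene.chrom], lo, hi)
            else:
                sites = np.arange(lo, hi - 1)
            level = methyl_params.level
            if mode == "ko":
                level *= 1.0 - methyl_params.knockdown
            for p in sites:
                # palindromic ApT: the A on the minus strand pairs with the T
                methyl_rows.append((gene.chrom, int(p), "+", level))
                methyl_rows.append((gene.chrom, int(p) + 1, "-", level))

    centers_df = pd.DataFrame(center_rows, columns=["chrom", "center", "gene_idx"])
    linkers_df = pd.DataFrame(linker_rows, columns=["chrom", "start", "end", "gene_idx"])
    methylome = Methylome(
        pd.DataFrame(methyl_rows, columns=["chrom", "pos", "strand", "level"])
    )
    return GroundTruth(
        condition=mode,
        repeat_length=L,
        nfr_width=nfr_width,
        jitter_sigma=float(jitter_sigma),
        centers=centers_df,
        linkers=linkers_df,
        methylome=methylome,
    )


# ---------------------------------------------------------------------------
# MNase fragments
# ---------------------------------------------------------------------------

def sim_mnase_fragments(
    truth: GroundTruth,
    genome: ToyGenome,
    depth: int = DEFAULT_DEPTH,
    core_bp: int = NUCLEOSOME_CORE_BP,
    overhang_mean: float = 3.0,
    seed: int = 0,
) -> FragmentSet:
    """MNase-protected fragments: ``depth`` per true nucleosome, each centered
    on the center jittered by Normal(0, jitter_sigma) per cell, with length
    core_bp + Poisson(overhang_mean) undigested overhang split between ends."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = _rng(seed, "mnase")
    rows = []
    sizes = genome.sizes
    for chrom, sub in truth.centers.groupby("chrom", sort=True):
        centers = np.repeat(sub["center"].to_numpy(), depth)
        n = len(centers)
        if n == 0:
            continue
        jitter = rng.normal(0.0, truth.jitter_sigma, size=n)
        cj = np.rint(centers + jitter).astype(int)
        overhang = rng.poisson(overhang_mean, size=n)
        left = rng.binomial(overhang, 0.5)
        half = core_bp // 2
        starts = cj - half - left
        ends = starts + core_bp + overhang
        strands = rng.choice(["+", "-"], size=n)
        lim = sizes[chrom]
        starts = np.clip(starts, 0, lim - 1)
        ends = np.clip(ends, starts + 1, lim)
        rows.append(pd.DataFrame(
            {"chrom": chrom, "start": starts, "end": ends, "strand": strands}
        ))
    df = (pd.concat(rows, ignore_index=True) if rows
          else pd.DataFrame({c: [] for c in FragmentSet.COLUMNS}))
    return FragmentSet(df, label="mnase")


# ---------------------------------------------------------------------------
# IP / input fragments
# ---------------------------------------------------------------------------

def sim_ip_reads(
    genome: ToyGenome,
    methylome: Methylome,
    n_fragments: int = 100_000,
    frag_len_mean: int = 250,
    frag_len_sd: float = 30.0,
    enrich_per_site: float = 8.0,
    seed: int = 0,
) -> tuple[FragmentSet, FragmentSet]:
    """Antibody pull-down vs input: input fragment starts are uniform over the
    genome; IP starts are drawn with weight 1 + enrich_per_site * (summed
    methylation level within the fragment), computed at the mean length."""
    if enrich_per_site < 0:
        raise ValueError("enrich_per_site must be >= 0")
    for chrom in set(methylome.df["chrom"]) if len(methylome.df) else set():
        if chrom not in genome.seqs:
            raise KeyError(f"methylome references absent chromosome {chrom!r}")
    rng = _rng(seed, "ip")
    flen = frag_len_mean
    chroms = sorted(genome.seqs)
    weights, n_starts = {}, {}
    for chrom in chroms:
        size = genome.sizes[chrom]
        m = n_starts[chrom] = max(size - flen + 1, 1)
        levels = methylome.level_track(chrom, size)
        csum = np.concatenate([[0.0], np.cumsum(levels)])
        in_frag = csum[flen : flen + m] - csum[:m]
        weights[chrom] = 1.0 + enrich_per_site * in_frag

    def _draw(label: str, per_chrom_w: dict[str, np.ndarray]) -> FragmentSet:
        totals = np.array([per_chrom_w[c].sum() for c in chroms])
        counts = rng.multinomial(n_fragments, totals / totals.sum())
        rows = []
        for chrom, k in zip(chroms, counts):
            if k == 0:
                continue
            w = per_chrom_w[chrom]
            starts = rng.choice(len(w), size=k, p=w / w.sum())
            lens = np.rint(rng.normal(flen, frag_len_sd, size=k)).astype(int)
            lens = np.clip(lens, 20, None)
            ends = np.minimum(starts + lens, genome.sizes[chrom])
            rows.append(pd.DataFrame({
                "chrom": chrom, "start": starts, "end": ends,
                "strand": rng.choice(["+", "-"], size=k),
            }))
        return FragmentSet(pd.concat(rows, ignore_index=True), label=label)

    ip = _draw("ip", weights)
    flat = {c: np.ones(n_starts[c]) for c in chroms}
    inp = _draw("input", flat)
    return ip, inp


# ---------------------------------------------------------------------------
# restriction digest
# ---------------------------------------------------------------------------

def sim_re_digest(
    genome: ToyGenome,
    methylome: Methylome,
    enzyme,
    cut_efficiency: float = 0.9,
    n_molecules: int = 30,
    seed: int = 0,
) -> FragmentSet:
    """Digest ``n_molecules`` copies of the genome with a methylation-sensitive
    enzyme and pool the fragments.

    Each recognition site on each molecule is cut with probability
    ``cut_efficiency * level`` (methylation-required enzymes, e.g. DpnI) or
    ``cut_efficiency * (1 - level)`` (methylation-blocked, e.g. DpnII/CviAII),
    where level is the mean methylation of the site's adenines. Fragments are
    the intervals between realized cut positions.
    """
    from .recall import scan_sites  # local import to avoid a cycle

    if not 0.0 <= cut_efficiency <= 1.0:
        raise ValueError("cut_efficiency must be in [0, 1]")
    rng = _rng(seed, f"re_{enzyme.name}")
    rows = []
    for chrom in sorted(genome.seqs):
        size = genome.sizes[chrom]
        sites = scan_sites(genome, enzyme, chrom=chrom)
        levels = methylome.level_track(chrom, size)
        site_levels = np.array([
            np.mean(levels[[s + enzyme.methylatable_A_offset,
                            s + enzyme.paired_A_offset]])
            for s in sites
        ]) if len(sites) else np.array([])
        # both-strand records each carry the full level; clip to [0,1]
        site_levels = np.clip(site_levels, 0.0, 1.0)
        if enzyme.sensitivity == "requires_6mA":
            p_cut = cut_efficiency * site_levels
        else:
            p_cut = cut_efficiency * (1.0 - site_levels)
        cut_pos = np.asarray(sites) + enzyme.cut_offset
        for _ in range(n_molecules):
            realized = cut_pos[rng.random(len(cut_pos)) < p_cut] if len(cut_pos) else []
            bounds = np.concatenate([[0], np.sort(realized), [size]]).astype(int)
            starts, ends = bounds[:-1], bounds[1:]
            keep = ends > starts
            rows.append(pd.DataFrame({
                "chrom": chrom, "start": starts[keep], "end": ends[keep],
                "strand": ".",
            }))
    df = pd.concat(rows, ignore_index=True)
    return FragmentSet(df, label=f"re_{enzyme.name}")


# ---------------------------------------------------------------------------
# step-parameter trajectories
# ---------------------------------------------------------------------------

#: Typical B-DNA per-snapshot means and fluctuation magnitudes
#: (degrees for angles, Angstrom for translations).
BASE_MEAN = {
    "roll": 2.0, "tilt": 0.0, "twist": 34.3, "slide": -0.4, "shift": 0.0,
    "rise": 3.34, "shear": 0.0, "stretch": 0.0, "stagger": 0.1,
    "buckle": 0.5, "propeller": -11.0, "opening": 1.5,
}
BASE_SD = {
    "roll": 5.5, "tilt": 3.5, "twist": 4.5, "slide": 0.5, "shift": 0.45,
    "rise": 0.3, "shear": 0.25, "stretch": 0.12, "stagger": 0.35,
    "buckle": 7.0, "propeller": 7.5, "opening": 4.0,
}


@dataclass(frozen=True)
class ModificationEffect:
    """Localized change imprinted by 6mA on the duplex mechanics.

    The effect is maximal at the modification site and tapers linearly to
    zero ``reach + 1`` bp away (the perturbation propagates ~3 bp per side).
    ``sd_scale`` < 1 means reduced fluctuation (stiffening).
    """

    delta_mean: dict = field(default_factory=lambda: {"roll": 3.0, "twist": -3.0})
    sd_scale: dict = field(default_factory=lambda: {
        "roll": 0.85, "twist": 0.93,
        "shift": 0.97, "rise": 0.97, "shear": 0.97, "stretch": 0.97,
        "stagger": 0.97, "propeller": 0.97,
        "tilt": 1.02, "slide": 1.02, "buckle": 1.02, "opening": 1.02,
    })
    reach: int = 3

    def taper(self, distance: np.ndarray) -> np.ndarray:
        return np.clip(1.0 - np.abs(distance) / (self.reach + 1), 0.0, 1.0)


def sim_step_series(
    n_positions: int = 33,
    n_snapshots: int = 5000,
    base_sd: dict | None = None,
    base_mean: dict | None = None,
    modification_effect: ModificationEffect | None = None,
    modification_site: int | None = None,
    ar1_rho: float = 0.6,
    seed: int = 0,
) -> tuple[StepParameterSeries, StepParameterSeries]:
    """Paired (unmodified, modified) trajectories of the 12 parameters.

    Each (parameter, position) series is a stationary AR(1) process with the
    requested stationary s.d.; the modified series shifts means and scales
    s.d. near the modification site per ``modification_effect``.
    """
    if not 0.0 <= ar1_rho < 1.0:
        raise ValueError("ar1_rho must be in [0, 1)")
    base_sd = {**BASE_SD, **(base_sd or {})}
    base_mean = {**BASE_MEAN, **(base_mean or {})}
    eff = modification_effect if modification_effect is not None else ModificationEffect()
    site = n_positions // 2 if modification_site is None else modification_site
    rng = _rng(seed, "mdsim")

    dist = np.abs(np.arange(n_positions) - site)
    taper = eff.taper(dist)
    # common random numbers: both series share innovations, so a zero
    # modification effect yields bit-identical trajectories and any
    # difference is attributable to the imposed effect alone
    eps = rng.standard_normal((len(ALL_PARAMETERS), n_positions, n_snapshots))

    def _build(modified: bool) -> StepParameterSeries:
        vals = np.empty((len(ALL_PARAMETERS), n_positions, n_snapshots))
        for pi, name in enumerate(ALL_PARAMETERS):
            mean = np.full(n_positions, base_mean[name])
            sd = np.full(n_positions, base_sd[name])
            if modified:
                mean = mean + eff.delta_mean.get(name, 0.0) * taper
                scale = eff.sd_scale.get(name, 1.0)
                sd = sd * (1.0 + (scale - 1.0) * taper)
            innov_sd = sd * np.sqrt(1.0 - ar1_rho**2)
            x = np.empty((n_positions, n_snapshots))
            x[:, 0] = sd * eps[pi, :, 0]
            for t in range(1, n_snapshots):
                x[:, t] = ar1_rho * x[:, t - 1] + innov_sd * eps[pi, :, t]
            vals[pi] = mean[:, None] + x
        return StepParameterSeries(vals, ALL_PARAMETERS, modification_site=site)

    return _build(False), _build(True)


# ---------------------------------------------------------------------------
# one-call convenience bundle
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    spec: GenomeSpec
    mode: str
    genome: ToyGenome
    genes: list[GeneModel]
    truth: GroundTruth


def gen_dataset(
    spec: GenomeSpec = GenomeSpec(),
    mode: str = "in_vivo",
    L: int = DEFAULT_L,
    nfr_width: int = DEFAULT_NFR_WIDTH,
    K: int = DEFAULT_K,
    jitter_sigma: float | None = None,
    methyl_params: MethylParams = MethylParams(),
) -> Dataset:
    """Genome + genes + ground truth under one root seed (``spec.seed``)."""
    genome, genes = gen_genome(spec, L=L, nfr_width=nfr_width, K=K)
    truth = gen_ground_truth(
        genome, genes, mode=mode, L=L, nfr_width=nfr_width, K=K,
        jitter_sigma=jitter_sigma, methyl_params=methyl_params, seed=spec.seed,
    )
    return Dataset(spec=spec, mode=mode, genome=genome, genes=genes, truth=truth)
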