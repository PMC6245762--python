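"""End-to-end orchestration: generate -> simulate -> call -> profile -> report.

``run_pipeline`` executes the full chain for one condition mode and writes
every artifact (FASTA/GFF3/BED/bedGraph/TSV) plus a JSON summary of the
headline statistics: 6mA and nucleosome periodicity, anti-correlation,
fuzziness, enrichment scores, the protected-6mA ratio and the MNase
fragment-length mode. The same config and seed reproduce the summary
byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import formats, metagene, nuccall, peakcall, recall, synthio
from .model import GenomeSpec, Track

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    mode: str = "in_vivo"
    seed: int = 0
    n_chrom: int = 5
    chrom_len: int = 220_000
    n_genes: int = 300
    gc_content: float = 0.30
    at_enrichment_in_linkers: float = 0.10
    repeat_length: int = synthio.DEFAULT_L
    nfr_width: int = synthio.DEFAULT_NFR_WIDTH
    nucleosomes_per_gene: int = synthio.DEFAULT_K
    jitter_sigma: float | None = None
    methyl_level: float = synthio.DEFAULT_LEVEL
    knockdown: float = synthio.KO_KNOCKDOWN
    mnase_depth: int = synthio.DEFAULT_DEPTH
    n_ip_fragments: int = 100_000
    enrich_per_site: float = 8.0
    enzymes: tuple[str, ...] = ("DpnI", "DpnII", "CviAII")
    n_molecules: int = 30
    profile_window: int = 1500
    n_permutations: int = 200
    write_artifacts: bool = True

    def validate(self) -> None:
        if self.mode not in synthio.MODES:
            raise ValueError(f"mode must be one of {synthio.MODES}")
        if self.repeat_length < 147:
            raise ValueError("repeat_length must be >= 147")
        GenomeSpec(self.n_chrom, self.chrom_len, self.n_genes,
                   self.gc_content, self.at_enrichment_in_linkers, self.seed)


def _tss_anchors(genes) -> list[tuple[str, int, str]]:
    return [(g.chrom, g.tss, g.strand) for g in genes]


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run the full analysis for one condition; returns the summary dict."""
    config.validate()
    out = Path(outdir) if outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    spec = GenomeSpec(config.n_chrom, config.chrom_len, config.n_genes,
                      config.gc_content, config.at_enrichment_in_linkers,
                      config.seed)
    data = synthio.gen_dataset(
        spec, mode=config.mode, L=config.repeat_length,
        nfr_width=config.nfr_width, K=config.nucleosomes_per_gene,
        jitter_sigma=config.jitter_sigma,
        methyl_params=synthio.MethylParams(config.methyl_level,
                                           config.knockdown),
    )
    genome, genes, truth = data.genome, data.genes, data.truth
    sizes = genome.sizes
    anchors = _tss_anchors(genes)
    summary: dict = {
        "mode": config.mode, "seed": config.seed,
        "n_genes": len(genes), "genome_bp": genome.total_bp,
        "repeat_length": config.repeat_length,
    }

    # --- MNase -> nucleosomes -------------------------------------------
    frags = synthio.sim_mnase_fragments(truth, genome, depth=config.mnase_depth,
                                        seed=config.seed)
    lengths = frags.lengths()
    summary["frag_len_mode"] = int(np.bincount(lengths).argmax())
    summary["frag_len_mode_rounded"] = int(round(summary["frag_len_mode"] / 10) * 10)

    tracks = nuccall.occupancy_track(frags, sizes)
    centers = nuccall.call_centers(tracks, min_spacing=147)
    numap = nuccall.fuzziness(frags, centers)
    summary["n_centers"] = int(len(centers))
    summary["mean_fuzziness"] = numap.genome_mean_fuzziness

    center_feats = {c: centers[centers["chrom"] == c]["center"].to_numpy()
                    for c in sorted(sizes)}
    nuc_profile = metagene.anchor_profile(center_feats, anchors,
                                          W=config.profile_window)
    nuc_period = metagene.periodicity(nuc_profile, seed=config.seed,
                                      n_permutations=config.n_permutations)
    summary["nucleosome_period"] = nuc_period

    prot = nuccall.protected_6mA_ratio(frags, truth.methylome, sizes,
                                       n_cells=config.mnase_depth,
                                       regions=truth.array_spans())
    summary["protected_6mA"] = {k: prot[k] for k in
                                ("inside_per_bp", "outside_per_bp", "ratio")}

    # --- RE-seq 6mA calling ---------------------------------------------
    called_positions: dict[str, np.ndarray] = {}
    if not truth.methylome.empty:
        per_chrom: dict[str, list[np.ndarray]] = {c: [] for c in sizes}
        n_called = 0
        for name in config.enzymes:
            enzyme = recall.get_enzyme(name)
            digest = synthio.sim_re_digest(genome, truth.methylome, enzyme,
                                           n_molecules=config.n_molecules,
                                           seed=config.seed)
            calls = recall.call_6mA_sites(digest, recall.scan_sites(genome, enzyme),
                                          enzyme)
            hits = calls[calls["called"]]
            n_called += int(len(hits))
            for chrom, sub in hits.groupby("chrom"):
                per_chrom[chrom].append(sub["pos"].to_numpy())
        called_positions = {
            c: np.unique(np.concatenate(v)) if v else np.array([], dtype=int)
            for c, v in per_chrom.items()
        }
        summary["n_6mA_calls"] = n_called
        site_profile = metagene.anchor_profile(called_positions, anchors,
                                               W=config.profile_window)
        summary["sixma_period"] = metagene.periodicity(
            site_profile, seed=config.seed,
            n_permutations=config.n_permutations)
        summary["anticorrelation"] = metagene.anticorrelation(
            site_profile, nuc_profile, smooth_sigma=20.0)

        # --- IP peaks + component enrichment ----------------------------
        ip, inp = synthio.sim_ip_reads(genome, truth.methylome,
                                       n_fragments=config.n_ip_fragments,
                                       enrich_per_site=config.enrich_per_site,
                                       seed=config.seed)
        peaks = peakcall.call_peaks(ip, inp, sizes)
        scores = peakcall.enrichment_score(peaks, genes, sizes)
        summary["n_peaks"] = int(len(peaks))
        summary["enrichment_scores"] = dict(
            zip(scores["component"], scores["score"]))
    else:
        summary["n_6mA_calls"] = 0

    # --- artifacts -------------------------------------------------------
    if out and config.write_artifacts:
        formats.write_fasta(genome, out / "genome.fa")
        formats.write_gff3(genes, out / "genes.gff3")
        formats.write_bed(frags, out / "mnase_fragments.bed")
        formats.write_methylome_bed(truth.methylome, out / "methylome.bed")
        formats.write_ground_truth(truth, out / "ground_truth.json")
        formats.write_bedgraph(
            [Track(c, np.round(t.values, 4)) for c, t in tracks.items()],
            out / "occupancy.bedGraph")
        centers.to_csv(out / "nucleosome_centers.tsv", sep="\t", index=False)
        numap.table.to_csv(out / "nucleosome_map.tsv", sep="\t", index=False)
    if out:
        (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                     sort_keys=True))
        logger.info("summary written to %s", out / "summary.json")
    return summary
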