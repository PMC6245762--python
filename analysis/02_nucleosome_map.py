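#!/usr/bin/env python
"""MNase simulation and nucleosome calling for WT and KO.

Simulates 30x protected fragments per condition, calls centers from the
smoothed midpoint density, and measures per-nucleosome fuzziness. Key
findings printed: the ~150-bp fragment mode, near-perfect center recovery,
fuzziness tracking the per-condition jitter, and the KO > WT fuzziness
ordering.
"""

import json
from pathlib import Path

import numpy as np

from sixma import formats, nuccall, synthio
from sixma.model import GenomeSpec

SEED = 1
ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    spec = GenomeSpec(seed=SEED)
    genome, genes = synthio.gen_genome(spec)
    out = ROOT / "nucleosomes"
    out.mkdir(parents=True, exist_ok=True)
    report = {}
    for mode in ("in_vivo", "ko"):
        truth = synthio.gen_ground_truth(genome, genes, mode=mode, seed=SEED)
        frags = synthio.sim_mnase_fragments(truth, genome, seed=SEED)
        lengths = frags.lengths()
        mode_len = int(np.bincount(lengths).argmax())
        tracks = nuccall.occupancy_track(frags, genome.sizes)
        centers = nuccall.call_centers(tracks)
        numap = nuccall.fuzziness(frags, centers)

        # positional accuracy vs truth
        errs = []
        for chrom in genome.sizes:
            called = np.sort(
                centers[centers["chrom"] == chrom]["center"].to_numpy())
            for c in truth.centers_on(chrom):
                i = np.searchsorted(called, c)
                errs.append(min(abs(called[j] - c) for j in
                                (max(i - 1, 0), min(i, len(called) - 1))))
        errs = np.array(errs)
        report[mode] = {
            "frag_len_mode": mode_len,
            "n_called": int(len(centers)),
            "n_true": int(len(truth.centers)),
            "center_recall_10bp": float((errs <= 10).mean()),
            "mean_center_error_bp": float(errs.mean()),
            "mean_fuzziness_bp": numap.genome_mean_fuzziness,
            "true_jitter_bp": truth.jitter_sigma,
        }
        formats.write_bed(frags, out / f"mnase_fragments_{mode}.bed")
        centers.to_csv(out / f"centers_{mode}.tsv", sep="\t", index=False)
        numap.table.to_csv(out / f"nucleosome_map_{mode}.tsv", sep="\t",
                           index=False)
        r = report[mode]
        print(f"{mode}: fragment mode {r['frag_len_mode']} bp, "
              f"{r['n_called']}/{r['n_true']} centers, "
              f"recall(<=10bp) {r['center_recall_10bp']:.1%}, "
              f"fuzziness {r['mean_fuzziness_bp']:.1f} bp "
              f"(true jitter {r['true_jitter_bp']:.0f})")
    assert report["ko"]["mean_fuzziness_bp"] > report["in_vivo"]["mean_fuzziness_bp"]
    print("=> knockout arrays are fuzzier than wild type, as expected "
          "when methylation constraints are weakened.")
    (out / "report.json").write_text(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
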