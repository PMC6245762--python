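#!/usr/bin/env python
"""Thermodynamic placement model: oracle agreement and 6mA repulsion.

Three experiments on the Tonks-gas model with per-6mA footprint penalties:

1. Metropolis occupancy vs the exact transfer-matrix DP on a 300-bp
   lattice (the correctness check for the sampler).
2. Occupancy around a single fully methylated site on the 208-bp 5S rDNA
   positioning element — the single-GATC model-substrate experiment:
   with the penalty on, the methylated bp is avoided.
3. Protected-vs-unprotected 6mA content of sampled configurations
   (native parameters vs zero-penalty control standing in for the
   unmethylated substrate).
"""

import json
from pathlib import Path

import numpy as np

from sixma import recall
from sixma.model import ToyGenome
from sixma.placement import (
    PlacementParams,
    exact_occupancy,
    place_mc,
    protected_methyl_stats,
)
from sixma.sequences import MODEL_DNA_208

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "placement"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    report = {}

    levels = np.zeros(300)
    levels[[90, 150, 210]] = 1.0
    params = PlacementParams(footprint=20, penalty_w=5.0, mu=2.0,
                             n_sweeps=50_000)
    _, occ = place_mc(300, levels, params, seed=SEED, sample_every=50)
    dp = exact_occupancy(300, levels, params).values
    dev = float(np.abs(occ.values - dp).max())
    report["mc_vs_dp_max_abs_dev"] = dev
    print(f"MC vs transfer-matrix DP: max |diff| = {dev:.4f} "
          f"(50k sweeps, 300-bp lattice)")

    # single-site experiment on the 208-bp positioning element
    genome = ToyGenome({"model": MODEL_DNA_208})
    site = int(recall.scan_sites(genome, recall.get_enzyme("DpnI"),
                                 chrom="model")[0])
    lv = np.zeros(208)
    lv[site + 1] = lv[site + 2] = 1.0  # both adenines of the GATC
    p208 = PlacementParams(footprint=50, penalty_w=5.0, mu=1.0,
                           n_sweeps=50_000)
    occ_meth = exact_occupancy(208, lv, p208).values
    occ_unme = exact_occupancy(208, np.zeros(208), p208).values
    report["model_dna"] = {
        "gatc_site": site,
        "occupancy_at_site_methylated": float(occ_meth[site + 1]),
        "occupancy_at_site_unmethylated": float(occ_unme[site + 1]),
    }
    print(f"208-bp model DNA, GATC at {site}: occupancy at the methylated "
          f"adenine {occ_meth[site + 1]:.3f} vs {occ_unme[site + 1]:.3f} "
          f"unmethylated")

    rng = np.random.default_rng(SEED)
    lv600 = np.zeros(600)
    lv600[rng.choice(600, 12, replace=False)] = 0.9
    for label, w in (("native", 5.0), ("unmethylated_control", 0.0)):
        pp = PlacementParams(footprint=30, penalty_w=w, mu=1.0,
                             n_sweeps=20_000)
        samples, _ = place_mc(600, lv600, pp, seed=SEED, sample_every=20)
        st = protected_methyl_stats(samples, lv600, footprint=30)
        report[f"protected_{label}"] = st
        print(f"{label:22s} 6mA/bp inside {st['inside']:.4f} "
              f"outside {st['outside']:.4f} ratio {st['ratio']:.3f}")
    print("=> protected DNA is depleted of 6mA only when the penalty "
          "(stiffening) is active.")
    (OUT / "report.json").write_text(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
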