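#!/usr/bin/env python
"""Structural-parameter statistics of the modified vs unmodified duplex.

Simulates AR(1)-correlated trajectories of the 12 base-pair parameters for
the 33-bp duplex with and without the central 6mA, then recovers the
imprinted effects with block-averaged statistics: roll fluctuation reduced
~15% and twist ~7% at the site, mean roll/twist shifted by ~3 degrees
nearby, effects decaying within ~3 bp.
"""

import json
from pathlib import Path

from sixma import formats, mdstats, synthio
from sixma.sequences import MD_DUPLEX_33, MD_DUPLEX_SITE

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "structural"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    n_snap = 25_000  # one snapshot per 20 ps of a 500-ns trajectory
    un, mod = synthio.sim_step_series(
        n_positions=len(MD_DUPLEX_33), n_snapshots=n_snap,
        modification_site=MD_DUPLEX_SITE, seed=SEED)
    # keep a light 1-in-50 thinned copy of the trajectory on disk
    thin = synthio.StepParameterSeries(un.values[:, :, ::50], un.parameters,
                                       modification_site=MD_DUPLEX_SITE)
    formats.write_step_series(thin, OUT / "trajectory_unmodified_thinned.tsv")

    su = mdstats.param_stats(un, block_len=100)
    sm = mdstats.param_stats(mod, block_len=100)
    delta = mdstats.delta_profiles(sm, su, MD_DUPLEX_SITE)
    delta.to_csv(OUT / "delta_profiles.tsv", sep="\t", index=False)
    win = mdstats.site_window_average(delta, half_width=1)
    win.to_csv(OUT / "site_window_averages.tsv", sep="\t", index=False)

    report = {}
    for param in ("roll", "twist"):
        sub = delta[delta["parameter"] == param].set_index("distance")
        report[param] = {
            "pct_sd_change_at_site": float(sub.loc[0, "percent_sd_change"]),
            "delta_mean_at_1bp": float(sub.loc[1, "delta_mean"]),
            "pct_sd_change_at_8bp": float(sub.loc[8, "percent_sd_change"]),
        }
        print(f"{param:6s} fluctuation change at site "
              f"{report[param]['pct_sd_change_at_site']:+.1f}% "
              f"(far field {report[param]['pct_sd_change_at_8bp']:+.1f}%), "
              f"mean shift at 1 bp "
              f"{report[param]['delta_mean_at_1bp']:+.2f} deg")
    print("=> the modification rigidifies the duplex locally: fluctuations "
          "drop at the site and recover within ~3 bp.")
    (OUT / "report.json").write_text(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
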