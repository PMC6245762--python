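#!/usr/bin/env python
"""Input% computation for 6mA-IP-qPCR site validation.

Demonstrates the dilution-corrected enrichment formula on a small Ct table
(two replicates per site, dilution factor 7) and writes the per-site
summary. Sites pulled down strongly (low IP Ct relative to input) show high
Input%; one extra IP cycle halves the value exactly.
"""

from pathlib import Path

import pandas as pd

from sixma.qpcr import input_percent_table

OUT = Path(__file__).resolve().parent.parent / "results" / "qpcr"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ct = pd.DataFrame({
        "site":     ["locus_A", "locus_A", "locus_B", "locus_B",
                     "control", "control"],
        "ct_ip":    [22.1, 22.3, 24.8, 25.0, 29.6, 29.9],
        "ct_input": [21.0, 21.1, 21.2, 21.3, 21.1, 21.0],
    })
    out = input_percent_table(ct)
    out.to_csv(OUT / "input_percent.tsv", sep="\t", index=False)
    per_site = out.drop_duplicates("site")[["site", "mean_input_percent"]]
    for r in per_site.itertuples():
        print(f"{r.site:9s} Input% = {r.mean_input_percent:7.3f}")
    print("=> methylated loci recover two orders of magnitude more input "
          "than the unmethylated control.")


if __name__ == "__main__":
    main()
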