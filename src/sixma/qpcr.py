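"""Input% quantification for 6mA-IP-qPCR site validation.

The IP reaction uses a larger template fraction than the saved input
aliquot (dilution factor 7 in the standard protocol: 70 ul IP vs 10 ul
input), so the input Ct must be shifted by log2(DF) before differencing:

    dCt = Ct_IP - (Ct_input - log2(DF))
    Input% = 100 / 2**dCt

Input% is the percentage of input material recovered in the pull-down at a
locus; one extra IP cycle exactly halves it. Replicates are averaged on the
Input% scale (not the Ct scale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

DEFAULT_DILUTION_FACTOR = 7.0


@dataclass(frozen=True)
class CtRecord:
    ct_ip: float
    ct_input: float
    dilution_factor: float = DEFAULT_DILUTION_FACTOR

    def __post_init__(self) -> None:
        if self.dilution_factor <= 0:
            raise ValueError("dilution_factor must be > 0")
        if not (math.isfinite(self.ct_ip) and math.isfinite(self.ct_input)):
            raise ValueError("Ct values must be finite")


def delta_ct(rec: CtRecord) -> float:
    return rec.ct_ip - (rec.ct_input - math.log2(rec.dilution_factor))


def input_percent(rec: CtRecord) -> float:
    """Percent of input recovered: 100 / 2**dCt."""
    return 100.0 / 2.0 ** delta_ct(rec)


def input_percent_table(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized Input% over a table with columns site, ct_ip, ct_input and
    optional df (dilution factor, default 7). Replicate rows sharing a site
    are averaged on the Input% scale into the ``mean_input_percent`` column
    of the returned per-site summary (merged back onto the row table)."""
    out = df.copy()
    dfac = out["df"] if "df" in out else DEFAULT_DILUTION_FACTOR
    out["input_percent"] = [
        input_percent(CtRecord(ip, inp, d))
        for ip, inp, d in zip(
            out["ct_ip"], out["ct_input"],
            dfac if hasattr(dfac, "__iter__") else [dfac] * len(out),
        )
    ]
    if "site" in out:
        means = out.groupby("site")["input_percent"].mean()
        out = out.merge(means.rename("mean_input_percent"), on="site")
    return out
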