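"""Readers and writers for every on-disk format the pipeline touches.

Internal coordinates are 0-based half-open everywhere; GFF3 (1-based,
inclusive) is converted at the boundary. BED6 scores carry methylation
levels scaled by 1000 (BED's 0-1000 convention). All round-trips are
identities.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    FragmentSet,
    GeneModel,
    GroundTruth,
    Methylome,
    StepParameterSeries,
    ToyGenome,
    Track,
)

# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(genome: ToyGenome, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(genome[c]), id=c, description="")
        for c in sorted(genome.seqs)
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: str | Path) -> ToyGenome:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence name {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"{rec.id}: unexpected characters {sorted(bad)}")
        seqs[rec.id] = seq.replace("N", "A") if "N" in seq else seq
    return ToyGenome(seqs)


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------

def write_bed(fragments: FragmentSet, path: str | Path,
              scores=None, names=None) -> None:
    df = fragments.df
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["start"],
        "end": df["end"],
        "name": names if names is not None else fragments.label,
        "score": scores if scores is not None else 0,
        "strand": df["strand"].where(df["strand"].isin(["+", "-"]), "."),
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path, label: str = "mnase") -> FragmentSet:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str},
    )
    for i, (s, e) in enumerate(zip(df["start"], df["end"]), start=1):
        if s >= e:
            raise ValueError(f"line {i}: start >= end ({s} >= {e})")
    return FragmentSet(df[["chrom", "start", "end", "strand"]], label=label)


def write_methylome_bed(methylome: Methylome, path: str | Path) -> None:
    """6mA records as single-bp BED6 with level*1000 in the score column."""
    df = methylome.df
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["pos"],
        "end": df["pos"] + 1,
        "name": "6mA",
        "score": np.rint(df["level"] * 1000).astype(int),
        "strand": df["strand"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_methylome_bed(path: str | Path) -> Methylome:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str},
    )
    return Methylome(pd.DataFrame({
        "chrom": df["chrom"],
        "pos": df["start"],
        "strand": df["strand"],
        "level": df["score"] / 1000.0,
    }))


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Gene + exon features; internal half-open 0-based becomes 1-based
    inclusive on disk."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, g in enumerate(genes):
            gid = f"gene{i + 1}"
            fh.write("\t".join([
                g.chrom, "sixma", "gene", str(g.start + 1), str(g.end),
                ".", g.strand, ".", f"ID={gid}",
            ]) + "\n")
            for j, (s, e) in enumerate(g.exons):
                fh.write("\t".join([
                    g.chrom, "sixma", "exon", str(s + 1), str(e),
                    ".", g.strand, ".", f"ID={gid}.e{j + 1};Parent={gid}",
                ]) + "\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, merge_strategy="error")
    genes = []
    for feat in db.features_of_type("gene", order_by="start"):
        exons = tuple(
            (e.start - 1, e.end)  # 1-based inclusive -> 0-based half-open
            for e in db.children(feat, featuretype="exon", order_by="start")
        )
        start, end = feat.start - 1, feat.end
        if feat.strand == "+":
            genes.append(GeneModel(feat.seqid, "+", tss=start, tts=end - 1,
                                   exons=exons))
        else:
            genes.append(GeneModel(feat.seqid, "-", tss=end - 1, tts=start,
                                   exons=exons))
    return genes


# ---------------------------------------------------------------------------
# bedGraph tracks
# ---------------------------------------------------------------------------

def write_bedgraph(tracks: list[Track], path: str | Path) -> None:
    """Run-length encode equal adjacent values; zero runs are kept so reads
    recover the track exactly."""
    with open(path, "w") as fh:
        for track in tracks:
            v = track.values
            if len(v) == 0:
                continue
            change = np.flatnonzero(np.diff(v) != 0)
            starts = np.concatenate([[0], change + 1])
            ends = np.concatenate([change + 1, [len(v)]])
            for s, e in zip(starts, ends):
                fh.write(f"{track.chrom}\t{s}\t{e}\t{v[s]:.10g}\n")


def read_bedgraph(path: str | Path) -> list[Track]:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str})
    tracks = []
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
            raise ValueError(f"{chrom}: overlapping bedGraph runs")
        values = np.zeros(int(sub["end"].max()))
        for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
            values[s:e] = v
        tracks.append(Track(chrom=chrom, values=values))
    return tracks


# ---------------------------------------------------------------------------
# step-parameter TSV (long form: snapshot, position, parameter, value)
# ---------------------------------------------------------------------------

def write_step_series(series: StepParameterSeries, path: str | Path) -> None:
    npar, npos, nsnap = series.values.shape
    par_idx, pos_idx, snap_idx = np.meshgrid(
        np.arange(npar), np.arange(npos), np.arange(nsnap), indexing="ij"
    )
    df = pd.DataFrame({
        "snapshot": snap_idx.ravel(),
        "position": pos_idx.ravel(),
        "parameter": np.array(series.parameters)[par_idx.ravel()],
        "value": series.values.ravel(),
    })
    df.to_csv(path, sep="\t", index=False)


def read_step_series(path: str | Path,
                     modification_site: int | None = None) -> StepParameterSeries:
    df = pd.read_csv(path, sep="\t")
    params = tuple(dict.fromkeys(df["parameter"]))
    npos = int(df["position"].max()) + 1
    nsnap = int(df["snapshot"].max()) + 1
    values = np.full((len(params), npos, nsnap), np.nan)
    pidx = {p: i for i, p in enumerate(params)}
    values[
        df["parameter"].map(pidx).to_numpy(),
        df["position"].to_numpy(),
        df["snapshot"].to_numpy(),
    ] = df["value"].to_numpy()
    return StepParameterSeries(values, params, modification_site=modification_site)


# ---------------------------------------------------------------------------
# ground-truth sidecar
# ---------------------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "condition": truth.condition,
        "repeat_length": truth.repeat_length,
        "nfr_width": truth.nfr_width,
        "jitter_sigma": truth.jitter_sigma,
        "centers": truth.centers.to_dict(orient="list"),
        "linkers": truth.linkers.to_dict(orient="list"),
        "methylome": truth.methylome.df.to_dict(orient="list"),
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        condition=payload["condition"],
        repeat_length=payload["repeat_length"],
        nfr_width=payload["nfr_width"],
        jitter_sigma=payload["jitter_sigma"],
        centers=pd.DataFrame(payload["centers"]),
        linkers=pd.DataFrame(payload["linkers"]),
        methylome=Methylome(pd.DataFrame(
            payload["methylome"],
            columns=["chrom", "pos", "strand", "level"],
        )),
    )
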