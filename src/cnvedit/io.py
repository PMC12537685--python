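"""Readers and writers for the toolkit's tabular dialects.

Clone counts travel as two-column TSV (``class``, ``count``); droplet
measurements as CSV with one row per channel per well
(``sample_id, channel, positives, total``), replicate wells pooled by
summing counts.  FASTA goes through Biopython.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .ddpcr import DropletCount, WellMeasurement, pool_wells
from .inference import AlleleCountTable

__all__ = [
    "read_counts_tsv",
    "write_counts_tsv",
    "read_wells_csv",
    "read_fasta",
]


def read_counts_tsv(path: str | Path) -> AlleleCountTable:
    df = pd.read_csv(path, sep="\t", dtype={"class": str, "count": int})
    if not {"class", "count"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'class' and 'count'")
    return AlleleCountTable.from_dict(dict(zip(df["class"], df["count"])))


def write_counts_tsv(table: AlleleCountTable, path: str | Path) -> None:
    pd.DataFrame(
        {"class": [c.label for c in table.classes], "count": list(table.counts)}
    ).to_csv(path, sep="\t", index=False)


def read_wells_csv(path: str | Path) -> dict[str, WellMeasurement]:
    """Load wells keyed by sample, pooling replicate wells per sample."""
    df = pd.read_csv(path)
    required = {"sample_id", "channel", "positives", "total"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    wells: dict[str, WellMeasurement] = {}
    for sample_id, grp in df.groupby("sample_id", sort=False):
        per_well: list[WellMeasurement] = []
        tgt = grp[grp["channel"] == "target"].reset_index(drop=True)
        ref = grp[grp["channel"] == "reference"].reset_index(drop=True)
        if len(tgt) != len(ref) or len(tgt) == 0:
            raise ValueError(
                f"{path}: sample {sample_id} needs paired target/reference rows"
            )
        for i in range(len(tgt)):
            per_well.append(
                WellMeasurement(
                    sample_id=str(sample_id),
                    target=DropletCount(
                        positives=int(tgt.loc[i, "positives"]),
                        total=int(tgt.loc[i, "total"]),
                        channel="target",
                    ),
                    reference=DropletCount(
                        positives=int(ref.loc[i, "positives"]),
                        total=int(ref.loc[i, "total"]),
                        channel="reference",
                    ),
                )
            )
        wells[str(sample_id)] = pool_wells(per_well)
    return wells


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
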