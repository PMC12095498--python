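"""File-format helpers: FASTQ/FASTA via Biopython, TSV tables via pandas."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .grains import GrainSample
from .reads import Fragment

__all__ = [
    "read_fragments_fastq",
    "read_fragments_fasta",
    "read_grain_table",
    "write_grain_table",
]


def read_fragments_fastq(path: str | Path) -> list[Fragment]:
    return [Fragment(id=rec.id, sequence=str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fastq")]


def read_fragments_fasta(path: str | Path) -> list[Fragment]:
    return [Fragment(id=rec.id, sequence=str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]


def read_grain_table(path: str | Path) -> dict[str, GrainSample]:
    """Read a TSV with columns sample, grain_id, De, se into GrainSamples."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for sid, grp in df.groupby("sample"):
        out[str(sid)] = GrainSample(sample_id=str(sid),
                                    de=grp["De"].to_numpy(),
                                    se=grp["se"].to_numpy())
    return out


def write_grain_table(samples: dict[str, GrainSample], path: str | Path) -> None:
    rows = []
    for sid, gs in samples.items():
        for j, (de, se) in enumerate(zip(gs.de, gs.se)):
            rows.append({"sample": sid, "grain_id": j, "De": de, "se": se})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
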