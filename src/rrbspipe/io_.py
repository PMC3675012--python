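"""File-format plumbing: FASTA/FASTQ, BED, TSV tables and run configs.

Coordinates in every TSV/BED written here are 0-based half-open, with
explicit headers on TSVs.
"""

from __future__ import annotations

import gzip
import json
import tomllib
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from . import seqs
from .simulate import ReadBatch, SimConfig


def _open(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# FASTA ---------------------------------------------------------------------

def read_fasta(path) -> dict[str, np.ndarray]:
    genome = {}
    with _open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            genome[rec.id] = seqs.encode(str(rec.seq))
    return genome


def write_fasta(genome: Mapping[str, np.ndarray], path, width: int = 70) -> None:
    with _open(path, "wt") as fh:
        for name, arr in genome.items():
            fh.write(f">{name}\n")
            s = seqs.decode(arr)
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# FASTQ ---------------------------------------------------------------------

def write_fastq_pair(batch: ReadBatch, path1, path2) -> None:
    for path, mat, quals, mate in ((path1, batch.r1, batch.q1, 1), (path2, batch.r2, batch.q2, 2)):
        with _open(path, "wt") as fh:
            for name, row, qrow in zip(batch.names, mat, quals):
                q = "".join(chr(v + 33) for v in qrow)
                fh.write(f"@{name}/{mate}\n{seqs.decode(row)}\n+\n{q}\n")


def read_fastq(path) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Read equal-length FASTQ records into (names, bases, phred) arrays."""
    names, rows, quals = [], [], []
    with _open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            names.append(title.split()[0])
            rows.append(seqs.encode(seq))
            quals.append(np.frombuffer(qual.encode(), dtype=np.uint8).astype(np.int16) - 33)
    if not rows:
        L = 0
        return names, np.empty((0, L), np.uint8), np.empty((0, L), np.int16)
    return names, np.vstack(rows), np.vstack(quals)


# BED / TSV -----------------------------------------------------------------

def write_bed(df: pd.DataFrame, path, extra_cols: Iterable[str] = ()) -> None:
    cols = ["chrom", "start", "end", *extra_cols]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, names=("chrom", "start", "end")) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(names)]
    df.columns = list(names)
    return df


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# Run configuration ---------------------------------------------------------

def load_config(path) -> SimConfig:
    """Load a SimConfig from a TOML or JSON file (keys = field names)."""
    path = Path(path)
    if path.suffix == ".toml":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    else:
        with open(path) as fh:
            data = json.load(fh)
    if "fragment_windows" in data:
        data["fragment_windows"] = tuple(tuple(w) for w in data["fragment_windows"])
    if "meth_weights" in data:
        data["meth_weights"] = tuple(data["meth_weights"])
    cfg = SimConfig(**data)
    cfg.validate()
    return cfg
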