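"""Readers and writers for the tabular and sequence formats of the pipeline."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .idr import DisorderProfile
from .tpp import MeltCurveMatrix

__all__ = [
    "read_melt_curves",
    "read_fasta",
    "write_fasta",
    "read_disorder_tracks",
    "write_idr_intervals",
    "write_run_summary",
]


def read_melt_curves(path, control: str = "DMSO") -> MeltCurveMatrix:
    """Read a melting-curve table, long or wide.

    Long format has columns protein_id, condition, temperature, intensity.
    Wide format has a protein_id column plus ``<condition>_<temperature>``
    headers (e.g. ``lipoamide_arsenate_46.9``).
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if {"protein_id", "condition", "temperature", "intensity"} <= set(df.columns):
        return MeltCurveMatrix.from_long(df, control=control)
    long_rows = []
    for col in df.columns:
        if col == "protein_id":
            continue
        cond, _, temp = col.rpartition("_")
        try:
            t = float(temp)
        except ValueError:
            raise ValueError(f"cannot parse wide header {col!r} as <condition>_<temperature>")
        for pid, val in zip(df["protein_id"], df[col]):
            long_rows.append((pid, cond, t, val))
    long_df = pd.DataFrame(long_rows, columns=["protein_id", "condition", "temperature", "intensity"])
    return MeltCurveMatrix.from_long(long_df, control=control)


def read_fasta(path) -> dict:
    """Sequences by record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict, path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_disorder_tracks(path, sequences: dict | None = None) -> list:
    """Read per-residue predictor calls from a TSV into DisorderProfiles.

    Columns: protein_id, residue_index (1-based), predictor_id, call (0/1).
    Residues absent from the table count as not-disordered for that predictor.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "residue_index", "predictor_id", "call"}
    if not required <= set(df.columns):
        raise ValueError(f"track table needs columns {sorted(required)}")
    profiles = []
    for pid, grp in df.groupby("protein_id", sort=True):
        predictors = sorted(grp["predictor_id"].unique())
        length = int(grp["residue_index"].max())
        if sequences and pid in sequences:
            length = max(length, len(sequences[pid]))
        calls = np.zeros((length, len(predictors)), dtype=bool)
        pred_idx = {p: j for j, p in enumerate(predictors)}
        for _, row in grp.iterrows():
            calls[int(row["residue_index"]) - 1, pred_idx[row["predictor_id"]]] = bool(row["call"])
        seq = sequences.get(pid) if sequences else None
        profiles.append(DisorderProfile(pid, calls, sequence=seq))
    return profiles


def write_idr_intervals(idrsets: list, path) -> None:
    """Write IDR intervals as TSV; coordinates are 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("# coordinates: 1-based inclusive residue intervals\n")
        fh.write("protein_id\tstart\tend\tidr_proportion\n")
        for s in idrsets:
            for (a, b) in s.intervals:
                fh.write(f"{s.protein_id}\t{a}\t{b}\t{s.idr_proportion:.6f}\n")


def write_run_summary(path, **fields) -> None:
    Path(path).write_text(json.dumps(fields, indent=2, default=str) + "\n")
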