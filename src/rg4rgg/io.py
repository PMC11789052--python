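"""Readers and writers for the plain-text formats the pipeline consumes."""

from __future__ import annotations

from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import Transcript, normalize_nt

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_transcripts",
    "read_rtstops",
    "read_expression",
    "read_scale",
]


def read_fasta(path) -> dict[str, str]:
    """FASTA -> {record id: sequence} (order preserved, Python 3.7+ dicts)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def read_transcripts(fasta_path, annotation_path, max_flank: int = 50) -> list[Transcript]:
    """Assemble transcripts from FASTA plus a CDS-coordinate table.

    The annotation TSV has columns ``transcript_id``, ``cds_start``,
    ``cds_end`` (0-based half-open, in the coordinates of the FASTA
    sequence).  Flanks are clipped to ``max_flank`` nucleotides.
    """
    seqs = read_fasta(fasta_path)
    ann = pd.read_csv(annotation_path, sep="\t")
    required = {"transcript_id", "cds_start", "cds_end"}
    if not required <= set(ann.columns):
        raise ValueError(f"annotation must have columns {sorted(required)}")
    out = []
    for row in ann.itertuples(index=False):
        tx_id = str(row.transcript_id)
        if tx_id not in seqs:
            raise ValueError(f"{tx_id} in annotation but not in FASTA")
        seq = normalize_nt(seqs[tx_id])
        s, e = int(row.cds_start), int(row.cds_end)
        if not (0 <= s < e <= len(seq)):
            raise ValueError(f"{tx_id}: CDS [{s}, {e}) outside sequence")
        out.append(
            Transcript(
                id=tx_id,
                cds=seq[s:e],
                utr5_flank=seq[max(0, s - max_flank) : s],
                utr3_flank=seq[e : e + max_flank],
            )
        )
    return out


def read_rtstops(path) -> dict[str, list[int]]:
    """RT-stop TSV (transcript_id, position) -> {transcript: positions}."""
    df = pd.read_csv(path, sep="\t")
    if not {"transcript_id", "position"} <= set(df.columns):
        raise ValueError("RT-stop table needs columns transcript_id, position")
    out: dict[str, list[int]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.transcript_id), []).append(int(row.position))
    return out


def read_expression(path) -> pd.DataFrame:
    """Expression TSV with a gene index column and one column per sample."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_scale(path) -> dict[str, float]:
    """Two-column TSV (residue, value) -> per-residue preference scale."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("residue"):
                continue
            aa, val = line.split("\t") if "\t" in line else line.split()
            out[aa.strip().upper()] = float(val)
    return out
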