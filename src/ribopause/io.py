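"""Readers and writers for the pipeline's on-disk formats.

All tabular intermediates are plain TSV so that runs diff cleanly; FASTA goes
through Biopython, SAM/BAM through pysam. Coordinates in TSVs are 0-based
half-open; SAM POS is converted to/from 1-based at this boundary only.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    FOOTPRINT_COLUMNS,
    CodonCountMatrix,
    OffsetTable,
    TranscriptModel,
    Transcriptome,
)


# ---------------------------------------------------------------- transcriptome

def write_transcriptome(
    transcriptome: Transcriptome, fasta_path, cds_table_path
) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.transcript_id, description=t.gene_id)
        for t in transcriptome.values()
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = [
        (t.transcript_id, t.gene_id, t.cds_start, t.cds_end)
        for t in transcriptome.values()
    ]
    pd.DataFrame(
        rows, columns=["transcript_id", "gene_id", "cds_start", "cds_end"]
    ).to_csv(cds_table_path, sep="\t", index=False)


def read_transcriptome(fasta_path, cds_table_path) -> Transcriptome:
    cds = pd.read_csv(cds_table_path, sep="\t").set_index("transcript_id")
    transcripts = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in cds.index:
            raise ValueError(f"transcript {rec.id!r} missing from CDS table")
        row = cds.loc[rec.id]
        transcripts.append(
            TranscriptModel(
                transcript_id=rec.id,
                gene_id=str(row["gene_id"]),
                sequence=str(rec.seq).upper(),
                cds_start=int(row["cds_start"]),
                cds_end=int(row["cds_end"]),
            )
        )
    return Transcriptome(transcripts)


# ------------------------------------------------------------------ footprints

def write_footprints_tsv(footprints: pd.DataFrame, path) -> None:
    footprints.loc[:, list(FOOTPRINT_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_footprints_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "read_id": str,
            "transcript_id": str,
            "five_prime_pos": np.int64,
            "length": np.int64,
        },
    )
    missing = set(FOOTPRINT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"footprint table missing columns: {sorted(missing)}")
    return df.loc[:, list(FOOTPRINT_COLUMNS)]


def write_footprints_sam(
    footprints: pd.DataFrame, transcriptome: Transcriptome, path
) -> None:
    """Write footprints as transcript-space SAM (sequence-less records)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for tid in transcriptome.ids:
            fh.write(f"@SQ\tSN:{tid}\tLN:{len(transcriptome[tid])}\n")
        for row in footprints.itertuples(index=False):
            fh.write(
                f"{row.read_id}\t0\t{row.transcript_id}\t{row.five_prime_pos + 1}"
                f"\t255\t{row.length}M\t*\t0\t0\t*\t*\n"
            )


def read_footprints_sam(path) -> pd.DataFrame:
    """Read transcript-space SAM/BAM alignments (primary, mapped records only)."""
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for rec in bam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            length = rec.query_length or rec.infer_query_length() or 0
            rows.append(
                (rec.query_name, rec.reference_name, rec.reference_start, length)
            )
    return pd.DataFrame(rows, columns=list(FOOTPRINT_COLUMNS)).astype(
        {"five_prime_pos": np.int64, "length": np.int64}
    )


# ----------------------------------------------------------------- offsets etc.

def write_offset_table(offsets: OffsetTable, path) -> None:
    rows = [
        (length, off, offsets.support.get(length, 0))
        for length, off in sorted(offsets.offsets.items())
    ]
    pd.DataFrame(rows, columns=["length", "a_site_offset", "support"]).to_csv(
        path, sep="\t", index=False
    )


def read_offset_table(path) -> OffsetTable:
    df = pd.read_csv(path, sep="\t")
    return OffsetTable(
        offsets={int(r.length): int(r.a_site_offset) for r in df.itertuples()},
        support={int(r.length): int(r.support) for r in df.itertuples()},
    )


def write_count_matrices(matrices: Mapping[str, CodonCountMatrix], path) -> None:
    """Sparse TSV: one row per (transcript, codon) with a non-zero count."""
    rows = []
    for tid in matrices:
        counts = matrices[tid].counts
        for idx in np.flatnonzero(counts):
            rows.append((tid, int(idx), int(counts[idx])))
    pd.DataFrame(rows, columns=["transcript_id", "codon_index", "count"]).to_csv(
        path, sep="\t", index=False
    )


def read_count_matrices(path, transcriptome: Transcriptome) -> dict[str, CodonCountMatrix]:
    df = pd.read_csv(path, sep="\t")
    matrices = {
        tid: CodonCountMatrix(tid, np.zeros(transcriptome[tid].n_codons, dtype=np.int64))
        for tid in transcriptome.ids
    }
    for row in df.itertuples(index=False):
        matrices[row.transcript_id].counts[row.codon_index] = row.count
    return matrices


def read_gene_list(path) -> set[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    genes = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.add(line)
    return genes


def write_gene_list(genes: Iterable[str], path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def read_expression_effects(path) -> pd.DataFrame:
    """Sleuth-style effect table: gene_id, beta (ln-scale), q_value."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "beta", "q_value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"effects table missing columns: {sorted(missing)}")
    return df
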