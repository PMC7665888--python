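"""A-site offset calibration and per-codon count matrices.

The offset from a footprint's 5' end to the nucleotide in the ribosomal
A-site depends on read length. It is calibrated from a metagene at annotated
start codons: initiating ribosomes sit with the start codon in the P-site, so
for each read length the modal distance ``cds_start - five_prime_pos`` over
reads whose 5' end falls upstream of the start codon is the P-site offset;
the A-site is one codon (3 nt) downstream.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    CodonCountMatrix,
    FootprintAlignment,
    OffsetTable,
    StageStats,
    TranscriptModel,
    Transcriptome,
)

logger = logging.getLogger(__name__)

#: nt from P-site to A-site (one codon downstream; standard 80S geometry).
P_TO_A_NT = 3

OUTSIDE_CDS = -1


def _modal_offset(distances: np.ndarray) -> int:
    """Mode of the distance distribution; ties broken toward the smaller value."""
    counts = Counter(distances.tolist())
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    return int(best[0])


def calibrate_offsets(
    footprints: pd.DataFrame,
    transcriptome: Transcriptome,
    min_support: int = 30,
) -> OffsetTable:
    """Per-read-length A-site offsets from the start-codon metagene.

    For each length the putative P-site-at-start reads are those whose 5' end
    lies strictly upstream of the CDS while the read overlaps the start codon
    (``1 <= cds_start - five_prime_pos < length``). Lengths with fewer than
    ``min_support`` such reads fall back to the global modal offset pooled
    across lengths, with a warning.
    """
    if footprints.empty:
        raise ValueError("cannot calibrate offsets from an empty library")
    tx_idx = transcriptome.transcript_indices(footprints["transcript_id"])
    d = transcriptome.cds_start_arr[tx_idx] - footprints["five_prime_pos"].to_numpy()
    lengths = footprints["length"].to_numpy()
    near_start = (d >= 1) & (d < lengths)
    d_start = d[near_start]
    len_start = lengths[near_start]
    if d_start.size == 0:
        raise ValueError("no reads overlap annotated start codons")

    global_p_offset = _modal_offset(d_start)
    offsets: dict[int, int] = {}
    support: dict[int, int] = {}
    for length in sorted(np.unique(lengths).tolist()):
        sel = d_start[len_start == length]
        support[length] = int(sel.size)
        if sel.size >= min_support:
            p_off = _modal_offset(sel)
        else:
            logger.warning(
                "length %d: only %d start-codon reads (< %d); using global offset",
                length, sel.size, min_support,
            )
            p_off = global_p_offset
        a_off = p_off + P_TO_A_NT
        if not 0 < a_off < length:
            logger.warning(
                "length %d: calibrated offset %d out of range; using global offset",
                length, a_off,
            )
            a_off = global_p_offset + P_TO_A_NT
        offsets[length] = a_off
    return OffsetTable(offsets=offsets, support=support)


def assign_asite_codon(
    alignment: FootprintAlignment,
    offsets: OffsetTable,
    transcript: TranscriptModel,
) -> int:
    """Codon index of the A-site, or ``OUTSIDE_CDS`` when it falls in a UTR."""
    if alignment.length not in offsets:
        raise KeyError(f"no A-site offset calibrated for length {alignment.length}")
    asite_nt = alignment.five_prime_pos + offsets[alignment.length]
    if transcript.cds_start <= asite_nt < transcript.cds_end:
        return (asite_nt - transcript.cds_start) // 3
    return OUTSIDE_CDS


def assign_asite_codons(
    footprints: pd.DataFrame,
    offsets: OffsetTable,
    transcriptome: Transcriptome,
) -> np.ndarray:
    """Vectorised A-site codon assignment; ``OUTSIDE_CDS`` for UTR placements."""
    lengths = footprints["length"].to_numpy()
    lookup = offsets.as_lookup(int(lengths.max(initial=0)))
    per_read_offset = lookup[lengths]
    if (per_read_offset < 0).any():
        missing = sorted(np.unique(lengths[per_read_offset < 0]).tolist())
        raise KeyError(f"no A-site offset calibrated for lengths {missing}")
    tx_idx = transcriptome.transcript_indices(footprints["transcript_id"])
    asite_nt = footprints["five_prime_pos"].to_numpy() + per_read_offset
    cds_start = transcriptome.cds_start_arr[tx_idx]
    inside = (asite_nt >= cds_start) & (asite_nt < transcriptome.cds_end_arr[tx_idx])
    codon = np.where(inside, (asite_nt - cds_start) // 3, OUTSIDE_CDS)
    return codon.astype(np.int64)


@dataclass
class CountMatrixResult:
    matrices: dict[str, CodonCountMatrix]
    stats: StageStats


def build_count_matrices(
    footprints: pd.DataFrame,
    offsets: OffsetTable,
    transcriptome: Transcriptome,
) -> CountMatrixResult:
    """Per-transcript, per-codon A-site counts; UTR A-sites excluded and counted.

    Every transcript in the transcriptome gets a matrix (all-zero when it
    received no reads), so downstream density thresholds see the full
    transcript universe.
    """
    if footprints.empty:
        codon = np.empty(0, dtype=np.int64)
        tx_idx = np.empty(0, dtype=np.int64)
    else:
        codon = assign_asite_codons(footprints, offsets, transcriptome)
        tx_idx = transcriptome.transcript_indices(footprints["transcript_id"])
    inside = codon != OUTSIDE_CDS
    n_codons = transcriptome.n_codons_arr
    # Flat key (transcript, codon) -> bincount over a ragged layout.
    starts = np.concatenate([[0], np.cumsum(n_codons)])
    flat = np.bincount(
        starts[tx_idx[inside]] + codon[inside], minlength=int(starts[-1])
    )
    matrices = {
        tid: CodonCountMatrix(tid, flat[starts[i] : starts[i + 1]])
        for i, tid in enumerate(transcriptome.ids)
    }
    stats = StageStats(
        "assign_asite",
        n_input=len(footprints),
        n_retained=int(inside.sum()),
        n_discarded=int((~inside).sum()),
    )
    logger.info(
        "A-site assignment: %d in CDS, %d outside CDS",
        stats.n_retained, stats.n_discarded,
    )
    return CountMatrixResult(matrices, stats)


def frame_fractions(
    footprints: pd.DataFrame, offsets: OffsetTable, transcriptome: Transcriptome
) -> np.ndarray:
    """Fraction of in-CDS A-sites in each reading frame (simple periodicity QC)."""
    tx_idx = transcriptome.transcript_indices(footprints["transcript_id"])
    lookup = offsets.as_lookup(int(footprints["length"].max()))
    asite_nt = footprints["five_prime_pos"].to_numpy() + lookup[footprints["length"]]
    rel = asite_nt - transcriptome.cds_start_arr[tx_idx]
    inside = (rel >= 0) & (asite_nt < transcriptome.cds_end_arr[tx_idx])
    frames = np.bincount(rel[inside] % 3, minlength=3)
    total = frames.sum()
    return frames / total if total else np.zeros(3)
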