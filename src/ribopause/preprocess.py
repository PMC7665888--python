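"""Footprint read preprocessing and alignment ingestion.

Raw footprint reads carry the 3' ligation adapter (the library's
``CTGTAGGCACCATCAAT`` linker) and an untemplated first base from reverse
transcription; clipping and trimming recover the protected fragment. Only
exact adapter matches are searched: with 26-34 nt inserts on 75 nt reads the
adapter must be present, so a read without it is treated as contamination and
discarded. Alignment ingestion validates transcript-space coordinates and
applies an optional read-id exclusion list (e.g. rRNA hits flagged upstream).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

import pandas as pd

from .model import StageStats, Transcriptome

logger = logging.getLogger(__name__)

#: The 3' adapter ligated during library construction.
DEFAULT_ADAPTER = "CTGTAGGCACCATCAAT"

#: Read-length window retained for A-site analysis.
DEFAULT_MIN_LENGTH = 29
DEFAULT_MAX_LENGTH = 33


class MalformedRecordError(ValueError):
    """A FASTQ record whose sequence and quality strings disagree in length."""


@dataclass(frozen=True)
class FastqRead:
    read_id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise MalformedRecordError(
                f"{self.read_id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.quality)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def clip_adapter(read: FastqRead, adapter: str = DEFAULT_ADAPTER) -> FastqRead | None:
    """Truncate at the leftmost exact adapter occurrence; quality in register.

    Returns ``None`` (discard) when the adapter is absent or the insert is
    empty.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    pos = read.sequence.find(adapter)
    if pos <= 0:
        # -1: no adapter (contamination); 0: empty insert.
        return None
    return FastqRead(read.read_id, read.sequence[:pos], read.quality[:pos])


def trim_first_base(read: FastqRead) -> FastqRead | None:
    """Drop the first base (and its quality) so reads start on the second base."""
    if len(read) < 2:
        return None
    return FastqRead(read.read_id, read.sequence[1:], read.quality[1:])


@dataclass
class PreprocessResult:
    reads: list[FastqRead]
    stats: list[StageStats]


def preprocess_reads(
    reads: Iterable[FastqRead],
    adapter: str = DEFAULT_ADAPTER,
    trim_first: bool = True,
) -> PreprocessResult:
    """Clip then trim a stream of FASTQ reads, with conservation bookkeeping."""
    clipped: list[FastqRead] = []
    n_in = 0
    for read in reads:
        n_in += 1
        out = clip_adapter(read, adapter)
        if out is not None:
            clipped.append(out)
    stats = [StageStats("clip_adapter", n_in, len(clipped), n_in - len(clipped))]
    if trim_first:
        trimmed = [t for r in clipped if (t := trim_first_base(r)) is not None]
        stats.append(
            StageStats("trim_first_base", len(clipped), len(trimmed),
                       len(clipped) - len(trimmed))
        )
        clipped = trimmed
    for s in stats:
        logger.info("%s: %d in, %d retained, %d discarded",
                    s.stage, s.n_input, s.n_retained, s.n_discarded)
    return PreprocessResult(clipped, stats)


def parse_fastq(path) -> Iterator[FastqRead]:
    """Stream a Phred+33 FASTQ file."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield FastqRead(title.split()[0], seq.upper(), qual)


def write_fastq(reads: Iterable[FastqRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def filter_lengths(
    footprints: pd.DataFrame,
    lo: int = DEFAULT_MIN_LENGTH,
    hi: int = DEFAULT_MAX_LENGTH,
) -> tuple[pd.DataFrame, StageStats]:
    """Retain alignments with lo <= length <= hi (inclusive bounds)."""
    if lo > hi:
        raise ValueError(f"invalid length window ({lo}, {hi})")
    mask = (footprints["length"] >= lo) & (footprints["length"] <= hi)
    kept = footprints.loc[mask].reset_index(drop=True)
    stats = StageStats("filter_lengths", len(footprints), len(kept),
                       int((~mask).sum()))
    logger.info("filter_lengths [%d, %d]: %d of %d retained",
                lo, hi, stats.n_retained, stats.n_input)
    return kept, stats


def validate_alignments(
    footprints: pd.DataFrame, transcriptome: Transcriptome
) -> tuple[pd.DataFrame, StageStats]:
    """Drop records with unknown transcripts or out-of-bounds coordinates."""
    known = footprints["transcript_id"].isin(transcriptome.index).to_numpy()
    n_unknown = int((~known).sum())
    if n_unknown:
        logger.warning("rejected %d alignments on unknown transcripts", n_unknown)
    df = footprints.loc[known]
    tx_idx = transcriptome.transcript_indices(df["transcript_id"])
    tx_len = transcriptome.length_arr[tx_idx]
    five = df["five_prime_pos"].to_numpy()
    lengths = df["length"].to_numpy()
    in_bounds = (five >= 0) & (lengths > 0) & (five + lengths <= tx_len)
    n_oob = int((~in_bounds).sum())
    if n_oob:
        logger.warning("rejected %d out-of-bounds alignments", n_oob)
    kept = df.loc[in_bounds].reset_index(drop=True)
    stats = StageStats("validate_alignments", len(footprints), len(kept),
                       n_unknown + n_oob)
    return kept, stats


def ingest_alignments(
    path,
    transcriptome: Transcriptome,
    fmt: str = "tsv",
    exclusion_list: set[str] | None = None,
) -> tuple[pd.DataFrame, list[StageStats]]:
    """Load transcript-space alignments from TSV or SAM/BAM into footprint records.

    Excluded read ids (e.g. rRNA hits identified elsewhere) are dropped first;
    remaining records are validated against the transcriptome. Only primary
    mapped records are read from SAM/BAM.
    """
    from . import io as rio

    if fmt == "tsv":
        df = rio.read_footprints_tsv(path)
    elif fmt in ("sam", "bam"):
        df = rio.read_footprints_sam(path)
    else:
        raise ValueError(f"unknown alignment format {fmt!r}")

    stats = []
    if exclusion_list:
        mask = ~df["read_id"].isin(exclusion_list)
        kept = df.loc[mask].reset_index(drop=True)
        stats.append(StageStats("exclusion_list", len(df), len(kept),
                                int((~mask).sum())))
        df = kept
    df, vstats = validate_alignments(df, transcriptome)
    stats.append(vstats)
    return df, stats


def length_histogram(footprints: pd.DataFrame) -> pd.Series:
    """Read counts per footprint length (retention diagnostics)."""
    return footprints["length"].value_counts().sort_index()
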