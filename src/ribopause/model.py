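"""Core domain objects shared by every pipeline stage.

Coordinates are 0-based, half-open, in transcript space throughout; conversion
to/from 1-based conventions happens only at file boundaries (SAM).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Iterator, Mapping

import numpy as np

BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")

#: The 61 sense codons in lexicographic order; the universal index space for
#: codon-level statistics (occupancy, dwell weights, usage vectors).
SENSE_CODONS: tuple[str, ...] = tuple(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOP_CODONS
)

CODON_TO_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

#: Footprint lengths a monosome can protect (nuclease footprint size range).
MIN_FOOTPRINT_LEN = 26
MAX_FOOTPRINT_LEN = 34

FOOTPRINT_COLUMNS = ("read_id", "transcript_id", "five_prime_pos", "length")


@dataclass
class TranscriptModel:
    """A coding transcript: sequence plus CDS interval in transcript coordinates.

    ``cds_start``/``cds_end`` are 0-based half-open and must span a whole
    number of codons, start codon first and stop codon last.
    """

    transcript_id: str
    gene_id: str
    sequence: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.cds_start < self.cds_end <= len(self.sequence)):
            raise ValueError(
                f"{self.transcript_id}: CDS [{self.cds_start}, {self.cds_end}) "
                f"outside transcript of length {len(self.sequence)}"
            )
        if (self.cds_end - self.cds_start) % 3:
            raise ValueError(
                f"{self.transcript_id}: CDS length not a multiple of 3"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_codons(self) -> int:
        return (self.cds_end - self.cds_start) // 3

    @cached_property
    def codons(self) -> tuple[str, ...]:
        cds = self.sequence[self.cds_start : self.cds_end]
        return tuple(cds[i : i + 3] for i in range(0, len(cds), 3))

    def codon(self, index: int) -> str:
        return self.codons[index]

    @cached_property
    def codon_codes(self) -> np.ndarray:
        """Sense-codon index per CDS codon; -1 for stops/ambiguous codons."""
        return np.array(
            [CODON_TO_INDEX.get(c, -1) for c in self.codons], dtype=np.int64
        )


class Transcriptome(Mapping[str, TranscriptModel]):
    """An ordered collection of transcripts with aligned lookup arrays."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self._transcripts: dict[str, TranscriptModel] = {}
        for t in transcripts:
            if t.transcript_id in self._transcripts:
                raise ValueError(f"duplicate transcript id {t.transcript_id!r}")
            self._transcripts[t.transcript_id] = t
        self.ids: tuple[str, ...] = tuple(self._transcripts)
        self.index: dict[str, int] = {tid: i for i, tid in enumerate(self.ids)}
        n = len(self.ids)
        self.cds_start_arr = np.empty(n, dtype=np.int64)
        self.cds_end_arr = np.empty(n, dtype=np.int64)
        self.length_arr = np.empty(n, dtype=np.int64)
        self.n_codons_arr = np.empty(n, dtype=np.int64)
        for i, tid in enumerate(self.ids):
            t = self._transcripts[tid]
            self.cds_start_arr[i] = t.cds_start
            self.cds_end_arr[i] = t.cds_end
            self.length_arr[i] = len(t.sequence)
            self.n_codons_arr[i] = t.n_codons

    def __getitem__(self, key: str) -> TranscriptModel:
        return self._transcripts[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._transcripts)

    def __len__(self) -> int:
        return len(self._transcripts)

    @property
    def gene_of(self) -> dict[str, str]:
        return {tid: t.gene_id for tid, t in self._transcripts.items()}

    def transcript_indices(self, transcript_ids) -> np.ndarray:
        """Vectorised transcript-id -> position lookup (raises on unknown ids)."""
        try:
            return np.array([self.index[t] for t in transcript_ids], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message clarity only
            raise KeyError(f"unknown transcript id {exc.args[0]!r}") from None


@dataclass(frozen=True)
class FootprintAlignment:
    """One ribosome footprint placed on a transcript (the atomic evidence unit)."""

    read_id: str
    transcript_id: str
    five_prime_pos: int
    length: int


@dataclass
class CodonCountMatrix:
    """Per-codon A-site read counts for one transcript."""

    transcript_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_codons(self) -> int:
        return self.counts.size

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())

    @property
    def density(self) -> float:
        """Mean reads per codon over the whole CDS."""
        return self.total_reads / self.n_codons if self.n_codons else 0.0


@dataclass
class OffsetTable:
    """Calibrated A-site offsets (nt from the read 5' end) per read length."""

    offsets: dict[int, int]
    support: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for length, off in self.offsets.items():
            if not 0 < off < length:
                raise ValueError(
                    f"A-site offset {off} invalid for read length {length}"
                )

    def __getitem__(self, length: int) -> int:
        return self.offsets[length]

    def __contains__(self, length: int) -> bool:
        return length in self.offsets

    def as_lookup(self, max_length: int = MAX_FOOTPRINT_LEN) -> np.ndarray:
        """Dense length-indexed lookup array with -1 for uncalibrated lengths."""
        arr = np.full(max_length + 1, -1, dtype=np.int64)
        for length, off in self.offsets.items():
            if length <= max_length:
                arr[length] = off
        return arr


@dataclass(frozen=True)
class StageStats:
    """Conservation bookkeeping for a filtering stage: input = retained + discarded."""

    stage: str
    n_input: int
    n_retained: int
    n_discarded: int

    def __post_init__(self) -> None:
        if self.n_input != self.n_retained + self.n_discarded:
            raise ValueError(
                f"{self.stage}: conservation violated "
                f"({self.n_input} != {self.n_retained} + {self.n_discarded})"
            )
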