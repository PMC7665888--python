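"""Genome-wide observed/expected ribosome occupancy per codon identity.

For each transcript the expected read count at a codon is the transcript's
in-window total divided by the number of window codons — i.e. reads assumed
uniformly distributed across the coding part of the transcript. Observed and
expected counts are then summed per codon identity across all transcripts,
and the ratio R_c = O_c / E_c reports relative dwell: ~1 means average
decoding speed, >1 slower (ribosomes enriched with that codon in the chosen
site).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import SENSE_CODONS, CodonCountMatrix, Transcriptome

#: Codon-identity shift per ribosomal site relative to the A-site index.
SITE_SHIFT = {"A": 0, "P": 1, "E": 2}

#: Default analysis window trims: the start codon plus the first decoded codon
#: (which carries the initiation peak) and the stop codon.
DEFAULT_EXCLUDE_START = 2
DEFAULT_EXCLUDE_END = 1


def expected_counts(matrix: CodonCountMatrix) -> np.ndarray:
    """Uniform expectation: total reads spread evenly over the CDS codons."""
    if matrix.n_codons == 0:
        raise ValueError("empty codon count matrix")
    return np.full(matrix.n_codons, matrix.total_reads / matrix.n_codons)


def codon_occupancy(
    matrices: Mapping[str, CodonCountMatrix],
    transcriptome: Transcriptome,
    site: str = "A",
    exclude_start: int = DEFAULT_EXCLUDE_START,
    exclude_end: int = DEFAULT_EXCLUDE_END,
) -> pd.DataFrame:
    """Observed, expected and ratio per sense codon for one library.

    ``site`` selects which ribosomal site's codon identity the counts are
    attributed to: the A-site read position reports the P-site codon one
    codon upstream (shift -1) and the E-site two codons upstream (shift -2).
    Codons never observed in any window have expected 0 and an undefined
    (NaN) ratio.
    """
    if site not in SITE_SHIFT:
        raise ValueError(f"site must be one of {sorted(SITE_SHIFT)}")
    shift = SITE_SHIFT[site]
    observed = np.zeros(len(SENSE_CODONS))
    expected = np.zeros(len(SENSE_CODONS))
    for tid, matrix in matrices.items():
        t = transcriptome[tid]
        n = matrix.n_codons
        lo, hi = exclude_start, n - exclude_end
        if hi - lo < 1 or lo - shift < 0:
            continue
        window = matrix.counts[lo:hi]
        total = window.sum()
        if total == 0:
            continue
        e_per_codon = total / window.size
        codes = t.codon_codes[lo - shift : hi - shift]
        sense = codes >= 0
        np.add.at(observed, codes[sense], window[sense])
        np.add.at(expected, codes[sense], e_per_codon)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(expected > 0, observed / expected, np.nan)
    return pd.DataFrame(
        {"observed": observed, "expected": expected, "ratio": ratio},
        index=pd.Index(SENSE_CODONS, name="codon"),
    )


def occupancy_replicate_summary(
    tables: Sequence[pd.DataFrame],
) -> pd.DataFrame:
    """Mean and SEM of the occupancy ratio across biological replicates."""
    ratios = pd.concat([t["ratio"] for t in tables], axis=1)
    return pd.DataFrame(
        {
            "mean_ratio": ratios.mean(axis=1),
            "sem_ratio": ratios.apply(
                lambda row: sps.sem(row.dropna()) if row.notna().sum() > 1 else np.nan,
                axis=1,
            ),
            "n_replicates": ratios.notna().sum(axis=1),
        }
    )


def occupancy_zscores(table: pd.DataFrame) -> pd.Series:
    """Standardise the 61 occupancy ratios to z-scores (presentation statistic)."""
    ratios = table["ratio"]
    defined = ratios.dropna()
    if defined.size < 3:
        raise ValueError("need at least 3 defined occupancy ratios")
    sd = float(defined.std(ddof=0))
    if sd == 0:
        z = pd.Series(0.0, index=defined.index)
    else:
        z = (defined - defined.mean()) / sd
    return z.reindex(ratios.index)
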