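"""Pause-site detection, replicate intersection, and pause-expression correlation.

A pause is a codon whose A-site read count stands far above the transcript's
own background. For each transcript with adequate coverage the per-codon
pause score is ``s(t,i) = o(t,i) / mean(o)`` and the z-score is
``z(t,i) = (o(t,i) - mu) / sigma`` with mu and sigma the mean and (population)
standard deviation of the counts over the analysis window. Standardising
within the transcript makes the statistic invariant to sequencing depth and
expression level; a z >= 10 call therefore marks a spike that dwarfs the
transcript's own coverage fluctuations.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import CodonCountMatrix, Transcriptome

logger = logging.getLogger(__name__)

DEFAULT_MIN_DENSITY = 0.5
DEFAULT_Z_MIN = 10.0
DEFAULT_MIN_REPLICATES = 2
#: Analysis-window trims (codons) masking the initiation ramp and termination.
DEFAULT_START_TRIM = 5
DEFAULT_END_TRIM = 5

PAUSE_TABLE_COLUMNS = (
    "transcript_id", "gene_id", "codon_index", "codon", "count", "score", "z",
)


def threshold_transcripts(
    matrices_per_sample: Mapping[str, Mapping[str, CodonCountMatrix]],
    min_density: float = DEFAULT_MIN_DENSITY,
) -> set[str]:
    """Transcripts with >= ``min_density`` reads/codon in every sample."""
    samples = list(matrices_per_sample)
    if not samples:
        return set()
    universe = set(matrices_per_sample[samples[0]])
    for sample in samples[1:]:
        if set(matrices_per_sample[sample]) != universe:
            raise ValueError("samples cover different transcript universes")
    return {
        tid
        for tid in universe
        if all(
            matrices_per_sample[s][tid].density >= min_density for s in samples
        )
    }


def pause_scores(
    matrix: CodonCountMatrix,
    start_trim: int = DEFAULT_START_TRIM,
    end_trim: int = DEFAULT_END_TRIM,
) -> pd.DataFrame | None:
    """Per-codon pause scores and z for one transcript, or None when untestable.

    Returns ``None`` when the analysis window has fewer than 3 codons or the
    window counts have zero variance (uniform coverage cannot pause).
    """
    n = matrix.n_codons
    lo, hi = start_trim, n - end_trim
    if hi - lo < 3:
        return None
    window = matrix.counts[lo:hi].astype(float)
    mu = window.mean()
    sigma = window.std(ddof=0)
    if sigma == 0 or mu == 0:
        return None
    return pd.DataFrame(
        {
            "codon_index": np.arange(lo, hi),
            "count": window.astype(np.int64),
            "score": window / mu,
            "z": (window - mu) / sigma,
        }
    )


def pause_table(
    matrices: Mapping[str, CodonCountMatrix],
    transcriptome: Transcriptome,
    analyzed: set[str] | None = None,
    start_trim: int = DEFAULT_START_TRIM,
    end_trim: int = DEFAULT_END_TRIM,
) -> pd.DataFrame:
    """Pause scores for every analyzed transcript of one library."""
    frames = []
    skipped = 0
    ids = transcriptome.ids if analyzed is None else [
        t for t in transcriptome.ids if t in analyzed
    ]
    for tid in ids:
        scores = pause_scores(matrices[tid], start_trim, end_trim)
        if scores is None:
            skipped += 1
            continue
        t = transcriptome[tid]
        scores = scores.assign(
            transcript_id=tid,
            gene_id=t.gene_id,
            codon=[t.codon(i) for i in scores["codon_index"]],
        )
        frames.append(scores.loc[:, list(PAUSE_TABLE_COLUMNS)])
    if skipped:
        logger.info("pause scoring skipped %d transcripts (no variance)", skipped)
    if not frames:
        return pd.DataFrame(columns=list(PAUSE_TABLE_COLUMNS))
    return pd.concat(frames, ignore_index=True)


@dataclass
class PauseCalls:
    """Per-replicate pause-gene sets and the cross-replicate consensus."""

    per_replicate: dict[str, set[str]]
    consensus: set[str]
    z_min: float
    codon: str | None
    min_replicates: int


def call_pause_genes(
    tables: Mapping[str, pd.DataFrame],
    z_min: float = DEFAULT_Z_MIN,
    codon: str | None = "AGA",
    min_replicates: int = DEFAULT_MIN_REPLICATES,
) -> PauseCalls:
    """Call pause genes per replicate (any qualifying site) plus a consensus set.

    A gene is called in a replicate when any site with the matching codon
    identity (or any codon when ``codon`` is None) has ``z >= z_min``
    (inclusive); the consensus requires calls in >= ``min_replicates``
    replicates.
    """
    if z_min <= 0 or min_replicates < 1:
        raise ValueError("thresholds must be positive")
    per_replicate: dict[str, set[str]] = {}
    for rep, table in tables.items():
        hits = table.loc[table["z"] >= z_min]
        if codon is not None:
            hits = hits.loc[hits["codon"] == codon]
        per_replicate[rep] = set(hits["gene_id"])
    counts: dict[str, int] = {}
    for genes in per_replicate.values():
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    consensus = {g for g, c in counts.items() if c >= min_replicates}
    return PauseCalls(per_replicate, consensus, z_min, codon, min_replicates)


@dataclass
class OverlapResult:
    pairwise: pd.DataFrame
    venn: dict[str, int] = field(default_factory=dict)

    @property
    def mean_shared_fraction(self) -> float:
        fracs = pd.concat(
            [self.pairwise["frac_a"], self.pairwise["frac_b"]]
        ).dropna()
        return float(fracs.mean()) if len(fracs) else math.nan


def intersect_pause_sets(sets: Mapping[str, set[str]]) -> OverlapResult:
    """Pairwise overlaps and (for 3 sets) the full Venn partition.

    Shared fractions are |A∩B|/|A| and |A∩B|/|B|; undefined (NaN) for empty
    sets.
    """
    names = list(sets)
    if len(names) < 2:
        raise ValueError("need at least two sets to intersect")
    rows = []
    for a, b in itertools.combinations(names, 2):
        shared = len(sets[a] & sets[b])
        rows.append(
            {
                "set_a": a,
                "set_b": b,
                "size_a": len(sets[a]),
                "size_b": len(sets[b]),
                "shared": shared,
                "frac_a": shared / len(sets[a]) if sets[a] else np.nan,
                "frac_b": shared / len(sets[b]) if sets[b] else np.nan,
            }
        )
    venn: dict[str, int] = {}
    if len(names) == 3:
        a, b, c = (sets[n] for n in names)
        for mask in itertools.product((0, 1), repeat=3):
            if mask == (0, 0, 0):
                continue
            region = set.intersection(
                *(s for s, m in zip((a, b, c), mask) if m)
            ) - set().union(*(s for s, m in zip((a, b, c), mask) if not m))
            venn["".join(map(str, mask))] = len(region)
    return OverlapResult(pd.DataFrame(rows), venn)


# ------------------------------------------------------------------- spearman

def _rho_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx**2).sum() * (ry**2).sum()))
    if denom == 0:
        return math.nan
    return float((rx * ry).sum() / denom)


def spearman(x, y, exact_max_n: int = 10) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties and a two-sided p.

    The p-value uses exact permutation enumeration for n <= ``exact_max_n``
    and the t-approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _rho_from_ranks(rx, ry)
    if math.isnan(rho):
        return rho, math.nan
    if n <= exact_max_n:
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = math.sqrt(float((rxc**2).sum() * (ryc**2).sum()))
        obs = abs(float((rxc * ryc).sum()))
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            stat = abs(float((rxc * ryc[list(perm)]).sum()))
            if stat >= obs - 1e-12 * denom:
                hits += 1
            total += 1
        return rho, hits / total
    t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho**2))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return rho, min(1.0, p)


def gene_pause_statistic(
    tables: Mapping[str, pd.DataFrame],
) -> pd.Series:
    """Gene pause score: per-replicate mean over transcripts of the transcript's
    maximum pause score, summed across replicates."""
    per_rep = []
    for rep, table in tables.items():
        if table.empty:
            continue
        tx_max = table.groupby(["gene_id", "transcript_id"])["score"].max()
        per_rep.append(tx_max.groupby("gene_id").mean().rename(rep))
    if not per_rep:
        return pd.Series(dtype=float, name="pause_statistic")
    wide = pd.concat(per_rep, axis=1).fillna(0.0)
    return wide.sum(axis=1).rename("pause_statistic")


def correlate_pause_with_expression(
    tables: Mapping[str, pd.DataFrame],
    effects: pd.DataFrame,
) -> tuple[float, float, int]:
    """Spearman correlation of the summed gene pause statistic with beta.

    ``effects`` must carry ``gene_id`` and ``beta`` (ln-scale effect size)
    columns; only genes present in both inputs are used. Returns
    (rho, p, n_genes).
    """
    stat = gene_pause_statistic(tables)
    eff = effects.set_index("gene_id")["beta"]
    common = stat.index.intersection(eff.index)
    if len(common) < 3:
        raise ValueError("fewer than 3 genes with both pause and expression data")
    rho, p = spearman(stat.loc[common].to_numpy(), eff.loc[common].to_numpy())
    return rho, p, len(common)
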