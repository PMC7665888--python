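"""Translational efficiency (TE) and differential-TE analysis.

TE is ribosome-footprint density over a gene's CDS normalised by its mRNA
abundance. Counts from both assays are normalised with median-of-ratios size
factors, per-sample log2 TE is formed with a 0.5 pseudocount, and a per-gene
Welch t-test compares conditions, with Benjamini-Hochberg correction across
genes. The module also implements codon-filtered TE: removing every footprint
whose A-site falls within +/- ``window`` codons of an instance of a target
codon (AGA by default) re-tests TE with pause-proximal evidence excluded.

Replication-competent histone mRNAs are not polyadenylated and distort
footprint/mRNA coupling, so genes with a configurable name prefix ("Hist")
are removed before testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .asite import OUTSIDE_CDS, assign_asite_codons
from .model import OffsetTable, StageStats, Transcriptome

logger = logging.getLogger(__name__)

PSEUDOCOUNT = 0.5
DEFAULT_HISTONE_PREFIX = "Hist"


@dataclass
class GeneFilterConfig:
    """Gene-level exclusions applied before TE testing."""

    histone_prefix: str = DEFAULT_HISTONE_PREFIX
    extra_exclusion: set[str] = field(default_factory=set)
    top_genes: set[str] = field(default_factory=set)


@dataclass
class TECountTable:
    """Matched footprint/RNA counts per gene per sample (same sample columns)."""

    footprints: pd.DataFrame
    rna: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.footprints.columns) != list(self.rna.columns):
            raise ValueError("footprint and RNA tables must share sample columns")
        if not self.footprints.index.equals(self.rna.index):
            raise ValueError("footprint and RNA tables must share the gene index")

    @property
    def genes(self) -> pd.Index:
        return self.footprints.index

    @property
    def samples(self) -> list[str]:
        return list(self.footprints.columns)


def apply_gene_filters(genes: pd.Index, filters: GeneFilterConfig) -> pd.Index:
    keep = ~genes.str.startswith(filters.histone_prefix)
    if filters.extra_exclusion:
        keep &= ~genes.isin(filters.extra_exclusion)
    return genes[keep]


def footprint_gene_counts(
    footprints: pd.DataFrame,
    offsets: OffsetTable,
    transcriptome: Transcriptome,
) -> pd.Series:
    """Reads per gene whose A-site lies inside the CDS."""
    genes = [transcriptome[tid].gene_id for tid in transcriptome.ids]
    counts = pd.Series(0, index=pd.Index(genes, name="gene_id"), dtype=np.int64)
    if footprints.empty:
        return counts
    codon = assign_asite_codons(footprints, offsets, transcriptome)
    inside = codon != OUTSIDE_CDS
    per_tx = footprints.loc[inside, "transcript_id"].value_counts()
    gene_of = transcriptome.gene_of
    per_gene = per_tx.groupby(per_tx.index.map(gene_of)).sum()
    counts.loc[per_gene.index] += per_gene.astype(np.int64)
    return counts


def count_for_te(
    footprint_libraries: Mapping[str, pd.DataFrame],
    offsets: OffsetTable,
    transcriptome: Transcriptome,
    rna_counts: pd.DataFrame,
    filters: GeneFilterConfig | None = None,
) -> TECountTable:
    """Assemble the matched footprint/RNA count table over the filtered gene set.

    Genes present in only one assay are excluded (logged); histone-prefix and
    exclusion-list genes are removed from both assays.
    """
    filters = filters or GeneFilterConfig()
    fp = pd.DataFrame(
        {
            sample: footprint_gene_counts(lib, offsets, transcriptome)
            for sample, lib in footprint_libraries.items()
        }
    )
    missing = fp.index.symmetric_difference(rna_counts.index)
    if len(missing):
        logger.warning(
            "%d genes present in only one assay were excluded", len(missing)
        )
    common = fp.index.intersection(rna_counts.index)
    kept = apply_gene_filters(common, filters)
    rna = rna_counts.loc[kept, list(footprint_libraries)]
    return TECountTable(fp.loc[kept], rna)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors (geometric-mean reference)."""
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        # Degenerate table: fall back to relative library totals.
        totals = arr.sum(axis=0)
        return pd.Series(totals / np.exp(np.mean(np.log(np.maximum(totals, 1)))),
                         index=counts.columns)
    ref = np.exp(np.log(arr[positive]).mean(axis=1))
    sf = np.median(arr[positive] / ref[:, None], axis=0)
    return pd.Series(sf, index=counts.columns)


def log2_te_matrix(table: TECountTable) -> pd.DataFrame:
    """Per-gene, per-sample log2 TE with pseudocount and size-factor scaling."""
    sf_fp = size_factors(table.footprints)
    sf_rna = size_factors(table.rna)
    fp_norm = (table.footprints + PSEUDOCOUNT).div(sf_fp, axis=1)
    rna_norm = (table.rna + PSEUDOCOUNT).div(sf_rna, axis=1)
    return np.log2(fp_norm) - np.log2(rna_norm)


def differential_te(
    table: TECountTable,
    condition_map: Mapping[str, str],
    conditions: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Per-gene Welch t-test on log2 TE between two conditions, BH-corrected.

    ``conditions`` orders (reference, treatment); ``delta_log2_te`` is
    treatment minus reference. Genes with zero variance in both groups get an
    undefined (NaN) p and q.
    """
    if conditions is None:
        found = sorted(set(condition_map.values()))
        if len(found) != 2:
            raise ValueError(f"need exactly two conditions, found {found}")
        conditions = (found[0], found[1])
    ref, alt = conditions
    ref_samples = [s for s in table.samples if condition_map[s] == ref]
    alt_samples = [s for s in table.samples if condition_map[s] == alt]
    if len(ref_samples) < 2 or len(alt_samples) < 2:
        raise ValueError("need >= 2 samples per condition")
    te = log2_te_matrix(table)
    a = te[alt_samples].to_numpy()
    b = te[ref_samples].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, pval = sps.ttest_ind(a, b, axis=1, equal_var=False)
    result = pd.DataFrame(
        {
            f"log2_te_{ref}": b.mean(axis=1),
            f"log2_te_{alt}": a.mean(axis=1),
            "delta_log2_te": a.mean(axis=1) - b.mean(axis=1),
            "p_value": pval,
        },
        index=table.genes,
    )
    valid = result["p_value"].notna()
    qvals = np.full(len(result), np.nan)
    if valid.any():
        qvals[valid.to_numpy()] = multipletests(
            result.loc[valid, "p_value"], method="fdr_bh"
        )[1]
    result["q_value"] = qvals
    return result


def differential_expression(
    rna_counts: pd.DataFrame,
    condition_map: Mapping[str, str],
    conditions: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Minimal internal DE test on RNA counts: Welch t on ln-normalised counts.

    ``beta`` is the natural-log fold change of size-factor-normalised means
    (treatment over reference) — the scale of a sleuth-style effect size.
    """
    if conditions is None:
        found = sorted(set(condition_map.values()))
        if len(found) != 2:
            raise ValueError(f"need exactly two conditions, found {found}")
        conditions = (found[0], found[1])
    ref, alt = conditions
    sf = size_factors(rna_counts)
    logn = np.log((rna_counts + PSEUDOCOUNT).div(sf, axis=1))
    ref_samples = [s for s in rna_counts.columns if condition_map[s] == ref]
    alt_samples = [s for s in rna_counts.columns if condition_map[s] == alt]
    a = logn[alt_samples].to_numpy()
    b = logn[ref_samples].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pval = sps.ttest_ind(a, b, axis=1, equal_var=False)
    beta = a.mean(axis=1) - b.mean(axis=1)
    result = pd.DataFrame(
        {"beta": beta, "p_value": pval}, index=rna_counts.index
    ).rename_axis("gene_id")
    valid = result["p_value"].notna()
    qvals = np.full(len(result), np.nan)
    if valid.any():
        qvals[valid.to_numpy()] = multipletests(
            result.loc[valid, "p_value"], method="fdr_bh"
        )[1]
    result["q_value"] = qvals
    return result.reset_index()


def filter_codon_asite_reads(
    footprints: pd.DataFrame,
    offsets: OffsetTable,
    transcriptome: Transcriptome,
    codon: str = "AGA",
    window: int = 1,
) -> tuple[pd.DataFrame, StageStats]:
    """Remove reads whose A-site falls within ``window`` codons of the target.

    A read is removed iff any codon in ``[a - window, a + window]`` (clipped
    to the CDS) matches ``codon``, where ``a`` is the read's assigned A-site
    codon. Reads whose A-site lies outside the CDS are retained (they carry
    no A-site codon).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    if footprints.empty:
        return footprints.copy(), StageStats("filter_codon_asite", 0, 0, 0)
    assigned = assign_asite_codons(footprints, offsets, transcriptome)
    remove = np.zeros(len(footprints), dtype=bool)
    tx_idx = transcriptome.transcript_indices(footprints["transcript_id"])
    order = np.argsort(tx_idx, kind="stable")
    sorted_tx = tx_idx[order]
    for gi, tid in enumerate(transcriptome.ids):
        lo = np.searchsorted(sorted_tx, gi, side="left")
        hi = np.searchsorted(sorted_tx, gi, side="right")
        if lo == hi:
            continue
        rows = order[lo:hi]
        t = transcriptome[tid]
        is_target = np.array([c == codon for c in t.codons])
        if not is_target.any():
            continue
        # Dilate the target mask by `window` codons on each side (clipped at
        # the CDS boundaries, never wrapping).
        near = is_target.copy()
        for w in range(1, window + 1):
            near[w:] |= is_target[:-w]
            near[:-w] |= is_target[w:]
        a = assigned[rows]
        inside = a != OUTSIDE_CDS
        remove[rows[inside]] = near[a[inside]]
    kept = footprints.loc[~remove].reset_index(drop=True)
    stats = StageStats(
        "filter_codon_asite", len(footprints), len(kept), int(remove.sum())
    )
    logger.info(
        "codon-filtered reads (%s +/-%d): removed %d of %d",
        codon, window, stats.n_discarded, stats.n_input,
    )
    return kept, stats


def top_gene_report(
    te_results: pd.DataFrame,
    top_genes: set[str],
    q_threshold: float = 0.05,
) -> tuple[pd.DataFrame, int]:
    """Restrict TE results to a 5'TOP gene list; count genes with q <= threshold."""
    if not top_genes:
        raise ValueError("TOP gene list is empty")
    subset = te_results.loc[te_results.index.isin(top_genes)]
    n_altered = int((subset["q_value"] <= q_threshold).sum())
    return subset, n_altered
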