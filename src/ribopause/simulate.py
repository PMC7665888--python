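"""Synthetic Ribo-seq experiment with known ground truth.

The generator emulates a tRNA-deficiency translatome: a toy multi-transcript
coding transcriptome, footprint libraries whose A-site positions are drawn
from a codon dwell-time model with stochastic, replicate-specific dwell
elevation at a pause codon (AGA by default, mirroring AGA decoding by a
depleted arginine tRNA), and matched negative-binomial RNA-seq counts with
configurable differential-expression and differential-TE effects.

Model, per library:

* reads are allocated to genes multinomially with weight
  ``rna_mean(g, cond) * 2**te_log2(g, cond) * body_codons(g)``, each weight
  multiplied by a Gamma(1/alpha, alpha) factor so gene counts are
  negative-binomial-like across replicates;
* within a gene, A-site codon positions are drawn multinomially over codons
  ``1 .. n-2`` (the decoded codons between start and stop) with weight
  ``w_c`` per codon instance; the first decoded codon carries an extra
  initiation-dwell multiplier (the start-codon peak seen in CHX-arrested
  profiling data, and the signal the metagene offset calibration relies on);
* in the mutant condition each gene independently (per replicate) receives a
  pause with probability ``pause_gene_fraction`` at one uniformly chosen
  instance of ``pause_codon``, multiplying that instance's weight by
  ``pause_multiplier``;
* the read 5' end is placed at ``A-site nt - true_offset(length)`` with the
  length drawn from ``read_length_distribution``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import (
    FOOTPRINT_COLUMNS,
    SENSE_CODONS,
    STOP_CODONS,
    CODON_TO_INDEX,
    TranscriptModel,
    Transcriptome,
)

logger = logging.getLogger(__name__)

CONDITIONS = ("control", "mutant")

_DEFAULT_READ_LENGTH_DIST = {
    26: 0.02, 27: 0.03, 28: 0.05, 29: 0.15, 30: 0.25,
    31: 0.25, 32: 0.15, 33: 0.07, 34: 0.03,
}
#: A-site offsets by read length, nt from the 5' end (riboWaltz-like geometry:
#: P-site ~12-14 nt in, A-site one codon further, drifting with read length).
_DEFAULT_TRUE_OFFSETS = {
    26: 13, 27: 13, 28: 14, 29: 15, 30: 15, 31: 16, 32: 16, 33: 17, 34: 17,
}

# Distinct sub-stream tags so each random purpose gets an independent stream
# derived from (seed, tag, ...); all integers stay below 2**31.
_TAG_TRANSCRIPTOME = 11
_TAG_EFFECTS = 22
_TAG_FOOTPRINTS = 33
_TAG_RNA = 44


@dataclass
class SimulationConfig:
    """Knobs of the synthetic experiment; defaults are the study conditions."""

    n_genes: int = 500
    #: CDS body length range in codons (between start and stop), inclusive.
    cds_length_range: tuple[int, int] = (150, 300)
    #: Probability vector over the 61 sense codons (lexicographic order);
    #: None means uniform usage.
    codon_usage: np.ndarray | None = None
    #: Relative dwell time per sense codon; None means uniform (w_c = 1).
    dwell_weights: np.ndarray | None = None
    pause_codon: str = "AGA"
    #: Extra dwell multiplier k at a paused codon instance.
    pause_multiplier: float = 50.0
    #: Probability p that a gene carries a pause in a given mutant replicate.
    pause_gene_fraction: float = 0.5
    #: Dwell elevation at the first decoded codon (initiation peak).
    init_dwell_multiplier: float = 5.0
    reads_per_library: int = 500_000
    read_length_distribution: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_READ_LENGTH_DIST)
    )
    true_offsets: dict[int, int] = field(
        default_factory=lambda: dict(_DEFAULT_TRUE_OFFSETS)
    )
    n_replicates_per_condition: int = 3
    utr5_length: int = 30
    utr3_length: int = 30
    #: Gene base expression drawn log-uniformly from this range (counts scale).
    rna_mean_range: tuple[float, float] = (200.0, 2000.0)
    #: Negative-binomial dispersion alpha (var = mu + alpha*mu^2).
    rna_dispersion: float = 0.01
    de_fraction: float = 0.1
    #: Differential-expression magnitude, natural-log scale (sign randomised).
    de_effect: float = 0.693
    te_shift_fraction: float = 0.1
    #: Differential-TE magnitude, log2 scale (sign randomised).
    te_effect: float = 1.0
    seed: int = 0

    def validate(self) -> list[str]:
        """Return all constraint violations (empty list = valid)."""
        problems = []
        if self.n_genes < 1:
            problems.append("n_genes must be >= 1")
        lo, hi = self.cds_length_range
        if lo > hi or lo < 1:
            problems.append(f"degenerate cds_length_range ({lo}, {hi})")
        if self.codon_usage is not None:
            u = np.asarray(self.codon_usage, dtype=float)
            if u.shape != (len(SENSE_CODONS),):
                problems.append("codon_usage must have 61 entries")
            elif abs(u.sum() - 1.0) > 1e-9 or (u < 0).any():
                problems.append("codon_usage must be a probability vector")
        if self.dwell_weights is not None:
            w = np.asarray(self.dwell_weights, dtype=float)
            if w.shape != (len(SENSE_CODONS),) or (w <= 0).any():
                problems.append("dwell_weights must be 61 positive reals")
        if self.pause_codon not in CODON_TO_INDEX:
            problems.append(f"pause_codon {self.pause_codon!r} is not a sense codon")
        if self.pause_multiplier <= 0:
            problems.append("pause_multiplier must be positive")
        if not 0.0 <= self.pause_gene_fraction <= 1.0:
            problems.append("pause_gene_fraction must lie in [0, 1]")
        if self.init_dwell_multiplier <= 0:
            problems.append("init_dwell_multiplier must be positive")
        if self.reads_per_library < 0:
            problems.append("reads_per_library must be non-negative")
        probs = np.array(list(self.read_length_distribution.values()), dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            problems.append("read_length_distribution must be a probability vector")
        for length in self.read_length_distribution:
            off = self.true_offsets.get(length)
            if off is None:
                problems.append(f"no true offset for read length {length}")
            elif not 0 < off < length:
                problems.append(f"true offset {off} invalid for length {length}")
        if self.rna_dispersion <= 0:
            problems.append("rna_dispersion must be positive")
        if not 0.0 <= self.de_fraction <= 1.0:
            problems.append("de_fraction must lie in [0, 1]")
        if not 0.0 <= self.te_shift_fraction <= 1.0:
            problems.append("te_shift_fraction must lie in [0, 1]")
        if self.n_replicates_per_condition < 1:
            problems.append("n_replicates_per_condition must be >= 1")
        return problems

    def check(self) -> "SimulationConfig":
        problems = self.validate()
        if problems:
            raise ValueError("; ".join(problems))
        return self

    def usage_vector(self) -> np.ndarray:
        if self.codon_usage is None:
            return np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))
        return np.asarray(self.codon_usage, dtype=float)

    def dwell_vector(self) -> np.ndarray:
        if self.dwell_weights is None:
            return np.ones(len(SENSE_CODONS))
        return np.asarray(self.dwell_weights, dtype=float)


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must rediscover."""

    #: (gene_id, library_label, codon_index) for every implanted pause.
    paused_sites: set[tuple[str, str, int]] = field(default_factory=set)
    #: gene x condition true RNA expression means.
    rna_means: pd.DataFrame | None = None
    #: gene x condition true log2 translational-efficiency offsets.
    te_log2: pd.DataFrame | None = None
    true_offsets: dict[int, int] = field(default_factory=dict)
    de_genes: set[str] = field(default_factory=set)
    te_shifted_genes: set[str] = field(default_factory=set)
    #: genes selected for pausing that carried no pause-codon instance.
    pause_skipped: list[tuple[str, str]] = field(default_factory=list)

    def paused_genes(self, library_label: str) -> set[str]:
        return {g for g, lib, _ in self.paused_sites if lib == library_label}


def library_label(condition: str, replicate: int) -> str:
    return f"{condition}_rep{replicate}"


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *tags])


# ---------------------------------------------------------------- transcriptome

def generate_transcriptome(config: SimulationConfig) -> Transcriptome:
    """One transcript per gene: 5'UTR + ATG + body + stop + 3'UTR.

    Body codons are drawn i.i.d. from ``codon_usage`` (sense codons only, so
    no internal stops by construction); deterministic given ``config.seed``.
    """
    config.check()
    rng = _rng(config.seed, _TAG_TRANSCRIPTOME)
    usage = config.usage_vector()
    lo, hi = config.cds_length_range
    width = len(str(config.n_genes))
    transcripts = []
    for g in range(config.n_genes):
        gene_id = f"gene{g + 1:0{width}d}"
        body_len = int(rng.integers(lo, hi + 1))
        body_idx = rng.choice(len(SENSE_CODONS), size=body_len, p=usage)
        body = "".join(SENSE_CODONS[i] for i in body_idx)
        stop = STOP_CODONS[int(rng.integers(len(STOP_CODONS)))]
        utr5 = "".join(rng.choice(list("ACGT"), size=config.utr5_length))
        utr3 = "".join(rng.choice(list("ACGT"), size=config.utr3_length))
        cds = "ATG" + body + stop
        transcripts.append(
            TranscriptModel(
                transcript_id=f"tx{g + 1:0{width}d}",
                gene_id=gene_id,
                sequence=utr5 + cds + utr3,
                cds_start=config.utr5_length,
                cds_end=config.utr5_length + len(cds),
            )
        )
    return Transcriptome(transcripts)


# -------------------------------------------------------------- gene effects

def draw_gene_effects(
    transcriptome: Transcriptome, config: SimulationConfig
) -> GroundTruth:
    """Draw per-gene expression means and DE/TE effects (deterministic in seed)."""
    config.check()
    rng = _rng(config.seed, _TAG_EFFECTS)
    genes = [transcriptome[tid].gene_id for tid in transcriptome.ids]
    n = len(genes)
    lo, hi = config.rna_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))

    de_mask = rng.random(n) < config.de_fraction
    de_sign = rng.choice([-1.0, 1.0], size=n)
    mutant_mean = base * np.where(de_mask, np.exp(de_sign * config.de_effect), 1.0)

    te_mask = rng.random(n) < config.te_shift_fraction
    te_sign = rng.choice([-1.0, 1.0], size=n)
    te_mut = np.where(te_mask, te_sign * config.te_effect, 0.0)

    rna_means = pd.DataFrame(
        {"control": base, "mutant": mutant_mean}, index=pd.Index(genes, name="gene_id")
    )
    te_log2 = pd.DataFrame(
        {"control": np.zeros(n), "mutant": te_mut},
        index=pd.Index(genes, name="gene_id"),
    )
    return GroundTruth(
        rna_means=rna_means,
        te_log2=te_log2,
        true_offsets=dict(config.true_offsets),
        de_genes={g for g, m in zip(genes, de_mask) if m},
        te_shifted_genes={g for g, m in zip(genes, te_mask) if m},
    )


# ----------------------------------------------------------------- footprints

def _gene_weights(
    transcriptome: Transcriptome,
    config: SimulationConfig,
    truth: GroundTruth,
    condition: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-gene library weights: expression x TE x length, gamma-mixed."""
    genes = [transcriptome[tid].gene_id for tid in transcriptome.ids]
    mu = truth.rna_means.loc[genes, condition].to_numpy()
    te = np.exp2(truth.te_log2.loc[genes, condition].to_numpy())
    body = transcriptome.n_codons_arr - 2  # decoded codons between start/stop
    w = mu * te * np.maximum(body, 1)
    alpha = config.rna_dispersion
    if alpha > 1e-8:
        w = w * rng.gamma(1.0 / alpha, alpha, size=w.size)
    return w


def allocate_gene_reads(
    transcriptome: Transcriptome,
    config: SimulationConfig,
    truth: GroundTruth,
    condition: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Multinomial read allocation across genes for one library."""
    w = _gene_weights(transcriptome, config, truth, condition, rng)
    return rng.multinomial(config.reads_per_library, w / w.sum())


def simulate_footprints(
    transcriptome: Transcriptome,
    config: SimulationConfig,
    truth: GroundTruth,
    replicate: int,
    condition: str,
) -> pd.DataFrame:
    """Simulate one footprint library; implanted pauses are recorded in ``truth``.

    Returns a footprint table (read_id, transcript_id, five_prime_pos, length)
    with exactly ``config.reads_per_library`` rows.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    config.check()
    label = library_label(condition, replicate)
    cond_idx = CONDITIONS.index(condition)
    rng = _rng(config.seed, _TAG_FOOTPRINTS, cond_idx, replicate)

    dwell = config.dwell_vector()
    pause_code = CODON_TO_INDEX[config.pause_codon]
    reads_per_gene = allocate_gene_reads(transcriptome, config, truth, condition, rng)

    # Pause implantation is drawn for every gene (not only those with reads),
    # so ground truth is independent of sampling depth.
    pause_draw = rng.random(len(transcriptome))

    codon_idx_parts: list[np.ndarray] = []
    tx_id_parts: list[np.ndarray] = []
    for gi, tid in enumerate(transcriptome.ids):
        t = transcriptome[tid]
        codes = t.codon_codes
        n = t.n_codons
        if n < 3:
            continue
        decoded = np.arange(1, n - 1)  # A-site can sit on codons 1..n-2
        w = dwell[codes[decoded]].astype(float)
        w[0] *= config.init_dwell_multiplier
        if condition == "mutant" and pause_draw[gi] < config.pause_gene_fraction:
            aga_local = np.flatnonzero(codes[decoded] == pause_code)
            if aga_local.size == 0:
                logger.warning(
                    "gene %s selected for pausing but has no %s codon; skipped",
                    t.gene_id, config.pause_codon,
                )
                truth.pause_skipped.append((t.gene_id, label))
            else:
                chosen = int(aga_local[rng.integers(aga_local.size)])
                w[chosen] *= config.pause_multiplier
                truth.paused_sites.add((t.gene_id, label, int(decoded[chosen])))
        n_reads = int(reads_per_gene[gi])
        if n_reads == 0:
            continue
        counts = rng.multinomial(n_reads, w / w.sum())
        codon_idx_parts.append(np.repeat(decoded, counts))
        tx_id_parts.append(np.repeat(gi, n_reads))

    if codon_idx_parts:
        codon_idx = np.concatenate(codon_idx_parts)
        tx_pos = np.concatenate(tx_id_parts)
    else:
        codon_idx = np.empty(0, dtype=np.int64)
        tx_pos = np.empty(0, dtype=np.int64)

    n_total = codon_idx.size
    lengths_avail = np.fromiter(config.read_length_distribution, dtype=np.int64)
    probs = np.array(
        [config.read_length_distribution[int(c)] for c in lengths_avail], dtype=float
    )
    lengths = rng.choice(lengths_avail, size=n_total, p=probs / probs.sum())
    offset_lookup = np.full(int(lengths_avail.max()) + 1, -1, dtype=np.int64)
    for length, off in config.true_offsets.items():
        if length <= lengths_avail.max():
            offset_lookup[length] = off
    asite_nt = transcriptome.cds_start_arr[tx_pos] + 3 * codon_idx
    five_prime = asite_nt - offset_lookup[lengths]

    tx_ids = np.asarray(transcriptome.ids, dtype=object)[tx_pos]
    read_ids = np.char.add(f"{label}:", np.arange(n_total).astype(str))
    return pd.DataFrame(
        {
            "read_id": read_ids,
            "transcript_id": tx_ids,
            "five_prime_pos": five_prime.astype(np.int64),
            "length": lengths.astype(np.int64),
        },
        columns=list(FOOTPRINT_COLUMNS),
    )


# ------------------------------------------------------------------ RNA counts

def simulate_rna_counts(
    transcriptome: Transcriptome,
    config: SimulationConfig,
    truth: GroundTruth,
) -> pd.DataFrame:
    """Negative-binomial gene x sample RNA-seq count table for both conditions."""
    config.check()
    genes = [transcriptome[tid].gene_id for tid in transcriptome.ids]
    alpha = config.rna_dispersion
    columns = {}
    for cond_idx, condition in enumerate(CONDITIONS):
        mu = truth.rna_means.loc[genes, condition].to_numpy()
        for rep in range(1, config.n_replicates_per_condition + 1):
            rng = _rng(config.seed, _TAG_RNA, cond_idx, rep)
            if alpha < 1e-8:  # Poisson limit of the NB
                counts = rng.poisson(mu)
            else:
                counts = rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu))
            columns[library_label(condition, rep)] = counts.astype(np.int64)
    return pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))


# ------------------------------------------------------------------ experiment

@dataclass
class SimulatedExperiment:
    transcriptome: Transcriptome
    truth: GroundTruth
    #: library label -> footprint table.
    footprints: dict[str, pd.DataFrame]
    rna_counts: pd.DataFrame
    condition_map: dict[str, str]


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Full synthetic study: transcriptome, all libraries, RNA counts, truth."""
    transcriptome = generate_transcriptome(config)
    truth = draw_gene_effects(transcriptome, config)
    footprints: dict[str, pd.DataFrame] = {}
    condition_map: dict[str, str] = {}
    for condition in CONDITIONS:
        for rep in range(1, config.n_replicates_per_condition + 1):
            label = library_label(condition, rep)
            footprints[label] = simulate_footprints(
                transcriptome, config, truth, rep, condition
            )
            condition_map[label] = condition
    rna_counts = simulate_rna_counts(transcriptome, config, truth)
    return SimulatedExperiment(transcriptome, truth, footprints, rna_counts, condition_map)


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``config`` with a different master seed."""
    return replace(config, seed=int(seed) & 0x7FFFFFFF)
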