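"""End-to-end orchestration: simulate -> preprocess -> asite -> occupancy ->
pause -> te, with serialized intermediates, structured logging and a JSON
report.

Every stage writes its outputs as TSV under the run directory and can be
re-run in isolation: a stage whose inputs are absent from memory loads them
from the serialized intermediates, so identical config + seed reproduce
byte-identical artifacts whether a run is executed in one pass or resumed
stage by stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__, io as rio
from . import asite as asite_mod
from . import occupancy as occ_mod
from . import pause as pause_mod
from . import preprocess as prep_mod
from . import te as te_mod
from .model import OffsetTable, Transcriptome
from .simulate import (
    CONDITIONS,
    GroundTruth,
    SimulationConfig,
    library_label,
    simulate_experiment,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "asite", "occupancy", "pause", "te")


@dataclass
class RunConfig:
    """Full parameterisation of a pipeline run (the default profile is the
    printed analysis protocol: adapter CTGTAGGCACCATCAAT, lengths 29-33,
    z >= 10 in >= 2 replicates, 0.5 reads/codon, +/-1 codon AGA filtering,
    histone prefix 'Hist')."""

    outdir: str = "ribopause_run"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    adapter: str = prep_mod.DEFAULT_ADAPTER
    trim_first: bool = True
    min_length: int = prep_mod.DEFAULT_MIN_LENGTH
    max_length: int = prep_mod.DEFAULT_MAX_LENGTH
    offset_min_support: int = 30
    occupancy_exclude_start: int = occ_mod.DEFAULT_EXCLUDE_START
    occupancy_exclude_end: int = occ_mod.DEFAULT_EXCLUDE_END
    z_min: float = pause_mod.DEFAULT_Z_MIN
    min_density: float = pause_mod.DEFAULT_MIN_DENSITY
    pause_codon: str = "AGA"
    min_replicates: int = pause_mod.DEFAULT_MIN_REPLICATES
    start_trim: int = pause_mod.DEFAULT_START_TRIM
    end_trim: int = pause_mod.DEFAULT_END_TRIM
    te_filter_codon: str = "AGA"
    te_filter_window: int = 1
    histone_prefix: str = te_mod.DEFAULT_HISTONE_PREFIX
    q_threshold: float = 0.05
    top_genes_path: str | None = None

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        sim_raw = raw.pop("simulation", {})
        for key in ("cds_length_range", "rna_mean_range"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        for key in ("read_length_distribution", "true_offsets"):
            if key in sim_raw:
                sim_raw[key] = {int(k): v for k, v in sim_raw[key].items()}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(simulation=SimulationConfig(**sim_raw), **raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        sim = d["simulation"]
        for key in ("codon_usage", "dwell_weights"):
            if sim[key] is not None:
                sim[key] = list(np.asarray(sim[key], dtype=float))
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)  # analysis parameters only, not the location
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_config(config: RunConfig) -> list[str]:
    """All precondition violations at once (empty list = valid)."""
    problems = list(config.simulation.validate())
    if not config.adapter:
        problems.append("adapter must be non-empty")
    if config.min_length > config.max_length:
        problems.append(
            f"min_length {config.min_length} > max_length {config.max_length}"
        )
    if config.z_min <= 0:
        problems.append("z_min must be positive")
    if config.min_density < 0:
        problems.append("min_density must be non-negative")
    if config.min_replicates < 1:
        problems.append("min_replicates must be >= 1")
    if config.min_replicates > config.simulation.n_replicates_per_condition:
        problems.append("min_replicates exceeds replicates per condition")
    if config.start_trim < 0 or config.end_trim < 0:
        problems.append("pause window trims must be non-negative")
    if config.occupancy_exclude_start < 0 or config.occupancy_exclude_end < 0:
        problems.append("occupancy exclusions must be non-negative")
    if config.te_filter_window < 0:
        problems.append("te_filter_window must be non-negative")
    if not 0 < config.q_threshold < 1:
        problems.append("q_threshold must lie in (0, 1)")
    if config.top_genes_path and not Path(config.top_genes_path).exists():
        problems.append(f"top gene list not found: {config.top_genes_path}")
    return problems


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineState:
    """Lazy handle on a run directory: loads intermediates on demand."""

    config: RunConfig

    def __post_init__(self) -> None:
        self.outdir = Path(self.config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.labels = [
            library_label(cond, rep)
            for cond in CONDITIONS
            for rep in range(1, self.config.simulation.n_replicates_per_condition + 1)
        ]
        self.condition_map = {
            lab: lab.rsplit("_rep", 1)[0] for lab in self.labels
        }
        self.truth: GroundTruth | None = None

    # --- loaders with disk fallback -------------------------------------
    def transcriptome(self) -> Transcriptome:
        if not hasattr(self, "_transcriptome"):
            self._transcriptome = rio.read_transcriptome(
                self.outdir / "transcriptome.fasta", self.outdir / "cds.tsv"
            )
        return self._transcriptome

    def raw_footprints(self, label: str) -> pd.DataFrame:
        return rio.read_footprints_tsv(self.outdir / f"footprints_{label}.tsv")

    def filtered_footprints(self, label: str) -> pd.DataFrame:
        return rio.read_footprints_tsv(
            self.outdir / f"footprints_{label}.filtered.tsv"
        )

    def rna_counts(self) -> pd.DataFrame:
        return pd.read_csv(
            self.outdir / "rna_counts.tsv", sep="\t", index_col="gene_id"
        )

    def offsets(self, label: str) -> OffsetTable:
        return rio.read_offset_table(self.outdir / f"offsets_{label}.tsv")

    def matrices(self, label: str):
        return rio.read_count_matrices(
            self.outdir / f"matrices_{label}.tsv", self.transcriptome()
        )


def _stage_simulate(state: PipelineState, counts: dict) -> None:
    exp = simulate_experiment(state.config.simulation)
    state._transcriptome = exp.transcriptome
    state.truth = exp.truth
    rio.write_transcriptome(
        exp.transcriptome, state.outdir / "transcriptome.fasta",
        state.outdir / "cds.tsv",
    )
    for label, lib in exp.footprints.items():
        rio.write_footprints_tsv(lib, state.outdir / f"footprints_{label}.tsv")
        counts.setdefault("simulate", {})[label] = len(lib)
    exp.rna_counts.to_csv(state.outdir / "rna_counts.tsv", sep="\t")
    truth_sites = pd.DataFrame(
        sorted(exp.truth.paused_sites),
        columns=["gene_id", "library", "codon_index"],
    )
    truth_sites.to_csv(state.outdir / "truth_paused_sites.tsv", sep="\t", index=False)


def _stage_preprocess(state: PipelineState, counts: dict) -> None:
    transcriptome = state.transcriptome()
    for label in state.labels:
        lib = state.raw_footprints(label)
        lib, vstats = prep_mod.validate_alignments(lib, transcriptome)
        lib, fstats = prep_mod.filter_lengths(
            lib, state.config.min_length, state.config.max_length
        )
        rio.write_footprints_tsv(
            lib, state.outdir / f"footprints_{label}.filtered.tsv"
        )
        counts.setdefault("preprocess", {})[label] = {
            "input": vstats.n_input,
            "retained": fstats.n_retained,
            "discarded": vstats.n_discarded + fstats.n_discarded,
        }


def _stage_asite(state: PipelineState, counts: dict) -> None:
    transcriptome = state.transcriptome()
    for label in state.labels:
        lib = state.filtered_footprints(label)
        offsets = asite_mod.calibrate_offsets(
            lib, transcriptome, state.config.offset_min_support
        )
        rio.write_offset_table(offsets, state.outdir / f"offsets_{label}.tsv")
        result = asite_mod.build_count_matrices(lib, offsets, transcriptome)
        rio.write_count_matrices(
            result.matrices, state.outdir / f"matrices_{label}.tsv"
        )
        counts.setdefault("asite", {})[label] = {
            "input": result.stats.n_input,
            "in_cds": result.stats.n_retained,
            "outside_cds": result.stats.n_discarded,
        }


def _stage_occupancy(state: PipelineState, counts: dict) -> None:
    transcriptome = state.transcriptome()
    per_condition: dict[str, list[pd.DataFrame]] = {c: [] for c in CONDITIONS}
    for label in state.labels:
        table = occ_mod.codon_occupancy(
            state.matrices(label), transcriptome,
            exclude_start=state.config.occupancy_exclude_start,
            exclude_end=state.config.occupancy_exclude_end,
        )
        table.to_csv(state.outdir / f"occupancy_{label}.tsv", sep="\t")
        per_condition[state.condition_map[label]].append(table)
        counts.setdefault("occupancy", {})[label] = {
            "observed_total": float(table["observed"].sum()),
            "expected_total": float(table["expected"].sum()),
        }
    for cond, tables in per_condition.items():
        summary = occ_mod.occupancy_replicate_summary(tables)
        summary.to_csv(state.outdir / f"occupancy_summary_{cond}.tsv", sep="\t")


def _stage_pause(state: PipelineState, counts: dict) -> None:
    cfg = state.config
    transcriptome = state.transcriptome()
    matrices = {label: state.matrices(label) for label in state.labels}
    analyzed = pause_mod.threshold_transcripts(matrices, cfg.min_density)
    tables: dict[str, pd.DataFrame] = {}
    for label in state.labels:
        table = pause_mod.pause_table(
            matrices[label], transcriptome, analyzed,
            cfg.start_trim, cfg.end_trim,
        )
        table.to_csv(state.outdir / f"pause_{label}.tsv", sep="\t", index=False)
        tables[label] = table
    mutant_labels = [l for l in state.labels if state.condition_map[l] == "mutant"]
    calls = pause_mod.call_pause_genes(
        {l: tables[l] for l in mutant_labels},
        cfg.z_min, cfg.pause_codon, cfg.min_replicates,
    )
    rio.write_gene_list(calls.consensus, state.outdir / "pause_genes_consensus.txt")
    gene_rows = [
        {"replicate": rep, "gene_id": g}
        for rep, genes in sorted(calls.per_replicate.items())
        for g in sorted(genes)
    ]
    pd.DataFrame(gene_rows, columns=["replicate", "gene_id"]).to_csv(
        state.outdir / "pause_genes.tsv", sep="\t", index=False
    )
    overlap = pause_mod.intersect_pause_sets(calls.per_replicate)
    overlap.pairwise.to_csv(state.outdir / "pause_overlap.tsv", sep="\t", index=False)
    counts["pause"] = {
        "transcripts_analyzed": len(analyzed),
        "calls_per_replicate": {
            rep: len(genes) for rep, genes in sorted(calls.per_replicate.items())
        },
        "consensus_genes": len(calls.consensus),
        "mean_pairwise_shared_fraction": overlap.mean_shared_fraction,
        "venn": overlap.venn,
    }
    # Pause-expression correlation against the internal DE effect sizes.
    effects = te_mod.differential_expression(
        state.rna_counts(), state.condition_map, conditions=CONDITIONS
    )
    effects.to_csv(state.outdir / "expression_effects.tsv", sep="\t", index=False)
    try:
        rho, pval, n = pause_mod.correlate_pause_with_expression(
            {l: tables[l] for l in mutant_labels}, effects
        )
        counts["pause"]["expression_correlation"] = {
            "spearman_rho": rho, "p_value": pval, "n_genes": n,
        }
    except ValueError as exc:
        counts["pause"]["expression_correlation"] = {"error": str(exc)}


def _stage_te(state: PipelineState, counts: dict) -> None:
    cfg = state.config
    transcriptome = state.transcriptome()
    filters = te_mod.GeneFilterConfig(
        histone_prefix=cfg.histone_prefix,
        top_genes=(
            rio.read_gene_list(cfg.top_genes_path) if cfg.top_genes_path else set()
        ),
    )
    libraries = {label: state.filtered_footprints(label) for label in state.labels}
    offsets = {label: state.offsets(label) for label in state.labels}
    rna = state.rna_counts()

    def run_te(libs: dict[str, pd.DataFrame], tag: str) -> pd.DataFrame:
        fp_counts = {}
        for label, lib in libs.items():
            fp_counts[label] = te_mod.footprint_gene_counts(
                lib, offsets[label], transcriptome
            )
        fp = pd.DataFrame(fp_counts)
        common = fp.index.intersection(rna.index)
        kept = te_mod.apply_gene_filters(common, filters)
        table = te_mod.TECountTable(fp.loc[kept], rna.loc[kept, list(libs)])
        result = te_mod.differential_te(
            table, state.condition_map, conditions=CONDITIONS
        )
        result.to_csv(state.outdir / f"te_results_{tag}.tsv", sep="\t")
        counts.setdefault("te", {})[tag] = {
            "genes_tested": int(result["p_value"].notna().sum()),
            "significant": int(
                (result["q_value"] <= cfg.q_threshold).fillna(False).sum()
            ),
        }
        return result

    run_te(libraries, "unfiltered")
    filtered_libs = {}
    removed = {}
    for label, lib in libraries.items():
        flib, stats = te_mod.filter_codon_asite_reads(
            lib, offsets[label], transcriptome,
            cfg.te_filter_codon, cfg.te_filter_window,
        )
        filtered_libs[label] = flib
        removed[label] = stats.n_discarded
    counts.setdefault("te", {})["codon_filtered_reads_removed"] = removed
    result_filtered = run_te(filtered_libs, "codon_filtered")
    if filters.top_genes:
        subset, n_altered = te_mod.top_gene_report(
            result_filtered, filters.top_genes, cfg.q_threshold
        )
        subset.to_csv(state.outdir / "te_top_genes.tsv", sep="\t")
        counts["te"]["top_genes"] = {
            "detected": len(subset), "altered": n_altered,
        }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "asite": _stage_asite,
    "occupancy": _stage_occupancy,
    "pause": _stage_pause,
    "te": _stage_te,
}


def run_pipeline(
    config: RunConfig, stages: tuple[str, ...] | list[str] | None = None
) -> dict[str, Any]:
    """Execute the requested stages in dependency order; returns the run report.

    With ``stages=None`` all stages run. A partial run loads its inputs from
    the intermediates a previous run serialized in ``config.outdir``.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    requested = list(STAGES) if stages is None else [s for s in STAGES if s in stages]
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    state = PipelineState(config)
    counts: dict[str, Any] = {}
    for stage in requested:
        logger.info("=== stage %s ===", stage)
        try:
            _STAGE_FUNCS[stage](state, counts)
        except Exception as exc:
            raise PipelineError(stage, exc) from exc
    report = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "stages_run": requested,
        "counts": counts,
    }
    with open(state.outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
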