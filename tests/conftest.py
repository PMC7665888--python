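import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from ribopause.model import TranscriptModel, Transcriptome
from ribopause.simulate import (
    SimulationConfig,
    draw_gene_effects,
    generate_transcriptome,
    simulate_experiment,
)


def toy_transcript(
    body_codons,
    transcript_id="tx1",
    gene_id="gene1",
    utr5=15,
    utr3=15,
    stop="TAA",
):
    """Build a transcript from explicit body codons (start/stop added)."""
    cds = "ATG" + "".join(body_codons) + stop
    seq = "A" * utr5 + cds + "C" * utr3
    return TranscriptModel(transcript_id, gene_id, seq, utr5, utr5 + len(cds))


@pytest.fixture
def toy_transcriptome():
    return Transcriptome(
        [
            toy_transcript(
                ["AAA", "AGA", "CCC", "GGG", "TTT", "AAA"], "tx1", "gene1"
            ),
            toy_transcript(
                ["CCC", "GGG", "AAA", "TTC", "GAT", "CGA", "AGA", "AAA"],
                "tx2", "gene2",
            ),
        ]
    )


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_genes=30,
        cds_length_range=(60, 120),
        reads_per_library=30_000,
        n_replicates_per_condition=2,
        seed=123,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return simulate_experiment(small_config)


@pytest.fixture(scope="session")
def medium_simulation():
    """A mid-size mutant library with its transcriptome and ground truth."""
    from ribopause.simulate import simulate_footprints

    config = SimulationConfig(
        n_genes=80, reads_per_library=120_000, pause_gene_fraction=1.0, seed=77
    )
    transcriptome = generate_transcriptome(config)
    truth = draw_gene_effects(transcriptome, config)
    footprints = simulate_footprints(transcriptome, config, truth, 1, "mutant")
    return config, transcriptome, truth, footprints


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
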