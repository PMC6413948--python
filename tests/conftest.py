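from pathlib import Path

import numpy as np
import pytest

from gatabind.annotation import GeneRecord
from gatabind.simulate import SimulationConfig, simulate_all


@pytest.fixture
def plus_gene() -> GeneRecord:
    return GeneRecord("chrI", 1000, 2000, "+", "geneA")


@pytest.fixture
def minus_gene() -> GeneRecord:
    return GeneRecord("chrI", 1000, 2000, "-", "geneB")


@pytest.fixture
def write_fasta(tmp_path):
    """Write {contig: sequence} as FASTA and return the path."""

    def _write(contigs: dict[str, str], name: str = "genome.fa") -> Path:
        path = tmp_path / name
        with open(path, "w") as fh:
            for contig, seq in contigs.items():
                fh.write(f">{contig}\n{seq}\n")
        return path

    return _write


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """One seeded 500-gene simulation shared across tests (expensive)."""
    outdir = tmp_path_factory.mktemp("sim") / "run"
    return simulate_all(SimulationConfig(seed=1), outdir), outdir


@pytest.fixture(scope="session")
def pipeline_summary(sim_bundle, tmp_path_factory):
    """Full pipeline run on the shared simulation."""
    from gatabind.pipeline import RunConfig, run_pipeline

    _objs, simdir = sim_bundle
    outdir = tmp_path_factory.mktemp("pipeline") / "out"
    config = RunConfig(
        annotation_path=str(simdir / "genes.bed"),
        genome_path=str(simdir / "genome.fa"),
        peaks_path=str(simdir / "peaks.bed"),
        counts_path=str(simdir / "counts.tsv"),
        samples_path=str(simdir / "samples.tsv"),
        tagged_track_path=str(simdir / "chip_tagged.bedgraph"),
        untagged_track_path=str(simdir / "chip_untagged.bedgraph"),
        out_dir=str(outdir),
        seed=1,
    )
    summary = run_pipeline(config)
    return summary, outdir


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
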