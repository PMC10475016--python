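import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from trascan.pipeline import PipelineConfig, run_pipeline
from trascan.simulate import SimulationTruth, default_fixture


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory) -> Path:
    """The seed-7 default fixture, generated once per session."""
    d = tmp_path_factory.mktemp("fixture7")
    default_fixture(d, seed=7)
    return d


@pytest.fixture(scope="session")
def fixture_truth(fixture_dir) -> SimulationTruth:
    return SimulationTruth.from_json(fixture_dir / "truth.json")


def pipeline_config(fixture_dir: Path, out_dir: Path, **kw) -> PipelineConfig:
    return PipelineConfig(
        tfbs_bed=str(fixture_dir / "tfbs_clusters.bed"),
        germline=str(fixture_dir / "germline.tsv"),
        diagnosis=str(fixture_dir / "diagnosis.tsv"),
        relapse=str(fixture_dir / "relapse.tsv"),
        gff=str(fixture_dir / "genes.gff3"),
        fasta=str(fixture_dir / "genome.fa"),
        gene_expression=str(fixture_dir / "gene_expression.tsv"),
        transcript_expression=str(fixture_dir / "transcript_expression.tsv"),
        out_dir=str(out_dir),
        **kw,
    )


@pytest.fixture(scope="session")
def fixture_run(fixture_dir, tmp_path_factory):
    """One full pipeline run on the fixture, shared across tests."""
    out = tmp_path_factory.mktemp("run7")
    manifest = run_pipeline(pipeline_config(fixture_dir, out))
    return out, manifest
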