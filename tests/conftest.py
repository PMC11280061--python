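import json

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from tfrn import genomic_io, pipeline, simulate


@pytest.fixture(scope="session")
def planted(tmp_path_factory):
    """Default noise-free 10-TF planted fixture, generated once per session."""
    out = tmp_path_factory.mktemp("fixture")
    spec = simulate.default_fixture(seed=11)
    paths = simulate.generate_fixture(spec, out)
    return spec, paths


@pytest.fixture(scope="session")
def planted_inputs(planted):
    """Loaded promoters, peak sets, DEG table and ground truth."""
    spec, paths = planted
    tss = genomic_io.load_tss_annotation(paths.annotation, format="tsv")
    promoters = genomic_io.extract_promoters(tss, upstream_len=spec.upstream_len)
    peaksets = genomic_io.load_peak_manifest(paths.manifest)
    degs = genomic_io.load_deg_lists(combined_path=paths.deg_csv)
    truth = json.loads(paths.ground_truth.read_text())
    return promoters, peaksets, degs, truth


@pytest.fixture(scope="session")
def planted_result(planted_inputs):
    promoters, peaksets, degs, truth = planted_inputs
    return pipeline.run_pipeline_from_objects(
        promoters, peaksets, degs, pipeline.PipelineConfig()
    )
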