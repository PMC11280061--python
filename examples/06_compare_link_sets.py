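"""Comparing the link sets of two network reconstructions.

Networks built from different peak libraries (or, as here, from DEG lists
called at different fold-change thresholds) can be compared as sets of
(regulator, target) pairs, ignoring peak evidence.
"""

import tempfile

from tfrn import genomic_io, network, pipeline, simulate

with tempfile.TemporaryDirectory() as td:
    spec = simulate.default_fixture(seed=42)
    paths = simulate.generate_fixture(spec, td)
    tss = genomic_io.load_tss_annotation(paths.annotation)
    promoters = genomic_io.extract_promoters(tss)
    peaksets = genomic_io.load_peak_manifest(paths.manifest)

    core = {"TF_DA1", "TF_DA2", "TF_UA1"}
    bound = simulate.fixture_bound_genes(spec, paths)
    strata = simulate.two_strata_for(spec, core, bound)
    fc_csv = simulate.generate_fc_strata(spec, strata, td + "/fc.csv")
    degs = genomic_io.load_deg_lists(combined_path=fc_csv)

    links = {}
    for t in (1.0, 2.0):
        res = pipeline.run_pipeline_from_objects(
            promoters, peaksets, degs.filter_by_fc(t)
        )
        links[t] = res.links

    only_a, only_b, common = network.compare_link_sets(links[1.0], links[2.0])
    print(f"links at threshold 1: {len(links[1.0])}, at threshold 2: {len(links[2.0])}")
    print(f"only at 1: {len(only_a)}, only at 2: {len(only_b)}, common: {len(common)}")
    print("common links:", sorted(common))
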