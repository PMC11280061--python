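"""Node persistence when the DEG fold-change threshold is raised.

The fixture's DEGs get |log2fc| values in two strata: the "core" TFs and
the background genes they bind in 2-4, everything else in 1-2. Re-calling
DEGs at threshold 2 should keep exactly the core TFs in the network.
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
    fc_csv = simulate.generate_fc_strata(spec, strata, td + "/degs_fc.csv")
    degs = genomic_io.load_deg_lists(combined_path=fc_csv)

    persistence = network.robustness_sweep(
        degs, [1.0, 2.0], pipeline.PipelineConfig(), promoters, peaksets
    )
    print("TF presence in the network by |log2fc| threshold:")
    print(persistence.to_string())
    robust = persistence.index[persistence[2.0]].tolist()
    print(f"\nrobust nodes (persist at threshold 2): {robust}")
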