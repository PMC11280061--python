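"""Overlaying network regulators onto a gene list and inspecting co-binding.

After reconstructing the fixture network, the downregulated DEGs are treated
as a functional gene list: which fraction is targeted by DAs and USes, and
how do regulator peaks stack within one promoter (TSS-relative, negative =
upstream)?
"""

import tempfile

from tfrn import genomic_io, overlay, pipeline, simulate

with tempfile.TemporaryDirectory() as td:
    spec = simulate.default_fixture(seed=42)
    paths = simulate.generate_fixture(spec, td)
    tss = genomic_io.load_tss_annotation(paths.annotation)
    promoters = genomic_io.extract_promoters(tss)
    peaksets = genomic_io.load_peak_manifest(paths.manifest)
    degs = genomic_io.load_deg_lists(combined_path=paths.deg_csv)
    result = pipeline.run_pipeline_from_objects(promoters, peaksets, degs)

    down_genes = sorted(degs.down)
    report = overlay.tf_targets_for_genes(
        down_genes, result.network_classes, promoters, peaksets,
        direction_filter="down", gene_list_name="downregulated DEGs",
    )
    print(f"gene list: {report.gene_list_name} ({len(down_genes)} genes)")
    for cls, frac in sorted(report.class_fractions.items()):
        print(f"  fraction targeted by {cls}: {frac:.2f}")
    top = sorted(report.regulator_target_counts.items(), key=lambda x: -x[1])[:3]
    print("  busiest regulators:", top)

    # co-binding in the promoter of the most-targeted gene
    target = max(report.regulators_by_gene, key=lambda g: len(report.regulators_by_gene[g]))
    cb = overlay.co_binding_report(target, result.network_classes, promoters, peaksets)
    print(f"\nco-binding in promoter of {target}:")
    for tf, peaks in sorted(cb.relative_peaks.items()):
        print(f"  {tf}: peaks at {peaks} (bp relative to TSS)")
    print("  overlap groups:", cb.groups)
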