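# Methods

## Model and assumptions

The package treats transcriptional reprogramming after a stimulus as the
superposition of two signed TF networks: a *repressed* (R) subnetwork of
TFs that were active before the stimulus and are encoded by downregulated
genes (DA = downregulated activator, DS = downregulated suppressor), and
an *activated* (A) subnetwork of stimulus-induced TFs (UA, US). The core
assumptions are:

1. A TF regulates a gene if it binds the gene's proximal promoter. Binding
   is taken from in-vitro peak sets (DAP-seq style), so an edge is a
   *potential* regulation: condition-specific chromatin state is not
   modeled.
2. Regulatory *direction* is inferred statistically, not mechanistically: a
   TF whose peaks are over-represented in promoters of downregulated genes
   and whose own gene is downregulated is most parsimoniously an activator
   whose withdrawal explains the downregulation (DA), and so on for the
   other three classes. TFs enriched in both directions or not
   differentially expressed cannot be signed and are excluded.
3. A regulator→target link between classified TFs is kept only when the
   pair is sign-consistent — activators may target co-directional genes,
   suppressors anti-directional ones — which admits 8 of the 16 ordered
   class pairs.

## Procedure

**Promoters.** One TSS per gene; the promoter is the `upstream_len` window
(default 1000 bp) strictly 5′ of the TSS in 0-based half-open coordinates:
`[tss − L, tss)` on `+`, `[tss + 1, tss + 1 + L)` on `−`, clipped at
chromosome boundaries (clipped-to-empty genes are excluded and reported).
The TSS base itself is not part of the promoter. For multi-isoform
annotations the representative TSS is the most upstream transcription
start (maximizing promoter coverage); a first-listed rule is selectable.

**Enrichment.** Per peak set and DEG direction, genes are binarized as
bound (≥ `min_overlap_bp` = 1 bp of peak overlap; multiplicity ignored)
and the one-sided Fisher exact p is the upper hypergeometric tail,
evaluated by `scipy.stats.hypergeom.sf`. The background universe defaults
to all annotated genes with a mappable promoter; an explicit universe can
be supplied. BH adjustment (`statsmodels`, `fdr_bh`) pools all tests of a
run — every peak set of the selected library × both directions — which is
the most conservative interpretable pool; per-direction pooling is a flag.
Peak libraries (e.g. native vs PCR-amplified genomic DNA, "col"/"colamp")
are processed in separate runs and mixing labels in one run is an error.
A TF with several peak sets is enriched in a direction if *any* of its
sets is; aggregation precedes classification, so conflicting sets route
the TF to the unsigned DR/UR/NTR path.

**Classification and network.** The class function is total over the
reachable 3 × 3 grid (enrichment pattern × own-gene direction). Links are
unweighted; multiple supporting peaks collapse onto one edge carrying the
evidence list. Self-links arise only for DA–DA and UA–UA (the only
meaningful same-class pairs). Tiers are assigned on the DA–DA edge subset:
tier 1 = no incoming core arc (self-loops excluded from in-degree), tier 2
= nodes with ≥ 1 incoming arc from tier 1 ("triggered by" read
inclusively; a strict all-parents-in-tier-1 variant is available via
`tier2_rule`), tier 3 = the rest. A purely cyclic core has no tier-1 seed;
its nodes are all assigned tier 3 with a warning rather than failing.
Every built graph passes an audit (sign/class invariant, pair rule,
subnetwork labels, tier partition) before it is returned.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `upstream_len` | 1000 bp | promoter window 5′ of the TSS |
| `min_overlap_bp` | 1 | peak–promoter overlap to count a gene as bound |
| `fdr_alpha` | 0.001 | BH FDR level for the enrichment flag |
| `bh_pool` | run | BH pool: whole run or per DEG direction |
| `tier2_rule` | any-parent | inclusive vs strict tier-2 membership |
| `tss_rule` | most-upstream | representative TSS for multi-isoform genes |

The 1000 bp window and FDR 0.001 are the protocol defaults this package
standardizes on; both are exposed because promoter compactness and peak-set
size vary across genomes.

## Synthetic fixtures

The simulator emulates the three input kinds from a planted ground truth:
genes on one chromosome with promoters spaced ≥ 3 kb apart so no peak can
ambiguously support two genes; each planted edge realized as a peak inside
the target's promoter; each planted class realized by making the TF's gene
a DEG of the right direction and salting bound DEG promoters until the
exact hypergeometric tail satisfies `p ≤ α / (m · s)` with `m` the number
of tests and `s` a safety factor (50) — a sufficient condition for the BH
q-value to clear α at any rank. The generator then re-verifies every
(TF, direction) test with the package's own `fisher_pvalue` and refuses to
write files if a planted test would fail or a decoy would pass; infeasible
demands (too few background DEGs) raise an error naming the bottleneck.
Noise is available as intergenic peaks (placed so they cannot touch a
promoter) and as spurious wrong-direction promoter hits whose counts are
verified to keep `p > α`. Default scale: 1 chromosome, 200 genes, 10 TFs
covering all seven classes, 10 edges spanning all four subnetwork edge
kinds and a three-tier core — generation plus full reconstruction runs in
about a second, and all test-suite and acceptance problem sizes (200-gene
universe, 46 376 oracle tables, 1000 BH vectors) were chosen to keep the
whole suite in the tens of seconds.

What the fixtures do **not** emulate: read-level signal, peak-width and
score distributions, promoter-proximal peak clustering, overlapping or
nested genes, unbalanced chromosome structure, and identifier mismatches
between expression platform and annotation. Passing recovery tests
therefore demonstrates the correctness of the inference logic under its
own assumptions, not the biological accuracy of networks inferred from
real peak collections, where FDR calibration and promoter-definition
sensitivity dominate.

The fold-change strata generator assigns |log2fc| uniformly within a
stratum's range (sign from the direction), with strata required to
partition the DEGs; the bundled two-strata design gives a chosen "core"
TF set and the background genes they bind the high range, so that raising
the DEG-calling threshold to the high range's floor removes exactly the
peripheral TFs — their coding genes stop being DEGs, which routes them to
NTR and out of the network irrespective of residual enrichment.

## Numerical and design notes

- Coordinates are BED-native (0-based half-open) throughout; GFF3 is
  converted on read. The minus-strand promoter convention (`[tss+1,
  tss+1+L)`) is documented prominently because annotation sources are
  silent about it.
- Fisher p-values use the survival function directly (no two-sided
  mid-p); degenerate margins give p = 1 by the tail definition.
- BH q-values come back in input order with monotonicity enforced by the
  step-up cumulative minimum; an empty input returns an empty output.
- Duplicate peaks are deduplicated on load: overlap is binarized
  downstream, so duplicates are pure noise.
- Gene universe = all annotated genes with a mappable promoter, not the
  DEG union; this makes the 2×2 margins independent of the DEG calling.
- TSS-relative co-binding coordinates are negative upstream on both
  strands (minus-strand promoters are mirrored), so reports from opposite
  strands are directly comparable.
- Determinism: the pipeline contains no randomness; the simulator is fully
  determined by its spec + seed (byte-identical outputs), and different
  seeds change coordinates but not the recovered topology.

## Known limitations

- Enrichment counts genes, not peaks; a TF with many peaks in few
  promoters is indistinguishable from one peak per promoter.
- The tier hierarchy is defined only for the DA–DA core, following the
  R-subnetwork-centric view of the cascade; no tiers are assigned in the
  A-subnetwork.
- `compare_link_sets` ignores signs and evidence, comparing only ordered
  (regulator, target) pairs.
- GO/functional enrichment of gene lists is consumed as precomputed input
  (the overlay takes arbitrary gene lists); it is never computed here.
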