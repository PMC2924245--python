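"""Locate CCGG sites, enumerate size-selected candidate fragments, and
report which sites the assay can interrogate.

A MethylSeq experiment only carries information about a CCGG site if the
site lies on some HpaII-HpaII fragment inside the size-selection window;
the span report summarizes how much sequence those fragments cover.
"""

from metmap import (
    DEFAULT_PARAMS,
    compute_span,
    enumerate_fragments,
    scan_cg_sites,
    simulate_genome,
    sites_in_scope,
)

params = DEFAULT_PARAMS
truth = simulate_genome(200_000, params, seed=1)
sites = scan_cg_sites(truth.sequence, truth.chrom)
hpaii = [s for s in sites if s.is_hpaii]
fragments = enumerate_fragments(hpaii, params.l_min, params.l_max)
scope = sites_in_scope(hpaii, fragments)
report = compute_span(
    hpaii, params.l_min, params.l_max, "methylseq", genome_length=200_000
)

print(f"CG sites: {len(sites)}, of which CCGG (HpaII): {len(hpaii)}")
print(f"candidate fragments in [{params.l_min}, {params.l_max}] bp: {len(fragments)}")
print(f"CCGG sites in experimental scope: {len(scope)} "
      f"({len(scope) / len(hpaii):.0%} of CCGGs)")
print(f"genome span: {report.genome_bp_spanned} bp "
      f"({report.fraction_of_genome:.1%} of the sequence)")
print()
print("A site out of scope has no size-passing fragment touching it, so no")
print("read depth at any fragment end can speak to its methylation state.")
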