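"""Load the dystonia gene panel and classify a few annotated variants.

The panel carries each gene's inheritance mode; variant classification
assigns the consequence class (LoF / damaging missense), the combined
gnomAD-EAS frequency, and the burden-subgroup cells the variant enters.
"""

from dytburden import load_panel, panel_summary
from dytburden.classify import classify, subgroup_membership
from dytburden.io import ExonicFunction, VariantAnnotation

panel = load_panel()
print(f"panel '{panel.name}': {len(panel)} genes, by inheritance {panel_summary(panel)}")
print(f"recessive-model genes: {len(panel.recessive_genes())} "
      f"(includes the {panel_summary(panel)['BOTH']} dual-inheritance genes)\n")

examples = [
    # a moderately rare damaging missense (ReVe 0.728, gnomAD-EAS 0.21%/0.12%)
    VariantAnnotation("chr2:238283448:G:A", "COL6A3", ExonicFunction.MISSENSE,
                      maf_exome_eas=0.0021, maf_genome_eas=0.0012, reve=0.728),
    # a gnomAD-absent stop gain
    VariantAnnotation("chr11:26621198:G:A", "ANO3", ExonicFunction.STOPGAIN,
                      cadd=41.0),
    # a splice-region change 3 bp from the junction: NOT loss-of-function
    VariantAnnotation("chr1:43391000:C:T", "SLC2A1", ExonicFunction.SPLICING,
                      splice_offset=3, maf_exome_eas=0.0004),
]

for ann in examples:
    vc = classify(ann)
    cells = sorted(f"{cls}@{thr}" for cls, thr in subgroup_membership(vc))
    print(f"{ann.variant_id} ({ann.gene}, {ann.exonic_function.value}):")
    print(f"  effective MAF {vc.effective_maf:g}, LoF={vc.is_lof}, "
          f"Dmis={vc.is_dmis}, deleterious={vc.is_deleterious}")
    print(f"  burden cells: {cells or 'none'}")

# The first variant is deleterious and rare at 1% but not at 0.1%, so it
# enters only the 0.01-threshold cells; the stop gain (frequency 0, treated
# as novel) enters every LoF/deleterious cell; the +3 bp splice change is
# outside the two-base-pair junction rule and is not deleterious.
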