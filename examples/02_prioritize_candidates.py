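"""Recessive and dominant candidate prioritization on the worked-example
fixtures, with control screening and ACMG classes.

The fixtures encode the published candidate tables (positions, frequencies,
scores, carriers) plus decoy variants that each fail exactly one filter, so
the printed output should show exactly the published findings surviving.
"""

from dytburden import load_panel
from dytburden.prioritize import (
    ad_candidates,
    ar_candidates,
    classify_findings,
    control_screen,
)
from dytburden.simulate import make_paper_fixture_data

panel = load_panel()

for which, finder, label in [
    ("table1_ar", ar_candidates, "recessive (homozygous / compound-het)"),
    ("table2_ad", ad_candidates, "dominant (heterozygous, MAF < 0.001)"),
]:
    cohort = make_paper_fixture_data(which)
    findings = finder(cohort, panel)
    control_screen(findings, cohort)
    kept = [f for f in findings if not f.screened_out]
    classify_findings(kept, cohort)
    print(f"\n{label}: {len(findings)} candidate finding(s), {len(kept)} retained "
          f"after control screening")
    for f in kept:
        changes = "+".join(a.protein_change or a.variant_id for a in f.annotations)
        print(f"  {f.sample_id:10s} {f.gene:7s} {f.model.value:10s} {changes:20s} "
              f"ACMG={f.acmg.value} support={f.predictor_support}")

# Five recessive carriers (two homozygotes, three compound-heterozygous
# pairs, all uncertain significance) and five dominant carriers of four
# variants (one pathogenic stop gain, three likely-pathogenic novel missense
# changes) should remain; every DEC-* decoy sample is filtered or screened.
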