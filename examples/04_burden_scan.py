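"""Simulate a spiked case-control cohort and run the SKAT-O burden scan.

One gene (TH) receives a five-fold carrier log-odds effect; the scan tests
every gene x variant-subgroup x MAF-threshold cell with a covariate-adjusted
SKAT-O and flags suggestive (p < 0.05) and Bonferroni-significant cells.
"""

import math

from dytburden.burden import run_burden_scan
from dytburden.panel import GenePanel, load_panel
from dytburden.simulate import SimConfig, simulate_cohort_data

panel = GenePanel(genes=list(load_panel())[:10], name="sim10")
cfg = SimConfig(seed=1003, effect_spec={"TH": math.log(5.0)})
cohort = simulate_cohort_data(cfg)
print(f"simulated {cohort.n_samples} samples, {cohort.n_variants} variants "
      f"in {len(panel)} genes; spiked gene: TH (carrier odds ratio 5)")

results = run_burden_scan(cohort, panel)
tested = sorted((r for r in results if r.tested), key=lambda r: r.p_value)
print(f"{len(results)} cells, {len(tested)} tested; top cells:")
for r in tested[:5]:
    flag = "significant" if r.significant else ("suggestive" if r.suggestive else "")
    print(f"  {r.gene:8s} {r.variant_subgroup:11s} MAF<{r.maf_threshold:<5g} "
          f"variants={r.n_variants:3d} carriers {r.case_carriers}/{r.control_carriers} "
          f"p={r.p_value:.2e} rho={r.rho_opt} {flag}")

# The spiked gene should dominate the top of the table: its deleterious and
# Dmis cells carry the excess case carriers, while null genes hover around
# the uniform p-value background.
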