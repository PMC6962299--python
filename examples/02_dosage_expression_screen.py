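"""Stages 1-2: find genes whose expression shifts with their copy-number
class (Wilcoxon CNAS vs CNNS, BH FDR, fold change)."""

from pdsgscreen import default_paper_like_config, screen_dosage_de, \
    simulate_cohort

cohort = simulate_cohort(default_paper_like_config(seed=0))
results = screen_dosage_de(cohort, x=0.3, min_alt=10,
                           p_max=0.01, fdr_max=0.1, fc_min=1.2)

print(f"{len(results)} gene/side tests with >=10 altered samples")
for r in results:
    if r.concordant:
        print(f"  {r.gene} ({r.side}): p={r.p:.2e} fdr={r.fdr:.2e} "
              f"FC={r.fc:.2f} ({r.n_alt} vs {r.n_non} samples)")
# Concordant genes are up-regulated where amplified (FC > 1.2, p < 0.01,
# FDR < 0.1) - the expression footprint a dosage-driven gene must show.
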