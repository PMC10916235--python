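"""Do the eQTL and GWAS association signals share one causal variant?

Builds two 50-SNP regions: one where the same variant drives expression and
disease (the H4 world) and one where the two signals sit on distinct
variants in different LD blocks (the H3 world), then compares the posterior
probabilities returned by the approximate-Bayes-factor colocalization.
"""

from targetmr import synth
from targetmr.coloc import RegionDataset, coloc_posteriors


def run(scenario: str, seed: int):
    region = synth.simulate_region(50, block_size=10, rho=0.8, seed=seed)
    kwargs = {}
    if scenario == "causal_distinct":
        # outcome signal in block 4, expression signal in block 0
        kwargs = {"outcome_causal_snp_ids": ["rs45"],
                  "outcome_betas": {"rs45": 0.25 * 0.35}}
    truth = synth.SimulationTruth(
        gene="DEMO", causal_snp_ids=["rs5"], eqtl_betas={"rs5": 0.35},
        theta=0.25, scenario=scenario, seed=seed, **kwargs)
    eqtl = synth.simulate_eqtl_summary(region, truth, seed=seed + 1)
    gwas = synth.simulate_gwas_summary(region, truth, seed=seed + 2)
    return coloc_posteriors(
        RegionDataset.from_records(eqtl, "quantitative"),
        RegionDataset.from_records(gwas, "case_control"), gene="DEMO")


for scenario in ("causal_shared", "causal_distinct"):
    res = run(scenario, seed=11)
    print(f"{scenario:16s} PP3 = {res.pp3:.3f}  PP4 = {res.pp4:.3f}  "
          f"colocalized (PP4 > 0.75): {res.colocalized}")
print("PP4 is the posterior that ONE variant drives both traits; a shared "
      "causal variant should push it above 0.75, while distinct variants "
      "push PP3 up instead.")
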