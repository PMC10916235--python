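"""On-target safety screen: one gene's instrument across many traits.

Re-tests a prioritized gene's instrument against a 200-trait synthetic
phenome panel in which exactly one trait truly responds to the gene's
expression.  A clean screen flags the responding trait and nothing else.
"""

from targetmr.phewas import phenome_scan, simulate_phenome_panel
from targetmr.types import SummaryStatRecord

# a strong single instrument for the gene (F ~ 1200)
instrument = SummaryStatRecord(
    snp_id="rs1", chrom="1", pos=1_000_000, effect_allele="A",
    other_allele="G", eaf=0.3, beta=0.35, se=0.01, pval=1e-100,
    n=31_684, gene="DEMO1", fdr=1e-90)

panel = simulate_phenome_panel([instrument], n_traits=200,
                               implanted={17: 0.3}, seed=9)
rows = phenome_scan("DEMO1", [instrument], panel)

flagged = [r for r in rows if r.testable and r.result.qval < 0.05]
print(f"traits tested: {sum(r.testable for r in rows)}; "
      f"flagged at q < 0.05: {len(flagged)}")
for r in flagged:
    print(f"  {r.trait_id}: beta = {r.result.beta:.3f}, "
          f"q = {r.result.qval:.2e}  (implanted effect was 0.3 on trait "
          f"{panel[17].trait_id})")
print("Every flagged trait beyond the implanted one would be a potential "
      "on-target side effect of drugging this gene.")
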