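"""Three-level inclusion triage of drug candidates for validated targets.

Loads the packaged five-drug candidate table (two approved TBK1 inhibitors,
two clinical-phase TNFSF12 antibodies, one broad-spectrum GPX3 cofactor),
applies the Level I-III gates, and checks each surviving drug's action
against the genetically inferred risk direction of its target.
"""

import math

from targetmr import repurpose as rep
from targetmr.synth import table1_replica
from targetmr.types import ColocResult, MrResult


def _target(gene, beta):
    se = 0.045
    mr = MrResult(gene=gene, method="wald_ratio", beta=beta, se=se,
                  pval=1e-8, qval=1e-6, or_point=math.exp(beta),
                  ci_low=math.exp(beta - 1.96 * se),
                  ci_high=math.exp(beta + 1.96 * se), nsnp=1)
    coloc = ColocResult(gene=gene, pp0=0.01, pp1=0.01, pp2=0.01, pp3=0.05,
                        pp4=0.92, n_snps=50, colocalized=True)
    return mr, coloc


# risk-increasing expression for all three genes (blood-tissue convention)
mrs, colocs = zip(*[_target(g, 0.26) for g in ("TBK1", "TNFSF12", "GPX3")])
targets = rep.prioritize_targets(list(mrs), list(colocs))
rep.attach_candidates(targets, table1_replica())

print("gene      drug          action     level  concordance")
for t in targets:
    for c in t.candidates:
        conc = rep.direction_concordance(t, c)
        print(f"{t.gene:9s} {c.drug_name:13s} {c.action_type:10s} "
              f"{c.level_passed}      {conc}")
print("\nLevel 3 = specific + safe + approved: only such drugs are "
      "proposed for repurposing trials; a concordant action opposes the "
      "risk direction (inhibit a risk-increasing target).")
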