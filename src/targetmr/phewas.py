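"""Phenome-wide MR safety screen.

One prioritized gene's instrument set is re-tested against a panel of
non-disease outcomes (emulating a several-hundred-trait hospital phenome
panel) using exactly the same estimators as the main analysis: Wald ratio
for one instrument, IVW otherwise.  BH-FDR is applied once across the whole
panel; traits whose GWAS lacks the instrument SNP(s) are reported as
not-testable rather than silently skipped, and are excluded from the BH
family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from . import mr as mr_core
from .errors import UsageError
from .harmonize import harmonize_many
from .synth import effective_sample_size
from .types import Instrument, MrResult, SummaryStatRecord


@dataclass
class PhenomeOutcome:
    """One panel trait: identifier, label, and GWAS records restricted to
    the gene's instrument SNPs."""

    trait_id: str
    trait_label: str
    records: list = field(default_factory=list)


@dataclass
class PhenomeScanRow:
    trait_id: str
    trait_label: str
    testable: bool
    result: Optional[MrResult] = None


def phenome_scan(gene: str, exposures: Sequence[SummaryStatRecord],
                 panel: Sequence[PhenomeOutcome],
                 ivw_model: str = "fixed", seed: int = 0,
                 palindrome_eaf_limit: float = 0.42) -> list[PhenomeScanRow]:
    """Per-trait MR of one gene's instruments across the phenome panel.

    Estimates are produced by the same mr_core routing used in the main
    analysis; q-values are BH over the testable traits only.
    """
    if not panel:
        raise UsageError("phenome panel is empty")
    ids = [t.trait_id for t in panel]
    if len(set(ids)) != len(ids):
        raise UsageError("trait_id values must be unique within a panel")

    rows: list[PhenomeScanRow] = []
    for trait in panel:
        by_snp = {r.snp_id: r for r in trait.records}
        ivs = harmonize_many(exposures, by_snp,
                             palindrome_eaf_limit=palindrome_eaf_limit)
        result = mr_core.run_gene_mr(gene, ivs, ivw_model=ivw_model, seed=seed)
        rows.append(PhenomeScanRow(trait_id=trait.trait_id,
                                   trait_label=trait.trait_label,
                                   testable=result is not None,
                                   result=result))
    testable = [r for r in rows if r.testable]
    mr_core.finalize_fdr([r.result for r in testable])
    return rows


def simulate_phenome_panel(exposures: Sequence[SummaryStatRecord],
                           n_traits: int = 200,
                           implanted: Optional[dict] = None,
                           n_cases: int = 5_000, n_controls: int = 400_000,
                           missing_fraction: float = 0.0,
                           seed: int = 0) -> list[PhenomeOutcome]:
    """Synthetic phenome panel over the instrument SNPs.

    Every trait is null unless listed in ``implanted`` (trait index ->
    causal effect theta on the log-odds scale).  ``missing_fraction`` of
    traits omit the instrument SNPs entirely (not-testable).  Sample sizes
    default to a typical biobank binary trait.
    """
    implanted = implanted or {}
    rng = np.random.default_rng(seed)
    n_eff = effective_sample_size(n_cases, n_controls)
    panel = []
    for t in range(n_traits):
        trait_id = f"T{t + 1:04d}"
        if missing_fraction > 0 and rng.random() < missing_fraction:
            panel.append(PhenomeOutcome(trait_id, f"trait {t + 1}", []))
            continue
        theta = implanted.get(t, 0.0)
        records = []
        for exp in exposures:
            eaf = exp.eaf if exp.eaf is not None else 0.25
            se = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n_eff)
            beta = theta * exp.beta + se * rng.standard_normal()
            pval = float(np.clip(2.0 * stats.norm.sf(abs(beta / se)), 1e-300, 1.0))
            records.append(SummaryStatRecord(
                snp_id=exp.snp_id, chrom=exp.chrom, pos=exp.pos,
                effect_allele=exp.effect_allele, other_allele=exp.other_allele,
                eaf=eaf, beta=float(beta), se=float(se), pval=pval,
                n=n_cases + n_controls))
        panel.append(PhenomeOutcome(trait_id, f"trait {t + 1}", records))
    return panel
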