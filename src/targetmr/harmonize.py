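"""Allele harmonization of exposure and outcome summary statistics.

Both records must describe the same SNP; the outcome effect is re-expressed
relative to the exposure's effect allele.  Four alignments are possible for
non-palindromic SNPs (identity, allele swap, strand flip, both); palindromic
SNPs (A/T, C/G) cannot be disambiguated by allele labels, so they are kept
only when the allele frequencies on both sides agree on which allele is the
minor one and sit clearly away from 0.5.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

from .errors import UsageError
from .types import COMPLEMENT, Instrument, SummaryStatRecord

PALINDROME_EAF_LIMIT = 0.42
FREQUENCY_TOLERANCE = 0.2


def _dropped(exposure: SummaryStatRecord, outcome: SummaryStatRecord,
             reason: str) -> Instrument:
    return Instrument(gene=exposure.gene or "", snp_id=exposure.snp_id,
                      beta_exp=exposure.beta, se_exp=exposure.se,
                      beta_out=outcome.beta, se_out=outcome.se,
                      eaf_exp=exposure.eaf, eaf_out=outcome.eaf,
                      action="dropped", drop_reason=reason,
                      n_exp=exposure.n, n_out=outcome.n)


def harmonize(exposure: SummaryStatRecord, outcome: SummaryStatRecord,
              palindrome_eaf_limit: float = PALINDROME_EAF_LIMIT,
              frequency_tolerance: float = FREQUENCY_TOLERANCE) -> Instrument:
    """Align one outcome record to the exposure's effect-allele convention.

    Returns an :class:`Instrument` whose ``action`` records the alignment
    applied (``none``, ``swap``, ``strand_flip``, ``swap_and_flip``) or
    ``dropped`` with a reason (``palindromic-ambiguous``,
    ``palindromic-no-frequency``, ``allele-mismatch``,
    ``frequency-discordant``).
    """
    if exposure.snp_id != outcome.snp_id:
        raise UsageError(
            f"snp_id mismatch: {exposure.snp_id} vs {outcome.snp_id}")

    e_ea, e_oa = exposure.effect_allele, exposure.other_allele
    o_ea, o_oa = outcome.effect_allele, outcome.other_allele

    beta_out, eaf_out = outcome.beta, outcome.eaf

    if exposure.is_palindromic():
        # Labels cannot distinguish strand; only match/swap are observable.
        if (o_ea, o_oa) == (e_ea, e_oa):
            action = "none"
        elif (o_ea, o_oa) == (e_oa, e_ea):
            action = "swap"
            beta_out = -beta_out
            eaf_out = None if eaf_out is None else 1.0 - eaf_out
        else:
            return _dropped(exposure, outcome, "allele-mismatch")
        if eaf_out is None:
            return _dropped(exposure, outcome, "palindromic-no-frequency")
        eaf_exp = exposure.eaf
        if eaf_exp is None:
            return _dropped(exposure, outcome, "palindromic-no-frequency")
        lo, hi = palindrome_eaf_limit, 1.0 - palindrome_eaf_limit
        ambiguous = (lo <= eaf_exp <= hi) or (lo <= eaf_out <= hi)
        same_side = (eaf_exp - 0.5) * (eaf_out - 0.5) > 0
        if ambiguous or not same_side:
            return _dropped(exposure, outcome, "palindromic-ambiguous")
    else:
        if (o_ea, o_oa) == (e_ea, e_oa):
            action = "none"
        elif (o_ea, o_oa) == (e_oa, e_ea):
            action = "swap"
        elif (COMPLEMENT[o_ea], COMPLEMENT[o_oa]) == (e_ea, e_oa):
            action = "strand_flip"
        elif (COMPLEMENT[o_ea], COMPLEMENT[o_oa]) == (e_oa, e_ea):
            action = "swap_and_flip"
        else:
            return _dropped(exposure, outcome, "allele-mismatch")
        if action in ("swap", "swap_and_flip"):
            beta_out = -beta_out
            eaf_out = None if eaf_out is None else 1.0 - eaf_out
        if (exposure.eaf is not None and eaf_out is not None
                and abs(exposure.eaf - eaf_out) > frequency_tolerance):
            return _dropped(exposure, outcome, "frequency-discordant")

    return Instrument(gene=exposure.gene or "", snp_id=exposure.snp_id,
                      beta_exp=exposure.beta, se_exp=exposure.se,
                      beta_out=beta_out, se_out=outcome.se,
                      eaf_exp=exposure.eaf, eaf_out=eaf_out,
                      action=action, drop_reason=None,
                      n_exp=exposure.n, n_out=outcome.n)


def harmonize_many(exposures: Sequence[SummaryStatRecord],
                   outcome_by_snp: dict,
                   palindrome_eaf_limit: float = PALINDROME_EAF_LIMIT,
                   frequency_tolerance: float = FREQUENCY_TOLERANCE
                   ) -> list[Instrument]:
    """Harmonize a list of exposure records against an outcome lookup.

    Exposure SNPs absent from the outcome GWAS are dropped with reason
    ``missing-from-outcome`` (no proxy substitution).
    """
    out = []
    for exp in exposures:
        rec = outcome_by_snp.get(exp.snp_id)
        if rec is None:
            out.append(Instrument(
                gene=exp.gene or "", snp_id=exp.snp_id, beta_exp=exp.beta,
                se_exp=exp.se, beta_out=0.0, se_out=1.0, eaf_exp=exp.eaf,
                eaf_out=None, action="dropped",
                drop_reason="missing-from-outcome", n_exp=exp.n, n_out=None))
        else:
            out.append(harmonize(exp, rec, palindrome_eaf_limit,
                                 frequency_tolerance))
    return out


def harmonization_report(instruments: Sequence[Instrument], path) -> None:
    """Audit ledger: one row per input SNP with the action and drop reason."""
    cols = ["gene", "snp_id", "beta_exp", "se_exp", "beta_out", "se_out",
            "eaf_exp", "eaf_out", "action", "drop_reason"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for iv in instruments:
            row = dataclasses.asdict(iv)
            fh.write("\t".join(
                "NA" if row[c] is None else
                (f"{row[c]:.6g}" if isinstance(row[c], float) else str(row[c]))
                for c in cols) + "\n")


def swap_alleles_and_negate(record: SummaryStatRecord) -> SummaryStatRecord:
    """Re-express a record with effect/other alleles exchanged (test helper
    for the involution property; also used by the simulator)."""
    return dataclasses.replace(
        record, effect_allele=record.other_allele,
        other_allele=record.effect_allele, beta=-record.beta,
        eaf=None if record.eaf is None else 1.0 - record.eaf)
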