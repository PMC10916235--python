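"""cis-eQTL instrument selection per druggable gene.

The funnel mirrors the study design: keep only genes on the druggable-genome
panel, restrict each gene's eQTLs to the +/-100 kb TSS window with
FDR < 0.05 (window inclusive, FDR strict), remove confounder-associated
SNPs from the blocklist, then greedily LD-clump at r^2 < 0.001 so retained
instruments are approximately independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import AnnotationError, CoverageError, ParameterError
from .types import GeneAnnotation, LdMatrix, SummaryStatRecord

WINDOW_BP_DEFAULT = 100_000
FDR_THRESHOLD_DEFAULT = 0.05
CLUMP_R2_DEFAULT = 0.001


@dataclass
class InstrumentCandidate:
    """An eQTL record surviving the per-gene filters, with its distance to
    the TSS and instrument strength F = (beta/se)^2."""

    gene: str
    record: SummaryStatRecord
    distance_to_tss: int
    f_statistic: float

    @property
    def snp_id(self) -> str:
        return self.record.snp_id

    @property
    def pval(self) -> float:
        return self.record.pval


def overlap_druggable(eqtl_records: Sequence[SummaryStatRecord],
                      gene_panel: Sequence[GeneAnnotation]
                      ) -> dict[str, list[SummaryStatRecord]]:
    """Keep only eQTL records whose gene is on the panel with a non-null
    druggability tier.  Returns a gene -> records map."""
    druggable = {g.symbol for g in gene_panel if g.druggable_tier is not None}
    out: dict[str, list[SummaryStatRecord]] = {}
    for rec in eqtl_records:
        if rec.gene in druggable:
            out.setdefault(rec.gene, []).append(rec)
    return out


def select_cis_window(records: Sequence[SummaryStatRecord],
                      gene: GeneAnnotation,
                      window_bp: int = WINDOW_BP_DEFAULT,
                      fdr_threshold: float = FDR_THRESHOLD_DEFAULT
                      ) -> list[InstrumentCandidate]:
    """Window and FDR filter: kept iff |pos - tss| <= window_bp (inclusive)
    and fdr < fdr_threshold (strict)."""
    if gene.tss is None:
        raise AnnotationError(f"{gene.symbol}: missing TSS annotation")
    out = []
    for rec in records:
        if rec.gene is not None and rec.gene != gene.symbol:
            continue
        if rec.fdr is None:
            raise AnnotationError(f"{rec.snp_id}: eQTL record lacks an FDR value")
        dist = rec.pos - gene.tss
        if abs(dist) <= window_bp and rec.fdr < fdr_threshold:
            out.append(InstrumentCandidate(
                gene=gene.symbol, record=rec, distance_to_tss=dist,
                f_statistic=(rec.beta / rec.se) ** 2))
    return out


def apply_blocklist(candidates: Sequence[InstrumentCandidate],
                    blocklist: set[str]
                    ) -> tuple[list[InstrumentCandidate], list[dict]]:
    """Remove confounder-associated SNPs.  Returns (kept, removed) where each
    removed entry records the SNP and the reason."""
    kept, removed = [], []
    for cand in candidates:
        if cand.snp_id in blocklist:
            removed.append({"gene": cand.gene, "snp_id": cand.snp_id,
                            "reason": "confounder-associated"})
        else:
            kept.append(cand)
    return kept, removed


def _sort_key(cand: InstrumentCandidate):
    # p ascending; ties broken by larger F, then lexicographic snp_id,
    # so clumping output is invariant to input order.
    return (cand.pval, -cand.f_statistic, cand.snp_id)


def clump(candidates: Sequence[InstrumentCandidate], ld: LdMatrix,
          r2_threshold: float = CLUMP_R2_DEFAULT) -> list[InstrumentCandidate]:
    """Greedy LD clumping: repeatedly keep the most significant remaining
    SNP and discard all others with r^2 >= threshold to it."""
    if not (0 < r2_threshold <= 1):
        raise ParameterError("r2_threshold must be in (0, 1]")
    missing = [c.snp_id for c in candidates if c.snp_id not in ld]
    if missing:
        raise CoverageError(
            f"SNP(s) absent from the LD panel: {', '.join(sorted(missing))}")
    remaining = sorted(candidates, key=_sort_key)
    kept: list[InstrumentCandidate] = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [c for c in remaining
                     if ld.r2(best.snp_id, c.snp_id) < r2_threshold]
    return kept


def select_instruments(records: Sequence[SummaryStatRecord],
                       gene: GeneAnnotation, ld: LdMatrix,
                       blocklist: Optional[set[str]] = None,
                       window_bp: int = WINDOW_BP_DEFAULT,
                       fdr_threshold: float = FDR_THRESHOLD_DEFAULT,
                       r2_threshold: float = CLUMP_R2_DEFAULT,
                       f_min: Optional[float] = None
                       ) -> list[InstrumentCandidate]:
    """Full per-gene funnel: window/FDR filter, blocklist, optional F filter,
    LD clumping.  ``f_min`` (e.g. 10) enforces a weak-instrument cutoff;
    by default F is reported but not filtered on."""
    cands = select_cis_window(records, gene, window_bp, fdr_threshold)
    if blocklist:
        cands, _ = apply_blocklist(cands, blocklist)
    if f_min is not None:
        cands = [c for c in cands if c.f_statistic >= f_min]
    if not cands:
        return []
    return clump(cands, ld, r2_threshold)
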