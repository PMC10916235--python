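"""Shared domain types.

These dataclasses are the currency passed between pipeline stages: one
SNP-trait association (:class:`SummaryStatRecord`), a harmonized
exposure/outcome pair (:class:`Instrument`), per-gene causal estimates
(:class:`MrResult`), colocalization posteriors (:class:`ColocResult`) and
gene-drug rows (:class:`DrugCandidate`).  Validation lives in
``__post_init__`` so an invalid object cannot be constructed silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import FormatError, ValidationError

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

MR_METHODS = ("wald_ratio", "ivw", "mr_egger", "weighted_median")
ACTION_TYPES = ("inhibitor", "antagonist", "antibody", "agonist", "activator",
                "cofactor", "other")
MAX_PHASES = ("1", "2", "3", "approved")


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass
class SummaryStatRecord:
    """One SNP's association with one trait.

    ``beta`` is on the log-odds scale for binary traits and in SD units of
    expression for eQTL records.  eQTL records additionally carry ``gene``
    and a per-record ``fdr``.  ``eaf`` may be ``None`` on GWAS records
    (harmonization then drops palindromic SNPs conservatively).
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: Optional[float]
    beta: float
    se: float
    pval: float
    n: int
    gene: Optional[str] = None
    fdr: Optional[float] = None

    def __post_init__(self) -> None:
        self.effect_allele = str(self.effect_allele).upper()
        self.other_allele = str(self.other_allele).upper()
        _check(self.effect_allele in VALID_ALLELES,
               f"{self.snp_id}: effect_allele {self.effect_allele!r} is not a single ACGT base")
        _check(self.other_allele in VALID_ALLELES,
               f"{self.snp_id}: other_allele {self.other_allele!r} is not a single ACGT base")
        _check(self.effect_allele != self.other_allele,
               f"{self.snp_id}: effect and other allele are identical")
        _check(self.pos >= 1, f"{self.snp_id}: pos must be >= 1")
        _check(self.se > 0, f"{self.snp_id}: se must be > 0")
        if self.eaf is not None and not (isinstance(self.eaf, float) and math.isnan(self.eaf)):
            _check(0.0 <= self.eaf <= 1.0, f"{self.snp_id}: eaf outside [0,1]")
        else:
            self.eaf = None
        _check(0.0 < self.pval <= 1.0, f"{self.snp_id}: pval outside (0,1]")
        _check(self.n >= 1, f"{self.snp_id}: n must be >= 1")
        if self.fdr is not None:
            _check(0.0 <= self.fdr <= 1.0, f"{self.snp_id}: fdr outside [0,1]")

    @property
    def z(self) -> float:
        return self.beta / self.se

    def is_palindromic(self) -> bool:
        return COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass
class GeneAnnotation:
    """Gene symbol, TSS (1-based, GRCh37 convention) and druggability tier.

    ``druggable_tier`` follows the druggable-genome classification:
    1 = targets of approved or clinical-phase drugs, 2 = proteins similar to
    drug targets or with drug-like ligands, 3 = extracellular proteins and
    members of key drug-target families; ``None`` marks a non-druggable gene.
    """

    symbol: str
    chrom: str
    tss: int
    druggable_tier: Optional[int] = None

    def __post_init__(self) -> None:
        _check(self.tss >= 1, f"{self.symbol}: tss must be >= 1")
        if self.druggable_tier is not None:
            _check(self.druggable_tier in (1, 2, 3),
                   f"{self.symbol}: druggable_tier must be 1, 2, 3 or null")


class LdMatrix:
    """Square pairwise LD correlation matrix over named SNPs.

    The constructor symmetrizes as ``(M + M.T)/2`` after checking asymmetry
    is below ``1e-8``, forces a unit diagonal, and rejects entries with
    ``|r| > 1 + 1e-8``.
    """

    def __init__(self, snp_ids: Sequence[str], r: np.ndarray):
        r = np.asarray(r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise FormatError(f"LD matrix must be square, got shape {r.shape}")
        if len(snp_ids) != r.shape[0]:
            raise FormatError(
                f"{len(snp_ids)} SNP ids for a {r.shape[0]}x{r.shape[1]} matrix")
        if np.max(np.abs(r - r.T)) > 1e-8:
            raise ValidationError("LD matrix asymmetry exceeds 1e-8")
        if np.max(np.abs(r)) > 1 + 1e-8:
            raise ValidationError("LD correlation with |r| > 1")
        self.snp_ids = list(snp_ids)
        self.r = (r + r.T) / 2.0
        np.fill_diagonal(self.r, 1.0)
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def r2(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]] ** 2)

    def submatrix(self, snp_ids: Sequence[str]) -> "LdMatrix":
        idx = [self._index[s] for s in snp_ids]
        return LdMatrix(list(snp_ids), self.r[np.ix_(idx, idx)])


@dataclass
class Instrument:
    """A harmonized exposure/outcome SNP pair bound to one gene.

    ``action`` records the allele alignment applied to the outcome record;
    dropped instruments keep their ``drop_reason`` for the audit ledger.
    """

    gene: str
    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: Optional[float]
    eaf_out: Optional[float]
    action: str = "none"
    drop_reason: Optional[str] = None
    n_exp: Optional[int] = None
    n_out: Optional[int] = None

    def __post_init__(self) -> None:
        _check(self.action in ("none", "swap", "strand_flip", "swap_and_flip", "dropped"),
               f"unknown harmonization action {self.action!r}")
        _check(self.se_exp > 0 and self.se_out > 0, f"{self.snp_id}: SEs must be > 0")

    @property
    def kept(self) -> bool:
        return self.action != "dropped"


@dataclass
class MethodEstimate:
    """Output of one MR estimator: method label, beta/se/p, and extras
    (Egger intercept, Cochran Q, bootstrap replicate count)."""

    method: str
    beta: float
    se: float
    pval: float
    nsnp: int
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check(self.method in MR_METHODS + ("egger_intercept",),
               f"unknown MR method {self.method!r}")
        _check(self.se >= 0, "estimate se must be >= 0")
        _check(0.0 < self.pval <= 1.0 or math.isnan(self.pval), "pval outside (0,1]")


@dataclass
class MrResult:
    """Per-gene causal estimate with OR scale reporting and FDR adjustment."""

    gene: str
    method: str
    beta: float
    se: float
    pval: float
    qval: float
    or_point: float
    ci_low: float
    ci_high: float
    nsnp: int
    steiger_correct: Optional[bool] = None
    sensitivity: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check(self.method in MR_METHODS, f"unknown MR method {self.method!r}")
        _check(self.or_point > 0, "or_point must be > 0")
        _check(self.ci_low <= self.or_point <= self.ci_high + 1e-12,
               "CI must bracket the OR point estimate")
        _check(self.qval >= self.pval - 1e-12, "BH q-value cannot undershoot p")
        _check(self.nsnp >= 1, "nsnp must be >= 1")


@dataclass
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses.

    H0 no association, H1 eQTL only, H2 GWAS only, H3 two distinct causal
    variants, H4 one shared causal variant.  ``colocalized`` is the strict
    PP4 > threshold verdict.
    """

    gene: str
    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    n_snps: int
    colocalized: bool

    def __post_init__(self) -> None:
        total = self.pp0 + self.pp1 + self.pp2 + self.pp3 + self.pp4
        _check(abs(total - 1.0) <= 1e-9, f"posteriors sum to {total}, not 1")
        for v in (self.pp0, self.pp1, self.pp2, self.pp3, self.pp4):
            _check(-1e-12 <= v <= 1 + 1e-12, "posterior outside [0,1]")


@dataclass
class DrugCandidate:
    """Gene-to-drug row with the three-level inclusion-gate outcome.

    Level I requires a specific action (not broad-spectrum), Level II an
    established safety/efficacy profile, Level III regulatory approval;
    ``level_passed`` is the highest gate cleared.
    """

    gene: str
    drug_name: str
    action_type: str
    max_phase: str
    broad_spectrum: bool
    safety_established: bool
    approved: bool
    level_passed: Optional[int] = None

    def __post_init__(self) -> None:
        _check(str(self.max_phase) in MAX_PHASES,
               f"{self.drug_name}: max_phase must be one of {MAX_PHASES}")
        self.max_phase = str(self.max_phase)
        if self.level_passed is not None:
            _check(self.level_passed in (0, 1, 2, 3), "level_passed outside 0..3")
            if self.level_passed == 3:
                _check(self.approved, "level 3 requires approval")
            if self.level_passed >= 2:
                _check(self.safety_established, "level >= 2 requires established safety")
            if self.level_passed >= 1:
                _check(not self.broad_spectrum, "level >= 1 requires a specific action")
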