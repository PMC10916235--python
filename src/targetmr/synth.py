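"""Synthetic summary-statistics generator with known ground truth.

The generator works entirely at the summary-statistics level: marginal
effect estimates are drawn from the sampling distribution implied by LD and
sample size, never from individual genotypes.  For a region with LD
correlation matrix ``R``, true standardized per-SNP effects ``b`` and
per-SNP standard errors ``se_i = 1/sqrt(2 maf_i (1-maf_i) n)``, the
observed marginal betas are

    beta_hat ~ MVN(R b,  D R D),    D = diag(se)

so each marginal estimate has exactly the stated SE and neighbouring
estimates carry the LD-consistent correlation that both clumping and
colocalization implicitly assume.

Default parameters are frozen to the emulated study: an eQTL panel of
31,684 blood samples, a case-control outcome GWAS of 29,612 cases and
122,656 controls (binary-trait SEs use the effective sample size
``4/(1/n_cases + 1/n_controls)`` with unit phenotype-variance proxy), a
causal expression effect of 0.35 SD per allele (instrument F around 1600,
about 5% expression variance explained) and a causal expression-to-outcome
effect theta = 0.25 on the log-odds scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import ParameterError, ValidationError
from .mr import bh_fdr
from .types import (COMPLEMENT, DrugCandidate, GeneAnnotation, LdMatrix,
                    SummaryStatRecord)

# Emulated study conditions (sample sizes of the source cohorts).
N_EQTL_DEFAULT = 31_684
N_CASES_DEFAULT = 29_612
N_CONTROLS_DEFAULT = 122_656
THETA_DEFAULT = 0.25
EQTL_BETA_DEFAULT = 0.35

SCENARIOS = ("null", "causal_shared", "causal_distinct", "pleiotropic")

# Non-palindromic allele pairs; palindromic pairs only on request so that
# harmonization drops are a deliberate experimental condition.
_NONPALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                         ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimulationTruth:
    """Ground truth for one simulated gene region."""

    gene: str
    causal_snp_ids: list
    eqtl_betas: dict  # snp_id -> true standardized effect on expression
    theta: float
    scenario: str
    seed: int
    outcome_causal_snp_ids: Optional[list] = None  # causal_distinct only
    outcome_betas: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ParameterError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "null" and self.theta != 0:
            raise ValidationError("null scenario requires theta = 0")
        if self.scenario == "causal_distinct":
            if not self.outcome_causal_snp_ids:
                raise ValidationError("causal_distinct requires an outcome causal SNP set")
            if set(self.outcome_causal_snp_ids) & set(self.causal_snp_ids):
                raise ValidationError("causal_distinct requires disjoint causal SNP sets")


@dataclass
class Region:
    """One simulated cis region: LD, MAFs, positions and fixed alleles."""

    snp_ids: list
    ld: LdMatrix
    maf: np.ndarray
    positions: np.ndarray
    chrom: str = "1"
    tss: int = 1_000_000
    effect_alleles: list = field(default_factory=list)
    other_alleles: list = field(default_factory=list)
    _chol: Optional[np.ndarray] = None

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def cholesky(self) -> np.ndarray:
        if self._chol is None:
            self._chol = np.linalg.cholesky(
                self.ld.r + 1e-10 * np.eye(self.n_snps))
        return self._chol


def simulate_region(n_snps: int, block_size: int = 10, rho: float = 0.8,
                    maf_range: tuple[float, float] = (0.05, 0.5),
                    seed: int = 0, chrom: str = "1", tss: int = 1_000_000,
                    snp_prefix: str = "rs", window_bp: int = 100_000,
                    palindromic_fraction: float = 0.0) -> Region:
    """Build a block-diagonal AR(1) LD region around a nominal TSS.

    Within a block ``r(i,j) = rho**|i-j|``; across blocks ``r = 0``.  Block
    boundaries double as independent-region ground truth for clumping and
    for the distinct-causal-variant coloc scenario.  Positions are strictly
    increasing and confined to ``tss +/- window_bp``.
    """
    if n_snps < 1 or block_size < 1:
        raise ParameterError("n_snps and block_size must be >= 1")
    if not (0 <= rho < 1):
        raise ParameterError("rho must be in [0, 1)")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ParameterError("maf_range must satisfy 0 < lo <= hi <= 0.5")

    rng = np.random.default_rng(seed)
    r = np.zeros((n_snps, n_snps))
    for start in range(0, n_snps, block_size):
        stop = min(start + block_size, n_snps)
        idx = np.arange(start, stop)
        r[np.ix_(idx, idx)] = rho ** np.abs(idx[:, None] - idx[None, :])
    ids = [f"{snp_prefix}{i + 1}" for i in range(n_snps)]
    ld = LdMatrix(ids, r)

    maf = rng.uniform(lo, hi, size=n_snps)
    offsets = np.sort(rng.choice(np.arange(-window_bp, window_bp + 1),
                                 size=n_snps, replace=False))
    positions = np.maximum(tss + offsets, 1)
    # clipping at 1 can create ties near the chromosome start; restore strictness
    for i in range(1, n_snps):
        if positions[i] <= positions[i - 1]:
            positions[i] = positions[i - 1] + 1

    eff, oth = [], []
    for _ in range(n_snps):
        if palindromic_fraction > 0 and rng.random() < palindromic_fraction:
            pair = _PALINDROMIC_PAIRS[rng.integers(len(_PALINDROMIC_PAIRS))]
        else:
            pair = _NONPALINDROMIC_PAIRS[rng.integers(len(_NONPALINDROMIC_PAIRS))]
        eff.append(pair[0])
        oth.append(pair[1])
    return Region(snp_ids=ids, ld=ld, maf=maf, positions=positions,
                  chrom=chrom, tss=tss, effect_alleles=eff, other_alleles=oth)


def _true_effect_vector(region: Region, betas: Optional[dict]) -> np.ndarray:
    b = np.zeros(region.n_snps)
    if betas:
        index = {s: i for i, s in enumerate(region.snp_ids)}
        for snp, val in betas.items():
            b[index[snp]] = val
    return b


def _marginal_draw(region: Region, b_true: np.ndarray, se: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    b_marg = region.ld.r @ b_true
    noise = region.cholesky() @ rng.standard_normal(region.n_snps)
    return b_marg + se * noise


def simulate_eqtl_summary(region: Region, truth: SimulationTruth,
                          n_eqtl: int = N_EQTL_DEFAULT,
                          seed: int = 0) -> list[SummaryStatRecord]:
    """Draw marginal cis-eQTL summary statistics for one gene region.

    Per-record FDR is Benjamini-Hochberg over the emitted region, matching
    the region-wise FDR fields of the emulated eQTL catalogues.
    """
    if n_eqtl < 2:
        raise ParameterError("n_eqtl must be >= 2")
    rng = np.random.default_rng(seed)
    se = 1.0 / np.sqrt(2.0 * region.maf * (1.0 - region.maf) * n_eqtl)
    b_true = _true_effect_vector(region, truth.eqtl_betas)
    beta_hat = _marginal_draw(region, b_true, se, rng)
    z = beta_hat / se
    pval = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    fdr = bh_fdr(pval)
    return [SummaryStatRecord(
        snp_id=region.snp_ids[i], chrom=region.chrom, pos=int(region.positions[i]),
        effect_allele=region.effect_alleles[i], other_allele=region.other_alleles[i],
        eaf=float(region.maf[i]), beta=float(beta_hat[i]), se=float(se[i]),
        pval=float(pval[i]), n=n_eqtl, gene=truth.gene, fdr=float(fdr[i]))
        for i in range(region.n_snps)]


def effective_sample_size(n_cases: int, n_controls: int) -> float:
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


def simulate_gwas_summary(region: Region, truth: SimulationTruth,
                          n_cases: int = N_CASES_DEFAULT,
                          n_controls: int = N_CONTROLS_DEFAULT,
                          pleiotropy_sd: float = 0.0,
                          swap_fraction: float = 0.0,
                          strand_fraction: float = 0.0,
                          seed: int = 0) -> list[SummaryStatRecord]:
    """Draw outcome GWAS summary statistics consistent with the truth scenario.

    causal_shared propagates ``theta`` through the eQTL causal variants;
    causal_distinct places the outcome effect on its own disjoint SNP set;
    pleiotropic adds per-SNP direct effects ``Normal(0, pleiotropy_sd)``.
    ``swap_fraction`` of rows are emitted with effect/other alleles swapped
    (beta negated, eaf complemented) and ``strand_fraction`` with both
    alleles strand-complemented, to exercise harmonization downstream.
    """
    if n_cases < 1 or n_controls < 1:
        raise ParameterError("case/control counts must be >= 1")
    if not (0 <= swap_fraction <= 1 and 0 <= strand_fraction <= 1):
        raise ParameterError("swap/strand fractions must be in [0,1]")
    rng = np.random.default_rng(seed)
    n_eff = effective_sample_size(n_cases, n_controls)
    se = 1.0 / np.sqrt(2.0 * region.maf * (1.0 - region.maf) * n_eff)

    if truth.scenario == "causal_distinct":
        b_true = _true_effect_vector(region, truth.outcome_betas)
    else:
        b_true = truth.theta * _true_effect_vector(region, truth.eqtl_betas)
    if truth.scenario == "pleiotropic" and pleiotropy_sd > 0:
        b_true = b_true + rng.normal(0.0, pleiotropy_sd, size=region.n_snps)

    beta_hat = _marginal_draw(region, b_true, se, rng)
    z = beta_hat / se
    pval = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)

    swap = rng.random(region.n_snps) < swap_fraction
    strand = rng.random(region.n_snps) < strand_fraction
    n_total = n_cases + n_controls
    records = []
    for i in range(region.n_snps):
        ea, oa = region.effect_alleles[i], region.other_alleles[i]
        beta, eaf = float(beta_hat[i]), float(region.maf[i])
        if swap[i]:
            ea, oa = oa, ea
            beta, eaf = -beta, 1.0 - eaf
        if strand[i]:
            ea, oa = COMPLEMENT[ea], COMPLEMENT[oa]
        records.append(SummaryStatRecord(
            snp_id=region.snp_ids[i], chrom=region.chrom,
            pos=int(region.positions[i]), effect_allele=ea, other_allele=oa,
            eaf=eaf, beta=beta, se=float(se[i]), pval=float(pval[i]), n=n_total))
    return records


# --- Drug table ------------------------------------------------------------

def table1_replica() -> list[DrugCandidate]:
    """The five gene-drug rows of the emulated study's candidate table."""
    return [
        DrugCandidate("TBK1", "fostamatinib", "inhibitor", "approved",
                      broad_spectrum=False, safety_established=True, approved=True),
        DrugCandidate("TBK1", "amlexanox", "inhibitor", "approved",
                      broad_spectrum=False, safety_established=True, approved=True),
        DrugCandidate("TNFSF12", "BIIB-023", "antibody", "2",
                      broad_spectrum=False, safety_established=False, approved=False),
        DrugCandidate("TNFSF12", "RG-7212", "antibody", "1",
                      broad_spectrum=False, safety_established=False, approved=False),
        DrugCandidate("GPX3", "glutathione", "cofactor", "3",
                      broad_spectrum=True, safety_established=True, approved=False),
    ]


_ARCHETYPES = [
    # (action_type, max_phase, broad, safe, approved) -> expected levels 3,2,1,0
    ("inhibitor", "approved", False, True, True),
    ("agonist", "3", False, True, False),
    ("antibody", "2", False, False, False),
    ("cofactor", "3", True, True, False),
]


def simulate_drug_table(genes: Sequence[str], seed: int = 0,
                        include_table1: bool = True) -> list[DrugCandidate]:
    """Emit a drug-candidate table mixing the archetypes the inclusion gates
    distinguish, plus (by default) the hand-coded five-drug replica rows."""
    rng = np.random.default_rng(seed)
    out = table1_replica() if include_table1 else []
    replica_genes = {c.gene for c in out}
    for gene in genes:
        if gene in replica_genes:
            continue
        action, phase, broad, safe, approved = _ARCHETYPES[rng.integers(len(_ARCHETYPES))]
        out.append(DrugCandidate(gene=gene, drug_name=f"cmpd-{gene.lower()}",
                                 action_type=action, max_phase=phase,
                                 broad_spectrum=broad, safety_established=safe,
                                 approved=approved))
    return out


# --- Whole-bundle simulation ----------------------------------------------

@dataclass
class Bundle:
    """Everything one pipeline run consumes, plus the generating truth."""

    genes: list  # GeneAnnotation
    regions: dict  # gene -> Region
    truths: dict  # gene -> SimulationTruth
    eqtl: list  # SummaryStatRecord (eqtl kind)
    gwas: list  # SummaryStatRecord (gwas kind)
    blocklist: set
    drugs: list  # DrugCandidate


def simulate_bundle(n_genes: int = 50,
                    n_causal: int = 5,
                    scenario: str = "causal_shared",
                    n_snps: int = 50,
                    block_size: int = 10,
                    rho: float = 0.8,
                    theta: float = THETA_DEFAULT,
                    eqtl_beta: float = EQTL_BETA_DEFAULT,
                    n_eqtl: int = N_EQTL_DEFAULT,
                    n_cases: int = N_CASES_DEFAULT,
                    n_controls: int = N_CONTROLS_DEFAULT,
                    swap_fraction: float = 0.1,
                    strand_fraction: float = 0.0,
                    druggable_fraction: float = 1.0,
                    n_blocked_snps: int = 0,
                    winners_curse_p: Optional[float] = None,
                    seed: int = 0) -> Bundle:
    """Simulate a full input bundle: ``n_causal`` genes follow ``scenario``
    (with effect ``theta``), the remainder are null (expression has a causal
    cis variant, theta = 0).  Every gene gets one causal eQTL SNP placed in
    a random LD block.

    ``winners_curse_p`` turns on significance-conditioned resampling: a
    gene's eQTL draw is re-emitted until its top p-value beats the
    threshold, reproducing the upward bias of discovery-significant effect
    estimates.  Off by default.
    """
    if n_causal > n_genes:
        raise ParameterError("n_causal cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    causal_idx = set(rng.choice(n_genes, size=n_causal, replace=False).tolist())

    genes, regions, truths = [], {}, {}
    eqtl_records, gwas_records = [], []
    for g in range(n_genes):
        name = f"G{g + 1:04d}"
        chrom = str(g % 22 + 1)
        tss = 1_000_000 + 300_000 * g
        tier = int(rng.integers(1, 4)) if rng.random() < druggable_fraction else None
        genes.append(GeneAnnotation(symbol=name, chrom=chrom, tss=tss,
                                    druggable_tier=tier))
        region_seed = int(rng.integers(2 ** 31))
        region = simulate_region(n_snps, block_size, rho, seed=region_seed,
                                 chrom=chrom, tss=tss, snp_prefix=f"rs{g + 1}_")
        causal_snp = region.snp_ids[int(rng.integers(n_snps))]
        sc = scenario if g in causal_idx else "null"
        kwargs = {}
        if sc == "causal_distinct":
            others = [s for s in region.snp_ids
                      if abs(region.snp_ids.index(s) // block_size
                             - region.snp_ids.index(causal_snp) // block_size) >= 1]
            out_snp = others[int(rng.integers(len(others)))]
            kwargs = {"outcome_causal_snp_ids": [out_snp],
                      "outcome_betas": {out_snp: theta * eqtl_beta}}
        truth = SimulationTruth(
            gene=name, causal_snp_ids=[causal_snp],
            eqtl_betas={causal_snp: eqtl_beta},
            theta=theta if sc != "null" else 0.0,
            scenario=sc, seed=region_seed, **kwargs)
        regions[name] = region
        truths[name] = truth
        gene_eqtl = simulate_eqtl_summary(
            region, truth, n_eqtl=n_eqtl, seed=int(rng.integers(2 ** 31)))
        if winners_curse_p is not None:
            # emit a region only once its top eQTL clears the discovery bar
            for _ in range(100):
                if min(r.pval for r in gene_eqtl) < winners_curse_p:
                    break
                gene_eqtl = simulate_eqtl_summary(
                    region, truth, n_eqtl=n_eqtl,
                    seed=int(rng.integers(2 ** 31)))
        eqtl_records.extend(gene_eqtl)
        gwas_records.extend(simulate_gwas_summary(
            region, truth, n_cases=n_cases, n_controls=n_controls,
            swap_fraction=swap_fraction, strand_fraction=strand_fraction,
            seed=int(rng.integers(2 ** 31))))

    # blocklist: non-causal SNPs flagged as confounder-associated
    non_causal = [r.snp_id for r in eqtl_records
                  if r.snp_id not in truths[r.gene].causal_snp_ids]
    blocked = set()
    if n_blocked_snps > 0 and non_causal:
        blocked = set(rng.choice(sorted(set(non_causal)),
                                 size=min(n_blocked_snps, len(set(non_causal))),
                                 replace=False).tolist())
    drugs = simulate_drug_table([g.symbol for g in genes],
                                seed=int(rng.integers(2 ** 31)))
    return Bundle(genes=genes, regions=regions, truths=truths,
                  eqtl=eqtl_records, gwas=gwas_records,
                  blocklist=blocked, drugs=drugs)


def write_bundle(bundle: Bundle, outdir, seed: Optional[int] = None) -> dict:
    """Write a bundle as the TSV input set a pipeline run consumes.

    Returns the path map.  LD matrices go one file per gene under ``ld/``.
    """
    from . import io as tio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "ld").mkdir(exist_ok=True)
    comments = [] if seed is None else [f"seed={seed}"]
    paths = {
        "eqtl": outdir / "eqtl.tsv",
        "gwas": outdir / "gwas.tsv",
        "genes": outdir / "genes.tsv",
        "blocklist": outdir / "blocklist.txt",
        "drugs": outdir / "drugs.tsv",
        "truth": outdir / "truth.tsv",
        "ld_dir": outdir / "ld",
    }
    tio.write_summary_stats(bundle.eqtl, paths["eqtl"], kind="eqtl",
                            header_comments=comments)
    tio.write_summary_stats(bundle.gwas, paths["gwas"], kind="gwas",
                            header_comments=comments)
    tio.write_gene_annotations(bundle.genes, paths["genes"])
    tio.write_blocklist(bundle.blocklist, paths["blocklist"])
    tio.write_results(bundle.drugs, paths["drugs"],
                      result_type=type(bundle.drugs[0]))
    for gene, region in bundle.regions.items():
        tio.write_ld_matrix(region.ld, paths["ld_dir"] / f"{gene}.tsv")
    with open(paths["truth"], "w") as fh:
        fh.write("gene\tscenario\ttheta\tcausal_snp_ids\toutcome_causal_snp_ids\n")
        for gene, truth in bundle.truths.items():
            out_ids = ",".join(truth.outcome_causal_snp_ids or [])
            fh.write(f"{gene}\t{truth.scenario}\t{truth.theta:.6g}\t"
                     f"{','.join(truth.causal_snp_ids)}\t{out_ids}\n")
    return paths
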