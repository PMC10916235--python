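"""End-to-end pipeline: inputs -> instruments -> harmonized MR -> coloc ->
prioritized targets, with a JSON run manifest.

Every stage output is a commented TSV carrying the config hash and seed, so
a run is auditable and re-running with identical config and inputs
reproduces byte-identical outputs.  The manifest records the stage funnel
(genes in, instruments selected, MR-significant genes, colocalized genes,
prioritized targets) the same way the emulated study reports its counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from . import coloc as coloc_mod
from . import instruments as instr_mod
from . import io as tio
from . import mr as mr_core
from . import repurpose as rep_mod
from .errors import TargetMrError
from .harmonize import harmonization_report, harmonize_many
from .types import ColocResult, DrugCandidate, MrResult

logger = logging.getLogger("targetmr")


@dataclass
class RunConfig:
    """All pipeline tunables with the study-default thresholds."""

    eqtl_path: str = ""
    gwas_path: str = ""
    genes_path: str = ""
    ld_dir: str = ""
    blocklist_path: Optional[str] = None
    drug_table_path: Optional[str] = None
    output_dir: str = "output"
    tissue: str = "blood"
    window_bp: int = 100_000
    fdr_threshold: float = 0.05
    clump_r2: float = 0.001
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    pp4_threshold: float = 0.75
    palindrome_eaf_limit: float = 0.42
    frequency_tolerance: float = 0.2
    ivw_model: str = "fixed"
    f_min: Optional[float] = None
    n_boot: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fdr_threshold < 1):
            raise TargetMrError("fdr_threshold must be in (0,1)")
        if not (0 < self.clump_r2 <= 1):
            raise TargetMrError("clump_r2 must be in (0,1]")
        if not (0 <= self.pp4_threshold <= 1):
            raise TargetMrError("pp4_threshold must be in [0,1]")
        if not (0 < self.palindrome_eaf_limit < 0.5):
            raise TargetMrError("palindrome_eaf_limit must be in (0,0.5)")
        if min(self.coloc_p1, self.coloc_p2, self.coloc_p12) <= 0:
            raise TargetMrError("coloc priors must be positive")

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Load a flat key-value (YAML) config document; keyword overrides
        win over file values.  Keys carry explicit units (window_bp)."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise TargetMrError(f"{path}: config must be a flat key-value map")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise TargetMrError(
                f"{path}: unknown config key(s): {', '.join(sorted(unknown))}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def config_hash(self) -> str:
        # analysis parameters only: where the output lands must not change
        # what the run computes
        payload = {k: v for k, v in dataclasses.asdict(self).items()
                   if k != "output_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; each stage's output is written before the
    next begins.  Returns the run manifest (also written as JSON)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    comments = [f"targetmr {__version__}",
                f"config_hash={config.config_hash()}",
                f"seed={config.seed}"]
    manifest: dict = {"version": __version__,
                      "config_hash": config.config_hash(),
                      "seed": config.seed, "counts": {}, "stages": []}

    def _record(stage: str, **counts) -> None:
        manifest["stages"].append(stage)
        manifest["counts"].update(counts)
        logger.info("stage %s: %s", stage,
                    ", ".join(f"{k}={v}" for k, v in counts.items()))
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    try:
        genes = tio.read_gene_annotations(config.genes_path)
        eqtl = tio.read_summary_stats(config.eqtl_path, kind="eqtl")
        gwas = tio.read_summary_stats(config.gwas_path, kind="gwas")
        blocklist = (tio.read_blocklist(config.blocklist_path)
                     if config.blocklist_path else set())
        _record("load", genes_in=len(genes), eqtl_records=len(eqtl),
                gwas_records=len(gwas), blocklist_snps=len(blocklist))

        gene_map = {g.symbol: g for g in genes}
        by_gene = instr_mod.overlap_druggable(eqtl, genes)
        _record("overlap_druggable", druggable_genes_with_eqtl=len(by_gene))

        ld_dir = Path(config.ld_dir)
        selected: dict[str, list] = {}
        for gene in sorted(by_gene):
            ld = tio.read_ld_matrix(ld_dir / f"{gene}.tsv")
            cands = instr_mod.select_instruments(
                by_gene[gene], gene_map[gene], ld, blocklist=blocklist,
                window_bp=config.window_bp,
                fdr_threshold=config.fdr_threshold,
                r2_threshold=config.clump_r2, f_min=config.f_min)
            if cands:
                selected[gene] = cands
        n_iv = sum(len(v) for v in selected.values())
        with open(outdir / "instruments.tsv", "w") as fh:
            for line in comments:
                fh.write(f"# {line}\n")
            fh.write("gene\tsnp_id\tbeta\tse\tpval\tfdr\tdistance_to_tss\tf_statistic\n")
            for gene in sorted(selected):
                for c in selected[gene]:
                    fh.write(f"{gene}\t{c.snp_id}\t{c.record.beta:.6g}\t"
                             f"{c.record.se:.6g}\t{c.record.pval:.6g}\t"
                             f"{c.record.fdr:.6g}\t{c.distance_to_tss}\t"
                             f"{c.f_statistic:.6g}\n")
        _record("instruments", genes_with_instruments=len(selected),
                instruments_selected=n_iv)

        gwas_by_snp = {r.snp_id: r for r in gwas}
        all_ivs = []
        ivs_by_gene: dict[str, list] = {}
        for gene in sorted(selected):
            ivs = harmonize_many(
                [c.record for c in selected[gene]], gwas_by_snp,
                palindrome_eaf_limit=config.palindrome_eaf_limit,
                frequency_tolerance=config.frequency_tolerance)
            ivs_by_gene[gene] = [iv for iv in ivs if iv.kept]
            all_ivs.extend(ivs)
        harmonization_report(all_ivs, outdir / "harmonization.tsv")
        _record("harmonize",
                instruments_harmonized=sum(len(v) for v in ivs_by_gene.values()),
                instruments_dropped=sum(1 for iv in all_ivs if not iv.kept))

        results: list[MrResult] = []
        for i, gene in enumerate(sorted(ivs_by_gene)):
            res = mr_core.run_gene_mr(
                gene, ivs_by_gene[gene], ivw_model=config.ivw_model,
                n_boot=config.n_boot,
                seed=(config.seed * 1_000_003 + i) % (2 ** 31))
            if res is not None:
                results.append(res)
        mr_core.finalize_fdr(results)
        tio.write_results(results, outdir / "mr_results.tsv",
                          result_type=MrResult, header_comments=comments)
        significant = [r for r in results if r.qval < config.fdr_threshold]
        _record("mr", genes_tested=len(results),
                genes_mr_significant=len(significant))

        eqtl_by_gene: dict[str, list] = {}
        for rec in eqtl:
            eqtl_by_gene.setdefault(rec.gene, []).append(rec)
        coloc_results: list[ColocResult] = []
        for r in significant:
            gene_records = [rec for rec in eqtl_by_gene.get(r.gene, [])
                            if rec.snp_id in gwas_by_snp]
            if not gene_records:
                continue
            d1 = coloc_mod.RegionDataset.from_records(
                gene_records, trait_type="quantitative")
            d2 = coloc_mod.RegionDataset.from_records(
                [gwas_by_snp[rec.snp_id] for rec in gene_records],
                trait_type="case_control")
            coloc_results.append(coloc_mod.coloc_posteriors(
                d1, d2, p1=config.coloc_p1, p2=config.coloc_p2,
                p12=config.coloc_p12, gene=r.gene,
                pp4_threshold=config.pp4_threshold))
        tio.write_results(coloc_results, outdir / "coloc_results.tsv",
                          result_type=ColocResult, header_comments=comments)
        _record("coloc", genes_colocalized=sum(
            1 for c in coloc_results if c.colocalized))

        targets = rep_mod.prioritize_targets(
            results, coloc_results, fdr=config.fdr_threshold,
            pp4=config.pp4_threshold, tissue=config.tissue)
        drug_table = (tio.read_drug_table(config.drug_table_path)
                      if config.drug_table_path else [])
        rep_mod.attach_candidates(targets, drug_table)
        with open(outdir / "prioritization.tsv", "w") as fh:
            for line in comments:
                fh.write(f"# {line}\n")
            fh.write("gene\ttissue\tor_point\tci_low\tci_high\tqval\tpp4\t"
                     "risk_direction\tdrug_name\taction_type\tlevel_passed\t"
                     "concordance\n")
            for t in targets:
                base = (f"{t.gene}\t{t.tissue}\t{t.mr.or_point:.6g}\t"
                        f"{t.mr.ci_low:.6g}\t{t.mr.ci_high:.6g}\t"
                        f"{t.mr.qval:.6g}\t{t.coloc.pp4:.6g}\t{t.risk_direction}")
                if not t.candidates:
                    fh.write(base + "\tNA\tNA\tNA\tNA\n")
                for cand in t.candidates:
                    conc = rep_mod.direction_concordance(t, cand)
                    fh.write(base + f"\t{cand.drug_name}\t{cand.action_type}\t"
                                    f"{cand.level_passed}\t{conc}\n")
        _record("prioritize", targets_prioritized=len(targets),
                drug_candidates=sum(len(t.candidates) for t in targets))
    except TargetMrError as exc:
        _record("error", failed_stage=len(manifest["stages"]))
        raise TargetMrError(
            f"pipeline aborted at stage {manifest['stages'][-2] if len(manifest['stages'])>1 else 'load'}: {exc}"
        ) from exc
    return manifest


def make_forest_table(mr_results, coloc_results) -> pd.DataFrame:
    """Publication-style per-gene summary joining MR and coloc outputs.

    One row per gene with "OR (95% CI)", q-value and PP0..PP4; rows ordered
    by tissue then ascending q-value.
    """
    coloc_by_gene = {c.gene: c for c in coloc_results}
    rows = []
    for r in mr_results:
        c = coloc_by_gene.get(r.gene)
        rows.append({
            "gene": r.gene,
            "tissue": getattr(r, "tissue", "blood"),
            "or_ci": f"{r.or_point:.2f} ({r.ci_low:.2f}, {r.ci_high:.2f})",
            "qval": r.qval,
            "nsnp": r.nsnp,
            "method": r.method,
            "pp0": c.pp0 if c else float("nan"),
            "pp1": c.pp1 if c else float("nan"),
            "pp2": c.pp2 if c else float("nan"),
            "pp3": c.pp3 if c else float("nan"),
            "pp4": c.pp4 if c else float("nan"),
        })
    df = pd.DataFrame(rows, columns=["gene", "tissue", "or_ci", "qval",
                                     "nsnp", "method", "pp0", "pp1", "pp2",
                                     "pp3", "pp4"])
    return df.sort_values(["tissue", "qval"], kind="mergesort").reset_index(drop=True)
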