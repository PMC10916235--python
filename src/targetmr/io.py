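"""Readers and writers for every tabular format the pipeline touches.

All files are plain TSV with a header row; lines starting with ``#`` are
comments (stage outputs use them to record the seed and config hash).
Column names are fixed snake_case; a ``rename`` map can adapt foreign
headers so the core parsers stay dialect-free.  Floats are written with six
significant digits, so a write/read round trip is exact to 1e-6 relative.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError, UsageError, ValidationError
from .types import (ColocResult, DrugCandidate, GeneAnnotation, LdMatrix,
                    MrResult, SummaryStatRecord)

GWAS_COLUMNS = ["snp_id", "chrom", "pos", "effect_allele", "other_allele",
                "eaf", "beta", "se", "pval", "n"]
EQTL_COLUMNS = GWAS_COLUMNS + ["gene", "fdr"]

MR_RESULT_COLUMNS = ["gene", "method", "beta", "se", "pval", "qval",
                     "or_point", "ci_low", "ci_high", "nsnp", "steiger_correct"]
COLOC_RESULT_COLUMNS = ["gene", "n_snps", "pp0", "pp1", "pp2", "pp3", "pp4",
                        "colocalized"]
DRUG_COLUMNS = ["gene", "drug_name", "action_type", "max_phase",
                "broad_spectrum", "safety_established", "approved", "level_passed"]

# 7 significant digits: guarantees <= 5e-7 relative round-trip error, so a
# write/read cycle reproduces every value within the stated 1e-6 tolerance.
_FLOAT_FMT = "%.7g"


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool) or isinstance(value, np.bool_):
        return "true" if value else "false"
    if isinstance(value, float) or isinstance(value, np.floating):
        if math.isnan(value):
            return "NA"
        return _FLOAT_FMT % value
    return str(value)


def _read_table(path, rename: Optional[Mapping[str, str]] = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False, na_values=["NA", ""])
    if rename:
        df = df.rename(columns=dict(rename))
    return df


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_summary_stats(path, kind: str = "gwas",
                       rename: Optional[Mapping[str, str]] = None
                       ) -> list[SummaryStatRecord]:
    """Read a GWAS or eQTL summary-statistics TSV.

    ``kind='eqtl'`` additionally requires ``gene`` and ``fdr`` columns.
    Row order is preserved; invariant violations are reported with the
    1-based data-row number.
    """
    if kind not in ("gwas", "eqtl"):
        raise UsageError(f"kind must be 'gwas' or 'eqtl', got {kind!r}")
    df = _read_table(path, rename)
    required = EQTL_COLUMNS if kind == "eqtl" else GWAS_COLUMNS
    _require_columns(df, required, path)

    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            eaf = row.eaf
            eaf = None if eaf is None or (isinstance(eaf, float) and math.isnan(eaf)) \
                else float(eaf)
            if eaf is None and kind == "eqtl":
                raise ValidationError("eaf is required on eQTL records")
            records.append(SummaryStatRecord(
                snp_id=str(row.snp_id), chrom=str(row.chrom), pos=int(row.pos),
                effect_allele=str(row.effect_allele), other_allele=str(row.other_allele),
                eaf=eaf, beta=float(row.beta), se=float(row.se),
                pval=float(row.pval), n=int(float(row.n)),
                gene=str(row.gene) if kind == "eqtl" else None,
                fdr=float(row.fdr) if kind == "eqtl" else None))
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return records


def write_summary_stats(records: Iterable[SummaryStatRecord], path,
                        kind: str = "gwas",
                        header_comments: Sequence[str] = ()) -> None:
    cols = EQTL_COLUMNS if kind == "eqtl" else GWAS_COLUMNS
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        fh.write("\t".join(cols) + "\n")
        for rec in records:
            fh.write("\t".join(_fmt(getattr(rec, c)) for c in cols) + "\n")


def read_ld_matrix(path) -> LdMatrix:
    """Read a square LD TSV whose first row and first column are SNP ids."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"{path}: LD block is {df.shape[0]}x{df.shape[1]}, not square")
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: LD row and column SNP ids disagree")
    return LdMatrix(list(df.columns), df.to_numpy(dtype=float))


def write_ld_matrix(ld: LdMatrix, path) -> None:
    df = pd.DataFrame(ld.r, index=ld.snp_ids, columns=ld.snp_ids)
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_gene_annotations(path) -> list[GeneAnnotation]:
    df = _read_table(path)
    _require_columns(df, ["symbol", "chrom", "tss", "druggable_tier"], path)
    out = []
    seen = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.symbol in seen:
            raise ValidationError(f"{path}: row {i}: duplicate gene symbol {row.symbol}")
        seen.add(row.symbol)
        tier = row.druggable_tier
        tier = None if tier is None or (isinstance(tier, float) and math.isnan(tier)) \
            else int(float(tier))
        try:
            out.append(GeneAnnotation(symbol=str(row.symbol), chrom=str(row.chrom),
                                      tss=int(float(row.tss)), druggable_tier=tier))
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return out


def write_gene_annotations(genes: Iterable[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("symbol\tchrom\ttss\tdruggable_tier\n")
        for g in genes:
            fh.write(f"{g.symbol}\t{g.chrom}\t{g.tss}\t{_fmt(g.druggable_tier)}\n")


def read_blocklist(path) -> set[str]:
    """One SNP id per line; '#' starts a comment."""
    ids = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            ids.add(line)
    return ids


def write_blocklist(snp_ids: Iterable[str], path) -> None:
    Path(path).write_text("".join(f"{s}\n" for s in sorted(snp_ids)))


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValidationError(f"cannot parse boolean from {x!r}")


def read_drug_table(path) -> list[DrugCandidate]:
    df = _read_table(path)
    _require_columns(df, DRUG_COLUMNS[:-1], path)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            level = getattr(row, "level_passed", None)
            level = None if level is None or (isinstance(level, float) and math.isnan(level)) \
                else int(float(level))
            out.append(DrugCandidate(
                gene=str(row.gene), drug_name=str(row.drug_name),
                action_type=str(row.action_type), max_phase=str(row.max_phase),
                broad_spectrum=_parse_bool(row.broad_spectrum),
                safety_established=_parse_bool(row.safety_established),
                approved=_parse_bool(row.approved), level_passed=level))
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return out


_RESULT_SCHEMAS = {
    MrResult: MR_RESULT_COLUMNS,
    ColocResult: COLOC_RESULT_COLUMNS,
    DrugCandidate: DRUG_COLUMNS,
}


def write_results(results: Sequence, path, result_type=None,
                  header_comments: Sequence[str] = ()) -> None:
    """Write a homogeneous list of MrResult / ColocResult / DrugCandidate.

    An empty list needs an explicit ``result_type`` to pick the header.
    Mixed types raise :class:`UsageError`.
    """
    if result_type is None:
        if not results:
            raise UsageError("empty result list requires an explicit result_type")
        result_type = type(results[0])
    if result_type not in _RESULT_SCHEMAS:
        raise UsageError(f"unsupported result type {result_type!r}")
    if any(type(r) is not result_type for r in results):
        raise UsageError("mixed result types in one table")
    cols = _RESULT_SCHEMAS[result_type]
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        fh.write("\t".join(cols) + "\n")
        for r in results:
            fh.write("\t".join(_fmt(getattr(r, c)) for c in cols) + "\n")


def read_mr_results(path) -> list[MrResult]:
    df = _read_table(path)
    _require_columns(df, MR_RESULT_COLUMNS, path)
    out = []
    for row in df.itertuples(index=False):
        steiger = row.steiger_correct
        steiger = None if steiger is None or (isinstance(steiger, float) and math.isnan(steiger)) \
            else _parse_bool(steiger)
        out.append(MrResult(
            gene=str(row.gene), method=str(row.method), beta=float(row.beta),
            se=float(row.se), pval=float(row.pval), qval=float(row.qval),
            or_point=float(row.or_point), ci_low=float(row.ci_low),
            ci_high=float(row.ci_high), nsnp=int(float(row.nsnp)),
            steiger_correct=steiger))
    return out


def read_coloc_results(path) -> list[ColocResult]:
    df = _read_table(path)
    _require_columns(df, COLOC_RESULT_COLUMNS, path)
    out = []
    for r in df.itertuples(index=False):
        pps = np.array([float(r.pp0), float(r.pp1), float(r.pp2),
                        float(r.pp3), float(r.pp4)])
        pps = pps / pps.sum()  # undo 6-digit rounding so posteriors sum to 1
        out.append(ColocResult(gene=str(r.gene), n_snps=int(float(r.n_snps)),
                               pp0=pps[0], pp1=pps[1], pp2=pps[2], pp3=pps[3],
                               pp4=pps[4], colocalized=_parse_bool(r.colocalized)))
    return out


def dataclass_frame(items: Sequence) -> pd.DataFrame:
    """Convenience: a list of dataclasses as a DataFrame (for examples/reporting)."""
    return pd.DataFrame([dataclasses.asdict(x) for x in items])
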