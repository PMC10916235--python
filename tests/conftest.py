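"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from targetmr.types import Instrument, SummaryStatRecord


def make_record(snp_id="rs1", chrom="1", pos=1_000_000, ea="A", oa="G",
                eaf=0.3, beta=0.1, se=0.02, pval=0.001, n=30_000,
                gene=None, fdr=None) -> SummaryStatRecord:
    return SummaryStatRecord(snp_id=snp_id, chrom=chrom, pos=pos,
                             effect_allele=ea, other_allele=oa, eaf=eaf,
                             beta=beta, se=se, pval=pval, n=n, gene=gene,
                             fdr=fdr)


def random_instruments(rng: np.random.Generator, n: int,
                       theta: float = 0.2) -> list[Instrument]:
    """Random harmonized instruments around a true causal slope theta."""
    ivs = []
    for i in range(n):
        bx = rng.uniform(0.1, 0.6) * rng.choice([-1.0, 1.0])
        sx = rng.uniform(0.01, 0.05)
        so = rng.uniform(0.01, 0.08)
        by = theta * bx + so * rng.standard_normal()
        ivs.append(Instrument(gene="G", snp_id=f"rs{i + 1}", beta_exp=bx,
                              se_exp=sx, beta_out=by, se_out=so,
                              eaf_exp=0.3, eaf_out=0.3,
                              n_exp=30_000, n_out=150_000))
    return ivs


# --- Independent oracles ---------------------------------------------------

def wls_origin_oracle(bx, by, so):
    """Weighted least squares through the origin by the normal equations."""
    bx, by, so = map(np.asarray, (bx, by, so))
    w = 1.0 / so ** 2
    beta = np.sum(w * bx * by) / np.sum(w * bx ** 2)
    se = 1.0 / np.sqrt(np.sum(w * bx ** 2))
    return beta, se


def wls_intercept_oracle(bx, by, so):
    """Weighted regression with intercept by explicit normal equations,
    residual variance on n-2 df (matches the t-reference fit)."""
    bx, by, so = map(np.asarray, (bx, by, so))
    w = np.diag(1.0 / so ** 2)
    x = np.column_stack([np.ones_like(bx), bx])
    xtwx_inv = np.linalg.inv(x.T @ w @ x)
    coef = xtwx_inv @ x.T @ w @ by
    resid = by - x @ coef
    sigma2 = (resid @ np.diag(1.0 / so ** 2) @ resid) / (len(bx) - 2)
    se = np.sqrt(np.diag(xtwx_inv) * sigma2)
    return coef, se  # (intercept, slope)


def weighted_median_oracle(ratios, weights):
    """Brute-force cumulative-weight interpolation at 0.5."""
    order = np.argsort(ratios)
    r = np.asarray(ratios)[order]
    w = np.asarray(weights)[order] / np.sum(weights)
    cum = np.cumsum(w) - w / 2.0
    if cum[0] >= 0.5:
        return float(r[0])
    for k in range(len(r) - 1):
        if cum[k] < 0.5 <= cum[k + 1]:
            return float(r[k] + (r[k + 1] - r[k])
                         * (0.5 - cum[k]) / (cum[k + 1] - cum[k]))
    return float(r[-1])


def coloc_enumeration_oracle(l1, l2, p1, p2, p12):
    """Posteriors by explicit enumeration of single-causal configurations,
    in plain (non-log) arithmetic — valid for moderate |z|."""
    abf1 = np.exp(np.asarray(l1))
    abf2 = np.exp(np.asarray(l2))
    n = len(abf1)
    s0 = 1.0
    s1 = p1 * np.sum(abf1)
    s2 = p2 * np.sum(abf2)
    s3 = 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                s3 += p1 * p2 * abf1[i] * abf2[j]
    s4 = p12 * np.sum(abf1 * abf2)
    total = s0 + s1 + s2 + s3 + s4
    return np.array([s0, s1, s2, s3, s4]) / total


def clump_oracle(candidates, ld, r2_threshold):
    """Greedy p-ranked insertion, checking each candidate against every
    already-kept SNP (quadratic, order-independent reference)."""
    ranked = sorted(candidates,
                    key=lambda c: (c.pval, -c.f_statistic, c.snp_id))
    kept = []
    for cand in ranked:
        if all(ld.r2(cand.snp_id, k.snp_id) < r2_threshold for k in kept):
            kept.append(cand)
    return kept


@pytest.fixture
def rng():
    return np.random.default_rng(20240305)
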