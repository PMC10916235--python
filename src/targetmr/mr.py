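"""Two-sample MR estimators and per-gene routing.

Estimators operate on harmonized instruments.  The primary estimate is the
Wald ratio for a single instrument and fixed-effect IVW for two or more;
MR-Egger and the weighted median are sensitivity analyses recorded whenever
three or more instruments are available.  The Steiger test checks that each
instrument explains more variance in expression than in the outcome, and
Benjamini-Hochberg adjustment across genes yields the FDR used for
significance (q < 0.05).
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import (EstimationError, InsufficientInstrumentsError,
                     ParameterError, UsageError, ValidationError)
from .types import Instrument, MethodEstimate, MrResult


def _two_sided_normal_p(z: float) -> float:
    return float(min(1.0, max(2.0 * stats.norm.sf(abs(z)), 1e-300)))


def wald_ratio(iv: Instrument, second_order: bool = False) -> MethodEstimate:
    """Single-instrument causal estimate beta_out / beta_exp.

    The default SE is the first-order delta method ``se_out / |beta_exp|``;
    ``second_order=True`` adds the ``beta_out^2 se_exp^2 / beta_exp^4`` term.
    """
    if iv.beta_exp == 0:
        raise EstimationError(f"{iv.snp_id}: exposure beta is zero (degenerate instrument)")
    beta = iv.beta_out / iv.beta_exp
    var = iv.se_out ** 2 / iv.beta_exp ** 2
    if second_order:
        var += iv.beta_out ** 2 * iv.se_exp ** 2 / iv.beta_exp ** 4
    se = math.sqrt(var)
    return MethodEstimate(method="wald_ratio", beta=beta, se=se,
                          pval=_two_sided_normal_p(beta / se), nsnp=1)


def ivw(ivs: Sequence[Instrument], model: str = "fixed") -> MethodEstimate:
    """Inverse-variance weighted meta-analysis of per-IV Wald ratios.

    Equivalent to weighted regression of beta_out on beta_exp through the
    origin with weights 1/se_out^2.  ``model='random'`` inflates the SE by
    ``max(1, sqrt(Q/(n-1)))`` (multiplicative random effects).
    """
    if model not in ("fixed", "random"):
        raise ParameterError(f"ivw model must be 'fixed' or 'random', got {model!r}")
    if len(ivs) < 2:
        raise UsageError("IVW needs >= 2 instruments; route single IVs to wald_ratio")
    bx = np.array([iv.beta_exp for iv in ivs])
    by = np.array([iv.beta_out for iv in ivs])
    so = np.array([iv.se_out for iv in ivs])
    if np.any(bx == 0):
        raise EstimationError("an instrument has zero exposure beta")
    ratios = by / bx
    w = bx ** 2 / so ** 2
    beta = float(np.sum(w * ratios) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    q = float(np.sum(w * (ratios - beta) ** 2))
    if model == "random":
        se *= max(1.0, math.sqrt(q / (len(ivs) - 1)))
    return MethodEstimate(method="ivw", beta=beta, se=se,
                          pval=_two_sided_normal_p(beta / se), nsnp=len(ivs),
                          extra={"cochran_q": q, "q_df": len(ivs) - 1,
                                 "model": model})


def mr_egger(ivs: Sequence[Instrument]) -> tuple[MethodEstimate, MethodEstimate]:
    """MR-Egger regression: weighted fit of beta_out on beta_exp with intercept.

    Instruments are first oriented so beta_exp >= 0 (flipping both members
    of a pair leaves the causal model unchanged).  Returns (slope,
    intercept) estimates; the intercept's p-value flags directional
    pleiotropy.  Inference uses the t reference on n-2 df.
    """
    if len(ivs) < 3:
        raise InsufficientInstrumentsError("MR-Egger needs >= 3 instruments")
    bx = np.array([iv.beta_exp for iv in ivs], dtype=float)
    by = np.array([iv.beta_out for iv in ivs], dtype=float)
    so = np.array([iv.se_out for iv in ivs], dtype=float)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    if np.ptp(bx) < 1e-14:
        raise EstimationError("all exposure betas identical: Egger design is singular")
    res = sm.WLS(by, sm.add_constant(bx), weights=1.0 / so ** 2).fit()
    df = len(ivs) - 2
    slope = MethodEstimate(
        method="mr_egger", beta=float(res.params[1]), se=float(res.bse[1]),
        pval=float(min(1.0, max(res.pvalues[1], 1e-300))), nsnp=len(ivs),
        extra={"df": df})
    intercept = MethodEstimate(
        method="egger_intercept", beta=float(res.params[0]), se=float(res.bse[0]),
        pval=float(min(1.0, max(res.pvalues[0], 1e-300))), nsnp=len(ivs),
        extra={"df": df})
    return slope, intercept


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - w / 2.0
    if cum[0] >= 0.5:
        return float(r[0])
    below = int(np.max(np.flatnonzero(cum < 0.5)))
    if below == len(r) - 1:
        return float(r[-1])
    frac = (0.5 - cum[below]) / (cum[below + 1] - cum[below])
    return float(r[below] + (r[below + 1] - r[below]) * frac)


def weighted_median(ivs: Sequence[Instrument], n_boot: int = 1000,
                    seed: int = 0) -> MethodEstimate:
    """Weighted median of per-IV Wald ratios, weights beta_exp^2/se_out^2.

    The point estimate interpolates the order statistics at cumulative
    weight 0.5; the SE comes from a parametric bootstrap that resamples
    (beta_exp, beta_out) from their Normal sampling distributions.
    """
    if len(ivs) < 3:
        raise InsufficientInstrumentsError("weighted median needs >= 3 instruments")
    bx = np.array([iv.beta_exp for iv in ivs])
    by = np.array([iv.beta_out for iv in ivs])
    sx = np.array([iv.se_exp for iv in ivs])
    so = np.array([iv.se_out for iv in ivs])
    if np.any(bx == 0):
        raise EstimationError("an instrument has zero exposure beta")
    beta = _weighted_median_point(by / bx, bx ** 2 / so ** 2)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = bx + sx * rng.standard_normal(len(ivs))
        by_b = by + so * rng.standard_normal(len(ivs))
        bx_b[bx_b == 0] = 1e-12
        boots[b] = _weighted_median_point(by_b / bx_b, bx_b ** 2 / so ** 2)
    se = float(np.std(boots, ddof=1))
    se = max(se, 1e-300)
    return MethodEstimate(method="weighted_median", beta=beta, se=se,
                          pval=_two_sided_normal_p(beta / se), nsnp=len(ivs),
                          extra={"n_boot": n_boot})


def steiger_test(iv: Instrument, n_exp: int, n_out: int) -> tuple[bool, float]:
    """Directionality check: does the instrument explain more variance in the
    exposure than in the outcome?

    Variance explained is ``r^2 = z^2 / (z^2 + n - 2)``; the p-value
    compares the two correlations via the Fisher z transform with variance
    ``1/(n_exp-3) + 1/(n_out-3)``.
    """
    if n_exp <= 3 or n_out <= 3:
        raise ParameterError("Steiger test needs sample sizes > 3")
    z_exp = iv.beta_exp / iv.se_exp
    z_out = iv.beta_out / iv.se_out
    r2_exp = z_exp ** 2 / (z_exp ** 2 + n_exp - 2)
    r2_out = z_out ** 2 / (z_out ** 2 + n_out - 2)
    fisher = (math.atanh(math.sqrt(r2_exp)) - math.atanh(math.sqrt(r2_out)))
    denom = math.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    pval = _two_sided_normal_p(fisher / denom)
    return bool(r2_exp > r2_out), pval


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def to_or_ci(beta: float, se: float) -> tuple[float, float, float]:
    """Odds-ratio scale reporting: exp(beta) with the Wald 95% CI."""
    if se < 0:
        raise ParameterError("se must be >= 0")
    return math.exp(beta), math.exp(beta - 1.96 * se), math.exp(beta + 1.96 * se)


def run_gene_mr(gene: str, ivs: Sequence[Instrument], ivw_model: str = "fixed",
                n_boot: int = 1000, seed: int = 0,
                steiger: bool = True) -> Optional[MrResult]:
    """Route one gene's instruments to the appropriate primary estimator.

    nsnp = 1 -> Wald ratio; nsnp >= 2 -> IVW; nsnp >= 3 additionally records
    MR-Egger and weighted-median sensitivity estimates.  Returns ``None``
    (gene skipped) when no kept instruments remain.  ``qval`` is set to
    ``pval`` here and replaced by the cross-gene BH adjustment in
    :func:`finalize_fdr`.
    """
    kept = [iv for iv in ivs if iv.kept]
    if not kept:
        return None
    sensitivity: dict = {}
    if len(kept) == 1:
        primary = wald_ratio(kept[0])
    else:
        primary = ivw(kept, model=ivw_model)
        sensitivity["cochran_q"] = primary.extra["cochran_q"]
        if len(kept) >= 3:
            try:
                slope, intercept = mr_egger(kept)
                sensitivity.update(egger_beta=slope.beta, egger_se=slope.se,
                                   egger_pval=slope.pval,
                                   egger_intercept=intercept.beta,
                                   egger_intercept_pval=intercept.pval)
            except EstimationError:
                sensitivity["egger_error"] = "singular design"
            wm = weighted_median(kept, n_boot=n_boot, seed=seed)
            sensitivity.update(wm_beta=wm.beta, wm_se=wm.se, wm_pval=wm.pval)

    steiger_flag: Optional[bool] = None
    if steiger:
        flags = []
        for iv in kept:
            if iv.n_exp and iv.n_out and iv.n_exp > 3 and iv.n_out > 3:
                flags.append(steiger_test(iv, iv.n_exp, iv.n_out)[0])
        if flags:
            steiger_flag = all(flags)

    or_point, ci_low, ci_high = to_or_ci(primary.beta, primary.se)
    return MrResult(gene=gene, method=primary.method, beta=primary.beta,
                    se=primary.se, pval=primary.pval, qval=primary.pval,
                    or_point=or_point, ci_low=ci_low, ci_high=ci_high,
                    nsnp=primary.nsnp, steiger_correct=steiger_flag,
                    sensitivity=sensitivity)


def finalize_fdr(results: Sequence[MrResult]) -> list[MrResult]:
    """Apply BH across genes (one family per exposure-dataset x outcome)."""
    if not results:
        return []
    q = bh_fdr([r.pval for r in results])
    for r, qv in zip(results, q):
        r.qval = float(qv)
    return list(results)
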