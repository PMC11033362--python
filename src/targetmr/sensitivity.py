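"""Heterogeneity, pleiotropy, outlier, and influence diagnostics.

An IVW estimate is only as credible as its instruments.  This module
implements the standard battery of checks that accompany a two-sample MR
result:

* :func:`cochran_q` — Cochran's Q heterogeneity statistic of the per-SNP
  Wald ratios around the IVW (df L-1) or Egger (df L-2) fit;
* :func:`egger_intercept_test` — the MR-Egger intercept as a test for
  directional (horizontal) pleiotropy;
* :func:`mr_presso` — a simulation-based residual test yielding a global
  heterogeneity p-value and per-SNP outlier flags (Bonferroni-corrected);
* :func:`leave_one_out` — the IVW estimate recomputed with each instrument
  removed in turn, to expose single-SNP leverage;
* :func:`sensitivity_report` — all of the above in one record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DegenerateWeightError,
    InsufficientInstrumentsError,
)
from .mr_core import MREstimate, egger, ivw, ratio_heterogeneity_q
from .summary_data import HarmonizedSet

logger = logging.getLogger(__name__)

__all__ = [
    "SensitivityReport",
    "cochran_q",
    "egger_intercept_test",
    "mr_presso",
    "leave_one_out",
    "sensitivity_report",
]


@dataclass
class SensitivityReport:
    """Bundle of diagnostics for one harmonised instrument set."""

    target: str
    q: float
    q_df: int
    q_pval: float
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_pval: float
    presso_global_pval: float
    presso_outliers: list[str]
    loo: list[dict] = field(default_factory=list)


def cochran_q(hset: HarmonizedSet, around: str = "ivw") -> tuple[float, int, float]:
    """Cochran's Q of the Wald ratios around a pooled fit.

    ``Q = sum_j w_j (by_j/bx_j - bhat_j)^2`` with ``w_j = bx_j^2/sy_j^2``
    and ``bhat_j`` the chosen fit's prediction on the ratio scale: the IVW
    slope (constant across SNPs, df = L-1) or the Egger line
    ``(a + b*bx_j)/bx_j`` (df = L-2).  The p-value is the upper chi-square
    tail.  The IVW flavour shares :func:`~targetmr.mr_core.ratio_heterogeneity_q`
    with the IVW variance model itself, so the Q used for diagnostics and
    the Q used to inflate the IVW SE are one computation.
    """
    L = hset.n_snp
    bx, by, sy = hset.bx, hset.by, hset.sy
    if np.any(sy == 0):
        raise DegenerateWeightError("cochran_q: zero outcome SE")
    if around == "ivw":
        if L < 2:
            raise InsufficientInstrumentsError("cochran_q(ivw): needs >= 2 SNPs")
        beta = ivw(hset, mode="fixed").beta
        q = ratio_heterogeneity_q(bx, by, sy, beta)
        df = L - 1
    elif around == "egger":
        if L < 3:
            raise InsufficientInstrumentsError("cochran_q(egger): needs >= 3 SNPs")
        slope_est, intercept = egger(hset)
        slope, a = slope_est.beta, intercept["estimate"]
        # residuals on the by scale weighted by 1/sy^2 == ratio-scale Q
        q = float(np.sum(((by - a - slope * bx) / sy) ** 2))
        df = L - 2
    else:
        raise ValueError(f"around must be 'ivw' or 'egger', got {around!r}")
    pval = float(stats.chi2.sf(q, df))
    return float(q), int(df), pval


def egger_intercept_test(hset: HarmonizedSet, alpha: float = 0.05) -> dict:
    """Directional-pleiotropy test via the MR-Egger intercept.

    Returns the intercept block of :func:`~targetmr.mr_core.egger` plus a
    boolean ``flagged`` at level ``alpha``: a non-zero intercept means the
    instruments' pleiotropic effects do not average out, biasing IVW.
    """
    _, intercept = egger(hset)
    return {
        "estimate": intercept["estimate"],
        "se": intercept["se"],
        "pval": intercept["pval"],
        "flagged": bool(intercept["pval"] < alpha),
    }


def _loo_slopes(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """IVW slope excluding each SNP in turn, vectorised.

    Works on 1-D arrays or on (n_sim x L) batches (excluding column j of
    each row).
    """
    w = 1.0 / (sy * sy)
    s_xy = np.sum(bx * by * w, axis=-1, keepdims=True)
    s_xx = np.sum(bx * bx * w, axis=-1, keepdims=True)
    return (s_xy - bx * by * w) / (s_xx - bx * bx * w)


def mr_presso(
    hset: HarmonizedSet,
    n_sim: int = 1_000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> dict:
    """Residual-based global heterogeneity and per-SNP outlier test.

    The observed statistic is the weighted residual sum of squares

    ``RSS_obs = sum_j (by_j - bx_j * bhat_(-j))^2 / sy_j^2``

    where ``bhat_(-j)`` is the IVW slope with SNP j excluded — each SNP is
    judged against a fit it did not influence.  The null distribution is
    built parametrically: ``n_sim`` times, draw ``bx* ~ N(bx, sx)`` and
    ``by* ~ N(bx * bhat_(-j), sy)`` and recompute the same statistic.  The
    global p-value is the (add-one) Monte-Carlo proportion of simulated RSS
    at or above the observed one; per-SNP outlier p-values compare each
    SNP's observed residual contribution with its simulated contributions,
    Bonferroni-adjusted across instruments.

    Monte-Carlo p-values use ``(1 + #exceedances) / (1 + n_sim)``, the
    standard positively biased estimator that can never return exactly
    zero.

    Returns a dict with ``global_pval``, ``outliers`` (snp_id list),
    ``outlier_pvals`` (Bonferroni-adjusted, per SNP), and ``rss_obs``.
    """
    L = hset.n_snp
    if L < 4:
        raise InsufficientInstrumentsError(f"mr_presso: needs >= 4 instruments, got {L}")
    if n_sim < 100:
        logger.warning("mr_presso: n_sim=%d is very small; p-values will be coarse", n_sim)
    bx, sx, by, sy = hset.bx, hset.sx, hset.by, hset.sy

    slopes_loo = _loo_slopes(bx, by, sy)
    contrib_obs = (by - bx * slopes_loo) ** 2 / (sy * sy)
    rss_obs = float(np.sum(contrib_obs))

    rng = np.random.default_rng(seed)
    BX = rng.normal(bx, sx, size=(n_sim, L))
    BY = rng.normal(bx * slopes_loo, sy, size=(n_sim, L))
    slopes_sim = _loo_slopes(BX, BY, sy)
    contrib_sim = (BY - BX * slopes_sim) ** 2 / (sy * sy)
    rss_sim = contrib_sim.sum(axis=1)

    global_pval = float((1 + np.sum(rss_sim >= rss_obs)) / (1 + n_sim))
    per_snp = (1 + np.sum(contrib_sim >= contrib_obs, axis=0)) / (1 + n_sim)
    adjusted = np.minimum(per_snp * L, 1.0)
    outliers = [s for s, p in zip(hset.snp_ids, adjusted) if p < outlier_alpha]
    return {
        "global_pval": global_pval,
        "outliers": outliers,
        "outlier_pvals": dict(zip(hset.snp_ids, adjusted.tolist())),
        "rss_obs": rss_obs,
    }


def leave_one_out(hset: HarmonizedSet, mode: str = "mre_floor") -> list[dict]:
    """IVW re-estimated with each instrument left out in turn.

    Returns one ``{"left_out_snp", "estimate"}`` record per input row, in
    input order.  Requires at least 3 instruments so every reduced set
    still supports an IVW fit.
    """
    if hset.n_snp < 3:
        raise InsufficientInstrumentsError(
            f"leave_one_out: needs >= 3 instruments, got {hset.n_snp}"
        )
    out = []
    for snp in hset.snp_ids:
        est = ivw(hset.drop_snp(snp), mode=mode)
        out.append({"left_out_snp": snp, "estimate": est})
    return out


def sensitivity_report(
    hset: HarmonizedSet,
    n_sim: int = 1_000,
    seed: int = 0,
    alpha: float = 0.05,
    ivw_mode: str = "mre_floor",
) -> SensitivityReport:
    """Run the full diagnostic battery on one harmonised set.

    Diagnostics whose instrument-count preconditions are not met are
    reported as NaN / empty rather than raising, so a thin target never
    aborts a multi-target run.
    """
    L = hset.n_snp
    q = q_df = q_pval = float("nan")
    if L >= 2:
        q, q_df, q_pval = cochran_q(hset, around="ivw")
    ei = {"estimate": float("nan"), "se": float("nan"), "pval": float("nan")}
    if L >= 3:
        ei = egger_intercept_test(hset, alpha=alpha)
    presso = {"global_pval": float("nan"), "outliers": []}
    if L >= 4:
        presso = mr_presso(hset, n_sim=n_sim, seed=seed, outlier_alpha=alpha)
    loo = leave_one_out(hset, mode=ivw_mode) if L >= 3 else []
    return SensitivityReport(
        target=hset.target,
        q=q,
        q_df=int(q_df) if not np.isnan(q_pval) else 0,
        q_pval=q_pval,
        egger_intercept=ei["estimate"],
        egger_intercept_se=ei["se"],
        egger_intercept_pval=ei["pval"],
        presso_global_pval=presso["global_pval"],
        presso_outliers=list(presso["outliers"]),
        loo=loo,
    )
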