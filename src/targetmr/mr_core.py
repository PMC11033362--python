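"""Two-sample MR estimators: Wald ratio, IVW, MR-Egger, weighted median.

All estimators consume a :class:`~targetmr.summary_data.HarmonizedSet` —
per-SNP exposure effects ``bx`` (SE ``sx``) and outcome effects ``by``
(SE ``sy``) aligned to a common effect allele — and return an
:class:`MREstimate` on the log-odds scale together with its odds-ratio
presentation.

Conventions
-----------
* IVW is the zero-intercept weighted regression of ``by`` on ``bx`` with
  weights ``1/sy^2``.  Its default variance is *multiplicative random
  effects floored at the fixed-effect value*: the fixed-effect SE is
  inflated by ``sqrt(Q/(L-1))`` only when that factor exceeds one, where Q
  is Cochran's heterogeneity statistic around the IVW fit.  Under
  homogeneity this reduces to the fixed-effect SE; under heterogeneity it
  matches the multiplicative random-effects model.
* MR-Egger adds a free intercept to the same weighted regression; its
  residual scale (L-2 df) is floored at one the same way, keeping the two
  estimators' uncertainty comparable.
* p-values are two-sided standard normal for all methods.
* The default 95% confidence interval uses the conventional multiplier
  1.96 (the reporting convention of standard MR tooling); other levels use
  the exact normal quantile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .exceptions import (
    ConfigurationError,
    DegenerateWeightError,
    DomainError,
    InsufficientInstrumentsError,
    UndefinedRatioError,
)
from .summary_data import HarmonizedSet

__all__ = [
    "MREstimate",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "to_odds_ratio",
    "ratio_heterogeneity_q",
    "IVW_MODES",
]

IVW_MODES = ("mre_floor", "fixed", "mre")


def _z_multiplier(level: float) -> float:
    """CI multiplier: 1.96 by convention at 95%, exact quantile otherwise."""
    if not 0 < level < 1:
        raise DomainError(f"confidence level must be in (0, 1), got {level}")
    if abs(level - 0.95) < 1e-12:
        return 1.96
    return float(stats.norm.ppf(0.5 + level / 2.0))


@dataclass
class MREstimate:
    """A causal estimate from one MR method.

    ``beta`` is on the log-odds (or linear outcome) scale; ``or_`` and the
    CI are its exponentiated presentation.
    """

    method: str
    beta: float
    se: float
    pval: float
    or_: float
    ci_low: float
    ci_high: float
    n_snp: int
    level: float = 0.95

    @classmethod
    def from_beta_se(
        cls, method: str, beta: float, se: float, n_snp: int, level: float = 0.95
    ) -> "MREstimate":
        if not se > 0:
            raise DegenerateWeightError(f"{method}: se must be positive, got {se}")
        or_, lo, hi = to_odds_ratio(beta, se, level)
        pval = float(2.0 * stats.norm.sf(abs(beta / se)))
        return cls(method, float(beta), float(se), pval, or_, lo, hi, int(n_snp), level)


def to_odds_ratio(beta: float, se: float, level: float = 0.95) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate: ``(OR, ci_low, ci_high)``."""
    if not se > 0:
        raise DomainError("se must be positive")
    z = _z_multiplier(level)
    return float(np.exp(beta)), float(np.exp(beta - z * se)), float(np.exp(beta + z * se))


def wald_ratio(
    beta_x: float, se_x: float, beta_y: float, se_y: float, level: float = 0.95
) -> MREstimate:
    """Single-instrument causal estimate ``beta_y / beta_x``.

    The SE is first-order (``se_y / |beta_x|``), ignoring the uncertainty
    of the exposure association — adequate for strong instruments, which is
    what the F filter guarantees.
    """
    if beta_x == 0:
        raise UndefinedRatioError("wald_ratio: beta_x is zero")
    beta = beta_y / beta_x
    se = se_y / abs(beta_x)
    return MREstimate.from_beta_se("wald", beta, se, n_snp=1, level=level)


def ratio_heterogeneity_q(
    bx: np.ndarray, by: np.ndarray, sy: np.ndarray, beta: float
) -> float:
    """Cochran's Q of the per-SNP Wald ratios around a pooled slope.

    ``Q = sum_j w_j (by_j/bx_j - beta)^2`` with ``w_j = bx_j^2 / sy_j^2``.
    This single routine is shared between the IVW variance model and the
    heterogeneity diagnostics so the two can never drift apart.
    """
    w = bx * bx / (sy * sy)
    return float(np.sum(w * (by / bx - beta) ** 2))


def ivw(hset: HarmonizedSet, mode: str = "mre_floor", level: float = 0.95) -> MREstimate:
    """Inverse-variance-weighted estimate for a harmonised set.

    A weighted regression of outcome betas on exposure betas through the
    origin with weights ``1/sy^2`` — equivalently, the inverse-variance
    meta-analysis of the per-SNP Wald ratios.  Variance model per ``mode``:

    ``fixed``
        the fixed-effect SE ``(sum bx^2/sy^2)^(-1/2)``;
    ``mre``
        fixed-effect SE times ``sqrt(Q/(L-1))`` (multiplicative random
        effects);
    ``mre_floor`` (default)
        fixed-effect SE times ``max(1, sqrt(Q/(L-1)))``.

    A single-SNP set delegates to :func:`wald_ratio`.
    """
    if mode not in IVW_MODES:
        raise ConfigurationError(f"unknown ivw mode {mode!r}; valid: {IVW_MODES}")
    L = hset.n_snp
    if L == 0:
        raise InsufficientInstrumentsError("ivw: empty instrument set")
    bx, by, sy = hset.bx, hset.by, hset.sy
    if np.any(sy == 0):
        raise DegenerateWeightError("ivw: zero outcome SE gives infinite weight")
    if L == 1:
        est = wald_ratio(bx[0], hset.sx[0], by[0], sy[0], level=level)
        return MREstimate("ivw", est.beta, est.se, est.pval, est.or_,
                          est.ci_low, est.ci_high, 1, level)
    w = 1.0 / (sy * sy)
    s_xy = float(np.sum(bx * by * w))
    s_xx = float(np.sum(bx * bx * w))
    beta = s_xy / s_xx
    se_fixed = s_xx ** -0.5
    q = ratio_heterogeneity_q(bx, by, sy, beta)
    phi = np.sqrt(q / (L - 1))
    if mode == "fixed":
        se = se_fixed
    elif mode == "mre":
        se = se_fixed * phi
    else:
        se = se_fixed * max(1.0, phi)
    return MREstimate.from_beta_se("ivw", beta, se, n_snp=L, level=level)


def egger(
    hset: HarmonizedSet, level: float = 0.95
) -> tuple[MREstimate, dict[str, float]]:
    """MR-Egger regression: slope (causal effect) and intercept (pleiotropy).

    Weighted least squares of ``by`` on ``bx`` with a free intercept and
    weights ``1/sy^2``, fitted with statsmodels.  The residual scale (L-2
    df) multiplies both coefficient SEs only when it exceeds one — the same
    floor convention as the default IVW, so slope and intercept
    uncertainties stay on a comparable footing.  An intercept distinguishable
    from zero indicates directional pleiotropy.

    Returns the slope as an :class:`MREstimate` and the intercept as a dict
    with keys ``estimate``, ``se``, ``pval``.
    """
    L = hset.n_snp
    if L < 3:
        raise InsufficientInstrumentsError(
            f"egger: needs >= 3 instruments, got {L}"
        )
    bx, by, sy = hset.bx, hset.by, hset.sy
    if np.any(sy == 0):
        raise DegenerateWeightError("egger: zero outcome SE gives infinite weight")
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=1.0 / (sy * sy)).fit()
    sigma2 = float(fit.scale)  # weighted SSR / (L - 2)
    # Unscaled SEs from (X'WX)^-1, then the floored residual scale on top
    # (avoids 0/0 when the fit is exact).
    se_unscaled = np.sqrt(np.diag(fit.normalized_cov_params))
    se_int, se_slope = (float(v) * max(1.0, np.sqrt(sigma2)) for v in se_unscaled)
    a, b = (float(v) for v in fit.params)
    slope = MREstimate.from_beta_se("egger", b, se_slope, n_snp=L, level=level)
    intercept = {
        "estimate": a,
        "se": se_int,
        "pval": float(2.0 * stats.norm.sf(abs(a / se_int))) if se_int > 0 else float("nan"),
    }
    return slope, intercept


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median with linear interpolation at the half-weight point.

    Sort values ascending; with normalised weights ``w`` the cumulative
    position of value ``i`` is ``cum_i = sum(w[:i+1]) - w[i]/2``.  The
    estimate interpolates linearly between the two values whose cumulative
    positions bracket 1/2 (clamping to the extremes outside the range).
    For equal weights and odd length this is the plain median.
    """
    order = np.argsort(values)
    v = values[order]
    w = weights[order] / np.sum(weights)
    cum = np.cumsum(w) - w / 2.0
    if 0.5 <= cum[0]:
        return float(v[0])
    if 0.5 >= cum[-1]:
        return float(v[-1])
    i = int(np.searchsorted(cum, 0.5, side="right")) - 1
    if cum[i] == 0.5:
        return float(v[i])
    return float(v[i] + (v[i + 1] - v[i]) * (0.5 - cum[i]) / (cum[i + 1] - cum[i]))


def _weighted_median_batch(V: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Row-wise weighted medians (same rule as :func:`_weighted_median`)."""
    order = np.argsort(V, axis=1)
    v = np.take_along_axis(V, order, axis=1)
    w = np.take_along_axis(W, order, axis=1)
    w = w / w.sum(axis=1, keepdims=True)
    cum = np.cumsum(w, axis=1) - w / 2.0
    n, L = v.shape
    # index of the last cumulative position <= 1/2 (clamped)
    idx = np.sum(cum < 0.5, axis=1) - 1
    lo_clamp = idx < 0
    hi_clamp = idx >= L - 1
    idx = np.clip(idx, 0, L - 2)
    rows = np.arange(n)
    c0, c1 = cum[rows, idx], cum[rows, idx + 1]
    v0, v1 = v[rows, idx], v[rows, idx + 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(c1 > c0, (0.5 - c0) / (c1 - c0), 0.0)
    out = v0 + (v1 - v0) * frac
    out = np.where(lo_clamp, v[:, 0], out)
    out = np.where(hi_clamp & (cum[:, -1] <= 0.5), v[:, -1], out)
    return out


def weighted_median(
    hset: HarmonizedSet,
    n_boot: int = 10_000,
    seed: int = 0,
    level: float = 0.95,
) -> MREstimate:
    """Weighted-median estimate with parametric-bootstrap SE.

    The point estimate is the weighted median of the per-SNP Wald ratios
    with weights ``bx^2/sy^2`` (inverse variance of each ratio,
    first-order); it is consistent when instruments carrying at least half
    the weight are valid.  The SE is the standard deviation of the
    statistic over ``n_boot`` parametric resamples, drawing ``bx*`` and
    ``by*`` normal around the observed values with the observed SEs —
    seeded, hence reproducible.
    """
    if n_boot <= 0:
        raise ConfigurationError("n_boot must be positive")
    L = hset.n_snp
    if L < 3:
        raise InsufficientInstrumentsError(
            f"weighted_median: needs >= 3 instruments, got {L}"
        )
    bx, sx, by, sy = hset.bx, hset.sx, hset.by, hset.sy
    point = _weighted_median(by / bx, bx * bx / (sy * sy))

    rng = np.random.default_rng(seed)
    BX = rng.normal(bx, sx, size=(n_boot, L))
    BY = rng.normal(by, sy, size=(n_boot, L))
    with np.errstate(divide="ignore", invalid="ignore"):
        R = BY / BX
        W = BX * BX / (sy * sy)
    boot = _weighted_median_batch(R, W)
    se = float(np.std(boot, ddof=1))
    return MREstimate.from_beta_se("weighted_median", point, se, n_snp=L, level=level)
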