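"""Two-sample Mendelian randomization estimators and heterogeneity statistics.

All estimators consume a :class:`~protmr.instruments.HarmonizedSet` and return
:class:`MREstimate` records on the log-odds (or outcome-unit) scale, with the
odds ratio and its confidence bounds exponentiated for reporting. The suite:

- Wald ratio (single instrument),
- inverse-variance-weighted (IVW) meta-analysis, fixed- or multiplicative
  random-effects, with automatic switching on Cochran's Q,
- MR-Egger weighted regression with intercept (pleiotropy) test,
- weighted median and weighted mode with parametric-bootstrap SEs,
- Cochran's Q / I² heterogeneity,
- Benjamini-Hochberg FDR across exposures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from protmr.instruments import HarmonizedSet, InsufficientInstrumentsError

logger = logging.getLogger(__name__)

Z_975 = float(stats.norm.ppf(0.975))  # 1.959964...

MIN_SNPS_MEDIAN = 3
MIN_SNPS_EGGER = 3


class DegenerateInstrumentError(ValueError):
    """An instrument with zero exposure effect cannot form a Wald ratio."""


@dataclass
class MREstimate:
    """One method's causal estimate on the log scale, with OR and 95% CI."""

    method: str
    n_snp: int
    beta: float
    se: float
    pval: float
    ci_low: float = dc_field(init=False)
    ci_high: float = dc_field(init=False)
    or_: float = dc_field(init=False)
    or_low: float = dc_field(init=False)
    or_high: float = dc_field(init=False)
    extra: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("MREstimate: se must be positive")
        self.ci_low = self.beta - Z_975 * self.se
        self.ci_high = self.beta + Z_975 * self.se
        self.or_ = float(np.exp(self.beta))
        self.or_low = float(np.exp(self.ci_low))
        self.or_high = float(np.exp(self.ci_high))


@dataclass
class HeterogeneityResult:
    """Cochran's Q with its chi-square p-value and the I² statistic."""

    q: float
    df: int
    pval: float
    i2: float


def _ratios(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant Wald ratios and their first-order delta SEs."""
    if np.any(h.beta_exp == 0):
        raise DegenerateInstrumentError("zero exposure effect among instruments")
    theta = h.beta_out / h.beta_exp
    se = h.se_out / np.abs(h.beta_exp)
    return theta, se


def wald_ratio(h: HarmonizedSet, second_order: bool = False) -> MREstimate:
    """Single-instrument causal estimate: beta_out / beta_exp.

    SE by the first-order delta method (outcome SE only); ``second_order``
    adds the exposure-uncertainty term
    sqrt(se_out²/beta_exp² + beta_out²·se_exp²/beta_exp⁴).
    """
    if len(h) != 1:
        raise ValueError(f"wald_ratio needs exactly 1 variant, got {len(h)}")
    bx, by = float(h.beta_exp[0]), float(h.beta_out[0])
    if bx == 0:
        raise DegenerateInstrumentError(f"{h.variant_ids[0]}: exposure beta is 0")
    beta = by / bx
    if second_order:
        se = float(np.sqrt(h.se_out[0] ** 2 / bx**2 + by**2 * h.se_exp[0] ** 2 / bx**4))
    else:
        se = float(h.se_out[0] / abs(bx))
    pval = float(2 * stats.norm.sf(abs(beta / se)))
    return MREstimate(method="wald", n_snp=1, beta=beta, se=se, pval=max(pval, np.nextafter(0, 1)))


def _ivw_core(h: HarmonizedSet) -> tuple[float, float, float, int]:
    """Fixed-effect IVW point estimate, SE, Cochran's Q and df."""
    theta, theta_se = _ratios(h)
    w = 1.0 / theta_se**2  # = beta_exp^2 / se_out^2
    beta = float(np.sum(w * theta) / np.sum(w))
    se_fe = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (theta - beta) ** 2))
    return beta, se_fe, q, len(h) - 1


def ivw(h: HarmonizedSet, model: str = "auto") -> MREstimate:
    """Inverse-variance-weighted estimate across instruments.

    The fixed-effect estimate is the precision-weighted mean of per-variant
    Wald ratios (equivalently the zero-intercept WLS slope of beta_out on
    beta_exp with weights se_out⁻²). ``model='random'`` inflates the SE by
    max(1, sqrt(Q/(J−1))); ``'auto'`` switches to random effects when the
    Cochran's Q p-value is ≤ 0.05. A single instrument delegates to
    :func:`wald_ratio`.
    """
    if model not in ("fixed", "random", "auto"):
        raise ValueError(f"model must be fixed|random|auto, got {model}")
    if len(h) == 0:
        raise InsufficientInstrumentsError("empty harmonized set")
    if len(h) == 1:
        return wald_ratio(h)
    beta, se_fe, q, df = _ivw_core(h)
    q_pval = float(stats.chi2.sf(q, df)) if df > 0 else 1.0
    use_random = model == "random" or (model == "auto" and q_pval <= 0.05)
    inflation = max(1.0, float(np.sqrt(q / df))) if df > 0 else 1.0
    se = se_fe * inflation if use_random else se_fe
    pval = float(2 * stats.norm.sf(abs(beta / se)))
    return MREstimate(
        method="ivw_re" if use_random else "ivw_fe",
        n_snp=len(h),
        beta=beta,
        se=se,
        pval=max(pval, np.nextafter(0, 1)),
        extra={"model": "random" if use_random else "fixed", "q": q, "q_pval": q_pval},
    )


def cochran_q(h: HarmonizedSet, at: MREstimate) -> HeterogeneityResult:
    """Cochran's Q heterogeneity of per-variant ratios around an estimate.

    Degrees of freedom are J−1, or J−2 when the reference estimate is an
    Egger regression (one extra fitted parameter).
    """
    if len(h) < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs >=2 variants")
    theta, theta_se = _ratios(h)
    w = 1.0 / theta_se**2
    q = float(np.sum(w * (theta - at.beta) ** 2))
    df = len(h) - (2 if at.method == "egger" else 1)
    pval = float(stats.chi2.sf(q, df)) if df > 0 else 1.0
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return HeterogeneityResult(q=q, df=df, pval=pval, i2=i2)


@dataclass
class EggerIntercept:
    """The MR-Egger intercept: the average directional pleiotropy test."""

    value: float
    se: float
    pval: float


def mr_egger(h: HarmonizedSet, constrain_intercept: bool = False) -> tuple[MREstimate, EggerIntercept]:
    """MR-Egger: weighted regression of outcome effects on exposure effects
    with a free intercept capturing average directional pleiotropy.

    Variants are oriented so beta_exp ≥ 0; weights are se_out⁻². SEs are
    inflated by max(1, sqrt(Q_egger/(J−2))) and p-values use t(J−2).
    ``constrain_intercept`` (test hook) forces the intercept to 0, which
    reproduces the fixed-effect IVW slope.
    """
    j = len(h)
    if j < MIN_SNPS_EGGER:
        raise InsufficientInstrumentsError(f"MR-Egger needs >={MIN_SNPS_EGGER} variants, got {j}")
    sign = np.where(h.beta_exp < 0, -1.0, 1.0)
    x = h.beta_exp * sign
    y = h.beta_out * sign
    w = 1.0 / h.se_out**2
    if not constrain_intercept and np.allclose(x, x[0]):
        raise ValueError("MR-Egger: no spread in |beta_exp| (collinear design)")

    if constrain_intercept:
        slope = float(np.sum(w * x * y) / np.sum(w * x**2))
        se_slope = float(1.0 / np.sqrt(np.sum(w * x**2)))
        resid_df = j - 1
        intercept = inter_se = 0.0
        rss = float(np.sum(w * (y - slope * x) ** 2))
    else:
        sw, swx, swy = np.sum(w), np.sum(w * x), np.sum(w * y)
        swxx, swxy = np.sum(w * x * x), np.sum(w * x * y)
        det = sw * swxx - swx**2
        slope = float((sw * swxy - swx * swy) / det)
        intercept = float((swxx * swy - swx * swxy) / det)
        se_slope = float(np.sqrt(sw / det))
        inter_se = float(np.sqrt(swxx / det))
        resid_df = j - 2
        rss = float(np.sum(w * (y - intercept - slope * x) ** 2))

    inflation = max(1.0, float(np.sqrt(rss / resid_df))) if resid_df > 0 else 1.0
    se_slope *= inflation
    inter_se *= inflation
    slope_p = float(2 * stats.t.sf(abs(slope / se_slope), resid_df)) if resid_df > 0 else 1.0
    inter_p = (
        float(2 * stats.t.sf(abs(intercept / inter_se), resid_df))
        if (resid_df > 0 and inter_se > 0)
        else 1.0
    )
    est = MREstimate(
        method="egger",
        n_snp=j,
        beta=slope,
        se=se_slope,
        pval=max(slope_p, np.nextafter(0, 1)),
        extra={"intercept": intercept, "intercept_se": inter_se, "intercept_pval": inter_p, "q_egger": rss},
    )
    return est, EggerIntercept(value=intercept, se=inter_se, pval=inter_p)


def _weighted_median_point(theta: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by cumulative-midpoint linear interpolation."""
    order = np.argsort(theta, kind="stable")
    t = theta[order]
    w = weights[order] / np.sum(weights)
    p = np.cumsum(w) - w / 2
    if 0.5 <= p[0]:
        return float(t[0])
    if 0.5 >= p[-1]:
        return float(t[-1])
    return float(np.interp(0.5, p, t))


def _parametric_boot(
    h: HarmonizedSet,
    point_fn,
    n_boot: int,
    rng: np.random.Generator,
) -> float:
    """SE of a ratio-based estimator over parametric resamples of the inputs."""
    bx = rng.normal(h.beta_exp, h.se_exp, size=(n_boot, len(h)))
    by = rng.normal(h.beta_out, h.se_out, size=(n_boot, len(h)))
    bx = np.where(bx == 0, np.finfo(float).tiny, bx)
    ests = np.empty(n_boot)
    for i in range(n_boot):
        theta = by[i] / bx[i]
        w = (bx[i] / h.se_out) ** 2
        ests[i] = point_fn(theta, w)
    return float(np.std(ests, ddof=1))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int | None = None) -> MREstimate:
    """Weighted-median estimator: consistent when instruments carrying at
    least half the weight are valid. SE by seeded parametric bootstrap.
    """
    if len(h) < MIN_SNPS_MEDIAN:
        raise InsufficientInstrumentsError(f"weighted median needs >={MIN_SNPS_MEDIAN} variants")
    theta, theta_se = _ratios(h)
    w = 1.0 / theta_se**2
    beta = _weighted_median_point(theta, w)
    rng = np.random.default_rng(seed)
    se = _parametric_boot(h, _weighted_median_point, n_boot, rng)
    if se <= 0:
        se = np.finfo(float).tiny
    pval = float(2 * stats.norm.sf(abs(beta / se)))
    return MREstimate(
        method="weighted_median", n_snp=len(h), beta=beta, se=se, pval=max(pval, np.nextafter(0, 1))
    )


def _mode_point(
    theta: np.ndarray,
    weights: np.ndarray,
    bandwidth_factor: float = 1.0,
    grid_size: int = 512,
) -> float:
    """Argmax of the weighted normal-kernel density of the ratios."""
    w = weights / np.sum(weights)
    sd = float(np.std(theta, ddof=1)) if theta.size > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(theta, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    bw = bandwidth_factor * 0.9 * spread * theta.size ** (-1 / 5)
    if bw <= 0:
        # all ratios identical (or numerically so): the mode is that ratio
        return float(np.average(theta, weights=w))
    lo, hi = theta.min() - 3 * bw, theta.max() + 3 * bw
    grid = np.linspace(lo, hi, grid_size)
    dens = np.sum(w[None, :] * np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / bw) ** 2), axis=1)
    return float(grid[np.argmax(dens)])


def weighted_mode(
    h: HarmonizedSet,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Weighted-mode estimator: consistent when the largest group of
    instruments sharing a ratio is valid, even if not a majority.
    """
    if len(h) < MIN_SNPS_MEDIAN:
        raise InsufficientInstrumentsError(f"weighted mode needs >={MIN_SNPS_MEDIAN} variants")
    theta, theta_se = _ratios(h)
    w = 1.0 / theta_se**2
    beta = _mode_point(theta, w, bandwidth_factor)
    rng = np.random.default_rng(seed)
    se = _parametric_boot(
        h, lambda t, wt: _mode_point(t, wt, bandwidth_factor), n_boot, rng
    )
    if se <= 0:
        logger.info("weighted mode: degenerate bootstrap SE, flooring")
        se = np.finfo(float).tiny
    pval = float(2 * stats.norm.sf(abs(beta / se)))
    return MREstimate(
        method="weighted_mode", n_snp=len(h), beta=beta, se=se, pval=max(pval, np.nextafter(0, 1))
    )


def estimate_all(
    h: HarmonizedSet,
    seed: int | None = None,
    n_boot: int = 1000,
    bandwidth_factor: float = 1.0,
) -> tuple[list[MREstimate], HeterogeneityResult | None]:
    """Run every estimator applicable at this instrument count.

    J=1: Wald ratio only. J≥2 adds IVW (auto model) and heterogeneity.
    J≥3 adds MR-Egger, weighted median and weighted mode, with the bootstrap
    seeds split deterministically from ``seed``.
    """
    if len(h) == 0:
        raise InsufficientInstrumentsError("empty harmonized set")
    if len(h) == 1:
        return [wald_ratio(h)], None
    results: list[MREstimate] = []
    est_ivw = ivw(h, model="auto")
    results.append(est_ivw)
    het = cochran_q(h, est_ivw)
    if len(h) >= MIN_SNPS_MEDIAN:
        seeds = np.random.SeedSequence(seed).spawn(2)
        results.append(weighted_median(h, n_boot=n_boot, seed=seeds[0]))
        results.append(weighted_mode(h, bandwidth_factor=bandwidth_factor, n_boot=n_boot, seed=seeds[1]))
        slope, _ = mr_egger(h)
        results.append(slope)
    return results, het


def bh_fdr(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_i = min over j with p_j ≥ p_i of m·p_j/rank_j, capped at 1; monotone
    nondecreasing in p.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
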