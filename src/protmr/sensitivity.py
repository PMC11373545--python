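"""Sensitivity analyses for the MR estimates: leave-one-out, the MR-PRESSO
global/outlier/distortion resampling tests, funnel-plot data, and the Egger
intercept pleiotropy report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from protmr.instruments import HarmonizedSet, InsufficientInstrumentsError
from protmr.mr_core import EggerIntercept, MREstimate, _ratios, ivw, mr_egger, wald_ratio

logger = logging.getLogger(__name__)


def leave_one_out(h: HarmonizedSet, model: str = "auto") -> pd.DataFrame:
    """IVW re-estimated with each instrument excluded in turn.

    Returns J+1 rows: one per excluded variant plus the all-instrument row
    (excluded = 'none').
    """
    j = len(h)
    if j < 3:
        raise InsufficientInstrumentsError("leave-one-out needs >=3 variants")
    rows = []
    for i in range(j):
        mask = np.ones(j, dtype=bool)
        mask[i] = False
        est = ivw(h.subset(mask), model=model)
        rows.append(
            {"excluded": h.variant_ids[i], "n_snp": est.n_snp, "beta": est.beta, "se": est.se, "pval": est.pval}
        )
    full = ivw(h, model=model)
    rows.append({"excluded": "none", "n_snp": full.n_snp, "beta": full.beta, "se": full.se, "pval": full.pval})
    return pd.DataFrame(rows)


@dataclass
class PressoResult:
    """MR-PRESSO output: observed residual sum of squares, the simulated
    global test, per-variant outlier tests, and the outlier-corrected IVW."""

    rss_obs: float
    global_p: float
    outlier_pvals: dict[str, float]
    outlier_ids: list[str]
    corrected: MREstimate | None
    distortion_p: float | None
    n_sim: int
    seed: int | None


def _loo_expected(beta_exp: np.ndarray, beta_out: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes times own beta_exp: the PRESSO expectations.

    Works on 1-D observed arrays or 2-D (n_sim x J) simulated arrays.
    """
    num = np.sum(w * beta_exp * beta_out, axis=-1, keepdims=True) - w * beta_exp * beta_out
    den = np.sum(w * beta_exp**2, axis=-1, keepdims=True) - w * beta_exp**2
    return num / den * beta_exp


def presso(
    h: HarmonizedSet,
    n_sim: int = 1000,
    seed: int | None = None,
    outlier_alpha: float = 0.05,
    distortion: bool = False,
) -> PressoResult:
    """MR-PRESSO: residual-sum-of-squares pleiotropy test with outlier
    detection and correction.

    Each variant's expected outcome effect is the leave-one-out IVW slope
    times its exposure effect; the observed weighted residual sum of squares
    is compared against ``n_sim`` parametric simulations drawn under the
    no-pleiotropy model. Per-variant outlier p-values are the empirical tails
    of each weighted squared residual, Bonferroni-multiplied by J; the
    corrected estimate is IVW on the non-outliers. Empirical p-values use the
    (1+k)/(n+1) correction.
    """
    j = len(h)
    if j < 4:
        raise InsufficientInstrumentsError("MR-PRESSO needs >=4 variants")
    w = 1.0 / h.se_out**2
    expected = _loo_expected(h.beta_exp, h.beta_out, w)
    resid_obs = w * (h.beta_out - expected) ** 2
    rss_obs = float(np.sum(resid_obs))

    rng = np.random.default_rng(seed)
    bx = rng.normal(h.beta_exp, h.se_exp, size=(n_sim, j))
    by = rng.normal(expected, h.se_out, size=(n_sim, j))
    expected_sim = _loo_expected(bx, by, w[None, :])
    resid_sim = w[None, :] * (by - expected_sim) ** 2
    rss_sim = np.sum(resid_sim, axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    raw = (1 + np.sum(resid_sim >= resid_obs[None, :], axis=0)) / (n_sim + 1)
    adj = np.minimum(raw * j, 1.0)
    outlier_pvals = dict(zip(h.variant_ids, adj.astype(float)))
    outlier_mask = adj < outlier_alpha
    outlier_ids = [v for v, flag in zip(h.variant_ids, outlier_mask) if flag]

    corrected: MREstimate | None = None
    distortion_p: float | None = None
    if outlier_ids:
        keep = ~outlier_mask
        if keep.sum() >= 1:
            sub = h.subset(keep)
            base = ivw(sub, model="auto") if len(sub) > 1 else wald_ratio(sub)
            corrected = MREstimate(
                method="presso_corrected", n_snp=base.n_snp, beta=base.beta,
                se=base.se, pval=base.pval, extra={"base_method": base.method},
            )
            if distortion and keep.sum() >= 2:
                distortion_p = _distortion_test(h, int(outlier_mask.sum()), corrected, rng, n_sim)
        else:
            logger.warning("MR-PRESSO flagged every instrument; no corrected estimate")
    return PressoResult(
        rss_obs=rss_obs,
        global_p=global_p,
        outlier_pvals=outlier_pvals,
        outlier_ids=outlier_ids,
        corrected=corrected,
        distortion_p=distortion_p,
        n_sim=n_sim,
        seed=seed,
    )


def _distortion_test(
    h: HarmonizedSet,
    n_out: int,
    corrected: MREstimate,
    rng: np.random.Generator,
    n_sim: int,
) -> float:
    """Compare the outlier-corrected slope shift against random-removal shifts."""
    full = ivw(h, model="auto")
    if full.beta == 0:
        return 1.0
    d_obs = abs((corrected.beta - full.beta) / full.beta)
    j = len(h)
    shifts = np.empty(n_sim)
    for i in range(n_sim):
        drop = rng.choice(j, size=n_out, replace=False)
        mask = np.ones(j, dtype=bool)
        mask[drop] = False
        sub = h.subset(mask)
        est = ivw(sub, model="auto") if len(sub) > 1 else wald_ratio(sub)
        shifts[i] = abs((est.beta - full.beta) / full.beta)
    return float((1 + np.sum(shifts >= d_obs)) / (n_sim + 1))


def funnel_data(h: HarmonizedSet) -> pd.DataFrame:
    """Per-instrument Wald ratio against its precision (1/SE) for funnel plots."""
    if len(h) < 1:
        raise InsufficientInstrumentsError("funnel needs >=1 variant")
    theta, theta_se = _ratios(h)
    return pd.DataFrame(
        {"variant_id": h.variant_ids, "theta": theta, "precision": 1.0 / theta_se}
    )


def pleiotropy_report(h: HarmonizedSet) -> EggerIntercept:
    """The MR-Egger intercept (value, SE, p) as the horizontal-pleiotropy test."""
    _, intercept = mr_egger(h)
    return intercept
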