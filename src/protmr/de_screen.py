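"""Differential-expression screen on the protein-array matrix.

Intensities are log2-transformed before testing; the log2 fold change is the
difference of group means of log2 values (the log2 ratio of geometric means).
A protein is a DEP when its two-sided p-value is below ``p_threshold`` and
|log2FC| exceeds ``fc_threshold`` (default 0.263, i.e. a 1.2-fold change).
BH q-values are computed alongside but do not enter the DEP rule.

Two tests are available: a plain Welch t-test on log2 intensities, and a
moderated t-test that shrinks each protein's pooled variance toward the
across-protein mean variance with an empirical-Bayes weight fit by the method
of moments on the log sample variances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from protmr.core_io import ExpressionMatrix
from protmr.mr_core import bh_fdr

logger = logging.getLogger(__name__)

FC_THRESHOLD_DEFAULT = 0.263  # |log2FC| > 0.263  <=>  FC > 1.2 or FC < 0.83
P_THRESHOLD_DEFAULT = 0.05
P_FLOOR_DEFAULT = 1e-300


@dataclass
class DEResult:
    """Per-protein screen outcome: effect size, p, q and DEP class."""

    protein_id: str
    log2fc: float
    pval: float
    qval: float | None
    de_class: str  # up | down | ns


def _log2_values(m: ExpressionMatrix, values_are_log2: bool) -> np.ndarray:
    if values_are_log2:
        return m.values
    if np.any(m.values <= 0):
        raise ValueError("nonpositive intensity; cannot log2-transform")
    return np.log2(m.values)


def log2_fold_change(
    m: ExpressionMatrix,
    protein_id: str,
    values_are_log2: bool = False,
    ratio_of_means: bool = False,
) -> float:
    """log2 fold change case vs control for one protein.

    Default: difference of group means of log2 intensities. With
    ``ratio_of_means`` the log2 of the ratio of arithmetic group means is used
    instead.
    """
    x = m.row(protein_id)
    case = m.case_mask
    if ratio_of_means:
        vals = 2.0**x if values_are_log2 else x
        if np.any(vals <= 0):
            raise ValueError(f"{protein_id}: nonpositive intensity")
        return float(np.log2(vals[case].mean() / vals[~case].mean()))
    if not values_are_log2 and np.any(x <= 0):
        raise ValueError(f"{protein_id}: nonpositive intensity")
    lx = np.log2(x) if not values_are_log2 else x
    return float(lx[case].mean() - lx[~case].mean())


def _welch_pvals(log2v: np.ndarray, case: np.ndarray) -> np.ndarray:
    a, b = log2v[:, case], log2v[:, ~case]
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups with equal means: undefined t -> p = 1
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        logger.info("%d proteins with degenerate variance; p set to 1", int(degenerate.sum()))
        p = np.where(degenerate, 1.0, p)
    return p


def _fit_d0(log_s2: np.ndarray, d: float) -> float:
    """Prior degrees of freedom by method of moments on log sample variances.

    Var(log s²) = trigamma(d/2) + trigamma(d0/2) under the scaled chi-square
    model; solve for d0, returning inf (full shrinkage) when the observed
    spread is no larger than the sampling component.
    """
    excess = float(np.var(log_s2, ddof=1)) - float(special.polygamma(1, d / 2))
    if excess <= 1e-10:
        return np.inf
    sol = optimize.brentq(lambda v: special.polygamma(1, v / 2) - excess, 1e-6, 1e8)
    return float(sol)


def _moderated_pvals(log2v: np.ndarray, case: np.ndarray) -> np.ndarray:
    n1, n2 = int(case.sum()), int((~case).sum())
    d = n1 + n2 - 2
    a, b = log2v[:, case], log2v[:, ~case]
    diff = a.mean(axis=1) - b.mean(axis=1)
    s2 = ((n1 - 1) * a.var(axis=1, ddof=1) + (n2 - 1) * b.var(axis=1, ddof=1)) / d
    positive = s2 > 0
    if positive.sum() >= 2:
        log_s2 = np.log(s2[positive])
        d0 = _fit_d0(log_s2, d)
        # prior scale on the log scale: under s0^2 * F(d, d0) the mean of
        # log s^2 is log s0^2 + (psi(d/2) - log(d/2)) - (psi(d0/2) - log(d0/2))
        corr = float(special.digamma(d / 2) - np.log(d / 2))
        if np.isfinite(d0):
            corr -= float(special.digamma(d0 / 2) - np.log(d0 / 2))
        s0_2 = float(np.exp(np.mean(log_s2) - corr))
    else:
        d0 = np.inf
        s0_2 = float(s2.mean())
    if np.isinf(d0):
        s2_mod = np.full_like(s2, s0_2)
        df_mod = 1e6  # effectively normal
    else:
        wgt = d0 / (d0 + d)
        s2_mod = wgt * s0_2 + (1 - wgt) * s2
        df_mod = d + d0
    se = np.sqrt(s2_mod * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    p = 2 * stats.t.sf(np.abs(t), df_mod)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        p = np.where(degenerate, 1.0, p)
    return np.asarray(p, dtype=float)


def de_test(
    m: ExpressionMatrix,
    protein_id: str,
    method: str = "welch",
    values_are_log2: bool = False,
) -> float:
    """Two-sided p-value comparing group means of log2 intensities."""
    p = de_test_all(m, method=method, values_are_log2=values_are_log2)
    return float(p[m.protein_ids.index(protein_id)])


def de_test_all(
    m: ExpressionMatrix,
    method: str = "welch",
    values_are_log2: bool = False,
) -> np.ndarray:
    """Vectorized per-protein p-values for the whole matrix."""
    if method not in ("welch", "moderated"):
        raise ValueError(f"method must be welch|moderated, got {method}")
    log2v = _log2_values(m, values_are_log2)
    case = m.case_mask
    if method == "welch":
        return _welch_pvals(log2v, case)
    return _moderated_pvals(log2v, case)


def screen(
    m: ExpressionMatrix,
    method: str = "welch",
    fc_threshold: float = FC_THRESHOLD_DEFAULT,
    p_threshold: float = P_THRESHOLD_DEFAULT,
    values_are_log2: bool = False,
) -> list[DEResult]:
    """Full screen: log2FC + test + DEP classification for every protein."""
    log2v = _log2_values(m, values_are_log2)
    case = m.case_mask
    log2fc = log2v[:, case].mean(axis=1) - log2v[:, ~case].mean(axis=1)
    pvals = de_test_all(m, method=method, values_are_log2=values_are_log2)
    triples = list(zip(m.protein_ids, log2fc.astype(float), pvals.astype(float)))
    return classify_deps(triples, fc_threshold=fc_threshold, p_threshold=p_threshold)


def classify_deps(
    results: list[tuple[str, float, float]],
    fc_threshold: float = FC_THRESHOLD_DEFAULT,
    p_threshold: float = P_THRESHOLD_DEFAULT,
) -> list[DEResult]:
    """Assign up/down/ns classes from (protein_id, log2fc, pval) triples.

    up: log2fc > fc_threshold and p < p_threshold; down: log2fc < −fc_threshold
    and p < p_threshold; ns otherwise. BH q-values are attached for reporting
    but do not affect the class.
    """
    if fc_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be positive")
    if not results:
        return []
    pvals = np.array([p for _, _, p in results])
    qvals = bh_fdr(pvals)
    out = []
    for (pid, fc, p), q in zip(results, qvals):
        if p < p_threshold and fc > fc_threshold:
            cls = "up"
        elif p < p_threshold and fc < -fc_threshold:
            cls = "down"
        else:
            cls = "ns"
        out.append(DEResult(protein_id=pid, log2fc=fc, pval=p, qval=float(q), de_class=cls))
    n_up = sum(r.de_class == "up" for r in out)
    n_down = sum(r.de_class == "down" for r in out)
    logger.info("DE screen: %d up, %d down, %d ns", n_up, n_down, len(out) - n_up - n_down)
    return out


def volcano_table(results: list[DEResult], p_floor: float = P_FLOOR_DEFAULT) -> pd.DataFrame:
    """One row per protein: (log2fc, −log10 p, de_class), p floored for finiteness."""
    if not results:
        raise ValueError("volcano_table: empty results")
    clamped = [r.pval < p_floor for r in results]
    if any(clamped):
        logger.warning("volcano: %d p-values clamped at floor %.1g", sum(clamped), p_floor)
    return pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in results],
            "log2fc": [r.log2fc for r in results],
            "neg_log10_p": [-np.log10(max(r.pval, p_floor)) for r in results],
            "de_class": [r.de_class for r in results],
            "p_clamped": clamped,
        }
    )


def median_center(m: ExpressionMatrix) -> ExpressionMatrix:
    """Per-sample median centering on the log2 scale (off by default in the
    screen; provided for inputs not normalized upstream)."""
    log2v = _log2_values(m, values_are_log2=False)
    centered = log2v - np.median(log2v, axis=0, keepdims=True) + np.median(log2v)
    return ExpressionMatrix(
        protein_ids=list(m.protein_ids),
        sample_ids=list(m.sample_ids),
        values=2.0**centered,
        group=list(m.group),
    )


def pearson_correlation(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with its two-sided p-value.

    Requires length ≥3 and nonzero variance in both vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("pearson_correlation needs equal-length vectors of size >=3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson_correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
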