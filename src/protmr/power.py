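"""Analytic post-hoc power for two-sample MR with a binary outcome.

The calculation follows the non-centrality-parameter approach used by the
standard online MR power calculators: the causal odds ratio per exposure SD
is attenuated to the observed (risk-difference) scale,

    b = K·(OR/(1 + K·(OR − 1)) − 1),

with K the case fraction; the outcome variance is v = K(1−K) − b²; the
non-centrality parameter of the two-sided Wald test at level alpha is

    NCP = N·R²·b² / (v·(1 − R²)),

where R² is the variance in the exposure explained by the instruments. Power
is the sum of both rejection tails,
Φ(−z_{1−α/2} + √NCP) + Φ(−z_{1−α/2} − √NCP), which reduces exactly to alpha
at OR = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

from scipy import stats


@dataclass(frozen=True)
class PowerQuery:
    """Inputs of the binary-outcome MR power calculation.

    n_total: outcome-GWAS sample size; case_fraction: proportion of cases K;
    or_per_sd: causal odds ratio per SD of the exposure; rsq_xz: instrument
    R² on the exposure; alpha: two-sided significance level.
    """

    n_total: int
    case_fraction: float
    or_per_sd: float
    rsq_xz: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if not (0 < self.case_fraction < 1):
            raise ValueError("case_fraction must lie in (0, 1)")
        if self.or_per_sd <= 0:
            raise ValueError("or_per_sd must be positive")
        if not (0 < self.rsq_xz < 1):
            raise ValueError("rsq_xz must lie in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


def mr_power_binary(q: PowerQuery) -> float:
    """Power of the two-sided MR Wald test for a binary outcome."""
    k = q.case_fraction
    b = k * (q.or_per_sd / (1 + k * (q.or_per_sd - 1)) - 1)
    v = k * (1 - k) - b**2
    ncp = q.n_total * q.rsq_xz * b**2 / (v * (1 - q.rsq_xz))
    z = stats.norm.ppf(1 - q.alpha / 2)
    root = math.sqrt(ncp)
    return float(stats.norm.cdf(-z + root) + stats.norm.cdf(-z - root))
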