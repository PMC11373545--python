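"""Network-MR mediation: two-step screening of candidate mediators and
product-of-coefficients decomposition of the total causal effect.

A mediator is screened in when both MR legs (exposure→mediator and
mediator→outcome, each estimated by IVW with automatic model choice) are
significant at the screening alpha. The decomposition computes the indirect
effect as the product of the leg estimates, its SE by the first-order delta
method assuming independent (non-overlapping) samples, and the proportion
mediated against the directly estimated total effect. Binary-outcome legs are
kept on the log-odds scale throughout; odds ratios are exponentiated only for
reporting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from protmr.instruments import HarmonizedSet
from protmr.mr_core import MREstimate, Z_975, ivw

logger = logging.getLogger(__name__)


@dataclass
class MediationResult:
    """Two-step MR decomposition for one mediator."""

    mediator: str
    beta_em: float
    se_em: float
    beta_mo: float
    se_mo: float
    beta_total: float
    se_total: float
    indirect: float
    indirect_se: float
    direct: float
    pm: float
    pm_se: float
    screened_in: bool = True
    pval_em: float | None = None
    pval_mo: float | None = None
    n_snp_em: int | None = None
    n_snp_mo: int | None = None

    @property
    def pm_ci(self) -> tuple[float, float]:
        return (self.pm - Z_975 * self.pm_se, self.pm + Z_975 * self.pm_se)


def decompose(
    beta_em: float,
    se_em: float,
    beta_mo: float,
    se_mo: float,
    beta_total: float,
    se_total: float,
    mediator: str = "mediator",
) -> MediationResult:
    """Product-of-coefficients decomposition of a total causal effect.

    indirect = beta_em·beta_mo with delta SE sqrt(beta_em²·se_mo² +
    beta_mo²·se_em²); pm = indirect / beta_total with first-order delta SE
    treating the legs and the total as independent estimates.
    """
    if beta_total == 0:
        raise ValueError("beta_total is 0: proportion mediated undefined")
    indirect = beta_em * beta_mo
    indirect_se = math.sqrt(beta_em**2 * se_mo**2 + beta_mo**2 * se_em**2)
    direct = beta_total - indirect
    pm = indirect / beta_total
    # grad of pm wrt (indirect, total): (1/total, -indirect/total^2)
    pm_se = math.sqrt(
        indirect_se**2 / beta_total**2 + indirect**2 * se_total**2 / beta_total**4
    )
    return MediationResult(
        mediator=mediator,
        beta_em=beta_em,
        se_em=se_em,
        beta_mo=beta_mo,
        se_mo=se_mo,
        beta_total=beta_total,
        se_total=se_total,
        indirect=indirect,
        indirect_se=indirect_se,
        direct=direct,
        pm=pm,
        pm_se=pm_se,
    )


def two_step_screen(
    legs: dict[str, tuple[HarmonizedSet | None, HarmonizedSet | None]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Estimate both MR legs per candidate mediator and flag the screened set.

    ``legs`` maps mediator name to (exposure→mediator, mediator→outcome)
    harmonized sets; a mediator is screened in iff both leg p-values are
    below ``alpha``. Mediators with a missing leg are skipped with a log
    entry.
    """
    rows = []
    for name, (h_em, h_mo) in legs.items():
        if h_em is None or h_mo is None:
            logger.warning("mediator %s: missing leg, skipped", name)
            continue
        est_em = ivw(h_em, model="auto")
        est_mo = ivw(h_mo, model="auto")
        rows.append(
            {
                "mediator": name,
                "n_snp_em": est_em.n_snp,
                "beta_em": est_em.beta,
                "se_em": est_em.se,
                "pval_em": est_em.pval,
                "n_snp_mo": est_mo.n_snp,
                "beta_mo": est_mo.beta,
                "se_mo": est_mo.se,
                "pval_mo": est_mo.pval,
                "or_mo": est_mo.or_,
                "or_mo_low": est_mo.or_low,
                "or_mo_high": est_mo.or_high,
                "screened_in": bool(est_em.pval < alpha and est_mo.pval < alpha),
            }
        )
    return pd.DataFrame(rows)


def mediate(
    screen: pd.DataFrame,
    total: MREstimate,
) -> list[MediationResult]:
    """Decompose the total effect through every screened-in mediator; legs of
    screened-out mediators are reported with pm left unset."""
    out: list[MediationResult] = []
    for _, row in screen.iterrows():
        if row["screened_in"]:
            res = decompose(
                beta_em=row["beta_em"],
                se_em=row["se_em"],
                beta_mo=row["beta_mo"],
                se_mo=row["se_mo"],
                beta_total=total.beta,
                se_total=total.se,
                mediator=row["mediator"],
            )
        else:
            res = MediationResult(
                mediator=row["mediator"],
                beta_em=row["beta_em"],
                se_em=row["se_em"],
                beta_mo=row["beta_mo"],
                se_mo=row["se_mo"],
                beta_total=total.beta,
                se_total=total.se,
                indirect=float("nan"),
                indirect_se=float("nan"),
                direct=float("nan"),
                pm=float("nan"),
                pm_se=float("nan"),
                screened_in=False,
            )
        res.screened_in = bool(row["screened_in"])
        res.pval_em = float(row["pval_em"])
        res.pval_mo = float(row["pval_mo"])
        res.n_snp_em = int(row["n_snp_em"])
        res.n_snp_mo = int(row["n_snp_mo"])
        out.append(res)
    return out


def mediation_table(results: list[MediationResult]) -> pd.DataFrame:
    """Report table: one row per mediator with leg estimates, ORs with 95% CI
    and the proportion mediated as a one-decimal percentage (blank when the
    mediator was screened out)."""
    if not results:
        raise ValueError("mediation_table: no mediators")
    rows = []
    for r in results:
        or_mo = math.exp(r.beta_mo)
        or_lo = math.exp(r.beta_mo - Z_975 * r.se_mo)
        or_hi = math.exp(r.beta_mo + Z_975 * r.se_mo)
        rows.append(
            {
                "mediator": r.mediator,
                "n_snp_em": r.n_snp_em,
                "beta_em": round(r.beta_em, 3),
                "se_em": round(r.se_em, 3),
                "pval_em": r.pval_em,
                "n_snp_mo": r.n_snp_mo,
                "or_mo": round(or_mo, 2),
                "or_mo_95ci": f"{or_lo:.2f}-{or_hi:.2f}",
                "pval_mo": r.pval_mo,
                "pm": f"{100 * r.pm:.1f}%" if r.screened_in else "-",
            }
        )
    return pd.DataFrame(rows)
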