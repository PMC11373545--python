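"""Genetic-instrument selection and exposure/outcome harmonization.

Instruments are pQTLs passing a significance threshold, an instrument-strength
filter (F-statistic > 10) and a minor-allele-frequency filter (MAF > 0.001),
then pruned for linkage disequilibrium (r² < 0.2 within a 500 kb window,
greedy by descending F). Instruments absent from the outcome GWAS may be
replaced by a highly correlated proxy (r² ≥ 0.8). Harmonization aligns the
outcome estimates to the exposure's effect-allele orientation; palindromic
(A/T, C/G) variants are resolved from allele frequencies or dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from protmr.core_io import LDMatrix, SummaryStats, VariantAssociation

logger = logging.getLogger(__name__)

# the pQTL discovery scan: 0.05 Bonferroni-corrected for 54,469 variants
# against 4,782 protein traits
DEFAULT_PQTL_P_MAX = 0.05 / 54_469 / 4_782

F_MIN_DEFAULT = 10.0
MAF_MIN_DEFAULT = 0.001
R2_PRUNE_DEFAULT = 0.2
WINDOW_BP_DEFAULT = 500_000
R2_PROXY_DEFAULT = 0.8

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class InsufficientInstrumentsError(ValueError):
    """Too few instruments for the requested operation."""


class HarmonizationError(ValueError):
    """No variants survive harmonization."""


def f_statistic(beta: float, se: float) -> float:
    """Instrument strength F = (beta/se)^2 for a single pQTL."""
    if se <= 0:
        raise ValueError(f"se must be positive, got {se}")
    return (beta / se) ** 2


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    return _COMPLEMENT[effect_allele] == other_allele


@dataclass
class InstrumentRecord:
    """One candidate instrument with its strength metrics and filter status."""

    assoc: VariantAssociation
    f_stat: float
    maf: float | None
    status: str = "kept"  # kept | removed_p | removed_f | removed_maf | removed_ld | removed_missing_outcome | proxied
    proxy_for: str | None = None

    @property
    def variant_id(self) -> str:
        return self.assoc.variant_id


def filter_instruments(
    s: SummaryStats,
    p_max: float = DEFAULT_PQTL_P_MAX,
    f_min: float = F_MIN_DEFAULT,
    maf_min: float = MAF_MIN_DEFAULT,
    missing_eaf_policy: str = "drop",
) -> list[InstrumentRecord]:
    """Label every variant with its first failing criterion (p, then F, then MAF).

    Returns one record per input variant; the kept subset satisfies all three
    thresholds. ``missing_eaf_policy`` decides what happens when the MAF filter
    is active but EAF is unreported: ``drop`` removes the record, ``keep``
    retains it with a warning.
    """
    if p_max <= 0 or f_min < 0 or maf_min < 0:
        raise ValueError("thresholds must be positive")
    if missing_eaf_policy not in ("drop", "keep"):
        raise ValueError(f"missing_eaf_policy must be drop|keep, got {missing_eaf_policy}")
    records: list[InstrumentRecord] = []
    for a in s.associations:
        f = f_statistic(a.beta, a.se)
        rec = InstrumentRecord(assoc=a, f_stat=f, maf=a.maf)
        if a.pval >= p_max:
            rec.status = "removed_p"
        elif f <= f_min:
            rec.status = "removed_f"
        elif a.maf is None:
            if missing_eaf_policy == "drop":
                rec.status = "removed_maf"
            else:
                logger.warning("%s: EAF missing, kept despite active MAF filter", a.variant_id)
        elif a.maf <= maf_min:
            rec.status = "removed_maf"
        records.append(rec)
    counts: dict[str, int] = {}
    for r in records:
        counts[r.status] = counts.get(r.status, 0) + 1
    logger.info("%s: instrument filter %s", s.trait_name, counts)
    return records


def ld_prune(
    records: Sequence[InstrumentRecord],
    ld: LDMatrix,
    r2_max: float = R2_PRUNE_DEFAULT,
    window_bp: int = WINDOW_BP_DEFAULT,
) -> list[InstrumentRecord]:
    """Greedy LD pruning of kept instruments, strongest (highest F) first.

    A record is accepted unless its r² with an already-accepted record on the
    same chromosome within ``window_bp`` exceeds ``r2_max``; rejected records
    get status ``removed_ld``. Every same-chromosome pair inside the window
    must have an r² entry; a missing pair raises.
    """
    kept = [r for r in records if r.status == "kept"]
    # deterministic order regardless of input order: F desc, then id
    kept.sort(key=lambda r: (-r.f_stat, r.variant_id))
    accepted: list[InstrumentRecord] = []
    for rec in kept:
        clash = False
        for acc in accepted:
            if acc.assoc.chrom != rec.assoc.chrom:
                continue
            if abs(acc.assoc.pos - rec.assoc.pos) > window_bp:
                continue
            r2 = ld.get(rec.variant_id, acc.variant_id)
            if r2 is None:
                raise ValueError(
                    f"LD matrix lacks r2 for required pair "
                    f"({rec.variant_id}, {acc.variant_id})"
                )
            if r2 > r2_max:
                clash = True
                break
        if clash:
            rec.status = "removed_ld"
        else:
            accepted.append(rec)
    return list(records)


def find_proxy(
    target: str,
    outcome: SummaryStats,
    ld: LDMatrix,
    r2_proxy_min: float = R2_PROXY_DEFAULT,
) -> str | None:
    """Best outcome-present proxy for a variant missing from the outcome GWAS.

    Returns the outcome variant with maximal r² to ``target`` provided
    r² ≥ ``r2_proxy_min``; ties broken by smaller position, then id.
    """
    if outcome.get(target) is not None:
        raise ValueError(f"{target} is present in the outcome; no proxy needed")
    best: tuple[float, int, str] | None = None
    for a in outcome.associations:
        r2 = ld.get(target, a.variant_id)
        if r2 is None or r2 < r2_proxy_min:
            continue
        key = (-r2, a.pos, a.variant_id)
        if best is None or key < best:
            best = key
    return None if best is None else best[2]


@dataclass
class HarmonizedSet:
    """Exposure/outcome effect estimates joined per variant on a common
    effect allele — the input unit for every MR estimator.

    Arrays cover retained variants only; ``dropped`` lists (variant_id, reason)
    for the rest.
    """

    exposure_name: str
    outcome_name: str
    variant_ids: list[str]
    effect_allele: list[str]
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    palindromic: np.ndarray = field(default=None)  # type: ignore[assignment]
    action: list[str] = field(default_factory=list)  # aligned | flipped per variant
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beta_exp = np.asarray(self.beta_exp, dtype=float)
        self.se_exp = np.asarray(self.se_exp, dtype=float)
        self.beta_out = np.asarray(self.beta_out, dtype=float)
        self.se_out = np.asarray(self.se_out, dtype=float)
        n = len(self.variant_ids)
        if len(set(self.variant_ids)) != n:
            raise ValueError("harmonized set: duplicate variant ids")
        for name in ("beta_exp", "se_exp", "beta_out", "se_out"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"harmonized set: {name} length mismatch")
        if self.palindromic is None:
            self.palindromic = np.zeros(n, dtype=bool)
        self.palindromic = np.asarray(self.palindromic, dtype=bool)
        if not self.action:
            self.action = ["aligned"] * n
        if np.any(self.se_exp <= 0) or np.any(self.se_out <= 0):
            raise ValueError("harmonized set: SEs must be positive")

    def __len__(self) -> int:
        return len(self.variant_ids)

    def subset(self, keep: np.ndarray | Sequence[int]) -> "HarmonizedSet":
        idx = np.asarray(keep)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return HarmonizedSet(
            exposure_name=self.exposure_name,
            outcome_name=self.outcome_name,
            variant_ids=[self.variant_ids[i] for i in idx],
            effect_allele=[self.effect_allele[i] for i in idx],
            beta_exp=self.beta_exp[idx],
            se_exp=self.se_exp[idx],
            beta_out=self.beta_out[idx],
            se_out=self.se_out[idx],
            palindromic=self.palindromic[idx],
            action=[self.action[i] for i in idx],
        )

    @classmethod
    def from_arrays(
        cls,
        beta_exp,
        se_exp,
        beta_out,
        se_out,
        exposure_name: str = "exposure",
        outcome_name: str = "outcome",
        variant_ids: Sequence[str] | None = None,
    ) -> "HarmonizedSet":
        """Construct directly from effect arrays (simulation / testing path)."""
        beta_exp = np.asarray(beta_exp, dtype=float)
        n = beta_exp.size
        ids = list(variant_ids) if variant_ids is not None else [f"v{i+1}" for i in range(n)]
        return cls(
            exposure_name=exposure_name,
            outcome_name=outcome_name,
            variant_ids=ids,
            effect_allele=["A"] * n,
            beta_exp=beta_exp,
            se_exp=np.broadcast_to(np.asarray(se_exp, dtype=float), (n,)).copy(),
            beta_out=np.asarray(beta_out, dtype=float),
            se_out=np.broadcast_to(np.asarray(se_out, dtype=float), (n,)).copy(),
        )


def harmonize(
    exposure: SummaryStats,
    outcome: SummaryStats,
    palindromic_policy: str = "infer",
    ambiguity_window: tuple[float, float] = (0.42, 0.58),
    proxies: dict[str, str] | None = None,
) -> HarmonizedSet:
    """Join exposure and outcome estimates per variant on the exposure's
    effect-allele orientation.

    For each shared variant: matching allele orientation keeps the outcome
    beta (action ``aligned``); swapped alleles negate it and complement the
    EAF (action ``flipped``); allele sets that match neither way are dropped.
    Palindromic variants are handled per ``palindromic_policy``:

    - ``infer`` (default): drop when either EAF is missing or the outcome EAF
      falls in ``ambiguity_window``; otherwise orient by whether the two EAFs
      sit on the same side of 0.5.
    - ``drop``: always drop palindromic variants.
    - ``keep``: treat alleles literally (assumes both studies report the same
      strand).

    ``proxies`` maps an exposure variant id to the outcome variant standing in
    for it; the proxy's outcome estimate is used as-is.
    """
    if palindromic_policy not in ("infer", "drop", "keep"):
        raise ValueError(f"unknown palindromic_policy {palindromic_policy}")
    proxies = proxies or {}
    out_index = {a.variant_id: a for a in outcome.associations}

    ids: list[str] = []
    eas: list[str] = []
    b_exp: list[float] = []
    s_exp: list[float] = []
    b_out: list[float] = []
    s_out: list[float] = []
    palin: list[bool] = []
    actions: list[str] = []
    dropped: list[tuple[str, str]] = []

    for exp in exposure.associations:
        out = out_index.get(exp.variant_id)
        used_proxy = False
        if out is None and exp.variant_id in proxies:
            out = out_index.get(proxies[exp.variant_id])
            used_proxy = out is not None
        if out is None:
            dropped.append((exp.variant_id, "missing_outcome"))
            continue
        pal = is_palindromic(exp.effect_allele, exp.other_allele)
        if used_proxy:
            # proxy alleles are a different variant; orientation taken as
            # reported (documented limitation)
            action = "aligned"
            beta_o, se_o = out.beta, out.se
        elif pal and palindromic_policy != "keep":
            if palindromic_policy == "drop":
                dropped.append((exp.variant_id, "palindromic"))
                continue
            lo, hi = ambiguity_window
            if exp.eaf is None or out.eaf is None or lo < out.eaf < hi or lo < exp.eaf < hi:
                dropped.append((exp.variant_id, "palindromic_ambiguous"))
                continue
            same_side = (exp.eaf < 0.5) == (out.eaf < 0.5)
            action = "aligned" if same_side else "flipped"
            beta_o = out.beta if same_side else -out.beta
            se_o = out.se
        else:
            exp_pair = (exp.effect_allele, exp.other_allele)
            if (out.effect_allele, out.other_allele) == exp_pair:
                action, beta_o, se_o = "aligned", out.beta, out.se
            elif (out.other_allele, out.effect_allele) == exp_pair:
                action, beta_o, se_o = "flipped", -out.beta, out.se
            else:
                dropped.append((exp.variant_id, "allele_mismatch"))
                continue
        ids.append(exp.variant_id)
        eas.append(exp.effect_allele)
        b_exp.append(exp.beta)
        s_exp.append(exp.se)
        b_out.append(beta_o)
        s_out.append(se_o)
        palin.append(pal)
        actions.append("proxied" if used_proxy else action)

    if not ids:
        raise HarmonizationError(
            f"no variants survive harmonization of {exposure.trait_name} "
            f"against {outcome.trait_name} ({len(dropped)} dropped)"
        )
    return HarmonizedSet(
        exposure_name=exposure.trait_name,
        outcome_name=outcome.trait_name,
        variant_ids=ids,
        effect_allele=eas,
        beta_exp=np.array(b_exp),
        se_exp=np.array(s_exp),
        beta_out=np.array(b_out),
        se_out=np.array(s_out),
        palindromic=np.array(palin, dtype=bool),
        action=actions,
        dropped=dropped,
    )


def select_and_harmonize(
    exposure: SummaryStats,
    outcome: SummaryStats,
    ld: LDMatrix | None = None,
    p_max: float = DEFAULT_PQTL_P_MAX,
    f_min: float = F_MIN_DEFAULT,
    maf_min: float = MAF_MIN_DEFAULT,
    r2_max: float = R2_PRUNE_DEFAULT,
    window_bp: int = WINDOW_BP_DEFAULT,
    r2_proxy_min: float = R2_PROXY_DEFAULT,
    palindromic_policy: str = "infer",
) -> tuple[list[InstrumentRecord], HarmonizedSet]:
    """Full instrument-selection + harmonization step for one exposure.

    Convenience wrapper: significance/F/MAF filters, optional LD pruning,
    proxy search for instruments missing from the outcome, harmonization.
    """
    records = filter_instruments(exposure, p_max=p_max, f_min=f_min, maf_min=maf_min)
    if ld is not None:
        records = ld_prune(records, ld, r2_max=r2_max, window_bp=window_bp)
    kept = [r for r in records if r.status == "kept"]
    out_ids = {a.variant_id for a in outcome.associations}
    proxies: dict[str, str] = {}
    for rec in kept:
        if rec.variant_id in out_ids:
            continue
        proxy = None
        if ld is not None and rec.variant_id in ld:
            proxy = find_proxy(rec.variant_id, outcome, ld, r2_proxy_min=r2_proxy_min)
        if proxy is not None:
            proxies[rec.variant_id] = proxy
            rec.status = "proxied"
            rec.proxy_for = proxy
        else:
            rec.status = "removed_missing_outcome"
    keep_ids = {r.variant_id for r in records if r.status in ("kept", "proxied")}
    if not keep_ids:
        raise InsufficientInstrumentsError(
            f"{exposure.trait_name}: no instruments survive selection"
        )
    filtered_exposure = SummaryStats(
        trait_name=exposure.trait_name,
        associations=[a for a in exposure.associations if a.variant_id in keep_ids],
        trait_type=exposure.trait_type,
    )
    h = harmonize(filtered_exposure, outcome, palindromic_policy=palindromic_policy, proxies=proxies)
    return records, h
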