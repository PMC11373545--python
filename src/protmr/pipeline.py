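"""End-to-end orchestration of the study design: differential-expression
screen, per-protein instrument selection and harmonization, the MR estimator
suite with BH FDR across tested proteins, the sensitivity suite for
FDR-significant hits, mediator decomposition, and the power report.

Configuration is a YAML file (unknown keys rejected); every run writes TSV
report tables plus a JSON manifest (config hash, seeds, per-stage counts) to
the output directory. Identical config and seeds give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from protmr import __version__
from protmr.core_io import read_expression, read_ld_matrix, read_sumstats
from protmr.de_screen import DEResult, screen, volcano_table
from protmr.instruments import (
    DEFAULT_PQTL_P_MAX,
    HarmonizedSet,
    InsufficientInstrumentsError,
    select_and_harmonize,
)
from protmr.mediation import mediate, mediation_table, two_step_screen
from protmr.mr_core import MREstimate, bh_fdr, estimate_all
from protmr.power import PowerQuery, mr_power_binary
from protmr.sensitivity import funnel_data, leave_one_out, pleiotropy_report, presso

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class MediatorConfig:
    """Per-mediator inputs: the mediator GWAS (outcome side of the
    exposure→mediator leg) and the mediator's own instrument summary file."""

    gwas: str
    instruments: str


@dataclass
class PipelineConfig:
    expression_matrix: str = ""
    groups: str = ""
    exposure_dir: str = ""
    outcome: str = ""
    ld_matrix: str | None = None
    mediators: dict[str, MediatorConfig] = field(default_factory=dict)
    out_dir: str = "protmr_out"
    seed: int = 0
    # differential-expression screen
    de_method: str = "welch"
    de_fc_threshold: float = 0.263
    de_p_threshold: float = 0.05
    # instrument selection
    p_max: float = DEFAULT_PQTL_P_MAX
    f_min: float = 10.0
    maf_min: float = 0.001
    r2_max: float = 0.2
    window_bp: int = 500_000
    r2_proxy_min: float = 0.8
    palindromic_policy: str = "infer"
    # inference
    fdr_alpha: float = 0.05
    screening_alpha: float = 0.05
    n_boot: int = 1000
    presso_n_sim: int = 1000
    sensitivity_all: bool = False
    # power report (optional)
    power: dict | None = None

    def validate(self) -> None:
        for name, lo, hi in (
            ("de_fc_threshold", 0, np.inf),
            ("de_p_threshold", 0, 1),
            ("p_max", 0, 1),
            ("maf_min", 0, 0.5),
            ("r2_max", 0, 1),
            ("r2_proxy_min", 0, 1),
            ("fdr_alpha", 0, 1),
            ("screening_alpha", 0, 1),
        ):
            v = getattr(self, name)
            if not (lo < v <= hi):
                raise ValueError(f"config: {name}={v} outside ({lo}, {hi}]")
        if self.f_min < 0 or self.window_bp < 0:
            raise ValueError("config: f_min and window_bp must be nonnegative")
        if self.de_method not in ("welch", "moderated"):
            raise ValueError(f"config: unknown de_method {self.de_method}")
        for name in ("expression_matrix", "groups", "exposure_dir", "outcome"):
            p = getattr(self, name)
            if not p:
                raise ValueError(f"config: missing required field {name}")
            if not Path(p).exists():
                raise ValueError(f"config: {name} path does not exist: {p}")
        if self.ld_matrix is not None and not Path(self.ld_matrix).exists():
            raise ValueError(f"config: ld_matrix path does not exist: {self.ld_matrix}")


def load_config(path: str | Path) -> PipelineConfig:
    """Read and validate a YAML pipeline config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"config: unknown keys {sorted(unknown)}")
    meds = {
        name: MediatorConfig(**spec) for name, spec in (raw.pop("mediators", {}) or {}).items()
    }
    cfg = PipelineConfig(**raw, mediators=meds)
    cfg.validate()
    return cfg


@dataclass
class PipelineResult:
    de_results: list[DEResult]
    mr_table: pd.DataFrame
    significant: list[str]
    sensitivity: dict[str, dict]
    mediation: pd.DataFrame | None
    power: float | None
    manifest: dict


def _config_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full study design and write all report tables.

    Stages: DE screen → instrument selection per DEP → harmonization → MR
    estimator suite per protein → BH FDR across the proteins actually tested
    → sensitivity suite for FDR-significant proteins → mediation for
    configured mediator traits → power report. Proteins without an exposure
    summary file or without surviving instruments are reported as skipped.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "stages": {},
    }

    # ---- stage 1: differential-expression screen
    try:
        matrix = read_expression(cfg.expression_matrix, cfg.groups)
        de_results = screen(
            matrix,
            method=cfg.de_method,
            fc_threshold=cfg.de_fc_threshold,
            p_threshold=cfg.de_p_threshold,
        )
    except Exception as e:  # noqa: BLE001 - stage-labeled diagnostics
        raise PipelineError("de_screen", str(e)) from e
    deps = [r for r in de_results if r.de_class != "ns"]
    manifest["stages"]["de_screen"] = {
        "n_proteins": len(de_results),
        "n_up": sum(r.de_class == "up" for r in de_results),
        "n_down": sum(r.de_class == "down" for r in de_results),
    }
    _write(
        pd.DataFrame(
            [
                {"protein_id": r.protein_id, "log2fc": r.log2fc, "pval": r.pval, "qval": r.qval, "de_class": r.de_class}
                for r in de_results
            ]
        ),
        out / "de_results.tsv",
    )
    _write(volcano_table(de_results), out / "volcano.tsv")
    if not deps:
        logger.warning("no DEPs after screening; MR section empty")

    # ---- stage 2: instruments + harmonization + MR per DEP
    try:
        outcome = read_sumstats(cfg.outcome, trait_type="binary")
    except Exception as e:
        raise PipelineError("instruments", f"outcome: {e}") from e
    ld = read_ld_matrix(cfg.ld_matrix) if cfg.ld_matrix else None

    mr_rows: list[dict] = []
    instrument_rows: list[dict] = []
    harmonized: dict[str, HarmonizedSet] = {}
    primary: dict[str, MREstimate] = {}
    skipped: list[str] = []
    root_ss = np.random.SeedSequence(cfg.seed)
    for i, dep in enumerate(deps):
        exp_path = Path(cfg.exposure_dir) / f"{dep.protein_id}.tsv"
        if not exp_path.exists():
            skipped.append(dep.protein_id)
            continue
        try:
            exposure = read_sumstats(exp_path, trait_name=dep.protein_id)
            records, h = select_and_harmonize(
                exposure,
                outcome,
                ld=ld,
                p_max=cfg.p_max,
                f_min=cfg.f_min,
                maf_min=cfg.maf_min,
                r2_max=cfg.r2_max,
                window_bp=cfg.window_bp,
                r2_proxy_min=cfg.r2_proxy_min,
                palindromic_policy=cfg.palindromic_policy,
            )
        except InsufficientInstrumentsError:
            skipped.append(dep.protein_id)
            continue
        except Exception as e:
            raise PipelineError("instruments", f"{dep.protein_id}: {e}") from e
        for r in records:
            instrument_rows.append(
                {
                    "exposure": dep.protein_id,
                    "variant_id": r.variant_id,
                    "f_stat": r.f_stat,
                    "maf": r.maf,
                    "status": r.status,
                    "proxy_for": r.proxy_for or "NA",
                }
            )
        harmonized[dep.protein_id] = h
        seed_i = int(root_ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        try:
            estimates, het = estimate_all(h, seed=seed_i, n_boot=cfg.n_boot)
        except Exception as e:
            raise PipelineError("mr", f"{dep.protein_id}: {e}") from e
        primary[dep.protein_id] = estimates[0]  # wald or ivw(auto)
        for est in estimates:
            mr_rows.append(
                {
                    "exposure": dep.protein_id,
                    "outcome": outcome.trait_name,
                    "method": est.method,
                    "n_snp": est.n_snp,
                    "beta": est.beta,
                    "se": est.se,
                    "or": est.or_,
                    "or_95ci": f"{est.or_low:.4f}-{est.or_high:.4f}",
                    "pval": est.pval,
                    "q_het": het.q if het else np.nan,
                    "q_het_pval": het.pval if het else np.nan,
                }
            )
    manifest["stages"]["instruments"] = {
        "n_dep": len(deps),
        "n_tested": len(primary),
        "n_skipped_no_instruments": len(skipped),
    }
    if instrument_rows:
        _write(pd.DataFrame(instrument_rows), out / "instruments.tsv")

    # ---- stage 3: FDR across the proteins actually tested by MR
    mr_table = pd.DataFrame(mr_rows)
    significant: list[str] = []
    if primary:
        tested = sorted(primary)
        qvals = bh_fdr([primary[p].pval for p in tested])
        qmap = dict(zip(tested, qvals))
        mr_table["qval_primary"] = [
            qmap[e] if m in ("ivw_fe", "ivw_re", "wald") else np.nan
            for e, m in zip(mr_table["exposure"], mr_table["method"])
        ]
        significant = [p for p in tested if qmap[p] < cfg.fdr_alpha]
    if not mr_table.empty:
        _write(mr_table, out / "mr_results.tsv")
    manifest["stages"]["mr"] = {"n_tested": len(primary), "n_fdr_significant": len(significant)}

    # ---- stage 4: sensitivity suite
    sens_targets = sorted(harmonized) if cfg.sensitivity_all else significant
    sensitivity: dict[str, dict] = {}
    for prot in sens_targets:
        h = harmonized[prot]
        entry: dict = {}
        seed_s = int(root_ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        try:
            if len(h) >= 3:
                loo = leave_one_out(h)
                _write(loo, out / f"loo_{prot}.tsv")
                entry["leave_one_out"] = loo
                intercept = pleiotropy_report(h)
                entry["egger_intercept"] = intercept
            if len(h) >= 4:
                pres = presso(h, n_sim=cfg.presso_n_sim, seed=seed_s)
                entry["presso"] = pres
            fun = funnel_data(h)
            _write(fun, out / f"funnel_{prot}.tsv")
            entry["funnel"] = fun
        except Exception as e:
            raise PipelineError("sensitivity", f"{prot}: {e}") from e
        sensitivity[prot] = entry
    if sensitivity:
        srows = []
        for prot, entry in sensitivity.items():
            inter = entry.get("egger_intercept")
            pres = entry.get("presso")
            srows.append(
                {
                    "exposure": prot,
                    "egger_intercept": inter.value if inter else np.nan,
                    "egger_intercept_se": inter.se if inter else np.nan,
                    "egger_intercept_pval": inter.pval if inter else np.nan,
                    "presso_global_p": pres.global_p if pres else np.nan,
                    "presso_outliers": ",".join(pres.outlier_ids) if pres and pres.outlier_ids else "none",
                }
            )
        _write(pd.DataFrame(srows), out / "sensitivity.tsv")
    manifest["stages"]["sensitivity"] = {"n_proteins": len(sensitivity)}

    # ---- stage 5: mediation for configured mediator traits
    mediation_df: pd.DataFrame | None = None
    if cfg.mediators and significant:
        top = significant[0] if len(significant) == 1 else min(significant, key=lambda p: primary[p].pval)
        legs: dict[str, tuple[HarmonizedSet | None, HarmonizedSet | None]] = {}
        for name, med in cfg.mediators.items():
            try:
                med_gwas = read_sumstats(med.gwas, trait_name=name)
                exposure = read_sumstats(Path(cfg.exposure_dir) / f"{top}.tsv", trait_name=top)
                _, h_em = select_and_harmonize(
                    exposure, med_gwas, ld=ld, p_max=cfg.p_max, f_min=cfg.f_min, maf_min=cfg.maf_min
                )
                med_instruments = read_sumstats(med.instruments, trait_name=name)
                _, h_mo = select_and_harmonize(
                    med_instruments, outcome, ld=ld, p_max=cfg.p_max, f_min=cfg.f_min, maf_min=cfg.maf_min
                )
                legs[name] = (h_em, h_mo)
            except InsufficientInstrumentsError:
                legs[name] = (None, None)
            except Exception as e:
                raise PipelineError("mediation", f"{name}: {e}") from e
        screen_df = two_step_screen(legs, alpha=cfg.screening_alpha)
        if not screen_df.empty:
            results = mediate(screen_df, primary[top])
            mediation_df = mediation_table(results)
            _write(mediation_df, out / "mediation.tsv")
            manifest["stages"]["mediation"] = {
                "n_mediators": len(results),
                "n_screened_in": sum(r.screened_in for r in results),
            }

    # ---- stage 6: power report
    power_val: float | None = None
    if cfg.power:
        q = PowerQuery(**cfg.power)
        power_val = mr_power_binary(q)
        _write(
            pd.DataFrame([{**cfg.power, "power": power_val}]),
            out / "power.tsv",
        )
        manifest["stages"]["power"] = {"power": power_val}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return PipelineResult(
        de_results=de_results,
        mr_table=mr_table,
        significant=significant,
        sensitivity=sensitivity,
        mediation=mediation_df,
        power=power_val,
        manifest=manifest,
    )
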