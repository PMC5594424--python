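"""Analysis orchestration: forward MR, bidirectional MR, risk-factor scans.

Each runner consumes an :class:`AnalysisConfig` (loadable from YAML/JSON),
drives instrument selection -> harmonisation -> estimation -> diagnostics,
and emits a report bundle of TSV/JSON tables plus a harmonisation audit.
Identical config + seed yields byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import diagnostics as diag
from . import estimators as est
from .estimators import (
    DAYS_PER_YEAR,
    MREstimate,
    YEARS_PER_SD_EDUCATION,
    estimates_to_frame,
    to_odds_ratio,
)
from .gwas_io import LDTable, ProxyMap, SummaryTable, read_proxy_map, read_summary_table, select_instruments, apply_proxies
from .harmonize import InstrumentSet, harmonize_datasets

logger = logging.getLogger("twosample_mr")

STOCHASTIC_METHODS = frozenset({"wmedian", "mode_simple", "mode_weighted", "egger_simex"})
DEFAULT_ESTIMATORS = ("ivw_mre", "ivw_fe", "egger", "wmedian")


@dataclass
class AnalysisConfig:
    """Everything one MR analysis needs; thresholds echo the usual GWAS
    conventions (P < 5e-8 significance, LD pruning at r^2 < 0.1, proxies
    accepted at r^2 >= 0.8)."""

    exposure_path: str = ""
    outcome_path: str = ""
    exposure_meta: dict = field(default_factory=lambda: {"name": "exposure"})
    outcome_meta: dict = field(default_factory=lambda: {"name": "outcome"})
    exposure_columns: dict = field(default_factory=dict)
    outcome_columns: dict = field(default_factory=dict)
    snp_list_path: str | None = None
    proxy_path: str | None = None
    ld_path: str | None = None
    p_threshold: float = 5e-8
    prune_r2_max: float = 0.1
    proxy_r2_min: float = 0.8
    palindromic_policy: str = "frequency"
    eaf_window: float = 0.08
    estimators: tuple = DEFAULT_ESTIMATORS
    estimator_settings: dict = field(default_factory=dict)
    seed: int | None = None
    out_dir: str = "mr_output"

    def __post_init__(self) -> None:
        for name, value in (
            ("p_threshold", self.p_threshold),
            ("prune_r2_max", self.prune_r2_max),
            ("proxy_r2_min", self.proxy_r2_min),
        ):
            if not (0.0 < value <= 1.0):
                raise ValueError(f"{name} must be in (0,1], got {value}")
        if STOCHASTIC_METHODS & set(self.estimators) and self.seed is None:
            raise ValueError(
                "a seed is required when stochastic estimators "
                f"({sorted(STOCHASTIC_METHODS & set(self.estimators))}) are requested"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        data = {k: tuple(v) if k == "estimators" else v for k, v in data.items()}
        return cls(**data)


# ---------------------------------------------------------------------------


def _default_columns(cols: dict) -> dict:
    return cols or {k: k for k in ("snp", "ea", "oa", "eaf", "beta", "se", "p", "n")}


def _load_inputs(config: AnalysisConfig):
    exposure = read_summary_table(
        config.exposure_path, _default_columns(config.exposure_columns), config.exposure_meta
    )
    outcome = read_summary_table(
        config.outcome_path, _default_columns(config.outcome_columns), config.outcome_meta
    )
    proxies = read_proxy_map(config.proxy_path) if config.proxy_path else ProxyMap()
    if config.snp_list_path:
        snps = [
            line.strip()
            for line in Path(config.snp_list_path).read_text().splitlines()
            if line.strip()
        ]
    else:
        ld = LDTable.from_tsv(config.ld_path) if config.ld_path else None
        snps = select_instruments(
            exposure, config.p_threshold, ld=ld, r2_max=config.prune_r2_max
        )
    return exposure, outcome, snps, proxies


def fit_estimators(
    instruments: InstrumentSet,
    methods: Sequence[str] = DEFAULT_ESTIMATORS,
    settings: dict | None = None,
    seed: int | None = None,
) -> list[MREstimate]:
    """Run the configured estimator suite on a harmonised instrument set."""
    settings = settings or {}
    out: list[MREstimate] = []
    for m in methods:
        kw = dict(settings.get(m, {}))
        if m == "ivw_fe":
            out.append(est.ivw(instruments, model="fixed"))
        elif m == "ivw_mre":
            out.append(est.ivw(instruments, model="multiplicative_random"))
        elif m == "egger":
            slope, intercept = est.mr_egger(instruments)
            out.extend([slope, intercept])
        elif m == "wmedian":
            kw.setdefault("seed", seed)
            out.append(est.weighted_median(instruments, **kw))
        elif m in ("mode_simple", "mode_weighted"):
            kw.setdefault("seed", seed)
            kw["weighting"] = "simple" if m == "mode_simple" else "weighted"
            out.append(est.mode_based(instruments, **kw))
        elif m == "egger_simex":
            kw.setdefault("seed", seed)
            out.append(est.egger_simex(instruments, **kw))
        else:
            raise ValueError(f"unknown estimator label {m!r}")
    return out


def _report_frame(estimates, outcome_type: str):
    frame = estimates_to_frame(estimates)
    if outcome_type == "binary":
        ors = [
            to_odds_ratio(e) if e.method != "egger_intercept" else (None, None, None)
            for e in estimates
        ]
        frame["or"] = [o[0] for o in ors]
        frame["or_ci_low"] = [o[1] for o in ors]
        frame["or_ci_high"] = [o[2] for o in ors]
    return frame


def run_forward_mr(config: AnalysisConfig, write: bool = True) -> dict:
    """The main analysis: harmonise, estimate, diagnose, report.

    Returns a bundle with the instrument set, the estimate list (plus
    odds ratios for binary outcomes), heterogeneity and instrument-strength
    statistics, and single-SNP / leave-one-out tables.
    """
    exposure, outcome, snps, proxies = _load_inputs(config)
    if not snps:
        raise est.EstimationError("no instrument SNPs available")
    instruments = harmonize_datasets(
        exposure,
        outcome,
        snps,
        proxies=proxies,
        proxy_r2_min=config.proxy_r2_min,
        palindromic_policy=config.palindromic_policy,
        eaf_window=config.eaf_window,
    )
    return analyze_instruments(
        instruments,
        methods=config.estimators,
        settings=config.estimator_settings,
        seed=config.seed,
        out_dir=Path(config.out_dir) if write else None,
    )


def analyze_instruments(
    instruments: InstrumentSet,
    methods: Sequence[str] = DEFAULT_ESTIMATORS,
    settings: dict | None = None,
    seed: int | None = None,
    out_dir: Path | None = None,
) -> dict:
    """Estimation + diagnostics on an already-harmonised instrument set."""
    estimates = fit_estimators(instruments, methods, settings, seed)
    ivw_beta = next((e.beta for e in estimates if e.method.startswith("ivw")), None)
    het = diag.cochran_q(instruments, ivw_beta) if ivw_beta is not None and len(instruments) >= 2 else None
    single = diag.single_snp_table(instruments)
    loo = (
        diag.leave_one_out(instruments, method="ivw_mre")
        if len(instruments) >= 3
        else None
    )
    bundle = {
        "instruments": instruments,
        "estimates": estimates,
        "estimate_table": _report_frame(estimates, instruments.outcome_type),
        "het": het,
        "single_snp": single,
        "leave_one_out": loo,
    }
    if out_dir is not None:
        _write_bundle(bundle, out_dir)
    return bundle


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    instruments: InstrumentSet = bundle["instruments"]
    bundle["estimate_table"].to_csv(out_dir / "estimates.tsv", sep="\t", index=False)
    payload = {
        "exposure": instruments.exposure_name,
        "outcome": instruments.outcome_name,
        "n_snps": len(instruments),
        "provenance": {
            "direct": instruments.provenance[0],
            "proxy": instruments.provenance[1],
            "dropped": instruments.provenance[2],
        },
        "estimates": [e.to_dict() for e in bundle["estimates"]],
    }
    if bundle["het"] is not None:
        payload["heterogeneity"] = dataclasses.asdict(bundle["het"])
    (out_dir / "estimates.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    instruments.write_audit(out_dir / "harmonization_audit.tsv")
    bundle["single_snp"].to_csv(out_dir / "single_snp.tsv", sep="\t", index=False)
    if bundle["leave_one_out"] is not None:
        bundle["leave_one_out"].to_csv(out_dir / "leave_one_out.tsv", sep="\t", index=False)
    logger.info("report written to %s", out_dir)


# ---------------------------------------------------------------------------
# bidirectional MR

#: SD of schooling -> days of schooling, the interpretable unit for
#: reverse-direction effects on education
SD_TO_DAYS = YEARS_PER_SD_EDUCATION * DAYS_PER_YEAR


def run_bidirectional(
    config_fwd: AnalysisConfig,
    config_rev: AnalysisConfig,
    reverse_scale_factor: float = SD_TO_DAYS,
    reverse_unit: str = "days of education per 1-log-odds of outcome",
    write: bool = True,
) -> dict:
    """Forward analysis plus the reverse direction with swapped roles.

    Reverse-direction estimates (effect of genetic outcome liability on the
    exposure) are rescaled to an interpretable unit; the default converts
    an SD-of-schooling effect into days of schooling.
    """
    forward = run_forward_mr(config_fwd, write=write)
    reverse = run_forward_mr(config_rev, write=False)
    reverse["estimates"] = [
        est.rescale(e, reverse_scale_factor, reverse_unit) for e in reverse["estimates"]
    ]
    reverse["estimate_table"] = _report_frame(
        reverse["estimates"], reverse["instruments"].outcome_type
    )
    if write:
        _write_bundle(reverse, Path(config_rev.out_dir))
    return {"forward": forward, "reverse": reverse}


# ---------------------------------------------------------------------------
# risk-factor scan


def run_riskfactor_scan(
    config: AnalysisConfig,
    outcomes: Sequence[SummaryTable],
    proxies: ProxyMap | None = None,
    snps: Sequence[str] | None = None,
    common_snps_only: bool = True,
    write: bool = True,
):
    """One-exposure, many-outcomes IVW scan.

    With ``common_snps_only`` (default) the instrument is first restricted
    to SNPs available — directly or through a proxy — in *every* outcome,
    so each row of the scan uses the same SNP set; per-outcome maximal
    instruments are available by flag.  Raw p-values are reported.
    """
    import pandas as pd

    exposure = read_summary_table(
        config.exposure_path, _default_columns(config.exposure_columns), config.exposure_meta
    )
    if snps is None:
        if config.snp_list_path:
            snps = [
                s.strip()
                for s in Path(config.snp_list_path).read_text().splitlines()
                if s.strip()
            ]
        else:
            snps = select_instruments(exposure, config.p_threshold, r2_max=config.prune_r2_max)
    if not outcomes:
        raise ValueError("risk-factor scan needs at least one outcome table")
    proxies = proxies or (read_proxy_map(config.proxy_path) if config.proxy_path else ProxyMap())

    used_snps = list(snps)
    if common_snps_only:
        for outcome in outcomes:
            matched = apply_proxies(used_snps, outcome, proxies, r2_min=config.proxy_r2_min)
            used_snps = [s for s in used_snps if s in matched]
        if not used_snps:
            raise est.EstimationError("no SNP is available in every scan outcome")
        logger.info(
            "risk-factor scan: %d of %d SNPs available in all %d outcomes",
            len(used_snps), len(snps), len(outcomes),
        )

    rows = []
    for outcome in outcomes:
        instruments = harmonize_datasets(
            exposure,
            outcome,
            used_snps,
            proxies=proxies,
            proxy_r2_min=config.proxy_r2_min,
            palindromic_policy=config.palindromic_policy,
            eaf_window=config.eaf_window,
        )
        estimate = est.ivw(instruments, model="multiplicative_random")
        row = {
            "outcome": outcome.trait_name,
            "outcome_type": outcome.trait_type,
            "unit": outcome.unit,
            "n_snps": estimate.n_snps,
            "beta": estimate.beta,
            "se": estimate.se,
            "ci_low": estimate.ci_low,
            "ci_high": estimate.ci_high,
            "pval": estimate.pval,
        }
        if outcome.trait_type == "binary":
            row["or"], row["or_ci_low"], row["or_ci_high"] = to_odds_ratio(estimate)
        rows.append(row)
    table = pd.DataFrame(rows)
    if write:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "riskfactor_scan.tsv", sep="\t", index=False)
    return table
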