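"""Synthetic two-sample GWAS summary statistics with known causal truth.

The generative model: L independent SNPs carry true exposure effects
gamma_j drawn from ``gamma_law``.  A fraction ``p_invalid`` of SNPs are
invalid instruments with an additive pleiotropic outcome effect
alpha_j ~ Normal(mu_alpha, sd_alpha^2); setting ``inside_violation_rho``
correlates alpha_j with instrument strength, violating the InSIDE
assumption that Egger regression requires.  True outcome effects are
Gamma_j = beta_true * gamma_j + alpha_j.  Observed estimates add
independent sampling noise in the two samples (the two-sample design):
gamma_hat ~ N(gamma, se_gamma^2), Gamma_hat ~ N(Gamma, se_Gamma^2).

The four canonical pleiotropy scenarios:

* none                 p_invalid = 0
* balanced             mu_alpha = 0, sd_alpha > 0
* directional (InSIDE) mu_alpha != 0, inside_violation_rho = 0
* InSIDE-violating     inside_violation_rho != 0

The ``education_like`` preset mirrors a strong polygenic instrument for
years of schooling: 162 SNPs jointly explaining about 1.8% of exposure
variance at a discovery sample of ~300k, against a case-control outcome
of ~194k (log-odds scale), with a true effect of -0.40 log-odds per SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .estimators import EstimationError, egger_simex, ivw, mode_based, mr_egger, weighted_median
from .gwas_io import SummaryRecord, SummaryTable
from .harmonize import InstrumentSet, harmonize_datasets

logger = logging.getLogger("twosample_mr")

#: non-palindromic allele pairs cycled across simulated SNPs
_ALLELE_CYCLE = (("A", "G"), ("C", "A"), ("G", "T"), ("T", "C"))


@dataclass(frozen=True)
class Scenario:
    """Generative parameters for one synthetic two-sample dataset."""

    beta_true: float
    L: int
    p_invalid: float = 0.0
    mu_alpha: float = 0.0
    sd_alpha: float = 0.0
    inside_violation_rho: float = 0.0
    gamma_law: tuple = ("uniform", 0.01, 0.1)
    se_gamma: float = 0.005
    se_Gamma: float = 0.02
    n_exp: int = 300_000
    n_out: int = 200_000
    seed: int = 0
    name: str = "scenario"

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValueError("L must be >= 2")
        if not (0.0 <= self.p_invalid <= 1.0):
            raise ValueError("p_invalid must be in [0,1]")
        if not (self.se_gamma > 0 and self.se_Gamma > 0):
            raise ValueError("sampling-noise scales must be positive")
        if not (-1.0 <= self.inside_violation_rho <= 1.0):
            raise ValueError("inside_violation_rho must be in [-1,1]")


def education_like(seed: int, **overrides) -> Scenario:
    """Preset calibrated to a schooling-like instrument.

    162 SNPs with per-allele effects drawn U[0.005, 0.027] SD and allele
    frequencies U[0.1, 0.9] jointly explain ~1.8% of exposure variance;
    SE scales correspond to ~300k (exposure) and ~194k case-control
    (outcome, log-odds) samples.  True effect -0.40 log-odds per SD
    (odds ratio ~0.67 per SD).
    """
    base = dict(
        beta_true=-0.40,
        L=162,
        gamma_law=("uniform", 0.005, 0.027),
        se_gamma=0.0028,
        se_Gamma=0.0075,
        n_exp=300_000,
        n_out=194_427,
        seed=seed,
        name="education_like",
    )
    base.update(overrides)
    return Scenario(**base)


def _draw_gamma(rng: np.random.Generator, law: tuple, L: int) -> np.ndarray:
    kind = law[0]
    if kind == "uniform":
        return rng.uniform(law[1], law[2], size=L)
    if kind == "normal":
        return rng.normal(law[1], law[2], size=L)
    raise ValueError(f"unknown gamma_law {law!r}")


def simulate_summary_stats(
    sc: Scenario,
) -> tuple[SummaryTable, SummaryTable, pd.DataFrame]:
    """Generate (exposure table, outcome table, truth record) for a scenario.

    Alleles are assigned non-palindromic and identical in both tables, so
    harmonisation is exercised but never drops simulated SNPs.  The truth
    record stores every latent value (gamma, alpha, Gamma, validity, EAF).
    """
    rng = np.random.default_rng(sc.seed)
    gamma = _draw_gamma(rng, sc.gamma_law, sc.L)
    n_invalid = int(round(sc.p_invalid * sc.L))
    invalid = np.zeros(sc.L, dtype=bool)
    if n_invalid:
        invalid[rng.choice(sc.L, size=n_invalid, replace=False)] = True
    alpha = np.zeros(sc.L)
    if n_invalid:
        alpha[invalid] = rng.normal(sc.mu_alpha, sc.sd_alpha, size=n_invalid)
        if sc.inside_violation_rho != 0.0 and sc.sd_alpha > 0:
            sd_g = np.std(gamma) or 1.0
            alpha[invalid] += (
                sc.inside_violation_rho
                * (gamma[invalid] - gamma.mean())
                * sc.sd_alpha
                / sd_g
            )
    Gamma = sc.beta_true * gamma + alpha

    gamma_hat = rng.normal(gamma, sc.se_gamma)
    Gamma_hat = rng.normal(Gamma, sc.se_Gamma)
    eaf = rng.uniform(0.1, 0.9, size=sc.L)

    exposure = SummaryTable("sim_exposure", "continuous", unit="SD")
    outcome = SummaryTable("sim_outcome", "binary", unit="log-odds")
    for j in range(sc.L):
        ea, oa = _ALLELE_CYCLE[j % len(_ALLELE_CYCLE)]
        snp = f"rs{j + 1:06d}"
        p_exp = float(2.0 * stats.norm.sf(abs(gamma_hat[j]) / sc.se_gamma))
        p_out = float(2.0 * stats.norm.sf(abs(Gamma_hat[j]) / sc.se_Gamma))
        exposure.add(
            SummaryRecord(snp, ea, oa, float(gamma_hat[j]), sc.se_gamma,
                          max(p_exp, 1e-300), eaf=float(eaf[j]), n=sc.n_exp)
        )
        outcome.add(
            SummaryRecord(snp, ea, oa, float(Gamma_hat[j]), sc.se_Gamma,
                          max(p_out, 1e-300), eaf=float(eaf[j]), n=sc.n_out)
        )
    truth = pd.DataFrame(
        {
            "snp": [f"rs{j + 1:06d}" for j in range(sc.L)],
            "gamma_true": gamma,
            "alpha": alpha,
            "Gamma_true": Gamma,
            "invalid": invalid,
            "eaf": eaf,
        }
    )
    return exposure, outcome, truth


def instrument_r2(truth: pd.DataFrame) -> float:
    """Variance of a standardized exposure explained by the simulated SNPs,
    sum over SNPs of 2 p (1-p) gamma^2."""
    p = truth["eaf"].to_numpy()
    g = truth["gamma_true"].to_numpy()
    return float(np.sum(2.0 * p * (1.0 - p) * g**2))


def harmonized_from_simulation(sc: Scenario) -> tuple[InstrumentSet, pd.DataFrame]:
    """Simulate a scenario and run it through the real harmonisation path."""
    exposure, outcome, truth = simulate_summary_stats(sc)
    instruments = harmonize_datasets(exposure, outcome, list(exposure.records))
    return instruments, truth


def validation_scenarios(seed: int = 0) -> dict[str, Scenario]:
    """The canonical study conditions used to validate the estimator suite.

    * ``none`` — no pleiotropy; checks IVW consistency and CI calibration.
    * ``balanced`` — every SNP pleiotropic with zero-mean direct effects
      (InSIDE holds); checks the type-I error of the Egger intercept test.
    * ``directional_inside`` — 30% invalid SNPs with mean direct effect
      0.1 (InSIDE holds); IVW is biased while Egger and the weighted
      median stay close to the truth.
    * ``attenuated`` — noisy SNP-exposure estimates (I2_GX ~ 0.7) on a
      162-SNP instrument; the Egger slope is diluted and SIMEX recovers it.
    * ``near_nome`` — the same instrument with negligible exposure noise
      (I2_GX ~ 1); SIMEX must coincide with plain Egger.
    """
    return {
        "none": Scenario(beta_true=-0.4, L=50, seed=seed, name="none"),
        "balanced": Scenario(
            beta_true=-0.4, L=50, p_invalid=1.0, mu_alpha=0.0, sd_alpha=0.02,
            se_gamma=0.001, seed=seed, name="balanced",
        ),
        "directional_inside": Scenario(
            beta_true=-0.4, L=50, p_invalid=0.3, mu_alpha=0.1, sd_alpha=0.02,
            se_gamma=0.001, se_Gamma=0.01, seed=seed, name="directional_inside",
        ),
        "attenuated": Scenario(
            beta_true=-0.4, L=162, se_gamma=0.017, se_Gamma=0.005,
            seed=seed, name="attenuated",
        ),
        "near_nome": Scenario(
            beta_true=-0.4, L=162, se_gamma=1e-4, se_Gamma=0.005,
            seed=seed, name="near_nome",
        ),
    }


# ---------------------------------------------------------------------------
# estimator-performance harness

GRID_METHODS = (
    "ivw_fe",
    "ivw_mre",
    "egger",
    "wmedian",
    "mode_simple",
    "mode_weighted",
    "egger_simex",
)


def _fit_method(method, instruments, seed, settings):
    if method == "ivw_fe":
        return ivw(instruments, model="fixed"), None
    if method == "ivw_mre":
        return ivw(instruments, model="multiplicative_random"), None
    if method == "egger":
        slope, intercept = mr_egger(instruments)
        return slope, intercept
    if method == "wmedian":
        return weighted_median(instruments, n_boot=settings.get("n_boot", 200), seed=seed), None
    if method in ("mode_simple", "mode_weighted"):
        return (
            mode_based(
                instruments,
                phi=settings.get("phi", 1.0),
                weighting="simple" if method == "mode_simple" else "weighted",
                n_boot=settings.get("n_boot", 200),
                seed=seed,
            ),
            None,
        )
    if method == "egger_simex":
        return (
            egger_simex(
                instruments,
                lambdas=settings.get("lambdas", (0.0, 0.5, 1.0, 1.5, 2.0)),
                n_sim=settings.get("n_sim", 200),
                seed=seed,
            ),
            None,
        )
    raise ValueError(f"unknown method label {method!r}")


def run_scenario_grid(
    scenarios: Sequence[Scenario],
    methods: Sequence[str],
    n_rep: int,
    seed: int,
    method_settings: dict | None = None,
) -> pd.DataFrame:
    """Monte-Carlo estimator performance over scenarios.

    For each (scenario, method) pair over ``n_rep`` replicates: mean bias,
    empirical SE, RMSE, 95% CI coverage of beta_true, and (when Egger runs)
    the rejection rate of the intercept-pleiotropy test at alpha=0.05.
    Replicate seeds derive deterministically from the master seed.
    """
    method_settings = method_settings or {}
    for m in methods:
        if m not in GRID_METHODS:
            raise ValueError(f"unknown method label {m!r}; choose from {GRID_METHODS}")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    master = np.random.default_rng(seed)
    rows = []
    for sc in scenarios:
        sim_seeds = master.integers(0, 2**31, size=n_rep)
        est_seeds = master.integers(0, 2**31, size=n_rep)
        results = {m: [] for m in methods}
        covered = {m: [] for m in methods}
        intercept_reject = []
        for r in range(n_rep):
            rep_sc = replace(sc, seed=int(sim_seeds[r]))
            instruments, _ = harmonized_from_simulation(rep_sc)
            for m in methods:
                est, extra = _fit_method(m, instruments, int(est_seeds[r]),
                                         method_settings.get(m, {}))
                results[m].append(est.beta)
                covered[m].append(est.ci_low <= sc.beta_true <= est.ci_high)
                if m == "egger" and extra is not None:
                    intercept_reject.append(extra.pval < 0.05)
        for m in methods:
            betas = np.array(results[m])
            bias = betas - sc.beta_true
            rows.append(
                {
                    "scenario": sc.name,
                    "method": m,
                    "n_rep": n_rep,
                    "mean_bias": float(bias.mean()),
                    "emp_se": float(betas.std(ddof=1)) if n_rep > 1 else np.nan,
                    "rmse": float(np.sqrt(np.mean(bias**2))),
                    "coverage": float(np.mean(covered[m])),
                    "intercept_rejection_rate": float(np.mean(intercept_reject))
                    if (m == "egger" and intercept_reject)
                    else np.nan,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# independent regression oracle (tests only)


def oracle_wls(
    x: Sequence[float],
    y: Sequence[float],
    w: Sequence[float],
    with_intercept: bool,
) -> tuple[float, float, tuple[float, float]]:
    """Weighted least squares via statsmodels, independent of the closed
    forms used by the estimators.  Returns (slope, intercept, (se_slope,
    se_intercept)); intercept terms are 0/NaN for through-origin fits.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (x.size == y.size == w.size):
        raise ValueError("x, y, w must have equal length")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    min_n = 3 if with_intercept else 2
    if x.size < min_n:
        raise ValueError(f"need >= {min_n} points")
    if with_intercept and np.ptp(x) == 0:
        raise np.linalg.LinAlgError("singular design: x constant")
    if not with_intercept and np.all(x == 0):
        raise np.linalg.LinAlgError("singular design: x identically zero")
    X = sm.add_constant(x) if with_intercept else x[:, None]
    fit = sm.WLS(y, X, weights=w).fit()
    if with_intercept:
        return (
            float(fit.params[1]),
            float(fit.params[0]),
            (float(fit.bse[1]), float(fit.bse[0])),
        )
    return float(fit.params[0]), 0.0, (float(fit.bse[0]), float("nan"))
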