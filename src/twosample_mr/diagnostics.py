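"""Heterogeneity, instrument-strength and sensitivity diagnostics.

Cochran's Q measures dispersion of per-SNP Wald ratios around a pooled
estimate; large Q flags pleiotropy or other violations.  I2_GX quantifies
how much measurement error in the SNP-exposure estimates violates the NOME
assumption of Egger regression (values well below 1 mean the Egger slope
is attenuated and a SIMEX correction is warranted).  Leave-one-out and
single-SNP tables support forest/funnel displays and influence checks.
The binary-outcome power calculation uses the standard asymptotic
approximation for case-control outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import EstimationError, MREstimate, ivw, mr_egger, wald_ratio, weighted_median
from .harmonize import InstrumentSet


@dataclass(frozen=True)
class HetStats:
    """Cochran's Q heterogeneity plus instrument-strength I2_GX."""

    Q: float
    df: int
    pval: float
    i2: float
    i2_gx: float


def cochran_q(instruments: InstrumentSet, beta: float) -> HetStats:
    """Q = sum w_j (ratio_j - beta)^2 over per-SNP Wald ratios.

    Weights are the first-order inverse variances gamma^2/se_Gamma^2;
    p-value from chi-square(L-1).  Also reports I2 = max(0, (Q-df)/Q) and
    the instrument-strength statistic from :func:`i2_gx`.
    """
    L = len(instruments)
    if L < 2:
        raise EstimationError("Cochran's Q needs >=2 SNPs")
    g, _, G, seG = instruments.gammas()
    ratios = G / g
    w = g**2 / seG**2
    Q = float(np.sum(w * (ratios - beta) ** 2))
    df = L - 1
    pval = float(stats.chi2.sf(Q, df))
    i2 = max(0.0, (Q - df) / Q) if Q > 0 else 0.0
    return HetStats(Q=Q, df=df, pval=pval, i2=i2, i2_gx=i2_gx(instruments))


def i2_gx(instruments: InstrumentSet) -> float:
    """Instrument-strength I2_GX in [0, 1].

    Q_GX = sum (gamma_j - gamma_bar_w)^2 / se_gamma_j^2 around the
    inverse-variance-weighted mean gamma; I2_GX = max(0, (Q_GX - (L-1))/Q_GX).
    Values near 1 mean SNP-exposure estimates are effectively noise-free
    (NOME holds); lower values quantify Egger regression dilution.
    """
    L = len(instruments)
    if L < 2:
        raise EstimationError("I2_GX needs >=2 SNPs")
    g, seg, _, _ = instruments.gammas()
    w = 1.0 / seg**2
    gbar = float(np.sum(w * g) / np.sum(w))
    Q_gx = float(np.sum((g - gbar) ** 2 / seg**2))
    if Q_gx <= 0:
        return 0.0
    return max(0.0, (Q_gx - (L - 1)) / Q_gx)


# ---------------------------------------------------------------------------
# influence tables

_REFIT: dict[str, Callable[..., MREstimate]] = {
    "ivw_fe": lambda s, **kw: ivw(s, model="fixed"),
    "ivw_mre": lambda s, **kw: ivw(s, model="multiplicative_random"),
    "egger_slope": lambda s, **kw: mr_egger(s)[0],
    "wmedian": lambda s, **kw: weighted_median(s, **kw),
}


def _subset(instruments: InstrumentSet, pairs) -> InstrumentSet:
    return InstrumentSet(
        exposure_name=instruments.exposure_name,
        outcome_name=instruments.outcome_name,
        exposure_unit=instruments.exposure_unit,
        outcome_unit=instruments.outcome_unit,
        outcome_type=instruments.outcome_type,
        pairs=list(pairs),
    )


def leave_one_out(instruments: InstrumentSet, method: str = "ivw_mre", **settings) -> pd.DataFrame:
    """Refit ``method`` on every (L-1)-subset; one row per omitted SNP.

    Stochastic methods must be given their seed via ``settings``.
    """
    if method not in _REFIT:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_REFIT)}")
    L = len(instruments)
    if L < 3:
        raise EstimationError("leave-one-out needs >=3 SNPs")
    if method == "wmedian" and "seed" not in settings:
        raise EstimationError("leave_one_out with a stochastic method requires a seed")
    rows = []
    for i, omitted in enumerate(instruments.pairs):
        sub = _subset(instruments, instruments.pairs[:i] + instruments.pairs[i + 1 :])
        est = _REFIT[method](sub, **settings)
        rows.append(
            {
                "omitted_snp": omitted.snp_id,
                "method": est.method,
                "beta": est.beta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pval": est.pval,
                "n_snps": est.n_snps,
            }
        )
    return pd.DataFrame(rows)


def single_snp_table(instruments: InstrumentSet) -> pd.DataFrame:
    """Per-SNP Wald estimates, ready for forest/funnel rendering."""
    rows = []
    for p in instruments.pairs:
        est = wald_ratio(p)
        rows.append(
            {
                "snp": p.snp_id,
                "beta": est.beta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pval": est.pval,
                "gamma": p.gamma,
                "Gamma": p.Gamma,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# power


def mr_power_binary(
    n_cases: int,
    n_controls: int,
    r2_gx: float,
    or_per_sd: float,
    alpha: float = 0.05,
) -> float:
    """Asymptotic two-sided power of an MR test with a binary outcome.

    With N = cases + controls, case fraction K and instrument strength
    r2_gx (variance of the exposure explained by the instrument), the
    noncentrality of the Wald test of b = log(or_per_sd) is
    |b| * sqrt(N * r2_gx * K * (1-K)); power is
    Phi(ncp - z_{1-alpha/2}) + Phi(-ncp - z_{1-alpha/2}).
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("case and control counts must be positive")
    if not (0.0 <= r2_gx < 1.0):
        raise ValueError(f"r2_gx must be in [0,1), got {r2_gx}")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if not or_per_sd > 0:
        raise ValueError("odds ratio must be positive")
    if r2_gx == 0.0:
        return alpha
    N = n_cases + n_controls
    K = n_cases / N
    b = np.log(or_per_sd)
    ncp = abs(b) * np.sqrt(N * r2_gx * K * (1.0 - K))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(stats.norm.cdf(ncp - z) + stats.norm.cdf(-ncp - z))
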