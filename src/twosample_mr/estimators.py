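"""Causal-effect estimators for two-sample Mendelian randomisation.

All estimators consume a harmonised :class:`~twosample_mr.harmonize.InstrumentSet`
of per-SNP pairs (gamma_j, se_gamma_j, Gamma_j, se_Gamma_j) and return an
:class:`MREstimate`.  The suite:

* Wald ratio — single-SNP estimate Gamma/gamma.
* IVW — inverse-variance-weighted regression of Gamma on gamma through the
  origin (fixed-effect, or multiplicative random-effects with the SE scaled
  by max(1, sqrt(Q/(L-1)))).
* MR-Egger — the same regression with an unconstrained intercept; the
  intercept estimates average directional pleiotropy, and the slope is a
  consistent causal estimate under the InSIDE assumption.
* Weighted median — consistent when SNPs carrying >=50% of the weight are
  valid instruments.
* Mode-based — consistent when the largest cluster of per-SNP ratios is
  formed by valid instruments (ZEMPA); simple or inverse-variance-weighted
  kernel density with tuning parameter phi.
* MR-Egger + SIMEX — simulation-extrapolation correction of the regression
  dilution that noisy SNP-exposure estimates induce in the Egger slope
  (the NOME violation measured by I2_GX).

Weights throughout are the first-order (delta-method) inverse variances,
1/se_Gamma^2 for regressions and gamma^2/se_Gamma^2 for per-SNP ratios.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import HarmonizedPair, InstrumentSet

logger = logging.getLogger("twosample_mr")

Z975 = float(stats.norm.ppf(0.975))


class EstimationError(ValueError):
    pass


@dataclass(frozen=True)
class MREstimate:
    """A causal estimate: point, SE, 95% CI, p-value and provenance."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    unit: str = ""
    settings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
            "n_snps": self.n_snps,
            "unit": self.unit,
            "settings": dict(self.settings),
        }


def estimates_to_frame(estimates: Sequence[MREstimate]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        d = e.to_dict()
        d["settings"] = json.dumps(d["settings"], sort_keys=True)
        rows.append(d)
    return pd.DataFrame(
        rows,
        columns=["method", "beta", "se", "ci_low", "ci_high", "pval", "n_snps", "unit", "settings"],
    )


def write_estimates(estimates: Sequence[MREstimate], tsv_path: str | Path) -> None:
    estimates_to_frame(estimates).to_csv(tsv_path, sep="\t", index=False)


def _normal_estimate(method, beta, se, n_snps, unit="", settings=None) -> MREstimate:
    se = float(se)
    pval = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else (1.0 if beta == 0 else 0.0)
    return MREstimate(
        method=method,
        beta=float(beta),
        se=se,
        ci_low=float(beta - Z975 * se),
        ci_high=float(beta + Z975 * se),
        pval=float(max(pval, np.finfo(float).tiny)),
        n_snps=n_snps,
        unit=unit,
        settings=settings or {},
    )


def _t_estimate(method, beta, se, df, n_snps, unit="", settings=None) -> MREstimate:
    se = float(se)
    tq = float(stats.t.ppf(0.975, df))
    pval = 2.0 * stats.t.sf(abs(beta) / se, df) if se > 0 else (1.0 if beta == 0 else 0.0)
    return MREstimate(
        method=method,
        beta=float(beta),
        se=se,
        ci_low=float(beta - tq * se),
        ci_high=float(beta + tq * se),
        pval=float(max(pval, np.finfo(float).tiny)),
        n_snps=n_snps,
        unit=unit,
        settings=settings or {},
    )


# ---------------------------------------------------------------------------
# Wald ratio and IVW


def wald_ratio(pair: HarmonizedPair) -> MREstimate:
    """Single-SNP causal estimate Gamma/gamma with first-order delta SE."""
    if pair.gamma == 0:
        raise EstimationError(f"{pair.snp_id}: Wald ratio undefined for gamma=0")
    beta = pair.Gamma / pair.gamma
    se = pair.se_Gamma / abs(pair.gamma)
    return _normal_estimate("wald", beta, se, 1, settings={"snp": pair.snp_id})


def ivw(instruments: InstrumentSet, model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate.

    Equivalent to weighted regression of Gamma on gamma through the origin
    with weights 1/se_Gamma^2; closed form
    beta = sum(gamma*Gamma/se_Gamma^2) / sum(gamma^2/se_Gamma^2).
    The multiplicative random-effects model inflates the fixed-effect SE by
    max(1, sqrt(Q/(L-1))) to absorb between-SNP heterogeneity.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    L = len(instruments)
    if L == 0:
        raise EstimationError("IVW on empty instrument set")
    if L == 1:
        logger.warning("IVW with a single SNP degrades to the Wald ratio")
        est = wald_ratio(instruments.pairs[0])
        return dc_replace(est, method="ivw_fe" if model == "fixed" else "ivw_mre")
    g, _, G, seG = instruments.gammas()
    w = 1.0 / seG**2
    denom = float(np.sum(w * g**2))
    beta = float(np.sum(w * g * G)) / denom
    se_fixed = denom**-0.5
    Q = float(np.sum(w * (G - beta * g) ** 2))
    if model == "fixed":
        return _normal_estimate("ivw_fe", beta, se_fixed, L, settings={"Q": Q})
    scale = max(1.0, np.sqrt(Q / (L - 1)))
    return _normal_estimate("ivw_mre", beta, se_fixed * scale, L, settings={"Q": Q})


# ---------------------------------------------------------------------------
# MR-Egger


def _check_oriented(instruments: InstrumentSet) -> None:
    if any(p.gamma < 0 for p in instruments.pairs):
        raise EstimationError(
            "instrument set must be oriented to exposure-increasing alleles "
            "(orient_to_exposure_increasing) before Egger regression"
        )


def mr_egger(instruments: InstrumentSet) -> tuple[MREstimate, MREstimate]:
    """Weighted regression of Gamma on gamma with intercept.

    Returns (slope, intercept).  The slope estimates the causal effect under
    InSIDE; the intercept estimates average directional pleiotropy, and its
    test against zero is the Egger pleiotropy test.  Inference uses
    t(L-2) with the SE inflated by max(1, sqrt(RSS_w/(L-2))).
    """
    L = len(instruments)
    if L < 3:
        raise EstimationError(f"MR-Egger needs >=3 SNPs, got {L}")
    _check_oriented(instruments)
    g, _, G, seG = instruments.gammas()
    w = 1.0 / seG**2
    sw, swx = float(np.sum(w)), float(np.sum(w * g))
    swxx, swy, swxy = float(np.sum(w * g**2)), float(np.sum(w * G)), float(np.sum(w * g * G))
    det = sw * swxx - swx**2
    if det <= 0 or np.isclose(det / (sw * swxx), 0.0, atol=1e-12):
        raise EstimationError("MR-Egger design is rank deficient (gamma constant across SNPs)")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    resid = G - intercept - slope * g
    rss_w = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(rss_w / (L - 2)))
    se_slope = np.sqrt(sw / det) * scale
    se_int = np.sqrt(swxx / det) * scale
    settings = {"rss_w": rss_w}
    return (
        _t_estimate("egger_slope", slope, se_slope, L - 2, L, settings=settings),
        _t_estimate("egger_intercept", intercept, se_int, L - 2, L, settings=settings),
    )


# ---------------------------------------------------------------------------
# Weighted median


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    b, w = ratios[order], weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, b))


def weighted_median(
    instruments: InstrumentSet,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Weighted median of per-SNP Wald ratios.

    Ratios are weighted by their first-order inverse variances
    gamma^2/se_Gamma^2; the estimate interpolates the ratio at cumulative
    standardized weight 0.5.  The SE comes from a seeded parametric
    bootstrap resampling (gamma_hat, Gamma_hat) from normals with their
    reported SEs.
    """
    if seed is None:
        raise EstimationError("weighted_median requires an explicit seed (reproducibility)")
    if n_boot < 100:
        logger.warning("weighted_median: n_boot=%d is small; SE will be unstable", n_boot)
    L = len(instruments)
    if L == 0:
        raise EstimationError("weighted_median on empty instrument set")
    g, seg, G, seG = instruments.gammas()
    if L == 1:
        est = wald_ratio(instruments.pairs[0])
        return dc_replace(est, method="wmedian")
    ratios = G / g
    weights = g**2 / seG**2
    beta = _weighted_median(ratios, weights)

    rng = np.random.default_rng(seed)
    gb = rng.normal(g, seg, size=(n_boot, L))
    Gb = rng.normal(G, seG, size=(n_boot, L))
    gb = np.where(gb == 0, np.finfo(float).tiny, gb)
    rb = Gb / gb
    wb = gb**2 / seG**2
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = _weighted_median(rb[i], wb[i])
    se = float(np.std(boots, ddof=1))
    if se == 0:
        se = np.finfo(float).tiny
    return _normal_estimate(
        "wmedian", beta, se, L, settings={"n_boot": n_boot, "seed": seed}
    )


# ---------------------------------------------------------------------------
# Mode-based estimate

MODE_GRID_SIZE = 512


def _mode_of_ratios(
    ratios: np.ndarray, weights: np.ndarray | None, phi: float
) -> tuple[float, float]:
    """Argmax of a normal-kernel density of the ratios; returns (mode, bandwidth).

    Bandwidth: phi * 0.9 * min(sd, 1.4826*mad) * L^(-1/5).  Weighted
    variant multiplies kernel contributions by weights normalized to sum L.
    Grid argmax ties break towards the smallest grid index.
    """
    L = ratios.size
    sd = float(np.std(ratios, ddof=1)) if L > 1 else 0.0
    mad = float(stats.median_abs_deviation(ratios, scale="normal"))
    spread = min(x for x in (sd, mad) if x > 0) if (sd > 0 or mad > 0) else 0.0
    h = phi * 0.9 * spread * L ** (-1 / 5)
    if h == 0:  # all ratios identical
        return float(ratios[0]), 0.0
    grid = np.linspace(ratios.min() - h, ratios.max() + h, MODE_GRID_SIZE)
    if weights is None:
        wts = np.ones(L)
    else:
        wts = weights * (L / np.sum(weights))
    dens = wts @ np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2)
    return float(grid[int(np.argmax(dens))]), h


def mode_based(
    instruments: InstrumentSet,
    phi: float = 1.0,
    weighting: str = "simple",
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Mode of the kernel-smoothed density of per-SNP Wald ratios.

    Consistent when the largest homogeneous cluster of ratios comes from
    valid instruments, even if they carry under half the weight.  ``phi``
    scales the kernel bandwidth; ``weighting`` selects the simple or the
    inverse-variance-weighted density.  SE by seeded parametric bootstrap.
    """
    if seed is None:
        raise EstimationError("mode_based requires an explicit seed (reproducibility)")
    if weighting not in ("simple", "weighted"):
        raise ValueError(f"unknown mode weighting {weighting!r}")
    if not phi > 0:
        raise ValueError("phi must be positive")
    L = len(instruments)
    if L < 3:
        raise EstimationError(f"mode_based needs >=3 SNPs, got {L}")
    g, seg, G, seG = instruments.gammas()
    ratios = G / g
    weights = g**2 / seG**2 if weighting == "weighted" else None
    beta, h = _mode_of_ratios(ratios, weights, phi)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        gb = rng.normal(g, seg)
        Gb = rng.normal(G, seG)
        gb = np.where(gb == 0, np.finfo(float).tiny, gb)
        rb = Gb / gb
        wb = gb**2 / seG**2 if weighting == "weighted" else None
        boots[i], _ = _mode_of_ratios(rb, wb, phi)
    se = float(np.std(boots, ddof=1))
    if se == 0:
        se = np.finfo(float).tiny
    method = "mode_simple" if weighting == "simple" else "mode_weighted"
    return _normal_estimate(
        method, beta, se, L,
        settings={"phi": phi, "bandwidth": h, "n_boot": n_boot, "seed": seed},
    )


# ---------------------------------------------------------------------------
# MR-Egger + SIMEX


def _egger_slopes_matrix(g: np.ndarray, G: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Egger fits: rows of (g, G) are independent pseudo-datasets.

    Each row is re-oriented to gamma >= 0 before fitting.  Returns
    (slopes, slope_variances) with the multiplicative residual scaling.
    """
    sign = np.where(g < 0, -1.0, 1.0)
    x = g * sign
    y = G * sign
    L = x.shape[1]
    sw = np.sum(w)
    swx = x @ w
    swxx = (x**2) @ w
    swy = y @ w
    swxy = (x * y) @ w
    det = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    resid = y - intercept[:, None] - slope[:, None] * x
    rss_w = (resid**2) @ w
    scale2 = np.maximum(1.0, rss_w / (L - 2))
    var_slope = sw / det * scale2
    return slope, var_slope


def _quad_extrapolate(lambdas: np.ndarray, values: np.ndarray, at: float = -1.0) -> float:
    coef = np.polynomial.polynomial.polyfit(lambdas, values, 2)
    return float(np.polynomial.polynomial.polyval(at, coef))


def egger_simex(
    instruments: InstrumentSet,
    lambdas: Sequence[float] = (0.0, 0.5, 1.0, 1.5, 2.0),
    n_sim: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """SIMEX-corrected MR-Egger slope.

    Measurement error in the SNP-exposure estimates attenuates the Egger
    slope towards the null (regression dilution; the NOME violation
    quantified by I2_GX).  SIMEX adds further noise of known size
    lambda * se_gamma^2, traces how the average slope degrades, fits a
    quadratic in lambda, and extrapolates back to lambda = -1 (no error).
    The SE extrapolates the sampling variance (mean model-based variance
    minus between-simulation variance) the same way, falling back to the
    plain Egger SE when that extrapolation is non-positive.
    """
    if seed is None:
        raise EstimationError("egger_simex requires an explicit seed (reproducibility)")
    lam = np.asarray(list(lambdas), dtype=float)
    if lam.size < 3:
        raise EstimationError("SIMEX needs >=3 lambda values for quadratic extrapolation")
    if lam[0] != 0.0 or np.any(np.diff(lam) <= 0):
        raise EstimationError("lambdas must start at 0 and strictly increase")
    if n_sim < 100:
        logger.warning("egger_simex: n_sim=%d is small; extrapolation will be noisy", n_sim)
    L = len(instruments)
    if L < 3:
        raise EstimationError(f"egger_simex needs >=3 SNPs, got {L}")
    _check_oriented(instruments)
    g, seg, G, seG = instruments.gammas()
    w = 1.0 / seG**2

    rng = np.random.default_rng(seed)
    mean_slopes = np.empty(lam.size)
    var_hat = np.empty(lam.size)
    Gmat = np.broadcast_to(G, (n_sim, L))
    for i, lmb in enumerate(lam):
        if lmb == 0.0:
            slopes, vars_ = _egger_slopes_matrix(g[None, :], G[None, :], w)
            mean_slopes[i] = slopes[0]
            var_hat[i] = vars_[0]
            continue
        gstar = g[None, :] + np.sqrt(lmb) * rng.normal(0.0, seg, size=(n_sim, L))
        slopes, vars_ = _egger_slopes_matrix(gstar, Gmat, w)
        mean_slopes[i] = slopes.mean()
        var_hat[i] = vars_.mean() - slopes.var(ddof=1)

    beta = _quad_extrapolate(lam, mean_slopes)
    var_extrap = _quad_extrapolate(lam, var_hat)
    if var_extrap > 0:
        se = float(np.sqrt(var_extrap))
    else:
        se = float(np.sqrt(var_hat[0]))
        logger.warning("egger_simex: variance extrapolation non-positive; using Egger SE")
    return _t_estimate(
        "egger_simex", beta, se, L - 2, L,
        settings={
            "lambdas": [float(x) for x in lam],
            "n_sim": n_sim,
            "seed": seed,
            "slopes_by_lambda": [float(x) for x in mean_slopes],
        },
    )


# ---------------------------------------------------------------------------
# scale conversions


def to_odds_ratio(est: MREstimate) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate and its CI to the odds-ratio scale."""
    return (float(np.exp(est.beta)), float(np.exp(est.ci_low)), float(np.exp(est.ci_high)))


def rescale(est: MREstimate, factor: float, new_unit: str = "") -> MREstimate:
    """Multiply beta, SE and CI by a unit-conversion factor (e.g. SD -> years: 3.6)."""
    if factor == 0:
        raise ValueError("rescale factor must be nonzero")
    lo, hi = est.ci_low * factor, est.ci_high * factor
    if factor < 0:
        lo, hi = hi, lo
    return dc_replace(
        est,
        beta=est.beta * factor,
        se=est.se * abs(factor),
        ci_low=lo,
        ci_high=hi,
        unit=new_unit or est.unit,
    )


#: years of schooling per 1 SD of educational attainment
YEARS_PER_SD_EDUCATION = 3.6
DAYS_PER_YEAR = 365.25
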