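"""Allele harmonisation of exposure and outcome summary statistics.

Two consortium tables may report the same SNP on different effect alleles
or opposite strands.  Harmonisation expresses both associations per copy of
the same allele: if the outcome's effect allele is the exposure's other
allele (directly or through the strand complement A<->T, C<->G) the outcome
beta is sign-flipped and its allele frequency complemented.  Palindromic
variants (A/T, G/C), whose strand cannot be resolved from alleles, are
resolved from allele frequencies or dropped.  Finally the instrument is
oriented so that every SNP-exposure effect is positive — the convention
required by Egger regression and used for reporting effects per 1 SD more
of the exposure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from .gwas_io import ProxyEntry, ProxyMap, SummaryRecord, SummaryTable, apply_proxies

logger = logging.getLogger("twosample_mr")

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class HarmonizationError(ValueError):
    """No SNP survived harmonisation; estimation cannot proceed."""


@dataclass(frozen=True)
class HarmonizedPair:
    """Per-SNP (gamma, Gamma) pair on a common effect allele.

    ``gamma``/``se_gamma`` are the SNP-exposure association and its SE;
    ``Gamma``/``se_Gamma`` the SNP-outcome association.  The Wald ratio
    Gamma/gamma is the per-SNP causal estimate.
    """

    snp_id: str
    gamma: float
    se_gamma: float
    Gamma: float
    se_Gamma: float
    used_outcome_snp: str = ""
    flipped: bool = False
    palindromic_resolution: str = "none"  # none | frequency | dropped

    def __post_init__(self) -> None:
        if not (self.se_gamma > 0 and self.se_Gamma > 0):
            raise ValueError(f"{self.snp_id}: standard errors must be positive")


@dataclass(frozen=True)
class DroppedSnp:
    snp_id: str
    reason: str


@dataclass
class InstrumentSet:
    """A harmonised instrument: the unit of all causal estimation."""

    exposure_name: str
    outcome_name: str
    exposure_unit: str = ""
    outcome_unit: str = ""
    outcome_type: str = "continuous"
    pairs: list[HarmonizedPair] = field(default_factory=list)
    dropped: list[DroppedSnp] = field(default_factory=list)
    n_direct: int = 0
    n_proxy: int = 0

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def provenance(self) -> tuple[int, int, int]:
        """(direct, proxy, dropped) SNP counts."""
        return (self.n_direct, self.n_proxy, len(self.dropped))

    def gammas(self):
        import numpy as np

        return (
            np.array([p.gamma for p in self.pairs]),
            np.array([p.se_gamma for p in self.pairs]),
            np.array([p.Gamma for p in self.pairs]),
            np.array([p.se_Gamma for p in self.pairs]),
        )

    def audit_frame(self) -> pd.DataFrame:
        """Harmonisation audit: one row per input SNP with the action taken."""
        rows = []
        for p in self.pairs:
            action = []
            if p.used_outcome_snp and p.used_outcome_snp != p.snp_id:
                action.append("proxy")
            if p.flipped:
                action.append("flipped")
            if not action:
                action.append("kept")
            rows.append(
                {
                    "snp": p.snp_id,
                    "used_snp": p.used_outcome_snp or p.snp_id,
                    "action": "+".join(action),
                    "reason": p.palindromic_resolution
                    if p.palindromic_resolution != "none"
                    else "",
                }
            )
        for d in self.dropped:
            rows.append({"snp": d.snp_id, "used_snp": "", "action": "dropped", "reason": d.reason})
        return pd.DataFrame(rows, columns=["snp", "used_snp", "action", "reason"])

    def write_audit(self, path: str | Path) -> None:
        self.audit_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------


def translate_proxy_record(out_rec: SummaryRecord, entry: ProxyEntry) -> SummaryRecord | None:
    """Re-express a proxy-SNP outcome record in the index SNP's alleles.

    The proxy map's allele correspondence carries the haplotype phase, so
    substituting alleles is sufficient; betas and frequencies carry over.
    Returns None when the proxy record's alleles do not match the map.
    """
    inverse = {v: k for k, v in entry.allele_correspondence.items()}
    ea = inverse.get(out_rec.effect_allele)
    oa = inverse.get(out_rec.other_allele)
    if ea is None or oa is None or ea == oa:
        return None
    return replace(out_rec, snp_id=entry.index_snp, effect_allele=ea, other_allele=oa)


def align_alleles(
    exp: SummaryRecord,
    out: SummaryRecord,
    policy: str = "frequency",
    eaf_window: float = 0.08,
) -> HarmonizedPair | DroppedSnp:
    """Align one outcome record to the exposure record's effect allele.

    Non-palindromic SNPs are matched directly or through the strand
    complement; a swapped allele order flips the outcome beta's sign and
    complements its frequency.  Palindromic SNPs are handled per ``policy``:
    ``"drop"`` always drops; ``"frequency"`` requires both allele
    frequencies to sit outside the ambiguity window around 0.5 and uses
    which side of 0.5 each falls on to decide the orientation.
    """
    if policy not in ("frequency", "drop"):
        raise ValueError(f"unknown palindromic policy {policy!r}")

    if exp.is_palindromic():
        if out.alleles != exp.alleles:
            return DroppedSnp(exp.snp_id, "allele_mismatch")
        if policy == "drop":
            return DroppedSnp(exp.snp_id, "palindromic_drop_policy")
        if exp.eaf is None or out.eaf is None:
            return DroppedSnp(exp.snp_id, "palindromic_missing_eaf")
        lo, hi = 0.5 - eaf_window, 0.5 + eaf_window
        # same-orientation reading of the outcome frequency
        out_eaf = out.eaf if out.effect_allele == exp.effect_allele else 1.0 - out.eaf
        out_beta = out.beta if out.effect_allele == exp.effect_allele else -out.beta
        if lo <= exp.eaf <= hi or lo <= out_eaf <= hi:
            return DroppedSnp(exp.snp_id, "palindromic_ambiguous_eaf")
        if (exp.eaf < 0.5) == (out_eaf < 0.5):
            flipped = out.effect_allele != exp.effect_allele
            Gamma, resolution = out_beta, "frequency"
        else:
            # minor alleles disagree: the outcome is on the other strand
            flipped = out.effect_allele == exp.effect_allele
            Gamma, resolution = -out_beta, "frequency"
        return HarmonizedPair(
            snp_id=exp.snp_id,
            gamma=exp.beta,
            se_gamma=exp.se,
            Gamma=Gamma,
            se_Gamma=out.se,
            used_outcome_snp=out.snp_id,
            flipped=flipped,
            palindromic_resolution=resolution,
        )

    exp_alleles = (exp.effect_allele, exp.other_allele)
    out_alleles = (out.effect_allele, out.other_allele)
    out_comp = (COMPLEMENT[out.effect_allele], COMPLEMENT[out.other_allele])
    if out_alleles == exp_alleles or out_comp == exp_alleles:
        Gamma, flipped = out.beta, False
    elif out_alleles == exp_alleles[::-1] or out_comp == exp_alleles[::-1]:
        Gamma, flipped = -out.beta, True
    else:
        return DroppedSnp(exp.snp_id, "allele_mismatch")
    return HarmonizedPair(
        snp_id=exp.snp_id,
        gamma=exp.beta,
        se_gamma=exp.se,
        Gamma=Gamma,
        se_Gamma=out.se,
        used_outcome_snp=out.snp_id,
        flipped=flipped,
    )


def orient_to_exposure_increasing(instruments: InstrumentSet) -> InstrumentSet:
    """Negate (gamma, Gamma) jointly wherever gamma < 0.

    Wald ratios are unchanged; afterwards every effect is expressed per
    exposure-increasing allele.  Pairs with gamma exactly 0 have no defined
    orientation and are dropped with a warning.
    """
    new_pairs: list[HarmonizedPair] = []
    dropped = list(instruments.dropped)
    for p in instruments.pairs:
        if p.gamma == 0:
            logger.warning("%s: gamma is exactly 0; dropped (undefined orientation)", p.snp_id)
            dropped.append(DroppedSnp(p.snp_id, "zero_exposure_effect"))
            continue
        if p.gamma < 0:
            p = replace(p, gamma=-p.gamma, Gamma=-p.Gamma, flipped=not p.flipped)
        new_pairs.append(p)
    return InstrumentSet(
        exposure_name=instruments.exposure_name,
        outcome_name=instruments.outcome_name,
        exposure_unit=instruments.exposure_unit,
        outcome_unit=instruments.outcome_unit,
        outcome_type=instruments.outcome_type,
        pairs=new_pairs,
        dropped=dropped,
        n_direct=instruments.n_direct,
        n_proxy=instruments.n_proxy,
    )


def harmonize_datasets(
    exposure: SummaryTable,
    outcome: SummaryTable,
    snps: Sequence[str],
    proxies: ProxyMap | None = None,
    proxy_r2_min: float = 0.8,
    palindromic_policy: str = "frequency",
    eaf_window: float = 0.08,
) -> InstrumentSet:
    """Proxy substitution -> allele alignment -> exposure-increasing orientation.

    Provenance counts satisfy direct + proxy + dropped == len(snps).
    Raises :class:`HarmonizationError` when no SNP survives.
    """
    if not snps:
        raise HarmonizationError("empty SNP list")
    proxies = proxies or ProxyMap()
    matched = apply_proxies(snps, outcome, proxies, r2_min=proxy_r2_min)

    result = InstrumentSet(
        exposure_name=exposure.trait_name,
        outcome_name=outcome.trait_name,
        exposure_unit=exposure.unit,
        outcome_unit=outcome.unit,
        outcome_type=outcome.trait_type,
    )
    for snp in snps:
        exp_rec = exposure.get(snp)
        if exp_rec is None:
            result.dropped.append(DroppedSnp(snp, "missing_in_exposure"))
            continue
        if snp not in matched:
            result.dropped.append(DroppedSnp(snp, "missing_in_outcome"))
            continue
        used_snp, is_proxy = matched[snp]
        out_rec = outcome.get(used_snp)
        if is_proxy:
            entry = max(
                (e for e in proxies.for_snp(snp) if e.proxy_snp == used_snp),
                key=lambda e: e.r2,
            )
            out_rec = translate_proxy_record(out_rec, entry)
            if out_rec is None:
                result.dropped.append(DroppedSnp(snp, "proxy_allele_mismatch"))
                continue
        aligned = align_alleles(exp_rec, out_rec, policy=palindromic_policy, eaf_window=eaf_window)
        if isinstance(aligned, DroppedSnp):
            result.dropped.append(aligned)
            continue
        aligned = replace(aligned, used_outcome_snp=used_snp)
        result.pairs.append(aligned)
        if is_proxy:
            result.n_proxy += 1
        else:
            result.n_direct += 1

    result = orient_to_exposure_increasing(result)
    # orientation may drop zero-gamma pairs; recount provenance from pairs
    kept_proxy = sum(1 for p in result.pairs if p.used_outcome_snp != p.snp_id)
    result.n_proxy = kept_proxy
    result.n_direct = len(result.pairs) - kept_proxy
    if not result.pairs:
        raise HarmonizationError(
            f"no SNP survived harmonisation of {exposure.trait_name!r} vs {outcome.trait_name!r}"
        )
    logger.info(
        "harmonized %s -> %s: %d direct, %d proxy, %d dropped",
        exposure.trait_name,
        outcome.trait_name,
        result.n_direct,
        result.n_proxy,
        len(result.dropped),
    )
    return result
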