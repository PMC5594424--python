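"""Reading, validating and writing GWAS summary-statistic tables.

The unit of input is one association record per SNP: alleles, effect size
(beta, on an additive scale), its standard error, p-value, effect-allele
frequency and sample size.  Tables for binary traits supplied as odds
ratios are converted to the log-odds scale at read time so that every
downstream computation works on the additive scale.

Instrument selection mirrors the usual GWAS post-processing: keep
genome-wide-significant SNPs (default P < 5e-8) and greedily prune by
pairwise linkage disequilibrium (default r^2 < 0.1), with the LD supplied
as a precomputed pairwise table rather than estimated from genotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("twosample_mr")

VALID_ALLELES = frozenset("ACGT")

#: canonical column names used when writing normalized tables
CANONICAL_COLUMNS = ["snp", "ea", "oa", "eaf", "beta", "se", "p", "n"]


class FormatError(ValueError):
    """A mapped column is missing or the file cannot be parsed."""


@dataclass(frozen=True)
class SummaryRecord:
    """One GWAS association: effect of one allele of one SNP on one trait."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele identical")
        if not (self.se > 0):
            raise ValueError(f"{self.snp_id}: se must be positive, got {self.se}")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.snp_id}: eaf outside [0,1]: {self.eaf}")

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset((self.effect_allele, self.other_allele))

    def is_palindromic(self) -> bool:
        """A/T or G/C variants cannot be strand-resolved from alleles alone."""
        return self.alleles in (frozenset("AT"), frozenset("GC"))


@dataclass
class SummaryTable:
    """A GWAS summary-statistic dataset for one trait, keyed by rsID."""

    trait_name: str
    trait_type: str = "continuous"  # continuous | binary
    unit: str = ""
    records: dict[str, SummaryRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"trait_type must be continuous|binary, got {self.trait_type!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.records

    def add(self, rec: SummaryRecord) -> None:
        if rec.snp_id in self.records:
            raise ValueError(f"duplicate snp_id {rec.snp_id} in table {self.trait_name!r}")
        self.records[rec.snp_id] = rec

    def get(self, snp_id: str) -> SummaryRecord | None:
        return self.records.get(snp_id)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "snp": r.snp_id,
                "ea": r.effect_allele,
                "oa": r.other_allele,
                "eaf": r.eaf,
                "beta": r.beta,
                "se": r.se,
                "p": r.pval,
                "n": r.n,
            }
            for r in self.records.values()
        ]
        return pd.DataFrame(rows, columns=CANONICAL_COLUMNS)


@dataclass(frozen=True)
class ProxyEntry:
    """One index-SNP → proxy-SNP substitution with its LD and allele map.

    ``allele_correspondence`` maps each index-SNP allele to the proxy allele
    it travels with on the same haplotype; the sign of LD (D' orientation)
    is therefore encoded in the map and never inferred here.
    """

    index_snp: str
    proxy_snp: str
    r2: float
    allele_correspondence: Mapping[str, str]

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0):
            raise ValueError(f"proxy r2 outside [0,1]: {self.r2}")
        ac = dict(self.allele_correspondence)
        if len(set(ac.values())) != len(ac):
            raise ValueError(
                f"allele correspondence for {self.index_snp}->{self.proxy_snp} is not a bijection"
            )


@dataclass
class ProxyMap:
    entries: list[ProxyEntry] = field(default_factory=list)

    def for_snp(self, index_snp: str) -> list[ProxyEntry]:
        return [e for e in self.entries if e.index_snp == index_snp]


# ---------------------------------------------------------------------------
# reading / writing


def _coerce_float(value) -> float | None:
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    return None if np.isnan(v) else v


def read_summary_table(
    path: str | Path,
    column_map: Mapping[str, str],
    trait_meta: Mapping[str, str],
    sep: str = "\t",
) -> SummaryTable:
    """Read a delimited summary-statistic file into a validated table.

    ``column_map`` maps standard field names (``snp``, ``ea``, ``oa``,
    ``eaf``, ``beta``, ``se``, ``p``, ``n``) to column names in the file.
    Mapping the key ``"or"`` instead of ``"beta"`` flags that the effect
    column holds odds ratios, which are log-converted on read.  Rows with a
    missing beta or se, a non-positive se, or a non-ACGT allele are dropped
    and counted in the log.
    """
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    or_input = "or" in column_map
    effect_key = "or" if or_input else "beta"
    required = ["snp", "ea", "oa", effect_key, "se", "p"]
    for key in required:
        if key not in column_map:
            raise FormatError(f"column_map lacks required field {key!r}")
        if column_map[key] not in df.columns:
            raise FormatError(
                f"mapped column {column_map[key]!r} (field {key!r}) not in {path}"
            )
    for key in ("eaf", "n"):
        if key in column_map and column_map[key] not in df.columns:
            raise FormatError(
                f"mapped column {column_map[key]!r} (field {key!r}) not in {path}"
            )

    table = SummaryTable(
        trait_name=str(trait_meta.get("name", Path(path).stem)),
        trait_type=str(trait_meta.get("type", "continuous")),
        unit=str(trait_meta.get("unit", "")),
    )
    dropped = 0
    for _, row in df.iterrows():
        beta = _coerce_float(row[column_map[effect_key]])
        se = _coerce_float(row[column_map["se"]])
        if beta is None or se is None:
            dropped += 1
            continue
        if or_input:
            if beta <= 0:
                dropped += 1
                continue
            beta = float(np.log(beta))
        eaf = _coerce_float(row[column_map["eaf"]]) if "eaf" in column_map else None
        n_val = _coerce_float(row[column_map["n"]]) if "n" in column_map else None
        pval = _coerce_float(row[column_map["p"]])
        try:
            rec = SummaryRecord(
                snp_id=str(row[column_map["snp"]]),
                effect_allele=str(row[column_map["ea"]]).upper(),
                other_allele=str(row[column_map["oa"]]).upper(),
                beta=beta,
                se=se,
                pval=pval if pval is not None else 1.0,
                eaf=eaf,
                n=int(n_val) if n_val is not None else None,
            )
            table.add(rec)
        except ValueError as exc:
            logger.warning("dropping row: %s", exc)
            dropped += 1
    if dropped:
        logger.info(
            "read_summary_table(%s): %d record(s) dropped, %d kept", path, dropped, len(table)
        )
    table.n_dropped_rows = dropped  # type: ignore[attr-defined]
    return table


def write_summary_table(table: SummaryTable, path: str | Path) -> None:
    """Write a table as TSV with the canonical column names."""
    table.to_dataframe().to_csv(path, sep="\t", index=False)


def read_proxy_map(path: str | Path) -> ProxyMap:
    """Read a proxy TSV: index_snp, proxy_snp, r2, index_ea, index_oa, proxy_ea, proxy_oa."""
    df = pd.read_csv(path, sep="\t")
    entries = []
    for _, row in df.iterrows():
        entries.append(
            ProxyEntry(
                index_snp=str(row["index_snp"]),
                proxy_snp=str(row["proxy_snp"]),
                r2=float(row["r2"]),
                allele_correspondence={
                    str(row["index_ea"]).upper(): str(row["proxy_ea"]).upper(),
                    str(row["index_oa"]).upper(): str(row["proxy_oa"]).upper(),
                },
            )
        )
    return ProxyMap(entries)


class LDTable:
    """Symmetric pairwise r^2 lookup; a missing pair is treated as r^2 = 0."""

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None):
        self._r2: dict[frozenset[str], float] = {}
        if pairs:
            for (a, b), r2 in pairs.items():
                self.set(a, b, r2)
        self._warned_missing = False

    def set(self, snp1: str, snp2: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 outside [0,1]: {r2}")
        self._r2[frozenset((snp1, snp2))] = r2

    def get(self, snp1: str, snp2: str) -> float:
        if snp1 == snp2:
            return 1.0
        key = frozenset((snp1, snp2))
        if key not in self._r2:
            if not self._warned_missing:
                logger.warning(
                    "LD table missing pair (%s, %s); missing pairs treated as r2=0", snp1, snp2
                )
                self._warned_missing = True
            return 0.0
        return self._r2[key]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LDTable":
        df = pd.read_csv(path, sep="\t")
        ld = cls()
        for _, row in df.iterrows():
            ld.set(str(row["snp1"]), str(row["snp2"]), float(row["r2"]))
        return ld


# ---------------------------------------------------------------------------
# instrument selection


def select_instruments(
    table: SummaryTable,
    p_threshold: float = 5e-8,
    ld: LDTable | None = None,
    r2_max: float = 0.1,
) -> list[str]:
    """Greedy LD pruning of genome-wide-significant SNPs.

    Candidates with p < ``p_threshold`` are ranked by ascending p-value
    (ties broken by larger \\|beta\\|, then lexicographic rsID, so the result
    is invariant to input row order); a SNP is kept iff its r^2 with every
    already-kept SNP is below ``r2_max``.  Returns rsIDs in selection order.
    """
    if ld is None:
        ld = LDTable()
    candidates = [r for r in table.records.values() if r.pval < p_threshold]
    candidates.sort(key=lambda r: (r.pval, -abs(r.beta), r.snp_id))
    kept: list[str] = []
    for rec in candidates:
        if all(ld.get(rec.snp_id, k) < r2_max for k in kept):
            kept.append(rec.snp_id)
    if not kept:
        logger.warning(
            "select_instruments: no SNP passes p<%g in table %r", p_threshold, table.trait_name
        )
    return kept


def apply_proxies(
    wanted: Sequence[str],
    outcome: SummaryTable,
    proxies: ProxyMap | None = None,
    r2_min: float = 0.8,
) -> dict[str, tuple[str, bool]]:
    """Match wanted SNPs against an outcome table, substituting proxies.

    A direct match is always preferred; otherwise the best-r^2 proxy with
    r^2 >= ``r2_min`` that is present in the outcome is used.  SNPs with
    neither are absent from the returned mapping and logged as unmatched.
    """
    if not (0.0 < r2_min <= 1.0):
        raise ValueError(f"r2_min must be in (0,1], got {r2_min}")
    proxies = proxies or ProxyMap()
    mapping: dict[str, tuple[str, bool]] = {}
    unmatched = []
    for snp in wanted:
        if snp in outcome:
            mapping[snp] = (snp, False)
            continue
        best: ProxyEntry | None = None
        for entry in proxies.for_snp(snp):
            if entry.r2 < r2_min or entry.proxy_snp not in outcome:
                continue
            if not entry.allele_correspondence:
                logger.warning(
                    "proxy %s for %s has no allele correspondence; skipped",
                    entry.proxy_snp,
                    snp,
                )
                continue
            if best is None or entry.r2 > best.r2:
                best = entry
        if best is not None:
            mapping[snp] = (best.proxy_snp, True)
        else:
            unmatched.append(snp)
    if unmatched:
        logger.info("apply_proxies: %d SNP(s) unmatched: %s", len(unmatched), unmatched)
    return mapping
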