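"""Tiered polygenic risk score construction.

Scores are unit-weighted additive risk-allele counts over SNPs passing a
strict p-value threshold, optionally intersected with the GSEA-mapped or
mapped-and-functional tier, then Z-standardized across samples.  The risk
allele is oriented by the summary-statistic direction: the effect allele when
the direction is positive, the other allele when negative.  Alleles are
matched literally against the genotype file; palindromic mismatches raise
rather than silently strand-flipping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dataio import GenotypeMatrix, InputError, SummaryStat

logger = logging.getLogger("funprs")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class OrientationError(ValueError):
    """A scoring SNP lacks the direction needed to orient its risk allele."""


class AlleleMismatchError(ValueError):
    """Risk/other alleles cannot be reconciled with the genotype alleles."""


@dataclass(frozen=True)
class ScoringSnp:
    snp_id: str
    risk_allele: str
    weight: float = 1.0  # unit weights by construction


@dataclass
class PrsResult:
    tier: str
    threshold: float
    sample_ids: list[str]
    raw: np.ndarray
    z: np.ndarray
    n_snps_used: int
    n_snps_missing_from_genotypes: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "raw": self.raw,
                "z": self.z,
                "n_snps_used": self.n_snps_used,
            }
        )


def select_scoring_snps(
    stats: Sequence[SummaryStat],
    tier_list: Iterable[str] | None,
    threshold: float = 0.05,
) -> list[ScoringSnp]:
    """Select SNPs with p strictly below ``threshold``, intersected with a
    tier list (None means the all-SNP tier), risk allele oriented by the
    direction column."""
    tier = None if tier_list is None else set(tier_list)
    out = []
    for s in stats:
        if s.pvalue >= threshold:
            continue
        if tier is not None and s.snp_id not in tier:
            continue
        if s.direction is None or s.direction == 0:
            raise OrientationError(
                f"SNP {s.snp_id} selected for scoring but has no direction; "
                "cannot orient its risk allele"
            )
        risk = s.allele_effect if s.direction > 0 else s.allele_other
        out.append(ScoringSnp(snp_id=s.snp_id, risk_allele=risk))
    return out


def compute_prs(
    matrix: GenotypeMatrix,
    scoring_snps: Sequence[ScoringSnp],
    missing_policy: str = "mean_impute",
) -> tuple[np.ndarray, int, int]:
    """Sum risk-allele counts per sample.

    Dosage is flipped (2 - d) when the risk allele is the non-counted allele.
    Missing calls contribute twice the sample-set risk-allele frequency at
    that SNP under ``mean_impute``; under ``omit`` they contribute 0.
    Returns (raw scores, n_snps_used, n_snps_missing_from_genotypes).
    """
    if missing_policy not in ("mean_impute", "omit"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    v = matrix.variants
    col = {snp: j for j, snp in enumerate(v["snp_id"])}
    raw = np.zeros(matrix.n_samples)
    used = 0
    absent = 0
    mismatched: list[str] = []
    for snp in scoring_snps:
        j = col.get(snp.snp_id)
        if j is None:
            absent += 1
            continue
        counted = v["allele_counted"].iloc[j]
        other = v["allele_other"].iloc[j]
        if snp.risk_allele == counted:
            d = matrix.dosage[:, j]
        elif snp.risk_allele == other:
            d = 2.0 - matrix.dosage[:, j]
        else:
            mismatched.append(snp.snp_id)
            continue
        miss = np.isnan(d)
        if miss.any():
            if missing_policy == "mean_impute":
                fill = d[~miss].mean() if (~miss).any() else 0.0
            else:
                fill = 0.0
            d = np.where(miss, fill, d)
        raw += d
        used += 1
    if mismatched:
        raise AlleleMismatchError(
            "risk alleles irreconcilable with genotype alleles (possible "
            f"palindromic strand ambiguity): {mismatched[:10]}"
        )
    if used == 0:
        raise InputError("zero usable scoring SNPs in the genotype matrix")
    return raw, used, absent


def z_transform(raw: np.ndarray) -> np.ndarray:
    """Standardize to mean 0, sd 1 (n-1 denominator)."""
    raw = np.asarray(raw, dtype=float)
    if raw.size < 2:
        raise InputError("z_transform needs >= 2 samples")
    sd = raw.std(ddof=1)
    if sd == 0:
        raise InputError("z_transform: scores have zero variance")
    return (raw - raw.mean()) / sd


def build_prs(
    matrix: GenotypeMatrix,
    stats: Sequence[SummaryStat],
    tier: str,
    tier_list: Iterable[str] | None = None,
    threshold: float = 0.05,
    missing_policy: str = "mean_impute",
) -> PrsResult:
    """Select, score and standardize in one step (tier in all/mapped/functional)."""
    snps = select_scoring_snps(stats, tier_list, threshold)
    raw, used, absent = compute_prs(matrix, snps, missing_policy)
    return PrsResult(
        tier=tier,
        threshold=threshold,
        sample_ids=list(matrix.sample_ids),
        raw=raw,
        z=z_transform(raw),
        n_snps_used=used,
        n_snps_missing_from_genotypes=absent,
    )


def prs_summary(
    results: Sequence[PrsResult],
    extra_columns: Mapping[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Pearson correlation matrix plus means/SDs of the raw (unstandardized)
    scores, with optional extra per-sample columns (e.g. phenotype waves)."""
    if not results:
        raise InputError("no PRS results to summarize")
    ids = results[0].sample_ids
    for r in results:
        if r.sample_ids != ids:
            raise InputError("sample ids differ across PRS results")
    data = {r.tier: r.raw for r in results}
    for name, col in (extra_columns or {}).items():
        col = np.asarray(col, dtype=float)
        if col.size != len(ids):
            raise InputError(f"extra column {name!r} length mismatch")
        data[name] = col
    df = pd.DataFrame(data)
    corr = df.corr(method="pearson")
    corr.index.name = "variable"
    out = corr.reset_index()
    means = ["mean"] + [df[c].mean() for c in corr.columns]
    sds = ["sd"] + [df[c].std(ddof=1) for c in corr.columns]
    out.loc[len(out)] = means
    out.loc[len(out)] = sds
    return out
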