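"""Genotype quality control.

Hardy–Weinberg exact test (conditional enumeration over heterozygote counts,
log-space recurrence), per-variant/per-sample call-rate and MAF statistics,
threshold filters in a fixed order, and physical-window LD pruning on squared
Pearson correlation of dosages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .dataio import GenotypeMatrix, InputError


class GenotypeCounts(NamedTuple):
    """Genotype counts: major homozygote, heterozygote, minor homozygote."""

    n_AA: int
    n_Aa: int
    n_aa: int


@dataclass
class QcReport:
    """Per-variant and per-sample QC statistics plus removal lists."""

    variant_stats: pd.DataFrame  # snp_id, maf, call_rate, hwe_p, all_missing
    sample_call_rate: pd.DataFrame  # sample_id, call_rate
    removed_variants: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)
    removed_samples: list[tuple[str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def _hwe_log_pmf(n_het: np.ndarray, n: int, n_a: int) -> np.ndarray:
    """Log conditional probability of each heterozygote count given allele
    counts: P(n_Aa) = n! / (n_AA! n_Aa! n_aa!) * 2^n_Aa * nA! na! / (2n)!"""
    from scipy.special import gammaln

    n_A = 2 * n - n_a
    n_aa = (n_a - n_het) // 2
    n_AA = n - n_het - n_aa
    return (
        gammaln(n + 1)
        - gammaln(n_AA + 1)
        - gammaln(n_het + 1)
        - gammaln(n_aa + 1)
        + n_het * np.log(2.0)
        + gammaln(n_A + 1)
        + gammaln(n_a + 1)
        - gammaln(2 * n + 1)
    )


def hwe_exact_p(counts: GenotypeCounts) -> float:
    """Exact conditional Hardy–Weinberg test p-value.

    Enumerates every heterozygote count consistent with the observed allele
    counts and sums the probabilities of configurations no more likely than
    the observed one.  Monomorphic variants return 1.0.
    """
    n_AA, n_Aa, n_aa = (int(x) for x in counts)
    if min(n_AA, n_Aa, n_aa) < 0:
        raise InputError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise InputError("total genotype count must be >= 1")
    n_minor = 2 * n_aa + n_Aa
    n_major = 2 * n_AA + n_Aa
    if n_minor > n_major:  # orient so 'a' is the minor allele
        n_minor, n_major = n_major, n_minor
    if n_minor == 0:
        return 1.0
    # heterozygote counts sharing the parity of the minor-allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    logp = _hwe_log_pmf(hets, n, n_minor)
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[hets == n_Aa][0]
    # sum of probabilities <= observed, with tolerance for float ties
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# Per-variant / per-sample statistics
# ---------------------------------------------------------------------------

def genotype_counts(dosage_col: np.ndarray) -> GenotypeCounts:
    """Genotype counts of one variant, oriented so the counted allele's
    homozygote is n_aa when it is minor (hwe_exact_p re-orients anyway)."""
    d = dosage_col[~np.isnan(dosage_col)]
    n2 = int((d == 2).sum())
    n1 = int((d == 1).sum())
    n0 = int((d == 0).sum())
    return GenotypeCounts(n_AA=n0, n_Aa=n1, n_aa=n2)


def variant_stats(matrix: GenotypeMatrix) -> QcReport:
    """Compute MAF, call rates and HWE p per variant, call rate per sample."""
    if matrix.n_variants == 0 or matrix.n_samples == 0:
        raise InputError("empty genotype matrix")
    d = matrix.dosage
    obs = ~np.isnan(d)
    n_obs = obs.sum(axis=0)
    call_rate = n_obs / d.shape[0]
    with np.errstate(invalid="ignore"):
        freq = np.nansum(d, axis=0) / (2 * np.maximum(n_obs, 1))
    freq = np.where(n_obs == 0, 0.0, freq)
    maf = np.minimum(freq, 1 - freq)
    all_missing = n_obs == 0
    hwe_p = np.ones(d.shape[1])
    for j in range(d.shape[1]):
        if n_obs[j] > 0:
            hwe_p[j] = hwe_exact_p(genotype_counts(d[:, j]))
    vstats = pd.DataFrame(
        {
            "snp_id": matrix.variants["snp_id"].to_numpy(),
            "maf": maf,
            "call_rate": call_rate,
            "hwe_p": hwe_p,
            "all_missing": all_missing,
        }
    )
    sstats = pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "call_rate": obs.sum(axis=1) / max(d.shape[1], 1),
        }
    )
    return QcReport(variant_stats=vstats, sample_call_rate=sstats)


# ---------------------------------------------------------------------------
# Threshold filters
# ---------------------------------------------------------------------------

def apply_variant_filters(
    matrix: GenotypeMatrix,
    hwe_thresh: float = 1e-6,
    maf_min: float = 0.01,
    miss_max: float = 0.05,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the QC filters in a fixed order.

    1. variants with missingness >= ``miss_max``;
    2. samples with missingness >= ``miss_max``;
    3. variants with MAF < ``maf_min`` (recomputed on surviving samples);
    4. variants with HWE exact p < ``hwe_thresh``.
    """
    removed_variants: list[tuple[str, str]] = []
    removed_samples: list[tuple[str, str]] = []

    d = matrix.dosage
    miss_v = np.isnan(d).mean(axis=0)
    keep_v = miss_v < miss_max
    for snp in matrix.variants.loc[~keep_v, "snp_id"]:
        removed_variants.append((snp, "missingness"))
    m = matrix.subset(variant_idx=np.flatnonzero(keep_v))

    miss_s = np.isnan(m.dosage).mean(axis=1) if m.n_variants else np.zeros(m.n_samples)
    keep_s = miss_s < miss_max
    for i in np.flatnonzero(~keep_s):
        removed_samples.append((m.sample_ids[i], "missingness"))
    m = m.subset(sample_idx=np.flatnonzero(keep_s))
    if m.n_samples == 0 or m.n_variants == 0:
        raise InputError("all samples or variants removed by missingness filter")

    report = variant_stats(m)
    vs = report.variant_stats
    keep_maf = (vs["maf"] >= maf_min).to_numpy()
    for snp in vs.loc[~keep_maf, "snp_id"]:
        removed_variants.append((snp, "maf"))
    keep_hwe = (vs["hwe_p"] >= hwe_thresh).to_numpy()
    for snp in vs.loc[keep_maf & ~keep_hwe, "snp_id"]:
        removed_variants.append((snp, "hwe"))
    m = m.subset(variant_idx=np.flatnonzero(keep_maf & keep_hwe))
    if m.n_variants == 0:
        raise InputError("all variants filtered")

    final = variant_stats(m)
    final.removed_variants = removed_variants
    final.removed_samples = removed_samples
    return m, final


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _pairwise_r2(d: np.ndarray, i: int, j: int) -> float:
    """Squared Pearson correlation of two dosage columns over
    pairwise-complete samples; 0 if undefined."""
    a, b = d[:, i], d[:, j]
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 2:
        return 0.0
    a, b = a[ok], b[ok]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _prune_set(
    d: np.ndarray,
    maf: np.ndarray,
    pos: np.ndarray,
    candidates: list[int],
    kept: set[int],
    window_bp: float,
    r2_max: float,
) -> None:
    """Greedy removal among ``candidates`` (already restricted to one
    chromosome): while a kept pair within window_bp has r2 > r2_max, remove
    the lower-MAF member of the most offending variants (tie: later position).
    Mutates ``kept`` in place."""
    cand = [c for c in candidates if c in kept]  # sorted by position
    pairs: set[tuple[int, int]] = set()
    for ai in range(len(cand)):
        for bi in range(ai + 1, len(cand)):
            i, j = cand[ai], cand[bi]
            if pos[j] - pos[i] > window_bp:
                break  # candidates sorted by position
            if _pairwise_r2(d, i, j) > r2_max:
                pairs.add((i, j))
    # removing a variant never creates new violating pairs, so one pair scan
    # suffices; iterate the deterministic removal rule on the shrinking set
    while pairs:
        violating = {i for p in pairs for i in p}
        # tie rule: remove lowest MAF, ties broken by later position
        drop = min(violating, key=lambda k: (maf[k], -pos[k]))
        kept.discard(drop)
        pairs = {p for p in pairs if drop not in p}


def ld_prune(
    matrix: GenotypeMatrix,
    window_kb: float = 50.0,
    step_snps: int = 5,
    r2_max: float = 0.5,
) -> list[str]:
    """Sliding-window LD pruning; returns the kept snp_id list.

    Variants must be sorted by (chrom, pos).  Windows are physical
    (``window_kb``) anchored every ``step_snps`` variants; a final global pass
    applies the same removal rule to any residual violating pair, so the
    retained set satisfies: no kept pair within ``window_kb`` has
    r² > ``r2_max``.
    """
    v = matrix.variants
    chrom = v["chrom"].to_numpy()
    pos = v["pos"].to_numpy(dtype=float)
    order_ok = True
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        if not np.all(np.diff(pos[idx]) >= 0):
            order_ok = False
    # also require chromosome blocks to be contiguous
    block_starts = np.flatnonzero(np.r_[True, chrom[1:] != chrom[:-1]])
    if len(block_starts) != len(pd.unique(chrom)):
        order_ok = False
    if not order_ok:
        raise InputError("variants must be sorted by (chrom, pos) for ld_prune")

    window_bp = window_kb * 1000.0
    d = matrix.dosage
    obs = ~np.isnan(d)
    with np.errstate(invalid="ignore"):
        freq = np.nansum(d, axis=0) / (2 * np.maximum(obs.sum(axis=0), 1))
    maf = np.minimum(freq, 1 - freq)

    kept: set[int] = set(range(matrix.n_variants))
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        cpos = pos[idx]
        start = 0
        while start < len(idx):
            stop = int(np.searchsorted(cpos, cpos[start] + window_bp, side="right"))
            _prune_set(d, maf, pos, list(idx[start:stop]), kept, window_bp, r2_max)
            start += max(step_snps, 1)
        # global cleanup on this chromosome: same rule over all kept pairs
        _prune_set(d, maf, pos, list(idx), kept, window_bp, r2_max)

    return [v["snp_id"].iloc[i] for i in sorted(kept)]
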