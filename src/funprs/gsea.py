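"""Competitive gene-set enrichment of GWAS summary statistics.

The engine maps SNPs to genes within a symmetric flank, scores each gene by
the best (smallest) p-value among its mapped SNPs on the -log10 scale, walks
the ranked gene list with a weighted Kolmogorov-Smirnov running sum to get a
per-set enrichment score (ES), rescales it by the ratio of significant-gene
proportions inside vs. outside the set (SPES, the competitive correction),
and calibrates significance by SNP-label permutation: p-values are shuffled
across SNP identifiers, preserving the SNP-to-gene topology, and the tail
ratio of permuted to observed SPES counts gives a monotone FDR q-value.

SNPs belonging to retained (FDR < threshold) sets are finally extracted at
two nested tiers: all mapped SNPs, and the subset that is functionally
annotated (directly or through an LD proxy).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataio import (
    FunctionalIndex,
    GeneAnnotation,
    GeneSetCollection,
    InputError,
    SummaryStat,
)

logger = logging.getLogger("funprs")

DEFAULT_FLANK_BP = 20_000
DEFAULT_SET_SIZE = (10, 200)
DEFAULT_TOP_FRAC = 0.05
# permutation FDR is estimated (and internally reportable) up to this cap;
# set selection uses the stricter fdr_max passed to select_gene_sets
FDR_REPORT_CAP = 1.0


class UndefinedStatisticError(ValueError):
    """The enrichment statistic is undefined for this set/universe pair."""


# ---------------------------------------------------------------------------
# SNP -> gene mapping
# ---------------------------------------------------------------------------

@dataclass
class SnpGeneMap:
    """(snp_id, gene_id) pairs from interval overlap with a symmetric flank."""

    pairs: pd.DataFrame  # columns: snp_id, gene_id
    flank_bp: int = DEFAULT_FLANK_BP

    @property
    def snp_ids(self) -> set[str]:
        return set(self.pairs["snp_id"])

    @property
    def gene_ids(self) -> set[str]:
        return set(self.pairs["gene_id"])

    def genes_of(self) -> dict[str, list[str]]:
        """gene_id -> list of mapped snp_ids."""
        out: dict[str, list[str]] = {}
        for s, g in zip(self.pairs["snp_id"], self.pairs["gene_id"]):
            out.setdefault(g, []).append(s)
        return out


def map_snps_to_genes(
    stats: Sequence[SummaryStat],
    annotations: Sequence[GeneAnnotation],
    flank_bp: int = DEFAULT_FLANK_BP,
) -> SnpGeneMap:
    """Map each SNP to every gene whose flanked interval contains it.

    A SNP at position p maps to gene g iff chrom matches and
    ``g.start - flank_bp <= p <= g.end + flank_bp``; the flank is symmetric
    regardless of strand, and one SNP may map to several genes.
    """
    if not annotations:
        raise InputError("gene annotations are empty")
    snp_ids = np.array([s.snp_id for s in stats])
    snp_chrom = np.array([s.chrom for s in stats])
    snp_pos = np.array([s.pos for s in stats], dtype=np.int64)

    rows_snp, rows_gene = [], []
    for chrom in pd.unique(np.array([g.chrom for g in annotations])):
        genes_c = [g for g in annotations if g.chrom == chrom]
        mask = snp_chrom == chrom
        if not mask.any():
            continue
        pos_c = snp_pos[mask]
        ids_c = snp_ids[mask]
        lo = np.array([g.start - flank_bp for g in genes_c])
        hi = np.array([g.end + flank_bp for g in genes_c])
        gids = [g.gene_id for g in genes_c]
        # chunked broadcast keeps memory bounded on large inputs
        chunk = max(1, 4_000_000 // max(len(genes_c), 1))
        for start in range(0, len(pos_c), chunk):
            p = pos_c[start : start + chunk]
            hit_snp, hit_gene = np.nonzero(
                (p[:, None] >= lo[None, :]) & (p[:, None] <= hi[None, :])
            )
            rows_snp.extend(ids_c[start + hit_snp])
            rows_gene.extend(gids[j] for j in hit_gene)
    if not rows_snp:
        logger.warning(
            "map_snps_to_genes: zero SNP-gene overlaps; SNP chromosomes %s vs "
            "annotation chromosomes %s — check chromosome naming",
            sorted(set(snp_chrom))[:5],
            sorted({g.chrom for g in annotations})[:5],
        )
    pairs = pd.DataFrame({"snp_id": rows_snp, "gene_id": rows_gene})
    return SnpGeneMap(pairs=pairs, flank_bp=flank_bp)


# ---------------------------------------------------------------------------
# Gene scores
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneScore:
    gene_id: str
    score: float  # -log10 of the smallest mapped p-value
    best_snp: str
    n_snps: int


def compute_gene_scores(
    snp_map: SnpGeneMap, stats: Sequence[SummaryStat]
) -> list[GeneScore]:
    """Score each gene with >= 1 mapped SNP by max over SNPs of -log10 p.

    Returned in descending score order, ties broken by gene_id.  The gene
    universe downstream is exactly the genes present in this list.
    """
    pmap = {s.snp_id: s.pvalue for s in stats}
    missing = set(snp_map.pairs["snp_id"]) - set(pmap)
    if missing:
        raise InputError(
            f"mapped SNPs absent from summary stats: {sorted(missing)[:5]}"
        )
    out = []
    for gene, snps in snp_map.genes_of().items():
        # tie on p broken by lexicographically smallest snp_id
        best = min(snps, key=lambda s: (pmap[s], s))
        out.append(
            GeneScore(
                gene_id=gene,
                score=float(-np.log10(pmap[best])),
                best_snp=best,
                n_snps=len(snps),
            )
        )
    out.sort(key=lambda g: (-g.score, g.gene_id))
    return out


# ---------------------------------------------------------------------------
# Enrichment score and the significance-proportion correction
# ---------------------------------------------------------------------------

def _running_es(
    ordered_scores: np.ndarray, ordered_hits: np.ndarray
) -> float:
    """Weighted KS running-sum extremum for one set over a ranked universe."""
    n = ordered_scores.size
    n_hit = int(ordered_hits.sum())
    n_miss = n - n_hit
    hit_total = float(ordered_scores[ordered_hits].sum())
    if hit_total > 0:
        inc = np.where(ordered_hits, ordered_scores / hit_total, 0.0)
    else:  # all members scored 0: fall back to uniform hit weights
        inc = np.where(ordered_hits, 1.0 / n_hit, 0.0)
    dec = np.where(ordered_hits, 0.0, 1.0 / n_miss)
    running = np.cumsum(inc - dec)
    i = int(np.argmax(np.abs(running)))
    return float(np.clip(running[i], -1.0, 1.0))


def enrichment_score(
    ranked_scores: Sequence[tuple[str, float]],
    set_members: set[str],
) -> float:
    """ES of one gene set against a ranked (descending) gene list.

    Walking the list, member genes increment the running sum by
    score / (sum of member scores) and non-members decrement it by
    1 / (universe size - set size); the ES is the extremum of largest
    magnitude, in [-1, 1].
    """
    gene_ids = [g for g, _ in ranked_scores]
    scores = np.array([s for _, s in ranked_scores], dtype=float)
    if np.any(np.diff(scores) > 0):
        raise InputError("ranked_scores must be sorted in descending order")
    hits = np.array([g in set_members for g in gene_ids])
    n_hit = int(hits.sum())
    if n_hit == 0:
        raise UndefinedStatisticError("gene set has no member in the universe")
    if n_hit == len(gene_ids):
        raise UndefinedStatisticError("gene set equals the whole universe")
    return _running_es(scores, hits)


def significance_proportion_correction(
    es: float,
    set_members: set[str],
    significant_genes: set[str],
    universe: set[str],
) -> tuple[float, float, float]:
    """Rescale an ES by the ratio of significant-gene proportions.

    k = proportion of significant genes inside the set, K = proportion in the
    whole universe; the corrected score is ``spes = es * k / K`` (0 when
    K = 0, flagged by a warning).  This is the competitive correction: a set
    whose members are significant more often than the universe average is
    boosted, one relying on a few strong but unrepresentative genes is shrunk.
    """
    members = set_members & universe
    if not members:
        raise UndefinedStatisticError("gene set has no member in the universe")
    k = len(members & significant_genes) / len(members)
    K = len(significant_genes & universe) / len(universe)
    if K == 0.0:
        logger.warning("no significant genes in the universe; spes set to 0")
        return 0.0, k, K
    return es * (k / K), k, K


# ---------------------------------------------------------------------------
# Permutation FDR engine
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    n_genes_in_universe: int
    es: float
    spes: float
    k: float
    K: float
    p_perm: float
    q_fdr: float


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_id": [r.set_id for r in results],
            "size": [r.n_genes_in_universe for r in results],
            "es": [r.es for r in results],
            "spes": [r.spes for r in results],
            "k": [r.k for r in results],
            "K": [r.K for r in results],
            "p_perm": [r.p_perm for r in results],
            "q_fdr": [r.q_fdr for r in results],
        }
    )


class _VectorEngine:
    """Array-based ES/SPES computation shared by the observed pass and the
    permutation loop.

    Genes are indexed in lexicographic gene_id order so that stable sorting
    of scores reproduces the documented tie rule bit-for-bit.
    """

    def __init__(
        self,
        snp_ids: Sequence[str],
        pvalues: np.ndarray,
        snp_map: SnpGeneMap,
        collection: GeneSetCollection,
        size_min: int,
        size_max: int,
        top_frac: float,
    ) -> None:
        self.snp_ids = list(snp_ids)
        self.p = np.asarray(pvalues, dtype=float)
        snp_index = {s: i for i, s in enumerate(self.snp_ids)}

        genes = sorted(set(snp_map.pairs["gene_id"]))
        gene_index = {g: i for i, g in enumerate(genes)}
        self.genes = genes
        self.pair_snp = np.array(
            [snp_index[s] for s in snp_map.pairs["snp_id"]], dtype=np.int64
        )
        self.pair_gene = np.array(
            [gene_index[g] for g in snp_map.pairs["gene_id"]], dtype=np.int64
        )
        self.n_genes = len(genes)

        # p-value threshold defining "significant" genes: best SNP p in the
        # top top_frac of ALL SNP p-values (the pool is permutation-invariant)
        self.p_threshold = float(np.quantile(self.p, top_frac)) if top_frac > 0 else 0.0

        self.set_ids, members_rows = [], []
        self.skipped: list[tuple[str, int]] = []
        for set_id, _, members in collection:
            in_universe = [gene_index[g] for g in members if g in gene_index]
            if not (size_min <= len(in_universe) <= size_max):
                self.skipped.append((set_id, len(in_universe)))
                continue
            if len(in_universe) == self.n_genes:
                self.skipped.append((set_id, len(in_universe)))
                logger.warning("set %s equals the universe; skipped", set_id)
                continue
            self.set_ids.append(set_id)
            members_rows.append(in_universe)
        self.n_sets = len(self.set_ids)
        self.M = np.zeros((self.n_sets, self.n_genes), dtype=bool)
        for i, row in enumerate(members_rows):
            self.M[i, row] = True
        self.set_sizes = self.M.sum(axis=1)

    def gene_min_p(self, p: np.ndarray) -> np.ndarray:
        out = np.ones(self.n_genes)
        np.minimum.at(out, self.pair_gene, p[self.pair_snp])
        return out

    def spes_all_sets(self, p: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
        """(es, spes, k, K) for every tested set under p-value assignment p."""
        min_p = self.gene_min_p(p)
        score = -np.log10(min_p)
        sig = min_p <= self.p_threshold
        order = np.argsort(-score, kind="stable")  # ties -> gene_id lex order
        s_ord = score[order]
        H = self.M[:, order]
        hit_tot = H @ s_ord
        n_miss = self.n_genes - self.set_sizes
        with np.errstate(divide="ignore", invalid="ignore"):
            inc = np.where(H, s_ord[None, :], 0.0) / hit_tot[:, None]
        # sets whose members all score 0: uniform hit weights
        degen = hit_tot == 0
        if degen.any():
            inc[degen] = np.where(H[degen], 1.0 / self.set_sizes[degen, None], 0.0)
        dec = np.where(H, 0.0, 1.0) / n_miss[:, None]
        running = np.cumsum(inc - dec, axis=1)
        idx = np.argmax(np.abs(running), axis=1)
        es = np.clip(running[np.arange(self.n_sets), idx], -1.0, 1.0)
        k = (self.M @ sig.astype(np.float64)) / self.set_sizes
        K = sig.sum() / self.n_genes
        spes = es * (k / K) if K > 0 else np.zeros_like(es)
        return es, spes, k, float(K)


def permutation_fdr(
    stats: Sequence[SummaryStat],
    snp_map: SnpGeneMap,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int | None = None,
    top_frac: float = DEFAULT_TOP_FRAC,
    size_min: int = DEFAULT_SET_SIZE[0],
    size_max: int = DEFAULT_SET_SIZE[1],
) -> list[EnrichmentResult]:
    """Enrichment with SNP-label permutation p-values and tail-ratio FDR.

    Each permutation shuffles the assignment of p-values to SNP identifiers
    (the SNP->gene topology is untouched) and recomputes gene scores, ES and
    SPES for every set.  Per set, ``p_perm = (1 + #{perm spes >= observed})
    / (1 + n_perm)``.  The q-value at threshold t is the mean permutation
    count of sets with spes >= t divided by the observed count, capped at 1
    and made monotone nonincreasing in t.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    eng = _VectorEngine(
        [s.snp_id for s in stats],
        np.array([s.pvalue for s in stats]),
        snp_map,
        sets,
        size_min,
        size_max,
        top_frac,
    )
    if eng.n_sets == 0:
        logger.warning("no gene set within size bounds in the universe")
        return []
    es_obs, spes_obs, k_obs, K = eng.spes_all_sets(eng.p)

    rng = np.random.default_rng(seed)
    perm_spes = np.empty((n_perm, eng.n_sets))
    for b in range(n_perm):
        _, perm_spes[b], _, _ = eng.spes_all_sets(rng.permutation(eng.p))

    ge_counts = (perm_spes >= spes_obs[None, :]).sum(axis=0)
    p_perm = (1.0 + ge_counts) / (1.0 + n_perm)

    # tail-ratio FDR at each observed spes threshold
    flat = np.sort(perm_spes.ravel())
    obs_sorted = np.sort(spes_obs)
    q_raw = np.empty(eng.n_sets)
    for i, t in enumerate(spes_obs):
        mean_perm_ge = (flat.size - np.searchsorted(flat, t, side="left")) / n_perm
        n_obs_ge = obs_sorted.size - np.searchsorted(obs_sorted, t, side="left")
        q_raw[i] = min(FDR_REPORT_CAP, mean_perm_ge / max(n_obs_ge, 1))
    # monotone nonincreasing in t: q(t) = min over thresholds t' <= t
    order = np.argsort(spes_obs)  # ascending
    q = np.empty_like(q_raw)
    running = np.inf
    for i in order:
        running = min(running, q_raw[i])
        q[i] = running

    return [
        EnrichmentResult(
            set_id=eng.set_ids[i],
            n_genes_in_universe=int(eng.set_sizes[i]),
            es=float(es_obs[i]),
            spes=float(spes_obs[i]),
            k=float(k_obs[i]),
            K=K,
            p_perm=float(p_perm[i]),
            q_fdr=float(q[i]),
        )
        for i in range(eng.n_sets)
    ]


# ---------------------------------------------------------------------------
# Set selection and tier extraction
# ---------------------------------------------------------------------------

def select_gene_sets(
    results: Sequence[EnrichmentResult],
    fdr_max: float = 0.05,
    size_min: int = DEFAULT_SET_SIZE[0],
    size_max: int = DEFAULT_SET_SIZE[1],
) -> list[str]:
    """Retain set ids with q strictly below ``fdr_max`` and size in bounds."""
    return [
        r.set_id
        for r in results
        if r.q_fdr < fdr_max and size_min <= r.n_genes_in_universe <= size_max
    ]


@dataclass
class TierSnpLists:
    mapped: set[str] = field(default_factory=set)
    functional: set[str] = field(default_factory=set)


def extract_tier_snps(
    retained_sets: Sequence[str],
    collection: GeneSetCollection,
    snp_map: SnpGeneMap,
    functional_index: FunctionalIndex | None,
    r2_proxy: float = 0.8,
) -> TierSnpLists:
    """Extract the two nested SNP tiers from the retained gene sets.

    ``mapped`` holds every SNP mapping to any gene of a retained set;
    ``functional`` is its subset passing ``is_functional`` (direct annotation
    or LD proxy at r2 >= ``r2_proxy``).
    """
    if not retained_sets:
        logger.warning("no retained gene sets; tier SNP lists are empty")
        return TierSnpLists()
    retained_genes: set[str] = set()
    for set_id in retained_sets:
        retained_genes |= collection.members(set_id)
    pairs = snp_map.pairs
    mapped = set(pairs.loc[pairs["gene_id"].isin(retained_genes), "snp_id"])
    if functional_index is None:
        functional: set[str] = set()
    else:
        functional = {
            s for s in mapped if functional_index.is_functional(s, r2_proxy)
        }
    return TierSnpLists(mapped=mapped, functional=functional)
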