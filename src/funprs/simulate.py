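"""Synthetic inputs with the statistical structure the pipeline assumes.

One :class:`SimConfig` seed deterministically fixes a gene universe with gene
sets (some planted with inflated association), GWAS summary statistics,
Hardy-Weinberg genotypes (optionally with population structure and
missingness), per-SNP functional annotations, and longitudinal phenotypes
whose association with a PRS follows a known smooth function of age.  A truth
sidecar records everything needed to score recovery downstream.

Null SNPs draw p ~ Uniform(0,1).  SNPs in planted-set genes draw
p = 10^(-e) with e = planted_effect + Exponential(scale = 1/ln 10), so a
planted effect of 0 reduces exactly to the uniform null and the mean
-log10 p uplift over null SNPs equals ``planted_effect``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .dataio import (
    GeneAnnotation,
    GeneSetCollection,
    GenotypeMatrix,
    LongRecord,
    SummaryStat,
    write_gene_annotation_bed,
    write_gmt,
    write_plink,
    write_table,
)

ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("C", "A"), ("G", "T")]


@dataclass
class SimConfig:
    """All knobs of the generator; defaults are the study-scale conditions."""

    seed: int = 0
    n_snps: int = 20_000
    n_genes: int = 1_000
    genes_per_set: int = 20
    n_sets: int = 100
    n_planted_sets: int = 5
    planted_effect: float = 3.0  # mean -log10 p uplift in planted-set genes
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_samples: int = 500
    n_populations: int = 1
    freq_divergence: float = 0.0
    missing_rate: float = 0.0
    frac_functional: float = 0.3
    n_proxy_pairs: int = 0
    beta_profile: tuple[str, dict] = ("bump", {"center": 3.5, "width": 0.4, "height": 0.5})
    ages_per_subject: tuple[int, int] = (4, 8)
    age_range: tuple[float, float] = (2.0, 5.0)
    noise_sd: float = 1.0
    subject_sd: float = 0.5  # random-intercept SD, exercises clustered errors
    covariate_effects: Mapping[str, float] = field(default_factory=lambda: {"sex": 0.2})
    # gene layout
    flank_bp: int = 20_000
    gene_length_bp: int = 10_000
    gene_spacing_bp: int = 100_000  # start-to-start; > gene + 2*flank by default
    overlapping_genes: bool = False
    n_chromosomes: int = 2

    def validate(self) -> None:
        if min(self.n_snps, self.n_genes, self.n_sets, self.n_samples) <= 0:
            raise ValueError("all counts must be positive")
        if self.n_planted_sets > self.n_sets:
            raise ValueError("planted sets must be a subset of sets")
        if not (0.0 <= self.frac_functional <= 1.0):
            raise ValueError("frac_functional must be in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")
        if not self.overlapping_genes and self.gene_spacing_bp <= (
            self.gene_length_bp + 2 * self.flank_bp
        ):
            raise ValueError(
                "gene_spacing_bp must exceed gene_length + 2*flank for "
                "non-overlapping layout (or set overlapping_genes=True)"
            )


def beta_profile_fn(profile: tuple[str, dict]) -> Callable[[np.ndarray], np.ndarray]:
    """Named smooth effect profiles beta(t) for the phenotype generator."""
    kind, kw = profile
    if kind == "constant":
        c = float(kw.get("c", 0.5))
        return lambda t: np.full_like(np.asarray(t, dtype=float), c)
    if kind == "linear":
        a, b = float(kw.get("a", 0.0)), float(kw.get("b", 0.2))
        return lambda t: a + b * np.asarray(t, dtype=float)
    if kind == "sine":
        return lambda t: np.sin(np.asarray(t, dtype=float))
    if kind == "bump":
        c = float(kw.get("center", 3.5))
        w = float(kw.get("width", 0.4))
        h = float(kw.get("height", 0.5))
        return lambda t: h * np.exp(-((np.asarray(t, dtype=float) - c) ** 2) / (2 * w**2))
    if kind == "zero":
        return lambda t: np.zeros_like(np.asarray(t, dtype=float))
    raise ValueError(f"unknown beta profile {kind!r}")


@dataclass
class GeneUniverse:
    annotations: list[GeneAnnotation]
    collection: GeneSetCollection
    planted_set_ids: list[str]
    snp_table: pd.DataFrame  # snp_id, chrom, pos, allele_effect, allele_other
    planted_gene_ids: set[str]


def gen_gene_universe(config: SimConfig, rng: np.random.Generator | None = None) -> GeneUniverse:
    """Lay out genes, SNP positions and gene sets on simulated chromosomes.

    Genes are non-overlapping with inter-gene gaps > 2*flank by default, so
    the SNP->gene map is single-valued; ``overlapping_genes=True`` halves the
    spacing instead.  SNPs fall inside genes (one guaranteed per gene), in
    flanks, and intergenic space.  Set membership is sampled without
    replacement per set; the first ``n_planted_sets`` sets are planted.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    spacing = (
        config.gene_spacing_bp
        if not config.overlapping_genes
        else max(config.gene_length_bp // 2, 1)
    )
    genes: list[GeneAnnotation] = []
    per_chrom = -(-config.n_genes // config.n_chromosomes)
    for g in range(config.n_genes):
        chrom = f"chr{g // per_chrom + 1}"
        rank = g % per_chrom
        start = 1 + config.flank_bp + rank * spacing
        genes.append(
            GeneAnnotation(
                gene_id=f"G{g:05d}",
                chrom=chrom,
                start=start,
                end=start + config.gene_length_bp - 1,
                strand="+" if rng.random() < 0.5 else "-",
            )
        )

    chrom_span = {}
    for g in genes:
        hi = g.end + config.flank_bp + spacing
        chrom_span[g.chrom] = max(chrom_span.get(g.chrom, 1), hi)

    # one SNP mid-gene per gene, the rest uniform over each chromosome span
    snp_chrom, snp_pos = [], []
    for g in genes:
        snp_chrom.append(g.chrom)
        snp_pos.append((g.start + g.end) // 2)
    n_extra = config.n_snps - len(genes)
    if n_extra < 0:
        raise ValueError("n_snps must be >= n_genes (one SNP per gene body)")
    chroms = sorted(chrom_span)
    extra_chrom = rng.choice(len(chroms), size=n_extra)
    for ci in extra_chrom:
        c = chroms[ci]
        snp_chrom.append(c)
        snp_pos.append(int(rng.integers(1, chrom_span[c] + 1)))
    order = np.lexsort((np.array(snp_pos), np.array(snp_chrom)))
    alleles = rng.choice(len(ALLELE_PAIRS), size=config.n_snps)
    snp_table = pd.DataFrame(
        {
            "snp_id": [f"rs{i:06d}" for i in range(config.n_snps)],
            "chrom": np.array(snp_chrom)[order],
            "pos": np.array(snp_pos)[order],
            "allele_effect": [ALLELE_PAIRS[a][0] for a in alleles],
            "allele_other": [ALLELE_PAIRS[a][1] for a in alleles],
        }
    )

    gene_ids = [g.gene_id for g in genes]
    sets = []
    for s in range(config.n_sets):
        members = rng.choice(gene_ids, size=config.genes_per_set, replace=False)
        sets.append((f"SET{s:04d}", "synthetic", frozenset(members)))
    planted_ids = [sets[s][0] for s in range(config.n_planted_sets)]
    planted_genes: set[str] = set()
    for s in range(config.n_planted_sets):
        planted_genes |= set(sets[s][2])
    return GeneUniverse(
        annotations=genes,
        collection=GeneSetCollection(sets),
        planted_set_ids=planted_ids,
        snp_table=snp_table,
        planted_gene_ids=planted_genes,
    )


def _planted_snp_mask(universe: GeneUniverse, config: SimConfig) -> np.ndarray:
    """SNPs inside planted genes' bodies (effect is planted at the gene)."""
    mask = np.zeros(len(universe.snp_table), dtype=bool)
    pos = universe.snp_table["pos"].to_numpy()
    chrom = universe.snp_table["chrom"].to_numpy()
    for g in universe.annotations:
        if g.gene_id in universe.planted_gene_ids:
            mask |= (chrom == g.chrom) & (pos >= g.start) & (pos <= g.end)
    return mask


def gen_gwas_summary(
    config: SimConfig,
    universe: GeneUniverse,
    rng: np.random.Generator | None = None,
) -> list[SummaryStat]:
    """Summary statistics: uniform null p-values, shifted-exponential
    -log10 p in planted-set genes, random effect directions."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    t = universe.snp_table
    n = len(t)
    p = rng.uniform(0.0, 1.0, size=n)
    p = np.where(p == 0.0, np.nextafter(0.0, 1.0), p)
    planted = _planted_snp_mask(universe, config)
    if config.planted_effect > 0 and planted.any():
        e = config.planted_effect + rng.exponential(
            scale=1.0 / np.log(10.0), size=int(planted.sum())
        )
        p[planted] = 10.0 ** (-e)
    direction = rng.choice([-1.0, 1.0], size=n)
    return [
        SummaryStat(
            snp_id=t["snp_id"].iloc[i],
            chrom=t["chrom"].iloc[i],
            pos=int(t["pos"].iloc[i]),
            allele_effect=t["allele_effect"].iloc[i],
            allele_other=t["allele_other"].iloc[i],
            pvalue=float(p[i]),
            direction=float(direction[i]),
        )
        for i in range(n)
    ]


def gen_genotypes(
    config: SimConfig,
    universe: GeneUniverse,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Hardy-Weinberg genotypes; returns (matrix, population labels).

    Per variant the counted-allele frequency is drawn in ``maf_range``; with
    k > 1 populations the per-population frequencies are offset symmetrically
    to span ``freq_divergence``.  Optional uniform missingness.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    t = universe.snp_table
    n, m = config.n_samples, len(t)
    base = rng.uniform(*config.maf_range, size=m)
    labels = np.repeat(
        np.arange(config.n_populations),
        -(-n // config.n_populations),
    )[:n]
    if config.n_populations > 1 and config.freq_divergence > 0:
        offsets = np.linspace(
            -config.freq_divergence / 2, config.freq_divergence / 2,
            config.n_populations,
        )
        freq = np.clip(base[None, :] + offsets[:, None], 0.01, 0.99)
    else:
        freq = np.tile(base, (config.n_populations, 1))
    dosage = rng.binomial(2, freq[labels]).astype(float)
    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        dosage[mask] = np.nan
    variants = t.rename(
        columns={"allele_effect": "allele_counted"}
    )[["snp_id", "chrom", "pos", "allele_counted", "allele_other"]].copy()
    matrix = GenotypeMatrix(
        sample_ids=[f"I{i:05d}" for i in range(n)],
        variants=variants,
        dosage=dosage,
    )
    return matrix, labels


def gen_functional_annotations(
    config: SimConfig,
    universe: GeneUniverse,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign a functional class to ``frac_functional`` of gene-mapped SNPs.

    Returns (functional table, proxy table); proxies pair unannotated mapped
    SNPs with annotated ones at r2 drawn in [0.5, 1].
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    t = universe.snp_table
    pos = t["pos"].to_numpy()
    chrom = t["chrom"].to_numpy()
    mapped = np.zeros(len(t), dtype=bool)
    for g in universe.annotations:
        mapped |= (
            (chrom == g.chrom)
            & (pos >= g.start - config.flank_bp)
            & (pos <= g.end + config.flank_bp)
        )
    mapped_ids = t.loc[mapped, "snp_id"].to_numpy()
    n_fun = int(round(config.frac_functional * len(mapped_ids)))
    chosen = rng.choice(mapped_ids, size=n_fun, replace=False)
    classes = rng.choice(["coding", "regulatory", "eqtl"], size=n_fun)
    fun = pd.DataFrame({"snp_id": chosen, "class": classes}).sort_values(
        "snp_id", ignore_index=True
    )
    unannotated = sorted(set(mapped_ids) - set(chosen))
    n_proxy = min(config.n_proxy_pairs, len(unannotated), len(chosen))
    if n_proxy > 0:
        partner = rng.choice(sorted(chosen), size=n_proxy, replace=False)
        proxies = pd.DataFrame(
            {
                "snp_a": rng.choice(unannotated, size=n_proxy, replace=False),
                "snp_b": partner,
                "r2": rng.uniform(0.5, 1.0, size=n_proxy),
            }
        )
    else:
        proxies = pd.DataFrame(columns=["snp_a", "snp_b", "r2"])
    return fun, proxies


def gen_longitudinal(
    config: SimConfig,
    prs_z: np.ndarray,
    rng: np.random.Generator | None = None,
    subject_ids: list[str] | None = None,
) -> tuple[list[LongRecord], dict]:
    """Repeated-measures phenotypes with a known time-varying PRS effect.

    y = beta0(t) + beta(t) * prs_z + gamma' z + b_i + noise, with b_i a
    subject random intercept and beta(t) the configured profile; the returned
    truth dict records every generator value needed for recovery scoring.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 4)
    n = len(prs_z)
    ids = subject_ids or [f"I{i:05d}" for i in range(n)]
    profile = beta_profile_fn(config.beta_profile)
    lo, hi = config.age_range
    cov_names = sorted(config.covariate_effects)
    covs = {c: rng.integers(0, 2, size=n).astype(float) for c in cov_names}
    b = rng.normal(0.0, config.subject_sd, size=n)
    records: list[LongRecord] = []
    for i in range(n):
        k = int(rng.integers(config.ages_per_subject[0],
                             config.ages_per_subject[1] + 1))
        ages = np.sort(rng.uniform(lo, hi, size=k))
        eps = rng.normal(0.0, config.noise_sd, size=k)
        y = (
            0.5  # constant baseline beta0
            + profile(ages) * prs_z[i]
            + sum(config.covariate_effects[c] * covs[c][i] for c in cov_names)
            + b[i]
            + eps
        )
        base_cov = {c: float(covs[c][i]) for c in cov_names}
        for j in range(k):
            records.append(
                LongRecord(
                    subject_id=ids[i],
                    age=float(ages[j]),
                    phenotype=float(y[j]),
                    covariates={**base_cov, "prs_z": float(prs_z[i])},
                )
            )
    truth = {
        "beta_profile": [config.beta_profile[0], dict(config.beta_profile[1])],
        "baseline": 0.5,
        "covariate_effects": dict(config.covariate_effects),
        "noise_sd": config.noise_sd,
        "subject_sd": config.subject_sd,
        "age_range": list(config.age_range),
    }
    return records, truth


# ---------------------------------------------------------------------------
# One-call generation of every pipeline input
# ---------------------------------------------------------------------------

def simulate_all(config: SimConfig, outdir: str | Path) -> dict:
    """Write every input format the pipeline reads, plus ``truth.json``.

    The phenotype's PRS predictor is the functional-tier score implied by the
    generator's own truth (SNPs in planted genes that are functional and pass
    p < 0.05), so an end-to-end run can test recovery of a known signal.
    """
    from .gsea import map_snps_to_genes
    from .prs import build_prs
    from .dataio import read_functional_table, stats_to_frame, records_to_frame

    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    universe = gen_gene_universe(config)
    stats = gen_gwas_summary(config, universe)
    matrix, labels = gen_genotypes(config, universe)
    fun, proxies = gen_functional_annotations(config, universe)

    write_table(stats_to_frame(stats), outdir / "summary.tsv")
    write_gene_annotation_bed(universe.annotations, outdir / "genes.bed")
    write_gmt(universe.collection, outdir / "sets.gmt")
    write_table(fun, outdir / "functional.tsv")
    write_table(proxies, outdir / "proxies.tsv")
    write_plink(matrix, outdir / "genotypes")

    # truth-defined functional-tier PRS drives the phenotype
    snp_map = map_snps_to_genes(stats, universe.annotations, config.flank_bp)
    pairs = snp_map.pairs
    planted_snps = set(
        pairs.loc[pairs["gene_id"].isin(universe.planted_gene_ids), "snp_id"]
    )
    findex = read_functional_table(
        outdir / "functional.tsv",
        outdir / "proxies.tsv" if len(proxies) else None,
    )
    tier = {s for s in planted_snps if findex.is_functional(s, 0.8)}
    if not tier:  # degenerate configs (e.g. frac_functional=0) fall back
        tier = planted_snps or None
    prs = build_prs(matrix, stats, tier="functional_truth", tier_list=tier)
    records, truth_pheno = gen_longitudinal(
        config, prs.z, subject_ids=list(matrix.sample_ids)
    )
    records_to_frame(records).to_csv(outdir / "phenotypes.csv", index=False)

    truth = {
        "config": _config_dict(config),
        "planted_set_ids": universe.planted_set_ids,
        "planted_gene_ids": sorted(universe.planted_gene_ids),
        "population_labels": labels.tolist(),
        "prs_tier_snps": sorted(tier) if tier else [],
        "phenotype": truth_pheno,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth


def _config_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["covariate_effects"] = dict(config.covariate_effects)
    d["beta_profile"] = [config.beta_profile[0], dict(config.beta_profile[1])]
    return d


def config_from_json(path: str | Path) -> SimConfig:
    with open(path) as fh:
        d = json.load(fh)
    if "beta_profile" in d:
        d["beta_profile"] = (d["beta_profile"][0], dict(d["beta_profile"][1]))
    for key in ("maf_range", "ages_per_subject", "age_range"):
        if key in d:
            d[key] = tuple(d[key])
    return SimConfig(**d)
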