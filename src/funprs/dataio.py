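"""Domain types and readers/writers for every format the pipeline touches.

Internal coordinate convention is 1-based inclusive everywhere (the GFF3/VCF
convention); converters live only in the readers and writers.  Genotypes are
additive hard-call dosages in {0, 1, 2} counting the recorded ``allele_counted``
(the .bim A1 / VCF ALT allele), with missing calls stored as NaN.

Errors are split into :class:`FormatError` (malformed bytes) and
:class:`InputError` (well-formed but inconsistent content), so callers can
distinguish "fix the file" from "fix the analysis".
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("funprs")

PLINK_BED_MAGIC = b"\x6c\x1b\x01"

FUNCTIONAL_CLASSES = frozenset({"coding", "regulatory", "eqtl"})


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class InputError(ValueError):
    """A well-formed file carries content the pipeline cannot accept."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SummaryStat:
    """One GWAS variant association record."""

    snp_id: str
    chrom: str
    pos: int
    allele_effect: str
    allele_other: str
    pvalue: float
    direction: float | None = None  # sign or signed effect size; None if absent

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise InputError("snp_id must be nonempty")
        if not (0.0 < self.pvalue <= 1.0):
            raise InputError(f"pvalue {self.pvalue} outside (0, 1] for {self.snp_id}")
        if self.pos < 1:
            raise InputError(f"pos {self.pos} < 1 for {self.snp_id}")


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval, 1-based inclusive."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InputError(f"gene {self.gene_id}: start {self.start} > end {self.end}")


@dataclass
class GeneSetCollection:
    """Named gene sets (set_id, source, member gene ids)."""

    sets: list[tuple[str, str, frozenset[str]]]

    def __post_init__(self) -> None:
        ids = [s[0] for s in self.sets]
        if len(ids) != len(set(ids)):
            raise InputError("duplicate set_ids in collection")
        for set_id, _, members in self.sets:
            if not members:
                raise InputError(f"gene set {set_id} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def members(self, set_id: str) -> frozenset[str]:
        for sid, _, genes in self.sets:
            if sid == set_id:
                return genes
        raise KeyError(set_id)


class FunctionalIndex:
    """Queryable index of per-SNP functional annotation with LD proxies.

    ``is_functional(snp, r2_threshold)`` is true when the SNP carries a
    functional class itself (coding / regulatory / eQTL) or is linked by a
    proxy pair with r² ≥ threshold to an annotated SNP.
    """

    def __init__(
        self,
        classes: Mapping[str, frozenset[str]],
        proxy_pairs: Iterable[tuple[str, str, float]] = (),
    ) -> None:
        for snp, cls in classes.items():
            bad = set(cls) - FUNCTIONAL_CLASSES
            if bad:
                raise FormatError(f"unknown functional class {sorted(bad)} for {snp}")
            if not cls:
                raise InputError(f"SNP {snp} listed with empty functional class")
        self.classes = dict(classes)
        self.proxy_pairs = []
        for a, b, r2 in proxy_pairs:
            if not (0.0 <= r2 <= 1.0):
                raise InputError(f"proxy r2 {r2} outside [0,1] for ({a},{b})")
            self.proxy_pairs.append((a, b, float(r2)))
        # adjacency: snp -> list of (partner, r2)
        self._adj: dict[str, list[tuple[str, float]]] = {}
        for a, b, r2 in self.proxy_pairs:
            self._adj.setdefault(a, []).append((b, r2))
            self._adj.setdefault(b, []).append((a, r2))

    def is_functional(self, snp_id: str, r2_threshold: float = 0.8) -> bool:
        if snp_id in self.classes:
            return True
        for partner, r2 in self._adj.get(snp_id, ()):
            if r2 >= r2_threshold and partner in self.classes:
                return True
        return False


@dataclass
class GenotypeMatrix:
    """Samples x variants additive dosage matrix with missingness as NaN.

    ``dosage[i, j]`` counts copies of ``variants.allele_counted[j]`` carried by
    ``sample_ids[i]``; values are 0/1/2 or NaN.
    """

    sample_ids: list[str]
    variants: pd.DataFrame  # columns: snp_id, chrom, pos, allele_counted, allele_other
    dosage: np.ndarray  # float array, shape (n_samples, n_variants)

    def __post_init__(self) -> None:
        n, m = self.dosage.shape
        if n != len(self.sample_ids) or m != len(self.variants):
            raise InputError("dosage shape inconsistent with sample/variant metadata")
        if self.variants["snp_id"].duplicated().any():
            dups = self.variants.loc[self.variants["snp_id"].duplicated(), "snp_id"]
            raise InputError(f"duplicate variant ids: {list(dups[:5])}")
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise InputError("dosage values must be 0, 1, 2 or missing")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in si],
            variants=self.variants.iloc[vi].reset_index(drop=True),
            dosage=self.dosage[np.ix_(si, vi)].copy(),
        )


@dataclass(frozen=True)
class LongRecord:
    """One longitudinal observation: subject, age (years), outcome, covariates."""

    subject_id: str
    age: float
    phenotype: float
    covariates: Mapping[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[SummaryStat]:
    """Read GWAS summary statistics from a TSV/CSV with header.

    ``column_map`` maps the internal field names (``snp_id``, ``pvalue``
    mandatory; ``chrom``, ``pos``, ``allele_effect``, ``allele_other``,
    ``direction`` optional) to the file's column names.  Rows with p-values
    outside (0, 1] are rejected (count logged); duplicate snp_ids keep the
    smallest p-value.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty:
        raise InputError(f"{path}: no data rows")
    cmap = dict(column_map or {})
    for name in ("snp_id", "chrom", "pos", "allele_effect", "allele_other",
                 "pvalue", "direction"):
        cmap.setdefault(name, name)
    for mandatory in ("snp_id", "pvalue"):
        if cmap[mandatory] not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {cmap[mandatory]!r}")

    def col(name, default=None):
        c = cmap[name]
        if c in df.columns:
            return df[c]
        return pd.Series([default] * len(df), index=df.index)

    pvals = pd.to_numeric(col("pvalue"), errors="coerce")
    ok = pvals.notna() & (pvals > 0) & (pvals <= 1)
    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.warning("%s: rejected %d rows with p outside (0,1]", path, n_rejected)
    df = df[ok]
    pvals = pvals[ok]

    records: dict[str, SummaryStat] = {}
    directions = pd.to_numeric(
        col("direction").replace({"+": "1", "-": "-1", "−": "-1"}), errors="coerce"
    )
    pos = pd.to_numeric(col("pos", "1"), errors="coerce").fillna(1).astype(int)
    for i in df.index:
        d = directions.get(i)
        rec = SummaryStat(
            snp_id=str(df.loc[i, cmap["snp_id"]]),
            chrom=str(col("chrom", "NA").loc[i]),
            pos=int(pos.loc[i]),
            allele_effect=str(col("allele_effect", "N").loc[i]),
            allele_other=str(col("allele_other", "N").loc[i]),
            pvalue=float(pvals.loc[i]),
            direction=None if d is None or np.isnan(d) else float(d),
        )
        prev = records.get(rec.snp_id)
        if prev is None or rec.pvalue < prev.pvalue:
            records[rec.snp_id] = rec
    return list(records.values())


def stats_to_frame(stats: Sequence[SummaryStat]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in stats],
            "chrom": [s.chrom for s in stats],
            "pos": [s.pos for s in stats],
            "allele_effect": [s.allele_effect for s in stats],
            "allele_other": [s.allele_other for s in stats],
            "pvalue": [s.pvalue for s in stats],
            "direction": [s.direction for s in stats],
        }
    )


# ---------------------------------------------------------------------------
# Gene sets (GMT) and gene annotations (BED / GFF3)
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, source: str | None = None) -> GeneSetCollection:
    """Read a GMT file: per line, set name, description, then gene ids."""
    path = Path(path)
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno} has fewer than 3 fields")
            set_id, desc = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            sets.append((set_id, source or desc, genes))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id, source, genes in collection:
            fh.write("\t".join([set_id, source, *sorted(genes)]) + "\n")


def read_gene_annotation(path: str | Path, format: str) -> list[GeneAnnotation]:
    """Read gene intervals from BED (0-based half-open) or GFF3 (1-based).

    All coordinates are normalized to 1-based inclusive.  GFF3 keeps only
    features whose type column is ``gene``.
    """
    path = Path(path)
    out: list[GeneAnnotation] = []
    seen: set[str] = set()
    if format == "bed":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                if len(f) < 4:
                    raise FormatError(f"{path}: BED line {lineno} needs >= 4 columns")
                start0, end0 = int(f[1]), int(f[2])
                if start0 >= end0:
                    raise FormatError(
                        f"{path}: BED line {lineno} start {start0} >= end {end0}"
                    )
                strand = f[5] if len(f) > 5 and f[5] in "+-" else "unknown"
                out.append(GeneAnnotation(f[3], f[0], start0 + 1, end0, strand))
    elif format == "gff3":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                if len(f) < 9:
                    raise FormatError(f"{path}: GFF3 line {lineno} needs 9 columns")
                if f[2] != "gene":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                gene_id = attrs.get("ID") or attrs.get("gene_id") or f"gene_{lineno}"
                strand = f[6] if f[6] in "+-" else "unknown"
                out.append(GeneAnnotation(gene_id, f[0], int(f[3]), int(f[4]), strand))
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    for g in out:
        if g.gene_id in seen:
            raise InputError(f"{path}: duplicate gene_id {g.gene_id}")
        seen.add(g.gene_id)
    return out


def write_gene_annotation_bed(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            strand = g.strand if g.strand in "+-" else "."
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{strand}\n")


# ---------------------------------------------------------------------------
# Genotypes: PLINK .bed/.bim/.fam and VCF
# ---------------------------------------------------------------------------

# PLINK 2-bit codes, variant-major: 0b00 hom A1, 0b01 missing, 0b10 het,
# 0b11 hom A2.  A1 is the counted allele.
_PLINK_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK .bed/.bim/.fam triplet (SNP-major .bed)."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"], dtype=str,
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"], dtype=str,
    )
    n, m = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != PLINK_BED_MAGIC:
        raise FormatError(f"{prefix}.bed: bad magic bytes (not SNP-major PLINK bed)")
    bytes_per_variant = (n + 3) // 4
    payload = np.frombuffer(raw[3:], dtype=np.uint8)
    if payload.size != bytes_per_variant * m:
        raise FormatError(
            f"{prefix}.bed: payload {payload.size} bytes, expected "
            f"{bytes_per_variant * m} for {n} samples x {m} variants"
        )
    payload = payload.reshape(m, bytes_per_variant)
    # unpack 2-bit codes, sample index little-endian within each byte
    codes = np.stack(
        [(payload >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=-1
    ).reshape(m, -1)[:, :n]
    dosage = _PLINK_CODE_TO_DOSAGE[codes].T.copy()  # (n, m), counts A1
    variants = pd.DataFrame(
        {
            "snp_id": bim["snp_id"],
            "chrom": bim["chrom"],
            "pos": bim["pos"].astype(int),
            "allele_counted": bim["a1"],
            "allele_other": bim["a2"],
        }
    )
    return GenotypeMatrix(list(fam["iid"]), variants, dosage)


def write_plink(matrix: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a GenotypeMatrix as a PLINK triplet (counted allele -> A1)."""
    prefix = Path(prefix)
    n, m = matrix.dosage.shape
    v = matrix.variants
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j in range(m):
            fh.write(
                f"{v['chrom'].iloc[j]}\t{v['snp_id'].iloc[j]}\t0\t"
                f"{v['pos'].iloc[j]}\t{v['allele_counted'].iloc[j]}\t"
                f"{v['allele_other'].iloc[j]}\n"
            )
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid in matrix.sample_ids:
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t-9\n")
    # dosage -> 2-bit codes
    d = matrix.dosage.T  # variant-major
    codes = np.full(d.shape, 0b01, dtype=np.uint8)  # missing
    codes[d == 2.0] = 0b00
    codes[d == 1.0] = 0b10
    codes[d == 0.0] = 0b11
    bytes_per_variant = (n + 3) // 4
    padded = np.full((m, bytes_per_variant * 4), 0b00, dtype=np.uint8)
    padded[:, :n] = codes
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(PLINK_BED_MAGIC)
        fh.write(packed.tobytes())


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read hard-call genotypes from a VCF; dosage counts the ALT allele.

    Multiallelic sites are rejected (count logged).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    rows, dosages = [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        # gts012: 0/1/2 = ALT count, 3 = missing
        gt = var.gt_types.astype(float)
        gt[gt == 3] = np.nan
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        rows.append((snp_id, str(var.CHROM), int(var.POS), var.ALT[0], var.REF))
        dosages.append(gt)
    if n_multi:
        logger.warning("%s: rejected %d multiallelic sites", path, n_multi)
    if not rows:
        raise InputError(f"{path}: no biallelic variants")
    variants = pd.DataFrame(
        rows, columns=["snp_id", "chrom", "pos", "allele_counted", "allele_other"]
    )
    return GenotypeMatrix(sample_ids, variants, np.array(dosages).T.copy())


def read_genotypes(path_or_prefix: str | Path, format: str) -> GenotypeMatrix:
    if format == "plink":
        return read_plink(path_or_prefix)
    if format == "vcf":
        return read_vcf(path_or_prefix)
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# Functional annotations
# ---------------------------------------------------------------------------

def read_functional_table(
    path: str | Path, proxy_path: str | Path | None = None
) -> FunctionalIndex:
    """Read per-SNP functional classes (TSV: snp_id, class) and optional
    proxy pairs (TSV: snp_a, snp_b, r2)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "snp_id" not in df.columns or "class" not in df.columns:
        raise FormatError(f"{path}: need columns snp_id and class")
    classes: dict[str, set[str]] = {}
    for snp, cls in zip(df["snp_id"], df["class"]):
        for token in str(cls).split(","):
            token = token.strip()
            if token not in FUNCTIONAL_CLASSES:
                raise FormatError(f"{path}: unknown class token {token!r}")
            classes.setdefault(snp, set()).add(token)
    proxies: list[tuple[str, str, float]] = []
    if proxy_path is not None:
        pdf = pd.read_csv(proxy_path, sep="\t", dtype=str)
        for col in ("snp_a", "snp_b", "r2"):
            if col not in pdf.columns:
                raise FormatError(f"{proxy_path}: need column {col}")
        proxies = [
            (a, b, float(r2))
            for a, b, r2 in zip(pdf["snp_a"], pdf["snp_b"], pdf["r2"])
        ]
    return FunctionalIndex(
        {k: frozenset(v) for k, v in classes.items()}, proxies
    )


# ---------------------------------------------------------------------------
# Longitudinal phenotypes
# ---------------------------------------------------------------------------

def read_long_phenotypes(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    covariate_columns: Sequence[str] | None = None,
) -> list[LongRecord]:
    """Read long-format repeated measures: one row per (subject, age).

    ``column_map`` names the ``subject_id``, ``age`` and ``phenotype``
    columns; all remaining columns (or ``covariate_columns`` if given) are
    treated as time-invariant covariates and checked constant per subject.
    Rows with an empty age or phenotype cell are rejected (count logged).
    """
    df = pd.read_csv(path)
    cmap = dict(column_map or {})
    for name in ("subject_id", "age", "phenotype"):
        cmap.setdefault(name, name)
        if cmap[name] not in df.columns:
            raise FormatError(f"{path}: missing column {cmap[name]!r}")
    covs = list(
        covariate_columns
        if covariate_columns is not None
        else [c for c in df.columns if c not in cmap.values()]
    )
    age = pd.to_numeric(df[cmap["age"]], errors="coerce")
    phen = pd.to_numeric(df[cmap["phenotype"]], errors="coerce")
    ok = age.notna() & phen.notna()
    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.warning("%s: rejected %d rows with missing age/phenotype", path, n_rejected)
    df, age, phen = df[ok], age[ok], phen[ok]
    for c in covs:
        nuniq = df.groupby(df[cmap["subject_id"]])[c].nunique()
        varying = nuniq[nuniq > 1]
        if len(varying):
            raise InputError(
                f"{path}: covariate {c!r} varies within subject "
                f"{varying.index[0]!r}"
            )
    return [
        LongRecord(
            subject_id=str(df[cmap["subject_id"]].iloc[i]),
            age=float(age.iloc[i]),
            phenotype=float(phen.iloc[i]),
            covariates={c: float(df[c].iloc[i]) for c in covs},
        )
        for i in range(len(df))
    ]


def records_to_frame(records: Sequence[LongRecord]) -> pd.DataFrame:
    covs = sorted(records[0].covariates) if records else []
    data = {
        "subject_id": [r.subject_id for r in records],
        "age": [r.age for r in records],
        "phenotype": [r.phenotype for r in records],
    }
    for c in covs:
        data[c] = [r.covariates[c] for r in records]
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Output tables and the run-metadata sidecar
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, float_format: str = "%.17g") -> None:
    """Write a TSV with header; %.17g keeps reals bit-reproducible on re-read."""
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def write_sidecar(path: str | Path, *, seed=None, parameters=None, provenance=None) -> None:
    """Write the JSON run-metadata sidecar (package version, seed, parameters)."""
    from funprs import __version__

    payload = {
        "package": "funprs",
        "version": __version__,
        "seed": seed,
        "parameters": parameters or {},
        "provenance": provenance or {},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
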