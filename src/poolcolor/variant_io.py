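"""Pooled-VCF input/output, allele-frequency extraction, and site filtering.

A "sample" in the VCFs handled here is a *pool*: a single sequencing library
made from the DNA of many individuals.  Only aggregate allele counts are
observable per pool, so the unit of data is the pair (AD, DP) of per-allele
and total read depths, from which the alternative-allele frequency
AF = ad_alt / (ad_ref + ad_alt) is estimated.

The module also implements the post-calling site filters used throughout the
pipeline (biallelic SNPs only, per-pool depth floor, no missing data, folded
MAF floor) and the decomposition of equal-length block substitutions (MNPs)
into their component SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "PoolDefinition",
    "PoolDepth",
    "VariantRecord",
    "AFMatrix",
    "FilterStats",
    "ManifestError",
    "VcfFormatError",
    "read_pool_manifest",
    "write_pool_manifest",
    "read_pooled_vcf",
    "compute_af",
    "apply_site_filters",
    "decompose_blocksub",
    "build_af_matrix",
]

_DNA = set("ACGT")


class ManifestError(ValueError):
    """Raised for malformed or inconsistent pool manifests."""


class VcfFormatError(ValueError):
    """Raised when a VCF does not carry the fields or samples the pipeline needs."""


@dataclass(frozen=True)
class PoolDefinition:
    """One sequenced pool: identity, phenotype/site labels and sample size.

    ``n_individuals`` is the number of diploid individuals whose DNA was
    pooled; ``ploidy * n_individuals`` is the number of chromosomes sampled
    by the pool (the haploid sample size used e.g. by the pi estimator).
    """

    pool_id: str
    site: str
    color: str
    n_individuals: int
    ploidy: int = 2

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ManifestError(
                f"pool {self.pool_id!r}: n_individuals must be >= 1, "
                f"got {self.n_individuals}"
            )
        if self.ploidy < 1:
            raise ManifestError(f"pool {self.pool_id!r}: ploidy must be >= 1")
        if self.haploid_size < 2:
            raise ManifestError(
                f"pool {self.pool_id!r}: haploid sample size "
                f"(ploidy * n_individuals) must be >= 2"
            )

    @property
    def haploid_size(self) -> int:
        return self.ploidy * self.n_individuals


@dataclass(frozen=True)
class PoolDepth:
    """Read-depth triple for one pool at one locus."""

    ad_ref: int
    ad_alt: int
    dp: int

    @property
    def informative(self) -> int:
        return self.ad_ref + self.ad_alt


@dataclass(frozen=True)
class VariantRecord:
    """One VCF locus with per-pool allele depths, 1-based coordinates."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    per_pool: tuple[PoolDepth, ...]

    def __post_init__(self) -> None:
        if not self.ref:
            raise VcfFormatError(f"{self.chrom}:{self.pos}: empty REF")
        if not self.alts or any(not a for a in self.alts):
            raise VcfFormatError(f"{self.chrom}:{self.pos}: empty ALT")

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1

    @property
    def alt(self) -> str:
        if not self.is_biallelic:
            raise ValueError(f"{self.chrom}:{self.pos} is not biallelic")
        return self.alts[0]

    @property
    def is_snp(self) -> bool:
        return self.is_biallelic and len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_block_substitution(self) -> bool:
        """Equal-length multi-base biallelic substitution (MNP)."""
        return (
            self.is_biallelic
            and len(self.ref) == len(self.alt)
            and len(self.ref) > 1
        )

    @property
    def locus(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def read_pool_manifest(path: str | Path) -> list[PoolDefinition]:
    """Read a TSV pool manifest (pool_id, site, color, n_individuals[, ploidy]).

    Pools are returned in file order.  Duplicate pool ids, duplicate
    (site, color) cells and non-positive sample sizes are rejected.
    """
    try:
        table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    except pd.errors.EmptyDataError as exc:
        raise ManifestError(f"{path}: empty manifest (no header)") from exc
    required = ["pool_id", "site", "color", "n_individuals"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ManifestError(f"{path}: missing manifest columns {missing}")
    pools: list[PoolDefinition] = []
    for row in table.itertuples(index=False):
        try:
            n = int(row.n_individuals)
        except ValueError as exc:
            raise ManifestError(
                f"{path}: non-integer n_individuals {row.n_individuals!r} "
                f"for pool {row.pool_id!r}"
            ) from exc
        ploidy = int(getattr(row, "ploidy", 2) or 2)
        pools.append(
            PoolDefinition(
                pool_id=str(row.pool_id),
                site=str(row.site),
                color=str(row.color),
                n_individuals=n,
                ploidy=ploidy,
            )
        )
    ids = [p.pool_id for p in pools]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ManifestError(f"{path}: duplicate pool_id {dupes}")
    cells = [(p.site, p.color) for p in pools]
    if len(set(cells)) != len(cells):
        raise ManifestError(f"{path}: duplicate (site, color) cell in manifest")
    return pools


def write_pool_manifest(pools: Sequence[PoolDefinition], path: str | Path) -> None:
    pd.DataFrame(
        {
            "pool_id": [p.pool_id for p in pools],
            "site": [p.site for p in pools],
            "color": [p.color for p in pools],
            "n_individuals": [p.n_individuals for p in pools],
            "ploidy": [p.ploidy for p in pools],
        }
    ).to_csv(path, sep="\t", index=False)


def read_pooled_vcf(
    path: str | Path, pools: Sequence[PoolDefinition]
) -> Iterator[VariantRecord]:
    """Stream VariantRecords from a VCF whose samples are the manifest pools.

    Sample columns may appear in any order; per-pool depths are re-ordered to
    manifest order.  The FORMAT must carry AD (per-allele depths, ref first)
    and DP.  A record lacking AD or DP raises ``VcfFormatError`` naming the
    locus; a sample-set mismatch with the manifest is fatal.
    """
    vcf = VCF(str(path))
    try:
        vcf_samples = list(vcf.samples)
        wanted = [p.pool_id for p in pools]
        if sorted(vcf_samples) != sorted(wanted):
            raise ManifestError(
                f"{path}: VCF samples {vcf_samples} do not match manifest "
                f"pools {wanted}"
            )
        order = np.array([vcf_samples.index(pid) for pid in wanted])
        for variant in vcf:
            locus = f"{variant.CHROM}:{variant.POS}"
            ad = variant.format("AD")
            dp = variant.format("DP")
            if ad is None or dp is None:
                raise VcfFormatError(f"{path}: {locus}: missing AD or DP FORMAT field")
            ad = np.asarray(ad)[order]
            dp = np.asarray(dp).reshape(-1)[order]
            # cyvcf2 encodes missing integers as negative sentinels
            ad = np.where(ad < 0, 0, ad)
            dp = np.where(dp < 0, 0, dp)
            per_pool = tuple(
                PoolDepth(int(ad[i, 0]), int(ad[i, 1]) if ad.shape[1] > 1 else 0, int(dp[i]))
                for i in range(len(wanted))
            )
            yield VariantRecord(
                chrom=variant.CHROM,
                pos=variant.POS,
                ref=variant.REF,
                alts=tuple(variant.ALT),
                per_pool=per_pool,
            )
    finally:
        vcf.close()


def compute_af(record: VariantRecord) -> np.ndarray:
    """Alternative-allele frequency per pool: ad_alt / (ad_ref + ad_alt).

    Pools with no informative reads (ad_ref + ad_alt == 0) yield NaN, the
    missing-data signal picked up by the no-missing filter downstream.
    """
    if not record.is_biallelic:
        raise ValueError(
            f"{record.chrom}:{record.pos}: AF is defined for biallelic records only"
        )
    ad_ref = np.array([d.ad_ref for d in record.per_pool], dtype=float)
    ad_alt = np.array([d.ad_alt for d in record.per_pool], dtype=float)
    informative = ad_ref + ad_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(informative > 0, ad_alt / informative, np.nan)
    return af


@dataclass
class FilterStats:
    """Per-rule rejection counts; each removed record is attributed to its
    first failing rule in the order biallelic -> depth -> missing -> MAF."""

    biallelic: int = 0
    depth: int = 0
    missing: int = 0
    maf: int = 0
    kept: int = 0
    n_indels: int = 0  # subset of `biallelic`: unequal-length REF/ALT

    def as_dict(self) -> dict[str, int]:
        return {
            "biallelic": self.biallelic,
            "depth": self.depth,
            "missing": self.missing,
            "maf": self.maf,
        }


def _passes_form(record: VariantRecord) -> bool:
    """Keep single-base SNPs and equal-length block substitutions only."""
    if not record.is_biallelic:
        return False
    ref, alt = record.ref, record.alt
    if set(ref) - _DNA or set(alt) - _DNA:
        return False
    return len(ref) == len(alt)


def apply_site_filters(
    records: Iterable[VariantRecord],
    min_dp: int = 20,
    min_maf: float = 0.01,
    depth_scope: str = "per_pool",
) -> tuple[list[VariantRecord], FilterStats]:
    """Apply the post-calling site filters.

    A record is kept iff it is a biallelic SNP or equal-length block
    substitution, every pool reports DP >= ``min_dp`` (``depth_scope
    "per_pool"``; ``"total"`` instead requires the summed DP across pools to
    reach the floor), no pool has missing AF, and the folded minor allele
    frequency of the unweighted across-pool mean AF is >= ``min_maf``.
    """
    if depth_scope not in ("per_pool", "total"):
        raise ValueError(f"unknown depth_scope {depth_scope!r}")
    kept: list[VariantRecord] = []
    stats = FilterStats()
    for record in records:
        if not _passes_form(record):
            stats.biallelic += 1
            if record.is_biallelic and len(record.ref) != len(record.alts[0]):
                stats.n_indels += 1
            continue
        dp = np.array([d.dp for d in record.per_pool])
        deep_enough = (
            bool((dp >= min_dp).all())
            if depth_scope == "per_pool"
            else int(dp.sum()) >= min_dp
        )
        if not deep_enough:
            stats.depth += 1
            continue
        af = compute_af(record)
        if np.isnan(af).any():
            stats.missing += 1
            continue
        p_bar = float(af.mean())
        if min(p_bar, 1.0 - p_bar) < min_maf:
            stats.maf += 1
            continue
        kept.append(record)
        stats.kept += 1
    return kept, stats


def decompose_blocksub(record: VariantRecord) -> list[VariantRecord]:
    """Split an equal-length block substitution into its component SNPs.

    One single-base record is emitted at ``pos + i`` for every position i
    where REF and ALT disagree, each inheriting the parent's per-pool depths
    verbatim (the depths were counted once for the whole haplotype block and
    are not re-estimated per base).  Plain SNPs pass through unchanged;
    unequal-length records (indels) yield an empty list.
    """
    if not record.is_biallelic:
        raise ValueError(
            f"{record.chrom}:{record.pos}: decompose_blocksub expects a "
            "biallelic record"
        )
    ref, alt = record.ref, record.alts[0]
    if len(ref) != len(alt):
        return []
    if len(ref) == 1:
        return [record]
    return [
        replace(record, pos=record.pos + i, ref=r, alts=(a,))
        for i, (r, a) in enumerate(zip(ref, alt))
        if r != a
    ]


@dataclass
class AFMatrix:
    """Pools x loci matrix of alternative-allele frequencies, no missing cells.

    Rows follow manifest order; columns are (chrom, pos, ref, alt) keys
    sorted by (chrom, pos).
    """

    pools: list[PoolDefinition]
    loci: list[tuple[str, int, str, str]]
    values: np.ndarray  # shape (n_pools, n_loci)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.pools), len(self.loci)):
            raise ValueError(
                f"AFMatrix shape {self.values.shape} does not match "
                f"{len(self.pools)} pools x {len(self.loci)} loci"
            )
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("duplicate locus keys in AFMatrix")
        if self.loci and (np.isnan(self.values).any()):
            raise ValueError("AFMatrix must have no missing cells")
        if self.loci and ((self.values < 0).any() or (self.values > 1).any()):
            raise ValueError("AF values must lie in [0, 1]")

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def to_dataframe(self) -> pd.DataFrame:
        """Loci as rows (chrom, pos, ref, alt index), pools as columns."""
        index = pd.MultiIndex.from_tuples(
            self.loci, names=["chrom", "pos", "ref", "alt"]
        )
        return pd.DataFrame(
            self.values.T, index=index, columns=[p.pool_id for p in self.pools]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(
        cls, path: str | Path, pools: Sequence[PoolDefinition]
    ) -> "AFMatrix":
        table = pd.read_csv(path, sep="\t")
        loci = [
            (str(c), int(p), str(r), str(a))
            for c, p, r, a in zip(table["chrom"], table["pos"], table["ref"], table["alt"])
        ]
        values = table[[p.pool_id for p in pools]].to_numpy(dtype=float).T
        return cls(pools=list(pools), loci=loci, values=values)


def build_af_matrix(
    records: Iterable[VariantRecord], pools: Sequence[PoolDefinition]
) -> AFMatrix:
    """Assemble the AF matrix from already-filtered (complete) SNP records."""
    records = list(records)
    loci = [r.locus for r in records]
    if len(set(loci)) != len(loci):
        seen: set[tuple] = set()
        for key in loci:
            if key in seen:
                raise ValueError(f"duplicate locus {key[0]}:{key[1]}")
            seen.add(key)
    if records:
        n_pools = {len(r.per_pool) for r in records}
        if n_pools != {len(pools)}:
            raise ValueError("record pool count does not match manifest")
    order = sorted(range(len(records)), key=lambda i: (loci[i][0], loci[i][1]))
    values = np.empty((len(pools), len(records)))
    sorted_loci = []
    for col, i in enumerate(order):
        af = compute_af(records[i])
        if np.isnan(af).any():
            raise ValueError(
                f"missing AF at {loci[i][0]}:{loci[i][1]}; records must be "
                "filtered before building the matrix"
            )
        values[:, col] = af
        sorted_loci.append(loci[i])
    return AFMatrix(pools=list(pools), loci=sorted_loci, values=values)
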