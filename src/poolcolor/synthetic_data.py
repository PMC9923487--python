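"""Synthetic pool-seq datasets with planted association structure.

The generator emulates the 12-pool study layout this pipeline was built
around: 4 sites x 3 inner-shell colors, 172 diploid individuals in total
(wild pools of 12-13 individuals, hatchery pools of 20).  Loci fall into
four classes:

    neutral  all pools share the baseline frequency p0
    color    one color's pools are shifted by ``color_effect`` at ALL sites
             (a universal control of color, identical across geography)
    site     one site's pools are shifted by ``site_effect`` for all colors
    both     independent color and site shifts

Observed read counts follow a two-stage noise model that separates pool-seq
from individual sequencing: the pool's realised allele frequency is a
binomial draw over its 2N chromosomes, and reads are then a second binomial
draw at a Poisson-distributed depth.  The extra pool-sampling variance is
what stresses the association model's error assumptions.

Randomness is counter-based: the truth table uses the stream (seed, 0) and
locus i's reads use (seed, 1, i), so draws never depend on locus order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .variant_io import PoolDefinition, PoolDepth, VariantRecord, write_pool_manifest

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "study_pools",
    "simulate_truth",
    "simulate_pool_reads",
    "simulate_records",
    "emit_dataset",
    "make_toy_genome",
]

DEFAULT_SITES = ["Takapoto", "Katiu", "Gambier", "Hatchery"]
DEFAULT_COLORS = ["red", "yellow", "green"]

# Wild pools hold 12-13 individuals, hatchery pools 20; 172 individuals total.
_DEFAULT_POOL_SIZES = {
    "Takapoto": (13, 12, 12),
    "Katiu": (13, 12, 12),
    "Gambier": (13, 13, 12),
    "Hatchery": (20, 20, 20),
}

CLASSES = ("neutral", "color", "site", "both")


def study_pools(
    sites: Sequence[str] = tuple(DEFAULT_SITES),
    colors: Sequence[str] = tuple(DEFAULT_COLORS),
    n_individuals: int | None = None,
) -> list[PoolDefinition]:
    """The default 12-pool manifest (site-major order).

    With ``n_individuals`` set, every pool gets that size; otherwise the
    default layout's 172 individuals are used.
    """
    pools = []
    for site in sites:
        sizes = _DEFAULT_POOL_SIZES.get(site)
        for i, color in enumerate(colors):
            if n_individuals is not None:
                n = n_individuals
            elif sizes is not None and i < len(sizes):
                n = sizes[i]
            else:
                n = 15
            pools.append(
                PoolDefinition(
                    pool_id=f"{site}_{color}", site=site, color=color, n_individuals=n
                )
            )
    return pools


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset; defaults are the study conditions."""

    seed: int
    n_loci: int = 5_000
    fractions: dict[str, float] = field(
        default_factory=lambda: {"neutral": 0.90, "color": 0.04, "site": 0.04, "both": 0.02}
    )
    color_effect: float = 0.4
    site_effect: float = 0.4
    baseline_af: tuple = ("uniform", 0.05, 0.95)
    mean_depth: float = 80.0
    pools: list[PoolDefinition] = field(default_factory=study_pools)
    chrom: str = "chr1"
    chrom_length: int = 10_000_000
    clamp: tuple[float, float] = (0.01, 0.99)

    def __post_init__(self) -> None:
        missing = set(CLASSES) - set(self.fractions)
        if missing:
            raise ValueError(f"fractions missing classes {sorted(missing)}")
        values = np.array([self.fractions[c] for c in CLASSES])
        if (values < 0).any() or abs(values.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must be nonnegative and sum to 1")
        if not (0 < self.color_effect < 1 and 0 < self.site_effect < 1):
            raise ValueError("effects must lie in (0, 1)")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.n_loci > self.chrom_length:
            raise ValueError("more loci than positions on the chromosome")

    @property
    def colors(self) -> list[str]:
        return list(dict.fromkeys(p.color for p in self.pools))

    @property
    def sites(self) -> list[str]:
        return list(dict.fromkeys(p.site for p in self.pools))


@dataclass
class TruthTable:
    """Planted truth for every simulated locus."""

    chrom: str
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    locus_class: np.ndarray
    affected_color: np.ndarray  # "" when not applicable
    affected_site: np.ndarray
    p0: np.ndarray
    true_af: np.ndarray  # n_loci x n_pools
    pools: list[PoolDefinition]

    def to_dataframe(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.positions,
                "ref": self.ref,
                "alt": self.alt,
                "class": self.locus_class,
                "affected_color": self.affected_color,
                "affected_site": self.affected_site,
                "p0": self.p0,
            }
        )
        for j, pool in enumerate(self.pools):
            frame[f"true_af:{pool.pool_id}"] = self.true_af[:, j]
        return frame

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


_BASES = np.array(list("ACGT"))


def simulate_truth(config: SimulationConfig) -> TruthTable:
    """Draw locus positions, classes, baseline and shifted pool frequencies."""
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_loci
    positions = np.sort(rng.choice(config.chrom_length, size=n, replace=False) + 1)
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    probs = [config.fractions[c] for c in CLASSES]
    classes = rng.choice(np.array(CLASSES, dtype=object), size=n, p=probs)
    colors, sites = config.colors, config.sites
    affected_color = np.where(
        np.isin(classes, ["color", "both"]),
        rng.choice(np.array(colors, dtype=object), size=n),
        "",
    )
    affected_site = np.where(
        np.isin(classes, ["site", "both"]),
        rng.choice(np.array(sites, dtype=object), size=n),
        "",
    )
    kind = config.baseline_af[0]
    if kind == "uniform":
        p0 = rng.uniform(config.baseline_af[1], config.baseline_af[2], size=n)
    elif kind == "beta":
        p0 = rng.beta(config.baseline_af[1], config.baseline_af[2], size=n)
    else:
        raise ValueError(f"unknown baseline_af distribution {kind!r}")
    true_af = np.tile(p0[:, None], (1, len(config.pools)))
    pool_colors = np.array([p.color for p in config.pools], dtype=object)
    pool_sites = np.array([p.site for p in config.pools], dtype=object)
    color_mask = affected_color[:, None] == pool_colors[None, :]
    site_mask = affected_site[:, None] == pool_sites[None, :]
    true_af = true_af + config.color_effect * color_mask + config.site_effect * site_mask
    true_af = np.clip(true_af, config.clamp[0], config.clamp[1])
    return TruthTable(
        chrom=config.chrom,
        positions=positions,
        ref=_BASES[ref_idx],
        alt=_BASES[alt_idx],
        locus_class=classes.astype(object),
        affected_color=affected_color.astype(object),
        affected_site=affected_site.astype(object),
        p0=p0,
        true_af=true_af,
        pools=list(config.pools),
    )


def simulate_pool_reads(
    true_af: float,
    pool: PoolDefinition,
    mean_depth: float,
    rng: np.random.Generator,
) -> tuple[int, int, int]:
    """Two-stage read sampling for one pool at one locus.

    Allele count c ~ Binomial(2N, true_af) gives the realised pool frequency
    q = c / 2N; depth dp ~ Poisson(mean_depth) floored at 1; alt reads
    ~ Binomial(dp, q).  Returns (ad_ref, ad_alt, dp).
    """
    if not 0.0 <= true_af <= 1.0:
        raise ValueError("true_af must lie in [0, 1]")
    n_chr = pool.haploid_size
    c = rng.binomial(n_chr, true_af)
    q = c / n_chr
    dp = max(1, int(rng.poisson(mean_depth)))
    ad_alt = int(rng.binomial(dp, q))
    return dp - ad_alt, ad_alt, dp


def simulate_records(
    config: SimulationConfig, truth: TruthTable | None = None
) -> tuple[list[VariantRecord], TruthTable]:
    """Generate in-memory VariantRecords (and the truth) for a config."""
    if truth is None:
        truth = simulate_truth(config)
    records = []
    for i in range(len(truth.positions)):
        rng = np.random.default_rng([config.seed, 1, i])
        per_pool = tuple(
            PoolDepth(*simulate_pool_reads(truth.true_af[i, j], pool, config.mean_depth, rng))
            for j, pool in enumerate(config.pools)
        )
        records.append(
            VariantRecord(
                chrom=truth.chrom,
                pos=int(truth.positions[i]),
                ref=str(truth.ref[i]),
                alts=(str(truth.alt[i]),),
                per_pool=per_pool,
            )
        )
    return records, truth


def _genotype(ad_ref: int, ad_alt: int) -> str:
    """Hard call from the observed frequency: <0.1 hom-ref, >0.9 hom-alt."""
    informative = ad_ref + ad_alt
    if informative == 0:
        return "./."
    af = ad_alt / informative
    if af < 0.1:
        return "0/0"
    if af > 0.9:
        return "1/1"
    return "0/1"


def write_vcf(
    records: Sequence[VariantRecord],
    pools: Sequence[PoolDefinition],
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write records as a plain-text VCF 4.2 with GT:AD:DP pool columns."""
    lines = [
        "##fileformat=VCFv4.2",
        "##source=poolcolor-synthetic",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Hard-called genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Per-allele read depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
    ]
    if contig_lengths:
        for name, length in contig_lengths.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header += [p.pool_id for p in pools]
    lines.append("\t".join(header))
    for rec in records:
        samples = [
            f"{_genotype(d.ad_ref, d.ad_alt)}:{d.ad_ref},{d.ad_alt}:{d.dp}"
            for d in rec.per_pool
        ]
        lines.append(
            "\t".join(
                [rec.chrom, str(rec.pos), ".", rec.ref, ",".join(rec.alts), ".", ".", ".", "GT:AD:DP"]
                + samples
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def emit_dataset(
    truth: TruthTable, config: SimulationConfig, out_prefix: str | Path
) -> dict[str, Path]:
    """Write the VCF, truth sidecar and manifest for a simulated dataset.

    Deterministic: the same config and seed produce byte-identical files.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    records, truth = simulate_records(config, truth)
    paths = {
        "vcf": out_prefix.with_suffix(".vcf"),
        "truth": Path(str(out_prefix) + ".truth.tsv"),
        "manifest": Path(str(out_prefix) + ".manifest.tsv"),
    }
    write_vcf(
        records, config.pools, paths["vcf"], {config.chrom: config.chrom_length}
    )
    truth.to_tsv(paths["truth"])
    write_pool_manifest(config.pools, paths["manifest"])
    return paths


# -- toy genome for the annotation module -----------------------------------

_STOP_FREE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def make_toy_genome(
    seed: int = 0,
    chrom: str = "chrT",
    length: int = 12_000,
    strand: str = "+",
    out_prefix: str | Path | None = None,
):
    """A single-gene genome with known coordinates for annotation tests.

    The gene spans [4001, 6998] with two fully coding exons [4001, 5000]
    and [6001, 6998] (CDS length 1998, a multiple of 3).  The spliced CDS
    starts with ATG, is free of internal stops, and ends with TAA, so every
    coding consequence class is reachable by a single substitution.
    Optionally writes ``<prefix>.fa`` and ``<prefix>.gff3``.

    Returns (reference dict, [GeneModel]).
    """
    from .effect_annotation import GeneModel

    rng = np.random.default_rng(seed)
    seq = rng.choice(_BASES, size=length)
    exons = ((4001, 5000), (6001, 6998))
    cds_len = sum(e - s + 1 for s, e in exons)
    n_codons = cds_len // 3
    codons = ["ATG"] + list(rng.choice(_STOP_FREE_CODONS, size=n_codons - 2)) + ["TAA"]
    spliced = "".join(codons)
    if strand == "-":
        from Bio.Seq import Seq

        spliced = str(Seq(spliced).reverse_complement())
    cursor = 0
    for s, e in exons:
        span = e - s + 1
        seq[s - 1 : e] = list(spliced[cursor : cursor + span])
        cursor += span
    reference = {chrom: "".join(seq)}
    gene = GeneModel(
        gene_id="toy_gene",
        chrom=chrom,
        strand=strand,
        tx_start=4001,
        tx_end=6998,
        exons=exons,
        cds=exons,
    )
    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        fasta = out_prefix.with_suffix(".fa")
        fasta.write_text(f">{chrom}\n{reference[chrom]}\n")
        gff = out_prefix.with_suffix(".gff3")
        rows = [
            "##gff-version 3",
            f"{chrom}\ttoy\tgene\t{gene.tx_start}\t{gene.tx_end}\t.\t{strand}\t.\tID=toy_gene",
        ]
        for k, (s, e) in enumerate(exons):
            rows.append(
                f"{chrom}\ttoy\texon\t{s}\t{e}\t.\t{strand}\t.\tID=toy_exon{k};Parent=toy_gene"
            )
            rows.append(
                f"{chrom}\ttoy\tCDS\t{s}\t{e}\t.\t{strand}\t0\tID=toy_cds{k};Parent=toy_gene"
            )
        gff.write_text("\n".join(rows) + "\n")
    return reference, [gene]
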