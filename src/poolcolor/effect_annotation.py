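"""Variant-effect classification against gene models, SnpEff-style.

A deliberately small effect vocabulary is used: the four impact categories
and the effect terms that matter for a color-association follow-up —
up/downstream (2 kb flank on each side of the gene, strand-aware), intron,
intergenic, and the coding consequences derived by splicing and translating
the CDS (synonymous, missense, stop gained/lost, start lost).

Impact mapping is fixed:
    HIGH      stop_gained, stop_lost, start_lost
    MODERATE  missense_variant
    LOW       synonymous_variant
    MODIFIER  upstream/downstream/intron/intergenic

Coordinates are 1-based inclusive throughout (VCF/GFF convention); BED12
input is converted on read.  Positions inside a gene but outside every CDS
interval (introns and any non-coding exon parts) are reported as
intron_variant — UTR classes are outside this vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import gffutils
import pandas as pd
from Bio.Seq import Seq

from .variant_io import VariantRecord

__all__ = [
    "GeneModel",
    "EffectAnnotation",
    "AAChange",
    "IMPACT_OF_EFFECT",
    "IMPACT_RANK",
    "read_gff3",
    "read_bed12",
    "translate_cds",
    "aa_change",
    "annotate_snp",
    "most_severe",
    "ann_string",
]

IMPACT_OF_EFFECT: dict[str, str] = {
    "stop_gained": "HIGH",
    "stop_lost": "HIGH",
    "start_lost": "HIGH",
    "missense_variant": "MODERATE",
    "synonymous_variant": "LOW",
    "upstream_gene_variant": "MODIFIER",
    "downstream_gene_variant": "MODIFIER",
    "intron_variant": "MODIFIER",
    "intergenic_variant": "MODIFIER",
}

IMPACT_RANK = {"HIGH": 3, "MODERATE": 2, "LOW": 1, "MODIFIER": 0}

_CODON_OK = set("ACGT")


class GeneModelError(ValueError):
    """Raised for inconsistent gene models."""


@dataclass(frozen=True)
class GeneModel:
    """One gene: transcript span with exon and CDS intervals, 1-based inclusive."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GeneModelError(f"{self.gene_id}: strand must be + or -")
        if self.tx_start > self.tx_end:
            raise GeneModelError(f"{self.gene_id}: tx_start > tx_end")
        for name, ivals in (("exon", self.exons), ("CDS", self.cds)):
            prev_end = 0
            for s, e in ivals:
                if s > e:
                    raise GeneModelError(f"{self.gene_id}: inverted {name} [{s},{e}]")
                if s <= prev_end:
                    raise GeneModelError(f"{self.gene_id}: unsorted/overlapping {name}s")
                prev_end = e
        for s, e in self.exons:
            if s < self.tx_start or e > self.tx_end:
                raise GeneModelError(f"{self.gene_id}: exon outside transcript span")
        for s, e in self.cds:
            if not any(s >= xs and e <= xe for xs, xe in self.exons):
                raise GeneModelError(f"{self.gene_id}: CDS not contained in an exon")
        if self.cds and self.cds_length % 3 != 0:
            raise GeneModelError(
                f"{self.gene_id}: CDS length {self.cds_length} not a multiple of 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def contains(self, pos: int) -> bool:
        return self.tx_start <= pos <= self.tx_end

    def in_cds(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.cds)

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)


@dataclass(frozen=True)
class AAChange:
    """Amino-acid substitution: 1-based position within the protein."""

    ref_aa: str
    aa_pos: int
    alt_aa: str

    def __str__(self) -> str:
        return f"{self.ref_aa}{self.aa_pos}{self.alt_aa}"


@dataclass(frozen=True)
class EffectAnnotation:
    effect: str
    impact: str
    gene_id: str | None = None
    aa_change: AAChange | None = None


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Load gene models (gene/exon/CDS features) from a GFF3 file."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for gene in db.features_of_type("gene"):
        exons = sorted(
            (f.start, f.end) for f in db.children(gene, featuretype="exon")
        )
        cds = sorted((f.start, f.end) for f in db.children(gene, featuretype="CDS"))
        if not exons:
            exons = [(gene.start, gene.end)]
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                tx_start=gene.start,
                tx_end=gene.end,
                exons=tuple(exons),
                cds=tuple(cds),
            )
        )
    return models


def read_bed12(path: str | Path) -> list[GeneModel]:
    """Load gene models from BED12 (0-based half-open -> 1-based inclusive).

    Blocks become exons; the thickStart/thickEnd span intersected with the
    blocks becomes the CDS.
    """
    names = [
        "chrom", "start", "end", "name", "score", "strand",
        "thick_start", "thick_end", "rgb", "block_count",
        "block_sizes", "block_starts",
    ]
    table = pd.read_csv(path, sep="\t", header=None, names=names, comment="#")
    models = []
    for row in table.itertuples(index=False):
        sizes = [int(x) for x in str(row.block_sizes).rstrip(",").split(",")]
        starts = [int(x) for x in str(row.block_starts).rstrip(",").split(",")]
        exons = tuple(
            (int(row.start) + bs + 1, int(row.start) + bs + sz)
            for bs, sz in zip(starts, sizes)
        )
        thick_s, thick_e = int(row.thick_start) + 1, int(row.thick_end)
        cds = tuple(
            (max(s, thick_s), min(e, thick_e))
            for s, e in exons
            if max(s, thick_s) <= min(e, thick_e)
        ) if thick_e >= thick_s else ()
        models.append(
            GeneModel(
                gene_id=str(row.name),
                chrom=str(row.chrom),
                strand=str(row.strand),
                tx_start=int(row.start) + 1,
                tx_end=int(row.end),
                exons=exons,
                cds=cds,
            )
        )
    return models


def translate_cds(seq: str) -> str:
    """Translate a spliced CDS with the standard genetic code, stops as '*'.

    Translation runs the full length (internal stops are retained so that
    stop-gain substitutions remain visible).
    """
    seq = seq.upper()
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} is not a multiple of 3")
    if set(seq) - _CODON_OK:
        raise ValueError(f"non-ACGT character in CDS: {sorted(set(seq) - _CODON_OK)}")
    return str(Seq(seq).translate())


def _fetch(reference, chrom: str, start: int, end: int) -> str:
    """1-based inclusive slice from a dict of strings or a pyfaidx Fasta."""
    return str(reference[chrom][start - 1 : end]).upper()


def spliced_cds(model: GeneModel, reference) -> str:
    """Strand-oriented spliced CDS sequence of a gene model."""
    parts = [_fetch(reference, model.chrom, s, e) for s, e in model.cds]
    seq = "".join(parts)
    if model.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def _cds_offset(model: GeneModel, pos: int) -> int:
    """0-based offset of a genomic position within the spliced, oriented CDS."""
    offset = 0
    for s, e in model.cds:
        if s <= pos <= e:
            offset += pos - s
            break
        offset += e - s + 1
    else:
        raise ValueError(f"{model.gene_id}: position {pos} is not in the CDS")
    if model.strand == "-":
        offset = model.cds_length - 1 - offset
    return offset


def aa_change(model: GeneModel, snp: VariantRecord, reference) -> AAChange | None:
    """Amino-acid consequence of a single-base substitution inside the CDS.

    Returns ``None`` for positions outside the CDS.  The reference base at
    the SNP position must match snp.ref; mismatches raise, flagging an
    inconsistency between VCF and reference sequence.
    """
    if len(snp.ref) != 1 or len(snp.alt) != 1:
        raise ValueError("aa_change expects a single-base substitution")
    if not model.in_cds(snp.pos):
        return None
    genome_base = _fetch(reference, snp.chrom, snp.pos, snp.pos)
    if genome_base != snp.ref.upper():
        raise ValueError(
            f"{snp.chrom}:{snp.pos}: reference sequence has {genome_base}, "
            f"VCF REF is {snp.ref}"
        )
    cds_seq = spliced_cds(model, reference)
    offset = _cds_offset(model, snp.pos)
    alt_base = snp.alt.upper()
    if model.strand == "-":
        alt_base = str(Seq(alt_base).reverse_complement())
    codon_i, within = divmod(offset, 3)
    codon = cds_seq[codon_i * 3 : codon_i * 3 + 3]
    alt_codon = codon[:within] + alt_base + codon[within + 1 :]
    return AAChange(
        ref_aa=translate_cds(codon),
        aa_pos=codon_i + 1,
        alt_aa=translate_cds(alt_codon),
    )


def _coding_effect(change: AAChange) -> str:
    if change.ref_aa == change.alt_aa:
        return "synonymous_variant"
    if change.alt_aa == "*":
        return "stop_gained"
    if change.ref_aa == "*":
        return "stop_lost"
    if change.aa_pos == 1 and change.ref_aa == "M":
        return "start_lost"
    return "missense_variant"


def annotate_snp(
    snp: VariantRecord,
    models: Sequence[GeneModel] | Mapping[str, Sequence[GeneModel]],
    reference=None,
    flank: int = 2000,
) -> list[EffectAnnotation]:
    """Annotate one SNP against all overlapping or flanking gene models.

    One annotation is emitted per gene whose body or ``flank``-bp
    strand-aware up/downstream window contains the SNP; when none does, a
    single intergenic annotation is returned.  CDS positions need a
    ``reference`` (dict of sequences or pyfaidx Fasta) to derive the
    amino-acid change.
    """
    if len(snp.ref) != 1 or len(snp.alts[0]) != 1 or not snp.is_biallelic:
        raise ValueError("annotate_snp expects a biallelic single-base SNP")
    if isinstance(models, Mapping):
        gene_list = list(models.get(snp.chrom, ()))
    else:
        gene_list = [g for g in models if g.chrom == snp.chrom]
    annotations: list[EffectAnnotation] = []
    for gene in gene_list:
        effect: str | None = None
        change: AAChange | None = None
        if gene.contains(snp.pos):
            if gene.in_cds(snp.pos):
                if reference is None:
                    raise ValueError(
                        f"{snp.chrom}:{snp.pos} lies in the CDS of "
                        f"{gene.gene_id}; a reference sequence is required"
                    )
                change = aa_change(gene, snp, reference)
                effect = _coding_effect(change)
            else:
                effect = "intron_variant"
        else:
            before = gene.tx_start - flank <= snp.pos < gene.tx_start
            after = gene.tx_end < snp.pos <= gene.tx_end + flank
            if before:
                effect = "upstream_gene_variant" if gene.strand == "+" else "downstream_gene_variant"
            elif after:
                effect = "downstream_gene_variant" if gene.strand == "+" else "upstream_gene_variant"
        if effect is not None:
            annotations.append(
                EffectAnnotation(
                    effect=effect,
                    impact=IMPACT_OF_EFFECT[effect],
                    gene_id=gene.gene_id,
                    aa_change=change,
                )
            )
    if not annotations:
        annotations.append(EffectAnnotation(effect="intergenic_variant", impact="MODIFIER"))
    return annotations


def most_severe(annotations: Sequence[EffectAnnotation]) -> EffectAnnotation:
    """Reduce to the highest-impact annotation (HIGH > MODERATE > LOW > MODIFIER)."""
    if not annotations:
        raise ValueError("no annotations to reduce")
    return max(annotations, key=lambda a: IMPACT_RANK[a.impact])


def ann_string(annotations: Sequence[EffectAnnotation]) -> str:
    """Pipe-delimited ANN-like string: effect|impact|gene|aa, comma-joined."""
    return ",".join(
        "|".join(
            [a.effect, a.impact, a.gene_id or "", str(a.aa_change) if a.aa_change else ""]
        )
        for a in annotations
    )
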