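import numpy as np
import pytest

from poolcolor.variant_io import PoolDefinition, PoolDepth, VariantRecord


@pytest.fixture
def pools12():
    """The 4-site x 3-color layout with uniform pool sizes."""
    sites = ["Takapoto", "Katiu", "Gambier", "Hatchery"]
    colors = ["red", "yellow", "green"]
    return [
        PoolDefinition(f"{s}_{c}", site=s, color=c, n_individuals=15)
        for s in sites
        for c in colors
    ]


@pytest.fixture
def pools2():
    return [
        PoolDefinition("poolA", site="S1", color="red", n_individuals=10),
        PoolDefinition("poolB", site="S1", color="green", n_individuals=10),
    ]


def make_record(chrom="chr1", pos=100, ref="A", alts=("G",), depths=((10, 10, 20),)):
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alts=tuple(alts),
        per_pool=tuple(PoolDepth(*d) for d in depths),
    )


@pytest.fixture
def record_factory():
    return make_record


def write_vcf_text(path, samples, rows):
    """Minimal hand-rolled VCF writer for fixtures (independent of the package)."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="ad">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for chrom, pos, ref, alt, calls in rows:
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\tGT:AD:DP\t" + "\t".join(calls)
        )
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def vcf_writer():
    return write_vcf_text


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
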