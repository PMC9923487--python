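"""Reference figures from the 12-pool pearl oyster sequencing experiment.

These are the published per-pool sequencing yields and genome-scale variant
counts of the dataset whose design (4 sites x 3 inner-shell colors, 172
individuals) the synthetic generator emulates.  They are inputs for
consistency checks — the raw reads themselves (terabyte scale) are not
needed by this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_sequencing_summary", "REPORTED_COUNTS"]

#: Published genome-scale counts for the reference dataset.
REPORTED_COUNTS: dict[str, int] = {
    # biallelic SNPs surviving the depth/MAF/missing filters
    "biallelic_snps": 22_169_780,
    # additional SNPs recovered by decomposing biallelic block substitutions
    "blocksub_recovered_snps": 1_848,
    # color-specific SNPs per phenotype
    "red_specific": 3_622,
    "yellow_specific": 3_564,
    "green_specific": 3_240,
}


def load_sequencing_summary() -> pd.DataFrame:
    """Per-pool sequencing yields: raw reads, trimming and mapping figures.

    One row per pool (color x site); counts are read pairs and percentages
    are relative to the raw yield.
    """
    with resources.files("poolcolor.resources").joinpath(
        "pool_sequencing_summary.tsv"
    ).open() as handle:
        return pd.read_csv(handle, sep="\t")
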