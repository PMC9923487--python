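"""Descriptive statistics over pool allele frequencies.

Windowed nucleotide diversity per pool, PCA of the pools-by-loci AF matrix,
30-bin AF histograms, and rank-based group comparisons (Kruskal-Wallis,
pairwise Wilcoxon rank-sum with Bonferroni adjustment and a compact letter
display).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variant_io import AFMatrix, PoolDefinition

__all__ = [
    "PiWindow",
    "PCAResult",
    "WilcoxonResult",
    "windowed_pi",
    "pca_af",
    "kruskal_wallis",
    "pairwise_wilcoxon",
    "af_histogram",
    "compact_letter_display",
]


@dataclass(frozen=True)
class PiWindow:
    """Nucleotide diversity of one pool in one genomic window (1-based, inclusive)."""

    pool_id: str
    chrom: str
    win_start: int
    win_end: int
    n_variant_sites: int
    pi: float


def windowed_pi(
    positions: Sequence[int],
    af: Sequence[float],
    pool: PoolDefinition,
    chrom: str = "chr1",
    window_bp: int = 10_000,
    chrom_length: int | None = None,
    denominator: str = "bp",
) -> list[PiWindow]:
    """Windowed nucleotide diversity from pool allele frequencies.

    Each variant site contributes the unbiased per-site heterozygosity
    ``(n_chr / (n_chr - 1)) * 2 p (1 - p)`` where ``n_chr`` is the pool's
    haploid sample size (ploidy x individuals); monomorphic sites (p = 0 or
    1) contribute nothing.  Windows tile the chromosome without overlap.
    With ``denominator="bp"`` (default) the per-window sum is divided by the
    window span in bases; ``"sites"`` divides by the number of variant sites
    in the window instead.
    """
    if pool.haploid_size < 2:
        raise ValueError(f"pool {pool.pool_id}: need haploid sample size >= 2")
    if denominator not in ("bp", "sites"):
        raise ValueError(f"unknown denominator {denominator!r}")
    positions = np.asarray(positions, dtype=int)
    af = np.asarray(af, dtype=float)
    if positions.shape != af.shape:
        raise ValueError("positions and AF must have equal length")
    if len(positions) > 1 and (np.diff(positions) < 0).any():
        raise ValueError("positions must be sorted")
    n_chr = pool.haploid_size
    correction = n_chr / (n_chr - 1)
    per_site = correction * 2.0 * af * (1.0 - af)
    end = chrom_length if chrom_length is not None else (
        int(positions.max()) if len(positions) else window_bp
    )
    windows = []
    for start in range(1, end + 1, window_bp):
        stop = min(start + window_bp - 1, end) if chrom_length is not None else (
            start + window_bp - 1
        )
        in_win = (positions >= start) & (positions <= stop)
        # sites with p in {0,1} carry no diversity and do not count as variant
        variant = in_win & (af > 0.0) & (af < 1.0)
        total = float(per_site[in_win].sum())
        n_var = int(variant.sum())
        if denominator == "bp":
            pi = total / window_bp
        else:
            pi = total / n_var if n_var else 0.0
        windows.append(
            PiWindow(
                pool_id=pool.pool_id,
                chrom=chrom,
                win_start=start,
                win_end=stop,
                n_variant_sites=n_var,
                pi=pi,
            )
        )
        if start + window_bp - 1 >= end:
            break
    return windows


def pi_table(windows: Sequence[PiWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pool_id": [w.pool_id for w in windows],
            "chrom": [w.chrom for w in windows],
            "bin_start": [w.win_start for w in windows],
            "bin_end": [w.win_end for w in windows],
            "n_variants": [w.n_variant_sites for w in windows],
            "pi": [w.pi for w in windows],
        }
    )


@dataclass
class PCAResult:
    """Pool coordinates on the principal axes of the centered AF matrix."""

    coordinates: np.ndarray  # pools x components
    explained_variance_fraction: np.ndarray
    components: np.ndarray  # components x loci, orthonormal rows
    pool_ids: list[str]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.coordinates,
            index=self.pool_ids,
            columns=[f"PC{i + 1}" for i in range(self.coordinates.shape[1])],
        )


def pca_af(matrix: AFMatrix | np.ndarray, n_components: int = 2,
           pool_ids: Sequence[str] | None = None) -> PCAResult:
    """PCA of the pools-by-loci AF matrix via SVD of the column-centered data.

    The sign of each component is fixed deterministically: the loading with
    the largest magnitude is made positive.  ``n_components`` is clipped to
    ``min(n_pools - 1, n_loci)``.
    """
    if isinstance(matrix, AFMatrix):
        ids = [p.pool_id for p in matrix.pools]
        X = matrix.values
    else:
        X = np.asarray(matrix, dtype=float)
        ids = list(pool_ids) if pool_ids is not None else [
            f"pool{i + 1}" for i in range(X.shape[0])
        ]
    n_pools, n_loci = X.shape
    if n_pools < 2 or n_loci < 1:
        raise ValueError("PCA needs >= 2 pools and >= 1 locus")
    max_comp = min(n_pools - 1, n_loci)
    n_components = min(n_components, max_comp)
    centered = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    U, s, Vt = U[:, :max_comp], s[:max_comp], Vt[:max_comp]
    # deterministic orientation: largest-|loading| entry of each axis positive
    for k in range(max_comp):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    var = s**2
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    return PCAResult(
        coordinates=(U * s)[:, :n_components],
        explained_variance_fraction=frac[:n_components],
        components=Vt[:n_components],
        pool_ids=ids,
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Rank-based k-sample test (tie-corrected H, chi-squared p on k-1 df).

    Degenerate input where every value is identical returns (0, 1) instead
    of the undefined tie correction.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("groups must be nonempty")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def _rank_sum_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by full enumeration of rank assignments."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    nx = len(x)
    observed = ranks[:nx].sum()
    sums = np.array(
        [sum(c) for c in itertools.combinations(ranks, nx)]
    )
    mean = ranks.sum() * nx / len(pooled)
    p = np.mean(np.abs(sums - mean) >= np.abs(observed - mean) - 1e-12)
    return float(min(1.0, p))


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact by enumeration when the combined sample size is at most 20 (ties
    included — enumeration handles them correctly); otherwise the normal
    approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    if len(x) + len(y) <= 20:
        return _rank_sum_exact_p(x, y)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.pvalue)


@dataclass
class WilcoxonResult:
    labels: list[str]
    p_raw: pd.DataFrame
    p_adj: pd.DataFrame
    letters: dict[str, str]


def pairwise_wilcoxon(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    adjust: str = "bonferroni",
    alpha: float = 0.05,
) -> WilcoxonResult:
    """All-pairs rank-sum tests with Bonferroni adjustment and letters.

    Groups that are *not* significantly different (at ``alpha`` on the
    adjusted p) share at least one letter in the compact letter display.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]
    labels = list(labels)
    k = len(groups)
    m = k * (k - 1) // 2
    p_raw = pd.DataFrame(np.ones((k, k)), index=labels, columns=labels)
    p_adj = p_raw.copy()
    for i, j in itertools.combinations(range(k), 2):
        p = rank_sum_test(groups[i], groups[j])
        padj = min(1.0, m * p) if adjust == "bonferroni" else p
        p_raw.iloc[i, j] = p_raw.iloc[j, i] = p
        p_adj.iloc[i, j] = p_adj.iloc[j, i] = padj
    different = {
        (i, j)
        for i, j in itertools.combinations(range(k), 2)
        if p_adj.iloc[i, j] < alpha
    }
    letters = compact_letter_display(k, different)
    return WilcoxonResult(
        labels=labels,
        p_raw=p_raw,
        p_adj=p_adj,
        letters={lab: letters[i] for i, lab in enumerate(labels)},
    )


def compact_letter_display(
    n_groups: int, different: set[tuple[int, int]]
) -> list[str]:
    """Greedy insert-absorb letter assignment.

    Each letter is a set of mutually non-different groups; a significant
    pair found sharing a letter splits that letter in two; sets subsumed by
    another are absorbed.  Ties are broken by group order.
    """
    sets: list[set[int]] = [set(range(n_groups))]
    for i, j in sorted(different):
        for current in list(sets):
            if i in current and j in current:
                sets.remove(current)
                without_i = current - {i}
                without_j = current - {j}
                for candidate in (without_i, without_j):
                    if candidate and not any(
                        candidate <= other for other in sets
                    ):
                        sets.append(candidate)
        # absorb: drop sets contained in another
        sets = [
            s
            for idx, s in enumerate(sets)
            if not any(s < t or (s == t and idx2 < idx)
                       for idx2, t in enumerate(sets) if idx2 != idx)
        ]
    sets.sort(key=lambda s: min(s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = ["" for _ in range(n_groups)]
    for letter, s in zip(alphabet, sets):
        for g in sorted(s):
            out[g] += letter
    return out


def af_histogram(
    values: Sequence[float], bins: int = 30, value_range: tuple[float, float] = (0.0, 1.0)
) -> np.ndarray:
    """Equal-width histogram counts on [0, 1]; the last bin is right-closed.

    Raises for values outside the range so silent truncation cannot skew
    the distribution plots.
    """
    values = np.asarray(values, dtype=float)
    lo, hi = value_range
    if len(values) and ((values < lo).any() or (values > hi).any()):
        raise ValueError(f"values outside [{lo}, {hi}]")
    counts, _ = np.histogram(values, bins=bins, range=value_range)
    return counts
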