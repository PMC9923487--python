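"""Per-SNP two-factor linear model and simultaneous pairwise contrasts.

For each locus the pool allele frequencies are modelled as

    AF ~ Color + Site

by ordinary least squares on the treatment-coded design (a Gaussian
identity-link GLM).  All pairwise differences between color levels (K1) and
between site levels (K2) are then tested simultaneously: the stacked
contrast matrix K = rbind(K1, K2) is applied to the fitted coefficients,
each row yielding an estimate, a standard error from the coefficient
covariance, a Student-t statistic on the residual degrees of freedom, and a
Bonferroni-adjusted p-value over the stacked family.

A locus is *geography-associated* when any site pair is significant;
*color-associated* when at least one color pair is significant and no site
pair is (the exclusion isolates a universal control of color, identical
across sites); and *specific* to one color when every pairwise comparison
involving that color is significant.

With 12 pools the fit leaves 6 residual degrees of freedom, so Student-t
p-values below ~1e-5 occur only when the residual variance is (near) zero,
i.e. for loci approaching fixed differences between phenotype groups.  Very
stringent thresholds such as the 1e-9 default therefore select essentially
degenerate, fixed-difference loci; see docs/methods.md.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variant_io import AFMatrix, PoolDefinition

# AF values live on [0, 1]; differences below these floors are floating-point
# residue of exactly-reproduced inputs, not signal.
_EST_ATOL = 1e-10
_VAR_ATOL = 1e-20

__all__ = [
    "DesignInfo",
    "ModelFit",
    "ContrastSet",
    "ContrastResult",
    "SNPClassification",
    "encode_design",
    "fit_af_glm",
    "pairwise_contrasts",
    "simultaneous_test",
    "classify_snp",
    "genome_scan",
]


def levels_from_pools(
    pools: Sequence[PoolDefinition],
) -> tuple[list[str], list[str]]:
    """Color and site levels in order of first appearance in the manifest."""
    colors = list(dict.fromkeys(p.color for p in pools))
    sites = list(dict.fromkeys(p.site for p in pools))
    return colors, sites


@dataclass
class DesignInfo:
    """Treatment-coded (reference-cell) design for AF ~ Color + Site.

    Columns: intercept, then one dummy per non-reference color in level
    order, then one dummy per non-reference site.  The first level of each
    factor is the reference.
    """

    color_levels: list[str]
    site_levels: list[str]
    matrix: np.ndarray
    column_names: list[str]
    rank_warning: bool = False

    @property
    def n_pools(self) -> int:
        return self.matrix.shape[0]

    @property
    def reference_color(self) -> str:
        return self.color_levels[0]

    @property
    def reference_site(self) -> str:
        return self.site_levels[0]


def encode_design(
    pools: Sequence[PoolDefinition],
    color_levels: Sequence[str] | None = None,
    site_levels: Sequence[str] | None = None,
) -> DesignInfo:
    """Build the treatment-coded design matrix for the pools.

    Level lists default to manifest order of first appearance.  A factor
    with a single level contributes no column.  A dummy column that is all
    zero (an empty factor cell making the design rank-deficient) sets
    ``rank_warning`` rather than failing, so callers can decide.
    """
    default_colors, default_sites = levels_from_pools(pools)
    color_levels = list(color_levels) if color_levels is not None else default_colors
    site_levels = list(site_levels) if site_levels is not None else default_sites
    for p in pools:
        if p.color not in color_levels:
            raise ValueError(f"pool {p.pool_id!r}: color {p.color!r} not in levels")
        if p.site not in site_levels:
            raise ValueError(f"pool {p.pool_id!r}: site {p.site!r} not in levels")
    n = len(pools)
    columns = [np.ones(n)]
    names = ["(Intercept)"]
    for level in color_levels[1:]:
        columns.append(np.array([1.0 if p.color == level else 0.0 for p in pools]))
        names.append(f"color[{level}]")
    for level in site_levels[1:]:
        columns.append(np.array([1.0 if p.site == level else 0.0 for p in pools]))
        names.append(f"site[{level}]")
    matrix = np.column_stack(columns)
    rank = np.linalg.matrix_rank(matrix)
    return DesignInfo(
        color_levels=color_levels,
        site_levels=site_levels,
        matrix=matrix,
        column_names=names,
        rank_warning=rank < matrix.shape[1],
    )


@dataclass
class ModelFit:
    """OLS fit of one locus: coefficients and their covariance."""

    beta: np.ndarray
    sigma2: float
    df_resid: int
    cov_beta: np.ndarray
    xtx_inv: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    rank_warning: bool = False


def fit_af_glm(af: np.ndarray, design: DesignInfo) -> ModelFit:
    """Ordinary least squares of the AF vector on the design.

    beta = (X'X)^-1 X'y, sigma2 = RSS / df_resid, cov = sigma2 (X'X)^-1.
    """
    y = np.asarray(af, dtype=float)
    X = design.matrix
    if y.shape != (X.shape[0],):
        raise ValueError(f"AF vector length {y.shape} does not match design {X.shape}")
    if design.rank_warning:
        raise ValueError(
            "design is rank deficient (empty factor cell); refusing to fit"
        )
    df_resid = X.shape[0] - X.shape[1]
    if df_resid <= 0:
        raise ValueError(
            f"no residual degrees of freedom ({X.shape[0]} pools, "
            f"{X.shape[1]} coefficients)"
        )
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / df_resid
    if sigma2 < _VAR_ATOL:  # numerically perfect fit
        sigma2 = 0.0
    return ModelFit(
        beta=beta,
        sigma2=sigma2,
        df_resid=df_resid,
        cov_beta=sigma2 * xtx_inv,
        xtx_inv=xtx_inv,
    )


@dataclass
class ContrastSet:
    """All pairwise level differences of one factor as rows acting on beta."""

    factor: str
    labels: list[str]
    K: np.ndarray


def _pair_rows(
    levels: Sequence[str], offset: int, n_cols: int
) -> tuple[list[str], np.ndarray]:
    """Rows encoding mean(A) - mean(B) for each unordered pair, A after B.

    Under treatment coding level i > 0 is represented by dummy column
    ``offset + i - 1`` and the reference level by no column.
    """
    labels, rows = [], []
    for b, a in itertools.combinations(range(len(levels)), 2):
        row = np.zeros(n_cols)
        if a > 0:
            row[offset + a - 1] = 1.0
        if b > 0:
            row[offset + b - 1] = -1.0
        labels.append(f"{levels[a]} - {levels[b]}")
        rows.append(row)
    return labels, np.array(rows)


def pairwise_contrasts(factor: str, design: DesignInfo) -> ContrastSet:
    """Tukey all-pairs contrast matrix for ``factor`` ("color" or "site")."""
    n_cols = design.matrix.shape[1]
    if factor == "color":
        levels, offset = design.color_levels, 1
    elif factor == "site":
        levels, offset = design.site_levels, 1 + len(design.color_levels) - 1
    else:
        raise ValueError(f"unknown factor {factor!r}")
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} needs >= 2 levels")
    labels, K = _pair_rows(levels, offset, n_cols)
    return ContrastSet(factor=factor, labels=labels, K=K)


@dataclass
class ContrastResult:
    """One pairwise comparison: estimate, SE, t, raw and adjusted p."""

    label: str
    factor: str
    estimate: float
    se: float
    statistic: float
    p_raw: float
    p_adj: float
    degenerate: bool = False


def _stack(sets: Sequence[ContrastSet]) -> tuple[np.ndarray, list[str], list[str]]:
    K = np.vstack([s.K for s in sets])
    labels = [lab for s in sets for lab in s.labels]
    factors = [s.factor for s in sets for _ in s.labels]
    return K, labels, factors


def simultaneous_test(
    fit: ModelFit,
    sets: Sequence[ContrastSet],
    correction: str = "bonferroni",
) -> list[ContrastResult]:
    """Test the stacked contrast family K = rbind(K1, K2, ...) on one fit.

    Raw p-values come from the two-sided Student-t on the residual df; the
    adjustment multiplies by the total number of stacked rows (Bonferroni)
    or leaves p unchanged (``correction="none"``).  Zero-SE rows from a
    zero-residual (saturated) fit are mapped to p=1 when the estimate is
    also zero and to p=0 with the ``degenerate`` flag otherwise.
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    K, labels, factors = _stack(sets)
    if K.shape[1] != fit.beta.shape[0]:
        raise ValueError("contrast matrix does not conform to coefficients")
    est = K @ fit.beta
    est[np.abs(est) < _EST_ATOL] = 0.0
    var = np.einsum("ij,jk,ik->i", K, fit.cov_beta, K)
    se = np.sqrt(np.maximum(var, 0.0))
    m = len(labels) if correction == "bonferroni" else 1
    results = []
    for j, (label, factor) in enumerate(zip(labels, factors)):
        e, s = float(est[j]), float(se[j])
        degenerate = False
        if s == 0.0:
            if e == 0.0:
                t, p = 0.0, 1.0
            else:
                t, p = np.inf if e > 0 else -np.inf, 0.0
                degenerate = True
        else:
            t = e / s
            p = float(2.0 * stats.t.sf(abs(t), fit.df_resid))
        results.append(
            ContrastResult(
                label=label,
                factor=factor,
                estimate=e,
                se=s,
                statistic=float(t),
                p_raw=p,
                p_adj=min(1.0, m * p),
                degenerate=degenerate,
            )
        )
    return results


@dataclass
class SNPClassification:
    """Decision outcome for one locus under the exclusion rule."""

    color_associated: bool
    specific_color: str | None
    geography_associated: bool
    significant_pairs: frozenset[str]
    all_color_pairs: bool = False  # every color pair significant: specificity ambiguous
    degenerate: bool = False


def classify_snp(
    results: Sequence[ContrastResult],
    alpha: float = 1e-9,
    color_levels: Sequence[str] | None = None,
) -> SNPClassification:
    """Classify one locus from its full set of pairwise contrast results.

    geography_associated: any site pair with p_adj < alpha.
    color_associated: >= 1 significant color pair AND no significant site
    pair.  A color c is *specific* when the locus is color-associated and
    every pair involving c is significant; if several colors qualify at once
    (with three colors: all three pairs significant) no specific color is
    assigned and ``all_color_pairs`` is flagged.
    """
    labels = [r.label for r in results]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate pairwise label in results")
    color_results = [r for r in results if r.factor == "color"]
    site_results = [r for r in results if r.factor == "site"]
    if color_levels is None:
        seen: list[str] = []
        for r in color_results:
            for lev in r.label.split(" - "):
                if lev not in seen:
                    seen.append(lev)
        color_levels = seen
    expected_pairs = len(color_levels) * (len(color_levels) - 1) // 2
    if len(color_results) != expected_pairs:
        raise ValueError(
            f"expected {expected_pairs} color pairs for levels {color_levels}, "
            f"got {len(color_results)}"
        )
    sig = {r.label for r in results if r.p_adj < alpha}
    geo = any(r.p_adj < alpha for r in site_results)
    any_color = any(r.p_adj < alpha for r in color_results)
    color_associated = any_color and not geo
    specific: str | None = None
    ambiguous = False
    if color_associated:
        candidates = []
        for c in color_levels:
            involving = [r for r in color_results if c in r.label.split(" - ")]
            if involving and all(r.p_adj < alpha for r in involving):
                candidates.append(c)
        if len(candidates) == 1:
            specific = candidates[0]
        elif len(candidates) > 1:
            ambiguous = True
    return SNPClassification(
        color_associated=color_associated,
        specific_color=specific,
        geography_associated=geo,
        significant_pairs=frozenset(sig),
        all_color_pairs=ambiguous,
        degenerate=any(r.degenerate for r in results),
    )


# -- vectorised whole-matrix scan -------------------------------------------


def _scan_arrays(
    Y: np.ndarray, design: DesignInfo, sets: Sequence[ContrastSet]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Estimates, SEs, t, raw p and degenerate flags for all loci at once.

    ``Y`` is loci x pools.  Same math as fit_af_glm + simultaneous_test,
    batched: B = Y pinv', sigma2 = RSS/df, Var(K beta) = sigma2 * diag(K
    (X'X)^-1 K').
    """
    X = design.matrix
    K, _, _ = _stack(sets)
    df = X.shape[0] - X.shape[1]
    xtx_inv = np.linalg.inv(X.T @ X)
    pinv = xtx_inv @ X.T
    B = Y @ pinv.T
    resid = Y - B @ X.T
    sigma2 = (resid**2).sum(axis=1) / df
    sigma2[sigma2 < _VAR_ATOL] = 0.0
    est = B @ K.T
    est[np.abs(est) < _EST_ATOL] = 0.0
    kvar = np.einsum("ij,jk,ik->i", K, xtx_inv, K)
    se = np.sqrt(np.outer(sigma2, kvar))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = est / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    zero_se = se == 0.0
    zero_est = est == 0.0
    p = np.where(zero_se & zero_est, 1.0, p)
    p = np.where(zero_se & ~zero_est, 0.0, p)
    t = np.where(zero_se & zero_est, 0.0, t)
    t = np.where(zero_se & ~zero_est, np.sign(est) * np.inf, t)
    degenerate = zero_se & ~zero_est
    return est, se, t, p, degenerate


def genome_scan(
    af: AFMatrix,
    pools: Sequence[PoolDefinition] | None = None,
    alpha: float = 1e-9,
    correction: str = "bonferroni",
    family_scope: str = "snp",
    color_levels: Sequence[str] | None = None,
    site_levels: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Fit, test and classify every locus of an AF matrix.

    Returns a per-locus table (locus key, per-pair estimates and adjusted
    p-values, flags, classification) and a summary dict with significant
    counts per pairwise comparison and classification totals.

    ``family_scope`` controls the Bonferroni family: ``"snp"`` adjusts over
    the 9 stacked contrasts within each locus (default), ``"genome"`` over
    contrasts x loci.
    """
    if pools is None:
        pools = af.pools
    if family_scope not in ("snp", "genome"):
        raise ValueError(f"unknown family_scope {family_scope!r}")
    design = encode_design(pools, color_levels, site_levels)
    k1 = pairwise_contrasts("color", design)
    k2 = pairwise_contrasts("site", design)
    _, labels, factors = _stack([k1, k2])
    n_loci = af.n_loci
    columns_meta = pd.DataFrame(
        af.loci, columns=["chrom", "pos", "ref", "alt"]
    ) if n_loci else pd.DataFrame(columns=["chrom", "pos", "ref", "alt"])
    if n_loci == 0:
        table = columns_meta.assign(
            degenerate=pd.Series(dtype=bool),
            color_associated=pd.Series(dtype=bool),
            specific_color=pd.Series(dtype=object),
            geography_associated=pd.Series(dtype=bool),
            all_color_pairs=pd.Series(dtype=bool),
        )
        summary = _summarise(table, labels, pd.DataFrame(columns=labels), alpha, design)
        return table, summary
    Y = af.values.T  # loci x pools
    est, se, t, p_raw, degenerate = _scan_arrays(Y, design, [k1, k2])
    m = len(labels) if correction == "bonferroni" else 1
    if family_scope == "genome" and correction == "bonferroni":
        m = len(labels) * n_loci
    p_adj = np.minimum(1.0, m * p_raw)
    is_color = np.array([f == "color" for f in factors])
    sig = p_adj < alpha
    geo = sig[:, ~is_color].any(axis=1)
    any_color = sig[:, is_color].any(axis=1)
    color_assoc = any_color & ~geo
    color_labels = [lab for lab, f in zip(labels, factors) if f == "color"]
    colors = design.color_levels
    involves = np.array(
        [[c in lab.split(" - ") for lab in color_labels] for c in colors]
    )  # colors x color-pairs
    sig_color = sig[:, is_color]
    all_involving = np.array(
        [sig_color[:, inv].all(axis=1) for inv in involves]
    ).T  # loci x colors
    n_candidates = (all_involving & color_assoc[:, None]).sum(axis=1)
    specific = np.full(n_loci, None, dtype=object)
    unique_mask = color_assoc & (n_candidates == 1)
    if unique_mask.any():
        idx = all_involving[unique_mask].argmax(axis=1)
        specific[unique_mask] = np.array(colors, dtype=object)[idx]
    ambiguous = color_assoc & (n_candidates > 1)
    table = columns_meta.copy()
    for j, lab in enumerate(labels):
        table[f"est({lab})"] = est[:, j]
    for j, lab in enumerate(labels):
        table[f"p_adj({lab})"] = p_adj[:, j]
    table["degenerate"] = degenerate.any(axis=1)
    table["color_associated"] = color_assoc
    table["specific_color"] = specific
    table["geography_associated"] = geo
    table["all_color_pairs"] = ambiguous
    padj_frame = pd.DataFrame(p_adj, columns=labels)
    summary = _summarise(table, labels, padj_frame, alpha, design)
    return table, summary


def _summarise(
    table: pd.DataFrame,
    labels: list[str],
    p_adj: pd.DataFrame,
    alpha: float,
    design: DesignInfo,
) -> dict:
    per_pair = {
        lab: int((p_adj[lab] < alpha).sum()) if len(p_adj) else 0 for lab in labels
    }
    per_color = {
        c: int((table["specific_color"] == c).sum()) if len(table) else 0
        for c in design.color_levels
    }
    return {
        "alpha": alpha,
        "n_loci": int(len(table)),
        "significant_per_pair": per_pair,
        "n_color_associated": int(table["color_associated"].sum()) if len(table) else 0,
        "n_specific_per_color": per_color,
        "n_geography_associated": (
            int(table["geography_associated"].sum()) if len(table) else 0
        ),
        "n_degenerate": int(table["degenerate"].sum()) if len(table) else 0,
    }
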