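"""Independent textbook implementations used only to check the package.

Everything here is written from first principles (pseudoinverse normal
equations, explicit enumeration, hand-coded codon table) and deliberately
shares no code path with poolcolor.
"""

import itertools

import numpy as np
from scipy import stats


def ols_contrast_oracle(y, X, K):
    """Estimates, SEs, t and two-sided p for contrast rows K on an OLS fit.

    Direct formula: beta = pinv(X) y; sigma2 = ||y - X beta||^2 / (n - p);
    Var(K beta) = sigma2 K (X'X)^-1 K'.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    K = np.atleast_2d(np.asarray(K, float))
    n, p = X.shape
    beta = np.linalg.pinv(X) @ y
    resid = y - X @ beta
    df = n - p
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    out = []
    for row in K:
        est = float(row @ beta)
        se = float(np.sqrt(row @ cov @ row))
        t = est / se
        pval = 2 * stats.t.sf(abs(t), df)
        out.append((est, se, t, pval))
    return out


def hamming_decompose_oracle(pos, ref, alt):
    """(position, ref_base, alt_base) for each mismatching site of two
    equal-length strings — brute-force character comparison."""
    assert len(ref) == len(alt)
    return [
        (pos + i, r, a) for i, (r, a) in enumerate(zip(ref, alt)) if r != a
    ]


def wilcoxon_exact_oracle(x, y):
    """Two-sided exact rank-sum p by enumerating every assignment of the
    pooled ranks to the first group (mid-ranks for ties)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    order = pooled.argsort(kind="mergesort")
    ranks = np.empty(len(pooled))
    i = 0
    sorted_vals = pooled[order]
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    nx = len(x)
    observed = ranks[:nx].sum()
    mean = ranks.sum() * nx / len(pooled)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), nx):
        s = ranks[list(combo)].sum()
        total += 1
        if abs(s - mean) >= abs(observed - mean) - 1e-12:
            count += 1
    return count / total


def classify_oracle(color_sig, site_sig, color_levels, color_pairs):
    """Brute-force evaluation of the classification rules from significance
    booleans.

    color_sig: dict label -> bool over color pairs; site_sig likewise.
    Returns (color_associated, specific_color, geography_associated,
    ambiguous_all_pairs).
    """
    geo = any(site_sig.values())
    any_color = any(color_sig.values())
    color_associated = any_color and not geo
    candidates = []
    if color_associated:
        for c in color_levels:
            involving = [lab for lab in color_pairs if c in lab.split(" - ")]
            if involving and all(color_sig[lab] for lab in involving):
                candidates.append(c)
    specific = candidates[0] if len(candidates) == 1 else None
    return color_associated, specific, geo, len(candidates) > 1


# Standard genetic code, written out by hand.
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate_oracle(seq):
    return "".join(CODON_TABLE[seq[i : i + 3]] for i in range(0, len(seq), 3))


def pca_eigh_oracle(X):
    """PCA via eigendecomposition of the covariance of the centered data.

    Returns (coordinates, explained_fractions) sorted by decreasing
    eigenvalue; component signs are arbitrary.
    """
    X = np.asarray(X, float)
    centered = X - X.mean(axis=0)
    cov = centered @ centered.T  # pools x pools Gram matrix
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals = np.clip(vals, 0, None)
    coords = vecs * np.sqrt(vals)
    frac = vals / vals.sum() if vals.sum() > 0 else vals
    return coords, frac
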