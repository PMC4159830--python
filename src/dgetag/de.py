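"""Exact two-library count test, BH correction, log2 ratios, DE calls.

The significance of a gene's tag counts x and y in two libraries of sizes N1
and N2 is judged with the classical conditional test for digital expression
profiles: given x, the count y follows

    p(y | x) = (N2/N1)^y * (x+y)! / (x! * y! * (1 + N2/N1)^(x+y+1)),

which is exactly a negative binomial NB(x + 1, N1/(N1+N2)). Two-sided
p-values double the smaller conditional tail (capped at 1). The test is made
symmetric in its two libraries by always conditioning on the smaller count.

A gene is called differentially expressed when FDR <= 0.001 and
|log2 ratio| >= 1 (both thresholds configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: Pairwise contrasts: label -> (numerator library, denominator library).
#: "F1-vs-P" compares F1 against P; its log2 ratio is log2(F1/P).
CONTRASTS = {
    "F1-vs-P": ("F1", "P"),
    "F1-vs-M": ("F1", "M"),
    "P-vs-M": ("P", "M"),
}

DEFAULT_FDR = 0.001
DEFAULT_LFC = 1.0
DEFAULT_PSEUDO_TAGS = 0.5


@dataclass
class DifferentialCall:
    """One gene, one contrast. ``x`` is the denominator-library count, ``y``
    the numerator-library count; log2_ratio is numerator over denominator."""

    gene_id: str
    contrast: str
    x: int
    y: int
    n1: int
    n2: int
    tpm_x: float
    tpm_y: float
    log2_ratio: float
    p_value: float
    fdr: float
    significant: bool
    direction: str  # up / down / none


def exact_count_test(x, y, n1, n2):
    """Two-sided exact p-value for counts x, y in libraries of sizes n1, n2.

    Vectorized over array inputs (broadcast). Symmetric: swapping (x, n1)
    with (y, n2) returns the same p-value.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    n1 = np.asarray(n1)
    n2 = np.asarray(n2)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if np.any(n1 < 1) or np.any(n2 < 1):
        raise ValueError("library sizes must be >= 1")
    x, y, n1, n2 = np.broadcast_arrays(x, y, n1, n2)
    # canonical orientation: condition on the smaller count
    swap = (y < x) | ((y == x) & (n2 < n1))
    a = np.where(swap, y, x)
    b = np.where(swap, x, y)
    na = np.where(swap, n2, n1).astype(float)
    nb = np.where(swap, n1, n2).astype(float)
    pr = na / (na + nb)
    lower = stats.nbinom.cdf(b, a + 1, pr)
    upper = stats.nbinom.sf(b - 1, a + 1, pr)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    # extreme tails underflow double precision; p-values are strictly positive
    p = np.maximum(p, np.finfo(float).tiny)
    return float(p) if p.ndim == 0 else p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log2_ratio(tpm_a, tpm_b, n1, n2, pseudo_tags: float = DEFAULT_PSEUDO_TAGS):
    """log2((tpm_b + pseudo) / (tpm_a + pseudo)), pseudo on zero sides only.

    The pseudocount is ``pseudo_tags`` tags expressed as TPM in the
    corresponding library, applied only where a TPM is zero; genes with both
    sides zero are excluded upstream.
    """
    tpm_a = np.asarray(tpm_a, dtype=float)
    tpm_b = np.asarray(tpm_b, dtype=float)
    a = np.where(tpm_a == 0, pseudo_tags / np.asarray(n1, dtype=float) * 1e6, tpm_a)
    b = np.where(tpm_b == 0, pseudo_tags / np.asarray(n2, dtype=float) * 1e6, tpm_b)
    out = np.log2(b / a)
    return float(out) if out.ndim == 0 else out


def _direction(log2r: np.ndarray, significant: np.ndarray) -> np.ndarray:
    d = np.where(log2r > 0, "up", "down")
    return np.where(significant, d, "none")


def _make_calls(
    gene_ids,
    contrast: str,
    x,
    y,
    n1: int,
    n2: int,
    fdr_threshold: float,
    lfc_threshold: float,
    pseudo_tags: float,
) -> pd.DataFrame:
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    tpm_x = x / n1 * 1e6
    tpm_y = y / n2 * 1e6
    l2r = log2_ratio(tpm_x, tpm_y, n1, n2, pseudo_tags)
    p = exact_count_test(x, y, n1, n2)
    p = np.atleast_1d(p)
    l2r = np.atleast_1d(l2r)
    fdr = bh_adjust(p)
    significant = (fdr <= fdr_threshold) & (np.abs(l2r) >= lfc_threshold)
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "contrast": contrast,
            "x": x,
            "y": y,
            "n1": n1,
            "n2": n2,
            "tpm_x": tpm_x,
            "tpm_y": tpm_y,
            "log2_ratio": l2r,
            "p_value": p,
            "fdr": fdr,
            "significant": significant,
            "direction": _direction(l2r, significant),
        }
    )


def call_differential(
    table,
    contrast: str,
    fdr_threshold: float = DEFAULT_FDR,
    lfc_threshold: float = DEFAULT_LFC,
    pseudo_tags: float = DEFAULT_PSEUDO_TAGS,
) -> pd.DataFrame:
    """Per-gene differential-expression calls for one pairwise contrast.

    ``table`` is an ExpressionTable containing both libraries of the
    contrast. Genes with zero counts in both libraries are excluded from
    testing; BH correction runs over all tested genes of the contrast.
    Returns one row per tested gene (DifferentialCall fields as columns).
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; expected one of {list(CONTRASTS)}")
    num, den = CONTRASTS[contrast]
    for lib in (num, den):
        if lib not in table.counts.columns:
            raise ValueError(f"library {lib!r} missing from expression table")
    xs = table.counts[den]
    ys = table.counts[num]
    tested = (xs > 0) | (ys > 0)
    xs, ys = xs[tested], ys[tested]
    return _make_calls(
        xs.index.to_numpy(),
        contrast,
        xs.to_numpy(),
        ys.to_numpy(),
        table.clean_totals[den],
        table.clean_totals[num],
        fdr_threshold,
        lfc_threshold,
        pseudo_tags,
    )


def row_to_call(row: pd.Series) -> DifferentialCall:
    """Convert one call_differential row into a DifferentialCall."""
    return DifferentialCall(
        gene_id=row["gene_id"],
        contrast=row["contrast"],
        x=int(row["x"]),
        y=int(row["y"]),
        n1=int(row["n1"]),
        n2=int(row["n2"]),
        tpm_x=float(row["tpm_x"]),
        tpm_y=float(row["tpm_y"]),
        log2_ratio=float(row["log2_ratio"]),
        p_value=float(row["p_value"]),
        fdr=float(row["fdr"]),
        significant=bool(row["significant"]),
        direction=str(row["direction"]),
    )
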