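"""Two-group differential expression of miRNA read counts.

The statistical recipe is the classical count-based one for deeply
sequenced small-RNA libraries: per-sample normalization by total
miRNA-assigned reads, an expression filter dropping miRNAs without more
than ``min_count`` reads in at least half the samples, and per-miRNA
two-sided Fisher's exact tests on pooled group counts (miRNA reads vs all
other miRNA reads, group 1 vs group 2) with Bonferroni correction. A
miRNA is called differentially expressed when the adjusted p-value is
below ``alpha`` and the fold change of group mean normalized counts
exceeds ``min_fold``.

Fisher's two-sided p-value uses the standard convention: the sum of the
probabilities of all tables (same margins) no more probable than the
observed one. For small tables the sum is evaluated in exact integer
arithmetic; large tables fall back to :func:`scipy.stats.fisher_exact`,
which implements the same convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_FOLD = 2.0
DEFAULT_MIN_COUNT = 10
DEFAULT_MIN_FRACTION = 0.5

# above this table total, exact integer enumeration hands over to scipy
_EXACT_TOTAL_LIMIT = 2000


def normalize_counts(matrix: pd.DataFrame, scale: float = 1.0) -> pd.DataFrame:
    """Divide each sample's counts by its total assigned reads, times scale.

    Raises if any sample has zero assigned reads (naming the sample), since
    normalization is then undefined.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    totals = matrix.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero assigned reads: {list(zero.index)}")
    return matrix / totals * scale


def filter_expressed(
    matrix: pd.DataFrame,
    min_count: int = DEFAULT_MIN_COUNT,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> pd.DataFrame:
    """Keep miRNAs with count strictly greater than ``min_count`` in at
    least ``ceil(min_fraction * n_samples)`` samples (default: >10 reads in
    at least half the libraries)."""
    n = matrix.shape[1]
    need = math.ceil(min_fraction * n)
    keep = (matrix > min_count).sum(axis=1) >= need
    return matrix.loc[keep]


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table of non-negative ints.

    A table with an all-zero row or column margin is degenerate: only one
    table has those margins, so p = 1 by convention.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    r1, r2 = a + b, c + d
    c1 = a + c
    if r1 == 0 or r2 == 0 or c1 == 0 or b + d == 0:
        return 1.0
    if r1 + r2 > _EXACT_TOTAL_LIMIT:
        return float(stats.fisher_exact([[a, b], [c, d]])[1])
    lo, hi = max(0, c1 - r2), min(r1, c1)
    w_obs = math.comb(r1, a) * math.comb(r2, c)
    total = selected = 0
    for x in range(lo, hi + 1):
        w = math.comb(r1, x) * math.comb(r2, c1 - x)
        total += w
        if w <= w_obs:
            selected += w
    return selected / total


@dataclass(frozen=True)
class DEResult:
    """One row of the differential-expression table."""

    mirna: str
    up_in: str
    mean_g1: float
    se_g1: float
    mean_g2: float
    se_g2: float
    fold_change: float
    p_raw: float
    p_bonferroni: float
    significant: bool
    degenerate: bool = False


def fisher_de(
    matrix: pd.DataFrame,
    grouping: dict[str, str],
    alpha: float = DEFAULT_ALPHA,
    min_fold: float = DEFAULT_MIN_FOLD,
    scale: float | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-miRNA Fisher's exact test between two sample groups.

    Parameters
    ----------
    matrix
        Raw (already expression-filtered) miRNA x sample integer counts.
    grouping
        sample id -> group label; exactly two groups, each with >= 1 sample.
    scale
        Normalization scale for the reported group means; defaults to the
        mean library total, so means read like library-scale counts.
    pseudocount
        Added to pooled normalized means only when computing the fold
        change of a miRNA absent from one group (avoids infinite folds);
        it never touches the test.

    Returns a DataFrame sorted by direction then descending fold change,
    with the Bonferroni denominator m = number of miRNAs tested attached
    in ``df.attrs["m"]``.
    """
    groups = sorted(set(grouping.values()))
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    g1, g2 = groups
    s1 = [s for s in matrix.columns if grouping.get(s) == g1]
    s2 = [s for s in matrix.columns if grouping.get(s) == g2]
    if not s1 or not s2:
        raise ValueError("each group needs at least one sample")
    if scale is None:
        scale = float(matrix.sum(axis=0).mean())
    norm = normalize_counts(matrix, scale=scale)
    pooled1 = matrix[s1].sum(axis=1)
    pooled2 = matrix[s2].sum(axis=1)
    tot1, tot2 = int(pooled1.sum()), int(pooled2.sum())
    m = matrix.shape[0]
    results: list[DEResult] = []
    for mirna in matrix.index:
        a, c = int(pooled1[mirna]), int(pooled2[mirna])
        b, d = tot1 - a, tot2 - c
        degenerate = (a + c == 0) or (b + d == 0)
        p = fisher_exact_two_sided([[a, b], [c, d]])
        v1, v2 = norm.loc[mirna, s1], norm.loc[mirna, s2]
        mean1, mean2 = float(v1.mean()), float(v2.mean())
        se1 = float(v1.std(ddof=1) / math.sqrt(len(s1))) if len(s1) > 1 else 0.0
        se2 = float(v2.std(ddof=1) / math.sqrt(len(s2))) if len(s2) > 1 else 0.0
        lo, hi = sorted([mean1, mean2])
        fold = (hi + (pseudocount if lo == 0 else 0)) / (lo if lo > 0 else pseudocount)
        up_in = g2 if mean2 >= mean1 else g1
        p_adj = min(1.0, p * m)
        results.append(
            DEResult(
                mirna=mirna,
                up_in=up_in,
                mean_g1=mean1,
                se_g1=se1,
                mean_g2=mean2,
                se_g2=se2,
                fold_change=float(fold),
                p_raw=p,
                p_bonferroni=p_adj,
                significant=bool(p_adj < alpha and fold > min_fold),
                degenerate=degenerate,
            )
        )
    df = pd.DataFrame([r.__dict__ for r in results])
    df = df.sort_values(
        ["up_in", "fold_change"], ascending=[True, False], kind="mergesort"
    ).reset_index(drop=True)
    df.attrs["m"] = m
    df.attrs["groups"] = (g1, g2)
    return df


def write_de_table(path, de: pd.DataFrame) -> None:
    """Write the differential-expression result as a TSV with group means
    and standard errors formatted side by side."""
    g1, g2 = de.attrs.get("groups", ("group1", "group2"))
    out = pd.DataFrame(
        {
            "mirna": de["mirna"],
            "up_regulated_in": de["up_in"],
            f"{g1}_counts_se": [
                f"{m:.1f} ({s:.2f})" for m, s in zip(de["mean_g1"], de["se_g1"])
            ],
            f"{g2}_counts_se": [
                f"{m:.1f} ({s:.2f})" for m, s in zip(de["mean_g2"], de["se_g2"])
            ],
            "p_value": de["p_raw"],
            "bonferroni_p": de["p_bonferroni"],
            "fold_change": de["fold_change"].round(2),
            "significant": de["significant"],
        }
    )
    out.to_csv(path, sep="\t", index=False)
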