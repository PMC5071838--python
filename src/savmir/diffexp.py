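"""Digital differential expression for single-library-per-condition designs.

Each miRNA is tested with a Pearson 2x2 chi-squared (count vs library
remainder, no continuity correction) on RAW counts; fold changes are
computed on counts normalized to the mean library total, with zeros floored
to 1 so ratios stay defined.  P-values are Bonferroni-corrected and a miRNA
is called differential at adjusted p <= alpha and fold change >= fc_min.

Orientation convention: the first library is the reference numerator
("WL"), so log2fc = log2(norm_wl / norm_w) and "up" means higher in WL.
The fold-change column is a magnitude (max/min >= 1); direction is carried
by the log2fc sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    p: float
    low_expected: bool  # any expected cell < 5


def normalize(counts: np.ndarray, totals: np.ndarray) -> np.ndarray:
    """Scale raw counts to the mean library total.

    ``counts`` is (n_mirnas, n_libs); ``totals`` the per-library totals.
    Returned values are full precision (round only at report time).
    """
    counts = np.asarray(counts, dtype=float)
    totals = np.asarray(totals, dtype=float)
    if np.any(totals <= 0):
        raise ValueError("library totals must be positive")
    return counts * (totals.mean() / totals)


def floor_counts(norm: np.ndarray) -> np.ndarray:
    """Floor normalized counts to 1 for ratio computation."""
    return np.maximum(np.asarray(norm, dtype=float), 1.0)


def fold_change(norm_wl: float, norm_w: float) -> tuple[float, float]:
    """(magnitude fold change, signed log2 fold change) of two normalized counts.

    Both inputs must already be >= 1 (after flooring).  The magnitude is
    max/min; the sign convention is log2(norm_wl / norm_w).
    """
    if norm_wl < 1 or norm_w < 1:
        raise ValueError("normalized counts must be >= 1 (apply floor_counts first)")
    fc = max(norm_wl, norm_w) / min(norm_wl, norm_w)
    return fc, math.log2(norm_wl / norm_w)


def chi2_2x2(a: int, b: int, total_a: int, total_b: int) -> Chi2Result:
    """Pearson chi-squared (df=1, no continuity correction) on
    [[a, total_a - a], [b, total_b - b]]."""
    if total_a <= 0 or total_b <= 0:
        raise ValueError("library totals must be positive")
    if a > total_a or b > total_b or a < 0 or b < 0:
        raise ValueError("counts must satisfy 0 <= count <= total")
    n = total_a + total_b
    c1 = a + b
    c2 = n - c1
    if c1 == 0 or c2 == 0:
        return Chi2Result(0.0, 1.0, True)
    det = a * (total_b - b) - b * (total_a - a)
    stat = n * det * det / (total_a * total_b * c1 * c2)
    expected_min = min(total_a * c1, total_a * c2, total_b * c1, total_b * c2) / n
    return Chi2Result(float(stat), float(stats.chi2.sf(stat, df=1)),
                      bool(expected_min < 5))


def adjust_bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * m), order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be >= number of p-values")
    return np.minimum(1.0, p * m)


def run(matrix: pd.DataFrame, totals: tuple[int, int], *,
        alpha: float = 0.05, fc_min: float = 1.5) -> pd.DataFrame:
    """Full digital DE analysis on a two-library count matrix.

    ``matrix`` must have columns [mirna_id, count_wl, count_w] (any names;
    first column is the id, then WL then W counts).  Returns a DataFrame
    with normalized counts, fc, log2fc, p, p_adj and call.
    """
    ids = matrix.iloc[:, 0].astype(str).to_numpy()
    raw = matrix.iloc[:, 1:3].to_numpy(dtype=np.int64)
    total_wl, total_w = int(totals[0]), int(totals[1])
    if np.any(raw.sum(axis=0) > np.array([total_wl, total_w])):
        raise ValueError("per-library count sums exceed the stated totals")

    norm = normalize(raw, np.array([total_wl, total_w]))
    floored = floor_counts(norm)
    fc = np.maximum(floored[:, 0], floored[:, 1]) / np.minimum(floored[:, 0], floored[:, 1])
    log2fc = np.log2(floored[:, 0] / floored[:, 1])

    # vectorized Pearson chi-squared on raw counts
    a, b = raw[:, 0].astype(float), raw[:, 1].astype(float)
    n = float(total_wl + total_w)
    c1 = a + b
    c2 = n - c1
    det = a * (total_w - b) - b * (total_wl - a)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(c1 * c2 > 0,
                        n * det * det / (float(total_wl) * total_w * c1 * c2), 0.0)
    p = stats.chi2.sf(stat, df=1)
    p = np.where(c1 * c2 > 0, p, 1.0)
    p_adj = adjust_bonferroni(p)

    sig = (p_adj <= alpha) & (fc >= fc_min)
    call = np.where(sig, np.where(floored[:, 0] > floored[:, 1], "up", "down"), "ns")
    return pd.DataFrame({
        "mirna_id": ids,
        "norm_wl": norm[:, 0], "norm_w": norm[:, 1],
        "fc": fc, "log2fc": log2fc,
        "chi2": stat, "p": p, "p_adj": p_adj,
        "call": call,
    })


def call_de(results: pd.DataFrame, alpha: float = 0.05, fc_min: float = 1.5,
            p_column: str = "p_adj") -> pd.DataFrame:
    """Subset of ``results`` called differential, with direction.

    ``results`` needs norm_wl, norm_w, fc and the chosen p column.  A row is
    significant iff p <= alpha and fc >= fc_min; direction is "up" when the
    WL normalized count is the larger one.
    """
    sig = (results[p_column] <= alpha) & (results["fc"] >= fc_min)
    out = results.loc[sig].copy()
    out["call"] = np.where(out["norm_wl"] > out["norm_w"], "up", "down")
    return out
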