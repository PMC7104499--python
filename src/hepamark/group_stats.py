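"""Per-gene all-pairs group comparisons via the studentized range.

Each gene is tested independently with the Tukey-Kramer statistic

    q_ij = |mean_i - mean_j| / sqrt((MSW / 2) * (1/n_i + 1/n_j))

where MSW is the pooled within-group mean square with N - k degrees of
freedom.  p-values come from the studentized range distribution (numerical
integration via :mod:`scipy.stats.studentized_range`).  No multiple-testing
correction is applied across genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import studentized_range

from .errors import DataValidationError
from .normalization import RatioMatrix

logger = logging.getLogger(__name__)


@dataclass
class TukeyResult:
    """All pairwise comparisons for every gene, with significance flags."""

    table: pd.DataFrame     # columns: gene, comparison, diff, q, p, sig<alpha>...
    msw: pd.Series          # pooled within-group variance per gene
    df: int                 # N - k
    alphas: tuple[float, ...]
    groups: tuple[str, ...]

    def comparisons(self) -> list[str]:
        return list(dict.fromkeys(self.table["comparison"]))


def _alpha_col(alpha: float) -> str:
    return "sig" + format(alpha, "g").replace("0.", "")


def _validate_groups(groups: pd.Series) -> tuple[list[str], pd.Series]:
    labels = list(dict.fromkeys(groups))
    if len(labels) < 2:
        raise DataValidationError("need at least 2 groups")
    sizes = groups.value_counts()
    small = [g for g in labels if sizes[g] < 2]
    if small:
        raise DataValidationError(f"groups with fewer than 2 samples: {small}")
    return labels, sizes


def tukey_q_statistics(
    values: np.ndarray, group_codes: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Vectorized Tukey-Kramer statistics for many genes at once.

    ``values`` is (n_samples, n_genes); ``group_codes`` assigns each sample
    to one of ``k`` groups.  Returns (diffs, q, msw, df) where diffs and q
    are (n_pairs, n_genes) in ``itertools.combinations`` pair order.
    """
    n_samples, n_genes = values.shape
    counts = np.bincount(group_codes, minlength=k).astype(float)
    df = int(n_samples - k)
    if df < 1:
        raise DataValidationError("no residual degrees of freedom")
    means = np.zeros((k, n_genes))
    ss_within = np.zeros(n_genes)
    for g in range(k):
        block = values[group_codes == g]
        means[g] = block.mean(axis=0)
        ss_within += ((block - means[g]) ** 2).sum(axis=0)
    msw = ss_within / df
    pairs = list(combinations(range(k), 2))
    diffs = np.array([means[i] - means[j] for i, j in pairs])
    se = np.array([
        np.sqrt((msw / 2.0) * (1.0 / counts[i] + 1.0 / counts[j]))
        for i, j in pairs
    ])
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.abs(diffs) / se
    return diffs, q, msw, df


def tukey_hsd(
    r: RatioMatrix,
    alphas: Sequence[float] = (0.05, 0.01),
    groups: pd.Series | None = None,
) -> TukeyResult:
    """Tukey-Kramer all-pairs test per gene on a ratio matrix."""
    groups = r.groups if groups is None else groups.loc[r.values.index]
    labels, _ = _validate_groups(groups)
    k = len(labels)
    code_of = {g: i for i, g in enumerate(labels)}
    codes = groups.map(code_of).to_numpy()
    values = r.values.to_numpy(dtype=float)
    genes = list(r.values.columns)

    diffs, q, msw, df = tukey_q_statistics(values, codes, k)
    p = np.where(np.isfinite(q), studentized_range.sf(np.where(np.isfinite(q), q, 0.0), k, df), np.nan)

    # Degenerate genes: zero pooled variance -> q undefined; report p by
    # whether the means actually differ.
    zero_var = msw == 0.0
    if zero_var.any():
        warnings.warn(
            "zero within-group variance for gene(s): "
            + ", ".join(np.array(genes)[zero_var]),
            stacklevel=2,
        )
        for col in np.flatnonzero(zero_var):
            for row in range(diffs.shape[0]):
                equal = diffs[row, col] == 0.0
                q[row, col] = 0.0 if equal else np.inf
                p[row, col] = 1.0 if equal else 0.0

    pair_names = [f"{labels[i]}-{labels[j]}" for i, j in combinations(range(k), 2)]
    records = []
    for row, comparison in enumerate(pair_names):
        for col, gene in enumerate(genes):
            rec = {
                "gene": gene, "comparison": comparison,
                "diff": diffs[row, col], "q": q[row, col], "p": p[row, col],
            }
            for alpha in alphas:
                rec[_alpha_col(alpha)] = bool(p[row, col] < alpha)
            records.append(rec)
    table = pd.DataFrame.from_records(records)
    # Stable output order: gene panel order within each comparison.
    table["_g"] = table["gene"].map({g: i for i, g in enumerate(genes)})
    table = table.sort_values(["comparison", "_g"]).drop(columns="_g")
    table = table.reset_index(drop=True)
    logger.info("tukey: %d genes, k=%d groups, df=%d", len(genes), k, df)
    return TukeyResult(
        table=table,
        msw=pd.Series(msw, index=genes),
        df=df,
        alphas=tuple(alphas),
        groups=tuple(labels),
    )


def significant_gene_sets(
    t: TukeyResult, comparison: str, alpha: float,
) -> list[str]:
    """Genes flagged for one comparison at one alpha, in input gene order.

    The comparison may be given in either orientation ("A-B" or "B-A").
    """
    available = set(t.table["comparison"])
    if comparison not in available:
        flipped = "-".join(reversed(comparison.split("-", 1)))
        if flipped in available:
            comparison = flipped
        else:
            raise DataValidationError(
                f"unknown comparison {comparison!r}; have {sorted(available)}"
            )
    col = _alpha_col(alpha)
    if col not in t.table.columns:
        raise DataValidationError(
            f"alpha {alpha} was not computed; available: {t.alphas}"
        )
    sub = t.table[t.table["comparison"] == comparison]
    return list(sub.loc[sub[col], "gene"])


def critical_q(alpha: float, k: int, df: int) -> float:
    """Critical value of the studentized range at family-wise level alpha."""
    return float(studentized_range.ppf(1.0 - alpha, k, df))
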