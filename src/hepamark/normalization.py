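"""Raw counts -> normalizer-adjusted log2(exp/cont) ratio vectors.

The chain is: log2(count + pseudocount), subtract the normalizer gene's
log2 value per sample (making every value library-depth invariant), then
subtract the per-gene control-group mean so control rows average exactly
zero.  Ratio matrices are restricted to the 12 marker genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataValidationError, NumericError
from .table_io import MARKER_GENES, ReadCountMatrix

logger = logging.getLogger(__name__)


@dataclass
class Log2Matrix:
    """Samples x genes matrix of log2-transformed counts."""

    values: pd.DataFrame
    pseudocount: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise NumericError("non-finite value in log2 matrix")


@dataclass
class RatioMatrix:
    """Samples x 12-marker-gene matrix of log2(exp/cont) ratios."""

    values: pd.DataFrame        # columns: the 12 marker genes
    groups: pd.Series
    control_label: str
    normalizer: str

    def __post_init__(self) -> None:
        if self.normalizer in self.values.columns:
            raise DataValidationError("normalizer gene must not be a ratio column")
        control = self.values.loc[self.groups == self.control_label]
        if len(control) and (control.mean(axis=0).abs() > 1e-9).any():
            raise NumericError("control-group mean is not zero")


@dataclass
class Log2RatioProfile:
    """One 12-gene ratio vector (a sample or a condition mean)."""

    values: pd.Series
    label: str

    def __post_init__(self) -> None:
        if len(self.values) != len(MARKER_GENES):
            raise DataValidationError(
                f"profile {self.label!r} must cover all {len(MARKER_GENES)} marker genes"
            )
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise NumericError(f"non-finite ratio in profile {self.label!r}")


def log2_transform(counts: ReadCountMatrix, pseudocount: float = 1.0) -> Log2Matrix:
    """Elementwise log2(count + pseudocount)."""
    if pseudocount < 0:
        raise DataValidationError("pseudocount must be >= 0")
    if pseudocount == 0 and (counts.counts.to_numpy() == 0).any():
        raise DataValidationError("zero count; set pseudocount")
    values = np.log2(counts.counts.astype(float) + pseudocount)
    logger.info("log2 transform: %s, pseudocount=%g", values.shape, pseudocount)
    return Log2Matrix(values=values, pseudocount=pseudocount)


def normalize_by_gene(m: Log2Matrix, normalizer: str) -> Log2Matrix:
    """Subtract the normalizer gene's log2 value per sample, then drop it."""
    if normalizer not in m.values.columns:
        raise DataValidationError(f"normalizer gene {normalizer!r} absent")
    adjusted = m.values.sub(m.values[normalizer], axis=0)
    adjusted = adjusted.drop(columns=[normalizer])
    return Log2Matrix(values=adjusted, pseudocount=m.pseudocount)


def ratio_vs_control(
    m: Log2Matrix,
    groups: pd.Series,
    control_label: str,
    normalizer: str,
    marker_genes: tuple[str, ...] = MARKER_GENES,
) -> RatioMatrix:
    """Center each gene on the control-group mean; keep the 12 markers only."""
    groups = groups.loc[m.values.index]
    control_mask = groups == control_label
    if control_mask.sum() < 2:
        raise DataValidationError(
            f"control group {control_label!r} absent or has fewer than 2 samples"
        )
    missing = [g for g in marker_genes if g not in m.values.columns]
    if missing:
        raise DataValidationError(f"marker genes missing: {missing}")
    markers = m.values[list(marker_genes)]
    centered = markers.sub(markers.loc[control_mask].mean(axis=0), axis=1)
    logger.info("ratio vs control %r: %s", control_label, centered.shape)
    return RatioMatrix(values=centered, groups=groups,
                       control_label=control_label, normalizer=normalizer)


def normalize_pipeline(
    counts: ReadCountMatrix,
    normalizer: str = "Dazap2",
    pseudocount: float = 1.0,
    control_label: str = "cont",
) -> RatioMatrix:
    """Full chain: log2 -> normalize by gene -> center on control mean."""
    log2m = log2_transform(counts, pseudocount)
    adjusted = normalize_by_gene(log2m, normalizer)
    return ratio_vs_control(adjusted, counts.groups, control_label, normalizer)


def condition_profile(r: RatioMatrix, group: str) -> Log2RatioProfile:
    """Per-gene arithmetic mean of a group's ratio rows."""
    mask = r.groups == group
    if not mask.any():
        raise DataValidationError(f"unknown group {group!r}")
    mean = r.values.loc[mask].mean(axis=0)
    return Log2RatioProfile(values=mean, label=group)


def sample_profile(r: RatioMatrix, sample: str) -> Log2RatioProfile:
    if sample not in r.values.index:
        raise DataValidationError(f"unknown sample {sample!r}")
    return Log2RatioProfile(values=r.values.loc[sample], label=sample)


def rank_normalizer_candidates(
    m: Log2Matrix, groups: pd.Series
) -> list[tuple[str, float]]:
    """Rank genes by expression stability across groups.

    Stability score is the standard deviation (ddof=1) of per-group mean
    log2 values across groups — lower is more stable.  Ties are broken in
    favour of higher overall mean expression.
    """
    groups = groups.loc[m.values.index]
    if groups.nunique() < 2:
        raise DataValidationError("need at least 2 groups to rank normalizers")
    group_means = m.values.groupby(groups).mean()
    scores = group_means.std(axis=0, ddof=1)
    overall = m.values.mean(axis=0)
    order = sorted(m.values.columns, key=lambda g: (scores[g], -overall[g]))
    return [(g, float(scores[g])) for g in order]
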