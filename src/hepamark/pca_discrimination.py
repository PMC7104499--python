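"""Correlation-matrix PCA of reference + query ratio rows, PC1 border,
and classification.

Rows are standardized per gene ((x - mu) / sigma with the n-1 sample SD),
decomposed by SVD, and then oriented: PC1 is flipped if necessary so that
genotoxic-class rows score lower than the rest, PC2 so that its
largest-magnitude loading is positive.  The decision border on PC1 is the
midpoint between the highest genotoxic score and the lowest non-genotoxic
score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataValidationError, NumericError
from .table_io import MARKER_GENES, ReferencePanel

logger = logging.getLogger(__name__)

GTHC_LABEL = "GTHC"
QUERY_LABEL = "QUERY"
POSITIVE_CALL = "GTHC-like"
NEGATIVE_CALL = "non-GTHC-like"


@dataclass
class PCAResult:
    loadings: pd.DataFrame          # genes x components (unit-norm columns)
    scores: pd.DataFrame            # points x components, plus "class" column
    explained_variance_ratio: np.ndarray
    mu: pd.Series                   # per-gene standardization mean
    sigma: pd.Series                # per-gene standardization SD (ddof=1)
    orientation: dict = field(default_factory=dict)

    @property
    def components(self) -> list[str]:
        return list(self.loadings.columns)

    def score_matrix(self) -> pd.DataFrame:
        return self.scores[self.components]


@dataclass
class BorderResult:
    border: float
    gthc_flank: str                 # point ID of the highest-scoring GTHC
    non_gthc_flank: str             # point ID of the lowest-scoring non-GTHC
    separable: bool


def standardize(
    rows: pd.DataFrame, ddof: int = 1
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Column-wise z-scoring; errors on any zero-variance gene."""
    if rows.shape[0] < 3:
        raise DataValidationError("need at least 3 rows to standardize")
    mu = rows.mean(axis=0)
    sigma = rows.std(axis=0, ddof=ddof)
    dead = sigma.index[sigma.to_numpy() == 0.0]
    if len(dead):
        raise NumericError(f"zero-variance gene(s): {list(dead)}")
    z = (rows - mu) / sigma
    return z, mu, sigma


def fit_pca(
    z: pd.DataFrame,
    labels: pd.Series,
    mu: pd.Series | None = None,
    sigma: pd.Series | None = None,
    n_components: int = 2,
) -> PCAResult:
    """SVD-based PCA of a standardized matrix, followed by sign orientation.

    ``labels`` aligns with the rows of ``z``; rows labeled QUERY take no
    part in orientation.  PC1 is oriented so genotoxic rows score low; PC2
    so its largest-|loading| gene loads positively.
    """
    if z.shape[0] < 3:
        raise DataValidationError("need at least 3 rows for PCA")
    labels = labels.loc[z.index]
    X = z.to_numpy(dtype=float)
    X = X - X.mean(axis=0)  # z is mean-centered already; guard against drift
    _, svals, vt = np.linalg.svd(X, full_matrices=False)
    n_components = min(n_components, vt.shape[0])
    ev = svals ** 2
    evr = ev / ev.sum()

    loadings = vt[:n_components].T.copy()            # genes x components
    scores = X @ loadings

    orientation = {}
    ref_mask = (labels != QUERY_LABEL).to_numpy()
    if ref_mask.any() and (labels[ref_mask] == GTHC_LABEL).any() \
            and (labels[ref_mask] != GTHC_LABEL).any():
        gthc = (labels == GTHC_LABEL).to_numpy()
        flip1 = scores[gthc, 0].mean() >= scores[ref_mask & ~gthc, 0].mean()
        if flip1:
            loadings[:, 0] *= -1.0
            scores[:, 0] *= -1.0
        orientation["pc1_flipped"] = bool(flip1)
    else:
        logger.warning("no labeled rows of both classes; PC1 orientation skipped")
        orientation["pc1_flipped"] = None
    if n_components >= 2:
        top = int(np.argmax(np.abs(loadings[:, 1])))
        flip2 = loadings[top, 1] < 0
        if flip2:
            loadings[:, 1] *= -1.0
            scores[:, 1] *= -1.0
        orientation["pc2_flipped"] = bool(flip2)

    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    loadings_df = pd.DataFrame(loadings, index=z.columns, columns=comp_names)
    scores_df = pd.DataFrame(scores, index=z.index, columns=comp_names)
    scores_df["class"] = labels
    logger.info("PCA: %d points, EVR %s", z.shape[0],
                np.round(evr[:n_components], 3))
    return PCAResult(
        loadings=loadings_df,
        scores=scores_df,
        explained_variance_ratio=evr[:n_components],
        mu=mu if mu is not None else pd.Series(0.0, index=z.columns),
        sigma=sigma if sigma is not None else pd.Series(1.0, index=z.columns),
        orientation=orientation,
    )


def fit_panel_pca(
    panel: ReferencePanel,
    queries: pd.DataFrame | None = None,
    project_only: bool = False,
    n_components: int = 2,
) -> PCAResult:
    """PCA of a reference panel, optionally with query ratio rows.

    By default queries join the fit (combined standardization); with
    ``project_only`` the fit uses reference rows alone and queries are
    projected using the reference mu/sigma and loadings.
    """
    ratios = panel.ratios()
    labels = panel.classes.copy()
    if queries is not None:
        queries = queries[list(panel.marker_genes)].astype(float)
        overlap = queries.index.intersection(ratios.index)
        if len(overlap):
            raise DataValidationError(f"query IDs collide with panel points: {list(overlap)}")
    if queries is not None and not project_only:
        ratios = pd.concat([ratios, queries])
        labels = pd.concat([labels, pd.Series(QUERY_LABEL, index=queries.index)])
    z, mu, sigma = standardize(ratios)
    result = fit_pca(z, labels, mu=mu, sigma=sigma, n_components=n_components)
    if queries is not None and project_only:
        zq = (queries - mu) / sigma
        proj = zq.to_numpy() @ result.loadings.to_numpy()
        extra = pd.DataFrame(proj, index=queries.index, columns=result.components)
        extra["class"] = QUERY_LABEL
        result.scores = pd.concat([result.scores, extra])
    return result


def pc1_border(result: PCAResult) -> BorderResult:
    """Midpoint border between the flanking class extremes on PC1."""
    scores = result.scores
    gthc = scores[scores["class"] == GTHC_LABEL]
    non = scores[~scores["class"].isin([GTHC_LABEL, QUERY_LABEL])]
    if gthc.empty or non.empty:
        raise DataValidationError("both GTHC and non-GTHC points are required")
    hi_gthc = gthc["PC1"].idxmax()
    lo_non = non["PC1"].idxmin()
    a, b = gthc.loc[hi_gthc, "PC1"], non.loc[lo_non, "PC1"]
    border = (a + b) / 2.0
    separable = bool(a < b)
    if not separable:
        logger.warning("classes overlap on PC1 (%.4g >= %.4g)", a, b)
    return BorderResult(border=float(border), gthc_flank=str(hi_gthc),
                        non_gthc_flank=str(lo_non), separable=separable)


def classify_by_pca(
    result: PCAResult, border: float, query_ids: list[str],
) -> pd.Series:
    """Label queries by their PC1 score: strictly below the border -> GTHC-like."""
    missing = [q for q in query_ids if q not in result.scores.index]
    if missing:
        raise DataValidationError(f"unknown query IDs: {missing}")
    pc1 = result.scores.loc[query_ids, "PC1"]
    return pd.Series(
        np.where(pc1 < border, POSITIVE_CALL, NEGATIVE_CALL),
        index=query_ids, name="call",
    )


def extract_fixed_constants(result: PCAResult, border: float | None = None,
                            provenance: str = "panel-fit"):
    """Freeze (PC1 loading, mu, sigma) per gene into portable score constants."""
    from .fixed_score import FixedScoreConstants

    if border is None:
        border = pc1_border(result).border
    genes = tuple(result.loadings.index)
    return FixedScoreConstants(
        genes=genes,
        a=tuple(float(v) for v in result.loadings["PC1"]),
        mu=tuple(float(result.mu[g]) for g in genes),
        sigma=tuple(float(result.sigma[g]) for g in genes),
        border=float(border),
        provenance=provenance,
    )
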