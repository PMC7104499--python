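"""Tabular I/O with fixed schemas, plus the gene panel and config plumbing.

Every table the pipeline touches is tab-separated UTF-8 with Unix newlines
and a header row.  Gene columns are always emitted in the canonical panel
order so downstream parsers see a stable schema.  Readers validate type
invariants and refuse to coerce silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DataValidationError

logger = logging.getLogger(__name__)

#: Number of significant digits used when writing floats.
FLOAT_FORMAT = "%.6g"

#: Reference-panel class labels accepted on input.
PANEL_CLASSES = ("GTHC", "NGTHC", "NGTNHC", "QUERY")


# ---------------------------------------------------------------------------
# Gene panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenePanel:
    """The marker-gene panel plus candidate normalizer genes.

    ``marker_genes`` keeps the canonical column order used by every table
    writer; ``gene_ids`` maps each symbol to its NCBI Gene ID.
    """

    marker_genes: tuple[str, ...]
    normalizer_genes: tuple[str, ...]
    gene_ids: Mapping[str, int]

    def __post_init__(self) -> None:
        if len(self.marker_genes) != 12:
            raise DataValidationError(
                f"panel must have exactly 12 marker genes, got {len(self.marker_genes)}"
            )
        all_genes = self.marker_genes + self.normalizer_genes
        if len(set(all_genes)) != len(all_genes):
            raise DataValidationError("gene symbols must be unique")
        missing = [g for g in all_genes if g not in self.gene_ids]
        if missing:
            raise DataValidationError(f"genes without an ID: {missing}")

    @property
    def all_genes(self) -> tuple[str, ...]:
        return self.marker_genes + self.normalizer_genes


#: Canonical 12 marker genes + 2 normalizer candidates with NCBI rat gene IDs.
DEFAULT_PANEL = GenePanel(
    marker_genes=(
        "Aen", "Bax", "Btg2", "Ccnf", "Ccng1", "Cdkn1a",
        "Gdf15", "Lrp1", "Mbd1", "Phlda3", "Plk2", "Tubb4b",
    ),
    normalizer_genes=("Dazap2", "Ube2d3"),
    gene_ids={
        "Aen": 361594,
        "Bax": 24887,
        "Btg2": 29619,
        "Ccnf": 117524,
        "Ccng1": 25405,
        "Cdkn1a": 114851,
        "Gdf15": 29455,
        "Lrp1": 299858,
        "Mbd1": 291439,
        "Phlda3": 363989,
        "Plk2": 83722,
        "Tubb4b": 296554,
        "Dazap2": 300235,
        "Ube2d3": 81920,
    },
)

MARKER_GENES: tuple[str, ...] = DEFAULT_PANEL.marker_genes
NORMALIZER_GENES: tuple[str, ...] = DEFAULT_PANEL.normalizer_genes


# ---------------------------------------------------------------------------
# Core table types
# ---------------------------------------------------------------------------

@dataclass
class ReadCountMatrix:
    """Raw targeted-RNA-Seq read counts (samples x genes) with group labels."""

    counts: pd.DataFrame            # index: sample IDs, columns: gene symbols, int64
    groups: pd.Series               # index: sample IDs, values: group labels

    def __post_init__(self) -> None:
        if self.counts.shape[0] == 0:
            raise DataValidationError("no samples in count matrix")
        if not np.issubdtype(self.counts.values.dtype, np.integer):
            raise DataValidationError("counts must be integers")
        if (self.counts.values < 0).any():
            r, c = np.argwhere(self.counts.values < 0)[0]
            raise DataValidationError(
                f"negative count at sample {self.counts.index[r]!r}, "
                f"gene {self.counts.columns[c]!r}"
            )
        missing = self.counts.index.difference(self.groups.index)
        if len(missing):
            raise DataValidationError(f"samples missing from group map: {list(missing)}")
        self.groups = self.groups.loc[self.counts.index]
        self.counts.index.name = "sample"
        self.groups.index.name = "sample"
        self.groups.name = "group"

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.columns)

    def group_sizes(self) -> dict[str, int]:
        return self.groups.value_counts().to_dict()


@dataclass
class ReferencePanel:
    """Labeled 12-gene log2 ratio rows (reference points + optional queries)."""

    data: pd.DataFrame  # index point_id; columns chemical, dose, time, class + 12 genes
    marker_genes: tuple[str, ...] = MARKER_GENES

    META_COLUMNS = ("chemical", "dose", "time", "class")

    def __post_init__(self) -> None:
        for col in self.META_COLUMNS:
            if col not in self.data.columns:
                raise DataValidationError(f"reference panel missing column {col!r}")
        missing = [g for g in self.marker_genes if g not in self.data.columns]
        if missing:
            raise DataValidationError(f"reference panel missing gene columns: {missing}")
        bad = set(self.data["class"]) - set(PANEL_CLASSES)
        if bad:
            raise DataValidationError(f"unknown class labels: {sorted(bad)}")
        if self.data.index.has_duplicates:
            raise DataValidationError("duplicate point IDs in reference panel")
        values = self.data[list(self.marker_genes)].to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise DataValidationError("non-finite ratio value in reference panel")
        # Normalize column order: metadata first, genes in panel order.
        self.data = self.data[list(self.META_COLUMNS) + list(self.marker_genes)]

    @property
    def classes(self) -> pd.Series:
        return self.data["class"]

    def ratios(self) -> pd.DataFrame:
        return self.data[list(self.marker_genes)].astype(float)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class AnalysisConfig:
    """Run-level parameters for the pipeline."""

    normalizer: str = "Dazap2"
    pseudocount: float = 1.0
    alphas: tuple[float, ...] = (0.05, 0.01)
    control_label: str = "cont"
    border_mode: str = "midpoint"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise DataValidationError("pseudocount must be >= 0")
        for a in self.alphas:
            if not 0.0 < a < 1.0:
                raise DataValidationError(f"alpha {a} outside (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise DataValidationError(f"unknown config keys: {sorted(unknown)}")
        if "alphas" in raw:
            raw["alphas"] = tuple(float(a) for a in raw["alphas"])
        return cls(**raw)

    def with_overrides(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataValidationError(f"file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise DataValidationError(f"no samples: {path} is empty") from None
    if df.shape[0] == 0:
        raise DataValidationError(f"no samples: {path} has a header but no rows")
    return df


def read_group_map(path: str | Path) -> pd.Series:
    """Read a two-column sample -> group TSV."""
    df = _read_tsv(path)
    if df.shape[1] < 1:
        raise DataValidationError(f"group map {path} needs a group column")
    series = df.iloc[:, 0]
    series.name = "group"
    series.index.name = "sample"
    return series


def read_count_table(
    path: str | Path,
    group_map: str | Path,
    panel: GenePanel = DEFAULT_PANEL,
    normalizer: str = "Dazap2",
) -> ReadCountMatrix:
    """Read a raw count TSV plus its sample -> group map.

    The count table has gene symbols as header and sample IDs in the first
    column.  Symbols are matched case-sensitively against the panel; the
    chosen normalizer gene must be present and every count must be a
    non-negative integer.
    """
    df = _read_tsv(path)
    counts = pd.DataFrame(index=df.index.astype(str))
    for col in df.columns:
        values = df[col]
        try:
            as_int = values.astype(np.int64)
        except (ValueError, TypeError):
            bad = values[pd.to_numeric(values, errors="coerce").isna()]
            where = bad.index[0] if len(bad) else values.index[0]
            raise DataValidationError(
                f"non-integer count at sample {where!r}, gene {col!r}"
            ) from None
        numeric = pd.to_numeric(values)
        if not (numeric == as_int).all():
            where = numeric.index[(numeric != as_int).to_numpy()][0]
            raise DataValidationError(
                f"non-integer count at sample {where!r}, gene {col!r}"
            )
        counts[col] = as_int
    if normalizer not in counts.columns:
        raise DataValidationError(
            f"normalizer gene {normalizer!r} missing from count table"
        )
    missing_markers = [g for g in panel.marker_genes if g not in counts.columns]
    if missing_markers:
        raise DataValidationError(f"marker genes missing from count table: {missing_markers}")
    groups = read_group_map(group_map)
    matrix = ReadCountMatrix(counts=counts, groups=groups)
    logger.info(
        "read count table %s: %d samples x %d genes, groups %s",
        path, counts.shape[0], counts.shape[1], matrix.group_sizes(),
    )
    return matrix


def write_count_table(matrix: ReadCountMatrix, path: str | Path,
                      group_map: str | Path | None = None) -> None:
    df = matrix.counts.copy()
    df.index.name = "sample"
    df.to_csv(path, sep="\t", lineterminator="\n")
    if group_map is not None:
        gm = matrix.groups.to_frame()
        gm.index.name = "sample"
        gm.to_csv(group_map, sep="\t", lineterminator="\n")


def read_reference_panel(path: str | Path,
                         panel: GenePanel = DEFAULT_PANEL) -> ReferencePanel:
    """Read a reference-panel TSV (point_id, chemical, dose, time, class, genes)."""
    df = _read_tsv(path)
    for gene in panel.marker_genes:
        if gene not in df.columns:
            raise DataValidationError(f"reference panel missing gene column {gene!r}")
        df[gene] = df[gene].astype(float)
    df.index = df.index.astype(str)
    df.index.name = "point_id"
    ref = ReferencePanel(data=df, marker_genes=panel.marker_genes)
    logger.info("read reference panel %s: %d points, classes %s",
                path, len(ref), ref.classes.value_counts().to_dict())
    return ref


def write_reference_panel(ref: ReferencePanel, path: str | Path) -> None:
    df = ref.data.copy()
    df.index.name = "point_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, lineterminator="\n")


def write_float_table(df: pd.DataFrame, path: str | Path, index_name: str) -> None:
    """Write a float-valued table at fixed 6-significant-digit precision."""
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, lineterminator="\n")


def read_float_table(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    return df.astype(float)


def write_ratio_matrix(ratio, path: str | Path) -> None:
    """Write a RatioMatrix's sample x 12-gene values at fixed precision."""
    write_float_table(ratio.values, path, "sample")


def read_ratio_matrix(
    path: str | Path,
    group_map: str | Path,
    control_label: str,
    normalizer: str = "Dazap2",
):
    """Re-read a ratio TSV written by :func:`write_ratio_matrix`.

    Fixed-precision formatting perturbs the control-group mean by ~1e-7,
    so the control centering is re-applied (idempotent up to rounding)
    before the control-mean-zero invariant is re-checked.
    """
    from .normalization import RatioMatrix

    values = read_float_table(path)
    values.index = values.index.astype(str)
    groups = read_group_map(group_map).loc[values.index]
    control = values.loc[groups == control_label]
    if len(control) < 2:
        raise DataValidationError(
            f"control group {control_label!r} absent or has fewer than 2 samples"
        )
    values = values.sub(control.mean(axis=0), axis=1)
    return RatioMatrix(values=values, groups=groups,
                       control_label=control_label, normalizer=normalizer)


def write_results(results, path: str | Path) -> list[Path]:
    """Write any typed pipeline product to TSV with a deterministic schema.

    Returns the list of files written (PCA results produce two tables).
    """
    from .group_stats import TukeyResult
    from .pca_discrimination import PCAResult

    path = Path(path)
    if isinstance(results, TukeyResult):
        write_float_table(results.table.set_index("gene"), path, "gene")
        return [path]
    if isinstance(results, PCAResult):
        scores_path = path.with_name(path.stem + "_scores.tsv")
        loadings_path = path.with_name(path.stem + "_loadings.tsv")
        write_float_table(results.scores, scores_path, "point_id")
        write_float_table(results.loadings, loadings_path, "gene")
        return [scores_path, loadings_path]
    if isinstance(results, pd.DataFrame):
        write_float_table(results, path, results.index.name or "id")
        return [path]
    raise DataValidationError(f"cannot serialise result of type {type(results).__name__}")
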