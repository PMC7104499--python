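"""Synthetic count tables and reference ratio panels.

Counts follow a negative binomial with mean/size parameterization
(variance = m + m^2/k) under a per-sample log-normal library-size factor,
so that reference-gene normalization cancels depth exactly in expectation.
Reference-panel points are drawn from per-class multivariate normals whose
default means keep the genotoxic class well below the fixed-score border.

All effect magnitudes here are the artifact's own presets; only the sign
pattern (which genes respond) mirrors the study design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataValidationError
from .table_io import (
    DEFAULT_PANEL,
    MARKER_GENES,
    GenePanel,
    ReadCountMatrix,
    ReferencePanel,
)

logger = logging.getLogger(__name__)

# NB sizes above this are drawn as Poisson (the k -> inf limit).
_POISSON_SIZE_CUTOFF = 1e8


@dataclass(frozen=True)
class EffectProfile:
    """Per-gene log2 fold-changes of a treatment group versus control."""

    name: str
    lfc: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = [g for g in MARKER_GENES if g not in self.lfc]
        if missing:
            raise DataValidationError(
                f"effect profile {self.name!r} missing lfc for: {missing}"
            )

    def lfc_for(self, gene: str) -> float:
        # Normalizer genes default to no change unless explicitly overridden.
        return float(self.lfc.get(gene, 0.0))

    def marker_vector(self) -> np.ndarray:
        return np.array([self.lfc_for(g) for g in MARKER_GENES])


def _profile(name: str, nonzero: Mapping[str, float]) -> EffectProfile:
    lfc = {g: 0.0 for g in MARKER_GENES}
    lfc.update(nonzero)
    return EffectProfile(name=name, lfc=lfc)


#: The eight marker genes that respond in the genotoxic-like preset.
GTHC_RESPONSIVE_GENES = (
    "Aen", "Bax", "Btg2", "Ccng1", "Gdf15", "Mbd1", "Phlda3", "Tubb4b",
)


def preset_profiles() -> dict[str, EffectProfile]:
    """Built-in effect profiles: genotoxic-like, non-genotoxic-like, and null.

    ``gthc_like`` up-regulates exactly the eight responsive marker genes
    (magnitudes 1.5-3.0, synthetic); ``ngthc_like`` changes only Gdf15;
    ``null`` changes nothing.
    """
    return {
        "gthc_like": _profile("gthc_like", {
            "Aen": 2.5, "Bax": 2.0, "Btg2": 2.5, "Ccng1": 2.0,
            "Gdf15": 3.0, "Mbd1": 1.5, "Phlda3": 2.5, "Tubb4b": 1.5,
        }),
        "ngthc_like": _profile("ngthc_like", {"Gdf15": 1.0}),
        "null": _profile("null", {}),
    }


#: Default expected read counts per gene (normalizer high, markers 10^2-10^4).
DEFAULT_BASELINE_MEAN: dict[str, float] = {
    "Aen": 800.0, "Bax": 3000.0, "Btg2": 1200.0, "Ccnf": 400.0,
    "Ccng1": 5000.0, "Cdkn1a": 1500.0, "Gdf15": 150.0, "Lrp1": 2500.0,
    "Mbd1": 600.0, "Phlda3": 900.0, "Plk2": 300.0, "Tubb4b": 7000.0,
    "Dazap2": 50000.0, "Ube2d3": 8000.0,
}

#: Default NB size parameters (markers moderately dispersed, normalizers tight).
DEFAULT_DISPERSION: dict[str, float] = dict(
    {g: 25.0 for g in MARKER_GENES}, Dazap2=100.0, Ube2d3=100.0,
)


@dataclass
class SimulationConfig:
    """Configuration of the count simulator."""

    group_profiles: Mapping[str, EffectProfile]
    n_per_group: int = 5
    baseline_mean: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_MEAN))
    dispersion: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DISPERSION))
    library_size_sd: float = 0.15
    seed: int = 0
    panel: GenePanel = DEFAULT_PANEL

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise DataValidationError("n_per_group must be >= 2")
        for g in self.panel.all_genes:
            if self.baseline_mean.get(g, 0.0) <= 0:
                raise DataValidationError(f"baseline mean for {g!r} must be > 0")
            if self.dispersion.get(g, 0.0) <= 0:
                raise DataValidationError(f"dispersion for {g!r} must be > 0")
        if self.library_size_sd < 0:
            raise DataValidationError("library_size_sd must be >= 0")


def simulate_counts(cfg: SimulationConfig) -> ReadCountMatrix:
    """Draw a ReadCountMatrix: NB(mean = L_s * baseline * 2^lfc, size = k)."""
    rng = np.random.default_rng(cfg.seed)
    genes = list(cfg.panel.all_genes)
    rows, sample_ids, group_labels = [], [], []
    for group, profile in cfg.group_profiles.items():
        for i in range(cfg.n_per_group):
            lib = float(np.exp(rng.normal(0.0, cfg.library_size_sd))) \
                if cfg.library_size_sd > 0 else 1.0
            counts = np.empty(len(genes), dtype=np.int64)
            for j, gene in enumerate(genes):
                mean = lib * cfg.baseline_mean[gene] * 2.0 ** profile.lfc_for(gene)
                size = cfg.dispersion[gene]
                if size >= _POISSON_SIZE_CUTOFF:
                    counts[j] = rng.poisson(mean)
                else:
                    counts[j] = rng.negative_binomial(size, size / (size + mean))
            rows.append(counts)
            sample_ids.append(f"{group}-{i + 1}")
            group_labels.append(group)
    counts_df = pd.DataFrame(np.vstack(rows), index=sample_ids, columns=genes)
    groups = pd.Series(group_labels, index=sample_ids, name="group")
    logger.info("simulated counts: %d samples x %d genes (seed=%d)",
                counts_df.shape[0], counts_df.shape[1], cfg.seed)
    return ReadCountMatrix(counts=counts_df, groups=groups)


def default_study_config(seed: int = 0, n_per_group: int = 5) -> SimulationConfig:
    """Three-group design: control, genotoxic-like, non-genotoxic-like."""
    presets = preset_profiles()
    return SimulationConfig(
        group_profiles={
            "cont": presets["null"],
            "AAF": presets["gthc_like"],
            "CRE": presets["ngthc_like"],
        },
        n_per_group=n_per_group,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Reference panel simulation
# ---------------------------------------------------------------------------

#: Default class-mean 12-gene ratio vectors (Table-1 gene order).  The
#: genotoxic class up-regulates the p53-response markers and slightly
#: down-regulates Lrp1, placing its fixed score near -6; the other classes
#: stay near 0 and score above the -0.710 border.
DEFAULT_CLASS_MEANS: dict[str, dict[str, float]] = {
    "GTHC": {
        "Aen": 2.5, "Bax": 2.0, "Btg2": 2.5, "Ccnf": 0.0, "Ccng1": 2.0,
        "Cdkn1a": 1.2, "Gdf15": 3.0, "Lrp1": -0.3, "Mbd1": 1.5,
        "Phlda3": 2.5, "Plk2": 1.0, "Tubb4b": 1.5,
    },
    "NGTHC": {g: (1.0 if g == "Gdf15" else 0.0) for g in MARKER_GENES},
    "NGTNHC": {g: 0.0 for g in MARKER_GENES},
}

DEFAULT_CLASS_POINTS = {"GTHC": 10, "NGTHC": 14, "NGTNHC": 22}
DEFAULT_CLASS_SD = 0.35


@dataclass
class PanelSimulationConfig:
    """Configuration of the reference-panel simulator."""

    n_points: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_POINTS))
    class_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLASS_MEANS.items()})
    class_cov: Mapping[str, np.ndarray] | None = None  # default: DEFAULT_CLASS_SD^2 * I
    timepoints: tuple[str, ...] = ("24h", "29d")
    seed: int = 0
    panel: GenePanel = DEFAULT_PANEL

    def __post_init__(self) -> None:
        for cls, n in self.n_points.items():
            if n < 1:
                raise DataValidationError(f"n_points for {cls!r} must be >= 1")
            if cls not in self.class_means:
                raise DataValidationError(f"no class mean for {cls!r}")

    def covariance(self, cls: str) -> np.ndarray:
        p = len(self.panel.marker_genes)
        if self.class_cov is None or cls not in self.class_cov:
            return (DEFAULT_CLASS_SD ** 2) * np.eye(p)
        cov = np.asarray(self.class_cov[cls], dtype=float)
        if cov.ndim == 1:
            cov = np.diag(cov)
        return cov


def simulate_reference_panel(cfg: PanelSimulationConfig) -> ReferencePanel:
    """Draw a labeled reference panel from per-class multivariate normals.

    Each class contributes ``n_points`` chemicals at every timepoint; the
    row's ratio vector is one multivariate-normal draw around the class mean.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = list(cfg.panel.marker_genes)
    records = []
    for cls in sorted(cfg.n_points):
        mean = np.array([cfg.class_means[cls][g] for g in genes], dtype=float)
        cov = cfg.covariance(cls)
        try:
            chol = np.linalg.cholesky(cov) if cov.any() else np.zeros_like(cov)
        except np.linalg.LinAlgError:
            raise DataValidationError(
                f"covariance for class {cls!r} is not positive definite"
            ) from None
        for i in range(cfg.n_points[cls]):
            chem = f"{cls}{i + 1:02d}"
            for tp in cfg.timepoints:
                z = rng.standard_normal(len(genes))
                values = mean + chol @ z
                records.append({
                    "point_id": f"{chem}-{tp}", "chemical": chem,
                    "dose": "M", "time": tp, "class": cls,
                    **{g: v for g, v in zip(genes, values)},
                })
    df = pd.DataFrame.from_records(records).set_index("point_id")
    panel = ReferencePanel(data=df, marker_genes=cfg.panel.marker_genes)
    logger.info("simulated reference panel: %d points (seed=%d)", len(panel), cfg.seed)
    return panel


def truth_labels(panel: ReferencePanel) -> pd.Series:
    """Binary ground truth for classification checks: GTHC vs everything else."""
    return panel.classes.map(
        lambda c: "GTHC-like" if c == "GTHC" else "non-GTHC-like")
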