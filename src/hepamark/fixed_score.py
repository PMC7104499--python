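"""Portable approximate-PC1 scoring from fixed per-gene constants.

The score of a 12-gene log2 ratio profile chi is

    Y1 = sum_g a_g * (chi_g - mu_g) / sigma_g

with the published coefficient/mean/SD triples embedded verbatim
(3 significant figures, provenance "paper-2020") and a decision border of
-0.710: scores strictly below it are called genotoxic-like.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataValidationError, NumericError
from .normalization import Log2RatioProfile, RatioMatrix, condition_profile
from .table_io import MARKER_GENES

POSITIVE_CALL = "GTHC-like"
NEGATIVE_CALL = "non-GTHC-like"

PAPER_PROVENANCE = "paper-2020"

# Published (a, mu, sigma) per gene, Table-1 order.  Stored verbatim; never
# re-derived.  The Ccnf and Lrp1 means are negative (printed as "+" offsets).
_PAPER_TRIPLES: tuple[tuple[str, float, float, float], ...] = (
    ("Aen",    -0.327,  0.316,  0.952),
    ("Bax",    -0.336,  0.320,  0.790),
    ("Btg2",   -0.324,  0.264,  0.945),
    ("Ccnf",    0.076, -0.0767, 0.413),
    ("Ccng1",  -0.344,  0.563,  1.16),
    ("Cdkn1a", -0.312,  0.405,  1.35),
    ("Gdf15",  -0.312,  0.354,  1.10),
    ("Lrp1",    0.263, -0.094,  0.338),
    ("Mbd1",   -0.207,  0.0309, 0.344),
    ("Phlda3", -0.306,  0.211,  1.12),
    ("Plk2",   -0.313,  0.172,  0.602),
    ("Tubb4b", -0.243,  0.276,  0.431),
)

PAPER_BORDER = -0.710


@dataclass(frozen=True)
class FixedScoreConstants:
    """Per-gene (a, mu, sigma) triples plus the PC1 decision border."""

    genes: tuple[str, ...]
    a: tuple[float, ...]
    mu: tuple[float, ...]
    sigma: tuple[float, ...]
    border: float
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        n = len(self.genes)
        if n != 12:
            raise DataValidationError(f"expected 12 gene triples, got {n}")
        if not (len(self.a) == len(self.mu) == len(self.sigma) == n):
            raise DataValidationError("a/mu/sigma length mismatch")
        if any(s <= 0 for s in self.sigma):
            raise DataValidationError("all sigma must be > 0")
        norm = float(np.sum(np.square(self.a)))
        if abs(norm - 1.0) > 1e-2:
            raise DataValidationError(
                f"loading vector norm^2 = {norm:.4f} is not ~1"
            )

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"a": self.a, "mu": self.mu, "sigma": self.sigma},
            index=list(self.genes),
        )

    def triple(self, gene: str) -> tuple[float, float, float]:
        i = self.genes.index(gene)
        return self.a[i], self.mu[i], self.sigma[i]


def default_constants() -> FixedScoreConstants:
    """The published constants, verbatim."""
    genes, a, mu, sigma = zip(*_PAPER_TRIPLES)
    return FixedScoreConstants(
        genes=genes, a=a, mu=mu, sigma=sigma,
        border=PAPER_BORDER, provenance=PAPER_PROVENANCE,
    )


def approximate_pc1(profile: Log2RatioProfile, c: FixedScoreConstants) -> float:
    """Evaluate Y1 for one profile; term order fixed to the constants' order."""
    missing = [g for g in c.genes if g not in profile.values.index]
    if missing:
        raise DataValidationError(
            f"profile {profile.label!r} missing gene(s): {missing}"
        )
    chi = profile.values.loc[list(c.genes)].to_numpy(dtype=float)
    if not np.isfinite(chi).all():
        raise NumericError(f"non-finite ratio in profile {profile.label!r}")
    a = np.asarray(c.a)
    mu = np.asarray(c.mu)
    sigma = np.asarray(c.sigma)
    return float(np.sum(a * (chi - mu) / sigma))


def classify_fixed(y1: float, c: FixedScoreConstants) -> str:
    """Strictly below the border -> genotoxic-like; at or above -> not."""
    if not np.isfinite(y1):
        raise NumericError("score is not finite")
    return POSITIVE_CALL if y1 < c.border else NEGATIVE_CALL


def score_batch(
    profiles: list[Log2RatioProfile], c: FixedScoreConstants,
) -> pd.DataFrame:
    """Score many profiles; one row (id, Y1, call) per profile, input order."""
    records = []
    for p in profiles:
        y1 = approximate_pc1(p, c)
        records.append({"id": p.label, "Y1": y1, "call": classify_fixed(y1, c)})
    return pd.DataFrame.from_records(
        records, columns=["id", "Y1", "call"]).set_index("id")


def score_ratio_matrix(
    r: RatioMatrix, c: FixedScoreConstants, per_sample: bool = True,
) -> pd.DataFrame:
    """Score every sample (or every group mean) of a ratio matrix."""
    if per_sample:
        profiles = [Log2RatioProfile(values=r.values.loc[s], label=str(s))
                    for s in r.values.index]
    else:
        profiles = [condition_profile(r, g)
                    for g in dict.fromkeys(r.groups) if g != r.control_label]
    return score_batch(profiles, c)


# ---------------------------------------------------------------------------
# Constants file: "symbol<TAB>a<TAB>mu<TAB>sigma" lines + "border<TAB>value".
# repr() floats give a bit-exact round trip.
# ---------------------------------------------------------------------------

def write_constants(c: FixedScoreConstants, path: str | Path) -> None:
    lines = [f"# provenance\t{c.provenance}"]
    for g, a, mu, sigma in zip(c.genes, c.a, c.mu, c.sigma):
        lines.append(f"{g}\t{a!r}\t{mu!r}\t{sigma!r}")
    lines.append(f"border\t{c.border!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_constants(path: str | Path) -> FixedScoreConstants:
    genes, a, mu, sigma = [], [], [], []
    border = None
    provenance = "file"
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].strip().split("\t")
            if len(parts) == 2 and parts[0] == "provenance":
                provenance = parts[1]
            continue
        parts = line.split("\t")
        if parts[0] == "border":
            border = float(parts[1])
            continue
        if len(parts) != 4:
            raise DataValidationError(f"bad constants line: {line!r}")
        genes.append(parts[0])
        a.append(float(parts[1]))
        mu.append(float(parts[2]))
        sigma.append(float(parts[3]))
    if border is None:
        raise DataValidationError("constants file has no border line")
    return FixedScoreConstants(
        genes=tuple(genes), a=tuple(a), mu=tuple(mu), sigma=tuple(sigma),
        border=border, provenance=provenance,
    )
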