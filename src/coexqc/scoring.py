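"""Combining the eight quality measures into one Quality score.

Across a *collection* of networks, the eight measures are standardized to
mean 0 / sd 1 and the first principal component of their correlation
matrix is taken as the common quality axis; it is sign-oriented so that
higher means better (positive correlation with the mean of the eight
measures) and min-max rescaled to [0, 1] over the collection:
Quality 0 is the worst network of the collection, 1 the best.

Quality is therefore collection-relative.  Scoring a network outside the
collection is possible by projecting its standardized measures onto the
stored loadings and clamping to [0, 1]; the clamping is an extension of
the scheme, flagged in the docs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .enrichment import MEASURE_COLUMNS, QualityMeasures

__all__ = ["QualityScoreTable", "combine_quality"]


@dataclass
class QualityScoreTable:
    """Per-network PC1 coordinates and Quality, plus the PCA itself."""

    table: pd.DataFrame            # input columns + "pc1" + "quality"
    loadings: pd.Series            # PC1 loadings per measure
    variance_fractions: np.ndarray  # fraction of variance per PC
    column_means: pd.Series
    column_sds: pd.Series
    pc1_min: float
    pc1_max: float

    @property
    def pc1_variance_fraction(self) -> float:
        return float(self.variance_fractions[0])

    def project(self, measures: pd.DataFrame, clamp: bool = True) -> pd.Series:
        """Quality of networks outside the fitted collection.

        Standardizes with the stored means/sds, projects on the stored
        loadings, rescales with the stored min/max and (by default)
        clamps into [0, 1].
        """
        z = (measures[list(self.loadings.index)] - self.column_means) / self.column_sds
        pc1 = z.to_numpy() @ self.loadings.to_numpy()
        q = (pc1 - self.pc1_min) / (self.pc1_max - self.pc1_min)
        if clamp:
            q = np.clip(q, 0.0, 1.0)
        return pd.Series(q, index=measures.index, name="quality")

    def write_loadings_json(self, path: str | Path) -> None:
        payload = {
            "loadings": self.loadings.to_dict(),
            "variance_fractions": [float(v) for v in self.variance_fractions],
            "column_means": self.column_means.to_dict(),
            "column_sds": self.column_sds.to_dict(),
            "pc1_min": self.pc1_min,
            "pc1_max": self.pc1_max,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _as_frame(measures) -> pd.DataFrame:
    if isinstance(measures, pd.DataFrame):
        return measures
    rows = []
    for m in measures:
        rows.append(m.to_row() if isinstance(m, QualityMeasures) else dict(m))
    return pd.DataFrame(rows)


def combine_quality(measures, columns: list[str] | None = None) -> QualityScoreTable:
    """PCA-derived scalar Quality for a collection of networks.

    Parameters
    ----------
    measures
        DataFrame with the eight measure columns (extra columns are kept
        as metadata), or a list of :class:`QualityMeasures` / dicts.
    columns
        Measure columns to combine; defaults to the canonical eight.

    Raises
    ------
    ValueError
        With fewer than 3 networks, or when a measure column is constant
        (its standardization is undefined; the offending measure is
        named).
    """
    frame = _as_frame(measures)
    columns = list(columns) if columns is not None else list(MEASURE_COLUMNS)
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValueError(f"missing measure columns: {missing}")
    if len(frame) < 3:
        raise ValueError("need at least 3 networks for a quality collection")
    x = frame[columns].to_numpy(dtype=float)
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    constant = [c for c, s in zip(columns, sds) if s == 0]
    if constant:
        raise ValueError(f"constant measure columns: {constant}")
    z = (x - means) / sds

    corr = np.corrcoef(z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    variance_fractions = eigvals / eigvals.sum()

    v1 = eigvecs[:, 0]
    pc1 = z @ v1
    mean_measure = z.mean(axis=1)
    orient = np.corrcoef(pc1, mean_measure)[0, 1] if mean_measure.std() > 0 else v1.sum()
    if orient < 0:
        v1 = -v1
        pc1 = -pc1

    lo, hi = float(pc1.min()), float(pc1.max())
    if hi == lo:
        raise ValueError("degenerate collection: all networks have identical PC1")
    quality = (pc1 - lo) / (hi - lo)

    table = frame.copy()
    table["pc1"] = pc1
    table["quality"] = quality
    return QualityScoreTable(
        table=table,
        loadings=pd.Series(v1, index=columns, name="pc1_loading"),
        variance_fractions=variance_fractions,
        column_means=pd.Series(means, index=columns),
        column_sds=pd.Series(sds, index=columns),
        pc1_min=lo,
        pc1_max=hi,
    )
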