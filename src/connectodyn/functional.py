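"""Functional connectome construction from ROI time series.

Each subject's resting-state signal matrix (regions x volumes) is reduced to
a symmetric z-score connectivity matrix: pairwise Pearson correlation between
region time courses, variance-stabilized with Fisher's r-to-z transform
(atanh).  Correlations are clipped to +/-(1 - 1e-7) before the transform so
duplicated series produce a large finite z rather than infinity.

An optional nuisance-regression hook residualizes each region series against
a confound table (e.g. realignment motion parameters) before correlation;
with synthetic inputs it is usually unused but preserves the stage real
pipelines need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RoiTimeSeries",
    "ConnectivityMatrix",
    "fisher_z",
    "correlation_matrix",
    "regress_confounds",
    "R_CLIP",
]

R_CLIP = 1.0 - 1e-7


@dataclass
class RoiTimeSeries:
    """One subject's region-by-time signal matrix."""

    subject_id: str
    data: np.ndarray
    region_labels: list[str]
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (regions x time)")
        n_regions, n_time = self.data.shape
        if n_regions < 2:
            raise ValueError("need at least 2 regions")
        if n_time < 16:
            raise ValueError("need at least 16 time points")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contain non-finite values")
        if len(self.region_labels) != n_regions:
            raise ValueError("one label per region required")
        if len(set(self.region_labels)) != n_regions:
            raise ValueError("region labels must be unique")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric association weights between nodes, zero diagonal."""

    subject_id: str
    weights: np.ndarray
    modality: str
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if np.abs(w - w.T).max() > 1e-10:
            raise ValueError("weights must be symmetric to 1e-10")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        self.weights = w
        if self.modality not in ("functional", "structural"):
            raise ValueError("modality must be 'functional' or 'structural'")
        if not self.node_labels:
            self.node_labels = [str(i) for i in range(w.shape[0])]

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def fisher_z(r):
    """Fisher r-to-z transform, atanh(r).  Odd; defined for |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| must be < 1 for the Fisher transform")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def regress_confounds(ts: RoiTimeSeries, confounds: pd.DataFrame) -> RoiTimeSeries:
    """Residualize every region series against confound columns (plus intercept)."""
    if len(confounds) != ts.n_volumes:
        raise ValueError("confound table must have one row per volume")
    x = np.column_stack([np.ones(ts.n_volumes), confounds.to_numpy(dtype=float)])
    beta, *_ = np.linalg.lstsq(x, ts.data.T, rcond=None)
    resid = ts.data.T - x @ beta
    return RoiTimeSeries(
        subject_id=ts.subject_id,
        data=resid.T,
        region_labels=list(ts.region_labels),
        tr_seconds=ts.tr_seconds,
    )


def correlation_matrix(
    ts: RoiTimeSeries, confounds: pd.DataFrame | None = None
) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of region time courses, Fisher-transformed.

    Correlations are clipped to ``+/-(1 - 1e-7)`` before atanh, so a duplicated
    pair of series saturates at z ~ 8.41 instead of diverging.  A constant
    region series is an error (its correlation is undefined).
    """
    if confounds is not None:
        ts = regress_confounds(ts, confounds)
    sd = ts.data.std(axis=1)
    if np.any(sd == 0):
        bad = [ts.region_labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant time series for region(s): {', '.join(bad)}")
    r = np.corrcoef(ts.data)
    r = np.clip(r, -R_CLIP, R_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return ConnectivityMatrix(
        subject_id=ts.subject_id,
        weights=z,
        modality="functional",
        node_labels=list(ts.region_labels),
    )
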