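"""Localization error metrics, error-map interpolation, and summaries.

Position errors are Euclidean distances reported in millimeters; orientation
errors are plain angles between the true and fitted moment vectors (0-180
degrees, no axis folding).  Per-facet error maps over a cortical surface are
inverse-distance-weighted means of the per-dipole errors within an
interpolation radius R.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import TriMesh

__all__ = ["position_error", "orientation_error", "rdm", "relative_l2",
           "interpolate_error_map", "summarize_errors", "ErrorMap"]


def position_error(p0, p1) -> float:
    """Euclidean distance between two positions (input m, output mm)."""
    return float(np.linalg.norm(np.asarray(p0, dtype=float)
                                - np.asarray(p1, dtype=float))) * 1e3


def orientation_error(q0, q1) -> float:
    """Angle between two moment vectors, degrees in [0, 180]."""
    q0 = np.asarray(q0, dtype=float)
    q1 = np.asarray(q1, dtype=float)
    n0, n1 = np.linalg.norm(q0), np.linalg.norm(q1)
    if n0 == 0 or n1 == 0:
        raise ZeroDivisionError("orientation error undefined for zero vectors")
    return float(np.degrees(np.arccos(np.clip(q0 @ q1 / (n0 * n1), -1.0, 1.0))))


def _average_reference(v):
    v = np.asarray(v, dtype=float)
    return v - v.mean()


def rdm(v1, v2) -> float:
    """Relative difference measure between two voltage vectors: the 2-norm of
    the difference of the average-referenced, unit-normalized vectors.  Zero
    for identical shapes regardless of scale."""
    a = _average_reference(v1)
    b = _average_reference(v2)
    return float(np.linalg.norm(a / np.linalg.norm(a) - b / np.linalg.norm(b)))


def relative_l2(v, v_ref) -> float:
    """||v - v_ref|| / ||v_ref|| on average-referenced vectors."""
    a = _average_reference(v)
    b = _average_reference(v_ref)
    return float(np.linalg.norm(a - b) / np.linalg.norm(b))


@dataclasses.dataclass
class ErrorMap:
    """Per-facet interpolated error with coverage diagnostics."""

    values: np.ndarray        # mm; nan where no source within radius
    n_contributing: np.ndarray
    radius: float

    @property
    def missing(self) -> np.ndarray:
        return self.n_contributing == 0


def interpolate_error_map(surface: TriMesh, sources, errors,
                          radius: float = 0.02) -> ErrorMap:
    """Inverse-distance-weighted error at every facet center:

        value(r) = sum_i eps_i / |r - s_i|  /  sum_i 1 / |r - s_i|

    over the sources s_i within ``radius`` of r.  A facet center coinciding
    with a source takes that source's error exactly (the limit value);
    facets with no source in range are flagged missing (nan).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    sources = np.atleast_2d(np.asarray(sources, dtype=float))
    errors = np.asarray(errors, dtype=float)
    if len(sources) == 0:
        raise ValueError("at least one source required")
    if len(errors) != len(sources):
        raise ValueError("one error value per source required")
    tree = cKDTree(sources)
    centers = surface.centers
    values = np.full(surface.n_faces, np.nan)
    counts = np.zeros(surface.n_faces, dtype=np.int64)
    neighbors = tree.query_ball_point(centers, r=radius)
    for m, idx in enumerate(neighbors):
        if not idx:
            continue
        d = np.linalg.norm(sources[idx] - centers[m], axis=1)
        counts[m] = len(idx)
        exact = d == 0.0
        if np.any(exact):
            values[m] = errors[np.asarray(idx)[exact][0]]
            continue
        w = 1.0 / d
        values[m] = (w @ errors[idx]) / w.sum()
    return ErrorMap(values, counts, float(radius))


def summarize_errors(results: pd.DataFrame, group_by=None,
                     value: str = "position_error_mm",
                     bin_width: float = 1.0):
    """Study-style summary of fit errors.

    ``results``: DataFrame with at least the ``value`` column (and optional
    grouping columns such as dipole label, model, or conductivity set).
    Returns (summary DataFrame with mean/std/count per group, histogram)
    where histogram is (counts, bin_edges) at the requested bin width.
    """
    if len(results) == 0:
        raise ValueError("at least one result required")
    if group_by:
        summary = (results.groupby(group_by)[value]
                   .agg(mean="mean", std="std", count="count")
                   .reset_index())
    else:
        summary = pd.DataFrame({
            "mean": [results[value].mean()],
            "std": [results[value].std()],
            "count": [len(results)],
        })
    summary["std"] = summary["std"].fillna(0.0)
    vals = results[value].to_numpy(dtype=float)
    top = max(vals.max(), bin_width)
    edges = np.arange(0.0, top + bin_width, bin_width)
    if edges[-1] <= vals.max():
        edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(vals, bins=edges)
    return summary, (counts, edges)
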