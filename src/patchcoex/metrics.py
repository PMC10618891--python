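"""Boundary-complexity metrics for patch outlines.

Two complementary metrics:

* m1 — macro-scale complexity: how much longer the patch perimeter P is
  than the perimeter of the circle with the same area A (the isoperimetric
  deficit). Reported both raw, ``m1_raw = P - 2*sqrt(pi*A)`` (length
  units), and normalized, ``m1_norm = P / (2*sqrt(pi*A)) - 1``
  (dimensionless, scale-invariant). High values indicate lobes, peninsulas
  and inlets.

* m2 — micro-scale complexity: the compressibility of the boundary's
  turning-angle sequence. The outline is resampled at equal arclength, the
  signed exterior angles are quantized into uniform bins, and the symbol
  sequence is DEFLATE-compressed; m2 is compressed length / sequence
  length. Smooth boundaries compress to almost nothing; jagged boundaries
  approach incompressibility. (This operationalizes a Kolmogorov-style
  complexity, which is itself uncomputable.)
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedCorrelationError
from .geometry import PatchOutline, polygon_measures

__all__ = [
    "ComplexityScores",
    "metric_m1",
    "turning_angles",
    "metric_m2",
    "compute_scores",
    "metrics_table",
    "pearson_r",
]


@dataclass(frozen=True)
class ComplexityScores:
    label: str
    area: float
    perimeter: float
    m1_raw: float
    m1_norm: float
    m2: float
    n_samples: int = 512
    n_bins: int = 64


def metric_m1(outline: PatchOutline) -> tuple[float, float]:
    """Isoperimetric deficit of the outline: (m1_raw, m1_norm)."""
    area, perimeter = polygon_measures(outline)
    circle_perimeter = 2.0 * np.sqrt(np.pi * area)
    return perimeter - circle_perimeter, perimeter / circle_perimeter - 1.0


def _as_vertices(outline) -> np.ndarray:
    """Vertex array of an outline, rolled to a canonical start vertex
    (lowest y, then lowest x) so results do not depend on which vertex the
    digitization happened to list first. Raw (N, 2) arrays pass through
    unrolled and are traversed exactly as given."""
    if isinstance(outline, PatchOutline):
        v = outline.vertices
        start = np.lexsort((v[:, 0], v[:, 1]))[0]
        return np.roll(v, -start, axis=0)
    return np.asarray(outline, dtype=float)


def _resample_boundary(v: np.ndarray, n_samples: int) -> np.ndarray:
    """Points at n_samples equal arclength stations, starting at vertex 0."""
    closed = np.vstack([v, v[0]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    stations = np.linspace(0.0, s[-1], n_samples, endpoint=False)
    x = np.interp(stations, s, closed[:, 0])
    y = np.interp(stations, s, closed[:, 1])
    return np.column_stack([x, y])


def turning_angles(outline, n_samples: int = 512) -> np.ndarray:
    """Signed exterior angles along the equal-arclength resampled boundary.

    Returns ``n_samples`` angles in (-pi, pi]; for a simple
    counter-clockwise outline they sum to 2*pi (total-turning theorem).
    Accepts a PatchOutline (counter-clockwise by construction, resampled
    from a canonical start vertex) or a raw (N, 2) vertex array traversed
    as given — mirroring an array and keeping its vertex order negates
    every angle.
    """
    if n_samples < 3:
        raise ValueError("n_samples must be >= 3")
    pts = _resample_boundary(_as_vertices(outline), n_samples)
    edges = np.roll(pts, -1, axis=0) - pts
    a, b = edges, np.roll(edges, -1, axis=0)
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    dot = (a * b).sum(axis=1)
    return np.arctan2(cross, dot)


def metric_m2(outline: PatchOutline, n_samples: int = 512, n_bins: int = 64) -> float:
    """Compression-based small-scale complexity of the boundary."""
    if not 2 <= n_bins <= 256:
        raise ValueError("n_bins must be in [2, 256]")
    angles = turning_angles(outline, n_samples)
    # uniform bins over (-pi, pi]
    idx = np.floor((angles + np.pi) / (2 * np.pi) * n_bins).astype(np.int64)
    idx = np.clip(idx, 0, n_bins - 1)
    raw = idx.astype(np.uint8).tobytes()
    return len(zlib.compress(raw, 9)) / len(raw)


def compute_scores(outline: PatchOutline, n_samples: int = 512,
                   n_bins: int = 64) -> ComplexityScores:
    area, perimeter = polygon_measures(outline)
    m1_raw, m1_norm = metric_m1(outline)
    return ComplexityScores(
        label=outline.label, area=area, perimeter=perimeter,
        m1_raw=m1_raw, m1_norm=m1_norm,
        m2=metric_m2(outline, n_samples, n_bins),
        n_samples=n_samples, n_bins=n_bins,
    )


def metrics_table(outlines, n_samples: int = 512, n_bins: int = 64) -> pd.DataFrame:
    """Per-outline metric table (label, area, perimeter, m1_raw, m1_norm, m2)."""
    rows = [compute_scores(o, n_samples, n_bins).__dict__ for o in outlines]
    return pd.DataFrame(rows).drop(columns=["n_samples", "n_bins"])


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation; errors on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length with at least 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)
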