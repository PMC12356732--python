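"""Trace-based laminar cortical thickness from a slice image plus boundary contours.

The procedure mirrors the classical intensity-profile approach to laminar
analysis of ultra-high-resolution slices: lines ("traces") are drawn from
every point on the superficial (gray matter-CSF) boundary to its nearest
point on the deep (gray matter-white matter) boundary and vice versa; image
intensity is sampled along each trace at fixed normalized depths; the mean
profile over traces is summarized by an ordinary least-squares quartic in
normalized depth; and the two interior inflection points of that quartic
delimit the middle laminar compartment.  Total thickness is the mean
Euclidean trace length converted to millimetres, and the superficial /
middle / deep compartment thicknesses are the corresponding depth fractions
of the total.

Depth convention: 0 at the gray-CSF border, 1 at the gray-white border.
Coordinates are pixel-centered and 0-based; a point (x, y) addresses column
x, row y of the raster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

from .errors import BoundsError, GeometryError, NoAdmissibleSplitError

__all__ = [
    "BoundaryPair",
    "Trace",
    "DepthProfile",
    "LaminarThickness",
    "build_traces",
    "sample_trace",
    "mean_profile",
    "fit_quartic",
    "inflections",
    "total_ct",
    "laminar_split",
    "subject_laminar_ct",
]

#: |c4| below this value means the quartic's second derivative is effectively
#: linear and cannot have two interior roots.
C4_DEGENERACY_TOL = 1e-12

DEFAULT_N_SAMPLES = 101


@dataclass(frozen=True)
class BoundaryPair:
    """Ordered superficial and deep boundary contours for one slice.

    Points are (x, y) pixel coordinates, sub-pixel allowed, pixel-centered
    and 0-based.
    """

    superficial: np.ndarray  # (Ns, 2)
    deep: np.ndarray         # (Nd, 2)
    pixel_mm: float

    def __post_init__(self):
        sup = np.atleast_2d(np.asarray(self.superficial, dtype=float))
        deep = np.atleast_2d(np.asarray(self.deep, dtype=float))
        object.__setattr__(self, "superficial", sup)
        object.__setattr__(self, "deep", deep)
        if sup.shape[0] < 1 or deep.shape[0] < 1:
            raise GeometryError("each contour needs at least one point")
        if sup.shape[1] != 2 or deep.shape[1] != 2:
            raise GeometryError("contour points must be (x, y) pairs")
        if not (self.pixel_mm > 0):
            raise GeometryError(f"pixel_mm must be positive, got {self.pixel_mm}")


@dataclass
class Trace:
    """One line across the cortical ribbon.

    ``start`` lies on the contour the trace originated from; ``direction``
    records which boundary that was.  ``intensities``, when set, are samples
    at equally spaced normalized depths with depth 0 at the superficial end
    regardless of direction.
    """

    start: np.ndarray
    end: np.ndarray
    direction: Literal["sup2deep", "deep2sup"]
    length_px: float
    intensities: Optional[np.ndarray] = None

    def length_mm(self, pixel_mm: float) -> float:
        return self.length_px * pixel_mm


@dataclass
class DepthProfile:
    """Mean intensity as a function of normalized cortical depth."""

    depths: np.ndarray
    mean_intensity: np.ndarray
    coeffs: Optional[np.ndarray] = None   # c0..c4, ascending powers
    rss: Optional[float] = None
    inflection_depths: Optional[tuple] = None

    def __post_init__(self):
        d = np.asarray(self.depths, dtype=float)
        if d.ndim != 1 or not np.all(np.diff(d) > 0):
            raise ValueError("depths must be a strictly increasing 1-D grid")
        self.depths = d
        self.mean_intensity = np.asarray(self.mean_intensity, dtype=float)


@dataclass(frozen=True)
class LaminarThickness:
    """Total and per-compartment thickness (mm) for one subject/region."""

    total_mm: float
    superficial_mm: float
    middle_mm: float
    deep_mm: float

    @property
    def fractions(self) -> tuple:
        return (
            self.superficial_mm / self.total_mm,
            self.middle_mm / self.total_mm,
            self.deep_mm / self.total_mm,
        )


def build_traces(
    boundaries: BoundaryPair,
    pairing_rule: Literal["nearest", "all_pairs"] = "nearest",
) -> list:
    """Construct traces from each boundary point to the opposite contour.

    With the default ``nearest`` rule every superficial point is paired with
    its nearest deep point and every deep point with its nearest superficial
    point; an ``all_pairs`` rule (every superficial point to every deep
    point) is kept as a non-default option but yields oblique, non-local
    traces on curved ribbons.  Traces whose unordered endpoint pair repeats
    are collapsed to a single trace.
    """
    sup, deep = boundaries.superficial, boundaries.deep
    pairs = []
    if pairing_rule == "nearest":
        deep_tree = cKDTree(deep)
        sup_tree = cKDTree(sup)
        _, j = deep_tree.query(sup)
        for i in range(len(sup)):
            pairs.append((sup[i], deep[j[i]], "sup2deep"))
        _, i2 = sup_tree.query(deep)
        for j2 in range(len(deep)):
            pairs.append((deep[j2], sup[i2[j2]], "deep2sup"))
    elif pairing_rule == "all_pairs":
        for i in range(len(sup)):
            for j in range(len(deep)):
                pairs.append((sup[i], deep[j], "sup2deep"))
        for j in range(len(deep)):
            for i in range(len(sup)):
                pairs.append((deep[j], sup[i], "deep2sup"))
    else:
        raise ValueError(f"unknown pairing rule {pairing_rule!r}")

    traces, seen = [], set()
    for start, end, direction in pairs:
        length = float(np.hypot(*(end - start)))
        if length <= 0:
            raise GeometryError(
                f"zero-length trace at {tuple(start)}: contours touch or coincide"
            )
        key = frozenset((tuple(np.round(start, 9)), tuple(np.round(end, 9))))
        if key in seen:
            continue
        seen.add(key)
        traces.append(Trace(start=start.copy(), end=end.copy(),
                            direction=direction, length_px=length))
    return traces


def sample_trace(image, trace: Trace, n_samples: int = DEFAULT_N_SAMPLES) -> Trace:
    """Sample image intensity along a trace at equally spaced normalized depths.

    Bilinear interpolation on the pixel-centered grid.  Samples are stored
    superficial-first: a deep-to-superficial trace is depth-reversed before
    storage so that depth 0 always refers to the gray-CSF border.
    """
    raster = np.asarray(image.raster, dtype=float)
    h, w = raster.shape
    for p in (trace.start, trace.end):
        if not (0 <= p[0] <= w - 1 and 0 <= p[1] <= h - 1):
            raise BoundsError(f"trace endpoint {tuple(p)} outside raster {w}x{h}")
    t = np.linspace(0.0, 1.0, n_samples)
    xs = trace.start[0] + t * (trace.end[0] - trace.start[0])
    ys = trace.start[1] + t * (trace.end[1] - trace.start[1])
    vals = map_coordinates(raster, np.vstack([ys, xs]), order=1, mode="nearest")
    if trace.direction == "deep2sup":
        vals = vals[::-1]
    trace.intensities = vals
    return trace


def mean_profile(traces: Sequence[Trace]) -> DepthProfile:
    """Pointwise mean over traces on the shared normalized-depth grid."""
    if len(traces) == 0:
        raise ValueError("mean_profile requires at least one trace")
    stacks = [t.intensities for t in traces]
    if any(s is None for s in stacks):
        raise ValueError("all traces must be sampled before averaging")
    n = len(stacks[0])
    if any(len(s) != n for s in stacks):
        raise ValueError("traces are not on a common sample grid")
    mean = np.mean(np.vstack(stacks), axis=0)
    return DepthProfile(depths=np.linspace(0.0, 1.0, n), mean_intensity=mean)


def fit_quartic(profile: DepthProfile) -> DepthProfile:
    """Ordinary least-squares polynomial of degree exactly 4 in normalized depth.

    Returns the same profile with ``coeffs`` (c0..c4, ascending) and the
    residual sum of squares filled in.
    """
    if len(profile.depths) < 5:
        raise np.linalg.LinAlgError(
            f"quartic fit needs >= 5 depth points, got {len(profile.depths)}"
        )
    coeffs = npoly.polyfit(profile.depths, profile.mean_intensity, 4)
    fitted = npoly.polyval(profile.depths, coeffs)
    profile.coeffs = coeffs
    profile.rss = float(np.sum((profile.mean_intensity - fitted) ** 2))
    return profile


def inflections(coeffs: Sequence[float]) -> tuple:
    """Interior inflection depths of a fitted quartic.

    Solves p''(x) = 12 c4 x^2 + 6 c3 x + 2 c2 = 0 and returns the two real
    roots, ordered, iff both lie strictly in (0, 1).  Anything else — complex
    roots, a root on or outside the depth interval, or |c4| so small that the
    second derivative degenerates to a linear function — raises
    :class:`NoAdmissibleSplitError` carrying the root diagnostics.
    """
    c = np.asarray(coeffs, dtype=float)
    if len(c) != 5:
        raise ValueError("expected 5 quartic coefficients c0..c4")
    if abs(c[4]) < C4_DEGENERACY_TOL:
        raise NoAdmissibleSplitError(
            f"second derivative degenerates to linear (|c4|={abs(c[4]):.3e})",
            coeffs=c,
        )
    roots = np.roots([12.0 * c[4], 6.0 * c[3], 2.0 * c[2]])
    if np.iscomplexobj(roots) and np.any(np.abs(roots.imag) > 0):
        raise NoAdmissibleSplitError(
            f"inflection equation has complex roots {roots}", roots=roots, coeffs=c
        )
    real = np.sort(roots.real)
    interior = real[(real > 0.0) & (real < 1.0)]
    if len(interior) != 2 or interior[0] == interior[1]:
        raise NoAdmissibleSplitError(
            f"no admissible laminar split: roots {real} not two distinct "
            "interior depths",
            roots=real,
            coeffs=c,
        )
    return float(interior[0]), float(interior[1])


def total_ct(boundaries: BoundaryPair,
             pairing_rule: str = "nearest",
             traces: Optional[Sequence[Trace]] = None) -> float:
    """Total regional cortical thickness: mean trace length times pixel size."""
    if traces is None:
        traces = build_traces(boundaries, pairing_rule)
    lengths = np.array([t.length_px for t in traces])
    return float(lengths.mean() * boundaries.pixel_mm)


def laminar_split(total_mm: float, d1: float, d2: float) -> LaminarThickness:
    """Partition total thickness at inflection depths d1 < d2.

    superficial = d1 * total, middle = (d2 - d1) * total, deep = (1 - d2) * total;
    the three parts sum to the total exactly by construction.
    """
    if not (0.0 < d1 < d2 < 1.0):
        raise ValueError(
            f"inflection depths must satisfy 0 < d1 < d2 < 1, got ({d1}, {d2})"
        )
    sup = d1 * total_mm
    mid = (d2 - d1) * total_mm
    deep = (1.0 - d2) * total_mm
    # reported total is the float sum of the parts, so the partition
    # identity holds exactly (the sum differs from total_mm by <= 1 ulp)
    return LaminarThickness(total_mm=sup + mid + deep, superficial_mm=sup,
                            middle_mm=mid, deep_mm=deep)


def _in_mask(points: np.ndarray, roi_mask) -> np.ndarray:
    """Boolean selector for boundary points inside an ROI.

    ``roi_mask`` may be a callable points -> bool array, or an axis-aligned
    bounding box (xmin, ymin, xmax, ymax) in pixel coordinates.
    """
    if callable(roi_mask):
        return np.asarray(roi_mask(points), dtype=bool)
    xmin, ymin, xmax, ymax = roi_mask
    return ((points[:, 0] >= xmin) & (points[:, 0] <= xmax)
            & (points[:, 1] >= ymin) & (points[:, 1] <= ymax))


def subject_laminar_ct(
    slices: Sequence[tuple],
    roi_mask=None,
    pairing_rule: str = "nearest",
    n_samples: int = DEFAULT_N_SAMPLES,
):
    """Pool traces across slices and derive one laminar thickness for a subject.

    Parameters
    ----------
    slices
        Sequence of ``(image, boundaries)`` pairs; each image exposes a
        2-D ``raster`` and each boundaries is a :class:`BoundaryPair`.
    roi_mask
        Optional region restriction applied to boundary points before
        tracing (callable or bounding box, see :func:`_in_mask`).

    Returns
    -------
    (LaminarThickness, DepthProfile)
        The subject-level thickness decomposition and the pooled profile
        with quartic coefficients and inflection depths attached.
    """
    if len(slices) == 0:
        raise ValueError("need at least one slice")
    pooled, lengths_mm = [], []
    for image, boundaries in slices:
        if roi_mask is not None:
            sup = boundaries.superficial[_in_mask(boundaries.superficial, roi_mask)]
            deep = boundaries.deep[_in_mask(boundaries.deep, roi_mask)]
            if len(sup) == 0 or len(deep) == 0:
                raise GeometryError("ROI mask excludes all boundary points")
            boundaries = BoundaryPair(sup, deep, boundaries.pixel_mm)
        traces = build_traces(boundaries, pairing_rule)
        for t in traces:
            sample_trace(image, t, n_samples)
            lengths_mm.append(t.length_px * boundaries.pixel_mm)
        pooled.extend(traces)
    profile = fit_quartic(mean_profile(pooled))
    d1, d2 = inflections(profile.coeffs)
    profile.inflection_depths = (d1, d2)
    total = float(np.mean(lengths_mm))
    return laminar_split(total, d1, d2), profile
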