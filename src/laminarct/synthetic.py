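"""Synthetic cortical-ribbon phantoms and cohorts.

Two generators make every downstream stage testable without any real data:

* :func:`generate_ribbon` renders a 2-D slice through a curved cortical
  ribbon with three laminar gray-matter compartments between CSF and white
  matter, on the 0.1875 mm reconstruction grid typical of ultra-high
  resolution susceptibility-weighted acquisitions.  Expected intensity along
  any line perpendicular to the ribbon midline is a piecewise-plateau
  profile with logistic partial-volume transitions centered at the layer
  boundary depth fractions; i.i.d. Gaussian noise is added on top.  Ground
  truth (boundary contours and layer fractions) is stored with the image.

* :func:`generate_cohort` draws a two-group cohort in which three ability
  composites (face, car, novel-object recognition) and a regional thickness
  have a specified Pearson correlation structure per group — e.g. a
  typically-developing-like group where face ability correlates negatively
  and car ability positively with thickness while novel-object ability is
  uncorrelated, against a group with attenuated structure.

All randomness flows through one ``numpy`` Generator per call, seeded
explicitly; identical spec + seed reproduces outputs bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import expit

from .errors import GeometryError, SpecError
from .laminar import BoundaryPair

__all__ = [
    "RibbonSpec",
    "RibbonImage",
    "CohortSpec",
    "generate_ribbon",
    "generate_cohort",
    "generate_behavior_table",
    "DEFAULT_TD_TARGETS",
    "DEFAULT_AUT_TARGETS",
]

# Default transition widths (depth-fraction units) for the four interfaces
# CSF|superficial, superficial|middle, middle|deep, deep|WM.  The widths are
# calibrated through the full rendered pipeline (pixel grid + bilinear trace
# sampling, which add blur of their own) so that, at the default geometry
# and contrast, the inflection points of the fitted quartic fall on the
# internal layer boundaries — making the quartic-inflection estimator
# unbiased on its reference phantom.
DEFAULT_TRANSITION_WIDTHS = (0.019, 0.033, 0.021, 0.024)


@dataclass(frozen=True)
class RibbonSpec:
    """Geometry, contrast and noise of a synthetic cortical ribbon slice.

    ``layer_fractions`` are the depth fractions (f_sup, f_mid) of the
    superficial and middle compartments; the two internal boundaries sit at
    normalized depths f_sup and f_sup + f_mid.  ``intensities`` are the mean
    gray values of the three laminar compartments, with ``i_csf`` above the
    superficial border and ``i_wm`` below the deep border.  The default
    contrast is a monotone ladder (CSF brightest, WM darkest) with a
    distinct plateau per compartment.
    """

    length_mm: float = 12.0
    thickness_mm: float = 2.4375
    layer_fractions: Tuple[float, float] = (1.0 / 3.0, 1.0 / 3.0)
    intensities: Tuple[float, float, float] = (120.0, 80.0, 40.0)
    i_csf: float = 200.0
    i_wm: float = 0.0
    transition_width = None  # set in __post_init__; scalar or 4-tuple
    noise_sd: float = 0.0
    pixel_mm: float = 0.1875
    curvature: float = 0.0
    margin_mm: float = 1.5
    seed: int = 0

    def __init__(self, length_mm=12.0, thickness_mm=2.4375,
                 layer_fractions=(1.0 / 3.0, 1.0 / 3.0),
                 intensities=(120.0, 80.0, 40.0), i_csf=200.0, i_wm=0.0,
                 transition_width=DEFAULT_TRANSITION_WIDTHS,
                 noise_sd=0.0, pixel_mm=0.1875, curvature=0.0,
                 margin_mm=1.5, seed=0):
        object.__setattr__(self, "length_mm", float(length_mm))
        object.__setattr__(self, "thickness_mm", float(thickness_mm))
        object.__setattr__(self, "layer_fractions", tuple(map(float, layer_fractions)))
        object.__setattr__(self, "intensities", tuple(map(float, intensities)))
        object.__setattr__(self, "i_csf", float(i_csf))
        object.__setattr__(self, "i_wm", float(i_wm))
        tw = ((float(transition_width),) * 4 if np.isscalar(transition_width)
              else tuple(map(float, transition_width)))
        if len(tw) != 4 or any(w <= 0 for w in tw):
            raise SpecError("transition_width must be a positive scalar or 4-tuple")
        object.__setattr__(self, "transition_width", tw)
        object.__setattr__(self, "noise_sd", float(noise_sd))
        object.__setattr__(self, "pixel_mm", float(pixel_mm))
        object.__setattr__(self, "curvature", float(curvature))
        object.__setattr__(self, "margin_mm", float(margin_mm))
        object.__setattr__(self, "seed", int(seed))
        f1, f2 = self.layer_fractions
        if not (0.0 < f1 and 0.0 < f2 and f1 + f2 < 1.0):
            raise SpecError(f"layer_fractions {self.layer_fractions} must be "
                            "strictly inside (0,1) with f_sup + f_mid < 1")
        if self.thickness_mm <= 0:
            raise SpecError("thickness_mm must be positive")
        if self.pixel_mm <= 0:
            raise SpecError("pixel_mm must be positive")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be non-negative")

    @property
    def boundary_fractions(self) -> Tuple[float, float]:
        """Normalized depths of the two internal laminar boundaries."""
        return (self.layer_fractions[0],
                self.layer_fractions[0] + self.layer_fractions[1])


@dataclass
class RibbonImage:
    """A 2-D intensity raster with pixel size and optional ground truth."""

    raster: np.ndarray
    pixel_mm: float
    truth: Optional[dict] = None   # {"boundaries": BoundaryPair, "f_sup", "f_mid"}

    def __post_init__(self):
        self.raster = np.asarray(self.raster, dtype=float)
        if not np.all(np.isfinite(self.raster)):
            raise ValueError("raster contains non-finite values")


def expected_depth_profile(spec: RibbonSpec, depths: np.ndarray) -> np.ndarray:
    """Noise-free expected intensity at normalized depths (0 = CSF border)."""
    f1, f2 = spec.boundary_fractions
    i_sup, i_mid, i_deep = spec.intensities
    w0, w1, w2, w3 = spec.transition_width
    u = np.asarray(depths, dtype=float)
    return (spec.i_csf
            + (i_sup - spec.i_csf) * expit(u / w0)
            + (i_mid - i_sup) * expit((u - f1) / w1)
            + (i_deep - i_mid) * expit((u - f2) / w2)
            + (spec.i_wm - i_deep) * expit((u - 1.0) / w3))


def generate_ribbon(spec: RibbonSpec) -> RibbonImage:
    """Render the ribbon phantom and its ground-truth boundary contours.

    The ribbon midline runs horizontally across the raster with an optional
    single-period sinusoidal bend of amplitude ``spec.curvature`` (mm).
    Each pixel's normalized depth is computed from its signed perpendicular
    distance to the midline (nearest-point lookup on a finely resampled
    midline), so the expected intensity profile along any perpendicular
    line is exactly :func:`expected_depth_profile`.  Ground-truth contours
    are the midline offset by half the thickness along the local normal.
    """
    px = spec.pixel_mm
    half_t = spec.thickness_mm / 2.0
    height_mm = spec.thickness_mm + 2.0 * spec.margin_mm + 2.0 * abs(spec.curvature)
    n_cols = int(round(spec.length_mm / px))
    n_rows = int(round(height_mm / px))
    if spec.thickness_mm >= height_mm or n_rows < 3 or n_cols < 2:
        raise GeometryError("ribbon does not fit in the raster")

    y_center = height_mm / 2.0

    def midline(x_mm):
        return y_center + spec.curvature * np.sin(2.0 * np.pi * x_mm / spec.length_mm)

    def midline_slope(x_mm):
        return (spec.curvature * 2.0 * np.pi / spec.length_mm
                * np.cos(2.0 * np.pi * x_mm / spec.length_mm))

    # fine midline polyline for nearest-point depth lookup
    x_fine = np.arange(-spec.thickness_mm, spec.length_mm + spec.thickness_mm,
                       px / 4.0)
    pts_fine = np.column_stack([x_fine, midline(x_fine)])
    slopes = midline_slope(x_fine)
    norms = np.sqrt(1.0 + slopes ** 2)
    # unit normal pointing toward increasing y (deep side)
    normals = np.column_stack([-slopes / norms, 1.0 / norms])

    tree = cKDTree(pts_fine)
    xx, yy = np.meshgrid(np.arange(n_cols) * px, np.arange(n_rows) * px)
    pix = np.column_stack([xx.ravel(), yy.ravel()])
    _, idx = tree.query(pix)
    signed = np.einsum("ij,ij->i", pix - pts_fine[idx], normals[idx])
    depth = (signed + half_t) / spec.thickness_mm  # 0 at superficial border

    raster = expected_depth_profile(spec, depth).reshape(n_rows, n_cols)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        raster = raster + rng.normal(0.0, spec.noise_sd, raster.shape)

    # ground-truth contours: one point per column of the ribbon interior
    x_c = np.arange(n_cols) * px
    keep = (x_c >= 0) & (x_c <= spec.length_mm)
    x_c = x_c[keep]
    sl = midline_slope(x_c)
    nrm = np.sqrt(1.0 + sl ** 2)
    nx, ny = -sl / nrm, 1.0 / nrm
    mid_y = midline(x_c)
    sup = np.column_stack([(x_c - half_t * nx) / px, (mid_y - half_t * ny) / px])
    deep = np.column_stack([(x_c + half_t * nx) / px, (mid_y + half_t * ny) / px])
    # clip contour points to raster bounds (curvature can push ends outside)
    inside = lambda c: ((c[:, 0] >= 0) & (c[:, 0] <= n_cols - 1)
                        & (c[:, 1] >= 0) & (c[:, 1] <= n_rows - 1))
    ok = inside(sup) & inside(deep)
    boundaries = BoundaryPair(sup[ok], deep[ok], pixel_mm=px)
    f1, f2 = spec.layer_fractions
    return RibbonImage(raster=raster, pixel_mm=px,
                       truth={"boundaries": boundaries, "f_sup": f1, "f_mid": f2,
                              "spec": spec})


# ---------------------------------------------------------------------------
# cohorts

#: Per-group target Pearson correlations of (face, car, novel) with thickness.
DEFAULT_TD_TARGETS = (-0.55, 0.45, 0.0)
DEFAULT_AUT_TARGETS = (-0.05, 0.05, 0.0)


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort with specified ability-thickness correlations.

    ``corr_targets`` maps group label to the target correlations of the
    (face, car, novel) ability composites with regional thickness;
    ``cross_corrs`` are the correlations among the three abilities
    (face-car, face-novel, car-novel), zero by default since the opposite
    correlations are treated as statistically independent effects.
    """

    n_per_group: Tuple[int, int] = (17, 16)
    corr_targets: dict = field(default_factory=lambda: {
        "TD": DEFAULT_TD_TARGETS, "AUT": DEFAULT_AUT_TARGETS})
    cross_corrs: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    ct_mean_mm: dict = field(default_factory=lambda: {"TD": 2.2, "AUT": 2.7})
    ct_sd_mm: dict = field(default_factory=lambda: {"TD": 0.25, "AUT": 0.2})
    seed: int = 0

    def __post_init__(self):
        if min(self.n_per_group) < 4:
            raise SpecError("n_per_group must be >= 4 per group "
                            "(the Fisher transform needs n - 3 > 0)")
        for group in self.corr_targets:
            self.correlation_matrix(group)  # raises if not PSD

    @property
    def groups(self) -> tuple:
        return tuple(self.corr_targets.keys())

    def correlation_matrix(self, group: str) -> np.ndarray:
        """4x4 correlation matrix over (face, car, novel, thickness)."""
        rf, rc, rn = self.corr_targets[group]
        fc, fn, cn = self.cross_corrs
        m = np.array([
            [1.0, fc, fn, rf],
            [fc, 1.0, cn, rc],
            [fn, cn, 1.0, rn],
            [rf, rc, rn, 1.0],
        ])
        eig = np.linalg.eigvalsh(m)
        if eig.min() < -1e-10:
            raise SpecError(
                f"correlation targets for group {group!r} give a non-PSD "
                f"matrix over (face, car, novel, thickness); eigenvalues {eig}"
            )
        return m


def _mvn_unit(rng: np.random.Generator, corr: np.ndarray, n: int) -> np.ndarray:
    """Standard-normal margins with given correlation, via eigen factor."""
    vals, vecs = np.linalg.eigh(corr)
    factor = vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))
    return rng.standard_normal((n, corr.shape[0])) @ factor.T


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw the cohort table: one row per subject.

    Columns: ``subject_id``, ``group``, ``face_agg``, ``car_agg``,
    ``novel_agg`` (unit-normal ability composites) and ``ct_mm`` (thickness
    rescaled to the per-group mean/SD).  Semantics match the real-data
    reader's merged table so the statistics layer is agnostic to the source.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    for group, n in zip(spec.groups, spec.n_per_group):
        z = _mvn_unit(rng, spec.correlation_matrix(group), n)
        ct = spec.ct_mean_mm[group] + spec.ct_sd_mm[group] * z[:, 3]
        frames.append(pd.DataFrame({
            "group": group,
            "face_agg": z[:, 0],
            "car_agg": z[:, 1],
            "novel_agg": z[:, 2],
            "ct_mm": ct,
        }))
    table = pd.concat(frames, ignore_index=True)
    table.insert(0, "subject_id", [f"S{i:03d}" for i in range(len(table))])
    return table


# default raw-score generation: each ability is measured by one memory and
# one matching task sharing `reliability` of their variance with the latent
_TASK_SCALE = {  # (mean accuracy, accuracy SD) for the five accuracy tasks
    "cfmt_acc": (0.75, 0.10), "vfmt_acc": (0.65, 0.10),
    "ccmt_acc": (0.72, 0.10), "vcmt_acc": (0.64, 0.10),
    "nomt_acc": (0.80, 0.08),
}


def generate_behavior_table(
    n_per_group: Tuple[int, int] = (17, 16),
    group_shift: dict = None,
    reliability: float = 0.7,
    nomat_trials: int = 48,
    seed: int = 0,
):
    """Simulate raw task scores from latent face/car/novel abilities.

    Each of the six tasks loads on its category's latent ability with
    ``sqrt(reliability)``; accuracy tasks are affinely scaled and clipped to
    [0, 1], and the novel-object matching task is scored as same/different
    counts drawn from hit and false-alarm rates implied by a latent d'.
    ``group_shift`` maps group label to additive shifts of the three latent
    abilities (e.g. a face-recognition deficit in one group).

    Returns ``(table, latents)``: the raw-score table consumed by the
    behavior module, and the generating latent abilities for validation.
    """
    if group_shift is None:
        group_shift = {"TD": (0.0, 0.0, 0.0), "AUT": (-0.9, 0.0, 0.0)}
    rng = np.random.default_rng(seed)
    lam = np.sqrt(reliability)
    eps = np.sqrt(1.0 - reliability)
    rows, lat_rows = [], []
    for group, n in zip(group_shift.keys(), n_per_group):
        shift = np.asarray(group_shift[group], dtype=float)
        latent = rng.standard_normal((n, 3)) + shift  # face, car, novel
        for i in range(n):
            face, car, novel = latent[i]
            row = {"group": group}
            for col, latent_val in (("cfmt_acc", face), ("vfmt_acc", face),
                                    ("ccmt_acc", car), ("vcmt_acc", car),
                                    ("nomt_acc", novel)):
                mu, sd = _TASK_SCALE[col]
                score = mu + sd * (lam * latent_val + eps * rng.standard_normal())
                row[col] = float(np.clip(score, 0.0, 1.0))
            # latent d' around 1.5, scaled by novel ability
            dprime_true = 1.5 + 0.5 * (lam * novel + eps * rng.standard_normal())
            from scipy.stats import norm
            hr = norm.cdf(dprime_true / 2.0)
            far = norm.cdf(-dprime_true / 2.0)
            n_same = nomat_trials // 2
            n_diff = nomat_trials - n_same
            row["nomat_hits"] = int(rng.binomial(n_same, hr))
            row["nomat_fas"] = int(rng.binomial(n_diff, far))
            row["nomat_n_same"] = n_same
            row["nomat_n_diff"] = n_diff
            rows.append(row)
            lat_rows.append({"group": group, "face": face, "car": car,
                             "novel": novel})
    return pd.DataFrame(rows), pd.DataFrame(lat_rows)
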