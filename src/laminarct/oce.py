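"""The opposite correlation effect (OCE) and its comparisons.

The OCE summarizes a crossover pattern in brain-behavior correlations: face
recognition ability correlating negatively, and car recognition ability
positively, with the thickness of a face-selective cortical region.  The
primary reading multiplies face ability by -1, sums it with car ability,
and correlates the composite with thickness; when the two opposite
correlations are strong and independent, the composite correlation exceeds
either alone, which is where the approach gains statistical power.  A
secondary reading — the raw difference of the two correlations — is
computed alongside.

Group differences in the OCE are tested on the Fisher r-to-z scale with
standard error sqrt(1/(n1-3) + 1/(n2-3)); regional differences within a
group use Williams' test for dependent correlations sharing one variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "OCEResult",
    "OCEComparison",
    "composite",
    "oce",
    "oce_difference",
    "compare_oce_groups",
    "partial_oce",
    "williams_dependent",
    "variance_compare",
]


@dataclass(frozen=True)
class OCEResult:
    group: str
    r: float
    n: int
    p: float
    measure: str = "total"


@dataclass(frozen=True)
class OCEComparison:
    """Normal deviate for a between-group OCE difference in Fisher-z space.

    ``order`` documents the direction of the difference (group2 - group1).
    """
    z: float
    p: float
    order: str


def composite(face_agg, car_agg) -> np.ndarray:
    """Opposite-correlation composite: car ability minus face ability."""
    return np.asarray(car_agg, dtype=float) - np.asarray(face_agg, dtype=float)


def oce(composite_scores, thickness, group: str = "", measure: str = "total") -> OCEResult:
    """Pearson correlation of the composite with thickness.

    Two-tailed p from the t distribution with n - 2 degrees of freedom.
    """
    x = np.asarray(composite_scores, dtype=float)
    y = np.asarray(thickness, dtype=float)
    if len(x) < 4:
        raise ValueError("OCE needs at least 4 subjects")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in composite or thickness")
    r, p = stats.pearsonr(x, y)
    return OCEResult(group=group, r=float(r), n=len(x), p=float(p),
                     measure=measure)


def oce_difference(face_agg, car_agg, thickness) -> float:
    """Secondary OCE reading: corr(car, CT) minus corr(face, CT)."""
    r_car = stats.pearsonr(np.asarray(car_agg, float),
                           np.asarray(thickness, float))[0]
    r_face = stats.pearsonr(np.asarray(face_agg, float),
                            np.asarray(thickness, float))[0]
    return float(r_car - r_face)


def compare_oce_groups(r1: float, n1: int, r2: float, n2: int,
                       order: str = "group2-group1") -> OCEComparison:
    """Fisher r-to-z test for a difference between two independent correlations.

    z = (atanh(r2) - atanh(r1)) / sqrt(1/(n1-3) + 1/(n2-3)), two-tailed p
    from the standard normal.
    """
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1.0:
            raise ValueError("|r| must be < 1 for the Fisher transform")
        if n < 4:
            raise ValueError("each group needs n >= 4 (n - 3 > 0)")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (np.arctanh(r2) - np.arctanh(r1)) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return OCEComparison(z=float(z), p=float(p), order=order)


def partial_oce(composite_scores, thickness, novel_agg):
    """First-order partial correlation of composite and thickness given novel ability.

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)); two-tailed
    p from the t distribution with n - 3 degrees of freedom.
    """
    x = np.asarray(composite_scores, float)
    y = np.asarray(thickness, float)
    z = np.asarray(novel_agg, float)
    n = len(x)
    if n < 5:
        raise ValueError("partial correlation needs at least 5 subjects")
    r_xy = stats.pearsonr(x, y)[0]
    r_xz = stats.pearsonr(x, z)[0]
    r_yz = stats.pearsonr(y, z)[0]
    denom = (1.0 - r_xz ** 2) * (1.0 - r_yz ** 2)
    if denom <= 1e-12:
        raise ValueError("control variable collinear with composite or thickness")
    r = (r_xy - r_xz * r_yz) / np.sqrt(denom)
    df = n - 3
    t = r * np.sqrt(df / (1.0 - r ** 2)) if abs(r) < 1 else np.inf
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(r), float(p)


def williams_dependent(r_jk: float, r_jh: float, r_kh: float, n: int):
    """Williams' test for two dependent correlations sharing variable j.

    Tests r_jk against r_jh when both are measured on the same n subjects and
    the third correlation r_kh links the two non-shared variables.
    Returns (t, p) with df = n - 3, two-tailed.
    """
    if n < 5:
        raise ValueError("Williams' test needs n >= 5")
    m = np.array([[1.0, r_jk, r_jh],
                  [r_jk, 1.0, r_kh],
                  [r_jh, r_kh, 1.0]])
    det = np.linalg.det(m)
    if np.linalg.eigvalsh(m).min() < -1e-10:
        raise ValueError("correlation triple does not form a PSD matrix")
    rbar = (r_jk + r_jh) / 2.0
    num = (r_jk - r_jh) * np.sqrt((n - 1) * (1.0 + r_kh))
    den = np.sqrt(2.0 * det * (n - 1) / (n - 3)
                  + rbar ** 2 * (1.0 - r_kh) ** 3)
    t = num / den
    p = 2.0 * stats.t.sf(abs(t), n - 3)
    return float(t), float(p)


def variance_compare(values_a, values_b, center: str = "median"):
    """Levene-type test for unequal spread between two groups.

    Brown-Forsythe by default (absolute deviations from the group median).
    Returns (F, p, eta_squared) where eta^2 is the between-group share of
    the ANOVA decomposition on the deviation scores.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 values")
    f, p = stats.levene(a, b, center=center)
    df_between, df_within = 1, len(a) + len(b) - 2
    eta2 = (df_between * f) / (df_between * f + df_within)
    return float(f), float(p), float(eta2)
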