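"""Per-feature distance functions.

Distribution-valued features (density profile, Voronoi volumes, surface
deformation) are compared with the 1-Wasserstein (earth mover's) distance;
the gaslike feature point with the Euclidean distance; the scalar surface
area with the squared error. Empirical-sample Wasserstein distances use the
binning-free quantile formulation, which equals the optimal-transport cost
for scalar supports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import wasserstein_distance

from .features import FeatureSet, GaslikeFeaturePoint

FEATURE_IDS = ("density", "gaslike", "voronoi", "area", "deformation")

#: Sentinel distance for surface features when either side was cut.
MISSING = None


@dataclass
class FeatureDistance:
    feature_id: str
    value: float

    def __post_init__(self) -> None:
        if self.feature_id not in FEATURE_IDS:
            raise ValueError(f"unknown feature_id {self.feature_id!r}")
        if self.value < 0:
            raise ValueError("distances are non-negative")


def wasserstein1_samples(a: Sequence[float], b: Sequence[float]) -> float:
    """1-Wasserstein distance between two empirical sample distributions.

    Computed by the order-statistic/quantile formulation (no binning), which
    handles unequal sample sizes exactly.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    return float(wasserstein_distance(a, b))


def wasserstein1_discrete(
    support_a: Sequence[float],
    mass_a: Sequence[float],
    support_b: Sequence[float],
    mass_b: Sequence[float],
) -> float:
    """1-Wasserstein distance between two discrete distributions.

    Equals the integral of |CDF_a − CDF_b| over the real line. Masses must
    each sum to 1 (tolerance 1e-9).
    """
    mass_a = np.asarray(mass_a, dtype=float)
    mass_b = np.asarray(mass_b, dtype=float)
    if np.any(mass_a < 0) or np.any(mass_b < 0):
        raise ValueError("masses must be non-negative")
    for m in (mass_a, mass_b):
        if abs(m.sum() - 1.0) > 1e-9:
            raise ValueError(f"masses must sum to 1 (got {m.sum()!r})")
    return float(
        wasserstein_distance(
            np.asarray(support_a, dtype=float),
            np.asarray(support_b, dtype=float),
            u_weights=mass_a,
            v_weights=mass_b,
        )
    )


def euclidean2(p: GaslikeFeaturePoint, q: GaslikeFeaturePoint) -> float:
    """Euclidean distance between two gaslike feature points."""
    return float(np.hypot(p.p_x - q.p_x, p.p_y - q.p_y))


def squared_error(a: float, b: float) -> float:
    """Squared difference between two scalars (the two-value MSE)."""
    return float((a - b) ** 2)


def _check_compatible(fs_i: FeatureSet, fs_j: FeatureSet) -> None:
    if (
        fs_i.config_hash is not None
        and fs_j.config_hash is not None
        and fs_i.config_hash != fs_j.config_hash
    ):
        raise ValueError("feature sets were extracted under different configs")
    if not np.isclose(fs_i.density.shell_thickness, fs_j.density.shell_thickness):
        raise ValueError("density profiles use different shell thicknesses")


def feature_distance(fs_i: FeatureSet, fs_j: FeatureSet, feature_id: str) -> Optional[FeatureDistance]:
    """Dispatch the appropriate metric for one feature.

    Returns ``None`` (MISSING) for the surface features when either side
    was cut.
    """
    _check_compatible(fs_i, fs_j)
    if feature_id == "density":
        value = wasserstein1_discrete(
            fs_i.density.midpoints,
            fs_i.density.fractions,
            fs_j.density.midpoints,
            fs_j.density.fractions,
        )
    elif feature_id == "gaslike":
        value = euclidean2(fs_i.gaslike_point, fs_j.gaslike_point)
    elif feature_id == "voronoi":
        value = wasserstein1_samples(fs_i.voronoi.volumes, fs_j.voronoi.volumes)
    elif feature_id == "area":
        if fs_i.surface_missing or fs_j.surface_missing:
            return MISSING
        value = squared_error(fs_i.surface_area, fs_j.surface_area)
    elif feature_id == "deformation":
        if fs_i.surface_missing or fs_j.surface_missing:
            return MISSING
        value = wasserstein1_samples(
            fs_i.deformation.scalar_products, fs_j.deformation.scalar_products
        )
    else:
        raise ValueError(f"unknown feature_id {feature_id!r}")
    return FeatureDistance(feature_id=feature_id, value=value)
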