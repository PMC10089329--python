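"""Validation transformations and the transformation-study harness.

A useful spheroid distance must be invariant under changes of the frame of
reference (rotation, translation) and monotone in genuine shape changes.
The transformations here produce controlled families of point clouds from a
reference spheroid: rigid rotation and translation, uniform positional
noise, a radial surface ripple, and a radial rescaling. The harness applies
a transformation at increasing strength and reports, per strength, the
standardized per-feature distances and the overall deviation score between
reference and transformed cloud under a frozen calibration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .features import PointCloud, centroid, extract_features
from .metrics import FEATURE_IDS, feature_distance
from .scoring import Calibration

TRANSFORM_KINDS = ("rotation", "translation", "noise", "deformation", "scaling")


@dataclass
class TransformSpec:
    """One transformation at one strength.

    ``alpha`` is radians for rotation, μm for noise and deformation
    amplitudes, dimensionless for scaling, and a 3-vector (μm) for
    translation. ``omega`` is the ripple frequency (deformation only),
    ``axis`` the rotation axis, ``r_ref`` the scaling normalization radius
    and ``seed`` the noise seed.
    """

    kind: str
    alpha: object = 0.0
    omega: float = 6.0
    axis: Optional[np.ndarray] = None
    r_ref: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in TRANSFORM_KINDS:
            raise ValueError(f"unknown transformation kind {self.kind!r}")
        if self.kind == "deformation" and self.omega <= 0:
            raise ValueError("omega must be > 0")
        if self.r_ref is not None and self.r_ref <= 0:
            raise ValueError("r_ref must be > 0")


def _rotation_matrix(axis: np.ndarray, alpha: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise ValueError("rotation axis must be non-zero")
    u = axis / n
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + np.sin(alpha) * K + (1 - np.cos(alpha)) * (K @ K)


def rotate(cloud: PointCloud, axis: np.ndarray, alpha: float) -> PointCloud:
    """Rotate all cells by angle alpha about an axis through the centroid."""
    R = _rotation_matrix(axis, alpha)
    c = centroid(cloud)
    return PointCloud(positions=(cloud.positions - c) @ R.T + c, label=cloud.label)


def translate(cloud: PointCloud, vector: Sequence[float]) -> PointCloud:
    """Shift every cell by the same vector."""
    v = np.asarray(vector, dtype=float)
    return PointCloud(positions=cloud.positions + v, label=cloud.label)


def jitter(cloud: PointCloud, alpha: float, seed: int) -> PointCloud:
    """Add α·X to each position, X uniform on [0, 1]³ per cell.

    The noise is uncentered, inducing a mean drift of α/2 per axis; this is
    harmless because every feature is translation invariant.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    rng = np.random.default_rng(seed)
    noise = alpha * rng.uniform(0.0, 1.0, size=cloud.positions.shape)
    return PointCloud(positions=cloud.positions + noise, label=cloud.label)


def ripple_deform(cloud: PointCloud, alpha: float, omega: float = 6.0) -> PointCloud:
    """Displace each cell radially by α(cos ωφ + sin ωθ).

    θ is the polar angle from +z in [0, π] and φ the azimuth in [0, 2π),
    both measured about the centroid; this adds ripples of frequency ω and
    amplitude α to the spheroid surface. Cells at the centroid (undefined
    radial direction) are left unmoved.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if omega <= 0:
        raise ValueError("omega must be > 0")
    c = centroid(cloud)
    rel = cloud.positions - c
    r = np.linalg.norm(rel, axis=1)
    moved = cloud.positions.copy()
    ok = r > 1e-12
    e_r = rel[ok] / r[ok, None]
    theta = np.arccos(np.clip(rel[ok, 2] / r[ok], -1.0, 1.0))
    phi = np.mod(np.arctan2(rel[ok, 1], rel[ok, 0]), 2 * np.pi)
    moved[ok] += alpha * e_r * (np.cos(omega * phi) + np.sin(omega * theta))[:, None]
    return PointCloud(positions=moved, label=cloud.label)


def radial_scale(cloud: PointCloud, alpha: float, r_ref: Optional[float] = None) -> PointCloud:
    """Rescale each cell's centroid distance by α·(r/r_ref).

    In centroid coordinates: P → α·(‖P‖/r_ref)·P, so cells farther from the
    center move proportionally more. ``r_ref`` defaults to the 95th
    percentile of centroid distances, which makes α a dimensionless scale
    factor with neutral point 1 for cells at the reference radius.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    c = centroid(cloud)
    rel = cloud.positions - c
    r = np.linalg.norm(rel, axis=1)
    if r_ref is None:
        r_ref = float(np.percentile(r, 95))
    if r_ref <= 0:
        raise ValueError("r_ref must be > 0")
    return PointCloud(positions=c + alpha * (r / r_ref)[:, None] * rel, label=cloud.label)


def apply_transform(cloud: PointCloud, spec: TransformSpec) -> PointCloud:
    if spec.kind == "rotation":
        axis = spec.axis if spec.axis is not None else np.array([0.0, 0.0, 1.0])
        return rotate(cloud, axis, float(spec.alpha))
    if spec.kind == "translation":
        return translate(cloud, np.asarray(spec.alpha, dtype=float))
    if spec.kind == "noise":
        if spec.seed is None:
            raise ValueError("noise requires a seed")
        return jitter(cloud, float(spec.alpha), spec.seed)
    if spec.kind == "deformation":
        return ripple_deform(cloud, float(spec.alpha), spec.omega)
    if spec.kind == "scaling":
        return radial_scale(cloud, float(spec.alpha), spec.r_ref)
    raise ValueError(spec.kind)  # pragma: no cover


def transformation_study(
    reference: PointCloud,
    spec_grid: Sequence[TransformSpec],
    calibration: Calibration,
    config=None,
) -> pd.DataFrame:
    """Distances between a reference cloud and transformed versions.

    Returns a tidy table with one row per (strength, feature): the raw
    distance ``raw``, the standardized distance ``d_star`` under the frozen
    calibration, plus one row per strength with ``feature == "D"`` carrying
    the overall deviation score (MISSING features dropped from the sum).
    Note the zero-strength row reports the standardized self-distance,
    which equals the calibration shift, not zero.

    For rotations, Voronoi volumes of the transformed cloud are computed in
    the co-rotated frame so the clipping box is rotation covariant.
    """
    ref_features = extract_features(reference, config=config)
    std = calibration.standardization
    lambdas = calibration.weights.lambdas
    rows = []
    for spec in spec_grid:
        transformed = apply_transform(reference, spec)
        frame = None
        if spec.kind == "rotation":
            axis = spec.axis if spec.axis is not None else np.array([0.0, 0.0, 1.0])
            frame = _rotation_matrix(axis, float(spec.alpha))
        feats = extract_features(transformed, config=config, voronoi_frame=frame)
        strength = spec.alpha if np.isscalar(spec.alpha) else float(np.linalg.norm(spec.alpha))
        D = 0.0
        for f, fid in enumerate(FEATURE_IDS):
            fd = feature_distance(ref_features, feats, fid)
            if fd is None:
                rows.append(dict(kind=spec.kind, alpha=strength, feature=fid,
                                 raw=np.nan, d_star=np.nan, missing=True))
                continue
            d_star = (fd.value - std.mu[f]) / std.sigma[f] + std.shift[f]
            D += lambdas[f] * d_star
            rows.append(dict(kind=spec.kind, alpha=strength, feature=fid,
                             raw=fd.value, d_star=d_star, missing=False))
        rows.append(dict(kind=spec.kind, alpha=strength, feature="D",
                         raw=np.nan, d_star=D, missing=False))
    return pd.DataFrame(rows)
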