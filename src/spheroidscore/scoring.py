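"""Standardization, overall deviation score, and weight calibration.

Raw per-feature distances d_{i,j,f} live on wildly different scales (μm,
μm⁴, dimensionless). Over a calibration set of M spheroids they are
standardized per feature — mean subtracted and divided by the population
standard deviation over all M² ordered entries (diagonal included, so M=20
gives the 400 calibration distances per feature) — then shifted so the
minimum is exactly zero:

    d*_{i,j,f} = (d_{i,j,f} − μ_f) / σ_f + |min_f|

The overall deviation score is the weighted sum D_{i,j} = Σ_f λ_f d*_{i,j,f}.
Weights are calibrated by "inverse clustering": maximize the summed
inter-phenotype minus intra-phenotype standardized distances of a labeled
calibration panel, subject to Σ λ_f² = 1 and λ_f ≥ 0. The objective is
linear in λ, so the optimum is the closed form λ = max(c, 0)/‖max(c, 0)‖₂;
the shipped optimizer is numeric (SLSQP) and reproduces it to 1e-6.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .features import FeatureSet
from .metrics import FEATURE_IDS, feature_distance

#: Published default feature weights (density, gaslike, voronoi, area,
#: deformation), calibrated on a panel of four simulated phenotypes.
DEFAULT_WEIGHTS = (0.41, 0.50, 0.43, 0.34, 0.52)


class DegenerateFeatureError(ValueError):
    """Raised when a feature's calibration distances have zero spread."""


class NotSeparableError(ValueError):
    """Raised when no feature has positive inter-minus-intra contrast."""


@dataclass
class DistanceTensor:
    """Raw per-feature distances over all ordered spheroid pairs.

    ``d`` is M×M×F with NaN marking MISSING (cut surface features); the
    diagonal is included and zero for non-missing features.
    """

    spheroid_ids: list[str]
    feature_ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        m = len(self.spheroid_ids)
        if self.d.shape != (m, m, len(self.feature_ids)):
            raise ValueError("tensor shape does not match ids")

    @property
    def n_entries_per_feature(self) -> int:
        return len(self.spheroid_ids) ** 2


@dataclass
class StandardizationParams:
    """Frozen per-feature standardization: μ_f, σ_f and the shift |min|."""

    feature_ids: tuple[str, ...]
    mu: np.ndarray
    sigma: np.ndarray
    shift: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")
        if np.any(self.shift < 0):
            raise ValueError("shift must be non-negative")


@dataclass
class WeightVector:
    """Non-negative feature weights λ_f with Σλ² ≈ 1.

    The unit-norm constraint is enforced to 1e-6 for calibrated outputs;
    construction tolerates 2% slack so the published rounded defaults
    (Σλ² = 0.989) remain usable as shipped.
    """

    feature_ids: tuple[str, ...]
    lambdas: np.ndarray

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if np.any(self.lambdas < 0):
            raise ValueError("weights must be non-negative")
        norm2 = float(np.sum(self.lambdas**2))
        if abs(norm2 - 1.0) > 0.02:
            raise ValueError(f"sum of squared weights must be ~1 (got {norm2})")


@dataclass
class PhenotypeLabels:
    """spheroid_id → phenotype mapping defining the sets P_k."""

    labels: dict[str, str]

    def groups(self, spheroid_ids: Sequence[str]) -> np.ndarray:
        missing = [s for s in spheroid_ids if s not in self.labels]
        if missing:
            raise ValueError(f"unlabeled spheroids: {missing}")
        names = sorted({self.labels[s] for s in spheroid_ids})
        index = {n: i for i, n in enumerate(names)}
        return np.array([index[self.labels[s]] for s in spheroid_ids])


@dataclass
class DeviationMatrix:
    """Overall deviation scores D plus the per-feature decomposition."""

    spheroid_ids: list[str]
    D: np.ndarray  # M×M
    decomposition: np.ndarray  # M×M×F weighted standardized distances
    feature_ids: tuple[str, ...] = FEATURE_IDS
    dropped: Optional[np.ndarray] = None  # M×M×F bool, features cut per pair


@dataclass
class Calibration:
    """Frozen standardization parameters plus the calibrated weights."""

    standardization: StandardizationParams
    weights: WeightVector
    config_hash: Optional[str] = None


# ---------------------------------------------------------------------------
# Pipeline operations
# ---------------------------------------------------------------------------


def distance_tensor(feature_sets: Sequence[FeatureSet], ids: Optional[Sequence[str]] = None) -> DistanceTensor:
    """All M×M ordered per-feature distances (diagonal included)."""
    m = len(feature_sets)
    if m < 2:
        raise ValueError("need at least two feature sets")
    if ids is None:
        ids = [fs.label or f"spheroid_{k}" for k, fs in enumerate(feature_sets)]
    d = np.zeros((m, m, len(FEATURE_IDS)))
    for i in range(m):
        for j in range(i, m):
            for f, fid in enumerate(FEATURE_IDS):
                fd = feature_distance(feature_sets[i], feature_sets[j], fid)
                val = np.nan if fd is None else fd.value
                d[i, j, f] = val
                d[j, i, f] = val
    return DistanceTensor(spheroid_ids=list(ids), feature_ids=FEATURE_IDS, d=d)


def standardize_tensor(tensor: DistanceTensor) -> tuple[StandardizationParams, np.ndarray]:
    """Per-feature standardization over all M² entries, then shift to min 0.

    Uses the population standard deviation; MISSING (NaN) entries are
    excluded from μ, σ and the minimum and stay NaN in the output.
    """
    d = tensor.d
    nf = d.shape[2]
    mu = np.empty(nf)
    sigma = np.empty(nf)
    shift = np.empty(nf)
    d_star = np.empty_like(d)
    for f in range(nf):
        vals = d[:, :, f]
        finite = vals[~np.isnan(vals)]
        if finite.size == 0:
            raise DegenerateFeatureError(f"feature {tensor.feature_ids[f]} entirely missing")
        mu[f] = finite.mean()
        sigma[f] = finite.std()  # population std (ddof=0)
        if sigma[f] <= 0:
            raise DegenerateFeatureError(
                f"feature {tensor.feature_ids[f]} has zero spread across the calibration set"
            )
        std = (vals - mu[f]) / sigma[f]
        shift[f] = abs(np.nanmin(std))
        d_star[:, :, f] = std + shift[f]
    params = StandardizationParams(
        feature_ids=tensor.feature_ids,
        mu=mu,
        sigma=sigma,
        shift=shift,
        provenance=list(tensor.spheroid_ids),
    )
    return params, d_star


def apply_standardization(params: StandardizationParams, tensor: DistanceTensor) -> np.ndarray:
    """Standardize a new tensor with *frozen* calibration parameters.

    No re-estimation: values may fall below zero when a new distance
    undercuts the calibration minimum; this is allowed.
    """
    if tuple(params.feature_ids) != tuple(tensor.feature_ids):
        raise ValueError("feature ids do not match the calibration")
    return (tensor.d - params.mu) / params.sigma + params.shift


def deviation_matrix(
    d_star: np.ndarray,
    weights: WeightVector,
    spheroid_ids: Optional[Sequence[str]] = None,
    missing_policy: str = "drop_feature",
) -> DeviationMatrix:
    """Overall deviation scores D_{i,j} = Σ_f λ_f d*_{i,j,f}.

    ``missing_policy="drop_feature"`` omits MISSING features from the sum
    for affected pairs (recording which were dropped, without weight
    renormalization); ``"error"`` raises instead.
    """
    if missing_policy not in ("error", "drop_feature"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    missing = np.isnan(d_star)
    if missing_policy == "error" and missing.any():
        raise ValueError("MISSING feature distances under policy='error'")
    weighted = d_star * weights.lambdas[None, None, :]
    decomposition = np.where(missing, np.nan, weighted)
    D = np.nansum(decomposition, axis=2)
    m = d_star.shape[0]
    if spheroid_ids is None:
        spheroid_ids = [f"spheroid_{k}" for k in range(m)]
    return DeviationMatrix(
        spheroid_ids=list(spheroid_ids),
        D=D,
        decomposition=decomposition,
        feature_ids=weights.feature_ids,
        dropped=missing,
    )


def contrast_vector(d_star: np.ndarray, labels: PhenotypeLabels, spheroid_ids: Sequence[str]) -> np.ndarray:
    """Per-feature inter-minus-intra contrast c_f over all phenotypes.

    c_f = Σ_k (Σ_{i∈P_k} Σ_{j∉P_k} d* − Σ_{i∈P_k} Σ_{j∈P_k} d*), intra sums
    including the zero diagonal.
    """
    groups = labels.groups(spheroid_ids)
    same = groups[:, None] == groups[None, :]
    c = np.empty(d_star.shape[2])
    for f in range(d_star.shape[2]):
        vals = d_star[:, :, f]
        if np.isnan(vals).any():
            raise ValueError("contrast requires a complete (non-missing) tensor")
        c[f] = vals[~same].sum() - vals[same].sum()
    return c


def optimize_weights(
    d_star: np.ndarray,
    labels: PhenotypeLabels,
    spheroid_ids: Sequence[str],
    tol: float = 1e-9,
) -> WeightVector:
    """Maximize Σ_f λ_f c_f subject to Σ λ_f² = 1, λ_f ≥ 0 (SLSQP).

    Raises :class:`NotSeparableError` when every contrast is non-positive,
    i.e. the labeled phenotypes are not separable by any feature.
    """
    c = contrast_vector(d_star, labels, spheroid_ids)
    return optimize_weights_from_contrast(c, tol=tol)


def optimize_weights_from_contrast(c: np.ndarray, tol: float = 1e-9) -> WeightVector:
    c = np.asarray(c, dtype=float)
    if np.all(c <= 0):
        raise NotSeparableError(
            "all feature contrasts are non-positive; phenotypes are not separable"
        )
    nf = c.size
    x0 = np.full(nf, 1.0 / np.sqrt(nf))
    res = minimize(
        lambda lam: -float(lam @ c),
        x0,
        jac=lambda lam: -c,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * nf,
        constraints=[{"type": "eq", "fun": lambda lam: float(lam @ lam) - 1.0,
                      "jac": lambda lam: 2.0 * lam}],
        options={"ftol": tol, "maxiter": 500},
    )
    if not res.success:
        raise RuntimeError(f"SLSQP failed: {res.message}")
    lam = np.clip(res.x, 0.0, None)
    lam /= np.linalg.norm(lam)
    return WeightVector(feature_ids=FEATURE_IDS, lambdas=lam)


def calibrate(
    feature_sets: Sequence[FeatureSet],
    labels: PhenotypeLabels,
    ids: Optional[Sequence[str]] = None,
) -> Calibration:
    """Full calibration: distance tensor → standardization → weights."""
    tensor = distance_tensor(feature_sets, ids=ids)
    params, d_star = standardize_tensor(tensor)
    weights = optimize_weights(d_star, labels, tensor.spheroid_ids)
    hashes = {fs.config_hash for fs in feature_sets if fs.config_hash is not None}
    if len(hashes) > 1:
        raise ValueError("feature sets were extracted under different configs")
    return Calibration(
        standardization=params,
        weights=weights,
        config_hash=hashes.pop() if hashes else None,
    )


def default_weights() -> WeightVector:
    """The published default weights, usable without recalibration."""
    return WeightVector(feature_ids=FEATURE_IDS, lambdas=np.array(DEFAULT_WEIGHTS))


def score(
    feature_sets: Sequence[FeatureSet],
    calibration: Calibration,
    ids: Optional[Sequence[str]] = None,
    missing_policy: str = "drop_feature",
) -> DeviationMatrix:
    """Deviation matrix of a batch under a frozen calibration."""
    tensor = distance_tensor(feature_sets, ids=ids)
    d_star = apply_standardization(calibration.standardization, tensor)
    return deviation_matrix(
        d_star, calibration.weights, spheroid_ids=tensor.spheroid_ids,
        missing_policy=missing_policy,
    )
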