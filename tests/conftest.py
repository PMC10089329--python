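"""Shared fixtures: synthetic panels, calibration, transformation studies.

The expensive artifacts (4×5 replicate panels at the full 2000-cell scale,
the frozen calibration, the transformation-study tables) are built once per
session and shared across unit and acceptance tests.
"""

import numpy as np
import pytest

import spheroidscore as s
from spheroidscore.transforms import TransformSpec, transformation_study

CAL_SEED = 0
VAL_SEED = 500
REF_SEED = 99


@pytest.fixture(scope="session")
def config():
    return s.RunConfig()


@pytest.fixture(scope="session")
def calibration_panel(config):
    """4 phenotypes × 5 replicates with extracted features (calibration set)."""
    clouds = s.phenotype_panel(base_seed=CAL_SEED)
    fsets = [s.extract_features(c, config=config) for c in clouds]
    ids = [c.label for c in clouds]
    labels = s.PhenotypeLabels({i: i.split("/")[0] for i in ids})
    return clouds, fsets, ids, labels


@pytest.fixture(scope="session")
def calibration_tensor(calibration_panel):
    _, fsets, ids, _ = calibration_panel
    return s.distance_tensor(fsets, ids=ids)


@pytest.fixture(scope="session")
def calibration(calibration_panel):
    _, fsets, ids, labels = calibration_panel
    return s.calibrate(fsets, labels, ids=ids)


@pytest.fixture(scope="session")
def validation_panel(config):
    """An independent 4×5 panel (fresh seeds) for separation checks."""
    clouds = s.phenotype_panel(base_seed=VAL_SEED)
    fsets = [s.extract_features(c, config=config) for c in clouds]
    ids = [c.label for c in clouds]
    labels = s.PhenotypeLabels({i: i.split("/")[0] for i in ids})
    return clouds, fsets, ids, labels


@pytest.fixture(scope="session")
def spherical_reference():
    return s.generate_phenotype(
        s.PhenotypeParams(phenotype_name="spherical", seed=REF_SEED)
    )


@pytest.fixture(scope="session")
def invariance_study(spherical_reference, calibration, config):
    """Rotation + translation grids against the spherical reference."""
    axis = np.array([1.0, 2.0, 2.0]) / 3.0
    grid = [TransformSpec(kind="rotation", alpha=a, axis=axis) for a in (0.5, 1.5, 3.0)]
    grid += [
        TransformSpec(kind="translation", alpha=np.array([37.0, -12.0, 200.0])),
        TransformSpec(kind="translation", alpha=np.array([-150.0, 80.0, 5.0])),
    ]
    return transformation_study(spherical_reference, grid, calibration, config=config)


@pytest.fixture(scope="session")
def monotonicity_studies(spherical_reference, calibration, config):
    """Noise / ripple / scaling strength grids (pre-breakdown)."""
    noise = [TransformSpec(kind="noise", alpha=a, seed=5) for a in (0, 10, 25, 50, 100, 150)]
    ripple = [TransformSpec(kind="deformation", alpha=a) for a in (0, 10, 20, 40, 60, 100)]
    scale = [TransformSpec(kind="scaling", alpha=a) for a in (0.5, 0.75, 0.9, 1.0, 1.1, 1.25, 1.5)]
    return {
        "noise": transformation_study(spherical_reference, noise, calibration, config=config),
        "deformation": transformation_study(spherical_reference, ripple, calibration, config=config),
        "scaling": transformation_study(spherical_reference, scale, calibration, config=config),
    }


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def lp_transport_cost(a, b):
    """Optimal-transport cost between uniform empirical measures, by LP.

    Independent of the quantile formulation used by the implementation:
    solves min Σ γ_ij |a_i − b_j| s.t. row sums 1/na, column sums 1/nb.
    """
    from scipy.optimize import linprog

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    cost = np.abs(np.subtract.outer(a, b)).ravel()
    A_eq = []
    b_eq = []
    for i in range(na):
        row = np.zeros((na, nb))
        row[i, :] = 1.0
        A_eq.append(row.ravel())
        b_eq.append(1.0 / na)
    for j in range(nb):
        col = np.zeros((na, nb))
        col[:, j] = 1.0
        A_eq.append(col.ravel())
        b_eq.append(1.0 / nb)
    res = linprog(cost, A_eq=np.array(A_eq), b_eq=np.array(b_eq), bounds=(0, None), method="highs")
    assert res.success
    return float(res.fun)


def brute_force_gaslike(positions, D_crit, d_crit):
    """O(N²) evaluation of the gaslike definition, no spatial index."""
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    center = positions.mean(axis=0)
    out = np.zeros(n, dtype=bool)
    for i in range(n):
        di = np.linalg.norm(positions[i] - center)
        nn = min(
            np.linalg.norm(positions[i] - positions[j]) for j in range(n) if j != i
        ) if n > 1 else np.inf
        out[i] = (di > D_crit) and (nn > d_crit)
    return out
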