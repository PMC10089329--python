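"""Seeded generative models of the four spheroid phenotypes.

The generator emulates, at the level of cell-center point clouds, the four
morphologies a tumor spheroid develops when invading a collagen matrix:

- ``spherical`` — a dense, smooth ball of cells.
- ``spherical_far_gaslikes`` — a spherical bulk surrounded by a halo of
  detached single cells far from the center.
- ``deformed`` — a spherical bulk with contiguous cell protrusions along
  random radial directions (invasion strands).
- ``disordered`` — cells dispersed through a large volume with mostly
  mutually detached spacing; the spheroid integrity is lost.

All sampling is dart-throwing (rejection) with a minimum-separation
constraint and an explicit seed; the same seed and parameters reproduce the
point cloud bit for bit. Clouds live in an (800 μm)³ system box centered on
the origin, at a scale of roughly 2000 cells in a 120 μm-radius bulk. The
bulk radius is deliberately below the 125 μm detachment threshold so that a
plain spherical cloud contains no gaslike cells by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .features import PointCloud

PHENOTYPES = ("spherical", "spherical_far_gaslikes", "deformed", "disordered")

#: Half-width of the system box (μm); clouds must stay inside ±400 μm.
SYSTEM_HALF_WIDTH = 400.0

_MAX_ATTEMPTS_PER_POINT = 100_000


class PackingError(RuntimeError):
    """Raised when dart throwing cannot place all points at min separation."""


@dataclass
class PhenotypeParams:
    """Generator parameters for one synthetic phenotype.

    Defaults echo the study scale: ~2000 cells, 120 μm bulk radius (inside
    the 125 μm detachment threshold, so spherical bulks carry no gaslikes),
    10 μm minimum cell separation; gaslike halo at 175–350 μm; four
    protrusion chains with 12 μm spacing and 5 μm jitter; disordered cells
    through a 350 μm ball at 25 μm separation (mostly above the 19 μm
    detachment threshold).
    """

    phenotype_name: str = "spherical"
    n_cells: int = 2000
    bulk_radius: float = 120.0
    min_separation: float = 10.0
    n_gaslike: int = 50
    halo_radius_range: tuple[float, float] = (175.0, 350.0)
    n_protrusions: int = 4
    protrusion_length: float = 100.0
    protrusion_spacing: float = 12.0
    protrusion_jitter: float = 5.0
    disorder_radius: float = 350.0
    disorder_separation: float = 25.0
    detachment_threshold: float = 19.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.phenotype_name not in PHENOTYPES:
            raise ValueError(
                f"unknown phenotype {self.phenotype_name!r}; expected one of {PHENOTYPES}"
            )
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.bulk_radius <= 0:
            raise ValueError("bulk_radius must be > 0")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")
        if self.halo_radius_range[0] <= self.bulk_radius:
            raise ValueError("halo must start beyond the bulk radius")
        if self.seed is None:
            raise ValueError("seed is mandatory; no implicit global randomness")


def _dart_throw(
    rng: np.random.Generator,
    n: int,
    min_separation: float,
    propose,
    existing: Optional[np.ndarray] = None,
    context: str = "",
) -> np.ndarray:
    """Place n points by rejection so all pairwise gaps ≥ min_separation.

    ``propose`` draws candidate points; ``existing`` points also repel the
    new ones. Cell-list acceleration keeps this fast at n ≈ 2000.
    """
    accepted: list[np.ndarray] = []
    h = max(min_separation, 1e-9)
    grid: dict[tuple[int, int, int], list[np.ndarray]] = {}

    def cell_of(p: np.ndarray) -> tuple[int, int, int]:
        return tuple(np.floor(p / h).astype(int))

    def ok(p: np.ndarray) -> bool:
        ci, cj, ck = cell_of(p)
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    for q in grid.get((ci + di, cj + dj, ck + dk), ()):
                        d = p - q
                        if d @ d < min_separation**2:
                            return False
        return True

    def insert(p: np.ndarray) -> None:
        grid.setdefault(cell_of(p), []).append(p)

    if existing is not None:
        for q in existing:
            insert(q)

    for _ in range(n):
        for attempt in range(_MAX_ATTEMPTS_PER_POINT):
            p = propose()
            if min_separation == 0 or ok(p):
                accepted.append(p)
                insert(p)
                break
        else:
            raise PackingError(
                f"could not place point {len(accepted) + 1}/{n} at min_separation="
                f"{min_separation} after {_MAX_ATTEMPTS_PER_POINT} attempts {context}"
            )
    return np.array(accepted)


def sample_ball(n: int, radius: float, min_separation: float, seed: int) -> PointCloud:
    """n points uniform in a ball of given radius with minimum separation.

    Dart-throwing rejection sampling; raises :class:`PackingError` with the
    offending parameters when the packing is infeasible within the attempt
    budget.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if radius <= 0:
        raise ValueError("radius must be > 0")
    rng = np.random.default_rng(seed)

    def propose() -> np.ndarray:
        while True:
            p = rng.uniform(-radius, radius, size=3)
            if p @ p <= radius**2:
                return p

    pts = _dart_throw(
        rng, n, min_separation, propose, context=f"(n={n}, radius={radius})"
    )
    return PointCloud(positions=pts, label="ball")


def generate_phenotype(params: PhenotypeParams) -> PointCloud:
    """Generate a synthetic point cloud of the requested phenotype."""
    rng = np.random.default_rng(params.seed)
    name = params.phenotype_name

    if name == "disordered":
        def propose() -> np.ndarray:
            while True:
                p = rng.uniform(-params.disorder_radius, params.disorder_radius, size=3)
                if p @ p <= params.disorder_radius**2:
                    return p

        pts = _dart_throw(
            rng, params.n_cells, params.disorder_separation, propose,
            context="(disordered)",
        )
        return _finish(pts, params)

    if name == "spherical":
        n_bulk = params.n_cells
    elif name == "spherical_far_gaslikes":
        n_bulk = params.n_cells - params.n_gaslike
    else:  # deformed
        n_chain = params.n_protrusions * (
            int(round(params.protrusion_length / params.protrusion_spacing))
        )
        n_bulk = params.n_cells - n_chain
    if n_bulk < 1:
        raise ValueError("n_cells too small for the requested decorations")

    def propose_bulk() -> np.ndarray:
        while True:
            p = rng.uniform(-params.bulk_radius, params.bulk_radius, size=3)
            if p @ p <= params.bulk_radius**2:
                return p

    bulk = _dart_throw(
        rng, n_bulk, params.min_separation, propose_bulk, context="(bulk)"
    )

    if name == "spherical":
        return _finish(bulk, params)

    if name == "spherical_far_gaslikes":
        # Halo cells placed so each is detached: farther than the detachment
        # threshold from every other cell (halo gap enforced with margin).
        gap = max(params.detachment_threshold * 1.3, params.min_separation)
        lo, hi = params.halo_radius_range

        def propose_halo() -> np.ndarray:
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            r = (rng.uniform(lo**3, hi**3)) ** (1.0 / 3.0)
            return r * v

        halo = _dart_throw(
            rng, params.n_gaslike, gap, propose_halo, existing=bulk, context="(halo)"
        )
        return _finish(np.vstack([bulk, halo]), params)

    # deformed: contiguous chains of cells along random radial directions
    chains = []
    n_per_chain = int(round(params.protrusion_length / params.protrusion_spacing))
    for _ in range(params.n_protrusions):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        for k in range(1, n_per_chain + 1):
            base = (params.bulk_radius - params.protrusion_spacing / 2
                    + k * params.protrusion_spacing) * u
            lateral = rng.normal(scale=params.protrusion_jitter / 2, size=3)
            lateral -= (lateral @ u) * u  # jitter perpendicular to the chain
            chains.append(base + lateral)
    return _finish(np.vstack([bulk, np.array(chains)]), params)


def _finish(pts: np.ndarray, params: PhenotypeParams) -> PointCloud:
    # system_box is left unset so the Voronoi step uses the padded tight
    # box: clipping to the full (800 μm)³ volume would hand hull cells
    # enormous regions that drown the volume distribution.
    if np.any(np.abs(pts) > SYSTEM_HALF_WIDTH):
        raise ValueError("generated cloud exceeds the system box")
    return PointCloud(positions=pts, label=params.phenotype_name, system_box=None)


def phenotype_panel(
    phenotypes=PHENOTYPES,
    n_replicates: int = 5,
    base_seed: int = 0,
    **overrides,
) -> list[PointCloud]:
    """A labeled panel of replicate clouds, e.g. the 4×5 calibration set.

    Replicate r of phenotype p gets seed ``base_seed + 1000·p_index + r`` so
    panels with different base seeds are independent.
    """
    clouds = []
    for p_idx, name in enumerate(phenotypes):
        for r in range(n_replicates):
            params = PhenotypeParams(
                phenotype_name=name,
                seed=int(base_seed + 1000 * p_idx + r),
                **overrides,
            )
            cloud = generate_phenotype(params)
            cloud.label = f"{name}/{r}"
            clouds.append(cloud)
    return clouds
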