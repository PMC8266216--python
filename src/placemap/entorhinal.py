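"""Synthetic entorhinal firing fields: grid cells and weakly spatial cells.

Three generators are provided.

* An idealized grid cell built from the sum of three sinusoidal gratings
  whose wavevectors are 60 degrees apart; the field is analytically
  normalized to [0, 1] with peaks exactly one grid spacing apart.
* A realistic grid cell built as a sum of Gaussian-like bumps placed on the
  vertices of a hexagonal lattice, with independently jittered per-vertex
  amplitudes, mimicking the field-to-field variability of recorded cells.
  Populations are drawn from four discrete spacing modules.
* A weakly spatial cell: spatially smoothed uniform noise, carrying spatial
  information without any structured (periodic) selectivity.

All population builders return fields with each column rescaled to a
maximum of exactly 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .environment import Environment

__all__ = [
    "GridParams",
    "ModuleSpec",
    "RealisticFieldParams",
    "EntorhinalPopulation",
    "mathematical_grid_field",
    "grid_field_math",
    "make_math_grid_population",
    "hex_lattice_vertices",
    "gaussian_bumps",
    "grid_field_realistic",
    "sample_realistic_grid_population",
    "weakly_spatial_field",
    "make_weakly_spatial_population",
    "entorhinal_response",
    "stretch_population",
]

#: smallest grid spacing (cm) and the geometric module ratio
BASE_SPACING_CM = 28.0
SPACING_RATIO = 1.42

#: sigma of a realistic grid bump as a fraction of the grid spacing
BUMP_SIGMA_FRACTION = 0.32

ORIENTATION_PERIOD_RAD = math.pi / 3  # hexagonal symmetry: 60 degrees


@dataclass(frozen=True)
class GridParams:
    """Spacing lambda (cm), orientation theta in [0, pi/3), phase in [0, lambda)^2."""

    spacing_cm: float
    orientation_rad: float = 0.0
    phase_cm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.spacing_cm <= 0:
            raise ValueError(f"grid spacing must be positive, got {self.spacing_cm}")
        if not 0 <= self.orientation_rad < ORIENTATION_PERIOD_RAD:
            raise ValueError(
                f"orientation must lie in [0, pi/3), got {self.orientation_rad}"
            )
        x0, y0 = self.phase_cm
        if not (0 <= x0 < self.spacing_cm and 0 <= y0 < self.spacing_cm):
            raise ValueError(
                f"phase {self.phase_cm} must lie in [0, spacing)^2 with spacing "
                f"{self.spacing_cm}"
            )

    def to_dict(self) -> dict:
        return {
            "spacing_cm": self.spacing_cm,
            "orientation_rad": self.orientation_rad,
            "phase_cm": list(self.phase_cm),
        }


@dataclass(frozen=True)
class ModuleSpec:
    """Four discrete grid modules (spacing/orientation distributions and mix).

    Defaults follow the experimentally observed module structure: spacing
    means 38.8, 48.4, 65 and 98.4 cm with a common 8 cm SD, orientation
    means 15, 30, 45 and 0 degrees with a 3 degree SD, and 87% of cells in
    the two small-spacing modules (43.5/43.5/6.5/6.5%).
    """

    spacing_means_cm: tuple[float, ...] = (38.8, 48.4, 65.0, 98.4)
    spacing_sd_cm: float = 8.0
    orientation_means_deg: tuple[float, ...] = (15.0, 30.0, 45.0, 0.0)
    orientation_sd_deg: float = 3.0
    proportions: tuple[float, ...] = (0.435, 0.435, 0.065, 0.065)

    def __post_init__(self) -> None:
        n = len(self.spacing_means_cm)
        if len(self.orientation_means_deg) != n or len(self.proportions) != n:
            raise ValueError("module parameter tuples must have equal length")
        if any(p < 0 for p in self.proportions):
            raise ValueError("module proportions must be non-negative")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError(
                f"module proportions must sum to 1, got {sum(self.proportions)}"
            )

    @property
    def n_modules(self) -> int:
        return len(self.spacing_means_cm)


@dataclass(frozen=True)
class RealisticFieldParams:
    """Geometry of one realistic grid cell: lattice vertices and bump amplitudes."""

    grid: GridParams
    vertices_cm: np.ndarray  # (m, 2)
    amplitudes: np.ndarray  # (m,)
    sigma_cm: float
    module: int = 0


@dataclass
class EntorhinalPopulation:
    """A bank of entorhinal firing fields over one environment.

    ``E`` has one row per location and one column per cell; every column is
    non-negative with maximum exactly 1.  ``params`` carries per-cell
    generation metadata (``GridParams``/``RealisticFieldParams`` or None for
    weakly spatial cells), which is what makes deterministic re-evaluation
    (e.g. under a stretched environment) possible.
    """

    E: np.ndarray
    kind: str  # grid_math | grid_realistic | weak_spatial
    env: Environment
    params: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        if self.E.ndim != 2 or self.E.shape[0] != self.env.n_locations:
            raise ValueError(
                f"E must be (n_locations, n_cells) = ({self.env.n_locations}, *), "
                f"got {self.E.shape}"
            )
        if self.params and len(self.params) != self.E.shape[1]:
            raise ValueError("per-cell metadata count must match column count")

    @property
    def n_cells(self) -> int:
        return self.E.shape[1]

    @property
    def n_locations(self) -> int:
        return self.E.shape[0]

    def validate(self) -> None:
        """Assert the field invariants (finite, non-negative, column max 1)."""
        if not np.all(np.isfinite(self.E)):
            raise ValueError("fields contain non-finite values")
        if self.E.min() < 0:
            raise ValueError("fields must be non-negative")
        if not np.allclose(self.E.max(axis=0), 1.0):
            raise ValueError("every field column must have maximum 1")


def _normalize_columns_max1(E: np.ndarray) -> np.ndarray:
    peaks = E.max(axis=0)
    if np.any(peaks <= 0):
        raise ValueError("cannot normalize an all-zero field column")
    return E / peaks


# ---------------------------------------------------------------------------
# mathematical grid model
# ---------------------------------------------------------------------------

def mathematical_grid_field(points_cm: np.ndarray, params: GridParams) -> np.ndarray:
    """Idealized grid field at arbitrary points: sum of three gratings.

    ``E(r) = (2/3) * ((1/3) * sum_j cos(k u_j . (r - r0)) + 1/2)`` with
    ``|k| = 4 pi / (sqrt(3) lambda)`` and unit vectors ``u_j`` at angles
    ``2 pi j / 3 + theta``.  The result lies in [0, 1], equals 1 exactly on
    the hexagonal lattice of peaks (nearest-neighbour distance lambda) and
    0 at the field minima.
    """
    pts = np.atleast_2d(np.asarray(points_cm, dtype=float))
    lam = params.spacing_cm
    theta = params.orientation_rad
    r0 = np.asarray(params.phase_cm, dtype=float)
    k = 4 * math.pi / (math.sqrt(3) * lam)
    d = pts - r0
    acc = np.zeros(pts.shape[0])
    for j in (1, 2, 3):
        ang = 2 * math.pi * j / 3 + theta
        acc += np.cos(k * (d[:, 0] * math.cos(ang) + d[:, 1] * math.sin(ang)))
    vals = (2.0 / 3.0) * (acc / 3.0 + 0.5)
    # analytic range is [0, 1]; clip float round-off at the boundaries
    return np.clip(vals, 0.0, 1.0)


def grid_field_math(env: Environment, params: GridParams) -> np.ndarray:
    """Idealized grid field sampled at the environment bin centers."""
    return mathematical_grid_field(env.centers_cm, params)


def math_grid_spacings(n_spacings: int) -> np.ndarray:
    """Geometric spacing sequence 28, 39.76, 56.46, 80.17 cm."""
    if not 1 <= n_spacings <= 4:
        raise ValueError(
            f"n_spacings must be in [1, 4] (largest spacing below the 1 m box), "
            f"got {n_spacings}"
        )
    return BASE_SPACING_CM * SPACING_RATIO ** np.arange(n_spacings)


def make_math_grid_population(
    env: Environment,
    n_spacings: int = 4,
    n_orientations: int = 6,
    n_phases_x: int = 5,
    n_phases_y: int = 5,
) -> EntorhinalPopulation:
    """Enumerate every (spacing, orientation, phase) combination.

    Spacings form the geometric sequence from 28 cm with ratio 1.42;
    orientations are evenly spaced samples of [0, 60) degrees starting at 0;
    phases are evenly spaced samples of [0, lambda) starting at 0 along each
    axis.  The population size is the product of the four counts.
    """
    if n_orientations < 1 or n_phases_x < 1 or n_phases_y < 1:
        raise ValueError("orientation and phase counts must be >= 1")
    spacings = math_grid_spacings(n_spacings)
    orientations = np.arange(n_orientations) * ORIENTATION_PERIOD_RAD / n_orientations
    cols, params = [], []
    for lam in spacings:
        xs = np.arange(n_phases_x) * lam / n_phases_x
        ys = np.arange(n_phases_y) * lam / n_phases_y
        for theta in orientations:
            for x0 in xs:
                for y0 in ys:
                    p = GridParams(float(lam), float(theta), (float(x0), float(y0)))
                    cols.append(grid_field_math(env, p))
                    params.append(p)
    E = _normalize_columns_max1(np.column_stack(cols))
    return EntorhinalPopulation(E=E, kind="grid_math", env=env, params=params)


# ---------------------------------------------------------------------------
# realistic grid model
# ---------------------------------------------------------------------------

def hex_lattice_vertices(
    params: GridParams,
    width_cm: float,
    height_cm: float,
    pad_cm: float,
) -> np.ndarray:
    """Vertices of the hexagonal lattice intersecting the padded box.

    The lattice has primitive vectors of length lambda at angles theta and
    theta + 60 degrees, offset by the phase (x0, y0).
    """
    lam = params.spacing_cm
    theta = params.orientation_rad
    v1 = lam * np.array([math.cos(theta), math.sin(theta)])
    v2 = lam * np.array(
        [math.cos(theta + math.pi / 3), math.sin(theta + math.pi / 3)]
    )
    origin = np.asarray(params.phase_cm, dtype=float)
    # conservative integer range covering the padded box
    reach = math.hypot(width_cm, height_cm) + pad_cm + 2 * lam
    nmax = int(math.ceil(reach / (lam * math.sin(math.pi / 3)))) + 1
    ii, jj = np.meshgrid(np.arange(-nmax, nmax + 1), np.arange(-nmax, nmax + 1))
    pts = origin + ii.ravel()[:, None] * v1 + jj.ravel()[:, None] * v2
    keep = (
        (pts[:, 0] >= -pad_cm)
        & (pts[:, 0] <= width_cm + pad_cm)
        & (pts[:, 1] >= -pad_cm)
        & (pts[:, 1] <= height_cm + pad_cm)
    )
    return pts[keep]


def gaussian_bumps(
    points_cm: np.ndarray,
    vertices_cm: np.ndarray,
    amplitudes: np.ndarray,
    sigma_cm: float,
) -> np.ndarray:
    """Sum of per-vertex bumps ``gamma_v * exp(-ln(5) * d^2 / sigma^2)``.

    Each bump falls to ``gamma_v / 5`` at distance ``sigma`` from its vertex.
    """
    pts = np.atleast_2d(np.asarray(points_cm, dtype=float))
    d2 = (
        (pts[:, None, 0] - vertices_cm[None, :, 0]) ** 2
        + (pts[:, None, 1] - vertices_cm[None, :, 1]) ** 2
    )
    return (np.exp(-math.log(5.0) * d2 / sigma_cm**2) * amplitudes).sum(axis=1)


def grid_field_realistic(
    env: Environment,
    params: GridParams,
    rng: np.random.Generator,
    module: int = 0,
) -> tuple[np.ndarray, RealisticFieldParams]:
    """Realistic grid field: jittered bumps on a hexagonal lattice.

    sigma = 0.32 * lambda; per-vertex amplitudes are drawn i.i.d. from
    N(1, 0.1).  Returns the raw (un-normalized) field values at the bin
    centers together with the frozen per-vertex geometry, so the same cell
    can be re-evaluated at other coordinates.
    """
    sigma = BUMP_SIGMA_FRACTION * params.spacing_cm
    verts = hex_lattice_vertices(params, env.width_cm, env.height_cm, pad_cm=3 * sigma)
    amps = 1.0 + 0.1 * rng.standard_normal(len(verts))
    meta = RealisticFieldParams(
        grid=params, vertices_cm=verts, amplitudes=amps, sigma_cm=sigma, module=module
    )
    return gaussian_bumps(env.centers_cm, verts, amps, sigma), meta


def _largest_remainder_counts(n: int, proportions: Sequence[float]) -> np.ndarray:
    """Deterministic apportionment of n cells across module proportions."""
    quotas = np.asarray(proportions, dtype=float) * n
    counts = np.floor(quotas).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def sample_realistic_grid_population(
    env: Environment,
    spec: ModuleSpec,
    n_cells: int,
    rng: np.random.Generator,
    fixed_phase_cm: Optional[tuple[float, float]] = None,
) -> EntorhinalPopulation:
    """Draw a population of realistic grid cells from the module mixture.

    Cells are apportioned across modules by largest remainder (then
    shuffled); per cell, spacing ~ N(module mean, SD) resampled until
    positive, orientation ~ N(module mean, SD) wrapped to [0, 60) degrees,
    and phase uniform on [0, lambda)^2 unless ``fixed_phase_cm`` pins it
    (phase-diversity ablation).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    counts = _largest_remainder_counts(n_cells, spec.proportions)
    modules = np.repeat(np.arange(spec.n_modules), counts)
    modules = rng.permutation(modules)
    cols, params = [], []
    for m in modules:
        lam = -1.0
        while lam <= 0:
            lam = spec.spacing_means_cm[m] + spec.spacing_sd_cm * rng.standard_normal()
        theta = math.radians(
            spec.orientation_means_deg[m]
            + spec.orientation_sd_deg * rng.standard_normal()
        ) % ORIENTATION_PERIOD_RAD
        phase = fixed_phase_cm if fixed_phase_cm is not None else tuple(
            rng.uniform(0.0, lam, size=2)
        )
        p = GridParams(float(lam), float(theta), (float(phase[0]), float(phase[1])))
        vals, meta = grid_field_realistic(env, p, rng, module=int(m))
        cols.append(vals)
        params.append(meta)
    E = _normalize_columns_max1(np.column_stack(cols))
    return EntorhinalPopulation(E=E, kind="grid_realistic", env=env, params=params)


# ---------------------------------------------------------------------------
# weakly spatial cells
# ---------------------------------------------------------------------------

def smoothed_noise_map(
    env: Environment, smooth_sd_cm: float, rng: np.random.Generator
) -> np.ndarray:
    """Uniform(0, 1) noise per bin, Gaussian-smoothed (reflective borders)."""
    if smooth_sd_cm <= 0:
        raise ValueError("smooth_sd_cm must be positive")
    raw = rng.random((env.ny, env.nx))
    sigma_bins = (smooth_sd_cm / env.dy_cm, smooth_sd_cm / env.dx_cm)
    return gaussian_filter(raw, sigma=sigma_bins, mode="reflect").ravel()


def weakly_spatial_field(
    env: Environment, smooth_sd_cm: float, rng: np.random.Generator
) -> np.ndarray:
    """Weakly spatial field: smoothed noise min-max rescaled to [0, 1]."""
    sm = smoothed_noise_map(env, smooth_sd_cm, rng)
    lo, hi = sm.min(), sm.max()
    if hi == lo:  # degenerate flat map
        return np.zeros_like(sm)
    return (sm - lo) / (hi - lo)


def make_weakly_spatial_population(
    env: Environment,
    n_cells: int,
    rng: np.random.Generator,
    smooth_sd_cm: float = 6.0,
) -> EntorhinalPopulation:
    cols = [weakly_spatial_field(env, smooth_sd_cm, rng) for _ in range(n_cells)]
    E = np.column_stack(cols)
    return EntorhinalPopulation(
        E=E, kind="weak_spatial", env=env, params=[None] * n_cells
    )


# ---------------------------------------------------------------------------
# responses and environment manipulation
# ---------------------------------------------------------------------------

def entorhinal_response(
    pop: EntorhinalPopulation,
    location_index: int,
    noise_amp: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Population response ``s_e = E^T r (+ gamma_n * n)`` at one location.

    Gaussian response noise (amplitude ``noise_amp``) is added unclipped;
    with ``noise_amp = 0`` the response is the exact row of ``E``.
    """
    if not 0 <= location_index < pop.n_locations:
        raise IndexError(
            f"location index {location_index} out of range [0, {pop.n_locations})"
        )
    s_e = pop.E[location_index].copy()
    if noise_amp < 0:
        raise ValueError("noise amplitude must be non-negative")
    if noise_amp > 0:
        if rng is None:
            raise ValueError("rng is required when noise_amp > 0")
        s_e += noise_amp * rng.standard_normal(pop.n_cells)
    return s_e


def stretch_population(
    pop: EntorhinalPopulation, factor_x: float
) -> EntorhinalPopulation:
    """Re-evaluate grid fields in a box stretched along x.

    The box width and grid resolution scale by ``factor_x`` and every field
    is evaluated at compressed x coordinates, so the firing pattern is
    stretched with the environment (deformed-arena experiment).  Weakly
    spatial populations carry no closed-form generation rule and cannot be
    stretched.
    """
    if factor_x < 1:
        raise ValueError("factor_x must be >= 1")
    if pop.kind == "weak_spatial":
        raise ValueError(
            "weakly spatial fields have no regeneration rule and cannot be stretched"
        )
    env = pop.env
    new_env = Environment(
        width_cm=env.width_cm * factor_x,
        height_cm=env.height_cm,
        nx=int(round(env.nx * factor_x)),
        ny=env.ny,
    )
    pts = new_env.centers_cm.copy()
    pts[:, 0] /= factor_x  # evaluate the original pattern at compressed x
    cols = []
    for meta in pop.params:
        if isinstance(meta, RealisticFieldParams):
            cols.append(
                gaussian_bumps(pts, meta.vertices_cm, meta.amplitudes, meta.sigma_cm)
            )
        elif isinstance(meta, GridParams):
            cols.append(mathematical_grid_field(pts, meta))
        else:
            raise ValueError("population lacks per-cell parameters; cannot stretch")
    E = _normalize_columns_max1(np.column_stack(cols))
    return EntorhinalPopulation(E=E, kind=pop.kind, env=new_env, params=list(pop.params))
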