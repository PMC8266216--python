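"""Firing-field recovery, Gaussian place-field fits and tiling metrics.

After training, hippocampal firing fields are estimated by reverse
correlation: present many random locations, and average the one-hot
location vectors weighted by each cell's response.  Each recovered field is
fitted with an isotropic peaked function

    Q(x, y) = gamma * exp(-ln(5) * ((x - xc)^2 + (y - yc)^2) / sigma^2)

whose value falls to gamma/5 at distance sigma from the center.  A cell is
a place cell when the relative squared fit residual is below 15% and the
breadth sigma exceeds 5 cm.  Tiling quality of the resulting place map is
summarized by the distance from every location to its nearest field center
(d_PF) and by each center's second-nearest-neighbour distance (d_ND).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist

from .environment import Environment
from .entorhinal import EntorhinalPopulation
from .network import ModelConfig, NetworkState, lca_infer_batch

__all__ = [
    "FiringField",
    "PlaceFit",
    "PlaceMapMetrics",
    "recover_fields",
    "fields_from_responses",
    "place_field_model",
    "fit_place_field",
    "classify_place_cell",
    "distance_to_place_field",
    "nearest_distance",
    "population_sparseness",
    "response_power_ratio",
    "analyze_place_map",
]

DEFAULT_RECOVERY_SAMPLES = 100_000
MAX_FIT_ERROR = 0.15
MIN_BREADTH_CM = 5.0


@dataclass(frozen=True)
class FiringField:
    """Recovered rate map of one hippocampal cell (normalized weights)."""

    values: np.ndarray  # (n_locations,), sums to 1 unless silent
    n_samples: int
    cell_index: int

    @property
    def is_silent(self) -> bool:
        return not np.any(self.values > 0)


@dataclass(frozen=True)
class PlaceFit:
    """Fitted place-field parameters and the relative squared residual."""

    amplitude: float
    breadth_cm: float
    center_cm: tuple[float, float]
    fit_error: float
    valid: bool = True

    @classmethod
    def invalid(cls) -> "PlaceFit":
        return cls(0.0, np.nan, (np.nan, np.nan), np.inf, valid=False)


@dataclass
class PlaceMapMetrics:
    """Population-level tiling statistics for one trained model."""

    n_cells: int
    n_place_cells: int
    radii_cm: np.ndarray
    d_pf_cm: np.ndarray  # per environment location
    d_nd_cm: np.ndarray  # per place cell (empty if < 3 centers)
    active_fraction: float
    power_ratio: float
    centers_cm: np.ndarray = dc_field(default_factory=lambda: np.empty((0, 2)))

    @property
    def mean_radius_cm(self) -> float:
        return float(np.mean(self.radii_cm)) if self.radii_cm.size else np.nan

    @property
    def mean_nearest_distance_cm(self) -> float:
        return float(np.mean(self.d_nd_cm)) if self.d_nd_cm.size else np.nan

    @property
    def max_distance_to_field_cm(self) -> float:
        return float(np.max(self.d_pf_cm)) if self.d_pf_cm.size else np.nan

    def to_dict(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "n_place_cells": self.n_place_cells,
            "mean_radius_cm": self.mean_radius_cm,
            "sd_radius_cm": float(np.std(self.radii_cm)) if self.radii_cm.size else float("nan"),
            "mean_nearest_distance_cm": self.mean_nearest_distance_cm,
            "sd_nearest_distance_cm": float(np.std(self.d_nd_cm)) if self.d_nd_cm.size else float("nan"),
            "max_distance_to_field_cm": self.max_distance_to_field_cm,
            "active_fraction": self.active_fraction,
            "power_ratio": self.power_ratio,
        }


# ---------------------------------------------------------------------------
# reverse correlation
# ---------------------------------------------------------------------------

def fields_from_responses(
    responses: np.ndarray, counts: np.ndarray
) -> np.ndarray:
    """Reverse-correlation fields from per-location responses and visit counts.

    With one-hot location inputs the response-weighted stimulus average
    reduces to ``F_j(loc) = counts[loc] * s_j(loc) / sum_loc counts * s_j``.
    Columns with zero total response come back all-zero (silent cells).
    """
    weighted = responses * counts[:, None]  # (n_loc, n_cells)
    totals = weighted.sum(axis=0)
    out = np.zeros_like(weighted)
    live = totals > 0
    out[:, live] = weighted[:, live] / totals[live]
    return out


def recover_fields(
    state: NetworkState,
    pop: EntorhinalPopulation,
    cfg: ModelConfig,
    n_samples: int = DEFAULT_RECOVERY_SAMPLES,
    rng: Optional[np.random.Generator] = None,
    locations: Optional[Sequence[int]] = None,
) -> list[FiringField]:
    """Estimate hippocampal firing fields by reverse correlation.

    ``n_samples`` locations are drawn uniformly over the grid (or taken
    from ``locations``, e.g. a discretized trajectory); responses are
    computed noise-free by the competitive dynamics at each distinct
    location, and fields are the response-weighted location averages.
    """
    n_loc = pop.n_locations
    if locations is not None:
        locations = np.asarray(locations, dtype=np.int64)
        counts = np.bincount(locations, minlength=n_loc).astype(float)
        n_samples = int(locations.size)
    else:
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if rng is None:
            raise ValueError("rng is required for uniform location sampling")
        counts = rng.multinomial(n_samples, np.full(n_loc, 1.0 / n_loc)).astype(float)
    visited = np.flatnonzero(counts > 0)
    S = np.zeros((n_loc, state.n_hippocampal))
    S[visited] = lca_infer_batch(state, pop.E[visited], cfg)
    F = fields_from_responses(S, counts)
    return [
        FiringField(values=F[:, j], n_samples=n_samples, cell_index=j)
        for j in range(state.n_hippocampal)
    ]


# ---------------------------------------------------------------------------
# Gaussian place-field fitting and classification
# ---------------------------------------------------------------------------

def place_field_model(
    points_cm: np.ndarray,
    amplitude: float,
    breadth_cm: float,
    xc: float,
    yc: float,
) -> np.ndarray:
    """Isotropic field falling to ``amplitude / 5`` at distance ``breadth``."""
    pts = np.atleast_2d(points_cm)
    d2 = (pts[:, 0] - xc) ** 2 + (pts[:, 1] - yc) ** 2
    return amplitude * np.exp(-math.log(5.0) * d2 / breadth_cm**2)


def fit_place_field(
    field: FiringField | np.ndarray,
    env: Environment,
    init_breadth_cm: float = 10.0,
) -> PlaceFit:
    """Nonlinear least-squares fit of the peaked field model to a rate map.

    Initialization puts the center and amplitude at the map maximum.  The
    fit error is the squared ratio of the residual norm to the field norm,
    so it is scale-free.  Optimizer failure or an all-zero field yields an
    invalid fit (never classified as a place cell).
    """
    F = field.values if isinstance(field, FiringField) else np.asarray(field, float)
    fnorm2 = float(F @ F)
    if fnorm2 <= 0 or not np.all(np.isfinite(F)):
        return PlaceFit.invalid()
    pts = env.centers_cm
    i0 = int(np.argmax(F))
    p0 = np.array([F[i0], init_breadth_cm, pts[i0, 0], pts[i0, 1]])
    diag = math.hypot(env.width_cm, env.height_cm)
    pad = 10.0
    lower = [0.0, 1e-2, -pad, -pad]
    upper = [np.inf, diag, env.width_cm + pad, env.height_cm + pad]
    p0 = np.clip(p0, lower, np.nextafter(upper, -np.inf))

    def resid(p):
        return place_field_model(pts, *p) - F

    try:
        res = least_squares(resid, p0, bounds=(lower, upper))
    except Exception:
        return PlaceFit.invalid()
    if not np.all(np.isfinite(res.x)):
        return PlaceFit.invalid()
    err = float(res.fun @ res.fun) / fnorm2
    amp, sigma, xc, yc = res.x
    return PlaceFit(
        amplitude=float(amp),
        breadth_cm=float(sigma),
        center_cm=(float(xc), float(yc)),
        fit_error=err,
        valid=bool(res.success),
    )


def classify_place_cell(
    fit: PlaceFit,
    max_fit_error: float = MAX_FIT_ERROR,
    min_breadth_cm: float = MIN_BREADTH_CM,
) -> bool:
    """Place cell iff the fit is valid, error < 15% and breadth > 5 cm."""
    return bool(
        fit.valid
        and np.isfinite(fit.fit_error)
        and fit.fit_error < max_fit_error
        and fit.breadth_cm > min_breadth_cm
    )


# ---------------------------------------------------------------------------
# tiling metrics
# ---------------------------------------------------------------------------

def distance_to_place_field(
    centers_cm: np.ndarray, env: Environment
) -> np.ndarray:
    """Euclidean distance from every location bin to its nearest center."""
    centers = np.atleast_2d(np.asarray(centers_cm, dtype=float))
    if centers.size == 0:
        raise ValueError("at least one place-field center is required")
    return cdist(env.centers_cm, centers).min(axis=1)


def nearest_distance(centers_cm: np.ndarray) -> np.ndarray:
    """Second-nearest-neighbour distance for every center.

    For center j, take the distances to all other centers, keep the two
    smallest, and return their maximum.  Requires at least 3 centers.
    """
    centers = np.atleast_2d(np.asarray(centers_cm, dtype=float))
    if centers.shape[0] < 3:
        raise ValueError("nearest_distance requires at least 3 centers")
    D = cdist(centers, centers)
    np.fill_diagonal(D, np.inf)
    two_smallest = np.partition(D, 1, axis=1)[:, :2]
    return two_smallest.max(axis=1)


def population_sparseness(
    state: NetworkState,
    pop: EntorhinalPopulation,
    cfg: ModelConfig,
    locations: Optional[Sequence[int]] = None,
) -> float:
    """Mean fraction of hippocampal cells active (rate > 0) per location."""
    E = pop.E if locations is None else pop.E[np.asarray(locations, dtype=int)]
    S = lca_infer_batch(state, E, cfg)
    return float(np.mean(S > 0))


def response_power_ratio(
    state: NetworkState,
    pop: EntorhinalPopulation,
    cfg: ModelConfig,
    locations: Optional[Sequence[int]] = None,
) -> float:
    """Mean squared entorhinal response over mean squared hippocampal rate."""
    E = pop.E if locations is None else pop.E[np.asarray(locations, dtype=int)]
    S = lca_infer_batch(state, E, cfg)
    denom = float(np.mean(S**2))
    if denom == 0:
        raise ZeroDivisionError(
            "hippocampal responses are identically zero; power ratio undefined"
        )
    return float(np.mean(E**2)) / denom


# ---------------------------------------------------------------------------
# end-to-end summary
# ---------------------------------------------------------------------------

def analyze_place_map(
    state: NetworkState,
    pop: EntorhinalPopulation,
    cfg: ModelConfig,
    n_samples: int = DEFAULT_RECOVERY_SAMPLES,
    rng: Optional[np.random.Generator] = None,
    recovery_locations: Optional[Sequence[int]] = None,
) -> tuple[PlaceMapMetrics, pd.DataFrame, list[FiringField]]:
    """Recover fields, fit them, classify place cells and compute metrics.

    Returns the population metrics, a per-cell table (fit parameters and
    classification) and the recovered fields themselves.
    """
    fields = recover_fields(
        state, pop, cfg, n_samples=n_samples, rng=rng, locations=recovery_locations
    )
    env = pop.env
    rows = []
    for f in fields:
        fit = PlaceFit.invalid() if f.is_silent else fit_place_field(f, env)
        rows.append(
            {
                "cell": f.cell_index,
                "silent": f.is_silent,
                "amplitude": fit.amplitude,
                "breadth_cm": fit.breadth_cm,
                "x_cm": fit.center_cm[0],
                "y_cm": fit.center_cm[1],
                "fit_error": fit.fit_error,
                "is_place_cell": classify_place_cell(fit),
            }
        )
    table = pd.DataFrame(rows)
    place = table[table.is_place_cell]
    centers = place[["x_cm", "y_cm"]].to_numpy()
    radii = place["breadth_cm"].to_numpy()
    d_pf = (
        distance_to_place_field(centers, env)
        if len(centers)
        else np.full(env.n_locations, np.nan)
    )
    d_nd = nearest_distance(centers) if len(centers) >= 3 else np.empty(0)
    metrics = PlaceMapMetrics(
        n_cells=len(fields),
        n_place_cells=int(table.is_place_cell.sum()),
        radii_cm=radii,
        d_pf_cm=d_pf,
        d_nd_cm=d_nd,
        active_fraction=population_sparseness(state, pop, cfg),
        power_ratio=response_power_ratio(state, pop, cfg),
        centers_cm=centers,
    )
    return metrics, table, fields
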