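"""Smoothed random-walk running trajectories for a virtual rat.

The generator produces a continuous path whose heading performs a wrapped
Gaussian random walk and whose speed mean-reverts around a target (default
25 cm/s), sampled at a fixed rate (default 20 Hz) with reflective walls.
Training and field recovery can then use the discretized location sequence
instead of uniformly random locations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .environment import Environment

__all__ = ["Trajectory", "simulate_trajectory"]


@dataclass(frozen=True)
class Trajectory:
    positions_cm: np.ndarray  # (n, 2), time-ordered
    rate_hz: float
    mean_speed_cm_s: float
    duration_s: float

    def __len__(self) -> int:
        return self.positions_cm.shape[0]

    @property
    def speeds_cm_s(self) -> np.ndarray:
        """Empirical speeds between consecutive samples."""
        steps = np.diff(self.positions_cm, axis=0)
        return np.hypot(steps[:, 0], steps[:, 1]) * self.rate_hz

    def to_location_indices(self, env: Environment) -> np.ndarray:
        return env.xy_to_indices(self.positions_cm)


def _reflect(value: float, lo: float, hi: float) -> float:
    """Fold a coordinate back into [lo, hi] by mirror reflection."""
    span = hi - lo
    v = (value - lo) % (2 * span)
    if v > span:
        v = 2 * span - v
    return lo + v


def simulate_trajectory(
    env: Environment,
    duration_s: float,
    rate_hz: float = 20.0,
    mean_speed_cm_s: float = 25.0,
    rng: np.random.Generator | None = None,
    heading_sd_rad: float = 0.2,
    speed_sd_cm_s: float = 5.0,
    speed_relax: float = 0.05,
) -> Trajectory:
    """Simulate a smoothed random walk in the box.

    Heading increments are N(0, heading_sd_rad) per sample; speed follows a
    mean-reverting (discrete Ornstein-Uhlenbeck) process around
    ``mean_speed_cm_s`` with stationary SD ``speed_sd_cm_s``, clipped at
    zero.  Walls reflect both the position and the heading.  The number of
    samples is ``duration_s * rate_hz``.
    """
    if duration_s <= 0 or rate_hz <= 0 or mean_speed_cm_s <= 0:
        raise ValueError("duration, rate and mean speed must be positive")
    rng = np.random.default_rng() if rng is None else rng
    n = int(round(duration_s * rate_hz))
    dt = 1.0 / rate_hz
    pos = np.empty((n, 2))
    x, y = env.width_cm / 2.0, env.height_cm / 2.0
    heading = rng.uniform(0.0, 2.0 * np.pi)
    speed = mean_speed_cm_s
    sigma_step = speed_sd_cm_s * np.sqrt(1.0 - (1.0 - speed_relax) ** 2)
    pos[0] = (x, y)
    for t in range(1, n):
        heading += heading_sd_rad * rng.standard_normal()
        speed += speed_relax * (mean_speed_cm_s - speed) + sigma_step * rng.standard_normal()
        speed = max(speed, 0.0)
        nx = x + speed * dt * np.cos(heading)
        ny = y + speed * dt * np.sin(heading)
        if nx < 0.0 or nx > env.width_cm:
            heading = np.pi - heading
            nx = _reflect(nx, 0.0, env.width_cm)
        if ny < 0.0 or ny > env.height_cm:
            heading = -heading
            ny = _reflect(ny, 0.0, env.height_cm)
        x, y = nx, ny
        pos[t] = (x, y)
    return Trajectory(
        positions_cm=pos,
        rate_hz=rate_hz,
        mean_speed_cm_s=mean_speed_cm_s,
        duration_s=duration_s,
    )
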