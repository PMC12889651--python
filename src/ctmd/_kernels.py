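"""Compiled inner loop for well-tempered metadynamics on the toy potential.

The biased overdamped Langevin propagation is the only hot loop in the
package (5e5 steps per replica, ~100 replicas per screen), so it runs
under numba.  The metadynamics bias force is kept on a uniform grid that
is updated analytically at each hill deposition and linearly interpolated
during dynamics; the bias *value* needed for the well-tempered height rule
is evaluated exactly from the hill list at deposition time (once per
``pace`` steps), so no approximation enters the deposited heights.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["wt_metad_gaussian_well"]


@njit(cache=True)
def _wt_metad_core(
    noise,
    dt,
    friction,
    kT,
    pace,
    w0,
    sigma,
    gamma,
    depth,
    width,
    center,
    wall_pos,
    wall_k,
    s0,
    grid_min,
    grid_spacing,
    n_grid,
):  # pragma: no cover - exercised through the wrapper
    n_steps = noise.shape[0]
    n_hills = n_steps // pace
    hill_centers = np.empty(n_hills)
    hill_heights = np.empty(n_hills)
    fbias = np.zeros(n_grid)  # -dV_bias/ds on the grid

    amp = math.sqrt(2.0 * kT * dt / friction)
    inv_w2 = 1.0 / (width * width)
    inv_sg2 = 1.0 / (sigma * sigma)
    s = s0
    k = 0
    for i in range(n_steps):
        # analytic force of the model potential (well + half-harmonic wall)
        d = s - center
        f = -depth * d * inv_w2 * math.exp(-0.5 * d * d * inv_w2)
        if s > wall_pos:
            f -= wall_k * (s - wall_pos)
        # bias force by linear interpolation
        x = (s - grid_min) / grid_spacing
        if x <= 0.0:
            f += fbias[0]
        elif x >= n_grid - 1:
            f += fbias[n_grid - 1]
        else:
            j = int(x)
            frac = x - j
            f += fbias[j] * (1.0 - frac) + fbias[j + 1] * frac

        s = s + f * dt / friction + amp * noise[i]
        if s < 0.0:
            s = -s  # reflecting boundary keeps the RMSD-like CV non-negative

        if (i + 1) % pace == 0 and k < n_hills:
            # exact accumulated bias at the deposition point
            v = 0.0
            for m in range(k):
                dd = s - hill_centers[m]
                v += hill_heights[m] * math.exp(-0.5 * dd * dd * inv_sg2)
            h = w0 * math.exp(-v / ((gamma - 1.0) * kT))
            hill_centers[k] = s
            hill_heights[k] = h
            # add the new hill's force to the grid
            for g in range(n_grid):
                xg = grid_min + g * grid_spacing
                dd = xg - s
                fbias[g] += h * dd * inv_sg2 * math.exp(-0.5 * dd * dd * inv_sg2)
            k += 1
    return hill_centers, hill_heights, s


def wt_metad_gaussian_well(
    noise: np.ndarray,
    dt: float,
    friction: float,
    kT: float,
    pace: int,
    w0: float,
    sigma: float,
    gamma: float,
    depth: float,
    width: float,
    center: float,
    wall_pos: float,
    wall_k: float,
    s0: float,
    grid_min: float,
    grid_max: float,
    n_grid: int = 1500,
):
    """Run one well-tempered metadynamics replica on a Gaussian-well potential.

    Returns (hill_centers, hill_heights, final_s); hill k is deposited at
    simulation time (k+1) * pace * dt.  Deterministic given the noise array.
    """
    spacing = (grid_max - grid_min) / (n_grid - 1)
    return _wt_metad_core(
        np.ascontiguousarray(noise, dtype=np.float64),
        float(dt),
        float(friction),
        float(kT),
        int(pace),
        float(w0),
        float(sigma),
        float(gamma),
        float(depth),
        float(width),
        float(center),
        float(wall_pos),
        float(wall_k),
        float(s0),
        float(grid_min),
        float(spacing),
        int(n_grid),
    )
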