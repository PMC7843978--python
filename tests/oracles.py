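"""Independent reference implementations used only as test oracles.

These deliberately share no code with ppgsim's kernel: the reflectance
oracle is a vectorized homogeneous-medium Monte Carlo with discrete albedo
weighting (no voxels, no weight windows, numpy RNG), so agreement with the
package's voxel kernel is a genuine cross-check of two implementations.
"""

from __future__ import annotations

import numpy as np


def hg_cos_oracle(g: float, u: np.ndarray) -> np.ndarray:
    """Henyey-Greenstein inverse-CDF sampling (independent coding)."""
    if abs(g) < 1e-12:
        return 2.0 * u - 1.0
    frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    return np.clip((1.0 + g * g - frac * frac) / (2.0 * g), -1.0, 1.0)


def semi_infinite_reflectance(
    mu_a: float, mu_s: float, g: float, n_photons: int, seed: int
) -> tuple[float, float]:
    """Total diffuse reflectance of a matched-boundary semi-infinite medium.

    Discrete albedo weighting: photons scatter at exponential mu_t
    intervals, keep albedo = mu_s/mu_t of their weight per collision, and
    tally their weight when crossing z < 0.  Returns (estimate, std error)
    over 10 photon blocks.
    """
    rng = np.random.default_rng(seed)
    mu_t = mu_a + mu_s
    albedo = mu_s / mu_t
    blocks = np.empty(10)
    n_block = n_photons // 10
    for b in range(10):
        pos = np.zeros((n_block, 3))
        direc = np.zeros((n_block, 3))
        direc[:, 2] = 1.0
        w = np.ones(n_block)
        alive = np.ones(n_block, dtype=bool)
        refl = 0.0
        while alive.any():
            idx = np.where(alive)[0]
            step = -np.log(1.0 - rng.random(len(idx))) / mu_t
            pos[idx] += direc[idx] * step[:, None]
            escaped = idx[pos[idx, 2] < 0.0]
            refl += w[escaped].sum()
            alive[escaped] = False
            idx = np.where(alive)[0]
            if len(idx) == 0:
                break
            w[idx] *= albedo
            # HG deflection about the current direction
            cost = hg_cos_oracle(g, rng.random(len(idx)))
            sint = np.sqrt(np.clip(1.0 - cost**2, 0.0, None))
            phi = 2.0 * np.pi * rng.random(len(idx))
            ux, uy, uz = direc[idx, 0], direc[idx, 1], direc[idx, 2]
            near_pole = np.abs(uz) > 0.99999
            tmp = np.sqrt(np.clip(1.0 - uz**2, 1e-30, None))
            nx = sint * (ux * uz * np.cos(phi) - uy * np.sin(phi)) / tmp + ux * cost
            ny = sint * (uy * uz * np.cos(phi) + ux * np.sin(phi)) / tmp + uy * cost
            nz = -sint * np.cos(phi) * tmp + uz * cost
            nx = np.where(near_pole, sint * np.cos(phi), nx)
            ny = np.where(near_pole, sint * np.sin(phi), ny)
            nz = np.where(near_pole, np.sign(uz) * cost, nz)
            norm = np.sqrt(nx**2 + ny**2 + nz**2)
            direc[idx, 0] = nx / norm
            direc[idx, 1] = ny / norm
            direc[idx, 2] = nz / norm
            # roulette low weights
            low = idx[w[idx] < 1e-4]
            if len(low):
                kill = rng.random(len(low)) > 0.1
                alive[low[kill]] = False
                boosted = low[~kill]
                w[boosted] *= 10.0
        blocks[b] = refl / n_block
    return float(blocks.mean()), float(blocks.std(ddof=1) / np.sqrt(len(blocks)))
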