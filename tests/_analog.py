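"""Naive analog Monte Carlo reference simulator for cross-checks.

Deliberately independent of the package's weighted estimator: photons carry
no weight (absorption and Fresnel reflection are sampled as discrete events),
the detector is scored by plain binary point-in-disk membership (no ring
averaging), and the RNG is numba's Mersenne Twister rather than the package's
inline xorshift generator.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def analog_reflectance(n_photons, mua, mus, g, src_r, det_r, sep, uz_min,
                       n_rel, sin_launch_max, kill_depth, max_steps, seed):
    np.random.seed(seed)
    detected = 0
    for _ in range(n_photons):
        rr = src_r * np.sqrt(np.random.random())
        ang = 2.0 * np.pi * np.random.random()
        x = rr * np.cos(ang)
        y = rr * np.sin(ang)
        z = 0.0
        cos_max = np.sqrt(1.0 - sin_launch_max * sin_launch_max)
        uz = cos_max + (1.0 - cos_max) * np.random.random()
        st = np.sqrt(max(0.0, 1.0 - uz * uz))
        ang = 2.0 * np.pi * np.random.random()
        ux = st * np.cos(ang)
        uy = st * np.sin(ang)
        mut = mua + mus
        alive = True
        steps = 0
        while alive:
            s = -np.log(np.random.random() + 1e-300) / mut
            while s > 0.0:
                if uz < 0.0 and z + s * uz <= 0.0:
                    db = -z / uz
                    x += db * ux
                    y += db * uy
                    s -= db
                    z = 0.0
                    cos_i = -uz
                    # Fresnel by sampling, not weight splitting
                    if n_rel == 1.0:
                        T = 1.0
                    else:
                        sin_t2 = (1.0 - cos_i * cos_i) / (n_rel * n_rel)
                        if sin_t2 >= 1.0:
                            T = 0.0
                        else:
                            cos_t = np.sqrt(1.0 - sin_t2)
                            rs = (cos_i - n_rel * cos_t) / (cos_i + n_rel * cos_t)
                            rp = (n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)
                            T = 1.0 - 0.5 * (rs * rs + rp * rp)
                    if np.random.random() < T:
                        dx = x - sep
                        if (dx * dx + y * y <= det_r * det_r
                                and cos_i >= uz_min):
                            detected += 1
                        alive = False
                        break
                    uz = -uz
                else:
                    x += s * ux
                    y += s * uy
                    z += s * uz
                    s = 0.0
            if not alive:
                break
            if z > kill_depth:
                break
            if np.random.random() < mua / mut:
                break  # absorbed
            # Henyey-Greenstein scatter
            u = np.random.random()
            if abs(g) < 1e-6:
                ct = 2.0 * u - 1.0
            else:
                t = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
                ct = (1.0 + g * g - t * t) / (2.0 * g)
            stt = np.sqrt(max(0.0, 1.0 - ct * ct))
            phi = 2.0 * np.pi * np.random.random()
            cp = np.cos(phi)
            sp = np.sin(phi)
            if abs(uz) > 0.99999:
                ux, uy, uz = stt * cp, stt * sp, ct * (1.0 if uz >= 0 else -1.0)
            else:
                den = np.sqrt(1.0 - uz * uz)
                nx = stt * (ux * uz * cp - uy * sp) / den + ux * ct
                ny = stt * (uy * uz * cp + ux * sp) / den + uy * ct
                nz = -stt * cp * den + uz * ct
                norm = np.sqrt(nx * nx + ny * ny + nz * nz)
                ux, uy, uz = nx / norm, ny / norm, nz / norm
            steps += 1
            if steps >= max_steps:
                break
    p = detected / n_photons
    se = np.sqrt(max(p * (1.0 - p), 1e-300) / n_photons)
    return p, se


def analog_node(mua, musp, geom, n_photons=200_000, g=0.9, seed=1,
                kill_depth=None):
    """Analog estimate at one LUT node with the package's probe geometry."""
    mus = musp / (1.0 - g)
    if kill_depth is None:
        kill_depth = min(2.0, max(0.2, 10.0 / musp))
    uz_min = np.sqrt(max(0.0, 1.0 - (geom.numerical_aperture
                                     / geom.n_tissue) ** 2))
    sin_launch = min(geom.numerical_aperture / geom.n_tissue, 1.0)
    return analog_reflectance(
        n_photons, mua, mus, g, geom.source_radius, geom.detector_radius,
        geom.center_separation, uz_min, geom.n_above / geom.n_tissue,
        sin_launch, kill_depth, 1_000_000, seed)
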