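"""Numba kernels for Monte Carlo canopy ray tracing.

Forward (source-to-scene) tracing with equal-energy rays.  Acceleration is a
uniform voxel grid traversed with the Amanatides–Woo 3D-DDA; triangles are
tested with Möller–Trumbore.  Every ray owns a private counter-based
(splitmix64) random stream seeded from (trace seed, global ray index), so
results are bit-reproducible and independent of traversal or batch order.

Energy accounting is deterministic: at each leaf hit the absorbed fraction
(1−ρ−τ) of the ray's current energy is scored, the ray continues with the
remainder (ρ+τ)·E, and only the scatter *direction* is random (reflect vs
transmit chosen with probability ρ/(ρ+τ), then cosine-weighted about the
surface normal on the corresponding side).  Rays terminate on escape or after
``max_impacts`` interactions (residual energy scored as truncated), so
absorbed + escaped + truncated + opaque-absorbed = emitted to round-off.
"""

from __future__ import annotations

import numpy as np
from numba import njit

U64 = np.uint64
_GOLDEN = U64(0x9E3779B97F4A7C15)
_INV_2_53 = 1.0 / 9007199254740992.0


@njit(cache=True, inline="always")
def _mix64(z):
    z = (z ^ (z >> U64(30))) * U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> U64(27))) * U64(0x94D049BB133111EB)
    return z ^ (z >> U64(31))


@njit(cache=True, inline="always")
def _rand(state):
    """Uniform in [0, 1); advances the 1-element uint64 state array."""
    state[0] = state[0] + _GOLDEN
    z = _mix64(state[0])
    return (z >> U64(11)) * _INV_2_53


@njit(cache=True)
def build_grid(tris, gmin, cell, ndiv):
    """Bin triangle AABBs into a uniform grid; returns CSR (starts, items)."""
    m = tris.shape[0]
    nx, ny, nz = ndiv[0], ndiv[1], ndiv[2]
    ncell = nx * ny * nz
    lo = np.empty((m, 3), np.int64)
    hi = np.empty((m, 3), np.int64)
    for i in range(m):
        for a in range(3):
            tmin = min(tris[i, 0, a], min(tris[i, 1, a], tris[i, 2, a]))
            tmax = max(tris[i, 0, a], max(tris[i, 1, a], tris[i, 2, a]))
            l = int(np.floor((tmin - gmin[a]) / cell[a]))
            h = int(np.floor((tmax - gmin[a]) / cell[a]))
            lo[i, a] = min(max(l, 0), ndiv[a] - 1)
            hi[i, a] = min(max(h, 0), ndiv[a] - 1)
    counts = np.zeros(ncell + 1, np.int64)
    for i in range(m):
        for ix in range(lo[i, 0], hi[i, 0] + 1):
            for iy in range(lo[i, 1], hi[i, 1] + 1):
                for iz in range(lo[i, 2], hi[i, 2] + 1):
                    counts[ix * ny * nz + iy * nz + iz + 1] += 1
    starts = np.cumsum(counts)
    items = np.empty(starts[-1], np.int64)
    fill = starts[:-1].copy()
    for i in range(m):
        for ix in range(lo[i, 0], hi[i, 0] + 1):
            for iy in range(lo[i, 1], hi[i, 1] + 1):
                for iz in range(lo[i, 2], hi[i, 2] + 1):
                    c = ix * ny * nz + iy * nz + iz
                    items[fill[c]] = i
                    fill[c] += 1
    return starts, items


@njit(cache=True, inline="always")
def _ray_triangle(tris, i, ox, oy, oz, dx, dy, dz, eps_t):
    """Möller–Trumbore; returns hit distance t or −1."""
    e1x = tris[i, 1, 0] - tris[i, 0, 0]
    e1y = tris[i, 1, 1] - tris[i, 0, 1]
    e1z = tris[i, 1, 2] - tris[i, 0, 2]
    e2x = tris[i, 2, 0] - tris[i, 0, 0]
    e2y = tris[i, 2, 1] - tris[i, 0, 1]
    e2z = tris[i, 2, 2] - tris[i, 0, 2]
    px = dy * e2z - dz * e2y
    py = dz * e2x - dx * e2z
    pz = dx * e2y - dy * e2x
    det = e1x * px + e1y * py + e1z * pz
    if -1e-14 < det < 1e-14:
        return -1.0
    inv = 1.0 / det
    tx = ox - tris[i, 0, 0]
    ty = oy - tris[i, 0, 1]
    tz = oz - tris[i, 0, 2]
    u = (tx * px + ty * py + tz * pz) * inv
    if u < -1e-12 or u > 1.0 + 1e-12:
        return -1.0
    qx = ty * e1z - tz * e1y
    qy = tz * e1x - tx * e1z
    qz = tx * e1y - ty * e1x
    v = (dx * qx + dy * qy + dz * qz) * inv
    if v < -1e-12 or u + v > 1.0 + 1e-12:
        return -1.0
    t = (e2x * qx + e2y * qy + e2z * qz) * inv
    if t <= eps_t:
        return -1.0
    return t


@njit(cache=True)
def _nearest_hit(tris, gmin, gmax, cell, ndiv, starts, items,
                 ox, oy, oz, dx, dy, dz, eps_t):
    """Nearest triangle along a ray via DDA grid traversal; (-1, inf) on miss."""
    # Clip ray to the grid AABB.
    t0 = 0.0
    t1 = 1.0e300
    o = (ox, oy, oz)
    d = (dx, dy, dz)
    for a in range(3):
        if abs(d[a]) < 1e-300:
            if o[a] < gmin[a] or o[a] > gmax[a]:
                return -1, 1.0e300
        else:
            ta = (gmin[a] - o[a]) / d[a]
            tb = (gmax[a] - o[a]) / d[a]
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
    if t0 > t1:
        return -1, 1.0e300
    tcur = t0 + 1e-12
    px = ox + tcur * dx
    py = oy + tcur * dy
    pz = oz + tcur * dz
    ix = min(max(int(np.floor((px - gmin[0]) / cell[0])), 0), ndiv[0] - 1)
    iy = min(max(int(np.floor((py - gmin[1]) / cell[1])), 0), ndiv[1] - 1)
    iz = min(max(int(np.floor((pz - gmin[2]) / cell[2])), 0), ndiv[2] - 1)
    idx = (ix, iy, iz)
    step = np.empty(3, np.int64)
    tmaxv = np.empty(3, np.float64)
    tdelta = np.empty(3, np.float64)
    ii = np.empty(3, np.int64)
    ii[0], ii[1], ii[2] = ix, iy, iz
    for a in range(3):
        if d[a] > 1e-300:
            step[a] = 1
            tmaxv[a] = ((gmin[a] + (ii[a] + 1) * cell[a]) - o[a]) / d[a]
            tdelta[a] = cell[a] / d[a]
        elif d[a] < -1e-300:
            step[a] = -1
            tmaxv[a] = ((gmin[a] + ii[a] * cell[a]) - o[a]) / d[a]
            tdelta[a] = -cell[a] / d[a]
        else:
            step[a] = 0
            tmaxv[a] = 1.0e300
            tdelta[a] = 1.0e300
    ny, nz = ndiv[1], ndiv[2]
    best_t = 1.0e300
    best_i = -1
    while True:
        c = ii[0] * ny * nz + ii[1] * nz + ii[2]
        for k in range(starts[c], starts[c + 1]):
            tri = items[k]
            t = _ray_triangle(tris, tri, ox, oy, oz, dx, dy, dz, eps_t)
            if 0.0 < t < best_t:
                best_t = t
                best_i = tri
        texit = min(tmaxv[0], min(tmaxv[1], tmaxv[2]))
        if best_i >= 0 and best_t <= texit + 1e-12:
            return best_i, best_t
        # advance to the next voxel
        if tmaxv[0] <= tmaxv[1] and tmaxv[0] <= tmaxv[2]:
            a = 0
        elif tmaxv[1] <= tmaxv[2]:
            a = 1
        else:
            a = 2
        ii[a] += step[a]
        if ii[a] < 0 or ii[a] >= ndiv[a]:
            break
        tmaxv[a] += tdelta[a]
    if best_i >= 0:
        return best_i, best_t
    return -1, 1.0e300


@njit(cache=True, inline="always")
def _cosine_sample(nx, ny, nz, u1, u2):
    """Cosine-weighted direction about unit normal (nx,ny,nz)."""
    r = np.sqrt(u1)
    phi = 6.283185307179586 * u2
    lx = r * np.cos(phi)
    ly = r * np.sin(phi)
    lz = np.sqrt(max(1.0 - u1, 0.0))
    # tangent frame
    if abs(nx) < 0.9:
        tx, ty, tz = 0.0, nz, -ny   # n × x̂... orthogonal to n
    else:
        tx, ty, tz = -nz, 0.0, nx
    norm = np.sqrt(tx * tx + ty * ty + tz * tz)
    tx, ty, tz = tx / norm, ty / norm, tz / norm
    bx = ny * tz - nz * ty
    by = nz * tx - nx * tz
    bz = nx * ty - ny * tx
    dx = lx * tx + ly * bx + lz * nx
    dy = lx * ty + ly * by + lz * ny
    dz = lx * tz + ly * bz + lz * nz
    return dx, dy, dz


@njit(cache=True)
def trace_emitter(tris, tri_leaf, normals,
                  gmin, gmax, cell, ndiv, starts, items,
                  emitter_kind, rect, z_emit, beam_dir, energy_per_ray,
                  rho, tau, max_impacts,
                  seed, ray_offset, n_rays, n_batches,
                  absorbed, escaped, truncated, absorbed_other, eps_t):
    """Trace ``n_rays`` from one emitter, accumulating per-batch scores.

    emitter_kind 0 = parallel beam (direction ``beam_dir``), 1 = isotropic
    diffuse sky (cosine-weighted downward).  ``absorbed`` has shape
    (n_batches, n_leaves); escaped/truncated/absorbed_other (n_batches,).
    """
    absorb_frac = 1.0 - rho - tau
    cont = rho + tau
    p_reflect = rho / cont if cont > 0.0 else 0.0
    have_tris = tris.shape[0] > 0
    state = np.empty(1, U64)
    for i in range(n_rays):
        b = i % n_batches
        state[0] = _mix64((U64(seed) + U64(1)) * _GOLDEN
                          ^ (U64(ray_offset + i) + U64(1)) * U64(0xBF58476D1CE4E5B9))
        u1 = _rand(state)
        u2 = _rand(state)
        ox = rect[0] + u1 * (rect[1] - rect[0])
        oy = rect[2] + u2 * (rect[3] - rect[2])
        oz = z_emit
        if emitter_kind == 0:
            dx, dy, dz = beam_dir[0], beam_dir[1], beam_dir[2]
        else:
            dx, dy, dz = _cosine_sample(0.0, 0.0, -1.0, _rand(state), _rand(state))
        energy = energy_per_ray
        alive = True
        for _imp in range(max_impacts):
            if have_tris:
                tri, t = _nearest_hit(tris, gmin, gmax, cell, ndiv, starts,
                                      items, ox, oy, oz, dx, dy, dz, eps_t)
            else:
                tri, t = -1, 1.0e300
            if tri < 0:
                escaped[b] += energy
                alive = False
                break
            hx = ox + t * dx
            hy = oy + t * dy
            hz = oz + t * dz
            leaf = tri_leaf[tri]
            if leaf < 0:  # opaque black surface: full absorption
                absorbed_other[b] += energy
                alive = False
                break
            absorbed[b, leaf] += absorb_frac * energy
            if cont <= 0.0:
                alive = False
                break
            energy *= cont
            nx, ny, nz = normals[tri, 0], normals[tri, 1], normals[tri, 2]
            if dx * nx + dy * ny + dz * nz > 0.0:
                nx, ny, nz = -nx, -ny, -nz
            if _rand(state) >= p_reflect:  # transmit: hemisphere on far side
                nx, ny, nz = -nx, -ny, -nz
            dx, dy, dz = _cosine_sample(nx, ny, nz, _rand(state), _rand(state))
            ox = hx + eps_t * dx
            oy = hy + eps_t * dy
            oz = hz + eps_t * dz
        if alive:
            truncated[b] += energy
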