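"""Numba kernels for the hot paths: spot dose deposition and trilinear resampling.

These are deliberately simple, allocation-light loops; everything
vectorizable at a higher level (scenario enumeration, DVH statistics,
accumulation) lives in numpy.  The Bragg-curve closed form here must stay in
sync with ``dose_engine.depth_dose`` (the vectorized reference used by the
tests).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# distal falloff is modelled as a truncated Gaussian; the curve reaches exactly
# zero at nominal_range + FALLOFF_CUTOFF_SIGMA * falloff_sigma
FALLOFF_CUTOFF_SIGMA = 3.0
LATERAL_CUTOFF_SIGMA = 3.0
_BUILDUP_FLOOR = 0.25  # entrance dose relative to the Bragg peak


@njit(cache=True, fastmath=True)
def _bragg(depth, nominal_range, falloff_sigma):
    """Peaked depth-dose surrogate: power-law build-up, truncated-Gaussian tail."""
    if depth < 0.0:
        return 0.0
    end = nominal_range + FALLOFF_CUTOFF_SIGMA * falloff_sigma
    if depth >= end:
        return 0.0
    if depth <= nominal_range:
        x = depth / nominal_range
        return _BUILDUP_FLOOR + (1.0 - _BUILDUP_FLOOR) * x * x * x
    t = (depth - nominal_range) / falloff_sigma
    edge = np.exp(-0.5 * FALLOFF_CUTOFF_SIGMA * FALLOFF_CUTOFF_SIGMA)
    g = (np.exp(-0.5 * t * t) - edge) / (1.0 - edge)
    return g if g > 0.0 else 0.0


@njit(cache=True, fastmath=True)
def deposit_spots(
    dose,        # (nx, ny, nz) float64, accumulated in place
    l1_sorted,   # (nx*ny,) first lateral beam coordinate, ascending
    l1_order,    # (nx*ny,) flat (ix*ny + iy) index for each sorted entry
    zc,          # (nz,) world z of voxel centers (second lateral coordinate)
    wepl,        # (nx, ny, nz) water-equivalent depth of each voxel, mm
    rho_scale,   # density/range scaling of the scenario
    d1, d2,      # lateral components of the scenario setup shift, mm
    p1, p2, rng, wt, sig,  # per-spot arrays: lateral position, range, weight, sigma
    falloff_sigma,
    medium,      # (nx, ny, nz) uint8: 1 where dose is scored (density > 0)
):
    nx, ny, nz = wepl.shape
    z0 = zc[0]
    dz = zc[1] - zc[0] if nz > 1 else 1.0
    g2 = np.empty(nz)
    for s in range(p1.shape[0]):
        if wt[s] == 0.0:
            continue
        cut = LATERAL_CUTOFF_SIGMA * sig[s]
        inv2s2 = 0.5 / (sig[s] * sig[s])
        # exact z-index window from the second lateral coordinate
        zcen = p2[s] - d2
        klo = int(np.ceil((zcen - cut - z0) / dz))
        khi = int(np.floor((zcen + cut - z0) / dz))
        if klo < 0:
            klo = 0
        if khi > nz - 1:
            khi = nz - 1
        if khi < klo:
            continue
        for k in range(klo, khi + 1):
            a2 = zc[k] + d2 - p2[s]
            g2[k] = np.exp(-a2 * a2 * inv2s2)
        dmax = rng[s] + FALLOFF_CUTOFF_SIGMA * falloff_sigma
        lcen = p1[s] - d1
        jlo = np.searchsorted(l1_sorted, lcen - cut)
        jhi = np.searchsorted(l1_sorted, lcen + cut)
        for j in range(jlo, jhi):
            a = l1_sorted[j] - lcen
            g1w = wt[s] * np.exp(-a * a * inv2s2)
            flat = l1_order[j]
            ix = flat // ny
            iy = flat - ix * ny
            for iz in range(klo, khi + 1):
                if medium[ix, iy, iz] == 0:
                    continue
                depth = wepl[ix, iy, iz] * rho_scale
                if depth >= dmax:
                    continue
                b = _bragg(depth, rng[s], falloff_sigma)
                if b > 0.0:
                    dose[ix, iy, iz] += g1w * g2[iz] * b


@njit(cache=True, fastmath=True)
def spot_columns(
    l1_sorted, l1_order, zc, wepl, rho_scale, d1, d2,
    p1, p2, rng, sig, falloff_sigma,
    medium,                       # (nx, ny, nz) uint8: 1 where dose is scored
    row_map,                      # (nvox,) compressed row id per voxel, -1 = skip
    out_idx, out_val, indptr,
):
    """Per-spot sparse dose columns (unit weight) in CSC layout, restricted to
    the voxels selected by ``row_map``.

    ``out_idx``/``out_val`` must be preallocated; ``indptr`` has length
    n_spots + 1.  Returns the total number of entries written, or -1 if the
    preallocated capacity was exceeded (caller retries with a larger buffer).
    """
    nx, ny, nz = wepl.shape
    z0 = zc[0]
    dz = zc[1] - zc[0] if nz > 1 else 1.0
    cap = out_idx.shape[0]
    g2 = np.empty(nz)
    pos = 0
    indptr[0] = 0
    for s in range(p1.shape[0]):
        cut = LATERAL_CUTOFF_SIGMA * sig[s]
        inv2s2 = 0.5 / (sig[s] * sig[s])
        zcen = p2[s] - d2
        klo = int(np.ceil((zcen - cut - z0) / dz))
        khi = int(np.floor((zcen + cut - z0) / dz))
        if klo < 0:
            klo = 0
        if khi > nz - 1:
            khi = nz - 1
        for k in range(klo, khi + 1):
            a2 = zc[k] + d2 - p2[s]
            g2[k] = np.exp(-a2 * a2 * inv2s2)
        dmax = rng[s] + FALLOFF_CUTOFF_SIGMA * falloff_sigma
        lcen = p1[s] - d1
        jlo = np.searchsorted(l1_sorted, lcen - cut)
        jhi = np.searchsorted(l1_sorted, lcen + cut)
        for j in range(jlo, jhi):
            a = l1_sorted[j] - lcen
            g1 = np.exp(-a * a * inv2s2)
            flat = l1_order[j]
            ix = flat // ny
            iy = flat - ix * ny
            base = flat * nz
            for iz in range(klo, khi + 1):
                if medium[ix, iy, iz] == 0:
                    continue
                row = row_map[base + iz]
                if row < 0:
                    continue
                depth = wepl[ix, iy, iz] * rho_scale
                if depth >= dmax:
                    continue
                b = _bragg(depth, rng[s], falloff_sigma)
                if b <= 0.0:
                    continue
                if pos >= cap:
                    return -1
                out_idx[pos] = row
                out_val[pos] = g1 * g2[iz] * b
                pos += 1
        indptr[s + 1] = pos
    return pos


@njit(cache=True)
def trilinear(vol, cx, cy, cz, out, zero_outside):
    """Sample ``vol`` at fractional index coordinates (flat arrays).

    ``zero_outside``: outside the grid the field is 0 (used for densities and
    masks); otherwise coordinates are clamped to the boundary.
    """
    nx, ny, nz = vol.shape
    n = cx.shape[0]
    for i in range(n):
        x = cx[i]
        y = cy[i]
        z = cz[i]
        if zero_outside and (
            x < -1.0 or x > nx or y < -1.0 or y > ny or z < -1.0 or z > nz
        ):
            out[i] = 0.0
            continue
        if x < 0.0:
            x = 0.0
        elif x > nx - 1:
            x = nx - 1.0
        if y < 0.0:
            y = 0.0
        elif y > ny - 1:
            y = ny - 1.0
        if z < 0.0:
            z = 0.0
        elif z > nz - 1:
            z = nz - 1.0
        i0 = int(x)
        j0 = int(y)
        k0 = int(z)
        if i0 > nx - 2:
            i0 = nx - 2 if nx > 1 else 0
        if j0 > ny - 2:
            j0 = ny - 2 if ny > 1 else 0
        if k0 > nz - 2:
            k0 = nz - 2 if nz > 1 else 0
        fx = x - i0
        fy = y - j0
        fz = z - k0
        i1 = i0 + 1 if nx > 1 else i0
        j1 = j0 + 1 if ny > 1 else j0
        k1 = k0 + 1 if nz > 1 else k0
        c00 = vol[i0, j0, k0] * (1 - fx) + vol[i1, j0, k0] * fx
        c10 = vol[i0, j1, k0] * (1 - fx) + vol[i1, j1, k0] * fx
        c01 = vol[i0, j0, k1] * (1 - fx) + vol[i1, j0, k1] * fx
        c11 = vol[i0, j1, k1] * (1 - fx) + vol[i1, j1, k1] * fx
        c0 = c00 * (1 - fy) + c10 * fy
        c1 = c01 * (1 - fy) + c11 * fy
        out[i] = c0 * (1 - fz) + c1 * fz


def sample_volume(vol, coords, zero_outside=True):
    """Convenience wrapper: trilinear sampling at index coords of shape (..., 3)."""
    vol = np.ascontiguousarray(vol, dtype=np.float64)
    c = np.asarray(coords, dtype=np.float64)
    flat = c.reshape(-1, 3)
    out = np.empty(flat.shape[0], dtype=np.float64)
    trilinear(
        vol,
        np.ascontiguousarray(flat[:, 0]),
        np.ascontiguousarray(flat[:, 1]),
        np.ascontiguousarray(flat[:, 2]),
        out,
        zero_outside,
    )
    return out.reshape(c.shape[:-1])


@njit(cache=True, fastmath=True)
def deposit_spots_multi(
    doses,       # (nx, ny, nz, C) float64, accumulated in place
    l1_sorted, l1_order, zc, wepl,
    rho,         # (C,) density scale per scenario
    rho_group,   # (C,) index into the distinct density values
    n_groups,
    d1, d2,      # (C,) lateral shift components per scenario
    p1, p2, rng, sig,      # per-spot arrays
    weights,     # (C, n_spots) per-scenario spot weights
    falloff_sigma, medium,
):
    """Scenario-batched variant of ``deposit_spots``: one pass over each
    spot's support evaluates all scenarios, sharing the WEPL loads and the
    band search.  Bragg values are cached per distinct density scale."""
    nx, ny, nz = wepl.shape
    C = rho.shape[0]
    z0 = zc[0]
    dz = zc[1] - zc[0] if nz > 1 else 1.0
    g2 = np.empty((C, nz))
    g1 = np.empty(C)
    bcache = np.empty(n_groups)
    bvalid = np.empty(n_groups, dtype=np.uint8)
    active = np.empty(C, dtype=np.int64)
    rho_min = rho[0]
    for c in range(C):
        if rho[c] < rho_min:
            rho_min = rho[c]
    for s in range(p1.shape[0]):
        na = 0
        for c in range(C):
            if weights[c, s] != 0.0:
                active[na] = c
                na += 1
        if na == 0:
            continue
        cut = LATERAL_CUTOFF_SIGMA * sig[s]
        inv2s2 = 0.5 / (sig[s] * sig[s])
        # union z-window over the active scenarios
        zlo_mm = 1e30
        zhi_mm = -1e30
        for a in range(na):
            c = active[a]
            zcen = p2[s] - d2[c]
            if zcen - cut < zlo_mm:
                zlo_mm = zcen - cut
            if zcen + cut > zhi_mm:
                zhi_mm = zcen + cut
        klo = int(np.ceil((zlo_mm - z0) / dz))
        khi = int(np.floor((zhi_mm - z0) / dz))
        if klo < 0:
            klo = 0
        if khi > nz - 1:
            khi = nz - 1
        if khi < klo:
            continue
        for a in range(na):
            c = active[a]
            for k in range(klo, khi + 1):
                a2 = zc[k] + d2[c] - p2[s]
                g2[c, k] = np.exp(-a2 * a2 * inv2s2) if abs(a2) <= cut else 0.0
        dmax_lo = rng[s] + FALLOFF_CUTOFF_SIGMA * falloff_sigma
        # union lateral band
        blo = 1e30
        bhi = -1e30
        for a in range(na):
            c = active[a]
            lcen = p1[s] - d1[c]
            if lcen - cut < blo:
                blo = lcen - cut
            if lcen + cut > bhi:
                bhi = lcen + cut
        jlo = np.searchsorted(l1_sorted, blo)
        jhi = np.searchsorted(l1_sorted, bhi)
        for j in range(jlo, jhi):
            lv = l1_sorted[j]
            for a in range(na):
                c = active[a]
                av = lv - (p1[s] - d1[c])
                g1[c] = (
                    weights[c, s] * np.exp(-av * av * inv2s2)
                    if -cut <= av <= cut
                    else 0.0
                )
            flat = l1_order[j]
            ix = flat // ny
            iy = flat - ix * ny
            for iz in range(klo, khi + 1):
                if medium[ix, iy, iz] == 0:
                    continue
                wv = wepl[ix, iy, iz]
                if wv * rho_min >= dmax_lo:   # distal of the peak in every scenario
                    continue
                for g in range(n_groups):
                    bvalid[g] = 0
                for a in range(na):
                    c = active[a]
                    g1c = g1[c]
                    if g1c == 0.0:
                        continue
                    g2c = g2[c, iz]
                    if g2c == 0.0:
                        continue
                    grp = rho_group[c]
                    if bvalid[grp] == 0:
                        bcache[grp] = _bragg(wv * rho[c], rng[s], falloff_sigma)
                        bvalid[grp] = 1
                    b = bcache[grp]
                    if b > 0.0:
                        doses[ix, iy, iz, c] += g1c * g2c * b
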