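"""Two-point asymmetric-echo water/fat separation.

Signal model per voxel (single-peak fat, real nonnegative amplitudes):

    s(TE_n) = (W + c(TE_n) F) * exp(i (2 pi psi TE_n + phi0)),
    c(TE)   = exp(2i pi f_fat TE)

with unknowns W, F >= 0, off-resonance psi (Hz) and a global receiver phase
phi0.  For a trial psi the echoes are demodulated and phi0 is eliminated in
closed form (smallest eigenvalue of a 2x2 normal matrix), leaving a 1D
residual R(psi).  The solver

1. enumerates candidate field-map values on a grid spanning one aliasing
   period and keeps the two best local minima per voxel,
2. resolves the water/fat ambiguity by magnitude-ordered region growing
   under a spatial-smoothness criterion on psi,
3. refines psi per voxel with a damped Newton iteration on R(psi), and
4. solves the linear system for W and F at the converged psi.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .phantom import DualEchoComplex

logger = logging.getLogger(__name__)

DEFINED_REL_THRESHOLD = 1e-6


@dataclass
class WaterFatResult:
    water: np.ndarray          # |W| per voxel
    fat: np.ndarray            # |F| per voxel
    fieldmap_hz: np.ndarray
    residual: np.ndarray       # squared residual norm per voxel
    defined: np.ndarray        # bool, amplitude above threshold
    converged: np.ndarray      # bool, refinement met tolerance


class _Model:
    """Precomputed linear system for fixed echo times and fat shift."""

    def __init__(self, echo_times_ms: Tuple[float, float], fat_shift_hz: float):
        self.te = np.asarray(echo_times_ms, dtype=float) * 1e-3
        self.c = np.exp(2j * np.pi * fat_shift_hz * self.te)
        c1, c2 = self.c
        self.A = np.array(
            [
                [1.0, c1.real],
                [0.0, c1.imag],
                [1.0, c2.real],
                [0.0, c2.imag],
            ]
        )
        self.pinvA = np.linalg.pinv(self.A)
        self.P = np.eye(4) - self.A @ self.pinvA
        self.alias_period = 1.0 / (self.te[1] - self.te[0])

    def _b_columns(self, s1, s2, psi):
        e1 = np.exp(-2j * np.pi * psi * self.te[0])
        e2 = np.exp(-2j * np.pi * psi * self.te[1])
        sp1, sp2 = s1 * e1, s2 * e2
        b_cos = np.stack([sp1.real, sp1.imag, sp2.real, sp2.imag], axis=-1)
        b_sin = np.stack([sp1.imag, -sp1.real, sp2.imag, -sp2.real], axis=-1)
        return b_cos, b_sin

    def _normal_matrix(self, s1, s2, psi):
        b_cos, b_sin = self._b_columns(s1, s2, psi)
        pc = b_cos @ self.P
        ps = b_sin @ self.P
        m00 = np.sum(pc * b_cos, axis=-1)
        m01 = np.sum(pc * b_sin, axis=-1)
        m11 = np.sum(ps * b_sin, axis=-1)
        return b_cos, b_sin, m00, m01, m11

    def residual(self, s1, s2, psi):
        """R(psi): least-squares residual with phi0 and W, F eliminated."""
        _, _, m00, m01, m11 = self._normal_matrix(s1, s2, psi)
        disc = np.sqrt((m00 - m11) ** 2 + 4.0 * m01**2)
        return np.maximum(0.5 * (m00 + m11 - disc), 0.0)

    def solve_amplitudes(self, s1, s2, psi):
        """W, F and residual at fixed psi (phi0 from the minimizing phase)."""
        b_cos, b_sin, m00, m01, m11 = self._normal_matrix(s1, s2, psi)
        disc = np.sqrt((m00 - m11) ** 2 + 4.0 * m01**2)
        lam = 0.5 * (m00 + m11 - disc)
        # eigenvector of the 2x2 normal matrix for the smallest eigenvalue
        v0a, v1a = m01, lam - m00
        v0b, v1b = lam - m11, m01
        use_a = v0a**2 + v1a**2 >= v0b**2 + v1b**2
        v0 = np.where(use_a, v0a, v0b)
        v1 = np.where(use_a, v1a, v1b)
        norm = np.hypot(v0, v1)
        deg = norm < 1e-30
        v0 = np.where(deg, 1.0, v0 / np.where(deg, 1.0, norm))
        v1 = np.where(deg, 0.0, v1 / np.where(deg, 1.0, norm))
        b = b_cos * v0[..., None] + b_sin * v1[..., None]
        wf = b @ self.pinvA.T
        flip = wf.sum(axis=-1) < 0
        wf = np.where(flip[..., None], -wf, wf)
        return wf[..., 0], wf[..., 1], np.maximum(lam, 0.0)


def _candidates(model: _Model, s1, s2, n_grid: int):
    """Two best circular local minima of R(psi) per voxel on a period grid."""
    grid = np.linspace(-model.alias_period / 2, model.alias_period / 2, n_grid, endpoint=False)
    R = np.stack([model.residual(s1, s2, p) for p in grid])
    is_min = (R <= np.roll(R, 1, axis=0)) & (R <= np.roll(R, -1, axis=0))
    R_masked = np.where(is_min, R, np.inf)
    order = np.argsort(R_masked, axis=0)
    best = order[0]
    second = order[1]
    n = s1.shape[0]
    cand_psi = np.stack([grid[best], grid[second]], axis=-1)
    cand_R = np.stack([R_masked[best, np.arange(n)], R_masked[second, np.arange(n)]], axis=-1)
    # voxels with a single local minimum: duplicate it
    dup = ~np.isfinite(cand_R[:, 1])
    cand_psi[dup, 1] = cand_psi[dup, 0]
    cand_R[dup, 1] = cand_R[dup, 0]
    return cand_psi, cand_R


def _refine(model: _Model, s1, s2, psi, iters: int, tol_hz: float):
    """Damped Newton minimization of R(psi), vectorized over voxels."""
    psi = np.array(psi, dtype=float)
    delta = 0.25
    # residual floor: minima at the numerical noise level count as converged
    floor = 1e-12 * 0.5 * (np.abs(s1) ** 2 + np.abs(s2) ** 2)
    conv = np.zeros(psi.shape, dtype=bool)
    for _ in range(iters):
        active = ~conv
        if not np.any(active):
            break
        p = psi[active]
        sa, sb = s1[active], s2[active]
        r0 = model.residual(sa, sb, p)
        at_floor = r0 <= floor[active]
        rp = model.residual(sa, sb, p + delta)
        rm = model.residual(sa, sb, p - delta)
        g = (rp - rm) / (2 * delta)
        h = (rp - 2 * r0 + rm) / delta**2
        step = np.where(h > 1e-300, -g / np.where(h > 1e-300, h, 1.0), -np.sign(g) * delta)
        step = np.clip(step, -25.0, 25.0)
        trial = p + step
        accept = model.residual(sa, sb, trial) <= r0
        psi[active] = np.where(accept, np.where(at_floor, p, trial), p)
        # a tiny proposed step means we are at a (local) minimum
        conv[active] = (np.abs(step) < tol_hz) | at_floor
    return psi, conv


def _neighbor_offsets(radius: int) -> list:
    offs = []
    r = max(int(radius), 1)
    for dz in range(-r, r + 1):
        for dy in range(-r, r + 1):
            for dx in range(-r, r + 1):
                if (dz, dy, dx) != (0, 0, 0):
                    offs.append((dz, dy, dx))
    return offs


def _region_grow(shape, mask, magnitude, cand_psi, cand_R, radius: int) -> np.ndarray:
    """Assign one candidate psi per in-mask voxel, growing from high magnitude.

    The seed takes its lowest-residual candidate (ties broken toward the
    smaller |psi|, i.e. the solution nearest on-resonance); every other voxel
    takes the candidate closest to the mean psi of its already-assigned
    neighbors.  Disconnected in-mask components are re-seeded.
    """
    nz, ny, nx = shape
    lin_index = np.full(shape, -1, dtype=np.int64)
    coords = np.argwhere(mask)
    lin_index[mask] = np.arange(coords.shape[0])
    psi = np.zeros(coords.shape[0])
    visited = np.zeros(coords.shape[0], dtype=bool)
    offsets = _neighbor_offsets(radius)

    mag = magnitude
    remaining_order = np.argsort(-mag, kind="stable")
    remaining_ptr = 0

    heap: list = []
    counter = 0
    while True:
        while remaining_ptr < len(remaining_order) and visited[remaining_order[remaining_ptr]]:
            remaining_ptr += 1
        if remaining_ptr >= len(remaining_order) and not heap:
            break
        if not heap:
            seed = int(remaining_order[remaining_ptr])
            heapq.heappush(heap, (-mag[seed], counter, seed))
            counter += 1
        neg_m, _, i = heapq.heappop(heap)
        if visited[i]:
            continue
        z, y, x = coords[i]
        acc = 0.0
        n_nb = 0
        for dz, dy, dx in offsets:
            zz, yy, xx = z + dz, y + dy, x + dx
            if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx:
                j = lin_index[zz, yy, xx]
                if j >= 0 and visited[j]:
                    acc += psi[j]
                    n_nb += 1
        if n_nb:
            target = acc / n_nb
            pick = 0 if abs(cand_psi[i, 0] - target) <= abs(cand_psi[i, 1] - target) else 1
        else:
            # seed: both candidates can be exact solutions of the two-point
            # system, so prefer the one nearest on-resonance when residuals
            # are comparable on the scale of the voxel's signal energy
            tie_tol = 0.01 * max(mag[i] ** 2, 1e-300)
            pick = 0 if cand_R[i, 0] <= cand_R[i, 1] else 1
            other = 1 - pick
            if cand_R[i, other] <= cand_R[i, pick] + tie_tol and abs(cand_psi[i, other]) < abs(
                cand_psi[i, pick]
            ):
                pick = other
        psi[i] = cand_psi[i, pick]
        visited[i] = True
        for dz, dy, dx in offsets:
            zz, yy, xx = z + dz, y + dy, x + dx
            if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx:
                j = lin_index[zz, yy, xx]
                if j >= 0 and not visited[j]:
                    heapq.heappush(heap, (-mag[j], counter, j))
                    counter += 1
    return psi


def separate(
    data: DualEchoComplex,
    n_fieldmap_candidates: int = 64,
    smoothing_radius: int = 1,
    refine_iters: int = 20,
    tol_hz: float = 0.01,
    mask: Optional[np.ndarray] = None,
) -> WaterFatResult:
    """Estimate per-voxel water/fat amplitudes and the off-resonance field."""
    model = _Model(data.echo_times, data.fat_shift_hz)
    shape = data.echo1.shape
    s1f = np.asarray(data.echo1).ravel()
    s2f = np.asarray(data.echo2).ravel()
    mag = 0.5 * (np.abs(s1f) + np.abs(s2f))
    peak = mag.max() if mag.size else 0.0

    water = np.zeros(shape)
    fat = np.zeros(shape)
    fieldmap = np.zeros(shape)
    residual = np.zeros(shape)
    defined = np.zeros(shape, dtype=bool)
    converged = np.zeros(shape, dtype=bool)
    if peak <= 0:
        return WaterFatResult(water, fat, fieldmap, residual, defined, converged)

    threshold = DEFINED_REL_THRESHOLD * peak
    if mask is None:
        mask3 = (mag > threshold).reshape(shape)
    else:
        mask3 = np.asarray(mask, dtype=bool) & (mag > threshold).reshape(shape)
    sel = mask3.ravel()
    s1, s2 = s1f[sel], s2f[sel]

    cand_psi, cand_R = _candidates(model, s1, s2, n_fieldmap_candidates)
    # polish each candidate to its local minimum before the ambiguity is
    # resolved spatially; grid-resolution residuals would otherwise mask ties
    for k in (0, 1):
        cand_psi[:, k], _ = _refine(model, s1, s2, cand_psi[:, k], refine_iters, tol_hz)
        cand_R[:, k] = model.residual(s1, s2, cand_psi[:, k])
    psi = _region_grow(shape, mask3, mag[sel], cand_psi, cand_R, smoothing_radius)
    psi, conv = _refine(model, s1, s2, psi, refine_iters, tol_hz)

    W, F, R = model.solve_amplitudes(s1, s2, psi)
    n_unconv = int(np.sum(~conv))
    if n_unconv:
        logger.warning("dixon refinement: %d voxels not converged; last iterate kept", n_unconv)

    water[mask3] = np.maximum(W, 0.0)
    fat[mask3] = np.maximum(F, 0.0)
    fieldmap[mask3] = psi
    residual[mask3] = R
    converged[mask3] = conv
    defined[mask3] = (water[mask3] + fat[mask3]) > threshold
    return WaterFatResult(water, fat, fieldmap, residual, defined, converged)


def water_percent_map(result: WaterFatResult) -> np.ndarray:
    """100 * |W| / (|W| + |F|); NaN where the separation is undefined."""
    total = result.water + result.fat
    out = np.full(total.shape, np.nan)
    ok = result.defined & (total > 0)
    out[ok] = 100.0 * result.water[ok] / total[ok]
    return out
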