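"""Voxelwise T2 mapping by ordinary least squares on log-intensity.

For each voxel, ln S is regressed against echo time; T2 = -1/slope and
S0 = exp(intercept).  Voxels with any echo at or below the intensity floor,
or with a non-negative slope, are flagged invalid rather than zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .phantom import MultiEchoStack


@dataclass
class T2Map:
    t2_ms: np.ndarray       # NaN where invalid
    s0: np.ndarray
    r_squared: np.ndarray
    valid: np.ndarray
    t2_clamp_ms: float


def fit_t2_map(
    stack: MultiEchoStack,
    mask: Optional[np.ndarray] = None,
    min_intensity: float = 1.0,
    t2_clamp_ms: float = 2000.0,
) -> T2Map:
    """Log-linear mono-exponential fit of a multi-echo magnitude stack.

    Parameters
    ----------
    stack
        Magnitude volumes (echo-first) with echo times in ms.
    mask
        Optional boolean volume restricting the fit.
    min_intensity
        Log-domain guard: voxels with any echo <= this value are invalid.
    t2_clamp_ms
        Upper clamp for the fitted T2; fitted values are in (0, t2_clamp_ms].
    """
    te = np.asarray(stack.echo_times, dtype=float)
    if te.size < 2:
        raise ValueError("need at least 2 echoes")
    if np.unique(te).size != te.size:
        raise ValueError("echo times must be distinct")
    vols = np.asarray(stack.volumes, dtype=float)
    shape = vols.shape[1:]
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise ValueError("mask shape mismatch")
    else:
        mask = np.ones(shape, dtype=bool)

    flat = vols.reshape(te.size, -1)
    sel = mask.ravel() & np.all(flat > min_intensity, axis=0)
    t2 = np.full(flat.shape[1], np.nan)
    s0 = np.full(flat.shape[1], np.nan)
    r2 = np.full(flat.shape[1], np.nan)
    valid = np.zeros(flat.shape[1], dtype=bool)

    if np.any(sel):
        y = np.log(flat[:, sel])
        te_c = te - te.mean()
        denom = float(np.sum(te_c**2))
        y_mean = y.mean(axis=0)
        slope = (te_c @ y) / denom
        s0_sel = np.exp(y_mean - slope * te.mean())  # intercept back-projected to TE = 0
        resid = y - (y_mean + np.outer(te_c, slope))
        ss_res = np.sum(resid**2, axis=0)
        ss_tot = np.sum((y - y_mean) ** 2, axis=0)
        ok = slope < 0
        with np.errstate(divide="ignore", invalid="ignore"):
            t2_sel = np.where(ok, -1.0 / np.where(ok, slope, -1.0), np.nan)
            r2_sel = np.where(ss_tot > 0, 1.0 - ss_res / np.where(ss_tot > 0, ss_tot, 1.0), 0.0)
        t2_sel = np.minimum(t2_sel, t2_clamp_ms)
        idx = np.nonzero(sel)[0]
        t2[idx[ok]] = t2_sel[ok]
        s0[idx[ok]] = s0_sel[ok]
        r2[idx[ok]] = r2_sel[ok]
        valid[idx[ok]] = True

    return T2Map(
        t2.reshape(shape), s0.reshape(shape), r2.reshape(shape), valid.reshape(shape), t2_clamp_ms
    )
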