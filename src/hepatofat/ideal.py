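"""IDEAL water/fat/field/R2* estimation from a multi-echo acquisition.

Each voxel is fit to

    y_i = (rho_w + rho_f e^{-j2pi df t_i}) e^{-j2pi phi t_i} e^{-R2* t_i} + eps_i

by alternating (i) an exact linear solve for the complex amplitudes given
(phi, R2*) and (ii) a damped Gauss-Newton update of (phi, R2*), with R2*
clamped non-negative and phi confined to the principal water-fat interval
(-|df|/2, +|df|/2]. The confinement resolves the chemical-shift/off-resonance
ambiguity the same way the three-point Dixon search does; when the true
off-resonance leaves that interval the best in-window solution is the
swapped one — the failure mode the downstream ROI heuristic targets.

Multi-start over field-frequency initializations guards against the swapped
local optimum; the start with minimal residual wins.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .types import FitResult, MultiEchoImage, PDFFMap, Protocol

__all__ = ["ideal_fit_voxel", "ideal_pdff_map", "pdff_from_components", "DEFAULT_R2STAR_START"]

DEFAULT_R2STAR_START = 30.0  # 1/s
_R2STAR_MAX = 2000.0  # safety clamp, far above the physiological range


def pdff_from_components(rho_w: float, rho_f: float) -> float:
    """PDFF = |rho_f| / (|rho_w| + |rho_f|); 0 when both amplitudes are 0."""
    rho_w = abs(rho_w)
    rho_f = abs(rho_f)
    total = rho_w + rho_f
    return rho_f / total if total > 0 else 0.0


def _solve_amplitudes(y, e, c):
    """Closed-form 2x2 complex normal equations for (rho_w, rho_f).

    y, e: (V, n) with e the (phi, R2*) demodulation basis; c: (n,) fat phasor.
    """
    g = (e.real**2 + e.imag**2)  # |e_i|^2, real (V, n)
    m00 = g.sum(axis=1)
    m01 = (g * c[None, :]).sum(axis=1)  # sum c_i |e_i|^2, complex
    ec = e.conj()
    b0 = (ec * y).sum(axis=1)
    b1 = (ec * c[None, :].conj() * y).sum(axis=1)
    det = m00 * m00 - (m01.real**2 + m01.imag**2)
    det = np.where(det > 0, det, np.finfo(float).tiny)
    a0 = (m00 * b0 - m01 * b1) / det
    a1 = (m00 * b1 - m01.conj() * b0) / det
    return a0, a1


def _fit_ideal_stack(
    y: np.ndarray,
    times: np.ndarray,
    fat_shift: float,
    starts: Sequence[float],
    r2_start: float = DEFAULT_R2STAR_START,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> dict:
    """Vectorized multi-start fit of a (V, n_echo) stack.

    Returns dict of arrays: rho_w, rho_f, phi, r2star, residual, iterations,
    converged, degenerate.
    """
    V, n = y.shape
    c = np.exp(-1j * 2 * np.pi * fat_shift * times)  # (n,)
    half = abs(fat_shift) / 2.0
    two_pi_t = 2 * np.pi * times

    best = None
    for phi0 in starts:
        phi = np.full(V, float(phi0))
        r2 = np.full(V, float(r2_start))
        lam = np.full(V, 1e-3)
        iters = np.zeros(V, dtype=int)
        conv = np.zeros(V, dtype=bool)

        def model_and_res(phi_v, r2_v):
            e = np.exp((-1j * 2 * np.pi * phi_v[:, None] - r2_v[:, None]) * times[None, :])
            a0, a1 = _solve_amplitudes(y, e, c)
            m = (a0[:, None] + a1[:, None] * c[None, :]) * e
            r = y - m
            res2 = np.einsum("vi,vi->v", r, r.conj()).real
            return a0, a1, m, r, res2

        a0, a1, m, r, res2 = model_and_res(phi, r2)
        for it in range(max_iter):
            active = ~conv
            if not active.any():
                break
            # Gauss-Newton on (phi, R2*) holding amplitudes: dm/dphi = -j2pi t m,
            # dm/dR2 = -t m. The cross term Re(conj(J_phi) J_r2) vanishes, so
            # the two updates decouple.
            tm = times[None, :] * m
            jphi = -1j * 2 * np.pi * tm
            jr2 = -tm
            g_phi = np.einsum("vi,vi->v", jphi.conj(), r).real
            g_r2 = np.einsum("vi,vi->v", jr2.conj(), r).real
            h_phi = np.einsum("vi,vi->v", jphi.conj(), jphi).real
            h_r2 = np.einsum("vi,vi->v", jr2.conj(), jr2).real

            floor = np.finfo(float).tiny
            d_phi = g_phi / np.maximum(h_phi * (1.0 + lam), floor)
            d_r2 = g_r2 / np.maximum(h_r2 * (1.0 + lam), floor)

            phi_try = np.clip(phi + d_phi, -half, half)
            r2_try = np.clip(r2 + d_r2, 0.0, _R2STAR_MAX)
            a0_t, a1_t, m_t, r_t, res2_t = model_and_res(phi_try, r2_try)

            improve = res2_t <= res2
            accept = improve & active
            step_phi = np.abs(phi_try - phi)
            step_r2 = np.abs(r2_try - r2)
            rel_step = np.maximum(step_phi / (1.0 + np.abs(phi)), step_r2 / (1.0 + r2))

            phi = np.where(accept, phi_try, phi)
            r2 = np.where(accept, r2_try, r2)
            a0 = np.where(accept, a0_t, a0)
            a1 = np.where(accept, a1_t, a1)
            m = np.where(accept[:, None], m_t, m)
            r = np.where(accept[:, None], r_t, r)
            res2 = np.where(accept, res2_t, res2)
            lam = np.where(accept, np.maximum(lam * 0.3, 1e-9), np.minimum(lam * 6.0, 1e9))
            iters = iters + active.astype(int)

            newly_conv = active & (
                (accept & (rel_step < tol))
                | (res2 <= (np.einsum("vi,vi->v", y, y.conj()).real + 1.0) * 1e-28)
                | (~improve & (lam >= 1e8))
            )
            conv = conv | newly_conv

        res = np.sqrt(np.maximum(res2, 0.0))
        cand = {
            "rho_w": np.abs(a0),
            "rho_f": np.abs(a1),
            "phi": phi,
            "r2star": r2,
            "residual": res,
            "iterations": iters,
            "converged": conv,
        }
        if best is None:
            best = cand
        else:
            better = cand["residual"] < best["residual"]
            for key in best:
                best[key] = np.where(better, cand[key], best[key])

    zero = np.all(y == 0, axis=1)
    for key in ("rho_w", "rho_f", "phi", "r2star", "residual"):
        best[key] = np.where(zero, 0.0, best[key])
    best["converged"] = np.where(zero, True, best["converged"]).astype(bool)
    best["iterations"] = best["iterations"].astype(int)
    best["degenerate"] = zero
    return best


def ideal_fit_voxel(
    signal: np.ndarray,
    protocol: Protocol,
    starts: Optional[Sequence[float]] = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    r2_start: float = DEFAULT_R2STAR_START,
) -> FitResult:
    """Fit the four-parameter signal model to one voxel.

    ``starts`` are initial field-frequency guesses in Hz (default
    ``{-df/2, 0, +df/2}``); the start reaching the smallest residual wins.
    An all-zero signal returns a degenerate zero fit.
    """
    signal = np.asarray(signal, dtype=complex).reshape(1, -1)
    if signal.shape[1] < 4:
        raise ValueError("IDEAL fitting needs at least 4 echoes")
    if signal.shape[1] != protocol.n_echo:
        raise ValueError("signal length does not match protocol echo count")
    if tol <= 0:
        raise ValueError("tol must be positive")
    times = np.asarray(protocol.echo_times_s)
    df = protocol.fat_shift_hz
    if starts is None:
        starts = (-abs(df) / 2.0, 0.0, abs(df) / 2.0)
    out = _fit_ideal_stack(signal, times, df, starts, r2_start=r2_start, tol=tol, max_iter=max_iter)
    return FitResult(
        rho_w=float(out["rho_w"][0]),
        rho_f=float(out["rho_f"][0]),
        field_map_hz=float(out["phi"][0]),
        r2star=float(out["r2star"][0]),
        residual=float(out["residual"][0]),
        iterations=int(out["iterations"][0]),
        converged=bool(out["converged"][0]),
        degenerate=bool(out["degenerate"][0]),
    )


def ideal_pdff_map(
    image: MultiEchoImage,
    tol: float = 1e-8,
    max_iter: int = 100,
    starts: Optional[Sequence[float]] = None,
) -> PDFFMap:
    """Voxelwise IDEAL fit inside the mask; returns PDFF, R2* and field maps.

    Voxels whose fit did not converge (or were degenerate) are flagged in
    ``convergence_mask``.
    """
    protocol = image.protocol
    if protocol.n_echo < 4:
        raise ValueError("IDEAL fitting needs at least 4 echoes")
    times = np.asarray(protocol.echo_times_s)
    df = protocol.fat_shift_hz
    if starts is None:
        starts = (-abs(df) / 2.0, 0.0, abs(df) / 2.0)

    mask = image.truth.mask if image.truth is not None else np.ones(image.shape, dtype=bool)
    y = image.data[mask]
    out = _fit_ideal_stack(y, times, df, starts, tol=tol, max_iter=max_iter)

    total = out["rho_w"] + out["rho_f"]
    pdff_vals = np.where(total > 0, out["rho_f"] / np.where(total > 0, total, 1.0), 0.0)
    pdff = np.zeros(image.shape)
    r2star = np.zeros(image.shape)
    field = np.zeros(image.shape)
    conv = np.zeros(image.shape, dtype=bool)
    pdff[mask] = pdff_vals
    r2star[mask] = out["r2star"]
    field[mask] = out["phi"]
    conv[mask] = out["converged"] & ~out["degenerate"]
    return PDFFMap(pdff=pdff, r2star=r2star, convergence_mask=conv, mask=mask, field_map=field)
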