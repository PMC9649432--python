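"""Three-point Dixon PDFF estimation (R2* neglected).

The fit is a variable-projection least squares: for a candidate field
frequency ``psi`` the data are demodulated by ``exp(+j2pi psi t_i)`` and the
complex water/fat amplitudes solve a 2-unknown linear problem against the
basis ``{1, exp(-j2pi df t_i)}``. Because the demodulation is unitary the
projected residual can be evaluated with one fixed 3x3 projector, so the
whole map is fit by a vectorized grid search over ``psi`` in the principal
interval ``(-|df|/2, +|df|/2]`` followed by golden-section refinement.

Note an identifiability fact used by the test suite: for *equally spaced*
echo triplets the projected residual is exactly periodic in ``psi`` with
period ``1/dTE`` (the demodulation change is a global phase absorbed by the
complex amplitudes), so field offsets alias without altering PDFF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import FitResult, MultiEchoImage, PDFFMap

__all__ = ["DixonConfig", "dixon_fit_voxel", "dixon_pdff_map"]

_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0  # golden-section ratio


@dataclass(frozen=True)
class DixonConfig:
    """Echo selection and field-search settings.

    ``echo_indices`` are 1-based indices into the protocol's echo train
    (default second, fourth and sixth echoes); ``psi_grid_points`` is the
    size of the coarse field-frequency grid; ``refine_tol`` the final
    golden-section bracket width in Hz.
    """

    echo_indices: tuple = (2, 4, 6)
    psi_grid_points: int = 128
    refine_tol: float = 1e-6

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.echo_indices)
        if len(idx) != 3 or len(set(idx)) != 3 or min(idx) < 1:
            raise ValueError("echo_indices must be three distinct 1-based indices")
        if self.psi_grid_points < 64:
            raise ValueError("psi_grid_points must be at least 64")
        if self.refine_tol <= 0:
            raise ValueError("refine_tol must be positive")
        object.__setattr__(self, "echo_indices", idx)


def _basis_projector(times: np.ndarray, fat_shift: float) -> tuple:
    """Return (B, Q) where Q projects onto the orthocomplement of span(B)."""
    c = np.exp(-1j * 2 * np.pi * fat_shift * times)
    B = np.column_stack([np.ones_like(c), c])  # (3, 2)
    pinv = np.linalg.pinv(B)
    Q = np.eye(3, dtype=complex) - B @ pinv
    return B, pinv, Q


def _residual2(psi: np.ndarray, y: np.ndarray, times: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Projected squared residual for per-voxel psi. y: (V, 3), psi: (V,)."""
    z = y * np.exp(1j * 2 * np.pi * psi[:, None] * times[None, :])
    r = z @ Q.T
    return np.einsum("vi,vi->v", r, r.conj()).real


def _fit_stack(y: np.ndarray, times: np.ndarray, fat_shift: float, config: DixonConfig) -> tuple:
    """Vectorized three-point fit. y: (V, 3) complex.

    Returns (rho_w, rho_f, psi, residual) arrays of shape (V,).
    """
    B, pinv, Q = _basis_projector(times, fat_shift)
    half = abs(fat_shift) / 2.0
    n_grid = config.psi_grid_points
    # grid over (-half, half]: offset so the right endpoint is included
    grid = -half + (np.arange(1, n_grid + 1) / n_grid) * (2 * half)
    step = grid[1] - grid[0]

    V = y.shape[0]
    res_grid = np.empty((n_grid, V))
    for k, psi in enumerate(grid):
        res_grid[k] = _residual2(np.full(V, psi), y, times, Q)
    best_res = res_grid.min(axis=0)
    # tie-break: among near-minimal grid points pick the smallest |psi|
    tol = best_res * 1e-9 + 1e-30
    near = res_grid <= (best_res + tol)[None, :]
    penal = np.where(near, np.abs(grid)[:, None], np.inf)
    k_best = penal.argmin(axis=0)

    # golden-section refinement within +/- one grid step
    a = grid[k_best] - step
    b = grid[k_best] + step
    c1 = b - _INVPHI * (b - a)
    c2 = a + _INVPHI * (b - a)
    f1 = _residual2(c1, y, times, Q)
    f2 = _residual2(c2, y, times, Q)
    n_iter = int(np.ceil(np.log(config.refine_tol / (2 * step)) / np.log(_INVPHI))) + 1
    for _ in range(max(n_iter, 1)):
        take1 = f1 < f2
        b = np.where(take1, c2, b)
        a = np.where(take1, a, c1)
        c1_new = b - _INVPHI * (b - a)
        c2_new = a + _INVPHI * (b - a)
        # only one new evaluation per voxel is mathematically needed; for
        # vectorization simplicity evaluate both candidate points
        f1 = _residual2(c1_new, y, times, Q)
        f2 = _residual2(c2_new, y, times, Q)
        c1, c2 = c1_new, c2_new
    psi = (a + b) / 2.0
    psi = np.clip(psi, -half, half)

    z = y * np.exp(1j * 2 * np.pi * psi[:, None] * times[None, :])
    amps = z @ pinv.T  # (V, 2) complex
    resid = np.sqrt(np.maximum(_residual2(psi, y, times, Q), 0.0))
    rho_w = np.abs(amps[:, 0])
    rho_f = np.abs(amps[:, 1])

    zero = np.all(y == 0, axis=1)
    rho_w[zero] = 0.0
    rho_f[zero] = 0.0
    psi = np.where(zero, 0.0, psi)
    resid[zero] = 0.0
    return rho_w, rho_f, psi, resid, zero


def dixon_fit_voxel(
    signal: np.ndarray,
    times: np.ndarray,
    fat_shift: float,
    config: DixonConfig = DixonConfig(),
) -> FitResult:
    """Fit one voxel from three complex echoes (times in seconds).

    Minimizes ``sum_i |y_i - (rho_w + rho_f e^{-j2pi df t_i}) e^{-j2pi psi t_i}|^2``
    over the complex amplitudes and the field frequency ``psi`` in
    ``(-|df|/2, +|df|/2]``, with R2* fixed at 0. Amplitude magnitudes are
    reported. An all-zero signal returns a degenerate zero fit.
    """
    signal = np.asarray(signal, dtype=complex).reshape(1, -1)
    times = np.asarray(times, dtype=float)
    if signal.shape[1] != 3 or times.shape != (3,):
        raise ValueError("dixon_fit_voxel needs exactly three echoes")
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal must be finite")
    if not np.all(np.diff(times) > 0):
        raise ValueError("echo times must be strictly increasing")
    rho_w, rho_f, psi, resid, zero = _fit_stack(signal, times, fat_shift, config)
    return FitResult(
        rho_w=float(rho_w[0]),
        rho_f=float(rho_f[0]),
        field_map_hz=float(psi[0]),
        r2star=0.0,
        residual=float(resid[0]),
        iterations=0,
        converged=True,
        degenerate=bool(zero[0]),
    )


def dixon_pdff_map(image: MultiEchoImage, config: DixonConfig = DixonConfig()) -> PDFFMap:
    """Voxelwise three-point Dixon PDFF map.

    Uses the configured echo triplet of the image's protocol; fits inside
    the truth mask when the image carries one, otherwise the whole frame.
    PDFF is ``rho_f / (rho_w + rho_f)`` with the 0/0 case defined as 0.
    """
    protocol = image.protocol
    idx0 = tuple(i - 1 for i in config.echo_indices)
    if max(idx0) >= protocol.n_echo:
        raise ValueError(
            f"echo index {max(config.echo_indices)} out of range for "
            f"{protocol.n_echo}-echo protocol"
        )
    times = np.asarray(protocol.echo_times_s)[list(idx0)]
    data = image.data[..., list(idx0)]

    mask = image.truth.mask if image.truth is not None else np.ones(image.shape, dtype=bool)
    y = data[mask]
    rho_w, rho_f, psi, resid, zero = _fit_stack(y, times, protocol.fat_shift_hz, config)

    total = rho_w + rho_f
    pdff_vals = np.where(total > 0, rho_f / np.where(total > 0, total, 1.0), 0.0)
    pdff = np.zeros(image.shape)
    field = np.zeros(image.shape)
    pdff[mask] = pdff_vals
    field[mask] = psi
    conv = np.zeros(image.shape, dtype=bool)
    conv[mask] = ~zero
    return PDFFMap(pdff=pdff, r2star=None, convergence_mask=conv, mask=mask, field_map=field)
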