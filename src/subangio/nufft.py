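"""Kaiser-Bessel gridding NUFFT on a precomputed sparse interpolation matrix.

Type-2 transform (image -> arbitrary k-space samples) implemented as
deapodization, zero-padded centered FFT on an oversampled grid, and sparse
kernel interpolation; the adjoint is the exact conjugate transpose of that
chain, so forward/adjoint pairs satisfy the inner-product identity to
machine precision independent of kernel accuracy.

Conventions: image indices are 0-based with the object centered at voxel
``n // 2``; k-space coordinates are in cycles/voxel with DC at 0, so the
forward model is ``s(k) = sum_r x[r] * exp(-2i*pi*k.(r - n//2))``.

Kernel width 6 and 2x oversampling with the Beatty beta keep the aliasing
error near 1e-6; a direct O(M*N) non-uniform DFT is provided as an oracle.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.special import i0

__all__ = ["Nufft3", "nudft3"]


def _kb_kernel(u: np.ndarray, width: float, beta: float) -> np.ndarray:
    """Unnormalized Kaiser-Bessel kernel on |u| <= width/2."""
    arg = 1.0 - (2.0 * u / width) ** 2
    out = np.zeros_like(u)
    ok = arg >= 0
    out[ok] = i0(beta * np.sqrt(arg[ok]))
    return out


def _kb_fourier(f: np.ndarray, width: float, beta: float) -> np.ndarray:
    """Continuous Fourier transform of the unnormalized KB kernel."""
    gamma_sq = beta**2 - (np.pi * width * f) ** 2
    out = np.empty_like(f, dtype=float)
    pos = gamma_sq > 0
    g = np.sqrt(np.abs(gamma_sq))
    out[pos] = width * np.sinh(g[pos]) / g[pos]
    out[~pos] = width * np.sinc(g[~pos] / np.pi)
    return out


class Nufft3:
    """3D gridding NUFFT for a fixed set of non-Cartesian coordinates."""

    def __init__(self, coords: np.ndarray, shape: tuple[int, int, int],
                 oversamp: float = 2.0, width: int = 6):
        coords = np.asarray(coords, float).reshape(-1, 3)
        if np.max(np.abs(coords)) > 0.5 + 1e-9:
            raise ValueError("coordinates must lie in [-0.5, 0.5] cycles/voxel")
        self.shape = tuple(int(n) for n in shape)
        self.n_samples = coords.shape[0]
        self.width = width
        grid = tuple(int(2 * np.ceil(oversamp * n / 2)) for n in self.shape)
        self.grid_shape = grid
        osf = grid[0] / self.shape[0]
        self.beta = np.pi * np.sqrt((width / osf) ** 2 * (osf - 0.5) ** 2 - 0.8)

        # per-axis neighbor indices and kernel weights
        idx_axes, w_axes = [], []
        for ax in range(3):
            kappa = coords[:, ax] * grid[ax]
            base = np.ceil(kappa - width / 2.0).astype(np.int64)
            offs = np.arange(width)
            g = base[:, None] + offs[None, :]                    # (M, w)
            w = _kb_kernel(kappa[:, None] - g, width, self.beta)
            idx_axes.append(np.mod(g + grid[ax] // 2, grid[ax]))
            w_axes.append(w)

        w = width
        vals = (w_axes[0][:, :, None, None]
                * w_axes[1][:, None, :, None]
                * w_axes[2][:, None, None, :]).reshape(self.n_samples, -1)
        cols = (idx_axes[0][:, :, None, None] * (grid[1] * grid[2])
                + idx_axes[1][:, None, :, None] * grid[2]
                + idx_axes[2][:, None, None, :]).reshape(self.n_samples, -1)
        rows = np.repeat(np.arange(self.n_samples), w**3)
        self._interp = sp.csr_matrix(
            (vals.ravel(), (rows, cols.ravel())),
            shape=(self.n_samples, int(np.prod(grid))),
        )

        # separable deapodization over the cropped (centered) image grid
        deapod = np.ones(self.shape)
        for ax in range(3):
            r = np.arange(self.shape[ax]) - self.shape[ax] // 2
            c = _kb_fourier(r / grid[ax], width, self.beta)
            shape_ax = [1, 1, 1]
            shape_ax[ax] = -1
            deapod = deapod * (1.0 / c).reshape(shape_ax)
        self._deapod = deapod
        self._pad_slices = tuple(
            slice(g // 2 - n // 2, g // 2 - n // 2 + n)
            for g, n in zip(grid, self.shape)
        )

    # -- forward -----------------------------------------------------------
    def forward(self, image: np.ndarray, rows=None) -> np.ndarray:
        """Evaluate k-space samples of ``image`` (optionally a row subset)."""
        if image.shape != self.shape:
            raise ValueError("image shape mismatch")
        padded = np.zeros(self.grid_shape, complex)
        padded[self._pad_slices] = image * self._deapod
        spectrum = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(padded)))
        flat = spectrum.ravel()
        mat = self._interp if rows is None else self._interp[rows]
        return mat @ flat

    # -- adjoint -----------------------------------------------------------
    def adjoint(self, samples: np.ndarray, rows=None) -> np.ndarray:
        """Exact adjoint of :meth:`forward`."""
        mat = self._interp if rows is None else self._interp[rows]
        grid_flat = mat.conj().T @ np.asarray(samples, complex)
        spectrum = grid_flat.reshape(self.grid_shape)
        image = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(spectrum)))
        image *= np.prod(self.grid_shape)
        return image[self._pad_slices] * self._deapod


def nudft3(image: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Direct non-uniform DFT oracle, O(M * N); small grids only."""
    shape = image.shape
    coords = np.asarray(coords, float).reshape(-1, 3)
    axes = [np.arange(n) - n // 2 for n in shape]
    rx, ry, rz = np.meshgrid(*axes, indexing="ij")
    r = np.stack([rx.ravel(), ry.ravel(), rz.ravel()], axis=1)
    phase = np.exp(-2j * np.pi * (coords @ r.T))
    return phase @ image.ravel().astype(complex)
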