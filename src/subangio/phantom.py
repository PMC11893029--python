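"""Single-vessel numerical phantom and simulated radial acquisition.

The phantom is a one-voxel-wide straight vessel through the volume center
with kinetic parameters ramping linearly along its length: transit time
0.25 -> 1.8 s, time-to-peak 0.1 -> 0.5 s, sharpness 1 -> 10 1/s, amplitude
1 on the vessel and 0 elsewhere, emulating increasing arrival delay and
dispersion downstream.  The 4D series is the kinetic-model timecourse per
vessel voxel, representing the control-label difference signal directly
(tag/control subtraction is an in-vivo preprocessing step).

K-space simulation applies the forward NUFFT per one-TR frame at the spokes
assigned to that timepoint, optionally weighted by coil sensitivities, with
optional seeded complex Gaussian noise (off by default: the reference
simulation is noiseless).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetic_model import SequenceParams, simulate_timecourses
from .nufft import Nufft3
from .trajectory import KSpaceSampling

__all__ = [
    "PHANTOM_RANGES",
    "VesselPhantom",
    "make_vessel_phantom",
    "phantom_series",
    "simulate_kspace",
]

#: Linear parameter ramps along the simulated vessel (entry -> exit).
PHANTOM_RANGES = {"delta_t": (0.25, 1.8), "p": (0.1, 0.5), "s": (1.0, 10.0)}


@dataclass
class VesselPhantom:
    """One-voxel-wide vessel with per-voxel kinetic parameters."""

    matrix_size: int
    vessel_axis: int
    delta_t: np.ndarray          # (matrix_size,) along the vessel
    s: np.ndarray
    p: np.ndarray
    amplitude: np.ndarray

    @property
    def vessel_indices(self) -> tuple:
        """Index tuple selecting the vessel line in a 3D volume."""
        c = self.matrix_size // 2
        idx = [c, c, c]
        idx[self.vessel_axis] = slice(None)
        return tuple(idx)

    def parameter_volumes(self) -> dict[str, np.ndarray]:
        """Ground-truth 3D maps (zero off the vessel, amplitude defines support)."""
        n = self.matrix_size
        out = {}
        for name in ("delta_t", "s", "p", "amplitude"):
            vol = np.zeros((n, n, n))
            vol[self.vessel_indices] = getattr(self, name)
            out[name] = vol
        return out


def make_vessel_phantom(matrix_size: int = 64,
                        ranges: dict | None = None,
                        vessel_axis: int = 0) -> VesselPhantom:
    """Linear parameter ramps along a centered one-voxel-wide vessel."""
    if matrix_size < 8:
        raise ValueError("matrix_size must be >= 8")
    ranges = {**PHANTOM_RANGES, **(ranges or {})}
    ramp = np.linspace(0.0, 1.0, matrix_size)

    def lin(key):
        lo, hi = ranges[key]
        return lo + (hi - lo) * ramp

    return VesselPhantom(
        matrix_size=matrix_size,
        vessel_axis=vessel_axis,
        delta_t=lin("delta_t"),
        s=lin("s"),
        p=lin("p"),
        amplitude=np.ones(matrix_size),
    )


def phantom_series(phantom: VesselPhantom, seq: SequenceParams,
                   dtype=np.complex64) -> np.ndarray:
    """4D image series (n_timepoints, n, n, n) of the phantom."""
    curves = simulate_timecourses(phantom.delta_t, phantom.s, phantom.p, seq,
                                  amplitude=phantom.amplitude)
    n = phantom.matrix_size
    series = np.zeros((seq.n_readouts, n, n, n), dtype=dtype)
    idx = (slice(None),) + phantom.vessel_indices
    series[idx] = curves.T.astype(dtype)
    return series


def simulate_kspace(series: np.ndarray, sampling: KSpaceSampling,
                    sensitivities: np.ndarray | None = None,
                    noise_sigma: float = 0.0, seed: int = 0,
                    nufft: Nufft3 | None = None) -> np.ndarray:
    """Forward-NUFFT acquisition of a 4D series along the sampling pattern.

    Returns complex data of shape (n_coils, n_timepoints, n_repeats,
    samples_per_spoke); ``sensitivities=None`` means one uniform coil.
    Frame ``i`` is evaluated only at the spokes assigned to timepoint ``i``.
    """
    n_t, nx, ny, nz = series.shape
    if n_t != sampling.n_timepoints:
        raise ValueError("series frames do not match sampling timepoints")
    if (nx, ny, nz) != (sampling.matrix_size,) * 3:
        raise ValueError("series grid does not match sampling matrix size")
    if sensitivities is None:
        sens = np.ones((1, nx, ny, nz), complex)
    else:
        sens = np.asarray(sensitivities, complex)
        if sens.shape[1:] != (nx, ny, nz):
            raise ValueError("sensitivity grid mismatch")
    if nufft is None:
        nufft = Nufft3(sampling.coords_flat(), (nx, ny, nz))

    sps = sampling.samples_per_spoke
    n_coils = sens.shape[0]
    data = np.zeros((n_coils, n_t, sampling.n_repeats, sps), complex)
    for i in range(n_t):
        spokes = sampling.assignment[i] - 1                   # 0-based
        rows = (spokes[:, None] * sps + np.arange(sps)).ravel()
        frame = np.asarray(series[i], complex)
        for c in range(n_coils):
            samples = nufft.forward(sens[c] * frame, rows=rows)
            data[c, i] = samples.reshape(sampling.n_repeats, sps)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        data = data + noise_sigma * (
            rng.standard_normal(data.shape)
            + 1j * rng.standard_normal(data.shape)
        )
    return data
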