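"""3D golden-ratio radial sampling with repeat-first spoke ordering.

Spoke ``m`` (1-based) points along azimuth ``2*pi*frac(m*phi1)`` and polar
angle ``arccos(frac(m*phi2))`` where ``(phi1, phi2)`` are the 3D golden
means derived from the real root of ``x**3 - x**2 - 1``.  Fractional parts
are taken before the trig functions (required for arccos; the azimuth is
2-pi periodic anyway).  Each spoke is a full diameter through the k-space
origin, so the hemispheric direction set still covers the sphere.

Acquisition ordering is repeat-first: the global spoke index advances over
the preparation repeats within one timepoint before moving to the next
timepoint, so every one-TR frame owns a contiguous golden-ratio run of
spokes and is itself approximately uniformly distributed.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .kinetic_model import SequenceParams

__all__ = [
    "golden_means",
    "spoke_direction",
    "build_sampling",
    "bin_frames",
    "KSpaceSampling",
]

KMAX = 0.5  # Nyquist radius, cycles/voxel


def golden_means() -> tuple[float, float]:
    """The two 3D golden means (phi1, phi2) = (1/psi, 1/psi**2).

    psi is the real root of x**3 - x**2 - 1 = 0.
    """
    roots = np.roots([1.0, -1.0, 0.0, -1.0])
    psi = float(roots[np.isreal(roots)].real.max())
    return 1.0 / psi, 1.0 / psi**2


def spoke_direction(m) -> np.ndarray:
    """Unit direction of the m-th golden-ratio spoke (m >= 1, vectorized)."""
    m = np.asarray(m)
    if np.any(m < 1):
        raise ValueError("spoke index m starts at 1")
    phi1, phi2 = golden_means()
    az = 2 * np.pi * np.mod(m * phi1, 1.0)
    cos_pol = np.mod(m * phi2, 1.0)
    sin_pol = np.sqrt(1.0 - cos_pol**2)
    return np.stack(
        [sin_pol * np.cos(az), sin_pol * np.sin(az), cos_pol], axis=-1
    )


@dataclass
class KSpaceSampling:
    """Spoke directions, sample coordinates, and the frame assignment.

    ``assignment[i, j]`` is the 1-based global spoke index acquired at
    timepoint ``i`` (0-based row) and repeat ``j`` (0-based column);
    coordinates are in cycles/voxel within the Nyquist ball.
    """

    spoke_directions: np.ndarray       # (n_spokes, 3)
    sample_coords: np.ndarray          # (n_spokes, samples_per_spoke, 3)
    assignment: np.ndarray             # (n_timepoints, n_repeats), 1-based
    samples_per_spoke: int
    matrix_size: int

    @property
    def n_timepoints(self) -> int:
        return self.assignment.shape[0]

    @property
    def n_repeats(self) -> int:
        return self.assignment.shape[1]

    @property
    def n_spokes(self) -> int:
        return self.spoke_directions.shape[0]

    def coords_flat(self) -> np.ndarray:
        """All sample coordinates, shape (n_spokes*samples_per_spoke, 3)."""
        return self.sample_coords.reshape(-1, 3)

    def timepoint_of_spoke(self) -> np.ndarray:
        """0-based timepoint index for each global spoke (spoke order)."""
        out = np.empty(self.n_spokes, int)
        for i in range(self.n_timepoints):
            out[self.assignment[i] - 1] = i
        return out

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("traj/coords",
                              data=self.sample_coords.astype(np.float32))
            fh.create_dataset("traj/assignment",
                              data=self.assignment.astype(np.int32))
            fh.attrs["n_timepoints"] = self.n_timepoints
            fh.attrs["n_repeats"] = self.n_repeats
            fh.attrs["samples_per_spoke"] = self.samples_per_spoke
            fh.attrs["matrix_size"] = self.matrix_size

    @classmethod
    def from_hdf5(cls, path) -> "KSpaceSampling":
        with h5py.File(path, "r") as fh:
            coords = fh["traj/coords"][()].astype(float)
            assignment = fh["traj/assignment"][()]
            sps = int(fh.attrs["samples_per_spoke"])
            ms = int(fh.attrs["matrix_size"])
        n_spokes = coords.shape[0]
        dirs = spoke_direction(np.arange(1, n_spokes + 1))
        return cls(spoke_directions=dirs, sample_coords=coords,
                   assignment=assignment, samples_per_spoke=sps, matrix_size=ms)


def build_sampling(seq: SequenceParams, n_repeats: int, matrix_size: int,
                   samples_per_spoke: int | None = None) -> KSpaceSampling:
    """Golden-ratio radial sampling for a full acquisition.

    Global spoke index m(i, j) = (i-1)*n_repeats + j with the repeat index
    varying fastest.  Each spoke is a diameter sampled uniformly from
    ``-kmax`` to ``+kmax*(1 - 2/samples_per_spoke)`` (2x readout
    oversampling by default).
    """
    if n_repeats < 1 or matrix_size < 1:
        raise ValueError("counts must be >= 1")
    if samples_per_spoke is None:
        samples_per_spoke = 2 * matrix_size
    n_timepoints = seq.n_readouts
    n_spokes = n_timepoints * n_repeats
    m = np.arange(1, n_spokes + 1)
    dirs = spoke_direction(m)
    radii = -KMAX + np.arange(samples_per_spoke) * (2 * KMAX / samples_per_spoke)
    coords = radii[None, :, None] * dirs[:, None, :]
    assignment = m.reshape(n_timepoints, n_repeats)
    return KSpaceSampling(
        spoke_directions=dirs,
        sample_coords=coords,
        assignment=assignment,
        samples_per_spoke=samples_per_spoke,
        matrix_size=matrix_size,
    )


def bin_frames(n_timepoints: int, bin_size: int,
               tr: float | None = None):
    """Contiguous non-overlapping temporal bins of one-TR timepoints.

    Returns a list of 0-based timepoint-index arrays, one per bin.  When
    ``tr`` is given, also returns the bin-center post-labeling delays in
    seconds (center of each temporal window, measured from the end of
    labeling).
    """
    if bin_size > n_timepoints:
        raise ValueError("bin_size exceeds number of timepoints")
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    starts = np.arange(0, n_timepoints, bin_size)
    bins = [np.arange(s, min(s + bin_size, n_timepoints)) for s in starts]
    if tr is None:
        return bins
    centers = np.array([(s + bin_size / 2.0) * tr for s in starts])
    return bins, centers
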