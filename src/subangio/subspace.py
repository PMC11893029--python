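"""Temporal subspace extraction from a simulated signal dictionary.

A dictionary of angiographic timecourses is simulated over a Cartesian grid
of kinetic parameters (transit time, sharpness, time-to-peak; the amplitude
is excluded since it does not affect the span).  The leading right singular
vectors of the dictionary form an orthonormal temporal basis ("principal
components"); each voxel's timecourse is then represented by K subspace
coefficients instead of N frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .kinetic_model import SequenceParams, KineticParams, simulate_timecourses

__all__ = [
    "DEFAULT_RANGES",
    "SignalDictionary",
    "TemporalSubspace",
    "parameter_grid",
    "build_dictionary",
    "extract_subspace",
    "relative_error",
    "nrmse_per_timepoint",
    "expand",
]

#: Physiological parameter ranges spanned by the dictionary:
#: transit time delta_t (s), sharpness s (1/s), time-to-peak p (s).
DEFAULT_RANGES = {"delta_t": (0.1, 2.0), "s": (1.0, 20.0), "p": (0.001, 0.5)}
DEFAULT_N_PER_AXIS = 40
DEFAULT_N_COMPONENTS = 12


@dataclass
class SignalDictionary:
    """Matrix of simulated timecourses (entries x timepoints) with its grid."""

    matrix: np.ndarray                      # (n_entries, N)
    grid: np.ndarray                        # (n_entries, 3) columns delta_t, s, p
    seq: SequenceParams

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        self.grid = np.asarray(self.grid, float)
        if self.matrix.shape[0] != self.grid.shape[0]:
            raise ValueError("dictionary rows and grid entries disagree")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("dictionary contains non-finite values")

    @property
    def n_entries(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[1]


@dataclass
class TemporalSubspace:
    """Orthonormal temporal basis Phi (N x K) with the singular values."""

    basis: np.ndarray                        # (N, K)
    singular_values: np.ndarray              # (min(n_entries, N),)
    seq: SequenceParams | None = None

    def __post_init__(self) -> None:
        self.basis = np.asarray(self.basis, float)
        self.singular_values = np.asarray(self.singular_values, float)
        gram = self.basis.T @ self.basis
        if not np.allclose(gram, np.eye(self.basis.shape[1]), atol=1e-10):
            raise ValueError("basis columns are not orthonormal")
        if np.any(np.diff(self.singular_values) > 1e-12):
            raise ValueError("singular values must be non-increasing")

    @property
    def n_components(self) -> int:
        return self.basis.shape[1]

    # -- HDF5 bundle -------------------------------------------------------
    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("subspace/basis", data=self.basis.astype(np.float64))
            fh.create_dataset("subspace/singular_values", data=self.singular_values)
            if self.seq is not None:
                for key, val in vars(self.seq).items():
                    fh.attrs[key] = val

    @classmethod
    def from_hdf5(cls, path) -> "TemporalSubspace":
        with h5py.File(path, "r") as fh:
            basis = fh["subspace/basis"][()]
            sv = fh["subspace/singular_values"][()]
            seq = None
            if "tr" in fh.attrs:
                seq = SequenceParams(**{k: fh.attrs[k].item() if hasattr(fh.attrs[k], "item") else fh.attrs[k]
                                        for k in SequenceParams.__dataclass_fields__})
        return cls(basis=basis, singular_values=sv, seq=seq)


def parameter_grid(ranges: dict | None = None,
                   n_per_axis: int = DEFAULT_N_PER_AXIS) -> np.ndarray:
    """Cartesian grid of (delta_t, s, p) triples, endpoints inclusive.

    The amplitude is fixed at 1 and excluded: it scales rows without
    changing the subspace they span.
    """
    ranges = {**DEFAULT_RANGES, **(ranges or {})}
    if n_per_axis < 2:
        raise ValueError("n_per_axis must be >= 2")
    axes = []
    for key in ("delta_t", "s", "p"):
        lo, hi = ranges[key]
        if not lo < hi:
            raise ValueError(f"invalid range for {key}: ({lo}, {hi})")
        axes.append(np.linspace(lo, hi, n_per_axis))
    dt, s, p = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([dt.ravel(), s.ravel(), p.ravel()])


def build_dictionary(grid: np.ndarray, seq: SequenceParams) -> SignalDictionary:
    """Simulate the timecourse of every grid entry (amplitude 1)."""
    grid = np.asarray(grid, float)
    if grid.size == 0:
        raise ValueError("empty parameter grid")
    mat = simulate_timecourses(grid[:, 0], grid[:, 1], grid[:, 2], seq)
    return SignalDictionary(matrix=mat, grid=grid, seq=seq)


def extract_subspace(dictionary: SignalDictionary,
                     n_components: int = DEFAULT_N_COMPONENTS) -> TemporalSubspace:
    """Leading right singular vectors of the dictionary matrix.

    The sign of each column is fixed so its largest-magnitude element is
    positive, making the basis reproducible across SVD implementations.
    """
    n = dictionary.n_timepoints
    if not 1 <= n_components <= n:
        raise ValueError("n_components out of range")
    _, sv, vt = np.linalg.svd(dictionary.matrix, full_matrices=False)
    basis = vt[:n_components].T.copy()
    flip = np.sign(basis[np.abs(basis).argmax(axis=0), np.arange(basis.shape[1])])
    basis *= np.where(flip == 0, 1.0, flip)
    return TemporalSubspace(basis=basis, singular_values=sv, seq=dictionary.seq)


def relative_error(dictionary: SignalDictionary, subspace: TemporalSubspace) -> float:
    """Frobenius-norm relative projection error of the dictionary, percent.

    100 * ||X - X Phi Phi^T||_F / ||X||_F.
    """
    x = dictionary.matrix
    norm = np.linalg.norm(x)
    if norm == 0:
        raise ValueError("zero-norm dictionary")
    phi = subspace.basis
    resid = x - (x @ phi) @ phi.T
    return 100.0 * np.linalg.norm(resid) / norm


def nrmse_per_timepoint(dictionary: SignalDictionary,
                        subspace: TemporalSubspace) -> np.ndarray:
    """Per-timepoint RMS residual normalized by the per-timepoint RMS signal."""
    x = dictionary.matrix
    phi = subspace.basis
    resid = x - (x @ phi) @ phi.T
    rms_resid = np.sqrt(np.mean(resid**2, axis=0))
    rms_signal = np.sqrt(np.mean(x**2, axis=0))
    out = np.zeros_like(rms_signal)
    nz = rms_signal > 0
    out[nz] = rms_resid[nz] / rms_signal[nz]
    return out


def expand(coefficients: np.ndarray, subspace: TemporalSubspace) -> np.ndarray:
    """Expand subspace coefficients to the full timecourse / frame series.

    ``coefficients`` has the component axis first: a K-vector yields an
    N-vector; a (K, *spatial) array yields (N, *spatial).
    """
    coeffs = np.asarray(coefficients)
    phi = subspace.basis
    if coeffs.shape[0] != phi.shape[1]:
        raise ValueError("coefficient count does not match basis size")
    return np.tensordot(phi, coeffs, axes=(1, 0))
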